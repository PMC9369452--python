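"""Synthetic knob tracks and metric tables.

Every downstream stage can be exercised without any structural database:

* :func:`generate_knob_track` inverts extraction — it lays knob residues
  along a helix by cumulatively summing a chosen decomposition, optionally
  repeated, and can inject the one irregularity whose handling is fully
  specified: a second contact residue immediately following a knob
  (unit-distance pair), plus optional genuinely irregular gaps.
* :func:`generate_metrics_table` draws the three structural metrics for a
  demanding and a non-demanding group from normal distributions (negative
  draws clipped to 0) over decompositions sampled from a supplied pool.

Defaults mirror the observed data shapes: 25 demanding coiled coils out
of 2284, group means 0.112/0.071 (highest local period deviation),
0.109/0.085 (local period range) and 0.713/0.622 Angstroem (local radius
range).  Spreads are free parameters; see the package methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .classify import is_demanding
from .compare import METRICS, MetricsRecord
from .enumeration import Decomposition
from .extract import KnobTrack

__all__ = [
    "DEFAULT_METRIC_MEANS",
    "DEFAULT_METRIC_SDS",
    "SyntheticConfig",
    "generate_knob_track",
    "generate_metrics_table",
]

#: (demanding, non-demanding) group means per metric.
DEFAULT_METRIC_MEANS: Dict[str, Tuple[float, float]] = {
    "max_period_dev": (0.112, 0.071),
    "period_range": (0.109, 0.085),
    "radius_range": (0.713, 0.622),
}

#: Within-group standard deviations (same for both groups by default);
#: chosen at roughly half the group mean, a typical spread for
#: range-type geometry summaries.
DEFAULT_METRIC_SDS: Dict[str, Tuple[float, float]] = {
    "max_period_dev": (0.05, 0.05),
    "period_range": (0.05, 0.05),
    "radius_range": (0.35, 0.35),
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Reproducible recipe for synthetic tables and tracks."""

    seed: int = 0
    n_demanding: int = 25
    n_other: int = 2259
    metric_means: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_METRIC_MEANS)
    )
    metric_sds: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_METRIC_SDS)
    )
    unit_pair_rate: float = 0.05
    repeats: int = 1

    def __post_init__(self) -> None:
        if self.n_demanding < 0 or self.n_other < 0:
            raise ValueError("group sizes must be >= 0")
        if not 0.0 <= self.unit_pair_rate <= 1.0:
            raise ValueError("unit_pair_rate must lie in [0, 1]")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        for name in METRICS:
            sds = self.metric_sds[name]
            if any(s <= 0 for s in sds):
                raise ValueError(f"{name}: standard deviations must be > 0")


def generate_knob_track(
    decomposition: Sequence[int],
    repeats: int = 1,
    start: int = 0,
    unit_pair_rate: float = 0.0,
    seed: int | None = None,
    *,
    record_id: str = "synthetic",
    chain: str = "A",
    rng: np.random.Generator | None = None,
) -> KnobTrack:
    """Knob positions realising a decomposition, with optional pair noise.

    Positions are cumulative sums of the decomposition repeated
    ``repeats`` times from ``start``.  With probability
    ``unit_pair_rate``, each knob after the first gains a partner residue
    one position downstream — the detection artefact that the extraction
    collapse removes, so extraction of a noisy track recovers the clean
    one exactly.
    """
    parts = tuple(int(p) for p in decomposition)
    if not parts or any(p < 2 for p in parts):
        raise ValueError("decomposition parts must all be >= 2")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    if not 0.0 <= unit_pair_rate <= 1.0:
        raise ValueError("unit_pair_rate must lie in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    knobs = [start]
    for p in parts * repeats:
        knobs.append(knobs[-1] + p)
    positions: List[int] = [knobs[0]]
    for k in knobs[1:]:
        positions.append(k)
        if unit_pair_rate and rng.random() < unit_pair_rate:
            positions.append(k + 1)
    return KnobTrack(record_id=record_id, chain=chain, positions=tuple(positions))


def generate_metrics_table(
    config: SyntheticConfig,
    decomposition_pool: Sequence[Decomposition | Sequence[int]],
) -> List[MetricsRecord]:
    """Draw a two-group metrics table.

    ``decomposition_pool`` (typically enumeration output) must contain at
    least one demanding and one non-demanding decomposition when the
    corresponding group size is positive.  Metrics are independent
    normals per group with negatives clipped to 0; fully reproducible
    from ``config.seed``.
    """
    pool_parts = [
        tuple(d.parts) if isinstance(d, Decomposition) else tuple(int(p) for p in d)
        for d in decomposition_pool
    ]
    groups = {
        True: sorted(p for p in pool_parts if is_demanding(p)),
        False: sorted(p for p in pool_parts if not is_demanding(p)),
    }
    sizes = {True: config.n_demanding, False: config.n_other}
    for demanding, size in sizes.items():
        if size > 0 and not groups[demanding]:
            label = "demanding" if demanding else "non-demanding"
            raise ValueError(f"decomposition pool lacks a {label} decomposition")

    rng = np.random.default_rng(config.seed)
    records: List[MetricsRecord] = []
    for demanding, prefix in ((True, "syn-dem"), (False, "syn-oth")):
        size = sizes[demanding]
        if size == 0:
            continue
        pool = groups[demanding]
        choice = rng.integers(0, len(pool), size=size)
        draws = {}
        for name in METRICS:
            mean = config.metric_means[name][0 if demanding else 1]
            sd = config.metric_sds[name][0 if demanding else 1]
            draws[name] = np.clip(rng.normal(mean, sd, size=size), 0.0, None)
        for i in range(size):
            parts = pool[int(choice[i])]
            records.append(
                MetricsRecord(
                    record_id=f"{prefix}-{i:04d}",
                    decomposition=parts,
                    demanding=demanding,
                    max_period_dev=float(draws["max_period_dev"][i]),
                    period_range=float(draws["period_range"][i]),
                    radius_range=float(draws["radius_range"][i]),
                )
            )
    return records
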