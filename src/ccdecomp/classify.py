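"""Run-length classification of decompositions.

Adjacent repeats of the same short distance strain helix geometry: a 3+3
repeat locally overwinds the helix and a 4+4 repeat unwinds it.  Two
rotation-invariant classifiers follow from this:

* *demanding* — contains at least one adjacent 3+3 or 4+4 pair;
* *long run* — contains a run of 3s or of 4s longer than two, a pattern
  not observed in natural dimeric coiled coils.

Runs are counted cyclically (wrap-around), so both labels are properties
of the rotation class rather than of the chosen representative.  Runs of 7
are ignored: a 7 is a full heptad and imposes no extra strain.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence

from .enumeration import DistanceAlphabet, enumerate_decompositions

__all__ = [
    "STRAINED_DISTANCES",
    "max_cyclic_run",
    "is_demanding",
    "has_long_run",
    "PeriodTally",
    "tally_periods",
]

#: Distances whose adjacent repetition strains the helix.
STRAINED_DISTANCES = (3, 4)


def max_cyclic_run(parts: Sequence[int], value: int) -> int:
    """Longest run of consecutive ``value`` entries in the cyclic sequence.

    Wrap-around counts: ``[4, 3, 4]`` has a cyclic run of two 4s.  If every
    part equals ``value`` the run is the whole sequence (no self-wrap
    multiplication); a single-part sequence ``[v]`` therefore has run 1.
    Rotation-invariant by construction.
    """
    parts = tuple(parts)
    if not parts:
        raise ValueError("parts must be non-empty")
    if all(p == value for p in parts):
        return len(parts)
    if value not in parts:
        return 0
    # Doubling linearizes the single wrap; safe because not all-equal.
    best = cur = 0
    for p in parts + parts:
        cur = cur + 1 if p == value else 0
        if cur > best:
            best = cur
    return best


def is_demanding(parts: Sequence[int]) -> bool:
    """True iff the cyclic sequence contains an adjacent 3+3 or 4+4 pair."""
    return any(max_cyclic_run(parts, v) >= 2 for v in STRAINED_DISTANCES)


def has_long_run(parts: Sequence[int]) -> bool:
    """True iff some cyclic run of 3s or of 4s is longer than two."""
    return any(max_cyclic_run(parts, v) >= 3 for v in STRAINED_DISTANCES)


@dataclass(frozen=True)
class PeriodTally:
    """Per-period decomposition counts.

    ``n_total`` non-redundant decompositions, of which ``n_no_long_run``
    survive the long-run filter and ``n_demanding`` carry a 3+3 or 4+4
    repeat.
    """

    period: int
    n_total: int
    n_no_long_run: int
    n_demanding: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_no_long_run <= self.n_total:
            raise ValueError("n_no_long_run out of range")
        if not 0 <= self.n_demanding <= self.n_total:
            raise ValueError("n_demanding out of range")


def tally_periods(
    max_period: int,
    alphabet: DistanceAlphabet | None = None,
    **enumerate_kwargs,
) -> List[PeriodTally]:
    """Classify every enumerated decomposition per period.

    One :class:`PeriodTally` per period from the smallest distance up to
    ``max_period``, in ascending order.
    """
    sets = enumerate_decompositions(max_period, alphabet, **enumerate_kwargs)
    tallies = []
    for period in sorted(sets):
        dset = sets[period]
        parts_list = [d.parts for d in dset]
        tallies.append(
            PeriodTally(
                period=period,
                n_total=len(parts_list),
                n_no_long_run=sum(not has_long_run(p) for p in parts_list),
                n_demanding=sum(is_demanding(p) for p in parts_list),
            )
        )
    return tallies
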