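"""From observed knob positions to a decomposition.

A knob track is the ordered list of residue indices (0-based) identified
as interhelical contact residues along one helix of one coiled coil.
Occasionally two neighbouring residues both form contacts, producing a
unit distance that is an artefact of contact detection rather than a
genuine period feature; from any such pair only the residue closest to the
N-terminus is considered.  The surviving inter-knob distances form the
decomposition; distances outside the alphabet are flagged as irregular.

The extracted decomposition keeps the full observed distance list — its
period is the full span of the repeat — because observed periods can be an
order of magnitude above the smallest distances; reduction to the
primitive rotation class is a separate, opt-in step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import FrozenSet, List, Sequence, Tuple

from .enumeration import Decomposition, DistanceAlphabet, canonical, primitive_root

__all__ = [
    "KnobTrack",
    "ExtractionResult",
    "distances_from_positions",
    "collapse_unit_distances",
    "extract_decomposition",
    "reduce_to_primitive",
    "read_knob_tracks",
    "write_extractions",
]

logger = logging.getLogger(__name__)

_TRACK_COLUMNS = ("record_id", "chain", "positions")
_RESULT_COLUMNS = (
    "record_id",
    "chain",
    "period",
    "decomposition",
    "irregular",
    "regular",
    "n_collapsed",
)


@dataclass(frozen=True)
class KnobTrack:
    """Ordered residue indices of knob residues along one helix.

    ``positions`` are 0-based and strictly increasing; at least two are
    required for any distance to exist.
    """

    record_id: str
    chain: str
    positions: Tuple[int, ...]

    def __post_init__(self) -> None:
        positions = tuple(int(p) for p in self.positions)
        if len(positions) < 2:
            raise ValueError(
                f"{self.record_id}: a knob track needs at least 2 positions"
            )
        if any(b <= a for a, b in zip(positions, positions[1:])):
            raise ValueError(
                f"{self.record_id}: positions must be strictly increasing"
            )
        object.__setattr__(self, "positions", positions)


@dataclass(frozen=True)
class ExtractionResult:
    """Decomposition extracted from one knob track.

    ``raw_distances`` are the successive differences before the unit-
    distance collapse; ``distances`` are the differences between the kept
    positions, all >= 2; ``irregular`` collects distances outside the
    alphabet.  ``long_collapse`` marks tracks where a run of three or more
    consecutive residues was collapsed (beyond the simple two-residue pair
    the collapse rule was designed for).
    """

    record_id: str
    chain: str
    raw_distances: Tuple[int, ...]
    kept_positions: Tuple[int, ...]
    distances: Tuple[int, ...]
    irregular: FrozenSet[int]
    long_collapse: bool = False

    @property
    def period(self) -> int:
        return sum(self.distances)

    @property
    def regular(self) -> bool:
        return not self.irregular

    @property
    def n_collapsed(self) -> int:
        return len(self.raw_distances) + 1 - len(self.kept_positions)


def distances_from_positions(positions: Sequence[int]) -> Tuple[int, ...]:
    """Successive differences between knob positions."""
    positions = tuple(positions)
    if len(positions) < 2:
        raise ValueError("need at least 2 positions")
    if any(b <= a for a, b in zip(positions, positions[1:])):
        raise ValueError("positions must be strictly increasing")
    return tuple(b - a for a, b in zip(positions, positions[1:]))


def collapse_unit_distances(positions: Sequence[int]) -> Tuple[int, ...]:
    """Drop the C-terminal residue of every unit-distance knob pair.

    Greedy N-to-C scan: the first position is always kept, and each later
    position is kept only if it lies >= 2 residues after the last kept
    one.  For an isolated neighbouring pair this keeps exactly the residue
    closest to the N-terminus; for a run of consecutive residues it keeps
    every other one.
    """
    positions = tuple(positions)
    if any(b <= a for a, b in zip(positions, positions[1:])):
        raise ValueError("positions must be strictly increasing")
    if not positions:
        return ()
    kept = [positions[0]]
    for p in positions[1:]:
        if p - kept[-1] >= 2:
            kept.append(p)
    return tuple(kept)


def extract_decomposition(
    track: KnobTrack, alphabet: DistanceAlphabet | None = None
) -> ExtractionResult:
    """Full pipeline: collapse unit distances, then take differences.

    The decomposition is the full observed distance list (period = total
    span); irregular distances are kept and flagged, not dropped.

    Raises
    ------
    ValueError
        If fewer than two positions survive the collapse — no
        decomposition exists.
    """
    if alphabet is None:
        alphabet = DistanceAlphabet()
    raw = distances_from_positions(track.positions)
    kept = collapse_unit_distances(track.positions)
    if len(kept) < 2:
        raise ValueError(
            f"{track.record_id}: no decomposition — fewer than 2 knobs "
            f"remain after collapsing unit distances"
        )
    # a run of >= 3 consecutive residues collapses more than one per pair
    run = best_run = 1
    for a, b in zip(track.positions, track.positions[1:]):
        run = run + 1 if b - a == 1 else 1
        best_run = max(best_run, run)
    long_collapse = best_run >= 3
    if long_collapse:
        logger.warning(
            "%s: collapsed a run of %d consecutive knob residues",
            track.record_id,
            best_run,
        )
    distances = tuple(b - a for a, b in zip(kept, kept[1:]))
    irregular = frozenset(d for d in distances if d not in alphabet)
    return ExtractionResult(
        record_id=track.record_id,
        chain=track.chain,
        raw_distances=raw,
        kept_positions=kept,
        distances=distances,
        irregular=irregular,
        long_collapse=long_collapse,
    )


def reduce_to_primitive(distances: Sequence[int]) -> Decomposition:
    """Canonical primitive rotation class of an observed distance list.

    ``[3,4,3,4]`` describes the same cyclic contact pattern as ``[3,4]``;
    the smallest period is the honest one.
    """
    root, _ = primitive_root(distances)
    return Decomposition(canonical(root))


def read_knob_tracks(path, *, one_based: bool = False) -> List[KnobTrack]:
    """Read knob tracks from TSV.

    Columns ``record_id``, ``chain``, ``positions`` (comma-separated
    integers); ``#`` comment lines permitted; a header row is required.
    Malformed rows raise with their line number.  ``one_based`` shifts
    incoming indices down by one.
    """
    path = Path(path)
    tracks: List[KnobTrack] = []
    header_seen = False
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if not header_seen:
                if tuple(fields) != _TRACK_COLUMNS:
                    expected = "\t".join(_TRACK_COLUMNS)
                    raise ValueError(
                        f"{path}:{lineno}: expected header {expected!r}, "
                        f"got {line!r}"
                    )
                header_seen = True
                continue
            if len(fields) != 3:
                raise ValueError(
                    f"{path}:{lineno}: expected 3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            record_id, chain, positions_text = fields
            try:
                positions = tuple(
                    int(tok) for tok in positions_text.split(",") if tok.strip()
                )
                if one_based:
                    positions = tuple(p - 1 for p in positions)
                track = KnobTrack(record_id, chain, positions)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            tracks.append(track)
    if not tracks:
        logger.warning("%s: no knob tracks found", path)
    return tracks


def write_extractions(path, results: Sequence[ExtractionResult]) -> None:
    """Write extraction results as TSV (deterministic row order: input
    order preserved)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(_RESULT_COLUMNS) + "\n")
        for r in results:
            fh.write(
                "\t".join(
                    (
                        r.record_id,
                        r.chain,
                        str(r.period),
                        "+".join(str(d) for d in r.distances),
                        "+".join(str(d) for d in sorted(r.irregular)),
                        str(int(r.regular)),
                        str(r.n_collapsed),
                    )
                )
                + "\n"
            )
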