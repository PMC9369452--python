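"""Enumeration and counting of coiled-coil period decompositions.

A *decomposition* is the cyclic sequence of sequence-distances between
successive interhelical contact ("knob") residues along one helix of a
coiled coil; its sum is the *period*.  In near-canonical coiled coils the
distances are drawn from {3, 4, 7}.  Two decompositions are the same object
when one is a cyclic rotation of the other, and a decomposition is only
counted for the smallest period it describes (a sequence that is a
repetition of a shorter sequence is redundant).

This module provides

* the bottom-up concatenation construction that builds every non-redundant
  decomposition of each period up to a maximum, storing rotational copies
  so later candidates can be recognised as duplicates;
* an independent brute-force oracle that exhausts all linear compositions
  of a single period and merges rotation classes;
* exact counting: the linear weighted-string recursion
  ``x[m] = sum_i x[m - a_i]`` with ``x[0] = 1``, and a Moebius-inversion
  closed form for the number of primitive rotation classes, which scales
  far past the range where explicit enumeration is feasible;
* Sylvester's two-coin Frobenius number.

Counts grow like ``1.29**n`` for the default alphabet, so all counting is
done with Python's arbitrary-precision integers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Sequence, Set, Tuple

from sympy import divisors, mobius

__all__ = [
    "DEFAULT_DISTANCES",
    "DEFAULT_ENUMERATION_CAP",
    "DistanceAlphabet",
    "Decomposition",
    "DecompositionSet",
    "CountTable",
    "rotations",
    "canonical",
    "primitive_root",
    "enumerate_decompositions",
    "enumerate_brute_force",
    "count_linear",
    "count_primitive_necklaces",
    "frobenius_two",
]

#: Distances between knob residues compatible with alpha-helical geometry.
DEFAULT_DISTANCES: Tuple[int, ...] = (3, 4, 7)

#: Periods above this are refused by explicit enumeration unless forced;
#: the number of members grows exponentially, while counting stays cheap.
DEFAULT_ENUMERATION_CAP: int = 80


@dataclass(frozen=True)
class DistanceAlphabet:
    """The allowed contact distances (coin values of the underlying
    money-changing problem).

    Parameters
    ----------
    distances
        Strictly increasing integers, each >= 2.  Defaults to ``(3, 4, 7)``,
        the knob-to-knob distances of canonical and single-insertion
        coiled-coil motifs (heptad = 3+4, decad = 3+3+4, ...).
    """

    distances: Tuple[int, ...] = DEFAULT_DISTANCES

    def __post_init__(self) -> None:
        distances = tuple(int(d) for d in self.distances)
        if not distances:
            raise ValueError("alphabet must contain at least one distance")
        if any(d < 2 for d in distances):
            raise ValueError("alphabet distances must all be >= 2")
        if any(b <= a for a, b in zip(distances, distances[1:])):
            raise ValueError("alphabet distances must be strictly increasing")
        object.__setattr__(self, "distances", distances)

    @property
    def min_distance(self) -> int:
        return self.distances[0]

    @property
    def min_concat(self) -> int:
        """Smallest period reachable by concatenating two decompositions
        (sum of the two smallest distances)."""
        if len(self.distances) == 1:
            return 2 * self.distances[0]
        return self.distances[0] + self.distances[1]

    def __contains__(self, value: object) -> bool:
        return value in self.distances

    def __iter__(self) -> Iterator[int]:
        return iter(self.distances)


def _as_parts(parts: Sequence[int]) -> Tuple[int, ...]:
    out = tuple(int(p) for p in parts)
    if not out:
        raise ValueError("parts must be non-empty")
    if any(p < 1 for p in out):
        raise ValueError("parts must be positive integers")
    return out


def rotations(parts: Sequence[int]) -> Set[Tuple[int, ...]]:
    """All distinct cyclic rotations of ``parts``.

    The number of distinct rotations equals the part count of the primitive
    root: ``len(rotations([3,4,3,4])) == 2``.
    """
    t = _as_parts(parts)
    return {t[i:] + t[:i] for i in range(len(t))}


def canonical(parts: Sequence[int]) -> Tuple[int, ...]:
    """Lexicographically smallest rotation — the class representative.

    The choice of representative within a rotation class is arbitrary in
    principle; fixing the lexicographic minimum makes set comparisons and
    file outputs deterministic.
    """
    return min(rotations(parts))


def primitive_root(parts: Sequence[int]) -> Tuple[Tuple[int, ...], int]:
    """Shortest sequence whose repetition gives ``parts``.

    Returns ``(root, multiplicity)`` with ``root * multiplicity == parts``.
    A sequence is *primitive* iff its multiplicity is 1; e.g. ``[3,4,3,4]``
    has root ``[3,4]`` and multiplicity 2, so as a cyclic object it belongs
    to period 7, not 14.
    """
    t = _as_parts(parts)
    n = len(t)
    for length in range(1, n + 1):
        if n % length == 0 and t[:length] * (n // length) == t:
            return t[:length], n // length
    raise AssertionError("unreachable: full length always divides")


@dataclass(frozen=True, order=True)
class Decomposition:
    """A cyclic sequence of knob-to-knob distances summing to the period."""

    parts: Tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "parts", _as_parts(self.parts))

    @property
    def period(self) -> int:
        return sum(self.parts)

    @property
    def is_canonical(self) -> bool:
        return self.parts == canonical(self.parts)

    @property
    def is_primitive(self) -> bool:
        return primitive_root(self.parts)[1] == 1

    def canonicalized(self) -> "Decomposition":
        return Decomposition(canonical(self.parts))

    def __str__(self) -> str:
        return "+".join(str(p) for p in self.parts)

    @classmethod
    def from_string(cls, text: str) -> "Decomposition":
        return cls(tuple(int(p) for p in text.split("+")))


@dataclass(frozen=True)
class DecompositionSet:
    """All non-redundant decompositions of one period.

    ``members`` holds one canonical representative per rotation class;
    ``rotational_registry`` holds every rotation of every member and is the
    working set the construction compares new candidates against.
    """

    period: int
    members: frozenset
    rotational_registry: frozenset

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self) -> Iterator[Decomposition]:
        return iter(sorted(self.members))

    def __contains__(self, item: object) -> bool:
        if isinstance(item, Decomposition):
            return item.canonicalized() in self.members
        return Decomposition(canonical(item)) in self.members


def enumerate_decompositions(
    max_period: int,
    alphabet: DistanceAlphabet | None = None,
    *,
    cap: int = DEFAULT_ENUMERATION_CAP,
    force: bool = False,
) -> Dict[int, DecompositionSet]:
    """Build every non-redundant decomposition of each period up to
    ``max_period`` by bottom-up concatenation.

    For each period ``i`` from the smallest distance upward: ``[i]`` is a
    member whenever ``i`` is itself an alphabet distance; and for every
    split ``i = x + (i - x)`` with ``min <= x <= i/2``, every concatenation
    of a stored rotational copy of a decomposition of ``x`` with one of
    ``i - x`` is a candidate.  Candidates are rejected when they are a
    repetition of a shorter sequence or already present (in any rotation)
    among this period's accepted members; on acceptance all rotational
    copies are stored so later duplicates are recognised.

    Parameters
    ----------
    max_period
        Largest period to build (inclusive); must be >= the smallest
        alphabet distance.
    cap, force
        Explicit enumeration is refused above ``cap`` unless ``force`` is
        set, because the member count grows exponentially; use
        :func:`count_primitive_necklaces` for large periods.

    Returns
    -------
    dict mapping each period in ``[min_distance, max_period]`` to its
    :class:`DecompositionSet` (possibly empty).
    """
    if alphabet is None:
        alphabet = DistanceAlphabet()
    if not isinstance(max_period, int) or isinstance(max_period, bool):
        raise TypeError(f"max_period must be an integer, got {max_period!r}")
    lo = alphabet.min_distance
    if max_period < lo:
        raise ValueError(
            f"max_period {max_period} is below the smallest distance {lo}"
        )
    if max_period > cap and not force:
        raise ValueError(
            f"max_period {max_period} exceeds the enumeration cap {cap}; "
            f"pass force=True to override, or use count_primitive_necklaces"
        )

    # Per-period registry of all rotations of accepted members.  Lists keep
    # a deterministic construction order; sets give O(1) duplicate checks.
    reg_list: Dict[int, List[Tuple[int, ...]]] = {}
    reg_set: Dict[int, Set[Tuple[int, ...]]] = {}
    members: Dict[int, List[Tuple[int, ...]]] = {}

    for i in range(lo, max_period + 1):
        mem: List[Tuple[int, ...]] = []
        rlist: List[Tuple[int, ...]] = []
        rset: Set[Tuple[int, ...]] = set()
        rejected: Set[Tuple[int, ...]] = set()

        def accept(cand: Tuple[int, ...]) -> None:
            rots = sorted(rotations(cand))
            mem.append(rots[0])
            rlist.extend(rots)
            rset.update(rots)

        if i in alphabet:
            accept((i,))
        if i >= alphabet.min_concat:
            for x in range(lo, i // 2 + 1):
                left = reg_list.get(x, ())
                right = reg_list.get(i - x, ())
                if not left or not right:
                    continue
                for u in left:
                    for v in right:
                        cand = u + v
                        if cand in rset or cand in rejected:
                            continue
                        # repetition of a shorter sequence -> redundant
                        if len(rotations(cand)) != len(cand):
                            rejected.add(cand)
                            continue
                        accept(cand)
        reg_list[i] = rlist
        reg_set[i] = rset
        members[i] = mem

    return {
        i: DecompositionSet(
            period=i,
            members=frozenset(Decomposition(m) for m in members[i]),
            rotational_registry=frozenset(reg_set[i]),
        )
        for i in range(lo, max_period + 1)
    }


def _linear_compositions(
    period: int, distances: Tuple[int, ...]
) -> List[Tuple[int, ...]]:
    """All ordered sequences over ``distances`` summing to ``period``."""
    out: List[Tuple[int, ...]] = []
    stack: List[Tuple[Tuple[int, ...], int]] = [((), period)]
    while stack:
        prefix, rem = stack.pop()
        if rem == 0:
            out.append(prefix)
            continue
        for a in distances:
            if a <= rem:
                stack.append((prefix + (a,), rem - a))
    return out


def enumerate_brute_force(
    period: int, alphabet: DistanceAlphabet | None = None
) -> Set[Decomposition]:
    """Independent oracle: exhaust all linear compositions of ``period``,
    merge rotation classes, and drop non-primitive classes.

    A class is primitive exactly when its number of distinct rotations
    equals its part count.  Must agree with
    :func:`enumerate_decompositions` for every period.
    """
    if alphabet is None:
        alphabet = DistanceAlphabet()
    if period < 1:
        raise ValueError("period must be >= 1")
    pool = set(_linear_compositions(period, alphabet.distances))
    out: Set[Decomposition] = set()
    while pool:
        s = pool.pop()
        rots = rotations(s)
        pool.difference_update(rots)
        if len(rots) == len(s):
            out.add(Decomposition(min(rots)))
    return out


@dataclass
class CountTable:
    """Lazy table of the weighted-string counts ``x[m]``.

    ``x[m]`` is the number of ordered sequences over the alphabet summing
    to ``m`` (rotations counted separately), with ``x[0] = 1``, satisfying
    the recursion ``x[m] = sum_i x[m - a_i]``.  Exact big-integer
    arithmetic throughout: the counts grow geometrically (ratio ~1.29 for
    the default alphabet) and must stay exact at periods of 140 and beyond.
    """

    alphabet: DistanceAlphabet = field(default_factory=DistanceAlphabet)
    values: Dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values.setdefault(0, 1)

    def count(self, m: int) -> int:
        if m < 0:
            raise ValueError("mass must be non-negative")
        top = max(self.values)
        for n in range(top + 1, m + 1):
            self.values[n] = sum(
                self.values[n - a] for a in self.alphabet.distances if a <= n
            )
        return self.values[m]


def count_linear(m: int, alphabet: DistanceAlphabet | None = None) -> int:
    """Number of ordered alphabet sequences with sum ``m`` (``x[m]``)."""
    return CountTable(alphabet or DistanceAlphabet()).count(m)


def count_primitive_necklaces(
    n: int, alphabet: DistanceAlphabet | None = None
) -> int:
    """Closed-form count of non-redundant rotation classes of mass ``n``.

    Moebius inversion over repetition multiplicity: with ``L(m, k)`` the
    number of ordered compositions of ``m`` into exactly ``k`` alphabet
    parts,

        P(n) = sum_k (1/k) * sum_{d | gcd(n, k)} mu(d) * L(n/d, k/d).

    Agrees with ``len(enumerate_decompositions(n)[n])`` everywhere while
    remaining cheap for ``n`` in the hundreds, where explicit enumeration
    is infeasible.
    """
    if alphabet is None:
        alphabet = DistanceAlphabet()
    if n < 1:
        raise ValueError("n must be >= 1")
    kmax = n // alphabet.min_distance
    if kmax == 0:
        return 0
    # L[m][k]: compositions of m into exactly k parts, exact integers.
    L = [[0] * (kmax + 1) for _ in range(n + 1)]
    L[0][0] = 1
    for m in range(1, n + 1):
        row = L[m]
        for k in range(1, kmax + 1):
            row[k] = sum(
                L[m - a][k - 1] for a in alphabet.distances if a <= m
            )
    total = 0
    for k in range(1, kmax + 1):
        inner = 0
        for d in divisors(math.gcd(n, k)):
            inner += int(mobius(d)) * L[n // d][k // d]
        if inner % k:
            raise AssertionError("Moebius sum not divisible by class size")
        total += inner // k
    return total


def frobenius_two(x1: int, x2: int) -> int:
    """Sylvester's two-coin Frobenius number ``x1*x2 - x1 - x2``:
    the largest integer not representable as a non-negative combination of
    the coprime pair ``(x1, x2)``.
    """
    if x1 < 2 or x2 < 2:
        raise ValueError("both values must be >= 2")
    if math.gcd(x1, x2) != 1:
        raise ValueError(f"({x1}, {x2}) are not coprime; Frobenius number undefined")
    return x1 * x2 - x1 - x2
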