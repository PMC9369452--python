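"""Two-group comparison of structural metrics.

Coiled coils whose decomposition is *demanding* (contains an adjacent 3+3
or 4+4 distance repeat) are compared with the rest on three per-structure
summaries of local geometry:

* ``max_period_dev`` — highest absolute deviation of local periodicity
  from the 3.5 residues-per-turn baseline;
* ``period_range``   — max minus min local periodicity;
* ``radius_range``   — max minus min local radius, in Angstroem.

For each metric a Levene test (median-centred, i.e. Brown-Forsythe) first
decides whether the two groups can be assumed to share a variance; the
pooled-variance Student t-test is used when they can, Welch's t-test with
Satterthwaite degrees of freedom otherwise.  Both t-tests are two-sided.
No multiple-testing correction is applied across the three metrics.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .classify import is_demanding

__all__ = [
    "METRICS",
    "MetricsRecord",
    "GroupComparison",
    "variance_equality_test",
    "two_sample_test",
    "compare_metrics",
    "read_metrics",
    "write_metrics",
    "write_comparisons",
]

#: Metric column names, in reporting order.
METRICS: Tuple[str, ...] = ("max_period_dev", "period_range", "radius_range")


@dataclass(frozen=True)
class MetricsRecord:
    """One coiled coil: its decomposition plus three structural summaries."""

    record_id: str
    decomposition: Tuple[int, ...]
    demanding: bool
    max_period_dev: float
    period_range: float
    radius_range: float

    def __post_init__(self) -> None:
        decomposition = tuple(int(d) for d in self.decomposition)
        object.__setattr__(self, "decomposition", decomposition)
        if self.demanding != is_demanding(decomposition):
            raise ValueError(
                f"{self.record_id}: demanding flag inconsistent with "
                f"decomposition {'+'.join(map(str, decomposition))}"
            )
        for name in METRICS:
            if getattr(self, name) < 0:
                raise ValueError(f"{self.record_id}: {name} must be >= 0")

    @classmethod
    def from_decomposition(
        cls,
        record_id: str,
        decomposition: Sequence[int],
        max_period_dev: float,
        period_range: float,
        radius_range: float,
    ) -> "MetricsRecord":
        decomposition = tuple(int(d) for d in decomposition)
        return cls(
            record_id=record_id,
            decomposition=decomposition,
            demanding=is_demanding(decomposition),
            max_period_dev=max_period_dev,
            period_range=period_range,
            radius_range=radius_range,
        )


@dataclass(frozen=True)
class GroupComparison:
    """Result of one variance-gated two-sample test."""

    metric: str
    n_demanding: int
    n_other: int
    mean_demanding: float
    mean_other: float
    variance_test_stat: float
    variance_test_p: float
    equal_variance_assumed: bool
    t_stat: float
    p_value: float
    df: float

    def summary(self) -> str:
        which = "Student (pooled)" if self.equal_variance_assumed else "Welch"
        return (
            f"{self.metric}: demanding n={self.n_demanding} "
            f"mean={self.mean_demanding:.4g} vs other n={self.n_other} "
            f"mean={self.mean_other:.4g} | Levene W={self.variance_test_stat:.4g} "
            f"p={self.variance_test_p:.4g} -> {which} t-test | "
            f"t={self.t_stat:.4g} df={self.df:.4g} p={self.p_value:.4g}"
        )

    def __str__(self) -> str:
        return self.summary()


def variance_equality_test(
    a: Sequence[float], b: Sequence[float], *, center: str = "median"
) -> Tuple[float, float]:
    """Levene test for equal variances (median-centred by default, the
    Brown-Forsythe variant; ``center='mean'`` gives the classical test).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        raise ValueError("degenerate variance test: both samples constant")
    res = stats.levene(a, b, center=center)
    return float(res.statistic), float(res.pvalue)


def two_sample_test(
    a: Sequence[float],
    b: Sequence[float],
    alpha: float = 0.05,
    *,
    metric: str = "",
    center: str = "median",
) -> GroupComparison:
    """Variance-gated two-sided t-test of group ``a`` against group ``b``.

    If the Levene p-value is >= ``alpha`` the pooled-variance Student
    t-test is used; otherwise Welch's t-test with Welch-Satterthwaite
    degrees of freedom.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    var_stat, var_p = variance_equality_test(a, b, center=center)
    equal_var = var_p >= alpha
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return GroupComparison(
        metric=metric,
        n_demanding=int(a.size),
        n_other=int(b.size),
        mean_demanding=float(a.mean()),
        mean_other=float(b.mean()),
        variance_test_stat=var_stat,
        variance_test_p=var_p,
        equal_variance_assumed=bool(equal_var),
        t_stat=float(res.statistic),
        p_value=float(res.pvalue),
        df=float(res.df),
    )


def compare_metrics(
    records: Sequence[MetricsRecord], alpha: float = 0.05
) -> List[GroupComparison]:
    """One :class:`GroupComparison` per metric, demanding group first."""
    demanding = [r for r in records if r.demanding]
    other = [r for r in records if not r.demanding]
    out = []
    for metric in METRICS:
        a = [getattr(r, metric) for r in demanding]
        b = [getattr(r, metric) for r in other]
        if len(a) < 2:
            raise ValueError(
                f"{metric}: demanding group has {len(a)} record(s); need >= 2"
            )
        if len(b) < 2:
            raise ValueError(
                f"{metric}: non-demanding group has {len(b)} record(s); need >= 2"
            )
        out.append(two_sample_test(a, b, alpha, metric=metric))
    return out


def read_metrics(path) -> List[MetricsRecord]:
    """Read a metrics table from TSV.

    Columns ``record_id``, ``decomposition`` ('+'-joined), and the three
    metrics.  The demanding flag is always derived from the decomposition,
    never read.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"record_id", "decomposition", *METRICS}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            MetricsRecord.from_decomposition(
                record_id=str(row.record_id),
                decomposition=[int(t) for t in str(row.decomposition).split("+")],
                max_period_dev=float(row.max_period_dev),
                period_range=float(row.period_range),
                radius_range=float(row.radius_range),
            )
        )
    return records


def write_comparisons(path, comparisons: Sequence[GroupComparison]) -> None:
    """Write comparison results as TSV."""
    df = pd.DataFrame([c.__dict__ for c in comparisons])
    df.to_csv(Path(path), sep="\t", index=False)


def write_metrics(path, records: Sequence[MetricsRecord]) -> None:
    """Write a metrics table as TSV (inverse of :func:`read_metrics`)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("record_id\tdecomposition\t" + "\t".join(METRICS) + "\n")
        for r in records:
            fh.write(
                f"{r.record_id}\t"
                + "+".join(str(d) for d in r.decomposition)
                + "".join(f"\t{getattr(r, m):.6g}" for m in METRICS)
                + "\n"
            )
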