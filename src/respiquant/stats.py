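"""Group-level statistics shared by all analysis stages.

Animals (mice/embryos), not bursts/breaths/somas, are the statistical
units: per-animal means are computed upstream and each ``GroupSample``
holds one value per animal.  Group comparisons use the unpaired
two-tailed Student's t-test (pooled variance; Welch available behind a
flag), with significance stars at 0.05 / 0.01 / 0.001 / 0.0001 and no
multiple-testing correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupSample",
    "TestResult",
    "ProportionSummary",
    "BoxSummary",
    "ttest_unpaired",
    "percent_change",
    "proportion_summary",
    "box_summary",
    "significance_stars",
]


@dataclass(frozen=True)
class GroupSample:
    """Per-animal measurements for one genotype/condition."""

    label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1:
            raise ValueError("group values must be one-dimensional")
        if v.size and not np.all(np.isfinite(v)):
            raise ValueError("group values must be finite")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def mean(self) -> float:
        return float(self.values.mean())


@dataclass(frozen=True)
class TestResult:
    t_stat: float
    df: float
    p_two_tailed: float
    mean_diff: float
    percent_change: float

    @property
    def stars(self) -> str:
        return significance_stars(self.p_two_tailed)


@dataclass(frozen=True)
class ProportionSummary:
    per_animal_pct: tuple[float, ...]
    mean_pct: float
    pooled_pct: float
    n_animals: int


@dataclass(frozen=True)
class BoxSummary:
    minimum: float
    q1: float
    median: float
    q3: float
    maximum: float
    mean: float


def ttest_unpaired(a: GroupSample, b: GroupSample, welch: bool = False) -> TestResult:
    """Unpaired two-tailed Student's t-test (pooled variance by default).

    Degenerate inputs with zero pooled variance give t = 0, p = 1 when the
    group means are equal, and are rejected otherwise.
    """
    if a.n < 2 or b.n < 2:
        raise ValueError("each group needs at least two animals")
    pct = 100.0 * (b.mean - a.mean) / a.mean if a.mean != 0 else np.nan
    if not welch and a.values.var(ddof=1) == 0 and b.values.var(ddof=1) == 0:
        if a.mean == b.mean:
            return TestResult(0.0, a.n + b.n - 2, 1.0, 0.0, 0.0)
        raise ValueError("degenerate samples: zero variance with unequal means")
    res = sps.ttest_ind(b.values, a.values, equal_var=not welch)
    df = float(res.df) if welch else float(a.n + b.n - 2)
    return TestResult(
        t_stat=float(res.statistic),
        df=df,
        p_two_tailed=float(res.pvalue),
        mean_diff=b.mean - a.mean,
        percent_change=float(pct),
    )


def percent_change(control: GroupSample, treated: GroupSample) -> float:
    """100 * (mean_treated - mean_control) / mean_control."""
    if control.mean == 0:
        raise ValueError("control mean must be nonzero")
    return 100.0 * (treated.mean - control.mean) / control.mean


def proportion_summary(counts: Sequence[tuple[int, int]]) -> ProportionSummary:
    """Per-animal percentages from (hits, totals), plus their unweighted mean
    and the pooled (summed-counts) percentage."""
    if len(counts) == 0:
        raise ValueError("at least one animal required")
    per_animal = []
    for hits, total in counts:
        if total <= 0:
            raise ValueError("totals must be positive")
        if not (0 <= hits <= total):
            raise ValueError("hits must lie in [0, totals]")
        per_animal.append(100.0 * hits / total)
    pooled = 100.0 * sum(h for h, _ in counts) / sum(t for _, t in counts)
    return ProportionSummary(
        per_animal_pct=tuple(per_animal),
        mean_pct=float(np.mean(per_animal)),
        pooled_pct=float(pooled),
        n_animals=len(counts),
    )


def box_summary(g: GroupSample) -> BoxSummary:
    """Five-number summary plus mean (quartiles by linear interpolation)."""
    if g.n < 1:
        raise ValueError("box summary requires at least one value")
    q0, q1, q2, q3, q4 = np.percentile(g.values, [0, 25, 50, 75, 100], method="linear")
    return BoxSummary(float(q0), float(q1), float(q2), float(q3), float(q4), g.mean)


def significance_stars(p: float) -> str:
    if p < 0.0001:
        return "****"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"
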