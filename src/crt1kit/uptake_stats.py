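"""Creatine-uptake statistics: percent-of-wild-type normalization, Welch's
heteroscedastic one-way ANOVA, per-variant comparisons and severity calls.

The assay design this serves: each genotype (WT or a transporter variant)
has >= 6 biological replicates of intracellular creatine after a single
uptake endpoint; replicate technical duplicates are averaged upstream.
Group means are expressed as a percentage of the wild-type mean; Welch's
one-way ANOVA (variance-weighted means, Welch-Satterthwaite denominator
degrees of freedom) tests equality of group means without assuming equal
variances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import stats

from .io_formats import UptakeRow


@dataclass
class UptakeGroup:
    genotype_label: str
    values: list[float]

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.values):
            raise ValueError(f"group {self.genotype_label}: negative measurement")

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        """Sample standard deviation (n-1 denominator)."""
        return float(np.std(self.values, ddof=1)) if self.n > 1 else float("nan")


def groups_from_rows(rows: list[UptakeRow]) -> list[UptakeGroup]:
    """Collect replicate rows into per-genotype groups, input order kept."""
    order: list[str] = []
    by_label: dict[str, list[float]] = {}
    for r in rows:
        if r.genotype_label not in by_label:
            order.append(r.genotype_label)
            by_label[r.genotype_label] = []
        by_label[r.genotype_label].append(r.creatine_amount)
    return [UptakeGroup(lbl, by_label[lbl]) for lbl in order]


@dataclass(frozen=True)
class GroupSummary:
    genotype_label: str
    n: int
    mean: float
    sd: float
    pct_of_wt: float
    pct_reduction: float


def summarize_groups(
    groups: list[UptakeGroup], wt_label: str = "WT"
) -> dict[str, GroupSummary]:
    """Mean ± SD per genotype plus percent-of-WT normalization.

    ``pct_of_wt = 100 * mean / WT_mean`` and ``pct_reduction`` is its
    complement to 100 (negative if uptake exceeds WT).
    """
    labels = [g.genotype_label for g in groups]
    if wt_label not in labels:
        raise ValueError(f"wild-type label {wt_label!r} not among groups {labels}")
    wt_mean = next(g for g in groups if g.genotype_label == wt_label).mean
    if wt_mean <= 0:
        raise ValueError("wild-type mean is zero; percent-of-WT undefined")
    out = {}
    for g in groups:
        pct = 100.0 * g.mean / wt_mean
        out[g.genotype_label] = GroupSummary(
            g.genotype_label, g.n, g.mean, g.sd, pct, 100.0 - pct
        )
    return out


@dataclass(frozen=True)
class WelchResult:
    F_statistic: float
    df_between: float
    df_within: float
    p_value: float

    def summary(self) -> str:
        return (
            f"Welch's one-way ANOVA: F({self.df_between:g}, "
            f"{self.df_within:.2f}) = {self.F_statistic:.4f}, "
            f"p = {self.p_value:.4g}"
        )


def welch_anova(groups: list[UptakeGroup]) -> WelchResult:
    """Welch's heteroscedastic one-way ANOVA, implemented from the
    definition.

    With k groups of size n_i, mean m_i and variance s_i^2, the weights are
    w_i = n_i / s_i^2.  The statistic is

        F = [sum w_i (m_i - m_w)^2 / (k-1)] /
            [1 + 2(k-2)/(k^2-1) * A],    A = sum (1 - w_i/W)^2 / (n_i - 1)

    where W = sum w_i and m_w = sum w_i m_i / W, referred to an F
    distribution with k-1 and (k^2-1)/(3A) degrees of freedom
    (Welch-Satterthwaite).  For k = 2 this is exactly the square of Welch's
    two-sample t statistic.
    """
    if len(groups) < 2:
        raise ValueError("Welch ANOVA needs at least 2 groups")
    for g in groups:
        if g.n < 2:
            raise ValueError(f"group {g.genotype_label}: need n >= 2 replicates")
        if np.var(g.values, ddof=1) == 0:
            raise ValueError(
                f"group {g.genotype_label} has zero variance; jitter or exclude it"
            )
    k = len(groups)
    n = np.array([g.n for g in groups], dtype=float)
    m = np.array([g.mean for g in groups])
    s2 = np.array([np.var(g.values, ddof=1) for g in groups])
    w = n / s2
    W = w.sum()
    mw = (w * m).sum() / W
    A = (((1.0 - w / W) ** 2) / (n - 1.0)).sum()
    num = (w * (m - mw) ** 2).sum() / (k - 1)
    den = 1.0 + 2.0 * (k - 2) / (k**2 - 1.0) * A
    F = float(num / den)
    df1 = float(k - 1)
    df2 = float((k**2 - 1.0) / (3.0 * A))
    p = float(stats.f.sf(F, df1, df2))
    return WelchResult(F, df1, df2, p)


def welch_t_vs_wt(groups: list[UptakeGroup], wt_label: str = "WT") -> dict[str, float]:
    """Per-variant Welch two-sample p-values against wild type
    (no multiplicity correction; pass the result through
    :func:`holm_adjust` if desired)."""
    wt = next(g for g in groups if g.genotype_label == wt_label)
    out = {}
    for g in groups:
        if g.genotype_label == wt_label or g.n < 2:
            continue
        res = stats.ttest_ind(g.values, wt.values, equal_var=False)
        out[g.genotype_label] = float(res.pvalue)
    return out


def holm_adjust(pvalues: dict[str, float]) -> dict[str, float]:
    """Holm step-down adjustment of a family of p-values."""
    items = sorted(pvalues.items(), key=lambda kv: kv[1])
    m = len(items)
    adjusted = {}
    running = 0.0
    for rank, (label, p) in enumerate(items):
        running = max(running, min(1.0, (m - rank) * p))
        adjusted[label] = running
    return adjusted


class Severity(str, Enum):
    SEVERE = "severe"
    MODERATE = "moderate"
    UNIMPAIRED = "unimpaired"


def classify_severity(
    summary: GroupSummary,
    significant: bool,
    severe_cutoff_pct_reduction: float = 88.0,
) -> Severity:
    """Call a variant severe (significant reduction at or beyond the
    cutoff), moderate (significant but smaller reduction) or unimpaired.

    The default cutoff of 88% reduction reflects the observed split between
    profoundly impaired and partially active transporter variants; it is a
    reporting convention, not a clinical threshold.
    """
    if not 0 < severe_cutoff_pct_reduction <= 100:
        raise ValueError("cutoff must be in (0, 100]")
    if not significant:
        return Severity.UNIMPAIRED
    if summary.pct_reduction >= severe_cutoff_pct_reduction:
        return Severity.SEVERE
    return Severity.MODERATE


@dataclass
class UptakeReport:
    """End-to-end per-dataset uptake analysis."""

    summaries: dict[str, GroupSummary]
    omnibus: WelchResult | None
    p_vs_wt: dict[str, float] = field(default_factory=dict)
    severity: dict[str, Severity] = field(default_factory=dict)
    excluded: list[str] = field(default_factory=list)


def analyze_uptake(
    rows: list[UptakeRow],
    wt_label: str = "WT",
    alpha: float = 0.05,
    severe_cutoff_pct_reduction: float = 88.0,
    holm: bool = False,
) -> UptakeReport:
    """Summarize, test and classify every genotype in a replicate table.

    Groups with fewer than 2 replicates are excluded from testing (but
    still summarized); the omnibus Welch ANOVA runs over all testable
    groups, and each variant also gets a Welch two-sample p against WT,
    optionally Holm-adjusted, driving the severity call at level ``alpha``.
    """
    groups = groups_from_rows(rows)
    summaries = summarize_groups(groups, wt_label)
    testable = [g for g in groups if g.n >= 2]
    excluded = [g.genotype_label for g in groups if g.n < 2]
    omnibus = welch_anova(testable) if len(testable) >= 2 else None
    p_vs_wt = (
        welch_t_vs_wt(testable, wt_label)
        if any(g.genotype_label == wt_label for g in testable) and len(testable) >= 2
        else {}
    )
    if holm and p_vs_wt:
        p_vs_wt = holm_adjust(p_vs_wt)
    severity = {
        label: classify_severity(
            summaries[label], p < alpha, severe_cutoff_pct_reduction
        )
        for label, p in p_vs_wt.items()
    }
    return UptakeReport(summaries, omnibus, p_vs_wt, severity, excluded)
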