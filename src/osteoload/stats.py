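"""Statistics chain for grouped bending-moment maxima.

Implements, from the defining formulas: descriptive statistics with both
population and sample SD conventions, the Shapiro–Wilk normality test
(Royston's AS R94 approximation), Levene's variance-homogeneity test,
the paired-sample t-test, classic one-way and Welch ANOVA, and the
Games–Howell post hoc procedure on the studentized-range distribution.

The decision logic mirrors common practice for unequal group sizes and
variances: normality is reported but does not divert the chain (one-way
ANOVA is robust to moderate non-normality); Levene's test selects between
the classic ANOVA and the Welch ANOVA + Games–Howell branch.  Outliers are
retained throughout.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupData",
    "TestReport",
    "descriptives",
    "paired_t",
    "shapiro_wilk",
    "levene",
    "one_way_anova",
    "welch_anova",
    "games_howell",
    "analysis_gate",
    "weighted_group_mean",
]

ALPHA_DEFAULT = 0.05


@dataclass(frozen=True)
class GroupData:
    """One comparison group (e.g. per-trial maximum moments of one digit)."""

    label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    @property
    def n(self) -> int:
        return len(self.values)


@dataclass
class TestReport:
    """Outcome of a single hypothesis test."""

    name: str
    statistic: float
    df: float | tuple[float, float] | None
    p_value: float
    alpha: float = ALPHA_DEFAULT
    pairwise: list["PairwiseComparison"] = field(default_factory=list)
    notes: str = ""

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha

    def __str__(self) -> str:  # human-readable log line
        df = self.df
        dftxt = "" if df is None else f", df={df}" if np.isscalar(df) else f", df={tuple(np.round(df, 2))}"
        return (
            f"{self.name}: stat={self.statistic:.4g}{dftxt}, "
            f"p={self.p_value:.4g} ({'significant' if self.significant else 'n.s.'}"
            f" at alpha={self.alpha})" + (f" [{self.notes}]" if self.notes else "")
        )


@dataclass
class PairwiseComparison:
    group_a: str
    group_b: str
    difference: float
    p_value: float
    ci_low: float
    ci_high: float


def _as_groups(groups: Sequence[GroupData | Sequence[float]]) -> list[GroupData]:
    out = []
    for i, g in enumerate(groups):
        if isinstance(g, GroupData):
            out.append(g)
        else:
            out.append(GroupData(label=str(i + 1), values=np.asarray(g, float)))
    labels = [g.label for g in out]
    if len(set(labels)) != len(labels):
        raise ValueError("group labels must be unique")
    return out


# ---------------------------------------------------------------------------
# descriptives
# ---------------------------------------------------------------------------


def descriptives(
    values: Sequence[float],
    sd_convention: Literal["population", "sample"] = "sample",
) -> tuple[float, float]:
    """Mean and standard deviation under the stated SD convention.

    The population convention divides by n (SPSS-style descriptive tables
    for a full roster use this), the sample convention by n - 1; they are
    related by ``sd_pop = sd_samp * sqrt((n-1)/n)``.  A single value has
    population SD 0; its sample SD is undefined and reported as nan with a
    warning.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("descriptives of an empty sample")
    mean = float(x.mean())
    if x.size == 1:
        if sd_convention == "population":
            return mean, 0.0
        warnings.warn("sample SD undefined for n=1; reporting nan")
        return mean, float("nan")
    ddof = 0 if sd_convention == "population" else 1
    return mean, float(x.std(ddof=ddof))


def weighted_group_mean(means: Sequence[float], ns: Sequence[int]) -> float:
    """Pooled mean of group means weighted by group sizes."""
    means = np.asarray(means, float)
    ns = np.asarray(ns, float)
    if means.shape != ns.shape:
        raise ValueError("means and ns must have equal length")
    if np.any(ns <= 0):
        raise ValueError("group sizes must be positive")
    return float((ns * means).sum() / ns.sum())


# ---------------------------------------------------------------------------
# paired t
# ---------------------------------------------------------------------------


def paired_t(a: Sequence[float], b: Sequence[float], alpha: float = ALPHA_DEFAULT) -> TestReport:
    """Two-sided paired-sample t-test; pairs with a missing member dropped."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    keep = np.isfinite(a) & np.isfinite(b)
    d = a[keep] - b[keep]
    n = len(d)
    if n < 2:
        raise ValueError("need at least 2 complete pairs")
    sd = d.std(ddof=1)
    mean = d.mean()
    if sd == 0.0:
        # degenerate: all differences identical
        p = 1.0 if mean == 0.0 else 0.0
        return TestReport(
            "paired t", 0.0 if mean == 0.0 else math.inf, n - 1, p, alpha,
            notes="degenerate: zero variance of differences",
        )
    t = mean / (sd / math.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), n - 1)
    return TestReport("paired t", float(t), n - 1, float(p), alpha)


# ---------------------------------------------------------------------------
# Shapiro-Wilk (Royston AS R94)
# ---------------------------------------------------------------------------

_SW_C1 = [0.0, 0.221157, -0.147981, -2.071190, 4.434685, -2.706056]
_SW_C2 = [0.0, 0.042981, -0.293762, -1.752461, 5.682633, -3.582633]


def _poly(coeffs: Sequence[float], x: float) -> float:
    return sum(c * x**i for i, c in enumerate(coeffs))


def shapiro_wilk(values: Sequence[float], alpha: float = ALPHA_DEFAULT) -> TestReport:
    """Shapiro–Wilk W test of normality, 3 <= n <= 5000.

    Weights and the p-value transformation follow Royston's polynomial
    approximation; for n = 3 the p-value is exact.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    if not 3 <= n <= 5000:
        raise ValueError(f"Shapiro-Wilk requires 3 <= n <= 5000, got {n}")
    if x[0] == x[-1]:
        raise ValueError("zero variance sample")

    m = sps.norm.ppf((np.arange(1, n + 1) - 0.375) / (n + 0.25))
    mm = float(m @ m)
    c = m / math.sqrt(mm)
    u = 1.0 / math.sqrt(n)
    a = np.empty(n)
    if n > 5:
        an = c[-1] + _poly(_SW_C1, u)
        an1 = c[-2] + _poly(_SW_C2, u)
        phi = (mm - 2 * m[-1] ** 2 - 2 * m[-2] ** 2) / (1 - 2 * an**2 - 2 * an1**2)
        a[2:-2] = m[2:-2] / math.sqrt(phi)
        a[-1], a[-2] = an, an1
        a[0], a[1] = -an, -an1
    else:
        an = c[-1] + _poly(_SW_C1, u)
        phi = (mm - 2 * m[-1] ** 2) / (1 - 2 * an**2) if n > 3 else 1.0
        if n == 3:
            a[:] = [-math.sqrt(0.5), 0.0, math.sqrt(0.5)]
        else:
            a[1:-1] = m[1:-1] / math.sqrt(phi)
            a[-1] = an
            a[0] = -an
    W = float((a @ x) ** 2 / ((x - x.mean()) @ (x - x.mean())))
    W = min(W, 1.0)

    if n == 3:
        p = 6.0 / math.pi * (math.asin(math.sqrt(W)) - math.asin(math.sqrt(0.75)))
        p = min(max(p, 0.0), 1.0)
    elif n <= 11:
        g = -2.273 + 0.459 * n
        w = -math.log(g - math.log(1.0 - W))
        mu = 0.5440 - 0.39978 * n + 0.025054 * n**2 - 0.0006714 * n**3
        sigma = math.exp(1.3822 - 0.77857 * n + 0.062767 * n**2 - 0.0020322 * n**3)
        p = float(sps.norm.sf((w - mu) / sigma))
    else:
        ln = math.log(n)
        w = math.log(1.0 - W)
        mu = 0.0038915 * ln**3 - 0.083751 * ln**2 - 0.31082 * ln - 1.5861
        sigma = math.exp(0.0030302 * ln**2 - 0.082676 * ln - 0.4803)
        p = float(sps.norm.sf((w - mu) / sigma))
    return TestReport("Shapiro-Wilk", W, None, p, alpha)


# ---------------------------------------------------------------------------
# Levene
# ---------------------------------------------------------------------------


def levene(
    groups: Sequence[GroupData | Sequence[float]],
    center: Literal["mean", "median"] = "mean",
    alpha: float = ALPHA_DEFAULT,
) -> TestReport:
    """Levene's test of variance homogeneity on absolute deviations from
    group centers (classic mean-centered form; ``center='median'`` gives
    the Brown–Forsythe variant)."""
    gs = _as_groups(groups)
    if len(gs) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.n < 2 for g in gs):
        raise ValueError("every group needs n >= 2")
    cen = np.median if center == "median" else np.mean
    z = [np.abs(g.values - cen(g.values)) for g in gs]
    k = len(z)
    N = sum(len(zi) for zi in z)
    zbar = np.concatenate(z).mean()
    zmeans = [zi.mean() for zi in z]
    num = sum(len(zi) * (zm - zbar) ** 2 for zi, zm in zip(z, zmeans)) / (k - 1)
    den = sum(((zi - zm) ** 2).sum() for zi, zm in zip(z, zmeans)) / (N - k)
    # guard against pure floating-point dust from exactly-constant groups
    scale = max(float(np.abs(np.concatenate([g.values for g in gs])).max()), 1.0)
    eps2 = (1e-10 * scale) ** 2
    num = 0.0 if num < eps2 else num
    den = 0.0 if den < eps2 else den
    notes = ""
    if den == 0.0:
        # zero within-group deviation spread (e.g. all n=2 groups)
        stat, p = (0.0, 1.0) if num == 0.0 else (math.inf, 0.0)
        if num > 0:
            notes = "degenerate: zero within-group deviation spread"
    else:
        stat = num / den
        p = float(sps.f.sf(stat, k - 1, N - k))
    return TestReport("Levene", float(stat), (k - 1, N - k), p, alpha, notes=notes)


# ---------------------------------------------------------------------------
# ANOVA family
# ---------------------------------------------------------------------------


def one_way_anova(
    groups: Sequence[GroupData | Sequence[float]], alpha: float = ALPHA_DEFAULT
) -> TestReport:
    """Classic one-way fixed-effects ANOVA F-test."""
    gs = _as_groups(groups)
    if len(gs) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.n < 2 for g in gs):
        raise ValueError("every group needs n >= 2")
    k = len(gs)
    N = sum(g.n for g in gs)
    grand = np.concatenate([g.values for g in gs]).mean()
    ssb = sum(g.n * (g.values.mean() - grand) ** 2 for g in gs)
    ssw = sum(((g.values - g.values.mean()) ** 2).sum() for g in gs)
    if ssw == 0.0:
        return TestReport(
            "one-way ANOVA", 0.0 if ssb == 0 else math.inf, (k - 1, N - k),
            1.0 if ssb == 0 else 0.0, alpha, notes="degenerate: zero within-group variance",
        )
    F = (ssb / (k - 1)) / (ssw / (N - k))
    p = float(sps.f.sf(F, k - 1, N - k))
    return TestReport("one-way ANOVA", float(F), (k - 1, N - k), p, alpha)


def welch_anova(
    groups: Sequence[GroupData | Sequence[float]], alpha: float = ALPHA_DEFAULT
) -> TestReport:
    """Welch's heteroscedastic one-way ANOVA with Welch–Satterthwaite df."""
    gs = _as_groups(groups)
    if len(gs) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.n < 2 for g in gs):
        raise ValueError("every group needs n >= 2")
    v = np.array([g.values.var(ddof=1) for g in gs])
    if np.any(v == 0):
        raise ValueError("zero-variance group in Welch ANOVA")
    n = np.array([g.n for g in gs], float)
    m = np.array([g.values.mean() for g in gs])
    w = n / v
    k = len(gs)
    mw = (w * m).sum() / w.sum()
    A = (w * (m - mw) ** 2).sum() / (k - 1)
    lam = ((1 - w / w.sum()) ** 2 / (n - 1)).sum() / (k**2 - 1)
    F = A / (1 + 2 * (k - 2) * lam)
    df2 = 1.0 / (3.0 * lam)
    p = float(sps.f.sf(F, k - 1, df2))
    return TestReport("Welch ANOVA", float(F), (k - 1, float(df2)), p, alpha)


def games_howell(
    groups: Sequence[GroupData | Sequence[float]],
    alpha: float = ALPHA_DEFAULT,
    compute_ci: bool = True,
) -> TestReport:
    """Games–Howell post hoc pairwise comparisons.

    Each pair uses its own Welch–Satterthwaite df; the adjusted p-value and
    the simultaneous CI come from the studentized-range distribution with
    the full number of groups k.
    """
    gs = _as_groups(groups)
    if len(gs) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.n < 2 for g in gs):
        raise ValueError("every group needs n >= 2")
    if any(g.values.var(ddof=1) == 0 for g in gs):
        raise ValueError("zero-variance group in Games-Howell")
    k = len(gs)
    comps: list[PairwiseComparison] = []
    worst_p = 0.0
    for i in range(k):
        for j in range(i + 1, k):
            a, b = gs[i], gs[j]
            va, vb = a.values.var(ddof=1), b.values.var(ddof=1)
            se2 = va / a.n + vb / b.n
            diff = a.values.mean() - b.values.mean()
            df = se2**2 / ((va / a.n) ** 2 / (a.n - 1) + (vb / b.n) ** 2 / (b.n - 1))
            q = abs(diff) / math.sqrt(se2 / 2.0)
            p = float(sps.studentized_range.sf(q, k, df))
            p = min(max(p, 0.0), 1.0)
            if compute_ci:
                qcrit = float(sps.studentized_range.ppf(1 - alpha, k, df))
                half = qcrit * math.sqrt(se2 / 2.0)
            else:
                half = math.nan
            comps.append(
                PairwiseComparison(a.label, b.label, float(diff), p, diff - half, diff + half)
            )
            worst_p = max(worst_p, 1 - p)
    min_p = min(c.p_value for c in comps)
    return TestReport(
        "Games-Howell", float("nan"), None, min_p, alpha, pairwise=comps,
        notes="statistic column not defined; see pairwise table",
    )


# ---------------------------------------------------------------------------
# decision gate
# ---------------------------------------------------------------------------


@dataclass
class GateResult:
    """Full record of the gated analysis chain."""

    normality: dict[str, TestReport]
    levene: TestReport
    omnibus: TestReport
    post_hoc: TestReport | None
    branch: Literal["welch", "classic"]

    def log(self) -> str:
        lines = [f"normality[{k}]: {r}" for k, r in self.normality.items()]
        lines.append(str(self.levene))
        lines.append(f"branch: {self.branch}")
        lines.append(str(self.omnibus))
        if self.post_hoc is not None:
            lines.append(str(self.post_hoc))
            for c in self.post_hoc.pairwise:
                lines.append(
                    f"  {c.group_a} vs {c.group_b}: diff={c.difference:.4g}, "
                    f"p={c.p_value:.4g}, CI=({c.ci_low:.4g}, {c.ci_high:.4g})"
                )
        return "\n".join(lines)


def analysis_gate(
    groups: Sequence[GroupData | Sequence[float]], alpha: float = ALPHA_DEFAULT
) -> GateResult:
    """Run the full decision chain on grouped maxima.

    Shapiro–Wilk runs per group for reporting only (non-normality does not
    divert the chain).  Levene's test selects the branch: heteroscedastic
    data go to Welch ANOVA + Games–Howell; homoscedastic data to the
    classic one-way ANOVA, followed by pairwise Welch t-tests flagged as an
    unadjusted fallback (no named post hoc is prescribed on this branch).
    """
    gs = _as_groups(groups)
    normality = {}
    for g in gs:
        try:
            normality[g.label] = shapiro_wilk(g.values, alpha)
        except ValueError as exc:
            normality[g.label] = TestReport(
                "Shapiro-Wilk", float("nan"), None, float("nan"), alpha,
                notes=f"skipped: {exc}",
            )
    lev = levene(gs, alpha=alpha)
    vscale = max(float(np.abs(np.concatenate([g.values for g in gs])).max()), 1.0)
    degenerate = any(g.values.var(ddof=1) <= (1e-10 * vscale) ** 2 for g in gs)
    if lev.significant and not degenerate:
        omnibus = welch_anova(gs, alpha)
        post = games_howell(gs, alpha)
        branch = "welch"
    elif degenerate:
        omnibus = one_way_anova(gs, alpha)
        post = TestReport(
            "pairwise Welch t (unadjusted)", float("nan"), None, float("nan"),
            alpha, notes="skipped: zero-variance group",
        )
        branch = "classic"
    else:
        omnibus = one_way_anova(gs, alpha)
        comps = []
        for i in range(len(gs)):
            for j in range(i + 1, len(gs)):
                a, b = gs[i], gs[j]
                t, p = sps.ttest_ind(a.values, b.values, equal_var=False)
                va, vb = a.values.var(ddof=1), b.values.var(ddof=1)
                se = math.sqrt(va / a.n + vb / b.n)
                df = (va / a.n + vb / b.n) ** 2 / (
                    (va / a.n) ** 2 / (a.n - 1) + (vb / b.n) ** 2 / (b.n - 1)
                )
                tcrit = sps.t.ppf(1 - alpha / 2, df)
                diff = a.values.mean() - b.values.mean()
                comps.append(
                    PairwiseComparison(
                        a.label, b.label, float(diff), float(p),
                        diff - tcrit * se, diff + tcrit * se,
                    )
                )
        post = TestReport(
            "pairwise Welch t (unadjusted)", float("nan"), None,
            min(c.p_value for c in comps), alpha, pairwise=comps,
            notes="warning: no multiplicity adjustment on the homoscedastic branch",
        )
        branch = "classic"
    return GateResult(normality=normality, levene=lev, omnibus=omnibus,
                      post_hoc=post, branch=branch)
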