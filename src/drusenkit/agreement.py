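"""Paired method-agreement statistics.

Implements, from the mean-squares / rank definitions, the statistics used
to compare two drusen-volume measurement methods on the same eyes:

* two-way single-measurement intraclass correlation, both consistency and
  agreement flavors with F-based 95% CIs — consistency ignores a
  systematic between-method offset (x = y + e), agreement penalizes it
  (x = y);
* Bland–Altman summaries (mean difference, SD, limits of agreement, and
  the mean difference standardized by the mean of the per-eye averages);
* paired RMSE;
* the Wilcoxon paired signed-rank test (exact distribution for small n,
  tie- and continuity-corrected normal approximation otherwise);
* the Jonckheere–Terpstra trend test for ordered groups;
* Cohen's kappa for a binary high-progression-risk cut-off.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats

__all__ = [
    "PairedMeasures",
    "IccResult",
    "BlandAltmanResult",
    "WilcoxonResult",
    "JonckheereResult",
    "KappaResult",
    "icc_two_way",
    "bland_altman",
    "paired_rmse",
    "wilcoxon_signed_rank",
    "jonckheere_terpstra",
    "kappa_high_risk",
]


@dataclass
class PairedMeasures:
    """Per-eye paired volumes from two methods, with stage / RPD labels."""

    value_a: np.ndarray
    value_b: np.ndarray
    method_a: str = "a"
    method_b: str = "b"
    eye_id: list[str] = field(default_factory=list)
    subject_id: list[str] = field(default_factory=list)
    stage: list[str] = field(default_factory=list)
    rpd: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.value_a = np.asarray(self.value_a, dtype=float)
        self.value_b = np.asarray(self.value_b, dtype=float)
        if self.value_a.shape != self.value_b.shape:
            raise ValueError("paired value vectors must have equal length")
        if np.isnan(self.value_a).any() or np.isnan(self.value_b).any():
            raise ValueError("missing values are not allowed")
        if (self.value_a < 0).any() or (self.value_b < 0).any():
            raise ValueError("volumes must be >= 0")

    def __len__(self) -> int:
        return len(self.value_a)


def _as_pairs(p) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(p, PairedMeasures):
        return p.value_a, p.value_b
    a, b = p
    return np.asarray(a, dtype=float), np.asarray(b, dtype=float)


@dataclass(frozen=True)
class IccResult:
    estimate: float
    ci_low: float
    ci_high: float
    kind: str
    status: str = "ok"  # "ok" | "undefined_low_variance"


def _mean_squares(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float, int]:
    """Two-way ANOVA mean squares for n subjects x k=2 raters."""
    x = np.column_stack([a, b])
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    resid = x - row_means[:, None] - col_means[None, :] + grand
    mse = np.sum(resid**2) / ((n - 1) * (k - 1))
    return float(msr), float(msc), float(mse), n


def icc_two_way(p, kind: str = "consistency", alpha: float = 0.05) -> IccResult:
    """Two-way single-measurement ICC with an F-based 95% CI.

    consistency: (MSR - MSE) / (MSR + (k-1) MSE)
    agreement:   (MSR - MSE) / (MSR + (k-1) MSE + k/n (MSC - MSE)),
    with a negative column variance component truncated to zero in the
    agreement penalty.  CIs follow the standard F constructions (exact for
    consistency, the Satterthwaite-df approximation for agreement).
    """
    if kind not in ("consistency", "agreement"):
        raise ValueError(f"unknown ICC kind: {kind!r}")
    a, b = _as_pairs(p)
    if len(a) < 3:
        raise ValueError("ICC requires at least 3 paired eyes")
    msr, msc, mse, n = _mean_squares(a, b)
    k = 2
    if msr <= 1e-30:
        return IccResult(np.nan, np.nan, np.nan, kind, "undefined_low_variance")
    if kind == "consistency":
        est = (msr - mse) / (msr + (k - 1) * mse)
        if mse <= 0:
            return IccResult(est, est, est, kind)
        f = msr / mse
        df1, df2 = n - 1, (n - 1) * (k - 1)
        fl = f / stats.f.ppf(1 - alpha / 2, df1, df2)
        fu = f * stats.f.ppf(1 - alpha / 2, df2, df1)
        lo = (fl - 1) / (fl + k - 1)
        hi = (fu - 1) / (fu + k - 1)
        return IccResult(float(est), float(lo), float(hi), kind)
    penalty = max(msc - mse, 0.0) * k / n
    est = (msr - mse) / (msr + (k - 1) * mse + penalty)
    if mse <= 0 and penalty <= 0:
        return IccResult(float(est), float(est), float(est), kind)
    a_coef = k * est / (n * (1 - est)) if est < 1 else np.inf
    b_coef = 1 + k * est * (n - 1) / (n * (1 - est)) if est < 1 else np.inf
    num = (a_coef * msc + b_coef * mse) ** 2
    den = (a_coef * msc) ** 2 / (k - 1) + (b_coef * mse) ** 2 / ((n - 1) * (k - 1))
    v = num / den if den > 0 else 1.0
    f_lo = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_hi = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lo = n * (msr - f_lo * mse) / (
        f_lo * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    hi = n * (f_hi * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_hi * msr
    )
    return IccResult(float(est), float(lo), float(hi), kind)


@dataclass(frozen=True)
class BlandAltmanResult:
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    standardized_mean_diff: float
    status: str = "ok"  # "ok" | "undefined_zero_mean"


def bland_altman(p) -> BlandAltmanResult:
    """Bland–Altman summary of the paired differences (a - b).

    Limits of agreement are mean +/- 1.96 SD; the standardized mean
    difference divides the mean difference by the mean over eyes of the
    per-eye averages (a + b) / 2.
    """
    a, b = _as_pairs(p)
    if len(a) < 2:
        raise ValueError("Bland-Altman requires at least 2 eyes")
    diff = a - b
    mean_diff = float(diff.mean())
    sd = float(diff.std(ddof=1))
    mean_avg = float(((a + b) / 2).mean())
    if mean_avg == 0:
        return BlandAltmanResult(
            mean_diff, sd, mean_diff - 1.96 * sd, mean_diff + 1.96 * sd,
            np.nan, "undefined_zero_mean",
        )
    return BlandAltmanResult(
        mean_diff, sd, mean_diff - 1.96 * sd, mean_diff + 1.96 * sd,
        mean_diff / mean_avg,
    )


def paired_rmse(p) -> float:
    """Root mean squared paired difference, sqrt(mean((a - b)^2))."""
    a, b = _as_pairs(p)
    if len(a) < 1:
        raise ValueError("RMSE requires at least 1 eye")
    return float(np.sqrt(np.mean((a - b) ** 2)))


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # W+ = sum of ranks of positive differences
    p_value: float
    n_nonzero: int
    exact: bool
    status: str = "ok"  # "ok" | "all_zero"


def _signed_rank_exact_p(ranks2: np.ndarray, w2: int) -> float:
    """Exact two-sided p for the signed-rank statistic.

    ``ranks2`` are the (mid)ranks doubled so they are integers; ``w2`` is the
    doubled observed W+.  The null distribution of W+ is built by the usual
    shift (generating-polynomial) recursion over all 2^m sign assignments.
    """
    max_sum = int(ranks2.sum())
    dist = np.zeros(max_sum + 1)
    dist[0] = 1.0
    for r in ranks2.astype(int):
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: max_sum + 1 - r]
        dist = dist + shifted
    dist /= dist.sum()
    p_le = dist[: w2 + 1].sum()
    p_ge = dist[w2:].sum()
    return float(min(1.0, 2 * min(p_le, p_ge)))


def wilcoxon_signed_rank(p, exact_max_n: int = 25) -> WilcoxonResult:
    """Wilcoxon paired signed-rank test, two-sided.

    Zero differences are dropped (Wilcoxon's original treatment).  With at
    most ``exact_max_n`` nonzero differences the exact null distribution is
    enumerated (midranks handled by doubling); beyond that, the normal
    approximation with tie correction and a 0.5 continuity correction is
    used.
    """
    a, b = _as_pairs(p)
    diff = a - b
    diff = diff[diff != 0]
    m = len(diff)
    if m == 0:
        return WilcoxonResult(0.0, 1.0, 0, True, "all_zero")
    ranks = stats.rankdata(np.abs(diff))
    w_pos = float(ranks[diff > 0].sum())
    if m <= exact_max_n:
        ranks2 = np.round(2 * ranks).astype(int)
        p_val = _signed_rank_exact_p(ranks2, int(round(2 * w_pos)))
        return WilcoxonResult(w_pos, p_val, m, True)
    mean = m * (m + 1) / 4
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = m * (m + 1) * (2 * m + 1) / 24 - np.sum(
        tie_counts**3 - tie_counts, dtype=float
    ) / 48
    if var <= 0:
        return WilcoxonResult(w_pos, 1.0, m, False, "all_zero")
    z = (w_pos - mean - 0.5 * np.sign(w_pos - mean)) / np.sqrt(var)
    p_val = float(min(1.0, 2 * stats.norm.sf(abs(z))))
    return WilcoxonResult(w_pos, p_val, m, False)


@dataclass(frozen=True)
class JonckheereResult:
    statistic: float  # J
    p_value: float  # one-sided, increasing trend
    exact: bool


def _jt_statistic(groups: list[np.ndarray]) -> float:
    j = 0.0
    for (ga, gb) in combinations(range(len(groups)), 2):
        x, y = groups[ga], groups[gb]
        j += np.sum(x[:, None] < y[None, :]) + 0.5 * np.sum(x[:, None] == y[None, :])
    return float(j)


def _jt_exact_p(groups: list[np.ndarray], observed: float) -> float:
    """Exact one-sided p by enumerating all assignments of the pooled values
    to the group slots (uniform under the null)."""
    pooled = np.concatenate(groups)
    sizes = [len(g) for g in groups]
    n = len(pooled)
    count = 0
    total = 0

    def recurse(remaining: tuple[int, ...], assigned: list[np.ndarray]) -> None:
        nonlocal count, total
        gi = len(assigned)
        if gi == len(sizes):
            nonlocal_j = _jt_statistic(assigned)
            total += 1
            if nonlocal_j >= observed - 1e-12:
                count += 1
            return
        for combo in combinations(remaining, sizes[gi]):
            rest = tuple(i for i in remaining if i not in combo)
            recurse(rest, assigned + [pooled[list(combo)]])

    recurse(tuple(range(n)), [])
    return count / total


def jonckheere_terpstra(
    groups: list, exact_max_n: int = 10
) -> JonckheereResult:
    """Jonckheere–Terpstra test for an increasing trend across ordered groups.

    J sums, over ordered group pairs, the number of pairs with the
    later-group value larger (ties counted 1/2).  The exact permutation
    distribution is enumerated when the pooled sample size is at most
    ``exact_max_n``; otherwise a normal approximation with tie-corrected
    variance is used.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    groups = [g for g in groups if len(g) > 0]
    if len(groups) < 2:
        raise ValueError("Jonckheere-Terpstra requires at least 2 non-empty groups")
    j = _jt_statistic(groups)
    n_total = sum(len(g) for g in groups)
    if n_total <= exact_max_n:
        return JonckheereResult(j, _jt_exact_p(groups, j), True)
    sizes = np.array([len(g) for g in groups], dtype=float)
    pooled = np.concatenate(groups)
    _, ties = np.unique(pooled, return_counts=True)
    ties = ties.astype(float)
    n = float(n_total)
    mean = (n * n - np.sum(sizes**2)) / 4
    term1 = (
        n * (n - 1) * (2 * n + 5)
        - np.sum(sizes * (sizes - 1) * (2 * sizes + 5))
        - np.sum(ties * (ties - 1) * (2 * ties + 5))
    ) / 72
    term2 = (
        np.sum(sizes * (sizes - 1) * (sizes - 2))
        * np.sum(ties * (ties - 1) * (ties - 2))
    ) / (36 * n * (n - 1) * (n - 2))
    term3 = (
        np.sum(sizes * (sizes - 1)) * np.sum(ties * (ties - 1))
    ) / (8 * n * (n - 1))
    var = term1 + term2 + term3
    if var <= 0:
        return JonckheereResult(j, 0.5, False)
    z = (j - mean - 0.5 * np.sign(j - mean)) / np.sqrt(var)
    return JonckheereResult(j, float(stats.norm.sf(z)), False)


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    percent_agreement: float
    status: str = "ok"  # "ok" | "undefined_degenerate"


def kappa_high_risk(p, cutoff_a: float, cutoff_b: float) -> KappaResult:
    """Cohen's kappa for binary high-risk classification against per-method
    volume cut-offs (high risk iff value >= the method's cut-off)."""
    if not (cutoff_a > 0 and cutoff_b > 0):
        raise ValueError("cut-offs must be > 0")
    a, b = _as_pairs(p)
    ca = a >= cutoff_a
    cb = b >= cutoff_b
    n = len(a)
    po = float(np.mean(ca == cb))
    p_a, p_b = float(ca.mean()), float(cb.mean())
    pe = p_a * p_b + (1 - p_a) * (1 - p_b)
    if pe >= 1.0 - 1e-15:
        return KappaResult(np.nan, 100 * po, "undefined_degenerate")
    return KappaResult(float((po - pe) / (1 - pe)), 100 * po)
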