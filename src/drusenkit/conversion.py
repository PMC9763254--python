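"""Inter-method drusen-volume conversion via Deming regression.

Both measurement methods are noisy, so ordinary least squares is biased
toward zero slope; Deming regression is the errors-in-variables fit with a
known error-variance ratio lambda.  With lambda = 1 (orthogonal
regression) the two fit directions are exact inverses of each other —
consistent with the published Cirrus<->Spectralis conversion formulas
being near-reciprocal (2.112 ~ 1/0.473).

The conversion workflow mirrors the clinical analysis: restrict to an
"optimal" subset with a clean linear inter-device trend (drop eyes where
the Cirrus-style value exceeds the Spectralis-style one, and eyes whose
mean value exceeds 0.2 mm^3), fit on a random 80% training split, and
report mean error / RMSE of converted vs observed values on the held-out
20%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .agreement import PairedMeasures

#: Published reference coefficients of the inter-device conversion lines
#: (drusen volume, mm^3): Cirrus -> Spectralis and Spectralis -> Cirrus.
PUBLISHED_CIRRUS_TO_SPECTRALIS = (2.112, 0.0193)
PUBLISHED_SPECTRALIS_TO_CIRRUS = (0.473, -0.0091)

#: Published high-progression-risk drusen-volume cut-off on the Cirrus scale.
HIGH_RISK_CUTOFF_CIRRUS_MM3 = 0.03


class UnidentifiableLineError(ValueError):
    """Zero covariance between the two methods: no conversion line exists."""


@dataclass(frozen=True)
class DemingFit:
    slope: float
    intercept: float
    lam: float = 1.0
    n_used: int = 0

    def __post_init__(self) -> None:
        if not np.isfinite(self.slope) or self.slope == 0:
            raise ValueError("slope must be finite and nonzero")
        if not self.lam > 0:
            raise ValueError("lambda must be > 0")


def deming_fit(x, y, lam: float = 1.0) -> DemingFit:
    """Closed-form Deming (errors-in-variables) regression of y on x.

    slope = (s_yy - lam s_xx + sqrt((s_yy - lam s_xx)^2 + 4 lam s_xy^2))
            / (2 s_xy),  intercept = ybar - slope * xbar.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("Deming regression requires n >= 3")
    if not lam > 0:
        raise ValueError("lambda must be > 0")
    xbar, ybar = x.mean(), y.mean()
    sxx = np.mean((x - xbar) ** 2)
    syy = np.mean((y - ybar) ** 2)
    sxy = np.mean((x - xbar) * (y - ybar))
    if sxy == 0:
        raise UnidentifiableLineError("zero covariance between methods")
    d = syy - lam * sxx
    slope = (d + np.sqrt(d * d + 4 * lam * sxy * sxy)) / (2 * sxy)
    return DemingFit(float(slope), float(ybar - slope * xbar), lam, len(x))


def apply_fit(fit: DemingFit, value):
    """Convert a source-method value: slope * value + intercept."""
    return fit.slope * np.asarray(value, dtype=float) + fit.intercept


def invert_fit(fit: DemingFit) -> DemingFit:
    """The inverse conversion line (apply o invert = identity)."""
    if fit.slope == 0:
        raise ValueError("cannot invert a zero-slope fit")
    return DemingFit(1 / fit.slope, -fit.intercept / fit.slope, fit.lam, fit.n_used)


class DemingRegression(RegressorMixin, BaseEstimator):
    """Deming errors-in-variables regression as a sklearn-style estimator.

    Parameters
    ----------
    lam : float, default 1.0
        Ratio of the y-error variance to the x-error variance; lam = 1 is
        orthogonal regression, whose forward and reverse fits are exact
        inverses.

    Attributes
    ----------
    slope_, intercept_ : float
        Coefficients of the fitted conversion line.
    fit_ : DemingFit
        The fitted line as a value object.
    """

    def __init__(self, lam: float = 1.0):
        self.lam = lam

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise ValueError("DemingRegression takes a single feature")
            X = X[:, 0]
        self.fit_ = deming_fit(X, y, self.lam)
        self.slope_ = self.fit_.slope
        self.intercept_ = self.fit_.intercept
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[:, 0]
        return apply_fit(self.fit_, X)


def select_optimal_subset(p: PairedMeasures, mean_cap: float = 0.2) -> PairedMeasures:
    """Restrict to eyes with a clean linear inter-device relation.

    ``value_a`` plays the higher-valued (Spectralis-like, S) role and
    ``value_b`` the lower-valued (Cirrus-like, C) role.  Drops eyes with
    C > S and eyes whose per-eye mean (S + C) / 2 strictly exceeds
    ``mean_cap`` (a pair sitting exactly at the cap is retained).  Order is
    preserved.
    """
    s, c = p.value_a, p.value_b
    keep = (c <= s) & ((s + c) / 2 <= mean_cap)
    if not keep.any():
        raise ValueError("optimal-subset selection removed every eye")
    idx = np.flatnonzero(keep)
    return PairedMeasures(
        value_a=s[idx],
        value_b=c[idx],
        method_a=p.method_a,
        method_b=p.method_b,
        eye_id=[p.eye_id[i] for i in idx] if p.eye_id else [],
        subject_id=[p.subject_id[i] for i in idx] if p.subject_id else [],
        stage=[p.stage[i] for i in idx] if p.stage else [],
        rpd=p.rpd[idx] if p.rpd is not None else None,
    )


def train_test_split_pairs(
    p: PairedMeasures, train_frac: float = 0.8, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded random index split into ~80% train / 20% test.

    Returns (train_idx, test_idx): a disjoint, exhaustive partition with
    train size round(n * train_frac).
    """
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must be in (0, 1)")
    n = len(p)
    if n < 5:
        raise ValueError("split requires n >= 5")
    n_train = int(np.floor(n * train_frac + 0.5))
    perm = np.random.default_rng(seed).permutation(n)
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


@dataclass(frozen=True)
class ConversionEval:
    mean_error: float
    rmse: float
    n_train: int
    n_test: int
    direction: str

    def __post_init__(self) -> None:
        if self.rmse < abs(self.mean_error) - 1e-12:
            raise ValueError("rmse cannot be smaller than |mean_error|")


def evaluate_conversion(
    fit: DemingFit, source, target, direction: str = "", n_train: int = 0
) -> ConversionEval:
    """Mean error and RMSE of converted source values against observed
    target values on a test set."""
    source = np.asarray(source, dtype=float)
    target = np.asarray(target, dtype=float)
    if len(source) == 0:
        raise ValueError("empty test set")
    err = apply_fit(fit, source) - target
    return ConversionEval(
        mean_error=float(err.mean()),
        rmse=float(np.sqrt(np.mean(err**2))),
        n_train=n_train,
        n_test=len(source),
        direction=direction,
    )
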