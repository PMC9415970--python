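"""Scikit-learn-style outlier detectors for personal baselines.

Each detector learns per-person thresholds from a training feature series
and flags test windows that fall outside them.  Following the sklearn
outlier-detection convention, ``predict`` returns +1 for inliers and −1
for outliers; the boolean mask is available via ``outside``.  All
threshold comparisons are strict: a value exactly at a threshold is an
inlier.

``GaussianBaselineDetector`` implements the μ ± α·σ band.
``QuantileBaselineDetector`` implements the empirical-quantile band that
leaves a requested fraction of the training data outside.
``BivariateFrameDetector`` implements an axis-aligned rectangle over two
features, calibrated so a requested fraction of (jittered) training
points fall outside it.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, OutlierMixin
from sklearn.utils.validation import check_is_fitted

from .exceptions import ContractError, ParameterError

SIDEDNESS = ("two_sided", "upper_only", "lower_only")


def _as_values(X) -> np.ndarray:
    """Accept a 1-D array or an (n, 1) column and return 1-D floats."""
    v = np.asarray(X, dtype=float)
    if v.ndim == 2 and v.shape[1] == 1:
        v = v[:, 0]
    if v.ndim != 1:
        raise ContractError("expected a single feature column")
    if v.size == 0:
        raise ContractError("feature series is empty")
    return v


class _BandDetector(OutlierMixin, BaseEstimator):
    """Shared predict machinery for interval-threshold detectors."""

    def outside(self, X) -> np.ndarray:
        """Boolean mask of values strictly outside the learned band."""
        check_is_fitted(self, "lower_")
        v = _as_values(X)
        return (v < self.lower_) | (v > self.upper_)

    def predict(self, X) -> np.ndarray:
        """+1 for inliers, −1 for outliers (sklearn convention)."""
        return np.where(self.outside(X), -1, 1)

    def score_samples(self, X) -> np.ndarray:
        """Signed distance to the nearest violated threshold (≥0 inside)."""
        check_is_fitted(self, "lower_")
        v = _as_values(X)
        lo = v - self.lower_ if np.isfinite(self.lower_) else np.full_like(v, np.inf)
        hi = self.upper_ - v if np.isfinite(self.upper_) else np.full_like(v, np.inf)
        return np.minimum(lo, hi)


class GaussianBaselineDetector(_BandDetector):
    """Mean ± alpha·sd outlier detector.

    Parameters
    ----------
    alpha : float
        Number of standard deviations defining the band; the field study
        reported results at 1.5.
    sidedness : {"two_sided", "upper_only", "lower_only"}
        Which band edge(s) can trigger an outlier.  One-sided modes set
        the unused edge to ±inf.
    ddof : int
        Degrees-of-freedom correction for the standard deviation
        (0 = population convention, 1 = sample).

    Attributes
    ----------
    mu_, sigma_ : float
        Training mean and standard deviation.
    lower_, upper_ : float
        mu − alpha·sigma and mu + alpha·sigma (±inf on the unused side).
    """

    def __init__(self, alpha: float = 1.5, sidedness: str = "two_sided", ddof: int = 0):
        self.alpha = alpha
        self.sidedness = sidedness
        self.ddof = ddof

    def fit(self, X, y=None):
        if not self.alpha > 0:
            raise ParameterError("alpha must be positive")
        if self.sidedness not in SIDEDNESS:
            raise ParameterError(f"sidedness must be one of {SIDEDNESS}")
        v = _as_values(X)
        self.n_samples_ = v.size
        self.mu_ = float(v.mean())
        self.sigma_ = float(v.std(ddof=self.ddof))
        lower = self.mu_ - self.alpha * self.sigma_
        upper = self.mu_ + self.alpha * self.sigma_
        self.lower_ = lower if self.sidedness != "upper_only" else -np.inf
        self.upper_ = upper if self.sidedness != "lower_only" else np.inf
        return self


class QuantileBaselineDetector(_BandDetector):
    """Empirical-quantile outlier detector leaving a set training fraction outside.

    ``two_sided`` splits ``outlier_fraction`` equally between the tails;
    the one-sided modes put all of it in one tail.  Thresholds are the
    nearest order statistics to the requested quantile levels, so they
    coincide with observed values.  When ``random_state`` is
    given, uniform jitter on [−jitter_halfwidth, +jitter_halfwidth] is
    added before taking quantiles — needed for integer-valued features
    (dominant-frequency bins) where ties would make thresholds
    degenerate.

    Attributes
    ----------
    lower_, upper_ : float
        Empirical-quantile thresholds (±inf on an unused side).
    train_outside_fraction_ : float
        Fraction of the (jittered) training values outside the band.
    """

    def __init__(
        self,
        outlier_fraction: float = 0.05,
        sidedness: str = "two_sided",
        jitter_halfwidth: float = 0.5,
        random_state: int | None = None,
    ):
        self.outlier_fraction = outlier_fraction
        self.sidedness = sidedness
        self.jitter_halfwidth = jitter_halfwidth
        self.random_state = random_state

    def fit(self, X, y=None):
        f = self.outlier_fraction
        if not 0 < f < 1:
            raise ParameterError("outlier_fraction must lie strictly between 0 and 1")
        if self.sidedness not in SIDEDNESS:
            raise ParameterError(f"sidedness must be one of {SIDEDNESS}")
        v = _as_values(X)
        if self.random_state is not None:
            rng = np.random.default_rng(self.random_state)
            v = v + rng.uniform(-self.jitter_halfwidth, self.jitter_halfwidth, v.size)
        # Nearest order statistic rather than interpolation: thresholds then
        # coincide with data values, so as outlier_fraction -> 0 the band
        # spans the full training range and (strict comparisons) flags
        # nothing, while at moderate fractions the outside-count still
        # matches the request to within ~1/n.
        if self.sidedness == "two_sided":
            self.lower_, self.upper_ = np.quantile(v, [f / 2, 1 - f / 2], method="nearest")
        elif self.sidedness == "upper_only":
            self.lower_, self.upper_ = -np.inf, float(np.quantile(v, 1 - f, method="nearest"))
        else:
            self.lower_, self.upper_ = float(np.quantile(v, f, method="nearest")), np.inf
        self.lower_, self.upper_ = float(self.lower_), float(self.upper_)
        self.n_samples_ = v.size
        self.train_outside_fraction_ = float(self.outside(v).mean())
        return self


class BivariateFrameDetector(OutlierMixin, BaseEstimator):
    """Rectangular outlier frame over two features.

    Fitting adds seeded uniform jitter to both coordinates, then finds a
    common per-axis two-tailed quantile level by bisection so that the
    fraction of jittered training points strictly outside the rectangle
    equals ``outlier_fraction`` (to within 1/n for continuous data).  At
    test time no jitter is applied: a point is an outlier iff it falls
    outside the rectangle on either axis (a point outside on both axes
    is still a single outlier).

    Attributes
    ----------
    x_lower_, x_upper_, y_lower_, y_upper_ : float
        Rectangle edges.
    per_axis_fraction_ : float
        Calibrated per-axis two-tailed quantile level.
    train_outside_fraction_ : float
        Achieved outside-fraction on the jittered training points.
    """

    def __init__(
        self,
        outlier_fraction: float = 0.05,
        jitter_halfwidth: float = 0.5,
        random_state: int = 0,
        max_iter: int = 60,
    ):
        self.outlier_fraction = outlier_fraction
        self.jitter_halfwidth = jitter_halfwidth
        self.random_state = random_state
        self.max_iter = max_iter

    @staticmethod
    def _check_xy(X) -> np.ndarray:
        pts = np.asarray(X, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ContractError("expected an (n, 2) array of bivariate feature points")
        if pts.shape[0] == 0:
            raise ContractError("feature series is empty")
        return pts

    @staticmethod
    def _edges(xj, yj, level):
        xl, xu = np.quantile(xj, [level / 2, 1 - level / 2])
        yl, yu = np.quantile(yj, [level / 2, 1 - level / 2])
        return xl, xu, yl, yu

    @staticmethod
    def _outside_mask(x, y, edges):
        xl, xu, yl, yu = edges
        return (x < xl) | (x > xu) | (y < yl) | (y > yu)

    def fit(self, X, y=None):
        f = self.outlier_fraction
        if not 0 < f < 1:
            raise ParameterError("outlier_fraction must lie strictly between 0 and 1")
        pts = self._check_xy(X)
        n = pts.shape[0]
        rng = np.random.default_rng(self.random_state)
        xj = pts[:, 0] + rng.uniform(-self.jitter_halfwidth, self.jitter_halfwidth, n)
        yj = pts[:, 1] + rng.uniform(-self.jitter_halfwidth, self.jitter_halfwidth, n)

        def achieved(level):
            return float(self._outside_mask(xj, yj, self._edges(xj, yj, level)).mean())

        # Outside-fraction is a non-decreasing step function of the per-axis
        # level; bisect, keeping the level whose achieved fraction is closest.
        lo, hi = 0.0, min(1.0, 2.0 * f)
        best_level, best_err = hi, abs(achieved(hi) - f)
        for _ in range(self.max_iter):
            mid = (lo + hi) / 2
            got = achieved(mid)
            err = abs(got - f)
            if err < best_err or (err == best_err and mid < best_level):
                best_level, best_err = mid, err
            if got < f:
                lo = mid
            else:
                hi = mid
        self.per_axis_fraction_ = float(best_level)
        self.x_lower_, self.x_upper_, self.y_lower_, self.y_upper_ = (
            float(e) for e in self._edges(xj, yj, best_level)
        )
        self.n_samples_ = n
        self.train_outside_fraction_ = achieved(best_level)
        return self

    def outside(self, X) -> np.ndarray:
        """Boolean mask of points strictly outside the frame (no jitter)."""
        check_is_fitted(self, "x_lower_")
        pts = self._check_xy(X)
        return self._outside_mask(
            pts[:, 0], pts[:, 1], (self.x_lower_, self.x_upper_, self.y_lower_, self.y_upper_)
        )

    def predict(self, X) -> np.ndarray:
        """+1 for points inside the frame, −1 for points outside."""
        return np.where(self.outside(X), -1, 1)
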