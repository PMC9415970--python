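"""Personal baseline records and fitting helpers.

A baseline is what ``train`` learns for one person × one feature ×
one variant and what ``detect`` applies to new data.  Three kinds exist:

* :class:`GaussianBaseline` — μ ± α·σ band over the training feature
  distribution (the primary rule for extrema and amplitude).
* :class:`QuantileThresholds` — empirical-quantile band leaving a fixed
  fraction of training values outside (the "5 % threshold" rule,
  used for integer-binned dominant-frequency features, with jitter).
* :class:`BivariateFrame` — rectangle over two features calibrated to a
  joint training outside-fraction.

The fitting functions are thin wrappers over the sklearn-style
detectors in :mod:`breathalert.detectors`; records serialize to JSON so
training and detection can run as separate invocations.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .detectors import (
    BivariateFrameDetector,
    GaussianBaselineDetector,
    QuantileBaselineDetector,
)
from .exceptions import AlignmentError, ContractError, TraceFormatError
from .windowed_features import FeatureSeries


@dataclass(frozen=True)
class GaussianBaseline:
    """μ ± α·σ thresholds learned from one person's feature distribution.

    ``sigma = 0`` is legal (constant training signal): the band
    degenerates to the point μ and any deviation from it alerts.
    """

    mu: float
    sigma: float
    alpha: float
    lower: float
    upper: float
    feature_kind: str = ""
    subject_id: str = ""

    def __post_init__(self):
        if self.sigma < 0 or self.alpha <= 0:
            raise ContractError("sigma must be >= 0 and alpha > 0")


@dataclass(frozen=True)
class QuantileThresholds:
    """Empirical-quantile band leaving ``outlier_fraction`` of training outside."""

    lower: float
    upper: float
    outlier_fraction: float
    sidedness: str = "two_sided"

    def __post_init__(self):
        if self.lower > self.upper:
            raise ContractError("lower threshold exceeds upper threshold")


@dataclass(frozen=True)
class BivariateFrame:
    """Axis-aligned rectangle over two features with a joint outside-fraction."""

    x_thresholds: QuantileThresholds
    y_thresholds: QuantileThresholds
    joint_outlier_fraction: float
    jitter_seed: int
    jitter_halfwidth: float

    def outside(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Boolean mask of (x, y) points strictly outside the rectangle."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape:
            raise AlignmentError("x and y must have equal length")
        return (
            (x < self.x_thresholds.lower)
            | (x > self.x_thresholds.upper)
            | (y < self.y_thresholds.lower)
            | (y > self.y_thresholds.upper)
        )


def _values(features: FeatureSeries | np.ndarray) -> np.ndarray:
    return features.values if isinstance(features, FeatureSeries) else np.asarray(features, float)


def fit_gaussian_baseline(
    features: FeatureSeries, alpha: float = 1.5, ddof: int = 0
) -> GaussianBaseline:
    """Fit μ, σ and the μ ± α·σ thresholds to a feature series."""
    det = GaussianBaselineDetector(alpha=alpha, ddof=ddof).fit(_values(features))
    return GaussianBaseline(
        mu=det.mu_,
        sigma=det.sigma_,
        alpha=alpha,
        lower=det.mu_ - alpha * det.sigma_,
        upper=det.mu_ + alpha * det.sigma_,
        feature_kind=getattr(features, "kind", ""),
        subject_id=getattr(features, "source_subject", ""),
    )


def fit_quantile_thresholds(
    features: FeatureSeries,
    outlier_fraction: float = 0.05,
    sidedness: str = "two_sided",
    jitter_seed: int | None = None,
    jitter_halfwidth: float = 0.5,
) -> QuantileThresholds:
    """Fit empirical-quantile thresholds; jitter is applied iff a seed is given."""
    det = QuantileBaselineDetector(
        outlier_fraction=outlier_fraction,
        sidedness=sidedness,
        jitter_halfwidth=jitter_halfwidth,
        random_state=jitter_seed,
    ).fit(_values(features))
    return QuantileThresholds(
        lower=det.lower_,
        upper=det.upper_,
        outlier_fraction=outlier_fraction,
        sidedness=sidedness,
    )


def fit_bivariate_frame(
    x: FeatureSeries,
    y: FeatureSeries,
    joint_outlier_fraction: float = 0.05,
    jitter_seed: int = 0,
    jitter_halfwidth: float = 0.5,
) -> BivariateFrame:
    """Fit the rectangular outlier frame over two aligned feature series."""
    xv, yv = _values(x), _values(y)
    if xv.size != yv.size:
        raise AlignmentError("x and y feature series must have equal length")
    det = BivariateFrameDetector(
        outlier_fraction=joint_outlier_fraction,
        jitter_halfwidth=jitter_halfwidth,
        random_state=jitter_seed,
    ).fit(np.column_stack([xv, yv]))
    per_axis = det.per_axis_fraction_
    return BivariateFrame(
        x_thresholds=QuantileThresholds(det.x_lower_, det.x_upper_, per_axis),
        y_thresholds=QuantileThresholds(det.y_lower_, det.y_upper_, per_axis),
        joint_outlier_fraction=joint_outlier_fraction,
        jitter_seed=jitter_seed,
        jitter_halfwidth=jitter_halfwidth,
    )


def jittered_training_outside_fraction(
    frame: BivariateFrame, x: FeatureSeries | np.ndarray, y: FeatureSeries | np.ndarray
) -> float:
    """Fraction of the jittered training points outside the frame.

    Re-applies the seeded jitter used at fit time (the x draw precedes
    the y draw on one generator), so on the original training series
    this reproduces the calibrated outside-fraction exactly.
    """
    xv, yv = _values(x), _values(y)
    rng = np.random.default_rng(frame.jitter_seed)
    xj = xv + rng.uniform(-frame.jitter_halfwidth, frame.jitter_halfwidth, xv.size)
    yj = yv + rng.uniform(-frame.jitter_halfwidth, frame.jitter_halfwidth, yv.size)
    return float(frame.outside(xj, yj).mean())


_BASELINE_TYPES = {
    "gaussian": GaussianBaseline,
    "quantile": QuantileThresholds,
    "bivariate_frame": BivariateFrame,
}


def save_baseline(
    baseline: GaussianBaseline | QuantileThresholds | BivariateFrame,
    path: str | Path,
    extra: dict | None = None,
) -> None:
    """Serialize a baseline record to JSON (with an optional metadata block)."""
    for tag, cls in _BASELINE_TYPES.items():
        if isinstance(baseline, cls):
            break
    else:
        raise ContractError(f"unknown baseline type {type(baseline).__name__}")
    payload = {"type": tag, "baseline": asdict(baseline)}
    if extra:
        payload["meta"] = extra
    Path(path).write_text(json.dumps(payload, indent=2))


def load_baseline(path: str | Path):
    """Load a baseline record written by :func:`save_baseline`."""
    payload = json.loads(Path(path).read_text())
    tag = payload.get("type")
    if tag not in _BASELINE_TYPES:
        raise TraceFormatError(f"{path}: unknown baseline type {tag!r}")
    fields = payload["baseline"]
    if tag == "bivariate_frame":
        fields = dict(
            fields,
            x_thresholds=QuantileThresholds(**fields["x_thresholds"]),
            y_thresholds=QuantileThresholds(**fields["y_thresholds"]),
        )
    return _BASELINE_TYPES[tag](**fields)
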