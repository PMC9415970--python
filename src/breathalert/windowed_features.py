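"""Per-window features of a respiration trace.

Four features summarise each sliding window of W samples starting at i:

* moving maximum   M(i) = max(s(i) … s(i+W−1))  — deepest inhalation
* moving minimum   m(i) = min(s(i) … s(i+W−1))  — fullest exhalation
* amplitude        A(i) = M(i) − m(i)           — breath depth
* dominant frequency f(i) = argmax_j |DFT(w_i)_j| — breathing-rate proxy,
  reported as a DFT bin index.

Windows slide with a configurable stride (default 1).  Two enumeration
conventions coexist because the source analyses index the extremum series
0…N−W but the frequency series 0…N−W−1: ``all_full_windows`` keeps every
complete window (⌊(N−W)/stride⌋ + 1 values) while ``drop_last`` discards
the final one (⌊(N−W)/stride⌋ values).

The DFT argmax has two modes.  The default demeans each window and
restricts the argmax to bins 1…⌊W/2⌋: a belt signal has a large positive
offset, so without demeaning the DC bin dominates every window and the
feature is uninformative.  ``paper_literal`` mode applies the raw formula
(no demeaning, argmax over all W bins, mirrored half included).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import AlignmentError, ContractError, ParameterError
from .signal_io import RespirationTrace

ENUMERATIONS = ("all_full_windows", "drop_last")
FEATURE_KINDS = ("moving_max", "moving_min", "amplitude", "dominant_frequency")
BIN_RANGES = ("all_bins", "positive_bins")


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry: size W, stride, and enumeration convention."""

    size: int
    stride: int = 1
    enumeration: str = "all_full_windows"

    def __post_init__(self):
        if self.size < 1:
            raise ParameterError("window size must be >= 1")
        if self.stride < 1:
            raise ParameterError("stride must be >= 1")
        if self.enumeration not in ENUMERATIONS:
            raise ParameterError(f"enumeration must be one of {ENUMERATIONS}")

    def n_windows(self, n_samples: int) -> int:
        """Number of feature values produced from a trace of n_samples."""
        if n_samples < self.size:
            raise ContractError(
                f"trace of {n_samples} samples is shorter than window size {self.size}"
            )
        full = (n_samples - self.size) // self.stride + 1
        if self.enumeration == "drop_last":
            full -= 1
        if full < 1:
            raise ContractError(
                f"no windows: {n_samples} samples, W={self.size}, stride={self.stride}, "
                f"{self.enumeration}"
            )
        return full


@dataclass
class FeatureSeries:
    """One windowed feature series with its provenance."""

    kind: str
    values: np.ndarray
    window: WindowSpec
    source_subject: str = ""
    variant: str = "combined"

    def __post_init__(self):
        if self.kind not in FEATURE_KINDS:
            raise ParameterError(f"kind must be one of {FEATURE_KINDS}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ContractError("feature values must be 1-D")

    def __len__(self) -> int:
        return self.values.size


def _windows(samples: np.ndarray, spec: WindowSpec) -> np.ndarray:
    n = spec.n_windows(samples.size)
    return sliding_window_view(samples, spec.size)[:: spec.stride][:n]


class WindowFeatureExtractor(TransformerMixin, BaseEstimator):
    """Transformer from a raw 1-D signal to a windowed feature series.

    Unlike tabular sklearn transformers this operates on a single 1-D
    signal (or a :class:`RespirationTrace`) and returns a 1-D array of
    per-window feature values; it is stateless, so ``fit`` only
    validates parameters.

    Parameters
    ----------
    kind : {"moving_max", "moving_min", "amplitude", "dominant_frequency"}
        Feature to compute. ``amplitude`` is the per-window max − min.
    window_size, stride, enumeration
        Sliding-window geometry; see :class:`WindowSpec`.
    demean : bool
        Subtract each window's mean before the DFT (frequency kind only).
    bin_range : {"positive_bins", "all_bins"}
        Restrict the DFT argmax to bins 1…⌊W/2⌋, or use all W bins
        (the literal formula, DC included).
    """

    def __init__(
        self,
        kind: str = "amplitude",
        window_size: int = 12,
        stride: int = 1,
        enumeration: str = "all_full_windows",
        demean: bool = True,
        bin_range: str = "positive_bins",
    ):
        self.kind = kind
        self.window_size = window_size
        self.stride = stride
        self.enumeration = enumeration
        self.demean = demean
        self.bin_range = bin_range

    def _spec(self) -> WindowSpec:
        return WindowSpec(self.window_size, self.stride, self.enumeration)

    def fit(self, X=None, y=None):
        if self.kind not in FEATURE_KINDS:
            raise ParameterError(f"kind must be one of {FEATURE_KINDS}")
        if self.bin_range not in BIN_RANGES:
            raise ParameterError(f"bin_range must be one of {BIN_RANGES}")
        self.window_spec_ = self._spec()
        return self

    def transform(self, X) -> np.ndarray:
        """Compute the feature over X (1-D array or RespirationTrace)."""
        if not hasattr(self, "window_spec_"):
            self.fit()
        samples = X.samples if isinstance(X, RespirationTrace) else np.asarray(X, dtype=float)
        if samples.ndim != 1:
            raise ContractError("expected a single 1-D signal")
        spec = self.window_spec_
        if self.kind in ("moving_max", "moving_min"):
            w = _windows(samples, spec)
            return w.max(axis=1) if self.kind == "moving_max" else w.min(axis=1)
        if self.kind == "amplitude":
            w = _windows(samples, spec)
            return w.max(axis=1) - w.min(axis=1)
        return self._dominant_frequency(samples, spec)

    def _dominant_frequency(self, samples: np.ndarray, spec: WindowSpec) -> np.ndarray:
        if spec.size < 2:
            raise ParameterError("dominant frequency needs a window of at least 2 samples")
        w = _windows(samples, spec)
        if self.demean:
            w = w - w.mean(axis=1, keepdims=True)
        # For a real signal, bins j and W−j have identical magnitude, so the
        # smallest-index tie-break means the all-bins argmax can only land in
        # 0…⌊W/2⌋; computing on the rfft half keeps that exact instead of
        # leaving the winner to float noise between mirrored bins.
        mags = np.abs(np.fft.rfft(w, axis=1))
        if self.bin_range == "positive_bins":
            return mags[:, 1 : spec.size // 2 + 1].argmax(axis=1).astype(float) + 1.0
        return mags.argmax(axis=1).astype(float)

    def extract(self, trace: RespirationTrace, variant: str = "combined") -> FeatureSeries:
        """Transform a trace and wrap the result with provenance."""
        self.fit()
        return FeatureSeries(
            kind=self.kind,
            values=self.transform(trace),
            window=self.window_spec_,
            source_subject=trace.subject_id,
            variant=variant,
        )


def moving_extremum(
    trace: RespirationTrace, window: WindowSpec, which: str = "max"
) -> FeatureSeries:
    """Moving maximum M(i) or minimum m(i) over sliding windows."""
    if which not in ("max", "min"):
        raise ParameterError("which must be 'max' or 'min'")
    ext = WindowFeatureExtractor(
        kind=f"moving_{which}",
        window_size=window.size,
        stride=window.stride,
        enumeration=window.enumeration,
    )
    return ext.extract(trace)


def amplitude(max_series: FeatureSeries, min_series: FeatureSeries) -> FeatureSeries:
    """Per-window breath depth A(i) = M(i) − m(i)."""
    if max_series.kind != "moving_max" or min_series.kind != "moving_min":
        raise ContractError("amplitude expects a moving_max and a moving_min series")
    if max_series.window != min_series.window or len(max_series) != len(min_series):
        raise AlignmentError("max and min series must share window spec and length")
    if max_series.source_subject != min_series.source_subject:
        raise AlignmentError("max and min series come from different subjects")
    return FeatureSeries(
        kind="amplitude",
        values=max_series.values - min_series.values,
        window=max_series.window,
        source_subject=max_series.source_subject,
        variant=max_series.variant,
    )


def dominant_frequency(
    trace: RespirationTrace,
    window: WindowSpec,
    demean: bool = True,
    bin_range: str = "positive_bins",
) -> FeatureSeries:
    """Dominant DFT bin index f(i) per window (breathing-rate proxy).

    Ties break toward the smallest bin index.  With ``demean=False`` and
    ``bin_range="all_bins"`` this is the literal argmax over all W bins.
    """
    ext = WindowFeatureExtractor(
        kind="dominant_frequency",
        window_size=window.size,
        stride=window.stride,
        enumeration=window.enumeration,
        demean=demean,
        bin_range=bin_range,
    )
    return ext.extract(trace)
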