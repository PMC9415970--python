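"""End-to-end train/detect pipelines.

Field mode trains each person's baselines on the resting portion of the
protocol (the leading sitting + walking phases, ~2880 samples at 12 Hz)
and tests on the running phase (~1440 samples).  Literature mode trains
on the first half of a recording and tests on the second half.  Each of
the three talking variants (talking / not_talking / combined) filters
the samples before feature extraction, so every variant gets its own
feature series and baselines.

Per-feature defaults: extrema and amplitude use window 12 (1 s at
12 Hz) with the Gaussian μ ± α·σ rule (α = 1.5); dominant frequency
uses window 48 with two-sided 5 % quantile thresholds, jittered because
the feature is integer-binned.  Literature mode uses window 128 for all
features.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .alerts import AlertSeries, RaLaCounts, detect_alerts, detect_bivariate_alerts, ra_la_counts
from .baseline import (
    BivariateFrame,
    GaussianBaseline,
    QuantileThresholds,
    fit_bivariate_frame,
    fit_gaussian_baseline,
    fit_quantile_thresholds,
)
from .exceptions import ContractError, ParameterError
from .signal_io import BivariateTrace, RespirationTrace
from .windowed_features import (
    FeatureSeries,
    WindowSpec,
    amplitude,
    dominant_frequency,
    moving_extremum,
)

FEATURE_SIDE_RULES: Mapping[str, str] = {
    "moving_max": "upper_only",   # deep breathing: belt extends beyond the band
    "moving_min": "lower_only",   # exhausted exhalation: belt below the band
    "amplitude": "upper_only",    # breath depth above the band
    "dominant_frequency": "two_sided",  # breathing too fast or too slow
}


def filter_variant(trace: RespirationTrace, variant: str) -> RespirationTrace:
    """Restrict a trace to its talking / non-talking samples (or keep all)."""
    if variant == "combined":
        return trace
    if trace.talking_flags is None:
        raise ContractError(f"variant {variant!r} requires talking flags on the trace")
    if variant == "talking":
        return trace.select(trace.talking_flags)
    if variant == "not_talking":
        return trace.select(~trace.talking_flags)
    raise ParameterError(f"unknown variant {variant!r}")


def field_split(trace: RespirationTrace) -> tuple[RespirationTrace, RespirationTrace]:
    """Split a field-protocol trace into (sit+walk training, running test)."""
    if trace.activity_labels is None:
        raise ContractError("field split requires activity labels")
    run = trace.activity_labels == "running"
    if not run.any():
        raise ContractError("trace has no running phase")
    first_run = int(np.flatnonzero(run)[0])
    if first_run == 0:
        raise ContractError("trace has no resting prefix to train on")
    return trace.slice(0, first_run), trace.select(run)


def final_rest_segment(trace: RespirationTrace) -> RespirationTrace:
    """The resting tail after the last running sample (the closing sit phase)."""
    if trace.activity_labels is None:
        raise ContractError("requires activity labels")
    run = np.flatnonzero(trace.activity_labels == "running")
    if run.size == 0 or run[-1] + 1 >= len(trace):
        raise ContractError("trace has no resting tail after running")
    return trace.slice(int(run[-1]) + 1, len(trace))


def literature_split(trace: RespirationTrace) -> tuple[RespirationTrace, RespirationTrace]:
    """First half for training, second half for testing."""
    half = len(trace) // 2
    if half == 0:
        raise ContractError("trace too short to split")
    return trace.slice(0, half), trace.slice(half, len(trace))


def extract_feature(
    trace: RespirationTrace,
    kind: str,
    window_size: int,
    stride: int = 1,
    fft_mode: str = "demeaned",
    variant: str = "combined",
) -> FeatureSeries:
    """Compute one feature series with the conventional enumeration per kind."""
    if kind == "dominant_frequency":
        spec = WindowSpec(window_size, stride, "drop_last")
        demean = fft_mode != "paper_literal"
        fs = dominant_frequency(
            trace, spec, demean=demean,
            bin_range="positive_bins" if demean else "all_bins",
        )
    else:
        spec = WindowSpec(window_size, stride, "all_full_windows")
        if kind == "amplitude":
            fs = amplitude(
                moving_extremum(trace, spec, "max"), moving_extremum(trace, spec, "min")
            )
        elif kind in ("moving_max", "moving_min"):
            fs = moving_extremum(trace, spec, kind.removeprefix("moving_"))
        else:
            raise ParameterError(f"unknown feature kind {kind!r}")
    fs.variant = variant
    return fs


@dataclass
class FeatureResult:
    """Everything the pipeline learned and detected for one feature."""

    kind: str
    baseline: GaussianBaseline | QuantileThresholds
    train_features: FeatureSeries
    test_features: FeatureSeries
    alerts: AlertSeries


def _analyze(
    train_trace: RespirationTrace,
    test_trace: RespirationTrace,
    variant: str,
    alpha: float,
    outlier_fraction: float,
    extremum_window: int,
    fft_window: int,
    stride: int,
    fft_mode: str,
    jitter_seed: int,
    side_rules: Mapping[str, str],
) -> dict[str, FeatureResult]:
    results: dict[str, FeatureResult] = {}
    for kind, side_rule in side_rules.items():
        w = fft_window if kind == "dominant_frequency" else extremum_window
        train_f = extract_feature(train_trace, kind, w, stride, fft_mode, variant)
        test_f = extract_feature(test_trace, kind, w, stride, fft_mode, variant)
        if kind == "dominant_frequency":
            baseline = fit_quantile_thresholds(
                train_f, outlier_fraction, side_rule, jitter_seed=jitter_seed
            )
        else:
            baseline = fit_gaussian_baseline(train_f, alpha)
        results[kind] = FeatureResult(
            kind=kind,
            baseline=baseline,
            train_features=train_f,
            test_features=test_f,
            alerts=detect_alerts(test_f, baseline, side_rule),
        )
    return results


def analyze_field_subject(
    trace: RespirationTrace,
    variant: str = "combined",
    alpha: float = 1.5,
    outlier_fraction: float = 0.05,
    extremum_window: int = 12,
    fft_window: int = 48,
    stride: int = 1,
    fft_mode: str = "demeaned",
    jitter_seed: int = 0,
    test_segment: str = "running",
    side_rules: Mapping[str, str] = FEATURE_SIDE_RULES,
) -> dict[str, FeatureResult]:
    """Train on the sit+walk prefix and detect on a test segment.

    ``test_segment`` is ``"running"`` (the study's evaluation) or
    ``"final_rest"`` (the closing sit phase, a same-condition control).
    """
    train_trace, run_trace = field_split(trace)
    test_trace = run_trace if test_segment == "running" else final_rest_segment(trace)
    return _analyze(
        filter_variant(train_trace, variant),
        filter_variant(test_trace, variant),
        variant, alpha, outlier_fraction, extremum_window, fft_window,
        stride, fft_mode, jitter_seed, side_rules,
    )


def analyze_literature_trace(
    trace: RespirationTrace,
    alpha: float = 1.5,
    outlier_fraction: float = 0.05,
    window: int = 128,
    stride: int = 1,
    fft_mode: str = "demeaned",
    jitter_seed: int = 0,
    side_rules: Mapping[str, str] = FEATURE_SIDE_RULES,
) -> dict[str, FeatureResult]:
    """First-half training, second-half testing, window 128 for all features."""
    train_trace, test_trace = literature_split(trace)
    return _analyze(
        train_trace, test_trace, "combined", alpha, outlier_fraction,
        window, window, stride, fft_mode, jitter_seed, side_rules,
    )


@dataclass
class BivariateResult:
    """Fitted frame plus test-set alerts for a two-channel recording."""

    frame: BivariateFrame
    alerts: AlertSeries
    train_inside_fraction: float
    test_inside_fraction: float


def analyze_bivariate(
    trace: BivariateTrace,
    joint_outlier_fraction: float = 0.05,
    window: int = 128,
    stride: int = 1,
    jitter_seed: int = 0,
    jitter_halfwidth: float = 0.5,
) -> BivariateResult:
    """Bivariate dominant-frequency frame: train on first half, test on second.

    The inside-fractions are reported on the unjittered feature points.
    """
    spec = WindowSpec(window, stride, "drop_last")
    feats = {}
    for name, chan in (("x", trace.channel_a), ("y", trace.channel_b)):
        train_c, test_c = literature_split(chan)
        feats[name] = (
            dominant_frequency(train_c, spec),
            dominant_frequency(test_c, spec),
        )
    frame = fit_bivariate_frame(
        feats["x"][0], feats["y"][0], joint_outlier_fraction, jitter_seed, jitter_halfwidth
    )
    alerts = detect_bivariate_alerts(feats["x"][1], feats["y"][1], frame)
    train_out = frame.outside(feats["x"][0].values, feats["y"][0].values).mean()
    return BivariateResult(
        frame=frame,
        alerts=alerts,
        train_inside_fraction=float(1.0 - train_out),
        test_inside_fraction=float(1.0 - alerts.fraction),
    )


def ra_la_sweep(
    traces: Iterable[RespirationTrace],
    window_sizes: Sequence[int] = (2, 3, 4, 12, 19, 20, 40),
    variant: str = "combined",
    alpha: float = 1.5,
    stride: int = 1,
) -> pd.DataFrame:
    """Window-size sensitivity of the amplitude feature.

    For each window size, counts the subjects whose two-sided amplitude
    alerts during running fall more often above the training mean than
    below it (RA > LA).
    """
    traces = list(traces)
    if not traces:
        raise ContractError("ra_la_sweep needs at least one trace")
    rows = []
    for w in window_sizes:
        n_gt = 0
        for trace in traces:
            train_trace, run_trace = field_split(trace)
            train_f = extract_feature(filter_variant(train_trace, variant), "amplitude", w, stride)
            test_f = extract_feature(filter_variant(run_trace, variant), "amplitude", w, stride)
            baseline = fit_gaussian_baseline(train_f, alpha)
            alerts = detect_alerts(test_f, baseline, "two_sided")
            counts = ra_la_counts(test_f, alerts, baseline)
            n_gt += int(counts.ra > counts.la)
        rows.append({"window_size": w, "ra_gt_la": n_gt, "n_subjects": len(traces)})
    return pd.DataFrame(rows)
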