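"""Applying baselines to test windows and summarising alerts.

Deep breathing shows as moving-max values above the personal band
(side "above"), exhausted exhalation as moving-min values below it
(side "below"); amplitude and dominant-frequency alerts are typically
one-sided upward but both sides are supported.  All comparisons are
strict: a value exactly at a threshold does not alert.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .baseline import BivariateFrame, GaussianBaseline, QuantileThresholds
from .exceptions import AlignmentError, ContractError, ParameterError
from .windowed_features import FeatureSeries

VARIANTS = ("talking", "not_talking", "combined")
SIDE_RULES = ("two_sided", "upper_only", "lower_only")


@dataclass
class AlertSeries:
    """Per-window alert flags for one subject × feature × variant."""

    flags: np.ndarray
    sides: np.ndarray
    values: np.ndarray
    feature_kind: str
    subject_id: str = ""
    variant: str = "combined"

    def __post_init__(self):
        self.flags = np.asarray(self.flags, dtype=bool)
        self.sides = np.asarray(self.sides, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        if not (self.flags.shape == self.sides.shape == self.values.shape):
            raise AlignmentError("flags, sides and values must be aligned")
        if self.variant not in VARIANTS:
            raise ParameterError(f"variant must be one of {VARIANTS}")
        if ((self.sides == "none") != ~self.flags).any():
            raise ContractError("sides must be 'none' exactly where flags are false")

    @property
    def n_windows(self) -> int:
        return self.flags.size

    @property
    def n_alerts(self) -> int:
        return int(self.flags.sum())

    @property
    def fraction(self) -> float:
        """Share of windows flagged — the primary evaluation statistic."""
        if self.n_windows == 0:
            raise ContractError("alert fraction of an empty series is undefined")
        return self.n_alerts / self.n_windows


@dataclass(frozen=True)
class RaLaCounts:
    """Alert counts right (above) and left (below) of the training mean."""

    ra: int
    la: int
    window_size: int


def detect_alerts(
    features: FeatureSeries,
    baseline: GaussianBaseline | QuantileThresholds,
    side_rule: str = "two_sided",
) -> AlertSeries:
    """Flag windows whose feature value violates the selected band edge(s)."""
    if side_rule not in SIDE_RULES:
        raise ParameterError(f"side_rule must be one of {SIDE_RULES}")
    if len(features) == 0:
        raise ContractError("cannot detect alerts on an empty feature series")
    if isinstance(baseline, GaussianBaseline) and baseline.feature_kind:
        if baseline.feature_kind != features.kind:
            raise ContractError(
                f"baseline was fit on {baseline.feature_kind!r} but series is {features.kind!r}"
            )
    v = features.values
    above = v > baseline.upper if side_rule != "lower_only" else np.zeros(v.size, bool)
    below = v < baseline.lower if side_rule != "upper_only" else np.zeros(v.size, bool)
    sides = np.where(above, "above", np.where(below, "below", "none")).astype(object)
    return AlertSeries(
        flags=above | below,
        sides=sides,
        values=v,
        feature_kind=features.kind,
        subject_id=features.source_subject,
        variant=features.variant,
    )


def detect_bivariate_alerts(
    x: FeatureSeries, y: FeatureSeries, frame: BivariateFrame
) -> AlertSeries:
    """Flag windows whose (x, y) point lies outside the rectangular frame.

    No jitter is applied at test time; a point outside on both axes is a
    single alert.  Side is "above" when any upper edge is violated,
    otherwise "below".
    """
    if len(x) != len(y):
        raise AlignmentError("x and y feature series must be aligned")
    out = frame.outside(x.values, y.values)
    over = (x.values > frame.x_thresholds.upper) | (y.values > frame.y_thresholds.upper)
    sides = np.where(out & over, "above", np.where(out, "below", "none")).astype(object)
    return AlertSeries(
        flags=out,
        sides=sides,
        values=x.values,
        feature_kind=x.kind,
        subject_id=x.source_subject,
        variant=x.variant,
    )


def alert_fraction(alerts: AlertSeries) -> float:
    """n_alerts / n_windows."""
    return alerts.fraction


def ra_la_counts(
    features: FeatureSeries, alerts: AlertSeries, baseline: GaussianBaseline
) -> RaLaCounts:
    """Split alerts by which side of the training mean their value falls.

    Values exactly equal to the mean count toward neither side.
    """
    if len(features) != alerts.n_windows:
        raise AlignmentError("features and alerts must be aligned")
    v = features.values[alerts.flags]
    return RaLaCounts(
        ra=int((v > baseline.mu).sum()),
        la=int((v < baseline.mu).sum()),
        window_size=features.window.size,
    )


def cohort_summary(
    per_subject_alerts: Iterable[AlertSeries],
    require_variant: str | None = None,
) -> pd.DataFrame:
    """Mean and sd of per-subject alert fractions, by feature kind and variant.

    The sd is the population convention (a single subject gives sd 0).
    With ``require_variant`` set, any series from another variant is a
    contract violation rather than silently forming its own group.
    """
    series = list(per_subject_alerts)
    if not series:
        raise ContractError("cohort summary of an empty collection")
    if require_variant is not None:
        wrong = {s.variant for s in series} - {require_variant}
        if wrong:
            raise ContractError(
                f"expected only variant {require_variant!r}, also got {sorted(wrong)}"
            )
    rows = pd.DataFrame(
        {
            "feature_kind": [s.feature_kind for s in series],
            "variant": [s.variant for s in series],
            "subject_id": [s.subject_id for s in series],
            "fraction": [s.fraction for s in series],
        }
    )
    dup = rows.duplicated(["feature_kind", "variant", "subject_id"])
    if dup.any():
        raise ContractError("duplicate subject within a feature/variant group")
    out = (
        rows.groupby(["feature_kind", "variant"])["fraction"]
        .agg(mean_fraction="mean", sd_fraction=lambda f: float(np.std(f)), n_subjects="size")
        .reset_index()
    )
    return out
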