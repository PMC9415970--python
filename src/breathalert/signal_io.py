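"""Reading and writing respiration traces and alert tables.

Traces travel as plain CSV: one header row, one sample per data row, with
optional ``activity`` and ``talking`` columns carrying per-sample protocol
labels.  The sampling rate is supplied out of band (it is a property of the
acquisition device, not of the file).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, TYPE_CHECKING

import numpy as np
import pandas as pd

from .exceptions import AlignmentError, ContractError, TraceFormatError, TraceParseError

if TYPE_CHECKING:  # pragma: no cover
    from .alerts import AlertSeries

#: Recognised per-sample activity categories.
ACTIVITIES = ("sitting", "walking", "running", "other")

#: Default CSV column names, keyed by trace field.
DEFAULT_COLUMNS: Mapping[str, str] = {
    "sample": "sample",
    "activity": "activity",
    "talking": "talking",
}


@dataclass
class RespirationTrace:
    """A sampled respiration-belt signal with optional protocol labels.

    Parameters
    ----------
    samples
        Belt-extension values s(i), arbitrary units.
    sampling_rate
        Samples per second (Hz); the field study used 12 Hz.
    activity_labels
        Optional per-sample category from :data:`ACTIVITIES`.
    talking_flags
        Optional per-sample boolean: was the subject talking at sample i.
    subject_id
        Opaque identifier for the person the trace belongs to.
    """

    samples: np.ndarray
    sampling_rate: float
    activity_labels: np.ndarray | None = None
    talking_flags: np.ndarray | None = None
    subject_id: str = ""

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ContractError("samples must be a non-empty 1-D sequence")
        if not self.sampling_rate > 0:
            raise ContractError("sampling_rate must be positive")
        if self.activity_labels is not None:
            self.activity_labels = np.asarray(self.activity_labels, dtype=object)
            if self.activity_labels.shape != self.samples.shape:
                raise AlignmentError("activity_labels length must match samples")
            bad = set(self.activity_labels) - set(ACTIVITIES)
            if bad:
                raise ContractError(f"unknown activity labels: {sorted(bad)}")
        if self.talking_flags is not None:
            self.talking_flags = np.asarray(self.talking_flags, dtype=bool)
            if self.talking_flags.shape != self.samples.shape:
                raise AlignmentError("talking_flags length must match samples")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Trace duration in seconds."""
        return len(self) / self.sampling_rate

    def slice(self, start: int, stop: int) -> "RespirationTrace":
        """Return the sub-trace covering sample indices [start, stop)."""
        return RespirationTrace(
            samples=self.samples[start:stop],
            sampling_rate=self.sampling_rate,
            activity_labels=None if self.activity_labels is None else self.activity_labels[start:stop],
            talking_flags=None if self.talking_flags is None else self.talking_flags[start:stop],
            subject_id=self.subject_id,
        )

    def select(self, mask: np.ndarray) -> "RespirationTrace":
        """Return the sub-trace at the True positions of a boolean mask.

        Selected samples are concatenated, so windows computed downstream
        may span removed gaps; this mirrors training on pooled
        talking-only or non-talking-only segments.
        """
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != self.samples.shape:
            raise AlignmentError("mask length must match samples")
        if not mask.any():
            raise ContractError("selection mask removes every sample")
        return RespirationTrace(
            samples=self.samples[mask],
            sampling_rate=self.sampling_rate,
            activity_labels=None if self.activity_labels is None else self.activity_labels[mask],
            talking_flags=None if self.talking_flags is None else self.talking_flags[mask],
            subject_id=self.subject_id,
        )


@dataclass
class BivariateTrace:
    """Two synchronously sampled channels (respiration + ocular movement)."""

    channel_a: RespirationTrace
    channel_b: RespirationTrace

    def __post_init__(self):
        if len(self.channel_a) != len(self.channel_b):
            raise AlignmentError("channels must have equal sample counts")
        if self.channel_a.sampling_rate != self.channel_b.sampling_rate:
            raise AlignmentError("channels must share a sampling rate")

    def __len__(self) -> int:
        return len(self.channel_a)


def read_trace_csv(
    path: str | Path,
    sampling_rate: float,
    column_map: Mapping[str, str] | None = None,
    subject_id: str = "",
) -> RespirationTrace:
    """Read a trace from CSV.

    ``column_map`` maps trace fields (``sample``, ``activity``, ``talking``)
    to CSV column names; only the sample column is required to exist.
    Raises :class:`TraceFormatError` if the sample column is missing and
    :class:`TraceParseError` (naming the 1-based data row) on a
    non-numeric sample value.
    """
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    frame = pd.read_csv(path, dtype=str, skipinitialspace=True)
    sample_col = cols["sample"]
    if sample_col not in frame.columns:
        raise TraceFormatError(
            f"{path}: missing sample column {sample_col!r} (found {list(frame.columns)})"
        )
    raw = frame[sample_col]
    values = pd.to_numeric(raw, errors="coerce")
    bad = values.isna() & raw.notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise TraceParseError(
            f"{path}: non-numeric sample value {raw.iloc[row]!r} at data row {row + 1}",
            row=row + 1,
        )
    if values.isna().any():
        row = int(np.flatnonzero(values.isna().to_numpy())[0])
        raise TraceParseError(f"{path}: empty sample value at data row {row + 1}", row=row + 1)

    activity = None
    if cols["activity"] in frame.columns:
        activity = frame[cols["activity"]].to_numpy(dtype=object)
    talking = None
    if cols["talking"] in frame.columns:
        talking = frame[cols["talking"]].str.strip().str.lower().isin(["true", "1", "yes"]).to_numpy()
    return RespirationTrace(
        samples=values.to_numpy(dtype=float),
        sampling_rate=sampling_rate,
        activity_labels=activity,
        talking_flags=talking,
        subject_id=subject_id,
    )


def write_trace_csv(trace: RespirationTrace, path: str | Path) -> None:
    """Write a trace as CSV (UTF-8, comma-separated, one header row)."""
    data = {"sample": trace.samples}
    if trace.activity_labels is not None:
        data["activity"] = trace.activity_labels
    if trace.talking_flags is not None:
        data["talking"] = trace.talking_flags
    pd.DataFrame(data).to_csv(path, index=False)


def write_bivariate_csv(trace: BivariateTrace, path: str | Path) -> None:
    """Write a two-channel trace as CSV with ``respiration``/``ocular`` columns."""
    pd.DataFrame(
        {"respiration": trace.channel_a.samples, "ocular": trace.channel_b.samples}
    ).to_csv(path, index=False)


def read_bivariate_csv(
    path: str | Path, sampling_rate: float, subject_id: str = ""
) -> BivariateTrace:
    """Read a two-channel trace written by :func:`write_bivariate_csv`."""
    a = read_trace_csv(path, sampling_rate, {"sample": "respiration"}, subject_id)
    b = read_trace_csv(path, sampling_rate, {"sample": "ocular"}, subject_id)
    return BivariateTrace(channel_a=a, channel_b=b)


def write_alerts_csv(alerts: "AlertSeries", path: str | Path) -> None:
    """Write an alert series as CSV: one row per window.

    Columns: window index, feature value, alert flag, side.
    """
    pd.DataFrame(
        {
            "window": np.arange(alerts.n_windows),
            "value": alerts.values,
            "alert": alerts.flags,
            "side": alerts.sides,
        }
    ).to_csv(path, index=False)


def read_alerts_csv(path: str | Path) -> pd.DataFrame:
    """Read an alert table back as a DataFrame (window, value, alert, side)."""
    frame = pd.read_csv(path)
    required = {"window", "value", "alert", "side"}
    if not required.issubset(frame.columns):
        raise TraceFormatError(f"{path}: alert table missing columns {sorted(required - set(frame.columns))}")
    frame["alert"] = frame["alert"].astype(bool)
    return frame
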