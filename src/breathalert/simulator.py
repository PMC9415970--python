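"""Synthetic respiration-belt signals following a study protocol.

The generator stands in for field recordings that cannot be shipped: a
belt trace is modelled as a baseline offset, a slow random-walk drift,
an activity-dependent sinusoid (breathing), and white sensor noise,

    s(i) = level + drift(i) + a(i) · sin(φ(i)) + ε(i),

where the instantaneous frequency and amplitude switch with the activity
phase, the oscillation phase φ is continuous across activity boundaries
(no spectral splatter at transitions), the per-breath amplitude is
jittered with a given coefficient of variation, and talking multiplies
the amplitude (speech interrupts the regular breathing envelope) while
doubling the per-breath CV.  Every stochastic component draws from its
own substream of a single seed, so components can be switched off
without perturbing the others.

Two canonical protocols are provided: the field protocol (sit / walk /
run / sit, 2 min each at 12 Hz, talking during each phase's second
minute — 5760 samples) and a literature-style protocol (one 63 s phase
at 128 Hz — 8064 samples, two channels).

The default activity parameters are test fixtures, not physiological
claims: they are chosen so resting and running feature distributions
overlap partially, which keeps alert fractions informative rather than
saturated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np

from .exceptions import ContractError, ParameterError
from .signal_io import ACTIVITIES, BivariateTrace, RespirationTrace

#: Talking schedule: list of (start_s, end_s) intervals in within-phase time.
TalkingSchedule = Sequence[tuple[float, float]]


@dataclass(frozen=True)
class ActivityParams:
    """Signal parameters for one activity.

    breathing_rate — sinusoid frequency, Hz; breathing_amplitude — peak
    belt units; amplitude_cv — per-breath amplitude jitter (coefficient
    of variation); talking_amplitude_factor — amplitude multiplier while
    talking; noise_sd — white-noise sd, belt units.
    """

    breathing_rate: float
    breathing_amplitude: float
    amplitude_cv: float = 0.1
    talking_amplitude_factor: float = 0.8
    noise_sd: float = 0.05

    def __post_init__(self):
        if self.breathing_rate <= 0 or self.breathing_amplitude < 0:
            raise ParameterError("breathing_rate must be > 0 and amplitude >= 0")
        if self.amplitude_cv < 0 or self.noise_sd < 0:
            raise ParameterError("scale parameters must be >= 0")
        if self.talking_amplitude_factor <= 0:
            raise ParameterError("talking_amplitude_factor must be > 0")


@dataclass(frozen=True)
class Phase:
    """One protocol phase: an activity held for a duration, with talking intervals."""

    activity: str
    duration: float
    talking: TalkingSchedule = ()

    def __post_init__(self):
        if self.activity not in ACTIVITIES:
            raise ParameterError(f"activity must be one of {ACTIVITIES}")
        if self.duration <= 0:
            raise ParameterError("phase duration must be positive")


@dataclass(frozen=True)
class ProtocolSpec:
    """An ordered sequence of activity phases at a fixed sampling rate."""

    phases: tuple[Phase, ...]
    sampling_rate: float
    baseline_level: float = 10.0
    drift_sd: float = 0.02  # belt units per sqrt(second)
    seed: int = 0

    def __post_init__(self):
        if not self.phases:
            raise ParameterError("protocol needs at least one phase")
        if self.sampling_rate <= 0:
            raise ParameterError("sampling_rate must be positive")
        total = self.total_duration * self.sampling_rate
        if abs(total - round(total)) > 1e-9:
            raise ParameterError("durations must yield an integer sample count")

    @property
    def total_duration(self) -> float:
        return sum(p.duration for p in self.phases)

    @property
    def n_samples(self) -> int:
        return round(self.total_duration * self.sampling_rate)

    def labels(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-sample (activity, talking) labels; boundaries at exact indices."""
        fs = self.sampling_rate
        activity = np.empty(self.n_samples, dtype=object)
        talking = np.zeros(self.n_samples, dtype=bool)
        start = 0
        for phase in self.phases:
            n = round(phase.duration * fs)
            activity[start : start + n] = phase.activity
            t_local = np.arange(n) / fs
            for a, b in phase.talking:
                talking[start : start + n] |= (t_local >= a) & (t_local < b)
            start += n
        return activity, talking


def field_protocol(sampling_rate: float = 12.0, seed: int = 0) -> ProtocolSpec:
    """The field-study protocol: sit, walk, run, sit — 2 min each,
    talking allowed only during each phase's second minute."""
    talk = ((60.0, 120.0),)
    return ProtocolSpec(
        phases=(
            Phase("sitting", 120.0, talk),
            Phase("walking", 120.0, talk),
            Phase("running", 120.0, talk),
            Phase("sitting", 120.0, talk),
        ),
        sampling_rate=sampling_rate,
        seed=seed,
    )


def deap_protocol(sampling_rate: float = 128.0, seed: int = 0) -> ProtocolSpec:
    """A literature-style single-phase protocol: 63 s at 128 Hz, no talking."""
    return ProtocolSpec(
        phases=(Phase("other", 63.0),), sampling_rate=sampling_rate, seed=seed
    )


#: Default per-activity parameters for the field protocol (fixture values).
DEFAULT_FIELD_PARAMS: Mapping[str, ActivityParams] = {
    "sitting": ActivityParams(breathing_rate=0.25, breathing_amplitude=1.0),
    "walking": ActivityParams(breathing_rate=0.30, breathing_amplitude=1.2),
    "running": ActivityParams(
        breathing_rate=0.60, breathing_amplitude=2.0, amplitude_cv=0.15, noise_sd=0.08
    ),
}

#: Default respiration / ocular channel parameters for the literature protocol.
DEFAULT_DEAP_RESP_PARAMS: Mapping[str, ActivityParams] = {
    "other": ActivityParams(breathing_rate=0.25, breathing_amplitude=1.0)
}
DEFAULT_DEAP_OCULAR_PARAMS: Mapping[str, ActivityParams] = {
    "other": ActivityParams(breathing_rate=1.0, breathing_amplitude=0.8, noise_sd=0.1)
}


def simulate_trace(
    protocol: ProtocolSpec,
    params_by_activity: Mapping[str, ActivityParams],
    seed: int | None = None,
) -> RespirationTrace:
    """Generate one labelled trace under a protocol.

    Fully reproducible from the seed (defaults to ``protocol.seed``); the
    random phase offset, drift walk, per-breath jitter and sensor noise
    each use an independent substream.
    """
    activity, talking = protocol.labels()
    missing = set(activity) - set(params_by_activity)
    if missing:
        raise ParameterError(f"no parameters for activities: {sorted(missing)}")
    fs = protocol.sampling_rate
    n = protocol.n_samples
    for act in set(activity):
        if params_by_activity[act].breathing_rate >= fs / 2:
            raise ParameterError(f"{act}: breathing_rate must be below Nyquist ({fs / 2} Hz)")

    rate = np.array([params_by_activity[a].breathing_rate for a in activity])
    amp = np.array([params_by_activity[a].breathing_amplitude for a in activity])
    cv = np.array([params_by_activity[a].amplitude_cv for a in activity])
    talk_factor = np.array([params_by_activity[a].talking_amplitude_factor for a in activity])
    noise_sd = np.array([params_by_activity[a].noise_sd for a in activity])

    root = np.random.SeedSequence(protocol.seed if seed is None else seed)
    rng_phase, rng_drift, rng_breath, rng_noise = (
        np.random.default_rng(s) for s in root.spawn(4)
    )

    # Continuous phase: integrate the instantaneous frequency.
    phi0 = rng_phase.uniform(0.0, 2 * np.pi)
    phase = phi0 + 2 * np.pi * np.cumsum(rate) / fs

    # One multiplicative amplitude factor per breath cycle; talking doubles
    # the per-breath CV on top of scaling the amplitude.
    cycle = np.floor((phase - phi0) / (2 * np.pi)).astype(int)
    z = rng_breath.standard_normal(cycle.max() + 1)
    eff_cv = np.where(talking, 2 * cv, cv)
    breath_factor = np.clip(1.0 + eff_cv * z[cycle], 0.0, None)
    amp_i = amp * np.where(talking, talk_factor, 1.0) * breath_factor

    drift = np.cumsum(rng_drift.standard_normal(n) * (protocol.drift_sd / np.sqrt(fs)))
    noise = rng_noise.standard_normal(n) * noise_sd

    samples = protocol.baseline_level + drift + amp_i * np.sin(phase) + noise
    return RespirationTrace(
        samples=samples,
        sampling_rate=fs,
        activity_labels=activity,
        talking_flags=talking,
    )


def simulate_bivariate(
    protocol: ProtocolSpec,
    resp_params: Mapping[str, ActivityParams] = DEFAULT_DEAP_RESP_PARAMS,
    ocular_params: Mapping[str, ActivityParams] = DEFAULT_DEAP_OCULAR_PARAMS,
    seed: int | None = None,
) -> BivariateTrace:
    """Generate a two-channel (respiration + ocular) trace; channels independent."""
    root = np.random.SeedSequence(protocol.seed if seed is None else seed)
    seed_a, seed_b = (int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(2))
    return BivariateTrace(
        channel_a=simulate_trace(protocol, resp_params, seed=seed_a),
        channel_b=simulate_trace(protocol, ocular_params, seed=seed_b),
    )


def simulate_cohort(
    n_subjects: int,
    protocol: ProtocolSpec | None = None,
    params_by_activity: Mapping[str, ActivityParams] = DEFAULT_FIELD_PARAMS,
    seed: int = 0,
) -> list[RespirationTrace]:
    """Simulate a cohort of field-protocol subjects with distinct substreams."""
    if n_subjects < 1:
        raise ParameterError("n_subjects must be >= 1")
    protocol = protocol or field_protocol()
    root = np.random.SeedSequence(seed)
    traces = []
    for k, child in enumerate(root.spawn(n_subjects)):
        t = simulate_trace(
            protocol, params_by_activity, seed=int(child.generate_state(1)[0] % (2**31))
        )
        t.subject_id = f"subject_{k:02d}"
        traces.append(t)
    return traces
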