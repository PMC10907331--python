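"""Phenomenological stochastic leaky-integrate-and-fire ANF model.

Each auditory nerve fiber is one site of excitation that low-pass filters
("leaky integrator", a first-order recursive filter with gain
coefficients b0, b1) the electrical current reaching it and releases at
most one action potential per pulse when the membrane trace exceeds a
stochastic threshold drawn per pulse from a normal law (SD ``delta``),
provided the charge-balancing phase does not repolarize the membrane
before action-potential initiation completes.  A crossing therefore
commits to a spike only if the membrane stays above the drawn threshold
for the fiber's critical period; this is the mechanism through which a
longer inter-phase gap recruits more fibers at a given charge.  Separate
threshold values are kept per polarity: refractoriness and spike-rate
adaptation raise both after a spike, whereas facilitation after
subthreshold stimulation lowers only the stimulated polarity's threshold.
Spike latency is a monotonically decreasing function of the
suprathreshold margin.

Currents are in uA, membrane potential and thresholds in uV, time in us.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import lfilter

from .stimulus import ANODIC, FineGrainSchedule, PulseSpec, make_biphasic_pulse

#: Sampling interval (us) at which the b0/b1 gain coefficients are defined.
REFERENCE_DT_US = 1.0


def attenuation_factor(distance_mm, db_per_mm: float = 2.0):
    """Amplitude factor 10^(-db_per_mm * d / 20) of the 2 dB/mm field decay."""
    d = np.asarray(distance_mm, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be non-negative")
    out = 10.0 ** (-db_per_mm * d / 20.0)
    return float(out) if np.isscalar(distance_mm) else out


def attenuate_current(current_ua, distance_mm, db_per_mm: float = 2.0):
    """Current reaching a neuron at ``distance_mm`` from the stimulating contact."""
    return np.asarray(current_ua, dtype=float) * attenuation_factor(distance_mm, db_per_mm)


@dataclass(frozen=True)
class FiberParams:
    """Single-fiber model parameters.

    ``threshold_sd`` (delta) and the leaky-integrator gains ``b0``/``b1``
    carry the modified values (delta doubled, gains tripled relative to
    the original single-fiber model) that calibrate the full 2-D model's
    eCAP thresholds into the clinically expected ~10 nC range and keep the
    latency-vs-amplitude map monotonic.  ``mean_threshold`` and the
    dynamics constants below are not tabulated in any source and are
    exposed as configuration; the shipped defaults were fixed once by
    ``scripts/calibrate.py`` against that same eCAP-threshold criterion.
    """

    threshold_sd: float = 9.2  # uV
    b0: float = 602.6e-6  # filter gains at 1 us sampling
    b1: float = 602.6e-6
    input_scale: float = 18.77  # filter input units per uA of stimulus current
    mean_threshold: float = 150.0  # uV, resting threshold of both polarities
    membrane_tau: float = 100.0  # us, leak time constant of the integrator
    critical_period: float = 15.0  # us the membrane must stay above threshold
    absolute_refractory: float = 330.0  # us, no spike at all after a spike
    refractory_increment: float = 300.0  # uV added to both thresholds per spike
    refractory_tau: float = 700.0  # us
    adaptation_increment: float = 0.5  # uV per spike, slow accumulation
    adaptation_tau: float = 50_000.0  # us
    facilitation_decrement: float = 1.5  # uV per subthreshold pulse
    facilitation_tau: float = 1_500.0  # us
    facilitation_drive_fraction: float = 0.5  # min peak drive (vs threshold) to facilitate
    threshold_floor_fraction: float = 0.05  # of mean_threshold; hard floor for thresholds
    latency_min: float = 370.0  # us, asymptotic latency at strong drive
    latency_max: float = 470.0  # us, latency at vanishing suprathreshold margin
    latency_scale: float = 0.5  # margin scale of the latency decay

    def __post_init__(self) -> None:
        if self.threshold_sd <= 0 or self.b0 <= 0 or self.b1 <= 0:
            raise ValueError("threshold_sd and filter gains must be positive")
        if self.mean_threshold <= 0:
            raise ValueError("mean_threshold must be positive")
        for name in ("membrane_tau", "refractory_tau", "adaptation_tau", "facilitation_tau"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.threshold_floor_fraction < 1:
            raise ValueError("threshold_floor_fraction must be in (0, 1)")
        if self.latency_min <= 0 or self.latency_max < self.latency_min:
            raise ValueError("latency map requires 0 < latency_min <= latency_max")

    @classmethod
    def original(cls, **overrides) -> "FiberParams":
        """Parameters of the unmodified single-fiber model (delta 4.6 uV, gains 200.9E-6)."""
        return cls(threshold_sd=4.6, b0=200.9e-6, b1=200.9e-6, **overrides)

    @property
    def threshold_floor(self) -> float:
        return self.threshold_floor_fraction * self.mean_threshold


@dataclass
class FiberState:
    """Dynamic state of one or many fibers (vectorised over fibers).

    Threshold modulations are stored as decaying amplitudes (uV);
    ``effective_mean_thresholds`` combines them into the current mean
    threshold per polarity.  State only evolves forward in time.
    """

    n_fibers: int
    params: FiberParams
    time_us: float = 0.0
    last_spike_us: np.ndarray = field(init=False)
    refractory: np.ndarray = field(init=False)  # (n,) uV
    adaptation: np.ndarray = field(init=False)  # (n,) uV
    facilitation: np.ndarray = field(init=False)  # (n, 2) uV, [anodic, cathodic]

    def __post_init__(self) -> None:
        self.last_spike_us = np.full(self.n_fibers, -np.inf)
        self.refractory = np.zeros(self.n_fibers)
        self.adaptation = np.zeros(self.n_fibers)
        self.facilitation = np.zeros((self.n_fibers, 2))

    def advance_to(self, t_us: float) -> None:
        """Decay all modulations to time ``t_us`` (must not move backwards)."""
        if t_us < self.time_us - 1e-9:
            raise ValueError("state evolves only forward in time")
        dt = t_us - self.time_us
        if dt > 0:
            p = self.params
            self.refractory *= np.exp(-dt / p.refractory_tau)
            self.adaptation *= np.exp(-dt / p.adaptation_tau)
            self.facilitation *= np.exp(-dt / p.facilitation_tau)
        self.time_us = t_us

    def effective_mean_thresholds(self) -> np.ndarray:
        """Current mean threshold per fiber and polarity, (n, 2) uV."""
        p = self.params
        base = p.mean_threshold + self.refractory + self.adaptation
        eff = base[:, None] - self.facilitation
        return np.maximum(eff, p.threshold_floor)

    def register_spikes(self, fibers: np.ndarray, spike_times_us: np.ndarray) -> None:
        p = self.params
        self.last_spike_us[fibers] = spike_times_us
        self.refractory[fibers] += p.refractory_increment
        self.adaptation[fibers] += p.adaptation_increment

    def register_facilitation(self, fibers: np.ndarray, channel: int) -> None:
        self.facilitation[fibers, channel] += self.params.facilitation_decrement


def integrate_membrane(
    current_ua: np.ndarray,
    params: FiberParams,
    dt_us: float = 1.0,
    initial: float = 0.0,
) -> np.ndarray:
    """Leaky integration of a current waveform; returns the membrane trace (uV).

    First-order recursive low-pass v[n] = a v[n-1] + b0 I[n] + b1 I[n-1]
    with a = exp(-dt / membrane_tau).  The gain coefficients are defined
    at 1 us sampling and rescaled by dt to keep the continuous-time
    response independent of the simulation step.
    """
    current_ua = np.asarray(current_ua, dtype=float)
    if not np.all(np.isfinite(current_ua)):
        raise ValueError("current waveform must be finite")
    a = np.exp(-dt_us / params.membrane_tau)
    scale = params.input_scale * dt_us / REFERENCE_DT_US
    zi = np.array([a * initial])
    out, _ = lfilter([params.b0 * scale, params.b1 * scale], [1.0, -a], current_ua, zi=zi)
    return out


def _channel_detect(
    trace: np.ndarray,
    scale: np.ndarray,
    thresholds: np.ndarray,
    dt_us: float,
    params: FiberParams,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Spike detection for one polarity channel of fibers sharing a trace shape.

    Fiber ``f`` sees the drive ``scale[f] * trace``; a spike commits when
    the drive stays above ``thresholds[f]`` for at least the critical
    period.  Returns (committed, spike_time_us, facilitated) where
    ``facilitated`` marks fibers whose peak drive reached the
    facilitation fraction of their threshold without a committed spike.
    """
    n = scale.shape[0]
    committed = np.zeros(n, dtype=bool)
    spike_time = np.full(n, np.nan)
    facilitated = np.zeros(n, dtype=bool)

    peak = float(trace.max(initial=0.0))
    if peak <= 0.0:
        return committed, spike_time, facilitated
    peak_drive = scale * peak

    cand = np.flatnonzero(peak_drive > thresholds)
    facilitated = (~committed) & (peak_drive >= params.facilitation_drive_fraction * thresholds) & (
        peak_drive <= thresholds
    )
    if cand.size == 0:
        return committed, spike_time, facilitated

    rho = thresholds[cand] / scale[cand]  # threshold in units of the shared trace
    above = trace[None, :] > rho[:, None]
    i_up = np.argmax(above, axis=1)
    cols = np.arange(trace.size)[None, :]
    below_after = (~above) & (cols >= i_up[:, None])
    has_down = below_after.any(axis=1)
    i_down = np.where(has_down, np.argmax(below_after, axis=1), trace.size)
    duration = (i_down - i_up) * dt_us

    ok = duration >= params.critical_period
    idx = cand[ok]
    committed[idx] = True
    margin = peak_drive[idx] / thresholds[idx] - 1.0
    latency = params.latency_min + (params.latency_max - params.latency_min) * np.exp(
        -margin / params.latency_scale
    )
    spike_time[idx] = i_up[ok] * dt_us + latency

    # crossed but cancelled by repolarization -> still subthreshold stimulation
    cancelled = cand[~ok]
    facilitated[cancelled] = True
    return committed, spike_time, facilitated


def unit_membrane_trace(spec: PulseSpec, params: FiberParams, tail_taus: float = 5.0) -> np.ndarray:
    """Membrane response (uV) to the pulse shape at 1 uA phase amplitude.

    Anodic-leading by construction; the cathodic-leading response is its
    negation.  A zero-current tail of ``tail_taus`` membrane time
    constants follows the pulse so that the passive decay below threshold
    is observed.
    """
    unit = replace(spec, charge_per_phase=spec.n_phase_samples * spec.dt / 1000.0,
                   leading_polarity=ANODIC)  # 1 uA amplitude
    _, current = make_biphasic_pulse(unit)
    tail = np.zeros(int(np.ceil(tail_taus * params.membrane_tau / spec.dt)))
    return integrate_membrane(np.concatenate([current, tail]), params, spec.dt)


@dataclass
class PulseOutcome:
    """Spikes evoked by one pulse of a sweep."""

    onset_ms: float
    charge_nc: float
    leading_polarity: str
    spike_fibers: np.ndarray  # indices into the fiber set
    spike_times_us: np.ndarray  # relative to pulse onset


def respond_to_pulse(
    spec: PulseSpec,
    scale: np.ndarray,
    state: FiberState,
    rng: np.random.Generator,
    onset_us: float,
    unit_trace: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Population response to one pulse; updates ``state`` in place.

    ``scale[f]`` is the peak current (uA) reaching fiber ``f`` per uA of
    phase amplitude times the phase amplitude — i.e. the distance-
    attenuated phase amplitude.  Returns (spike fiber indices,
    spike times in us relative to pulse onset).
    """
    p = state.params
    state.advance_to(onset_us)
    if spec.charge_per_phase == 0.0 or not np.any(scale > 0):
        return np.empty(0, dtype=int), np.empty(0)

    if unit_trace is None:
        unit_trace = unit_membrane_trace(spec, p)
    lead = 1.0 if spec.leading_polarity == ANODIC else -1.0

    eff = state.effective_mean_thresholds()
    draws = rng.normal(loc=eff, scale=p.threshold_sd)
    thresholds = np.maximum(draws, p.threshold_floor)

    in_refractory = (onset_us - state.last_spike_us) < p.absolute_refractory
    blocked_scale = np.where(in_refractory, 0.0, scale)

    spike_time = np.full((scale.shape[0], 2), np.nan)
    committed = np.zeros((scale.shape[0], 2), dtype=bool)
    facilitated = np.zeros((scale.shape[0], 2), dtype=bool)
    for ch, ch_sign in ((0, 1.0), (1, -1.0)):  # anodic, cathodic thresholds
        g = (lead * ch_sign) * unit_trace
        committed[:, ch], spike_time[:, ch], facilitated[:, ch] = _channel_detect(
            g, blocked_scale, thresholds[:, ch], spec.dt, p
        )

    spiking = committed.any(axis=1)
    fibers = np.flatnonzero(spiking)
    times = np.nanmin(spike_time[fibers], axis=1) if fibers.size else np.empty(0)

    # state updates: spikes raise both thresholds, subthreshold drive
    # facilitates the stimulated polarity only
    for ch in (0, 1):
        fac = np.flatnonzero(facilitated[:, ch] & ~spiking)
        if fac.size:
            state.register_facilitation(fac, ch)
    if fibers.size:
        state.register_spikes(fibers, onset_us + times)
    return fibers, times


def simulate_pulse_response(
    current_ua: np.ndarray,
    params: FiberParams,
    state: FiberState | None = None,
    rng: np.random.Generator | None = None,
    dt_us: float = 1.0,
    onset_us: float = 0.0,
    tail_taus: float = 5.0,
) -> tuple[float | None, FiberState]:
    """Response of a single fiber to an arbitrary (already attenuated) waveform.

    Returns (spike latency in us from waveform onset, or None) and the
    updated state.  The same commit rule as the population engine is
    applied to the membrane trace of the given current.
    """
    if state is None:
        state = FiberState(1, params)
    if state.n_fibers != 1:
        raise ValueError("simulate_pulse_response expects single-fiber state")
    rng = rng or np.random.default_rng()
    state.advance_to(onset_us)

    current_ua = np.asarray(current_ua, dtype=float)
    if not np.all(np.isfinite(current_ua)):
        raise ValueError("current waveform must be finite")
    if not current_ua.any():
        return None, state
    tail = np.zeros(int(np.ceil(tail_taus * params.membrane_tau / dt_us)))
    trace = integrate_membrane(np.concatenate([current_ua, tail]), params, dt_us)

    eff = state.effective_mean_thresholds()
    thresholds = np.maximum(rng.normal(loc=eff, scale=params.threshold_sd), params.threshold_floor)
    if (onset_us - state.last_spike_us[0]) < params.absolute_refractory:
        return None, state

    one = np.ones(1)
    best_time = None
    spiked = False
    for ch, ch_sign in ((0, 1.0), (1, -1.0)):
        committed, t_spike, facilitated = _channel_detect(
            ch_sign * trace, one, thresholds[:, ch], dt_us, params
        )
        if committed[0]:
            spiked = True
            if best_time is None or t_spike[0] < best_time:
                best_time = float(t_spike[0])
        elif facilitated[0]:
            state.register_facilitation(np.array([0]), ch)
    if spiked:
        state.register_spikes(np.array([0]), np.array([onset_us + best_time]))
        return best_time, state
    return None, state


@dataclass
class SpikeTrain:
    """Per-fiber spike times accumulated over a pulse train."""

    outcomes: list[PulseOutcome]
    n_fibers: int

    @property
    def n_spikes(self) -> int:
        return int(sum(o.spike_fibers.size for o in self.outcomes))

    def flatten(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (fiber ids, absolute spike times in ms)."""
        fibers = np.concatenate([o.spike_fibers for o in self.outcomes]) if self.outcomes else np.empty(0, int)
        times = (
            np.concatenate([o.onset_ms + o.spike_times_us / 1000.0 for o in self.outcomes])
            if self.outcomes
            else np.empty(0)
        )
        return fibers, times

    def export_csv(self) -> str:
        buf = io.StringIO()
        buf.write("fiber_id,spike_time_ms\n")
        for f, t in zip(*self.flatten()):
            buf.write(f"{f},{t:.6f}\n")
        return buf.getvalue()


def simulate_train(
    schedule: FineGrainSchedule,
    attenuation: np.ndarray,
    params: FiberParams,
    seed: int | np.random.Generator = 0,
    callback=None,
) -> SpikeTrain:
    """Run a pulse schedule over a fiber population.

    ``attenuation[f]`` is the amplitude factor from the stimulating
    contact to fiber ``f`` (10^(-2 r_s / 20)).  Fiber state (membrane,
    refractoriness, adaptation, facilitation) is carried across pulses so
    the phenomena interact along the train; identical seeds reproduce
    identical spike trains.  ``callback(outcome)`` is invoked per pulse.
    """
    attenuation = np.asarray(attenuation, dtype=float)
    onsets = [onset for onset, _ in schedule.entries]
    if any(b < a for a, b in zip(onsets, onsets[1:])):
        raise ValueError("schedule must be sorted by onset")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    state = FiberState(attenuation.shape[0], params)

    trace_cache: dict[tuple[float, float, float], np.ndarray] = {}
    outcomes: list[PulseOutcome] = []
    for onset_ms, spec in schedule.entries:
        key = (spec.phase_duration, spec.ipg, spec.dt)
        if key not in trace_cache:
            trace_cache[key] = unit_membrane_trace(spec, params)
        amp_ua = 1000.0 * spec.charge_per_phase / (spec.n_phase_samples * spec.dt)
        fibers, times = respond_to_pulse(
            spec, attenuation * amp_ua, state, rng, onset_ms * 1000.0, trace_cache[key]
        )
        outcome = PulseOutcome(onset_ms, spec.charge_per_phase, spec.leading_polarity, fibers, times)
        outcomes.append(outcome)
        if callback is not None:
            callback(outcome)
    return SpikeTrain(outcomes, attenuation.shape[0])
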