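"""Charge-balanced biphasic pulses and the fine-grain stimulation schedule.

Stimuli are symmetric charge-balanced biphasic current pulses (default
phase duration 40 us) whose two phases are separated by an inter-phase gap
(IPG, default 2.1 us).  Amplitude-growth functions are measured with the
fine-grain paradigm: the per-phase charge ramps from 0 to 30 nC at
1.5 nC/s while pulses are presented at 80 Hz, alternating the leading
polarity for artifact reduction.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace

import numpy as np

#: Fixed length of the eCAP recording window, ms.
RECORDING_WINDOW_MS = 1.7
#: Recording delay for the reference IPG of 2.1 us, us from pulse onset.
BASE_RECORDING_DELAY_US = 145.0
REFERENCE_IPG_US = 2.1

ANODIC = "anodic"
CATHODIC = "cathodic"


def recording_delay(ipg: float) -> float:
    """Recording-window onset d_R = 145 us + (ipg - 2.1 us), us from pulse onset."""
    if ipg < 0:
        raise ValueError("ipg must be non-negative")
    return BASE_RECORDING_DELAY_US + (ipg - REFERENCE_IPG_US)


@dataclass(frozen=True)
class PulseSpec:
    """One symmetric charge-balanced biphasic pulse.

    charge_per_phase in nC, durations in us, dt in us.  The realised phase
    and gap durations are rounded to whole samples of ``dt``; amplitudes
    are computed from the realised phase duration so the waveform stays
    exactly charge balanced.
    """

    charge_per_phase: float
    phase_duration: float = 40.0
    ipg: float = 2.1
    leading_polarity: str = ANODIC
    dt: float = 1.0

    def __post_init__(self) -> None:
        if self.charge_per_phase < 0:
            raise ValueError("charge_per_phase must be >= 0")
        if self.phase_duration <= 0:
            raise ValueError("phase_duration must be positive")
        if self.ipg < 0:
            raise ValueError("ipg must be >= 0")
        if self.leading_polarity not in (ANODIC, CATHODIC):
            raise ValueError(f"unknown polarity {self.leading_polarity!r}")
        if self.dt > self.phase_duration:
            raise ValueError("dt must not exceed phase_duration")

    @property
    def n_phase_samples(self) -> int:
        return max(1, round(self.phase_duration / self.dt))

    @property
    def n_gap_samples(self) -> int:
        return round(self.ipg / self.dt)

    @property
    def realized_ipg(self) -> float:
        """IPG as realised on the sample grid, us (logged in run metadata)."""
        return self.n_gap_samples * self.dt

    @property
    def duration(self) -> float:
        """Total realised duration 2 * phase + gap, us."""
        return (2 * self.n_phase_samples + self.n_gap_samples) * self.dt


def make_biphasic_pulse(spec: PulseSpec) -> tuple[np.ndarray, np.ndarray]:
    """Sample the pulse current; returns (time us, current uA).

    First-phase amplitude is charge_per_phase / phase_duration (0.75 mA for
    30 nC over 40 us), signed by the leading polarity; the second phase has
    equal magnitude and opposite sign, and the gap carries zero current.
    """
    n_ph, n_gap = spec.n_phase_samples, spec.n_gap_samples
    # nC / us = mA; express in uA
    amp = 1000.0 * spec.charge_per_phase / (n_ph * spec.dt)
    sign = 1.0 if spec.leading_polarity == ANODIC else -1.0
    current = np.concatenate(
        [
            np.full(n_ph, sign * amp),
            np.zeros(n_gap),
            np.full(n_ph, -sign * amp),
        ]
    )
    t = np.arange(current.size) * spec.dt
    return t, current


@dataclass
class FineGrainSchedule:
    """Ordered pulse sequence of a fine-grain AGF sweep.

    ``entries`` pairs each pulse onset (ms) with its :class:`PulseSpec`.
    In the default ``pair`` mode both leading polarities are presented at
    the same charge in consecutive 1/pulse_rate slots and the charge steps
    by 2 * charge_rate / pulse_rate per pair, so the two traces of a pair
    can be averaged at a common charge.  ``per_slot`` mode increments the
    charge every slot instead (strict 1.5 nC/s ramp; polarities then
    alternate along the ramp).  Passing ``charge_step`` selects a coarse
    grid of paired pulses with that step, keeping the same pulse rate.
    """

    entries: list[tuple[float, PulseSpec]]
    max_charge: float = 30.0
    charge_rate: float = 1.5
    pulse_rate: float = 80.0
    polarity_mode: str = "pair"
    charge_step: float | None = None

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def charges(self) -> np.ndarray:
        return np.array([spec.charge_per_phase for _, spec in self.entries])

    @property
    def charge_levels(self) -> np.ndarray:
        """Distinct charge levels in sweep order."""
        seen: dict[float, None] = {}
        for _, spec in self.entries:
            seen.setdefault(spec.charge_per_phase, None)
        return np.array(list(seen))

    def export_csv(self) -> str:
        buf = io.StringIO()
        buf.write("slot,onset_ms,charge_nC,leading_polarity\n")
        for slot, (onset, spec) in enumerate(self.entries):
            buf.write(f"{slot},{onset:.6f},{spec.charge_per_phase:.6f},{spec.leading_polarity}\n")
        return buf.getvalue()


def fine_grain_schedule(
    max_charge: float = 30.0,
    charge_rate: float = 1.5,
    pulse_rate: float = 80.0,
    polarity_mode: str = "pair",
    charge_step: float | None = None,
    phase_duration: float = 40.0,
    ipg: float = 2.1,
    dt: float = 1.0,
) -> FineGrainSchedule:
    """Build the fine-grain sweep from 0 to ``max_charge`` nC.

    With ``charge_step`` set, charge levels form the coarse grid
    0, step, ..., max_charge (both polarities per level, presented at
    ``pulse_rate``); otherwise the ramp follows ``charge_rate``.
    """
    if max_charge < 0:
        raise ValueError("max_charge must be >= 0")
    if charge_rate <= 0 or pulse_rate <= 0:
        raise ValueError("rates must be positive")
    if polarity_mode not in ("pair", "per_slot"):
        raise ValueError(f"unknown polarity_mode {polarity_mode!r}")

    base = PulseSpec(0.0, phase_duration=phase_duration, ipg=ipg, dt=dt)
    slot_ms = 1000.0 / pulse_rate

    if charge_step is not None:
        if charge_step <= 0:
            raise ValueError("charge_step must be positive")
        n_levels = int(round(max_charge / charge_step)) + 1
        levels = np.minimum(np.arange(n_levels) * charge_step, max_charge)
    elif polarity_mode == "pair":
        step = 2.0 * charge_rate / pulse_rate
        n_levels = int(np.floor(max_charge / step + 1e-9)) + 1
        levels = np.arange(n_levels) * step
        if max_charge > 0 and levels[-1] < max_charge - 1e-9:
            levels = np.append(levels, max_charge)
    else:  # per_slot: one pulse per slot, alternating polarity along the ramp
        step = charge_rate / pulse_rate
        n_slots = int(np.floor(max_charge / step + 1e-9)) + 1
        charges = np.minimum(np.arange(n_slots) * step, max_charge)
        entries = [
            (
                k * slot_ms,
                replace(base, charge_per_phase=float(q), leading_polarity=ANODIC if k % 2 == 0 else CATHODIC),
            )
            for k, q in enumerate(charges)
        ]
        return FineGrainSchedule(entries, max_charge, charge_rate, pulse_rate, polarity_mode, charge_step)

    entries = []
    slot = 0
    for q in levels:
        for pol in (ANODIC, CATHODIC):
            entries.append((slot * slot_ms, replace(base, charge_per_phase=float(q), leading_polarity=pol)))
            slot += 1
    return FineGrainSchedule(entries, max_charge, charge_rate, pulse_rate, polarity_mode, charge_step)
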