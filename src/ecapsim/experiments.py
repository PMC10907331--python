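"""Condition grid of simulated eCAP AGF measurements and summary tables.

The default grid crosses neural survival (500/1000/1500/2000 fibers), the
two scala-tympani height profiles (electrode-neuron distance conditions)
and the two inter-phase gaps (2.1 and 30 us).  Contact #6 in the middle of
the array stimulates; eCAPs are recorded simultaneously at all other
contacts.  Each condition yields one AGF per recording electrode, a
sigmoid fit with threshold/slope, and — pairing the two IPGs — the three
IPG-effect metrics.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import agf_metrics
from .ecap import (
    AGF,
    ECAPTrace,
    UnitaryResponseParams,
    average_polarity_pair,
    compound_response_multi,
    extract_ecap_amplitude,
    sample_unitary_response,
)
from .fiber import FiberParams, attenuation_factor, simulate_train
from .geometry import GeometryConfig, build_geometry
from .stimulus import (
    RECORDING_WINDOW_MS,
    FineGrainSchedule,
    fine_grain_schedule,
    recording_delay,
)


@dataclass(frozen=True)
class ConditionKey:
    n_fibers: int
    height_profile: str
    ipg: float

    def label(self) -> str:
        return f"n{self.n_fibers}_{self.height_profile}_ipg{self.ipg:g}"


@dataclass
class ExperimentConfig:
    """Parameters of a full simulation grid.

    ``charge_step`` selects the coarse charge grid (default 0.25 nC, 121
    levels x 2 polarities); ``charge_step=None`` runs the full fine-grain
    ramp (charge step 2 x 1.5/80 = 0.0375 nC per polarity pair).  The
    analysis is identical in both modes and the mode is recorded in the
    output metadata.
    """

    n_fibers_list: tuple[int, ...] = (500, 1000, 1500, 2000)
    ipgs: tuple[float, ...] = (2.1, 30.0)
    height_profiles: tuple[str, ...] = ("short", "long")
    stim_electrode: int = 6
    recording_electrodes: tuple[int, ...] | None = None
    charge_step: float | None = 0.25
    max_charge: float = 30.0
    charge_rate: float = 1.5
    pulse_rate: float = 80.0
    phase_duration: float = 40.0
    dt: float = 1.0
    seed: int = 0
    n_repetitions: int = 1
    recording_noise_uv: float = 0.0
    fiber_params: FiberParams = field(default_factory=FiberParams)
    ur_params: UnitaryResponseParams = field(default_factory=UnitaryResponseParams)
    geometry: GeometryConfig = field(default_factory=GeometryConfig)

    def __post_init__(self) -> None:
        if self.recording_electrodes is not None and self.stim_electrode in self.recording_electrodes:
            raise ValueError("stimulating electrode must be excluded from the recording set")
        keys = [
            (n, p, i)
            for n in self.n_fibers_list
            for p in self.height_profiles
            for i in self.ipgs
        ]
        if len(set(keys)) != len(keys):
            raise ValueError("condition tuples must be unique")

    def recording_set(self) -> tuple[int, ...]:
        if self.recording_electrodes is not None:
            return self.recording_electrodes
        return tuple(
            e for e in range(1, self.geometry.n_electrodes + 1) if e != self.stim_electrode
        )

    def condition_keys(self) -> list[ConditionKey]:
        return [
            ConditionKey(n, p, i)
            for n in self.n_fibers_list
            for p in self.height_profiles
            for i in self.ipgs
        ]

    def condition_seed(self, key: ConditionKey, repetition: int = 0) -> int:
        """Seed of one condition's sweep.

        Deliberately depends only on (seed, n_fibers, repetition): matched
        conditions that differ in IPG or height profile share their
        threshold-draw stream, so paired comparisons (IPG effects,
        threshold ratios between profiles) use common random numbers and
        are not blurred by between-sweep sampling noise.
        """
        ss = np.random.SeedSequence([int(self.seed), int(key.n_fibers), repetition])
        return int(ss.generate_state(1, np.uint32)[0])


@dataclass
class ConditionResult:
    """One condition's AGFs, fits, and provenance metadata."""

    key: ConditionKey
    agfs: dict[int, AGF]
    fits: dict[int, agf_metrics.SigmoidFit]
    metadata: dict = field(default_factory=dict)

    def max_amplitudes(self) -> dict[int, float]:
        return {e: agf.max_amplitude for e, agf in self.agfs.items()}


def simulate_condition(
    config: ExperimentConfig, key: ConditionKey, schedule: FineGrainSchedule | None = None
) -> ConditionResult:
    """Run one stimulation sweep and build the AGFs at all recording contacts.

    The two pulses of each charge level (anodic- and cathodic-leading) are
    averaged into one eCAP trace before N1/P2 extraction.  Optional
    additive Gaussian recording noise (``recording_noise_uv`` RMS) models
    the measurement-noise floor; it is off by default.
    """
    geo_cfg = replace(config.geometry, n_fibers=key.n_fibers, height_profile=key.height_profile)
    geometry = build_geometry(geo_cfg)
    if schedule is None:
        schedule = fine_grain_schedule(
            max_charge=config.max_charge,
            charge_rate=config.charge_rate,
            pulse_rate=config.pulse_rate,
            charge_step=config.charge_step,
            phase_duration=config.phase_duration,
            ipg=key.ipg,
            dt=config.dt,
        )
    rec_ids = config.recording_set()
    r_s = geometry.distances_from(config.stim_electrode)
    r_r = np.stack([geometry.distances_from(e) for e in rec_ids])
    atten = attenuation_factor(r_s)

    d_r = recording_delay(key.ipg)
    window_len_us = RECORDING_WINDOW_MS * 1000.0
    n_out = int(round(window_len_us / config.dt))
    ur_sampled = sample_unitary_response(config.ur_params, config.dt)

    levels: list[float] = []
    sums: list[np.ndarray] = []  # per level: summed traces (n_elec, n_out)
    counts: list[int] = []
    level_index: dict[float, int] = {}
    spike_total = 0

    noise_rng = np.random.default_rng(config.condition_seed(key, repetition=10_000))

    def on_pulse(outcome):
        nonlocal spike_total
        traces = compound_response_multi(
            outcome.spike_times_us,
            outcome.spike_fibers,
            r_r,
            d_r,
            window_len_us,
            config.dt,
            ur_sampled=ur_sampled,
            ur_params=config.ur_params,
        )
        if config.recording_noise_uv > 0:
            traces = traces + noise_rng.normal(0.0, config.recording_noise_uv, traces.shape)
        spike_total += outcome.spike_fibers.size
        q = outcome.charge_nc
        if q not in level_index:
            level_index[q] = len(levels)
            levels.append(q)
            sums.append(np.zeros((len(rec_ids), n_out)))
            counts.append(0)
        i = level_index[q]
        sums[i] += traces
        counts[i] += 1

    reps = max(1, config.n_repetitions)
    for rep in range(reps):
        simulate_train(schedule, atten, config.fiber_params, config.condition_seed(key, rep),
                       callback=on_pulse)

    charges = np.array(levels)
    amps = np.zeros((len(rec_ids), charges.size))
    for i, (q, total, cnt) in enumerate(zip(levels, sums, counts)):
        mean_traces = total / cnt
        for j, e in enumerate(rec_ids):
            trace = ECAPTrace(mean_traces[j], d_r, config.dt, electrode_id=e,
                              charge_nc=q, ipg_us=key.ipg)
            amps[j, i] = extract_ecap_amplitude(trace).amplitude

    one_spec = schedule.entries[0][1]
    meta_common = {
        "n_fibers": key.n_fibers,
        "height_profile": key.height_profile,
        "ipg_us": key.ipg,
        "realized_ipg_us": one_spec.realized_ipg,
        "stim_electrode": config.stim_electrode,
        "charge_step_nc": config.charge_step,
        "pulse_rate_hz": config.pulse_rate,
        "phase_duration_us": config.phase_duration,
        "dt_us": config.dt,
        "seed": config.seed,
        "condition_seed": config.condition_seed(key),
        "n_repetitions": reps,
        "height_polynomials": {k: list(v) for k, v in geo_cfg.height_polynomials.items()},
        "recording_noise_uv": config.recording_noise_uv,
        "total_spikes": spike_total,
    }
    agfs, fits = {}, {}
    order = np.argsort(charges)
    for j, e in enumerate(rec_ids):
        agfs[e] = AGF(charges[order], amps[j][order], {**meta_common, "recording_electrode": e})
        fits[e] = agf_metrics.fit_sigmoid(agfs[e])
    return ConditionResult(key, agfs, fits, meta_common)


@dataclass
class GridResult:
    config: ExperimentConfig
    results: list[ConditionResult]
    failures: dict[str, str] = field(default_factory=dict)

    def get(self, n_fibers: int, height_profile: str, ipg: float) -> ConditionResult:
        for r in self.results:
            if r.key == ConditionKey(n_fibers, height_profile, ipg):
                return r
        raise KeyError((n_fibers, height_profile, ipg))


def run_grid(config: ExperimentConfig, verbose: bool = False) -> GridResult:
    """Run every condition of the grid; failures are isolated per condition."""
    results, failures = [], {}
    for key in config.condition_keys():
        try:
            res = simulate_condition(config, key)
            results.append(res)
            if verbose:
                print(f"[ecapsim] {key.label()}: {res.metadata['total_spikes']} spikes")
        except Exception as exc:  # noqa: BLE001 - isolate per condition
            failures[key.label()] = f"{type(exc).__name__}: {exc}"
            if verbose:
                print(f"[ecapsim] {key.label()} FAILED: {exc}")
    return GridResult(config, results, failures)


def summarize_thresholds_slopes(grid: GridResult) -> pd.DataFrame:
    """Long-format table of fitted eCAP threshold and slope per condition."""
    rows = []
    for res in grid.results:
        for e, fit in res.fits.items():
            rows.append(
                {
                    "n_fibers": res.key.n_fibers,
                    "height_profile": res.key.height_profile,
                    "ipg_us": res.key.ipg,
                    "recording_electrode": e,
                    "x_thr_nc": fit.x_thr if fit.accepted else np.nan,
                    "theta_uv_per_nc": fit.theta if fit.accepted else np.nan,
                    "accepted": fit.accepted,
                }
            )
    return pd.DataFrame(rows)


def mean_profile_distance_difference(config: ExperimentConfig,
                                     profiles: tuple[str, str] = ("short", "long")) -> float:
    """Mean electrode-neuron distance difference (mm) between the two profiles."""
    geos = [
        build_geometry(replace(config.geometry, height_profile=p, n_fibers=2000))
        for p in profiles
    ]
    dist = [
        np.array([g.electrode_fiber_distance(e) for e in range(1, g.n_electrodes + 1)])
        for g in geos
    ]
    return float(np.mean(dist[1] - dist[0]))


def threshold_increase_rate_db_per_mm(
    grid: GridResult,
    n_fibers: int | None = None,
    ipg: float | None = None,
    profiles: tuple[str, str] = ("short", "long"),
) -> float:
    """Average threshold increase between the height profiles, dB re charge per mm.

    For every (n_fibers, ipg, recording electrode) present with both
    profiles, the threshold ratio long/short is expressed in dB and
    averaged; the mean is divided by the mean electrode-neuron distance
    difference between the profiles.
    """
    table = summarize_thresholds_slopes(grid)
    if n_fibers is not None:
        table = table[table.n_fibers == n_fibers]
    if ipg is not None:
        table = table[np.isclose(table.ipg_us, ipg)]
    wide = table.pivot_table(
        index=["n_fibers", "ipg_us", "recording_electrode"],
        columns="height_profile",
        values="x_thr_nc",
    ).dropna()
    if wide.empty or not set(profiles) <= set(wide.columns):
        raise ValueError("grid lacks paired profiles for the threshold-rate summary")
    ratio_db = 20.0 * np.log10(wide[profiles[1]] / wide[profiles[0]])
    delta_mm = mean_profile_distance_difference(grid.config, profiles)
    if delta_mm == 0:
        return 0.0
    return float(ratio_db.mean() / delta_mm)


def summarize_ipg_effects(
    grid: GridResult, ipg_short: float | None = None, ipg_long: float | None = None
) -> pd.DataFrame:
    """Absolute/relative/offset IPG effects per condition and recording electrode."""
    ipgs = sorted(grid.config.ipgs)
    ipg_short = ipgs[0] if ipg_short is None else ipg_short
    ipg_long = ipgs[-1] if ipg_long is None else ipg_long
    rows = []
    for res in grid.results:
        if not np.isclose(res.key.ipg, ipg_short):
            continue
        try:
            other = grid.get(res.key.n_fibers, res.key.height_profile, ipg_long)
        except KeyError:
            continue
        for e in res.fits:
            fs, fl = res.fits[e], other.fits.get(e)
            if fl is None:
                continue
            ok = fs.accepted and fl.accepted
            off = (
                agf_metrics.ipg_offset(res.agfs[e], other.agfs[e], fs, fl)
                if ok
                else agf_metrics.OffsetResult(np.nan, (np.nan, np.nan), False, "unaccepted fit")
            )
            rows.append(
                {
                    "n_fibers": res.key.n_fibers,
                    "height_profile": res.key.height_profile,
                    "recording_electrode": e,
                    "theta_short": fs.theta if ok else np.nan,
                    "theta_long": fl.theta if ok else np.nan,
                    "ipg_effect_absolute": agf_metrics.ipg_effect_absolute(fs, fl) if ok else np.nan,
                    "ipg_effect_relative": agf_metrics.ipg_effect_relative(fs, fl) if ok else np.nan,
                    "ipg_offset_db": off.offset_db if off.valid else np.nan,
                    "offset_range_lo_db": off.range_db[0],
                    "offset_range_hi_db": off.range_db[1],
                }
            )
    return pd.DataFrame(rows)


def normalized_max_amplitudes(grid: GridResult) -> pd.DataFrame:
    """Maximum eCAP amplitude per AGF, normalised within each condition group.

    Normalisation divides by the largest maximum amplitude within the same
    (height profile, n_fibers, IPG) condition — i.e. by the value at the
    recording contact adjacent to the stimulating one.
    """
    rows = []
    for res in grid.results:
        maxima = res.max_amplitudes()
        biggest = max(maxima.values()) if maxima else np.nan
        stim = grid.config.stim_electrode
        for e, m in maxima.items():
            rows.append(
                {
                    "n_fibers": res.key.n_fibers,
                    "height_profile": res.key.height_profile,
                    "ipg_us": res.key.ipg,
                    "recording_electrode": e,
                    "distance_contacts": abs(e - stim),
                    "max_amplitude_uv": m,
                    "normalized_max_amplitude": m / biggest if biggest else np.nan,
                }
            )
    return pd.DataFrame(rows)


def export_grid(grid: GridResult, out_dir: str | Path) -> None:
    """Write AGF CSVs, summary tables and a JSON metadata sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for res in grid.results:
        for e, agf in res.agfs.items():
            (out / f"agf_{res.key.label()}_rec{e}.csv").write_text(agf.export_csv())
    summarize_thresholds_slopes(grid).to_csv(out / "thresholds_slopes.csv", index=False)
    if len(grid.config.ipgs) > 1:
        summarize_ipg_effects(grid).to_csv(out / "ipg_effects.csv", index=False)
    normalized_max_amplitudes(grid).to_csv(out / "normalized_max_amplitudes.csv", index=False)
    meta = {
        "config": _config_dict(grid.config),
        "conditions": [res.metadata for res in grid.results],
        "failures": grid.failures,
    }
    (out / "metadata.json").write_text(json.dumps(meta, indent=2, default=str))


def _config_dict(config: ExperimentConfig) -> dict:
    d = asdict(config)
    d["fiber_params"] = asdict(config.fiber_params)
    d["ur_params"] = asdict(config.ur_params)
    d["geometry"] = asdict(config.geometry)
    return d
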