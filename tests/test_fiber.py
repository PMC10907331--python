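"""Stochastic LIF fiber model: attenuation, integration, spiking statistics.

The Monte-Carlo checks exploit that all fibers of a population run the
same membrane trace shape, so a population of identical fibers at equal
distance yields i.i.d. spike draws for a single pulse.
"""

import numpy as np
import pytest
from scipy.stats import norm

from ecapsim.fiber import (
    FiberParams,
    FiberState,
    attenuate_current,
    attenuation_factor,
    integrate_membrane,
    respond_to_pulse,
    simulate_pulse_response,
    simulate_train,
    unit_membrane_trace,
)
from ecapsim.stimulus import CATHODIC, FineGrainSchedule, PulseSpec, make_biphasic_pulse

PARAMS = FiberParams()


def commit_level(trace, params):
    """Oracle: largest trace level held for at least the critical period."""
    best = 0.0
    for level in np.linspace(1e-6, trace.max(), 3000):
        above = trace > level
        if not above.any():
            break
        i = int(np.argmax(above))
        rest = ~above[i:]
        j = i + (int(np.argmax(rest)) if rest.any() else above.size - i)
        if (j - i) >= params.critical_period:
            best = level
    return best


def oracle_spike_probability(charge, ipg, params):
    """Normal-CDF oracle for a single pulse on a resting fiber at distance 0."""
    spec = PulseSpec(charge, ipg=ipg)
    m = unit_membrane_trace(spec, params)
    amp = 1000.0 * charge / (spec.n_phase_samples * spec.dt)
    p_total = 0.0
    for shape in (m, -m):  # leading and trailing excitation channels
        level = amp * commit_level(shape, params)
        p = norm.cdf((level - params.mean_threshold) / params.threshold_sd)
        if level < params.threshold_floor:
            p = 0.0
        p_total = 1.0 - (1.0 - p_total) * (1.0 - p)
    return p_total


def mc_spike_probability(charge, ipg, params, n=1000, seed=0, polarity="anodic"):
    spec = PulseSpec(charge, ipg=ipg, leading_polarity=polarity)
    state = FiberState(n, params)
    rng = np.random.default_rng(seed)
    amp = 1000.0 * charge / (spec.n_phase_samples * spec.dt)
    fibers, _ = respond_to_pulse(spec, np.full(n, amp), state, rng, 0.0)
    return fibers.size / n


def near_threshold_charge(params, ipg=2.1):
    """Charge at ~50 % single-fiber spike probability (oracle inversion)."""
    spec = PulseSpec(1.0, ipg=ipg)
    m = unit_membrane_trace(spec, params)
    level = commit_level(m, params)
    return params.mean_threshold / (25.0 * level)


class TestAttenuation:
    @pytest.mark.parametrize(
        "d,factor", [(0.0, 1.0), (10.0, 0.1), (1.0, 10 ** (-0.1))]
    )
    def test_2db_per_mm_factors(self, d, factor):
        assert attenuation_factor(d) == pytest.approx(factor)

    def test_shape_preserving(self):
        _, current = make_biphasic_pulse(PulseSpec(10.0))
        out = attenuate_current(current, 3.0)
        np.testing.assert_allclose(out, current * 10 ** (-0.3))

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            attenuation_factor(-1.0)


class TestMembraneIntegration:
    def test_zero_input_zero_output(self):
        assert not integrate_membrane(np.zeros(100), PARAMS).any()

    def test_step_response_monotone_saturating(self):
        v = integrate_membrane(np.ones(2000), PARAMS)
        assert np.all(np.diff(v) >= -1e-12)
        assert np.diff(v)[-1] < np.diff(v)[0]

    def test_linearity(self, rng):
        x = rng.normal(size=300)
        v1 = integrate_membrane(x, PARAMS)
        v2 = integrate_membrane(2 * x, PARAMS)
        np.testing.assert_allclose(v2, 2 * v1, atol=1e-12)

    def test_decay_towards_rest_without_input(self):
        v = integrate_membrane(np.concatenate([np.ones(50), np.zeros(500)]), PARAMS)
        tail = v[50:]
        assert np.all(np.diff(tail) < 0) and tail[-1] < 0.01 * tail[0]

    def test_non_finite_input_rejected(self):
        with pytest.raises(ValueError):
            integrate_membrane(np.array([1.0, np.nan]), PARAMS)


class TestParameterTable:
    def test_modified_values_triple_gains_double_sd(self):
        mod, orig = FiberParams(), FiberParams.original()
        # tripling holds to the 4 significant digits the values carry
        assert mod.b0 == pytest.approx(3 * orig.b0, rel=1e-3)
        assert mod.b1 == pytest.approx(3 * orig.b1, rel=1e-3)
        assert mod.threshold_sd == pytest.approx(2 * orig.threshold_sd)
        assert (orig.b0, orig.threshold_sd) == (200.9e-6, 4.6)
        assert (mod.b0, mod.threshold_sd) == (602.6e-6, 9.2)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"threshold_sd": -1.0},
            {"mean_threshold": 0.0},
            {"membrane_tau": -5.0},
            {"threshold_floor_fraction": 1.5},
            {"latency_min": 500.0, "latency_max": 100.0},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            FiberParams(**kwargs)


class TestSinglePulseStatistics:
    def test_zero_amplitude_no_spike_no_state_change(self):
        state = FiberState(10, PARAMS)
        fibers, _ = respond_to_pulse(
            PulseSpec(0.0), np.ones(10), state, np.random.default_rng(0), 0.0
        )
        assert fibers.size == 0
        assert not state.facilitation.any() and not state.adaptation.any()

    def test_far_suprathreshold_always_spikes(self):
        # drive at >= mean + 6 sd: spike probability ~ 1
        q = near_threshold_charge(PARAMS) * (1 + 8 * 9.2 / 150.0)
        p = mc_spike_probability(q, 2.1, PARAMS, n=2000, seed=3)
        assert p > 0.995

    @pytest.mark.parametrize("p_target", [0.25, 0.5, 0.8])
    def test_probability_matches_normal_cdf_oracle(self, p_target):
        # invert the oracle for the charge at the target probability, then
        # compare a 1000-draw Monte-Carlo estimate within the binomial CI
        q50 = near_threshold_charge(PARAMS)
        z = norm.ppf(p_target)
        q = q50 * (1 + z * 9.2 / 150.0)
        p_oracle = oracle_spike_probability(q, 2.1, PARAMS)
        p_mc = mc_spike_probability(q, 2.1, PARAMS, n=1000, seed=11)
        ci = 1.96 * np.sqrt(p_oracle * (1 - p_oracle) / 1000)
        assert abs(p_mc - p_oracle) <= ci + 0.01

    def test_longer_ipg_raises_near_threshold_probability(self):
        q = near_threshold_charge(PARAMS, ipg=2.1)
        p_short = mc_spike_probability(q, 2.1, PARAMS, n=2000, seed=5)
        p_long = mc_spike_probability(q, 30.0, PARAMS, n=2000, seed=5)
        assert p_long > p_short + 0.1

    def test_anodic_cathodic_thresholds_symmetric(self):
        q = near_threshold_charge(PARAMS)
        p_a = mc_spike_probability(q, 2.1, PARAMS, n=4000, seed=7, polarity="anodic")
        p_c = mc_spike_probability(q, 2.1, PARAMS, n=4000, seed=7, polarity=CATHODIC)
        assert p_a == pytest.approx(p_c, abs=0.04)

    def test_doubling_sd_doubles_dynamic_range(self):
        # 10-90 % width of the single-fiber rate curve scales with delta
        widths = []
        for sd in (9.2, 18.4):
            params = FiberParams(threshold_sd=sd)
            q50 = near_threshold_charge(params)
            qs = q50 * (1 + np.linspace(-4, 4, 33) * sd / 150.0)
            ps = [mc_spike_probability(q, 2.1, params, n=800, seed=13) for q in qs]
            widths.append(
                np.interp(0.9, ps, qs) - np.interp(0.1, ps, qs)
            )
        assert widths[1] / widths[0] == pytest.approx(2.0, rel=0.25)

    def test_latency_non_increasing_with_charge_common_draws(self):
        q50 = near_threshold_charge(PARAMS)
        charges = q50 * np.array([1.05, 1.2, 1.5, 2.0, 3.0])
        latencies = []
        for q in charges:
            spec = PulseSpec(q)
            state = FiberState(400, PARAMS)
            rng = np.random.default_rng(77)  # identical threshold draws
            amp = 1000.0 * q / (spec.n_phase_samples * spec.dt)
            fibers, times = respond_to_pulse(spec, np.full(400, amp), state, rng, 0.0)
            latencies.append(dict(zip(fibers.tolist(), times.tolist())))
        for lo, hi in zip(latencies, latencies[1:]):
            common = set(lo) & set(hi)
            assert common
            assert all(hi[f] <= lo[f] + 1e-9 for f in common)


class TestStateDynamics:
    def _strong_spec(self):
        return PulseSpec(near_threshold_charge(PARAMS) * 3)

    def test_no_spike_during_absolute_refractoriness(self):
        spec = self._strong_spec()
        sched = FineGrainSchedule(
            entries=[(0.0, spec), (0.6, spec), (12.5, spec)], max_charge=spec.charge_per_phase
        )
        train = simulate_train(sched, np.ones(1), PARAMS, seed=2)
        per_pulse = [o.spike_fibers.size for o in train.outcomes]
        assert per_pulse[0] == 1
        assert per_pulse[1] == 0  # 0.6 ms after the previous spike
        assert per_pulse[2] == 1  # fully recovered at 12.5 ms

    def test_spike_raises_both_polarity_thresholds(self):
        spec = self._strong_spec()
        amp = 1000.0 * spec.charge_per_phase / spec.phase_duration
        state = FiberState(1, PARAMS)
        respond_to_pulse(spec, np.full(1, amp), state, np.random.default_rng(0), 0.0)
        eff = state.effective_mean_thresholds()
        assert state.refractory[0] > 0 and state.adaptation[0] > 0
        assert np.all(eff[0] > PARAMS.mean_threshold)

    def test_subthreshold_pulse_facilitates_stimulated_polarity_only(self):
        params = FiberParams(threshold_sd=1e-6)
        spec = PulseSpec(near_threshold_charge(params) * 0.8)
        amp = 1000.0 * spec.charge_per_phase / spec.phase_duration
        state = FiberState(1, params)
        respond_to_pulse(spec, np.full(1, amp), state, np.random.default_rng(0), 0.0)
        fac = state.facilitation[0]
        assert fac[0] > 0 and fac[1] == 0.0  # anodic-leading drives the anodic site

    def test_facilitation_cannot_push_threshold_below_floor(self):
        state = FiberState(1, PARAMS)
        state.facilitation[0, :] = 10 * PARAMS.mean_threshold
        eff = state.effective_mean_thresholds()
        assert np.all(eff >= PARAMS.threshold_floor)

    def test_state_only_moves_forward(self):
        state = FiberState(1, PARAMS)
        state.advance_to(100.0)
        with pytest.raises(ValueError):
            state.advance_to(50.0)


class TestTrains:
    def test_all_zero_schedule_empty_train(self):
        sched = FineGrainSchedule(entries=[(k * 12.5, PulseSpec(0.0)) for k in range(5)])
        train = simulate_train(sched, np.ones(20), PARAMS, seed=0)
        assert train.n_spikes == 0

    def test_same_seed_identical_trains(self):
        from ecapsim.stimulus import fine_grain_schedule

        sched = fine_grain_schedule(max_charge=20.0, charge_step=2.0)
        atten = attenuation_factor(np.linspace(0.5, 5.0, 100))
        a = simulate_train(sched, atten, PARAMS, seed=9).export_csv()
        b = simulate_train(sched, atten, PARAMS, seed=9).export_csv()
        assert a == b

    def test_spike_count_grows_with_max_charge(self):
        from ecapsim.stimulus import fine_grain_schedule

        atten = attenuation_factor(np.linspace(0.5, 5.0, 100))
        totals = [
            simulate_train(
                fine_grain_schedule(max_charge=q, charge_step=1.0), atten, PARAMS, seed=4
            ).n_spikes
            for q in (8.0, 16.0, 30.0)
        ]
        assert totals[0] < totals[1] < totals[2]

    def test_unsorted_schedule_rejected(self):
        sched = FineGrainSchedule(entries=[(10.0, PulseSpec(1.0)), (0.0, PulseSpec(1.0))])
        with pytest.raises(ValueError):
            simulate_train(sched, np.ones(1), PARAMS, seed=0)


class TestSinglePulseAPI:
    def test_suprathreshold_waveform_spikes_with_latency(self):
        q = near_threshold_charge(PARAMS) * 3
        _, current = make_biphasic_pulse(PulseSpec(q))
        latency, state = simulate_pulse_response(
            current, PARAMS, rng=np.random.default_rng(1)
        )
        assert latency is not None
        assert PARAMS.latency_min <= latency <= PARAMS.latency_max + 100.0
        assert state.last_spike_us[0] == pytest.approx(latency)

    def test_zero_waveform_no_spike(self):
        latency, _ = simulate_pulse_response(np.zeros(100), PARAMS)
        assert latency is None

    def test_non_finite_waveform_rejected(self):
        with pytest.raises(ValueError):
            simulate_pulse_response(np.array([np.inf, 0.0]), PARAMS)
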