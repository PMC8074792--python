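"""Time binning, trace normalization, the two-compartment model and its fit."""

import numpy as np
import pytest

from memprobe import synthetic
from memprobe.cytometry import Channel, EventTable, Gate, apply_gate
from memprobe.kinetics import (
    FitError,
    KineticTrace,
    TwoCompartmentParams,
    bin_time_series,
    endpoint_compare,
    escape_ratio_trace,
    fit_two_compartment,
    normalize_trace,
    simulate_two_compartment,
    trace_value_at,
)

PARAMS = TwoCompartmentParams(u_max=1.0, k_u=0.02, k_e=0.002, q=0.05, baseline=0.1)


def event_table(t, **channels):
    names = list(channels)
    events = np.column_stack([np.asarray(channels[n], float) for n in names])
    return EventTable(events=events, channels=[Channel(n) for n in names],
                      time_s=np.asarray(t, float))


def split_trace(trace, names):
    return [KineticTrace(trace.bin_centers_s, {n: trace.channel(n)}, trace.counts,
                         trace.window_s, normalized=trace.normalized) for n in names]


class TestBinning:
    def test_constant_channel_single_bin(self):
        table = event_table(np.arange(1.0, 10.0), A=np.full(9, 5.0))
        trace = bin_time_series(table)
        assert trace.bin_centers_s.tolist() == [5.0]
        assert trace.channel("A")[0] == pytest.approx(5.0)
        assert trace.counts[0] == 9

    def test_uniform_rate_counts_within_poisson_band(self, rng):
        n = 10_000
        t = np.sort(rng.uniform(0, 100, n))
        table = event_table(t, A=np.ones(n))
        trace = bin_time_series(table)
        assert trace.counts.size == 10
        # 99% Poisson band around 1000 per bin
        band = 2.58 * np.sqrt(1000)
        assert np.all(np.abs(trace.counts - 1000) < band + 30)

    def test_linear_signal_reproduced_at_bin_centers(self, rng):
        t = np.sort(rng.uniform(0, 200, 50_000))
        table = event_table(t, A=3.0 * t + 10.0)
        for mode in ("tumbling", "sliding"):
            trace = bin_time_series(table, mode=mode)
            expected = 3.0 * trace.bin_centers_s + 10.0
            keep = trace.nonempty
            np.testing.assert_allclose(trace.channel("A")[keep], expected[keep],
                                       rtol=0.02)

    def test_empty_bins_carry_zero_count(self):
        table = event_table([1.0, 35.0], A=[1.0, 2.0])
        trace = bin_time_series(table)
        assert trace.counts.tolist() == [1, 0, 0, 1]
        assert np.isnan(trace.channel("A")[1])

    def test_no_time_information_rejected(self):
        table = EventTable(events=np.ones((3, 1)), channels=[Channel("A")])
        with pytest.raises(ValueError, match="time"):
            bin_time_series(table)


class TestNormalize:
    def test_constant_channel_all_ones(self):
        table = event_table(np.arange(0.0, 50.0), A=np.full(50, 7.0))
        norm = normalize_trace(bin_time_series(table))
        np.testing.assert_allclose(norm.channel("A"), 1.0)

    def test_fold_change_preserved(self):
        t = np.arange(0.0, 20.0)
        table = event_table(t, A=np.where(t < 10, 2.0, 4.0))
        norm = normalize_trace(bin_time_series(table))
        assert norm.channel("A")[0] == pytest.approx(1.0, abs=1e-12)
        assert norm.channel("A")[1] == pytest.approx(2.0)

    def test_generator_fold_change_recovered(self):
        config = synthetic.SimulationConfig(seed=17, measurement_cv=0.02,
                                            lognormal_sigma=0.1,
                                            dapi_positive_fraction=0.0)
        table = synthetic.simulate_uptake_events(config, duration_s=950.0)
        trace = bin_time_series(table, channels=["AF532"])
        norm = normalize_trace(trace)
        curves = simulate_two_compartment(config.kinetic_params,
                                          np.array([5.0, 905.0]))
        expected_fold = curves["F_AF"][1] / curves["F_AF"][0]
        observed = trace_value_at(norm, 905.0, "AF532")
        assert observed == pytest.approx(expected_fold, rel=0.1)

    def test_nonpositive_first_window_rejected(self):
        table = event_table([1.0, 11.0], A=[0.0, 5.0])
        with pytest.raises(ValueError, match="first-window"):
            normalize_trace(bin_time_series(table))


class TestRatioTrace:
    def test_identical_traces_ratio_one(self):
        table = event_table(np.arange(0.0, 100.0), A=np.arange(100.0) + 1.0)
        norm = normalize_trace(bin_time_series(table))
        ratio = escape_ratio_trace(norm, norm)
        np.testing.assert_allclose(ratio.channel("ratio"), 1.0)

    def test_no_quenching_gives_flat_ratio(self):
        params = TwoCompartmentParams(u_max=1.0, k_u=0.02, k_e=0.002, q=1.0,
                                      baseline=0.1)
        config = synthetic.SimulationConfig(seed=19, measurement_cv=0.0,
                                            lognormal_sigma=0.0,
                                            dapi_positive_fraction=0.0,
                                            kinetic_params=params)
        table = synthetic.simulate_uptake_events(config)
        norm = normalize_trace(bin_time_series(table, channels=["AF532", "NF"]))
        af, nf = split_trace(norm, ["AF532", "NF"])
        ratio = escape_ratio_trace(nf, af)
        np.testing.assert_allclose(ratio.channel("ratio"), 1.0, rtol=1e-9)

    def test_quenched_ratio_dips_then_rises(self):
        config = synthetic.SimulationConfig(seed=23, measurement_cv=0.0,
                                            lognormal_sigma=0.0,
                                            dapi_positive_fraction=0.0)
        table = synthetic.simulate_uptake_events(config)
        norm = normalize_trace(bin_time_series(table, channels=["AF532", "NF"]))
        af, nf = split_trace(norm, ["AF532", "NF"])
        ratio = escape_ratio_trace(nf, af).channel("ratio")
        dip = ratio.argmin()
        assert ratio[dip] < ratio[0]          # early decline (filling endo-lysosomes)
        assert ratio[-1] > ratio[dip]         # later gradual rise (escape)

    def test_unnormalized_traces_rejected(self):
        table = event_table(np.arange(0.0, 30.0), A=np.ones(30))
        trace = bin_time_series(table)
        with pytest.raises(ValueError, match="normalized"):
            escape_ratio_trace(trace, trace)


class TestModel:
    T = np.linspace(0.0, 1200.0, 241)

    def test_no_escape_limit(self):
        params = TwoCompartmentParams(u_max=2.0, k_u=0.02, k_e=1e-12, q=0.05,
                                      baseline=0.3)
        curves = simulate_two_compartment(params, self.T)
        np.testing.assert_allclose(curves["C"], 0.0, atol=1e-8)
        np.testing.assert_allclose(curves["F_NF"], 0.05 * curves["U"] + 0.3, atol=1e-8)

    def test_no_quenching_limit(self):
        params = TwoCompartmentParams(u_max=1.0, k_u=0.02, k_e=0.002, q=1.0)
        curves = simulate_two_compartment(params, self.T)
        np.testing.assert_allclose(curves["F_NF"], curves["F_AF"], rtol=1e-12)

    def test_asymptote(self):
        curves = simulate_two_compartment(PARAMS, np.array([1e6]))
        assert curves["C"][0] == pytest.approx(PARAMS.u_max, rel=1e-9)
        assert curves["E"][0] == pytest.approx(0.0, abs=1e-9)

    def test_closed_form_vs_rk4_oracle(self):
        # fixed-step fourth-order Runge-Kutta on dC/dt = k_e (U - C)
        dt = 0.1
        t = np.arange(0.0, 1200.0 + dt / 2, dt)
        u = PARAMS.u_max * (1 - np.exp(-PARAMS.k_u * t))
        c = np.zeros_like(t)
        k_e = PARAMS.k_e

        def du(time):
            return PARAMS.u_max * (1 - np.exp(-PARAMS.k_u * time))

        for i in range(t.size - 1):
            ti, ci = t[i], c[i]
            k1 = k_e * (du(ti) - ci)
            k2 = k_e * (du(ti + dt / 2) - (ci + dt / 2 * k1))
            k3 = k_e * (du(ti + dt / 2) - (ci + dt / 2 * k2))
            k4 = k_e * (du(ti + dt) - (ci + dt * k3))
            c[i + 1] = ci + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        closed = simulate_two_compartment(PARAMS, t)["C"]
        assert np.max(np.abs(closed - c)) < 1e-6 * PARAMS.u_max

    def test_equal_rates_limit_continuous(self):
        k = 0.01
        near = TwoCompartmentParams(u_max=1.0, k_u=k * (1 + 1e-7), k_e=k, q=0.1)
        equal = TwoCompartmentParams(u_max=1.0, k_u=k, k_e=k, q=0.1)
        t = np.linspace(0, 600, 61)
        np.testing.assert_allclose(simulate_two_compartment(near, t)["C"],
                                   simulate_two_compartment(equal, t)["C"],
                                   rtol=1e-5, atol=1e-9)

    def test_af_saturates_and_nf_lags(self):
        curves = simulate_two_compartment(PARAMS, self.T)
        plateau = PARAMS.u_max + PARAMS.baseline
        sat_idx = np.searchsorted(curves["F_AF"],
                                  PARAMS.baseline + 0.95 * PARAMS.u_max)
        t_sat = self.T[sat_idx]
        assert 100.0 <= t_sat <= 300.0

        def t_half(signal):
            half = signal[0] + 0.5 * (signal[-1] - signal[0])
            return self.T[np.searchsorted(signal, half)]

        assert t_half(curves["F_NF"]) > t_half(curves["F_AF"])

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            TwoCompartmentParams(u_max=1.0, k_u=0.0, k_e=0.002, q=0.5)
        with pytest.raises(ValueError):
            TwoCompartmentParams(u_max=1.0, k_u=0.02, k_e=0.002, q=1.5)


class TestFit:
    def _traces(self, config, duration=1200.0):
        table = synthetic.simulate_uptake_events(config, duration_s=duration)
        norm = normalize_trace(bin_time_series(table, channels=["AF532", "NF"]))
        return split_trace(norm, ["AF532", "NF"])

    def test_noiseless_parameters_recovered_within_one_percent(self):
        # noiseless: dense deterministic event times, intensities exactly on
        # the closed-form curves (no arrival-time sampling noise)
        t = np.arange(0.05, 1200.0, 0.1)
        curves = simulate_two_compartment(PARAMS, t)
        table = event_table(t, AF532=curves["F_AF"], NF=curves["F_NF"])
        norm = normalize_trace(bin_time_series(table))
        af, nf = split_trace(norm, ["AF532", "NF"])
        params, report = fit_two_compartment(af, nf)
        assert params.k_u == pytest.approx(PARAMS.k_u, rel=0.01)
        assert params.k_e == pytest.approx(PARAMS.k_e, rel=0.01)
        assert params.q == pytest.approx(PARAMS.q, abs=0.01)

    def test_flat_traces_rejected_as_unidentifiable(self):
        centers = np.arange(5.0, 1200.0, 10.0)
        flat = KineticTrace(centers, {"A": np.ones_like(centers)},
                            np.full(centers.size, 10), normalized=True)
        flat2 = KineticTrace(centers, {"B": np.ones_like(centers)},
                             np.full(centers.size, 10), normalized=True)
        with pytest.raises(FitError, match="unidentifiable"):
            fit_two_compartment(flat, flat2)

    def test_short_traces_rejected(self):
        config = synthetic.SimulationConfig(seed=31)
        af, nf = self._traces(config, duration=300.0)
        with pytest.raises(FitError, match="600"):
            fit_two_compartment(af, nf)


class TestEndpoint:
    def _ratio_trace(self, seed, k_e_factor=1.0):
        params = TwoCompartmentParams(u_max=1.0, k_u=0.02,
                                      k_e=0.002 * k_e_factor, q=0.05, baseline=0.1)
        config = synthetic.SimulationConfig(seed=seed, kinetic_params=params,
                                            event_rate_hz=10.0)
        table = synthetic.simulate_uptake_events(config, duration_s=950.0)
        gated = apply_gate(table, Gate("threshold-below", ("DAPI",), bounds=(1_000.0,)))
        norm = normalize_trace(bin_time_series(gated, channels=["AF532", "NF"]))
        af, nf = split_trace(norm, ["AF532", "NF"])
        return escape_ratio_trace(nf, af)

    def test_identical_groups_not_significant(self):
        groups = {"control": [self._ratio_trace(s) for s in (40, 41, 42)],
                  "treated": [self._ratio_trace(s) for s in (43, 44, 45)]}
        result = endpoint_compare(groups, t_eval=900.0)
        assert not result["tukey"].significant.any()

    def test_enhanced_escape_flagged(self):
        groups = {"control": [self._ratio_trace(s) for s in range(50, 55)],
                  "enhanced": [self._ratio_trace(s, k_e_factor=1.5)
                               for s in range(60, 65)]}
        result = endpoint_compare(groups, t_eval=900.0)
        assert result["tukey"].significant.iloc[0]

    def test_two_groups_tukey_equals_pairwise(self):
        from memprobe import stats as mpstats

        groups = {"a": [self._ratio_trace(s) for s in (70, 71, 72)],
                  "b": [self._ratio_trace(s, 1.3) for s in (73, 74, 75)]}
        result = endpoint_compare(groups, t_eval=900.0)
        pairwise = mpstats.tukey_hsd(result["values"])
        assert result["tukey"].p_adjusted.iloc[0] == pytest.approx(
            pairwise.p_adjusted.iloc[0])

    def test_t_eval_outside_trace_rejected(self):
        groups = {"a": [self._ratio_trace(s) for s in (80, 81)],
                  "b": [self._ratio_trace(s) for s in (82, 83)]}
        with pytest.raises(ValueError, match="outside"):
            endpoint_compare(groups, t_eval=5_000.0)
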