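"""The generative circuit model: spatial summation, gating, kinetics, noise."""

import numpy as np
import pytest
from scipy import integrate

from aiirf import metrics, synth
from aiirf.containers import TrialSet
from aiirf.stim import make_annulus_protocol, make_sinusoid_protocol, make_spot_protocol
from aiirf.synth import (
    Condition,
    pathway_gate,
    response_timecourse,
    simulate_population,
    simulate_spikes,
    simulate_trace,
    simulate_trialset,
    spatial_drive,
    surround_gate,
)

FS = 10_000.0


def _spot(d, bg=500.0, contrast=1.0):
    return make_spot_protocol([d], contrast=contrast, background_rstar=bg)[0]


class TestSpatialDrive:
    def test_limits(self, params):
        c_big, s_big = spatial_drive(_spot(1e6), params)
        assert c_big == pytest.approx(1.0) and s_big == pytest.approx(1.0)
        c_tiny, s_tiny = spatial_drive(_spot(1e-3), params)
        assert c_tiny == pytest.approx(0.0, abs=1e-6)
        assert s_tiny == pytest.approx(0.0, abs=1e-6)

    def test_half_maximum_diameter_closed_form(self, params):
        # center drive = 0.5 at d = 2*sigma*sqrt(2 ln 2)
        d_half = 2.0 * params.sigma_c_um * np.sqrt(2.0 * np.log(2.0))
        c, _ = spatial_drive(_spot(d_half), params)
        assert c == pytest.approx(0.5, abs=1e-12)

    def test_disc_integral_matches_numerical_quadrature(self, params):
        # independent oracle: integrate the normalized 2-D Gaussian in polar form
        sigma = params.sigma_c_um
        for d in (30.0, 88.0, 325.0):
            oracle, _ = integrate.quad(
                lambda r: r / sigma**2 * np.exp(-(r**2) / (2 * sigma**2)), 0.0, d / 2
            )
            c, _ = spatial_drive(_spot(d), params)
            assert c == pytest.approx(oracle, abs=1e-9)

    def test_annulus_is_disc_difference(self, params):
        ann = make_annulus_protocol([1.0])[0]
        _, s_ann = spatial_drive(ann, params)
        _, s_outer = spatial_drive(_spot(1000.0), params)
        _, s_inner = spatial_drive(_spot(250.0), params)
        assert s_ann == pytest.approx(s_outer - s_inner, abs=1e-12)

    def test_bar_matches_2d_quadrature(self, params):
        from aiirf.stim import make_bar_protocol

        bar = make_bar_protocol(spacing_um=20.0, n_positions=3)[2]  # offset +20
        sigma = params.sigma_c_um

        def gauss2d(y, x):
            return np.exp(-(x**2 + y**2) / (2 * sigma**2)) / (2 * np.pi * sigma**2)

        oracle, _ = integrate.dblquad(
            gauss2d,
            bar.offset_um - bar.bar_w_um / 2, bar.offset_um + bar.bar_w_um / 2,
            -bar.bar_l_um / 2, bar.bar_l_um / 2,
        )
        c, _ = spatial_drive(bar, params)
        assert c == pytest.approx(oracle, abs=1e-7)


class TestPathwayGate:
    def test_wt_control_is_identity(self, params):
        assert pathway_gate(500.0, Condition(), params) == pytest.approx(1.0)

    def test_nbqx_leaves_only_cone_pathway_scotopic(self, params):
        g = pathway_gate(0.5, Condition(drugs={"NBQX"}), params)
        assert g == pytest.approx(1.0 - params.at(0.5).f_rbc)
        assert g < 0.05  # scotopic input is nearly all rod-bipolar

    def test_cx36ko_leaves_only_rod_pathway_photopic(self, params):
        g = pathway_gate(25000.0, Condition(genotype="Cx36KO"), params)
        assert g == pytest.approx(params.at(25000.0).f_rbc)
        assert g < 0.1

    def test_uncalibrated_background_rejected(self, params):
        with pytest.raises(KeyError):
            pathway_gate(123.0, Condition(), params)


class TestSurroundGate:
    def test_control_identity(self, params):
        w = surround_gate(Condition(), 500.0, params)
        bp = params.at(500.0)
        assert w.w_pre_eff == pytest.approx(bp.w_pre_psp)
        assert w.f_trans_eff == pytest.approx(bp.f_transient)

    def test_ttx_plus_hepes_removes_presynaptic_surround(self, params):
        w = surround_gate(Condition(drugs={"TTX", "HEPES"}), 500.0, params)
        assert w.w_pre_eff == 0.0 and w.w_post_eff == 0.0

    def test_nnos_ablation_is_mesopic_specific(self, params):
        w_meso = surround_gate(Condition(genotype="nNOS_ablated"), 500.0, params)
        w_photo = surround_gate(Condition(genotype="nNOS_ablated"), 25000.0, params)
        assert w_meso.w_pre_trans == 0.0
        assert w_photo.w_pre_trans > 0.0

    def test_gabazine_boosts_presynaptic_and_removes_direct(self, params):
        ctrl = surround_gate(Condition(mode="EPSC"), 500.0, params)
        gbz = surround_gate(Condition(mode="EPSC", drugs={"gabazine"}), 500.0, params)
        assert gbz.w_pre_eff == pytest.approx(params.gabazine_boost * ctrl.w_pre_eff)
        assert gbz.w_post_eff == 0.0

    def test_tpmpa_removes_presynaptic_weight(self, params):
        w = surround_gate(Condition(drugs={"gabazine", "TPMPA"}), 25000.0, params)
        assert w.w_pre_eff == 0.0


class TestResponseTimecourse:
    def test_small_spot_rises_to_plateau_without_dip(self, params):
        tc = response_timecourse(_spot(88.0, bg=25000.0), Condition(), params, FS)
        i0, i1 = int(0.5 * FS), int(1.0 * FS)
        stim = tc.values[i0:i1]
        peak = stim.max()
        assert stim[-1] > 0.95 * peak  # sustained: plateau stays near the peak
        assert stim[stim.argmax():].min() > 0.95 * peak

    def test_large_spot_photopic_is_suppressed_and_transient(self, params):
        small = response_timecourse(_spot(88.0, bg=25000.0), Condition(), params, FS)
        large = response_timecourse(_spot(1200.0, bg=25000.0), Condition(), params, FS)
        i0, i1 = int(0.5 * FS), int(1.0 * FS)
        seg = large.values[i0:i1]
        assert seg.max() < small.values[i0:i1].max()
        # post-onset trough well below the response peak (brief/transient shape)
        assert seg[seg.argmax():].min() < 0.5 * seg.max()

    def test_no_surround_responses_scale_with_center_drive(self, linear_params):
        cond = Condition()
        tc_1200 = response_timecourse(_spot(1200.0), cond, linear_params, FS)
        ep_full = _spot(1200.0)
        ep_full.shape, ep_full.diameter_um = "uniform", None
        tc_full = response_timecourse(ep_full, cond, linear_params, FS)
        c_1200, _ = spatial_drive(_spot(1200.0), linear_params)
        np.testing.assert_allclose(tc_1200.values, tc_full.values * c_1200, atol=1e-9)

    def test_negative_contrast_annulus_has_no_transient_surround(self, params):
        ep = make_annulus_protocol([-1.0], background_rstar=500.0)[0]
        tc = response_timecourse(ep, Condition(), params, FS)
        assert np.all(tc.transient_surround == 0.0)
        # sustained (horizontal-cell) disinhibition depolarizes
        assert tc.values.max() > 0.0

    def test_positive_annulus_hyperpolarizes_then_sustains(self, params):
        ep = make_annulus_protocol([1.0], background_rstar=500.0)[0]
        tc = response_timecourse(ep, Condition(), params, FS)
        ts = TrialSet(traces=tc.values[None, :], fs_hz=FS, units="mV", epoch=ep)
        transient, sustained = metrics.annulus_metrics(ts)
        assert transient < sustained < 0.0


class TestSimulation:
    def test_same_seed_bitwise_identical(self, params):
        ep = _spot(88.0)
        a = simulate_trace(ep, Condition(), params, cell_id=3, trial=1, seed=11)
        b = simulate_trace(ep, Condition(), params, cell_id=3, trial=1, seed=11)
        assert np.array_equal(a.values, b.values)
        c = simulate_trace(ep, Condition(), params, cell_id=3, trial=2, seed=11)
        assert not np.array_equal(a.values, c.values)

    def test_zero_noise_equals_noiseless_timecourse(self, params):
        p = params.copy()
        p.noise_sd_mv = p.cell_cv = p.trial_cv = 0.0
        ep = _spot(88.0)
        tr = simulate_trace(ep, Condition(), p, seed=5)
        tc = response_timecourse(ep, Condition(), p)
        np.testing.assert_allclose(tr.values, tc.values, atol=1e-12)

    def test_trial_mean_converges_to_noiseless(self, params):
        # Monte-Carlo oracle: the mean over repeats approaches the noiseless
        # trace and the residual shrinks roughly as 1/sqrt(n)
        p = params.copy()
        p.cell_cv = p.trial_cv = 0.0
        ep = _spot(88.0)
        tc = response_timecourse(ep, Condition(), p)

        def max_dev(n):
            mean = np.mean(
                [simulate_trace(ep, Condition(), p, trial=i, seed=2).values for i in range(n)],
                axis=0,
            )
            return np.abs(mean - tc.values).max()

        d_small, d_large = max_dev(10), max_dev(160)
        assert d_large < d_small / 2.0  # expected factor 4, allow slack

    def test_population_cardinality_and_determinism(self, params):
        protocol = make_spot_protocol([88.0, 1200.0], background_rstar=500.0)
        pop = simulate_population(protocol, Condition(), params, n_cells=3, n_trials=4, seed=9)
        assert len(pop) == 3
        assert sum(ts.n_trials for per in pop.values() for ts in per.values()) == 3 * 2 * 4
        pop2 = simulate_population(protocol, Condition(), params, n_cells=3, n_trials=4, seed=9)
        for cid in pop:
            for label in pop[cid]:
                assert np.array_equal(pop[cid][label].traces, pop2[cid][label].traces)

    def test_population_mean_peak_matches_calibrated_gain(self, params):
        # gains are lognormal with mean 1: with recording noise off the
        # population-mean small-spot peak estimates the calibrated amplitude
        p = params.copy()
        p.noise_sd_mv = 0.0
        protocol = make_spot_protocol([88.0], background_rstar=500.0)
        pop = simulate_population(protocol, Condition(), p, n_cells=200, n_trials=4, seed=3)
        peaks = [
            metrics.peak_depolarization(next(iter(per.values()))) for per in pop.values()
        ]
        expected = response_timecourse(protocol[0], Condition(), p).values.max()
        sem = np.std(peaks, ddof=1) / np.sqrt(len(peaks))
        assert abs(np.mean(peaks) - expected) < 2 * sem + 1e-9

    def test_cx36ko_photopic_response_below_noise_floor(self, params):
        cond = Condition(genotype="Cx36KO", mode="EPSC")
        for d in (88.0, 325.0, 1200.0):
            tc = response_timecourse(_spot(d, bg=25000.0), cond, params, FS)
            assert np.abs(tc.values).max() < 3.0 * params.noise_sd_pa

    def test_linear_model_sinusoid_is_unrectified(self, linear_params):
        ep = make_sinusoid_protocol([1.0], [1000.0], background_rstar=25000.0)[0]
        tc = response_timecourse(ep, Condition(), linear_params, FS)
        ts = TrialSet(traces=tc.values[None, :], fs_hz=FS, units="mV", epoch=ep)
        ri = metrics.rectification_index(metrics.cycle_response(ts))
        assert abs(ri) < 1e-6


class TestSpikes:
    def test_requires_rgc(self, params):
        with pytest.raises(ValueError):
            Condition(mode="spikes", cell="AII")

    def test_zero_gain_gives_homogeneous_poisson(self, params):
        p = params.copy()
        p.rate_gain_hz, p.rate_base_hz, p.cell_cv = 0.0, 50.0, 0.0
        ep = _spot(200.0, bg=25000.0)
        st = simulate_spikes(ep, Condition(mode="spikes", cell="sONalpha"), p,
                             n_trials=100, seed=21)
        counts = [s.size for s in st.spike_times]
        expected = 50.0 * ep.total_s
        tol = 3.0 * np.sqrt(expected / len(counts))
        assert abs(np.mean(counts) - expected) < tol

    def test_empirical_rate_tracks_analytic_rate(self, params):
        # Poisson oracle: mean spike count in the stimulus window vs the
        # integral of the analytic rate function
        p = params.copy()
        p.cell_cv = 0.0
        cond = Condition(mode="spikes", cell="sONalpha")
        ep = _spot(200.0, bg=25000.0)
        st = simulate_spikes(ep, cond, p, n_trials=200, seed=22)
        per_trial, mean = metrics.spike_count(st)
        tc = response_timecourse(ep, cond, p)
        i0, i1 = int(0.5 * FS), int(1.0 * FS)
        lam = float(np.trapezoid(tc.rate_hz[i0:i1], dx=1.0 / FS))
        assert abs(mean - lam) < 3.0 * np.sqrt(lam / len(per_trial))

    def test_wt_large_spot_shows_burst_pause_firing(self, params):
        cond = Condition(mode="spikes", cell="sONalpha")
        tc = response_timecourse(_spot(1200.0, bg=25000.0), cond, params, FS)
        i0, i1 = int(0.5 * FS), int(1.0 * FS)
        r = tc.rate_hz[i0:i1]
        onset_peak = r[: int(0.12 * FS)].max()
        pause = r[int(0.10 * FS) : int(0.35 * FS)].min()
        resumed = r[-int(0.05 * FS):].mean()
        assert pause < 0.5 * onset_peak  # burst followed by a pause
        assert resumed > 2 * pause       # then resumption of sustained firing

    def test_cx36ko_rgc_is_sustained_at_all_sizes(self, params):
        cond = Condition(genotype="Cx36KO", mode="spikes", cell="sONalpha")
        tc = response_timecourse(_spot(1200.0, bg=25000.0, contrast=3.0), cond, params, FS)
        i0, i1 = int(0.5 * FS), int(1.0 * FS)
        r = tc.rate_hz[i0:i1]
        assert r[r.argmax():].min() > 0.8 * r.max()  # no pause
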