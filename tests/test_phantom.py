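"""Synthetic phantom: atlas, ground truth, paradigms, traces, forward model."""

import dataclasses

import numpy as np
import pytest
from scipy import stats as st

from cvrkit.phantom import (
    antr_paradigm,
    breath_hold_paradigm,
    condition_fraction,
    draw_ground_truth,
    gas_block_paradigm,
    generate_phantom,
    petco2_envelope,
    scap_paradigm,
    simulate_respiratory_trace,
    simulate_run,
    stop_signal_paradigm,
    task_switch_paradigm,
)


class TestGeneratePhantom:
    def test_default_atlas_has_68_adequate_parcels(self):
        ph = generate_phantom(68, (24, 24, 18), seed=7)
        labels = np.unique(ph.label_volume)
        assert set(ph.label_table) == set(range(1, 69))
        for lab in ph.label_table:
            assert (ph.label_volume == lab).sum() >= 20
        assert set(labels) - {0} == set(range(1, 69))

    def test_seeded_determinism(self):
        a = generate_phantom(68, (24, 24, 18), seed=7)
        b = generate_phantom(68, (24, 24, 18), seed=7)
        np.testing.assert_array_equal(a.label_volume, b.label_volume)
        c = generate_phantom(68, (24, 24, 18), seed=8)
        assert not np.array_equal(a.label_volume, c.label_volume)

    def test_two_parcels_partition_small_grid(self):
        # enumerate all 64 voxels: background plus parcels partition the grid
        ph = generate_phantom(2, (4, 4, 4), seed=0)
        counts = {lab: int((ph.label_volume == lab).sum()) for lab in (0, 1, 2)}
        assert sum(counts.values()) == 64
        assert counts[1] >= 20 and counts[2] >= 20

    def test_parcels_are_connected_blocks(self):
        from scipy import ndimage

        ph = generate_phantom(6, (10, 10, 6), seed=3)
        for lab in ph.label_table:
            _, n = ndimage.label(ph.label_volume == lab)
            assert n == 1

    def test_too_small_grid_names_required_minimum(self):
        with pytest.raises(ValueError, match=r"at least 160"):
            generate_phantom(8, (4, 4, 4), seed=0)

    def test_hemisphere_tags(self):
        ph = generate_phantom(68, (24, 24, 18), seed=7)
        hemis = {v["hemisphere"] for v in ph.label_table.values()}
        assert hemis == {"L", "R"}


class TestDrawGroundTruth:
    def test_noiseless_coupling_is_exact(self, small_atlas):
        truth = draw_ground_truth(small_atlas, n_subjects=3, subject_sd=0.0, seed=2)
        for s in range(3):
            x = truth.bh_psc_true[:, s]
            y = truth.task_amp_true[:, s]
            fit = st.linregress(x, y)
            assert fit.rvalue**2 == pytest.approx(1.0, abs=1e-12)
            assert fit.slope == pytest.approx(truth.coupling_slope, abs=1e-12)

    def test_null_coupling_has_no_shared_variance(self):
        # with no coupling, across-parcel R^2 is pure chance (E ~ 1/(R-1))
        ph = generate_phantom(68, (24, 24, 18), seed=0)
        r2s = []
        for seed in range(20):
            truth = draw_ground_truth(
                ph, n_subjects=1, coupling_slope=0.0, subject_sd=0.4, seed=seed
            )
            fit = st.linregress(truth.bh_psc_true[:, 0], truth.task_amp_true[:, 0])
            r2s.append(fit.rvalue**2)
        assert np.mean(r2s) < 0.06

    def test_ols_on_truth_covers_generating_slope(self):
        ph = generate_phantom(68, (24, 24, 18), seed=1)
        truth = draw_ground_truth(
            ph, n_subjects=100, coupling_slope=0.5, coupling_intercept=0.2,
            subject_sd=0.3, seed=1,
        )
        x = truth.bh_psc_true.ravel()
        y = truth.task_amp_true.ravel()
        fit = st.linregress(x, y)
        half = st.t.ppf(0.975, x.size - 2) * fit.stderr
        assert fit.slope - half <= 0.5 <= fit.slope + half

    def test_reproducible_and_positive(self, small_atlas):
        a = draw_ground_truth(small_atlas, 5, seed=9)
        b = draw_ground_truth(small_atlas, 5, seed=9)
        np.testing.assert_array_equal(a.task_amp_true, b.task_amp_true)
        assert np.all(a.cvr_true > 0)

    def test_validation_errors(self, small_atlas):
        with pytest.raises(ValueError):
            draw_ground_truth(small_atlas, 0)
        with pytest.raises(ValueError, match="cvr_log_sd"):
            draw_ground_truth(small_atlas, 2, cvr_log_sd=0.0)


class TestParadigms:
    def test_breath_hold_defaults(self):
        bh = breath_hold_paradigm()
        assert bh.total_duration == 150.0  # 2.5 min
        assert bh.onsets.size == 5
        assert np.all(bh.durations == 13.5)
        assert np.all(np.diff(bh.onsets) == 30.0)  # 13.5 s hold + 16.5 s rest

    def test_gas_block_defaults(self):
        gas = gas_block_paradigm()
        assert gas.total_duration == 360.0
        assert gas.onsets[0] == 120.0 and gas.durations[0] == 120.0

    @pytest.mark.parametrize(
        "factory,n_trials", [(scap_paradigm, 48), (stop_signal_paradigm, 128),
                             (task_switch_paradigm, 96), (antr_paradigm, 72)]
    )
    def test_event_counts_and_validity(self, factory, n_trials):
        par = factory(seed=4)
        assert par.onsets.size == n_trials
        assert np.all(np.diff(par.onsets) > 0)
        assert np.all(par.onsets + par.durations <= par.total_duration)
        assert par.correctness.sum() == n_trials - round(0.1 * n_trials)

    def test_condition_structure(self):
        assert condition_fraction(stop_signal_paradigm(seed=0), label="stop") == 0.25
        assert condition_fraction(antr_paradigm(seed=0), exclude="no_cue") == pytest.approx(60 / 72)
        assert condition_fraction(task_switch_paradigm(seed=0), label="switch") == pytest.approx(1 / 3, abs=0.01)
        assert antr_paradigm().n_volumes == 260

    def test_invalid_specs_rejected(self):
        from cvrkit.phantom import ParadigmSpec

        with pytest.raises(ValueError, match="increasing"):
            ParadigmSpec("event_task", [5.0, 5.0], [1.0, 1.0], ["a", "a"], 100.0, 2.0)
        with pytest.raises(ValueError, match="total_duration"):
            ParadigmSpec("event_task", [99.5], [1.0], ["a"], 100.0, 2.0)
        with pytest.raises(ValueError, match="kind"):
            ParadigmSpec("mystery", [1.0], [1.0], ["a"], 100.0, 2.0)


class TestRespiratoryTrace:
    def test_end_tidal_plateau_construction(self):
        # per-breath maxima averaged over the CO2 plateau hit the configured level
        gas = gas_block_paradigm()
        trace = simulate_respiratory_trace(gas)
        from scipy.signal import find_peaks

        peaks, _ = find_peaks(trace.co2, distance=int(2.0 / 0.05), prominence=2.0)
        tpk = trace.time[peaks]
        plateau = (tpk > 120 + 15) & (tpk < 240)
        assert trace.co2[peaks][plateau].mean() == pytest.approx(45.19, abs=0.1)
        baselinepk = tpk < 120
        assert trace.co2[peaks][baselinepk].mean() == pytest.approx(35.38, abs=0.1)

    def test_envelope_reaches_exact_plateau(self):
        gas = gas_block_paradigm()
        t = np.arange(0, 360, 0.05)
        env = petco2_envelope(gas, t)
        inside = (t >= 135.0) & (t < 240.0)
        assert np.all(env[inside] == 45.19)
        assert np.all(env[t < 120.0] == 35.38)


class TestSimulateRun:
    def test_seeded_determinism(self, small_atlas, bh_paradigm, truth_factory):
        truth = truth_factory(noise_sd=1.0)
        a = simulate_run(small_atlas, truth, bh_paradigm, 0, seed=5)
        b = simulate_run(small_atlas, truth, bh_paradigm, 0, seed=5)
        np.testing.assert_array_equal(a.data, b.data)

    def test_zero_cvr_parcel_is_constant_when_noiseless(self, small_atlas, bh_paradigm, truth_factory):
        truth = truth_factory(lag_choices=(0.0,))
        cvr = truth.cvr_true.copy()
        cvr[0] = 0.0
        truth = dataclasses.replace(truth, cvr_true=cvr)
        run = simulate_run(small_atlas, truth, bh_paradigm, 0, noise_sd=0.0, seed=0)
        series = run.data[small_atlas.label_volume == 1]
        assert np.all(series == series[:, [0]])

    def test_gas_peak_psc_equals_cvr_times_delta(self, truth_factory):
        # noiseless, zero lag: per-voxel peak PSC = cvr_true * 9.81 by construction
        atlas = generate_phantom(4, (8, 8, 6), seed=1)
        truth = draw_ground_truth(atlas, 1, seed=1, lag_choices=(0.0,))
        gas = gas_block_paradigm()
        run, trace = simulate_run(atlas, truth, gas, 0, noise_sd=0.0, seed=0)
        for lab in atlas.label_table:
            vox = run.data[atlas.label_volume == lab][0]
            peak_psc = (vox.max() / 100.0 - 1.0) * 100.0
            expected = truth.cvr_subject[lab - 1, 0] * 9.81
            assert peak_psc == pytest.approx(expected, rel=1e-6)

    def test_subject_out_of_range(self, small_atlas, bh_paradigm, truth_factory):
        truth = truth_factory()
        with pytest.raises(IndexError):
            simulate_run(small_atlas, truth, bh_paradigm, subject=5, seed=0)

    def test_ar1_noise_is_autocorrelated(self, small_atlas, bh_paradigm, truth_factory):
        truth = truth_factory()
        white = simulate_run(small_atlas, truth, bh_paradigm, 0, noise_sd=2.0, seed=3)
        ar = simulate_run(small_atlas, truth, bh_paradigm, 0, noise_sd=2.0, seed=3, ar_rho=0.5)
        def lag1(run):
            d = run.data[small_atlas.brain_mask] - run.data[small_atlas.brain_mask].mean(axis=1, keepdims=True)
            return np.mean(np.sum(d[:, 1:] * d[:, :-1], axis=1) / np.sum(d**2, axis=1))
        assert lag1(ar) > lag1(white) + 0.2

    def test_motion_attached(self, small_atlas, bh_paradigm, truth_factory):
        run = simulate_run(small_atlas, truth_factory(), bh_paradigm, 0, seed=0)
        assert run.meta["motion"].shape == (run.n_volumes, 6)
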