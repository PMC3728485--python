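"""fMRI branch: HRF sampling, masks, exemplar filter, GLM, features."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from icdecode import synth
from icdecode.fmri import (HRFParams, BinaryMask, SpatialMap, Volume4D,
                           build_fmri_features, filter_consecutive_exemplars,
                           glm_zstat, hrf_peak_sample_times,
                           mask_mean_timecourse, sample_hrf, spatial_ica,
                           threshold_binarize)


def _events(labels, onsets=None):
    labels = list(labels)
    if onsets is None:
        onsets = 10.0 + 4.0 * np.arange(len(labels))
    return pd.DataFrame({"onset": onsets, "duration": 1.0,
                         "trial_type": labels,
                         "response_time": 1.0})


class TestHRF:
    def test_peak_lag_matches_grid_oracle(self):
        p = HRFParams()
        # independent oracle: dense-grid argmax of the double-gamma density
        t = np.arange(0, 32, 0.01)
        h = stats.gamma.pdf(t, p.peak_delay / p.peak_dispersion,
                            scale=p.peak_dispersion) - \
            p.undershoot_ratio * stats.gamma.pdf(
                t, p.undershoot_delay / p.undershoot_dispersion,
                scale=p.undershoot_dispersion)
        assert abs(p.peak_lag - t[np.argmax(h)]) < 0.02

    def test_sample_indices_round_onset_plus_lag(self):
        p = HRFParams()
        ev = _events(["B"], onsets=[0.0])
        idx, kept = hrf_peak_sample_times(ev, p, TR=2.0, n_scans=100)
        assert idx[0] == round(p.peak_lag / 2.0)

    def test_event_past_scan_end_dropped(self):
        ev = _events(["B", "DB"], onsets=[10.0, 500.0])
        idx, kept = hrf_peak_sample_times(ev, HRFParams(), TR=2.0, n_scans=50)
        assert list(kept) == [0]

    def test_integer_tr_spacing_preserved(self):
        ev = _events(["B", "DB"], onsets=[10.0, 30.0])  # 10 TRs apart
        idx, _ = hrf_peak_sample_times(ev, HRFParams(), TR=2.0, n_scans=100)
        assert idx[1] - idx[0] == 10


class TestConsecutiveFilter:
    def test_worked_example(self):
        ev = _events(["B", "B", "DB", "B", "DB", "DB"])
        kept = filter_consecutive_exemplars(ev)
        assert list(kept.index) == [0, 1, 4, 5]

    def test_alternating_labels_all_dropped(self):
        ev = _events(["B", "DB"] * 5)
        assert len(filter_consecutive_exemplars(ev)) == 0

    def test_matches_brute_force_runs(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            labels = rng.choice(["B", "DB"], size=rng.integers(1, 40))
            ev = _events(labels)
            kept = set(filter_consecutive_exemplars(ev).index)
            # oracle: expand runs of length >= 2 via groupby
            expected, pos = set(), 0
            for _, grp in itertools.groupby(labels):
                run = list(grp)
                if len(run) >= 2:
                    expected |= set(range(pos, pos + len(run)))
                pos += len(run)
            assert kept == expected

    def test_global_label_swap_invariance(self):
        rng = np.random.default_rng(1)
        labels = rng.choice(["B", "DB"], size=60)
        a = filter_consecutive_exemplars(_events(labels)).index
        swapped = np.where(labels == "B", "DB", "B")
        b = filter_consecutive_exemplars(_events(swapped)).index
        assert list(a) == list(b)


class TestThreshold:
    def test_inclusive_threshold(self):
        m = SpatialMap(values=np.array([[[1.0, 2.3, 3.0]]]), kind="IC",
                       map_id="IC0")
        mask = threshold_binarize(m, 2.3)
        np.testing.assert_array_equal(mask.values[0, 0], [False, True, True])

    def test_all_negative_map_empty_with_flag(self):
        m = SpatialMap(values=-np.ones((2, 2, 2)), kind="IC", map_id="IC1")
        mask = threshold_binarize(m, 2.3)
        assert mask.empty and mask.n_voxels == 0

    def test_degenerate_threshold_selects_everything(self):
        m = SpatialMap(values=np.random.default_rng(0).standard_normal(
            (3, 3, 3)), kind="IC", map_id="IC2")
        mask = threshold_binarize(m, -np.inf)
        assert mask.n_voxels == 27


class TestMaskMean:
    def test_single_voxel_mask(self):
        rng = np.random.default_rng(2)
        vol = Volume4D(values=rng.standard_normal((4, 4, 4, 20)), TR=2.0)
        mask = BinaryMask(values=np.zeros((4, 4, 4), bool), threshold=0.0,
                          parent_id="x")
        mask.values[1, 2, 3] = True
        np.testing.assert_array_equal(mask_mean_timecourse(vol, mask),
                                      vol.values[1, 2, 3])

    def test_constant_volume(self):
        vol = Volume4D(values=np.full((3, 3, 3, 5), 4.2), TR=1.0)
        mask = BinaryMask(values=np.ones((3, 3, 3), bool), threshold=0.0,
                          parent_id="x")
        np.testing.assert_allclose(mask_mean_timecourse(vol, mask), 4.2)

    def test_empty_mask_rejected(self):
        vol = Volume4D(values=np.zeros((2, 2, 2, 4)), TR=1.0)
        mask = BinaryMask(values=np.zeros((2, 2, 2), bool), threshold=0.0,
                          parent_id="x")
        with pytest.raises(ValueError, match="empty"):
            mask_mean_timecourse(vol, mask)


class TestSpatialICA:
    def test_zscored_maps(self, small_fmri):
        cfg, vol, _ = small_fmri
        maps, _ = spatial_ica(Volume4D(values=vol, TR=cfg.TR), K=3, seed=0)
        for m in maps:
            assert abs(m.values.mean()) < 1e-6
            assert abs(m.values.std() - 1.0) < 1e-6

    def test_recovers_planted_maps_and_timecourses(self):
        cfg = synth.FMRISimConfig(seed=5, noise_sd=0.0)
        vol, truth = synth.simulate_fmri(cfg)
        v = Volume4D(values=vol, TR=cfg.TR)
        maps, tcs = spatial_ica(v, K=3, seed=0)
        for k in range(3):
            mc = max(abs(np.corrcoef(maps[k].values.ravel(),
                                     truth.true_maps[j].ravel())[0, 1])
                     for j in range(3))
            assert mc > 0.9
            tc = max(abs(np.corrcoef(tcs[:, k], truth.true_timecourses[j])[0, 1])
                     for j in range(3))
            assert tc > 0.9

    def test_k_exceeding_scans_rejected(self):
        vol = Volume4D(values=np.random.default_rng(0).standard_normal(
            (4, 4, 4, 5)), TR=2.0)
        with pytest.raises(ValueError, match="exceeds"):
            spatial_ica(vol, K=6)


class TestGLM:
    def test_single_class_component_lights_blob(self):
        cfg = synth.FMRISimConfig(
            n_components=1, n_events_per_class=10, noise_sd=0.0,
            amplitude_jitter_sd=0.3, loadings=[(1.0, 0.0)], seed=4)
        vol, truth = synth.simulate_fmri(cfg)
        z = glm_zstat(Volume4D(values=vol, TR=cfg.TR), truth.event_table,
                      contrast="B-DB")
        blob = truth.true_maps[0] > 0.3
        assert (z.values[blob] > 0).all()
        assert np.abs(z.values[~(truth.true_maps[0] > 0)]).max() < 1e-6

    def test_contrast_antisymmetry(self, small_fmri):
        cfg, vol, truth = small_fmri
        v = Volume4D(values=vol, TR=cfg.TR)
        a = glm_zstat(v, truth.event_table, contrast="B-DB")
        b = glm_zstat(v, truth.event_table, contrast="DB-B")
        np.testing.assert_allclose(a.values, -b.values, atol=1e-10)

    def test_null_rate_calibrated(self):
        rng = np.random.default_rng(5)
        ev = synth.simulate_event_schedule(n_events=60, seed=5)
        T = int((ev["onset"].iloc[-1] + 32) / 2.0)
        vol = Volume4D(values=rng.standard_normal((12, 12, 8, T)), TR=2.0)
        z = glm_zstat(vol, ev)
        p = 2 * stats.norm.sf(2.3)
        rate = (np.abs(z.values) >= 2.3).mean()
        n_vox = z.values.size
        assert abs(rate - p) < 4 * np.sqrt(p * (1 - p) / n_vox)

    def test_too_few_events_rejected(self):
        vol = Volume4D(values=np.zeros((2, 2, 2, 30)), TR=2.0)
        with pytest.raises(ValueError, match="events"):
            glm_zstat(vol, _events(["B", "B", "B", "DB"]))


class TestFeatures:
    def test_one_column_per_component(self):
        tcs = np.random.default_rng(6).standard_normal((50, 6))
        ev = _events(["B", "DB", "B", "DB"])
        X, y, flags = build_fmri_features(tcs, [3, 8, 13, 18], ev)
        assert X.shape == (4, 6)
        assert not flags.any()

    def test_collision_flagged_and_droppable(self):
        tcs = np.random.default_rng(7).standard_normal((50, 2))
        ev = _events(["B", "DB", "B"])
        X, y, flags = build_fmri_features(tcs, [3, 3, 10], ev)
        assert flags[:2].all() and not flags[2]
        Xd, yd, _ = build_fmri_features(tcs, [3, 3, 10], ev,
                                        on_collision="drop")
        assert Xd.shape[0] == 1

    def test_differential_component_separates_classes(self):
        cfg = synth.FMRISimConfig(n_events_per_class=40, noise_sd=0.2, seed=8)
        vol, truth = synth.simulate_fmri(cfg)
        idx, kept = hrf_peak_sample_times(truth.event_table, cfg.hrf_params,
                                          cfg.TR, vol.shape[-1])
        ev = truth.event_table.iloc[kept]
        X, y, _ = build_fmri_features(truth.true_timecourses.T, idx, ev)
        b, db = X[y == "B", 0], X[y == "DB", 0]
        t = (b.mean() - db.mean()) / np.sqrt(b.var(ddof=1) / len(b)
                                             + db.var(ddof=1) / len(db))
        assert t > 3

    def test_zero_noise_isolated_event_feature_equals_amplitude(self):
        amp = 2.0
        cfg = synth.FMRISimConfig(
            n_components=1, n_events_per_class=3, mean_iti=35.0,
            noise_sd=0.0, amplitude_jitter_sd=0.0, loadings=[(amp, amp)],
            seed=9)
        vol, truth = synth.simulate_fmri(cfg)
        idx, kept = hrf_peak_sample_times(truth.event_table, cfg.hrf_params,
                                          cfg.TR, vol.shape[-1])
        X, y, _ = build_fmri_features(truth.true_timecourses.T, idx,
                                      truth.event_table.iloc[kept])
        # HRF is unit-peak and events isolated, but sampling rounds to the
        # TR grid: h(peak +- TR/2) / h(peak) ~ 0.91 bounds the undershoot
        np.testing.assert_allclose(X[:, 0], amp, rtol=0.10)


class TestEndToEnd:
    def test_accuracy_monotone_in_effect_size(self):
        from icdecode.decode import ClassifierSpec, CVSpec, run_nested_cv
        from icdecode.pipeline import FMRIICBuilder
        means = []
        for contrast in (0.0, 0.4, 0.8):
            accs = []
            for seed in range(5):
                cfg = synth.FMRISimConfig(
                    seed=seed, noise_sd=0.3,
                    loadings=[(1.0, 1.0 - contrast), (1.0 - contrast, 1.0),
                              (0.6, 0.6)])
                vol, truth = synth.simulate_fmri(cfg)
                b = FMRIICBuilder(Volume4D(values=vol, TR=cfg.TR),
                                  truth.event_table, K=3, seed=0, n_keep=3)
                rep = run_nested_cv(b, ClassifierSpec("naive_bayes"),
                                    CVSpec(outer_folds=5, inner_folds=5,
                                           seed=0))
                accs.append(rep.mean_accuracy)
            means.append(np.mean(accs))
        assert means[0] <= means[1] + 0.05  # chance level, within noise
        assert means[2] >= means[1] - 0.02
        assert means[2] > means[0]
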