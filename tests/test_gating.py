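"""ROC analysis, threshold selection, mixtures, enumeration, LoD."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import roc_auc_score

import holoenum as he
from holoenum.gating import DEFAULT_ALPHA_GRID, MixtureSpec, ROCCurve


class TestRoc:
    def test_perfect_scores(self):
        p = np.array([1.0] * 20 + [0.0] * 20)
        y = np.array([1] * 20 + [0] * 20)
        curve = he.roc(p, y)
        np.testing.assert_array_equal(curve.tpr, 1.0)
        np.testing.assert_array_equal(curve.fpr, 0.0)

    def test_fpr_tpr_non_increasing_in_threshold(self, trained_snet):
        model, _, test_crops, test_labels = trained_snet
        p = he.predict_proba(model, test_crops)
        curve = he.roc(p, test_labels)
        # thresholds descending -> rates must be non-decreasing along the list
        assert np.all(np.diff(curve.tpr) >= 0)
        assert np.all(np.diff(curve.fpr) >= 0)

    def test_default_grid_spans_paper_thresholds(self):
        for a in (0.5, 0.9, 0.999, 0.9999999):
            assert a in DEFAULT_ALPHA_GRID

    def test_random_scores_near_diagonal(self):
        """Uninformative scores give an ROC hugging the diagonal; checked
        against scikit-learn's AUC on the same data as the oracle."""
        rng = np.random.default_rng(0)
        p = rng.uniform(0, 1, 4000)
        y = rng.integers(0, 2, 4000)
        auc = roc_auc_score(y, p)
        assert abs(auc - 0.5) < 0.05
        grid = np.linspace(0.0, 1.0 - 1e-9, 101)
        curve = he.roc(p, y, grid)
        assert np.max(np.abs(curve.tpr - curve.fpr)) < 0.07

    def test_points_match_empirical_rates(self, trained_snet):
        """Dual route: each (FPR, TPR) computed here equals the empirical
        rates computed independently."""
        model, _, test_crops, test_labels = trained_snet
        p = he.predict_proba(model, test_crops[:800])
        y = test_labels[:800]
        curve = he.roc(p, y, (0.3, 0.6, 0.9))
        for thr, tpr, fpr in zip(curve.thresholds, curve.tpr, curve.fpr):
            assert tpr == pytest.approx(np.mean(p[y == 1] > thr))
            assert fpr == pytest.approx(np.mean(p[y == 0] > thr))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            he.roc([0.1, 0.9], [1, 1])


class TestSelectAlpha:
    def test_smallest_threshold_at_min_fpr(self):
        curve = ROCCurve(
            thresholds=np.array([0.9999, 0.999, 0.99, 0.5]),
            tpr=np.array([0.5, 0.6, 0.8, 0.99]),
            fpr=np.array([0.0003, 0.0003, 0.001, 0.01]),
        )
        assert he.select_alpha(curve) == 0.999

    def test_all_zero_fpr_gives_smallest_threshold(self):
        curve = ROCCurve(
            thresholds=np.array([0.999, 0.9, 0.5]),
            tpr=np.array([0.7, 0.9, 1.0]),
            fpr=np.zeros(3),
        )
        assert he.select_alpha(curve) == 0.5

    def test_selected_alpha_never_worse_than_default_gate(self, trained_snet):
        model, _, test_crops, test_labels = trained_snet
        p = he.predict_proba(model, test_crops)
        curve = he.roc(p, test_labels)
        alpha = he.select_alpha(curve)
        fpr_at = lambda a: he.confusion(p, test_labels, alpha=a).fpr
        assert fpr_at(alpha) <= fpr_at(0.5)


class TestMixtures:
    def test_counts_and_labels(self, crop_pools):
        tumor, wbc = crop_pools
        crops, labels, _, _ = he.make_mixture(
            tumor, wbc, MixtureSpec(n_tumor=100, n_wbc=500, seed=1)
        )
        assert len(crops) == 600
        assert labels.sum() == 100

    def test_single_tumor_cell_mixture(self, crop_pools):
        tumor, wbc = crop_pools
        crops, labels, tumor_ids, _ = he.make_mixture(
            tumor, wbc, MixtureSpec(n_tumor=1, n_wbc=500, seed=2)
        )
        assert labels.sum() == 1 and len(tumor_ids) == 1

    def test_no_overlap_across_datasets(self, crop_pools):
        tumor, wbc = crop_pools
        used_t, used_w = set(), set()
        all_t, all_w = [], []
        for k in range(4):
            _, _, t_ids, w_ids = he.make_mixture(
                tumor,
                wbc,
                MixtureSpec(n_tumor=50, n_wbc=400, seed=k),
                used_tumor=used_t,
                used_wbc=used_w,
            )
            all_t.append(set(t_ids.tolist()))
            all_w.append(set(w_ids.tolist()))
        for i in range(4):
            for j in range(i + 1, 4):
                assert not (all_t[i] & all_t[j])
                assert not (all_w[i] & all_w[j])

    def test_pool_exhaustion_raises(self, crop_pools):
        tumor, wbc = crop_pools
        with pytest.raises(ValueError):
            he.make_mixture(tumor, wbc, MixtureSpec(n_tumor=len(tumor) + 1, n_wbc=0))

    def test_false_positives_scale_linearly_with_wbc_count(
        self, trained_snet, crop_pools
    ):
        """At a fixed moderate threshold the per-crop FPR is constant, so
        FP counts across mixtures are proportional to N_WBC (chi-squared
        goodness of fit at 5%)."""
        from scipy import stats

        model, _, _, _ = trained_snet
        tumor, wbc = crop_pools
        n_wbcs = [800, 1600, 3200]
        fps = []
        for k, n in enumerate(n_wbcs):
            crops, labels, _, _ = he.make_mixture(
                tumor, wbc, MixtureSpec(n_tumor=50, n_wbc=n, seed=10 + k, no_overlap=False)
            )
            p = he.predict_proba(model, crops)
            fps.append(he.confusion(p, labels, alpha=0.5).fp)
        fps = np.asarray(fps, float)
        rate = fps.sum() / sum(n_wbcs)
        assert rate > 0, "no false positives at alpha=0.5; test uninformative"
        expected = rate * np.asarray(n_wbcs, float)
        chi2 = float(((fps - expected) ** 2 / expected).sum())
        assert stats.chi2.sf(chi2, df=len(n_wbcs) - 1) > 0.05


class TestVolumes:
    def test_full_acquisition_images_one_ml(self, flow_default):
        vol = he.imaged_volume_ml(10_100, flow_default)
        assert vol == pytest.approx(1.0, rel=0.01)

    def test_zero_frames_zero_volume(self, flow_default):
        assert he.imaged_volume_ml(0, flow_default) == 0.0

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(n=st.integers(1, 50_000))
    def test_volume_linear_in_frames(self, n):
        flow = he.FlowConfig()
        assert he.imaged_volume_ml(2 * n, flow) == pytest.approx(
            2 * he.imaged_volume_ml(n, flow)
        )

    def test_geometric_frame_volume(self, optics_default):
        """800 um streamwise FOV x 500 um core x 330 um depth ~ 0.13 uL."""
        vol_ul = he.frame_geometric_volume_ml(optics_default) * 1e3
        assert vol_ul == pytest.approx(0.132, abs=0.005)


class TestEnumerate:
    def test_counts_to_concentration(self, flow_default):
        p = np.concatenate([np.full(100, 0.99999999), np.full(500, 0.1)])
        res = he.enumerate_detections(p, 0.9999999, 10_100, flow_default)
        assert res.detected_count == 100
        assert res.concentration_per_ml == pytest.approx(100.0, rel=0.01)

    def test_alpha_one_gates_everything(self, flow_default):
        p = np.array([0.9, 0.99, 0.999999])
        res = he.enumerate_detections(p, 1.0, 100, flow_default)
        assert res.detected_count == 0

    def test_count_monotone_in_alpha(self, flow_default):
        rng = np.random.default_rng(3)
        p = rng.uniform(0, 1, 500)
        counts = [
            he.enumerate_detections(p, a, 100, flow_default).detected_count
            for a in DEFAULT_ALPHA_GRID
        ]
        assert all(c1 >= c2 for c1, c2 in zip(counts, counts[1:]))


class TestLimitOfDetection:
    def test_constant_counts(self):
        mu, sd, lod = he.limit_of_detection([1, 1, 1])
        assert (mu, sd, lod) == (1.0, 0.0, 1.0)

    def test_printed_statistics_reproduced(self):
        """Three negative-control trials of (1,1,2) per mL give mu=1.33,
        sigma=0.58, LoD=2.49 to two decimals."""
        mu, sd, lod = he.limit_of_detection([1, 1, 2])
        assert round(mu, 2) == 1.33
        assert round(sd, 2) == 0.58
        assert round(lod, 2) == 2.49

    def test_fewer_than_two_trials_rejected(self):
        with pytest.raises(ValueError):
            he.limit_of_detection([3])

    def test_formula(self):
        assert he.lod_from_stats(2.33, 1.0) == pytest.approx(4.33)


class TestRetrainingGeneralization:
    def test_same_architecture_learns_second_tumor_line(self, optics_default):
        """Retraining the identical architecture on a different tumor
        class (SkOV3-like: smaller, lower contrast) gives held-out
        accuracy within 0.05 of the first-line run at equal scale."""
        accs = []
        for sim, seed in [
            (he.SimParams(), 201),
            (
                he.SimParams(tumor_diameter_um=16.0, tumor_amplitude_contrast=0.35),
                202,
            ),
        ]:
            crops, labels = he.make_training_crops(600, optics_default, sim=sim, seed=seed)
            model = he.build_snet(seed=0)
            he.train(model, crops, labels, epochs=8, seed=0)
            tc, tl = he.make_training_crops(300, optics_default, sim=sim, seed=seed + 50)
            p = he.predict_proba(model, tc)
            accs.append(float(np.mean((p > 0.5) == tl)))
        assert abs(accs[0] - accs[1]) <= 0.05
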