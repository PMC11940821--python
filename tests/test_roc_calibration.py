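"""ROC sweep, Youden selection, AUC estimators and channel calibration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from sklearn.metrics import roc_auc_score

import behavcal as bc
from behavcal.roc_calibration import BELOW


def _frame(pos_scores, neg_scores, pos_behaviour=bc.Behaviour.SPRINTING,
           neg_behaviour=bc.Behaviour.SEDENTARY_SCREEN_TIME):
    rows = []
    for b, scores in [(pos_behaviour, pos_scores), (neg_behaviour, neg_scores)]:
        for j, c in enumerate(scores):
            rows.append(
                {
                    "child_id": "c1",
                    "device": bc.Device.MW8,
                    "position": bc.Position.WRIST,
                    "behaviour": b,
                    "epoch_index": j,
                    "count": float(c),
                }
            )
    return pd.DataFrame(rows)


def brute_force_auc(pos, neg):
    """Independent oracle: count concordant (pos > neg) pairs, ties half."""
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def exhaustive_youden(pos, neg):
    """Independent oracle: scan every candidate threshold for max J."""
    best = -np.inf
    pos, neg = np.asarray(pos, float), np.asarray(neg, float)
    cands = np.unique(np.concatenate([pos, neg, [min(pos.min(), neg.min()) - 1]]))
    for t in cands:
        j = (pos > t).mean() + (neg <= t).mean() - 1.0
        best = max(best, j)
    return best


class TestBinarize:
    def test_ovr_partitions_by_behaviour(self, small_labeled):
        scores, labels = bc.binarize_ovr(small_labeled, bc.VPA)
        assert labels.sum() == 3 and len(labels) == 18
        assert set(scores[labels == 1]) == {60.0, 61.0, 62.0}  # sprinting counts

    def test_lmvpa_positive_set_is_the_three_mobile_behaviours(self):
        assert bc.LMVPA.positive_set == frozenset(
            {bc.Behaviour.SPRINTING, bc.Behaviour.FLOORBALL_WALK, bc.Behaviour.PLAY_ON_FLOOR}
        )

    def test_moa_scheme_is_screen_time_below_threshold(self, small_labeled):
        assert bc.MOA.positive_set == frozenset({bc.Behaviour.SEDENTARY_SCREEN_TIME})
        assert bc.MOA.direction == BELOW
        scores, labels = bc.binarize_ovr(small_labeled, bc.MOA)
        # scores are negated so that higher = more likely motionless
        assert scores.max() == -10.0

    def test_degenerate_problem_rejected(self):
        frame = _frame([1, 2], [])
        with pytest.raises(bc.DegenerateProblemError):
            bc.binarize_ovr(frame, bc.VPA)

    def test_ovo_keeps_only_the_two_classes(self, small_labeled):
        scores, labels = bc.binarize_ovo(
            small_labeled, {bc.Behaviour.SPRINTING}, {bc.Behaviour.FLOORBALL_WALK}
        )
        assert len(labels) == 6 and labels.sum() == 3

    def test_ovo_sed_merges_crafts_and_recumbent(self, small_labeled):
        scores, labels = bc.binarize_ovo(
            small_labeled, bc.SED_BEHAVIOURS, {bc.Behaviour.SEDENTARY_SCREEN_TIME}
        )
        assert labels.sum() == 6  # two pooled positive behaviours, 3 epochs each

    def test_ovo_overlap_rejected(self, small_labeled):
        with pytest.raises(bc.ValidationError, match="disjoint"):
            bc.binarize_ovo(small_labeled, {bc.Behaviour.SPRINTING}, {bc.Behaviour.SPRINTING})


class TestRocCurve:
    def test_separable_reaches_perfect_point(self):
        roc = bc.roc_curve(np.array([10, 11, 1, 2.0]), np.array([1, 1, 0, 0]))
        assert any(p.sensitivity == 1.0 and p.specificity == 1.0 for p in roc)

    def test_constant_scores_only_trivial_points(self):
        roc = bc.roc_curve(np.array([5.0, 5, 5, 5]), np.array([1, 0, 1, 0]))
        assert {(p.sensitivity, p.specificity) for p in roc} == {(1.0, 0.0), (0.0, 1.0)}

    def test_hand_enumerated_confusion_table(self):
        # pos {3, 5}, neg {1, 4}: at t=4 predictions positive iff count > 4
        roc = bc.roc_curve(np.array([3, 5, 1, 4.0]), np.array([1, 1, 0, 0]))
        at4 = next(p for p in roc if p.threshold == 4.0)
        assert (at4.sensitivity, at4.specificity) == (0.5, 1.0)


class TestYouden:
    def test_separable_gives_j_one_at_largest_negative(self):
        roc = bc.roc_curve(np.array([10, 11, 1, 2.0]), np.array([1, 1, 0, 0]))
        res = bc.youden_cutoff(roc)
        assert res.youden_j == 1.0 and res.cutoff == 2.0

    def test_identical_distributions_give_j_zero(self):
        roc = bc.roc_curve(np.array([1, 2, 1, 2.0]), np.array([1, 1, 0, 0]))
        assert bc.youden_cutoff(roc).youden_j == pytest.approx(0.0)

    def test_tie_breaks_toward_smallest_threshold(self):
        # pos {3, 5}, neg {1, 4}: J = 0.5 at t=1 (sens 1.0) and t=4 (spec 1.0)
        roc = bc.roc_curve(np.array([3, 5, 1, 4.0]), np.array([1, 1, 0, 0]))
        res = bc.youden_cutoff(roc)
        assert res.youden_j == pytest.approx(0.5)
        assert res.cutoff == 1.0 and res.sensitivity == 1.0

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_selected_j_equals_exhaustive_scan(self, seed):
        rng = np.random.default_rng(seed)
        pos = rng.integers(0, 20, size=rng.integers(2, 15)).astype(float)
        neg = rng.integers(0, 20, size=rng.integers(2, 15)).astype(float)
        scores = np.concatenate([pos, neg])
        labels = np.concatenate([np.ones_like(pos), np.zeros_like(neg)]).astype(int)
        res = bc.youden_cutoff(bc.roc_curve(scores, labels))
        assert res.youden_j == pytest.approx(exhaustive_youden(pos, neg))
        assert res.youden_j == pytest.approx(res.sensitivity + res.specificity - 1.0)


class TestAuc:
    def test_hand_cases(self):
        assert bc.auc(np.array([10, 11, 1, 2.0]), np.array([1, 1, 0, 0])) == 1.0
        assert bc.auc(np.array([1, 2, 1, 2.0]), np.array([1, 1, 0, 0])) == 0.5
        # pos {3, 5}, neg {1, 4}: 3 of 4 pairs concordant
        assert bc.auc(np.array([3, 5, 1, 4.0]), np.array([1, 1, 0, 0])) == 0.75

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_equals_brute_force_pair_count_and_sklearn(self, seed):
        rng = np.random.default_rng(seed)
        pos = rng.integers(0, 15, size=rng.integers(2, 30)).astype(float)
        neg = rng.integers(0, 15, size=rng.integers(2, 30)).astype(float)
        scores = np.concatenate([pos, neg])
        labels = np.concatenate([np.ones_like(pos), np.zeros_like(neg)]).astype(int)
        expected = brute_force_auc(pos, neg)
        assert bc.auc(scores, labels) == pytest.approx(expected)
        assert roc_auc_score(labels, scores) == pytest.approx(expected)

    def test_equals_trapezoid_under_own_curve(self):
        rng = np.random.default_rng(11)
        scores = rng.normal(size=300) + np.repeat([1.0, 0.0], [120, 180])
        labels = np.repeat([1, 0], [120, 180])
        roc = bc.roc_curve(scores, labels)
        # points in ascending threshold order sweep the curve right-to-left
        fpr = np.array([1 - p.specificity for p in roc])
        tpr = np.array([p.sensitivity for p in roc])
        trap = -float(np.trapezoid(tpr, fpr))
        assert bc.auc(scores, labels) == pytest.approx(trap, abs=1e-12)

    def test_ovr_auc_is_mean_of_pairwise_aucs_at_equal_class_sizes(self):
        """With equal epoch counts per behaviour, the OvR AUC decomposes
        exactly into the unweighted mean of pairwise AUCs."""
        rng = np.random.default_rng(5)
        frames = []
        for i, b in enumerate(bc.Behaviour):
            frames.append(
                pd.DataFrame(
                    {
                        "child_id": "c1",
                        "device": bc.Device.MW8,
                        "position": bc.Position.WRIST,
                        "behaviour": b,
                        "epoch_index": np.arange(25),
                        "count": rng.normal(loc=20.0 * i, scale=12.0, size=25),
                    }
                )
            )
        labeled = pd.concat(frames, ignore_index=True)
        for scheme in bc.OVR_SCHEMES:
            scores, labels = bc.binarize_ovr(labeled, scheme)
            ovr_auc = bc.auc(scores, labels)
            sign = -1.0 if scheme.direction == BELOW else 1.0
            pairwise = []
            for bp in scheme.positive_set:
                for bq in scheme.negative_set:
                    p = labeled[labeled.behaviour == bp]["count"].to_numpy() * sign
                    q = labeled[labeled.behaviour == bq]["count"].to_numpy() * sign
                    pairwise.append(brute_force_auc(p, q))
            assert ovr_auc == pytest.approx(np.mean(pairwise), abs=1e-12)


class TestAucCi:
    def test_delong_contains_point_auc(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            pos = rng.normal(1.0, 1.0, size=40)
            neg = rng.normal(0.0, 1.0, size=60)
            scores = np.concatenate([pos, neg])
            labels = np.repeat([1, 0], [40, 60])
            lo, hi = bc.auc_ci(scores, labels, method="delong")
            a = bc.auc(scores, labels)
            assert lo <= a <= hi
            assert 0.0 <= lo <= hi <= 1.0

    def test_separable_large_sample_collapses_toward_one(self):
        scores = np.concatenate([np.arange(100, 200), np.arange(0, 100)]).astype(float)
        labels = np.repeat([1, 0], [100, 100])
        lo, hi = bc.auc_ci(scores, labels, method="delong")
        assert lo > 0.99 and hi == 1.0

    def test_bootstrap_reproducible_from_seed(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=80) + np.repeat([1.0, 0.0], [30, 50])
        labels = np.repeat([1, 0], [30, 50])
        a = bc.auc_ci(scores, labels, method="bootstrap", seed=7, n_boot=200)
        b = bc.auc_ci(scores, labels, method="bootstrap", seed=7, n_boot=200)
        assert a == b

    def test_delong_needs_two_per_class(self):
        with pytest.raises(bc.ValidationError):
            bc.auc_ci(np.array([1.0, 2, 3]), np.array([1, 0, 0]), method="delong")


class TestAccuracyBand:
    @pytest.mark.parametrize(
        "value,band",
        [
            (0.95, "outstanding"),
            (0.90, "outstanding"),
            (0.85, "excellent"),
            (0.80, "excellent"),
            (0.75, "acceptable"),
            (0.70, "acceptable"),
            (0.69, "poor"),
            (0.5, "poor"),
        ],
    )
    def test_band_boundaries(self, value, band):
        assert bc.accuracy_band(value) == band

    def test_out_of_range_rejected(self):
        with pytest.raises(bc.ValidationError):
            bc.accuracy_band(1.2)


class TestCalibrateChannel:
    def test_missing_behaviour_listed(self, default_cohort):
        trimmed = default_cohort[default_cohort.behaviour != bc.Behaviour.SPRINTING]
        with pytest.raises(bc.ValidationError, match="sprinting"):
            bc.calibrate_channel(trimmed, bc.Device.MW8, bc.Position.WRIST)

    def test_default_cohort_calibration_structure(self, default_cohort):
        table = bc.calibrate_channel(default_cohort, bc.Device.MW8, bc.Position.WRIST)
        assert set(table.results) == {"VPA", "MVPA", "LMVPA", "MOA"}
        assert table.sed_range == (table.moa_cut, table.lmvpa_cut)
        for name in ("VPA", "MVPA", "LMVPA"):
            assert table.results[name].auc > 0.9
        for r in table.results.values():
            lo, hi = r.auc_ci
            assert lo <= r.auc <= hi
            assert r.youden_j == pytest.approx(r.sensitivity + r.specificity - 1.0)

    def test_nested_schemes_give_monotone_cutoffs(self, default_cohort):
        """On well-separated data the nested positive sets push the
        thresholds downward: vpa > mvpa > lmvpa > moa."""
        for dev, pos in bc.CHANNELS:
            t = bc.calibrate_channel(default_cohort, dev, pos)
            assert t.vpa_cut > t.mvpa_cut > t.lmvpa_cut > t.moa_cut

    def test_moa_cutoff_reported_on_original_scale(self, default_cohort):
        t = bc.calibrate_channel(default_cohort, bc.Device.MW8, bc.Position.WRIST)
        moa = t.results["MOA"]
        # motionless-alert cut must sit in the low-count region, below LMVPA
        assert 0.0 <= moa.cutoff < t.lmvpa_cut


class TestGaussianMixtureAuc:
    def test_equal_means_give_half(self):
        params = [
            bc.ChannelBehaviourParams(bc.Device.MW8, bc.Position.WRIST, b, mean=5.0, sd=2.0)
            for b in bc.Behaviour
        ]
        assert bc.gaussian_mixture_auc(params, bc.VPA) == pytest.approx(0.5)

    def test_zero_variance_equal_means_contribute_half(self):
        params = [
            bc.ChannelBehaviourParams(bc.Device.MW8, bc.Position.WRIST, b, mean=5.0, sd=0.0)
            for b in bc.Behaviour
        ]
        assert bc.gaussian_mixture_auc(params, bc.MVPA) == pytest.approx(0.5)

    def test_reference_channel_values(self):
        """Closed form evaluated on the published wrist-MW8 and hip-GT3X
        moments (hand-checked: mean over pairs of Phi(dmu/sqrt(s1^2+s2^2)))."""
        wrist_mw8 = [
            p for p in bc.reference_params()
            if p.device == bc.Device.MW8 and p.position == bc.Position.WRIST
        ]
        hip_gt3x = [
            p for p in bc.reference_params()
            if p.device == bc.Device.GT3X and p.position == bc.Position.HIP
        ]
        assert bc.gaussian_mixture_auc(wrist_mw8, bc.VPA) == pytest.approx(0.979, abs=5e-4)
        assert bc.gaussian_mixture_auc(hip_gt3x, bc.LMVPA) == pytest.approx(0.957, abs=5e-4)

    def test_monte_carlo_agreement(self, default_cohort):
        """Empirical AUCs from the normal-family cohort agree with the
        closed form within +-0.02 for every channel and scheme."""
        for dev, pos in bc.CHANNELS:
            params = [p for p in bc.reference_params() if p.device == dev and p.position == pos]
            table = bc.calibrate_channel(default_cohort, dev, pos)
            for scheme in bc.OVR_SCHEMES:
                oracle = bc.gaussian_mixture_auc(params, scheme)
                assert table.results[scheme.name].auc == pytest.approx(oracle, abs=0.02)
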