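"""ROC/AUC machinery against independent brute-force oracles."""


import numpy as np
import pytest

from longconn import (
    auc,
    bootstrap_ci,
    classification_metrics,
    covariate_adjusted_p,
    evaluate,
    optimal_threshold,
    roc_curve,
    scalar_marker_eval,
)


def auc_pair_count(scores, labels):
    """Brute-force Mann-Whitney oracle: enumerate all (pos, neg) pairs."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    pos, neg = s[y == 1], s[y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def threshold_scan_oracle(scores, labels):
    """Exhaustive scan of every candidate threshold (all gap midpoints plus
    the observed values); returns (best criterion, best threshold)."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    u = np.unique(s)
    cands = np.unique(np.r_[u, (u[:-1] + u[1:]) / 2.0, u[-1] + 1.0])
    best_crit, best_thr = -1.0, None
    for t in cands:
        pred = s >= t
        sens = (pred & (y == 1)).sum() / (y == 1).sum()
        spec = (~pred & (y == 0)).sum() / (y == 0).sum()
        crit = sens**2 + spec**2
        if crit > best_crit + 1e-12 or (
            abs(crit - best_crit) <= 1e-12 and t < best_thr
        ):
            best_crit, best_thr = crit, t
    return best_crit, best_thr


class TestAuc:
    def test_trivial_cases(self):
        assert auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0
        assert auc([0.5, 0.5, 0.5, 0.5], [0, 0, 1, 1]) == 0.5

    def test_toy_pair_count(self):
        assert auc([0.2, 0.6, 0.4, 0.8], [0, 0, 1, 1]) == 0.75

    def test_pair_count_oracle_100_instances(self, rng):
        """Rank-based AUC equals brute-force pair counting to 1e-12 on 100
        random instances (with ties) up to n = 30."""
        for _ in range(100):
            n = rng.integers(4, 31)
            y = np.zeros(n, int)
            y[: rng.integers(1, n)] = 1
            rng.shuffle(y)
            # discretized scores to generate plenty of ties
            s = np.round(rng.uniform(0, 1, n), rng.integers(1, 3))
            assert abs(auc(s, y) - auc_pair_count(s, y)) < 1e-12

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([0.1, 0.2], [1, 1])


class TestRocCurve:
    def test_endpoints_and_monotonicity(self, rng):
        for _ in range(20):
            n = rng.integers(4, 40)
            y = np.r_[np.zeros(n // 2, int), np.ones(n - n // 2, int)]
            s = np.round(rng.uniform(0, 1, n), 2)
            roc = roc_curve(s, y)
            assert roc.fpr[0] == 0 and roc.tpr[0] == 0
            assert roc.fpr[-1] == 1 and roc.tpr[-1] == 1
            assert (np.diff(roc.fpr) >= 0).all() and (np.diff(roc.tpr) >= 0).all()

    def test_trapezoid_area_equals_pair_count_auc(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 30))
            y = np.zeros(n, int)
            y[: int(rng.integers(1, n))] = 1
            rng.shuffle(y)
            s = np.round(rng.uniform(0, 1, n), 1)
            assert abs(roc_curve(s, y).area() - auc(s, y)) < 1e-12

    def test_single_pos_neg(self):
        roc = roc_curve([0.2, 0.9], [0, 1])
        assert any((f == 0 and t == 1) for f, t in zip(roc.fpr, roc.tpr))


class TestOptimalThreshold:
    def test_perfect_separation_returns_gap_midpoint(self):
        s = np.array([0.1, 0.2, 0.8, 0.9])
        y = np.array([0, 0, 1, 1])
        thr = optimal_threshold(roc_curve(s, y))
        assert thr == pytest.approx(0.5)
        cm = classification_metrics(s, y, thr)
        assert cm.sensitivity == 1.0 and cm.specificity == 1.0

    def test_matches_exhaustive_scan(self, rng):
        s = np.array([0.9, 0.8, 0.4, 0.3, 0.2, 0.6])
        y = np.array([1, 1, 1, 0, 0, 0])
        best_crit, _ = threshold_scan_oracle(s, y)
        thr = optimal_threshold(roc_curve(s, y))
        cm = classification_metrics(s, y, thr)
        assert cm.sensitivity**2 + cm.specificity**2 == pytest.approx(best_crit)

    def test_attains_max_on_random_instances(self, rng):
        for _ in range(50):
            n = int(rng.integers(6, 25))
            y = np.zeros(n, int)
            y[: int(rng.integers(2, n - 1))] = 1
            rng.shuffle(y)
            s = np.round(rng.uniform(0, 1, n), 2)
            best_crit, _ = threshold_scan_oracle(s, y)
            thr = optimal_threshold(roc_curve(s, y))
            cm = classification_metrics(s, y, thr)
            assert cm.sensitivity**2 + cm.specificity**2 == pytest.approx(best_crit)


class TestClassificationMetrics:
    def test_perfect_classifier(self):
        cm = classification_metrics([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1], 0.5)
        assert cm.sensitivity == cm.specificity == 1.0
        assert cm.balanced_accuracy == cm.kappa == 1.0

    def test_fixed_confusion_table_closed_form(self):
        """TP=19 FN=2 TN=23 FP=7: metrics match the hand computation."""
        scores = np.r_[np.full(19, 0.9), np.full(2, 0.1), np.full(23, 0.1), np.full(7, 0.9)]
        labels = np.r_[np.ones(21, int), np.zeros(30, int)]
        cm = classification_metrics(scores, labels, 0.5)
        assert (cm.tp, cm.fn, cm.tn, cm.fp) == (19, 2, 23, 7)
        assert cm.sensitivity == pytest.approx(19 / 21)
        assert cm.specificity == pytest.approx(23 / 30)
        assert cm.balanced_accuracy == pytest.approx((19 / 21 + 23 / 30) / 2)
        p_o = 42 / 51
        p_e = (26 * 21 + 25 * 30) / 51**2
        assert cm.kappa == pytest.approx((p_o - p_e) / (1 - p_e))

    def test_chance_predictions_give_near_zero_kappa(self, rng):
        y = rng.integers(0, 2, 4000)
        s = rng.uniform(0, 1, 4000)
        cm = classification_metrics(s, y, 0.5)
        assert abs(cm.kappa) < 0.05

    def test_out_of_range_threshold_warns(self):
        with pytest.warns(UserWarning, match="outside"):
            classification_metrics([0.1, 0.9], [0, 1], 1.5)


class TestBootstrap:
    def test_perfect_separation_ci_is_degenerate(self):
        s = np.r_[np.linspace(0, 0.3, 10), np.linspace(0.7, 1.0, 10)]
        y = np.r_[np.zeros(10, int), np.ones(10, int)]
        b = bootstrap_ci(s, y, n_reps=200, seed=0)
        assert b.ci_low == b.ci_high == 1.0

    def test_percentiles_consistent_with_replicates(self, rng):
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        s = rng.uniform(0, 1, 40)
        b = bootstrap_ci(s, y, n_reps=300, seed=1)
        lo, hi = np.percentile(b.replicates, [5.0, 95.0])
        assert b.ci_low == pytest.approx(lo)
        assert b.ci_high == pytest.approx(hi)

    def test_interval_shrinks_with_n(self, rng):
        def width(n, seed):
            y = np.r_[np.zeros(n // 2, int), np.ones(n // 2, int)]
            s = np.clip(rng.normal(0.4, 0.15, n) + 0.2 * y, 0, 1)
            b = bootstrap_ci(s, y, n_reps=300, seed=seed)
            return b.ci_high - b.ci_low

        assert width(160, 2) < width(40, 3)

    def test_tiny_classes_warn(self):
        with pytest.warns(UserWarning, match="unstable"):
            bootstrap_ci([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1], n_reps=50, seed=0)


class TestCovariateAdjustedP:
    def test_strong_signal_is_significant(self, rng):
        hits = 0
        for rep in range(20):
            r = np.random.default_rng(rep)
            y = np.r_[np.zeros(30, int), np.ones(21, int)]
            s = np.clip(r.normal(0.3, 0.15, 51) + 0.4 * y, 0, 1)
            age = r.normal(66, 5, 51)
            gender = r.integers(0, 2, 51)
            if covariate_adjusted_p(s, y, age, gender) < 0.05:
                hits += 1
        assert hits >= 18

    def test_constant_score_rejected(self, rng):
        y = np.r_[np.zeros(10, int), np.ones(10, int)]
        with pytest.raises(ValueError, match="constant"):
            covariate_adjusted_p(np.full(20, 0.5), y, rng.normal(66, 5, 20), y)

    def test_separation_falls_back_with_warning(self, rng):
        y = np.r_[np.zeros(15, int), np.ones(15, int)]
        s = y.astype(float)  # perfectly separating score
        with pytest.warns(UserWarning, match="ridge"):
            p = covariate_adjusted_p(s, y, rng.normal(66, 5, 30), rng.integers(0, 2, 30))
        assert 0 <= p <= 1


class TestScalarMarker:
    def test_label_marker_perfect(self, rng):
        y = np.r_[np.zeros(20, int), np.ones(20, int)]
        res = scalar_marker_eval(y.astype(float), y)
        assert res.auc == 1.0

    def test_orientation_autoflip(self, rng):
        y = np.r_[np.zeros(50, int), np.ones(50, int)]
        v = rng.normal(0, 1, 100) - 2.0 * y  # lower = more diseased
        res = scalar_marker_eval(v, y)
        assert res.flipped
        assert res.auc >= 0.5

    def test_random_marker_near_half(self, rng):
        y = np.r_[np.zeros(500, int), np.ones(500, int)]
        res = scalar_marker_eval(rng.normal(size=1000), y)
        assert 0.5 <= res.auc < 0.57  # flipped to >= 0.5 by construction


class TestClinicalMarkerContrast:
    def test_cross_sectional_strong_longitudinal_weak(self, default_cohort):
        """Baseline UPDRS-III separates controls from established patients
        almost perfectly, while its one-year change separates controls from
        the intermediate prodromal group far less well — the reason a
        connectome-based progression marker is needed."""
        from longconn import simulate_clinical

        clin = simulate_clinical(default_cohort.config, default_cohort)
        wide = clin.scale("updrs3")
        man = default_cohort.manifest.set_index("subject_id")
        ids = man.index[man["group"].isin(["CNT", "PD"])]
        y = (man.loc[ids, "group"] == "PD").astype(int).to_numpy()
        cross = scalar_marker_eval(wide.loc[ids, 0.0].to_numpy(), y)
        assert cross.auc > 0.9
        ids2 = man.index[man["group"].isin(["CNT", "PROD"])]
        y2 = (man.loc[ids2, "group"] == "PROD").astype(int).to_numpy()
        diff = (wide[1.0] - wide[0.0]).loc[ids2].to_numpy()
        longi = scalar_marker_eval(diff, y2)
        assert longi.auc < cross.auc


class TestEvaluate:
    def test_report_fields_and_fixed_threshold_variant(self, rng):
        y = np.r_[np.zeros(30, int), np.ones(21, int)]
        s = np.clip(rng.normal(0.35, 0.2, 51) + 0.3 * y, 0, 1)
        rep, roc, boot = evaluate(
            s, y, age=rng.normal(66, 5, 51), gender=rng.integers(0, 2, 51),
            n_boot=200, seed=0,
        )
        assert 0 <= rep.auc <= 1
        assert rep.fixed_threshold_metrics["threshold"] == 0.5
        assert rep.n_pos == 21 and rep.n_neg == 30
        assert rep.adjusted_p is not None
        assert rep.settings["ci"] == "percentile 5th-95th"
        cm = classification_metrics(s, y, rep.chosen_threshold)
        assert rep.sensitivity == cm.sensitivity
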