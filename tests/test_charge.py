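import numpy as np
import pytest
from sklearn.base import clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from etdprep import (ChargeFeatureExtractor, LinearDiscriminantChargeClassifier,
                     Spectrum, assign_charges, cp_feature_windows,
                     extract_features, load_model, mh, neutral_mass,
                     nl_feature_windows, reduced_precursor_series, save_model)
from etdprep.pipeline import predict_assignments

from helpers import bayes_posterior


class TestFeatureWindows:
    def test_cp_window_geometry(self):
        # M = 2000 under a 2+ hypothesis: X = 2 Da at z = 2, tolp/z = 1 Da
        pmz = mh(2000.0, 2)
        w = cp_feature_windows(pmz, 2)[1]
        center = mh(2000.0, 2)
        assert center - w.lo == pytest.approx(1.0)
        assert w.hi - center == pytest.approx(3.0)

    def test_single_charge_single_window(self):
        assert len(cp_feature_windows(500.0, 1)) == 1

    def test_windows_cover_reduced_series(self):
        windows = cp_feature_windows(492.2, 3)
        for (z, m), w in zip(reduced_precursor_series(492.2, 3), windows):
            assert w.contains(m)

    def test_nl_centers_disambiguate_multiples(self):
        # toy arithmetic with H = 1: the 2+ and 4+ hypotheses share the
        # 599 Da precursor bin but their water-loss bins differ (581 vs 590)
        w2 = nl_feature_windows(300.0, 2, proton_mass=1.0)[0]
        assert (w2.lo + w2.hi) / 2 == pytest.approx(581.0)
        w4 = nl_feature_windows(300.0, 4, proton_mass=1.0)[1]
        assert (w4.lo + w4.hi) / 2 == pytest.approx(590.0)
        assert mh(neutral_mass(300.0, 2, 1.0), 1, 1.0) == pytest.approx(599.0)
        assert mh(neutral_mass(300.0, 4, 1.0), 2, 1.0) == pytest.approx(599.0)

    def test_nl_window_spans_water_and_ammonia(self):
        w = nl_feature_windows(800.0, 1)[0]
        c1 = mh(neutral_mass(800.0, 1), 1)
        assert w.contains(c1 - 18.0) and w.contains(c1 - 17.0)
        assert (w.lo, w.hi) == pytest.approx((c1 - 22.0, c1 - 14.0))


class TestExtractFeatures:
    def test_pure_ladder_saturates_true_hypothesis(self):
        series = [m for _, m in reduced_precursor_series(492.2, 3)]
        s = Spectrum(series, [50.0, 30.0, 20.0], precursor_mz=492.2)
        feats = extract_features(s, candidate_charges=(3, 4, 5, 6, 7))
        cp = dict(zip((3, 4, 5, 6, 7), feats[:5]))
        assert cp[3] == pytest.approx(1.0)
        assert cp[4] < 1.0  # the 4+ hypothesis windows miss the 1+/2+ peaks

    def test_empty_feature_region_gives_zeros(self):
        s = Spectrum([200.0, 210.0], [1.0, 1.0], precursor_mz=900.0)
        assert np.all(extract_features(s) == 0.0)

    def test_zero_tic_rejected(self):
        s = Spectrum([200.0], [0.0], precursor_mz=900.0)
        with pytest.raises(ValueError, match="total ion current"):
            extract_features(s)

    def test_features_bounded(self, study):
        X = study["extractor"].transform(study["test_spectra"][:50])
        assert np.all(X >= 0.0) and np.all(X <= 1.0)

    def test_extractor_is_cloneable(self):
        ext = ChargeFeatureExtractor(candidate_charges=(2, 3), include_nl=False)
        assert clone(ext).get_params() == ext.get_params()
        with pytest.raises(ValueError):
            ChargeFeatureExtractor(candidate_charges=(4, 3)).fit([])


class TestLdaClassifier:
    @pytest.fixture
    def two_class_fixture(self):
        # exactly symmetric clouds around (0,0) and (10,10) so the fitted
        # class means are the nominal ones
        offsets = np.array([[0.5, 0.0], [-0.5, 0.0], [0.0, 0.5], [0.0, -0.5]])
        X = np.vstack([offsets, offsets + 10.0])
        y = np.array([0] * 4 + [1] * 4)
        return X, y

    def test_separated_classes(self, two_class_fixture):
        X, y = two_class_fixture
        clf = LinearDiscriminantChargeClassifier().fit(X, y)
        mid = clf.predict_proba([[5.0, 5.0]])[0]
        assert mid == pytest.approx([0.5, 0.5], abs=1e-9)
        extreme = clf.predict_proba([[-2.0, -2.0]])[0]
        assert extreme[0] > 0.999

    def test_posterior_matches_gaussian_bayes_oracle(self, rng):
        X = np.vstack([rng.normal(0.0, 1.0, (10, 3)),
                       rng.normal(2.0, 1.0, (10, 3))])
        y = np.array([0] * 10 + [1] * 10)
        clf = LinearDiscriminantChargeClassifier().fit(X, y)
        for x in rng.normal(1.0, 2.0, (5, 3)):
            expected = bayes_posterior(x, clf.means_, clf.covariance_,
                                       clf.priors_)
            assert clf.predict_proba([x])[0] == pytest.approx(expected,
                                                              abs=1e-9)

    def test_matches_sklearn_lda(self, study):
        X = study["extractor"].transform(study["train_spectra"])
        y = study["train_charges"]
        ours = study["classifier"]
        ref = LinearDiscriminantAnalysis(solver="svd").fit(X, y)
        Xt = study["extractor"].transform(study["test_spectra"][:100])
        assert np.allclose(ours.predict_proba(Xt), ref.predict_proba(Xt),
                           atol=1e-3)
        assert (ours.predict(Xt) == ref.predict(Xt)).mean() >= 0.99

    def test_posteriors_normalised_and_argmax_consistent(self, two_class_fixture):
        X, y = two_class_fixture
        clf = LinearDiscriminantChargeClassifier().fit(X, y)
        P = clf.predict_proba(X)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-9)
        assert np.array_equal(P.argmax(axis=1),
                              clf.decision_function(X).argmax(axis=1))

    def test_shift_invariance_of_softmax(self, two_class_fixture):
        X, y = two_class_fixture
        clf = LinearDiscriminantChargeClassifier().fit(X, y)
        d = clf.decision_function(X[:5])
        def softmax(a):
            e = np.exp(a - a.max(axis=1, keepdims=True))
            return e / e.sum(axis=1, keepdims=True)
        assert np.allclose(softmax(d), softmax(d + 123.4), atol=1e-12)

    def test_equidistant_point_uniform_posterior(self):
        X = np.array([[0.0, 0.0], [0.1, 0.0], [4.0, 0.0], [3.9, 0.0]])
        y = np.array([0, 0, 1, 1])
        clf = LinearDiscriminantChargeClassifier(priors=[0.5, 0.5]).fit(X, y)
        p = clf.predict_proba([[2.0, 0.0]])[0]
        assert p == pytest.approx([0.5, 0.5], abs=1e-9)

    def test_fit_validation(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            LinearDiscriminantChargeClassifier().fit(
                np.zeros((3, 2)) + np.arange(3)[:, None], [0, 0, 1])
        with pytest.raises(ValueError, match="at least 2"):
            LinearDiscriminantChargeClassifier().fit(np.ones((4, 2)),
                                                     [1, 1, 1, 1])
        clf = LinearDiscriminantChargeClassifier().fit(
            np.array([[0.0, 0], [0.1, 0], [1, 0], [1.1, 0]]), [0, 0, 1, 1])
        with pytest.raises(ValueError, match="features"):
            clf.predict_proba([[1.0, 2.0, 3.0]])


class TestAssignCharges:
    CLASSES = (3, 4, 5, 6, 7)

    def test_confident_spectrum_gets_single_charge(self):
        a = assign_charges([0.995, 0.004, 0.0005, 0.0004, 0.0001],
                           self.CLASSES, "all")
        assert a.assigned == (3,)

    def test_intermediate_confidence_gets_top_two(self):
        a = assign_charges([0.95, 0.04, 0.005, 0.004, 0.001],
                           self.CLASSES, "all")
        assert a.assigned == (3, 4)

    def test_low_confidence_gets_full_range(self):
        a = assign_charges([0.5, 0.3, 0.1, 0.06, 0.04], self.CLASSES, "all")
        assert a.assigned == (3, 4, 5, 6, 7)

    def test_top1_always_single(self):
        a = assign_charges([0.3, 0.25, 0.2, 0.15, 0.1], self.CLASSES, "top1")
        assert a.assigned == (3,)

    def test_threshold_boundaries(self):
        # at exactly t1 the two-tier strategy keeps one charge, but the
        # three-tier strategy (strict "greater than t1") emits two
        p = [0.99, 0.005, 0.003, 0.001, 0.001]
        assert assign_charges(p, self.CLASSES, "top2").assigned == (3,)
        assert assign_charges(p, self.CLASSES, "all").assigned == (3, 4)
        p2 = [0.9, 0.05, 0.03, 0.01, 0.01]
        assert assign_charges(p2, self.CLASSES, "all").assigned == (3, 4)

    def test_posterior_tie_prefers_lower_charge(self):
        a = assign_charges([0.48, 0.48, 0.02, 0.01, 0.01],
                           self.CLASSES, "top1")
        assert a.assigned == (3,)

    def test_invalid_thresholds(self):
        with pytest.raises(ValueError, match="t1"):
            assign_charges([1.0, 0.0], (3, 4), "all", t1=0.5, t2=0.9)

    def test_nested_candidate_sets(self, study):
        # the three strategies produce nested sets, so their error rates
        # are monotone: top1 >= top1/top2 >= 1/2/all
        X = study["extractor"].transform(study["test_spectra"][:200])
        P = study["classifier"].predict_proba(X)
        for p in P:
            sets = {s: set(assign_charges(p, study["classifier"].classes_,
                                          s).assigned)
                    for s in ("top1", "top2", "all")}
            assert sets["top1"] <= sets["top2"] <= sets["all"]


class TestModelPersistence:
    def test_round_trip(self, study, tmp_path):
        path = tmp_path / "model.yaml"
        save_model(path, study["classifier"], study["extractor"])
        clf, ext = load_model(path)
        spectra = study["test_spectra"][:20]
        X0 = study["extractor"].transform(spectra)
        X1 = ext.transform(spectra)
        assert np.allclose(X0, X1)
        assert np.allclose(study["classifier"].predict_proba(X0),
                           clf.predict_proba(X1), atol=1e-9)
        assert ext.candidate_charges == study["extractor"].candidate_charges


class TestParameterRecovery:
    def test_held_out_misclassification(self, study):
        assignments = predict_assignments(
            study["test_spectra"][:400], study["classifier"],
            study["extractor"], strategy="all")
        missed = sum(1 for a, t in zip(assignments, study["test_charges"])
                     if int(t) not in a.assigned)
        assert missed / len(assignments) <= 0.05
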