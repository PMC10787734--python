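"""Random-forest identification, post-hoc test and evaluation protocols."""

import warnings

import numpy as np
import pandas as pd
import pytest

from masstaxa.classify import (FingerprintClassifier, align_peaklists,
                               cluster_bootstrap, congeneric_affinity,
                               gini_top_peaks, highertax_fallback, identify,
                               loo_species_identification, train_rf)
from masstaxa.peaks import FeatureMatrix
from masstaxa.spectra import PeakList


def blobs(rng, n_per=10, n_feat=12, sep=6.0, n_classes=2):
    """Well-separated Gaussian classes in feature space."""
    X, y = [], []
    for c in range(n_classes):
        centre = np.zeros(n_feat)
        centre[c::n_classes] = sep
        X.append(rng.normal(centre, 1.0, (n_per, n_feat)))
        y += [f"class{c}"] * n_per
    return np.abs(np.vstack(X)), np.array(y)


class TestFingerprintClassifier:
    def test_separable_classes_reach_low_oob(self):
        errs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X, y = blobs(rng)
            clf = FingerprintClassifier(ntree=200, mtry=4, random_state=seed)
            clf.fit(X, y)
            errs.append(clf.oob_error_)
        assert np.mean(errs) <= 0.02

    def test_permuted_labels_sit_at_chance(self):
        errs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X, _ = blobs(rng, n_per=25)
            y = np.array(["a", "b"] * 25)
            rng.shuffle(y)
            clf = FingerprintClassifier(ntree=300, mtry=4, random_state=seed)
            clf.fit(X, y)
            errs.append(clf.oob_error_)
        assert 0.4 <= np.mean(errs) <= 0.6

    def test_same_seed_reproduces_oob(self, rng):
        X, y = blobs(rng)
        a = FingerprintClassifier(ntree=100, mtry=3, random_state=5).fit(X, y)
        b = FingerprintClassifier(ntree=100, mtry=3, random_state=5).fit(X, y)
        assert a.oob_error_ == b.oob_error_

    def test_oob_error_matches_recount_from_stored_votes(self, rng):
        X, y = blobs(rng, n_per=15)
        clf = FingerprintClassifier(ntree=300, mtry=4, random_state=0).fit(X, y)
        oob = clf.forest_.oob_decision_function_
        covered = oob.sum(axis=1) > 0
        pred = clf.classes_[np.argmax(oob, axis=1)]
        recount = np.mean(pred[covered] != y[covered])
        assert clf.oob_error_ == pytest.approx(recount)

    def test_every_class_has_stored_probabilities(self, rng):
        X, y = blobs(rng, n_classes=3, n_feat=15)
        clf = FingerprintClassifier(ntree=200, mtry=4, random_state=0).fit(X, y)
        assert set(clf.oob_prob_by_class_) == set(clf.classes_)
        assert all(len(v) >= 1 for v in clf.oob_prob_by_class_.values())

    def test_single_row_class_rejected_by_name(self, rng):
        X, y = blobs(rng)
        y = y.copy()
        y[0] = "lonely"
        with pytest.raises(ValueError, match="lonely"):
            FingerprintClassifier(ntree=50).fit(X, y)

    def test_one_class_rejected(self, rng):
        X, _ = blobs(rng)
        with pytest.raises(ValueError, match="two classes"):
            FingerprintClassifier(ntree=50).fit(X, ["a"] * len(X))

    def test_mtry_clamped_with_warning(self, rng):
        X, y = blobs(rng, n_feat=9)
        with pytest.warns(RuntimeWarning, match="mtry"):
            clf = FingerprintClassifier(ntree=50, mtry=35,
                                        random_state=0).fit(X, y)
        assert clf.mtry_ == 3  # floor(sqrt(9))


class _StubForest:
    """Deterministic vote fractions, for post-hoc arithmetic tests."""

    def __init__(self, proba, classes):
        self._proba = np.asarray(proba, dtype=float)
        self.classes_ = np.asarray(classes)

    def predict_proba(self, X):
        return self._proba[: len(X)]


def stub_model(stored, proba, classes=("A", "B")):
    clf = FingerprintClassifier(alpha=0.05)
    clf.forest_ = _StubForest(proba, classes)
    clf.classes_ = np.asarray(classes)
    clf.oob_prob_by_class_ = {c: np.asarray(v) for c, v in stored.items()}
    clf.oob_error_ = 0.0
    return clf


class TestPosthoc:
    def test_left_tail_proportion_hand_example(self):
        m = stub_model({"A": [0.4, 0.6, 0.8, 1.0], "B": [1.0]},
                       [[0.6, 0.4]])
        ident = m.identify([[0]])[0]
        assert ident.predicted == "A"
        assert ident.posthoc_p == pytest.approx(0.5)  # 2 of 4 <= 0.6
        assert ident.accepted

    def test_prob_at_or_above_max_accepts(self):
        m = stub_model({"A": [0.4, 0.6], "B": [1.0]}, [[0.9, 0.1]])
        ident = m.identify([[0]])[0]
        assert ident.posthoc_p == 1.0 and ident.accepted

    def test_prob_below_min_rejects(self):
        m = stub_model({"A": [0.8, 0.9], "B": [1.0]}, [[0.5, 0.5]])
        ident = m.identify([[0]])[0]
        assert ident.posthoc_p == 0.0 and not ident.accepted

    def test_tied_votes_resolve_lexicographically(self):
        m = stub_model({"A": [0.5], "B": [0.5]}, [[0.5, 0.5]])
        assert m.identify([[0]])[0].predicted == "A"

    def test_posthoc_p_monotone_in_prob(self):
        m = stub_model({"A": [0.2, 0.5, 0.7, 0.9], "B": [1.0]}, [[1.0, 0.0]])
        ps = [m.posthoc_p("A", p) for p in np.linspace(0, 1, 21)]
        assert all(a <= b for a, b in zip(ps, ps[1:]))

    def test_accept_flag_consistent_with_alpha(self):
        m = stub_model({"A": [0.2, 0.5, 0.7, 0.9], "B": [1.0]}, [[1.0, 0.0]])
        for prob in (0.1, 0.3, 0.6, 0.95):
            pp = m.posthoc_p("A", prob)
            ident = stub_model({"A": [0.2, 0.5, 0.7, 0.9], "B": [1.0]},
                               [[prob, 0.0]]).identify([[0]])[0]
            assert ident.accepted == (pp > 0.05)


class TestAlignment:
    def feats(self):
        return np.array([1000.0, 1500.0, 2000.0])

    def test_peaks_assigned_to_anchored_bins(self):
        q = [PeakList(masses=[1000.4, 1999.0], intensities=[2.0, 3.0],
                      snr_values=[5, 5])]
        X = align_peaklists(q, self.feats(), 0.002)
        np.testing.assert_allclose(X, [[2.0, 0.0, 3.0]])

    def test_unmatched_peaks_dropped_with_warning(self):
        q = [PeakList(masses=[1000.0, 1250.0], intensities=[1.0, 9.0],
                      snr_values=[5, 5])]
        with pytest.warns(RuntimeWarning, match="matched no feature"):
            X = align_peaklists(q, self.feats(), 0.002)
        np.testing.assert_allclose(X, [[1.0, 0.0, 0.0]])

    def test_no_overlap_is_an_error(self):
        q = [PeakList(masses=[5000.0], intensities=[1.0], snr_values=[5])]
        with pytest.raises(ValueError, match="overlap"):
            align_peaklists(q, self.feats(), 0.002)

    def test_identify_on_training_rows_returns_own_class(self,
                                                         small_library_matrix):
        model = train_rf(small_library_matrix, "species", ntree=200, mtry=35,
                         seed=0)
        ids = identify(model, small_library_matrix)
        truth = small_library_matrix.meta["species"]
        assert all(i.predicted == truth.loc[i.query_id] for i in ids)


class TestLOO:
    def test_summary_structure_and_nesting(self, small_library_matrix):
        table, summary = loo_species_identification(
            small_library_matrix, ntree=150, seed=0)
        o = summary["overall"]
        assert 0 <= o["accepted_correct"] <= o["correct"] <= 1
        assert len(table) == small_library_matrix.meta["specimen_id"].nunique()
        assert o["correct"] >= 0.95  # separable synthetic library

    def test_min_specimens_enforced_and_reported(self, small_library_matrix):
        with pytest.raises(ValueError, match="min_specimens"):
            loo_species_identification(small_library_matrix, ntree=50,
                                       min_specimens=10)
        sp = small_library_matrix.meta["species"].unique()[0]
        keep = (small_library_matrix.meta["species"] != sp) | \
            small_library_matrix.meta["specimen_id"].isin(
                small_library_matrix.meta.loc[
                    small_library_matrix.meta["species"] == sp,
                    "specimen_id"].unique()[:3])
        sub = small_library_matrix.select_rows(keep.to_numpy())
        table, summary = loo_species_identification(
            sub, ntree=150, min_specimens=6, filter_low=True, seed=0)
        assert summary["excluded_species"] == [sp]
        assert sp not in set(table["true_species"])


class TestFallback:
    def test_sole_member_species_skipped_with_warning(self,
                                                      small_library_matrix):
        # the two classes have two species each; shrink one class to one
        # species so that removing it would empty the class
        meta = small_library_matrix.meta
        cls = meta["class_"].unique()[0]
        sp_in_cls = meta.loc[meta["class_"] == cls, "species"].unique()
        keep = ~meta["species"].isin(sp_in_cls[1:])
        sub = small_library_matrix.select_rows(keep.to_numpy())
        with pytest.warns(RuntimeWarning, match="sole member"):
            table, summary = highertax_fallback(sub, "class", ntree=150, seed=0)
        assert sp_in_cls[0] not in set(table["species"])

    def test_tp_fraction_never_exceeds_correct(self, hierarchy_matrix):
        table, summary = highertax_fallback(hierarchy_matrix, "phylum",
                                            ntree=150, seed=0)
        assert (summary["tp"] <= summary["correct"] + 1e-12).all()

    def test_two_categories_required(self, small_library_matrix):
        with pytest.raises(ValueError, match="categories"):
            highertax_fallback(small_library_matrix, "phylum", ntree=50)


class TestCongeneric:
    def test_requires_multi_species_genus(self, small_library_matrix):
        with pytest.raises(ValueError, match="genus"):
            congeneric_affinity(small_library_matrix, ntree=50)

    def test_single_species_genera_excluded(self, hierarchy_matrix):
        overall, table = congeneric_affinity(hierarchy_matrix, ntree=150,
                                             seed=0)
        assert 0.0 <= overall <= 1.0
        counts = hierarchy_matrix.meta.groupby("genus")["species"].nunique()
        assert set(table["genus"]) <= set(counts[counts >= 2].index)


class TestGini:
    def test_importances_sorted_and_k_clamped(self, rng):
        X, y = blobs(rng, n_feat=8)
        m = _matrix_from_arrays(X, y)
        model = train_rf(m, "species", ntree=150, mtry=3, seed=0)
        with pytest.warns(RuntimeWarning, match="clamped"):
            out = gini_top_peaks(model, m, k=30)
        assert len(out) == 8
        assert np.all(np.diff(out["importance"]) <= 1e-15)

    def test_constant_feature_has_negligible_importance(self):
        errs = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X, y = blobs(rng, n_feat=10)
            X[:, 4] = 2.5  # constant in the matrix the forest sees
            m = _matrix_from_arrays(X, y)
            model = train_rf(m, "species", ntree=200, mtry=3, seed=seed,
                             apply_hellinger=False)
            imp = model.forest_.feature_importances_
            errs.append(imp[4] / imp.sum())
        assert max(errs) <= 1e-6

    def test_single_discriminating_feature_ranked_first(self, rng):
        X = np.abs(rng.normal(1.0, 0.05, (30, 6)))
        y = np.array(["a"] * 15 + ["b"] * 15)
        X[15:, 2] += 3.0  # only feature 2 separates
        m = _matrix_from_arrays(X, y)
        model = train_rf(m, "species", ntree=200, mtry=2, seed=0,
                         apply_hellinger=False)
        out = gini_top_peaks(model, m, k=3)
        assert out.loc[0, "feature_mass"] == m.feature_masses[2]
        assert {f"mean_a", f"mean_b"} <= set(out.columns)


def _matrix_from_arrays(X, y):
    cols = 1000.0 + 100.0 * np.arange(X.shape[1])
    idx = [f"s{i}" for i in range(len(X))]
    intens = pd.DataFrame(np.abs(X), columns=cols, index=idx)
    meta = pd.DataFrame({"specimen_id": idx, "replicate_id": "",
                         "species": y, "genus": [f"g_{v}" for v in y],
                         "class_": "c", "phylum": "p", "sex": ""}, index=idx)
    return FeatureMatrix(intens, meta)


class TestClusterBootstrap:
    def two_groups(self, rng):
        # groups differ in composition (which peaks carry the signal),
        # not in overall scale — scale is removed by the Hellinger rows
        a = np.abs(rng.normal(1, 0.02, (5, 10)))
        b = np.abs(rng.normal(1, 0.02, (5, 10)))
        b[:, :5] += 4.0
        y = np.array(["a"] * 5 + ["b"] * 5)
        return _matrix_from_arrays(np.vstack([a, b]), y)

    def test_clear_groups_get_full_support(self, rng):
        m = self.two_groups(rng)
        tree, supports, newick = cluster_bootstrap(m, B=50, seed=0)
        group_a = frozenset(range(5))
        group_b = frozenset(range(5, 10))
        assert supports.get(group_a, 0) == 100.0
        assert supports.get(group_b, 0) == 100.0

    def test_leaf_count_and_determinism(self, rng):
        m = self.two_groups(rng)
        t1, s1, n1 = cluster_bootstrap(m, B=25, seed=3)
        t2, s2, n2 = cluster_bootstrap(m, B=25, seed=3)
        assert len(list(t1.tips())) == len(m)
        assert s1 == s2 and n1 == n2

    def test_newick_parses_back(self, rng):
        from skbio import TreeNode
        import io
        m = self.two_groups(rng)
        _, _, newick = cluster_bootstrap(m, B=10, seed=0)
        tree = TreeNode.read(io.StringIO(newick))
        assert len(list(tree.tips())) == len(m)

    def test_invalid_b_rejected(self, rng):
        with pytest.raises(ValueError):
            cluster_bootstrap(self.two_groups(rng), B=0)
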