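"""Random-forest identification with an empirical post-hoc acceptance test.

A random forest is trained on Hellinger-transformed binned peak
intensities with class labels at a chosen taxonomic level. Besides the
out-of-bag (OOB) error, the fitted model stores, for every class, the
empirical distribution of OOB assignment probabilities of that class's
own training specimens — the fraction of OOB trees voting the true
class. A query is identified by majority vote; its assignment
probability (vote fraction) is then compared with the predicted class's
stored OOB distribution: the post-hoc statistic is the left-tail
proportion of stored probabilities <= the query's probability, and the
identification is accepted when that proportion exceeds ``alpha``
(default 0.05). Queries with untypically low assignment probabilities —
e.g. specimens of species absent from the reference library — are
thereby flagged as probable false positives.

Evaluation utilities implement leave-one-specimen-out species
identification, higher-taxon (class/phylum) fallback with full removal
of the target species from training, congeneric-affinity analysis, Gini
importance ranking of discriminating peaks, and feature-bootstrap
support for hierarchical clustering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage as scipy_linkage, to_tree
from scipy.spatial.distance import pdist
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.utils.validation import check_is_fitted

from .peaks import FeatureMatrix, hellinger
from .spectra import PeakList

__all__ = [
    "FingerprintClassifier",
    "Identification",
    "train_rf",
    "identify",
    "align_peaklists",
    "loo_species_identification",
    "highertax_fallback",
    "congeneric_affinity",
    "gini_top_peaks",
    "cluster_bootstrap",
]


@dataclass
class Identification:
    """Result of identifying one query row."""

    query_id: str
    predicted: str
    prob: float
    posthoc_p: float
    accepted: bool


class FingerprintClassifier(ClassifierMixin, BaseEstimator):
    """Random-forest species identifier with a post-hoc acceptance test.

    Parameters
    ----------
    ntree, mtry
        Forest size and the number of features tried per split. ``mtry``
        larger than the number of features is clamped to
        ``floor(sqrt(n_features))`` with a warning.
    alpha
        Left-tail threshold of the post-hoc test: an identification is
        accepted iff the fraction of the predicted class's stored OOB
        assignment probabilities <= the query's vote fraction exceeds
        ``alpha``.
    random_state
        Seed of the forest; a fixed seed gives a reproducible model,
        OOB error and stored distributions.

    Fitted attributes
    -----------------
    forest_ : the trained ``RandomForestClassifier``
    classes_ : class labels (lexicographically sorted)
    oob_error_ : out-of-bag misclassification rate
    oob_prob_by_class_ : dict class -> array of OOB assignment
        probabilities of the class's own training rows
    feature_masses_ : feature masses, when fitted from a FeatureMatrix
    """

    def __init__(self, ntree: int = 2000, mtry: int = 35,
                 alpha: float = 0.05, random_state: int | None = None):
        self.ntree = ntree
        self.mtry = mtry
        self.alpha = alpha
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        labels, counts = np.unique(y, return_counts=True)
        if len(labels) < 2:
            raise ValueError("need at least two classes")
        lonely = labels[counts < 2]
        if len(lonely):
            raise ValueError(
                "class(es) with a single training row: " + ", ".join(map(str, lonely)))
        mtry = self.mtry
        if mtry > X.shape[1]:
            mtry = max(1, int(np.sqrt(X.shape[1])))
            warnings.warn(
                f"mtry={self.mtry} exceeds n_features={X.shape[1]}; "
                f"clamped to floor(sqrt(n_features))={mtry}", RuntimeWarning,
                stacklevel=2)
        self.mtry_ = mtry
        rf = RandomForestClassifier(
            n_estimators=self.ntree, max_features=mtry, oob_score=True,
            bootstrap=True, random_state=self.random_state, n_jobs=1)
        with warnings.catch_warnings():
            # sklearn warns if a row was never OOB; handled explicitly below
            warnings.filterwarnings(
                "ignore", message="Some inputs do not have OOB scores")
            rf.fit(X, y)
        self.forest_ = rf
        self.classes_ = rf.classes_
        oob = rf.oob_decision_function_
        covered = oob.sum(axis=1) > 0
        if not covered.all():
            warnings.warn(
                f"{(~covered).sum()} row(s) were never out of bag; excluded "
                "from the OOB error and the stored distributions",
                RuntimeWarning, stacklevel=2)
        class_index = {c: j for j, c in enumerate(self.classes_)}
        true_idx = np.array([class_index[c] for c in y])
        pred = np.argmax(oob, axis=1)
        self.oob_error_ = float(np.mean(pred[covered] != true_idx[covered]))
        self.oob_prob_by_class_ = {
            c: oob[covered & (y == c), class_index[c]] for c in self.classes_}
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "forest_")
        return self.forest_.predict_proba(np.asarray(X, dtype=float))

    def predict(self, X):
        # argmax of vote fractions; sklearn breaks exact ties by class
        # order, i.e. lexicographically — the documented tie rule
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]

    def posthoc_p(self, predicted: str, prob: float) -> float:
        """Left-tail proportion of the class's stored OOB probabilities <= prob."""
        stored = self.oob_prob_by_class_[predicted]
        return float(np.mean(stored <= prob + 1e-12))

    def identify(self, X, query_ids=None, alpha: float | None = None
                 ) -> list[Identification]:
        """Identify query rows and apply the post-hoc acceptance test."""
        alpha = self.alpha if alpha is None else alpha
        proba = self.predict_proba(X)
        if query_ids is None:
            query_ids = [f"query{i}" for i in range(len(proba))]
        out = []
        for qid, p in zip(query_ids, proba):
            j = int(np.argmax(p))
            predicted = self.classes_[j]
            prob = float(p[j])
            pp = self.posthoc_p(predicted, prob)
            out.append(Identification(
                query_id=str(qid), predicted=str(predicted), prob=prob,
                posthoc_p=pp, accepted=pp > alpha))
        return out


# ---------------------------------------------------------------------------
# matrix-level API


def train_rf(matrix: FeatureMatrix, label_level: str = "species", *,
             ntree: int = 2000, mtry: int = 35, seed: int | None = None,
             alpha: float = 0.05, apply_hellinger: bool = True,
             labels=None) -> FingerprintClassifier:
    """Fit a :class:`FingerprintClassifier` on a feature matrix.

    The matrix is expected on the TIC scale; by default rows are
    Hellinger-transformed before training (set ``apply_hellinger=False``
    if the matrix is already transformed). ``labels`` overrides the
    taxon column for custom groupings (e.g. sex).
    """
    mat = hellinger(matrix) if apply_hellinger else matrix
    y = np.asarray(labels) if labels is not None else mat.labels(label_level)
    clf = FingerprintClassifier(ntree=ntree, mtry=mtry, alpha=alpha,
                                random_state=seed)
    clf.fit(mat.values, y)
    clf.feature_masses_ = matrix.feature_masses
    clf.apply_hellinger_ = apply_hellinger
    return clf


def align_peaklists(peaklists: list[PeakList], feature_masses: np.ndarray,
                    tolerance: float = 0.002) -> np.ndarray:
    """Map query peak lists onto a model's feature masses.

    The model's feature masses act as anchor peaks and the query peaks
    are re-binned against them with the strict binning rule (every
    member within ``tolerance`` of the group mean, one peak per source,
    groups split at their largest internal gap). A query peak is
    assigned to the feature anchoring its bin; this resolves ties
    between adjacent features the way training-time binning would,
    instead of by raw nearest distance. Query peaks landing in a bin
    without an anchor are dropped with a warning; absent features stay
    0. Returns a (n_queries, n_features) intensity array. Raises if no
    query peak matches any feature.
    """
    from .peaks import _assign_bins

    feature_masses = np.asarray(feature_masses, dtype=float)
    nf = len(feature_masses)
    X = np.zeros((len(peaklists), nf))
    masses = np.concatenate([feature_masses] + [p.masses for p in peaklists])
    sources = np.concatenate(
        [np.zeros(nf, dtype=int)]
        + [np.full(len(p), i + 1) for i, p in enumerate(peaklists)])
    anchor_idx = np.concatenate(
        [np.arange(nf)] + [np.full(len(p), -1) for p in peaklists])
    intens = np.concatenate(
        [np.zeros(nf)] + [p.intensities for p in peaklists])
    order = np.argsort(masses, kind="stable")
    bin_ids = _assign_bins(masses[order], sources[order], tolerance)
    total = sum(len(p) for p in peaklists)
    dropped = 0
    nbins = bin_ids.max() + 1
    # per bin: which feature anchors it (if any)
    anchors = np.full(nbins, -1, dtype=int)
    srt_anchor = anchor_idx[order]
    for pos in np.flatnonzero(srt_anchor >= 0):
        anchors[bin_ids[pos]] = srt_anchor[pos]
    srt_src, srt_int = sources[order], intens[order]
    for pos in np.flatnonzero(srt_src > 0):
        feat = anchors[bin_ids[pos]]
        if feat < 0:
            dropped += 1
            continue
        i = srt_src[pos] - 1
        X[i, feat] = max(X[i, feat], srt_int[pos])
    if total and dropped == total:
        raise ValueError("no query peak overlaps the model's feature masses")
    if dropped:
        warnings.warn(f"{dropped}/{total} query peak(s) matched no feature "
                      "and were dropped", RuntimeWarning, stacklevel=2)
    return X


def identify(model: FingerprintClassifier, queries, query_ids=None,
             alpha: float | None = None, tolerance: float = 0.002
             ) -> list[Identification]:
    """Identify queries given as an array, FeatureMatrix or peak lists.

    FeatureMatrix/peak-list queries are aligned to the model's feature
    masses (absent features 0, unmatched query features dropped with a
    warning) and Hellinger-transformed if the model was trained that way.
    """
    if isinstance(queries, FeatureMatrix):
        fm = model.feature_masses_
        qm = queries.feature_masses
        nearest = np.argmin(np.abs(fm[None, :] - qm[:, None]), axis=1)
        matched = np.abs(fm[nearest] - qm) <= tolerance * fm[nearest]
        if not matched.any():
            raise ValueError("no query feature overlaps the model's feature masses")
        vals = queries.values
        if (~matched).any() and np.any(vals[:, ~matched] > 0):
            warnings.warn(
                f"{(~matched).sum()} query feature(s) match no model feature "
                "and were dropped", RuntimeWarning, stacklevel=2)
        q = np.zeros((vals.shape[0], len(fm)))
        for j_q in np.flatnonzero(matched):
            j_m = nearest[j_q]
            q[:, j_m] = np.maximum(q[:, j_m], vals[:, j_q])
        if query_ids is None:
            query_ids = list(queries.intensities.index)
    elif queries and isinstance(queries[0], PeakList):
        q = align_peaklists(queries, model.feature_masses_, tolerance)
        if query_ids is None:
            query_ids = [p.specimen_id for p in queries]
    else:
        q = np.asarray(queries, dtype=float)
    if getattr(model, "apply_hellinger_", False):
        sums = q.sum(axis=1, keepdims=True)
        if np.any(sums <= 0):
            raise ValueError("query row with no matched intensity")
        q = np.sqrt(q / sums)
    return model.identify(q, query_ids=query_ids, alpha=alpha)


# ---------------------------------------------------------------------------
# evaluation


def _specimen_groups(matrix: FeatureMatrix) -> pd.Series:
    return matrix.meta["specimen_id"]


def _filter_min_specimens(matrix: FeatureMatrix, min_specimens: int,
                          filter_low: bool):
    """Drop (or reject) species with fewer specimens than ``min_specimens``."""
    counts = (matrix.meta.groupby("species")["specimen_id"].nunique())
    low = counts[counts < min_specimens].index.tolist()
    if low and not filter_low:
        raise ValueError(
            f"species below min_specimens={min_specimens}: "
            + ", ".join(low) + " (set filter_low=True to drop them)")
    if low:
        keep = ~matrix.meta["species"].isin(low)
        matrix = matrix.select_rows(keep.to_numpy())
    return matrix, low


def loo_species_identification(matrix: FeatureMatrix, *, ntree: int = 2000,
                               mtry: int = 35, alpha: float = 0.05,
                               min_specimens: int = 6, filter_low: bool = False,
                               seed: int | None = 0):
    """Leave-one-specimen-out species identification.

    For every specimen, the model is retrained without any of that
    specimen's rows (all technical replicates removed) and the specimen
    identified with the post-hoc test. Returns ``(identifications,
    summary)`` where summary holds the overall fraction of correct and
    of correct-and-accepted identifications plus per-class and
    per-phylum breakdowns and the list of excluded species.
    """
    matrix, excluded = _filter_min_specimens(matrix, min_specimens, filter_low)
    specs = _specimen_groups(matrix)
    results = []
    for k, sid in enumerate(specs.unique()):
        held = (specs == sid).to_numpy()
        train = matrix.select_rows(~held)
        sub_seed = None if seed is None else (seed + k) % (2**31)
        model = train_rf(train, "species", ntree=ntree, mtry=mtry,
                         seed=sub_seed, alpha=alpha)
        query = matrix.select_rows(held)
        ids = identify(model, query, query_ids=[sid] * held.sum(), alpha=alpha)
        truth = matrix.meta.loc[held, "species"].iloc[0]
        # per-specimen verdict: majority over replicate rows (one row
        # under the default replicate-mean policy)
        preds = [i.predicted for i in ids]
        pred = max(sorted(set(preds)), key=preds.count)
        accepted = any(i.accepted and i.predicted == pred for i in ids)
        results.append({
            "specimen_id": sid, "true_species": truth, "predicted": pred,
            "prob": float(np.mean([i.prob for i in ids])),
            "posthoc_p": float(np.mean([i.posthoc_p for i in ids])),
            "correct": pred == truth, "accepted": accepted,
            "class_": matrix.meta.loc[held, "class_"].iloc[0],
            "phylum": matrix.meta.loc[held, "phylum"].iloc[0]})
    table = pd.DataFrame(results)
    table["accepted_correct"] = table["correct"] & table["accepted"]

    def frac(df):
        return pd.Series({"n": len(df),
                          "correct": df["correct"].mean(),
                          "accepted_correct": df["accepted_correct"].mean()})

    summary = {
        "overall": frac(table),
        "by_class": table.groupby("class_").apply(frac, include_groups=False),
        "by_phylum": table.groupby("phylum").apply(frac, include_groups=False),
        "excluded_species": excluded,
    }
    return table, summary


def highertax_fallback(matrix: FeatureMatrix, level: str = "class", *,
                       ntree: int = 2000, mtry: int = 35, alpha: float = 0.05,
                       seed: int | None = 0):
    """Higher-taxon classification of species absent from the library.

    Species are removed from training one at a time; a model trained at
    ``level`` (class or phylum) on the remaining spectra classifies the
    removed specimens. Reports per-category fraction correct and
    fraction correct-and-accepted (true positives).
    """
    col = {"class": "class_", "phylum": "phylum"}[level]
    cats = matrix.meta[col].unique()
    if len(cats) < 2:
        raise ValueError(f"need >= 2 categories at level '{level}'")
    rows = []
    for k, species in enumerate(matrix.meta["species"].unique()):
        held = (matrix.meta["species"] == species).to_numpy()
        remaining = matrix.meta.loc[~held, col]
        truth = matrix.meta.loc[held, col].iloc[0]
        if truth not in set(remaining):
            warnings.warn(f"species '{species}' is the sole member of its "
                          f"{level}; skipped", RuntimeWarning, stacklevel=2)
            continue
        train = matrix.select_rows(~held)
        sub_seed = None if seed is None else (seed + k) % (2**31)
        model = train_rf(train, level, ntree=ntree, mtry=mtry, seed=sub_seed,
                         alpha=alpha)
        ids = identify(model, matrix.select_rows(held), alpha=alpha)
        for ident in ids:
            rows.append({"species": species, "category": truth,
                         "predicted": ident.predicted, "prob": ident.prob,
                         "correct": ident.predicted == truth,
                         "tp": ident.accepted and ident.predicted == truth})
    table = pd.DataFrame(rows)
    if table.empty:
        raise ValueError("no species could be evaluated")
    summary = table.groupby("category").agg(
        n=("correct", "size"), correct=("correct", "mean"), tp=("tp", "mean"))
    summary.loc["overall"] = [len(table), table["correct"].mean(),
                              table["tp"].mean()]
    return table, summary


def congeneric_affinity(matrix: FeatureMatrix, *, ntree: int = 2000,
                        mtry: int = 35, seed: int | None = 0):
    """Fraction of specimens classified as a congener when their species
    is removed from the library.

    Only species with at least one congener present are eligible. The
    overall fraction is specimen-weighted.
    """
    meta = matrix.meta
    genus_species = meta.groupby("genus")["species"].nunique()
    multi = genus_species[genus_species >= 2].index
    if len(multi) == 0:
        raise ValueError("no genus with >= 2 species in the library")
    rows = []
    eligible = meta.loc[meta["genus"].isin(multi), "species"].unique()
    for k, species in enumerate(eligible):
        held = (meta["species"] == species).to_numpy()
        genus = meta.loc[held, "genus"].iloc[0]
        congeners = set(meta.loc[(meta["genus"] == genus)
                                 & (meta["species"] != species), "species"])
        train = matrix.select_rows(~held)
        sub_seed = None if seed is None else (seed + k) % (2**31)
        model = train_rf(train, "species", ntree=ntree, mtry=mtry, seed=sub_seed)
        ids = identify(model, matrix.select_rows(held))
        n_cong = sum(i.predicted in congeners for i in ids)
        rows.append({"species": species, "genus": genus, "n": len(ids),
                     "n_congeneric": n_cong,
                     "congeneric_fraction": n_cong / len(ids)})
    table = pd.DataFrame(rows)
    overall = table["n_congeneric"].sum() / table["n"].sum()
    return float(overall), table


def gini_top_peaks(model: FingerprintClassifier, matrix: FeatureMatrix,
                   k: int = 30) -> pd.DataFrame:
    """Top-k discriminating peaks by mean-decrease-Gini importance.

    Returns features sorted by decreasing importance with the per-class
    mean Hellinger intensity of each (heat-map data). ``matrix`` must be
    the matrix the model was trained from (TIC scale if the model
    applied the Hellinger transform itself).
    """
    check_is_fitted(model, "forest_")
    imp = model.forest_.feature_importances_
    if k > len(imp):
        warnings.warn(f"k={k} exceeds n_features={len(imp)}; clamped",
                      RuntimeWarning, stacklevel=2)
        k = len(imp)
    mat = hellinger(matrix) if getattr(model, "apply_hellinger_", True) else matrix
    order = np.argsort(imp)[::-1][:k]
    fm = matrix.feature_masses
    out = pd.DataFrame({"feature_mass": fm[order], "importance": imp[order]})
    # recover the label level the model was trained on from classes_
    level_labels = mat.labels("species")
    for lvl in ("species", "genus", "class", "phylum", "sex"):
        cand = mat.labels(lvl)
        if set(model.classes_) <= set(cand):
            level_labels = cand
            break
    vals = mat.values
    for c in model.classes_:
        out[f"mean_{c}"] = vals[level_labels == c][:, order].mean(axis=0)
    return out.reset_index(drop=True)


def _node_leafsets(Z: np.ndarray, n: int) -> list[frozenset]:
    """Leaf-index sets of all internal nodes of a scipy linkage tree."""
    sets: dict[int, frozenset] = {i: frozenset([i]) for i in range(n)}
    out = []
    for i, (a, b, *_rest) in enumerate(Z):
        s = sets[int(a)] | sets[int(b)]
        sets[n + i] = s
        out.append(s)
    return out


def cluster_bootstrap(matrix: FeatureMatrix, linkage: str = "average",
                      B: int = 100, seed: int | None = 0,
                      apply_hellinger: bool = True):
    """Hierarchical clustering with feature-bootstrap node support.

    Rows are clustered on Euclidean distance of their Hellinger
    intensities; each internal node's support is the percentage of ``B``
    feature-bootstrap replicates (features resampled with replacement)
    in which the node's exact leaf set reappears. Returns
    ``(tree, supports, newick)`` where tree is an skbio TreeNode whose
    internal nodes are named with their support.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if linkage not in ("average", "ward"):
        raise ValueError("linkage must be 'average' or 'ward'")
    if len(matrix) < 3:
        raise ValueError("need at least 3 rows to cluster")
    from skbio import TreeNode

    X = hellinger(matrix).values if apply_hellinger else matrix.values
    n = X.shape[0]
    Z = scipy_linkage(X, method=linkage, metric="euclidean")
    ref_sets = _node_leafsets(Z, n)
    counts = {s: 0 for s in ref_sets}
    rng = np.random.default_rng(seed)
    for _ in range(B):
        cols = rng.integers(0, X.shape[1], X.shape[1])
        Zb = scipy_linkage(X[:, cols], method=linkage, metric="euclidean")
        for s in _node_leafsets(Zb, n):
            if s in counts:
                counts[s] += 1
    supports = {s: 100.0 * c / B for s, c in counts.items()}
    ids = list(matrix.intensities.index.astype(str))
    tree = TreeNode.from_linkage_matrix(Z, ids)
    id_to_idx = {name: i for i, name in enumerate(ids)}
    for node in tree.non_tips(include_self=True):
        leafset = frozenset(id_to_idx[t.name] for t in node.tips())
        if leafset in supports:
            node.name = f"{supports[leafset]:.0f}"
    return tree, supports, str(tree)
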