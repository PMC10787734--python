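"""Peak detection, strict cross-spectrum binning and feature-matrix assembly.

A conditioned spectrum is reduced to a peak list: local maxima within a
half-window of ``hws`` sample points whose intensity exceeds ``snr`` times
the noise scale (1.4826 x the median absolute deviation of the whole
spectrum). Peaks of all spectra are then pooled and binned so that
specimens become comparable rows of a feature matrix: a group of pooled
peaks forms one bin only if every member lies within a relative mass
tolerance of the group mean and no spectrum contributes two peaks;
violating groups are split at their largest internal mass gap and the
rule re-applied. Binning of the re-labelled peaks is repeated until the
number of distinct features stops changing. Finally, matrix rows are
Hellinger-transformed (square root of row-relative abundances) for
classification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import maximum_filter1d
from sklearn.base import BaseEstimator, TransformerMixin

from .spectra import PeakList, RawSpectrum, TaxonLabel

__all__ = [
    "PeakParams",
    "FeatureMatrix",
    "estimate_noise",
    "detect_peaks",
    "bin_peaks",
    "bin_to_convergence",
    "build_feature_matrix",
    "hellinger",
    "PeakDetector",
    "PeakBinner",
    "HellingerTransformer",
]

_TAXON_COLS = ("species", "genus", "class_", "phylum", "sex")


@dataclass
class PeakParams:
    """Peak-picking and binning settings.

    snr
        Signal-to-noise threshold; a point must exceed ``snr`` times the
        MAD-based noise estimate to qualify. Higher values drop
        low-intensity signals.
    hws
        Half window size in sample points; a peak must be the strict
        maximum within ``[i - hws, i + hws]``. Higher values pick fewer,
        coarser peaks.
    bin_tolerance
        Relative mass tolerance of a bin (|m - mean| <= tol * mean).
    """

    snr: float = 3.0
    hws: int = 7
    bin_tolerance: float = 0.002

    def validate(self) -> None:
        if self.snr <= 0:
            raise ValueError("snr must be > 0")
        if self.hws < 1:
            raise ValueError("hws must be >= 1")
        if not 0 < self.bin_tolerance < 0.1:
            raise ValueError("bin_tolerance must be in (0, 0.1)")


def estimate_noise(s: RawSpectrum) -> float:
    """Noise scale: 1.4826 x median absolute deviation of the intensities.

    The factor makes the MAD consistent with the standard deviation of a
    Gaussian. A degenerate (constant) spectrum returns a tiny positive
    fallback with a warning so downstream SNR thresholds stay finite.
    """
    if len(s) < 2:
        raise ValueError("need at least two points to estimate noise")
    med = np.median(s.intensities)
    mad = np.median(np.abs(s.intensities - med))
    noise = 1.4826 * mad
    if noise == 0.0:
        noise = np.finfo(float).eps * max(1.0, abs(float(med)))
        warnings.warn("MAD noise estimate is zero; using epsilon fallback",
                      RuntimeWarning, stacklevel=2)
    return float(noise)


def detect_peaks(s: RawSpectrum, params: PeakParams | None = None, *,
                 noise: float | None = None) -> PeakList:
    """Pick peaks: strict window maxima above the SNR threshold.

    A point is a peak iff its intensity exceeds ``snr * noise`` and is
    strictly greater than every other intensity within ``hws`` points;
    among exactly tied window maxima only the leftmost survives.
    ``noise`` can be supplied to override the MAD estimate (used by
    tests with a pinned noise scale).
    """
    params = params or PeakParams()
    params.validate()
    y = s.intensities
    n = len(y)
    if noise is None:
        noise = estimate_noise(s)
    thr = params.snr * noise
    w = 2 * params.hws + 1
    winmax = maximum_filter1d(y, size=w, mode="constant", cval=-np.inf)
    cand = np.flatnonzero((y > thr) & (y == winmax))
    keep = []
    for i in cand:
        lo = max(0, i - params.hws)
        # reject if an equal value sits earlier in the window (leftmost wins)
        if np.any(y[lo:i] == y[i]):
            continue
        keep.append(i)
    idx = np.asarray(keep, dtype=int)
    return PeakList(
        masses=s.masses[idx], intensities=y[idx], snr_values=y[idx] / noise,
        specimen_id=s.specimen_id, replicate_id=s.replicate_id, taxon=s.taxon)


# ---------------------------------------------------------------------------
# strict binning


def _assign_bins(masses: np.ndarray, sources: np.ndarray, tolerance: float) -> np.ndarray:
    """Assign sorted pooled peaks to bins by recursive splitting.

    A candidate group is one bin iff every mass is within ``tolerance *
    mean`` of the group mean and no source spectrum appears twice;
    otherwise it is split at the largest internal gap (leftmost on ties)
    and the rule applied to both halves.
    """
    bin_ids = np.empty(len(masses), dtype=int)
    counter = 0
    stack = [(0, len(masses))]
    while stack:
        lo, hi = stack.pop()
        m = masses[lo:hi]
        if hi - lo == 1:
            ok = True
        else:
            mean = m.mean()
            ok = np.all(np.abs(m - mean) <= tolerance * mean) and \
                len(np.unique(sources[lo:hi])) == hi - lo
        if ok:
            bin_ids[lo:hi] = counter
            counter += 1
        else:
            gaps = np.diff(m)
            split = lo + int(np.argmax(gaps)) + 1
            stack.append((split, hi))
            stack.append((lo, split))
    return bin_ids


def bin_peaks(peaklists: list[PeakList], tolerance: float = 0.002
              ) -> tuple[list[PeakList], np.ndarray]:
    """One strict binning pass over pooled peaks of all spectra.

    Returns the peak lists with masses re-labelled to their bin mean and
    the sorted array of distinct feature masses.
    """
    if not 0 < tolerance < 0.1:
        raise ValueError("tolerance must be in (0, 0.1)")
    if not peaklists or all(len(p) == 0 for p in peaklists):
        raise ValueError("need at least one non-empty peak list")
    masses = np.concatenate([p.masses for p in peaklists])
    sources = np.concatenate([np.full(len(p), i) for i, p in enumerate(peaklists)])
    order = np.argsort(masses, kind="stable")
    inv = np.empty_like(order)
    inv[order] = np.arange(len(order))
    bin_ids_sorted = _assign_bins(masses[order], sources[order], tolerance)
    bin_ids = bin_ids_sorted[inv]
    # bin mass = mean of member masses
    nbins = bin_ids.max() + 1
    sums = np.bincount(bin_ids, weights=masses, minlength=nbins)
    counts = np.bincount(bin_ids, minlength=nbins)
    bin_mass = sums / counts
    new_lists = []
    start = 0
    for p in peaklists:
        ids = bin_ids[start:start + len(p)]
        start += len(p)
        new_m = bin_mass[ids]
        order_p = np.argsort(new_m, kind="stable")
        new_lists.append(replace(p, masses=new_m[order_p],
                                 intensities=p.intensities[order_p],
                                 snr_values=p.snr_values[order_p]))
    return new_lists, np.unique(bin_mass)


def bin_to_convergence(peaklists: list[PeakList], tolerance: float = 0.002
                       ) -> tuple[list[PeakList], np.ndarray, int]:
    """Repeat :func:`bin_peaks` until the feature count stops changing.

    The count is non-increasing (re-binning can only merge further) and
    bounded below by 1, so the loop terminates; the final pass confirms
    stability, hence an already-stable input reports ``n_rounds == 2``.
    """
    prev = -1
    n_rounds = 0
    feature_masses = np.array([])
    while True:
        peaklists, feature_masses = bin_peaks(peaklists, tolerance)
        n_rounds += 1
        if len(feature_masses) == prev:
            break
        prev = len(feature_masses)
    return peaklists, feature_masses, n_rounds


# ---------------------------------------------------------------------------
# feature matrix


@dataclass
class FeatureMatrix:
    """Specimens x binned-mass features of non-negative peak intensities.

    ``intensities`` is a DataFrame whose columns are the feature masses
    (floats, strictly increasing) and whose index holds row ids;
    ``meta`` is an aligned DataFrame with columns ``specimen_id``,
    ``replicate_id``, ``species``, ``genus``, ``class_``, ``phylum``,
    ``sex``.
    """

    intensities: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.intensities.shape[0] == 0 or self.intensities.shape[1] == 0:
            raise ValueError("feature matrix is empty")
        if not self.intensities.index.equals(self.meta.index):
            raise ValueError("intensities and meta indices differ")
        fm = self.feature_masses
        if np.any(np.diff(fm) <= 0):
            raise ValueError("feature masses must be strictly increasing")
        if (self.intensities.values < 0).any():
            raise ValueError("intensities must be non-negative")

    @property
    def feature_masses(self) -> np.ndarray:
        return np.asarray(self.intensities.columns, dtype=float)

    @property
    def values(self) -> np.ndarray:
        return self.intensities.to_numpy(dtype=float)

    def labels(self, level: str = "species") -> np.ndarray:
        col = {"species": "species", "genus": "genus", "class": "class_",
               "class_": "class_", "phylum": "phylum", "sex": "sex"}[level]
        return self.meta[col].to_numpy()

    def __len__(self) -> int:
        return len(self.intensities)

    def select_rows(self, mask) -> "FeatureMatrix":
        """Row subset (boolean mask, positions or row ids), metadata aligned."""
        arr = np.asarray(mask)
        if arr.dtype.kind in "iu":  # integer positions
            return FeatureMatrix(self.intensities.iloc[arr].copy(),
                                 self.meta.iloc[arr].copy())
        return FeatureMatrix(self.intensities.loc[mask].copy(),
                             self.meta.loc[mask].copy())


def _taxon_row(t: TaxonLabel | None) -> dict:
    t = t or TaxonLabel()
    return {"species": t.species, "genus": t.genus, "class_": t.class_,
            "phylum": t.phylum, "sex": t.sex}


def build_feature_matrix(peaklists: list[PeakList],
                         feature_masses: np.ndarray,
                         replicate_policy: str = "mean") -> FeatureMatrix:
    """Assemble the specimens x features table from converged peak lists.

    Cells hold the binned peak intensity, 0 where a specimen lacks the
    peak. With ``replicate_policy='mean'`` technical replicates of a
    specimen are averaged per feature into one row; ``'separate'`` keeps
    one row per replicate. All-zero feature columns are dropped with a
    warning.
    """
    if replicate_policy not in ("mean", "separate"):
        raise ValueError("replicate_policy must be 'mean' or 'separate'")
    feature_masses = np.asarray(feature_masses, dtype=float)
    col_index = {m: j for j, m in enumerate(feature_masses)}
    rows, meta_rows, row_ids = [], [], []
    for p in peaklists:
        v = np.zeros(len(feature_masses))
        for m, inten in zip(p.masses, p.intensities):
            j = col_index.get(m)
            if j is None:
                # nearest converged feature (guards float round-trips)
                j = int(np.argmin(np.abs(feature_masses - m)))
            v[j] = inten
        rows.append(v)
        row_ids.append((p.specimen_id, p.replicate_id))
        meta_rows.append({"specimen_id": p.specimen_id,
                          "replicate_id": p.replicate_id, **_taxon_row(p.taxon)})
    df = pd.DataFrame(rows, columns=feature_masses)
    meta = pd.DataFrame(meta_rows)
    if replicate_policy == "mean":
        df["__sid"] = [sid for sid, _ in row_ids]
        df = df.groupby("__sid", sort=False).mean()
        meta = meta.drop(columns="replicate_id").drop_duplicates("specimen_id")
        meta = meta.set_index("specimen_id", drop=False)
        meta["replicate_id"] = ""
        df.index.name = None
        meta.index.name = None
        meta = meta.loc[df.index]
    else:
        idx = [f"{sid}__{rid}" for sid, rid in row_ids]
        if len(set(idx)) != len(idx):
            raise ValueError("duplicate (specimen_id, replicate_id) rows")
        df.index = idx
        meta.index = idx
    zero_cols = df.columns[(df == 0).all(axis=0)]
    if len(zero_cols):
        warnings.warn(f"dropping {len(zero_cols)} all-zero feature column(s)",
                      RuntimeWarning, stacklevel=2)
        df = df.drop(columns=zero_cols)
    meta = meta[["specimen_id", "replicate_id", *_TAXON_COLS]]
    return FeatureMatrix(df, meta)


def hellinger(matrix: FeatureMatrix) -> FeatureMatrix:
    """Hellinger transform: value' = sqrt(value / row_sum).

    Squared row values then sum to 1; the transform is invariant to row
    scaling, which removes residual per-specimen intensity scale.
    """
    vals = matrix.values
    sums = vals.sum(axis=1)
    bad = np.flatnonzero(sums <= 0)
    if len(bad):
        names = ", ".join(map(str, matrix.intensities.index[bad]))
        raise ValueError(f"all-zero row(s) cannot be Hellinger-transformed: {names}")
    out = np.sqrt(vals / sums[:, None])
    return FeatureMatrix(
        pd.DataFrame(out, index=matrix.intensities.index,
                     columns=matrix.intensities.columns),
        matrix.meta.copy())


def hellinger_array(X: np.ndarray) -> np.ndarray:
    """Hellinger transform of a plain array (rows must have positive sums)."""
    X = np.asarray(X, dtype=float)
    sums = X.sum(axis=1, keepdims=True)
    if np.any(sums <= 0):
        raise ValueError("all-zero row in Hellinger transform")
    return np.sqrt(X / sums)


# ---------------------------------------------------------------------------
# sklearn-style wrappers


class PeakDetector(TransformerMixin, BaseEstimator):
    """Stateless transformer: list of spectra -> list of PeakList."""

    def __init__(self, snr: float = 3.0, hws: int = 7):
        self.snr = snr
        self.hws = hws

    def fit(self, X, y=None):
        PeakParams(snr=self.snr, hws=self.hws).validate()
        return self

    def transform(self, X):
        p = PeakParams(snr=self.snr, hws=self.hws)
        return [detect_peaks(s, p) for s in X]


class PeakBinner(TransformerMixin, BaseEstimator):
    """Bins peak lists to convergence; learns the feature-mass set.

    After ``fit`` the attributes ``feature_masses_`` and ``n_rounds_``
    hold the converged feature set and the number of binning passes.
    """

    def __init__(self, bin_tolerance: float = 0.002):
        self.bin_tolerance = bin_tolerance

    def fit(self, X, y=None):
        binned, fm, rounds = bin_to_convergence(X, self.bin_tolerance)
        self.binned_ = binned
        self.feature_masses_ = fm
        self.n_rounds_ = rounds
        return self

    def transform(self, X):
        # binning is a joint operation over the collection seen at fit
        # time; transform returns that converged state
        return self.binned_

    def fit_transform(self, X, y=None):
        return self.fit(X).binned_


class HellingerTransformer(TransformerMixin, BaseEstimator):
    """Row-wise Hellinger transform for plain arrays (sklearn-compatible)."""

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        return hellinger_array(X)
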