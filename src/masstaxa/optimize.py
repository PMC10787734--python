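"""Standardization of data processing: grid search, GAM driver analysis
and reference-library sizing.

Three processing choices materially shape the feature matrix a random
forest learns from: the number of SNIP baseline iterations (more
iterations erode low-intensity peaks), the peak-picking signal-to-noise
threshold (higher SNR drops faint signals) and the peak-picking half
window size (larger HWS picks fewer, coarser peaks). ``grid_search``
evaluates the full Cartesian product of candidate values by running the
complete pipeline — preprocess, detect, bin to convergence, Hellinger,
random forest — and recording the OOB error of each combination.
``fit_gam`` then asks which parameter drives classification success by
fitting a binomial (logit) generalized additive model of the OOB error
on smooth terms of the three parameters. ``specimen_saturation``
measures how the OOB error shrinks as more specimens per species enter
the reference library.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import train_rf
from .peaks import (PeakParams, bin_to_convergence, build_feature_matrix,
                    detect_peaks, FeatureMatrix)
from .preprocess import PreprocessParams, preprocess_pipeline
from .spectra import RawSpectrum

__all__ = [
    "GridResult",
    "GAMSummary",
    "SaturationResult",
    "build_grid",
    "grid_search",
    "recommend_settings",
    "fit_gam",
    "specimen_saturation",
]


@dataclass
class GridResult:
    """One row per evaluated (baseline_iterations, hws, snr) combination."""

    table: pd.DataFrame  # baseline_iterations, hws, snr, n_features,
    #                      oob_error, n_bin_rounds, zero_features flag

    def argmin(self) -> pd.Series:
        """Best row: lowest OOB error; ties broken by fewer features,
        then lower snr, lower hws, lower baseline_iterations."""
        t = self.table.sort_values(
            ["oob_error", "n_features", "snr", "hws", "baseline_iterations"],
            kind="stable")
        return t.iloc[0]


@dataclass
class GAMSummary:
    """Per-term smooth statistics of the binomial GAM."""

    terms: pd.DataFrame        # index term name; edf, ref_df, chi_sq, p_value
    intercept: float
    deviance_explained: float  # percent
    adj_r_squared: float

    def p_value(self, term: str) -> float:
        return float(self.terms.loc[term, "p_value"])


@dataclass
class SaturationResult:
    """OOB error as a function of specimens per species."""

    table: pd.DataFrame    # n, rep, oob_error
    summary: pd.DataFrame  # per n: mean, sd, min, max


def build_grid(baseline_iterations, hws, snr) -> pd.DataFrame:
    """Cartesian product of candidate parameter values, one row each."""
    rows = list(itertools.product(sorted(set(baseline_iterations)),
                                  sorted(set(hws)), sorted(set(snr))))
    if not rows:
        raise ValueError("empty parameter grid")
    return pd.DataFrame(rows, columns=["baseline_iterations", "hws", "snr"])


def _pipeline_oob(spectra, base_iter, hws, snr, *, tolerance, replicate_policy,
                  ntree, mtry, rf_seed, preprocessed=None):
    """Run detect->bin->matrix->RF for one grid point; returns stats."""
    if preprocessed is None:
        pp = PreprocessParams(baseline_iterations=int(base_iter))
        preprocessed = [preprocess_pipeline(s, pp) for s in spectra]
    pk = PeakParams(snr=float(snr), hws=int(hws), bin_tolerance=tolerance)
    peaklists = [detect_peaks(s, pk) for s in preprocessed]
    if all(len(p) == 0 for p in peaklists):
        return None
    binned, fm, rounds = bin_to_convergence(peaklists, tolerance)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        matrix = build_feature_matrix(binned, fm, replicate_policy)
        model = train_rf(matrix, "species", ntree=ntree, mtry=mtry, seed=rf_seed)
    return {"n_features": len(matrix.feature_masses),
            "oob_error": model.oob_error_, "n_bin_rounds": rounds,
            "n_specimens": len(matrix)}


def grid_search(spectra: list[RawSpectrum], grid: dict, *,
                ntree: int = 2000, mtry: int = 35, seed: int = 0,
                tolerance: float = 0.002, replicate_policy: str = "mean",
                min_specimens: int = 6) -> GridResult:
    """Evaluate every (baseline_iterations, hws, snr) combination.

    ``grid`` maps the three parameter names to iterables of candidate
    values. Every species in ``spectra`` must have at least
    ``min_specimens`` specimens. Each grid point trains its forest with
    a seed derived from ``seed`` and the grid coordinates, so any row
    can be recomputed in isolation. Preprocessing is shared across grid
    points with equal baseline iterations. Rows are returned sorted by
    OOB error ascending; a grid point yielding zero features is recorded
    with ``oob_error = 1.0`` and flagged.
    """
    gtab = build_grid(grid["baseline_iterations"], grid["hws"], grid["snr"])
    counts = pd.Series(
        [s.specimen_id for s in spectra if s.taxon is not None],
        dtype=object).groupby(
            pd.Series([s.taxon.species for s in spectra if s.taxon is not None],
                      dtype=object)).nunique()
    low = counts[counts < min_specimens]
    if len(low):
        raise ValueError("species below min_specimens: "
                         + ", ".join(low.index.astype(str)))
    rows = []
    for b, sub in gtab.groupby("baseline_iterations", sort=True):
        pp = PreprocessParams(baseline_iterations=int(b))
        pre = [preprocess_pipeline(s, pp) for s in spectra]
        for _, grow in sub.iterrows():
            hws, snr = grow["hws"], grow["snr"]
            rf_seed = int(np.random.SeedSequence(
                [seed, int(b), int(hws), int(round(snr * 1000))]
            ).generate_state(1)[0] % (2**31))
            stats = _pipeline_oob(
                spectra, b, hws, snr, tolerance=tolerance,
                replicate_policy=replicate_policy, ntree=ntree, mtry=mtry,
                rf_seed=rf_seed, preprocessed=pre)
            if stats is None:
                rows.append({"baseline_iterations": b, "hws": hws, "snr": snr,
                             "n_features": 0, "oob_error": 1.0,
                             "n_bin_rounds": 0, "zero_features": True})
            else:
                rows.append({"baseline_iterations": b, "hws": hws, "snr": snr,
                             "n_features": stats["n_features"],
                             "oob_error": stats["oob_error"],
                             "n_bin_rounds": stats["n_bin_rounds"],
                             "zero_features": False})
    table = pd.DataFrame(rows).sort_values(
        ["oob_error", "n_features", "snr", "hws", "baseline_iterations"],
        kind="stable").reset_index(drop=True)
    return GridResult(table=table)


def recommend_settings(grid: GridResult) -> tuple[PreprocessParams, PeakParams]:
    """Parameters of the best grid row (lowest OOB error, deterministic ties)."""
    best = grid.argmin()
    return (PreprocessParams(baseline_iterations=int(best["baseline_iterations"])),
            PeakParams(snr=float(best["snr"]), hws=int(best["hws"])))


# ---------------------------------------------------------------------------
# GAM driver analysis


def fit_gam(grid: GridResult, weights=None, *, alpha: float = 1.0,
            df: int = 5) -> GAMSummary:
    """Binomial (logit) GAM of OOB error on the three processing parameters.

    The OOB error enters as a binomial proportion with ``weights``
    (specimens per analysis; scalar or per-row, default 100) as the
    denominator. Each nonconstant parameter gets a penalized B-spline
    smooth (basis dimension <= ``df``; predictors with fewer distinct
    values than needed for a spline enter linearly). Per-term effective
    degrees of freedom come from the penalized hat matrix; significance
    is a likelihood-ratio chi-square against the model with the term
    removed, on the term's effective degrees of freedom.
    """
    import statsmodels.api as sm
    from statsmodels.gam.api import BSplines, GLMGam
    from scipy import stats as sps
    from scipy.linalg import block_diag

    t = grid.table
    if len(t) < 10:
        raise ValueError("need at least 10 grid rows to fit the GAM")
    y = np.clip(t["oob_error"].to_numpy(dtype=float), 1e-10, 1 - 1e-10)
    if weights is None:
        weights = 100.0
    w = np.broadcast_to(np.asarray(weights, dtype=float), y.shape).copy()

    names = ["baseline_iterations", "hws", "snr"]
    smooth_terms, linear_terms = [], []
    for name in names:
        x = t[name].to_numpy(dtype=float)
        nuniq = len(np.unique(x))
        if nuniq < 2:
            warnings.warn(f"predictor '{name}' is constant; term dropped",
                          RuntimeWarning, stacklevel=2)
        elif nuniq <= df:
            linear_terms.append(name)
        else:
            smooth_terms.append(name)
    if not smooth_terms and not linear_terms:
        raise ValueError("all predictors constant")

    def _design(linear: list[str], smooth: list[str]):
        cols = [np.ones(len(t))]
        for name in linear:
            x = t[name].to_numpy(dtype=float)
            cols.append((x - x.mean()) / (x.std() or 1.0))
        exog = np.column_stack(cols)
        bs = None
        if smooth:
            xs = t[smooth].to_numpy(dtype=float)
            bs = BSplines(xs, df=[df] * len(smooth), degree=[3] * len(smooth))
        return exog, bs

    def _fit(linear: list[str], smooth: list[str]):
        exog, bs = _design(linear, smooth)
        if bs is not None:
            model = GLMGam(y, exog=exog, smoother=bs,
                           family=sm.families.Binomial(), var_weights=w,
                           alpha=[alpha] * len(smooth))
        else:
            model = sm.GLM(y, exog, family=sm.families.Binomial(),
                           var_weights=w)
        return model.fit(), exog, bs

    res, exog, bs = _fit(linear_terms, smooth_terms)

    # effective degrees of freedom from the penalized hat matrix:
    # F = (X'WX + 2*alpha*S)^-1 X'WX ; edf of a term = trace of its block
    if bs is not None:
        X = np.column_stack([exog] + [s.basis for s in bs.smoothers])
        S = block_diag(np.zeros((exog.shape[1], exog.shape[1])),
                       *[alpha * P for P in bs.penalty_matrices])
        mu = res.fittedvalues
        Wd = w * mu * (1 - mu)
        XtWX = (X.T * Wd) @ X
        F = np.linalg.solve(XtWX + 2.0 * S, XtWX)
        edf_per_param = np.diag(F)
    else:
        X = exog
        edf_per_param = np.ones(X.shape[1])

    # per-term LRT: deviance increase when the term is dropped
    term_rows = {}
    dev_full = float(res.deviance)
    col = exog.shape[1]
    edf_of_term = {}
    for j, name in enumerate(linear_terms, start=1):
        edf_of_term[name] = float(edf_per_param[j])
    if bs is not None:
        for k, name in enumerate(smooth_terms):
            ncol = bs.smoothers[k].basis.shape[1]
            edf_of_term[name] = float(edf_per_param[col:col + ncol].sum())
            col += ncol
    for name in linear_terms + smooth_terms:
        red_lin = [n for n in linear_terms if n != name]
        red_smo = [n for n in smooth_terms if n != name]
        if red_lin or red_smo:
            res_red, *_ = _fit(red_lin, red_smo)
            dev_red = float(res_red.deviance)
        else:
            dev_red = float(res.null_deviance)
        chi = max(dev_red - dev_full, 0.0)
        edf = edf_of_term[name]
        ref_df = 1.0 if name in linear_terms else float(df - 1)
        test_df = max(1.0, edf)
        term_rows[name] = {"edf": edf, "ref_df": ref_df, "chi_sq": chi,
                           "p_value": float(sps.chi2.sf(chi, test_df))}
    params = np.asarray(res.params)

    terms = pd.DataFrame(term_rows).T[["edf", "ref_df", "chi_sq", "p_value"]]
    null_dev = float(res.null_deviance) if hasattr(res, "null_deviance") else np.nan
    dev = float(res.deviance)
    dev_expl = 100.0 * (1.0 - dev / null_dev) if null_dev else np.nan
    # adjusted R^2 on the response scale
    resid = y - res.fittedvalues
    r2 = 1.0 - resid.var() / y.var() if y.var() > 0 else np.nan
    edf_total = float(np.sum(edf_per_param))
    n = len(y)
    adj = 1.0 - (1.0 - r2) * (n - 1) / max(n - edf_total, 1)
    return GAMSummary(terms=terms, intercept=float(params[0]),
                      deviance_explained=float(dev_expl),
                      adj_r_squared=float(adj))


# ---------------------------------------------------------------------------
# specimens-per-species saturation


def specimen_saturation(matrix: FeatureMatrix, *, n_range=(2, 11),
                        reps: int = 100, min_pool: int = 11,
                        ntree: int = 500, mtry: int = 35,
                        seed: int = 0) -> SaturationResult:
    """OOB error vs number of specimens per species.

    Only species with at least ``min_pool`` specimens are eligible. For
    every ``n`` (an inclusive ``(lo, hi)`` tuple or an explicit list)
    and every replicate, ``n`` specimens per species are sampled without
    replacement with a seed derived from ``(seed, n, rep)``, a forest is
    trained and its OOB error recorded.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if isinstance(n_range, tuple) and len(n_range) == 2:
        ns = list(range(int(n_range[0]), int(n_range[1]) + 1))
    else:
        ns = [int(v) for v in n_range]
    counts = matrix.meta.groupby("species")["specimen_id"].nunique()
    eligible = counts[counts >= min_pool].index
    if len(eligible) < 2:
        raise ValueError(
            f"need >= 2 species with >= {min_pool} specimens; found {len(eligible)}")
    sub = matrix.select_rows(matrix.meta["species"].isin(eligible).to_numpy())
    specs_by_species = {
        sp: sub.meta.loc[sub.meta["species"] == sp, "specimen_id"].unique()
        for sp in eligible}
    rows = []
    for n in ns:
        for rep in range(reps):
            rng = np.random.default_rng([seed, n, rep])
            chosen = []
            for sp in eligible:
                pool = specs_by_species[sp]
                chosen.extend(rng.choice(pool, size=n, replace=False))
            mask = sub.meta["specimen_id"].isin(chosen).to_numpy()
            rf_seed = int(np.random.SeedSequence([seed, n, rep, 77]
                                                 ).generate_state(1)[0] % (2**31))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                model = train_rf(sub.select_rows(mask), "species",
                                 ntree=ntree, mtry=mtry, seed=rf_seed)
            rows.append({"n": n, "rep": rep, "oob_error": model.oob_error_})
    table = pd.DataFrame(rows)
    summary = table.groupby("n")["oob_error"].agg(
        mean="mean", sd="std", min="min", max="max")
    return SaturationResult(table=table, summary=summary)
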