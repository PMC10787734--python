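"""Deterministic spectrum conditioning.

The chain applied to every raw fingerprint before peak picking is, in
order: trim to a common mass window, square-root variance stabilization,
Savitzky-Golay smoothing, SNIP baseline subtraction and total-ion-current
(TIC) normalization. Every stage is a pure function of its input; the
whole pipeline is exposed both as :func:`preprocess_pipeline` and as the
sklearn-style :class:`SpectrumPreprocessor` transformer.

Notes on the two non-trivial stages:

* Savitzky-Golay operates on the sample index, not the Da axis (profile
  spectra come on a near-uniform grid). Each point is replaced by the
  centre value of a degree-``polyorder`` least-squares polynomial fitted
  to the ``2*half_window + 1`` surrounding intensities; at the spectrum
  edges the window is truncated and the fit repeated on what remains.
* SNIP (statistics-sensitive non-linear iterative peak clipping)
  estimates the baseline by repeated clipping: at window size ``k`` each
  point is replaced by ``min(y_i, (y_{i-k} + y_{i+k}) / 2)``. The window
  grows ``k = 1..m`` by default; a decreasing schedule is available since
  published implementations differ.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter
from sklearn.base import BaseEstimator, TransformerMixin

from .spectra import RawSpectrum

__all__ = [
    "PreprocessParams",
    "PreprocessError",
    "trim",
    "sqrt_transform",
    "savitzky_golay",
    "snip_baseline",
    "subtract_baseline",
    "tic_normalize",
    "preprocess_pipeline",
    "SpectrumPreprocessor",
]


class PreprocessError(RuntimeError):
    """A preprocessing stage failed; the message names the stage."""


@dataclass
class PreprocessParams:
    """Settings of the conditioning chain.

    trim_lo, trim_hi
        Mass window in Da kept for analysis (closed interval). Default
        2000-20000 Da, the intact-protein fingerprint range.
    sg_half_window, sg_polyorder
        Savitzky-Golay one-sided window (points) and polynomial degree.
    baseline_iterations
        Number of SNIP clipping iterations ``m``; larger m removes wider
        structures and progressively erodes low-intensity peaks.
    snip_decreasing
        Run the clipping window from m down to 1 instead of 1 up to m.
    """

    trim_lo: float = 2000.0
    trim_hi: float = 20000.0
    sg_half_window: int = 10
    sg_polyorder: int = 3
    baseline_iterations: int = 22
    snip_decreasing: bool = False

    def validate(self) -> None:
        if not self.trim_lo < self.trim_hi:
            raise ValueError("trim_lo must be < trim_hi")
        if self.sg_polyorder >= 2 * self.sg_half_window + 1:
            raise ValueError("sg_polyorder must be < 2*sg_half_window + 1")
        if self.baseline_iterations < 1:
            raise ValueError("baseline_iterations must be >= 1")


def trim(s: RawSpectrum, lo: float, hi: float) -> RawSpectrum:
    """Keep points with ``lo <= mass <= hi`` (closed interval)."""
    if not lo < hi:
        raise ValueError("lo must be < hi")
    keep = (s.masses >= lo) & (s.masses <= hi)
    if not keep.any():
        raise ValueError(f"trim [{lo}, {hi}] leaves no points "
                         f"(spectrum spans {s.masses[0]:.1f}-{s.masses[-1]:.1f} Da)")
    from dataclasses import replace
    return replace(s, masses=s.masses[keep], intensities=s.intensities[keep])


def sqrt_transform(s: RawSpectrum) -> RawSpectrum:
    """Square-root variance stabilization (ion counts are Poisson-like)."""
    if np.any(s.intensities < 0):
        raise ValueError("negative intensity")
    return s.with_intensities(np.sqrt(s.intensities))


def savitzky_golay(s: RawSpectrum, half_window: int, polyorder: int) -> RawSpectrum:
    """Savitzky-Golay smoothing on the sample index.

    Interior points use :func:`scipy.signal.savgol_filter`; the first and
    last ``half_window`` points are re-fitted on the truncated window so
    the contract "least-squares polynomial on the surrounding window"
    holds at every index. Negative smoothing overshoot (possible only
    where the signal sits at the noise floor) is clamped to zero to
    preserve the spectrum's non-negativity.
    """
    n = len(s)
    w = 2 * half_window + 1
    if w > n:
        raise ValueError(f"spectrum of {n} points shorter than window {w}")
    if polyorder >= w:
        raise ValueError("polyorder must be < window length")
    y = s.intensities
    out = savgol_filter(y, window_length=w, polyorder=polyorder, mode="interp")
    # truncated-window refit at the edges
    for i in range(half_window):
        for idx, sl in ((i, slice(0, i + half_window + 1)),
                        (n - 1 - i, slice(n - 1 - i - half_window, n))):
            xs = np.arange(sl.start, sl.stop, dtype=float)
            deg = min(polyorder, len(xs) - 1)
            coef = np.polynomial.polynomial.polyfit(xs - idx, y[sl], deg)
            out[idx] = coef[0]
    return s.with_intensities(np.maximum(out, 0.0))


def snip_baseline(s: RawSpectrum, iterations: int, decreasing: bool = False) -> np.ndarray:
    """SNIP baseline estimate (returned as an array, not subtracted).

    Boundary points closer than ``k`` to either edge are left unchanged at
    that window size. The estimate is pointwise <= the input and
    non-increasing over iterations.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    n = len(s)
    if iterations >= n:
        raise ValueError(f"iterations ({iterations}) must be < spectrum length ({n})")
    y = s.intensities.astype(float).copy()
    ks = range(iterations, 0, -1) if decreasing else range(1, iterations + 1)
    for k in ks:
        if 2 * k >= n:
            continue
        mid = 0.5 * (y[: n - 2 * k] + y[2 * k:])
        np.minimum(y[k: n - k], mid, out=y[k: n - k])
    return y


def subtract_baseline(s: RawSpectrum, baseline: np.ndarray) -> RawSpectrum:
    """Subtract a baseline, clamping negative results to zero."""
    baseline = np.asarray(baseline, dtype=float)
    if baseline.shape != s.intensities.shape:
        raise ValueError("baseline length does not match spectrum")
    return s.with_intensities(np.maximum(s.intensities - baseline, 0.0))


def tic_normalize(s: RawSpectrum) -> RawSpectrum:
    """Scale intensities so the total ion current equals 1."""
    total = s.tic()
    if total <= 0:
        raise ValueError("cannot TIC-normalize an all-zero spectrum")
    return s.with_intensities(s.intensities / total)


def preprocess_pipeline(s: RawSpectrum, params: PreprocessParams | None = None) -> RawSpectrum:
    """Full conditioning chain: trim, sqrt, smooth, SNIP-subtract, TIC."""
    params = params or PreprocessParams()
    params.validate()
    stages = [
        ("trim", lambda x: trim(x, params.trim_lo, params.trim_hi)),
        ("sqrt", sqrt_transform),
        ("savitzky_golay", lambda x: savitzky_golay(
            x, params.sg_half_window, params.sg_polyorder)),
        ("snip_subtract", lambda x: subtract_baseline(
            x, snip_baseline(x, params.baseline_iterations, params.snip_decreasing))),
        ("tic", tic_normalize),
    ]
    for name, fn in stages:
        try:
            s = fn(s)
        except Exception as exc:  # noqa: BLE001 - stage name must be attached
            raise PreprocessError(f"stage '{name}' failed: {exc}") from exc
    return s


class SpectrumPreprocessor(TransformerMixin, BaseEstimator):
    """sklearn-style transformer applying the conditioning chain to spectra.

    ``transform`` maps a list of :class:`RawSpectrum` to a list of
    conditioned spectra; the transformer is stateless (``fit`` is a no-op)
    so it composes with sklearn pipelines and ``get_params``-based search.
    """

    def __init__(self, trim_lo: float = 2000.0, trim_hi: float = 20000.0,
                 sg_half_window: int = 10, sg_polyorder: int = 3,
                 baseline_iterations: int = 22, snip_decreasing: bool = False):
        self.trim_lo = trim_lo
        self.trim_hi = trim_hi
        self.sg_half_window = sg_half_window
        self.sg_polyorder = sg_polyorder
        self.baseline_iterations = baseline_iterations
        self.snip_decreasing = snip_decreasing

    def _params(self) -> PreprocessParams:
        return PreprocessParams(
            trim_lo=self.trim_lo, trim_hi=self.trim_hi,
            sg_half_window=self.sg_half_window, sg_polyorder=self.sg_polyorder,
            baseline_iterations=self.baseline_iterations,
            snip_decreasing=self.snip_decreasing)

    def fit(self, X, y=None):  # noqa: D102 - stateless
        self._params().validate()
        return self

    def transform(self, X):
        """Condition every spectrum in ``X`` (a list of RawSpectrum)."""
        p = self._params()
        return [preprocess_pipeline(s, p) for s in X]
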