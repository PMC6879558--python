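"""Locally weighted polynomial regression (LOESS) for pool-seq tracks.

The pipeline uses local regression twice, following classical loess
semantics (k-nearest-neighbour window, tricube weights, low-degree local
polynomial, no robustness iterations):

* allele frequency smoothed against genomic position, per chromosome,
  with a window of a fixed number of markers (default 80);
* among-replicate SD smoothed against allele frequency, genome-wide,
  with a window of a fixed fraction of markers (default 0.10).

The implementation is deliberately self-contained: the windowing rule
(symmetric k-nearest by predictor distance, boundary ties included), the
tricube kernel and the zero-robustness-iteration Gaussian fit are part of
the method's definition here, and tests check it against a brute-force
weighted-least-squares oracle.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .errors import ParameterError

log = logging.getLogger(__name__)

__all__ = [
    "SmoothSpec",
    "SmoothedTrack",
    "loess_fit",
    "smooth_frequency_by_position",
    "smooth_sd_by_frequency",
]


@dataclass(frozen=True)
class SmoothSpec:
    """Window and polynomial settings for one smoothing pass.

    span_mode
        ``"points"``: the window holds ``span_value`` nearest markers.
        ``"fraction"``: the window holds ``ceil(span_value * N)`` markers.
    degree
        Local polynomial degree, 0-2.
    """

    span_mode: Literal["points", "fraction"] = "points"
    span_value: float = 80
    degree: int = 2

    def __post_init__(self) -> None:
        if self.degree not in (0, 1, 2):
            raise ParameterError(f"degree must be 0, 1 or 2, got {self.degree}")
        if self.span_value <= 0:
            raise ParameterError("span_value must be positive")
        if self.span_mode not in ("points", "fraction"):
            raise ParameterError(f"unknown span_mode {self.span_mode!r}")
        if self.span_mode == "fraction" and self.span_value > 1:
            raise ParameterError("fractional span must be in (0, 1]")

    def window_size(self, n: int) -> int:
        if self.span_mode == "points":
            k = int(self.span_value)
        else:
            k = math.ceil(self.span_value * n)
        return max(min(k, n), 1)


@dataclass
class SmoothedTrack:
    """A smoothing result: raw and fitted responses at the observed sites."""

    x: np.ndarray
    raw: np.ndarray
    fitted: np.ndarray
    spec: SmoothSpec


def loess_fit(x: np.ndarray, y: np.ndarray, spec: SmoothSpec) -> np.ndarray:
    """Fit a loess curve and return the fitted value at every input site.

    ``x`` must be sorted ascending (ties allowed; tied sites share one
    evaluation).  At each site the ``spec.window_size(n)`` nearest
    neighbours by predictor distance are selected (all boundary ties
    included), weighted by the tricube kernel
    ``w = (1 - (d/dmax)^3)^3``, and a degree-``spec.degree`` weighted
    least-squares polynomial is evaluated at the site.  No robustness
    iterations are performed.  A window in which all predictors coincide
    degenerates to the weighted mean.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or x.shape != y.shape:
        raise ParameterError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n == 0:
        return np.empty(0)
    if np.any(np.diff(x) < 0):
        raise ParameterError("x must be sorted ascending")
    k = spec.window_size(n)
    if k < spec.degree + 1:
        raise ParameterError(
            f"span of {k} points cannot support a degree-{spec.degree} fit"
        )

    fitted = np.empty(n)
    # Cache fits for tied predictor values: one evaluation per site.
    site_cache: dict[float, float] = {}
    lo, hi = 0, k  # sliding window [lo, hi) of the k nearest points
    for i in range(n):
        xi = x[i]
        if xi in site_cache:
            fitted[i] = site_cache[xi]
            continue
        # Advance the k-window so it holds the k nearest points to xi.
        while hi < n and x[hi] - xi < xi - x[lo]:
            lo += 1
            hi += 1
        # Include boundary ties: every point at distance exactly dmax.
        dmax = max(xi - x[lo], x[hi - 1] - xi)
        a, b = lo, hi
        while a > 0 and xi - x[a - 1] <= dmax:
            a -= 1
        while b < n and x[b] - xi <= dmax:
            b += 1
        xw = x[a:b]
        yw = y[a:b]
        d = np.abs(xw - xi)
        if dmax == 0:
            w = np.ones_like(d)
        else:
            w = (1.0 - (d / dmax) ** 3) ** 3
            w[w < 0] = 0.0
        fitted[i] = _weighted_polyfit_at(xw - xi, yw, w, spec.degree)
        site_cache[xi] = fitted[i]
    return fitted


def _weighted_polyfit_at(xc: np.ndarray, y: np.ndarray, w: np.ndarray,
                         degree: int) -> float:
    """Weighted LS polynomial in centred predictor; value at 0 = intercept."""
    pos = w > 0
    if pos.sum() == 0:  # dmax ties put weight 0 everywhere except centre
        pos = np.ones_like(w, dtype=bool)
        w = np.ones_like(w)
    xc, y, w = xc[pos], y[pos], w[pos]
    if np.ptp(xc) == 0.0 or degree == 0:
        return float(np.average(y, weights=w))
    # Scale the predictor to keep the Vandermonde matrix well conditioned.
    scale = np.max(np.abs(xc))
    xs = xc / scale
    X = np.vander(xs, degree + 1, increasing=True)
    sw = np.sqrt(w)
    beta, _, rank, _ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    if rank < degree + 1:
        log.debug("singular local design; falling back to weighted mean")
        return float(np.average(y, weights=w))
    return float(beta[0])


def smooth_frequency_by_position(
    positions: np.ndarray,
    chroms: np.ndarray,
    values: np.ndarray,
    spec: SmoothSpec | None = None,
) -> np.ndarray:
    """Smooth frequency columns against bp position, chromosome by chromosome.

    ``values`` is (n_markers, n_columns); each column (one subpool) is
    smoothed independently within each chromosome.  Chromosomes with
    fewer than 3 markers pass through unsmoothed.  Fitted frequencies
    are clipped to [0, 1].
    """
    if spec is None:
        spec = SmoothSpec("points", 80, 2)
    positions = np.asarray(positions)
    chroms = np.asarray(chroms)
    values = np.asarray(values, dtype=float)
    out = np.array(values, copy=True)
    for chrom in np.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        if idx.size < 3:
            log.info("chromosome %s has %d markers; left unsmoothed",
                     chrom, idx.size)
            continue
        order = idx[np.argsort(positions[idx], kind="stable")]
        x = positions[order].astype(float)
        for col in range(values.shape[1]):
            col_vals = values[order, col]
            ok = ~np.isnan(col_vals)
            if ok.sum() < 3:
                continue
            out[order[ok], col] = loess_fit(x[ok], col_vals[ok], spec)
    return np.clip(out, 0.0, 1.0)


def smooth_sd_by_frequency(
    sd: np.ndarray,
    freq: np.ndarray,
    spec: SmoothSpec | None = None,
) -> np.ndarray:
    """Smooth among-replicate SD against allele frequency, genome-wide.

    Markers are ordered by frequency for fitting and the fit is mapped
    back to the original marker order; negative fitted SDs are clipped
    to 0.  If every frequency coincides the global mean SD is returned.
    """
    if spec is None:
        spec = SmoothSpec("fraction", 0.10, 2)
    sd = np.asarray(sd, dtype=float)
    freq = np.asarray(freq, dtype=float)
    if sd.shape != freq.shape:
        raise ParameterError("sd and freq must be aligned")
    out = np.array(sd, copy=True)
    ok = ~(np.isnan(sd) | np.isnan(freq))
    if ok.sum() == 0:
        return out
    f, s = freq[ok], sd[ok]
    if np.ptp(f) == 0.0:
        log.info("all frequencies identical; returning global mean SD")
        out[ok] = s.mean()
        return np.clip(out, 0.0, None)
    order = np.argsort(f, kind="stable")
    fitted = loess_fit(f[order], s[order], spec)
    back = np.empty_like(fitted)
    back[order] = fitted
    out[ok] = back
    return np.clip(out, 0.0, None)
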