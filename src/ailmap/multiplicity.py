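"""Multiple-testing layer: true-null estimation, FDR thresholds, power table.

With tens of thousands of marker tests per trait, significance is declared
by the false discovery rate rather than a family-wise criterion.  The
number of true null markers ``n2`` is estimated from the P-value histogram
by an iterative excess-over-uniform procedure; ``n1 = N - n2`` estimates
the markers linked to a causative site.  Detection power at a given FDR
level is then the expected number of true discoveries over ``n1``::

    power = R * (1 - FDR) / n1

where R is the number of markers declared significant at that level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError

log = logging.getLogger(__name__)

DEFAULT_FDR_LEVELS = (0.001, 0.01, 0.05, 0.1, 0.2)

__all__ = [
    "MultiplicityReport", "estimate_true_nulls", "n1_from_n2",
    "fdr_threshold", "power_at_fdr", "build_report",
]


@dataclass
class MultiplicityReport:
    """N, the n1/n2 split, and one (critical P, R, power) row per FDR level."""

    N: int
    n2: int
    rows: pd.DataFrame = field(repr=False)

    @property
    def n1(self) -> int:
        return self.N - self.n2


def _as_pvalues(pvalues) -> np.ndarray:
    p = np.asarray(pvalues, dtype=float)
    p = p[~np.isnan(p)]
    if p.size == 0:
        raise ParameterError("no P-values supplied")
    if np.any((p <= 0) | (p > 1)):
        raise ParameterError("P-values must lie in (0, 1]")
    return p


def estimate_true_nulls(pvalues, bin_width: float = 0.10) -> int:
    """Estimate the number of true null hypotheses from the P histogram.

    Iterative procedure: starting from ``n2 = N``, find the lowest-P bin
    whose observed count does not exceed the count expected from ``n2``
    uniform nulls (``n2 * bin_width``); let ``p*`` be its left edge, and
    re-estimate ``n2 = #{p > p*} / (1 - p*)``.  Iterate to convergence
    (change < 0.5) and return ``n2`` rounded and clipped to [0, N].

    Bins above the excess region look uniform, so the tail count scaled
    by its width estimates the null density; the excess in the low bins
    is attributed to true associations.
    """
    p = _as_pvalues(pvalues)
    N = p.size
    if not 0 < bin_width < 1:
        raise ParameterError("bin_width must be in (0, 1)")
    nbins = int(round(1.0 / bin_width))
    edges = np.linspace(0.0, 1.0, nbins + 1)
    counts, _ = np.histogram(p, bins=edges)
    # histogram puts p == 1 in the last bin, consistent with (0, 1] support

    n2 = float(N)
    for _ in range(100):
        expected = n2 * bin_width
        ok = np.flatnonzero(counts <= expected)
        if ok.size == 0:
            # every bin over-full relative to the current null estimate:
            # only possible transiently; treat the last bin as null-like
            p_star = edges[-2]
        else:
            p_star = edges[ok[0]]
        if p_star >= 1.0:
            n2_new = 0.0
        else:
            n2_new = float(np.sum(p > p_star)) / (1.0 - p_star)
        if abs(n2_new - n2) < 0.5:
            n2 = n2_new
            break
        n2 = n2_new
    return int(np.clip(round(n2), 0, N))


def n1_from_n2(N: int, n2: int) -> int:
    """Estimated non-null (linked) marker count, n1 = N - n2."""
    if not 0 <= n2 <= N:
        raise ParameterError("n2 must lie in [0, N]")
    return N - n2


def fdr_threshold(pvalues, alpha: float, n2: int | None = None
                  ) -> tuple[float, int]:
    """Benjamini-Hochberg step-up threshold at level ``alpha``.

    Returns ``(critical_P, R)``: the largest sorted ``p(i)`` satisfying
    ``p(i) <= i * alpha / m`` and the number of P-values at or below it.
    ``m`` is the total test count N (plain BH) or, when ``n2`` is given,
    the estimated null count (adaptive variant).  ``(0.0, 0)`` if nothing
    qualifies; at ``alpha = 1`` everything does.
    """
    if not 0 < alpha <= 1:
        raise ParameterError("alpha must be in (0, 1]")
    p = np.sort(_as_pvalues(pvalues))
    N = p.size
    m = N if n2 is None else max(int(n2), 1)
    i = np.arange(1, N + 1)
    ok = p <= i * alpha / m
    if not ok.any():
        return 0.0, 0
    critical = float(p[np.flatnonzero(ok)[-1]])
    R = int(np.sum(p <= critical))
    return critical, R


def power_at_fdr(R: int, fdr_level: float, n1: int) -> float:
    """Expected true-discovery fraction of the non-nulls, R(1-FDR)/n1."""
    if n1 <= 0:
        return float("nan")
    if R < 0:
        raise ParameterError("R must be non-negative")
    return float(np.clip(R * (1.0 - fdr_level) / n1, 0.0, 1.0))


def build_report(pvalues, fdr_levels=DEFAULT_FDR_LEVELS,
                 bin_width: float = 0.10, adaptive: bool = False
                 ) -> MultiplicityReport:
    """Full multiplicity report: n2, n1, and per-FDR-level threshold rows.

    Rows are returned sorted by FDR level regardless of input order.  The
    power column is NaN when n1 = 0 (no estimated non-nulls).
    """
    p = _as_pvalues(pvalues)
    N = p.size
    n2 = estimate_true_nulls(p, bin_width=bin_width)
    n1 = n1_from_n2(N, n2)
    rows = []
    for level in sorted(fdr_levels):
        crit, R = fdr_threshold(p, level, n2=n2 if adaptive else None)
        rows.append({
            "fdr_level": level,
            "critical_P": crit,
            "n_significant": R,
            "power": power_at_fdr(R, level, n1) if n1 > 0 else float("nan"),
        })
    return MultiplicityReport(N=N, n2=n2, rows=pd.DataFrame(rows))
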