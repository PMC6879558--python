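"""Per-marker association tests for selective DNA pooling.

For each marker the YE-531 allele frequency difference between a selected
tail and the unselected control, ``D = mean(tail subpools) - mean(control
subpools)``, is standardised by an *empirical* standard error built from
the among-replicate variance of the three subpools in each category::

    SE^2(D) = VarS/3 + VarCtrl/3

where VarS and VarCtrl are the smoothed among-replicate variances of the
selected and control pools.  Z = D/SE is referred to the standard normal,
two-sided, giving a comparison-wise (per-marker) P-value.

Pipeline order is fixed: smooth frequencies by position, take subpool
means and among-replicate SDs, smooth the SDs by allele frequency, square
to variances, then D, SE, Z, P.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError
from .io_qc import FrequencyMatrix
from .loess import SmoothSpec, smooth_frequency_by_position, smooth_sd_by_frequency

log = logging.getLogger(__name__)

REPLICATES = 3
P_FLOOR = 1e-300


def sd_unbias_constant(n: int = REPLICATES) -> float:
    """Normal-theory c4(n): E[sample SD of n draws] = c4(n) * sigma.

    The among-replicate sample SD underestimates sigma in expectation
    (c4(3) ~ 0.886).  In a plain t statistic the compensating heavy tail
    of 1/s cancels this, but smoothing the SDs across thousands of
    markers makes the SE nearly deterministic at the *biased* value, so
    Z would be inflated by 1/c4.  Dividing the smoothed SD by c4 keeps
    the null Z standard normal.
    """
    from scipy.special import gammaln
    return float(np.sqrt(2.0 / (n - 1))
                 * np.exp(gammaln(n / 2.0) - gammaln((n - 1) / 2.0)))

__all__ = [
    "subpool_stats", "d_value", "standard_error", "cwer_test",
    "smooth_frequencies", "associate_trait",
]


def smooth_frequencies(freqs: FrequencyMatrix,
                       spec: SmoothSpec | None = None) -> FrequencyMatrix:
    """LOESS-smooth every (category, subpool) column against bp position."""
    if freqs.markers is None:
        raise ParameterError("FrequencyMatrix lacks marker positions")
    smoothed = smooth_frequency_by_position(
        freqs.markers["pos"].to_numpy(),
        freqs.markers["chrom"].to_numpy(),
        freqs.values.to_numpy(),
        spec,
    )
    values = pd.DataFrame(smoothed, index=freqs.values.index,
                          columns=freqs.values.columns)
    return FrequencyMatrix(values=values, stage="smoothed", markers=freqs.markers)


def subpool_stats(freqs: FrequencyMatrix, category: str
                  ) -> tuple[pd.Series, pd.Series]:
    """Per-marker mean and among-replicate sample variance (n-1 = 2).

    A marker with any missing subpool frequency is masked (NaN) for the
    category: the replicate variance would not be comparable.
    """
    sub = freqs.category(category)
    if sub.shape[1] != REPLICATES:
        raise ParameterError(
            f"category {category!r} has {sub.shape[1]} subpools, expected 3")
    complete = sub.notna().all(axis=1)
    if (~complete).any():
        log.info("%d markers masked in category %s (missing subpool values)",
                 int((~complete).sum()), category)
    mean = sub.mean(axis=1).where(complete)
    var = sub.var(axis=1, ddof=1).where(complete)
    return mean, var


def d_value(tail_mean, control_mean):
    """Allele-frequency difference D = tail - control (vectorised)."""
    return tail_mean - control_mean


def standard_error(var_tail, var_ctrl, replicates: int = REPLICATES):
    """SE(D) = sqrt(VarS/replicates + VarCtrl/replicates)."""
    return np.sqrt(np.asarray(var_tail, float) / replicates
                   + np.asarray(var_ctrl, float) / replicates)


def cwer_test(D, SE):
    """Z = D/SE and the two-sided comparison-wise P = 2(1 - Phi(|Z|)).

    Markers with SE <= 0 (or undefined) are masked: Z is undefined there.
    P is clamped to (1e-300, 1].
    """
    D = np.asarray(D, float)
    SE = np.asarray(SE, float)
    valid = np.isfinite(SE) & (SE > 0) & np.isfinite(D)
    Z = np.where(valid, D / np.where(valid, SE, 1.0), np.nan)
    P = np.where(valid, 2.0 * stats.norm.sf(np.abs(Z)), np.nan)
    P = np.clip(P, P_FLOOR, 1.0)
    P = np.where(valid, P, np.nan)
    return Z, P


def associate_trait(
    freqs: FrequencyMatrix,
    trait: str,
    control: str = "control",
    sd_spec: SmoothSpec | None = None,
    unbias_sd: bool = True,
) -> pd.DataFrame:
    """Full single-marker association scan for one trait.

    ``freqs`` must already be position-smoothed (stage ``"smoothed"``).
    Among-replicate SDs of both the trait and the control category are
    smoothed against the category's own mean allele frequency before
    squaring into the variance components of SE(D); with ``unbias_sd``
    (default) the smoothed SD is divided by the c4(3) constant so the
    null Z stays standard normal (see :func:`sd_unbias_constant`).

    Returns a DataFrame with columns ``chrom pos freq_ctrl freq_tail D SE
    Z P`` in marker order; masked markers carry NaN.
    """
    if freqs.stage != "smoothed":
        raise ParameterError("associate_trait expects position-smoothed input")
    tail_mean, tail_var = subpool_stats(freqs, trait)
    ctrl_mean, ctrl_var = subpool_stats(freqs, control)

    tail_sd_sm = smooth_sd_by_frequency(
        np.sqrt(tail_var.to_numpy(float)), tail_mean.to_numpy(float), sd_spec)
    ctrl_sd_sm = smooth_sd_by_frequency(
        np.sqrt(ctrl_var.to_numpy(float)), ctrl_mean.to_numpy(float), sd_spec)
    if unbias_sd:
        c4 = sd_unbias_constant(REPLICATES)
        tail_sd_sm = tail_sd_sm / c4
        ctrl_sd_sm = ctrl_sd_sm / c4

    D = d_value(tail_mean.to_numpy(float), ctrl_mean.to_numpy(float))
    SE = standard_error(tail_sd_sm ** 2, ctrl_sd_sm ** 2)
    Z, P = cwer_test(D, SE)

    out = pd.DataFrame({
        "chrom": freqs.markers["chrom"],
        "pos": freqs.markers["pos"],
        "freq_ctrl": ctrl_mean,
        "freq_tail": tail_mean,
        "D": D,
        "SE": SE,
        "Z": Z,
        "P": P,
    })
    out["trait"] = trait
    return out
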