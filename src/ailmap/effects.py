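"""Allele substitution effects from tail-vs-control frequency shifts.

Under truncation selection of a proportion ``alpha`` on a normally
distributed trait, an additive biallelic locus with substitution effect
``delta`` and allele frequencies p, q shifts in frequency between the
selected tail and the base population by approximately::

    E[D] = p * q * (delta / sigma_P) * i(alpha)

where ``i(alpha) = phi(Phi^-1(1 - alpha)) / alpha`` is the standardised
selection intensity.  Inverting gives the estimator used per marker::

    delta = D * sigma_P / (p * q * i)

A QTL's effect is the average over its top three markers (smallest P),
signed by the majority D sign, with p̄, q̄ the mean control frequencies
of the same markers; its variance contribution is ``VarQ = 2 p̄ q̄ delta²``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError
from .qtl import QTLInterval

log = logging.getLogger(__name__)

__all__ = [
    "SelectionScheme", "EffectEstimate", "selection_intensity",
    "allele_effect", "qtl_effect", "variance_contribution",
    "summarize_effects",
]


@dataclass(frozen=True)
class SelectionScheme:
    """The two-stage one-tail selection design of the experiment.

    Stage 1 keeps a fraction of the population (mass survival under
    stress), stage 2 the top fraction of an individually phenotyped
    sample, so the combined selected proportion is their product.  For a
    one-tail design the mapping power is equivalent to a two-tail design
    at twice the combined proportion; ``intensity_alpha`` chooses which
    proportion feeds the intensity function for effect estimation
    (default: the actual combined proportion).
    """

    stage1_proportion: float = 0.35
    stage2_proportion: float = 0.30
    design: str = "one_tail"
    intensity_alpha: float | None = None

    def __post_init__(self) -> None:
        for p in (self.stage1_proportion, self.stage2_proportion):
            if not 0 < p <= 1:
                raise ParameterError("selection proportions must be in (0, 1]")
        if self.design not in ("one_tail", "two_tail"):
            raise ParameterError(f"unknown design {self.design!r}")

    @property
    def combined(self) -> float:
        return self.stage1_proportion * self.stage2_proportion

    @property
    def equivalent_proportion(self) -> float:
        """Two-tail-equivalent selected proportion (2x combined, one tail)."""
        return 2 * self.combined if self.design == "one_tail" else self.combined

    @property
    def alpha(self) -> float:
        return self.intensity_alpha if self.intensity_alpha is not None \
            else self.combined

    @property
    def intensity(self) -> float:
        return selection_intensity(self.alpha)


@dataclass
class EffectEstimate:
    """Per-QTL effect: delta (trait units), frequencies and variance share."""

    qtl_id: str
    chrom: str
    peak_pos: int
    delta: float
    delta_sdu: float
    p_bar: float
    q_bar: float
    var_q: float
    var_fraction: float
    favorable_parent: str
    top_markers: list = field(default_factory=list)


def selection_intensity(alpha: float) -> float:
    """Standardised truncation-selection intensity i = phi(z)/alpha,
    with z the standard-normal quantile at 1 - alpha."""
    if not 0 < alpha < 1:
        raise ParameterError("selected proportion must be in (0, 1)")
    z = stats.norm.ppf(1.0 - alpha)
    return float(stats.norm.pdf(z) / alpha)


def allele_effect(D, sigma_P: float, p, q, i: float):
    """delta = D * sigma_P / (p * q * i); NaN where p or q is 0 or 1."""
    if sigma_P <= 0:
        raise ParameterError("sigma_P must be positive")
    if i <= 0:
        raise ParameterError("selection intensity must be positive")
    D = np.asarray(D, dtype=float)
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    pq = p * q
    with np.errstate(invalid="ignore", divide="ignore"):
        delta = np.where(pq > 0, D * sigma_P / (pq * i), np.nan)
    return delta if delta.ndim else float(delta)


def qtl_effect(
    qtl: QTLInterval,
    assoc: pd.DataFrame,
    sigma_P: float,
    scheme: SelectionScheme = SelectionScheme(),
    var_pheno: float | None = None,
    qtl_id: str = "",
) -> EffectEstimate:
    """Per-QTL effect estimate from its top three member markers.

    ``assoc`` is the trait's association table; ``qtl.member_idx`` holds
    its row labels.  The top three members by smallest P (ties by
    larger |D|, then position) supply the averaged |delta|, signed by the
    majority D sign, and the mean control frequencies p̄, q̄.  The wild
    parent (YE-531) is favourable when the signed effect is positive:
    D > 0 means its allele was enriched in the selected tail.
    """
    members = assoc.loc[qtl.member_idx].copy()
    members = members.dropna(subset=["P", "D", "freq_ctrl"])
    if members.empty:
        raise ParameterError(f"QTL {qtl_id or qtl.peak_pos} has no testable markers")
    members["absD"] = members["D"].abs()
    top = members.sort_values(["P", "absD", "pos"],
                              ascending=[True, False, True]).head(3)

    i = scheme.intensity
    p = top["freq_ctrl"].to_numpy(float)
    delta_per_marker = allele_effect(top["D"].to_numpy(float), sigma_P,
                                     p, 1.0 - p, i)
    sign = 1.0 if (top["D"] > 0).sum() * 2 >= len(top) else -1.0
    delta = sign * float(np.nanmean(np.abs(delta_per_marker)))
    p_bar = float(np.mean(p))
    q_bar = 1.0 - p_bar

    if var_pheno is None:
        var_pheno = sigma_P ** 2
    var_q, fraction = variance_contribution(delta, p_bar, q_bar, var_pheno)
    return EffectEstimate(
        qtl_id=qtl_id or f"{qtl.chrom}:{qtl.peak_pos}",
        chrom=qtl.chrom,
        peak_pos=qtl.peak_pos,
        delta=delta,
        delta_sdu=delta / sigma_P,
        p_bar=p_bar,
        q_bar=q_bar,
        var_q=var_q,
        var_fraction=fraction,
        favorable_parent="YE-531" if delta >= 0 else "S288c",
        top_markers=list(top["pos"]),
    )


def variance_contribution(delta: float, p_bar: float, q_bar: float,
                          var_pheno: float) -> tuple[float, float]:
    """VarQ = 2 p̄ q̄ delta² and its fraction of the phenotypic variance."""
    if var_pheno <= 0:
        raise ParameterError("phenotypic variance must be positive")
    var_q = 2.0 * p_bar * q_bar * delta ** 2
    return var_q, var_q / var_pheno


def summarize_effects(estimates: list[EffectEstimate], sigma_P: float,
                      trait_mean: float | None = None,
                      heritability: float | None = None) -> dict:
    """Trait-level effect summary: mean/range of delta (trait units and
    s.d.u.), percent of the trait mean, and total variance explained —
    also as a fraction of the *genetic* variance when h² is supplied."""
    if sigma_P <= 0:
        raise ParameterError("sigma_P must be positive")
    summary: dict = {"n_qtls": len(estimates)}
    if not estimates:
        return summary
    d = np.array([abs(e.delta) for e in estimates])
    summary["mean_delta"] = float(d.mean())
    summary["min_delta"] = float(d.min())
    summary["max_delta"] = float(d.max())
    summary["mean_delta_sdu"] = float((d / sigma_P).mean())
    summary["min_delta_sdu"] = float((d / sigma_P).min())
    summary["max_delta_sdu"] = float((d / sigma_P).max())
    if trait_mean:
        summary["mean_percent_of_mean"] = float(100.0 * (d / trait_mean).mean())
    fractions = np.array([e.var_fraction for e in estimates])
    summary["mean_var_fraction"] = float(fractions.mean())
    summary["total_var_fraction"] = float(fractions.sum())
    if heritability:
        summary["genetic_var_fraction"] = float(
            min(1.0, fractions.sum() / heritability))
    return summary
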