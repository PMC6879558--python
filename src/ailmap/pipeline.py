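"""End-to-end orchestration: QC -> smoothing -> testing -> FDR -> QTLs -> effects.

A run is described by one declarative config (YAML on disk or a
:class:`RunConfig` in memory) naming the input marker table (or a
simulation spec), the traits to map, and every numeric tuning parameter.
Outputs are plain-text tables plus a JSON report bundle that records the
full effective configuration and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association, io_qc, multiplicity, qtl, simulate
from .effects import SelectionScheme, qtl_effect, summarize_effects
from .errors import AilmapError, ConfigurationError
from .loess import SmoothSpec

log = logging.getLogger(__name__)

TRAITS = ("growth", "survival")


@dataclass
class RunConfig:
    """Every tunable of a mapping run, with the study's defaults."""

    input_table: str | None = None
    simulation: simulate.SimConfig | None = None
    traits: tuple[str, ...] = TRAITS
    out_dir: str = "ailmap_out"
    seed: int = 0
    # QC
    maf_min: float = 0.05
    dual_ref_tol: float = 0.01
    parent_min_coverage: int = 10
    # LOESS
    position_span_points: int = 80
    sd_span_fraction: float = 0.10
    degree: int = 2
    # multiplicity
    fdr_alpha: float = 0.2
    fdr_levels: tuple[float, ...] = multiplicity.DEFAULT_FDR_LEVELS
    adaptive_bh: bool = False
    null_bin_width: float = 0.10
    # effects
    sigma_p: dict = field(default_factory=lambda: {"growth": 0.148,
                                                   "survival": 2.75})
    trait_mean: dict = field(default_factory=dict)
    heritability: float | None = None
    selection: SelectionScheme = field(default_factory=SelectionScheme)
    # annotation
    gene_annotation: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulation", None)
        sel = raw.pop("selection", None)
        cfg = cls(**{k: v for k, v in raw.items()
                     if k in {f.name for f in dataclasses.fields(cls)}})
        if sim is not None:
            qtls = tuple(simulate.QTLSpec(**q) for q in sim.pop("qtl_truth", []))
            cfg.simulation = simulate.SimConfig(qtl_truth=qtls, **sim)
        if sel is not None:
            cfg.selection = SelectionScheme(**sel)
        if isinstance(cfg.traits, list):
            cfg.traits = tuple(cfg.traits)
        return cfg


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline for each trait; write and return the bundle.

    Stages (per trait): marker QC -> LOESS frequency smoothing by
    position -> subpool means/SDs -> SD smoothing by frequency -> D, SE,
    Z, P -> true-null estimation and FDR thresholding -> 1-log-drop QTL
    calling -> per-QTL allele effects.  Any stage error is re-raised with
    the stage name attached.
    """
    if not config.traits:
        raise ConfigurationError("config names no traits to map")
    bad = [t for t in config.traits if t not in TRAITS]
    if bad:
        raise ConfigurationError(f"unknown trait(s): {', '.join(bad)}")

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"traits": {}, "seed": config.seed}

    def _stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except AilmapError as exc:
            raise type(exc)(f"[stage {name}] {exc}") from exc

    # ---- input ----
    truth = None
    if config.simulation is not None:
        sim_cfg = dataclasses.replace(config.simulation, seed=config.seed)
        markers, truth = _stage("simulate", simulate.simulate_experiment, sim_cfg)
        simulate.emit(markers, truth, out / "simulation")
    elif config.input_table is not None:
        markers = _stage("read", io_qc.read_marker_table, config.input_table)
    else:
        raise ConfigurationError("config names neither input_table nor simulation")

    # ---- QC ----
    markers, qc_report = _stage("qc", io_qc.filter_markers, markers,
                                maf_min=config.maf_min,
                                dual_ref_tol=config.dual_ref_tol,
                                parent_min_coverage=config.parent_min_coverage)
    bundle["qc"] = dataclasses.asdict(qc_report)

    # ---- smoothing ----
    freqs = io_qc.frequencies(markers)
    pos_spec = SmoothSpec("points", config.position_span_points, config.degree)
    sd_spec = SmoothSpec("fraction", config.sd_span_fraction, config.degree)
    smoothed = _stage("smoothing", association.smooth_frequencies, freqs, pos_spec)

    genes = (qtl.read_gene_annotation(config.gene_annotation)
             if config.gene_annotation else None)

    for trait in config.traits:
        tb: dict = {}
        assoc = _stage("association", association.associate_trait,
                       smoothed, trait, sd_spec=sd_spec)
        assoc_path = out / f"association_{trait}.tsv"
        assoc.to_csv(assoc_path, sep="\t", index=False, float_format="%.6g")

        pvals = assoc["P"].dropna()
        report = _stage("multiplicity", multiplicity.build_report, pvals,
                        fdr_levels=config.fdr_levels,
                        bin_width=config.null_bin_width,
                        adaptive=config.adaptive_bh)
        report.rows.to_csv(out / f"multiplicity_{trait}.tsv", sep="\t",
                           index=False)
        tb["multiplicity"] = {"N": report.N, "n1": report.n1, "n2": report.n2}

        crit_row = report.rows[np.isclose(report.rows["fdr_level"],
                                          config.fdr_alpha)]
        critical_P = float(crit_row["critical_P"].iloc[0]) if len(crit_row) \
            else multiplicity.fdr_threshold(pvals, config.fdr_alpha)[0]
        tb["critical_P"] = critical_P

        qtls = _stage("qtl_calling", qtl.call_qtls_genome, assoc, critical_P,
                      trait=trait)
        qtl.qtls_to_bed(qtls).to_csv(out / f"qtls_{trait}.bed", sep="\t",
                                     index=False, header=False)
        qtl_rows = pd.DataFrame({
            "qtl_id": [f"{trait}_qtl_{i + 1}" for i in range(len(qtls))],
            "chrom": [q.chrom for q in qtls],
            "start": [q.start for q in qtls],
            "end": [q.end for q in qtls],
            "peak_pos": [q.peak_pos for q in qtls],
            "peak_neglog10P": [round(q.peak_score, 4) for q in qtls],
            "length_bp": [q.length_bp for q in qtls],
            "n_markers": [len(q.member_idx) for q in qtls],
        })
        qtl_rows.to_csv(out / f"qtls_{trait}.tsv", sep="\t", index=False)
        tb["qtl_summary"] = qtl.summarize_qtls(qtls, genes)

        sigma = config.sigma_p.get(trait, 1.0)
        estimates = [
            _stage("effects", qtl_effect, q, assoc, sigma,
                   scheme=config.selection, qtl_id=f"{trait}_qtl_{i + 1}")
            for i, q in enumerate(qtls)
        ]
        eff = pd.DataFrame([{
            "qtl_id": e.qtl_id, "chrom": e.chrom, "peak": e.peak_pos,
            "delta": e.delta, "delta_sdu": e.delta_sdu, "p_bar": e.p_bar,
            "VarQ": e.var_q, "var_fraction": e.var_fraction,
            "favorable_parent": e.favorable_parent,
        } for e in estimates])
        eff.to_csv(out / f"effects_{trait}.tsv", sep="\t", index=False,
                   float_format="%.6g")
        tb["effects_summary"] = summarize_effects(
            estimates, sigma, trait_mean=config.trait_mean.get(trait),
            heritability=config.heritability)
        tb["qtls"] = qtl_rows.to_dict(orient="records")
        bundle["traits"][trait] = tb
        bundle["traits"][trait]["_qtl_objects"] = qtls  # in-memory only

    # ---- cross-trait overlap ----
    if len(config.traits) == 2:
        a, b = (bundle["traits"][t].pop("_qtl_objects") for t in config.traits)
        pairs = qtl.overlap_qtls(a, b)
        pd.DataFrame([{
            "chrom": x.chrom,
            f"{config.traits[0]}_start": x.start, f"{config.traits[0]}_end": x.end,
            f"{config.traits[1]}_start": y.start, f"{config.traits[1]}_end": y.end,
        } for x, y in pairs]).to_csv(out / "qtl_overlaps.tsv", sep="\t",
                                     index=False)
        bundle["n_overlaps"] = len(pairs)
    else:
        for t in config.traits:
            bundle["traits"][t].pop("_qtl_objects", None)

    bundle["config"] = _config_snapshot(config)
    (out / "report.json").write_text(json.dumps(bundle, indent=1, default=str))
    if truth is not None:
        bundle["truth"] = truth
    return bundle


def _config_snapshot(config: RunConfig) -> dict:
    snap = dataclasses.asdict(config)
    return json.loads(json.dumps(snap, default=str))
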