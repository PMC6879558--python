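"""Shared fixtures: small marker tables and seeded simulated experiments."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from ailmap import io_qc
from ailmap.pipeline import RunConfig, run_pipeline
from ailmap.simulate import QTLSpec, SimConfig


def make_marker_table(n: int = 3, seed: int = 0,
                      counts: np.ndarray | None = None) -> pd.DataFrame:
    """A small well-formed marker table; counts default to depth-100 pools
    at frequency 0.5 plus noise."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({
        "chrom": ["chr01"] * n,
        "pos": np.arange(1, n + 1) * 1000,
        "allele_s288c": ["A"] * n,
        "allele_ye531": ["G"] * n,
    })
    for col in io_qc.count_columns():
        if col.endswith("ye531"):
            vals = counts if counts is not None else rng.binomial(100, 0.5, n)
            df[col] = vals
        else:
            df[col] = 100 - df[col.replace("_other", "_ye531")]
    return df


def freq_matrix_from_columns(cols: dict, chrom=None, pos=None
                             ) -> io_qc.FrequencyMatrix:
    """Build a (possibly 'pre-smoothed') FrequencyMatrix directly from
    per-(category, subpool) frequency arrays."""
    values = pd.DataFrame(cols)
    values.columns = pd.MultiIndex.from_tuples(values.columns,
                                               names=["category", "subpool"])
    n = len(values)
    markers = pd.DataFrame({
        "chrom": chrom if chrom is not None else ["chr01"] * n,
        "pos": pos if pos is not None else np.arange(1, n + 1) * 1000,
    })
    return io_qc.FrequencyMatrix(values=values, stage="smoothed",
                                 markers=markers)


# --- the shared end-to-end recovery run (computed once per session) --------

RECOVERY_SEED = 11


def recovery_sim_config() -> SimConfig:
    """Ten QTLs of small/moderate/large effect, one per chromosome, under
    the study's selection design (35% -> 300 -> top 90, 3x30 subpools,
    1000x coverage) on a desk-scale genome."""
    base = SimConfig(chrom_lengths=(250_000,) * 10, markers_per_chrom=250,
                     pop_size=3000, h2=0.5, coverage=1000.0,
                     seed=RECOVERY_SEED)
    deltas = [0.1] * 4 + [0.2] * 3 + [0.4] * 3
    parents = ["YE-531"] * 9 + ["S288c"]
    qtls = tuple(
        QTLSpec(c, int(base.positions(c)[125]), d, favorable_parent=p)
        for c, (d, p) in enumerate(zip(deltas, parents)))
    return dataclasses.replace(base, qtl_truth=qtls)


@pytest.fixture(scope="session")
def recovery_run(tmp_path_factory):
    """Full pipeline output + ground truth for the recovery simulation."""
    out = tmp_path_factory.mktemp("recovery")
    cfg = RunConfig(simulation=recovery_sim_config(), out_dir=str(out),
                    seed=RECOVERY_SEED, traits=("growth", "survival"))
    bundle = run_pipeline(cfg)
    bundle["out_dir"] = out
    return bundle


def match_truth_to_calls(truth_qtls, called, trait="growth",
                         radius=25_000):
    """For each truth QTL: distance to the nearest called interval on its
    chromosome (None if the chromosome has no calls) and the matched call
    index when within ``radius``."""
    rows = []
    for q in truth_qtls:
        pos, chrom = q["pos"], q["chrom_label"]
        best, dist = None, None
        for i, c in enumerate(called):
            if c["chrom"] != chrom:
                continue
            if c["start"] <= pos <= c["end"]:
                d = 0
            else:
                d = min(abs(c["start"] - pos), abs(c["end"] - pos))
            if dist is None or d < dist:
                dist, best = d, i
        matched = best if (dist is not None and dist <= radius) else None
        rows.append({"truth": q, "distance": dist, "call_index": matched})
    return rows
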