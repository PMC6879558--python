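"""Forward simulation of the whole pooled-mapping experiment.

The generator emulates the study design end to end so that the inference
chain can be verified by parameter recovery:

* two fully diverged haploid founders (every marker fixed-different), an
  F1 heterozygous everywhere, then five rounds of random intercrossing
  with Haldane (no-interference, Poisson) recombination and drift;
* additive QTLs with configurable substitution effects placed at marker
  positions; phenotypes with a target heritability, the survival trait
  discretised to a 0-14 score;
* two-stage one-tail selection: mass survival of the top 35% on the
  survival phenotype (shared by both traits), then the top 90 of a random
  300 by each trait's own phenotype;
* pooling into 3 replicate subpools of 30 diploids and binomial
  sequencing noise at Poisson-distributed depth (default mean 1,000x).

Everything is driven by one :class:`numpy.random.Generator` seeded from
``SimConfig.seed``; identical configs give identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io_qc
from .errors import ConfigurationError, ParameterError

log = logging.getLogger(__name__)

__all__ = [
    "QTLSpec", "SimConfig", "SimTruth", "make_parents", "meiosis",
    "advance_generations", "assign_phenotypes", "two_stage_select",
    "pool_and_sequence", "simulate_experiment", "emit", "binomial_drift_sd",
]


@dataclass(frozen=True)
class QTLSpec:
    """One true QTL.

    ``delta`` is the per-allele substitution effect on the latent trait
    scale: each copy of the favourable allele adds ``delta`` to the
    genotypic value, so the homozygote difference is ``2*delta`` and the
    locus contributes ``2*p*q*delta^2`` to the genetic variance.  The
    realized phenotypic SD (recorded in the simulation truth) converts
    it to s.d.u.
    """

    chrom: int
    pos: int
    delta: float
    favorable_parent: str = "YE-531"
    trait: str = "both"  # growth | survival | both

    def __post_init__(self) -> None:
        if self.favorable_parent not in ("YE-531", "S288c"):
            raise ConfigurationError(
                f"unknown parent {self.favorable_parent!r}")
        if self.trait not in ("growth", "survival", "both"):
            raise ConfigurationError(f"unknown trait {self.trait!r}")

    def affects(self, trait: str) -> bool:
        return self.trait in (trait, "both")


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of a simulated experiment.

    Defaults mirror the mapped experiment: six AIL generations (five
    intercross rounds after the F1), 35% stage-1 mass survival, top 90 of
    a random 300 in stage 2, 3 subpools of 30 diploids per category, and
    ~1,000x pooled coverage.  ``recomb_rate_cm_per_kb`` defaults to a
    yeast-like 0.38 cM/kb.  ``pop_size`` defaults to 10,000 — large
    enough that intercross drift is modest, small enough to simulate on a
    desktop (the real population exceeded 1e5).
    """

    chrom_lengths: tuple[int, ...] = (300_000, 300_000)
    markers_per_chrom: int = 300
    recomb_rate_cm_per_kb: float = 0.38
    n_generations: int = 6
    pop_size: int = 10_000
    qtl_truth: tuple[QTLSpec, ...] = ()
    h2: float = 0.5
    stage1_fraction: float = 0.35
    stage2_sample: int = 300
    stage2_top: int = 90
    subpools: int = 3
    subpool_size: int = 30
    coverage: float = 1_000.0
    base_error: float = 0.0
    drift_amplification: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stage2_top > self.stage2_sample:
            raise ConfigurationError("stage2_top must not exceed stage2_sample")
        for f in (self.stage1_fraction,):
            if not 0 < f <= 1:
                raise ConfigurationError("fractions must be in (0, 1]")

    # -- genome layout -----------------------------------------------------
    @property
    def n_chrom(self) -> int:
        return len(self.chrom_lengths)

    def positions(self, chrom: int) -> np.ndarray:
        """1-based marker positions, evenly spaced along the chromosome."""
        length = self.chrom_lengths[chrom]
        m = self.markers_per_chrom
        return np.unique(np.round(np.linspace(1, length, m)).astype(np.int64))

    def marker_frame(self) -> pd.DataFrame:
        frames = [pd.DataFrame({"chrom": f"chr{c + 1:02d}",
                                "pos": self.positions(c)})
                  for c in range(self.n_chrom)]
        return pd.concat(frames, ignore_index=True)

    def genetic_positions(self, chrom: int) -> np.ndarray:
        """Marker positions in Morgans (linear map, constant cM/kb)."""
        morgans_per_bp = self.recomb_rate_cm_per_kb / 1e5
        return self.positions(chrom).astype(float) * morgans_per_bp

    def chrom_slices(self) -> list[slice]:
        sizes = [self.positions(c).size for c in range(self.n_chrom)]
        edges = np.concatenate([[0], np.cumsum(sizes)])
        return [slice(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:])]

    def qtl_marker_index(self, qtl: QTLSpec) -> int:
        """Flat marker index of a truth QTL; the position must be a marker."""
        sl = self.chrom_slices()[qtl.chrom]
        pos = self.positions(qtl.chrom)
        hits = np.flatnonzero(pos == qtl.pos)
        if hits.size == 0:
            raise ConfigurationError(
                f"QTL at chr{qtl.chrom + 1}:{qtl.pos} is not at a marker; "
                f"nearest marker is {pos[np.argmin(np.abs(pos - qtl.pos))]}")
        return sl.start + int(hits[0])


@dataclass
class SimTruth:
    """Ground truth of one simulated experiment."""

    config: SimConfig
    qtls: list[dict]
    tail_members: dict
    control_members: dict
    subpool_true_freq: dict
    sigma_p: dict = field(default_factory=dict)
    phenotypes: dict = field(repr=False, default_factory=dict)


# ---------------------------------------------------------------------------
# genetics engine


def make_parents(config: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """The founder haplotypes: S288c all-0, YE-531 all-1 (one row each)."""
    m = sum(config.positions(c).size for c in range(config.n_chrom))
    return np.zeros(m, dtype=np.uint8), np.ones(m, dtype=np.uint8)


def _f1_population(config: SimConfig) -> np.ndarray:
    a, b = make_parents(config)
    pop = np.empty((config.pop_size, 2, a.size), dtype=np.uint8)
    pop[:, 0, :] = a
    pop[:, 1, :] = b
    return pop


def _gametes(haps: np.ndarray, config: SimConfig,
             rng: np.random.Generator) -> np.ndarray:
    """One recombinant gamete per diploid in ``haps`` (K, 2, M) -> (K, M).

    Crossovers per chromosome are Poisson with mean equal to the map
    length in Morgans, positions uniform on the genetic map (Haldane, no
    interference); the starting haplotype is chosen at random.
    """
    K, _, M = haps.shape
    out = np.empty((K, M), dtype=np.uint8)
    for c, sl in enumerate(config.chrom_slices()):
        g = config.genetic_positions(c)
        span = float(g[-1] - g[0]) if g.size > 1 else 0.0
        start = rng.integers(0, 2, size=K).astype(np.uint8)
        counts = np.zeros((K, g.size), dtype=np.int64)
        if span > 0:
            n_xo = rng.poisson(span, size=K)
            kmax = int(n_xo.max()) if K else 0
            for col in range(kmax):
                active = n_xo > col
                u = rng.uniform(g[0], g[-1], size=K)
                # crossover col only exists for gametes with n_xo > col
                counts += (active[:, None] & (u[:, None] < g[None, :]))
        parity = (counts + start[:, None]) % 2
        h0 = haps[:, 0, sl]
        h1 = haps[:, 1, sl]
        out[:, sl] = np.where(parity == 0, h0, h1)
    return out


def meiosis(diploid: np.ndarray, config: SimConfig,
            rng: np.random.Generator) -> np.ndarray:
    """A single recombinant gamete from one diploid genome (2, M)."""
    return _gametes(diploid[None, :, :], config, rng)[0]


def advance_generations(config: SimConfig,
                        rng: np.random.Generator) -> np.ndarray:
    """Random intercrossing from the F1 to the F(n_generations) population.

    Each round pairs gametes from parents drawn with replacement.  A
    ``drift_amplification`` factor > 1 shrinks the effective parent pool,
    emulating extra frequency variance from clonal reproduction and
    fitness selection between sexual generations (default: off).
    """
    pop = _f1_population(config)
    n = config.pop_size
    n_eff = max(2, int(round(n / config.drift_amplification)))
    for _ in range(config.n_generations - 1):
        pool = pop if n_eff == n else pop[rng.choice(n, size=n_eff,
                                                     replace=False)]
        p1 = pool[rng.integers(0, len(pool), size=n)]
        p2 = pool[rng.integers(0, len(pool), size=n)]
        new = np.empty_like(pop)
        new[:, 0, :] = _gametes(p1, config, rng)
        new[:, 1, :] = _gametes(p2, config, rng)
        pop = new
    return pop


# ---------------------------------------------------------------------------
# phenotypes and selection


@dataclass
class Phenotypes:
    """Latent (continuous) and observed phenotype plus genetic values."""

    trait: str
    latent: np.ndarray
    value: np.ndarray
    genetic: np.ndarray


def assign_phenotypes(pop: np.ndarray, config: SimConfig, trait: str,
                      rng: np.random.Generator) -> Phenotypes:
    """Additive phenotypes at the target heritability.

    The genotypic value sums ``(favourable allele count) * delta`` over
    the trait's QTLs (``delta`` the per-allele substitution effect);
    Gaussian noise is scaled so that Var(genetic)/Var(total) equals
    ``h2``.  The survival trait is additionally discretised to a 0-14
    score by equal-probability thresholds on the latent scale.
    """
    n = pop.shape[0]
    genetic = np.zeros(n)
    for q in config.qtl_truth:
        if not q.affects(trait):
            continue
        idx = config.qtl_marker_index(q)
        dosage = pop[:, 0, idx].astype(float) + pop[:, 1, idx]
        if q.favorable_parent == "S288c":
            dosage = 2.0 - dosage
        genetic += dosage * q.delta

    var_g = genetic.var()
    h2 = config.h2
    if h2 <= 0:
        latent = rng.normal(0.0, 1.0, size=n)  # trait carries no signal
    elif var_g == 0:
        latent = genetic + rng.normal(0.0, 1.0, size=n)
    elif h2 >= 1:
        # infinitesimal tie-break noise keeps ranking well defined
        latent = genetic + rng.normal(0.0, 1e-9, size=n)
    else:
        var_e = var_g * (1.0 - h2) / h2
        latent = genetic + rng.normal(0.0, np.sqrt(var_e), size=n)

    if trait == "survival":
        qs = np.quantile(latent, np.arange(1, 15) / 15.0)
        value = np.searchsorted(qs, latent, side="right").astype(float)
    else:
        value = latent
    return Phenotypes(trait=trait, latent=latent, value=value, genetic=genetic)


def two_stage_select(phen: dict[str, Phenotypes], config: SimConfig,
                     rng: np.random.Generator) -> dict[str, np.ndarray]:
    """The two-stage one-tail selection; returns tail indices per trait.

    Stage 1 (shared): the top ``stage1_fraction`` of the population by
    the survival phenotype.  Stage 2 (per trait): a uniform sample of
    ``stage2_sample`` survivors is ranked by the trait's own phenotype
    and the top ``stage2_top`` kept.  Ties are broken at random.
    """
    n = phen["survival"].value.size
    n_surv = int(np.ceil(config.stage1_fraction * n))
    if n_surv < config.stage2_sample:
        raise ConfigurationError(
            "population too small for the two-stage selection design: "
            f"{n_surv} stage-1 survivors < stage2_sample={config.stage2_sample}")
    jitter = rng.permutation(n)  # random tie-break for the discrete score
    order = np.lexsort((jitter, -phen["survival"].value))
    survivors = order[:n_surv]

    tails = {}
    for trait in ("growth", "survival"):
        sample = rng.choice(survivors, size=config.stage2_sample, replace=False)
        jit = rng.permutation(sample.size)
        rank = np.lexsort((jit, -phen[trait].value[sample]))
        tails[trait] = np.sort(sample[rank[:config.stage2_top]])
    return tails


# ---------------------------------------------------------------------------
# pooling and sequencing


def pool_and_sequence(individuals: np.ndarray | None, pop: np.ndarray,
                      config: SimConfig, rng: np.random.Generator
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray, list]:
    """Split into subpools, compute true pool frequencies, draw reads.

    ``individuals`` is the selected tail (partitioned at random into the
    3 subpools) or None for the control category, which is realised as 3
    independent random samples of ``subpool_size`` from the whole F6.
    Returns (ye_counts, other_counts, true_freqs) of shape (3, M) —
    zero-depth markers carry 0/0 counts, i.e. missing — plus the subpool
    memberships.
    """
    m = pop.shape[2]
    ye = np.zeros((config.subpools, m), dtype=np.int64)
    other = np.zeros((config.subpools, m), dtype=np.int64)
    true_f = np.zeros((config.subpools, m))
    memberships = []
    if individuals is not None:
        perm = rng.permutation(individuals)
        groups = [perm[j * config.subpool_size:(j + 1) * config.subpool_size]
                  for j in range(config.subpools)]
    else:
        groups = [rng.choice(pop.shape[0], size=config.subpool_size,
                             replace=False)
                  for _ in range(config.subpools)]
    for j, grp in enumerate(groups):
        memberships.append(np.sort(grp).tolist())
        dosage = pop[grp].sum(axis=1)          # (30, M) in {0, 1, 2}
        f = dosage.mean(axis=0) / 2.0
        true_f[j] = f
        f_obs = f * (1 - config.base_error) + (1 - f) * config.base_error
        depth = rng.poisson(config.coverage, size=m)
        ye[j] = rng.binomial(depth, f_obs)
        other[j] = depth - ye[j]
    return ye, other, true_f, memberships


# ---------------------------------------------------------------------------
# experiment driver


def simulate_experiment(config: SimConfig) -> tuple[pd.DataFrame, SimTruth]:
    """Run the full simulated experiment; return the marker table + truth."""
    rng = np.random.default_rng(config.seed)
    pop = advance_generations(config, rng)
    phen = {t: assign_phenotypes(pop, config, t, rng)
            for t in ("growth", "survival")}
    tails = two_stage_select(phen, config, rng)

    markers = config.marker_frame()
    markers["allele_s288c"] = "A"
    markers["allele_ye531"] = "G"

    truth_freq: dict = {}
    members: dict = {}
    for cat in ("growth", "survival", "control"):
        sel = tails.get(cat)
        ye, other, tf, grp = pool_and_sequence(sel, pop, config, rng)
        truth_freq[cat] = tf
        members[cat] = grp
        for j in range(config.subpools):
            depth = ye[j] + other[j]
            # zero-depth markers are missing ('.') in the emitted table
            markers[f"cnt_{cat}_{j + 1}_ye531"] = \
                pd.array(ye[j], dtype="Int64")
            markers[f"cnt_{cat}_{j + 1}_other"] = \
                pd.array(other[j], dtype="Int64")
            markers.loc[depth == 0, [f"cnt_{cat}_{j + 1}_ye531",
                                     f"cnt_{cat}_{j + 1}_other"]] = pd.NA

    pop_freq = pop.mean(axis=(0, 1))
    sigma_p = {t: float(phen[t].latent.std()) for t in phen}
    qtl_truth = []
    for q in config.qtl_truth:
        idx = config.qtl_marker_index(q)
        rec = dataclasses.asdict(q)
        rec["marker_index"] = idx
        rec["chrom_label"] = f"chr{q.chrom + 1:02d}"
        rec["pop_freq_ye531"] = float(pop_freq[idx])
        for trait in ("growth", "survival"):
            if q.affects(trait):
                tail_f = float(pop[tails[trait], :, idx].mean())
                rec[f"realized_shift_{trait}"] = tail_f - float(pop_freq[idx])
                rec[f"delta_sdu_{trait}"] = q.delta / sigma_p[trait]
        qtl_truth.append(rec)

    truth = SimTruth(
        config=config,
        sigma_p=sigma_p,
        qtls=qtl_truth,
        tail_members={t: np.sort(v).tolist() for t, v in tails.items()},
        control_members={"control": members["control"]},
        subpool_true_freq={k: v.tolist() for k, v in truth_freq.items()},
        phenotypes={t: {"value": phen[t].value.tolist()} for t in phen}
        if config.pop_size <= 2_000 else {},
    )
    return markers, truth


def emit(markers: pd.DataFrame, truth: SimTruth, outdir) -> dict[str, Path]:
    """Write the marker table, ground truth and config snapshot to disk."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "markers": outdir / "markers.tsv",
        "truth": outdir / "truth.json",
        "config": outdir / "sim_config.json",
    }
    io_qc.write_marker_table(markers, paths["markers"])
    truth_payload = {
        "sigma_p": truth.sigma_p,
        "qtls": truth.qtls,
        "tail_members": truth.tail_members,
        "control_members": truth.control_members,
        "subpool_true_freq": truth.subpool_true_freq,
    }
    paths["truth"].write_text(json.dumps(truth_payload, indent=1))
    cfg = dataclasses.asdict(truth.config)
    paths["config"].write_text(json.dumps(cfg, indent=1, default=list))
    return paths


# ---------------------------------------------------------------------------
# drift


def binomial_drift_sd(p0: float = 0.5, effective_size: int = 1_000,
                      generations: int = 6, replicates: int = 10_000,
                      seed: int | np.random.Generator = 0) -> float:
    """SD of allele frequency after pure binomial drift.

    Each replicate lineage resamples ``effective_size`` allele copies per
    generation starting from ``p0``; returns the across-replicate SD of
    the final frequency.  The closed form is
    ``sqrt(p0 q0 (1 - (1 - 1/N)^t))``.
    """
    if not 0 <= p0 <= 1:
        raise ParameterError("p0 must be in [0, 1]")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    p = np.full(replicates, p0)
    for _ in range(generations):
        p = rng.binomial(effective_size, p) / effective_size
    return float(p.std(ddof=1))
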