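"""Forward simulator: recombination, drift, phenotypes, selection, pooling."""

import dataclasses
import json

import numpy as np
import pytest

from ailmap import io_qc
from ailmap.errors import ConfigurationError
from ailmap.simulate import (QTLSpec, SimConfig, advance_generations,
                             assign_phenotypes, binomial_drift_sd, emit,
                             make_parents, meiosis, pool_and_sequence,
                             simulate_experiment, two_stage_select)
from ailmap.effects import selection_intensity


def small_config(**kw):
    defaults = dict(chrom_lengths=(100_000,), markers_per_chrom=50,
                    pop_size=1000, seed=0)
    defaults.update(kw)
    return SimConfig(**defaults)


class TestParentsAndMeiosis:
    def test_f1_frequency_exactly_half_everywhere(self):
        cfg = small_config()
        a, b = make_parents(cfg)
        assert a.sum() == 0 and b.sum() == b.size
        diploid = np.stack([a, b])
        assert diploid.mean() == 0.5

    def test_zero_map_length_returns_parental_haplotype(self):
        cfg = small_config(recomb_rate_cm_per_kb=0.0)
        a, b = make_parents(cfg)
        rng = np.random.default_rng(1)
        for _ in range(10):
            g = meiosis(np.stack([a, b]), cfg, rng)
            assert np.array_equal(g, a) or np.array_equal(g, b)

    def test_single_marker_transmission_is_mendelian(self):
        cfg = small_config()
        a, b = make_parents(cfg)
        rng = np.random.default_rng(2)
        het = np.stack([a, b])[None].repeat(4000, axis=0)
        from ailmap.simulate import _gametes
        g = _gametes(het, cfg, rng)
        freq = g[:, 25].mean()
        assert freq == pytest.approx(0.5, abs=3 * 0.5 / np.sqrt(4000))

    def test_terminal_recombination_fraction_matches_haldane(self):
        """Across a 1-Morgan chromosome the two ends recombine with
        probability (1 - exp(-2L))/2 under Poisson crossovers."""
        # 263.2 kb at 0.38 cM/kb spans ~1 Morgan
        cfg = small_config(chrom_lengths=(263_158,), markers_per_chrom=10)
        length_m = cfg.genetic_positions(0)[-1] - cfg.genetic_positions(0)[0]
        a, b = make_parents(cfg)
        rng = np.random.default_rng(3)
        from ailmap.simulate import _gametes
        het = np.stack([a, b])[None].repeat(10_000, axis=0)
        g = _gametes(het, cfg, rng)
        rec = (g[:, 0] != g[:, -1]).mean()
        expected = 0.5 * (1 - np.exp(-2 * length_m))
        assert rec == pytest.approx(expected, abs=3 * 0.5 / np.sqrt(10_000))


class TestAdvanceGenerations:
    def test_neutral_drift_mean_and_bound(self):
        """Fifty independently assorting markers, population 1,000: mean
        F6 frequency stays at 0.5 and the across-marker SD respects the
        six-generation binomial drift bound of 0.06."""
        cfg = SimConfig(chrom_lengths=(1_000,) * 50, markers_per_chrom=1,
                        pop_size=1000, seed=4)
        pop = advance_generations(cfg, np.random.default_rng(4))
        freq = pop.mean(axis=(0, 1))
        assert freq.mean() == pytest.approx(0.5, abs=0.02)
        assert freq.std(ddof=1) <= 0.06
        assert freq.min() > 0.0 and freq.max() < 1.0  # no loss/fixation

    def test_haplotype_blocks_shorten_with_generations(self):
        def median_block(n_gen, seed):
            cfg = SimConfig(chrom_lengths=(1_000_000,), markers_per_chrom=500,
                            pop_size=200, n_generations=n_gen, seed=seed)
            pop = advance_generations(cfg, np.random.default_rng(seed))
            lengths = []
            for ind in range(10):
                hap = pop[ind, 0]
                change = np.flatnonzero(np.diff(hap)) + 1
                runs = np.diff(np.concatenate([[0], change, [hap.size]]))
                lengths.extend(runs)
            return np.median(lengths)

        assert median_block(6, seed=5) < median_block(2, seed=5)


class TestPhenotypes:
    def _cfg(self, h2, deltas=(0.3,), trait="both"):
        cfg = small_config(pop_size=4000, h2=h2)
        qtls = tuple(QTLSpec(0, int(cfg.positions(0)[10 + 5 * i]), d,
                             trait=trait)
                     for i, d in enumerate(deltas))
        return dataclasses.replace(cfg, qtl_truth=qtls)

    def test_zero_heritability_decouples_phenotype(self):
        cfg = self._cfg(h2=0.0)
        rng = np.random.default_rng(6)
        pop = advance_generations(cfg, rng)
        ph = assign_phenotypes(pop, cfg, "growth", rng)
        r = np.corrcoef(ph.value, ph.genetic)[0, 1]
        assert abs(r) < 0.05

    def test_full_heritability_orders_phenotype_by_allele_count(self):
        """With h2 = 1 and one QTL the phenotype ranking follows the
        favourable-allele dosage exactly (groups do not interleave)."""
        cfg = self._cfg(h2=1.0)
        rng = np.random.default_rng(7)
        pop = advance_generations(cfg, rng)
        ph = assign_phenotypes(pop, cfg, "growth", rng)
        idx = cfg.qtl_marker_index(cfg.qtl_truth[0])
        dosage = pop[:, :, idx].sum(axis=1)
        for low, high in ((0, 1), (1, 2)):
            assert ph.value[dosage == low].max() < \
                ph.value[dosage == high].min()

    def test_realized_heritability_near_target(self):
        cfg = self._cfg(h2=0.5, deltas=(0.2, 0.2, 0.3))
        rng = np.random.default_rng(8)
        pop = advance_generations(cfg, rng)
        ph = assign_phenotypes(pop, cfg, "growth", rng)
        realized = ph.genetic.var() / ph.latent.var()
        assert realized == pytest.approx(0.5, abs=0.05)

    def test_survival_score_spans_0_to_14(self):
        cfg = self._cfg(h2=0.5)
        rng = np.random.default_rng(9)
        pop = advance_generations(cfg, rng)
        ph = assign_phenotypes(pop, cfg, "survival", rng)
        assert ph.value.min() == 0 and ph.value.max() == 14
        assert set(np.unique(ph.value)) <= set(range(15))

    def test_qtl_off_marker_grid_rejected(self):
        cfg = small_config()
        bad = dataclasses.replace(cfg, qtl_truth=(QTLSpec(0, 12_345, 0.3),))
        rng = np.random.default_rng(10)
        pop = advance_generations(cfg, rng)
        with pytest.raises(ConfigurationError, match="not at a marker"):
            assign_phenotypes(pop, bad, "growth", rng)


class TestSelection:
    def test_strong_qtl_dominates_tail(self):
        """With h2 = 1 and a single large QTL, every selected individual
        carries at least the population-median favourable allele count."""
        cfg = small_config(pop_size=3000, h2=1.0)
        cfg = dataclasses.replace(
            cfg, qtl_truth=(QTLSpec(0, int(cfg.positions(0)[25]), 0.5),))
        rng = np.random.default_rng(11)
        pop = advance_generations(cfg, rng)
        phen = {t: assign_phenotypes(pop, cfg, t, rng)
                for t in ("growth", "survival")}
        tails = two_stage_select(phen, cfg, rng)
        idx = cfg.qtl_marker_index(cfg.qtl_truth[0])
        dosage = pop[:, :, idx].sum(axis=1)
        median = np.median(dosage)
        assert np.all(dosage[tails["growth"]] >= median)

    def test_null_trait_tail_matches_population(self):
        cfg = small_config(pop_size=3000, h2=0.0)
        rng = np.random.default_rng(12)
        pop = advance_generations(cfg, rng)
        phen = {t: assign_phenotypes(pop, cfg, t, rng)
                for t in ("growth", "survival")}
        tails = two_stage_select(phen, cfg, rng)
        pop_freq = pop.mean(axis=(0, 1))
        tail_freq = pop[tails["growth"]].mean(axis=(0, 1))
        # 90 diploids -> sampling SD ~ sqrt(pq/180) ~ 0.037 per marker
        assert np.abs(tail_freq - pop_freq).mean() < 3 * 0.037

    def test_tail_size_and_stage_arithmetic(self):
        cfg = small_config(pop_size=3000)
        rng = np.random.default_rng(13)
        pop = advance_generations(cfg, rng)
        phen = {t: assign_phenotypes(pop, cfg, t, rng)
                for t in ("growth", "survival")}
        tails = two_stage_select(phen, cfg, rng)
        assert len(tails["growth"]) == cfg.stage2_top == 90
        assert cfg.stage1_fraction * cfg.stage2_top / cfg.stage2_sample == \
            pytest.approx(0.105)

    def test_population_too_small_rejected(self):
        cfg = small_config(pop_size=500)
        rng = np.random.default_rng(0)
        pop = advance_generations(cfg, rng)
        phen = {t: assign_phenotypes(pop, cfg, t, rng)
                for t in ("growth", "survival")}
        with pytest.raises(ConfigurationError, match="too small"):
            two_stage_select(phen, cfg, rng)


class TestPoolAndSequence:
    def test_read_sampling_sd_matches_binomial(self):
        """At true frequency 0.5 and ~1,000x coverage the observed pool
        frequency has SD ~ sqrt(0.25/1000) = 0.0158."""
        cfg = small_config(chrom_lengths=(1_000_000,), markers_per_chrom=2000,
                          pop_size=1000)
        # all-heterozygote pool: true frequency exactly 0.5 at all markers
        a, b = make_parents(cfg)
        pop = np.stack([a, b])[None].repeat(90, axis=0)
        rng = np.random.default_rng(14)
        ye, other, tf, _ = pool_and_sequence(np.arange(90), pop, cfg, rng)
        assert np.allclose(tf, 0.5)
        f_obs = ye[0] / (ye[0] + other[0])
        assert f_obs.std() == pytest.approx(np.sqrt(0.25 / 1000), rel=0.08)

    def test_deep_coverage_recovers_true_frequency(self):
        cfg = small_config(coverage=1e6, pop_size=1000)
        rng = np.random.default_rng(15)
        pop = advance_generations(cfg, rng)
        ye, other, tf, _ = pool_and_sequence(None, pop, cfg, rng)
        f_obs = ye / (ye + other)
        assert np.abs(f_obs - tf).max() < 0.002

    def test_subpools_partition_the_tail(self):
        cfg = small_config(pop_size=1000)
        rng = np.random.default_rng(16)
        pop = advance_generations(cfg, rng)
        tail = np.arange(90)
        _, _, _, groups = pool_and_sequence(tail, pop, cfg, rng)
        flat = np.sort(np.concatenate(groups))
        assert np.array_equal(flat, tail)
        assert all(len(g) == 30 for g in groups)


class TestExperimentAndEmit:
    def _cfg(self, seed=17):
        cfg = small_config(pop_size=1200, markers_per_chrom=40, seed=seed)
        return dataclasses.replace(
            cfg, qtl_truth=(QTLSpec(0, int(cfg.positions(0)[20]), 0.4),))

    def test_emitted_table_round_trips(self, tmp_path):
        markers, truth = simulate_experiment(self._cfg())
        paths = emit(markers, truth, tmp_path)
        back = io_qc.read_marker_table(paths["markers"])
        for col in io_qc.count_columns():
            assert back[col].astype("Int64").equals(
                markers[col].astype("Int64"))

    def test_truth_json_contents(self, tmp_path):
        markers, truth = simulate_experiment(self._cfg())
        paths = emit(markers, truth, tmp_path)
        payload = json.loads(paths["truth"].read_text())
        assert len(payload["qtls"]) == 1
        assert len(payload["tail_members"]["growth"]) == 90
        assert set(payload["sigma_p"]) == {"growth", "survival"}

    def test_same_seed_identical_files(self, tmp_path):
        m1, t1 = simulate_experiment(self._cfg(seed=18))
        m2, t2 = simulate_experiment(self._cfg(seed=18))
        p1 = emit(m1, t1, tmp_path / "a")
        p2 = emit(m2, t2, tmp_path / "b")
        assert p1["markers"].read_bytes() == p2["markers"].read_bytes()
        assert p1["truth"].read_bytes() == p2["truth"].read_bytes()

    def test_realized_shift_matches_truncation_theory(self):
        """Closing the loop with the effect estimator: with h2 = 1 the
        two-stage design reduces to one 10.5% truncation, so the mean
        realized tail-minus-population frequency shift across QTLs should
        match p q (delta/sigma) i(0.105)."""
        base = SimConfig(chrom_lengths=(50_000,) * 20, markers_per_chrom=10,
                         pop_size=3000, h2=1.0, seed=19)
        qtls = tuple(QTLSpec(c, int(base.positions(c)[5]), 0.1)
                     for c in range(20))
        cfg = dataclasses.replace(base, qtl_truth=qtls)
        markers, truth = simulate_experiment(cfg)
        i = selection_intensity(0.105)
        ratios = []
        for q in truth.qtls:
            p = q["pop_freq_ye531"]
            expected = p * (1 - p) * (0.1 / truth.sigma_p["growth"]) * i
            ratios.append(q["realized_shift_growth"] / expected)
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.15)


class TestDrift:
    def test_binomial_drift_sd_matches_closed_form(self):
        """Six generations at Ne = 1,000 from p = 0.5: SD close to
        sqrt(0.25 (1 - (1 - 1/N)^6)) ~ 0.0387 and below the 0.06 bound."""
        sd = binomial_drift_sd(0.5, 1000, 6, replicates=20_000, seed=20)
        closed = np.sqrt(0.25 * (1 - (1 - 1 / 1000) ** 6))
        assert sd == pytest.approx(closed, rel=0.05)
        assert sd <= 0.06
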