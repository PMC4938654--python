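"""Synthetic F2 experiment: meiosis model, bulks, pooled counts, panels."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bsamap.config import SimConfig, demo_config
from bsamap.simulate import (
    _simulate_gametes,
    make_bulks,
    simulate_experiment,
    simulate_f2_population,
    simulate_panels,
    simulate_pool_counts,
)


def small_config(**overrides) -> SimConfig:
    params = dict(
        chromosomes=[("chr1", 10_000_000)],
        causal_locus=("chr1", 5_000_000),
        marker_spacing=500_000,
        n_f2=400,
        seed=11,
    )
    params.update(overrides)
    return SimConfig(**params)


class TestConfigValidation:
    @pytest.mark.parametrize("field, value", [
        ("n_f2", 0),
        ("depth_pool", -1.0),
        ("base_error", 0.5),
        ("phenotyping_error", -0.1),
        ("causal_locus", ("chr9", 100)),
        ("causal_locus", ("chr1", 99_000_000)),
    ])
    def test_invalid_field_named_in_error(self, field, value):
        with pytest.raises(ValueError, match=field):
            small_config(**{field: value})


class TestMeiosis:
    def test_suppressed_recombination_transmits_intact_haplotypes(self):
        # with an effectively infinite cM<->bp scale no crossover can occur,
        # so every gamete is constant along the chromosome
        cfg = small_config(bp_per_cm=1e15)
        pop = simulate_f2_population(cfg)
        hap = pop.haplotypes["chr1"]
        assert np.all(hap == hap[:, [0]])

    def test_mutant_fraction_is_one_quarter(self):
        pop = simulate_f2_population(small_config(n_f2=400, phenotyping_error=0.0))
        frac = pop.phenotype.mean()
        # binomial(400, 1/4): 3 SD band
        assert abs(frac - 0.25) <= 3 * math.sqrt(0.25 * 0.75 / 400)

    def test_recombinant_fraction_matches_haldane(self):
        # two loci one Morgan apart; Haldane: r = (1 - exp(-2)) / 2
        rng = np.random.default_rng(5)
        positions = np.array([1.0, 25_000_001.0])
        gam = _simulate_gametes(10_000, 25_000_002, positions, 250_000.0, rng)
        r_obs = np.mean(gam[:, 0] != gam[:, 1])
        r_exp = (1 - math.exp(-2.0)) / 2
        assert abs(r_obs - r_exp) <= 3 * math.sqrt(r_exp * (1 - r_exp) / 10_000)

    def test_phenotyping_error_flips_labels(self):
        cfg = small_config(phenotyping_error=0.3, n_f2=2000)
        pop = simulate_f2_population(cfg)
        true_mut = pop.causal_genotype == 2
        flip_rate = np.mean(pop.phenotype != true_mut)
        assert abs(flip_rate - 0.3) <= 3 * math.sqrt(0.3 * 0.7 / 2000)


class TestBulks:
    def test_exact_class_size_forces_full_selection(self):
        pop = simulate_f2_population(small_config())
        n_mut = int(pop.phenotype.sum())
        cfg = dataclasses.replace(pop.config, bulk_size_mutant=n_mut)
        bulks = make_bulks(pop, cfg)
        assert np.array_equal(bulks.mutant, np.flatnonzero(pop.phenotype))

    def test_seeded_bulks_are_reproducible(self):
        pop = simulate_f2_population(small_config())
        b1 = make_bulks(pop, pop.config, np.random.default_rng(3))
        b2 = make_bulks(pop, pop.config, np.random.default_rng(3))
        assert np.array_equal(b1.mutant, b2.mutant)
        assert np.array_equal(b1.normal, b2.normal)

    def test_insufficient_class_raises_with_shortfall(self):
        pop = simulate_f2_population(small_config())
        cfg = dataclasses.replace(pop.config, bulk_size_mutant=pop.config.n_f2)
        with pytest.raises(ValueError, match="mutant bulk"):
            make_bulks(pop, cfg)

    def test_mutant_bulk_fixed_at_causal_locus(self):
        """Without phenotyping error the mutant bulk is pure MH86 at the causal site."""
        pop, bulks, table = simulate_experiment(small_config(phenotyping_error=0.0))
        truth = table.truth
        row = truth[(truth.chrom == "chr1") & (truth.pos == 5_000_000)].iloc[0]
        assert row.freq_mutant_bulk == 1.0
        # normal bulk mixes 2/3 het + 1/3 homozygous wild-type: E = 1/3,
        # per-plant variance 1/18, 50 plants
        assert abs(row.freq_normal_bulk - 1 / 3) <= 3 * math.sqrt(1 / 18 / 50)


class TestPoolCounts:
    def test_error_free_causal_marker_is_pure_in_mutant_pool(self):
        pop, bulks, table = simulate_experiment(small_config(base_error=0.0))
        m = table.markers
        row = m[(m.chrom == "chr1") & (m.pos == 5_000_000)].iloc[0]
        assert row.m2 == 0 and row.m1 > 0

    def test_mean_depth_is_poisson(self):
        cfg = SimConfig(
            chromosomes=[("chr1", 50_000_000)], causal_locus=("chr1", 25_000_000),
            marker_spacing=5_000, n_f2=400, seed=2,
        )
        pop, bulks, table = simulate_experiment(cfg)
        depth = (table.markers.m1 + table.markers.m2).to_numpy()
        n = depth.size
        assert n >= 10_000
        assert abs(depth.mean() - cfg.depth_pool) <= 3 * math.sqrt(cfg.depth_pool / n)

    def test_base_error_dilutes_fixed_marker(self):
        cfg = small_config(base_error=0.01, depth_pool=1000.0, phenotyping_error=0.0)
        pop, bulks, table = simulate_experiment(cfg)
        m = table.markers
        row = m[(m.chrom == "chr1") & (m.pos == 5_000_000)].iloc[0]
        depth = row.m1 + row.m2
        frac = row.m1 / depth
        assert abs(frac - 0.99) <= 3 * math.sqrt(0.99 * 0.01 / depth)

    def test_fixed_seed_reproduces_marker_table(self):
        cfg = small_config()
        _, _, t1 = simulate_experiment(cfg)
        _, _, t2 = simulate_experiment(cfg)
        pd.testing.assert_frame_equal(t1.markers, t2.markers)
        pd.testing.assert_frame_equal(t1.truth, t2.truth)


class TestPanels:
    def test_finemap_panel_fixed_at_causal_marker(self):
        cfg = small_config(n_f2=1200, seed=4)
        pop = simulate_f2_population(cfg)
        fm, _ = simulate_panels(pop, cfg, n_finemap=199, n_coseg=100)
        assert set(fm["chr1:5000000"]) == {"A"}

    def test_unlinked_marker_segregates_1_2_1(self):
        cfg = SimConfig(
            chromosomes=[("chr1", 10_000_000), ("chr2", 10_000_000)],
            causal_locus=("chr1", 5_000_000),
            marker_spacing=5_000_000, n_f2=1200, seed=4,
        )
        pop = simulate_f2_population(cfg)
        panel_markers = pd.DataFrame({"chrom": ["chr2"], "pos": [5_000_000]})
        fm, _ = simulate_panels(pop, cfg, 199, 100, panel_markers=panel_markers)
        counts = fm["chr2:5000000"].value_counts()
        n = 199
        for code, p in (("A", 0.25), ("H", 0.5), ("B", 0.25)):
            sd = math.sqrt(n * p * (1 - p))
            assert abs(counts.get(code, 0) - n * p) <= 3 * sd

    def test_coseg_panel_concordant_without_phenotyping_error(self):
        cfg = small_config(phenotyping_error=0.0)
        pop = simulate_f2_population(cfg)
        _, coseg = simulate_panels(pop, cfg, n_finemap=50, n_coseg=200)
        is_mut = coseg["phenotype"] == "mutant"
        assert ((coseg["genotype"] == "-/-") == is_mut).all()

    def test_insufficient_mutants_raise(self):
        cfg = small_config(n_f2=100)
        pop = simulate_f2_population(cfg)
        with pytest.raises(ValueError, match="fine-mapping panel"):
            simulate_panels(pop, cfg, n_finemap=99, n_coseg=10)


def test_truth_frequency_decays_with_distance_from_causal_locus():
    """Averaged over seeds, the mutant-bulk MH86 frequency falls off with
    genetic distance from the causal locus (rank correlation, not per-run)."""
    cfg0 = demo_config()
    sums = None
    for seed in range(20):
        cfg = demo_config(seed=seed)
        _, _, table = simulate_experiment(cfg)
        truth = table.truth
        sub = truth[truth.chrom == "chr2"]
        sums = sub.freq_mutant_bulk.to_numpy() if sums is None else sums + sub.freq_mutant_bulk.to_numpy()
    pos = truth[truth.chrom == "chr2"].pos.to_numpy()
    dist = np.abs(pos - cfg0.causal_locus[1])
    rho, _ = stats.spearmanr(dist, sums)
    assert rho < -0.8
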