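"""Synthetic F2 bulk-sequencing data with known truth.

Simulates the genetic structure a bulked-segregant scan assumes: an F2 from a
cross of a heterozygous mutation carrier (MH86 background) with 93-11, a
recessive causal locus, phenotype-selected DNA bulks, and pooled short-read
allele counts at a genome-wide marker grid. Meiosis uses a no-interference
(Haldane) crossover model: the number of crossovers per chromosome per gamete
is Poisson with mean equal to the map length in Morgans, and crossover
positions are uniform.

Allele coding: 1 = MH86-derived haplotype (carries the mutation at the causal
locus), 0 = 93-11-derived.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SimConfig

__all__ = [
    "PopulationTruth",
    "Bulks",
    "MarkerTable",
    "simulate_f2_population",
    "make_bulks",
    "simulate_pool_counts",
    "simulate_panels",
    "simulate_region_variants",
    "simulate_experiment",
]

_BASES = np.array(list("ACGT"))


@dataclass
class PopulationTruth:
    """True haplotypes, causal genotypes and phenotype labels of an F2."""

    config: SimConfig
    positions: dict[str, np.ndarray]          # marker bp per chromosome
    haplotypes: dict[str, np.ndarray]         # (2*n_f2, n_markers) uint8; rows 2j, 2j+1 = plant j
    causal_gametes: np.ndarray                # (2*n_f2,) allele at the causal locus
    phenotype: np.ndarray                     # (n_f2,) bool, True = labeled mutant

    @property
    def n_plants(self) -> int:
        return self.config.n_f2

    @property
    def causal_genotype(self) -> np.ndarray:
        """MH86-allele dose (0/1/2) at the causal locus, per plant."""
        return self.causal_gametes.reshape(-1, 2).sum(axis=1)

    def marker_positions_frame(self) -> pd.DataFrame:
        frames = [
            pd.DataFrame({"chrom": chrom, "pos": self.positions[chrom]})
            for chrom, _ in self.config.chromosomes
        ]
        return pd.concat(frames, ignore_index=True)


@dataclass
class Bulks:
    """Plant indices composing the two DNA pools."""

    mutant: np.ndarray
    normal: np.ndarray


@dataclass
class MarkerTable:
    """Simulated allele counts plus the exact bulk-frequency truth sidecar.

    ``markers`` columns follow the pipeline TSV contract: chrom, pos (1-based),
    mh86_allele, other_allele, m1, m2, n1, n2, p1_ref_count, p1_alt_count,
    p2_ref_count, p2_alt_count. By simulator convention REF is the MH86 allele
    and ALT the 93-11 allele, so p1_ref_count counts MH86-allele reads in the
    MH86 parent sample.
    """

    markers: pd.DataFrame
    truth: pd.DataFrame  # chrom, pos, freq_mutant_bulk, freq_normal_bulk


def _simulate_gametes(
    n: int, length_bp: int, positions: np.ndarray, bp_per_cm: float, rng: np.random.Generator
) -> np.ndarray:
    """Haldane gametes: alleles (0/1) at `positions` for `n` meiotic products."""
    morgans = length_bp / (bp_per_cm * 100.0)
    out = np.empty((n, positions.size), dtype=np.uint8)
    n_xo = rng.poisson(morgans, size=n)
    starts = rng.integers(0, 2, size=n, dtype=np.uint8)
    for i in range(n):
        if n_xo[i]:
            xo = np.sort(rng.uniform(0.0, length_bp, size=n_xo[i]))
            out[i] = (starts[i] + np.searchsorted(xo, positions)) % 2
        else:
            out[i] = starts[i]
    return out


def _marker_grid(config: SimConfig) -> dict[str, np.ndarray]:
    return {
        name: np.arange(config.marker_spacing, length + 1, config.marker_spacing, dtype=np.int64)
        for name, length in config.chromosomes
    }


def simulate_f2_population(
    config: SimConfig, rng: np.random.Generator | None = None
) -> PopulationTruth:
    """Simulate an F2 population from a genome-wide heterozygous F1.

    Each plant fuses two independent gametes; each gamete is one Haldane
    crossover realization per chromosome. Phenotype is mutant iff the plant is
    homozygous for the MH86-derived allele at the causal locus, then flipped
    with probability ``phenotyping_error``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    grid = _marker_grid(config)
    c_chrom, c_pos = config.causal_locus
    n_gam = 2 * config.n_f2

    haplotypes: dict[str, np.ndarray] = {}
    causal_gametes: np.ndarray | None = None
    for name, length in config.chromosomes:
        positions = grid[name]
        if name == c_chrom:
            # evaluate the causal locus on the same crossover realization
            aug = np.append(positions, c_pos).astype(float)
            order = np.argsort(aug, kind="stable")
            gam = _simulate_gametes(n_gam, length, aug[order], config.bp_per_cm, rng)
            inv = np.empty_like(order)
            inv[order] = np.arange(order.size)
            gam = gam[:, inv]
            haplotypes[name] = np.ascontiguousarray(gam[:, :-1])
            causal_gametes = gam[:, -1].copy()
        else:
            haplotypes[name] = _simulate_gametes(n_gam, length, positions.astype(float),
                                                 config.bp_per_cm, rng)
    assert causal_gametes is not None

    genotype = causal_gametes.reshape(-1, 2).sum(axis=1)
    phenotype = genotype == 2
    if config.phenotyping_error > 0:
        flips = rng.random(config.n_f2) < config.phenotyping_error
        phenotype = phenotype ^ flips

    return PopulationTruth(
        config=config,
        positions=grid,
        haplotypes=haplotypes,
        causal_gametes=causal_gametes,
        phenotype=phenotype,
    )


def make_bulks(
    pop: PopulationTruth, config: SimConfig, rng: np.random.Generator | None = None
) -> Bulks:
    """Draw the M-pool and N-pool plant sets from the phenotype classes.

    Sampling is uniform without replacement within each class.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    mutants = np.flatnonzero(pop.phenotype)
    normals = np.flatnonzero(~pop.phenotype)
    if mutants.size < config.bulk_size_mutant:
        raise ValueError(
            f"mutant bulk needs {config.bulk_size_mutant} plants but only "
            f"{mutants.size} labeled mutants are available"
        )
    if normals.size < config.bulk_size_normal:
        raise ValueError(
            f"normal bulk needs {config.bulk_size_normal} plants but only "
            f"{normals.size} labeled normals are available"
        )
    m = np.sort(rng.choice(mutants, size=config.bulk_size_mutant, replace=False))
    n = np.sort(rng.choice(normals, size=config.bulk_size_normal, replace=False))
    return Bulks(mutant=m, normal=n)


def _bulk_frequencies(pop: PopulationTruth, plants: np.ndarray) -> dict[str, np.ndarray]:
    """Exact MH86-allele frequency per marker across a bulk's 2k haplotypes."""
    rows = np.empty(2 * plants.size, dtype=np.int64)
    rows[0::2] = 2 * plants
    rows[1::2] = 2 * plants + 1
    return {
        chrom: pop.haplotypes[chrom][rows].mean(axis=0)
        for chrom, _ in pop.config.chromosomes
    }


def _pool_counts(
    freq: np.ndarray, depth: float, base_error: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Poisson depth, binomial MH86-read count with symmetric error flips.

    Reads are independent uniform draws from the bulk haplotypes, so the
    per-read sampling reduces exactly to a binomial with success probability
    f(1-e) + (1-f)e.
    """
    d = rng.poisson(depth, size=freq.size)
    p = freq * (1.0 - base_error) + (1.0 - freq) * base_error
    k = rng.binomial(d, p)
    return k, d - k


def simulate_pool_counts(
    pop: PopulationTruth,
    bulks: Bulks,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> MarkerTable:
    """Generate pooled and parental allele counts at every marker."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    fm = _bulk_frequencies(pop, bulks.mutant)
    fn = _bulk_frequencies(pop, bulks.normal)

    frames = []
    truths = []
    e = config.base_error
    for chrom, _ in config.chromosomes:
        pos = pop.positions[chrom]
        k = pos.size
        m1, m2 = _pool_counts(fm[chrom], config.depth_pool, e, rng)
        n1, n2 = _pool_counts(fn[chrom], config.depth_pool, e, rng)
        # parents are fixed homozygotes: MH86 all-1, 93-11 all-0
        p1_1, p1_2 = _pool_counts(np.ones(k), config.depth_parent1, e, rng)
        p2_1, p2_2 = _pool_counts(np.zeros(k), config.depth_parent2, e, rng)
        ref = rng.integers(0, 4, size=k)
        alt = (ref + rng.integers(1, 4, size=k)) % 4
        frames.append(pd.DataFrame({
            "chrom": chrom,
            "pos": pos,
            "mh86_allele": _BASES[ref],
            "other_allele": _BASES[alt],
            "m1": m1, "m2": m2, "n1": n1, "n2": n2,
            "p1_ref_count": p1_1, "p1_alt_count": p1_2,
            "p2_ref_count": p2_1, "p2_alt_count": p2_2,
        }))
        truths.append(pd.DataFrame({
            "chrom": chrom,
            "pos": pos,
            "freq_mutant_bulk": fm[chrom],
            "freq_normal_bulk": fn[chrom],
        }))
    return MarkerTable(
        markers=pd.concat(frames, ignore_index=True),
        truth=pd.concat(truths, ignore_index=True),
    )


_GENO_CODE = np.array(["B", "H", "A"])       # MH86 dose 0/1/2
_CAUSAL_CODE = np.array(["+/+", "-/+", "-/-"])


def _genotype_codes(pop: PopulationTruth, plants: np.ndarray,
                    chrom: str, positions: np.ndarray) -> np.ndarray:
    """A/H/B genotype matrix (plants x markers) read from truth haplotypes."""
    grid = pop.positions[chrom]
    idx = np.searchsorted(grid, positions)
    if not np.all((idx < grid.size) & (grid[np.minimum(idx, grid.size - 1)] == positions)):
        raise ValueError("panel marker positions must lie on the simulated marker grid")
    hap = pop.haplotypes[chrom][:, idx]
    dose = hap[2 * plants] + hap[2 * plants + 1]
    return _GENO_CODE[dose]


def simulate_panels(
    pop: PopulationTruth,
    config: SimConfig,
    n_finemap: int,
    n_coseg: int,
    panel_markers: pd.DataFrame | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Genotyping panels for fine mapping and cosegregation.

    Returns ``(finemap_panel, coseg_panel)``. The fine-mapping panel holds
    ``n_finemap`` phenotypically mutant plants genotyped A/H/B at
    ``panel_markers`` (columns chrom, pos; defaults to the full grid of the
    causal chromosome). The cosegregation panel is a random F2 sample of
    ``n_coseg`` plants with phenotype and causal-variant genotype
    (-/-, -/+, +/+).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 3)
    if panel_markers is None:
        chrom = config.causal_locus[0]
        panel_markers = pd.DataFrame({"chrom": chrom, "pos": pop.positions[chrom]})

    mutants = np.flatnonzero(pop.phenotype)
    if mutants.size < n_finemap:
        raise ValueError(
            f"fine-mapping panel needs {n_finemap} mutant plants but only "
            f"{mutants.size} are available"
        )
    if pop.n_plants < n_coseg:
        raise ValueError(
            f"cosegregation panel needs {n_coseg} plants but the population has "
            f"{pop.n_plants}"
        )
    fm_plants = np.sort(rng.choice(mutants, size=n_finemap, replace=False))
    columns: dict[str, object] = {
        "plant_id": [f"M{p:04d}" for p in fm_plants],
        "phenotype": "mutant",
    }
    for chrom, grp in panel_markers.groupby("chrom", sort=False):
        codes = _genotype_codes(pop, fm_plants, str(chrom), grp["pos"].to_numpy())
        for j, p in enumerate(grp["pos"].to_numpy()):
            columns[f"{chrom}:{p}"] = codes[:, j]
    finemap = pd.DataFrame(columns)

    cs_plants = np.sort(rng.choice(pop.n_plants, size=n_coseg, replace=False))
    coseg = pd.DataFrame({
        "plant_id": [f"F{p:04d}" for p in cs_plants],
        "phenotype": np.where(pop.phenotype[cs_plants], "mutant", "normal"),
        "genotype": _CAUSAL_CODE[pop.causal_genotype[cs_plants]],
    })
    return finemap, coseg


def simulate_region_variants(
    pop: PopulationTruth,
    bulks: Bulks,
    config: SimConfig,
    region: tuple[str, int, int],
    n_background: int = 500,
    depth_pool: float | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, int]:
    """Variant calls across a candidate region, with the causal site implanted.

    Background variants are ordinary MH86/93-11 polymorphisms (the ALT allele
    rides on one parental haplotype, chosen at random per site, and is present
    in that parent's sample). The causal variant's ALT allele arose after the
    MH86 parent was sampled (tissue-culture origin), so it is absent from both
    parents and segregates with the MH86-derived haplotype in the pools.

    Returns the variant table (columns chrom, pos, ref, alt, m_ref, m_alt,
    n_ref, n_alt, p1_ref, p1_alt, p2_ref, p2_alt; REF = wild-type allele,
    ALT = candidate mutant allele) and the causal position.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 4)
    chrom, start, end = region
    c_chrom, c_pos = config.causal_locus
    if chrom != c_chrom or not (start <= c_pos <= end):
        raise ValueError(f"region {region} does not contain the causal locus {config.causal_locus}")
    if depth_pool is None:
        depth_pool = config.depth_pool
    e = config.base_error

    grid = pop.positions[chrom]
    in_region = np.flatnonzero((grid >= start) & (grid <= end))
    if in_region.size == 0:
        raise ValueError(f"no simulated markers inside region {region}")
    fm = _bulk_frequencies(pop, bulks.mutant)[chrom]
    fn = _bulk_frequencies(pop, bulks.normal)[chrom]

    # background sites anchor to a random marker of the region (its local
    # haplotype frequency) with a small positional jitter
    anchors = rng.choice(in_region, size=n_background, replace=True)
    jitter = rng.integers(-config.marker_spacing // 2 + 1, config.marker_spacing // 2,
                          size=n_background)
    pos = np.clip(grid[anchors] + jitter, start, end)
    keep = pos != c_pos  # the causal site is added explicitly below
    pos, anchors = pos[keep], anchors[keep]
    n_background = int(keep.sum())
    mh86_origin = rng.random(n_background) < 0.5
    # ALT frequency among bulk haplotypes at each site
    alt_fm = np.where(mh86_origin, fm[anchors], 1.0 - fm[anchors])
    alt_fn = np.where(mh86_origin, fn[anchors], 1.0 - fn[anchors])
    # parent truth: ALT fixed in its parent of origin, absent from the other
    p1_alt_f = np.where(mh86_origin, 1.0, 0.0)
    p2_alt_f = np.where(mh86_origin, 0.0, 1.0)

    # causal site: exact bulk frequencies of the MH86-derived (mutant) allele
    rows_m = np.repeat(2 * bulks.mutant, 2) + np.tile([0, 1], bulks.mutant.size)
    rows_n = np.repeat(2 * bulks.normal, 2) + np.tile([0, 1], bulks.normal.size)
    causal_fm = float(pop.causal_gametes[rows_m].mean())
    causal_fn = float(pop.causal_gametes[rows_n].mean())

    pos = np.append(pos, c_pos)
    alt_fm = np.append(alt_fm, causal_fm)
    alt_fn = np.append(alt_fn, causal_fn)
    p1_alt_f = np.append(p1_alt_f, 0.0)
    p2_alt_f = np.append(p2_alt_f, 0.0)
    k = pos.size

    m_alt, m_ref = _pool_counts(alt_fm, depth_pool, e, rng)
    n_alt, n_ref = _pool_counts(alt_fn, depth_pool, e, rng)
    p1_alt, p1_ref = _pool_counts(p1_alt_f, config.depth_parent1, e, rng)
    p2_alt, p2_ref = _pool_counts(p2_alt_f, config.depth_parent2, e, rng)
    ref_b = rng.integers(0, 4, size=k)
    alt_b = (ref_b + rng.integers(1, 4, size=k)) % 4

    df = pd.DataFrame({
        "chrom": chrom,
        "pos": pos,
        "ref": _BASES[ref_b],
        "alt": _BASES[alt_b],
        "m_ref": m_ref, "m_alt": m_alt,
        "n_ref": n_ref, "n_alt": n_alt,
        "p1_ref": p1_ref, "p1_alt": p1_alt,
        "p2_ref": p2_ref, "p2_alt": p2_alt,
    })
    df = df.sort_values(["pos", "ref"], kind="stable").reset_index(drop=True)
    return df, int(c_pos)


def simulate_experiment(
    config: SimConfig,
) -> tuple[PopulationTruth, Bulks, MarkerTable]:
    """Population -> bulks -> pooled counts, with one seed split per stage."""
    ss = np.random.SeedSequence(config.seed)
    r_pop, r_bulk, r_counts = [np.random.default_rng(s) for s in ss.spawn(3)]
    pop = simulate_f2_population(config, r_pop)
    bulks = make_bulks(pop, config, r_bulk)
    table = simulate_pool_counts(pop, bulks, config, r_counts)
    return pop, bulks, table
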