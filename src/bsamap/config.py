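"""Experiment configuration for the synthetic F2 bulk-sequencing simulator.

A :class:`SimConfig` fully parameterizes one simulated mapping experiment:
genome layout, causal locus, F2 population size, bulk sizes, sequencing
depths, error rates, the genome-wide cM<->bp scale, and the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

__all__ = ["SimConfig", "default_config", "demo_config", "load_config"]


@dataclass
class SimConfig:
    """Parameters of a simulated F2 bulked-segregant experiment.

    Attributes
    ----------
    chromosomes:
        Ordered ``(name, length_bp)`` pairs.
    causal_locus:
        ``(chromosome, position_bp)`` of the recessive causal mutation. The
        mutation-carrying haplotype is the MH86-derived one genome-wide, so
        the mutant pool is enriched for MH86 alleles around this locus.
    marker_spacing:
        Distance in bp between consecutive simulated marker sites.
    n_f2:
        Number of F2 plants.
    bulk_size_mutant, bulk_size_normal:
        Plants pooled into the mutant (M) and phenotypically normal (N) bulks.
    depth_pool:
        Mean sequencing depth per marker per pool (Poisson).
    depth_parent1, depth_parent2:
        Mean depths for the two parents (MH86 and 93-11).
    base_error:
        Probability that a sampled read reports the wrong allele.
    phenotyping_error:
        Probability that a plant's phenotype label is flipped.
    bp_per_cm:
        Genome-wide physical-to-genetic scale (bp per centiMorgan).
    seed:
        Seed for the top-level random generator.
    """

    chromosomes: list[tuple[str, int]]
    causal_locus: tuple[str, int]
    marker_spacing: int = 5_000
    n_f2: int = 333
    bulk_size_mutant: int = 50
    bulk_size_normal: int = 50
    depth_pool: float = 12.0
    depth_parent1: float = 50.0
    depth_parent2: float = 30.0
    base_error: float = 0.01
    phenotyping_error: float = 0.0
    bp_per_cm: float = 250_000.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.chromosomes = [(str(n), int(l)) for n, l in self.chromosomes]
        self.causal_locus = (str(self.causal_locus[0]), int(self.causal_locus[1]))
        if not self.chromosomes:
            raise ValueError("chromosomes: at least one chromosome is required")
        names = [n for n, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosomes: duplicate chromosome names")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosomes: length of {name!r} must be > 0")
        lengths = dict(self.chromosomes)
        c_chrom, c_pos = self.causal_locus
        if c_chrom not in lengths:
            raise ValueError(f"causal_locus: chromosome {c_chrom!r} not in genome")
        if not (1 <= c_pos <= lengths[c_chrom]):
            raise ValueError(
                f"causal_locus: position {c_pos} outside chromosome {c_chrom!r} "
                f"(length {lengths[c_chrom]})"
            )
        for attr in ("marker_spacing", "n_f2", "bulk_size_mutant", "bulk_size_normal"):
            if getattr(self, attr) <= 0:
                raise ValueError(f"{attr} must be > 0")
        for attr in ("depth_pool", "depth_parent1", "depth_parent2", "bp_per_cm"):
            if getattr(self, attr) <= 0:
                raise ValueError(f"{attr} must be > 0")
        for attr in ("base_error", "phenotyping_error"):
            v = getattr(self, attr)
            if not (0.0 <= v < 0.5):
                raise ValueError(f"{attr} must be in [0, 0.5), got {v}")

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["chromosomes"] = [list(c) for c in self.chromosomes]
        d["causal_locus"] = list(self.causal_locus)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f for f in cls.__dataclass_fields__}
        extra = set(d) - known
        if extra:
            raise ValueError(f"unknown config fields: {sorted(extra)}")
        for required in ("chromosomes", "causal_locus"):
            if required not in d:
                raise ValueError(f"missing required config field: {required}")
        d = dict(d)
        d["chromosomes"] = [tuple(c) for c in d["chromosomes"]]
        d["causal_locus"] = tuple(d["causal_locus"])
        return cls(**d)


def default_config(seed: int = 0, **overrides) -> SimConfig:
    """Study-scale synthetic experiment: 5 chromosomes x 30 Mb, ~30,000 markers,
    50/50 bulks at 12x, parents at 50x/30x, 1% base error. The F2 holds 900
    plants so that, besides the bulks, a 199-plant mutant fine-mapping panel
    can be drawn from the same population (expected mutant class ~225)."""
    params = dict(
        chromosomes=[(f"chr{i}", 30_000_000) for i in range(1, 6)],
        causal_locus=("chr4", 23_000_000),
        marker_spacing=5_000,
        n_f2=900,
        seed=seed,
    )
    params.update(overrides)
    return SimConfig(**params)


def demo_config(seed: int = 0, **overrides) -> SimConfig:
    """Small, fast configuration for demos and tests (3 chromosomes x 6 Mb)."""
    params = dict(
        chromosomes=[("chr1", 6_000_000), ("chr2", 6_000_000), ("chr3", 6_000_000)],
        causal_locus=("chr2", 4_000_000),
        marker_spacing=5_000,
        n_f2=333,
        seed=seed,
    )
    params.update(overrides)
    return SimConfig(**params)


def load_config(path: str | Path) -> tuple[SimConfig, dict]:
    """Read a YAML pipeline configuration.

    The file has a required ``sim`` section (:class:`SimConfig` fields) and
    optional per-stage sections (``markers``, ``scan``, ``finemap``,
    ``candidate``, ``coseg``). Returns the SimConfig and the dict of stage
    options.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "sim" not in raw:
        raise ValueError(f"{path}: expected a mapping with a 'sim' section")
    sim = SimConfig.from_dict(raw["sim"])
    stages = {k: v for k, v in raw.items() if k != "sim"}
    return sim, stages
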