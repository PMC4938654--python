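"""Presence-pattern candidate screen and cosegregation test.

A recessive causal variant that arose in the MH86 background after the MH86
parent line was established (here, via tissue culture) shows a unique
presence pattern across the four sequenced samples: the mutant allele ("-")
appears alone in the M-pool, together with the wild-type allele ("+") in the
N-pool (which mixes +/+ and -/+ plants), and not at all in either parent.
Ordinary MH86/93-11 polymorphisms fail the pattern because one parent carries
the variant allele.

Variant tables use REF = wild-type allele, ALT = candidate mutant allele.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import pandas as pd

__all__ = [
    "ONLY_MUTANT",
    "ONLY_WILDTYPE",
    "BOTH",
    "NO_DATA",
    "PresenceCall",
    "CosegregationResult",
    "classify_group",
    "classify_presence",
    "filter_candidates",
    "cosegregation_test",
]

ONLY_MUTANT = "only-mutant-allele"
ONLY_WILDTYPE = "only-wildtype-allele"
BOTH = "both"
NO_DATA = "no-data"

GROUPS = ("m_pool", "n_pool", "parent1", "parent2")
# the expected pattern of the causal variant
CAUSAL_PATTERN = {
    "m_pool": ONLY_MUTANT,
    "n_pool": BOTH,
    "parent1": ONLY_WILDTYPE,
    "parent2": ONLY_WILDTYPE,
}


@dataclass(frozen=True)
class PresenceCall:
    """Which alleles are present in each sample group at one variant."""

    m_pool: str
    n_pool: str
    parent1: str
    parent2: str
    min_support: int
    max_contam_fraction: float

    def matches_causal_pattern(self) -> bool:
        return all(getattr(self, g) == CAUSAL_PATTERN[g] for g in GROUPS)

    def undetermined(self) -> bool:
        """True when no group contradicts the causal pattern but some lack data."""
        calls = {g: getattr(self, g) for g in GROUPS}
        if not any(v == NO_DATA for v in calls.values()):
            return False
        return all(v in (NO_DATA, CAUSAL_PATTERN[g]) for g, v in calls.items())


@dataclass
class CosegregationResult:
    """Genotype-by-phenotype table of a segregating panel at the candidate."""

    mutant_by_genotype: dict[str, int]
    normal_by_genotype: dict[str, int]
    concordant: bool
    discordant_plants: list[str]

    def to_dict(self) -> dict:
        return asdict(self)


def classify_group(
    mut_reads: int,
    wt_reads: int,
    min_support: int = 2,
    max_contam_fraction: float = 0.05,
) -> str:
    """Presence call for one sample group from its two allele read counts.

    An allele counts as present when it has at least ``min_support`` reads
    and more than ``max_contam_fraction`` of the group's reads (so a trickle
    of reads at high depth is treated as contamination or sequencing error).
    A group with zero depth — or where neither allele reaches the presence
    bar — is reported as no-data, never silently as "absent".
    """
    total = mut_reads + wt_reads
    if total <= 0:
        return NO_DATA
    mut_present = mut_reads >= min_support and mut_reads / total > max_contam_fraction
    wt_present = wt_reads >= min_support and wt_reads / total > max_contam_fraction
    if mut_present and wt_present:
        return BOTH
    if mut_present:
        return ONLY_MUTANT
    if wt_present:
        return ONLY_WILDTYPE
    return NO_DATA


def classify_presence(
    variant: pd.Series | dict,
    min_support: int = 2,
    max_contam_fraction: float = 0.05,
) -> PresenceCall:
    """Presence pattern of one variant across M-pool, N-pool and parents.

    ``variant`` carries counts m_ref/m_alt, n_ref/n_alt, p1_ref/p1_alt,
    p2_ref/p2_alt with ALT as the candidate mutant allele.
    """
    def call(prefix: str) -> str:
        return classify_group(
            int(variant[f"{prefix}_alt"]), int(variant[f"{prefix}_ref"]),
            min_support=min_support, max_contam_fraction=max_contam_fraction,
        )

    return PresenceCall(
        m_pool=call("m"), n_pool=call("n"),
        parent1=call("p1"), parent2=call("p2"),
        min_support=min_support, max_contam_fraction=max_contam_fraction,
    )


def filter_candidates(
    variants: pd.DataFrame,
    min_support: int = 2,
    max_contam_fraction: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep variants whose presence pattern matches a post-MH86 recessive causal.

    Returns ``(candidates, undetermined)``: candidates match the pattern
    exactly (M-pool only mutant allele, N-pool both, parents only wild-type);
    undetermined variants contradict nothing but have at least one no-data
    group (e.g. a pool with no coverage). Both frames carry the per-group
    presence calls and are ordered by (chrom, pos), independent of input
    order.
    """
    if len(variants) == 0:
        empty = variants.copy()
        return empty, empty.copy()
    out = variants.copy()
    calls = [
        classify_presence(row, min_support=min_support, max_contam_fraction=max_contam_fraction)
        for _, row in out.iterrows()
    ]
    for g in GROUPS:
        out[f"presence_{g}"] = [getattr(c, g) for c in calls]
    is_candidate = pd.Series([c.matches_causal_pattern() for c in calls], index=out.index)
    is_undet = pd.Series([c.undetermined() for c in calls], index=out.index)
    order = ["chrom", "pos"] if "chrom" in out.columns else ["pos"]
    candidates = out.loc[is_candidate].sort_values(order, kind="stable").reset_index(drop=True)
    undetermined = out.loc[is_undet].sort_values(order, kind="stable").reset_index(drop=True)
    return candidates, undetermined


def cosegregation_test(panel: pd.DataFrame) -> CosegregationResult:
    """Concordance of candidate genotype with phenotype across an F2 panel.

    ``panel`` has columns plant_id, phenotype ('mutant'/'normal') and genotype
    ('-/-', '-/+', '+/+'). The panel cosegregates when every mutant plant is
    -/- and every normal plant carries at least one wild-type allele.
    """
    if len(panel) == 0:
        raise ValueError("cosegregation test requires a non-empty panel")
    required = {"plant_id", "phenotype", "genotype"}
    missing = required - set(panel.columns)
    if missing:
        raise ValueError(f"panel is missing columns: {sorted(missing)}")
    bad_pheno = set(panel["phenotype"]) - {"mutant", "normal"}
    if bad_pheno:
        raise ValueError(f"unknown phenotype labels: {sorted(bad_pheno)}")
    bad_geno = set(panel["genotype"]) - {"-/-", "-/+", "+/+"}
    if bad_geno:
        raise ValueError(f"unknown genotype codes: {sorted(bad_geno)}")

    mut = panel[panel["phenotype"] == "mutant"]
    nor = panel[panel["phenotype"] == "normal"]
    mut_counts = mut["genotype"].value_counts().to_dict()
    nor_counts = nor["genotype"].value_counts().to_dict()
    discordant = list(mut.loc[mut["genotype"] != "-/-", "plant_id"]) + \
        list(nor.loc[nor["genotype"] == "-/-", "plant_id"])
    return CosegregationResult(
        mutant_by_genotype={g: int(mut_counts.get(g, 0)) for g in ("-/-", "-/+", "+/+")},
        normal_by_genotype={g: int(nor_counts.get(g, 0)) for g in ("-/-", "-/+", "+/+")},
        concordant=len(discordant) == 0,
        discordant_plants=discordant,
    )
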