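"""File formats: TSV tables, minimal four-sample VCF 4.2, bedGraph and BED.

Conventions (also stated in each file's header): TSV and VCF positions are
1-based; bedGraph and BED intervals are 0-based half-open.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .scan import RegionCall

__all__ = [
    "write_tsv",
    "read_tsv",
    "marker_table_to_raw",
    "write_vcf",
    "read_vcf",
    "write_bedgraph",
    "write_region",
    "read_region",
]

VCF_SAMPLES = ("M_POOL", "N_POOL", "PARENT1", "PARENT2")


def write_tsv(df: pd.DataFrame, path: str | Path, comment: str | None = None) -> None:
    """Write a TSV with optional '#'-prefixed header comment lines."""
    path = Path(path)
    with open(path, "w") as fh:
        if comment:
            for line in comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def marker_table_to_raw(markers: pd.DataFrame) -> pd.DataFrame:
    """Raw four-sample ref/alt view of a simulated marker table.

    Simulated tables are written with REF = MH86 allele, so the oriented pool
    counts map directly onto ref/alt counts.
    """
    return pd.DataFrame({
        "chrom": markers["chrom"],
        "pos": markers["pos"],
        "ref": markers["mh86_allele"],
        "alt": markers["other_allele"],
        "m_ref": markers["m1"], "m_alt": markers["m2"],
        "n_ref": markers["n1"], "n_alt": markers["n2"],
        "p1_ref": markers["p1_ref_count"], "p1_alt": markers["p1_alt_count"],
        "p2_ref": markers["p2_ref_count"], "p2_alt": markers["p2_alt_count"],
    })


def write_vcf(raw: pd.DataFrame, path: str | Path,
              contigs: dict[str, int] | None = None) -> None:
    """Write a raw variant table as a minimal VCF 4.2 with per-sample AD.

    Samples are M_POOL, N_POOL, PARENT1, PARENT2 in that order; each carries
    GT (./.) and AD (ref,alt depths). Input columns: chrom, pos, ref, alt and
    the eight ref/alt count columns.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=bsamap\n")
        if contigs:
            for name, length in contigs.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,'
                 'Description="Allelic depths for the ref and alt alleles">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(VCF_SAMPLES) + "\n")
        cols = [("m_ref", "m_alt"), ("n_ref", "n_alt"),
                ("p1_ref", "p1_alt"), ("p2_ref", "p2_alt")]
        for row in raw.itertuples(index=False):
            d = row._asdict()
            fields = [str(d["chrom"]), str(int(d["pos"])), ".", str(d["ref"]),
                      str(d["alt"]), ".", "PASS", ".", "GT:AD"]
            fields += [f"./.:{int(d[r])},{int(d[a])}" for r, a in cols]
            fh.write("\t".join(fields) + "\n")


def read_vcf(path: str | Path,
             sample_roles: dict[str, str] | None = None) -> tuple[pd.DataFrame, int]:
    """Read a VCF with per-sample AD into a raw variant table.

    ``sample_roles`` maps VCF sample names to roles 'm_pool', 'n_pool',
    'parent1', 'parent2'; defaults to the names :func:`write_vcf` emits.
    Multi-allelic records are skipped and counted; returns
    ``(variants, n_multiallelic_skipped)``.
    """
    from cyvcf2 import VCF

    if sample_roles is None:
        sample_roles = dict(zip(VCF_SAMPLES, ("m_pool", "n_pool", "parent1", "parent2")))
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    idx = {}
    for name, role in sample_roles.items():
        if name not in samples:
            raise ValueError(f"sample {name!r} not found in {path} (has {samples})")
        idx[role] = samples.index(name)
    prefix = {"m_pool": "m", "n_pool": "n", "parent1": "p1", "parent2": "p2"}

    rows = []
    n_multi = 0
    for v in vcf:
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        ad = v.format("AD")
        if ad is None:
            raise ValueError(f"{path}: record {v.CHROM}:{v.POS} lacks the AD format field")
        rec = {"chrom": v.CHROM, "pos": v.POS, "ref": v.REF, "alt": v.ALT[0]}
        for role, i in idx.items():
            rec[f"{prefix[role]}_ref"] = max(int(ad[i][0]), 0)
            rec[f"{prefix[role]}_alt"] = max(int(ad[i][1]), 0)
        rows.append(rec)
    return pd.DataFrame(rows), n_multi


def write_bedgraph(scores: pd.DataFrame, path: str | Path, step: int) -> None:
    """CAAFD profile as bedGraph: one record per window step interval.

    Each emitted window contributes the step-sized interval around its center
    ([center, center + step), 0-based half-open) with the window's CAAFD as
    value, so adjacent records tile the stepped scan.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write('track type=bedGraph name="CAAFD" description="cubic average '
                 'allele frequency difference (0-based half-open intervals)"\n')
        for row in scores.itertuples(index=False):
            fh.write(f"{row.chrom}\t{int(row.center)}\t{int(row.center) + step}\t"
                     f"{row.caafd:.6g}\n")


def write_region(region: RegionCall, json_path: str | Path,
                 bed_path: str | Path | None = None) -> None:
    """RegionCall as a JSON summary plus an optional BED line (0-based)."""
    with open(json_path, "w") as fh:
        json.dump(region.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    if bed_path is not None:
        with open(bed_path, "w") as fh:
            fh.write(f"{region.chrom}\t{region.start}\t{region.end}\t"
                     f"peak@{region.peak_center}\t{region.peak_caafd:.6g}\n")


def read_region(json_path: str | Path) -> RegionCall:
    with open(json_path) as fh:
        return RegionCall(**json.load(fh))
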