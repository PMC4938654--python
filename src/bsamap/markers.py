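"""Marker selection from four-sample allele counts.

Raw variant calls (M-pool, N-pool, and the two parents) are turned into the
oriented marker set the CAAFD scan consumes: each kept site is an explicit
MH86/93-11 polymorphism, oriented so that m1/n1 count reads of the MH86
allele, and has a mean pool allele frequency (fM + fN)/2 inside the selection
band — 0.3 to 0.7 by default, a closed interval. Markers at this band's
center carry no mapping signal penalty; the band removes sites whose pooled
frequencies are distorted by mismapping or residual heterozygosity in a
parent.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "RAW_COUNT_COLUMNS",
    "call_parental_alleles",
    "pool_frequencies",
    "orient_pool_counts",
    "select_markers",
    "prepare_markers",
]

RAW_COUNT_COLUMNS = [
    "m_ref", "m_alt", "n_ref", "n_alt", "p1_ref", "p1_alt", "p2_ref", "p2_alt",
]

# rejection reason codes, in reporting order
REASON_PARENT_DEPTH = "parent_depth"
REASON_PARENT_IMPURE = "parent_impure"
REASON_MONOMORPHIC = "monomorphic"
REASON_POOL_DEPTH = "pool_depth"
REASON_ZERO_POOL_DEPTH = "zero_pool_depth"
REASON_MEAN_FREQ = "mean_freq_outside_band"


def _require_columns(df: pd.DataFrame, cols: list[str]) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"variant table is missing columns: {missing}")


def call_parental_alleles(
    variants: pd.DataFrame,
    purity: float = 0.9,
    min_parent_depth: int = 10,
) -> pd.DataFrame:
    """Orient biallelic variants by their parental allele counts.

    A site is accepted when each parent has total depth >= ``min_parent_depth``
    with at least ``purity`` of its reads on a single allele, and the two
    parents' majority alleles differ. The returned copy gains a
    ``mh86_is_ref`` column (which input allele the MH86 parent carries) and a
    ``reject_reason`` column (empty string for accepted sites). Rejection is a
    normal outcome, not an error.
    """
    _require_columns(variants, ["chrom", "pos", "p1_ref", "p1_alt", "p2_ref", "p2_alt"])
    out = variants.copy()
    p1d = out["p1_ref"] + out["p1_alt"]
    p2d = out["p2_ref"] + out["p2_alt"]
    with np.errstate(invalid="ignore", divide="ignore"):
        p1_ref_frac = out["p1_ref"] / p1d
        p2_ref_frac = out["p2_ref"] / p2d
    p1_major_ref = p1_ref_frac >= 0.5
    p2_major_ref = p2_ref_frac >= 0.5
    p1_purity = np.where(p1_major_ref, p1_ref_frac, 1.0 - p1_ref_frac)
    p2_purity = np.where(p2_major_ref, p2_ref_frac, 1.0 - p2_ref_frac)

    reason = np.full(len(out), "", dtype=object)
    depth_ok = (p1d >= min_parent_depth) & (p2d >= min_parent_depth)
    reason[~depth_ok] = REASON_PARENT_DEPTH
    pure_ok = (p1_purity >= purity) & (p2_purity >= purity)
    reason[depth_ok & ~pure_ok] = REASON_PARENT_IMPURE
    poly = p1_major_ref != p2_major_ref
    reason[depth_ok & pure_ok & ~poly] = REASON_MONOMORPHIC

    out["mh86_is_ref"] = p1_major_ref
    out["reject_reason"] = reason
    return out


def pool_frequencies(markers: pd.DataFrame) -> pd.DataFrame:
    """MH86-allele frequencies fM, fN of each oriented marker.

    Expects oriented counts m1/m2/n1/n2. Markers with zero total depth in a
    pool get NaN frequencies and ``usable = False``; they are excluded
    downstream rather than raising.
    """
    _require_columns(markers, ["m1", "m2", "n1", "n2"])
    out = markers.copy()
    md = out["m1"] + out["m2"]
    nd = out["n1"] + out["n2"]
    usable = (md > 0) & (nd > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out["fM"] = np.where(md > 0, out["m1"] / md, np.nan)
        out["fN"] = np.where(nd > 0, out["n1"] / nd, np.nan)
    out["mean_f"] = (out["fM"] + out["fN"]) / 2.0
    out["usable"] = usable
    return out


def orient_pool_counts(variants: pd.DataFrame) -> pd.DataFrame:
    """Map raw ref/alt counts to MH86-oriented m1/m2/n1/n2 using mh86_is_ref."""
    _require_columns(variants, ["mh86_is_ref", "m_ref", "m_alt", "n_ref", "n_alt"])
    out = variants.copy()
    is_ref = out["mh86_is_ref"].to_numpy(dtype=bool)
    out["m1"] = np.where(is_ref, out["m_ref"], out["m_alt"])
    out["m2"] = np.where(is_ref, out["m_alt"], out["m_ref"])
    out["n1"] = np.where(is_ref, out["n_ref"], out["n_alt"])
    out["n2"] = np.where(is_ref, out["n_alt"], out["n_ref"])
    if "ref" in out.columns and "alt" in out.columns:
        out["mh86_allele"] = np.where(is_ref, out["ref"], out["alt"])
        out["other_allele"] = np.where(is_ref, out["alt"], out["ref"])
    return out


def select_markers(
    markers: pd.DataFrame,
    freq_low: float = 0.3,
    freq_high: float = 0.7,
    min_pool_depth: int = 4,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the pool-depth and mean-frequency filters.

    Keeps markers whose pools each reach ``min_pool_depth`` and whose mean
    MH86-allele frequency (fM + fN)/2 lies in the closed interval
    [freq_low, freq_high]. Genomic order is preserved. Returns the selected
    table and per-reason rejection tallies.
    """
    if len(markers) == 0:
        return markers.copy(), {}
    freqs = pool_frequencies(markers)
    md = freqs["m1"] + freqs["m2"]
    nd = freqs["n1"] + freqs["n2"]
    usable = freqs["usable"].to_numpy(dtype=bool)
    depth_ok = (md >= min_pool_depth) & (nd >= min_pool_depth) & usable
    band_ok = (freqs["mean_f"] >= freq_low) & (freqs["mean_f"] <= freq_high)
    keep = depth_ok & band_ok

    tallies: dict[str, int] = {}
    n_zero = int((~usable).sum())
    if n_zero:
        tallies[REASON_ZERO_POOL_DEPTH] = n_zero
    n_depth = int((usable & ~depth_ok).sum())
    if n_depth:
        tallies[REASON_POOL_DEPTH] = n_depth
    n_band = int((depth_ok & ~band_ok).sum())
    if n_band:
        tallies[REASON_MEAN_FREQ] = n_band

    selected = freqs.loc[keep].drop(columns=["usable"]).reset_index(drop=True)
    return selected, tallies


def prepare_markers(
    variants: pd.DataFrame,
    purity: float = 0.9,
    min_parent_depth: int = 10,
    min_pool_depth: int = 4,
    freq_low: float = 0.3,
    freq_high: float = 0.7,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Full marker-selection stage: orient by parents, then filter by pools.

    Input is a raw variant table (chrom, pos, optional ref/alt, and
    ``RAW_COUNT_COLUMNS``). Returns the selected oriented marker table
    (with m1/m2/n1/n2, fM, fN, mean_f) and combined rejection tallies.
    """
    _require_columns(variants, ["chrom", "pos"] + RAW_COUNT_COLUMNS)
    called = call_parental_alleles(variants, purity=purity, min_parent_depth=min_parent_depth)
    reasons = called["reject_reason"].to_numpy()
    tallies: dict[str, int] = {}
    for code in (REASON_PARENT_DEPTH, REASON_PARENT_IMPURE, REASON_MONOMORPHIC):
        n = int((reasons == code).sum())
        if n:
            tallies[code] = n
    oriented = orient_pool_counts(called.loc[called["reject_reason"] == ""])
    selected, pool_tallies = select_markers(
        oriented, freq_low=freq_low, freq_high=freq_high, min_pool_depth=min_pool_depth
    )
    tallies.update(pool_tallies)
    drop = [c for c in ("reject_reason",) if c in selected.columns]
    return selected.drop(columns=drop).reset_index(drop=True), tallies
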