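"""Selected-recessive fine mapping.

Every plant in a mutant-only F2 panel is homozygous for the causal mutation,
so it received two mutation-carrying gametes. At a linked marker, a
93-11-derived allele on such a gamete marks one recombination event between
the marker and the trait locus, which makes recombinant gametes directly
countable from the A/H/B genotype classes:

    R = H + 2*B recombinant gametes out of G = 2*(A + H + B)

r_hat = R/G is the maximum-likelihood estimate of the recombination fraction
under the selected-gamete binomial; the LOD score compares it against free
recombination (r = 0.5), with 3.0 the conventional linkage threshold. Map
distances use the Kosambi function d = 25 * ln((1+2r)/(1-2r)) cM, which
allows moderate crossover interference.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

__all__ = [
    "RecombEstimate",
    "MapInterval",
    "estimate_r_selected",
    "lod_selected",
    "kosambi",
    "kosambi_inverse",
    "analyze_panel",
    "delimit_interval",
]


@dataclass(frozen=True)
class RecombEstimate:
    """Two-point linkage of one marker to the trait locus in a mutant panel."""

    marker: str
    A: int           # MH86 homozygotes
    H: int           # heterozygotes
    B: int           # 93-11 homozygotes
    R: int           # recombinant gametes = H + 2B
    G: int           # gametes scored = 2(A + H + B)
    r_hat: float
    lod: float

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class MapInterval:
    """Candidate interval between the innermost recombinant-bearing markers."""

    left_marker: str | None
    right_marker: str | None
    left_pos: int | None
    right_pos: int | None
    cosegregating: tuple[str, ...]   # zero-recombinant (or minimum-R) markers inside
    length_bp: int | None
    open_left: bool
    open_right: bool

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cosegregating"] = list(self.cosegregating)
        return d


def lod_selected(R: int, G: int, r_hat: float | None = None) -> float:
    """Base-10 LOD of linkage at r_hat against r = 0.5.

    lod = R*log10(r/0.5) + (G-R)*log10((1-r)/0.5); the R*log10(r) term is 0
    by convention when R = 0.
    """
    if G <= 0 or not (0 <= R <= G):
        raise ValueError(f"require 0 <= R <= G with G > 0, got R={R}, G={G}")
    if r_hat is None:
        r_hat = R / G
    lod = 0.0
    if R > 0:
        lod += R * np.log10(r_hat / 0.5)
    if G - R > 0:
        lod += (G - R) * np.log10((1.0 - r_hat) / 0.5)
    return float(lod)


def estimate_r_selected(A: int, H: int, B: int, marker: str = "") -> RecombEstimate:
    """Recombination fraction from A/H/B counts of a mutant-only panel."""
    if min(A, H, B) < 0:
        raise ValueError("genotype counts must be non-negative")
    plants = A + H + B
    if plants < 1:
        raise ValueError("at least one genotyped plant is required")
    R = H + 2 * B
    G = 2 * plants
    r_hat = min(R / G, 0.5)  # R <= G by construction; cap kept for imported data
    return RecombEstimate(marker=marker, A=A, H=H, B=B, R=R, G=G,
                          r_hat=r_hat, lod=lod_selected(R, G, r_hat))


def kosambi(r: float | np.ndarray) -> float | np.ndarray:
    """Kosambi map distance in cM: d = 25 * ln((1+2r)/(1-2r))."""
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r >= 0.5)):
        raise ValueError("recombination fraction must lie in [0, 0.5)")
    d = 25.0 * np.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))
    return float(d) if d.ndim == 0 else d


def kosambi_inverse(d: float | np.ndarray) -> float | np.ndarray:
    """Inverse Kosambi: r = 0.5 * tanh(d / 50) for d in cM."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be >= 0")
    r = 0.5 * np.tanh(d / 50.0)
    return float(r) if r.ndim == 0 else r


def _marker_estimates(panel: pd.DataFrame, marker_cols: list[str]) -> tuple[list[RecombEstimate], dict[str, int]]:
    estimates = []
    dropped: dict[str, int] = {}
    for col in marker_cols:
        g = panel[col].astype(str)
        valid = g.isin(["A", "H", "B"])
        n_drop = int((~valid).sum())
        if n_drop:
            dropped[col] = n_drop
        g = g[valid]
        if len(g) == 0:
            raise ValueError(f"marker {col!r}: no usable genotypes")
        counts = g.value_counts()
        estimates.append(estimate_r_selected(
            int(counts.get("A", 0)), int(counts.get("H", 0)), int(counts.get("B", 0)),
            marker=col,
        ))
    return estimates, dropped


def analyze_panel(
    panel: pd.DataFrame,
    positions: pd.DataFrame,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Per-marker linkage estimates for a mutant-only genotyping panel.

    ``panel`` holds one row per plant with A/H/B genotype columns named in
    ``positions`` (columns ``marker``, ``chrom``, ``pos``). Genotypes outside
    {A, H, B} (missing data) are dropped per marker and tallied. Returns a
    frame ordered by physical position with columns marker, chrom, pos, A, H,
    B, R, G, r_hat, cM, lod, plus the per-marker dropped-genotype tally.
    """
    pos_sorted = positions.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    missing = [m for m in pos_sorted["marker"] if m not in panel.columns]
    if missing:
        raise ValueError(f"panel lacks genotype columns for markers: {missing}")
    estimates, dropped = _marker_estimates(panel, list(pos_sorted["marker"]))
    table = pd.DataFrame([e.to_dict() for e in estimates])
    table.insert(1, "chrom", pos_sorted["chrom"].to_numpy())
    table.insert(2, "pos", pos_sorted["pos"].to_numpy())
    table["cM"] = [kosambi(e.r_hat) if e.r_hat < 0.5 else np.inf for e in estimates]
    return table, dropped


def delimit_interval(estimates: pd.DataFrame) -> MapInterval:
    """Delimit the candidate interval from physically ordered marker estimates.

    The interval is bracketed by the innermost markers carrying at least one
    recombinant on each side of the zero-recombinant markers (falling back to
    the minimum-recombinant markers when none is zero). When several separate
    runs of minimum-R markers exist, the longest (first on ties) anchors the
    interval. A side with no recombinant-bearing marker leaves the interval
    open on that side rather than silently clipped.
    """
    if len(estimates) < 2:
        raise ValueError("need at least two markers to delimit an interval")
    est = estimates.reset_index(drop=True)
    R = est["R"].to_numpy(dtype=int)
    if np.all(R == 0):
        raise ValueError("interval unresolvable: no marker shows a recombinant")
    min_r = int(R.min())
    is_min = R == min_r

    # longest run of minimum-R markers (first on ties)
    best = (0, -1, -1)
    i = 0
    while i < len(R):
        if is_min[i]:
            j = i
            while j + 1 < len(R) and is_min[j + 1]:
                j += 1
            if j - i + 1 > best[0]:
                best = (j - i + 1, i, j)
            i = j + 1
        else:
            i += 1
    _, lo, hi = best

    left = next((k for k in range(lo - 1, -1, -1) if R[k] > 0), None)
    right = next((k for k in range(hi + 1, len(R)) if R[k] > 0), None)
    left_row = est.iloc[left] if left is not None else None
    right_row = est.iloc[right] if right is not None else None
    length = None
    if left_row is not None and right_row is not None and left_row["chrom"] == right_row["chrom"]:
        length = int(right_row["pos"] - left_row["pos"])
    return MapInterval(
        left_marker=None if left_row is None else str(left_row["marker"]),
        right_marker=None if right_row is None else str(right_row["marker"]),
        left_pos=None if left_row is None else int(left_row["pos"]),
        right_pos=None if right_row is None else int(right_row["pos"]),
        cosegregating=tuple(est.iloc[k]["marker"] for k in range(lo, hi + 1)),
        length_bp=length,
        open_left=left_row is None,
        open_right=right_row is None,
    )
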