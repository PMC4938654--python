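"""Classical-genetics statistics: segregation goodness-of-fit and cross summaries.

The two-class segregation test compares observed phenotype counts against a
Mendelian ratio (3:1 by default for a recessive trait in an F2) with a
chi-square statistic on 1 degree of freedom. The Yates continuity correction
is applied by default; with a single degree of freedom the uncorrected
Pearson statistic is anti-conservative at these sample sizes, and both values
are always reported.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from math import sqrt

import numpy as np
from scipy import stats

__all__ = ["SegregationResult", "CrossSummary", "segregation_chisq", "cross_summary"]


@dataclass(frozen=True)
class SegregationResult:
    observed: tuple[int, int]
    expected: tuple[float, float]
    ratio: tuple[float, float]
    continuity: bool
    chi_square: float
    p_value: float
    chi_square_uncorrected: float
    p_value_uncorrected: float

    def to_dict(self) -> dict:
        d = asdict(self)
        for k in ("observed", "expected", "ratio"):
            d[k] = list(d[k])
        return d


@dataclass(frozen=True)
class CrossSummary:
    """Seed-setting summary of one cross, per-panicle and pooled."""

    n_panicles: int
    total_spikelets: int
    total_seeds: int
    rates: tuple[float, ...]     # per-panicle seed-setting rates, %
    mean_rate: float             # mean over panicles, %
    sd_rate: float               # sample SD (n-1) over panicles; 0 with n = 1
    sd_defined: bool             # False when only one panicle
    pooled_rate: float           # 100 * total seeds / total spikelets

    def to_dict(self) -> dict:
        d = asdict(self)
        d["rates"] = list(d["rates"])
        return d


def segregation_chisq(
    observed: tuple[int, int],
    ratio: tuple[float, float] = (3.0, 1.0),
    continuity: bool = True,
) -> SegregationResult:
    """Two-class segregation chi-square test (1 df).

    With ``continuity`` on, each class contributes (max(|O-E| - 0.5, 0))^2/E
    (Yates); off, the plain Pearson (O-E)^2/E. Both statistics and p-values
    are computed; ``chi_square``/``p_value`` reflect the requested mode.
    """
    o = np.asarray(observed, dtype=float)
    w = np.asarray(ratio, dtype=float)
    if o.shape != (2,) or w.shape != (2,):
        raise ValueError("segregation_chisq handles exactly two phenotype classes")
    if np.any(o < 0) or o.sum() < 1:
        raise ValueError("observed counts must be non-negative with a positive total")
    if np.any(w <= 0):
        raise ValueError("ratio weights must be positive")
    e = o.sum() * w / w.sum()

    pearson = float(np.sum((o - e) ** 2 / e))
    corrected = float(np.sum(np.maximum(np.abs(o - e) - 0.5, 0.0) ** 2 / e))
    p_pearson = float(stats.chi2.sf(pearson, df=1))
    p_corrected = float(stats.chi2.sf(corrected, df=1))
    chi, p = (corrected, p_corrected) if continuity else (pearson, p_pearson)
    return SegregationResult(
        observed=(int(observed[0]), int(observed[1])),
        expected=(float(e[0]), float(e[1])),
        ratio=(float(ratio[0]), float(ratio[1])),
        continuity=continuity,
        chi_square=chi,
        p_value=p,
        chi_square_uncorrected=pearson,
        p_value_uncorrected=p_pearson,
    )


def cross_summary(panicles: list[tuple[int, int]]) -> CrossSummary:
    """Summarize seed setting of a cross from per-panicle (spikelets, seeds).

    Per-panicle rate = 100 * seeds / spikelets. The mean and SD are taken
    over panicle rates (sample SD, n-1 denominator), matching how reciprocal-
    cross seed-setting tables are reported; the pooled rate uses summed
    counts. A single panicle has no sample SD: it is reported as 0 with
    ``sd_defined = False``.
    """
    if not panicles:
        raise ValueError("cross_summary requires at least one panicle")
    for spikelets, seeds in panicles:
        if spikelets < 1:
            raise ValueError(f"panicle spikelet count must be >= 1, got {spikelets}")
        if not (0 <= seeds <= spikelets):
            raise ValueError(f"seeds ({seeds}) must be in [0, spikelets ({spikelets})]")
    rates = [100.0 * seeds / spikelets for spikelets, seeds in panicles]
    n = len(rates)
    mean = sum(rates) / n
    if n > 1:
        sd = sqrt(sum((r - mean) ** 2 for r in rates) / (n - 1))
        sd_defined = True
    else:
        sd, sd_defined = 0.0, False
    total_spk = sum(s for s, _ in panicles)
    total_seed = sum(x for _, x in panicles)
    return CrossSummary(
        n_panicles=n,
        total_spikelets=total_spk,
        total_seeds=total_seed,
        rates=tuple(rates),
        mean_rate=mean,
        sd_rate=sd,
        sd_defined=sd_defined,
        pooled_rate=100.0 * total_seed / total_spk,
    )
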