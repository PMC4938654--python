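"""End-to-end pipeline: simulate -> select markers -> scan -> fine-map ->
candidate screen -> cosegregation -> segregation test.

One global seed is split deterministically across the stochastic stages, so
identical config + seed reproduces every stage output byte for byte; the run
manifest records a sha256 digest per output file to make this checkable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import SimConfig
from .candidates import cosegregation_test, filter_candidates
from .finemap import analyze_panel, delimit_interval
from .genstats import segregation_chisq
from .io import (
    marker_table_to_raw,
    write_bedgraph,
    write_region,
    write_tsv,
)
from .markers import prepare_markers
from .scan import call_peak_region, scan_genome
from .simulate import (
    simulate_f2_population,
    make_bulks,
    simulate_panels,
    simulate_pool_counts,
    simulate_region_variants,
)

__all__ = ["PipelineOptions", "RunManifest", "run_pipeline", "DEMO_STAGE_OPTIONS"]

logger = logging.getLogger("bsamap")
if not logger.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("[bsamap:%(stage)s] %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)


def _log(stage: str, msg: str) -> None:
    logger.info(msg, extra={"stage": stage})


@dataclass
class PipelineOptions:
    """Tunable per-stage options with pipeline defaults."""

    # marker selection
    purity: float = 0.9
    min_parent_depth: int = 10
    min_pool_depth: int = 4
    freq_low: float = 0.3
    freq_high: float = 0.7
    # scan
    window_size: int = 2_000_000
    step: int = 10_000
    alpha: float = 0.5
    min_markers: int = 1
    # fine mapping
    n_panel: int = 199
    n_panel_markers: int = 11
    lod_threshold: float = 3.0
    # candidate screen
    n_background: int = 500
    depth_region_screen: float = 40.0
    min_support: int = 2
    max_contam_fraction: float = 0.05
    # cosegregation
    n_coseg: int = 280

    @classmethod
    def from_stage_dict(cls, stages: dict) -> "PipelineOptions":
        flat: dict = {}
        for section in ("markers", "scan", "finemap", "candidate", "coseg"):
            flat.update(stages.get(section) or {})
        known = set(cls.__dataclass_fields__)
        extra = set(flat) - known
        if extra:
            raise ValueError(f"unknown pipeline options: {sorted(extra)}")
        return cls(**flat)


# option overrides that keep the demo pipeline fast on a small population
DEMO_STAGE_OPTIONS = {"finemap": {"n_panel": 60}, "coseg": {"n_coseg": 100}}


@dataclass
class RunManifest:
    config: dict
    options: dict
    seed: int
    version: str
    digests: dict[str, str] = field(default_factory=dict)
    timestamps: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "options": self.options,
            "seed": self.seed,
            "version": self.version,
            "digests": self.digests,
            "timestamps": self.timestamps,
        }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_json(obj: dict, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_pipeline(
    config: SimConfig,
    out_dir: str | Path,
    options: PipelineOptions | None = None,
    seed: int | None = None,
) -> tuple[RunManifest, dict]:
    """Run every stage, write all outputs under ``out_dir``, return manifest.

    ``seed`` overrides ``config.seed``. The returned dict exposes the key
    in-memory results (region call, interval, cosegregation and segregation
    results, candidate table) for programmatic use.
    """
    opts = options or PipelineOptions()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if seed is None:
        seed = config.seed
    rngs = [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(5)]
    r_pop, r_bulk, r_counts, r_panels, r_region = rngs
    manifest = RunManifest(
        config=config.to_dict(), options=opts.__dict__.copy(),
        seed=seed, version=__version__,
    )
    files: list[Path] = []

    def emit(name: str, writer) -> Path:
        path = out / name
        writer(path)
        manifest.timestamps[name] = time.time()
        files.append(path)
        return path

    # stage 1: simulate population, bulks, pooled counts
    _log("simulate", f"simulating F2 of {config.n_f2} plants, seed {seed}")
    pop = simulate_f2_population(config, r_pop)
    n_mut = int(pop.phenotype.sum())
    _log("simulate", f"{n_mut} mutant / {config.n_f2 - n_mut} normal plants")
    bulks = make_bulks(pop, config, r_bulk)
    table = simulate_pool_counts(pop, bulks, config, r_counts)
    coord_note = "pos is 1-based"
    emit("markers.tsv", lambda p: write_tsv(table.markers, p, comment=coord_note))
    emit("truth_markers.tsv", lambda p: write_tsv(table.truth, p, comment=coord_note))
    plants = pd.DataFrame({
        "plant_id": [f"F{j:04d}" for j in range(config.n_f2)],
        "phenotype": np.where(pop.phenotype, "mutant", "normal"),
        "causal_genotype": pop.causal_genotype,
    })
    emit("plants.tsv", lambda p: write_tsv(plants, p))

    # stage 2: marker selection
    raw = marker_table_to_raw(table.markers)
    selected, tallies = prepare_markers(
        raw, purity=opts.purity, min_parent_depth=opts.min_parent_depth,
        min_pool_depth=opts.min_pool_depth,
        freq_low=opts.freq_low, freq_high=opts.freq_high,
    )
    _log("select", f"kept {len(selected)}/{len(raw)} markers; rejections {tallies}")
    emit("selected_markers.tsv", lambda p: write_tsv(selected, p, comment=coord_note))
    rej = pd.DataFrame(sorted(tallies.items()), columns=["reason", "count"])
    emit("rejections.tsv", lambda p: write_tsv(rej, p))
    if len(selected) == 0:
        raise RuntimeError("stage select: no markers survived selection")

    # stage 3: CAAFD scan and peak region
    scores = scan_genome(
        selected, window_size=opts.window_size, step=opts.step,
        chrom_lengths=config.chrom_lengths, min_markers=opts.min_markers,
    )
    region = call_peak_region(scores, alpha=opts.alpha)
    _log("scan", f"{len(scores)} windows; peak {region.chrom}:{region.peak_center} "
                 f"CAAFD={region.peak_caafd:.3f}, region "
                 f"{region.chrom}:{region.start}-{region.end}")
    emit("scan.tsv", lambda p: write_tsv(
        scores, p, comment="window [start,end) 0-based half-open; center on step grid"))
    emit("scan.bedgraph", lambda p: write_bedgraph(scores, p, step=opts.step))
    emit("region.json", lambda p: write_region(region, p, bed_path=None))
    emit("region.bed", lambda p: write_region(region, out / "region.json", bed_path=p))

    # stage 4: fine mapping inside the called region
    chrom_grid = pop.positions[region.chrom]
    in_region = chrom_grid[(chrom_grid >= region.start) & (chrom_grid <= region.end)]
    if in_region.size < 2:
        raise RuntimeError("stage finemap: called region holds fewer than two markers")
    pick = np.unique(np.linspace(0, in_region.size - 1, opts.n_panel_markers).round().astype(int))
    panel_markers = pd.DataFrame({"chrom": region.chrom, "pos": in_region[pick]})
    fm_panel, coseg_panel = simulate_panels(
        pop, config, n_finemap=opts.n_panel, n_coseg=opts.n_coseg,
        panel_markers=panel_markers, rng=r_panels,
    )
    positions = pd.DataFrame({
        "marker": [f"{region.chrom}:{p}" for p in panel_markers["pos"]],
        "chrom": region.chrom,
        "pos": panel_markers["pos"],
    })
    estimates, dropped = analyze_panel(fm_panel, positions)
    interval = delimit_interval(estimates)
    linked = estimates[estimates["lod"] >= opts.lod_threshold]
    _log("finemap", f"{len(linked)}/{len(estimates)} markers pass LOD >= "
                    f"{opts.lod_threshold}; interval "
                    f"{interval.left_marker} .. {interval.right_marker}")
    emit("finemap_panel.tsv", lambda p: write_tsv(fm_panel, p))
    emit("finemap_estimates.tsv", lambda p: write_tsv(estimates, p, comment=coord_note))
    emit("interval.json", lambda p: _write_json(interval.to_dict(), p))

    # stage 5: candidate-variant screen over the called region
    screen_region = (region.chrom, region.start, max(region.end, region.start + 1))
    variants, causal_pos = simulate_region_variants(
        pop, bulks, config, screen_region, n_background=opts.n_background,
        depth_pool=opts.depth_region_screen, rng=r_region,
    )
    cands, undet = filter_candidates(
        variants, min_support=opts.min_support,
        max_contam_fraction=opts.max_contam_fraction,
    )
    _log("candidate", f"{len(cands)} candidate(s), {len(undet)} undetermined "
                      f"among {len(variants)} region variants")
    emit("region_variants.tsv", lambda p: write_tsv(variants, p, comment=coord_note))
    emit("candidates.tsv", lambda p: write_tsv(cands, p, comment=coord_note))
    emit("undetermined.tsv", lambda p: write_tsv(undet, p, comment=coord_note))

    # stage 6: cosegregation of the top candidate in a random F2 sample
    coseg = cosegregation_test(coseg_panel)
    _log("coseg", f"concordant={coseg.concordant} over {len(coseg_panel)} plants")
    emit("coseg_panel.tsv", lambda p: write_tsv(coseg_panel, p))
    emit("cosegregation.json", lambda p: _write_json(coseg.to_dict(), p))

    # stage 7: segregation goodness-of-fit (3:1 for a recessive trait)
    n_mutant = int((plants["phenotype"] == "mutant").sum())
    n_normal = config.n_f2 - n_mutant
    seg = segregation_chisq((n_normal, n_mutant), ratio=(3.0, 1.0))
    _log("segtest", f"{n_normal}:{n_mutant} vs 3:1, chi2={seg.chi_square:.3f} "
                    f"p={seg.p_value:.3f}")
    emit("segregation.json", lambda p: _write_json(seg.to_dict(), p))

    for path in files:
        manifest.digests[path.name] = _sha256(path)
    _write_json(manifest.to_dict(), out / "manifest.json")

    results = {
        "population": pop,
        "bulks": bulks,
        "region": region,
        "interval": interval,
        "estimates": estimates,
        "candidates": cands,
        "cosegregation": coseg,
        "segregation": seg,
        "causal_pos": causal_pos,
        "scores": scores,
    }
    return manifest, results
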