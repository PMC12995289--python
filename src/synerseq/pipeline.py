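"""End-to-end orchestration: simulate -> fit -> classify -> summarize.

A :class:`RunConfig` captures every knob (seed, design size, planted
archetypes, thresholds, stage toggles); :func:`run_pipeline` executes the
enabled stages, writes all TSV/JSON artifacts into an output directory and
returns a manifest (config echo, per-stage row counts, artifact paths).
Fixed config + seed gives byte-identical artifacts.  Real count/design
inputs, or an externally produced DE table, can replace the simulation
stage.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from . import io as sio
from .classify import Thresholds, classify_table, summarize_regulation
from .de import run_de
from .sets import concordance_r2, deg_sets
from .simulate import make_design, plant_archetypes, simulate_counts

logger = logging.getLogger(__name__)

# per-stage child seeds derived from the master seed by fixed offsets, so a
# stage rerun in isolation reproduces the full run's stream
SEED_OFFSET_DESIGN = 1
SEED_OFFSET_TRUTH = 2
SEED_OFFSET_COUNTS = 3


@dataclass
class RunConfig:
    seed: int = 0
    n_per_group: int = 7
    archetype_counts: dict | int = 200
    effect_size: float = 1.5
    dispersion: float = 0.05
    size_factor_range: tuple = (0.7, 1.4)
    baseline_log2_mean_range: tuple = (3.0, 12.0)
    alpha: float = 0.05
    min_abs_l2fc: float = 0.585
    zero_tol: float = 0.01
    min_total: int = 10
    counts_path: str | None = None
    design_path: str | None = None
    de_table_path: str | None = None
    outdir: str = "synerseq_out"
    do_simulate: bool = True
    do_fit: bool = True
    do_classify: bool = True
    do_summarize: bool = True

    @property
    def thresholds(self) -> Thresholds:
        return Thresholds(alpha=self.alpha, min_abs_l2fc=self.min_abs_l2fc)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the enabled stages and return the artifact manifest."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(cfg).items()},
        "stages": {},
        "artifacts": {},
    }
    th = cfg.thresholds
    cm = None
    de = None

    if cfg.do_simulate and cfg.counts_path is None and cfg.de_table_path is None:
        t0 = time.perf_counter()
        design = make_design(cfg.n_per_group, tuple(cfg.size_factor_range), cfg.seed + SEED_OFFSET_DESIGN)
        truth = plant_archetypes(
            cfg.archetype_counts,
            cfg.effect_size,
            tuple(cfg.baseline_log2_mean_range),
            cfg.dispersion,
            cfg.seed + SEED_OFFSET_TRUTH,
        )
        cm = simulate_counts(truth, design, cfg.seed + SEED_OFFSET_COUNTS)
        sio.write_design(design, out / "design.tsv")
        sio.write_truth(truth, out / "truth.tsv")
        sio.write_counts(cm, out / "counts.tsv")
        manifest["artifacts"].update(
            design=str(out / "design.tsv"), truth=str(out / "truth.tsv"), counts=str(out / "counts.tsv")
        )
        manifest["stages"]["simulate"] = {
            "genes_simulated": cm.n_genes,
            "samples": cm.n_samples,
            "seconds": round(time.perf_counter() - t0, 3),
        }
        logger.info("simulated %d genes x %d samples", cm.n_genes, cm.n_samples)
    elif cfg.counts_path is not None:
        cm = sio.read_counts(cfg.counts_path, cfg.design_path)
        manifest["stages"]["load_counts"] = {"genes": cm.n_genes, "samples": cm.n_samples}

    if cfg.do_fit and cfg.de_table_path is None:
        if cm is None:
            raise ValueError("fit stage requires counts (simulated or loaded)")
        t0 = time.perf_counter()
        de = run_de(cm, min_total=cfg.min_total)
        sio.write_de_table(de, out / "de_table.tsv")
        manifest["artifacts"]["de_table"] = str(out / "de_table.tsv")
        manifest["stages"]["fit"] = {
            "genes_tested": int(de["gene_id"].nunique()),
            "seconds": round(time.perf_counter() - t0, 3),
        }
        logger.info("fitted %d genes", de["gene_id"].nunique())
    elif cfg.de_table_path is not None:
        de = sio.read_de_table(cfg.de_table_path)
        manifest["stages"]["load_de_table"] = {"genes_tested": int(de["gene_id"].nunique())}

    reg = None
    if cfg.do_classify:
        if de is None:
            raise ValueError("classify stage requires a DE table")
        t0 = time.perf_counter()
        reg = classify_table(de, th, zero_tol=cfg.zero_tol)
        sio.write_regulation(reg, out / "regulation.tsv")
        manifest["artifacts"]["regulation"] = str(out / "regulation.tsv")
        manifest["stages"]["classify"] = {
            "genes_classified": int(len(reg)),
            "seconds": round(time.perf_counter() - t0, 3),
        }

    if cfg.do_summarize and de is not None:
        t0 = time.perf_counter()
        summary: dict = {"deg_counts": {}}
        for contrast in ("A", "B", "AB", "INT"):
            (s,) = deg_sets({"all": de}, contrast, th)
            summary["deg_counts"][contrast] = {"total": len(s.genes), "up": s.n_up, "down": s.n_down}
        try:
            r2, n = concordance_r2(de, "AB_degs", th)
            summary["concordance_r2_AB_degs"] = {"r2": r2, "n": n}
        except ValueError:
            summary["concordance_r2_AB_degs"] = None
        if reg is not None:
            summary["regulation"] = summarize_regulation(reg)
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)
        manifest["artifacts"]["summary"] = str(out / "summary.json")
        manifest["stages"]["summarize"] = {"seconds": round(time.perf_counter() - t0, 3)}

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
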