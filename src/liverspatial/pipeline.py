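"""End-to-end orchestration: simulate -> qc -> score -> layers -> enrich ->
diverge -> coloc -> de, producing files plus a run report with digests.

A single global seed is fanned out deterministically to per-stage seeds by
hashing the stage name, so adding or reordering stages never perturbs the
randomness of the others.  Every intermediate is written to ``outdir`` and
its SHA-256 digest recorded in the report, making a run auditable and
exactly repeatable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import composition, coloc, divergence, diffexpr, scoring, zonation
from .core_io import QCConfig, normalize_log1p, qc_filter, write_counts, write_obs_meta
from .synth import CellTypeSpec, GroupSpec, SynthConfig, simulate_single_cell, simulate_spatial

__all__ = ["RunConfig", "run_pipeline", "stage_seed", "load_run_config"]

logger = logging.getLogger(__name__)


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31 derived from a global seed."""
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """Validated parameters of a full pipeline run."""

    seed: int = 0
    qc_spot: QCConfig = field(default_factory=lambda: QCConfig(
        max_mito_fraction=0.05, min_genes=5, max_genes=None))
    qc_cell: QCConfig = field(default_factory=lambda: QCConfig(
        max_mito_fraction=0.10, min_genes=5, max_genes=6000))
    cv_signature: str = "CV"
    pv_signature: str = "PV"
    n_layers: int = 9
    n_per_group: int = 250
    reps: int = 100
    dims: int = 10
    n_perm: int = 10000
    lfc_thresh: float = 1.0
    padj_thresh: float = 0.05
    coloc_pair: tuple[str, str] = ("Tex", "PP_hepatocyte")
    synth: SynthConfig = field(default_factory=SynthConfig)

    def validate(self) -> None:
        problems = []
        if not self.cv_signature:
            problems.append("cv_signature: missing")
        if not self.pv_signature:
            problems.append("pv_signature: missing")
        for name, lo in (("n_layers", 2), ("n_per_group", 2), ("reps", 1),
                         ("dims", 1), ("n_perm", 1)):
            if getattr(self, name) < lo:
                problems.append(f"{name}: must be >= {lo}")
        if not 0 < self.padj_thresh <= 1:
            problems.append("padj_thresh: must be in (0, 1]")
        if problems:
            raise ValueError("invalid run config: " + "; ".join(problems))


def load_run_config(path: str | Path) -> RunConfig:
    d = yaml.safe_load(Path(path).read_text()) or {}
    kwargs: dict = {}
    for key in ("seed", "cv_signature", "pv_signature", "n_layers", "n_per_group",
                "reps", "dims", "n_perm", "lfc_thresh", "padj_thresh"):
        if key in d:
            kwargs[key] = d[key]
    if "coloc_pair" in d:
        kwargs["coloc_pair"] = tuple(d["coloc_pair"])
    for qc_key, attr in (("qc_spot", "qc_spot"), ("qc_cell", "qc_cell")):
        if qc_key in d:
            kwargs[attr] = QCConfig.from_dict(d[qc_key])
    if "synth" in d:
        s = dict(d["synth"])
        if "cell_types" in s:
            s["cell_types"] = [CellTypeSpec(**ct) for ct in s["cell_types"]]
        if "sc_groups" in s:
            s["sc_groups"] = {g: GroupSpec(**spec) for g, spec in s["sc_groups"].items()}
        if "grid_shape" in s:
            s["grid_shape"] = tuple(s["grid_shape"])
        kwargs["synth"] = SynthConfig(**s)
    cfg = RunConfig(**kwargs)
    cfg.validate()
    return cfg


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: RunConfig, outdir: str | Path) -> dict:
    """Execute all stages on synthetic data; returns the run report dict."""
    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}, "seed": cfg.seed, "files": {}}
    t_all = time.time()

    def record(stage: str, t0: float, **info) -> None:
        report["stages"][stage] = {"elapsed_s": round(time.time() - t0, 3), **info}
        logger.info("stage %s done in %.2fs", stage, time.time() - t0)

    def save(name: str, writer) -> Path:
        path = outdir / name
        writer(path)
        report["files"][name] = _digest(path)
        return path

    try:
        # --- simulate -------------------------------------------------
        t0 = time.time()
        synth_cfg = SynthConfig(**{**cfg.synth.__dict__,
                                   "seed": stage_seed(cfg.seed, "simulate")})
        sp_counts, sp_meta, ab, sp_truth = simulate_spatial(synth_cfg)
        sc_counts, sc_meta, sc_truth = simulate_single_cell(synth_cfg)
        save("spatial_counts.tsv", lambda p: write_counts(sp_counts, p))
        save("spatial_meta.tsv", lambda p: write_obs_meta(sp_meta, p))
        save("abundance.tsv", lambda p: ab.to_csv(p, sep="\t"))
        save("truth.json", lambda p: sp_truth.to_json(p))
        record("simulate", t0, n_spots=sp_counts.shape[0], n_cells=sc_counts.shape[0])

        # --- qc -------------------------------------------------------
        t0 = time.time()
        sp_counts_f, sp_report = qc_filter(sp_counts, cfg.qc_spot)
        sc_counts_f, sc_report = qc_filter(sc_counts, cfg.qc_cell)
        ab = ab.loc[sp_counts_f.obs_ids]
        record("qc", t0, spot=sp_report.to_dict(), cell=sc_report.to_dict())

        # --- normalize + score ---------------------------------------
        t0 = time.time()
        sp_norm = normalize_log1p(sp_counts_f)
        sc_norm = normalize_log1p(sc_counts_f)
        sigs = scoring.SignatureSet({
            cfg.cv_signature: sp_truth.cv_markers,
            cfg.pv_signature: sp_truth.pv_markers,
        })
        score_table = scoring.score_all(sp_norm, sigs,
                                        seed=stage_seed(cfg.seed, "score"))
        save("scores.tsv", lambda p: score_table.to_csv(p, sep="\t"))
        record("score", t0, signatures=list(sigs))

        # --- layers ---------------------------------------------------
        t0 = time.time()
        rs = zonation.region_score(score_table, cfg.cv_signature, cfg.pv_signature)
        layers = zonation.assign_layers(rs, sp_meta, n_layers=cfg.n_layers)
        save("layers.tsv", lambda p: layers.to_csv(p, sep="\t", index=False))
        record("layers", t0, n_layers=cfg.n_layers)

        # --- enrich ---------------------------------------------------
        t0 = time.time()
        sc_meta_f = sc_meta[sc_meta["obs_id"].isin(sc_counts_f.obs_ids)]
        enrich = composition.roe_enrichment(sc_meta_f)
        save("enrichment.tsv", lambda p: enrich.to_csv(p, sep="\t"))
        record("enrich", t0, n_types=len(enrich))

        # --- diverge --------------------------------------------------
        t0 = time.time()
        emb = divergence.embed_pca(sc_norm, dims=cfg.dims)
        div = divergence.subsampled_divergence(
            emb, sc_meta_f, n_per_group=cfg.n_per_group, reps=cfg.reps,
            seed=stage_seed(cfg.seed, "diverge"))
        save("divergence.tsv", lambda p: div.summary().to_csv(p, sep="\t"))
        record("diverge", t0, ranked=list(div.median.index))

        # --- coloc ----------------------------------------------------
        t0 = time.time()
        profile = coloc.layer_profile(ab, layers, sp_meta)
        save("layer_profile.tsv", lambda p: profile.long().to_csv(p, sep="\t", index=False))
        perm = coloc.permutation_coloc(
            ab, sp_meta, *cfg.coloc_pair, n_perm=cfg.n_perm,
            seed=stage_seed(cfg.seed, "coloc"))
        save("coloc.json", lambda p: p.write_text(json.dumps(perm.to_dict(), indent=1)))
        record("coloc", t0, p_perm=perm.p_perm)

        # --- de -------------------------------------------------------
        t0 = time.time()
        de = diffexpr.de_test(sc_norm, sc_meta_f, "old", "young",
                              lfc_thresh=cfg.lfc_thresh, padj_thresh=cfg.padj_thresh)
        save("de.tsv", lambda p: de.to_csv(p, sep="\t", index=False))
        record("de", t0, n_up=int((de["direction"] == "up").sum()),
               n_down=int((de["direction"] == "down").sum()))
    except Exception as err:
        done = list(report["stages"])
        stage = "simulate qc score layers enrich diverge coloc de".split()[len(done)] \
            if len(done) < 8 else "?"
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    report["elapsed_s"] = round(time.time() - t_all, 3)
    (outdir / "report.json").write_text(json.dumps(report, indent=1))
    return report
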