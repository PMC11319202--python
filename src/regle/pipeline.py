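"""End-to-end driver: simulate -> QC -> features -> encode -> GWAS -> PRS.

Reproduces the three-step design on synthetic data at desk scale:
learn a low-dimensional embedding of the waveforms, run a GWAS on each
latent coordinate, then train a small linear model combining the
per-coordinate polygenic scores into a disease score.  Every stage
writes its outputs under the run directory and records them in a
manifest (file, checksum, stage, seed); deterministic stages reproduce
their checksums on rerun.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import assoc, features, preprocess, prs, representation, synthgen
from .io import write_effects_tsv, write_loci_bed

logger = logging.getLogger("regle")

__all__ = ["PipelineConfig", "run_pipeline", "load_pipeline_config"]


@dataclass
class PipelineConfig:
    """One YAML-mappable object driving the whole pipeline."""

    sim: synthgen.SimConfig = field(default_factory=synthgen.SimConfig)
    vae: representation.VAEConfig = field(default_factory=representation.VAEConfig)
    p_thresh: float = assoc.GWS_P
    r2_thresh: float = assoc.CLUMP_R2
    merge_dist: int = assoc.LOCUS_MERGE_DISTANCE
    bootstrap_reps: int = prs.BOOTSTRAP_REPS
    train_frac: float = 0.8
    seed: int = 0

    def validate(self) -> None:
        self.sim.validate()
        self.vae.validate()
        if min(self.p_thresh, self.r2_thresh, self.merge_dist) <= 0:
            raise ValueError("association thresholds must be positive")
        if self.bootstrap_reps < 2:
            raise ValueError("bootstrap_reps must be at least 2")

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @classmethod
    def from_mapping(cls, raw: dict) -> "PipelineConfig":
        sim = synthgen.SimConfig(**raw.get("sim", {}))
        vae_raw = dict(raw.get("vae", {}))
        for key in ("conv_channels", "fc_widths"):
            if key in vae_raw:
                vae_raw[key] = tuple(vae_raw[key])
        vae = representation.VAEConfig(**vae_raw)
        kw = {k: v for k, v in raw.items() if k not in ("sim", "vae")}
        return cls(sim=sim, vae=vae, **kw)


def load_pipeline_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "sim" in raw and "disease_weights" in raw["sim"]:
        raw["sim"]["disease_weights"] = tuple(raw["sim"]["disease_weights"])
    return PipelineConfig.from_mapping(raw)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class _Manifest:
    def __init__(self, outdir: str, seed: int):
        self.outdir = outdir
        self.seed = seed
        self.entries: List[Dict] = []

    def add(self, stage: str, path: str) -> None:
        self.entries.append(
            {
                "stage": stage,
                "file": os.path.relpath(path, self.outdir),
                "sha256": _sha256(path),
                "seed": self.seed,
            }
        )

    def write(self) -> str:
        path = os.path.join(self.outdir, "manifest.json")
        with open(path, "w") as fh:
            json.dump(self.entries, fh, indent=2)
        return path


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run every stage, returning the manifest as a dict.

    Aborts with the failing stage's name on error; stages completed up to
    that point remain on disk with a partial manifest.
    """
    config.validate()
    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    manifest = _Manifest(outdir, config.seed)
    handler = logging.StreamHandler()
    logfile = os.path.join(outdir, "pipeline.log")
    fhandler = logging.FileHandler(logfile)
    logger.addHandler(handler)
    logger.addHandler(fhandler)
    logger.setLevel(logging.INFO)
    logger.info("effective config:\n%s", config.to_yaml())

    stage = "simulate"
    try:
        t0 = time.time()
        cohort = synthgen.simulate_cohort(config.sim)
        paths = synthgen.write_cohort(cohort, os.path.join(outdir, "cohort"))
        for p in paths.values():
            manifest.add(stage, p)
        logger.info("stage %s done in %.1fs", stage, time.time() - t0)

        stage = "preprocess"
        t0 = time.time()
        ids = cohort.sample_ids
        flows = [cohort.flow_record(i) for i in range(len(ids))]
        volumes = [cohort.volume_record(i) for i in range(len(ids))]
        edfs = [features.spirogram_edfs(v, f) for v, f in zip(volumes, flows)]
        stats = preprocess.spirogram_cohort_stats(
            [e.fev1 for e in edfs], [e.fvc for e in edfs], [e.pef for e in edfs]
        )
        reports = [
            preprocess.qc_spirogram(f, v, e, stats)
            for f, v, e in zip(flows, volumes, edfs)
        ]
        qc_path = os.path.join(outdir, "qc_reports.tsv")
        pd.DataFrame(
            {
                "id": [r.individual_id for r in reports],
                "passed": [r.passed for r in reports],
                "reasons": [",".join(sorted(r.reasons)) for r in reports],
            }
        ).to_csv(qc_path, sep="\t", index=False)
        manifest.add(stage, qc_path)
        passed = [i for i, r in enumerate(reports) if r.passed]
        logger.info("stage %s: %d/%d pass QC (%.1fs)",
                    stage, len(passed), len(ids), time.time() - t0)

        stage = "edf"
        edf_table = features.spirogram_edf_table([edfs[i] for i in passed])
        edf_path = os.path.join(outdir, "edfs.tsv")
        edf_table.to_csv(edf_path, sep="\t")
        manifest.add(stage, edf_path)

        stage = "train"
        t0 = time.time()
        kept_ids = [ids[i] for i in passed]
        train_ids, valid_ids = preprocess.split_cohort(
            kept_ids, frac=config.train_frac, seed=config.seed
        )
        pos = {v: i for i, v in enumerate(ids)}
        curves = np.stack([cohort.spiro_volume, cohort.spiro_flow], axis=2)
        tr = [pos[i] for i in train_ids]
        model = representation.train_vae(curves[tr], config=config.vae)
        model_dir = os.path.join(outdir, "model")
        model.save(model_dir)
        for name in ("config.json", "history.csv"):
            manifest.add(stage, os.path.join(model_dir, name))
        logger.info("stage %s done in %.1fs", stage, time.time() - t0)

        stage = "encode"
        keep = [pos[i] for i in kept_ids]
        enc = representation.encode_table(model, curves[keep], kept_ids)
        enc_path = os.path.join(outdir, "encodings.tsv")
        enc.to_csv(enc_path, sep="\t")
        manifest.add(stage, enc_path)

        stage = "gwas"
        t0 = time.time()
        panel, qc_report = assoc.variant_qc(cohort.genotypes)
        tr_rows = [panel.sample_ids.index(i) for i in train_ids]
        sub = synthgen.GenotypePanel(
            dosages=panel.dosages[tr_rows],
            variants=panel.variants,
            sample_ids=train_ids,
        )
        cov = cohort.covariates.loc[train_ids]
        scans = []
        for col in enc.columns:
            scan = assoc.association_scan(
                sub, enc.loc[train_ids, col].to_numpy(), cov, coordinate=col
            )
            path = os.path.join(outdir, f"gwas_{col}.tsv")
            scan.to_csv(path, sep="\t", index=False)
            manifest.add(stage, path)
            scans.append(scan)
        logger.info("stage %s done in %.1fs", stage, time.time() - t0)

        stage = "loci"
        all_hits = []
        for scan in scans:
            hits = assoc.clump_hits(scan, sub, config.p_thresh, config.r2_thresh)
            all_hits.append(hits)
        hits_cat = (
            pd.concat(all_hits).sort_values("P").drop_duplicates("ID")
            if all_hits else pd.DataFrame()
        )
        hits_path = os.path.join(outdir, "hits.tsv")
        hits_cat.to_csv(hits_path, sep="\t", index=False)
        manifest.add(stage, hits_path)
        loci = assoc.define_loci(hits_cat, sub, config.r2_thresh, config.merge_dist)
        bed = os.path.join(outdir, "loci.bed")
        tsv = os.path.join(outdir, "loci.tsv")
        write_loci_bed(loci, bed, tsv)
        manifest.add(stage, bed)
        manifest.add(stage, tsv)

        stage = "echi2"
        echi2_all, df = assoc.expected_chi2(scans)
        echi2_path = os.path.join(outdir, "expected_chi2.json")
        with open(echi2_path, "w") as fh:
            json.dump({"mean_chi2": echi2_all, "df": df}, fh, indent=2)
        manifest.add(stage, echi2_path)

        stage = "prs"
        t0 = time.time()
        effects = prs.CoordinateEffects.from_scans(scans)
        eff_path = os.path.join(outdir, "effects.tsv")
        write_effects_tsv(effects, eff_path)
        manifest.add(stage, eff_path)
        scores = prs.coordinate_prs(panel, effects)
        weights = prs.fit_disease_weights(
            scores.loc[train_ids], cohort.labels.loc[train_ids]
        )
        combined = prs.disease_score(scores, weights)
        score_path = os.path.join(outdir, "scores.tsv")
        out_scores = scores.copy()
        out_scores["disease_score"] = combined
        out_scores.to_csv(score_path, sep="\t")
        manifest.add(stage, score_path)
        logger.info("stage %s done in %.1fs", stage, time.time() - t0)

        stage = "evaluate"
        y_val = cohort.labels.loc[valid_ids].to_numpy()
        s_val = combined.loc[valid_ids].to_numpy()
        report = prs.evaluate_scores(s_val, y_val)
        rng = np.random.default_rng(config.seed)
        permuted = rng.permutation(s_val)
        paired = prs.paired_bootstrap(
            s_val, permuted, y_val, reps=config.bootstrap_reps, seed=config.seed
        )
        report["significant_vs_permuted"] = paired["significant"]
        eval_path = os.path.join(outdir, "evaluation.json")
        with open(eval_path, "w") as fh:
            json.dump(report, fh, indent=2, default=float)
        manifest.add(stage, eval_path)
    except Exception as err:
        manifest.write()
        logger.removeHandler(handler)
        logger.removeHandler(fhandler)
        fhandler.close()
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    path = manifest.write()
    logger.removeHandler(handler)
    logger.removeHandler(fhandler)
    fhandler.close()
    return {"manifest": path, "entries": manifest.entries}
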