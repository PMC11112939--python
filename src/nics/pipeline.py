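"""End-to-end pipeline: simulate -> normalize/segment -> features -> grade.

Configuration is YAML with a versioned schema; every run writes a
resolved-config copy and a manifest with a content hash per artifact, so
a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from nics._util import sha256_file
from nics.cnv_calling import call_cnvs, gc_normalize, reference_normalize, segment_cbs
from nics.cnv_calling.calls import write_callsets, write_seg
from nics.feature_extraction import extract_features, write_features_csv
from nics.genome import make_genome
from nics.grading import (
    cohort_grade_summary,
    grade_embryos,
    save_model,
    train_classifier,
    write_grades_csv,
)
from nics.synthetic_data import (
    KaryotypeParams,
    simulate_karyotype,
    simulate_read_counts,
    truth_to_callset,
    write_bin_counts,
)
from nics.synthetic_data.karyotype import write_truths

logger = logging.getLogger("nics.pipeline")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and its input."""


@dataclass(frozen=True)
class PipelineConfig:
    schema_version: int = 1
    seed: int = 7
    n_embryos: int = 50
    depth: int = 2_000_000
    dispersion: float = 0.05
    genome_config: str | None = None
    karyotype: dict = field(default_factory=dict)
    cbs: dict = field(
        default_factory=lambda: {"alpha": 0.01, "n_perm": 1000, "min_bins": 3, "undo_sd": 1.0}
    )
    calling: dict = field(
        default_factory=lambda: {"call_margin": 0.3, "min_size_mb": 10.0}
    )
    features: dict = field(
        default_factory=lambda: {"full_threshold": 0.8, "redefine_threshold": 0.5}
    )
    grades: dict = field(default_factory=lambda: {"a_min": 0.94, "c_max": 0.70})
    classifier: dict = field(
        default_factory=lambda: {"n_trees": 300, "n_train": 1500, "fraction_noise_sd": 0.05}
    )
    reference_panel_size: int = 6

    def __post_init__(self) -> None:
        g = self.grades
        a_min, c_max = float(g.get("a_min", 0.94)), float(g.get("c_max", 0.70))
        if not (0 < c_max < a_min < 1):
            raise ValueError(
                f"grade thresholds must satisfy 0 < c_max < a_min < 1, got "
                f"c_max={c_max}, a_min={a_min}"
            )
        for key in ("full_threshold", "redefine_threshold"):
            v = float(self.features.get(key, 0.5))
            if not 0 < v < 1:
                raise ValueError(f"features.{key} must be in (0, 1)")
        if self.n_embryos <= 0:
            raise ValueError("n_embryos must be positive")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")

    def to_dict(self) -> dict:
        return {
            "schema_version": self.schema_version,
            "seed": self.seed,
            "n_embryos": self.n_embryos,
            "depth": self.depth,
            "dispersion": self.dispersion,
            "genome_config": self.genome_config,
            "karyotype": dict(self.karyotype),
            "cbs": dict(self.cbs),
            "calling": dict(self.calling),
            "features": dict(self.features),
            "grades": dict(self.grades),
            "classifier": dict(self.classifier),
            "reference_panel_size": self.reference_panel_size,
        }


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    cfg = {}
    if path is not None:
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
    cfg.update(overrides)
    return PipelineConfig(**cfg)


def _stage(name: str, detail: str = ""):
    logger.info(json.dumps({"stage": name, "detail": detail}))


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute the full pipeline; returns the run manifest."""
    outdir = Path(outdir)
    (outdir / "counts").mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    rng_train, rng_panel, rng_embryos, rng_seg = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    params = KaryotypeParams(**config.karyotype)
    cls_cfg = config.classifier

    try:
        _stage("genome", config.genome_config or "bundled default")
        genome = make_genome(config.genome_config)
    except Exception as exc:
        raise PipelineError(f"stage genome failed ({config.genome_config})") from exc

    try:
        _stage("train", f"n_train={cls_cfg.get('n_train', 1500)}")
        train_feats, train_labels = [], []
        for i in range(int(cls_cfg.get("n_train", 1500))):
            truth = simulate_karyotype(rng_train, params, genome, f"train_{i:05d}")
            cs = truth_to_callset(
                truth,
                genome,
                fraction_noise_sd=float(cls_cfg.get("fraction_noise_sd", 0.05)),
                rng=rng_train,
                call_margin=float(config.calling.get("call_margin", 0.3)),
                min_size_mb=float(config.calling.get("min_size_mb", 10.0)),
            )
            train_feats.append(extract_features(cs, **_feat_kwargs(config)))
            train_labels.append(truth.label_euploid)
        model = train_classifier(
            train_feats,
            train_labels,
            n_trees=int(cls_cfg.get("n_trees", 300)),
            seed=config.seed,
        )
    except Exception as exc:
        raise PipelineError("stage train failed (synthetic training cohort)") from exc

    try:
        _stage("reference_panel", f"n={config.reference_panel_size}")
        panel = []
        euploid_params = KaryotypeParams(p_euploid=1.0, p_xx=params.p_xx)
        for i in range(config.reference_panel_size):
            truth = simulate_karyotype(rng_panel, euploid_params, genome, f"ref_{i:03d}")
            counts = simulate_read_counts(
                truth, genome, depth=config.depth, dispersion=config.dispersion, rng=rng_panel
            )
            panel.append(gc_normalize(counts, genome))
    except Exception as exc:
        raise PipelineError("stage reference_panel failed") from exc

    truths, callsets, features, all_segments = [], [], [], []
    for i in range(config.n_embryos):
        embryo_id = f"embryo_{i:04d}"
        counts_path = outdir / "counts" / f"{embryo_id}.tsv"
        try:
            truth = simulate_karyotype(rng_embryos, params, genome, embryo_id)
            counts = simulate_read_counts(
                truth, genome, depth=config.depth, dispersion=config.dispersion, rng=rng_embryos
            )
            write_bin_counts(counts, genome, counts_path)
            profile = gc_normalize(counts, genome)
            if panel:
                profile = reference_normalize(profile, panel, genome)
            segments = segment_cbs(
                profile,
                genome,
                alpha=float(config.cbs.get("alpha", 0.01)),
                n_perm=int(config.cbs.get("n_perm", 1000)),
                min_bins=int(config.cbs.get("min_bins", 3)),
                undo_sd=float(config.cbs.get("undo_sd", 1.0)),
                rng=rng_seg,
            )
            callset = call_cnvs(
                segments,
                genome,
                call_margin=float(config.calling.get("call_margin", 0.3)),
                min_size_mb=float(config.calling.get("min_size_mb", 10.0)),
                sample_id=embryo_id,
            )
            truths.append(truth)
            callsets.append(callset)
            features.append(extract_features(callset, **_feat_kwargs(config)))
            all_segments.append((embryo_id, segments))
        except Exception as exc:
            raise PipelineError(
                f"stage call_embryo failed for {embryo_id} ({counts_path})"
            ) from exc

    try:
        _stage("grade", f"n={len(features)}")
        results = grade_embryos(model, features)
        summary = cohort_grade_summary(results)
    except Exception as exc:
        raise PipelineError("stage grade failed") from exc

    _stage("write", str(outdir))
    write_truths(truths, outdir / "truths.json")
    with open(outdir / "segments.seg", "w") as fh:
        first = True
        for embryo_id, segments in all_segments:
            tmp = outdir / "segments._part.tsv"
            write_seg(segments, genome, embryo_id, tmp)
            lines = tmp.read_text().splitlines(keepends=True)
            fh.writelines(lines if first else lines[1:])
            first = False
            tmp.unlink()
    write_callsets(callsets, outdir / "callsets.json")
    write_features_csv(features, outdir / "features.csv")
    write_grades_csv(results, outdir / "grades.csv")
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    save_model(model, outdir / "model.joblib")
    with open(outdir / "resolved_config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)

    artifacts = sorted(
        str(p.relative_to(outdir))
        for p in outdir.rglob("*")
        if p.is_file() and p.name != "manifest.json" and p.suffix != ".joblib"
    )
    manifest = {
        "schema_version": config.schema_version,
        "seed": config.seed,
        "n_embryos": config.n_embryos,
        "grade_summary": summary,
        "artifacts": {a: sha256_file(outdir / a) for a in artifacts},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def _feat_kwargs(config: PipelineConfig) -> dict:
    return {
        "full_threshold": float(config.features.get("full_threshold", 0.8)),
        "redefine_threshold": float(config.features.get("redefine_threshold", 0.5)),
    }
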