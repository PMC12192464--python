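"""End-to-end pipeline runner: session -> windowed FC -> FCD -> reports.

One :class:`PipelineConfig` drives every stage with the study defaults
(5 s windows, 50% overlap, K = 5 folds, alpha = 0.001, median thresholds
0.5 / 0.8).  A single global seed fans out to per-stage seeds by fixed
offsets, and the resolved config plus its hash are serialized next to the
outputs so any artifact can be traced to the exact settings that produced
it.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dynamics import fcd, fcd_task_contrast, sliding_fc
from .fusion import FusionConfig, default_config
from .io import (config_hash, read_annotations, read_recording,
                 write_windowed_fc)
from .netprofiles import RegionAtlasMap, build_profiles, region_windowed_fc
from .recording import Recording
from .taskcompare import (classify_links, contrasts_to_frame,
                          highlight_regions, links_to_frame)
from .taskstates import classify_tasks, cluster_windows, clustering_metrics

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)

# per-stage seed offsets fanned out from the global seed
STAGE_SEEDS = {"cluster": 11, "classify": 23, "tsne": 37}


@dataclass
class PipelineConfig:
    """Resolved settings for one pipeline run (defaults = study conditions)."""

    window_s: float = 5.0
    overlap: float = 0.5
    band: tuple[float, float] = (1.0, 45.0)
    mvar_order: int | str = "auto"
    max_order: int = 5
    fusion_config_path: str | None = None
    cluster_k: int | None = None          # default: number of tasks
    cluster_algorithms: tuple[str, ...] = ("spectral", "birch")
    classifier: str = "rfc"
    folds: int = 5
    strong_thresh: float = 0.5
    dist_thresh: float = 0.2
    med_lo: float = 0.5
    med_hi: float = 0.8
    alpha: float = 0.001
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _load_fusion(config: PipelineConfig) -> FusionConfig:
    if config.fusion_config_path:
        return FusionConfig.from_json(config.fusion_config_path)
    return default_config()


def run_pipeline(config: PipelineConfig, out_dir: str | Path,
                 recording: Recording | None = None,
                 annotations: list[tuple[float, float, str]] | None = None,
                 recording_path: str | Path | None = None,
                 annotations_path: str | Path | None = None,
                 atlas: RegionAtlasMap | None = None) -> dict[str, Path]:
    """Run all stages in order and write the artifacts to ``out_dir``.

    Stages: windowed FC -> FCD -> clustering report -> classification
    report -> profiles (if an atlas is given) -> between-task comparisons
    (if an atlas is given and >= 2 tasks).  Any stage failure halts with
    the stage name; earlier artifacts are retained.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if recording is None:
        if recording_path is None:
            raise ValueError("either recording or recording_path is required")
        recording = read_recording(recording_path, apply_bipolar=True)
    if annotations is None:
        if annotations_path is None:
            raise ValueError("annotations (or their path) are required")
        annotations = read_annotations(annotations_path)

    cfg_dict = config.to_dict()
    chash = config_hash(cfg_dict)
    manifest: dict = {"fcdyn_version": __version__, "config": cfg_dict,
                      "config_hash": chash, "stages": {}}
    artifacts: dict[str, Path] = {}

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                fn()
            except Exception as exc:
                manifest["stages"][name] = {"status": "failed", "error": str(exc)}
                (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
                raise RuntimeError(f"stage '{name}' failed: {exc}") from exc
            manifest["stages"][name] = {
                "status": "ok", "seconds": round(time.perf_counter() - t0, 3)}
        return deco

    state: dict = {}

    @stage("windowed_fc")
    def _wfc():
        wfc = sliding_fc(recording, annotations,
                         window_s=config.window_s, overlap=config.overlap,
                         fusion_config=_load_fusion(config),
                         order=config.mvar_order, max_order=config.max_order,
                         band=config.band)
        state["wfc"] = wfc
        p = out_dir / f"windowed_fc_{chash}.npz"
        write_windowed_fc(wfc, p)
        artifacts["windowed_fc"] = p

    @stage("fcd")
    def _fcd():
        m = fcd(state["wfc"])
        state["fcd"] = m
        within, between = fcd_task_contrast(m)
        p = out_dir / f"fcd_{chash}.csv"
        pd.DataFrame(m.values).to_csv(p, index=False)
        (out_dir / f"fcd_contrast_{chash}.json").write_text(json.dumps(
            {"within_task_mean": within, "between_task_mean": between,
             "config_hash": chash}, indent=2))
        artifacts["fcd"] = p

    @stage("clustering")
    def _cluster():
        wfc = state["wfc"]
        true_labels = np.array(wfc.non_mixed().task_labels)
        k = config.cluster_k or len(set(true_labels))
        report = {"config_hash": chash, "k": k}
        for algo in config.cluster_algorithms:
            pred = cluster_windows(wfc, k, algo, seed=config.seed + STAGE_SEEDS["cluster"])
            report[algo] = clustering_metrics(pred, true_labels).to_dict()
        p = out_dir / f"clustering_{chash}.json"
        p.write_text(json.dumps(report, indent=2))
        artifacts["clustering"] = p

    @stage("classification")
    def _classify():
        rep = classify_tasks(state["wfc"], model=config.classifier,
                             K=config.folds,
                             seed=config.seed + STAGE_SEEDS["classify"])
        d = rep.to_dict()
        d["config_hash"] = chash
        p = out_dir / f"classification_{chash}.json"
        p.write_text(json.dumps(d, indent=2))
        artifacts["classification"] = p

    if atlas is not None:
        @stage("profiles")
        def _profiles():
            rwfc = region_windowed_fc(state["wfc"], atlas)
            state["rwfc"] = rwfc
            df = build_profiles(rwfc, atlas)
            p = out_dir / f"profiles_{chash}.csv"
            df.to_csv(p, index=False)
            artifacts["profiles"] = p

        @stage("comparisons")
        def _compare():
            rwfc = state["rwfc"]
            tasks = [t for t in dict.fromkeys(rwfc.task_labels) if t != "mixed"]
            if len(tasks) < 2:
                logger.info("fewer than 2 tasks; comparison stage skipped")
                return
            ta, tb = tasks[:2]
            def task_subset(t):
                keep = [i for i, lab in enumerate(rwfc.task_labels) if lab == t]
                from .dynamics import WindowedFC
                return WindowedFC([rwfc.windows[i] for i in keep],
                                  rwfc.matrices[keep],
                                  [rwfc.task_labels[i] for i in keep],
                                  rwfc.channel_labels)
            wa, wb = task_subset(ta), task_subset(tb)
            links = classify_links(wa, wb, config.strong_thresh,
                                   config.dist_thresh)
            links_to_frame(links).to_csv(out_dir / f"links_{chash}.csv",
                                         index=False)
            frames = [contrasts_to_frame(
                highlight_regions(wa, wb, metric=m, alpha=config.alpha,
                                  med_lo=config.med_lo, med_hi=config.med_hi))
                for m in ("in_degree", "out_degree")]
            p = out_dir / f"degree_contrasts_{chash}.csv"
            pd.concat(frames).to_csv(p, index=False)
            artifacts["links"] = out_dir / f"links_{chash}.csv"
            artifacts["degree_contrasts"] = p

    (out_dir / "config_resolved.json").write_text(
        json.dumps(cfg_dict, indent=2, default=str))
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    artifacts["manifest"] = out_dir / "manifest.json"
    return artifacts
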