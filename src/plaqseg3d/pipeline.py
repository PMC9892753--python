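"""End-to-end orchestration: synth -> preprocess -> train -> detect -> PRM ->
segment -> montage -> eval -> quantify, with a JSON manifest recording the
config, seed, package version and output checksums for reproducibility.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__, detect3d, evalmetrics, prm, quantify, segment2dotsu
from .detect3d import AnchorSet, DetectorModel, TrainConfig
from .estimators import PlaqueDetector
from .hrnet3d import HRNetConfig
from .preprocess import (calibrate_brightness, compute_tissue_mask, enhance_snr,
                         extract_block, partition_blocks)
from .synthgen import SceneConfig, generate_scene, generate_toy_atlas
from .volio import (SegmentationMask, VolumeStack, read_boxes, read_volume,
                    write_boxes, write_labels, write_mask, write_volume)

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Everything one end-to-end run needs; serialisable to JSON."""

    out_dir: str = "run"
    seed: int = 0
    # synthetic scene (train scene and a held-out test scene are derived)
    scene_shape: tuple[int, int, int] = (64, 128, 128)
    n_plaques: int = 40
    noise_sd: float = 0.01
    depth_decay_strength: float = 0.3
    # preprocessing
    sigma: float = 2.0
    block_shape: tuple[int, int, int] = (64, 64, 64)
    min_tissue_frac: float = 0.01
    # detector
    n_branches: int = 3
    base_channels: int = 8
    n_stages: int = 2
    max_iterations: int = 300
    lr: float = 0.01
    weight_decay: float = 0.0001
    score_thresh: float = 0.5
    nms_iou: float = 0.3
    # segmentation / quantification
    bins: int = 64
    roi_dilate: int = 4
    n_regions: int = 6
    input_volume: str | None = None   # skip the synth stage when given
    input_boxes: str | None = None
    checkpoint: str | None = None     # resume: skip training when present
    log_level: str = "info"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kw = {f.name: d[f.name] for f in dataclasses.fields(cls) if f.name in d}
        for key in ("scene_shape", "block_shape"):
            if key in kw:
                kw[key] = tuple(kw[key])
        return cls(**kw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _log(run_dir: Path, record: dict) -> None:
    with (run_dir / "log.jsonl").open("a") as f:
        f.write(json.dumps(record) + "\n")


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the run directory.

    Stage outputs land under the run directory; any stage failure raises
    :class:`PipelineError` naming the stage, leaving earlier outputs on disk.
    """
    if config.input_volume is not None and not Path(config.input_volume).exists():
        raise PipelineError(f"stage inputs: missing input volume {config.input_volume}")
    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "seed": config.seed,
                      "version": __version__, "stages": {}, "checksums": {}}

    def checkpoint_stage(name: str, outputs: dict[str, Path], t0: float) -> None:
        entry = manifest["stages"].setdefault(name, {})
        entry["wall_time_s"] = round(time.time() - t0, 3)
        for k, p in outputs.items():
            manifest["checksums"][k] = _sha256(Path(p))
        _log(run_dir, {"stage": name, "wall_time_s": time.time() - t0})

    stage = "synth"
    try:
        t0 = time.time()
        if config.input_volume is None:
            b = (lambda z: 1.0 - config.depth_decay_strength
                 * z / max(config.scene_shape[0] - 1, 1))
            scene = generate_scene(SceneConfig(
                shape=config.scene_shape, n_plaques=config.n_plaques,
                noise_sd=config.noise_sd,
                depth_decay=lambda z: b(z), seed=config.seed,
            ))
            vol, gt_mask, boxes = scene
            vol_path = write_volume(vol, run_dir / "scene.nii")
            write_mask(gt_mask, run_dir / "gt_mask.nii")
            write_boxes(boxes, run_dir / "boxes.json")
        else:
            vol = read_volume(config.input_volume).normalized()
            vol_path = Path(config.input_volume)
            boxes = read_boxes(config.input_boxes) if config.input_boxes else []
            gt_mask = None
        checkpoint_stage("synth", {"scene": vol_path}, t0)

        stage = "preprocess"
        t0 = time.time()
        tissue = compute_tissue_mask(vol)
        calibrated, profile = calibrate_brightness(vol, tissue)
        smoothed = enhance_snr(calibrated, sigma=config.sigma)
        grid = partition_blocks(smoothed, tissue, config.block_shape,
                                config.min_tissue_frac)
        write_mask(tissue, run_dir / "tissue.nii")
        np.savetxt(run_dir / "gains.csv",
                   np.column_stack([np.arange(len(profile.gain)), profile.gain]),
                   delimiter=",", header="z,gain", comments="")
        (run_dir / "blocks.json").write_text(json.dumps({
            "block_shape": list(grid.block_shape),
            "origins": grid.origins.tolist(),
            "kept": grid.kept.tolist(),
            "tissue_fraction": grid.tissue_fraction.tolist(),
        }, indent=2))
        checkpoint_stage("preprocess", {"blocks": run_dir / "blocks.json"}, t0)

        stage = "train"
        t0 = time.time()
        kept = grid.kept_indices()
        block_vols = [extract_block(smoothed.data, grid, int(i)) for i in kept]
        block_boxes = []
        for i in kept:
            o = grid.origins[int(i)]
            bb = []
            for box in boxes:
                c = [(a + b2) / 2 for a, b2 in zip(box.zyx_min, box.zyx_max)]
                if all(oo <= cc < oo + s for oo, cc, s in
                       zip(o, c, grid.block_shape)):
                    lo = [max(0, a - int(oo)) for a, oo in zip(box.zyx_min, o)]
                    hi = [min(s, b2 - int(oo)) for b2, oo, s in
                          zip(box.zyx_max, o, grid.block_shape)]
                    if all(h > l for l, h in zip(lo, hi)):
                        from .volio import BoundingBox3D
                        bb.append(BoundingBox3D(tuple(lo), tuple(hi)))
            block_boxes.append(bb)
        ckpt_path = run_dir / "checkpoint.npz"
        if config.checkpoint is not None and Path(config.checkpoint).exists():
            model = detect3d.load_checkpoint(config.checkpoint)
            manifest["stages"]["train"] = {"skipped": True,
                                           "resumed_from": str(config.checkpoint)}
            detect3d.save_checkpoint(model, ckpt_path)
        else:
            det = PlaqueDetector(
                n_branches=config.n_branches, base_channels=config.base_channels,
                n_stages=config.n_stages, lr=config.lr,
                weight_decay=config.weight_decay,
                max_iterations=config.max_iterations,
                score_thresh=config.score_thresh, nms_iou=config.nms_iou,
                random_state=config.seed,
            ).fit(block_vols, block_boxes)
            model = det.model_
            detect3d.save_checkpoint(model, ckpt_path)
        checkpoint_stage("train", {"checkpoint": ckpt_path}, t0)

        stage = "detect+segment"
        t0 = time.time()
        block_masks: dict[int, SegmentationMask] = {}
        all_dets = []
        for i in kept:
            data = extract_block(smoothed.data, grid, int(i))
            dets, rpn = detect3d.detect(model, data, config.score_thresh,
                                        config.nms_iou)
            o = grid.origins[int(i)]
            all_dets.extend([
                type(d)(tuple(int(a) + int(oo) for a, oo in zip(d.zyx_min, o)),
                        tuple(int(b2) + int(oo) for b2, oo in zip(d.zyx_max, o)),
                        d.score)
                for d in dets
            ])
            if not dets:
                block_masks[int(i)] = SegmentationMask(np.zeros(data.shape, bool))
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                agg, _ = prm.prm_for_block(model, data, rpn,
                                           score_thresh=config.score_thresh)
                roi = segment2dotsu.detection_roi(data.shape, dets,
                                                  dilate=config.roi_dilate)
                block_masks[int(i)] = segment2dotsu.segment_block(
                    data, agg, roi, bins=(config.bins, config.bins))
        for i in range(grid.n_blocks):
            if i not in block_masks:
                block_masks[i] = SegmentationMask(
                    np.zeros(tuple(grid.block_shape), bool))
        whole = segment2dotsu.montage(grid, block_masks, vol.spacing)
        write_mask(whole, run_dir / "segmentation.nii")
        write_boxes(all_dets, run_dir / "detections.json")
        checkpoint_stage("detect+segment",
                         {"segmentation": run_dir / "segmentation.nii"}, t0)

        stage = "eval"
        t0 = time.time()
        summary: dict = {}
        if gt_mask is not None:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                summary["metrics"] = evalmetrics.evaluate(whole, gt_mask,
                                                          vol.spacing)
        (run_dir / "metrics.json").write_text(json.dumps(summary, indent=2))
        checkpoint_stage("eval", {"metrics": run_dir / "metrics.json"}, t0)

        stage = "quantify"
        t0 = time.time()
        atlas = generate_toy_atlas(whole.shape, config.n_regions,
                                   seed=config.seed)
        plaques = quantify.label_components(whole)
        stats = quantify.region_stats(plaques, atlas,
                                      voxel_volume_um3=float(np.prod(vol.spacing)))
        stats.to_csv(run_dir / "region_stats.csv")
        quantify.plaque_table(plaques).to_csv(run_dir / "plaques.csv", index=False)
        write_labels(atlas, run_dir / "atlas.nii")
        checkpoint_stage("quantify", {"region_stats": run_dir / "region_stats.csv"}, t0)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - surfaced with stage context
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return run_dir
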