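"""File I/O and pipeline orchestration.

Conventions (used in every output): pixel coordinates, origin at the top-left
corner, (row, col) order, 0-based; label 0 is background in all mask files.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import fixtures, genealogy, metrics, tracking
from .config import PipelineConfig

logger = logging.getLogger(__name__)

TRACK_COLUMNS = [
    "frame", "trajectory_id", "parent_id", "centroid_row", "centroid_col",
    "area_px", "length_um", "width_um", "divided_flag",
]


@dataclass
class FrameStack:
    frames: np.ndarray          # (T, H, W)
    calibration: float          # um / px
    frame_interval: float       # seconds
    source: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or len(self.frames) < 1:
            raise IOError("a stack needs at least one 2-D frame")
        if self.calibration <= 0:
            raise ValueError("calibration must be positive")

    @property
    def n_frames(self) -> int:
        return len(self.frames)


def _numeric_key(path: Path):
    nums = re.findall(r"\d+", path.stem)
    return (int(nums[-1]) if nums else 0, path.name)


def load_stack(
    path: str | Path, calibration: float = 0.15, frame_interval: float = 69.0
) -> FrameStack:
    """Load a multi-page TIFF or a directory of numbered PNG/TIFF frames."""
    path = Path(path)
    if path.is_dir():
        files = sorted(
            [p for p in path.iterdir() if p.suffix.lower() in {".tif", ".tiff", ".png"}],
            key=_numeric_key,
        )
        if not files:
            raise IOError(f"no image frames found in {path}")
        frames = []
        shape = None
        for f in files:
            if f.suffix.lower() == ".png":
                import imageio.v3 as iio

                img = np.asarray(iio.imread(f))
            else:
                img = tifffile.imread(f)
            if img.ndim == 3:  # drop a color axis if present
                img = img.mean(axis=-1)
            if shape is None:
                shape = img.shape
            elif img.shape != shape:
                raise IOError(
                    f"frame {f.name} has shape {img.shape}, expected {shape}"
                )
            frames.append(np.asarray(img, dtype=float))
        stack = np.stack(frames)
    else:
        try:
            stack = tifffile.imread(path)
        except Exception as exc:  # noqa: BLE001
            raise IOError(f"could not read stack {path}: {exc}") from exc
        if stack.ndim == 2:
            stack = stack[None]
        if stack.ndim != 3:
            raise IOError(f"{path}: expected a (T, H, W) stack, got {stack.shape}")
    return FrameStack(
        frames=stack.astype(float),
        calibration=calibration,
        frame_interval=frame_interval,
        source=str(path),
    )


def write_label_stack(path: str | Path, per_frame_regions, shape) -> np.ndarray:
    """16-bit multi-page TIFF; pixel value = trajectory id, 0 = background."""
    masks = np.zeros((len(per_frame_regions), *shape), dtype=np.uint16)
    for t, regions in enumerate(per_frame_regions):
        for region in regions:
            masks[t][region.mask] = region.label
    tifffile.imwrite(path, masks, photometric="minisblack")
    return masks


def track_table(state: tracking.TrackingState) -> pd.DataFrame:
    rows = []
    for tr in state.trajectories:
        for t in sorted(tr.regions):
            region = tr.regions[t]
            rows.append(
                {
                    "frame": t,
                    "trajectory_id": tr.id,
                    "parent_id": -1 if tr.parent is None else tr.parent,
                    "centroid_row": region.centroid[0],
                    "centroid_col": region.centroid[1],
                    "area_px": region.area,
                    "length_um": region.length_um,
                    "width_um": region.width_um,
                    "divided_flag": int(region.divided),
                }
            )
    return pd.DataFrame(rows, columns=TRACK_COLUMNS).sort_values(
        ["frame", "trajectory_id"], ignore_index=True
    )


def lineage_json(state: tracking.TrackingState) -> list[dict]:
    tree = genealogy.build_tree(state)
    return [
        {
            "id": n.id,
            "parent": n.parent,
            "children": list(n.children) if n.children else None,
            "b": n.b,
            "d": n.d,
            "generation": n.generation,
        }
        for n in sorted(tree.nodes.values(), key=lambda n: n.id)
    ]


def run_pipeline(stack: FrameStack, config: PipelineConfig, out_dir: str | Path) -> dict:
    """Segment + track a stack and write all artifacts to ``out_dir``.

    Outputs: labels.tif (16-bit label masks), tracks.csv, lineage.json,
    growth.csv, run_log.json (full effective configuration).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.calibration = stack.calibration if stack.calibration else config.calibration
    per_frame, state, lineage = tracking.track_stack(
        stack, config.seg, config.track, config.drlse, calibration=stack.calibration
    )

    masks = write_label_stack(out / "labels.tif", per_frame, stack.frames.shape[1:])
    table = track_table(state)
    table.to_csv(out / "tracks.csv", index=False)
    (out / "lineage.json").write_text(json.dumps(lineage_json(state), indent=2))

    records = genealogy.growth_curves(state, frame_interval=stack.frame_interval)
    pd.DataFrame([vars(r) for r in records]).to_csv(out / "growth.csv", index=False)

    log = {
        "source": stack.source,
        "n_frames": stack.n_frames,
        "config": config.to_dict(),
        "n_trajectories": len(state.trajectories),
        "n_divisions": len(lineage),
        "coordinates": "pixel units, origin top-left, (row, col), 0-based",
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2))
    return {
        "labels": str(out / "labels.tif"),
        "tracks": str(out / "tracks.csv"),
        "lineage": str(out / "lineage.json"),
        "growth": str(out / "growth.csv"),
        "log": str(out / "run_log.json"),
        "state": state,
        "masks": masks,
        "per_frame": per_frame,
    }


def evaluate_against_scene(
    scene: "fixtures.SyntheticScene",
    per_frame,
    state: tracking.TrackingState,
    iou_min: float = 0.5,
    dist_max: float = 5.0,
) -> dict:
    """Score a tracking run against the synthetic ground truth it came from.

    Applies the division-leniency rule: a ground-truth mother in her final
    frame may be covered by one or two predictions and still count as TP.
    """
    n = scene.n_frames
    dices, seg_evals = [], []
    for t in range(n):
        gt = scene.label_mask(t)
        pred = np.zeros_like(gt)
        for region in per_frame[t]:
            pred[region.mask] = region.label
        dices.append(metrics.dice(pred > 0, gt > 0))
        seg_evals.append(
            metrics.classify_segmentation(
                pred, gt, iou_min, dividing_gt=scene.dividing_labels(t)
            )
        )
    seg = metrics.combine_seg_evals(seg_evals)
    pred_pos = {tr.id: dict(tr.positions) for tr in state.trajectories}
    track_eval = metrics.evaluate_tracking(
        pred_pos, scene.positions_px(), n, dist_max=dist_max
    )
    return {
        "dice_mean": float(np.mean(dices)),
        "seg_accuracy_percent": seg.accuracy,
        "seg_counts": {
            "TP": seg.TP, "over_seg": seg.over_seg,
            "under_seg": seg.under_seg, "FN": seg.FN, "total_gt": seg.total_gt,
        },
        "motp_px": track_eval.motp,
        "mota_percent": track_eval.mota,
        "fn_ratio_percent": track_eval.fn_ratio,
        "fp_ratio_percent": track_eval.fp_ratio,
        "mm_ratio_percent": track_eval.mm_ratio,
    }


def run_simulate(
    out_dir: str | Path,
    n_frames: int = 20,
    seed: int = 0,
    noise_sd: float = 0.45,
    **sim_kwargs,
) -> dict:
    """Generate a synthetic benchmark dataset on disk."""
    scene = fixtures.simulate_colony(n_frames, seed, **sim_kwargs)
    return fixtures.write_scene(scene, out_dir, noise_sd=noise_sd)


def run_evaluate(
    pred_labels_path: str | Path,
    gt_labels_path: str | Path,
    out_path: str | Path | None = None,
    iou_min: float = 0.5,
    dist_max: float = 5.0,
) -> dict:
    """Score predicted label masks against ground truth; JSON-able report."""
    pred = tifffile.imread(pred_labels_path)
    gt = tifffile.imread(gt_labels_path)
    if pred.ndim == 2:
        pred, gt = pred[None], gt[None]
    if pred.shape != gt.shape:
        raise IOError(f"pred shape {pred.shape} != gt shape {gt.shape}")

    seg_evals, dices = [], []
    for t in range(len(pred)):
        seg_evals.append(metrics.classify_segmentation(pred[t], gt[t], iou_min))
        dices.append(metrics.dice(pred[t] > 0, gt[t] > 0))
    seg = metrics.combine_seg_evals(seg_evals)

    def positions(stack: np.ndarray) -> dict[int, dict[int, np.ndarray]]:
        out: dict[int, dict[int, np.ndarray]] = {}
        for t in range(len(stack)):
            for lab in np.unique(stack[t]):
                if lab == 0:
                    continue
                rows, cols = np.nonzero(stack[t] == lab)
                out.setdefault(int(lab), {})[t] = np.array(
                    [rows.mean(), cols.mean()]
                )
        return out

    track_eval = metrics.evaluate_tracking(
        positions(pred), positions(gt), len(pred), dist_max=dist_max
    )
    report = {
        "dice_mean": float(np.mean(dices)),
        "dice_per_frame": [float(d) for d in dices],
        "segmentation": {
            "TP": seg.TP,
            "over_seg": seg.over_seg,
            "under_seg": seg.under_seg,
            "FN": seg.FN,
            "total_gt": seg.total_gt,
            "accuracy_percent": seg.accuracy,
        },
        "tracking": {
            "MOTP_px": track_eval.motp,
            "FN_ratio_percent": track_eval.fn_ratio,
            "FP_ratio_percent": track_eval.fp_ratio,
            "MM_ratio_percent": track_eval.mm_ratio,
            "MOTA_percent": track_eval.mota,
        },
        "thresholds": {"iou_min": iou_min, "dist_max_px": dist_max,
                       "link_rule": "overlap >= iou_min of either object"},
    }
    if out_path is not None:
        Path(out_path).write_text(json.dumps(report, indent=2))
    return report
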