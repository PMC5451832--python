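"""Evaluation: Dice overlap, segmentation outcome categories, MOTP and MOTA.

MOTA follows the higher-is-better percentage convention,
``100 * (1 - (sum FN + FP + MM) / sum g_t)``, matching how the aggregate is
reported alongside its three error ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class SegEval:
    TP: int = 0
    over_seg: int = 0
    under_seg: int = 0
    FN: int = 0
    total_gt: int = 0
    accuracy: float = 0.0  # 100 * TP / total_gt


@dataclass
class TrackEval:
    motp: float | None
    fn_ratio: float
    fp_ratio: float
    mm_ratio: float
    mota: float
    totals: dict = field(default_factory=dict)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A| + |B|); two empty masks score 1."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    sa, sb = int(a.sum()), int(b.sum())
    if sa + sb == 0:
        return 1.0
    return 2.0 * int(np.sum(a & b)) / (sa + sb)


def _object_links(pred: np.ndarray, gt: np.ndarray, iou_min: float):
    """Overlap links between gt and pred objects.

    A link is formed when the intersection covers at least ``iou_min`` of
    either object, so that k predictions tiling one cell (over-segmentation)
    and one prediction covering k cells (under-segmentation) both stay
    linked; a clean one-to-one match at the default threshold implies
    IoU >= 0.5.
    """
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValueError("shape mismatch between pred and gt masks")
    gt_ids = [int(i) for i in np.unique(gt) if i != 0]
    pred_ids = [int(i) for i in np.unique(pred) if i != 0]
    gt_sizes = {g: int(np.sum(gt == g)) for g in gt_ids}
    pred_sizes = {p: int(np.sum(pred == p)) for p in pred_ids}
    links: dict[int, set[int]] = {g: set() for g in gt_ids}
    rlinks: dict[int, set[int]] = {p: set() for p in pred_ids}
    # joint histogram of (gt, pred) label pairs
    both = (gt.astype(np.int64) << 32) | pred.astype(np.int64)
    vals, counts = np.unique(both[(gt != 0) & (pred != 0)], return_counts=True)
    for v, n in zip(vals, counts):
        g, p = int(v >> 32), int(v & 0xFFFFFFFF)
        if n / pred_sizes[p] >= iou_min or n / gt_sizes[g] >= iou_min:
            links[g].add(p)
            rlinks[p].add(g)
    return gt_ids, pred_ids, links, rlinks


def classify_segmentation(
    pred: np.ndarray,
    gt: np.ndarray,
    iou_min: float = 0.5,
    dividing_gt: set[int] | None = None,
) -> SegEval:
    """Classify every ground-truth cell as TP, over-, under-segmented or FN.

    ``dividing_gt`` lists gt labels undergoing division in this frame; such a
    cell matched by either one or two predictions counts as TP (division
    leniency).
    """
    dividing_gt = dividing_gt or set()
    gt_ids, _, links, rlinks = _object_links(pred, gt, iou_min)
    ev = SegEval(total_gt=len(gt_ids))
    for g in gt_ids:
        preds = links[g]
        if not preds:
            ev.FN += 1
        elif any(len(rlinks[p]) > 1 for p in preds):
            ev.under_seg += 1
        elif len(preds) == 1:
            ev.TP += 1
        elif len(preds) == 2 and g in dividing_gt:
            ev.TP += 1
        else:
            ev.over_seg += 1
    ev.accuracy = 100.0 * ev.TP / ev.total_gt if ev.total_gt else 0.0
    return ev


def combine_seg_evals(evals: list[SegEval]) -> SegEval:
    out = SegEval()
    for e in evals:
        out.TP += e.TP
        out.over_seg += e.over_seg
        out.under_seg += e.under_seg
        out.FN += e.FN
        out.total_gt += e.total_gt
    out.accuracy = 100.0 * out.TP / out.total_gt if out.total_gt else 0.0
    return out


def motp(matches: list[list[tuple[object, object, float]]]) -> float | None:
    """Mean matched distance: sum of distances over sum of per-frame matches.

    ``matches`` is a per-frame list of (object, hypothesis, distance) tuples.
    Returns None when there are no matches at all.
    """
    total_dist = 0.0
    total_matched = 0
    for frame_matches in matches:
        for _, _, d in frame_matches:
            total_dist += float(d)
            total_matched += 1
    if total_matched == 0:
        return None
    return total_dist / total_matched


def mota(
    fn_t: list[int], fp_t: list[int], mm_t: list[int], g_t: list[int]
) -> tuple[float, float, float, float]:
    """Error ratios and the aggregate accuracy percentage.

    Returns (fn_ratio, fp_ratio, mm_ratio, mota_percent) with ratios in
    percent of total ground-truth objects and
    mota = 100 * (1 - sum(FN + FP + MM) / sum g).
    """
    total_g = float(sum(g_t))
    if total_g <= 0:
        raise ValueError("sum of g_t must be positive")
    fn_ratio = 100.0 * sum(fn_t) / total_g
    fp_ratio = 100.0 * sum(fp_t) / total_g
    mm_ratio = 100.0 * sum(mm_t) / total_g
    return fn_ratio, fp_ratio, mm_ratio, 100.0 - fn_ratio - fp_ratio - mm_ratio


def match_tracks(
    pred_positions: dict[int, dict[int, np.ndarray]],
    gt_positions: dict[int, dict[int, np.ndarray]],
    n_frames: int,
    dist_max: float = 5.0,
    gt_divisions: dict[int, tuple[int, int]] | None = None,
) -> dict:
    """Frame-by-frame correspondence between tracker output and ground truth.

    ``*_positions`` map track id -> {frame -> (row, col)}.  Matching is
    greedy nearest-centroid under ``dist_max``, keeping the previous frame's
    pairing when still valid (identity persistence).  A mismatch (MM) is
    counted whenever a gt track's matched hypothesis id changes between
    consecutive frames; divisions in ``gt_divisions`` (parent -> children)
    exempt the handover from parent to child identities.
    """
    matches_per_frame: list[list[tuple[int, int, float]]] = []
    fn_t, fp_t, mm_t, g_t = [], [], [], []
    prev_match: dict[int, int] = {}  # gt id -> hyp id
    for t in range(n_frames):
        gt_here = {g: pos[t] for g, pos in gt_positions.items() if t in pos}
        hyp_here = {h: pos[t] for h, pos in pred_positions.items() if t in pos}
        matched: dict[int, int] = {}
        used_hyps: set[int] = set()
        # keep existing pairings while they remain close enough
        for g, h in prev_match.items():
            if g in gt_here and h in hyp_here:
                d = float(np.linalg.norm(np.asarray(gt_here[g]) - np.asarray(hyp_here[h])))
                if d <= dist_max:
                    matched[g] = h
                    used_hyps.add(h)
        # greedy nearest-centroid for the rest
        pairs = []
        for g, gp in gt_here.items():
            if g in matched:
                continue
            for h, hp in hyp_here.items():
                if h in used_hyps:
                    continue
                d = float(np.linalg.norm(np.asarray(gp) - np.asarray(hp)))
                if d <= dist_max:
                    pairs.append((d, g, h))
        for d, g, h in sorted(pairs):
            if g in matched or h in used_hyps:
                continue
            matched[g] = h
            used_hyps.add(h)

        frame_matches = [
            (g, h, float(np.linalg.norm(np.asarray(gt_here[g]) - np.asarray(hyp_here[h]))))
            for g, h in matched.items()
        ]
        matches_per_frame.append(frame_matches)

        # a gt division opens fresh gt tracks, so parent->child handovers never
        # register as an id change within one gt track
        mm = sum(
            1
            for g, h in matched.items()
            if g in prev_match and prev_match[g] != h
        )
        mm_t.append(mm)
        fn_t.append(len(gt_here) - len(matched))
        fp_t.append(len(hyp_here) - len(used_hyps))
        g_t.append(len(gt_here))
        prev_match = matched

    return {
        "matches": matches_per_frame,
        "FN_t": fn_t,
        "FP_t": fp_t,
        "MM_t": mm_t,
        "g_t": g_t,
    }


def evaluate_tracking(
    pred_positions: dict[int, dict[int, np.ndarray]],
    gt_positions: dict[int, dict[int, np.ndarray]],
    n_frames: int,
    dist_max: float = 5.0,
    gt_divisions: dict[int, tuple[int, int]] | None = None,
) -> TrackEval:
    """match_tracks + MOTP + MOTA in one report."""
    corr = match_tracks(pred_positions, gt_positions, n_frames, dist_max, gt_divisions)
    fn_r, fp_r, mm_r, mota_pct = mota(
        corr["FN_t"], corr["FP_t"], corr["MM_t"], corr["g_t"]
    )
    return TrackEval(
        motp=motp(corr["matches"]),
        fn_ratio=fn_r,
        fp_ratio=fp_r,
        mm_ratio=mm_r,
        mota=mota_pct,
        totals={k: corr[k] for k in ("FN_t", "FP_t", "MM_t", "g_t")},
    )
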