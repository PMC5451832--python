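"""Frame-to-frame tracking: windowed level-set propagation, septum- and
width-based division detection, and global trajectory-energy assignment.

The tracker works in the fixed intensity convention of the renderer: cells
dark on a bright background.  All septum logic runs on the *inverted*
smoothed image (background-level minus intensity), where the septum of a
dividing cell is a local minimum of the major-axis profile; the division
threshold is r_m = mean + tau * sd of the boundary-band intensities of all
segmented cells in the current frame, and a cell is cut at the deepest local
minimum below r_m.

Identity assignment minimizes the trajectory energy

    E(X) = beta * E_vel + gamma * E_exc + eta * E_reg

over all consistent region-to-trajectory assignments of each ambiguous
component (exact enumeration up to a cap, then greedy fallback).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import drlse
from .config import ConfigurationError, DrlseParams, SegConfig, TrackConfig
from .segmentation import (
    CellRegion,
    capture_new_cells,
    initial_seeds,
    make_region,
    segment_first_frame,
)

logger = logging.getLogger(__name__)

Window = tuple[int, int, int, int]  # r0, c0, r1, c1 (half-open)


# ---------------------------------------------------------------------------
# region propagation via sub-windows


def split_into_windows(region: CellRegion, w: float, calibration: float) -> list[Window]:
    """Axis-aligned grid of side ``round(w / calibration)`` px over the
    region's bounding box; only windows intersecting the mask are returned."""
    side = int(round(w / calibration))
    if side < 1:
        raise ConfigurationError(
            f"window size {w} um is below one pixel at {calibration} um/px"
        )
    r0, c0, r1, c1 = region.bbox
    windows = []
    for rs in range(r0, r1, side):
        for cs in range(c0, c1, side):
            win = (rs, cs, min(rs + side, r1), min(cs + side, c1))
            if region.mask[win[0]:win[2], win[1]:win[3]].any():
                windows.append(win)
    return windows


def classify_windows(
    windows: list[Window], image: np.ndarray
) -> tuple[list[Window], list[Window]]:
    """Partition windows into (interior, boundary) by their peak gradient.

    A window is "boundary" when its maximum gradient magnitude of the image
    exceeds an Otsu split of the per-window peaks (data-driven; the split is
    skipped when the peaks are all alike, in which case everything is
    interior).
    """
    if not windows:
        return [], []
    gy, gx = np.gradient(np.asarray(image, dtype=float))
    gm = np.sqrt(gy**2 + gx**2)
    peaks = np.array(
        [gm[w[0]:w[2], w[1]:w[3]].max() for w in windows]
    )
    if peaks.max() - peaks.min() < 1e-9:
        return list(windows), []
    from skimage.filters import threshold_otsu

    thresh = threshold_otsu(peaks)
    interior = [w for w, p in zip(windows, peaks) if p <= thresh]
    boundary = [w for w, p in zip(windows, peaks) if p > thresh]
    return interior, boundary


def _windows_to_mask(windows: list[Window], shape: tuple[int, int]) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    for r0, c0, r1, c1 in windows:
        mask[r0:r1, c0:c1] = True
    return mask


def propagate_region(
    prev: CellRegion,
    cur_image: np.ndarray,
    cfg: TrackConfig,
    params: DrlseParams,
    calibration: float,
    freeze_mask: np.ndarray | None = None,
    g: np.ndarray | None = None,
    support_mask: np.ndarray | None = None,
) -> CellRegion | None:
    """Grow the previous frame's region into the current frame.

    Interior sub-windows of the previous mask seed a level set that is
    coevolved with ``freeze_mask`` blocking pixels claimed by other labels
    (contours can touch but never merge).  ``support_mask`` (dark-foreground
    evidence in the current frame) clips the result so a stale seed over
    vacated background cannot balloon across the flat field.  Returns None on
    a lost cell.
    """
    cur_image = np.asarray(cur_image, dtype=float)
    smoothed = drlse.smooth(cur_image, params.sigma)
    if g is None:
        g = drlse.edge_indicator(cur_image, params.sigma)

    windows = split_into_windows(prev, cfg.w, calibration)
    interior, _ = classify_windows(windows, smoothed)
    seed = _windows_to_mask(interior, prev.mask.shape) & prev.mask
    if freeze_mask is not None:
        seed &= ~freeze_mask
    if seed.sum() >= 0.5 * prev.area:
        # overlap region V: the connected seed component that retains the most
        # of the previous mask
        labels, n = ndimage.label(seed)
        if n > 1:
            sizes = ndimage.sum_labels(prev.mask, labels, index=np.arange(1, n + 1))
            seed = labels == (int(np.argmax(sizes)) + 1)
    else:
        # degenerate case (boundary ramp wider than the windows, or cell
        # thinner than a window): fall back to whole-region overlap with the
        # full previous mask
        seed = prev.mask.copy()
        if freeze_mask is not None:
            seed &= ~freeze_mask
    if not seed.any():
        logger.warning("lost cell: label %d has no usable seed", prev.label)
        return None

    margin = cfg.propagate_margin
    rows, cols = np.nonzero(prev.mask | seed)
    h, w = prev.mask.shape
    r0, r1 = max(rows.min() - margin, 0), min(rows.max() + margin + 1, h)
    c0, c1 = max(cols.min() - margin, 0), min(cols.max() + margin + 1, w)
    window = (slice(r0, r1), slice(c0, c1))

    phi0 = drlse.binary_initial_phi(seed[window], params.c0)
    sub_freeze = freeze_mask[window] if freeze_mask is not None else None
    state, _ = drlse.evolve(
        drlse.LevelSetState(phi0, prev.label), g[window], params, freeze_mask=sub_freeze
    )
    grown = state.phi < 0
    if sub_freeze is not None:
        grown &= ~sub_freeze
    if support_mask is not None:
        grown &= support_mask[window]
    labels, n = ndimage.label(grown)
    if n == 0:
        logger.warning("lost cell: label %d evolved to empty", prev.label)
        return None
    if n > 1:
        # keep components connected to the seed (same cell), drop debris
        hit = np.unique(labels[seed[window] & grown])
        hit = hit[hit > 0]
        if hit.size == 0:
            sizes = ndimage.sum_labels(grown, labels, index=np.arange(1, n + 1))
            hit = np.array([int(np.argmax(sizes)) + 1])
        grown = np.isin(labels, hit)
    full = np.zeros_like(prev.mask)
    full[window] = grown
    region = make_region(full, prev.frame + 1, prev.label, calibration)
    return region


# ---------------------------------------------------------------------------
# septum / width division detection


@dataclass
class AxisProfile:
    positions: np.ndarray       # arc-length samples, px
    intensities: np.ndarray     # (inverted) image values at the samples
    origin: np.ndarray          # (row, col) of sample 0
    direction: np.ndarray       # unit vector along the sampled axis
    minima: list[tuple[int, float]] = field(default_factory=list)
    l_m: float | None = None
    l_m_index: int | None = None

    def point_at(self, index: float) -> np.ndarray:
        return self.origin + index * self.direction


def _principal_axes(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    coords = np.argwhere(mask).astype(float)
    centroid = coords.mean(axis=0)
    cov = np.cov((coords - centroid).T)
    vals, vecs = np.linalg.eigh(np.atleast_2d(cov))
    order = np.argsort(vals)[::-1]
    major = vecs[:, order[0]]
    minor = vecs[:, order[1]] if vecs.shape[1] > 1 else np.array([-major[1], major[0]])
    return centroid, major, minor


def axis_profile(
    region: CellRegion,
    image: np.ndarray,
    axis: str = "major",
    pole_margin: int = 2,
    min_prominence: float = 0.5,
) -> AxisProfile:
    """Intensity profile along the region's principal axis.

    Samples at 1-px arc steps, averaged over a 3-px transverse band, and
    records the qualifying local minimum l_m (interior, >= ``pole_margin`` px
    from either pole, dipping at least ``min_prominence`` below its flanking
    maxima so sub-pixel rasterization ripple never qualifies) if one exists.
    Pass the *inverted* smoothed image to use the division convention.
    """
    image = np.asarray(image, dtype=float)
    centroid, major, minor = _principal_axes(region.mask)
    u, v = (major, minor) if axis == "major" else (minor, major)

    coords = np.argwhere(region.mask).astype(float)
    proj = (coords - centroid) @ u
    pmin, pmax = proj.min(), proj.max()
    n = max(int(round(pmax - pmin)) + 1, 3)
    s = pmin + np.arange(n)
    origin = centroid + pmin * u
    pts = centroid[None, :] + s[:, None] * u[None, :]
    band = []
    for k in (-1.0, 0.0, 1.0):
        q = pts + k * v[None, :]
        band.append(
            ndimage.map_coordinates(image, q.T, order=1, mode="nearest")
        )
    intensities = np.mean(band, axis=0)

    minima: list[tuple[int, float]] = []
    for i in range(pole_margin, n - pole_margin):
        if not (0 < i < n - 1):
            continue
        if intensities[i] < intensities[i - 1] and intensities[i] < intensities[i + 1]:
            prominence = (
                min(intensities[:i].max(), intensities[i + 1:].max()) - intensities[i]
            )
            if prominence >= min_prominence:
                minima.append((i, float(intensities[i])))
    profile = AxisProfile(
        positions=np.arange(n, dtype=float),
        intensities=intensities,
        origin=origin,
        direction=u,
        minima=minima,
    )
    if minima:
        idx, val = min(minima, key=lambda m: m[1])
        profile.l_m = val
        profile.l_m_index = idx
    return profile


def boundary_band(mask: np.ndarray) -> np.ndarray:
    """Two-pixel band straddling the region contour (the membrane ring).

    Pooling the ring just inside with the ring just outside puts the septum
    threshold r_m between interior and background levels: a constriction must
    cut well past the membrane intensity before its profile minimum
    qualifies, without demanding a drop all the way to pure background.
    """
    return ndimage.binary_dilation(mask) & ~ndimage.binary_erosion(mask)


def septum_threshold(boundary_pixels: np.ndarray, tau: float) -> float:
    """r_m = mean + tau * sd of the pooled cell-boundary intensities."""
    boundary_pixels = np.asarray(boundary_pixels, dtype=float).ravel()
    if boundary_pixels.size == 0:
        raise ValueError("empty boundary sample")
    return float(boundary_pixels.mean() + tau * boundary_pixels.std())


def detect_division(profile: AxisProfile, r_m: float) -> int | None:
    """Deepest qualifying local minimum strictly below r_m, or None."""
    below = [(i, v) for i, v in profile.minima if v < r_m]
    if not below:
        return None
    return min(below, key=lambda m: m[1])[0]


def split_region(
    region: CellRegion, split_point: np.ndarray, axis_direction: np.ndarray
) -> tuple[CellRegion, CellRegion] | None:
    """Cut the region along the line through ``split_point`` perpendicular to
    ``axis_direction``; returns the two daughters or None if a side is empty."""
    coords = np.argwhere(region.mask)
    proj = (coords - np.asarray(split_point, dtype=float)) @ np.asarray(axis_direction, dtype=float)
    side_a = coords[proj < 0]
    side_b = coords[proj > 0]
    if len(side_a) == 0 or len(side_b) == 0:
        logger.warning("split rejected for label %d: empty side", region.label)
        return None
    daughters = []
    for side in (side_a, side_b):
        mask = np.zeros_like(region.mask)
        mask[side[:, 0], side[:, 1]] = True
        daughters.append(mask)
    calibration = _calibration_of(region)
    a = make_region(daughters[0], region.frame, region.label, calibration)
    b = make_region(daughters[1], region.frame, region.label, calibration)
    if a is None or b is None:
        return None
    return a, b


def _calibration_of(region: CellRegion) -> float:
    """Recover um/px from the stored descriptors (they were derived from px)."""
    from skimage import measure

    props = measure.regionprops(region.mask.astype(np.uint8))[0]
    major_px = float(props.axis_major_length)
    if major_px == 0:
        return 1.0
    return region.length_um / major_px


def split_by_width(
    region: CellRegion, r_w: float, image: np.ndarray, r_m: float | None = None
) -> list[CellRegion]:
    """Split laterally-merged cells: if the minor-axis width strictly exceeds
    ``r_w`` (um), look for a septum-style minimum across the *minor* axis and
    cut along the major axis.  Unchanged region returned otherwise."""
    if not region.width_um > r_w:
        return [region]
    profile = axis_profile(region, image, axis="minor")
    if r_m is None:
        idx = profile.l_m_index
    else:
        idx = detect_division(profile, r_m)
    if idx is None:
        return [region]
    out = split_region(region, profile.point_at(idx), profile.direction)
    if out is None:
        return [region]
    return list(out)


# ---------------------------------------------------------------------------
# trajectory energies


@dataclass
class Trajectory:
    id: int
    b: int                           # birth frame
    d: int                           # final frame
    positions: dict[int, np.ndarray] = field(default_factory=dict)
    regions: dict[int, CellRegion] = field(default_factory=dict)
    parent: int | None = None
    children: tuple[int, int] | None = None

    @property
    def F(self) -> int:
        return self.d - self.b + 1

    def position_array(self) -> np.ndarray:
        return np.array([self.positions[t] for t in range(self.b, self.d + 1)])


@dataclass
class TrackingState:
    trajectories: list[Trajectory] = field(default_factory=list)
    n_frames: int = 0
    calibration: float = 1.0

    def live_at(self, t: int) -> list[Trajectory]:
        return [tr for tr in self.trajectories if tr.b <= t <= tr.d]

    def by_id(self, tid: int) -> Trajectory:
        for tr in self.trajectories:
            if tr.id == tid:
                return tr
        raise KeyError(tid)


def energy_vel(state: TrackingState) -> float:
    """Constant-velocity penalty: sum of squared second differences."""
    total = 0.0
    for tr in state.trajectories:
        if tr.F < 3:
            continue
        x = tr.position_array()
        total += float(np.sum((x[:-2] - 2 * x[1:-1] + x[2:]) ** 2))
    return total


def energy_exc(state: TrackingState, r_w: float) -> float:
    """Mutual-exclusion penalty over ordered pairs of coexisting cells."""
    if not state.trajectories:
        return 0.0
    t_min = min(tr.b for tr in state.trajectories)
    t_max = max(tr.d for tr in state.trajectories)
    total = 0.0
    for t in range(t_min, t_max + 1):
        alive = state.live_at(t)
        for i, tr_n in enumerate(alive):
            for j, tr_j in enumerate(alive):
                if i == j:
                    continue
                d2 = float(np.sum((tr_n.positions[t] - tr_j.positions[t]) ** 2))
                if d2 == 0.0:
                    return float("inf")
                total += r_w**2 / d2
    return total


def energy_reg(state: TrackingState) -> float:
    """Trajectory-count regularizer: N + sum 1/F(n)."""
    if not state.trajectories:
        return 0.0
    return float(len(state.trajectories) + sum(1.0 / tr.F for tr in state.trajectories))


def energy_total(state: TrackingState, cfg: TrackConfig) -> float:
    """Weighted trajectory energy; r_w is converted to px via the state's
    calibration."""
    r_w_px = cfg.r_w / state.calibration
    return (
        cfg.beta * energy_vel(state)
        + cfg.gamma * energy_exc(state, r_w_px)
        + cfg.eta * energy_reg(state)
    )


# ---------------------------------------------------------------------------
# identity assignment


def _overlap(a: CellRegion, b: CellRegion) -> int:
    return int(np.sum(a.mask & b.mask))


def _component_energy(
    trajs: list[Trajectory],
    assignment: dict[int, int | None],
    candidates: list[CellRegion],
    frame: int,
    cfg: TrackConfig,
    calibration: float,
) -> float:
    """Energy of one tentative assignment: extend each assigned trajectory by
    its candidate's centroid, open new single-frame tracks for the rest."""
    mini = TrackingState(calibration=calibration)
    assigned = {}
    for ci, tid in assignment.items():
        if tid is not None:
            assigned[tid] = ci
    for tr in trajs:
        ext = Trajectory(tr.id, tr.b, tr.d, dict(tr.positions))
        if tr.id in assigned:
            ext.positions[frame] = candidates[assigned[tr.id]].centroid
            ext.d = frame
        mini.trajectories.append(ext)
    next_new = max((tr.id for tr in trajs), default=0) + 1
    for ci, tid in assignment.items():
        if tid is None:
            mini.trajectories.append(
                Trajectory(
                    next_new, frame, frame, {frame: candidates[ci].centroid}
                )
            )
            next_new += 1
    return energy_total(mini, cfg)


def assign_optimal(
    candidates: list[CellRegion],
    state: TrackingState,
    frame: int,
    cfg: TrackConfig,
    links: dict[int, set[int]] | None = None,
) -> dict[int, int | None]:
    """Assign frame-``frame`` candidate regions to trajectories.

    ``links`` maps candidate index -> set of admissible trajectory ids
    (default: mask overlap with the trajectory's previous region).  Returns
    candidate index -> trajectory id (None = open a new trajectory).
    Unambiguous one-to-one links are accepted directly; ambiguous components
    are resolved by exact enumeration of consistent assignments, scored with
    the total trajectory energy, with a greedy maximum-overlap fallback past
    ``cfg.max_assignments``.
    """
    live = [tr for tr in state.trajectories if tr.d == frame - 1 and tr.children is None]
    if links is None:
        links = {}
        for ci, cand in enumerate(candidates):
            linked = set()
            for tr in live:
                prev_region = tr.regions.get(frame - 1)
                if prev_region is not None and _overlap(cand, prev_region) > 0:
                    linked.add(tr.id)
            links[ci] = linked

    # connected components of the bipartite candidate/trajectory graph
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        while parent.setdefault(x, x) != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: str, b: str) -> None:
        parent[find(a)] = find(b)

    for ci in range(len(candidates)):
        find(f"c{ci}")
        for tid in links.get(ci, ()):
            union(f"c{ci}", f"t{tid}")

    groups: dict[str, tuple[list[int], set[int]]] = {}
    for ci in range(len(candidates)):
        root = find(f"c{ci}")
        groups.setdefault(root, ([], set()))[0].append(ci)
        groups[root][1].update(links.get(ci, ()))

    result: dict[int, int | None] = {}
    for cand_ids, traj_ids in groups.values():
        tlist = sorted(traj_ids)
        if len(cand_ids) == 1 and len(tlist) <= 1:
            result[cand_ids[0]] = tlist[0] if tlist else None
            continue
        trajs = [state.by_id(tid) for tid in tlist]
        options = [sorted(links[ci]) + [None] for ci in cand_ids]
        best: dict[int, int | None] | None = None
        best_energy = float("inf")
        count = 0
        exploded = False
        for combo in itertools.product(*options):
            taken = [t for t in combo if t is not None]
            if len(taken) != len(set(taken)):
                continue
            count += 1
            if count > cfg.max_assignments:
                exploded = True
                break
            assignment = dict(zip(cand_ids, combo))
            e = _component_energy(
                trajs, assignment, candidates, frame, cfg, state.calibration
            )
            if e < best_energy:
                best_energy = e
                best = assignment
        if exploded or best is None:
            logger.warning(
                "assignment enumeration capped (%d candidates, %d tracks); "
                "falling back to greedy overlap", len(cand_ids), len(tlist)
            )
            best = {}
            used: set[int] = set()
            pairs = []
            for ci in cand_ids:
                for tid in links[ci]:
                    prev_region = state.by_id(tid).regions.get(frame - 1)
                    if prev_region is not None:
                        pairs.append((_overlap(candidates[ci], prev_region), ci, tid))
            for _, ci, tid in sorted(pairs, reverse=True):
                if ci in best or tid in used:
                    continue
                best[ci] = tid
                used.add(tid)
            for ci in cand_ids:
                best.setdefault(ci, None)
        result.update(best)
    return result


# ---------------------------------------------------------------------------
# full tracking pass


def _relabel(region: CellRegion, label: int, frame: int) -> CellRegion:
    region.label = label
    region.frame = frame
    return region


def track_stack(
    frames: "np.ndarray | object",
    seg_cfg: SegConfig,
    track_cfg: TrackConfig,
    params: DrlseParams,
    calibration: float | None = None,
):
    """Run the full pipeline over an image stack.

    ``frames`` is a (T, H, W) array or any object with ``.frames`` and
    ``.calibration``.  Returns (per-frame region lists, TrackingState,
    lineage dict parent_id -> (child_id, child_id)).
    """
    if hasattr(frames, "frames"):
        calibration = getattr(frames, "calibration", calibration)
        frames = np.asarray(frames.frames, dtype=float)
    else:
        frames = np.asarray(frames, dtype=float)
    if calibration is None:
        calibration = seg_cfg.calibration
    n_frames = len(frames)
    min_split = (
        track_cfg.min_split_length_um
        if track_cfg.min_split_length_um is not None
        else 2.0 * seg_cfg.r_s
    )

    state = TrackingState(n_frames=n_frames, calibration=calibration)
    lineage: dict[int, tuple[int, int]] = {}
    per_frame: list[list[CellRegion]] = []
    next_id = 1
    # septum evidence must persist for two consecutive frames before a split
    # is committed (guards against transient noise dips)
    septum_pending: set[int] = set()

    first = segment_first_frame(frames[0], seg_cfg, params)
    frame_regions = []
    for region in first:
        region = _relabel(region, next_id, 0)
        state.trajectories.append(
            Trajectory(
                next_id, 0, 0,
                positions={0: region.centroid},
                regions={0: region},
            )
        )
        frame_regions.append(region)
        next_id += 1
    per_frame.append(frame_regions)

    for t in range(1, n_frames):
        image = frames[t]
        smoothed = drlse.smooth(image, params.sigma)
        inverted = smoothed.max() - smoothed
        g = drlse.edge_indicator(image, params.sigma)
        # dark-foreground support for this frame, slightly dilated so the
        # clipped contour keeps the blurred cell margin
        support = ndimage.binary_dilation(
            initial_seeds(smoothed, seg_cfg), iterations=2
        )

        live = [tr for tr in state.trajectories if tr.d == t - 1 and tr.children is None]
        shape = image.shape
        prev_union = np.zeros(shape, dtype=bool)
        for tr in live:
            prev_union |= tr.regions[t - 1].mask

        claimed = np.zeros(shape, dtype=bool)
        raw: list[tuple[Trajectory, CellRegion]] = []
        for tr in live:
            own_prev = tr.regions[t - 1].mask
            freeze = claimed | (prev_union & ~own_prev)
            cand = propagate_region(
                tr.regions[t - 1], image, track_cfg, params, calibration,
                freeze_mask=freeze, g=g, support_mask=support,
            )
            if cand is None:
                logger.warning("trajectory %d lost at frame %d", tr.id, t)
                continue
            claimed |= cand.mask
            raw.append((tr, cand))

        # per-frame septum threshold from all candidates' boundary bands
        band_values = [inverted[boundary_band(c.mask)] for _, c in raw]
        pooled = np.concatenate(band_values) if band_values else np.array([])
        r_m = septum_threshold(pooled, track_cfg.tau) if pooled.size else None

        candidates: list[CellRegion] = []
        links: dict[int, set[int]] = {}

        def add_candidate(region: CellRegion, linked: set[int]) -> None:
            links[len(candidates)] = linked
            candidates.append(region)

        for tr, cand in raw:
            pieces = split_by_width(cand, track_cfg.r_w, inverted, r_m)
            if len(pieces) == 2:
                for piece in pieces:
                    add_candidate(piece, {tr.id})
                continue
            cand = pieces[0]
            if r_m is not None and cand.length_um >= min_split:
                profile = axis_profile(cand, inverted, axis="major")
                idx = detect_division(profile, r_m)
                if idx is not None and tr.id not in septum_pending:
                    septum_pending.add(tr.id)
                    idx = None
                elif idx is None:
                    septum_pending.discard(tr.id)
                if idx is not None:
                    split = split_region(
                        cand, profile.point_at(idx), profile.direction
                    )
                    if split is not None and min(
                        split[0].length_um, split[1].length_um
                    ) < seg_cfg.r_s:
                        # a complete cell is never shorter than r_s: a cut
                        # that close to a pole is a noise dip, not a septum
                        split = None
                    if split is not None:
                        # division: close the mother, open two daughters
                        child_ids = []
                        for daughter in split:
                            daughter = _relabel(daughter, next_id, t)
                            state.trajectories.append(
                                Trajectory(
                                    next_id, t, t,
                                    positions={t: daughter.centroid},
                                    regions={t: daughter},
                                    parent=tr.id,
                                )
                            )
                            child_ids.append(next_id)
                            next_id += 1
                        tr.children = (child_ids[0], child_ids[1])
                        tr.regions[t - 1].divided = True
                        lineage[tr.id] = tr.children
                        continue
            add_candidate(cand, {tr.id})

        # new cells entering the field of view
        occupied = np.zeros(shape, dtype=bool)
        for region in candidates:
            occupied |= region.mask
        for tr in state.trajectories:
            if tr.b == t:
                occupied |= tr.regions[t].mask
        fresh = capture_new_cells(
            image, occupied, seg_cfg, params, frame=t, first_label=next_id
        )
        for region in fresh:
            add_candidate(region, set())

        assignment = assign_optimal(candidates, state, t, track_cfg, links=links)
        for ci, tid in assignment.items():
            region = candidates[ci]
            if tid is None:
                region = _relabel(region, next_id, t)
                state.trajectories.append(
                    Trajectory(
                        next_id, t, t,
                        positions={t: region.centroid},
                        regions={t: region},
                    )
                )
                next_id += 1
            else:
                tr = state.by_id(tid)
                region = _relabel(region, tid, t)
                tr.positions[t] = region.centroid
                tr.regions[t] = region
                tr.d = t

        per_frame.append([tr.regions[t] for tr in state.trajectories if tr.b <= t <= tr.d])

    return per_frame, state, lineage
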