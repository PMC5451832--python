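"""First-frame segmentation and capture of newly entering cells.

Rough seeds come from adaptive thresholding (dark cells on a bright
background); each seed is then evolved independently by the level-set flow,
small debris is removed with the minimum-length filter ``r_s`` and objects
touching the image border are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure

from . import drlse
from .config import DrlseParams, SegConfig


@dataclass
class CellRegion:
    """One segmented cell in one frame."""

    label: int
    frame: int
    mask: np.ndarray            # bool, full-frame
    contour: np.ndarray         # (N, 2) float, (row, col) polyline
    centroid: np.ndarray        # (row, col), px
    area: int                   # px^2
    length_um: float            # major-axis extent
    width_um: float             # minor-axis extent
    orientation: float          # radians, skimage convention
    eccentricity: float
    touches_border: bool
    divided: bool = False

    @property
    def bbox(self) -> tuple[int, int, int, int]:
        rows, cols = np.nonzero(self.mask)
        return rows.min(), cols.min(), rows.max() + 1, cols.max() + 1


def make_region(
    mask: np.ndarray, frame: int, label: int, calibration: float
) -> CellRegion | None:
    """Build a :class:`CellRegion` from a boolean mask; None if empty."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return None
    props = measure.regionprops(mask.astype(np.uint8))[0]
    contours = measure.find_contours(mask.astype(float), 0.5)
    contour = max(contours, key=len) if contours else np.zeros((0, 2))
    h, w = mask.shape
    touches = bool(
        mask[0, :].any() or mask[-1, :].any() or mask[:, 0].any() or mask[:, -1].any()
    )
    return CellRegion(
        label=label,
        frame=frame,
        mask=mask,
        contour=contour,
        centroid=np.array(props.centroid),
        area=int(props.area),
        length_um=float(props.axis_major_length) * calibration,
        width_um=float(props.axis_minor_length) * calibration,
        orientation=float(props.orientation),
        eccentricity=float(props.eccentricity),
        touches_border=touches,
    )


def initial_seeds(image: np.ndarray, cfg: SegConfig) -> np.ndarray:
    """Rough cell-interior mask via local-mean adaptive thresholding."""
    image = np.asarray(image, dtype=float)
    local_mean = ndimage.uniform_filter(image, size=cfg.thresh_block, mode="nearest")
    seeds = image < local_mean - cfg.thresh_offset
    seeds = ndimage.binary_fill_holes(seeds)
    # drop specks that could never be cells
    labels, n = ndimage.label(seeds)
    if n:
        sizes = ndimage.sum_labels(seeds, labels, index=np.arange(1, n + 1))
        keep = np.flatnonzero(sizes >= cfg.min_seed_area) + 1
        seeds = np.isin(labels, keep)
    return seeds


def _evolve_seed(
    seed: np.ndarray,
    g: np.ndarray,
    params: DrlseParams,
    freeze: np.ndarray | None,
    margin: int = 15,
) -> np.ndarray:
    """Evolve one seed on a cropped sub-domain; returns the grown full mask."""
    rows, cols = np.nonzero(seed)
    h, w = seed.shape
    r0, r1 = max(rows.min() - margin, 0), min(rows.max() + margin + 1, h)
    c0, c1 = max(cols.min() - margin, 0), min(cols.max() + margin + 1, w)
    window = (slice(r0, r1), slice(c0, c1))
    phi0 = drlse.binary_initial_phi(seed[window], params.c0)
    sub_freeze = freeze[window] if freeze is not None else None
    state, _ = drlse.evolve(
        drlse.LevelSetState(phi0), g[window], params, freeze_mask=sub_freeze
    )
    grown = state.phi < 0
    if sub_freeze is not None:
        grown &= ~sub_freeze
    # keep only the component(s) connected to the seed
    labels, n = ndimage.label(grown)
    if n > 1:
        hit = np.unique(labels[seed[window] & grown])
        hit = hit[hit > 0]
        grown = np.isin(labels, hit) if hit.size else grown
    full = np.zeros_like(seed)
    full[window] = grown
    return full


def _segment_from_seeds(
    seeds: np.ndarray,
    g: np.ndarray,
    frame: int,
    cfg: SegConfig,
    params: DrlseParams,
    forbidden: np.ndarray | None = None,
    first_label: int = 1,
    evidence: np.ndarray | None = None,
) -> list[CellRegion]:
    """Evolve each seed component and filter the results.

    ``evidence`` is the unrestricted dark-foreground mask; a grown region
    must draw at least half its area from it, which stops a stray seed from
    ballooning across the featureless background (where the edge indicator
    is ~1 and nothing else halts an expanding contour).
    """
    seed_labels, n = ndimage.label(seeds)
    claimed = np.zeros_like(seeds) if forbidden is None else forbidden.copy()
    regions: list[CellRegion] = []
    order = sorted(
        range(1, n + 1), key=lambda k: -int(np.sum(seed_labels == k))
    )
    label = first_label
    for k in order:
        seed = seed_labels == k
        grown = _evolve_seed(seed, g, params, freeze=claimed)
        region = make_region(grown, frame, label, cfg.calibration)
        if region is None:
            continue
        if region.length_um < cfg.r_s or region.touches_border:
            continue
        if evidence is not None:
            support = np.sum(grown & evidence) / region.area
            if support < 0.5:
                continue
        claimed |= grown
        regions.append(region)
        label += 1
    return regions


def segment_first_frame(
    image: np.ndarray, cfg: SegConfig, params: DrlseParams
) -> list[CellRegion]:
    """Segment a frame from scratch: seeds, per-seed evolution, size filter.

    Components shorter than ``r_s`` (um, major axis) or touching the image
    border are removed; survivors are labelled 1..n.
    """
    image = np.asarray(image, dtype=float)
    smoothed = drlse.smooth(image, params.sigma)
    g = drlse.edge_indicator(image, params.sigma)
    seeds = initial_seeds(smoothed, cfg)
    if not seeds.any():
        return []
    return _segment_from_seeds(
        seeds, g, frame=0, cfg=cfg, params=params, evidence=seeds
    )


def capture_new_cells(
    image: np.ndarray,
    occupied: np.ndarray,
    cfg: SegConfig,
    params: DrlseParams,
    frame: int = 0,
    first_label: int = 1,
) -> list[CellRegion]:
    """Run the first-frame scheme on the complement of already-tracked area."""
    image = np.asarray(image, dtype=float)
    occupied = np.asarray(occupied, dtype=bool)
    smoothed = drlse.smooth(image, params.sigma)
    g = drlse.edge_indicator(image, params.sigma)
    barrier = ndimage.binary_dilation(occupied, iterations=2)
    evidence = initial_seeds(smoothed, cfg)
    seeds = evidence & ~barrier
    labels, n = ndimage.label(seeds)
    if n:
        sizes = ndimage.sum_labels(seeds, labels, index=np.arange(1, n + 1))
        keep = np.flatnonzero(sizes >= cfg.min_seed_area) + 1
        seeds = np.isin(labels, keep)
    if not seeds.any():
        return []
    return _segment_from_seeds(
        seeds, g, frame=frame, cfg=cfg, params=params,
        forbidden=occupied, first_label=first_label, evidence=evidence,
    )
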