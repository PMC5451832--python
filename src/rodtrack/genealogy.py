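"""Lineage trees and single-cell growth statistics."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .tracking import TrackingState, Trajectory

logger = logging.getLogger(__name__)


class LineageError(ValueError):
    """Inconsistent parent/child links in a tracking state."""


@dataclass
class LineageNode:
    id: int
    b: int
    d: int
    parent: int | None
    children: tuple[int, int] | None
    generation: int


@dataclass
class LineageTree:
    nodes: dict[int, LineageNode]
    roots: list[int]

    def generations(self) -> dict[int, int]:
        return {nid: node.generation for nid, node in self.nodes.items()}

    def to_newick(self) -> str:
        """Newick forest, branch lengths = trajectory duration in frames."""

        def fmt(nid: int) -> str:
            node = self.nodes[nid]
            length = node.d - node.b + 1
            if node.children is None:
                return f"{nid}:{length}"
            a, b = node.children
            return f"({fmt(a)},{fmt(b)}){nid}:{length}"

        return ";".join(fmt(r) for r in self.roots) + ";"


@dataclass
class GrowthRecord:
    trajectory_id: int
    size_at_birth: float        # um
    size_at_division: float     # um
    division_time_frames: int
    division_time_seconds: float
    elongation_rate: float      # per frame, log-linear fit
    divided: bool


def build_tree(state: TrackingState) -> LineageTree:
    """Validate the parent/child links and return the lineage forest."""
    by_id = {tr.id: tr for tr in state.trajectories}
    bad: list[int] = []
    graph = nx.DiGraph()
    for tr in state.trajectories:
        graph.add_node(tr.id)
        if tr.children is not None:
            if len(set(tr.children)) != 2:
                bad.append(tr.id)
                continue
            for child in tr.children:
                if child not in by_id or by_id[child].parent != tr.id:
                    bad.append(tr.id)
                    continue
                if by_id[child].b != tr.d + 1:
                    bad.append(tr.id)
                graph.add_edge(tr.id, child)
        if tr.parent is not None:
            p = by_id.get(tr.parent)
            if p is None or p.children is None or tr.id not in p.children:
                bad.append(tr.id)
    if bad:
        raise LineageError(f"inconsistent lineage links for trajectories {sorted(set(bad))}")
    if graph.number_of_nodes() and not nx.is_forest(graph):
        raise LineageError("lineage graph contains a cycle")

    roots = [tr.id for tr in state.trajectories if tr.parent is None]
    nodes: dict[int, LineageNode] = {}

    def walk(nid: int, gen: int) -> None:
        tr = by_id[nid]
        nodes[nid] = LineageNode(nid, tr.b, tr.d, tr.parent, tr.children, gen)
        if tr.children is not None:
            for child in tr.children:
                walk(child, gen + 1)

    for root in roots:
        walk(root, 0)
    return LineageTree(nodes=nodes, roots=sorted(roots))


def growth_curves(
    state: TrackingState, frame_interval: float = 69.0
) -> list[GrowthRecord]:
    """Per-trajectory growth statistics from the tracked region lengths.

    The elongation rate is the slope of a least-squares line fit to
    log(length) against frame index (cells elongate approximately
    exponentially, so the log-linear slope is the per-frame rate).
    """
    records: list[GrowthRecord] = []
    for tr in state.trajectories:
        frames = sorted(tr.regions)
        lengths = np.array([tr.regions[t].length_um for t in frames], dtype=float)
        if np.any(lengths <= 0):
            logger.warning("trajectory %d skipped: non-positive length", tr.id)
            continue
        if len(frames) >= 3:
            rate = float(np.polyfit(np.asarray(frames, dtype=float), np.log(lengths), 1)[0])
        else:
            rate = float("nan")
        divided = tr.children is not None
        records.append(
            GrowthRecord(
                trajectory_id=tr.id,
                size_at_birth=float(lengths[0]),
                size_at_division=float(lengths[-1]),
                division_time_frames=tr.F,
                division_time_seconds=tr.F * frame_interval,
                elongation_rate=rate,
                divided=divided,
            )
        )
    return records
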