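"""Lineage trees of contracting regions: origins, ASC and ASTC analyses.

Each supra-threshold connected region in each frame becomes a node.
Lineage runs forward in time toward the merged peak-contraction region:
a node's parent is a region in a later frame of the same contraction
cycle whose member set contains the node's centroid, so the fully merged
region is the root (depth 0) and the earliest small regions are leaves.
Leaves of multi-node trees are candidate contraction origins — deeper
leaves lead the contraction by more frames and rank as stronger origins.
Isolated single-frame regions are singletons (independent beating areas).

The ASC (accumulative spatial contraction) map assigns every grid point
the maximum tree depth of any node covering it, accumulated over the
whole video, so origins appear as elevated peaks.  The ASTC table lays
the same forest out in space and time (node and edge tables), exposing
propagation delays and synchrony between origins.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from skimage import measure as sk_measure

__all__ = [
    "Region",
    "RegionNode",
    "ContractionForest",
    "Origin",
    "label_regions",
    "segment_cycles",
    "build_forest",
    "find_origins",
    "asc_map",
    "astc_table",
    "origin_lags",
]


@dataclass(frozen=True)
class Region:
    """One 8-connected supra-threshold component on the vector grid."""

    frame_index: int
    cells: frozenset  # {(row, col)} grid indices
    area_um2: float
    centroid_grid: tuple[float, float]  # (row, col), grid-index units
    centroid_um: tuple[float, float]  # (x_um, y_um)

    def contains(self, centroid_grid: tuple[float, float]) -> bool:
        """Centroid containment, evaluated on the grid member set."""
        cell = (int(round(centroid_grid[0])), int(round(centroid_grid[1])))
        return cell in self.cells


@dataclass
class RegionNode:
    id: int
    frame_index: int
    cells: frozenset
    area_um2: float
    centroid_grid: tuple[float, float]
    centroid_um: tuple[float, float]
    cycle_id: int
    parent: int | None = None
    children: list[int] = dc_field(default_factory=list)
    depth: int = 0

    def contains(self, centroid_grid: tuple[float, float]) -> bool:
        cell = (int(round(centroid_grid[0])), int(round(centroid_grid[1])))
        return cell in self.cells


@dataclass
class ContractionForest:
    """All lineage trees of a video, one tree per (cycle, root)."""

    nodes: dict[int, RegionNode]
    roots: list[int]
    cycles: list[tuple[int, int]]  # inclusive (start, end) frame ranges
    grid_shape: tuple[int, int]
    fps: float

    @property
    def leaves(self) -> list[int]:
        return [i for i, n in self.nodes.items() if not n.children]

    @property
    def singletons(self) -> list[int]:
        """Nodes that are simultaneously leaf and root."""
        rootset = set(self.roots)
        return [i for i in self.leaves if i in rootset]

    def tree_members(self, root_id: int) -> list[int]:
        out = []
        todo = [root_id]
        while todo:
            i = todo.pop()
            out.append(i)
            todo.extend(self.nodes[i].children)
        return out

    def root_of(self, node_id: int) -> int:
        n = self.nodes[node_id]
        while n.parent is not None:
            n = self.nodes[n.parent]
        return n.id

    def path_to_root(self, node_id: int) -> list[int]:
        path = [node_id]
        n = self.nodes[node_id]
        while n.parent is not None:
            path.append(n.parent)
            n = self.nodes[n.parent]
        return path

    @property
    def max_depth(self) -> int:
        return max((n.depth for n in self.nodes.values()), default=0)


def label_regions(
    mask: np.ndarray,
    block_area_um2: float,
    min_area_um2: float,
    grid_x: np.ndarray,
    grid_y: np.ndarray,
    pixel_size_um: float,
    frame_index: int = 0,
) -> list[Region]:
    """8-connected components of a grid mask, small components dropped."""
    labels = sk_measure.label(np.asarray(mask, dtype=bool), connectivity=2)
    regions: list[Region] = []
    for lab in range(1, labels.max() + 1):
        rr, cc = np.nonzero(labels == lab)
        area = len(rr) * block_area_um2
        if area < min_area_um2:
            continue
        crow = float(rr.mean())
        ccol = float(cc.mean())
        x_um = float(np.mean(grid_x[cc])) * pixel_size_um
        y_um = float(np.mean(grid_y[rr])) * pixel_size_um
        regions.append(
            Region(
                frame_index=frame_index,
                cells=frozenset(zip(rr.tolist(), cc.tolist())),
                area_um2=area,
                centroid_grid=(crow, ccol),
                centroid_um=(x_um, y_um),
            )
        )
    return regions


def segment_cycles(region_counts) -> list[tuple[int, int]]:
    """Contraction cycles: maximal runs of frames with any region present.

    ``region_counts`` is a per-frame sequence of region counts (or any
    truthy indicator).  A run touching the end of the video is closed at
    the last frame.
    """
    active = [bool(c) for c in region_counts]
    cycles = []
    start = None
    for i, a in enumerate(active):
        if a and start is None:
            start = i
        elif not a and start is not None:
            cycles.append((start, i - 1))
            start = None
    if start is not None:
        cycles.append((start, len(active) - 1))
    return cycles


def _assign_parents(nodes: list[RegionNode], by_frame: dict[int, list[RegionNode]],
                    cycle_end: int) -> None:
    """Attach each node to the smallest containing region in the nearest
    later frame of the cycle (frame-by-frame forward search)."""
    for node in sorted(nodes, key=lambda n: (n.area_um2, n.frame_index, n.id)):
        for t in range(node.frame_index + 1, cycle_end + 1):
            candidates = [
                cand
                for cand in by_frame.get(t, [])
                if cand.contains(node.centroid_grid)
            ]
            if candidates:
                parent = min(candidates, key=lambda c: (c.area_um2, c.id))
                node.parent = parent.id
                parent.children.append(node.id)
                break


def build_forest(
    masks,
    block_area_um2: float,
    min_area_um2: float,
    grid_x: np.ndarray,
    grid_y: np.ndarray,
    pixel_size_um: float,
    fps: float,
) -> ContractionForest:
    """Build the full contraction forest from per-frame grid masks.

    ``masks`` maps frame index to boolean grid mask (a sequence indexed by
    frame also works).  One tree is built per contraction cycle; nodes at
    the cycle's last frame, or with no containing region in any later
    frame of the cycle, become roots.
    """
    if isinstance(masks, dict):
        frame_ids = sorted(masks)
        mask_list = [masks[i] for i in frame_ids]
    else:
        mask_list = list(masks)
        frame_ids = list(range(len(mask_list)))
    grid_shape = np.asarray(mask_list[0]).shape

    regions_by_frame: dict[int, list[Region]] = {}
    for fid, m in zip(frame_ids, mask_list):
        regs = label_regions(m, block_area_um2, min_area_um2, grid_x, grid_y,
                             pixel_size_um, frame_index=fid)
        if regs:
            regions_by_frame[fid] = regs

    counts = [len(regions_by_frame.get(fid, [])) for fid in frame_ids]
    cycle_ranges = [
        (frame_ids[a], frame_ids[b]) for a, b in segment_cycles(counts)
    ]

    nodes: dict[int, RegionNode] = {}
    roots: list[int] = []
    next_id = 0
    for cycle_id, (start, end) in enumerate(cycle_ranges):
        cycle_nodes: list[RegionNode] = []
        by_frame: dict[int, list[RegionNode]] = {}
        for fid in range(start, end + 1):
            for reg in regions_by_frame.get(fid, []):
                node = RegionNode(
                    id=next_id,
                    frame_index=fid,
                    cells=reg.cells,
                    area_um2=reg.area_um2,
                    centroid_grid=reg.centroid_grid,
                    centroid_um=reg.centroid_um,
                    cycle_id=cycle_id,
                )
                next_id += 1
                cycle_nodes.append(node)
                by_frame.setdefault(fid, []).append(node)
        _assign_parents(cycle_nodes, by_frame, end)
        for node in cycle_nodes:
            nodes[node.id] = node
            if node.parent is None:
                roots.append(node.id)

    # depth runs root-down: depth(child) = depth(parent) + 1
    for root in roots:
        todo = [(root, 0)]
        while todo:
            nid, d = todo.pop()
            nodes[nid].depth = d
            todo.extend((c, d + 1) for c in nodes[nid].children)

    return ContractionForest(nodes=nodes, roots=roots, cycles=cycle_ranges,
                             grid_shape=tuple(grid_shape), fps=fps)


@dataclass
class Origin:
    """A consolidated contraction origin (leaf cluster across cycles)."""

    centroid_grid: tuple[float, float]
    centroid_um: tuple[float, float]
    max_depth: int
    total_path_area_um2: float
    leaf_ids: list[int]

    @property
    def n_cycles(self) -> int:
        return len(self.leaf_ids)


def find_origins(
    forest: ContractionForest,
    consolidate: bool = True,
    merge_dist_cells: float = 1.5,
) -> tuple[list[Origin], list[int]]:
    """Ranked contraction origins plus independent (singleton) regions.

    Origins are the leaves of multi-node trees, ranked by depth below the
    root (a deeper lineage leads the contraction for longer and marks a
    stronger origin), ties broken by the total area along the leaf-to-root
    path.  With ``consolidate`` the per-cycle leaves are clustered by
    centroid proximity so recurring origins appear once.
    """
    singles = set(forest.singletons)
    leaves = [i for i in forest.leaves if i not in singles]

    def rank_key(leaf_id: int):
        path = forest.path_to_root(leaf_id)
        area = sum(forest.nodes[i].area_um2 for i in path)
        return (forest.nodes[leaf_id].depth, area)

    ranked = sorted(leaves, key=rank_key, reverse=True)
    origins: list[Origin] = []
    for leaf_id in ranked:
        node = forest.nodes[leaf_id]
        depth = node.depth
        path_area = sum(forest.nodes[i].area_um2
                        for i in forest.path_to_root(leaf_id))
        if consolidate:
            merged = False
            for o in origins:
                dr = node.centroid_grid[0] - o.centroid_grid[0]
                dc = node.centroid_grid[1] - o.centroid_grid[1]
                if np.hypot(dr, dc) <= merge_dist_cells:
                    o.leaf_ids.append(leaf_id)
                    o.max_depth = max(o.max_depth, depth)
                    o.total_path_area_um2 += path_area
                    merged = True
                    break
            if merged:
                continue
        origins.append(
            Origin(
                centroid_grid=node.centroid_grid,
                centroid_um=node.centroid_um,
                max_depth=depth,
                total_path_area_um2=path_area,
                leaf_ids=[leaf_id],
            )
        )
    origins.sort(key=lambda o: (o.max_depth, o.total_path_area_um2), reverse=True)
    return origins, sorted(singles)


def asc_map(forest: ContractionForest, mode: str = "max") -> np.ndarray:
    """Accumulated spatial contraction map on the vector grid.

    Each grid point carries the maximum (or, with ``mode="sum"``, the
    summed) tree depth of the nodes covering it across all trees of the
    video; elevated peaks mark contraction origins.
    """
    if mode not in ("max", "sum"):
        raise ValueError("mode must be 'max' or 'sum'")
    out = np.zeros(forest.grid_shape, dtype=float)
    for node in forest.nodes.values():
        rr, cc = zip(*node.cells)
        if mode == "max":
            np.maximum.at(out, (np.array(rr), np.array(cc)), node.depth)
        else:
            np.add.at(out, (np.array(rr), np.array(cc)), node.depth)
    return out


def astc_table(forest: ContractionForest) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Space-time node and edge tables of the contraction forest."""
    origins, singletons = find_origins(forest, consolidate=False)
    origin_leaves = {o.leaf_ids[0] for o in origins}
    single_set = set(singletons)
    rows = []
    for node in sorted(forest.nodes.values(), key=lambda n: n.id):
        rows.append(
            {
                "id": node.id,
                "x_um": node.centroid_um[0],
                "y_um": node.centroid_um[1],
                "t_s": node.frame_index / forest.fps,
                "area_um2": node.area_um2,
                "depth": node.depth,
                "cycle_id": node.cycle_id,
                "is_origin": int(node.id in origin_leaves),
                "is_singleton": int(node.id in single_set),
            }
        )
    nodes_df = pd.DataFrame(
        rows,
        columns=["id", "x_um", "y_um", "t_s", "area_um2", "depth", "cycle_id",
                 "is_origin", "is_singleton"],
    )
    edges = [
        {"parent_id": n.parent, "child_id": n.id}
        for n in sorted(forest.nodes.values(), key=lambda n: n.id)
        if n.parent is not None
    ]
    edges_df = pd.DataFrame(edges, columns=["parent_id", "child_id"])
    return nodes_df, edges_df


def origin_lags(forest: ContractionForest, merge_dist_cells: float = 1.5):
    """Per-cycle onset times of each consolidated origin and pairwise lags.

    Returns (onsets, lags): ``onsets`` maps origin rank to {cycle_id:
    onset_s}; ``lags`` is a DataFrame of mean onset differences between
    origin pairs (propagation delay, quantised to the frame period).
    """
    origins, _ = find_origins(forest, consolidate=True,
                              merge_dist_cells=merge_dist_cells)
    onsets: dict[int, dict[int, float]] = {}
    for rank, o in enumerate(origins):
        per_cycle: dict[int, float] = {}
        for leaf_id in o.leaf_ids:
            node = forest.nodes[leaf_id]
            t = node.frame_index / forest.fps
            if node.cycle_id not in per_cycle or t < per_cycle[node.cycle_id]:
                per_cycle[node.cycle_id] = t
        onsets[rank] = per_cycle
    rows = []
    for a in onsets:
        for b in onsets:
            if b <= a:
                continue
            shared = sorted(set(onsets[a]) & set(onsets[b]))
            if not shared:
                continue
            diffs = [onsets[b][c] - onsets[a][c] for c in shared]
            rows.append(
                {
                    "origin_a": a,
                    "origin_b": b,
                    "n_cycles": len(shared),
                    "mean_lag_s": float(np.mean(diffs)),
                    "sd_lag_s": float(np.std(diffs)),
                }
            )
    return onsets, pd.DataFrame(
        rows, columns=["origin_a", "origin_b", "n_cycles", "mean_lag_s", "sd_lag_s"]
    )
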