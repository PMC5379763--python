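"""Frame-to-frame cell correspondence and lineage trees.

A cell in a movie can proliferate, divide, or be lost (death or drift out of
the field of view).  The tracker here is a deliberately simple stand-in with a
swappable interface: consecutive frames are matched per colony by maximizing
pixel overlap after compensating for the colony's centroid drift, and a
mother maps to two daughters when their combined overlap reaches 60% of her
area with each daughter contributing at least 20%.  The lineage forest
condenses to a "divisions tree" whose nodes are only the division events,
convenient for visualizing life attributes across generations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol

import numpy as np

__all__ = [
    "LineageNode",
    "LineageForest",
    "DivisionsTree",
    "OverlapTracker",
    "track_cells",
    "build_divisions_tree",
    "export_graphml",
    "export_cell_table",
]


@dataclass
class LineageNode:
    cell_id: int
    colony_track_id: int
    parent_cell_id: int | None
    birth_frame: int
    division_frame: int | None = None
    fate: str = "censored"            # divided | lost | censored
    instants: list[tuple[int, int]] = field(default_factory=list)
    # instants: (frame, cell_instant_id)
    children: list[int] = field(default_factory=list)

    @property
    def generation(self) -> int:
        raise NotImplementedError  # computed by the forest (needs ancestry)


@dataclass
class LineageForest:
    nodes: dict[int, LineageNode] = field(default_factory=dict)

    def roots(self) -> list[LineageNode]:
        return [n for n in self.nodes.values() if n.parent_cell_id is None]

    def generation(self, cell_id: int) -> int:
        g = 0
        node = self.nodes[cell_id]
        while node.parent_cell_id is not None:
            node = self.nodes[node.parent_cell_id]
            g += 1
        return g

    def divisions(self) -> list[tuple[int, int, int]]:
        """(parent, child, division_frame) triples."""
        out = []
        for n in self.nodes.values():
            if n.fate == "divided":
                for ch in n.children:
                    out.append((n.cell_id, ch, self.nodes[ch].birth_frame))
        return out


@dataclass
class DivisionsTree:
    """Condensation of a lineage tree: one node per division event (+ root)."""

    graph: "object"                   # networkx.DiGraph
    root: int


class Tracker(Protocol):
    def track(self, cells_by_frame: list[list]) -> LineageForest: ...


class OverlapTracker:
    """Motion-compensated overlap tracker.

    Parameters mirror the division rule: a mother divides into the two
    best-overlapping daughters when their combined overlap is at least
    ``combined_frac`` of her area and each contributes ``each_frac``.
    """

    def __init__(self, combined_frac: float = 0.6, each_frac: float = 0.2):
        self.combined_frac = combined_frac
        self.each_frac = each_frac

    def track(self, cells_by_frame: list[list]) -> LineageForest:
        forest = LineageForest()
        next_cell_id = 1
        # active: maps index-in-current-frame -> cell_id
        active: dict[int, int] = {}
        prev_cells: list = []
        for f, cells in enumerate(cells_by_frame):
            if f == 0:
                for j, c in enumerate(cells):
                    node = LineageNode(cell_id=next_cell_id,
                                       colony_track_id=c.colony_id,
                                       parent_cell_id=None, birth_frame=f)
                    node.instants.append((f, c.cell_instant_id))
                    forest.nodes[next_cell_id] = node
                    active[j] = next_cell_id
                    next_cell_id += 1
                prev_cells = cells
                continue
            overlaps = _overlap_matrix(prev_cells, cells)
            new_active: dict[int, int] = {}
            # continuation: greedy best-overlap assignment (prev -> curr)
            order = np.argsort(-overlaps, axis=None)
            taken_prev: set[int] = set()
            taken_curr: set[int] = set()
            cont: dict[int, int] = {}
            n_prev, n_curr = overlaps.shape
            for flat in order:
                i, j = divmod(int(flat), n_curr)
                if overlaps[i, j] <= 0:
                    break
                if i in taken_prev or j in taken_curr:
                    continue
                cont[i] = j
                taken_prev.add(i)
                taken_curr.add(j)
            # attach leftover current cells to their best-overlap mother
            claims: dict[int, list[int]] = {}
            for j in range(n_curr):
                if j in taken_curr:
                    continue
                if n_prev:
                    i = int(np.argmax(overlaps[:, j]))
                    if overlaps[i, j] > 0:
                        claims.setdefault(i, []).append(j)
                        continue
                # no overlap with anything: new track (cell entering view)
                node = LineageNode(cell_id=next_cell_id,
                                   colony_track_id=cells[j].colony_id,
                                   parent_cell_id=None, birth_frame=f)
                node.instants.append((f, cells[j].cell_instant_id))
                forest.nodes[next_cell_id] = node
                new_active[j] = next_cell_id
                next_cell_id += 1
            for i in range(n_prev):
                cid = active.get(i)
                if cid is None:
                    continue
                node = forest.nodes[cid]
                j_cont = cont.get(i)
                extras = claims.get(i, [])
                area_i = prev_cells[i].area_px
                division = False
                if j_cont is not None and extras:
                    # candidate division: continuation + strongest extra
                    j2 = max(extras, key=lambda j: overlaps[i, j])
                    combined = overlaps[i, j_cont] + overlaps[i, j2]
                    if (combined >= self.combined_frac * area_i
                            and overlaps[i, j_cont] >= self.each_frac * area_i
                            and overlaps[i, j2] >= self.each_frac * area_i):
                        division = True
                        daughters = [j_cont, j2]
                if division:
                    node.fate = "divided"
                    node.division_frame = f
                    for j in daughters:
                        child = LineageNode(cell_id=next_cell_id,
                                            colony_track_id=cells[j].colony_id,
                                            parent_cell_id=cid, birth_frame=f)
                        child.instants.append((f, cells[j].cell_instant_id))
                        forest.nodes[next_cell_id] = child
                        node.children.append(next_cell_id)
                        new_active[j] = next_cell_id
                        next_cell_id += 1
                    extras = [j for j in extras if j not in daughters]
                elif j_cont is not None:
                    node.instants.append((f, cells[j_cont].cell_instant_id))
                    new_active[j_cont] = cid
                else:
                    node.fate = "lost"
                # unused extra claims become fresh tracks seeded by the mother
                for j in extras:
                    if j in new_active:
                        continue
                    child = LineageNode(cell_id=next_cell_id,
                                        colony_track_id=cells[j].colony_id,
                                        parent_cell_id=None, birth_frame=f)
                    child.instants.append((f, cells[j].cell_instant_id))
                    forest.nodes[next_cell_id] = child
                    new_active[j] = next_cell_id
                    next_cell_id += 1
            active = new_active
            prev_cells = cells
        return forest


def _overlap_matrix(prev_cells, curr_cells) -> np.ndarray:
    """Pixel-overlap counts after colony-drift compensation."""
    n_prev, n_curr = len(prev_cells), len(curr_cells)
    out = np.zeros((n_prev, n_curr))
    if n_prev == 0 or n_curr == 0:
        return out
    # per-colony centroid displacement (median over matched colony ids)
    shift: dict[int, np.ndarray] = {}
    for col in {c.colony_id for c in curr_cells}:
        p = [c.centroid for c in prev_cells if c.colony_id == col]
        q = [c.centroid for c in curr_cells if c.colony_id == col]
        if p and q:
            shift[col] = np.mean(q, axis=0) - np.mean(p, axis=0)
    curr_pixels = {}
    for j, c in enumerate(curr_cells):
        curr_pixels[j] = set(zip(c.rows.tolist(), c.cols.tolist()))
    for i, p in enumerate(prev_cells):
        dr, dc = shift.get(p.colony_id, np.zeros(2))
        rows = np.round(p.rows + dr).astype(int)
        cols = np.round(p.cols + dc).astype(int)
        mine = set(zip(rows.tolist(), cols.tolist()))
        for j, c in enumerate(curr_cells):
            if abs(p.centroid[0] + dr - c.centroid[0]) > 40 or \
               abs(p.centroid[1] + dc - c.centroid[1]) > 40:
                continue
            out[i, j] = len(mine & curr_pixels[j])
    return out


def track_cells(cells_by_frame: list[list],
                tracker: Tracker | None = None) -> LineageForest:
    """Build the lineage forest over per-frame SegmentedCell lists."""
    if tracker is None:
        tracker = OverlapTracker()
    return tracker.track(cells_by_frame)


def build_divisions_tree(forest: LineageForest,
                         boundary_flags: dict[int, bool] | None = None,
                         attributes: dict[int, dict] | None = None) -> list[DivisionsTree]:
    """Condense each lineage tree to its division events.

    Each cell's whole life span contracts to a single node: the root cell
    plus every cell born from a division (whose node *is* that division
    event — its birth frame equals the parent's division frame).  Node
    attributes carry any supplied life attributes, the generation index, and
    the on-colony-boundary glyph flag (triangular vs circular glyphs in
    external viewers).
    """
    import networkx as nx

    trees = []
    for root in forest.roots():
        g = nx.DiGraph()

        def add(node: LineageNode, parent: int | None):
            attrs = dict(attributes.get(node.cell_id, {})) if attributes else {}
            if boundary_flags is not None:
                attrs["on_colony_boundary"] = bool(
                    boundary_flags.get(node.cell_id, False))
            attrs["division_frame"] = node.division_frame
            attrs["fate"] = node.fate
            attrs["generation"] = forest.generation(node.cell_id)
            g.add_node(node.cell_id, **attrs)
            if parent is not None:
                g.add_edge(parent, node.cell_id)
            for ch in node.children:
                add(forest.nodes[ch], node.cell_id)

        add(root, None)
        trees.append(DivisionsTree(graph=g, root=root.cell_id))
    return trees


def export_graphml(trees: list[DivisionsTree] | LineageForest, path) -> None:
    """GraphML export for external tree viewers."""
    import networkx as nx

    if isinstance(trees, LineageForest):
        g = nx.DiGraph()
        for n in trees.nodes.values():
            g.add_node(n.cell_id, birth_frame=n.birth_frame, fate=n.fate,
                       colony_track_id=n.colony_track_id,
                       generation=trees.generation(n.cell_id))
            if n.parent_cell_id is not None:
                g.add_edge(n.parent_cell_id, n.cell_id)
    else:
        g = nx.DiGraph()
        for t in trees:
            g = nx.compose(g, t.graph)
    for _, data in g.nodes(data=True):
        for k, v in list(data.items()):
            if v is None:
                data[k] = ""
    nx.write_graphml(g, path)


def export_cell_table(forest: LineageForest, sampling_period: float = 1.0):
    """Flat parent-child table of whole cell lives."""
    import pandas as pd

    rows = []
    for n in sorted(forest.nodes.values(), key=lambda n: n.cell_id):
        rows.append({
            "cell_id": n.cell_id,
            "parent_cell_id": n.parent_cell_id,
            "colony_track_id": n.colony_track_id,
            "birth_frame": n.birth_frame + 1,       # 1-based in reports
            "division_frame": (n.division_frame + 1
                               if n.division_frame is not None else None),
            "fate": n.fate,
            "generation": forest.generation(n.cell_id),
            "n_instants": len(n.instants),
        })
    return pd.DataFrame(rows)
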