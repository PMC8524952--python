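"""Chemical-space tree maps from MinHash fingerprints.

A large fingerprint collection is visualized as the minimum spanning tree
of its approximate k-nearest-neighbor graph: an LSH forest over the
MinHash vectors answers approximate nearest-neighbor queries, the union of
per-molecule neighbor lists forms a weighted graph (edge weight =
1 - MinHash match fraction), the graph is reduced to its minimum spanning
tree (a forest when the graph is disconnected), and the tree is drawn in
the plane with a deterministic layout. Nodes can be colored by any
per-molecule channel (MW, Fsp3, AlogP, origin, category, ...).

The LSH forest follows the prefix-tree construction: each tree stores the
fingerprints under a random permutation of the MinHash coordinates in
lexicographically sorted order; a query descends to its would-be position
in each tree and collects the surrounding window as candidates, which are
then ranked by the exact MinHash match fraction.
"""

from __future__ import annotations

import dataclasses
from bisect import bisect_left
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .errors import DegenerateInputError, DimensionError, NotATreeError

DEFAULT_N_TREES = 32
DEFAULT_K_NEIGHBORS = 20


class LSHForest:
    """Prefix-sorted LSH forest over MinHash fingerprint vectors.

    Trees built from the same seed are nested: a forest with more trees
    reuses the first trees of a forest with fewer, so candidate sets (and
    hence recall against the exact oracle) can only grow with ``n_trees``.
    """

    def __init__(self, fingerprints, n_trees: int = DEFAULT_N_TREES,
                 seed: int = 0, prefix_length: int = 16):
        X = np.asarray(fingerprints)
        if X.ndim != 2:
            raise DimensionError("fingerprints must form an (n, d) array")
        if X.shape[0] < 2:
            raise DegenerateInputError("LSH forest needs >= 2 items")
        if n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        self.X = X
        self.n_items, self.d = X.shape
        self.n_trees = n_trees
        self.prefix_length = min(prefix_length, self.d)
        rng = np.random.default_rng(seed)
        self._perms = [rng.permutation(self.d)[: self.prefix_length]
                       for _ in range(n_trees)]
        self._trees = []
        for perm in self._perms:
            keys = [tuple(row) for row in X[:, perm]]
            order = sorted(range(self.n_items), key=keys.__getitem__)
            self._trees.append(([keys[i] for i in order], order))

    def _candidates(self, vector: np.ndarray, window: int) -> set[int]:
        cand: set[int] = set()
        for perm, (sorted_keys, order) in zip(self._perms, self._trees):
            key = tuple(vector[perm])
            pos = bisect_left(sorted_keys, key)
            lo = max(0, pos - window)
            hi = min(self.n_items, pos + window)
            cand.update(order[lo:hi])
        return cand

    def query(self, item_or_vector, k: int = 1, window: int | None = None):
        """Approximate k nearest neighbors by MinHash match fraction.

        ``item_or_vector`` is either an index into the indexed set (the
        item itself is then excluded from the result) or an external
        MinHash vector. Returns (indices, similarities), best first.
        """
        if np.isscalar(item_or_vector):
            idx = int(item_or_vector)
            vector = self.X[idx]
        else:
            idx = None
            vector = np.asarray(item_or_vector)
            if vector.shape != (self.d,):
                raise DimensionError(f"query vector must have length {self.d}")
        if window is None:
            window = max(2 * k, 8)
        cand = self._candidates(vector, window)
        if idx is not None:
            cand.discard(idx)
        if not cand:
            cand = set(range(self.n_items)) - ({idx} if idx is not None else set())
        cand = np.fromiter(cand, dtype=int, count=len(cand))
        sims = (self.X[cand] == vector).mean(axis=1)
        # sort by similarity desc, index asc for deterministic ties
        order = np.lexsort((cand, -sims))[:k]
        return cand[order], sims[order]


def build_lsh_forest(fingerprints, n_trees: int = DEFAULT_N_TREES,
                     seed: int = 0) -> LSHForest:
    return LSHForest(fingerprints, n_trees=n_trees, seed=seed)


def knn_graph(forest: LSHForest, k: int = DEFAULT_K_NEIGHBORS) -> nx.Graph:
    """Undirected approximate kNN graph; weight = 1 - match fraction.

    An edge (i, j) is present when j is among i's k approximate nearest
    neighbors or vice versa.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    g = nx.Graph()
    g.add_nodes_from(range(forest.n_items))
    for i in range(forest.n_items):
        nbrs, sims = forest.query(i, k=min(k, forest.n_items - 1))
        for j, s in zip(nbrs, sims):
            a, b = (i, int(j)) if i < j else (int(j), i)
            g.add_edge(a, b, weight=float(1.0 - s))
    return g


def minimum_spanning_tree(graph: nx.Graph) -> list[tuple[int, int, float]]:
    """Kruskal minimum spanning tree (forest for disconnected graphs).

    Edges are processed in (weight, i, j) order so equal-weight ties break
    deterministically. Returns edges as (i, j, weight) with i < j.
    """
    if graph.number_of_nodes() == 0:
        raise DegenerateInputError("empty graph")
    edges = sorted(
        (float(data.get("weight", 1.0)), min(u, v), max(u, v))
        for u, v, data in graph.edges(data=True)
    )
    uf = nx.utils.UnionFind(graph.nodes())
    tree = []
    for w, u, v in edges:
        if uf[u] != uf[v]:
            uf.union(u, v)
            tree.append((u, v, w))
    return tree


def layout_tree(edges, nodes=None) -> dict[int, tuple[float, float]]:
    """Deterministic 2D coordinates for a forest.

    Each connected component is laid out with the Kamada-Kawai algorithm
    (distance-preserving for trees, deterministic) and components are
    placed side by side with non-overlapping bounding boxes.
    """
    g = nx.Graph()
    if nodes is not None:
        g.add_nodes_from(nodes)
    g.add_weighted_edges_from(edges)
    if not nx.is_forest(g):
        raise NotATreeError("input graph contains a cycle")
    coords: dict[int, tuple[float, float]] = {}
    x_offset = 0.0
    gap = 1.0
    for comp in sorted(nx.connected_components(g), key=lambda c: min(c)):
        sub = g.subgraph(comp)
        if len(comp) == 1:
            pos = {next(iter(comp)): np.zeros(2)}
        else:
            # layout on hop counts; edge weights near 0 would collapse nodes
            pos = nx.kamada_kawai_layout(sub, weight=None)
        xs = np.array([p[0] for p in pos.values()])
        ys = np.array([p[1] for p in pos.values()])
        shift = x_offset - xs.min()
        for node, p in pos.items():
            coords[node] = (float(p[0] + shift), float(p[1] - ys.min()))
        x_offset += (xs.max() - xs.min()) + gap
    return coords


@dataclass
class ChemSpaceLayout:
    """Coordinates, tree and graph edges, and color channels of a map."""

    coordinates: dict[int, tuple[float, float]]
    mst_edges: list[tuple[int, int, float]]
    knn_edges: list[tuple[int, int, float]]
    color_channels: dict[str, list] = field(default_factory=dict)

    @property
    def n_items(self) -> int:
        return len(self.coordinates)


def build_layout(
    fingerprints,
    n_trees: int = DEFAULT_N_TREES,
    k: int = DEFAULT_K_NEIGHBORS,
    seed: int = 0,
    color_channels: dict[str, list] | None = None,
) -> ChemSpaceLayout:
    """LSH forest -> kNN graph -> minimum spanning tree -> 2D layout."""
    forest = build_lsh_forest(fingerprints, n_trees=n_trees, seed=seed)
    graph = knn_graph(forest, k=k)
    mst = minimum_spanning_tree(graph)
    coords = layout_tree(mst, nodes=graph.nodes())
    return ChemSpaceLayout(
        coordinates=coords,
        mst_edges=mst,
        knn_edges=sorted(
            (min(u, v), max(u, v), float(d["weight"]))
            for u, v, d in graph.edges(data=True)
        ),
        color_channels=dict(color_channels or {}),
    )


# ---------------------------------------------------------------------------
# Export / import
# ---------------------------------------------------------------------------

def export_layout(layout: ChemSpaceLayout, outdir, channels=None,
                  image_format: str = "png") -> dict[str, str]:
    """Write coordinates, edges, channel tables and one image per channel.

    Returns a name -> path mapping of everything written.
    """
    import pathlib

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    channels = list(channels if channels is not None else layout.color_channels)
    missing = [c for c in channels if c not in layout.color_channels]
    if missing:
        raise KeyError(f"missing channel values: {missing}")
    for c in channels:
        if len(layout.color_channels[c]) != layout.n_items:
            raise ValueError(f"channel {c!r} does not cover every molecule")

    nodes = sorted(layout.coordinates)
    coord_df = pd.DataFrame(
        {
            "node": nodes,
            "x": [layout.coordinates[n][0] for n in nodes],
            "y": [layout.coordinates[n][1] for n in nodes],
            **{c: list(layout.color_channels[c]) for c in channels},
        }
    )
    mst_set = {(u, v) for u, v, _ in layout.mst_edges}
    edge_df = pd.DataFrame(
        [(u, v, w, (u, v) in mst_set) for u, v, w in layout.knn_edges],
        columns=["i", "j", "weight", "in_mst"],
    )
    written = {}
    coord_path = outdir / "coordinates.csv"
    edge_path = outdir / "edges.csv"
    # %.17g guarantees exact float round-trip through the CSV
    coord_df.to_csv(coord_path, index=False, float_format="%.17g")
    edge_df.to_csv(edge_path, index=False, float_format="%.17g")
    written["coordinates"] = str(coord_path)
    written["edges"] = str(edge_path)
    for c in channels:
        img = outdir / f"map_{c}.{image_format}"
        _plot_channel(layout, c, img)
        written[f"image_{c}"] = str(img)
    return written


def import_layout(outdir) -> ChemSpaceLayout:
    """Re-read an exported layout (coordinates, edges, channels)."""
    import pathlib

    outdir = pathlib.Path(outdir)
    coord_df = pd.read_csv(outdir / "coordinates.csv", float_precision="round_trip")
    edge_df = pd.read_csv(outdir / "edges.csv", float_precision="round_trip")
    coords = {int(r.node): (float(r.x), float(r.y)) for r in coord_df.itertuples()}
    knn = sorted((int(r.i), int(r.j), float(r.weight)) for r in edge_df.itertuples())
    # restore the Kruskal emission order (ascending weight, then i, j)
    mst = sorted(
        ((int(r.i), int(r.j), float(r.weight))
         for r in edge_df.itertuples() if r.in_mst),
        key=lambda e: (e[2], e[0], e[1]),
    )
    channels = {
        c: coord_df[c].tolist()
        for c in coord_df.columns
        if c not in ("node", "x", "y")
    }
    return ChemSpaceLayout(coordinates=coords, mst_edges=mst,
                           knn_edges=knn, color_channels=channels)


def _plot_channel(layout: ChemSpaceLayout, channel: str, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    nodes = sorted(layout.coordinates)
    xs = [layout.coordinates[n][0] for n in nodes]
    ys = [layout.coordinates[n][1] for n in nodes]
    values = layout.color_channels[channel]
    fig, ax = plt.subplots(figsize=(7, 6))
    for u, v, _ in layout.mst_edges:
        ax.plot(
            [layout.coordinates[u][0], layout.coordinates[v][0]],
            [layout.coordinates[u][1], layout.coordinates[v][1]],
            color="0.8", linewidth=0.5, zorder=1,
        )
    if all(isinstance(v, (int, float, np.integer, np.floating)) for v in values):
        sc = ax.scatter(xs, ys, c=values, s=12, cmap="viridis", zorder=2)
        fig.colorbar(sc, ax=ax, label=channel)
    else:
        cats = sorted(set(values))
        cmap = matplotlib.colormaps["tab10"]
        for ci, cat in enumerate(cats):
            pts = [(x, y) for x, y, v in zip(xs, ys, values) if v == cat]
            if pts:
                px, py = zip(*pts)
                ax.scatter(px, py, color=cmap(ci % 10), s=12, label=str(cat), zorder=2)
        ax.legend(markerscale=2, fontsize=8)
    ax.set_title(f"chemical space map — {channel}")
    ax.set_xticks([])
    ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
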