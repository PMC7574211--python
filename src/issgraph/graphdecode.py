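"""Graph-based decoding of signal candidates into barcode reads.

Every signal candidate becomes a split *D node*: an in/out node pair joined
by an edge whose cost is the negative log of the candidate's signal
probability, so using an unlikely detection is expensive.  Candidates of
different sequencing cycles are linked when they are spatially close, with an
edge cost that grows with distance,

    w_i  = -log(p_i)                (node cost)
    w_ij = -log(1 / (1 + k d_ij))   (inter-cycle edge cost)

where ``d_ij`` is the Euclidean pixel distance and ``k`` modulates its
contribution.  Connected components are formed within a direct-connection
distance ``d_th``; inside each component, extra "forced" edges are added
between unconnected candidates of consecutive cycles closer than ``d_max``;
edges between non-consecutive cycles are then removed; and a source/sink are
attached to the first/last cycle.  Solving the resulting network by maximum
flow of minimum cost yields node-disjoint paths, one per rolony, whose
channel letters in cycle order are the decoded barcodes.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .spots import SignalCandidate

UNEXPECTED = "UNEXPECTED"

PROBABILITY_FLOOR = 1e-6  # clamp before -log to avoid infinite node cost


@dataclass
class Codebook:
    """Mapping from gene names to fixed-length barcodes over {A,C,G,T}."""

    entries: dict

    def __post_init__(self):
        if not self.entries:
            self.entries = {}
            return
        lengths = {len(b) for b in self.entries.values()}
        if len(lengths) > 1:
            raise ValueError("all barcodes must have the same length")
        if any(set(b) - set("ACGT") for b in self.entries.values()):
            raise ValueError("barcodes must be over the alphabet {A,C,G,T}")
        if len(set(self.entries.values())) != len(self.entries):
            raise ValueError("barcodes must be unique")

    @property
    def barcode_length(self) -> int:
        return len(next(iter(self.entries.values()))) if self.entries else 0

    @property
    def genes(self):
        return list(self.entries)

    def gene_for(self, barcode: str) -> str:
        """Exact codebook match, else :data:`UNEXPECTED`."""
        for gene, bc in self.entries.items():
            if bc == barcode:
                return gene
        return UNEXPECTED

    @classmethod
    def from_csv(cls, path) -> "Codebook":
        df = pd.read_csv(path)
        return cls(dict(zip(df["gene"].astype(str), df["barcode"].astype(str))))

    def to_csv(self, path) -> None:
        pd.DataFrame({"gene": list(self.entries),
                      "barcode": list(self.entries.values())}).to_csv(
            path, index=False)


@dataclass
class DecodedRead:
    """One decoded barcode call: a path of one detection per cycle."""

    path: list                      # SignalCandidate per cycle, cycle order
    barcode: str
    x: float
    y: float
    gene: str
    max_pair_distance: float
    quality: float | None = None            # Q_s in [0, n_cycles]
    per_base_quality: list | None = None    # Q_sb per cycle


@dataclass
class DetectionGraph:
    """Pruned split-node flow graph over signal candidates."""

    candidates: dict                # id -> SignalCandidate
    edges: list                     # (id_i, id_j, weight, kind) with cycle_i < cycle_j
    components: list                # lists of candidate ids
    k: float
    d_th: float
    d_max: float
    n_cycles: int

    @property
    def n_candidates(self) -> int:
        return len(self.candidates)

    def node_weight(self, cand_id: int) -> float:
        p = min(max(self.candidates[cand_id].probability, PROBABILITY_FLOOR), 1.0)
        return -math.log(p)


def edge_weight(d: float, k: float) -> float:
    """Inter-cycle edge cost ``-log(1/(1 + k d))`` for distance ``d``."""
    return math.log1p(k * d)


def build_graph(candidates, k: float = 1.0, d_th: float = 2.0,
                d_max: float = 3.0, n_cycles: int | None = None,
                ) -> DetectionGraph:
    """Build the pruned detection graph.

    Steps, in order: (1) connected components over links between candidates
    of *different* cycles within ``d_th``; (2) within each component, forced
    edges between unconnected candidates of *consecutive* cycles closer than
    ``d_max``; (3) removal of edges between non-consecutive cycles.  Source
    and sink attachment happens at solve time.
    """
    if not (d_max >= d_th > 0):
        raise ValueError("require d_max >= d_th > 0")
    if k <= 0:
        raise ValueError("k must be > 0")
    cands = sorted(candidates, key=lambda c: c.id)
    if n_cycles is None:
        n_cycles = max((c.cycle for c in cands), default=0)
    for c in cands:
        if c.probability is None or not (0 < c.probability <= 1):
            raise ValueError(
                f"candidate {c.id} has probability {c.probability!r}; "
                "expected a value in (0, 1]")
    if not cands:
        return DetectionGraph({}, [], [], k, d_th, d_max, n_cycles)

    ids = [c.id for c in cands]
    index = {cid: i for i, cid in enumerate(ids)}
    pos = np.array([[c.x, c.y] for c in cands])
    cyc = np.array([c.cycle for c in cands])

    # (1) direct links within d_th between different cycles -> components
    tree = cKDTree(pos)
    pairs = sorted(tree.query_pairs(d_th))
    parent = list(range(len(cands)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    direct = set()
    for i, j in pairs:
        if cyc[i] == cyc[j]:
            continue
        direct.add((i, j))
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    comp_members: dict = {}
    for i in range(len(cands)):
        comp_members.setdefault(find(i), []).append(i)
    components = sorted(comp_members.values(), key=lambda m: m[0])

    # (2) forced edges within components, consecutive cycles, d < d_max
    # (3) keep only consecutive-cycle edges
    edges = []
    for members in components:
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                i, j = members[a], members[b]
                if abs(int(cyc[i]) - int(cyc[j])) != 1:
                    continue
                lo, hi = (i, j) if cyc[i] < cyc[j] else (j, i)
                d = float(np.linalg.norm(pos[lo] - pos[hi]))
                key = (min(i, j), max(i, j))
                if key in direct:
                    edges.append((ids[lo], ids[hi], edge_weight(d, k), "direct"))
                elif d < d_max:
                    edges.append((ids[lo], ids[hi], edge_weight(d, k), "forced"))

    return DetectionGraph(
        candidates={c.id: c for c in cands},
        edges=sorted(edges, key=lambda e: (e[0], e[1])),
        components=[[ids[i] for i in m] for m in components],
        k=k, d_th=d_th, d_max=d_max, n_cycles=n_cycles)


# ---------------------------------------------------------------------------
# min-cost max-flow: successive shortest augmenting paths (unit capacities)
# ---------------------------------------------------------------------------

class _FlowNet:
    """Residual network with Dijkstra-based successive shortest paths.

    All costs are non-negative, so Johnson potentials start at zero and each
    augmentation is a plain Dijkstra on reduced costs.  Exact cost ties are
    broken toward the lexicographically smallest candidate-id sequence.
    """

    def __init__(self):
        self.adj: dict = {}
        self.edges = []  # [to, cap, cost, flow]

    def add_node(self, u):
        self.adj.setdefault(u, [])

    def add_edge(self, u, v, cap, cost):
        self.add_node(u)
        self.add_node(v)
        self.adj[u].append(len(self.edges))
        self.edges.append([v, cap, cost, 0])
        self.adj[v].append(len(self.edges))
        self.edges.append([u, 0, -cost, 0])

    def _shortest_path(self, s, t, pot):
        dist = {u: math.inf for u in self.adj}
        seq = {u: () for u in self.adj}      # id sequence for tie-breaking
        prev_edge: dict = {}
        dist[s] = 0.0
        order = {u: i for i, u in enumerate(self.adj)}
        heap = [(0.0, (), order[s], s)]
        done = set()
        while heap:
            d, sq, _, u = heapq.heappop(heap)
            if u in done:
                continue
            done.add(u)
            for ei in self.adj[u]:
                v, cap, cost, flow = self.edges[ei]
                if cap - flow <= 0 or v in done:
                    continue
                nd = d + cost + pot[u] - pot[v]
                # tie-break sequences carry candidate ids only
                nsq = sq + (v[0],) if isinstance(v, tuple) else sq
                if nd < dist[v] - 1e-15 or (
                        abs(nd - dist[v]) <= 1e-15 and nsq < seq[v]):
                    dist[v] = nd
                    seq[v] = nsq
                    prev_edge[v] = ei
                    heapq.heappush(heap, (nd, nsq, order[v], v))
        return dist, prev_edge

    def solve(self, s, t):
        self.add_node(s)
        self.add_node(t)
        pot = {u: 0.0 for u in self.adj}
        flow_value, total_cost = 0, 0.0
        while True:
            dist, prev_edge = self._shortest_path(s, t, pot)
            if not math.isfinite(dist[t]):
                break
            for u in self.adj:
                if math.isfinite(dist[u]):
                    pot[u] += dist[u]
            # augment one unit along s -> t
            v = t
            while v != s:
                ei = prev_edge[v]
                self.edges[ei][3] += 1
                self.edges[ei ^ 1][3] -= 1
                total_cost += self.edges[ei][2]
                v = self.edges[ei ^ 1][0]
            flow_value += 1
        return flow_value, total_cost

    def unit_paths(self, s, t):
        """Decompose the integral flow into source->sink node paths."""
        paths = []
        for ei in self.adj[s]:
            if self.edges[ei][3] <= 0:
                continue
            path, u = [], self.edges[ei][0]
            while u != t:
                path.append(u)
                for ej in self.adj[u]:
                    if self.edges[ej][3] > 0:
                        self.edges[ej][3] -= 1
                        u = self.edges[ej][0]
                        break
                else:  # pragma: no cover - flow conservation guarantees exit
                    raise RuntimeError("flow decomposition failed")
            paths.append(path)
        return paths


def solve(graph: DetectionGraph, return_cost: bool = False):
    """Decode candidate paths by maximum flow of minimum cost.

    Every detection and every inter-cycle edge has unit capacity, so the
    maximum flow equals the largest number of node-disjoint source-to-sink
    paths and, among all maximum flows, the one with minimal total cost
    (sum of node and edge weights along used paths) is returned.  Components
    that do not span all cycles yield no paths.

    Returns a list of candidate paths (each one :class:`SignalCandidate` per
    cycle, in cycle order); with ``return_cost=True`` also returns
    ``(flow_value, total_cost)`` summed over components.
    """
    all_paths = []
    flow_value, total_cost = 0, 0.0
    edges_by_comp: dict = {}
    comp_of = {}
    for ci, members in enumerate(graph.components):
        for cid in members:
            comp_of[cid] = ci
    for e in graph.edges:
        edges_by_comp.setdefault(comp_of[e[0]], []).append(e)

    for ci, members in enumerate(graph.components):
        cycles_present = {graph.candidates[cid].cycle for cid in members}
        if len(cycles_present) < graph.n_cycles:
            continue
        net = _FlowNet()
        source, sink = "S", "T"
        for cid in sorted(members):
            cand = graph.candidates[cid]
            net.add_edge((cid, "in"), (cid, "out"), 1, graph.node_weight(cid))
            if cand.cycle == 1:
                net.add_edge(source, (cid, "in"), 1, 0.0)
            if cand.cycle == graph.n_cycles:
                net.add_edge((cid, "out"), sink, 1, 0.0)
        for i, j, w, _kind in edges_by_comp.get(ci, []):
            net.add_edge((i, "out"), (j, "in"), 1, w)
        fv, cost = net.solve(source, sink)
        flow_value += fv
        total_cost += cost
        for node_path in net.unit_paths(source, sink):
            cand_ids = [u[0] for u in node_path if u[1] == "in"]
            path = sorted((graph.candidates[cid] for cid in cand_ids),
                          key=lambda c: c.cycle)
            all_paths.append(path)

    if return_cost:
        return all_paths, (flow_value, total_cost)
    return all_paths


def decode(paths, codebook: Codebook) -> list:
    """Turn candidate paths into :class:`DecodedRead` records.

    Barcode = channel letters in cycle order; position = centroid of the
    path's detections; unmatched barcodes are kept with gene
    :data:`UNEXPECTED` (they serve as negatives for quality calibration).
    """
    n = codebook.barcode_length
    reads = []
    for path in paths:
        cycles = [c.cycle for c in path]
        if cycles != list(range(1, len(path) + 1)):
            raise ValueError(f"path must have one candidate per cycle, got "
                             f"cycles {cycles}")
        if n and len(path) != n:
            raise ValueError(
                f"path length {len(path)} != barcode length {n}")
        barcode = "".join(c.channel for c in path)
        pos = np.array([[c.x, c.y] for c in path])
        dmax = 0.0
        for a in range(len(path)):
            for b in range(a + 1, len(path)):
                dmax = max(dmax, float(np.linalg.norm(pos[a] - pos[b])))
        reads.append(DecodedRead(
            path=list(path), barcode=barcode,
            x=float(pos[:, 0].mean()), y=float(pos[:, 1].mean()),
            gene=codebook.gene_for(barcode), max_pair_distance=dmax))
    return reads


def reads_to_frame(reads, tile_origin=(0, 0)) -> pd.DataFrame:
    """Tabulate reads with global coordinates (tile origin is (row, col))."""
    return pd.DataFrame(
        [{"x": r.x + tile_origin[1], "y": r.y + tile_origin[0],
          "barcode": r.barcode, "gene": r.gene, "quality": r.quality,
          "per_base_quality": None if r.per_base_quality is None else
          ";".join(f"{q:.6g}" for q in r.per_base_quality),
          "max_pair_distance": r.max_pair_distance}
         for r in reads])
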