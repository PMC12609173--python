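"""ROI-level causal network: construction, degrees, hubs, modularity, decoding.

The ROI-to-ROI network applies the same signed-path-coefficient Granger
causality (GC) used voxel-wise to every ordered pair of region series,
retaining edges with |GC| above the analysis threshold. Node roles are
classified from the binary out−in degree (sources project, targets
receive); community structure is found by maximizing the directed
weighted (Leicht–Newman) modularity

    Q = (1/m) * sum_ij [A_ij − s_i_out * s_j_in / m] * delta(c_i, c_j)

with A the |GC| weights, m the total weight and s the weighted out/in
strengths. Behavioural-domain decoding is a one-sided binomial enrichment
of activation counts against database base rates, FDR-corrected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .config import AnalysisConfig
from .cascn import signed_gc_pair


@dataclass
class CausalGraph:
    """Signed, directed, weighted adjacency over named ROIs.

    ``adjacency[(i, j)]`` holds the signed GC of the retained edge
    i → j; absent pairs failed the |GC| threshold. No self-edges.
    """

    nodes: list
    adjacency: dict = field(default_factory=dict)
    threshold: float = 0.20

    def __post_init__(self) -> None:
        for (i, j), gc in self.adjacency.items():
            if i == j:
                raise ValueError("self-edges are not allowed")
            if abs(gc) <= self.threshold:
                raise ValueError(f"edge ({i},{j}) below threshold")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.adjacency)

    def weight_matrix(self, absolute: bool = True) -> np.ndarray:
        """Dense adjacency; |GC| weights by default (null model needs >= 0)."""
        idx = {n: i for i, n in enumerate(self.nodes)}
        W = np.zeros((self.n_nodes, self.n_nodes))
        for (i, j), gc in self.adjacency.items():
            W[idx[i], idx[j]] = abs(gc) if absolute else gc
        return W

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for (i, j), gc in self.adjacency.items():
            g.add_edge(i, j, gc=gc, weight=abs(gc), sign=int(np.sign(gc)))
        return g

    def edge_frame(self) -> pd.DataFrame:
        rows = [dict(source=i, target=j, gc=gc, sign=int(np.sign(gc)))
                for (i, j), gc in sorted(self.adjacency.items())]
        return pd.DataFrame(rows, columns=["source", "target", "gc", "sign"])


@dataclass
class ModularPartition:
    membership: dict            # node -> module id (0-based, contiguous)
    q: float
    method: str = ""
    seed: Optional[int] = None

    @property
    def n_modules(self) -> int:
        return len(set(self.membership.values()))

    def modules(self) -> list:
        out: dict = {}
        for node, m in self.membership.items():
            out.setdefault(m, []).append(node)
        return [sorted(v) for _, v in sorted(out.items())]


def roi_gc_matrix(roi_series: np.ndarray, names: Optional[Sequence[str]] = None,
                  config: Optional[AnalysisConfig] = None) -> CausalGraph:
    """Signed GC for every ordered ROI pair; keep edges with |GC| > threshold."""
    cfg = config or AnalysisConfig()
    S = np.asarray(roi_series, dtype=float)
    if S.ndim != 2 or S.shape[1] < 2:
        raise ValueError("need a T × R matrix with at least 2 ROIs")
    if S.shape[0] < 10:
        raise ValueError("need at least 10 pseudo-time points")
    R = S.shape[1]
    names = list(names) if names is not None else [f"roi{i}" for i in range(R)]
    if len(names) != R:
        raise ValueError("names length must match ROI count")
    adj = {}
    for i in range(R):
        for j in range(R):
            if i == j:
                continue
            gc = signed_gc_pair(S[:, i], S[:, j], order=cfg.gc_order)
            if abs(gc) > cfg.gc_threshold:
                adj[(names[i], names[j])] = gc
    return CausalGraph(nodes=names, adjacency=adj, threshold=cfg.gc_threshold)


def degree_metrics(graph: CausalGraph) -> pd.DataFrame:
    """Binary and weighted in/out degrees and out−in differences per node.

    Weighted degrees sum |GC| over retained edges (signs are kept on the
    edge list for reporting, not in the strengths).
    """
    rows = {n: dict(node=n, out_bin=0, in_bin=0, out_w=0.0, in_w=0.0)
            for n in graph.nodes}
    for (i, j), gc in graph.adjacency.items():
        rows[i]["out_bin"] += 1
        rows[j]["in_bin"] += 1
        rows[i]["out_w"] += abs(gc)
        rows[j]["in_w"] += abs(gc)
    df = pd.DataFrame([rows[n] for n in graph.nodes]).set_index("node")
    df["out_in_bin"] = df["out_bin"] - df["in_bin"]
    df["out_in_w"] = df["out_w"] - df["in_w"]
    return df


def classify_hubs(degrees: pd.DataFrame) -> pd.Series:
    """source / target / balanced by the sign of the binary out−in degree."""
    diff = degrees["out_in_bin"]
    return pd.Series(np.where(diff > 0, "source",
                              np.where(diff < 0, "target", "balanced")),
                     index=degrees.index, name="role")


def modularity_q(graph: CausalGraph, membership: dict) -> float:
    """Directed weighted modularity of a partition (|GC| weights)."""
    W = graph.weight_matrix()
    m = W.sum()
    if m == 0:
        raise ValueError("graph has no edges")
    s_out = W.sum(axis=1)
    s_in = W.sum(axis=0)
    comm = np.array([membership[n] for n in graph.nodes])
    same = comm[:, None] == comm[None, :]
    return float(((W - np.outer(s_out, s_in) / m) * same).sum() / m)


def _set_partitions(n: int):
    """All set partitions of range(n) as membership arrays (restricted growth)."""
    a = [0] * n
    while True:
        yield list(a)
        for i in range(n - 1, 0, -1):
            if a[i] <= max(a[:i]):     # can grow without skipping a label
                a[i] += 1
                for j in range(i + 1, n):
                    a[j] = 0
                break
        else:
            return


def _exhaustive_partition(graph: CausalGraph):
    best_q, best = -np.inf, None
    nodes = graph.nodes
    for memb in _set_partitions(len(nodes)):
        q = modularity_q(graph, dict(zip(nodes, memb)))
        if q > best_q + 1e-12:
            best_q, best = q, memb
    return dict(zip(nodes, (int(x) for x in best))), best_q


def _greedy_partition(graph: CausalGraph, seed: int):
    """Agglomerative merging followed by single-node move refinement."""
    nodes = graph.nodes
    memb = {n: i for i, n in enumerate(nodes)}
    q = modularity_q(graph, memb)
    improved = True
    while improved:
        improved = False
        mods = sorted(set(memb.values()))
        best_gain, best_pair = 1e-12, None
        for m1, m2 in combinations(mods, 2):
            trial = {n: (m1 if c == m2 else c) for n, c in memb.items()}
            gain = modularity_q(graph, trial) - q
            if gain > best_gain:
                best_gain, best_pair = gain, (m1, m2)
        if best_pair:
            m1, m2 = best_pair
            memb = {n: (m1 if c == m2 else c) for n, c in memb.items()}
            q += best_gain
            improved = True
    # pairwise-move refinement: move single nodes to neighbouring modules
    rng = np.random.default_rng(seed)
    order = list(nodes)
    improved = True
    while improved:
        improved = False
        rng.shuffle(order)
        for n in order:
            current = memb[n]
            for target in sorted(set(memb.values()) | {max(memb.values()) + 1}):
                if target == current:
                    continue
                trial = dict(memb)
                trial[n] = target
                gain = modularity_q(graph, trial) - q
                if gain > 1e-12:
                    memb, q = trial, q + gain
                    improved = True
                    break
    return memb, q


def newman_modularity(graph: CausalGraph, seed: int = 0) -> ModularPartition:
    """Maximize directed weighted modularity.

    Exhaustive search over set partitions for graphs with <= 10 nodes
    (globally optimal); greedy agglomeration with single-node move
    refinement above that, deterministic for a fixed seed.
    """
    if graph.n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    if graph.n_edges == 0:
        raise ValueError("graph has no edges")
    if graph.n_nodes <= 10:
        memb, q = _exhaustive_partition(graph)
        method = "exhaustive"
    else:
        memb, q = _greedy_partition(graph, seed)
        method = "greedy+moves"
    # relabel modules contiguously in node order
    relabel, out = {}, {}
    for n in graph.nodes:
        m = memb[n]
        relabel.setdefault(m, len(relabel))
        out[n] = relabel[m]
    return ModularPartition(membership=out, q=float(q), method=method, seed=seed)


def forward_inference_decoding(domain_table: pd.DataFrame,
                               alpha: float = 0.05) -> pd.DataFrame:
    """Binomial forward-inference enrichment of behavioural domains.

    ``domain_table`` needs columns ``domain``, ``k`` (in-module activation
    count), ``n`` (module total) and ``p`` (database base rate). Returns
    the table with one-sided binomial tail p-values P(X >= k | n, p),
    Benjamini–Hochberg q-values and an ``enriched`` flag (q < alpha).
    """
    t = domain_table.copy()
    for col in ("domain", "k", "n", "p"):
        if col not in t.columns:
            raise ValueError(f"domain table missing column {col!r}")
    if ((t["p"] <= 0) | (t["p"] >= 1)).any():
        raise ValueError("base rates must lie strictly in (0, 1)")
    if ((t["k"] < 0) | (t["k"] > t["n"])).any():
        raise ValueError("need 0 <= k <= n")
    t["p_value"] = stats.binom.sf(t["k"] - 1, t["n"], t["p"])
    t["q"] = stats.false_discovery_control(t["p_value"], method="bh")
    t["enriched"] = t["q"] < alpha
    return t


def adjusted_rand_index(labels_a: Sequence, labels_b: Sequence) -> float:
    """Adjusted Rand index between two labelings of the same items."""
    a = pd.factorize(pd.Series(list(labels_a)))[0]
    b = pd.factorize(pd.Series(list(labels_b)))[0]
    n = len(a)
    ct = np.zeros((a.max() + 1, b.max() + 1))
    for i, j in zip(a, b):
        ct[i, j] += 1

    def comb2(x):
        return x * (x - 1) / 2.0

    sum_ij = comb2(ct).sum()
    sum_a = comb2(ct.sum(axis=1)).sum()
    sum_b = comb2(ct.sum(axis=0)).sum()
    expected = sum_a * sum_b / comb2(n)
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))
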