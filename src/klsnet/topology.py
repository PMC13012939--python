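"""Binary graph construction across sparsity thresholds and graph metrics.

Similarity matrices are thresholded to fixed edge counts (sparsity), then
profiled with global metrics (clustering, path length, efficiencies,
null-normalized small-world indices) and nodal metrics (degree, betweenness,
nodal efficiency, nodal local efficiency), summarized by the area under each
metric-vs-sparsity curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .atlases import AAL116, DK68
from .network import SimilarityMatrix

#: null-model ensemble size used in the full-scale analysis
DEFAULT_N_NULLS = 1000

GLOBAL_METRICS = ("Cp", "Lp", "Eg", "Eloc", "gamma", "lambda", "sigma")
NODAL_METRICS = ("degree", "bc", "ne", "nle")


@dataclass
class BinaryGraph:
    """Undirected binary graph with labelled nodes."""

    labels: tuple[str, ...]
    adjacency: np.ndarray
    sparsity: float = float("nan")

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        n = len(self.labels)
        if a.shape != (n, n):
            raise ValueError("adjacency shape does not match labels")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency diagonal must be zero")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency must be binary")
        self.labels = tuple(self.labels)
        self.adjacency = a.astype(np.uint8)

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum() // 2)

    def to_networkx(self) -> nx.Graph:
        g = nx.from_numpy_array(self.adjacency)
        return nx.relabel_nodes(g, dict(enumerate(self.labels)))


def sparsity_grid(atlas: str) -> np.ndarray:
    """Sparsity thresholds: 0.05..0.30 step 0.01 for the 116-node atlas,
    starting at 0.07 for the 68-node atlas (connectedness)."""
    start = {AAL116: 5, DK68: 7}[atlas]
    return np.round(np.arange(start, 31) / 100.0, 2)


def binarize_at_sparsity(mat: SimilarityMatrix, s: float) -> BinaryGraph:
    """Keep the k = round(s * N(N-1)/2) largest off-diagonal weights as
    edges; weight ties broken by ascending lexicographic node-pair order."""
    if not 0 < s <= 1:
        raise ValueError(f"sparsity must be in (0, 1], got {s}")
    n = mat.n_nodes
    n_pairs = n * (n - 1) // 2
    k = int(np.floor(s * n_pairs + 0.5))
    iu, ju = np.triu_indices(n, k=1)
    w = mat.values[iu, ju]
    # stable sort on -weight keeps ascending (i, j) order among ties
    order = np.argsort(-w, kind="stable")
    adj = np.zeros((n, n), dtype=np.uint8)
    if k == 0:
        warnings.warn(f"sparsity {s} yields an empty graph on {n} nodes")
    else:
        keep = order[:k]
        adj[iu[keep], ju[keep]] = 1
        adj |= adj.T
    return BinaryGraph(labels=mat.labels, adjacency=adj, sparsity=s)


def _distances(adj: np.ndarray) -> np.ndarray:
    """All-pairs shortest path lengths of a binary graph (inf when
    disconnected), via breadth-first levels of boolean matrix products."""
    n = adj.shape[0]
    a = adj.astype(np.uint8)
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    reached = np.eye(n, dtype=bool)
    current = np.eye(n, dtype=bool)
    k = 1
    while True:
        newly = ((current.astype(np.uint8) @ a) > 0) & ~reached
        if not newly.any():
            break
        dist[newly] = k
        reached |= newly
        current = newly
        k += 1
    return dist


def _clustering_coeffs(adj: np.ndarray) -> np.ndarray:
    """Watts-Strogatz local clustering per node (0 for degree < 2)."""
    deg = adj.sum(axis=1).astype(float)
    a = adj.astype(float)
    triangles = np.diag(a @ a @ a) / 2.0
    denom = deg * (deg - 1) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, triangles / denom, 0.0)
    return c


def _global_efficiency(adj: np.ndarray) -> float:
    n = adj.shape[0]
    if n < 2:
        return 0.0
    d = _distances(adj)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def _cp_lp(adj: np.ndarray) -> dict[str, float]:
    """Clustering coefficient and path length only (null-model hot path)."""
    n = adj.shape[0]
    cp = float(_clustering_coeffs(adj).mean())
    d = _distances(adj)
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(d) & off
    lp = float(d[finite].mean()) if finite.any() else float("nan")
    return {"Cp": cp, "Lp": lp}


def _local_efficiencies(adj: np.ndarray) -> np.ndarray:
    """Global efficiency of each node's neighbor-induced subgraph."""
    n = adj.shape[0]
    nle = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(adj[i])
        if nbrs.size >= 2:
            nle[i] = _global_efficiency(adj[np.ix_(nbrs, nbrs)])
    return nle


def _betweenness(adj: np.ndarray) -> np.ndarray:
    """Normalized shortest-path betweenness (Brandes)."""
    n = adj.shape[0]
    try:
        import igraph as ig

        g = ig.Graph.Adjacency(adj.astype(bool).tolist(), mode="undirected")
        bc = np.asarray(g.betweenness(), dtype=float)
    except ImportError:  # pragma: no cover - igraph is normally present
        bc_map = nx.betweenness_centrality(
            nx.from_numpy_array(adj), normalized=False
        )
        bc = np.array([bc_map[i] for i in range(n)])
    return bc / ((n - 1) * (n - 2) / 2.0)


def _all_metrics(adj: np.ndarray) -> tuple[dict[str, float], dict[str, np.ndarray]]:
    """Global and nodal metrics from one distance computation."""
    n = adj.shape[0]
    cp_nodes = _clustering_coeffs(adj)
    d = _distances(adj)
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(d) & off
    lp = float(d[finite].mean()) if finite.any() else float("nan")
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    ne = inv.sum(axis=1) / (n - 1)
    nle = _local_efficiencies(adj)
    glob = {
        "Cp": float(cp_nodes.mean()),
        "Lp": lp,
        "Eg": float(ne.mean()),
        "Eloc": float(nle.mean()),
        "connected": bool(finite.sum() == off.sum()),
    }
    nodal = {
        "degree": adj.sum(axis=1).astype(float),
        "bc": _betweenness(adj),
        "ne": ne,
        "nle": nle,
    }
    return glob, nodal


def global_metrics(g: BinaryGraph) -> dict[str, float]:
    """Cp, Lp (connected pairs only), Eg, Eloc plus the connectedness flag."""
    if g.n_nodes < 3:
        raise ValueError("global metrics require >= 3 nodes")
    glob, _ = _all_metrics(g.adjacency)
    return glob


def nodal_metrics(g: BinaryGraph) -> pd.DataFrame:
    """Per-node degree, normalized betweenness, nodal efficiency and nodal
    local efficiency, indexed by node label."""
    if g.n_nodes < 3:
        raise ValueError("nodal metrics require >= 3 nodes")
    _, nodal = _all_metrics(g.adjacency)
    return pd.DataFrame(nodal, index=pd.Index(g.labels, name="roi"))


def random_null_ensemble(
    g: BinaryGraph, n_nulls: int, seed: int
) -> list[BinaryGraph]:
    """Degree-preserving rewired ensemble (Maslov-Sneppen double edge
    swaps); every null keeps the exact degree sequence."""
    if n_nulls < 1:
        raise ValueError("n_nulls must be >= 1")
    if g.n_edges < 2:
        warnings.warn("graph has < 2 edges; null ensemble is copies of the input")
        return [BinaryGraph(g.labels, g.adjacency.copy(), g.sparsity) for _ in range(n_nulls)]
    seeds = np.random.SeedSequence(seed).spawn(n_nulls)
    nulls = []
    for ss in seeds:
        rng = np.random.default_rng(ss)
        adj = _rewire(g.adjacency, rng, 10 * g.n_edges)
        nulls.append(BinaryGraph(g.labels, adj, g.sparsity))
    return nulls


def _rewire(adj: np.ndarray, rng: np.random.Generator, n_attempts: int) -> np.ndarray:
    """Double-edge-swap rewiring: (u,v),(x,y) -> (u,x),(v,y) when valid.

    Each attempt draws one candidate swap; invalid candidates (shared nodes
    or edges already present) are skipped, so the degree sequence is
    preserved exactly."""
    iu, ju = np.nonzero(np.triu(adj, 1))
    edges = [(int(a), int(b)) for a, b in zip(iu, ju)]
    eset = set(edges)
    ne = len(edges)
    pick = rng.integers(0, ne, size=(n_attempts, 2))
    flip = rng.random(n_attempts) < 0.5
    for t in range(n_attempts):
        a, b = pick[t]
        if a == b:
            continue
        u, v = edges[a]
        x, y = edges[b]
        if flip[t]:
            x, y = y, x
        if len({u, v, x, y}) < 4:
            continue
        e1 = (u, x) if u < x else (x, u)
        e2 = (v, y) if v < y else (y, v)
        if e1 in eset or e2 in eset:
            continue
        eset.discard(edges[a])
        eset.discard(edges[b])
        eset.add(e1)
        eset.add(e2)
        edges[a] = e1
        edges[b] = e2
    out = np.zeros_like(adj)
    for u, v in edges:
        out[u, v] = 1
        out[v, u] = 1
    return out


def smallworld_normalize(
    g: BinaryGraph, nulls: list[BinaryGraph]
) -> tuple[float, float, float]:
    """(gamma, lambda, sigma) = (Cp/<Cp_rand>, Lp/<Lp_rand>, gamma/lambda)."""
    if not nulls:
        raise ValueError("null ensemble must be non-empty")
    gm = _cp_lp(g.adjacency)
    null_cp = np.array([_cp_lp(h.adjacency)["Cp"] for h in nulls])
    null_lp = np.array([_cp_lp(h.adjacency)["Lp"] for h in nulls])
    mean_cp, mean_lp = float(null_cp.mean()), float(np.nanmean(null_lp))
    gamma = gm["Cp"] / mean_cp if mean_cp > 0 else float("nan")
    lam = gm["Lp"] / mean_lp if mean_lp > 0 else float("nan")
    sigma = gamma / lam if lam and np.isfinite(lam) and lam != 0 else float("nan")
    return gamma, lam, sigma


def metric_auc(values: np.ndarray, thresholds: np.ndarray) -> float:
    """Trapezoidal area under the metric-vs-sparsity curve; NaN points are
    dropped pairwise with a warning."""
    v = np.asarray(values, dtype=float)
    t = np.asarray(thresholds, dtype=float)
    if v.shape != t.shape or v.size < 2:
        raise ValueError("values and thresholds must have equal length >= 2")
    if not np.all(np.diff(t) > 0):
        raise ValueError("thresholds must be strictly increasing")
    ok = np.isfinite(v)
    if not ok.all():
        warnings.warn(f"dropping {int((~ok).sum())} missing values from AUC")
        v, t = v[ok], t[ok]
        if v.size < 2:
            return float("nan")
    return float(np.trapezoid(v, t))


def density_curve(mat: SimilarityMatrix, cutoffs: np.ndarray) -> np.ndarray:
    """Fraction of off-diagonal pairs with similarity strictly above each
    absolute cutoff."""
    cutoffs = np.asarray(cutoffs, dtype=float)
    if np.any((cutoffs <= 0) | (cutoffs >= 1)):
        raise ValueError("cutoffs must lie in (0, 1)")
    w = mat.offdiag_values()
    return np.array([(w > tau).mean() for tau in cutoffs])


@dataclass
class TopologyProfile:
    """Global and nodal metric tables across the sparsity grid plus AUCs."""

    subject_id: str
    metric: str
    thresholds: np.ndarray
    global_table: pd.DataFrame  # index threshold, columns GLOBAL_METRICS
    nodal_table: pd.DataFrame  # columns: threshold, roi, degree, bc, ne, nle
    auc: dict[str, float] = field(default_factory=dict)


def compute_topology_profile(
    mat: SimilarityMatrix,
    thresholds: np.ndarray | None = None,
    n_nulls: int = DEFAULT_N_NULLS,
    seed: int = 0,
) -> TopologyProfile:
    """Full profile of one similarity matrix across the sparsity grid."""
    if thresholds is None:
        thresholds = sparsity_grid(mat.atlas)
    g_rows, n_rows = [], []
    for s in thresholds:
        g = binarize_at_sparsity(mat, float(s))
        gm, nodal = _all_metrics(g.adjacency)
        nulls = random_null_ensemble(g, n_nulls, seed)
        gamma, lam, sigma = smallworld_normalize(g, nulls)
        gm.update({"gamma": gamma, "lambda": lam, "sigma": sigma})
        gm["threshold"] = float(s)
        g_rows.append(gm)
        nd = pd.DataFrame(nodal, index=pd.Index(g.labels, name="roi")).reset_index()
        nd.insert(0, "threshold", float(s))
        n_rows.append(nd)
    global_table = pd.DataFrame(g_rows).set_index("threshold")
    nodal_table = pd.concat(n_rows, ignore_index=True)
    auc = {
        name: metric_auc(global_table[name].to_numpy(), np.asarray(thresholds, float))
        for name in GLOBAL_METRICS
    }
    return TopologyProfile(
        subject_id=mat.subject_id,
        metric=mat.metric,
        thresholds=np.asarray(thresholds, float),
        global_table=global_table,
        nodal_table=nodal_table,
        auc=auc,
    )


def nodal_auc_table(profile: TopologyProfile) -> pd.DataFrame:
    """AUC across thresholds for every nodal metric and node."""
    t = profile.thresholds
    rows = []
    for roi, sub in profile.nodal_table.groupby("roi", sort=False):
        sub = sub.sort_values("threshold")
        row = {"roi": roi}
        for m in NODAL_METRICS:
            row[m] = metric_auc(sub[m].to_numpy(), sub["threshold"].to_numpy())
        rows.append(row)
    return pd.DataFrame(rows).set_index("roi")
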