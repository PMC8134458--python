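"""Binary graph topology across sparsity thresholds.

Similarity matrices are binarized by retaining the strongest S-fraction
of off-diagonal edges for each sparsity S in a threshold scheme
(default 0.10..0.34, step 0.01). Global measures (clustering
coefficient Cp, characteristic path length Lp, global/local efficiency)
and their small-world normalizations (gamma = Cp/<Cp_rand>,
lambda = Lp/<Lp_rand>, sigma = gamma/lambda, with degree-preserving
rewired null graphs) are computed per threshold, and each metric curve
is summarized by its trapezoidal area under the curve (AUC) over S, a
threshold-free scalar used by all group comparisons.

Shortest paths on disconnected graphs are averaged over connected pairs
only (a warning is logged); nodes of degree < 2 contribute 0 to Cp.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap

__all__ = [
    "ThresholdScheme",
    "BinaryGraph",
    "GlobalMetrics",
    "NodalMetrics",
    "MetricCurve",
    "threshold_by_sparsity",
    "global_metrics",
    "nodal_metrics",
    "rewire_null",
    "metric_auc",
    "global_metric_curves",
]

REWIRE_SWAP_FACTOR = 10  # attempted double-edge swaps per edge


@dataclass(frozen=True)
class ThresholdScheme:
    """Ordered sparsity values with the AUC summarization rule."""

    s_values: tuple[float, ...] = tuple(
        float(s) for s in np.round(np.arange(0.10, 0.3401, 0.01), 2)
    )

    def __post_init__(self) -> None:
        s = np.asarray(self.s_values, dtype=float)
        if s.size < 1:
            raise ValueError("threshold scheme needs at least one sparsity")
        if np.any(s <= 0) or np.any(s >= 1):
            raise ValueError("sparsities must lie in (0, 1)")
        if np.any(np.diff(s) <= 0):
            raise ValueError("sparsities must be strictly increasing")

    def __len__(self) -> int:
        return len(self.s_values)

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.s_values, dtype=float)


@dataclass
class BinaryGraph:
    """Undirected binary graph: symmetric boolean adjacency, no self-loops."""

    adjacency: np.ndarray
    sparsity: float = float("nan")

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency, dtype=bool)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if np.any(a != a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a)):
            raise ValueError("self-loops are not allowed")
        self.adjacency = a

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2


@dataclass
class GlobalMetrics:
    cp: float
    lp: float
    gamma: float
    lambda_: float
    sigma: float
    eglob: float
    eloc: float
    null_cp_mean: float = float("nan")
    null_cp_sd: float = float("nan")
    null_lp_mean: float = float("nan")
    null_lp_sd: float = float("nan")

    def as_dict(self) -> dict[str, float]:
        return {
            "cp": self.cp,
            "lp": self.lp,
            "gamma": self.gamma,
            "lambda": self.lambda_,
            "sigma": self.sigma,
            "eglob": self.eglob,
            "eloc": self.eloc,
        }


@dataclass
class NodalMetrics:
    degree: np.ndarray
    efficiency: np.ndarray
    betweenness: np.ndarray


@dataclass
class MetricCurve:
    """A metric evaluated across the threshold scheme, with its AUC."""

    s_values: np.ndarray
    values: np.ndarray
    auc: float = field(init=False)

    def __post_init__(self) -> None:
        self.s_values = np.asarray(self.s_values, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.s_values.shape != self.values.shape:
            raise ValueError("curve values must align with the threshold scheme")
        self.auc = metric_auc(self.values, self.s_values)


def _round_half_up(x: float) -> int:
    # round() half-to-even is wrong here; guard float dust first
    return int(math.floor(round(x, 9) + 0.5))


def threshold_by_sparsity(matrix, s: float) -> BinaryGraph:
    """Binarize a similarity matrix at sparsity ``s``.

    Retains the ``round-half-up(s * N(N-1)/2)`` strongest off-diagonal
    edges; ties are broken by descending weight, then ascending
    (row, column) index. The diagonal never participates.
    """
    values = matrix.values if hasattr(matrix, "values") else np.asarray(matrix, dtype=float)
    values = np.asarray(values, dtype=float)
    if not 0.0 < s < 1.0:
        raise ValueError(f"sparsity must lie in (0, 1), got {s}")
    iu, ju, order = _edge_order(values)
    return _graph_from_order(values.shape[0], iu, ju, order, s)


def _edge_order(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Off-diagonal edges sorted by descending weight, ties by (row, col)."""
    n = values.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    w = values[iu, ju]
    order = np.lexsort((ju, iu, -w))
    return iu, ju, order


def _graph_from_order(
    n: int, iu: np.ndarray, ju: np.ndarray, order: np.ndarray, s: float
) -> BinaryGraph:
    m = order.size
    k = min(max(_round_half_up(s * m), 0), m)
    keep = order[:k]
    adj = np.zeros((n, n), dtype=bool)
    adj[iu[keep], ju[keep]] = True
    adj |= adj.T
    return BinaryGraph(adjacency=adj, sparsity=k / m if m else float("nan"))


# ---------------------------------------------------------------------------
# metric primitives (dense numpy / csgraph)


def _distances(adj: np.ndarray) -> np.ndarray:
    """All-pairs unweighted shortest-path lengths (inf if unreachable).

    Level-synchronous BFS over all sources at once via boolean matrix
    products (BLAS sgemm), which beats per-source traversal for the
    dense ~90-node graphs this pipeline thresholds.
    """
    n = adj.shape[0]
    A = adj.astype(np.float32)
    dist = np.where(adj, 1.0, np.inf)
    np.fill_diagonal(dist, 0.0)
    reach = adj | np.eye(n, dtype=bool)
    frontier = adj.astype(np.float32)
    d = 1
    while True:
        nxt = (frontier @ A) > 0
        newly = nxt & ~reach
        if not newly.any():
            return dist
        d += 1
        dist[newly] = d
        reach |= newly
        frontier = newly.astype(np.float32)


def _clustering_coefficient(adj: np.ndarray) -> float:
    a = adj.astype(np.float64)
    k = a.sum(axis=1)
    a2 = a @ a
    triangles = (a2 * a).sum(axis=1) / 2.0
    denom = k * (k - 1) / 2.0
    cp = np.zeros_like(k)
    mask = denom > 0
    cp[mask] = triangles[mask] / denom[mask]
    return float(cp.mean())


_warned_disconnected = False


def _lp_from_dist(dist: np.ndarray, warn: bool = False) -> float:
    global _warned_disconnected
    n = dist.shape[0]
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(dist) & off
    if warn and finite.sum() < off.sum():
        if not _warned_disconnected:
            logger.warning(
                "graph is disconnected; Lp averaged over connected pairs only "
                "(further occurrences logged at DEBUG level)"
            )
            _warned_disconnected = True
        else:
            logger.debug("disconnected graph; Lp over connected pairs only")
    if not finite.any():
        return float("nan")
    return float(dist[finite].mean())


def _eglob_from_dist(dist: np.ndarray) -> float:
    n = dist.shape[0]
    if n < 2:
        return 0.0
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(dist) & (dist > 0), 1.0 / dist, 0.0)
    return float(inv[off].sum() / (n * (n - 1)))


def _eloc(adj: np.ndarray) -> float:
    n = adj.shape[0]
    total = 0.0
    for i in range(n):
        nbrs = np.flatnonzero(adj[i])
        if nbrs.size < 2:
            continue
        sub = adj[np.ix_(nbrs, nbrs)]
        total += _eglob_from_dist(_distances(sub))
    return total / n


# ---------------------------------------------------------------------------
# degree-preserving rewiring


@njit(cache=False)
def _swap_loop(adj, edges, n_attempts, seed):  # pragma: no cover - jitted
    np.random.seed(seed)
    n_edges = edges.shape[0]
    for _ in range(n_attempts):
        a = np.random.randint(0, n_edges)
        b = np.random.randint(0, n_edges)
        if a == b:
            continue
        u, v = edges[a, 0], edges[a, 1]
        x, y = edges[b, 0], edges[b, 1]
        if np.random.random() < 0.5:
            x, y = y, x
        if u == x or u == y or v == x or v == y:
            continue
        if adj[u, x] or adj[v, y]:
            continue
        adj[u, v] = False
        adj[v, u] = False
        adj[x, y] = False
        adj[y, x] = False
        adj[u, x] = True
        adj[x, u] = True
        adj[v, y] = True
        adj[y, v] = True
        edges[a, 0], edges[a, 1] = u, x
        edges[b, 0], edges[b, 1] = v, y


def rewire_null(graph: BinaryGraph, seed: int, swap_factor: int = REWIRE_SWAP_FACTOR) -> BinaryGraph:
    """Degree-preserving randomization by attempted double-edge swaps.

    ``swap_factor * n_edges`` swaps are *attempted* (rejected proposals —
    duplicate edges, self-loops, shared endpoints — count as attempts).
    Connectedness is not enforced.
    """
    adj = graph.adjacency.copy()
    iu, ju = np.nonzero(np.triu(adj, k=1))
    edges = np.stack([iu, ju], axis=1).astype(np.int64)
    if edges.shape[0] < 2:
        raise ValueError("graph too small to rewire (needs >= 2 edges)")
    _swap_loop(adj, edges, int(swap_factor) * edges.shape[0], int(seed) % (2**32))
    return BinaryGraph(adjacency=adj, sparsity=graph.sparsity)


# ---------------------------------------------------------------------------
# public metric operations


def global_metrics(graph: BinaryGraph, n_nulls: int = 100, seed: int | None = 0) -> GlobalMetrics:
    """All seven global measures of one binary graph.

    gamma/lambda/sigma come from ``n_nulls`` degree-preserving rewired
    graphs; pass ``n_nulls=0`` to skip the null ensemble (they are then
    NaN). Cp counts nodes of degree < 2 as 0; Lp averages over connected
    ordered pairs.
    """
    if graph.n_edges == 0:
        raise ValueError("graph has no edges")
    if n_nulls < 0:
        raise ValueError("n_nulls must be >= 0")
    adj = graph.adjacency
    dist = _distances(adj)
    cp = _clustering_coefficient(adj)
    lp = _lp_from_dist(dist, warn=True)
    eglob = _eglob_from_dist(dist)
    eloc = _eloc(adj)

    gamma = lambda_ = sigma = float("nan")
    ncm = ncs = nlm = nls = float("nan")
    if n_nulls > 0:
        seeds = np.random.SeedSequence(seed).generate_state(n_nulls)
        null_cp = np.empty(n_nulls)
        null_lp = np.empty(n_nulls)
        for i in range(n_nulls):
            null = rewire_null(graph, seed=int(seeds[i]))
            null_cp[i] = _clustering_coefficient(null.adjacency)
            null_lp[i] = _lp_from_dist(_distances(null.adjacency))
        ncm, ncs = float(null_cp.mean()), float(null_cp.std())
        nlm, nls = float(null_lp.mean()), float(null_lp.std())
        gamma = cp / ncm if ncm > 0 else float("nan")
        lambda_ = lp / nlm if nlm > 0 else float("nan")
        sigma = gamma / lambda_ if lambda_ > 0 else float("nan")

    return GlobalMetrics(
        cp=cp, lp=lp, gamma=gamma, lambda_=lambda_, sigma=sigma,
        eglob=eglob, eloc=eloc,
        null_cp_mean=ncm, null_cp_sd=ncs, null_lp_mean=nlm, null_lp_sd=nls,
    )


def nodal_metrics(graph: BinaryGraph) -> NodalMetrics:
    """Degree, nodal efficiency and (unnormalized) betweenness per node."""
    import networkx as nx

    if graph.n_edges == 0:
        raise ValueError("graph has no edges")
    adj = graph.adjacency
    n = graph.n_nodes
    degree = adj.sum(axis=1).astype(int)
    dist = _distances(adj)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(dist) & (dist > 0), 1.0 / dist, 0.0)
    efficiency = inv.sum(axis=1) / (n - 1) if n > 1 else np.zeros(n)
    g = nx.from_numpy_array(adj.astype(int))
    bc = nx.betweenness_centrality(g, normalized=False)
    betweenness = np.array([bc[i] for i in range(n)])
    return NodalMetrics(degree=degree, efficiency=efficiency, betweenness=betweenness)


def metric_auc(values, s_values) -> float:
    """Trapezoidal area under a metric curve over the sparsity range."""
    v = np.asarray(values, dtype=float)
    s = np.asarray(s_values, dtype=float)
    if v.shape != s.shape:
        raise ValueError("curve length must match the threshold scheme")
    if v.size < 2:
        raise ValueError("AUC needs at least two thresholds")
    return float(np.trapezoid(v, s))


def global_metric_curves(
    matrix,
    scheme: ThresholdScheme | None = None,
    n_nulls: int = 0,
    seed: int | None = 0,
    metrics: tuple[str, ...] = ("cp", "lp", "eglob", "eloc"),
) -> dict[str, MetricCurve]:
    """Global metric curves (and AUCs) of one similarity matrix.

    Small-world curves (gamma/lambda/sigma) are included when
    ``n_nulls > 0``. ``metrics`` restricts the plain metrics computed,
    which matters at scale (eloc dominates the per-threshold cost).
    """
    scheme = scheme or ThresholdScheme()
    names = list(metrics) + (["gamma", "lambda", "sigma"] if n_nulls > 0 else [])
    out: dict[str, list[float]] = {name: [] for name in names}
    seeds = np.random.SeedSequence(seed).generate_state(len(scheme))
    values = matrix.values if hasattr(matrix, "values") else np.asarray(matrix, dtype=float)
    iu, ju, order = _edge_order(values)  # sort once, reuse across thresholds
    for t, s in enumerate(scheme.s_values):
        graph = _graph_from_order(values.shape[0], iu, ju, order, s)
        if n_nulls > 0 or "eloc" in metrics:
            gm = global_metrics(graph, n_nulls=n_nulls, seed=int(seeds[t]))
            vals = gm.as_dict()
        else:
            adj = graph.adjacency
            dist = _distances(adj)
            vals = {
                "cp": _clustering_coefficient(adj),
                "lp": _lp_from_dist(dist, warn=True),
                "eglob": _eglob_from_dist(dist),
            }
        for name in names:
            out[name].append(vals[name])
    s_arr = scheme.array
    return {name: MetricCurve(s_values=s_arr, values=np.array(v)) for name, v in out.items()}


def nodal_metric_curves(matrix, scheme: ThresholdScheme | None = None) -> dict[str, np.ndarray]:
    """Nodal metric AUCs of one similarity matrix.

    Returns ``{"degree": (n_regions,), "efficiency": ..., "betweenness": ...}``
    arrays of per-node AUC values over the threshold scheme.
    """
    scheme = scheme or ThresholdScheme()
    per_s = {"degree": [], "efficiency": [], "betweenness": []}
    for s in scheme.s_values:
        nm = nodal_metrics(threshold_by_sparsity(matrix, s))
        per_s["degree"].append(nm.degree.astype(float))
        per_s["efficiency"].append(nm.efficiency)
        per_s["betweenness"].append(nm.betweenness)
    s_arr = scheme.array
    return {
        name: np.trapezoid(np.stack(v, axis=0), s_arr, axis=0) for name, v in per_s.items()
    }
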