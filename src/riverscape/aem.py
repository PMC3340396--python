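"""Asymmetric eigenvector maps (AEM): spatial eigenfunctions for directed networks.

AEM encodes *directional* spatial influence — in a river, an upstream site
can affect a downstream one but never the reverse.  From a directed acyclic
station graph it builds a sites x edges incidence matrix whose (i, j) entry
is the weight of edge j if that edge lies on a path from an origin to site
i, and zero otherwise.  The left singular vectors of the column-centered
incidence matrix are the AEM eigenfunctions: orthonormal, zero-mean site
scores ordered from broad downstream gradients to fine local structure.
They serve as spatial covariates that soak up connectivity-driven
autocorrelation in downstream regressions.

Eigenfunctions relevant to a given response are picked by forward selection
with a permutation test and an adjusted-R² stopping rule (the standard
double stopping criterion for spatial eigenfunction selection).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "AEMBasis",
    "SelectionResult",
    "build_incidence",
    "compute_basis",
    "aem_basis_from_graph",
    "select_eigenvectors",
    "read_edge_list",
    "write_edge_list",
]


@dataclass
class AEMBasis:
    """Centered orthonormal spatial eigenfunctions (sites x k)."""

    vectors: np.ndarray          # sites x k, unit-norm zero-mean columns
    singular_values: np.ndarray  # length k, descending
    sites: list[str]
    incidence: np.ndarray = field(repr=False, default=None)  # for diagnostics

    @property
    def k(self) -> int:
        return self.vectors.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.vectors,
            index=self.sites,
            columns=[f"aem{i + 1}" for i in range(self.k)],
        )
        df.index.name = "station"
        return df


@dataclass
class SelectionResult:
    """Forward-selection outcome over AEM eigenfunctions."""

    indices: list[int]          # retained columns, in selection order
    p_values: list[float]
    cum_adj_r2: list[float]

    @property
    def n_retained(self) -> int:
        return len(self.indices)


def _origins(graph: nx.DiGraph) -> list[str]:
    explicit = [n for n, d in graph.nodes(data=True) if d.get("kind") == "origin"]
    if explicit:
        return sorted(explicit)
    return sorted(n for n in graph.nodes if graph.in_degree(n) == 0)


def _stations(graph: nx.DiGraph) -> list[str]:
    origins = set(_origins(graph))
    return sorted(n for n in graph.nodes if n not in origins)


def build_incidence(graph: nx.DiGraph) -> tuple[np.ndarray, list[str], list[tuple]]:
    """Sites x edges AEM incidence matrix.

    Entry (i, j) = weight of edge j when edge j lies on some path from an
    origin to site i.  Origin rows are excluded.  Multiple origins are
    handled as if joined to a single super-origin by zero-influence
    bookkeeping edges (only the graph's real edges become columns); for
    sites fed by several paths the union of the paths' edges is used.

    Returns (matrix, site order, edge order).
    """
    if not nx.is_directed_acyclic_graph(graph):
        raise ValueError("AEM graph must be acyclic")
    sites = _stations(graph)
    origins = set(_origins(graph))
    edges = sorted(graph.edges())
    edge_pos = {e: j for j, e in enumerate(edges)}
    # union of path edge sets, accumulated in topological order
    edge_sets: dict[str, set] = {}
    for node in nx.topological_sort(graph):
        acc: set = set()
        for parent in graph.predecessors(node):
            acc |= edge_sets[parent]
            acc.add((parent, node))
        edge_sets[node] = acc
    unreachable = [
        s for s in sites
        if not edge_sets[s] and not any(o in graph.predecessors(s) for o in origins)
    ]
    if unreachable:
        raise ValueError(f"sites unreachable from any origin: {unreachable}")
    mat = np.zeros((len(sites), len(edges)))
    for i, s in enumerate(sites):
        if not edge_sets[s]:
            raise ValueError(f"site unreachable from any origin: {s}")
        for e in edge_sets[s]:
            mat[i, edge_pos[e]] = graph.edges[e].get("weight", 1.0)
    return mat, sites, edges


def compute_basis(
    incidence: np.ndarray,
    sites: list[str] | None = None,
    rtol: float = 1e-10,
) -> AEMBasis:
    """AEM eigenfunctions: SVD of the column-centered incidence matrix.

    Keeps left singular vectors with singular value > rtol * largest; the
    sign of each column is fixed so its largest-magnitude element is
    positive (deterministic across linear-algebra backends).  The number of
    eigenfunctions equals the rank of the centered matrix — at most
    n_sites - 1.
    """
    inc = np.asarray(incidence, dtype=float)
    n = inc.shape[0]
    if n < 2:
        raise ValueError("need at least 2 sites")
    if sites is None:
        sites = [f"site{i}" for i in range(n)]
    centered = inc - inc.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    keep = s > (rtol * s[0] if s.size and s[0] > 0 else np.inf)
    u, s = u[:, keep], s[keep]
    if u.shape[1] == 0:
        import warnings

        warnings.warn("all sites have identical connectivity: empty AEM basis")
    for j in range(u.shape[1]):
        i_max = np.argmax(np.abs(u[:, j]))
        if u[i_max, j] < 0:
            u[:, j] = -u[:, j]
    return AEMBasis(vectors=u, singular_values=s, sites=list(sites), incidence=inc)


def aem_basis_from_graph(graph: nx.DiGraph) -> AEMBasis:
    """Convenience: incidence + SVD in one step."""
    inc, sites, _ = build_incidence(graph)
    return compute_basis(inc, sites)


def _ols_r2(X: np.ndarray, y: np.ndarray) -> float:
    """R² of OLS of y on X (intercept included)."""
    n = y.size
    Xd = np.column_stack([np.ones(n), X]) if X.size else np.ones((n, 1))
    beta, *_ = np.linalg.lstsq(Xd, y, rcond=None)
    resid = y - Xd @ beta
    tss = np.sum((y - y.mean()) ** 2)
    if tss == 0:
        return 0.0
    return 1.0 - np.sum(resid**2) / tss


def _adj_r2(r2: float, n: int, p: int) -> float:
    if n - p - 1 <= 0:
        return -np.inf
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def select_eigenvectors(
    basis: AEMBasis,
    response: np.ndarray,
    alpha: float = 0.05,
    n_permutations: int = 999,
    seed: int | None = None,
) -> SelectionResult:
    """Forward-select the eigenfunctions relevant to a response.

    Candidates are scanned in singular-value order; at each step the
    candidate giving the largest R² gain enters provisionally, its gain is
    tested by permuting the response residuals of the current model
    (``n_permutations`` draws, seeded), and selection stops when the
    permutation p-value exceeds ``alpha`` or the adjusted R² no longer
    increases (double stopping rule).
    """
    y = np.asarray(response, dtype=float)
    V = basis.vectors
    if y.size != V.shape[0]:
        raise ValueError("response length must equal the number of sites")
    if np.allclose(y, y[0]):
        return SelectionResult(indices=[], p_values=[], cum_adj_r2=[])
    rng = np.random.default_rng(seed)
    n = y.size
    # AEM columns are zero-mean and orthonormal, so the R² gain of adding
    # column j never depends on the columns already selected:
    # R²(S ∪ {j}) − R²(S) = (u_j·y_c)² / ||y_c||².  This makes both the scan
    # and the permutation null fully vectorizable.
    yc = y - y.mean()
    tss = float(yc @ yc)
    proj2 = (V.T @ yc) ** 2 / tss  # per-column R² contribution
    selected: list[int] = []
    p_values: list[float] = []
    cum_adj: list[float] = []
    remaining = list(range(basis.k))
    r2_cur = 0.0
    current_adj = 0.0
    while remaining:
        rem = np.array(remaining)
        j_best = remaining[int(np.argmax(proj2[rem]))]
        gain_obs = float(proj2[j_best])
        new_adj = _adj_r2(r2_cur + gain_obs, n, len(selected) + 1)
        if new_adj <= current_adj and selected:
            break
        # permutation test on residuals of the current model, using the same
        # best-of-remaining statistic (accounts for selection bias)
        fitted = V[:, selected] @ (V[:, selected].T @ yc) + y.mean()
        resid = y - fitted
        perm = np.array([rng.permutation(resid) for _ in range(n_permutations)]).T
        y_perm = fitted[:, None] + perm                      # n x n_perm
        ypc = y_perm - y_perm.mean(axis=0, keepdims=True)
        tss_perm = np.sum(ypc**2, axis=0)
        gains_perm = np.max((V[:, rem].T @ ypc) ** 2, axis=0) / tss_perm
        p_val = (int(np.sum(gains_perm >= gain_obs)) + 1) / (n_permutations + 1)
        if p_val > alpha:
            break
        selected.append(j_best)
        remaining.remove(j_best)
        p_values.append(p_val)
        r2_cur += gain_obs
        current_adj = new_adj
        cum_adj.append(current_adj)
    return SelectionResult(indices=selected, p_values=p_values, cum_adj_r2=cum_adj)


def read_edge_list(path: str | Path) -> nx.DiGraph:
    """Read a ``parent<TAB>child<TAB>weight`` edge list into a DiGraph.

    Nodes with in-degree zero are treated as origins.
    """
    g = nx.DiGraph()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"malformed edge line: {line!r}")
            w = float(parts[2]) if len(parts) > 2 else 1.0
            if w <= 0:
                raise ValueError(f"nonpositive edge weight: {line!r}")
            g.add_edge(parts[0], parts[1], weight=w)
    for n in g.nodes:
        g.nodes[n]["kind"] = "origin" if g.in_degree(n) == 0 else "station"
    return g


def write_edge_list(graph: nx.DiGraph, path: str | Path) -> None:
    with open(path, "w") as fh:
        for u, v, d in sorted(graph.edges(data=True)):
            fh.write(f"{u}\t{v}\t{d.get('weight', 1.0)}\n")
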