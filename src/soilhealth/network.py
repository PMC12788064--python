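"""Spearman correlation network and minimum-data-set (MDS) selection.

The MDS procedure reduces a panel of soil indicators to a non-redundant
core in four stages:

1. ``spearman_matrix`` — pairwise Spearman rank correlations over all
   samples, with two-sided p-values from the t approximation
   ``t = rho * sqrt((n-2)/(1-rho^2))`` on n-2 degrees of freedom.
2. ``build_network`` — indicators become nodes; an undirected edge joins
   two indicators when the correlation is both strong (|rho| >= 0.60,
   inclusive) and significant (p < 0.01, strict). The adjacency is binary.
3. ``eigenvector_centrality`` — node importance x_i proportional to the
   summed importance of neighbors, x = (1/lambda) A x: the dominant
   eigenvector of each connected component's adjacency, computed by power
   iteration and nonnegative by Perron-Frobenius. Each component's vector
   is scaled to unit maximum (power iteration fixes it only up to scale,
   and there is no canonical relative scale between disconnected
   components), so the global maximum is 1 and a high-centrality threshold
   reads the same within every block of the network. Isolated nodes get 0.
4. ``select_candidates`` + ``resolve_redundancy`` — keep high-centrality
   nodes (threshold rule, default >= 0.9, or top-fraction rule), then
   cluster candidates by the same significant-edge rule and keep, per
   cluster, the member with the highest cumulative sum of |rho| to the
   rest of its cluster. Survivors form the MDS.
"""
from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, ConvergenceError, SelectionError, ValidationError
from .indicators import IndicatorTable


@dataclass
class CorrelationResult:
    """Symmetric Spearman rho and p matrices over indicators."""

    rho: pd.DataFrame
    p: pd.DataFrame
    n_samples: int

    @property
    def indicators(self) -> list[str]:
        return list(self.rho.columns)


@dataclass
class CorrelationNetwork:
    """Thresholded binary correlation graph."""

    nodes: list[str]
    adjacency: pd.DataFrame  # binary, symmetric, zero diagonal
    edges: pd.DataFrame  # columns: source, target, rho, p
    r_threshold: float
    alpha: float
    use_absolute: bool

    def to_graphml(self, path: str | Path) -> Path:
        path = Path(path)
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for row in self.edges.itertuples(index=False):
            g.add_edge(row.source, row.target, rho=float(row.rho), p=float(row.p))
        nx.write_graphml(g, path)
        return path


@dataclass
class CentralityResult:
    """Eigenvector centrality per node, with component bookkeeping."""

    centrality: pd.Series  # max-normalized to 1 over the graph; isolated = 0
    component: pd.Series  # component label per node (-1 for isolated)
    eigenvalues: dict[int, float]  # dominant eigenvalue per component

    def ordered(self) -> pd.Series:
        """Centrality sorted descending, ties by name (deterministic)."""
        frame = self.centrality.rename("centrality").reset_index()
        frame = frame.sort_values(
            ["centrality", "index"], ascending=[False, True], kind="mergesort"
        )
        return frame.set_index("index")["centrality"]


@dataclass
class MDSSelection:
    """Candidates, redundancy clusters and the surviving minimum data set."""

    candidates: pd.Series  # candidate -> centrality
    clusters: list[list[str]]
    mds: list[str]
    trace: list[dict] = field(default_factory=list)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "candidates": {k: float(v) for k, v in self.candidates.items()},
            "clusters": self.clusters,
            "mds": self.mds,
            "trace": self.trace,
        }
        path.write_text(json.dumps(payload, indent=2))
        return path


# ---------------------------------------------------------------------------


def spearman_matrix(table: IndicatorTable | pd.DataFrame) -> CorrelationResult:
    """Pairwise Spearman correlations over all samples (pooled).

    Constant indicators (zero variance) are excluded with a warning rather
    than propagating NaN. Perfect monotone pairs (|rho| = 1) get p = 0.
    """
    if isinstance(table, IndicatorTable):
        values = table.values()
    else:
        values = table
    if len(values) < 4:
        raise ValidationError(
            f"need >= 4 samples for the correlation stage, got {len(values)}"
        )
    variances = values.var(axis=0, ddof=0)
    constant = list(values.columns[variances == 0.0])
    if constant:
        warnings.warn(
            f"excluding constant indicator(s) from the correlation network: {constant}",
            UserWarning,
            stacklevel=2,
        )
        values = values.drop(columns=constant)
    if values.shape[1] < 2:
        raise ValidationError("need at least 2 non-constant indicators")

    n = len(values)
    rho_mat, p_mat = stats.spearmanr(values.to_numpy(), axis=0)
    if np.ndim(rho_mat) == 0:  # scipy collapses the 2-column case to scalars
        rho_mat = np.array([[1.0, float(rho_mat)], [float(rho_mat), 1.0]])
        p_mat = np.array([[0.0, float(p_mat)], [float(p_mat), 0.0]])
    np.fill_diagonal(rho_mat, 1.0)
    np.fill_diagonal(p_mat, 0.0)
    # t approximation degenerates at |rho| = 1; the exact p there is 0
    p_mat[np.isclose(np.abs(rho_mat), 1.0)] = 0.0

    cols = list(values.columns)
    return CorrelationResult(
        rho=pd.DataFrame(rho_mat, index=cols, columns=cols),
        p=pd.DataFrame(p_mat, index=cols, columns=cols),
        n_samples=n,
    )


def build_network(
    corr: CorrelationResult,
    r_threshold: float = 0.60,
    alpha: float = 0.01,
    use_absolute: bool = True,
) -> CorrelationNetwork:
    """Threshold the correlation matrix into a binary indicator graph.

    Edge (i, j) exists iff the correlation magnitude passes ``r_threshold``
    (inclusive) and the p-value is below ``alpha`` (strict). With
    ``use_absolute=False`` only positive correlations qualify.
    """
    if not 0 <= r_threshold <= 1:
        raise ConfigurationError(f"r_threshold must be in [0, 1], got {r_threshold}")
    if not 0 < alpha < 1:
        raise ConfigurationError(f"alpha must be in (0, 1), got {alpha}")

    nodes = corr.indicators
    rho = corr.rho.to_numpy()
    p = corr.p.to_numpy()
    strength = np.abs(rho) if use_absolute else rho
    adj = (strength >= r_threshold) & (p < alpha)
    np.fill_diagonal(adj, False)
    adj = adj & adj.T  # symmetry guard (inputs are symmetric already)

    rows = []
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            if adj[i, j]:
                rows.append((nodes[i], nodes[j], float(rho[i, j]), float(p[i, j])))
    edges = pd.DataFrame(rows, columns=["source", "target", "rho", "p"])
    return CorrelationNetwork(
        nodes=nodes,
        adjacency=pd.DataFrame(adj.astype(int), index=nodes, columns=nodes),
        edges=edges,
        r_threshold=r_threshold,
        alpha=alpha,
        use_absolute=use_absolute,
    )


def eigenvector_centrality(
    network: CorrelationNetwork,
    tol: float = 1e-10,
    max_iter: int = 1000,
    epsilon: float = 1.0,
) -> CentralityResult:
    """Dominant-eigenvector importance of each node, by power iteration.

    Runs independently on each connected component with at least one edge,
    starting from a uniform positive vector, renormalizing to unit maximum
    each sweep, and stopping when successive iterates differ by less than
    ``tol`` in the max norm. Isolated nodes get centrality 0.

    The update is the lazy iteration ``v ← A v + epsilon * v``: shifting the
    adjacency by ``epsilon * I`` leaves its eigenvectors unchanged but makes
    the dominant eigenvalue strictly largest in magnitude, so the iteration
    converges even on bipartite components (e.g. a 3-node path), where the
    raw ``epsilon = 0`` update oscillates forever. The reported eigenvalue
    is that of the unshifted adjacency.
    """
    nodes = network.nodes
    adj = network.adjacency.to_numpy(dtype=float)
    n = len(nodes)
    centrality = np.zeros(n)
    component = np.full(n, -1, dtype=int)
    eigenvalues: dict[int, float] = {}

    g = nx.from_numpy_array(adj)
    comp_id = 0
    for members in nx.connected_components(g):
        idx = sorted(members)
        if len(idx) == 1 and adj[idx[0], idx[0]] == 0:
            continue  # isolated node: centrality stays 0, label -1
        sub = adj[np.ix_(idx, idx)]
        v = np.ones(len(idx))
        converged = False
        residual = math.inf
        for _ in range(max_iter):
            w = sub @ v + epsilon * v
            wmax = w.max()
            if wmax <= 0:  # defensive; cannot happen for a component with an edge
                raise ConvergenceError(
                    f"component {comp_id}: iteration collapsed to zero"
                )
            w /= wmax
            residual = float(np.max(np.abs(w - v)))
            v = w
            if residual < tol:
                converged = True
                break
        if not converged:
            raise ConvergenceError(
                f"power iteration did not converge on component {comp_id} "
                f"({len(idx)} nodes) after {max_iter} iterations; "
                f"last residual {residual:.3e}"
            )
        # Rayleigh quotient of the converged vector = dominant eigenvalue
        eigenvalues[comp_id] = float(v @ (sub @ v) / (v @ v))
        centrality[idx] = v / v.max()
        component[idx] = comp_id
        comp_id += 1

    return CentralityResult(
        centrality=pd.Series(centrality, index=nodes, name="centrality"),
        component=pd.Series(component, index=nodes, name="component"),
        eigenvalues=eigenvalues,
    )


def select_candidates(
    centrality: CentralityResult,
    rule: str = "threshold",
    threshold: float = 0.9,
    top_fraction: float = 0.10,
) -> list[str]:
    """High-centrality candidate indicators.

    rule="threshold" keeps nodes with centrality >= threshold.
    rule="top_fraction" keeps the ceil(fraction × n) highest-centrality
    nodes, extending the cut to include all nodes tied at the cutoff value.
    """
    scores = centrality.centrality
    if rule == "threshold":
        if not 0 < threshold <= 1:
            raise ConfigurationError(f"threshold must be in (0, 1], got {threshold}")
        kept = scores[scores >= threshold]
    elif rule == "top_fraction":
        if not 0 < top_fraction <= 1:
            raise ConfigurationError(
                f"top_fraction must be in (0, 1], got {top_fraction}"
            )
        k = math.ceil(top_fraction * len(scores))
        ordered = scores.sort_values(ascending=False, kind="mergesort")
        cutoff = ordered.iloc[k - 1]
        kept = scores[scores >= cutoff]
    else:
        raise ConfigurationError(
            f"rule must be 'threshold' or 'top_fraction', got {rule!r}"
        )
    if kept.empty:
        raise SelectionError(
            "no indicator passed the centrality cut; lower the threshold or "
            "use rule='top_fraction'"
        )
    return sorted(kept.index)


def resolve_redundancy(
    candidates: list[str],
    corr: CorrelationResult,
    r_threshold: float = 0.60,
    alpha: float = 0.01,
    centrality: CentralityResult | None = None,
) -> MDSSelection:
    """Collapse inter-correlated candidates to one survivor each.

    Candidates are clustered as connected components of the significant-edge
    subgraph restricted to the candidate set (same |rho|/p gates as the full
    network). Within each cluster of size >= 2 the survivor is the member
    with the highest cumulative sum of |rho| to the other cluster members;
    ties break on lexicographic name. Singletons survive unchanged.
    """
    if not candidates:
        raise SelectionError("candidate set is empty")
    missing = [c for c in candidates if c not in corr.indicators]
    if missing:
        raise ValidationError(f"candidate(s) not in correlation matrix: {missing}")

    cand = sorted(candidates)
    rho = corr.rho.loc[cand, cand].to_numpy()
    p = corr.p.loc[cand, cand].to_numpy()
    adj = (np.abs(rho) >= r_threshold) & (p < alpha)
    np.fill_diagonal(adj, False)

    g = nx.from_numpy_array(adj.astype(int))
    clusters: list[list[str]] = []
    mds: list[str] = []
    trace: list[dict] = []
    for members in sorted(nx.connected_components(g), key=min):
        idx = sorted(members)
        names = [cand[i] for i in idx]
        clusters.append(names)
        if len(idx) == 1:
            mds.append(names[0])
            trace.append({"cluster": names, "survivor": names[0], "sums": {}})
            continue
        sums = {}
        for i in idx:
            sums[cand[i]] = float(
                sum(abs(rho[i, j]) for j in idx if j != i)
            )
        # argmax cumulative |rho|, lexicographic tie-break
        survivor = min(sums, key=lambda name: (-sums[name], name))
        mds.append(survivor)
        trace.append({"cluster": names, "survivor": survivor, "sums": sums})

    mds = sorted(mds)
    if centrality is not None:
        order = centrality.ordered()
        mds = [name for name in order.index if name in set(mds)]
    scores = (
        centrality.centrality.loc[cand]
        if centrality is not None
        else pd.Series(np.nan, index=cand)
    )
    return MDSSelection(candidates=scores, clusters=clusters, mds=mds, trace=trace)


def select_mds(
    table: IndicatorTable,
    r_threshold: float = 0.60,
    alpha: float = 0.01,
    use_absolute: bool = True,
    rule: str = "threshold",
    threshold: float = 0.9,
    top_fraction: float = 0.10,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> tuple[CorrelationResult, CorrelationNetwork, CentralityResult, MDSSelection]:
    """Run the full correlation → network → centrality → MDS chain."""
    corr = spearman_matrix(table)
    net = build_network(corr, r_threshold=r_threshold, alpha=alpha, use_absolute=use_absolute)
    cent = eigenvector_centrality(net, tol=tol, max_iter=max_iter)
    cands = select_candidates(cent, rule=rule, threshold=threshold, top_fraction=top_fraction)
    sel = resolve_redundancy(cands, corr, r_threshold=r_threshold, alpha=alpha, centrality=cent)
    return corr, net, cent, sel
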