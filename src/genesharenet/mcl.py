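"""Markov Clustering (MCL) of weighted undirected networks.

MCL simulates flow on the graph: the column-stochastic transition matrix
is alternately *expanded* (matrix power, letting flow travel) and
*inflated* (entrywise power followed by column renormalization, boosting
strong currents and demoting weak ones) until the process converges to a
near-idempotent limit whose nonzero structure spells out the clusters.
The inflation exponent is the granularity knob: higher values fragment
the graph into more, tighter clusters.  The default inflation of 1.5 is
the setting used for genome gene-sharing networks here.

Self-loops are added before normalization — each node gets a loop
weighted at its maximum incident edge weight, a common MCL practice that
damps oscillation (isolated nodes get weight 1, which normalizes away).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = ["ClusterAssignment", "mcl_cluster"]


@dataclass
class ClusterAssignment:
    """Result of an MCL run.

    ``labels`` maps every node to a cluster id; ids are contiguous from
    1, numbered by each cluster's lexicographically smallest member so
    the output is independent of node input order.
    """

    labels: dict[str, int]
    attractors: dict[int, list[str]] = field(default_factory=dict)
    converged: bool = True
    n_iter: int = 0

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels.values()))

    def clusters(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for node, lab in self.labels.items():
            out.setdefault(lab, []).append(node)
        return {k: sorted(v) for k, v in sorted(out.items())}


def _column_normalize(m: np.ndarray) -> np.ndarray:
    colsum = m.sum(axis=0)
    colsum[colsum == 0] = 1.0
    return m / colsum


def mcl_cluster(
    network: nx.Graph,
    inflation: float = 1.5,
    expansion: int = 2,
    prune_threshold: float = 1e-5,
    max_iter: int = 200,
    tol: float = 1e-6,
    self_loops: str = "max",
) -> ClusterAssignment:
    """Cluster a weighted undirected network with MCL.

    Parameters
    ----------
    inflation : granularity exponent, must be > 1.
    expansion : matrix-power exponent of the expand step.
    prune_threshold : entries below this are zeroed (then columns are
        renormalized) after each inflation, keeping the matrix sparse.
    self_loops : "max" adds a loop at each node's maximum incident edge
        weight; "one" adds unit loops; "none" adds none.

    Clusters are the connected components of the symmetrized nonzero
    structure of the limit matrix.  A node reached by attractors of more
    than one cluster is assigned to the cluster whose attractors carry
    the largest limit mass in its column (ties broken toward the cluster
    containing the lexicographically smallest attractor).
    """
    if inflation <= 1:
        raise ValueError("inflation must be > 1")
    if len(network) == 0:
        raise ValueError("network is empty")

    nodes = sorted(network.nodes)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    m = np.zeros((n, n))
    for u, v, data in network.edges(data=True):
        w = float(data.get("weight", 1.0))
        m[idx[u], idx[v]] = w
        m[idx[v], idx[u]] = w
    if self_loops == "max":
        loop = m.max(axis=0)
        loop[loop == 0] = 1.0
        np.fill_diagonal(m, loop)
    elif self_loops == "one":
        np.fill_diagonal(m, 1.0)
    elif self_loops != "none":
        raise ValueError(f"unknown self_loops policy {self_loops!r}")
    if self_loops == "none" and (m.sum(axis=0) == 0).any():
        # fully isolated nodes need a loop to keep columns stochastic
        for i in np.flatnonzero(m.sum(axis=0) == 0):
            m[i, i] = 1.0

    m = _column_normalize(m)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        prev = m
        m = np.linalg.matrix_power(m, expansion)
        m = _column_normalize(np.power(m, inflation))
        m[m < prune_threshold] = 0.0
        m = _column_normalize(m)
        if np.abs(m - prev).max() < tol:
            converged = True
            break

    labels = _extract_clusters(m, nodes)
    attractors = _attractors(m, nodes, labels)
    return ClusterAssignment(labels, attractors, converged=converged, n_iter=it)


def _extract_clusters(m: np.ndarray, nodes: list[str]) -> dict[str, int]:
    n = len(nodes)
    # attractors: nodes retaining mass on the diagonal at the limit
    diag = np.diag(m)
    attractor_ix = np.flatnonzero(diag > 0)
    structure = (m > 0) | (m.T > 0)

    # attractor systems: components of the structure restricted to attractors
    parent = list(range(n))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    aset = set(attractor_ix)
    for i in attractor_ix:
        for j in attractor_ix:
            if j > i and structure[i, j]:
                union(i, j)

    # system id -> member attractor indices
    systems: dict[int, list[int]] = {}
    for i in attractor_ix:
        systems.setdefault(find(i), []).append(i)

    assignment: dict[str, int] = {}
    unassigned: list[int] = []
    for j in range(n):
        if j in aset:
            assignment[nodes[j]] = find(j)
            continue
        # mass flowing from node j toward each attractor system
        mass: dict[int, float] = {}
        for i in attractor_ix:
            if m[i, j] > 0:
                mass[find(i)] = mass.get(find(i), 0.0) + m[i, j]
        if not mass:
            unassigned.append(j)
            continue
        best = max(mass.values())
        tied = [s for s, v in mass.items() if v == best]
        if len(tied) > 1:
            tied.sort(key=lambda s: min(nodes[i] for i in systems[s]))
        assignment[nodes[j]] = tied[0]

    # nodes with no attractor flow (non-convergence corner): own cluster
    for j in unassigned:
        assignment[nodes[j]] = -(j + 1)

    # renumber clusters 1..k by smallest member taxon id
    members: dict[int, list[str]] = {}
    for node, sysid in assignment.items():
        members.setdefault(sysid, []).append(node)
    order = sorted(members, key=lambda s: min(members[s]))
    relabel = {s: k + 1 for k, s in enumerate(order)}
    return {node: relabel[s] for node, s in assignment.items()}


def _attractors(
    m: np.ndarray, nodes: list[str], labels: dict[str, int]
) -> dict[int, list[str]]:
    diag = np.diag(m)
    out: dict[int, list[str]] = {lab: [] for lab in set(labels.values())}
    for i, node in enumerate(nodes):
        if diag[i] > 0:
            out[labels[node]].append(node)
    return {k: sorted(v) for k, v in sorted(out.items())}
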