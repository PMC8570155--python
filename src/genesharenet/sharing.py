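"""Copy-count matrices and the normalized gene-sharing statistic.

Two taxa i and j (individual genomes, or whole family pangenomes) are
compared by the orthogroups they carry.  With U_ij the number of
orthogroups present in both, and T_i the number of orthogroups of i
present in at least one *other* taxon of the matrix, the sharing level is

    S_ij = U_ij / sqrt(T_i * T_j)

i.e. the shared count normalized by the geometric mean of each taxon's
total shared-with-anyone repertoire.  The geometric mean keeps a very
gene-rich partner from swamping the statistic.  S is in [0, 1]; a pair
with an isolated member (T = 0) is assigned S = 0.  Presence/absence
drives U and T; copy numbers are carried in the count matrix for the
downstream copy-number summaries only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .data_io import GenomeMeta, OrthogroupCatalog

__all__ = [
    "CountMatrix",
    "SharingMatrix",
    "build_count_matrix",
    "collapse_to_pangenomes",
    "compute_sharing",
    "build_network",
]


@dataclass
class CountMatrix:
    """Taxa x orthogroups gene-copy counts.

    ``level`` records whether rows are individual genomes or family
    pangenomes (sums over member genomes).
    """

    counts: pd.DataFrame  # int, taxa x orthogroups
    level: str = "genome"

    def __post_init__(self) -> None:
        if self.level not in ("genome", "pangenome"):
            raise ValueError(f"unknown level {self.level!r}")
        if (self.counts.values < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def taxa(self) -> list[str]:
        return list(self.counts.index)

    @property
    def orthogroups(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def presence(self) -> pd.DataFrame:
        return self.counts > 0


@dataclass
class SharingMatrix:
    """Pairwise sharing: U (shared counts), T (shared-with-any totals), S."""

    U: pd.DataFrame  # symmetric int
    T: pd.Series  # per-taxon
    S: pd.DataFrame  # symmetric float in [0, 1], diagonal not meaningful

    @property
    def taxa(self) -> list[str]:
        return list(self.S.index)


def build_count_matrix(catalog: OrthogroupCatalog, meta: GenomeMeta) -> CountMatrix:
    """Tally gene copies per (genome, orthogroup) from catalog membership.

    The metadata table is the taxon registry: every metadata genome gets
    a row (all-zero if it shares nothing), and a catalog genome missing
    from the metadata is an error.
    """
    taxa = meta.virus_ids
    known = set(taxa)
    offenders = sorted(catalog.genomes - known)
    if offenders:
        raise ValueError(f"catalog genomes absent from metadata: {offenders}")

    ogs = sorted(catalog.groups)
    counts = np.zeros((len(taxa), len(ogs)), dtype=np.int64)
    row = {t: i for i, t in enumerate(taxa)}
    for j, gid in enumerate(ogs):
        for virus, _ in catalog.groups[gid]:
            counts[row[virus], j] += 1
    df = pd.DataFrame(counts, index=pd.Index(taxa, name="taxon"), columns=ogs)
    return CountMatrix(df, level="genome")


def collapse_to_pangenomes(
    matrix: CountMatrix, grouping: Mapping[str, str]
) -> CountMatrix:
    """Sum genome rows into family-pangenome rows.

    All genes of a family's genomes are pooled into one pangenome taxon;
    pangenome presence is the union of member presences.
    """
    unmapped = [t for t in matrix.taxa if t not in grouping]
    if unmapped:
        raise ValueError(f"taxa without a family mapping: {unmapped}")
    fam = pd.Series({t: grouping[t] for t in matrix.taxa}, name="family")
    collapsed = matrix.counts.groupby(fam).sum()
    collapsed = collapsed.sort_index()
    collapsed.index.name = "taxon"
    return CountMatrix(collapsed, level="pangenome")


def compute_sharing(matrix: CountMatrix) -> SharingMatrix:
    """Compute U, T and S from a count matrix.

    T is evaluated over the taxon set of this matrix only, so S values
    are context-dependent by construction (a genome-level and a
    family-level matrix give independently normalized networks).
    """
    if len(matrix.taxa) < 2:
        raise ValueError("sharing requires at least 2 taxa")
    P = matrix.presence.to_numpy(dtype=np.int64)
    U = P @ P.T
    # orthogroup is "shared" for taxon i if some other taxon also has it
    colsum = P.sum(axis=0)
    T = (P * (colsum - P >= 1)).sum(axis=1)
    denom = np.sqrt(np.outer(T, T).astype(float))
    with np.errstate(divide="ignore", invalid="ignore"):
        S = np.where(denom > 0, U / denom, 0.0)
    np.fill_diagonal(S, 0.0)
    idx = pd.Index(matrix.taxa, name="taxon")
    return SharingMatrix(
        U=pd.DataFrame(U, index=idx, columns=idx),
        T=pd.Series(T, index=idx, name="T"),
        S=pd.DataFrame(S, index=idx, columns=idx),
    )


def build_network(
    sharing: SharingMatrix,
    node_attrs: Mapping[str, Mapping[str, object]] | None = None,
    min_weight: float = 0.0,
) -> nx.Graph:
    """Build the undirected gene-sharing network.

    Every taxon becomes a node (isolates included); an edge joins each
    pair with U_ij >= 1 and weight S_ij.  ``min_weight`` defaults to 0:
    no thresholding before clustering.
    """
    g = nx.Graph()
    taxa = sharing.taxa
    for t in taxa:
        attrs = dict(node_attrs.get(t, {})) if node_attrs else {}
        g.add_node(t, **attrs)
    U = sharing.U.to_numpy()
    S = sharing.S.to_numpy()
    for i in range(len(taxa)):
        for j in range(i + 1, len(taxa)):
            if U[i, j] >= 1 and S[i, j] >= min_weight and S[i, j] > 0:
                g.add_edge(taxa[i], taxa[j], weight=float(S[i, j]))
    return g
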