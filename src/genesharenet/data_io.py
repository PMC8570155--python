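"""Readers and writers for the pipeline's tabular and tree formats.

The package consumes the outputs of an upstream ortholog-clustering run
(an OrthoMCL-style ``groups`` file whose members are ``VirusID|protein``
tokens), a genome metadata table, an optional core-gene tree in newick,
and an optional orthogroup annotation table.  It emits Cytoscape-ready
edge tables and cluster-assignment tables.  All tables are plain TSV.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "ValidationError",
    "GenomeMeta",
    "OrthogroupCatalog",
    "PhyloTree",
    "HOST_TYPES",
    "HOST_SUPERGROUPS",
    "HOST_TYPE_ALIASES",
    "SUPERGROUP_ALIASES",
    "read_metadata",
    "read_orthogroups",
    "read_tree",
    "read_annotations",
    "write_edge_table",
    "read_edge_table",
    "write_cluster_assignment",
    "read_cluster_assignment",
]


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class ValidationError(ValueError):
    """A file parses but violates a data-model invariant."""


# The four comparative host types plus a catch-all.
HOST_TYPES = ("vertebrate", "insect", "amoeba", "alga", "other")

# The six eukaryotic supergroups with known NCLDV hosts.
HOST_SUPERGROUPS = (
    "Amoebozoa",
    "Archaeplastida",
    "Discoba",
    "Haptista",
    "Opisthokonta",
    "SAR",
)

# Host labels in source tables are free text; this editable alias map
# normalizes common variants onto the canonical enum tokens.
HOST_TYPE_ALIASES = {
    "vertebrate": "vertebrate",
    "vertebrates": "vertebrate",
    "fish": "vertebrate",
    "amphibian": "vertebrate",
    "reptile": "vertebrate",
    "mammal": "vertebrate",
    "insect": "insect",
    "insects": "insect",
    "amoeba": "amoeba",
    "amoebae": "amoeba",
    "amoebal": "amoeba",
    "alga": "alga",
    "algae": "alga",
    "algal": "alga",
    "other": "other",
    "unknown": "other",
    "": "other",
}

SUPERGROUP_ALIASES = {s.lower(): s for s in HOST_SUPERGROUPS}
SUPERGROUP_ALIASES.update({"unknown": "unknown", "": "unknown"})

_META_REQUIRED = ("virus_id", "family", "lineage", "host_type", "host_supergroup")


@dataclass
class GenomeMeta:
    """Validated genome metadata: one row per viral genome.

    ``table`` columns: virus_id, family, lineage, host_type,
    host_supergroup, plus optional genome_size and protein_count.
    Alternate family labelings (e.g. a nine-family column next to the
    seven-family one) travel as extra ``family_*`` columns.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        for col in _META_REQUIRED:
            if col not in t.columns:
                raise FormatError(f"metadata missing required column {col!r}")
        dup = t["virus_id"][t["virus_id"].duplicated()]
        if len(dup):
            raise ValidationError(
                f"duplicate virus_id values: {sorted(dup.unique())}"
            )
        # each lineage must belong to exactly one family
        fam_per_lin = t.groupby("lineage")["family"].nunique()
        bad = fam_per_lin[fam_per_lin > 1]
        if len(bad):
            raise ValidationError(
                f"lineages mapped to multiple families: {sorted(bad.index)}"
            )
        if "protein_count" in t.columns:
            pc = t["protein_count"].dropna()
            if (pc < 0).any():
                raise ValidationError("protein_count must be >= 0")
        if "genome_size" in t.columns:
            gs = t["genome_size"].dropna()
            if (gs <= 0).any():
                raise ValidationError("genome_size must be > 0")

    @property
    def virus_ids(self) -> list[str]:
        return list(self.table["virus_id"])

    def column_map(self, col: str) -> dict[str, str]:
        """virus_id -> value mapping for a metadata column."""
        return dict(zip(self.table["virus_id"], self.table[col]))

    @property
    def family_map(self) -> dict[str, str]:
        return self.column_map("family")

    @property
    def lineage_map(self) -> dict[str, str]:
        return self.column_map("lineage")

    @property
    def host_type_map(self) -> dict[str, str]:
        return self.column_map("host_type")

    def lineage_family_map(self) -> dict[str, str]:
        """lineage -> family (well defined by the invariant)."""
        return dict(zip(self.table["lineage"], self.table["family"]))


@dataclass
class OrthogroupCatalog:
    """Orthogroup membership: group id -> (genome, protein) pairs.

    ``singletons`` are proteins assigned to no group; they are only
    known when a full protein index was supplied (``has_protein_index``),
    otherwise singleton-dependent metrics are unavailable.
    """

    groups: dict[str, list[tuple[str, str]]]
    singletons: list[tuple[str, str]] = field(default_factory=list)
    has_protein_index: bool = False

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for gid, members in self.groups.items():
            if len(members) < 2:
                raise ValidationError(
                    f"orthogroup {gid!r} has {len(members)} member(s); >= 2 required"
                )
            for m in members:
                if m in seen:
                    raise ValidationError(
                        f"protein {m!r} appears in more than one orthogroup"
                    )
                seen.add(m)
        overlap = seen.intersection(self.singletons)
        if overlap:
            raise ValidationError(
                f"singletons overlap group members: {sorted(overlap)[:5]}"
            )

    @property
    def n_members(self) -> int:
        return sum(len(m) for m in self.groups.values())

    @property
    def genomes(self) -> set[str]:
        out = {v for members in self.groups.values() for v, _ in members}
        out.update(v for v, _ in self.singletons)
        return out

    def singleton_counts(self) -> dict[str, int]:
        """Singletons per genome (genomes with none are absent)."""
        counts: dict[str, int] = {}
        for v, _ in self.singletons:
            counts[v] = counts.get(v, 0) + 1
        return counts


@dataclass
class PhyloTree:
    """A rooted/unrooted tree with branch lengths and unique tip labels."""

    tree: dendropy.Tree
    _pdm: dendropy.PhylogeneticDistanceMatrix | None = None

    @property
    def tip_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def patristic(self, a: str, b: str) -> float:
        """Sum of branch lengths along the path between two tips."""
        if self._pdm is None:
            self._pdm = self.tree.phylogenetic_distance_matrix()
        ns = self.tree.taxon_namespace
        ta, tb = ns.get_taxon(a), ns.get_taxon(b)
        if ta is None or tb is None:
            missing = [x for x, t in ((a, ta), (b, tb)) if t is None]
            raise KeyError(f"tip label(s) not in tree: {missing}")
        return float(self._pdm.patristic_distance(ta, tb))


def read_metadata(path: str | Path) -> GenomeMeta:
    """Read a genome metadata TSV, normalizing host labels via the alias maps.

    Unknown host tokens map to ``other`` / ``unknown`` with a logged warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, comment="#")
    for col in _META_REQUIRED:
        if col not in df.columns:
            raise FormatError(f"metadata file {path} missing required column {col!r}")

    def norm(value: str, aliases: dict[str, str], fallback: str, col: str) -> str:
        key = value.strip()
        hit = aliases.get(key.lower())
        if hit is None:
            log.warning("unrecognized %s token %r mapped to %r", col, value, fallback)
            return fallback
        return hit

    df["host_type"] = [
        norm(v, HOST_TYPE_ALIASES, "other", "host_type") for v in df["host_type"]
    ]
    df["host_supergroup"] = [
        norm(v, SUPERGROUP_ALIASES, "unknown", "host_supergroup")
        for v in df["host_supergroup"]
    ]
    for col in ("genome_size", "protein_count"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col].replace("", pd.NA))
    return GenomeMeta(df.reset_index(drop=True))


_GROUP_HEADER = re.compile(r"^(?P<gid>\S+?)\s*(?:\(\d+\s*genes,\s*\d+\s*taxa\))?$")


def _parse_member(token: str, lineno: int) -> tuple[str, str]:
    # VirusID tokens are not guaranteed to avoid '|'; split on the first one.
    if "|" not in token:
        raise FormatError(
            f"line {lineno}: member {token!r} lacks the 'VirusID|protein' separator"
        )
    virus, protein = token.split("|", 1)
    return virus, protein


def read_orthogroups(
    path: str | Path,
    protein_index: Iterable[tuple[str, str]] | None = None,
) -> OrthogroupCatalog:
    """Parse a groups file in either the plain ``id: members`` or the
    OrthoMCL ``id(N genes,M taxa): members`` dialect.

    Parenthesized counts in the OrthoMCL header are ignored, not trusted.
    When ``protein_index`` (every (genome, protein) in the dataset) is
    given, singletons are derived as the index entries absent from all
    groups; without it singleton-based metrics are flagged unavailable.
    """
    groups: dict[str, list[tuple[str, str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            head, sep, rest = line.partition(":")
            m = _GROUP_HEADER.match(head.strip()) if sep else None
            if m is None or not rest.strip():
                raise FormatError(
                    f"line {lineno}: expected '<group_id>: member member ...'"
                )
            gid = m.group("gid")
            if gid in groups:
                raise ValidationError(f"line {lineno}: duplicate group id {gid!r}")
            groups[gid] = [_parse_member(tok, lineno) for tok in rest.split()]

    singletons: list[tuple[str, str]] = []
    has_index = protein_index is not None
    if has_index:
        clustered = {m for members in groups.values() for m in members}
        singletons = sorted(set(map(tuple, protein_index)) - clustered)
    return OrthogroupCatalog(groups, singletons, has_protein_index=has_index)


def read_protein_index(path: str | Path) -> list[tuple[str, str]]:
    """Read a 2-column TSV (virus_id, protein_id) listing every protein."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, comment="#")
    if not {"virus_id", "protein_id"} <= set(df.columns):
        raise FormatError(f"{path}: need columns virus_id, protein_id")
    return list(zip(df["virus_id"], df["protein_id"]))


def read_tree(
    path: str | Path, known_labels: Sequence[str] | None = None
) -> tuple[PhyloTree, list[str]]:
    """Read a newick tree; returns (tree, tips absent from known_labels)."""
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick")
    except Exception as exc:  # dendropy raises several parse error types
        raise FormatError(f"malformed newick in {path}: {exc}") from exc
    pt = PhyloTree(tree)
    labels = pt.tip_labels
    if len(set(labels)) != len(labels):
        raise ValidationError("duplicate tip labels in tree")
    unknown: list[str] = []
    if known_labels is not None:
        unknown = sorted(set(labels) - set(known_labels))
        if unknown:
            log.warning("tree tips absent from metadata: %s", unknown)
    return pt, unknown


def read_annotations(path: str | Path) -> dict[str, str]:
    """Read an orthogroup annotation TSV (orthogroup_id, annotation)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, comment="#")
    if not {"orthogroup_id", "annotation"} <= set(df.columns):
        raise FormatError(f"{path}: need columns orthogroup_id, annotation")
    return dict(zip(df["orthogroup_id"], df["annotation"]))


def write_edge_table(network, path: str | Path) -> None:
    """Write an undirected weighted network as a Cytoscape-importable TSV.

    Three columns (source, target, weight); one row per edge with
    source < target lexicographically, rows sorted by (source, target).
    """
    rows = []
    for u, v, data in network.edges(data=True):
        a, b = sorted((str(u), str(v)))
        rows.append((a, b, data["weight"]))
    rows.sort()
    df = pd.DataFrame(rows, columns=["source", "target", "weight"])
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_edge_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"source": str, "target": str}, comment="#")
    if list(df.columns[:3]) != ["source", "target", "weight"]:
        raise FormatError(f"{path}: expected columns source, target, weight")
    return df


def write_cluster_assignment(assignment, path: str | Path) -> None:
    """Write (taxon, cluster) rows sorted by taxon id."""
    rows = sorted(assignment.labels.items())
    pd.DataFrame(rows, columns=["taxon", "cluster"]).to_csv(
        path, sep="\t", index=False
    )


def read_cluster_assignment(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", dtype={"taxon": str, "cluster": int}, comment="#")
    if list(df.columns[:2]) != ["taxon", "cluster"]:
        raise FormatError(f"{path}: expected columns taxon, cluster")
    return dict(zip(df["taxon"], df["cluster"]))
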