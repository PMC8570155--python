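"""Synthetic gene-content datasets with planted structure.

The generator emulates the block structure of giant-virus gene
repertoires so every pipeline stage can be exercised, and its answers
checked, without any real download:

- a handful of universal core orthogroups carried by every genome
  (the analog of the few widely distributed core proteins);
- a family-core pool per family, each gene independently retained by
  each member genome with ``retention_prob``;
- lineage-private orthogroups confined to one lineage;
- a host-type gene pool per host type, retained with
  ``host_retention_prob`` by every genome of that host type *regardless
  of family* — the planted cross-family host signal the comparative
  screen is supposed to recover;
- per-genome unique singletons; and
- per-present-gene copy numbers of 1 + Poisson(copy_lambda).

Families come in pairs that split two host types between their lineages
(mirroring the vertebrate/insect and alga/amoeba family pairs of real
NCLDV data), so each host type spans two families.  A nested
family>lineage>genome tree with exponential branch lengths (deeper
family stems than lineage stems) accompanies the catalog.  All
randomness flows from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .data_io import GenomeMeta, OrthogroupCatalog, PhyloTree

__all__ = ["SimulationParams", "GroundTruth", "simulate_dataset", "write_dataset"]

HOST_TYPE_PAIRS = (("vertebrate", "insect"), ("alga", "amoeba"))
SUPERGROUP_OF_HOST = {
    "vertebrate": "Opisthokonta",
    "insect": "Opisthokonta",
    "alga": "Archaeplastida",
    "amoeba": "Amoebozoa",
    "other": "unknown",
}


@dataclass
class SimulationParams:
    """Knobs of the generator; defaults define the standard test regime."""

    n_families: int = 4
    lineages_per_family: int = 3
    genomes_per_lineage: int = 4
    n_universal_core: int = 5
    family_core_pool_size: int = 100
    retention_prob: float = 0.8
    lineage_private_pool_size: int = 20
    host_gene_pool_size: int = 30
    host_retention_prob: float = 0.7
    singletons_per_genome: float = 10.0
    copy_lambda: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "n_families",
            "lineages_per_family",
            "genomes_per_lineage",
            "n_universal_core",
            "family_core_pool_size",
            "lineage_private_pool_size",
            "host_gene_pool_size",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("retention_prob", "host_retention_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.copy_lambda < 0 or self.singletons_per_genome < 0:
            raise ValueError("copy_lambda and singletons_per_genome must be >= 0")
        if self.n_families < 1 or self.lineages_per_family < 1:
            raise ValueError("need at least one family with one lineage")
        if self.genomes_per_lineage < 1:
            raise ValueError("genomes_per_lineage must be >= 1")


@dataclass
class GroundTruth:
    """What was planted: the partition and the host-gene lists."""

    family_of: dict[str, str]
    lineage_of: dict[str, str]
    host_type_of: dict[str, str]
    # per host type: pool orthogroups that ended up carried by that host
    # type's viruses in at least two distinct families (i.e. recoverable)
    host_genes: dict[str, set[str]] = field(default_factory=dict)
    host_pools: dict[str, list[str]] = field(default_factory=dict)


def _layout(params: SimulationParams):
    """Enumerate (genome, family, lineage, host_type) in deterministic order."""
    rows = []
    for f in range(params.n_families):
        fam = f"Fam{f + 1:02d}"
        pair = HOST_TYPE_PAIRS[(f // 2) % len(HOST_TYPE_PAIRS)]
        for l in range(params.lineages_per_family):
            lin = f"{fam}_L{l + 1}"
            host = pair[l % 2]
            for g in range(params.genomes_per_lineage):
                vid = f"F{f + 1:02d}L{l + 1}G{g + 1:02d}"
                rows.append((vid, fam, lin, host))
    return rows


def simulate_dataset(
    params: SimulationParams | None = None,
) -> tuple[OrthogroupCatalog, GenomeMeta, PhyloTree, GroundTruth]:
    """Generate a catalog, metadata table, tree and ground truth.

    Fully reproducible from ``params.seed``.  Orthogroups that end up
    with a single member protein are demoted to singletons, as an
    ortholog-clustering run would leave them unclustered.
    """
    params = params or SimulationParams()
    params.validate()
    rng = np.random.default_rng(params.seed)
    layout = _layout(params)
    genomes = [vid for vid, _, _, _ in layout]
    families = sorted({fam for _, fam, _, _ in layout})
    lineages = sorted({lin for _, _, lin, _ in layout})
    host_types = sorted({h for _, _, _, h in layout})

    universal = [f"CORE{i + 1:03d}" for i in range(params.n_universal_core)]
    family_pool = {
        fam: [f"FC_{fam}_{i + 1:04d}" for i in range(params.family_core_pool_size)]
        for fam in families
    }
    lineage_pool = {
        lin: [f"LP_{lin}_{i + 1:03d}" for i in range(params.lineage_private_pool_size)]
        for lin in lineages
    }
    host_pool = {
        h: [f"HG_{h}_{i + 1:03d}" for i in range(params.host_gene_pool_size)]
        for h in host_types
    }

    # presence draws, genome by genome in layout order
    present: dict[str, list[str]] = {}
    for vid, fam, lin, host in layout:
        ogs = list(universal)
        if family_pool[fam]:
            keep = rng.random(len(family_pool[fam])) < params.retention_prob
            ogs.extend(g for g, k in zip(family_pool[fam], keep) if k)
        ogs.extend(lineage_pool[lin])
        if host_pool[host]:
            keep = rng.random(len(host_pool[host])) < params.host_retention_prob
            ogs.extend(g for g, k in zip(host_pool[host], keep) if k)
        present[vid] = ogs

    # copy numbers and protein ids
    groups: dict[str, list[tuple[str, str]]] = {}
    protein_index: list[tuple[str, str]] = []
    protein_counter = {vid: 0 for vid in genomes}

    def next_protein(vid: str) -> str:
        protein_counter[vid] += 1
        return f"p{protein_counter[vid]:05d}"

    for vid, _, _, _ in layout:
        for og in present[vid]:
            copies = 1 + (
                rng.poisson(params.copy_lambda) if params.copy_lambda > 0 else 0
            )
            for _ in range(copies):
                pid = next_protein(vid)
                groups.setdefault(og, []).append((vid, pid))
                protein_index.append((vid, pid))

    singletons: list[tuple[str, str]] = []
    for vid, _, _, _ in layout:
        n_single = rng.poisson(params.singletons_per_genome)
        for _ in range(n_single):
            pid = next_protein(vid)
            singletons.append((vid, pid))
            protein_index.append((vid, pid))

    # demote single-member groups to singletons
    for og in sorted(groups):
        if len(groups[og]) < 2:
            singletons.extend(groups.pop(og))
    singletons.sort()

    catalog = OrthogroupCatalog(groups, singletons, has_protein_index=True)

    # metadata
    fam_of = {vid: fam for vid, fam, _, _ in layout}
    lin_of = {vid: lin for vid, _, lin, _ in layout}
    host_of = {vid: host for vid, _, _, host in layout}
    prot_count = {vid: protein_counter[vid] for vid in genomes}
    meta = GenomeMeta(
        pd.DataFrame(
            {
                "virus_id": genomes,
                "family": [fam_of[v] for v in genomes],
                "lineage": [lin_of[v] for v in genomes],
                "host_type": [host_of[v] for v in genomes],
                "host_supergroup": [SUPERGROUP_OF_HOST[host_of[v]] for v in genomes],
                "genome_size": [prot_count[v] * 1085 for v in genomes],
                "protein_count": [prot_count[v] for v in genomes],
            }
        )
    )

    tree = _simulate_tree(params, layout, rng)

    # recoverable planted host genes: carried by >= 2 families of that host type
    host_genes: dict[str, set[str]] = {h: set() for h in host_types}
    for h in host_types:
        for og in host_pool[h]:
            if og not in groups:
                continue
            fams_carrying = {
                fam_of[v]
                for v, _ in groups[og]
                if host_of[v] == h
            }
            if len(fams_carrying) >= 2:
                host_genes[h].add(og)

    truth = GroundTruth(
        family_of=fam_of,
        lineage_of=lin_of,
        host_type_of=host_of,
        host_genes=host_genes,
        host_pools=host_pool,
    )
    return catalog, meta, tree, truth


def _simulate_tree(params, layout, rng) -> PhyloTree:
    """Nested family>lineage>genome newick with exponential branch lengths.

    Family stems are drawn deeper (mean 0.5) than lineage stems (0.2)
    and tip branches (0.05) so patristic distances separate the levels.
    """
    by_family: dict[str, dict[str, list[str]]] = {}
    for vid, fam, lin, _ in layout:
        by_family.setdefault(fam, {}).setdefault(lin, []).append(vid)

    def clade(tips: list[str], mean: float) -> str:
        parts = [f"{t}:{rng.exponential(mean):.6f}" for t in tips]
        return parts[0] if len(parts) == 1 else "(" + ",".join(parts) + ")"

    fam_parts = []
    for fam in sorted(by_family):
        lin_parts = []
        for lin in sorted(by_family[fam]):
            sub = clade(by_family[fam][lin], 0.05)
            lin_parts.append(f"{sub}:{rng.exponential(0.2):.6f}")
        inner = "(" + ",".join(lin_parts) + ")" if len(lin_parts) > 1 else lin_parts[0]
        fam_parts.append(f"{inner}:{rng.exponential(0.5):.6f}")
    newick = (
        "(" + ",".join(fam_parts) + ");" if len(fam_parts) > 1 else fam_parts[0] + ";"
    )
    tree = dendropy.Tree.get(data=newick, schema="newick")
    return PhyloTree(tree)


def write_dataset(
    catalog: OrthogroupCatalog,
    meta: GenomeMeta,
    tree: PhyloTree,
    outdir: str | Path,
    seed: int | None = None,
) -> dict[str, Path]:
    """Write the generated dataset in the formats the readers consume.

    Emits groups.txt, protein_index.tsv, metadata.tsv, tree.nwk; the
    seed is embedded in a header comment of each text table.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    banner = f"# seed: {seed}\n" if seed is not None else ""

    paths = {}
    p = outdir / "groups.txt"
    with open(p, "w") as fh:
        fh.write(banner)
        for og in sorted(catalog.groups):
            members = " ".join(f"{v}|{pid}" for v, pid in sorted(catalog.groups[og]))
            fh.write(f"{og}: {members}\n")
    paths["groups"] = p

    p = outdir / "protein_index.tsv"
    index = sorted(
        {m for ms in catalog.groups.values() for m in ms} | set(catalog.singletons)
    )
    with open(p, "w") as fh:
        fh.write(banner)
        fh.write("virus_id\tprotein_id\n")
        for v, pid in index:
            fh.write(f"{v}\t{pid}\n")
    paths["protein_index"] = p

    p = outdir / "metadata.tsv"
    with open(p, "w") as fh:
        fh.write(banner)
        meta.table.to_csv(fh, sep="\t", index=False)
    paths["metadata"] = p

    p = outdir / "tree.nwk"
    newick = tree.tree.as_string(schema="newick", suppress_rooting=True)
    with open(p, "w") as fh:
        if seed is not None:
            fh.write(f"[seed: {seed}]")
        fh.write(newick)
    paths["tree"] = p
    return paths
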