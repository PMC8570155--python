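"""Intrafamilial genomic variation and Shannon host diversity.

Databases oversample some strains, so variation within a virus family is
measured between *lineages* (groups of closely related genomes, roughly
genus level), not between genomes: per-genome quantities are first
averaged within each lineage, then summarized across lineages of a
family.  Three variation measures are reported per family —

1. sample SD of protein-coding sequence counts across lineages,
2. sample SD of unclustered singleton sequence counts across lineages,
3. mean between-lineage patristic distance on the core-gene tree
   (substitutions/site, averaged over all cross-lineage tip pairs and
   then over lineage pairs),

— alongside a Shannon host-diversity index D = -sum_j p_j ln p_j, where
p_j is the proportion of the family's lineages whose hosts fall in
eukaryotic supergroup j (six supergroups, so 0 <= D <= ln 6).
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd

from .data_io import GenomeMeta, OrthogroupCatalog, PhyloTree, ValidationError

log = logging.getLogger(__name__)

__all__ = [
    "lineage_means",
    "family_sd",
    "mean_interlineage_patristic",
    "lineage_supergroups",
    "shannon_host_diversity",
    "family_variation_report",
]


def lineage_means(
    per_genome_values: Mapping[str, float], lineage_map: Mapping[str, str]
) -> dict[str, float]:
    """Arithmetic mean of a per-genome quantity within each lineage."""
    unmapped = sorted(set(per_genome_values) - set(lineage_map))
    if unmapped:
        raise ValueError(f"genomes without a lineage: {unmapped}")
    acc: dict[str, list[float]] = {}
    for genome, value in per_genome_values.items():
        acc.setdefault(lineage_map[genome], []).append(float(value))
    return {lin: float(np.mean(vals)) for lin, vals in acc.items()}


def family_sd(
    lineage_values: Mapping[str, float], family_map: Mapping[str, str]
) -> dict[str, float]:
    """Sample SD (n-1 denominator) over lineage values per family.

    Families with fewer than two lineages get NaN (undefined spread).
    """
    acc: dict[str, list[float]] = {}
    for lin, value in lineage_values.items():
        acc.setdefault(family_map[lin], []).append(float(value))
    return {
        fam: float(np.std(vals, ddof=1)) if len(vals) >= 2 else math.nan
        for fam, vals in acc.items()
    }


def mean_interlineage_patristic(
    tree: PhyloTree,
    lineage_map: Mapping[str, str],
    family_map: Mapping[str, str],
    representative: bool = False,
) -> dict[str, float]:
    """Mean between-lineage core-tree distance per family.

    The distance between two lineages is the mean patristic distance
    over all cross-lineage tip pairs (or, with ``representative=True``,
    between each lineage's alphabetically first genome, for sensitivity
    checks); the family value averages over all unordered lineage pairs.
    Single-lineage families get NaN.
    """
    tips = set(tree.tip_labels)
    missing = sorted(set(lineage_map) - tips)
    if missing:
        raise ValueError(f"genomes missing from tree: {missing}")

    by_lineage: dict[str, list[str]] = {}
    for genome, lin in lineage_map.items():
        by_lineage.setdefault(lin, []).append(genome)
    for lin in by_lineage:
        by_lineage[lin].sort()

    by_family: dict[str, list[str]] = {}
    for lin in by_lineage:
        by_family.setdefault(family_map[lin], []).append(lin)

    out: dict[str, float] = {}
    for fam, lins in by_family.items():
        if len(lins) < 2:
            out[fam] = math.nan
            continue
        pair_means = []
        for la, lb in combinations(sorted(lins), 2):
            ga = by_lineage[la][:1] if representative else by_lineage[la]
            gb = by_lineage[lb][:1] if representative else by_lineage[lb]
            dists = [tree.patristic(a, b) for a in ga for b in gb]
            pair_means.append(float(np.mean(dists)))
        out[fam] = float(np.mean(pair_means))
    return out


def lineage_supergroups(meta: GenomeMeta) -> dict[str, str]:
    """Assign each lineage its (majority) host supergroup.

    A lineage whose genomes span several supergroups takes the majority
    one; an exact tie is a validation error the user must resolve.
    Lineages resolving to ``unknown`` are excluded with a warning.
    """
    table = meta.table
    out: dict[str, str] = {}
    for lin, sub in table.groupby("lineage"):
        counts = Counter(sub["host_supergroup"])
        known = {k: v for k, v in counts.items() if k != "unknown"}
        if not known:
            log.warning("lineage %s has no known host supergroup; excluded", lin)
            continue
        top = max(known.values())
        winners = sorted(k for k, v in known.items() if v == top)
        if len(winners) > 1:
            raise ValidationError(
                f"lineage {lin!r} ties between supergroups {winners}; "
                "resolve in the metadata"
            )
        out[lin] = winners[0]
    return out


def shannon_host_diversity(
    lineage_supergroup: Mapping[str, str], family_map: Mapping[str, str]
) -> dict[str, float]:
    """Shannon index D = -sum p_j ln p_j over host supergroups, per family.

    p_j is the fraction of the family's (supergroup-assigned) lineages
    infecting supergroup j.  Families with no assigned lineage get NaN.
    """
    by_family: dict[str, list[str]] = {}
    for lin, sg in lineage_supergroup.items():
        by_family.setdefault(family_map[lin], []).append(sg)
    out: dict[str, float] = {}
    for fam, sgs in by_family.items():
        if not sgs:
            out[fam] = math.nan
            continue
        n = len(sgs)
        d = -sum(
            (c / n) * math.log(c / n) for c in Counter(sgs).values() if c > 0
        )
        out[fam] = float(d)
    return out


def family_variation_report(
    meta: GenomeMeta,
    catalog: OrthogroupCatalog | None = None,
    tree: PhyloTree | None = None,
) -> pd.DataFrame:
    """Per-family table of host diversity and the three variation measures.

    Columns: family, lineage_count, host_diversity_D, sd_protein_counts,
    sd_singleton_counts, mean_patristic.  Measures whose inputs are
    unavailable (no protein_count column, no protein index for
    singletons, no tree) are NaN, never zero.
    """
    table = meta.table
    lin_map = meta.lineage_map
    fam_of_lin = meta.lineage_family_map()
    families = sorted(table["family"].unique())

    lineage_count = {
        fam: table[table["family"] == fam]["lineage"].nunique() for fam in families
    }

    div = shannon_host_diversity(lineage_supergroups(meta), fam_of_lin)

    sd_prot: dict[str, float] = {}
    if "protein_count" in table.columns and table["protein_count"].notna().all():
        per_genome = dict(zip(table["virus_id"], table["protein_count"]))
        sd_prot = family_sd(lineage_means(per_genome, lin_map), fam_of_lin)

    sd_single: dict[str, float] = {}
    if catalog is not None and catalog.has_protein_index:
        counts = catalog.singleton_counts()
        per_genome = {v: float(counts.get(v, 0)) for v in meta.virus_ids}
        sd_single = family_sd(lineage_means(per_genome, lin_map), fam_of_lin)

    patristic: dict[str, float] = {}
    if tree is not None:
        patristic = mean_interlineage_patristic(tree, lin_map, fam_of_lin)

    rows = []
    for fam in families:
        rows.append(
            {
                "family": fam,
                "lineage_count": lineage_count[fam],
                "host_diversity_D": div.get(fam, math.nan),
                "sd_protein_counts": sd_prot.get(fam, math.nan),
                "sd_singleton_counts": sd_single.get(fam, math.nan),
                "mean_patristic": patristic.get(fam, math.nan),
            }
        )
    return pd.DataFrame(rows)


def plot_variation_report(report: pd.DataFrame, path: str) -> None:
    """Scatter each variation measure against host diversity D.

    One panel per measure, family names as point labels; written to
    ``path`` (format from the extension).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    measures = ["sd_protein_counts", "sd_singleton_counts", "mean_patristic"]
    titles = ["SD protein counts", "SD singleton counts",
              "mean patristic distance"]
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.6), sharex=True)
    for ax, col, title in zip(axes, measures, titles):
        sub = report.dropna(subset=[col, "host_diversity_D"])
        ax.scatter(sub["host_diversity_D"], sub[col], s=25)
        for _, row in sub.iterrows():
            ax.annotate(row["family"], (row["host_diversity_D"], row[col]),
                        fontsize=7, xytext=(3, 3), textcoords="offset points")
        ax.set_xlabel("host diversity D (nats)")
        ax.set_ylabel(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
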