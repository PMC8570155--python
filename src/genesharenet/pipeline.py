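"""End-to-end orchestration with a config file and a checksummed manifest.

A pipeline run reads the orthogroup catalog, metadata and optional tree/
annotations, then produces in order: the genome-level sharing matrix and
edge table, the MCL cluster assignment, family-pangenome edge tables for
every family labeling column in the metadata (e.g. a seven-family and a
nine-family classification are just alternate columns, not code paths),
the per-family variation/host-diversity report, the similar/dissimilar
host comparisons, and the target/reference host-shared orthogroup
reports.  Every artifact is listed in a manifest with its SHA-256, and
every parameter is recorded there for provenance; identical inputs and
config give byte-identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import data_io, diversity, hostcomp, mcl, sharing

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the original cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Inputs, analysis settings and output location for one run."""

    groups: str
    metadata: str
    outdir: str
    protein_index: str | None = None
    tree: str | None = None
    annotations: str | None = None
    # [famA, famB, host_type] triples for the similar/dissimilar test
    host_comparisons: list[list[str]] = field(default_factory=list)
    # [famA, famB, target, reference] quadruples for the orthogroup screen
    host_screens: list[list[str]] = field(default_factory=list)
    inflation: float = 1.5
    prune_threshold: float = 1e-5
    max_iter: int = 200
    self_loops: str = "max"
    min_weight: float = 0.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        for name in ("groups", "metadata", "protein_index", "tree", "annotations"):
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise FileNotFoundError(f"{name} file not found: {value}")
        for row in self.host_comparisons:
            if len(row) != 3:
                raise ValueError(f"host_comparisons rows need 3 fields, got {row}")
        for row in self.host_screens:
            if len(row) != 4:
                raise ValueError(f"host_screens rows need 4 fields, got {row}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _family_columns(meta: data_io.GenomeMeta) -> list[str]:
    """The primary family column plus any alternate family labelings."""
    cols = [c for c in meta.table.columns if c == "family" or c.startswith("family_")]
    return cols


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run every configured analysis; return the manifest dict.

    The manifest (also written to ``<outdir>/manifest.json``) lists each
    artifact with its SHA-256 and all effective parameters.  A stage
    failure writes a manifest with a ``failed_stage`` marker, keeps any
    partial outputs, and raises :class:`PipelineError`.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, dict[str, str]] = {}
    manifest: dict[str, Any] = {
        "parameters": {
            "inflation": config.inflation,
            "prune_threshold": config.prune_threshold,
            "max_iter": config.max_iter,
            "self_loops": config.self_loops,
            "min_weight": config.min_weight,
            "seed": config.seed,
        },
        "artifacts": artifacts,
    }

    def record(name: str, path: Path) -> None:
        artifacts[name] = {"path": path.name, "sha256": _sha256(path)}

    def fail(stage: str, exc: Exception) -> None:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        _write_manifest(manifest, outdir)
        raise PipelineError(stage, exc) from exc

    stage = "load_inputs"
    try:
        index = (
            data_io.read_protein_index(config.protein_index)
            if config.protein_index
            else None
        )
        catalog = data_io.read_orthogroups(config.groups, protein_index=index)
        meta = data_io.read_metadata(config.metadata)
        tree = None
        if config.tree:
            tree, _ = data_io.read_tree(config.tree, known_labels=meta.virus_ids)
        annotations = (
            data_io.read_annotations(config.annotations) if config.annotations else None
        )
    except Exception as exc:
        fail(stage, exc)

    stage = "genome_sharing"
    try:
        counts = sharing.build_count_matrix(catalog, meta)
        genome_sharing = sharing.compute_sharing(counts)
        network = sharing.build_network(
            genome_sharing,
            node_attrs={v: {"family": f} for v, f in meta.family_map.items()},
            min_weight=config.min_weight,
        )
        p = outdir / "genome_sharing_matrix.tsv"
        genome_sharing.S.to_csv(p, sep="\t", float_format="%.10g")
        record("genome_sharing_matrix", p)
        p = outdir / "genome_edges.tsv"
        data_io.write_edge_table(network, p)
        record("genome_edges", p)
    except Exception as exc:
        fail(stage, exc)

    stage = "mcl_clustering"
    try:
        assignment = mcl.mcl_cluster(
            network,
            inflation=config.inflation,
            prune_threshold=config.prune_threshold,
            max_iter=config.max_iter,
            self_loops=config.self_loops,
        )
        p = outdir / "mcl_clusters.tsv"
        data_io.write_cluster_assignment(assignment, p)
        record("mcl_clusters", p)
        manifest["parameters"]["mcl_converged"] = assignment.converged
        manifest["parameters"]["mcl_n_clusters"] = assignment.n_clusters
    except Exception as exc:
        fail(stage, exc)

    stage = "family_networks"
    try:
        for col in _family_columns(meta):
            grouping = meta.column_map(col)
            pancounts = sharing.collapse_to_pangenomes(counts, grouping)
            pansharing = sharing.compute_sharing(pancounts)
            pannet = sharing.build_network(pansharing, min_weight=config.min_weight)
            p = outdir / f"pangenome_edges_{col}.tsv"
            data_io.write_edge_table(pannet, p)
            record(f"pangenome_edges_{col}", p)
    except Exception as exc:
        fail(stage, exc)

    stage = "variation_report"
    try:
        report = diversity.family_variation_report(meta, catalog=catalog, tree=tree)
        p = outdir / "family_variation.tsv"
        report.to_csv(p, sep="\t", index=False, float_format="%.10g")
        record("family_variation", p)
    except Exception as exc:
        fail(stage, exc)

    stage = "host_comparisons"
    try:
        rows = []
        pair_rows = []
        for fam_a, fam_b, host_type in config.host_comparisons:
            cmp_ = hostcomp.cross_family_pair_sharing(
                genome_sharing, meta, fam_a, fam_b, host_type
            )
            if cmp_.testable:
                cmp_.run_test()
            for stratum, pairs, values in (
                ("similar", cmp_.similar_pairs, cmp_.similar_values),
                ("dissimilar", cmp_.dissimilar_pairs, cmp_.dissimilar_values),
            ):
                for (va, vb), s in zip(pairs, values):
                    pair_rows.append(
                        {
                            "family_a": fam_a,
                            "family_b": fam_b,
                            "host_type": host_type,
                            "virus_a": va,
                            "virus_b": vb,
                            "stratum": stratum,
                            "sharing": s,
                        }
                    )
            rows.append(
                {
                    "family_a": fam_a,
                    "family_b": fam_b,
                    "host_type": host_type,
                    "n_similar": cmp_.n_similar,
                    "n_dissimilar": cmp_.n_dissimilar,
                    "U": cmp_.U_statistic,
                    "p_value": cmp_.p_value,
                    "testable": cmp_.testable,
                }
            )
        if config.host_comparisons:
            import pandas as pd

            p = outdir / "host_comparisons.tsv"
            pd.DataFrame(rows).to_csv(p, sep="\t", index=False, float_format="%.10g")
            record("host_comparisons", p)
            p = outdir / "host_comparison_pairs.tsv"
            pd.DataFrame(pair_rows).to_csv(
                p, sep="\t", index=False, float_format="%.10g"
            )
            record("host_comparison_pairs", p)
    except Exception as exc:
        fail(stage, exc)

    stage = "host_screens"
    try:
        for fam_a, fam_b, target, reference in config.host_screens:
            report = hostcomp.host_shared_orthogroups(
                counts, meta, fam_a, fam_b, target, reference, annotations=annotations
            )
            p = outdir / f"host_shared_{target}_vs_{reference}.tsv"
            report.to_csv(p, sep="\t", index=False, float_format="%.10g")
            record(f"host_shared_{target}_vs_{reference}", p)
    except Exception as exc:
        fail(stage, exc)

    _write_manifest(manifest, outdir)
    return manifest


def _write_manifest(manifest: dict[str, Any], outdir: Path) -> Path:
    p = outdir / "manifest.json"
    with open(p, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return p
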