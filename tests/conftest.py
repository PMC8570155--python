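"""Shared fixtures and independent brute-force oracles.

The oracles re-derive expected values by direct set enumeration /
double loops, deliberately avoiding the vectorized implementation paths
they are used to check.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from genesharenet.data_io import GenomeMeta, OrthogroupCatalog
from genesharenet.sharing import CountMatrix


# ---------------------------------------------------------------- oracles


def sharing_oracle(repertoires: dict[str, set[str]]):
    """Brute-force U, T, S from per-taxon orthogroup sets."""
    taxa = list(repertoires)
    T = {}
    for i in taxa:
        shared = {
            g
            for g in repertoires[i]
            if any(g in repertoires[j] for j in taxa if j != i)
        }
        T[i] = len(shared)
    U = {
        (i, j): len(repertoires[i] & repertoires[j])
        for i in taxa
        for j in taxa
    }
    S = {}
    for i in taxa:
        for j in taxa:
            if i == j:
                continue
            denom = math.sqrt(T[i] * T[j])
            S[(i, j)] = U[(i, j)] / denom if denom > 0 else 0.0
    return U, T, S


def host_screen_oracle(
    counts: pd.DataFrame,
    fam_of: dict[str, str],
    host_of: dict[str, str],
    fam_a: str,
    fam_b: str,
    target: str,
    reference: str,
):
    """Double-loop re-derivation of the host-shared orthogroup report."""
    rows = {}
    for g in counts.columns:
        strata = {}
        for fam in (fam_a, fam_b):
            for host in (target, reference):
                strata[(fam, host)] = [
                    v
                    for v in counts.index
                    if fam_of[v] == fam and host_of[v] == host
                ]
        shared = {}
        for host in (target, reference):
            ok = True
            for fam in (fam_a, fam_b):
                if not any(counts.loc[v, g] > 0 for v in strata[(fam, host)]):
                    ok = False
            shared[host] = ok
        if not (shared[target] and not shared[reference]):
            continue
        freqs = {}
        for host in (target, reference):
            fr = []
            for fam in (fam_a, fam_b):
                members = strata[(fam, host)]
                fr.append(
                    sum(counts.loc[v, g] > 0 for v in members) / len(members)
                )
            freqs[host] = sum(fr) / 2
        copy_means = []
        for fam in (fam_a, fam_b):
            carriers = [v for v in strata[(fam, target)] if counts.loc[v, g] > 0]
            if carriers:
                copy_means.append(
                    sum(counts.loc[v, g] for v in carriers) / len(carriers)
                )
        rows[g] = {
            "freq_target": freqs[target],
            "freq_reference": freqs[reference],
            "freq_diff": freqs[target] - freqs[reference],
            "mean_copy_number": sum(copy_means) / len(copy_means),
        }
    return rows


def random_count_matrix(rng: np.random.Generator, n_taxa=6, n_ogs=15) -> CountMatrix:
    """Random small count matrix with every orthogroup present somewhere."""
    counts = rng.integers(0, 3, size=(n_taxa, n_ogs))
    for j in range(n_ogs):  # spec invariant: no all-zero columns
        if counts[:, j].sum() == 0:
            counts[rng.integers(n_taxa), j] = 1
    taxa = [f"T{i}" for i in range(n_taxa)]
    ogs = [f"og{j}" for j in range(n_ogs)]
    return CountMatrix(
        pd.DataFrame(counts, index=pd.Index(taxa, name="taxon"), columns=ogs)
    )


# --------------------------------------------------------------- fixtures


@pytest.fixture
def tiny_meta() -> GenomeMeta:
    return GenomeMeta(
        pd.DataFrame(
            {
                "virus_id": ["V1", "V2", "V3"],
                "family": ["FamA", "FamA", "FamB"],
                "lineage": ["L1", "L2", "L3"],
                "host_type": ["vertebrate", "insect", "alga"],
                "host_supergroup": ["Opisthokonta", "Opisthokonta", "Archaeplastida"],
            }
        )
    )


@pytest.fixture
def tiny_catalog() -> OrthogroupCatalog:
    return OrthogroupCatalog(
        groups={
            "OG1": [("V1", "p1"), ("V1", "p2"), ("V2", "p3")],
            "OG2": [("V2", "p4"), ("V3", "p5")],
        },
        singletons=[("V3", "p9")],
        has_protein_index=True,
    )


@pytest.fixture(scope="session")
def sim_default():
    """One default-parameter simulated dataset, shared across tests."""
    from genesharenet.simulate import SimulationParams, simulate_dataset

    return simulate_dataset(SimulationParams(seed=42))
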