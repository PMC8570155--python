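"""Host-association comparative analyses.

Two questions are asked of a pair of virus families whose members infect
a mix of host types (e.g. Iridoviridae-Poxviridae over vertebrates and
insects, Mimiviridae-Phycodnaviridae over algae and amoebae):

1. Do cross-family virus pairs that infect the *same* host type share
   more orthogroups than pairs that do not?  All (a in famA, b in famB)
   pairs are split into "similar" (both infect the focal host type) and
   "dissimilar" (exactly one does); a one-sided Mann-Whitney-Wilcoxon
   test asks whether similar-host S values are stochastically greater.
   Comparing across families disentangles host association from
   phylogenetic relatedness.

2. Which orthogroups are behind that signal?  An orthogroup is
   "shared by the target host type" if at least one target-host virus of
   each family carries it; the screen reports orthogroups shared by the
   target host type but NOT by the reference host type, with carrier
   frequencies (averaged across the two families), their difference,
   and mean copy number among target-host carriers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb, sqrt
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import GenomeMeta
from .sharing import CountMatrix, SharingMatrix

__all__ = [
    "HostPairComparison",
    "cross_family_pair_sharing",
    "mww_one_sided",
    "host_shared_orthogroups",
    "presence_heatmap_matrix",
]

# exact permutation test up to this many similar x dissimilar products
EXACT_LIMIT = 400


@dataclass
class HostPairComparison:
    """Similar- vs dissimilar-host gene sharing across one family pair."""

    family_pair: tuple[str, str]
    host_type: str
    similar_values: list[float]
    dissimilar_values: list[float]
    similar_pairs: list[tuple[str, str]] = field(default_factory=list)
    dissimilar_pairs: list[tuple[str, str]] = field(default_factory=list)
    U_statistic: float | None = None
    p_value: float | None = None

    @property
    def n_similar(self) -> int:
        return len(self.similar_values)

    @property
    def n_dissimilar(self) -> int:
        return len(self.dissimilar_values)

    @property
    def testable(self) -> bool:
        return self.n_similar > 0 and self.n_dissimilar > 0

    def run_test(self, exact_limit: int = EXACT_LIMIT) -> "HostPairComparison":
        if not self.testable:
            raise ValueError(
                f"comparison {self.family_pair}/{self.host_type} is untestable: "
                f"n_similar={self.n_similar}, n_dissimilar={self.n_dissimilar}"
            )
        self.U_statistic, self.p_value = mww_one_sided(
            self.similar_values, self.dissimilar_values, exact_limit=exact_limit
        )
        return self


def cross_family_pair_sharing(
    sharing: SharingMatrix,
    meta: GenomeMeta,
    fam_a: str,
    fam_b: str,
    host_type: str,
) -> HostPairComparison:
    """Route every cross-family virus pair into similar/dissimilar bins.

    Pairs where neither virus infects ``host_type`` are excluded
    entirely (they say nothing about that host type).
    """
    fam_map = meta.family_map
    host_map = meta.host_type_map
    members_a = sorted(v for v, f in fam_map.items() if f == fam_a)
    members_b = sorted(v for v, f in fam_map.items() if f == fam_b)
    if not members_a or not members_b:
        empty = fam_a if not members_a else fam_b
        raise ValueError(f"family {empty!r} has no members in the metadata")

    S = sharing.S
    similar, dissimilar = [], []
    similar_pairs, dissimilar_pairs = [], []
    for a in members_a:
        for b in members_b:
            hits = (host_map[a] == host_type) + (host_map[b] == host_type)
            if hits == 2:
                similar.append(float(S.loc[a, b]))
                similar_pairs.append((a, b))
            elif hits == 1:
                dissimilar.append(float(S.loc[a, b]))
                dissimilar_pairs.append((a, b))
    return HostPairComparison(
        (fam_a, fam_b), host_type, similar, dissimilar, similar_pairs, dissimilar_pairs
    )


def _exact_greater_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact permutation p for 'x stochastically greater', via midranks.

    A shift-algorithm DP counts, over all C(n, nx) subsets of the pooled
    midranks, how many achieve a rank sum at least the observed one.
    Midranks are doubled to keep the DP integral; ties are thereby
    handled exactly.
    """
    pooled = np.concatenate([x, y])
    ranks2 = np.rint(2 * stats.rankdata(pooled)).astype(np.int64)
    nx_, n = len(x), len(pooled)
    observed = int(ranks2[:nx_].sum())
    total = int(ranks2.sum())
    # dp[k][s] = number of k-subsets with doubled-rank sum s
    dp = [np.zeros(total + 1, dtype=float) for _ in range(nx_ + 1)]
    dp[0][0] = 1.0
    for r in ranks2:
        for k in range(nx_, 0, -1):
            dp[k][r:] += dp[k - 1][: total + 1 - r]
    count_ge = float(dp[nx_][observed:].sum())
    return count_ge / comb(n, nx_)


def mww_one_sided(
    similar: list[float] | np.ndarray,
    dissimilar: list[float] | np.ndarray,
    exact_limit: int = EXACT_LIMIT,
) -> tuple[float, float]:
    """One-sided Mann-Whitney-Wilcoxon test (similar > dissimilar).

    Uses the exact permutation distribution of the midrank sum when
    n1*n2 <= ``exact_limit``; otherwise the normal approximation with
    tie-corrected variance and a 0.5 continuity correction.  Returns
    (U, one-sided p).
    """
    x = np.asarray(similar, dtype=float)
    y = np.asarray(dissimilar, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    r1 = ranks[:n1].sum()
    u = r1 - n1 * (n1 + 1) / 2.0

    if n1 * n2 <= exact_limit:
        p = _exact_greater_p(x, y)
    else:
        n = n1 + n2
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = float(((tie_counts**3 - tie_counts)).sum()) / (n * (n - 1))
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        if var <= 0:  # all values identical
            return float(u), 1.0
        z = (u - n1 * n2 / 2.0 - 0.5) / sqrt(var)
        p = float(stats.norm.sf(z))
    return float(u), float(min(p, 1.0))


def host_shared_orthogroups(
    matrix: CountMatrix,
    meta: GenomeMeta,
    fam_a: str,
    fam_b: str,
    target: str,
    reference: str,
    annotations: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Screen for orthogroups tied to the target host type.

    A row appears for every orthogroup present in >= 1 target-host virus
    of *each* family (shared-by-target) but not similarly shared by the
    reference-host viruses.  Columns:

    - freq_target / freq_reference: carrier fraction among the family's
      target-/reference-host viruses, averaged across the two families;
    - freq_diff = freq_target - freq_reference (sorted descending,
      ties by orthogroup id);
    - mean_copy_number: mean copy count among each family's target-host
      *carriers*, averaged over the families that have >= 1 carrier;
    - annotation: from the optional annotation table, else empty.
    """
    if matrix.level != "genome":
        raise ValueError("host screen requires a genome-level count matrix")
    fam_map = meta.family_map
    host_map = meta.host_type_map

    strata: dict[tuple[str, str], list[str]] = {}
    for fam in (fam_a, fam_b):
        for host in (target, reference):
            members = [
                v
                for v in matrix.taxa
                if fam_map.get(v) == fam and host_map.get(v) == host
            ]
            if not members:
                raise ValueError(
                    f"no {host!r}-host viruses in family {fam!r}: "
                    "screen precondition violated"
                )
            strata[(fam, host)] = members

    counts = matrix.counts
    presence = matrix.presence

    def shared_by(host: str) -> pd.Series:
        a = presence.loc[strata[(fam_a, host)]].any(axis=0)
        b = presence.loc[strata[(fam_b, host)]].any(axis=0)
        return a & b

    keep = shared_by(target) & ~shared_by(reference)
    ogs = [g for g in matrix.orthogroups if keep[g]]

    def freq(host: str, g: str) -> float:
        fr = [
            presence.loc[strata[(fam, host)], g].mean() for fam in (fam_a, fam_b)
        ]
        return float(np.mean(fr))

    rows = []
    for g in ogs:
        ft, fr = freq(target, g), freq(reference, g)
        copy_means = []
        for fam in (fam_a, fam_b):
            carriers = [v for v in strata[(fam, target)] if presence.loc[v, g]]
            if carriers:
                copy_means.append(float(counts.loc[carriers, g].mean()))
        rows.append(
            {
                "orthogroup_id": g,
                "freq_target": ft,
                "freq_reference": fr,
                "freq_diff": ft - fr,
                "mean_copy_number": float(np.mean(copy_means)),
                "annotation": (annotations or {}).get(g, ""),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "orthogroup_id",
            "freq_target",
            "freq_reference",
            "freq_diff",
            "mean_copy_number",
            "annotation",
        ],
    )
    return df.sort_values(
        ["freq_diff", "orthogroup_id"], ascending=[False, True]
    ).reset_index(drop=True)


def presence_heatmap_matrix(
    matrix: CountMatrix,
    orthogroups: list[str],
    taxon_order: list[str] | None = None,
) -> pd.DataFrame:
    """Orthogroups x genomes presence/absence block for external plotting.

    ``taxon_order`` (e.g. tip order of the core-gene tree) fixes the
    column order; unknown taxa raise.
    """
    taxa = taxon_order if taxon_order is not None else matrix.taxa
    missing = sorted(set(taxa) - set(matrix.taxa))
    if missing:
        raise ValueError(f"taxa not in count matrix: {missing}")
    return matrix.presence.loc[taxa, orthogroups].T.astype(int)
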