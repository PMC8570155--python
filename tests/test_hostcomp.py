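"""Similar/dissimilar host comparisons and the host-shared orthogroup screen."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from genesharenet.data_io import GenomeMeta
from genesharenet.hostcomp import (
    cross_family_pair_sharing,
    host_shared_orthogroups,
    mww_one_sided,
    presence_heatmap_matrix,
)
from genesharenet.sharing import CountMatrix, compute_sharing

from conftest import host_screen_oracle


def _meta(rows):
    return GenomeMeta(
        pd.DataFrame(
            rows,
            columns=["virus_id", "family", "lineage", "host_type", "host_supergroup"],
        )
    )


def _counts(presence: dict[str, set[str]]) -> CountMatrix:
    ogs = sorted({g for r in presence.values() for g in r})
    df = pd.DataFrame(
        [[1 if g in presence[t] else 0 for g in ogs] for t in presence],
        index=pd.Index(list(presence), name="taxon"),
        columns=ogs,
    )
    return CountMatrix(df)


FOUR_VIRUS_META = _meta(
    [
        ["a1", "FamA", "La1", "vertebrate", "Opisthokonta"],
        ["a2", "FamA", "La2", "insect", "Opisthokonta"],
        ["b1", "FamB", "Lb1", "vertebrate", "Opisthokonta"],
        ["b2", "FamB", "Lb2", "insect", "Opisthokonta"],
    ]
)


class TestPairRouting:
    def test_exhaustive_pair_enumeration(self):
        counts = _counts(
            {
                "a1": {"g1", "g2"},
                "a2": {"g2", "g3"},
                "b1": {"g1", "g3"},
                "b2": {"g2", "g3"},
            }
        )
        sh = compute_sharing(counts)
        cmp_ = cross_family_pair_sharing(
            sh, FOUR_VIRUS_META, "FamA", "FamB", "vertebrate"
        )
        assert cmp_.similar_pairs == [("a1", "b1")]
        assert set(cmp_.dissimilar_pairs) == {("a1", "b2"), ("a2", "b1")}
        # the insect-insect pair concerns neither stratum
        assert ("a2", "b2") not in cmp_.similar_pairs + cmp_.dissimilar_pairs
        assert cmp_.similar_values == [pytest.approx(float(sh.S.loc["a1", "b1"]))]

    def test_untestable_when_everyone_shares_host(self):
        meta = _meta(
            [
                ["a1", "FamA", "La1", "alga", "SAR"],
                ["b1", "FamB", "Lb1", "alga", "SAR"],
            ]
        )
        counts = _counts({"a1": {"g"}, "b1": {"g"}})
        cmp_ = cross_family_pair_sharing(
            compute_sharing(counts), meta, "FamA", "FamB", "alga"
        )
        assert cmp_.n_dissimilar == 0 and not cmp_.testable
        with pytest.raises(ValueError, match="untestable"):
            cmp_.run_test()

    def test_empty_family_rejected(self):
        counts = _counts({"a1": {"g"}, "b1": {"g"}})
        meta = _meta(
            [
                ["a1", "FamA", "La1", "alga", "SAR"],
                ["b1", "FamB", "Lb1", "alga", "SAR"],
            ]
        )
        with pytest.raises(ValueError, match="FamC"):
            cross_family_pair_sharing(
                compute_sharing(counts), meta, "FamA", "FamC", "alga"
            )


class TestMWW:
    def test_exact_p_one_sixth(self):
        # all C(4,2)=6 rank splits; only {3,4} reaches the observed sum
        u, p = mww_one_sided([3, 4], [1, 2])
        assert u == 4.0
        assert p == pytest.approx(1 / 6, abs=1e-5)

    def test_worst_ordering_p_one(self):
        _, p = mww_one_sided([1], [2])
        assert p == 1.0

    def test_complete_ties_p_one(self):
        _, p = mww_one_sided([5, 5, 5], [5, 5])
        assert p == 1.0
        _, p_norm = mww_one_sided([5.0] * 25, [5.0] * 25, exact_limit=0)
        assert p_norm == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mww_one_sided([], [1.0])

    def test_exact_matches_scipy_without_ties(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.normal(size=rng.integers(2, 8))
            y = rng.normal(size=rng.integers(2, 8))
            u, p = mww_one_sided(x, y)
            ref = stats.mannwhitneyu(x, y, alternative="greater", method="exact")
            assert u == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_exact_matches_permutation_with_ties(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            x = rng.integers(0, 4, size=5).astype(float)
            y = rng.integers(0, 4, size=6).astype(float)

            def statistic(x_, y_):
                r = stats.rankdata(np.concatenate([x_, y_]))
                return r[: len(x_)].sum()

            ref = stats.permutation_test(
                (x, y), statistic, permutation_type="independent",
                alternative="greater", n_resamples=np.inf,
            )
            _, p = mww_one_sided(x, y)
            assert p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_normal_branch_close_to_scipy_asymptotic(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0.3, 1, 25)
        y = rng.normal(0, 1, 30)
        _, p = mww_one_sided(x, y)  # 750 > 400 -> normal branch
        ref = stats.mannwhitneyu(x, y, alternative="greater", method="asymptotic")
        assert p == pytest.approx(ref.pvalue, rel=1e-9)


class TestHostScreen:
    def test_hand_worked_example(self):
        counts = _counts(
            {
                "a1": {"g1", "g2"},
                "a2": {"g2"},
                "b1": {"g1", "g3"},
                "b2": {"g3"},
            }
        )
        report = host_shared_orthogroups(
            counts, FOUR_VIRUS_META, "FamA", "FamB", "vertebrate", "insect"
        )
        assert list(report["orthogroup_id"]) == ["g1"]
        row = report.iloc[0]
        assert row["freq_target"] == 1.0
        assert row["freq_reference"] == 0.0
        assert row["freq_diff"] == 1.0
        assert row["mean_copy_number"] == 1.0

    def test_one_family_only_and_both_strata_excluded(self):
        counts = _counts(
            {
                "a1": {"gA", "gBoth"},  # gA in FamA target only
                "a2": {"gBoth"},
                "b1": {"gBoth"},
                "b2": {"gBoth"},
            }
        )
        report = host_shared_orthogroups(
            counts, FOUR_VIRUS_META, "FamA", "FamB", "vertebrate", "insect"
        )
        assert len(report) == 0

    def test_empty_stratum_rejected(self):
        meta = _meta(
            [
                ["a1", "FamA", "La1", "vertebrate", "Opisthokonta"],
                ["b1", "FamB", "Lb1", "vertebrate", "Opisthokonta"],
                ["b2", "FamB", "Lb2", "insect", "Opisthokonta"],
            ]
        )
        counts = _counts({"a1": {"g"}, "b1": {"g"}, "b2": {"g"}})
        with pytest.raises(ValueError, match="FamA"):
            host_shared_orthogroups(
                counts, meta, "FamA", "FamB", "vertebrate", "insect"
            )

    def test_swapped_direction_reports_are_disjoint(self):
        rng = np.random.default_rng(3)
        counts, meta = _random_screen_fixture(rng)
        fwd = host_shared_orthogroups(
            counts, meta, "FamA", "FamB", "vertebrate", "insect"
        )
        rev = host_shared_orthogroups(
            counts, meta, "FamA", "FamB", "insect", "vertebrate"
        )
        assert not set(fwd["orthogroup_id"]) & set(rev["orthogroup_id"])

    def test_matches_double_loop_oracle_on_random_fixtures(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            counts, meta = _random_screen_fixture(rng)
            report = host_shared_orthogroups(
                counts, meta, "FamA", "FamB", "vertebrate", "insect"
            )
            expected = host_screen_oracle(
                counts.counts, meta.family_map, meta.host_type_map,
                "FamA", "FamB", "vertebrate", "insect",
            )
            assert set(report["orthogroup_id"]) == set(expected)
            for _, row in report.iterrows():
                exp = expected[row["orthogroup_id"]]
                for col in ("freq_target", "freq_reference", "freq_diff",
                            "mean_copy_number"):
                    assert row[col] == pytest.approx(exp[col], abs=1e-12)
            # sorted by freq_diff descending, ties by orthogroup id
            key = list(zip(-report["freq_diff"], report["orthogroup_id"]))
            assert key == sorted(key)

    def test_copy_number_averages_only_carrier_families(self):
        counts = CountMatrix(
            pd.DataFrame(
                {"g1": [3, 0, 2, 0], "filler": [1, 1, 1, 1]},
                index=pd.Index(["a1", "a2", "b1", "b2"], name="taxon"),
            )
        )
        report = host_shared_orthogroups(
            counts, FOUR_VIRUS_META, "FamA", "FamB", "vertebrate", "insect"
        )
        row = report.set_index("orthogroup_id").loc["g1"]
        assert row["mean_copy_number"] == pytest.approx((3 + 2) / 2)


class TestHeatmapExport:
    def test_tree_order_and_shape(self):
        counts = _counts({"a1": {"g1"}, "a2": {"g1", "g2"}, "b1": {"g2"}})
        hm = presence_heatmap_matrix(counts, ["g2", "g1"], ["b1", "a2", "a1"])
        assert list(hm.columns) == ["b1", "a2", "a1"]
        assert list(hm.index) == ["g2", "g1"]
        assert hm.loc["g2", "b1"] == 1 and hm.loc["g2", "a1"] == 0

    def test_unknown_taxon_rejected(self):
        counts = _counts({"a1": {"g1"}, "a2": {"g1"}})
        with pytest.raises(ValueError, match="zz"):
            presence_heatmap_matrix(counts, ["g1"], ["a1", "zz"])


def _random_screen_fixture(rng):
    genomes, rows = [], []
    for fam in ("FamA", "FamB"):
        for host in ("vertebrate", "insect"):
            for k in range(rng.integers(1, 4)):
                vid = f"{fam}_{host[:4]}{k}"
                genomes.append(vid)
                rows.append([vid, fam, f"L_{vid}", host, "Opisthokonta"])
    meta = _meta(rows)
    ogs = [f"og{j}" for j in range(25)]
    counts = rng.integers(0, 3, size=(len(genomes), len(ogs)))
    for j in range(len(ogs)):
        if counts[:, j].sum() == 0:
            counts[rng.integers(len(genomes)), j] = 1
    cm = CountMatrix(
        pd.DataFrame(counts, index=pd.Index(genomes, name="taxon"), columns=ogs)
    )
    return cm, meta
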