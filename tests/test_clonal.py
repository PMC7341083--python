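"""Clonotype construction and entropy-index behavior."""

import numpy as np
import pandas as pd
import pytest
from oracle_utils import (
    expa_bruteforce,
    ptran_bruteforce,
    random_clonotype_table,
    shared_clones_bruteforce,
    tran_bruteforce,
)

from dptscope import clonal


class TestBuildClonotypes:
    def test_identical_cdr3_pairs_share_one_clonotype(self):
        contigs = pd.DataFrame(
            {
                "barcode": ["b1", "b1", "b2", "b2", "b3"],
                "chain": ["TRA", "TRB", "TRB", "TRA", "TRA"],
                "cdr3": ["CAVR", "CASS", "CASS", "CAVR", "CAXX"],
                "productive": [True] * 5,
            }
        )
        out = clonal.build_clonotypes(contigs)
        ids = out.set_index("barcode")["clonotype_id"]
        assert ids["b1"] == ids["b2"]
        assert ids["b3"] != ids["b1"]

    def test_clonotypes_are_patient_scoped(self):
        contigs = pd.DataFrame(
            {
                "barcode": ["b1", "b2"],
                "chain": ["TRB", "TRB"],
                "cdr3": ["CASS", "CASS"],
                "productive": [True, True],
            }
        )
        labels = pd.DataFrame({"barcode": ["b1", "b2"], "patient": ["P1", "P2"]})
        out = clonal.build_clonotypes(contigs, labels)
        assert out["clonotype_id"].nunique() == 2

    def test_unproductive_cells_dropped_and_counted(self):
        contigs = pd.DataFrame(
            {
                "barcode": ["b1", "b2"],
                "chain": ["TRB", "TRB"],
                "cdr3": ["CASS", "CAXX"],
                "productive": ["True", "False"],
            }
        )
        out = clonal.build_clonotypes(contigs)
        assert list(out["barcode"]) == ["b1"]
        assert out.attrs["n_dropped"] == 1

    def test_six_cells_three_cdr3_sets(self):
        contigs = pd.DataFrame(
            {
                "barcode": ["b1", "b2", "b3", "b4", "b5", "b6"],
                "chain": ["TRB"] * 6,
                "cdr3": ["X", "X", "X", "Y", "Y", "Z"],
                "productive": [True] * 6,
            }
        )
        out = clonal.build_clonotypes(contigs)
        sizes = sorted(out["clonotype_id"].value_counts())
        assert sizes == [1, 2, 3]


class TestExpa:
    @pytest.mark.parametrize(
        "sizes, expected",
        [
            ({"A": 1, "B": 1, "C": 1}, 0.0),          # maximal diversity
            ({"A": 5}, 1.0),                           # monoclonal convention
            ({"A": 3, "B": 1}, 1 - 0.5623351446188083 / np.log(2)),
        ],
    )
    def test_hand_computed_values(self, sizes, expected):
        rows = [(c, "K1") for c, n in sizes.items() for _ in range(n)]
        t = pd.DataFrame(rows, columns=["clonotype_id", "cluster"])
        got = clonal.startrac_expa(t)["expa"].iloc[0]
        assert got == pytest.approx(expected, abs=1e-12)

    def test_splitting_an_expanded_clone_decreases_expa(self):
        expanded = pd.DataFrame(
            {"clonotype_id": ["A"] * 6 + ["B", "C"], "cluster": "K1"}
        )
        split = expanded.copy()
        split["clonotype_id"] = [f"A{i}" for i in range(6)] + ["B", "C"]
        e1 = clonal.startrac_expa(expanded)["expa"].iloc[0]
        e2 = clonal.startrac_expa(split)["expa"].iloc[0]
        assert e2 < e1

    def test_bounded_on_random_tables(self, rng):
        for _ in range(20):
            t = random_clonotype_table(rng)
            e = clonal.startrac_expa(t)["expa"]
            assert ((e >= -1e-12) & (e <= 1 + 1e-12)).all()


class TestTran:
    def test_confined_clones_give_zero(self):
        t = pd.DataFrame(
            {"clonotype_id": ["A", "A", "B", "B"], "cluster": ["K1", "K1", "K2", "K2"]}
        )
        assert (clonal.startrac_tran(t)["tran"] == 0).all()

    def test_even_split_single_clone_gives_one(self):
        t = pd.DataFrame({"clonotype_id": ["A"] * 4, "cluster": ["K1", "K1", "K2", "K2"]})
        assert clonal.startrac_tran(t)["tran"].tolist() == [1.0, 1.0]

    def test_single_cluster_is_undefined(self, toy_clonotypes):
        with pytest.raises(clonal.ClonotypeError):
            clonal.startrac_tran(toy_clonotypes[toy_clonotypes["cluster"] == "K1"])

    def test_reassigning_a_confined_clone_increases_tran(self):
        confined = pd.DataFrame(
            {"clonotype_id": ["A"] * 4 + ["B"] * 2, "cluster": ["K1"] * 4 + ["K2"] * 2}
        )
        moved = confined.copy()
        moved.loc[3, "cluster"] = "K2"  # one cell of clone A crosses over
        t1 = clonal.startrac_tran(confined)["tran"]["K1"]
        t2 = clonal.startrac_tran(moved)["tran"]["K1"]
        assert t2 > t1


class TestPairwiseTran:
    def test_disjoint_clone_sets_give_zero(self):
        t = pd.DataFrame(
            {"clonotype_id": ["A", "A", "B", "B"], "cluster": ["K1", "K1", "K2", "K2"]}
        )
        assert clonal.pstartrac_tran(t, "K1", "K2") == 0.0

    def test_all_clones_split_evenly_give_one(self):
        t = pd.DataFrame(
            {
                "clonotype_id": ["A", "A", "B", "B"],
                "cluster": ["K1", "K2", "K1", "K2"],
            }
        )
        assert clonal.pstartrac_tran(t, "K1", "K2") == pytest.approx(1.0, abs=1e-12)

    def test_symmetry_on_random_tables(self, rng):
        for _ in range(30):
            t = random_clonotype_table(rng)
            clusters = sorted(set(t["cluster"]))
            a, b = clusters[0], clusters[1]
            assert clonal.pstartrac_tran(t, a, b) == pytest.approx(
                clonal.pstartrac_tran(t, b, a), abs=1e-15
            )


class TestOracleEquivalence:
    def test_indices_match_bruteforce(self, rng):
        for _ in range(25):
            t = random_clonotype_table(rng, max_cells=200)
            expa = clonal.startrac_expa(t)["expa"]
            for cl, v in expa_bruteforce(t).items():
                assert expa[cl] == pytest.approx(v, abs=1e-12)
            tran = clonal.startrac_tran(t)["tran"]
            for cl, v in tran_bruteforce(t).items():
                assert tran[cl] == pytest.approx(v, abs=1e-12)

    def test_shared_counts_match_set_intersections(self, rng):
        for _ in range(10):
            t = random_clonotype_table(rng, max_cells=200)
            got = clonal.shared_clone_counts(t)
            want = shared_clones_bruteforce(t)
            pd.testing.assert_frame_equal(
                got.astype(int), want.astype(int), check_names=False
            )

    def test_ptran_matches_bruteforce(self, rng):
        for _ in range(10):
            t = random_clonotype_table(rng, max_cells=150)
            clusters = sorted(set(t["cluster"]))
            got = clonal.pstartrac_tran(t, clusters[0], clusters[1])
            want = ptran_bruteforce(t, clusters[0], clusters[1])
            assert got == pytest.approx(want, abs=1e-12)


class TestSharing:
    def test_diagonal_equals_unique_clone_count(self, toy_clonotypes):
        shared = clonal.shared_clone_counts(toy_clonotypes)
        expa = clonal.startrac_expa(toy_clonotypes)
        for cl in shared.index:
            assert shared.loc[cl, cl] == expa.loc[cl, "n_clones"]

    def test_venn_regions_partition_clones(self, toy_clonotypes):
        regions = clonal.venn_regions(toy_clonotypes)
        assert sum(regions.values()) == toy_clonotypes["clonotype_id"].nunique()
        assert regions["TCD8T&TDPT"] == 1  # clone A spans both

    def test_merging_clusters_never_increases_offdiag_sharing(self, rng):
        for _ in range(10):
            t = random_clonotype_table(rng, max_cells=150)
            clusters = sorted(set(t["cluster"]))
            a, b = clusters[0], clusters[1]
            before = clonal.shared_clone_counts(t)
            merged = t.copy()
            merged.loc[merged["cluster"].isin([a, b]), "cluster"] = "AB"
            after = clonal.shared_clone_counts(merged)
            for other in clusters[2:]:
                union_before = len(
                    (set(t.loc[t["cluster"] == a, "clonotype_id"])
                     | set(t.loc[t["cluster"] == b, "clonotype_id"]))
                    & set(t.loc[t["cluster"] == other, "clonotype_id"])
                )
                assert after.loc["AB", other] == union_before
                assert after.loc["AB", other] <= before.loc[a, other] + before.loc[b, other]


class TestExpandedClones:
    def test_all_singletons_yield_empty_output(self):
        t = pd.DataFrame(
            {
                "clonotype_id": [f"c{i}" for i in range(20)],
                "cluster": "K1",
                "compartment": "TDPT",
            }
        )
        inc, pairs = clonal.expanded_clone_cooccurrence(t)
        assert inc.empty

    def test_threshold_is_strict(self):
        t = pd.DataFrame(
            {
                "clonotype_id": ["A"] * 10 + ["B"] * 11,
                "cluster": "K1",
                "compartment": ["TDPT"] * 10 + ["TDPT"] * 5 + ["TCD8T"] * 6,
            }
        )
        inc, pairs = clonal.expanded_clone_cooccurrence(t, min_freq=10)
        assert list(inc.index) == ["B"]  # size 10 excluded, size 11 kept
        assert pairs["TCD8T&TDPT"] == 1.0

    def test_split_clone_reports_both_compartments(self):
        t = pd.DataFrame(
            {
                "clonotype_id": ["A"] * 12,
                "cluster": "K1",
                "compartment": ["TDPT"] * 6 + ["TCD8T"] * 6,
            }
        )
        inc, pairs = clonal.expanded_clone_cooccurrence(t)
        assert bool(inc.loc["A", "TDPT"]) and bool(inc.loc["A", "TCD8T"])


class TestTopCloneProjection:
    def test_rank_matches_bruteforce_sort(self, rng):
        t = random_clonotype_table(rng, max_cells=200)
        out = clonal.top_clone_projection(t, n_top=4)
        sizes = t["clonotype_id"].value_counts()
        want = sorted(sizes.index, key=lambda c: (-sizes[c], c))[:4]
        assert list(out.columns) == want

    def test_zero_top_clones_highlights_nothing(self, toy_clonotypes):
        out = clonal.top_clone_projection(toy_clonotypes, n_top=0)
        assert out.shape[1] == 0

    def test_largest_clone_only(self, toy_clonotypes):
        out = clonal.top_clone_projection(toy_clonotypes, n_top=1)
        assert list(out.columns) == ["A"]
        assert out["A"].sum() == 3
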