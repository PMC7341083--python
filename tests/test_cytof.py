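"""Marker transform, gating, enrichment and coexpression."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dptscope import cytof, synthetic


class TestArcsinh:
    def test_closed_form(self):
        assert cytof.arcsinh_transform(np.array([0.0]))[0] == 0.0
        assert cytof.arcsinh_transform(np.array([5.0]), cofactor=5.0)[0] == pytest.approx(
            np.arcsinh(1.0)
        )

    def test_negative_values_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            out = cytof.arcsinh_transform(np.array([-1.0, 4.0]))
        assert out[0] == 0.0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        x1=st.floats(0, 1e4), delta=st.floats(1e-3, 1e4),
        cofactor=st.floats(0.1, 100),
    )
    def test_monotone(self, x1, delta, cofactor):
        y = cytof.arcsinh_transform(np.array([x1, x1 + delta]), cofactor=cofactor)
        assert y[1] > y[0]


class TestGating:
    def test_grid_of_four_cells_covers_all_compartments(self):
        m = pd.DataFrame(
            {"CD4": [2.0, 2.0, 0.1, 0.2], "CD8": [1.8, 0.1, 1.8, 0.2]}
        )
        g = cytof.gate_compartments(m, theta_cd4=1.0, theta_cd8=1.0)
        assert list(g.compartment) == ["DPT", "CD4SPT", "CD8SPT", "DNT"]

    def test_partition_is_exhaustive_and_exclusive(self, small_cohort):
        markers, _ = small_cohort
        g = cytof.gate_compartments(markers, theta_cd4=1.0, theta_cd8=1.0)
        assert not g.compartment.isna().any()
        assert set(g.compartment.unique()) <= set(cytof.COMPARTMENTS)

    def test_missing_marker_column_raises(self):
        with pytest.raises(KeyError):
            cytof.gate_compartments(pd.DataFrame({"CD4": [1.0]}))

    def test_gmm_threshold_separates_two_populations(self, rng):
        v = np.concatenate([rng.normal(0.2, 0.2, 2000), rng.normal(2.2, 0.3, 2000)])
        theta = cytof.gmm_threshold(v)
        assert 0.6 < theta < 1.8


class TestSubsetPhenotype:
    def test_empty_predicate_returns_whole_compartment(self, small_cohort):
        markers, _ = small_cohort
        g = cytof.gate_compartments(markers, 1.0, 1.0)
        cells = cytof.subset_phenotype(markers, g, "DPT")
        assert len(cells) == (g.compartment == "DPT").sum()

    def test_threshold_predicate_selects_exactly_matching_cells(self):
        m = pd.DataFrame(
            {
                "CD4": [2.0] * 10,
                "CD8": [2.0] * 10,
                "PD1": [0.1, 0.2, 2.0, 0.3, 2.5, 0.4, 3.0, 0.1, 0.6, 0.9],
            }
        )
        g = cytof.gate_compartments(m, 1.0, 1.0)
        cells = cytof.subset_phenotype(m, g, "DPT", {"PD1": 1.0})
        assert list(cells) == [2, 4, 6]

    def test_absent_predicate_marker_raises(self, small_cohort):
        markers, _ = small_cohort
        g = cytof.gate_compartments(markers, 1.0, 1.0)
        with pytest.raises(KeyError):
            cytof.subset_phenotype(markers, g, "DPT", {"NOPE": 1.0})


class TestFrequencies:
    def test_two_cluster_30_70_split(self):
        ann = pd.DataFrame({"patient": "p1", "region": "T"}, index=range(10))
        labels = pd.Series(["a"] * 3 + ["b"] * 7)
        f = cytof.cluster_region_frequencies(labels, ann)
        assert f.loc[("p1", "T"), "a"] == pytest.approx(0.3)
        assert f.loc[("p1", "T"), "b"] == pytest.approx(0.7)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_rows_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 200))
        ann = pd.DataFrame(
            {
                "patient": rng.choice(["p1", "p2"], n),
                "region": rng.choice(["T", "L", "N"], n),
            }
        )
        labels = pd.Series(rng.choice(["a", "b", "c"], n))
        f = cytof.cluster_region_frequencies(labels, ann)
        assert np.allclose(f.sum(axis=1), 1.0, atol=1e-9)


class TestEnrichment:
    def test_cluster_present_only_in_one_region(self):
        rows = []
        for p in range(5):
            for r in ("T", "L", "N"):
                n_x = 30 if r == "L" else 1
                rows += [(f"p{p}", r, "x")] * n_x + [(f"p{p}", r, "y")] * 70
        ann = pd.DataFrame(rows, columns=["patient", "region", "cluster"])
        f = cytof.cluster_region_frequencies(ann["cluster"], ann)
        res = cytof.assign_region_enrichment(f)
        assert res.loc["x", "region"] == "L"
        assert res.loc["x", "p_value"] < 0.05

    def test_uniform_cluster_gets_none_or_insignificant(self):
        rows = []
        for p in range(4):
            for r in ("T", "L", "N"):
                rows += [(f"p{p}", r, "x")] * 50 + [(f"p{p}", r, "y")] * 50
        ann = pd.DataFrame(rows, columns=["patient", "region", "cluster"])
        f = cytof.cluster_region_frequencies(ann["cluster"], ann)
        res = cytof.assign_region_enrichment(f)
        assert res.loc["x", "region"] == "none" or not res.loc["x", "significant"]

    def test_single_patient_flags_undefined_p(self):
        ann = pd.DataFrame(
            {"patient": "p1", "region": ["T"] * 5 + ["L"] * 5, "cluster": ["x"] * 10}
        )
        f = cytof.cluster_region_frequencies(ann["cluster"], ann)
        res = cytof.assign_region_enrichment(f)
        assert np.isnan(res.loc["x", "p_value"])

    def test_planted_leading_edge_enrichment_recovered(self, small_cohort):
        markers, ann = small_cohort
        f = cytof.cluster_region_frequencies(ann["population"], ann)
        res = cytof.assign_region_enrichment(f)
        assert res.loc["DPT_PD1pos", "region"] == "L"
        assert res.loc["DPT_PD1pos", "significant"]


class TestCoexpression:
    def test_diagonal_is_one_and_symmetric(self, small_cohort):
        markers, _ = small_cohort
        r, p = cytof.coexpression_matrix(markers[["CD4", "CD8", "PD1", "CD45RO"]])
        assert np.allclose(np.diag(r), 1.0)
        assert np.allclose(r, r.T)

    def test_planted_correlation_recovered_within_fisher_se(self, rng):
        rho = 0.23
        cov = [[1, rho], [rho, 1]]
        X = rng.multivariate_normal([0, 0], cov, size=10_000)
        m = pd.DataFrame(X, columns=["CD45RO", "TIM3"])
        r, _ = cytof.coexpression_matrix(m)
        assert r.loc["CD45RO", "TIM3"] == pytest.approx(rho, abs=0.03)

    def test_matches_bruteforce_covariance_formula(self, rng):
        m = pd.DataFrame(rng.normal(size=(50, 3)), columns=list("abc"))
        r, _ = cytof.coexpression_matrix(m)
        for i in "abc":
            for j in "abc":
                x, y = m[i].to_numpy(), m[j].to_numpy()
                want = ((x - x.mean()) * (y - y.mean())).mean() / (x.std() * y.std())
                assert r.loc[i, j] == pytest.approx(want, abs=1e-12)


class TestGroupComparison:
    def test_identical_groups_give_zero_t(self):
        t, p = cytof.compare_group_levels([1, 2, 3], [1, 2, 3])
        assert t == 0.0

    def test_hand_computed_pooled_t(self):
        t, p = cytof.compare_group_levels([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3.674, abs=1e-3)
        assert p == pytest.approx(0.0213, abs=1e-3)

    def test_abs_t_monotone_in_shift(self, rng):
        base = rng.normal(size=40)
        other = rng.normal(size=40)
        prev = 0.0
        for delta in (0.5, 1.0, 2.0, 4.0):
            t, _ = cytof.compare_group_levels(base, other + delta)
            assert abs(t) > prev
            prev = abs(t)


class TestSubsampling:
    def test_caps_cells_per_sample(self, small_cohort):
        markers, ann = small_cohort
        idx = cytof.subsample_per_sample(markers, ann, n=500, seed=0)
        kept = ann.loc[idx]
        assert kept.groupby(["patient", "region"], observed=True).size().max() <= 500

    def test_enrichment_stable_under_half_subsampling(self):
        cfg = synthetic.default_cohort_config(n_patients=6, cells_per_sample=1200, seed=11)
        markers, ann = synthetic.gen_cytof_cohort(cfg)
        f_full = cytof.cluster_region_frequencies(ann["population"], ann)
        full = cytof.assign_region_enrichment(f_full)["region"]
        changed = 0
        for rep in range(10):
            sub = ann.sample(frac=0.5, random_state=rep)
            f_sub = cytof.cluster_region_frequencies(sub["population"], sub)
            part = cytof.assign_region_enrichment(f_sub)["region"]
            changed += int(part["DPT_PD1pos"] != full["DPT_PD1pos"])
        assert changed == 0
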