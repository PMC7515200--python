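"""TR ranking, interaction matrices, correlation, burden, heatmap scaling."""

import numpy as np
import pandas as pd
import pytest

from enhancerlink.io import ExpressionMatrix, MethylationMatrix
from enhancerlink.network import (
    BurdenParams,
    RankingParams,
    heatmap_export,
    interaction_matrix,
    minmax_scale,
    rank_trs,
    sample_link_burden,
    shared_probe_fraction,
    tr_expression_correlation,
)


def _links(pairs, direction="activated"):
    return pd.DataFrame(
        [
            {"tr_gene": tr, "probe_id": p, "direction": direction,
             "n_group_low": 5, "n_group_high": 5, "statistic": 1.0,
             "raw_p": 0.001, "adjusted_p": 0.01}
            for tr, p in pairs
        ]
    )


class TestRankTrs:
    def test_empty_links_empty_table(self):
        out = rank_trs(pd.DataFrame(columns=["tr_gene", "probe_id", "direction"]))
        assert out.empty

    def test_toy_counting_and_ranks(self):
        out = rank_trs(_links([("A", "p1"), ("A", "p2"), ("B", "p1")]))
        a = out[out["tr_gene"] == "A"].iloc[0]
        b = out[out["tr_gene"] == "B"].iloc[0]
        assert (a["n_links"], a["rank"]) == (2, 1)
        assert (b["n_links"], b["rank"]) == (1, 2)

    def test_threshold_flags_exactly_qualifying_trs(self):
        pairs = (
            [("T1", f"p{i}") for i in range(60)]
            + [("T2", f"q{i}") for i in range(55)]
            + [("T3", f"r{i}") for i in range(12)]
        )
        out = rank_trs(_links(pairs), RankingParams(activated_min_links=50))
        assert list(out[out["flagged"]]["tr_gene"]) == ["T1", "T2"]

    def test_duplicate_probe_links_counted_once(self):
        out = rank_trs(_links([("A", "p1"), ("A", "p1")]))
        assert out.iloc[0]["n_links"] == 1


class TestInteractionMatrix:
    def test_single_tr_all_ones(self):
        links = _links([("A", "p1"), ("A", "p2"), ("A", "p3")])
        mat = interaction_matrix(links, ["A"])
        assert mat.shape == (3, 1) and (mat["A"] == 1).all()

    def test_row_sums_equal_per_probe_degree(self, rng):
        trs = [f"T{i}" for i in range(6)]
        pairs = set()
        while len(pairs) < 60:
            pairs.add((trs[rng.integers(6)], f"p{rng.integers(25)}"))
        links = _links(sorted(pairs))
        mat = interaction_matrix(links, trs)
        degree = links.groupby("probe_id")["tr_gene"].nunique()
        assert (mat.sum(axis=1) == degree.loc[mat.index]).all()

    def test_column_sums_reconcile_with_rank_table(self, rng):
        trs = [f"T{i}" for i in range(4)]
        pairs = {(trs[rng.integers(4)], f"p{rng.integers(30)}") for _ in range(50)}
        links = _links(sorted(pairs))
        mat = interaction_matrix(links, trs)
        ranks = rank_trs(links).set_index("tr_gene")
        for tr in trs:
            assert mat[tr].sum() == ranks.loc[tr, "n_links"]


class TestSharedProbeFraction:
    def test_three_quarters(self):
        links = _links(
            [("A", f"p{i}") for i in range(1, 5)]
            + [("B", "p1"), ("B", "p2"), ("C", "p3")]
        )
        assert shared_probe_fraction(links, "A", {"B", "C"}) == 0.75

    def test_full_containment_is_one(self):
        links = _links([("A", "p1"), ("B", "p1"), ("B", "p2")])
        assert shared_probe_fraction(links, "A", {"B"}) == 1.0

    def test_no_links_is_nan(self):
        links = _links([("B", "p1")])
        assert np.isnan(shared_probe_fraction(links, "A", {"B"}))

    def test_random_bipartite_matches_set_oracle(self, rng):
        trs = [f"T{i}" for i in range(5)]
        pairs = {(trs[rng.integers(5)], f"p{rng.integers(40)}") for _ in range(80)}
        links = _links(sorted(pairs))
        probes = {t: {p for tr, p in pairs if tr == t} for t in trs}
        for t in trs:
            others = set(trs) - {t}
            expected = len(
                probes[t] & set().union(*(probes[o] for o in others))
            ) / len(probes[t])
            assert shared_probe_fraction(links, t, others) == pytest.approx(expected)


class TestCorrelation:
    def _expr(self, arr, genes, samples):
        return ExpressionMatrix(
            values=pd.DataFrame(arr, index=genes, columns=samples),
            transform="log2p1",
        )

    def test_perfect_linear_r2_one(self):
        x = np.array([1.0, 2, 3, 4])
        e = self._expr(np.vstack([x, 2 * x]), ["a", "b"], list("wxyz"))
        r2 = tr_expression_correlation(e, ["a", "b"], list("wxyz"))
        assert r2.loc["a", "b"] == pytest.approx(1.0)

    def test_anticorrelation_r2_one(self):
        x = np.array([1.0, 2, 3, 4])
        e = self._expr(np.vstack([x, -x + 10]), ["a", "b"], list("wxyz"))
        r2 = tr_expression_correlation(e, ["a", "b"], list("wxyz"))
        assert r2.loc["a", "b"] == pytest.approx(1.0)

    def test_matches_covariance_formula(self, rng):
        arr = rng.normal(5, 1, size=(10, 30))
        genes = [f"g{i}" for i in range(10)]
        samples = [f"s{j}" for j in range(30)]
        r2 = tr_expression_correlation(self._expr(arr, genes, samples), genes, samples)
        for i in range(10):
            for j in range(10):
                xi, xj = arr[i], arr[j]
                num = ((xi - xi.mean()) * (xj - xj.mean())).sum()
                den = np.sqrt(
                    ((xi - xi.mean()) ** 2).sum() * ((xj - xj.mean()) ** 2).sum()
                )
                assert r2.iloc[i, j] == pytest.approx((num / den) ** 2, abs=1e-12)

    def test_symmetric_unit_diagonal_in_range(self, rng):
        arr = rng.normal(5, 1, size=(6, 20))
        genes = [f"g{i}" for i in range(6)]
        samples = [f"s{j}" for j in range(20)]
        r2 = tr_expression_correlation(self._expr(arr, genes, samples), genes, samples)
        assert np.allclose(r2, r2.T)
        assert np.allclose(np.diag(r2), 1.0)
        assert ((r2.values >= 0) & (r2.values <= 1 + 1e-12)).all()

    def test_zero_variance_gene_warns_and_nans(self, rng):
        arr = np.vstack([np.full(10, 3.0), rng.normal(size=10)])
        e = self._expr(arr, ["flat", "ok"], [f"s{j}" for j in range(10)])
        with pytest.warns(UserWarning, match="zero-variance"):
            r2 = tr_expression_correlation(e, ["flat", "ok"], [f"s{j}" for j in range(10)])
        assert np.isnan(r2.loc["flat", "ok"])


class TestBurden:
    def _beta(self, arr, probes, samples):
        return MethylationMatrix(beta=pd.DataFrame(arr, index=probes, columns=samples))

    def test_all_high_betas_zero_burden(self):
        beta = self._beta([[0.9], [0.9]], ["p1", "p2"], ["s1"])
        links = _links([("A", "p1"), ("A", "p2")])
        out = sample_link_burden(beta, links, ["A"], ["s1"])
        assert out.loc["s1", "burden"] == 0
        assert out.loc["s1", "subgroup"] == "no_link"

    def test_counting_two_of_three_links(self):
        beta = self._beta([[0.1], [0.2], [0.9]], ["p1", "p2", "p3"], ["s1"])
        links = _links([("A", "p1"), ("A", "p2"), ("A", "p3")])
        out = sample_link_burden(beta, links, ["A"], ["s1"])
        assert out.loc["s1", "burden"] == 2

    def test_probe_linked_to_two_trs_counts_twice(self):
        beta = self._beta([[0.1]], ["p1"], ["s1"])
        links = _links([("A", "p1"), ("B", "p1")])
        out = sample_link_burden(beta, links, ["A", "B"], ["s1"])
        assert out.loc["s1", "burden"] == 2

    def test_quantile_rule_on_spread_burdens(self, rng):
        # 100 samples with burdens 0..99: probes arranged so sample k is
        # hypomethylated at exactly k linked probes
        samples = [f"s{k:02d}" for k in range(100)]
        probes = [f"p{i:02d}" for i in range(99)]
        arr = np.ones((99, 100)) * 0.9
        for k in range(100):
            arr[: k, k] = 0.1
        beta = self._beta(arr, probes, samples)
        links = _links([("A", p) for p in probes])
        out = sample_link_burden(beta, links, ["A"], samples,
                                 BurdenParams(burden_quantile=0.90))
        threshold = np.quantile(np.arange(100), 0.90)
        expected = {s for k, s in enumerate(samples) if k >= threshold}
        assert set(out.index[out["subgroup"] == "highly_linked"]) == expected

    def test_burden_monotone_in_cutoff(self, default_bundle):
        b = default_bundle
        links = _links(
            list(map(tuple, b.truth_links[["tr_gene", "probe_id"]].values))
        )
        tumor = b.clinical.tumor_samples
        trs = list(b.truth_links["tr_gene"].unique())
        b1 = sample_link_burden(b.beta, links, trs, tumor,
                                BurdenParams(active_beta_cutoff=0.3))
        b2 = sample_link_burden(b.beta, links, trs, tumor,
                                BurdenParams(active_beta_cutoff=0.5))
        assert (b2["burden"] >= b1["burden"]).all()


class TestHeatmapScaling:
    def test_minmax_formula(self):
        assert np.allclose(minmax_scale([2, 4, 6]), [0, 0.5, 1])

    def test_zeros_replaced_by_min_nonzero_before_scaling(self):
        assert np.allclose(minmax_scale([0, 2, 4]), [0, 0, 1])

    def test_matches_direct_formula_on_random_vector(self, rng):
        x = rng.uniform(1, 9, size=50)
        lo, hi = x.min(), x.max()
        assert np.allclose(minmax_scale(x), (x - lo) / (hi - lo))

    def test_constant_covariate_scales_to_half_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            out = minmax_scale([3.0, 3.0, 3.0])
        assert np.allclose(out, 0.5)

    def test_heatmap_export_is_deterministic(self, rng):
        mat = pd.DataFrame(
            rng.random((12, 9)),
            index=[f"p{i}" for i in range(12)],
            columns=[f"s{j}" for j in range(9)],
        )
        b1 = heatmap_export(mat)
        b2 = heatmap_export(mat)
        assert b1["row_order"] == b2["row_order"]
        assert b1["col_order"] == b2["col_order"]
        assert b1["matrix"].equals(b2["matrix"])
        # betas exported raw
        assert set(b1["matrix"].index) == set(mat.index)
        assert np.allclose(
            b1["matrix"].loc[mat.index, mat.columns].to_numpy(), mat.to_numpy()
        )
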