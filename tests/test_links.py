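"""Link engine: grouping, rank-sum test, BH, planted recovery, symmetry."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from enhancerlink.classify import classify_probes
from enhancerlink.io import ClinicalTable, ExpressionMatrix, MethylationMatrix
from enhancerlink.links import (
    LinkParams,
    adjust_bh,
    find_links,
    n_tests,
    permutation_z_test,
    rank_sum_test,
    split_tumor_groups,
)
from enhancerlink.simulate import FixtureConfig, PlantedTr, generate_fixture

from oracles import bh_stepup, enum_ranksum_p


class TestSplitGroups:
    def test_direct_thresholding(self):
        betas = pd.Series({"s1": 0.1, "s2": 0.3, "s3": 0.5, "s4": 0.9})
        params = LinkParams(group_low_cutoff=0.4, group_high_cutoff=0.8)
        low, high = split_tumor_groups(betas, params)
        assert low == ["s1", "s2"] and high == ["s4"]

    def test_all_intermediate_gives_empty_groups(self):
        betas = pd.Series({"s1": 0.5, "s2": 0.5})
        low, high = split_tumor_groups(betas, LinkParams())
        assert low == [] and high == []

    def test_random_betas_match_set_comprehension(self, rng):
        betas = pd.Series(rng.random(200), index=[f"s{i}" for i in range(200)])
        params = LinkParams(group_low_cutoff=0.35, group_high_cutoff=0.75)
        low, high = split_tumor_groups(betas, params)
        assert set(low) == {s for s, v in betas.items() if v < 0.35}
        assert set(high) == {s for s, v in betas.items() if v > 0.75}


class TestRankSum:
    def test_identical_multisets_not_significant(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        _, p = rank_sum_test(a, a + 1e-9, side="greater")
        assert p >= 0.5

    def test_complete_separation_exact_p(self):
        a = np.array([10.0, 11, 12, 13, 14])
        b = np.array([1.0, 2, 3, 4, 5])
        _, p = rank_sum_test(a, b, side="greater")
        assert p == pytest.approx(1 / 252, abs=1e-15)

    def test_exact_p_equals_enumeration_8v8(self, rng):
        a = rng.normal(size=8)
        b = rng.normal(size=8)
        for side in ("greater", "less"):
            _, p = rank_sum_test(a, b, side=side)
            assert p == pytest.approx(enum_ranksum_p(a, b, side), abs=1e-12)

    def test_exact_p_equals_enumeration_all_small_sizes(self, rng):
        # every group-size split with pooled size up to 12
        for n in range(2, 13):
            for na in range(1, n):
                vals = rng.permutation(np.arange(n, dtype=float) + rng.random(n))
                a, b = vals[:na], vals[na:]
                _, p = rank_sum_test(a, b, side="greater")
                assert p == pytest.approx(
                    enum_ranksum_p(a, b, "greater"), abs=1e-12
                ), (n, na)


class TestBh:
    def test_closed_form_triple(self):
        assert np.allclose(adjust_bh([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert adjust_bh([0.2])[0] == pytest.approx(0.2)

    def test_matches_independent_step_up_on_random_vectors(self, rng):
        for _ in range(100):
            p = rng.random(rng.integers(1, 40))
            assert np.allclose(adjust_bh(p), bh_stepup(p), atol=1e-12)


def _mini_fixture(rng, n_tumor=60, shift=2.0, mirror=False):
    """One TR driving 20 probes in a 10-normal / n_tumor bundle, built by
    hand so the planted truth is explicit."""
    n_normal = 10
    samples = [f"N{i}" for i in range(n_normal)] + [f"T{i}" for i in range(n_tumor)]
    affected = rng.choice(n_tumor, size=n_tumor // 2, replace=False)
    probes = [f"cg{i:03d}" for i in range(20)]
    beta = np.clip(rng.normal(0.9, 0.03, size=(20, n_normal + n_tumor)), 0, 1)
    for i in range(20):
        beta[i, n_normal + affected] = np.clip(
            rng.normal(0.2, 0.05, size=len(affected)), 0, 1
        )
    genes = ["TRX"] + [f"bg{i}" for i in range(9)]
    expr = 2.0 ** rng.normal(5, 1, size=(10, n_normal + n_tumor))
    expr[0, n_normal + affected] *= 2.0**shift
    if mirror:
        beta = 1.0 - beta
    clinical = ClinicalTable(
        data=pd.DataFrame(
            {
                "sample_id": samples,
                "group": ["normal"] * n_normal + ["tumor"] * n_tumor,
                "time": 100.0,
                "event": 0,
            }
        )
    )
    return (
        ExpressionMatrix(values=pd.DataFrame(expr, index=genes, columns=samples)),
        MethylationMatrix(beta=pd.DataFrame(beta, index=probes, columns=samples)),
        clinical,
        genes,
    )


class TestFindLinks:
    def test_planted_tr_links_all_recovered(self, rng):
        expr, beta, clinical, genes = _mini_fixture(rng)
        classes = classify_probes(beta, clinical)
        assert (classes["class"] == "hypomethylated").all()
        links = find_links(expr, beta, classes, genes, clinical, LinkParams(seed=0))
        planted = links[links["tr_gene"] == "TRX"]
        assert set(planted["probe_id"]) == set(beta.probe_ids)
        assert (planted["direction"] == "activated").all()

    def test_null_tr_produces_few_false_links(self, rng):
        expr, beta, clinical, genes = _mini_fixture(rng, shift=0.0)
        classes = classify_probes(beta, clinical)
        links = find_links(expr, beta, classes, genes, clinical, LinkParams(seed=0))
        total = n_tests(beta, classes, genes, clinical, expr)
        assert total == 20 * 10
        assert len(links) <= 0.05 * total

    def test_mirrored_fixture_gives_mirrored_directions(self, rng):
        seed_rng = np.random.default_rng(77)
        expr, beta, clinical, genes = _mini_fixture(seed_rng)
        seed_rng = np.random.default_rng(77)
        _, beta_m, clinical_m, _ = _mini_fixture(seed_rng, mirror=True)
        # full mirror: flip betas AND reverse every gene's expression ranks
        # (reciprocal is positive and strictly rank-reversing)
        expr_m = ExpressionMatrix(values=1.0 / expr.values)
        classes = classify_probes(beta, clinical)
        classes_m = classify_probes(beta_m, clinical_m)
        params = LinkParams(group_low_cutoff=0.4, group_high_cutoff=0.8, seed=0)
        # mirrored cutoffs: beta -> 1 - beta swaps the group thresholds
        params_m = LinkParams(group_low_cutoff=0.2, group_high_cutoff=0.6, seed=0)
        links = find_links(expr, beta, classes, genes, clinical, params)
        links_m = find_links(expr_m, beta_m, classes_m, genes, clinical_m, params_m)
        act = links[links["direction"] == "activated"]
        inact = links_m[links_m["direction"] == "inactivated"]
        assert set(map(tuple, act[["tr_gene", "probe_id"]].values)) == set(
            map(tuple, inact[["tr_gene", "probe_id"]].values)
        )

    def test_byte_identical_given_same_seed(self, rng):
        expr, beta, clinical, genes = _mini_fixture(rng)
        classes = classify_probes(beta, clinical)
        params = LinkParams(test="permutation_z", n_permutations=200, seed=42)
        t1 = find_links(expr, beta, classes, genes, clinical, params)
        t2 = find_links(expr, beta, classes, genes, clinical, params)
        assert t1.to_csv() == t2.to_csv()

    def test_link_count_monotone_in_alpha(self, rng):
        expr, beta, clinical, genes = _mini_fixture(rng, shift=0.8)
        classes = classify_probes(beta, clinical)
        counts = [
            len(find_links(expr, beta, classes, genes, clinical,
                           LinkParams(alpha=a, seed=0)))
            for a in (0.01, 0.05, 0.2)
        ]
        assert counts[0] <= counts[1] <= counts[2]


class TestPermutationVariant:
    def test_converges_to_ranksum_ordering(self, rng):
        # p-value ranking across 100 pairs agrees between the two tests
        wilcoxon_p, perm_p = [], []
        perm_rng = np.random.default_rng(5)
        for _ in range(100):
            shift = rng.uniform(0, 0.8)
            a = rng.normal(shift, 1, size=12)
            b = rng.normal(0, 1, size=12)
            _, wp = rank_sum_test(a, b, side="greater")
            _, pp = permutation_z_test(a, b, "greater", 8000, perm_rng)
            wilcoxon_p.append(wp)
            perm_p.append(pp)
        rho = stats.spearmanr(wilcoxon_p, perm_p).statistic
        assert rho > 0.99
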