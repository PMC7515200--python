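"""Target-gene nomination: windows, DE, TAD co-membership, knockdown."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from enhancerlink.io import ClinicalTable, ExpressionMatrix, TssRecord, ValidationError
from enhancerlink.targets import (
    TadRegion,
    TargetSearchParams,
    de_upregulated,
    genes_within_window,
    integrate_knockdown,
    map_targets,
    same_tad,
    validate_tads,
)

from oracles import welch_t


class TestWindow:
    def test_900kb_included(self):
        tss = [TssRecord("g1", "chr1", 5_900_000, "+")]
        out = genes_within_window("chr1", 5_000_000, tss)
        assert list(out["gene_id"]) == ["g1"]
        assert out.iloc[0]["distance_bp"] == 900_000

    def test_1100kb_excluded(self):
        tss = [TssRecord("g1", "chr1", 6_100_000, "+")]
        out = genes_within_window("chr1", 5_000_000, tss)
        assert out.empty

    def test_other_chromosome_excluded(self):
        tss = [TssRecord("g1", "chr2", 5_000_100, "+")]
        assert genes_within_window("chr1", 5_000_000, tss).empty

    def test_min_distance_over_transcripts(self):
        tss = [
            TssRecord("g1", "chr1", 5_100_000, "+", "t1"),
            TssRecord("g1", "chr1", 5_050_000, "+", "t2"),
        ]
        out = genes_within_window("chr1", 5_000_000, tss)
        assert out.iloc[0]["distance_bp"] == 50_000

    def test_random_pairs_match_all_pairs_brute_force(self, rng):
        tss = [
            TssRecord(f"g{i}", "chr1", int(rng.integers(0, 10**7)), "+")
            for i in range(100)
        ]
        params = TargetSearchParams(window_bp=500_000)
        for _ in range(10):
            pos = int(rng.integers(0, 10**7))
            got = set(genes_within_window("chr1", pos, tss, params)["gene_id"])
            expected = {
                t.gene_id for t in tss if abs(t.position - pos) <= 500_000
            }
            assert got == expected

    def test_candidates_monotone_in_window(self, rng):
        tss = [
            TssRecord(f"g{i}", "chr1", int(rng.integers(0, 10**6)), "+")
            for i in range(50)
        ]
        sizes = [
            len(genes_within_window("chr1", 500_000, tss,
                                    TargetSearchParams(window_bp=w)))
            for w in (10_000, 100_000, 1_000_000)
        ]
        assert sizes[0] <= sizes[1] <= sizes[2]


def _expr_clinical(rng, n_tumor=30, n_normal=30, shift_genes=(), shift=2.0):
    samples = [f"N{i}" for i in range(n_normal)] + [f"T{i}" for i in range(n_tumor)]
    genes = [f"g{i}" for i in range(20)]
    log_vals = rng.normal(5, 0.5, size=(20, len(samples)))
    for g in shift_genes:
        log_vals[genes.index(g), n_normal:] += shift
    expr = ExpressionMatrix(
        values=pd.DataFrame(log_vals, index=genes, columns=samples),
        transform="log2p1",
    )
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
    return expr, clinical


class TestDeUpregulated:
    def test_identical_distributions_not_flagged(self, rng):
        expr, clinical = _expr_clinical(rng)
        out = de_upregulated(expr, clinical)
        assert not out["upregulated"].any()

    def test_planted_shift_flagged(self, rng):
        expr, clinical = _expr_clinical(rng, shift_genes=("g3", "g7"))
        out = de_upregulated(expr, clinical)
        assert out.loc["g3", "upregulated"] and out.loc["g7", "upregulated"]

    def test_welch_t_matches_closed_form_3v3(self):
        x = np.array([4.0, 5.0, 6.5])
        y = np.array([1.0, 2.0, 2.5])
        t = stats.ttest_ind(x, y, equal_var=False).statistic
        assert t == pytest.approx(welch_t(x, y), abs=1e-12)
        # the module's table reports the same statistic
        samples = [f"N{i}" for i in range(3)] + [f"T{i}" for i in range(3)]
        expr = ExpressionMatrix(
            values=pd.DataFrame([list(y) + list(x)], index=["g"], columns=samples),
            transform="log2p1",
        )
        clinical = ClinicalTable(
            data=pd.DataFrame(
                {
                    "sample_id": samples,
                    "group": ["normal"] * 3 + ["tumor"] * 3,
                    "time": 1.0,
                    "event": 0,
                }
            )
        )
        out = de_upregulated(expr, clinical)
        assert out.loc["g", "t"] == pytest.approx(welch_t(x, y), abs=1e-12)


class TestSameTad:
    TADS = [
        TadRegion("chr1", 100, 1000, source="A"),
        TadRegion("chr1", 1000, 2000, source="A"),
    ]

    def test_both_inside_one_tad(self):
        assert same_tad("chr1", 150, "chr1", 900, self.TADS)

    def test_adjacent_tads_false(self):
        assert not same_tad("chr1", 900, "chr1", 1100, self.TADS)

    def test_outside_all_tads_false(self):
        assert not same_tad("chr1", 50, "chr1", 60, self.TADS)

    def test_symmetric_in_arguments(self, rng):
        for _ in range(50):
            a, b = int(rng.integers(0, 2500)), int(rng.integers(0, 2500))
            assert same_tad("chr1", a, "chr1", b, self.TADS) == same_tad(
                "chr1", b, "chr1", a, self.TADS
            )

    def test_random_fixture_matches_containment_scan(self, rng):
        tads = [
            TadRegion("chr1", s, s + 500, source="A")
            for s in range(0, 10_000, 700)
        ]
        for _ in range(100):
            a, b = int(rng.integers(0, 10_000)), int(rng.integers(0, 10_000))
            expected = any(
                t.start <= a < t.end and t.start <= b < t.end for t in tads
            )
            assert same_tad("chr1", a, "chr1", b, tads) == expected

    def test_overlapping_tads_rejected(self):
        with pytest.raises(ValidationError, match="overlap"):
            validate_tads(
                [TadRegion("chr1", 0, 100, "A"), TadRegion("chr1", 50, 150, "A")]
            )


class TestKnockdown:
    def _candidates(self, genes):
        return pd.DataFrame(
            {"probe_id": "p1", "gene_id": genes, "distance_bp": 100_000}
        )

    def test_published_style_downregulation_supported(self):
        # ~40% reduction (log2fc -0.74) at adjusted p 2.5e-7
        table = pd.DataFrame(
            {"gene_id": ["TK1"], "log2fc": [-0.74], "adjusted_p": [2.506e-7]}
        ).set_index("gene_id", drop=False)
        out = integrate_knockdown(self._candidates(["TK1"]), {"MYBL2": table})
        assert out.iloc[0]["knockdown_support"] == "MYBL2"

    def test_insignificant_p_is_none(self):
        table = pd.DataFrame(
            {"gene_id": ["gA"], "log2fc": [-1.0], "adjusted_p": [0.2]}
        ).set_index("gene_id", drop=False)
        out = integrate_knockdown(self._candidates(["gA"]), {"E1": table})
        assert out.iloc[0]["knockdown_support"] == "none"

    def test_upregulated_gene_is_none(self):
        table = pd.DataFrame(
            {"gene_id": ["gA"], "log2fc": [1.0], "adjusted_p": [1e-9]}
        ).set_index("gene_id", drop=False)
        out = integrate_knockdown(self._candidates(["gA"]), {"E1": table})
        assert out.iloc[0]["knockdown_support"] == "none"

    def test_absent_gene_is_none_and_two_hits_multiple(self):
        t1 = pd.DataFrame(
            {"gene_id": ["gA"], "log2fc": [-1.0], "adjusted_p": [1e-5]}
        ).set_index("gene_id", drop=False)
        t2 = t1.copy()
        out = integrate_knockdown(
            self._candidates(["gA", "gB"]), {"E1": t1, "E2": t2}
        )
        assert out.iloc[0]["knockdown_support"] == "multiple"
        assert out.iloc[1]["knockdown_support"] == "none"


class TestMapTargetsAudit:
    def test_full_table_rederivable_from_inputs(self, small_bundle):
        b = small_bundle
        probes = b.truth_probes[b.truth_probes["planted_tr"] != ""].head(10)
        table = map_targets(
            probes[["probe_id", "chrom", "position"]],
            b.tss,
            b.expr,
            b.clinical,
            tads_by_source=b.tads,
            de_tables=b.de_tables,
        )
        assert not table.empty
        de = de_upregulated(b.expr, b.clinical)
        params = TargetSearchParams()
        tss_by_gene = {}
        for t in b.tss:
            tss_by_gene.setdefault(t.gene_id, []).append(t)
        probe_pos = probes.set_index("probe_id")["position"]
        for _, row in table.iterrows():
            pos = int(probe_pos[row["probe_id"]])
            d = min(
                abs(pos - t.position)
                for t in tss_by_gene[row["gene_id"]]
                if t.chrom == "chr1"
            )
            assert d == row["distance_bp"] <= params.window_bp
            assert row["upregulated"] == bool(
                de["upregulated"].get(row["gene_id"], False)
            )
            for source, tads in b.tads.items():
                expected = any(
                    same_tad("chr1", pos, t.chrom, t.position, tads)
                    for t in tss_by_gene[row["gene_id"]]
                )
                assert row[f"same_tad_{source}"] == expected

    def test_planted_target_genes_upregulated_and_supported(self, small_bundle):
        b = small_bundle
        tr = b.config.planted_activated_trs[0].tr_gene
        planted = b.truth_probes[b.truth_probes["planted_tr"] == tr]
        table = map_targets(
            planted[["probe_id", "chrom", "position"]],
            b.tss,
            b.expr,
            b.clinical,
            tads_by_source=b.tads,
            de_tables=b.de_tables,
        )
        # the gene adjacent to each planted probe is upregulated in tumors
        # and downregulated in that TR's knockdown table
        adjacent = {
            f"G{i % b.config.n_genes:04d}"
            for i in planted.index
        }
        sub = table[table["gene_id"].isin(adjacent)]
        assert not sub.empty
        # upregulation is a statistical call (BH near-misses possible with
        # few normals); knockdown support is deterministic in the fixture
        up_by_gene = sub.groupby("gene_id")["upregulated"].first()
        assert up_by_gene.mean() >= 0.9
        assert (sub["knockdown_support"] != "none").all()
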