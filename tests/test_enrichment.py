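"""Fisher over-representation, ontology level projection, bin crosstabs."""

import math

import numpy as np
import pandas as pd
import pytest

from hetexpr.enrichment import (
    OntologyGraph,
    crosstab_bins,
    fisher_enrichment,
    project_to_level,
    propagate_annotations,
)
from hetexpr.errors import ContractViolation, DataError
from hetexpr.simulate import (
    SimulationConfig,
    generate_gene_models,
    hybrid_specific_truth,
    plant_expression,
    plant_go_annotations,
)


def _hypergeom_tail_oracle(a, N, K, n):
    """P(X >= a) by direct binomial-coefficient summation."""
    denom = math.comb(N, n)
    hi = min(K, n)
    return sum(math.comb(K, k) * math.comb(N - K, n - k) for k in range(a, hi + 1)) / denom


class TestFisher:
    def test_term_annotating_everything_is_not_enriched(self):
        test = {"a", "b"}
        ref = {"a", "b", "c", "d"}
        ann = {t: {"GO:1"} for t in ref}
        df = fisher_enrichment(test, ref, ann)
        assert df.loc[0, "p_value"] == pytest.approx(1.0)

    def test_matches_tail_enumeration(self):
        # 8/10 annotated in test vs 10/100 in the reference remainder
        test = {f"t{i}" for i in range(10)}
        ref_only = {f"r{i}" for i in range(100)}
        ann = {f"t{i}": {"GO:X"} for i in range(8)}
        ann.update({f"r{i}": {"GO:X"} for i in range(10)})
        df = fisher_enrichment(test, test | ref_only, ann).set_index("term_id")
        assert df.loc["GO:X", "p_value"] == pytest.approx(
            _hypergeom_tail_oracle(8, 110, 18, 10), rel=1e-12
        )
        assert df.loc["GO:X", ["test_in", "test_out", "ref_in", "ref_out"]].tolist() == [
            8, 2, 10, 90,
        ]

    def test_identical_proportions_not_significant(self):
        test = {f"t{i}" for i in range(20)}
        ref_only = {f"r{i}" for i in range(80)}
        ann = {f"t{i}": {"GO:X"} for i in range(10)}
        ann.update({f"r{i}": {"GO:X"} for i in range(40)})
        df = fisher_enrichment(test, test | ref_only, ann)
        assert df.loc[0, "p_value"] >= 0.5

    def test_empty_test_set_rejected(self):
        with pytest.raises(ContractViolation):
            fisher_enrichment(set(), {"a"}, {"a": {"GO:1"}})

    def test_test_set_must_be_subset(self):
        with pytest.raises(ContractViolation):
            fisher_enrichment({"z"}, {"a"}, {"a": {"GO:1"}})

    def test_oracle_equivalence_small_universe(self):
        # every 2x2 table with N <= 20 against the enumeration oracle
        from scipy import stats as sps

        for N in range(1, 21):
            for K in range(N + 1):
                for n in range(N + 1):
                    lo = max(0, n - (N - K))
                    for a in range(lo, min(K, n) + 1):
                        assert sps.hypergeom.sf(a - 1, N, K, n) == pytest.approx(
                            _hypergeom_tail_oracle(a, N, K, n), rel=1e-9, abs=1e-300
                        )


class TestOntology:
    @pytest.fixture()
    def diamond(self):
        return OntologyGraph.from_edges(
            [("a", "root"), ("b", "root"), ("t", "a"), ("t", "b")]
        )

    def test_levels_min_depth(self, diamond):
        assert diamond.level("root") == 1
        assert diamond.level("a") == 2
        assert diamond.level("t") == 3

    def test_root_projects_to_itself(self, diamond):
        assert diamond.project("root", 1) == {"root"}

    def test_child_of_root_projects_to_itself_at_level_2(self, diamond):
        assert diamond.project("a", 2) == {"a"}

    def test_diamond_projects_to_both_branches(self, diamond):
        assert diamond.project("t", 2) == {"a", "b"}

    def test_term_above_requested_level_maps_to_nothing(self, diamond):
        assert diamond.project("root", 2) == frozenset()

    def test_cycle_rejected(self):
        with pytest.raises(DataError):
            OntologyGraph.from_edges([("a", "b"), ("b", "a"), ("b", "root")])

    def test_projection_idempotent(self, diamond):
        ann = {"x": {"t"}, "y": {"a", "t"}}
        once = project_to_level(ann, diamond, 2)
        twice = project_to_level(once, diamond, 2)
        assert once == twice
        assert once["x"] == {"a", "b"}

    def test_unknown_term_warns_and_skips(self, diamond, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="hetexpr.enrichment"):
            out = project_to_level({"x": {"GO:missing", "t"}}, diamond, 2)
        assert out["x"] == {"a", "b"}
        assert any("GO:missing" in rec.message for rec in caplog.records)

    def test_from_obo_reads_is_a_edges(self, tmp_path):
        obo = tmp_path / "mini.obo"
        obo.write_text(
            "format-version: 1.2\n\n"
            "[Term]\nid: GO:0000001\nname: root\n\n"
            "[Term]\nid: GO:0000002\nname: a\nis_a: GO:0000001 ! root\n\n"
            "[Term]\nid: GO:0000003\nname: t\nis_a: GO:0000002 ! a\n"
            "relationship: part_of GO:0000001 ! ignored\n"
        )
        g = OntologyGraph.from_obo(str(obo))
        assert g.level("GO:0000003") == 3
        assert g.parents["GO:0000003"] == {"GO:0000002"}  # part_of ignored

    def test_true_path_propagation(self, diamond):
        out = propagate_annotations({"x": {"t"}}, diamond)
        assert out["x"] == {"t", "a", "b", "root"}

    def test_propagation_feeds_fisher(self, diamond):
        # leaf annotations should count for the parent term as well
        test = {"x1", "x2"}
        ref = test | {f"r{i}" for i in range(20)}
        ann = {"x1": {"t"}, "x2": {"t"}}
        df = fisher_enrichment(test, ref, ann, ontology=diamond).set_index("term_id")
        assert df.loc["a", "test_in"] == 2


class TestPlantedEnrichment:
    def test_planted_term_has_tiny_p(self):
        # background 5%, factor 5, test ~200+, reference ~10,000
        cfg = SimulationConfig(
            n_genes=6200, frac_null=0.6, library_size=500_000, seed=31
        )
        models = generate_gene_models(cfg)
        truth, _ = plant_expression(models, cfg)
        ann, enriched = plant_go_annotations(
            models, truth, n_terms=30, enrichment_factor=5.0, seed=31,
            background_rate=0.05, n_enriched=3,
        )
        test = set(hybrid_specific_truth(truth))
        assert len(test) >= 200
        df = fisher_enrichment(test, set(truth.index), ann).set_index("term_id")
        for term in enriched:
            assert df.loc[term, "p_value"] < 1e-6
            assert df.loc[term, "enriched"]

    def test_null_annotations_rarely_flagged(self):
        cfg = SimulationConfig(n_genes=700, frac_null=0.5, seed=13)
        models = generate_gene_models(cfg)
        truth, _ = plant_expression(models, cfg)
        test = set(hybrid_specific_truth(truth))
        flagged = terms = 0
        for rep in range(25):
            ann, enriched = plant_go_annotations(
                models, truth, n_terms=40, enrichment_factor=1.0, seed=1000 + rep
            )
            assert enriched == []
            df = fisher_enrichment(test, set(truth.index), ann)
            flagged += int(df["enriched"].sum())
            terms += len(df)
        rate = flagged / terms
        assert rate <= 0.01 + 3 * np.sqrt(0.01 * 0.99 / terms)


class TestCrosstab:
    def test_empty_terms_give_headed_empty_table(self):
        bins = pd.DataFrame(columns=["transcript_id", "bin"])
        out = crosstab_bins({}, bins)
        assert list(out.columns) == ["Up1", "Up2", "Down1", "Down2", "FDR"]
        assert len(out) == 0

    def test_counts_per_bin(self):
        bins = pd.DataFrame(
            {
                "transcript_id": ["a", "b", "c", "d"],
                "bin": ["Up2", "Up1", "Down2", None],
            }
        )
        out = crosstab_bins(
            {"GO:1": {"a", "b", "c", "d"}}, bins, fdrs={"GO:1": 0.002}
        )
        assert out.loc["GO:1", ["Up1", "Up2", "Down1", "Down2"]].tolist() == [1, 1, 0, 1]
        assert out.loc["GO:1", "FDR"] == 0.002
        assert out.loc["Total", "Up2"] == 1

    def test_two_entries_per_transcript_counted(self):
        # one row per parental comparison: both contribute
        bins = pd.DataFrame(
            {"transcript_id": ["a", "a"], "bin": ["Up2", "Up1"]}
        )
        out = crosstab_bins({"GO:1": {"a"}}, bins)
        assert out.loc["GO:1", "Up1"] == 1 and out.loc["GO:1", "Up2"] == 1
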