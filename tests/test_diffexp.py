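"""Single-library differential test, fold changes, BH FDR and call_de."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hetexpr.diffexp import (
    adjust_fdr,
    call_de,
    compute_fold_change,
    effective_library_sizes,
)
from hetexpr.diffexp import test_differential as differential_test
from hetexpr.errors import ConfigError, ContractViolation
from hetexpr.quantify import ExpressionTable
from hetexpr.simulate import (
    SimulationConfig,
    generate_gene_models,
    plant_expression,
    sample_counts,
)


class TestTestDifferential:
    def test_no_counts_no_evidence(self):
        p, direction = differential_test(0, 1000, 0, 1000)
        assert p == 1.0 and direction == "none"

    def test_perfectly_balanced(self):
        p, _ = differential_test(100, 10_000, 100, 10_000)
        assert p >= 0.9

    def test_extreme_imbalance(self):
        p, direction = differential_test(0, 10_000, 100, 10_000)
        assert p < 1e-20  # exact binomial tail 2 * 0.5**100
        assert direction == "down_in_a"

    def test_zero_total_rejected(self):
        with pytest.raises(ContractViolation):
            differential_test(1, 0, 1, 100)

    @settings(max_examples=100, derandomize=True)
    @given(
        a=st.integers(0, 300),
        b=st.integers(0, 300),
        ta=st.integers(1, 10**6),
        tb=st.integers(1, 10**6),
        phi=st.sampled_from([1.0, 2.5, 10.0]),
    )
    def test_symmetry_under_sample_swap(self, a, b, ta, tb, phi):
        p_ab, _ = differential_test(a, ta, b, tb, overdispersion=phi)
        p_ba, _ = differential_test(b, tb, a, ta, overdispersion=phi)
        assert p_ab == pytest.approx(p_ba, rel=1e-12)
        assert 0 <= p_ab <= 1

    def test_overdispersion_weakens_evidence(self):
        p1, _ = differential_test(150, 10_000, 50, 10_000, overdispersion=1.0)
        p5, _ = differential_test(150, 10_000, 50, 10_000, overdispersion=5.0)
        assert p5 > p1


class TestFoldChange:
    def test_equal_levels(self):
        assert compute_fold_change(4.2, 4.2) == 0.0

    def test_log_identity(self):
        assert compute_fold_change(np.e**2 * 50.0, 50.0, pseudo_fpkm=1e-9) == pytest.approx(
            2.0, abs=1e-3
        )

    def test_zero_expression_stays_finite(self):
        assert compute_fold_change(0.0, 10.0, pseudo_fpkm=0.1) == pytest.approx(
            np.log(0.1 / 10.1)
        )


class TestAdjustFdr:
    def test_single_p(self):
        assert adjust_fdr([0.04])[0] == pytest.approx(0.04)

    def test_step_up_by_hand(self):
        assert adjust_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_all_ones(self):
        assert adjust_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ContractViolation):
            adjust_fdr([0.5, 1.5])

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=30))
    def test_matches_hand_rolled_bh(self, ps):
        # independent step-up oracle
        p = np.asarray(ps)
        m = len(p)
        order = np.argsort(p, kind="stable")
        ranked = p[order] * m / np.arange(1, m + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(ranked, 1.0)
        assert adjust_fdr(p) == pytest.approx(expected, rel=1e-12)
        assert (adjust_fdr(p) >= p - 1e-15).all()


class TestEffectiveLibrarySizes:
    def test_total_method_returns_column_sums(self, tiny_expression):
        sizes = effective_library_sizes(tiny_expression.counts, method="total")
        pd.testing.assert_series_equal(
            sizes, tiny_expression.counts.sum(axis=0).astype(float)
        )

    def test_mode_method_tracks_unchanged_majority(self):
        # a third of transcripts strongly up in H; the unchanged majority
        # should set the size factors, which stay ~equal
        rng = np.random.default_rng(3)
        base = rng.integers(100, 1000, size=400).astype(float)
        counts = pd.DataFrame({"H": base.copy(), "P1": base.copy(), "P2": base.copy()})
        counts.loc[:132, "H"] *= 8
        counts = counts.apply(lambda c: rng.poisson(c))
        sizes = effective_library_sizes(counts, method="ratio_mode")
        ratio = sizes["H"] / sizes["P1"]
        assert 0.8 < ratio < 1.25

    def test_unknown_method_rejected(self, tiny_expression):
        with pytest.raises(ConfigError):
            effective_library_sizes(tiny_expression.counts, method="magic")


class TestCallDe:
    def _expr_from_counts(self, counts):
        counts.index.name = "transcript_id"
        lengths = pd.Series(1000, index=counts.index)
        genes = pd.Series(counts.index.str.replace("t", "g"), index=counts.index)
        return ExpressionTable.from_counts(counts, lengths, genes)

    def test_identical_samples_no_calls(self):
        counts = pd.DataFrame(
            {"H": [50, 80, 10], "P1": [50, 80, 10], "P2": [50, 80, 10]},
            index=pd.Index(["t1", "t2", "t3"]),
        )
        de = call_de(self._expr_from_counts(counts))
        assert not de["significant"].any()

    def test_planted_extreme_called_in_hybrid_comparisons_only(self):
        rng = np.random.default_rng(11)
        n = 60
        base = rng.integers(50, 200, size=n)
        counts = pd.DataFrame(
            {"H": base, "P1": base, "P2": base},
            index=pd.Index([f"t{i}" for i in range(n)]),
        ).apply(lambda c: rng.poisson(c))
        counts.loc["t0"] = [1000, 10, 10]
        de = call_de(self._expr_from_counts(counts)).set_index(
            ["transcript_id", "comparison"]
        )
        assert de.loc[("t0", "H_vs_P1"), "significant"]
        assert de.loc[("t0", "H_vs_P2"), "significant"]
        assert not de.loc[("t0", "P1_vs_P2"), "significant"]
        assert de.loc[("t0", "H_vs_P1"), "direction"] == "up_in_hybrid"
        assert de.loc[("t0", "H_vs_P1"), "ln_ratio"] < 0

    def test_missing_sample_rejected(self):
        counts = pd.DataFrame({"H": [1], "P1": [1]}, index=pd.Index(["t1"]))
        lengths = pd.Series(1000, index=counts.index)
        expr = ExpressionTable(
            counts=counts, fpkm=counts.astype(float), lengths=lengths,
            gene_ids=pd.Series("g", index=counts.index), totals=counts.sum(),
        )
        with pytest.raises(ConfigError):
            call_de(expr)

    def test_null_type_one_error_controlled(self):
        # all-null simulation: raw rejections at most alpha within 3 SE
        cfg = SimulationConfig(n_genes=350, frac_null=1.0, library_size=200_000, seed=5)
        models = generate_gene_models(cfg)
        _, means = plant_expression(models, cfg)
        lengths = pd.Series({m.transcript_id: m.length for m in models})
        genes = pd.Series({m.transcript_id: m.gene_id for m in models})
        rng = np.random.default_rng(17)
        rejections, n_tests = 0, 0
        for _ in range(15):
            counts = sample_counts(means, models, cfg, rng=rng)
            de = call_de(ExpressionTable.from_counts(counts, lengths, genes))
            rejections += int((de["p_value"] <= 0.05).sum())
            n_tests += len(de)
        frac = rejections / n_tests
        se = np.sqrt(0.05 * 0.95 / n_tests)
        assert frac <= 0.05 + 3 * se

    def test_power_on_planted_effects(self):
        # delta = 2 log-units, library 1e6, dispersion 0.1: planted non-null
        # transcripts should be called wherever their true means differ
        cfg = SimulationConfig(n_genes=500, seed=23)
        models = generate_gene_models(cfg)
        truth, means = plant_expression(models, cfg)
        counts = sample_counts(means, models, cfg)
        lengths = pd.Series({m.transcript_id: m.length for m in models})
        genes = pd.Series({m.transcript_id: m.gene_id for m in models})
        de = call_de(ExpressionTable.from_counts(counts, lengths, genes))
        sig = de.pivot(index="transcript_id", columns="comparison", values="significant")
        pairs = {"H_vs_P1": ("true_mean_fpkm_H", "true_mean_fpkm_P1"),
                 "H_vs_P2": ("true_mean_fpkm_H", "true_mean_fpkm_P2"),
                 "P1_vs_P2": ("true_mean_fpkm_P1", "true_mean_fpkm_P2")}
        hits, wanted = 0, 0
        for comp, (ca, cb) in pairs.items():
            differs = truth[ca] != truth[cb]
            wanted += int(differs.sum())
            hits += int(sig.loc[truth.index[differs], comp].sum())
        assert hits / wanted >= 0.90
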