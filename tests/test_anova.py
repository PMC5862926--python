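"""g-prior linear models: design coding, marginal likelihoods, model BFs."""

import math

import numpy as np
import pytest

import defaultbf as d
from defaultbf.anova import (GPriorSettings, ModelSpec, _GIntegrand,
                             _log_bf_importance, _log_bf_quadrature,
                             build_design, marginal_likelihood, model_bf)
from defaultbf.ttest import TTestSufficientStats


def one_factor_model(name="factor", random=()):
    return ModelSpec(frozenset({(name,)}), random_factors=frozenset(random))


class TestBuildDesign:
    def test_k_level_factor_gives_k_minus_1_columns(self, hair_color):
        y, blocks = build_design(hair_color, "Pain Tolerance",
                                 one_factor_model("Hair Color"))
        assert blocks[("Hair Color",)].shape == (19, 3)

    def test_sum_to_zero_on_balanced_replication(self):
        table = d.generate(d.SimSpec(design="oneway", n=6, levels=(4,), seed=0))
        _, blocks = build_design(table, "y", one_factor_model())
        np.testing.assert_allclose(blocks[("factor",)].sum(axis=0),
                                   0.0, atol=1e-10)

    def test_two_level_factor_single_pm_column(self):
        table = d.generate(d.SimSpec(design="two_group", n=4, seed=0))
        _, blocks = build_design(table, "y", one_factor_model("group"))
        col = blocks[("group",)][:, 0]
        assert set(np.round(np.abs(col), 12)) == {round(1 / math.sqrt(2), 12)}
        assert col.sum() == pytest.approx(0.0, abs=1e-12)

    def test_full_model_spans_cell_means_space(self):
        """mains + interaction columns span the same space as cell dummies."""
        table = d.generate(d.SimSpec(design="factorial", n=5,
                                     levels=(3, 2), seed=1))
        model = ModelSpec(frozenset({("f1",), ("f2",), ("f1", "f2")}))
        y, blocks = build_design(table, "y", model)
        x = np.concatenate([np.ones((len(y), 1))]
                           + [blocks[t] for t in model.sorted_terms], axis=1)
        cells = np.zeros((len(y), 6))
        f1 = table.column("f1")
        f2 = table.column("f2")
        labels = sorted(set(zip(f1, f2)))
        for i, lab in enumerate(zip(f1, f2)):
            cells[i, labels.index(lab)] = 1.0
        assert np.linalg.matrix_rank(x) == np.linalg.matrix_rank(cells) == 6
        assert np.linalg.matrix_rank(np.concatenate([x, cells], axis=1)) == 6

    def test_single_level_factor_rejected(self):
        table = d.DataTable({"y": [1.0, 2.0, 3.0], "f": ["a", "a", "a"]},
                            {"y": "continuous", "f": "nominal"})
        with pytest.raises(d.DataError, match="fewer than 2 levels"):
            build_design(table, "y", one_factor_model("f"))

    def test_empty_interaction_cell_rejected(self):
        table2 = d.DataTable(
            {"y": [1.0, 2.0, 3.0, 1.5, 2.5, 3.5],
             "a": ["a1", "a1", "a2"] * 2,
             "b": ["b1", "b2", "b1"] * 2},
            {"y": "continuous", "a": "nominal", "b": "nominal"})
        model = ModelSpec(frozenset({("a",), ("b",), ("a", "b")}))
        with pytest.raises(d.DataError, match="empty cell"):
            build_design(table2, "y", model)


class TestModelSpec:
    def test_marginality_enforced(self):
        with pytest.raises(ValueError, match="marginality"):
            ModelSpec(frozenset({("a", "b")}))
        ModelSpec(frozenset({("a",), ("b",), ("a", "b")}))  # fine

    def test_nuisance_must_be_included(self):
        with pytest.raises(ValueError):
            ModelSpec(frozenset({("a",)}), nuisance=frozenset({("b",)}))


class TestMarginalLikelihood:
    def test_hair_color_bayes_factor(self, hair_color):
        res = d.run_anova(hair_color, "Pain Tolerance", fixed=["Hair Color"])
        assert res.comparison[1].bf10 == pytest.approx(11.97, rel=0.03)

    def test_null_vs_itself_is_one(self, hair_color):
        null = ModelSpec(frozenset())
        bf = model_bf(hair_color, "Pain Tolerance", null, null)
        assert bf.log_bf10 == 0.0
        assert bf.error_pct is None

    def test_balanced_two_group_equals_jzs_ttest(self):
        """One-factor g-prior BF (r=0.5) == JZS t-test BF (r=0.707)."""
        table = d.generate(d.SimSpec(design="two_group", n=24, seed=3,
                                     delta=0.4))
        y, blocks = build_design(table, "y", one_factor_model("group"))
        est = marginal_likelihood(y, blocks, GPriorSettings(r_fixed=0.5))
        null = marginal_likelihood(y, {}, GPriorSettings())
        report = d.jzs_ttest_from_table(
            table, "y", "group",
            d.EffectSizePrior("cauchy", math.sqrt(2) * 0.5))
        assert est.log_ml - null.log_ml == pytest.approx(
            report.bf.log_bf10, abs=1e-3)

    def test_importance_sampling_agrees_with_quadrature(self):
        table = d.generate(d.SimSpec(design="oneway", n=10, levels=(3,),
                                     seed=7, effects=(0.5, 0.0, -0.5)))
        y, blocks = build_design(table, "y", one_factor_model())
        core = _GIntegrand(y, blocks, [0.5])
        log_quad, _ = _log_bf_quadrature(core)
        log_mc, rel_err = _log_bf_importance(core, GPriorSettings(seed=9))
        assert abs(math.exp(log_mc - log_quad) - 1.0) < 3 * max(rel_err, 1e-3)

    def test_seeded_estimates_bit_reproducible(self):
        table = d.generate(d.SimSpec(design="factorial", n=10,
                                     levels=(2, 2), seed=4))
        model = ModelSpec(frozenset({("f1",), ("f2",)}))
        y, blocks = build_design(table, "y", model)
        settings = GPriorSettings(seed=42, mc_samples=2000)
        a = marginal_likelihood(y, blocks, settings)
        b = marginal_likelihood(y, blocks, settings)
        assert a.log_ml == b.log_ml
        assert a.mc_error_pct == b.mc_error_pct

    def test_response_rescaling_leaves_bf_invariant(self):
        table = d.generate(d.SimSpec(design="oneway", n=12, levels=(3,), seed=6))
        model = one_factor_model()
        y, blocks = build_design(table, "y", model)
        settings = GPriorSettings(seed=5)
        base = marginal_likelihood(y, blocks, settings)
        null = marginal_likelihood(y, {}, settings)
        y2 = 3.7 * y + 11.0
        scaled = marginal_likelihood(y2, blocks, settings)
        null2 = marginal_likelihood(y2, {}, settings)
        assert (base.log_ml - null.log_ml) == pytest.approx(
            scaled.log_ml - null2.log_ml, abs=1e-6)

    def test_pure_noise_factor_usually_disfavored(self):
        """A spurious factor should yield BF < 1 in at least 90% of replicates."""
        favored = 0
        reps = 100
        for seed in range(reps):
            table = d.generate(d.SimSpec(design="two_group", n=50, seed=seed))
            y, blocks = build_design(table, "y", one_factor_model("group"))
            est = marginal_likelihood(y, blocks)
            null = marginal_likelihood(y, {})
            favored += (est.log_ml - null.log_ml) < 0
        assert favored >= 90

    def test_insufficient_observations_rejected(self):
        rngy = np.random.default_rng(0)
        y = rngy.normal(size=4)
        blocks = {("f",): rngy.normal(size=(4, 3))}
        with pytest.raises(d.DataError):
            marginal_likelihood(y, blocks)


class TestSingersTwoWay:
    """The classic 2x4 singers design: published reference values."""

    def test_interaction_bf_via_nuisance(self, singers):
        base = ModelSpec(frozenset({("Gender",), ("Pitch",)}),
                         nuisance=frozenset({("Gender",), ("Pitch",)}))
        full = ModelSpec(frozenset({("Gender",), ("Pitch",),
                                    ("Gender", "Pitch")}),
                         nuisance=base.nuisance)
        bf = model_bf(singers, "Height", full, base,
                      GPriorSettings(seed=8, mc_samples=20000))
        assert bf.bf10 == pytest.approx(0.108, rel=0.05)

    def test_log_additivity(self, singers):
        settings = GPriorSettings(seed=2, mc_samples=5000)
        base = ModelSpec(frozenset({("Gender",)}),
                         nuisance=frozenset({("Gender",)}))
        full = ModelSpec(frozenset({("Gender",), ("Pitch",)}),
                         nuisance=base.nuisance)
        bf = model_bf(singers, "Height", full, base, settings)
        mls = []
        for spec in (full, base):
            y, blocks = build_design(singers, "Height", spec)
            mls.append(marginal_likelihood(y, blocks, settings).log_ml)
        assert bf.log_bf10 == pytest.approx(mls[0] - mls[1], abs=1e-12)


class TestRepeatedMeasures:
    def test_within_design_runs_and_orders_effects(self):
        wide = d.generate(d.SimSpec(design="within", n=30, seed=12,
                                    levels=(2, 2), subject_sd=1.0))
        res = d.run_rm_anova(
            wide,
            {"A": ["a1", "a2"], "B": ["b1", "b2"]},
            {"f1l1_f2l1": ("a1", "b1"), "f1l1_f2l2": ("a1", "b2"),
             "f1l2_f2l1": ("a2", "b1"), "f1l2_f2l2": ("a2", "b2")},
            GPriorSettings(seed=1, mc_samples=2000))
        assert len(res.comparison) == 5
        assert res.comparison[0].model.name() == "Null model"
        # subject term present in every model, including the null
        assert all(("subject",) in row.model.terms for row in res.comparison)
        probs = [row.posterior_prob for row in res.comparison]
        assert sum(probs) == pytest.approx(1.0, abs=1e-10)
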