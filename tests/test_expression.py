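import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from icfp.expression import (
    DifferentialCall,
    ExpressionSeries,
    ExpressionTransformError,
    VarianceModeration,
    call_differential,
    classify_by_fold_change,
    classify_series_route,
    estimate_fdr,
    map_to_reactions,
    merge_gene_protein,
    preprocess,
    threshold_regression_test,
)
from icfp.fixtures import synthetic_expression
from icfp.network import CarbonArcTable, Metabolite, MetabolicNetwork, Reaction
from icfp.gpr import parse_gpr

CONDITIONS = np.linspace(0.1, 0.45, 8)


def series(values, conditions=CONDITIONS, kind="gene", fid="f1", log2=True):
    return ExpressionSeries(fid, kind, np.asarray(conditions, float),
                            np.asarray(values, float), log2_scale=log2)


class TestPreprocess:
    def test_short_series_routed_to_invariant_pool(self):
        s = series([1.0, 2.0, np.nan, np.nan, np.nan, np.nan, np.nan, 3.0])
        kept, invariant = preprocess([s], {"f1"})
        assert kept == [] and invariant == {"f1"}

    def test_non_metabolic_feature_dropped_entirely(self):
        s = series(np.ones(8))
        kept, invariant = preprocess([s], {"other_gene"})
        assert kept == [] and invariant == set()

    def test_full_series_kept(self):
        s = series(np.arange(8.0))
        kept, invariant = preprocess([s], {"f1"})
        assert [k.feature_id for k in kept] == ["f1"] and invariant == set()

    def test_raw_values_log2_transformed_once(self):
        s = series([4.0] * 8, log2=False)
        kept, _ = preprocess([s], {"f1"})
        assert np.allclose(kept[0].values, 2.0)
        assert kept[0].log2_scale

    def test_non_positive_raw_value_raises(self):
        s = series([1.0, -2.0] + [1.0] * 6, log2=False)
        with pytest.raises(ExpressionTransformError, match="f1"):
            preprocess([s], {"f1"})


class TestThresholdRegression:
    def test_flat_series_gives_p_one_sign_zero(self):
        p, sign = threshold_regression_test(series([3.0] * 8))
        assert p == 1.0 and sign == 0

    def test_noiseless_large_effect_significant_positive(self):
        # planted change of 2.0 log2 units across the range, no noise
        values = 2.0 * (CONDITIONS - CONDITIONS[0]) / (
            CONDITIONS[-1] - CONDITIONS[0]
        )
        p, sign = threshold_regression_test(series(values))
        assert sign == 1
        assert p < 0.05

    def test_effect_exactly_at_threshold_is_never_significant(self):
        # fitted change == log2(1.5): the right tail is P(t > 0) = 1/2
        tau = math.log2(1.5)
        rng = np.random.default_rng(7)
        for _ in range(5):
            noise = rng.normal(0, 0.1, 8)
            resid = noise - np.polyval(np.polyfit(CONDITIONS, noise, 1), CONDITIONS)
            values = tau * (CONDITIONS - CONDITIONS[0]) / (
                CONDITIONS[-1] - CONDITIONS[0]
            ) + resid
            p, sign = threshold_regression_test(series(values))
            assert p >= 0.5
            assert sign == 1

    def test_matches_independent_ols_computation(self):
        """Dual route: statsmodels OLS + explicit t tails."""
        sm = pytest.importorskip("statsmodels.api")
        from scipy import stats

        rng = np.random.default_rng(3)
        values = 1.3 * CONDITIONS + rng.normal(0, 0.3, 8)
        p, sign = threshold_regression_test(series(values))

        fit = sm.OLS(values, sm.add_constant(CONDITIONS)).fit()
        delta = fit.params[1] * (CONDITIONS[-1] - CONDITIONS[0])
        se = fit.bse[1] * (CONDITIONS[-1] - CONDITIONS[0])
        tau = math.log2(1.5)
        expected = stats.t.sf((abs(delta) - tau) / se, 6) + stats.t.sf(
            (abs(delta) + tau) / se, 6
        )
        assert p == pytest.approx(min(1.0, expected), rel=1e-10)
        assert sign == int(np.sign(fit.params[1]))

    def test_zero_residual_variance_limiting_test(self):
        big = 3.0 * (CONDITIONS - CONDITIONS[0])  # exact line, change 1.05 > tau
        p, sign = threshold_regression_test(series(big))
        assert p == 0.0 and sign == 1
        tiny = 0.1 * (CONDITIONS - CONDITIONS[0])  # exact line, change below tau
        p, sign = threshold_regression_test(series(tiny))
        assert p == 1.0 and sign == 1

    def test_constant_condition_design_gives_no_direction(self):
        p, sign = threshold_regression_test(
            series(np.arange(8.0), conditions=np.ones(8))
        )
        assert p == 1.0 and sign == 0

    def test_too_few_points_raises(self):
        with pytest.raises(ValueError):
            threshold_regression_test(series([1, 2, 3], conditions=[1, 2, 3]))

    def test_moderation_pulls_small_variances_up(self):
        rng = np.random.default_rng(0)
        # fitted change well above the threshold, nearly noiseless fit:
        # widening the variance can only make the test less extreme
        values = 3.0 * CONDITIONS + rng.normal(0, 0.01, 8)
        p_plain, _ = threshold_regression_test(series(values))
        mod = VarianceModeration(prior_df=4.0, prior_s2=0.25**2)
        p_mod, _ = threshold_regression_test(series(values), moderation=mod)
        assert p_mod > p_plain


class TestMerging:
    def test_protein_call_wins(self):
        g = [DifferentialCall("locus1", 0.5, sign=1, source="gene")]
        p = [DifferentialCall("locus1", 0.01, sign=-1, source="protein")]
        (merged,) = merge_gene_protein(g, p)
        assert merged.p_value == 0.01 and merged.sign == -1
        assert merged.source == "protein"

    def test_gene_call_used_when_no_protein(self):
        g = [DifferentialCall("locus1", 0.2, sign=1, source="gene")]
        (merged,) = merge_gene_protein(g, [])
        assert merged.p_value == 0.2 and merged.source == "gene"

    def test_feature_with_neither_becomes_non_differential(self):
        (merged,) = merge_gene_protein([], [], all_features=["locus9"])
        assert merged.source == "none" and merged.sign == 0
        assert merged.p_value == 1.0


class TestFdr:
    def test_bh_hand_computation(self):
        q = estimate_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p(self):
        assert estimate_fdr([0.5])[0] == pytest.approx(0.5)

    def test_all_ones(self):
        assert np.all(estimate_fdr([1.0, 1.0, 1.0]) == 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            estimate_fdr([0.5, 1.5])

    def test_density_estimator_monotone_and_bounded(self):
        rng = np.random.default_rng(1)
        p = np.concatenate([rng.uniform(0, 0.01, 50), rng.uniform(0, 1, 450)])
        q = estimate_fdr(p, method="density")
        assert np.all((q >= 0) & (q <= 1))
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestCalling:
    def test_below_cut_with_sign_called(self):
        calls = [DifferentialCall("g", 0.01, q_value=0.1, sign=1)]
        assert call_differential(calls) == {"g": "up"}

    def test_boundary_q_is_invariant(self):
        calls = [DifferentialCall("g", 0.01, q_value=0.2, sign=1)]
        assert call_differential(calls) == {"g": "invariant"}

    def test_no_sign_is_invariant(self):
        calls = [DifferentialCall("g", 0.01, q_value=0.05, sign=0)]
        assert call_differential(calls) == {"g": "invariant"}

    @settings(derandomize=True, max_examples=30)
    @given(
        qs=st.lists(st.floats(0, 1), min_size=1, max_size=20),
        cut_lo=st.floats(0.01, 0.5),
        cut_hi=st.floats(0.5, 0.99),
    )
    def test_raising_the_cut_never_uncalls(self, qs, cut_lo, cut_hi):
        calls = [
            DifferentialCall(f"g{i}", 0.0, q_value=q, sign=1)
            for i, q in enumerate(qs)
        ]
        lo = call_differential(calls, fdr_cut=cut_lo)
        hi = call_differential(calls, fdr_cut=cut_hi)
        for g, state in lo.items():
            if state != "invariant":
                assert hi[g] == state


class TestFoldChangeRoute:
    @pytest.mark.parametrize(
        "value, expected",
        [(0.60, "up"), (-0.60, "down"), (0.0, "invariant"),
         (0.5850, "invariant"), (-0.5850, "invariant"), (float("nan"), "invariant")],
    )
    def test_cutoff_rule(self, value, expected):
        assert classify_by_fold_change({"g": value})["g"] == expected

    def test_pure_function(self):
        fc = {"a": 1.0, "b": -1.0}
        assert classify_by_fold_change(fc) == classify_by_fold_change(fc)


def gpr_net(rules):
    mets = [Metabolite("A", is_internal=False, in_medium=True), Metabolite("B")]
    rxns = [
        Reaction(f"r{i}", {"A": -1.0, "B": 1.0}, gpr=parse_gpr(rule))
        for i, rule in enumerate(rules)
    ]
    return MetabolicNetwork(metabolites=mets, reactions=rxns,
                            carbon_arcs=CarbonArcTable())


class TestMapToReactions:
    def test_or_of_up_and_down_is_h(self):
        net = gpr_net(["g1 or g2"])
        cls = map_to_reactions(net, {"g1": "up", "g2": "down"})
        assert cls["r0"] == "H"

    def test_and_of_up_and_invariant_is_m(self):
        net = gpr_net(["g1 and g2"])
        cls = map_to_reactions(net, {"g1": "up", "g2": "invariant"})
        assert cls["r0"] == "M"

    def test_empty_gpr_is_m(self):
        net = gpr_net([""])
        assert map_to_reactions(net, {"g1": "up"})["r0"] == "M"

    def test_partition_is_exhaustive_and_exclusive(self):
        net = gpr_net(["g1", "g1 and g2", "g2", "", "g1 or g2"])
        cls = map_to_reactions(net, {"g1": "up", "g2": "down"})
        assert len(cls) == len(net.reactions)
        assert set(cls.values()) <= {"H", "M", "L"}


class TestPipeline:
    def test_noiseless_recovery_is_exact(self):
        series_list, truth = synthetic_expression(
            n_features=60, noise_sd=0.0, effect_log2=1.0, seed=5
        )
        net = gpr_net([""])  # irrelevant; we inspect gene states
        features = set(truth.feature_states)
        _, states, _ = classify_series_route(
            series_list, net, metabolic_genes=features
        )
        for fid, planted in truth.feature_states.items():
            assert states[fid] == planted

    def test_partition_property_on_pipeline_output(self):
        series_list, truth = synthetic_expression(n_features=40, seed=2)
        net = gpr_net(["g1", "g1 and g2", ""])
        cls, _, _ = classify_series_route(
            series_list, net, metabolic_genes=set(truth.feature_states)
        )
        assert sorted(cls) == sorted(r.id for r in net.reactions)
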