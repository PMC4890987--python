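"""Least-squares fitting, AIC order detection, and pruning."""

import math

import numpy as np
import pandas as pd
import pytest

from genpnp import (
    CandidateGEN,
    CohortDataset,
    aic_score,
    build_grn_problem,
    build_ppi_problem,
    detect_order_and_prune,
    faithful_recovery,
    identify_gen,
    least_squares_fit,
    support_metrics,
)
from genpnp.datatypes import BASAL, RegressionProblem, RegressorLabel


def _problem(X, y, kinds=None):
    p = X.shape[1]
    kinds = kinds or [("tf", f"R{j}") for j in range(p)]
    design = np.column_stack([X, np.ones(len(y))])
    labels = [RegressorLabel(k, r) for k, r in kinds] + [BASAL]
    return RegressionProblem("target", np.asarray(y, float), design, labels)


def _tiny_data(y_rows, x_rows, mir_rows, samples):
    cols = [f"s{j}" for j in range(samples)]
    return CohortDataset(
        gene_expr=pd.DataFrame(x_rows, columns=cols),
        mirna_expr=pd.DataFrame(mir_rows, columns=cols),
        sample_groups=pd.Series("g", index=cols),
        protein_expr=pd.DataFrame(y_rows, columns=cols),
    )


class TestProblemBuilders:
    def _data(self):
        y = pd.DataFrame(
            {"P1": [1.0, 2.0], "P2": [3.0, 4.0], "P3": [5.0, 6.0]}
        ).T
        y.columns = ["s0", "s1"]
        mir = pd.DataFrame({"m1": [2.0, 5.0]}).T
        mir.columns = ["s0", "s1"]
        return CohortDataset(
            gene_expr=y.copy(),
            mirna_expr=mir,
            sample_groups=pd.Series("g", index=["s0", "s1"]),
            protein_expr=y,
        )

    def test_no_partners_gives_intercept_only(self):
        cand = CandidateGEN(set(), set(), set(), ["P1", "P2", "P3"], ["m1"])
        prob = build_ppi_problem("P1", self._data(), cand)
        assert prob.labels == [BASAL]
        assert np.allclose(prob.design, 1.0)

    def test_ppi_column_is_elementwise_product(self):
        cand = CandidateGEN({("P1", "P2")}, set(), set(), ["P1", "P2", "P3"], ["m1"])
        prob = build_ppi_problem("P1", self._data(), cand)
        assert np.allclose(prob.design[:, 0], [1 * 3, 2 * 4])
        assert np.allclose(prob.response, [1.0, 2.0])

    def test_mirna_column_is_negated(self):
        cand = CandidateGEN(set(), set(), {("m1", "P1")}, ["P1", "P2", "P3"], ["m1"])
        prob = build_grn_problem("P1", self._data(), cand)
        assert np.allclose(prob.design[:, 0], [-2.0, -5.0])

    def test_mixed_design_matches_hand_built_matrix(self):
        rng = np.random.default_rng(0)
        y = rng.normal(2, 0.5, size=(4, 5))
        mir = rng.lognormal(0, 0.3, size=(2, 5))
        data = _tiny_data(y, y.copy(), mir, 5)
        data.gene_expr.index = data.protein_expr.index = ["P0", "P1", "P2", "P3"]
        data.mirna_expr.index = ["m0", "m1"]
        cand = CandidateGEN(
            {("P0", "P2"), ("P0", "P3")},
            {("P1", "P0"), ("P2", "P0")},
            {("m0", "P0"), ("m1", "P0")},
            ["P0", "P1", "P2", "P3"],
            ["m0", "m1"],
        )
        ppi = build_ppi_problem("P0", data, cand)
        expected = np.column_stack([y[0] * y[2], y[0] * y[3], np.ones(5)])
        assert np.allclose(ppi.design, expected)
        grn = build_grn_problem("P0", data, cand)
        expected = np.column_stack([y[1], y[2], -mir[0], -mir[1], np.ones(5)])
        assert np.allclose(grn.design, expected)

    def test_missing_partner_named_in_error(self):
        cand = CandidateGEN({("P1", "P9")}, set(), set(), ["P1", "P9"], ["m1"])
        with pytest.raises(KeyError, match="P9"):
            build_ppi_problem("P1", self._data(), cand)


class TestLeastSquaresFit:
    def test_exact_proportional_response(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=20)
        fit = least_squares_fit(_problem(x[:, None], 2.0 * x))
        assert fit.estimates[0] == pytest.approx(2.0, abs=1e-12)
        assert fit.rss == pytest.approx(0.0, abs=1e-20)

    def test_intercept_only_estimates_mean(self):
        y = np.array([1.0, 4.0, 7.0, 8.0])
        prob = RegressionProblem("t", y, np.ones((4, 1)), [BASAL])
        fit = least_squares_fit(prob)
        assert fit.estimates[0] == pytest.approx(y.mean())

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(10, 3))
        y = rng.normal(size=10)
        fit = least_squares_fit(_problem(X, y))
        Xd = np.column_stack([X, np.ones(10)])
        beta = np.linalg.solve(Xd.T @ Xd, Xd.T @ y)
        assert np.allclose(fit.estimates, beta, atol=1e-10)

    def test_matches_statsmodels_inference(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 4))
        y = X @ [1.0, -0.5, 0.0, 0.2] + rng.normal(size=40)
        fit = least_squares_fit(_problem(X, y))
        ref = sm.OLS(y, np.column_stack([X, np.ones(40)])).fit()
        assert np.allclose(fit.estimates, ref.params, atol=1e-10)
        assert np.allclose(fit.se, ref.bse, atol=1e-10)
        assert np.allclose(fit.p, ref.pvalues, atol=1e-10)

    def test_constant_column_dropped(self):
        rng = np.random.default_rng(4)
        X = np.column_stack([rng.normal(size=12), np.full(12, 3.0)])
        fit = least_squares_fit(_problem(X, rng.normal(size=12)))
        assert [lab for lab, reason in fit.dropped] == [RegressorLabel("tf", "R1")]
        assert fit.dropped[0][1] == "constant"

    def test_collinear_column_dropped_rightmost_first(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=15)
        X = np.column_stack([x, rng.normal(size=15), 2.0 * x])
        fit = least_squares_fit(_problem(X, rng.normal(size=15)))
        dropped = [lab.ref for lab, reason in fit.dropped]
        assert dropped == ["R2"]  # the dependent rightmost copy

    def test_underdetermined_raises(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(4, 6))
        with pytest.raises(ValueError, match="reduce the candidate set"):
            least_squares_fit(_problem(X, rng.normal(size=4)))


class TestAicScore:
    def test_reference_points(self):
        assert aic_score(20.0, 20, 0) == 0.0
        base = aic_score(3.7, 20, 4)
        assert aic_score(3.7, 20, 5) == pytest.approx(base + 2.0)
        assert base == pytest.approx(20 * math.log(3.7 / 20) + 8)

    def test_perfect_fit_sentinel(self):
        assert aic_score(0.0, 10, 2) == -math.inf

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            aic_score(-1.0, 10, 2)
        with pytest.raises(ValueError):
            aic_score(1.0, 0, 2)


class TestDetectOrderAndPrune:
    def test_strong_single_regressor_always_retained(self):
        # Monte-Carlo power oracle: |coef|/noise_sd = 5
        rng = np.random.default_rng(7)
        kept = 0
        reps = 300
        for _ in range(reps):
            x = rng.normal(size=100)
            y = 5.0 * x + rng.normal(size=100)
            fit = detect_order_and_prune(_problem(x[:, None], y), 0.05)
            kept += RegressorLabel("tf", "R0") in fit.labels
        assert kept / reps >= 0.99

    def test_null_regressors_rarely_retained(self):
        rng = np.random.default_rng(8)
        retained = total = 0
        for _ in range(150):
            X = rng.normal(size=(100, 8))
            y = rng.normal(size=100)
            fit = detect_order_and_prune(_problem(X, y), 0.05)
            retained += sum(1 for lab in fit.labels if lab.kind != "basal")
            total += 8
        assert retained / total < 0.10

    def test_order_invariance(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(60, 5))
        y = X[:, 1] * 1.2 - X[:, 3] * 0.8 + rng.normal(size=60) * 0.5
        fit = detect_order_and_prune(_problem(X, y), 0.05)
        perm = [3, 0, 4, 1, 2]
        fit_perm = detect_order_and_prune(
            _problem(X[:, perm], y, kinds=[("tf", f"R{j}") for j in perm]), 0.05
        )
        assert {lab: round(fit.coef(lab), 9) for lab in fit.labels} == {
            lab: round(fit_perm.coef(lab), 9) for lab in fit_perm.labels
        }

    def test_eliminations_recorded_with_reason(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(50, 4))
        y = 2.0 * X[:, 0] + rng.normal(size=50)
        fit = detect_order_and_prune(_problem(X, y), 0.05)
        gone = {lab.ref for lab, _ in fit.eliminated}
        kept = {lab.ref for lab in fit.labels if lab.kind != "basal"}
        assert "R0" in kept
        assert gone.isdisjoint(kept)
        assert all(reason in {"aic", "ttest"} for _, reason in fit.eliminated)
        assert all(p < 0.05 for lab, p in zip(fit.labels, fit.p) if lab.kind != "basal")


class TestIdentifyGen:
    def test_empty_candidates_yield_basal_only(self, small_cohorts):
        data = small_cohorts["young"]
        cand = CandidateGEN(set(), set(), set(), data.node_ids, data.mirna_ids)
        gen = identify_gen(data, cand, 0.05)
        assert gen.edges.empty
        assert set(gen.basal["model"]) == {"ppi", "grn"}
        assert len(gen.basal) == 2 * len(data.node_ids)

    def test_retained_edges_are_candidates_with_significant_p(
        self, small_cohorts, small_candidates
    ):
        gen = identify_gen(small_cohorts["elderly"], small_candidates, 0.05)
        cand_edges = (
            {(u, v, "ppi") for u, v in small_candidates.ppi_edges}
            | {(v, u, "ppi") for u, v in small_candidates.ppi_edges}
            | {(s, t, "tf") for s, t in small_candidates.tf_edges}
            | {(m, t, "mirna") for m, t in small_candidates.mirna_edges}
        )
        assert gen.edge_set() <= cand_edges
        assert (gen.edges["p"] < 0.05).all()

    def test_grn_support_recovery_on_joint_data(self, small_truth, small_candidates):
        # the regulatory model is exogenous on joint data: near-nominal FDR
        from genpnp import simulate_cohort

        data = simulate_cohort(small_truth, "elderly", 146, seed=404)
        gen = identify_gen(data, small_candidates, 0.05)
        recovered = {e for e in gen.edge_set() if e[2] != "ppi"}
        true = {e for e in small_truth.edge_set() if e[2] != "ppi"}
        m = support_metrics(recovered, true)
        assert m["sensitivity"] >= 0.9
        assert m["fdr"] <= 0.15

    def test_noiseless_faithful_recovery_is_exact(self):
        from genpnp import SimulationConfig, emit_candidate_network, generate_ground_truth

        cfg = SimulationConfig(
            n_nodes=20, n_mirnas=6, n_samples={"g": 60}, noise_sd=0.0,
            de_fraction=0.0, methylation_fraction=0.0, fp_fraction=0.5, seed=21,
        )
        gt = generate_ground_truth(cfg)
        cand = emit_candidate_network(gt, 0.5, seed=22)
        recovered = faithful_recovery(gt, cand, "g", 60, seed=23)
        assert recovered == gt.edge_set()

    def test_ability_estimates_close_to_truth(self, small_truth, small_candidates):
        from genpnp import simulate_cohort

        data = simulate_cohort(small_truth, "elderly", 146, seed=505)
        gen = identify_gen(data, small_candidates, 0.05)
        tf_edges = gen.edges[gen.edges["edge_type"] == "tf"]
        errors = []
        for row in tf_edges.itertuples(index=False):
            key = (row.regulator, row.target)
            if key in small_truth.true_tf_reg:
                errors.append(
                    abs(row.ability - small_truth.true_tf_reg[key]) / row.se
                )
        assert errors, "no true TF edge recovered"
        assert np.mean(errors) <= 3.0
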