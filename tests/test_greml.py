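import numpy as np
import pytest
from scipy.optimize import minimize

import gdblup as g
from gdblup.errors import InputError
from gdblup.gblup_ce import CEWorkspace

from conftest import random_mixed_instance


def _qm_step(inst, vc):
    Ta_s, Td_s = inst["pair"].scaled_codings(inst["Ta"], inst["Td"])
    system = g.assemble_mme(inst["y"], inst["X"], inst["Z"], Ta_s, Td_s, vc)
    return g.em_step_qm(system)


class TestEMEquivalence:
    @pytest.mark.parametrize(
        "q,m,duplicate,definition",
        [(6, 12, False, "II"), (10, 10, False, "III"), (16, 5, False, "II"),
         (12, 6, True, "II"), (8, 20, True, "III")],
    )
    def test_ce_step_equals_qm_step(self, q, m, duplicate, definition):
        inst = random_mixed_instance(100 + q * m, q=q, m=m, duplicate=duplicate,
                                     definition=definition)
        vc = inst["vc"]
        ce = g.em_step_ce(inst["y"], inst["X"], inst["Z"], inst["pair"].G, inst["pair"].D, vc)
        qm = _qm_step(inst, vc)
        assert np.allclose(ce.as_array(), qm.as_array(), rtol=1e-8, atol=1e-12)

    def test_zero_component_is_absorbing(self):
        inst = random_mixed_instance(101, vc=g.VarianceComponents(0.0, 0.4, 0.8))
        ce = g.em_step_ce(inst["y"], inst["X"], inst["Z"], inst["pair"].G, inst["pair"].D, inst["vc"])
        qm = _qm_step(inst, inst["vc"])
        assert ce.sigma2_a == 0.0 and qm.sigma2_a == 0.0


class TestEMBehaviour:
    def test_scalar_single_marker_oracle(self):
        # m=1, q=3: every quantity computable with plain dense algebra
        y = np.array([1.0, 0.5, -1.5])
        X = np.ones((3, 1))
        Ta = np.array([[1.0], [0.0], [-1.0]])
        Td = np.array([[0.4], [-0.8], [0.4]])
        G = Ta @ Ta.T
        D = Td @ Td.T
        vc = g.VarianceComponents(0.7, 0.5, 1.1)
        V = 0.7 * G + 0.5 * D + 1.1 * np.eye(3)
        Vi = np.linalg.inv(V)
        P = Vi - Vi @ X @ np.linalg.inv(X.T @ Vi @ X) @ X.T @ Vi
        Py = P @ y
        exp_a = 0.7 + 0.7**2 / 3 * (Py @ G @ Py - np.trace(P @ G))
        exp_d = 0.5 + 0.5**2 / 3 * (Py @ D @ Py - np.trace(P @ D))
        exp_e = 1.1 + 1.1**2 / 2 * (Py @ Py - np.trace(P))
        step = g.em_step_ce(y, X, np.eye(3), G, D, vc)
        assert step.sigma2_a == pytest.approx(max(exp_a, 0.0), rel=1e-10)
        assert step.sigma2_d == pytest.approx(max(exp_d, 0.0), rel=1e-10)
        assert step.sigma2_e == pytest.approx(exp_e, rel=1e-10)

    def test_likelihood_nondecreasing_along_em(self):
        inst = random_mixed_instance(102, q=40, m=60)
        vc = g.VarianceComponents(0.3, 0.3, 0.4)
        ws = CEWorkspace(inst["y"], inst["X"], inst["Z"], inst["pair"].G, inst["pair"].D)
        lls = []
        for _ in range(25):
            ws.set_vc(vc)
            lls.append(ws.reml_loglik())
            vc = g.em_step_ce(inst["y"], inst["X"], inst["Z"],
                              inst["pair"].G, inst["pair"].D, vc, workspace=ws)
        assert np.all(np.diff(lls) > -1e-9)

    def test_converged_solution_is_em_fixed_point(self):
        inst = random_mixed_instance(103, q=50, m=80)
        vc, trace = g.ai_reml(inst["y"], inst["X"], inst["Z"],
                              inst["pair"].G, inst["pair"].D, tol=1e-12, max_iter=500)
        assert trace.converged
        step = g.em_step_ce(inst["y"], inst["X"], inst["Z"],
                            inst["pair"].G, inst["pair"].D, vc)
        assert np.allclose(step.as_array(), vc.as_array(), rtol=1e-5, atol=1e-10)

    def test_ridge_trace_monotone_in_lambda(self):
        inst = random_mixed_instance(104, q=12, m=8)
        Ta_s, Td_s = inst["pair"].scaled_codings(inst["Ta"], inst["Td"])
        traces = []
        for s2a in (2.0, 0.5, 0.1):  # increasing lambda_alpha
            vc = g.VarianceComponents(s2a, 0.5, 1.0)
            system = g.assemble_mme(inst["y"], inst["X"], inst["Z"], Ta_s, Td_s, vc)
            sol = g.solve_mme(system)
            Caa, _, _ = sol.C_blocks()
            traces.append(np.trace(Caa))
        assert traces[0] > traces[1] > traces[2]


class TestAIReml:
    def test_matches_direct_likelihood_maximization(self):
        inst = random_mixed_instance(105, q=60, m=90)
        y, X, Z = inst["y"], inst["X"], inst["Z"]
        G, D = inst["pair"].G, inst["pair"].D
        vc, trace = g.ai_reml(y, X, Z, G, D, tol=1e-10, max_iter=300)
        ws = CEWorkspace(y, X, Z, G, D)

        def negll(t):
            try:
                ws.set_vc(g.VarianceComponents(*np.exp(t)))
            except Exception:
                return 1e10
            return -ws.reml_loglik()

        start = np.log(np.maximum(vc.as_array(), 1e-4) * 1.7)
        res = minimize(negll, start, method="Nelder-Mead",
                       options=dict(xatol=1e-10, fatol=1e-13, maxiter=4000))
        assert -res.fun <= g.reml_loglik(y, X, Z, G, D, vc) + 1e-6

    def test_em_and_hybrid_share_the_optimum(self):
        # interior optimum: strong additive and dominance signal
        cfg = g.SimConfig(n_individuals=120, m_qtl=300, h2_a=0.4, h2_d=0.25, seed=9)
        rng = np.random.default_rng(9)
        gm, _ = g.simulate_genotypes(cfg, rng)
        truth = g.simulate_phenotypes(gm, cfg, rng)
        Ta, Td = gm.codings()
        pair = g.build_grm(Ta, Td, freqs=gm.freqs, definition="II")
        X = np.ones((120, 1))
        Z = np.eye(120)
        vc_h, tr_h = g.ai_reml(truth.y, X, Z, pair.G, pair.D, tol=1e-12, max_iter=500)
        vc_e, tr_e = g.ai_reml(truth.y, X, Z, pair.G, pair.D, tol=1e-10,
                               max_iter=20000, algorithm="em")
        assert tr_h.converged and tr_e.converged
        assert np.allclose(vc_h.as_array(), vc_e.as_array(), atol=1e-6)

    def test_trace_bounded_and_nonconvergence_flagged(self):
        inst = random_mixed_instance(106, q=30, m=50)
        vc, trace = g.ai_reml(inst["y"], inst["X"], inst["Z"],
                              inst["pair"].G, inst["pair"].D, max_iter=2, tol=1e-14)
        assert trace.n_iter <= 2 and not trace.converged
        assert vc.sigma2_e > 0

    def test_boundary_truth_estimated_at_zero(self):
        # dominance-only phenotype: additive component should hit the boundary
        cfg = g.SimConfig(n_individuals=400, m_qtl=600, h2_a=0.0, h2_d=0.35, seed=21)
        rng = np.random.default_rng(21)
        gm, _ = g.simulate_genotypes(cfg, rng)
        truth = g.simulate_phenotypes(gm, cfg, rng)
        Ta, Td = gm.codings()
        pair = g.build_grm(Ta, Td, freqs=gm.freqs, definition="II")
        res = g.run_greml(truth.y, np.ones((400, 1)), np.eye(400), pair.G, pair.D,
                          max_iter=200, tol=1e-6)
        assert res.converged
        assert res.heritability.h2_a < 0.05
        assert res.heritability.h2_d == pytest.approx(0.35, abs=0.12)


class TestHeritabilities:
    def test_arithmetic(self):
        h = g.heritabilities(g.VarianceComponents(1.0, 0.0, 1.0))
        assert (h.h2_a, h.h2_d, h.H2) == (0.5, 0.0, 0.5)
        h2 = g.heritabilities(g.VarianceComponents(0.3, 0.15, 0.55))
        assert h2.H2 == pytest.approx(0.45)
        assert h2.sigma2_p == pytest.approx(1.0)

    def test_all_zero_rejected(self):
        with pytest.raises(InputError):
            g.heritabilities(g.VarianceComponents(0.0, 0.0, 0.0))


class TestRunGreml:
    def test_auto_formulation_runs_qm_em(self):
        inst = random_mixed_instance(107, q=40, m=10)
        Ta_s, Td_s = inst["pair"].scaled_codings(inst["Ta"], inst["Td"])
        res_qm = g.run_greml(inst["y"], inst["X"], inst["Z"], inst["pair"].G, inst["pair"].D,
                             t_alpha_star=Ta_s, t_delta_star=Td_s,
                             algorithm="em", formulation="auto", max_iter=300, tol=1e-8)
        assert res_qm.trace.algorithm == "em-qm"  # q >= 2m routes to the MME algebra
        res_ce = g.run_greml(inst["y"], inst["X"], inst["Z"], inst["pair"].G, inst["pair"].D,
                             algorithm="em", formulation="ce", max_iter=300, tol=1e-8)
        assert np.allclose(res_qm.vc.as_array(), res_ce.vc.as_array(), rtol=1e-6, atol=1e-10)

    def test_reports_standard_errors(self):
        inst = random_mixed_instance(108, q=50, m=80)
        res = g.run_greml(inst["y"], inst["X"], inst["Z"], inst["pair"].G, inst["pair"].D,
                          max_iter=200, tol=1e-8)
        assert set(res.se_vc) == {"sigma2_a", "sigma2_d", "sigma2_e"}
        assert all(v >= 0 for v in res.se_vc.values())
        assert set(res.se_h2) == {"h2_a", "h2_d", "H2"}

    def test_trace_length_bounded(self):
        inst = random_mixed_instance(109, q=20, m=30)
        res = g.run_greml(inst["y"], inst["X"], inst["Z"], inst["pair"].G, inst["pair"].D,
                          max_iter=7, tol=1e-16)
        assert res.trace.n_iter <= 7


class TestNormalizationMatters:
    def test_raw_matrices_shrink_estimates_with_marker_count(self):
        # the pathology normalization prevents: with unnormalized Gram
        # matrices the implied variance components fall as m grows, while
        # Definition II keeps them on a stable scale
        est = {}
        for m in (50, 400):
            cfg = g.SimConfig(n_individuals=150, m_qtl=m, h2_a=0.4, h2_d=0.2, seed=3)
            rng = np.random.default_rng(3)
            gm, _ = g.simulate_genotypes(cfg, rng)
            truth = g.simulate_phenotypes(gm, cfg, rng)
            Ta, Td = gm.codings()
            X = np.ones((150, 1))
            Z = np.eye(150)
            for defn in ("raw", "II"):
                pair = g.build_grm(Ta, Td, freqs=gm.freqs, definition=defn)
                res = g.run_greml(truth.y, X, Z, pair.G, pair.D, max_iter=400, tol=1e-8)
                est[(defn, m)] = res.vc.sigma2_a
        assert est[("raw", 400)] < est[("raw", 50)] / 2
        assert 0.5 < est[("II", 400)] / est[("II", 50)] < 2.0
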