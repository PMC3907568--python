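import numpy as np
import pytest

import gdblup as g
from gdblup.errors import DimensionError
from gdblup.grm import RelationshipPair

from conftest import random_mixed_instance


def _qm_from_instance(inst):
    Ta_s, Td_s = inst["pair"].scaled_codings(inst["Ta"], inst["Td"])
    return g.gblup_qm(inst["y"], inst["X"], inst["Z"], Ta_s, Td_s, inst["vc"])


class TestBuildV:
    def test_pure_residual(self):
        vc = g.VarianceComponents(0.0, 0.0, 2.0)
        V = g.build_V(np.eye(3), np.eye(3), np.eye(3), vc)
        assert np.allclose(V, 2.0 * np.eye(3))

    def test_two_by_two_hand_algebra(self):
        G = np.array([[1.0, 0.5], [0.5, 1.0]])
        D = np.eye(2)
        vc = g.VarianceComponents(2.0, 1.0, 0.5)
        V = g.build_V(np.eye(2), G, D, vc)
        assert np.allclose(V, [[3.5, 1.0], [1.0, 3.5]])
        assert np.allclose(V, V.T)


class TestGblupCE:
    def test_zero_additive_variance_gives_zero_blup(self):
        inst = random_mixed_instance(1, vc=g.VarianceComponents(0.0, 0.5, 1.0))
        pred = g.gblup_ce(inst["y"], inst["X"], inst["Z"], inst["pair"].G, inst["pair"].D, inst["vc"])
        assert np.all(pred.a_hat == 0.0)
        assert np.all(pred.rel_a == 0.0)
        assert np.allclose(pred.g_hat, pred.d_hat)

    def test_blue_matches_dense_gls_oracle(self):
        inst = random_mixed_instance(2, q=12, m=30)
        y, X, Z, vc = inst["y"], inst["X"], inst["Z"], inst["vc"]
        G, D = inst["pair"].G, inst["pair"].D
        pred = g.gblup_ce(y, X, Z, G, D, vc)
        # independent brute-force GLS
        V = vc.sigma2_a * Z @ G @ Z.T + vc.sigma2_d * Z @ D @ Z.T + vc.sigma2_e * np.eye(len(y))
        Vi = np.linalg.inv(V)
        b = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        assert np.allclose(pred.b_hat, b, rtol=1e-10)
        a = vc.sigma2_a * G @ Z.T @ Vi @ (y - X @ b)
        assert np.allclose(pred.a_hat, a, rtol=1e-8, atol=1e-12)

    def test_ghat_is_sum_of_parts(self):
        inst = random_mixed_instance(3)
        pred = g.gblup_ce(inst["y"], inst["X"], inst["Z"], inst["pair"].G, inst["pair"].D, inst["vc"])
        assert np.allclose(pred.g_hat, pred.a_hat + pred.d_hat)

    def test_reliabilities_within_unit_interval(self):
        for seed in (4, 5, 6):
            inst = random_mixed_instance(seed, q=9, m=14, duplicate=(seed == 5))
            rel = g.reliability_ce(
                inst["y"], inst["X"], inst["Z"], inst["pair"].G, inst["pair"].D, inst["vc"]
            )
            for r in rel:
                assert np.all(r >= -1e-10) and np.all(r <= 1 + 1e-10)

    def test_reliability_approaches_one_with_growing_signal(self):
        # the approach to 1 is limited by the fixed-effect projection, so a
        # moderate sample is needed for the limit to be visibly near 1
        inst = random_mixed_instance(7, q=60, m=150)
        G, D = inst["pair"].G, inst["pair"].D
        X = np.ones((60, 1))
        prev = -1.0
        for s2a in (1.0, 100.0, 10000.0):
            vc = g.VarianceComponents(s2a, 0.3, 1.0)
            rel_a, _, _ = g.reliability_ce(inst["y"], X, inst["Z"], G, D, vc)
            cur = rel_a.mean()
            assert cur > prev
            prev = cur
        assert prev > 0.9


class TestFormulationEquivalence:
    @pytest.mark.parametrize(
        "q,m,duplicate,definition",
        [(6, 12, False, "II"), (10, 10, False, "III"), (16, 5, False, "II"),
         (12, 6, True, "II"), (8, 20, True, "III"), (9, 9, False, "I")],
    )
    def test_ce_equals_qm_everywhere(self, q, m, duplicate, definition):
        inst = random_mixed_instance(q * m, q=q, m=m, duplicate=duplicate, definition=definition)
        pred_ce = g.gblup_ce(inst["y"], inst["X"], inst["Z"], inst["pair"].G, inst["pair"].D, inst["vc"])
        pred_qm, _ = _qm_from_instance(inst)
        for attr in ("b_hat", "a_hat", "d_hat", "g_hat", "rel_a", "rel_d", "rel_g"):
            assert np.allclose(getattr(pred_ce, attr), getattr(pred_qm, attr),
                               rtol=1e-8, atol=1e-10), attr

    def test_equivalence_with_repeated_records(self):
        inst = random_mixed_instance(77, q=7, m=11, two_obs=True)
        pred_ce = g.gblup_ce(inst["y"], inst["X"], inst["Z"], inst["pair"].G, inst["pair"].D, inst["vc"])
        pred_qm, _ = _qm_from_instance(inst)
        assert np.allclose(pred_ce.g_hat, pred_qm.g_hat, rtol=1e-8)
        assert np.allclose(pred_ce.rel_g, pred_qm.rel_g, rtol=1e-8)

    def test_rank_deficient_x_gives_same_estimable_functions(self):
        inst = random_mixed_instance(8, q=10, m=15, rank_deficient_X=True)
        pred_ce = g.gblup_ce(inst["y"], inst["X"], inst["Z"], inst["pair"].G, inst["pair"].D, inst["vc"])
        pred_qm, _ = _qm_from_instance(inst)
        # b itself is not identified; X b and the random-effect BLUPs are
        assert np.allclose(inst["X"] @ pred_ce.b_hat, inst["X"] @ pred_qm.b_hat, rtol=1e-8)
        assert np.allclose(pred_ce.a_hat, pred_qm.a_hat, rtol=1e-8, atol=1e-10)


class TestMMEStructure:
    def test_absorption_projector_identities(self):
        inst = random_mixed_instance(9, rank_deficient_X=True)
        Ta_s, Td_s = inst["pair"].scaled_codings(inst["Ta"], inst["Td"])
        system = g.assemble_mme(inst["y"], inst["X"], inst["Z"], Ta_s, Td_s, inst["vc"])
        S = system.S
        assert np.allclose(S @ inst["X"], 0.0, atol=1e-10)
        assert np.allclose(S @ S, S, atol=1e-10)
        assert system.rank_r == system.rank_X + 2 * system.m

    def test_single_marker_hand_solve(self):
        # m=1, q=2, no dominance: ridge solution (w'w + lambda)^-1 w'y
        y = np.array([1.0, -1.0])
        X = np.zeros((2, 0))
        Z = np.eye(2)
        Ta = np.array([[1.0], [-1.0]])
        Td = np.array([[0.5], [0.5]])
        vc = g.VarianceComponents(2.0, 0.0, 1.0)
        system = g.assemble_mme(y, X, Z, Ta, Td, vc)
        sol = g.solve_mme(system)
        lam = 0.5  # sigma2_e / sigma2_a
        expected = (Ta[:, 0] @ y) / (Ta[:, 0] @ Ta[:, 0] + lam)
        assert sol.alpha_hat[0] == pytest.approx(expected)
        assert np.all(sol.delta_hat == 0.0)

    def test_snp_permutation_invariance(self):
        inst = random_mixed_instance(10, q=6, m=9)
        Ta_s, Td_s = inst["pair"].scaled_codings(inst["Ta"], inst["Td"])
        _, sol = g.gblup_qm(inst["y"], inst["X"], inst["Z"], Ta_s, Td_s, inst["vc"])
        perm = np.random.default_rng(0).permutation(9)
        _, sol_p = g.gblup_qm(inst["y"], inst["X"], inst["Z"], Ta_s[:, perm], Td_s[:, perm], inst["vc"])
        pred = g.gblup_qm_validation(sol, Ta_s, Td_s)
        pred_p = g.gblup_qm_validation(sol_p, Ta_s[:, perm], Td_s[:, perm])
        assert np.allclose(pred.g_hat, pred_p.g_hat, rtol=1e-9)

    def test_vanishing_components_kill_reliability(self):
        inst = random_mixed_instance(11, vc=g.VarianceComponents(1e-10, 1e-10, 1.0))
        pred_qm, _ = _qm_from_instance(inst)
        assert np.all(pred_qm.rel_a < 1e-4)
        assert np.all(pred_qm.rel_d < 1e-4)


class TestValidation:
    def _combined(self, seed=12, q=12, n_train=9, definition="III"):
        inst = random_mixed_instance(seed, q=q, m=25, definition=definition)
        train = np.arange(n_train)
        val = np.arange(n_train, q)
        rng = np.random.default_rng(seed + 1)
        y = rng.standard_normal(n_train)
        X = np.ones((n_train, 1))
        Z = np.eye(n_train)
        return inst, train, val, y, X, Z

    def test_ce_equals_qm_for_validation(self):
        inst, train, val, y, X, Z = self._combined()
        vc = inst["vc"]
        pv_ce = g.gblup_ce_validation(y, X, Z, inst["pair"], train, val, vc)
        Ta_s, Td_s = inst["pair"].scaled_codings(inst["Ta"], inst["Td"])
        _, sol = g.gblup_qm(y, X, Z, Ta_s[train], Td_s[train], vc)
        pv_qm = g.gblup_qm_validation(sol, Ta_s[val], Td_s[val])
        for attr in ("a_hat", "d_hat", "g_hat", "rel_a", "rel_d", "rel_g"):
            assert np.allclose(getattr(pv_ce, attr), getattr(pv_qm, attr),
                               rtol=1e-8, atol=1e-10), attr

    def test_genotype_copy_inherits_training_prediction(self):
        # a validation individual identical to a training one (Definition III)
        inst = random_mixed_instance(13, q=8, m=30, definition="III")
        counts = np.vstack([inst["gm"].counts, inst["gm"].counts[0]])
        gm = g.GenotypeMatrix.from_counts(counts, freqs=inst["gm"].freqs)
        Ta, Td = gm.codings()
        pair = g.build_grm(Ta, Td, definition="III")
        train, val = np.arange(8), np.array([8])
        rng = np.random.default_rng(14)
        y = rng.standard_normal(8)
        pred_t = g.gblup_ce(y, np.ones((8, 1)), np.eye(8), *_blocks(pair, train), inst["vc"])
        pred_v = g.gblup_ce_validation(y, np.ones((8, 1)), np.eye(8), pair, train, val, inst["vc"])
        assert pred_v.a_hat[0] == pytest.approx(pred_t.a_hat[0], rel=1e-9)
        assert pred_v.g_hat[0] == pytest.approx(pred_t.g_hat[0], rel=1e-9)

    def test_unrelated_validation_individual_predicts_zero(self):
        inst, train, val, y, X, Z = self._combined(seed=15)
        pair = inst["pair"]
        G = pair.G.copy()
        D = pair.D.copy()
        G[np.ix_(val, train)] = 0.0
        G[np.ix_(train, val)] = 0.0
        D[np.ix_(val, train)] = 0.0
        D[np.ix_(train, val)] = 0.0
        pair0 = RelationshipPair(G, D, pair.definition, pair.k_alpha, pair.k_delta)
        pv = g.gblup_ce_validation(y, X, Z, pair0, train, val, inst["vc"])
        assert np.allclose(pv.a_hat, 0.0) and np.allclose(pv.g_hat, 0.0)

    def test_empty_validation_set_rejected(self):
        inst, train, _, y, X, Z = self._combined()
        with pytest.raises(DimensionError):
            g.gblup_ce_validation(y, X, Z, inst["pair"], train, np.array([], dtype=int), inst["vc"])

    def test_coding_mismatch_rejected(self):
        inst = random_mixed_instance(16, q=6, m=10)
        Ta_s, Td_s = inst["pair"].scaled_codings(inst["Ta"], inst["Td"])
        _, sol = g.gblup_qm(inst["y"], inst["X"], inst["Z"], Ta_s, Td_s, inst["vc"])
        with pytest.raises(DimensionError):
            g.gblup_qm_validation(sol, Ta_s[:, :5], Td_s[:, :5])


def _blocks(pair, idx):
    sub = pair.submatrix(idx)
    return sub.G, sub.D


class TestChooseFormulation:
    def test_many_markers_prefers_ce(self):
        assert g.choose_formulation(1654, 40000) == "ce"

    def test_many_individuals_prefers_qm(self):
        assert g.choose_formulation(4000, 1000) == "qm"
        assert g.choose_formulation(1654, 503) == "qm"

    def test_boundary_is_qm(self):
        assert g.choose_formulation(40, 20) == "qm"
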