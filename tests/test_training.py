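"""Pseudo-likelihood objective, gradients, and the alternating fit."""

import numpy as np
import pytest
from scipy.special import logsumexp

import annealdca as ad
from annealdca import AnnealModel, FitConfig, PottsEnergy

from .conftest import make_random_dataset, make_random_energy


def naive_pseudo_loglik(model, dataset, lambda_h=0.0, lambda_j=0.0):
    """Slow, loop-based reimplementation of the site-conditional objective."""
    total = 0.0
    L, q = model.L, model.q
    for r in dataset.rounds:
        beta = model.betas[r.round_label]
        for w, s in zip(r.weights, r.sequences):
            for i in range(L):
                logits = np.empty(q)
                for a in range(q):
                    mod = s.copy()
                    mod[i] = a
                    logits[a] = -(beta * model.E.energy(mod) + model.G.energy(mod))
                total += w * (logits[s[i]] - logsumexp(logits))
    for e, lam_h, lam_j in ((model.E, lambda_h, lambda_j),
                            (model.G, lambda_h, lambda_j)):
        total -= lam_h * (e.h ** 2).sum()
        if e.J is not None:
            iu, ju = np.triu_indices(L, k=1)
            total -= lam_j * (e.J[iu, ju] ** 2).sum()
    return total


def random_model(rng, L, q, labels=(0, 1, 2), pairwise=True):
    betas = {labels[0]: 0.0}
    if len(labels) > 1:
        betas[labels[1]] = 1.0
    for t in labels[2:]:
        betas[t] = float(rng.uniform(-1.0, 2.5))
    return AnnealModel(
        make_random_energy(rng, L, q, pairwise=pairwise),
        make_random_energy(rng, L, q, pairwise=pairwise),
        betas, alphabet=ad.Alphabet.generic(q),
    )


class TestPseudoLoglik:
    def test_uniform_model_value(self, rng):
        L, q, n_rounds = 3, 2, 2
        ds = make_random_dataset(rng, L, q, labels=(0, 1))
        z = PottsEnergy.zeros(L, q, pairwise=True)
        m = AnnealModel(z, z, {0: 0.0, 1: 1.0})
        value = ad.pseudo_loglik(m, ds, FitConfig(lambda_h=0.0, lambda_j=0.0))
        assert value == pytest.approx(n_rounds * L * np.log(1.0 / q))

    def test_matches_naive_reimplementation(self, rng):
        m = random_model(rng, 3, 3)
        ds = make_random_dataset(rng, 3, 3, M=8)
        cfg = FitConfig(lambda_h=1e-3, lambda_j=2e-3)
        assert ad.pseudo_loglik(m, ds, cfg) == pytest.approx(
            naive_pseudo_loglik(m, ds, 1e-3, 2e-3), abs=1e-10
        )

    def test_single_coupling_hand_enumeration(self):
        # L=2, q=2, one coupling J_12(1,1)=0.7 in E, one weighted sequence
        E = PottsEnergy.from_blocks(
            np.zeros((2, 2)), {(0, 1): np.array([[0.0, 0.0], [0.0, 0.7]])}
        )
        G = PottsEnergy.zeros(2, 2, pairwise=True)
        m = AnnealModel(E, G, {0: 0.0, 1: 1.0})
        abc = ad.Alphabet.generic(2)
        rounds = [
            ad.SequenceRound(0, np.array([[1, 1]]), np.array([4])),
            ad.SequenceRound(1, np.array([[1, 1]]), np.array([4])),
        ]
        ds = ad.ScreeningDataset(rounds, abc)
        # round 0 (beta 0): conditionals uniform -> 2 log(1/2)
        # round 1: each site conditional = e^{0.7}/(1 + e^{0.7})
        expected = 2 * np.log(0.5) + 2 * (0.7 - np.log(1 + np.exp(0.7)))
        value = ad.pseudo_loglik(m, ds, FitConfig(lambda_h=0.0, lambda_j=0.0))
        assert value == pytest.approx(expected, abs=1e-12)

    def test_independent_site_equals_exact_likelihood(self, rng):
        for _ in range(5):
            m = random_model(rng, 4, 3, pairwise=False)
            ds = make_random_dataset(rng, 4, 3)
            pl = ad.pseudo_loglik(m, ds, FitConfig(e_family="indep",
                                                   g_family="indep",
                                                   lambda_h=0.0, lambda_j=0.0))
            assert pl == pytest.approx(ad.exact_loglik(m, ds), abs=1e-10)

    def test_gauge_invariance_of_data_term(self, rng):
        # site conditionals are gauge invariant, so the unregularized
        # objective is identical after the zero-sum transform
        m = random_model(rng, 4, 3)
        ds = make_random_dataset(rng, 4, 3)
        cfg = FitConfig(lambda_h=0.0, lambda_j=0.0)
        gauged = AnnealModel(ad.to_zero_sum_gauge(m.E), ad.to_zero_sum_gauge(m.G),
                             m.betas, fixed_scale=False)
        assert ad.pseudo_loglik(gauged, ds, cfg) == pytest.approx(
            ad.pseudo_loglik(m, ds, cfg), abs=1e-8
        )


class TestPseudoGrad:
    def test_matches_finite_differences(self, rng):
        from annealdca.protocols import gradient_finite_difference

        report = gradient_finite_difference(20240917, n_models=1)
        assert report["max_rel_error"] < 1e-5

    def test_penalty_gradient_component(self, rng):
        # grad(lambda) - grad(0) must equal the -2*lambda*theta penalty pull
        m = random_model(rng, 3, 3)
        ds = make_random_dataset(rng, 3, 3)
        g1 = ad.pseudo_grad(m, ds, FitConfig(lambda_h=0.05, lambda_j=0.02))
        g0 = ad.pseudo_grad(m, ds, FitConfig(lambda_h=0.0, lambda_j=0.0))
        np.testing.assert_allclose(g1.h_e - g0.h_e, -2 * 0.05 * m.E.h, atol=1e-12)
        iu, ju = np.triu_indices(3, k=1)
        np.testing.assert_allclose(g1.j_g - g0.j_g, -2 * 0.02 * m.G.J[iu, ju],
                                   atol=1e-12)

    def test_stationary_at_single_site_optimum(self, rng):
        # unregularized one-site fit: the fitted point has ~zero gradient
        abc = ad.Alphabet.generic(3)
        rounds = [
            ad.SequenceRound(t, rng.integers(0, 3, size=(30, 1)).astype(np.uint8),
                             rng.integers(1, 10, size=30))
            for t in (0, 1)
        ]
        ds = ad.ScreeningDataset(rounds, abc)
        cfg = FitConfig(e_family="indep", g_family="indep", lambda_h=1e-9,
                        lambda_j=0.0, grad_tol=1e-12,
                        max_inner_iterations=2000)
        result = ad.fit(ds, cfg)
        g = ad.pseudo_grad(result.model, ds, cfg)
        assert max(np.abs(g.h_e).max(), np.abs(g.h_g).max()) < 1e-7


class TestFit:
    def test_deterministic_given_config(self, rng):
        ds = make_random_dataset(rng, 4, 3, M=25)
        cfg = FitConfig(max_outer_iterations=5)
        r1 = ad.fit(ds, cfg)
        r2 = ad.fit(ds, cfg)
        np.testing.assert_array_equal(r1.model.E.h, r2.model.E.h)
        np.testing.assert_array_equal(r1.model.E.J, r2.model.E.J)
        assert r1.model.betas == r2.model.betas
        np.testing.assert_array_equal(r1.objective_trace, r2.objective_trace)

    def test_objective_trace_nondecreasing(self, rng):
        ds = make_random_dataset(rng, 4, 3, M=25)
        result = ad.fit(ds, FitConfig(max_outer_iterations=6))
        assert (np.diff(result.objective_trace) >= -1e-9).all()

    def test_fit_theta_improves_objective(self, rng):
        ds = make_random_dataset(rng, 4, 3, M=20)
        cfg = FitConfig()
        betas = {0: 0.0, 1: 1.0, 2: 2.0}
        zeros = PottsEnergy.zeros(4, 3, pairwise=True)
        before = ad.pseudo_loglik(AnnealModel(zeros, zeros, betas), ds, cfg)
        E, G, info = ad.fit_theta(ds, betas, cfg)
        after = ad.pseudo_loglik(AnnealModel(E, G, betas), ds, cfg)
        assert after >= before - 1e-9
        assert info["objective"] == pytest.approx(after, abs=1e-8)

    def test_scale_constraints_always_reported(self, rng):
        ds = make_random_dataset(rng, 4, 3, M=20)
        result = ad.fit(ds, FitConfig(max_outer_iterations=3))
        labels = result.model.round_labels
        assert result.model.betas[labels[0]] == 0.0
        assert result.model.betas[labels[1]] == 1.0

    def test_two_rounds_beta_fixed_by_constraints(self, rng):
        ds = make_random_dataset(rng, 4, 3, labels=(0, 1), M=20)
        result = ad.fit(ds, FitConfig(max_outer_iterations=3))
        assert result.model.betas == {0: 0.0, 1: 1.0}

    def test_duplicated_round_gets_unit_beta(self, rng):
        # an identical sample at a later label implies identical temperature
        sim = ad.SimConfig(L=5, q=3, truth_E=ad.EnergyPrior(field_scale=1.0),
                           truth_G=ad.EnergyPrior(field_scale=0.4),
                           alpha_schedule=(1.0,), population_size=5 * 10 ** 4,
                           sequencing_depth=5 * 10 ** 4, sequenced_rounds=(0, 1),
                           seed=13)
        ds, _ = ad.simulate_experiment(sim)
        r1 = ds.round(1)
        dup = ad.SequenceRound(2, r1.sequences, r1.counts)
        ds3 = ad.ScreeningDataset(list(ds.rounds) + [dup], ds.alphabet)
        result = ad.fit(ds3, FitConfig(e_family="indep", g_family="indep"))
        assert result.model.betas[2] == pytest.approx(1.0, abs=0.05)

    def test_no_signal_shrinks_selection_energy(self, rng):
        # two identical rounds carry no selection signal: E is regularized away
        seqs = rng.integers(0, 3, size=(40, 5)).astype(np.uint8)
        counts = rng.integers(1, 30, size=40)
        rounds = [ad.SequenceRound(t, seqs, counts) for t in (0, 1)]
        ds = ad.ScreeningDataset(rounds, ad.Alphabet.generic(3))
        result = ad.fit(ds, FitConfig(e_family="indep", g_family="indep"))
        norm_e = np.linalg.norm(result.model.E.h)
        norm_g = np.linalg.norm(result.model.G.h)
        assert norm_e < norm_g / 10

    def test_independent_site_field_recovery(self, rng):
        # simulated two-round screen at the stated depth recovers the truth
        sim = ad.SimConfig(L=8, q=4, truth_E=ad.EnergyPrior(field_scale=1.0),
                           truth_G=ad.EnergyPrior(field_scale=0.5),
                           alpha_schedule=(1.0,), population_size=5 * 10 ** 4,
                           sequencing_depth=5 * 10 ** 4,
                           sequenced_rounds=(0, 1), seed=29)
        ds, truth = ad.simulate_experiment(sim)
        result = ad.fit(ds, FitConfig(e_family="indep", g_family="indep",
                                      lambda_h=1e-4))
        fitted = result.model.E.h - result.model.E.h.mean(axis=1, keepdims=True)
        true = truth.truth_E.h - truth.truth_E.h.mean(axis=1, keepdims=True)
        r = np.corrcoef(fitted.ravel(), true.ravel())[0, 1]
        assert r >= 0.95

    def test_recovery_improves_with_depth(self):
        corr = []
        for depth in (300, 3000, 30000):
            sim = ad.SimConfig(L=6, q=3, truth_E=ad.EnergyPrior(field_scale=1.0),
                               truth_G=ad.EnergyPrior(field_scale=0.4),
                               alpha_schedule=(1.0,), population_size=10 ** 5,
                               sequencing_depth=depth, sequenced_rounds=(0, 1),
                               seed=101)
            ds, truth = ad.simulate_experiment(sim)
            result = ad.fit(ds, FitConfig(e_family="indep", g_family="indep"))
            seqs = ad.enumerate_sequences(6, 3)
            corr.append(np.corrcoef(result.model.E.energy(seqs),
                                    truth.truth_E.energy(seqs))[0, 1])
        assert corr[0] <= corr[1] + 0.02 and corr[1] <= corr[2] + 0.02
        assert corr[2] > corr[0]

    def test_label_permutation_equivariance(self, rng):
        ds = make_random_dataset(rng, 4, 3, M=20)
        perm = np.array([2, 0, 1])
        inv = np.argsort(perm)
        permuted_rounds = [
            ad.SequenceRound(r.round_label, perm[r.sequences], r.counts)
            for r in ds.rounds
        ]
        ds_perm = ad.ScreeningDataset(permuted_rounds, ds.alphabet)
        cfg = FitConfig(max_outer_iterations=8, grad_tol=1e-9)
        m1 = ad.fit(ds, cfg).model
        m2 = ad.fit(ds_perm, cfg).model
        probe = np.stack([r for r in ad.enumerate_sequences(4, 3)])
        e1 = m1.E.energy(probe)
        e2 = m2.E.energy(perm[probe])
        np.testing.assert_allclose(e1 - e1.mean(), e2 - e2.mean(), atol=1e-3)
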