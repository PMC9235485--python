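import math

import numpy as np
import pytest
from scipy import integrate, stats

from sparseddi import autodiff as ad
from sparseddi.autodiff import Tensor
from sparseddi.hypergraph import DDIHypergraph
from sparseddi.objective import (HorseshoeState, ObjectiveConfig,
                                 all_canonical_triples, build_evaluation_set,
                                 gaussian_log_likelihood, horseshoe_log_prior,
                                 laplace_log_prior, objective,
                                 reconstruction_log_likelihood,
                                 sample_negative_triples, shrinkage_profile,
                                 triple_log_likelihood)
from sparseddi.encoder import LatentState
from sparseddi.tensor_ops import InteractionTensor

LOG_INV_SQRT_2PI = -0.5 * math.log(2 * math.pi)


class TestTripleLikelihood:
    def test_zero_residual(self):
        assert triple_log_likelihood(1.0, 1, 1.0) == pytest.approx(
            LOG_INV_SQRT_2PI)

    def test_unit_residual(self):
        assert triple_log_likelihood(0.0, 1, 1.0) == pytest.approx(
            LOG_INV_SQRT_2PI - 0.5)

    def test_matches_scipy_normal(self, rng):
        for _ in range(50):
            score = rng.normal()
            label = rng.integers(0, 2)
            sigma = rng.uniform(0.2, 3.0)
            want = stats.norm.logpdf(label - score, scale=sigma)
            assert triple_log_likelihood(score, label, sigma) == \
                pytest.approx(want, abs=1e-10)

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            triple_log_likelihood(0.0, 1, 0.0)


class TestEvaluationSet:
    def _toy(self):
        return DDIHypergraph.from_triples(
            ["a", "b", "c"], ["s", "t"],
            [(0, 1, 0), (0, 2, 1)])

    def test_exhaustive_single_positive(self):
        G = DDIHypergraph.from_triples(["a", "b"], ["s"], [(0, 1, 0)])
        cfg = ObjectiveConfig(prior_kind="none", exhaustive=True)
        triples, labels = build_evaluation_set(G, cfg)
        assert len(triples) == 1 and labels.tolist() == [1.0]
        ll = reconstruction_log_likelihood(np.array([1.0]), labels)
        assert ll == pytest.approx(LOG_INV_SQRT_2PI)

    def test_exhaustive_matches_loop_oracle(self, rng):
        G = self._toy()
        cfg = ObjectiveConfig(prior_kind="none", exhaustive=True)
        triples, labels = build_evaluation_set(G, cfg)
        scores = rng.random(len(triples))
        got = reconstruction_log_likelihood(scores, labels)
        # loop over every canonical triple independently
        want = 0.0
        k = 0
        for u in range(3):
            for v in range(u + 1, 3):
                for t in range(2):
                    lab = 1.0 if (u, v, t) in G else 0.0
                    want += stats.norm.logpdf(lab - scores[k])
                    k += 1
        assert got == pytest.approx(want, abs=1e-9)

    def test_sampled_mode_count_contract(self):
        G = self._toy()
        cfg = ObjectiveConfig(prior_kind="none", neg_ratio=1, neg_seed=3)
        triples, labels = build_evaluation_set(G, cfg)
        assert len(triples) == 2 * G.n_edges
        assert labels.sum() == G.n_edges

    def test_negatives_avoid_positives(self, rng):
        G = self._toy()
        neg = sample_negative_triples(3, 2, 4, rng, G._edge_set)
        assert len(neg) == 4
        assert len({tuple(e) for e in neg.tolist()}) == 4
        for e in map(tuple, neg.tolist()):
            assert e not in G
            assert e[0] < e[1]

    def test_exhaustive_guard(self):
        G = self._toy()
        cfg = ObjectiveConfig(exhaustive=True, exhaustive_guard=2)
        with pytest.raises(ValueError, match="guard"):
            build_evaluation_set(G, cfg)

    def test_all_canonical_triples_lexicographic(self):
        t = all_canonical_triples(3, 2)
        assert t.tolist() == [[0, 1, 0], [0, 1, 1], [0, 2, 0], [0, 2, 1],
                              [1, 2, 0], [1, 2, 1]]


class TestPriors:
    def test_horseshoe_at_unit_scales(self):
        B = np.zeros((2, 2, 2))
        lam = np.ones((2, 2, 2))
        assert horseshoe_log_prior(B, lam, tau=0.5) == pytest.approx(
            -8 * math.log(2))

    def test_horseshoe_quadratic_in_B(self, rng):
        lam = rng.random((2, 2, 2)) + 0.5
        B = rng.random((2, 2, 2))
        tau = 0.3
        base = horseshoe_log_prior(np.zeros_like(B), lam, tau)
        got = horseshoe_log_prior(B, lam, tau)
        got2 = horseshoe_log_prior(2 * B, lam, tau)
        q1 = base - got      # ½ Σ (B/τΛ)²
        q2 = base - got2     # 4 × that
        assert q2 == pytest.approx(4 * q1, rel=1e-9)

    def test_half_cauchy_normalized(self):
        val, _ = integrate.quad(lambda x: 2 / math.pi / (1 + x * x), 0,
                                np.inf)
        assert val == pytest.approx(1.0, abs=1e-9)

    def test_zero_local_scale_contract(self):
        lam = np.array([[[0.0]]])
        assert horseshoe_log_prior(np.array([[[1.0]]]), lam, 1.0) == -np.inf

    def test_laplace_cases(self, rng):
        assert laplace_log_prior(np.zeros((2, 2, 2)), 1.0) == 0.0
        assert laplace_log_prior(np.ones((2, 2, 2)), 1.0) == -8.0
        B = rng.normal(size=(3, 3, 2))
        assert laplace_log_prior(B, 0.7) == pytest.approx(
            -np.abs(B).sum() / 0.7)

    def test_tensor_path_matches_numpy(self, rng):
        B = rng.random((2, 2, 2))
        lam = rng.random((2, 2, 2)) + 0.2
        want = horseshoe_log_prior(B, lam, 0.4)
        got = horseshoe_log_prior(Tensor(B), Tensor(lam), 0.4)
        assert got.item() == pytest.approx(want, rel=1e-12)
        assert laplace_log_prior(Tensor(B), 0.4).item() == pytest.approx(
            laplace_log_prior(B, 0.4), rel=1e-12)


class TestObjective:
    def _setup(self, rng, prior_kind):
        G = DDIHypergraph.from_triples(
            ["a", "b", "c"], ["s", "t"], [(0, 1, 0), (1, 2, 1)])
        latent = LatentState(rng.random((3, 2)), rng.random((2, 2)))
        B = InteractionTensor(rng.random((2, 2, 2)))
        hs = HorseshoeState(rng.random((2, 2, 2)) + 0.5, 0.3)
        cfg = ObjectiveConfig(prior_kind=prior_kind, tau=0.3,
                              exhaustive=True)
        return G, latent, B, hs, cfg

    def test_no_prior_equals_likelihood(self, rng):
        G, latent, B, hs, cfg = self._setup(rng, "none")
        from sparseddi.tensor_ops import batch_scores

        triples, labels = build_evaluation_set(G, cfg)
        scores = batch_scores(B, latent.H_d, latent.H_s, triples)
        want = gaussian_log_likelihood(scores, labels, cfg.sigma)
        assert objective(G, latent, B, None, cfg) == pytest.approx(want)

    def test_horseshoe_additivity(self, rng):
        G, latent, B, hs, cfg = self._setup(rng, "horseshoe")
        base_cfg = ObjectiveConfig(prior_kind="none", exhaustive=True)
        got = objective(G, latent, B, hs, cfg)
        want = objective(G, latent, B, None, base_cfg) + \
            horseshoe_log_prior(B, hs, cfg.tau)
        assert got == pytest.approx(want, rel=1e-12)

    def test_gradient_matches_finite_differences(self, rng):
        """d(objective)/dB on a toy, via the autodiff path used in fit."""
        G, latent, B, hs, cfg = self._setup(rng, "horseshoe")
        triples, labels = build_evaluation_set(G, cfg)
        hu = latent.H_d[triples[:, 0]]
        hv = latent.H_d[triples[:, 1]]
        ht = latent.H_s[triples[:, 2]]

        def value(Bv):
            Bt = Tensor(Bv, requires_grad=True)
            s = ad.trilinear_scores(Bt, Tensor(hu), Tensor(hv), Tensor(ht))
            ll = gaussian_log_likelihood(s, labels, cfg.sigma)
            pr = horseshoe_log_prior(Bt, Tensor(hs.lam), cfg.tau)
            return ll + pr, Bt

        out, Bt = value(B.values)
        out.backward()
        eps = 1e-6
        num = np.zeros_like(B.values)
        it = np.nditer(B.values, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            for s_, e in ((1, eps), (-1, -eps)):
                Bp = B.values.copy()
                Bp[idx] += e
                num[idx] += s_ * value(Bp)[0].item()
            num[idx] /= 2 * eps
        assert np.allclose(Bt.grad, num, atol=1e-5)

    def test_gradients_finite_for_positive_scales(self, rng):
        lam = Tensor(rng.random((2, 2, 2)) + 0.1, requires_grad=True)
        B = Tensor(rng.random((2, 2, 2)), requires_grad=True)
        out = horseshoe_log_prior(B, lam, 0.05)
        out.backward()
        assert np.isfinite(B.grad).all()
        assert np.isfinite(lam.grad).all()


class TestShrinkageProfile:
    def test_no_shrinkage(self, rng):
        B = rng.random((2, 2, 2)) + 0.1
        kappa, excluded = shrinkage_profile(B, B)
        assert np.allclose(kappa, 0.0)
        assert excluded == 0

    def test_complete_shrinkage(self, rng):
        B = rng.random((2, 2, 2)) + 0.1
        kappa, _ = shrinkage_profile(np.zeros_like(B), B)
        assert np.allclose(kappa, 1.0)

    def test_zero_denominators_excluded(self):
        B_ml = np.array([[[0.0, 2.0]]])
        B_map = np.array([[[1.0, 1.0]]])
        kappa, excluded = shrinkage_profile(B_map, B_ml)
        assert excluded == 1
        assert kappa.tolist() == [0.5]
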