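import numpy as np
import pytest

from sparseddi.hypergraph import data_sparsity
from sparseddi.synthetic import (SyntheticConfig, apply_noise,
                                 expected_sparsity,
                                 generate_calibrated_dataset,
                                 generate_dataset, generate_latent_interactions,
                                 generate_node_latents_and_features,
                                 generate_true_triples,
                                 generate_uniform_support,
                                 property1_experiment,
                                 uniform_hit_probability, write_dataset)


def brute_force_true_triples(A, g_d, g_s):
    """All-pairs oracle for the planted-edge rule."""
    Aset = {(min(i, j), max(i, j), k) for (i, j, k) in A}
    out = set()
    for u in range(len(g_d)):
        for v in range(u + 1, len(g_d)):
            for t in range(len(g_s)):
                hit = any((min(i, j), max(i, j), k) in Aset
                          for i in g_d[u] for j in g_d[v] for k in g_s[t])
                if hit:
                    out.add((u, v, t))
    return out


class TestLatentInteractions:
    def test_forced_counts_with_m1(self, rng):
        cfg = SyntheticConfig(n_drugs=5, n_side_effects=5, K_D=4, K_S=3,
                              M=1, N1=1, N2=1)
        A = generate_latent_interactions(cfg, rng)
        assert len(A) == 3
        assert {k for (_, _, k) in A} == {0, 1, 2}

    def test_pair_support_bound(self, rng):
        cfg = SyntheticConfig(n_drugs=5, n_side_effects=5, K_D=2, K_S=8,
                              M=3, N1=1, N2=1)
        A = generate_latent_interactions(cfg, rng)
        assert {(i, j) for (i, j, _) in A} <= {(0, 0), (0, 1), (1, 1)}

    def test_mean_support_size(self):
        # n_k ~ U{1..M} so E|A per k| = (M+1)/2 (ignoring rare collisions)
        M, K_S, n = 4, 6, 200
        sizes = []
        for seed in range(n):
            cfg = SyntheticConfig(n_drugs=5, n_side_effects=5, K_D=10,
                                  K_S=K_S, M=M, N1=1, N2=1)
            A = generate_latent_interactions(
                cfg, np.random.default_rng(seed))
            sizes.append(len(A))
        mean = np.mean(sizes)
        se = np.std(sizes, ddof=1) / np.sqrt(n)
        assert abs(mean - K_S * (M + 1) / 2) <= 3 * se + 0.2

    def test_capping_warns(self, rng):
        cfg = SyntheticConfig(n_drugs=5, n_side_effects=5, K_D=2, K_S=1,
                              M=10, N1=1, N2=1)
        with pytest.warns(UserWarning, match="capping"):
            generate_latent_interactions(cfg, rng)


class TestNodeLatentsAndFeatures:
    def test_noiseless_block_indicator(self):
        cfg = SyntheticConfig(n_drugs=50, n_side_effects=5, K_D=3, K_S=3,
                              M=1, N1=1, N2=1, delta=0.0, c=2, seed=0)
        rng = np.random.default_rng(0)
        g_d, g_s, F = generate_node_latents_and_features(cfg, rng)
        assert F.shape == (50, 6)
        for u, g in enumerate(g_d):
            want = np.zeros(6)
            for i in g:
                want[2 * i:2 * i + 2] = 1.0
            np.testing.assert_array_equal(F[u], want)
            # thresholding at 0.5 recovers the latent set exactly
            assert {b for b in range(3) if F[u][2 * b] > 0.5} == g

    def test_noise_std_before_clipping(self):
        # use mean-1 blocks (clipping at 0 is rare there) to estimate std
        delta, reps = 0.1, 400
        vals = []
        for seed in range(reps):
            cfg = SyntheticConfig(n_drugs=2, n_side_effects=2, K_D=1,
                                  K_S=1, M=1, N1=1, N2=1, delta=delta, c=3)
            rng = np.random.default_rng(seed)
            _, _, F = generate_node_latents_and_features(cfg, rng)
            vals.append(F[0, 0])  # block mean is 1 here
        sd = np.std(vals, ddof=1)
        assert sd == pytest.approx(delta, rel=0.25)

    def test_latent_counts_within_bounds(self, rng):
        cfg = SyntheticConfig(n_drugs=200, n_side_effects=100, K_D=6,
                              K_S=5, M=2, N1=3, N2=2)
        g_d, g_s, _ = generate_node_latents_and_features(cfg, rng)
        assert all(1 <= len(g) <= 3 for g in g_d)
        assert all(1 <= len(g) <= 2 for g in g_s)

    def test_allow_empty_drug_latents(self, rng):
        cfg = SyntheticConfig(n_drugs=300, n_side_effects=5, K_D=4, K_S=3,
                              M=1, N1=1, N2=1, allow_empty_drug_latents=True)
        g_d, _, _ = generate_node_latents_and_features(cfg, rng)
        sizes = {len(g) for g in g_d}
        assert sizes == {0, 1}


class TestTrueTriplesAndNoise:
    def test_empty_support_empty_edges(self):
        assert generate_true_triples(set(), [{0}] * 4, [{0}] * 3, 2, 2) \
            == set()

    def test_forced_inclusion_single_latents(self):
        A = {(0, 1, 0)}
        g_d = [{0}, {1}, {0}, {2}]
        g_s = [{0}, {1}]
        E = generate_true_triples(A, g_d, g_s, 3, 2)
        # drugs carrying latents {0} x {1} with side effect latent 0
        assert E == {(0, 1, 0), (1, 2, 0)}

    def test_matches_brute_force_oracle(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            g_d = [set(r.choice(5, size=r.integers(1, 3),
                                replace=False).tolist()) for _ in range(12)]
            g_s = [set(r.choice(4, size=r.integers(1, 3),
                                replace=False).tolist()) for _ in range(6)]
            A = {(int(i), int(j), int(k))
                 for i, j, k in zip(r.integers(0, 5, 6), r.integers(0, 5, 6),
                                    r.integers(0, 4, 6))}
            got = generate_true_triples(A, g_d, g_s, 5, 4)
            assert got == brute_force_true_triples(A, g_d, g_s)

    def test_noise_r0_identity(self, rng):
        E = {(0, 1, 0), (1, 2, 1)}
        assert apply_noise(E, 0.0, rng, 4, 2) == E

    def test_noise_conserves_size(self):
        E = {(u, v, t) for u in range(6) for v in range(u + 1, 6)
             for t in range(2) if (u + v + t) % 3 == 0}
        for r in (0.3, 1.0):
            out = apply_noise(E, r, np.random.default_rng(1), 6, 2)
            assert len(out) == len(E)

    def test_replacement_fraction(self):
        E = {(u, v, 0) for u in range(20) for v in range(u + 1, 20)}
        E = set(sorted(E)[:100])
        r, reps = 0.2, 150
        fracs = []
        for seed in range(reps):
            out = apply_noise(E, r, np.random.default_rng(seed), 20, 3)
            fracs.append(1 - len(out & E) / len(E))
        mean = np.mean(fracs)
        se = np.std(fracs, ddof=1) / np.sqrt(reps)
        assert abs(mean - r) <= 3 * se


class TestExpectedSparsity:
    def test_fully_sparse_model(self):
        assert expected_sparsity(1.0, 2, 2, 5, 5) == 1.0

    def test_saturated_model(self):
        assert expected_sparsity(0.0, 5, 5, 5, 5) == 0.0

    def test_p1_formula(self):
        assert uniform_hit_probability(2, 2, 5, 5) == pytest.approx(8 / 125)

    def test_first_order_linearization(self):
        # for very sparse supports E(s_d) ≈ 1 - (1-s_l) n_u² n_t
        s_l = 0.999
        got = expected_sparsity(s_l, 2, 2, 20, 10)
        lin = 1 - (1 - s_l) * 2 ** 2 * 2
        assert got == pytest.approx(lin, abs=2e-4)

    def test_monte_carlo_agreement(self):
        """Mean sparsity of hypergraphs generated from a uniform-random
        sparse support matches the closed form within 3 standard errors,
        and exceeds s_l * p1 in every run."""
        res = property1_experiment(0.99, 2, 2, 10, 10, n_drugs=40,
                                   n_side_effects=30, n_seeds=30, seed=3)
        assert abs(res["mean"] - res["expected"]) <= 3 * res["std_error"]
        assert np.all(res["per_seed"] > res["s_l"] * res["p1"])

    def test_uniform_support_is_offdiagonal(self, rng):
        A = generate_uniform_support(5, 4, 10, rng)
        assert len(A) == 10
        assert all(i < j for (i, j, _) in A)

    def test_non_integer_support_rejected(self):
        with pytest.raises(ValueError, match="non-integer"):
            property1_experiment(0.9876, 2, 2, 3, 3, n_seeds=2)


class TestDatasetGeneration:
    def test_deterministic(self):
        cfg = SyntheticConfig(n_drugs=30, n_side_effects=10, K_D=4, K_S=4,
                              M=1, N1=1, N2=1, seed=7)
        d1, d2 = generate_dataset(cfg), generate_dataset(cfg)
        assert np.array_equal(d1.G.hyperedges, d2.G.hyperedges)
        assert np.array_equal(d1.F.values, d2.F.values)
        assert d1.A == d2.A

    def test_size_conserved_under_noise(self):
        cfg = SyntheticConfig(n_drugs=30, n_side_effects=10, K_D=4, K_S=4,
                              M=1, N1=1, N2=1, r=0.01, seed=7)
        ds = generate_dataset(cfg)
        assert ds.G.n_edges == len(ds.true_triples)

    def test_achieved_sparsity_recorded(self):
        cfg = SyntheticConfig(n_drugs=30, n_side_effects=10, K_D=4, K_S=4,
                              M=1, N1=1, N2=1, seed=7)
        ds = generate_dataset(cfg)
        assert ds.achieved_sparsity == pytest.approx(data_sparsity(ds.G))

    def test_calibration_reaches_high_sparsity_at_small_k(self):
        ds = generate_calibrated_dataset(0.98, K_D=5, K_S=5, n_drugs=100,
                                         n_side_effects=60, seed=1)
        assert abs(ds.achieved_sparsity - 0.98) <= 0.005

    def test_write_and_reload(self, tmp_path):
        from sparseddi.hypergraph import load_hypergraph

        cfg = SyntheticConfig(n_drugs=20, n_side_effects=8, K_D=3, K_S=3,
                              M=1, N1=1, N2=1, seed=3, c=2)
        ds = generate_dataset(cfg)
        write_dataset(ds, tmp_path)
        G2, F2 = load_hypergraph(tmp_path / "triples.tsv",
                                 tmp_path / "features.tsv")
        assert G2.n_edges == ds.G.n_edges
        assert (tmp_path / "ground_truth.json").exists()


def test_config_validation():
    with pytest.raises(ValueError):
        SyntheticConfig(r=1.5)
    with pytest.raises(ValueError):
        SyntheticConfig(N1=10, K_D=5)
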