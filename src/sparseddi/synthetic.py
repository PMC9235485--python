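"""Synthetic DDI hypergraphs with planted latent interactions.

The generator realizes the model's own generative story so that recovery
can be tested without external data:

1. *Latent interactions*: for each side-effect latent feature ``k``, draw
   ``n_k ~ U{1..M}`` unordered drug-latent pairs; their union is the
   support ``A`` of the true interaction tensor.
2. *Node latents and features*: each drug gets ``n_u ~ U{1..N1}`` latent
   features ``g_u`` (optionally ``U{0..N1}``, see below) and an observable
   feature vector of length ``K_D·c`` that is 1 on the ``c`` columns of
   each owned latent, plus Gaussian noise of std ``δ``, clipped at 0;
   each side effect gets ``n_t ~ U{1..N2}`` latents ``g_t``.
3. *True triples*: ``(u, v, t)`` is a true DDI iff
   ``g_u × g_v × g_t ∩ A ≠ ∅`` (exact enumeration, no sampling).
4. *Noise*: each true triple is, with probability ``r``, replaced by a
   uniformly drawn non-member, conserving ``|E|``.

``allow_empty_drug_latents`` draws ``n_u ~ U{0..N1}``: drugs owning no
latent feature cause no interactions, which is the only way very sparse
data (e.g. 98% at K_D = K_S = 5) can be generated — with at least one
latent per drug the achievable sparsity at small K is bounded well below
that.  The calibration search uses it when needed.

``expected_sparsity`` gives the expected data sparsity of a model whose
support is *uniformly random* at latent sparsity ``s_l`` with exact
per-node latent counts: with ``m = (1-s_l)·K_D²K_S/2`` support entries
each hitting a given triple with probability ``q = 2 n_u² n_t/(K_D²K_S)``,
``E(s_d) = (1-q)^m ≈ 1 - (1-s_l)·n_u²·n_t``.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .hypergraph import DDIHypergraph, DrugFeatureMatrix, data_sparsity

__all__ = [
    "SyntheticConfig",
    "SyntheticDataset",
    "generate_latent_interactions",
    "generate_node_latents_and_features",
    "generate_true_triples",
    "apply_noise",
    "expected_sparsity",
    "uniform_hit_probability",
    "generate_uniform_support",
    "property1_experiment",
    "generate_dataset",
    "calibrate_sparsity",
    "generate_calibrated_dataset",
    "write_dataset",
]


@dataclass
class SyntheticConfig:
    n_drugs: int = 400
    n_side_effects: int = 300
    K_D: int = 50
    K_S: int = 50
    M: int = 1       # max drug-latent pairs per side-effect latent
    N1: int = 4      # max drug latent features per drug
    N2: int = 4      # max side-effect latent features per side effect
    r: float = 0.01  # noise: probability a true triple is replaced
    delta: float = 0.1  # feature noise std
    c: int = 10      # feature replication factor (K0 = K_D * c)
    seed: int = 0
    allow_empty_drug_latents: bool = False
    allow_empty_side_effect_latents: bool = False

    def __post_init__(self):
        for name in ("n_drugs", "n_side_effects", "K_D", "K_S", "M",
                     "N1", "N2", "c"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (0.0 <= self.r <= 1.0):
            raise ValueError("noise rate r must be in [0, 1]")
        if self.delta < 0:
            raise ValueError("delta must be nonnegative")
        if self.N1 > self.K_D or self.N2 > self.K_S:
            raise ValueError("per-node latent counts cannot exceed the "
                             "number of latent features")


@dataclass(eq=False)
class SyntheticDataset:
    """Generated data plus the hidden ground truth for recovery tests."""

    G: DDIHypergraph
    F: DrugFeatureMatrix
    A: set              # planted support {(i, j, k)}, i <= j
    g_drugs: list       # per-drug latent sets
    g_side_effects: list
    true_triples: set   # E* before noise
    config: SyntheticConfig
    achieved_sparsity: float = field(init=False)

    def __post_init__(self):
        self.achieved_sparsity = data_sparsity(self.G)


# ---------------------------------------------------------------------------
# Generation steps
# ---------------------------------------------------------------------------

def generate_latent_interactions(config: SyntheticConfig,
                                 rng: np.random.Generator) -> set:
    """Planted support A: per side-effect latent k, 1..M distinct unordered
    drug-latent pairs (diagonal pairs allowed)."""
    pairs = [(i, j) for i in range(config.K_D)
             for j in range(i, config.K_D)]
    A = set()
    for k in range(config.K_S):
        n_k = int(rng.integers(1, config.M + 1))
        if n_k > len(pairs):
            warnings.warn(f"requested {n_k} pairs but only {len(pairs)} "
                          "distinct pairs exist; capping")
            n_k = len(pairs)
        chosen = rng.choice(len(pairs), size=n_k, replace=False)
        for c in chosen:
            A.add((*pairs[int(c)], k))
    return A


def _sample_latent_sets(n_nodes: int, K: int, n_max: int, allow_empty: bool,
                        rng: np.random.Generator) -> list[set]:
    low = 0 if allow_empty else 1
    out = []
    for _ in range(n_nodes):
        n = int(rng.integers(low, n_max + 1))
        out.append(set(rng.choice(K, size=n, replace=False).tolist()))
    return out


def generate_node_latents_and_features(config: SyntheticConfig,
                                       rng: np.random.Generator,
                                       ) -> tuple[list, list, np.ndarray]:
    """Per-drug and per-side-effect latent sets, plus noisy drug features.

    The noiseless feature vector of drug u is the block indicator of g_u
    replicated c times; Gaussian noise of std δ is added and the result is
    clipped at zero to keep features nonnegative.
    """
    g_drugs = _sample_latent_sets(config.n_drugs, config.K_D, config.N1,
                                  config.allow_empty_drug_latents, rng)
    g_ses = _sample_latent_sets(config.n_side_effects, config.K_S, config.N2,
                                config.allow_empty_side_effect_latents, rng)
    K0 = config.K_D * config.c
    means = np.zeros((config.n_drugs, K0))
    for u, g in enumerate(g_drugs):
        for i in g:
            means[u, i * config.c:(i + 1) * config.c] = 1.0
    F = means + rng.normal(0.0, config.delta, size=means.shape)
    return g_drugs, g_ses, np.clip(F, 0.0, None)


def generate_true_triples(A: set, g_drugs: list, g_side_effects: list,
                          K_D: int, K_S: int) -> set:
    """Exact enumeration of E*: (u,v,t) with u<v is a true triple iff some
    (i,j,k) with i ∈ g_u, j ∈ g_v, k ∈ g_t lies in the (symmetrized)
    planted support."""
    nd, ns = len(g_drugs), len(g_side_effects)
    Asym = np.zeros((K_D, K_D, K_S))
    for (i, j, k) in A:
        Asym[i, j, k] = 1.0
        Asym[j, i, k] = 1.0
    Gd = np.zeros((nd, K_D))
    for u, g in enumerate(g_drugs):
        Gd[u, list(g)] = 1.0
    # pair_hits[u, v, k] > 0 iff drugs u, v cover some pair of A's slice k
    X = np.einsum("ui,ijk->ujk", Gd, Asym)
    pair_hits = np.einsum("ujk,vj->uvk", X, Gd) > 0
    iu, iv = np.triu_indices(nd, k=1)
    E_star = set()
    for t, g in enumerate(g_side_effects):
        if not g:
            continue
        hit = pair_hits[:, :, list(g)].any(axis=2)
        for u, v in zip(iu[hit[iu, iv]], iv[hit[iu, iv]]):
            E_star.add((int(u), int(v), int(t)))
    return E_star


def apply_noise(true_triples: set, r: float, rng: np.random.Generator,
                n_drugs: int, n_side_effects: int) -> set:
    """Replace each true triple, with probability r, by a uniform canonical
    non-member of E*; the edge count is conserved."""
    from .objective import sample_negative_triples

    if not (0.0 <= r <= 1.0):
        raise ValueError("noise rate must be in [0, 1]")
    triples = sorted(true_triples)
    flags = rng.random(len(triples)) < r
    kept = {e for e, f in zip(triples, flags) if not f}
    n_replace = int(flags.sum())
    if n_replace == 0:
        return set(triples)
    universe = n_drugs * (n_drugs - 1) // 2 * n_side_effects
    if universe - len(true_triples) < n_replace:
        raise ValueError("hypergraph too complete to draw replacement "
                         "non-members")
    repl = sample_negative_triples(n_drugs, n_side_effects, n_replace, rng,
                                   frozenset(true_triples))
    return kept | set(map(tuple, repl.tolist()))


# ---------------------------------------------------------------------------
# Expected sparsity of a uniformly random sparse model (Property-1 law)
# ---------------------------------------------------------------------------

def uniform_hit_probability(n_u: int, n_t: int, K_D: int, K_S: int) -> float:
    """p1 = n_u² n_t / (K_D² K_S): probability that one uniform (ordered)
    support entry lands among the latent combinations of a given triple."""
    return (n_u ** 2 * n_t) / (K_D ** 2 * K_S)


def expected_sparsity(s_l: float, n_u: int, n_t: int, K_D: int,
                      K_S: int) -> float:
    """Expected data sparsity generated by a uniformly random support at
    latent sparsity ``s_l`` with exactly ``n_u``/``n_t`` latents per node.

    Each of the ``m = (1-s_l) K_D² K_S / 2`` unordered support entries
    hits a given triple with probability ``q = 2 n_u² n_t / (K_D² K_S)``
    (twice p1: either orientation of the drug pair), so a triple is a
    non-edge with probability ``(1-q)^m``; to first order this is
    ``1 - (1-s_l) n_u² n_t``.
    """
    if not (0.0 <= s_l <= 1.0):
        raise ValueError("latent sparsity must be in [0, 1]")
    m = (1.0 - s_l) * K_D ** 2 * K_S / 2.0
    q = min(1.0, 2.0 * uniform_hit_probability(n_u, n_t, K_D, K_S))
    return float((1.0 - q) ** m)


def generate_uniform_support(K_D: int, K_S: int, n_entries: int,
                             rng: np.random.Generator) -> set:
    """Uniformly random support of ``n_entries`` distinct (i < j, k)
    off-diagonal entries — the reference generative process behind the
    expected-sparsity law."""
    pairs = [(i, j) for i in range(K_D) for j in range(i + 1, K_D)]
    cells = [(i, j, k) for (i, j) in pairs for k in range(K_S)]
    if n_entries > len(cells):
        raise ValueError("support size exceeds number of off-diagonal cells")
    chosen = rng.choice(len(cells), size=n_entries, replace=False)
    return {cells[int(c)] for c in chosen}


def property1_experiment(s_l: float, n_u: int, n_t: int, K_D: int, K_S: int,
                         n_drugs: int = 40, n_side_effects: int = 30,
                         n_seeds: int = 30, seed: int = 0) -> dict:
    """Monte-Carlo check of the expected-sparsity law.

    Per seed: draw a uniform support at latent sparsity ``s_l``, give every
    drug exactly ``n_u`` and every side effect exactly ``n_t`` latents,
    enumerate the generated hypergraph and record its data sparsity.
    Returns the per-seed sparsities, their mean and standard error, the
    closed-form expectation and ``p1``.
    """
    m = (1.0 - s_l) * K_D ** 2 * K_S / 2.0
    n_entries = int(round(m))
    if abs(m - n_entries) > 1e-9:
        raise ValueError(
            f"latent sparsity {s_l} implies a non-integer support size {m}")
    rng = np.random.default_rng(seed)
    achieved = []
    for _ in range(n_seeds):
        A = generate_uniform_support(K_D, K_S, n_entries, rng)
        g_d = [set(rng.choice(K_D, size=n_u, replace=False).tolist())
               for _ in range(n_drugs)]
        g_s = [set(rng.choice(K_S, size=n_t, replace=False).tolist())
               for _ in range(n_side_effects)]
        E = generate_true_triples(A, g_d, g_s, K_D, K_S)
        sd = 1.0 - 2.0 * len(E) / (n_drugs * (n_drugs - 1) * n_side_effects)
        achieved.append(sd)
    achieved = np.asarray(achieved)
    return {
        "per_seed": achieved,
        "mean": float(achieved.mean()),
        "std_error": float(achieved.std(ddof=1) / np.sqrt(n_seeds)),
        "expected": expected_sparsity(s_l, n_u, n_t, K_D, K_S),
        "p1": uniform_hit_probability(n_u, n_t, K_D, K_S),
        "s_l": s_l,
    }


# ---------------------------------------------------------------------------
# Full dataset generation and sparsity calibration
# ---------------------------------------------------------------------------

def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Compose the four generation steps into a dataset with ground truth."""
    rng = np.random.default_rng(config.seed)
    A = generate_latent_interactions(config, rng)
    g_d, g_s, F = generate_node_latents_and_features(config, rng)
    E_star = generate_true_triples(A, g_d, g_s, config.K_D, config.K_S)
    if not E_star:
        raise ValueError("generated hypergraph has no true triples; "
                         "increase M/N1/N2 or the node counts")
    E = apply_noise(E_star, config.r, rng, config.n_drugs,
                    config.n_side_effects)
    drug_ids = [f"D{u:04d}" for u in range(config.n_drugs)]
    se_ids = [f"S{t:03d}" for t in range(config.n_side_effects)]
    feat_names = [f"lat{i}_r{j}" for i in range(config.K_D)
                  for j in range(config.c)]
    G = DDIHypergraph.from_triples(drug_ids, se_ids, sorted(E))
    return SyntheticDataset(G, DrugFeatureMatrix(F, feat_names), A, g_d,
                            g_s, E_star, config)


def calibrate_sparsity(target: float, K_D: int, K_S: int, n_drugs: int,
                       n_side_effects: int, r: float = 0.01,
                       delta: float = 0.1, c: int = 10, seed: int = 0,
                       n_reps: int = 6, probe_drugs: int | None = None,
                       probe_side_effects: int | None = None,
                       ) -> SyntheticConfig:
    """Search (M, N1, N2, allow-empty) for a target data sparsity.

    Candidate settings are scored by the mean sparsity of ``n_reps``
    probe generations (at the requested node counts by default; the
    achievable sparsities form a discrete spectrum, so enough replicates
    are needed to separate neighbouring candidates); the closest
    candidate is returned as a full-size config.  Deterministic given
    the seed.
    """
    if not (0.0 < target < 1.0):
        raise ValueError("target sparsity must be in (0, 1)")
    probe_drugs = probe_drugs or n_drugs
    probe_side_effects = probe_side_effects or n_side_effects
    max_pairs = K_D * (K_D + 1) // 2
    Ms = [m for m in (1, 2, 4, 8, 16, 32) if m <= max_pairs]
    N1s = [n for n in (1, 2, 3, 4) if n <= K_D]
    N2s = [n for n in (1, 2, 3, 4) if n <= K_S]
    best, best_gap = None, np.inf
    for allow_empty in (False, True):
        for M, N1, N2 in itertools.product(Ms, N1s, N2s):
            probe = SyntheticConfig(
                n_drugs=probe_drugs, n_side_effects=probe_side_effects,
                K_D=K_D, K_S=K_S, M=M, N1=N1, N2=N2, r=0.0, delta=0.0,
                c=1, seed=seed, allow_empty_drug_latents=allow_empty)
            vals = []
            for rep in range(n_reps):
                rng = np.random.default_rng(
                    np.random.SeedSequence(entropy=(seed, M, N1, N2,
                                                    int(allow_empty), rep)))
                A = generate_latent_interactions(probe, rng)
                g_d = _sample_latent_sets(probe.n_drugs, K_D, N1,
                                          allow_empty, rng)
                g_s = _sample_latent_sets(probe.n_side_effects, K_S, N2,
                                          False, rng)
                E = generate_true_triples(A, g_d, g_s, K_D, K_S)
                vals.append(1.0 - 2.0 * len(E) / (probe.n_drugs *
                            (probe.n_drugs - 1) * probe.n_side_effects))
            gap = abs(float(np.mean(vals)) - target)
            # prefer the simpler convention (no empty drugs) on near-ties
            if gap < best_gap - 1e-9:
                best_gap = gap
                best = (M, N1, N2, allow_empty)
    M, N1, N2, allow_empty = best
    return SyntheticConfig(n_drugs=n_drugs, n_side_effects=n_side_effects,
                           K_D=K_D, K_S=K_S, M=M, N1=N1, N2=N2, r=r,
                           delta=delta, c=c, seed=seed,
                           allow_empty_drug_latents=allow_empty)


def generate_calibrated_dataset(target: float, K_D: int, K_S: int,
                                n_drugs: int, n_side_effects: int,
                                r: float = 0.01, seed: int = 0,
                                tol: float = 0.003,
                                max_tries: int = 8) -> SyntheticDataset:
    """A dataset whose *realized* sparsity matches the target.

    ``calibrate_sparsity`` tunes the generator in expectation, but a
    single realization still scatters around the target (the planted
    blocks vary in size).  This wrapper regenerates (deterministically,
    seeds derived from ``seed``) until the achieved sparsity falls within
    ``tol`` of the target, returning the closest realization if none
    does.
    """
    cfg = calibrate_sparsity(target, K_D, K_S, n_drugs, n_side_effects,
                             r=r, seed=seed)
    best = None
    for attempt in range(max_tries):
        ds_seed = int(np.random.SeedSequence(
            entropy=(seed, attempt)).generate_state(1)[0] % (2 ** 31))
        ds = generate_dataset(SyntheticConfig(
            **{**asdict(cfg), "seed": ds_seed}))
        gap = abs(ds.achieved_sparsity - target)
        if best is None or gap < abs(best.achieved_sparsity - target):
            best = ds
        if gap <= tol:
            return ds
    return best


def write_dataset(ds: SyntheticDataset, directory) -> None:
    """Write triples/features TSVs plus a JSON ground-truth sidecar."""
    from pathlib import Path

    from .hypergraph import save_features, save_triples

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    save_triples(ds.G, directory / "triples.tsv")
    save_features(ds.G, ds.F, directory / "features.tsv")
    sidecar = {
        "config": asdict(ds.config),
        "A": sorted(map(list, ds.A)),
        "g_drugs": [sorted(g) for g in ds.g_drugs],
        "g_side_effects": [sorted(g) for g in ds.g_side_effects],
        "n_true_triples": len(ds.true_triples),
        "achieved_sparsity": ds.achieved_sparsity,
    }
    with open(directory / "ground_truth.json", "w") as fh:
        json.dump(sidecar, fh)
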