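"""Reconstruction likelihood, shrinkage priors and the MAP objective.

The decoder treats the membership indicator of every triple as a Gaussian
observation centred on the model score,

    log p(e | B, H) = -(i(e) - m(e))² / (2σ²) - log(σ√(2π)),

summed over an evaluated triple set.  The literal likelihood runs over
*all* canonical triples, which is intractable beyond toys, so the default
evaluates the positives plus uniformly sampled non-edge negatives
(``neg_ratio`` per positive, redrawn each epoch); an exhaustive mode is
used when the triple universe is small.

Three model variants differ only in the prior placed on the interaction
tensor ``B``: none, Laplace (an L1 penalty), or the horseshoe —
``B_ijk ~ N(0, τ²Λ_ijk²)`` with half-Cauchy local scales ``Λ_ijk`` and
global scale ``τ``.  All functions accept plain arrays (returning floats)
or autodiff Tensors (returning Tensors), so the same expressions define
the training gradient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .hypergraph import DDIHypergraph
from .tensor_ops import InteractionTensor

__all__ = [
    "HorseshoeState",
    "ObjectiveConfig",
    "triple_log_likelihood",
    "gaussian_log_likelihood",
    "sample_negative_triples",
    "all_canonical_triples",
    "build_evaluation_set",
    "reconstruction_log_likelihood",
    "horseshoe_log_prior",
    "laplace_log_prior",
    "objective",
    "shrinkage_profile",
]

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


@dataclass(eq=False)
class HorseshoeState:
    """Local scales Λ (same shape as B) and the global scale τ."""

    lam: np.ndarray
    tau: float

    def __post_init__(self):
        self.lam = np.asarray(self.lam, dtype=np.float64)
        if self.lam.size and self.lam.min() < 0:
            raise ValueError("local scales must be nonnegative")
        if self.tau <= 0:
            raise ValueError("tau must be positive")


@dataclass
class ObjectiveConfig:
    sigma: float = 1.0
    prior_kind: str = "horseshoe"      # none | laplace | horseshoe
    tau: float = 0.02
    laplace_scale: float | None = None  # defaults to tau (shared grid)
    neg_ratio: int = 1
    neg_seed: int = 0
    exhaustive: bool = False
    exhaustive_guard: int = 500_000     # max |V_D|²|V_S| for exhaustive mode

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.prior_kind not in ("none", "laplace", "horseshoe"):
            raise ValueError(f"unknown prior_kind {self.prior_kind!r}")
        if self.neg_ratio < 1:
            raise ValueError("neg_ratio must be >= 1")

    @property
    def effective_laplace_scale(self) -> float:
        return self.tau if self.laplace_scale is None else self.laplace_scale


def _maybe_item(t: Tensor, inputs) -> Tensor | float:
    if any(isinstance(x, Tensor) for x in inputs):
        return t
    return t.item()


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

def triple_log_likelihood(score, label, sigma: float = 1.0):
    """Gaussian log-density of one triple's indicator at the model score."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return gaussian_log_likelihood(np.atleast_1d(score) if not isinstance(
        score, Tensor) else score, np.atleast_1d(label) if not isinstance(
        label, Tensor) else label, sigma)


def gaussian_log_likelihood(scores, labels, sigma: float = 1.0):
    """Σ log N(label − score; 0, σ²) over a batch of triples."""
    s, l = ad.wrap(scores), ad.wrap(labels)
    n = s.value.size
    resid = l - s
    ll = ad.total(ad.square(resid)) * (-0.5 / sigma ** 2) + \
        (-n * (math.log(sigma) + _LOG_SQRT_2PI))
    return _maybe_item(ll, (scores, labels))


# ---------------------------------------------------------------------------
# Triple-set construction
# ---------------------------------------------------------------------------

def all_canonical_triples(n_drugs: int, n_side_effects: int) -> np.ndarray:
    """All (u, v, t) with u < v, as an (n, 3) array in lexicographic order."""
    u, v = np.triu_indices(n_drugs, k=1)
    pairs = np.column_stack([u, v])
    reps = np.repeat(pairs, n_side_effects, axis=0)
    ts = np.tile(np.arange(n_side_effects), len(pairs))
    return np.column_stack([reps, ts]).astype(np.int64)


def encode_triples(triples: np.ndarray, n_drugs: int,
                   n_side_effects: int) -> np.ndarray:
    """Bijection from canonical triples to flat integer ids."""
    triples = np.asarray(triples, dtype=np.int64).reshape(-1, 3)
    return ((triples[:, 0] * n_drugs + triples[:, 1]) * n_side_effects
            + triples[:, 2])


def sample_negative_triples(n_drugs: int, n_side_effects: int, n: int,
                            rng: np.random.Generator,
                            exclude,
                            with_replacement: bool = False) -> np.ndarray:
    """Uniform canonical triples avoiding ``exclude`` (a set of triples or
    a pre-sorted array of flat ids) and, by default, repeats within the
    drawn batch.  Collisions are rejected and redrawn."""
    n_possible = n_drugs * (n_drugs - 1) // 2 * n_side_effects
    if not with_replacement and n > n_possible - len(exclude):
        raise ValueError("not enough non-excluded canonical triples")
    if isinstance(exclude, np.ndarray):
        exclude_ids = exclude
    else:
        exclude_ids = np.sort(encode_triples(
            np.array(sorted(exclude), dtype=np.int64).reshape(-1, 3),
            n_drugs, n_side_effects)) if len(exclude) else np.empty(0, int)
    chunks: list[np.ndarray] = []
    seen = np.empty(0, dtype=np.int64)
    remaining = n
    while remaining > 0:
        m = max(256, int(1.5 * remaining))
        u = rng.integers(0, n_drugs, size=m)
        v = rng.integers(0, n_drugs, size=m)
        t = rng.integers(0, n_side_effects, size=m)
        ok = u != v
        lo, hi = np.minimum(u, v)[ok], np.maximum(u, v)[ok]
        ids = (lo * n_drugs + hi) * n_side_effects + t[ok]
        pos = np.searchsorted(exclude_ids, ids)
        pos = np.minimum(pos, len(exclude_ids) - 1) if len(exclude_ids) \
            else pos
        if len(exclude_ids):
            ids = ids[exclude_ids[pos] != ids]
        if not with_replacement:
            ids = ids[~np.isin(ids, seen)]
            ids = _unique_keep_order(ids)
            seen = np.concatenate([seen, ids[:remaining]])
        take = ids[:remaining]
        chunks.append(take)
        remaining -= len(take)
    ids = np.concatenate(chunks)
    t = ids % n_side_effects
    rest = ids // n_side_effects
    return np.column_stack([rest // n_drugs, rest % n_drugs, t])


def _unique_keep_order(ids: np.ndarray) -> np.ndarray:
    """First-occurrence unique (order-preserving)."""
    _, first = np.unique(ids, return_index=True)
    return ids[np.sort(first)]


def build_evaluation_set(G: DDIHypergraph, config: ObjectiveConfig,
                         rng: np.random.Generator | None = None,
                         ) -> tuple[np.ndarray, np.ndarray]:
    """The triple set the likelihood runs over, with 0/1 labels.

    Exhaustive mode (all canonical triples) when requested and the
    universe is below the size guard; otherwise positives plus
    ``neg_ratio`` sampled negatives per positive.
    """
    nd, ns = G.n_drugs, G.n_side_effects
    universe = nd * (nd - 1) // 2 * ns
    if config.exhaustive:
        if universe > config.exhaustive_guard:
            raise ValueError(
                f"exhaustive likelihood over {universe} triples exceeds the "
                f"size guard {config.exhaustive_guard}")
        triples = all_canonical_triples(nd, ns)
        labels = np.array([G.indicator(*e) for e in triples], dtype=float)
        return triples, labels
    if rng is None:
        rng = np.random.default_rng(config.neg_seed)
    pos = G.hyperedges
    neg = sample_negative_triples(nd, ns, config.neg_ratio * len(pos), rng,
                                  G._edge_set)
    triples = np.vstack([pos, neg])
    labels = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
    return triples, labels


def reconstruction_log_likelihood(scores, labels, sigma: float = 1.0):
    """Sum of per-triple Gaussian log-likelihoods over an evaluated set."""
    return gaussian_log_likelihood(scores, labels, sigma)


# ---------------------------------------------------------------------------
# Priors
# ---------------------------------------------------------------------------

def horseshoe_log_prior(B, lam, tau: float):
    """log p(B | Λ, τ) + log p(Λ), additive constant dropped.

    ``Σ [-½ (B_ijk/(τΛ_ijk))² - log Λ_ijk] + Σ log 1/(1+Λ_ijk²)``.
    A zero local scale with a nonzero matching B entry gives −inf.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    if isinstance(B, InteractionTensor):
        B = B.values
    if isinstance(lam, HorseshoeState):
        lam = lam.lam
    Bt, Lt = ad.wrap(B), ad.wrap(lam)
    if isinstance(B, Tensor) or isinstance(lam, Tensor):
        ratio = Bt * _reciprocal(Lt, tau)
        term = (ad.total(ad.square(ratio)) * (-0.5)
                - ad.total(ad.log(Lt))
                - ad.total(ad.log(ad.square(Lt) + 1.0)))
        return term
    B = np.asarray(B, dtype=float)
    lam = np.asarray(lam, dtype=float)
    pos = lam > 0
    safe = np.where(pos, lam, 1.0)
    per_entry = (-0.5 * (B / (tau * safe)) ** 2 - np.log(safe)
                 - np.log1p(safe ** 2))
    # Λ = 0: the density has an infinite spike at B = 0 and no mass elsewhere
    per_entry = np.where(pos, per_entry,
                         np.where(B != 0, -np.inf, np.inf))
    if np.any(np.isneginf(per_entry)):
        return float("-inf")
    return float(per_entry.sum())


def _reciprocal(lam: Tensor, tau: float) -> Tensor:
    inv = Tensor(1.0 / (tau * lam.value), _parents=(lam,))

    def bw(g):
        lam._accumulate(-g / (tau * lam.value ** 2))

    inv._backward = bw
    return inv


def laplace_log_prior(B, scale: float):
    """L1 shrinkage: −Σ |B_ijk| / scale (normalization dropped)."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    if isinstance(B, InteractionTensor):
        B = B.values
    t = ad.total(ad.absolute(ad.wrap(B))) * (-1.0 / scale)
    return _maybe_item(t, (B,))


def prior_log_density(B, lam, config: ObjectiveConfig):
    """Dispatch on the variant: none → 0, laplace → L1, horseshoe → HS."""
    if config.prior_kind == "none":
        return ad.wrap(0.0) if isinstance(B, Tensor) else 0.0
    if config.prior_kind == "laplace":
        return laplace_log_prior(B, config.effective_laplace_scale)
    return horseshoe_log_prior(B, lam, config.tau)


def objective(G: DDIHypergraph, latent, B, horseshoe: HorseshoeState | None,
              config: ObjectiveConfig,
              rng: np.random.Generator | None = None) -> float:
    """MAP objective (to maximize): reconstruction log-likelihood plus the
    selected prior term, evaluated with numpy on given latent states."""
    from .tensor_ops import batch_scores

    triples, labels = build_evaluation_set(G, config, rng)
    scores = batch_scores(B, latent.H_d, latent.H_s, triples)
    ll = gaussian_log_likelihood(scores, labels, config.sigma)
    lam = horseshoe.lam if horseshoe is not None else None
    if config.prior_kind == "horseshoe" and lam is None:
        raise ValueError("horseshoe prior requires a HorseshoeState")
    return float(ll + prior_log_density(
        B.values if isinstance(B, InteractionTensor) else B, lam, config))


# ---------------------------------------------------------------------------
# Shrinkage diagnostics
# ---------------------------------------------------------------------------

def shrinkage_profile(B_map, B_ml, denom_eps: float = 1e-12,
                      ) -> tuple[np.ndarray, int]:
    """Per-entry shrinkage factors κ = 1 − B_map/B_ml, clipped to [0, 1].

    Entries whose unpenalized estimate is (numerically) zero cannot define
    a shrinkage factor; they are excluded and counted.  Returns the flat
    array of valid κ values and the number of excluded entries.
    """
    a = B_map.values if isinstance(B_map, InteractionTensor) else np.asarray(B_map, float)
    b = B_ml.values if isinstance(B_ml, InteractionTensor) else np.asarray(B_ml, float)
    if a.shape != b.shape:
        raise ValueError("shapes of the two estimates differ")
    valid = np.abs(b) > denom_eps
    kappa = 1.0 - a[valid] / b[valid]
    return np.clip(kappa, 0.0, 1.0), int((~valid).sum())
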