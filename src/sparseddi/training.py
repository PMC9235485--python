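"""Model fitting by stochastic gradient MAP estimation, and prediction.

Three variants share one architecture and differ only in the prior on the
interaction tensor:

* ``SPARSE``  — horseshoe prior (global scale τ, half-Cauchy local scales,
  optimized jointly via Λ = exp(λ)),
* ``SPARSEL`` — Laplace prior (L1 penalty at scale τ),
* ``SPARSEO`` — no sparsity prior.

The objective is maximized with Adam over the encoder weights, the free
tensor parameter and (for the horseshoe) the local log-scales, with fresh
uniformly sampled negatives every epoch.  Everything is deterministic for
a fixed seed.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import autodiff as ad
from .autodiff import Tensor
from .encoder import (EncoderConfig, GraphArrays, LatentState, encode_graph,
                      init_parameters, parameter_list)
from .hypergraph import DDIHypergraph, DrugFeatureMatrix
from .objective import (HorseshoeState, ObjectiveConfig,
                        all_canonical_triples, encode_triples,
                        gaussian_log_likelihood, prior_log_density,
                        sample_negative_triples)
from .tensor_ops import InteractionTensor, batch_scores

__all__ = [
    "TrainConfig",
    "TrainedModel",
    "LATENT_DIM_GRID",
    "TAU_GRID",
    "N_LAYERS_GRID",
    "VARIANTS",
    "fit",
    "predict_scores",
    "rank_unknown_triples",
    "grid_search",
]

#: hyperparameter grids used by the grid-search driver
LATENT_DIM_GRID = (30, 40, 50, 60)
TAU_GRID = (0.01, 0.02, 0.03, 0.05, 0.1)
N_LAYERS_GRID = (1, 2, 3)

VARIANTS = {"SPARSE": "horseshoe", "SPARSEL": "laplace", "SPARSEO": "none"}


@dataclass
class TrainConfig:
    variant: str = "SPARSE"        # SPARSE | SPARSEL | SPARSEO
    latent_dim: int = 50
    n_layers: int = 2
    tau: float = 0.02
    learning_rate: float = 1e-2
    epochs: int = 500
    seed: int = 0
    neg_ratio: int = 1
    sigma: float = 1.0
    b_parameterization: str = "free_parameter"
    hidden_width: int | None = None  # message-MLP width; default latent_dim
    n_restarts: int = 1              # independent inits raced for `restart_epochs`
    restart_epochs: int | None = None  # selection point; default epochs // 2

    def __post_init__(self):
        v = self.variant.upper()
        if v in VARIANTS:
            self.variant = v
        elif self.variant.lower() in VARIANTS.values():
            self.variant = {p: n for n, p in VARIANTS.items()}[
                self.variant.lower()]
        else:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0 or self.tau <= 0:
            raise ValueError("learning_rate and tau must be positive")

    @property
    def prior_kind(self) -> str:
        return VARIANTS[self.variant]

    def encoder_config(self) -> EncoderConfig:
        return EncoderConfig(n_layers=self.n_layers,
                             latent_dim=self.latent_dim,
                             b_parameterization=self.b_parameterization,
                             hidden_width=self.hidden_width)

    def objective_config(self) -> ObjectiveConfig:
        return ObjectiveConfig(sigma=self.sigma, prior_kind=self.prior_kind,
                               tau=self.tau, neg_ratio=self.neg_ratio,
                               neg_seed=self.seed)


@dataclass(eq=False)
class TrainedModel:
    """A fitted model: weights, latent snapshot, tensor, vocabularies."""

    config: TrainConfig
    drug_ids: list[str]
    side_effect_ids: list[str]
    params: dict[str, np.ndarray]
    latent: LatentState
    B: InteractionTensor
    horseshoe: HorseshoeState | None
    trace: pd.DataFrame
    _drug_index: dict = field(init=False, repr=False)
    _se_index: dict = field(init=False, repr=False)

    def __post_init__(self):
        self._drug_index = {d: i for i, d in enumerate(self.drug_ids)}
        self._se_index = {s: i for i, s in enumerate(self.side_effect_ids)}

    # -- persistence ----------------------------------------------------
    def save(self, path) -> None:
        meta = {
            "config": asdict(self.config),
            "drug_ids": self.drug_ids,
            "side_effect_ids": self.side_effect_ids,
            "tau": None if self.horseshoe is None else self.horseshoe.tau,
            "param_names": sorted(self.params),
        }
        arrays = {f"param_{k}": v for k, v in self.params.items()}
        arrays["H_d"] = self.latent.H_d
        arrays["H_s"] = self.latent.H_s
        arrays["B"] = self.B.values
        if self.horseshoe is not None:
            arrays["lam"] = self.horseshoe.lam
        buf = io.BytesIO()
        self.trace.to_csv(buf, index=False)
        arrays["trace_csv"] = np.frombuffer(buf.getvalue(), dtype=np.uint8)
        arrays["meta_json"] = np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "TrainedModel":
        with np.load(path) as f:
            meta = json.loads(bytes(f["meta_json"]).decode())
            params = {k: f[f"param_{k}"] for k in meta["param_names"]}
            hs = (HorseshoeState(f["lam"], meta["tau"])
                  if "lam" in f else None)
            trace = pd.read_csv(io.BytesIO(bytes(f["trace_csv"])))
            return cls(TrainConfig(**meta["config"]), meta["drug_ids"],
                       meta["side_effect_ids"], params,
                       LatentState(f["H_d"], f["H_s"]),
                       InteractionTensor(f["B"]), hs, trace)

    # -- lookups ----------------------------------------------------------
    def triple_indices(self, triples) -> np.ndarray:
        out = []
        for (a, b, s) in triples:
            if isinstance(a, str) or isinstance(b, str) or isinstance(s, str):
                for x, table, kind in ((a, self._drug_index, "drug"),
                                       (b, self._drug_index, "drug"),
                                       (s, self._se_index, "side effect")):
                    if x not in table:
                        raise KeyError(f"unknown {kind} id {x!r}")
                out.append((self._drug_index[a], self._drug_index[b],
                            self._se_index[s]))
            else:
                out.append((int(a), int(b), int(s)))
        return np.asarray(out, dtype=np.int64).reshape(-1, 3)


class _TrainState:
    """One optimization run: parameters, optimizer and sampling stream."""

    def __init__(self, G: DDIHypergraph, F_d: DrugFeatureMatrix,
                 config: TrainConfig, arrays: GraphArrays, restart: int,
                 initial_params: dict[str, np.ndarray] | None = None,
                 train_only: tuple[str, ...] | None = None):
        self.G, self.F_d, self.config = G, F_d, config
        self.arrays = arrays
        self.enc_cfg = config.encoder_config()
        self.obj_cfg = config.objective_config()
        if initial_params is not None:
            self.params = {k: Tensor(v.copy(), requires_grad=True)
                           for k, v in initial_params.items()}
        else:
            rng_init = np.random.default_rng(np.random.SeedSequence(
                entropy=(config.seed, restart)))
            self.params = init_parameters(self.enc_cfg, G.n_drugs,
                                          G.n_side_effects, F_d.n_features,
                                          rng_init)
        if config.prior_kind == "horseshoe" and "lam_raw" not in self.params:
            d = config.latent_dim
            self.params["lam_raw"] = Tensor(np.zeros((d, d, d)),
                                            requires_grad=True)
        trainable = (self.params if train_only is None
                     else {k: v for k, v in self.params.items()
                           if k in train_only})
        self.opt = ad.Adam(parameter_list(trainable),
                           lr=config.learning_rate)
        self.rng_neg = np.random.default_rng(np.random.SeedSequence(
            entropy=(config.seed, restart, 0x5eed)))
        self.pos = G.hyperedges
        self.pos_ids = np.sort(encode_triples(self.pos, G.n_drugs,
                                              G.n_side_effects))
        self.labels = np.concatenate([
            np.ones(len(self.pos)),
            np.zeros(config.neg_ratio * len(self.pos))])
        self.rows: list[dict] = []

    def run_epochs(self, n: int) -> None:
        cfg = self.config
        for _ in range(n):
            epoch = len(self.rows)
            neg = sample_negative_triples(
                self.G.n_drugs, self.G.n_side_effects,
                cfg.neg_ratio * len(self.pos), self.rng_neg, self.pos_ids)
            triples = np.vstack([self.pos, neg])
            h_d, h_s, B = encode_graph(self.params, self.arrays, self.F_d,
                                       self.enc_cfg)
            scores = _symmetric_scores(B, h_d, h_s, triples)
            ll = gaussian_log_likelihood(scores, self.labels, cfg.sigma)
            lam = (ad.exp(self.params["lam_raw"])
                   if cfg.prior_kind == "horseshoe" else None)
            prior = prior_log_density(B, lam, self.obj_cfg)
            obj = ll + prior
            if not np.isfinite(obj.value):
                raise RuntimeError(
                    f"objective diverged at epoch {epoch}: "
                    f"loglik={ll.value:.4g}, "
                    f"prior={float(prior.value):.4g}")
            loss = obj * (-1.0)
            loss.backward()
            self.opt.step()
            self.rows.append({"epoch": epoch,
                              "log_likelihood": float(ll.value),
                              "log_prior": float(prior.value),
                              "objective": float(obj.value)})

    def recent_objective(self, window: int = 10) -> float:
        vals = [r["objective"] for r in self.rows[-window:]]
        return float(np.mean(vals))

    def finalize(self) -> TrainedModel:
        cfg = self.config
        h_d, h_s, B = encode_graph(self.params, self.arrays, self.F_d,
                                   self.enc_cfg)
        hs_state = None
        if cfg.prior_kind == "horseshoe":
            hs_state = HorseshoeState(np.exp(self.params["lam_raw"].value),
                                      cfg.tau)
        return TrainedModel(cfg, list(self.G.drug_ids),
                            list(self.G.side_effect_ids),
                            {k: v.value.copy()
                             for k, v in self.params.items()},
                            LatentState(h_d.value, h_s.value),
                            InteractionTensor(B.value), hs_state,
                            pd.DataFrame(self.rows))


def fit(G: DDIHypergraph, F_d: DrugFeatureMatrix, config: TrainConfig,
        warm_start: TrainedModel | None = None,
        train_only: tuple[str, ...] | None = None) -> TrainedModel:
    """Maximize the MAP objective by Adam for ``config.epochs`` epochs.

    Negatives are redrawn each epoch at ``neg_ratio`` per positive.  With
    ``n_restarts > 1``, that many independently initialized runs are
    raced for ``restart_epochs`` epochs and the one with the best recent
    training objective continues — a guard against occasional poor
    optimization basins; no held-out data is involved in the selection.

    ``warm_start`` continues optimization from a previously fitted
    model's parameters (fresh optimizer state); this is how a penalized
    fit is anchored to the unpenalized optimum when measuring shrinkage.
    The returned model holds the final-epoch parameters, the encoded
    latent state, the interaction tensor and the objective trace.
    """
    if G.n_edges == 0:
        raise ValueError("cannot fit on a hypergraph without hyperedges")
    arrays = GraphArrays.build(G)
    if warm_start is not None:
        st = _TrainState(G, F_d, config, arrays, 0,
                         initial_params=warm_start.params,
                         train_only=train_only)
        st.run_epochs(config.epochs)
        return st.finalize()
    stage1 = config.restart_epochs or max(1, config.epochs // 2)
    stage1 = min(stage1, config.epochs)
    states = [_TrainState(G, F_d, config, arrays, r)
              for r in range(max(1, config.n_restarts))]
    for st in states:
        st.run_epochs(stage1)
    best = max(states, key=lambda st: st.recent_objective())
    best.run_epochs(config.epochs - stage1)
    return best.finalize()


def _symmetric_scores(B: Tensor, h_d: Tensor, h_s: Tensor,
                      triples: np.ndarray) -> Tensor:
    # averaging the two drug orientations equals contracting with the
    # drug-mode-symmetrized tensor, which needs only one trilinear pass
    hu = ad.gather_rows(h_d, triples[:, 0])
    hv = ad.gather_rows(h_d, triples[:, 1])
    ht = ad.gather_rows(h_s, triples[:, 2])
    B_sym = (B + ad.transpose(B, (1, 0, 2))) * 0.5
    return ad.trilinear_scores(B_sym, hu, hv, ht)


def predict_scores(model: TrainedModel, triples, symmetrize: bool = True,
                   ) -> np.ndarray:
    """Order-preserving scores for triples of known drug/side-effect ids."""
    idx = model.triple_indices(triples)
    nd, ns = len(model.drug_ids), len(model.side_effect_ids)
    if idx.size and (idx[:, :2].max() >= nd or idx[:, 2].max() >= ns
                     or idx.min() < 0):
        raise KeyError("triple index out of range for this model")
    return batch_scores(model.B, model.latent.H_d, model.latent.H_s, idx,
                        symmetrize=symmetrize)


def rank_unknown_triples(model: TrainedModel, G: DDIHypergraph, top_n: int,
                         size_guard: int = 5_000_000,
                         seed: int = 0) -> list[tuple[tuple[str, str, str], float]]:
    """Top ``top_n`` canonical non-edges by descending score.

    Ties are broken by lexicographic triple order.  Above the size guard
    the candidate non-edges are uniformly sampled instead of enumerated.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    nd, ns = G.n_drugs, G.n_side_effects
    universe = nd * (nd - 1) // 2 * ns
    n_unknown = universe - G.n_edges
    if universe <= size_guard:
        cand = all_canonical_triples(nd, ns)
        mask = np.array([(u, v, t) not in G._edge_set
                         for (u, v, t) in map(tuple, cand.tolist())])
        cand = cand[mask]
    else:
        rng = np.random.default_rng(seed)
        cand = sample_negative_triples(
            nd, ns, min(size_guard, n_unknown), rng, G._edge_set)
    scores = batch_scores(model.B, model.latent.H_d, model.latent.H_s, cand)
    order = np.lexsort((cand[:, 2], cand[:, 1], cand[:, 0], -scores))
    top = order[:top_n]
    return [((G.drug_ids[u], G.drug_ids[v], G.side_effect_ids[t]), float(s))
            for (u, v, t), s in zip(cand[top], scores[top])]


def shrinkage_experiment(G: DDIHypergraph, F_d: DrugFeatureMatrix,
                         base_config: TrainConfig, prior_epochs: int = 300,
                         denom_floor: float = 1e-3) -> dict:
    """Fit the unpenalized model, then shrink it under each prior.

    The shrinkage factor κ = 1 − B_map/B_ml compares a penalized estimate
    of a coefficient with the *same* unpenalized one, so the penalized
    fits are continuations of the no-prior fit with the encoder frozen
    (the latent states act as a fixed design; only the tensor and the
    local scales adapt).  Entries whose unpenalized value sits at the
    numerical floor carry no shrinkage information and are excluded.

    Returns the three fitted models and, per prior, the κ values and the
    fractions of mass in [0, 0.1], (0.1, 0.9) and [0.9, 1].
    """
    from .objective import shrinkage_profile

    ml_cfg = TrainConfig(**{**base_config.__dict__, "variant": "SPARSEO"})
    ml = fit(G, F_d, ml_cfg)
    mask = ml.B.values > denom_floor
    out = {"SPARSEO": ml, "kappa": {}, "mass": {}}
    for variant in ("SPARSE", "SPARSEL"):
        cfg = TrainConfig(**{**base_config.__dict__, "variant": variant,
                             "epochs": prior_epochs, "n_restarts": 1})
        m = fit(G, F_d, cfg, warm_start=ml, train_only=("B_raw", "lam_raw"))
        kappa, _ = shrinkage_profile(m.B.values[mask], ml.B.values[mask])
        out[variant] = m
        out["kappa"][variant] = kappa
        out["mass"][variant] = {
            "low": float((kappa <= 0.1).mean()),
            "mid": float(((kappa > 0.1) & (kappa < 0.9)).mean()),
            "high": float((kappa >= 0.9).mean()),
        }
    return out


def grid_search(G: DDIHypergraph, F_d: DrugFeatureMatrix,
                base_config: TrainConfig, k: int = 20,
                latent_dims=LATENT_DIM_GRID, taus=TAU_GRID,
                layer_counts=N_LAYERS_GRID, metric: str = "auc",
                eval_neg_ratio: int = 1, seed: int = 0) -> pd.DataFrame:
    """Rerun cross-validation across the hyperparameter grids and report
    the mean metric per configuration (best first)."""
    from .evaluation import cross_validate

    rows = []
    for d in latent_dims:
        for tau in taus:
            for n_layers in layer_counts:
                cfg = TrainConfig(**{**asdict(base_config),
                                     "latent_dim": d, "tau": tau,
                                     "n_layers": n_layers})
                res = cross_validate(G, F_d, cfg, k=k,
                                     eval_neg_ratio=eval_neg_ratio, seed=seed)
                rows.append({"latent_dim": d, "tau": tau,
                             "n_layers": n_layers,
                             "auc_mean": res.auc_mean, "auc_std": res.auc_std,
                             "aupr_mean": res.aupr_mean,
                             "aupr_std": res.aupr_std})
    df = pd.DataFrame(rows)
    return df.sort_values(f"{metric}_mean", ascending=False,
                          ignore_index=True)
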