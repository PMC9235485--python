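"""Hypergraph message-passing encoder.

The encoder maps the DDI hypergraph plus drug features to nonnegative
latent matrices ``H_d`` (drugs) and ``H_s`` (side effects) and to the
latent interaction tensor ``B``.

Each node ``a`` starts from a learned linear lift of its observable
features (drug rows of ``F_D``; side effects get a learned embedding row,
equivalent to lifting their one-hot features).  A message-passing layer
collects, for every hyperedge ``e`` incident to ``a``, the sum over
co-members ``b ∈ e`` of a two-layer feedforward map applied to
``(c(a), c(b), h(a), h(b))`` — where ``c`` is +1 for drugs and −1 for
side effects — then aggregates the per-edge messages with a mean and
applies an activation.  Nodes in no hyperedge keep their current state.

Nonnegativity is enforced by construction: the initial lift and the final
emission pass through softplus, hidden layers through a rectifier, and
``B`` is a free parameter emitted through softplus (a network
parameterization pooling the final node states is available as an
alternative).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from . import autodiff as ad
from .autodiff import Tensor
from .hypergraph import DDIHypergraph, DrugFeatureMatrix
from .tensor_ops import InteractionTensor

__all__ = [
    "EncoderConfig",
    "LatentState",
    "GraphArrays",
    "init_parameters",
    "init_node_states",
    "message_passing_layer",
    "encode",
    "encode_graph",
]

_ACTIVATIONS = {"relu": ad.relu, "softplus": ad.softplus}


@dataclass
class EncoderConfig:
    n_layers: int = 2
    latent_dim: int = 50
    aggregation: str = "mean"
    hidden_activation: str = "relu"
    output_activation: str = "softplus"
    b_parameterization: str = "free_parameter"  # or "network"
    hidden_width: int | None = None  # message-MLP width; default latent_dim
    normalize_latents: bool = True   # pin latent column scale (RMS = 1)

    def __post_init__(self):
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if self.aggregation != "mean":
            raise ValueError("only mean aggregation is supported")
        for name in (self.hidden_activation, self.output_activation):
            if name not in _ACTIVATIONS:
                raise ValueError(f"unknown activation {name!r}")
        if self.b_parameterization not in ("free_parameter", "network"):
            raise ValueError(
                f"unknown b_parameterization {self.b_parameterization!r}")

    @property
    def mlp_width(self) -> int:
        return self.hidden_width or self.latent_dim


@dataclass(eq=False)
class LatentState:
    """Nonnegative latent representations of drug and side-effect nodes."""

    H_d: np.ndarray  # (|V_D|, K_D)
    H_s: np.ndarray  # (|V_S|, K_S)

    def __post_init__(self):
        self.H_d = np.asarray(self.H_d, dtype=np.float64)
        self.H_s = np.asarray(self.H_s, dtype=np.float64)
        for m in (self.H_d, self.H_s):
            if m.size and m.min() < 0:
                raise ValueError("latent states must be nonnegative")

    def latent_support(self, threshold: float = 0.0):
        """Per-node sets of active latent features (g_u / g_t)."""
        gd = [set(np.nonzero(r > threshold)[0].tolist()) for r in self.H_d]
        gs = [set(np.nonzero(r > threshold)[0].tolist()) for r in self.H_s]
        return gd, gs


@dataclass(eq=False)
class GraphArrays:
    """Precomputed incidence structure for vectorized message passing."""

    n_drugs: int
    n_side_effects: int
    a_idx: np.ndarray       # (9|E|,) receiving-node id per message term
    b_idx: np.ndarray       # (9|E|,) sending-node id per message term
    c_cols: np.ndarray      # (9|E|, 2) node-type codes (c(a), c(b))
    s_msg: sp.csr_matrix    # (3|E|, 9|E|) sums the 3 b-terms per incidence
    s_node: sp.csr_matrix   # (N, 3|E|) mean over incident hyperedges
    iso: np.ndarray         # (N, 1) 1.0 where the node has no hyperedge
    _c_tensor: Tensor = field(init=False, repr=False)

    def __post_init__(self):
        self._c_tensor = Tensor(self.c_cols)

    @classmethod
    def build(cls, G: DDIHypergraph) -> "GraphArrays":
        nd, ns = G.n_drugs, G.n_side_effects
        n_nodes = nd + ns
        E = G.hyperedges
        if len(E) == 0:
            raise ValueError("cannot build message passing on an empty graph")
        nodes = np.column_stack([E[:, 0], E[:, 1], nd + E[:, 2]])  # (|E|, 3)
        inc_nodes = nodes.ravel()                          # (3|E|,)
        a_idx = np.repeat(inc_nodes, 3)                    # (9|E|,)
        b_idx = np.tile(nodes, (1, 3)).ravel()             # (9|E|,)
        c = lambda ids: np.where(ids < nd, 1.0, -1.0)
        c_cols = np.column_stack([c(a_idx), c(b_idx)])
        m = len(E)
        s_msg = sp.csr_matrix(
            (np.ones(9 * m), (np.repeat(np.arange(3 * m), 3),
                              np.arange(9 * m))),
            shape=(3 * m, 9 * m))
        deg = np.bincount(inc_nodes, minlength=n_nodes).astype(float)
        inv = np.divide(1.0, deg, out=np.zeros_like(deg), where=deg > 0)
        s_node = sp.csr_matrix(
            (inv[inc_nodes], (inc_nodes, np.arange(3 * m))),
            shape=(n_nodes, 3 * m))
        iso = (deg == 0).astype(float)[:, None]
        return cls(nd, ns, a_idx, b_idx, c_cols, s_msg, s_node, iso)


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

def init_parameters(config: EncoderConfig, n_drugs: int, n_side_effects: int,
                    n_features: int, rng: np.random.Generator,
                    ) -> dict[str, Tensor]:
    """Fan-in-scaled random initialization of all learnable weights."""
    d, h = config.latent_dim, config.mlp_width

    def w(shape, fan_in, loc=0.0):
        return Tensor(loc + rng.normal(0.0, 1.0 / np.sqrt(fan_in), shape),
                      requires_grad=True)

    params = {
        "lift_W": w((n_features, d), n_features),
        "lift_b": w((d,), 1),
        "se_emb": w((n_side_effects, d), 1),
    }
    for layer in range(config.n_layers):
        params[f"mlp{layer}_W1"] = w((2 * d + 2, h), 2 * d + 2)
        params[f"mlp{layer}_b1"] = Tensor(np.zeros(h), requires_grad=True)
        params[f"mlp{layer}_W2"] = w((h, d), h)
        params[f"mlp{layer}_b2"] = Tensor(np.zeros(d), requires_grad=True)
    # start B near zero so initial scores are O(1) regardless of latent_dim
    b_loc = -(3.0 * np.log(d) + 0.5)
    if config.b_parameterization == "free_parameter":
        params["B_raw"] = w((d, d, d), 1.0, loc=b_loc)
    else:
        params["bnet_W"] = w((d, d * d * d), d)
        params["bnet_b"] = w((d * d * d,), 1, loc=b_loc)
    return params


def parameter_list(params: dict[str, Tensor]) -> list[Tensor]:
    return [params[k] for k in sorted(params)]


# ---------------------------------------------------------------------------
# Forward passes
# ---------------------------------------------------------------------------

def init_node_states(params: dict[str, Tensor], F_d: DrugFeatureMatrix | np.ndarray,
                     config: EncoderConfig) -> Tensor:
    """Initial states h^(0): lifted drug features stacked over side-effect
    embeddings, emitted through the nonnegativity map."""
    values = F_d.values if isinstance(F_d, DrugFeatureMatrix) else np.asarray(F_d)
    if values.shape[1] != params["lift_W"].shape[0]:
        raise ValueError(
            f"feature matrix has {values.shape[1]} columns, lift expects "
            f"{params['lift_W'].shape[0]}")
    act = _ACTIVATIONS[config.output_activation]
    h_drugs = ad.matmul(Tensor(values), params["lift_W"]) + params["lift_b"]
    return act(ad.vconcat([h_drugs, params["se_emb"]]))


def message_passing_layer(arrays: GraphArrays, h: Tensor,
                          params: dict[str, Tensor], layer: int,
                          config: EncoderConfig, *, final: bool) -> Tensor:
    """One layer: per-edge summed two-layer-MLP messages, mean-aggregated
    per node, then the layer activation; isolated nodes pass through."""
    ha = ad.gather_rows(h, arrays.a_idx)
    hb = ad.gather_rows(h, arrays.b_idx)
    x = ad.hconcat([arrays._c_tensor, ha, hb])
    hid = ad.relu(x @ params[f"mlp{layer}_W1"] + params[f"mlp{layer}_b1"])
    msg = hid @ params[f"mlp{layer}_W2"] + params[f"mlp{layer}_b2"]
    per_edge = ad.sparse_matmul(arrays.s_msg, msg)      # sum over b ∈ e
    agg = ad.sparse_matmul(arrays.s_node, per_edge)     # mean over e ∈ N_a
    act = _ACTIVATIONS[config.output_activation if final
                       else config.hidden_activation]
    keep = Tensor(arrays.iso)
    return act(agg) * Tensor(1.0 - arrays.iso) + h * keep


def interaction_tensor_forward(params: dict[str, Tensor],
                               config: EncoderConfig,
                               h_final: Tensor | None = None) -> Tensor:
    """B as softplus of a free parameter (default) or of a linear map of
    the mean-pooled final node representation."""
    d = config.latent_dim
    if config.b_parameterization == "free_parameter":
        return ad.softplus(params["B_raw"])
    if h_final is None:
        raise ValueError("network parameterization needs final node states")
    n = h_final.shape[0]
    pool = sp.csr_matrix(np.full((1, n), 1.0 / n))
    pooled = ad.sparse_matmul(pool, h_final)            # (1, d)
    flat = ad.matmul(pooled, params["bnet_W"]) + params["bnet_b"]
    return ad.softplus(ad.reshape(flat, (d, d, d)))


def encode_graph(params: dict[str, Tensor], arrays: GraphArrays,
                 F_d, config: EncoderConfig) -> tuple[Tensor, Tensor, Tensor]:
    """Differentiable forward pass: returns (H_d, H_s, B) as graph Tensors."""
    h = init_node_states(params, F_d, config)
    for layer in range(config.n_layers):
        h = message_passing_layer(arrays, h, params, layer, config,
                                  final=(layer == config.n_layers - 1))
    nd = arrays.n_drugs
    h_d = ad.gather_rows(h, np.arange(nd))
    h_s = ad.gather_rows(h, np.arange(nd, nd + arrays.n_side_effects))
    if config.normalize_latents:
        # fix the latent scale so magnitude lives in B (the score is
        # invariant under B -> cB, H -> c^(-1/3)H, which would otherwise
        # let the representations absorb any shrinkage applied to B)
        h_d = ad.rms_normalize_columns(h_d)
        h_s = ad.rms_normalize_columns(h_s)
    B = interaction_tensor_forward(params, config, h_final=h)
    return h_d, h_s, B


def encode(G: DDIHypergraph, F_d: DrugFeatureMatrix, config: EncoderConfig,
           params: dict[str, Tensor] | None = None, seed: int = 0,
           ) -> tuple[LatentState, InteractionTensor]:
    """Encode a hypergraph into latent states and the interaction tensor.

    With ``params=None`` freshly initialized (seeded) weights are used,
    which is deterministic for a fixed seed.
    """
    if params is None:
        rng = np.random.default_rng(seed)
        params = init_parameters(config, G.n_drugs, G.n_side_effects,
                                 F_d.n_features, rng)
    arrays = GraphArrays.build(G)
    h_d, h_s, B = encode_graph(params, arrays, F_d, config)
    return LatentState(h_d.value, h_s.value), InteractionTensor(B.value)
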