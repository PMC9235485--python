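"""n-mode tensor products and the latent interaction tensor.

The model scores a triple (u, v, t) by contracting a nonnegative 3-way
tensor ``B`` (shape K_D × K_D × K_S) with the latent vectors of the two
drugs and the side effect:

    score(u, v, t) = B ×₁ h_d(u) ×₂ h_d(v) ×₃ h_s(t)
                   = Σ_ijk B[i,j,k] · h_d(u)[i] · h_d(v)[j] · h_s(t)[k].

``B`` also carries the model's sparsity structure: its support ``A`` is
the set of interacting latent-feature triples, and the latent sparsity
``s_l`` measures how few of the possible latent triples interact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "InteractionTensor",
    "n_mode_product",
    "triple_score",
    "batch_scores",
    "support_set",
    "latent_sparsity",
    "save_tensor",
    "load_tensor",
]

#: default support threshold absorbing floating-point dust
SUPPORT_EPS = 1e-8


@dataclass(eq=False)
class InteractionTensor:
    """Nonnegative K_D × K_D × K_S tensor of latent-feature interactions."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("interaction tensor must be 3-way")
        if self.values.shape[0] != self.values.shape[1]:
            raise ValueError("modes 1 and 2 index drug latent features and "
                             "must have equal size")
        if self.values.size and self.values.min() < 0:
            raise ValueError("interaction tensor must be nonnegative")

    @property
    def k_drug(self) -> int:
        return self.values.shape[0]

    @property
    def k_side_effect(self) -> int:
        return self.values.shape[2]


def _as_array(B) -> np.ndarray:
    return B.values if isinstance(B, InteractionTensor) else np.asarray(B, float)


def n_mode_product(B, H: np.ndarray, n: int) -> np.ndarray:
    """Contract mode ``n`` (1, 2 or 3) of a 3-way tensor with matrix ``H``.

    ``H`` has shape (T, K_n); the result replaces the extent of mode ``n``
    by T, e.g. for n=1: ``(B ×₁ H)[t,j,k] = Σ_i B[i,j,k] H[t,i]``.
    """
    B = _as_array(B)
    H = np.asarray(H, dtype=np.float64)
    if H.ndim == 1:
        H = H[None, :]
    if n not in (1, 2, 3):
        raise ValueError("mode must be 1, 2 or 3")
    if H.shape[1] != B.shape[n - 1]:
        raise ValueError(
            f"mode-{n} mismatch: tensor extent {B.shape[n - 1]}, "
            f"matrix has {H.shape[1]} columns")
    subscripts = {1: "ijk,ti->tjk", 2: "ijk,tj->itk", 3: "ijk,tk->ijt"}[n]
    return np.einsum(subscripts, B, H)


def triple_score(B, hd_u, hd_v, hs_t, symmetrize: bool = True) -> float:
    """Score of one (drug, drug, side effect) triple.

    With ``symmetrize`` (default) the mean of the (u,v) and (v,u)
    orientations is returned, making the score invariant to drug order;
    the raw asymmetric contraction is available for debugging.
    """
    B = _as_array(B)
    hd_u = np.asarray(hd_u, float)
    hd_v = np.asarray(hd_v, float)
    hs_t = np.asarray(hs_t, float)
    for name, vec, mode in (("hd_u", hd_u, 0), ("hd_v", hd_v, 1),
                            ("hs_t", hs_t, 2)):
        if vec.shape != (B.shape[mode],):
            raise ValueError(f"{name} has shape {vec.shape}, expected "
                             f"({B.shape[mode]},)")
    s = float(np.einsum("ijk,i,j,k->", B, hd_u, hd_v, hs_t))
    if not symmetrize:
        return s
    s_rev = float(np.einsum("ijk,i,j,k->", B, hd_v, hd_u, hs_t))
    return 0.5 * (s + s_rev)


def batch_scores(B, H_d: np.ndarray, H_s: np.ndarray, triples: np.ndarray,
                 symmetrize: bool = True) -> np.ndarray:
    """Vectorized triple scores for an (n, 3) array of index triples."""
    B = _as_array(B)
    triples = np.asarray(triples, dtype=np.intp).reshape(-1, 3)
    hu = H_d[triples[:, 0]]
    hv = H_d[triples[:, 1]]
    ht = H_s[triples[:, 2]]
    Bt = np.einsum("ijk,bk->bij", B, ht)
    s = np.einsum("bij,bi,bj->b", Bt, hu, hv)
    if symmetrize:
        s = 0.5 * (s + np.einsum("bij,bi,bj->b", Bt, hv, hu))
    return s


def support_set(B, threshold: float = 0.0) -> set[tuple[int, int, int]]:
    """Support A = {(i,j,k) : B[i,j,k] > threshold} (0-based indices)."""
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    B = _as_array(B)
    return set(zip(*map(list, np.nonzero(B > threshold))))


def latent_sparsity(A, K_D: int, K_S: int) -> float:
    """Latent sparsity ``s_l = 1 - 2|A| / (K_D² K_S)``.

    ``A`` may contain ordered index triples; the count used is the number
    of distinct *unordered* drug-feature pairs (i, j) per side-effect
    feature k.  Off-diagonal pairs account for the factor 2; diagonal
    pairs (i == j) would make the formula exceed its nominal range, so the
    result is clamped to [0, 1].
    """
    pairs = set()
    for (i, j, k) in A:
        if not (0 <= i < K_D and 0 <= j < K_D and 0 <= k < K_S):
            raise ValueError(f"latent index {(i, j, k)} out of range")
        pairs.add((min(i, j), max(i, j), k))
    s = 1.0 - 2.0 * len(pairs) / (K_D * K_D * K_S)
    return float(min(1.0, max(0.0, s)))


def save_tensor(B, path) -> None:
    """Round-trip-exact serialization (npz container with shape metadata)."""
    np.savez_compressed(path, values=_as_array(B))


def load_tensor(path) -> InteractionTensor:
    with np.load(path) as f:
        return InteractionTensor(f["values"])
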