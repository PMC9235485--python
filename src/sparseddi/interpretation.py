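"""Mapping predicted triples back to observable drug features.

A fitted model explains a predicted triple (u, v, t) in two steps:

1. For every drug latent feature k, rank the observable feature columns
   by correlation (Pearson by default) with the latent column over drugs
   and keep the top T (``a_k``).
2. Entrywise-multiply B with the rank-1 outer product of the three latent
   vectors (``ss``); its positive entries ``tt`` are the latent
   interactions active for this triple — their sum is exactly the
   (unsymmetrized) triple score.  For each active (i, j, k), pair u's
   nonzero observable features within ``a_i`` with v's within ``a_j``.

The union of those pairs, with feature names attached, is the
explanation.  By default ``ss`` is symmetrized over the drug order so
that (u, v, t) and (v, u, t) explain identically; the literal asymmetric
form is available for debugging.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .hypergraph import DrugFeatureMatrix
from .tensor_ops import InteractionTensor

__all__ = [
    "ExplanationConfig",
    "Explanation",
    "top_correlated_features",
    "active_latent_interactions",
    "explain_triple",
]


@dataclass
class ExplanationConfig:
    top_T: int = 20
    correlation: str = "pearson"   # or "spearman"
    activity_threshold: float = 0.0
    symmetrize: bool = True
    feature_threshold: float = 0.0  # strict > 0 marks a feature as present
    # pair the second drug's features via the side-effect latent index k
    # instead of the second drug-latent index j (the literal pseudocode
    # reading, kept for debugging; requires K_S <= K_D)
    literal_side_effect_index: bool = False

    def __post_init__(self):
        if self.top_T < 1:
            raise ValueError("top_T must be >= 1")
        if self.correlation not in ("pearson", "spearman"):
            raise ValueError(f"unknown correlation {self.correlation!r}")
        if self.activity_threshold < 0:
            raise ValueError("activity_threshold must be >= 0")


def _column_correlations(H: np.ndarray, F: np.ndarray,
                         method: str) -> np.ndarray:
    """(K_D, K0) correlation matrix between latent and feature columns;
    zero-variance columns get correlation 0 and sink in the ranking."""
    if method == "spearman":
        H = stats.rankdata(H, axis=0)
        F = stats.rankdata(F, axis=0)
    Hc = H - H.mean(axis=0)
    Fc = F - F.mean(axis=0)
    hs = np.sqrt((Hc ** 2).sum(axis=0))
    fs = np.sqrt((Fc ** 2).sum(axis=0))
    num = Hc.T @ Fc
    denom = np.outer(hs, fs)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
    return corr


def top_correlated_features(H_d: np.ndarray, F_d, top_T: int = 20,
                            method: str = "pearson") -> list[np.ndarray]:
    """Per drug-latent feature k, indices of the top-T observable feature
    columns by correlation across drugs (ties by ascending feature index)."""
    F = F_d.values if isinstance(F_d, DrugFeatureMatrix) else np.asarray(F_d)
    H = np.asarray(H_d, dtype=float)
    if H.shape[0] < 3:
        raise ValueError("correlations need at least 3 drugs")
    if H.shape[0] != F.shape[0]:
        raise ValueError("latent and feature matrices disagree on drugs")
    corr = _column_correlations(H, F, method)
    K0 = F.shape[1]
    t = min(top_T, K0)
    out = []
    for k in range(corr.shape[0]):
        order = np.lexsort((np.arange(K0), -corr[k]))
        out.append(order[:t])
    return out


def active_latent_interactions(B, hd_u, hd_v, hs_t, threshold: float = 0.0,
                               ) -> tuple[np.ndarray, set]:
    """ss = B ⊙ (h_d(u) ⊗ h_d(v) ⊗ h_s(t)); tt = entries above threshold.

    Σ ss equals the unsymmetrized triple score exactly.
    """
    Bv = B.values if isinstance(B, InteractionTensor) else np.asarray(B)
    ss = Bv * np.einsum("i,j,k->ijk", np.asarray(hd_u, float),
                        np.asarray(hd_v, float), np.asarray(hs_t, float))
    tt = set(zip(*map(list, np.nonzero(ss > threshold))))
    return ss, tt


@dataclass
class Explanation:
    triple: tuple
    status: str                    # "ok" or "no active interaction"
    active: list                   # [((i, j, k), ss_value), ...]
    feature_pairs: set             # {(tuple of u-features, tuple of v-features)}
    per_drug: dict = field(default_factory=dict)  # drug id -> sorted features

    def to_json(self) -> str:
        return json.dumps({
            "triple": list(self.triple),
            "status": self.status,
            "active": [{"ijk": list(ijk), "ss": v} for ijk, v in self.active],
            "feature_pairs": [[list(a), list(b)]
                              for a, b in sorted(self.feature_pairs)],
            "per_drug": {k: sorted(v) for k, v in self.per_drug.items()},
        }, indent=2)

    def render(self) -> str:
        lines = [f"triple: {self.triple}", f"status: {self.status}"]
        for (ijk, v) in self.active:
            lines.append(f"  active latent interaction {ijk}: ss = {v:.4g}")
        for drug, feats in self.per_drug.items():
            lines.append(f"  {drug}: {', '.join(sorted(feats)) or '(none)'}")
        return "\n".join(lines)


def explain_triple(model, F_d: DrugFeatureMatrix, triple,
                   config: ExplanationConfig | None = None) -> Explanation:
    """Associated observable drug features for one predicted triple.

    ``model`` is a TrainedModel (or any object with ``latent``, ``B`` and
    ``triple_indices``).  For each active latent interaction (i, j, k) the
    first drug's present features within a_i are paired with the second
    drug's within a_j.
    """
    config = config or ExplanationConfig()
    (u, v, t), = model.triple_indices([triple]).tolist()
    H_d, H_s = model.latent.H_d, model.latent.H_s
    a_sets = top_correlated_features(H_d, F_d, config.top_T,
                                     config.correlation)
    ss, _ = active_latent_interactions(model.B, H_d[u], H_d[v], H_s[t])
    if config.symmetrize:
        ss = 0.5 * (ss + ss.transpose(1, 0, 2))
    tt = set(zip(*map(list, np.nonzero(ss > config.activity_threshold))))
    names = np.asarray(F_d.feature_names, dtype=object)
    fu = F_d.values[u] > config.feature_threshold
    fv = F_d.values[v] > config.feature_threshold
    pairs = set()
    active = sorted(((int(i), int(j), int(k)), float(ss[i, j, k]))
                    for (i, j, k) in tt)
    for (i, j, k), _val in active:
        second = k if config.literal_side_effect_index else j
        if second >= len(a_sets):
            raise ValueError("literal side-effect indexing needs "
                             "K_S <= K_D")
        feats_u = tuple(sorted(names[a_sets[i][fu[a_sets[i]]]]))
        feats_v = tuple(sorted(names[a_sets[second][fv[a_sets[second]]]]))
        pairs.add((feats_u, feats_v))
    per_drug = {}
    du, dv = model.drug_ids[u], model.drug_ids[v]
    for (feats_u, feats_v) in pairs:
        per_drug.setdefault(du, set()).update(feats_u)
        per_drug.setdefault(dv, set()).update(feats_v)
    status = "ok" if tt else "no active interaction"
    return Explanation((model.drug_ids[u], model.drug_ids[v],
                        model.side_effect_ids[t]), status, active, pairs,
                       {k: sorted(vset) for k, vset in per_drug.items()})
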