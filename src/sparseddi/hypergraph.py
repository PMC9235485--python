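"""Drug–drug interaction (DDI) hypergraphs and drug feature matrices.

A DDI dataset is a hypergraph whose nodes are drugs and side effects and
whose hyperedges are triples ``(u, v, t)``: drugs ``u`` and ``v`` taken
together cause side effect ``t``.  The pair of drugs is unordered, so each
edge is stored once in canonical orientation ``u <= v`` (by internal
0-based index); self-pairs ``(u, u, t)`` are invalid.

Drug nodes carry a nonnegative observable feature matrix ``F_D``
(rows follow ``drug_ids``); side-effect node features are implicit
one-hot vectors and are never materialized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DDIHypergraph",
    "DrugFeatureMatrix",
    "canonical_triple",
    "load_hypergraph",
    "load_triples",
    "load_features",
    "save_triples",
    "save_features",
    "data_sparsity",
    "data_sparsity_from_counts",
    "stratified_kfold",
]


def canonical_triple(u: int, v: int, t: int) -> tuple[int, int, int]:
    """Canonical orientation of a hyperedge: drug indices sorted ascending."""
    if u == v:
        raise ValueError(f"self-pair ({u}, {u}, {t}) is not a valid hyperedge")
    return (u, v, t) if u < v else (v, u, t)


@dataclass(eq=False)
class DDIHypergraph:
    """A DDI hypergraph G = (V_D ∪ V_S, E) with canonical triple edges."""

    drug_ids: list[str]
    side_effect_ids: list[str]
    hyperedges: np.ndarray  # (|E|, 3) int array, rows canonical & unique

    _edge_set: frozenset = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        edges = np.asarray(self.hyperedges, dtype=np.int64).reshape(-1, 3)
        if edges.size:
            u, v, t = edges[:, 0], edges[:, 1], edges[:, 2]
            if np.any(u == v):
                bad = edges[u == v][0]
                raise ValueError(f"self-pair hyperedge {tuple(bad)} is invalid")
            if np.any(u > v):
                raise ValueError("hyperedges must be canonical (u <= v)")
            if (u.min() < 0 or v.max() >= len(self.drug_ids)
                    or t.min() < 0 or t.max() >= len(self.side_effect_ids)):
                raise ValueError("hyperedge index out of range")
            edges = np.unique(edges, axis=0)
        self.hyperedges = edges
        self._edge_set = frozenset(map(tuple, edges.tolist()))

    # -- basic accessors ------------------------------------------------
    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def n_side_effects(self) -> int:
        return len(self.side_effect_ids)

    @property
    def n_edges(self) -> int:
        return len(self.hyperedges)

    def indicator(self, u: int, v: int, t: int) -> int:
        """Membership indicator i(e): 1 if the triple is an observed DDI."""
        return int(canonical_triple(u, v, t) in self._edge_set)

    def __contains__(self, triple) -> bool:
        return canonical_triple(*triple) in self._edge_set

    @classmethod
    def from_triples(cls, drug_ids, side_effect_ids, triples) -> "DDIHypergraph":
        """Build from an iterable of (possibly unordered, duplicated) triples."""
        canon = sorted({canonical_triple(u, v, t) for (u, v, t) in triples})
        edges = (np.asarray(canon, dtype=np.int64).reshape(-1, 3)
                 if canon else np.empty((0, 3), dtype=np.int64))
        return cls(list(drug_ids), list(side_effect_ids), edges)

    def restrict_edges(self, keep: np.ndarray) -> "DDIHypergraph":
        """Same node sets, hyperedges restricted to the given row indices."""
        return DDIHypergraph(self.drug_ids, self.side_effect_ids,
                             self.hyperedges[np.asarray(keep)])


@dataclass(eq=False)
class DrugFeatureMatrix:
    """Nonnegative observable drug features F_D, rows aligned to drug_ids."""

    values: np.ndarray  # (|V_D|, K0), entrywise >= 0
    feature_names: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length does not match columns")
        if self.values.size and self.values.min() < 0:
            raise ValueError("drug features must be nonnegative")

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


# ---------------------------------------------------------------------------
# I/O: tab-separated triples and feature tables
# ---------------------------------------------------------------------------

def load_triples(path, header: bool = False, sep: str = "\t"):
    """Read a 3-column (drug_A, drug_B, side_effect) table.

    Returns ``(drug_ids, side_effect_ids, triples)`` with identifiers in
    order of first appearance and triples canonicalized/deduplicated.
    Rows with a missing column raise with the offending line number.
    """
    df = pd.read_csv(path, sep=sep, header=0 if header else None,
                     dtype=str, skip_blank_lines=False)
    if df.shape[1] != 3:
        raise ValueError(
            f"{path}: expected 3 columns, found {df.shape[1]}")
    offset = 2 if header else 1
    bad = np.where(df.isna().any(axis=1))[0]
    if bad.size:
        raise ValueError(f"{path}: malformed row at line {bad[0] + offset}")
    drug_index: dict[str, int] = {}
    se_index: dict[str, int] = {}
    triples = []
    for row in df.itertuples(index=False):
        a, b, s = str(row[0]), str(row[1]), str(row[2])
        u = drug_index.setdefault(a, len(drug_index))
        v = drug_index.setdefault(b, len(drug_index))
        t = se_index.setdefault(s, len(se_index))
        triples.append(canonical_triple(u, v, t))
    return list(drug_index), list(se_index), triples


def load_features(path, header: bool = True, sep: str = "\t"):
    """Read a feature table: first column drug id, then K0 numeric columns."""
    df = pd.read_csv(path, sep=sep, header=0 if header else None, index_col=0)
    values = df.to_numpy(dtype=np.float64)
    if np.isnan(values).any():
        r = int(np.where(np.isnan(values).any(axis=1))[0][0])
        raise ValueError(f"{path}: non-numeric or missing feature value in "
                         f"row for drug {df.index[r]!r}")
    if values.size and values.min() < 0:
        raise ValueError(f"{path}: negative feature value")
    names = [str(c) for c in df.columns]
    return [str(i) for i in df.index], names, values


def load_hypergraph(triples_path, features_path, *, header_triples=False,
                    header_features=True, min_interactions: int = 0):
    """Load a DDI hypergraph together with its aligned drug feature matrix.

    Drugs present in the triples but missing from the feature table raise;
    drugs with features but no interactions are retained (appended after
    the triple-ordered drugs).  ``min_interactions`` optionally drops drugs
    appearing in that many hyperedges or fewer before anything else, the
    way dense benchmark datasets are pre-filtered.
    """
    drug_ids, se_ids, triples = load_triples(triples_path,
                                             header=header_triples)
    if min_interactions > 0:
        drug_ids, se_ids, triples = _filter_rare_drugs(
            drug_ids, se_ids, triples, min_interactions)
    feat_ids, feat_names, feat_values = load_features(
        features_path, header=header_features)
    feat_row = {d: i for i, d in enumerate(feat_ids)}
    missing = [d for d in drug_ids if d not in feat_row]
    if missing:
        raise ValueError(f"drugs missing from feature table: {missing[:5]}"
                         + ("..." if len(missing) > 5 else ""))
    all_drugs = drug_ids + [d for d in feat_ids if d not in set(drug_ids)]
    rows = np.array([feat_row[d] for d in all_drugs], dtype=np.intp)
    G = DDIHypergraph.from_triples(all_drugs, se_ids, triples)
    F = DrugFeatureMatrix(feat_values[rows], feat_names)
    return G, F


def _filter_rare_drugs(drug_ids, se_ids, triples, min_interactions):
    counts = np.zeros(len(drug_ids), dtype=int)
    for (u, v, _t) in triples:
        counts[u] += 1
        counts[v] += 1
    keep = {i for i in range(len(drug_ids)) if counts[i] > min_interactions}
    kept_triples = [(u, v, t) for (u, v, t) in triples
                    if u in keep and v in keep]
    new_drug, new_se = {}, {}
    remapped = []
    for (u, v, t) in kept_triples:
        a = new_drug.setdefault(drug_ids[u], len(new_drug))
        b = new_drug.setdefault(drug_ids[v], len(new_drug))
        s = new_se.setdefault(se_ids[t], len(new_se))
        remapped.append(canonical_triple(a, b, s))
    return list(new_drug), list(new_se), remapped


def save_triples(G: DDIHypergraph, path, sep: str = "\t") -> None:
    rows = [(G.drug_ids[u], G.drug_ids[v], G.side_effect_ids[t])
            for (u, v, t) in G.hyperedges]
    pd.DataFrame(rows).to_csv(path, sep=sep, header=False, index=False)


def save_features(G: DDIHypergraph, F: DrugFeatureMatrix, path,
                  sep: str = "\t") -> None:
    df = pd.DataFrame(F.values, index=G.drug_ids, columns=F.feature_names)
    df.index.name = "drug_id"
    df.to_csv(path, sep=sep)


# ---------------------------------------------------------------------------
# Sparsity and cross-validation folds
# ---------------------------------------------------------------------------

def data_sparsity_from_counts(n_drugs: int, n_side_effects: int,
                              n_edges: int) -> float:
    """``s_d = 1 - 2|E| / (|V_D| (|V_D|-1) |V_S|)`` from summary counts."""
    if n_drugs < 2 or n_side_effects < 1:
        raise ValueError("data sparsity needs >= 2 drugs and >= 1 side effect")
    return 1.0 - 2.0 * n_edges / (n_drugs * (n_drugs - 1) * n_side_effects)


def data_sparsity(G: DDIHypergraph) -> float:
    """Fraction of possible (drug, drug, side effect) triples that are not
    observed DDIs."""
    return data_sparsity_from_counts(G.n_drugs, G.n_side_effects, G.n_edges)


def stratified_kfold(G: DDIHypergraph, k: int, seed: int) -> list[np.ndarray]:
    """Split hyperedges into ``k`` folds balanced per side effect.

    Each side effect's hyperedges are shuffled (seeded) and dealt
    round-robin starting from a rotating offset, so per-fold counts of any
    side effect differ by at most one and fold sizes stay balanced.
    Returns a list of ``k`` disjoint arrays of hyperedge row indices whose
    union is all of ``E``.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > G.n_edges:
        raise ValueError(f"k={k} exceeds number of hyperedges {G.n_edges}")
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    t_col = G.hyperedges[:, 2]
    offset = 0
    for t in range(G.n_side_effects):
        idx = np.where(t_col == t)[0]
        if idx.size == 0:
            continue
        rng.shuffle(idx)
        for j, e in enumerate(idx):
            folds[(offset + j) % k].append(int(e))
        offset = (offset + idx.size) % k
    return [np.array(sorted(f), dtype=np.intp) for f in folds]
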