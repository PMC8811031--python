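"""Semantic similarity of diagnosis codes, code sets, and patients.

Code-level similarity is a Wu–Palmer-style ratio on the level-depth
information content of the reconstructed ICD-9 ontology:

    s(a, b) = 2·IC(LCA(a, b)) / (IC(a) + IC(b))

Set-level similarity averages, over both directions, each code's best match
in the other patient's deduplicated code set:

    S(Di, Dj) = 1 − [ Σ_{g∈Di} min_{h∈Dj} (1 − s(g,h))
                    + Σ_{h∈Dj} min_{g∈Di} (1 − s(h,g)) ] / (|Di| + |Dj|)

Diagnosis order is deliberately ignored at this stage (it re-enters during
pattern extraction). Four classical exact-match set measures (Dice, Jaccard,
cosine, overlap) are provided as baselines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

from .ontology import (
    ICD9Code,
    OntologyTree,
    ROOT_CANONICAL,
    build_ontology,
    canonicalize,
)

CodeLike = Union[str, ICD9Code]

BASELINE_METHODS = ("dice", "jaccard", "cosine", "cosine_printed", "overlap")


@dataclass
class PatientDiagnosis:
    """One admission's ordered diagnosis codes.

    ``entries`` is a list of (canonical code, order) pairs with unique orders;
    ``codes`` is the deduplicated code set used by the set similarity measure.
    """

    patient_id: str
    entries: list[tuple[str, int]]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError(f"patient {self.patient_id!r} has no diagnosis codes")
        orders = [o for _, o in self.entries]
        if any(o < 1 for o in orders):
            raise ValueError(f"patient {self.patient_id!r}: orders must be >= 1")
        if len(set(orders)) != len(orders):
            raise ValueError(f"patient {self.patient_id!r}: duplicate diagnosis orders")
        codes = [c for c, _ in self.entries]
        if len(set(codes)) != len(codes):
            raise ValueError(f"patient {self.patient_id!r}: duplicate codes in entries")
        self.entries = sorted(self.entries, key=lambda e: e[1])

    @classmethod
    def from_raw(
        cls, patient_id: str, raw_entries: Iterable[tuple[CodeLike, int]]
    ) -> "PatientDiagnosis":
        """Canonicalize codes, collapsing duplicates onto the smallest order."""
        best: dict[str, int] = {}
        for raw, order in raw_entries:
            canonical = canonicalize(raw).canonical
            if canonical not in best or order < best[canonical]:
                best[canonical] = int(order)
        return cls(patient_id=str(patient_id), entries=list(best.items()))

    @property
    def codes(self) -> frozenset[str]:
        return frozenset(c for c, _ in self.entries)

    def order_of(self, code: CodeLike) -> int:
        canonical = canonicalize(code).canonical
        for c, o in self.entries:
            if c == canonical:
                return o
        raise KeyError(f"patient {self.patient_id!r} lacks code {canonical!r}")


def code_similarity(a: CodeLike, b: CodeLike, tree: OntologyTree) -> float:
    """LCA-based semantic similarity of two diagnosis codes, in [0, 1]."""
    ca, cb = tree.resolve(a), tree.resolve(b)
    if ROOT_CANONICAL in (ca, cb):
        raise ValueError("code similarity is undefined for the root node")
    ic_lca = tree.level(tree.lca(ca, cb))
    return 2.0 * ic_lca / (tree.level(ca) + tree.level(cb))


def _as_code_list(codes: Iterable[CodeLike], tree: OntologyTree) -> list[str]:
    out = [tree.resolve(c) for c in codes]
    if not out:
        raise ValueError("set similarity is undefined for an empty code set")
    return sorted(set(out))


def set_similarity(
    Di: Iterable[CodeLike], Dj: Iterable[CodeLike], tree: OntologyTree
) -> float:
    """Best-match average similarity of two deduplicated code sets."""
    gi = _as_code_list(Di, tree)
    gj = _as_code_list(Dj, tree)
    M = np.empty((len(gi), len(gj)))
    for u, g in enumerate(gi):
        for v, h in enumerate(gj):
            M[u, v] = code_similarity(g, h, tree)
    # 1 - [Σ min(1-s) + Σ min(1-s)]/(n+m)  ==  [Σ max s + Σ max s]/(n+m)
    return float((M.max(axis=1).sum() + M.max(axis=0).sum()) / (len(gi) + len(gj)))


def baseline_set_similarity(
    Di: Iterable[CodeLike], Dj: Iterable[CodeLike], method: str
) -> float:
    """Exact-match set similarity (no ontology): dice, jaccard, cosine, overlap.

    ``cosine`` uses the standard |A∩B|/√(|A|·|B|); ``cosine_printed`` is the
    unnormalised |A∩B|/(|A|·|B|) variant kept for comparability audits.
    """
    if method not in BASELINE_METHODS:
        raise ValueError(f"unknown baseline method {method!r}; use {BASELINE_METHODS}")
    A = {canonicalize(c).canonical for c in Di}
    B = {canonicalize(c).canonical for c in Dj}
    if not A or not B:
        raise ValueError("baseline set similarity is undefined for empty sets")
    inter = len(A & B)
    if method == "dice":
        return 2.0 * inter / (len(A) + len(B))
    if method == "jaccard":
        return inter / len(A | B)
    if method == "overlap":
        return inter / min(len(A), len(B))
    if method == "cosine":
        return inter / float(np.sqrt(len(A) * len(B)))
    return inter / float(len(A) * len(B))  # cosine_printed


@dataclass
class SimilarityMatrix:
    """Symmetric patient-by-patient similarity with unit diagonal."""

    ids: list[str]
    values: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("similarity matrix shape does not match id list")
        if not np.isfinite(self.values).all():
            raise ValueError("similarity matrix contains non-finite entries")
        self._index = {pid: i for i, pid in enumerate(self.ids)}
        if len(self._index) != n:
            raise ValueError("duplicate patient ids in similarity matrix")

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, patient_id: str) -> int:
        return self._index[patient_id]

    def sim(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, float_format="%.17g")

    @classmethod
    def from_csv(cls, path) -> "SimilarityMatrix":
        frame = pd.read_csv(path, index_col=0)
        frame.index = frame.index.astype(str)
        frame.columns = frame.columns.astype(str)
        return cls(ids=list(frame.index), values=frame.to_numpy(dtype=float))


def similarity_matrix(
    patients: Sequence[PatientDiagnosis],
    tree: OntologyTree | None = None,
    method: str = "ontology",
) -> SimilarityMatrix:
    """Pairwise patient similarity over deduplicated code sets.

    ``method`` selects the ontology-embedded measure (default) or one of the
    exact-match baselines. Each unordered pair is computed once; the result is
    symmetric with a unit diagonal regardless of evaluation order.
    """
    if len(patients) < 2:
        raise ValueError("need at least two patients for a similarity matrix")
    ids = [p.patient_id for p in patients]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate patient ids")
    if method != "ontology" and method not in BASELINE_METHODS:
        raise ValueError(f"unknown similarity method {method!r}")

    n = len(patients)
    values = np.eye(n)
    if method == "ontology":
        if tree is None:
            tree = build_ontology(c for p in patients for c in p.codes)
        universe = sorted({c for p in patients for c in p.codes})
        uidx = {c: i for i, c in enumerate(universe)}
        U = len(universe)
        cs = np.eye(U)
        for u in range(U):
            for v in range(u + 1, U):
                cs[u, v] = cs[v, u] = code_similarity(universe[u], universe[v], tree)
        members = [np.array([uidx[c] for c in sorted(p.codes)]) for p in patients]
        for i in range(n):
            for j in range(i + 1, n):
                M = cs[np.ix_(members[i], members[j])]
                sij = (M.max(axis=1).sum() + M.max(axis=0).sum()) / (
                    len(members[i]) + len(members[j])
                )
                values[i, j] = values[j, i] = sij
    else:
        sets = [p.codes for p in patients]
        for i in range(n):
            for j in range(i + 1, n):
                sij = baseline_set_similarity(sets[i], sets[j], method)
                values[i, j] = values[j, i] = sij
    return SimilarityMatrix(ids=ids, values=values)
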