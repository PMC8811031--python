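"""Unifying-diagnosis identification: LCoP grouping, CCoM, primary-vs-complication split.

Typical codes are first merged under least common ancestors: codes whose
pairwise LCA is not the root (i.e. codes sharing a chapter) form one entry,
represented by the LCA of the whole group; isolated codes stay themselves.
Each entry inherits the minimum re-order rank of its members.

A conditional co-occurrence matrix (CCoM) over the entries is then computed
on the core patients: off-diagonal (i, j) = P(d_j | d_i), diagonal (i, i) =
Freq(d_i)/|Core|. A patient "has" an entry when any of their codes equals the
entry's node or descends from it. Strong asymmetries — entry i's conditional
or marginal exceeding entry j's by a dominance ratio ρ — indicate that d_j
tends to follow d_i, marking d_i as primary and d_j as a complication. The
unifying diagnosis is the prefix of the order-sorted entries that maximises
net dominance wins over the suffix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .ontology import OntologyTree, ROOT_CANONICAL, canonicalize
from .patterns import CoreZone, TDCCoP

DEFAULT_RHO = 1.5


@dataclass(frozen=True)
class LCoPEntry:
    """One LCA co-occurrence pattern entry: a TDC or an ancestor of ≥2 TDCs."""

    node: str
    members: tuple[str, ...]
    order: int | None = None


@dataclass
class CCoM:
    """Conditional co-occurrence matrix over LCoP entries."""

    nodes: list[str]
    matrix: np.ndarray
    core_size: int
    direction: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.nodes, columns=self.nodes)

    def value(self, a: str, b: str) -> float:
        i, j = self.nodes.index(a), self.nodes.index(b)
        return float(self.matrix[i, j])


@dataclass
class UDResult:
    """Primary diseases (the unifying diagnosis) vs complications, with audit."""

    cluster: int
    primaries: list[str]
    complications: list[str]
    rho: float
    dominance: np.ndarray  # [i, j] True when entry i dominates entry j
    split_scores: list[float]
    nodes: list[str]  # order-sorted LCoP nodes the split was taken over


def group_lcop(tdccop: TDCCoP, tree: OntologyTree) -> list[LCoPEntry]:
    """Partition TDCs into connected components under "pairwise LCA ≠ root".

    Multi-member components are replaced by the LCA of all members; singleton
    components keep their own code. Orders are assigned by :func:`lcop_order`.
    """
    codes = tdccop.codes
    if not codes:
        return []
    for c in codes:
        tree.add(c)
    # union-find over the "shares a non-root LCA" relation
    parent = list(range(len(codes)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(codes)):
        for j in range(i + 1, len(codes)):
            if tree.lca(codes[i], codes[j]).canonical != ROOT_CANONICAL:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    groups: dict[int, list[str]] = {}
    for i, code in enumerate(codes):
        groups.setdefault(find(i), []).append(code)
    entries = []
    for members in groups.values():
        if len(members) == 1:
            node = members[0]
        else:
            node = members[0]
            for other in members[1:]:
                node = tree.lca(node, other).canonical
        entries.append(LCoPEntry(node=node, members=tuple(members)))
    return entries


def lcop_order(entries: Sequence[LCoPEntry], tdccop: TDCCoP) -> list[LCoPEntry]:
    """Assign each entry the minimum re-order rank of its members; sort ascending."""
    ordered = []
    for e in entries:
        ranks = [tdccop.rank_of(m) for m in e.members]
        ordered.append(LCoPEntry(node=e.node, members=e.members, order=min(ranks)))
    ordered.sort(key=lambda e: e.order)
    return ordered


def ccom(
    entries: Sequence[LCoPEntry],
    core: CoreZone,
    tree: OntologyTree,
    direction: str = "symmetric",
) -> CCoM:
    """Conditional co-occurrence matrix of LCoP entries over core patients.

    ``symmetric`` counts patients carrying both entries; ``order_directed``
    counts, among those, patients whose earliest d_i code precedes their
    earliest d_j code (the causal reading of "d_j occurs after d_i").
    """
    if direction not in ("symmetric", "order_directed"):
        raise ValueError("direction must be 'symmetric' or 'order_directed'")
    if len(core) == 0:
        raise ValueError("empty core zone")
    nodes = [e.node for e in entries]
    for node in nodes:
        tree.add(node)
    L = len(nodes)
    # min order of each entry per patient (NaN when the patient lacks it)
    min_order = np.full((len(core), L), np.nan)
    for pi, patient in enumerate(core.patients):
        for ei, node in enumerate(nodes):
            orders = [
                o for c, o in patient.entries if tree.is_a(c, node)
            ]
            if orders:
                min_order[pi, ei] = min(orders)
    has = ~np.isnan(min_order)
    freq = has.sum(axis=0)
    matrix = np.zeros((L, L))
    for i in range(L):
        if freq[i] == 0:
            warnings.warn(
                f"LCoP entry {nodes[i]!r} occurs in no core patient; "
                "its conditional row is set to 0",
                stacklevel=2,
            )
            continue
        for j in range(L):
            if i == j:
                matrix[i, i] = freq[i] / len(core)
                continue
            both = has[:, i] & has[:, j]
            if direction == "symmetric":
                num = both.sum()
            else:
                num = (both & (min_order[:, i] < min_order[:, j])).sum()
            matrix[i, j] = num / freq[i]
    return CCoM(nodes=nodes, matrix=matrix, core_size=len(core), direction=direction)


def _dominance(matrix: np.ndarray, rho: float) -> np.ndarray:
    """dom[i, j]: entry i dominates j via conditional or marginal ratio ρ.

    The left-hand side must be strictly positive so that empty co-occurrence
    (0 vs 0) never counts as dominance.
    """
    L = matrix.shape[0]
    dom = np.zeros((L, L), dtype=bool)
    for i in range(L):
        for j in range(L):
            if i == j:
                continue
            cond = matrix[i, j] > 0 and matrix[i, j] >= rho * matrix[j, i]
            marg = matrix[i, i] > 0 and matrix[i, i] >= rho * matrix[j, j]
            dom[i, j] = cond or marg
    return dom


def identify_ud(
    lcop: Sequence[LCoPEntry],
    ccom_k: CCoM,
    rho: float = DEFAULT_RHO,
    cluster: int = 0,
) -> UDResult:
    """Split the order-sorted LCoP into primary diseases (UD) and complications.

    The split point maximises (dominance wins of the prefix over the suffix)
    − (wins of the suffix over the prefix); ties favour the smaller prefix.
    """
    if rho <= 1:
        raise ValueError("dominance ratio rho must exceed 1")
    entries = sorted(lcop, key=lambda e: (e.order is None, e.order))
    nodes = [e.node for e in entries]
    if not nodes:
        raise ValueError("empty LCoP")
    perm = [ccom_k.nodes.index(n) for n in nodes]
    matrix = ccom_k.matrix[np.ix_(perm, perm)]
    dom = _dominance(matrix, rho)
    L = len(nodes)
    if L == 1:
        return UDResult(
            cluster=cluster,
            primaries=nodes,
            complications=[],
            rho=rho,
            dominance=dom,
            split_scores=[],
            nodes=nodes,
        )
    scores = []
    for t in range(1, L):  # prefix size; complications stay non-empty
        prefix, suffix = range(t), range(t, L)
        wins = sum(dom[i, j] for i in prefix for j in suffix)
        losses = sum(dom[j, i] for i in prefix for j in suffix)
        scores.append(float(wins - losses))
    best = int(np.argmax(scores))  # argmax takes the first max → smallest prefix
    t = best + 1
    return UDResult(
        cluster=cluster,
        primaries=nodes[:t],
        complications=nodes[t:],
        rho=rho,
        dominance=dom,
        split_scores=scores,
        nodes=nodes,
    )
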