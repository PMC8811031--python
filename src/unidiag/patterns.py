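"""Typical diagnosis code (TDC) co-occurrence pattern extraction.

Within each cluster a *core zone* of patients most similar to the exemplar is
selected (by similarity threshold τ or by count). A code is *typical* when
its occurrence probability in the core exceeds δ₁ (strict). Each typical
code gets an average order (AOrd) — its mean position in the ordered
diagnosis lists of the core patients that carry it — and the TDCCoP is the
list of typical codes re-ranked 1..H′ by ascending AOrd (smaller AOrd ≈ more
central disease). Ties break on higher occurrence probability, then on the
canonical code string.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .ontology import canonicalize
from .similarity import CodeLike, PatientDiagnosis, SimilarityMatrix

DEFAULT_DELTA1 = 0.3
DEFAULT_CORE_N = 800


@dataclass
class CoreZone:
    """The most exemplar-similar members of one cluster (exemplar first)."""

    cluster: int
    exemplar_id: str
    patients: list[PatientDiagnosis]
    mode: str  # "top_n" | "threshold"
    param: float

    def __post_init__(self) -> None:
        if not self.patients or self.patients[0].patient_id != self.exemplar_id:
            raise ValueError("core zone must contain the exemplar as first member")

    @property
    def member_ids(self) -> list[str]:
        return [p.patient_id for p in self.patients]

    def __len__(self) -> int:
        return len(self.patients)


def core_zone(
    cluster_members: Sequence[PatientDiagnosis],
    exemplar_id: str,
    S: SimilarityMatrix,
    mode: str = "top_n",
    n: int = DEFAULT_CORE_N,
    tau: float | None = None,
    cluster: int = 0,
) -> CoreZone:
    """Select core patients by top-n similarity to the exemplar or threshold τ."""
    ids = {p.patient_id for p in cluster_members}
    if exemplar_id not in ids:
        raise ValueError(f"exemplar {exemplar_id!r} is not a cluster member")
    if mode not in ("top_n", "threshold"):
        raise ValueError("mode must be 'top_n' or 'threshold'")
    ranked = sorted(
        cluster_members,
        key=lambda p: (
            p.patient_id != exemplar_id,  # exemplar first
            -S.sim(p.patient_id, exemplar_id),
            p.patient_id,
        ),
    )
    if mode == "threshold":
        if tau is None or not 0 <= tau <= 1:
            raise ValueError("threshold mode requires tau in [0, 1]")
        kept = [p for p in ranked if S.sim(p.patient_id, exemplar_id) >= tau]
        param = float(tau)
    else:
        if n < 1:
            raise ValueError("top-n mode requires n >= 1")
        if n > len(ranked):
            warnings.warn(
                f"core size {n} exceeds cluster size {len(ranked)}; clamping",
                stacklevel=2,
            )
            n = len(ranked)
        kept = ranked[:n]
        param = float(n)
    return CoreZone(
        cluster=cluster, exemplar_id=exemplar_id, patients=kept, mode=mode, param=param
    )


def code_probability(core: CoreZone, code: CodeLike) -> float:
    """Fraction of core patients whose deduplicated code set contains the code."""
    if len(core) == 0:
        raise ValueError("empty core zone")
    canonical = canonicalize(code).canonical
    return sum(canonical in p.codes for p in core.patients) / len(core)


def typical_codes(core: CoreZone, delta1: float = DEFAULT_DELTA1) -> pd.DataFrame:
    """Codes with occurrence probability strictly above δ₁, with probabilities."""
    if not 0 <= delta1 < 1:
        raise ValueError("delta1 must lie in [0, 1)")
    counts: dict[str, int] = {}
    for p in core.patients:
        for c in p.codes:
            counts[c] = counts.get(c, 0) + 1
    rows = [
        (code, cnt / len(core))
        for code, cnt in counts.items()
        if cnt / len(core) > delta1
    ]
    rows.sort(key=lambda r: (-r[1], r[0]))
    return pd.DataFrame(rows, columns=["code", "probability"])


def average_order(core: CoreZone, code: CodeLike) -> float:
    """Mean order of the code over exactly the core patients that carry it."""
    canonical = canonicalize(code).canonical
    orders = [p.order_of(canonical) for p in core.patients if canonical in p.codes]
    if not orders:
        raise ValueError(f"code {canonical!r} occurs in no core patient")
    return float(np.mean(orders))


def _assign_ranks(entries: pd.DataFrame) -> pd.DataFrame:
    """Rank 1..H′ by ascending AOrd; ties → higher probability, then code."""
    out = entries.sort_values(
        ["average_order", "probability", "code"],
        ascending=[True, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


@dataclass
class TDCCoP:
    """Ranked typical-diagnosis-code co-occurrence pattern of one cluster."""

    cluster: int
    entries: pd.DataFrame  # columns: code, probability, average_order, rank

    @classmethod
    def from_summaries(
        cls,
        codes: Sequence[str],
        average_orders: Sequence[float],
        probabilities: Sequence[float] | None = None,
        cluster: int = 0,
    ) -> "TDCCoP":
        """Build a pattern from per-code summaries (e.g. a published table)."""
        if len(codes) != len(average_orders):
            raise ValueError("codes and average_orders lengths differ")
        probs = (
            list(probabilities) if probabilities is not None else [1.0] * len(codes)
        )
        entries = pd.DataFrame(
            {
                "code": [canonicalize(c).canonical for c in codes],
                "probability": probs,
                "average_order": list(average_orders),
            }
        )
        return cls(cluster=cluster, entries=_assign_ranks(entries))

    @property
    def codes(self) -> list[str]:
        return list(self.entries["code"])

    def rank_of(self, code: CodeLike) -> int:
        canonical = canonicalize(code).canonical
        row = self.entries[self.entries["code"] == canonical]
        if row.empty:
            raise KeyError(f"code {canonical!r} not in TDCCoP")
        return int(row["rank"].iloc[0])

    def __len__(self) -> int:
        return len(self.entries)


def build_tdccop(core: CoreZone, delta1: float = DEFAULT_DELTA1) -> TDCCoP:
    """Extract and rank the typical codes of a core zone."""
    typ = typical_codes(core, delta1)
    if typ.empty:
        warnings.warn(
            f"cluster {core.cluster}: no code exceeds delta1={delta1}; "
            "empty TDCCoP",
            stacklevel=2,
        )
        entries = pd.DataFrame(
            columns=["code", "probability", "average_order", "rank"]
        )
        return TDCCoP(cluster=core.cluster, entries=entries)
    typ = typ.copy()
    typ["average_order"] = [average_order(core, c) for c in typ["code"]]
    return TDCCoP(cluster=core.cluster, entries=_assign_ranks(typ))


def tdc_stability(
    cluster_members: Sequence[PatientDiagnosis],
    exemplar_id: str,
    S: SimilarityMatrix,
    core_sizes: Iterable[int],
    delta1: float = DEFAULT_DELTA1,
    cluster: int = 0,
) -> tuple[dict[int, frozenset[str]], pd.DataFrame]:
    """TDC sets across core sizes plus a pairwise-equality report.

    A stable size range is one over which the typical-code set does not
    change; the report flags, per size, whether it matches the previous one.
    """
    sizes = list(core_sizes)
    sets: dict[int, frozenset[str]] = {}
    for size in sizes:
        core = core_zone(
            cluster_members, exemplar_id, S, mode="top_n", n=size, cluster=cluster
        )
        sets[size] = frozenset(typical_codes(core, delta1)["code"])
    rows = []
    prev: frozenset[str] | None = None
    for size in sizes:
        rows.append(
            {
                "core_size": size,
                "n_tdcs": len(sets[size]),
                "same_as_previous": prev is not None and sets[size] == prev,
            }
        )
        prev = sets[size]
    return sets, pd.DataFrame(rows)
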