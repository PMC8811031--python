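"""Seeded synthetic EMR cohorts with known group structure.

Each patient belongs to one of K latent disease groups. A group is defined by
a *signature* — ICD-9 leaf codes carried with high probability at low
diagnosis orders — while a shared noise pool contributes incidental codes at
low probability and late orders. Admission features mirror the standard
four-block schema (3 demographics, 16 symptom flags, 19 labs × 5-number
summaries, 6 severity indicators = 120 raw columns), with group effects
injected as lab shifts and boosted symptom probabilities.

Because group membership, signatures and effect sizes are known, every
pipeline stage can be checked against ground truth without any restricted
clinical data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .ontology import build_ontology, canonicalize
from .patterns import TDCCoP
from .prediction import SYMPTOM_NAMES, lab_five_tuple
from .similarity import PatientDiagnosis
from .unifying import group_lcop, lcop_order

#: The 19 laboratory indicators summarised as 5-tuples (baseline mean, sd).
LAB_BASELINES: dict[str, tuple[float, float]] = {
    "potassium": (4.1, 0.5),
    "po2": (95.0, 25.0),
    "bicarbonate": (24.0, 4.0),
    "temperature": (37.0, 0.7),
    "sodium": (139.0, 4.0),
    "urine_out_foley": (120.0, 60.0),
    "urea_nitrogen": (25.0, 12.0),
    "wbc": (11.0, 5.0),
    "bilirubin": (1.2, 1.0),
    "gcs_motor": (5.5, 0.8),
    "gcs_eyes": (3.5, 0.7),
    "hr": (88.0, 16.0),
    "gcs_verbal": (4.0, 1.0),
    "nbp": (78.0, 14.0),
    "rr": (19.0, 5.0),
    "spo2": (96.0, 3.0),
    "hemoglobin": (10.5, 2.0),
    "platelet_count": (220.0, 90.0),
    "creatinine": (1.3, 1.0),
}

LAB_NAMES = tuple(LAB_BASELINES)
FIVE_STATS = ("min", "max", "median", "mean", "var")
SEVERITY_BINARY = ("aids", "hematologic_malignancy", "metastatic_cancer")
SEVERITY_SCORES = ("sofa", "saps", "sapsii")


@dataclass(frozen=True)
class SignatureCode:
    """One group-defining code: inclusion probability and order distribution."""

    code: str
    probability: float
    order_mean: float
    order_sd: float = 1.0


@dataclass(frozen=True)
class GroupSpec:
    name: str
    proportion: float
    signature: tuple[SignatureCode, ...]
    shifted_labs: tuple[str, ...] = ()
    lab_shift: float = 1.5  # in units of the lab's baseline sd
    boosted_symptoms: tuple[str, ...] = ()
    symptom_prob: float = 0.7


@dataclass(frozen=True)
class CohortConfig:
    n_patients: int = 200
    groups: tuple[GroupSpec, ...] = ()
    noise_codes: tuple[str, ...] = ()
    noise_rate: float = 0.1
    noise_order_mean: float = 7.0
    noise_order_sd: float = 2.0
    baseline_symptom_prob: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("config needs at least one group")
        for g in self.groups:
            if not g.signature:
                raise ValueError(f"group {g.name!r} has an empty signature")
            for sc in g.signature:
                if not 0 <= sc.probability <= 1:
                    raise ValueError(f"probability out of [0,1] for {sc.code}")
                canonicalize(sc.code)
        if not 0 <= self.noise_rate <= 1:
            raise ValueError("noise_rate must lie in [0, 1]")
        if abs(sum(g.proportion for g in self.groups) - 1.0) > 1e-9:
            raise ValueError("group proportions must sum to 1")
        for c in self.noise_codes:
            canonicalize(c)


def default_config(
    n_patients: int = 200, seed: int = 0, noise_rate: float = 0.1
) -> CohortConfig:
    """Three well-separated groups with signatures in disjoint chapters.

    Respiratory, circulatory and genitourinary phenotypes (3 codes each,
    inclusion probabilities 0.95/0.90/0.85 at order means 1/2/3) over a noise
    pool drawn from other chapters at rate 0.1 — the regime in which pattern
    recovery is expected to be exact.
    """
    groups = (
        GroupSpec(
            name="respiratory",
            proportion=1 / 3,
            signature=(
                SignatureCode("518.81", 0.95, 1.0),
                SignatureCode("486", 0.90, 2.0),
                SignatureCode("491.21", 0.85, 3.0),
            ),
            shifted_labs=("po2", "rr", "spo2", "wbc"),
            boosted_symptoms=("cough", "shortness_of_breath"),
        ),
        GroupSpec(
            name="circulatory",
            proportion=1 / 3,
            signature=(
                SignatureCode("428.0", 0.95, 1.0),
                SignatureCode("427.31", 0.90, 2.0),
                SignatureCode("410.71", 0.85, 3.0),
            ),
            shifted_labs=("hr", "nbp", "hemoglobin", "sodium"),
            boosted_symptoms=("palpitation", "weakness"),
        ),
        GroupSpec(
            name="genitourinary",
            proportion=1 / 3,
            signature=(
                SignatureCode("584.9", 0.95, 1.0),
                SignatureCode("599.0", 0.90, 2.0),
                SignatureCode("585.9", 0.85, 3.0),
            ),
            shifted_labs=("creatinine", "urea_nitrogen", "urine_out_foley", "potassium"),
            boosted_symptoms=("dysuria", "fever"),
        ),
    )
    noise = ("038.9", "276.2", "250.00", "285.9", "311", "305.1", "V58.61", "780.60")
    return CohortConfig(
        n_patients=n_patients,
        groups=groups,
        noise_codes=noise,
        noise_rate=noise_rate,
        seed=seed,
    )


def _draw_labels(config: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    props = np.array([g.proportion for g in config.groups])
    return rng.choice(len(config.groups), size=config.n_patients, p=props)


def generate_diagnoses(
    config: CohortConfig, seed: int | None = None
) -> tuple[list[PatientDiagnosis], np.ndarray]:
    """Sample diagnosis records; returns (patients, true group labels).

    Signature codes enter independently with their configured probabilities;
    order keys are sampled from each code's order distribution and re-ranked
    to the unique integers 1..m, so earlier order means land earlier ranks in
    expectation. Same config and seed → identical cohort.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    labels = _draw_labels(config, rng)
    patients = []
    for i in range(config.n_patients):
        group = config.groups[labels[i]]
        codes: list[str] = []
        keys: list[float] = []
        for sc in group.signature:
            if rng.random() < sc.probability:
                codes.append(canonicalize(sc.code).canonical)
                keys.append(rng.normal(sc.order_mean, sc.order_sd))
        for nc in config.noise_codes:
            if rng.random() < config.noise_rate:
                codes.append(canonicalize(nc).canonical)
                keys.append(rng.normal(config.noise_order_mean, config.noise_order_sd))
        if not codes:  # guarantee the non-empty record invariant
            sc = group.signature[0]
            codes, keys = [canonicalize(sc.code).canonical], [sc.order_mean]
        order = np.argsort(np.argsort(keys)) + 1  # dense ranks 1..m, no ties
        patients.append(
            PatientDiagnosis(
                patient_id=f"P{i:04d}",
                entries=list(zip(codes, (int(o) for o in order))),
            )
        )
    return patients, labels


def generate_admission_features(
    config: CohortConfig, labels: np.ndarray, seed: int | None = None
) -> pd.DataFrame:
    """120-column admission feature table mirroring the four-block schema.

    Blocks carry their prefixes (``de_``, ``sy_``, ``le_``, ``sev_``);
    demographics stay nominal (one-hot happens in ``fuse_features``). Group
    effects: configured labs shifted by ``lab_shift`` baseline sds, configured
    symptom probabilities boosted; severity is group-independent.
    """
    rng = np.random.default_rng((config.seed if seed is None else seed) + 1)
    labels = np.asarray(labels)
    if len(labels) != config.n_patients:
        raise ValueError("labels length does not match config.n_patients")
    n = config.n_patients
    ids = [f"P{i:04d}" for i in range(n)]
    cols: dict[str, list] = {}

    cols["de_age"] = list(np.clip(rng.normal(66, 14, size=n).round(1), 18, 89))
    cols["de_gender"] = [("F", "M")[v] for v in rng.integers(0, 2, size=n)]
    cols["de_admission_type"] = list(
        rng.choice(["EMERGENCY", "ELECTIVE", "URGENT"], size=n, p=[0.8, 0.05, 0.15])
    )

    for name in SYMPTOM_NAMES:
        flags = []
        for i in range(n):
            g = config.groups[labels[i]]
            prob = g.symptom_prob if name in g.boosted_symptoms else (
                config.baseline_symptom_prob
            )
            flags.append(int(rng.random() < prob))
        cols[f"sy_{name}"] = flags

    for lab, (mu, sd) in LAB_BASELINES.items():
        tuples = []
        for i in range(n):
            g = config.groups[labels[i]]
            shift = g.lab_shift * sd if lab in g.shifted_labs else 0.0
            m = int(rng.integers(5, 13))
            tuples.append(lab_five_tuple(rng.normal(mu + shift, sd, size=m)))
        for si, stat in enumerate(FIVE_STATS):
            cols[f"le_{lab}_{stat}"] = [t[si] for t in tuples]

    for name, p in zip(SEVERITY_BINARY, (0.03, 0.08, 0.10)):
        cols[f"sev_{name}"] = list((rng.random(n) < p).astype(int))
    cols["sev_sofa"] = list(np.clip(rng.normal(6, 2.5, n).round(), 0, 24).astype(int))
    cols["sev_saps"] = list(np.clip(rng.normal(16, 4, n).round(), 0, 56).astype(int))
    cols["sev_sapsii"] = list(np.clip(rng.normal(35, 9, n).round(), 0, 120).astype(int))

    return pd.DataFrame(cols, index=pd.Index(ids, name="patient_id"))


@dataclass(frozen=True)
class GroupTruth:
    """Expected pipeline outputs for one group under the configured regime."""

    name: str
    tdcs: frozenset[str]
    lcop_nodes: frozenset[str]
    primary_node: str


def ground_truth(config: CohortConfig, delta1: float = 0.3) -> dict[str, GroupTruth]:
    """Per group: expected TDC set, LCoP nodes, and the primary-disease entry.

    TDCs are the signature codes whose configured probability exceeds δ₁;
    LCoP nodes follow from grouping them under least common ancestors; the
    primary entry is the one containing the earliest-order signature code.
    """
    tree = build_ontology(
        [sc.code for g in config.groups for sc in g.signature]
        + list(config.noise_codes)
    )
    truths = {}
    for g in config.groups:
        expected = [sc for sc in g.signature if sc.probability > delta1]
        tdcs = frozenset(canonicalize(sc.code).canonical for sc in expected)
        by_order = sorted(expected, key=lambda sc: sc.order_mean)
        tdccop = TDCCoP.from_summaries(
            [sc.code for sc in by_order],
            [sc.order_mean for sc in by_order],
            [sc.probability for sc in by_order],
        )
        entries = lcop_order(group_lcop(tdccop, tree), tdccop)
        first = canonicalize(by_order[0].code).canonical if by_order else None
        primary = next(e.node for e in entries if first in e.members)
        truths[g.name] = GroupTruth(
            name=g.name,
            tdcs=tdcs,
            lcop_nodes=frozenset(e.node for e in entries),
            primary_node=primary,
        )
    return truths


def zero_effect_config(config: CohortConfig) -> CohortConfig:
    """Copy of a config with all feature-block group effects removed."""
    groups = tuple(
        replace(g, shifted_labs=(), boosted_symptoms=()) for g in config.groups
    )
    return replace(config, groups=groups)
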