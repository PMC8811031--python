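"""Readers, writers and the end-to-end pipeline runner.

The diagnoses reader consumes the common critical-care CSV dialect (one row
per admission/code with a 1-based rank column, dotless or dotted ICD-9
codes). All artifacts are plain CSV/JSON; every run emits its resolved
parameter set so results can be reproduced bit-for-bit from the artifacts.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .clustering import ClusteringResult
from .estimators import UnifyingDiagnosisIdentifier
from .ontology import canonicalize
from .prediction import CLASSIFIER_NAMES, fuse_features, split_blocks, train_and_evaluate
from .similarity import PatientDiagnosis, SimilarityMatrix


@dataclass
class RunConfig:
    """Resolved parameters of one pipeline run (all defaults are the
    package's standard operating point)."""

    diagnoses_csv: str
    out_dir: str
    features_csv: str | None = None
    id_col: str = "hadm_id"
    order_col: str = "seq_num"
    code_col: str = "icd9_code"
    method: str = "ontology"
    p: float | None = None
    p_coe: float = 0.025
    damping: float = 0.9
    max_iter: int = 1000
    convergence_window: int = 50
    core_mode: str = "top_n"
    core_n: int = 800
    tau: float = 0.5
    delta1: float = 0.3
    delta2: float = 0.005
    rho: float = 1.5
    Z: int = 10
    direction: str = "symmetric"
    classifiers: Sequence[str] = field(default_factory=lambda: list(CLASSIFIER_NAMES))
    seed: int = 0


def read_diagnoses(
    path,
    id_col: str = "hadm_id",
    order_col: str = "seq_num",
    code_col: str = "icd9_code",
    on_error: str = "warn",
) -> list[PatientDiagnosis]:
    """Read per-admission diagnosis rows into PatientDiagnosis records.

    Codes are canonicalized; entries sort by order; duplicate (patient, code)
    rows collapse onto the smallest order. Unparseable codes are reported
    with their CSV line numbers and either skipped (``on_error="warn"``) or
    fatal (``"raise"``); patients left with no valid code are dropped.
    """
    frame = pd.read_csv(path, dtype={code_col: str, id_col: str})
    missing = [c for c in (id_col, order_col, code_col) if c not in frame.columns]
    if missing:
        raise ValueError(f"diagnoses CSV lacks columns {missing}")
    bad: list[str] = []
    rows: dict[str, list[tuple[str, int]]] = {}
    for pos, row in enumerate(frame.itertuples(index=False)):
        raw = getattr(row, code_col)
        try:
            code = canonicalize(raw).canonical
            order = int(getattr(row, order_col))
        except (ValueError, TypeError) as exc:
            bad.append(f"line {pos + 2}: {exc}")  # +2: header + 1-based
            continue
        rows.setdefault(str(getattr(row, id_col)), []).append((code, order))
    if bad:
        report = "; ".join(bad)
        if on_error == "raise":
            raise ValueError(f"unparseable diagnosis rows: {report}")
        warnings.warn(f"skipped unparseable diagnosis rows: {report}", stacklevel=2)
    patients = []
    for pid, entries in rows.items():
        if not entries:
            continue
        patients.append(PatientDiagnosis.from_raw(pid, entries))
    dropped = set(frame[id_col].astype(str)) - {p.patient_id for p in patients}
    if dropped:
        warnings.warn(
            f"dropped patients with no valid code: {sorted(dropped)}", stacklevel=2
        )
    return patients


def write_diagnoses(
    patients: Sequence[PatientDiagnosis],
    path,
    id_col: str = "hadm_id",
    order_col: str = "seq_num",
    code_col: str = "icd9_code",
) -> None:
    rows = [
        {id_col: p.patient_id, order_col: o, code_col: c}
        for p in patients
        for c, o in p.entries
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_features(path) -> pd.DataFrame:
    frame = pd.read_csv(path, index_col=0)
    frame.index = frame.index.astype(str)
    return frame


def write_clusters(result: ClusteringResult, path) -> None:
    exemplars = set(result.exemplar_indices)
    pd.DataFrame(
        {
            "patient_id": result.ids,
            "cluster": result.labels,
            "is_exemplar": [int(i in exemplars) for i in range(len(result.ids))],
        }
    ).to_csv(path, index=False)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _write_json(obj, path) -> None:
    Path(path).write_text(
        json.dumps(obj, indent=2, sort_keys=True, default=_json_default) + "\n"
    )


def run_pipeline(config: RunConfig) -> dict[str, str]:
    """Execute the full pipeline, writing artifacts into ``config.out_dir``.

    Stages: similarity → clustering → TDCCoP extraction → UD identification,
    then prediction when a feature table is supplied. A stage failure aborts
    with the stage name; artifacts written before the failure persist.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    _write_json(dataclasses.asdict(config), out / "resolved_config.json")
    artifacts["config"] = str(out / "resolved_config.json")

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    patients = stage(
        "read",
        lambda: read_diagnoses(
            config.diagnoses_csv,
            id_col=config.id_col,
            order_col=config.order_col,
            code_col=config.code_col,
        ),
    )
    model = UnifyingDiagnosisIdentifier(
        method=config.method,
        p=config.p,
        p_coe=config.p_coe,
        damping=config.damping,
        max_iter=config.max_iter,
        convergence_window=config.convergence_window,
        core_mode=config.core_mode,
        core_n=config.core_n,
        tau=config.tau,
        delta1=config.delta1,
        rho=config.rho,
        direction=config.direction,
        random_state=config.seed,
    )
    stage("identify", lambda: model.fit(patients))

    model.similarity_.to_csv(out / "similarity.csv")
    artifacts["similarity"] = str(out / "similarity.csv")

    write_clusters(model.clustering_, out / "clusters.csv")
    artifacts["clusters"] = str(out / "clusters.csv")
    _write_json(
        {
            "p": model.clustering_.p,
            "p_coe": config.p_coe,
            "K": model.clustering_.K,
            "SS": model.ss_,
            "supports": model.clustering_.supports,
            "exemplars": model.clustering_.exemplar_ids,
            "converged": model.clustering_.converged,
            "n_iter": model.clustering_.n_iter,
        },
        out / "cluster_meta.json",
    )
    artifacts["cluster_meta"] = str(out / "cluster_meta.json")

    _write_json(
        [
            {
                "cluster": t.cluster,
                "core_size": len(model.core_zones_[k]),
                "entries": t.entries.to_dict(orient="records"),
            }
            for k, t in enumerate(model.tdccops_)
        ],
        out / "tdccop.json",
    )
    artifacts["tdccop"] = str(out / "tdccop.json")

    ud_payload = []
    for k, result in enumerate(model.ud_results_):
        if result is None:
            ud_payload.append({"cluster": k, "lcop": [], "primaries": []})
            continue
        ud_payload.append(
            {
                "cluster": k,
                "lcop": [
                    {"node": e.node, "order": e.order, "members": list(e.members)}
                    for e in model.lcops_[k]
                ],
                "ccom": model.ccoms_[k].matrix,
                "ccom_nodes": model.ccoms_[k].nodes,
                "direction": config.direction,
                "rho": config.rho,
                "primaries": result.primaries,
                "complications": result.complications,
                "dominance": result.dominance.astype(int),
                "split_scores": result.split_scores,
            }
        )
    _write_json(ud_payload, out / "ud.json")
    artifacts["ud"] = str(out / "ud.json")

    if config.features_csv is None:
        warnings.warn("no feature table supplied; prediction stage skipped")
        return artifacts

    def predict_stage():
        table = read_features(config.features_csv)
        table = table.loc[list(model.similarity_.ids)]
        X = fuse_features(*split_blocks(table))
        y = model.labels_
        return train_and_evaluate(
            X,
            y,
            classifiers=list(config.classifiers),
            Z=config.Z,
            seed=config.seed,
            delta2=config.delta2,
        )

    report = stage("predict", predict_stage)
    _write_json(
        {
            "metrics": report.metrics.to_dict(orient="index"),
            "fold_errors": report.fold_errors,
            "classes": report.classes,
        },
        out / "metrics.json",
    )
    artifacts["metrics"] = str(out / "metrics.json")
    report.selected.rename_axis("feature").reset_index().to_csv(
        out / "selected_features.csv", index=False
    )
    artifacts["selected_features"] = str(out / "selected_features.csv")
    return artifacts
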