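"""High-level estimator running similarity → clustering → patterns → UD."""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator

from .clustering import cluster, sum_of_similarities
from .ontology import build_ontology
from .patterns import build_tdccop, core_zone
from .similarity import similarity_matrix
from .unifying import ccom, group_lcop, identify_ud, lcop_order


class UnifyingDiagnosisIdentifier(BaseEstimator):
    """Identify unifying diagnoses from multi-code diagnostic records.

    ``fit`` takes a list of :class:`~unidiag.similarity.PatientDiagnosis` and
    executes the unsupervised pipeline: ontology-embedded patient similarity,
    affinity propagation clustering, core-zone typical-code extraction, LCA
    grouping, conditional co-occurrence analysis and the primary-disease
    split. Results live in trailing-underscore attributes.

    Parameters
    ----------
    method : str
        Set similarity: "ontology" (default) or an exact-match baseline
        ("dice", "jaccard", "cosine", "cosine_printed", "overlap").
    p, p_coe : float
        Exemplar preference, given directly or via the coefficient rule
        p = median(offdiag) − p_coe·N.
    damping, max_iter, convergence_window : AP message-passing controls.
    core_mode, core_n, tau : core-zone selection (top-n count or similarity
        threshold).
    delta1 : occurrence-probability threshold for typical codes.
    rho : dominance ratio for the primary/complication split.
    direction : co-occurrence counting, "symmetric" or "order_directed".
    random_state : seeds the AP tie-breaking jitter.

    Attributes
    ----------
    tree_ : OntologyTree over all patient codes.
    similarity_ : SimilarityMatrix.
    clustering_ : ClusteringResult (labels_, exemplar ids, supports, K_).
    ss_ : sum of member-to-exemplar similarities.
    core_zones_, tdccops_, lcops_, ccoms_, ud_results_ : per-cluster outputs.
    """

    def __init__(
        self,
        method: str = "ontology",
        p: float | None = None,
        p_coe: float = 0.025,
        damping: float = 0.9,
        max_iter: int = 1000,
        convergence_window: int = 50,
        core_mode: str = "top_n",
        core_n: int = 800,
        tau: float = 0.5,
        delta1: float = 0.3,
        rho: float = 1.5,
        direction: str = "symmetric",
        random_state: int = 0,
    ):
        self.method = method
        self.p = p
        self.p_coe = p_coe
        self.damping = damping
        self.max_iter = max_iter
        self.convergence_window = convergence_window
        self.core_mode = core_mode
        self.core_n = core_n
        self.tau = tau
        self.delta1 = delta1
        self.rho = rho
        self.direction = direction
        self.random_state = random_state

    def fit(self, patients, y=None, tree=None):
        patients = list(patients)
        self.tree_ = tree if tree is not None else build_ontology(
            c for p in patients for c in p.codes
        )
        self.similarity_ = similarity_matrix(
            patients, tree=self.tree_, method=self.method
        )
        self.clustering_ = cluster(
            self.similarity_,
            p=self.p,
            p_coe=self.p_coe,
            damping=self.damping,
            max_iter=self.max_iter,
            convergence_window=self.convergence_window,
            seed=self.random_state,
        )
        self.labels_ = self.clustering_.labels
        self.K_ = self.clustering_.K
        self.ss_ = sum_of_similarities(self.similarity_, self.clustering_)

        by_id = {p.patient_id: p for p in patients}
        self.core_zones_, self.tdccops_ = [], []
        self.lcops_, self.ccoms_, self.ud_results_ = [], [], []
        for k in range(self.K_):
            members = [by_id[pid] for pid in self.clustering_.members_of(k)]
            exemplar = self.clustering_.exemplar_ids[k]
            with warnings.catch_warnings():
                # top-n larger than a small cluster is routine here
                warnings.simplefilter("ignore")
                core = core_zone(
                    members,
                    exemplar,
                    self.similarity_,
                    mode=self.core_mode,
                    n=self.core_n,
                    tau=self.tau,
                    cluster=k,
                )
            self.core_zones_.append(core)
            tdccop = build_tdccop(core, delta1=self.delta1)
            self.tdccops_.append(tdccop)
            if len(tdccop) == 0:
                warnings.warn(f"cluster {k}: empty TDCCoP, no UD identified")
                self.lcops_.append([])
                self.ccoms_.append(None)
                self.ud_results_.append(None)
                continue
            lcop = lcop_order(group_lcop(tdccop, self.tree_), tdccop)
            self.lcops_.append(lcop)
            matrix = ccom(lcop, core, self.tree_, direction=self.direction)
            self.ccoms_.append(matrix)
            self.ud_results_.append(
                identify_ud(lcop, matrix, rho=self.rho, cluster=k)
            )
        return self

    @property
    def unifying_diagnoses_(self) -> list[list[str]]:
        return [r.primaries if r is not None else [] for r in self.ud_results_]
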