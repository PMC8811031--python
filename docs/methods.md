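# Methods

## Scope and model

`unidiag` treats unifying-diagnosis (UD) discovery as a two-part problem:

* **unsupervised** — group admissions by the semantic similarity of their
  diagnosis-code sets, then summarise each group by a ranked co-occurrence
  pattern of typical codes and split that pattern into primary diseases
  (the UD) and complications;
* **supervised** — predict the group (hence the UD) of a new admission from
  features available at admission time.

The unit of analysis is one hospital admission with its ordered ICD-9 code
list. Order is assumed to encode clinical priority (rank 1 = most central
disease); the similarity stage deliberately ignores it, and it re-enters
only when ranking typical codes by average position.

## Ontology reconstruction

The five-level ontology is rebuilt from a packaged chapter/section range
table derived from the standard ICD-9-CM tabular list: 19 chapters (17
disease chapters plus the V- and E-code supplementary classifications) and
~155 sections. Published descriptions of this structure sometimes count 129
sections; section tables differ slightly across ICD-9-CM revisions and the
exact count has no effect on any quantity computed here beyond the depth of
individual codes. Two conventions matter:

* **Degenerate chapters.** Chapters 280–289 and 740–759 contain no internal
  sections; rather than duplicating the chapter range as a pseudo-section,
  the section level is skipped there (a category's parent is the chapter).
  Consequently `IC(parent) = IC(child) − 1` holds everywhere except across
  those two category→chapter edges.
* **Range levels.** A range token is a chapter if it matches a chapter row,
  else a section. In particular 520–579 (digestive system) is a chapter,
  level 1: the least common ancestor of 541 and 550.13 is that chapter, so
  s(541, 550.13) = 2·1/(3+5) = 0.25 under the level-depth information
  content.

E-codes carry a four-character category stem (`E950`) and at most one
decimal digit, placed at level 4; they have no level-5 extensions. Dotless
MIMIC-style strings, dotted strings, and lowercase v/e are all accepted;
the canonical form is dotted with leading zeros (`038.9`). Virtual sibling
padding (placeholder codes that complete each decade of subcodes) is never
materialised — it cannot affect LCA queries, which walk actual ancestor
chains.

## Similarity

Code similarity is the Wu–Palmer-style ratio on level-depth IC; it is 1 iff
the codes are identical and 0 iff they share only the root (different
chapters). Patient similarity is the best-match average over both
deduplicated code sets (duplicate codes within one admission collapse onto
their smallest order at ingestion). The matrix builder computes each
unordered pair once from a cached code-pair similarity table, so results are
independent of evaluation order.

The printed definition of the cosine baseline in some comparative tables
omits the square root (|A∩B| / (|A|·|B|)); because that variant is not
bounded consistently with the other measures, `cosine` here is the standard
|A∩B| / √(|A|·|B|) and the unnormalised form is available as
`cosine_printed`.

## Clustering

Affinity propagation (Frey–Dueck message passing, via scikit-learn) with:

* preference `p = median(off-diagonal similarities) − p_coe·N`. The median
  is taken over off-diagonal entries only: the unit diagonal is a
  placeholder, not data. `p` may also be supplied directly for sweeps.
* damping 0.9, max 1000 iterations, convergence window 50 — conservative
  settings favouring stability on blocky clinical similarity matrices.
* a tiny seeded jitter (the scikit-learn implementation's tie-breaker)
  makes runs deterministic given a seed even on exactly tied similarities.

If message passing fails to produce a valid exemplar set, the result is a
single cluster around the max-row-sum medoid with `converged=False` and a
warning — downstream stages still run, flagged. Affinity propagation is a
heuristic: on instances where the preference makes the exemplar count
marginal it can settle in a suboptimal fixed point; the test suite checks
optimality against exhaustive exemplar search only on well-separated block
fixtures, which is the regime the method is meant to operate in.

## Pattern extraction and UD identification

* **Core zone** — default top-`n` (n = 800, clamped to the cluster size with
  a warning) because published experiments fix patient counts; threshold
  mode `S(member, exemplar) ≥ τ` is also provided. Members are ordered by
  descending exemplar similarity with the exemplar first; ties break on
  patient id for determinism.
* **Typical codes** — occurrence probability strictly greater than δ₁
  (default 0.3), computed on deduplicated per-patient code sets.
* **Ranking** — ascending average order; ties break on higher occurrence
  probability, then lexicographic canonical code.
* **LCoP grouping** — connected components under "pairwise LCA ≠ root"
  (equivalently: same chapter); a multi-member component is represented by
  the LCA of all members, singletons keep their own code, and each entry's
  order is the minimum re-order rank of its members.
* **CCoM** — a patient *has* an entry when any of their codes equals it or
  descends from it (core patients carry leaf codes, entries may be ranges).
  The default symmetric mode counts patients carrying both entries;
  `order_directed` mode counts, among those, patients whose earliest code
  under entry i precedes their earliest code under entry j — the causal
  reading of "j tends to occur after i". Neither mode is claimed to match
  any particular historical implementation; both are exported for audit.
* **Dominance and split** — the qualitative "much greater" between
  conditional or marginal probabilities is formalised as a ratio test with
  ρ (default 1.5): entry i dominates j when `CCoM(i,j) ≥ ρ·CCoM(j,i)` or
  `CCoM(i,i) ≥ ρ·CCoM(j,j)`, with the left side required to be strictly
  positive so that empty co-occurrence never dominates. The UD is the
  prefix of the order-sorted entries maximising (prefix-over-suffix wins −
  suffix-over-prefix wins); ties favour the smaller prefix, and a
  single-entry pattern is its own UD. This maximisation is one explicit
  formalisation of a split that is often performed by visual inspection;
  the full dominance matrix and per-split scores are exported so users can
  audit or override it. Raising ρ never creates new dominance, so the split
  is weakly monotone in ρ.

## Prediction

* **Lab five-tuples** use population variance (ddof = 0): the summary is
  descriptive of the observed within-stay series, not an estimate of a
  superpopulation parameter.
* **Symptom extraction** is a compact dictionary-plus-negation surrogate for
  a full clinical-NLP pipeline: case-insensitive token n-gram matching of
  surface forms (including abbreviations such as "SOB"), with a negation
  window of 3 tokens that does not cross clause boundaries (commas,
  semicolons, periods). It is adequate for template-like synthetic snippets
  and for smoke-testing real text, not a validated clinical NLP system.
* **Fusion** one-hot encodes nominal columns and min–max normalises
  numerics. The canonical admission schema has 120 raw columns
  (3 demographic + 16 symptoms + 19 labs × 5 + 6 severity); one-hot
  expansion of 3-level admission type and gender yields 123 model columns.
* **Information gain** is computed in bits; numeric features are first
  discretised into 10 equal-frequency bins (right-closed); missing values
  form their own bin. Selection keeps IG strictly above δ₂ (default 0.005).
* **Cross-validation** is stratified Z-fold (default 10). Imputation
  (training-fold medians plus missingness indicators), IG selection and
  seeded random oversampling of minority classes to the majority count are
  all refit inside each training fold — the test suite asserts the absence
  of leakage with a label-copy canary under permuted labels.
* **Metrics**: accuracy; precision/recall/F1 support-weighted over classes
  (weighted recall is algebraically identical to accuracy); one-vs-rest
  support-weighted AUC; CV error is the mean per-fold 0/1 mismatch rate —
  the squared-error form of the CV criterion reduces to a mismatch
  indicator for nominal labels.

## Synthetic cohorts

The generator emulates the ingestion schema: per-patient code lists with
dense unique order ranks, and the 120-column admission feature table. Its
default regime — three groups with 3-code signatures in disjoint chapters at
inclusion probabilities 0.95/0.90/0.85 and order means 1/2/3, over an
8-code cross-chapter noise pool at rate 0.1 — is the well-separated setting
in which clustering should recover groups near-perfectly and typical-code
sets should equal the signatures. Order keys are sampled normally around
each code's configured mean and re-ranked to 1..m, so uniqueness of orders
holds by construction.

What the generator does **not** emulate: realistic code-frequency
distributions (real cohorts have thousands of distinct codes with heavy
tails), correlated comorbidity structure beyond the planted signatures,
informative missingness in labs, or realistic clinical prose (symptom
snippets are template-based). Passing the recovery tests therefore shows
the pipeline is correct and self-consistent under its stated assumptions —
not that any particular clinical cohort will produce stable clusters.

## Numerical and determinism notes

* All randomness flows from explicit integer seeds (`numpy.random.default_rng`
  and scikit-learn `random_state`); identical configuration + seed gives
  byte-identical artifacts, which the pipeline test verifies by checksum.
* Similarity values are exact rational arithmetic in floating point
  (small-integer numerators/denominators), so worked-example checks use
  exact equality.
* Problem sizes in the test suite (cohorts of 60–200 patients, 10 recovery
  seeds, Z = 5 folds in most prediction tests) were chosen as the smallest
  sizes at which the statistical assertions are stable.

## Known limitations

* Order-weighted similarity (down-weighting late, incidental codes) is not
  implemented; similarity treats all codes in the deduplicated set equally.
* The LCoP grouping merges any same-chapter codes; very heterogeneous
  chapters (e.g. injury and poisoning, 800–999) can merge clinically
  unrelated typical codes.
* ICD-10 is out of scope; so is computing severity scores (SOFA, SAPS),
  which are consumed as given numeric columns.
* The dominance ratio ρ has no canonical value; 1.5 is a conservative
  default and the exported dominance ledger is the intended audit path.
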