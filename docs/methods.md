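# Methods

This note records the model implemented by `comorbnet`, the parameter choices
baked into its defaults, what the synthetic generators do and do not emulate,
and the numerical conventions that affect results.

## Claims processing and the phenotypic disease network

**Input model.** Hospital claims are rows with `patient_id`, `sex`, `age`,
`admission_date` and up to five diagnosis slots (`dx1`–`dx5`) holding
ICD-9-CM codes. Codes may carry or omit the decimal point; both forms are
accepted and normalised. A patient may appear on many admissions; all
counting is at the patient level — a code contributes at most once per
patient regardless of how many admissions list it. Patient sex and age are
taken from the first admission in file order.

**Code granularity.** Codes are truncated to a configurable `node_level`
before counting: 3 digits (default), 4, or 5. E-codes have a four-character
root. Truncation happens before deduplication, so a patient with 250.01 and
250.13 contributes a single count to node "250" at level 3.

**Diabetes typing.** An inpatient's diabetes type is read from the fifth
digit of any 250.xx code: 1 or 3 → type 1, 0 or 2 → type 2, any other
250 code → "other". Type 1 takes precedence when a patient carries codes of
both kinds, on the rationale that a type-1 code is the more specific claim.
Patients without a 250 code are typed "none".

**φ-correlation.** For a pair (i, j):

φ = (N·N_ij − N_i·N_j) / √(N_i·N_j·(N−N_i)·(N−N_j))

This is algebraically identical to the Pearson correlation of the two binary
indicator vectors, and the test suite verifies the identity on randomly
generated 2×2 tables. φ is undefined when either disease is carried by no
patient or by every patient (zero variance); the library raises
`UndefinedPhiError` rather than returning a sentinel.

**Link selection.** Candidate pairs are every unordered pair of codes with
N_ij ≥ 1. The PDN keeps the top `ceil(threshold_fraction × n_candidates)`
pairs by φ, descending; pairs tied with the cut-off value are all included
(tie extension), so the network never depends on an arbitrary tie order.
The default fraction is 0.006 (0.6%). Nodes are the endpoints of retained
links; codes that never enter a retained link do not appear.

**Category profiles and comparison.** Nodes are mapped to 13 ICD-9-CM
chapter categories spanning 001–629 and 680–759 (infectious; neoplasms;
endocrine/metabolic; blood; mental; nervous system and sense organs;
circulatory; respiratory; digestive; genitourinary; skin; musculoskeletal;
congenital). Codes in 630–679, 760–999 and E/V chapters are excluded from
profiles. Two strata's profiles are compared per category with the pooled
two-sample proportion z-test, without continuity correction; one- or
two-sided p-values come from the normal survival function. When the pooled
standard error is zero the comparison is flagged `undefined` instead of
fabricating a statistic. Bonferroni correction across the 13 categories is
optional and off by default, so the caller chooses the error-rate policy.

## Graph topology

**Connected component.** Analyses run on the giant component. Ties in
component size are broken deterministically by the lexicographically smallest
node label, so results do not depend on traversal order.

**Centralities.** Betweenness centrality is normalised by (n−1)(n−2)/2
(undirected convention); closeness is the standard (n−1)/Σd form, not the
harmonic variant. Average clustering includes degree-<2 nodes with
coefficient 0. Shortest-path quantities require a connected graph and raise
`DisconnectedGraphError` otherwise. The test suite pins these conventions
against a brute-force path-enumeration oracle on all connected 4-node graphs
and on random graphs up to 8 nodes, so a library upgrade that silently
changed normalisation would be caught.

**Backbone.** The backbone is the induced subgraph on the top
`backbone_fraction` (default 0.20) of nodes by betweenness. The cut-off is
the k-th descending value with k = ceil(fraction × n), applied inclusively —
the same tie-extension rule as link selection. Because the subgraph is
induced, backbone links are exactly the original links among backbone nodes.

**Roles.** Hubs are nodes at or above a degree cut-off, bottlenecks at or
above a betweenness cut-off. Cut-offs may be given as top fractions (defaults
0.10 and 0.10) or as explicit values; explicit values matter when the records
at hand are a pre-selected subset (e.g. a published backbone table) but the
cut-offs were defined on the full component. The four roles — date-hub,
party-hub, nonhub-bottleneck, other — partition the nodes exhaustively and
exclusively. Role assignment is invariant to rescaling of betweenness, since
fraction-based cut-offs are rank-based.

The bundled backbone table ships with the value cut-offs DC ≥ 12 and
BC ≥ 0.0344 that were defined on its 230-node parent component. Applying the
rule to the 46 tabulated rows yields 16 date-hubs; the accompanying published
narrative lists 13. The three extra proteins (CTNNB1, CREBBP, PTPN11) clear
both cut-offs by the tabulated values, so the package reports the rule's
output and treats the narrative count as an inconsistency in the source
material, not something to reproduce by special-casing.

## Gene–miRNA bipartite analysis

miRNA identifiers are canonicalised by case-folding, stripping the `hsa-`
prefix, and applying an alias table; the bundled table fixes one obvious
typo family (`leg-7g` → `let-7g`). Arm suffixes (`-3p`/`-5p`) are *not*
merged by default — arms are distinct molecules — though a `merge_arm`
helper is provided for analyses that want mature-sequence-agnostic counting.
Proteins with zero miRNA partners are retained as isolated nodes so that
degree summaries are over the full protein set.

Hubs are defined by strict thresholds: protein hubs have more than 10 miRNA
partners (≥ 11), miRNA hubs more than 12 protein targets (≥ 13). Applied to
the bundled 243-edge table these rules yield 6 protein hubs and 7 miRNA
hubs; the source narrative names CASP3 (10 partners) and miR-23a-3p
(12 targets) as hubs even though they sit exactly at, not above, the stated
thresholds. The package again follows the stated rule and documents the
discrepancy rather than widening thresholds post hoc.

Pathway annotation is case-insensitive set intersection against GMT gene
sets; overlap members are reported sorted so output is order-invariant.

## Synthetic generators

The generators exist to give every analysis a ground truth; they are not
epidemiological simulators.

**Cohorts.** Each disease is an independent Bernoulli per patient at its
specified prevalence, except for planted pairs, which are sampled from the
2×2 joint distribution implied by the two marginals and a target φ:
p₁₁ = pᵢpⱼ + φ·√(pᵢ(1−pᵢ)pⱼ(1−pⱼ)). Pairs whose implied cell probabilities
violate the Fréchet bounds are rejected at specification time
(`InfeasiblePairError`), so infeasible targets fail loudly before any
sampling. A diabetes-type mix is planted through the fifth digit of an
appended 250.xx code. Each patient's codes are spread over one to three
claims with up to five diagnosis slots each, so deduplication logic is
genuinely exercised. The generator does **not** model age- or sex-dependent
prevalence, disease progression, coding noise, or correlated triples — only
pairwise planted structure.

**Planted graphs.** Modules are Erdős–Rényi graphs wired internally and
joined only through connector nodes, each linked to one node in every
module. Connectors therefore lie on every inter-module shortest path and
must dominate betweenness — which is what makes them a usable ground truth
for backbone extraction. Module connectivity is ensured with a random
recursive tree before extra edges are added.

**Bipartite networks.** Edges are independent Bernoulli draws between the
protein and miRNA sides; degrees are Binomial, giving closed-form bands for
statistical tests.

All generators consume a single `numpy.random.default_rng(seed)` stream and
emit byte-identical output for a given seed.

## Numerical and engineering conventions

- Bundled data tables are verified against a SHA-256 manifest at load time;
  tampering raises `FixtureIntegrityError`.
- The pipeline writes a run manifest with SHA-256 digests of every output
  file; re-running with the same seed reproduces identical digests.
- Regression tolerances against bundled tables reflect the tables'
  precision: printed averages were computed before per-row rounding, so
  recomputed means are matched to within one unit in the last printed digit
  (e.g. mean betweenness to ±1e-6), not to machine precision.
- Statistical generator tests use wide bands (≥ 4 standard errors) at fixed
  seeds, so they are deterministic and have negligible false-failure
  probability without being vacuous.

## Limitations

- ICD-9-CM only; no ICD-10 mapping.
- The z-test is asymptotic; for very rare categories (small expected counts)
  an exact test would be preferable and is not implemented.
- φ on truncated 3-digit codes inherits the usual aggregation caveat: a
  3-digit association can differ from its 5-digit constituents.
- The PDN keeps a top fraction of links rather than testing each φ for
  significance; the fraction is a tunable modelling choice, not an inference
  procedure.
- The miRNA alias table covers only the typo families present in the bundled
  data; it is not a general nomenclature resolver.
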