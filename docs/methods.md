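# Methods

## Cohort model and code handling

A cohort is a set of patients who all carry a configurable index disease
(default: the hepatocellular-carcinoma family, `C220` at 4-character level
or `C22` after 3-character rollup). Diagnosis codes are normalized by
uppercasing, whitespace stripping, and dot removal, and are compared as
exact strings; the only hierarchy operation is truncation to the ICD-10
3-character category (`category3`), which is idempotent and never
increases a patient's diagnosis count. No further ICD-10 semantics are
modelled: published analyses of this kind name diseases rather than code
granularities, so both levels are exposed as a configuration knob and the
choice is left to the analyst.

Raw records carry at most 16 diagnosis slots (1 primary + 15 secondary).
Multiple input rows for one patient (long layout) are merged into a single
record; conflicting age or sex across rows is an error rather than a
silent overwrite, since each patient contributes one initial-visit
demographic tuple. Sex is strictly binary at ingestion because all
downstream group comparisons are 2×2. Age maps to exactly one of the bins
≤39, 40–49, 50–59, 60–69, ≥70.

## Statistics

**Prevalence.** Carrier count over stratum size, always with the full
stratum N as denominator (never a diagnosed-subset denominator).
Percentages are rounded half-up to two decimals, the convention of
clinical prevalence tables. The index disease is excluded from every
table: it is carried by all patients, so its prevalence is 1 and its pair
statistics are degenerate.

**Relative risk.** RR = (C_AB·N)/(C_A·C_B), the observed pair prevalence
over the product of marginal prevalences. Significance is the strict
RR > 1.0 used for network construction; no multiple-testing correction is
applied, matching the screening character of the statistic. A Katz-style
log-normal 95% interval (SE ≈ √(1/C_AB + 1/E − 2/N), E the expected pair
count) is computed and stored as an annotation but does not affect
filtering. Pairs with a zero marginal are excluded as undefined rather
than assigned 0 or ∞. Pair counting uses a sparse patient × disease
indicator matrix (C = XᵀX), so a 50,000-patient screen over ~50 diseases
runs in well under a second.

**Group comparisons.** 2×2 carrier-by-group tables are tested two-sided
with a Cochran-style selection rule: Pearson χ² when all four expected
counts are ≥ 5, Yates continuity-corrected χ² when the minimum expected
count is in [1, 5), Fisher's exact test when any expected count is below
1. The rule can be overridden per call. Degenerate tables (a zero margin)
are rejected. Computation is delegated to scipy.stats; the test suite
cross-checks the χ² statistic against the squared two-proportion z
statistic and Fisher's p against direct hypergeometric tail enumeration.

## Network construction

Nodes: diseases with prevalence strictly above `min_prevalence` (default
0.01). Edges: pairs with RR strictly above `rr_threshold` (default 1.0)
and both endpoints retained. Edge weight is the raw co-occurrence count
C_AB — the one quantified notion of link strength in this design — while
RR rides along as an annotation. Isolated nodes passing the prevalence cut
are retained, since node and edge criteria are independent. Raising either
threshold can only shrink the network (tested as a monotonicity property).
Export formats are GEXF 1.2draft (with viz hints: node size ∝ prevalence,
grey level ∝ degree), GraphML, and a delimited edge list; all three
round-trip losslessly through the matching importer. GEXF files are
checked by a structural validator (namespace, version, undirected graph,
node/attribute referential integrity).

## Community detection

Weighted modularity is Q = Σ_c [W_c/m − γ(d_c/2m)²] with W_c the
intra-community edge weight (self-loops once), d_c the community's total
weighted degree (self-loops twice), m the total edge weight, and γ the
resolution (default 1.0, plain modularity). Q is undefined for edgeless
graphs and the code refuses them explicitly.

The optimizer is the greedy two-phase local-move algorithm. Phase 1 sweeps
nodes in a seeded random permutation, re-drawn each sweep, moving each
node to the neighboring community with the largest strictly positive gain
ΔQ; ties go to the lowest community id, making runs fully deterministic
given (graph, seed, γ). Phase 2 collapses communities to super-nodes with
intra-weight as self-loops and recurses. The self-loop convention above
keeps Q invariant across levels, which the implementation asserts by
recomputing Q on the original graph each pass and checking it never
decreases. Isolated nodes get singleton communities and contribute nothing
to Q. Only the final flat partition is reported.

The exhaustive oracle enumerates all set partitions via restricted growth
strings for graphs of ≤ 12 nodes (Bell(12) ≈ 4.2·10⁶), breaking ties by
fewest communities, then lexicographically first canonical labelling. It
dominates the heuristic by construction and is used throughout the tests;
on a fixed suite of 100 Erdős–Rényi graphs (n ∈ [4,10], p = 0.3) the
single-run heuristic attains the exact optimum in 91 cases with a worst
modularity gap of 0.049. Because the algorithm is single-restart by
design, occasional gaps up to ~0.07 occur on other random graph suites;
no restart loop is layered on top.

## Synthetic cohort generator

The generator emulates the structure of an index-disease discharge
cohort: every patient carries the index code; diseases belong either to
latent modules or to an independent background. Per patient and module m,
an activation z_m ~ Bernoulli(π_m) is drawn; module disease j is carried
with probability q1_j if active, q0_j otherwise (q1_j ≥ q0_j), giving
marginal prevalence p_j = π_m q1_j + (1−π_m) q0_j. Module activations are
independent across modules, so cross-module and background RR is exactly
1 — a sharp null — while the within-module RR has the closed form
(π q1_j q1_k + (1−π) q0_j q0_k)/(p_j p_k), implemented as
`expected_pair_rr` and used as the analytic oracle.

Demographic defaults are the age-bin fractions 0.0289/0.1459/0.2947/
0.3526/0.1779 and male fraction 0.7601 of a large North-east Chinese
hepatocellular-carcinoma inpatient cohort; age and sex are sampled
independently of disease status by default (an optional per-age-bin
multiplier on module activation exists for stratified-analysis tests, so
stratification machinery can be exercised under confounding). The
study-scale default configuration (`default_config`) plants five modules
echoing the canonical comorbidity patterns of this disease — cirrhosis
and viral-hepatitis complications, benign cysts/stones, metabolic
derangements with gastrointestinal bleeding, age-related chronic disease,
and second cancers — plus 18 independent background diagnoses, spanning
marginal prevalences from 0.5% to ~58% across 46 comorbid codes at
N = 14,891. Patients exceeding the 15-comorbidity slot limit are truncated
by dropping their rarest codes (logged and recorded in the ground truth);
at default rates this is rare. Same configuration and seed yield a
byte-identical cohort.

What the generator deliberately does not model: correlated module
activations, disease-onset order or causality, visit sequences, coding
error, or any confounding of disease with demographics by default.
Passing tests therefore demonstrate that the pipeline recovers structure
of this planted-partition form at realistic sizes and rates; they do not
certify behaviour under real-EHR pathologies such as miscoding or
admission bias.

## Validation design and problem sizes

Every pipeline stage is checked against an independent oracle: per-patient
brute-force recounts for prevalence and pair counting (100-patient random
cohorts), printed-table arithmetic for percentage and p-value formatting
(cohorts materialized so that carrier counts equal published marginal
counts exactly), hand-evaluated closed forms for modularity (0, 5/14,
−1/3 benchmarks), the exhaustive partition oracle for the heuristic, and
the generative closed forms for the synthetic pipeline. Module-recovery
experiments use 3 modules × 5 diseases (π=0.3, q1=0.8, q0=0.05) at
N = 5,000 over 20 replicates (ARI ≥ 0.9 expected in ≥ 19), convergence
checks use N = 50,000 (empirical RR within ±0.1 of 2.562; null mean RR
within 1 ± 0.05). These sizes give tight Monte-Carlo tolerances while the
full suite completes in well under a minute.

## Numerical conventions

Ratios are computed in double precision from integer counts, so RR and
prevalence identities hold to ~1e-15. Percentage rounding is half-up (not
banker's). Modularity assertions use 1e-12 tolerances; the Louvain gain
comparison uses a 1e-15 guard so exact ties never cause seed-dependent
oscillation. Empty cohorts flow through all statistics as empty tables;
empty networks are legal, and community detection on them raises the
explicit undefined-modularity error rather than returning a vacuous
partition.
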