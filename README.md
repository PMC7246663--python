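# comorbnet

Comorbidity-network analysis for index-disease cohorts.

Hospital discharge records describe each patient as one primary plus up to
15 secondary ICD-10 diagnoses. For a cohort defined by an *index disease*
(the package ships configured for hepatocellular carcinoma, ICD-10 C22.0),
`comorbnet` turns such records into:

1. **stratified prevalence statistics** — carrier counts and percentages per
   disease, by sex and by age bin (≤39, 40–49, 50–59, 60–69, ≥70), with
   two-sided 2×2 group comparisons (Pearson χ², Yates-corrected χ², or
   Fisher's exact test, selected by the Cochran expected-count rule);
2. **pairwise co-occurrence screening** — for diseases A and B with carrier
   counts C_A, C_B in a cohort of N patients and C_AB patients carrying
   both, the observed/expected relative risk

       RR(A,B) = (C_AB / N) / (p_A · p_B) = (C_AB · N) / (C_A · C_B),

   with a pair called significant when RR > 1 strictly;
3. **a thresholded comorbidity network** — nodes are diseases with
   prevalence > 1%, edges are pairs with RR > 1, edge weight is the raw
   co-occurrence count C_AB; exported as Gephi-ready GEXF 1.2, GraphML, or
   a plain edge list;
4. **comorbidity modules** — weighted-modularity community detection with a
   seeded, deterministic implementation of the two-phase Blondel/Louvain
   algorithm (resolution γ exposed, default 1.0), plus an exhaustive
   set-partition oracle for graphs of ≤12 nodes used to validate it.

Because patient-level hospital extracts of this kind are not publicly
deposited, the package includes a first-class **synthetic cohort
generator**: a planted-partition model over binary disease indicators in
which latent module activations (Bernoulli π) raise member-disease rates
from q0 to q1. Every statistic of that model has a closed form — e.g. a
within-module pair with π=0.3, q1=0.8, q0=0.05 has RR ≈ 2.562 — so the
whole pipeline is testable against analytic ground truth, including module
recovery measured by the adjusted Rand index.

## Worked example

```sh
python examples/03_network_and_modules.py
```

simulates 5,000 patients from a configuration with three planted modules of
five diseases each (π=0.3, q1=0.8, q0=0.05), builds the thresholded
network, and detects modules:

```
network: 15 nodes, 77 edges

Louvain: 3 modules, Q = 0.2796
  module 1 (5 nodes): D03, D01, D00, D04, D02
  module 2 (5 nodes): D13, D10, D11, D12, D14
  module 3 (5 nodes): D24, D20, D21, D23, D22

adjusted Rand index vs planted modules: 1.000  (1 = exact recovery)
```

All 15 diseases pass the 1% prevalence cut; within-module relative risks
(~2.6) put 30 true edges in the network alongside noise edges near RR ≈ 1,
and Louvain at γ=1 recovers the planted three-way partition exactly
(ARI = 1) with modularity Q = 0.28. `examples/01_simulate_cohort.py` shows
the study-scale default cohort (14,891 patients, five modules, ~46
diseases) and `examples/02_relative_risk_screen.py` compares empirical
pairwise RR against the closed forms (within-module mean 2.575 vs analytic
2.562 at N = 20,000; cross-module mean 1.004 against a null of 1).

The same pipeline is scriptable from a shell:

```sh
comorbnet simulate --n 5000 --seed 7 --out cohort.csv
comorbnet run --records cohort.csv --out-dir results/
```

which writes demographics, stratified prevalence tables with p-values,
pair statistics, the GEXF/GraphML/edge-list network, the partition and
module report, and a JSON manifest recording configuration and seed.

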