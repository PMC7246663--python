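"""Screen disease pairs for co-occurrence above independence.

Runs the pairwise relative-risk statistic RR = (C_AB * N) / (C_A * C_B)
on a small planted-module cohort and compares the empirical values with
the generator's closed-form expectations: within-module pairs should sit
near the analytic RR (~2.56 here), cross-module pairs near 1.
"""

from comorbnet import (
    expected_pair_rr,
    generate_cohort,
    pair_counts,
    prevalence_table,
    recovery_config,
    relative_risk,
)

cfg = recovery_config(n=20_000)  # 3 modules x 5 diseases, pi=0.3, q1=0.8, q0=0.05
cohort, _ = generate_cohort(cfg, seed=11)

prev = prevalence_table(cohort)
rr = relative_risk(pair_counts(cohort), prev)

same = rr[rr.disease_a.str[1] == rr.disease_b.str[1]]
cross = rr[rr.disease_a.str[1] != rr.disease_b.str[1]]

print(f"N = {cohort.n}; {len(rr)} co-occurring pairs "
      f"({same.shape[0]} within-module, {cross.shape[0]} cross-module)")
print(f"analytic within-module RR: {expected_pair_rr(cfg, 'D00', 'D01'):.4f}")
print(f"empirical within-module RR: mean {same.rr.mean():.4f}")
print(f"empirical cross-module RR:  mean {cross.rr.mean():.4f} (null = 1)")

print("\nStrongest five pairs:")
cols = ["disease_a", "disease_b", "co_count", "rr", "significant"]
print(rr.sort_values("rr", ascending=False).head(5)[cols].to_string(index=False))

# Within-module pairs cluster tightly around the closed form while
# cross-module pairs fluctuate around RR = 1: the statistic separates
# planted structure from sampling noise at this cohort size.
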