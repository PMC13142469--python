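"""Benchmark genome-wide ancestry proportions against a reference.

Prints the agreement statistics (Pearson R, OLS slope beta, mean absolute
difference Delta) and reruns the engine with down-sampled hunter-gatherer
source panels, mirroring the source-size optimization.
"""

import laibench as lb

cohort = lb.simulate_cohort(lb.SimulationConfig(n_admixed=30, seed=13))
truth = lb.global_proportions(cohort.truth_calls)

calls = lb.call_hmm(
    cohort.panel,
    cohort.admixed,
    lb.estimate_frequencies(cohort.source_hg),
    lb.estimate_frequencies(cohort.source_farmer),
)
st = lb.compare_to_reference(lb.global_proportions(calls), truth)
print(f"48v7 sources: R={st.r:.3f} beta={st.beta:.3f} Delta={st.delta:.3f}")
print("(Delta is the mean per-individual error; the upward bias comes from the")
print(" unbalanced source panels favouring the better-sampled HG ancestry)")

table = lb.subsample_experiment(cohort, hg_sizes=[48, 7, 3], seeds=[0, 1, 2])
print(table.groupby("hg_size")[["r", "beta", "delta"]].mean().round(3))
best = lb.select_optimal(table)
print(f"recommended HG source size: {int(best['hg_size'])} "
      f"(min Delta {best['delta']:.3f})")
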