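"""Quantify agreement between ancestry-call tracks in genomic bins.

Correlates binned hunter-gatherer ancestry between the two engines and the
truth, at the population level and per individual.
"""

import laibench as lb

cohort = lb.simulate_cohort(lb.SimulationConfig(n_admixed=15, seed=19))
tracks = {
    "truth": cohort.truth_calls,
    "hmm": lb.call_hmm(
        cohort.panel,
        cohort.admixed,
        lb.estimate_frequencies(cohort.source_hg),
        lb.estimate_frequencies(cohort.source_farmer),
    ),
    "mismatch": lb.call_mismatch(
        cohort.panel,
        cohort.admixed,
        cohort.source_hg,
        cohort.source_farmer,
        lb.MismatchConfig(span_bp=10_000_000, step_bp=5_000_000, min_sites=10),
    ),
}

for width in (100_000, 1_000_000):
    mat = lb.pairwise_population_correlation(tracks, cohort.panel, width)
    print(f"population-level Pearson matrix at {width // 1000} kb bins:")
    print(mat.round(3).to_string())

ind = lb.individual_level_correlation(tracks, cohort.panel, 1_000_000)
print(f"individual-level mean correlation (1 Mb bins): "
      f"{ind.mean():.3f} (range {ind.min():.3f}-{ind.max():.3f})")
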