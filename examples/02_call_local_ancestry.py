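"""Call local ancestry with both in-repo engines and post-process the calls.

The two-state HMM decodes each haplotype against source allele frequencies;
the mismatch caller assigns each window to the source panel holding the
closest haplotype.  Posterior filtering (> 0.9) then trades coverage for
accuracy, and unkinking repairs phase-switch artifacts.
"""

import numpy as np

import laibench as lb

cohort = lb.simulate_cohort(lb.SimulationConfig(n_admixed=20, phase_switch_rate=0.02, seed=11))
truth = cohort.truth_calls.labels

fh = lb.estimate_frequencies(cohort.source_hg)
ff = lb.estimate_frequencies(cohort.source_farmer)
hmm = lb.call_hmm(cohort.panel, cohort.admixed, fh, ff)
mism = lb.call_mismatch(
    cohort.panel, cohort.admixed, cohort.source_hg, cohort.source_farmer,
    lb.MismatchConfig(span_bp=10_000_000, step_bp=5_000_000, min_sites=10),
)

for calls in (hmm, mism):
    acc = np.mean(calls.labels == truth)
    print(f"{calls.method:9s} per-site accuracy vs truth: {acc:.3f}")

filtered = lb.apply_posterior_filter(hmm, 0.9)
kept = np.mean(filtered.labels != -1)
ok = filtered.labels != -1
acc = np.mean(filtered.labels[ok] == truth[ok])
print(f"hmm after posterior>0.9: accuracy {acc:.3f} on {kept:.0%} of calls")

unkinked = lb.unkink(hmm)
print(f"switch count {lb.count_switches(hmm, cohort.panel)} -> "
      f"{lb.count_switches(unkinked, cohort.panel)} after unkinking "
      f"(truth {lb.count_switches(cohort.truth_calls, cohort.panel)})")
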