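# laibench

Local-ancestry benchmarking for two-way admixed cohorts: simulation of
single-pulse admixed haplotypes with ancient-DNA-style noise, in-repo
local-ancestry callers, global/local ancestry benchmarking, tract-length
admixture dating, and a covariance-corrected sliding-window scan for loci
with deviant ancestry.

The motivating setting is Neolithic Europe: admixed genomes carrying ~20%
Western hunter-gatherer (HG) ancestry on a farmer background, with small and
unbalanced source panels (say 48 HG vs 7 farmers), imperfect phasing, and
low-coverage (pseudohaploid) replication data.  Every stage works from a
single currency — per-haplotype, per-SNP ancestry calls — so externally
produced call tracks (RFMix-style msp tables) drop into the same benchmarks
as the in-repo engines.

## The model in brief

A single admixture pulse `T` generations ago leaving a fraction `p` of the
focal ancestry makes ancestry along a haplotype a two-state Markov process in
genetic distance: tract lengths of ancestry `a` (proportion `p_a`) are
exponential with rate

    lambda = T (1 - p_a) / 100   per cM,

so `P_bin = exp(-lambda b_start) - exp(-lambda b_end)` gives the expected
tract-length distribution and a censored/truncated exponential likelihood
recovers `T` from observed tracts.  For the selection scan, each method's
per-SNP population mean HG ancestry is standardized in 51-SNP sliding
windows, and method Z tracks are combined accounting for their correlation:

    Z_combined = sum_i Z_i / sqrt(1' Sigma 1),

with `Sigma` the genome-wide covariance matrix of the method tracks.
Discovery requires `|Z| > 3`; replication requires a matching-sign window
with `|Z| >= 2.84` within 2 Mb of the discovery lead SNP.  See
`docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

Simulate a cohort with two injected ancestry deviations (+0.15 and -0.15),
call ancestry with both engines, scan, and replicate in an independent
cohort:

```bash
python examples/06_deviation_scan.py
```

```
candidate regions (|combined Z| > 3):
  chrom  lead_pos  lead_z    p  sign  replicated  best_replication_z
0     2  31344135   4.737  0.0     1        True               4.636
1     4  31232524  -4.926  0.0    -1        True              -3.829
injected loci (+0.15 on chr2 @31 cM, -0.15 on chr4 @31 cM) both recovered: True
spurious regions: 0; both replicated in the independent cohort: True
```

Both injected loci are discovered at the right position with the right sign
(positive Z = excess hunter-gatherer ancestry), no spurious region appears,
and both replicate in a second, independently simulated cohort.  Dating the
pulse from tract lengths (`examples/04_tract_dating.py`):

```
theory: lambda = 0.28 per cM at T=35, p=0.2
fitted T = 36.3 generations (95% CI 34.0-38.7) from 975 tracts >= 10 cM
```

The other examples cover simulation (`01`), calling and rephasing (`02`),
global-ancestry benchmarking and source-size optimization (`03`), and
binned concordance between call tracks (`05`).  Each prints the numbers it
computes and a line on what they mean.

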