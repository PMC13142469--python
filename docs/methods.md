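# Methods

`laibench` studies how well local-ancestry inference (LAI) works in a
two-way admixed cohort — the motivating case is Neolithic Europeans carrying
a ~20% minority of Western hunter-gatherer (HG) ancestry on an Anatolian
farmer background — and what downstream analyses built on LAI calls can and
cannot detect: genome-wide ancestry proportions, tract-length dating of the
admixture pulse, and a genome scan for loci whose local ancestry deviates
from the genome-wide average.

## The admixture model

Ancestry along a haplotype is modelled as a two-state Markov jump process in
genetic distance.  After a single admixture pulse `T` generations ago that
left a fraction `p` of the focal ancestry, the process leaves ancestry `a`
(genome-wide proportion `p_a`) at rate

    lambda_a = T * (1 - p_a) / 100   per cM,

so tract lengths of ancestry `a` are exponential with rate `lambda_a` and
the stationary HG fraction is exactly `p`.  The `/100` converts Morgans to
centimorgans.  This is the stationary approximation to a `T`-generation
pedigree: it is exact in the large-`T`, random-mating limit and realizes the
same tract-length law the dating model assumes, which keeps the simulator
closed-form testable.  The probability that a tract falls in a length bin is

    P_bin = exp(-lambda * b_start) - exp(-lambda * b_end),

and bins partitioning `[0, inf)` sum to one.

Source divergence follows a Balding–Nichols model: each site draws an
ancestral frequency `f ~ Uniform(0.05, 0.95)` and two population frequencies
`Beta(f(1-F)/F, (1-f)(1-F)/F)` with `F` the target F_ST (default 0.1, a
realistic figure for strongly drifted prehistoric populations).  The uniform
support avoids near-fixed sites that make the Beta degenerate and mimics a
MAF-filtered panel.  Source panels and admixed haplotypes draw alleles
independently from their population's (tract-conditional) frequencies.

**What the generator does not emulate.**  There is no linkage disequilibrium
within source populations and no identity-by-descent between an admixed
tract and any specific source haplotype.  Haplotype-copying callers (random
forest or Li–Stephens types) derive most of their power from exactly that
sharing, so the in-repo minimum-mismatch caller is systematically weaker
here than its real-data counterpart (per-site accuracy ~0.6 at F_ST = 0.1 on
the default sparse panels, versus ~0.8 for the frequency-based HMM there and
~0.99 at the scan study's 160 SNP/cM density with balanced sources — the HMM
loses nothing under this emission model).  Passing benchmarks therefore certify the *pipeline
machinery* — window bookkeeping, standardization, covariance correction,
censored-likelihood fitting — not real-data caller accuracy.  Genotype
error, phase-switch error and pseudohaploid sampling are modelled as
independent per-site/ per-point processes, a simplification of real
ancient-DNA damage.

**Selection injection.**  A deviation `delta` at a locus is realized by
interval conversion: each haplotype independently converts to the target
ancestry with probability `|delta|/(1-p)` (or `|delta|/p` for negative
`delta`) over an interval whose half-width is `Uniform(0, radius)`.
Marginally this gives local ancestry `p + delta` at the locus with an exactly
linear taper to `p` at the radius — precise control of the effect size a
scan must recover, at the cost of not modelling the haplotype structure a
real sweep would leave.

## The callers

*Two-state HMM.*  Per haplotype, hidden states {farmer, HG} with prior
`(1-p, p)`; transition over a gap of `d` cM leaves ancestry `a` with
probability `1 - exp(-T (1-p_a) d / 100)`, the same rate structure as the
tract model, so calling and dating are mutually consistent.  Emissions are
Bernoulli in the source allele frequency (clamped to `[1e-3, 1-1e-3]`);
read-count mode shifts frequencies by the error rate, with one pseudohaploid
allele treated as a single read.  Posterior decoding is exact
forward–backward; on chains short enough to enumerate, posteriors match
brute-force path summation to 1e-9.  An effective-population-size parameter
is accepted for interface parity with the established read-count HMM tool
but is inert: a per-haplotype two-state chain has no drift term.

*Minimum-mismatch windows.*  For each sliding window (default 1 Mb span,
0.5 Mb step) and haplotype, the mismatch fraction over pairwise non-missing
sites is minimized over every HG and every farmer source haplotype; the
window takes the ancestry of the smaller minimum, exact ties going to the
majority (farmer) ancestry and counted.  Mismatch *fraction* rather than raw
count keeps missing data from favouring sparser sources.  SNPs inherit the
nearest window center's label; the pseudo-posterior `worse/(best+worse)` is
a margin, clipped to `[0.5, 1]`, not a calibrated probability — which is why
posterior filtering defaults are applied to the HMM track only.  The
mismatch-ratio threshold carried in the configuration is reported as an
ambiguity diagnostic and does not veto calls.

*Post-processing.*  External path-code tracks are recoded onto the two
sources ({3, 4} → HG, {1, 2, 5, 6} → farmer); population mean-ancestry
tracks can be re-centred per chromosome (after which every chromosome mean
equals the genome mean to 1e-12); unkinking swaps haplotype label
assignments downstream of simultaneous opposite switches, which provably
never increases the switch count; male X haplotypes are de-duplicated after
calling on pseudo-diploid encodings.

## Tract-length dating

Tracts are maximal same-label runs; missing runs of at most 2 SNPs flanked
by the same label are bridged by default, because posterior filtering would
otherwise shatter tracts (both behaviours are exposed).  Tracts shorter than
10 cM are excluded from fitting — short fragments are dominated by phasing
and genotype noise.  Uncensored tracts follow a doubly truncated exponential
on `[10, L]` cM (`L` the chromosome length); tracts touching a chromosome
end contribute survival terms `exp(-lambda (l - 10))`.  The likelihood is
maximized in `T in [1, 500]` by root-finding the analytic score (the
numerical-noise floor of a generic scalar optimizer is ~1e-6 in `T`; the
score root is machine-precision), with a profile-likelihood 95% CI at the
chi-square(1) cutoff.  Data sets where every tract is censored push the
estimate to the lower bound and raise a warning rather than an error — the
signature of callers that emit near-full-chromosome tracts.

## The deviation scan

Per method: per-SNP population mean HG ancestry (SNPs under 50% call rate
are dropped), averaged in 51-SNP windows at step 1; `Z` subtracts the
genome-wide mean of per-SNP means and divides by the SD of the window
statistic over all unmasked windows.  The published wording of the
denominator is ambiguous (per-SNP SD versus SD of window means); the window
statistic's SD is the default because it makes the null track self-normalized
(SD = 1 by construction), matching the tabulated Z-to-p arithmetic; the
per-SNP variant sits behind a flag.  Windows overlapping a mask (long-range
LD intervals, or unmappable regions grown by 2.5 Mb flanks), crossing a
chromosome end, or with over 20% missing SNPs are masked.

Method tracks combine as `Z_comb = sum_i Z_i / sqrt(1' Sigma 1)` with
`Sigma` the covariance of the method Z tracks over jointly unmasked windows
(correlation optional), eigenvalue-floored to positive semidefinite if
needed.  With `Sigma = I` this is Stouffer's method; with perfectly
correlated tracks it reduces to a single track.  Because the SD denominator
is estimated on the same windows, injected signal inflates it slightly —
a conservative property that suppresses false positives at the price of a
mild power loss.

Discovery: windows with `|Z| > 3`, merged when lead SNPs fall within 1 Mb
(well inside the 2 Mb replication radius, so merging cannot create
replication ambiguity); the region lead is the max-|Z| window and positive Z
means excess HG ancestry.  Replication: a matching-sign window with
`|Z| >= 2.84` within 2 Mb of the discovery lead.  The 2.84 constant is the
published Bonferroni threshold for p = 0.05/10 and is honoured verbatim even
though the normal quantile gives 2.81 (two-sided) or 2.58 (one-sided); the
formula-derived path is available via `p_to_z_threshold`, which also
reproduces the one-sided X-chromosome threshold 0.05/2 → 1.96.  Discovery
p-values are two-sided by default, matching the tabulated Z/p pairs.

The low-ancestry diagnostic recomputes each region's deviation in the subset
of individuals below 10% reference ancestry, who are nearly unaffected by
selection on the minor ancestry: a region is selection-consistent when the
subset deviation is under half the full-cohort deviation (ratio
configurable), and misclassification-suspect otherwise.

## Study sizes and numerical choices

Benchmarks run at desk scale, chosen once as the package's own conditions:

- *Tract recovery*: 200 haplotypes x 35 chromosomes x 150 cM at T=35,
  p=0.2; fit from HG tracts >= 10 cM.  Recovery lands in [30, 40]
  generations in >=90% of 50 seeds (the estimator is ~1 generation
  conservative because interior-tract truncation is not modelled).
- *Scan power*: 150 diploids, 5 chromosomes x 10,000 SNPs x 62 cM (matching
  the ~160 SNP/cM density of the motivating 572k-SNP panel), deviations
  +/-0.15 with a 5 cM taper radius, balanced 48v48 source panels so scan
  behaviour is measured apart from source-imbalance bias (studied
  separately); discovery and replication cohorts are independent
  simulations.
- *Null calibration*: same geometry, no selection, 100 diploids.
- *Source imbalance*: 30 diploids, 3 chromosomes x 3,000 SNPs, engines run
  with 48v7 and 7v7 panels on identical seeds.

Ancestry labels are int8 (0 farmer, 1 HG, -1 missing); all proportions are
HG fractions.  MAF/INFO/posterior thresholds are strict `>`.  Site
coordinates are 1-based inclusive (VCF); masks half-open 0-based (BED).
Genetic positions missing from a map are interpolated linearly and
extrapolated at the chromosome's mean rate.  Forward–backward runs in
float64 with per-site normalization (posterior pairs sum to 1 exactly);
large cohorts may request float32 output storage.

## Limitations

- No LD or IBD in the source model (above); copying-based callers cannot be
  benchmarked for accuracy here, only ingested as external tracks.
- The simulator's X chromosome is the autosomal machinery with ploidy-1
  males; no sex-specific recombination map.
- The single-pulse likelihood ignores interior-tract truncation by
  chromosome ends (censored tracts carry survival terms, uncensored tracts
  the truncated density); at 150 cM chromosomes and T near 35 the resulting
  bias is about one generation, visible but harmless at the benchmark
  tolerances.
- Window-level mismatch calling quantizes tract boundaries to the window
  grid; boundary SNPs within one window span of a true switch may be
  mislabelled even in the separable-sources limit.
- Selection injection resamples every haplotype at the locus, independent of
  the individual's genome-wide ancestry.  The low-ancestry diagnostic's
  premise — that individuals carrying little of the minor ancestry are
  nearly unaffected by selection on it — therefore does not hold for
  *injected* deviations, which the diagnostic deliberately flags as
  misclassification-like; its unit tests use constructed tracks with the
  premise built in.
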