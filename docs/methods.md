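# Methods

## Experimental model

The package models a targeted deep-sequencing experiment on sorted
peripheral-blood mononuclear cells. Each patient contributes one DNA
sample per subpopulation (CD4+, CD8+, CD19+ and the triple-negative
"others"); all samples are sequenced over one shared target region.
Three kinds of signal coexist in the reads:

* **sequencing/PCR noise** — independent substitutions at per-base rate
  *e* (default 1e-4, the practical quality ceiling of the platform),
  uniform over the three non-reference bases (*e*/3 each);
* **germline variants** — heterozygous sites (AF 0.5) shared by *all*
  subpopulations of a patient, placed at rate 1e-3 per base (a realistic
  human heterozygosity for exonic targets);
* **somatic clones** — a cell clone of fraction *c* carrying a
  heterozygous mutation contributes alt reads at AF *c*/2; clones are
  specified directly in AF units, confined to one subpopulation, with
  AF ≤ 0.5 by construction.

A somatic clone is therefore distinguishable from noise by its
read-count excess over the binomial error model, and from germline
variation by its absence from the patient's other subpopulations.

## Simulators

**Read-level** (`simulate_patient_cohort`). Fragments are placed
uniformly in the region with normal lengths (default mean 180 bp,
SD 40 bp, truncated to [read length, region length]); each fragment
yields an FR pair of 100 bp mates, so fragments shorter than 200 bp have
overlapping mates. Substitution errors are drawn **on the fragment
template**: both mates read the same template, so an error inside the
overlap appears on both. This choice is what makes the double-counting
artifact reproducible — errors independent per mate would never be
counted twice, and mate consensus would remove essentially all of them.
It also reflects the physics: at these rates, template/PCR errors
propagated to both reads dominate the artifact, while uncorrelated
base-calling noise averages out. Coordinate-duplicate fragments
(PCR duplicates) are generated at a configurable rate and removed by
`dedup_fragments` (smallest fragment id wins).

Variant sites are placed at least one read length away from the region
edges (when the region is long enough): fragments are drawn wholly
inside the finite region, so its outermost bases are covered almost
exclusively by one mate orientation; a variant there would fail the
strand-bias filter for purely geometric reasons. Real capture targets
sit interior to the fragmented library, so this restriction matches the
experiment rather than avoiding a difficulty.

**Count-level** (`simulate_pileup_cohort`). Draws per-site allele
× strand counts directly: depth ~ Poisson(mean), variant reads ~
Binomial(depth, AF), remaining reads mismatch with probability *e*, and
every count splits Binomial(·, ½) between strands. Each template is
counted once, so these pileups correspond to consensus (`COUNT_ONCE`)
counting. This path runs 10 kb × 12 samples × 1000× in tens of
milliseconds and powers the calibration and power studies; the
read-level path is used wherever the mate-overlap mechanism itself is
under study.

**Amplicons** (`simulate_amplicon`) use the same count-level model at a
single site (default depth 100,000×), always paired with a variant-free
donor-control amplicon. **Follow-up** (`simulate_followup`) multiplies
each somatic clone's AF by a positive drift factor (fixed, per-clone, or
log-normal with median 1) and clamps to [0, 0.5]; germline records are
untouched.

What the generators do *not* emulate: alignment and mapping error,
base-quality variation, GC/coverage bias, indels, contamination between
samples of the *same* patient, and real linkage between sites. Passing
tests therefore demonstrate the statistical machinery under the stated
error model, not robustness to artefacts outside it.

## Counting policies

`COUNT_BOTH` counts every mate base at every covered site — up to two
observations per fragment at overlapped sites. `COUNT_ONCE` keeps exactly
one observation per fragment at sites covered by both mates: the shared
base when the mates agree, nothing when they disagree (the conservative
reading — an error seen on one mate only is suppressed, while a true
variant on a non-overlapping read still counts). The surviving consensus
observation has no natural strand; it is assigned +/− by fragment-id
parity, a deterministic, strand-balanced rule that keeps the strand-bias
statistics meaningful. Depth under `COUNT_ONCE` is ≤ depth under
`COUNT_BOTH` at every site, with equality exactly where no mates overlap.

## The screen

Parameters (all in `ScreenConfig`, defaults in brackets):

* `min_alt_reads` [3] — minimum alt evidence before any testing; the
  lowest AF the screen is expected to find (~0.5% at 1000×) corresponds
  to ~5 reads, so the floor only removes singleton noise.
* `binomial_alpha` [0.05] — cutoff on the Bonferroni-corrected binomial
  p-value. The correction factor is region length × 4, one test per
  possible base per site.
* `germline_af_threshold` [0.05] — separates the somatic AF regime
  (≤ ~5%) from germline hets; used for error-rate site exclusion, the
  cross-patient contamination filter, and the control-germline
  classification.
* `strand_min_per_strand` [1] and `strand_bias_p` [0.001] — strand-bias
  filter: alt evidence required on both strands, two-sided Fisher test
  of alt vs ref strand ratios must not reject at 0.001.
* `fdr_q` [0.05] — Benjamini–Hochberg cutoff, applied once, globally,
  over all samples' surviving candidates.
* `error_rate_floor` [1e-6] — floor on the estimated error rate so a
  mismatch-free small dataset does not yield degenerate p = 0 nulls.

The error rate is estimated from the data being screened: pooled
non-reference fraction over all samples, excluding sites where any
sample's non-reference AF reaches the germline threshold. The somatic
Fisher test is one-sided (target enriched) by default — the
tumor-vs-normal semantics of the design; a two-sided variant is
available by flag. Candidates whose *merged control* already carries the
allele at germline-like AF are classified germline and never reach the
FDR stage: a target-vs-control contrast can reject noise, but a het site
is non-somatic by definition regardless of a lucky enrichment
fluctuation.

Numerical notes: the binomial tail is the regularised-beta survival
function; the one-sided Fisher p is the hypergeometric survival function
at fixed margins (vectorisable, and exactly the classical test); both are
verified against exact rational-arithmetic enumeration to 1e-10 relative
error in the test suite. BH q-values use the monotone cumulative-minimum
adjustment. Zero depth on either side of a contrast returns p = 1 with a
warning rather than an error.

## Validation

`validate_candidate` reads the threshold "p ≤ 0.001 Bonferroni-corrected
by the number of verifications" as α = 0.001/n_verifications — the only
reading that uses both numbers; `bonferroni=False` gives the plain 0.001.
The control is a separate donor DNA amplicon, not the patient's other
subpopulations. The strand-bias check reuses the screen's filter with the
same defaults. The validated AF is reported as a percentage rounded to
two decimals, the convention of the validated-mutation table shipped as
a fixture. A zero-depth amplicon is an assay failure, reported as such
and never counted as a refutation.

## Summary layer

Clone size = 2 × AF (heterozygous model), capped at 100%; AF > 50% is
rejected as non-clonal. The cohort maximum clone size doubles the
1-decimal-rounded maximum AF (4.63% → 4.6% → 9.2%), matching the
convention of the source cohort. CADD scaled ≥ 20 flags a mutation
predictably deleterious; FPKM ≥ 1 flags the gene expressed; missing
annotations stay NA rather than being guessed. Persistence trends use a
configurable stable band (|fold − 1| ≤ 0.05 by default; the source data
report one mutation "at the same level" without a tolerance, so the band
is explicit and adjustable); a follow-up with zero alt evidence is LOST.
The Vβ large-clone rule flags a type seen in ≥ 10% of cells *and* at
more than twice the population-control frequency.

The packaged fixture stores the 27 validated mutations of a 20-patient
cohort with their published novelty flags; the recomputed novel
percentage (70.4%) differs from the figure printed alongside the original
table (67%), a discrepancy the package reports as recomputed rather than
resolves.

## Problem sizes in the shipped studies

The acceptance studies run at the experiment's stated operating point
but at economical scale: FDR calibration on 50 (tests) / 20 (script)
clone-free cohorts of 4 patients × 3 subpopulations, 10 kb at 1000×;
power on 50 replicates of a 2% clone in a 2 kb region; overlap-artifact
runs on a 1.5 kb region at 1200× with 110 ± 10 bp fragments (≈ 90%
mate overlap); amplicon studies at 100,000×. These sizes give the
binomial standard errors quoted in the tests while keeping the whole
suite fast.

## Known limitations

* Substitutions only: the statistical machinery is exercised on SNVs;
  in-frame deletions seen in real data of this design are out of scope.
* The error spectrum is uniform; real platforms have context-dependent
  error (e.g. oxidative artefacts) that the strand-bias filter only
  partially captures.
* `COUNT_ONCE`'s discard-on-disagreement rule is one of several
  defensible consensus rules; taking the higher-quality mate would trade
  specificity for sensitivity.
* The contamination filter needs at least one other patient in the
  batch; single-patient runs skip it vacuously.
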