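# Methods

## Setting and model

The analysis targets cohorts hemizygous for one contiguous chromosomal
region (default `chr22:18,400,394–22,600,038`, the 22q11.2 deletion
interval plus flanks, hg19). Because each sample carries exactly one
allele of the region, genotype collapses to a carrier indicator: the
remaining allele either bears the alternate allele or it does not.
All association tests are therefore two-sided Fisher exact tests on
2×2 tables of carrier status × diagnostic group, and effect sizes are
odds ratios of carriage.

The two-sided p-value uses the classical probability ordering: with
margins fixed, it sums hypergeometric probabilities of all tables no
more probable than the observed one, with a relative tie tolerance of
1e-7 (the convention of R's `fisher.test`, which keeps probabilities
equal up to floating-point noise on the same side). Because group sizes
are constant across the thousands of units tested, p-values come from a
precomputed `(n_case+1) × (n_control+1)` lookup table; the tests verify
this table against exhaustive enumeration from exact binomial
coefficients for every margin pair up to 60, and against
`scipy.stats.fisher_exact`. The odds-ratio point estimate is
`(a·d)/(b·c)`, with 0.5 added to every cell only when some cell is zero
(Haldane–Anscombe correction); it never affects the p-value.

Family-wise error is controlled by Bonferroni at `α/m` within each
family (variants; genes; each window size separately). Thresholds are
reported both exactly and rounded to the nearest power of ten, the form
in which such thresholds are conventionally printed (0.05/4,176 → 10⁻⁵;
0.05/73 → 10⁻³). A Benjamini–Hochberg adjusted p-value is emitted as a
side column for reference but never drives the significance flag.
Whether the three window sizes should instead form one joint family is
ambiguous; per-size correction is implemented and the choice is visible
in the output (each size carries its own threshold).

## Retention filters

A call enters the analysis iff (all bounds inclusive):

* caller quality ≥ 50 (SNVs) or ≥ 600 (indels), dispatched on the
  `CALLER` INFO key, falling back to allele-length inference when the
  key is absent (single-base ref and alt ⇒ SNV);
* population (public-database) allele frequency ≤ 0.30. Calls with no
  annotation are **retained** — novel variants are precisely the
  hypothesis class of a recessive-unmasking study;
* at least 2 carriers among all samples (dataset singletons excluded).

Multi-allelic records are split per alt allele with disjoint carrier
attribution. Diploid-coded genotypes in the hemizygous region ("1/1",
"0/1", as emitted by callers run in default diploid mode) count as
carriers; "./." and "0"-genotypes do not. Filtering is idempotent,
order-independent and monotone in each threshold; the filter stage
writes a per-variant audit table recording every pass/fail.

## Annotation

Gene models (exon and CDS intervals, 1-based inclusive) come from GFF3.
Per (variant, gene): *coding* if the position lies in a CDS interval
(synonymous status is not resolvable without transcript sequence, so all
CDS hits count; the qualifying class set is a parameter); else
*splice_site* if within 6 nt of an internal exon boundary on the
intronic side (donor and acceptor ends; transcript start/end are not
splice sites); else *other*. The definition is strand-symmetric. Indels
classify by their leftmost affected base (VCF left-alignment). The
classifier is verified base-by-base against a brute-force set-membership
oracle on toy genes.

## Coverage-based CNV test

Per sample, coverage is normalised per nucleotide as reads overlapping
the base divided by the sample's total read count, which removes
library-size differences (the statistic is invariant to rescaling any
sample's depths and total jointly). Feeding a Fisher test requires
dichotomising this continuous value; the procedure is a reconstruction
(flagged as such in outputs) and fully parameterised:

* reference level at each base = median normalised coverage over a
  reference sample set. The pipeline uses the **controls** as the
  reference: a CNV carried by a large fraction of cases would otherwise
  contaminate a pooled median (with 40/88 samples aberrant the pooled
  median sits between the two coverage states and detection collapses).
  Under the null the groups are exchangeable, so the choice does not
  inflate type I error — confirmed empirically by the null-calibration
  tests.
* a sample is *loss* below `loss_ratio` × reference and *gain* above
  `gain_ratio` × reference, both strict. Defaults 0.75 and 1.5 place
  the decision boundary midway between the normal level and a halved
  (resp. doubled) coverage state; a cutoff at 0.5 would sit exactly on
  the halved state itself and classify such carriers at chance.
* bases where the reference is zero, or where fewer than 80% of samples
  have nonzero raw depth (capture gaps), are skipped and logged.

Aberrant (loss or gain) vs normal by group forms the 2×2 per base;
Bonferroni threshold `α / n_tested_bases`; runs of adjacent significant
bases merge into reported BED intervals. A hook ingests externally
called per-sample CNV intervals (BED) into the same 2×2 test, in place
of re-implementing a dedicated read-depth caller.

## Power simulation

`p1 = OR·p0 / (1 − p0 + OR·p0)` converts a control carrier frequency
and odds ratio into the case carrier frequency. Each replicate draws
case carriers ~ Binomial(n_case, p1) and control carriers ~
Binomial(n_control, p0) and applies the two-sided Fisher test; power is
the fraction of replicates below α. An exact companion
(`exact_power`) enumerates both binomials against the p-value table and
is used to validate the Monte-Carlo route. At the reference design
(p0 = 0.01, OR = 22, 40/48, α = 0.05) the exact power is 0.848; the 80%
crossing of the power curve sits near OR = 20. Note the distinction
between a prevalence (risk) ratio and an odds ratio: prevalences of 30%
vs 1% are a risk ratio of 30 but an odds ratio of ≈ 42.9; both helpers
are provided and the package reports each on its own scale.

`min_detectable_or` bisects on log OR with common random numbers (the
same uniform draws underlie every evaluated OR), which makes the
estimated power monotone along the search and stabilises the crossing;
the result is reported with its bracketing interval.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
not sequence: 40 cases and 48 controls (defaults), manifest ages
~ Normal(22.2, 6.0) years (controls floored at the 15-year enrolment
minimum), and a multi-sample VCF over the region with haploid genotypes,
caller quality in QUAL and population AF + caller class in INFO.

Background loci are independent (no linkage disequilibrium): each locus
draws a population allele frequency from a three-component uniform
mixture — weights 0.37 on (0.001, 0.05), 0.15 on (0.05, 0.30), 0.48 on
(0.30, 0.95) — and carriers are Bernoulli(AF) per sample (hemizygous
model: carrier probability equals allele frequency). The locus count is
calibrated analytically so the expected number of carried variants per
sample equals `mean_variants_per_sample` (default 4,600). With the
default mixture this reproduces the reference cohort's whole filter
funnel: ≈4,600 variants per sample, of which ≈4,200 distinct loci
survive the common-variant and singleton filters — most per-sample yield
comes from common polymorphisms that the AF filter removes, as in real
cohorts. Ten percent of loci are emitted as forced dataset singletons
and 5% lack the AF annotation, so every filter branch is exercised on
default data. Quality scores straddle their cutoffs (SNV ~ N(120, 60²)
vs cutoff 50; indel ~ N(900, 250²) vs cutoff 600, ≈12% failing each).
An optional risk variant is injected with carrier probability `p0` in
controls and `p1` (from the odds ratio) in cases, written with a quality
and AF that pass the filters so that its detectability reflects the
association test, not the filter.

Depth tracks: per-sample mean coverage ~ Normal(100, 15) truncated at 5
(the reference study's ~20 million mapped reads over 4.2 Mb put mean
per-base coverage in the hundreds; 100 is a conservative choice above
its ≥20× QC floor), per-base depth negative binomial with dispersion 80
(mildly overdispersed relative to Poisson). An injected CNV multiplies
carrier means by `fold_change` over its interval for the configured
fraction of cases. Depth is simulated over a 50 kb window of the region
by default (`depth_region`): per-base tracks for 88 samples over the
full 4.2 Mb would be ~370M values, and the per-nucleotide test is
position-wise, so a window demonstrates the method at full fidelity.

All randomness flows from one seed through named substreams; identical
configurations give byte-identical output files.

**What the generator does not emulate** — and what passing tests
therefore cannot show about real data: linkage disequilibrium between
background variants (window-test correlation structure is optimistic),
capture/GC bias and batch effects in coverage, caller-specific error
modes (the quality scores are labels, not error models), population
stratification, and any true association other than the injected ones.

## Simulation scales in the test suite

Null calibration runs 200 full-scale null cohorts through
simulate → filter → test and checks each family's rejection rate against
5% + 2 s.e.; signal recovery uses 50 seeds for the injected OR = 60
variant and a 15 kb CNV within the 50 kb coverage window; the CNV null
check uses 25 seeds; the Fisher oracle comparison is exhaustive for all
margin pairs up to 60. The acceptance script estimates power with
500,000 replicates (Monte-Carlo s.e. ≈ 0.05 percentage points). These
sizes were chosen so each check's sampling error is small relative to
the tolerance it asserts.

## Known limitations

* The coverage dichotomisation is a principled reconstruction, not a
  published procedure; conclusions about CNVs depend on its thresholds,
  which are exposed as parameters.
* Gene burden counts all CDS-overlapping variants; without transcript
  sequence, synonymous variants cannot be excluded.
* Bonferroni across highly correlated windows is conservative; no
  permutation alternative is provided (deliberately out of scope).
* The pipeline tests association only; it performs no alignment,
  variant calling, or CNV segmentation.
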