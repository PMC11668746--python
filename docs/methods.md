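# Methods

This note documents the statistical models, numerical choices and known
limitations behind each stage of foundertrace, and what the synthetic-data
tests do and do not demonstrate about real data.

## Carrier frequency and incidence

Variant alleles in a screening cohort are modelled as Binomial(2n, q) for
n diploid individuals; carriers are counted as *alleles*, so a homozygote
contributes 2 (this is why 1 carrier among 132 individuals is 1/264). The
confidence interval is the exact Clopper-Pearson interval, computed from
beta quantiles (`scipy.stats.beta.ppf`) rather than by inverting binomial
tail sums numerically; a bisection tail-inversion implementation is kept
in the test suite as an independent oracle and agrees to 1e-8. Boundary
conventions: the lower bound is exactly 0 when x = 0 and the upper bound
exactly 1 when x = n. The source study names its interval method
"Klopper-Pearson"; we read this as the standard Clopper-Pearson exact
interval — the printed bounds confirm the reading — and document rather
than silently correct the spelling. No continuity or mid-p variant is
applied: the plain exact interval reproduces the reported values.

Incidence under Hardy-Weinberg equilibrium is q² (autosomal recessive,
random mating, no inbreeding-coefficient adjustment, no mutation-selection
balance). Squaring is monotone on [0, 1], so squaring the frequency CI
bounds yields an exact CI for q². All chained arithmetic uses unrounded
values; display rounds frequencies to 6 decimals and per-100,000
incidences to 5, which is the precision at which the squared-unrounded and
squared-rounded upper bounds become distinguishable.

## RFLP simulation

Primer binding is exact string matching (the forward primer on the given
strand, the reverse complement of the reverse primer downstream of it).
Zero products raise "no amplification"; more than one raises
"non-specific amplification" listing every product. Melting temperature,
mismatch tolerance and primer thermodynamics are deliberately out of
scope: the module verifies assay *design*, not chemistry.

Enzymes are an IUPAC degenerate recognition site plus a top-strand cut
offset. At construction the site is checked for self-complementarity:
palindromic sites (Hpy188III's TCNNGA reverse-complements to itself) need
only a top-strand scan; otherwise both strands are scanned with the cut
offset mirrored. Overlapping matches are all reported (regex lookahead).
Hpy188III is modelled as `TC^NNGA` (cut offset 2). The published assay
constrains only the fragment sizes, not the offset; any offset consistent
with the 189+168 / 168+122+67 arithmetic would serve, and the amplicon
fixture encodes the printed fragment arithmetic, not the genomic sequence,
because the variant's exact position within the amplicon is not public.

Genotype calls compare band patterns as a gel does: distinct sizes,
shared fragments appearing once, sizes within a configurable
co-migration tolerance (default 0 bp for simulated digests) treated as one
band. A pattern matching zero or several of {wild-type, mutant, union} is
"uncalled" — a value, not an error.

## Genetic maps

Maps are per-chromosome knot tables (bp strictly increasing, cM
non-decreasing). Interpolation is piecewise linear; queries beyond the
terminal knots return the terminal cM with a logged warning. Constant
extrapolation was chosen over linear because ROH boundaries frequently
exceed map support, and extending the terminal recombination rate would
fabricate genetic length precisely where the dating estimator is most
sensitive. Duplicate physical positions collapse to the first row with a
warning; decreasing cM is a hard error naming the offending rows.
Coordinates are 1-based inclusive internally; BED export converts to
0-based half-open. The genome build is deliberately unchecked — the
declared build string is carried through, nothing more — because mixed
build provenance is common in practice and a liftover is out of scope.

The Kosambi map function r = ½·tanh(2d) and its inverse are exact
closed forms; map distances themselves are already additive cM, so the
map function is needed only where recombination fractions are (e.g. the
simulator's cross-check path). cM convert to Morgans by a fixed factor of
100.

## ROH detection

Windows are counted in markers, not bp, for robustness to exome marker
density. A window of `window_markers` consecutive markers passes when it
contains at most `max_het_per_window` heterozygous and
`max_missing_per_window` missing calls; markers covered by any passing
window form candidate regions; regions are trimmed so both ends are
homozygous non-missing; regions shorter than `min_length_bp` or supported
by fewer than `min_markers` markers are dropped. Missing calls never
terminate a run by themselves — only heterozygote excess does. Defaults
(25 / 1 / 2 / 1 Mb / 50) approximate published exome autozygosity-mapper
behaviour; all are exposed because the thresholds are not standardised.
Fewer markers than one window yields an empty result with a warning, not
an error. The caller is verified against an exhaustive loop-based
enumeration of the same window rules on randomised instances; boundary
placement is guaranteed only to within one window of markers, which is
the resolution the windowed definition itself has. Manual curation of
segment borders (as practised after visual inspection in real studies)
cannot be replicated; the per-segment marker and heterozygote counts in
the output are the provided substitute.

The shared core across patients is the intersection [max of starts, min
of ends] of segments that each contain the anchor locus; a segment
missing the anchor is an error naming the sample. Segment length in Mb is
(end − start + 1)/1e6 unrounded, displayed at 1 decimal (half-up).

## Founder dating

Model: in a patient whose two lineages each trace g meioses to the
founder, the nearest crossover to the variant on one side of one lineage
is Exponential(g) in Morgans (superposition of g unit-rate Poisson
crossover processes); the autozygous flank is the minimum over the two
lineages, hence Exponential(2g); a patient's ROH genetic length is the sum
of its two flanks; the pooled length S of n independent patients is
Gamma(2n, rate 2g). This yields the MLE ĝ = n/S and the exact equal-tailed
CI ĝ_bounds = GammaQuantile(α/2, 1−α/2; shape 2n)/(2S). The estimator
pools segments (the MLE) rather than averaging per-patient estimates;
pooling is efficient and makes the pivot exact. A plug-in per-segment
meiosis count m_i (default 2) generalises to unequal lineage depths:
ĝ = 2n / Σ m_i L_i with pivot g·Σ m_i L_i ~ Gamma(2n, 1).

Assumptions worth stating: patients are independent (no shared recent
pedigree beyond the founder), lineage depths are equal and shared, no
mutation or gene-conversion boundary effects, and segment boundaries are
measured without error. The default path applies no correction for
length-biased ascertainment; because ROH callers cannot see segments
below their minimum length, an optional truncated-likelihood variant is
provided that conditions each Gamma(2, 2g) length on exceeding a
detection threshold (closed-form survival (1+2gt)e^(−2gt); score solved
by Brent's method bracketed around the untruncated MLE; Wald CI on
log g from the numerically differentiated observed information). The
default generation interval is 25 years, configurable.

The published point estimates for this stage are not recomputable from
public inputs (they require the external genetic map and the patients'
sequencing data, and the cited method's equations are not restated), so
the estimator is validated by forward simulation instead: at true g = 10
with n = 50 patients over 500 seeded replicates, the mean estimate falls
within 5% of truth (the exact bias factor is 2n/(2n−1)) and the 95% CI
covers truth at its nominal rate. Tests also check scale consistency
(doubling lengths halves ĝ exactly) and CI shrinkage in n.

## Synthetic data

The simulator is the generative counterpart of the dating model: flank
erosion is drawn directly as exponentials on the genetic scale and mapped
to physical coordinates through an invertible synthetic map (strictly
increasing cM; lognormal local rates around a configurable mean, default
1 cM/Mb). A slower meiosis-by-meiosis path (Poisson crossovers per
meiosis, nearest-crossover flanks) is included as an independent
generative route and agrees in distribution. Markers (default 5,000 over
100 Mb, random placement) carry population frequencies drawn
Uniform(0.1, 0.9) — an informative-genotyping-panel regime; inside the
planted segment genotypes are homozygous for a founder haplotype drawn
once per marker and shared by all patients of a cohort, outside they are
Hardy-Weinberg draws. Optional error knobs: heterozygous miscalls inside
the segment and missingness anywhere.

What passing tests show: the pipeline's inference is correct *under its
own model* — windowed detection recovers planted segments, and the dating
estimator is unbiased with exact coverage when descent really is
exponential flank erosion. What they do not show: performance under
linkage disequilibrium between markers, population-specific allele
frequencies, genotyping batch effects, pedigree structure among patients,
or map error — none of which the generator emulates. Cohort draws are
plain Binomial(2n, q); the 357-bp amplicon fixture is a synthetic
sequence constructed (and verified by digestion at build time) to
reproduce the assay's printed fragment arithmetic.

## Problem sizes and determinism

Default verification sizes — 500 dating replicates of n = 50, 50
randomised ROH-oracle instances of up to 5,000 markers, 100 random
sequences for the digestion scanner, 2,000 binomial draws for CI
coverage — were chosen so the full suite completes in about a minute on a
single core while keeping Monte-Carlo noise well inside the asserted
tolerances. Every stochastic component takes an explicit seed
(`numpy.random.default_rng`); identical seeds give byte-identical
artifacts, and each CLI run writes a manifest (inputs, parameters,
version, seed) sufficient to reproduce it.

## Known limitations

- Biallelic markers and a single chromosome per analysis; no genome-wide
  F_ROH summaries or allele-frequency-weighted autozygosity likelihoods.
- Dating uses autozygous homozygotes only; haplotype-sharing dating from
  heterozygous carriers is not implemented.
- No genome-build liftover; the caller must keep map and coordinates on
  one build.
- PCR is sequence-exact; degenerate or mismatched primer binding is not
  modelled.
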