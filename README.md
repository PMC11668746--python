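# foundertrace

Analysis toolkit for founder-variant studies in isolated populations:
estimate how common a recessive disease allele is, genotype it cheaply by
PCR-RFLP, map the autozygous region that carries it, and date the founder
event from the decay of shared haplotype length. The package grew out of
the analysis chain used for the GNE myopathy founder allele in the Mari
population (a 357-bp Hpy188III assay, carrier screening of three Volga
populations, autozygosity mapping on chromosome 9 and segment-length
dating), but every stage is generic and fully parameterised.

It is aimed at medical geneticists and population-genetics analysts who
have: genotype calls for one chromosome (minimal VCF), a genetic-map knot
table (Rutgers-style `chromosome  bp  cM`), carrier counts from a
screening cohort, and optionally a template/primer pair for an RFLP assay.
A forward simulator generates all of these inputs synthetically, so the
whole pipeline is testable without any data download.

## What it computes

**Carrier statistics** (`foundertrace.freqstats`). From *x* variant
alleles in *n* diploid individuals, `q̂ = x / 2n` with the exact
(Clopper-Pearson) binomial 95% CI obtained from beta quantiles,
`q_lo = B(α/2; x, 2n−x+1)`, `q_hi = B(1−α/2; x+1, 2n−x)`. Disease
incidence under Hardy-Weinberg equilibrium is `q̂² × 100 000`, with CI
bounds the squares of the unrounded frequency bounds (squaring is monotone
on [0, 1]).

**RFLP genotyping in silico** (`foundertrace.rflp`). Exact-match PCR
followed by digestion with an enzyme given as an IUPAC degenerate site and
cut offset (Hpy188III = `TC^NNGA` is built in). Genotypes are called by
matching fragment-size multisets against the wild-type pattern, the mutant
pattern and their union (shared sizes co-migrate as one band).

**ROH detection** (`foundertrace.roh`). A parameterised sliding-window
caller: windows of `w` markers tolerating ≤ `h` heterozygous and ≤ `m`
missing calls seed regions, seeds merge, boundaries are trimmed to
homozygous markers, and regions below a physical length or marker count
are dropped. Defaults (`w=25, h=1, m=2, ≥1 Mb, ≥50 markers`) give
exome-scale behaviour.

**Genetic maps** (`foundertrace.genmap`). Piecewise-linear interpolation of
physical positions into sex-averaged Kosambi cM, constant extrapolation
beyond map support, and the Kosambi map function
`r = ½·tanh(2d)`, `d = ¼·ln((1+2r)/(1−2r))`.

**Founder dating** (`foundertrace.dating`). In a patient autozygous for
the founder allele, each ROH flank is Exponential(2g) in Morgans after `g`
generations per lineage, so the pooled length `S` of `n` patients'
segments is Gamma(2n, rate 2g). The MLE is `ĝ = n/S` with an exact CI from
the pivot `2gS ~ Gamma(2n, 1)`; years follow as `ĝ ×` generation interval
(default 25 y). An optional truncated-likelihood variant corrects for the
minimum detectable segment length.

**Simulation** (`foundertrace.simulate`). Founder-haplotype descent
(exponential flank erosion, or an independent meiosis-by-meiosis Poisson
crossover path), Hardy-Weinberg genotypes outside the segment, invertible
synthetic genetic maps, binomial cohort draws and the 357-bp amplicon
fixture.

## Worked example

Carrier screening — one variant allele among 132 individuals:

```text
$ foundertrace freq --carriers 1 --individuals 132 --population Mari
population       : Mari
individuals (n)  : 132
alleles observed : 1/264
allele frequency : 0.003788 (95%CI: 0.000096–0.020923)
HWE incidence    : 1.43480 (95%CI: 0.00092–43.77669) per 100,000
```

The allele frequency is 1/264 with its exact binomial CI; squaring and
scaling gives the expected number of affected births per 100,000 — about
1.4, but with a CI spanning four orders of magnitude, as a single observed
allele warrants.

Simulate four autozygous patients (true depth g = 10 generations), call
their ROH and date the founder event:

```text
$ foundertrace simulate roh --seed 7 --out-dir sim --n-patients 4 --marker-count 4000
$ for i in 0 1 2 3; do foundertrace roh --vcf sim/sim$i.vcf --out sim/roh$i.bed; done
$ cat sim/roh*.bed > sim/all.bed
$ foundertrace date --segments sim/all.bed --map sim/map.tsv
model: per-patient ROH genetic length = sum of two Exponential(2g)
       flanks (Morgans); pooled MLE g = n/S with exact Gamma pivot CI
patients (n)       : 4
generations g      : 14.64 (95%CI: 6.32-26.39)
age in years       : 365.92 (95%CI: 157.98-659.69) at 25 y/generation
```

With only four patients the CI is wide — it covers the simulated truth of
10 generations — and it tightens as `n` grows (the Gamma(2n) quantile
ratio approaches 1).

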