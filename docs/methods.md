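# Methods

This note documents the statistical procedures implemented in `rohpop`,
the choices made where conventions diverge, and what the bundled simulator
does and does not emulate.

## Genotype model and conventions

Genotypes are diploid, biallelic, autosomal, coded 0 (homozygous allele A),
1 (heterozygous), 2 (homozygous allele B), −1 (missing). Allele A is the
first allele encountered per marker when reading PED text unless an allele
reference is supplied; every downstream statistic is invariant to this
choice (tested by flipping the coding). Coordinates are 1-based inclusive
throughout; only BED export converts to 0-based half-open. Autosome labels
are integers 1–30. Unsorted marker maps are sorted by (chromosome,
position) with a warning; duplicate positions are allowed but flagged.

QC retains SNPs with call rate **strictly** greater than the threshold
(default 0.99): a SNP at exactly the threshold is removed. The filter is a
single pass on the joint panel and is idempotent.

## ROH detection

The consecutive-run scan grows a run over homozygous SNPs along a
chromosome and closes it at (i) a heterozygous call once the `max_het`
allowance (default 0) is spent, (ii) a missing call once `max_missing`
(default 0) is spent, or (iii) an inter-SNP gap larger than `max_gap_bp`
(default 1 Mb). A gap splits the run without disqualifying either flank. A
closed run is emitted iff it contains ≥ `min_snps` (default 150) SNPs and
spans ≥ `min_length_bp` (default 1 Mb), where the span is
`end − start + 1` with boundaries at the first/last member SNP — not
midpoints to flanking SNPs — because downstream island boundaries are
reported as inclusive SNP positions. The min-length test uses this same
span, so ≥150 SNPs squeezed into <1 Mb are rejected. With non-zero
allowances the scan is greedy (a run absorbs hets until the allowance is
spent); boundaries are always trimmed back to homozygous SNPs. With the
default allowances of zero the output is exactly the set of maximal pure
homozygous gap-bounded runs, and the test suite proves it identical to an
exhaustive candidate-interval enumeration on random panels.

Length classes are left-closed right-open: [1,2), [2,4), [4,8), [8,16) Mb
and a 16+ overflow class, so a 2.000000 Mb run falls in 2–4.

F_ROH divides a bird's summed ROH length by the SNP-covered autosomal
genome length; the default denominator, 902,020,024 bp, is the standard
value for the 650K turkey array panel the package's defaults target, and is
configurable (the analysis scripts pass the simulated genome length).

## F_HOM

F_HOM is the method-of-moments excess-homozygosity ratio
`(O − E)/(L − E)` per bird: O = observed homozygous genotype count over the
bird's typed SNPs, L = typed SNP count, and
`E = Σ_snps [1 − 2p̂q̂·n_al/(n_al − 1)]` with p̂ the within-population
allele frequency over non-missing calls and n_al the number of observed
alleles at the SNP. SNPs with fewer than two observed alleles are excluded
from both O and E. The ratio is negative for birds more heterozygous than
expectation and is not clamped: population means can be (and in highly
outbred groups are) below zero. The small-sample factor n/(n−1) is the
standard unbiased correction for expected heterozygosity; without it F_HOM
would be biased upward in breeds of 20–30 birds.

For the Table-style per-breed summary, "observed homozygous SNPs" is
defined as the number of SNPs with zero heterozygous calls in the breed,
and "expected homozygous SNPs" as `Σ_snps (1 − 2p̂q̂)^n_typed` — the
probability under Hardy–Weinberg that none of the typed birds is
heterozygous. These two definitions satisfy the internal consistency
constraint that the observed count can never be below the monomorphic
count.

## F_ST, IBS, NJ, PCA

Pairwise F_ST is the Weir & Cockerham (1984) two-population estimator
assembled as a ratio of sums over SNPs (Σa / Σ(a+b+c)); per-SNP sample
sizes use non-missing calls, SNPs monomorphic across the pair contribute
nothing, and pairs with no polymorphic SNP raise a distinct error rather
than returning 0. A Hudson-type estimator (Bhatia et al. 2013) is available
behind a flag for sensitivity checks. On Balding–Nichols panels the
estimator's 20-replicate mean recovers the generating θ within ±0.05 at
θ = 0.05, 0.2 and 0.5 (tested).

IBS distance between two birds is 1 − (mean shared-allele count)/2 over
SNPs typed in both; it is a pseudo-metric (zero diagonal, symmetric) and a
pair with no overlapping SNPs gets NaN, flagged downstream.

Neighbour joining is the standard Saitou–Nei agglomeration on the Q
criterion with two determinism rules: ties pick the lexicographically
lowest index pair of the working matrix, and negative limb lengths are
clamped to zero with a flag on the returned tree. On any additive matrix
the reconstruction is exact (topology and branch lengths), which the suite
checks on random 5–8-taxon trees and cross-checks against scikit-bio.

PCA mean-centres genotypes per SNP, imputes missing cells to the SNP mean,
optionally applies Patterson 1/√(p̂(1−p̂)) scaling, and takes the SVD of
the centred matrix; eigenvalues are of the sample covariance (ddof = 1) and
percent variance is relative to the full spectrum.

## Effective population size from LD

For each intra-chromosomal SNP pair within a distance window the package
computes the squared Pearson correlation of 0/1/2 genotype codes over
birds typed at both SNPs (monomorphic SNPs skipped). Physical distance maps
to recombination fraction linearly, `c = rate × bp`, with rate default
1e−8 M/bp (1 cM/Mb); Haldane and Sved–Feldman mappings are options. Pairs
are binned (default 30 log-spaced bins over 50 kb–5 Mb); each bin mean r²
is reduced by the unphased finite-sample term 1/(2n) (1/n when phased) and
inverted through Sved's expectation:

    N_e(t) = (1/(4 c̄)) (1/r²_adj − α),   t = 1/(2 c̄)

with α = 2 by default (mutation accounted) and α = 1 selectable — the
drift-simulation tests use α = 1 because the simulator has no mutation.
Bins whose adjusted mean r² is non-positive, or where 1/r²_adj ≤ α, carry
no information about a positive N_e and are dropped with a warning. The
inversion is exact on injected Sved-curve values; on drift simulations
(N = 50, 30 generations) the estimates dated 10–30 generations back lie
within a factor of two of census size.

## ROH islands

An island is a (chromosome, start, end) triple shared as a bit-identical
ROH by at least `ceil(fraction × n)` of a breed's n birds (75% default).
The threshold count snaps products within 1e−9 of an integer before taking
the ceiling so that binary float artifacts (e.g. 0.60 × 25) cannot shift
the count by one. Because exact-boundary sharing is strict, an
incidence-based caller — maximal runs of SNPs whose per-SNP coverage count
reaches the threshold — is provided as an alternative for Manhattan-style
analyses; exact-boundary remains the default. Cross-breed sharing merges
islands from different breeds transitively on ≥ 1 bp overlap and reports
union boundaries, since any stricter merge rule would depend on an
arbitrary anchor breed. Gene annotation is a pure interval intersection
(≥ 1 bp, 1-based inclusive), equivalent to intersectBed on the converted
coordinates; chromosome labels that cannot be reduced to integer autosomes
raise an error listing the offending labels.

## The simulator

Each breed draws per-SNP allele frequencies from the Balding–Nichols
distribution Beta(p(1−θ)/θ, (1−p)(1−θ)/θ) around ancestral frequencies
shared across breeds (drawn Uniform(0.05, 0.95), mimicking an
ascertained array); θ = 0 returns the ancestral frequencies exactly.
Founder haplotypes are Bernoulli draws from the breed frequencies. Discrete
generations follow a size schedule; each transmitted chromosome receives
Poisson(rate × length) crossovers at uniform positions and is stored as a
piecewise map from bp intervals to founder-haplotype ids. True autozygous
segments are the intervals where a bird's two maps agree; segments covering
fewer than two SNPs are dropped (nothing shorter is detectable from the
map). Genotypes are read off the founder haplotypes, so genotypes inside
true IBD segments are homozygous by construction; `add_genotyping_noise`
breaks that guarantee deliberately (hom→het flips and missingness) for
stress tests.

Two mating systems: `monogamous` (default) shuffles parents into disjoint
pairs — no selfing, so one generation from unrelated founders produces
exactly zero IBD — and `random` (Wright–Fisher union of gametes, selfing
allowed), for which E[F_t] = 1 − (1 − 1/2N)^t holds exactly and is used for
closed-form calibration. Under monogamy at N = 2 the pedigree is the
classical full-sib line and per-bird inbreeding equals the recursion
F_t = (1 + 2F_{t−1} + F_{t−2})/4; note that g generations from unrelated
founders contain g−1 sib-mating steps. Per-bird pedigree F is computed from
the realized pedigree by the kinship recursion (founders unrelated and
non-inbred), so it is the exact conditional expectation of the autozygous
fraction.

Default scenario (the analysis scripts' study stand-in): 7 breeds × 25
birds, 5 chromosomes × 20 Mb × 2,000 SNPs (≈100 SNPs/Mb), 50 founders,
20 generations with a contraction to 10 breeding birds from generation 11
and a final sampled cohort of 25, θ = 0.3, 1 cM/Mb. These sizes scale the
panel it emulates (seven breeds of 22–31 birds, 346k SNPs over 902 Mb,
recent census collapse, pairwise F_ST 0.18–0.63) down by roughly 10× in
genome size so the full chain runs in seconds; the analysis scripts use
`min_snps = 50` for ROH detection, keeping the SNP-count threshold at the
same ≈0.5 Mb of marker span as 150 SNPs on a 650K array.

What the simulator does **not** emulate: mutation (hence α = 1 in its Ne
tests), sex chromosomes and sexed mating, overlapping generations,
genotyping error beyond the simple noise model, a non-uniform genetic map,
and array ascertainment beyond the uniform ancestral-frequency draw.
Passing tests therefore demonstrate correctness of the estimators under
drift, recombination and bottlenecks — not robustness to array artifacts.

## Numerical and degenerate-input choices

* `sharing_threshold` uses the snap-then-ceiling rule described above.
* F_ST with no polymorphic SNPs, NJ with <3 taxa, PCA on an all-monomorphic
  panel, Ne with no pairs, and regressions with zero variance all raise
  typed errors; the pipeline logs and skips optional stages (Ne, PCA,
  per-breed regressions) and always completes the rest.
* The pipeline writes every table with a fixed float format, so identical
  inputs and seed give byte-identical files; `manifest.json` records sha256
  checksums.
* NJ branch lengths are clamped at 0 when negative (flagged); on additive
  inputs no clamping occurs.

## Known limitations

Exact-boundary islands require every shared run to start and end on the
same SNP; in the simulator this effectively requires local fixation out to
the same flanking heterozygous SNP in ≥75% of birds, which is rare unless a
bottleneck fixes a whole chromosome. Real 650K panels show such islands
because marker density and strong local LD make boundary coincidence
common; with the scaled-down map the incidence-based caller is the more
sensitive instrument, and the default scenario typically yields exact
islands only under severe (N ≤ 2) contractions. The per-breed SNP counts of
a jointly QC'd panel are all equal by construction here; pipelines that
re-filter per breed would differ by a handful of SNPs.
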