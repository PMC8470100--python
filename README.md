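# rohpop

Runs of homozygosity (ROH), ROH islands, genomic inbreeding and population
structure for SNP-array genotype panels of small, closed populations —
heritage livestock and poultry breeds in particular. The package bundles a
forward-time multi-breed simulator with exact autozygosity ground truth, so
every estimator can be validated against known truth rather than only
against other software.

## What it computes

Given a diploid autosomal genotype panel (PLINK text PED/MAP or a native
TSV matrix) with sample-to-population labels:

* **QC** — keep SNPs on autosomes 1–30 with call rate strictly above a
  threshold (default 0.99).
* **Diversity** — per breed: monomorphic SNP count, observed/expected
  heterozygosity, mean MAF, observed/expected homozygous-SNP counts.
* **Structure** — pairwise Weir–Cockerham (1984) F_ST (ratio of sums over
  SNPs, Σa / Σ(a+b+c)); identity-by-state distances (1 − mean shared-allele
  fraction / 2); Saitou–Nei neighbour joining with Newick export; genotype
  PCA with optional Patterson scaling.
* **ROH** — consecutive-run detection: a run of homozygous SNPs terminated
  by a heterozygous call, a missing call, or an inter-SNP gap > 1 Mb, kept
  if it has ≥ 150 SNPs and spans ≥ 1 Mb (all four thresholds are
  parameters); length classes 1–2 / 2–4 / 4–8 / 8–16 / 16+ Mb; per-breed
  summaries.
* **Inbreeding** — F_ROH = Σ ROH length / SNP-covered genome length
  (default denominator 902,020,024 bp); F_HOM = (O − E)/(L − E) from
  observed vs Hardy–Weinberg-expected homozygous genotype counts with the
  small-sample correction 2p̂q̂·n/(n−1); per-breed OLS regression and
  Pearson correlation between the two.
* **ROH islands** — per-SNP incidence (count of birds whose ROH covers the
  SNP) and island calling: exact-boundary clusters shared by at least a
  threshold fraction of the breed (default 75%, count = smallest integer ≥
  fraction × n), plus an incidence-based caller; cross-breed sharing by
  ≥ 1 bp overlap with union boundaries; gene-interval annotation with
  intersectBed semantics.
* **Ne from LD** — squared genotype correlations binned by recombination
  distance, corrected by 1/(2n), inverted through Sved's
  E[r²] ≈ 1/(α + 4N_e c): one (t = 1/2c, N_e) point per bin.
* **Simulator** — Balding–Nichols breed differentiation around shared
  ancestral frequencies, discrete generations of monogamous (or
  Wright–Fisher random) mating with Poisson recombination, founder-haplotype
  tracking for exact IBD segments, pedigree inbreeding via the kinship
  recursion, optional genotyping noise.

## Worked example

Simulate seven breeds with a recent contraction, then run the full chain:

```
python analysis/01_simulate_panel.py --outdir results --seed 7
python analysis/02_qc_diversity.py --outdir results
python analysis/03_population_structure.py --outdir results
python analysis/04_roh_inbreeding.py --outdir results
python analysis/05_roh_islands.py --outdir results
python analysis/06_effective_population_size.py --outdir results
```

Step 01 prints

```
simulated 175 birds in 7 breeds, 10000 SNPs over 100 Mb (theta_fst=0.3, bottleneck [(11, 10), (20, 25)])
mean pedigree F = 0.373; true IBD segments: 909
```

and step 04 closes the loop against that ground truth:

```
mean F_ROH = 0.367 vs mean pedigree F = 0.373
```

i.e. the summed length of detected ROH per bird, divided by the 100 Mb
simulated genome, recovers the pedigree expectation of the autozygous
genome fraction to within 0.006. The same step prints per-breed
F_HOM ~ F_ROH regressions (r = 0.995–0.999 here — the two inbreeding
coefficients rank birds almost identically). Step 06 prints, per breed,
the most recent LD-based estimate, e.g. `Ne~23 at t~11 generations`,
which matches the simulated contraction to 10–25 breeding birds about a
decade of generations ago.

The same pipeline runs on real PLINK filesets through the CLI:

```
rohpop all --ped birds.ped --map birds.map --outdir out \
    --min-snps 150 --min-length-bp 1000000 --max-gap-bp 1000000 \
    --island-threshold 0.75 --genome-length 902020024
```

Subcommands `simulate`, `qc`, `diversity`, `structure`, `roh`, `islands`,
`inbreeding` and `ne` run individual stages; `all` writes every table plus
a `manifest.json` of sha256 checksums (same inputs + seed ⇒ byte-identical
outputs).

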