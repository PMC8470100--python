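"""Per-population marker diversity statistics and the F_HOM inbreeding
coefficient.

All per-SNP frequencies are computed from non-missing calls only, within
the requested population. F_HOM is the method-of-moments excess-homozygosity
ratio (O - E) / (L - E), where E carries the small-sample correction
2*p*q * n_al/(n_al - 1) familiar from PLINK's ``--het``; it is negative for
individuals more heterozygous than the Hardy-Weinberg expectation and is
deliberately not clamped at zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GenotypePanel, MISSING


@dataclass
class PopDiversity:
    population: str
    n_birds: int
    n_snps: int
    n_monomorphic: int
    obs_het: float
    exp_het: float
    maf_mean: float
    obs_hom_snps: int
    exp_hom_snps: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(self)])


def _pop_freq_stats(geno: np.ndarray):
    """Per-SNP (n_called, allele count, p_hat, het count) for one population."""
    called = geno != MISSING
    n_called = called.sum(axis=0)
    het = (geno == 1).sum(axis=0)
    alt = np.where(geno == MISSING, 0, geno).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_hat = np.where(n_called > 0, alt / (2 * n_called), np.nan)
    return n_called, het, p_hat


def pop_diversity(panel: GenotypePanel, population: str) -> PopDiversity:
    """Marker diversity summary for one population.

    Per SNP within the population: ``p_hat`` is the allele-B frequency over
    non-missing calls; a SNP is monomorphic iff ``p_hat`` is 0 or 1. Means
    (observed/expected heterozygosity, MAF) run over SNPs with at least one
    call. ``obs_hom_snps`` counts SNPs with no observed heterozygote;
    ``exp_hom_snps`` is the summed probability, under Hardy-Weinberg at
    ``p_hat``, that none of the typed birds is heterozygous.
    """
    geno = panel.pop_matrix(population)
    n_birds = geno.shape[0]
    if n_birds < 2:
        raise ValueError(f"population {population!r} needs >=2 samples")
    n_called, het, p_hat = _pop_freq_stats(geno)
    informative = n_called > 0
    p = p_hat[informative]
    q = 1 - p
    obs_het_frac = het[informative] / n_called[informative]
    return PopDiversity(
        population=population,
        n_birds=n_birds,
        n_snps=panel.n_snps,
        n_monomorphic=int(((p == 0) | (p == 1)).sum()),
        obs_het=float(obs_het_frac.mean()) if informative.any() else 0.0,
        exp_het=float((2 * p * q).mean()) if informative.any() else 0.0,
        maf_mean=float(np.minimum(p, q).mean()) if informative.any() else 0.0,
        obs_hom_snps=int((het[informative] == 0).sum()),
        exp_hom_snps=float(
            ((1 - 2 * p * q) ** n_called[informative]).sum()),
    )


def diversity_table(panel: GenotypePanel) -> pd.DataFrame:
    """One :func:`pop_diversity` row per population."""
    rows = [vars(pop_diversity(panel, p)) for p in panel.population_labels]
    return pd.DataFrame(rows)


def f_hom(panel: GenotypePanel, population: str) -> pd.DataFrame:
    """Per-sample excess-homozygosity inbreeding coefficients.

    Returns a DataFrame with columns ``sample, o_hom, e_hom, l_typed, f_hom``.
    SNPs with fewer than two non-missing allele observations in the
    population are excluded from both the observed and expected counts.
    """
    sample_ids = panel.pop_samples(population)
    if len(sample_ids) < 2:
        raise ValueError(f"population {population!r} needs >=2 samples")
    geno = panel.pop_matrix(population)
    n_called, _, p_hat = _pop_freq_stats(geno)
    n_al = 2 * n_called
    usable = n_al >= 2
    with np.errstate(invalid="ignore", divide="ignore"):
        e_per_snp = np.where(
            usable, 1 - 2 * p_hat * (1 - p_hat) * (n_al / np.maximum(n_al - 1, 1)),
            0.0)
    rows = []
    for i, sid in enumerate(sample_ids):
        g = geno[i]
        typed = (g != MISSING) & usable
        l_typed = int(typed.sum())
        o = int(((g == 0) | (g == 2))[typed].sum())
        e = float(e_per_snp[typed].sum())
        denom = l_typed - e
        f = (o - e) / denom if denom != 0 else np.nan
        rows.append((sid, o, e, l_typed, f))
    return pd.DataFrame(rows,
                        columns=["sample", "o_hom", "e_hom", "l_typed",
                                 "f_hom"])


def f_hom_all(panel: GenotypePanel) -> pd.DataFrame:
    """F_HOM for every population, concatenated with a population column."""
    parts = []
    for pop in panel.population_labels:
        part = f_hom(panel, pop)
        part.insert(1, "population", pop)
        parts.append(part)
    return pd.concat(parts, ignore_index=True)
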