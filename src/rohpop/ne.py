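"""Historical effective population size from the decay of linkage
disequilibrium with recombination distance.

The estimator follows Sved's expectation for the squared correlation of
allele state at two loci a recombination distance ``c`` (Morgans) apart,
E[r2] ~= 1/(alpha + 4 N c), where alpha = 1 ignores mutation and alpha = 2
accounts for it. Squared genotype correlations are binned by distance, each
bin mean is corrected for finite sample size (1/(2n) for unphased
genotypes, 1/n for phased haplotypes), and each bin yields one point of a
trajectory: N_e(t) = (1/(4 c)) (1/r2_adj - alpha) at t = 1/(2 c)
generations in the past.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import GenotypePanel, MISSING

#: default genetic-map scale, Morgans per bp (1 cM/Mb)
DEFAULT_RECOMB_RATE = 1e-8


def pairwise_r2(panel: GenotypePanel, population: str | None = None,
                max_dist_bp: int = 5_000_000,
                min_dist_bp: int = 0) -> pd.DataFrame:
    """Squared genotype correlations for intra-chromosomal SNP pairs.

    Returns a DataFrame ``dist_bp, r2`` for every pair of SNPs on the same
    chromosome whose distance is within ``(min_dist_bp, max_dist_bp]``,
    using samples non-missing at both SNPs; monomorphic SNPs are skipped.
    """
    geno = (panel.genotypes if population is None
            else panel.pop_matrix(population))
    chrom_all = panel.markers["chrom"].to_numpy()
    pos_all = panel.markers["pos_bp"].to_numpy()
    dists: list[np.ndarray] = []
    r2s: list[np.ndarray] = []
    for ch in np.unique(chrom_all):
        sel = chrom_all == ch
        g = geno[:, sel].astype(float)
        pos = pos_all[sel]
        g[g == MISSING] = np.nan
        with np.errstate(invalid="ignore"):
            sd = np.nanstd(g, axis=0)
        poly = sd > 0
        g, pos = g[:, poly], pos[poly]
        m = g.shape[1]
        if m < 2:
            continue
        if not np.isnan(g).any():
            z = (g - g.mean(axis=0)) / g.std(axis=0)
            r = (z.T @ z) / g.shape[0]
        else:
            r = _pairwise_complete_corr(g)
        iu, ju = np.triu_indices(m, k=1)
        d = pos[ju] - pos[iu]
        keep = (d <= max_dist_bp) & (d > min_dist_bp)
        rv = r[iu[keep], ju[keep]]
        ok = np.isfinite(rv)
        dists.append(d[keep][ok])
        r2s.append(rv[ok] ** 2)
    if not dists:
        return pd.DataFrame(columns=["dist_bp", "r2"])
    return pd.DataFrame({"dist_bp": np.concatenate(dists),
                         "r2": np.concatenate(r2s)})


def _pairwise_complete_corr(g: np.ndarray) -> np.ndarray:
    """Correlation matrix over pairwise-complete observations (NaN-aware)."""
    m = g.shape[1]
    r = np.full((m, m), np.nan)
    for i in range(m):
        xi = g[:, i]
        for j in range(i + 1, m):
            xj = g[:, j]
            ok = ~np.isnan(xi) & ~np.isnan(xj)
            if ok.sum() < 2:
                continue
            a, b = xi[ok], xj[ok]
            sa, sb = a.std(), b.std()
            if sa == 0 or sb == 0:
                continue
            r[i, j] = ((a - a.mean()) * (b - b.mean())).mean() / (sa * sb)
    return r


def _map_to_morgans(dist_bp: np.ndarray, recomb_rate: float,
                    mapping: str) -> np.ndarray:
    """bp -> recombination fraction c (Morgans for small c)."""
    d = np.asarray(dist_bp, dtype=float) * recomb_rate
    if mapping == "linear":
        return d
    if mapping == "haldane":
        return 0.5 * (1 - np.exp(-2 * d))
    if mapping == "sved":
        return d / (1 + 2 * d)  # Sved & Feldman 1973
    raise ValueError(f"unknown mapping {mapping!r}")


def default_bins_bp(low_bp: int = 50_000, high_bp: int = 5_000_000,
                    n_bins: int = 30) -> np.ndarray:
    """Log-spaced distance bin edges in bp (30 bins over 50 kb - 5 Mb)."""
    return np.geomspace(low_bp, high_bp, n_bins + 1)


def estimate_ne(pairs: pd.DataFrame, n_samples: int,
                bins_bp: np.ndarray | None = None,
                recomb_rate: float = DEFAULT_RECOMB_RATE,
                alpha: float = 2.0, mapping: str = "linear",
                phased: bool = False) -> pd.DataFrame:
    """Effective-population-size trajectory from binned LD.

    Parameters
    ----------
    pairs
        ``dist_bp, r2`` pairs from :func:`pairwise_r2` (order irrelevant).
    n_samples
        Number of genotyped individuals behind the r2 values; sets the
        finite-sample correction 1/(2n) (or 1/n when ``phased``).
    alpha
        Sved constant: 2 (default) accounts for mutation, 1 ignores it.

    Returns one row per retained bin with columns ``c_low, c_high, mean_c,
    mean_r2, mean_r2_adj, n_pairs, t, ne``; bins whose adjusted mean r2
    would give a non-positive Ne are dropped.
    """
    if recomb_rate <= 0:
        raise ValueError("recomb_rate must be positive")
    if len(pairs) == 0:
        raise ValueError("no SNP pairs supplied")
    if bins_bp is None:
        bins_bp = default_bins_bp()
    c = _map_to_morgans(pairs["dist_bp"].to_numpy(), recomb_rate, mapping)
    r2 = pairs["r2"].to_numpy(dtype=float)
    edges = _map_to_morgans(np.asarray(bins_bp, dtype=float), recomb_rate,
                            mapping)
    idx = np.digitize(c, edges) - 1
    corr = (1.0 / n_samples) if phased else 1.0 / (2 * n_samples)
    rows = []
    for b in range(len(edges) - 1):
        in_bin = idx == b
        n_pairs = int(in_bin.sum())
        if n_pairs == 0:
            continue
        mean_c = float(c[in_bin].mean())
        mean_r2 = float(r2[in_bin].mean())
        r2_adj = mean_r2 - corr
        if r2_adj <= 0 or 1.0 / r2_adj <= alpha:
            continue  # Ne undefined in this bin
        ne = (1.0 / (4 * mean_c)) * (1.0 / r2_adj - alpha)
        rows.append((edges[b], edges[b + 1], mean_c, mean_r2, r2_adj,
                     n_pairs, 1.0 / (2 * mean_c), ne))
    return pd.DataFrame(rows, columns=[
        "c_low", "c_high", "mean_c", "mean_r2", "mean_r2_adj", "n_pairs",
        "t", "ne"])


def ne_trajectory(panel: GenotypePanel, population: str,
                  max_dist_bp: int = 5_000_000,
                  min_dist_bp: int = 50_000,
                  recomb_rate: float = DEFAULT_RECOMB_RATE,
                  alpha: float = 2.0, mapping: str = "linear",
                  phased: bool = False,
                  bins_bp: np.ndarray | None = None) -> pd.DataFrame:
    """Convenience wrapper: r2 pairs then :func:`estimate_ne` for one breed."""
    pairs = pairwise_r2(panel, population, max_dist_bp=max_dist_bp,
                        min_dist_bp=min_dist_bp)
    n = len(panel.pop_samples(population))
    if bins_bp is None:
        bins_bp = default_bins_bp(max(min_dist_bp, 1), max_dist_bp)
    return estimate_ne(pairs, n, bins_bp=bins_bp, recomb_rate=recomb_rate,
                       alpha=alpha, mapping=mapping, phased=phased)
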