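import numpy as np
import pandas as pd
import pytest

from rohpop.io import GenotypePanel


def make_panel(geno, chrom=None, pos=None, populations=None, samples=None):
    """Build a GenotypePanel from a genotype matrix and optional map info."""
    geno = np.asarray(geno, dtype=np.int8)
    n, m = geno.shape
    chrom = np.asarray(chrom) if chrom is not None else np.ones(m, dtype=int)
    if pos is None:
        pos = np.zeros(m, dtype=int)
        for c in np.unique(chrom):
            sel = chrom == c
            pos[sel] = 10_000 * (np.arange(sel.sum()) + 1)
    markers = pd.DataFrame({
        "snp_id": [f"s{k}" for k in range(m)],
        "chrom": chrom,
        "pos_bp": np.asarray(pos),
        "allele_a": "A",
        "allele_b": "G",
    })
    if samples is None:
        samples = [f"ind{i}" for i in range(n)]
    if populations is None:
        populations = {s: "POP" for s in samples}
    elif isinstance(populations, (list, tuple)):
        populations = dict(zip(samples, populations))
    return GenotypePanel(markers, list(samples), populations, geno)


def random_panel(rng, n_samples=6, n_snps=60, n_chrom=2, missing_rate=0.05,
                 n_pops=1, hom_bias=0.0):
    """Random panel; hom_bias > 0 enriches homozygous calls (for ROH tests)."""
    probs = np.array([1, 1, 1], dtype=float)
    probs[0] += hom_bias
    probs[2] += hom_bias
    probs /= probs.sum()
    geno = rng.choice([0, 1, 2], size=(n_samples, n_snps), p=probs)
    geno[rng.random(geno.shape) < missing_rate] = -1
    chrom = np.sort(rng.integers(1, n_chrom + 1, size=n_snps))
    pos = np.zeros(n_snps, dtype=int)
    for c in np.unique(chrom):
        sel = chrom == c
        pos[sel] = np.sort(rng.choice(
            np.arange(1, 5_000_000, 7), size=sel.sum(), replace=False))
    if n_pops == 1:
        pops = ["POP"] * n_samples
    else:
        pops = [f"P{1 + i * n_pops // n_samples}" for i in range(n_samples)]
    return make_panel(geno, chrom=chrom, pos=pos, populations=pops)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
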