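"""Forward-time multi-breed simulator with exact autozygosity ground truth.

Each breed starts from a pool of founder haplotypes whose allele frequencies
are drawn around a shared ancestral frequency under the Balding-Nichols
model (Beta with parameters p(1-theta)/theta, (1-p)(1-theta)/theta), so the
expected multi-locus Weir-Cockerham F_ST between breeds is approximately
``theta_fst``. Discrete generations of random mating follow, with crossover
counts Poisson(recomb_rate x chrom_length) per transmitted chromosome.
Every transmitted chromosome is stored as a piecewise map from base-pair
intervals to founder-haplotype ids, so true autozygous (IBD) segments --
intervals where an individual's two haplotypes descend from the same founder
haplotype -- are exact, and genotypes inside them are homozygous by
construction (no genotyping error unless added explicitly).

Two mating systems are available:

* ``"monogamous"`` (default): parents are shuffled into disjoint pairs and
  each offspring is produced by one random pair; selfing is impossible.
* ``"random"``: Wright-Fisher random union of gametes (selfing allowed), for
  which the classical recursion F_t = 1 - (1 - 1/(2N))^t holds exactly in
  expectation.

Pedigree inbreeding coefficients are computed from the realized pedigree by
the standard kinship recursion, so ``TruthSet.pedigree_f`` is the exact
expectation of the autozygous genome fraction for each simulated bird.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import GenotypePanel


@dataclass
class SimConfig:
    """Scenario description for :func:`simulate_breed`.

    Defaults emulate a small-scale heritage-breed panel: seven breeds of 25
    birds genotyped at 2,000 SNPs on each of five 20-Mb autosomes, founded
    from 50 birds 20 generations ago, contracted to 10 breeding birds for
    the last decade of generations with a final sampled cohort of 25, and
    breed differentiation theta = 0.3.
    """

    n_breeds: int = 7
    n_per_breed: int = 25
    n_chrom: int = 5
    chrom_length_bp: int = 20_000_000
    n_snps_per_chrom: int = 2_000
    founder_haplotypes: int = 100
    generations: int = 20
    bottleneck_schedule: list[tuple[int, int]] = field(
        default_factory=lambda: [(11, 10), (20, 25)])
    theta_fst: float = 0.3
    recomb_rate: float = 1e-8  # Morgans per bp
    seed: int = 0
    mating: str = "monogamous"  # or "random"
    snp_grid: str = "uniform"   # or "fixed" (evenly spaced, for oracles)

    def __post_init__(self) -> None:
        for name in ("n_breeds", "n_per_breed", "n_chrom", "chrom_length_bp",
                     "n_snps_per_chrom", "founder_haplotypes", "generations"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.theta_fst < 1:
            raise ValueError("theta_fst must be in [0, 1)")
        if self.founder_haplotypes % 2:
            raise ValueError("founder_haplotypes must be even")
        if self.mating not in ("monogamous", "random"):
            raise ValueError("mating must be 'monogamous' or 'random'")
        for gen, size in self.bottleneck_schedule:
            if not 1 <= gen <= self.generations:
                raise ValueError("schedule generation outside [1, generations]")
            if size < 2:
                raise ValueError("population size < 2 in bottleneck schedule")

    def sizes(self) -> list[int]:
        """Population size for generations 1..generations."""
        size = self.founder_haplotypes // 2
        sched = dict(self.bottleneck_schedule)
        out = []
        for g in range(1, self.generations + 1):
            size = sched.get(g, size)
            out.append(size)
        return out

    def to_dict(self) -> dict:
        d = asdict(self)
        d["bottleneck_schedule"] = [list(x) for x in self.bottleneck_schedule]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        d["bottleneck_schedule"] = [tuple(x) for x in
                                    d.get("bottleneck_schedule", [])]
        return cls(**d)


@dataclass
class TruthSet:
    """Simulation ground truth.

    ibd_segments : DataFrame(sample, chrom, start_bp, end_bp) of autozygous
        intervals (1-based inclusive), non-overlapping per sample/chromosome.
    pedigree_f : Series sample -> expected autozygous genome fraction.
    true_freqs : (n_breeds, n_snps) allele-B frequencies per breed.
    breeds : breed labels indexing true_freqs rows.
    """

    ibd_segments: pd.DataFrame
    pedigree_f: pd.Series
    true_freqs: np.ndarray
    breeds: list[str]

    def realized_autozygosity(self, genome_length_bp: int) -> pd.Series:
        """Per-sample total IBD length / genome length."""
        tot = self.ibd_segments.assign(
            length=lambda d: d.end_bp - d.start_bp + 1
        ).groupby("sample")["length"].sum()
        out = tot.reindex(self.pedigree_f.index, fill_value=0)
        return out / genome_length_bp


# ---------------------------------------------------------------------------
# Balding-Nichols breed frequencies
# ---------------------------------------------------------------------------

def draw_breed_frequencies(ancestral_freqs: np.ndarray, theta_fst: float,
                           n_breeds: int, seed) -> np.ndarray:
    """Per-breed allele frequencies under the Balding-Nichols model.

    ``theta_fst = 0`` returns the ancestral frequencies unchanged (the
    exact limit of the Beta distribution as theta -> 0).
    """
    p = np.asarray(ancestral_freqs, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("ancestral frequencies must be in (0, 1)")
    if not 0 <= theta_fst < 1:
        raise ValueError("theta_fst must be in [0, 1)")
    if theta_fst == 0:
        return np.tile(p, (n_breeds, 1))
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    scale = (1 - theta_fst) / theta_fst
    return rng.beta(p * scale, (1 - p) * scale, size=(n_breeds, p.size))


# ---------------------------------------------------------------------------
# Haplotype machinery: piecewise founder-id maps
# ---------------------------------------------------------------------------
# A haplotype on one chromosome is (starts, ids): segment k covers
# [starts[k], starts[k+1]-1] (1-based, inclusive; sentinel L+1 at the end)
# and carries founder-haplotype id ids[k].

def _founder_hap(founder_id: int, length: int):
    return (np.array([1, length + 1], dtype=np.int64),
            np.array([founder_id], dtype=np.int64))


def _slice_hap(hap, lo: int, hi: int):
    """Segments of ``hap`` restricted to [lo, hi] (inclusive)."""
    starts, ids = hap
    i = np.searchsorted(starts, lo, side="right") - 1
    j = np.searchsorted(starts, hi, side="right")
    s = starts[i:j].copy()
    s[0] = lo
    return s, ids[i:j].copy()


def _meiosis(hap_a, hap_b, length: int, recomb_rate: float,
             rng: np.random.Generator):
    """One gamete from two parental haplotypes.

    Crossover count ~ Poisson(recomb_rate * length); positions uniform;
    the starting haplotype is chosen at random.
    """
    n_x = rng.poisson(recomb_rate * length)
    first = rng.integers(2)
    if n_x == 0:
        starts, ids = (hap_a, hap_b)[first]
        return starts.copy(), ids.copy()
    xs = np.unique(rng.integers(2, length + 1, size=n_x))
    bounds = np.concatenate(([1], xs, [length + 1]))
    seg_starts: list[np.ndarray] = []
    seg_ids: list[np.ndarray] = []
    for k in range(len(bounds) - 1):
        src = (hap_a, hap_b)[(first + k) % 2]
        s, ids = _slice_hap(src, int(bounds[k]), int(bounds[k + 1]) - 1)
        seg_starts.append(s)
        seg_ids.append(ids)
    starts0 = np.concatenate(seg_starts)
    ids0 = np.concatenate(seg_ids)
    change = np.concatenate(([True], ids0[1:] != ids0[:-1]))
    return (np.concatenate([starts0[change], [length + 1]]).astype(np.int64),
            ids0[change].astype(np.int64))


def _ibd_intervals(hap1, hap2, length: int):
    """Intervals (start, end) where both haplotypes share a founder id."""
    s1, i1 = hap1
    s2, i2 = hap2
    bounds = np.unique(np.concatenate([s1, s2]))
    lo = bounds[:-1]
    id_a = i1[np.searchsorted(s1, lo, side="right") - 1]
    id_b = i2[np.searchsorted(s2, lo, side="right") - 1]
    same = id_a == id_b
    out = []
    k = 0
    while k < len(same):
        if same[k]:
            j = k
            while j + 1 < len(same) and same[j + 1]:
                j += 1
            out.append((int(bounds[k]), int(bounds[j + 1]) - 1))
            k = j + 1
        else:
            k += 1
    return out


# ---------------------------------------------------------------------------
# Pedigree bookkeeping
# ---------------------------------------------------------------------------

def _kinship_forward(pedigree: list[np.ndarray], n_founders: int
                     ) -> np.ndarray:
    """Inbreeding coefficients of the final generation.

    ``pedigree[g]`` holds, for each individual of generation g+1, the pair
    (sire index, dam index) into the previous generation. Founders are
    non-inbred and unrelated.
    """
    K = np.full((n_founders, n_founders), 0.0)
    np.fill_diagonal(K, 0.5)
    F = np.zeros(n_founders)
    for parents in pedigree:
        p1 = parents[:, 0]
        p2 = parents[:, 1]
        F = K[p1, p2]
        Knew = 0.25 * (K[np.ix_(p1, p1)] + K[np.ix_(p1, p2)]
                       + K[np.ix_(p2, p1)] + K[np.ix_(p2, p2)])
        np.fill_diagonal(Knew, 0.5 * (1 + F))
        K = Knew
    return F


def _choose_parents(n_parents: int, n_offspring: int, mating: str,
                    rng: np.random.Generator) -> np.ndarray:
    """(n_offspring, 2) parent index pairs under the mating system."""
    if mating == "random":
        return rng.integers(n_parents, size=(n_offspring, 2))
    # monogamous disjoint pairs; an odd last parent sits out
    perm = rng.permutation(n_parents)
    n_pairs = n_parents // 2
    pairs = perm[: 2 * n_pairs].reshape(n_pairs, 2)
    pick = rng.integers(n_pairs, size=n_offspring)
    return pairs[pick]


# ---------------------------------------------------------------------------
# Main simulation
# ---------------------------------------------------------------------------

def simulate_breed(config: SimConfig) -> tuple[GenotypePanel, TruthSet]:
    """Simulate all breeds of ``config`` and return panel plus ground truth.

    Pure function of the config (including its seed): identical configs give
    bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    L = config.chrom_length_bp
    m = config.n_snps_per_chrom

    # marker map, shared across breeds
    pos_by_chrom = []
    for _ in range(config.n_chrom):
        if config.snp_grid == "fixed":
            pos = np.linspace(1, L, m).astype(np.int64)
        else:
            pool = np.unique(rng.integers(1, L + 1, size=2 * m))
            while len(pool) < m:  # only if SNPs nearly saturate the chromosome
                pool = np.unique(np.concatenate(
                    [pool, rng.integers(1, L + 1, size=m)]))
            pos = np.sort(rng.choice(pool, size=m, replace=False))
        pos_by_chrom.append(pos.astype(np.int64))
    markers = pd.DataFrame({
        "snp_id": [f"snp{c + 1}_{k + 1}" for c in range(config.n_chrom)
                   for k in range(m)],
        "chrom": np.repeat(np.arange(1, config.n_chrom + 1), m),
        "pos_bp": np.concatenate(pos_by_chrom),
        "allele_a": "A",
        "allele_b": "B",
    })
    n_snps_total = config.n_chrom * m

    ancestral = rng.uniform(0.05, 0.95, size=n_snps_total)
    breed_freqs = draw_breed_frequencies(ancestral, config.theta_fst,
                                         config.n_breeds, rng)
    breeds = [f"B{b + 1}" for b in range(config.n_breeds)]

    samples: list[str] = []
    populations: dict[str, str] = {}
    geno_rows: list[np.ndarray] = []
    ibd_rows: list[tuple] = []
    ped_f: dict[str, float] = {}

    sizes = config.sizes()
    n_founders = config.founder_haplotypes // 2

    for b, breed in enumerate(breeds):
        # founder haplotype alleles: (2*n_founders, n_snps)
        founder_alleles = (rng.random((config.founder_haplotypes,
                                       n_snps_total))
                           < breed_freqs[b]).astype(np.int8)
        # population: per individual, per chromosome, two haplotypes
        pop = [[(_founder_hap(2 * i, L), _founder_hap(2 * i + 1, L))
                for _ in range(config.n_chrom)]
               for i in range(n_founders)]
        pedigree: list[np.ndarray] = []
        for size in sizes:
            parents = _choose_parents(len(pop), size, config.mating, rng)
            pedigree.append(parents)
            new_pop = []
            for p1, p2 in parents:
                child = []
                for c in range(config.n_chrom):
                    g1 = _meiosis(*pop[p1][c], L, config.recomb_rate, rng)
                    g2 = _meiosis(*pop[p2][c], L, config.recomb_rate, rng)
                    child.append((g1, g2))
                new_pop.append(child)
            pop = new_pop

        f_final = _kinship_forward(pedigree, n_founders)
        n_take = min(config.n_per_breed, len(pop))
        take = rng.choice(len(pop), size=n_take, replace=False)
        take.sort()
        for rank, idx in enumerate(take):
            sid = f"{breed}_S{rank + 1:03d}"
            samples.append(sid)
            populations[sid] = breed
            ped_f[sid] = float(f_final[idx])
            geno = np.empty(n_snps_total, dtype=np.int8)
            for c in range(config.n_chrom):
                pos = pos_by_chrom[c]
                sl = slice(c * m, (c + 1) * m)
                h1, h2 = pop[idx][c]
                fid1 = h1[1][np.searchsorted(h1[0], pos, side="right") - 1]
                fid2 = h2[1][np.searchsorted(h2[0], pos, side="right") - 1]
                col = np.arange(sl.start, sl.stop)
                geno[sl] = (founder_alleles[fid1, col]
                            + founder_alleles[fid2, col])
                for start, end in _ibd_intervals(h1, h2, L):
                    # drop segments shorter than one SNP interval
                    k0 = np.searchsorted(pos, start, side="left")
                    k1 = np.searchsorted(pos, end, side="right")
                    if k1 - k0 >= 2:
                        ibd_rows.append((sid, c + 1, start, end))
            geno_rows.append(geno)

    panel = GenotypePanel(markers, samples, populations,
                          np.vstack(geno_rows))
    truth = TruthSet(
        ibd_segments=pd.DataFrame(
            ibd_rows, columns=["sample", "chrom", "start_bp", "end_bp"]),
        pedigree_f=pd.Series(ped_f, name="pedigree_f"),
        true_freqs=breed_freqs,
        breeds=breeds,
    )
    return panel, truth


def panel_from_frequencies(breed_freqs: np.ndarray, n_per_breed: int,
                           seed=0, chrom: int = 1,
                           spacing_bp: int = 10_000) -> GenotypePanel:
    """Hardy-Weinberg genotype panel drawn directly from per-breed allele
    frequencies (no pedigree, no linkage): genotype ~ Binomial(2, p).

    Useful for calibration tests of frequency-based estimators where drift
    and LD would confound the expectation.
    """
    freqs = np.atleast_2d(np.asarray(breed_freqs, dtype=float))
    n_breeds, m = freqs.shape
    rng = np.random.default_rng(seed)
    geno = np.concatenate(
        [rng.binomial(2, freqs[b], size=(n_per_breed, m)).astype(np.int8)
         for b in range(n_breeds)])
    markers = pd.DataFrame({
        "snp_id": [f"snp{k + 1}" for k in range(m)],
        "chrom": chrom,
        "pos_bp": spacing_bp * np.arange(1, m + 1),
        "allele_a": "A",
        "allele_b": "B",
    })
    samples = [f"B{b + 1}_S{i + 1:03d}" for b in range(n_breeds)
               for i in range(n_per_breed)]
    populations = {s: s.split("_")[0] for s in samples}
    return GenotypePanel(markers, samples, populations, geno)


def add_genotyping_noise(panel: GenotypePanel, het_error: float = 0.0,
                         missing_rate: float = 0.0, seed=0) -> GenotypePanel:
    """Flip homozygous calls to heterozygous with probability ``het_error``
    and set cells missing with probability ``missing_rate`` (independently).
    """
    if not (0 <= het_error < 1 and 0 <= missing_rate < 1):
        raise ValueError("rates must be in [0, 1)")
    geno = panel.genotypes.copy()
    rng = np.random.default_rng(seed)
    if het_error > 0:
        hom = (geno == 0) | (geno == 2)
        flip = hom & (rng.random(geno.shape) < het_error)
        geno[flip] = 1
    if missing_rate > 0:
        geno[rng.random(geno.shape) < missing_rate] = -1
    return GenotypePanel(panel.markers.copy(), list(panel.samples),
                         dict(panel.populations), geno)
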