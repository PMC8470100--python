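"""Consecutive-run detection of runs of homozygosity (ROH), length-class
binning, per-population summaries and the F_ROH genomic inbreeding
coefficient.

A run grows over consecutive homozygous SNPs along a chromosome and is
terminated by a heterozygous call (once ``max_het`` is exhausted), a missing
call (once ``max_missing`` is exhausted), or an inter-SNP gap larger than
``max_gap_bp``; a gap splits the run without disqualifying its flanks. A
terminated run is emitted iff it contains at least ``min_snps`` SNPs and
spans at least ``min_length_bp``, with boundaries at its first and last
member SNP and length = end - start + 1 (inclusive). Defaults are the
conventional SNP-array settings for avian/livestock panels: >=1 Mb, >=150
SNPs, no heterozygous or missing calls, gap <= 1 Mb.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import GenotypePanel, MISSING

#: total autosomal length covered by the reference turkey SNP dataset (bp)
DEFAULT_GENOME_LENGTH_BP = 902_020_024

LENGTH_CLASSES = ("1-2", "2-4", "4-8", "8-16", "16+")

SEGMENT_COLUMNS = ["sample", "chrom", "start_bp", "end_bp", "n_snps",
                   "length_bp"]


@dataclass
class RohParams:
    min_length_bp: int = 1_000_000
    min_snps: int = 150
    max_het: int = 0
    max_missing: int = 0
    max_gap_bp: int = 1_000_000

    def __post_init__(self) -> None:
        if min(self.min_length_bp, self.min_snps, self.max_het,
               self.max_missing, self.max_gap_bp) < 0:
            raise ValueError("ROH parameters must be non-negative")


def _trim(idx_geno: np.ndarray, lo: int, hi: int) -> tuple[int, int]:
    """Shrink [lo, hi] so the run starts and ends on a homozygous SNP."""
    hom = (idx_geno == 0) | (idx_geno == 2)
    while lo <= hi and not hom[lo]:
        lo += 1
    while hi >= lo and not hom[hi]:
        hi -= 1
    return lo, hi


def detect_roh(panel: GenotypePanel, sample: str,
               params: RohParams | None = None) -> pd.DataFrame:
    """Detect ROH for one sample; returns a segment DataFrame with columns
    ``sample, chrom, start_bp, end_bp, n_snps, length_bp``, sorted and
    non-overlapping within each chromosome.

    With ``max_het``/``max_missing`` > 0 the scan is greedy: a run absorbs
    up to that many heterozygous/missing calls before the next one closes
    it; run boundaries are always homozygous SNPs.
    """
    params = params or RohParams()
    gi = panel.sample_index(sample)
    geno_all = panel.genotypes[gi]
    chrom_all = panel.markers["chrom"].to_numpy()
    pos_all = panel.markers["pos_bp"].to_numpy()
    rows: list[tuple] = []
    for chrom in np.unique(chrom_all):
        sel = chrom_all == chrom
        pos = pos_all[sel]
        geno = geno_all[sel]
        n = len(pos)
        lo = 0
        het_used = miss_used = 0
        k = 0

        def close(lo, hi):
            lo, hi = _trim(geno, lo, hi)
            if hi < lo:
                return
            n_snps = hi - lo + 1
            length = int(pos[hi] - pos[lo] + 1)
            if n_snps >= params.min_snps and length >= params.min_length_bp:
                rows.append((sample, int(chrom), int(pos[lo]), int(pos[hi]),
                             n_snps, length))

        while k < n:
            g = geno[k]
            gap_break = k > lo and pos[k] - pos[k - 1] > params.max_gap_bp
            if gap_break:
                close(lo, k - 1)
                lo, het_used, miss_used = k, 0, 0
                continue  # re-examine SNP k as a run start
            if g == 1:
                if het_used < params.max_het:
                    het_used += 1
                else:
                    close(lo, k - 1)
                    lo, het_used, miss_used = k + 1, 0, 0
            elif g == MISSING:
                if miss_used < params.max_missing:
                    miss_used += 1
                else:
                    close(lo, k - 1)
                    lo, het_used, miss_used = k + 1, 0, 0
            k += 1
        close(lo, n - 1)
    return pd.DataFrame(rows, columns=SEGMENT_COLUMNS)


def detect_roh_all(panel: GenotypePanel,
                   params: RohParams | None = None) -> pd.DataFrame:
    """ROH segments for every sample, concatenated."""
    parts = [detect_roh(panel, s, params) for s in panel.samples]
    if not parts:
        return pd.DataFrame(columns=SEGMENT_COLUMNS)
    return pd.concat(parts, ignore_index=True)


def bin_length_class(length_bp: int) -> str:
    """Length class of a segment: [1,2), [2,4), [4,8), [8,16) Mb, else 16+."""
    mb = length_bp / 1_000_000
    if mb < 1:
        raise ValueError("ROH shorter than 1 Mb cannot be classified")
    for hi, label in ((2, "1-2"), (4, "2-4"), (8, "4-8"), (16, "8-16")):
        if mb < hi:
            return label
    return "16+"


@dataclass
class RohSummary:
    population: str
    n_samples: int
    total_roh: int
    min_count: int
    max_count: int
    mean_count: float
    sd_count: float
    min_length_bp: int
    max_length_bp: int
    mean_length_bp: float
    mean_coverage_bp: float
    mean_coverage_pct: float
    class_counts: dict[str, int]

    def to_frame(self) -> pd.DataFrame:
        d = {k: v for k, v in vars(self).items() if k != "class_counts"}
        for label in LENGTH_CLASSES:
            d[f"n_{label}Mb"] = self.class_counts.get(label, 0)
        return pd.DataFrame([d])


def summarize_roh(segments: pd.DataFrame, samples: list[str],
                  genome_length_bp: int = DEFAULT_GENOME_LENGTH_BP,
                  population: str = "ALL") -> RohSummary:
    """Descriptive ROH statistics for one population.

    ``samples`` is the full population sample list; samples without any
    segment contribute zero to the per-animal counts and coverage. Count and
    coverage dispersion use the sample standard deviation (ddof=1).
    """
    if not samples:
        raise ValueError("empty population")
    seg = segments[segments["sample"].isin(samples)]
    counts = seg.groupby("sample").size().reindex(samples, fill_value=0)
    cover = seg.groupby("sample")["length_bp"].sum().reindex(samples,
                                                             fill_value=0)
    total = int(len(seg))
    classes = {label: 0 for label in LENGTH_CLASSES}
    for length in seg["length_bp"]:
        classes[bin_length_class(int(length))] += 1
    mean_cov = float(cover.mean())
    return RohSummary(
        population=population,
        n_samples=len(samples),
        total_roh=total,
        min_count=int(counts.min()),
        max_count=int(counts.max()),
        mean_count=float(counts.mean()),
        sd_count=float(counts.std(ddof=1)) if len(samples) > 1 else 0.0,
        min_length_bp=int(seg["length_bp"].min()) if total else 0,
        max_length_bp=int(seg["length_bp"].max()) if total else 0,
        mean_length_bp=float(seg["length_bp"].mean()) if total else 0.0,
        mean_coverage_bp=mean_cov,
        mean_coverage_pct=100.0 * mean_cov / genome_length_bp,
        class_counts=classes,
    )


def f_roh(segments: pd.DataFrame, sample: str,
          genome_length_bp: int = DEFAULT_GENOME_LENGTH_BP) -> float:
    """Genomic inbreeding of one sample: summed ROH length over the
    SNP-covered autosomal genome length."""
    if genome_length_bp <= 0:
        raise ValueError("genome_length_bp must be positive")
    seg = segments[segments["sample"] == sample]
    return float(seg["length_bp"].sum() / genome_length_bp)


def f_roh_table(segments: pd.DataFrame, samples: list[str],
                genome_length_bp: int = DEFAULT_GENOME_LENGTH_BP
                ) -> pd.DataFrame:
    """Per-sample F_ROH table (sample, sum_roh_bp, genome_length_bp, f_roh)."""
    sums = (segments.groupby("sample")["length_bp"].sum()
            .reindex(samples, fill_value=0))
    return pd.DataFrame({
        "sample": samples,
        "sum_roh_bp": sums.to_numpy(),
        "genome_length_bp": genome_length_bp,
        "f_roh": sums.to_numpy() / genome_length_bp,
    })


def froh_vs_fhom(f_roh_values, f_hom_values) -> dict[str, float]:
    """Ordinary least squares of F_HOM on F_ROH plus Pearson correlation.

    Returns ``{"slope", "intercept", "r", "n"}``. Raises on fewer than three
    pairs or zero variance in either variable.
    """
    x = np.asarray(f_roh_values, dtype=float)
    y = np.asarray(f_hom_values, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >=3 paired inbreeding values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in F_ROH or F_HOM")
    res = stats.linregress(x, y)
    return {"slope": float(res.slope), "intercept": float(res.intercept),
            "r": float(res.rvalue), "n": int(x.size)}


def segments_to_bed(segments: pd.DataFrame, path) -> None:
    """Export segments as BED (0-based half-open), name = sample id."""
    bed = pd.DataFrame({
        "chrom": segments["chrom"],
        "start": segments["start_bp"] - 1,
        "end": segments["end_bp"],
        "name": segments["sample"],
    })
    bed.to_csv(path, sep="\t", index=False, header=False)
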