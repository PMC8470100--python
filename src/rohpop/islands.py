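"""ROH incidence tracks, ROH_island calling, cross-population sharing and
gene-interval annotation.

An ROH_island is an exact-boundary homozygous region: a (chrom, start, end)
triple shared as an identical ROH by at least a threshold fraction of a
population's samples (default 75%). An incidence-based caller (maximal SNP
runs whose coverage meets the threshold) is available for Manhattan-style
analyses. All coordinates are 1-based inclusive; overlap means >=1 shared
base pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class RohIsland:
    population: str
    chrom: int
    start_bp: int
    end_bp: int
    n_samples_sharing: int
    threshold_used: float

    def to_tuple(self):
        return (self.population, self.chrom, self.start_bp, self.end_bp,
                self.n_samples_sharing, self.threshold_used)


def islands_to_frame(islands: list[RohIsland]) -> pd.DataFrame:
    return pd.DataFrame(
        [i.to_tuple() for i in islands],
        columns=["population", "chrom", "start_bp", "end_bp",
                 "n_samples_sharing", "threshold_used"])


def sharing_threshold(n: int, fraction: float) -> int:
    """Smallest integer >= fraction * n (e.g. 75% of 181 birds -> 136).

    Products within 1e-9 of an integer are snapped to it first, so binary
    floating-point representations of fractions like 0.60 cannot push the
    ceiling up a unit.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    x = fraction * n
    nearest = round(x)
    if abs(x - nearest) < 1e-9:
        return int(nearest)
    return int(math.ceil(x))


def incidence(segments: pd.DataFrame, markers: pd.DataFrame,
              population_size: int) -> pd.DataFrame:
    """Per-SNP count (and fraction) of samples whose ROH covers the SNP.

    Returns a DataFrame ``snp_id, chrom, pos_bp, count, fraction`` aligned
    with the marker map. A sample contributes at most 1 per SNP.
    """
    chrom = markers["chrom"].to_numpy()
    pos = markers["pos_bp"].to_numpy()
    count = np.zeros(len(markers), dtype=np.int64)
    for ch, grp in segments.groupby("chrom"):
        sel = np.flatnonzero(chrom == ch)
        if sel.size == 0:
            continue
        cpos = pos[sel]
        lo = np.searchsorted(cpos, grp["start_bp"].to_numpy(), side="left")
        hi = np.searchsorted(cpos, grp["end_bp"].to_numpy(), side="right")
        # per-sample coverage mask, so overlapping segments of one sample
        # still count that sample once per SNP
        for sample_lo_hi in pd.DataFrame(
                {"sample": grp["sample"].to_numpy(), "lo": lo,
                 "hi": hi}).groupby("sample"):
            covered = np.zeros(sel.size, dtype=bool)
            for a, b in zip(sample_lo_hi[1]["lo"], sample_lo_hi[1]["hi"]):
                covered[a:b] = True
            count[sel] += covered
    return pd.DataFrame({
        "snp_id": markers["snp_id"],
        "chrom": chrom,
        "pos_bp": pos,
        "count": count,
        "fraction": count / population_size,
    })


def find_islands(segments: pd.DataFrame, population_size: int,
                 fraction: float = 0.75, population: str = "ALL",
                 method: str = "exact",
                 markers: pd.DataFrame | None = None) -> list[RohIsland]:
    """Call ROH_islands for one population.

    ``method="exact"`` (default) groups segments by identical
    (chrom, start_bp, end_bp) and keeps groups whose distinct-sample count
    reaches :func:`sharing_threshold`. ``method="incidence"`` instead calls
    maximal runs of consecutive SNPs whose incidence count reaches the
    threshold (requires ``markers``); boundaries are the first/last SNP of
    the run. Output is sorted by genome position.
    """
    need = sharing_threshold(population_size, fraction)
    out: list[RohIsland] = []
    if method == "exact":
        if len(segments):
            grouped = (segments.groupby(["chrom", "start_bp", "end_bp"])
                       ["sample"].nunique())
            for (ch, start, end), n_shared in grouped.items():
                if n_shared >= need:
                    out.append(RohIsland(population, int(ch), int(start),
                                         int(end), int(n_shared), fraction))
    elif method == "incidence":
        if markers is None:
            raise ValueError("incidence method requires markers")
        track = incidence(segments, markers, population_size)
        for ch, grp in track.groupby("chrom", sort=True):
            hot = (grp["count"] >= need).to_numpy()
            pos = grp["pos_bp"].to_numpy()
            cnt = grp["count"].to_numpy()
            k = 0
            while k < len(hot):
                if hot[k]:
                    j = k
                    while j + 1 < len(hot) and hot[j + 1]:
                        j += 1
                    out.append(RohIsland(
                        population, int(ch), int(pos[k]), int(pos[j]),
                        int(cnt[k:j + 1].min()), fraction))
                    k = j + 1
                else:
                    k += 1
    else:
        raise ValueError(f"unknown island method {method!r}")
    out.sort(key=lambda i: (i.chrom, i.start_bp, i.end_bp))
    return out


def cross_breed_sharing(islands_by_pop: dict[str, list[RohIsland]]
                        ) -> pd.DataFrame:
    """Merge islands from different populations into shared regions.

    Islands whose intervals overlap by >=1 bp are merged transitively; each
    output row reports the union boundaries, the contributing populations
    (comma-separated, sorted) and the island count. Rows are sorted by
    genome position.
    """
    if len(islands_by_pop) < 2:
        raise ValueError("need islands from >=2 populations")
    rows = [(isl.chrom, isl.start_bp, isl.end_bp, pop)
            for pop, isls in islands_by_pop.items() for isl in isls]
    rows.sort()
    merged: list[list] = []  # [chrom, start, end, set(pops), n]
    for ch, start, end, pop in rows:
        if merged and merged[-1][0] == ch and start <= merged[-1][2]:
            merged[-1][2] = max(merged[-1][2], end)
            merged[-1][3].add(pop)
            merged[-1][4] += 1
        else:
            merged.append([ch, start, end, {pop}, 1])
    return pd.DataFrame(
        [(ch, s, e, ",".join(sorted(pops)), len(pops), n)
         for ch, s, e, pops, n in merged],
        columns=["chrom", "start_bp", "end_bp", "populations",
                 "n_populations", "n_islands"])


# ---------------------------------------------------------------------------
# Gene annotation
# ---------------------------------------------------------------------------

def _norm_chrom(label) -> int:
    s = str(label)
    if s.lower().startswith("chr"):
        s = s[3:]
    return int(s)


def read_gene_table(path) -> pd.DataFrame:
    """Read a gene interval table.

    ``.bed`` files are 0-based half-open (chrom, start, end, name) and are
    converted to 1-based inclusive; anything else is a 4-column TSV with a
    header (gene, chrom, start_bp, end_bp), 1-based inclusive.
    """
    if str(path).endswith(".bed"):
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["chrom", "start", "end", "gene"])
        return pd.DataFrame({
            "gene": df["gene"],
            "chrom": df["chrom"].map(_norm_chrom),
            "start_bp": df["start"] + 1,
            "end_bp": df["end"],
        })
    df = pd.read_csv(path, sep="\t")
    df = df.rename(columns={c: c.lower() for c in df.columns})
    out = df[["gene", "chrom", "start_bp", "end_bp"]].copy()
    out["chrom"] = out["chrom"].map(_norm_chrom)
    return out


def annotate_islands(islands: list[RohIsland], genes: pd.DataFrame
                     ) -> pd.DataFrame:
    """Intersect islands with gene intervals (>=1 bp overlap, 1-based
    inclusive, intersectBed semantics).

    Returns one row per (island, gene) hit with gene order following genome
    position. Raises if chromosome labels in the gene table cannot be
    matched to integer autosome labels.
    """
    bad = []
    chroms = []
    for label in genes["chrom"]:
        try:
            chroms.append(_norm_chrom(label))
        except (ValueError, TypeError):
            bad.append(label)
    if bad:
        raise ValueError(f"unmatched chromosome labels in gene table: "
                         f"{sorted(set(map(str, bad)))}")
    g = genes.assign(chrom=chroms).sort_values(
        ["chrom", "start_bp", "end_bp"], kind="mergesort")
    rows = []
    for isl in islands:
        sub = g[(g["chrom"] == isl.chrom)
                & (g["start_bp"] <= isl.end_bp)
                & (g["end_bp"] >= isl.start_bp)]
        for gene in sub.itertuples(index=False):
            rows.append((isl.population, isl.chrom, isl.start_bp, isl.end_bp,
                         gene.gene, gene.start_bp, gene.end_bp))
    return pd.DataFrame(rows, columns=[
        "population", "chrom", "island_start_bp", "island_end_bp",
        "gene", "gene_start_bp", "gene_end_bp"])
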