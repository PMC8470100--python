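"""Genotype panel container, PLINK text PED/MAP I/O and SNP quality control.

Conventions used throughout the package:

* genotypes are coded ``0`` (homozygous for allele A), ``1`` (heterozygous),
  ``2`` (homozygous for allele B) and ``-1`` (missing);
* base-pair coordinates are 1-based and inclusive; BED export converts to
  0-based half-open;
* autosomes are integer chromosome labels, 1..30 after QC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

MARKER_COLUMNS = ["snp_id", "chrom", "pos_bp", "allele_a", "allele_b"]


class PedParseError(ValueError):
    """Malformed PED/MAP input."""


@dataclass
class QcReport:
    """Reconciliation of a SNP quality-control pass."""

    n_snps_in: int
    n_snps_out: int
    n_removed_nonautosomal: int
    n_removed_callrate: int
    callrate_threshold: float

    def __post_init__(self) -> None:
        removed = self.n_removed_nonautosomal + self.n_removed_callrate
        if self.n_snps_out != self.n_snps_in - removed:
            raise ValueError("QcReport counts do not reconcile")
        if min(self.n_snps_in, self.n_snps_out,
               self.n_removed_nonautosomal, self.n_removed_callrate) < 0:
            raise ValueError("QcReport counts must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(self)])


@dataclass
class GenotypePanel:
    """Samples x SNPs diploid genotype matrix with marker map and labels.

    Parameters
    ----------
    markers
        DataFrame with columns ``snp_id, chrom, pos_bp, allele_a, allele_b``,
        sorted by ``(chrom, pos_bp)``.
    samples
        Sample identifiers, one per matrix row.
    populations
        Mapping sample id -> population label.
    genotypes
        ``(n_samples, n_snps)`` int8 array coded 0/1/2/-1.
    """

    markers: pd.DataFrame
    samples: list[str]
    populations: dict[str, str]
    genotypes: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.markers = self.markers.reset_index(drop=True)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.validate()

    # -- basic shape ---------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.markers)

    @property
    def population_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(self.populations[s], None)
        return list(seen)

    def validate(self) -> None:
        if list(self.markers.columns[:5]) != MARKER_COLUMNS:
            raise ValueError(f"marker map must have columns {MARKER_COLUMNS}")
        if self.genotypes.shape != (len(self.samples), len(self.markers)):
            raise ValueError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"{len(self.samples)} samples x {len(self.markers)} SNPs")
        bad = ~np.isin(self.genotypes, (-1, 0, 1, 2))
        if bad.any():
            raise ValueError("genotype codes must be in {-1, 0, 1, 2}")
        missing_pop = [s for s in self.samples if s not in self.populations]
        if missing_pop:
            raise ValueError(f"samples without population label: {missing_pop}")
        if self.markers["snp_id"].duplicated().any():
            raise ValueError("duplicate snp_id in marker map")
        chrom = self.markers["chrom"].to_numpy()
        pos = self.markers["pos_bp"].to_numpy()
        order = np.lexsort((pos, chrom))
        if not np.array_equal(order, np.arange(len(order))):
            warnings.warn("marker map was unsorted; sorting by (chrom, pos_bp)")
            self.markers = self.markers.iloc[order].reset_index(drop=True)
            self.genotypes = self.genotypes[:, order]
            chrom, pos = chrom[order], pos[order]
        dup = (np.diff(chrom) == 0) & (np.diff(pos) == 0)
        if dup.any():
            warnings.warn(f"{int(dup.sum())} duplicate positions in marker map")

    # -- selection helpers ---------------------------------------------
    def sample_index(self, sample: str) -> int:
        return self.samples.index(sample)

    def pop_samples(self, population: str) -> list[str]:
        return [s for s in self.samples if self.populations[s] == population]

    def pop_matrix(self, population: str) -> np.ndarray:
        idx = [i for i, s in enumerate(self.samples)
               if self.populations[s] == population]
        if not idx:
            raise KeyError(f"no samples in population {population!r}")
        return self.genotypes[idx]

    def subset_snps(self, mask: np.ndarray) -> "GenotypePanel":
        mask = np.asarray(mask, dtype=bool)
        return GenotypePanel(self.markers.loc[mask].reset_index(drop=True),
                             list(self.samples), dict(self.populations),
                             self.genotypes[:, mask])

    def subset_samples(self, keep: list[str]) -> "GenotypePanel":
        idx = [self.samples.index(s) for s in keep]
        return GenotypePanel(self.markers.copy(), list(keep),
                             {s: self.populations[s] for s in keep},
                             self.genotypes[idx])

    def equals(self, other: "GenotypePanel") -> bool:
        return (self.samples == other.samples
                and self.populations == other.populations
                and self.markers[MARKER_COLUMNS].equals(other.markers[MARKER_COLUMNS])
                and np.array_equal(self.genotypes, other.genotypes))


# ---------------------------------------------------------------------------
# PLINK text PED/MAP
# ---------------------------------------------------------------------------

def read_ped_map(ped_path, map_path, allele_ref: pd.DataFrame | None = None
                 ) -> GenotypePanel:
    """Read a whitespace-separated PLINK text fileset.

    The PED family id becomes the population label. Alleles are recoded to
    0/1/2 with ``allele_a`` = first allele encountered per marker, unless
    ``allele_ref`` (DataFrame with snp_id/allele_a/allele_b) pins the coding.
    Missing alleles are "0"; a half-missing genotype is treated as missing.
    """
    mp = pd.read_csv(map_path, sep=r"\s+", header=None,
                     names=["chrom", "snp_id", "cm", "pos_bp"],
                     dtype={"chrom": int, "snp_id": str, "pos_bp": int})
    n_snps = len(mp)
    ref_a: list[str | None]
    ref_b: list[str | None]
    if allele_ref is not None:
        ref = allele_ref.set_index("snp_id")
        ref_a = [ref.at[s, "allele_a"] for s in mp["snp_id"]]
        ref_b = [ref.at[s, "allele_b"] for s in mp["snp_id"]]
    else:
        ref_a = [None] * n_snps
        ref_b = [None] * n_snps

    samples: list[str] = []
    populations: dict[str, str] = {}
    rows: list[np.ndarray] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * n_snps:
                raise PedParseError(
                    f"PED line {lineno}: expected {6 + 2 * n_snps} fields "
                    f"for {n_snps} markers, got {len(fields)}")
            fam, iid = fields[0], fields[1]
            samples.append(iid)
            populations[iid] = fam
            geno = np.empty(n_snps, dtype=np.int8)
            alleles = fields[6:]
            for j in range(n_snps):
                a1, a2 = alleles[2 * j], alleles[2 * j + 1]
                if a1 == "0" or a2 == "0":
                    geno[j] = MISSING
                    continue
                code = 0
                for a in (a1, a2):
                    if ref_a[j] is None:
                        ref_a[j] = a
                    if a == ref_a[j]:
                        continue
                    if ref_b[j] is None:
                        ref_b[j] = a
                    if a == ref_b[j]:
                        code += 1
                    else:
                        raise PedParseError(
                            f"marker {mp['snp_id'][j]!r}: allele {a!r} not in "
                            f"{{{ref_a[j]!r}, {ref_b[j]!r}}} (PED line {lineno})")
                geno[j] = code
            rows.append(geno)

    markers = pd.DataFrame({
        "snp_id": mp["snp_id"],
        "chrom": mp["chrom"],
        "pos_bp": mp["pos_bp"],
        "allele_a": [a if a is not None else "A" for a in ref_a],
        "allele_b": [b if b is not None else "B" for b in ref_b],
    })
    geno_mat = (np.vstack(rows) if rows
                else np.empty((0, n_snps), dtype=np.int8))
    return GenotypePanel(markers, samples, populations, geno_mat)


def write_ped_map(panel: GenotypePanel, ped_path, map_path) -> None:
    """Write a panel as PLINK-compatible text; missing genotypes as "0 0"."""
    with open(map_path, "w") as fh:
        for row in panel.markers.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.snp_id}\t0\t{row.pos_bp}\n")
    aa = panel.markers["allele_a"].to_numpy()
    bb = panel.markers["allele_b"].to_numpy()
    lookup = np.stack([
        np.char.add(np.char.add(aa.astype(str), " "), aa.astype(str)),
        np.char.add(np.char.add(aa.astype(str), " "), bb.astype(str)),
        np.char.add(np.char.add(bb.astype(str), " "), bb.astype(str)),
        np.full(panel.n_snps, "0 0"),
    ])
    with open(ped_path, "w") as fh:
        for i, sample in enumerate(panel.samples):
            geno = panel.genotypes[i].copy()
            geno[geno == MISSING] = 3
            prefix = f"{panel.populations[sample]} {sample} 0 0 0 -9"
            body = " ".join(lookup[geno, np.arange(panel.n_snps)])
            fh.write(prefix + (" " + body if panel.n_snps else "") + "\n")


# ---------------------------------------------------------------------------
# Native TSV genotype matrix
# ---------------------------------------------------------------------------

def write_genotype_tsv(panel: GenotypePanel, geno_path, map_path=None) -> None:
    """Native format: sample, population, then one column per snp_id."""
    df = pd.DataFrame(panel.genotypes, columns=panel.markers["snp_id"])
    df.insert(0, "population", [panel.populations[s] for s in panel.samples])
    df.insert(0, "sample", panel.samples)
    df.to_csv(geno_path, sep="\t", index=False)
    if map_path is not None:
        panel.markers.to_csv(map_path, sep="\t", index=False)


def read_genotype_tsv(geno_path, map_path) -> GenotypePanel:
    geno = pd.read_csv(geno_path, sep="\t", dtype={"sample": str})
    markers = pd.read_csv(map_path, sep="\t",
                          dtype={"snp_id": str, "allele_a": str, "allele_b": str})
    samples = geno["sample"].tolist()
    populations = dict(zip(samples, geno["population"].astype(str)))
    mat = geno[markers["snp_id"]].to_numpy(dtype=np.int8)
    return GenotypePanel(markers, samples, populations, mat)


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------

def qc_filter(panel: GenotypePanel, callrate_min: float = 0.99,
              autosome_max: int = 30) -> tuple[GenotypePanel, QcReport]:
    """Retain autosomal SNPs (chrom in [1, autosome_max]) with call rate
    strictly greater than ``callrate_min``.

    The call-rate inequality is strict: a SNP at exactly the threshold is
    removed. Marker order is preserved and the returned report reconciles
    counts exactly. Idempotent.
    """
    if not 0 <= callrate_min <= 1:
        raise ValueError("callrate_min must be in [0, 1]")
    chrom = panel.markers["chrom"].to_numpy()
    autosomal = (chrom >= 1) & (chrom <= autosome_max)
    n = panel.n_samples
    if n == 0:
        callrate = np.ones(panel.n_snps)
    else:
        callrate = (panel.genotypes != MISSING).sum(axis=0) / n
    good_rate = callrate > callrate_min
    keep = autosomal & good_rate
    n_nonauto = int((~autosomal).sum())
    n_callrate = int((autosomal & ~good_rate).sum())
    report = QcReport(
        n_snps_in=panel.n_snps,
        n_snps_out=int(keep.sum()),
        n_removed_nonautosomal=n_nonauto,
        n_removed_callrate=n_callrate,
        callrate_threshold=callrate_min,
    )
    return panel.subset_snps(keep), report
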