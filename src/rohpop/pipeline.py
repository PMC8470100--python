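"""End-to-end analysis pipeline: QC -> diversity -> structure -> ROH ->
islands -> inbreeding -> Ne, from a PED/MAP fileset or a simulated panel.

Outputs are plain TSV/BED/Newick files under an output directory, plus a
``manifest.json`` with sha256 checksums; given the same inputs and seed the
numeric outputs are byte-identical (fixed float formatting).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import diversity, io, islands, ne, roh, structure
from .sim import SimConfig, simulate_breed

log = logging.getLogger("rohpop")

FLOAT_FMT = "%.8g"


class RunConfig:
    """Validated pipeline configuration.

    Exactly one of ``ped``/``map`` input paths or a ``simulate`` block (a
    :class:`~rohpop.sim.SimConfig` mapping) must be present.
    """

    def __init__(self, *, outdir, ped=None, map=None, simulate=None,
                 seed: int = 0, callrate_min: float = 0.99,
                 autosome_max: int = 30,
                 roh_params: dict | None = None,
                 island_threshold: float = 0.75,
                 genome_length_bp: int | None = None,
                 ne_settings: dict | None = None):
        has_files = ped is not None or map is not None
        if has_files == (simulate is not None):
            raise ValueError(
                "config must contain exactly one of ped/map or simulate")
        if has_files and (ped is None or map is None):
            raise ValueError("both ped and map paths are required")
        self.outdir = Path(outdir)
        self.ped, self.map = ped, map
        self.seed = int(seed)
        if simulate is not None:
            simulate = dict(simulate)
            simulate.setdefault("seed", self.seed)
            self.simulate = SimConfig.from_dict(simulate)
        else:
            self.simulate = None
        self.callrate_min = callrate_min
        self.autosome_max = autosome_max
        self.roh_params = roh.RohParams(**(roh_params or {}))
        self.island_threshold = island_threshold
        self.genome_length_bp = genome_length_bp
        self.ne_settings = ne_settings or {}

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ValueError("config file must contain a mapping")
        return cls(**data)

    def resolved_genome_length(self) -> int:
        if self.genome_length_bp is not None:
            return self.genome_length_bp
        if self.simulate is not None:
            return self.simulate.n_chrom * self.simulate.chrom_length_bp
        return roh.DEFAULT_GENOME_LENGTH_BP


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path, manifest: dict,
           index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT)
    manifest[path.name] = _sha256(path)


def run_pipeline(config: RunConfig) -> dict:
    """Run every analysis stage; returns (and writes) the output manifest.

    An optional stage that fails on the data at hand (e.g. Ne with too few
    informative pairs) is logged and skipped; the run continues.
    """
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    if config.simulate is not None:
        panel, truth = simulate_breed(config.simulate)
        _write(truth.ibd_segments, out / "truth_ibd_segments.tsv", manifest)
        _write(truth.pedigree_f.rename_axis("sample").reset_index(),
               out / "truth_pedigree_f.tsv", manifest)
    else:
        panel = io.read_ped_map(config.ped, config.map)

    unlabelled = [s for s in panel.samples if s not in panel.populations]
    if unlabelled:
        raise ValueError(f"samples without population label: {unlabelled}")

    # --- QC ---------------------------------------------------------------
    panel, qc_report = io.qc_filter(panel, config.callrate_min,
                                    config.autosome_max)
    log.info("QC: %d -> %d SNPs (removed %d non-autosomal, %d call-rate)",
             qc_report.n_snps_in, qc_report.n_snps_out,
             qc_report.n_removed_nonautosomal, qc_report.n_removed_callrate)
    _write(qc_report.to_frame(), out / "qc_report.tsv", manifest)
    io.write_genotype_tsv(panel, out / "genotypes.tsv", out / "markers.tsv")
    manifest["genotypes.tsv"] = _sha256(out / "genotypes.tsv")
    manifest["markers.tsv"] = _sha256(out / "markers.tsv")

    pops = panel.population_labels
    genome_length = config.resolved_genome_length()

    # --- diversity + F_HOM -------------------------------------------------
    _write(diversity.diversity_table(panel), out / "diversity.tsv", manifest)
    fhom = diversity.f_hom_all(panel)
    _write(fhom, out / "fhom.tsv", manifest)

    # --- structure ---------------------------------------------------------
    if len(pops) >= 2:
        _write(structure.fst_matrix(panel), out / "fst_matrix.tsv", manifest,
               index=True)
    dist = structure.ibs_distance(panel)
    _write(dist, out / "ibs_distance.tsv", manifest, index=True)
    if panel.n_samples >= 3:
        tree = structure.nj_tree(dist)
        (out / "nj_tree.nwk").write_text(tree.to_newick() + "\n")
        manifest["nj_tree.nwk"] = _sha256(out / "nj_tree.nwk")
    try:
        pca = structure.pca_scores(panel, n_components=10)
        scores = pca.scores.copy()
        scores.insert(0, "population",
                      [panel.populations[s] for s in scores.index])
        _write(scores.rename_axis("sample").reset_index(),
               out / "pca_scores.tsv", manifest)
        _write(pd.DataFrame({"eigenvalue": pca.eigenvalues[
                   :len(pca.percent_variance)],
                             "percent_variance": pca.percent_variance}),
               out / "pca_eigenvalues.tsv", manifest)
    except ValueError as exc:
        log.warning("PCA skipped: %s", exc)

    # --- ROH ---------------------------------------------------------------
    segments = roh.detect_roh_all(panel, config.roh_params)
    _write(segments, out / "roh_segments.tsv", manifest)
    roh.segments_to_bed(segments, out / "roh_segments.bed")
    manifest["roh_segments.bed"] = _sha256(out / "roh_segments.bed")
    summaries = pd.concat(
        [roh.summarize_roh(segments, panel.pop_samples(p), genome_length, p
                           ).to_frame() for p in pops], ignore_index=True)
    _write(summaries, out / "roh_summary.tsv", manifest)

    # --- inbreeding --------------------------------------------------------
    froh = roh.f_roh_table(segments, panel.samples, genome_length)
    froh.insert(1, "population",
                [panel.populations[s] for s in froh["sample"]])
    _write(froh, out / "froh.tsv", manifest)
    reg_rows = []
    merged = froh.merge(fhom, on=["sample", "population"])
    for p in pops:
        sub = merged[merged["population"] == p]
        try:
            res = roh.froh_vs_fhom(sub["f_roh"], sub["f_hom"])
            reg_rows.append({"population": p, **res})
        except ValueError as exc:
            log.warning("F_ROH~F_HOM regression skipped for %s: %s", p, exc)
    if reg_rows:
        _write(pd.DataFrame(reg_rows), out / "froh_fhom_regression.tsv",
               manifest)

    # --- incidence + islands ----------------------------------------------
    islands_by_pop: dict[str, list] = {}
    inc_parts = []
    for p in pops:
        pop_samples = panel.pop_samples(p)
        seg_p = segments[segments["sample"].isin(pop_samples)]
        inc = islands.incidence(seg_p, panel.markers, len(pop_samples))
        inc.insert(0, "population", p)
        inc_parts.append(inc)
        islands_by_pop[p] = islands.find_islands(
            seg_p, len(pop_samples), config.island_threshold, p)
    _write(pd.concat(inc_parts, ignore_index=True), out / "incidence.tsv",
           manifest)
    all_islands = [i for lst in islands_by_pop.values() for i in lst]
    _write(islands.islands_to_frame(all_islands), out / "islands.tsv",
           manifest)
    pooled = islands.find_islands(segments, panel.n_samples,
                                  config.island_threshold, "ALL")
    _write(islands.islands_to_frame(pooled), out / "islands_pooled.tsv",
           manifest)
    if len(pops) >= 2:
        shared = islands.cross_breed_sharing(islands_by_pop)
        _write(shared[shared["n_populations"] >= 2].reset_index(drop=True),
               out / "islands_shared.tsv", manifest)

    # --- Ne ----------------------------------------------------------------
    ne_parts = []
    for p in pops:
        try:
            traj = ne.ne_trajectory(panel, p, **config.ne_settings)
            if len(traj) == 0:
                log.warning("Ne skipped for %s: no informative bins", p)
                continue
            traj.insert(0, "population", p)
            ne_parts.append(traj)
        except ValueError as exc:
            log.warning("Ne skipped for %s: %s", p, exc)
    if ne_parts:
        _write(pd.concat(ne_parts, ignore_index=True),
               out / "ne_trajectory.tsv", manifest)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
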