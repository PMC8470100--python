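import numpy as np
import pandas as pd
import pytest

from rohpop.roh import (RohParams, bin_length_class, detect_roh,
                        detect_roh_all, f_roh, f_roh_table, froh_vs_fhom,
                        summarize_roh)

from _oracles import roh_oracle
from conftest import make_panel, random_panel


def one_sample_panel(geno, pos, chrom=None):
    geno = np.asarray([geno], dtype=np.int8)
    chrom = chrom if chrom is not None else np.ones(len(pos), dtype=int)
    return make_panel(geno, chrom=chrom, pos=pos)


class TestDetectRoh:
    def test_long_homozygous_run_single_segment(self):
        pos = 1_000_000 + np.arange(200) * 10_050  # spans ~2 Mb
        panel = one_sample_panel(np.zeros(200, dtype=np.int8), pos)
        seg = detect_roh(panel, "ind0", RohParams())
        assert len(seg) == 1
        row = seg.iloc[0]
        assert (row.start_bp, row.end_bp) == (pos[0], pos[-1])
        assert row.n_snps == 200
        assert row.length_bp == pos[-1] - pos[0] + 1

    def test_single_heterozygote_destroys_both_halves(self):
        pos = 1_000_000 + np.arange(200) * 10_050
        geno = np.zeros(200, dtype=np.int8)
        geno[100] = 1  # two candidate runs of ~100 SNPs < 150 each
        panel = one_sample_panel(geno, pos)
        assert len(detect_roh(panel, "ind0", RohParams())) == 0

    def test_large_gap_splits_run(self):
        # 300 homozygous SNPs with a 1,000,001 bp gap in the middle
        left = 1_000_000 + np.arange(150) * 10_000
        right = left[-1] + 1_000_001 + np.arange(150) * 10_000
        pos = np.concatenate([left, right])
        panel = one_sample_panel(np.full(300, 2, dtype=np.int8), pos)
        seg = detect_roh(panel, "ind0", RohParams())
        assert len(seg) == 2
        assert seg.iloc[0].end_bp == left[-1]
        assert seg.iloc[1].start_bp == right[0]

    def test_gap_exactly_at_threshold_does_not_split(self):
        left = 1_000_000 + np.arange(150) * 10_000
        right = left[-1] + 1_000_000 + np.arange(150) * 10_000
        pos = np.concatenate([left, right])
        panel = one_sample_panel(np.zeros(300, dtype=np.int8), pos)
        assert len(detect_roh(panel, "ind0", RohParams())) == 1

    def test_min_length_uses_snp_span(self):
        # 160 SNPs in only 900 kb: enough SNPs, too short a span
        pos = 1_000_000 + np.arange(160) * 5_000
        panel = one_sample_panel(np.zeros(160, dtype=np.int8), pos)
        assert len(detect_roh(panel, "ind0", RohParams())) == 0

    def test_runs_never_span_chromosomes(self):
        pos = np.concatenate([1_000_000 + np.arange(100) * 10_000] * 2)
        chrom = np.repeat([1, 2], 100)
        panel = one_sample_panel(np.zeros(200, dtype=np.int8), pos, chrom)
        seg = detect_roh(panel, "ind0",
                         RohParams(min_snps=50, min_length_bp=500_000))
        assert len(seg) == 2
        assert set(seg["chrom"]) == {1, 2}

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        panel = random_panel(rng, n_samples=4, n_snps=250, n_chrom=2,
                             missing_rate=0.03, hom_bias=6.0)
        params = RohParams(min_length_bp=int(rng.integers(1, 400_000)),
                           min_snps=int(rng.integers(2, 25)),
                           max_gap_bp=int(rng.integers(50_000, 2_000_000)))
        for sample in panel.samples:
            seg = detect_roh(panel, sample, params)
            got = sorted((int(r.chrom), int(r.start_bp), int(r.end_bp),
                          int(r.n_snps), int(r.length_bp))
                         for r in seg.itertuples())
            i = panel.sample_index(sample)
            expected = roh_oracle(panel.genotypes[i],
                                  panel.markers["pos_bp"].to_numpy(),
                                  panel.markers["chrom"].to_numpy(),
                                  params.min_length_bp, params.min_snps,
                                  params.max_gap_bp)
            assert got == expected

    def test_locality_under_appended_chromosome(self, rng):
        panel = random_panel(rng, n_samples=3, n_snps=200, n_chrom=1,
                             hom_bias=6.0)
        params = RohParams(min_snps=10, min_length_bp=100_000)
        base = detect_roh(panel, "ind0", params)
        extra_geno = np.hstack([panel.genotypes,
                                rng.choice([0, 1, 2], size=(3, 50))])
        chrom = np.concatenate([panel.markers["chrom"], np.full(50, 9)])
        pos = np.concatenate([panel.markers["pos_bp"],
                              10_000 * (np.arange(50) + 1)])
        bigger = make_panel(extra_geno.astype(np.int8), chrom=chrom, pos=pos)
        again = detect_roh(bigger, "ind0", params)
        assert base.equals(again[again["chrom"] != 9].reset_index(drop=True))

    def test_relaxing_min_snps_is_monotone(self, rng):
        panel = random_panel(rng, n_samples=5, n_snps=300, hom_bias=6.0)
        strict = RohParams(min_snps=20, min_length_bp=100_000)
        loose = RohParams(min_snps=10, min_length_bp=100_000)
        assert len(detect_roh_all(panel, loose)) >= \
            len(detect_roh_all(panel, strict))


class TestLengthClasses:
    @pytest.mark.parametrize("length,label", [
        (1_500_000, "1-2"),
        (2_000_000, "2-4"),          # boundary: left-closed
        (3_999_999, "2-4"),
        (4_000_000, "4-8"),
        (14_291_629, "8-16"),        # longest run in the reference panel
        (16_000_000, "16+"),
    ])
    def test_binning(self, length, label):
        assert bin_length_class(length) == label

    def test_sub_megabase_rejected(self):
        with pytest.raises(ValueError):
            bin_length_class(999_999)


def seg_frame(rows):
    return pd.DataFrame(rows, columns=["sample", "chrom", "start_bp",
                                       "end_bp", "n_snps", "length_bp"])


class TestSummaries:
    def test_single_sample_single_roh(self):
        seg = seg_frame([("s1", 1, 1_000_000, 2_999_999, 200, 2_000_000)])
        s = summarize_roh(seg, ["s1"], genome_length_bp=100_000_000)
        assert s.total_roh == 1 and s.mean_count == 1
        assert s.mean_coverage_pct == pytest.approx(2.0)
        assert s.class_counts["2-4"] == 1

    def test_samples_without_roh_count_as_zero(self):
        seg = seg_frame([("s1", 1, 1_000_000, 2_999_999, 200, 2_000_000)])
        s = summarize_roh(seg, ["s1", "s2"], genome_length_bp=100_000_000)
        assert s.min_count == 0 and s.max_count == 1
        assert s.mean_count == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_flat_recount(self, seed):
        rng = np.random.default_rng(seed)
        samples = [f"s{i}" for i in range(6)]
        rows = []
        for _ in range(rng.integers(5, 40)):
            start = int(rng.integers(1, 50_000_000))
            length = int(rng.integers(1_000_000, 17_000_000))
            rows.append((samples[rng.integers(6)], int(rng.integers(1, 5)),
                         start, start + length - 1, 100, length))
        seg = seg_frame(rows)
        s = summarize_roh(seg, samples, genome_length_bp=902_020_024)
        counts = [sum(1 for r in rows if r[0] == smp) for smp in samples]
        lengths = [r[5] for r in rows]
        assert s.total_roh == len(rows)
        assert s.mean_count == pytest.approx(np.mean(counts))
        assert s.sd_count == pytest.approx(np.std(counts, ddof=1))
        assert s.min_length_bp == min(lengths)
        assert s.max_length_bp == max(lengths)
        assert s.mean_length_bp == pytest.approx(np.mean(lengths))
        assert sum(s.class_counts.values()) == s.total_roh
        per_sample = [sum(r[5] for r in rows if r[0] == smp)
                      for smp in samples]
        assert s.mean_coverage_bp == pytest.approx(np.mean(per_sample))


class TestFroh:
    def test_no_segments_zero(self):
        assert f_roh(seg_frame([]), "s1") == 0.0

    def test_whole_genome_is_one(self):
        seg = seg_frame([("s1", 1, 1, 902_020_024, 1, 902_020_024)])
        assert f_roh(seg, "s1") == pytest.approx(1.0)

    def test_table_aligns_samples(self):
        seg = seg_frame([("s2", 1, 1_000_000, 2_999_999, 10, 2_000_000)])
        tab = f_roh_table(seg, ["s1", "s2"], genome_length_bp=10_000_000)
        assert tab.set_index("sample")["f_roh"].tolist() == [0.0, 0.2]


class TestFrohVsFhom:
    def test_identity_gives_unit_slope_and_r(self):
        x = np.array([0.1, 0.2, 0.3, 0.4])
        res = froh_vs_fhom(x, x)
        assert res["slope"] == pytest.approx(1.0)
        assert res["r"] == pytest.approx(1.0)

    def test_matches_hand_computed_ols(self):
        # five pairs; slope/intercept/r from the closed-form normal equations
        x = np.array([0.05, 0.10, 0.20, 0.30, 0.40])
        y = np.array([-0.10, 0.00, 0.05, 0.18, 0.25])
        sxx = ((x - x.mean()) ** 2).sum()
        sxy = ((x - x.mean()) * (y - y.mean())).sum()
        syy = ((y - y.mean()) ** 2).sum()
        res = froh_vs_fhom(x, y)
        assert res["slope"] == pytest.approx(sxy / sxx)
        assert res["intercept"] == pytest.approx(y.mean()
                                                 - sxy / sxx * x.mean())
        assert res["r"] == pytest.approx(sxy / np.sqrt(sxx * syy))

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            froh_vs_fhom([0.1, 0.1, 0.1], [0.0, 0.1, 0.2])
        with pytest.raises(ValueError):
            froh_vs_fhom([0.1, 0.2], [0.0, 0.1])
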