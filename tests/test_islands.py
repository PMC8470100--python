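import numpy as np
import pandas as pd
import pytest

from rohpop.islands import (RohIsland, annotate_islands, cross_breed_sharing,
                            find_islands, incidence, islands_to_frame,
                            read_gene_table, sharing_threshold)

from _oracles import incidence_oracle, island_grouping_oracle


def seg_frame(rows):
    return pd.DataFrame(rows, columns=["sample", "chrom", "start_bp",
                                       "end_bp", "n_snps", "length_bp"])


def marker_frame(chrom, pos):
    return pd.DataFrame({
        "snp_id": [f"s{k}" for k in range(len(pos))],
        "chrom": chrom, "pos_bp": pos, "allele_a": "A", "allele_b": "G"})


def random_segments(rng, n_samples=10, n_dup_groups=4):
    """Segment set with deliberately duplicated exact boundaries."""
    rows = []
    for _ in range(n_dup_groups):
        ch = int(rng.integers(1, 4))
        start = int(rng.integers(1, 5_000_000))
        end = start + int(rng.integers(1_000_000, 3_000_000))
        for i in rng.choice(n_samples, size=rng.integers(1, n_samples + 1),
                            replace=False):
            rows.append((f"s{i}", ch, start, end, 100, end - start + 1))
    for _ in range(rng.integers(0, 10)):  # unique singletons
        ch = int(rng.integers(1, 4))
        start = int(rng.integers(1, 8_000_000))
        end = start + int(rng.integers(1_000_000, 2_000_000))
        rows.append((f"s{int(rng.integers(n_samples))}", ch, start, end,
                     100, end - start + 1))
    return seg_frame(rows)


class TestSharingThreshold:
    @pytest.mark.parametrize("n,fraction,expected", [
        (181, 0.75, 136),   # pooled panel at 75%
        (25, 0.60, 15),     # relaxed 60% threshold for a 25-bird breed
        (4, 0.75, 3),
        (24, 0.75, 18),     # exact product stays (no spurious ceiling)
        (10, 1.0, 10),
    ])
    def test_printed_thresholds(self, n, fraction, expected):
        assert sharing_threshold(n, fraction) == expected

    @pytest.mark.parametrize("n", [1, 7, 22, 181])
    @pytest.mark.parametrize("fraction", [0.1, 0.25, 0.6, 0.75, 0.9, 1.0])
    def test_is_smallest_integer_at_least_fraction_n(self, n, fraction):
        k = sharing_threshold(n, fraction)
        assert k - 1 < fraction * n <= k + 1e-9

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            sharing_threshold(0, 0.75)
        with pytest.raises(ValueError):
            sharing_threshold(10, 0.0)


class TestIncidence:
    def test_no_segments_all_zero(self):
        markers = marker_frame(np.ones(5, int), [10, 20, 30, 40, 50])
        track = incidence(seg_frame([]), markers, 10)
        assert (track["count"] == 0).all()

    def test_single_roh_covers_exact_snp_range(self):
        markers = marker_frame(np.ones(6, int), [10, 20, 30, 40, 50, 60])
        seg = seg_frame([("s1", 1, 20, 45, 3, 26)])
        track = incidence(seg, markers, 4)
        assert track["count"].tolist() == [0, 1, 1, 1, 0, 0]
        assert track["fraction"].tolist() == [0, 0.25, 0.25, 0.25, 0, 0]

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_containment_scan(self, seed):
        rng = np.random.default_rng(seed)
        chrom = np.sort(rng.integers(1, 4, size=40))
        pos = np.zeros(40, int)
        for c in np.unique(chrom):
            sel = chrom == c
            pos[sel] = np.sort(rng.choice(10_000_000, sel.sum(),
                                          replace=False)) + 1
        markers = marker_frame(chrom, pos)
        seg = random_segments(rng)
        track = incidence(seg, markers, 10)
        tuples = [(r.sample, r.chrom, r.start_bp, r.end_bp)
                  for r in seg.itertuples()]
        assert track["count"].tolist() == incidence_oracle(tuples, chrom, pos)


class TestFindIslands:
    def test_eight_of_ten_sharing_is_island(self):
        rows = [(f"s{i}", 3, 1_000_000, 2_500_000, 150, 1_500_001)
                for i in range(8)]
        isl = find_islands(seg_frame(rows), 10, 0.75, "POP")
        assert len(isl) == 1
        assert isl[0].n_samples_sharing == 8
        assert (isl[0].start_bp, isl[0].end_bp) == (1_000_000, 2_500_000)

    def test_seven_of_ten_is_not(self):
        rows = [(f"s{i}", 3, 1_000_000, 2_500_000, 150, 1_500_001)
                for i in range(7)]
        assert find_islands(seg_frame(rows), 10, 0.75) == []

    def test_lowering_threshold_never_removes_islands(self, rng):
        seg = random_segments(rng)
        high = {(i.chrom, i.start_bp, i.end_bp)
                for i in find_islands(seg, 10, 0.75)}
        low = {(i.chrom, i.start_bp, i.end_bp)
               for i in find_islands(seg, 10, 0.5)}
        assert high <= low

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_grouping_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        seg = random_segments(rng)
        need = sharing_threshold(10, 0.6)
        got = sorted(((i.chrom, i.start_bp, i.end_bp), i.n_samples_sharing)
                     for i in find_islands(seg, 10, 0.6))
        tuples = [(r.sample, r.chrom, r.start_bp, r.end_bp)
                  for r in seg.itertuples()]
        assert got == island_grouping_oracle(tuples, need)

    def test_island_implies_incidence_at_threshold(self, rng):
        seg = random_segments(rng, n_samples=10)
        chrom = np.sort(rng.integers(1, 4, size=60))
        pos = np.zeros(60, int)
        for c in np.unique(chrom):
            sel = chrom == c
            pos[sel] = np.sort(rng.choice(9_000_000, sel.sum(),
                                          replace=False)) + 1
        markers = marker_frame(chrom, pos)
        track = incidence(seg, markers, 10)
        for isl in find_islands(seg, 10, 0.6):
            inside = ((track["chrom"] == isl.chrom)
                      & (track["pos_bp"] >= isl.start_bp)
                      & (track["pos_bp"] <= isl.end_bp))
            assert (track.loc[inside, "count"] >= isl.n_samples_sharing).all()

    def test_incidence_method_calls_hot_runs(self):
        markers = marker_frame(np.ones(8, int),
                               [10, 20, 30, 40, 50, 60, 70, 80])
        rows = [(f"s{i}", 1, 15, 62, 5, 48) for i in range(8)]
        isl = find_islands(seg_frame(rows), 10, 0.75, method="incidence",
                           markers=markers)
        assert len(isl) == 1
        assert (isl[0].start_bp, isl[0].end_bp) == (20, 60)


class TestCrossBreedSharing:
    def island(self, pop, ch, s, e, n=8):
        return RohIsland(pop, ch, s, e, n, 0.75)

    def test_identical_interval_two_pops(self):
        shared = cross_breed_sharing({
            "A": [self.island("A", 1, 100, 200)],
            "B": [self.island("B", 1, 100, 200)]})
        assert len(shared) == 1
        row = shared.iloc[0]
        assert row.populations == "A,B" and row.n_populations == 2

    def test_disjoint_intervals_not_merged(self):
        shared = cross_breed_sharing({
            "A": [self.island("A", 1, 100, 200)],
            "B": [self.island("B", 1, 201, 300)]})
        assert (shared["n_populations"] == 1).all()

    def test_union_boundaries(self):
        shared = cross_breed_sharing({
            "A": [self.island("A", 2, 100, 250)],
            "B": [self.island("B", 2, 200, 400)]})
        merged = shared[shared["n_populations"] == 2].iloc[0]
        assert (merged.start_bp, merged.end_bp) == (100, 400)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_pairwise_overlap_union_find(self, seed):
        rng = np.random.default_rng(seed)
        by_pop = {}
        items = []
        for pop in "ABC":
            isls = []
            for _ in range(rng.integers(1, 6)):
                ch = int(rng.integers(1, 3))
                s = int(rng.integers(1, 2_000_000))
                e = s + int(rng.integers(100_000, 1_500_000))
                isls.append(self.island(pop, ch, s, e))
                items.append((pop, ch, s, e))
            by_pop[pop] = isls
        # oracle: union-find over pairwise >=1 bp overlaps
        parent = list(range(len(items)))

        def find(i):
            while parent[i] != i:
                i = parent[i]
            return i

        for i in range(len(items)):
            for j in range(i + 1, len(items)):
                a, b = items[i], items[j]
                if a[1] == b[1] and a[2] <= b[3] and b[2] <= a[3]:
                    parent[find(i)] = find(j)
        groups = {}
        for k, it in enumerate(items):
            groups.setdefault(find(k), []).append(it)
        expected = sorted(
            (g[0][1], min(x[2] for x in g), max(x[3] for x in g),
             ",".join(sorted({x[0] for x in g})))
            for g in groups.values())
        shared = cross_breed_sharing(by_pop)
        got = sorted(zip(shared["chrom"], shared["start_bp"],
                         shared["end_bp"], shared["populations"]))
        assert got == expected


class TestAnnotateIslands:
    def genes(self):
        return pd.DataFrame({
            "gene": ["PTGS2", "PLA2G4A", "KITLG"],
            "chrom": [10, 10, 1],
            "start_bp": [500_000, 1_200_000, 41_354_392],
            "end_bp": [520_000, 1_300_000, 41_408_938]})

    def test_gene_inside_island_reported(self):
        isl = [RohIsland("ALL", 10, 311_121, 1_681_212, 136, 0.75)]
        hits = annotate_islands(isl, self.genes())
        assert hits["gene"].tolist() == ["PTGS2", "PLA2G4A"]

    def test_abutting_gene_not_reported(self):
        isl = [RohIsland("A", 10, 100, 499_999, 8, 0.75)]
        hits = annotate_islands(isl, self.genes())
        assert len(hits) == 0
        isl = [RohIsland("A", 10, 100, 500_000, 8, 0.75)]  # 1 bp overlap
        assert len(annotate_islands(isl, self.genes())) == 1

    def test_unmatched_chromosome_labels_listed(self):
        genes = self.genes().astype({"chrom": object})
        genes.loc[0, "chrom"] = "chrUn_scaffold12"
        with pytest.raises(ValueError, match="chrUn_scaffold12"):
            annotate_islands([RohIsland("A", 1, 1, 2, 3, 0.75)], genes)

    def test_chr_prefix_accepted(self):
        genes = self.genes().astype({"chrom": str})
        genes["chrom"] = "chr" + genes["chrom"]
        isl = [RohIsland("ALL", 10, 311_121, 1_681_212, 136, 0.75)]
        assert len(annotate_islands(isl, genes)) == 2

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_quadratic_all_pairs(self, seed):
        rng = np.random.default_rng(seed)
        isls = [RohIsland("P", int(rng.integers(1, 4)),
                          s := int(rng.integers(1, 3_000_000)),
                          s + int(rng.integers(10_000, 2_000_000)), 5, 0.75)
                for _ in range(8)]
        genes = pd.DataFrame({
            "gene": [f"g{k}" for k in range(30)],
            "chrom": rng.integers(1, 4, size=30),
            "start_bp": (starts := rng.integers(1, 4_000_000, size=30)),
            "end_bp": starts + rng.integers(1_000, 800_000, size=30)})
        hits = annotate_islands(isls, genes)
        expected = set()
        for isl in isls:
            for g in genes.itertuples(index=False):
                if (g.chrom == isl.chrom and g.start_bp <= isl.end_bp
                        and g.end_bp >= isl.start_bp):
                    expected.add((isl.start_bp, isl.end_bp, g.gene))
        got = set(zip(hits["island_start_bp"], hits["island_end_bp"],
                      hits["gene"]))
        assert got == expected

    def test_bed_gene_table_converts_coordinates(self, tmp_path):
        bed = tmp_path / "genes.bed"
        bed.write_text("10\t499999\t520000\tPTGS2\n")  # 0-based half-open
        genes = read_gene_table(bed)
        assert genes.loc[0, "start_bp"] == 500_000
        assert genes.loc[0, "end_bp"] == 520_000

    def test_islands_frame_columns(self):
        df = islands_to_frame([RohIsland("A", 1, 10, 20, 8, 0.75)])
        assert df.loc[0, "n_samples_sharing"] == 8
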