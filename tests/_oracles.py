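"""Brute-force reference implementations used to validate the package.

These deliberately re-derive each quantity from first principles with
simple loops, independent of the vectorized code paths they check.
"""

import numpy as np


def roh_oracle(geno, pos, chrom, min_length_bp, min_snps, max_gap_bp):
    """Enumerate every candidate interval and keep valid, maximal runs.

    Assumes the no-heterozygote / no-missing rule (the default detection
    mode): a valid run is a set of consecutive SNPs, all homozygous, with
    every inter-SNP gap <= max_gap_bp, containing >= min_snps SNPs and
    spanning >= min_length_bp; emitted runs are maximal valid intervals.
    """
    out = []
    for ch in sorted(set(chrom)):
        idx = [k for k in range(len(pos)) if chrom[k] == ch]
        n = len(idx)

        def valid_core(i, j):
            """All genotypes homozygous and gaps fine on idx[i..j]."""
            for k in range(i, j + 1):
                if geno[idx[k]] not in (0, 2):
                    return False
            for k in range(i + 1, j + 1):
                if pos[idx[k]] - pos[idx[k - 1]] > max_gap_bp:
                    return False
            return True

        for i in range(n):
            for j in range(i, n):
                if not valid_core(i, j):
                    continue
                # maximality: cannot extend either way
                if i > 0 and valid_core(i - 1, j):
                    continue
                if j < n - 1 and valid_core(i, j + 1):
                    continue
                n_snps = j - i + 1
                length = pos[idx[j]] - pos[idx[i]] + 1
                if n_snps >= min_snps and length >= min_length_bp:
                    out.append((int(ch), int(pos[idx[i]]), int(pos[idx[j]]),
                                n_snps, int(length)))
    return sorted(out)


def diversity_oracle(geno):
    """Per-SNP recount: (n_called, p_hat, het_fraction) lists, loops only."""
    n, m = geno.shape
    stats = []
    for j in range(m):
        calls = [geno[i][j] for i in range(n) if geno[i][j] != -1]
        if not calls:
            stats.append(None)
            continue
        alt = sum(calls)
        het = sum(1 for g in calls if g == 1)
        stats.append((len(calls), alt / (2 * len(calls)), het / len(calls)))
    return stats


def fhom_oracle(geno):
    """Per-sample (o_hom, e_hom, l_typed, f_hom) by direct counting."""
    n, m = geno.shape
    per_snp = []
    for j in range(m):
        calls = [geno[i][j] for i in range(n) if geno[i][j] != -1]
        n_al = 2 * len(calls)
        if n_al < 2:
            per_snp.append(None)
            continue
        p = sum(calls) / n_al
        per_snp.append(1 - 2 * p * (1 - p) * n_al / (n_al - 1))
    out = []
    for i in range(n):
        o = e = l = 0
        for j in range(m):
            if geno[i][j] == -1 or per_snp[j] is None:
                continue
            l += 1
            e += per_snp[j]
            if geno[i][j] in (0, 2):
                o += 1
        f = (o - e) / (l - e) if l != e else float("nan")
        out.append((o, e, l, f))
    return out


def ibs_oracle(geno):
    """Pairwise 1 - mean shared-allele fraction by exhaustive loops."""
    n, m = geno.shape
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            tot = cnt = 0
            for k in range(m):
                if geno[i][k] == -1 or geno[j][k] == -1:
                    continue
                tot += 2 - abs(geno[i][k] - geno[j][k])
                cnt += 1
            d[i, j] = d[j, i] = (1 - tot / (2 * cnt)) if cnt else np.nan
    return d


def incidence_oracle(segments, chrom, pos):
    """Per-SNP containment scan over (sample, chrom, start, end) tuples."""
    counts = []
    for k in range(len(pos)):
        samples = {s for (s, ch, start, end) in segments
                   if ch == chrom[k] and start <= pos[k] <= end}
        counts.append(len(samples))
    return counts


def island_grouping_oracle(segments, need):
    """Exact-boundary grouping: {(chrom,start,end): n_distinct_samples}."""
    groups = {}
    for (s, ch, start, end) in segments:
        groups.setdefault((ch, start, end), set()).add(s)
    return sorted((key, len(v)) for key, v in groups.items()
                  if len(v) >= need)


def r2_oracle(geno, pos, max_dist):
    """All intra-chromosome pair (dist, r2) via the textbook formula."""
    out = []
    m = len(pos)
    for i in range(m):
        for j in range(i + 1, m):
            d = pos[j] - pos[i]
            if d > max_dist or d <= 0:
                continue
            xs, ys = [], []
            for k in range(geno.shape[0]):
                if geno[k][i] != -1 and geno[k][j] != -1:
                    xs.append(float(geno[k][i]))
                    ys.append(float(geno[k][j]))
            if len(xs) < 2:
                continue
            xs, ys = np.array(xs), np.array(ys)
            if xs.std() == 0 or ys.std() == 0:
                continue
            r = ((xs - xs.mean()) * (ys - ys.mean())).mean() / (
                xs.std() * ys.std())
            out.append((d, r * r))
    return out
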