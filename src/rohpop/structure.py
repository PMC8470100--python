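"""Between-population structure: pairwise F_ST, IBS distances, NJ tree, PCA.

F_ST uses the Weir & Cockerham (1984) method-of-moments estimator as a ratio
of sums over SNPs (sum a / sum (a+b+c)); a Hudson-style estimator (Bhatia et
al. 2013 "ratio of averages") is available behind a flag. The NJ builder is
the standard Saitou-Nei agglomeration with a deterministic lowest-index
tie-break and negative branch lengths clamped to zero (flagged).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GenotypePanel, MISSING


class NoPolymorphicSnpsError(ValueError):
    """Raised when an F_ST estimate is undefined (no polymorphic SNPs)."""


# ---------------------------------------------------------------------------
# F_ST
# ---------------------------------------------------------------------------

def _pop_counts(geno: np.ndarray):
    called = geno != MISSING
    n = called.sum(axis=0).astype(float)            # individuals typed
    het = (geno == 1).sum(axis=0).astype(float)
    alt = np.where(called, geno, 0).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / (2 * n), np.nan)
        h = np.where(n > 0, het / n, np.nan)
    return n, p, h


def fst_components(panel: GenotypePanel, pop_a: str, pop_b: str
                   ) -> pd.DataFrame:
    """Per-SNP Weir-Cockerham variance components a, b, c for two
    populations (r = 2). SNPs monomorphic across the pair, or with fewer
    than two typed individuals in either population, are excluded."""
    ga = panel.pop_matrix(pop_a)
    gb = panel.pop_matrix(pop_b)
    n1, p1, h1 = _pop_counts(ga)
    n2, p2, h2 = _pop_counts(gb)
    ok = (n1 >= 2) & (n2 >= 2)
    poly = ok & ~(((p1 == 0) & (p2 == 0)) | ((p1 == 1) & (p2 == 1)))
    n1, p1, h1 = n1[poly], p1[poly], h1[poly]
    n2, p2, h2 = n2[poly], p2[poly], h2[poly]
    r = 2.0
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2
                             - hbar / 4) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                               - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return pd.DataFrame({"a": a, "b": b, "c": c,
                         "snp_index": np.flatnonzero(poly)})


def pairwise_fst(panel: GenotypePanel, pop_a: str, pop_b: str,
                 estimator: str = "wc") -> float:
    """Multi-locus pairwise F_ST between two populations.

    ``estimator="wc"`` (default) is Weir-Cockerham 1984 ratio of sums;
    ``estimator="hudson"`` is the Hudson estimator. Raises
    :class:`NoPolymorphicSnpsError` when no SNP is polymorphic in the pair.
    """
    if estimator == "wc":
        comp = fst_components(panel, pop_a, pop_b)
        if comp.empty:
            raise NoPolymorphicSnpsError(
                f"no polymorphic SNPs between {pop_a!r} and {pop_b!r}")
        denom = (comp.a + comp.b + comp.c).sum()
        if denom == 0:
            raise NoPolymorphicSnpsError(
                f"zero total variance between {pop_a!r} and {pop_b!r}")
        return float(comp.a.sum() / denom)
    if estimator == "hudson":
        ga, gb = panel.pop_matrix(pop_a), panel.pop_matrix(pop_b)
        n1, p1, _ = _pop_counts(ga)
        n2, p2, _ = _pop_counts(gb)
        m1, m2 = 2 * n1, 2 * n2  # allele counts
        ok = (m1 >= 2) & (m2 >= 2)
        poly = ok & ~(((p1 == 0) & (p2 == 0)) | ((p1 == 1) & (p2 == 1)))
        p1, p2, m1, m2 = p1[poly], p2[poly], m1[poly], m2[poly]
        if p1.size == 0:
            raise NoPolymorphicSnpsError(
                f"no polymorphic SNPs between {pop_a!r} and {pop_b!r}")
        num = ((p1 - p2) ** 2 - p1 * (1 - p1) / (m1 - 1)
               - p2 * (1 - p2) / (m2 - 1))
        den = p1 * (1 - p2) + p2 * (1 - p1)
        return float(num.sum() / den.sum())
    raise ValueError(f"unknown estimator {estimator!r}")


def fst_matrix(panel: GenotypePanel, estimator: str = "wc") -> pd.DataFrame:
    """Symmetric matrix of pairwise F_ST over all populations (diagonal 0).

    Pairs with no polymorphic SNPs get NaN.
    """
    pops = panel.population_labels
    out = pd.DataFrame(0.0, index=pops, columns=pops)
    for i, a in enumerate(pops):
        for b in pops[i + 1:]:
            try:
                v = pairwise_fst(panel, a, b, estimator=estimator)
            except NoPolymorphicSnpsError:
                v = np.nan
            out.loc[a, b] = out.loc[b, a] = v
    return out


# ---------------------------------------------------------------------------
# IBS distance
# ---------------------------------------------------------------------------

def ibs_distance(panel: GenotypePanel) -> pd.DataFrame:
    """1 - mean identity-by-state similarity for all sample pairs.

    Per pair, over SNPs non-missing in both samples, the shared-allele count
    is ``2 - |g_i - g_j|``; similarity is its mean divided by 2. Pairs with
    zero overlapping SNPs get NaN.
    """
    if panel.n_samples < 2:
        raise ValueError("need >=2 samples")
    g = panel.genotypes.astype(np.int16)
    called = g != MISSING
    n = panel.n_samples
    dist = np.zeros((n, n))
    for i in range(n):
        both = called[i] & called[i + 1:]
        diff = np.abs(g[i] - g[i + 1:]) * both
        n_overlap = both.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(n_overlap > 0,
                         diff.sum(axis=1) / (2.0 * n_overlap), np.nan)
        dist[i, i + 1:] = d
        dist[i + 1:, i] = d
    return pd.DataFrame(dist, index=panel.samples, columns=panel.samples)


def population_mean_distance(dist: pd.DataFrame,
                             populations: dict[str, str]) -> pd.DataFrame:
    """Collapse a sample-level distance matrix to population means."""
    labels = pd.Series({s: populations[s] for s in dist.index})
    pops: list[str] = list(dict.fromkeys(labels))
    out = pd.DataFrame(0.0, index=pops, columns=pops)
    for i, a in enumerate(pops):
        ia = labels.index[labels == a]
        for b in pops[i + 1:]:
            ib = labels.index[labels == b]
            v = float(np.nanmean(dist.loc[ia, ib].to_numpy()))
            out.loc[a, b] = out.loc[b, a] = v
    return out


# ---------------------------------------------------------------------------
# Neighbour joining
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    """Node of an unrooted NJ tree (children carry branch lengths)."""

    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def to_newick(self, _top=True) -> str:
        if self.is_leaf():
            body = self.name or ""
        else:
            inner = ",".join(f"{c.to_newick(False)}:{ln:.10g}"
                             for c, ln in self.children)
            body = f"({inner})" + (self.name or "")
        return body + ";" if _top else body

    def leaf_names(self) -> list[str]:
        if self.is_leaf():
            return [self.name]
        out = []
        for c, _ in self.children:
            out.extend(c.leaf_names())
        return out


@dataclass
class NjTree:
    root: TreeNode
    negative_branches_clamped: bool = False

    def to_newick(self) -> str:
        return self.root.to_newick()

    def leaf_names(self) -> list[str]:
        return self.root.leaf_names()

    def path_distances(self) -> pd.DataFrame:
        """Pairwise leaf-to-leaf path lengths (the additive metric)."""
        leaves = self.leaf_names()
        dist = pd.DataFrame(0.0, index=leaves, columns=leaves)

        def walk(node, depths):
            if node.is_leaf():
                return {node.name: 0.0}
            below: dict[str, float] = {}
            groups = []
            for child, ln in node.children:
                sub = walk(child, depths)
                sub = {k: v + ln for k, v in sub.items()}
                groups.append(sub)
            for gi in range(len(groups)):
                for gj in range(gi + 1, len(groups)):
                    for la, da in groups[gi].items():
                        for lb, db in groups[gj].items():
                            dist.loc[la, lb] = dist.loc[lb, la] = da + db
                below = {k: v for g in groups for k, v in g.items()}
            return below

        walk(self.root, None)
        return dist


def nj_tree(dist: pd.DataFrame) -> NjTree:
    """Saitou-Nei neighbour joining with deterministic tie-breaking.

    Ties in the Q criterion are broken by the lexicographically lowest index
    pair of the current working matrix. Negative branch lengths are clamped
    to zero and flagged on the returned tree. Requires >=3 taxa with finite
    distances.
    """
    labels = list(dist.index)
    if len(labels) < 3:
        raise ValueError("neighbour joining needs >=3 taxa; "
                         "join the pair directly for 2")
    D = dist.to_numpy(dtype=float).copy()
    if not np.isfinite(D).all():
        raise ValueError("distance matrix contains non-finite values")
    nodes = [TreeNode(name=l) for l in labels]
    clamped = False

    def clamp(x):
        nonlocal clamped
        if x < 0:
            clamped = True
            return 0.0
        return float(x)

    while len(nodes) > 3:
        n = len(nodes)
        rs = D.sum(axis=1)
        Q = (n - 2) * D - rs[:, None] - rs[None, :]
        np.fill_diagonal(Q, np.inf)
        # argmin scans row-major: first minimum is the lowest-index pair
        i, j = divmod(int(np.argmin(Q)), n)
        if i > j:
            i, j = j, i
        li = 0.5 * D[i, j] + (rs[i] - rs[j]) / (2 * (n - 2))
        lj = D[i, j] - li
        li, lj = clamp(li), clamp(lj)
        new = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        d_new = 0.5 * (D[i] + D[j] - D[i, j])
        keep = [k for k in range(n) if k not in (i, j)]
        D2 = np.empty((n - 1, n - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = d_new[keep]
        D2[-1, -1] = 0.0
        D = D2
        nodes = [nodes[k] for k in keep] + [new]

    # final trivalent root from the 3-taxon closed form
    (a, b, c) = nodes
    la = clamp(0.5 * (D[0, 1] + D[0, 2] - D[1, 2]))
    lb = clamp(0.5 * (D[0, 1] + D[1, 2] - D[0, 2]))
    lc = clamp(0.5 * (D[0, 2] + D[1, 2] - D[0, 1]))
    root = TreeNode(children=[(a, la), (b, lb), (c, lc)])
    return NjTree(root=root, negative_branches_clamped=clamped)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PcaResult:
    scores: pd.DataFrame          # samples x components
    eigenvalues: np.ndarray       # all positive eigenvalues of the covariance
    percent_variance: np.ndarray  # per returned component


def pca_scores(panel: GenotypePanel, n_components: int = 10,
               patterson_scaling: bool = False) -> PcaResult:
    """Genotype PCA: per-SNP mean centring (missing imputed to the SNP
    mean), optional Patterson 1/sqrt(p(1-p)) scaling, eigendecomposition of
    the sample covariance via SVD. Percent variance is relative to the sum
    of all eigenvalues."""
    n = panel.n_samples
    if n < 2:
        raise ValueError("need >=2 samples")
    n_components = min(n_components, n - 1)
    g = panel.genotypes.astype(float)
    g[g == MISSING] = np.nan
    mean = np.nanmean(g, axis=0)
    keep = ~np.isnan(mean)
    g, mean = g[:, keep], mean[keep]
    inds = np.where(np.isnan(g))
    g[inds] = mean[inds[1]]
    x = g - mean
    if patterson_scaling:
        p = mean / 2
        denom = np.sqrt(p * (1 - p))
        with np.errstate(invalid="ignore", divide="ignore"):
            x = np.where(denom > 0, x / denom, 0.0)
    if not np.any(x):
        raise ValueError("panel has zero variance (all SNPs monomorphic)")
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    eig = s ** 2 / (n - 1)
    pos = eig > 1e-12 * eig[0]
    eig = eig[pos]
    k = min(n_components, eig.size)
    scores = (u[:, :k] * s[:k])
    cols = [f"PC{c + 1}" for c in range(k)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=panel.samples, columns=cols),
        eigenvalues=eig,
        percent_variance=100 * eig[:k] / eig.sum(),
    )
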