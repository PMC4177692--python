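"""Population-genetic statistics on a genotype matrix.

Weir-Cockerham multilocus Fst (ratio of sums), VanRaden genomic
relationships, uncorrected-P distances, neighbour-joining trees with
bootstrap split supports, genotype PCA and k-means cluster assignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

MISSING = -1  # genotype code for a missing diploid call


@dataclass
class GenotypeMatrix:
    """samples x biallelic loci, codes {0,1,2} with -1 for missing."""

    samples: list[str]
    codes: np.ndarray            # (n_samples, n_loci) int8
    chrom: np.ndarray            # (n_loci,) str
    pos: np.ndarray              # (n_loci,) int, 1-based
    ref: np.ndarray
    alt: np.ndarray
    groups: pd.Series = None     # sample -> group label

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        if self.codes.shape != (len(self.samples), len(self.pos)):
            raise ValueError("codes shape does not match samples x loci")
        bad = ~np.isin(self.codes, [-1, 0, 1, 2])
        if bad.any():
            raise ValueError("genotype codes must be in {-1, 0, 1, 2}")
        order = np.lexsort((self.pos, self.chrom.astype(str)))
        if not np.array_equal(order, np.arange(len(order))):
            warnings.warn("loci not sorted by (chrom, pos); sorting")
            self._reorder(order)
        key = pd.MultiIndex.from_arrays([self.chrom.astype(str), self.pos])
        if key.duplicated().any():
            dup = key[key.duplicated()][0]
            raise ValueError(f"duplicate locus {dup[0]}:{dup[1]}")

    def _reorder(self, order: np.ndarray) -> None:
        self.codes = self.codes[:, order]
        self.chrom = self.chrom[order]
        self.pos = self.pos[order]
        self.ref = np.asarray(self.ref, dtype=object)[order]
        self.alt = np.asarray(self.alt, dtype=object)[order]

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.pos)

    def subset_loci(self, mask: np.ndarray) -> "GenotypeMatrix":
        idx = np.flatnonzero(mask) if mask.dtype == bool else np.asarray(mask)
        return GenotypeMatrix(
            samples=list(self.samples),
            codes=self.codes[:, idx],
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            ref=np.asarray(self.ref, dtype=object)[idx],
            alt=np.asarray(self.alt, dtype=object)[idx],
            groups=self.groups,
        )

    def dosage(self, impute: bool = False) -> np.ndarray:
        """Float dosage matrix; missing as NaN, or mean-imputed per locus."""
        d = self.codes.astype(float)
        d[d == MISSING] = np.nan
        if impute:
            col_mean = np.nanmean(d, axis=0)
            col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
            idx = np.where(np.isnan(d))
            d[idx] = col_mean[idx[1]]
        return d

    def allele_frequencies(self) -> np.ndarray:
        """Alternate-allele frequency per locus over non-missing calls."""
        d = self.dosage()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(d, axis=0) / 2.0


@dataclass
class KinshipMatrix:
    values: pd.DataFrame  # samples x samples

    def __post_init__(self) -> None:
        v = self.values.to_numpy()
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("kinship matrix must be symmetric")

    @property
    def matrix(self) -> np.ndarray:
        return self.values.to_numpy(float)


# ---------------------------------------------------------------------------
# Weir-Cockerham Fst


def _wc_components(
    codes1: np.ndarray, codes2: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus Weir-Cockerham a, b, c variance components for two groups.

    Loci where either group has fewer than two non-missing calls are
    excluded (returned as NaN components).
    """
    comps = []
    for codes in (codes1, codes2):
        c = codes.astype(float)
        c[c == MISSING] = np.nan
        n = np.sum(~np.isnan(c), axis=0).astype(float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            p = np.nanmean(c, axis=0) / 2.0
            h = np.nanmean(c == 1, axis=0)
        comps.append((n, p, h))
    (n1, p1, h1), (n2, p2, h2) = comps

    valid = (n1 >= 2) & (n2 >= 2)
    r = 2.0
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        a = (nbar / nc) * (
            s2
            - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar)
            - (r - 1) / r * s2
            - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2.0
    a = np.where(valid, a, np.nan)
    b = np.where(valid, b, np.nan)
    c = np.where(valid, c, np.nan)
    return a, b, c


def fst_weir_cockerham(codes1: np.ndarray, codes2: np.ndarray) -> float:
    """Multilocus theta between two groups: sum(a) / sum(a + b + c)."""
    a, b, c = _wc_components(codes1, codes2)
    num = np.nansum(a)
    den = np.nansum(a + b + c)
    if den == 0 or np.all(np.isnan(a)):
        return np.nan
    return float(num / den)


def pairwise_fst(g: GenotypeMatrix) -> pd.DataFrame:
    """Group-by-group multilocus Weir-Cockerham theta (raw, unclipped)."""
    if g.groups is None:
        raise ValueError("genotype matrix has no group labels")
    labels = g.groups.reindex(g.samples).to_numpy()
    group_names = sorted(pd.unique(labels))
    if len(group_names) < 2:
        raise ValueError("need at least two groups")
    out = pd.DataFrame(0.0, index=group_names, columns=group_names)
    for i, gi in enumerate(group_names):
        for j in range(i + 1, len(group_names)):
            gj = group_names[j]
            theta = fst_weir_cockerham(
                g.codes[labels == gi], g.codes[labels == gj]
            )
            out.loc[gi, gj] = out.loc[gj, gi] = theta
    return out


# ---------------------------------------------------------------------------
# VanRaden kinship


def vanraden_kinship(g: GenotypeMatrix) -> KinshipMatrix:
    """G = ZZ' / (2 * sum_k p_k (1 - p_k)), Z = M - 2p on observed dosages.

    Missing dosages are replaced by 2p (mean imputation) for this
    computation only; monomorphic loci are dropped.
    """
    p = g.allele_frequencies()
    poly = (p > 0) & (p < 1) & ~np.isnan(p)
    if not poly.any():
        raise ValueError("all loci monomorphic: kinship undefined")
    d = g.dosage()[:, poly]
    pp = p[poly]
    z = d - 2.0 * pp
    z = np.where(np.isnan(z), 0.0, z)  # missing -> 2p, i.e. centered 0
    denom = 2.0 * np.sum(pp * (1.0 - pp))
    gmat = z @ z.T / denom
    return KinshipMatrix(pd.DataFrame(gmat, index=g.samples, columns=g.samples))


# ---------------------------------------------------------------------------
# Distances


def p_distance(g: GenotypeMatrix) -> pd.DataFrame:
    """Uncorrected-P distance: differing codes / loci non-missing in both."""
    codes = g.codes
    n = g.n_samples
    out = np.zeros((n, n))
    miss = codes == MISSING
    for i in range(n):
        for j in range(i + 1, n):
            shared = ~(miss[i] | miss[j])
            ns = int(shared.sum())
            if ns == 0:
                out[i, j] = out[j, i] = np.nan
                continue
            diff = np.sum(codes[i, shared] != codes[j, shared])
            out[i, j] = out[j, i] = diff / ns
    return pd.DataFrame(out, index=g.samples, columns=g.samples)


# ---------------------------------------------------------------------------
# Neighbour joining


class TreeNode:
    """Minimal unrooted-tree node for NJ output."""

    __slots__ = ("name", "children", "length")

    def __init__(self, name: str | None = None, length: float = 0.0):
        self.name = name
        self.children: list[TreeNode] = []
        self.length = length

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf():
            return [self.name]
        out = []
        for ch in self.children:
            out.extend(ch.leaves())
        return out

    def newick(self) -> str:
        return self._newick_inner() + ";"

    def _newick_inner(self) -> str:
        if self.is_leaf():
            return f"{self.name}:{self.length:.6g}"
        inner = ",".join(ch._newick_inner() for ch in self.children)
        if self.length:
            return f"({inner}):{self.length:.6g}"
        return f"({inner})"

    def splits(self) -> set[frozenset]:
        """Non-trivial bipartitions, each canonicalized against leaf order."""
        all_leaves = frozenset(self.leaves())
        anchor = min(all_leaves)
        out: set[frozenset] = set()

        def rec(node: TreeNode) -> frozenset:
            if node.is_leaf():
                return frozenset([node.name])
            below = frozenset().union(*(rec(ch) for ch in node.children))
            if node is not self and 1 < len(below) < len(all_leaves) - 1:
                side = below if anchor not in below else all_leaves - below
                out.add(side)
            return below

        rec(self)
        return out

    def cophenetic(self, labels: Sequence[str]) -> np.ndarray:
        """Path-length distances between leaves, in the given label order."""
        idx = {name: i for i, name in enumerate(labels)}
        n = len(labels)
        dist = np.zeros((n, n))

        def rec(node: TreeNode) -> dict[int, float]:
            if node.is_leaf():
                return {idx[node.name]: 0.0}
            merged: dict[int, float] = {}
            for ch in node.children:
                below = {k: v + ch.length for k, v in rec(ch).items()}
                for i, di in merged.items():
                    for j, dj in below.items():
                        dist[i, j] = dist[j, i] = di + dj
                merged.update(below)
            return merged

        rec(self)
        return dist


def nj_tree(dist: pd.DataFrame) -> TreeNode:
    """Canonical neighbour joining (Saitou-Nei Q-criterion)."""
    d = dist.to_numpy(float).copy()
    labels = list(dist.index)
    if len(labels) < 3:
        raise ValueError("need at least 3 taxa")
    if np.isnan(d).any():
        raise ValueError("distance matrix has missing entries; impute first")

    nodes = [TreeNode(name=str(lbl)) for lbl in labels]
    active = list(range(len(labels)))
    while len(active) > 2:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i, j = np.unravel_index(np.argmin(q), q.shape)
        if i > j:
            i, j = j, i
        ai, aj = active[i], active[j]
        dij = sub[i, j]
        vi = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        vj = dij - vi
        node = TreeNode()
        nodes[ai].length = max(vi, 0.0)
        nodes[aj].length = max(vj, 0.0)
        node.children = [nodes[ai], nodes[aj]]
        # distances from the new node to the remaining taxa
        new_d = 0.5 * (d[ai, :] + d[aj, :] - dij)
        d[ai, :] = new_d
        d[:, ai] = new_d
        d[ai, ai] = 0.0
        nodes[ai] = node
        active.pop(j)
    # join the last two nodes with the remaining edge
    a0, a1 = active
    root = nodes[a0] if not nodes[a0].is_leaf() else nodes[a1]
    other = nodes[a1] if root is nodes[a0] else nodes[a0]
    other.length = max(d[a0, a1], 0.0)
    root.children.append(other)
    return root


def nj_with_bootstrap(
    dist: pd.DataFrame,
    column_matrix: np.ndarray | None = None,
    dist_fn: Callable[[np.ndarray], pd.DataFrame] | None = None,
    n_reps: int = 0,
    seed: int = 0,
) -> tuple[TreeNode, dict[frozenset, float]]:
    """NJ tree plus bootstrap split supports.

    ``column_matrix`` holds the per-taxon data columns (loci or regions)
    that are resampled with replacement; ``dist_fn`` rebuilds a distance
    matrix from a resampled copy.
    """
    tree = nj_tree(dist)
    supports: dict[frozenset, float] = {}
    if n_reps and column_matrix is not None and dist_fn is not None:
        rng = np.random.default_rng(seed)
        target = tree.splits()
        counts = {s: 0 for s in target}
        n_cols = column_matrix.shape[1]
        for _ in range(n_reps):
            cols = rng.integers(0, n_cols, size=n_cols)
            try:
                bd = dist_fn(column_matrix[:, cols])
                bs = nj_tree(bd).splits()
            except ValueError:
                continue
            for s in target:
                if s in bs:
                    counts[s] += 1
        supports = {s: c / n_reps for s, c in counts.items()}
    return tree, supports


# ---------------------------------------------------------------------------
# PCA and clustering


def genotype_pca(
    g: GenotypeMatrix, n_pcs: int = 5, standardize: bool = False
) -> pd.DataFrame:
    """Leading PC scores of the (mean-imputed, centered) dosage matrix."""
    if n_pcs >= min(g.n_samples, g.n_loci):
        raise ValueError("n_pcs must be < min(samples, loci)")
    d = g.dosage(impute=True)
    d = d - d.mean(axis=0)
    if standardize:
        sd = d.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        d = d / sd
    u, s, vt = np.linalg.svd(d, full_matrices=False)
    # deterministic sign: largest-magnitude score entry positive
    for comp in range(n_pcs):
        col = u[:, comp]
        if col[np.argmax(np.abs(col))] < 0:
            u[:, comp] = -col
    scores = u[:, :n_pcs] * s[:n_pcs]
    cols = [f"PC{i + 1}" for i in range(n_pcs)]
    return pd.DataFrame(scores, index=g.samples, columns=cols)


def assign_clusters(
    scores: pd.DataFrame, k: int, seed: int = 0, n_init: int = 10
) -> pd.Series:
    """k-means cluster labels on PC scores (seeded, restarted)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(scores):
        raise ValueError("k exceeds the number of samples")
    if k == 1:
        return pd.Series(0, index=scores.index, name="cluster")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(scores.to_numpy(float))
    return pd.Series(labels, index=scores.index, name="cluster")


def select_k(
    scores: pd.DataFrame, k_range: Sequence[int], seed: int = 0
) -> tuple[int, dict[int, float]]:
    """Pick k maximizing the silhouette score over ``k_range``."""
    sils: dict[int, float] = {}
    x = scores.to_numpy(float)
    for k in k_range:
        if not 2 <= k < len(scores):
            continue
        labels = assign_clusters(scores, k, seed=seed)
        sils[k] = float(silhouette_score(x, labels.to_numpy()))
    if not sils:
        raise ValueError("no valid k in range")
    best = max(sils, key=lambda k: sils[k])
    return best, sils
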