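"""Pairwise D' with confidence bounds, Gabriel LD blocks, and the
LD-corrected Bonferroni threshold.

Haplotype frequencies for unphased pairs come from a two-locus EM;
confidence bounds of |D'| from the profile of the two-locus multinomial
likelihood on a grid (one-sided 5% each tail at the default 90%
confidence). Block detection follows the Gabriel convention: a candidate
block's outermost pair must be in strong LD and, among informative pairs
classified as strong LD or strong recombination, the strong fraction must
reach ``min_strong_fraction``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .popgen import MISSING, GenotypeMatrix

_DP_GRID = np.linspace(0.0, 1.0, 101)
_EPS = 1e-10


@dataclass
class LDPairStats:
    i: int
    j: int
    dprime: float          # |D'| point estimate
    lower: float           # lower confidence bound of |D'|
    upper: float           # upper confidence bound of |D'|
    informative: bool

    def __post_init__(self) -> None:
        if self.informative and not (
            -1e-9 <= self.lower <= self.dprime + 1e-9
            and self.dprime <= self.upper + 1e-9 <= 1 + 2e-9
        ):
            raise ValueError("bounds must satisfy 0 <= lower <= D' <= upper <= 1")


@dataclass
class LDBlockPartition:
    """Ordered partition of loci into blocks (contiguous, size >= 2) and
    singletons; the number of independent tests is #blocks + #singletons."""

    n_loci: int
    blocks: list[tuple[int, int]]      # inclusive index ranges
    singletons: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        covered: set[int] = set()
        for start, end in self.blocks:
            if end - start + 1 < 2:
                raise ValueError("blocks must contain at least 2 loci")
            span = set(range(start, end + 1))
            if span & covered:
                raise ValueError("blocks overlap")
            covered |= span
        if covered & set(self.singletons):
            raise ValueError("singleton inside a block")
        if covered | set(self.singletons) != set(range(self.n_loci)):
            raise ValueError("blocks and singletons must cover all loci")

    @property
    def n_independent_tests(self) -> int:
        return len(self.blocks) + len(self.singletons)


# ---------------------------------------------------------------------------
# Two-locus EM and likelihood confidence bounds


def _joint_table(ga: np.ndarray, gb: np.ndarray) -> np.ndarray:
    """3x3 joint genotype counts over samples non-missing at both loci."""
    ok = (ga != MISSING) & (gb != MISSING)
    a, b = ga[ok], gb[ok]
    table = np.zeros((3, 3))
    for i in range(3):
        for j in range(3):
            table[i, j] = np.sum((a == i) & (b == j))
    return table

def _em_hap_freqs(table: np.ndarray, n_iter: int = 200, tol: float = 1e-12
                  ) -> np.ndarray:
    """EM haplotype frequencies (f11, f10, f01, f00); alleles 1 = alt."""
    n = table.sum()
    if n == 0:
        return np.full(4, np.nan)
    # fixed haplotype counts from unambiguous cells
    c11 = 2 * table[2, 2] + table[2, 1] + table[1, 2]
    c10 = 2 * table[2, 0] + table[2, 1] + table[1, 0]
    c01 = 2 * table[0, 2] + table[0, 1] + table[1, 2]
    c00 = 2 * table[0, 0] + table[0, 1] + table[1, 0]
    ndh = table[1, 1]  # double heterozygotes: phase unknown
    f = np.array([0.25, 0.25, 0.25, 0.25])
    for _ in range(n_iter):
        coup = f[0] * f[3]
        rep = f[1] * f[2]
        pc = coup / (coup + rep) if coup + rep > 0 else 0.5
        new = np.array(
            [c11 + ndh * pc, c10 + ndh * (1 - pc),
             c01 + ndh * (1 - pc), c00 + ndh * pc]
        ) / (2.0 * n)
        if np.max(np.abs(new - f)) < tol:
            f = new
            break
        f = new
    return f


def _d_stats(f: np.ndarray) -> tuple[float, float, float, float]:
    """(D, |D'|, pA, pB) from haplotype frequencies."""
    pa = f[0] + f[1]
    pb = f[0] + f[2]
    d = f[0] - pa * pb
    if d >= 0:
        dmax = min(pa * (1 - pb), (1 - pa) * pb)
    else:
        dmax = min(pa * pb, (1 - pa) * (1 - pb))
    dprime = abs(d) / dmax if dmax > _EPS else 0.0
    return d, min(dprime, 1.0), pa, pb


def _cell_probs(f11, f10, f01, f00) -> np.ndarray:
    """Genotype-cell probabilities (row-major 3x3) under random haplotype
    union; inputs may be arrays broadcast along the grid axis."""
    return np.stack(
        [
            f00**2, 2 * f01 * f00, f01**2,
            2 * f10 * f00, 2 * (f11 * f00 + f10 * f01), 2 * f11 * f01,
            f10**2, 2 * f11 * f10, f11**2,
        ],
        axis=-1,
    )


def _likelihood_bounds(
    table: np.ndarray, pa: float, pb: float, sign: float, confidence: float
) -> tuple[float, float]:
    """Confidence bounds of |D'| from the normalized likelihood over a grid,
    allele frequencies held at their estimates (Gabriel/Haploview style)."""
    if sign >= 0:
        dmax = min(pa * (1 - pb), (1 - pa) * pb)
    else:
        dmax = min(pa * pb, (1 - pa) * (1 - pb))
    if dmax < _EPS:
        return 0.0, 1.0
    d_grid = (1.0 if sign >= 0 else -1.0) * _DP_GRID * dmax
    f11 = np.clip(pa * pb + d_grid, _EPS, 1.0)
    f10 = np.clip(pa * (1 - pb) - d_grid, _EPS, 1.0)
    f01 = np.clip((1 - pa) * pb - d_grid, _EPS, 1.0)
    f00 = np.clip((1 - pa) * (1 - pb) + d_grid, _EPS, 1.0)
    probs = _cell_probs(f11, f10, f01, f00)  # (grid, 9)
    counts = table.reshape(-1)  # row-major, matching _cell_probs ordering
    ll = (counts * np.log(probs)).sum(axis=1)
    lik = np.exp(ll - ll.max())
    lik /= lik.sum()
    tail = (1.0 - confidence) / 2.0
    cum = np.cumsum(lik)
    lower_idx = int(np.searchsorted(cum, tail))
    upper_idx = int(np.searchsorted(cum, 1.0 - tail))
    lower = _DP_GRID[min(lower_idx, len(_DP_GRID) - 1)]
    upper = _DP_GRID[min(upper_idx, len(_DP_GRID) - 1)]
    return float(lower), float(upper)


def dprime_ci(
    ga: np.ndarray,
    gb: np.ndarray,
    confidence: float = 0.90,
    i: int = 0,
    j: int = 1,
    min_maf: float = 0.05,
    min_joint: int = 20,
) -> LDPairStats:
    """EM-based |D'| with likelihood confidence bounds for one locus pair."""
    table = _joint_table(np.asarray(ga), np.asarray(gb))
    n = table.sum()
    if n == 0:
        return LDPairStats(i, j, np.nan, np.nan, np.nan, False)
    pa_obs = (table * np.arange(3)[:, None]).sum() / (2 * n)
    pb_obs = (table * np.arange(3)[None, :]).sum() / (2 * n)
    maf_a = min(pa_obs, 1 - pa_obs)
    maf_b = min(pb_obs, 1 - pb_obs)
    if maf_a == 0 or maf_b == 0:
        return LDPairStats(i, j, np.nan, np.nan, np.nan, False)
    informative = maf_a >= min_maf and maf_b >= min_maf and n >= min_joint
    f = _em_hap_freqs(table)
    d, dprime, pa, pb = _d_stats(f)
    lower, upper = _likelihood_bounds(table, pa, pb, np.sign(d) or 1.0, confidence)
    lower = min(lower, dprime)
    upper = max(upper, dprime)
    return LDPairStats(i, j, dprime, lower, upper, bool(informative))


# ---------------------------------------------------------------------------
# Gabriel block detection


def _classify_pairs(
    g: GenotypeMatrix,
    window: int,
    strong: tuple[float, float],
    recomb_upper: float,
    confidence: float,
    min_maf: float,
    min_joint: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean (strong, recomb) matrices for same-chromosome pairs within
    the marker window; uninformative pairs are neither."""
    n = g.n_loci
    strong_m = np.zeros((n, n), dtype=bool)
    recomb_m = np.zeros((n, n), dtype=bool)
    upper_cut, lower_cut = strong
    chrom = g.chrom.astype(str)
    for i in range(n):
        for j in range(i + 1, min(n, i + window)):
            if chrom[i] != chrom[j]:
                break
            st = dprime_ci(
                g.codes[:, i], g.codes[:, j],
                confidence=confidence, i=i, j=j,
                min_maf=min_maf, min_joint=min_joint,
            )
            if not st.informative:
                continue
            if st.upper > upper_cut and st.lower > lower_cut:
                strong_m[i, j] = True
            elif st.upper < recomb_upper:
                recomb_m[i, j] = True
    return strong_m, recomb_m


def gabriel_blocks(
    g: GenotypeMatrix,
    window: int = 500,
    strong: tuple[float, float] = (0.98, 0.7),
    recomb_upper: float = 0.9,
    min_strong_fraction: float = 0.95,
    confidence: float = 0.90,
    min_maf: float = 0.05,
    min_joint: int = 20,
) -> LDBlockPartition:
    """Gabriel-method LD block partition within a sliding marker window.

    A candidate block is a contiguous run whose outermost pair is in strong
    LD and whose classified informative pairs are at least
    ``min_strong_fraction`` strong (strong vs recombination evidence).
    Overlapping candidates are resolved greedily, largest first, leftmost on
    ties; every uncovered locus is a singleton.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    n = g.n_loci
    strong_m, recomb_m = _classify_pairs(
        g, window, strong, recomb_upper, confidence, min_maf, min_joint
    )
    candidates: list[tuple[int, int, int]] = []  # (size, start, end)
    for i in range(n):
        n_strong = 0
        n_recomb = 0
        for j in range(i + 1, min(n, i + window)):
            n_strong += int(strong_m[i:j, j].sum())
            n_recomb += int(recomb_m[i:j, j].sum())
            if not strong_m[i, j]:
                continue
            decided = n_strong + n_recomb
            if decided and n_strong / decided >= min_strong_fraction:
                candidates.append((j - i + 1, i, j))
    candidates.sort(key=lambda t: (-t[0], t[1]))
    taken = np.zeros(n, dtype=bool)
    blocks: list[tuple[int, int]] = []
    for _, i, j in candidates:
        if taken[i : j + 1].any():
            continue
        blocks.append((i, j))
        taken[i : j + 1] = True
    blocks.sort()
    singletons = [int(k) for k in np.flatnonzero(~taken)]
    return LDBlockPartition(n_loci=n, blocks=blocks, singletons=singletons)


def ld_bonferroni(partition: LDBlockPartition, alpha_target: float = 0.1) -> float:
    """Per-test threshold: alpha_target / number of independent tests."""
    if partition.n_independent_tests < 1:
        raise ValueError("need at least one independent test")
    return alpha_target / partition.n_independent_tests
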