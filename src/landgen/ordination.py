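"""Canonical correspondence analysis with a permutation test.

ter Braak's algorithm: the group x region presence matrix is treated as a
contingency table, chi-square standardized, and its weighted projection
onto the constraint space decomposed; constrained inertia over total
inertia is the test statistic of the row-permutation test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class CCAResult:
    constrained_eigenvalues: np.ndarray
    unconstrained_eigenvalues: np.ndarray
    total_inertia: float
    site_scores: pd.DataFrame = None
    object_scores: pd.DataFrame = None
    constraint_vectors: pd.DataFrame = None
    permutation_p: float = field(default=np.nan)

    def __post_init__(self) -> None:
        ce = np.asarray(self.constrained_eigenvalues)
        ue = np.asarray(self.unconstrained_eigenvalues)
        if np.any(ce < -1e-10) or np.any(ue < -1e-10):
            raise ValueError("eigenvalues must be non-negative")
        if not 0.0 <= self.constrained_fraction <= 1.0 + 1e-9:
            raise ValueError("constrained fraction must be in [0, 1]")

    @property
    def constrained_fraction(self) -> float:
        if self.total_inertia == 0:
            return 0.0
        return float(np.sum(self.constrained_eigenvalues) / self.total_inertia)


def _prepare(presence: pd.DataFrame, constraints: pd.DataFrame):
    y = presence.to_numpy(float)
    keep_rows = y.sum(axis=1) > 0
    keep_cols = y.sum(axis=0) > 0
    if not keep_rows.all() or not keep_cols.all():
        warnings.warn("dropping all-zero rows/columns from the presence matrix")
    presence = presence.loc[keep_rows, keep_cols]
    constraints = constraints.reindex(presence.index)
    if constraints.isna().any().any():
        raise ValueError("constraints missing for some groups")
    return presence, constraints


def cca_fit(
    presence: pd.DataFrame, constraints: pd.DataFrame
) -> CCAResult:
    """Fit a CCA of a binary (or count) site x object matrix on constraints.

    Total inertia equals the scaled chi-square statistic of the table;
    constrained eigenvalues come from the SVD of the weighted projection of
    the standardized table onto the (row-weighted) constraint space.
    """
    presence, constraints = _prepare(presence, constraints)
    y = presence.to_numpy(float)
    x = constraints.to_numpy(float)
    n_sites, n_objs = y.shape
    if x.shape[1] >= n_sites:
        raise ValueError("saturated model: #constraints must be < #sites")

    total = y.sum()
    p = y / total
    r = p.sum(axis=1)            # row (site) weights
    c = p.sum(axis=0)            # column (object) weights
    expected = np.outer(r, c)
    qbar = (p - expected) / np.sqrt(expected)
    total_inertia = float((qbar**2).sum())

    # weighted regression of the standardized table on the constraints
    xc = x - (r @ x)             # center with row weights
    xw = xc * np.sqrt(r)[:, None]
    u_x, s_x, _ = np.linalg.svd(xw, full_matrices=False)
    rank = int(np.sum(s_x > s_x.max() * 1e-10)) if s_x.size else 0
    proj = u_x[:, :rank]
    fitted = proj @ (proj.T @ qbar)
    residual = qbar - fitted

    uf, sf, vft = np.linalg.svd(fitted, full_matrices=False)
    ur, sr, _ = np.linalg.svd(residual, full_matrices=False)
    ce = sf[:rank] ** 2
    ue = sr[sr**2 > 1e-12] ** 2

    axis_names = [f"CCA{i + 1}" for i in range(rank)]
    with np.errstate(divide="ignore", invalid="ignore"):
        site = uf[:, :rank] / np.sqrt(r)[:, None]
        obj = vft[:rank].T / np.sqrt(c)[:, None]
    site_scores = pd.DataFrame(site, index=presence.index, columns=axis_names)
    object_scores = pd.DataFrame(obj, index=presence.columns, columns=axis_names)
    # constraint biplot vectors: weighted correlation of constraints with axes
    site_lc = uf[:, :rank] * sf[:rank]
    vec = xw.T @ site_lc
    norm = np.linalg.norm(xw, axis=0)[:, None] * np.maximum(
        np.linalg.norm(site_lc, axis=0)[None, :], 1e-300
    )
    constraint_vectors = pd.DataFrame(
        vec / np.where(norm == 0, 1.0, norm),
        index=constraints.columns,
        columns=axis_names,
    )
    return CCAResult(
        constrained_eigenvalues=ce,
        unconstrained_eigenvalues=ue,
        total_inertia=total_inertia,
        site_scores=site_scores,
        object_scores=object_scores,
        constraint_vectors=constraint_vectors,
    )


def cca_permutation(
    presence: pd.DataFrame,
    constraints: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
    exhaustive: bool = False,
) -> tuple[float, CCAResult]:
    """Row-permutation test of the constrained-inertia fraction.

    p = (1 + #{permuted fraction >= observed}) / (n_perm + 1); with
    ``exhaustive=True`` all row permutations are enumerated and
    p = #{fraction >= observed} / n! (identity included).
    """
    if n_perm < 1 and not exhaustive:
        raise ValueError("n_perm must be >= 1")
    fit = cca_fit(presence, constraints)
    observed = fit.constrained_fraction
    x = constraints.to_numpy(float)

    def stat_for(idx: np.ndarray) -> float:
        shuffled = pd.DataFrame(
            x[idx], index=constraints.index, columns=constraints.columns
        )
        return cca_fit(presence, shuffled).constrained_fraction

    if exhaustive:
        from itertools import permutations

        hits = 0
        total = 0
        for perm in permutations(range(len(constraints))):
            total += 1
            if stat_for(np.array(perm)) >= observed - 1e-12:
                hits += 1
        fit.permutation_p = hits / total
        return fit.permutation_p, fit

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(constraints))
        if stat_for(perm) >= observed - 1e-12:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    fit.permutation_p = p
    return p, fit
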