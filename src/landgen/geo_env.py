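"""Geodesic distances, environmental PCA, and matrix correlation.

Sampling points carry WGS84 decimal-degree coordinates. Great-circle
distances use the WGS84 equatorial radius (6378.137 km); environmental
tables are z-normalized per variable before decomposition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sphere radius used for great-circle distances, in km (WGS84 equatorial).
EARTH_RADIUS_KM = 6378.137


@dataclass
class SampleSheet:
    """Per-sample metadata: id, group label, WGS84 coordinates, altitude."""

    table: pd.DataFrame  # columns: sample, group, lat, lon, altitude

    def __post_init__(self) -> None:
        required = {"sample", "group", "lat", "lon", "altitude"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
        lat = self.table["lat"].to_numpy(float)
        lon = self.table["lon"].to_numpy(float)
        if np.any((lat < -90) | (lat > 90)):
            raise ValueError("latitude outside [-90, 90]")
        if np.any((lon < -180) | (lon > 180)):
            raise ValueError("longitude outside [-180, 180]")
        if self.table["sample"].duplicated().any():
            raise ValueError("duplicate sample ids in sample sheet")

    @property
    def samples(self) -> list[str]:
        return self.table["sample"].tolist()

    @property
    def groups(self) -> pd.Series:
        return self.table.set_index("sample")["group"]

    def group_coordinates(self) -> pd.DataFrame:
        """Mean lat/lon/altitude per group (groups are sampling locations)."""
        return self.table.groupby("group")[["lat", "lon", "altitude"]].mean()


@dataclass
class EnvPCs:
    """Scores, loadings and variance fractions of the environment PCA."""

    scores: pd.DataFrame        # locations x components
    loadings: pd.DataFrame      # variables x components
    variance_fractions: np.ndarray  # over the retained components
    all_variance_fractions: np.ndarray = field(default=None)  # every component

    def __post_init__(self) -> None:
        vf = np.asarray(self.variance_fractions, float)
        if np.any(np.diff(vf) > 1e-12):
            raise ValueError("variance fractions must be non-increasing")
        if vf.sum() > 1 + 1e-9:
            raise ValueError("variance fractions sum above 1")


def geodesic_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle (haversine) distance in km between two WGS84 points."""
    for lat in (lat1, lat2):
        if not -90 <= lat <= 90:
            raise ValueError(f"latitude {lat} outside [-90, 90]")
    for lon in (lon1, lon2):
        if not -180 <= lon <= 180:
            raise ValueError(f"longitude {lon} outside [-180, 180]")
    la1, lo1, la2, lo2 = np.radians([lat1, lon1, lat2, lon2])
    h = (
        np.sin((la2 - la1) / 2.0) ** 2
        + np.cos(la1) * np.cos(la2) * np.sin((lo2 - lo1) / 2.0) ** 2
    )
    return float(2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h)))


def distance_matrix_km(points: pd.DataFrame) -> pd.DataFrame:
    """Pairwise great-circle distances for a table with lat/lon columns."""
    labels = list(points.index)
    n = len(labels)
    out = np.zeros((n, n))
    lat = points["lat"].to_numpy(float)
    lon = points["lon"].to_numpy(float)
    for i in range(n):
        for j in range(i + 1, n):
            d = geodesic_km(lat[i], lon[i], lat[j], lon[j])
            out[i, j] = out[j, i] = d
    return pd.DataFrame(out, index=labels, columns=labels)


def env_pca(env_table: pd.DataFrame, k: int = 3) -> EnvPCs:
    """PCA of a locations-by-variables environment table.

    Each variable is z-normalized (mean 0, sd 1) before eigendecomposition;
    zero-variance variables are dropped with a warning. Loading vectors are
    oriented so their largest-magnitude entry is positive.
    """
    x = env_table.to_numpy(float)
    if np.isnan(x).any():
        raise ValueError("environment table contains missing values")
    if env_table.shape[0] < k + 1:
        raise ValueError(f"need at least {k + 1} locations for k={k} components")

    sd = x.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        dropped = [c for c, k_ in zip(env_table.columns, keep) if not k_]
        warnings.warn(f"dropping zero-variance variables: {dropped}")
        x = x[:, keep]
        sd = sd[keep]
    cols = [c for c, k_ in zip(env_table.columns, keep) if k_]

    z = (x - x.mean(axis=0)) / sd
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    eigvals = s**2 / (z.shape[0] - 1)
    fractions = eigvals / eigvals.sum()

    # deterministic sign: largest-magnitude loading entry positive
    for comp in range(vt.shape[0]):
        j = np.argmax(np.abs(vt[comp]))
        if vt[comp, j] < 0:
            vt[comp] *= -1.0
            u[:, comp] *= -1.0

    k_eff = min(k, len(s))
    comp_names = [f"PC{i + 1}" for i in range(k_eff)]
    scores = pd.DataFrame(
        (u[:, :k_eff] * s[:k_eff]), index=env_table.index, columns=comp_names
    )
    loadings = pd.DataFrame(vt[:k_eff].T, index=cols, columns=comp_names)
    return EnvPCs(
        scores=scores,
        loadings=loadings,
        variance_fractions=fractions[:k_eff],
        all_variance_fractions=fractions,
    )


def matrix_spearman(
    dist_a: pd.DataFrame | np.ndarray,
    dist_b: pd.DataFrame | np.ndarray,
    n_perm: int = 999,
    seed: int = 0,
    exhaustive: bool = False,
) -> tuple[float, float]:
    """Mantel-style Spearman correlation between two distance matrices.

    rho is computed over upper-triangle entries; the p-value is two-sided by
    |rho| from ``n_perm`` permutations of the row/column labels of the second
    matrix: p = (1 + #{|rho_perm| >= |rho_obs|}) / (n_perm + 1). With
    ``exhaustive=True`` all n! label permutations are enumerated instead and
    p = #{|rho_perm| >= |rho_obs|} / n! (the identity permutation counts).
    """
    a = np.asarray(dist_a, float)
    b = np.asarray(dist_b, float)
    if a.shape != b.shape or a.shape[0] != a.shape[1]:
        raise ValueError("matrices must be square and of equal size")
    n = a.shape[0]
    iu = np.triu_indices(n, k=1)

    def _rho(m_b: np.ndarray) -> float:
        va, vb = a[iu], m_b[iu]
        if np.all(va == va[0]) or np.all(vb == vb[0]):
            return np.nan
        ra = pd.Series(va).rank().to_numpy()
        rb = pd.Series(vb).rank().to_numpy()
        return float(np.corrcoef(ra, rb)[0, 1])

    rho = _rho(b)
    if np.isnan(rho):
        warnings.warn("constant distance matrix: rho undefined")
        return np.nan, np.nan

    if exhaustive:
        from itertools import permutations

        hits = 0
        total = 0
        for perm in permutations(range(n)):
            idx = np.array(perm)
            r = _rho(b[np.ix_(idx, idx)])
            total += 1
            if not np.isnan(r) and abs(r) >= abs(rho) - 1e-12:
                hits += 1
        return rho, hits / total

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r = _rho(b[np.ix_(perm, perm)])
        if not np.isnan(r) and abs(r) >= abs(rho) - 1e-12:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return rho, p
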