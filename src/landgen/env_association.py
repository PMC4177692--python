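"""Genotype-environment association engines.

Two structure-aware engines share a result contract: a kinship mixed
model solved by spectral decomposition (single variance component, REML
variance ratio estimated once on the null model), and a latent-factor
regression with genomic-control recalibration. Significance is judged
against an externally supplied LD-corrected Bonferroni threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .popgen import GenotypeMatrix, KinshipMatrix

_CHI2_MEDIAN_1DF = stats.chi2.ppf(0.5, df=1)


@dataclass
class AssocResult:
    """Per-locus association statistics for one environmental response."""

    table: pd.DataFrame  # columns: locus, chrom, pos, pc, beta, stat, p
    method: str

    def significant(self, threshold: float) -> pd.DataFrame:
        out = self.table.copy()
        out["flag"] = out["p"] < threshold
        return out


def _response_vector(env_pc: pd.Series | np.ndarray, samples: list[str],
                     groups: pd.Series | None) -> np.ndarray:
    """Map a per-location (or per-sample) response onto samples."""
    if isinstance(env_pc, pd.Series):
        if set(samples) <= set(env_pc.index):
            return env_pc.reindex(samples).to_numpy(float)
        if groups is not None:
            return env_pc.reindex(groups.reindex(samples)).to_numpy(float)
        raise ValueError("cannot align response with samples")
    y = np.asarray(env_pc, float)
    if len(y) != len(samples):
        raise ValueError("response length does not match samples")
    return y


# ---------------------------------------------------------------------------
# Mixed model (EMMA-style spectral solve)


def _reml_neg_loglik(log_delta: float, yt: np.ndarray, xt: np.ndarray,
                     s: np.ndarray) -> float:
    delta = np.exp(log_delta)
    w = s + delta
    xw = xt / w[:, None]
    xtx = xt.T @ xw
    beta = np.linalg.solve(xtx, xw.T @ yt)
    r = yt - xt @ beta
    n, q = xt.shape
    sigma2 = float(r @ (r / w)) / (n - q)
    _, logdet_xtx = np.linalg.slogdet(xtx)
    ll = -0.5 * (
        (n - q) * (np.log(2 * np.pi * sigma2) + 1.0)
        + np.sum(np.log(w))
        + logdet_xtx
    )
    return -ll


def mlm_assoc(
    g: GenotypeMatrix,
    env_pc: pd.Series | np.ndarray,
    K: KinshipMatrix,
    Q: pd.DataFrame | None = None,
    pc_name: str = "PC1",
    delta: float | None = None,
) -> AssocResult:
    """Kinship mixed-model association of each locus with one response.

    The variance ratio delta = sigma_e^2 / sigma_g^2 is REML-estimated once
    on the null model (intercept + Q) via Brent search on log-delta in
    [-10, 10], then each SNP is tested by generalized least squares in the
    eigenbasis of K (exact F test, 1 df). Missing dosages are mean-imputed
    per locus; loci collinear with the covariates get a missing p.
    """
    y = _response_vector(env_pc, g.samples, g.groups)
    kmat = K.values.reindex(index=g.samples, columns=g.samples).to_numpy(float)
    s, u = np.linalg.eigh(kmat)
    s = np.clip(s, 0.0, None)

    covs = [np.ones((g.n_samples, 1))]
    if Q is not None:
        covs.append(Q.reindex(g.samples).to_numpy(float))
    x0 = np.hstack(covs)

    yt = u.T @ y
    x0t = u.T @ x0
    if delta is None:
        res = optimize.minimize_scalar(
            _reml_neg_loglik,
            bounds=(-10.0, 10.0),
            args=(yt, x0t, s),
            method="bounded",
            options={"xatol": 1e-8},
        )
        delta = float(np.exp(res.x))
    w = s + delta

    dos = g.dosage(impute=True)
    dost = u.T @ dos
    n = g.n_samples
    q_full = x0.shape[1] + 1
    df_resid = n - q_full

    betas = np.full(g.n_loci, np.nan)
    stats_ = np.full(g.n_loci, np.nan)
    pvals = np.full(g.n_loci, np.nan)
    sw = 1.0 / w
    for k in range(g.n_loci):
        xt = np.column_stack([x0t, dost[:, k]])
        xw = xt * sw[:, None]
        xtx = xt.T @ xw
        try:
            xtx_inv = np.linalg.inv(xtx)
        except np.linalg.LinAlgError:
            continue
        if np.linalg.cond(xtx) > 1e12:
            continue
        beta = xtx_inv @ (xw.T @ yt)
        r = yt - xt @ beta
        sigma2 = float(r @ (r * sw)) / df_resid
        se2 = sigma2 * xtx_inv[-1, -1]
        if se2 <= 0:
            continue
        tstat = beta[-1] / np.sqrt(se2)
        betas[k] = beta[-1]
        stats_[k] = tstat**2
        pvals[k] = stats.f.sf(tstat**2, 1, df_resid)

    table = pd.DataFrame(
        {
            "locus": np.arange(g.n_loci),
            "chrom": g.chrom,
            "pos": g.pos,
            "pc": pc_name,
            "beta": betas,
            "stat": stats_,
            "p": pvals,
        }
    )
    return AssocResult(table=table, method="mlm")


# ---------------------------------------------------------------------------
# Latent-factor regression


def _latent_factors(
    centered: np.ndarray, y: np.ndarray, L: int, ridge: float
) -> np.ndarray:
    """Latent factor scores from a ridge-regularized truncated decomposition.

    The genotype matrix is rotated into the eigenbasis of the (centered)
    response design and the response direction shrunk by
    sqrt(ridge / (ridge + s^2)) before the rank-L SVD, so factors explain
    structure rather than the tested environmental axis; ridge -> inf
    recovers the plain truncated SVD.
    """
    n = centered.shape[0]
    yc = (y - y.mean()).reshape(-1, 1)
    q, s, _ = np.linalg.svd(yc, full_matrices=True)
    shrink = np.ones(n)
    shrink[: len(s)] = np.sqrt(ridge / (ridge + s**2))
    yt = (q.T @ centered) * shrink[:, None]
    u, _, _ = np.linalg.svd(yt, full_matrices=False)
    factors = q @ (u[:, :L] / shrink[:, None][: u.shape[0]])
    # orthonormalize for a well-conditioned design
    factors, _ = np.linalg.qr(factors)
    return factors


def lfmm_assoc(
    g: GenotypeMatrix,
    env_pc: pd.Series | np.ndarray,
    L: int = 5,
    pc_name: str = "PC1",
    calibrate: bool = True,
    ridge: float = 1e-5,
) -> AssocResult:
    """Latent-factor association: regress each locus dosage on the response
    given L latent factors (ridge-regularized least-squares estimate, see
    :func:`_latent_factors`); z-scores are recalibrated by a median-based
    genomic-inflation factor before p-values. L=0 reduces to plain
    per-locus regression.
    """
    if L < 0:
        raise ValueError("L must be >= 0")
    if L >= g.n_samples:
        raise ValueError("L must be < number of samples")
    y = _response_vector(env_pc, g.samples, g.groups)
    dos = g.dosage(impute=True)
    centered = dos - dos.mean(axis=0)

    design = [np.ones(g.n_samples), y]
    if L > 0:
        factors = _latent_factors(centered, y, L, ridge)
        design.extend(factors.T)
    x = np.column_stack(design)
    q = x.shape[1]
    df = g.n_samples - q
    if df < 1:
        raise ValueError("not enough samples for the requested factors")

    xtx_inv = np.linalg.inv(x.T @ x)
    hat = xtx_inv @ x.T
    betas_all = hat @ centered              # (q, n_loci)
    resid = centered - x @ betas_all
    sigma2 = (resid**2).sum(axis=0) / df
    se = np.sqrt(np.clip(sigma2 * xtx_inv[1, 1], 1e-300, None))
    z = betas_all[1] / se

    gif = 1.0
    if calibrate:
        med = np.median(z[np.isfinite(z)] ** 2)
        gif = max(med / _CHI2_MEDIAN_1DF, 1e-12)
    z2 = z**2 / gif
    pvals = stats.chi2.sf(z2, df=1)

    table = pd.DataFrame(
        {
            "locus": np.arange(g.n_loci),
            "chrom": g.chrom,
            "pos": g.pos,
            "pc": pc_name,
            "beta": betas_all[1],
            "stat": z2,
            "p": pvals,
        }
    )
    result = AssocResult(table=table, method="lfmm")
    result.inflation_factor = gif
    return result


# ---------------------------------------------------------------------------
# Thresholding and method intersection


def select_eas(result: AssocResult, threshold: float) -> pd.DataFrame:
    """Loci passing the LD-corrected threshold, with significance flags."""
    flagged = result.significant(threshold)
    return flagged[flagged["flag"]].reset_index(drop=True)


def intersect_methods(
    a: pd.DataFrame, b: pd.DataFrame, per_pc: bool = True
) -> pd.DataFrame:
    """Loci significant in both engines (per environmental PC by default;
    set per_pc=False for the pooled union over PCs)."""
    keys = ["locus", "pc"] if per_pc else ["locus"]
    ka = a[keys].drop_duplicates()
    kb = b[keys].drop_duplicates()
    both = ka.merge(kb, on=keys)
    return both.sort_values(keys).reset_index(drop=True)
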