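"""Bayesian Fst-decomposition outlier scan.

Per-locus, per-population differentiation is modelled on the logit scale
as a locus effect plus a population effect, logit(Fst_ij) = alpha_i +
beta_j, with a beta-binomial likelihood of the observed alternate-allele
counts given ancestral frequencies. The locus effect carries a
spike-and-slab inclusion indicator (Kuo-Mallick variable selection) with
fixed prior odds against inclusion; outliers are flagged by q-value at an
FDR threshold computed from posterior inclusion probabilities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln, logit

from .popgen import MISSING, GenotypeMatrix

_ALPHA_PRIOR_SD = 1.0
_BETA_PRIOR_MEAN = -1.0
_BETA_PRIOR_SD = 1.8


@dataclass
class OutlierResult:
    """Per-locus posterior quantities and FDR flags."""

    table: pd.DataFrame  # columns: locus, alpha_mean, inclusion_prob, q, flag
    beta_mean: np.ndarray
    fdr: float
    converged: bool = True
    trace: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        t = self.table.sort_values("inclusion_prob", ascending=False)
        q = t["q"].to_numpy()
        if np.any(np.diff(q) < -1e-9):
            raise ValueError("q-values must be non-decreasing in rank")


def allele_counts(
    g: GenotypeMatrix, groups: pd.Series | None = None
) -> tuple[np.ndarray, np.ndarray, list]:
    """Per-locus per-group (alt, total) allele counts from non-missing calls.

    Returns (alt_counts, total_counts, group_names), each counts array of
    shape (n_loci, n_groups); totals are 2 x non-missing samples.
    """
    if groups is None:
        groups = g.groups
    if groups is None:
        raise ValueError("no group labels available")
    labels = groups.reindex(g.samples).to_numpy()
    names = sorted(pd.unique(labels))
    n_loci = g.n_loci
    alt = np.zeros((n_loci, len(names)), dtype=np.int64)
    tot = np.zeros((n_loci, len(names)), dtype=np.int64)
    for j, name in enumerate(names):
        codes = g.codes[labels == name]
        obs = codes != MISSING
        alt[:, j] = np.where(obs, codes, 0).sum(axis=0)
        tot[:, j] = 2 * obs.sum(axis=0)
    return alt, tot, names


def _betabinom_loglik(
    alt: np.ndarray, tot: np.ndarray, p: np.ndarray, fst: np.ndarray
) -> np.ndarray:
    """Element-wise beta-binomial log-likelihood (binomial coefficient
    dropped); p broadcast per locus, fst per locus x population."""
    theta = 1.0 / np.clip(fst, 1e-12, 1 - 1e-12) - 1.0
    a1 = theta * p
    a2 = theta * (1.0 - p)
    return (
        gammaln(alt + a1)
        + gammaln(tot - alt + a2)
        - gammaln(tot + theta)
        - gammaln(a1)
        - gammaln(a2)
        + gammaln(theta)
    )


def _locus_loglik(alt, tot, p, alpha, beta, include) -> np.ndarray:
    """Row sums of the likelihood given current parameters."""
    eff = np.where(include, alpha, 0.0)
    fst = expit(eff[:, None] + beta[None, :])
    return _betabinom_loglik(alt, tot, p[:, None], fst).sum(axis=1)


def bayes_fst_scan(
    counts: tuple[np.ndarray, np.ndarray],
    n_burn: int = 1000,
    n_iter: int = 10000,
    thin: int = 10,
    prior_odds: float = 10.0,
    fdr: float = 0.05,
    seed: int = 0,
) -> OutlierResult:
    """Metropolis-within-Gibbs scan for locus-specific selection effects.

    ``counts`` is the (alt, total) pair from :func:`allele_counts`.
    Proposal scales are tuned adaptively during burn-in (target 25-45%
    acceptance) and frozen afterwards. Identical seeds give identical
    posterior summaries.
    """
    alt, tot = counts
    alt = np.asarray(alt, float)
    tot = np.asarray(tot, float)
    n_loci, n_pops = alt.shape
    if n_pops < 2:
        raise ValueError("need at least two populations")
    rng = np.random.default_rng(seed)

    # initial state: ancestral freqs from pooled counts, no selection
    pool = (alt.sum(axis=1) + 1.0) / (tot.sum(axis=1) + 2.0)
    x = logit(np.clip(pool, 1e-4, 1 - 1e-4))     # logit ancestral freq
    alpha = rng.normal(0.0, _ALPHA_PRIOR_SD, size=n_loci)
    include = np.zeros(n_loci, dtype=bool)
    beta = np.full(n_pops, _BETA_PRIOR_MEAN)
    pi_incl = 1.0 / (1.0 + prior_odds)
    log_prior_odds = np.log(pi_incl) - np.log1p(-pi_incl)

    sd_p = np.full(n_loci, 0.5)
    sd_a = np.full(n_loci, 0.5)
    sd_b = np.full(n_pops, 0.3)
    acc_p = np.zeros(n_loci)
    acc_a = np.zeros(n_loci)
    acc_b = np.zeros(n_pops)

    def full_ll(xv, av, inc, bv):
        p = expit(xv)
        return _locus_loglik(alt, tot, p, av, bv, inc)

    ll_rows = full_ll(x, alpha, include, beta)

    keep_incl = np.zeros(n_loci)
    keep_alpha = np.zeros(n_loci)
    keep_beta = np.zeros(n_pops)
    beta_first = np.zeros(n_pops)
    beta_second = np.zeros(n_pops)
    n_kept = 0
    n_first = 0
    n_second = 0

    total_sweeps = n_burn + n_iter
    tune_every = 50
    for sweep in range(total_sweeps):
        # --- ancestral frequencies (vectorized MH on the logit scale;
        # uniform prior on p gives a log-Jacobian term log p(1-p))
        prop_x = x + rng.normal(0.0, sd_p, size=n_loci)
        prop_rows = full_ll(prop_x, alpha, include, beta)
        log_jac = (np.log(expit(prop_x)) + np.log1p(-expit(prop_x))) - (
            np.log(expit(x)) + np.log1p(-expit(x))
        )
        accept = np.log(rng.random(n_loci)) < prop_rows - ll_rows + log_jac
        x = np.where(accept, prop_x, x)
        ll_rows = np.where(accept, prop_rows, ll_rows)
        acc_p += accept

        # --- locus effects: MH when included, prior draw when excluded
        prop_a = alpha + rng.normal(0.0, sd_a, size=n_loci)
        prop_rows = full_ll(x, prop_a, include, beta)
        log_prior = -0.5 * (prop_a**2 - alpha**2) / _ALPHA_PRIOR_SD**2
        accept = np.log(rng.random(n_loci)) < prop_rows - ll_rows + log_prior
        accept &= include
        alpha = np.where(accept, prop_a, alpha)
        ll_rows = np.where(accept, prop_rows, ll_rows)
        acc_a += accept
        fresh = ~include
        alpha[fresh] = rng.normal(0.0, _ALPHA_PRIOR_SD, size=int(fresh.sum()))

        # --- inclusion indicators (Gibbs given alpha)
        ll_in = full_ll(x, alpha, np.ones(n_loci, bool), beta)
        ll_out = full_ll(x, alpha, np.zeros(n_loci, bool), beta)
        logit_post = log_prior_odds + ll_in - ll_out
        include = np.log(rng.random(n_loci)) < -np.logaddexp(0.0, -logit_post)
        ll_rows = np.where(include, ll_in, ll_out)

        # --- population effects (MH one at a time)
        p = expit(x)
        eff = np.where(include, alpha, 0.0)
        for j in range(n_pops):
            prop_b = beta[j] + rng.normal(0.0, sd_b[j])
            fst_old = expit(eff + beta[j])
            fst_new = expit(eff + prop_b)
            ll_old = _betabinom_loglik(
                alt[:, j], tot[:, j], p, fst_old
            ).sum()
            ll_new = _betabinom_loglik(
                alt[:, j], tot[:, j], p, fst_new
            ).sum()
            dprior = -0.5 * (
                (prop_b - _BETA_PRIOR_MEAN) ** 2 - (beta[j] - _BETA_PRIOR_MEAN) ** 2
            ) / _BETA_PRIOR_SD**2
            if np.log(rng.random()) < ll_new - ll_old + dprior:
                beta[j] = prop_b
                acc_b[j] += 1
        ll_rows = full_ll(x, alpha, include, beta)

        # --- adaptive tuning during burn-in
        if sweep < n_burn and (sweep + 1) % tune_every == 0:
            for sd_arr, acc_arr in ((sd_p, acc_p), (sd_a, acc_a), (sd_b, acc_b)):
                rate = acc_arr / tune_every
                sd_arr[rate > 0.45] *= 1.4
                sd_arr[rate < 0.25] *= 0.7
                np.clip(sd_arr, 1e-3, 10.0, out=sd_arr)
                acc_arr[:] = 0.0

        if sweep >= n_burn and (sweep - n_burn) % thin == 0:
            keep_incl += include
            keep_alpha += np.where(include, alpha, 0.0)
            keep_beta += beta
            n_kept += 1
            if sweep - n_burn < n_iter // 2:
                beta_first += beta
                n_first += 1
            else:
                beta_second += beta
                n_second += 1

    pip = keep_incl / n_kept
    alpha_mean = keep_alpha / n_kept
    beta_mean = keep_beta / n_kept

    converged = True
    if n_first and n_second:
        gap = np.abs(beta_first / n_first - beta_second / n_second)
        if np.any(gap > 0.5):
            converged = False
            warnings.warn(
                "population-effect chain halves disagree; consider longer runs"
            )

    # q-value: mean (1 - PIP) over loci at least as included as locus i
    order = np.argsort(-pip, kind="stable")
    one_minus = 1.0 - pip[order]
    q_sorted = np.cumsum(one_minus) / np.arange(1, n_loci + 1)
    # ties in PIP share the q of the last tied rank (pip_j >= pip_i rule)
    pip_sorted = pip[order]
    for end in range(n_loci - 2, -1, -1):
        if pip_sorted[end] == pip_sorted[end + 1]:
            q_sorted[end] = q_sorted[end + 1]
    q = np.empty(n_loci)
    q[order] = q_sorted
    flag = q <= fdr

    table = pd.DataFrame(
        {
            "locus": np.arange(n_loci),
            "alpha_mean": alpha_mean,
            "inclusion_prob": pip,
            "q": q,
            "flag": flag,
        }
    )
    return OutlierResult(
        table=table, beta_mean=beta_mean, fdr=fdr, converged=converged
    )


def summarize_scan(result_or_n, n_total_loci: int) -> dict:
    """Outlier count and percentage of loci analysed (one decimal)."""
    if isinstance(result_or_n, OutlierResult):
        n_outliers = int(result_or_n.table["flag"].sum())
    else:
        n_outliers = int(result_or_n)
    if n_total_loci <= 0:
        raise ValueError("n_total_loci must be positive")
    pct = round(100.0 * n_outliers / n_total_loci, 1)
    return {"n_outliers": n_outliers, "n_total_loci": n_total_loci,
            "percent": pct}
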