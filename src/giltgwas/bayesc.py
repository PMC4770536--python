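"""BayesC / BayesC-pi whole-genome regression by single-site Gibbs sampling.

Model:  y = X beta + Z u + e

Each SNP effect u_j is zero with prior probability pi and otherwise drawn
from a common normal N(0, sigma2_u); sigma2_u and sigma2_e carry
scaled-inverse-chi-square priors; fixed effects are flat.  In
"estimated" pi mode (BayesC-pi) pi gets a uniform prior and is sampled
from its Beta full conditional each iteration.  The intended two-stage
use mirrors common practice: estimate pi once with BayesC-pi, then rerun
BayesC with pi fixed at that estimate.

The sweep updates, in order: fixed effects; each SNP (indicator delta_j
from its marginalised Bernoulli full conditional, then the effect from
its normal full conditional when included); sigma2_u; sigma2_e; pi.
SNPs are visited in column order and the residual vector is updated
incrementally, so one iteration costs O(nm).  The hot loop is compiled
with numba.

Per retained iteration the sampler records the genetic variance as the
empirical variance across animals of the genomic values Zu (an
alternative sum(2*p*q*u^2) definition is available via
``genvar_mode="sum2pq"``) and the total variance as genetic + sigma2_e;
marker heritability is the posterior mean of their ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from numba import njit

from .pedigree import PriorSpec


class McmcError(RuntimeError):
    pass


@dataclass
class McmcConfig:
    """Sampler settings.

    pi is the prior probability of a zero SNP effect; with
    ``estimate_pi=True`` it is only the starting value.  ``s_u``/``s_e``
    left as None are derived from the phenotypic variance (half assigned
    to markers, half to residual) — a weakly informative default used when
    no REML priors are supplied.  ``fix_sigma2_u``/``fix_sigma2_e`` clamp
    the variances (used by the SNP-BLUP equivalence checks).
    """

    n_iter: int = 5000
    burn_in: int = 1000
    thin: int = 1
    pi: float = 0.9935
    estimate_pi: bool = False
    nu_u: float = 4.0
    s_u: float | None = None
    nu_e: float = 10.0
    s_e: float | None = None
    seed: int = 0
    fix_sigma2_u: float | None = None
    fix_sigma2_e: float | None = None
    genvar_mode: str = "genomic"  # empirical var(Zu) | "sum2pq"

    def __post_init__(self):
        if not 0 <= self.burn_in < self.n_iter:
            raise McmcError("require 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise McmcError("thin must be >= 1")
        if not 0.0 <= self.pi < 1.0:
            # pi = 0 keeps every SNP in the model (the SNP-BLUP limit)
            raise McmcError("pi must lie in [0, 1)")

    @property
    def n_kept(self) -> int:
        return (self.n_iter - self.burn_in + self.thin - 1) // self.thin

    def with_priors(self, priors: PriorSpec) -> "McmcConfig":
        return replace(
            self, nu_u=priors.nu_u, s_u=priors.s_u, nu_e=priors.nu_e, s_e=priors.s_e
        )


@dataclass
class PosteriorSummary:
    """Posterior means and retained variance chains from one sampler run."""

    beta_mean: np.ndarray
    u_mean: np.ndarray
    inclusion_prob: np.ndarray
    chains: dict  # sigma2_u, sigma2_e, pi, genetic_variance, total_variance, n_included
    config: McmcConfig
    markers: pd.DataFrame | None = None

    @property
    def pi_mean(self) -> float:
        return float(np.mean(self.chains["pi"]))

    @property
    def sigma2_e_mean(self) -> float:
        return float(np.mean(self.chains["sigma2_e"]))

    @property
    def genetic_variance_mean(self) -> float:
        return float(np.mean(self.chains["genetic_variance"]))

    @property
    def h2_marker(self) -> float:
        return marker_h2(self)

    def effects_frame(self) -> pd.DataFrame:
        df = (
            self.markers[["name", "chrom", "pos_bp"]].copy()
            if self.markers is not None
            else pd.DataFrame(index=range(self.u_mean.size))
        )
        df["u_mean"] = self.u_mean
        df["inclusion_prob"] = self.inclusion_prob
        return df


@njit(cache=True)
def _gibbs_kernel(
    y,
    X,
    Z,
    het,
    n_iter,
    burn_in,
    thin,
    pi0,
    estimate_pi,
    nu_u,
    s_u,
    nu_e,
    s_e,
    fix_u_flag,
    fix_u_val,
    fix_e_flag,
    fix_e_val,
    genvar_sum2pq,
    seed,
):
    np.random.seed(seed)
    n, m = Z.shape
    p = X.shape[1]
    xnorm = np.empty(p)
    for j in range(p):
        s = 0.0
        for i in range(n):
            s += X[i, j] * X[i, j]
        xnorm[j] = s
    znorm = np.empty(m)
    for j in range(m):
        s = 0.0
        for i in range(n):
            s += Z[i, j] * Z[i, j]
        znorm[j] = s

    beta = np.zeros(p)
    u = np.zeros(m)
    r = y.copy()
    fixed_part = np.zeros(n)

    sigma2_e = fix_e_val if fix_e_flag else max(np.var(y) * 0.5, 1e-8)
    sigma2_u = fix_u_val if fix_u_flag else s_u * nu_u / max(nu_u - 2.0, 1.0)
    pi = pi0

    n_kept = (n_iter - burn_in + thin - 1) // thin
    c_su = np.empty(n_kept)
    c_se = np.empty(n_kept)
    c_pi = np.empty(n_kept)
    c_gv = np.empty(n_kept)
    c_k = np.empty(n_kept)
    u_sum = np.zeros(m)
    d_sum = np.zeros(m)
    b_sum = np.zeros(p)
    kept = 0

    for it in range(n_iter):
        # fixed effects, flat prior
        for j in range(p):
            rhs = 0.0
            for i in range(n):
                rhs += X[i, j] * r[i]
            rhs += xnorm[j] * beta[j]
            mean = rhs / xnorm[j]
            new = mean + np.random.standard_normal() * np.sqrt(sigma2_e / xnorm[j])
            diff = new - beta[j]
            if diff != 0.0:
                for i in range(n):
                    r[i] -= X[i, j] * diff
                    fixed_part[i] += X[i, j] * diff
            beta[j] = new

        # SNP indicators and effects
        k = 0
        uss = 0.0
        log_prior_odds = np.log(1.0 - pi) - np.log(pi)
        lam = sigma2_e / sigma2_u
        for j in range(m):
            c = znorm[j]
            if c <= 0.0:
                u[j] = 0.0
                continue
            rhs = 0.0
            for i in range(n):
                rhs += Z[i, j] * r[i]
            if u[j] != 0.0:
                rhs += c * u[j]
            v = c + lam
            log_bf = 0.5 * (np.log(lam) - np.log(v)) + rhs * rhs / (
                2.0 * sigma2_e * v
            )
            t = log_bf + log_prior_odds
            if t > 35.0:
                prob1 = 1.0
            elif t < -35.0:
                prob1 = 0.0
            else:
                prob1 = 1.0 / (1.0 + np.exp(-t))
            if np.random.random() < prob1:
                newu = rhs / v + np.random.standard_normal() * np.sqrt(sigma2_e / v)
                k += 1
                uss += newu * newu
                if it >= burn_in:
                    d_sum[j] += 1.0
            else:
                newu = 0.0
            diff = newu - u[j]
            if diff != 0.0:
                for i in range(n):
                    r[i] -= Z[i, j] * diff
            u[j] = newu

        # variances
        if not fix_u_flag:
            sigma2_u = (uss + nu_u * s_u) / np.random.chisquare(nu_u + k)
        if not fix_e_flag:
            sse = 0.0
            for i in range(n):
                sse += r[i] * r[i]
            sigma2_e = (sse + nu_e * s_e) / np.random.chisquare(nu_e + n)
        if not np.isfinite(sigma2_e) or sigma2_e > 1e30:
            return (
                it,
                beta,
                u_sum,
                d_sum,
                b_sum,
                c_su,
                c_se,
                c_pi,
                c_gv,
                c_k,
            )
        if estimate_pi:
            pi = np.random.beta(m - k + 1.0, k + 1.0)
            if pi >= 1.0 - 1e-12:
                pi = 1.0 - 1e-12
            elif pi <= 1e-12:
                pi = 1e-12

        if it >= burn_in and (it - burn_in) % thin == 0:
            if genvar_sum2pq:
                gv = 0.0
                for j in range(m):
                    if u[j] != 0.0:
                        gv += het[j] * u[j] * u[j]
            else:
                mean_g = 0.0
                for i in range(n):
                    mean_g += y[i] - fixed_part[i] - r[i]
                mean_g /= n
                gv = 0.0
                for i in range(n):
                    gi = y[i] - fixed_part[i] - r[i] - mean_g
                    gv += gi * gi
                gv /= n - 1
            c_su[kept] = sigma2_u
            c_se[kept] = sigma2_e
            c_pi[kept] = pi
            c_gv[kept] = gv
            c_k[kept] = k
            u_sum += u
            b_sum += beta
            kept += 1

    return (-1, beta, u_sum, d_sum, b_sum, c_su, c_se, c_pi, c_gv, c_k)


def run_mcmc(
    y: np.ndarray,
    X: np.ndarray,
    Z: np.ndarray,
    config: McmcConfig,
    markers: pd.DataFrame | None = None,
) -> PosteriorSummary:
    """Run the Gibbs sampler and summarise the posterior.

    ``X`` must be full column rank (use :func:`year_season_design`);
    ``Z`` is the centred genotype design from
    :func:`giltgwas.qc.encode_center_impute`.
    """
    y = np.ascontiguousarray(y, dtype=np.float64)
    X = np.asfortranarray(X, dtype=np.float64)
    Z = np.asfortranarray(Z, dtype=np.float64)
    n, m = Z.shape
    if y.shape != (n,) or X.shape[0] != n:
        raise McmcError(
            f"non-conformable shapes: y {y.shape}, X {X.shape}, Z {Z.shape}"
        )
    if markers is not None and len(markers) != m:
        raise McmcError("marker table does not match Z columns")

    cfg = _fill_default_scales(config, y, Z)
    # heterozygosity proxy from the centred design: mean(z^2) ~= 2 p q
    het = np.ascontiguousarray((Z**2).mean(axis=0))

    status, beta, u_sum, d_sum, b_sum, c_su, c_se, c_pi, c_gv, c_k = _gibbs_kernel(
        y,
        X,
        Z,
        het,
        cfg.n_iter,
        cfg.burn_in,
        cfg.thin,
        cfg.pi,
        cfg.estimate_pi,
        cfg.nu_u,
        cfg.s_u,
        cfg.nu_e,
        cfg.s_e,
        cfg.fix_sigma2_u is not None,
        cfg.fix_sigma2_u if cfg.fix_sigma2_u is not None else 0.0,
        cfg.fix_sigma2_e is not None,
        cfg.fix_sigma2_e if cfg.fix_sigma2_e is not None else 0.0,
        cfg.genvar_mode == "sum2pq",
        int(config.seed) & 0x7FFFFFFF,
    )
    if status >= 0:
        raise McmcError(f"residual variance diverged at iteration {status}")
    kept = cfg.n_kept
    denom = (cfg.n_iter - cfg.burn_in)  # every post-burn-in iteration counts delta
    chains = {
        "sigma2_u": c_su[:kept],
        "sigma2_e": c_se[:kept],
        "pi": c_pi[:kept],
        "genetic_variance": c_gv[:kept],
        "total_variance": c_gv[:kept] + c_se[:kept],
        "n_included": c_k[:kept],
    }
    return PosteriorSummary(
        beta_mean=b_sum / kept,
        u_mean=u_sum / kept,
        inclusion_prob=d_sum / denom,
        chains=chains,
        config=cfg,
        markers=markers,
    )


def _fill_default_scales(config: McmcConfig, y, Z) -> McmcConfig:
    if config.s_u is not None and config.s_e is not None:
        return config
    vary = float(np.var(y, ddof=1))
    m = Z.shape[1]
    mean_het = float((Z**2).mean())
    s_e = config.s_e
    s_u = config.s_u
    if s_e is None:
        s_e = 0.5 * vary * (config.nu_e - 2.0) / config.nu_e
    if s_u is None:
        expected_included = max(m * (1.0 - config.pi), 1.0)
        e_su = 0.5 * vary / (expected_included * max(mean_het, 1e-12))
        s_u = e_su * (config.nu_u - 2.0) / config.nu_u
    return replace(config, s_u=float(s_u), s_e=float(s_e))


def year_season_design(phen: pd.DataFrame, column: str = "year_season") -> np.ndarray:
    """Intercept + dummy columns for all but the first contemporary-group class."""
    labels = phen[column].astype(str)
    classes = list(pd.unique(labels))
    X = np.ones((len(labels), len(classes)))
    for j, c in enumerate(classes[1:], start=1):
        X[:, j] = (labels == c).to_numpy(float)
    return X


def estimate_pi(
    y: np.ndarray,
    X: np.ndarray,
    Z: np.ndarray,
    config: McmcConfig,
    markers: pd.DataFrame | None = None,
) -> tuple[float, PosteriorSummary]:
    """BayesC-pi: sample pi and return its posterior mean with the full summary.

    Two-stage use: feed the returned estimate back into a fixed-pi BayesC
    run for effect estimation and window scanning.
    """
    cfg = replace(config, estimate_pi=True)
    summary = run_mcmc(y, X, Z, cfg, markers=markers)
    return summary.pi_mean, summary


def marker_h2(summary: PosteriorSummary) -> float:
    """Posterior mean of genetic/(genetic+residual) variance across the chain."""
    gv = summary.chains["genetic_variance"]
    se = summary.chains["sigma2_e"]
    if gv.size == 0:
        raise McmcError("empty chains")
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(gv + se > 0, gv / (gv + se), 0.0)
    return float(np.mean(ratio))
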