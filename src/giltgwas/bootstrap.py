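"""Parametric-bootstrap window test and proportion-of-false-positives control.

The null distribution of a putative QTL window's genetic variance is
built by simulating phenotypes from the fitted model with that window's
SNP effects set to zero:

    y* = X beta_hat + Z u_hat(window zeroed) + e*,   e* ~ N(0, sigma2_e_hat I)

so replicates differ only in their residual draws.  Each replicate is
reanalysed with the same BayesC model and the tested window's genetic
variance recomputed; with k the number of replicate statistics at or
above the observed one (ties count as exceedances — conservative) out of
B replicates, the comparison-wise p-value is the interval
(k/B, (k+1)/B).

Multiple testing across the scan is summarised by the proportion of
false positives, a function of the average comparison-wise type-I error,
the proportion of true nulls, and the assumed power.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bayesc import McmcConfig, McmcError, PosteriorSummary, run_mcmc
from .windows import WINDOW_SIZE, WindowDef


@dataclass
class BootstrapResult:
    """Observed window statistic and its bootstrap exceedance count."""

    window_id: int
    observed_gv: float
    n_replicates: int
    exceed_count: int
    replicate_gv: np.ndarray | None = None

    def __post_init__(self):
        if not 0 <= self.exceed_count <= self.n_replicates:
            raise ValueError("exceedance count must lie in [0, B]")

    @property
    def p_lower(self) -> float:
        return self.exceed_count / self.n_replicates

    @property
    def p_upper(self) -> float:
        return (self.exceed_count + 1) / self.n_replicates

    def significant_at(self, alpha: float) -> bool:
        """Classify using the conservative upper end of the p interval."""
        return self.p_upper <= alpha


def simulate_null_dataset(
    summary: PosteriorSummary,
    X: np.ndarray,
    Z: np.ndarray,
    window: WindowDef,
    seed: int,
) -> np.ndarray:
    """One bootstrap phenotype vector under "no QTL in this window".

    Uses the posterior means of the fixed effects, of every SNP effect
    outside the window (inside set to zero), and of the residual
    variance.
    """
    u = np.array(summary.u_mean, float, copy=True)
    if window.first_index + WINDOW_SIZE > u.size:
        raise ValueError("window not contained in the fitted marker set")
    u[window.first_index : window.first_index + WINDOW_SIZE] = 0.0
    mean = X @ summary.beta_mean + Z @ u
    rng = np.random.default_rng(seed)
    return mean + rng.normal(0.0, np.sqrt(summary.sigma2_e_mean), size=mean.size)


def _window_gv(u_mean: np.ndarray, Z: np.ndarray, window: WindowDef) -> float:
    sl = slice(window.first_index, window.first_index + WINDOW_SIZE)
    return float(np.var(Z[:, sl] @ u_mean[sl], ddof=1))


def bootstrap_window_test(
    summary: PosteriorSummary,
    X: np.ndarray,
    Z: np.ndarray,
    window: WindowDef,
    observed_gv: float,
    B: int,
    mcmc: McmcConfig,
    seed: int = 0,
    keep_replicates: bool = False,
) -> BootstrapResult:
    """Parametric-bootstrap test of one window's genetic variance.

    ``summary`` is the real-data fit; ``mcmc`` configures the replicate
    reanalyses (typically a shortened chain).  Replicate b uses seeds
    derived from ``seed + b`` for both the residual draw and the sampler;
    a failed replicate is retried once with a fresh seed.
    """
    if B < 1:
        raise ValueError("need at least one bootstrap replicate")
    gvs = np.empty(B)
    for b in range(B):
        for attempt in range(2):
            s = seed + b + attempt * 1_000_003
            ystar = simulate_null_dataset(summary, X, Z, window, seed=s)
            try:
                rep = run_mcmc(
                    ystar,
                    X,
                    Z,
                    McmcConfig(
                        n_iter=mcmc.n_iter,
                        burn_in=mcmc.burn_in,
                        thin=mcmc.thin,
                        pi=mcmc.pi,
                        estimate_pi=mcmc.estimate_pi,
                        nu_u=mcmc.nu_u,
                        s_u=mcmc.s_u,
                        nu_e=mcmc.nu_e,
                        s_e=mcmc.s_e,
                        seed=(s * 2_654_435_761) & 0x7FFFFFFF,
                    ),
                )
                break
            except McmcError:
                if attempt == 1:
                    raise
        gvs[b] = _window_gv(rep.u_mean, Z, window)
    k = int(np.sum(gvs >= observed_gv))
    return BootstrapResult(
        window_id=window.window_id,
        observed_gv=float(observed_gv),
        n_replicates=B,
        exceed_count=k,
        replicate_gv=gvs if keep_replicates else None,
    )


def pfp_adjust(alphas, pi0: float, power: float, n_tests: int | None = None) -> float:
    """Proportion of false positives across a set of declared tests.

    PFP = pi0 * sum(alpha_i) / (pi0 * sum(alpha_i) + (1 - pi0) * n_tests * power)

    i.e. expected false positives over expected total positives, with
    ``alphas`` the comparison-wise error rates (use p_upper), ``pi0`` the
    proportion of true null hypotheses among all tested, and ``power``
    the assumed per-test power against true alternatives.
    """
    alphas = np.atleast_1d(np.asarray(alphas, float))
    if n_tests is None:
        n_tests = alphas.size
    if not (0 <= pi0 <= 1 and 0 <= power <= 1):
        raise ValueError("pi0 and power must lie in [0, 1]")
    if ((alphas < 0) | (alphas > 1)).any():
        raise ValueError("alphas must lie in [0, 1]")
    num = pi0 * float(alphas.sum())
    denom = num + (1.0 - pi0) * n_tests * power
    if denom == 0:
        if num == 0 and pi0 < 1:
            raise ValueError("no declared power and zero error rates: PFP undefined")
        if pi0 == 0:
            return 0.0
        raise ValueError("zero denominator: no declared power")
    return num / denom
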