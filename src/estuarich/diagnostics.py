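"""MCMC convergence diagnostics and posterior predictive checks.

Implements the classic (non-split) Gelman-Rubin potential scale reduction
factor, the Raftery-Lewis independence-chain minimum sample size, the
posterior predictive Bayesian p-value with chi-square or Freeman-Tukey
discrepancies, and hold-out validation of a fitted model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .model import ModelData, PosteriorDraws

__all__ = [
    "ConvergenceReport",
    "PPCResult",
    "gelman_rubin",
    "convergence_report",
    "raftery_lewis_nmin",
    "posterior_predictive_p",
    "validate_holdout",
    "bayes_p_from_pairs",
]


class DegenerateChainsError(ValueError):
    """All chains have zero within-chain variance."""


def gelman_rubin(draws_per_chain, split: bool = False) -> float:
    """Classic potential scale reduction factor R-hat.

    ``draws_per_chain`` is (m, n): m >= 2 chains of equal length n >= 2.
    W is the mean within-chain variance, B/n the between-chain variance of
    chain means, var+ = (n-1)/n W + B/n, and R-hat = sqrt(var+/W).
    ``split=True`` halves each chain first (split-chain variant).
    """
    x = np.asarray(draws_per_chain, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a (chains, draws) array")
    if split:
        n2 = x.shape[1] // 2
        x = np.vstack([x[:, :n2], x[:, n2: 2 * n2]])
    m, n = x.shape
    if m < 2 or n < 2:
        raise ValueError("need >= 2 chains of length >= 2")
    within = x.var(axis=1, ddof=1)
    w = within.mean()
    if w == 0.0:
        raise DegenerateChainsError("zero within-chain variance in all chains")
    chain_means = x.mean(axis=1)
    b_over_n = chain_means.var(ddof=1)
    var_plus = (n - 1) / n * w + b_over_n
    return float(np.sqrt(var_plus / w))


#: Parameters monitored for convergence by default (prefix match).
DEFAULT_MONITORED_PREFIXES = ("beta", "sigma2_s", "Sigma1", "Sigma2")


@dataclass
class ConvergenceReport:
    rhat: dict[str, float]
    max_rhat: float
    nmin: int
    passed: bool
    threshold: float = 1.10
    degenerate: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "rhat": self.rhat,
            "max_rhat": self.max_rhat,
            "raftery_lewis_nmin": self.nmin,
            "passed": self.passed,
            "threshold": self.threshold,
            "degenerate": self.degenerate,
        }


def _is_monitored(label: str, prefixes) -> bool:
    base = label.split("[")[0]
    if base not in prefixes:
        return False
    # for covariance matrices only track the diagonal
    if base in ("Sigma1", "Sigma2", "Sigma3") and "[" in label:
        idx = label[label.index("[") + 1: -1].split(",")
        return idx[0] == idx[1]
    return True


def convergence_report(
    draws: PosteriorDraws,
    threshold: float = 1.10,
    parameters: tuple[str, ...] | None = None,
    split: bool = False,
) -> ConvergenceReport:
    """Per-parameter R-hat over the monitored scalar parameters."""
    prefixes = parameters or DEFAULT_MONITORED_PREFIXES
    scalars = draws.per_chain_scalars()
    rhat: dict[str, float] = {}
    degenerate: list[str] = []
    for label, arr in scalars.items():
        if not _is_monitored(label, prefixes):
            continue
        try:
            rhat[label] = gelman_rubin(arr, split=split)
        except DegenerateChainsError:
            degenerate.append(label)
    if not rhat:
        raise ValueError("no monitored parameters found in draws")
    max_rhat = max(rhat.values())
    return ConvergenceReport(
        rhat=rhat,
        max_rhat=max_rhat,
        nmin=raftery_lewis_nmin(),
        passed=max_rhat < threshold and not degenerate,
        threshold=threshold,
        degenerate=degenerate,
    )


def raftery_lewis_nmin(
    q: float = 0.025, r: float = 0.005, s: float = 0.95
) -> int:
    """Raftery-Lewis minimum chain length (independence-chain bound).

    N_min = ceil(q(1-q) (z_{(1+s)/2} / r)^2): draws needed to estimate the
    q-quantile to within +/- r with probability s, assuming independence.
    """
    if not (0 < q < 1) or r <= 0 or not (0 < s < 1):
        raise ValueError("require 0<q<1, r>0, 0<s<1")
    z = stats.norm.ppf((1 + s) / 2)
    return math.ceil(q * (1 - q) * (z / r) ** 2)


# ---------------------------------------------------------------------------
# Posterior predictive checks
# ---------------------------------------------------------------------------


def chisq_discrepancy(y: np.ndarray, lam: np.ndarray) -> np.ndarray:
    """Chi-square discrepancy sum((y - lambda)^2 / lambda), per draw.

    ``y`` broadcasts against ``lam`` of shape (draws, n).
    """
    return ((y - lam) ** 2 / lam).sum(axis=-1)


def freeman_tukey_discrepancy(y: np.ndarray, lam: np.ndarray) -> np.ndarray:
    return ((np.sqrt(y) - np.sqrt(lam)) ** 2).sum(axis=-1)


_DISCREPANCIES = {
    "chisq": chisq_discrepancy,
    "freeman-tukey": freeman_tukey_discrepancy,
}


@dataclass
class PPCResult:
    bayes_p: float
    discrepancy: str
    t_rep: np.ndarray
    t_obs: np.ndarray

    def to_dict(self) -> dict:
        return {"bayes_p": self.bayes_p, "discrepancy": self.discrepancy}


def _lambda_draws(draws: PosteriorDraws, max_draws: int | None) -> np.ndarray:
    if "log_lambda" not in draws.draws:
        raise ValueError(
            "draws do not contain log_lambda; refit with monitor_latent=True"
        )
    lam = np.exp(draws.flat("log_lambda"))
    if max_draws is not None and lam.shape[0] > max_draws:
        idx = np.linspace(0, lam.shape[0] - 1, max_draws).astype(int)
        lam = lam[idx]
    return lam


def bayes_p_from_pairs(t_rep, t_obs) -> float:
    """P_B as the proportion of draws with T(y_rep) >= T(y); ties count."""
    return float(np.mean(np.asarray(t_rep) >= np.asarray(t_obs)))


def _ppc(
    lam_sim: np.ndarray,
    y: np.ndarray,
    discrepancy: str,
    seed: int,
    lam_t: np.ndarray | None = None,
) -> PPCResult:
    """Replicates are drawn from Poisson(lam_sim); the discrepancy is
    evaluated against ``lam_t`` (default: lam_sim) for both replicate and
    observed counts."""
    if lam_t is None:
        lam_t = lam_sim
    if (lam_sim <= 0).any() or (lam_t <= 0).any():
        raise ValueError("non-positive lambda draw violates Poisson support")
    t_fn = _DISCREPANCIES[discrepancy]
    rng = np.random.default_rng(seed)
    y_new = rng.poisson(lam_sim)
    t_rep = t_fn(y_new, lam_t)
    t_obs = t_fn(y[None, :], lam_t)
    bayes_p = bayes_p_from_pairs(t_rep, t_obs)
    return PPCResult(
        bayes_p=bayes_p, discrepancy=discrepancy, t_rep=t_rep, t_obs=t_obs
    )


def posterior_predictive_p(
    draws: PosteriorDraws,
    data: ModelData,
    discrepancy: str = "chisq",
    seed: int = 0,
    max_draws: int | None = 2000,
) -> PPCResult:
    """Bayesian p-value on the fitted data.

    For each posterior draw, replicate counts are simulated from
    Poisson(lambda) and P_B is the proportion of draws with
    T(y_rep, theta) >= T(y, theta) (ties count).
    """
    if discrepancy not in _DISCREPANCIES:
        raise ValueError(f"unknown discrepancy {discrepancy!r}")
    lam = _lambda_draws(draws, max_draws)
    return _ppc(lam, np.asarray(data.y), discrepancy, seed)


def _holdout_lambda(
    draws: PosteriorDraws,
    holdout: ModelData,
    seed: int,
    max_draws: int | None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-draw (simulation lambda, discrepancy lambda) for hold-out rows.

    The simulation lambda carries fresh observation-level lognormal noise
    (a draw from the full posterior predictive); the discrepancy lambda is
    the conditional mean exp(g + sigma2/2), so observed counts — whose
    latent noise is unknowable — are scored against the same reference as
    the replicates.  Rows whose estuary/program index is negative (unseen
    in fitting) get random effects drawn fresh from that draw's fitted
    covariance.
    """
    rng = np.random.default_rng(seed)
    beta = draws.flat("beta")
    a_est = draws.flat("alpha_est")
    a_prog = draws.flat("alpha_prog")
    s1 = draws.flat("Sigma1")
    s2c = draws.flat("Sigma2")
    sig2 = draws.flat("sigma2_s")
    n_total = beta.shape[0]
    if max_draws is not None and n_total > max_draws:
        keep = np.linspace(0, n_total - 1, max_draws).astype(int)
    else:
        keep = np.arange(n_total)

    n = holdout.n
    z = np.empty((n, beta.shape[1]))
    z[:, 0] = 1.0
    z[:, 1] = holdout.x1
    z[:, 2] = holdout.x2
    z[:, 3:] = holdout.x_est[np.clip(holdout.j, 0, None)]
    u = z[:, :3]
    unseen_j = holdout.j < 0
    unseen_k = holdout.k < 0

    lam_sim = np.empty((len(keep), n))
    lam_mean = np.empty((len(keep), n))
    for out_i, d in enumerate(keep):
        aj = a_est[d][np.clip(holdout.j, 0, None)]
        ak = a_prog[d][np.clip(holdout.k, 0, None)]
        if unseen_j.any():
            fresh = rng.multivariate_normal(np.zeros(3), s1[d], unseen_j.sum())
            aj = aj.copy()
            aj[unseen_j] = fresh
        if unseen_k.any():
            fresh = rng.multivariate_normal(np.zeros(3), s2c[d], unseen_k.sum())
            ak = ak.copy()
            ak[unseen_k] = fresh
        g = z @ beta[d] + (u * aj).sum(1) + (u * ak).sum(1)
        s2d = sig2[d] if np.ndim(sig2[d]) == 0 else float(np.mean(sig2[d]))
        lam_sim[out_i] = np.exp(g + math.sqrt(s2d) * rng.standard_normal(n))
        lam_mean[out_i] = np.exp(g + s2d / 2.0)
    return lam_sim, lam_mean


def validate_holdout(
    draws: PosteriorDraws,
    holdout: ModelData,
    discrepancy: str = "chisq",
    seed: int = 0,
    max_draws: int | None = 1000,
) -> PPCResult:
    """Bayesian p-value of posterior predictions against hold-out rows."""
    if holdout.n == 0:
        raise ValueError("empty holdout set")
    if discrepancy not in _DISCREPANCIES:
        raise ValueError(f"unknown discrepancy {discrepancy!r}")
    lam_sim, lam_mean = _holdout_lambda(draws, holdout, seed, max_draws)
    return _ppc(
        lam_sim, np.asarray(holdout.y), discrepancy, seed + 1, lam_t=lam_mean
    )
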