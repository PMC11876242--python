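"""Bayesian inversion of Michaelis–Menten parameters from rate data.

The observable is the initial rate v0 at a series of substrate
concentrations. The model is

    v_obs ~ Normal(mm_rate(S; k_cat * E_total, K_M), noise_sd)

with priors on (K_M, k_cat) that are log-uniform or log-normal (strictly
positive support) and a half-normal prior on the noise scale. Sampling uses
an adaptive random-walk Metropolis algorithm in log-parameter space: the
diagonal proposal scale adapts toward a 0.2–0.5 acceptance rate during
burn-in only, so the post-burn-in chain is a valid Metropolis sampler.
Multiple chains give the split-R̂ convergence diagnostic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .kinetics import mm_rate

__all__ = [
    "PriorSpec",
    "ParameterPrior",
    "RateDataset",
    "Posterior",
    "log_posterior",
    "run_mcmc",
    "summarize_posterior",
    "split_rhat",
]

PARAM_NAMES = ("K_M", "k_cat", "noise_sd")
_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class ParameterPrior:
    """Prior for one positive parameter.

    family "log-uniform": uniform on log(theta) over [log low, log high].
    family "log-normal": Normal(mean, sd) on log(theta).
    """

    family: str
    low: Optional[float] = None
    high: Optional[float] = None
    mean: Optional[float] = None
    sd: Optional[float] = None

    def __post_init__(self) -> None:
        if self.family == "log-uniform":
            if self.low is None or self.high is None or not 0 < self.low < self.high:
                raise ValueError("log-uniform prior needs 0 < low < high")
        elif self.family == "log-normal":
            if self.mean is None or self.sd is None or self.sd <= 0:
                raise ValueError("log-normal prior needs mean and sd > 0 (log space)")
        else:
            raise ValueError(f"unknown prior family {self.family!r}")

    def log_pdf(self, log_theta: float) -> float:
        """Log-density with respect to d(log theta)."""
        if self.family == "log-uniform":
            if np.log(self.low) <= log_theta <= np.log(self.high):
                return -float(np.log(np.log(self.high) - np.log(self.low)))
            return -np.inf
        z = (log_theta - self.mean) / self.sd
        return -0.5 * (z * z + _LOG_2PI) - float(np.log(self.sd))

    def quantile(self, q) -> np.ndarray:
        """Quantile of theta (not log theta)."""
        q = np.asarray(q, dtype=float)
        if self.family == "log-uniform":
            return np.exp(np.log(self.low) + q * (np.log(self.high) - np.log(self.low)))
        from scipy.stats import norm

        return np.exp(norm.ppf(q, loc=self.mean, scale=self.sd))


@dataclass(frozen=True)
class PriorSpec:
    """Joint prior: (K_M, k_cat) priors plus a half-normal noise scale.

    Defaults span reported peroxidase literature ranges without being
    informative: K_M in [1, 1e4] μM, k_cat in [1e-2, 1e3] 1/s, log-uniform.
    """

    K_M: ParameterPrior = field(
        default_factory=lambda: ParameterPrior("log-uniform", low=1.0, high=1e4)
    )
    k_cat: ParameterPrior = field(
        default_factory=lambda: ParameterPrior("log-uniform", low=1e-2, high=1e3)
    )
    noise_scale: float = 1.0  # half-normal scale for noise_sd, μM/s

    def log_pdf(self, log_theta: np.ndarray) -> float:
        lp = self.K_M.log_pdf(log_theta[0]) + self.k_cat.log_pdf(log_theta[1])
        if not np.isfinite(lp):
            return -np.inf
        # half-normal on noise_sd, expressed in log space (includes Jacobian)
        sd = np.exp(log_theta[2])
        if sd > 10 * self.noise_scale * 10:  # generous hard cap keeps chains proper
            return -np.inf
        lp += -0.5 * (sd / self.noise_scale) ** 2 + log_theta[2]
        return float(lp)

    def initial_point(self, rng: np.random.Generator) -> np.ndarray:
        def draw(p: ParameterPrior) -> float:
            if p.family == "log-uniform":
                return rng.uniform(np.log(p.low), np.log(p.high))
            return rng.normal(p.mean, p.sd)

        return np.array(
            [draw(self.K_M), draw(self.k_cat), np.log(self.noise_scale * rng.uniform(0.1, 1.0))]
        )


@dataclass(frozen=True)
class RateDataset:
    """Initial-rate observations (S μM, v_obs μM/s) at known total enzyme."""

    S: np.ndarray
    v_obs: np.ndarray
    E_total: float
    condition: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        S = np.asarray(self.S, dtype=float)
        v = np.asarray(self.v_obs, dtype=float)
        if S.shape != v.shape or S.ndim != 1:
            raise ValueError("S and v_obs must be aligned 1-D arrays")
        if len(np.unique(S)) < 4:
            raise ValueError("need >= 4 distinct substrate concentrations")
        if np.any(v < 0):
            raise ValueError("observed rates must be non-negative")
        if self.E_total <= 0:
            raise ValueError("E_total must be positive")
        object.__setattr__(self, "S", S)
        object.__setattr__(self, "v_obs", v)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"S_uM": self.S, "v0_uM_per_s": self.v_obs})


@dataclass(frozen=True)
class Posterior:
    """MCMC samples (draw × {K_M, k_cat, noise_sd}) with diagnostics."""

    samples: pd.DataFrame
    acceptance_rate: float
    n_chains: int
    burn_in: int
    rhat: Dict[str, float]
    converged: bool
    seed: int

    def summaries(self) -> pd.DataFrame:
        return summarize_posterior(self)

    def median(self, name: str) -> float:
        return float(self.samples[name].median())


def log_likelihood(theta: np.ndarray, data: RateDataset) -> float:
    """Gaussian log-likelihood of the rates; theta = (K_M, k_cat, noise_sd)."""
    K_M, k_cat, sd = theta
    mu = mm_rate(data.S, k_cat * data.E_total, K_M)
    resid = data.v_obs - mu
    n = len(resid)
    return float(-0.5 * np.sum(resid**2) / sd**2 - n * np.log(sd) - 0.5 * n * _LOG_2PI)


def log_posterior(
    theta: Sequence[float], data: Optional[RateDataset], prior: PriorSpec
) -> float:
    """Log posterior density at theta = (K_M, k_cat, noise_sd), natural scale.

    Returns −inf outside the prior support. ``data=None`` disables the
    likelihood (prior-only target, useful for prior-recovery checks).
    """
    theta = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(theta)) or np.any(theta <= 0):
        return -np.inf
    log_theta = np.log(theta)
    lp = prior.log_pdf(log_theta)
    if not np.isfinite(lp):
        return -np.inf
    if data is not None:
        lp += log_likelihood(theta, data)
    return float(lp)


def split_rhat(chains: np.ndarray) -> float:
    """Split-R̂ potential-scale-reduction statistic for one parameter.

    ``chains`` has shape (n_chains, n_draws); each chain is split in half so
    within-chain non-stationarity also inflates the statistic.
    """
    chains = np.asarray(chains, dtype=float)
    n = chains.shape[1] // 2
    halves = np.concatenate([chains[:, :n], chains[:, n : 2 * n]], axis=0)
    m, n = halves.shape
    means = halves.mean(axis=1)
    W = halves.var(axis=1, ddof=1).mean()
    B = n * means.var(ddof=1)
    if W == 0:
        return 1.0
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


def _moment_start(data: RateDataset, prior: PriorSpec) -> np.ndarray:
    """Method-of-moments starting point in log space, clipped to the prior box.

    V_max from the largest observed rate, K_M from the substrate level where
    the rates cross half of it — crude, but it drops every chain near the
    posterior bulk so burn-in only has to refine, not search.
    """
    v_max = 1.2 * float(np.max(data.v_obs))
    half = 0.5 * v_max
    above = data.v_obs >= half
    K_M0 = float(data.S[np.argmin(np.abs(data.v_obs - half))]) if above.any() else float(
        np.median(data.S)
    )
    k_cat0 = max(v_max / data.E_total, 1e-12)
    noise0 = max(0.1 * float(np.mean(data.v_obs)), 1e-12)

    def clip(value: float, p: ParameterPrior) -> float:
        if p.family == "log-uniform":
            return float(np.clip(value, p.low * 1.01, p.high * 0.99))
        return value

    return np.log(
        np.array([clip(K_M0, prior.K_M), clip(k_cat0, prior.k_cat), noise0])
    )


def _run_chain(
    data: Optional[RateDataset],
    prior: PriorSpec,
    n_steps: int,
    burn_in: int,
    rng: np.random.Generator,
) -> Tuple[np.ndarray, float]:
    """Adaptive random-walk Metropolis in log space. Returns (log draws, acc)."""
    if data is not None:
        # jittered data-driven start; burn-in refines it
        x = _moment_start(data, prior) + 0.2 * rng.standard_normal(3)
    else:
        x = prior.initial_point(rng)
    lp = log_posterior(np.exp(x), data, prior)
    # re-draw until we start inside the support (flat targets can place the
    # noise init in the truncated tail; jitter can leave the prior box)
    tries = 0
    while not np.isfinite(lp) and tries < 100:
        x = prior.initial_point(rng)
        lp = log_posterior(np.exp(x), data, prior)
        tries += 1
    if not np.isfinite(lp):
        raise RuntimeError("could not find a valid starting point in the prior support")

    scale = 0.5
    shape = np.ones(3)  # per-component proposal shape, geometric mean 1
    draws = np.empty((n_steps, 3))
    accepted_total = 0
    accepted_window = 0
    window = 100
    for i in range(n_steps):
        prop = x + scale * shape * rng.standard_normal(3)
        lp_prop = log_posterior(np.exp(prop), data, prior)
        if np.log(rng.uniform()) < lp_prop - lp:
            x, lp = prop, lp_prop
            accepted_total += 1
            accepted_window += 1
        draws[i] = x
        # adapt only during burn-in; frozen proposal afterwards
        if i < burn_in and (i + 1) % window == 0:
            rate = accepted_window / window
            if rate < 0.2:
                scale *= 0.7
            elif rate > 0.5:
                scale *= 1.4
            accepted_window = 0
            if i + 1 >= 4 * window:
                # shape the proposal to the recent per-component spreads so
                # parameters with very different posterior scales all mix
                recent = draws[max(0, i - 1000) : i + 1]
                sd = np.clip(recent.std(axis=0), 1e-3, None)
                shape = sd / np.exp(np.mean(np.log(sd)))
    return draws, accepted_total / n_steps


def run_mcmc(
    data: Optional[RateDataset],
    prior: PriorSpec = PriorSpec(),
    n_chains: int = 4,
    n_steps: int = 20_000,
    burn_in: Optional[int] = None,
    seed: int = 0,
    rhat_threshold: float = 1.1,
) -> Posterior:
    """Sample the posterior of (K_M, k_cat, noise_sd).

    ``burn_in`` defaults to half the steps. Identical seeds give identical
    samples. Non-convergence (R̂ above 1.2 or a frozen chain) produces a
    warning and ``converged=False``, never an exception.
    """
    if n_chains < 2 or n_steps < 10:
        raise ValueError("need >= 2 chains and >= 10 steps")
    burn_in = n_steps // 2 if burn_in is None else burn_in
    if not 0 < burn_in < n_steps:
        raise ValueError("burn_in must be in (0, n_steps)")
    root = np.random.SeedSequence(seed)
    all_draws = []
    accs = []
    for child in root.spawn(n_chains):
        rng = np.random.default_rng(child)
        draws, acc = _run_chain(data, prior, n_steps, burn_in, rng)
        all_draws.append(draws[burn_in:])
        accs.append(acc)
    kept = np.array(all_draws)  # (chain, draw, 3) in log space
    rhat = {
        name: split_rhat(kept[:, :, j]) for j, name in enumerate(PARAM_NAMES)
    }
    acceptance = float(np.mean(accs))
    converged = all(r <= rhat_threshold for r in rhat.values()) and acceptance > 0
    if acceptance == 0 or max(rhat.values()) > 1.2:
        warnings.warn(
            f"MCMC convergence suspect: acceptance={acceptance:.3f}, rhat={rhat}",
            RuntimeWarning,
            stacklevel=2,
        )
    flat = np.exp(kept.reshape(-1, 3))
    samples = pd.DataFrame(flat, columns=list(PARAM_NAMES))
    return Posterior(
        samples=samples,
        acceptance_rate=acceptance,
        n_chains=n_chains,
        burn_in=burn_in,
        rhat=rhat,
        converged=converged,
        seed=seed,
    )


def summarize_posterior(post: Posterior) -> pd.DataFrame:
    """Median, mean, sd and 5%/95% quantiles per parameter (recomputable)."""
    if len(post.samples) == 0:
        raise ValueError("empty posterior")
    rows = []
    for name in PARAM_NAMES:
        x = post.samples[name].to_numpy()
        rows.append(
            {
                "parameter": name,
                "median": float(np.median(x)),
                "mean": float(np.mean(x)),
                "sd": float(np.std(x, ddof=1)) if len(x) > 1 else 0.0,
                "q05": float(np.quantile(x, 0.05)),
                "q95": float(np.quantile(x, 0.95)),
                "rhat": post.rhat[name],
            }
        )
    return pd.DataFrame(rows)
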