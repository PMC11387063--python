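"""Posterior assembly, MCMC sampling, convergence diagnostics and summaries.

The joint posterior couples the three fecundity submodels (per sex), the
mark-recapture-recovery likelihood, the covariate-imputation layer and the
priors: Normal(0, 1.5) on every link-scale coefficient, Uniform(0, 1) on the
detection probabilities and half-normal(1) on imputation group standard
deviations.  Sampling uses adaptive random-walk Metropolis: submodel fits
update the whole coefficient vector with a covariance-adapted proposal;
the joint model is a Metropolis-within-Gibbs scheme whose blocks are the
eight sex-specific coefficient vectors, the detection parameters, the
imputation hyperparameters, and the latent covariate cells and reproduction
counts (accepted per individual, which keeps every accept/reject decision a
valid Metropolis step because distinct individuals contribute disjoint
likelihood terms).  All chains are advanced simultaneously as a vectorized
batch; every random draw derives from the configuration seed.

Convergence is assessed with the rank-normalized split R-hat and bulk
effective sample size (both via arviz); parameters with R-hat >= 1.01 are
flagged.  Summaries report the posterior median, the equal-tailed 95%
credible interval, and f, the proportion of the posterior on the same side
of zero as the posterior mean.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import arviz as az
import numpy as np
import pandas as pd
from scipy import special

from owlpath.exceptions import ConfigurationError, DataError, InitializationError
from owlpath.params import ModelParameters
from owlpath.survival_mrr import mrr_loglik_matrix

RHAT_THRESHOLD = 1.01


@dataclass
class MCMCConfig:
    """Iteration protocol for one MCMC run.

    The default is a desk-scale protocol (4 chains x 4000 iterations,
    1000 burn-in, thin 2); :func:`paper_protocol` returns the full-scale
    protocol of 250 000 iterations with 100 000 burn-in and thinning 25.
    """

    n_iterations: int = 4000
    n_chains: int = 4
    n_burnin: int = 1000
    thin: int = 2
    seed: int = 0
    prior_scale: float = 1.5

    def validate(self) -> None:
        if self.n_burnin >= self.n_iterations:
            raise ConfigurationError("n_burnin must be smaller than n_iterations")
        if self.thin < 1:
            raise ConfigurationError("thin must be >= 1")
        if self.n_chains < 2:
            raise ConfigurationError("n_chains must be >= 2")
        if self.prior_scale <= 0:
            raise ConfigurationError("prior_scale must be positive")

    @property
    def n_retained(self) -> int:
        """Retained draws per chain after burn-in and thinning."""
        return -((self.n_iterations - self.n_burnin) // -self.thin)  # ceil division


def paper_protocol(seed: int = 0) -> MCMCConfig:
    """The full-scale protocol: 250 000 iterations, 4 chains, 100 000 burn-in, thin 25."""
    return MCMCConfig(n_iterations=250_000, n_chains=4, n_burnin=100_000, thin=25, seed=seed)


@dataclass
class InferenceResult:
    """Post-burn-in, thinned draws plus parameter names and the run config."""

    chains: np.ndarray  # (n_chains, n_retained, n_params)
    names: list[str]
    config: MCMCConfig

    def posterior(self, name: str) -> np.ndarray:
        j = self.names.index(name)
        return self.chains[:, :, j]

    def summary(self) -> pd.DataFrame:
        return summarize(self.chains, self.names)

    def save(self, out_dir) -> None:
        """Write chains/*.csv, summary.csv and diagnostics.json."""
        out = Path(out_dir)
        (out / "chains").mkdir(parents=True, exist_ok=True)
        for c in range(self.chains.shape[0]):
            pd.DataFrame(self.chains[c], columns=self.names).to_csv(
                out / "chains" / f"chain_{c}.csv", index=False
            )
        summ = self.summary()
        summ.to_csv(out / "summary.csv")
        diag = {
            "rhat": {n: float(summ.loc[n, "rhat"]) for n in self.names},
            "ess": {n: float(summ.loc[n, "ess"]) for n in self.names},
            "flagged": [
                n
                for n in self.names
                if not np.isfinite(summ.loc[n, "rhat"]) or summ.loc[n, "rhat"] >= RHAT_THRESHOLD
            ],
            "config": {
                "n_iterations": self.config.n_iterations,
                "n_chains": self.config.n_chains,
                "n_burnin": self.config.n_burnin,
                "thin": self.config.thin,
                "seed": self.config.seed,
            },
        }
        with open(out / "diagnostics.json", "w") as fh:
            json.dump(diag, fh, indent=2)


# ---------------------------------------------------------------------------
# Diagnostics and summaries


def compute_rhat(chains: np.ndarray) -> float:
    """Rank-normalized split R-hat of one parameter's (n_chains, n_draws) draws.

    A degenerate (constant) chain yields NaN, which callers treat as
    not-converged rather than raising.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2 or chains.shape[1] < 10:
        raise DataError("compute_rhat needs >= 2 chains with >= 10 draws each")
    with np.errstate(invalid="ignore"):
        return float(az.rhat(chains))


def compute_ess(chains: np.ndarray) -> float:
    """Bulk effective sample size of one parameter's (n_chains, n_draws) draws."""
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2 or chains.shape[1] < 10:
        raise DataError("compute_ess needs >= 2 chains with >= 10 draws each")
    with np.errstate(invalid="ignore"):
        return float(az.ess(chains))


def posterior_f(draws: np.ndarray) -> float:
    """Proportion of draws on the same side of zero as the pooled mean.

    Draws exactly at zero count with the mean's side; a zero mean counts as
    positive (ties are measure-zero for continuous parameters).
    """
    draws = np.asarray(draws, dtype=float).ravel()
    side = 1.0 if draws.mean() >= 0 else -1.0
    return float(np.mean(side * draws >= 0))


def summarize(chains: np.ndarray, names: list[str]) -> pd.DataFrame:
    """Posterior summary table: median, 95% CrI, f, R-hat and ESS per parameter."""
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 3:
        raise DataError("chains must have shape (n_chains, n_draws, n_params)")
    rows = {}
    for j, name in enumerate(names):
        x = chains[:, :, j]
        pooled = x.ravel()
        lo, med, hi = np.percentile(pooled, [2.5, 50.0, 97.5])
        try:
            rhat = compute_rhat(x)
            ess = compute_ess(x)
        except DataError:
            rhat, ess = np.nan, np.nan
        rows[name] = {
            "median": med,
            "cri_low": lo,
            "cri_high": hi,
            "f": posterior_f(pooled),
            "rhat": rhat,
            "ess": ess,
        }
    df = pd.DataFrame(rows).T
    df.index.name = "parameter"
    return df


# ---------------------------------------------------------------------------
# Generic adaptive Metropolis (all chains advanced as one batch)

_TARGET_ACCEPT = 0.234


def adaptive_metropolis(
    log_target,
    x0: np.ndarray,
    config: MCMCConfig,
    rng: np.random.Generator | None = None,
    jitter: float = 0.05,
) -> np.ndarray:
    """Sample a log-density with covariance-adapted random-walk Metropolis.

    ``log_target`` maps an (n_chains, P) parameter batch to (n_chains,) log
    densities.  Proposal covariance and step size adapt during burn-in only,
    so the retained draws come from a fixed kernel.  Returns draws with shape
    (n_chains, n_retained, P).
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    x0 = np.asarray(x0, dtype=float)
    P = x0.size
    C = config.n_chains
    x = x0[None, :] + jitter * rng.standard_normal((C, P))
    lp = np.asarray(log_target(x), dtype=float)
    if not np.all(np.isfinite(lp)):
        raise InitializationError(f"log target not finite at initial values: {lp}")

    scale = 2.38 / np.sqrt(P)
    L = np.eye(P)
    buffer: list[np.ndarray] = []
    out = np.empty((C, config.n_retained, P))
    k = 0
    for t in range(config.n_iterations):
        z = rng.standard_normal((C, P))
        prop = x + scale * z @ L.T
        lp_prop = np.asarray(log_target(prop), dtype=float)
        accept = np.log(rng.random(C)) < lp_prop - lp
        x[accept] = prop[accept]
        lp[accept] = lp_prop[accept]
        if t < config.n_burnin:
            gamma = min(0.1, 5.0 / (t + 10.0) ** 0.7)
            scale *= np.exp(gamma * (accept.mean() - _TARGET_ACCEPT))
            buffer.append(x.copy())
            if len(buffer) > 1000:
                buffer.pop(0)
            if t >= 400 and t % 250 == 0 and P > 1:
                pooled = np.concatenate(buffer, axis=0)
                cov = np.cov(pooled.T) + 1e-8 * np.eye(P)
                L = np.linalg.cholesky(cov)
                scale = 2.38 / np.sqrt(P)
        elif (t - config.n_burnin) % config.thin == 0:
            out[:, k, :] = x
            k += 1
    return out


def _coefficient_prior(beta: np.ndarray, prior_scale: float) -> np.ndarray:
    return -0.5 * (beta**2).sum(axis=-1) / prior_scale**2


def _uniform_prob_prior(logit_value: np.ndarray) -> np.ndarray:
    """Log-density on the logit scale of a Uniform(0,1) probability."""
    return logit_value - 2.0 * np.logaddexp(0.0, logit_value)


# ---------------------------------------------------------------------------
# Stand-alone submodel fits (complete data)


def fit_poisson_submodel(
    X: np.ndarray, counts: np.ndarray, names: list[str], config: MCMCConfig
) -> InferenceResult:
    """Bayesian Poisson log-linear regression (egg submodel) on complete data."""
    from owlpath.fecundity import poisson_loglik_matrix

    X = np.asarray(X, dtype=float)
    counts = np.asarray(counts, dtype=float)

    def log_target(beta):
        return poisson_loglik_matrix(X, beta, counts) + _coefficient_prior(
            beta, config.prior_scale
        )

    chains = adaptive_metropolis(log_target, np.zeros(X.shape[1]), config)
    return InferenceResult(chains=chains, names=list(names), config=config)


def fit_binomial_submodel(
    X: np.ndarray,
    successes: np.ndarray,
    trials: np.ndarray,
    names: list[str],
    config: MCMCConfig,
) -> InferenceResult:
    """Bayesian binomial logit regression (hatch/fledge submodel) on complete data."""
    from owlpath.fecundity import binomial_loglik_matrix

    X = np.asarray(X, dtype=float)
    successes = np.asarray(successes, dtype=float)
    trials = np.asarray(trials, dtype=float)

    def log_target(beta):
        return binomial_loglik_matrix(X, beta, successes, trials) + _coefficient_prior(
            beta, config.prior_scale
        )

    chains = adaptive_metropolis(log_target, np.zeros(X.shape[1]), config)
    return InferenceResult(chains=chains, names=list(names), config=config)


def fit_mrr_submodel(
    codes: np.ndarray,
    first_occasion: np.ndarray,
    Z: np.ndarray,
    names: list[str],
    config: MCMCConfig,
) -> InferenceResult:
    """Bayesian MRR fit with logit-linear survival and a single detection group.

    ``Z`` has shape (n_ind, n_intervals, P): the survival design per
    individual-interval (intercept column first).  Two extra parameters,
    ``p`` and ``r``, are sampled on the logit scale with Uniform(0,1) priors
    and reported on the probability scale.
    """
    codes = np.asarray(codes)
    first_occasion = np.asarray(first_occasion)
    Z = np.asarray(Z, dtype=float)
    n_ind, n_int, P = Z.shape

    def log_target(x):
        beta = x[:, :P]
        lp, lr = x[:, P], x[:, P + 1]
        phi = special.expit(np.einsum("nip,cp->cni", Z, beta))
        ll = mrr_loglik_matrix(
            codes, first_occasion, phi, special.expit(lp)[:, None], special.expit(lr)[:, None]
        ).sum(axis=-1)
        prior = _coefficient_prior(beta, config.prior_scale)
        prior = prior + _uniform_prob_prior(lp) + _uniform_prob_prior(lr)
        return ll + prior

    x0 = np.zeros(P + 2)
    x0[P + 1] = special.logit(0.2)
    chains = adaptive_metropolis(log_target, x0, config)
    # report detection on the probability scale
    chains[:, :, P] = special.expit(chains[:, :, P])
    chains[:, :, P + 1] = special.expit(chains[:, :, P + 1])
    return InferenceResult(chains=chains, names=list(names) + ["p", "r"], config=config)


# ---------------------------------------------------------------------------
# Joint model surface

from owlpath.joint import JointModel  # noqa: E402  (re-export)


def assemble_log_posterior(model: JointModel, params: ModelParameters, hypers=None) -> float:
    """Total joint log posterior (see :meth:`JointModel.log_posterior`)."""
    return model.log_posterior(params, hypers=hypers)


def run_mcmc(dataset, config: MCMCConfig, spec=None, **kwargs) -> InferenceResult:
    """Fit the joint path model to a dataset by Metropolis-within-Gibbs."""
    model = JointModel.from_dataset(dataset, spec=spec, **kwargs)
    return model.fit(config)
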