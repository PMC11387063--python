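"""Annual reproduction submodels: eggs, hatching success, fledging success.

The annual reproduction of one adult in one year is a chain
``E -> N -> F``: the number of eggs E follows a Poisson distribution whose
mean ``psi`` is log-linear in the egg-model covariates; the number of
nestlings N (alive at day 25) is a binomial outcome of E trials with
hatching probability ``rho_E``; and the number of fledglings F (alive at day
55) is a binomial outcome of N trials with fledging probability ``rho_N``.
Both success probabilities are logit-linear in their covariate sets, which
include the preceding count of the chain as a standardized predictor.  Each
sex has its own coefficient set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats

from owlpath.exceptions import ChainViolationError, DataError
from owlpath.params import (
    EggModelCoefficients,
    FledgeModelCoefficients,
    HatchModelCoefficients,
)


@dataclass
class AnnualReproduction:
    """Annual egg / nestling / fledgling totals with observation flags."""

    eggs: int
    nestlings: int
    fledglings: int
    eggs_observed: bool = True
    nestlings_observed: bool = True
    fledglings_observed: bool = True

    def validate(self) -> None:
        if self.eggs_observed and self.nestlings_observed and self.eggs < self.nestlings:
            raise ChainViolationError(
                f"nestlings ({self.nestlings}) exceed eggs ({self.eggs})"
            )
        if (
            self.nestlings_observed
            and self.fledglings_observed
            and self.nestlings < self.fledglings
        ):
            raise ChainViolationError(
                f"fledglings ({self.fledglings}) exceed nestlings ({self.nestlings})"
            )
        for name in ("eggs", "nestlings", "fledglings"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise DataError(f"{name} must be a non-negative integer, got {v}")


def _linear_predictor(coeffs, covariates: dict[str, np.ndarray]) -> np.ndarray:
    """Intercept plus sum of slope * covariate for the named terms.

    ``covariates`` maps each non-intercept term (e.g. "laying_date") to a
    scalar or array of z-scored values.
    """
    beta = coeffs.as_array()
    terms = type(coeffs).TERMS
    eta = np.asarray(beta[0], dtype=float)
    for b, term in zip(beta[1:], terms[1:]):
        x = np.asarray(covariates[term], dtype=float)
        if not np.all(np.isfinite(x)):
            raise DataError(f"covariate {term!r} contains non-finite values")
        eta = eta + b * x
    return eta


def egg_rate(coeffs: EggModelCoefficients, covariates: dict[str, np.ndarray]) -> np.ndarray:
    """Expected annual egg number psi = exp(linear predictor); positive."""
    return np.exp(_linear_predictor(coeffs, covariates))


def hatch_prob(coeffs: HatchModelCoefficients, covariates: dict[str, np.ndarray]) -> np.ndarray:
    """Hatching probability rho_E = logit^-1(linear predictor), in (0, 1)."""
    return special.expit(_linear_predictor(coeffs, covariates))


def fledge_prob(coeffs: FledgeModelCoefficients, covariates: dict[str, np.ndarray]) -> np.ndarray:
    """Fledging probability rho_N = logit^-1(linear predictor), in (0, 1)."""
    return special.expit(_linear_predictor(coeffs, covariates))


def egg_loglik(eggs, psi) -> np.ndarray:
    """Poisson log-probability of the annual egg count."""
    E = np.asarray(eggs)
    if np.any(E < 0) or np.any(E != np.floor(E)):
        raise DataError("egg counts must be non-negative integers")
    if np.any(np.asarray(psi) <= 0):
        raise DataError("psi must be strictly positive")
    return stats.poisson.logpmf(E, psi)

def binomial_loglik(successes, trials, prob) -> np.ndarray:
    """Binomial log-probability; zero trials with zero successes has log-prob 0."""
    k = np.asarray(successes)
    n = np.asarray(trials)
    if np.any(k < 0) or np.any(n < 0):
        raise DataError("counts must be non-negative")
    if np.any(k > n):
        raise ChainViolationError("successes exceed trials")
    return stats.binom.logpmf(k, n, prob)


# ---------------------------------------------------------------------------
# Vectorized log-likelihood kernels used by the samplers.  These accept a
# design matrix X (n_records x n_terms, intercept column first) and a
# coefficient array beta with arbitrary leading batch dimensions (..., n_terms),
# and return per-record log-likelihood contributions summed over records.


def poisson_loglik_matrix(X: np.ndarray, beta: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Sum of Poisson log-pmfs with log-rate X @ beta; batched over beta."""
    eta = np.einsum("...p,np->...n", np.atleast_2d(beta), X)
    # log pmf = E*eta - exp(eta) - log(E!)
    ll = counts * eta - np.exp(eta) - special.gammaln(counts + 1.0)
    return ll.sum(axis=-1)


def binomial_loglik_matrix(
    X: np.ndarray, beta: np.ndarray, successes: np.ndarray, trials: np.ndarray
) -> np.ndarray:
    """Sum of binomial log-pmfs with logit X @ beta; batched over beta."""
    eta = np.einsum("...p,np->...n", np.atleast_2d(beta), X)
    # log pmf = log C(n,k) + k*eta - n*log(1+exp(eta))
    const = (
        special.gammaln(trials + 1.0)
        - special.gammaln(successes + 1.0)
        - special.gammaln(trials - successes + 1.0)
    )
    ll = const + successes * eta - trials * np.logaddexp(0.0, eta)
    return ll.sum(axis=-1)


# ---------------------------------------------------------------------------
# Maximum-likelihood fits (per submodel, used by the recovery suites).


def _mle(negloglik_grad, x0: np.ndarray) -> np.ndarray:
    res = optimize.minimize(negloglik_grad, x0, jac=True, method="BFGS")
    return res.x


def fit_poisson_mle(X: np.ndarray, counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """MLE and standard errors of a Poisson log-linear model.

    Standard errors come from the inverse Fisher information X' diag(psi) X
    evaluated at the MLE.
    """

    def nll(beta):
        eta = X @ beta
        mu = np.exp(eta)
        ll = counts @ eta - mu.sum()
        grad = X.T @ (counts - mu)
        return -ll, -grad

    beta = _mle(nll, np.zeros(X.shape[1]))
    mu = np.exp(X @ beta)
    info = X.T @ (X * mu[:, None])
    se = np.sqrt(np.diag(np.linalg.inv(info)))
    return beta, se


def fit_binomial_mle(
    X: np.ndarray, successes: np.ndarray, trials: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """MLE and standard errors of a binomial logit model with trials >= 0."""

    def nll(beta):
        eta = X @ beta
        ll = successes @ eta - trials @ np.logaddexp(0.0, eta)
        p = special.expit(eta)
        grad = X.T @ (successes - trials * p)
        return -ll, -grad

    beta = _mle(nll, np.zeros(X.shape[1]))
    p = special.expit(X @ beta)
    w = trials * p * (1.0 - p)
    info = X.T @ (X * w[:, None])
    se = np.sqrt(np.diag(np.linalg.inv(info)))
    return beta, se
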