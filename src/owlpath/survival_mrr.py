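"""Joint live-recapture / dead-recovery (mark-recapture-recovery) likelihood.

Encounter histories code each occasion as 0 (not seen), 1 (captured alive)
or 2 (recovered dead).  Conditioning on first release, each interval applies
a latent-state transition: an alive bird survives with probability ``phi``
(logit-linear in that year's covariates, including the standardized nestling
and fledgling totals) and is then recaptured with probability ``p``; a bird
that dies in the interval is recovered (code 2) with probability ``r`` in
that interval only, after which it leaves the detectable population for
good.  ``p`` and ``r`` are specific to the tag group (ring-only vs
VHF-transmitter) and constant over time.

``history_loglik`` implements the forward recursion over the latent states
{alive, newly dead, departed}; ``brute_force_history_prob`` enumerates every
latent fate and serves as an exact oracle for small histories.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy import special

from owlpath.exceptions import DataError, IllegalHistoryError
from owlpath.params import DetectionParameters, SurvivalCoefficients

CODES = (0, 1, 2)


@dataclass
class EncounterHistory:
    """Per-occasion detection codes for one individual."""

    first_occasion: int
    codes: tuple[int, ...]

    def __post_init__(self):
        self.codes = tuple(int(c) for c in self.codes)
        validate_history(self.codes, self.first_occasion)

    @property
    def n_occasions(self) -> int:
        return len(self.codes)


def validate_history(codes, first_occasion: int) -> None:
    codes = list(codes)
    if first_occasion < 0 or first_occasion >= len(codes):
        raise IllegalHistoryError(
            f"first_occasion {first_occasion} outside 0..{len(codes) - 1}"
        )
    if any(c not in CODES for c in codes):
        raise IllegalHistoryError(f"codes must be in {CODES}: {codes}")
    if codes[first_occasion] != 1:
        raise IllegalHistoryError("history must start with code 1 at the release occasion")
    if any(c != 0 for c in codes[:first_occasion]):
        raise IllegalHistoryError("codes before first capture must be 0")
    if codes.count(2) > 1:
        raise IllegalHistoryError("at most one dead recovery per history")
    if 2 in codes:
        k = codes.index(2)
        if any(c != 0 for c in codes[k + 1 :]):
            raise IllegalHistoryError("no nonzero code after a dead recovery")


def survival_prob(
    coeffs: SurvivalCoefficients, covariates: dict[str, np.ndarray]
) -> np.ndarray:
    """Annual survival probability phi = logit^-1(linear predictor)."""
    from owlpath.fecundity import _linear_predictor

    return special.expit(_linear_predictor(coeffs, covariates))


def _emission_probs(p: float, r: float):
    """Per-code emission probabilities for the alive and newly-dead states."""
    alive = {0: 1.0 - p, 1: p, 2: 0.0}
    dead = {0: 1.0 - r, 1: 0.0, 2: r}
    return alive, dead


def history_loglik(
    history: EncounterHistory,
    phi: np.ndarray,
    detection: DetectionParameters,
    group: str,
) -> float:
    """Log-probability of one encounter history by forward recursion.

    ``phi`` holds one survival probability per interval from the release
    occasion (length n_occasions - 1 - first_occasion).  Scaling at each step
    keeps the recursion finite for long histories (contract: no underflow up
    to 50 occasions).
    """
    phi = np.asarray(phi, dtype=float)
    n_int = history.n_occasions - 1 - history.first_occasion
    if phi.shape != (n_int,):
        raise DataError(f"phi must have one entry per interval ({n_int}), got {phi.shape}")
    p, r = detection.p(group), detection.r(group)
    e_alive, e_dead = _emission_probs(p, r)

    a = 1.0  # P(history so far, alive now)
    d = 0.0  # P(history so far, departed)
    loglik = 0.0
    for t in range(n_int):
        y = history.codes[history.first_occasion + t + 1]
        a_new = a * phi[t] * e_alive[y]
        d_new = a * (1.0 - phi[t]) * e_dead[y] + (d if y == 0 else 0.0)
        total = a_new + d_new
        if total <= 0.0:
            return -np.inf
        a, d = a_new / total, d_new / total
        loglik += np.log(total)
    return float(loglik)


def brute_force_history_prob(
    history: EncounterHistory,
    phi: np.ndarray,
    detection: DetectionParameters,
    group: str,
) -> float:
    """Exact history probability by enumerating every latent fate.

    A fate is either death during interval k (for each k after release) or
    survival through the whole history.  Limited to 12 occasions.
    """
    if history.n_occasions > 12:
        raise DataError("brute-force oracle limited to 12 occasions")
    phi = np.asarray(phi, dtype=float)
    first = history.first_occasion
    n_int = history.n_occasions - 1 - first
    if phi.shape != (n_int,):
        raise DataError(f"phi must have one entry per interval ({n_int}), got {phi.shape}")
    p, r = detection.p(group), detection.r(group)
    e_alive, e_dead = _emission_probs(p, r)
    obs = history.codes[first + 1 :]

    total = 0.0
    # Death during interval k (0-based from release): alive for intervals < k.
    for k in range(n_int):
        prob = 1.0
        for t in range(k):
            prob *= phi[t] * e_alive[obs[t]]
        prob *= (1.0 - phi[k]) * e_dead[obs[k]]
        for t in range(k + 1, n_int):  # departed afterwards: must be unseen
            prob *= 1.0 if obs[t] == 0 else 0.0
        total += prob
    # Survival throughout.
    prob = 1.0
    for t in range(n_int):
        prob *= phi[t] * e_alive[obs[t]]
    total += prob
    return float(total)


def enumerate_legal_histories(n_occasions: int, first_occasion: int = 0):
    """All legal code sequences for a release at ``first_occasion``."""
    n_after = n_occasions - 1 - first_occasion
    for tail in product(CODES, repeat=n_after):
        codes = (0,) * first_occasion + (1,) + tail
        try:
            validate_history(codes, first_occasion)
        except IllegalHistoryError:
            continue
        yield EncounterHistory(first_occasion, codes)


# ---------------------------------------------------------------------------
# Vectorized kernel used by the samplers.


try:  # compiled fast path for the batched forward recursion
    from numba import njit as _njit

    @_njit(cache=True)
    def _mrr_core(codes, first, phi, p, r, out):  # pragma: no cover - exercised via wrapper
        B, n_ind, n_int = phi.shape
        for b in range(B):
            for i in range(n_ind):
                a = 1.0
                d = 0.0
                ll = 0.0
                for t in range(first[i], n_int):
                    y = codes[i, t + 1]
                    ph = phi[b, i, t]
                    if y == 0:
                        a_new = a * ph * (1.0 - p[b, i])
                        d_new = a * (1.0 - ph) * (1.0 - r[b, i]) + d
                    elif y == 1:
                        a_new = a * ph * p[b, i]
                        d_new = 0.0
                    else:
                        a_new = 0.0
                        d_new = a * (1.0 - ph) * r[b, i]
                    tot = a_new + d_new
                    if tot <= 0.0:
                        ll = -np.inf
                        break
                    a = a_new / tot
                    d = d_new / tot
                    ll += np.log(tot)
                out[b, i] = ll

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def mrr_loglik_matrix(
    codes: np.ndarray,
    first_occasion: np.ndarray,
    phi: np.ndarray,
    p: np.ndarray,
    r: np.ndarray,
) -> np.ndarray:
    """Per-individual history log-likelihoods, batched over parameter sets.

    Parameters
    ----------
    codes : (n_ind, n_occ) int array of encounter codes.
    first_occasion : (n_ind,) int array of release occasions.
    phi : (..., n_ind, n_occ - 1) survival probability per interval
        (entries for intervals before release are ignored).
    p, r : broadcastable to (..., n_ind) group-specific detection.

    Returns
    -------
    (..., n_ind) array of log-probabilities.
    """
    codes = np.asarray(codes)
    if _HAVE_NUMBA and codes.ndim == 2:
        n_ind, n_occ = codes.shape
        phi = np.asarray(phi, dtype=float)
        batch = phi.shape[:-2]
        B = int(np.prod(batch)) if batch else 1
        phi3 = np.ascontiguousarray(phi.reshape(B, n_ind, n_occ - 1))
        p2 = np.ascontiguousarray(
            np.broadcast_to(np.asarray(p, dtype=float), batch + (n_ind,)).reshape(B, n_ind)
        )
        r2 = np.ascontiguousarray(
            np.broadcast_to(np.asarray(r, dtype=float), batch + (n_ind,)).reshape(B, n_ind)
        )
        out = np.empty((B, n_ind))
        _mrr_core(
            np.ascontiguousarray(codes, dtype=np.int64),
            np.ascontiguousarray(first_occasion, dtype=np.int64),
            phi3,
            p2,
            r2,
            out,
        )
        return out.reshape(batch + (n_ind,))
    return _mrr_loglik_numpy(codes, first_occasion, phi, p, r)


def _mrr_loglik_numpy(
    codes: np.ndarray,
    first_occasion: np.ndarray,
    phi: np.ndarray,
    p: np.ndarray,
    r: np.ndarray,
) -> np.ndarray:
    """Pure-numpy reference implementation of :func:`mrr_loglik_matrix`."""
    codes = np.asarray(codes)
    n_ind, n_occ = codes.shape
    phi = np.asarray(phi, dtype=float)
    batch = phi.shape[:-2]
    p = np.broadcast_to(np.asarray(p, dtype=float), batch + (n_ind,))
    r = np.broadcast_to(np.asarray(r, dtype=float), batch + (n_ind,))

    a = np.zeros(batch + (n_ind,))
    d = np.zeros(batch + (n_ind,))
    loglik = np.zeros(batch + (n_ind,))
    released = np.zeros(n_ind, dtype=bool)
    for t in range(n_occ - 1):
        released |= first_occasion == t
        a[..., released & (first_occasion == t)] = 1.0
        active = released
        if not active.any():
            continue
        y = codes[:, t + 1]
        ph = phi[..., t]
        # emissions
        e_a = np.where(y == 1, p, np.where(y == 0, 1.0 - p, 0.0))
        e_d = np.where(y == 2, r, np.where(y == 0, 1.0 - r, 0.0))
        a_new = a * ph * e_a
        d_new = a * (1.0 - ph) * e_d + np.where(y == 0, d, 0.0)
        total = a_new + d_new
        with np.errstate(divide="ignore", invalid="ignore"):
            step = np.where(total > 0.0, np.log(np.maximum(total, 1e-300)), -np.inf)
            inv = np.where(total > 0.0, 1.0 / np.maximum(total, 1e-300), 0.0)
        loglik = loglik + np.where(active, step, 0.0)
        a = np.where(active, a_new * inv, a)
        d = np.where(active, d_new * inv, d)
    return loglik


def detection_arrays(
    detection: DetectionParameters, groups: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-individual (p, r) arrays from tag-group labels."""
    groups = np.asarray(groups)
    p = np.where(groups == "vhf", detection.p_vhf, detection.p_ring)
    r = np.where(groups == "vhf", detection.r_vhf, detection.r_ring)
    return p.astype(float), r.astype(float)
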