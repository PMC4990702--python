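"""Occupancy-process probabilities and the marginal site likelihood.

The occupancy state z[i,j,t] of species i in 5 km cell j and year t is a
two-state Markov chain: an occupied cell persists with probability
phi[i,j,t] (a logit-linear function of last year's centred covariates)
and an unoccupied cell is colonised with species-specific probability
gamma[i].  Detection on visit k is conditional on presence, with
probability p[i,k] depending on the visit's list category and a year
effect.  The marginal likelihood of a species' detection history at one
site integrates the latent chain out exactly by the forward algorithm;
``brute_force_log_likelihood`` enumerates all 2^T occupancy paths and is
the test oracle for that recursion.
"""

from __future__ import annotations

import itertools

import numpy as np

__all__ = [
    "inv_logit",
    "persistence_prob",
    "transition_prob",
    "detection_prob",
    "emission_loglik",
    "site_log_likelihood",
    "brute_force_log_likelihood",
]

_NEG_INF = -np.inf


def inv_logit(x):
    """Numerically stable logistic function."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    if out.ndim == 0:
        return float(out)
    return out


def persistence_prob(beta0, beta1, beta2, beta3, osr_c, neonic_c, fii_c):
    """Persistence probability phi from last year's centred covariates.

    phi = inv_logit(beta0 + beta1*OSR + beta2*neonic + beta3*FII), all
    covariates centred so phi at covariate zero is the persistence in the
    average occupied cell.  Inputs broadcast.
    """
    return inv_logit(
        np.asarray(beta0)
        + np.asarray(beta1) * np.asarray(osr_c)
        + np.asarray(beta2) * np.asarray(neonic_c)
        + np.asarray(beta3) * np.asarray(fii_c)
    )


def transition_prob(z_prev, phi, gamma):
    """P(z_t = 1 | z_{t-1}) = z_prev*phi + (1-z_prev)*gamma."""
    return np.asarray(z_prev) * np.asarray(phi) + (1 - np.asarray(z_prev)) * np.asarray(gamma)


def detection_prob(beta4, beta5, beta6, alpha_t, is_short, is_long):
    """Per-visit detection probability given presence.

    p = inv_logit(beta4 + beta5*is_short + beta6*is_long + alpha_t); at
    alpha_t = 0 and a single-species list, p = inv_logit(beta4).
    """
    return inv_logit(
        np.asarray(beta4)
        + np.asarray(beta5) * np.asarray(is_short)
        + np.asarray(beta6) * np.asarray(is_long)
        + np.asarray(alpha_t)
    )


def emission_loglik(p_visits: np.ndarray, y_visits: np.ndarray) -> tuple[float, float]:
    """Log P(y | z) for one site-year given per-visit detection probs.

    Returns ``(log P(y | z=1), log P(y | z=0))``; the z=0 emission is 0
    when nothing was detected (detections are conditional on presence, so
    there are no false positives) and -inf otherwise.
    """
    p = np.asarray(p_visits, dtype=float)
    y = np.asarray(y_visits, dtype=float)
    with np.errstate(divide="ignore"):
        # select per visit so that p of exactly 0 or 1 stays well-defined
        ll1 = float(np.sum(np.where(y > 0, np.log(p), np.log1p(-p))))
    ll0 = 0.0 if not np.any(y > 0) else _NEG_INF
    return ll1, ll0


def site_log_likelihood(
    psi0: float,
    gamma: float,
    phi: np.ndarray,
    p: list[np.ndarray],
    y: list[np.ndarray],
) -> float:
    """Exact marginal log-likelihood of one species' history at one site.

    Parameters
    ----------
    psi0 : initial occupancy probability (year index 0).
    gamma : colonisation probability.
    phi : array (T-1,) — phi[t-1] is the persistence probability from
        year t-1 into year t (built from covariates at t-1).
    p, y : length-T lists of per-visit detection probabilities and binary
        outcomes; an unsurveyed year is an empty array and contributes
        only transition factors.

    The latent chain is marginalised by a scaled forward recursion, so
    the value is exact up to floating point regardless of run length.
    """
    T = len(y)
    if len(p) != T or len(phi) != T - 1:
        raise ValueError("p must have T entries and phi T-1 entries")
    prior1, prior0 = float(psi0), 1.0 - float(psi0)
    ll = 0.0
    f1, f0 = prior1, prior0
    for t in range(T):
        le1, le0 = emission_loglik(p[t], y[t])
        m = max(le1, le0)
        if m == _NEG_INF:
            return _NEG_INF
        e1 = np.exp(le1 - m)
        e0 = np.exp(le0 - m) if le0 != _NEG_INF else 0.0
        a1 = f1 * e1
        a0 = f0 * e0
        s = a1 + a0
        if s <= 0.0:
            return _NEG_INF
        ll += m + np.log(s)
        f1, f0 = a1 / s, a0 / s
        if t < T - 1:
            f1, f0 = f1 * phi[t] + f0 * gamma, f1 * (1 - phi[t]) + f0 * (1 - gamma)
    return float(ll)


def brute_force_log_likelihood(
    psi0: float,
    gamma: float,
    phi: np.ndarray,
    p: list[np.ndarray],
    y: list[np.ndarray],
    max_years: int = 12,
) -> float:
    """Marginal log-likelihood by enumerating every occupancy path.

    Sums P(path) * P(y | path) over all 2^T paths; test oracle for
    :func:`site_log_likelihood`, refusing T beyond ``max_years``.
    """
    T = len(y)
    if T > max_years:
        raise ValueError(f"brute force enumeration refused for T={T} > {max_years}")
    total = 0.0
    for path in itertools.product((0, 1), repeat=T):
        prob = psi0 if path[0] == 1 else 1.0 - psi0
        for t in range(1, T):
            pt = transition_prob(path[t - 1], phi[t - 1], gamma)
            prob *= pt if path[t] == 1 else 1.0 - pt
        like = 1.0
        for t in range(T):
            le1, le0 = emission_loglik(p[t], y[t])
            le = le1 if path[t] == 1 else le0
            like *= 0.0 if le == _NEG_INF else np.exp(le)
        total += prob * like
    with np.errstate(divide="ignore"):
        return float(np.log(total))
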