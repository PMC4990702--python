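"""MCMC machinery for the multi-species dynamic occupancy model.

Two samplers target the same posterior:

``run_chain_marginal`` (default, numba-compiled) integrates the latent
occupancy states out of the likelihood with the forward algorithm and
updates parameters by adaptive random-walk Metropolis-within-Gibbs, with
conjugate Gibbs draws for the hierarchical group means.  Marginalising z
shortens the chain's autocorrelation and makes the likelihood exactly
testable against brute-force path enumeration.

``run_chain_augmented`` (numpy) keeps the latent states explicit —
sampling z by forward-filtering backward-sampling and parameters from
their conditionals given z — mirroring the formulation a BUGS-style
sampler uses.  It is slower and exists as an independent route to the
same posterior; agreement between the two on small datasets is part of
the test suite.

Parameter packing (per-species array ``theta`` of width 9):
``0=logit colonisation, 1..4 = persistence intercept/OSR/neonic/FII,
5..7 = detection intercept/short-list/long-list, 8 = logit initial
occupancy``.  Hyper-parameter slots 0..10: gamma, beta0, beta1 (forager,
non-forager), beta2 (f, nf), beta3 (f, nf), beta4, beta5, beta6.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "HYPER_NAMES",
    "THETA_COLS",
    "hyper_index_matrix",
    "run_chain_marginal",
    "run_chain_augmented",
]

THETA_COLS = (
    "lgamma", "beta0", "beta1", "beta2", "beta3", "beta4", "beta5", "beta6", "lpsi0",
)

HYPER_NAMES = (
    "gamma", "beta0",
    "beta1_forager", "beta1_nonforager",
    "beta2_forager", "beta2_nonforager",
    "beta3_forager", "beta3_nonforager",
    "beta4", "beta5", "beta6",
)

# theta column governed by each hyper slot, and the group it applies to
# (-1 = all species, 0 = forager, 1 = non-forager).
_HYPER_COL = np.array([0, 1, 2, 2, 3, 3, 4, 4, 5, 6, 7], dtype=np.int64)
_HYPER_GRP = np.array([-1, -1, 0, 1, 0, 1, 0, 1, -1, -1, -1], dtype=np.int64)

_CLIP = 35.0


def hyper_index_matrix(group: np.ndarray) -> np.ndarray:
    """(S, 9) map from species/column to hyper slot; -1 = flat prior (psi0)."""
    S = len(group)
    hidx = np.empty((S, 9), dtype=np.int64)
    hidx[:, 0] = 0
    hidx[:, 1] = 1
    hidx[:, 2] = np.where(group == 0, 2, 3)
    hidx[:, 3] = np.where(group == 0, 4, 5)
    hidx[:, 4] = np.where(group == 0, 6, 7)
    hidx[:, 5] = 8
    hidx[:, 6] = 9
    hidx[:, 7] = 10
    hidx[:, 8] = -1
    return hidx


@njit(cache=True)
def _sigmoid(x):
    if x > _CLIP:
        x = _CLIP
    elif x < -_CLIP:
        x = -_CLIP
    if x >= 0.0:
        return 1.0 / (1.0 + np.exp(-x))
    e = np.exp(x)
    return e / (1.0 + e)


@njit(cache=True)
def _fill_logp(b4, b5, b6, alpha, logp1, log1mp):
    T = alpha.shape[0]
    for t in range(T):
        for c in range(3):
            x = b4 + alpha[t]
            if c == 1:
                x += b5
            elif c == 2:
                x += b6
            p = _sigmoid(x)
            logp1[t, c] = np.log(p)
            log1mp[t, c] = np.log1p(-p)


@njit(cache=True)
def _fill_em1(det_i, nvis, logp1, log1mp, em1_i):
    J, T = em1_i.shape
    for j in range(J):
        for t in range(T):
            s = 0.0
            for c in range(3):
                n = nvis[j, t, c]
                if n > 0.0:
                    d = det_i[j, t, c]
                    s += d * logp1[t, c] + (n - d) * log1mp[t, c]
            em1_i[j, t] = s


@njit(cache=True)
def _fill_em1_exp(det_i, nvis, logp1, log1mp, em1_i, eem1_i):
    J, T = em1_i.shape
    for j in range(J):
        for t in range(T):
            s = 0.0
            for c in range(3):
                n = nvis[j, t, c]
                if n > 0.0:
                    d = det_i[j, t, c]
                    s += d * logp1[t, c] + (n - d) * log1mp[t, c]
            em1_i[j, t] = s
            eem1_i[j, t] = np.exp(s)


@njit(cache=True)
def _fill_phi(b0, b1, b2, b3, cov, phi_i):
    J, Tm1 = phi_i.shape
    for j in range(J):
        for t in range(Tm1):
            phi_i[j, t] = _sigmoid(
                b0 + b1 * cov[j, t, 0] + b2 * cov[j, t, 1] + b3 * cov[j, t, 2]
            )


@njit(cache=True)
def _forward(psi0, gamma, phi_i, em1_i, anydet_i):
    """Marginal log-likelihood for one species, summed over sites."""
    J, T = em1_i.shape
    ll = 0.0
    for j in range(J):
        f1 = psi0
        f0 = 1.0 - psi0
        for t in range(T):
            le1 = em1_i[j, t]
            if anydet_i[j, t]:
                # z=0 emits probability 0: collapse to the occupied state.
                if f1 <= 0.0:
                    return -1.0e300
                ll += le1 + np.log(f1)
                f1 = 1.0
                f0 = 0.0
            else:
                a1 = f1 * np.exp(le1)
                s = a1 + f0
                ll += np.log(s)
                f1 = a1 / s
                f0 = f0 / s
            if t < T - 1:
                ph = phi_i[j, t]
                f1n = f1 * ph + f0 * gamma
                f0 = f1 * (1.0 - ph) + f0 * (1.0 - gamma)
                f1 = f1n
    return ll


@njit(cache=True)
def _species_ll(det_i, nvis, cov, anydet_i, row, alpha, logp1, log1mp, em1_i, phi_i):
    _fill_logp(row[5], row[6], row[7], alpha, logp1, log1mp)
    _fill_em1(det_i, nvis, logp1, log1mp, em1_i)
    _fill_phi(row[1], row[2], row[3], row[4], cov, phi_i)
    return _forward(_sigmoid(row[8]), _sigmoid(row[0]), phi_i, em1_i, anydet_i)


_TINY = 1e-280


@njit(cache=True)
def _forward_fast(psi0, gamma, phi_i, em1_i, eem1_i, anydet_i):
    """Forward pass using a cached exp(emission); log taken only on
    renormalisation, so the inner loop is multiply/divide bound."""
    J, T = em1_i.shape
    ll = 0.0
    for j in range(J):
        f1 = psi0
        f0 = 1.0 - psi0
        prod = 1.0
        for t in range(T):
            if anydet_i[j, t]:
                if f1 <= 0.0:
                    return -1.0e300
                ll += em1_i[j, t]
                prod *= f1
                f1 = 1.0
                f0 = 0.0
            else:
                a1 = f1 * eem1_i[j, t]
                s = a1 + f0
                prod *= s
                f1 = a1 / s
                f0 = f0 / s
            if prod < _TINY:
                if prod <= 0.0:
                    return -1.0e300
                ll += np.log(prod)
                prod = 1.0
            if t < T - 1:
                ph = phi_i[j, t]
                f1n = f1 * ph + f0 * gamma
                f0 = f1 * (1.0 - ph) + f0 * (1.0 - gamma)
                f1 = f1n
        ll += np.log(prod)
    return ll


@njit(cache=True)
def _forward_replace_col(psi0, gamma, phi_i, em1_i, eem1_i, anydet_i,
                         em1_col, eem1_col, tr):
    """Forward pass with year ``tr``'s emission taken from the proposal
    columns instead of the cache (detection year-effect updates)."""
    J, T = em1_i.shape
    ll = 0.0
    for j in range(J):
        f1 = psi0
        f0 = 1.0 - psi0
        prod = 1.0
        for t in range(T):
            if t == tr:
                le1 = em1_col[j]
                ee1 = eem1_col[j]
            else:
                le1 = em1_i[j, t]
                ee1 = eem1_i[j, t]
            if anydet_i[j, t]:
                if f1 <= 0.0:
                    return -1.0e300
                ll += le1
                prod *= f1
                f1 = 1.0
                f0 = 0.0
            else:
                a1 = f1 * ee1
                s = a1 + f0
                prod *= s
                f1 = a1 / s
                f0 = f0 / s
            if prod < _TINY:
                if prod <= 0.0:
                    return -1.0e300
                ll += np.log(prod)
                prod = 1.0
            if t < T - 1:
                ph = phi_i[j, t]
                f1n = f1 * ph + f0 * gamma
                f0 = f1 * (1.0 - ph) + f0 * (1.0 - gamma)
                f1 = f1n
        ll += np.log(prod)
    return ll


@njit(cache=True)
def _normal_logpdf(x, mu, sd):
    z = (x - mu) / sd
    return -0.5 * z * z - np.log(sd)


@njit(cache=True)
def _lpsi_logprior(x):
    # logit-scale density of a Uniform(0,1) prior on psi0: log p + log(1-p)
    p = _sigmoid(x)
    return np.log(p) + np.log1p(-p)


@njit(cache=True)
def _sd_logprior(sd, scale, kind):
    # kind 0 = half-normal, 1 = half-Cauchy, both with the given scale
    if kind == 0:
        return -0.5 * (sd / scale) ** 2
    return -np.log1p((sd / scale) ** 2)


@njit(cache=True)
def run_chain_marginal(
    det, nvis, cov, anydet, hidx, hyper_col, hyper_grp, group,
    theta, alpha, hyper_mu, hyper_sd, sigma_alpha,
    n_iter, n_burn, thin, seed,
    mu_prior_sd, sd_prior_scale, sd_prior_kind, sample_hypers, adapt,
):
    """One MCMC chain on the marginalised likelihood.  Mutates the
    parameter arrays in place and returns the kept draws."""
    np.random.seed(seed)
    S, J, T, _ = det.shape
    n_hyper = hyper_mu.shape[0]

    logp1 = np.empty((T, 3))
    log1mp = np.empty((T, 3))
    s_em1 = np.empty((J, T))
    s_eem1 = np.empty((J, T))
    s_phi = np.empty((J, T - 1))
    em1 = np.empty((S, J, T))
    eem1 = np.empty((S, J, T))
    phi = np.empty((S, J, T - 1))
    cur_ll = np.empty(S)
    new_lls = np.empty(S)
    col_em = np.empty((S, J))
    col_eem = np.empty((S, J))
    for i in range(S):
        _fill_logp(theta[i, 5], theta[i, 6], theta[i, 7], alpha, logp1, log1mp)
        _fill_em1_exp(det[i], nvis, logp1, log1mp, em1[i], eem1[i])
        _fill_phi(theta[i, 1], theta[i, 2], theta[i, 3], theta[i, 4], cov, phi[i])
        cur_ll[i] = _forward_fast(
            _sigmoid(theta[i, 8]), _sigmoid(theta[i, 0]), phi[i], em1[i], eem1[i], anydet[i]
        )

    steps_theta = np.full((S, 9), 0.25)
    steps_alpha = np.full(T, 0.15)
    steps_sd = np.full(n_hyper + 1, 0.3)
    acc_theta = np.zeros((S, 9))
    acc_alpha = np.zeros(T)
    acc_sd = np.zeros(n_hyper + 1)
    batch_len = 50

    n_keep = 0
    for it in range(n_burn, n_iter):
        if (it - n_burn) % thin == 0:
            n_keep += 1
    out_theta = np.empty((n_keep, S, 9))
    out_alpha = np.empty((n_keep, T))
    out_mu = np.empty((n_keep, n_hyper))
    out_sd = np.empty((n_keep, n_hyper))
    out_salpha = np.empty(n_keep)
    keep = 0

    prop_row = np.empty(9)
    for it in range(n_iter):
        # --- species-level parameters, scalar random-walk Metropolis ---
        for i in range(S):
            for c in range(9):
                for k in range(9):
                    prop_row[k] = theta[i, k]
                prop_row[c] = theta[i, c] + steps_theta[i, c] * np.random.normal()
                g_p = _sigmoid(prop_row[0])
                psi_p = _sigmoid(prop_row[8])
                if c == 0 or c == 8:
                    new_ll = _forward_fast(
                        psi_p, g_p, phi[i], em1[i], eem1[i], anydet[i]
                    )
                elif c <= 4:
                    _fill_phi(
                        prop_row[1], prop_row[2], prop_row[3], prop_row[4], cov, s_phi
                    )
                    new_ll = _forward_fast(
                        psi_p, g_p, s_phi, em1[i], eem1[i], anydet[i]
                    )
                else:
                    _fill_logp(
                        prop_row[5], prop_row[6], prop_row[7], alpha, logp1, log1mp
                    )
                    _fill_em1_exp(det[i], nvis, logp1, log1mp, s_em1, s_eem1)
                    new_ll = _forward_fast(
                        psi_p, g_p, phi[i], s_em1, s_eem1, anydet[i]
                    )
                h = hidx[i, c]
                if h >= 0:
                    dprior = _normal_logpdf(prop_row[c], hyper_mu[h], hyper_sd[h]) - \
                        _normal_logpdf(theta[i, c], hyper_mu[h], hyper_sd[h])
                else:
                    dprior = _lpsi_logprior(prop_row[c]) - _lpsi_logprior(theta[i, c])
                if np.log(np.random.uniform(0.0, 1.0)) < new_ll - cur_ll[i] + dprior:
                    theta[i, c] = prop_row[c]
                    cur_ll[i] = new_ll
                    if 1 <= c <= 4:
                        phi[i] = s_phi
                    elif c >= 5:
                        em1[i] = s_em1
                        eem1[i] = s_eem1
                    acc_theta[i, c] += 1.0

        # --- detection year effects ---
        for t in range(T):
            a_old = alpha[t]
            a_new = a_old + steps_alpha[t] * np.random.normal()
            dll = 0.0
            for i in range(S):
                # proposal changes only year t's detection logits
                for c3 in range(3):
                    x = theta[i, 5] + a_new
                    if c3 == 1:
                        x += theta[i, 6]
                    elif c3 == 2:
                        x += theta[i, 7]
                    p = _sigmoid(x)
                    logp1[0, c3] = np.log(p)
                    log1mp[0, c3] = np.log1p(-p)
                for j in range(J):
                    s = 0.0
                    for c3 in range(3):
                        n = nvis[j, t, c3]
                        if n > 0.0:
                            d = det[i, j, t, c3]
                            s += d * logp1[0, c3] + (n - d) * log1mp[0, c3]
                    col_em[i, j] = s
                    col_eem[i, j] = np.exp(s)
                nll = _forward_replace_col(
                    _sigmoid(theta[i, 8]), _sigmoid(theta[i, 0]), phi[i],
                    em1[i], eem1[i], anydet[i], col_em[i], col_eem[i], t,
                )
                new_lls[i] = nll
                dll += nll - cur_ll[i]
            dprior = -0.5 * ((a_new / sigma_alpha) ** 2 - (a_old / sigma_alpha) ** 2)
            if np.log(np.random.uniform(0.0, 1.0)) < dll + dprior:
                alpha[t] = a_new
                for i in range(S):
                    cur_ll[i] = new_lls[i]
                    for j in range(J):
                        em1[i, j, t] = col_em[i, j]
                        eem1[i, j, t] = col_eem[i, j]
                acc_alpha[t] += 1.0

        # --- hierarchical group means (Gibbs) and SDs (Metropolis) ---
        if sample_hypers:
            for h in range(n_hyper):
                c = hyper_col[h]
                g = hyper_grp[h]
                n = 0
                sx = 0.0
                for i in range(S):
                    if g < 0 or group[i] == g:
                        n += 1
                        sx += theta[i, c]
                sd2 = hyper_sd[h] * hyper_sd[h]
                post_var = 1.0 / (n / sd2 + 1.0 / (mu_prior_sd * mu_prior_sd))
                post_mean = post_var * sx / sd2
                hyper_mu[h] = post_mean + np.sqrt(post_var) * np.random.normal()

                ls_old = np.log(hyper_sd[h])
                ls_new = ls_old + steps_sd[h] * np.random.normal()
                sd_new = np.exp(ls_new)
                dll = 0.0
                for i in range(S):
                    if g < 0 or group[i] == g:
                        dll += _normal_logpdf(theta[i, c], hyper_mu[h], sd_new) - \
                            _normal_logpdf(theta[i, c], hyper_mu[h], hyper_sd[h])
                dprior = _sd_logprior(sd_new, sd_prior_scale, sd_prior_kind) - \
                    _sd_logprior(hyper_sd[h], sd_prior_scale, sd_prior_kind)
                # log-scale proposal Jacobian
                dprior += ls_new - ls_old
                if np.log(np.random.uniform(0.0, 1.0)) < dll + dprior:
                    hyper_sd[h] = sd_new
                    acc_sd[h] += 1.0

            # year-effect scale
            ls_old = np.log(sigma_alpha)
            ls_new = ls_old + steps_sd[n_hyper] * np.random.normal()
            sa_new = np.exp(ls_new)
            dll = 0.0
            for t in range(T):
                dll += _normal_logpdf(alpha[t], 0.0, sa_new) - \
                    _normal_logpdf(alpha[t], 0.0, sigma_alpha)
            dprior = _sd_logprior(sa_new, sd_prior_scale, sd_prior_kind) - \
                _sd_logprior(sigma_alpha, sd_prior_scale, sd_prior_kind) + ls_new - ls_old
            if np.log(np.random.uniform(0.0, 1.0)) < dll + dprior:
                sigma_alpha = sa_new
                acc_sd[n_hyper] += 1.0

        # --- step-size adaptation during burn-in ---
        if adapt and it < n_burn and (it + 1) % batch_len == 0:
            for i in range(S):
                for c in range(9):
                    rate = acc_theta[i, c] / batch_len
                    steps_theta[i, c] *= np.exp(0.66 * (rate - 0.44))
                    acc_theta[i, c] = 0.0
            for t in range(T):
                rate = acc_alpha[t] / batch_len
                steps_alpha[t] *= np.exp(0.66 * (rate - 0.44))
                acc_alpha[t] = 0.0
            for h in range(n_hyper + 1):
                rate = acc_sd[h] / batch_len
                steps_sd[h] *= np.exp(0.66 * (rate - 0.44))
                acc_sd[h] = 0.0

        if it >= n_burn and (it - n_burn) % thin == 0:
            out_theta[keep] = theta
            out_alpha[keep] = alpha
            out_mu[keep] = hyper_mu
            out_sd[keep] = hyper_sd
            out_salpha[keep] = sigma_alpha
            keep += 1

    return out_theta, out_alpha, out_mu, out_sd, out_salpha


# ---------------------------------------------------------------------------
# Data-augmented variant (explicit latent states, numpy)
# ---------------------------------------------------------------------------

def _sigmoid_np(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -_CLIP, _CLIP)))


def _em1_np(det_i, nvis, b4, b5, b6, alpha):
    """(J, T) log P(y | z=1) for one species from category counts."""
    T = alpha.shape[0]
    offs = np.array([0.0, b5, b6])
    logits = b4 + alpha[:, None] + offs[None, :]  # (T, 3)
    p = _sigmoid_np(logits)
    lp, l1p = np.log(p), np.log1p(-p)
    return np.einsum("jtc,tc->jt", det_i, lp) + np.einsum(
        "jtc,tc->jt", nvis - det_i, l1p
    )


def _ffbs_species(rng, psi0, gamma, phi_i, em1_i, anydet_i):
    """Sample latent z (J, T) by forward filtering, backward sampling."""
    J, T = em1_i.shape
    e1 = np.exp(em1_i - em1_i.max(axis=1, keepdims=True) * 0)  # keep raw scale
    # emission for z=0 is 1 unless a detection happened
    e0 = (~anydet_i).astype(float)
    f1 = np.empty((J, T))
    f0 = np.empty((J, T))
    a1 = psi0 * np.exp(em1_i[:, 0])
    a0 = (1 - psi0) * e0[:, 0]
    s = a1 + a0
    f1[:, 0], f0[:, 0] = a1 / s, a0 / s
    for t in range(1, T):
        ph = phi_i[:, t - 1]
        pr1 = f1[:, t - 1] * ph + f0[:, t - 1] * gamma
        pr0 = f1[:, t - 1] * (1 - ph) + f0[:, t - 1] * (1 - gamma)
        a1 = pr1 * np.exp(em1_i[:, t])
        a0 = pr0 * e0[:, t]
        s = a1 + a0
        f1[:, t], f0[:, t] = a1 / s, a0 / s
    z = np.empty((J, T), dtype=np.int64)
    z[:, T - 1] = rng.random(J) < f1[:, T - 1]
    for t in range(T - 2, -1, -1):
        ph = phi_i[:, t]
        # P(z_t=1 | z_{t+1}, y_{1:t})
        w1 = f1[:, t] * np.where(z[:, t + 1] == 1, ph, 1 - ph)
        w0 = f0[:, t] * np.where(z[:, t + 1] == 1, gamma, 1 - gamma)
        z[:, t] = rng.random(J) < w1 / (w1 + w0)
    return z


def run_chain_augmented(
    det, nvis, cov, anydet, hidx, group,
    theta, alpha, hyper_mu, hyper_sd, sigma_alpha,
    n_iter, n_burn, thin, seed,
    mu_prior_sd=10.0, sd_prior_scale=2.5, sd_prior_kind=0,
    sample_hypers=True, step=0.25,
):
    """One chain of the explicit-latent-state sampler (slow; small data).

    Alternates forward-filtering backward-sampling of z per species with
    Metropolis updates of the parameters given z (conjugate Beta draw for
    initial occupancy, Gibbs for hyper-means).  Targets the same
    posterior as :func:`run_chain_marginal`.
    """
    rng = np.random.default_rng(seed)
    S, J, T, _ = det.shape
    theta = theta.copy()
    alpha = alpha.copy()
    hyper_mu = hyper_mu.copy()
    hyper_sd = hyper_sd.copy()
    n_hyper = len(hyper_mu)

    def phi_of(row):
        return _sigmoid_np(row[1] + cov[:, :, 0] * row[2] + cov[:, :, 1] * row[3]
                           + cov[:, :, 2] * row[4])

    def trans_ll(row, z_i, phi_i):
        g = _sigmoid_np(row[0])
        zp, zn = z_i[:, :-1], z_i[:, 1:]
        with np.errstate(divide="ignore", invalid="ignore"):
            occ = zp * (zn * np.log(phi_i) + (1 - zn) * np.log1p(-phi_i))
            emp = (1 - zp) * (zn * np.log(g) + (1 - zn) * np.log1p(-g))
        return float(np.sum(occ + emp))

    def det_ll(row, z_i, em1_i):
        return float(np.sum(em1_i[z_i == 1]))

    z = np.zeros((S, J, T), dtype=np.int64)
    keeps = []
    for it in range(n_iter):
        for i in range(S):
            row = theta[i]
            phi_i = phi_of(row)
            em1_i = _em1_np(det[i], nvis, row[5], row[6], row[7], alpha)
            z[i] = _ffbs_species(
                rng, _sigmoid_np(row[8]), _sigmoid_np(row[0]), phi_i, em1_i, anydet[i]
            )
            # psi0: conjugate Beta draw under the flat prior
            k1 = int(z[i, :, 0].sum())
            theta[i, 8] = _logit(rng.beta(1 + k1, 1 + J - k1))
            # remaining columns: scalar Metropolis given z
            for c in (0, 1, 2, 3, 4, 5, 6, 7):
                prop = theta[i].copy()
                prop[c] = theta[i, c] + step * rng.normal()
                if c in (0, 1, 2, 3, 4):
                    cur = trans_ll(theta[i], z[i], phi_of(theta[i]))
                    new = trans_ll(prop, z[i], phi_of(prop))
                else:
                    cur = det_ll(theta[i], z[i], _em1_np(det[i], nvis, *theta[i, 5:8], alpha))
                    new = det_ll(prop, z[i], _em1_np(det[i], nvis, *prop[5:8], alpha))
                h = hidx[i, c]
                dprior = (
                    _normal_logpdf_np(prop[c], hyper_mu[h], hyper_sd[h])
                    - _normal_logpdf_np(theta[i, c], hyper_mu[h], hyper_sd[h])
                )
                if np.log(rng.random()) < new - cur + dprior:
                    theta[i] = prop

        for t in range(T):
            a_prop = alpha.copy()
            a_prop[t] = alpha[t] + step * rng.normal()
            cur = new = 0.0
            for i in range(S):
                em_cur = _em1_np(det[i], nvis, *theta[i, 5:8], alpha)
                em_new = _em1_np(det[i], nvis, *theta[i, 5:8], a_prop)
                m = z[i] == 1
                cur += float(em_cur[m].sum())
                new += float(em_new[m].sum())
            dprior = -0.5 * ((a_prop[t] / sigma_alpha) ** 2 - (alpha[t] / sigma_alpha) ** 2)
            if np.log(rng.random()) < new - cur + dprior:
                alpha = a_prop

        if sample_hypers:
            for h in range(n_hyper):
                c = _HYPER_COL[h]
                g = _HYPER_GRP[h]
                mask = np.ones(S, dtype=bool) if g < 0 else (group == g)
                x = theta[mask, c]
                sd2 = hyper_sd[h] ** 2
                post_var = 1.0 / (len(x) / sd2 + 1.0 / mu_prior_sd**2)
                post_mean = post_var * x.sum() / sd2
                hyper_mu[h] = rng.normal(post_mean, np.sqrt(post_var))
                ls_new = np.log(hyper_sd[h]) + step * rng.normal()
                sd_new = np.exp(ls_new)
                dll = float(
                    np.sum(_normal_logpdf_np(x, hyper_mu[h], sd_new))
                    - np.sum(_normal_logpdf_np(x, hyper_mu[h], hyper_sd[h]))
                )
                dpr = (
                    _sd_logprior_np(sd_new, sd_prior_scale, sd_prior_kind)
                    - _sd_logprior_np(hyper_sd[h], sd_prior_scale, sd_prior_kind)
                    + ls_new - np.log(hyper_sd[h])
                )
                if np.log(rng.random()) < dll + dpr:
                    hyper_sd[h] = sd_new

        if it >= n_burn and (it - n_burn) % thin == 0:
            keeps.append(
                (theta.copy(), alpha.copy(), hyper_mu.copy(), hyper_sd.copy(), sigma_alpha)
            )

    out_theta = np.stack([k[0] for k in keeps])
    out_alpha = np.stack([k[1] for k in keeps])
    out_mu = np.stack([k[2] for k in keeps])
    out_sd = np.stack([k[3] for k in keeps])
    out_salpha = np.array([k[4] for k in keeps])
    return out_theta, out_alpha, out_mu, out_sd, out_salpha


def _logit(p):
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return np.log(p) - np.log1p(-p)


def _normal_logpdf_np(x, mu, sd):
    z = (np.asarray(x) - mu) / sd
    return -0.5 * z * z - np.log(sd)


def _sd_logprior_np(sd, scale, kind):
    if kind == 0:
        return -0.5 * (sd / scale) ** 2
    return -np.log1p((sd / scale) ** 2)
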