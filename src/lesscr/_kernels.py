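"""Numba kernels for the Metropolis-within-Gibbs SCR sampler.

Everything here operates on flat arrays so the per-iteration sweeps compile
to tight loops.  Per-individual log-likelihoods are evaluated lazily over
each individual's detector index only (never via a full individuals x
detectors distance matrix): this locality is what makes the local-evaluation
model fast.

A per-individual cache ``curll`` holds the current log-likelihood of every
included (z = 1) individual; it is refreshed whenever that individual's
activity center, the detection parameters, or its inclusion flag changes,
so scalar-parameter updates need only one fresh likelihood evaluation.

Randomness uses numba's thread-local ``np.random`` state, seeded once per
chain via :func:`seed_rng`; a chain is therefore a pure function of its seed
and inputs.
"""

import numpy as np
from numba import njit

__all__ = [
    "seed_rng",
    "in_habitat",
    "loglik_one",
    "loglik_zero",
    "z_conditional",
    "sweep_s",
    "sweep_z",
    "update_sigma",
    "update_p0",
    "update_psi0",
    "all_loglik",
    "run_chain",
]


@njit(cache=True)
def seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True, inline="always")
def in_habitat(x, y, hab, x0, y0, cell):
    ny, nx = hab.shape
    ix = int(np.floor((x - x0) / cell))
    iy = int(np.floor((y - y0) / cell))
    if ix < 0 or iy < 0 or ix >= nx or iy >= ny:
        return False
    return hab[iy, ix]


@njit(cache=True, inline="always")
def _reflect(v, lo, hi):
    # fold a real line proposal back into [lo, hi) (symmetric reflection)
    w = hi - lo
    t = (v - lo) % (2.0 * w)
    if t < 0.0:
        t += 2.0 * w
    if t >= w:
        t = 2.0 * w - t
    r = lo + t
    if r >= hi:
        r = np.nextafter(hi, lo)
    return r


@njit(cache=True)
def loglik_one(px, py, i, idx, nd, ypad, det_x, det_y, p0, sigma):
    """Bernoulli log-likelihood of individual i's data at AC (px, py)."""
    inv2s2 = 1.0 / (2.0 * sigma * sigma)
    lp0 = np.log(p0)
    ll = 0.0
    for k in range(nd[i]):
        j = idx[i, k]
        dx = px - det_x[j]
        dy = py - det_y[j]
        d2 = dx * dx + dy * dy
        if ypad[i, k] == 1:
            ll += lp0 - d2 * inv2s2
        else:
            ll += np.log1p(-p0 * np.exp(-d2 * inv2s2))
    return ll


@njit(cache=True)
def loglik_zero(px, py, i, idx, nd, det_x, det_y, p0, sigma):
    """Log-probability of zero detections everywhere in i's window."""
    inv2s2 = 1.0 / (2.0 * sigma * sigma)
    ll = 0.0
    for k in range(nd[i]):
        j = idx[i, k]
        dx = px - det_x[j]
        dy = py - det_y[j]
        ll += np.log1p(-p0 * np.exp(-(dx * dx + dy * dy) * inv2s2))
    return ll


@njit(cache=True, inline="always")
def _psi_i(psi0, prop):
    # 1 - (1 - psi0)^prop, stable near psi0 = 1
    return -np.expm1(prop * np.log1p(-psi0))


@njit(cache=True)
def z_conditional(px, py, i, idx, nd, det_x, det_y, p0, sigma, psi0, prop_i):
    """P(z_i = 1 | everything else) for an augmented all-zero individual."""
    if prop_i <= 0.0:
        return 0.0
    ll0 = loglik_zero(px, py, i, idx, nd, det_x, det_y, p0, sigma)
    q = np.exp(ll0)
    psi = _psi_i(psi0, prop_i)
    return psi * q / (psi * q + 1.0 - psi)


@njit(cache=True)
def sweep_s(
    sx, sy, z, curll, win, hab, x0, y0, cell,
    idx, nd, ypad, det_x, det_y, p0, sigma, n_det, sds, acc,
):
    """One reflected random-walk update of every activity center.

    Proposals are reflected at the AC-window boundary (symmetric) and
    rejected outright when they land in non-suitable habitat.  Excluded
    (z = 0) augmented individuals have a flat likelihood, so an in-habitat
    proposal is always accepted for them.
    """
    m = sx.shape[0]
    for i in range(m):
        if z[i] == 0 and i >= n_det and curll[i] == np.inf:
            # permanently excluded (no suitable habitat in window)
            continue
        px = _reflect(sx[i] + sds[i] * np.random.normal(), win[i, 0], win[i, 1])
        py = _reflect(sy[i] + sds[i] * np.random.normal(), win[i, 2], win[i, 3])
        if not in_habitat(px, py, hab, x0, y0, cell):
            continue
        if z[i] == 0 and i >= n_det:
            sx[i] = px
            sy[i] = py
            acc[i] += 1
            continue
        llp = loglik_one(px, py, i, idx, nd, ypad, det_x, det_y, p0, sigma)
        if np.log(np.random.random()) < llp - curll[i]:
            sx[i] = px
            sy[i] = py
            curll[i] = llp
            acc[i] += 1


@njit(cache=True)
def sweep_z(sx, sy, z, curll, prop, psi0, idx, nd, det_x, det_y, p0, sigma, n_det):
    """Exact Bernoulli draw of each augmented inclusion flag from its full
    conditional; detected individuals keep z = 1."""
    m = sx.shape[0]
    for i in range(n_det, m):
        if prop[i] <= 0.0:
            z[i] = 0
            continue
        ll0 = loglik_zero(sx[i], sy[i], i, idx, nd, det_x, det_y, p0, sigma)
        q = np.exp(ll0)
        psi = _psi_i(psi0, prop[i])
        pz = psi * q / (psi * q + 1.0 - psi)
        if np.random.random() < pz:
            z[i] = 1
            curll[i] = ll0
        else:
            z[i] = 0


@njit(cache=True)
def all_loglik(sx, sy, z, curll, idx, nd, ypad, det_x, det_y, p0, sigma, n_det):
    """Refresh ``curll`` for every included individual; return the total."""
    tot = 0.0
    for i in range(sx.shape[0]):
        if i < n_det or z[i] == 1:
            curll[i] = loglik_one(
                sx[i], sy[i], i, idx, nd, ypad, det_x, det_y, p0, sigma
            )
            tot += curll[i]
    return tot


@njit(cache=True)
def update_sigma(
    sx, sy, z, curll, tmpll, idx, nd, ypad, det_x, det_y,
    p0, sigma, sigma_max, sd, n_det,
):
    """Metropolis update of sigma on the log scale, Uniform(0, sigma_max) prior."""
    sigp = sigma * np.exp(sd * np.random.normal())
    if sigp >= sigma_max:
        return sigma, 0
    m = sx.shape[0]
    cur = 0.0
    prop_tot = 0.0
    for i in range(m):
        if i < n_det or z[i] == 1:
            cur += curll[i]
            tmpll[i] = loglik_one(
                sx[i], sy[i], i, idx, nd, ypad, det_x, det_y, p0, sigp
            )
            prop_tot += tmpll[i]
    if np.log(np.random.random()) < prop_tot - cur + np.log(sigp / sigma):
        for i in range(m):
            if i < n_det or z[i] == 1:
                curll[i] = tmpll[i]
        return sigp, 1
    return sigma, 0


@njit(cache=True)
def update_p0(
    sx, sy, z, curll, tmpll, idx, nd, ypad, det_x, det_y,
    p0, sigma, sd, n_det,
):
    """Metropolis update of p0 on the logit scale, Uniform(0, 1) prior."""
    lg = np.log(p0 / (1.0 - p0)) + sd * np.random.normal()
    p0p = 1.0 / (1.0 + np.exp(-lg))
    m = sx.shape[0]
    cur = 0.0
    prop_tot = 0.0
    for i in range(m):
        if i < n_det or z[i] == 1:
            cur += curll[i]
            tmpll[i] = loglik_one(
                sx[i], sy[i], i, idx, nd, ypad, det_x, det_y, p0p, sigma
            )
            prop_tot += tmpll[i]
    jac = np.log(p0p * (1.0 - p0p)) - np.log(p0 * (1.0 - p0))
    if np.log(np.random.random()) < prop_tot - cur + jac:
        for i in range(m):
            if i < n_det or z[i] == 1:
                curll[i] = tmpll[i]
        return p0p, 1
    return p0, 0


@njit(cache=True)
def _psi0_loglik(psi0, z, prop):
    # sum_i log Bernoulli(z_i | psi_i), psi_i = 1 - (1 - psi0)^prop_i
    l1m = np.log1p(-psi0)
    ll = 0.0
    for i in range(z.shape[0]):
        if prop[i] <= 0.0:
            continue  # psi_i = 0 and z_i = 0: zero contribution
        a = prop[i] * l1m
        if z[i] == 1:
            ll += np.log(-np.expm1(a))
        else:
            ll += a
    return ll


@njit(cache=True)
def update_psi0(z, prop, psi0, sd):
    """Metropolis update of psi0 on the logit scale, Uniform(0, 1) prior.

    When all prop_habitat equal 1 the target reduces to the conjugate
    Beta(1 + sum z, 1 + M - sum z) full conditional.
    """
    lg = np.log(psi0 / (1.0 - psi0)) + sd * np.random.normal()
    psip = 1.0 / (1.0 + np.exp(-lg))
    cur = _psi0_loglik(psi0, z, prop)
    prop_ll = _psi0_loglik(psip, z, prop)
    jac = np.log(psip * (1.0 - psip)) - np.log(psi0 * (1.0 - psi0))
    if np.log(np.random.random()) < prop_ll - cur + jac:
        return psip, 1
    return psi0, 0


@njit(cache=True)
def run_chain(
    seed,
    n_adapt,
    n_iter,
    thin,
    sx, sy, z, sigma, p0, psi0,
    win, prop, idx, nd, ypad, det_x, det_y,
    hab, x0, y0, cell,
    n_det, sigma_max,
    sds, sd_sigma, sd_p0, sd_psi0,
    store_sz,
):
    """One full MCMC chain: adaptive phase then sampling phase.

    Proposal scales adapt in batches of 50 iterations during the adaptive
    phase only (Robbins-Monro on the log scale, target acceptance 0.35) and
    are frozen afterwards to preserve detailed balance.  Returns thinned
    draws of (sigma, p0, psi0, N) plus optional (s, z) snapshots and
    post-adaptation acceptance rates.
    """
    np.random.seed(seed)
    m = sx.shape[0]
    curll = np.empty(m)
    tmpll = np.empty(m)
    for i in range(m):
        if i >= n_det and prop[i] <= 0.0:
            z[i] = 0
            curll[i] = np.inf  # permanent-exclusion sentinel
            continue
        curll[i] = loglik_one(sx[i], sy[i], i, idx, nd, ypad, det_x, det_y, p0, sigma)

    kept = n_iter // thin
    out_sigma = np.empty(kept)
    out_p0 = np.empty(kept)
    out_psi0 = np.empty(kept)
    out_n = np.empty(kept, dtype=np.int64)
    if store_sz:
        out_s = np.empty((kept, m, 2))
        out_z = np.empty((kept, m), dtype=np.int8)
    else:
        out_s = np.empty((0, m, 2))
        out_z = np.empty((0, m), dtype=np.int8)

    batch = 50
    acc_s = np.zeros(m, dtype=np.int64)
    acc_scalar = np.zeros(3, dtype=np.int64)  # sigma, p0, psi0 in batch
    post_acc_s = np.zeros(m, dtype=np.int64)
    post_acc_scalar = np.zeros(3, dtype=np.int64)
    target = 0.35
    n_batches = 0
    kept_i = 0

    for t in range(n_adapt + n_iter):
        adapting = t < n_adapt
        sweep_s(
            sx, sy, z, curll, win, hab, x0, y0, cell,
            idx, nd, ypad, det_x, det_y, p0, sigma, n_det, sds, acc_s,
        )
        sweep_z(sx, sy, z, curll, prop, psi0, idx, nd, det_x, det_y, p0, sigma, n_det)
        sigma, a = update_sigma(
            sx, sy, z, curll, tmpll, idx, nd, ypad, det_x, det_y,
            p0, sigma, sigma_max, sd_sigma, n_det,
        )
        acc_scalar[0] += a
        p0, a = update_p0(
            sx, sy, z, curll, tmpll, idx, nd, ypad, det_x, det_y,
            p0, sigma, sd_p0, n_det,
        )
        acc_scalar[1] += a
        psi0, a = update_psi0(z, prop, psi0, sd_psi0)
        acc_scalar[2] += a

        if adapting and (t + 1) % batch == 0:
            n_batches += 1
            step = min(0.25, 1.0 / np.sqrt(n_batches))
            for i in range(m):
                rate = acc_s[i] / batch
                sds[i] *= np.exp(step * (rate - target))
                lim = win[i, 1] - win[i, 0]
                if sds[i] > lim:
                    sds[i] = lim
                if sds[i] < 1e-4:
                    sds[i] = 1e-4
                acc_s[i] = 0
            sd_sigma *= np.exp(step * (acc_scalar[0] / batch - target))
            sd_p0 *= np.exp(step * (acc_scalar[1] / batch - target))
            sd_psi0 *= np.exp(step * (acc_scalar[2] / batch - target))
            sd_sigma = min(max(sd_sigma, 1e-4), 5.0)
            sd_p0 = min(max(sd_p0, 1e-4), 5.0)
            sd_psi0 = min(max(sd_psi0, 1e-4), 5.0)
            acc_scalar[:] = 0
        if t == n_adapt - 1:
            acc_s[:] = 0
            acc_scalar[:] = 0

        if not adapting:
            post_acc_s[:] = acc_s
            post_acc_scalar[:] = acc_scalar
            if (t - n_adapt + 1) % thin == 0 and kept_i < kept:
                out_sigma[kept_i] = sigma
                out_p0[kept_i] = p0
                out_psi0[kept_i] = psi0
                nn = 0
                for i in range(m):
                    if i < n_det or z[i] == 1:
                        nn += 1
                out_n[kept_i] = nn
                if store_sz:
                    for i in range(m):
                        out_s[kept_i, i, 0] = sx[i]
                        out_s[kept_i, i, 1] = sy[i]
                        out_z[kept_i, i] = 1 if (i < n_det or z[i] == 1) else 0
                kept_i += 1

    denom = n_iter if n_iter > 0 else 1
    acc_rate_s = post_acc_s / denom
    acc_rate_scalar = post_acc_scalar / denom
    return (
        out_sigma, out_p0, out_psi0, out_n, out_s, out_z,
        acc_rate_s, acc_rate_scalar, sds, sd_sigma, sd_p0, sd_psi0,
    )
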