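"""Numba kernels for the hot loops: window variance and MH updates.

All sampling kernels work on the flattened pixel arrays assembled in
:mod:`hicsampler.mcmc_sampler` and consume pre-drawn per-pixel random
numbers, so the result of a sweep phase does not depend on the order in
which conditionally independent pixels are processed.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def sigma2_window(L, half, floor):
    """Variance of adjacent log differences in a clipped square window.

    ``L`` is the (n_bins, W+1) banded log-value matrix with NaN marking
    unusable cells; ``half`` is half the window width.
    """
    n, wp1 = L.shape
    W = wp1 - 1
    out = np.full((n, wp1), floor)
    for i in range(n):
        for d in range(wp1):
            j = i + d
            if j >= n or not np.isfinite(L[i, d]):
                continue
            s = 0.0
            s2 = 0.0
            cnt = 0
            for r in range(i - half, i + half + 1):
                if r < 0 or r >= n:
                    continue
                for c in range(j - half, j + half + 1):
                    if c < r or c >= n or c - r > W:
                        continue
                    v = L[r, c - r]
                    if not np.isfinite(v):
                        continue
                    if c + 1 <= j + half and c + 1 < n and c + 1 - r <= W:
                        w = L[r, c + 1 - r]
                        if np.isfinite(w):
                            dv = v - w
                            s += dv
                            s2 += dv * dv
                            cnt += 1
                    if r + 1 <= i + half and r + 1 <= c and c - (r + 1) <= W:
                        w = L[r + 1, c - r - 1]
                        if np.isfinite(w):
                            dv = v - w
                            s += dv
                            s2 += dv * dv
                            cnt += 1
            if cnt >= 2:
                var = (s2 - s * s / cnt) / (cnt - 1)
                if var > floor:
                    out[i, d] = var
    return out


@njit(cache=True)
def mh_tile(idx, u, sd, acc, prop, o, bpair, logg, inv2om,
            nbr, nbr_inv2var, nbr_n, variant, z, logru):
    """One Metropolis–Hastings update for each pixel in ``idx``.

    Proposals are Gaussian in u = log t space; the acceptance ratio
    includes the +u change-of-variable term.  ``variant``: 0 uniform,
    1 local potential only, 2 local + pairwise (for the fixed-variance
    variant ``nbr_inv2var`` is pre-filled with the shared value).
    """
    for k in range(idx.size):
        p = idx[k]
        u0 = u[p]
        u1 = u0 + sd[p] * z[p]
        # Poisson term o*u - b*e^u plus the +u Jacobian
        dl = (o[p] + 1.0) * (u1 - u0) - bpair[p] * (np.exp(u1) - np.exp(u0))
        if variant >= 1:
            a1 = u1 - logg[p]
            a0 = u0 - logg[p]
            dl -= (a1 * a1 - a0 * a0) * inv2om[p]
        if variant >= 2:
            for m in range(nbr_n[p]):
                q = nbr[p, m]
                uq = u[q]
                b1 = u1 - uq
                b0 = u0 - uq
                dl -= (b1 * b1 - b0 * b0) * nbr_inv2var[p, m]
        prop[p] += 1
        if logru[p] < dl:
            u[p] = u1
            acc[p] += 1


@njit(cache=True)
def single_pixel_chain(o, bpair, logg, inv2om, nbr_u, nbr_inv2var, variant,
                       n_draws, thin, n_adapt, adapt_len, target, seed):
    """Adaptive MH chain for one pixel with fixed neighbour values.

    Returns (draws of u, final proposal sd, post-adaptation acceptance
    rate).  Used by the marginal-oracle diagnostics.
    """
    np.random.seed(seed)
    u = 0.0
    sd = 1.0

    def _delta(u0, u1):
        dl = (o + 1.0) * (u1 - u0) - bpair * (np.exp(u1) - np.exp(u0))
        if variant >= 1:
            dl -= ((u1 - logg) ** 2 - (u0 - logg) ** 2) * inv2om
        if variant >= 2:
            for m in range(nbr_u.size):
                dl -= ((u1 - nbr_u[m]) ** 2 - (u0 - nbr_u[m]) ** 2) \
                    * nbr_inv2var[m]
        return dl

    for r in range(1, n_adapt + 1):
        acc = 0
        for _ in range(adapt_len):
            u1 = u + sd * np.random.normal()
            if np.log(np.random.random()) < _delta(u, u1):
                u = u1
                acc += 1
        rate = acc / adapt_len
        sd *= np.exp((rate - target) / r)

    draws = np.empty(n_draws)
    acc_total = 0
    n_total = n_draws * thin
    for k in range(n_total):
        u1 = u + sd * np.random.normal()
        if np.log(np.random.random()) < _delta(u, u1):
            u = u1
            acc_total += 1
        if (k + 1) % thin == 0:
            draws[(k + 1) // thin - 1] = u
    return draws, sd, acc_total / n_total
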