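"""Model checking: predictive p-values, held-out likelihood, KL curves.

The posterior predictive check uses randomized p-values: for a discrete
count o with predictive CDF F, p ~ Uniform(F(o-1), F(o)).  Under the
true generating model these are exactly Uniform(0, 1), so the one-sample
KS statistic against the uniform is a calibrated summary of fit.

Held-out scoring follows the common Monte-Carlo approximation: the test
log-likelihood is the mean over posterior draws of the Poisson
log-likelihood of the held-out counts.  Train/test replicates are
produced by independent binomial downsampling of one deep contact map.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .contact_io import BiasVector, ContactMap
from .mcmc_sampler import PosteriorSamples

__all__ = ["downsample", "ppc_pvalues", "heldout_loglik", "kl_vs_sample_size"]


def downsample(o: ContactMap, fraction: float, seed: int = 0) -> ContactMap:
    """Binomial thinning: each count is replaced by Binomial(count, f)."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    out = o.copy()
    out.data = rng.binomial(o.data, fraction).astype(np.int64)
    out.data[~o.band_mask] = 0
    return out


def _pixel_arrays(ps: PosteriorSamples, o: ContactMap, b: BiasVector):
    if (o.n_bins != ps.n_bins or o.max_distance_bins != ps.max_distance_bins
            or b.n_bins != ps.n_bins):
        raise ValueError("grid mismatch between samples, contacts and bias")
    i, d = ps.pixel_i, ps.pixel_d
    keep = b.mask[i] & b.mask[i + d]
    return i[keep], d[keep], keep


def ppc_pvalues(ps: PosteriorSamples, o: ContactMap, b: BiasVector,
                seed: int = 0, max_samples: int | None = None):
    """Randomized posterior-predictive p-values and their KS statistic.

    The predictive CDF at each pixel is the average of Poisson CDFs over
    the posterior draws at rate ``b_ij * t_ij``; the p-value is drawn
    uniformly between CDF(o-1) and CDF(o).  Returns ``(pvals, ks_stat)``
    with masked pixels skipped.
    """
    S = ps.n_samples if max_samples is None else min(max_samples, ps.n_samples)
    if S < 50:
        raise ValueError("posterior predictive check requires >= 50 samples")
    i, d, keep = _pixel_arrays(ps, o, b)
    obs = o.data[i, d]
    bp = b.values[i] * b.values[i + d]
    lo = np.zeros(i.size)
    hi = np.zeros(i.size)
    for s in range(S):  # accumulate draw-wise to bound memory
        rate = bp * ps.samples[s, keep]
        hi += stats.poisson.cdf(obs, rate)
        lo += stats.poisson.cdf(obs - 1, rate)
    hi /= S
    lo /= S
    rng = np.random.default_rng(seed)
    pvals = lo + rng.random(i.size) * (hi - lo)
    ks = float(stats.kstest(pvals, "uniform").statistic)
    return pvals, ks


def heldout_loglik(ps: PosteriorSamples, test: ContactMap, b: BiasVector,
                   n_draws: int = 100) -> float:
    """Mean over the first ``n_draws`` posterior draws of the test
    Poisson log-likelihood (sum over unmasked in-band pixels)."""
    if ps.n_samples < n_draws:
        raise ValueError(f"need >= {n_draws} samples, have {ps.n_samples}")
    i, d, keep = _pixel_arrays(ps, test, b)
    obs = test.data[i, d]
    bp = b.values[i] * b.values[i + d]
    total = 0.0
    for s in range(n_draws):
        rate = bp * ps.samples[s, keep]
        total += float(stats.poisson.logpmf(obs, rate).sum())
    return total / n_draws


def kl_vs_sample_size(ps: PosteriorSamples, sizes, gold_size: int,
                      bins: int = 30) -> dict[int, float]:
    """Mean per-pixel KL(subset || gold) of marginal histograms.

    Both marginals are histogrammed on shared per-pixel log-scale bins
    spanning the gold draws, with add-one smoothing.  Subsets are the
    first-N prefixes of the gold draw sequence.
    """
    if gold_size > ps.n_samples:
        raise ValueError("gold_size exceeds available draws")
    sizes = sorted(int(s) for s in sizes)
    if sizes and sizes[-1] > gold_size:
        raise ValueError("requested size exceeds gold_size")
    X = np.log(ps.samples[:gold_size])         # (S, P)
    lo = X.min(axis=0)
    hi = X.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    idx = np.clip(((X - lo) / span * bins).astype(np.int64), 0, bins - 1)
    P = ps.n_pixels
    offsets = np.arange(P) * bins

    def hist(upto: int) -> np.ndarray:
        flat = (idx[:upto] + offsets).ravel()
        return np.bincount(flat, minlength=P * bins).reshape(P, bins)

    gold = hist(gold_size) + 1.0
    gold /= gold.sum(axis=1, keepdims=True)
    out = {}
    degenerate = hi <= lo
    for size in sizes:
        sub = hist(size) + 1.0
        sub /= sub.sum(axis=1, keepdims=True)
        kl = (sub * np.log(sub / gold)).sum(axis=1)
        kl[degenerate] = 0.0
        out[size] = float(kl.mean())
    return out
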