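"""Markov-random-field prior over the true interaction frequency matrix.

Each in-band pixel (i, j) carries a latent positive frequency t_ij.  The
prior combines:

* a local potential pulling log t_ij toward the fitted distance decay
  log g(|i-j|), with per-distance variance omega^2(d);
* pairwise potentials penalizing log differences between t_ij and its
  second-order (8-pixel) neighbours, with per-pixel variance sigma^2_ij;
  the variance of an edge is max(sigma^2_p, sigma^2_q) so the potential
  is symmetric in its arguments.

Both potentials are Gaussian kernels on the log scale: the log potential
is -(delta log)^2 / (2 v).  Hyperparameters are estimated empirically
from the ICE-normalized map (omega^2 per distance stratum, sigma^2 from
adjacent differences in a window, default 17 x 17).  Edges crossing
sharp domain boundaries — detected with two-sample Kolmogorov–Smirnov
tests on the flanking strips — are pruned from the Markov blankets so
the smoothing prior does not blur TAD boundaries.

Prior variants kept for model comparison: ``uniform`` (no prior terms),
``gaussian_local_only`` (distance-decay pull only), ``fixed_sigma``
(pairwise terms share one global variance), and the default ``full``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import special
from scipy.stats import poisson

from .contact_io import FrequencyMatrix
from ._kernels import sigma2_window

__all__ = [
    "MRFSpec",
    "VARIANTS",
    "estimate_omega2",
    "estimate_sigma2",
    "prune_blanket",
    "log_local_potential",
    "log_pairwise_potential",
    "log_conditional",
    "joint_log_prior",
    "neighbors",
    "build_spec",
]

VARIANTS = ("full", "uniform", "gaussian_local_only", "fixed_sigma")


@dataclass
class MRFSpec:
    """Hyperparameters and topology of the MRF prior."""

    omega2: np.ndarray                    # (W+1,) per-distance variance
    sigma2: np.ndarray                    # (n_bins, W+1) per-pixel variance
    pruned_edges: set = field(default_factory=set)
    window: int = 17
    variant: str = "full"
    sigma2_fixed: float | None = None
    variance_floor: float = 1e-4

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown prior variant {self.variant!r}")
        if self.variant == "fixed_sigma" and self.sigma2_fixed is None:
            raise ValueError("fixed_sigma variant requires sigma2_fixed")

    def edge_variance(self, p, q) -> float:
        """Variance of the pairwise potential on edge (p, q)."""
        if self.variant == "fixed_sigma":
            return float(self.sigma2_fixed)
        (i1, j1), (i2, j2) = p, q
        return float(max(self.sigma2[i1, j1 - i1], self.sigma2[i2, j2 - i2]))

    def is_pruned(self, p, q) -> bool:
        return (p, q) in self.pruned_edges


def _log_values(norm: FrequencyMatrix, mask=None) -> np.ndarray:
    """(n, W+1) log normalized values; NaN where unusable."""
    n = norm.n_bins
    vals = np.where(norm.band_mask & (norm.data > 0), norm.data, np.nan)
    if mask is not None:
        ii = np.arange(n)[:, None]
        jj = np.minimum(ii + np.arange(norm.data.shape[1])[None, :], n - 1)
        vals = np.where(mask[:, None] & mask[jj], vals, np.nan)
    with np.errstate(invalid="ignore"):
        return np.log(vals)


def estimate_omega2(norm: FrequencyMatrix, mask=None,
                    variance_floor: float = 1e-4) -> np.ndarray:
    """Per-distance variance of log normalized frequencies.

    Strata with fewer than 3 positive pixels borrow the nearest populated
    stratum's value (with a warning).  All entries are floored.
    """
    L = _log_values(norm, mask)
    W = norm.max_distance_bins
    out = np.full(W + 1, np.nan)
    counts = np.zeros(W + 1, dtype=int)
    for d in range(W + 1):
        col = L[: norm.n_bins - d, d] if d < norm.n_bins else np.empty(0)
        col = col[np.isfinite(col)]
        counts[d] = col.size
        if col.size >= 3:
            out[d] = max(np.var(col, ddof=1), variance_floor)
    if np.isnan(out).any():
        pop = np.nonzero(~np.isnan(out))[0]
        if pop.size == 0:
            warnings.warn("no populated distance stratum; omega2 set to floor")
            return np.full(W + 1, variance_floor)
        # strata beyond n_bins - 1 are structurally empty, not data-sparse
        n_sparse = int(np.isnan(out[: norm.n_bins]).sum())
        if n_sparse:
            warnings.warn(
                f"{n_sparse} distance strata have <3 positive pixels; "
                "using nearest populated stratum")
        for d in np.nonzero(np.isnan(out))[0]:
            out[d] = out[pop[np.argmin(np.abs(pop - d))]]
    return out


def estimate_sigma2(norm: FrequencyMatrix, window: int = 17, mask=None,
                    variance_floor: float = 1e-4) -> np.ndarray:
    """Per-pixel variance of first-order-adjacent log differences.

    For each in-band pixel, the variance of differences between
    horizontally / vertically adjacent pixel pairs whose endpoints both
    lie in the ``window x window`` square centred at the pixel (clipped
    to the valid banded upper triangle).
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    L = _log_values(norm, mask)
    return sigma2_window(L, window // 2, float(variance_floor))


def _ks_pvalue(x: np.ndarray, y: np.ndarray) -> float:
    """Asymptotic two-sample KS p-value (Smirnov)."""
    m, n = x.size, y.size
    grid = np.concatenate([x, y])
    grid.sort(kind="mergesort")
    cx = np.searchsorted(np.sort(x), grid, side="right") / m
    cy = np.searchsorted(np.sort(y), grid, side="right") / n
    d = np.abs(cx - cy).max()
    en = np.sqrt(m * n / (m + n))
    return float(special.kolmogorov((en + 0.12 + 0.11 / en) * d))


def prune_blanket(norm: FrequencyMatrix, alpha: float = 0.01, flank: int = 8,
                  mask=None) -> set:
    """Detect sharp transitions and prune the crossing neighbour edges.

    For every pair of vertically adjacent pixels (i, j)-(i+1, j) the log
    values in the ``flank``-row strips above and below the candidate
    boundary (columns j-flank .. j+flank) are compared with a two-sample
    KS test; horizontal edges analogously.  When p < alpha the edge is
    removed from both pixels' Markov blankets.  Edges without at least
    ``flank`` usable values per side are kept (conservative).

    Values are standardized per distance stratum (z-scores of the log
    normalized frequencies) before testing: both the decay trend and the
    count-noise variance vary systematically with distance, which would
    otherwise register as a transition at every edge; after
    standardization only departures from the expected decay (e.g. TAD
    edges) separate the two strips.

    ``alpha = 0`` disables pruning entirely.
    """
    if flank < 5:
        raise ValueError("flank must be >= 5 pixels per side")
    pruned: set = set()
    if alpha <= 0:
        return pruned
    n = norm.n_bins
    W = norm.max_distance_bins
    Lb = _log_values(norm, mask)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        cols = [Lb[: max(n - d, 1), d] if d < n else np.empty(0)
                for d in range(W + 1)]
        d_mean = np.array([np.nanmean(c) if c.size else np.nan for c in cols])
        d_sd = np.array([np.nanstd(c, ddof=1) if c.size > 2 else np.nan
                         for c in cols])
    d_sd = np.where(np.isfinite(d_sd) & (d_sd > 0), d_sd, 1.0)
    Lb = (Lb - np.where(np.isfinite(d_mean), d_mean, 0.0)[None, :]) / d_sd[None, :]
    # dense upper-triangle log matrix (NaN outside the valid band)
    dense = np.full((n, n), np.nan)
    ii, dd = np.nonzero(np.isfinite(Lb))
    dense[ii, ii + dd] = Lb[ii, dd]

    def strips(r0, r1, c0, c1, r2, r3):
        a = dense[max(r0, 0):max(r1, 0), max(c0, 0):c1].ravel()
        b = dense[max(r2, 0):max(r3, 0), max(c0, 0):c1].ravel()
        return a[np.isfinite(a)], b[np.isfinite(b)]

    f = flank
    for i in range(n):
        for j in range(max(i, 1), min(n, i + W + 1)):
            # vertical edge (i,j)-(i+1,j): boundary between rows i, i+1
            if i + 1 <= j and i + 1 < n and j - (i + 1) <= W:
                a, b = strips(i - f + 1, i + 1, j - f, j + f + 1, i + 1, i + f + 1)
                if a.size >= f and b.size >= f and _ks_pvalue(a, b) < alpha:
                    p, q = (i, j), (i + 1, j)
                    pruned.add((p, q))
                    pruned.add((q, p))
            # horizontal edge (i,j)-(i,j+1): boundary between cols j, j+1
            if j + 1 < n and (j + 1) - i <= W:
                a = dense[max(i - f, 0):i + f + 1, max(j - f + 1, 0):j + 1].ravel()
                b = dense[max(i - f, 0):i + f + 1, j + 1:j + f + 1].ravel()
                a, b = a[np.isfinite(a)], b[np.isfinite(b)]
                if a.size >= f and b.size >= f and _ks_pvalue(a, b) < alpha:
                    p, q = (i, j), (i, j + 1)
                    pruned.add((p, q))
                    pruned.add((q, p))
    return pruned


def log_local_potential(t: float, g: float, omega2: float) -> float:
    """Log Gaussian-kernel pull of t toward the decay expectation g."""
    if t <= 0 or g <= 0:
        raise ValueError("t and g must be positive")
    return -((np.log(t) - np.log(g)) ** 2) / (2.0 * omega2)


def log_pairwise_potential(t_p: float, t_q: float, sigma2_edge: float) -> float:
    """Log Gaussian-kernel smoothness penalty between neighbour values."""
    if t_p <= 0 or t_q <= 0:
        raise ValueError("frequencies must be positive")
    return -((np.log(t_p) - np.log(t_q)) ** 2) / (2.0 * sigma2_edge)


def neighbors(i: int, j: int, n_bins: int, max_distance_bins: int) -> list:
    """Second-order neighbourhood of pixel (i, j), canonicalized.

    Neighbours falling below the diagonal are reflected onto the upper
    triangle; out-of-band and out-of-range positions (and the pixel
    itself, which can arise by reflection on the diagonal) are dropped.
    """
    out = []
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == 0 and dj == 0:
                continue
            a, b = i + di, j + dj
            if a > b:
                a, b = b, a
            if (a, b) == (i, j) or a < 0 or b >= n_bins:
                continue
            if b - a > max_distance_bins:
                continue
            if (a, b) not in out:
                out.append((a, b))
    return out


def log_conditional(t: float, pixel: tuple, state: FrequencyMatrix,
                    o_ij: int, b_ij: float, g_ij: float, spec: MRFSpec) -> float:
    """Unnormalized log full-conditional density of t at one pixel.

    Sum of the Poisson log-likelihood at rate ``b_ij * t``, the local
    potential (except under the uniform variant), and the pairwise
    potentials over the pruned second-order blanket (except under the
    uniform and gaussian-local-only variants).
    """
    if t <= 0:
        return -np.inf
    i, j = pixel
    lp = float(poisson.logpmf(o_ij, b_ij * t))
    if spec.variant != "uniform":
        lp += log_local_potential(t, g_ij, float(spec.omega2[j - i]))
    if spec.variant in ("full", "fixed_sigma"):
        for q in neighbors(i, j, state.n_bins, state.max_distance_bins):
            if spec.is_pruned(pixel, q):
                continue
            tq = state.data[q[0], q[1] - q[0]]
            if tq <= 0:
                continue
            lp += log_pairwise_potential(t, tq, spec.edge_variance(pixel, q))
    return lp


def joint_log_prior(state: FrequencyMatrix, spec: MRFSpec, decay) -> float:
    """Log of the (unnormalized) joint MRF prior at a full state.

    Local terms are summed over valid positive pixels; every retained
    edge contributes exactly once.
    """
    if spec.variant == "uniform":
        return 0.0
    n, W = state.n_bins, state.max_distance_bins
    g_cache = np.atleast_1d(decay.predict(np.arange(min(W, n - 1) + 1)))
    total = 0.0
    for i in range(n):
        for d in range(min(W, n - 1 - i) + 1):
            t = state.data[i, d]
            if t <= 0:
                continue
            total += log_local_potential(t, g_cache[d], float(spec.omega2[d]))
            if spec.variant == "gaussian_local_only":
                continue
            p = (i, i + d)
            for q in neighbors(i, i + d, n, W):
                if q <= p:  # count each edge once
                    continue
                if spec.is_pruned(p, q):
                    continue
                tq = state.data[q[0], q[1] - q[0]]
                if tq <= 0:
                    continue
                total += log_pairwise_potential(t, tq, spec.edge_variance(p, q))
    return total


def build_spec(norm: FrequencyMatrix, mask=None, window: int = 17,
               alpha: float = 0.01, flank: int = 8, variant: str = "full",
               variance_floor: float = 1e-4,
               sigma2_fixed: float | None = None) -> MRFSpec:
    """Estimate all MRF hyperparameters from a normalized map.

    For the ``fixed_sigma`` variant, an unspecified ``sigma2_fixed``
    defaults to the band-wide mean of the per-pixel estimates.
    """
    omega2 = estimate_omega2(norm, mask, variance_floor)
    sigma2 = estimate_sigma2(norm, window, mask, variance_floor)
    if variant == "fixed_sigma" and sigma2_fixed is None:
        sigma2_fixed = float(sigma2[norm.band_mask].mean())
    pruned = prune_blanket(norm, alpha, flank, mask) if variant in (
        "full", "fixed_sigma") and alpha > 0 else set()
    return MRFSpec(omega2=omega2, sigma2=sigma2, pruned_edges=pruned,
                   window=window, variant=variant, sigma2_fixed=sigma2_fixed,
                   variance_floor=variance_floor)
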