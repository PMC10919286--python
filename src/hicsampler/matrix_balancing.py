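"""Iterative correction (ICE) of a banded contact map.

ICE assumes equal visibility of every usable bin: after dividing the raw
counts by the outer product of a per-bin bias vector, all unmasked bins
should have equal marginal coverage.  The bias vector is found by fixed
point iteration on the marginals.  Bins with zero or bottom-quantile raw
coverage are masked before iteration and excluded throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contact_io import BiasVector, ContactMap, FrequencyMatrix

__all__ = ["ice_balance", "banded_marginals", "IceResult"]


def banded_marginals(data: np.ndarray, n_bins: int) -> np.ndarray:
    """Full-matrix row sums of a banded symmetric matrix (diagonal once)."""
    s = np.nansum(data[:n_bins], axis=1).astype(float)
    W = data.shape[1] - 1
    for d in range(1, W + 1):
        if d < n_bins:
            s[d:] += np.nan_to_num(data[:n_bins - d, d])
    return s


@dataclass
class IceResult:
    bias: BiasVector
    normalized: FrequencyMatrix
    converged: bool
    n_iter: int


def ice_balance(o: ContactMap, max_iter: int = 200, tol: float = 1e-6,
                mask_quantile: float = 0.02) -> IceResult:
    """Balance a contact map, returning bias vector and normalized matrix.

    Parameters
    ----------
    o
        Raw banded contact map.
    max_iter, tol
        Iteration stops when the largest relative change of any unmasked
        bias entry falls below ``tol``; if that never happens within
        ``max_iter`` iterations the last iterate is returned with
        ``converged=False``.
    mask_quantile
        Bins whose raw marginal is zero, or below this quantile of the
        nonzero marginals, are masked.

    The returned bias is scaled to unit mean over unmasked bins, so
    ``normalized[i, j] = o[i, j] / (b[i] * b[j])`` reconstructs the raw
    counts exactly and unmasked rows of ``normalized`` have equal sums.
    """
    if o.total() == 0:
        raise ValueError("cannot balance an empty contact map")
    n = o.n_bins
    raw_marg = banded_marginals(o.data.astype(float), n)
    mask = raw_marg > 0
    if mask.sum() == 0:
        raise ValueError("all bins have zero coverage")
    thresh = np.quantile(raw_marg[mask], mask_quantile)
    mask &= raw_marg >= thresh

    # bin index of the column partner for every banded cell
    jj = np.arange(n)[:, None] + np.arange(o.data.shape[1])[None, :]
    jj_clip = np.minimum(jj, n - 1)  # out-of-band cells are zero anyway
    pair_ok = mask[:, None] & mask[jj_clip] & o.band_mask

    counts = np.where(pair_ok, o.data.astype(float), 0.0)
    b = np.ones(n)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        w = counts / (b[:, None] * b[jj_clip])
        s = banded_marginals(w, n)
        rel = s[mask] / s[mask].mean()
        delta = np.abs(rel - 1.0).max()
        upd = np.ones(n)
        upd[mask] = rel
        b = b * upd
        if delta < tol:
            converged = True
            break

    b = b / b[mask].mean()
    bias = BiasVector(np.where(mask, b, np.nan), mask)

    norm = np.where(pair_ok, counts / (b[:, None] * b[jj_clip]), 0.0)
    normalized = FrequencyMatrix(o.chrom, o.bin_size, n, o.max_distance_bins, norm)
    return IceResult(bias, normalized, converged, it)
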