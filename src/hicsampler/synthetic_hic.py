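"""Synthetic Hi-C generator: ground-truth frequencies and Poisson counts.

The generator produces the minimal structure the model exploits: a
power-law distance decay, multiplicative TAD blocks (sharp boundaries),
focal Gaussian loop enrichments, and a log-normal per-bin bias vector.
Counts are then drawn independently as Pois(b_i * b_j * t_ij), the
observation model of the sampler, with t scaled so the expected total
count in the band equals the requested sequencing depth.

The default parameters define the standard study fixture: a 200-bin
map (1 Mb at 5 kb resolution) with 3 TADs, 2 loops and 5e5 expected
read pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np

from .contact_io import BiasVector, ContactMap, FrequencyMatrix

__all__ = ["SyntheticParams", "SyntheticTruth", "make_truth", "simulate_counts",
           "default_params"]


@dataclass(frozen=True)
class SyntheticParams:
    """Fully determines a synthetic truth given the seed."""

    n_bins: int = 200
    bin_size: int = 5_000
    max_distance_bins: int = 1_000
    decay_exponent: float = 1.0
    tad_boundaries: tuple = (70, 135)      # bin indices -> 3 TADs
    tad_enrichment: float = 3.0
    loop_positions: tuple = ((30, 60, 4.0), (150, 185, 4.0))  # (i, j, fold)
    loop_width: float = 2.0                # bins, Gaussian bump sd
    bias_lognormal_sd: float = 0.3
    depth: float = 5e5                     # expected total band counts
    seed: int = 0
    chrom: str = "chrSim"


def default_params(**overrides) -> SyntheticParams:
    return replace(SyntheticParams(), **overrides)


@dataclass
class SyntheticTruth:
    t_true: FrequencyMatrix
    bias_true: BiasVector
    params: SyntheticParams = field(repr=False)


def _tad_labels(n_bins: int, boundaries) -> np.ndarray:
    lab = np.zeros(n_bins, dtype=np.int64)
    for b in boundaries:
        lab[b:] += 1
    return lab


def make_truth(params: SyntheticParams | None = None, **overrides) -> SyntheticTruth:
    """Build the ground-truth frequency matrix and bias vector.

    t(i, j) = c * (1 + d)^(-decay_exponent) * tad_factor * loop_factor,
    scaled so that the expected total band count at the stated bias
    equals ``depth``.
    """
    params = replace(params or SyntheticParams(), **overrides)
    n = params.n_bins
    if n < 50:
        raise ValueError("n_bins must be >= 50")
    bounds = sorted(params.tad_boundaries)
    if bounds and (bounds[0] <= 0 or bounds[-1] >= n):
        raise ValueError("TAD boundaries out of range")
    W = min(params.max_distance_bins, n - 1)

    ii = np.arange(n)[:, None] + np.zeros(W + 1, dtype=np.int64)[None, :]
    dd = np.zeros((n, 1), dtype=np.int64) + np.arange(W + 1)[None, :]
    jj = ii + dd
    valid = jj < n
    jj_c = np.minimum(jj, n - 1)

    t = (1.0 + dd) ** (-params.decay_exponent)

    lab = _tad_labels(n, bounds)
    t *= np.where(lab[ii] == lab[jj_c], params.tad_enrichment, 1.0)

    for (li, lj, fold) in params.loop_positions:
        li, lj = min(li, lj), max(li, lj)
        if not (0 <= li <= lj < n) or (lj - li) > W:
            raise ValueError(f"loop anchor ({li}, {lj}) out of band")
        bump = np.exp(-((ii - li) ** 2 + (jj_c - lj) ** 2)
                      / (2.0 * params.loop_width ** 2))
        t *= 1.0 + (fold - 1.0) * bump

    t[~valid] = 0.0

    rng = np.random.default_rng(params.seed)
    if params.bias_lognormal_sd > 0:
        b = rng.lognormal(0.0, params.bias_lognormal_sd, size=n)
        b /= b.mean()
    else:
        b = np.ones(n)

    expected = (b[:, None] * b[jj_c] * t)[valid].sum()
    t *= params.depth / expected

    t_true = FrequencyMatrix(params.chrom, params.bin_size, n, W, t)
    bias = BiasVector(b, np.ones(n, dtype=bool))
    return SyntheticTruth(t_true=t_true, bias_true=bias, params=params)


def simulate_counts(truth: SyntheticTruth, depth: float | None = None,
                    seed: int = 0) -> ContactMap:
    """Draw o_ij ~ Pois(b_i * b_j * t_ij) independently over the band.

    If ``depth`` differs from the truth's depth, t is rescaled so the
    expected total equals ``depth`` (the stored truth is unchanged).
    """
    params = truth.params
    t = truth.t_true.data
    if depth is not None:
        if depth <= 0:
            raise ValueError("depth must be positive")
        t = t * (depth / params.depth)
    n = truth.t_true.n_bins
    W = truth.t_true.max_distance_bins
    b = truth.bias_true.values
    jj = np.minimum(np.arange(n)[:, None] + np.arange(W + 1)[None, :], n - 1)
    lam = b[:, None] * b[jj] * t
    rng = np.random.default_rng(seed)
    counts = rng.poisson(lam).astype(np.int64)
    counts[~truth.t_true.band_mask] = 0
    return ContactMap(params.chrom, params.bin_size, n, W, counts)


def params_dict(params: SyntheticParams) -> dict:
    return asdict(params)
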