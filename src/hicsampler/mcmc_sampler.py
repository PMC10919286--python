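"""Adaptive Metropolis–Hastings-within-Gibbs sampling of the frequency matrix.

Each unmasked in-band pixel holds a latent log frequency u = log t.  One
sweep proposes a Gaussian step in u at every pixel and accepts with the
MH ratio of the pixel's full conditional (Poisson likelihood x MRF
potentials) including the +u change-of-variable term.  Proposal scales
are tuned per pixel during burn-in toward the 0.234 optimal acceptance
rate with a diminishing (1/sqrt(round)) gain, then frozen.

Burn-in length is decided by a two-chain rule: two independently
initialized chains are thinned every ``thin`` sweeps and mixing is
declared once the mean inter-chain RMSE and the mean intra-chain RMSE
over the last 10 thinned draws agree within ``rmse_tolerance``.

Sweeps are organized in a four-phase checkerboard schedule: pixels whose
(row, column) parities match are never second-order neighbours (even
after reflection at the diagonal), so all pixels of one phase are
conditionally independent and can be updated in any order — tiles within
a phase are exchangeable, which makes parallel execution equivalent to a
sequential scan.  Per-pixel random numbers are drawn once per sweep, so
the chain is reproducible under any tile order.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass, field, asdict
from typing import NamedTuple

import numpy as np

from ._kernels import mh_tile, single_pixel_chain
from .contact_io import BiasVector, ContactMap, FrequencyMatrix
from .distance_decay import DecayModel
from .mrf_model import MRFSpec, neighbors

__all__ = [
    "SamplerConfig",
    "ChainState",
    "PosteriorSamples",
    "Problem",
    "build_problem",
    "make_plan",
    "sweep",
    "mh_update",
    "adapt_proposals",
    "assess_mixing",
    "run",
    "summarize",
    "sample_pixel_marginal",
]

_VARIANT_CODE = {"uniform": 0, "gaussian_local_only": 1, "full": 2,
                 "fixed_sigma": 2}


@dataclass
class SamplerConfig:
    """Tunable parameters of the sampler (defaults are the study settings)."""

    n_chains: int = 2
    thin: int = 50                 # k: sweeps between collected draws
    min_mixing_draws: int = 10     # K >= 10 k before mixing can be declared
    rmse_tolerance: float = 0.10
    adapt_interval: int = 10       # sweeps between proposal adaptations
    target_accept: float = 0.234
    adapt_gain: float = 1.0        # initial Robbins–Monro gain, decays as 1/round
    n_samples: int = 500
    max_sweeps: int = 10_000
    tile_size: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if not 0 < self.target_accept < 1:
            raise ValueError("target_accept must be in (0, 1)")
        if self.n_chains < 2:
            raise ValueError("mixing diagnosis requires >= 2 chains")


@dataclass
class Problem:
    """Flattened per-pixel arrays the kernels operate on."""

    chrom: str
    bin_size: int
    n_bins: int
    max_distance_bins: int
    pixel_i: np.ndarray        # (P,)
    pixel_d: np.ndarray        # (P,)
    o: np.ndarray              # (P,) observed counts
    bpair: np.ndarray          # (P,) b_i * b_j
    logg: np.ndarray           # (P,) log decay expectation
    inv2om: np.ndarray         # (P,) 1 / (2 omega^2)
    nbr: np.ndarray            # (P, 8) neighbour pixel index, -1 padded
    nbr_inv2var: np.ndarray    # (P, 8) 1 / (2 edge variance)
    nbr_n: np.ndarray          # (P,) neighbour count
    color: np.ndarray          # (P,) checkerboard phase 0..3
    variant_code: int
    variant: str

    @property
    def n_pixels(self) -> int:
        return self.pixel_i.size

    def to_matrix(self, values: np.ndarray) -> FrequencyMatrix:
        data = np.zeros((self.n_bins, self.max_distance_bins + 1))
        data[self.pixel_i, self.pixel_d] = values
        return FrequencyMatrix(self.chrom, self.bin_size, self.n_bins,
                               self.max_distance_bins, data)


def build_problem(o: ContactMap, bias: BiasVector, decay: DecayModel,
                  spec: MRFSpec) -> Problem:
    """Assemble the flat pixel arrays for a sampling run."""
    n, W = o.n_bins, o.max_distance_bins
    max_d = min(W, n - 1, decay.max_distance_bins)
    ii, dd = np.nonzero(o.band_mask)
    keep = bias.mask[ii] & bias.mask[ii + dd] & (dd <= max_d)
    ii, dd = ii[keep], dd[keep]
    P = ii.size

    index = np.full((n, W + 1), -1, dtype=np.int64)
    index[ii, dd] = np.arange(P)

    g_by_d = decay.predict(np.arange(max_d + 1))
    logg = np.log(g_by_d)[dd]
    om2 = np.maximum(spec.omega2[dd], spec.variance_floor)
    inv2om = 1.0 / (2.0 * om2)
    sg2 = np.maximum(spec.sigma2[ii, dd], spec.variance_floor)

    nbr = np.full((P, 8), -1, dtype=np.int64)
    nbr_var = np.zeros((P, 8))
    nbr_n = np.zeros(P, dtype=np.int64)
    pairwise = spec.variant in ("full", "fixed_sigma")
    if pairwise:
        for p in range(P):
            i, j = int(ii[p]), int(ii[p] + dd[p])
            cnt = 0
            for (a, bcol) in neighbors(i, j, n, W):
                q = index[a, bcol - a]
                if q < 0 or spec.is_pruned((i, j), (a, bcol)):
                    continue
                nbr[p, cnt] = q
                if spec.variant == "fixed_sigma":
                    nbr_var[p, cnt] = spec.sigma2_fixed
                else:
                    nbr_var[p, cnt] = max(sg2[p], sg2[q])
                cnt += 1
            nbr_n[p] = cnt
    with np.errstate(divide="ignore"):
        nbr_inv2var = np.where(nbr_var > 0, 1.0 / (2.0 * nbr_var), 0.0)

    return Problem(
        chrom=o.chrom, bin_size=o.bin_size, n_bins=n, max_distance_bins=W,
        pixel_i=ii, pixel_d=dd, o=o.data[ii, dd].astype(np.float64),
        bpair=bias.values[ii] * bias.values[ii + dd], logg=logg,
        inv2om=inv2om, nbr=nbr, nbr_inv2var=nbr_inv2var, nbr_n=nbr_n,
        color=(2 * (ii % 2) + (ii + dd) % 2).astype(np.int64),
        variant_code=_VARIANT_CODE[spec.variant], variant=spec.variant)


def make_plan(problem: Problem, tile_size: int = 200) -> list:
    """Four checkerboard phases, each split into row-block tiles.

    Within a phase no two pixels are in each other's Markov blanket, so
    tiles may be processed in any order (or concurrently).
    """
    plan = []
    for c in range(4):
        pix = np.nonzero(problem.color == c)[0]
        blocks = problem.pixel_i[pix] // max(tile_size, 1)
        phase = [pix[blocks == bl] for bl in np.unique(blocks)]
        plan.append(phase)
    _validate_plan(problem, plan)
    return plan


def _validate_plan(problem: Problem, plan: list) -> None:
    covered = np.zeros(problem.n_pixels, dtype=np.int64)
    for phase in plan:
        members = np.concatenate(phase) if phase else np.empty(0, np.int64)
        in_phase = np.zeros(problem.n_pixels, dtype=bool)
        in_phase[members] = True
        covered[members] += 1
        for p in members:
            for m in range(problem.nbr_n[p]):
                if in_phase[problem.nbr[p, m]]:
                    raise ValueError(
                        "invalid schedule: concurrent pixels share a blanket")
    if not np.all(covered == 1):
        raise ValueError("schedule must cover every pixel exactly once")


@dataclass
class ChainState:
    """Mutable state of one chain (u = log t per pixel)."""

    u: np.ndarray
    proposal_sd: np.ndarray
    accept_count: np.ndarray
    propose_count: np.ndarray
    rng: np.random.Generator
    sweep_index: int = 0
    frozen: bool = False
    adapt_round: int = 0

    @property
    def t(self) -> np.ndarray:
        return np.exp(self.u)


def init_chain(problem: Problem, seed) -> ChainState:
    """Initialize t ~ Uniform(0, 1) i.i.d. per pixel."""
    rng = np.random.default_rng(seed)
    u = np.log(rng.random(problem.n_pixels))
    return ChainState(u=u, proposal_sd=np.ones(problem.n_pixels),
                      accept_count=np.zeros(problem.n_pixels, np.int64),
                      propose_count=np.zeros(problem.n_pixels, np.int64),
                      rng=rng)


def sweep(state: ChainState, problem: Problem, plan: list) -> ChainState:
    """Update every pixel exactly once (in checkerboard phase order)."""
    P = problem.n_pixels
    z = state.rng.standard_normal(P)
    logru = np.log(state.rng.random(P))
    for phase in plan:
        for tile in phase:
            mh_tile(tile, state.u, state.proposal_sd, state.accept_count,
                    state.propose_count, problem.o, problem.bpair,
                    problem.logg, problem.inv2om, problem.nbr,
                    problem.nbr_inv2var, problem.nbr_n,
                    problem.variant_code, z, logru)
    state.sweep_index += 1
    return state


def mh_update(pixel: int, state: ChainState, problem: Problem) -> bool:
    """Single-pixel MH update (reference-path twin of the kernel).

    Returns True if the proposal was accepted.  Non-finite conditionals
    indicate upstream corruption and abort.
    """
    p = int(pixel)
    u0 = state.u[p]
    z = state.rng.standard_normal()
    u1 = u0 + state.proposal_sd[p] * z
    dl = (problem.o[p] + 1.0) * (u1 - u0) \
        - problem.bpair[p] * (np.exp(u1) - np.exp(u0))
    if problem.variant_code >= 1:
        dl -= ((u1 - problem.logg[p]) ** 2
               - (u0 - problem.logg[p]) ** 2) * problem.inv2om[p]
    if problem.variant_code >= 2:
        for m in range(problem.nbr_n[p]):
            uq = state.u[problem.nbr[p, m]]
            dl -= ((u1 - uq) ** 2 - (u0 - uq) ** 2) * problem.nbr_inv2var[p, m]
    if not np.isfinite(dl):
        raise FloatingPointError(
            f"non-finite conditional at pixel index {p} "
            f"(i={problem.pixel_i[p]}, d={problem.pixel_d[p]})")
    state.propose_count[p] += 1
    accepted = np.log(state.rng.random()) < dl
    if accepted:
        state.u[p] = u1
        state.accept_count[p] += 1
    return bool(accepted)


def adapt_proposals(state: ChainState, target_accept: float = 0.234,
                    gain: float = 1.0) -> ChainState:
    """Rescale per-pixel proposal sd toward the target acceptance rate.

    The log-sd moves by ``gain / sqrt(round) * (rate - target)`` — a
    diminishing Robbins–Monro schedule that still tracks the setpoint
    late in burn-in; ergodicity is guaranteed regardless because the
    scales are frozen once burn-in ends, after which the call is a no-op.
    """
    if state.frozen:
        return state
    state.adapt_round += 1
    step = gain / np.sqrt(state.adapt_round)
    seen = state.propose_count > 0
    rate = np.where(seen, state.accept_count / np.maximum(state.propose_count, 1),
                    target_accept)
    state.proposal_sd *= np.exp(step * (rate - target_accept))
    state.accept_count[:] = 0
    state.propose_count[:] = 0
    return state


class MixingCheck(NamedTuple):
    assessable: bool
    mixed: bool
    inter: float
    intra: float


def _rmse(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean((a - b) ** 2)))


def assess_mixing(draws_a, draws_b, tol: float = 0.10,
                  min_draws: int = 10) -> MixingCheck:
    """Two-chain mixing rule on thinned draws (t scale).

    Over the last ``min_draws`` draws: the inter-chain RMSE averages the
    same-index pairs across chains; the intra-chain RMSE averages the
    consecutive-pair RMSEs within each chain.  Mixing is declared when
    |inter - intra| / intra <= tol.
    """
    if len(draws_a) < min_draws or len(draws_b) < min_draws:
        return MixingCheck(False, False, np.nan, np.nan)
    A = list(draws_a)[-min_draws:]
    B = list(draws_b)[-min_draws:]
    inter = float(np.mean([_rmse(a, b) for a, b in zip(A, B)]))
    intra_vals = [_rmse(c[s], c[s + 1]) for c in (A, B)
                  for s in range(min_draws - 1)]
    intra = float(np.mean(intra_vals))
    if intra == 0.0:
        return MixingCheck(True, inter == 0.0, inter, intra)
    return MixingCheck(True, abs(inter - intra) / intra <= tol, inter, intra)


@dataclass
class PosteriorSamples:
    """Thinned posterior draws of the frequency matrix plus summaries."""

    samples: np.ndarray            # (S, P)
    pixel_i: np.ndarray
    pixel_d: np.ndarray
    chrom: str
    bin_size: int
    n_bins: int
    max_distance_bins: int
    mean: np.ndarray | None = None
    variance: np.ndarray | None = None
    dispersion: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_pixels(self) -> int:
        return self.pixel_i.size

    def _to_matrix(self, values: np.ndarray) -> FrequencyMatrix:
        data = np.zeros((self.n_bins, self.max_distance_bins + 1))
        data[self.pixel_i, self.pixel_d] = values
        return FrequencyMatrix(self.chrom, self.bin_size, self.n_bins,
                               self.max_distance_bins, data)

    def sample_matrix(self, s: int) -> FrequencyMatrix:
        return self._to_matrix(self.samples[s])

    def mean_matrix(self) -> FrequencyMatrix:
        return self._to_matrix(self.mean)

    def variance_matrix(self) -> FrequencyMatrix:
        return self._to_matrix(self.variance)

    def dispersion_matrix(self) -> FrequencyMatrix:
        return self._to_matrix(self.dispersion)


def summarize(samples: np.ndarray):
    """Element-wise mean, variance and dispersion index of the draws."""
    samples = np.asarray(samples)
    if samples.ndim != 2 or samples.shape[0] < 2:
        raise ValueError("summaries require at least 2 samples")
    mean = samples.mean(axis=0)
    variance = samples.var(axis=0, ddof=1)
    dispersion = np.where(mean > 0, variance / np.where(mean > 0, mean, 1.0), 0.0)
    return mean, variance, dispersion


def run(o: ContactMap, bias: BiasVector, decay: DecayModel, spec: MRFSpec,
        config: SamplerConfig | None = None) -> PosteriorSamples:
    """Full sampling run: burn-in to mixing, freeze, collect, summarize.

    Two chains are burned in together; after the mixing rule fires the
    proposal scales are frozen and ``n_samples`` thinned draws are
    collected from chain A (chain B only serves the diagnosis).
    """
    config = config or SamplerConfig()
    problem = build_problem(o, bias, decay, spec)
    plan = make_plan(problem, config.tile_size)
    ss = np.random.SeedSequence(config.seed)
    chains = [init_chain(problem, s) for s in ss.spawn(config.n_chains)]

    k = config.thin
    buffers = [deque(maxlen=config.min_mixing_draws) for _ in chains]
    history = []
    mixed = False
    burn_in_sweep = config.max_sweeps
    s = 0
    while s < config.max_sweeps:
        s += 1
        for c in chains:
            sweep(c, problem, plan)
        if s % config.adapt_interval == 0:
            for c in chains:
                adapt_proposals(c, config.target_accept, config.adapt_gain)
        if s % k == 0:
            for c, buf in zip(chains, buffers):
                buf.append(c.t)
            check = assess_mixing(buffers[0], buffers[1],
                                  config.rmse_tolerance,
                                  config.min_mixing_draws)
            if check.assessable:
                history.append({"sweep": s, "inter": check.inter,
                                "intra": check.intra, "mixed": check.mixed})
                if check.mixed:
                    mixed = True
                    burn_in_sweep = s
                    break
    if not mixed:
        warnings.warn(
            f"mixing not achieved within {config.max_sweeps} sweeps; "
            "returning samples anyway")
        burn_in_sweep = s

    for c in chains:
        c.frozen = True
        c.accept_count[:] = 0
        c.propose_count[:] = 0

    main = chains[0]
    draws = np.empty((config.n_samples, problem.n_pixels))
    for idx in range(config.n_samples):
        for _ in range(k):
            sweep(main, problem, plan)
        draws[idx] = main.t

    total_prop = int(main.propose_count.sum())
    accept_rate = (main.accept_count.sum() / total_prop) if total_prop else np.nan

    mean = variance = dispersion = None
    if config.n_samples >= 2:
        mean, variance, dispersion = summarize(draws)

    provenance = {
        "config": asdict(config),
        "variant": problem.variant,
        "n_pixels": problem.n_pixels,
        "burn_in_sweep": int(burn_in_sweep),
        "mixed": bool(mixed),
        "post_freeze_accept_rate": float(accept_rate),
        "post_freeze_sweeps": config.n_samples * k,
        "mixing_history": history,
    }
    return PosteriorSamples(
        samples=draws, pixel_i=problem.pixel_i, pixel_d=problem.pixel_d,
        chrom=problem.chrom, bin_size=problem.bin_size, n_bins=problem.n_bins,
        max_distance_bins=problem.max_distance_bins, mean=mean,
        variance=variance, dispersion=dispersion, provenance=provenance)


def sample_pixel_marginal(o_ij: float, b_ij: float, g_ij: float,
                          omega2: float, neighbor_t=(), sigma2_edges=(),
                          variant: str = "full", n_draws: int = 50_000,
                          thin: int = 10, seed: int = 0):
    """Adaptive MH chain for one pixel with its neighbours held fixed.

    Returns (t draws, proposal sd, acceptance rate).  This is the
    single-site sampler used to cross-check the MCMC marginal against
    numerical quadrature of the full conditional.
    """
    nbr_u = np.log(np.asarray(neighbor_t, dtype=float)) \
        if len(neighbor_t) else np.empty(0)
    s2 = np.asarray(sigma2_edges, dtype=float)
    inv2v = 1.0 / (2.0 * s2) if s2.size else np.empty(0)
    draws_u, sd, rate = single_pixel_chain(
        float(o_ij), float(b_ij), float(np.log(g_ij)),
        1.0 / (2.0 * omega2), nbr_u, inv2v, _VARIANT_CODE[variant],
        int(n_draws), int(thin), 50, 100, 0.234, int(seed) % (2 ** 31))
    return np.exp(draws_u), sd, rate
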