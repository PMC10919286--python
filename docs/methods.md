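# Methods

## Observation model and prior

Each intra-chromosomal contact count is modelled as
`o_ij ~ Pois(b_i b_j t_ij)`, where `b` is a per-bin multiplicative
visibility bias and `t_ij > 0` the latent relative interaction
frequency. Inference is per chromosome, restricted to the band
`|i - j| <= max_distance` (default 5 Mb) — beyond a few megabases
counts are too sparse to inform the smoothing prior and the cost of a
full matrix is quadratic. The bias is estimated first (ICE) and held
fixed during sampling; a two-phase design keeps the sampler compatible
with biases produced by any external normalization.

The prior over `t` is a pairwise Markov random field on the banded
upper triangle with a second-order (8-neighbour) system, reflected at
the diagonal. Potentials are Gaussian kernels on the log scale:

* local: `-(log t_ij - log g(d))^2 / (2 w2(d))`, pulling toward the
  fitted distance decay `g`;
* pairwise: `-(log t_ij - log t_i'j')^2 / (2 s2_edge)`, with
  `s2_edge = max(s2_ij, s2_i'j')` so that the edge term is symmetric
  in its two pixels.

Both log-scale Gaussians are proper; a non-negative exponent would make
the prior improper, so the kernels are the only coherent reading of the
model. All variances are floored at `variance_floor = 1e-4`
(log-scale), which prevents degenerate zero-variance strata from
producing infinite precision.

### Empirical-Bayes hyperparameters

`w2(d)` is the sample variance of log ICE-normalized values in the
distance-`d` stratum (positive, unmasked pixels only). Strata with
fewer than 3 usable pixels borrow the nearest populated stratum;
structurally empty strata (`d >= n_bins`) do so silently. `s2_ij` is
the variance of first-order-adjacent log differences inside a
`window x window` square centred on the pixel (default 17, odd,
clipped to the valid band). The variances are computed on the log
scale because the potentials penalize log differences; raw-scale
variances would not be comparable with the exponent's denominator.

### Boundary-aware pruning

For every pair of vertically (and horizontally) adjacent pixels, the
`flank`-wide strips on either side of the candidate transition are
compared with a two-sample Kolmogorov–Smirnov test (asymptotic
p-value); the edge is removed from both Markov blankets when
`p < alpha` (defaults `alpha = 0.01`, `flank = 8`, i.e. half the
17-window). Strips are z-scored per distance stratum first: both the
decay trend and the count-noise variance change systematically with
distance, and without standardization every strip pair differs and the
test prunes indiscriminately. On homogeneous log-normal fields the
measured pruning rate matches `alpha`; in a two-block simulation with
a 4-SD jump every boundary-crossing edge is pruned. Edges with fewer
than `flank` usable values per side are kept (conservative), and
`alpha = 0` disables pruning. Diagonal-step neighbours are never
pruned — only sharp horizontal/vertical transitions mark domain
boundaries.

### Distance decay

`ln g(d) = w0 + B(d)` is fitted as a Poisson GLM (statsmodels IRLS,
maxiter 100, tol 1e-8) with offset `ln(b_i b_j)` on a random 10%
subsample of in-band pixels (uniform, without replacement, seeded;
zero-count pixels included — they carry information under a Poisson
likelihood). `B` is a clamped cubic B-spline whose five knots sit at
0/25/50/75/100% of the maximum analysis distance; the basis is
evaluated on a `log(1 + d)` axis, where power-law-like decays are
nearly linear — on the raw distance axis five knots cannot track the
steep curvature near `d = 0` (the fitted log-curve would miss a known
smooth decay by several tenths, versus < 0.1 RMSE on the log axis).
The first basis column is dropped in favour of an explicit intercept
(the clamped basis sums to one). Rank-deficient designs (e.g. all
sampled pixels at one distance) raise immediately.

## Sampling

The sampler is Metropolis–Hastings-within-Gibbs on `u = log t`.
Working in `u` avoids rejected negative proposals; the acceptance
ratio carries the `+u` change-of-variable term. Chains are initialized
`t ~ Uniform(0, 1)` i.i.d. per pixel. One *sweep* updates every
unmasked in-band pixel exactly once.

**Schedule.** Pixels are partitioned into four checkerboard phases by
the parity of (row, column); two pixels of the same phase are never in
each other's Markov blanket (including reflection at the diagonal), so
all updates within a phase are conditionally independent. Per-pixel
proposal and acceptance randoms are drawn once per sweep before any
update, so the chain is invariant to the processing order of tiles
within a phase — parallel execution is exactly equivalent to a
sequential scan, and runs are bit-reproducible for a given seed.
`tile_size` (default 200 rows) controls the work-unit granularity.

**Adaptation.** Per-pixel proposal scales start at 1 and are updated
every `adapt_interval = 10` sweeps by
`sd *= exp(gain/sqrt(r) * (rate - 0.234))`, `r` the adaptation round.
The square-root decay still diminishes but keeps enough late gain to
settle near the 0.234 setpoint before freezing (a `1/r` schedule
under-corrects the early transient and freezes around 0.19);
ergodicity is unaffected either way because adaptation stops entirely
at the end of burn-in. Acceptance targets are per pixel; the band-wide
mean is what is reported.

**Burn-in / mixing.** Two chains are thinned every `k = 50` sweeps.
After at least 10 collected draws, mixing is declared when
`|inter - intra| / intra <= 0.10`, where *inter* averages the RMSE of
same-index draw pairs across chains and *intra* averages the RMSE of
consecutive draws within each chain (both over the last 10 draws, in
t-space, over unmasked in-band pixels). Note the rule requires `k`
large enough that consecutive thinned draws are nearly independent;
with aggressive thinning (`k <= 5`) the intra term stays deflated by
autocorrelation and the rule may never fire. Identical chains have
inter = 0 and are therefore *not* declared mixed — the rule tests
agreement of two *independent* chains, not equality. If the rule never
fires within `max_sweeps` (default 10,000) the run returns with
`mixed=False` and a warning rather than failing.

After mixing, proposals freeze and `n_samples` draws are collected
every `k` sweeps from chain A only (chain B exists for the diagnosis;
pooling chains would mix two autocorrelation structures in the output).
Summaries are element-wise mean, sample variance (ddof 1) and
dispersion index variance/mean (0 where the mean is 0).

## Diagnostics

* **Posterior predictive check**: the predictive CDF at a pixel is the
  draw-average of Poisson CDFs at rate `b_ij t_ij^(s)`; the p-value is
  drawn uniformly between `CDF(o-1)` and `CDF(o)`. Randomization makes
  the null distribution exactly uniform for discrete counts, so the
  one-sample KS statistic is directly interpretable.
* **Held-out log-likelihood**: the mean over the first 100 posterior
  draws of the Poisson log-likelihood of an independent test map
  (train and test are independent binomial thinnings of one deep map).
  "Mean of log-likelihoods" is deliberate — not log-mean-likelihood.
* **KL versus sample count**: per-pixel marginals are histogrammed on
  30 shared log-scale bins spanning the gold draw range with add-one
  smoothing; subsets are prefixes of the gold sequence, and
  `KL(subset || gold)` is averaged over pixels.

## Synthetic generator

`t(i,j) = c (1+d)^(-a) * tad * loop` with multiplicative TAD blocks
(sharp boundaries, fold 3), Gaussian loop bumps (sd 2 bins, fold 4),
log-normal bias (sd 0.3), scaled so the expected band total equals the
requested depth; counts are independent Poisson draws. The default
fixture — 200 bins of 5 kb (1 Mb), 3 TADs, 2 loops, depth 5e5 — is the
condition under which the sampler metrics are measured; at that depth
the mean pixel count is ~25, comparable to a deep experiment at 5 kb.
The generator reproduces exactly the features the prior exploits
(decay, block structure, smoothness, focal peaks, multiplicative bias)
and nothing else: no fragment-level effects, no mappability holes, no
translocations, no over-dispersion beyond Poisson. Passing tests
demonstrate correctness of the inference under the stated model, not
robustness to real-data artefacts such as copy-number variation or
unbalanced coverage.

## Problem sizes used by the test suite

Chosen so the whole suite runs in minutes on one CPU: the fixture run
uses two chains and 10 thinned draws (500 post-freeze sweeps — the
window over which the frozen acceptance rate is measured); calibration
uses a 150-bin matched-generator map (>1e4 pixels, 300 draws at
k = 50); model ranking uses 100 draws per variant at thin 10; the KL
curve uses a 60-bin map with 5,000 gold draws at thin 5. Single-pixel
marginals are validated against 20,001-point grid quadrature with
5e4 thinned draws.

## Known limitations

* The empirical-Bayes variances are estimated from the same map that
  is then sampled; with very shallow maps they are noisy and the
  normal-theory KS pruning becomes conservative.
* The banded dense storage is simple and fast at desk scale but costs
  `n_bins * (W+1)` doubles regardless of sparsity.
* ICE here balances the banded matrix as loaded; biases estimated from
  a genome-wide map can be supplied through `read_bias` instead and
  are generally preferable for real data.
* Per-pixel adaptive scales target the acceptance rate under the
  burn-in trajectory; the frozen band-wide mean typically lands within
  a point or two of the 0.234 setpoint rather than exactly on it.
* The mixing rule compares only two chains and first-order RMSE; it is
  a practical stopping heuristic, not a convergence proof.
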