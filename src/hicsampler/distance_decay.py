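"""Distance-decay model: Poisson regression with a B-spline in distance.

The expected normalized interaction frequency at genomic distance
``d = |i - j|`` (in bins) is modelled on the log scale as

    ln g(d) = w0 + B(d)

where ``B`` is a cubic B-spline with knots at the distances 0%, 25%,
50%, 75% and 100% of the maximum analysis distance, evaluated on a
log(1 + d) axis so that power-law-like decays are captured smoothly.  The model is fitted by maximum
likelihood on the observed counts with a Poisson log-link GLM and offset
``ln(b_i * b_j)``, so the spline describes the bias-corrected decay.
Training uses a random subsample of in-band pixels (default 10%),
zero-count pixels included — they are informative under a Poisson model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy.interpolate import BSpline

from .contact_io import BiasVector, ContactMap

__all__ = ["DecayModel", "fit_decay", "decay_knots"]

_DEGREE = 3


def decay_knots(max_distance_bins: int) -> np.ndarray:
    """Knot positions at 0/25/50/75/100% of the maximum distance."""
    return np.round(max_distance_bins * np.array([0.0, 0.25, 0.5, 0.75, 1.0]))


def _knot_vector(knots: np.ndarray, degree: int) -> np.ndarray:
    return np.concatenate([np.repeat(knots[0], degree),
                           knots,
                           np.repeat(knots[-1], degree)])


def _basis(d: np.ndarray, knots: np.ndarray, degree: int) -> np.ndarray:
    # knots are genomic distances; the spline is evaluated on log(1 + d),
    # where power-law-like decays are nearly linear — on the raw distance
    # axis a handful of knots cannot track the steep small-d curvature
    t = _knot_vector(np.log1p(knots), degree)
    x = np.log1p(np.clip(np.asarray(d, dtype=float), knots[0], knots[-1]))
    # clamp the right end inside the half-open support of the last basis fn
    hi = np.log1p(knots[-1])
    x = np.nextafter(x, -np.inf, where=x >= hi, out=x.copy())
    full = BSpline.design_matrix(x, t, degree).toarray()
    # the clamped basis sums to one, so drop the first column and carry an
    # explicit intercept instead
    return full[:, 1:]


@dataclass
class DecayModel:
    """Fitted log-linear decay curve g(d) = exp(w0 + B(d))."""

    w0: float
    spline_coeffs: np.ndarray
    knots: np.ndarray  # the 5 knot positions, in bins
    degree: int
    max_distance_bins: int

    def predict(self, d) -> np.ndarray:
        """Expected normalized frequency g at distance ``d`` (bins)."""
        d_arr = np.atleast_1d(np.asarray(d, dtype=float))
        if np.any(d_arr < 0) or np.any(d_arr > self.max_distance_bins):
            raise ValueError(
                f"distance out of fitted domain [0, {self.max_distance_bins}]")
        eta = self.w0 + _basis(d_arr, self.knots, self.degree) @ self.spline_coeffs
        g = np.exp(eta)
        return g if np.ndim(d) else float(g[0])

    def to_json(self, path=None) -> str:
        payload = json.dumps({
            "w0": self.w0,
            "spline_coeffs": list(self.spline_coeffs),
            "knots": list(self.knots),
            "degree": self.degree,
            "max_distance_bins": self.max_distance_bins,
        }, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload

    @classmethod
    def from_json(cls, src) -> "DecayModel":
        if isinstance(src, (str, bytes)) and str(src).lstrip().startswith("{"):
            obj = json.loads(src)
        else:
            with open(src) as fh:
                obj = json.load(fh)
        return cls(w0=float(obj["w0"]),
                   spline_coeffs=np.asarray(obj["spline_coeffs"], dtype=float),
                   knots=np.asarray(obj["knots"], dtype=float),
                   degree=int(obj["degree"]),
                   max_distance_bins=int(obj["max_distance_bins"]))


def fit_decay(o: ContactMap, b: BiasVector, sample_frac: float = 0.10,
              seed: int = 0, max_iter: int = 100, tol: float = 1e-8) -> DecayModel:
    """Fit the decay GLM on a random subsample of in-band pixels.

    Pixels with either bin masked are excluded.  Sampling is uniform
    without replacement over the remaining pixels (zero counts kept).
    """
    if not (0 < sample_frac <= 1):
        raise ValueError("sample_frac must be in (0, 1]")
    if b.n_bins != o.n_bins:
        raise ValueError("bias / contact map bin count mismatch")
    n = o.n_bins
    max_d = min(o.max_distance_bins, n - 1)

    ii, dd = np.nonzero(o.band_mask)
    jj = ii + dd
    ok = b.mask[ii] & b.mask[jj] & (dd <= max_d)
    ii, jj, dd = ii[ok], jj[ok], dd[ok]

    rng = np.random.default_rng(seed)
    m = max(1, int(round(sample_frac * ii.size)))
    pick = rng.choice(ii.size, size=m, replace=False) if m < ii.size \
        else np.arange(ii.size)
    ii, jj, dd = ii[pick], jj[pick], dd[pick]

    y = o.data[ii, dd].astype(float)
    offset = np.log(b.values[ii] * b.values[jj])
    knots = decay_knots(max_d)
    X = np.column_stack([np.ones(ii.size), _basis(dd, knots, _DEGREE)])

    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            "degenerate design: sampled pixels do not span enough distinct "
            "distances to identify the spline basis")

    model = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset)
    res = model.fit(maxiter=max_iter, tol=tol)
    params = np.asarray(res.params)
    if not np.all(np.isfinite(params)):
        raise ValueError("decay fit produced non-finite coefficients")
    return DecayModel(w0=float(params[0]), spline_coeffs=params[1:],
                      knots=knots, degree=_DEGREE, max_distance_bins=max_d)
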