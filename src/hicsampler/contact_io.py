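"""Sparse banded contact-map containers and plain-text I/O.

Intra-chromosomal Hi-C data at a fixed bin size are held as banded
upper-triangular matrices: entry ``(i, j)`` with ``0 <= i <= j < n_bins``
and ``j - i <= max_distance_bins`` is stored at ``data[i, j - i]``.
Symmetry is implicit (querying ``(j, i)`` returns the ``(i, j)`` value)
and absent entries read as zero.

On disk, matrices are 3-column TSV triples ``(i, j, value)`` in either
``bins`` dialect (0-based bin indices) or ``bp`` dialect (0-based
half-open bin starts in base pairs).  Posterior sample sets are stored in
an HDF5 container with one dataset for the draws plus summary matrices.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ContactMap",
    "FrequencyMatrix",
    "BiasVector",
    "read_contacts",
    "read_frequencies",
    "write_matrix",
    "read_bias",
    "write_bias",
    "write_run",
    "read_run",
]


class ContactIOError(ValueError):
    """Raised when an input file violates the format contract."""


@dataclass
class _Banded:
    """Banded symmetric matrix over fixed-size genomic bins."""

    chrom: str
    bin_size: int
    n_bins: int
    max_distance_bins: int
    data: np.ndarray = field(repr=False)  # (n_bins, max_distance_bins + 1)

    def __post_init__(self) -> None:
        expected = (self.n_bins, self.max_distance_bins + 1)
        if self.data.shape != expected:
            raise ValueError(f"data shape {self.data.shape} != {expected}")

    @property
    def band_mask(self) -> np.ndarray:
        """Boolean (n_bins, W+1) mask of positions inside the matrix."""
        i = np.arange(self.n_bins)[:, None]
        d = np.arange(self.max_distance_bins + 1)[None, :]
        return i + d < self.n_bins

    def get(self, i: int, j: int):
        if i > j:
            i, j = j, i
        d = j - i
        if j >= self.n_bins or i < 0 or d > self.max_distance_bins:
            return self.data.dtype.type(0)
        return self.data[i, d]

    def entries(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Nonzero upper-triangle entries as (i, j, value) arrays."""
        ii, dd = np.nonzero(self.data)
        keep = ii + dd < self.n_bins
        ii, dd = ii[keep], dd[keep]
        return ii, ii + dd, self.data[ii, dd]

    def copy(self):
        return type(self)(self.chrom, self.bin_size, self.n_bins,
                          self.max_distance_bins, self.data.copy())

    def __eq__(self, other) -> bool:  # value equality, used in round-trip tests
        if not isinstance(other, _Banded):
            return NotImplemented
        return (self.chrom == other.chrom
                and self.bin_size == other.bin_size
                and self.n_bins == other.n_bins
                and self.max_distance_bins == other.max_distance_bins
                and np.array_equal(self.data, other.data))


class ContactMap(_Banded):
    """Observed read-count matrix o (non-negative integers)."""

    def total(self) -> int:
        return int(self.data[self.band_mask].sum())


class FrequencyMatrix(_Banded):
    """Real-valued interaction-frequency matrix t (positive in band)."""


@dataclass
class BiasVector:
    """Per-bin multiplicative bias b with a usability mask.

    The pairwise bias is always the outer product ``b[i] * b[j]``; it is
    never materialised densely.  Masked bins (``mask[i] == False``) are
    excluded from every likelihood and potential term.
    """

    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask length mismatch")
        if np.any(~(self.values[self.mask] > 0)):
            raise ValueError("bias must be positive on unmasked bins")

    @property
    def n_bins(self) -> int:
        return self.values.size

    def pair(self, i, j) -> np.ndarray:
        return self.values[i] * self.values[j]

    @classmethod
    def identity(cls, n_bins: int) -> "BiasVector":
        return cls(np.ones(n_bins), np.ones(n_bins, dtype=bool))


def _empty(cls, chrom, bin_size, n_bins, max_distance_bins, dtype):
    data = np.zeros((n_bins, max_distance_bins + 1), dtype=dtype)
    return cls(chrom, bin_size, n_bins, max_distance_bins, data)


def _load_triples(path, bin_size, n_bins, max_distance_bins, dialect):
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["a", "b", "v"], dtype={"a": np.int64, "b": np.int64})
    if len(df) == 0:
        return (np.empty(0, np.int64),) * 2 + (np.empty(0),)
    a = df["a"].to_numpy()
    b = df["b"].to_numpy()
    v = df["v"].to_numpy()
    if dialect == "bp":
        off = (a % bin_size != 0) | (b % bin_size != 0)
        if off.any():
            row = int(np.nonzero(off)[0][0]) + 1
            raise ContactIOError(
                f"row {row}: coordinate not a multiple of bin_size={bin_size}")
        a = a // bin_size
        b = b // bin_size
    elif dialect != "bins":
        raise ContactIOError(f"unknown dialect {dialect!r}")
    i = np.minimum(a, b)
    j = np.maximum(a, b)
    if (i < 0).any() or (j >= n_bins).any():
        row = int(np.nonzero((i < 0) | (j >= n_bins))[0][0]) + 1
        raise ContactIOError(f"row {row}: bin index out of range [0, {n_bins})")
    keep = (j - i) <= max_distance_bins
    return i[keep], j[keep], v[keep]


def _sniff_dialect(path) -> str | None:
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "dialect=" in line:
                return line.split("dialect=")[1].strip()
    return None


def read_contacts(path, bin_size: int, chrom: str, max_distance: int,
                  n_bins: int | None = None, dialect: str = "auto") -> ContactMap:
    """Read a contact map from 3-column TSV triples.

    Entries beyond ``max_distance`` (bp) are dropped, duplicate ``(i, j)``
    rows are summed, and ``(j, i)`` rows are folded onto ``(i, j)``.
    ``dialect`` is ``"bins"``, ``"bp"``, or ``"auto"`` (honour a
    ``# dialect=...`` header, defaulting to ``bins``).
    """
    if dialect == "auto":
        dialect = _sniff_dialect(path) or "bins"
    max_distance_bins = max_distance // bin_size
    if n_bins is None:
        # infer from data: smallest grid containing every entry
        i, j, v = _load_triples(path, bin_size, np.iinfo(np.int64).max,
                                max_distance_bins, dialect)
        n_bins = int(j.max()) + 1 if j.size else 1
    else:
        i, j, v = _load_triples(path, bin_size, n_bins, max_distance_bins, dialect)
    if np.any(v < 0):
        row = int(np.nonzero(v < 0)[0][0]) + 1
        raise ContactIOError(f"row {row}: negative count")
    if np.any(v != np.floor(v)):
        row = int(np.nonzero(v != np.floor(v))[0][0]) + 1
        raise ContactIOError(f"row {row}: non-integer count")
    cm = _empty(ContactMap, chrom, bin_size, n_bins, max_distance_bins, np.int64)
    np.add.at(cm.data, (i, j - i), v.astype(np.int64))
    return cm


def read_frequencies(path, bin_size: int, chrom: str, max_distance: int,
                     n_bins: int | None = None, dialect: str = "auto") -> FrequencyMatrix:
    """Read a real-valued matrix (same conventions as :func:`read_contacts`)."""
    if dialect == "auto":
        dialect = _sniff_dialect(path) or "bins"
    max_distance_bins = max_distance // bin_size
    if n_bins is None:
        i, j, v = _load_triples(path, bin_size, np.iinfo(np.int64).max,
                                max_distance_bins, dialect)
        n_bins = int(j.max()) + 1 if j.size else 1
    else:
        i, j, v = _load_triples(path, bin_size, n_bins, max_distance_bins, dialect)
    fm = _empty(FrequencyMatrix, chrom, bin_size, n_bins, max_distance_bins, float)
    np.add.at(fm.data, (i, j - i), v)
    return fm


def write_matrix(m: _Banded, path, dialect: str = "bins") -> None:
    """Write the upper triangle as TSV triples in deterministic (i, j) order."""
    i, j, v = m.entries()
    order = np.lexsort((j, i))
    i, j, v = i[order], j[order], v[order]
    if dialect == "bp":
        i = i * m.bin_size
        j = j * m.bin_size
    with open(path, "w") as fh:
        fh.write(f"# chrom={m.chrom} bin_size={m.bin_size} n_bins={m.n_bins} "
                 f"max_distance_bins={m.max_distance_bins}\n")
        fh.write(f"# dialect={dialect}\n")
        if np.issubdtype(np.asarray(v).dtype, np.integer):
            for a, b, c in zip(i, j, v):
                fh.write(f"{a}\t{b}\t{c}\n")
        else:
            for a, b, c in zip(i, j, v):
                fh.write(f"{a}\t{b}\t{float(c)!r}\n")


def read_bias(path, n_bins: int) -> BiasVector:
    """Read a per-bin bias vector.

    Accepts one value per line, or two-column ``(bin, value)`` TSV.
    Non-positive or missing values mask the bin.  The file must describe
    exactly ``n_bins`` bins.
    """
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    if df.shape[1] == 1:
        vals = df[0].to_numpy(dtype=float)
        if vals.size != n_bins:
            raise ContactIOError(f"bias length {vals.size} != n_bins {n_bins}")
    elif df.shape[1] == 2:
        vals = np.full(n_bins, np.nan)
        idx = df[0].to_numpy(dtype=np.int64)
        if idx.min() < 0 or idx.max() >= n_bins:
            raise ContactIOError("bias bin index out of range")
        vals[idx] = df[1].to_numpy(dtype=float)
    else:
        raise ContactIOError("bias file must have 1 or 2 columns")
    mask = np.isfinite(vals) & (vals > 0)
    vals = np.where(mask, vals, np.nan)
    return BiasVector(vals, mask)


def write_bias(b: BiasVector, path) -> None:
    with open(path, "w") as fh:
        for v, ok in zip(b.values, b.mask):
            fh.write(f"{float(v)!r}\n" if ok else "nan\n")


def write_run(path, samples, *, extra: dict | None = None) -> None:
    """Persist a :class:`~hicsampler.mcmc_sampler.PosteriorSamples` to HDF5."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("samples", data=samples.samples, track_times=False)
        f.create_dataset("pixel_i", data=samples.pixel_i, track_times=False)
        f.create_dataset("pixel_d", data=samples.pixel_d, track_times=False)
        for name in ("mean", "variance", "dispersion"):
            arr = getattr(samples, name)
            if arr is not None:
                f.create_dataset(name, data=arr, track_times=False)
        f.attrs["chrom"] = samples.chrom
        f.attrs["bin_size"] = samples.bin_size
        f.attrs["n_bins"] = samples.n_bins
        f.attrs["max_distance_bins"] = samples.max_distance_bins
        f.attrs["provenance"] = json.dumps(samples.provenance, default=str)
        if extra:
            f.attrs["extra"] = json.dumps(extra, default=str)


def read_run(path):
    import h5py

    from .mcmc_sampler import PosteriorSamples

    with h5py.File(path, "r") as f:
        return PosteriorSamples(
            samples=f["samples"][...],
            pixel_i=f["pixel_i"][...],
            pixel_d=f["pixel_d"][...],
            chrom=str(f.attrs["chrom"]),
            bin_size=int(f.attrs["bin_size"]),
            n_bins=int(f.attrs["n_bins"]),
            max_distance_bins=int(f.attrs["max_distance_bins"]),
            mean=f["mean"][...] if "mean" in f else None,
            variance=f["variance"][...] if "variance" in f else None,
            dispersion=f["dispersion"][...] if "dispersion" in f else None,
            provenance=json.loads(f.attrs["provenance"]),
        )
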