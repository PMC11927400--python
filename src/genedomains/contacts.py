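"""Loading, balancing and distance-normalizing binned Hi-C contact data.

A :class:`ContactMatrix` holds one chromosome's intra-chromosomal contacts as
a sparse upper-triangular matrix at a fixed bin width.  Distance normalization
("observed over expected", OE) divides every contact by the genome-wide mean
contact frequency at the same bin separation, removing the strong polymer
distance decay so that local structure (domains, insulation) becomes visible.

Genomic positions are 1-based inclusive throughout; a position ``pos`` falls
into bin ``(pos - 1) // resolution``.  Only intra-chromosomal contacts are
represented.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.signal import fftconvolve

__all__ = [
    "ContactMatrix",
    "ExpectedProfile",
    "read_contacts",
    "write_triplet",
    "balance_matrix",
    "expected_profile",
    "oe_values",
]


def n_bins_for(chrom_length: int, resolution: int) -> int:
    return -(-int(chrom_length) // int(resolution))


@dataclass
class ContactMatrix:
    """Sparse upper-triangular binned contact map for one chromosome.

    Parameters
    ----------
    chrom : str
        Chromosome identifier.
    chrom_length : int
        Chromosome length in bp.
    resolution : int
        Bin width in bp.
    counts : scipy.sparse.csr_matrix
        ``(n_bins, n_bins)`` upper-triangular matrix of (normalized) contact
        frequencies; entries with ``i > j`` are never stored.
    normalization : {"raw", "balanced", "external"}
        Provenance of the values: raw counts, balanced by this package's
        iterative correction, or normalized upstream (e.g. matrix-balancing
        weights stored in a cooler file).
    mask : numpy.ndarray of bool
        Per-bin invalidity flags (True = bin excluded: zero coverage or
        unbalanceable).  Masked bins carry no stored counts after balancing.
    """

    chrom: str
    chrom_length: int
    resolution: int
    counts: sp.csr_matrix
    normalization: str = "raw"
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    converged: bool = True

    def __post_init__(self) -> None:
        n = self.n_bins
        if self.counts.shape != (n, n):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match n_bins {n}"
            )
        if self.mask is None:
            self.mask = np.zeros(n, dtype=bool)
        coo = self.counts.tocoo()
        if coo.nnz:
            if (coo.row > coo.col).any():
                raise ValueError("counts must be upper-triangular (i <= j)")
            if not np.all(np.isfinite(coo.data)) or (coo.data < 0).any():
                raise ValueError("contact values must be finite and >= 0")

    @property
    def n_bins(self) -> int:
        return n_bins_for(self.chrom_length, self.resolution)

    def dense(self) -> np.ndarray:
        """Symmetric dense view (upper triangle mirrored)."""
        u = self.counts.toarray()
        return u + u.T - np.diag(np.diag(u))


@dataclass
class ExpectedProfile:
    """Mean contact frequency per bin separation, floored away from zero.

    ``expected[d]`` is the mean normalized contact over *all* valid (unmasked)
    bin pairs at separation ``d``, counting unstored pairs as zero.  Entries
    below ``floor_eps`` are replaced by ``floor_eps`` so OE division is always
    defined.
    """

    resolution: int
    expected: np.ndarray
    floor_eps: float = 1e-9

    def __post_init__(self) -> None:
        self.expected = np.asarray(self.expected, dtype=float)
        if (self.expected < self.floor_eps).any():
            raise ValueError("expected entries must be >= floor_eps")


# ---------------------------------------------------------------------------
# Readers / writers


def _triplet_records(path: str, resolution: int):
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) == 1:
                parts = line.split()
            if len(parts) != 3:
                raise ValueError(
                    f"{path}:{lineno}: expected 3 columns, got {len(parts)}"
                )
            try:
                s1, s2, c = int(parts[0]), int(parts[1]), float(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed record: {exc}") from None
            if s1 < 0 or s2 < 0 or c < 0 or not math.isfinite(c):
                raise ValueError(f"{path}:{lineno}: negative or non-finite field")
            yield s1 // resolution, s2 // resolution, c


def _read_triplet(path, chrom, resolution, chrom_length):
    if chrom_length is None:
        raise ValueError("chrom_length is required for the triplet format")
    n = n_bins_for(chrom_length, resolution)
    rows, cols, data = [], [], []
    for i, j, c in _triplet_records(path, resolution):
        if i > j:
            i, j = j, i
        if j >= n:
            raise ValueError(
                f"{path}: bin pair ({i},{j}) outside chromosome of {n} bins"
            )
        rows.append(i)
        cols.append(j)
        data.append(c)
    m = sp.coo_matrix((data, (rows, cols)), shape=(n, n)).tocsr()
    m.sum_duplicates()
    return ContactMatrix(chrom, chrom_length, resolution, m, normalization="raw")


def _read_cool(path, chrom, resolution, chrom_length):
    import h5py

    with h5py.File(path, "r") as f:
        grp = f
        if "resolutions" in f:  # .mcool layout
            key = str(int(resolution))
            if key not in f["resolutions"]:
                avail = sorted(int(k) for k in f["resolutions"])
                raise ValueError(
                    f"resolution {resolution} not stored; available: {avail}"
                )
            grp = f[f"resolutions/{key}"]
        binsize = int(grp["bins/start"][1] - grp["bins/start"][0]) if grp[
            "bins/start"
        ].shape[0] > 1 else int(grp.attrs.get("bin-size", resolution))
        if binsize != resolution:
            raise ValueError(
                f"stored resolution {binsize} does not match requested {resolution}"
            )
        chrom_names = [
            c.decode() if isinstance(c, bytes) else str(c) for c in grp["chroms/name"]
        ]
        if chrom not in chrom_names:
            raise ValueError(
                f"unknown chromosome {chrom!r}; available: {chrom_names}"
            )
        cid = chrom_names.index(chrom)
        length = int(grp["chroms/length"][cid])
        bin_chrom = grp["bins/chrom"][:]
        sel = np.flatnonzero(bin_chrom == cid)
        lo, hi = int(sel[0]), int(sel[-1]) + 1
        n = hi - lo
        b1 = grp["pixels/bin1_id"][:]
        b2 = grp["pixels/bin2_id"][:]
        cnt = grp["pixels/count"][:].astype(float)
        keep = (b1 >= lo) & (b1 < hi) & (b2 >= lo) & (b2 < hi)
        b1, b2, cnt = b1[keep] - lo, b2[keep] - lo, cnt[keep]
        normalization = "raw"
        if "bins/weight" in grp:
            w = np.asarray(grp["bins/weight"][lo:hi], dtype=float)
            good = np.isfinite(w)
            cnt = cnt * np.where(good, w, 0.0)[b1] * np.where(good, w, 0.0)[b2]
            normalization = "external"
        i = np.minimum(b1, b2)
        j = np.maximum(b1, b2)
        m = sp.coo_matrix((cnt, (i, j)), shape=(n, n)).tocsr()
        m.sum_duplicates()
        cm = ContactMatrix(chrom, length, resolution, m, normalization=normalization)
        if normalization == "external" and "bins/weight" in grp:
            cm.mask = ~np.isfinite(np.asarray(grp["bins/weight"][lo:hi], dtype=float))
        return cm


def _read_hic(path, chrom, resolution, chrom_length):
    try:
        import hicstraw  # noqa: F401
    except ImportError as exc:
        raise RuntimeError(
            ".hic support requires the optional 'hicstraw' package "
            "(pip install genedomains[hic]); alternatively convert the file "
            "to cooler or triplet text"
        ) from exc
    records = hicstraw.straw("observed", "NONE", path, chrom, chrom, "BP", resolution)
    if chrom_length is None:
        chrom_length = max(max(r.binX, r.binY) for r in records) + resolution
    n = n_bins_for(chrom_length, resolution)
    rows = [min(r.binX, r.binY) // resolution for r in records]
    cols = [max(r.binX, r.binY) // resolution for r in records]
    data = [r.counts for r in records]
    m = sp.coo_matrix((data, (rows, cols)), shape=(n, n)).tocsr()
    m.sum_duplicates()
    return ContactMatrix(chrom, chrom_length, resolution, m, normalization="external")


def read_contacts(
    path: str,
    format: str,
    chrom: str,
    resolution: int,
    chrom_length: int | None = None,
) -> ContactMatrix:
    """Load one chromosome's contacts from triplet text, ``.cool`` or ``.hic``.

    Records with ``i > j`` are transposed on load and duplicates summed, so
    the result is always upper-triangular.  For the triplet format the two
    coordinate columns are bin *start* positions in bp and ``chrom_length``
    is required; cooler files carry their own chromosome table.
    """
    readers = {"triplet": _read_triplet, "cool": _read_cool, "hic": _read_hic}
    if format not in readers:
        raise ValueError(f"unknown format {format!r}; choose from {sorted(readers)}")
    return readers[format](path, chrom, resolution, chrom_length)


def write_triplet(m: ContactMatrix, path: str) -> None:
    """Write the upper-triangular pairs as ``start1<TAB>start2<TAB>count``."""
    coo = m.counts.tocoo()
    order = np.lexsort((coo.col, coo.row))
    res = m.resolution
    with open(path, "w") as fh:
        fh.write(f"# chrom={m.chrom} length={m.chrom_length} resolution={res}\n")
        for k in order:
            fh.write(
                f"{coo.row[k] * res}\t{coo.col[k] * res}\t{coo.data[k]:.17g}\n"
            )


# ---------------------------------------------------------------------------
# Balancing


def balance_matrix(
    m: ContactMatrix, max_iter: int = 200, tol: float = 1e-6
) -> ContactMatrix:
    """Iterative-correction (alternating row/column scaling) balancing.

    Divides every contact by the product of its two bins' bias factors until
    all unmasked marginals agree within ``tol`` (relative).  Bins whose
    marginal is zero are masked and their stored entries dropped.  On
    non-convergence a warning is issued and the best-effort result is
    returned with ``converged=False``.
    """
    if m.normalization != "raw":
        raise ValueError("balance_matrix expects a raw matrix")
    n = m.n_bins
    coo = m.counts.tocoo()
    row, col, data = coo.row, coo.col, coo.data.astype(float).copy()
    diag = row == col

    def marginals(values: np.ndarray) -> np.ndarray:
        marg = np.bincount(row, weights=values, minlength=n) + np.bincount(
            col, weights=values, minlength=n
        )
        marg -= np.bincount(row[diag], weights=values[diag], minlength=n)
        return marg

    mask = m.mask.copy()
    mask |= marginals(data) == 0
    keep = ~(mask[row] | mask[col])
    row, col, data, diag = row[keep], col[keep], data[keep], diag[keep]

    bias = np.ones(n)
    converged = False
    for _ in range(max_iter):
        marg = marginals(data)
        active = ~mask
        if not active.any():
            break
        mean_marg = marg[active].mean()
        if mean_marg == 0:
            break
        rel = marg[active] / mean_marg
        if np.max(np.abs(rel - 1)) < tol:
            converged = True
            break
        step = np.ones(n)
        step[active] = rel
        data /= step[row] * step[col]
        bias *= step
    else:  # pragma: no cover - loop exhausted without break
        pass
    if not converged:
        marg = marginals(data)
        active = ~mask
        if active.any() and marg[active].size:
            mm = marg[active].mean()
            if mm > 0 and np.max(np.abs(marg[active] / mm - 1)) < tol:
                converged = True
    if not converged:
        warnings.warn(
            "matrix balancing did not converge; returning best-effort result",
            RuntimeWarning,
            stacklevel=2,
        )
    out = sp.coo_matrix((data, (row, col)), shape=(n, n)).tocsr()
    return ContactMatrix(
        m.chrom,
        m.chrom_length,
        m.resolution,
        out,
        normalization="balanced",
        mask=mask,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# Distance normalization


def expected_profile(m: ContactMatrix, floor_eps: float = 1e-9) -> ExpectedProfile:
    """Per-separation mean contact over all valid bin pairs.

    Unstored pairs count as zero; pairs touching masked bins are excluded
    from both numerator and denominator.  Separations with no valid pairs
    (or a mean below ``floor_eps``) get ``floor_eps``.
    """
    if m.normalization == "raw":
        raise ValueError("expected_profile requires a normalized matrix")
    n = m.n_bins
    coo = m.counts.tocoo()
    keep = ~(m.mask[coo.row] | m.mask[coo.col])
    sums = np.bincount(
        coo.col[keep] - coo.row[keep], weights=coo.data[keep], minlength=n
    )
    valid = (~m.mask).astype(float)
    # autocorrelation: number of unmasked pairs at each separation d
    ac = fftconvolve(valid, valid[::-1])
    pair_counts = np.rint(ac[n - 1 :]).astype(np.int64)
    with np.errstate(invalid="ignore", divide="ignore"):
        exp = np.where(pair_counts > 0, sums / np.maximum(pair_counts, 1), 0.0)
    exp = np.maximum(exp, floor_eps)
    return ExpectedProfile(m.resolution, exp, floor_eps=floor_eps)


def oe_values(m: ContactMatrix, e: ExpectedProfile, region) -> np.ndarray:
    """OE values, one per unmasked pair of ``region``, in row-major order.

    ``OE(i, j) = observed(i, j) / expected[j - i]`` with unstored observed
    treated as zero.  Pairs touching masked bins are dropped, so the result
    may be shorter than the region.
    """
    pairs = np.asarray(region.pairs if hasattr(region, "pairs") else region)
    if pairs.size == 0:
        return np.empty(0)
    ii, jj = pairs[:, 0], pairs[:, 1]
    if (ii < 0).any() or (jj >= m.n_bins).any() or (ii > jj).any():
        raise ValueError("region pairs out of bounds or not upper-triangular")
    keep = ~(m.mask[ii] | m.mask[jj])
    ii, jj = ii[keep], jj[keep]
    if ii.size == 0:
        return np.empty(0)
    obs = np.asarray(m.counts[ii, jj]).ravel()
    return obs / e.expected[jj - ii]
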