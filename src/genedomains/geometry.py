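"""Target and control bin-pair regions on the contact map.

The caller's statistics compare observed/expected (OE) values between a
*target* region (contacts expected to be enriched inside a domain) and
*control* regions placed equidistant from the matrix diagonal.  Because the
expected profile depends only on bin separation ``j - i``, controls are built
by translating the target along the genomic axis: both anchors shift by the
same number of bins, so the multiset of separations — and hence the OE null —
is preserved exactly (up to chromosome-edge clipping).

Bin membership is decided by bin midpoint: bin ``i`` covers 1-based positions
``[i*res + 1, (i+1)*res]`` and its midpoint is ``i*res + (res + 1)/2``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .annotation import GeneModel, gene_bins

__all__ = [
    "BinPairRegion",
    "single_gene_regions",
    "single_gene_target_pairs",
    "multigene_regions",
    "multigene_comparison_pairs",
    "diff_regions",
    "DEFAULT_MIN_PAIRS",
    "DEFAULT_MIN_GENE_BINS",
]

DEFAULT_MIN_PAIRS = 3
DEFAULT_MIN_GENE_BINS = 2


@dataclass
class BinPairRegion:
    """An explicit, ordered set of upper-triangular bin pairs."""

    label: str
    pairs: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=np.int64))

    def __post_init__(self) -> None:
        p = np.asarray(self.pairs, dtype=np.int64).reshape(-1, 2)
        # canonical row-major order makes downstream OE collection deterministic
        if p.shape[0]:
            p = p[np.lexsort((p[:, 1], p[:, 0]))]
        self.pairs = p

    def __len__(self) -> int:
        return self.pairs.shape[0]

    @property
    def separations(self) -> np.ndarray:
        """Sorted multiset of ``j - i``."""
        return np.sort(self.pairs[:, 1] - self.pairs[:, 0])

    def translated(self, shift_bins: int, label: str) -> "BinPairRegion":
        return BinPairRegion(label, self.pairs + shift_bins)

    def clipped(self, n_bins: int) -> "BinPairRegion":
        p = self.pairs
        keep = (p[:, 0] >= 0) & (p[:, 1] < n_bins)
        return BinPairRegion(self.label, p[keep])


def bin_midpoint(i: np.ndarray | int, resolution: int) -> np.ndarray | float:
    return i * resolution + (resolution + 1) / 2


def _bins_with_midpoint_in(lo: float, hi: float, resolution: int) -> np.ndarray:
    """Bin indices whose midpoint x satisfies lo <= x <= hi (may be empty)."""
    if hi < lo:
        return np.empty(0, dtype=np.int64)
    first = math.ceil((lo - (resolution + 1) / 2) / resolution)
    last = math.floor((hi - (resolution + 1) / 2) / resolution)
    return np.arange(first, last + 1, dtype=np.int64)


# ---------------------------------------------------------------------------
# Single-gene geometry


def single_gene_target_pairs(g: GeneModel, resolution: int) -> np.ndarray:
    """Intragenic target triangle hanging from the TSS–TES anchor.

    All pairs ``(i, j)`` whose bin midpoints both lie within the gene and
    whose genomic span ``x_j - x_i`` is at least half the gene length — the
    triangle of height L/2 below the anchor point of the contact map.
    Indices may be out of matrix bounds for genes near chromosome edges;
    callers clip.
    """
    bins = _bins_with_midpoint_in(g.start, g.end, resolution)
    if bins.size < 2:
        return np.empty((0, 2), dtype=np.int64)
    half = g.length / 2
    ii, jj = np.meshgrid(bins, bins, indexing="ij")
    keep = (jj > ii) & ((jj - ii) * resolution >= half)
    return np.stack([ii[keep], jj[keep]], axis=1)


def single_gene_regions(
    g: GeneModel,
    resolution: int,
    n_bins: int,
    min_pairs: int = DEFAULT_MIN_PAIRS,
    min_gene_bins: int = DEFAULT_MIN_GENE_BINS,
) -> dict[str, BinPairRegion] | None:
    """Target plus left/right control triangles for one gene.

    Controls are the target translated by ∓ceil(L/2) bp along the genome
    (rounded to whole bins), so each control pairs one anchor outside the
    gene body with one inside, at identical distance from the diagonal.
    Returns ``None`` (untestable) when the gene spans too few bins or any
    region is smaller than ``min_pairs`` after clipping to the chromosome.
    """
    fb, lb = gene_bins(g, resolution)
    if lb - fb + 1 < min_gene_bins:
        return None
    target_pairs = single_gene_target_pairs(g, resolution)
    target = BinPairRegion("target", target_pairs).clipped(n_bins)
    shift_bp = math.ceil(g.length / 2)
    shift = int(math.floor(shift_bp / resolution + 0.5))
    left = BinPairRegion("control_left", target_pairs - shift).clipped(n_bins)
    right = BinPairRegion("control_right", target_pairs + shift).clipped(n_bins)
    if min(len(target), len(left), len(right)) < min_pairs:
        return None
    return {"target": target, "control_left": left, "control_right": right}


# ---------------------------------------------------------------------------
# Multigene geometry


def _block_pairs(rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    ii, jj = np.meshgrid(rows, cols, indexing="ij")
    keep = jj > ii
    return np.stack([ii[keep], jj[keep]], axis=1)


def multigene_comparison_pairs(
    cluster: list[GeneModel], resolution: int
) -> list[tuple[BinPairRegion, list[BinPairRegion]]]:
    """Unclipped target/control comparisons for a cluster of adjacent genes.

    With boundary genes g1 (bins B_L) and gk (bins B_R) and interior spans
    D = bins(g2..gk), D' = bins(g1..g(k-1)):

    * corner: B_L x B_R (gene-to-gene contacts between the two boundary
      genes), controls translated by -|B_L| and +|B_R| bins;
    * for k >= 3, boundary stripes: B_L x D and D' x B_R (contacts from each
      boundary gene into the rest of the domain), controls translated by the
      width of the corresponding boundary block.

    For k = 2 the stripes coincide with the corner and only the corner
    comparison is emitted.
    """
    k = len(cluster)
    if k < 2:
        raise ValueError("a multigene cluster needs at least 2 genes")
    chroms = {g.chrom for g in cluster}
    if len(chroms) != 1:
        raise ValueError("cluster genes must share a chromosome")
    for a, b in zip(cluster, cluster[1:]):
        if b.start < a.start:
            raise ValueError("cluster genes must be in genomic order")
    spans = [gene_bins(g, resolution) for g in cluster]
    bl = np.arange(spans[0][0], spans[0][1] + 1)
    br = np.arange(spans[-1][0], spans[-1][1] + 1)
    comparisons = []

    def with_controls(target, width_left, width_right):
        return (
            target,
            [
                target.translated(-width_left, target.label + "_control_left"),
                target.translated(+width_right, target.label + "_control_right"),
            ],
        )

    corner = BinPairRegion("corner_target", _block_pairs(bl, br))
    comparisons.append(with_controls(corner, len(bl), len(br)))
    if k >= 3:
        d = np.arange(spans[1][0], spans[-1][1] + 1)
        dp = np.arange(spans[0][0], spans[-2][1] + 1)
        stripe_l = BinPairRegion("stripe_left", _block_pairs(bl, d))
        comparisons.append(with_controls(stripe_l, len(bl), len(bl)))
        stripe_r = BinPairRegion("stripe_right", _block_pairs(dp, br))
        comparisons.append(with_controls(stripe_r, len(br), len(br)))
    return comparisons


def multigene_regions(
    cluster: list[GeneModel],
    resolution: int,
    n_bins: int,
    min_pairs: int = DEFAULT_MIN_PAIRS,
) -> list[tuple[BinPairRegion, list[BinPairRegion]]] | None:
    """Clipped comparisons for a cluster; ``None`` when any region is too small."""
    comparisons = []
    for target, controls in multigene_comparison_pairs(cluster, resolution):
        t = target.clipped(n_bins)
        cs = [c.clipped(n_bins) for c in controls]
        if len(t) < min_pairs or any(len(c) < min_pairs for c in cs):
            return None
        comparisons.append((t, cs))
    return comparisons


# ---------------------------------------------------------------------------
# Differential geometry


def diff_regions(
    g: GeneModel,
    resolution: int,
    n_bins: int,
    flank: int = 2000,
) -> dict[str, BinPairRegion]:
    """Gene-body and surrounding-flank regions for differential insulation.

    ``gene_body``: both bin midpoints inside ``[start, end]`` (i < j).
    ``surrounding``: exactly one midpoint inside the gene, the other within
    ``flank`` bp beyond either border — the contacts that cross a gene
    border into its immediate neighborhood.
    """
    body_bins = _bins_with_midpoint_in(g.start, g.end, resolution)
    left_bins = _bins_with_midpoint_in(g.start - flank, g.start - 1e-9, resolution)
    left_bins = left_bins[
        bin_midpoint(left_bins, resolution) < g.start
    ]  # strict: midpoint in [start-flank, start)
    right_bins = _bins_with_midpoint_in(g.end + 1e-9, g.end + flank, resolution)
    right_bins = right_bins[bin_midpoint(right_bins, resolution) > g.end]

    body = _block_pairs(body_bins, body_bins)
    surr_parts = []
    if left_bins.size and body_bins.size:
        surr_parts.append(_block_pairs(left_bins, body_bins))
    if right_bins.size and body_bins.size:
        surr_parts.append(_block_pairs(body_bins, right_bins))
    surr = (
        np.concatenate(surr_parts, axis=0)
        if surr_parts
        else np.empty((0, 2), dtype=np.int64)
    )
    return {
        "gene_body": BinPairRegion("gene_body", body).clipped(n_bins),
        "surrounding": BinPairRegion("surrounding", surr).clipped(n_bins),
    }
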