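"""Synthetic Hi-C maps with planted gene domains, plus truth-based scoring.

The generative model is the simplest one consistent with the statistics the
caller consumes: contact counts are independent Poisson draws around a
power-law distance decay,

    lambda(i, j) = depth_c * (1 + (j - i)) ** (-decay_alpha) * f(i, j),

where the modifier ``f`` multiplies a planted domain's target-triangle pairs
by ``enrichment`` (elevated intragenic contacts near the TSS–TES anchor),
divides border-crossing pairs within 2 kb of a planted border by
``insulation``, and applies analogous factors for planted multigene clusters
and per-condition differential effects.  Because Poisson intensities add and
thin exactly, enrichment is realized by adding an independent
Poisson((f - 1) * lambda) on top of the base draw and insulation by binomial
thinning — both exact, so the emitted map is a genuine Poisson sample from
the modified intensity.

Everything is driven by one seeded numpy Generator: a fixed seed gives a
byte-identical annotation and contact map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from . import geometry
from .annotation import GeneModel
from .contacts import ContactMatrix, n_bins_for

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_annotation",
    "simulate_contacts",
    "subsample_counts",
    "evaluate_calls",
]


@dataclass
class SimulationConfig:
    """Study conditions for one simulated chromosome.

    Defaults emulate a compact plant genome at high resolution: a 2-Mb
    chromosome binned at 250 bp, genes of 1–5 kb separated by 0.2–2 kb
    gaps, power-law decay with exponent 1 and ~50 expected counts at one-bin
    separation (deep sequencing), two-fold OE enrichment inside planted
    domain triangles.
    """

    chrom: str = "chrSim"
    chrom_length: int = 2_000_000
    resolution: int = 250
    n_genes: int = 200
    gene_length_range: tuple[int, int] = (1000, 5000)
    intergenic_gap_range: tuple[int, int] = (200, 2000)
    frac_single_domains: float = 0.25
    enrichment: float = 2.0
    insulation: float = 1.0
    insulation_flank: int = 2000
    decay_alpha: float = 1.0
    depth_c: float = 50.0
    seed: int = 1
    multigene_clusters: tuple = ()  # ((first_idx, last_idx), enrichment) pairs
    diff_spec: dict | None = None  # gene_idx -> (body_factor_B, surr_factor_B)
    overdispersion: float | None = None  # NB 1/size; None = pure Poisson

    def validate(self) -> None:
        if not (0 <= self.frac_single_domains <= 1):
            raise ValueError("frac_single_domains must lie in [0, 1]")
        if self.enrichment < 1 or self.insulation < 1:
            raise ValueError("enrichment and insulation must be >= 1")
        for rng_ in (self.gene_length_range, self.intergenic_gap_range):
            if rng_[0] <= 0 or rng_[1] < rng_[0]:
                raise ValueError(f"invalid range {rng_}")
        worst = self.gene_length_range[1] + self.intergenic_gap_range[1]
        if self.n_genes * worst > self.chrom_length:
            raise ValueError(
                f"{self.n_genes} genes of up to {worst} bp (gene + gap) cannot "
                f"fit in {self.chrom_length} bp; reduce n_genes to "
                f"<= {self.chrom_length // worst} or shorten genes/gaps"
            )

    @staticmethod
    def max_genes_for(chrom_length, gene_length_range, intergenic_gap_range) -> int:
        return chrom_length // (gene_length_range[1] + intergenic_gap_range[1])


@dataclass
class GroundTruth:
    """Planted-domain truth matched to the emitted annotation."""

    has_single_domain: list[bool]
    multigene_clusters: list[tuple[int, int]] = field(default_factory=list)
    diff_genes: list[int] = field(default_factory=list)


def simulate_annotation(cfg: SimulationConfig) -> tuple[list[GeneModel], GroundTruth]:
    """Draw non-overlapping genes and the planted-domain flags."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    genes = []
    pos = 1
    for idx in range(cfg.n_genes):
        gap = int(rng.integers(cfg.intergenic_gap_range[0],
                               cfg.intergenic_gap_range[1] + 1))
        length = int(rng.integers(cfg.gene_length_range[0],
                                  cfg.gene_length_range[1] + 1))
        start = pos + gap
        end = start + length - 1
        if end > cfg.chrom_length:
            raise ValueError(
                "genes do not fit in chrom_length; reduce n_genes or lengths"
            )
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(f"g{idx:04d}", cfg.chrom, start, end, strand))
        pos = end
    flags = [bool(v) for v in rng.random(cfg.n_genes) < cfg.frac_single_domains]
    truth = GroundTruth(
        has_single_domain=flags,
        multigene_clusters=[tuple(span) for span, _ in cfg.multigene_clusters],
        diff_genes=sorted(cfg.diff_spec) if cfg.diff_spec else [],
    )
    return genes, truth


# ---------------------------------------------------------------------------
# Contact map generation


def _border_pairs(border_bp, flank, resolution):
    """Pairs with one midpoint within `flank` bp left of the border and the
    other within `flank` bp right of it (border-crossing contacts)."""
    left = geometry._bins_with_midpoint_in(border_bp - flank, border_bp - 1e-9,
                                           resolution)
    right = geometry._bins_with_midpoint_in(border_bp + 1e-9, border_bp + flank,
                                            resolution)
    if left.size == 0 or right.size == 0:
        return np.empty((0, 2), dtype=np.int64)
    ii, jj = np.meshgrid(left, right, indexing="ij")
    keep = jj > ii
    return np.stack([ii[keep], jj[keep]], axis=1)


def _modifier_map(genes, truth, cfg, condition=None):
    """Multiplicative lambda factors per (i, j) pair, combined across effects."""
    factors: dict[tuple[int, int], float] = {}

    def apply(pairs, f):
        if f == 1.0:
            return
        for i, j in np.asarray(pairs).reshape(-1, 2):
            key = (int(i), int(j))
            factors[key] = factors.get(key, 1.0) * f

    for g, has in zip(genes, truth.has_single_domain):
        if not has:
            continue
        apply(geometry.single_gene_target_pairs(g, cfg.resolution), cfg.enrichment)
        if cfg.insulation > 1:
            for border in (g.start, g.end):
                apply(_border_pairs(border, cfg.insulation_flank, cfg.resolution),
                      1.0 / cfg.insulation)
    for (first, last), enr in cfg.multigene_clusters:
        cluster = genes[first : last + 1]
        for target, _ in geometry.multigene_comparison_pairs(cluster, cfg.resolution):
            apply(target.pairs, enr)
        if cfg.insulation > 1:
            for border in (cluster[0].start, cluster[-1].end):
                apply(_border_pairs(border, cfg.insulation_flank, cfg.resolution),
                      1.0 / cfg.insulation)
    if condition == "treat" and cfg.diff_spec:
        n_bins = n_bins_for(cfg.chrom_length, cfg.resolution)
        for gi, (body_f, surr_f) in cfg.diff_spec.items():
            regions = geometry.diff_regions(genes[gi], cfg.resolution, n_bins)
            apply(regions["gene_body"].pairs, body_f)
            apply(regions["surrounding"].pairs, surr_f)
    return factors


def _draw_matrix(cfg, factors, rng) -> ContactMatrix:
    n = n_bins_for(cfg.chrom_length, cfg.resolution)
    by_diag: dict[int, tuple[list[int], list[float]]] = {}
    for (i, j), f in sorted(factors.items()):
        if 0 <= i <= j < n:
            d = j - i
            by_diag.setdefault(d, ([], []))[0].append(i)
            by_diag[d][1].append(f)
    rows, cols, data = [], [], []
    for d in range(n):
        lam = cfg.depth_c * (1.0 + d) ** (-cfg.decay_alpha)
        m = n - d
        if cfg.overdispersion:
            size = 1.0 / cfg.overdispersion
            lam_i = rng.gamma(size, lam / size, m)
            counts = rng.poisson(lam_i)
        else:
            counts = rng.poisson(lam, m)
        if d in by_diag:
            idx = np.asarray(by_diag[d][0])
            fs = np.asarray(by_diag[d][1])
            up = fs > 1
            if up.any():
                counts[idx[up]] += rng.poisson((fs[up] - 1.0) * lam)
            down = fs < 1
            if down.any():
                counts[idx[down]] = rng.binomial(counts[idx[down]], fs[down])
        nz = np.flatnonzero(counts)
        rows.append(nz)
        cols.append(nz + d)
        data.append(counts[nz])
    mat = sp.coo_matrix(
        (np.concatenate(data).astype(float),
         (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    ).tocsr()
    return ContactMatrix(cfg.chrom, cfg.chrom_length, cfg.resolution, mat,
                         normalization="raw")


def simulate_contacts(genes, truth, cfg: SimulationConfig):
    """Draw the contact map (or a control/treatment pair when diff_spec set)."""
    if cfg.diff_spec:
        m_a = _draw_matrix(cfg, _modifier_map(genes, truth, cfg, "control"),
                           np.random.default_rng([cfg.seed, 0]))
        m_b = _draw_matrix(cfg, _modifier_map(genes, truth, cfg, "treat"),
                           np.random.default_rng([cfg.seed, 1]))
        return m_a, m_b
    return _draw_matrix(cfg, _modifier_map(genes, truth, cfg),
                        np.random.default_rng([cfg.seed, 0]))


def subsample_counts(m: ContactMatrix, frac: float, seed: int) -> ContactMatrix:
    """Binomial thinning of every stored count — an exact `frac` subsample of
    the read pool, as used for technical-replicate reproducibility checks."""
    if not (0 < frac <= 1):
        raise ValueError("frac must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    coo = m.counts.tocoo()
    thinned = rng.binomial(coo.data.astype(np.int64), frac).astype(float)
    keep = thinned > 0
    out = sp.coo_matrix(
        (thinned[keep], (coo.row[keep], coo.col[keep])), shape=m.counts.shape
    ).tocsr()
    return ContactMatrix(m.chrom, m.chrom_length, m.resolution, out,
                         normalization=m.normalization, mask=m.mask.copy())


# ---------------------------------------------------------------------------
# Truth-based evaluation


def evaluate_calls(calls, truth_intervals, resolution, tol_bins: int = 1) -> dict:
    """Sensitivity / precision / FDP of calls against planted intervals.

    A planted domain is recovered iff some call matches both its boundaries
    within ``tol_bins`` bins; matching is one-to-one.  With no calls and no
    planted domains, precision is defined as 1.
    """
    tol = tol_bins * resolution
    pos = [c for c in calls if getattr(c, "is_domain", True)]
    matched_truth = set()
    matched_calls = set()
    for ti, (ts, te) in enumerate(truth_intervals):
        for ci, c in enumerate(pos):
            if ci in matched_calls:
                continue
            if abs(c.start - ts) <= tol and abs(c.end - te) <= tol:
                matched_truth.add(ti)
                matched_calls.add(ci)
                break
    n_true = len(truth_intervals)
    n_call = len(pos)
    sensitivity = len(matched_truth) / n_true if n_true else 1.0
    precision = len(matched_calls) / n_call if n_call else (
        1.0 if n_true == 0 else 1.0
    )
    if n_call == 0:
        precision = 1.0
    return {
        "sensitivity": sensitivity,
        "precision": precision,
        "false_discovery_proportion": 1.0 - precision,
        "n_called": n_call,
        "n_true": n_true,
    }
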