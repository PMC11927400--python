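"""Statistical engines for single-gene, multigene and differential calls.

Single-gene and multigene domains are declared when target-region OE values
are stochastically greater than those of *every* equidistant control region
(one-sided Mann–Whitney U, combined as the maximum p over controls — an
intersection–union test), with Benjamini–Hochberg control of the false
discovery rate across all testable genes or candidate clusters at Q < 0.05.

Differential insulation between two conditions is tested per gene with a
two-sided Wilcoxon signed-rank on the paired OE differences of the contacts
crossing the gene borders (the surrounding 2-kb region), then filtered by a
mean fold-change cutoff of 0.1 on both the gene-body and surrounding OE
ratios, in opposite directions:

    body_control / body_treat < (1 - 0.1)   and
    surr_treat / surr_control < (1 - 0.1)

declares insulation enhanced in the treatment condition (more internal
contacts, fewer border-crossing contacts); the reciprocal pair of
inequalities declares enhancement in the control condition.

All rank tests use tie-corrected normal approximations for determinism and
speed; genes or clusters whose regions are too small are *untestable* and
excluded from the BH family rather than silently passed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import geometry
from .annotation import GeneModel
from .contacts import ContactMatrix, ExpectedProfile, expected_profile, oe_values
from .geometry import DEFAULT_MIN_GENE_BINS, DEFAULT_MIN_PAIRS

logger = logging.getLogger(__name__)

__all__ = [
    "SingleDomainCall",
    "MultiDomainCall",
    "DiffDomainCall",
    "mannwhitney_greater",
    "wilcoxon_signed_rank",
    "bh_adjust",
    "fold_change_direction",
    "call_single_domains",
    "call_multi_domains",
    "call_diff_domains",
    "write_bed",
    "calls_to_frame",
]


@dataclass
class SingleDomainCall:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    p_value: float
    q_value: float
    mean_oe_target: float
    mean_oe_control_left: float
    mean_oe_control_right: float
    is_domain: bool


@dataclass
class MultiDomainCall:
    gene_ids: tuple[str, ...]
    chrom: str
    start: int
    end: int
    k: int
    p_value: float
    q_value: float
    is_domain: bool

    @property
    def strand(self) -> str:
        return "."

    @property
    def gene_id(self) -> str:
        return ",".join(self.gene_ids)


@dataclass
class DiffDomainCall:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    body_oe_control: float
    body_oe_treat: float
    surr_oe_control: float
    surr_oe_treat: float
    wilcoxon_p: float
    q_value: float
    r_body: float
    r_surr: float
    direction: str  # enhanced_in_treat | enhanced_in_control | none
    passes: bool


# ---------------------------------------------------------------------------
# Elementary tests


def mannwhitney_greater(x, y) -> float | None:
    """One-sided Mann–Whitney U p-value for "x stochastically greater than y".

    Tie-corrected normal approximation with continuity correction.  Returns
    ``None`` (untestable) for samples smaller than 3.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size < 3:
        return None
    if np.ptp(np.concatenate([x, y])) == 0:
        return 0.5  # complete tie: no evidence either way
    return float(
        stats.mannwhitneyu(x, y, alternative="greater", method="asymptotic").pvalue
    )


def wilcoxon_signed_rank(diffs) -> float | None:
    """Two-sided Wilcoxon signed-rank p on paired differences.

    Zero differences are dropped (Wilcoxon convention); requires at least 5
    nonzero differences, otherwise ``None``.  Small tie-free samples (n <= 12)
    use the exact signed-rank distribution, where the normal approximation is
    too coarse; everything else uses the tie-corrected normal approximation
    with continuity correction.  Both paths are deterministic.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    if d.size < 5:
        return None
    tie_free = np.unique(np.abs(d)).size == d.size
    method = "exact" if (tie_free and d.size <= 12) else "approx"
    return float(
        stats.wilcoxon(
            d,
            zero_method="wilcox",
            alternative="two-sided",
            method=method,
            correction=True,
        ).pvalue
    )


def bh_adjust(pvals) -> list[float | None]:
    """Benjamini–Hochberg step-up Q values; ``None`` entries pass through.

    Untestable entries (``None``) are excluded from the family size m.
    """
    idx = [k for k, p in enumerate(pvals) if p is not None]
    out: list[float | None] = [None] * len(pvals)
    if idx:
        ps = np.array([pvals[k] for k in idx], dtype=float)
        if (ps < 0).any() or (ps > 1).any():
            raise ValueError("p-values must lie in [0, 1]")
        qs = multipletests(ps, method="fdr_bh")[1]
        for k, q in zip(idx, qs):
            out[k] = float(q)
    return out


def fold_change_direction(
    r_body: float, r_surr: float, fc_cutoff: float = 0.1
) -> str:
    """Direction implied by the two mean fold-change ratios.

    ``r_body = body_control / body_treat`` and
    ``r_surr = surr_treat / surr_control``; both below ``1 - fc_cutoff``
    means insulation enhanced in treatment, both reciprocals below the bound
    means enhanced in control, anything else is ``none``.
    """
    bound = 1.0 - fc_cutoff
    if not (
        math.isfinite(r_body) and math.isfinite(r_surr) and r_body > 0 and r_surr > 0
    ):
        return "none"
    if r_body < bound and r_surr < bound:
        return "enhanced_in_treat"
    if 1.0 / r_body < bound and 1.0 / r_surr < bound:
        return "enhanced_in_control"
    return "none"


# ---------------------------------------------------------------------------
# Callers


def _region_oe(m, e, region, min_pairs):
    vals = oe_values(m, e, region)
    return vals if vals.size >= min_pairs else None


def call_single_domains(
    m: ContactMatrix,
    e: ExpectedProfile,
    genes: list[GeneModel],
    q_cutoff: float = 0.05,
    min_pairs: int = DEFAULT_MIN_PAIRS,
    min_gene_bins: int = DEFAULT_MIN_GENE_BINS,
) -> list[SingleDomainCall]:
    """Test every gene for a single-gene contact domain.

    Per testable gene the target OE sample is compared against each control
    with a one-sided Mann–Whitney U; the combined p is the max over the two
    controls, and BH runs across all testable genes.  Untestable genes
    (too few bins or clipped/masked regions) are logged and omitted.
    """
    if m.normalization == "raw":
        raise ValueError("call_single_domains requires a normalized matrix")
    n_bins = m.n_bins
    rows = []
    untestable = []
    for g in genes:
        if g.chrom != m.chrom:
            continue
        regions = geometry.single_gene_regions(
            g, m.resolution, n_bins, min_pairs=min_pairs, min_gene_bins=min_gene_bins
        )
        if regions is None:
            untestable.append(g.gene_id)
            continue
        t = _region_oe(m, e, regions["target"], min_pairs)
        cl = _region_oe(m, e, regions["control_left"], min_pairs)
        cr = _region_oe(m, e, regions["control_right"], min_pairs)
        if t is None or cl is None or cr is None:
            untestable.append(g.gene_id)
            continue
        p_left = mannwhitney_greater(t, cl)
        p_right = mannwhitney_greater(t, cr)
        if p_left is None or p_right is None:
            untestable.append(g.gene_id)
            continue
        rows.append(
            (g, max(p_left, p_right), float(t.mean()), float(cl.mean()), float(cr.mean()))
        )
    if untestable:
        logger.info(
            "%d untestable genes: %s%s",
            len(untestable),
            ",".join(untestable[:10]),
            "..." if len(untestable) > 10 else "",
        )
    if not rows:
        logger.warning("no testable genes on %s", m.chrom)
        return []
    qs = bh_adjust([r[1] for r in rows])
    return [
        SingleDomainCall(
            gene_id=g.gene_id,
            chrom=g.chrom,
            start=g.start,
            end=g.end,
            strand=g.strand,
            p_value=p,
            q_value=q,
            mean_oe_target=mt,
            mean_oe_control_left=ml,
            mean_oe_control_right=mr,
            is_domain=bool(q < q_cutoff),
        )
        for (g, p, mt, ml, mr), q in zip(rows, qs)
    ]


def call_multi_domains(
    m: ContactMatrix,
    e: ExpectedProfile,
    genes: list[GeneModel],
    q_cutoff: float = 0.05,
    max_genes: int = 10,
    min_pairs: int = DEFAULT_MIN_PAIRS,
) -> list[MultiDomainCall]:
    """Test every window of 2..max_genes adjacent genes for a multigene domain.

    A cluster is significant only if every boundary comparison (corner and,
    for k >= 3, both boundary stripes) beats both of its controls; the
    cluster p is the max over all comparisons and controls, BH runs across
    all testable candidate windows, and nested/overlapping passing windows
    are all retained.
    """
    if m.normalization == "raw":
        raise ValueError("call_multi_domains requires a normalized matrix")
    chrom_genes = sorted(
        (g for g in genes if g.chrom == m.chrom), key=lambda g: (g.start, g.end)
    )
    n_bins = m.n_bins
    rows = []
    for k in range(2, max_genes + 1):
        for s in range(0, len(chrom_genes) - k + 1):
            cluster = chrom_genes[s : s + k]
            comparisons = geometry.multigene_regions(
                cluster, m.resolution, n_bins, min_pairs=min_pairs
            )
            if comparisons is None:
                continue
            p_cluster = 0.0
            testable = True
            for target, controls in comparisons:
                t = _region_oe(m, e, target, min_pairs)
                if t is None:
                    testable = False
                    break
                for c in controls:
                    cv = _region_oe(m, e, c, min_pairs)
                    p = mannwhitney_greater(t, cv) if cv is not None else None
                    if p is None:
                        testable = False
                        break
                    p_cluster = max(p_cluster, p)
                if not testable:
                    break
            if testable:
                rows.append((cluster, p_cluster))
    if not rows:
        return []
    qs = bh_adjust([p for _, p in rows])
    return [
        MultiDomainCall(
            gene_ids=tuple(g.gene_id for g in cluster),
            chrom=cluster[0].chrom,
            start=cluster[0].start,
            end=cluster[-1].end,
            k=len(cluster),
            p_value=p,
            q_value=q,
            is_domain=bool(q < q_cutoff),
        )
        for (cluster, p), q in zip(rows, qs)
    ]


def call_diff_domains(
    m_control: ContactMatrix,
    m_treat: ContactMatrix,
    genes: list[GeneModel],
    q_cutoff: float = 0.05,
    fc_cutoff: float = 0.1,
    flank: int = 2000,
    min_gene_bins: int = DEFAULT_MIN_GENE_BINS,
) -> list[DiffDomainCall]:
    """Differential insulation between two matched Hi-C datasets.

    Expected profiles are computed per matrix independently; surrounding-
    region OE values are paired by identical bin pair across conditions and
    the differences tested with a two-sided Wilcoxon signed-rank, BH across
    testable genes.  The fold-change filter then assigns the direction.
    """
    if m_control.resolution != m_treat.resolution:
        raise ValueError("matrices must share a resolution")
    if m_control.chrom != m_treat.chrom:
        raise ValueError("matrices must be on the same chromosome")
    for mm in (m_control, m_treat):
        if mm.normalization == "raw":
            raise ValueError("call_diff_domains requires normalized matrices")
    e_control = expected_profile(m_control)
    e_treat = expected_profile(m_treat)
    n_bins = min(m_control.n_bins, m_treat.n_bins)
    joint_mask = m_control.mask | m_treat.mask

    rows = []
    for g in genes:
        if g.chrom != m_control.chrom:
            continue
        fb, lb = (g.start - 1) // m_control.resolution, (g.end - 1) // m_control.resolution
        if lb - fb + 1 < min_gene_bins:
            continue
        regions = geometry.diff_regions(g, m_control.resolution, n_bins, flank=flank)
        surr = regions["surrounding"].pairs
        body = regions["gene_body"].pairs
        if surr.shape[0] == 0 or body.shape[0] == 0:
            continue
        keep = ~(joint_mask[surr[:, 0]] | joint_mask[surr[:, 1]])
        surr = surr[keep]
        keep_b = ~(joint_mask[body[:, 0]] | joint_mask[body[:, 1]])
        body = body[keep_b]
        if surr.shape[0] < 5 or body.shape[0] == 0:
            continue
        surr_a = oe_values(m_control, e_control, surr)
        surr_b = oe_values(m_treat, e_treat, surr)
        body_a = oe_values(m_control, e_control, body)
        body_b = oe_values(m_treat, e_treat, body)
        p = wilcoxon_signed_rank(surr_b - surr_a)
        if p is None:
            continue
        rows.append(
            (g, p, body_a.mean(), body_b.mean(), surr_a.mean(), surr_b.mean())
        )
    if not rows:
        return []
    qs = bh_adjust([r[1] for r in rows])
    calls = []
    for (g, p, ba, bb, sa, sb), q in zip(rows, qs):
        r_body = ba / bb if bb > 0 else math.inf
        r_surr = sb / sa if sa > 0 else math.inf
        direction = (
            fold_change_direction(r_body, r_surr, fc_cutoff)
            if q < q_cutoff
            else "none"
        )
        calls.append(
            DiffDomainCall(
                gene_id=g.gene_id,
                chrom=g.chrom,
                start=g.start,
                end=g.end,
                strand=g.strand,
                body_oe_control=float(ba),
                body_oe_treat=float(bb),
                surr_oe_control=float(sa),
                surr_oe_treat=float(sb),
                wilcoxon_p=p,
                q_value=q,
                r_body=float(r_body),
                r_surr=float(r_surr),
                direction=direction,
                passes=direction != "none",
            )
        )
    return calls


# ---------------------------------------------------------------------------
# Output


def _bed_score(q: float) -> int:
    if q <= 0:
        return 1000
    return min(1000, int(round(-10.0 * math.log10(q))))


def write_bed(calls, path: str, only_domains: bool = True) -> None:
    """BED6 export: name is the gene id(s), score is -10*log10(Q) capped at 1000."""
    with open(path, "w") as fh:
        for c in calls:
            flag = getattr(c, "is_domain", getattr(c, "passes", True))
            if only_domains and not flag:
                continue
            q = getattr(c, "q_value")
            fh.write(
                f"{c.chrom}\t{c.start - 1}\t{c.end}\t{c.gene_id}"
                f"\t{_bed_score(q)}\t{c.strand}\n"
            )


def calls_to_frame(calls):
    """Full statistics table as a pandas DataFrame (for TSV export)."""
    import pandas as pd
    from dataclasses import asdict

    return pd.DataFrame([asdict(c) for c in calls])
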