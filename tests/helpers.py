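"""Independent brute-force oracles shared by the test modules.

Everything here is deliberately naive — exhaustive enumeration and double
loops — and independent of the library code paths it checks.
"""

from itertools import combinations

import numpy as np
import scipy.sparse as sp
from scipy.stats import rankdata

from genedomains.contacts import ContactMatrix


def exact_mannwhitney_greater(x, y) -> float:
    """One-sided permutation p: P(U >= U_obs) over all C(n+m, n) labelings."""
    x = list(map(float, x))
    y = list(map(float, y))
    pooled = x + y
    n = len(x)

    def u_stat(sample_x, sample_y):
        return sum(
            1.0 if xv > yv else 0.5 if xv == yv else 0.0
            for xv in sample_x
            for yv in sample_y
        )

    u_obs = u_stat(x, y)
    idx = range(len(pooled))
    count = total = 0
    for comb in combinations(idx, n):
        chosen = set(comb)
        xs = [pooled[i] for i in comb]
        ys = [pooled[i] for i in idx if i not in chosen]
        if u_stat(xs, ys) >= u_obs - 1e-12:
            count += 1
        total += 1
    return count / total


def exact_wilcoxon_two_sided(diffs) -> float:
    """Two-sided sign-flip p: P(|W+ - mu| >= |obs - mu|) over 2^n flips."""
    d = np.asarray([v for v in diffs if v != 0], dtype=float)
    n = d.size
    ranks = rankdata(np.abs(d))
    mu = n * (n + 1) / 4.0
    w_obs = ranks[d > 0].sum()
    count = 0
    for bits in range(2 ** n):
        signs = [(bits >> k) & 1 for k in range(n)]
        w = sum(r for r, s in zip(ranks, signs) if s)
        if abs(w - mu) >= abs(w_obs - mu) - 1e-12:
            count += 1
    return count / 2 ** n


def brute_single_target(gene, resolution, n_bins):
    """Double-loop midpoint-predicate enumeration of the intragenic triangle."""
    a, b, half = gene.start, gene.end, gene.length / 2
    pairs = []
    for i in range(n_bins):
        xi = i * resolution + (resolution + 1) / 2
        for j in range(i + 1, n_bins):
            xj = j * resolution + (resolution + 1) / 2
            if a <= xi < xj <= b and xj - xi >= half:
                pairs.append((i, j))
    return pairs


def brute_diff_surrounding(gene, resolution, n_bins, flank):
    a, b = gene.start, gene.end
    pairs = []
    for i in range(n_bins):
        xi = i * resolution + (resolution + 1) / 2
        for j in range(i + 1, n_bins):
            xj = j * resolution + (resolution + 1) / 2
            in_i = a <= xi <= b
            in_j = a <= xj <= b
            out_i = (a - flank <= xi < a) or (b < xi <= b + flank)
            out_j = (a - flank <= xj < a) or (b < xj <= b + flank)
            if (in_i and out_j) or (out_i and in_j):
                pairs.append((i, j))
    return pairs


def dense_to_matrix(arr, resolution=250, chrom="chrT", normalization="balanced"):
    """Upper-triangular ContactMatrix from a dense symmetric array."""
    arr = np.asarray(arr, dtype=float)
    n = arr.shape[0]
    upper = np.triu(arr)
    return ContactMatrix(
        chrom,
        n * resolution,
        resolution,
        sp.csr_matrix(upper),
        normalization=normalization,
    )


def uniform_matrix(n_bins, value=1.0, resolution=250):
    return dense_to_matrix(
        np.full((n_bins, n_bins), float(value)), resolution=resolution
    )
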