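"""Independent brute-force reference for the ARTP permutation machinery.

Pure-Python loops and direct counting, deliberately sharing no code with
pathartp.artp. Arithmetic is performed in the same left-to-right
ascending-sorted order as the implementation so exact float equality is a
meaningful assertion.
"""

import math


def brute_rtp(pvalues, j):
    return -sum(math.log(p) for p in sorted(pvalues)[:j])


def default_points(n_items, cap=10):
    return list(range(1, min(n_items, cap) + 1))


def brute_minp_rows(p_rows, points):
    """MinP per row: min over truncation points of the estimated p-value."""
    R = len(p_rows)
    stats = [[brute_rtp(row, j) for j in points] for row in p_rows]
    minp = []
    for b in range(R):
        shat = [
            sum(stats[b2][k] >= stats[b][k] for b2 in range(R)) / R
            for k in range(len(points))
        ]
        minp.append(min(shat))
    return minp


def brute_adjusted_p(p_rows, points=None):
    """Gene-level ARTP adjusted p by direct enumeration of the pool."""
    points = points or default_points(len(p_rows[0]))
    minp = brute_minp_rows(p_rows, points)
    return sum(m <= minp[0] for m in minp) / len(minp)


def brute_pathway_p(p_matrix, gene_columns, gene_points=None,
                    pathway_points=None):
    """Two-stage pathway ARTP on a (B+1) x n_snps matrix of row-lists.

    ``gene_columns`` maps each gene to its column indices. Stage 1 computes
    every row's per-gene estimated p (row pooled with all others); stage 2
    repeats the RTP/MinP counting across genes.
    """
    R = len(p_matrix)
    gene_p_rows = [[] for _ in range(R)]
    for cols in gene_columns:
        rows = [[p_matrix[b][c] for c in cols] for b in range(R)]
        points = gene_points or default_points(len(cols))
        minp = brute_minp_rows(rows, points)
        for b in range(R):
            gene_p_rows[b].append(sum(m <= minp[b] for m in minp) / R)
    points = pathway_points or default_points(len(gene_columns))
    minp = brute_minp_rows(gene_p_rows, points)
    return sum(m <= minp[0] for m in minp) / R, [row[:] for row in gene_p_rows]
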