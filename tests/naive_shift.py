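"""Independent full-recomputation reference for the trace-shifting engine.

Rebuilds both half-matrices (pairwise medians and variances) from scratch
at every iteration instead of updating only the affected row/column.  Uses
its own numpy arithmetic throughout; with identical tie-breaking (lowest
(row, column) pair at equal minimum variance, second member shifted onto
the first, member-weighted averaging) it must agree with the incremental
engine bit for bit.
"""

import numpy as np


def _stats(va, vb):
    """(median, variance, n_overlap) of va - vb on the joint support."""
    mask = ~np.isnan(va) & ~np.isnan(vb)
    n = int(mask.sum())
    if n == 0:
        return np.nan, np.nan, 0
    d = va[mask] - vb[mask]
    med = float(np.median(d))
    var = float(np.var(d, ddof=1)) if n >= 2 else np.inf
    return med, var, n


def naive_hierarchical_shift(matrix):
    """Shifts for the rows of a (n_traces x n_features) log2 matrix.

    Returns ``(shifts, unmerged_row_indices)``.
    """
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    active = [matrix[i].copy() for i in range(n)]
    weights = [1.0] * n
    members = [{i: 0.0} for i in range(n)]

    while len(active) > 1:
        # full recomputation of both half-matrices
        best, best_var = None, None
        for i in range(len(active)):
            for j in range(i + 1, len(active)):
                med, var, nov = _stats(active[i], active[j])
                if nov == 0:
                    continue
                if best is None or var < best_var:
                    best, best_var, best_med = (i, j), var, med
        if best is None:
            break
        i, j = best
        va, vb = active[i], active[j] + best_med
        wa, wb = weights[i], weights[j]
        both = ~np.isnan(va) & ~np.isnan(vb)
        merged = np.where(np.isnan(va), vb, va)
        merged[both] = (wa * va[both] + wb * vb[both]) / (wa + wb)
        for orig in members[j]:
            members[j][orig] += best_med
        active[i] = merged
        weights[i] = wa + wb
        members[i] = {**members[i], **members[j]}
        del active[j], weights[j], members[j]

    shifts = np.zeros(n)
    unmerged = set()
    if len(active) == 1:
        for orig, s in members[0].items():
            shifts[orig] = s
    else:
        sizes = [len(m) for m in members]
        main = int(np.argmax(sizes))
        if sizes[main] > 1:
            for orig, s in members[main].items():
                shifts[orig] = s
            flagged = [k for k in range(len(active)) if k != main]
        else:
            flagged = list(range(len(active)))
        for k in flagged:
            unmerged.update(members[k])
    return shifts, unmerged
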