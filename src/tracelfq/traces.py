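"""Intensity traces and the hierarchical pairwise shifting engine.

An *intensity trace* is a vector of log2 intensities over a shared feature
axis, with missing entries encoded as NaN.  For between-sample normalization
each trace is a sample and the features are ions; for protein intensity
estimation each trace is an ion and the features are samples.  In both cases
systematic multiplicative biases in linear space become additive offsets in
log2 space, so aligning traces reduces to finding one additive scaling
factor per trace.

The engine aligns a set of traces with an adapted single-linkage procedure:
all pairs are compared by the median and variance of their element-wise
difference on the jointly observed features, the lowest-variance pair is
shifted together and replaced by a member-weighted average trace, the
affected matrix entries are recalculated, and the process repeats until one
trace remains.  A cap ``nmax`` on the number of traces entering the full
pairwise stage keeps the cost linear in the number of traces: beyond-``nmax``
traces are each shifted independently onto the frozen anchor average.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: variance sentinel for pairs whose overlap is too small (< 2 features) to
#: estimate a spread; such pairs are merged last but their median is usable.
UNDEFINED_VARIANCE = np.inf


@dataclass
class IntensityTrace:
    """One log2 intensity vector over the shared feature axis.

    Parameters
    ----------
    trace_id : str
        Opaque identifier, unique within a :class:`TraceSet`.
    values : ndarray of float
        log2 intensities; missing entries are NaN.
    n_members : int
        Number of original traces averaged into this trace (1 for raw
        traces; grows during hierarchical merging).
    """

    trace_id: str
    values: np.ndarray
    n_members: int = 1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("trace values must be one-dimensional")
        finite_or_nan = np.isfinite(self.values) | np.isnan(self.values)
        if not finite_or_nan.all():
            raise ValueError(
                f"trace {self.trace_id!r}: non-missing values must be finite"
            )
        if self.n_members < 1:
            raise ValueError("n_members must be >= 1")

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.values).sum())


@dataclass
class TraceSet:
    """An ordered collection of traces sharing one feature axis."""

    features: list
    traces: list

    def __post_init__(self) -> None:
        nfeat = len(self.features)
        for tr in self.traces:
            if len(tr.values) != nfeat:
                raise ValueError(
                    f"trace {tr.trace_id!r} has length {len(tr.values)}, "
                    f"expected {nfeat}"
                )
        ids = [tr.trace_id for tr in self.traces]
        if len(set(ids)) != len(ids):
            raise ValueError("trace_ids must be unique")

    def __len__(self) -> int:
        return len(self.traces)

    @property
    def trace_ids(self) -> list:
        return [tr.trace_id for tr in self.traces]

    def values_matrix(self) -> np.ndarray:
        """Stack trace values into an (n_traces, n_features) array."""
        return np.vstack([tr.values for tr in self.traces])

    @classmethod
    def from_matrix(cls, mat, trace_ids, features=None) -> "TraceSet":
        mat = np.asarray(mat, dtype=float)
        if features is None:
            features = list(range(mat.shape[1]))
        traces = [
            IntensityTrace(tid, row) for tid, row in zip(trace_ids, mat)
        ]
        return cls(features=list(features), traces=traces)


@dataclass
class PairStats:
    """Median and variance of the difference of two traces on their overlap.

    The median estimates the systematic shift between the traces; the
    sample variance (ddof=1) of the difference distribution measures their
    overall divergence.  ``n_overlap == 0`` marks an incomparable pair: both
    statistics are NaN.
    """

    median_shift: float
    variance: float
    n_overlap: int

    @property
    def comparable(self) -> bool:
        return self.n_overlap >= 1


@dataclass
class ShiftSolution:
    """Per-trace additive log2 scaling factors plus merge provenance.

    Attributes
    ----------
    shifts : ndarray of float
        One additive log2 factor per input trace, aligned with the input
        order.  Traces that could not be connected to the main merge
        component keep a shift of 0 and appear in ``unmerged``.
    merge_log : list of (str, str, float)
        ``(kept_trace_id, shifted_trace_id, applied_shift)`` per merge, in
        merge order.
    unmerged : set of str
        trace_ids never merged into the main component.
    n_comparisons : int
        Pairwise comparisons filling new matrix cells (initial half-matrix
        construction plus single anchor-average comparisons).
    n_updates : int
        Recalculations of existing matrix cells after merges.
    """

    shifts: np.ndarray
    merge_log: list = field(default_factory=list)
    unmerged: set = field(default_factory=set)
    n_comparisons: int = 0
    n_updates: int = 0


def _mode_of(diffs: np.ndarray) -> float:
    """Kernel-density peak of a difference distribution.

    Fallback location estimator for the case where a majority of features
    is regulated; noisier than the median and therefore not the default.
    """
    from scipy.stats import gaussian_kde

    if diffs.size < 2 or np.ptp(diffs) == 0:
        return float(np.median(diffs))
    kde = gaussian_kde(diffs)
    grid = np.linspace(diffs.min(), diffs.max(), 512)
    return float(grid[int(np.argmax(kde(grid)))])


def pairwise_stats(a: IntensityTrace, b: IntensityTrace, center: str = "median") -> PairStats:
    """Compare two traces on their jointly observed features.

    Returns the ``center`` (median by default, KDE mode as an option) and
    sample variance (ddof=1) of the element-wise difference ``a - b``.
    Zero overlap yields the incomparable sentinel (NaN/NaN, n_overlap=0)
    rather than an error; an overlap of exactly one feature yields a usable
    median but an undefined (infinite) variance so the pair is merged last.
    """
    va, vb = a.values, b.values
    mask = ~np.isnan(va) & ~np.isnan(vb)
    n = int(mask.sum())
    if n == 0:
        return PairStats(np.nan, np.nan, 0)
    d = va[mask] - vb[mask]
    shift = _mode_of(d) if center == "mode" else float(np.median(d))
    var = float(np.var(d, ddof=1)) if n >= 2 else UNDEFINED_VARIANCE
    return PairStats(shift, var, n)


def merge_pair(a: IntensityTrace, b: IntensityTrace, stats: PairStats) -> IntensityTrace:
    """Average two traces after aligning ``b`` onto ``a``.

    ``b`` is shifted by ``stats.median_shift``; where both traces are
    observed the merged value is the ``n_members``-weighted mean, where only
    one is observed its value is taken (the averaged trace automatically
    fills missing entries), and where neither is observed the merged entry
    stays missing.
    """
    if not stats.comparable:
        raise ValueError(
            f"cannot merge incomparable traces {a.trace_id!r}, {b.trace_id!r}"
        )
    vb = b.values + stats.median_shift
    va = a.values
    wa, wb = float(a.n_members), float(b.n_members)
    both = ~np.isnan(va) & ~np.isnan(vb)
    merged = np.where(np.isnan(va), vb, va)
    merged[both] = (wa * va[both] + wb * vb[both]) / (wa + wb)
    return IntensityTrace(
        trace_id=f"({a.trace_id}+{b.trace_id})",
        values=merged,
        n_members=a.n_members + b.n_members,
    )


def select_anchor_traces(ts: TraceSet, nmax: int) -> list:
    """Indices of the ``min(nmax, n)`` traces with fewest missing values.

    Ties are broken by input order, so complete data yields the first
    ``nmax`` traces.
    """
    if nmax < 1:
        raise ValueError("nmax must be >= 1")
    if nmax >= len(ts):
        return list(range(len(ts)))
    missing = [tr.n_missing for tr in ts.traces]
    order = sorted(range(len(ts)), key=lambda i: (missing[i], i))
    return order[:nmax]


class _MergeState:
    """Active-trace bookkeeping shared by the shifting engine.

    Tracks, for every active (possibly averaged) trace, which original
    traces it contains and their accumulated shifts, so scaling factors
    applied to an averaged trace propagate to all underlying originals.
    """

    def __init__(self, ts: TraceSet, center: str):
        self.center = center
        self.active = list(ts.traces)
        # per active trace: {original_index: accumulated_shift}
        self.members = [{i: 0.0} for i in range(len(ts))]
        self.shifts = np.zeros(len(ts))
        self.merge_log: list = []
        self.n_comparisons = 0
        self.n_updates = 0

    def compare(self, i: int, j: int, *, update: bool) -> PairStats:
        st = pairwise_stats(self.active[i], self.active[j], center=self.center)
        if update:
            self.n_updates += 1
        else:
            self.n_comparisons += 1
        return st

    def merge(self, i: int, j: int, stats: PairStats) -> None:
        """Shift active trace ``j`` onto ``i`` and replace the pair."""
        a, b = self.active[i], self.active[j]
        for orig in self.members[j]:
            self.members[j][orig] += stats.median_shift
        self.merge_log.append((a.trace_id, b.trace_id, stats.median_shift))
        merged = merge_pair(a, b, stats)
        self.active[i] = merged
        self.members[i] = {**self.members[i], **self.members[j]}
        del self.active[j], self.members[j]

    def finalize(self) -> ShiftSolution:
        """Collect shifts; components outside the main one are reset to 0.

        The main component is the largest final active trace (ties broken
        by position).  If no merge happened at all while more than one
        trace was present, every trace is flagged.
        """
        unmerged: set = set()
        if len(self.active) == 1:
            for orig, s in self.members[0].items():
                self.shifts[orig] = s
        else:
            sizes = [len(m) for m in self.members]
            main = int(np.argmax(sizes))
            if sizes[main] > 1:
                for orig, s in self.members[main].items():
                    self.shifts[orig] = s
                flagged = [k for k in range(len(self.active)) if k != main]
            else:  # no merges at all
                flagged = list(range(len(self.active)))
            for k in flagged:
                unmerged.update(self._orig_id(o) for o in self.members[k])
        if unmerged:
            logger.warning(
                "%d trace(s) could not be merged with the main component "
                "and keep shift 0: %s", len(unmerged), sorted(unmerged)
            )
        return ShiftSolution(
            shifts=self.shifts,
            merge_log=self.merge_log,
            unmerged=unmerged,
            n_comparisons=self.n_comparisons,
            n_updates=self.n_updates,
        )

    def set_original_ids(self, ids: list) -> None:
        self._original_ids = ids

    def _orig_id(self, orig_index: int) -> str:
        return self._original_ids[orig_index]


def hierarchical_shift(ts: TraceSet, center: str = "median") -> ShiftSolution:
    """Align all traces by iterative minimum-variance pairwise merging.

    Builds the half-matrices of pairwise medians and variances, repeatedly
    merges the comparable pair with the smallest variance (ties: lowest
    (row, column) position), recalculates only the matrix entries involving
    the merged trace, and stops when a single trace remains or no comparable
    pair is left.  Returns one additive log2 shift per input trace; the
    solution is defined up to a common additive constant.
    """
    if len(ts) == 0:
        raise ValueError("hierarchical_shift requires at least one trace")
    state = _MergeState(ts, center)
    state.set_original_ids(ts.trace_ids)
    if len(ts) == 1:
        return state.finalize()

    # half-matrix as dict keyed by active-list positions (i < j)
    stats: dict = {}
    n = len(state.active)
    for i in range(n):
        for j in range(i + 1, n):
            stats[(i, j)] = state.compare(i, j, update=False)

    while len(state.active) > 1:
        best = None
        for (i, j), st in sorted(stats.items()):
            if not st.comparable:
                continue
            if best is None or st.variance < stats[best].variance:
                best = (i, j)
        if best is None:
            break
        i, j = best
        state.merge(i, j, stats[best])
        # reindex: positions > j shift down by one; drop row/col j,
        # recalculate row/col i against every survivor
        new_stats = {}
        for (p, q), st in stats.items():
            if p == j or q == j or p == i or q == i:
                continue
            p2 = p - 1 if p > j else p
            q2 = q - 1 if q > j else q
            new_stats[(p2, q2)] = st
        for k in range(len(state.active)):
            if k == i:
                continue
            key = (min(i, k), max(i, k))
            new_stats[key] = state.compare(key[0], key[1], update=True)
        stats = new_stats

    return state.finalize()


def capped_shift(ts: TraceSet, nmax: int, center: str = "median") -> ShiftSolution:
    """Align traces with the pairwise stage capped at ``nmax`` traces.

    With ``n <= nmax`` this is exactly :func:`hierarchical_shift`.
    Otherwise the ``nmax`` most complete traces (the *anchors*) are merged
    hierarchically into an averaged anchor trace, and every remaining trace
    is shifted independently onto that frozen average by the median of its
    difference — one comparison per remaining trace, hence linear scaling:
    at most ``nmax*(nmax-1)/2`` comparisons for the anchors plus
    ``n - nmax`` for the rest.
    """
    if nmax < 1:
        raise ValueError("nmax must be >= 1")
    n = len(ts)
    if n <= nmax:
        return hierarchical_shift(ts, center=center)

    anchor_idx = select_anchor_traces(ts, nmax)
    anchor_set = TraceSet(
        features=ts.features, traces=[ts.traces[i] for i in anchor_idx]
    )
    sol = hierarchical_shift(anchor_set, center=center)

    # rebuild the final averaged anchor trace in the aligned frame
    shifted = anchor_set.values_matrix() + sol.shifts[:, None]
    main_rows = [
        k for k, tid in enumerate(anchor_set.trace_ids)
        if tid not in sol.unmerged
    ]
    if not main_rows:  # no anchors merged; fall back to all
        main_rows = list(range(len(anchor_set)))
    import warnings

    with warnings.catch_warnings():
        # features unobserved in every anchor stay NaN
        warnings.simplefilter("ignore", category=RuntimeWarning)
        anchor_avg = IntensityTrace(
            "(anchor-average)", np.nanmean(shifted[main_rows], axis=0),
            n_members=len(main_rows),
        )

    shifts = np.zeros(n)
    unmerged = set(sol.unmerged)
    n_comparisons = sol.n_comparisons
    for pos, i in enumerate(anchor_idx):
        shifts[i] = sol.shifts[pos]
    remaining = [i for i in range(n) if i not in set(anchor_idx)]
    for i in remaining:
        st = pairwise_stats(anchor_avg, ts.traces[i], center=center)
        n_comparisons += 1
        if st.comparable:
            shifts[i] = st.median_shift
        else:
            unmerged.add(ts.traces[i].trace_id)
    if unmerged - set(sol.unmerged):
        logger.warning(
            "%d beyond-anchor trace(s) share no features with the anchor "
            "average and keep shift 0", len(unmerged - set(sol.unmerged))
        )
    return ShiftSolution(
        shifts=shifts,
        merge_log=sol.merge_log,
        unmerged=unmerged,
        n_comparisons=n_comparisons,
        n_updates=sol.n_updates,
    )


def apply_shifts(ts: TraceSet, solution: ShiftSolution) -> TraceSet:
    """Return a new TraceSet with each trace's shift added to its values."""
    traces = [
        IntensityTrace(tr.trace_id, tr.values + s, tr.n_members)
        for tr, s in zip(ts.traces, solution.shifts)
    ]
    return TraceSet(features=ts.features, traces=traces)
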