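"""Between-sample normalization by trace shifting.

Each sample is one intensity trace over the ions of the dataset; a single
multiplicative factor per sample (additive in log2) removes systematic
biases such as unequal sample loading or drifting instrument performance.
The underlying assumption is that the majority of proteins are not
regulated between samples, which makes the pairwise median an unbiased and
outlier-robust estimator of the sample-to-sample shift.  When that
assumption fails for a known reason, normalization can be restricted to a
user-supplied subset of housekeeping proteins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .ion_table import IonTable
from .traces import capped_shift

logger = logging.getLogger(__name__)

DEFAULT_NMAX_SAMPLES = 50


def _as_table(X) -> IonTable:
    if isinstance(X, IonTable):
        return X
    return IonTable(pd.DataFrame(X))


@dataclass
class NormalizationResult:
    """Normalized table plus the per-sample log2 factors that produced it."""

    normalized_table: IonTable
    log2_factors: pd.Series
    flags: pd.Series  # True where a sample could not be aligned


class SampleNormalizer(BaseEstimator, TransformerMixin):
    """Remove per-sample multiplicative intensity bias.

    Sample traces are aligned with the capped hierarchical shifting engine:
    the ``nmax`` most complete samples are merged pairwise into an anchor
    average and any further samples are shifted onto it independently, so
    the cost grows linearly with the number of samples.  Factors are
    re-centered so their median is 0, which keeps the overall intensity
    scale of the dataset (shifts are only defined up to a common constant).

    Parameters
    ----------
    nmax : int, default 50
        Cap on the number of sample traces entering full pairwise merging.
    subset : collection of protein ids, optional
        Housekeeping proteins; when given, sample traces are built only
        from their ions but the factors are applied to the whole table.
    center : {"median", "mode"}, default "median"
        Location estimator for pairwise trace differences.  The mode
        (kernel-density peak) is for datasets where a majority of proteins
        is regulated; it is noisier and off by default.

    Attributes
    ----------
    log2_factors_ : pd.Series
        Additive log2 factor per sample (multiplicative in linear space).
    flags_ : pd.Series of bool
        True for samples that shared no ions with the anchor traces and
        kept factor 0.
    """

    def __init__(self, nmax: int = DEFAULT_NMAX_SAMPLES, subset=None,
                 center: str = "median"):
        self.nmax = nmax
        self.subset = subset
        self.center = center

    def fit(self, X, y=None):
        t = _as_table(X)
        basis = t if self.subset is None else t.restrict_to_proteins(self.subset)
        ts = basis.to_trace_set_by_sample()
        sol = capped_shift(ts, nmax=self.nmax, center=self.center)
        factors = pd.Series(sol.shifts, index=ts.trace_ids, name="log2_factor")
        factors = factors.reindex(t.samples, fill_value=0.0)
        factors -= factors.median()
        flags = pd.Series(
            [s in sol.unmerged for s in factors.index],
            index=factors.index, name="flag",
        )
        if flags.any():
            logger.warning("%d sample(s) could not be normalized and keep "
                           "factor 0", int(flags.sum()))
        self.log2_factors_ = factors
        self.flags_ = flags
        self.n_comparisons_ = sol.n_comparisons
        return self

    def transform(self, X) -> pd.DataFrame:
        t = _as_table(X)
        return t.scale_samples(self.log2_factors_).df

    def fit_transform(self, X, y=None, **kwargs) -> pd.DataFrame:
        return self.fit(X).transform(X)


def normalize_samples(t, nmax: int = DEFAULT_NMAX_SAMPLES, subset=None,
                      center: str = "median") -> NormalizationResult:
    """Normalize an ion table; see :class:`SampleNormalizer`."""
    t = _as_table(t)
    norm = SampleNormalizer(nmax=nmax, subset=subset, center=center).fit(t)
    return NormalizationResult(
        normalized_table=t.scale_samples(norm.log2_factors_),
        log2_factors=norm.log2_factors_,
        flags=norm.flags_,
    )
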