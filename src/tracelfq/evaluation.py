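"""Benchmark statistics: group fold changes and replicate CVs.

Mixed-species spike-in designs make quantification accuracy measurable:
every protein of a species has the same known abundance ratio between the
two conditions, so the per-species distribution of estimated log2 fold
changes should be centered on the known log2 ratio, and its spread measures
precision.  Replicate consistency is summarized by the per-protein
coefficient of variation of linear intensities.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def log2fc_per_protein(intensities: pd.DataFrame, group_a, group_b) -> pd.Series:
    """Per-protein log2 fold change: median over group A minus over group B.

    ``intensities`` is the (protein x sample) linear table; medians are
    taken over log2 intensities within each sample group.  Proteins missing
    in all samples of a group get NaN.
    """
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ValueError("both sample groups must be non-empty")
    if set(group_a) & set(group_b):
        raise ValueError("sample groups must be disjoint")
    log2 = np.log2(intensities)
    fc = log2[group_a].median(axis=1) - log2[group_b].median(axis=1)
    return fc.rename("log2_fc")


def cv_per_protein(intensities: pd.DataFrame, samples=None) -> pd.Series:
    """Per-protein coefficient of variation over replicate samples.

    CV = standard deviation / mean of the *linear* intensities (ddof=1).
    Proteins with fewer than two observed values get NaN.
    """
    sub = intensities if samples is None else intensities[list(samples)]
    n = sub.notna().sum(axis=1)
    cv = sub.std(axis=1, ddof=1) / sub.mean(axis=1)
    cv[n < 2] = np.nan
    return cv.rename("cv")


def summarize_by_species(fc: pd.Series, species_of: pd.Series) -> pd.DataFrame:
    """Median and SD (ddof=1) of per-protein log2 fold changes per species."""
    df = pd.DataFrame({"log2_fc": fc, "species": species_of.reindex(fc.index)})
    out = df.dropna().groupby("species")["log2_fc"].agg(
        median="median", sd=lambda x: x.std(ddof=1), n="count")
    return out
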