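"""Protein intensity estimation from aligned ion traces.

Within one protein, each ion is a trace over samples.  Peptide-specific
ionization efficiencies offset these traces by large constants in log2
space; shifting them on top of each other removes the offsets without
altering any trace's shape.  The per-sample median of the aligned traces is
the relative protein profile, which is transformed back to linear space and
rescaled by a single factor so that the protein's total linear intensity
over all samples equals the total linear intensity of its ions — the
overall peptide signal is conserved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .ion_table import IonTable
from .normalization import _as_table
from .traces import TraceSet, apply_shifts, capped_shift

logger = logging.getLogger(__name__)

DEFAULT_NMAX_IONS = 10


def estimate_relative_profile(ts: TraceSet, nmax: int = DEFAULT_NMAX_IONS):
    """Median profile of ion traces after alignment.

    Returns ``(profile, aligned)``: the per-sample median of the aligned
    log2 ion traces (NaN where the protein has no ion evidence), and the
    aligned TraceSet itself.
    """
    if len(ts) == 0:
        raise ValueError("profile estimation requires at least one ion trace")
    sol = capped_shift(ts, nmax=nmax)
    aligned = apply_shifts(ts, sol)
    mat = aligned.values_matrix()
    with np.errstate(invalid="ignore"):
        all_nan = np.all(np.isnan(mat), axis=0)
        profile = np.full(mat.shape[1], np.nan)
        profile[~all_nan] = np.nanmedian(mat[:, ~all_nan], axis=0)
    return profile, aligned


def rescale_to_linear(profile: np.ndarray, total_ion_intensity: float) -> np.ndarray:
    """Back-transform a log2 profile and restore the total ion signal.

    The linear profile is multiplied by one factor — the sum of all linear
    ion intensities over all samples divided by the sum of the linear
    profile over all samples — so that per-protein total intensity is
    conserved exactly.
    """
    linear = np.exp2(profile)
    denom = np.nansum(linear)
    if denom == 0 or np.isnan(denom):
        return np.full_like(profile, np.nan)
    return linear * (total_ion_intensity / denom)


@dataclass
class ProteinQuantResult:
    """Per-protein linear intensities plus the aligned ion traces.

    ``intensities``: (protein x sample) linear intensities, NaN = no ion
    evidence.  ``aligned_ions``: long table of shifted log2 ion traces
    (normalized peptide intensity estimates), which lets the protein
    estimate be retraced.  ``n_ions``: ion count per quantified protein.
    """

    intensities: pd.DataFrame
    aligned_ions: pd.DataFrame
    n_ions: pd.Series


class ProteinQuantifier(BaseEstimator):
    """Estimate per-protein, per-sample linear intensities.

    Proteins are processed independently: their ion traces are aligned by
    capped hierarchical shifting (``nmax`` most complete ions merged
    pairwise, the rest shifted onto the anchor average), the per-sample
    median of the aligned traces gives the relative profile, and linear
    rescaling restores the protein's total ion signal.

    Parameters
    ----------
    nmax : int, default 10
        Cap on ion traces entering full pairwise merging.
    min_ions : int, default 1
        Proteins with fewer ions are dropped (logged).

    Attributes
    ----------
    protein_intensities_ : pd.DataFrame
        (protein x sample) linear intensities.
    aligned_ions_ : pd.DataFrame
        Long table ``protein, ion, sample, aligned_log2_intensity``.
    n_ions_ : pd.Series
        Ions per quantified protein.
    """

    def __init__(self, nmax: int = DEFAULT_NMAX_IONS, min_ions: int = 1):
        self.nmax = nmax
        self.min_ions = min_ions

    def fit(self, X, y=None):
        res = self._quantify(_as_table(X))
        self.protein_intensities_ = res.intensities
        self.aligned_ions_ = res.aligned_ions
        self.n_ions_ = res.n_ions
        return self

    def transform(self, X) -> pd.DataFrame:
        """Quantify the given table (stateless; proteins are independent)."""
        return self._quantify(_as_table(X)).intensities

    def fit_transform(self, X, y=None, **kwargs) -> pd.DataFrame:
        return self.fit(X).protein_intensities_

    def _quantify(self, t: IonTable) -> ProteinQuantResult:
        samples = t.samples
        totals = t.df.groupby("protein", sort=False)["intensity"].sum()
        rows, aligned_rows, n_ions = {}, [], {}
        n_dropped = 0
        for protein, ts in t.to_trace_sets_by_protein().items():
            if len(ts) < self.min_ions:
                n_dropped += 1
                continue
            profile, aligned = estimate_relative_profile(ts, nmax=self.nmax)
            rows[protein] = rescale_to_linear(profile, float(totals[protein]))
            n_ions[protein] = len(ts)
            for tr in aligned.traces:
                mask = ~np.isnan(tr.values)
                for s, v in zip(np.asarray(samples, dtype=object)[mask],
                                tr.values[mask]):
                    aligned_rows.append((protein, tr.trace_id, s, v))
        if n_dropped:
            logger.info("dropped %d protein(s) with fewer than %d ions",
                        n_dropped, self.min_ions)
        if not rows:
            raise ValueError("no protein passed the min_ions filter")
        intensities = pd.DataFrame.from_dict(rows, orient="index",
                                             columns=samples)
        intensities.index.name = "protein"
        aligned_ions = pd.DataFrame(
            aligned_rows,
            columns=["protein", "ion", "sample", "aligned_log2_intensity"],
        )
        return ProteinQuantResult(intensities, aligned_ions,
                                  pd.Series(n_ions, name="n_ions"))


def quantify_all_proteins(t, nmax: int = DEFAULT_NMAX_IONS,
                          min_ions: int = 1) -> ProteinQuantResult:
    """Quantify every protein in the table; see :class:`ProteinQuantifier`."""
    q = ProteinQuantifier(nmax=nmax, min_ions=min_ions).fit(_as_table(t))
    return ProteinQuantResult(q.protein_intensities_, q.aligned_ions_,
                              q.n_ions_)
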