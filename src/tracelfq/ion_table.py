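"""Canonical long-format store of quantified ions.

Every pipeline stage reads from and writes to an :class:`IonTable`: records
of (protein group, ion, sample, linear intensity).  Absence of a record
means the ion was not quantified in that sample; stored intensities are
strictly positive because zero or negative linear signal carries no
information once log2-transformed.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .traces import IntensityTrace, TraceSet

logger = logging.getLogger(__name__)

COLUMNS = ["protein", "ion", "sample", "intensity"]

#: delimiter joining the hierarchical components of an ion identifier
#: (modified sequence, charge, optional fragment/isotope tag)
ION_SEP = "|"


def make_ion_id(*components) -> str:
    """Render hierarchical ion components as one delimited string."""
    return ION_SEP.join(str(c) for c in components)


def split_ion_id(ion_id: str) -> list:
    return ion_id.split(ION_SEP)


class IonTable:
    """Long-format table of (protein, ion, sample, linear intensity).

    Construction enforces the table invariants: duplicate (ion, sample)
    rows are summed in linear space (total-signal semantics, e.g. multiple
    evidence rows for one precursor in one run), ions mapping to more than
    one protein group are dropped with a warning, and non-positive or
    non-finite intensities are removed (zero linear signal means missing).
    Sample order is first appearance in the input and is stable.
    """

    def __init__(self, df: pd.DataFrame, validate: bool = True):
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"ion table is missing columns: {missing}")
        df = df.loc[:, COLUMNS].copy()
        if validate:
            df = self._clean(df)
        if df.empty:
            raise ValueError("ion table has no records")
        self.df = df.reset_index(drop=True)
        self.samples = list(pd.unique(self.df["sample"]))

    @staticmethod
    def _clean(df: pd.DataFrame) -> pd.DataFrame:
        df = df.astype({"protein": str, "ion": str, "sample": str})
        df["intensity"] = pd.to_numeric(df["intensity"], errors="coerce")
        bad = ~(df["intensity"] > 0) | ~np.isfinite(df["intensity"])
        if bad.any():
            logger.info("dropping %d records with missing/zero/negative "
                        "intensity", int(bad.sum()))
            df = df[~bad]
        # an ion must map to exactly one protein group
        nprot = df.groupby("ion")["protein"].nunique()
        shared = nprot.index[nprot > 1]
        if len(shared):
            logger.warning(
                "dropping %d ion(s) mapped to multiple protein groups "
                "(grouping is deferred to the search engine)", len(shared)
            )
            df = df[~df["ion"].isin(set(shared))]
        # duplicate (ion, sample) rows are summed in linear space
        dup = df.duplicated(["ion", "sample"]).sum()
        if dup:
            logger.info("summing %d duplicate (ion, sample) record(s) in "
                        "linear space", int(dup))
            df = (
                df.groupby(["protein", "ion", "sample"], sort=False,
                           as_index=False)["intensity"].sum()
            )
        return df

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        if not isinstance(other, IonTable):
            return NotImplemented
        a = self.df.sort_values(["protein", "ion", "sample"]).reset_index(drop=True)
        b = other.df.sort_values(["protein", "ion", "sample"]).reset_index(drop=True)
        return a.equals(b)

    @property
    def proteins(self) -> list:
        return list(pd.unique(self.df["protein"]))

    @property
    def ions(self) -> list:
        return list(pd.unique(self.df["ion"]))

    def restrict_to_proteins(self, proteins) -> "IonTable":
        sub = self.df[self.df["protein"].isin(set(proteins))]
        if sub.empty:
            raise ValueError(
                f"no ions found for the requested protein subset "
                f"({sorted(set(proteins))[:5]}...)"
            )
        return IonTable(sub, validate=False)

    def scale_samples(self, log2_factors: pd.Series) -> "IonTable":
        """Multiply each sample's intensities by 2**factor, exactly."""
        fac = self.df["sample"].map(log2_factors).to_numpy(dtype=float)
        out = self.df.copy()
        out["intensity"] = out["intensity"].to_numpy() * np.exp2(fac)
        return IonTable(out, validate=False)

    # ---- pivots to trace sets -------------------------------------------

    def to_wide(self) -> pd.DataFrame:
        """Pivot to an (ion x sample) matrix of linear intensities (NaN =
        missing), with samples in first-appearance order."""
        wide = self.df.pivot(index="ion", columns="sample", values="intensity")
        return wide.reindex(columns=self.samples)

    def to_trace_set_by_sample(self) -> TraceSet:
        """One trace per sample over the union of all ions (log2 scale)."""
        wide = self.to_wide()
        mat = np.log2(wide.to_numpy(dtype=float)).T  # samples x ions
        return TraceSet(
            features=list(wide.index),
            traces=[IntensityTrace(s, row) for s, row in zip(self.samples, mat)],
        )

    def to_trace_sets_by_protein(self) -> dict:
        """Per protein, one trace per ion over the shared sample axis.

        The feature axis is the full ordered sample list of the table, not
        only the samples in which the protein was observed, so profiles of
        different proteins stay comparable.
        """
        out = {}
        sample_pos = {s: k for k, s in enumerate(self.samples)}
        for protein, sub in self.df.groupby("protein", sort=False):
            ions = list(pd.unique(sub["ion"]))
            ion_pos = {i: k for k, i in enumerate(ions)}
            mat = np.full((len(ions), len(self.samples)), np.nan)
            mat[
                sub["ion"].map(ion_pos).to_numpy(),
                sub["sample"].map(sample_pos).to_numpy(),
            ] = np.log2(sub["intensity"].to_numpy(dtype=float))
            out[protein] = TraceSet(
                features=list(self.samples),
                traces=[IntensityTrace(i, row) for i, row in zip(ions, mat)],
            )
        return out

    @classmethod
    def from_trace_set_by_sample(cls, ts: TraceSet, protein_of: dict) -> "IonTable":
        """Inverse of :meth:`to_trace_set_by_sample` (non-missing entries)."""
        rows = []
        for tr in ts.traces:
            for ion, v in zip(ts.features, tr.values):
                if not np.isnan(v):
                    rows.append((protein_of[ion], ion, tr.trace_id, float(2.0 ** v)))
        return cls(pd.DataFrame(rows, columns=COLUMNS), validate=False)

    def protein_of_ion(self) -> dict:
        return dict(self.df.drop_duplicates("ion")[["ion", "protein"]].values)
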