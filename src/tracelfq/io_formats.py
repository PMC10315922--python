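"""Readers for search-engine outputs and writers for results.

Every reader parses a TSV export into the canonical :class:`IonTable`;
required columns are validated before any parsing work and unknown extra
columns are ignored.  Supported dialects:

``maxquant_evidence``
    MaxQuant ``evidence.txt`` (DDA, MS1 precursor intensities), optionally
    with ``proteinGroups.txt`` for protein-group mapping.
``diann_report``
    DIA-NN main report: one MS1 trace per precursor (``MS1.Area``) plus one
    trace per fragment position (``Fragment.Quant.Raw``).
``spectronaut_fragion``
    Spectronaut fragment-ion long export (run / protein group / precursor /
    fragment / quantity).
``generic_long`` / ``generic_wide``
    The package's own dialects: ``protein, ion, sample, intensity`` (long)
    or ``protein, ion`` plus one column per sample (wide).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .ion_table import COLUMNS, IonTable, make_ion_id

logger = logging.getLogger(__name__)

DIALECTS = ("maxquant_evidence", "diann_report", "spectronaut_fragion",
            "generic_long", "generic_wide")

#: separator inside DIA-NN's Fragment.Quant.Raw column
FRAGMENT_SEP = ";"


def _read_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty:
        raise ValueError(f"{path}: input file contains no data rows")
    return df


def _require(df: pd.DataFrame, columns, path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {missing}")


def _numeric(s: pd.Series) -> pd.Series:
    out = pd.to_numeric(s, errors="coerce")
    bad = s.notna() & out.isna()
    if bad.any():
        logger.warning("skipped %d row(s) with unparseable intensity",
                       int(bad.sum()))
    return out


def read_maxquant(evidence_path, protein_groups_path=None) -> IonTable:
    """Parse MaxQuant ``evidence.txt`` into an ion table.

    Ions are (modified sequence, charge); samples are raw files.  Rows
    flagged Reverse or Potential contaminant (``+``) are dropped by default.
    When ``proteinGroups.txt`` is given, evidence rows are remapped to its
    protein-group ids via the evidence ``id`` / group ``Evidence IDs``
    linkage; otherwise the evidence protein column is used.
    """
    df = _read_tsv(evidence_path)
    _require(df, ["Modified sequence", "Charge", "Raw file", "Intensity"],
             evidence_path)
    for flag_col in ("Reverse", "Potential contaminant"):
        if flag_col in df.columns:
            df = df[df[flag_col].fillna("") != "+"]

    protein_col = next(
        (c for c in ("Leading razor protein", "Proteins") if c in df.columns),
        None,
    )
    if protein_col is None and protein_groups_path is None:
        raise ValueError(f"{evidence_path}: missing required column(s): "
                         "['Proteins' or 'Leading razor protein']")

    if protein_groups_path is not None:
        groups = _read_tsv(protein_groups_path)
        _require(groups, ["Protein IDs", "Evidence IDs"], protein_groups_path)
        _require(df, ["id"], evidence_path)
        ev2group = {}
        for gid, ev_ids in zip(groups["Protein IDs"], groups["Evidence IDs"]):
            for ev in str(ev_ids).split(";"):
                if ev:
                    ev2group[ev] = gid
        protein = df["id"].map(ev2group)
        dropped = protein.isna().sum()
        if dropped:
            logger.warning("%d evidence row(s) not listed in any protein "
                           "group were dropped", int(dropped))
    else:
        protein = df[protein_col]

    out = pd.DataFrame({
        "protein": protein,
        "ion": [make_ion_id(s, c) for s, c in
                zip(df["Modified sequence"], df["Charge"])],
        "sample": df["Raw file"],
        "intensity": _numeric(df["Intensity"]),
    }).dropna(subset=["protein"])
    return IonTable(out)


def read_diann(report_path) -> IonTable:
    """Parse a DIA-NN main report into an ion table.

    Each precursor contributes one ion from ``MS1.Area`` plus one ion per
    position of the ``Fragment.Quant.Raw`` list (semicolon-separated;
    trailing empties ignored); zero-valued fragments are dropped.
    """
    df = _read_tsv(report_path)
    _require(df, ["Run", "Protein.Group", "Precursor.Id", "MS1.Area",
                  "Fragment.Quant.Raw"], report_path)
    rows = []
    for run, protein, prec, ms1, frags in zip(
            df["Run"], df["Protein.Group"], df["Precursor.Id"],
            df["MS1.Area"], df["Fragment.Quant.Raw"]):
        rows.append((protein, make_ion_id(prec, "MS1"), run, ms1))
        if isinstance(frags, str) and frags.strip():
            for k, v in enumerate(x for x in frags.split(FRAGMENT_SEP)
                                  if x.strip() != ""):
                rows.append((protein, make_ion_id(prec, f"FRG{k}"), run, v))
    out = pd.DataFrame(rows, columns=COLUMNS)
    out["intensity"] = _numeric(out["intensity"])
    return IonTable(out)


def read_spectronaut(report_path) -> IonTable:
    """Parse a Spectronaut fragment-ion long export into an ion table.

    Expects run (``R.FileName``), protein group (``PG.ProteinGroups``),
    precursor (``EG.PrecursorId``), fragment/isotope identifier
    (``F.FrgIon``) and quantity (``F.PeakArea``) columns; each fragment or
    MS1 isotope of a precursor is one independent ion.
    """
    df = _read_tsv(report_path)
    _require(df, ["R.FileName", "PG.ProteinGroups", "EG.PrecursorId",
                  "F.FrgIon", "F.PeakArea"], report_path)
    out = pd.DataFrame({
        "protein": df["PG.ProteinGroups"],
        "ion": [make_ion_id(p, f) for p, f in
                zip(df["EG.PrecursorId"], df["F.FrgIon"])],
        "sample": df["R.FileName"],
        "intensity": _numeric(df["F.PeakArea"]),
    })
    return IonTable(out)


def read_generic(path, dialect=None) -> IonTable:
    """Read the package's generic long or wide TSV dialect.

    With ``dialect=None`` the layout is detected from the header: the long
    dialect has exactly the four canonical columns, the wide dialect has
    ``protein`` and ``ion`` plus one column per sample.  Detection failure
    raises and asks for an explicit ``--input-type``.
    """
    df = _read_tsv(path)
    cols = list(df.columns)
    if dialect is None:
        if set(COLUMNS).issubset(cols):
            dialect = "generic_long"
        elif {"protein", "ion"}.issubset(cols) and len(cols) > 2:
            dialect = "generic_wide"
        else:
            raise ValueError(
                f"{path}: cannot detect dialect from columns {cols}; "
                "pass an explicit --input-type")
    if dialect == "generic_long":
        _require(df, COLUMNS, path)
        df["intensity"] = _numeric(df["intensity"])
        return IonTable(df)
    if dialect == "generic_wide":
        _require(df, ["protein", "ion"], path)
        long = df.melt(id_vars=["protein", "ion"], var_name="sample",
                       value_name="intensity")
        long["intensity"] = _numeric(long["intensity"])
        return IonTable(long)
    raise ValueError(f"unknown generic dialect {dialect!r}")


def read_table(path, input_type=None, protein_groups=None) -> IonTable:
    """Dispatch on ``input_type`` (one of DIALECTS) or auto-detect generic."""
    if input_type in (None, "generic_long", "generic_wide"):
        return read_generic(path, dialect=input_type)
    if input_type == "maxquant_evidence":
        return read_maxquant(path, protein_groups)
    if input_type == "diann_report":
        return read_diann(path)
    if input_type == "spectronaut_fragion":
        return read_spectronaut(path)
    raise ValueError(f"unknown input type {input_type!r}; "
                     f"expected one of {DIALECTS}")


# ---- writers -------------------------------------------------------------

def write_long_table(t: IonTable, path) -> None:
    t.df.to_csv(path, sep="\t", index=False)


def write_wide_table(t: IonTable, path) -> None:
    wide = t.to_wide()
    wide.insert(0, "protein", pd.Series(t.protein_of_ion()))
    wide.reset_index().to_csv(path, sep="\t", index=False)


def write_outputs(result, out_dir, normalization=None) -> dict:
    """Write the standard result files into ``out_dir``.

    ``protein_intensities.tsv``: rows = protein groups, columns = samples,
    linear intensities, empty cell = missing.  ``aligned_ions.tsv``: the
    shifted log2 ion traces.  ``normalization_factors.tsv`` (if a
    normalization result is given): per-sample log2 factor and flag.
    Returns the mapping of output name -> path.
    """
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}

    p = out_dir / "protein_intensities.tsv"
    result.intensities.reset_index().to_csv(p, sep="\t", index=False)
    paths["protein_intensities"] = p

    p = out_dir / "aligned_ions.tsv"
    result.aligned_ions.to_csv(p, sep="\t", index=False)
    paths["aligned_ions"] = p

    if normalization is not None:
        p = out_dir / "normalization_factors.tsv"
        pd.DataFrame({
            "sample": normalization.log2_factors.index,
            "log2_factor": normalization.log2_factors.values,
            "flag": normalization.flags.values.astype(int),
        }).to_csv(p, sep="\t", index=False)
        paths["normalization_factors"] = p
    return paths


def read_protein_table(path) -> pd.DataFrame:
    """Read back a ``protein_intensities.tsv`` written by write_outputs."""
    df = pd.read_csv(path, sep="\t")
    return df.set_index("protein")
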