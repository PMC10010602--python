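"""Readers and writers for protein tables, intensity matrices and designs.

Dialects
--------
* MaxQuant ``proteinGroups.txt``: tab-delimited, one row per protein group,
  intensity columns named ``"LFQ intensity <sample>"`` / ``"iBAQ <sample>"``
  / ``"Intensity <sample>"``, quality flags marked with ``"+"`` in the
  ``Potential contaminant`` (older versions: ``Contaminant``), ``Reverse``
  and ``Only identified by site`` columns.
* Generic matrix: tab-delimited, first column protein IDs, remaining
  columns numeric intensities.
* Design: tab-delimited with header ``sample<TAB>group[<TAB>tech_rep]``.
  The ``sample`` field names either a full intensity column, the short
  label after the intensity prefix, or (with ``tech_rep``) the biological
  sample whose column is ``<sample>_<tech_rep>``.  Resolution tries the
  exact column name first.

All readers tolerate LF and CRLF and use "." as the decimal separator
regardless of locale.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .data import Design, IntensityMatrix, ProteinGroupsTable

logger = logging.getLogger("lfqpipe.io")

__all__ = [
    "FormatError",
    "INTENSITY_PREFIXES",
    "read_protein_groups",
    "read_intensity_matrix",
    "read_design",
    "write_intensity_matrix",
    "read_intensity_matrix_tsv",
]

#: Column-name prefix per intensity type (prefix + single space).
INTENSITY_PREFIXES = {
    "LFQ": "LFQ intensity ",
    "iBAQ": "iBAQ ",
    "Intensity": "Intensity ",
}

_ID_COLUMNS = ("Majority protein IDs", "Protein IDs")
_FLAG_COLUMNS = {
    "is_contaminant": ("Potential contaminant", "Contaminant"),
    "is_reverse": ("Reverse",),
    "only_by_site": ("Only identified by site",),
}
_UNIQUE_PEPTIDES_COLUMN = "Unique peptides"


class FormatError(ValueError):
    """Raised when an input file does not follow the expected dialect."""


def _read_tsv_text(path) -> pd.DataFrame:
    # dtype=str keeps full control over numeric parsing; keep_default_na=False
    # so empty cells stay "" and "NA"-like protein names survive.
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def _parse_numeric(frame: pd.DataFrame, columns: list[str], blank_to: float = 0.0) -> pd.DataFrame:
    out = {}
    for col in columns:
        raw = frame[col].str.strip()
        blank = raw == ""
        parsed = pd.to_numeric(raw.mask(blank), errors="coerce")
        bad = parsed.isna() & ~blank
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise FormatError(
                f"unparseable numeric value {raw.iloc[row]!r} at data row {row + 1}, "
                f"column {col!r}"
            )
        # re-parse through Python's correctly-rounded float() so written
        # values round-trip bit-exactly
        out[col] = np.array(
            [blank_to if s == "" else float(s) for s in raw], dtype=float
        )
    return pd.DataFrame(out, index=frame.index)


def read_protein_groups(path, intensity_type: str = "LFQ") -> ProteinGroupsTable:
    """Parse a MaxQuant-style ``proteinGroups.txt`` file.

    Parameters
    ----------
    path
        Tab-delimited file with a header row.
    intensity_type
        Which family of intensity columns to load: ``"LFQ"``, ``"iBAQ"``
        or ``"Intensity"`` (raw).

    Returns
    -------
    ProteinGroupsTable
        One record per data row.  Blank intensity cells become 0; flags are
        True exactly where the corresponding column holds ``"+"``.
    """
    if intensity_type not in INTENSITY_PREFIXES:
        raise FormatError(
            f"unknown intensity_type {intensity_type!r}; expected one of "
            f"{sorted(INTENSITY_PREFIXES)}"
        )
    prefix = INTENSITY_PREFIXES[intensity_type]
    frame = _read_tsv_text(path)
    intensity_cols = [c for c in frame.columns if c.startswith(prefix)]
    if not intensity_cols:
        raise FormatError(
            f"no intensity columns found: expected at least one column name "
            f"starting with {prefix!r}"
        )

    id_col = next((c for c in _ID_COLUMNS if c in frame.columns), frame.columns[0])
    intensities = _parse_numeric(frame, intensity_cols)
    intensities.index = pd.Index(frame[id_col].to_numpy(), name="protein_id")

    flags = pd.DataFrame(index=intensities.index)
    for flag, candidates in _FLAG_COLUMNS.items():
        col = next((c for c in candidates if c in frame.columns), None)
        marks = frame[col].str.strip() == "+" if col is not None else False
        flags[flag] = np.asarray(marks) if col is not None else False

    if _UNIQUE_PEPTIDES_COLUMN in frame.columns:
        uniq = _parse_numeric(frame, [_UNIQUE_PEPTIDES_COLUMN])[_UNIQUE_PEPTIDES_COLUMN]
        unique_peptides = uniq.astype(int)
        unique_peptides.index = intensities.index
    else:
        logger.warning(
            "no %r column in %s; unique-peptide counts unavailable, the "
            "peptide filter will be skipped", _UNIQUE_PEPTIDES_COLUMN, path,
        )
        unique_peptides = None

    return ProteinGroupsTable(
        intensities=intensities,
        flags=flags,
        unique_peptides=unique_peptides,
        column_prefix=prefix,
    )


def read_intensity_matrix(path) -> ProteinGroupsTable:
    """Parse a generic protein x sample intensity table.

    The first column holds protein IDs, the remaining columns linear-scale
    intensities.  All quality flags are False and unique-peptide counts are
    unavailable, so the peptide filter is later skipped.
    """
    frame = _read_tsv_text(path)
    if frame.shape[1] < 2:
        raise FormatError("intensity matrix needs an ID column plus >=1 numeric column")
    ids = frame.iloc[:, 0]
    if ids.duplicated().any():
        dup = sorted(set(ids[ids.duplicated()]))
        raise FormatError(f"duplicate protein IDs: {dup}")
    value_cols = list(frame.columns[1:])
    intensities = _parse_numeric(frame, value_cols)
    intensities.index = pd.Index(ids.to_numpy(), name="protein_id")
    flags = pd.DataFrame(
        False, index=intensities.index, columns=list(ProteinGroupsTable.FLAG_NAMES)
    )
    logger.info("generic matrix: no unique-peptide counts; peptide filter will be skipped")
    return ProteinGroupsTable(intensities=intensities, flags=flags, unique_peptides=None)


def _resolve_column(table: ProteinGroupsTable, sample: str, tech_rep) -> str | None:
    candidates = [sample]
    if tech_rep is not pd.NA and tech_rep is not None and not pd.isna(tech_rep):
        label = f"{sample}_{int(tech_rep)}"
        candidates += [label, table.column_prefix + label]
    candidates.append(table.column_prefix + sample)
    for cand in candidates:
        if cand in table.intensities.columns:
            return cand
    return None


def read_design(path, table: ProteinGroupsTable) -> Design:
    """Read a design file and resolve its rows against ``table``'s columns.

    Raises
    ------
    FormatError
        If a row references a column absent from ``table``, or on duplicate
        (sample, tech_rep) pairs.
    """
    frame = _read_tsv_text(path)
    cols = {c.lower().strip(): c for c in frame.columns}
    sample_col = cols.get("sample") or cols.get("column_label")
    group_col = cols.get("group") or cols.get("condition")
    if sample_col is None or group_col is None:
        raise FormatError(
            "design file needs 'sample' and 'group' columns "
            f"(found {list(frame.columns)})"
        )
    tech_col = cols.get("tech_rep")
    if tech_col is not None:
        tech = _parse_numeric(frame, [tech_col], blank_to=np.nan)[tech_col]
        tech = tech.astype("Int64")
        if (tech.dropna() < 1).any():
            raise FormatError("tech_rep indices must be positive integers")
    else:
        tech = pd.array([pd.NA] * len(frame), dtype="Int64")

    rows = []
    for i in range(len(frame)):
        sample = frame[sample_col].iloc[i].strip()
        group = frame[group_col].iloc[i].strip()
        tr = tech[i]
        column = _resolve_column(table, sample, tr)
        if column is None:
            raise FormatError(
                f"design row {i + 1}: no intensity column matches sample "
                f"{sample!r}" + (f" tech_rep {tr}" if not pd.isna(tr) else "")
            )
        rows.append(
            {
                "column_label": column,
                "label": table.short_label(column),
                "sample_id": sample,
                "group": group,
                "tech_rep": tr,
            }
        )
    entries = pd.DataFrame(rows)
    entries["tech_rep"] = entries["tech_rep"].astype("Int64")
    design = Design(entries=entries)
    if len(design.groups) < 2:
        logger.warning(
            "design lists %d group(s); differential expression needs at least 2",
            len(design.groups),
        )
    return design


def write_intensity_matrix(m: IntensityMatrix, path) -> None:
    """Serialize a stage matrix as TSV (proteins x samples, "NA" missing).

    Group labels and the stage tag are stored in ``#``-prefixed header
    comments so the file round-trips through
    :func:`read_intensity_matrix_tsv`.
    """
    with open(path, "w", newline="\n") as fh:
        fh.write(f"# stage: {m.stage}\n")
        fh.write("# groups: " + "\t".join(f"{s}={g}" for s, g in m.groups.items()) + "\n")
        m.values.to_csv(fh, sep="\t", na_rep="NA", index_label="protein_id")


def read_intensity_matrix_tsv(path) -> IntensityMatrix:
    """Read a stage TSV written by :func:`write_intensity_matrix`."""
    stage = "raw"
    group_map: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            body = line[1:].strip()
            if body.startswith("stage:"):
                stage = body.split(":", 1)[1].strip()
            elif body.startswith("groups:"):
                for item in body.split(":", 1)[1].strip().split("\t"):
                    sample, group = item.split("=", 1)
                    group_map[sample] = group
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        values = pd.read_csv(fh, sep="\t", index_col="protein_id", na_values=["NA"])
    groups = pd.Series({s: group_map.get(s, "?") for s in values.columns})
    return IntensityMatrix(values=values, groups=groups, stage=stage)
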