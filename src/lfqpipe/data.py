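"""Core data containers shared across the pipeline.

Three containers travel through the analysis workflow:

``ProteinGroupsTable``
    The parsed protein-level quantification table (one row per protein
    group): linear-scale intensities per measurement column, quality flags
    (contaminant / reverse-decoy / only-identified-by-site) and
    unique-peptide counts.

``Design``
    The experimental design: which intensity column belongs to which
    biological sample, which group (condition) that sample is in, and an
    optional technical-replicate index.

``IntensityMatrix``
    The working proteins x samples matrix of log2 intensities with missing
    values as NaN, tagged with its processing stage (``raw`` -> ``imputed``
    / ``normalized``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = ["ProteinGroupsTable", "Design", "IntensityMatrix", "STAGES"]

STAGES = ("raw", "imputed", "normalized")


@dataclass
class ProteinGroupsTable:
    """Raw protein-level quantification table on the linear intensity scale.

    Parameters
    ----------
    intensities
        proteins x intensity-columns frame, non-negative, linear scale.
        The index holds protein identifiers (majority protein IDs).
    flags
        Boolean frame aligned to ``intensities`` rows with columns
        ``is_contaminant``, ``is_reverse``, ``only_by_site``.
    unique_peptides
        Per-protein unique-peptide counts, or ``None`` when the source
        table does not report them (the peptide filter is then skipped).
    column_prefix
        Prefix stripped from intensity column names to obtain the short
        sample label (e.g. ``"LFQ intensity "``); empty for generic tables.
    """

    intensities: pd.DataFrame
    flags: pd.DataFrame
    unique_peptides: Optional[pd.Series] = None
    column_prefix: str = ""

    FLAG_NAMES = ("is_contaminant", "is_reverse", "only_by_site")

    def __post_init__(self) -> None:
        if (self.intensities.to_numpy() < 0).any():
            raise ValueError("intensities must be non-negative")
        if self.intensities.columns.duplicated().any():
            dup = self.intensities.columns[self.intensities.columns.duplicated()]
            raise ValueError(f"duplicate intensity column labels: {list(dup)}")
        missing = [f for f in self.FLAG_NAMES if f not in self.flags.columns]
        if missing:
            raise ValueError(f"flags frame lacks columns: {missing}")
        if len(self.flags) != len(self.intensities):
            raise ValueError("flags must have one record per protein row")

    @property
    def protein_ids(self) -> pd.Index:
        return self.intensities.index

    @property
    def column_labels(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def n_proteins(self) -> int:
        return len(self.intensities)

    def short_label(self, column: str) -> str:
        """Sample label: the column name with the intensity prefix removed."""
        if self.column_prefix and column.startswith(self.column_prefix):
            return column[len(self.column_prefix):]
        return column


@dataclass
class Design:
    """Mapping of intensity columns to samples, groups and technical replicates.

    ``entries`` has one row per intensity column with columns
    ``column_label`` (full column name in the source table), ``label``
    (short sample label), ``sample_id`` (biological sample), ``group`` and
    nullable integer ``tech_rep``.
    """

    entries: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"column_label", "label", "sample_id", "group"}
        missing = required - set(self.entries.columns)
        if missing:
            raise ValueError(f"design entries lack columns: {sorted(missing)}")
        if "tech_rep" not in self.entries.columns:
            self.entries = self.entries.assign(tech_rep=pd.array([pd.NA] * len(self.entries), dtype="Int64"))
        self.entries = self.entries.reset_index(drop=True)
        if self.entries["column_label"].duplicated().any():
            dup = self.entries.loc[self.entries["column_label"].duplicated(), "column_label"]
            raise ValueError(f"design maps an intensity column twice: {list(dup)}")
        key = self.entries[["sample_id", "tech_rep"]].astype(object)
        if key.duplicated().any():
            dup = key[key.duplicated()].itertuples(index=False, name=None)
            raise ValueError(f"duplicate (sample_id, tech_rep) pairs: {list(dup)}")

    @property
    def groups(self) -> list[str]:
        """Distinct group labels in file order."""
        return list(dict.fromkeys(self.entries["group"]))

    @property
    def has_tech_reps(self) -> bool:
        return self.entries["tech_rep"].notna().any()

    def group_of_label(self) -> pd.Series:
        return pd.Series(self.entries["group"].to_numpy(), index=self.entries["label"])


@dataclass
class IntensityMatrix:
    """proteins x samples matrix of log2 intensities with NaN for missing.

    ``groups`` is a Series indexed by sample id giving each sample's group
    label; ``stage`` tags the processing state.  ``meta`` carries optional
    provenance (imputation parameters, per-column centres, ...).
    """

    values: pd.DataFrame
    groups: pd.Series
    stage: str = "raw"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"stage must be one of {STAGES}, got {self.stage!r}")
        if self.values.columns.duplicated().any():
            raise ValueError("sample ids must be unique")
        if list(self.groups.index) != list(self.values.columns):
            self.groups = self.groups.reindex(self.values.columns)
        if self.groups.isna().any():
            raise ValueError("every sample needs a group label")
        if np.isneginf(self.values.to_numpy()).any():
            raise ValueError("matrix contains -inf; zeros must become missing before log2")

    @property
    def protein_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s, g in self.groups.items() if g == group]

    def with_values(self, values: pd.DataFrame, stage: str | None = None, **meta) -> "IntensityMatrix":
        """Copy carrying new values (and optionally a new stage tag)."""
        return IntensityMatrix(
            values=values,
            groups=self.groups.copy(),
            stage=stage or self.stage,
            meta={**self.meta, **meta},
        )
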