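"""Filtering and transformation of raw protein tables into working matrices.

The raw table is cleaned in three steps mirroring standard label-free QC
practice: (1) drop contaminants, reverse-database decoys,
only-identified-by-site rows and proteins supported by too few unique
peptides, convert zero intensities to missing and move to the log2 scale;
(2) optionally average technical replicates per biological sample;
(3) drop proteins with too much missingness inside any group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd

from .data import Design, IntensityMatrix, ProteinGroupsTable

logger = logging.getLogger("lfqpipe.preprocess")

__all__ = ["FilterParams", "create_intensity_frame", "average_tech_reps", "filter_by_group_na"]


@dataclass
class FilterParams:
    """Row-filter thresholds.

    uniq_pep_min
        Keep proteins identified by at least this many unique peptides
        (default 3, i.e. remove proteins with two or fewer).
    max_group_na
        Largest tolerated missing-value fraction within any single group;
        proteins strictly above it in at least one group are removed.
    """

    uniq_pep_min: int = 3
    max_group_na: float = 0.34

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_group_na <= 1.0:
            raise ValueError("max_group_na must lie in [0, 1]")


def create_intensity_frame(
    table: ProteinGroupsTable,
    design: Design,
    params: FilterParams | None = None,
) -> IntensityMatrix:
    """Build the raw log2 intensity matrix from a parsed protein table.

    Removes flagged rows (contaminant / reverse / only-by-site) and
    proteins with fewer than ``params.uniq_pep_min`` unique peptides (the
    peptide filter is skipped, with a notice, when counts are unavailable).
    Zero intensities become missing; surviving values are log2-transformed.
    Columns are ordered and grouped per the design file.
    """
    params = params or FilterParams()
    flags = table.flags
    flagged = flags["is_contaminant"] | flags["is_reverse"] | flags["only_by_site"]
    for reason in ProteinGroupsTable.FLAG_NAMES:
        n = int(flags[reason].sum())
        if n:
            logger.info("removing %d proteins flagged %s", n, reason)
    keep = ~flagged
    if table.unique_peptides is not None:
        few = table.unique_peptides < params.uniq_pep_min
        logger.info(
            "removing %d proteins with < %d unique peptides",
            int((few & keep).sum()), params.uniq_pep_min,
        )
        keep &= ~few
    else:
        logger.info("unique-peptide counts unavailable; peptide filter skipped")
    if not keep.any():
        raise ValueError("no proteins survive filters")

    columns = list(design.entries["column_label"])
    values = table.intensities.loc[keep.to_numpy(), columns].copy()
    values.columns = list(design.entries["label"])
    arr = values.to_numpy(dtype=float)
    arr[arr == 0.0] = np.nan
    with np.errstate(invalid="ignore"):
        arr = np.log2(arr)
    values = pd.DataFrame(arr, index=values.index, columns=values.columns)
    groups = design.group_of_label()
    logger.info("raw matrix: %d proteins x %d columns", *values.shape)
    return IntensityMatrix(values=values, groups=groups, stage="raw")


def average_tech_reps(m: IntensityMatrix, design: Design) -> IntensityMatrix:
    """Average technical-replicate columns per biological sample.

    Means are taken on the log2 scale over observed values only; a sample
    whose replicates are all missing stays missing.
    """
    if not design.has_tech_reps:
        raise ValueError("design has no tech_rep information; nothing to average")
    if m.stage != "raw":
        raise ValueError("technical replicates are averaged on the raw matrix")
    sample_order = list(dict.fromkeys(design.entries["sample_id"]))
    out = {}
    groups = {}
    for sample in sample_order:
        rows = design.entries[design.entries["sample_id"] == sample]
        labels = [lab for lab in rows["label"] if lab in m.values.columns]
        out[sample] = m.values[labels].mean(axis=1, skipna=True).to_numpy()
        groups[sample] = rows["group"].iloc[0]
    values = pd.DataFrame(out, index=m.values.index)
    logger.info("averaged %d columns into %d biological samples", m.values.shape[1], values.shape[1])
    return IntensityMatrix(values=values, groups=pd.Series(groups), stage="raw", meta=dict(m.meta))


def filter_by_group_na(m: IntensityMatrix, params: FilterParams | None = None) -> IntensityMatrix:
    """Drop proteins whose missing fraction exceeds the cap in any group.

    A protein is retained iff, for every group, its within-group missing
    fraction is <= ``params.max_group_na``.  Fractions are compared as
    exact rationals so 1/3 vs 0.34 never hinges on float rounding.
    """
    params = params or FilterParams()
    cap = Fraction(str(params.max_group_na))
    keep = np.ones(len(m.values), dtype=bool)
    for group in dict.fromkeys(m.groups):
        samples = m.samples_in_group(group)
        miss = m.values[samples].isna().sum(axis=1).to_numpy()
        n = len(samples)
        over = np.array([Fraction(int(k), n) > cap for k in miss])
        keep &= ~over
    removed = int((~keep).sum())
    logger.info(
        "group-missingness filter (max %.0f%% per group): removed %d, retained %d",
        params.max_group_na * 100, removed, int(keep.sum()),
    )
    if not keep.any():
        logger.warning("no proteins survive the group-missingness filter")
    return m.with_values(m.values.loc[keep])
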