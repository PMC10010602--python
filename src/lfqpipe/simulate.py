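"""Synthetic label-free proteomics experiments with known ground truth.

The generator emulates the data model of a MaxQuant protein-level table:

* protein base abundances are log-normal (Normal on the log2 scale);
* a chosen subset of proteins carries a true group effect of magnitude
  ``effect_log2`` (random sign) in the second group;
* biological replicates add Normal(0, sigma_within) noise on log2;
  technical replicates scatter around their biological value with half
  the variance (tech reps are tighter than bio reps);
* dropout is intensity-dependent (left-censored, MNAR): the probability
  that a cell goes missing is a decreasing logistic function of its log2
  intensity, centred at a low quantile of all intensities; dropped cells
  are written as 0 on the linear scale, exactly as MaxQuant renders
  non-quantified proteins;
* decoy rows (contaminants, reverse-database hits, only-identified-by-site)
  are appended with their flags set, purely to exercise the row filters;
* unique-peptide counts are drawn per protein (real proteins 3-25,
  decoys 1-10).

Everything is reproducible under ``SimParams.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data import Design, ProteinGroupsTable

__all__ = ["SimParams", "SimTruth", "simulate_lfq_experiment", "write_protein_groups"]


@dataclass
class SimParams:
    """Generator settings; defaults give a small two-group LFQ experiment."""

    n_proteins: int = 500
    n_de: int = 50
    groups: tuple[str, str] = ("WT", "KO")
    bio_reps: int = 3
    tech_reps: int = 1
    effect_log2: float = 2.0
    sigma_within: float = 0.5
    base_mean: float = 25.0
    base_sd: float = 2.5
    mnar_center: float = 0.1
    mnar_steepness: float = 0.8
    dropout: bool = True
    contaminant_frac: float = 0.05
    reverse_frac: float = 0.05
    site_frac: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_de > self.n_proteins:
            raise ValueError("n_de cannot exceed n_proteins")
        for name in ("contaminant_frac", "reverse_frac", "site_frac"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0.0 < self.mnar_center < 1.0:
            raise ValueError("mnar_center must lie in (0, 1)")


@dataclass
class SimTruth:
    """Ground truth: per-protein effects and the per-cell dropout mask."""

    true_log2fc: pd.Series  # signed effect (group2 - group1), 0 for null proteins
    is_de: pd.Series
    censored: pd.DataFrame  # proteins x columns boolean dropout mask

    def __post_init__(self) -> None:
        mism = (self.true_log2fc.abs() > 0) != self.is_de
        if mism.any():
            raise ValueError("|true log2FC| > 0 must hold exactly for DE proteins")


def simulate_lfq_experiment(p: SimParams) -> tuple[ProteinGroupsTable, Design, SimTruth]:
    """Generate a protein table, matching design and ground truth."""
    rng = np.random.default_rng(p.seed)
    ga, gb = p.groups

    base = rng.normal(p.base_mean, p.base_sd, size=p.n_proteins)
    de_idx = rng.choice(p.n_proteins, size=p.n_de, replace=False)
    signs = rng.choice([-1.0, 1.0], size=p.n_de)
    effect = np.zeros(p.n_proteins)
    effect[de_idx] = signs * p.effect_log2

    columns: list[str] = []
    col_meta: list[dict] = []
    log2_cells = np.empty((p.n_proteins, 0))
    for group, shift in ((ga, 0.0), (gb, 1.0)):
        for b in range(1, p.bio_reps + 1):
            bio = base + shift * effect + rng.normal(0.0, p.sigma_within, size=p.n_proteins)
            sample_id = f"{group}_{b}"
            if p.tech_reps > 1:
                for t in range(1, p.tech_reps + 1):
                    tech = bio + rng.normal(0.0, p.sigma_within / np.sqrt(2.0), size=p.n_proteins)
                    columns.append(f"{sample_id}_{t}")
                    col_meta.append({"sample_id": sample_id, "group": group, "tech_rep": t})
                    log2_cells = np.c_[log2_cells, tech]
            else:
                columns.append(sample_id)
                col_meta.append({"sample_id": sample_id, "group": group, "tech_rep": None})
                log2_cells = np.c_[log2_cells, bio]

    # intensity-dependent dropout: logistic decreasing in log2 intensity
    if p.dropout:
        center = np.quantile(log2_cells, p.mnar_center)
        p_drop = 1.0 / (1.0 + np.exp(p.mnar_steepness * (log2_cells - center)))
        censored = rng.random(log2_cells.shape) < p_drop
    else:
        censored = np.zeros(log2_cells.shape, dtype=bool)

    linear = np.exp2(log2_cells)
    linear[censored] = 0.0

    protein_ids = [f"PROT{i:05d}" for i in range(p.n_proteins)]
    n_cont = int(round(p.contaminant_frac * p.n_proteins))
    n_rev = int(round(p.reverse_frac * p.n_proteins))
    n_site = int(round(p.site_frac * p.n_proteins))
    decoy_kinds = ["is_contaminant"] * n_cont + ["is_reverse"] * n_rev + ["only_by_site"] * n_site
    decoy_ids = [f"{'CON_' if k == 'is_contaminant' else 'REV_' if k == 'is_reverse' else 'SITE_'}{i:04d}"
                 for i, k in enumerate(decoy_kinds)]
    decoy_vals = np.exp2(
        rng.normal(p.base_mean, p.base_sd, size=(len(decoy_kinds), len(columns)))
        + rng.normal(0.0, p.sigma_within, size=(len(decoy_kinds), len(columns)))
    )

    all_ids = protein_ids + decoy_ids
    intensities = pd.DataFrame(
        np.vstack([linear, decoy_vals]) if len(decoy_kinds) else linear,
        index=pd.Index(all_ids, name="protein_id"),
        columns=columns,
    )
    flags = pd.DataFrame(False, index=intensities.index, columns=list(ProteinGroupsTable.FLAG_NAMES))
    for did, kind in zip(decoy_ids, decoy_kinds):
        flags.loc[did, kind] = True
    uniq = pd.Series(
        np.r_[rng.integers(3, 26, size=p.n_proteins), rng.integers(1, 11, size=len(decoy_kinds))],
        index=intensities.index,
    )

    table = ProteinGroupsTable(
        intensities=intensities, flags=flags, unique_peptides=uniq, column_prefix=""
    )
    entries = pd.DataFrame(
        {
            "column_label": columns,
            "label": columns,
            "sample_id": [cm["sample_id"] for cm in col_meta],
            "group": [cm["group"] for cm in col_meta],
            "tech_rep": pd.array([cm["tech_rep"] for cm in col_meta], dtype="Int64"),
        }
    )
    design = Design(entries=entries)
    truth = SimTruth(
        true_log2fc=pd.Series(effect, index=pd.Index(protein_ids, name="protein_id")),
        is_de=pd.Series(effect != 0.0, index=pd.Index(protein_ids, name="protein_id")),
        censored=pd.DataFrame(censored, index=protein_ids, columns=columns),
    )
    return table, design, truth


def write_protein_groups(t: ProteinGroupsTable, design: Design, path) -> tuple[Path, Path]:
    """Write a MaxQuant-dialect proteinGroups TSV plus its design TSV.

    Returns the (protein table path, design path).  Files round-trip
    through :func:`lfqpipe.io.read_protein_groups` /
    :func:`lfqpipe.io.read_design`.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    design_path = path.with_name(path.stem + "_design.tsv")

    frame = pd.DataFrame({"Majority protein IDs": t.intensities.index})
    for col in t.intensities.columns:
        vals = t.intensities[col]
        frame[f"LFQ intensity {col}"] = [
            "0" if v == 0 else format(float(v), ".17g") for v in vals
        ]
    if t.unique_peptides is not None:
        frame["Unique peptides"] = t.unique_peptides.to_numpy()
    for flag, colname in (
        ("is_contaminant", "Potential contaminant"),
        ("is_reverse", "Reverse"),
        ("only_by_site", "Only identified by site"),
    ):
        frame[colname] = np.where(t.flags[flag].to_numpy(), "+", "")
    frame.to_csv(path, sep="\t", index=False, lineterminator="\n")

    dsn = design.entries[["sample_id", "group", "tech_rep"]].copy()
    dsn.columns = ["sample", "group", "tech_rep"]
    if dsn["tech_rep"].isna().all():
        dsn = dsn.drop(columns="tech_rep")
    dsn.to_csv(design_path, sep="\t", index=False, lineterminator="\n")
    return path, design_path
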