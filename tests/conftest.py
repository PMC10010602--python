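"""Shared fixtures: toy files, simulated datasets, trained model sets.

Expensive fixtures (simulations, repeated-CV training) are session-scoped
so several tests can interrogate the same objects.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import lfqpipe as lp

TOY_PROTEIN_GROUPS = "\n".join([
    "Majority protein IDs\tLFQ intensity A\tLFQ intensity B\tReverse\t"
    "Potential contaminant\tOnly identified by site\tUnique peptides",
    "P1\t100\t200\t\t\t\t5",
    "P2\t300\t\t+\t\t\t4",
    "P3\t50\t60\t\t+\t\t2",
    "",
])

TOY_DESIGN = "sample\tgroup\nA\tctrl\nB\ttreat\n"


@pytest.fixture
def toy_pg_path(tmp_path):
    path = tmp_path / "proteinGroups.txt"
    path.write_text(TOY_PROTEIN_GROUPS)
    return path


@pytest.fixture
def toy_design_path(tmp_path):
    path = tmp_path / "design.tsv"
    path.write_text(TOY_DESIGN)
    return path


def make_matrix(values, groups, stage="raw", proteins=None, samples=None):
    """Quick IntensityMatrix from a 2-D array."""
    values = np.asarray(values, dtype=float)
    proteins = proteins or [f"P{i}" for i in range(values.shape[0])]
    samples = samples or [f"S{j}" for j in range(values.shape[1])]
    return lp.IntensityMatrix(
        values=pd.DataFrame(values, index=pd.Index(proteins, name="protein_id"),
                            columns=samples),
        groups=pd.Series(list(groups), index=samples),
        stage=stage,
    )


def make_design(samples, groups, tech_reps=None):
    entries = pd.DataFrame({
        "column_label": samples,
        "label": samples,
        "sample_id": samples,
        "group": list(groups),
    })
    if tech_reps is not None:
        entries["sample_id"] = [s.rsplit("_", 1)[0] for s in samples]
        entries["tech_rep"] = pd.array(tech_reps, dtype="Int64")
    return lp.Design(entries=entries)


@pytest.fixture(scope="session")
def sim_techreps():
    """Two-group experiment with 3 bio x 3 tech replicates (study shape)."""
    params = lp.SimParams(n_proteins=500, n_de=50, bio_reps=3, tech_reps=3, seed=11)
    table, design, truth = lp.simulate_lfq_experiment(params)
    return params, table, design, truth


@pytest.fixture(scope="session")
def separable_mf():
    """Linearly separable two-class blobs: centroid distance >> noise."""
    rng = np.random.default_rng(7)
    n, f = 30, 10
    a = rng.normal(0.0, 1.0, (n, f))
    b = rng.normal(6.0, 1.0, (n, f))
    feats = pd.DataFrame(
        np.vstack([a, b]),
        index=[f"S{i}" for i in range(2 * n)],
        columns=[f"P{j}" for j in range(f)],
    )
    labels = pd.Series(["healthy"] * n + ["disease"] * n, index=feats.index)
    return lp.ModelFrame(
        features=feats,
        labels=labels,
        classes=["healthy", "disease"],
        provenance=pd.DataFrame({"protein_id": feats.columns, "adj_p_value": 0.01}),
    )


@pytest.fixture(scope="session")
def separable_models(separable_mf):
    split = lp.split_data(separable_mf, seed=1)
    ms = lp.train_models(split, separable_mf, algorithms=lp.DEFAULT_ALGORITHMS,
                         k=10, repeats=3, seed=1)
    probs = lp.test_models(ms, split, separable_mf)
    return split, ms, probs


@pytest.fixture(scope="session")
def null_models():
    """Random features, permuted balanced labels: no signal to learn."""
    rng = np.random.default_rng(13)
    feats = pd.DataFrame(
        rng.normal(0.0, 1.0, (60, 20)),
        index=[f"S{i}" for i in range(60)],
        columns=[f"Q{j}" for j in range(20)],
    )
    labels = pd.Series(rng.permutation(["healthy"] * 30 + ["disease"] * 30),
                       index=feats.index)
    mf = lp.ModelFrame(
        features=feats, labels=labels, classes=["healthy", "disease"],
        provenance=pd.DataFrame({"protein_id": feats.columns, "adj_p_value": 0.01}),
    )
    split = lp.split_data(mf, seed=2)
    ms = lp.train_models(split, mf, algorithms=lp.DEFAULT_ALGORITHMS,
                         k=10, repeats=3, seed=2)
    return mf, split, ms


@pytest.fixture(scope="session")
def gaussian_null_de():
    """find_dep on no-effect Gaussian data: 2000 proteins, 3 vs 3."""
    rng = np.random.default_rng(42)
    cols = ["A_1", "A_2", "A_3", "B_1", "B_2", "B_3"]
    m = make_matrix(rng.normal(25.0, 1.0, (2000, 6)), ["A"] * 3 + ["B"] * 3,
                    stage="imputed", samples=cols)
    design = make_design(cols, ["A"] * 3 + ["B"] * 3)
    return lp.find_dep(m, design)
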