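"""Quantile normalization of intensity matrices.

Forces every sample (column) to share one intensity distribution: the
value at rank r in each column is replaced by the mean, across columns,
of the rank-r order statistics.  Tied values receive the mean of their
tied targets.  Columns containing missing values are mapped through
linear interpolation of the mean quantile function at the observed
entries' quantile positions; missing entries stay missing.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .data import IntensityMatrix

logger = logging.getLogger("lfqpipe.normalize")

__all__ = ["quantile_normalize"]


def _mean_quantile_function(values: pd.DataFrame, grid: np.ndarray) -> np.ndarray:
    curves = []
    for col in values.columns:
        obs = np.sort(values[col].dropna().to_numpy())
        if len(obs) == 1:
            curves.append(np.full_like(grid, obs[0]))
            continue
        pos = np.linspace(0.0, 1.0, len(obs))
        curves.append(np.interp(grid, pos, obs))
    return np.mean(curves, axis=0)


def quantile_normalize(m: IntensityMatrix) -> IntensityMatrix:
    """Quantile-normalize across samples, tolerating missing values.

    For complete data this is the textbook procedure (mean of order
    statistics, ties averaged).  Within-column rank order of observed
    values is preserved; sorted output columns are identical whenever the
    input is complete.
    """
    if m.stage not in ("raw", "imputed"):
        raise ValueError(f"cannot normalize a matrix at stage {m.stage!r}")
    if m.values.shape[1] < 2:
        logger.warning("single-column matrix: quantile normalization is a no-op")
        return m.with_values(m.values.copy(), stage="normalized")

    n_rows = m.values.shape[0]
    grid = np.linspace(0.0, 1.0, n_rows) if n_rows > 1 else np.array([0.5])
    qbar = _mean_quantile_function(m.values, grid)

    out = m.values.copy()
    for col in out.columns:
        colvals = out[col].to_numpy(copy=True)
        mask = ~np.isnan(colvals)
        obs = colvals[mask]
        n = len(obs)
        if n == 0:
            continue
        order = np.argsort(obs, kind="stable")
        pos = np.linspace(0.0, 1.0, n) if n > 1 else np.array([0.5])
        targets_sorted = np.interp(pos, grid, qbar)
        targets = np.empty(n)
        targets[order] = targets_sorted
        # ties: every occurrence of a tied value gets the mean of the
        # targets assigned to that value's order statistics
        frame = pd.DataFrame({"v": obs, "t": targets})
        targets = frame.groupby("v")["t"].transform("mean").to_numpy()
        colvals[mask] = targets
        out[col] = colvals
    return m.with_values(out, stage="normalized")
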