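"""Left-censored (MNAR) missing-value imputation.

Label-free intensity data lose values preferentially at low abundance:
a protein below the detection limit in one run yields a missing cell, so
missingness is left-censored rather than random.  The minimum-probability
("MinProb") strategy implemented here replaces each missing cell with a
draw from a Gaussian centred near the low tail of its sample's observed
intensity distribution:

    x_miss(i, j) ~ Normal(mu_j, sigma)

where ``mu_j`` is the q-th quantile (default q = 0.01) of column j's
observed values and ``sigma`` is ``tune_sigma`` times the median, over
proteins, of the per-protein standard deviation of observed values.
Observed cells are never touched.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import IntensityMatrix

logger = logging.getLogger("lfqpipe.impute")

__all__ = ["ImputeParams", "impute_minprob", "write_impute_record"]


@dataclass
class ImputeParams:
    """MinProb imputation parameters.

    q
        Quantile of each column's observed values used as the draw centre;
        small q places imputed values near the detection limit.
    tune_sigma
        Multiplier on the spread (median per-protein SD); 0 makes
        imputation deterministic at exactly the column quantile.
    seed
        Seed for the single generator used for all draws.
    """

    q: float = 0.01
    tune_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.q < 1.0:
            raise ValueError("q must lie strictly in (0, 1)")
        if self.tune_sigma < 0.0:
            raise ValueError("tune_sigma must be non-negative")


def _minprob_spread(values: pd.DataFrame) -> float:
    # median over proteins of the per-protein SD of observed values;
    # proteins with <2 observed values carry no spread information.
    sds = values.std(axis=1, ddof=1, skipna=True)
    sds = sds[values.notna().sum(axis=1) >= 2]
    return float(sds.median()) if len(sds) else 0.0


def impute_minprob(m: IntensityMatrix, params: ImputeParams | None = None) -> IntensityMatrix:
    """Impute every missing cell with a left-censored Gaussian draw.

    Draws are consumed column-major from one seeded generator, so results
    are bit-reproducible for a fixed seed regardless of missingness
    pattern elsewhere.  With ``tune_sigma=0`` every imputed value in
    column j equals exactly the q-quantile of that column.

    Raises
    ------
    ValueError
        If any column has fewer than two observed values (its quantile
        centre would be meaningless).
    """
    params = params or ImputeParams()
    if m.stage not in ("raw", "normalized"):
        raise ValueError(f"cannot impute a matrix at stage {m.stage!r}")
    observed_counts = m.values.notna().sum(axis=0)
    thin = observed_counts[observed_counts < 2]
    if len(thin):
        raise ValueError(
            f"column(s) with fewer than 2 observed values: {list(thin.index)}"
        )

    sigma = params.tune_sigma * _minprob_spread(m.values)
    rng = np.random.default_rng(params.seed)
    out = m.values.copy()
    centers: dict[str, float] = {}
    n_imputed = 0
    for col in out.columns:
        colvals = out[col]
        mu = float(np.quantile(colvals.dropna().to_numpy(), params.q))
        centers[col] = mu
        mask = colvals.isna().to_numpy()
        k = int(mask.sum())
        if k:
            draws = rng.normal(loc=mu, scale=sigma, size=k) if sigma > 0 else np.full(k, mu)
            arr = colvals.to_numpy(copy=True)
            arr[mask] = draws
            out[col] = arr
            n_imputed += k
    logger.info("imputed %d missing cells (sigma=%.4g)", n_imputed, sigma)
    return m.with_values(
        out,
        stage="imputed",
        impute=dict(
            method="minprob",
            q=params.q,
            tune_sigma=params.tune_sigma,
            seed=params.seed,
            sigma=sigma,
            centers=centers,
            n_imputed=n_imputed,
        ),
    )


def write_impute_record(m: IntensityMatrix, path) -> None:
    """Write the imputation sidecar JSON (seed, q, tune_sigma, mu_j, sigma)."""
    record = m.meta.get("impute")
    if record is None:
        raise ValueError("matrix carries no imputation record")
    with open(path, "w") as fh:
        json.dump(record, fh, indent=2, sort_keys=True)
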