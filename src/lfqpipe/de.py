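"""Two-group differential abundance testing with moderated t-statistics.

Model
-----
For protein g with complete log2 intensities in groups A (n_A samples) and
B (n_B samples):

* log2 fold change  ``beta_g = mean_A - mean_B``
* pooled residual variance ``s2_g`` on ``d = n_A + n_B - 2`` degrees of
  freedom, with unscaled standard-error factor ``v = 1/n_A + 1/n_B``.

The per-protein variances are then shrunk toward a common prior by
empirical Bayes.  Assuming ``s2_g ~ s0^2 * F(d, d0)`` marginally, the
hyperparameters (prior df ``d0``, prior variance ``s0^2``) are estimated
by moment-matching on ``e_g = log s2_g - psi(d/2) + log(d/2)``, whose
theoretical mean and variance involve the digamma/trigamma functions.
The posterior ("squeezed") variance is the precision-weighted blend

    s2_tilde_g = (d0 * s0^2 + d * s2_g) / (d0 + d)

and the moderated statistic ``t_g = beta_g / sqrt(s2_tilde_g * v)`` is
referred to a Student t distribution with ``d + d0`` degrees of freedom
(standard normal when ``d0`` is infinite).  The extra prior degrees of
freedom are what make moderated tests well behaved with 2-3 replicates
per group.

Significance follows the conventional volcano rule: |log2FC| > 1 and
Benjamini-Hochberg adjusted p < 0.05, both strict.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .data import Design, IntensityMatrix

logger = logging.getLogger("lfqpipe.de")

__all__ = [
    "GroupFit",
    "EBayesParams",
    "DEResult",
    "fit_group_model",
    "squeeze_variances",
    "moderated_t",
    "adjust_bh",
    "find_dep",
    "write_de_result",
    "read_de_result",
]


@dataclass
class GroupFit:
    """Per-protein two-group fit: means, log2FC, pooled variance."""

    protein_ids: pd.Index
    mean_a: np.ndarray
    mean_b: np.ndarray
    log2fc: np.ndarray
    s2: np.ndarray
    df_residual: int
    v: float
    contrast: tuple[str, str]


@dataclass
class EBayesParams:
    """Empirical-Bayes prior (d0, s0^2) and posterior variances."""

    d0: float
    s0_sq: float
    s2_post: np.ndarray


@dataclass
class DEResult:
    """Ranked differential-expression table with the thresholds applied."""

    table: pd.DataFrame  # protein_id, log2FC, t, p_value, adj_p_value, significant
    lfc_cut: float = 1.0
    adj_p_cut: float = 0.05
    contrast: tuple[str, str] = ("", "")
    eb: EBayesParams | None = field(default=None, repr=False)

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())

    def significant_ids(self) -> list[str]:
        return list(self.table.loc[self.table["significant"], "protein_id"])


def fit_group_model(
    m: IntensityMatrix,
    design: Design,
    contrast: tuple[str, str] | None = None,
) -> GroupFit:
    """Fit per-protein group means and pooled residual variance.

    The contrast direction is group1 - group2 where group1 is the first
    group in design-file order (or the pair named by ``contrast``).
    """
    if m.values.isna().any().any():
        raise ValueError("matrix contains missing values; impute before fitting")
    groups = design.groups
    if contrast is None:
        if len(groups) != 2:
            raise ValueError(
                f"matrix has groups {groups}; name a contrast pair for >2 groups"
            )
        contrast = (groups[0], groups[1])
    ga, gb = contrast
    cols_a = m.samples_in_group(ga)
    cols_b = m.samples_in_group(gb)
    n_a, n_b = len(cols_a), len(cols_b)
    if n_a < 2 or n_b < 2:
        raise ValueError(f"each group needs >=2 samples (got {ga}:{n_a}, {gb}:{n_b})")

    a = m.values[cols_a].to_numpy(dtype=float)
    b = m.values[cols_b].to_numpy(dtype=float)
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    d = n_a + n_b - 2
    ss = ((a - mean_a[:, None]) ** 2).sum(axis=1) + ((b - mean_b[:, None]) ** 2).sum(axis=1)
    return GroupFit(
        protein_ids=m.protein_ids,
        mean_a=mean_a,
        mean_b=mean_b,
        log2fc=mean_a - mean_b,
        s2=ss / d,
        df_residual=d,
        v=1.0 / n_a + 1.0 / n_b,
        contrast=contrast,
    )


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by damped Newton iteration."""
    if x <= 0:
        raise ValueError("trigamma inverse needs a positive argument")
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(100):
        tri = float(special.polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += dif
        if abs(dif) < 1e-8:
            break
    return y


def squeeze_variances(s2: np.ndarray, d: int) -> EBayesParams:
    """Estimate the variance prior and shrink each s2 toward it.

    Moment matching on ``e_g = log s2_g - psi(d/2) + log(d/2)``: with mean
    ``ebar`` and unbiased variance ``V`` of the finite e_g, set
    ``V' = V - psi'(d/2)``; if positive, ``d0 = 2 * psi'^{-1}(V')`` and
    ``s0^2 = exp(ebar + psi(d0/2) - log(d0/2))``, otherwise the prior is
    degenerate (``d0 = inf``, ``s0^2 = exp(ebar)``) and every posterior
    variance equals ``s0^2``.  Zero variances are excluded from the moment
    estimation but still shrunk.
    """
    s2 = np.asarray(s2, dtype=float)
    if (s2 < 0).any():
        raise ValueError("variances must be non-negative")
    if d < 1:
        raise ValueError("residual df must be >= 1")
    with np.errstate(divide="ignore"):
        e = np.log(s2) - special.digamma(d / 2.0) + math.log(d / 2.0)
    finite = np.isfinite(e)
    if finite.sum() < 2:
        raise ValueError("cannot estimate prior: fewer than 2 finite log-variances")
    ebar = float(e[finite].mean())
    v_e = float(e[finite].var(ddof=1))
    v_prime = v_e - float(special.polygamma(1, d / 2.0))
    if v_prime > 0:
        d0 = 2.0 * _trigamma_inverse(v_prime)
        s0_sq = math.exp(ebar + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0))
        s2_post = (d0 * s0_sq + d * s2) / (d0 + d)
    else:
        d0 = math.inf
        s0_sq = math.exp(ebar)
        s2_post = np.full_like(s2, s0_sq)
    logger.info("variance prior: d0=%.4g, s0^2=%.4g", d0, s0_sq)
    return EBayesParams(d0=d0, s0_sq=s0_sq, s2_post=s2_post)


def moderated_t(fit: GroupFit, eb: EBayesParams) -> tuple[np.ndarray, np.ndarray]:
    """Moderated t-statistics and two-sided p-values.

    ``t_g = beta_g / sqrt(s2_tilde_g * v)`` on ``d + d0`` degrees of
    freedom; a normal tail is used when ``d0`` is infinite.  Proteins with
    zero posterior variance get t = +/-inf and p = 0.
    """
    se = np.sqrt(eb.s2_post * fit.v)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, fit.log2fc / np.where(se > 0, se, 1.0), np.sign(fit.log2fc) * np.inf)
    t = np.where((se == 0) & (fit.log2fc == 0), 0.0, t)
    df_total = fit.df_residual + eb.d0
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df=df_total)
    p = np.where(np.isinf(t), 0.0, p)
    n_degenerate = int((se == 0).sum())
    if n_degenerate:
        logger.warning("%d proteins with zero posterior variance (t = +/-inf)", n_degenerate)
    return t, p


def adjust_bh(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    if len(p) == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def find_dep(
    m: IntensityMatrix,
    design: Design,
    lfc_cut: float = 1.0,
    adj_p_cut: float = 0.05,
    contrast: tuple[str, str] | None = None,
) -> DEResult:
    """Full differential-expression pipeline on a complete matrix.

    Fit group means -> squeeze variances -> moderated t -> BH adjustment.
    A protein is significant iff |log2FC| > ``lfc_cut`` AND adjusted
    p < ``adj_p_cut`` (both strict).  The result is sorted by adjusted p
    ascending, ties broken by |log2FC| descending then protein id.
    """
    fit = fit_group_model(m, design, contrast=contrast)
    eb = squeeze_variances(fit.s2, fit.df_residual)
    t, p = moderated_t(fit, eb)
    adj = adjust_bh(p)
    table = pd.DataFrame(
        {
            "protein_id": fit.protein_ids.to_numpy(),
            "log2FC": fit.log2fc,
            "t": t,
            "p_value": p,
            "adj_p_value": adj,
            "significant": (np.abs(fit.log2fc) > lfc_cut) & (adj < adj_p_cut),
        }
    )
    table["_abs_lfc"] = np.abs(table["log2FC"])
    table = table.sort_values(
        by=["adj_p_value", "_abs_lfc", "protein_id"],
        ascending=[True, False, True],
        kind="mergesort",
    ).drop(columns="_abs_lfc").reset_index(drop=True)
    result = DEResult(
        table=table, lfc_cut=lfc_cut, adj_p_cut=adj_p_cut, contrast=fit.contrast, eb=eb
    )
    logger.info(
        "find_dep: %d / %d proteins significant (|log2FC| > %g, adj p < %g; contrast %s - %s)",
        result.n_significant, len(table), lfc_cut, adj_p_cut, *fit.contrast,
    )
    return result


def write_de_result(de: DEResult, path) -> None:
    """Write the DE table as TSV with thresholds/contrast in '#' comments."""
    with open(path, "w", newline="\n") as fh:
        fh.write(f"# contrast: {de.contrast[0]} - {de.contrast[1]}\n")
        fh.write(f"# lfc_cut: {de.lfc_cut}\n")
        fh.write(f"# adj_p_cut: {de.adj_p_cut}\n")
        de.table.to_csv(fh, sep="\t", index=False)


def read_de_result(path) -> DEResult:
    """Read a TSV written by :func:`write_de_result`."""
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, value = line[1:].partition(":")
            meta[key.strip()] = value.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        table = pd.read_csv(fh, sep="\t")
    table["significant"] = table["significant"].astype(bool)
    contrast = tuple(s.strip() for s in meta.get("contrast", " - ").split(" - "))[:2]
    return DEResult(
        table=table,
        lfc_cut=float(meta.get("lfc_cut", 1.0)),
        adj_p_cut=float(meta.get("adj_p_cut", 0.05)),
        contrast=contrast,  # type: ignore[arg-type]
    )
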