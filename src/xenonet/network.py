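"""Weighted co-expression networks and differential connectivity.

One network is built per experimental group from the same genes.  A gene's
connectivity k is the sum of its adjacency weights (soft-powered
correlations) to all other genes; within each group the connectivities are
divided by the group's maximum so the two networks are on a comparable
[0, 1] scale.  The differential-connectivity statistic is

    K_diff = k_norm(treated) - k_norm(control)   in [-1, 1],

and genes with |K_diff| > 0.6 are flagged: positive values mark genes that
gained connectivity under treatment, negative values genes that were hubs
in the control network and lost their connections.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("xenonet")

__all__ = [
    "AdjacencyParams",
    "correlation_matrix",
    "pick_soft_power",
    "adjacency_connectivity",
    "diff_connectivity",
    "connectivity_from_expression",
]

DEFAULT_BETA = 6
DC_THRESHOLD = 0.6


@dataclass
class AdjacencyParams:
    """Soft-threshold adjacency parameters.

    unsigned: a_ij = |cor_ij|^beta;  signed: a_ij = ((1+cor_ij)/2)^beta.
    """

    beta: int = DEFAULT_BETA
    mode: str = "unsigned"
    correlation: str = "pearson"

    def __post_init__(self):
        if self.beta < 1:
            raise ValueError("beta must be >= 1")
        if self.mode not in ("unsigned", "signed"):
            raise ValueError("mode must be 'unsigned' or 'signed'")
        if self.correlation != "pearson":
            raise ValueError("only pearson correlation is supported")


def correlation_matrix(expr: pd.DataFrame) -> pd.DataFrame:
    """Gene-gene Pearson correlation of a gene x sample expression matrix."""
    if expr.shape[1] < 3:
        raise ValueError("need at least three samples")
    values = expr.to_numpy(float)
    sd = values.std(axis=1)
    constant = [g for g, s in zip(expr.index, sd) if s == 0]
    if constant:
        raise ValueError(
            f"constant genes have undefined correlations (QC should remove "
            f"them): {constant[:10]}"
        )
    cor = np.corrcoef(values)
    np.clip(cor, -1.0, 1.0, out=cor)
    return pd.DataFrame(cor, index=expr.index, columns=expr.index)


def pick_soft_power(
    cor: pd.DataFrame,
    candidate_betas=range(1, 21),
    r2_target: float = 0.8,
    n_bins: int = 10,
) -> int:
    """Smallest beta giving an approximately scale-free degree distribution.

    For each candidate power the connectivity distribution is binned and the
    linear fit of log10 frequency on log10 mean connectivity evaluated; the
    smallest beta with fit R^2 >= ``r2_target`` and negative slope wins.
    Falls back to beta=6 with a warning when no candidate qualifies.
    """
    candidates = sorted(candidate_betas)
    if cor.shape[0] < 30:
        raise ValueError("need at least 30 genes to assess scale-free fit")
    a = np.abs(cor.to_numpy(float))
    np.fill_diagonal(a, 0.0)
    for beta in candidates:
        k = (a**beta).sum(axis=1)
        if r2_target <= 0:
            return beta
        if k.max() <= 0:
            continue
        edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
        which = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
        freq = np.bincount(which, minlength=n_bins).astype(float)
        centers = np.array([k[which == b].mean() if freq[b] else np.nan
                            for b in range(n_bins)])
        ok = (freq > 0) & (centers > 0)
        if ok.sum() < 3:
            continue
        x, y = np.log10(centers[ok]), np.log10(freq[ok])
        if np.ptp(x) == 0:
            continue
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (slope * x + intercept)
        ss_tot = ((y - y.mean()) ** 2).sum()
        r2 = 1.0 - (resid**2).sum() / ss_tot if ss_tot > 0 else 0.0
        if r2 >= r2_target and slope < 0:
            return beta
    warnings.warn(
        f"no candidate beta reached scale-free fit R^2 >= {r2_target}; "
        f"falling back to beta={DEFAULT_BETA}",
        stacklevel=2,
    )
    return DEFAULT_BETA


def adjacency_connectivity(
    cor: pd.DataFrame, params: AdjacencyParams | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Soft-threshold adjacency and per-gene raw/max-normalized connectivity."""
    params = params or AdjacencyParams()
    values = cor.to_numpy(float)
    if values.shape[0] != values.shape[1] or not np.allclose(values, values.T, atol=1e-10):
        raise ValueError("correlation matrix must be square and symmetric")
    if params.mode == "unsigned":
        adj = np.abs(values) ** params.beta
    else:
        adj = ((1.0 + values) / 2.0) ** params.beta
    np.fill_diagonal(adj, 0.0)
    k_raw = adj.sum(axis=1)
    k_max = k_raw.max() if len(k_raw) else 0.0
    if k_max <= 0:
        raise ValueError("degenerate network: all connectivities are zero")
    table = pd.DataFrame(
        {"k_raw": k_raw, "k_norm": k_raw / k_max}, index=cor.index
    )
    table.index.name = "gene"
    adjacency = pd.DataFrame(adj, index=cor.index, columns=cor.columns)
    return adjacency, table


def connectivity_from_expression(
    expr: pd.DataFrame, params: AdjacencyParams | None = None
) -> pd.DataFrame:
    """Expression -> correlation -> connectivity table in one step."""
    _, table = adjacency_connectivity(correlation_matrix(expr), params)
    return table


def diff_connectivity(
    k_control: pd.DataFrame,
    k_treated: pd.DataFrame,
    threshold: float = DC_THRESHOLD,
) -> pd.DataFrame:
    """K_diff = k_norm(treated) - k_norm(control) with three-way calls.

    TREATED_HIGH iff K_diff > threshold; CONTROL_HIGH iff K_diff <
    -threshold (strict inequalities; exact ties are logged and NOT_DC).
    """
    genes_c, genes_t = set(k_control.index), set(k_treated.index)
    if genes_c != genes_t:
        diff = sorted(genes_c ^ genes_t)
        raise ValueError(f"gene sets differ between groups: {diff[:10]}")
    kt = k_treated["k_norm"].reindex(k_control.index)
    kc = k_control["k_norm"]
    k_diff = kt - kc
    dc_class = np.where(
        k_diff > threshold,
        "TREATED_HIGH",
        np.where(k_diff < -threshold, "CONTROL_HIGH", "NOT_DC"),
    )
    ties = int((np.abs(k_diff) == threshold).sum())
    if ties:
        logger.info("%d genes sit exactly at the |%.2f| boundary (NOT_DC)", ties, threshold)
    out = pd.DataFrame(
        {
            "k_norm_control": kc,
            "k_norm_treated": kt,
            "k_diff": k_diff,
            "dc_class": dc_class,
        },
        index=k_control.index,
    )
    out.index.name = "gene"
    return out
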