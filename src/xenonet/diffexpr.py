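"""Two-group negative-binomial differential expression.

A deliberately compact NB testing core in the DESeq2 mould: median-of-ratios
size factors, per-gene method-of-moments dispersion pooled within groups,
and a Wald test on the log2 ratio of normalized group means, with
Benjamini-Hochberg FDR control.  No dispersion shrinkage or trend fitting
is attempted; this is a transparent approximation, not a DESeq2 clone.

Calls use the thresholds adjP <= 0.1 and |log2FC| >= 0.58 (a 1.5-fold
change; log2(1.5) = 0.5849..., printed and applied as 0.58).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LOG2_FC_15",
    "size_factors",
    "dispersion_mom",
    "nb_wald",
    "bh_adjust",
    "call_de",
    "de_analysis",
]

LOG2_FC_15 = 0.5849625007211562  # log2(1.5); displayed as 0.58
DISPERSION_FLOOR = 1e-8


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Reference genes are those with no zero entry; each sample's factor is
    the median over reference genes of count / geometric-mean-count.
    """
    values = counts.to_numpy(float)
    positive = (values > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no gene has all-positive counts; supply size factors computed "
            "from a pseudo-reference instead"
        )
    ref = values[positive]
    log_geo = np.log(ref).mean(axis=1)
    ratios = np.log(ref) - log_geo[:, None]
    log_sf = np.median(ratios, axis=0)
    log_sf -= log_sf.mean()  # geometric mean 1
    return pd.Series(np.exp(log_sf), index=counts.columns, name="size_factor")


def _group_index(groups: pd.Series, counts: pd.DataFrame,
                 control: str, treated: str) -> tuple[np.ndarray, np.ndarray]:
    groups = pd.Series(groups)
    missing = [s for s in counts.columns if s not in groups.index]
    if missing:
        raise ValueError(f"group label missing for samples: {missing}")
    lab = groups.reindex(counts.columns)
    idx_c = np.flatnonzero((lab == control).to_numpy())
    idx_t = np.flatnonzero((lab == treated).to_numpy())
    if len(idx_c) == 0 or len(idx_t) == 0:
        raise ValueError(f"need samples in both groups {control!r} and {treated!r}")
    return idx_c, idx_t


def dispersion_mom(
    counts: pd.DataFrame,
    sf: pd.Series,
    groups: pd.Series,
    control: str = "control",
    treated: str = "treated",
    floor: float = DISPERSION_FLOOR,
) -> pd.Series:
    """Method-of-moments NB dispersion on normalized counts.

    alpha = max(floor, (pooled within-group variance - mean) / mean^2).
    """
    idx_c, idx_t = _group_index(groups, counts, control, treated)
    if len(idx_c) < 2 or len(idx_t) < 2:
        raise ValueError("need at least two samples per group")
    norm = counts.to_numpy(float) / pd.Series(sf).reindex(counts.columns).to_numpy()
    xc, xt = norm[:, idx_c], norm[:, idx_t]
    pooled_var = (
        (len(idx_c) - 1) * xc.var(axis=1, ddof=1)
        + (len(idx_t) - 1) * xt.var(axis=1, ddof=1)
    ) / (len(idx_c) + len(idx_t) - 2)
    mean = norm.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (pooled_var - mean) / mean**2
    alpha = np.where(np.isfinite(alpha), alpha, floor)
    return pd.Series(np.maximum(alpha, floor), index=counts.index, name="dispersion")


def nb_wald(
    counts: pd.DataFrame,
    sf: pd.Series,
    groups: pd.Series,
    dispersions: pd.Series,
    control: str = "control",
    treated: str = "treated",
    reference: str = "t",
) -> pd.DataFrame:
    """Per-gene Wald test of the treated-vs-control log2 fold change.

    The estimate is log2 of the ratio of normalized group means (with a 0.5
    pseudo-count when a group mean is zero); its standard error comes from
    the NB variance function var = mu + alpha mu^2 by the delta method.
    ``reference`` picks the null distribution of the Wald statistic:
    Student t with n_total - 2 degrees of freedom (default; calibrated at
    small n where the dispersion is estimated from the same few samples)
    or ``"normal"``.  Genes with all-zero counts in both groups are
    NOT_TESTED (NaN statistics).
    """
    if reference not in ("t", "normal"):
        raise ValueError("reference must be 't' or 'normal'")
    idx_c, idx_t = _group_index(groups, counts, control, treated)
    if len(idx_c) < 2 or len(idx_t) < 2:
        raise ValueError("need at least two samples per group")
    norm = counts.to_numpy(float) / pd.Series(sf).reindex(counts.columns).to_numpy()
    alpha = pd.Series(dispersions).reindex(counts.index).to_numpy(float)
    mc = norm[:, idx_c].mean(axis=1)
    mt = norm[:, idx_t].mean(axis=1)
    tested = ~((mc == 0) & (mt == 0))

    mc_eff = np.where(mc == 0, 0.5, mc)
    mt_eff = np.where(mt == 0, 0.5, mt)
    # zero in exactly one group: shift both means to keep the ratio honest
    one_zero = tested & ((mc == 0) | (mt == 0))
    mc_eff = np.where(one_zero, mc + 0.5, mc_eff)
    mt_eff = np.where(one_zero, mt + 0.5, mt_eff)

    log2fc = np.log2(mt_eff / mc_eff)
    vc = mc_eff + alpha * mc_eff**2
    vt = mt_eff + alpha * mt_eff**2
    se_ln = np.sqrt(vc / (len(idx_c) * mc_eff**2) + vt / (len(idx_t) * mt_eff**2))
    se = se_ln / np.log(2)
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = log2fc / se
    if reference == "t":
        df = len(idx_c) + len(idx_t) - 2
        p = 2.0 * stats.t.sf(np.abs(wald), df=df)
    else:
        p = 2.0 * stats.norm.sf(np.abs(wald))
    p = np.minimum(p, 1.0)

    out = pd.DataFrame(
        {
            "baseMean": norm.mean(axis=1),
            "log2FC": np.where(tested, log2fc, np.nan),
            "se": np.where(tested, se, np.nan),
            "p": np.where(tested, p, np.nan),
        },
        index=counts.index,
    )
    out.index.name = "gene"
    return out


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaN passed through).

    The multiple-testing universe is the non-NaN entries.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    q = p[mask]
    if np.any((q < 0) | (q > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(q)
    if m:
        order = np.argsort(q, kind="stable")
        ranked = q[order] * m / np.arange(1, m + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        adj = np.empty(m)
        adj[order] = np.minimum(ranked, 1.0)
        out[mask] = adj
    return out


def call_de(
    results: pd.DataFrame,
    padj_max: float = 0.1,
    min_abs_log2fc: float = 0.58,
) -> pd.DataFrame:
    """Attach BH-adjusted p-values and UP/DOWN/NOT_DE/NOT_TESTED calls."""
    out = results.copy()
    if "padj" not in out.columns:
        out["padj"] = bh_adjust(out["p"].to_numpy())
    call = np.where(
        out["p"].isna(),
        "NOT_TESTED",
        np.where(
            (out["padj"] <= padj_max) & (out["log2FC"] >= min_abs_log2fc),
            "UP",
            np.where(
                (out["padj"] <= padj_max) & (out["log2FC"] <= -min_abs_log2fc),
                "DOWN",
                "NOT_DE",
            ),
        ),
    )
    out["call"] = call
    return out


def de_analysis(
    counts: pd.DataFrame,
    groups: pd.Series,
    control: str = "control",
    treated: str = "treated",
    padj_max: float = 0.1,
    min_abs_log2fc: float = 0.58,
    reference: str = "t",
) -> pd.DataFrame:
    """Counts-to-calls convenience wrapper over the individual steps."""
    sf = size_factors(counts)
    disp = dispersion_mom(counts, sf, groups, control, treated)
    res = nb_wald(counts, sf, groups, disp, control, treated, reference)
    return call_de(res, padj_max=padj_max, min_abs_log2fc=min_abs_log2fc)
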