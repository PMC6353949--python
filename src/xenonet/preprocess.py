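"""Gene-level quality control and normalization ahead of network analysis.

Two exclusion rules are applied to a count matrix: genes with zero counts
in more than half of the samples (low-signal dropouts), and genes whose
mean count is below 10 while their standard deviation is below 5 (flat,
barely expressed genes that contribute little to a co-expression network).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["FilterReport", "network_qc_filter", "normalize_log"]


@dataclass
class FilterReport:
    n_input_genes: int
    n_removed_zero_rule: int
    n_removed_lowvar_rule: int
    n_kept: int
    reasons: dict[str, str] = field(default_factory=dict)  # removed gene -> rule

    def to_dict(self) -> dict:
        return {
            "n_input_genes": self.n_input_genes,
            "n_removed_zero_rule": self.n_removed_zero_rule,
            "n_removed_lowvar_rule": self.n_removed_lowvar_rule,
            "n_kept": self.n_kept,
        }


def network_qc_filter(
    counts: pd.DataFrame,
    mean_min: float = 10.0,
    sd_min: float = 5.0,
    combine: str = "and",
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the two QC exclusion rules, preserving gene order.

    A gene is removed when more than ``floor(n_samples/2)`` of its entries
    are zero, or when its mean is below ``mean_min`` and (default) its
    sample standard deviation is below ``sd_min``.  ``combine="or"`` turns
    the low-signal rule into a disjunction.  The first matching rule is
    the attributed removal reason.
    """
    if counts.shape[1] < 2:
        raise ValueError("need at least two samples")
    if combine not in ("and", "or"):
        raise ValueError("combine must be 'and' or 'or'")
    values = counts.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError("counts must be numeric integers")
    if np.any(values < 0):
        raise ValueError("counts must be non-negative")
    if not np.allclose(values, np.round(values)):
        raise ValueError("counts must be integers")

    n = counts.shape[1]
    n_zero = (values == 0).sum(axis=1)
    zero_rule = n_zero > n // 2
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    if combine == "and":
        lowvar_rule = (mean < mean_min) & (sd < sd_min)
    else:
        lowvar_rule = (mean < mean_min) | (sd < sd_min)

    reasons: dict[str, str] = {}
    for gene, z, lv in zip(counts.index, zero_rule, lowvar_rule):
        if z:
            reasons[gene] = "zero_rule"
        elif lv:
            reasons[gene] = "lowvar_rule"
    keep = ~(zero_rule | lowvar_rule)
    kept = counts.loc[keep]
    report = FilterReport(
        n_input_genes=len(counts),
        n_removed_zero_rule=int(zero_rule.sum()),
        n_removed_lowvar_rule=int((lowvar_rule & ~zero_rule).sum()),
        n_kept=int(keep.sum()),
        reasons=reasons,
    )
    return kept, report


def normalize_log(counts: pd.DataFrame, size_factors: pd.Series) -> pd.DataFrame:
    """log2(count / size_factor + 1) expression for network input."""
    sf = pd.Series(size_factors).reindex(counts.columns)
    if sf.isna().any():
        raise ValueError("size factor missing for some samples")
    if (sf <= 0).any():
        raise ValueError("size factors must be positive")
    return np.log2(counts.div(sf, axis=1) + 1.0)
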