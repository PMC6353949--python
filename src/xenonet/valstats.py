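"""Closed-form wet-lab validation statistics.

Caliper tumor volume, qPCR relative expression by the 2^-ddCt method, and
the two-sample t-test computed from printed group summaries (mean, SD, n).
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

__all__ = [
    "GroupSummary",
    "tumor_volume",
    "ddct_relative_expression",
    "ttest_from_summary",
]


@dataclass
class GroupSummary:
    """Published group summary; ``sd`` is the sample standard deviation
    unless the caller opts into an SEM interpretation at the test site."""

    mean: float
    sd: float
    n: int

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if self.n < 2:
            raise ValueError("n must be >= 2")


def tumor_volume(length: float, width: float) -> float:
    """Ellipsoid-approximation caliper volume: length x width^2 / 2 (mm^3)."""
    if length < 0 or width < 0:
        raise ValueError("length and width must be non-negative")
    return length * width * width / 2.0


def ddct_relative_expression(
    ct_target_treated: float,
    ct_ref_treated: float,
    ct_target_control: float,
    ct_ref_control: float,
) -> float:
    """2^-ddCt fold change of a target gene, reference-gene normalized."""
    ddct = (ct_target_treated - ct_ref_treated) - (
        ct_target_control - ct_ref_control
    )
    return 2.0 ** (-ddct)


def ttest_from_summary(
    a: GroupSummary, b: GroupSummary, variant: str = "student"
) -> tuple[float, float, float]:
    """(t, df, two-sided p) from two group summaries.

    ``student`` pools the variances (df = n_a + n_b - 2); ``welch`` uses
    the Satterthwaite degrees of freedom.  Two identical degenerate groups
    (both SD 0, equal means) give t = 0, p = 1 by convention.
    """
    if variant not in ("student", "welch"):
        raise ValueError("variant must be 'student' or 'welch'")
    if a.sd == 0 and b.sd == 0:
        if a.mean == b.mean:
            df = a.n + b.n - 2
            return 0.0, float(df), 1.0
        raise ValueError("zero variance in both groups with unequal means")
    va, vb = a.sd**2, b.sd**2
    if variant == "student":
        df = a.n + b.n - 2
        pooled = ((a.n - 1) * va + (b.n - 1) * vb) / df
        se = (pooled * (1 / a.n + 1 / b.n)) ** 0.5
    else:
        se = (va / a.n + vb / b.n) ** 0.5
        df = (va / a.n + vb / b.n) ** 2 / (
            (va / a.n) ** 2 / (a.n - 1) + (vb / b.n) ** 2 / (b.n - 1)
        )
    t = (a.mean - b.mean) / se
    p = 2.0 * stats.t.sf(abs(t), df=df)
    return float(t), float(df), float(min(p, 1.0))
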