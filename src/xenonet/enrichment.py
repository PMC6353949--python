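"""Hypergeometric over-representation analysis (ORA) of gene lists.

For a gene list of size n drawn from a background of N genes, a category
containing C background genes and overlapping the list in O genes is
scored with the exact hypergeometric upper tail P(X >= O), the expected
overlap E = n*C/N, and the enrichment ratio R = O/E; p-values across
categories are Benjamini-Hochberg adjusted.  A Poisson (and binomial)
tail is available for cross-checks in the small-E regime.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "ora_test",
    "ora_table",
    "poisson_upper_tail",
    "reconstruct_ratio",
]


def poisson_upper_tail(observed: int, expected: float) -> float:
    """P(X >= observed) for X ~ Poisson(expected).

    The small-E limit of the hypergeometric ORA tail; useful to cross-check
    printed enrichment p-values when only E (or O and R) is recoverable.
    """
    if observed < 0:
        raise ValueError("observed must be non-negative")
    if expected < 0:
        raise ValueError("expected must be non-negative")
    return float(stats.poisson.sf(observed - 1, expected))


@dataclass
class GeneSetCollection:
    """Named gene categories plus the background universe they live in."""

    sets: dict[str, frozenset] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)
    background_size: int | None = None  # genome-size override

    @property
    def universe(self) -> frozenset:
        out: set = set()
        for members in self.sets.values():
            out |= members
        return frozenset(out)

    def effective_background(self) -> int:
        return self.background_size or len(self.universe)


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file (name, description, members per tab-separated line)."""
    sets: dict[str, frozenset] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"GMT line {lineno} has {len(fields)} fields; expected >= 3"
                )
            name, desc, *members = fields
            members = [m for m in members if m]
            unique = frozenset(members)
            if len(unique) < len(members):
                warnings.warn(
                    f"duplicate genes in category {name!r} collapsed", stacklevel=2
                )
            if not unique:
                raise ValueError(f"GMT line {lineno}: category {name!r} is empty")
            sets[name] = unique
            descriptions[name] = desc
    if not sets:
        warnings.warn("empty GMT file: no categories read", stacklevel=2)
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def ora_test(
    n: int, N: int, C: int, O: int, mode: str = "hypergeometric"
) -> tuple[float, float | None, float]:
    """(E, R, rawP) for one category.

    E = n*C/N expected overlap, R = O/E (None when E = 0), rawP the
    upper-tail P(X >= O).  ``mode`` selects the exact hypergeometric tail
    (default) or its Poisson / binomial approximations.
    """
    if not (0 < n <= N):
        raise ValueError("need 0 < n <= N")
    if not (0 < C <= N):
        raise ValueError("need 0 < C <= N")
    if not (0 <= O <= min(n, C)):
        raise ValueError("need 0 <= O <= min(n, C)")
    E = n * C / N
    R = (O / E) if E > 0 else None
    if mode == "hypergeometric":
        raw_p = float(stats.hypergeom.sf(O - 1, N, C, n))
    elif mode == "poisson":
        raw_p = float(stats.poisson.sf(O - 1, E))
    elif mode == "binomial":
        raw_p = float(stats.binom.sf(O - 1, n, C / N))
    else:
        raise ValueError("mode must be hypergeometric, poisson or binomial")
    return E, R, min(raw_p, 1.0)


def ora_table(
    de_genes,
    collection: GeneSetCollection,
    padj_max: float = 0.1,
    min_overlap: int = 1,
    lenient: bool = False,
    mode: str = "hypergeometric",
) -> pd.DataFrame:
    """ORA over every category with overlap >= ``min_overlap``.

    ``de_genes`` must lie inside the background universe; under
    ``lenient=True`` outsiders are dropped with a warning instead of
    raising.  BH adjustment runs across the tested categories; rows are
    sorted by adjP then rawP and flagged significant at adjP <= padj_max.
    """
    gene_set = set(de_genes)
    if not gene_set:
        raise ValueError("empty gene set")
    universe = collection.universe
    outside = sorted(gene_set - universe)
    if outside:
        if lenient:
            warnings.warn(
                f"{len(outside)} query genes outside background dropped",
                stacklevel=2,
            )
            gene_set -= set(outside)
            if not gene_set:
                raise ValueError("empty gene set after dropping outsiders")
        else:
            raise ValueError(
                f"query genes missing from background: {outside[:10]}"
            )
    N = collection.effective_background()
    n = len(gene_set)
    rows = []
    for name, members in collection.sets.items():
        C = len(members)
        O = len(gene_set & members)
        if O < min_overlap:
            continue
        E, R, raw_p = ora_test(n, N, C, O, mode=mode)
        rows.append(
            {"category": name, "C": C, "O": O, "E": E, "R": R, "rawP": raw_p}
        )
    table = pd.DataFrame(
        rows, columns=["category", "C", "O", "E", "R", "rawP"]
    ).set_index("category")
    if len(table):
        table["adjP"] = bh_adjust(table["rawP"].to_numpy())
        table["significant"] = table["adjP"] <= padj_max
        table = table.sort_values(["adjP", "rawP"])
    else:
        table["adjP"] = pd.Series(dtype=float)
        table["significant"] = pd.Series(dtype=bool)
    return table


def reconstruct_ratio(rows: pd.DataFrame, tolerance: float = 0.01) -> dict:
    """Back out the common gene-set/background ratio implied by printed ORA rows.

    Each row with category size C, overlap O and enrichment ratio R implies
    n/N = (O/R)/C.  The mean implied ratio re-predicts every row's R as
    R_hat = O/(C*ratio); rows whose printed R deviates by more than
    ``tolerance`` (relative) are flagged inconsistent.
    """
    required = {"C", "O", "R"}
    if not required.issubset(rows.columns):
        raise ValueError(f"rows must carry columns {sorted(required)}")
    if len(rows) < 1:
        raise ValueError("need at least one row")
    if (rows["R"] <= 0).any():
        raise ValueError("R must be positive")
    implied = (rows["O"] / rows["R"]) / rows["C"]
    ratio = float(implied.mean())
    predicted = rows["O"] / (rows["C"] * ratio)
    deviation = (predicted - rows["R"]).abs() / rows["R"]
    report = pd.DataFrame(
        {
            "implied_ratio": implied,
            "predicted_R": predicted,
            "relative_deviation": deviation,
            "inconsistent": deviation > tolerance,
        },
        index=rows.index,
    )
    return {"ratio": ratio, "report": report}
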