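"""Species-of-origin read partitioning for xenograft libraries.

Each read of a mixed human/mouse library is aligned to both reference
genomes separately; reads aligning with equal similarity to both genomes
carry no species information and are discarded.  This module classifies
reads from a dual-alignment summary table, reports the class breakdown,
and accumulates species-specific gene counts from the retained reads.
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .synthetic import ALIGNMENT_COLUMNS, DualCountMatrices

__all__ = [
    "ReadClass",
    "PartitionReport",
    "classify_read",
    "partition_reads",
    "gene_counts",
    "read_alignment_table",
    "write_alignment_table",
    "read_alignments_sam",
]


class ReadClass(str, Enum):
    HUMAN_UNIQUE = "HUMAN_UNIQUE"
    MOUSE_UNIQUE = "MOUSE_UNIQUE"
    AMBIGUOUS = "AMBIGUOUS"
    UNMAPPED = "UNMAPPED"


@dataclass
class PartitionReport:
    """Read-class counts and percentages over one library."""

    counts: dict[str, int]
    total: int

    @property
    def percentages(self) -> dict[str, float]:
        if self.total == 0:
            return {k: 0.0 for k in self.counts}
        return {k: 100.0 * v / self.total for k, v in self.counts.items()}

    def to_dict(self) -> dict:
        return {
            "total_reads": self.total,
            "counts": dict(self.counts),
            "percentages": self.percentages,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _is_missing(score) -> bool:
    return score is None or (isinstance(score, float) and math.isnan(score))


def classify_read(
    mapped_h, score_h, mapped_m, score_m, margin: float = 0.0
) -> ReadClass:
    """Classify one read from its two single-genome alignment results.

    A read mapping to only one genome is unique to that species.  A read
    mapping to both is ambiguous when its two alignment scores differ by at
    most ``margin`` (equal similarity at the default margin 0), otherwise
    it is assigned to the higher-scoring species.
    """
    if margin < 0:
        raise ValueError("margin must be non-negative")
    mapped_h, mapped_m = bool(mapped_h), bool(mapped_m)
    if mapped_h and _is_missing(score_h):
        raise ValueError("read mapped to human but has no human score")
    if mapped_m and _is_missing(score_m):
        raise ValueError("read mapped to mouse but has no mouse score")
    if not mapped_h and not mapped_m:
        return ReadClass.UNMAPPED
    if mapped_h and not mapped_m:
        return ReadClass.HUMAN_UNIQUE
    if mapped_m and not mapped_h:
        return ReadClass.MOUSE_UNIQUE
    if abs(float(score_h) - float(score_m)) <= margin:
        return ReadClass.AMBIGUOUS
    return ReadClass.HUMAN_UNIQUE if score_h > score_m else ReadClass.MOUSE_UNIQUE


def partition_reads(
    table: pd.DataFrame,
    margin: float = 0.0,
    strict_dual_discard: bool = False,
) -> tuple[pd.Series, PartitionReport]:
    """Classify every read of an alignment table.

    ``strict_dual_discard=True`` discards any read mapping to both genomes
    regardless of score (the stronger filter-out variant of the workflow);
    the default compares scores and discards only equal-similarity reads.
    """
    if len(table) == 0:
        raise ValueError("no reads in alignment table")
    mh = table["mapped_human"].to_numpy().astype(bool)
    mm = table["mapped_mouse"].to_numpy().astype(bool)
    sh = pd.to_numeric(table["score_human"], errors="coerce").to_numpy(float)
    sm = pd.to_numeric(table["score_mouse"], errors="coerce").to_numpy(float)
    if np.any(mh & np.isnan(sh)):
        raise ValueError("read mapped to human but has no human score")
    if np.any(mm & np.isnan(sm)):
        raise ValueError("read mapped to mouse but has no mouse score")

    cls = np.full(len(table), ReadClass.UNMAPPED.value, dtype=object)
    cls[mh & ~mm] = ReadClass.HUMAN_UNIQUE.value
    cls[mm & ~mh] = ReadClass.MOUSE_UNIQUE.value
    both = mh & mm
    if strict_dual_discard:
        cls[both] = ReadClass.AMBIGUOUS.value
    else:
        with np.errstate(invalid="ignore"):
            tie = both & (np.abs(sh - sm) <= margin)
            hwin = both & ~tie & (sh > sm)
            mwin = both & ~tie & (sh < sm)
        cls[tie] = ReadClass.AMBIGUOUS.value
        cls[hwin] = ReadClass.HUMAN_UNIQUE.value
        cls[mwin] = ReadClass.MOUSE_UNIQUE.value

    assignments = pd.Series(cls, index=table["read_id"].to_numpy(), name="read_class")
    counts = {rc.value: int((cls == rc.value).sum()) for rc in ReadClass}
    report = PartitionReport(counts=counts, total=len(table))
    return assignments, report


def _split_genes(value) -> list[str]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return []
    text = str(value).strip()
    if not text:
        return []
    return [g for g in text.replace(";", ",").split(",") if g]


def gene_counts(
    assignments: pd.Series,
    table: pd.DataFrame,
    sample_name: str = "sample",
) -> tuple[DualCountMatrices, dict[str, int]]:
    """Accumulate single-sample gene counts from partitioned reads.

    Only species-unique reads count, each incrementing its annotated gene
    by one in that species' matrix.  Reads without a gene annotation are
    tallied as ``no_feature``; reads annotated to more than one gene in
    their species are tallied as ``ambiguous_feature``.  Both tallies are
    returned in the feature report alongside ``counted``.
    """
    known = set(table["read_id"])
    unknown = [r for r in assignments.index if r not in known]
    if unknown:
        raise ValueError(f"assignments reference unknown reads: {unknown[:5]}")
    tallies: Counter[str] = Counter(counted=0, no_feature=0, ambiguous_feature=0)
    per_species: dict[str, Counter] = {"human": Counter(), "mouse": Counter()}
    cls = assignments.reindex(table["read_id"]).to_numpy()
    for row_cls, gh, gm in zip(cls, table["gene_human"], table["gene_mouse"]):
        if row_cls == ReadClass.HUMAN_UNIQUE.value:
            species, genes = "human", _split_genes(gh)
        elif row_cls == ReadClass.MOUSE_UNIQUE.value:
            species, genes = "mouse", _split_genes(gm)
        else:
            continue
        if not genes:
            tallies["no_feature"] += 1
        elif len(genes) > 1:
            tallies["ambiguous_feature"] += 1
        else:
            per_species[species][genes[0]] += 1
            tallies["counted"] += 1
    frames = {}
    for species, counter in per_species.items():
        frame = pd.DataFrame(
            {sample_name: pd.Series(counter, dtype=int)}
        ).sort_index()
        frame.index.name = "gene_id"
        frames[species] = frame
    # share the sample axis even when one species saw no reads
    for species in frames:
        if frames[species].empty:
            frames[species] = pd.DataFrame(
                {sample_name: pd.Series(dtype=int)}
            )
            frames[species].index.name = "gene_id"
    return DualCountMatrices(human=frames["human"], mouse=frames["mouse"]), dict(tallies)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_alignment_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_alignment_table(path) -> pd.DataFrame:
    """Read the tab-separated dual-alignment summary (header required)."""
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in ALIGNMENT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"alignment table missing columns: {missing}")
    return table[ALIGNMENT_COLUMNS]


def read_alignments_sam(human_sam, mouse_sam) -> pd.DataFrame:
    """Build a dual-alignment table from two per-genome SAM files.

    Uses the ``AS`` alignment-score tag when present, falling back to the
    mapped flag with score 0.  Gene annotation is not recoverable from SAM;
    gene columns are left blank.  Requires pysam.
    """
    import pysam

    def scan(path):
        scores: dict[str, float] = {}
        with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
            for aln in fh:
                if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                    continue
                score = float(aln.get_tag("AS")) if aln.has_tag("AS") else 0.0
                prev = scores.get(aln.query_name)
                if prev is None or score > prev:
                    scores[aln.query_name] = score
        return scores

    hum, mus = scan(human_sam), scan(mouse_sam)
    ids = sorted(set(hum) | set(mus))
    return pd.DataFrame(
        {
            "read_id": ids,
            "mapped_human": [int(r in hum) for r in ids],
            "score_human": [hum.get(r, np.nan) for r in ids],
            "mapped_mouse": [int(r in mus) for r in ids],
            "score_mouse": [mus.get(r, np.nan) for r in ids],
            "gene_human": ["" for _ in ids],
            "gene_mouse": ["" for _ in ids],
        }
    )
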