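"""Synthetic dual-species RNA-seq data with planted ground truth.

A xenograft sequencing library mixes reads from the engrafted human tumor
cells and the murine host (the tumor microenvironment).  This module
generates the two kinds of input the downstream pipeline consumes —
per-read dual-genome alignment summaries and per-species count matrices —
together with a truth manifest recording every planted feature, so each
analysis stage can be validated against known structure without any
external data.

The count generator is a latent-factor negative-binomial model: a gene's
log2 mean expression is ``log2(baseline) + loading * factor[sample] +
noise_sd * eps`` where each co-expression module owns one latent factor per
sample.  Treatment effects are planted as additive log2 fold-change shifts;
connectivity rewiring replaces a gene's module factor with a private one in
the treated group; module destruction permutes each member gene's factor
contribution across treated samples.  Counts are drawn gamma-Poisson so
that variance = mu + dispersion * mu^2.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "TruthManifest",
    "DualCountMatrices",
    "simulate_alignment_table",
    "simulate_dual_counts",
    "write_truth_manifest",
    "read_truth_manifest",
    "largest_remainder_counts",
]

ALIGNMENT_COLUMNS = [
    "read_id",
    "mapped_human",
    "score_human",
    "mapped_mouse",
    "score_mouse",
    "gene_human",
    "gene_mouse",
]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic xenograft experiment.

    The read-class fractions default to the mixture observed in a
    human-in-mouse xenograft library: ~57% human-unique, ~30% mouse-unique,
    11% mapping equally well to both genomes, with the small remainder
    unmapped.  Group size defaults to 5 vs 5 (control vs treated tumors).
    """

    seed: int = 0
    # --- read-level simulation ---
    n_reads: int = 10_000
    frac_human_unique: float = 0.5724
    frac_mouse_unique: float = 0.2966
    frac_ambiguous: float = 0.11
    frac_unmapped: float = 0.021
    score_delta: int = 5          # score gap between genomes for unique reads
    # --- count-level simulation ---
    n_genes_per_species: int = 2000
    n_samples_per_group: int = 5
    n_modules: int = 4
    module_sizes: Sequence[int] = (150, 150, 150, 150)
    module_loading: float = 0.9   # log2-scale loading on the module factor
    noise_sd: float = 0.4         # log2-scale iid gene/sample noise
    n_de_genes: int = 100
    de_log2fc: float = 1.0
    n_rewired_genes: int = 0
    rewired_loading: float | None = None  # defaults to module_loading
    destroyed_modules: Sequence[int] = ()
    nb_dispersion: float = 0.05
    baseline_mean: float = 100.0

    def validate(self) -> None:
        fracs = (
            self.frac_human_unique,
            self.frac_mouse_unique,
            self.frac_ambiguous,
            self.frac_unmapped,
        )
        if any(f < 0 or f > 1 for f in fracs):
            raise ValueError("read-class fractions must lie in [0, 1]")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError(
                f"read-class fractions must sum to 1 (got {sum(fracs)!r})"
            )
        if self.n_reads < 0 or self.n_genes_per_species < 0:
            raise ValueError("counts must be non-negative")
        if self.n_samples_per_group < 1:
            raise ValueError("need at least one sample per group")
        if len(self.module_sizes) != self.n_modules:
            raise ValueError("module_sizes length must equal n_modules")
        if sum(self.module_sizes) > self.n_genes_per_species:
            raise ValueError("module sizes exceed n_genes_per_species")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be positive")
        if any(m < 0 or m >= self.n_modules for m in self.destroyed_modules):
            raise ValueError("destroyed_modules indices out of range")
        if self.n_de_genes > self.n_genes_per_species:
            raise ValueError("n_de_genes exceeds n_genes_per_species")
        if self.n_rewired_genes > sum(self.module_sizes):
            raise ValueError("rewired genes must be module members")


@dataclass
class TruthManifest:
    """Planted ground truth for one simulation.

    ``reads`` maps read id to its true class; ``genes`` holds one record per
    simulated gene (species, DE status and true log2FC, module label in each
    group, rewired flag); ``modules`` holds one record per planted module
    (species, label, destroyed flag).
    """

    reads: dict[str, str] = field(default_factory=dict)
    genes: dict[str, dict] = field(default_factory=dict)
    modules: dict[str, dict] = field(default_factory=dict)

    def __eq__(self, other) -> bool:  # field-for-field
        if not isinstance(other, TruthManifest):
            return NotImplemented
        return (
            self.reads == other.reads
            and self.genes == other.genes
            and self.modules == other.modules
        )


@dataclass
class DualCountMatrices:
    """Gene x sample integer counts for the two species on a shared sample axis."""

    human: pd.DataFrame
    mouse: pd.DataFrame

    def __post_init__(self):
        if not self.human.columns.equals(self.mouse.columns):
            raise ValueError("human and mouse matrices must share the sample axis")


def largest_remainder_counts(fractions: Sequence[float], total: int) -> list[int]:
    """Apportion ``total`` into integer counts proportional to ``fractions``.

    Largest-remainder (Hamilton) rounding: exact totals, no sampling error.
    Ties in remainder are broken by position for determinism.
    """
    quotas = [f * total for f in fractions]
    counts = [math.floor(q) for q in quotas]
    short = total - sum(counts)
    remainders = sorted(
        range(len(fractions)), key=lambda i: (-(quotas[i] - counts[i]), i)
    )
    for i in remainders[:short]:
        counts[i] += 1
    return counts


# ---------------------------------------------------------------------------
# read-level simulation
# ---------------------------------------------------------------------------

def simulate_alignment_table(config: SimulationConfig) -> tuple[pd.DataFrame, TruthManifest]:
    """Simulate a per-read dual-genome alignment summary table.

    Each read is allocated deterministically (largest-remainder) to one of
    the four classes so the class proportions match the configuration
    exactly.  Human-unique reads either fail to map to mouse or map with a
    score lower by ``score_delta``; ambiguous reads carry equal integer
    scores in both genomes; unmapped reads map to neither.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_reads
    n_h, n_m, n_a, n_u = largest_remainder_counts(
        [
            config.frac_human_unique,
            config.frac_mouse_unique,
            config.frac_ambiguous,
            config.frac_unmapped,
        ],
        n,
    )
    classes = np.array(
        ["HUMAN_UNIQUE"] * n_h + ["MOUSE_UNIQUE"] * n_m
        + ["AMBIGUOUS"] * n_a + ["UNMAPPED"] * n_u
    )
    rng.shuffle(classes)

    width = max(6, len(str(n)))
    read_ids = np.array([f"read_{i:0{width}d}" for i in range(n)])
    n_genes = max(config.n_genes_per_species, 1)
    hum_genes = np.array([f"hsa_g{i:05d}" for i in range(n_genes)])
    mus_genes = np.array([f"mmu_g{i:05d}" for i in range(n_genes)])

    base = rng.integers(60, 101, size=n)
    rows: dict[str, np.ndarray] = {
        "read_id": read_ids,
        "mapped_human": np.zeros(n, dtype=int),
        "score_human": np.full(n, np.nan),
        "mapped_mouse": np.zeros(n, dtype=int),
        "score_mouse": np.full(n, np.nan),
        "gene_human": np.full(n, "", dtype=object),
        "gene_mouse": np.full(n, "", dtype=object),
    }
    cross_maps = rng.random(n) < 0.5  # unique reads that also map to the other genome
    gh = rng.integers(0, n_genes, size=n)
    gm = rng.integers(0, n_genes, size=n)

    is_h = classes == "HUMAN_UNIQUE"
    rows["mapped_human"][is_h] = 1
    rows["score_human"][is_h] = base[is_h]
    rows["gene_human"][is_h] = hum_genes[gh[is_h]]
    hx = is_h & cross_maps
    rows["mapped_mouse"][hx] = 1
    rows["score_mouse"][hx] = base[hx] - config.score_delta
    rows["gene_mouse"][hx] = mus_genes[gm[hx]]

    is_m = classes == "MOUSE_UNIQUE"
    rows["mapped_mouse"][is_m] = 1
    rows["score_mouse"][is_m] = base[is_m]
    rows["gene_mouse"][is_m] = mus_genes[gm[is_m]]
    mx = is_m & cross_maps
    rows["mapped_human"][mx] = 1
    rows["score_human"][mx] = base[mx] - config.score_delta
    rows["gene_human"][mx] = hum_genes[gh[mx]]

    is_a = classes == "AMBIGUOUS"
    rows["mapped_human"][is_a] = 1
    rows["mapped_mouse"][is_a] = 1
    rows["score_human"][is_a] = base[is_a]
    rows["score_mouse"][is_a] = base[is_a]
    rows["gene_human"][is_a] = hum_genes[gh[is_a]]
    rows["gene_mouse"][is_a] = mus_genes[gm[is_a]]

    table = pd.DataFrame(rows, columns=ALIGNMENT_COLUMNS)
    manifest = TruthManifest(reads=dict(zip(read_ids, classes)))
    return table, manifest


# ---------------------------------------------------------------------------
# count-level simulation
# ---------------------------------------------------------------------------

def _module_labels(config: SimulationConfig) -> np.ndarray:
    lab = np.full(config.n_genes_per_species, -1, dtype=int)
    g = 0
    for m, size in enumerate(config.module_sizes):
        lab[g : g + size] = m
        g += size
    return lab


def _simulate_species_counts(
    config: SimulationConfig, rng: np.random.Generator, prefix: str
) -> tuple[pd.DataFrame, dict[str, dict], dict[str, dict]]:
    p = config.n_genes_per_species
    n = config.n_samples_per_group
    labels = _module_labels(config)
    module_genes = np.flatnonzero(labels >= 0)
    gene_ids = [f"{prefix}_g{i:05d}" for i in range(p)]
    samples = [f"C{j+1}" for j in range(n)] + [f"T{j+1}" for j in range(n)]

    de_idx = rng.choice(p, size=config.n_de_genes, replace=False) if config.n_de_genes else np.array([], dtype=int)
    if config.n_rewired_genes:
        rew_idx = rng.choice(module_genes, size=config.n_rewired_genes, replace=False)
    else:
        rew_idx = np.array([], dtype=int)
    is_de = np.zeros(p, bool)
    is_de[de_idx] = True
    is_rew = np.zeros(p, bool)
    is_rew[rew_idx] = True
    destroyed = set(config.destroyed_modules)
    a = config.module_loading
    a_rew = config.rewired_loading if config.rewired_loading is not None else a

    log_mu = np.empty((p, 2 * n))
    for g_off, group in ((0, "control"), (n, "treated")):
        factors = rng.standard_normal((max(config.n_modules, 1), n))
        eps = rng.standard_normal((p, n))
        L = math.log2(config.baseline_mean) + config.noise_sd * eps
        for m in range(config.n_modules):
            members = labels == m
            contrib = np.outer(np.full(members.sum(), a), factors[m])
            if group == "treated" and m in destroyed:
                # permute each member gene's factor contribution across samples
                for r in range(contrib.shape[0]):
                    contrib[r] = contrib[r, rng.permutation(n)]
            L[members] += contrib
        if group == "treated":
            if len(rew_idx):
                # private factor per rewired gene replaces the module factor
                L[rew_idx] = (
                    math.log2(config.baseline_mean)
                    + config.noise_sd * rng.standard_normal((len(rew_idx), n))
                    + a_rew * rng.standard_normal((len(rew_idx), n))
                )
            L[de_idx] += config.de_log2fc
        log_mu[:, g_off : g_off + n] = L

    mu = np.exp2(log_mu)
    alpha = config.nb_dispersion
    lam = rng.gamma(1.0 / alpha, alpha * mu) if alpha > 1e-8 else mu
    counts = rng.poisson(lam)
    frame = pd.DataFrame(counts, index=gene_ids, columns=samples)
    frame.index.name = "gene_id"

    color = ["m%d" % m for m in range(config.n_modules)]
    genes = {}
    for i, gid in enumerate(gene_ids):
        m = int(labels[i])
        mod = color[m] if m >= 0 else "none"
        mod_treated = mod
        if m in destroyed or is_rew[i]:
            mod_treated = "none"
        genes[gid] = {
            "species": prefix,
            "de": bool(is_de[i]),
            "log2fc": float(config.de_log2fc) if is_de[i] else 0.0,
            "module_control": mod,
            "module_treated": mod_treated,
            "rewired": bool(is_rew[i]),
        }
    modules = {
        f"{prefix}:{color[m]}": {
            "species": prefix,
            "label": color[m],
            "size": int(config.module_sizes[m]),
            "destroyed": m in destroyed,
        }
        for m in range(config.n_modules)
    }
    return frame, genes, modules


def simulate_dual_counts(config: SimulationConfig) -> tuple[DualCountMatrices, TruthManifest]:
    """Simulate human and mouse count matrices over a shared 2n-sample axis.

    Samples C1..Cn are controls, T1..Tn treated.  The two species are drawn
    independently (separate latent factors) from the same configuration.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    rng_h = np.random.default_rng(rng.integers(2**31))
    rng_m = np.random.default_rng(rng.integers(2**31))
    human, genes_h, mods_h = _simulate_species_counts(config, rng_h, "hsa")
    mouse, genes_m, mods_m = _simulate_species_counts(config, rng_m, "mmu")
    manifest = TruthManifest(
        genes={**genes_h, **genes_m}, modules={**mods_h, **mods_m}
    )
    return DualCountMatrices(human=human, mouse=mouse), manifest


# ---------------------------------------------------------------------------
# truth-manifest persistence (JSON lines, one record per line)
# ---------------------------------------------------------------------------

def write_truth_manifest(manifest: TruthManifest, path) -> None:
    """Write a manifest as JSON-lines; one flat record per read/gene/module."""
    with open(path, "w") as fh:
        for rid, cls in manifest.reads.items():
            fh.write(json.dumps({"record": "read", "id": rid, "class": cls}) + "\n")
        for gid, rec in manifest.genes.items():
            fh.write(json.dumps({"record": "gene", "id": gid, **rec}) + "\n")
        for mid, rec in manifest.modules.items():
            fh.write(json.dumps({"record": "module", "id": mid, **rec}) + "\n")


def read_truth_manifest(path) -> TruthManifest:
    """Parse a JSON-lines manifest; malformed lines raise with their number."""
    manifest = TruthManifest()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
                kind = rec.pop("record")
                rid = rec.pop("id")
            except (json.JSONDecodeError, KeyError) as exc:
                raise ValueError(
                    f"malformed manifest record at line {lineno}: {line[:80]!r}"
                ) from exc
            if kind == "read":
                manifest.reads[rid] = rec["class"]
            elif kind == "gene":
                manifest.genes[rid] = rec
            elif kind == "module":
                manifest.modules[rid] = rec
            else:
                raise ValueError(
                    f"unknown record type {kind!r} at line {lineno}"
                )
    return manifest
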