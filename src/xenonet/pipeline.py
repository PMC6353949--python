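"""End-to-end orchestration of the xenograft co-expression analysis.

Stage order mirrors the analysis itself: simulate (or load) inputs,
partition reads by species, QC-filter the count matrices, call
differential expression, build the per-group networks and K_diff, detect
and score modules, and run over-representation analysis on the DE genes.
Every stage consumes only prior-stage outputs; a single global seed fans
out to per-stage seeds (stage_seed = (1000*seed + stage_index) mod 2^31)
so each stage is individually reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import time
from dataclasses import dataclass, field

import pandas as pd

from . import diffexpr, enrichment, modules as modmod, network, preprocess
from .partition import gene_counts, partition_reads, read_alignment_table
from .synthetic import (
    DualCountMatrices,
    SimulationConfig,
    simulate_alignment_table,
    simulate_dual_counts,
    write_truth_manifest,
)

logger = logging.getLogger("xenonet")

__all__ = [
    "PipelineConfig",
    "PipelineReport",
    "run_pipeline",
    "write_report",
    "validate_report",
    "stage_seed",
]

STAGES = ["simulate", "partition", "filter", "de", "network", "modules", "ora"]

REPORT_SCHEMA = {
    "required": ["seed", "parameters", "stages"],
    "stage_required": ["status"],
}


@dataclass
class PipelineConfig:
    """All stage parameters plus input/output paths for one run."""

    out_dir: str = "xenonet_out"
    seed: int = 0
    # inputs: either simulate, or point at existing files
    simulate: bool = True
    sim: SimulationConfig | None = None
    alignments: str | None = None
    counts_human: str | None = None
    counts_mouse: str | None = None
    # stage parameters
    margin: float = 0.0
    strict_dual_discard: bool = False
    mean_min: float = 10.0
    sd_min: float = 5.0
    combine: str = "and"
    padj_max: float = 0.1
    lfc_min: float = 0.58
    beta: int | str = "auto"
    adjacency_mode: str = "unsigned"
    dc_threshold: float = 0.6
    top_m: int = 3000
    min_module_size: int = 20
    cut_height: float = 0.995
    merge_r: float = 0.9
    n_perm: int = 100
    gmt: str | None = None

    def validate(self) -> None:
        if not self.simulate and self.counts_human is None and self.alignments is None:
            raise ValueError("no inputs: either simulate or provide files")
        if not 0 < self.padj_max <= 1:
            raise ValueError("padj_max must be in (0, 1]")
        if self.dc_threshold < 0 or self.dc_threshold > 1:
            raise ValueError("dc_threshold must be in [0, 1]")
        if isinstance(self.beta, str) and self.beta != "auto":
            raise ValueError("beta must be an integer or 'auto'")


@dataclass
class PipelineReport:
    seed: int
    parameters: dict
    stages: dict = field(default_factory=dict)
    timings: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "parameters": self.parameters,
            "stages": self.stages,
            "timings": self.timings,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineReport":
        return cls(
            seed=d["seed"],
            parameters=d["parameters"],
            stages=d["stages"],
            timings=d.get("timings", {}),
        )


def stage_seed(seed: int, stage: str) -> int:
    return (1000 * seed + STAGES.index(stage)) % 2**31


def _atomic_write_tsv(frame: pd.DataFrame, path: str, **kwargs) -> None:
    tmp = f"{path}.tmp"
    frame.to_csv(tmp, sep="\t", **kwargs)
    os.replace(tmp, path)


def _atomic_write_json(obj, path: str) -> None:
    tmp = f"{path}.tmp"
    with open(tmp, "w") as fh:
        json.dump(obj, fh, indent=2, default=str)
    os.replace(tmp, path)


def _groups_from_columns(columns) -> pd.Series:
    labels = {}
    for c in columns:
        if str(c).startswith("C"):
            labels[c] = "control"
        elif str(c).startswith("T"):
            labels[c] = "treated"
        else:
            raise ValueError(
                f"cannot infer group for sample {c!r}: columns must be "
                "C* (control) or T* (treated)"
            )
    return pd.Series(labels)


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Run every applicable stage; see module docstring for the order."""
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    params = dataclasses.asdict(config)
    report = PipelineReport(seed=config.seed, parameters=params)

    def record(stage: str, started: float, **payload) -> None:
        report.stages[stage] = {"status": "ok", **payload}
        report.timings[stage] = time.perf_counter() - started

    # --- simulate -----------------------------------------------------
    t0 = time.perf_counter()
    alignment_table = None
    if config.simulate:
        sim = config.sim or SimulationConfig()
        sim = dataclasses.replace(sim, seed=stage_seed(config.seed, "simulate"))
        alignment_table, read_truth = simulate_alignment_table(sim)
        dual, truth = simulate_dual_counts(sim)
        truth.reads = read_truth.reads
        _atomic_write_tsv(dual.human, os.path.join(config.out_dir, "counts_human.tsv"))
        _atomic_write_tsv(dual.mouse, os.path.join(config.out_dir, "counts_mouse.tsv"))
        tmp = os.path.join(config.out_dir, "truth_manifest.jsonl.tmp")
        write_truth_manifest(truth, tmp)
        os.replace(tmp, os.path.join(config.out_dir, "truth_manifest.jsonl"))
        alignment_table.to_csv(
            os.path.join(config.out_dir, "alignments.tsv"), sep="\t", index=False
        )
        record(
            "simulate",
            t0,
            n_reads=int(len(alignment_table)),
            n_genes_per_species=sim.n_genes_per_species,
            n_samples_per_group=sim.n_samples_per_group,
        )
    else:
        dual = None
        if config.counts_human and config.counts_mouse:
            dual = DualCountMatrices(
                human=pd.read_csv(config.counts_human, sep="\t", index_col=0),
                mouse=pd.read_csv(config.counts_mouse, sep="\t", index_col=0),
            )
        if config.alignments:
            alignment_table = read_alignment_table(config.alignments)
        report.stages["simulate"] = {"status": "skipped"}

    # --- partition ----------------------------------------------------
    t0 = time.perf_counter()
    if alignment_table is not None:
        assignments, preport = partition_reads(
            alignment_table,
            margin=config.margin,
            strict_dual_discard=config.strict_dual_discard,
        )
        single_sample, feature_report = gene_counts(assignments, alignment_table)
        _atomic_write_json(
            preport.to_dict(), os.path.join(config.out_dir, "partition_report.json")
        )
        _atomic_write_tsv(
            single_sample.human,
            os.path.join(config.out_dir, "partition_counts_human.tsv"),
        )
        _atomic_write_tsv(
            single_sample.mouse,
            os.path.join(config.out_dir, "partition_counts_mouse.tsv"),
        )
        record(
            "partition", t0, report=preport.to_dict(), features=feature_report
        )
        if dual is None:
            # single-library run: no multi-sample matrices to analyze further
            for stage in STAGES[2:]:
                report.stages[stage] = {"status": "skipped"}
            return report
    else:
        report.stages["partition"] = {"status": "skipped"}
    if dual is None:
        raise ValueError("stage 'filter': no count matrices available")

    species_counts = {"human": dual.human, "mouse": dual.mouse}

    # --- filter -------------------------------------------------------
    t0 = time.perf_counter()
    kept: dict[str, pd.DataFrame] = {}
    filter_summary = {}
    for sp, counts in species_counts.items():
        kept[sp], frep = preprocess.network_qc_filter(
            counts, mean_min=config.mean_min, sd_min=config.sd_min,
            combine=config.combine,
        )
        filter_summary[sp] = frep.to_dict()
        _atomic_write_tsv(
            kept[sp], os.path.join(config.out_dir, f"filtered_counts_{sp}.tsv")
        )
    record("filter", t0, **filter_summary)

    # --- differential expression ---------------------------------------
    t0 = time.perf_counter()
    de_summary = {}
    de_results: dict[str, pd.DataFrame] = {}
    for sp, counts in kept.items():
        groups = _groups_from_columns(counts.columns)
        res = diffexpr.de_analysis(
            counts, groups, padj_max=config.padj_max,
            min_abs_log2fc=config.lfc_min,
        )
        de_results[sp] = res
        _atomic_write_tsv(res, os.path.join(config.out_dir, f"de_{sp}.tsv"))
        de_summary[sp] = res["call"].value_counts().to_dict()
    record("de", t0, **{sp: {"calls": v} for sp, v in de_summary.items()})

    # --- network / differential connectivity ---------------------------
    t0 = time.perf_counter()
    net_summary = {}
    conn: dict[str, dict[str, pd.DataFrame]] = {}
    expr_groups: dict[str, dict[str, pd.DataFrame]] = {}
    for sp, counts in kept.items():
        groups = _groups_from_columns(counts.columns)
        sf = diffexpr.size_factors(counts)
        expr = preprocess.normalize_log(counts, sf)
        ctrl = expr.loc[:, groups[expr.columns] == "control"]
        trt = expr.loc[:, groups[expr.columns] == "treated"]
        cor_c = network.correlation_matrix(ctrl)
        beta = (
            network.pick_soft_power(cor_c)
            if config.beta == "auto"
            else int(config.beta)
        )
        params = network.AdjacencyParams(beta=beta, mode=config.adjacency_mode)
        _, tab_c = network.adjacency_connectivity(cor_c, params)
        _, tab_t = network.adjacency_connectivity(
            network.correlation_matrix(trt), params
        )
        kdiff = network.diff_connectivity(tab_c, tab_t, threshold=config.dc_threshold)
        kdiff.insert(0, "k_raw_control", tab_c["k_raw"])
        kdiff.insert(1, "k_raw_treated", tab_t["k_raw"])
        _atomic_write_tsv(kdiff, os.path.join(config.out_dir, f"kdiff_{sp}.tsv"))
        conn[sp] = {"control": tab_c, "treated": tab_t, "kdiff": kdiff,
                    "params": params}
        expr_groups[sp] = {"control": ctrl, "treated": trt}
        net_summary[sp] = {
            "beta": beta,
            "dc_calls": kdiff["dc_class"].value_counts().to_dict(),
        }
    record("network", t0, **net_summary)

    # --- modules / preservation ----------------------------------------
    t0 = time.perf_counter()
    mod_summary = {}
    module_labels: dict[str, pd.Series] = {}
    for sp in kept:
        tab_c, tab_t = conn[sp]["control"], conn[sp]["treated"]
        params = conn[sp]["params"]
        selected = modmod.select_top_connected(tab_c, tab_t, m=config.top_m)
        ctrl = expr_groups[sp]["control"].loc[selected]
        trt = expr_groups[sp]["treated"].loc[selected]
        adj_c, _ = network.adjacency_connectivity(
            network.correlation_matrix(ctrl), params
        )
        tom = modmod.tom_similarity(adj_c)
        labels = modmod.detect_modules(
            tom, min_module_size=config.min_module_size,
            cut_height=config.cut_height,
        )
        if len(set(labels) - {modmod.GREY}) >= 2:
            labels = modmod.merge_modules(labels, ctrl, r_min=config.merge_r)
        module_labels[sp] = labels
        preservation = modmod.preservation_zsummary(
            ctrl, trt, labels, params, n_perm=config.n_perm,
            seed=stage_seed(config.seed, "modules"),
        )
        _atomic_write_tsv(
            labels.to_frame(), os.path.join(config.out_dir, f"modules_{sp}.tsv")
        )
        _atomic_write_tsv(
            preservation, os.path.join(config.out_dir, f"preservation_{sp}.tsv")
        )
        mod_summary[sp] = {
            "n_selected": len(selected),
            "n_modules": int(len(set(labels) - {modmod.GREY})),
            "preservation_bins": preservation["bin"].value_counts().to_dict()
            if len(preservation) else {},
        }
    record("modules", t0, **mod_summary)

    # --- over-representation -------------------------------------------
    t0 = time.perf_counter()
    ora_summary = {}
    for sp in kept:
        de_genes = de_results[sp].index[
            de_results[sp]["call"].isin(["UP", "DOWN"])
        ].tolist()
        if config.gmt:
            collection = enrichment.read_gmt(config.gmt)
        else:
            # default collection: the control-group modules of this species
            labels = module_labels[sp]
            sets = {
                f"module_{lab}": frozenset(labels.index[labels == lab])
                for lab in sorted(set(labels) - {modmod.GREY})
            }
            collection = enrichment.GeneSetCollection(
                sets=sets, background_size=len(kept[sp])
            )
        if not de_genes or not collection.sets:
            ora_summary[sp] = {"status": "skipped", "n_de_genes": len(de_genes)}
            continue
        table = enrichment.ora_table(
            de_genes, collection, padj_max=config.padj_max, lenient=True,
        )
        _atomic_write_tsv(table, os.path.join(config.out_dir, f"ora_{sp}.tsv"))
        ora_summary[sp] = {
            "n_de_genes": len(de_genes),
            "n_categories_tested": int(len(table)),
            "n_significant": int(table["significant"].sum()) if len(table) else 0,
        }
    record("ora", t0, **ora_summary)
    return report


def write_report(report: PipelineReport, path: str) -> None:
    """Write the JSON report plus a human-readable .txt summary beside it."""
    _atomic_write_json(report.to_dict(), path)
    lines = [f"xenonet pipeline report (seed {report.seed})", ""]
    for stage, entry in report.stages.items():
        status = entry.get("status", "?")
        lines.append(f"[{stage}] {status}")
        if stage == "partition" and status == "ok":
            pct = entry["report"]["percentages"]
            lines.append(
                "  reads: "
                + ", ".join(f"{k} {v:.2f}%" for k, v in pct.items())
            )
        if stage == "de" and status == "ok":
            for sp, v in entry.items():
                if sp == "status":
                    continue
                calls = v.get("calls", {})
                lines.append(
                    f"  {sp}: {calls.get('UP', 0)} up, {calls.get('DOWN', 0)} down"
                )
        if stage == "network" and status == "ok":
            for sp, v in entry.items():
                if sp == "status":
                    continue
                dc = v.get("dc_calls", {})
                lines.append(
                    f"  {sp}: {dc.get('TREATED_HIGH', 0)} treated-high, "
                    f"{dc.get('CONTROL_HIGH', 0)} control-high (beta={v.get('beta')})"
                )
        if stage == "modules" and status == "ok":
            for sp, v in entry.items():
                if sp == "status":
                    continue
                lines.append(
                    f"  {sp}: {v.get('n_modules')} modules, bins "
                    f"{v.get('preservation_bins')}"
                )
    text_path = os.path.splitext(path)[0] + ".txt"
    tmp = text_path + ".tmp"
    with open(tmp, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    os.replace(tmp, text_path)


def validate_report(d: dict) -> None:
    """Check a report dict against the published minimal schema."""
    for key in REPORT_SCHEMA["required"]:
        if key not in d:
            raise ValueError(f"report missing required key {key!r}")
    if not isinstance(d["stages"], dict):
        raise ValueError("report 'stages' must be an object")
    for stage, entry in d["stages"].items():
        for key in REPORT_SCHEMA["stage_required"]:
            if key not in entry:
                raise ValueError(f"stage {stage!r} missing key {key!r}")
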