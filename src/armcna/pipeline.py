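"""End-to-end orchestration: simulate → call → profile → cluster → associate.

A single :func:`run_pipeline` call executes the full analysis on a synthetic
cohort and returns a structured report whose payload is a pure function of
the configuration and master seed (re-running with the same config
reproduces it byte-for-byte; no timestamps are embedded).

Stages
------
1. genome + planted CNA truth + paired probe signals (per archetype)
2. allelic-ratio calling, smoothing, segmentation, span classification
3. arm-level profiling: CIN classes, arm-event table, whole-arm ratio test,
   tumor-suppressor LOH, CNA-profile clustering
4. expression: planted subtype matrix, normalization, filtering,
   hierarchical + consensus k-means subtyping with NMF k selection
5. association: contingency tests, Kaplan–Meier/log-rank, Cox model
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calling import (CallerConfig, arm_events_from_segments, call_segments,
                      classify_arm_span, compute_allelic_ratios, smooth_ratios,
                      write_seg)
from .cin import (arm_event_matrix, arm_event_table, build_cna_profiles,
                  cluster_cna_profiles, loh_co_occurrence, mean_cna_count,
                  tsg_loh_status, whole_arm_ratio_test)
from .expression import (FilterConfig, consensus_kmeans, filter_probes,
                         global_normalize, hierarchical_clusters,
                         rank_marker_genes, select_k_nmf)
from .simulate import (SimulationConfig, generate_genome,
                       simulate_background_signals, simulate_clinical,
                       simulate_cna_profiles, simulate_expression,
                       simulate_probe_signals)
from .stats import cox_multivariate, fisher_exact_two_sided, km_logrank

__all__ = ["PipelineConfig", "run_pipeline", "write_fixture_bundle"]

log = logging.getLogger("armcna")


@dataclass
class PipelineConfig:
    """Everything one reproducible run needs.

    ``consensus_n_iter`` defaults to 100 (a desk-scale stand-in for the
    classical 1000 resamples; configurable).  The master seed is mandatory
    and feeds every stochastic stage through independent substreams.
    """

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    caller: CallerConfig = field(default_factory=CallerConfig)
    expr_filter: FilterConfig = field(default_factory=FilterConfig)
    consensus_k_range: tuple = (2, 10)
    consensus_n_iter: int = 100
    consensus_n_genes: int = 3000
    nmf_restarts: int = 10
    cna_cluster_k: int = 2
    run_expression: bool = True
    run_survival: bool = True
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        self.simulation.seed = self.seed
        lo, hi = self.consensus_k_range
        if not 2 <= lo <= hi:
            raise ValueError("consensus k range must satisfy 2 <= lo <= hi")

    # -- YAML round trip ---------------------------------------------------

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", {})
        arch = sim.pop("archetypes", None)
        kwargs = {}
        if arch is not None:
            from .simulate import ArchetypeConfig
            sim["archetypes"] = [ArchetypeConfig(**a) for a in arch]
        kwargs["simulation"] = SimulationConfig(**sim)
        if "caller" in raw:
            kwargs["caller"] = CallerConfig(**raw.pop("caller"))
        if "expr_filter" in raw:
            kwargs["expr_filter"] = FilterConfig(**raw.pop("expr_filter"))
        if "consensus_k_range" in raw:
            raw["consensus_k_range"] = tuple(raw["consensus_k_range"])
        return cls(**kwargs, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _stage(name: str):
    log.info("stage %s", name)
    return time.monotonic()


def call_cohort(truths: pd.DataFrame, genome, caller: CallerConfig,
                purity: float, noise_sd: float, seed: int,
                all_sample_ids=None) -> pd.DataFrame:
    """Simulate signals for a planted cohort and call every sample.

    Returns the classified segment table for all samples (samples with no
    planted events are still processed; they should yield no segments).
    """
    tables = simulate_probe_signals(truths, genome, purity, noise_sd, seed=seed)
    ids = list(all_sample_ids) if all_sample_ids is not None else sorted(tables)
    silent = [s for s in ids if s not in tables]
    tables.update(simulate_background_signals(silent, genome, noise_sd,
                                              seed=seed + 1))
    frames = []
    for sid in ids:
        ratios = compute_allelic_ratios(tables[sid])
        smoothed = smooth_ratios(ratios, caller)
        segs = call_segments(smoothed, genome, caller, sample_id=sid)
        if len(segs):
            frames.append(classify_arm_span(segs, genome, caller))
    if not frames:
        return pd.DataFrame(columns=["sample_id", "chrom", "arm", "start", "end",
                                     "state_a", "state_b", "category", "n_probes",
                                     "ratio_a", "ratio_b", "span_fraction",
                                     "span_class"])
    return pd.concat(frames, ignore_index=True)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all enabled stages and return the analysis report.

    The report is a JSON-serializable dict with one section per stage plus a
    provenance block (config hash, seed, package version).
    """
    config.simulation.validate()
    sim = config.simulation
    report: dict = {"provenance": {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
    }}

    t0 = _stage("simulate")
    genome = generate_genome(sim)
    truths = simulate_cna_profiles(genome, sim)
    histology = {}
    for arch in sim.archetypes:
        for i in range(arch.n_samples):
            histology[f"{arch.name}-{i + 1:03d}"] = arch.name
    sample_ids = list(histology)
    log.info("simulated %d samples, %d planted events (%.1fs)",
             len(sample_ids), len(truths), time.monotonic() - t0)

    t0 = _stage("call-cna")
    classified = call_cohort(truths, genome, config.caller, sim.purity,
                             sim.noise_sd, seed=sim.seed + 17,
                             all_sample_ids=sample_ids)
    events = arm_events_from_segments(classified)
    log.info("called %d segments, %d arm events (%.1fs)",
             len(classified), len(events), time.monotonic() - t0)

    t0 = _stage("cin")
    profiles = build_cna_profiles(events, genome, sample_ids=sample_ids,
                                  histology=histology)
    groups = pd.Series(histology)
    evt_table = arm_event_table(events, groups, genome)
    arch_names = [a.name for a in sim.archetypes]
    group_b = arch_names[1] if len(arch_names) > 1 else arch_names[0]
    ratio_res = whole_arm_ratio_test(evt_table, arch_names[0], group_b)
    matrix = arm_event_matrix(events, genome, sample_ids=sample_ids)
    cna_labels, _ = cluster_cna_profiles(matrix, config.cna_cluster_k)
    loh = tsg_loh_status(classified, genome=genome, sample_ids=sample_ids)
    co = loh_co_occurrence(loh, groups)
    report["cin"] = {
        "cin_class_counts": profiles.groupby(["histology", "cin_class"])
        .size().reset_index(name="n").to_dict("records"),
        "mean_cna_count": {a: mean_cna_count(profiles, a) for a in arch_names},
    }
    report["arm_events"] = {
        "table": evt_table.to_dict("records"),
        "totals": {g: {"whole_arm": int(evt_table[evt_table["group"] == g]["whole_arm"].sum()),
                       "focal": int(evt_table[evt_table["group"] == g]["focal"].sum())}
                   for g in arch_names},
    }
    report["whole_arm_ratio"] = {
        "ratios": ratio_res.ratios, "counts": {k: list(v) for k, v in
                                               ratio_res.counts.items()},
        "fisher_p": ratio_res.p_value,
    }
    report["tsg_loh"] = {
        "status_counts": {gene: loh[gene].value_counts().to_dict()
                          for gene in loh.columns},
        "co_occurrence": co.to_dict("records"),
    }
    report["cna_clusters"] = {
        "k": config.cna_cluster_k,
        "labels": {s: int(v) for s, v in cna_labels.items()},
    }
    log.info("profiled cohort (%.1fs)", time.monotonic() - t0)

    expr_labels = None
    if config.run_expression:
        t0 = _stage("cluster-expr")
        planted = pd.Series(
            [1 + i % sim.n_clusters for i in range(len(sample_ids))],
            index=sample_ids)
        esim = simulate_expression(planted, sim)
        norm = global_normalize(esim.matrix, config.expr_filter)
        filtered = filter_probes(norm, config.expr_filter)
        hier_labels, _ = hierarchical_clusters(filtered, sim.n_clusters,
                                               config.expr_filter)
        lo, hi = config.consensus_k_range
        cons = consensus_kmeans(filtered, range(lo, hi + 1),
                                n_iter=config.consensus_n_iter,
                                n_genes=config.consensus_n_genes,
                                seed=sim.seed + 23, config=config.expr_filter)
        cons = select_k_nmf(cons, n_restarts=config.nmf_restarts,
                            seed=sim.seed + 29)
        expr_labels = cons.labels[cons.chosen_k]
        markers = rank_marker_genes(filtered, expr_labels, 1, 2)
        report["expression_clusters"] = {
            "planted_k": sim.n_clusters,
            "chosen_k": cons.chosen_k,
            "nmf_error": cons.nmf_error,
            "hierarchical_labels": {s: int(v) for s, v in hier_labels.items()},
            "consensus_labels": {s: int(v) for s, v in expr_labels.items()},
            "top_markers": markers.head(20).to_dict("records"),
        }
        log.info("expression subtyping done, chosen k=%d (%.1fs)",
                 cons.chosen_k, time.monotonic() - t0)

    if config.run_survival:
        if expr_labels is None and not config.run_expression:
            raise ValueError("survival stage requires clinical table "
                             "(enable expression clustering to plant one)")
        t0 = _stage("associate")
        planted = pd.Series(
            [1 + i % sim.n_clusters for i in range(len(sample_ids))],
            index=sample_ids)
        clinical = simulate_clinical(planted, sim)
        clinical = clinical.set_index("sample_id", drop=False)
        clinical["group"] = planted
        tab = pd.crosstab(clinical["group"] == 2, clinical["stage"])
        fisher = fisher_exact_two_sided(tab.to_numpy()) if tab.shape == (2, 2) \
            else None
        curves, lr = km_logrank(clinical, group_col="group")
        clinical["protective_cluster"] = (clinical["group"] == 2).astype(int)
        clinical["advanced_stage"] = (clinical["stage"] == "III/IV").astype(int)
        cox = cox_multivariate(clinical, ["protective_cluster",
                                          "advanced_stage", "age"])
        report["association"] = {
            "stage_by_cluster_fisher": None if fisher is None else fisher.to_dict(),
            "logrank": lr.to_dict(),
            "cox": {k: v.to_dict() for k, v in cox.items()},
        }
        log.info("association stats done (%.1fs)", time.monotonic() - t0)

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True, default=_jsonable)
        write_seg(classified, out / "segments.seg", out / "segments.tsv")
        evt_table.to_csv(out / "arm_event_table.tsv", sep="\t", index=False)
        loh.to_csv(out / "tsg_loh.tsv", sep="\t")
        with open(out / "summary.txt", "w") as fh:
            fh.write(render_summary(report))
    return report


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return str(obj)


def render_summary(report: dict) -> str:
    """Short human-readable digest of a report."""
    lines = [f"armcna report (seed {report['provenance']['seed']}, "
             f"config {report['provenance']['config_hash']})"]
    if "cin" in report:
        lines.append("mean CNA count per group: "
                     + ", ".join(f"{g}={v}" for g, v in
                                 report["cin"]["mean_cna_count"].items()))
    if "whole_arm_ratio" in report:
        w = report["whole_arm_ratio"]
        rat = ", ".join(f"{g}={v:.3f}" if v is not None else f"{g}=NA"
                        for g, v in w["ratios"].items())
        p = w["fisher_p"]
        lines.append(f"whole-arm ratio: {rat}; Fisher p="
                     + (f"{p:.3g}" if p is not None else "NA"))
    if "expression_clusters" in report:
        e = report["expression_clusters"]
        lines.append(f"expression subtyping: chosen k={e['chosen_k']} "
                     f"(planted {e['planted_k']})")
    if "association" in report:
        lr = report["association"]["logrank"]
        lines.append(f"log-rank chi2={lr['statistic']:.3f}, p={lr['p_value']:.3g}")
    return "\n".join(lines) + "\n"


def write_fixture_bundle(config: PipelineConfig, out_dir, force: bool = False
                         ) -> dict:
    """Emit a small self-contained cohort fixture and its checksum manifest.

    Writes the genome (cytoBand dialect + probe map), per-sample paired
    signal TSVs, the planted truth table, an expression matrix and a
    clinical CSV.  Refuses to overwrite a non-empty directory unless
    *force*.  Returns the manifest (relative path -> sha256).
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} is not empty (use force=True)")
    out.mkdir(parents=True, exist_ok=True)
    sim = config.simulation
    genome = generate_genome(sim)
    truths = simulate_cna_profiles(genome, sim)
    histology = {f"{a.name}-{i + 1:03d}": a.name
                 for a in sim.archetypes for i in range(a.n_samples)}
    tables = simulate_probe_signals(truths, genome, sim.purity, sim.noise_sd,
                                    seed=sim.seed + 17)
    tables.update(simulate_background_signals(
        [s for s in histology if s not in tables], genome, sim.noise_sd,
        seed=sim.seed + 18))
    genome.write_cytoband(out / "cytoBand.txt")
    genome.write_probes(out / "probes.tsv")
    truths.to_csv(out / "truth.tsv", sep="\t", index=False)
    sig_dir = out / "signals"
    sig_dir.mkdir(exist_ok=True)
    for sid in sorted(histology):
        tables[sid].to_csv(sig_dir / f"{sid}.tsv", sep="\t", index=False,
                           float_format="%.4f")
    planted = pd.Series([1 + i % sim.n_clusters for i in range(len(histology))],
                        index=sorted(histology))
    esim = simulate_expression(planted, sim)
    esim.matrix.round(3).to_csv(out / "expression.tsv", sep="\t")
    clinical = simulate_clinical(planted, sim)
    clinical.to_csv(out / "clinical.csv", index=False)
    manifest = {}
    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "MANIFEST.json":
            manifest[str(path.relative_to(out))] = hashlib.sha256(
                path.read_bytes()).hexdigest()
    with open(out / "MANIFEST.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def setup_logging(verbose: bool = True) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("[%(asctime)s] %(message)s",
                                           datefmt="%H:%M:%S"))
    log.handlers[:] = [handler]
    log.setLevel(logging.INFO if verbose else logging.WARNING)
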