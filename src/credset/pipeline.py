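"""Umbrella pipeline: simulate -> finemap -> annotate -> enrich ->
imbalance -> eqtl -> report.

Each stage reads its inputs from and writes its outputs to a working
directory, so stages can be toggled independently and re-run; a stage
whose inputs are missing aborts with the stage name and the missing
dependency.  The final report (JSON + markdown) collates baseline and
reweighted credible sets, the selected annotations with their
enrichments, the allelic-imbalance table and the eQTL table.  No
timestamps are written, so identical configurations produce
byte-identical reports.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import pandas as pd

from . import io
from .annot import build_annotation_matrix, derive_stretch_enhancers
from .enrich import AnnotationEnrichment, FitConfig
from .eqtl import CisEqtlModel
from .finemap import ABFConfig, finemap_signals
from .imbalance import imbalance_report, analyze_allelic_imbalance
from .simulate import SimConfig, simulate_allele_counts, simulate_chromatin_states, \
    simulate_eqtl_dataset, simulate_signals

log = logging.getLogger("credset")

ALL_STAGES = ("simulate", "finemap", "annotate", "enrich", "imbalance", "eqtl", "report")


@dataclass
class PipelineConfig:
    out_dir: str = "credset_run"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    sim: dict = field(default_factory=dict)
    # On the z scale (V = 1) the prior effect variance W must also be on
    # the z**2 scale; the synthetic design centres causal z at 5, so the
    # pipeline defaults to prior z-SD 5.  Override for beta/se input.
    finemap: dict = field(default_factory=lambda: {"W": 25.0})
    enrich: dict = field(default_factory=dict)  # FitConfig fields + target_signal, loo_target
    imbalance: dict = field(default_factory=dict)  # min_reads, min_het_samples, ...
    eqtl: dict = field(default_factory=dict)  # mode

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown pipeline config keys: {sorted(unknown)}")
        cfg = cls(**d)
        bad = set(cfg.stages) - set(ALL_STAGES)
        if bad:
            raise ValueError(f"unknown stage(s): {sorted(bad)}")
        return cfg


def _require(path: Path, stage: str, produced_by: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"stage '{stage}' needs {path.name}, which the '{produced_by}' stage "
            f"produces; enable it or provide the file"
        )
    return path


def run_pipeline(config: PipelineConfig | dict) -> dict:
    """Run the enabled stages in order and return the report dict."""
    if isinstance(config, dict):
        config = PipelineConfig.from_dict(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = set(config.stages)
    report: dict = {"seed": config.seed, "stages": [s for s in ALL_STAGES if s in stages]}

    if "simulate" in stages:
        sim_cfg = SimConfig(**{"seed": config.seed, **config.sim})
        log.info("simulate: %s", sim_cfg)
        stats, annotations, truth = simulate_signals(sim_cfg)
        io.write_summary_stats(stats, out / "summary_stats.tsv")
        io.write_annotation_matrix(annotations, out / "annotations.tsv")
        segments = simulate_chromatin_states(sim_cfg)
        io.write_segments_bed(segments, out / "chromatin_states.bed")
        target = stats[stats["signal_id"] == stats["signal_id"].iloc[0]]
        counts, ase_truth = simulate_allele_counts(sim_cfg, target)
        io.write_allele_counts(counts, out / "allele_counts.tsv")
        eq = simulate_eqtl_dataset(sim_cfg)
        io.write_genotypes_vcf(eq.genotypes, eq.variants, out / "genotypes.vcf")
        io.write_expression(eq.expression, eq.features, out / "expression.tsv")
        io.write_covariates(eq.covariates, out / "covariates.tsv")
        truth.true_allelic_ratio = ase_truth.true_allelic_ratio
        truth.true_eqtl_beta = eq.truth.true_eqtl_beta
        io.write_truth(truth, out / "truth.json")
        report["simulate"] = {
            "n_signals": sim_cfg.n_signals,
            "n_variants_per_signal": sim_cfg.n_variants_per_signal,
            "true_log_enrichments": list(sim_cfg.true_log_enrichments),
        }

    abf_cfg = ABFConfig(**config.finemap)
    if "finemap" in stages:
        stats = io.read_summary_stats(_require(out / "summary_stats.tsv", "finemap", "simulate"))
        log.info("finemap: W=%g level=%g", abf_cfg.W, abf_cfg.level)
        posteriors, credsets = finemap_signals(stats, abf_cfg)
        io.write_posterior_table(posteriors, out / "posteriors.tsv")
        io.write_credible_sets(credsets, out / "credible_sets.json")
        report["finemap"] = {
            "W": abf_cfg.W,
            "level": abf_cfg.level,
            "n_signals": len(credsets),
            "credible_set_sizes": {sid: len(cs) for sid, cs in credsets.items()},
        }

    if "annotate" in stages:
        stats = io.read_summary_stats(_require(out / "summary_stats.tsv", "annotate", "simulate"))
        segments = io.read_segments_bed(
            _require(out / "chromatin_states.bed", "annotate", "simulate")
        )
        matrix = build_annotation_matrix(stats, segments)
        io.write_annotation_matrix(matrix, out / "annotations_chromatin.tsv")
        stretch = derive_stretch_enhancers(segments)
        io.write_segments_bed(stretch, out / "stretch_enhancers.bed")
        report["annotate"] = {
            "n_annotation_columns": matrix.shape[1],
            "n_stretch_enhancers": int(len(stretch)),
        }

    if "enrich" in stages:
        posteriors = io.read_posterior_table(
            _require(out / "posteriors.tsv", "enrich", "finemap")
        )
        annotations = io.read_annotation_matrix(
            _require(out / "annotations.tsv", "enrich", "simulate")
        )
        opts = dict(config.enrich)
        target_signal = opts.pop("target_signal", None) or str(posteriors["signal_id"].iloc[0])
        loo = opts.pop("loo_target", False)
        fit_cfg = FitConfig(**{"seed": config.seed, **opts})
        train = posteriors[posteriors["signal_id"] != target_signal] if loo else posteriors
        results = AnnotationEnrichment(train, annotations, fit_cfg).fit()
        io.write_model(results.model, out / "enrichment_model.json")
        target = posteriors[posteriors["signal_id"] == target_signal].reset_index(drop=True)
        if len(target) == 0:
            raise ValueError(f"target signal {target_signal!r} not in posterior table")
        reweighted, credset = results.reweight(target, annotations, abf_cfg)
        reweighted["in_credible_set"] = reweighted["variant_id"].isin(credset.variant_ids)
        io.write_posterior_table(reweighted, out / "posteriors_reweighted.tsv")
        io.write_credible_sets({target_signal: credset}, out / "credible_sets_reweighted.json")
        report["enrich"] = {
            "target_signal": target_signal,
            "selected_annotations": list(results.model.annotations),
            "gamma": [float(g) for g in results.model.gamma],
            "penalty": results.model.penalty,
            "reweighted_credible_set_size": len(credset),
        }

    if "imbalance" in stages:
        counts = io.read_allele_counts(
            _require(out / "allele_counts.tsv", "imbalance", "simulate")
        )
        stats = io.read_summary_stats(
            _require(out / "summary_stats.tsv", "imbalance", "simulate")
        )
        results = analyze_allelic_imbalance(counts, stats, **config.imbalance)
        table = imbalance_report(results) if len(results) else results
        table.to_csv(out / "imbalance.tsv", sep="\t", index=False)
        report["imbalance"] = {
            "n_tested": int(len(table)),
            "n_risk_lower": int((table["direction"] == "risk_lower").sum()) if len(table) else 0,
        }

    if "eqtl" in stages:
        genotypes, variants = io.read_genotypes_vcf(
            _require(out / "genotypes.vcf", "eqtl", "simulate")
        )
        values, features = io.read_expression(
            _require(out / "expression.tsv", "eqtl", "simulate")
        )
        covariates = io.read_covariates(_require(out / "covariates.tsv", "eqtl", "simulate"))
        mode = config.eqtl.get("mode", "tss_flank_1mb")
        results = CisEqtlModel(values, features, genotypes, variants, covariates, mode).fit()
        results.table.to_csv(out / "eqtl.tsv", sep="\t", index=False)
        report["eqtl"] = {
            "mode": mode,
            "n_pairs": int(len(results.table)),
            "min_p": float(results.table["p"].min()) if len(results.table) else None,
        }

    if "report" in stages:
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
        (out / "report.md").write_text(_markdown_report(report))
    return report


def _markdown_report(report: dict) -> str:
    lines = ["# credset pipeline report", ""]
    lines.append(f"- seed: {report['seed']}")
    lines.append(f"- stages: {', '.join(report['stages'])}")
    if "finemap" in report:
        fm = report["finemap"]
        sizes = list(fm["credible_set_sizes"].values())
        lines += [
            "",
            "## Fine-mapping",
            f"- signals: {fm['n_signals']} (W={fm['W']}, level={fm['level']})",
            f"- mean credible-set size: {sum(sizes) / len(sizes):.6g}",
        ]
    if "enrich" in report:
        en = report["enrich"]
        lines += [
            "",
            "## Enrichment / reweighting",
            f"- target signal: {en['target_signal']}",
            f"- selected annotations: {en['selected_annotations'] or '(none)'}",
            f"- log-enrichments: {[round(g, 4) for g in en['gamma']]}",
            f"- reweighted credible-set size: {en['reweighted_credible_set_size']}",
        ]
    if "imbalance" in report:
        im = report["imbalance"]
        lines += [
            "",
            "## Allelic imbalance",
            f"- variants tested: {im['n_tested']}; risk-lower direction: {im['n_risk_lower']}",
        ]
    if "eqtl" in report:
        eq = report["eqtl"]
        lines += [
            "",
            "## cis-eQTL",
            f"- pairs tested: {eq['n_pairs']} ({eq['mode']}); min p = {eq['min_p']:.6g}",
        ]
    return "\n".join(lines) + "\n"
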