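"""End-to-end orchestration: quantify -> diffexp -> heterosis -> enrichment.

A :class:`PipelineConfig` (YAML-loadable) either points at user files
(GTF models, TSV counts, TSV annotations, optional OBO ontology) or embeds
a simulation block; :func:`run_pipeline` executes the stages, returns every
stage table, and optionally writes the TSV reports plus a JSON run manifest
recording the configuration and per-stage record counts. Identical config
and seed give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diffexp, enrichment, heterosis, io, quantify, report, simulate
from .errors import ConfigError
from .quantify import SAMPLES

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run.

    Thresholds: alpha (BH FDR level per comparison), min_abs_ln_ratio
    (extra fold-change gate, natural-log units), pseudo_fpkm (pseudocount
    keeping log ratios finite), tolerance_tau (gene-action "approximate"
    tolerance, log units), filter_value (enrichment FDR filter), go_level
    (ontology level for annotation projection; None = no projection),
    mp/jp (alignment-score penalties), nb_dispersion (assumed NB
    dispersion of the count noise), normalize (library-size estimator).
    """

    simulation: simulate.SimulationConfig | None = None
    models_path: str | None = None
    counts_path: str | None = None
    annotations_path: str | None = None
    ontology_path: str | None = None
    alpha: float = 0.05
    min_abs_ln_ratio: float = 0.0
    pseudo_fpkm: float = 0.1
    tolerance_tau: float = heterosis.DEFAULT_TAU
    filter_value: float = 0.01
    go_level: int | None = None
    mp: float = 1.0
    jp: float = 0.0
    nb_dispersion: float = 0.1
    normalize: str = "ratio_mode"
    n_go_terms: int = 50
    go_enrichment_factor: float = 5.0
    go_background_rate: float = 0.05
    n_enriched_terms: int = 5
    seed: int = 0
    out_dir: str | None = None

    def validate(self) -> None:
        if self.simulation is None and (self.models_path is None or self.counts_path is None):
            raise ConfigError(
                "config needs either a simulation block or models_path + counts_path"
            )
        for name in ("alpha", "filter_value"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ConfigError(f"{name} must be in (0, 1], got {v}")
        if self.pseudo_fpkm <= 0:
            raise ConfigError(f"pseudo_fpkm must be > 0, got {self.pseudo_fpkm}")
        if self.tolerance_tau <= 0:
            raise ConfigError(f"tolerance_tau must be > 0, got {self.tolerance_tau}")
        if self.min_abs_ln_ratio < 0:
            raise ConfigError(f"min_abs_ln_ratio must be >= 0, got {self.min_abs_ln_ratio}")
        if self.mp < 0 or self.jp < 0:
            raise ConfigError("mp and jp must be >= 0")
        if self.nb_dispersion < 0:
            raise ConfigError(f"nb_dispersion must be >= 0, got {self.nb_dispersion}")
        if self.go_level is not None and self.go_level < 1:
            raise ConfigError(f"go_level must be >= 1, got {self.go_level}")
        for name in ("models_path", "counts_path", "annotations_path", "ontology_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ConfigError(f"{name}: no such file {p}")
        if self.simulation is not None:
            self.simulation.validate()

    @classmethod
    def from_dict(cls, data: dict, **overrides) -> "PipelineConfig":
        data = dict(data or {})
        data.update({k: v for k, v in overrides.items() if v is not None})
        sim = data.pop("simulation", None)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**data)
        if sim is not None:
            if isinstance(sim, dict):
                sim = dict(sim)
                sim.setdefault("seed", cfg.seed)
                try:
                    sim = simulate.SimulationConfig(**sim)
                except TypeError as exc:
                    raise ConfigError(f"simulation block: {exc}") from exc
            cfg.simulation = sim
        return cfg

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data, **overrides)


@dataclass
class PipelineResult:
    """Every stage table of one run, plus the manifest."""

    expression: quantify.ExpressionTable
    abundance_summary: pd.DataFrame
    abundance_totals: dict
    de_calls: pd.DataFrame
    subgroups: pd.Series
    actions: pd.DataFrame
    action_summary: pd.DataFrame
    fold_bins: pd.DataFrame
    enrichment: pd.DataFrame
    crosstab: pd.DataFrame
    manifest: dict
    truth: pd.DataFrame | None = None
    enriched_terms_truth: list[str] | None = None


def _load_inputs(config: PipelineConfig):
    if config.simulation is not None:
        study = simulate.simulate_study(
            config.simulation,
            n_terms=config.n_go_terms,
            enrichment_factor=config.go_enrichment_factor,
            background_rate=config.go_background_rate,
            n_enriched=config.n_enriched_terms,
        )
        return (
            study.models,
            study.counts,
            study.gene_ids,
            study.lengths,
            study.annotations,
            study,
        )
    models = io.read_gtf(config.models_path)
    counts, gene_ids = io.read_counts(config.counts_path)
    lengths = pd.Series({m.transcript_id: m.length for m in models}, name="length")
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = counts.index[lengths.isna()][:5].tolist()
        raise ConfigError(f"counts reference transcripts absent from models, e.g. {missing}")
    annotations = (
        io.read_annotations(config.annotations_path) if config.annotations_path else {}
    )
    return models, counts, gene_ids, lengths, annotations, None


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full analysis; write reports when out_dir is set."""
    config.validate()
    models, counts, gene_ids, lengths, annotations, study = _load_inputs(config)
    manifest: dict = {"config": _config_echo(config), "stages": {}}

    sizes = diffexp.effective_library_sizes(counts, method=config.normalize)
    expression = quantify.ExpressionTable.from_counts(
        counts, lengths, gene_ids, totals=sizes
    )
    raw_expression = quantify.ExpressionTable.from_counts(counts, lengths, gene_ids)
    abundance_summary, abundance_totals = quantify.summarize_abundance(raw_expression)
    manifest["stages"]["quantify"] = {
        "transcripts": int(len(counts)),
        "effective_library_sizes": {s: float(sizes[s]) for s in SAMPLES},
        "detected_union": abundance_totals["transcript_union"],
    }
    logger.info("quantify: %d transcripts", len(counts))

    de_calls = diffexp.call_de(
        expression,
        alpha=config.alpha,
        min_abs_ln_ratio=config.min_abs_ln_ratio,
        pseudo_fpkm=config.pseudo_fpkm,
        nb_dispersion=config.nb_dispersion,
        normalize=config.normalize,
    )
    n_sig = int(de_calls["significant"].sum())
    manifest["stages"]["diffexp"] = {
        "tests": int(len(de_calls)),
        "significant_calls": n_sig,
        "alpha": config.alpha,
        "min_abs_ln_ratio": config.min_abs_ln_ratio,
    }
    logger.info("diffexp: %d significant calls", n_sig)

    subgroups = heterosis.partition_subgroups(de_calls)
    hybrid_ids = subgroups.index[subgroups != "PPU"]
    actions = heterosis.classify_table(
        expression.fpkm.loc[hybrid_ids],
        tolerance_tau=config.tolerance_tau,
        pseudo_fpkm=config.pseudo_fpkm,
    )
    action_summary = heterosis.summarize_actions(subgroups, actions)
    hybrid_rows = de_calls[de_calls["comparison"].isin(["H_vs_P1", "H_vs_P2"])]
    fold_bins = hybrid_rows[["transcript_id", "comparison", "ln_ratio"]].copy()
    fold_bins["bin"] = heterosis.bin_fold_changes(fold_bins["ln_ratio"].to_numpy()).to_numpy()
    manifest["stages"]["heterosis"] = {
        "differential_transcripts": int(len(subgroups)),
        "hybrid_dts": int(len(hybrid_ids)),
        "tolerance_tau": config.tolerance_tau,
        "subgroup_sizes": subgroups.value_counts().to_dict(),
    }
    logger.info("heterosis: %d DTs, %d hybrid DTs", len(subgroups), len(hybrid_ids))

    enrich_df, crosstab = _run_enrichment(
        config, annotations, subgroups, raw_expression, fold_bins
    )
    manifest["stages"]["enrichment"] = {
        "tested_terms": int(len(enrich_df)),
        "enriched_terms": int(enrich_df["enriched"].sum()) if len(enrich_df) else 0,
        "filter_value": config.filter_value,
    }

    truth = study.truth if study is not None else None
    if truth is not None:
        manifest["stages"]["recovery"] = recovery_metrics(
            truth, de_calls, actions, enrich_df, study.enriched_terms
        )

    result = PipelineResult(
        expression=expression,
        abundance_summary=abundance_summary,
        abundance_totals=abundance_totals,
        de_calls=de_calls,
        subgroups=subgroups,
        actions=actions,
        action_summary=action_summary,
        fold_bins=fold_bins,
        enrichment=enrich_df,
        crosstab=crosstab,
        manifest=manifest,
        truth=truth,
        enriched_terms_truth=study.enriched_terms if study is not None else None,
    )
    if config.out_dir is not None:
        _write_outputs(config, result, models, counts, gene_ids, annotations, study)
    return result


def _run_enrichment(config, annotations, subgroups, raw_expression, fold_bins):
    """Fisher enrichment of the hybrid-specific core (HPco) against all
    identified transcripts, then the per-term fold-change crosstab."""
    empty = pd.DataFrame(
        columns=["term_id", "test_in", "test_out", "ref_in", "ref_out",
                 "p_value", "fdr", "enriched"]
    )
    test = set(subgroups.index[subgroups == "HPco"])
    detected = raw_expression.fpkm.index[(raw_expression.fpkm > 0).any(axis=1)]
    reference = set(detected) | test
    ontology = (
        enrichment.OntologyGraph.from_obo(config.ontology_path)
        if config.ontology_path
        else None
    )
    if not test or not annotations:
        return empty, enrichment.crosstab_bins({}, fold_bins.iloc[0:0])
    enrich_df = enrichment.fisher_enrichment(
        test, reference, annotations,
        filter_value=config.filter_value, ontology=ontology,
    )
    ann = annotations
    if ontology is not None:
        ann = enrichment.propagate_annotations(annotations, ontology)
        if config.go_level is not None:
            ann = enrichment.project_to_level(annotations, ontology, config.go_level)
    enriched_terms = enrich_df.loc[enrich_df["enriched"], "term_id"]
    term_members = {
        term: {tid for tid in test if term in ann.get(tid, ())}
        for term in enriched_terms
    }
    fdrs = dict(zip(enrich_df["term_id"], enrich_df["fdr"]))
    test_bins = fold_bins[fold_bins["transcript_id"].isin(test)]
    crosstab = enrichment.crosstab_bins(term_members, test_bins, fdrs=fdrs)
    return enrich_df, crosstab


def recovery_metrics(
    truth: pd.DataFrame,
    de_calls: pd.DataFrame,
    actions: pd.DataFrame,
    enrich_df: pd.DataFrame,
    enriched_truth: list[str],
) -> dict:
    """Compare pipeline output with the planted truth.

    category_recovery: among planted non-null transcripts that were called
    as hybrid DTs, the fraction whose assigned category equals the planted
    mode. planted_terms_flagged: how many truly enriched GO terms the
    enrichment stage flagged.
    """
    nonnull = truth.index[truth["planted_mode"] != "null"]
    called = actions.index.intersection(nonnull)
    if len(called):
        agree = (
            actions.loc[called, "category"].to_numpy()
            == truth.loc[called, "planted_mode"].to_numpy()
        )
        recovery = float(np.mean(agree))
    else:
        recovery = float("nan")
    flagged = (
        set(enrich_df.loc[enrich_df["enriched"], "term_id"]) if len(enrich_df) else set()
    )
    null_ids = truth.index[truth["planted_mode"] == "null"]
    hyb = de_calls[de_calls["comparison"].isin(["H_vs_P1", "H_vs_P2"])]
    null_sig = hyb[hyb["transcript_id"].isin(null_ids)]["significant"]
    return {
        "planted_nonnull": int(len(nonnull)),
        "nonnull_called": int(len(called)),
        "category_recovery": recovery,
        "planted_enriched_terms": len(enriched_truth),
        "planted_terms_flagged": len(flagged & set(enriched_truth)),
        "null_hybrid_call_rate": float(null_sig.mean()) if len(null_sig) else 0.0,
    }


def _config_echo(config: PipelineConfig) -> dict:
    echo = dataclasses.asdict(config)
    echo.pop("out_dir", None)  # location, not analysis state: keep manifests comparable
    if config.simulation is not None:
        sim = dataclasses.asdict(config.simulation)
        sim["isoforms_per_gene"] = {int(k): float(v) for k, v in sim["isoforms_per_gene"].items()}
        sim["mode_proportions"] = [float(x) for x in sim["mode_proportions"]]
        echo["simulation"] = sim
    return echo


def _write_outputs(config, result, models, counts, gene_ids, annotations, study):
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if study is not None:
        io.write_gtf(models, out / "models.gtf")
        io.write_counts(counts, gene_ids, out / "counts.tsv")
        study.truth.to_csv(out / "truth.tsv", sep="\t")
        io.write_annotations(annotations, out / "annotations.tsv")
        io.write_enriched_terms(study.enriched_terms, out / "enriched_terms_truth.json")
    fpkm = result.expression.fpkm.copy()
    fpkm.insert(0, "gene_id", gene_ids.reindex(fpkm.index))
    report.render_tsv(fpkm, out / "fpkm.tsv")
    report.render_tsv(result.abundance_summary, out / "abundance_summary.tsv")
    result.de_calls.to_csv(out / "de_calls.tsv", sep="\t", index=False)
    result.subgroups.to_frame().to_csv(out / "subgroups.tsv", sep="\t")
    report.render_tsv(result.actions, out / "gene_actions.tsv")
    report.render_tsv(result.action_summary, out / "gene_action_summary.tsv")
    result.fold_bins.to_csv(out / "fold_bins.tsv", sep="\t", index=False)
    result.enrichment.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    report.render_tsv(result.crosstab, out / "enriched_term_bins.tsv")
    with open(out / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
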