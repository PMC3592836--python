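"""Synthetic three-sample transcriptome studies with planted gene action.

Generates everything the downstream stages consume: simplified gene models
(GTF-writable exon structures), planted per-sample mean FPKM with known
gene-action modes, negative-binomial fragment counts, and GO annotations
with planted enrichment -- so the whole pipeline is testable against known
truth without any sequencing data.

The generator emulates the study design it is built for: one pooled library
per genotype (hybrid H, parent P1, parent P2), log-normal baseline
abundance, parents separated by a fixed log-scale effect where the planted
mode requires distinct parental levels, and the hybrid mean placed exactly
at the value its mode dictates (mid-parent mean, one parent's level, or
offset beyond the extreme parent for over/under-dominance).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError, ContractViolation
from .quantify import SAMPLES, TranscriptModel

MODES = ("below_low", "low_parent", "mid_parent", "high_parent", "above_high")

#: default mode mix among non-null transcripts; proportions follow the
#: marginal category counts reported for the pufferfish hybrid study
#: (742 : 1,132 : 507 : 1,042 : 7,529)
_DEFAULT_MODE_PROPORTIONS = tuple(
    np.array([742, 1132, 507, 1042, 7529], dtype=float) / 10952.0
)

# substream tags: one master seed, deterministic child stream per stage
_STREAM_MODELS, _STREAM_EXPRESSION, _STREAM_COUNTS, _STREAM_GO = 0, 1, 2, 3


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), stream])


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic three-sample transcriptome.

    n_genes            : number of gene loci.
    isoforms_per_gene  : {isoform count: probability} distribution.
    mode_proportions   : 5-vector over gene-action modes (sums to 1),
                         order below_low, low_parent, mid_parent,
                         high_parent, above_high.
    baseline_log_mean/sd : log-normal baseline abundance on the FPKM scale.
    effect_size_delta  : natural-log separation between parents and between
                         the hybrid and the extreme parent for
                         over/under-dominant transcripts.
    nb_dispersion      : NB dispersion d, var = mu + d*mu^2 (0 -> Poisson).
    library_size       : expected total fragments per sample.
    frac_null          : fraction of transcripts with no planted difference.
    read_length        : bases per read (mapping-summary arithmetic only).
    seed               : master seed; per-stage substreams derive from it.
    """

    n_genes: int = 2000
    isoforms_per_gene: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.55, 2: 0.30, 3: 0.15}
    )
    mode_proportions: tuple[float, ...] = _DEFAULT_MODE_PROPORTIONS
    baseline_log_mean: float = 1.0
    baseline_log_sd: float = 1.0
    effect_size_delta: float = 2.0
    nb_dispersion: float = 0.1
    library_size: float = 1_000_000.0
    frac_null: float = 0.5
    read_length: int = 50
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigError(f"n_genes must be >= 1, got {self.n_genes}")
        if self.library_size < 1:
            raise ConfigError(f"library_size must be >= 1, got {self.library_size}")
        if self.nb_dispersion < 0:
            raise ConfigError(f"nb_dispersion must be >= 0, got {self.nb_dispersion}")
        if not 0 <= self.frac_null <= 1:
            raise ConfigError(f"frac_null must be in [0, 1], got {self.frac_null}")
        if self.baseline_log_sd < 0:
            raise ConfigError(f"baseline_log_sd must be >= 0, got {self.baseline_log_sd}")
        if self.effect_size_delta < 0:
            raise ConfigError(f"effect_size_delta must be >= 0, got {self.effect_size_delta}")
        if self.read_length < 1:
            raise ConfigError(f"read_length must be >= 1, got {self.read_length}")
        props = np.asarray(self.mode_proportions, dtype=float)
        if props.shape != (5,) or (props < 0).any() or abs(props.sum() - 1.0) > 1e-9:
            raise ConfigError(
                "mode_proportions must be 5 non-negative values summing to 1"
            )
        iso = dict(self.isoforms_per_gene)
        if not iso or any(k < 1 for k in iso) or any(v < 0 for v in iso.values()):
            raise ConfigError("isoforms_per_gene must map counts >=1 to probabilities >=0")
        if abs(sum(iso.values()) - 1.0) > 1e-9:
            raise ConfigError("isoforms_per_gene probabilities must sum to 1")


def generate_gene_models(config: SimulationConfig) -> list[TranscriptModel]:
    """Lay out ``n_genes`` loci on one synthetic chromosome.

    Exon structure is deliberately simple (1-4 uniform-length exons per
    transcript; isoforms of a gene share the locus start) because only the
    summed exon length feeds the downstream quantification. Deterministic
    given the config seed.
    """
    config.validate()
    rng = _rng(config.seed, _STREAM_MODELS)
    iso_counts = np.array(sorted(config.isoforms_per_gene))
    iso_probs = np.array([config.isoforms_per_gene[k] for k in iso_counts], dtype=float)
    iso_probs = iso_probs / iso_probs.sum()
    models: list[TranscriptModel] = []
    cursor = 1000
    width = len(str(config.n_genes)) + 1
    for g in range(config.n_genes):
        gene_id = f"G{g + 1:0{width}d}"
        strand = "+" if rng.random() < 0.5 else "-"
        n_iso = int(rng.choice(iso_counts, p=iso_probs))
        locus_end = cursor
        for t in range(n_iso):
            n_exons = int(rng.integers(1, 5))
            pos = cursor
            exons = []
            for _ in range(n_exons):
                exon_len = int(rng.integers(100, 400))
                exons.append((pos, pos + exon_len))
                pos += exon_len + int(rng.integers(50, 200))
            models.append(
                TranscriptModel(
                    transcript_id=f"{gene_id}.{t + 1}",
                    gene_id=gene_id,
                    chrom="chrS1",
                    strand=strand,
                    exons=tuple(exons),
                )
            )
            locus_end = max(locus_end, exons[-1][1])
        cursor = locus_end + 1000
    return models


def plant_expression(
    models: list[TranscriptModel], config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign each transcript a gene-action mode and per-sample mean FPKM.

    Null transcripts (probability ``frac_null``) get H = P1 = P2 at the
    log-normal baseline. Non-null transcripts draw a mode from
    ``mode_proportions``; parental means sit ``effect_size_delta`` apart in
    log space where the mode needs distinct parents (always for
    low/mid/high parent; with probability 1/2 for above_high/below_low,
    whose hybrid effect is defined even against identical parents -- those
    equal-parent transcripts are the planted hybrid-specific core). The
    hybrid mean is then set exactly: the parental mean (mid_parent), the
    lower/higher parent (low/high_parent), or effect_size_delta beyond the
    extreme parent (above_high/below_low).

    All three samples are finally rescaled by one common factor so the
    average per-sample FPKM mass matches a nominal depth of
    ``library_size`` fragments; a shared factor keeps every planted
    relation exact.

    Returns (truth table, mean-FPKM table), both indexed by transcript_id.
    """
    if not models:
        raise ContractViolation("plant_expression needs a non-empty model collection")
    config.validate()
    rng = _rng(config.seed, _STREAM_EXPRESSION)
    n = len(models)
    tids = [m.transcript_id for m in models]
    lengths = np.array([m.length for m in models], dtype=float)
    baseline = np.exp(rng.normal(config.baseline_log_mean, config.baseline_log_sd, size=n))
    is_null = rng.random(n) < config.frac_null
    modes = np.array(
        rng.choice(MODES, size=n, p=np.asarray(config.mode_proportions, dtype=float)),
        dtype=object,
    )
    modes[is_null] = "null"
    half = config.effect_size_delta / 2.0
    p1_high = rng.random(n) < 0.5  # which parent carries the higher level
    extreme = modes == "above_high"
    extreme |= modes == "below_low"
    parents_equal = is_null | (extreme & (rng.random(n) < 0.5))
    hi = np.where(parents_equal, baseline, baseline * math.exp(half))
    lo = np.where(parents_equal, baseline, baseline * math.exp(-half))
    p1 = np.where(p1_high, hi, lo)
    p2 = np.where(p1_high, lo, hi)
    h = baseline.copy()
    h[modes == "mid_parent"] = ((p1 + p2) / 2.0)[modes == "mid_parent"]
    h[modes == "low_parent"] = lo[modes == "low_parent"]
    h[modes == "high_parent"] = hi[modes == "high_parent"]
    h[modes == "above_high"] = (hi * math.exp(config.effect_size_delta))[modes == "above_high"]
    h[modes == "below_low"] = (lo * math.exp(-config.effect_size_delta))[modes == "below_low"]
    # one shared scale: average per-sample sum(FPKM * kb) == 1e6, so the
    # average expected library equals library_size and ratios stay exact
    kb = lengths / 1e3
    mass = (h + p1 + p2) @ kb
    scale = 3e6 / mass if mass > 0 else 1.0
    mean_fpkm = pd.DataFrame(
        {"H": h * scale, "P1": p1 * scale, "P2": p2 * scale}, index=pd.Index(tids, name="transcript_id")
    )
    truth = pd.DataFrame(
        {
            "planted_mode": modes,
            "true_mean_fpkm_H": mean_fpkm["H"],
            "true_mean_fpkm_P1": mean_fpkm["P1"],
            "true_mean_fpkm_P2": mean_fpkm["P2"],
            "parents_equal": parents_equal,
            "enriched_go_flag": False,
        },
        index=mean_fpkm.index,
    )
    return truth, mean_fpkm


def sample_counts(
    mean_fpkm: pd.DataFrame,
    models: list[TranscriptModel],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw negative-binomial fragment counts from the planted means.

    Expected count = mean_fpkm * (length/1e3) * (library_size/1e6);
    var = mu + d*mu^2 via a gamma-Poisson mixture (Poisson when d = 0).
    Reproducible from the config seed unless an explicit generator is
    passed (replicate draws).
    """
    config.validate()
    if (mean_fpkm.to_numpy() < 0).any():
        raise ContractViolation("mean FPKM values must be >= 0")
    if rng is None:
        rng = _rng(config.seed, _STREAM_COUNTS)
    lengths = pd.Series(
        {m.transcript_id: m.length for m in models}, name="length"
    ).reindex(mean_fpkm.index)
    mu = mean_fpkm.mul(lengths / 1e3, axis=0) * (config.library_size / 1e6)
    d = config.nb_dispersion
    out = {}
    for s in mean_fpkm.columns:
        m = mu[s].to_numpy()
        if d == 0:
            out[s] = rng.poisson(m)
        else:
            lam = np.where(m > 0, rng.gamma(1.0 / d, np.maximum(m, 1e-300) * d), 0.0)
            out[s] = rng.poisson(lam)
    return pd.DataFrame(out, index=mean_fpkm.index)


def hybrid_specific_truth(truth: pd.DataFrame) -> pd.Index:
    """Transcripts whose planted means show the hybrid-specific pattern
    (H differs from both parents, parents identical) -- the planted
    counterpart of the HPco subgroup."""
    h = truth["true_mean_fpkm_H"]
    p1 = truth["true_mean_fpkm_P1"]
    p2 = truth["true_mean_fpkm_P2"]
    mask = (p1 == p2) & (h != p1) & (truth["planted_mode"] != "null")
    return truth.index[mask]


def plant_go_annotations(
    models: list[TranscriptModel],
    truth: pd.DataFrame,
    n_terms: int = 50,
    enrichment_factor: float = 5.0,
    seed: int | None = None,
    background_rate: float = 0.05,
    n_enriched: int = 5,
) -> tuple[dict[str, frozenset[str]], list[str]]:
    """Annotate transcripts to synthetic GO terms with planted enrichment.

    Every transcript is annotated to each term independently at
    ``background_rate``; the first ``n_enriched`` terms annotate the
    planted hybrid-specific transcripts at ``enrichment_factor`` times
    that rate instead. With factor 1 no term is enriched by construction
    and the returned truth list is empty. Sets truth's ``enriched_go_flag``
    for transcripts annotated to a truly enriched term.
    """
    if n_terms < 1:
        raise ContractViolation("n_terms must be >= 1")
    if enrichment_factor < 1:
        raise ContractViolation("enrichment_factor must be >= 1")
    if not 0 < background_rate <= 1:
        raise ContractViolation("background_rate must be in (0, 1]")
    rng = _rng(0 if seed is None else seed, _STREAM_GO)
    tids = truth.index
    target = truth.index.isin(hybrid_specific_truth(truth))
    width = len(str(n_terms)) + 1
    terms = [f"GO:SIM{i + 1:0{width}d}" for i in range(n_terms)]
    enriched = terms[: min(n_enriched, n_terms)] if enrichment_factor > 1 else []
    rate = np.full((len(tids), n_terms), background_rate)
    for j, term in enumerate(terms):
        if term in enriched:
            rate[target, j] = min(1.0, enrichment_factor * background_rate)
    hits = rng.random(rate.shape) < rate
    annotation = {
        tid: frozenset(terms[j] for j in np.flatnonzero(hits[i]))
        for i, tid in enumerate(tids)
    }
    enriched_set = set(enriched)
    truth["enriched_go_flag"] = [
        bool(annotation[tid] & enriched_set) for tid in tids
    ]
    return annotation, enriched


@dataclass
class SimulatedStudy:
    """Bundle of one synthetic study: models, truth, means, counts, GO."""

    config: SimulationConfig
    models: list[TranscriptModel]
    truth: pd.DataFrame
    mean_fpkm: pd.DataFrame
    counts: pd.DataFrame
    annotations: dict[str, frozenset[str]]
    enriched_terms: list[str]

    @property
    def gene_ids(self) -> pd.Series:
        return pd.Series(
            {m.transcript_id: m.gene_id for m in self.models}, name="gene_id"
        ).reindex(self.counts.index)

    @property
    def lengths(self) -> pd.Series:
        return pd.Series(
            {m.transcript_id: m.length for m in self.models}, name="length"
        ).reindex(self.counts.index)


def simulate_study(
    config: SimulationConfig,
    n_terms: int = 50,
    enrichment_factor: float = 5.0,
    background_rate: float = 0.05,
    n_enriched: int = 5,
) -> SimulatedStudy:
    """Run all four generator stages under one master seed."""
    models = generate_gene_models(config)
    truth, mean_fpkm = plant_expression(models, config)
    counts = sample_counts(mean_fpkm, models, config)
    annotations, enriched = plant_go_annotations(
        models,
        truth,
        n_terms=n_terms,
        enrichment_factor=enrichment_factor,
        seed=config.seed,
        background_rate=background_rate,
        n_enriched=n_enriched,
    )
    return SimulatedStudy(config, models, truth, mean_fpkm, counts, annotations, enriched)
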