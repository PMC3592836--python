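"""Transcript abundance and read-mapping summaries.

FPKM (fragments per kilobase of exon per million mapped fragments),
gene-locus coverage from read intervals, per-sample abundance/coverage bin
summaries, read-mapping rates, and alignment-score arithmetic for 50 bp
single-end reads.

All genomic coordinates in this package are 0-based half-open; the GTF
reader converts from GTF's 1-based closed convention at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ContractViolation

#: canonical sample order: hybrid, parent 1 (tiger puffer), parent 2 (tawny puffer)
SAMPLES = ("H", "P1", "P2")


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript: its gene, exon structure and summed exon length.

    Exons are 0-based half-open intervals, sorted and non-overlapping.
    The summed exon length is the denominator of FPKM.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ContractViolation(f"{self.transcript_id}: transcript needs >=1 exon")
        if self.strand not in ("+", "-"):
            raise ContractViolation(f"{self.transcript_id}: strand must be '+' or '-'")
        prev_end = None
        for start, end in self.exons:
            if end <= start:
                raise ContractViolation(
                    f"{self.transcript_id}: empty exon interval [{start}, {end})"
                )
            if prev_end is not None and start < prev_end:
                raise ContractViolation(
                    f"{self.transcript_id}: exons unsorted or overlapping"
                )
            prev_end = end

    @property
    def length(self) -> int:
        """Summed exon length in bases."""
        return sum(end - start for start, end in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        """Genomic span from first exon start to last exon end."""
        return self.exons[0][0], self.exons[-1][1]


@dataclass(frozen=True)
class AlignmentScoreParams:
    """Penalties of the read alignment score: ``len - nm*(1+mp) - jp``.

    mp : mapping-mismatch penalty (dimensionless, >= 0)
    jp : flat junction-alignment penalty, applied only to junction reads
    """

    mp: float = 1.0
    jp: float = 0.0

    def __post_init__(self) -> None:
        if self.mp < 0:
            raise ContractViolation("mp must be >= 0")
        if self.jp < 0:
            raise ContractViolation("jp must be >= 0")


@dataclass(frozen=True)
class MappingStats:
    """Read-mapping summary for one library."""

    reads_generated: int
    reads_mapped: int
    reads_unique: int
    read_length: int = 50

    @property
    def mapping_rate(self) -> float:
        """Mapped reads / generated reads, in percent."""
        return self.reads_mapped / self.reads_generated * 100.0

    @property
    def unique_rate(self) -> float:
        """Uniquely mapped reads / mapped reads, in percent."""
        return self.reads_unique / self.reads_mapped * 100.0

    @property
    def total_bases(self) -> int:
        """Total sequenced bases: generated reads x read length."""
        return self.reads_generated * self.read_length


@dataclass
class ExpressionTable:
    """Per-transcript fragment counts and FPKM for the three samples.

    counts, fpkm : DataFrames indexed by transcript_id with columns SAMPLES.
    lengths      : summed exon length per transcript (bp).
    gene_ids     : gene of each transcript.
    """

    counts: pd.DataFrame
    fpkm: pd.DataFrame
    lengths: pd.Series
    gene_ids: pd.Series
    totals: pd.Series = field(default=None)  # fragments used as FPKM denominator

    @classmethod
    def from_counts(
        cls,
        counts: pd.DataFrame,
        lengths: pd.Series,
        gene_ids: pd.Series,
        totals: pd.Series | None = None,
    ) -> "ExpressionTable":
        """Build the table, deriving FPKM from counts.

        ``totals`` defaults to each sample's realized total mapped fragments
        (the literal FPKM definition); pass effective library sizes instead
        to obtain depth-normalized FPKM.
        """
        counts = counts.loc[:, list(SAMPLES)]
        lengths = lengths.reindex(counts.index)
        gene_ids = gene_ids.reindex(counts.index)
        if totals is None:
            totals = counts.sum(axis=0)
        totals = pd.Series(totals).reindex(counts.columns)
        fpkm = pd.DataFrame(
            {
                s: compute_fpkm(counts[s].to_numpy(), lengths.to_numpy(), totals[s])
                for s in counts.columns
            },
            index=counts.index,
        )
        return cls(counts=counts, fpkm=fpkm, lengths=lengths, gene_ids=gene_ids, totals=totals)


def compute_fpkm(count, transcript_length_bp, total_mapped_fragments):
    """FPKM = count / ((length/1000) * (total/1e6)).

    Accepts scalars or numpy arrays; zero iff count is zero.
    """
    length = np.asarray(transcript_length_bp, dtype=float)
    total = float(total_mapped_fragments)
    if np.any(length <= 0):
        raise ContractViolation("transcript length must be > 0")
    if total <= 0:
        raise ContractViolation("total mapped fragments must be > 0")
    count_arr = np.asarray(count, dtype=float)
    if np.any(count_arr < 0):
        raise ContractViolation("fragment count must be >= 0")
    out = count_arr / ((length / 1_000.0) * (total / 1_000_000.0))
    if np.isscalar(count) or np.ndim(count) == 0:
        return float(out)
    return out


def _merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for start, end in sorted((int(s), int(e)) for s, e in intervals):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def compute_locus_coverage(
    gene_locus: tuple[int, int], read_intervals: Iterable[tuple[int, int]]
) -> float:
    """Fraction of locus bases overlapped by >=1 read interval.

    Both the locus and the reads are 0-based half-open intervals on the
    same chromosome. A coverage of 1 means the locus is fully covered.
    """
    start, end = int(gene_locus[0]), int(gene_locus[1])
    if end <= start:
        raise ContractViolation(f"empty gene locus [{start}, {end})")
    covered = 0
    for rs, re in _merge_intervals(read_intervals):
        covered += max(0, min(re, end) - max(rs, start))
    return covered / (end - start)


def alignment_score(
    length: float, nm: float, params: AlignmentScoreParams, junction: bool = False
) -> float:
    """Alignment score ``len - nm*(1+mp) - jp`` (jp only for junction reads).

    ``length`` is the number of alignment hits (colors, for 2-base-encoded
    reads) and ``nm`` the mismatch count.
    """
    if length < 0 or nm < 0:
        raise ContractViolation("len and nm must be >= 0")
    return float(length) - float(nm) * (1.0 + params.mp) - (params.jp if junction else 0.0)


def score_cdf(scores: Sequence[float], thresholds: Sequence[float]) -> np.ndarray:
    """For each threshold t, the fraction of scores >= t (complementary CDF).

    Non-increasing in t; all values in [0, 1].
    """
    arr = np.asarray(list(scores), dtype=float)
    if arr.size == 0:
        raise ContractViolation("score_cdf requires a non-empty score collection")
    sorted_scores = np.sort(arr)
    ts = np.asarray(list(thresholds), dtype=float)
    # fraction >= t == 1 - (index of first element >= t)/n
    idx = np.searchsorted(sorted_scores, ts, side="left")
    return 1.0 - idx / arr.size


def mapping_stats(
    reads_generated: int, reads_mapped: int, reads_unique: int, read_length: int = 50
) -> MappingStats:
    """Mapping-rate summary; enforces unique <= mapped <= generated."""
    if not (0 <= reads_unique <= reads_mapped <= reads_generated):
        raise ContractViolation(
            "read counts must satisfy unique <= mapped <= generated "
            f"(got {reads_unique}, {reads_mapped}, {reads_generated})"
        )
    if reads_generated <= 0 or reads_mapped <= 0:
        raise ContractViolation("generated and mapped read counts must be positive")
    return MappingStats(reads_generated, reads_mapped, reads_unique, read_length)


def gene_loci(models: Iterable[TranscriptModel]) -> pd.DataFrame:
    """Per-gene locus span (min exon start to max exon end over transcripts)."""
    rows: dict[str, list] = {}
    for m in models:
        s, e = m.span
        if m.gene_id in rows:
            rows[m.gene_id][1] = min(rows[m.gene_id][1], s)
            rows[m.gene_id][2] = max(rows[m.gene_id][2], e)
        else:
            rows[m.gene_id] = [m.chrom, s, e]
    df = pd.DataFrame.from_dict(rows, orient="index", columns=["chrom", "start", "end"])
    df.index.name = "gene_id"
    return df


def coverage_table(
    models: Iterable[TranscriptModel],
    read_intervals: dict[str, pd.DataFrame],
) -> pd.DataFrame:
    """Gene-locus coverage per sample.

    ``read_intervals`` maps sample name -> BED-style DataFrame with columns
    chrom/start/end. Returns a gene x sample DataFrame of coverage fractions.
    """
    loci = gene_loci(models)
    out = {}
    for sample, bed in read_intervals.items():
        by_chrom = {c: sub[["start", "end"]].to_numpy() for c, sub in bed.groupby("chrom")}
        vals = []
        for gid, row in loci.iterrows():
            reads = by_chrom.get(row["chrom"], np.empty((0, 2), dtype=int))
            vals.append(compute_locus_coverage((row["start"], row["end"]), reads))
        out[sample] = vals
    return pd.DataFrame(out, index=loci.index)


def summarize_abundance(
    expression: ExpressionTable,
    coverage: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Per-sample abundance summary with the standard reporting bins.

    For each sample: transcripts detected (FPKM>0), detected in that sample
    only, low-abundance (0<FPKM<1) and high-abundance (FPKM>100) bins; genes
    detected / unique; and, when a gene x sample ``coverage`` table is given,
    genes with locus coverage <0.2 and >0.8 among detected genes.

    Returns the per-sample table plus union/intersection sizes across samples.
    """
    fpkm = expression.fpkm
    detected = fpkm > 0
    gene_ids = expression.gene_ids
    rows = {}
    n_detected_samples = detected.sum(axis=1)
    gene_detected = {s: set(gene_ids[detected[s]]) for s in fpkm.columns}
    genes_in_one_sample = {
        s: gene_detected[s].difference(*(gene_detected[o] for o in fpkm.columns if o != s))
        for s in fpkm.columns
    }
    for s in fpkm.columns:
        det = detected[s]
        row = {
            "transcripts_all": int(det.sum()),
            "transcripts_unique": int((det & (n_detected_samples == 1)).sum()),
            "fpkm_lt1": int((det & (fpkm[s] < 1)).sum()),
            "fpkm_gt100": int((fpkm[s] > 100).sum()),
            "genes_all": len(gene_detected[s]),
            "genes_unique": len(genes_in_one_sample[s]),
        }
        if coverage is not None and s in coverage.columns:
            cov = coverage.loc[sorted(gene_detected[s] & set(coverage.index)), s]
            row["cov_lt02"] = int((cov < 0.2).sum())
            row["cov_gt08"] = int((cov > 0.8).sum())
        rows[s] = row
    summary = pd.DataFrame.from_dict(rows, orient="index")
    summary.index.name = "sample"
    union_t = int((n_detected_samples > 0).sum())
    inter_t = int((n_detected_samples == len(fpkm.columns)).sum())
    all_gene_sets = list(gene_detected.values())
    totals = {
        "transcript_union": union_t,
        "transcript_intersection": inter_t,
        "gene_union": len(set().union(*all_gene_sets)) if all_gene_sets else 0,
        "gene_intersection": len(set.intersection(*all_gene_sets)) if all_gene_sets else 0,
    }
    return summary, totals
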