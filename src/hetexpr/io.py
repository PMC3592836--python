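"""Readers and writers for the pipeline's file formats.

GTF gene models (1-based closed on disk, 0-based half-open in memory),
TSV count/truth/annotation tables, BED read intervals, per-read alignment
statistics, and the JSON list of truly enriched terms.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import DataError
from .quantify import SAMPLES, TranscriptModel


def write_gtf(models: Iterable[TranscriptModel], path) -> None:
    """Write exon features, converting to GTF's 1-based closed coordinates."""
    with open(path, "w") as fh:
        for m in models:
            for start, end in m.exons:
                attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}";'
                fh.write(
                    f"{m.chrom}\thetexpr\texon\t{start + 1}\t{end}\t.\t{m.strand}\t.\t{attrs}\n"
                )


def read_gtf(path) -> list[TranscriptModel]:
    """Read exon features into transcript models (via gffutils)."""
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    grouped: dict[str, dict] = {}
    for feat in db.features_of_type("exon"):
        tid = feat.attributes["transcript_id"][0]
        gid = feat.attributes["gene_id"][0]
        rec = grouped.setdefault(
            tid, {"gene_id": gid, "chrom": feat.seqid, "strand": feat.strand, "exons": []}
        )
        rec["exons"].append((feat.start - 1, feat.end))  # to 0-based half-open
    models = []
    for tid, rec in grouped.items():
        models.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=rec["gene_id"],
                chrom=rec["chrom"],
                strand=rec["strand"] if rec["strand"] in ("+", "-") else "+",
                exons=tuple(sorted(rec["exons"])),
            )
        )
    if not models:
        raise DataError(f"no exon features found in {path}")
    return models


def write_counts(counts: pd.DataFrame, gene_ids: pd.Series, path) -> None:
    out = counts.copy()
    out.insert(0, "gene_id", gene_ids.reindex(counts.index))
    out.index.name = "transcript_id"
    out.to_csv(path, sep="\t")


def read_counts(path) -> tuple[pd.DataFrame, pd.Series]:
    """Read a count table; returns (counts[H, P1, P2], gene_ids)."""
    df = pd.read_csv(path, sep="\t", index_col="transcript_id")
    # accept either canonical or count_-prefixed column names
    renames = {f"count_{s}": s for s in SAMPLES}
    df = df.rename(columns=renames)
    missing = [s for s in SAMPLES if s not in df.columns]
    if missing:
        raise DataError(f"count table {path} lacks column(s) {missing}")
    gene_ids = df["gene_id"] if "gene_id" in df.columns else pd.Series(index=df.index, dtype=object)
    return df[list(SAMPLES)], gene_ids


def read_bed(path) -> pd.DataFrame:
    """Read BED3 intervals (chrom, start, end; 0-based half-open)."""
    df = pd.read_csv(
        path, sep="\t", header=None, usecols=[0, 1, 2], names=["chrom", "start", "end"],
        comment="#",
    )
    if (df["end"] <= df["start"]).any():
        raise DataError(f"{path}: BED intervals must have end > start")
    return df


def write_annotations(annotation_map: Mapping[str, Iterable[str]], path) -> None:
    """Two-column TSV: transcript_id, GO term (one row per pair)."""
    with open(path, "w") as fh:
        for tid in sorted(annotation_map):
            for term in sorted(annotation_map[tid]):
                fh.write(f"{tid}\t{term}\n")


def read_annotations(path) -> dict[str, frozenset[str]]:
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise DataError(f"{path}:{i}: expected 2 tab-separated columns")
            out.setdefault(parts[0], set()).add(parts[1])
    return {k: frozenset(v) for k, v in out.items()}


def read_alignment_stats(path) -> pd.DataFrame:
    """TSV of per-read alignment stats: len, nm, junction (0/1)."""
    df = pd.read_csv(path, sep="\t")
    needed = {"len", "nm", "junction"}
    if not needed <= set(df.columns):
        raise DataError(f"{path}: alignment stats need columns {sorted(needed)}")
    return df


def write_enriched_terms(terms: Iterable[str], path) -> None:
    Path(path).write_text(json.dumps(sorted(terms), indent=0) + "\n")


def read_enriched_terms(path) -> list[str]:
    return list(json.loads(Path(path).read_text()))
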