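"""Reporting helpers: half-up percentage rounding and table rendering.

Percentages are reported to 1 decimal place with half-up rounding, the
convention of the study tables this layout mirrors.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .quantify import MappingStats, mapping_stats


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Round half away from zero (0.25 -> 0.3 at 1 digit), unlike the
    banker's rounding of built-in round()."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def pct(numerator: float, denominator: float, ndigits: int = 1) -> float:
    """Percentage at fixed precision, half-up."""
    return round_half_up(numerator / denominator * 100.0, ndigits)


def mapping_summary(read_counts: pd.DataFrame, read_length: int = 50) -> pd.DataFrame:
    """Mapping-rate table with a Total row, from per-sample read counts.

    ``read_counts`` needs columns reads_generated, reads_mapped,
    reads_unique (one row per library). Rates are percentages at 1 d.p.;
    total sequenced megabases come from generated reads x read length.
    """
    rows = {}
    for name, rec in read_counts.iterrows():
        st = mapping_stats(
            int(rec["reads_generated"]), int(rec["reads_mapped"]), int(rec["reads_unique"]),
            read_length,
        )
        rows[name] = _mapping_row(st)
    total = mapping_stats(
        int(read_counts["reads_generated"].sum()),
        int(read_counts["reads_mapped"].sum()),
        int(read_counts["reads_unique"].sum()),
        read_length,
    )
    rows["Total"] = _mapping_row(total)
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "sample"
    return out


def _mapping_row(st: MappingStats) -> dict:
    return {
        "reads_generated": st.reads_generated,
        "reads_mapped": st.reads_mapped,
        "mapping_rate_pct": round_half_up(st.mapping_rate, 1),
        "reads_unique": st.reads_unique,
        "unique_rate_pct": round_half_up(st.unique_rate, 1),
        "total_mbp": round_half_up(st.total_bases / 1e6, 1),
    }


def abundance_shares(abundance: pd.DataFrame) -> pd.DataFrame:
    """Low/high-abundance bin shares per sample (percent of detected)."""
    out = pd.DataFrame(index=abundance.index)
    out["fpkm_lt1_pct"] = [
        pct(r["fpkm_lt1"], r["transcripts_all"]) for _, r in abundance.iterrows()
    ]
    out["fpkm_gt100_pct"] = [
        pct(r["fpkm_gt100"], r["transcripts_all"]) for _, r in abundance.iterrows()
    ]
    return out


def extreme_fold_share(bin_totals: pd.Series) -> float:
    """Share (percent, 1 d.p.) of strongly changed entries: (Up2 + Down2)
    over all four fold-change bins."""
    total = float(sum(bin_totals[b] for b in ("Up1", "Up2", "Down1", "Down2")))
    return pct(bin_totals["Up2"] + bin_totals["Down2"], total)


def render_tsv(df: pd.DataFrame, path) -> None:
    """Write a table deterministically (fixed column order, '\\t', no mtime
    dependence)."""
    df.to_csv(path, sep="\t")
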