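"""Gene-action classification of hybrid differential transcripts.

Differential transcripts (DTs) from the three pairwise comparisons are
partitioned into seven mutually exclusive subgroups by their significance
pattern, every hybrid DT is classified into one of five gene-action
categories by comparing its hybrid expression with the two parental levels,
and parental fold changes are binned by magnitude.

Categories and the heterosis mode each one indicates:

====================  =========================================
above_high            overdominance (hybrid above both parents)
high_parent           dominance toward the higher parent
mid_parent            additivity (hybrid at the parental mean)
low_parent            dominance toward the lower parent
below_low             underdominance (hybrid below both parents)
====================  =========================================
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ContractViolation

CATEGORIES = ("below_low", "low_parent", "mid_parent", "high_parent", "above_high")

#: fixed category -> heterosis mode map
MODE_MAP = {
    "below_low": "underdominance",
    "low_parent": "dominance_low",
    "mid_parent": "additivity",
    "high_parent": "dominance_high",
    "above_high": "overdominance",
}

#: significance pattern (H_vs_P1, H_vs_P2, P1_vs_P2) -> subgroup label.
#: HP1/HP2 are the hybrid-vs-one-parent DTs that are also parental DTs;
#: HPco is the hybrid-specific core (both hybrid comparisons, parents alike).
SUBGROUP_PATTERNS = {
    (True, False, False): "HTiU",
    (False, True, False): "HTaU",
    (False, False, True): "PPU",
    (True, False, True): "HP1",
    (False, True, True): "HP2",
    (True, True, False): "HPco",
    (True, True, True): "co",
}

SUBGROUPS = ("HTiU", "HP1", "HPco", "co", "HTaU", "HP2", "PPU")
#: subgroups whose members are hybrid DTs (PPU is parent-only)
HYBRID_SUBGROUPS = ("HTiU", "HP1", "HPco", "co", "HTaU", "HP2")

DEFAULT_TAU = math.log(1.5)

FOLD_BINS = ("Up1", "Up2", "Down1", "Down2")


@dataclass(frozen=True)
class GeneActionCall:
    """One transcript's gene-action category and heterosis mode."""

    transcript_id: str
    category: str
    mode: str
    tolerance_used: float


def partition_subgroups(de_calls: pd.DataFrame) -> pd.Series:
    """Assign each DT to one of the seven subgroups by significance pattern.

    ``de_calls`` must hold all three comparisons for every transcript
    (the output of :func:`hetexpr.diffexp.call_de`). Transcripts significant
    in no comparison are excluded. Returns transcript_id -> subgroup label.
    """
    wide = de_calls.pivot(index="transcript_id", columns="comparison", values="significant")
    expected = {"H_vs_P1", "H_vs_P2", "P1_vs_P2"}
    if set(wide.columns) != expected or wide.isna().any().any():
        raise ContractViolation(
            "partition_subgroups needs all three comparisons per transcript"
        )
    labels = {}
    for tid, row in wide.iterrows():
        pattern = (bool(row["H_vs_P1"]), bool(row["H_vs_P2"]), bool(row["P1_vs_P2"]))
        if pattern == (False, False, False):
            continue
        labels[tid] = SUBGROUP_PATTERNS[pattern]
    out = pd.Series(labels, dtype=object)
    out.index.name = "transcript_id"
    out.name = "subgroup"
    return out


def _classify_arrays(h, p1, p2, tau: float, pseudo: float):
    """Vectorized gene-action classification on pseudocount-adjusted FPKM."""
    h = np.asarray(h, dtype=float) + pseudo
    p1 = np.asarray(p1, dtype=float) + pseudo
    p2 = np.asarray(p2, dtype=float) + pseudo
    m = np.minimum(p1, p2)
    big = np.maximum(p1, p2)
    mid = (p1 + p2) / 2.0
    d_low = np.abs(np.log(h / m))
    d_mid = np.abs(np.log(h / mid))
    d_high = np.abs(np.log(h / big))
    out = np.empty(h.shape, dtype=object)
    # nearest anchor in log space; any exact tie for the minimum -> mid_parent
    nearest = np.where(
        (d_mid <= d_low) & (d_mid <= d_high),
        "mid_parent",
        np.where(d_low < d_high, "low_parent",
                 np.where(d_high < d_low, "high_parent", "mid_parent")),
    )
    out[:] = nearest
    out[np.log(h / big) > tau] = "above_high"
    out[np.log(m / h) > tau] = "below_low"
    return out


def classify_gene_action(
    fpkm_h: float,
    fpkm_p1: float,
    fpkm_p2: float,
    tolerance_tau: float = DEFAULT_TAU,
    pseudo_fpkm: float = 0.1,
    transcript_id: str = "",
) -> GeneActionCall:
    """Classify one transcript's gene action from its three FPKM values.

    On pseudocount-adjusted FPKM with m = min(P1,P2), M = max(P1,P2) and
    mid = (P1+P2)/2: ln(H/M) > tau -> above_high; ln(m/H) > tau ->
    below_low; otherwise the nearest of {m, mid, M} in absolute log
    distance gives {low, mid, high}_parent, with exact ties going to
    mid_parent. tau is the log-scale tolerance behind "approximate to"
    (default ln 1.5).
    """
    if tolerance_tau <= 0:
        raise ContractViolation("tolerance_tau must be > 0")
    if min(fpkm_h, fpkm_p1, fpkm_p2) < 0:
        raise ContractViolation("FPKM values must be >= 0")
    category = _classify_arrays(
        np.array([fpkm_h]), np.array([fpkm_p1]), np.array([fpkm_p2]), tolerance_tau, pseudo_fpkm
    )[0]
    return GeneActionCall(transcript_id, category, MODE_MAP[category], tolerance_tau)


def classify_table(
    fpkm: pd.DataFrame,
    tolerance_tau: float = DEFAULT_TAU,
    pseudo_fpkm: float = 0.1,
) -> pd.DataFrame:
    """Classify every row of a transcript x {H, P1, P2} FPKM table.

    Returns a DataFrame indexed by transcript_id with columns category, mode.
    """
    if tolerance_tau <= 0:
        raise ContractViolation("tolerance_tau must be > 0")
    cats = _classify_arrays(
        fpkm["H"].to_numpy(), fpkm["P1"].to_numpy(), fpkm["P2"].to_numpy(),
        tolerance_tau, pseudo_fpkm,
    )
    out = pd.DataFrame({"category": cats}, index=fpkm.index)
    out["mode"] = out["category"].map(MODE_MAP)
    out.index.name = "transcript_id"
    return out


def bin_fold_change(ln_ratio: float) -> str | None:
    """Bin a parental fold change ln(x/H) by sign and magnitude.

    Up1: -2 <= ln < 0 (up-regulated in the hybrid, moderate); Up2: ln < -2
    (strong); Down1: 0 < ln <= 2; Down2: ln > 2. Exact boundary values go
    to the adjacent bin nearer zero; ln == 0 falls in no bin (None).
    """
    if not np.isfinite(ln_ratio):
        raise ContractViolation("ln_ratio must be finite")
    if ln_ratio < -2:
        return "Up2"
    if ln_ratio < 0:
        return "Up1"
    if ln_ratio == 0:
        return None
    if ln_ratio <= 2:
        return "Down1"
    return "Down2"


def bin_fold_changes(ln_ratios) -> pd.Series:
    """Vectorized :func:`bin_fold_change`; index is preserved."""
    s = pd.Series(ln_ratios, dtype=float)
    if not np.isfinite(s.to_numpy()).all():
        raise ContractViolation("ln ratios must be finite")
    return s.map(bin_fold_change)


def summarize_actions(subgroups: pd.Series, action_calls: pd.DataFrame) -> pd.DataFrame:
    """Subgroup x category contingency table with totals and shares.

    ``subgroups`` maps transcript_id -> subgroup label and ``action_calls``
    is the output of :func:`classify_table`. PPU transcripts are not hybrid
    DTs and are excluded. The result has one row per hybrid subgroup plus a
    Total row, one column per category plus a row_total column, and a final
    "pct_of_total" row of category shares (percent of the grand total,
    1 decimal place, half-up).
    """
    from .report import round_half_up

    sub = subgroups[subgroups != "PPU"]
    joined = action_calls.join(sub.rename("subgroup"), how="inner")
    table = pd.DataFrame(0, index=list(HYBRID_SUBGROUPS), columns=list(CATEGORIES))
    if len(joined):
        counts = joined.groupby(["subgroup", "category"], observed=True).size()
        for (sg, cat), n in counts.items():
            table.loc[sg, cat] = int(n)
    table.loc["Total"] = table.sum(axis=0)
    table["row_total"] = table.sum(axis=1)
    grand = int(table.loc["Total", "row_total"])
    pct = {
        cat: round_half_up(table.loc["Total", cat] / grand * 100, 1) if grand else 0.0
        for cat in CATEGORIES
    }
    pct["row_total"] = 100.0 if grand else 0.0
    table.loc["pct_of_total"] = pd.Series(pct)
    table.index.name = "subgroup"
    return table
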