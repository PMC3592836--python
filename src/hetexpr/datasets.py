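"""Bundled example data: published summary tables from a three-sample
pufferfish transcriptome experiment.

A tiger puffer (P1), a tawny puffer (P2) and their F1 hybrid (H) were
sequenced with 50 bp single-end reads, one pooled library per genotype.
These are the study's printed summary tables -- read-mapping counts,
abundance bins, the gene-action contingency table and the enriched-term
fold-change bins -- used as worked-example inputs for the reporting
operations. They are inputs to arithmetic, not outputs of this package.
"""

from __future__ import annotations

import pandas as pd

READ_LENGTH = 50

_SAMPLE_ORDER = ["tiger_puffer", "tawny_puffer", "hybrid"]


def mapping_counts() -> pd.DataFrame:
    """Per-library read counts: generated, mapped, uniquely mapped."""
    return pd.DataFrame(
        {
            "reads_generated": [82_479_484, 70_915_736, 90_401_656],
            "reads_mapped": [41_074_430, 44_304_273, 51_003_170],
            "reads_unique": [31_028_999, 35_089_656, 39_219_548],
        },
        index=pd.Index(_SAMPLE_ORDER, name="sample"),
    )


def abundance_counts() -> pd.DataFrame:
    """Per-sample transcript/gene abundance and coverage bins."""
    return pd.DataFrame(
        {
            "transcripts_all": [36_760, 38_238, 38_178],
            "transcripts_unique": [1_676, 2_096, 1_953],
            "fpkm_lt1": [19_444, 17_136, 14_910],
            "fpkm_gt100": [836, 1_101, 1_427],
            "genes_all": [16_399, 16_912, 17_032],
            "genes_unique": [325, 470, 517],
            "cov_lt02": [7_039, 5_179, 5_080],
            "cov_gt08": [3_154, 5_384, 5_634],
        },
        index=pd.Index(_SAMPLE_ORDER, name="sample"),
    )


#: union sizes over the three samples
TRANSCRIPT_UNION = 44_305
GENE_UNION = 18_164
#: potentially novel transcript isoforms reported for the hybrid
NOVEL_ISOFORMS_HYBRID = 8_579


def gene_action_counts() -> pd.DataFrame:
    """Hybrid-DT subgroup x gene-action category contingency table."""
    return pd.DataFrame(
        {
            "below_low": [187, 7, 237, 16, 289, 6],
            "low_parent": [65, 210, 0, 35, 176, 646],
            "mid_parent": [1, 407, 0, 20, 6, 73],
            "high_parent": [79, 850, 0, 0, 13, 100],
            "above_high": [3_094, 1_173, 1_787, 142, 1_114, 219],
        },
        index=pd.Index(["HTiU", "HP1", "HPco", "co", "HTaU", "HP2"], name="subgroup"),
    )


def enriched_bin_counts() -> pd.DataFrame:
    """Fold-change bin counts per enriched level-4 GO term, with FDR."""
    rows = [
        ("intracellular", 215, 296, 14, 63, 7.12e-5),
        ("nucleotide binding", 76, 111, 9, 21, 1.88e-4),
        ("GTPase regulator activity", 17, 26, 2, 7, 2.81e-4),
        ("ligase activity", 23, 15, 5, 3, 2.81e-4),
        ("hydrolase activity", 65, 110, 4, 25, 5.86e-4),
        ("protein metabolic process", 72, 136, 5, 22, 2.10e-3),
        ("cellular catabolic process", 43, 41, 3, 7, 2.33e-3),
    ]
    return pd.DataFrame(
        rows, columns=["term", "Up1", "Up2", "Down1", "Down2", "FDR"]
    ).set_index("term")
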