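"""GO-term over-representation analysis.

One-tailed (upper-tail) Fisher's exact test of a test set of transcripts
against a reference set per GO term, Benjamini-Hochberg FDR across tested
terms and a 0.01 enrichment filter; plus is_a-level projection of
annotations for level-2 / level-4 summaries (root = level 1, minimum-depth
convention) and the true-path rule (a transcript annotated to a term is
annotated to all its ancestors).
"""

from __future__ import annotations

import logging
from typing import Collection, Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ContractViolation, DataError
from .diffexp import adjust_fdr

logger = logging.getLogger(__name__)


class OntologyGraph:
    """A DAG of GO terms with is_a parent edges and level bookkeeping.

    Levels follow the convention used by GO summary tools: a namespace root
    is level 1 and level(t) = 1 + min over parents, i.e. the shortest is_a
    path from a root. The graph must be acyclic with every term reaching a
    root.
    """

    def __init__(self, parents: Mapping[str, Iterable[str]]):
        self.parents: dict[str, frozenset[str]] = {}
        terms = set(parents)
        for t, ps in parents.items():
            ps = frozenset(ps)
            terms |= ps
            self.parents[t] = ps
        for t in terms:
            self.parents.setdefault(t, frozenset())
        self.roots = frozenset(t for t, ps in self.parents.items() if not ps)
        if not self.roots:
            raise DataError("ontology has no root terms")
        self.levels: dict[str, int] = {}
        self._compute_levels()

    def _compute_levels(self) -> None:
        # iterative DFS with cycle detection; level = 1 + min(parent levels)
        WHITE, GRAY, BLACK = 0, 1, 2
        color = {t: WHITE for t in self.parents}
        for start in self.parents:
            if color[start] != WHITE:
                continue
            stack = [(start, iter(self.parents[start]))]
            color[start] = GRAY
            while stack:
                node, it = stack[-1]
                advanced = False
                for p in it:
                    if color[p] == GRAY:
                        raise DataError(f"ontology contains a cycle through {p!r}")
                    if color[p] == WHITE:
                        color[p] = GRAY
                        stack.append((p, iter(self.parents[p])))
                        advanced = True
                        break
                if advanced:
                    continue
                stack.pop()
                color[node] = BLACK
                ps = self.parents[node]
                self.levels[node] = 1 if not ps else 1 + min(self.levels[p] for p in ps)

    @classmethod
    def from_obo(cls, path) -> "OntologyGraph":
        """Read is_a edges from an OBO file (via obonet)."""
        import obonet

        graph = obonet.read_obo(path)
        parents: dict[str, set[str]] = {n: set() for n in graph.nodes}
        for child, parent, key in graph.edges(keys=True):
            if key == "is_a":
                parents[child].add(parent)
        return cls(parents)

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]]) -> "OntologyGraph":
        """Build from (child, parent) pairs."""
        parents: dict[str, set[str]] = {}
        for child, parent in edges:
            parents.setdefault(child, set()).add(parent)
            parents.setdefault(parent, set())
        return cls(parents)

    def __contains__(self, term: str) -> bool:
        return term in self.parents

    def level(self, term: str) -> int:
        return self.levels[term]

    def ancestors(self, term: str) -> frozenset[str]:
        """All ancestors of a term, including the term itself."""
        seen: set[str] = set()
        frontier = [term]
        while frontier:
            t = frontier.pop()
            if t in seen:
                continue
            seen.add(t)
            frontier.extend(self.parents[t])
        return frozenset(seen)

    def project(self, term: str, level: int) -> frozenset[str]:
        """Ancestors of ``term`` (term included) sitting at ``level``.

        Empty when the term is nearer the root than the requested level.
        """
        return frozenset(t for t in self.ancestors(term) if self.levels[t] == level)


def propagate_annotations(
    annotation_map: Mapping[str, Collection[str]], ontology: OntologyGraph
) -> dict[str, frozenset[str]]:
    """True-path rule: extend each transcript's terms with all ancestors.

    Terms absent from the ontology are kept as-is (flat annotation).
    """
    out = {}
    for tid, terms in annotation_map.items():
        full: set[str] = set()
        for term in terms:
            if term in ontology:
                full |= ontology.ancestors(term)
            else:
                full.add(term)
        out[tid] = frozenset(full)
    return out


def project_to_level(
    annotation_map: Mapping[str, Collection[str]], ontology: OntologyGraph, level: int
) -> dict[str, frozenset[str]]:
    """Replace each annotation by its ancestor set at the requested level.

    Terms above the requested level map to nothing; duplicates collapse per
    transcript; terms missing from the ontology are skipped with a warning.
    """
    if level < 1:
        raise ContractViolation("level must be >= 1")
    out = {}
    missing: set[str] = set()
    for tid, terms in annotation_map.items():
        projected: set[str] = set()
        for term in terms:
            if term not in ontology:
                missing.add(term)
                continue
            projected |= ontology.project(term, level)
        out[tid] = frozenset(projected)
    for term in sorted(missing):
        logger.warning("term %s absent from ontology; skipped", term)
    return out


def fisher_enrichment(
    test_set: Collection[str],
    reference_set: Collection[str],
    annotation_map: Mapping[str, Collection[str]],
    filter_value: float = 0.01,
    ontology: OntologyGraph | None = None,
) -> pd.DataFrame:
    """Upper-tail Fisher's exact over-representation test per GO term.

    The test set must be contained in the reference set; the reference
    margin of the 2x2 table excludes test members. When an ontology is
    given, annotations are first propagated by the true-path rule. One
    record per term annotating at least one test member; BH FDR across the
    tested terms; ``enriched`` iff fdr < filter_value.
    """
    test = set(test_set)
    reference = set(reference_set)
    if not test:
        raise ContractViolation("test set must be non-empty")
    if not annotation_map:
        raise ContractViolation("annotation map must be non-empty")
    if not test <= reference:
        raise ContractViolation("test set must be a subset of the reference set")
    if ontology is not None:
        annotation_map = propagate_annotations(annotation_map, ontology)
    ref_only = reference - test
    term_test: dict[str, int] = {}
    term_ref: dict[str, int] = {}
    for tid in test:
        for term in annotation_map.get(tid, ()):
            term_test[term] = term_test.get(term, 0) + 1
    for tid in ref_only:
        for term in annotation_map.get(tid, ()):
            term_ref[term] = term_ref.get(term, 0) + 1
    n_test, n_ref = len(test), len(ref_only)
    records = []
    for term in sorted(term_test):
        a = term_test[term]
        c = term_ref.get(term, 0)
        records.append((term, a, n_test - a, c, n_ref - c))
    if not records:
        return pd.DataFrame(
            columns=["term_id", "test_in", "test_out", "ref_in", "ref_out",
                     "p_value", "fdr", "enriched"]
        )
    df = pd.DataFrame(records, columns=["term_id", "test_in", "test_out", "ref_in", "ref_out"])
    # upper hypergeometric tail: P(X >= test_in) drawing n_test from the
    # pooled margin -- identical to one-tailed Fisher (greater)
    N = n_test + n_ref
    K = df["test_in"] + df["ref_in"]
    df["p_value"] = stats.hypergeom.sf(df["test_in"] - 1, N, K, n_test)
    df["fdr"] = adjust_fdr(df["p_value"])
    df["enriched"] = df["fdr"] < filter_value
    return df.sort_values(["p_value", "term_id"], ignore_index=True)


def crosstab_bins(
    term_members: Mapping[str, Collection[str]],
    fold_bins: pd.DataFrame,
    fdrs: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Per enriched term, the count of member fold-change entries per bin.

    ``term_members`` maps term -> member transcript ids; ``fold_bins`` has
    one row per (transcript, parental comparison) with columns
    transcript_id and bin (one of Up1/Up2/Down1/Down2, or None for a zero
    ratio, which is dropped). Returns a term x bin count table with an FDR
    column and a Total row; with no terms, an empty table with headers.
    """
    cols = list(heterosis_bins())
    out = pd.DataFrame(columns=cols + ["FDR"])
    out.index.name = "term"
    if not term_members:
        return out
    binned = fold_bins.dropna(subset=["bin"])
    by_tid = binned.groupby("transcript_id")["bin"]
    bin_counts = {tid: grp.value_counts() for tid, grp in by_tid}
    for term in sorted(term_members):
        counts = dict.fromkeys(cols, 0)
        for tid in term_members[term]:
            for b, n in bin_counts.get(tid, pd.Series(dtype=int)).items():
                counts[b] += int(n)
        row = [counts[c] for c in cols]
        row.append(fdrs.get(term, np.nan) if fdrs else np.nan)
        out.loc[term] = row
    total = out[cols].sum(axis=0)
    out.loc["Total"] = list(total) + [np.nan]
    out[cols] = out[cols].astype(int)
    return out


def heterosis_bins() -> tuple[str, ...]:
    from .heterosis import FOLD_BINS

    return FOLD_BINS
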