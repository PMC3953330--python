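"""Merge transcripts into loci and compare locus sets.

A locus is the maximal set of same-strand transcripts connected by at least
one base of exonic overlap — the connected components of the graph whose
edges join same-strand transcripts whose exons intersect. Overlap is tested
on half-open intervals, so abutting exons (end == start) do not merge.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd
from intervaltree import IntervalTree

from .feature_io import ExpressionMatrix, TranscriptModel

__all__ = [
    "Locus",
    "LocusOverlapReport",
    "build_loci",
    "match_loci",
    "library_overlap_stats",
    "locus_expression",
    "per_tissue_locus_counts",
]


@dataclass(frozen=True)
class Locus:
    """A maximal set of same-strand, exon-overlapping transcripts."""

    locus_id: str
    chrom: str
    strand: str
    transcripts: tuple
    footprint: tuple  # merged exonic (start, end) intervals, sorted, disjoint
    span: tuple  # (min start, max end)
    library_evidence: frozenset

    @property
    def transcript_ids(self) -> tuple:
        return tuple(t.transcript_id for t in self.transcripts)

    @property
    def max_exons(self) -> int:
        return max(t.n_exons for t in self.transcripts)

    @property
    def five_prime(self) -> int:
        return self.span[0] if self.strand == "+" else self.span[1] - 1


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def _merge_intervals(intervals: Iterable[Tuple[int, int]]) -> tuple:
    merged: List[List[int]] = []
    for s, e in sorted(intervals):
        if merged and s < merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return tuple((s, e) for s, e in merged)


def build_loci(
    transcripts: Iterable[TranscriptModel], id_prefix: str = "LOC"
) -> List[Locus]:
    """Partition transcripts into loci by same-strand exonic overlap.

    Uses a sweep over exon start positions with union-find: within one
    (chrom, strand) group, an exon whose start falls before the running
    maximum end of the current cluster connects its transcript to that
    cluster. This yields exactly the connected components of the pairwise
    exon-overlap graph.
    """
    txs = list(transcripts)
    uf = _UnionFind(len(txs))
    groups: Dict[tuple, List[Tuple[int, int, int]]] = {}
    for idx, tx in enumerate(txs):
        for e in tx.exons:
            groups.setdefault((tx.chrom, tx.strand), []).append(
                (e.start, e.end, idx)
            )
    for exons in groups.values():
        exons.sort()
        cluster_rep = -1
        cluster_end = -1
        for start, end, idx in exons:
            if start < cluster_end:
                uf.union(cluster_rep, idx)
                cluster_end = max(cluster_end, end)
            else:
                cluster_rep = idx
                cluster_end = end
    components: Dict[int, List[int]] = {}
    for idx in range(len(txs)):
        components.setdefault(uf.find(idx), []).append(idx)
    loci = []
    for members in components.values():
        mtx = tuple(sorted((txs[i] for i in members), key=lambda t: (t.start, t.transcript_id)))
        footprint = _merge_intervals(
            (e.start, e.end) for t in mtx for e in t.exons
        )
        evidence = frozenset().union(*(t.library_evidence for t in mtx))
        loci.append(
            Locus(
                locus_id="",
                chrom=mtx[0].chrom,
                strand=mtx[0].strand,
                transcripts=mtx,
                footprint=footprint,
                span=(min(t.start for t in mtx), max(t.end for t in mtx)),
                library_evidence=evidence,
            )
        )
    loci.sort(key=lambda l: (l.chrom, l.span[0], l.span[1], l.strand))
    return [
        Locus(
            locus_id=f"{id_prefix}{i + 1:06d}",
            chrom=l.chrom,
            strand=l.strand,
            transcripts=l.transcripts,
            footprint=l.footprint,
            span=l.span,
            library_evidence=l.library_evidence,
        )
        for i, l in enumerate(loci)
    ]


@dataclass(frozen=True)
class LocusOverlapReport:
    """Per-direction overlap accounting between two locus sets."""

    a_shared: int
    a_only: int
    b_shared: int
    b_only: int

    @property
    def a_total(self) -> int:
        return self.a_shared + self.a_only

    @property
    def b_total(self) -> int:
        return self.b_shared + self.b_only

    def fractions(self) -> dict:
        out = {}
        out["a_shared"] = self.a_shared / self.a_total if self.a_total else 0.0
        out["a_only"] = self.a_only / self.a_total if self.a_total else 0.0
        out["b_shared"] = self.b_shared / self.b_total if self.b_total else 0.0
        out["b_only"] = self.b_only / self.b_total if self.b_total else 0.0
        return out


def _footprint_trees(loci: Sequence[Locus]) -> Dict[tuple, IntervalTree]:
    trees: Dict[tuple, IntervalTree] = {}
    for locus in loci:
        tree = trees.setdefault((locus.chrom, locus.strand), IntervalTree())
        for s, e in locus.footprint:
            tree.addi(s, e)
    return trees


def match_loci(set_a: Sequence[Locus], set_b: Sequence[Locus]) -> LocusOverlapReport:
    """Count loci shared between two sets by same-strand exonic overlap.

    A locus in one set is *shared* iff some locus in the other set overlaps
    its merged exonic footprint by >=1 bp on the same strand; the counts
    are reported per direction (they need not be symmetric).
    """
    trees_b = _footprint_trees(set_b)
    trees_a = _footprint_trees(set_a)

    def shared_count(loci: Sequence[Locus], trees: Dict[tuple, IntervalTree]) -> int:
        n = 0
        for locus in loci:
            tree = trees.get((locus.chrom, locus.strand))
            if tree is not None and any(
                tree.overlap(s, e) for s, e in locus.footprint
            ):
                n += 1
        return n

    a_shared = shared_count(set_a, trees_b)
    b_shared = shared_count(set_b, trees_a)
    return LocusOverlapReport(
        a_shared=a_shared,
        a_only=len(set_a) - a_shared,
        b_shared=b_shared,
        b_only=len(set_b) - b_shared,
    )


def library_overlap_stats(
    loci: Sequence[Locus],
    expr: ExpressionMatrix,
    threshold: float = 0.1,
) -> dict:
    """Fraction of loci detected by both, one, or neither library method.

    A locus counts as detected under a method iff its maximum FPKM over
    that method's samples is strictly greater than *threshold*. Expression
    rows are keyed by locus id. Fractions sum to 1 over the input loci.
    """
    cols = {m: expr.columns_for(method=m) for m in ("polyA", "DSN")}
    counts = {"both": 0, "polyA_only": 0, "DSN_only": 0, "neither": 0}
    for locus in loci:
        for method, c in cols.items():
            if not c:
                raise ValueError(
                    f"locus {locus.locus_id}: no samples of method {method}"
                )
        row = expr.row(locus.locus_id)
        in_polya = row[cols["polyA"]].max() > threshold
        in_dsn = row[cols["DSN"]].max() > threshold
        if in_polya and in_dsn:
            counts["both"] += 1
        elif in_polya:
            counts["polyA_only"] += 1
        elif in_dsn:
            counts["DSN_only"] += 1
        else:
            counts["neither"] += 1
    total = len(loci)
    return {k: (v / total if total else 0.0) for k, v in counts.items()}


def locus_expression(
    loci: Sequence[Locus], expr: ExpressionMatrix
) -> ExpressionMatrix:
    """Lift a transcript-level matrix to locus level (max over members).

    Member transcripts absent from the matrix contribute zero.
    """
    rows = {}
    for locus in loci:
        present = [t for t in locus.transcript_ids if t in expr.values.index]
        if present:
            rows[locus.locus_id] = expr.values.loc[present].max(axis=0)
        else:
            rows[locus.locus_id] = pd.Series(0.0, index=expr.values.columns)
    df = pd.DataFrame(rows).T
    df.index.name = "feature_id"
    return ExpressionMatrix(df, expr.samples)


def per_tissue_locus_counts(
    transcripts: Sequence[TranscriptModel],
    expr: ExpressionMatrix,
    threshold: float = 0.1,
    merge_first: bool = True,
) -> pd.DataFrame:
    """Detected-locus counts per tissue and library method.

    With ``merge_first=True`` loci are built once from all transcripts and
    counted as detected per (tissue, method) when their expression exceeds
    *threshold* there; with ``merge_first=False`` loci are re-built per
    tissue from that tissue's detected transcripts before counting. The two
    orders can differ when cross-tissue transcripts bridge loci.
    """
    methods = sorted({s.method for s in expr.samples})
    tissues = expr.tissues
    if merge_first:
        loci = build_loci(transcripts)
        lexpr = locus_expression(loci, expr)
        out = {}
        for m in methods:
            row = []
            for t in tissues:
                cols = lexpr.columns_for(method=m, tissue=t)
                if not cols:
                    row.append(0)
                    continue
                row.append(int((lexpr.values[cols].max(axis=1) > threshold).sum()))
            out[m] = row
        return pd.DataFrame(out, index=tissues).T
    out = {}
    for m in methods:
        row = []
        for t in tissues:
            cols = expr.columns_for(method=m, tissue=t)
            if not cols:
                row.append(0)
                continue
            detected = set(
                expr.values.index[(expr.values[cols].max(axis=1) > threshold)]
            )
            txs = [x for x in transcripts if x.transcript_id in detected]
            row.append(len(build_loci(txs)))
        out[m] = row
    return pd.DataFrame(out, index=tissues).T
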