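"""Category assignment for RNA-seq loci.

Every locus receives exactly one label from a fixed decision cascade
(first match wins):

1. same-strand exonic overlap with a coding reference/ortholog gene, or a
   positive coding-potential verdict -> ``protein_coding_hiconf``
2. opposite-strand overlap with >=1 exon of a coding gene ->
   ``antisense_exonic``
3. fully inside an intron of a coding gene -> ``intronic_sense`` /
   ``intronic_antisense`` by strand
4. intergenic, multi-exon, no coding verdict -> ``lincRNA``
5. intergenic single-exon starting within the run-off window (default
   25 kb) downstream of the nearest same-strand gene's 3' end ->
   ``intergenic_runoff_3prime``
6. intergenic single-exon on the reverse strand starting within the
   divergent window (default 5 kb) upstream of the nearest gene's
   transcription start -> ``intergenic_divergent_promoter``
7. remaining intergenic -> ``intergenic_distal``
8. anything else -> ``other_unclassified``

Distances are measured from the locus's 5'-most base to the gene anchor
(3' end for run-off, TSS for divergent) and the windows are inclusive.
The cascade order is a fixed design choice: the categories themselves do
not define a precedence for loci matching several rules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from intervaltree import IntervalTree

from .coding_potential import CodingEvidence
from .feature_io import ExpressionMatrix, GenomicInterval, TranscriptModel, ValidationError
from .locus_builder import Locus, build_loci

__all__ = [
    "CATEGORIES",
    "CategoryLabel",
    "ClassifierConfig",
    "ReferenceIndex",
    "ClassifiedLocus",
    "classify_locus",
    "classify_catalog",
    "mark_unexpressed_reference",
    "compact_catalog",
    "snap_splice_boundaries",
]

log = logging.getLogger(__name__)

CATEGORIES = (
    "protein_coding_hiconf",
    "protein_coding_unexpressed",
    "antisense_exonic",
    "lincRNA",
    "intronic_sense",
    "intronic_antisense",
    "intergenic_runoff_3prime",
    "intergenic_divergent_promoter",
    "intergenic_distal",
    "other_unclassified",
)


class ClassificationError(ValueError):
    pass


@dataclass(frozen=True)
class CategoryLabel:
    category: str
    fired_rule: str
    host_gene_id: Optional[str] = None
    distance: Optional[int] = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValidationError(f"unknown category {self.category!r}")


@dataclass(frozen=True)
class ClassifierConfig:
    """Thresholds and distance windows used throughout the catalogue."""

    runoff_window: int = 25_000
    divergent_window: int = 5_000
    detection_fpkm: float = 0.1
    orf_min_aa: int = 50
    bitscore_min: float = 60.0
    multiexon_min_exons: int = 2
    snap_max_shift: int = 5

    def __post_init__(self) -> None:
        for name in (
            "runoff_window",
            "divergent_window",
            "detection_fpkm",
            "orf_min_aa",
            "bitscore_min",
            "multiexon_min_exons",
            "snap_max_shift",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")


@dataclass(frozen=True)
class _Gene:
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple  # merged (start, end)
    introns: tuple  # (start, end) gaps between merged exons

    @property
    def tss(self) -> int:
        """Genomic position of the first transcribed base."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        """Genomic position of the last transcribed base (3' end)."""
        return self.end - 1 if self.strand == "+" else self.start


class ReferenceIndex:
    """Strand-aware interval index over reference coding genes.

    Built from reference transcript models; transcripts whose source is
    ``reference_coding`` or ``ortholog_coding`` define the coding gene set
    used by the classification cascade.
    """

    def __init__(self, reference: Iterable[TranscriptModel]):
        by_gene: Dict[str, List[TranscriptModel]] = {}
        for tx in reference:
            if tx.source not in ("reference_coding", "ortholog_coding"):
                continue
            gid = tx.gene_id or tx.transcript_id
            by_gene.setdefault(gid, []).append(tx)
        self.genes: Dict[str, _Gene] = {}
        self._exon_trees: Dict[str, IntervalTree] = {}
        self._span_trees: Dict[str, IntervalTree] = {}
        self._genes_by_chrom: Dict[str, List[_Gene]] = {}
        for gid, txs in sorted(by_gene.items()):
            chroms = {t.chrom for t in txs}
            strands = {t.strand for t in txs}
            if len(chroms) > 1 or len(strands) > 1:
                raise ValidationError(
                    f"gene {gid}: transcripts on multiple chromosomes/strands"
                )
            exons = _merge(
                (e.start, e.end) for t in txs for e in t.exons
            )
            introns = tuple(
                (a[1], b[0]) for a, b in zip(exons, exons[1:])
            )
            gene = _Gene(
                gene_id=gid,
                chrom=txs[0].chrom,
                strand=txs[0].strand,
                start=exons[0][0],
                end=exons[-1][1],
                exons=exons,
                introns=introns,
            )
            self.genes[gid] = gene
            et = self._exon_trees.setdefault(gene.chrom, IntervalTree())
            for s, e in exons:
                et.addi(s, e, gene)
            self._span_trees.setdefault(gene.chrom, IntervalTree()).addi(
                gene.start, gene.end, gene
            )
            self._genes_by_chrom.setdefault(gene.chrom, []).append(gene)

    def exon_overlaps(self, chrom: str, intervals: Sequence[tuple]) -> List[_Gene]:
        tree = self._exon_trees.get(chrom)
        if tree is None:
            return []
        hits = {}
        for s, e in intervals:
            for iv in tree.overlap(s, e):
                hits[iv.data.gene_id] = iv.data
        return [hits[k] for k in sorted(hits)]

    def span_overlaps(self, chrom: str, start: int, end: int) -> List[_Gene]:
        tree = self._span_trees.get(chrom)
        if tree is None:
            return []
        hits = {iv.data.gene_id: iv.data for iv in tree.overlap(start, end)}
        return [hits[k] for k in sorted(hits)]

    def genes_on(self, chrom: str) -> List[_Gene]:
        return self._genes_by_chrom.get(chrom, [])


def _merge(intervals: Iterable[tuple]) -> tuple:
    merged: List[List[int]] = []
    for s, e in sorted(intervals):
        if merged and s < merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return tuple((s, e) for s, e in merged)


def _nearest_runoff(
    locus: Locus, genes: Sequence[_Gene], window: int
) -> Optional[Tuple[_Gene, int]]:
    """Nearest same-strand gene with the locus 5' base within *window*
    downstream of the gene's 3' end; (gene, distance) or None."""
    p = locus.five_prime
    best: Optional[Tuple[int, str, _Gene]] = None
    for g in genes:
        if g.strand != locus.strand:
            continue
        if g.strand == "+":
            d = p - g.tes
        else:
            d = g.tes - p
        if 1 <= d <= window:
            key = (d, g.gene_id)
            if best is None or key < (best[0], best[1]):
                best = (d, g.gene_id, g)
    if best is None:
        return None
    return best[2], best[0]


def _nearest_divergent(
    locus: Locus, genes: Sequence[_Gene], window: int
) -> Optional[Tuple[_Gene, int]]:
    """Nearest opposite-strand gene with the locus 5' base within *window*
    upstream of the gene's TSS; (gene, distance) or None."""
    p = locus.five_prime
    best: Optional[Tuple[int, str, _Gene]] = None
    for g in genes:
        if g.strand == locus.strand:
            continue
        if g.strand == "+":
            d = g.tss - p
        else:
            d = p - g.tss
        if 1 <= d <= window:
            key = (d, g.gene_id)
            if best is None or key < (best[0], best[1]):
                best = (d, g.gene_id, g)
    if best is None:
        return None
    return best[2], best[0]


def classify_locus(
    locus: Locus,
    reference: ReferenceIndex,
    evidence: Mapping[str, CodingEvidence],
    cfg: ClassifierConfig = ClassifierConfig(),
) -> CategoryLabel:
    """Assign one category to *locus* via the decision cascade."""
    for tid in locus.transcript_ids:
        if tid not in evidence:
            raise ClassificationError(
                f"locus {locus.locus_id}: missing coding evidence for {tid}"
            )
    verdict_any = any(evidence[t].verdict for t in locus.transcript_ids)

    exon_hits = reference.exon_overlaps(locus.chrom, locus.footprint)
    same = [g for g in exon_hits if g.strand == locus.strand]
    opposite = [g for g in exon_hits if g.strand != locus.strand]

    # (1) coding
    if same:
        return CategoryLabel(
            "protein_coding_hiconf",
            fired_rule="same-strand exonic overlap with coding gene",
            host_gene_id=same[0].gene_id,
        )
    if verdict_any:
        return CategoryLabel(
            "protein_coding_hiconf",
            fired_rule="coding-potential verdict (ORF/domain/homology)",
        )
    # (2) antisense
    if opposite:
        return CategoryLabel(
            "antisense_exonic",
            fired_rule="opposite-strand overlap with coding exon",
            host_gene_id=opposite[0].gene_id,
        )
    # (3) intronic
    span_s, span_e = locus.span
    containing = reference.span_overlaps(locus.chrom, span_s, span_e)
    for g in containing:
        for i_s, i_e in g.introns:
            if i_s <= span_s and span_e <= i_e:
                if locus.strand == g.strand:
                    return CategoryLabel(
                        "intronic_sense",
                        fired_rule="contained in intron, same strand as host",
                        host_gene_id=g.gene_id,
                    )
                return CategoryLabel(
                    "intronic_antisense",
                    fired_rule="contained in intron, opposite strand to host",
                    host_gene_id=g.gene_id,
                )
    if containing:
        # overlaps a gene span without exon overlap or intron containment
        return CategoryLabel(
            "other_unclassified",
            fired_rule="straddles gene structure without exonic overlap",
            host_gene_id=containing[0].gene_id,
        )
    # intergenic from here on
    if locus.max_exons >= cfg.multiexon_min_exons:
        return CategoryLabel(
            "lincRNA",
            fired_rule="intergenic multi-exon without coding potential",
        )
    genes = reference.genes_on(locus.chrom)
    hit = _nearest_runoff(locus, genes, cfg.runoff_window)
    if hit is not None:
        g, d = hit
        return CategoryLabel(
            "intergenic_runoff_3prime",
            fired_rule=f"starts {d} bp downstream of 3' end (<= {cfg.runoff_window})",
            host_gene_id=g.gene_id,
            distance=d,
        )
    hit = _nearest_divergent(locus, genes, cfg.divergent_window)
    if hit is not None:
        g, d = hit
        return CategoryLabel(
            "intergenic_divergent_promoter",
            fired_rule=f"starts {d} bp upstream of TSS (<= {cfg.divergent_window})",
            host_gene_id=g.gene_id,
            distance=d,
        )
    return CategoryLabel(
        "intergenic_distal",
        fired_rule="intergenic, beyond proximity windows",
    )


@dataclass(frozen=True)
class ClassifiedLocus:
    locus: Locus
    label: CategoryLabel

    @property
    def category(self) -> str:
        return self.label.category


def classify_catalog(
    loci: Sequence[Locus],
    reference: ReferenceIndex,
    evidence: Mapping[str, CodingEvidence],
    cfg: ClassifierConfig = ClassifierConfig(),
) -> List[ClassifiedLocus]:
    return [
        ClassifiedLocus(locus, classify_locus(locus, reference, evidence, cfg))
        for locus in loci
    ]


def mark_unexpressed_reference(
    reference_loci: Sequence[Locus],
    expr: ExpressionMatrix,
    cfg: ClassifierConfig = ClassifierConfig(),
) -> set:
    """Ids of reference coding loci with no measurable expression.

    A locus is flagged when its maximum FPKM over all samples is <= the
    detection threshold; flagged loci are relabelled
    ``protein_coding_unexpressed`` but retained in the coding list.
    """
    flagged = set()
    for locus in reference_loci:
        row = expr.row(locus.locus_id)
        if row.max() <= cfg.detection_fpkm:
            flagged.add(locus.locus_id)
    return flagged


def compact_catalog(
    catalog: Sequence[ClassifiedLocus],
) -> Tuple[List[ClassifiedLocus], int]:
    """Drop intronic sense loci (likely immature-splicing by-products).

    Returns the compacted catalogue and the number of loci removed.
    """
    kept = [c for c in catalog if c.category != "intronic_sense"]
    return kept, len(catalog) - len(kept)


def _shift_candidates(max_shift: int):
    yield 0
    for k in range(1, max_shift + 1):
        yield k
        yield -k


def snap_splice_boundaries(
    transcript: TranscriptModel,
    genome,
    max_shift: int = 5,
) -> TranscriptModel:
    """Snap internal exon boundaries to canonical GT..AG splice sites.

    Each intron boundary is shifted independently by at most *max_shift*
    nucleotides to the nearest position where the intron begins GT at the
    donor and ends AG at the acceptor (strand-aware; on the minus strand
    the genomic motifs are CT at the low end and AC at the high end). Ties
    between equal shifts resolve to the downstream (positive genomic)
    shift. A boundary is left unchanged when no canonical site lies within
    the window or when shifting would create a zero-length exon.
    """
    if transcript.n_exons < 2:
        raise ValidationError(
            f"transcript {transcript.transcript_id}: splice snapping needs >=2 exons"
        )
    from .coding_potential import _fetch  # shared genome accessor

    chrom = transcript.chrom
    plus = transcript.strand == "+"
    bounds = [[e.start, e.end] for e in transcript.exons]

    def motif_at(pos: int, motif: str) -> bool:
        if pos < 0:
            return False
        return _fetch(genome, chrom, pos, pos + 2) == motif

    for i in range(len(bounds) - 1):
        intron_start = bounds[i][1]
        intron_end = bounds[i + 1][0]
        # donor side (low coordinate on +; motif GT / genomic CT on -)
        low_motif = "GT" if plus else "CT"
        high_motif = "AG" if plus else "AC"
        for delta in _shift_candidates(max_shift):
            if motif_at(intron_start + delta, low_motif):
                new_end = intron_start + delta
                if bounds[i][0] < new_end and new_end < intron_end:
                    bounds[i][1] = new_end
                elif delta != 0:
                    log.warning(
                        "transcript %s: donor shift %+d would collapse an exon; "
                        "boundary left unchanged",
                        transcript.transcript_id,
                        delta,
                    )
                break
        intron_start = bounds[i][1]
        # acceptor side (high coordinate): motif ends at intron_end
        for delta in _shift_candidates(max_shift):
            if motif_at(intron_end + delta - 2, high_motif):
                new_start = intron_end + delta
                if new_start < bounds[i + 1][1] and new_start > intron_start:
                    bounds[i + 1][0] = new_start
                elif delta != 0:
                    log.warning(
                        "transcript %s: acceptor shift %+d would collapse an exon; "
                        "boundary left unchanged",
                        transcript.transcript_id,
                        delta,
                    )
                break
    exons = tuple(
        GenomicInterval(chrom, s, e, transcript.strand) for s, e in bounds
    )
    return TranscriptModel(
        transcript_id=transcript.transcript_id,
        exons=exons,
        gene_id=transcript.gene_id,
        source=transcript.source,
        library_evidence=transcript.library_evidence,
    )
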