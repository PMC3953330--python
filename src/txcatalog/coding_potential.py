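"""Coding-potential screening for transcript models.

A transcript is judged to have recognisable coding potential by three
complementary screens, any one of which suffices:

1. an open reading frame of at least ``orf_min_aa`` amino acids (default
   50) on the sense strand of the spliced sequence;
2. a protein-domain hit (e.g. a Pfam match from an ORF-prediction run),
   consumed as a pre-computed table;
3. a protein-homology hit (e.g. blastx against vertebrate proteins) with
   bitscore strictly greater than ``bitscore_min`` (default 60).

Running the domain/homology searches themselves is out of scope — their
outputs are consumed as plain TSV tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Mapping, Optional, Sequence, Union

import pandas as pd
from Bio.Seq import reverse_complement

from .feature_io import TranscriptModel, ValidationError

__all__ = [
    "CodingEvidence",
    "spliced_sequence",
    "longest_orf",
    "coding_verdict",
    "read_homology_table",
    "read_domain_table",
]

log = logging.getLogger(__name__)

_STOPS = frozenset({"TAA", "TAG", "TGA"})


def _contig_length(genome, chrom: str) -> int:
    seq = genome[chrom]
    return len(seq)


def _fetch(genome, chrom: str, start: int, end: int) -> str:
    """Fetch genome[start:end); accepts pyfaidx.Fasta or a dict of strings."""
    seq = genome[chrom][start:end]
    return str(seq).upper()


def spliced_sequence(transcript: TranscriptModel, genome) -> str:
    """Spliced (exon-concatenated) sequence, 5' to 3'.

    Minus-strand transcripts are reverse-complemented. *genome* may be a
    ``pyfaidx.Fasta`` or any mapping of chromosome name to sequence string.
    """
    n = _contig_length(genome, transcript.chrom)
    for e in transcript.exons:
        if e.end > n:
            raise ValidationError(
                f"transcript {transcript.transcript_id}: exon [{e.start}, {e.end}) "
                f"beyond end of {transcript.chrom} (length {n})"
            )
    seq = "".join(
        _fetch(genome, transcript.chrom, e.start, e.end) for e in transcript.exons
    )
    if transcript.strand == "-":
        seq = reverse_complement(seq)
    return seq


def longest_orf(seq: str) -> int:
    """Length in amino acids (excluding the stop) of the longest sense ORF.

    An ORF is an ATG followed by an in-frame stop codon within the
    sequence, scanned over the three sense-strand frames only; ORFs running
    off the 3' end are not counted. Codons containing N match neither ATG
    nor a stop.
    """
    seq = seq.upper()
    best = 0
    for frame in range(3):
        start: Optional[int] = None
        n_codons = (len(seq) - frame) // 3
        for ci in range(n_codons):
            codon = seq[frame + 3 * ci : frame + 3 * ci + 3]
            if start is None:
                if codon == "ATG":
                    start = ci
            elif codon in _STOPS:
                best = max(best, ci - start)
                start = None
    return best


@dataclass(frozen=True)
class CodingEvidence:
    """Three-way coding-potential verdict for one transcript."""

    transcript_id: str
    longest_orf_aa: int
    has_domain_hit: bool
    best_homology_bitscore: Optional[float]
    verdict: bool


def coding_verdict(
    transcript: TranscriptModel,
    genome,
    domain_hits: Optional[Mapping[str, Sequence[str]]] = None,
    homology_hits: Optional[Mapping[str, float]] = None,
    orf_min_aa: int = 50,
    bitscore_min: float = 60.0,
) -> CodingEvidence:
    """Evaluate the three coding screens for one transcript.

    ``domain_hits`` maps transcript id -> domain ids; ``homology_hits``
    maps transcript id -> best bitscore. The bitscore comparison is strict
    (a hit at exactly ``bitscore_min`` does not count). Absent tables mean
    "no hits" and are logged once per call site.
    """
    if domain_hits is None:
        log.warning("no domain-hit table supplied; treating as no hits")
        domain_hits = {}
    if homology_hits is None:
        log.warning("no homology-hit table supplied; treating as no hits")
        homology_hits = {}
    tid = transcript.transcript_id
    orf_aa = longest_orf(spliced_sequence(transcript, genome))
    has_domain = bool(domain_hits.get(tid))
    bitscore = homology_hits.get(tid)
    if bitscore is not None and bitscore < 0:
        raise ValidationError(f"transcript {tid}: negative bitscore {bitscore}")
    verdict = (
        orf_aa >= orf_min_aa
        or has_domain
        or (bitscore is not None and bitscore > bitscore_min)
    )
    return CodingEvidence(
        transcript_id=tid,
        longest_orf_aa=orf_aa,
        has_domain_hit=has_domain,
        best_homology_bitscore=bitscore,
        verdict=verdict,
    )


def read_homology_table(path: Union[str, Path]) -> Dict[str, float]:
    """Read a (transcript_id, bitscore) TSV; keeps the best score per id."""
    df = pd.read_csv(path, sep="\t", header=0)
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: expected >=2 columns (id, bitscore)")
    out: Dict[str, float] = {}
    for tid, score in zip(df.iloc[:, 0], df.iloc[:, 1].astype(float)):
        if score < 0:
            raise ValidationError(f"{path}: negative bitscore for {tid}")
        if tid not in out or score > out[tid]:
            out[tid] = score
    return out


def read_domain_table(path: Union[str, Path]) -> Dict[str, list]:
    """Read a (transcript_id, domain_id) TSV into id -> domain list."""
    df = pd.read_csv(path, sep="\t", header=0)
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: expected >=2 columns (id, domain)")
    out: Dict[str, list] = {}
    for tid, dom in zip(df.iloc[:, 0], df.iloc[:, 1]):
        out.setdefault(tid, []).append(dom)
    return out
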