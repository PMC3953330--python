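"""Synthetic genomes, annotations, transcripts and expression matrices.

Every generator is a pure function of (config, seed) and records a truth
table, so each pipeline stage can be tested against known ground truth
without any external download.

The generator plants one cassette per requested locus: a multi-exon coding
gene with a real ORF where the category needs a host or neighbour gene,
plus the category's transcript placed to satisfy its geometric definition
with a comfortable margin (run-off transcripts start strictly inside the
25 kb window, distal ones with >=200 kb gene-free flanks, and so on).

Planted regions are written A-free outside ORF start/stop codons. This is
a deliberate trick: an open reading frame needs an ATG (and hence an A),
and an ATG on the reverse strand needs a CAT on the forward strand, so an
A-free stretch provably contains no ORF on either strand. Planted
non-coding transcripts therefore always screen negative for coding
potential, and antisense partners of coding exons can never gain a
spurious ORF, whatever the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .feature_io import (
    ExpressionMatrix,
    GenomicInterval,
    SampleMeta,
    TranscriptModel,
    write_expression,
    write_gtf,
    write_samples,
)

__all__ = [
    "GenerationError",
    "SyntheticConfig",
    "PlantedUnit",
    "SyntheticTruth",
    "SyntheticCatalog",
    "generate_genome",
    "write_genome_fasta",
    "generate_catalog",
    "generate_expression",
    "generate_tree_expression",
    "default_samples",
]


class GenerationError(RuntimeError):
    pass


TISSUES = (
    "blood",
    "brain",
    "heart",
    "kidney",
    "liver",
    "lung",
    "muscle",
    "ovary",
    "skin",
    "testis",
)

#: Planted categories the generator can emit directly.
PLANTABLE = (
    "protein_coding_hiconf",
    "antisense_exonic",
    "lincRNA",
    "intronic_sense",
    "intronic_antisense",
    "intergenic_runoff_3prime",
    "intergenic_divergent_promoter",
    "intergenic_distal",
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions emulated by the generator.

    Category median FPKM and the both/one/neither detection-pattern mix
    follow the catalogue's reported structure (protein coding expressed
    well above lincRNAs, lincRNAs above antisense; 57% of loci reported by
    both library methods); tissue-specificity probabilities give lincRNAs
    a 37% single-tissue share and antisense loci 21.4%.
    """

    category_counts: Mapping[str, int] = field(
        default_factory=lambda: {c: 5 for c in PLANTABLE}
    )
    n_silent_reference: int = 0
    tissues: Tuple[str, ...] = TISSUES
    methods: Tuple[str, ...] = ("polyA", "DSN")
    runoff_window: int = 25_000
    divergent_window: int = 5_000
    orf_aa: int = 120
    gene_exon_len: int = 400
    gene_intron_len: int = 1_500
    host_intron_len: int = 4_000
    cassette_gap: int = 40_000
    distal_flank: int = 200_000
    distal_spacing: int = 2_000
    median_fpkm: Mapping[str, float] = field(
        default_factory=lambda: {
            "protein_coding_hiconf": 20.0,
            "protein_coding_unexpressed": 0.0,
            "lincRNA": 2.0,
            "antisense_exonic": 1.0,
            "intronic_sense": 1.5,
            "intronic_antisense": 1.0,
            "intergenic_runoff_3prime": 2.4,
            "intergenic_divergent_promoter": 2.3,
            "intergenic_distal": 1.5,
        }
    )
    single_tissue_prob: Mapping[str, float] = field(
        default_factory=lambda: {
            "protein_coding_hiconf": 0.05,
            "lincRNA": 0.37,
            "antisense_exonic": 0.214,
            "intronic_sense": 0.3,
            "intronic_antisense": 0.3,
            "intergenic_runoff_3prime": 0.3,
            "intergenic_divergent_promoter": 0.3,
            "intergenic_distal": 0.3,
        }
    )
    detection_pattern_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "both": 0.57,
            "polyA_only": 0.20,
            "DSN_only": 0.20,
            "neither": 0.03,
        }
    )
    sigma_locus: float = 0.6
    sigma_tissue: float = 0.5
    sigma_method: float = 0.2
    min_detected_fpkm: float = 0.2


@dataclass(frozen=True)
class PlantedUnit:
    """Ground truth for one planted locus."""

    unit_id: str
    category: str
    transcript_ids: Tuple[str, ...]
    gene_id: Optional[str]
    tau_regime: str  # single_tissue | broad
    detection_pattern: str  # both | polyA_only | DSN_only | neither
    peak_tissue: Optional[str] = None


@dataclass(frozen=True)
class SyntheticTruth:
    units: Tuple[PlantedUnit, ...]
    seed: int
    config: SyntheticConfig

    def label_by_transcript(self) -> Dict[str, str]:
        out: Dict[str, str] = {}
        for u in self.units:
            for tid in u.transcript_ids:
                out[tid] = u.category
        return out

    def unit_by_transcript(self) -> Dict[str, PlantedUnit]:
        out: Dict[str, PlantedUnit] = {}
        for u in self.units:
            for tid in u.transcript_ids:
                out[tid] = u
        return out

    def counts(self) -> Dict[str, int]:
        out: Dict[str, int] = {}
        for u in self.units:
            out[u.category] = out.get(u.category, 0) + 1
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "unit_id": [u.unit_id for u in self.units],
                "category": [u.category for u in self.units],
                "transcripts": [",".join(u.transcript_ids) for u in self.units],
                "gene_id": [u.gene_id or "" for u in self.units],
                "tau_regime": [u.tau_regime for u in self.units],
                "detection_pattern": [u.detection_pattern for u in self.units],
                "peak_tissue": [u.peak_tissue or "" for u in self.units],
            }
        )


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_AFREE = np.frombuffer(b"CGT", dtype=np.uint8)


def generate_genome(
    n_chrom: int = 2,
    length: int = 1_000_000,
    gc: float = 0.41,
    seed: int = 0,
) -> Dict[str, str]:
    """Random genome: *n_chrom* chromosomes of *length* bp at GC fraction *gc*."""
    if length < 10_000:
        raise GenerationError("chromosome length must be >= 10 kb")
    if not (0.0 < gc < 1.0):
        raise GenerationError(f"GC fraction must be in (0, 1), got {gc}")
    rng = np.random.default_rng(seed)
    at = (1.0 - gc) / 2.0
    p = [at, gc / 2.0, gc / 2.0, at]
    genome = {}
    for i in range(n_chrom):
        arr = rng.choice(_BASES, size=length, p=p)
        genome[f"chr{i + 1}"] = arr.tobytes().decode()
    return genome


def write_genome_fasta(genome: Mapping[str, str], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# Catalogue
# ---------------------------------------------------------------------------

_SAFE_CODONS = [
    a + b + c for a in "GCT" for b in "GCT" for c in "GCT"
]  # over {G,C,T}: never a stop, never ATG


@dataclass
class _GeneShape:
    gene_id: str
    chrom: str
    strand: str
    exons: List[Tuple[int, int]]
    start: int
    end: int

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start


@dataclass(frozen=True)
class SyntheticCatalog:
    genome: Dict[str, str]
    reference: Tuple[TranscriptModel, ...]
    transcripts: Tuple[TranscriptModel, ...]
    truth: SyntheticTruth

    def write(self, outdir: Union[str, Path]) -> Dict[str, Path]:
        """Write genome.fa, reference.gtf, transcripts.gtf and truth.tsv."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fa",
            "reference": outdir / "reference.gtf",
            "transcripts": outdir / "transcripts.gtf",
            "truth": outdir / "truth.tsv",
        }
        write_genome_fasta(self.genome, paths["genome"])
        write_gtf(self.reference, paths["reference"])
        write_gtf(self.transcripts, paths["transcripts"])
        self.truth.to_frame().to_csv(paths["truth"], sep="\t", index=False)
        return paths


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


class _Planter:
    """Mutable genome with helpers for planting scrubbed regions and genes."""

    def __init__(self, genome: Mapping[str, str], rng: np.random.Generator):
        self.chroms = {k: bytearray(v, "ascii") for k, v in genome.items()}
        self.rng = rng

    def scrub(self, chrom: str, start: int, end: int) -> None:
        """Overwrite [start, end) with A-free sequence (no ORF either strand)."""
        arr = self.rng.choice(_AFREE, size=end - start)
        self.chroms[chrom][start:end] = arr.tobytes()

    def write(self, chrom: str, start: int, seq: str) -> None:
        self.chroms[chrom][start : start + len(seq)] = seq.encode()

    def orf_sequence(self, spliced_len: int, orf_aa: int) -> str:
        """A spliced sense sequence with exactly one ORF of *orf_aa* aa."""
        utr5 = (
            self.rng.choice(_AFREE, size=29).tobytes().decode() + "G"
        )  # last base G so no CAT forms before the ATG
        codons = "".join(
            self.rng.choice(_SAFE_CODONS) for _ in range(orf_aa - 1)
        )
        body = utr5 + "ATG" + codons + "TAA"
        if len(body) > spliced_len:
            raise GenerationError("spliced length too short for requested ORF")
        pad = self.rng.choice(_AFREE, size=spliced_len - len(body)).tobytes().decode()
        return body + pad

    def plant_gene(
        self,
        gene_id: str,
        chrom: str,
        pos: int,
        strand: str,
        exon_lens: Sequence[int],
        intron_lens: Sequence[int],
        orf_aa: int,
    ) -> _GeneShape:
        """Plant a multi-exon coding gene with canonical splice sites."""
        exons: List[Tuple[int, int]] = []
        cur = pos
        for i, el in enumerate(exon_lens):
            exons.append((cur, cur + el))
            cur += el
            if i < len(intron_lens):
                cur += intron_lens[i]
        spliced = self.orf_sequence(sum(exon_lens), orf_aa)
        genomic = spliced if strand == "+" else _revcomp(spliced)
        # distribute across exons (genomic order)
        off = 0
        for s, e in exons:
            self.write(chrom, s, genomic[off : off + (e - s)])
            off += e - s
        # introns: A-free interior plus canonical dinucleotides
        for (s1, e1), (s2, _e2) in zip(exons, exons[1:]):
            self.scrub(chrom, e1, s2)
            if strand == "+":
                self.write(chrom, e1, "GT")
                self.write(chrom, s2 - 2, "AG")
            else:
                self.write(chrom, e1, "CT")
                self.write(chrom, s2 - 2, "AC")
        return _GeneShape(
            gene_id=gene_id,
            chrom=chrom,
            strand=strand,
            exons=exons,
            start=exons[0][0],
            end=exons[-1][1],
        )

    def plant_noncoding_exons(
        self,
        chrom: str,
        pos: int,
        strand: str,
        exon_lens: Sequence[int],
        intron_lens: Sequence[int],
    ) -> List[Tuple[int, int]]:
        """Plant ORF-free exons with canonical splice sites between them."""
        exons: List[Tuple[int, int]] = []
        cur = pos
        for i, el in enumerate(exon_lens):
            exons.append((cur, cur + el))
            cur += el
            if i < len(intron_lens):
                cur += intron_lens[i]
        self.scrub(chrom, exons[0][0], exons[-1][1])
        for (s1, e1), (s2, _e2) in zip(exons, exons[1:]):
            if strand == "+":
                self.write(chrom, e1, "GT")
                self.write(chrom, s2 - 2, "AG")
            else:
                self.write(chrom, e1, "CT")
                self.write(chrom, s2 - 2, "AC")
        return exons

    def freeze(self) -> Dict[str, str]:
        return {k: v.decode() for k, v in self.chroms.items()}


def _tx(
    tid: str,
    chrom: str,
    strand: str,
    exons: Sequence[Tuple[int, int]],
    gene_id: Optional[str] = None,
    source: str = "assembled",
) -> TranscriptModel:
    return TranscriptModel(
        transcript_id=tid,
        exons=tuple(GenomicInterval(chrom, s, e, strand) for s, e in exons),
        gene_id=gene_id,
        source=source,
    )


def generate_catalog(
    genome: Mapping[str, str],
    config: SyntheticConfig = SyntheticConfig(),
    seed: int = 0,
) -> SyntheticCatalog:
    """Plant the requested categories into *genome* and record the truth.

    Returns the modified genome alongside reference transcripts (the
    planted coding genes), assembled transcripts (one per planted locus),
    and the :class:`SyntheticTruth` table. Raises
    :class:`GenerationError` when the genome cannot hold the request.
    """
    for cat in config.category_counts:
        if cat not in PLANTABLE:
            raise GenerationError(f"cannot plant category {cat!r}")
    rng = np.random.default_rng(seed)
    planter = _Planter(genome, rng)
    chrom_names = sorted(planter.chroms)
    cursors = {c: 10_000 for c in chrom_names}

    def alloc(length: int) -> Tuple[str, int]:
        for c in chrom_names:
            if cursors[c] + length + 10_000 <= len(planter.chroms[c]):
                pos = cursors[c]
                cursors[c] = pos + length + config.cassette_gap
                return c, pos
        raise GenerationError(
            f"cannot place a cassette of {length} bp: genome too small "
            f"for the requested category counts"
        )

    reference: List[TranscriptModel] = []
    transcripts: List[TranscriptModel] = []
    units: List[PlantedUnit] = []
    gene_n = 0
    tx_n = 0

    def next_gene_id() -> str:
        nonlocal gene_n
        gene_n += 1
        return f"G{gene_n:05d}"

    def next_tx_id(cat: str) -> str:
        nonlocal tx_n
        tx_n += 1
        return f"TX{tx_n:05d}_{cat}"

    def regimes(cat: str) -> Tuple[str, str]:
        p1 = config.single_tissue_prob.get(cat, 0.3)
        regime = "single_tissue" if rng.random() < p1 else "broad"
        pats = list(config.detection_pattern_probs)
        probs = np.array([config.detection_pattern_probs[p] for p in pats])
        pattern = pats[rng.choice(len(pats), p=probs / probs.sum())]
        return regime, pattern

    def add_gene(
        chrom: str, pos: int, strand: str, intron1: Optional[int] = None
    ) -> _GeneShape:
        gid = next_gene_id()
        introns = [
            intron1 if intron1 is not None else config.gene_intron_len,
            config.gene_intron_len,
        ]
        shape = planter.plant_gene(
            gid,
            chrom,
            pos,
            strand,
            exon_lens=[config.gene_exon_len] * 3,
            intron_lens=introns,
            orf_aa=config.orf_aa,
        )
        reference.append(
            _tx(f"REF_{gid}", chrom, strand, shape.exons, gene_id=gid,
                source="reference_coding")
        )
        return shape

    strand_cycle = ["+", "-"]
    distal_queue: List[str] = []

    order = [c for c in PLANTABLE for _ in range(config.category_counts.get(c, 0))]
    for k, cat in enumerate(order):
        strand = strand_cycle[k % 2]
        if cat == "intergenic_distal":
            distal_queue.append(cat)
            continue
        regime, pattern = regimes(cat)
        if cat == "protein_coding_hiconf":
            chrom, pos = alloc(config.gene_exon_len * 3 + config.gene_intron_len * 2)
            g = add_gene(chrom, pos, strand)
            tid = next_tx_id(cat)
            transcripts.append(_tx(tid, chrom, strand, g.exons))
            units.append(PlantedUnit(tid, cat, (tid,), g.gene_id, regime, pattern))
        elif cat == "antisense_exonic":
            chrom, pos = alloc(config.gene_exon_len * 3 + config.gene_intron_len * 2)
            g = add_gene(chrom, pos, strand)
            e2 = g.exons[1]
            anti = "-" if strand == "+" else "+"
            exon = (e2[0] + 100, e2[0] + 350)
            tid = next_tx_id(cat)
            transcripts.append(_tx(tid, chrom, anti, [exon]))
            units.append(PlantedUnit(tid, cat, (tid,), g.gene_id, regime, pattern))
        elif cat in ("intronic_sense", "intronic_antisense"):
            chrom, pos = alloc(
                config.gene_exon_len * 3
                + config.host_intron_len
                + config.gene_intron_len
            )
            g = add_gene(chrom, pos, strand, intron1=config.host_intron_len)
            i_s = g.exons[0][1]
            exon = (i_s + 800, i_s + 1400)
            tstrand = strand if cat == "intronic_sense" else (
                "-" if strand == "+" else "+"
            )
            tid = next_tx_id(cat)
            transcripts.append(_tx(tid, chrom, tstrand, [exon]))
            units.append(PlantedUnit(tid, cat, (tid,), g.gene_id, regime, pattern))
        elif cat == "lincRNA":
            exon_lens = [250, 250, 250]
            intron_lens = [600, 600]
            chrom, pos = alloc(sum(exon_lens) + sum(intron_lens))
            exons = planter.plant_noncoding_exons(
                chrom, pos, strand, exon_lens, intron_lens
            )
            tid = next_tx_id(cat)
            transcripts.append(_tx(tid, chrom, strand, exons))
            units.append(PlantedUnit(tid, cat, (tid,), None, regime, pattern))
        elif cat == "intergenic_runoff_3prime":
            d = int(rng.integers(2_000, config.runoff_window - 2_000))
            gene_len = config.gene_exon_len * 3 + config.gene_intron_len * 2
            chrom, pos = alloc(gene_len + d + 500)
            if strand == "+":
                g = add_gene(chrom, pos, strand)
                p5 = g.tes + d
                exon = (p5, p5 + 400)
            else:
                # gene placed after the transcript so the run-off region
                # (downstream of a minus-strand gene = lower coordinates)
                # stays inside the cassette
                g = add_gene(chrom, pos + d + 500, strand)
                p5 = g.tes - d
                exon = (p5 - 399, p5 + 1)
            planter.scrub(chrom, exon[0], exon[1])
            tid = next_tx_id(cat)
            transcripts.append(_tx(tid, chrom, strand, [exon]))
            units.append(PlantedUnit(tid, cat, (tid,), g.gene_id, regime, pattern))
        elif cat == "intergenic_divergent_promoter":
            d = int(rng.integers(500, config.divergent_window - 500))
            gene_len = config.gene_exon_len * 3 + config.gene_intron_len * 2
            chrom, pos = alloc(gene_len + d + 500)
            anti = "-" if strand == "+" else "+"
            if strand == "+":
                g = add_gene(chrom, pos + d + 450, strand)
                p5 = g.tss - d
                exon = (p5 - 399, p5 + 1)
            else:
                g = add_gene(chrom, pos, strand)
                p5 = g.tss + d
                exon = (p5, p5 + 400)
            planter.scrub(chrom, exon[0], exon[1])
            tid = next_tx_id(cat)
            transcripts.append(_tx(tid, chrom, anti, [exon]))
            units.append(PlantedUnit(tid, cat, (tid,), g.gene_id, regime, pattern))

    # silent reference genes (annotated but never expressed)
    for _ in range(config.n_silent_reference):
        strand = strand_cycle[gene_n % 2]
        chrom, pos = alloc(config.gene_exon_len * 3 + config.gene_intron_len * 2)
        g = add_gene(chrom, pos, strand)
        units.append(
            PlantedUnit(
                f"REF_{g.gene_id}",
                "protein_coding_unexpressed",
                (f"REF_{g.gene_id}",),
                g.gene_id,
                "broad",
                "neither",
            )
        )

    # distal transcripts share one gene-free block with wide flanks
    if distal_queue:
        n = len(distal_queue)
        block = 2 * config.distal_flank + n * (400 + config.distal_spacing)
        chrom, pos = alloc(block)
        cur = pos + config.distal_flank
        for k, cat in enumerate(distal_queue):
            strand = strand_cycle[k % 2]
            regime, pattern = regimes(cat)
            exon = (cur, cur + 400)
            planter.scrub(chrom, exon[0], exon[1])
            tid = next_tx_id(cat)
            transcripts.append(_tx(tid, chrom, strand, [exon]))
            units.append(PlantedUnit(tid, cat, (tid,), None, regime, pattern))
            cur += 400 + config.distal_spacing

    return SyntheticCatalog(
        genome=planter.freeze(),
        reference=tuple(reference),
        transcripts=tuple(transcripts),
        truth=SyntheticTruth(units=tuple(units), seed=seed, config=config),
    )


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def default_samples(
    tissues: Sequence[str] = TISSUES, methods: Sequence[str] = ("polyA", "DSN")
) -> List[SampleMeta]:
    return [
        SampleMeta(f"{t}_{m}", tissue=t, method=m, replicate=1)
        for t in tissues
        for m in methods
    ]


def generate_expression(
    truth: SyntheticTruth,
    config: Optional[SyntheticConfig] = None,
    seed: int = 0,
) -> ExpressionMatrix:
    """Realise FPKM values honouring each unit's planted regimes.

    One row per transcript id in the truth table (assembled transcripts
    and reference gene transcripts alike; host genes not listed as units
    receive a broad, both-method coding-level profile). Values follow a
    lognormal around the category median; a ``single_tissue`` unit is
    nonzero in exactly one tissue, and each method's columns are zeroed
    or kept according to the planted detection pattern. Nonzero entries
    are floored just above the detection threshold so planted patterns
    are recovered exactly.
    """
    config = config or truth.config
    rng = np.random.default_rng(seed)
    samples = default_samples(config.tissues, config.methods)
    tissues = list(config.tissues)

    unit_rows: Dict[str, np.ndarray] = {}

    def realise(category: str, regime: str, pattern: str) -> Tuple[np.ndarray, str]:
        median = config.median_fpkm.get(category, 1.5)
        base = median * float(np.exp(rng.normal(0.0, config.sigma_locus)))
        if regime == "single_tissue":
            peak = int(rng.integers(len(tissues)))
            tissue_vals = np.zeros(len(tissues))
            tissue_vals[peak] = base
        else:
            tissue_vals = base * np.exp(
                rng.normal(0.0, config.sigma_tissue, size=len(tissues))
            )
            peak = int(np.argmax(tissue_vals))
        row = np.zeros(len(samples))
        for i, s in enumerate(samples):
            v = tissue_vals[tissues.index(s.tissue)]
            if v > 0:
                v = v * float(np.exp(rng.normal(0.0, config.sigma_method)))
                v = max(v, config.min_detected_fpkm)
            keep = (
                pattern == "both"
                or (pattern == "polyA_only" and s.method == "polyA")
                or (pattern == "DSN_only" and s.method == "DSN")
            )
            row[i] = v if keep else 0.0
        return row, tissues[peak]

    units_out = []
    host_genes_with_units = set()
    for u in truth.units:
        row, peak = realise(u.category, u.tau_regime, u.detection_pattern)
        for tid in u.transcript_ids:
            unit_rows[tid] = row
        units_out.append((u, peak))
        if u.gene_id:
            host_genes_with_units.add(u.gene_id)

    # reference gene transcripts not covered above: expressed coding profile
    ref_ids = {
        f"REF_{g}" for g in host_genes_with_units
    }
    for tid in sorted(ref_ids):
        if tid not in unit_rows:
            row, _ = realise("protein_coding_hiconf", "broad", "both")
            unit_rows[tid] = row

    df = pd.DataFrame.from_dict(
        unit_rows, orient="index", columns=[s.sample_id for s in samples]
    )
    df.index.name = "feature_id"
    return ExpressionMatrix(df, samples)


def generate_tree_expression(
    n_loci: int = 200,
    tissues: Sequence[str] = TISSUES,
    methods: Sequence[str] = ("polyA", "DSN"),
    tissue_sd: float = 1.0,
    method_sd: float = 0.1,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> ExpressionMatrix:
    """Loci x samples matrix with controllable tissue vs method effects.

    log-FPKM for locus l in sample (t, m) is
    ``mu_l + a_{l,t} + b_{l,m} + eps`` with tissue effects a ~ N(0,
    tissue_sd^2) and method effects b ~ N(0, method_sd^2). With
    ``tissue_sd >> method_sd`` samples of the same tissue correlate most
    strongly (tissue-first tree grouping); reversing the ratio makes the
    library method dominate.
    """
    rng = np.random.default_rng(seed)
    samples = default_samples(tissues, methods)
    mu = rng.normal(1.0, 1.0, size=n_loci)
    a = rng.normal(0.0, tissue_sd, size=(n_loci, len(tissues)))
    b = rng.normal(0.0, method_sd, size=(n_loci, len(methods)))
    cols = {}
    for s in samples:
        ti = list(tissues).index(s.tissue)
        mi = list(methods).index(s.method)
        eps = rng.normal(0.0, noise_sd, size=n_loci)
        cols[s.sample_id] = np.exp(mu + a[:, ti] + b[:, mi] + eps)
    df = pd.DataFrame(cols, index=[f"L{i:05d}" for i in range(n_loci)])
    df.index.name = "feature_id"
    return ExpressionMatrix(df, samples)
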