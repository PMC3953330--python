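"""Read/write the standard formats the pipeline touches.

All coordinates are kept in a single internal convention: 0-based,
half-open, as in BED. GTF/GFF input (1-based, closed) is converted at the
boundary; writing converts back, so a GTF -> internal -> GTF round trip is
the identity on coordinates.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

__all__ = [
    "GenomicInterval",
    "TranscriptModel",
    "SampleMeta",
    "ExpressionMatrix",
    "FeatureFileError",
    "ValidationError",
    "SOURCES",
    "CATEGORY_PALETTE",
    "read_annotation",
    "write_gtf",
    "read_expression",
    "write_expression",
    "read_samples",
    "write_samples",
    "write_catalog_bed",
    "read_catalog_bed",
]

STRANDS = ("+", "-")

#: Recognised provenance tags for a transcript model.
SOURCES = ("reference_coding", "reference_noncoding", "ortholog_coding", "assembled")

#: Library construction methods (poly-A selection vs duplex-specific nuclease).
METHODS = ("polyA", "DSN")


class FeatureFileError(ValueError):
    """A feature file could not be parsed."""


class ValidationError(ValueError):
    """An in-memory object violates a structural invariant."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval", stranded: bool = True) -> bool:
        """True if the half-open intersection with *other* is non-empty."""
        if self.chrom != other.chrom:
            return False
        if stranded and self.strand != other.strand:
            return False
        return self.start < other.end and other.start < self.end


@dataclass(frozen=True)
class TranscriptModel:
    """A stranded, exon-structured transcript.

    Exons are stored sorted by start and must be pairwise disjoint and all
    on one chromosome and strand.
    """

    transcript_id: str
    exons: tuple
    gene_id: Optional[str] = None
    source: str = "assembled"
    library_evidence: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValidationError(f"transcript {self.transcript_id}: no exons")
        exons = tuple(sorted(self.exons, key=lambda e: e.start))
        object.__setattr__(self, "exons", exons)
        chroms = {e.chrom for e in exons}
        strands = {e.strand for e in exons}
        if len(chroms) > 1:
            raise ValidationError(
                f"transcript {self.transcript_id}: exons on multiple chromosomes"
            )
        if len(strands) > 1:
            raise ValidationError(
                f"transcript {self.transcript_id}: exons on mixed strands"
            )
        for a, b in zip(exons, exons[1:]):
            if b.start < a.end:
                raise ValidationError(
                    f"transcript {self.transcript_id}: overlapping exons"
                )
        if self.source not in SOURCES:
            raise ValidationError(
                f"transcript {self.transcript_id}: unknown source {self.source!r}"
            )
        object.__setattr__(self, "library_evidence", frozenset(self.library_evidence))

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def five_prime(self) -> int:
        """Genomic position of the 5'-most transcribed base."""
        return self.start if self.strand == "+" else self.end - 1

    def introns(self) -> list:
        """Half-open intron intervals between consecutive exons."""
        return [
            (a.end, b.start) for a, b in zip(self.exons, self.exons[1:])
        ]


@dataclass(frozen=True)
class SampleMeta:
    """One sequencing library: a tissue profiled with one library method."""

    sample_id: str
    tissue: str
    method: str
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValidationError(
                f"sample {self.sample_id}: unknown method {self.method!r}"
            )


class ExpressionMatrix:
    """Features x samples FPKM table with tissue / library-method metadata.

    Parameters
    ----------
    values
        DataFrame indexed by feature id, one column per sample id. All
        entries must be finite and non-negative.
    samples
        One :class:`SampleMeta` per column; (tissue, method, replicate)
        must be unique.
    """

    def __init__(self, values: pd.DataFrame, samples: Sequence[SampleMeta]):
        samples = list(samples)
        ids = [s.sample_id for s in samples]
        if sorted(values.columns) != sorted(ids):
            unknown = set(values.columns) - set(ids)
            missing = set(ids) - set(values.columns)
            raise ValidationError(
                f"sample columns do not match metadata "
                f"(unknown={sorted(unknown)}, missing={sorted(missing)})"
            )
        keys = {(s.tissue, s.method, s.replicate) for s in samples}
        if len(keys) != len(samples):
            raise ValidationError("duplicate (tissue, method, replicate) in samples")
        if values.isna().any().any():
            raise ValidationError("expression matrix contains missing values")
        if (values.values < 0).any():
            raise ValidationError("expression values must be non-negative")
        self.values = values[ids].astype(float)
        self.samples = samples
        self._by_id = {s.sample_id: s for s in samples}

    # -- basic views ----------------------------------------------------
    @property
    def feature_ids(self) -> list:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list:
        return [s.sample_id for s in self.samples]

    @property
    def tissues(self) -> list:
        seen: dict = {}
        for s in self.samples:
            seen.setdefault(s.tissue, None)
        return list(seen)

    def meta(self, sample_id: str) -> SampleMeta:
        return self._by_id[sample_id]

    def columns_for(
        self, method: Optional[str] = None, tissue: Optional[str] = None
    ) -> list:
        out = []
        for s in self.samples:
            if method is not None and s.method != method:
                continue
            if tissue is not None and s.tissue != tissue:
                continue
            out.append(s.sample_id)
        return out

    def by_tissue(self, agg: str = "max") -> pd.DataFrame:
        """Aggregate samples to one value per tissue (max or mean)."""
        if agg not in ("max", "mean"):
            raise ValueError(f"unknown aggregation {agg!r}")
        groups = {t: self.columns_for(tissue=t) for t in self.tissues}
        cols = {
            t: getattr(self.values[c], agg)(axis=1) for t, c in groups.items()
        }
        return pd.DataFrame(cols)

    def subset(self, feature_ids: Iterable[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(feature_ids)], self.samples)

    def row(self, feature_id: str) -> pd.Series:
        return self.values.loc[feature_id]


# ---------------------------------------------------------------------------
# GTF / GFF3
# ---------------------------------------------------------------------------

_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')
_GFF3_ATTR = re.compile(r"([^=;]+)=([^;]*)")


def _detect_dialect(attrs: str) -> str:
    if '"' in attrs and _GTF_ATTR.search(attrs):
        return "gtf"
    if "=" in attrs:
        return "gff3"
    raise FeatureFileError(f"unrecognised attribute column: {attrs!r}")


def _parse_attrs(attrs: str, dialect: str) -> dict:
    if dialect == "gtf":
        return {k: v for k, v in _GTF_ATTR.findall(attrs)}
    return {k.strip(): v.strip() for k, v in _GFF3_ATTR.findall(attrs)}


_BIOTYPE_TO_SOURCE = {
    "protein_coding": "reference_coding",
    "ortholog_coding": "ortholog_coding",
}


def read_annotation(
    path: Union[str, Path],
    biotype_field: str = "gene_biotype",
    default_source: str = "assembled",
) -> list:
    """Parse exon features from a GTF or GFF3 file into transcript models.

    The dialect (GTF `key "value";` vs GFF3 `key=value`) is auto-detected
    from the first attribute column and must be consistent; mixed files are
    rejected. Coordinates are converted from 1-based closed to the internal
    0-based half-open convention, exons are grouped per transcript and
    sorted. The *biotype_field* attribute, when present, maps to the
    transcript source tag (``protein_coding`` -> ``reference_coding``,
    other values -> ``reference_noncoding``); otherwise *default_source*
    applies.
    """
    path = Path(path)
    dialect = None
    exons: dict = {}
    meta: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FeatureFileError(
                    f"{path.name}:{lineno}: expected 9 tab-separated columns, "
                    f"got {len(fields)}"
                )
            chrom, _src, ftype, start, end, _score, strand, _frame, attrs = fields
            if ftype != "exon":
                continue
            this_dialect = _detect_dialect(attrs)
            if dialect is None:
                dialect = this_dialect
            elif dialect != this_dialect:
                raise FeatureFileError(
                    f"{path.name}:{lineno}: mixed GTF/GFF3 attribute dialects"
                )
            attr = _parse_attrs(attrs, dialect)
            tid = attr.get("transcript_id") or attr.get("Parent")
            if not tid:
                raise FeatureFileError(
                    f"{path.name}:{lineno}: exon without transcript_id/Parent"
                )
            if strand not in STRANDS:
                raise FeatureFileError(
                    f"{path.name}:{lineno}: exon with invalid strand {strand!r}"
                )
            try:
                iv = GenomicInterval(chrom, int(start) - 1, int(end), strand)
            except (ValueError, ValidationError) as exc:
                raise FeatureFileError(f"{path.name}:{lineno}: {exc}") from exc
            exons.setdefault(tid, []).append(iv)
            if tid not in meta:
                biotype = attr.get(biotype_field)
                source = _BIOTYPE_TO_SOURCE.get(
                    biotype, "reference_noncoding" if biotype else default_source
                )
                libs = attr.get("library_evidence", "")
                meta[tid] = {
                    "gene_id": attr.get("gene_id") or attr.get("gene"),
                    "source": source,
                    "library_evidence": frozenset(
                        x for x in libs.split(",") if x
                    ),
                }
    out = []
    for tid, ivs in exons.items():
        m = meta[tid]
        try:
            out.append(
                TranscriptModel(
                    transcript_id=tid,
                    exons=tuple(ivs),
                    gene_id=m["gene_id"],
                    source=m["source"],
                    library_evidence=m["library_evidence"],
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path.name}: {exc}") from exc
    return out


def write_gtf(transcripts: Iterable[TranscriptModel], path: Union[str, Path]) -> None:
    """Write transcripts as GTF exon lines (1-based closed coordinates)."""
    _SOURCE_TO_BIOTYPE = {
        "reference_coding": "protein_coding",
        "ortholog_coding": "ortholog_coding",
        "reference_noncoding": "noncoding",
    }
    with open(path, "w") as fh:
        for tx in transcripts:
            attrs = [f'transcript_id "{tx.transcript_id}"']
            if tx.gene_id:
                attrs.append(f'gene_id "{tx.gene_id}"')
            biotype = _SOURCE_TO_BIOTYPE.get(tx.source)
            if biotype:
                attrs.append(f'gene_biotype "{biotype}"')
            if tx.library_evidence:
                libs = ",".join(sorted(tx.library_evidence))
                attrs.append(f'library_evidence "{libs}"')
            attr_col = "; ".join(attrs) + ";"
            for e in tx.exons:
                fh.write(
                    f"{e.chrom}\ttxcatalog\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f"{e.strand}\t.\t{attr_col}\n"
                )


# ---------------------------------------------------------------------------
# Expression tables
# ---------------------------------------------------------------------------

def read_expression(
    path: Union[str, Path], samples: Sequence[SampleMeta]
) -> ExpressionMatrix:
    """Read a feature x sample FPKM TSV whose header names the sample ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(df, samples)


def write_expression(expr: ExpressionMatrix, path: Union[str, Path]) -> None:
    expr.values.to_csv(path, sep="\t", index_label="feature_id")


def read_samples(path: Union[str, Path]) -> list:
    """Read sample metadata TSV: sample_id, tissue, method, replicate."""
    df = pd.read_csv(path, sep="\t")
    return [
        SampleMeta(r.sample_id, r.tissue, r.method, int(r.replicate))
        for r in df.itertuples()
    ]


def write_samples(samples: Sequence[SampleMeta], path: Union[str, Path]) -> None:
    pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "tissue": [s.tissue for s in samples],
            "method": [s.method for s in samples],
            "replicate": [s.replicate for s in samples],
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BED12 catalogue output
# ---------------------------------------------------------------------------

#: Fixed category -> itemRgb palette for the colour-coded catalogue BED.
CATEGORY_PALETTE: Mapping[str, tuple] = {
    "protein_coding_hiconf": (31, 119, 180),
    "protein_coding_unexpressed": (140, 160, 200),
    "antisense_exonic": (214, 39, 40),
    "lincRNA": (44, 160, 44),
    "intronic_sense": (148, 103, 189),
    "intronic_antisense": (227, 119, 194),
    "intergenic_runoff_3prime": (255, 127, 14),
    "intergenic_divergent_promoter": (188, 189, 34),
    "intergenic_distal": (127, 127, 127),
    "other_unclassified": (23, 190, 207),
}

_RGB_TO_CATEGORY = {v: k for k, v in CATEGORY_PALETTE.items()}


class CatalogError(ValueError):
    pass


def write_catalog_bed(
    records: Iterable[tuple],
    path: Union[str, Path],
    expr: Optional[ExpressionMatrix] = None,
    tsv_path: Optional[Union[str, Path]] = None,
) -> None:
    """Write a colour-coded BED12 catalogue.

    *records* yields ``(transcript, category)`` pairs; one BED12 line is
    written per transcript with blockSizes/blockStarts encoding the exon
    structure and itemRgb encoding the category through
    :data:`CATEGORY_PALETTE`. When *expr* is given, a companion TSV
    (``tsv_path``, default ``<path>.expr.tsv``) serialises per-tissue
    expression (max FPKM over each tissue's samples) per transcript; the
    companion layout is this package's own.
    """
    path = Path(path)
    by_tissue = expr.by_tissue(agg="max") if expr is not None else None
    tsv_rows = []
    with open(path, "w") as fh:
        for tx, category in records:
            if category is None:
                raise CatalogError(
                    f"transcript {tx.transcript_id} has no category"
                )
            if category not in CATEGORY_PALETTE:
                raise CatalogError(f"unknown category {category!r}")
            rgb = ",".join(str(c) for c in CATEGORY_PALETTE[category])
            sizes = ",".join(str(len(e)) for e in tx.exons)
            starts = ",".join(str(e.start - tx.start) for e in tx.exons)
            fh.write(
                "\t".join(
                    [
                        tx.chrom,
                        str(tx.start),
                        str(tx.end),
                        tx.transcript_id,
                        "0",
                        tx.strand,
                        str(tx.start),
                        str(tx.end),
                        rgb,
                        str(tx.n_exons),
                        sizes,
                        starts,
                    ]
                )
                + "\n"
            )
            if by_tissue is not None and tx.transcript_id in by_tissue.index:
                row = by_tissue.loc[tx.transcript_id]
                tsv_rows.append((tx.transcript_id, category, row))
    if expr is not None:
        tsv_path = Path(tsv_path) if tsv_path else path.with_suffix(
            path.suffix + ".expr.tsv"
        )
        tissues = list(by_tissue.columns)
        with open(tsv_path, "w") as fh:
            fh.write("transcript_id\tcategory\t" + "\t".join(tissues) + "\n")
            for tid, category, row in tsv_rows:
                vals = "\t".join(f"{row[t]:g}" for t in tissues)
                fh.write(f"{tid}\t{category}\t{vals}\n")


def read_catalog_bed(path: Union[str, Path]) -> list:
    """Read a catalogue BED12 back into ``(transcript, category)`` pairs."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) != 12:
                raise FeatureFileError(
                    f"{Path(path).name}:{lineno}: expected 12 BED columns"
                )
            chrom, start, name, strand = f[0], int(f[1]), f[3], f[5]
            rgb = tuple(int(x) for x in f[8].split(","))
            n = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != n or len(offsets) != n:
                raise FeatureFileError(
                    f"{Path(path).name}:{lineno}: blockCount mismatch"
                )
            exons = tuple(
                GenomicInterval(chrom, start + o, start + o + s, strand)
                for o, s in zip(offsets, sizes)
            )
            category = _RGB_TO_CATEGORY.get(rgb)
            out.append((TranscriptModel(transcript_id=name, exons=exons), category))
    return out
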