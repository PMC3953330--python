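"""End-to-end orchestration of the catalogue pipeline.

``run_catalog`` executes feature_io -> locus_builder -> coding_potential ->
classifier -> expression_atlas -> expression_trees on a bundle of input
files and writes the catalogue TSV, colour-coded BED12, atlas TSV, Newick
trees and a JSON summary report. Everything is deterministic given the
run configuration.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Union

import pandas as pd

from . import feature_io
from .classifier import (
    ClassifiedLocus,
    ClassifierConfig,
    ReferenceIndex,
    classify_catalog,
    compact_catalog,
    mark_unexpressed_reference,
)
from .coding_potential import (
    coding_verdict,
    read_domain_table,
    read_homology_table,
)
from .expression_atlas import category_summary, compute_tau, single_tissue_fraction
from .expression_trees import expression_distance, neighbor_joining
from .feature_io import ExpressionMatrix
from .locus_builder import (
    Locus,
    build_loci,
    library_overlap_stats,
    locus_expression,
    match_loci,
)

__all__ = ["RunConfig", "CatalogResult", "run_catalog", "run_compare"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """All inputs, thresholds and paths for one catalogue run."""

    reference_gtf: str
    transcript_gtf: str
    genome_fasta: str
    expression_tsv: str
    samples_tsv: str
    outdir: str
    domain_hits_tsv: Optional[str] = None
    homology_hits_tsv: Optional[str] = None
    runoff_window: int = 25_000
    divergent_window: int = 5_000
    detection_fpkm: float = 0.1
    orf_min_aa: int = 50
    bitscore_min: float = 60.0
    multiexon_min_exons: int = 2
    tree_min_fpkm: float = 1.0
    percentiles: tuple = (95.0,)
    compact: bool = True
    seed: int = 0

    def classifier_config(self) -> ClassifierConfig:
        return ClassifierConfig(
            runoff_window=self.runoff_window,
            divergent_window=self.divergent_window,
            detection_fpkm=self.detection_fpkm,
            orf_min_aa=self.orf_min_aa,
            bitscore_min=self.bitscore_min,
            multiexon_min_exons=self.multiexon_min_exons,
        )

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["percentiles"] = list(self.percentiles)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        d["percentiles"] = tuple(d["percentiles"])
        return cls(**d)


@dataclass
class CatalogResult:
    catalog: List[ClassifiedLocus]
    removed_intronic_sense: int
    unexpressed_reference: set
    locus_expr: ExpressionMatrix
    summaries: Dict[str, object]
    single_tissue: Dict[str, Optional[float]]
    overlap_fractions: Dict[str, float]
    trees: Dict[str, str]  # group name -> Newick
    summary: dict

    def labels(self) -> Dict[str, str]:
        return {c.locus.locus_id: c.category for c in self.catalog}


#: Figure-style grouping of categories for the expression trees.
TREE_GROUPS = {
    "protein_coding": ("protein_coding_hiconf",),
    "antisense": ("antisense_exonic",),
    "lincRNA": ("lincRNA",),
    "single_exon_intergenic": (
        "intergenic_runoff_3prime",
        "intergenic_divergent_promoter",
        "intergenic_distal",
    ),
}


class StageError(RuntimeError):
    def __init__(self, stage: str, exc: Exception):
        super().__init__(f"stage {stage!r} failed: {exc}")
        self.stage = stage


def _require(path: Union[str, Path], what: str) -> Path:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"{what} not found: {p}")
    return p


def run_catalog(cfg: RunConfig) -> CatalogResult:
    """Run every stage and write reports under ``cfg.outdir``."""
    import pyfaidx

    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ccfg = cfg.classifier_config()

    # --- inputs -----------------------------------------------------------
    reference = feature_io.read_annotation(
        _require(cfg.reference_gtf, "reference annotation"),
        default_source="reference_noncoding",
    )
    assembled = feature_io.read_annotation(
        _require(cfg.transcript_gtf, "transcript models"),
        default_source="assembled",
    )
    genome = pyfaidx.Fasta(str(_require(cfg.genome_fasta, "genome FASTA")))
    samples = feature_io.read_samples(_require(cfg.samples_tsv, "sample table"))
    expr = feature_io.read_expression(
        _require(cfg.expression_tsv, "expression table"), samples
    )
    domain_hits = (
        read_domain_table(cfg.domain_hits_tsv) if cfg.domain_hits_tsv else None
    )
    homology_hits = (
        read_homology_table(cfg.homology_hits_tsv) if cfg.homology_hits_tsv else None
    )

    # --- loci -------------------------------------------------------------
    try:
        loci = build_loci(assembled)
        ref_loci = build_loci(reference, id_prefix="REFLOC")
    except Exception as exc:  # pragma: no cover - defensive
        raise StageError("locus_builder", exc)

    # --- coding potential -------------------------------------------------
    try:
        evidence = {
            tx.transcript_id: coding_verdict(
                tx,
                genome,
                domain_hits=domain_hits if domain_hits is not None else {},
                homology_hits=homology_hits if homology_hits is not None else {},
                orf_min_aa=cfg.orf_min_aa,
                bitscore_min=cfg.bitscore_min,
            )
            for tx in assembled
        }
    except Exception as exc:
        raise StageError("coding_potential", exc)

    # --- classification ---------------------------------------------------
    try:
        ref_index = ReferenceIndex(reference)
        catalog = classify_catalog(loci, ref_index, evidence, ccfg)
    except Exception as exc:
        raise StageError("classifier", exc)
    removed = 0
    if cfg.compact:
        catalog, removed = compact_catalog(catalog)

    # --- expression atlas -------------------------------------------------
    lexpr = locus_expression([c.locus for c in catalog], expr)
    labels = {c.locus.locus_id: c.category for c in catalog}
    summaries = category_summary(
        labels,
        lexpr,
        percentiles=cfg.percentiles,
        detection_threshold=cfg.detection_fpkm,
    )
    single = single_tissue_fraction(labels, lexpr, threshold=cfg.detection_fpkm)
    overlap = library_overlap_stats(
        [c.locus for c in catalog], lexpr, threshold=cfg.detection_fpkm
    )

    ref_expr = locus_expression(ref_loci, expr)
    unexpressed = mark_unexpressed_reference(ref_loci, ref_expr, ccfg)

    # --- trees ------------------------------------------------------------
    trees: Dict[str, str] = {}
    for group, cats in TREE_GROUPS.items():
        ids = [lid for lid, cat in labels.items() if cat in cats]
        if len(ids) < 2:
            continue
        try:
            dm = expression_distance(lexpr, feature_ids=ids, min_fpkm=cfg.tree_min_fpkm)
            trees[group] = neighbor_joining(dm).to_newick()
        except ValueError as exc:
            log.warning("tree for %s skipped: %s", group, exc)

    # --- outputs ----------------------------------------------------------
    tau_table = compute_tau(lexpr)
    _write_catalog_tsv(catalog, outdir / "catalog.tsv")
    _write_atlas_tsv(labels, lexpr, tau_table, cfg.detection_fpkm, outdir / "atlas.tsv")
    records = [
        (tx, c.category) for c in catalog for tx in c.locus.transcripts
    ]
    feature_io.write_catalog_bed(records, outdir / "catalog.bed")
    for group, nwk in trees.items():
        (outdir / f"tree_{group}.nwk").write_text(nwk + "\n")

    counts: Dict[str, int] = {}
    for c in catalog:
        counts[c.category] = counts.get(c.category, 0) + 1
    summary = {
        "config": json.loads(cfg.to_json()),
        "n_loci": len(catalog),
        "category_counts": counts,
        "removed_intronic_sense": removed,
        "unexpressed_reference_loci": len(unexpressed),
        "library_overlap_fractions": overlap,
        "single_tissue_fractions": single,
        "percentile_fpkm": {
            label: s.percentile_fpkm for label, s in summaries.items()
        },
        "mean_tau": {label: s.mean_tau for label, s in summaries.items()},
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))

    return CatalogResult(
        catalog=catalog,
        removed_intronic_sense=removed,
        unexpressed_reference=unexpressed,
        locus_expr=lexpr,
        summaries=summaries,
        single_tissue=single,
        overlap_fractions=overlap,
        trees=trees,
        summary=summary,
    )


def _write_catalog_tsv(catalog: Sequence[ClassifiedLocus], path: Path) -> None:
    rows = []
    for c in catalog:
        rows.append(
            {
                "locus_id": c.locus.locus_id,
                "chrom": c.locus.chrom,
                "start": c.locus.span[0],
                "end": c.locus.span[1],
                "strand": c.locus.strand,
                "n_transcripts": len(c.locus.transcripts),
                "category": c.category,
                "fired_rule": c.label.fired_rule,
                "host_gene_id": c.label.host_gene_id or "",
                "distance": "" if c.label.distance is None else c.label.distance,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _write_atlas_tsv(
    labels: Mapping[str, str],
    lexpr: ExpressionMatrix,
    tau_table: pd.DataFrame,
    threshold: float,
    path: Path,
) -> None:
    df = lexpr.values.copy()
    df.insert(0, "category", [labels.get(i, "") for i in df.index])
    df["detected"] = (lexpr.values.max(axis=1) > threshold).astype(int)
    df["tau"] = tau_table["tau"]
    df["peak_tissue"] = tau_table["peak_tissue"]
    df.to_csv(path, sep="\t", index_label="locus_id")


def run_compare(
    set_a: Sequence[Locus], set_b: Sequence[Locus]
) -> dict:
    """Per-direction shared/exclusive counts and fractions for two locus sets."""
    rep = match_loci(set_a, set_b)
    out = {
        "a_total": rep.a_total,
        "b_total": rep.b_total,
        "a_shared": rep.a_shared,
        "a_only": rep.a_only,
        "b_shared": rep.b_shared,
        "b_only": rep.b_only,
    }
    out.update({f"frac_{k}": v for k, v in rep.fractions().items()})
    return out
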