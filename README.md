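# txcatalog

Tools for building a transcript catalogue from assembled RNA-seq
transcript models, in the style of whole-transcriptome annotation efforts
that combine poly-A-selected and DSN-normalised libraries across a tissue
panel.

Given a reference annotation (GTF/GFF3), assembled transcript models
(GTF), a genome (FASTA) and per-sample FPKM tables, the package:

- **merges transcripts into loci** — a locus is the maximal set of
  same-strand transcripts connected by ≥1 bp of exonic overlap;
- **screens coding potential** three complementary ways: a sense-strand
  open reading frame of ≥50 amino acids, a protein-domain hit, or a
  protein-homology hit with bitscore strictly >60 (domain/homology results
  are consumed as pre-computed tables);
- **classifies every locus** into one of: high-confidence protein coding,
  antisense (opposite strand, overlapping ≥1 coding exon), lincRNA
  (intergenic, spliced multi-exon, no coding potential), intronic
  sense/antisense, 3′ run-off (single-exon, same strand, starting within
  25 kb downstream of a gene's 3′ end), divergent-promoter (single-exon,
  reverse strand, starting within 5 kb upstream of a TSS), distal
  intergenic, or unclassified;
- **computes an expression atlas**: detection at FPKM > 0.1, the tau
  tissue-specificity index
  τ = Σᵢ (1 − xᵢ/x_max) / (n − 1),
  per-category 95th-percentile FPKM summaries, single-tissue fractions,
  and the fraction of loci reported by both library construction methods;
- **builds neighbor-joining trees** over samples from d = 1 − Spearman's ρ
  on loci with FPKM > 1.0, written as Newick;
- **writes the catalogue** as a colour-coded BED12 with a companion
  per-tissue expression TSV,

plus a fully seeded **synthetic-data generator** that plants each category
with known ground truth (genome, annotations, expression), so every stage
is testable end to end without any external data.

## Worked example

```python
from txcatalog import synthetic_data as sd
from txcatalog import (build_loci, coding_verdict, ReferenceIndex,
                       classify_catalog, locus_expression,
                       category_summary, library_overlap_stats)

cfg = sd.SyntheticConfig()                      # 5 loci per category
genome = sd.generate_genome(n_chrom=1, length=3_000_000, gc=0.41, seed=7)
cat = sd.generate_catalog(genome, cfg, seed=7)
expr = sd.generate_expression(cat.truth, cfg, seed=8)

loci = build_loci(cat.transcripts)
evidence = {t.transcript_id: coding_verdict(t, cat.genome, {}, {})
            for t in cat.transcripts}
classified = classify_catalog(loci, ReferenceIndex(cat.reference), evidence)

truth = cat.truth.label_by_transcript()
hits = sum(truth[c.locus.transcript_ids[0]] == c.category for c in classified)
print(f"recovered {hits}/{len(classified)} planted labels")

lexpr = locus_expression(loci, expr)
print(library_overlap_stats(loci, lexpr, threshold=0.1))
```

prints

```
recovered 40/40 planted labels
{'both': 0.6, 'polyA_only': 0.225, 'DSN_only': 0.15, 'neither': 0.025}
```

— all 40 planted loci (5 per category across the 8 categories) come back
with their planted label, and the both/one/neither library-method
detection split equals the pattern planted by the generator (drawn around
a 57/20/20/3 mix).

The same flow is available from the shell:

```sh
txcatalog generate --outdir bundle --per-category 5 --seed 7
txcatalog run-all --config run.json      # RunConfig JSON
txcatalog compare a.gtf b.gtf
```

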