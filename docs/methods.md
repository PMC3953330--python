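# Methods

## The catalogue model

The package treats a transcriptome catalogue as three layers:

1. **Transcript models** — stranded, exon-structured features parsed from
   GTF/GFF3. Internally all coordinates are 0-based half-open (BED
   convention); conversion from the 1-based closed GTF convention happens
   only at the file boundary, so a read→write round trip is the identity.
2. **Loci** — the unit of classification and expression. A locus is the
   maximal set of same-strand transcripts connected by exonic overlap.
   Overlap requires at least one shared base on half-open intervals, so
   abutting exons do not merge; there is no minimum-overlap fraction. The
   partition is computed by a sweep over exon starts with union-find,
   which is exactly the connected components of the pairwise overlap
   graph (the test suite checks this against a brute-force O(n²) oracle).
3. **Categories** — each locus gets exactly one label from a fixed
   decision cascade (first match wins):
   coding (same-strand exonic overlap with a coding reference/ortholog
   gene, or a positive coding screen) → antisense (opposite-strand
   overlap with ≥1 coding exon) → intronic sense/antisense (span fully
   inside one intron) → lincRNA (intergenic, ≥2 exons, no coding screen
   positive for any member) → 3′ run-off → divergent-promoter → distal →
   unclassified. The categories themselves do not define a precedence for
   loci matching several rules; the cascade order is this package's
   design choice (coding evidence outranks position, antisense outranks
   intronic) and is applied deterministically.

## Coding-potential screens

A transcript screens positive if any of three tests fire:

- **ORF length** ≥ `orf_min_aa` (default 50 aa, counting the initial Met
  and excluding the stop). ORFs are scanned on the three sense-strand
  frames only and must terminate at an in-frame stop codon inside the
  transcript; ORFs running off the 3′ end are not counted. This is the
  conservative reading — it keeps lincRNA calls stricter — and is a
  package choice, since requiring the stop is a genuinely open decision.
  Codons containing N match neither ATG nor a stop.
- **Domain hit** — any entry for the transcript in a pre-computed
  (transcript, domain) table.
- **Homology** — best bitscore strictly greater than `bitscore_min`
  (default 60); a hit at exactly 60 does not count. Running the
  domain/homology searches is out of scope; their outputs are consumed
  as TSVs, and an absent table means "no hits" (logged).

## Distance windows

Proximity classes use two windows, both inclusive: run-off within
25,000 bp downstream of a gene's 3′ end (same strand) and
divergent-promoter within 5,000 bp upstream of a TSS (opposite strand).
Distances are measured from the locus's 5′-most base to the gene anchor;
"nearest gene" minimises that distance with ties broken by smaller gene
id. Whether the original windows were measured from the locus boundary
or its start is not documented anywhere we could rely on; measuring from
the transcript start is our documented choice, and enlarging a window can
only move loci from distal into the proximity class (tested property).

## Splice-boundary snapping

For cross-annotation comparison, internal exon boundaries can be snapped
to canonical GT–AG introns: each boundary independently moves at most
5 nt to the nearest position carrying the donor (GT) or acceptor (AG)
motif, strand-aware (genomic CT/AC on the minus strand). GC–AG introns
are not accepted. Ties between equal shifts resolve downstream; a shift
that would collapse an exon is refused with a warning.

## Expression atlas

- **Detection** is strict: max FPKM > 0.1 (a value of exactly 0.1 is not
  detected).
- **Tau** uses the Yanai-style index τ = Σᵢ(1 − xᵢ/x_max)/(n − 1) on one
  aggregated value per tissue. Aggregation defaults to the maximum over
  that tissue's samples (both library methods, all replicates) and can be
  switched to the mean; no log transform is applied. τ = 1 iff expression
  is confined to one tissue; an all-zero profile leaves τ undefined and
  excluded from category means. Whether the original atlas computed τ on
  poly-A samples only is unknown; using both methods is our default and
  the aggregation is configurable.
- **Category summaries** report the empirical percentile (linear
  interpolation) of per-locus max FPKM, the detected fraction, and mean τ
  over detected loci.
- **Library overlap** calls a locus detected under a method if its max
  FPKM over that method's samples exceeds the threshold; the
  both/polyA-only/DSN-only/neither fractions sum to one.

## Expression trees

Sample distances are d = 1 − Spearman's ρ (average ranks for ties) over
loci with FPKM > 1.0 in at least one sample — a single global filter, not
per-pair, which is our reading of an underdetermined rule. A sample with
zero variance over the retained loci has no defined ρ and is reported as
an error rather than silently patched. Neighbor joining is the classical
Saitou–Nei algorithm; negative branch-length estimates are clamped to
zero with the deficit moved to the sister branch (preserving the pair
distance), and all ties break lexicographically on the smallest leaf
label under each node, so the canonical Newick output is invariant under
sample permutation. On additive matrices the output reproduces every
leaf-to-leaf distance to 1e−9.

## Synthetic data: what it emulates, and what it does not

The generator plants one cassette per requested locus on a random genome
(default GC 0.41): a three-exon coding gene with a genuine ORF (default
120 aa) and canonical splice sites wherever the category needs a host or
neighbour gene, plus the category's transcript placed with ≥1 bp margin
inside its geometric definition — antisense over a coding exon, intronic
transcripts 800 bp inside a 4 kb intron, run-off starts 2–23 kb
downstream, divergent starts 0.5–4.5 kb upstream, and distal transcripts
in a block with ≥200 kb gene-free flanks (echoing the observation that
distal intergenic transcripts sit ~150 kb from the nearest gene).
Cassettes are separated by 40 kb so proximity rules cannot fire across
cassettes.

Planted regions are written A-free outside ORF start/stop codons. Since
an ORF needs an ATG and a reverse-strand ATG needs a forward-strand CAT,
an A-free stretch provably has no ORF on either strand: planted
non-coding transcripts always screen negative, whatever the seed. This
is the key unrealism of the generator — real intergenic sequence has
uniform base composition and produces borderline ORFs — so passing the
recovery tests shows the *rules* are implemented correctly, not that the
50-aa screen cleanly separates coding from non-coding in real data.
Other simplifications: one transcript per planted locus (no isoform
complexity), no sequencing noise or assembly artifacts, a complete
10-tissue × 2-method sample grid, and expression drawn lognormal around
category medians {coding 20, lincRNA 2, antisense 1 FPKM} with planted
single-tissue probabilities (lincRNA 0.37, antisense 0.214) and a
57/20/20/3 both/polyA-only/DSN-only/neither detection mix. Nonzero
entries are floored at 0.2 FPKM so planted detection patterns are
recovered exactly rather than within sampling error.

A separate helper (`generate_tree_expression`) produces loci × samples
matrices with independent per-locus tissue and method effects on the log
scale; setting one standard deviation well above the other makes the NJ
tree pair samples by tissue or by method respectively, which is the
qualitative structure the tree tests and acceptance script check.

## Problem sizes and numerical choices

The acceptance script uses a 9 Mb two-chromosome genome with 50 planted
loci per category (400 loci), 200 random instances of ≤100 transcripts
for the locus oracle, 100 random 6–10-leaf additive trees, 1,000 random
tau vectors, and 1,500 loci per category for the expression statistics;
these sizes give stable estimates while the whole script runs in a few
seconds. Percentiles use linear interpolation; distance matrices are
symmetrised and clipped to [0, 2] against floating-point drift;
all randomness flows from numpy `default_rng` seeded from a single
`--seed`.

## Known limitations

- Ortholog-derived coding transcripts are consumed pre-mapped (source
  tag `ortholog_coding`); the synteny mapping itself is not implemented.
- FPKM normalisation and differential expression are upstream/out of
  scope; the atlas consumes the tables as given.
- The BED12 companion TSV layout (per-tissue max FPKM per transcript) is
  this package's own, as the original companion format is undocumented.
- Loci that straddle gene structure without exonic overlap (e.g. crossing
  a gene boundary on the opposite strand) fall to `other_unclassified`;
  real catalogues may want finer sub-rules there.
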