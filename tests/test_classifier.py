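import numpy as np
import pandas as pd
import pytest

from txcatalog.classifier import (
    ClassifierConfig,
    ReferenceIndex,
    classify_catalog,
    classify_locus,
    compact_catalog,
    mark_unexpressed_reference,
    snap_splice_boundaries,
)
from txcatalog.coding_potential import CodingEvidence
from txcatalog.feature_io import ExpressionMatrix, SampleMeta, ValidationError
from txcatalog.locus_builder import build_loci


def no_coding(tids):
    return {
        t: CodingEvidence(t, 0, False, None, False) for t in tids
    }


@pytest.fixture
def reference(tx_factory):
    """One plus-strand coding gene on chr1: exons [10000,10400),
    [11000,11400), [12000,12400); TSS at 10000, 3' end at 12399."""
    ref = tx_factory(
        "REF_G1",
        "chr1",
        "+",
        [(10_000, 10_400), (11_000, 11_400), (12_000, 12_400)],
        gene_id="G1",
        source="reference_coding",
    )
    return ReferenceIndex([ref])


def one_locus(tx_factory, tid, strand, exons):
    (locus,) = build_loci([tx_factory(tid, "chr1", strand, exons)])
    return locus


class TestCascade:
    def test_same_strand_exon_overlap_is_coding(self, reference, tx_factory):
        locus = one_locus(tx_factory, "t", "+", [(10_200, 10_600)])
        label = classify_locus(locus, reference, no_coding(["t"]))
        assert label.category == "protein_coding_hiconf"
        assert label.host_gene_id == "G1"

    def test_coding_verdict_alone_is_coding(self, reference, tx_factory):
        locus = one_locus(tx_factory, "t", "+", [(500_000, 500_400)])
        ev = {"t": CodingEvidence("t", 120, False, None, True)}
        assert classify_locus(locus, reference, ev).category == "protein_coding_hiconf"

    def test_antisense_exonic(self, reference, tx_factory):
        locus = one_locus(tx_factory, "t", "-", [(11_100, 11_300)])
        label = classify_locus(locus, reference, no_coding(["t"]))
        assert label.category == "antisense_exonic"
        assert label.host_gene_id == "G1"

    def test_intronic_sense_and_antisense(self, reference, tx_factory):
        sense = one_locus(tx_factory, "t", "+", [(10_500, 10_900)])
        anti = one_locus(tx_factory, "t", "-", [(10_500, 10_900)])
        assert classify_locus(sense, reference, no_coding(["t"])).category == "intronic_sense"
        assert classify_locus(anti, reference, no_coding(["t"])).category == "intronic_antisense"

    def test_straddling_gene_end_is_unclassified(self, reference, tx_factory):
        # opposite strand, overlaps intron 2 and runs past the gene end
        locus = one_locus(tx_factory, "t", "-", [(11_500, 11_900), (12_500, 12_800)])
        label = classify_locus(locus, reference, no_coding(["t"]))
        assert label.category == "other_unclassified"

    def test_distant_multiexon_is_lincRNA(self, reference, tx_factory):
        locus = one_locus(
            tx_factory, "t", "+", [(500_000, 500_200), (501_000, 501_200), (502_000, 502_150)]
        )
        label = classify_locus(locus, reference, no_coding(["t"]))
        assert label.category == "lincRNA"

    @pytest.mark.parametrize(
        "offset,expected",
        [
            (10_000, "intergenic_runoff_3prime"),
            (25_000, "intergenic_runoff_3prime"),  # inclusive window edge
            (25_001, "intergenic_distal"),
            (30_000, "intergenic_distal"),
        ],
    )
    def test_runoff_window_boundary(self, reference, tx_factory, offset, expected):
        """Single-exon same-strand transcripts inside/outside 25 kb downstream."""
        tes = 12_399
        locus = one_locus(tx_factory, "t", "+", [(tes + offset, tes + offset + 400)])
        label = classify_locus(locus, reference, no_coding(["t"]))
        assert label.category == expected
        if expected == "intergenic_runoff_3prime":
            assert label.distance == offset

    @pytest.mark.parametrize(
        "offset,expected",
        [
            (3_000, "intergenic_divergent_promoter"),
            (5_000, "intergenic_divergent_promoter"),  # inclusive window edge
            (5_001, "intergenic_distal"),
        ],
    )
    def test_divergent_window_boundary(self, reference, tx_factory, offset, expected):
        """Reverse-strand single-exon transcripts upstream of the TSS."""
        tss = 10_000
        p5 = tss - offset  # 5'-most base of a minus-strand transcript
        locus = one_locus(tx_factory, "t", "-", [(p5 - 399, p5 + 1)])
        label = classify_locus(locus, reference, no_coding(["t"]))
        assert label.category == expected

    def test_minus_strand_gene_geometry(self, tx_factory):
        ref = ReferenceIndex(
            [
                tx_factory(
                    "REF_G2",
                    "chr1",
                    "-",
                    [(50_000, 50_400), (51_000, 51_400)],
                    gene_id="G2",
                    source="reference_coding",
                )
            ]
        )
        # 3' end of a minus gene is its lowest coordinate (50,000);
        # run-off extends to lower coordinates on the same strand
        run = one_locus(tx_factory, "t", "-", [(39_601, 40_001)])  # 5' base 40,000
        assert classify_locus(run, ref, no_coding(["t"])).category == "intergenic_runoff_3prime"
        # TSS is the highest base (51,399); divergent partner on + strand above it
        div = one_locus(tx_factory, "t", "+", [(54_399, 54_799)])  # 5' base 54,399, d=3000
        assert classify_locus(div, ref, no_coding(["t"])).category == "intergenic_divergent_promoter"

    def test_missing_evidence_errors(self, reference, tx_factory):
        locus = one_locus(tx_factory, "t", "+", [(500_000, 500_400)])
        with pytest.raises(Exception, match="missing coding evidence"):
            classify_locus(locus, reference, {})

    def test_runoff_window_monotonicity(self, reference, tx_factory):
        """Enlarging the run-off window only moves distal -> run-off."""
        rng = np.random.default_rng(0)
        tes = 12_399
        loci = [
            one_locus(tx_factory, f"t{i}", "+", [(tes + int(d), tes + int(d) + 300)])
            for i, d in enumerate(rng.integers(1_000, 60_000, size=30))
        ]
        ev = no_coding([l.transcript_ids[0] for l in loci])
        small = {
            l.locus_id: classify_locus(l, reference, ev, ClassifierConfig(runoff_window=20_000))
            for l in loci
        }
        big = {
            l.locus_id: classify_locus(l, reference, ev, ClassifierConfig(runoff_window=40_000))
            for l in loci
        }
        for lid in small:
            if small[lid].category == "intergenic_runoff_3prime":
                assert big[lid].category == "intergenic_runoff_3prime"

    def test_determinism(self, small_bundle):
        cfg, catalog, _ = small_bundle
        loci = build_loci(catalog.transcripts)
        ev = no_coding([t for l in loci for t in l.transcript_ids])
        ref = ReferenceIndex(catalog.reference)
        a = [c.label for c in classify_catalog(loci, ref, ev)]
        b = [c.label for c in classify_catalog(loci, ref, ev)]
        assert a == b

    def test_every_locus_gets_exactly_one_label(self, classified_small_bundle):
        catalog, classified = classified_small_bundle
        counts = {}
        for c in classified:
            counts[c.category] = counts.get(c.category, 0) + 1
        assert sum(counts.values()) == len(classified)


class TestMarkUnexpressed:
    def _expr(self, rows, ids):
        samples = [
            SampleMeta("s1", "brain", "polyA"),
            SampleMeta("s2", "liver", "DSN"),
        ]
        df = pd.DataFrame(rows, index=ids, columns=["s1", "s2"])
        return ExpressionMatrix(df, samples)

    def test_all_zero_is_flagged(self, tx_factory):
        loci = build_loci(
            [tx_factory("r", "chr1", "+", [(0, 100)], source="reference_coding")]
        )
        expr = self._expr([[0.0, 0.0]], [loci[0].locus_id])
        assert mark_unexpressed_reference(loci, expr) == {loci[0].locus_id}

    def test_above_threshold_stays_expressed(self, tx_factory):
        loci = build_loci(
            [tx_factory("r", "chr1", "+", [(0, 100)], source="reference_coding")]
        )
        expr = self._expr([[0.0, 0.2]], [loci[0].locus_id])
        assert mark_unexpressed_reference(loci, expr) == set()

    def test_planted_silent_genes_recovered(self, tx_factory):
        """Exactly the 3 planted silent genes out of 20 are flagged."""
        txs = [
            tx_factory(f"r{i}", "chr1", "+", [(i * 10_000, i * 10_000 + 500)],
                       source="reference_coding")
            for i in range(20)
        ]
        loci = build_loci(txs)
        silent = {loci[3].locus_id, loci[8].locus_id, loci[15].locus_id}
        rows = [
            [0.0, 0.0] if l.locus_id in silent else [1.0, 0.5] for l in loci
        ]
        expr = self._expr(rows, [l.locus_id for l in loci])
        assert mark_unexpressed_reference(loci, expr) == silent


class TestCompact:
    def test_removes_only_intronic_sense(self, classified_small_bundle):
        _, classified = classified_small_bundle
        n_intronic = sum(1 for c in classified if c.category == "intronic_sense")
        kept, removed = compact_catalog(classified)
        assert removed == n_intronic
        assert all(c.category != "intronic_sense" for c in kept)
        assert len(kept) + removed == len(classified)

    def test_identity_without_intronic_sense(self, classified_small_bundle):
        _, classified = classified_small_bundle
        kept, _ = compact_catalog(classified)
        again, removed = compact_catalog(kept)
        assert removed == 0 and again == kept


class TestSpliceSnap:
    def _genome(self, intron, flank="C" * 30):
        # exon1 [0,30), intron [30, 30+len), exon2
        seq = flank + intron + flank
        return {"chr1": seq}, 30, 30 + len(intron)

    def test_canonical_intron_unchanged(self, tx_factory):
        genome, i_s, i_e = self._genome("GT" + "C" * 50 + "AG")
        tx = tx_factory("t", "chr1", "+", [(0, i_s), (i_e, i_e + 30)])
        assert snap_splice_boundaries(tx, genome).exons == tx.exons

    def test_donor_shift_plus_three(self, tx_factory):
        """GT three nt right of the predicted boundary pulls the donor +3."""
        genome, i_s, i_e = self._genome("CCC" + "GT" + "C" * 47 + "AG")
        tx = tx_factory("t", "chr1", "+", [(0, i_s), (i_e, i_e + 30)])
        snapped = snap_splice_boundaries(tx, genome, max_shift=5)
        assert snapped.exons[0].end == i_s + 3
        assert snapped.exons[1].start == i_e

    def test_donor_beyond_window_unchanged(self, tx_factory):
        genome, i_s, i_e = self._genome("CCCCCC" + "GT" + "C" * 44 + "AG")
        tx = tx_factory("t", "chr1", "+", [(0, i_s), (i_e, i_e + 30)])
        snapped = snap_splice_boundaries(tx, genome, max_shift=5)
        assert snapped.exons[0].end == i_s  # GT only at +6

    def test_acceptor_shift_minus_two(self, tx_factory):
        genome, i_s, i_e = self._genome("GT" + "C" * 48 + "AG" + "CC")
        # predicted acceptor 2 nt right of the true AG
        tx = tx_factory("t", "chr1", "+", [(0, i_s), (i_e, i_e + 30)])
        snapped = snap_splice_boundaries(tx, genome, max_shift=5)
        assert snapped.exons[1].start == i_e - 2

    def test_minus_strand_motifs(self, tx_factory):
        # minus intron: genomic CT ... AC
        genome, i_s, i_e = self._genome("CT" + "G" * 50 + "AC")
        tx = tx_factory("t", "chr1", "-", [(0, i_s), (i_e, i_e + 30)])
        assert snap_splice_boundaries(tx, genome).exons == tx.exons

    def test_single_exon_rejected(self, tx_factory):
        genome = {"chr1": "ACGT" * 30}
        tx = tx_factory("t", "chr1", "+", [(0, 30)])
        with pytest.raises(ValidationError, match=">=2 exons"):
            snap_splice_boundaries(tx, genome)

    def test_exon_order_and_disjointness_preserved(self, tx_factory):
        rng = np.random.default_rng(4)
        seq = "".join(rng.choice(list("ACGT"), size=2_000))
        genome = {"chr1": seq}
        tx = tx_factory("t", "chr1", "+", [(50, 300), (500, 800), (1_200, 1_500)])
        snapped = snap_splice_boundaries(tx, genome, max_shift=5)
        exons = snapped.exons
        assert all(a.end <= b.start for a, b in zip(exons, exons[1:]))
        assert all(len(e) > 0 for e in exons)
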