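import pytest

from txcatalog import synthetic_data as sd
from txcatalog.classifier import ReferenceIndex, classify_catalog
from txcatalog.coding_potential import coding_verdict
from txcatalog.feature_io import GenomicInterval, TranscriptModel
from txcatalog.locus_builder import build_loci


@pytest.fixture(scope="session")
def small_bundle():
    """A 5-per-category planted genome/catalogue/expression bundle."""
    cfg = sd.SyntheticConfig()
    genome = sd.generate_genome(n_chrom=1, length=3_000_000, gc=0.41, seed=7)
    catalog = sd.generate_catalog(genome, cfg, seed=7)
    expr = sd.generate_expression(catalog.truth, cfg, seed=8)
    return cfg, catalog, expr


@pytest.fixture(scope="session")
def classified_small_bundle(small_bundle):
    cfg, catalog, expr = small_bundle
    loci = build_loci(catalog.transcripts)
    evidence = {
        t.transcript_id: coding_verdict(t, catalog.genome, {}, {})
        for t in catalog.transcripts
    }
    ref = ReferenceIndex(catalog.reference)
    classified = classify_catalog(loci, ref, evidence)
    return catalog, classified


def make_transcript(tid, chrom, strand, exons, **kw):
    return TranscriptModel(
        transcript_id=tid,
        exons=tuple(GenomicInterval(chrom, s, e, strand) for s, e in exons),
        **kw,
    )


@pytest.fixture
def tx_factory():
    return make_transcript
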