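import numpy as np
import pytest

from hgtkit import screen, synth


@pytest.fixture(scope="session")
def ref_db():
    return synth.simulate_reference_db(seed=1)


@pytest.fixture(scope="session")
def benchmark(ref_db):
    """The synthetic screening benchmark: 20 native, 3 HGT, 5 contaminant
    transcripts, error-free staged reads, and alignment-score hit tables."""
    txm = synth.simulate_recipient_transcriptome(
        ref_db, n_native=20, n_hgt=3, n_contaminants=5,
        emit_retention_isoform=False, seed=2)
    reads = synth.simulate_reads(txm, depth=8.0, error_rate=0.0, seed=3)
    queries = [screen.SeqRecord(t.id, screen.predict_orf(t).protein.seq,
                                moltype="protein")
               for t in txm.transcripts]
    hits = synth.build_hit_table(queries, ref_db)
    cdna_hits = synth.build_cdna_hit_table(txm.transcripts, txm.truth,
                                           ref_db.taxonomy)
    host_free = [s.name for s in synth.DEFAULT_STAGES if s.host_free]
    return {"txm": txm, "reads": reads, "hits": hits, "cdna_hits": cdna_hits,
            "host_free": host_free, "taxonomy": ref_db.taxonomy}


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
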