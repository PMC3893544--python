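import math

import numpy as np
import pytest

from hgtkit import screen, synth
from hgtkit.io import Hit, SeqRecord
from hgtkit.screen import AlienVerdict, ScreenConfig


def _read(seq, qual=None, rid="r"):
    return SeqRecord(rid, seq, quality=qual if qual is not None else [40] * len(seq))


def _naive_trim(seq, qual, floor, adapters):
    """Independent character-level reference implementation."""
    for ad in adapters:
        if ad and len(ad) <= len(seq):
            i = seq.find(ad)
            if i >= 0:
                seq, qual = seq[:i], qual[:i]
    out_s, out_q = [], []
    for c, q in zip(seq, qual):
        if q < floor:
            break
        out_s.append(c)
        out_q.append(q)
    return "".join(out_s), out_q


class TestTrimReads:
    def test_high_quality_unchanged(self):
        r = _read("ACGTACGT")
        out = screen.trim_reads([r], 25)
        assert out[0].seq == "ACGTACGT"

    def test_adapter_clipped(self):
        r = _read("ACGTNNNN")
        out = screen.trim_reads([r], 25, adapters=["NNNN"])
        assert out[0].seq == "ACGT"

    def test_adapter_longer_than_read_ignored(self):
        r = _read("ACGT")
        out = screen.trim_reads([r], 25, adapters=["ACGTACGTACGT"])
        assert out[0].seq == "ACGT"

    def test_truncates_at_first_low_quality_base(self):
        r = _read("ACGTAC", qual=[30, 30, 10, 30, 30, 30])
        out = screen.trim_reads([r], 25)
        assert out[0].seq == "AC"

    def test_empty_reads_dropped(self):
        r = _read("ACGT", qual=[5, 5, 5, 5])
        assert screen.trim_reads([r], 25) == []

    def test_matches_naive_scan_on_simulated_reads(self, rng):
        adapters = ["AGATCGGAAG"]
        reads = []
        for i in range(10000):
            n = int(rng.integers(10, 60))
            seq = "".join(rng.choice(list("ACGT"), size=n))
            if rng.random() < 0.2:  # plant an adapter
                pos = int(rng.integers(0, n))
                seq = seq[:pos] + adapters[0] + seq[pos:]
            qual = [int(q) for q in rng.integers(5, 41, size=len(seq))]
            reads.append(SeqRecord(f"r{i}", seq, quality=qual))
        trimmed = screen.trim_reads(reads, 25, adapters)
        expected = {}
        for r in reads:
            s, q = _naive_trim(r.seq, r.quality, 25, adapters)
            if s:
                expected[r.id] = (s, q)
        assert {(r.id, r.seq) for r in trimmed} == \
               {(k, v[0]) for k, v in expected.items()}


class TestAssignReads:
    TR = [SeqRecord("t1", "ACGTACGTACGTACGTACGTAAATTTCCCGGG"),
          SeqRecord("t2", "TTTTGGGGCCCCAAAATTTTGGGGCCCCAAAA")]

    def test_unique_exact_read_counts_one(self):
        reads = {"s": [_read(self.TR[0].seq[2:22], rid="f/1")]}
        table, rep = screen.assign_reads(self.TR, reads, k=15)
        assert table.counts.loc["t1", "s"] == 1.0
        assert table.counts.loc["t2", "s"] == 0.0

    def test_tie_gives_fractional_credit(self):
        twins = [SeqRecord("a", "ACGTACGTACGTACGTACGTACGT"),
                 SeqRecord("b", "ACGTACGTACGTACGTACGTACGT")]
        reads = {"s": [_read("ACGTACGTACGTACGT", rid="f/1")]}
        table, _ = screen.assign_reads(twins, reads, k=11)
        assert table.counts.loc["a", "s"] == 0.5
        assert table.counts.loc["b", "s"] == 0.5

    def test_unmatched_read_reported(self):
        reads = {"s": [_read("TATATATATATATATA", rid="f/1")]}
        table, rep = screen.assign_reads(self.TR, reads, k=15)
        assert rep.unassigned_fragments == 1
        assert table.counts.to_numpy().sum() == 0.0

    def test_pair_counts_as_one_fragment(self):
        r1 = _read(self.TR[0].seq[:20], rid="f/1")
        r2 = _read(synth.revcomp(self.TR[0].seq[-20:]), rid="f/2")
        table, _ = screen.assign_reads(self.TR, {"s": [r1, r2]}, k=15)
        assert table.counts.loc["t1", "s"] == 1.0

    def test_totals_match_ground_truth_on_error_free_reads(self, benchmark):
        txm = benchmark["txm"]
        table, _ = screen.assign_reads(txm.transcripts, benchmark["reads"], k=21)
        for stage, reads in benchmark["reads"].items():
            truth = {}
            for r in reads:
                if r.id.endswith("/1"):
                    truth[r.id.split(":")[1]] = truth.get(r.id.split(":")[1], 0) + 1
            for tid, n in truth.items():
                assert table.counts.loc[tid, stage] == pytest.approx(n)


class TestContaminationFilter:
    def test_filters_by_host_free_evidence(self, benchmark):
        txm = benchmark["txm"]
        table, _ = screen.assign_reads(txm.transcripts, benchmark["reads"], k=21)
        kept, removed = screen.contamination_filter(
            txm.transcripts, table, benchmark["host_free"])
        labels = benchmark["txm"].truth.labels
        assert {t.id for t in removed} == \
               {t for t, lab in labels.items() if lab == "contaminant"}
        assert all(labels[t.id] != "contaminant" for t in kept)

    def test_missing_stage_errors(self, benchmark):
        txm = benchmark["txm"]
        table, _ = screen.assign_reads(txm.transcripts,
                                       {"attached": benchmark["reads"]["attached"]}, k=21)
        with pytest.raises(ValueError, match="absent"):
            screen.contamination_filter(txm.transcripts, table, ["seedling"])


class TestPredictOrf:
    def test_simple_orf(self):
        orf = screen.predict_orf(SeqRecord("x", "ATGAAATAA"))
        assert orf.protein.seq == "MK" and orf.strand == "+"
        assert (orf.start, orf.end) == (0, 6)

    def test_reverse_strand_symmetry(self):
        fwd = "ATGAAAGGGTTTTAA"
        embedded = "CCCC" + synth.revcomp(fwd) + "GGGG"
        orf = screen.predict_orf(SeqRecord("x", embedded))
        assert orf.protein.seq == "MKGF" and orf.strand == "-"

    def test_forward_preferred_on_tie(self):
        fwd = "ATGAAATAA"          # MK forward
        rev = synth.revcomp("ATGGGGTAA")  # MG on reverse
        seq = fwd + "CC" + rev
        orf = screen.predict_orf(SeqRecord("x", seq))
        assert orf.strand == "+"

    def test_no_atg_flagged(self):
        orf = screen.predict_orf(SeqRecord("x", "CCCAAACCCAAA"))
        assert orf.no_atg

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            screen.predict_orf(SeqRecord("x", "AT"))


class TestLengthGates:
    CFG = ScreenConfig()

    def _gate(self, nt, aa):
        tr = SeqRecord("t", "A" * nt)
        orf = screen.OrfResult(SeqRecord("p", "K" * aa, moltype="protein"),
                               "+", 0, 0, 3 * aa)
        return screen.length_gates(tr, orf, self.CFG)

    def test_boundaries_inclusive(self):
        assert not self._gate(299, 100).passed
        assert self._gate(300, 100).passed
        assert not self._gate(300, 99).passed

    def test_matches_direct_boolean_on_random_cases(self, rng):
        for _ in range(1000):
            nt = int(rng.integers(200, 400))
            aa = int(rng.integers(50, 150))
            got = self._gate(nt, aa).passed
            assert got == (nt >= 300 and aa >= 100)


def _hit(query, subject, bit, lineage):
    return Hit(query, subject, 90.0, 100, bit, 1e-10, lineage)


IN = ["Eukaryota", "Lamiales", "x"]
OUT = ["Eukaryota", "Brassicales", "y"]
CFG = ScreenConfig()


class TestAlienScore:
    def test_ratio_above_threshold_is_candidate(self):
        v = screen.alien_score([_hit("q", "o", 121, OUT), _hit("q", "i", 100, IN)], CFG)
        assert v.ratio == pytest.approx(1.21) and v.is_candidate

    def test_ratio_below_threshold_not_candidate(self):
        v = screen.alien_score([_hit("q", "o", 110, OUT), _hit("q", "i", 100, IN)], CFG)
        assert v.ratio == pytest.approx(1.1) and not v.is_candidate

    def test_threshold_is_strict(self):
        v = screen.alien_score([_hit("q", "o", 120, OUT), _hit("q", "i", 100, IN)], CFG)
        assert not v.is_candidate

    def test_no_ingroup_hit_candidate_with_flag(self):
        v = screen.alien_score([_hit("q", "o", 100, OUT)], CFG)
        assert v.is_candidate and math.isinf(v.ratio)
        assert "no_ingroup_hit" in v.flags

    def test_no_outgroup_hit_never_candidate(self):
        v = screen.alien_score([_hit("q", "i", 100, IN)], CFG)
        assert not v.is_candidate and "no_outgroup_hit" in v.flags

    def test_empty_hits_both_flags(self):
        v = screen.alien_score([], CFG, query_id="q")
        assert not v.is_candidate
        assert v.flags == {"no_ingroup_hit", "no_outgroup_hit"}

    def test_self_hits_removed(self):
        v = screen.alien_score([_hit("q", "q", 500, OUT),
                                _hit("q", "o", 110, OUT),
                                _hit("q", "i", 100, IN)], CFG)
        assert v.ratio == pytest.approx(1.1)

    def test_ratio_invariant_to_common_rescaling(self, rng):
        for _ in range(20):
            bits = rng.uniform(50, 400, size=6)
            hits = [_hit("q", f"s{i}", b, IN if i % 2 else OUT)
                    for i, b in enumerate(bits)]
            scale = float(rng.uniform(0.1, 10))
            scaled = [_hit("q", f"s{i}", b * scale, IN if i % 2 else OUT)
                      for i, b in enumerate(bits)]
            assert screen.alien_score(hits, CFG).ratio == \
                   pytest.approx(screen.alien_score(scaled, CFG).ratio)

    def test_raising_threshold_never_adds_candidates(self, rng):
        for _ in range(50):
            hits = [_hit("q", f"s{i}", float(rng.uniform(30, 300)),
                         IN if rng.random() < 0.5 else OUT) for i in range(8)]
            lo = screen.alien_score(hits, ScreenConfig(ratio_threshold=1.1))
            hi = screen.alien_score(hits, ScreenConfig(ratio_threshold=1.5))
            assert not (hi.is_candidate and not lo.is_candidate)


class TestSisterFilter:
    def test_sister_cdna_hit_removes_candidate(self):
        v = AlienVerdict("q", None, None, 2.0, True)
        sister_lineage = ["Eukaryota", "Lamiales", CFG.sister_taxon_name]
        out = screen.sister_taxon_filter(
            [v], {"q": [_hit("q", "sis", 300, sister_lineage)]}, CFG)
        assert not out[0].is_candidate
        assert "sister_taxon_cdna_hit" in out[0].flags

    def test_donor_cdna_hit_retains_candidate(self):
        v = AlienVerdict("q", None, None, 2.0, True)
        out = screen.sister_taxon_filter([v], {"q": [_hit("q", "d", 300, OUT)]}, CFG)
        assert out[0].is_candidate

    def test_no_cdna_hits_retained(self):
        v = AlienVerdict("q", None, None, 2.0, True)
        out = screen.sister_taxon_filter([v], {}, CFG)
        assert out[0].is_candidate


class TestRunScreen:
    def test_empty_transcriptome_empty_report(self):
        res = screen.run_screen([], {"s": []}, ["s"], {}, None,
                                ScreenConfig(), trim=False)
        assert res.report.empty

    def test_benchmark_recovers_exactly_planted_hgt(self, benchmark):
        cfg = ScreenConfig(sister_taxon_name=benchmark["taxonomy"].sister)
        res = screen.run_screen(benchmark["txm"].transcripts, benchmark["reads"],
                                benchmark["host_free"], benchmark["hits"],
                                benchmark["cdna_hits"], cfg, trim=False)
        truth = {t for t, lab in benchmark["txm"].truth.labels.items() if lab == "hgt"}
        assert set(res.candidates) == truth
        assert len(truth) == 3

    def test_report_deterministic(self, benchmark):
        cfg = ScreenConfig(sister_taxon_name=benchmark["taxonomy"].sister)
        args = (benchmark["txm"].transcripts, benchmark["reads"],
                benchmark["host_free"], benchmark["hits"], benchmark["cdna_hits"])
        a = screen.run_screen(*args, cfg, trim=False).report.to_csv(sep="\t")
        b = screen.run_screen(*args, cfg, trim=False).report.to_csv(sep="\t")
        assert a == b

    def test_report_sorted_by_ratio(self, benchmark):
        cfg = ScreenConfig(sister_taxon_name=benchmark["taxonomy"].sister)
        res = screen.run_screen(benchmark["txm"].transcripts, benchmark["reads"],
                                benchmark["host_free"], benchmark["hits"],
                                benchmark["cdna_hits"], cfg, trim=False)
        ratios = res.report["ratio"].to_numpy()
        assert (np.diff(ratios) <= 1e-12).all()
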