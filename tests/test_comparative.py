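import functools
import itertools

import numpy as np
import pytest

from hgtkit import comparative as cmp, synth
from hgtkit.io import MSA, SeqRecord

MATCH, MISMATCH, OPEN, EXTEND = 2.0, -3.0, -5.0, -2.0


def oracle_global_score(a, b):
    """Independent affine-gap alignment score by memoized recursion.

    Scores the first gap position with the open score and later positions
    with the extend score, matching the aligner's convention.
    """
    @functools.lru_cache(maxsize=None)
    def best(i, j, state):
        # state: 0 diagonal, 1 gap in b (a consumed), 2 gap in a (b consumed)
        if i == len(a) and j == len(b):
            return 0.0
        cands = []
        if i < len(a) and j < len(b):
            s = MATCH if a[i] == b[j] else MISMATCH
            cands.append(s + best(i + 1, j + 1, 0))
        if i < len(a):
            g = EXTEND if state == 1 else OPEN
            cands.append(g + best(i + 1, j, 1))
        if j < len(b):
            g = EXTEND if state == 2 else OPEN
            cands.append(g + best(i, j + 1, 2))
        return max(cands)

    return best(0, 0, 0)


def enumerate_alignments_score(a, b):
    """Score of the best alignment by full enumeration (tiny inputs only)."""
    best = [-np.inf]

    def rec(i, j, cols):
        if i == len(a) and j == len(b):
            score = 0.0
            prev = None
            for x, y in cols:
                if x != "-" and y != "-":
                    score += MATCH if x == y else MISMATCH
                    prev = "d"
                elif y == "-":
                    score += EXTEND if prev == "u" else OPEN
                    prev = "u"
                else:
                    score += EXTEND if prev == "l" else OPEN
                    prev = "l"
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, cols + [(a[i], b[j])])
        if i < len(a):
            rec(i + 1, j, cols + [(a[i], "-")])
        if j < len(b):
            rec(i, j + 1, cols + [("-", b[j])])

    rec(0, 0, [])
    return best[0]


class TestPairwiseAlign:
    def test_identical_global_no_gaps(self):
        aln = cmp.pairwise_align("ACGTACGT", "ACGTACGT")
        assert "-" not in aln.aligned_a and aln.percent_identity == 100.0

    def test_single_gap(self):
        aln = cmp.pairwise_align("ACGT", "ACT")
        assert aln.aligned_a.count("-") + aln.aligned_b.count("-") == 1

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            cmp.pairwise_align("", "ACGT")

    def test_dp_equals_memoized_recursion_oracle(self, rng):
        for _ in range(50):
            a = "".join(rng.choice(list("ACGT"), size=rng.integers(3, 13)))
            b = "".join(rng.choice(list("ACGT"), size=rng.integers(3, 13)))
            assert cmp.pairwise_align(a, b).score == \
                   pytest.approx(oracle_global_score(a, b), abs=1e-8)

    def test_dp_equals_full_enumeration_tiny(self, rng):
        for _ in range(15):
            a = "".join(rng.choice(list("ACGT"), size=rng.integers(2, 7)))
            b = "".join(rng.choice(list("ACGT"), size=rng.integers(2, 7)))
            assert cmp.pairwise_align(a, b).score == \
                   pytest.approx(enumerate_alignments_score(a, b), abs=1e-8)


class TestPercentIdentity:
    def test_simple_fraction(self):
        assert cmp.percent_identity("AAAA", "AAAT") == 75.0

    def test_symmetric(self, rng):
        for _ in range(10):
            a = "".join(rng.choice(list("ACGT"), size=20))
            b = "".join(rng.choice(list("ACGT"), size=20))
            assert cmp.percent_identity(a, b) == cmp.percent_identity(b, a)

    def test_100_iff_identical_same_length(self, rng):
        a = "".join(rng.choice(list("ACGT"), size=30))
        assert cmp.percent_identity(a, a) == 100.0
        b = a[:-1] + ("A" if a[-1] != "A" else "C")
        assert cmp.percent_identity(a, b) < 100.0


class TestBackTranslate:
    def test_single_sequence(self):
        msa = MSA([SeqRecord("x", "MK", moltype="protein")])
        out = cmp.back_translate_alignment(msa, {"x": "ATGAAA"})
        assert out.records[0].seq == "ATGAAA"

    def test_gap_becomes_triple_dash(self):
        msa = MSA([SeqRecord("x", "M-K", moltype="protein"),
                   SeqRecord("y", "MQK", moltype="protein")])
        out = cmp.back_translate_alignment(msa, {"x": "ATGAAA", "y": "ATGCAAAAA"})
        assert out.records[0].seq == "ATG---AAA"

    def test_stop_codon_trimmed(self):
        msa = MSA([SeqRecord("x", "MK", moltype="protein")])
        out = cmp.back_translate_alignment(msa, {"x": "ATGAAATAA"})
        assert out.records[0].seq == "ATGAAA"

    def test_mismatch_reports_sequence_and_position(self):
        msa = MSA([SeqRecord("x", "MK", moltype="protein")])
        with pytest.raises(ValueError, match="x.*residue 1"):
            cmp.back_translate_alignment(msa, {"x": "ATGCCC"})

    def test_translate_of_back_translate_is_identity(self, ref_db):
        from Bio.Seq import Seq
        rng = np.random.default_rng(0)
        for fam in ref_db.families[:20]:
            msa = fam.alignment
            cdna = {}
            for rec in msa.records:
                prot = rec.seq.replace("-", "")
                cdna[rec.id] = synth._reverse_translate(prot, rng)
            codon = cmp.back_translate_alignment(msa, cdna)
            for rec, prot_rec in zip(codon.records, msa.records):
                back = "".join(
                    str(Seq(rec.seq[i:i + 3]).translate()) if rec.seq[i:i + 3] != "---"
                    else "-" for i in range(0, len(rec.seq), 3))
                assert back == prot_rec.seq


class TestTrimAlignment:
    def test_gapless_unchanged(self):
        msa = MSA([SeqRecord("a", "MKL", moltype="protein"),
                   SeqRecord("b", "MQL", moltype="protein")])
        res = cmp.trim_alignment(msa)
        assert res.msa.records[0].seq == "MKL" and res.removed_columns == []

    def test_single_gap_column_removed_strict(self):
        msa = MSA([SeqRecord("a", "M-L", moltype="protein"),
                   SeqRecord("b", "MQL", moltype="protein")])
        res = cmp.trim_alignment(msa)
        assert res.msa.records[0].seq == "ML" and res.removed_columns == [1]

    def test_all_removed_errors(self):
        msa = MSA([SeqRecord("a", "-", moltype="protein"),
                   SeqRecord("b", "Q", moltype="protein")])
        with pytest.raises(ValueError):
            cmp.trim_alignment(msa)

    def test_column_mapping_is_consistent(self, rng):
        for _ in range(10):
            n = int(rng.integers(5, 30))
            rows = []
            for r in range(4):
                row = "".join(rng.choice(list("ACD-"), size=n))
                rows.append(SeqRecord(f"r{r}", row, moltype="protein"))
            try:
                res = cmp.trim_alignment(MSA(rows))
            except ValueError:
                continue
            for old, new in res.old_to_new.items():
                assert res.msa.records[0].seq[new] == rows[0].seq[old]
                assert old not in res.removed_columns


class TestDiagnosticSites:
    def _msa(self, rows, group):
        return MSA([SeqRecord(f"r{i}", s, moltype="protein")
                    for i, s in enumerate(rows)],
                   {"g": [f"r{i}" for i in group]})

    def test_unique_residue_found(self):
        msa = self._msa(["K", "K", "R", "Q", "E"], [0, 1])
        sites = cmp.diagnostic_sites(msa, "g")
        assert len(sites) == 1 and sites[0].kind == "residue"
        assert sites[0].group_state == "K"

    def test_shared_single_column_deletion(self):
        msa = self._msa(["A-C", "A-C", "AQC", "AEC"], [0, 1])
        sites = cmp.diagnostic_sites(msa, "g")
        dels = [s for s in sites if s.kind == "deletion"]
        assert len(dels) == 1 and dels[0].column == 1 and dels[0].length == 1

    def test_residue_shared_outside_not_diagnostic(self):
        msa = self._msa(["K", "K", "K", "Q"], [0, 1])
        assert cmp.diagnostic_sites(msa, "g") == []

    def test_planted_group_specific_columns_recovered(self, rng):
        n = 60
        base = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=n))
        planted = sorted(rng.choice(n, size=5, replace=False))
        rows = []
        for i in range(6):
            row = list(base)
            for p in planted:
                row[p] = "W" if i < 3 else "Y"
            rows.append(SeqRecord(f"r{i}", "".join(row), moltype="protein"))
        msa = MSA(rows, {"g": ["r0", "r1", "r2"]})
        got = [s.column for s in cmp.diagnostic_sites(msa, "g")]
        assert got == list(planted)

    def test_group_covering_all_rows_rejected(self):
        msa = self._msa(["K", "K"], [0, 1])
        with pytest.raises(ValueError):
            cmp.diagnostic_sites(msa, "g")


class TestMapIntrons:
    def test_exact_single_intron(self):
        e1, e2 = "ATGGCCAAATTTGGGCCC", "TTTAAACCCGGGATAGCA"
        intron = "GT" + "C" * 46 + "AG"
        genomic = SeqRecord("g", e1 + intron + e2)
        cdna = SeqRecord("c", e1 + e2)
        st = cmp.map_introns(cdna, genomic)
        assert st.introns == [(len(e1), len(e1) + 50)]
        assert st.gt_ag == [True]
        assert st.intron_positions_in_cdna() == [len(e1)]

    def test_simulated_structures_recovered_exactly(self, ref_db):
        for seed in range(3):
            txm = synth.simulate_recipient_transcriptome(ref_db, seed=seed)
            for gid, g in txm.genomic.items():
                cdna = next(t for t in txm.transcripts if t.id == gid)
                st = cmp.map_introns(cdna, g)
                assert st.introns == txm.truth.intron_positions[gid], gid

    def test_unrelated_sequences_rejected(self, rng):
        a = "".join(rng.choice(list("ACGT"), size=300))
        b = "".join(rng.choice(list("ACGT"), size=400))
        with pytest.raises(ValueError, match="identity"):
            cmp.map_introns(SeqRecord("a", a), SeqRecord("b", b))


class TestCompareStructures:
    def _structure(self, exon_lens, intron_lens, gene="g"):
        exons, introns, pos = [], [], 0
        for i, el in enumerate(exon_lens):
            exons.append((pos, pos + el))
            pos += el
            if i < len(intron_lens):
                introns.append((pos, pos + intron_lens[i]))
                pos += intron_lens[i]
        return cmp.GeneStructure(gene, exons, introns)

    def test_identical_structures_all_shared(self):
        s1 = self._structure([30, 30, 30], [50, 60], "g1")
        s2 = self._structure([30, 30, 30], [50, 60], "g2")
        msa = MSA([SeqRecord("g1", "M" * 30, moltype="protein"),
                   SeqRecord("g2", "M" * 30, moltype="protein")])
        table = cmp.compare_structures({"g1": s1, "g2": s2}, msa,
                                       {"g1": 0, "g2": 0}, "g1")
        assert (table.loc["g2"] == "shared").all()

    def test_missing_last_intron_absent(self):
        s1 = self._structure([30, 30, 30], [50, 60], "g1")
        s2 = self._structure([30, 60], [50], "g2")
        msa = MSA([SeqRecord("g1", "M" * 30, moltype="protein"),
                   SeqRecord("g2", "M" * 30, moltype="protein")])
        table = cmp.compare_structures({"g1": s1, "g2": s2}, msa,
                                       {"g1": 0, "g2": 0}, "g1")
        assert list(table.loc["g2"]) == ["shared", "absent"]

    def test_gene_absent_from_msa_rejected(self):
        s1 = self._structure([30, 30], [50], "g1")
        msa = MSA([SeqRecord("other", "M" * 20, moltype="protein")])
        with pytest.raises(ValueError):
            cmp.compare_structures({"g1": s1}, msa, {"g1": 0}, "g1")

    def test_hgt_genes_share_donor_intron_positions(self, ref_db):
        """Planted foreign genes carry donor-architecture introns at the
        same codon positions in every simulated replicate of the family."""
        t1 = synth.simulate_recipient_transcriptome(ref_db, seed=11)
        t2 = synth.simulate_recipient_transcriptome(ref_db, seed=22)
        for gid in t1.truth.intron_positions:
            if not gid.startswith("hgt"):
                continue
            c1 = t1.truth.cds_span[gid][0]
            c2 = t2.truth.cds_span[gid][0]
            pos1 = [(p - c1) for p in
                    cmp.map_introns(next(t for t in t1.transcripts if t.id == gid),
                                    t1.genomic[gid]).intron_positions_in_cdna()]
            pos2 = [(p - c2) for p in
                    cmp.map_introns(next(t for t in t2.transcripts if t.id == gid),
                                    t2.genomic[gid]).intron_positions_in_cdna()]
            assert [p // 3 for p in pos1] == [p // 3 for p in pos2]


class TestIntronRetention:
    def test_identical_isoforms_no_insertion(self):
        a = SeqRecord("a", "ACGTACGT")
        rep = cmp.detect_intron_retention(a, SeqRecord("b", a.seq))
        assert rep.insert_length is None and not rep.partial_retention

    def test_planted_21nt_block_called_partial_retention(self):
        st = synth.ssl_standins()
        rep = cmp.detect_intron_retention(
            st.isoform_spliced, st.isoform_retained,
            [st.intron_intervals[0][0]])
        assert rep.insert_length == 21 and rep.partial_retention
        assert rep.matched_intron == 0

    def test_multiple_blocks_no_call(self):
        a = SeqRecord("a", "AAAACCCCGGGGTTTT")
        b = SeqRecord("b", "AAAATTTCCCCGGGGAAATTTT")
        rep = cmp.detect_intron_retention(a, b)
        assert not rep.partial_retention and rep.n_differences > 0
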