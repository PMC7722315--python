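"""Backsplice-junction reference construction and read mapping."""

import numpy as np
import pytest

from circscreen.bsjmap import (BsjReference, EclipRead, SampleRole, build_bsj_reference,
                               call_junction_sites, dedup_reads, junction_counts,
                               map_read, revcomp)
from circscreen.intervals import GenomicInterval, TranscriptModel


def make_genome(rng, length=5000):
    return {"chr1": "".join(rng.choice(list("ACGT"), size=length))}


def make_transcript(exon_pairs, strand="+", tx_id="T1"):
    return TranscriptModel(tx_id, "G1", "chr1", strand,
                           [GenomicInterval("chr1", s, e, strand) for s, e in exon_pairs])


class TestReferenceConstruction:
    def test_pair_enumeration_count(self):
        rng = np.random.default_rng(0)
        genome = make_genome(rng)
        for n in (1, 2, 3, 5):
            tx = make_transcript([(i * 200, i * 200 + 100) for i in range(n)])
            refs = build_bsj_reference([tx], genome)
            n_ids = sum(len(r.junction_ids) for r in refs)
            assert n_ids == n * (n + 1) // 2

    def test_sequences_are_2k_donor_then_acceptor(self):
        rng = np.random.default_rng(1)
        genome = make_genome(rng)
        tx = make_transcript([(0, 100), (200, 300)])
        refs = {r.junction_id: r for r in build_bsj_reference([tx], genome, k=30)}
        seq = genome["chr1"]
        # donor exon 2 end + acceptor exon 1 start
        assert refs["T1:2:1"].sequence == seq[270:300] + seq[0:30]
        assert refs["T1:2:1"].junction_offset == 30
        assert all(len(r.sequence) == 60 for r in refs.values())
        # single-exon circle junction exists
        assert "T1:1:1" in refs

    def test_minus_strand_uses_transcript_orientation(self):
        rng = np.random.default_rng(2)
        genome = make_genome(rng)
        tx = make_transcript([(0, 100), (200, 300)], strand="-")
        refs = {r.junction_id: r for r in build_bsj_reference([tx], genome, k=30)}
        seq = genome["chr1"]
        # transcript order on minus strand: exon1 = [200,300) revcomp'd
        exon1 = revcomp(seq[200:300])
        exon2 = revcomp(seq[0:100])
        assert refs["T1:2:1"].sequence == exon2[-30:] + exon1[:30]

    def test_short_exon_truncated_not_padded(self):
        rng = np.random.default_rng(3)
        genome = make_genome(rng)
        tx = make_transcript([(0, 20), (200, 300)])
        refs = {r.junction_id: r for r in build_bsj_reference([tx], genome, k=30)}
        r = refs["T1:1:1"]
        assert r.truncated and r.sequence == genome["chr1"][0:20] * 2
        assert r.junction_offset == 20


def brute_force_hits(seq, refs, max_mismatches, min_span):
    """All-offsets Hamming scan in pure python, both orientations."""
    out = set()
    for orientation, s in (("+", seq), ("-", revcomp(seq))):
        for ref in refs:
            for off in range(0, len(ref.sequence) - len(s) + 1):
                left = ref.junction_offset - off
                right = off + len(s) - ref.junction_offset
                if left < min_span or right < min_span:
                    continue
                mm = sum(a != b for a, b in zip(s, ref.sequence[off:off + len(s)]))
                if mm <= max_mismatches:
                    for jid in ref.junction_ids:
                        out.add((jid, off, orientation))
    return out


class TestMapRead:
    def refs(self, rng, n_tx=4):
        genome = make_genome(rng, 20_000)
        txs = [
            make_transcript(
                [(base + i * 300, base + i * 300 + 120) for i in range(3)],
                tx_id=f"T{t}",
            )
            for t, base in enumerate(range(0, n_tx * 2000, 2000))
        ]
        return build_bsj_reference(txs, genome)

    def test_planted_read_with_five_bp_span_recovered(self):
        rng = np.random.default_rng(4)
        refs = self.refs(rng)
        ref = refs[3]
        read_seq = ref.sequence[20:40]  # 10 bp each side of the junction at offset 30
        read = EclipRead("r1:AAAA", "AAAA", read_seq, SampleRole.IP_REP1)
        hits = map_read(read, refs)
        assert any(h.junction_id == ref.junction_id and h.offset == 20 for h in hits)

    def test_span_floor_rejects_four_bp_overhang(self):
        rng = np.random.default_rng(5)
        refs = self.refs(rng)
        ref = refs[2]
        read = EclipRead("r1:AAAA", "AAAA", ref.sequence[26:46], SampleRole.IP_REP1)
        hits = [h for h in map_read(read, refs) if h.junction_id == ref.junction_id
                and h.offset == 26]
        assert hits == []

    def test_three_mismatches_rejected_two_accepted(self):
        rng = np.random.default_rng(6)
        refs = self.refs(rng)
        ref = refs[1]
        seq = list(ref.sequence[18:42])
        for pos in (0, 5, 11):
            seq[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[pos]]
        bad = EclipRead("r:B", "B", "".join(seq), SampleRole.IP_REP1)
        assert all(h.mismatches > 2 or h.offset != 18 for h in map_read(bad, refs)) \
            or not any(h.offset == 18 and h.junction_id == ref.junction_id
                       for h in map_read(bad, refs))
        seq2 = list(ref.sequence[18:42])
        for pos in (0, 5):
            seq2[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq2[pos]]
        ok = EclipRead("r:B", "B", "".join(seq2), SampleRole.IP_REP1)
        assert any(h.offset == 18 and h.junction_id == ref.junction_id
                   for h in map_read(ok, refs))

    def test_reverse_complement_orientation_found(self):
        rng = np.random.default_rng(7)
        refs = self.refs(rng)
        ref = refs[0]
        read = EclipRead("r:C", "C", revcomp(ref.sequence[22:44]), SampleRole.INPUT)
        assert any(h.orientation == "-" and h.junction_id == ref.junction_id
                   for h in map_read(read, refs))

    def test_too_short_read_yields_no_hits(self):
        rng = np.random.default_rng(8)
        refs = self.refs(rng)
        read = EclipRead("r:D", "D", refs[0].sequence[25:34], SampleRole.IP_REP1)
        assert map_read(read, refs) == []

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(9)
        refs = self.refs(rng, n_tx=4)
        assert len(refs) <= 100
        for _ in range(40):
            ref = refs[int(rng.integers(0, len(refs)))]
            L = int(rng.integers(12, 26))
            off = int(rng.integers(0, len(ref.sequence) - L + 1))
            seq = list(ref.sequence[off:off + L])
            for _ in range(int(rng.integers(0, 4))):  # 0-3 mutations
                pos = int(rng.integers(0, L))
                seq[pos] = str(rng.choice(list("ACGT")))
            read = EclipRead("r:X", "X", "".join(seq), SampleRole.IP_REP1)
            got = {(h.junction_id, h.offset, h.orientation) for h in map_read(read, refs)}
            assert got == brute_force_hits("".join(seq), refs, 2, 5)


def hit(read_id, barcode, jid, offset, role=SampleRole.IP_REP1):
    from circscreen.bsjmap import JunctionHit

    return JunctionHit(read_id, barcode, role, jid, offset, "+", 0)


class TestDedup:
    def test_same_barcode_and_position_collapsed(self):
        hits = [hit("r1", "A", "j", 100), hit("r2", "A", "j", 100), hit("r3", "B", "j", 100)]
        assert len(dedup_reads(hits)) == 2

    def test_different_offsets_kept(self):
        hits = [hit("r1", "A", "j", 100), hit("r2", "A", "j", 101)]
        assert len(dedup_reads(hits)) == 2

    def test_idempotent_and_order_insensitive(self):
        rng = np.random.default_rng(10)
        hits = [hit(f"r{i}", str(rng.integers(0, 4)), "j", int(rng.integers(0, 5)))
                for i in range(40)]
        once = dedup_reads(hits)
        assert dedup_reads(once) == once
        shuffled = [hits[i] for i in rng.permutation(len(hits))]
        assert len(dedup_reads(shuffled)) == len(once)

    def test_empty(self):
        assert dedup_reads([]) == []


class TestJunctionCalls:
    def counts(self, rep1, rep2, inp):
        import pandas as pd

        return pd.DataFrame([{"junction_id": "j", "IP_rep1": rep1, "IP_rep2": rep2,
                              "input": inp}])

    @pytest.mark.parametrize("rep1,rep2,inp,called", [
        (15, 15, 1, True),    # log2(16/2)=3.0 in both
        (15, 9, 0, False),    # replicate read floor
        (100, 100, 40, False),  # log2(101/41)~1.3
    ])
    def test_thresholds(self, rep1, rep2, inp, called):
        out = call_junction_sites(self.counts(rep1, rep2, inp))
        assert bool(out["called"].iloc[0]) == called

    def test_missing_replicate_column_rejected(self):
        import pandas as pd

        with pytest.raises(ValueError):
            call_junction_sites(pd.DataFrame([{"junction_id": "j", "IP_rep1": 5, "input": 0}]))

    def test_counts_from_dedup_hits(self):
        hits = [hit("r1", "A", "j1", 1), hit("r2", "B", "j1", 2),
                hit("r3", "C", "j1", 1, SampleRole.INPUT)]
        table = junction_counts(dedup_reads(hits)).set_index("junction_id")
        assert table.loc["j1", "IP_rep1"] == 2
        assert table.loc["j1", "input"] == 1
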