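"""uORF discovery, self-duplication scanning and the exon-shuffling signature."""

import math

import numpy as np
import pytest

from utrapa import (
    TranscriptModel,
    find_uorfs,
    frame_usage,
    intron_margin_check,
    make_genome,
    plant_duplication,
    self_duplication_scan,
    stop_codon_origin,
)
from utrapa.uorf_evolution import DuplicationReport

STOPS = {"TAA", "TAG", "TGA"}


def _oracle_uorfs(seq, min_peptide_len=2):
    """Independent pattern scan: every ATG, walk codons to the first stop."""
    out = []
    seq = seq.upper()
    for i in range(len(seq) - 2):
        if seq[i : i + 3] != "ATG":
            continue
        j = i + 3
        stop = None
        while j + 3 <= len(seq):
            if seq[j : j + 3] in STOPS:
                stop = j
                break
            j += 3
        if stop is not None:
            n_pep = (stop - i) // 3
            end = stop + 3
        else:
            n_pep = (len(seq) - i) // 3
            end = i + 3 * n_pep
        if n_pep >= min_peptide_len:
            out.append((i + 1, end, i % 3 + 1, stop is not None))
    return out


class TestFindUorfs:
    def test_hand_decodable(self):
        (u,) = find_uorfs("ATGAAATAA")
        assert (u.start, u.end, u.frame, u.peptide, u.has_stop) == (1, 9, 1, "MK", True)

    def test_no_atg(self):
        assert find_uorfs("CCCTTTGGGCCC") == []

    def test_matches_pattern_scan_oracle_on_random_sequences(self):
        rng = np.random.default_rng(10)
        for _ in range(30):
            seq = "".join(rng.choice(list("ACGT"), 300))
            got = [(u.start, u.end, u.frame, u.has_stop) for u in find_uorfs(seq)]
            assert got == _oracle_uorfs(seq)

    def test_stop_codon_bookkeeping(self):
        for u in find_uorfs("".join(np.random.default_rng(3).choice(list("ACGT"), 300))):
            if u.has_stop:
                assert (u.end - u.start + 1) % 3 == 0
                assert len(u.peptide) == (u.end - u.start + 1) // 3 - 1


def test_frame_usage():
    uorfs = find_uorfs("ATGAAATAA" + "CC" + "ATGCCCTGTTAG")
    usage = frame_usage(uorfs)
    assert usage["distinct_frames"] is True
    single = frame_usage(find_uorfs("ATGAAATAA"))
    assert single["distinct_frames"] is False


class TestSelfDuplicationScan:
    def test_identity_case(self):
        rng = np.random.default_rng(5)
        x = "".join(rng.choice(list("ACGT"), 100))
        rep = self_duplication_scan(x, x)
        assert rep.percent_identity == 100.0
        assert rep.n_columns == 100

    def test_self_scan_is_100_for_any_long_sequence(self):
        rng = np.random.default_rng(6)
        for n in (50, 75, 300):
            x = "".join(rng.choice(list("ACGT"), n))
            rep = self_duplication_scan(x, x)
            assert rep.percent_identity == 100.0

    def test_symmetric_under_swap(self, dup_world):
        world, entry = dup_world
        utr, morf = world.duplication_sequences(entry.gene_id)
        a = self_duplication_scan(utr, morf)
        b = self_duplication_scan(morf, utr, window_5prime=10_000)
        assert a.percent_identity == pytest.approx(b.percent_identity)
        assert a.n_columns == b.n_columns

    def test_degenerate_input(self):
        assert self_duplication_scan("ACGT", "ACGT") is None

    def test_planted_duplication_is_exactly_recovered(self, dup_world):
        world, entry = dup_world
        utr, morf = world.duplication_sequences(entry.gene_id)
        rep = self_duplication_scan(utr, morf)
        # mask-count oracle: identity = 100 * (1 - |mask| / L)
        expected = 100.0 * (entry.tract_len - len(entry.substitution_mask)) / entry.tract_len
        assert rep.percent_identity == expected == 69.0
        assert rep.utr_interval == entry.tract_utr_interval

    @pytest.mark.parametrize("rate", [0.1, 0.3])
    def test_planted_identity_recovery_across_rates(self, rate):
        world = make_genome(6, seed=21)
        host = next(g.gene_id for g in world.genes if g.gene_id in world.slots)
        plant_duplication(world, host, identity_target=1 - rate, seed=22)
        utr, morf = world.duplication_sequences(host)
        rep = self_duplication_scan(utr, morf)
        assert abs(rep.percent_identity - 100 * (1 - rate)) <= 2.0


class TestStopCodonOrigin:
    def test_planted_substitution_pair_recovered_exactly(self, dup_world):
        world, entry = dup_world
        utr, morf = world.duplication_sequences(entry.gene_id)
        rep = self_duplication_scan(utr, morf)
        uorfs = find_uorfs(utr)
        subs = stop_codon_origin(rep, uorfs, utr, morf)
        assert sorted((s.morf_codon, s.uorf_codon) for s in subs) == [
            ("TAC", "TAA"),
            ("TGA", "TAA"),
        ]
        assert not any(s.indeterminate for s in subs)

    def test_identical_codons_are_not_substitutions(self):
        # perfect duplication: uORF stop aligns to an identical mORF codon
        core = "ATGCCTCGTCCGCATCCGTAA"
        pad = "CCGGTTCCGGTTCCGGTTCCGGTTCCGGTTCCGGTT"
        seq = pad + core + pad
        rep = self_duplication_scan(seq, seq)
        subs = stop_codon_origin(rep, find_uorfs(seq), seq, seq)
        assert subs == []


class TestIntronMargin:
    def _report(self, utr_end):
        return DuplicationReport(
            utr_interval=(1, utr_end),
            morf_interval=(1, utr_end),
            percent_identity=100.0,
            n_columns=utr_end,
            n_matches=utr_end,
            trace=[(i, i) for i in range(utr_end)],
        )

    def _transcript(self, intron_start, intron_len=100):
        exons = [(0, intron_start), (intron_start + intron_len, intron_start + intron_len + 500)]
        return TranscriptModel("t", "c", "+", exons, None)

    @pytest.mark.parametrize(
        "offset,expected_flag", [(0, True), (30, True), (31, False)]
    )
    def test_tolerance_boundary(self, offset, expected_flag):
        tract_end = 200
        t = self._transcript(intron_start=tract_end + offset)
        flag, dist = intron_margin_check(self._report(tract_end), t, tolerance_nt=30)
        assert flag is expected_flag
        assert dist == offset

    def test_intronless_gene(self):
        t = TranscriptModel("t", "c", "+", [(0, 1000)], None)
        flag, dist = intron_margin_check(self._report(200), t)
        assert flag is False and math.isinf(dist)

    def test_planted_offset_recovered(self, dup_world):
        world, entry = dup_world
        utr, morf = world.duplication_sequences(entry.gene_id)
        rep = self_duplication_scan(utr, morf)
        from utrapa import longest_transcript

        t = longest_transcript(world.gene(entry.gene_id))
        flag, dist = intron_margin_check(rep, t)
        assert flag is True
        assert dist == entry.intron_offset
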