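"""Editor registry, PAM matching, protospacer enumeration, guide search."""

from itertools import product

import numpy as np
import pytest

from bemux.guide_design import (
    BAD_CONTEXT,
    LOW_POSITION,
    OUTSIDE_CORE_WINDOW,
    EditorSpec,
    GuideCandidate,
    default_registry,
    efficiency_flags,
    enumerate_protospacers,
    find_guides,
    find_guides_for_changes,
    match_pam,
    registry_by_name,
)
from bemux.seqmodel import CodingChange, ProteinChange, Transcript, reverse_complement

from conftest import random_transcript
from oracles import oracle_guides, oracle_placements


class TestRegistry:
    def test_pam_variants(self, registry_map):
        assert registry_map["SaKKH-CBE"].pam == "NNNRRT"
        assert registry_map["SpRY-CBE"].pam == "NAN"
        assert registry_map["SpCas9-CBE"].pam == "NGG"
        assert registry_map["SpCas9-NG-ABE"].pam == "NG"
        assert registry_map["SpCas9-NGT-CBE"].pam == "NGT"
        assert registry_map["SaCas9-ABE"].pam == "NNGRRT"

    def test_every_entry_uses_the_canonical_window(self, registry):
        for e in registry:
            assert e.window == (4, 8)
            assert e.extended_window == (3, 9)

    def test_spacer_lengths_by_homolog(self, registry):
        for e in registry:
            assert e.spacer_len == (20 if e.homolog == "Sp" else 21)

    def test_both_chemistries_per_variant(self, registry):
        names = {e.name for e in registry}
        for base in ("SpCas9", "SpRY", "SaKKH", "SaCas9"):
            assert f"{base}-CBE" in names and f"{base}-ABE" in names

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            EditorSpec("X", "Sp", "CBE", "NQG", 20)
        with pytest.raises(ValueError):
            EditorSpec("X", "Sp", "CBE", "NGG", 20, window=(4, 25))


class TestMatchPam:
    @pytest.mark.parametrize(
        "seq,pattern,expected",
        [
            ("AGG", "NGG", True),
            ("TGC", "NGG", False),
            ("TAT", "NAN", True),
            ("TTT", "NAN", False),
            ("TTGAGT", "NNGRRT", True),
        ],
    )
    def test_examples(self, seq, pattern, expected):
        assert match_pam(seq, pattern) is expected

    def test_nngrrt_against_full_expansion(self):
        # brute-force the full set of matching hexamers and check membership
        matching = {
            "".join(h)
            for h in product("ACGT", repeat=6)
            if h[2] == "G" and h[3] in "AG" and h[4] in "AG" and h[5] == "T"
        }
        for h in ("".join(x) for x in product("ACGT", repeat=6)):
            assert match_pam(h, "NNGRRT") is (h in matching)

    def test_length_mismatch_and_bad_pattern(self):
        with pytest.raises(ValueError):
            match_pam("AG", "NGG")
        with pytest.raises(ValueError):
            match_pam("AGG", "NQG")


class TestEnumerateProtospacers:
    def test_too_short_sequence(self, registry_map):
        assert enumerate_protospacers("ACGT" * 5, registry_map["SpCas9-CBE"]) == []

    def test_single_possible_offset(self, registry_map):
        seq = "T" * 20 + "AGG"
        hits = enumerate_protospacers(seq, registry_map["SpCas9-CBE"])
        assert len(hits) == 1
        assert hits[0].start == 1 and hits[0].pam_seq == "AGG"

    def test_matches_sliding_window_oracle(self, rng, registry):
        for _ in range(5):
            seq = "".join("ACGT"[i] for i in rng.integers(4, size=200))
            for editor in registry:
                got = [(p.start, p.spacer, p.pam_seq) for p in enumerate_protospacers(seq, editor)]
                assert got == oracle_placements(seq, editor.spacer_len, editor.pam)


def kras_like_context():
    """30-nt sense context: GGT codon with a TGT PAM so the antisense
    protospacer covers the codon at window offsets around 5-7."""
    # antisense protospacer: PAM 'TGT' on antisense = 'ACA' on sense, 5' of
    # the edited G's.  Layout (sense): [pad 3] ACA [20-nt spacer span] [pad]
    # GGT codon placed so its G's sit at antisense window offsets 5-6.
    # sense positions: 1-3 pad, 4-6 'ACA' (-> TGT PAM on antisense),
    # 7-18 filler, 19-21 GGT (codon 7), 22-30 filler.  The antisense
    # protospacer starts at antisense position 5; the codon's Gs land at
    # window offsets 7 and 8.
    cds = "TTT" + "ACA" + "T" * 12 + "GGT" + "T" * 9
    assert len(cds) == 30
    return Transcript("KRASLIKE", cds, role="oncogene")


class TestFindGuides:
    def test_transversion_has_no_chemistry(self, kras, registry):
        # C>G is neither a CBE nor an ABE product: no candidates, no error
        pos = kras.cds.index("C") + 1
        assert find_guides(CodingChange(pos, "C", "G"), kras, registry) == []

    def test_planted_kras_codon_g12s_vs_g12n(self, registry_map):
        t = kras_like_context()
        editors = [registry_map["SpCas9-NG-CBE"], registry_map["SpCas9-NGT-CBE"]]
        residue = 7  # GGT codon (positions 19-21)
        assert t.codon(residue) == "GGT"
        one = find_guides(ProteinChange(residue, "G", "S"), t, editors)
        two = find_guides(ProteinChange(residue, "G", "N"), t, editors)
        assert one and two
        assert all(len(c.target_offsets) == 1 for c in one)
        assert all(len(c.target_offsets) == 2 for c in two)
        assert {c.strand for c in one + two} == {"antisense"}
        # same placements serve both edits
        assert {(c.editor, c.protospacer_start) for c in one} == {
            (c.editor, c.protospacer_start) for c in two
        }

    def test_candidates_reextract_from_transcript(self, rng, registry):
        for seed in range(10):
            t = random_transcript(np.random.default_rng(seed))
            c_positions = [i + 1 for i, b in enumerate(t.cds) if b == "C"][:3]
            for pos in c_positions:
                for cand in find_guides(CodingChange(pos, "C", "T"), t, registry):
                    ctx = t.context
                    sseq = ctx if cand.strand == "sense" else reverse_complement(ctx)
                    s = cand.protospacer_start
                    assert sseq[s - 1 : s - 1 + len(cand.spacer)] == cand.spacer
                    assert sseq[
                        s - 1 + len(cand.spacer) : s - 1 + len(cand.spacer) + len(cand.pam_seq)
                    ] == cand.pam_seq

    def test_strand_symmetry(self, registry):
        # a sense C>T design equals the mirrored G>A design on the
        # reverse-complemented transcript, with strands swapped
        rng = np.random.default_rng(11)
        for _ in range(5):
            t = random_transcript(rng)
            rc_seq = reverse_complement(t.context)
            rc = Transcript("RC", rc_seq, frame_offset=len(rc_seq) % 3)
            n = len(t.context)
            c_pos = [i + 1 for i, b in enumerate(t.cds) if b == "C"][:3]
            for pos in c_pos:
                fwd = find_guides(CodingChange(pos, "C", "T"), t, registry)
                ctx_pos = t.cds_to_context(pos)
                mirrored_pos = n - ctx_pos + 1
                rev = find_guides(CodingChange(mirrored_pos, "G", "A"), rc, registry)
                flip = {"sense": "antisense", "antisense": "sense"}
                assert {(c.editor, flip[c.strand], c.spacer, c.pam_seq) for c in fwd} == {
                    (c.editor, c.strand, c.spacer, c.pam_seq) for c in rev
                }

    def test_extended_window_is_superset(self, registry):
        rng = np.random.default_rng(5)
        for _ in range(10):
            t = random_transcript(rng)
            pos = next((i + 1 for i, b in enumerate(t.cds) if b == "C"), None)
            if pos is None:
                continue
            core = find_guides(CodingChange(pos, "C", "T"), t, registry, allow_extended=False)
            ext = find_guides(CodingChange(pos, "C", "T"), t, registry, allow_extended=True)
            key = lambda cs: {(c.editor, c.strand, c.protospacer_start) for c in cs}
            assert key(core) <= key(ext)

    def test_matches_brute_force_oracle(self, registry):
        rng = np.random.default_rng(99)
        for _ in range(20):
            t = random_transcript(rng, n_codons=20)
            for ref, alt in (("C", "T"), ("G", "A"), ("A", "G"), ("T", "C")):
                positions = [i + 1 for i, b in enumerate(t.cds) if b == ref][:2]
                for pos in positions:
                    cc = CodingChange(pos, ref, alt)
                    for editor in registry:
                        got = {
                            (c.strand, c.protospacer_start)
                            for c in find_guides_for_changes([cc], t, [editor])
                        }
                        want = oracle_guides(
                            [(pos, ref, alt)], t.context, len(t.up_flank), editor, False
                        )
                        assert got == want


class TestEfficiencyFlags:
    def make(self, spacer, offsets):
        return GuideCandidate(
            editor="SpCas9-CBE",
            spacer=spacer,
            strand="sense",
            protospacer_start=1,
            pam_seq="AGG",
            target_offsets=frozenset(offsets),
            substrate_offsets=frozenset(offsets),
        )

    def test_position3_flags_low_and_outside(self):
        flags = efficiency_flags(self.make("TTCTTTTTTTTTTTTTTTTT", {3}))
        assert flags == {LOW_POSITION, OUTSIDE_CORE_WINDOW}

    def test_benign_position_and_context(self):
        flags = efficiency_flags(self.make("TTTTTCATTTTTTTTTTTTT", {6}))
        assert flags == frozenset()

    def test_position8_in_acg_context(self):
        # offset 8 target with protospacer trinucleotide ACG around it
        flags = efficiency_flags(self.make("TTTTTTACGTTTTTTTTTTT", {8}))
        assert flags == {LOW_POSITION, BAD_CONTEXT}
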