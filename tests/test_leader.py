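"""uAUG discovery, Kozak classification and uORF geometry."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from magscan import (
    InputError,
    LeaderSequence,
    annotate,
    annotation_table,
    classify_context,
    find_uaugs,
    gc_content,
)

PUR = {"A", "G"}


def _leader(bases, main_start, id="t"):
    return LeaderSequence(id, bases, main_start)


class TestLeaderSequence:
    def test_t_normalized_to_u(self):
        ldr = _leader("GGATGCCATGG", 8)
        assert "T" not in ldr.bases
        assert ldr.codon(8) == "AUG"

    def test_bad_alphabet_names_position(self):
        with pytest.raises(InputError, match="position 3"):
            _leader("GGXAUGCC", 4)

    def test_main_start_must_be_aug(self):
        with pytest.raises(InputError, match="main_start"):
            _leader("GGGAUGCC", 2)

    def test_main_start_bounds(self):
        with pytest.raises(InputError):
            _leader("AUG", 5)


class TestFindUaugs:
    def test_no_upstream_aug(self):
        assert find_uaugs(_leader("CCCCCCAUGCC", 7)) == []

    def test_exhaustive_scan_example(self):
        # brute-force oracle over the printed toy sequence
        ldr = _leader("GGAUGCCAUGG", 8)
        oracle = [
            p for p in range(1, ldr.main_start)
            if ldr.bases[p - 1 : p + 2] == "AUG"
        ]
        assert find_uaugs(ldr) == oracle == [3]

    def test_trpm7_fixture_has_two_uaugs(self, trpm7_leader):
        assert len(find_uaugs(trpm7_leader)) == 2

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        prefix=st.text(alphabet="ACGT", min_size=6, max_size=80),
        suffix=st.text(alphabet="ACGT", min_size=3, max_size=30),
    )
    def test_property_matches_triplet_oracle(self, prefix, suffix):
        bases = prefix + "ATG" + suffix
        main = len(prefix) + 1
        ldr = _leader(bases, main)
        oracle = [
            p for p in range(1, main)
            if ldr.bases[p - 1 : p + 2] == "AUG"
        ]
        assert find_uaugs(ldr) == oracle

    def test_random_sequences_match_triplet_oracle(self, rng):
        bases = "ACGU"
        for _ in range(25):
            n = int(rng.integers(30, 120))
            seq = list(rng.choice(list(bases), size=n))
            main = int(rng.integers(10, n - 2))
            seq[main - 1 : main + 2] = list("AUG")
            ldr = _leader("".join(seq), main)
            oracle = [
                p for p in range(1, main)
                if ldr.bases[p - 1 : p + 2] == "AUG"
            ]
            assert find_uaugs(ldr) == oracle


class TestClassifyContext:
    @pytest.mark.parametrize("m3", list("ACGU"))
    @pytest.mark.parametrize("p4", list("ACGU"))
    def test_all_sixteen_pairs(self, m3, p4):
        # purine at both critical positions -> strong; pyrimidine at
        # both -> weak; mixed -> adequate
        ldr = _leader(f"GG{m3}GGAUG{p4}GG" + "CCCAUGCC", 15)
        ctx = classify_context(ldr, 6)
        expected = (
            "strong" if m3 in PUR and p4 in PUR
            else "weak" if m3 not in PUR and p4 not in PUR
            else "adequate"
        )
        assert (ctx.minus3, ctx.plus4, ctx.cls) == (m3, p4, expected)

    def test_paper_strong_example(self):
        ctx = classify_context(_leader("GGAGGAUGAGGCCCAUGCC", 15), 6)
        assert ctx.cls == "strong"

    def test_uaug2_suboptimal_context_is_adequate(self):
        ctx = classify_context(_leader("GGUGGAUGGGGCCCAUGCC", 15), 6)
        assert (ctx.minus3, ctx.plus4) == ("U", "G")
        assert ctx.cls == "adequate"

    def test_padding_counts_as_non_matching(self):
        # AUG at position 1: -3 is an N pad; +4 pyrimidine -> weak
        ctx = classify_context(_leader("AUGCCCAUGCC", 7), 1)
        assert ctx.minus3 == "N"
        assert ctx.window.startswith("NNNNNN")
        assert ctx.cls == "weak"

    def test_window_centers_on_aug(self, trpm7_leader):
        ctx = classify_context(trpm7_leader, 101)
        assert ctx.window[6:9] == "AUG"
        assert len(ctx.window) == 10

    def test_non_aug_position_rejected(self):
        with pytest.raises(InputError, match="not an AUG"):
            classify_context(_leader("GGGAUGCC", 4), 2)


class TestAnnotate:
    def test_uorf1_geometry(self, trpm7_annotation):
        u1 = trpm7_annotation.uorfs[0]
        assert u1.start == 101
        assert u1.length_nt == 390
        assert u1.overlaps_main and u1.overlap_nt == 206
        assert u1.gap_to_main is None
        assert u1.context.cls == "strong"

    def test_uorf2_geometry(self, trpm7_annotation):
        u2 = trpm7_annotation.uorfs[1]
        assert u2.length_nt == 63
        assert not u2.overlaps_main and u2.overlap_nt == 0
        assert u2.gap_to_main == 5
        assert u2.context.cls == "adequate"

    def test_uaugs_out_of_frame(self, trpm7_annotation):
        frames = [u.frame_vs_main for u in trpm7_annotation.uorfs]
        assert 0 not in frames and frames[0] != frames[1]

    def test_all_a_leader_is_empty(self):
        ldr = _leader("A" * 30 + "AUG" + "A" * 6, 31)
        ann = annotate(ldr)
        assert ann.uorfs == () and ann.gc_fraction == 0.0

    def test_t_u_invariance(self, rng):
        for _ in range(10):
            n = int(rng.integers(40, 100))
            seq = list(rng.choice(list("ACGU"), size=n))
            main = int(rng.integers(12, n - 5))
            seq[main - 1 : main + 2] = list("AUG")
            rna = "".join(seq)
            dna = rna.replace("U", "T")
            a, b = annotate(_leader(rna, main)), annotate(_leader(dna, main))
            assert [(u.start, u.length_nt, u.context.cls) for u in a.uorfs] \
                == [(u.start, u.length_nt, u.context.cls) for u in b.uorfs]

    def test_overlap_flag_matches_bruteforce(self, rng):
        stops = {"UAA", "UAG", "UGA"}
        for _ in range(20):
            n = int(rng.integers(60, 150))
            seq = list(rng.choice(list("ACGU"), size=n))
            main = int(rng.integers(20, n - 5))
            seq[main - 1 : main + 2] = list("AUG")
            ann = annotate(_leader("".join(seq), main))
            s = ann.leader.bases
            for u in ann.uorfs:
                stop = next(
                    (p for p in range(u.start + 3, len(s) - 1, 3)
                     if s[p - 1 : p + 2] in stops),
                    None,
                )
                expected = stop is None or stop + 2 >= main
                assert u.overlaps_main == expected

    def test_annotation_table_layout(self, trpm7_annotation):
        tbl = annotation_table([trpm7_annotation])
        assert list(tbl["length_nt"]) == [390, 63]
        assert set(tbl["cls"]) == {"strong", "adequate"}


class TestGcContent:
    def test_all_gc(self):
        assert gc_content(_leader("GCGCAUGCC", 5)) == 1.0

    def test_no_gc(self):
        assert gc_content(_leader("AUAUAUGCC", 5)) == 0.0

    def test_matches_character_count_oracle(self, rng):
        seq = list(rng.choice(list("ACGU"), size=200))
        seq[199:202] = list("AUG")
        ldr = _leader("".join(seq) + "CC", 200)
        region = ldr.bases[:199]
        assert gc_content(ldr) == pytest.approx(
            (region.count("G") + region.count("C")) / 199
        )

    def test_empty_leader_region_rejected(self):
        with pytest.raises(InputError):
            gc_content(_leader("AUGCC", 1))
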