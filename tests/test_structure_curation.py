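"""Folding against exhaustive enumeration; conservation and curation rules."""

import numpy as np
import pytest

from mirseed.errors import ContractError, ValidationError
from mirseed.io_formats import FamilyAlignment
from mirseed.structure_curation import (
    ALLOWED_PAIRS,
    CurationParams,
    HairpinStructure,
    align_candidate,
    classify_hairpin,
    conservation_profile,
    curate,
    fold_max_pairing,
    mature_conservation_score,
)


def enumerate_all_structures(seq, min_loop=3, allowed=ALLOWED_PAIRS):
    """Independent oracle: explicitly enumerate every nested structure of a
    short sequence and yield its pair set."""

    def rec(lo, hi):
        if lo >= hi:
            yield frozenset()
            return
        yield from rec(lo + 1, hi)  # lo unpaired
        for j in range(lo + min_loop + 1, hi):
            if seq[lo] + seq[j] in allowed:
                for inner in rec(lo + 1, j):
                    for outer in rec(j + 1, hi):
                        yield inner | outer | {(lo, j)}

    return rec(0, len(seq))


def brute_force_max_pairs(seq, min_loop=3):
    return max(len(s) for s in enumerate_all_structures(seq, min_loop))


def _structure_is_valid(structure, min_loop=3):
    taken = set()
    for i, j in structure.pairs:
        assert structure.sequence[i] + structure.sequence[j] in ALLOWED_PAIRS
        assert j - i - 1 >= min_loop
        assert i not in taken and j not in taken
        taken |= {i, j}
    # nested (non-crossing)
    for a, b in structure.pairs:
        for c, d in structure.pairs:
            assert not (a < c < b < d)


class TestFoldMaxPairing:
    def test_canonical_triplet_hairpin(self):
        s = fold_max_pairing("GGGAAACCC", min_loop=3)
        assert s.n_pairs == 3
        assert s.dot_bracket == "(((...)))"
        assert s.n_pairs == brute_force_max_pairs("GGGAAACCC")

    def test_unpairable_sequence_stays_open(self):
        s = fold_max_pairing("AAAAAA")
        assert s.n_pairs == 0
        assert s.dot_bracket == "......"

    def test_invalid_alphabet_rejected(self):
        with pytest.raises(ValidationError):
            fold_max_pairing("ACGTX")

    def test_matches_exhaustive_enumeration_on_random_short_sequences(self):
        rng = np.random.default_rng(42)
        letters = np.array(list("ACGU"))
        for _ in range(120):
            n = int(rng.integers(6, 13))
            seq = "".join(rng.choice(letters, size=n))
            s = fold_max_pairing(seq)
            assert s.n_pairs == brute_force_max_pairs(seq), seq
            _structure_is_valid(s)

    def test_n_never_pairs(self):
        s = fold_max_pairing("GGGNNNNCCC")
        # N cannot pair, G-C pairs across still possible
        for i, j in s.pairs:
            assert "N" not in (s.sequence[i], s.sequence[j])

    def test_traceback_is_deterministic(self):
        seq = "GCGCAAAGCGCAAAGCGC"
        assert fold_max_pairing(seq).dot_bracket == fold_max_pairing(seq).dot_bracket


class TestClassifyHairpin:
    def test_perfect_stem_accepted(self):
        seq = "G" * 20 + "AAAA" + "C" * 20
        s = fold_max_pairing(seq)
        ok, reasons = classify_hairpin(s)
        assert ok and reasons == []
        assert s.loop_size == 4 and s.n_stem_loops == 1

    def test_two_stem_cloverleaf_rejected(self):
        db = "((((....))))((((....))))"
        pairs = [(i, 11 - i) for i in range(4)] + [(12 + i, 23 - i) for i in range(4)]
        s = HairpinStructure(sequence="A" * 24, dot_bracket=db, pairs=pairs)
        params = CurationParams(min_stem_pairs=4, min_paired_fraction=0.3)
        ok, reasons = classify_hairpin(s, params)
        assert not ok
        assert any("multiple stems" in r for r in reasons)

    def test_generated_precursor_passes(self, toy_family):
        s = fold_max_pairing(toy_family.consensus)
        ok, reasons = classify_hairpin(s)
        assert ok, reasons
        assert s.n_pairs >= 18  # 14-pair minimum plus the generator's margin

    def test_too_few_pairs_reported(self):
        s = fold_max_pairing("GGGAAACCC")
        ok, reasons = classify_hairpin(s)
        assert not ok
        assert any("too few pairs" in r for r in reasons)


class TestConservationProfile:
    def _aln(self, cols):
        rows = [(f"s{i}", "".join(col[i] for col in cols)) for i in range(len(cols[0]))]
        return FamilyAlignment(family_id="F", rows=rows)

    def test_hand_computed_columns(self):
        aln = self._aln([["A", "A", "A", "A"], ["A", "A", "G", "-"], ["-", "-", "-", "-"]])
        profile = conservation_profile(aln)
        assert profile[0] == 1.0
        assert profile[1] == pytest.approx(2 / 3)
        assert profile[2] == 0.0

    def test_single_row_is_contract_error(self):
        with pytest.raises(ContractError):
            conservation_profile(FamilyAlignment(family_id="F", rows=[("a", "ACGU")]))

    def test_invariant_under_row_reordering(self, toy_family):
        aln = toy_family.alignment
        reordered = FamilyAlignment(
            family_id=aln.family_id, rows=list(reversed(aln.rows)), arm_spans=aln.arm_spans
        )
        assert conservation_profile(aln) == conservation_profile(reordered)


class TestMatureConservation:
    def test_identity_and_mismatch_scores(self, toy_family):
        aln = toy_family.alignment
        spans = dict((label, (s, e)) for label, s, e in aln.arm_spans[aln.rows[0][0]])
        start, end = spans["mature"]
        # a candidate equal to the modal character everywhere scores 1.0
        modal_row = []
        for col in range(aln.length):
            from mirseed.structure_curation import _modal_char

            modal_row.append(_modal_char(aln.column(col)) or "A")
        perfect = FamilyAlignment(
            family_id=aln.family_id,
            rows=aln.rows + [("cand", "".join(modal_row))],
            arm_spans=aln.arm_spans,
        )
        assert mature_conservation_score(perfect, "cand", "mature") == 1.0
        # two mismatches over the 22-column mature span
        mutated = list(modal_row)
        for col in (start, start + 1):
            mutated[col] = "G" if mutated[col] != "G" else "C"
        two_off = FamilyAlignment(
            family_id=aln.family_id,
            rows=aln.rows + [("cand", "".join(mutated))],
            arm_spans=aln.arm_spans,
        )
        score = mature_conservation_score(two_off, "cand", "mature")
        assert score == pytest.approx((end - start - 2) / (end - start))

    def test_all_gap_candidate_scores_zero(self, toy_family):
        aln = toy_family.alignment
        gapped = FamilyAlignment(
            family_id=aln.family_id,
            rows=aln.rows + [("cand", "-" * aln.length)],
            arm_spans=aln.arm_spans,
        )
        assert mature_conservation_score(gapped, "cand", "mature") == 0.0

    def test_family_without_arm_annotation_is_contract_error(self):
        aln = FamilyAlignment(
            family_id="F", rows=[("a", "ACGUACGU"), ("b", "ACGUACGU"), ("c", "ACGUACGU")]
        )
        with pytest.raises(ContractError):
            mature_conservation_score(aln, "c", "mature")


class TestAlignCandidate:
    def test_identical_candidate_inserts_without_gaps(self, toy_family):
        aln = toy_family.alignment
        out = align_candidate(aln, toy_family.consensus, "cand")
        assert len(out.rows) == len(aln.rows) + 1
        assert out.length == aln.length
        assert "-" not in out.get_row("cand")

    def test_deletion_places_gap_characters(self):
        rows = [("a", "ACGUACGUACGUACG"), ("b", "ACGUACGUACGUACG")]
        aln = FamilyAlignment(family_id="F", rows=rows)
        candidate = "ACGUA" + "UACGUACG"  # consensus minus the "CG" at columns 5-6
        out = align_candidate(aln, candidate, "cand")
        row = out.get_row("cand")
        assert row.count("-") == 2
        assert out.length == aln.length  # deletions add no columns
        assert [out.get_row("a"), out.get_row("b")] == [r for _, r in rows]

    def test_insertion_appends_columns_and_remaps_spans(self, toy_family):
        aln = toy_family.alignment
        consensus = toy_family.consensus
        candidate = consensus[:30] + "ACGU" + consensus[30:]
        out = align_candidate(aln, candidate, "cand")
        assert out.length == aln.length + 4
        # existing rows gain exactly 4 gap characters
        for name, seq in aln.rows:
            assert out.get_row(name).replace("-", "") == seq.replace("-", "")
        # spans still select the same member characters
        for name, entries in aln.arm_spans.items():
            old = dict((label, (s, e)) for label, s, e in entries)
            new = dict((label, (s, e)) for label, s, e in out.arm_spans[name])
            old_row, new_row = aln.get_row(name), out.get_row(name)
            for label in old:
                old_text = old_row[old[label][0] : old[label][1]]
                new_text = new_row[new[label][0] : new[label][1]].replace("-", "")
                assert new_text == old_text

    def test_empty_candidate_rejected(self, toy_family):
        with pytest.raises(ValidationError):
            align_candidate(toy_family.alignment, "")


class TestCurate:
    def test_planted_candidate_accepted_and_shuffle_rejected(self, toy_family):
        from mirseed.candidate_filter import Candidate
        from mirseed.io_formats import GenomicInterval
        from mirseed.synthetic_data import (
            GeneratorParams,
            _derive_candidate,
            _derive_hairpin_decoy,
        )

        rng = np.random.default_rng(8)
        params = CurationParams()
        good_seq = _derive_candidate(rng, toy_family, GeneratorParams(), params)
        bad_seq = _derive_hairpin_decoy(rng, toy_family, params)
        fam_id = toy_family.alignment.family_id

        def cand(cid, seq):
            return Candidate(cid, fam_id, GenomicInterval("chr1", 0, len(seq)), 40.0, 1e-6, seq)

        decisions = curate(
            [cand("good", good_seq), cand("bad", bad_seq)],
            {fam_id: toy_family.alignment},
            params,
        )
        good, bad = decisions
        assert good.accepted and good.reasons == []
        assert not bad.accepted
        assert any("hairpin" in r or "conservation" in r for r in bad.reasons)

    def test_acceptance_monotone_in_thresholds(self, toy_family):
        from mirseed.candidate_filter import Candidate
        from mirseed.io_formats import GenomicInterval
        from mirseed.synthetic_data import GeneratorParams, _derive_candidate

        rng = np.random.default_rng(9)
        seq = _derive_candidate(rng, toy_family, GeneratorParams(), CurationParams())
        fam_id = toy_family.alignment.family_id
        c = Candidate("x", fam_id, GenomicInterval("chr1", 0, len(seq)), 40.0, 1e-6, seq)
        strict = CurationParams()
        lax = CurationParams(min_conservation=0.5, min_stem_pairs=8)
        (d_strict,) = curate([c], {fam_id: toy_family.alignment}, strict)
        (d_lax,) = curate([c], {fam_id: toy_family.alignment}, lax)
        assert d_strict.accepted <= d_lax.accepted  # lowering thresholds never rejects

    def test_empty_candidate_list(self, toy_family):
        assert curate([], {toy_family.alignment.family_id: toy_family.alignment}) == []

    def test_unknown_family_raises_lookup_error(self, toy_family):
        from mirseed.candidate_filter import Candidate
        from mirseed.io_formats import GenomicInterval

        c = Candidate("x", "MIPF_MISSING", GenomicInterval("chr1", 0, 30), 40.0, 1e-6,
                      "ACGU" * 8)
        with pytest.raises(KeyError):
            curate([c], {toy_family.alignment.family_id: toy_family.alignment})
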