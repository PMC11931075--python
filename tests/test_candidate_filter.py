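"""Filter cascade: threshold formula, stage semantics, brute-force agreement."""

import numpy as np
import pytest

from mirseed.candidate_filter import (
    Candidate,
    FilterParams,
    compute_bitscore_threshold,
    filter_known_overlaps,
    filter_repeat_overlaps,
    filter_reverse_complements,
    filter_significance,
    filter_unfinished_duplicates,
    run_cascade,
)
from mirseed.errors import ValidationError
from mirseed.io_formats import CMHit, GenomicInterval, GenomeStore, RepeatFeature


def _hit(seq_id="chr1", start=100, end=172, strand="+", score=40.0, e=1e-5, fam="F1"):
    return CMHit(fam, GenomicInterval(seq_id, start, end, strand), score, e)


def _random_hits(rng, n, seqs=("chr1", "chr2"), span=500):
    hits = []
    for _ in range(n):
        seq = seqs[rng.integers(0, len(seqs))]
        start = int(rng.integers(0, span))
        length = int(rng.integers(20, 90))
        strand = "+" if rng.random() < 0.5 else "-"
        hits.append(
            _hit(seq, start, start + length, strand,
                 score=float(rng.uniform(10, 60)), e=float(10 ** rng.uniform(-8, 0)))
        )
    return hits


def brute_force_reverse_complement(hits):
    """Independent oracle: grow conflict components by repeated expansion,
    keep only the best hit of each; returns the removed hits in order."""

    def conflicts(x, y):
        return (
            x.target.seq_id == y.target.seq_id
            and x.target.strand != y.target.strand
            and x.target.start < y.target.end
            and y.target.start < x.target.end
        )

    unassigned = list(range(len(hits)))
    expected_drop = set()
    while unassigned:
        comp = {unassigned.pop(0)}
        grew = True
        while grew:
            grew = False
            for j in list(unassigned):
                if any(conflicts(hits[j], hits[i]) for i in comp):
                    comp.add(j)
                    unassigned.remove(j)
                    grew = True
        if len(comp) > 1:
            best = min(
                comp,
                key=lambda k: (
                    hits[k].e_value,
                    -hits[k].bit_score,
                    (hits[k].target.seq_id, hits[k].target.start, hits[k].target.strand),
                ),
            )
            expected_drop |= comp - {best}
    return [h for i, h in enumerate(hits) if i in expected_drop]


class TestBitscoreThreshold:
    @pytest.mark.parametrize(
        "genome_size,expected",
        [(2_870_000_000, 33), (1, 1), (2**31, 32)],
    )
    def test_closed_form(self, genome_size, expected):
        assert compute_bitscore_threshold(genome_size) == expected

    def test_non_positive_size_rejected(self):
        with pytest.raises(ValidationError):
            compute_bitscore_threshold(0)


class TestSignificance:
    def test_boundaries(self):
        params = FilterParams(e_value_cutoff=0.01, bit_score_cutoff=33)
        keep = _hit(score=40.0, e=0.005)
        drop_score = _hit(score=32.9, e=0.005)
        drop_e = _hit(score=40.0, e=0.011)
        on_boundary = _hit(score=33.0, e=0.01)
        kept, removed = filter_significance([keep, drop_score, drop_e, on_boundary], params)
        assert kept == [keep, on_boundary]
        assert removed == [drop_score, drop_e]

    def test_partitions_input_exactly(self):
        rng = np.random.default_rng(0)
        hits = _random_hits(rng, 100)
        params = FilterParams(e_value_cutoff=0.01, bit_score_cutoff=33)
        kept, removed = filter_significance(hits, params)
        assert sorted(map(id, kept + removed)) == sorted(map(id, hits))
        assert all(h.e_value <= 0.01 and h.bit_score >= 33 for h in kept)

    def test_monotone_in_both_cutoffs(self):
        rng = np.random.default_rng(1)
        hits = _random_hits(rng, 150)
        sizes = []
        for e_cut, b_cut in [(0.1, 20), (0.01, 20), (0.01, 33), (0.001, 40)]:
            kept, _ = filter_significance(
                hits, FilterParams(e_value_cutoff=e_cut, bit_score_cutoff=b_cut)
            )
            sizes.append(len(kept))
        assert sizes == sorted(sizes, reverse=True)


class TestKnownOverlaps:
    def test_overlap_and_half_open_adjacency(self):
        overlapping = _hit(start=100, end=170)
        adjacent = _hit(start=100, end=170, strand="-")
        known = [GenomicInterval("chr1", 150, 220)]
        kept, removed = filter_known_overlaps([overlapping], known)
        assert removed == [overlapping]
        kept, removed = filter_known_overlaps([adjacent], [GenomicInterval("chr1", 170, 240)])
        assert kept == [adjacent]

    def test_agrees_with_all_pairs_brute_force(self):
        rng = np.random.default_rng(2)
        hits = _random_hits(rng, 50)
        known = [
            GenomicInterval(
                ("chr1", "chr2")[rng.integers(0, 2)],
                int(s := rng.integers(0, 500)),
                int(s + rng.integers(10, 80)),
            )
            for _ in range(20)
        ]
        kept, removed = filter_known_overlaps(hits, known)
        expected_removed = [
            h
            for h in hits
            if any(
                h.target.seq_id == k.seq_id and h.target.start < k.end and k.start < h.target.end
                for k in known
            )
        ]
        assert removed == expected_removed
        assert kept == [h for h in hits if h not in expected_removed]


class TestUnfinishedDuplicates:
    @pytest.fixture
    def genome(self):
        rng = np.random.default_rng(3)
        letters = np.array(list("ACGT"))
        seqs = {
            name: "".join(rng.choice(letters, size=400))
            for name in ("chr1", "KL567001.1", "KL567002.1")
        }
        # copy chr1[100:172] onto both scaffolds
        for scaf in ("KL567001.1", "KL567002.1"):
            seqs[scaf] = seqs[scaf][:50] + seqs["chr1"][100:172] + seqs[scaf][122:]
        return GenomeStore(seqs)

    def test_scaffold_copy_of_primary_hit_removed(self, genome):
        params = FilterParams()
        chr_hit = _hit("chr1", 100, 172)
        scaf_hit = _hit("KL567001.1", 50, 122)
        kept, removed = filter_unfinished_duplicates([chr_hit, scaf_hit], genome, params)
        assert kept == [chr_hit]
        assert removed == [scaf_hit]

    def test_scaffold_hit_without_duplicate_kept(self, genome):
        params = FilterParams()
        lone = _hit("KL567001.1", 200, 272)
        kept, removed = filter_unfinished_duplicates([lone], genome, params)
        assert kept == [lone] and removed == []

    def test_between_scaffolds_lower_evalue_wins(self, genome):
        params = FilterParams()
        better = _hit("KL567001.1", 50, 122, e=1e-5)
        worse = _hit("KL567002.1", 50, 122, e=1e-3)
        kept, removed = filter_unfinished_duplicates([worse, better], genome, params)
        assert kept == [better]
        assert removed == [worse]

    def test_primary_hits_never_removed(self, genome):
        params = FilterParams()
        a = _hit("chr1", 100, 172, e=1e-3)
        b = _hit("chr1", 100, 172, strand="-", e=1e-5)
        kept, removed = filter_unfinished_duplicates([a, b], genome, params)
        assert kept == [a, b] and removed == []


class TestReverseComplements:
    def test_smaller_evalue_wins_at_a_locus(self):
        a = _hit(strand="+", e=1e-6)
        b = _hit(strand="-", e=1e-3)
        kept, removed = filter_reverse_complements([a, b])
        assert kept == [a] and removed == [b]

    def test_same_strand_overlaps_untouched(self):
        a = _hit(strand="+", start=100, end=170)
        b = _hit(strand="+", start=120, end=190)
        kept, removed = filter_reverse_complements([a, b])
        assert kept == [a, b] and removed == []

    def test_component_chain_resolved_to_single_best(self):
        # A(+) overlaps B(-) overlaps C(+): one component, keep min-e B
        a = _hit(strand="+", start=100, end=170, e=1e-4)
        b = _hit(strand="-", start=150, end=220, e=1e-6)
        c = _hit(strand="+", start=200, end=270, e=1e-5)
        kept, removed = filter_reverse_complements([a, b, c])
        assert kept == [b]
        assert removed == [a, c]

    def test_agrees_with_brute_force_component_resolution(self):
        rng = np.random.default_rng(4)
        hits = _random_hits(rng, 60, span=300)
        _, removed = filter_reverse_complements(hits)
        assert brute_force_reverse_complement(hits) == removed


class TestCascade:
    def test_empty_input_gives_all_zero_report(self):
        genome = GenomeStore({"chr1": "ACGT" * 100})
        candidates, report = run_cascade([], genome, [], [], FilterParams())
        assert candidates == []
        assert all(r.n_in == r.n_out == r.n_removed == 0 for r in report.stages)

    def test_report_counts_chain_and_stage_names_canonical(self, default_instance):
        from mirseed.io_formats import read_bed_intervals, read_cm_tblout, read_repeats

        paths, _ = default_instance
        genome = GenomeStore.from_fasta(paths.genome)
        hits = read_cm_tblout(paths.tblout)
        repeats = read_repeats(paths.repeats, "bed")
        known = read_bed_intervals(paths.known)
        candidates, report = run_cascade(hits, genome, repeats, known)
        assert [r.stage_name for r in report.stages] == [
            "significance",
            "known_overlap",
            "unfinished_duplicates",
            "repeat_overlap",
            "reverse_complement",
        ]
        for prev, cur in zip(report.stages, report.stages[1:]):
            assert cur.n_in == prev.n_out
        assert report.n_final == len(candidates)

    def test_each_decoy_removed_at_its_planted_stage(self, default_instance):
        from mirseed.io_formats import read_bed_intervals, read_cm_tblout, read_repeats

        paths, manifest = default_instance
        genome = GenomeStore.from_fasta(paths.genome)
        hits = read_cm_tblout(paths.tblout)
        repeats = read_repeats(paths.repeats, "bed")
        known = read_bed_intervals(paths.known)
        candidates, report = run_cascade(hits, genome, repeats, known)
        removed_at = {
            hid: rec.stage_name for rec in report.stages for hid in rec.removed_ids
        }
        for rec in manifest.records:
            if rec.expected_fate.startswith("removed_at:"):
                stage = rec.expected_fate.split(":", 1)[1]
                assert removed_at.get(rec.candidate_id) == stage, rec.label
            else:
                assert rec.candidate_id not in removed_at, rec.label
        survivor_ids = {c.candidate_id for c in candidates}
        expected = {
            r.candidate_id
            for r in manifest.records
            if r.expected_fate in ("survive_all", "rejected_at_curation")
        }
        assert survivor_ids == expected

    def test_candidate_sequences_are_strand_corrected_rna(self, default_instance):
        from mirseed.io_formats import read_bed_intervals, read_cm_tblout, read_repeats

        paths, manifest = default_instance
        genome = GenomeStore.from_fasta(paths.genome)
        hits = read_cm_tblout(paths.tblout)
        candidates, _ = run_cascade(
            hits, genome, read_repeats(paths.repeats, "bed"), read_bed_intervals(paths.known)
        )
        planted = {r.candidate_id: r.sequence for r in manifest.records}
        for c in candidates:
            assert c.sequence == planted[c.candidate_id]

    def test_stages_are_idempotent(self, default_instance):
        from mirseed.io_formats import read_bed_intervals, read_cm_tblout, read_repeats

        paths, _ = default_instance
        genome = GenomeStore.from_fasta(paths.genome)
        hits = read_cm_tblout(paths.tblout)
        repeats = read_repeats(paths.repeats, "bed")
        known = read_bed_intervals(paths.known)
        params = FilterParams(bit_score_cutoff=17)
        stages = [
            lambda h: filter_significance(h, params),
            lambda h: filter_known_overlaps(h, known),
            lambda h: filter_unfinished_duplicates(h, genome, params),
            lambda h: filter_repeat_overlaps(h, repeats, params),
            filter_reverse_complements,
        ]
        current = hits
        for stage in stages:
            kept, _ = stage(current)
            kept_again, removed_again = stage(kept)
            assert kept_again == kept and removed_again == []
            current = kept


def test_repeat_overlap_agrees_with_brute_force():
    rng = np.random.default_rng(5)
    hits = _random_hits(rng, 50)
    repeats = [
        RepeatFeature(
            GenomicInterval(
                ("chr1", "chr2")[rng.integers(0, 2)],
                int(s := rng.integers(0, 500)),
                int(s + rng.integers(10, 120)),
            )
        )
        for _ in range(15)
    ]
    params = FilterParams(min_repeat_overlap=1)
    kept, removed = filter_repeat_overlaps(hits, repeats, params)
    expected_removed = [
        h
        for h in hits
        if any(
            max(0, min(h.target.end, r.interval.end) - max(h.target.start, r.interval.start)) >= 1
            and h.target.seq_id == r.interval.seq_id
            for r in repeats
        )
    ]
    assert removed == expected_removed
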