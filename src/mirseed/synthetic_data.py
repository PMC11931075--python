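"""Seeded synthetic test instances with planted ground truth.

Real inputs of a genome-wide miRNA homology screen (a reference genome,
family covariance models, repeat annotations, short-read libraries) are
too large to carry around; this module generates complete, self-consistent
miniature instances instead: a toy multi-sequence genome (primary
chromosomes plus accession-named "unfinished" scaffolds), miRNA family
alignments with mature/mature* arm annotations built around guaranteed
hairpin consensi, a covariance-model hit table whose planted true
positives clear every filter while each decoy class is constructed to die
at exactly one labeled cascade stage, repeat tracts, known annotations,
a liftover chain to a shifted synthetic assembly, and per-sample read
intervals realizing a prescribed tissue-detection pattern. A manifest
records the expected fate of every planted entity, so end-to-end runs are
verifiable without downloads.

Every draw flows from one integer seed; identical (params, seed) produce
byte-identical files.

Precursor anatomy (defaults): 10 nt flank + 22 nt mature arm + 8 nt loop
+ (22 + bulges) nt star arm + 10 nt flank, ~72 nt total, mirroring the
~70 nt pre-miRNA stem-loop. Flanks and loops are drawn from {A, C} only,
so spurious base pairs cannot open a second stem; decoy scores are placed
at least 5 bits / an order of magnitude in e-value away from thresholds
so acceptance checks are never knife-edge.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .candidate_filter import Candidate, FilterParams, compute_bitscore_threshold
from .errors import ValidationError
from .expression_support import SampleReads
from .io_formats import (
    Chain,
    ChainBlock,
    ChainFile,
    CMHit,
    FamilyAlignment,
    GenomicInterval,
    reverse_complement,
    write_chain,
    write_cm_tblout,
    write_fasta,
    write_stockholm,
)
from .structure_curation import CurationParams, curate

RNA = "ACGU"
_RNA_RC = str.maketrans("ACGU", "UGCA")

SPECIES = ("mmu", "hsa", "ptr", "cfa", "bta", "mdo", "gga", "xtr", "dre", "oan")


def rna_reverse_complement(seq: str) -> str:
    return seq.translate(_RNA_RC)[::-1]


@dataclass
class GeneratorParams:
    """Study conditions of the default synthetic instance."""

    n_chromosomes: int = 3
    chromosome_length: int = 10_000
    n_scaffolds: int = 3
    scaffold_length: int = 3_000
    n_families: int = 5
    members_per_family: int = 5
    arm_length: int = 22
    loop_length: int = 8
    flank_length: int = 9
    precursor_length: int = 72
    mutation_rate_non_arm: float = 0.10
    mutation_rate_arm: float = 0.02
    n_true: int = 5
    n_subthreshold_decoys: int = 3
    n_known_overlap_decoys: int = 2
    n_scaffold_duplicate_decoys: int = 2
    n_repeat_decoys: int = 2
    n_revcomp_decoys: int = 2
    n_hairpin_decoys: int = 2
    n_conservation_decoys: int = 2
    n_repeats: int = 6
    repeat_length: int = 300
    n_known: int = 4
    n_thyroid_samples: int = 40
    n_liver_samples: int = 35
    read_length: int = 22

    def __post_init__(self) -> None:
        if not (0 <= self.mutation_rate_non_arm < 1 and 0 <= self.mutation_rate_arm < 1):
            raise ValidationError("mutation rates must lie in [0, 1)")
        if self.n_bulges < 0:
            raise ValidationError("arms, loop and flanks do not fit into the precursor")

    @property
    def n_bulges(self) -> int:
        """Unpaired star-arm bulges; whatever length the precursor has left
        over after flanks, arms and loop."""
        return (
            self.precursor_length
            - 2 * self.flank_length
            - 2 * self.arm_length
            - self.loop_length
        )


@dataclass
class PlantedRecord:
    """Ground truth for one planted hit (true candidate or decoy)."""

    label: str
    candidate_id: str
    family_id: str
    seq_id: str
    start: int
    end: int
    strand: str
    sequence: str  # strand-corrected precursor, RNA
    expected_fate: str  # survive_all | removed_at:<stage> | rejected_at_curation
    expected_name: str | None = None

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.seq_id, self.start, self.end, self.strand)


@dataclass
class TruthManifest:
    seed: int
    records: list[PlantedRecord] = field(default_factory=list)
    supported: dict[str, dict[str, bool]] = field(default_factory=dict)
    chain_dest_names: dict[str, str] = field(default_factory=dict)

    def by_fate(self, fate: str) -> list[PlantedRecord]:
        return [r for r in self.records if r.expected_fate == fate]

    @property
    def survivors(self) -> list[PlantedRecord]:
        return self.by_fate("survive_all")

    def save(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "records": [dataclasses.asdict(r) for r in self.records],
            "supported": self.supported,
            "chain_dest_names": self.chain_dest_names,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "TruthManifest":
        payload = json.loads(Path(path).read_text())
        return cls(
            seed=payload["seed"],
            records=[PlantedRecord(**r) for r in payload["records"]],
            supported=payload["supported"],
            chain_dest_names=payload["chain_dest_names"],
        )


# ---------------------------------------------------------------------------
# Hairpin and family construction
# ---------------------------------------------------------------------------


def _random_seq(rng: np.random.Generator, alphabet: str, n: int) -> str:
    return "".join(rng.choice(list(alphabet), size=n))


def _build_hairpin(rng: np.random.Generator, params: GeneratorParams) -> tuple[str, dict]:
    """One precursor skeleton: flank + mature arm + loop + star arm + flank.

    Flanks and loop use {A, C} only (they cannot pair with each other),
    keeping the fold a single stem-loop. Returns the RNA string and the
    arm spans in sequence coordinates.
    """
    arm = _random_seq(rng, RNA, params.arm_length)
    star = list(rna_reverse_complement(arm))
    for _ in range(params.n_bulges):  # unpaired bulge nucleotides in the star arm
        pos = int(rng.integers(1, len(star)))
        star.insert(pos, str(rng.choice(["A", "C"])))
    star_seq = "".join(star)
    flank_l = _random_seq(rng, "AC", params.flank_length)
    flank_r = _random_seq(rng, "AC", params.flank_length)
    loop = _random_seq(rng, "AC", params.loop_length)
    seq = flank_l + arm + loop + star_seq + flank_r
    f, a, l = params.flank_length, params.arm_length, params.loop_length
    spans = {
        "mature": (f, f + a),
        "mature_star": (f + a + l, f + a + l + len(star_seq)),
    }
    return seq, spans


def _mutate(
    rng: np.random.Generator,
    seq: str,
    arm_cols: set[int],
    rate_arm: float,
    rate_non_arm: float,
    frozen: set[int] | None = None,
) -> str:
    """Point-mutate a precursor: arm columns over ACGU, non-arm columns
    within {A, C} (preserving the no-spurious-pairing property)."""
    frozen = frozen or set()
    out = list(seq)
    for i, ch in enumerate(out):
        if i in frozen:
            continue
        rate = rate_arm if i in arm_cols else rate_non_arm
        if rng.random() < rate:
            pool = RNA if i in arm_cols else "AC"
            choices = [c for c in pool if c != ch]
            out[i] = str(rng.choice(choices))
    return "".join(out)


@dataclass
class FamilyBundle:
    """A generated family with its alignment and construction metadata."""

    alignment: FamilyAlignment
    consensus: str
    base: str  # e.g. "mir-101"
    model_name: str
    subtype_labels: dict[str, str] = field(default_factory=dict)
    diagnostic_columns: list[int] = field(default_factory=list)


def generate_family(
    params: GeneratorParams,
    seed: int | np.random.Generator,
    index: int = 0,
    two_subtype: bool = False,
    n_diagnostic: int = 6,
    curation_params: CurationParams | None = None,
) -> FamilyBundle:
    """Generate one family alignment around a guaranteed hairpin consensus.

    The consensus is folded and classified at generation time and must
    clear the hairpin screen with a 4-pair margin (regenerated otherwise).
    Members are the consensus mutated at ``mutation_rate_arm`` inside arms
    and ``mutation_rate_non_arm`` outside. In two-subtype mode exactly
    ``n_diagnostic`` diagnostic columns are planted (complementary stem
    positions are changed pairwise, keeping both subtypes folding).
    """
    if params.members_per_family < 2:
        raise ValidationError("members_per_family must be >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cur = curation_params or CurationParams()
    base_num = 100 + index
    base = f"mir-{base_num}"
    family_id = f"MIPF{9000 + index:07d}"

    from .naming import identify_diagnostic_columns  # local import to avoid cycle

    for _attempt in range(200):
        consensus, spans = _build_hairpin(rng, params)
        from .structure_curation import classify_hairpin, fold_max_pairing

        structure = fold_max_pairing(consensus, cur.min_loop, cur.allowed_pairs)
        ok, _ = classify_hairpin(structure, cur)
        if not (ok and structure.n_pairs >= cur.min_stem_pairs + 4):
            continue
        arm_cols = set(range(*spans["mature"])) | set(range(*spans["mature_star"]))
        diagnostic: list[int] = []
        consensus_b = consensus
        if two_subtype:
            stem_pairs = [
                (i, j)
                for i, j in structure.pairs
                if i in range(*spans["mature"]) and j in range(*spans["mature_star"])
            ]
            need_pairs = n_diagnostic // 2
            if len(stem_pairs) < need_pairs:
                continue
            chosen_idx = rng.choice(len(stem_pairs), size=need_pairs, replace=False)
            chosen = [stem_pairs[i] for i in sorted(chosen_idx)]
            cb = list(consensus)
            for i, j in chosen:
                new = str(rng.choice([c for c in RNA if c != cb[i]]))
                cb[i] = new
                cb[j] = rna_reverse_complement(new)
                diagnostic.extend([i, j])
            if n_diagnostic % 2:
                loop_cols = [
                    c
                    for c in range(spans["mature"][1], spans["mature_star"][0])
                    if c not in arm_cols
                ]
                c = int(rng.choice(loop_cols))
                cb[c] = "A" if consensus[c] != "A" else "C"
                diagnostic.append(c)
            diagnostic.sort()
            consensus_b = "".join(cb)

        frozen = set(diagnostic)
        rows: list[tuple[str, str]] = []
        labels: dict[str, str] = {}
        n = params.members_per_family
        for m in range(n):
            sp = SPECIES[m % len(SPECIES)]
            if two_subtype:
                subtype = "A" if m < (n + 1) // 2 else "B"
                name = f"{sp}-{base}-{1 if subtype == 'A' else 2}"
                template = consensus if subtype == "A" else consensus_b
                labels[name] = subtype
            else:
                name = f"{sp}-{base}"
                template = consensus
            rows.append(
                (
                    name,
                    _mutate(
                        rng,
                        template,
                        arm_cols,
                        params.mutation_rate_arm,
                        params.mutation_rate_non_arm,
                        frozen,
                    ),
                )
            )
        arm_spans = {
            name: [
                ("mature", *spans["mature"]),
                ("mature_star", *spans["mature_star"]),
            ]
            for name, _ in rows
        }
        aln = FamilyAlignment(family_id=family_id, rows=rows, arm_spans=arm_spans)
        if two_subtype:
            # plant-and-verify: the diagnostic set must come out exactly
            if identify_diagnostic_columns(aln, labels) != diagnostic:
                continue
        # the consensus itself must pass curation against its members
        probe = Candidate(
            candidate_id="__probe__",
            family_id=family_id,
            interval=GenomicInterval("chr1", 0, len(consensus)),
            bit_score=50.0,
            e_value=1e-9,
            sequence=consensus,
        )
        decision = curate([probe], {family_id: aln}, cur)[0]
        if not (decision.accepted and decision.conservation_score >= cur.min_conservation + 0.05):
            continue
        return FamilyBundle(
            alignment=aln,
            consensus=consensus,
            base=base,
            model_name=base,
            subtype_labels=labels,
            diagnostic_columns=diagnostic,
        )
    raise RuntimeError("family generation failed to satisfy hairpin/curation margins")


def _derive_candidate(
    rng: np.random.Generator,
    bundle: FamilyBundle,
    params: GeneratorParams,
    cur: CurationParams,
) -> str:
    """A plantable true candidate: consensus mutated mostly outside arms,
    validated to pass curation with margin."""
    spans = dict(
        (label, (s, e))
        for label, s, e in bundle.alignment.arm_spans[bundle.alignment.rows[0][0]]
    )
    arm_cols = set(range(*spans["mature"])) | set(range(*spans["mature_star"]))
    for _ in range(200):
        seq = _mutate(
            rng,
            bundle.consensus,
            arm_cols,
            params.mutation_rate_arm,
            params.mutation_rate_non_arm,
        )
        probe = Candidate(
            candidate_id="__probe__",
            family_id=bundle.alignment.family_id,
            interval=GenomicInterval("chr1", 0, len(seq)),
            bit_score=50.0,
            e_value=1e-9,
            sequence=seq,
        )
        d = curate([probe], {bundle.alignment.family_id: bundle.alignment}, cur)[0]
        if d.accepted and d.conservation_score >= cur.min_conservation + 0.05:
            return seq
    raise RuntimeError("candidate derivation failed to satisfy curation margins")


def _derive_hairpin_decoy(
    rng: np.random.Generator, bundle: FamilyBundle, cur: CurationParams
) -> str:
    """Shuffled-composition decoy validated to be rejected by curation."""
    letters = list(bundle.consensus)
    for _ in range(200):
        perm = rng.permutation(len(letters))
        seq = "".join(letters[i] for i in perm)
        probe = Candidate(
            candidate_id="__probe__",
            family_id=bundle.alignment.family_id,
            interval=GenomicInterval("chr1", 0, len(seq)),
            bit_score=50.0,
            e_value=1e-9,
            sequence=seq,
        )
        d = curate([probe], {bundle.alignment.family_id: bundle.alignment}, cur)[0]
        if not d.accepted:
            return seq
    raise RuntimeError("hairpin decoy derivation failed")


def _derive_conservation_decoy(
    rng: np.random.Generator,
    bundle: FamilyBundle,
    params: GeneratorParams,
    cur: CurationParams,
) -> str:
    """A well-folding hairpin unrelated to the family: hairpin_ok but
    conservation clearly below threshold."""
    for _ in range(200):
        seq, _spans = _build_hairpin(rng, params)
        probe = Candidate(
            candidate_id="__probe__",
            family_id=bundle.alignment.family_id,
            interval=GenomicInterval("chr1", 0, len(seq)),
            bit_score=50.0,
            e_value=1e-9,
            sequence=seq,
        )
        d = curate([probe], {bundle.alignment.family_id: bundle.alignment}, cur)[0]
        if d.hairpin_ok and d.conservation_score <= cur.min_conservation - 0.10:
            return seq
    raise RuntimeError("conservation decoy derivation failed")


# ---------------------------------------------------------------------------
# Genome assembly with planted features
# ---------------------------------------------------------------------------


class _GenomeBuilder:
    def __init__(self, rng: np.random.Generator, params: GeneratorParams):
        self.rng = rng
        self.seqs: dict[str, list[str]] = {}
        self.occupied: dict[str, list[tuple[int, int]]] = {}
        self.chrom_names: list[str] = []
        self.scaffold_names: list[str] = []
        for i in range(params.n_chromosomes):
            name = f"chr{i + 1}"
            self.seqs[name] = list(_random_seq(rng, "ACGT", params.chromosome_length))
            self.occupied[name] = []
            self.chrom_names.append(name)
        for _ in range(params.n_scaffolds):
            name = f"KL{int(rng.integers(100000, 999999))}.1"
            while name in self.seqs:
                name = f"KL{int(rng.integers(100000, 999999))}.1"
            self.seqs[name] = list(_random_seq(rng, "ACGT", params.scaffold_length))
            self.occupied[name] = []
            self.scaffold_names.append(name)

    def reserve(self, seq_id: str, start: int, end: int) -> None:
        self.occupied[seq_id].append((start, end))

    def alloc(self, seq_id: str, length: int, pad: int = 60) -> int:
        size = len(self.seqs[seq_id])
        for _ in range(500):
            start = int(self.rng.integers(pad, size - length - pad))
            end = start + length
            if all(
                end + pad <= s or e + pad <= start for s, e in self.occupied[seq_id]
            ):
                self.occupied[seq_id].append((start, end))
                return start
        raise RuntimeError(f"could not place a {length} bp feature on {seq_id}")

    def plant(self, seq_id: str, start: int, rna_seq: str, strand: str) -> GenomicInterval:
        dna = rna_seq.replace("U", "T")
        if strand == "-":
            dna = reverse_complement(dna)
        self.seqs[seq_id][start : start + len(dna)] = list(dna)
        return GenomicInterval(seq_id, start, start + len(rna_seq), strand)

    def finalize(self) -> dict[str, str]:
        return {name: "".join(chars) for name, chars in self.seqs.items()}


# ---------------------------------------------------------------------------
# Reads realizing a tissue-detection pattern
# ---------------------------------------------------------------------------


def build_support_reads(
    rng: np.random.Generator,
    mirnas: Sequence[tuple[str, GenomicInterval]],
    n_both: int,
    n_first_only: int,
    n_second_only: int,
    n_first_samples: int,
    n_second_samples: int,
    tissues: tuple[str, str] = ("thyroid", "liver"),
    read_length: int = 22,
) -> tuple[list[SampleReads], dict[str, dict[str, bool]]]:
    """Per-sample reads realizing an exact detection pattern.

    The first ``n_both`` miRNAs (in list order) are detected in both
    tissues, the next ``n_first_only`` only in the first, the next
    ``n_second_only`` only in the second; the rest get no sense-strand
    reads. Read counts per detected (miRNA, sample) are log-uniform in
    1..2000, echoing the few-to-thousands spread of real libraries; a
    sprinkling of antisense reads is added that must never count.
    """
    if n_both + n_first_only + n_second_only > len(mirnas):
        raise ValidationError("detection pattern larger than the miRNA set")
    first, second = tissues
    samples = [
        SampleReads(f"{first}_{i + 1:02d}", first) for i in range(n_first_samples)
    ] + [SampleReads(f"{second}_{i + 1:02d}", second) for i in range(n_second_samples)]
    by_tissue = {
        first: [s for s in samples if s.tissue == first],
        second: [s for s in samples if s.tissue == second],
    }
    expected: dict[str, dict[str, bool]] = {}
    for idx, (name, iv) in enumerate(mirnas):
        in_first = idx < n_both + n_first_only
        in_second = idx < n_both or (
            n_both + n_first_only <= idx < n_both + n_first_only + n_second_only
        )
        expected[name] = {first: in_first, second: in_second}
        for tissue, flag in ((first, in_first), (second, in_second)):
            if not flag:
                continue
            pool = by_tissue[tissue]
            n_det = int(rng.integers(1, min(4, len(pool)) + 1))
            chosen = rng.choice(len(pool), size=n_det, replace=False)
            for s_idx in sorted(chosen):
                sample = pool[s_idx]
                n_reads = int(10 ** rng.uniform(0, 3.3))
                for _ in range(n_reads):
                    off = int(rng.integers(0, iv.length - read_length + 1))
                    sample.reads.append(
                        GenomicInterval(
                            iv.seq_id, iv.start + off, iv.start + off + read_length, iv.strand
                        )
                    )
        # antisense noise on undetected loci: must never count
        if not (expected[name][first] or expected[name][second]):
            sample = samples[int(rng.integers(0, len(samples)))]
            anti = "-" if iv.strand == "+" else "+"
            sample.reads.append(
                GenomicInterval(iv.seq_id, iv.start, iv.start + read_length, anti)
            )
    return samples, expected


def generate_support_instance(
    seed: int,
    n_mirnas: int = 55,
    n_both: int = 30,
    n_first_only: int = 5,
    n_second_only: int = 2,
    n_first_samples: int = 40,
    n_second_samples: int = 35,
    read_length: int = 22,
) -> tuple[list[tuple[str, GenomicInterval]], list[SampleReads], dict[str, dict[str, bool]]]:
    """A standalone read-support instance: n_mirnas loci with an exact
    union / first-tissue / second-tissue detection pattern (defaults:
    37 union = 35 thyroid / 32 liver, with 30 in both)."""
    rng = np.random.default_rng(seed)
    mirnas = [
        (
            f"rno-mir-{500 + i}",
            GenomicInterval("chr1", 1000 + 200 * i, 1072 + 200 * i, "+" if i % 2 == 0 else "-"),
        )
        for i in range(n_mirnas)
    ]
    samples, expected = build_support_reads(
        rng,
        mirnas,
        n_both,
        n_first_only,
        n_second_only,
        n_first_samples,
        n_second_samples,
        read_length=read_length,
    )
    return mirnas, samples, expected


# ---------------------------------------------------------------------------
# Full instance generation
# ---------------------------------------------------------------------------


@dataclass
class InstancePaths:
    root: Path
    genome: Path
    tblout: Path
    repeats: Path
    known: Path
    families_dir: Path
    chain: Path
    reads_dir: Path
    sample_sheet: Path
    manifest: Path


def generate_instance(
    params: GeneratorParams | None = None,
    seed: int = 0,
    out_dir: str | Path = ".",
) -> tuple[InstancePaths, TruthManifest]:
    """Emit a complete instance to ``out_dir`` and return its manifest.

    See the module docstring for what is planted; every decoy class is
    labeled with the exact cascade stage expected to remove it.
    """
    params = params or GeneratorParams()
    rng = np.random.default_rng(seed)
    cur = CurationParams()
    out = Path(out_dir)
    (out / "families").mkdir(parents=True, exist_ok=True)
    (out / "reads").mkdir(exist_ok=True)

    builder = _GenomeBuilder(rng, params)
    genome_size = sum(len(s) for s in builder.seqs.values())
    threshold = compute_bitscore_threshold(genome_size)

    # reserve the chain-deletion windows before planting anything
    gap_regions: dict[str, tuple[int, int]] = {}
    for name in builder.seqs:
        size = len(builder.seqs[name])
        gpos = int(0.75 * size)
        gap_regions[name] = (gpos, gpos + 100)
        builder.reserve(name, gpos - 5, gpos + 105)

    bundles = [
        generate_family(params, rng, index=i, curation_params=cur)
        for i in range(params.n_families)
    ]
    fam_count: dict[str, int] = {}

    hits: list[CMHit] = []
    records: list[PlantedRecord] = []

    def good_e() -> float:
        return float(10 ** rng.uniform(-8, -4))

    def good_score() -> float:
        return float(threshold + 5 + rng.uniform(0, 10))

    def add_hit(
        label: str,
        family_id: str,
        interval: GenomicInterval,
        e_value: float,
        score: float,
        sequence: str,
        fate: str,
        expected_name: str | None = None,
    ) -> CMHit:
        hit = CMHit(
            family_id=family_id,
            target=interval,
            bit_score=round(score, 1),
            e_value=float(f"{e_value:.3g}"),
            model_span=(1, interval.length),
        )
        hits.append(hit)
        records.append(
            PlantedRecord(
                label=label,
                candidate_id=hit.hit_id,
                family_id=family_id,
                seq_id=interval.seq_id,
                start=interval.start,
                end=interval.end,
                strand=interval.strand,
                sequence=sequence,
                expected_fate=fate,
                expected_name=expected_name,
            )
        )
        return hit

    # --- true candidates -------------------------------------------------
    true_records: list[PlantedRecord] = []
    for i in range(params.n_true):
        bundle = bundles[i % params.n_families]
        fam_count[bundle.alignment.family_id] = (
            fam_count.get(bundle.alignment.family_id, 0) + 1
        )
        seq = _derive_candidate(rng, bundle, params, cur)
        chrom = builder.chrom_names[i % len(builder.chrom_names)]
        strand = "+" if i % 2 == 0 else "-"
        start = builder.alloc(chrom, len(seq))
        interval = builder.plant(chrom, start, seq, strand)
        e = float(10 ** rng.uniform(-10, -5))
        expected_name = (
            f"rno-{bundle.base}"
            if params.n_true <= params.n_families
            else None
        )
        add_hit(
            f"true_{i:03d}",
            bundle.alignment.family_id,
            interval,
            e,
            threshold + 5 + rng.uniform(0, 15),
            seq,
            "survive_all",
            expected_name,
        )
        true_records.append(records[-1])

    # --- significance decoys ---------------------------------------------
    for i in range(params.n_subthreshold_decoys):
        chrom = builder.chrom_names[i % len(builder.chrom_names)]
        start = builder.alloc(chrom, params.precursor_length)
        interval = GenomicInterval(chrom, start, start + params.precursor_length, "+")
        bundle = bundles[i % params.n_families]
        seq = "".join(builder.seqs[chrom][start : start + params.precursor_length]).replace(
            "T", "U"
        )
        if i % 2 == 0:  # fails the e-value cutoff
            e, score = float(10 ** rng.uniform(-1, 0.7)), good_score()
        else:  # fails the bit-score threshold
            e, score = good_e(), float(threshold - 5 - rng.uniform(0, 10))
        add_hit(
            f"subthr_{i:03d}",
            bundle.alignment.family_id,
            interval,
            e,
            score,
            seq,
            "removed_at:significance",
        )

    # --- known annotations and their decoys -------------------------------
    known_entries: list[tuple[str, GenomicInterval]] = []
    for k in range(params.n_known):
        chrom = builder.chrom_names[k % len(builder.chrom_names)]
        start = builder.alloc(chrom, 80)
        known_entries.append(
            (f"rno-mir-{300 + k}", GenomicInterval(chrom, start, start + 80, "+"))
        )
    for i in range(params.n_known_overlap_decoys):
        name, kiv = known_entries[i % len(known_entries)]
        start = max(0, kiv.start - 20)
        interval = GenomicInterval(kiv.seq_id, start, start + params.precursor_length, "+")
        bundle = bundles[i % params.n_families]
        seq = "".join(
            builder.seqs[kiv.seq_id][start : start + params.precursor_length]
        ).replace("T", "U")
        add_hit(
            f"known_{i:03d}",
            bundle.alignment.family_id,
            interval,
            good_e(),
            good_score(),
            seq,
            "removed_at:known_overlap",
        )

    # --- scaffold duplicates of true candidates ---------------------------
    for i in range(params.n_scaffold_duplicate_decoys):
        source = true_records[i % len(true_records)]
        scaffold = builder.scaffold_names[i % len(builder.scaffold_names)]
        start = builder.alloc(scaffold, len(source.sequence))
        interval = builder.plant(scaffold, start, source.sequence, source.strand)
        add_hit(
            f"scafdup_{i:03d}",
            source.family_id,
            interval,
            good_e(),
            good_score(),
            source.sequence,
            "removed_at:unfinished_duplicates",
        )

    # --- repeats and repeat-overlap decoys ---------------------------------
    repeat_tracts: list[tuple[str, GenomicInterval]] = []
    repeat_classes = ("SINE/Alu", "LINE/L1", "LTR/ERVK")
    for r in range(params.n_repeats):
        chrom = builder.chrom_names[r % len(builder.chrom_names)]
        start = builder.alloc(chrom, params.repeat_length)
        repeat_tracts.append(
            (
                repeat_classes[r % len(repeat_classes)],
                GenomicInterval(chrom, start, start + params.repeat_length, "+"),
            )
        )
    for i in range(params.n_repeat_decoys):
        cls, riv = repeat_tracts[i % len(repeat_tracts)]
        start = riv.start + 50
        interval = GenomicInterval(riv.seq_id, start, start + params.precursor_length, "+")
        bundle = bundles[i % params.n_families]
        seq = "".join(
            builder.seqs[riv.seq_id][start : start + params.precursor_length]
        ).replace("T", "U")
        add_hit(
            f"repeat_{i:03d}",
            bundle.alignment.family_id,
            interval,
            good_e(),
            good_score(),
            seq,
            "removed_at:repeat_overlap",
        )

    # --- reverse-complement decoys (losers at true loci) --------------------
    for i in range(params.n_revcomp_decoys):
        winner = true_records[i % len(true_records)]
        loser_strand = "-" if winner.strand == "+" else "+"
        interval = GenomicInterval(winner.seq_id, winner.start, winner.end, loser_strand)
        winner_hit = next(h for h in hits if h.hit_id == winner.candidate_id)
        e = min(winner_hit.e_value * float(10 ** rng.uniform(2, 3)), 5e-3)
        seq = rna_reverse_complement(winner.sequence)
        add_hit(
            f"revcomp_{i:03d}",
            winner.family_id,
            interval,
            e,
            threshold + 5 + rng.uniform(0, 5),
            seq,
            "removed_at:reverse_complement",
        )

    # --- curation decoys ----------------------------------------------------
    for i in range(params.n_hairpin_decoys):
        bundle = bundles[i % params.n_families]
        seq = _derive_hairpin_decoy(rng, bundle, cur)
        chrom = builder.chrom_names[(i + 1) % len(builder.chrom_names)]
        start = builder.alloc(chrom, len(seq))
        interval = builder.plant(chrom, start, seq, "+")
        add_hit(
            f"shuffle_{i:03d}",
            bundle.alignment.family_id,
            interval,
            good_e(),
            good_score(),
            seq,
            "rejected_at_curation",
        )
    for i in range(params.n_conservation_decoys):
        bundle = bundles[i % params.n_families]
        seq = _derive_conservation_decoy(rng, bundle, params, cur)
        chrom = builder.chrom_names[(i + 2) % len(builder.chrom_names)]
        start = builder.alloc(chrom, len(seq))
        interval = builder.plant(chrom, start, seq, "-")
        add_hit(
            f"foreign_{i:03d}",
            bundle.alignment.family_id,
            interval,
            good_e(),
            good_score(),
            seq,
            "rejected_at_curation",
        )

    # --- chains to the shifted synthetic assembly ---------------------------
    chains = []
    dest_names = {}
    for idx, (name, seq_chars) in enumerate(builder.seqs.items()):
        size = len(seq_chars)
        shift = 10 * (idx + 1)
        gstart, gend = gap_regions[name]
        dest_name = f"{name}_new"
        dest_names[name] = dest_name
        dest_span = size - (gend - gstart)
        chains.append(
            Chain(
                chain_id=str(idx + 1),
                score=1000.0 + idx,
                source_name=name,
                source_size=size,
                source_start=0,
                source_end=size,
                dest_name=dest_name,
                dest_size=shift + dest_span + 50,
                dest_strand="+",
                dest_start=shift,
                dest_end=shift + dest_span,
                blocks=(
                    ChainBlock(gstart, gap_source=gend - gstart, gap_dest=0),
                    ChainBlock(size - gend),
                ),
            )
        )
    chain_file = ChainFile(chains)

    # --- reads over the survivors -------------------------------------------
    survivor_mirnas = [
        (r.expected_name or r.label, r.interval) for r in true_records
    ]
    n_surv = len(survivor_mirnas)
    n_both = min(3, n_surv)
    n_first = min(1, max(0, n_surv - n_both))
    n_second = min(1, max(0, n_surv - n_both - n_first))
    samples, expected_support = build_support_reads(
        rng,
        survivor_mirnas,
        n_both,
        n_first,
        n_second,
        params.n_thyroid_samples,
        params.n_liver_samples,
        read_length=params.read_length,
    )

    # --- write everything ----------------------------------------------------
    genome = builder.finalize()
    paths = InstancePaths(
        root=out,
        genome=out / "genome.fa",
        tblout=out / "hits.tbl",
        repeats=out / "repeats.bed",
        known=out / "known.bed",
        families_dir=out / "families",
        chain=out / "old_to_new.chain",
        reads_dir=out / "reads",
        sample_sheet=out / "samples.tsv",
        manifest=out / "manifest.json",
    )
    write_fasta(sorted(genome.items()), paths.genome)
    order = rng.permutation(len(hits))
    write_cm_tblout(
        [hits[i] for i in order],
        paths.tblout,
        model_names={b.alignment.family_id: b.model_name for b in bundles},
    )
    with open(paths.repeats, "w") as fh:
        for cls, iv in sorted(repeat_tracts, key=lambda t: (t[1].seq_id, t[1].start)):
            fh.write(f"{iv.seq_id}\t{iv.start}\t{iv.end}\t{cls}\t0\t{iv.strand}\n")
    with open(paths.known, "w") as fh:
        for name, iv in sorted(known_entries, key=lambda t: (t[1].seq_id, t[1].start)):
            fh.write(f"{iv.seq_id}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")
    for bundle in bundles:
        write_stockholm(
            bundle.alignment, paths.families_dir / f"{bundle.alignment.family_id}.sto"
        )
    write_chain(chain_file, paths.chain)
    with open(paths.sample_sheet, "w") as fh:
        fh.write("sample_id\ttissue\n")
        for s in samples:
            fh.write(f"{s.sample_id}\t{s.tissue}\n")
    for s in samples:
        with open(paths.reads_dir / f"{s.sample_id}.bed", "w") as fh:
            for j, read in enumerate(
                sorted(s.reads, key=lambda r: (r.seq_id, r.start, r.strand))
            ):
                fh.write(
                    f"{read.seq_id}\t{read.start}\t{read.end}\tread{j}\t0\t{read.strand}\n"
                )

    manifest = TruthManifest(
        seed=seed,
        records=records,
        supported=expected_support,
        chain_dest_names=dest_names,
    )
    manifest.save(paths.manifest)
    return paths, manifest
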