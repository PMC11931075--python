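"""The candidate filter cascade applied to covariance-model hits.

Homology scans of a whole genome with miRNA family covariance models
produce large numbers of significant hits, most of which are not novel
miRNA loci: repeat-derived copies, assembly artifacts on unplaced
scaffolds, opposite-strand shadows of real hits, and re-discoveries of
already annotated genes. This module implements the cascade that reduces
the raw hit table to a candidate set, with per-stage accounting:

1. ``significance``            — e-value and bit-score thresholds; the
   bit-score threshold defaults to ceil(log2(2 * genome size)), the
   database-size-scaled reporting threshold recommended for covariance
   model searches.
2. ``known_overlap``           — drop hits overlapping annotated miRNAs.
3. ``unfinished_duplicates``   — drop scaffold copies of sequences also
   found on primary chromosomes (or on a better-scoring scaffold hit).
4. ``repeat_overlap``          — drop hits overlapping repeat-masked tracts.
5. ``reverse_complement``      — among opposite-strand overlapping hits at
   one locus, keep only the smallest e-value.

Every stage preserves input order and returns an exact partition of its
input, so the cascade report's counts chain consistently.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import pandas as pd

from .errors import ValidationError
from .io_formats import CMHit, GenomicInterval, GenomeStore, RepeatFeature

STAGE_ORDER = (
    "significance",
    "known_overlap",
    "unfinished_duplicates",
    "repeat_overlap",
    "reverse_complement",
)

#: seq_ids NOT of the form chr1..chrNN / chrX / chrY / chrM are treated as
#: unfinished scaffolds by default.
DEFAULT_UNFINISHED_PATTERN = r"^(?!chr(\d+|[XYM])$).*$"


@dataclass
class FilterParams:
    """Thresholds and patterns steering the cascade.

    ``bit_score_cutoff=None`` means "derive from genome size" via
    :func:`compute_bitscore_threshold`.
    """

    e_value_cutoff: float = 0.01
    bit_score_cutoff: float | None = None
    unfinished_pattern: str = DEFAULT_UNFINISHED_PATTERN
    min_repeat_overlap: int = 1

    def __post_init__(self) -> None:
        if self.e_value_cutoff <= 0:
            raise ValidationError("e_value_cutoff must be > 0")
        if self.min_repeat_overlap < 1:
            raise ValidationError("min_repeat_overlap must be >= 1")
        re.compile(self.unfinished_pattern)


@dataclass
class Candidate:
    """A hit that survived the cascade, with its extracted precursor."""

    candidate_id: str
    family_id: str
    interval: GenomicInterval
    bit_score: float
    e_value: float
    sequence: str  # strand-corrected precursor, RNA alphabet
    stages_passed: list[str] = field(default_factory=list)
    name: str | None = None


@dataclass
class StageRecord:
    stage_name: str
    n_in: int
    n_removed: int
    n_out: int
    removed_ids: list[str] = field(default_factory=list)


@dataclass
class FilterReport:
    """Per-stage input/removed/surviving counts for one cascade run."""

    stages: list[StageRecord] = field(default_factory=list)
    parameters: dict = field(default_factory=dict)

    def validate(self) -> None:
        for rec in self.stages:
            if rec.n_out != rec.n_in - rec.n_removed:
                raise ValidationError(f"stage {rec.stage_name}: n_out != n_in - n_removed")
            if rec.n_removed != len(rec.removed_ids):
                raise ValidationError(f"stage {rec.stage_name}: removed_ids length mismatch")
        for prev, cur in zip(self.stages, self.stages[1:]):
            if cur.n_in != prev.n_out:
                raise ValidationError(
                    f"stage {cur.stage_name}: n_in {cur.n_in} != previous n_out {prev.n_out}"
                )

    @property
    def n_final(self) -> int:
        return self.stages[-1].n_out if self.stages else 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.stage_name, r.n_in, r.n_removed, r.n_out) for r in self.stages],
            columns=["stage", "n_in", "n_removed", "n_out"],
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def compute_bitscore_threshold(genome_size: int) -> int:
    """Database-size-scaled reporting threshold: ceil(log2(2 * genome size)).

    For a 2.87 Gb genome this gives 33 bits.
    """
    if genome_size < 1:
        raise ValidationError(f"genome size must be >= 1, got {genome_size}")
    return math.ceil(math.log2(2 * genome_size))


# ---------------------------------------------------------------------------
# Individual stages — each returns (kept, removed), preserving input order
# ---------------------------------------------------------------------------


def filter_significance(
    hits: Sequence[CMHit], params: FilterParams, bit_cutoff: float | None = None
) -> tuple[list[CMHit], list[CMHit]]:
    """Keep hits with e-value <= cutoff and bit score >= cutoff."""
    if bit_cutoff is None:
        bit_cutoff = params.bit_score_cutoff
    if bit_cutoff is None:
        raise ValidationError("bit score cutoff unresolved; pass bit_cutoff or set params")
    kept, removed = [], []
    for h in hits:
        if h.e_value <= params.e_value_cutoff and h.bit_score >= bit_cutoff:
            kept.append(h)
        else:
            removed.append(h)
    return kept, removed


def filter_known_overlaps(
    hits: Sequence[CMHit], known: Sequence[GenomicInterval]
) -> tuple[list[CMHit], list[CMHit]]:
    """Remove hits overlapping any known annotation by >= 1 bp (either strand)."""
    by_seq: dict[str, list[GenomicInterval]] = {}
    for iv in known:
        by_seq.setdefault(iv.seq_id, []).append(iv)
    kept, removed = [], []
    for h in hits:
        anns = by_seq.get(h.target.seq_id, ())
        if any(h.target.overlaps(iv) for iv in anns):
            removed.append(h)
        else:
            kept.append(h)
    return kept, removed


def filter_unfinished_duplicates(
    hits: Sequence[CMHit], genome: GenomeStore, params: FilterParams
) -> tuple[list[CMHit], list[CMHit]]:
    """Remove scaffold hits duplicating a primary-chromosome hit's sequence.

    A hit is removed iff its seq_id matches ``unfinished_pattern`` and its
    strand-corrected sequence is identical to (a) any hit on a primary
    sequence, or (b) a better hit on an unfinished sequence — better
    meaning strictly smaller e-value, or equal e-value and smaller
    deterministic ``(seq_id, start, end, strand)`` key. Primary hits are
    never removed here.
    """
    pattern = re.compile(params.unfinished_pattern)
    seqs = [genome.fetch(h.target) for h in hits]
    unfinished = [bool(pattern.match(h.target.seq_id)) for h in hits]
    primary_seqs = {s for s, u in zip(seqs, unfinished) if not u}
    kept, removed = [], []
    for i, h in enumerate(hits):
        if not unfinished[i]:
            kept.append(h)
            continue
        drop = seqs[i] in primary_seqs
        if not drop:
            for j, g in enumerate(hits):
                if j == i or not unfinished[j] or seqs[j] != seqs[i]:
                    continue
                if g.e_value < h.e_value or (
                    g.e_value == h.e_value and g.sort_key < h.sort_key
                ):
                    drop = True
                    break
        (removed if drop else kept).append(h)
    return kept, removed


def filter_repeat_overlaps(
    hits: Sequence[CMHit], repeats: Sequence[RepeatFeature], params: FilterParams
) -> tuple[list[CMHit], list[CMHit]]:
    """Remove hits overlapping any repeat by >= min_repeat_overlap bp."""
    by_seq: dict[str, list[GenomicInterval]] = {}
    for r in repeats:
        by_seq.setdefault(r.interval.seq_id, []).append(r.interval)
    kept, removed = [], []
    for h in hits:
        tracts = by_seq.get(h.target.seq_id, ())
        if any(h.target.overlap_length(iv) >= params.min_repeat_overlap for iv in tracts):
            removed.append(h)
        else:
            kept.append(h)
    return kept, removed


def filter_reverse_complements(hits: Sequence[CMHit]) -> tuple[list[CMHit], list[CMHit]]:
    """Resolve opposite-strand overlapping hits, keeping the best per locus.

    Conflict edges connect hits on the same sequence whose intervals
    overlap on opposite strands; within each connected component of that
    graph only the hit with the smallest e-value survives (ties: higher
    bit score, then smallest ``(seq_id, start, strand)``).
    """
    graph = nx.Graph()
    graph.add_nodes_from(range(len(hits)))
    by_seq: dict[str, list[int]] = {}
    for i, h in enumerate(hits):
        by_seq.setdefault(h.target.seq_id, []).append(i)
    for idxs in by_seq.values():
        for a_pos, i in enumerate(idxs):
            for j in idxs[a_pos + 1 :]:
                hi, hj = hits[i].target, hits[j].target
                if hi.strand != hj.strand and hi.overlaps(hj):
                    graph.add_edge(i, j)
    drop: set[int] = set()
    for component in nx.connected_components(graph):
        if len(component) < 2:
            continue
        best = min(
            component,
            key=lambda k: (
                hits[k].e_value,
                -hits[k].bit_score,
                (hits[k].target.seq_id, hits[k].target.start, hits[k].target.strand),
            ),
        )
        drop.update(component - {best})
    kept = [h for i, h in enumerate(hits) if i not in drop]
    removed = [h for i, h in enumerate(hits) if i in drop]
    return kept, removed


# ---------------------------------------------------------------------------
# The cascade
# ---------------------------------------------------------------------------


def run_cascade(
    hits: Sequence[CMHit],
    genome: GenomeStore,
    repeats: Sequence[RepeatFeature],
    known: Sequence[GenomicInterval],
    params: FilterParams | None = None,
) -> tuple[list[Candidate], FilterReport]:
    """Apply all five stages in canonical order and account for every hit.

    Returns surviving :class:`Candidate` objects (with strand-corrected
    RNA precursor sequences) and a validated :class:`FilterReport`.
    """
    params = params or FilterParams()
    bit_cutoff = (
        params.bit_score_cutoff
        if params.bit_score_cutoff is not None
        else compute_bitscore_threshold(genome.total_length)
    )
    report = FilterReport(
        parameters={
            "e_value_cutoff": params.e_value_cutoff,
            "bit_score_cutoff": bit_cutoff,
            "unfinished_pattern": params.unfinished_pattern,
            "min_repeat_overlap": params.min_repeat_overlap,
        }
    )
    current = list(hits)

    def record(stage: str, kept: list[CMHit], removed: list[CMHit]) -> list[CMHit]:
        report.stages.append(
            StageRecord(
                stage_name=stage,
                n_in=len(kept) + len(removed),
                n_removed=len(removed),
                n_out=len(kept),
                removed_ids=[h.hit_id for h in removed],
            )
        )
        return kept

    current = record("significance", *filter_significance(current, params, bit_cutoff))
    current = record("known_overlap", *filter_known_overlaps(current, known))
    current = record(
        "unfinished_duplicates", *filter_unfinished_duplicates(current, genome, params)
    )
    current = record("repeat_overlap", *filter_repeat_overlaps(current, repeats, params))
    current = record("reverse_complement", *filter_reverse_complements(current))
    report.validate()

    candidates = [
        Candidate(
            candidate_id=h.hit_id,
            family_id=h.family_id,
            interval=h.target,
            bit_score=h.bit_score,
            e_value=h.e_value,
            sequence=genome.fetch(h.target).replace("T", "U"),
            stages_passed=list(STAGE_ORDER),
        )
        for h in current
    ]
    return candidates, report
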