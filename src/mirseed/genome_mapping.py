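"""Precise coordinate recovery and assembly liftover.

Curated precursor sequences originate from the searched genome itself,
so their exact coordinates can be recovered by ungapped scanning (an
in-package stand-in for a blastn lookup): all occurrences on both
strands, optionally tolerating a few mismatches via pigeonhole
seed-and-verify. Coordinates are projected between assemblies through
UCSC chain files with a strict both-endpoints-in-blocks contract.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .errors import ValidationError
from .io_formats import Chain, ChainFile, GenomicInterval, GenomeStore, reverse_complement

MIN_QUERY_LENGTH = 20


@dataclass(frozen=True)
class SequenceMatch:
    """An ungapped occurrence of a query in the genome."""

    query_id: str
    interval: GenomicInterval
    n_mismatches: int

    def __post_init__(self) -> None:
        if self.n_mismatches < 0:
            raise ValidationError("mismatch count must be >= 0")


def _exact_occurrences(haystack: str, needle: str) -> list[int]:
    out, pos = [], haystack.find(needle)
    while pos != -1:
        out.append(pos)
        pos = haystack.find(needle, pos + 1)
    return out


def _hamming_within(a: str, b: str, limit: int) -> int | None:
    mismatches = 0
    for x, y in zip(a, b):
        if x != y:
            mismatches += 1
            if mismatches > limit:
                return None
    return mismatches


def locate_sequence(
    genome: GenomeStore,
    query: str,
    max_mismatches: int = 0,
    query_id: str = "query",
) -> list[SequenceMatch]:
    """All ungapped occurrences of ``query`` on both strands.

    ``U`` is treated as ``T``. For ``max_mismatches = k > 0`` the scan
    uses k+1 non-overlapping exact seeds of length ``len(query) // (k+1)``
    (pigeonhole: any occurrence with <= k mismatches contains at least
    one exact seed) and verifies each seed extension by Hamming distance.
    Matches are sorted by ``(seq_id, start, strand)``.
    """
    q = query.upper().replace("U", "T")
    if len(q) < MIN_QUERY_LENGTH:
        raise ValidationError(
            f"query length {len(q)} below minimum {MIN_QUERY_LENGTH}"
        )
    patterns = {"+": q, "-": reverse_complement(q)}
    found: set[tuple[str, int, str, int]] = set()
    for seq_id, seq in genome.sequences.items():
        for strand, pattern in patterns.items():
            if max_mismatches == 0:
                for pos in _exact_occurrences(seq, pattern):
                    found.add((seq_id, pos, strand, 0))
                continue
            k = max_mismatches
            seed_len = len(pattern) // (k + 1)
            if seed_len == 0:
                raise ValidationError("query too short for requested mismatch count")
            for s in range(k + 1):
                offset = s * seed_len
                seed = pattern[offset : offset + seed_len]
                for pos in _exact_occurrences(seq, seed):
                    start = pos - offset
                    if start < 0 or start + len(pattern) > len(seq):
                        continue
                    d = _hamming_within(seq[start : start + len(pattern)], pattern, k)
                    if d is not None:
                        found.add((seq_id, start, strand, d))
    matches = [
        SequenceMatch(query_id, GenomicInterval(s, p, p + len(q), strand), d)
        for s, p, strand, d in found
    ]
    matches.sort(key=lambda m: (m.interval.seq_id, m.interval.start, m.interval.strand))
    return matches


# ---------------------------------------------------------------------------
# Liftover through chain files
# ---------------------------------------------------------------------------

UNMAPPED_REASONS = ("no_chain", "endpoint_in_gap", "split_across_chains")


@dataclass(frozen=True)
class LiftoverResult:
    """Either a mapped interval or an unmapped reason (never both)."""

    mapped: GenomicInterval | None
    reason: str | None = None
    chain_id: str | None = None

    @property
    def ok(self) -> bool:
        return self.mapped is not None


def _project_position(chain: Chain, pos: int) -> int | None:
    """Project one source position through a chain; None if it falls in a
    gap. The returned coordinate is in the chain's destination strand
    space."""
    s, d = chain.source_start, chain.dest_start
    for block in chain.blocks:
        if s <= pos < s + block.size:
            return d + (pos - s)
        s += block.size + block.gap_source
        d += block.size + block.gap_dest
    return None


def liftover(interval: GenomicInterval, chains: ChainFile) -> LiftoverResult:
    """Project an interval to the destination assembly.

    Both endpoints must fall inside aligned blocks of the single
    highest-scoring chain that spans the whole interval; a ``-``
    destination strand flips coordinates and strand. Failure is a value
    (``no_chain``, ``split_across_chains`` or ``endpoint_in_gap``), not
    an error.
    """
    overlapping = [
        c
        for c in chains
        if c.source_name == interval.seq_id
        and c.source_start < interval.end
        and interval.start < c.source_end
    ]
    if not overlapping:
        return LiftoverResult(None, reason="no_chain")
    containing = [
        c
        for c in overlapping
        if c.source_start <= interval.start and interval.end <= c.source_end
    ]
    if not containing:
        return LiftoverResult(None, reason="split_across_chains")
    chain = max(containing, key=lambda c: (c.score, c.chain_id))
    first = _project_position(chain, interval.start)
    last = _project_position(chain, interval.end - 1)
    if first is None or last is None:
        return LiftoverResult(None, reason="endpoint_in_gap", chain_id=chain.chain_id)
    if chain.dest_strand == "+":
        mapped = GenomicInterval(chain.dest_name, first, last + 1, interval.strand)
    else:
        fwd_start = chain.dest_size - 1 - last
        fwd_end = chain.dest_size - first
        strand = "-" if interval.strand == "+" else "+"
        mapped = GenomicInterval(chain.dest_name, fwd_start, fwd_end, strand)
    return LiftoverResult(mapped, chain_id=chain.chain_id)


def liftover_all(
    intervals: Sequence[GenomicInterval], chains: ChainFile
) -> list[LiftoverResult]:
    return [liftover(iv, chains) for iv in intervals]
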