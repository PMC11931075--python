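"""Readers and writers for every on-disk format the pipeline touches.

A single internal coordinate convention is used throughout the package:
0-based, half-open intervals with an explicit ``+``/``-`` strand. The
1-based inclusive conventions of covariance-model hit tables, RepeatMasker
``.out`` files and GFF3 are converted at this I/O boundary and nowhere
else. Minus-strand hit-table records (seq-from > seq-to) are normalized at
parse time so that ``start < end`` always holds downstream.

Arm annotations in Stockholm family alignments use this package's own
per-sequence tag dialect::

    #=GS <seqname> MATURE <start>-<end>
    #=GS <seqname> STAR   <start>-<end>

with 0-based half-open *alignment column* coordinates (see README).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import AlignIO, SeqIO
from Bio.Seq import Seq

from .errors import ContractError, FormatError, ValidationError

logger = logging.getLogger("mirseed")

GAP_CHARS = {"-", "."}
RNA_ALPHABET = set("ACGUN") | GAP_CHARS

# Unicode dash glyphs that show up in published tables; normalized on ingest.
_DASH_RE = re.compile("[‐‑‒–—−]")


def normalize_dashes(text: str) -> str:
    """Replace typographic dash glyphs with the ASCII hyphen."""
    return _DASH_RE.sub("-", text)


# ---------------------------------------------------------------------------
# Core domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval with strand.

    Parameters
    ----------
    seq_id :
        Chromosome or scaffold identifier; must be non-empty.
    start, end :
        0-based half-open coordinates, ``0 <= start < end``.
    strand :
        ``"+"`` or ``"-"``; the Unicode minus sign is accepted and
        normalized.
    """

    seq_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.seq_id:
            raise ValidationError("seq_id must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        strand = "-" if self.strand in {"−", "-"} else self.strand
        if strand not in {"+", "-"}:
            raise ValidationError(f"strand must be '+' or '-', got {self.strand!r}")
        object.__setattr__(self, "strand", strand)

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Strand-agnostic overlap by at least one base."""
        return self.seq_id == other.seq_id and self.start < other.end and other.start < self.end

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.seq_id != other.seq_id:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class CMHit:
    """One covariance-model homology hit against the genome."""

    family_id: str
    target: GenomicInterval
    bit_score: float
    e_value: float
    truncation_flag: str = "no"
    model_span: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        if not self.e_value > 0:
            raise ValidationError(f"e-value must be > 0, got {self.e_value}")
        if not (self.bit_score == self.bit_score and abs(self.bit_score) != float("inf")):
            raise ValidationError("bit score must be finite")

    @property
    def hit_id(self) -> str:
        t = self.target
        return f"{self.family_id}@{t.seq_id}:{t.start}-{t.end}:{t.strand}"

    @property
    def sort_key(self) -> tuple:
        t = self.target
        return (t.seq_id, t.start, t.end, t.strand, self.family_id)


@dataclass(frozen=True)
class RepeatFeature:
    """A repeat-masked tract of the genome."""

    interval: GenomicInterval
    repeat_class: str = "Unknown"


@dataclass
class FamilyAlignment:
    """A miRNA family multiple alignment with mature/mature* arm columns.

    ``rows`` is an ordered list of ``(seq_name, aligned_seq)`` with equal
    lengths; ``arm_spans`` maps sequence names to ``(label, start_col,
    end_col)`` triples in 0-based half-open alignment-column coordinates,
    with label ``"mature"`` or ``"mature_star"``.
    """

    family_id: str
    rows: list[tuple[str, str]]
    arm_spans: dict[str, list[tuple[str, int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValidationError("alignment must have at least one row")
        lengths = {len(seq) for _, seq in self.rows}
        if len(lengths) != 1:
            raise FormatError(f"ragged alignment rows, lengths {sorted(lengths)}")
        bad = set("".join(seq for _, seq in self.rows)) - RNA_ALPHABET
        if bad:
            raise ValidationError(f"invalid alignment characters {sorted(bad)}")
        ncol = self.length
        names = {n for n, _ in self.rows}
        for name, spans in self.arm_spans.items():
            if name not in names:
                raise ValidationError(f"arm span for unknown sequence {name!r}")
            for label, start, end in spans:
                if label not in {"mature", "mature_star"}:
                    raise ValidationError(f"unknown arm label {label!r}")
                if not (0 <= start < end <= ncol):
                    raise ValidationError(
                        f"arm span [{start},{end}) outside columns of {name!r}"
                    )

    @property
    def length(self) -> int:
        return len(self.rows[0][1])

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.rows]

    def get_row(self, name: str) -> str:
        for n, seq in self.rows:
            if n == name:
                return seq
        raise KeyError(name)

    def column(self, idx: int) -> list[str]:
        return [seq[idx] for _, seq in self.rows]


@dataclass(frozen=True)
class ChainBlock:
    """One ungapped alignment block followed by gaps to the next block."""

    size: int
    gap_source: int = 0
    gap_dest: int = 0

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValidationError("chain block size must be >= 1")
        if self.gap_source < 0 or self.gap_dest < 0:
            raise ValidationError("chain gaps must be >= 0")


@dataclass(frozen=True)
class Chain:
    """A UCSC liftover chain: colinear blocks from source to destination."""

    chain_id: str
    score: float
    source_name: str
    source_size: int
    source_start: int
    source_end: int
    dest_name: str
    dest_size: int
    dest_strand: str
    dest_start: int
    dest_end: int
    blocks: tuple[ChainBlock, ...]

    def __post_init__(self) -> None:
        span_s = sum(b.size + b.gap_source for b in self.blocks)
        span_d = sum(b.size + b.gap_dest for b in self.blocks)
        if span_s != self.source_end - self.source_start:
            raise ValidationError(
                f"chain {self.chain_id}: source block span {span_s} != "
                f"{self.source_end - self.source_start}"
            )
        if span_d != self.dest_end - self.dest_start:
            raise ValidationError(
                f"chain {self.chain_id}: dest block span {span_d} != "
                f"{self.dest_end - self.dest_start}"
            )


@dataclass
class ChainFile:
    chains: list[Chain]

    def __iter__(self):
        return iter(self.chains)

    def invert(self) -> "ChainFile":
        """Swap source and destination of every chain.

        Only chains whose destination strand is ``+`` can be inverted
        losslessly with this simple swap; a ``-`` destination raises.
        """
        inverted = []
        for c in self.chains:
            if c.dest_strand != "+":
                raise ValidationError(
                    f"chain {c.chain_id}: cannot invert a '-' destination strand"
                )
            blocks = tuple(
                ChainBlock(b.size, gap_source=b.gap_dest, gap_dest=b.gap_source)
                for b in c.blocks
            )
            inverted.append(
                Chain(
                    chain_id=c.chain_id,
                    score=c.score,
                    source_name=c.dest_name,
                    source_size=c.dest_size,
                    source_start=c.dest_start,
                    source_end=c.dest_end,
                    dest_name=c.source_name,
                    dest_size=c.source_size,
                    dest_strand="+",
                    dest_start=c.source_start,
                    dest_end=c.source_end,
                    blocks=blocks,
                )
            )
        return ChainFile(inverted)


# ---------------------------------------------------------------------------
# Genome store
# ---------------------------------------------------------------------------

_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


class GenomeStore:
    """In-memory genome with strand-aware subsequence extraction."""

    def __init__(self, sequences: dict[str, str]):
        self.sequences = {name: seq.upper() for name, seq in sequences.items()}

    @classmethod
    def from_fasta(cls, path: str | Path) -> "GenomeStore":
        records = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
        if not records:
            raise FormatError(f"no FASTA records in {path}")
        return cls(records)

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self.sequences

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def fetch(self, interval: GenomicInterval) -> str:
        """Return the strand-corrected DNA of ``interval`` (5'->3')."""
        try:
            seq = self.sequences[interval.seq_id]
        except KeyError:
            raise KeyError(f"sequence {interval.seq_id!r} absent from genome") from None
        if interval.end > len(seq):
            raise ValidationError(
                f"interval {interval} beyond end of {interval.seq_id} ({len(seq)} bp)"
            )
        sub = seq[interval.start : interval.end]
        return reverse_complement(sub) if interval.strand == "-" else sub


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Covariance-model hit tables (classic 18-column cmsearch --tblout)
# ---------------------------------------------------------------------------


def read_cm_tblout(path: str | Path) -> list[CMHit]:
    """Parse a cmsearch ``--tblout`` hit table.

    Input coordinates are 1-based inclusive; records with seq-from >
    seq-to are minus-strand hits and are normalized to ``start < end``
    with strand ``-``. The family identifier is the query accession when
    present, otherwise the query name.
    """
    hits: list[CMHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 17:
                raise FormatError(
                    f"{path}:{lineno}: expected >= 17 whitespace-separated "
                    f"fields, got {len(fields)}"
                )
            try:
                target_name = fields[0]
                query_name, query_acc = fields[2], fields[3]
                mdl_from, mdl_to = int(fields[5]), int(fields[6])
                seq_from, seq_to = int(fields[7]), int(fields[8])
                strand_col = normalize_dashes(fields[9])
                trunc = fields[10]
                score = float(fields[14])
                e_value = float(fields[15])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: malformed record ({exc})") from None
            if e_value <= 0:
                raise ValidationError(f"{path}:{lineno}: non-positive e-value {e_value}")
            if seq_from > seq_to:
                strand = "-"
                start, end = seq_to - 1, seq_from
            else:
                strand = "-" if strand_col == "-" else "+"
                start, end = seq_from - 1, seq_to
            family_id = query_acc if query_acc not in {"-", ""} else query_name
            hits.append(
                CMHit(
                    family_id=family_id,
                    target=GenomicInterval(target_name, start, end, strand),
                    bit_score=score,
                    e_value=e_value,
                    truncation_flag=trunc,
                    model_span=(mdl_from, mdl_to),
                )
            )
    return hits


def write_cm_tblout(hits: Sequence[CMHit], path: str | Path,
                    model_names: dict[str, str] | None = None) -> None:
    """Write hits back out in the classic tblout layout (for round trips
    and synthetic instances)."""
    model_names = model_names or {}
    with open(path, "w") as fh:
        fh.write("#target name\taccession\tquery name\taccession\tmdl\tmdl from\t"
                 "mdl to\tseq from\tseq to\tstrand\ttrunc\tpass\tgc\tbias\tscore\t"
                 "E-value\tinc\tdescription of target\n".replace("\t", " "))
        for h in hits:
            t = h.target
            if t.strand == "-":
                seq_from, seq_to = t.end, t.start + 1
            else:
                seq_from, seq_to = t.start + 1, t.end
            qname = model_names.get(h.family_id, h.family_id)
            fh.write(
                f"{t.seq_id} - {qname} {h.family_id} cm "
                f"{h.model_span[0]} {h.model_span[1]} {seq_from} {seq_to} "
                f"{t.strand} {h.truncation_flag} 1 0.45 0.0 "
                f"{h.bit_score:.1f} {h.e_value:.3g} ! -\n"
            )


# ---------------------------------------------------------------------------
# Stockholm family alignments
# ---------------------------------------------------------------------------

_ARM_TAG_RE = re.compile(r"^#=GS\s+(\S+)\s+(MATURE|STAR)\s+(\d+)-(\d+)\s*$")
_ARM_LABELS = {"MATURE": "mature", "STAR": "mature_star"}


def read_stockholm(path: str | Path, family_id: str | None = None) -> FamilyAlignment:
    """Read a Stockholm 1.0 family alignment with optional arm tags.

    ``T`` is normalized to ``U``; sequences are upper-cased. A family
    lacking arm annotations parses fine with empty ``arm_spans`` and a
    logged warning.
    """
    path = Path(path)
    text = path.read_text()
    if not text.startswith("# STOCKHOLM 1.0"):
        raise FormatError(f"{path}: missing Stockholm 1.0 header")
    try:
        aln = AlignIO.read(str(path), "stockholm")
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from None
    rows = [(rec.id, str(rec.seq).upper().replace("T", "U")) for rec in aln]
    arm_spans: dict[str, list[tuple[str, int, int]]] = {}
    fam = family_id
    for line in text.splitlines():
        m = _ARM_TAG_RE.match(line)
        if m:
            name, tag, start, end = m.group(1), m.group(2), int(m.group(3)), int(m.group(4))
            arm_spans.setdefault(name, []).append((_ARM_LABELS[tag], start, end))
        elif line.startswith("#=GF ID") and fam is None:
            fam = line.split(None, 2)[2].strip()
        elif line.startswith("#=GF AC"):
            fam = line.split(None, 2)[2].strip()
    if not arm_spans:
        logger.warning("%s: no MATURE/STAR arm annotations found", path)
    return FamilyAlignment(family_id=fam or path.stem, rows=rows, arm_spans=arm_spans)


def write_stockholm(aln: FamilyAlignment, path: str | Path) -> None:
    """Write a single-block Stockholm 1.0 file with the package's arm tags."""
    name_w = max(len(n) for n, _ in aln.rows) + 2
    with open(path, "w") as fh:
        fh.write("# STOCKHOLM 1.0\n")
        fh.write(f"#=GF AC {aln.family_id}\n")
        for name, spans in sorted(aln.arm_spans.items()):
            for label, start, end in spans:
                tag = "MATURE" if label == "mature" else "STAR"
                fh.write(f"#=GS {name} {tag} {start}-{end}\n")
        for name, seq in aln.rows:
            fh.write(f"{name.ljust(name_w)}{seq}\n")
        fh.write("//\n")


# ---------------------------------------------------------------------------
# Repeat annotations
# ---------------------------------------------------------------------------


def read_repeats(path: str | Path, dialect: str = "bed") -> list[RepeatFeature]:
    """Read repeat annotations from BED or RepeatMasker ``.out``.

    Both dialects are converted to 0-based half-open intervals
    (RepeatMasker ``.out`` begin/end are 1-based inclusive).
    """
    if dialect not in {"bed", "rmout"}:
        raise ValidationError(f"unknown repeat dialect {dialect!r}")
    feats: list[RepeatFeature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith(("#", "track")):
                continue
            fields = stripped.split()
            if dialect == "bed":
                try:
                    seq_id, start, end = fields[0], int(fields[1]), int(fields[2])
                except (IndexError, ValueError) as exc:
                    raise FormatError(f"{path}:{lineno}: malformed BED line ({exc})") from None
                cls = fields[3] if len(fields) > 3 else "Unknown"
                feats.append(RepeatFeature(GenomicInterval(seq_id, start, end), cls))
            else:
                # .out header lines start with column titles; skip anything
                # whose first field is not a Smith-Waterman score.
                if not fields[0].isdigit():
                    continue
                try:
                    seq_id = fields[4]
                    begin, end = int(fields[5]), int(fields[6])
                    cls = fields[10] if len(fields) > 10 else "Unknown"
                except (IndexError, ValueError) as exc:
                    raise FormatError(f"{path}:{lineno}: malformed .out record ({exc})") from None
                feats.append(RepeatFeature(GenomicInterval(seq_id, begin - 1, end), cls))
    return feats


# ---------------------------------------------------------------------------
# Annotation output (GFF3 / BED) and simple interval input
# ---------------------------------------------------------------------------

GFF3_TYPE = "miRNA_primary_transcript"


def write_annotations(candidates: Sequence, fmt: str, path: str | Path) -> None:
    """Write named, coordinate-resolved candidates as GFF3 or BED6.

    GFF3 is 1-based inclusive with type ``miRNA_primary_transcript``; BED
    stays 0-based half-open. Output is deterministically sorted by
    ``(seq_id, start, end, name)``.
    """
    if fmt not in {"gff3", "bed"}:
        raise ValidationError(f"unknown annotation format {fmt!r}")
    resolved = []
    for cand in candidates:
        name = getattr(cand, "name", None)
        interval = getattr(cand, "interval", None)
        if interval is None and isinstance(cand, tuple):
            name, interval = cand
        if not name:
            raise ContractError("cannot write an unnamed candidate")
        resolved.append((interval.seq_id, interval.start, interval.end, name, interval))
    resolved.sort(key=lambda r: r[:4])
    with open(path, "w") as fh:
        if fmt == "gff3":
            fh.write("##gff-version 3\n")
            for seq_id, start, end, name, iv in resolved:
                attrs = f"ID={name};Name={name}"
                fh.write(
                    f"{seq_id}\tmirseed\t{GFF3_TYPE}\t{start + 1}\t{end}\t.\t"
                    f"{iv.strand}\t.\t{attrs}\n"
                )
        else:
            fh.write('track name="mirseed" description="miRNA annotations"\n')
            for seq_id, start, end, name, iv in resolved:
                fh.write(f"{seq_id}\t{start}\t{end}\t{name}\t0\t{iv.strand}\n")


def read_annotations(path: str | Path, fmt: str) -> list[tuple[str, GenomicInterval]]:
    """Read ``(name, interval)`` pairs from GFF3 or BED6 (round-trip of
    :func:`write_annotations`, and loader for known-annotation inputs)."""
    if fmt not in {"gff3", "bed"}:
        raise ValidationError(f"unknown annotation format {fmt!r}")
    out: list[tuple[str, GenomicInterval]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith(("#", "track", "browser")):
                continue
            fields = stripped.split("\t") if "\t" in stripped else stripped.split()
            try:
                if fmt == "gff3":
                    seq_id = fields[0]
                    start, end = int(fields[3]) - 1, int(fields[4])
                    strand = fields[6]
                    name = "."
                    for kv in fields[8].split(";"):
                        if kv.startswith("Name="):
                            name = kv[5:]
                    out.append((name, GenomicInterval(seq_id, start, end, strand)))
                else:
                    seq_id, start, end = fields[0], int(fields[1]), int(fields[2])
                    name = fields[3] if len(fields) > 3 else "."
                    strand = fields[5] if len(fields) > 5 else "+"
                    out.append((name, GenomicInterval(seq_id, start, end, strand)))
            except (IndexError, ValueError) as exc:
                raise FormatError(f"{path}:{lineno}: malformed {fmt} line ({exc})") from None
    return out


def read_bed_intervals(path: str | Path) -> list[GenomicInterval]:
    return [iv for _, iv in read_annotations(path, "bed")]


# ---------------------------------------------------------------------------
# UCSC chain files
# ---------------------------------------------------------------------------


def read_chain(path: str | Path) -> ChainFile:
    """Parse a UCSC chain file, validating block-span bookkeeping."""
    chains: list[Chain] = []
    header: list[str] | None = None
    blocks: list[tuple[int, int, int]] = []
    closed = True

    def finish() -> None:
        nonlocal header, blocks, closed
        assert header is not None
        (_, score, t_name, t_size, t_strand, t_start, t_end,
         q_name, q_size, q_strand, q_start, q_end, chain_id) = header
        if t_strand != "+":
            raise FormatError(f"chain {chain_id}: source strand must be '+'")
        chain_blocks = tuple(
            ChainBlock(size, gap_source=dt, gap_dest=dq) for size, dt, dq in blocks
        )
        chains.append(
            Chain(
                chain_id=str(chain_id),
                score=float(score),
                source_name=t_name,
                source_size=int(t_size),
                source_start=int(t_start),
                source_end=int(t_end),
                dest_name=q_name,
                dest_size=int(q_size),
                dest_strand=q_strand,
                dest_start=int(q_start),
                dest_end=int(q_end),
                blocks=chain_blocks,
            )
        )
        header, blocks, closed = None, [], True

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if stripped.startswith("#"):
                continue
            if not stripped:
                continue
            fields = stripped.split()
            if fields[0] == "chain":
                if not closed:
                    raise FormatError(f"{path}:{lineno}: chain starts before previous one ended")
                if len(fields) != 13:
                    raise FormatError(f"{path}:{lineno}: chain header needs 13 fields")
                header = fields
                closed = False
            else:
                if header is None:
                    raise FormatError(f"{path}:{lineno}: block line outside a chain")
                try:
                    nums = [int(x) for x in fields]
                except ValueError:
                    raise FormatError(f"{path}:{lineno}: non-integer block line") from None
                if len(nums) == 3:
                    blocks.append((nums[0], nums[1], nums[2]))
                elif len(nums) == 1:
                    blocks.append((nums[0], 0, 0))
                    finish()
                else:
                    raise FormatError(f"{path}:{lineno}: block line needs 1 or 3 integers")
    if not closed:
        raise ValidationError(f"{path}: truncated chain {header[12]}")
    if not chains:
        raise FormatError(f"{path}: no chains found")
    return ChainFile(chains)


def write_chain(chain_file: ChainFile, path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in chain_file.chains:
            fh.write(
                f"chain {c.score:.0f} {c.source_name} {c.source_size} + "
                f"{c.source_start} {c.source_end} {c.dest_name} {c.dest_size} "
                f"{c.dest_strand} {c.dest_start} {c.dest_end} {c.chain_id}\n"
            )
            for b in c.blocks[:-1]:
                fh.write(f"{b.size} {b.gap_source} {b.gap_dest}\n")
            fh.write(f"{c.blocks[-1].size}\n\n")
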