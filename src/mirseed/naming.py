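"""miRBase-style naming of homology-derived miRNA candidates.

Accepted candidates are named after their closest homolog in the family
(for rat, typically the mouse member): the species prefix is swapped to
``rno`` and paralog conflicts are resolved the way miRBase does —
identical mature sequences at distinct loci get numeric copy indices
(``-1``, ``-2``, ... in genomic order), diverged mature sequences get
letter variants (``a``, ``b``, ...). Renaming of previously misassigned
annotations is strictly table-driven; the packaged rename table for rat
ships with the package data.

The module also provides subtype diagnostics: alignment columns at which
two paralog lineages of a family differ cleanly, and majority-vote
classification of a new candidate into one of the lineages.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import ContractError, FormatError, ValidationError
from .io_formats import FamilyAlignment, GAP_CHARS, normalize_dashes

_NAME_RE = re.compile(
    r"^([A-Za-z]{3,4})-((?:mir|miR|let|lin)-\d+)([a-z])?(?:-(\d+))?$"
)


@dataclass(frozen=True)
class NameRecord:
    """A decomposed miRBase-style name: prefix-base[letter][-copy]."""

    species_prefix: str
    base: str
    letter_variant: str | None = None
    copy_index: int | None = None

    def __post_init__(self) -> None:
        if self.copy_index is not None and self.copy_index < 1:
            raise ValidationError("copy index must be a positive integer")

    def render(self) -> str:
        text = f"{self.species_prefix}-{self.base}{self.letter_variant or ''}"
        if self.copy_index is not None:
            text += f"-{self.copy_index}"
        return text

    def __str__(self) -> str:
        return self.render()


def parse_name(text: str) -> NameRecord:
    """Parse a miRBase-style name, tolerating typographic dashes."""
    if not text:
        raise FormatError("empty miRNA name")
    normalized = normalize_dashes(text.strip())
    m = _NAME_RE.match(normalized)
    if not m:
        raise FormatError(f"cannot parse miRNA name {text!r}")
    prefix, base, letter, copy = m.groups()
    return NameRecord(
        species_prefix=prefix,
        base=base,
        letter_variant=letter,
        copy_index=int(copy) if copy else None,
    )


# ---------------------------------------------------------------------------
# Rename tables
# ---------------------------------------------------------------------------


@dataclass
class RenameTable:
    """Ordered (previous_name, updated_name, family_id) rename directives."""

    pairs: list[tuple[str, str, str]]

    def __post_init__(self) -> None:
        prev = [p for p, _, _ in self.pairs]
        if len(prev) != len(set(prev)):
            raise ValidationError("previous names in a rename table must be unique")

    @property
    def mapping(self) -> dict[str, str]:
        return {p: u for p, u, _ in self.pairs}

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RenameTable":
        pairs = []
        with open(path) as fh:
            for line in fh:
                stripped = line.strip()
                if not stripped or stripped.startswith("#"):
                    continue
                fields = [normalize_dashes(f.strip()) for f in stripped.split("\t")]
                if fields[0].lower().startswith("previous"):
                    continue
                if len(fields) < 3:
                    raise FormatError(f"rename table line needs 3 columns: {line!r}")
                pairs.append((fields[0], fields[1], fields[2]))
        return cls(pairs)


def load_packaged_rename_table() -> RenameTable:
    """The curated rat rename table shipped with the package."""
    ref = resources.files("mirseed.data").joinpath("rno_rename_table.tsv")
    with resources.as_file(ref) as path:
        return RenameTable.from_tsv(path)


def apply_renaming(annotations: Sequence[str], table: RenameTable) -> tuple[list[str], int]:
    """Rewrite every annotation name found in the table; return the
    updated list and the number of records changed.

    Deterministic and order-independent: each name is looked up
    individually against the (validated, injective) previous-name map.
    """
    mapping = table.mapping
    updated, n_changed = [], 0
    for name in annotations:
        key = normalize_dashes(name)
        if key in mapping:
            updated.append(mapping[key])
            n_changed += 1
        else:
            updated.append(name)
    return updated, n_changed


# ---------------------------------------------------------------------------
# Assigning names to new candidates
# ---------------------------------------------------------------------------


def assign_name(
    candidate,
    homolog_names: Sequence[NameRecord],
    existing_species_names: Sequence[NameRecord],
    identical_mature: bool,
    species_prefix: str = "rno",
) -> NameRecord:
    """Name one accepted candidate after its best homolog.

    ``homolog_names`` is ordered best-first (highest mature-region
    identity; ties by full-precursor identity, then lexical); the base
    and letter variant of the first entry are adopted. If the species
    already uses that base+letter: identical mature sequences get the
    smallest free copy index (a bare existing name implicitly occupies
    index 1), diverged matures get the next free letter variant. The
    result never collides with ``existing_species_names``.
    """
    if not homolog_names:
        raise ContractError("no homolog names provided")
    hom = homolog_names[0]
    base, letter = hom.base, hom.letter_variant
    existing = list(existing_species_names)
    same_locus = [
        n
        for n in existing
        if n.species_prefix == species_prefix
        and n.base == base
        and n.letter_variant == letter
    ]
    if not same_locus:
        return NameRecord(species_prefix, base, letter, None)
    if identical_mature:
        used = {n.copy_index if n.copy_index is not None else 1 for n in same_locus}
        idx = 1
        while idx in used:
            idx += 1
        return NameRecord(species_prefix, base, letter, idx)
    used_letters = {
        n.letter_variant
        for n in existing
        if n.species_prefix == species_prefix and n.base == base and n.letter_variant
    }
    for variant in "abcdefghijklmnopqrstuvwxyz":
        if variant not in used_letters and variant != letter:
            return NameRecord(species_prefix, base, variant, None)
    raise ValidationError(f"letter variants exhausted for {species_prefix}-{base}")


def assign_names(
    entries: Sequence[tuple[object, NameRecord, str]],
    existing_species_names: Sequence[NameRecord],
    species_prefix: str = "rno",
) -> list[NameRecord]:
    """Batch naming of accepted candidates in genomic order.

    ``entries`` are ``(candidate, best_homolog, mature_sequence)``
    triples already sorted by genomic coordinate. Candidates sharing a
    base+letter are copy-indexed ``-1, -2, ...`` when their matures are
    identical (even when no prior name exists, so two new identical loci
    never produce a bare name plus an indexed one) and lettered when they
    diverge. Assigned names are injective and avoid all existing names.
    """
    existing = list(existing_species_names)
    # group in-run candidates by proposed base+letter
    groups: dict[tuple[str, str | None], list[int]] = {}
    for idx, (_, hom, _) in enumerate(entries):
        groups.setdefault((hom.base, hom.letter_variant), []).append(idx)

    assigned: dict[int, NameRecord] = {}
    for (base, letter), idxs in groups.items():
        prior = [
            n
            for n in existing
            if n.species_prefix == species_prefix
            and n.base == base
            and n.letter_variant == letter
        ]
        matures = [entries[i][2] for i in idxs]
        all_identical = len(set(matures)) == 1
        if len(idxs) > 1 and all_identical and not prior:
            for copy, i in enumerate(idxs, start=1):
                assigned[i] = NameRecord(species_prefix, base, letter, copy)
                existing.append(assigned[i])
            continue
        for pos, i in enumerate(idxs):
            identical = all_identical if len(idxs) > 1 else bool(prior)
            # against pre-existing names, treat "identical mature" as given
            # by the caller's grouping: same mature as the previous locus
            if pos > 0:
                identical = matures[pos] == matures[0]
            name = assign_name(
                entries[i][0], [NameRecord(species_prefix, base, letter)],
                existing, identical, species_prefix,
            )
            assigned[i] = name
            existing.append(name)
    return [assigned[i] for i in range(len(entries))]


def choose_homolog(
    candidate_row: str,
    aln: FamilyAlignment,
    mature_columns: Sequence[int],
    parseable_only: bool = True,
) -> list[NameRecord]:
    """Rank family members as naming homologs for an inserted candidate.

    Ranking: highest mature-column identity, then highest full-row
    identity, then lexically smallest name. Returns parsed names,
    best first.
    """
    cand = aln.get_row(candidate_row)

    def identity(seq: str, cols: Iterable[int]) -> float:
        cols = list(cols)
        if not cols:
            return 0.0
        hits = sum(
            1
            for c in cols
            if cand[c] == seq[c] and cand[c] not in GAP_CHARS
        )
        return hits / len(cols)

    ranked = []
    for name, seq in aln.rows:
        if name == candidate_row:
            continue
        try:
            record = parse_name(name)
        except FormatError:
            if parseable_only:
                continue
            raise
        ranked.append(
            (
                -identity(seq, mature_columns),
                -identity(seq, range(aln.length)),
                name,
                record,
            )
        )
    if not ranked:
        raise ContractError("no parseable homolog names in family alignment")
    ranked.sort(key=lambda t: t[:3])
    return [record for _, _, _, record in ranked]


# ---------------------------------------------------------------------------
# Subtype diagnostics (paralog lineages within a family)
# ---------------------------------------------------------------------------


def identify_diagnostic_columns(
    aln: FamilyAlignment, subtype_labels: Mapping[str, str]
) -> list[int]:
    """Columns at which two subtypes are each unanimous (non-gap) and
    differ from one another; ascending order."""
    groups: dict[str, list[str]] = {"A": [], "B": []}
    for name, seq in aln.rows:
        label = subtype_labels.get(name)
        if label in groups:
            groups[label].append(seq)
    if len(groups["A"]) < 2 or len(groups["B"]) < 2:
        raise ContractError("each subtype needs at least 2 members")
    cols = []
    for col in range(aln.length):
        chars_a = {seq[col] for seq in groups["A"]}
        chars_b = {seq[col] for seq in groups["B"]}
        if (
            len(chars_a) == 1
            and len(chars_b) == 1
            and not chars_a & GAP_CHARS
            and not chars_b & GAP_CHARS
            and chars_a != chars_b
        ):
            cols.append(col)
    return cols


@dataclass
class DiagnosticProfile:
    """Diagnostic columns plus each subtype's character there."""

    columns: list[int]
    chars: dict[int, tuple[str, str]] = field(default_factory=dict)  # col -> (A, B)


def build_diagnostic_profile(
    aln: FamilyAlignment, subtype_labels: Mapping[str, str]
) -> DiagnosticProfile:
    cols = identify_diagnostic_columns(aln, subtype_labels)
    chars = {}
    rows = dict(aln.rows)
    a_name = next(n for n, l in subtype_labels.items() if l == "A" and n in rows)
    b_name = next(n for n, l in subtype_labels.items() if l == "B" and n in rows)
    for col in cols:
        chars[col] = (rows[a_name][col], rows[b_name][col])
    return DiagnosticProfile(columns=cols, chars=chars)


def classify_subtype(candidate_row: str, diagnostic: DiagnosticProfile) -> str:
    """Majority vote of a candidate's aligned row over diagnostic columns.

    Returns ``"A"``, ``"B"`` or ``"ambiguous"`` (tie, or more than half
    of the diagnostic positions gapped in the candidate).
    """
    if not diagnostic.columns:
        raise ContractError("empty diagnostic profile")
    gaps = sum(1 for col in diagnostic.columns if candidate_row[col] in GAP_CHARS)
    if 2 * gaps > len(diagnostic.columns):
        return "ambiguous"
    votes_a = votes_b = 0
    for col in diagnostic.columns:
        c = candidate_row[col]
        char_a, char_b = diagnostic.chars[col]
        if c == char_a:
            votes_a += 1
        elif c == char_b:
            votes_b += 1
    if votes_a > votes_b:
        return "A"
    if votes_b > votes_a:
        return "B"
    return "ambiguous"
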