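"""Hairpin-structure and conservation curation of filtered candidates.

The curation that separates genuine pre-miRNA candidates from spurious
homology hits asks two qualitative questions: does the candidate fold
into a single stem-loop (hairpin), and are its mature and/or mature*
regions conserved within the family alignment? This module
operationalizes both with exact, dependency-free primitives:

* folding is nested base-pair *maximization* (dynamic programming over
  Watson-Crick plus G·U wobble pairs with a minimum hairpin-loop size),
  not thermodynamic free-energy minimization — the criterion being
  qualitative, an exact and enumeration-checkable optimum is preferred;
* conservation is column identity to the modal character of the family
  members over the family's consensus arm columns, after the candidate
  is inserted into the alignment by global alignment to the family
  consensus.

This is an explicit in-package surrogate for external family-curation
tools; it does not reproduce their precursor-correction moves.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from Bio import Align

from .candidate_filter import Candidate
from .errors import ContractError, ValidationError
from .io_formats import FamilyAlignment, GAP_CHARS

ALLOWED_PAIRS = frozenset({"AU", "UA", "GC", "CG", "GU", "UG"})
FOLD_ALPHABET = set("ACGUN")


@dataclass
class CurationParams:
    """Thresholds of the hairpin/conservation screen (all configurable)."""

    min_loop: int = 3
    min_paired_fraction: float = 0.5
    min_stem_pairs: int = 14
    max_stems: int = 1
    min_conservation: float = 0.75
    allowed_pairs: frozenset = ALLOWED_PAIRS

    def __post_init__(self) -> None:
        if self.min_loop < 0 or self.min_stem_pairs < 0 or self.max_stems < 1:
            raise ValidationError("invalid curation thresholds")
        if not (0 <= self.min_paired_fraction <= 1 and 0 <= self.min_conservation <= 1):
            raise ValidationError("fractions must lie in [0, 1]")


@dataclass
class HairpinStructure:
    """A nested secondary structure with stem/loop descriptors."""

    sequence: str
    dot_bracket: str
    pairs: list[tuple[int, int]]
    n_pairs: int = field(init=False)
    paired_fraction: float = field(init=False)
    n_stem_loops: int = field(init=False)
    loop_size: int = field(init=False)
    stem_length: int = field(init=False)

    def __post_init__(self) -> None:
        n = len(self.sequence)
        if len(self.dot_bracket) != n:
            raise ValidationError("dot-bracket length mismatch")
        self.n_pairs = len(self.pairs)
        self.paired_fraction = 2 * self.n_pairs / n if n else 0.0
        innermost = [
            (i, j)
            for (i, j) in self.pairs
            if not any(i < a and b < j for (a, b) in self.pairs)
        ]
        self.n_stem_loops = len(innermost)
        self.loop_size = min((j - i - 1 for i, j in innermost), default=0)
        self.stem_length = self._max_nesting_depth()

    def _max_nesting_depth(self) -> int:
        """Pairs in the longest chain of nested pairs (one helix stack,
        bulges and internal loops allowed)."""
        depth = best = 0
        for ch in self.dot_bracket:
            if ch == "(":
                depth += 1
                best = max(best, depth)
            elif ch == ")":
                depth -= 1
        return best


def fold_max_pairing(
    seq: str, min_loop: int = 3, allowed_pairs: frozenset = ALLOWED_PAIRS
) -> HairpinStructure:
    """Maximum-cardinality nested pairing of an RNA sequence.

    Dynamic programming over all nested structures whose hairpin loops
    span at least ``min_loop`` unpaired bases; ``N`` pairs with nothing.
    Among co-optimal structures the traceback deterministically prefers
    pairing the outermost ends ``(i, j)`` over leaving ``i`` unpaired or
    bifurcating.
    """
    seq = seq.upper()
    bad = set(seq) - FOLD_ALPHABET
    if bad:
        raise ValidationError(f"invalid RNA characters {sorted(bad)}")
    n = len(seq)
    if n < min_loop + 2:
        raise ValidationError(f"sequence of length {n} too short to fold (min_loop={min_loop})")

    def can_pair(i: int, j: int) -> bool:
        return seq[i] + seq[j] in allowed_pairs

    m = [[0] * n for _ in range(n)]
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = m[i + 1][j]
            for k in range(i + min_loop + 1, j + 1):
                if can_pair(i, k):
                    inner = m[i + 1][k - 1] if k - 1 > i + 1 else 0
                    rest = m[k + 1][j] if k + 1 < j else 0
                    best = max(best, 1 + inner + rest)
            m[i][j] = best

    pairs: list[tuple[int, int]] = []
    stack = [(0, n - 1)] if n else []
    while stack:
        i, j = stack.pop()
        if j - i <= min_loop:
            continue
        score = m[i][j]
        if score == 0:
            continue
        inner_ij = m[i + 1][j - 1] if j - 1 > i + 1 else 0
        if can_pair(i, j) and score == inner_ij + 1:
            pairs.append((i, j))
            stack.append((i + 1, j - 1))
            continue
        if score == m[i + 1][j]:
            stack.append((i + 1, j))
            continue
        for k in range(j - 1, i + min_loop, -1):
            inner = m[i + 1][k - 1] if k - 1 > i + 1 else 0
            rest = m[k + 1][j] if k + 1 < j else 0
            if can_pair(i, k) and score == 1 + inner + rest:
                pairs.append((i, k))
                stack.append((i + 1, k - 1))
                stack.append((k + 1, j))
                break
        else:  # pragma: no cover - DP recurrence guarantees a branch
            raise AssertionError("traceback failed")

    pairs.sort()
    db = ["."] * n
    for i, j in pairs:
        db[i], db[j] = "(", ")"
    return HairpinStructure(sequence=seq, dot_bracket="".join(db), pairs=pairs)


def classify_hairpin(
    structure: HairpinStructure, params: CurationParams | None = None
) -> tuple[bool, list[str]]:
    """Decide whether a folded structure is a single qualifying hairpin.

    Returns ``(ok, reasons)`` where ``reasons`` lists every failed
    criterion (empty when ok).
    """
    params = params or CurationParams()
    reasons: list[str] = []
    if structure.n_pairs == 0:
        reasons.append("hairpin: no base pairs")
    elif structure.n_stem_loops > params.max_stems:
        reasons.append(f"hairpin: multiple stems ({structure.n_stem_loops} stem-loops)")
    if structure.n_pairs < params.min_stem_pairs:
        reasons.append(
            f"hairpin: too few pairs ({structure.n_pairs} < {params.min_stem_pairs})"
        )
    if structure.paired_fraction < params.min_paired_fraction:
        reasons.append(
            f"hairpin: low paired fraction ({structure.paired_fraction:.2f} "
            f"< {params.min_paired_fraction})"
        )
    return (not reasons, reasons)


# ---------------------------------------------------------------------------
# Conservation within the family alignment
# ---------------------------------------------------------------------------


def _modal_char(chars: Sequence[str]) -> str | None:
    """Modal non-gap character of a column; ties broken lexicographically;
    None for an all-gap column."""
    counts = Counter(c for c in chars if c not in GAP_CHARS)
    if not counts:
        return None
    top = max(counts.values())
    return min(c for c, n in counts.items() if n == top)


def conservation_profile(aln: FamilyAlignment) -> list[float]:
    """Per-column fraction of non-gap characters equal to the modal
    non-gap character; all-gap columns score 0."""
    if len(aln.rows) < 2:
        raise ContractError("conservation undefined for a single-row alignment")
    profile = []
    for col in range(aln.length):
        chars = aln.column(col)
        non_gap = [c for c in chars if c not in GAP_CHARS]
        if not non_gap:
            profile.append(0.0)
            continue
        modal = _modal_char(chars)
        profile.append(sum(1 for c in non_gap if c == modal) / len(non_gap))
    return profile


def family_arm_columns(
    aln: FamilyAlignment, arm: str, exclude: set[str] | None = None
) -> list[int]:
    """Consensus arm columns: those covered by at least half of the member
    arm annotations for ``arm``."""
    exclude = exclude or set()
    spans = [
        (start, end)
        for name, entries in aln.arm_spans.items()
        if name not in exclude
        for label, start, end in entries
        if label == arm
    ]
    if not spans:
        raise ContractError(f"family {aln.family_id}: no {arm} arm annotations")
    coverage = Counter()
    for start, end in spans:
        for col in range(start, end):
            coverage[col] += 1
    n = len(spans)
    return sorted(col for col, cov in coverage.items() if 2 * cov >= n)


def mature_conservation_score(
    aln: FamilyAlignment, candidate_row: str, arm: str = "mature"
) -> float:
    """Identity of a candidate to the family modal character over the
    family's consensus arm columns.

    ``candidate_row`` names the candidate's row in ``aln`` (it must
    already be inserted, e.g. via :func:`align_candidate`); the modal
    character at each column is computed over the *other* rows.
    """
    if arm not in {"mature", "mature_star"}:
        raise ValidationError(f"unknown arm {arm!r}")
    cand_seq = aln.get_row(candidate_row)
    cols = family_arm_columns(aln, arm, exclude={candidate_row})
    members = [seq for name, seq in aln.rows if name != candidate_row]
    if not members:
        raise ContractError("alignment contains only the candidate")
    matches = 0
    for col in cols:
        modal = _modal_char([seq[col] for seq in members])
        c = cand_seq[col]
        if modal is not None and c not in GAP_CHARS and c == modal:
            matches += 1
    return matches / len(cols)


# ---------------------------------------------------------------------------
# Inserting a candidate into the family alignment
# ---------------------------------------------------------------------------


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -1
    return aligner


def align_candidate(
    aln: FamilyAlignment, candidate_seq: str, candidate_name: str = "candidate"
) -> FamilyAlignment:
    """Insert a candidate into a family alignment.

    The candidate is globally aligned to the family's ungapped consensus
    (match +1, mismatch -1, gap open -5, gap extend -1) and projected back
    onto alignment columns. Existing columns are unchanged; candidate
    insertions relative to the consensus become new all-gap columns for
    the existing rows, and member arm spans are remapped accordingly.
    """
    if not candidate_seq:
        raise ValidationError("empty candidate sequence")
    candidate_seq = candidate_seq.upper().replace("T", "U")
    if candidate_name in aln.names:
        raise ValidationError(f"row {candidate_name!r} already present")

    # consensus over non-all-gap columns, remembering each consensus
    # position's source column
    cons_chars: list[str] = []
    cons_cols: list[int] = []
    for col in range(aln.length):
        modal = _modal_char(aln.column(col))
        if modal is not None:
            cons_chars.append(modal)
            cons_cols.append(col)
    consensus = "".join(cons_chars)

    alignment = _aligner().align(consensus, candidate_seq)[0]
    # per consensus position: candidate char or None; plus insertions
    # keyed by the consensus position they follow (-1 = before the first)
    cand_at: dict[int, str] = {}
    insertions: dict[int, str] = {}
    ci = qi = 0
    for (c_start, c_end), (q_start, q_end) in zip(*alignment.aligned):
        if q_start > qi:  # candidate insertion before this block
            insertions[ci - 1] = insertions.get(ci - 1, "") + candidate_seq[qi:q_start]
        ci, qi = c_start, q_start
        for off in range(c_end - c_start):
            cand_at[c_start + off] = candidate_seq[q_start + off]
        ci, qi = c_end, q_end
    if qi < len(candidate_seq):
        insertions[ci - 1] = insertions.get(ci - 1, "") + candidate_seq[qi:]

    # map: original column -> new column index, accounting for inserted columns
    ins_after_col: dict[int, str] = {}
    if -1 in insertions:
        ins_after_col[-1] = insertions[-1]
    for cons_pos, ins in insertions.items():
        if cons_pos >= 0:
            ins_after_col[cons_cols[cons_pos]] = ins

    col_map: dict[int, int] = {}
    new_len = 0
    if -1 in ins_after_col:
        new_len += len(ins_after_col[-1])
    for col in range(aln.length):
        col_map[col] = new_len
        new_len += 1
        if col in ins_after_col and col >= 0:
            new_len += len(ins_after_col[col])

    def expand(row: str, fill: str = "-") -> list[str]:
        out = [fill] * new_len
        for col, ch in enumerate(row):
            out[col_map[col]] = ch
        return out

    new_rows = [(name, "".join(expand(seq))) for name, seq in aln.rows]

    # build the candidate row
    cand_row = ["-"] * new_len
    if -1 in ins_after_col:
        for off, ch in enumerate(ins_after_col[-1]):
            cand_row[off] = ch
    for cons_pos, ch in cand_at.items():
        cand_row[col_map[cons_cols[cons_pos]]] = ch
    for col, ins in ins_after_col.items():
        if col >= 0:
            base = col_map[col]
            for off, ch in enumerate(ins, start=1):
                cand_row[base + off] = ch
    new_rows.append((candidate_name, "".join(cand_row)))

    def remap_span(start: int, end: int) -> tuple[int, int]:
        new_start = col_map[start]
        new_end = col_map[end - 1] + 1
        return new_start, new_end

    new_spans = {
        name: [(label, *remap_span(s, e)) for label, s, e in entries]
        for name, entries in aln.arm_spans.items()
    }
    return FamilyAlignment(family_id=aln.family_id, rows=new_rows, arm_spans=new_spans)


# ---------------------------------------------------------------------------
# The curation decision
# ---------------------------------------------------------------------------


@dataclass
class CurationDecision:
    candidate_id: str
    family_id: str
    accepted: bool
    hairpin_ok: bool
    conservation_score: float
    conservation_by_arm: dict[str, float] = field(default_factory=dict)
    n_pairs: int = 0
    loop_size: int = 0
    reasons: list[str] = field(default_factory=list)


def curate(
    candidates: Sequence[Candidate],
    families: Mapping[str, FamilyAlignment],
    params: CurationParams | None = None,
) -> list[CurationDecision]:
    """Fold, classify, align and conservation-score each candidate.

    A candidate is accepted iff its precursor folds into a qualifying
    hairpin *and* the best of its mature / mature* conservation scores
    reaches ``min_conservation``; ``reasons`` lists every failed
    criterion.
    """
    params = params or CurationParams()
    decisions: list[CurationDecision] = []
    for cand in candidates:
        if cand.family_id not in families:
            raise KeyError(f"family {cand.family_id!r} not provided for {cand.candidate_id}")
        family = families[cand.family_id]
        structure = fold_max_pairing(cand.sequence, params.min_loop, params.allowed_pairs)
        hairpin_ok, reasons = classify_hairpin(structure, params)

        row_name = "__candidate__"
        inserted = align_candidate(family, cand.sequence, candidate_name=row_name)
        arm_scores: dict[str, float] = {}
        annotated = {
            label for entries in family.arm_spans.values() for label, _, _ in entries
        }
        if not annotated:
            raise ContractError(f"family {family.family_id}: no arm annotations")
        for arm in ("mature", "mature_star"):
            if arm in annotated:
                arm_scores[arm] = mature_conservation_score(inserted, row_name, arm)
        best = max(arm_scores.values())
        if best < params.min_conservation:
            reasons.append(
                f"conservation below threshold ({best:.3f} < {params.min_conservation})"
            )
        decisions.append(
            CurationDecision(
                candidate_id=cand.candidate_id,
                family_id=cand.family_id,
                accepted=hairpin_ok and best >= params.min_conservation,
                hairpin_ok=hairpin_ok,
                conservation_score=best,
                conservation_by_arm=arm_scores,
                n_pairs=structure.n_pairs,
                loop_size=structure.loop_size,
                reasons=reasons,
            )
        )
    return decisions


def decisions_to_frame(decisions: Sequence[CurationDecision]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                d.candidate_id,
                d.family_id,
                d.accepted,
                d.hairpin_ok,
                d.n_pairs,
                d.loop_size,
                d.conservation_by_arm.get("mature", float("nan")),
                d.conservation_by_arm.get("mature_star", float("nan")),
                ";".join(d.reasons),
            )
            for d in decisions
        ],
        columns=[
            "candidate_id",
            "family_id",
            "accepted",
            "hairpin_ok",
            "n_pairs",
            "loop_size",
            "conservation_mature",
            "conservation_star",
            "reasons",
        ],
    )


def write_decisions(decisions: Sequence[CurationDecision], path: str | Path) -> None:
    decisions_to_frame(decisions).to_csv(path, sep="\t", index=False)
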