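"""Backtracking scan of sequences for a pattern set.

The engine tries pattern units left to right from every start offset,
binding each unit's matched span by name so later complement/repeat units
can refer to the matched *text*.  Search order is fixed and deterministic:

* range units enumerate lengths from ``min_len`` upward;
* units with a variation budget enumerate window lengths from
  ``template_len - deletions`` to ``template_len + insertions``;
* alternatives try the left branch first;
* the first acceptable assignment at a start offset is reported and the
  scan advances to the next offset (``per_start`` mode) or past the match
  (``non_overlapping`` mode).

Variation budgets are three independent caps — mismatches, insertions
(extra sequence letters) and deletions (skipped template positions) — not a
combined edit distance; a window is accepted if any alignment respects all
three caps simultaneously.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, FrozenSet, Iterator, List, Optional, Sequence, Tuple

from .alphabet import (
    Alphabet,
    DEFAULT_RULES,
    Molecule,
    PairingRules,
    alphabet_for,
    expand_ambiguity,
    reverse_complement,
    reverse_complement_sequence,
)
from .errors import PatScanError, PatternValidationError
from .pattern_model import (
    AlternativeUnit,
    AnyOfUnit,
    ComplementUnit,
    LengthConstraintUnit,
    NotAnyOfUnit,
    PatternSet,
    PatternUnit,
    RangeUnit,
    RepeatUnit,
    StringUnit,
    VariationBudget,
    WeightMatrix,
    WeightUnit,
    validate_pattern_set,
)

Template = Sequence[FrozenSet[str]]

FORWARD = "+"
REVERSE = "-"


@dataclass(frozen=True)
class UnitSpan:
    """One unit's contribution to a match: name, span, and matched text."""

    name: str
    start: int  # 0-based half-open, on the forward sequence
    end: int
    text: str   # as matched (reverse-strand hits keep the strand's letters)
    score: Optional[float] = None  # set for weight units only


@dataclass
class Match:
    """A hit on one sequence.

    ``start``/``end`` are 0-based half-open coordinates on the forward
    sequence.  ``unit_spans`` lists the top-level units in pattern order;
    for forward hits they partition ``[start, end)`` left to right.
    ``score`` is present iff a weight unit participated.
    """

    seq_id: str
    strand: str
    start: int
    end: int
    unit_spans: List[UnitSpan]
    score: Optional[float] = None


@dataclass
class ScanOptions:
    both_strands: bool = False
    max_hits: Optional[int] = None
    overlap_mode: str = "per_start"  # or "non_overlapping"

    def __post_init__(self):
        if self.max_hits is not None and self.max_hits < 1:
            raise ValueError("max_hits must be >= 1")
        if self.overlap_mode not in ("per_start", "non_overlapping"):
            raise ValueError(f"unknown overlap mode {self.overlap_mode!r}")


# ---------------------------------------------------------------------------
# Primitive matchers
# ---------------------------------------------------------------------------

def _allowed_set(letter: str, alphabet: Alphabet) -> FrozenSet[str]:
    # A sequence letter matches a pattern position iff it is literally a
    # member of the position's set; the pattern letter itself is included so
    # that e.g. sequence 'N' matches pattern 'N' but not pattern 'A'.
    return expand_ambiguity(letter, alphabet) | {letter.upper()}


def string_template(text: str, alphabet: Alphabet) -> List[FrozenSet[str]]:
    return [_allowed_set(ch, alphabet) for ch in text]


def match_string_unit(window: str, unit: StringUnit, alphabet: Alphabet) -> bool:
    """Exact (zero-budget) string match: position-wise set membership."""
    if len(window) != len(unit.text):
        return False
    return all(
        ch in allowed
        for ch, allowed in zip(window, string_template(unit.text, alphabet))
    )


def match_with_variations(
    template: Template, window: str, budget: VariationBudget
) -> Optional[Tuple[int, int, int]]:
    """Align a window to a set-valued template under a variation budget.

    Returns the ``(mismatches, insertions, deletions)`` actually used by the
    accepting alignment minimizing ``(insertions + deletions, mismatches)``,
    or ``None`` if no alignment respects all three caps.
    """
    T, W = len(template), len(window)
    if not (T - budget.deletions <= W <= T + budget.insertions):
        return None
    best: List[Optional[Tuple[int, int, int]]] = [None]
    seen = set()

    def rec(ti: int, wi: int, mm: int, ins: int, dl: int) -> None:
        key = (ti, wi, mm, ins, dl)
        if key in seen:
            return
        seen.add(key)
        # prune: remaining length difference must be absorbable
        rem_t, rem_w = T - ti, W - wi
        if rem_w - rem_t > budget.insertions - ins:
            return
        if rem_t - rem_w > budget.deletions - dl:
            return
        if ti == T and wi == W:
            cand = (mm, ins, dl)
            if best[0] is None or (ins + dl, mm) < (
                best[0][1] + best[0][2],
                best[0][0],
            ):
                best[0] = cand
            return
        if ti < T and wi < W:
            if window[wi] in template[ti]:
                rec(ti + 1, wi + 1, mm, ins, dl)
            elif mm < budget.mismatches:
                rec(ti + 1, wi + 1, mm + 1, ins, dl)
        if wi < W and ins < budget.insertions:
            rec(ti, wi + 1, mm, ins + 1, dl)
        if ti < T and dl < budget.deletions:
            rec(ti + 1, wi, mm, ins, dl + 1)

    rec(0, 0, 0, 0, 0)
    return best[0]


def match_complement_unit(
    bindings: Dict[str, UnitSpan],
    unit: ComplementUnit,
    window: str,
    rules: PairingRules,
) -> bool:
    """Window vs the reverse complement of the target's bound text."""
    bound = bindings.get(unit.target)
    if bound is None:
        raise PatScanError(f"complement target {unit.target} is unbound")
    template = reverse_complement(bound.text, rules)
    return match_with_variations(template, window, unit.budget) is not None


def match_repeat_unit(
    bindings: Dict[str, UnitSpan], unit: RepeatUnit, window: str
) -> bool:
    """Window vs the target's bound text (the match, not the pattern)."""
    bound = bindings.get(unit.target)
    if bound is None:
        raise PatScanError(f"repeat target {unit.target} is unbound")
    template = [frozenset(ch) for ch in bound.text]
    return match_with_variations(template, window, unit.budget) is not None


def score_weight_window(matrix: WeightMatrix, window: str) -> float:
    """Sum per-column percentages; letters outside A,C,G,T contribute 0."""
    if len(window) != len(matrix):
        raise PatScanError(
            f"weight window length {len(window)} != {len(matrix)} columns"
        )
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    score = 0.0
    for ch, col in zip(window, matrix.columns):
        j = idx.get(ch)
        if j is not None:
            score += col[j]
    return score


def check_length_constraint(
    bindings: Dict[str, UnitSpan], unit: LengthConstraintUnit
) -> bool:
    total = 0
    for t in unit.targets:
        bound = bindings.get(t)
        if bound is None:
            return False  # target branch not taken on this path
        total += bound.end - bound.start
    if unit.comparator == "less_than":
        return total < unit.bound
    return total > unit.bound


def check_length_constraints(
    bindings: Dict[str, UnitSpan], ps: PatternSet
) -> bool:
    """Evaluate every length-constraint unit of ``ps`` against bindings."""
    from .pattern_model import iter_units

    return all(
        check_length_constraint(bindings, u)
        for u in iter_units(ps.units)
        if isinstance(u, LengthConstraintUnit)
    )


# ---------------------------------------------------------------------------
# Backtracking search
# ---------------------------------------------------------------------------

def _rules_for(unit: ComplementUnit, ps: PatternSet) -> PairingRules:
    if unit.rules is None:
        return DEFAULT_RULES
    return ps.rule_declarations[unit.rules]


def _window_lengths(template_len: int, budget: VariationBudget) -> range:
    lo = max(0, template_len - budget.deletions)
    return range(lo, template_len + budget.insertions + 1)


def _unit_candidates(
    residues: str,
    unit: PatternUnit,
    pos: int,
    bindings: Dict[str, UnitSpan],
    ps: PatternSet,
    alphabet: Alphabet,
) -> Iterator[Tuple[Optional[UnitSpan], int, Dict[str, UnitSpan]]]:
    """Yield (span, next position, updated bindings) in search order."""
    n = len(residues)

    def bind(end: int, score: Optional[float] = None):
        span = UnitSpan(unit.name, pos, end, residues[pos:end], score)
        nb = dict(bindings)
        nb[unit.name] = span
        return span, end, nb

    if isinstance(unit, StringUnit):
        template = string_template(unit.text, alphabet)
        for wlen in _window_lengths(len(template), unit.budget):
            end = pos + wlen
            if end > n:
                break
            if match_with_variations(template, residues[pos:end], unit.budget):
                yield bind(end)
    elif isinstance(unit, RangeUnit):
        for wlen in range(unit.min_len, unit.max_len + 1):
            end = pos + wlen
            if end > n:
                break
            yield bind(end)
    elif isinstance(unit, ComplementUnit):
        bound = bindings.get(unit.target)
        if bound is None:
            return  # target inside an untaken branch: reject this path
        template = reverse_complement(bound.text, _rules_for(unit, ps))
        for wlen in _window_lengths(len(template), unit.budget):
            end = pos + wlen
            if end > n:
                break
            if match_with_variations(template, residues[pos:end], unit.budget):
                yield bind(end)
    elif isinstance(unit, RepeatUnit):
        bound = bindings.get(unit.target)
        if bound is None:
            return
        template = [frozenset(ch) for ch in bound.text]
        for wlen in _window_lengths(len(template), unit.budget):
            end = pos + wlen
            if end > n:
                break
            if match_with_variations(template, residues[pos:end], unit.budget):
                yield bind(end)
    elif isinstance(unit, AlternativeUnit):
        for branch in (unit.left, unit.right):
            for _, end, nb in _iter_assignments(
                residues, branch, 0, pos, bindings, ps, alphabet
            ):
                span = UnitSpan(unit.name, pos, end, residues[pos:end])
                nb2 = dict(nb)
                nb2[unit.name] = span
                yield span, end, nb2
    elif isinstance(unit, LengthConstraintUnit):
        if check_length_constraint(bindings, unit):
            yield None, pos, bindings
    elif isinstance(unit, WeightUnit):
        end = pos + len(unit.matrix)
        if end <= n:
            score = score_weight_window(unit.matrix, residues[pos:end])
            if score >= unit.threshold:  # minimum threshold is inclusive
                yield bind(end, score)
    elif isinstance(unit, AnyOfUnit):
        if pos < n and residues[pos] in unit.residues:
            yield bind(pos + 1)
    elif isinstance(unit, NotAnyOfUnit):
        if pos < n and residues[pos] not in unit.residues:
            yield bind(pos + 1)
    else:  # pragma: no cover - guarded by validation
        raise PatScanError(f"unhandled unit type {type(unit).__name__}")


def _iter_assignments(
    residues: str,
    units: List[PatternUnit],
    idx: int,
    pos: int,
    bindings: Dict[str, UnitSpan],
    ps: PatternSet,
    alphabet: Alphabet,
) -> Iterator[Tuple[List[UnitSpan], int, Dict[str, UnitSpan]]]:
    if idx == len(units):
        yield [], pos, bindings
        return
    unit = units[idx]
    for span, npos, nb in _unit_candidates(
        residues, unit, pos, bindings, ps, alphabet
    ):
        for rest, end, fb in _iter_assignments(
            residues, units, idx + 1, npos, nb, ps, alphabet
        ):
            spans = [span] + rest if span is not None else rest
            yield spans, end, fb


def _first_match_at(
    residues: str,
    start: int,
    ps: PatternSet,
    alphabet: Alphabet,
) -> Optional[Tuple[List[UnitSpan], int, Optional[float]]]:
    for spans, end, bindings in _iter_assignments(
        residues, ps.units, 0, start, {}, ps, alphabet
    ):
        scores = [
            sp.score for sp in bindings.values() if sp.score is not None
        ]
        score = sum(scores) if scores else None
        return spans, end, score
    return None


def _scan_forward(
    residues: str, seq_id: str, ps: PatternSet, opts: ScanOptions, strand: str
) -> List[Match]:
    alphabet = alphabet_for(ps.molecule)
    hits: List[Match] = []
    s = 0
    n = len(residues)
    while s < n:
        found = _first_match_at(residues, s, ps, alphabet)
        if found is None:
            s += 1
            continue
        spans, end, score = found
        hits.append(Match(seq_id, strand, s, end, spans, score))
        if opts.overlap_mode == "non_overlapping":
            s = max(end, s + 1)
        else:
            s += 1
    return hits


def _map_to_forward(m: Match, seq_len: int) -> Match:
    """Map a hit found on the reverse-complemented sequence back to forward
    coordinates.  Unit spans stay in pattern order (so their coordinates run
    right-to-left along the forward strand); texts keep the strand that
    matched."""
    spans = [
        UnitSpan(sp.name, seq_len - sp.end, seq_len - sp.start, sp.text, sp.score)
        for sp in m.unit_spans
    ]
    return Match(
        m.seq_id, REVERSE, seq_len - m.end, seq_len - m.start, spans, m.score
    )


def _validate_for_scan(ps: PatternSet, molecule: Molecule) -> None:
    violations = validate_pattern_set(ps)
    if violations:
        raise PatternValidationError(violations)
    if Molecule(ps.molecule) is not Molecule(molecule):
        raise PatternValidationError(
            [f"pattern is for {Molecule(ps.molecule).value} input but the "
             f"sequence is {Molecule(molecule).value}"]
        )


def scan_sequence(record, ps: PatternSet, opts: Optional[ScanOptions] = None) -> List[Match]:
    """Scan one sequence record for a pattern set.

    Matches are sorted by start position (forward-strand hits first when
    ``both_strands`` is set), at most one match per start offset per strand,
    deterministic for fixed input.  Raises on pattern/molecule mismatch —
    never a silent empty result.
    """
    opts = opts or ScanOptions()
    molecule = getattr(record, "molecule", Molecule.NUCLEOTIDE)
    _validate_for_scan(ps, molecule)
    residues = record.residues
    hits = _scan_forward(residues, record.id, ps, opts, FORWARD)
    if opts.both_strands:
        if Molecule(molecule) is not Molecule.NUCLEOTIDE:
            raise PatternValidationError(
                ["both-strand scanning requires nucleotide input"]
            )
        rc = reverse_complement_sequence(residues)
        rev = _scan_forward(rc, record.id, ps, opts, REVERSE)
        hits.extend(_map_to_forward(m, len(residues)) for m in rev)
    if opts.max_hits is not None:
        hits = hits[: opts.max_hits]
    return hits


def scan_both_strands(record, ps: PatternSet, opts: Optional[ScanOptions] = None) -> List[Match]:
    """Scan forward then reverse strand (coordinates mapped back forward)."""
    opts = opts or ScanOptions()
    return scan_sequence(record, ps, replace(opts, both_strands=True))


def scan_records(
    records, ps: PatternSet, opts: Optional[ScanOptions] = None
) -> List[Match]:
    """Scan several records in file order; ``max_hits`` counts across all."""
    opts = opts or ScanOptions()
    hits: List[Match] = []
    for record in records:
        remaining = None
        if opts.max_hits is not None:
            remaining = opts.max_hits - len(hits)
            if remaining <= 0:
                break
        per_record = replace(opts, max_hits=remaining)
        hits.extend(scan_sequence(record, ps, per_record))
    return hits
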