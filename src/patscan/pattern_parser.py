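"""Parser for the textual pattern language.

Grammar (whitespace-insensitive between tokens, case-insensitive keywords):

.. code-block:: text

    pattern-set : item+
    item        : rule-decl | [ name "=" ] unit
    rule-decl   : RULENAME "=" "{" PAIR ("," PAIR)* "}"      e.g. r1={GT,TG}
    unit        : string | range | complement | repeat
                | alternative | length | weight | anyof
    string      : LETTERS [ budget ]                         e.g. CAGTG[1,0,0]
    range       : INT "..." INT                              e.g. 5...6
    complement  : [ RULENAME ] "~" NAME [ budget ]           e.g. r1~p2[1,0,0]
    repeat      : NAME [ budget ]                            e.g. p2
    alternative : "(" item+ "|" item+ ")"
    length      : "length" "(" NAME ("+" NAME)* ")" ("<"|">") INT
    weight      : "{" col ("," col)* "}" ">" NUMBER
    col         : "(" NUMBER "," NUMBER "," NUMBER "," NUMBER ")"  (A,C,G,T)
    anyof       : ("any"|"notany") "(" LETTERS ")"           protein only
    budget      : "[" INT "," INT "," INT "]"        mismatches,ins,dels
    NAME        : p<digits>        RULENAME : r<digits>

A bare NAME is a repeat of the earlier unit of that name.  The weight
threshold is a minimum: ``> t`` reads as "score >= t".  Unnamed units
receive implicit names (p1, p2, ...) after parsing; semantic checks are
delegated to :func:`~patscan.pattern_model.validate_pattern_set` and raised
as :class:`~patscan.errors.PatternValidationError`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import List, Optional, Tuple

from .alphabet import Molecule, PairingRules
from .errors import PatternSyntaxError, PatternValidationError
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
    UNIT_NAME_RE,
    RULE_NAME_RE,
    VariationBudget,
    WeightMatrix,
    WeightUnit,
    assign_names,
    validate_pattern_set,
)

_TOKEN_RE = re.compile(
    r"""
    (?P<WORD>[A-Za-z][A-Za-z0-9]*)
  | (?P<NUMBER>\d+(?:\.\d+)?)
  | (?P<DOTS>\.\.\.)
  | (?P<SYM>[()\[\]{}|=~<>,+])
    """,
    re.VERBOSE,
)


@dataclass(frozen=True)
class _Token:
    kind: str
    text: str
    offset: int


def _tokenize(text: str) -> List[_Token]:
    tokens = []
    i = 0
    n = len(text)
    while i < n:
        if text[i].isspace():
            i += 1
            continue
        m = _TOKEN_RE.match(text, i)
        if m is None:
            raise PatternSyntaxError(
                f"unexpected character {text[i]!r}", i, "a pattern token"
            )
        kind = m.lastgroup
        tokens.append(_Token(kind, m.group(), i))
        i = m.end()
    return tokens


class _Parser:
    def __init__(self, text: str, molecule: Molecule):
        self.text = text
        self.molecule = Molecule(molecule)
        self.tokens = _tokenize(text)
        self.pos = 0

    # -- token plumbing ----------------------------------------------------
    def peek(self, ahead: int = 0) -> Optional[_Token]:
        i = self.pos + ahead
        return self.tokens[i] if i < len(self.tokens) else None

    def next(self) -> _Token:
        tok = self.peek()
        if tok is None:
            raise PatternSyntaxError(
                "unexpected end of pattern", len(self.text), "more input"
            )
        self.pos += 1
        return tok

    def expect(self, text: str, hint: str = "") -> _Token:
        tok = self.peek()
        if tok is None or tok.text != text:
            off = tok.offset if tok else len(self.text)
            got = repr(tok.text) if tok else "end of pattern"
            raise PatternSyntaxError(
                f"got {got}", off, hint or repr(text)
            )
        return self.next()

    def fail(self, message: str, hint: str = "") -> None:
        tok = self.peek()
        off = tok.offset if tok else len(self.text)
        raise PatternSyntaxError(message, off, hint)

    # -- grammar -----------------------------------------------------------
    def parse(self) -> PatternSet:
        ps = PatternSet(self.molecule, [], {})
        while self.peek() is not None:
            tok = self.peek()
            nxt = self.peek(1)
            low = tok.text.lower()
            if (
                tok.kind == "WORD"
                and RULE_NAME_RE.match(low)
                and nxt is not None
                and nxt.text == "="
            ):
                self._parse_rule_decl(ps)
            else:
                ps.units.append(self._parse_item())
        if not ps.units:
            self.fail("empty pattern", "at least one pattern unit")
        assign_names(ps)
        violations = validate_pattern_set(ps)
        if violations:
            raise PatternValidationError(violations)
        return ps

    def _parse_rule_decl(self, ps: PatternSet) -> None:
        name_tok = self.next()
        name = name_tok.text.lower()
        self.expect("=")
        self.expect("{", "'{' opening the pair list")
        pair_tokens = []
        while True:
            tok = self.next()
            if tok.kind != "WORD" or len(tok.text) != 2:
                raise PatternSyntaxError(
                    f"got {tok.text!r}", tok.offset,
                    "a two-letter pair like GT",
                )
            pair_tokens.append(tok.text)
            tok = self.next()
            if tok.text == "}":
                break
            if tok.text != ",":
                raise PatternSyntaxError(
                    f"got {tok.text!r}", tok.offset, "',' or '}'"
                )
        if name in ps.rule_declarations:
            raise PatternValidationError(
                [f"duplicate rule set {name}"]
            )
        try:
            ps.rule_declarations[name] = PairingRules.from_pairs(
                name, pair_tokens
            )
        except Exception as exc:
            raise PatternSyntaxError(str(exc), name_tok.offset) from None

    def _parse_item(self) -> PatternUnit:
        tok = self.peek()
        nxt = self.peek(1)
        name = ""
        if (
            tok.kind == "WORD"
            and UNIT_NAME_RE.match(tok.text.lower())
            and nxt is not None
            and nxt.text == "="
        ):
            name = self.next().text.lower()
            self.expect("=")
        unit = self._parse_unit()
        if name:
            unit.name = name
            unit.explicit_name = True
        return unit

    def _parse_unit(self) -> PatternUnit:
        tok = self.peek()
        if tok is None:
            self.fail("unexpected end of pattern", "a pattern unit")
        start = tok.offset

        if tok.text == "~":
            return self._parse_complement(start, rules=None)
        if tok.text == "(":
            return self._parse_alternative(start)
        if tok.text == "{":
            return self._parse_weight(start)
        if tok.kind == "NUMBER":
            return self._parse_range(start)
        if tok.kind == "WORD":
            low = tok.text.lower()
            nxt = self.peek(1)
            if (
                low in ("length", "any", "notany")
                and nxt is not None
                and nxt.text == "("
            ):
                if low == "length":
                    return self._parse_length(start)
                return self._parse_anyof(start, negate=(low == "notany"))
            if RULE_NAME_RE.match(low) and nxt is not None and nxt.text == "~":
                self.next()
                self.next()  # consume rule name and '~'
                return self._parse_complement_tail(start, rules=low)
            if UNIT_NAME_RE.match(low):
                self.next()
                budget = self._parse_budget()
                return RepeatUnit(
                    target=low, budget=budget, src_span=(start, self._end())
                )
            if tok.text.isalpha():
                self.next()
                budget = self._parse_budget()
                return StringUnit(
                    tok.text.upper().replace("U", "T")
                    if self.molecule is Molecule.NUCLEOTIDE
                    else tok.text.upper(),
                    budget,
                    src_span=(start, self._end()),
                )
            self.fail(f"invalid token {tok.text!r}", "a pattern unit")
        self.fail(f"got {tok.text!r}", "a pattern unit")

    def _end(self) -> int:
        prev = self.tokens[self.pos - 1]
        return prev.offset + len(prev.text)

    def _parse_complement(self, start: int, rules: Optional[str]) -> PatternUnit:
        self.expect("~")
        return self._parse_complement_tail(start, rules)

    def _parse_complement_tail(
        self, start: int, rules: Optional[str]
    ) -> PatternUnit:
        tok = self.next()
        low = tok.text.lower()
        if tok.kind != "WORD" or not UNIT_NAME_RE.match(low):
            raise PatternSyntaxError(
                f"got {tok.text!r}", tok.offset, "a unit name like p2"
            )
        budget = self._parse_budget()
        return ComplementUnit(
            target=low, budget=budget, rules=rules,
            src_span=(start, self._end()),
        )

    def _parse_budget(self) -> VariationBudget:
        tok = self.peek()
        if tok is None or tok.text != "[":
            return VariationBudget()
        self.next()
        nums = []
        for i in range(3):
            nums.append(self._parse_int())
            if i < 2:
                self.expect(",")
        self.expect("]")
        return VariationBudget(*nums)

    def _parse_int(self) -> int:
        tok = self.next()
        if tok.kind != "NUMBER" or "." in tok.text:
            raise PatternSyntaxError(
                f"got {tok.text!r}", tok.offset, "an integer"
            )
        return int(tok.text)

    def _parse_number(self) -> float:
        tok = self.next()
        if tok.kind != "NUMBER":
            raise PatternSyntaxError(
                f"got {tok.text!r}", tok.offset, "a number"
            )
        return float(tok.text)

    def _parse_range(self, start: int) -> PatternUnit:
        lo = self._parse_int()
        tok = self.next()
        if tok.kind != "DOTS":
            raise PatternSyntaxError(
                f"got {tok.text!r}", tok.offset, "'...' in a range"
            )
        hi = self._parse_int()
        return RangeUnit(lo, hi, src_span=(start, self._end()))

    def _parse_alternative(self, start: int) -> PatternUnit:
        self.expect("(")
        left: List[PatternUnit] = []
        right: List[PatternUnit] = []
        current = left
        while True:
            tok = self.peek()
            if tok is None:
                self.fail("unterminated alternative", "')'")
            if tok.text == "|":
                if current is right:
                    self.fail(
                        "alternative takes exactly two branches", "')'"
                    )
                self.next()
                current = right
                continue
            if tok.text == ")":
                self.next()
                break
            current.append(self._parse_item())
        return AlternativeUnit(left, right, src_span=(start, self._end()))

    def _parse_length(self, start: int) -> PatternUnit:
        self.next()  # 'length'
        self.expect("(")
        targets = []
        while True:
            tok = self.next()
            low = tok.text.lower()
            if tok.kind != "WORD" or not UNIT_NAME_RE.match(low):
                raise PatternSyntaxError(
                    f"got {tok.text!r}", tok.offset, "a unit name like p1"
                )
            targets.append(low)
            tok = self.next()
            if tok.text == ")":
                break
            if tok.text != "+":
                raise PatternSyntaxError(
                    f"got {tok.text!r}", tok.offset, "'+' or ')'"
                )
        tok = self.next()
        if tok.text not in ("<", ">"):
            raise PatternSyntaxError(
                f"got {tok.text!r}", tok.offset, "'<' or '>'"
            )
        comparator = "less_than" if tok.text == "<" else "greater_than"
        bound = self._parse_int()
        return LengthConstraintUnit(
            tuple(targets), comparator, bound, src_span=(start, self._end())
        )

    def _parse_weight(self, start: int) -> PatternUnit:
        self.expect("{")
        columns = []
        while True:
            self.expect("(", "'(' opening a weight column")
            col = []
            for i in range(4):
                col.append(self._parse_number())
                if i < 3:
                    self.expect(",")
            self.expect(")")
            columns.append(tuple(col))
            tok = self.next()
            if tok.text == "}":
                break
            if tok.text != ",":
                raise PatternSyntaxError(
                    f"got {tok.text!r}", tok.offset, "',' or '}'"
                )
        self.expect(">", "'>' and a score threshold")
        threshold = self._parse_number()
        return WeightUnit(
            WeightMatrix(tuple(columns)), threshold,
            src_span=(start, self._end()),
        )

    def _parse_anyof(self, start: int, negate: bool) -> PatternUnit:
        self.next()  # keyword
        self.expect("(")
        tok = self.next()
        if tok.kind != "WORD" or not tok.text.isalpha():
            raise PatternSyntaxError(
                f"got {tok.text!r}", tok.offset, "a residue list like FILV"
            )
        residues = frozenset(tok.text.upper())
        self.expect(")")
        cls = NotAnyOfUnit if negate else AnyOfUnit
        return cls(residues, src_span=(start, self._end()))


def parse_pattern(text: str, molecule: Molecule = Molecule.NUCLEOTIDE) -> PatternSet:
    """Parse a pattern expression into a validated :class:`PatternSet`.

    Raises :class:`PatternSyntaxError` (with character offset and an
    expected-token hint) on bad syntax, and :class:`PatternValidationError`
    listing every semantic violation otherwise.
    """
    if not text or not text.strip():
        raise PatternSyntaxError("empty pattern", 0, "a pattern expression")
    return _Parser(text, molecule).parse()
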