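"""Pattern abstract syntax: typed units, variation budgets, validation.

A pattern set is an ordered list of units scanned left to right.  Units are
tagged variants:

========== =====================================================
string      literal residues (IUPAC codes legal for nucleotide)
range       ``min...max`` arbitrary residues, the "spacer" unit
complement  reverse complement of an earlier unit's matched text
repeat      an earlier unit's matched text again
alternative two branches, one of which must match
length      constraint on the summed length of earlier matches
weight      per-position percentage matrix with a score threshold
any_of      one position drawn from a residue set (protein only)
not_any_of  one position outside a residue set (protein only)
========== =====================================================

String, complement and repeat units carry a variation budget: independent
maxima on mismatches, insertions and deletions (not a combined edit
distance).  Complement and repeat units refer to units defined earlier by
name; unnamed units receive implicit sequential names (p1, p2, ...) in order
of appearance so they can be referenced and labelled in reports.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterator, List, Optional, Tuple, Union

from .alphabet import (
    Molecule,
    PairingRules,
    alphabet_for,
)
from .errors import PatternValidationError

UNIT_NAME_RE = re.compile(r"p[0-9]+\Z")
RULE_NAME_RE = re.compile(r"r[0-9]+\Z")


@dataclass(frozen=True)
class VariationBudget:
    """Independent caps on mismatches, insertions and deletions."""

    mismatches: int = 0
    insertions: int = 0
    deletions: int = 0

    def __post_init__(self):
        if min(self.mismatches, self.insertions, self.deletions) < 0:
            raise ValueError("variation budget components must be >= 0")

    @property
    def is_exact(self) -> bool:
        return self == EXACT


EXACT = VariationBudget()


@dataclass(frozen=True)
class WeightMatrix:
    """Per-position base percentages in fixed A,C,G,T column order."""

    columns: Tuple[Tuple[float, float, float, float], ...]

    def __post_init__(self):
        if not self.columns:
            raise ValueError("weight matrix needs at least one column")

    def __len__(self) -> int:
        return len(self.columns)


@dataclass
class PatternUnit:
    """Common bookkeeping shared by every unit variant."""

    tag = "unit"
    # Implicit names are assigned post-parse; explicitness and source spans
    # are presentation detail, excluded from structural equality.
    name: str = field(default="", kw_only=True)
    explicit_name: bool = field(default=False, compare=False, kw_only=True)
    src_span: Optional[Tuple[int, int]] = field(
        default=None, compare=False, kw_only=True
    )


@dataclass
class StringUnit(PatternUnit):
    tag = "string"
    text: str = ""
    budget: VariationBudget = EXACT


@dataclass
class RangeUnit(PatternUnit):
    tag = "range"
    min_len: int = 0
    max_len: int = 0


@dataclass
class ComplementUnit(PatternUnit):
    tag = "complement"
    target: str = ""
    budget: VariationBudget = EXACT
    rules: Optional[str] = None  # rule-set name; None = Watson-Crick default


@dataclass
class RepeatUnit(PatternUnit):
    tag = "repeat"
    target: str = ""
    budget: VariationBudget = EXACT


@dataclass
class AlternativeUnit(PatternUnit):
    tag = "alternative"
    left: List[PatternUnit] = field(default_factory=list)
    right: List[PatternUnit] = field(default_factory=list)


@dataclass
class LengthConstraintUnit(PatternUnit):
    tag = "length_constraint"
    targets: Tuple[str, ...] = ()
    comparator: str = "less_than"  # or "greater_than"
    bound: int = 1


@dataclass
class WeightUnit(PatternUnit):
    tag = "weight"
    matrix: WeightMatrix = None  # type: ignore[assignment]
    threshold: float = 0.0


@dataclass
class AnyOfUnit(PatternUnit):
    tag = "any_of"
    residues: FrozenSet[str] = frozenset()


@dataclass
class NotAnyOfUnit(PatternUnit):
    tag = "not_any_of"
    residues: FrozenSet[str] = frozenset()


#: Units that consume sequence and bind matched text.
MATCH_PRODUCING = (
    StringUnit,
    RangeUnit,
    ComplementUnit,
    RepeatUnit,
    AlternativeUnit,
    WeightUnit,
    AnyOfUnit,
    NotAnyOfUnit,
)


@dataclass
class PatternSet:
    """A compiled query: rule declarations plus an ordered unit list."""

    molecule: Molecule
    units: List[PatternUnit]
    rule_declarations: Dict[str, PairingRules] = field(default_factory=dict)

    def __post_init__(self):
        self.molecule = Molecule(self.molecule)


def iter_units(units: List[PatternUnit]) -> Iterator[PatternUnit]:
    """Depth-first traversal: a unit precedes the contents of its branches."""
    for u in units:
        yield u
        if isinstance(u, AlternativeUnit):
            yield from iter_units(u.left)
            yield from iter_units(u.right)


def assign_names(ps: PatternSet) -> None:
    """Give every unnamed unit the next free implicit name p1, p2, ...

    Two passes: explicit names are reserved first so that a later explicit
    ``p4=`` never collides with an implicit assignment.  A unit never
    receives a name it itself references (so ``~p1`` alone stays a dangling
    reference instead of silently becoming a self-complement).
    Deterministic, so serialization followed by re-parsing reproduces
    identical names.
    """
    taken = {u.name for u in iter_units(ps.units) if u.name}
    counter = 1
    for u in iter_units(ps.units):
        if u.name:
            continue
        own_refs: set = set()
        if isinstance(u, (ComplementUnit, RepeatUnit)):
            own_refs = {u.target}
        elif isinstance(u, LengthConstraintUnit):
            own_refs = set(u.targets)
        k = counter
        while f"p{k}" in taken or f"p{k}" in own_refs:
            k += 1
        u.name = f"p{k}"
        taken.add(u.name)
        if k == counter:
            counter += 1


@dataclass(frozen=True)
class Violation:
    """One semantic problem, located by depth-first unit index."""

    index: int
    message: str

    def __str__(self) -> str:
        return f"unit {self.index}: {self.message}"


def _check_letters(text: str, molecule: Molecule) -> Optional[str]:
    amap = alphabet_for(molecule).ambiguity_map
    for ch in text:
        if ch not in amap:
            return ch
    return None


def validate_pattern_set(ps: PatternSet) -> List[Violation]:
    """Return every semantic violation (empty list = valid).

    Total on structurally well-formed input: never raises, reports all
    violations ordered by depth-first unit index.
    """
    violations: List[Violation] = []
    molecule = Molecule(ps.molecule)
    ordered = list(iter_units(ps.units))
    position = {}
    seen_names = set()

    for idx, u in enumerate(ordered):
        if u.name:
            if u.name in seen_names:
                violations.append(Violation(idx, f"duplicate name {u.name}"))
            else:
                seen_names.add(u.name)
                position[u.name] = idx
            if not UNIT_NAME_RE.match(u.name):
                violations.append(
                    Violation(idx, f"unit name {u.name!r} must match p<digits>")
                )

    for rname in ps.rule_declarations:
        if not RULE_NAME_RE.match(rname):
            violations.append(
                Violation(0, f"rule-set name {rname!r} must match r<digits>")
            )

    by_name = {u.name: u for u in ordered if u.name}

    for idx, u in enumerate(ordered):
        if isinstance(u, StringUnit):
            if not u.text:
                violations.append(Violation(idx, "empty string pattern"))
            bad = _check_letters(u.text, molecule)
            if bad is not None:
                violations.append(
                    Violation(
                        idx,
                        f"letter {bad!r} not valid for {molecule.value} input",
                    )
                )
        elif isinstance(u, RangeUnit):
            if u.min_len < 0 or u.min_len > u.max_len:
                violations.append(
                    Violation(idx, "range requires 0 <= min <= max")
                )
        elif isinstance(u, (ComplementUnit, RepeatUnit)):
            kind = u.tag
            if isinstance(u, ComplementUnit) and molecule is not Molecule.NUCLEOTIDE:
                violations.append(
                    Violation(idx, "complement requires nucleotide input")
                )
            tpos = position.get(u.target)
            if tpos is None:
                violations.append(
                    Violation(idx, f"unknown reference {u.target}")
                )
            elif tpos >= idx:
                violations.append(
                    Violation(
                        idx,
                        f"{kind} target {u.target} must be defined earlier",
                    )
                )
            else:
                tgt = by_name[u.target]
                if isinstance(tgt, (WeightUnit, LengthConstraintUnit)):
                    violations.append(
                        Violation(
                            idx,
                            f"{kind} target {u.target} must be a "
                            "text-matching unit",
                        )
                    )
            if isinstance(u, ComplementUnit) and u.rules is not None:
                if u.rules not in ps.rule_declarations:
                    violations.append(
                        Violation(idx, f"unknown rule set {u.rules}")
                    )
        elif isinstance(u, AlternativeUnit):
            if not u.left or not u.right:
                violations.append(
                    Violation(idx, "alternative branches must be non-empty")
                )
        elif isinstance(u, LengthConstraintUnit):
            if not u.targets:
                violations.append(
                    Violation(idx, "length constraint needs targets")
                )
            if u.bound < 0:
                violations.append(
                    Violation(idx, "length bound must be non-negative")
                )
            if u.comparator not in ("less_than", "greater_than"):
                violations.append(
                    Violation(idx, f"unknown comparator {u.comparator!r}")
                )
            for t in u.targets:
                tpos = position.get(t)
                if tpos is None:
                    violations.append(Violation(idx, f"unknown reference {t}"))
                elif tpos >= idx:
                    violations.append(
                        Violation(
                            idx, f"length target {t} must be defined earlier"
                        )
                    )
                elif isinstance(by_name[t], LengthConstraintUnit):
                    violations.append(
                        Violation(
                            idx, f"length target {t} is not match-producing"
                        )
                    )
        elif isinstance(u, WeightUnit):
            if molecule is not Molecule.NUCLEOTIDE:
                violations.append(
                    Violation(idx, "weight patterns require nucleotide input")
                )
        elif isinstance(u, (AnyOfUnit, NotAnyOfUnit)):
            if molecule is not Molecule.PROTEIN:
                violations.append(
                    Violation(
                        idx, f"{u.tag} patterns require protein input"
                    )
                )
            bad = _check_letters("".join(sorted(u.residues)), Molecule.PROTEIN)
            if not u.residues:
                violations.append(Violation(idx, "empty residue set"))
            elif bad is not None:
                violations.append(
                    Violation(idx, f"letter {bad!r} is not an amino acid")
                )

    if not any(isinstance(u, MATCH_PRODUCING) for u in ps.units):
        violations.append(
            Violation(0, "pattern set has no match-producing unit")
        )

    violations.sort(key=lambda v: v.index)
    return violations


# ---------------------------------------------------------------------------
# Serialization back to the textual pattern language
# ---------------------------------------------------------------------------

def _fmt_num(x: float) -> str:
    return str(int(x)) if float(x) == int(x) else repr(float(x))


def _budget_suffix(b: VariationBudget) -> str:
    if b.is_exact:
        return ""
    return f"[{b.mismatches},{b.insertions},{b.deletions}]"


def _referenced_names(units: List[PatternUnit]) -> set:
    refs = set()
    for u in iter_units(units):
        if isinstance(u, (ComplementUnit, RepeatUnit)):
            refs.add(u.target)
        elif isinstance(u, LengthConstraintUnit):
            refs.update(u.targets)
    return refs


def _serialize_unit(u: PatternUnit) -> str:
    if isinstance(u, StringUnit):
        return u.text + _budget_suffix(u.budget)
    if isinstance(u, RangeUnit):
        return f"{u.min_len}...{u.max_len}"
    if isinstance(u, ComplementUnit):
        prefix = u.rules if u.rules else ""
        return f"{prefix}~{u.target}" + _budget_suffix(u.budget)
    if isinstance(u, RepeatUnit):
        return u.target + _budget_suffix(u.budget)
    if isinstance(u, AlternativeUnit):
        raise AssertionError("alternatives handled by _serialize_items")
    if isinstance(u, LengthConstraintUnit):
        cmp_ch = "<" if u.comparator == "less_than" else ">"
        return f"length({'+'.join(u.targets)}) {cmp_ch} {u.bound}"
    if isinstance(u, WeightUnit):
        cols = ",".join(
            "(" + ",".join(_fmt_num(v) for v in col) + ")"
            for col in u.matrix.columns
        )
        return "{" + cols + "} > " + _fmt_num(u.threshold)
    if isinstance(u, AnyOfUnit):
        return f"any({''.join(sorted(u.residues))})"
    if isinstance(u, NotAnyOfUnit):
        return f"notany({''.join(sorted(u.residues))})"
    raise AssertionError(f"unhandled unit {u!r}")


def _serialize_items(units: List[PatternUnit], referenced: set) -> str:
    parts = []
    for u in units:
        prefix = f"{u.name}=" if (u.explicit_name or u.name in referenced) else ""
        if isinstance(u, AlternativeUnit):
            body = (
                "( "
                + _serialize_items(u.left, referenced)
                + " | "
                + _serialize_items(u.right, referenced)
                + " )"
            )
        else:
            body = _serialize_unit(u)
        parts.append(prefix + body)
    return " ".join(parts)


def serialize_pattern(ps: PatternSet) -> str:
    """Emit the textual expression for a valid pattern set.

    Round-trip guarantee: ``parse_pattern(serialize_pattern(ps))`` is
    structurally equal to ``ps``.  Refuses invalid sets with the first
    violation.
    """
    violations = validate_pattern_set(ps)
    if violations:
        raise PatternValidationError(violations[:1])
    parts = []
    for rname in sorted(ps.rule_declarations):
        rules = ps.rule_declarations[rname]
        tokens = sorted(
            f"{x}{y}" for x, ys in rules.pairs.items() for y in ys
        )
        parts.append(f"{rname}={{{','.join(tokens)}}}")
    referenced = _referenced_names(ps.units)
    parts.append(_serialize_items(ps.units, referenced))
    return " ".join(p for p in parts if p)
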