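"""Synthetic planted-motif sequences, the IRE pattern family, and oracles.

The generator emulates exploratory motif hunting in bacterial 5'-UTRs:
i.i.d. background at a configurable GC fraction (default 0.72, GC-rich as in
*Streptomyces*) with non-overlapping motif instances planted at recorded
positions.  The canned iron-response-element (IRE) pattern family walks the
classic relaxation ladder from the strict eukaryotic consensus (C bulge,
6-nt stem, CAGUG loop, perfect Watson-Crick pairing) to a bacterial-style
search (one stem mismatch, optional extra loop base, 5-6 nt stems, GAGAG
alternative loop, G·U wobble pairing).

Also provided: a brute-force matcher that exhaustively enumerates every
decomposition — the independent oracle the engine is tested against — and a
random generator of valid pattern sets / sequences for property testing.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import (
    Callable,
    Dict,
    FrozenSet,
    Iterator,
    List,
    Optional,
    Tuple,
    Union,
)

from .alphabet import (
    DEFAULT_RULES,
    Molecule,
    PairingRules,
    alphabet_for,
)
from .errors import FixtureError, OracleBoundError, PatternValidationError
from .io_report import SequenceRecord
from .match_engine import FORWARD, Match, UnitSpan
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
from .pattern_parser import parse_pattern

# ---------------------------------------------------------------------------
# The IRE pattern relaxation ladder
# ---------------------------------------------------------------------------

IRE_STAGES = (
    "basic",
    "mismatch",
    "extra_loop_base",
    "short_stem",
    "alt_loop",
    "wobble",
)

IRE_EXPRESSIONS: Dict[str, str] = {
    # strict eukaryotic consensus: C bulge, 6-nt stem, CAGUG loop, WC stem
    "basic": "p1=C p2=6...6 p3=CAGTG p4=~p2",
    # tolerate one mispaired stem position
    "mismatch": "p1=C p2=6...6 p3=CAGTG p4=~p2[1,0,0]",
    # allow one extra loop base after the CAGUG
    "extra_loop_base": "p1=C p2=6...6 p3=CAGTG p4=0...1 p5=~p2[1,0,0]",
    # bacterial stems may be only five bases long
    "short_stem": "p1=C p2=5...6 p3=CAGTG p4=0...1 p5=~p2[1,0,0]",
    # the GAGAG loop is also functional
    "alt_loop": "p1=C p2=5...6 p3=( CAGTG | GAGAG ) p4=0...1 p5=~p2[1,0,0]",
    # RNA allows G.U wobble pairs in the stem
    "wobble": (
        "r1={AT,TA,GC,CG,GT,TG} "
        "p1=C p2=5...6 p3=( CAGTG | GAGAG ) p4=0...1 p5=r1~p2[1,0,0]"
    ),
}

_WC = {"A": "T", "T": "A", "G": "C", "C": "G"}
_WOBBLE_PARTNERS = {"A": "T", "T": "AG", "G": "CT", "C": "G"}


def ire_pattern(stage: str) -> PatternSet:
    """The pattern set for one step of the IRE relaxation ladder."""
    if stage not in IRE_EXPRESSIONS:
        raise ValueError(f"unknown IRE stage {stage!r}; one of {IRE_STAGES}")
    return parse_pattern(IRE_EXPRESSIONS[stage], Molecule.NUCLEOTIDE)


def ire_instance(rng: random.Random, stage: str) -> str:
    """Sample one IRE sequence that the given stage (and every later, more
    relaxed stage) detects at its start.

    Stems with a single repeated letter are resampled: they are the only
    construction under which a bacterial variant can alias back to the
    strict eukaryotic form, and bacterial instances must stay bacterial.
    """
    if stage not in IRE_EXPRESSIONS:
        raise ValueError(f"unknown IRE stage {stage!r}")
    stem_len, loop, extra, mism, wobble = 6, "CAGTG", 0, 0, 0
    if stage == "mismatch":
        mism = 1
    elif stage == "extra_loop_base":
        extra, mism = 1, rng.randint(0, 1)
    elif stage == "short_stem":
        stem_len, extra, mism = 5, rng.randint(0, 1), rng.randint(0, 1)
    elif stage == "alt_loop":
        loop = "GAGAG"
        stem_len = rng.choice((5, 6))
        extra, mism = rng.randint(0, 1), rng.randint(0, 1)
    elif stage == "wobble":
        wobble = 1
        stem_len = rng.choice((5, 6))
        loop = rng.choice(("CAGTG", "GAGAG"))
        extra, mism = rng.randint(0, 1), rng.randint(0, 1)

    stem = [rng.choice("ACGT") for _ in range(stem_len)]
    while len(set(stem)) == 1:
        stem = [rng.choice("ACGT") for _ in range(stem_len)]
    if wobble and not any(b in "GT" for b in stem):
        stem[rng.randrange(stem_len)] = rng.choice("GT")
    comp = [_WC[b] for b in reversed(stem)]

    wob_pos = None
    if wobble:
        candidates = [i for i, b in enumerate(stem) if b in "GT"]
        i = rng.choice(candidates)
        wob_pos = stem_len - 1 - i
        comp[wob_pos] = "T" if stem[i] == "G" else "G"
    if mism:
        j = rng.choice([k for k in range(stem_len) if k != wob_pos])
        base = stem[stem_len - 1 - j]
        comp[j] = rng.choice(
            [c for c in "ACGT" if c not in _WOBBLE_PARTNERS[base]]
        )
    extra_txt = rng.choice("ACGT") if extra else ""
    return "C" + "".join(stem) + loop + extra_txt + "".join(comp)


def ire_sampler(stage: Optional[str] = None) -> Callable[[random.Random], str]:
    """Motif sampler for :func:`generate_planted`.

    ``stage=None`` samples uniformly over the five bacterial stages
    (everything except ``basic``), emulating the mixed variant population
    the strict eukaryotic pattern misses entirely.
    """
    if stage is None:
        stages = IRE_STAGES[1:]
        return lambda rng: ire_instance(rng, rng.choice(stages))
    return lambda rng: ire_instance(rng, stage)


# ---------------------------------------------------------------------------
# Planted-motif sequence generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Placement:
    """Ground truth for one planted motif instance."""

    seq_id: str
    start: int  # 0-based half-open
    end: int
    text: str


def generate_planted(
    n_seqs: int,
    seq_len: int,
    motif: Union[str, Callable[[random.Random], str]],
    k_per_seq: int = 1,
    gc: float = 0.72,
    seed: int = 0,
) -> Tuple[List[SequenceRecord], List[Placement]]:
    """i.i.d. background at the given GC fraction with ``k_per_seq``
    non-overlapping motif instances planted per sequence.

    ``motif`` is a literal string or a sampler called once per instance.
    Deterministic for a fixed seed.  Raises :class:`FixtureError` when the
    instances cannot be packed into ``seq_len``.
    """
    if n_seqs < 1 or seq_len < 1 or k_per_seq < 0:
        raise FixtureError("need n_seqs, seq_len >= 1 and k_per_seq >= 0")
    rng = random.Random(seed)
    sampler = motif if callable(motif) else (lambda _rng: motif)

    def bg_char() -> str:
        return rng.choice("GC") if rng.random() < gc else rng.choice("AT")

    records: List[SequenceRecord] = []
    placements: List[Placement] = []
    for i in range(n_seqs):
        seq_id = f"seq{i + 1}"
        texts = [sampler(rng) for _ in range(k_per_seq)]
        total = sum(len(t) for t in texts)
        if total > seq_len:
            raise FixtureError(
                f"cannot pack {k_per_seq} instances ({total} nt) "
                f"into {seq_len} nt"
            )
        residues = [bg_char() for _ in range(seq_len)]
        # place left to right: sorted uniform offsets in the slack space,
        # shifted by the cumulative length of earlier instances
        offsets = sorted(rng.randint(0, seq_len - total) for _ in texts)
        consumed = 0
        for off, text in zip(offsets, texts):
            start = off + consumed
            residues[start : start + len(text)] = text
            placements.append(
                Placement(seq_id, start, start + len(text), text)
            )
            consumed += len(text)
        records.append(
            SequenceRecord(
                seq_id,
                "synthetic planted-motif sequence",
                "".join(residues),
                rna_flag=False,
                molecule=Molecule.NUCLEOTIDE,
            )
        )
    return records, placements


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------

_ORACLE_LIMIT = 5_000_000

_Binding = Tuple[int, int, str]  # start, end, text


def _bf_bound(units: List[PatternUnit]) -> int:
    prod = 1
    for u in units:
        if isinstance(u, RangeUnit):
            prod *= u.max_len - u.min_len + 1
        elif isinstance(u, (StringUnit, ComplementUnit, RepeatUnit)):
            prod *= u.budget.insertions + u.budget.deletions + 1
            prod *= 1 + u.budget.mismatches + u.budget.insertions
        elif isinstance(u, AlternativeUnit):
            prod *= _bf_bound(u.left) + _bf_bound(u.right)
    return prod


def _bf_edit_ok(
    template: List[FrozenSet[str]], window: str, mm: int, ins: int, dl: int
) -> bool:
    """Plain recursive alignment enumeration — no memoization or pruning, so
    it stays independent of the engine's search."""
    if not template:
        return len(window) <= ins
    if window and window[0] in template[0]:
        if _bf_edit_ok(template[1:], window[1:], mm, ins, dl):
            return True
    if window and mm > 0:
        if _bf_edit_ok(template[1:], window[1:], mm - 1, ins, dl):
            return True
    if window and ins > 0:
        if _bf_edit_ok(template, window[1:], mm, ins - 1, dl):
            return True
    if dl > 0:
        if _bf_edit_ok(template[1:], window, mm, ins, dl - 1):
            return True
    return False


def _bf_candidates(
    residues: str,
    unit: PatternUnit,
    pos: int,
    bindings: Dict[str, _Binding],
    ps: PatternSet,
) -> Iterator[Tuple[Optional[_Binding], int, Dict[str, _Binding]]]:
    """Yield (binding-or-None, end, updated bindings) in the engine's
    declared search order, computed from first principles."""
    n = len(residues)
    amap = alphabet_for(ps.molecule).ambiguity_map

    def bound_with(end: int) -> Tuple[_Binding, int, Dict[str, _Binding]]:
        b = (pos, end, residues[pos:end])
        nb = dict(bindings)
        nb[unit.name] = b
        return b, end, nb

    def budget_windows(tlen: int, budget: VariationBudget):
        for wlen in range(
            max(0, tlen - budget.deletions), tlen + budget.insertions + 1
        ):
            if pos + wlen <= n:
                yield residues[pos : pos + wlen], pos + wlen

    if isinstance(unit, StringUnit):
        template = [amap[ch] | {ch} for ch in unit.text]
        b = unit.budget
        for window, end in budget_windows(len(template), b):
            if _bf_edit_ok(template, window, b.mismatches, b.insertions,
                           b.deletions):
                yield bound_with(end)
    elif isinstance(unit, RangeUnit):
        for wlen in range(unit.min_len, unit.max_len + 1):
            if pos + wlen > n:
                break
            yield bound_with(pos + wlen)
    elif isinstance(unit, (ComplementUnit, RepeatUnit)):
        prior = bindings.get(unit.target)
        if prior is None:
            return
        text = prior[2]
        if isinstance(unit, ComplementUnit):
            rules = (
                ps.rule_declarations[unit.rules] if unit.rules
                else DEFAULT_RULES
            )
            template = [
                rules.pairs.get(ch, frozenset()) for ch in reversed(text)
            ]
        else:
            template = [frozenset(ch) for ch in text]
        b = unit.budget
        for window, end in budget_windows(len(template), b):
            if _bf_edit_ok(template, window, b.mismatches, b.insertions,
                           b.deletions):
                yield bound_with(end)
    elif isinstance(unit, AlternativeUnit):
        for branch in (unit.left, unit.right):
            for _, end, nb in _bf_assignments(residues, branch, pos,
                                              bindings, ps):
                b = (pos, end, residues[pos:end])
                nb2 = dict(nb)
                nb2[unit.name] = b
                yield b, end, nb2
    elif isinstance(unit, LengthConstraintUnit):
        total = 0
        for t in unit.targets:
            prior = bindings.get(t)
            if prior is None:
                return
            total += prior[1] - prior[0]
        ok = (
            total < unit.bound
            if unit.comparator == "less_than"
            else total > unit.bound
        )
        if ok:
            yield None, pos, bindings
    elif isinstance(unit, WeightUnit):
        end = pos + len(unit.matrix.columns)
        if end <= n:
            window = residues[pos:end]
            score = sum(
                col["ACGT".index(ch)] if ch in "ACGT" else 0.0
                for ch, col in zip(window, unit.matrix.columns)
            )
            if score >= unit.threshold:
                yield bound_with(end)
    elif isinstance(unit, AnyOfUnit):
        if pos < n and residues[pos] in unit.residues:
            yield bound_with(pos + 1)
    elif isinstance(unit, NotAnyOfUnit):
        if pos < n and residues[pos] not in unit.residues:
            yield bound_with(pos + 1)


def _bf_assignments(
    residues: str,
    units: List[PatternUnit],
    pos: int,
    bindings: Dict[str, _Binding],
    ps: PatternSet,
) -> Iterator[Tuple[List[Tuple[str, _Binding]], int, Dict[str, _Binding]]]:
    if not units:
        yield [], pos, bindings
        return
    unit = units[0]
    for b, end, nb in _bf_candidates(residues, unit, pos, bindings, ps):
        for rest, final, fb in _bf_assignments(
            residues, units[1:], end, nb, ps
        ):
            spans = ([(unit.name, b)] + rest) if b is not None else rest
            yield spans, final, fb


def brute_force_scan(record, ps: PatternSet) -> List[Match]:
    """Exhaustively enumerate every start offset, unit-length assignment,
    alternative branch and variation alignment; report the first accepting
    decomposition per start under the declared search order.

    Refuses combinatorially unbounded cases with :class:`OracleBoundError`.
    """
    violations = validate_pattern_set(ps)
    if violations:
        raise PatternValidationError(violations)
    residues = record if isinstance(record, str) else record.residues
    seq_id = "seq" if isinstance(record, str) else record.id
    if (len(residues) + 1) * _bf_bound(ps.units) > _ORACLE_LIMIT:
        raise OracleBoundError(
            "pattern/sequence combination exceeds the oracle's enumeration "
            "bound; shrink the case"
        )
    hits: List[Match] = []
    for s in range(len(residues)):
        for spans, end, _fb in _bf_assignments(residues, ps.units, s, {}, ps):
            hits.append(
                Match(
                    seq_id,
                    FORWARD,
                    s,
                    end,
                    [
                        UnitSpan(name, b[0], b[1], b[2])
                        for name, b in spans
                    ],
                    None,
                )
            )
            break
    return hits


# ---------------------------------------------------------------------------
# Random valid pattern sets and sequences for property testing
# ---------------------------------------------------------------------------

def random_sequence(rng: random.Random, max_len: int = 200,
                    gc: float = 0.5) -> str:
    n = rng.randint(1, max_len)
    return "".join(
        (rng.choice("GC") if rng.random() < gc else rng.choice("AT"))
        for _ in range(n)
    )


def _random_budget(rng: random.Random, max_budget: int) -> VariationBudget:
    return VariationBudget(
        rng.randint(0, max_budget),
        rng.randint(0, max_budget),
        rng.randint(0, max_budget),
    )


def _random_string_unit(rng: random.Random, max_budget: int) -> StringUnit:
    length = rng.randint(1, 5)
    letters = "ACGT" if rng.random() < 0.85 else "ACGTNRY"
    text = "".join(rng.choice(letters) for _ in range(length))
    return StringUnit(text, _random_budget(rng, max_budget))


def random_pattern_set(
    rng: random.Random,
    max_units: int = 5,
    max_budget: int = 1,
    molecule: Molecule = Molecule.NUCLEOTIDE,
) -> PatternSet:
    """A random valid nucleotide pattern set, sized for the oracle.

    Draws from every unit type the molecule admits: strings (occasionally
    with ambiguity codes), narrow ranges, complements (sometimes under
    declared wobble rules), repeats, two-branch alternatives, weights, and
    length constraints over earlier units.  All names are explicit, so the
    serializer emits them and round-trips are exact.
    """
    ps = PatternSet(molecule, [], {})
    use_rules = rng.random() < 0.3
    if use_rules:
        ps.rule_declarations["r1"] = PairingRules.from_pairs(
            "r1", ["AT", "TA", "GC", "CG", "GT", "TG"]
        )
    n_units = rng.randint(1, max_units)
    bindable: List[str] = []
    counter = 0

    def fresh_name() -> str:
        nonlocal counter
        counter += 1
        return f"p{counter}"

    for _ in range(n_units):
        choices = ["string", "string", "range", "weight", "alternative"]
        if bindable:
            choices += ["complement", "repeat", "length"]
        kind = rng.choice(choices)
        name = fresh_name()
        u: PatternUnit
        if kind == "string":
            u = _random_string_unit(rng, max_budget)
        elif kind == "range":
            lo = rng.randint(0, 3)
            u = RangeUnit(lo, lo + rng.randint(0, 2))
        elif kind == "weight":
            ncols = rng.randint(1, 3)
            cols = tuple(
                tuple(
                    float(rng.choice((0, 10, 25, 50, 80, 90)))
                    for _ in range(4)
                )
                for _ in range(ncols)
            )
            max_score = sum(max(c) for c in cols)
            u = WeightUnit(
                WeightMatrix(cols),
                threshold=round(rng.uniform(0, max_score), 1),
            )
        elif kind == "alternative":
            left: List[PatternUnit] = [_random_string_unit(rng, 0)]
            right: List[PatternUnit] = (
                [_random_string_unit(rng, 0)]
                if rng.random() < 0.7
                else [RangeUnit(1, 2)]
            )
            u = AlternativeUnit(left, right)
        elif kind == "complement":
            u = ComplementUnit(
                target=rng.choice(bindable),
                budget=_random_budget(rng, max_budget),
                rules="r1" if use_rules and rng.random() < 0.5 else None,
            )
        elif kind == "repeat":
            u = RepeatUnit(
                target=rng.choice(bindable),
                budget=_random_budget(rng, max_budget),
            )
        else:  # length constraint
            k = min(len(bindable), rng.randint(1, 2))
            targets = tuple(rng.sample(bindable, k))
            u = LengthConstraintUnit(
                targets,
                rng.choice(("less_than", "greater_than")),
                rng.randint(1, 12),
            )
        u.name = name
        u.explicit_name = True
        if isinstance(u, AlternativeUnit):
            for b in u.left + u.right:
                b.name = fresh_name()
                b.explicit_name = True
        ps.units.append(u)
        if not isinstance(u, LengthConstraintUnit):
            bindable.append(name)
    if validate_pattern_set(ps):  # pragma: no cover - degenerate draw
        return random_pattern_set(rng, max_units, max_budget, molecule)
    return ps


def plant_witness(rng: random.Random, ps: PatternSet, seq: str) -> str:
    """Overwrite a random stretch of ``seq`` with a text the pattern can
    match (sampled without spending any variation budget), raising the hit
    rate of random oracle-equivalence cases.  Returns ``seq`` unchanged when
    the pattern cannot be realized within it."""
    bindings: Dict[str, str] = {}

    def realize(units: List[PatternUnit]) -> Optional[str]:
        out = []
        for u in units:
            text: Optional[str]
            if isinstance(u, StringUnit):
                amap = alphabet_for(ps.molecule).ambiguity_map
                text = "".join(rng.choice(sorted(amap[ch])) for ch in u.text)
            elif isinstance(u, RangeUnit):
                text = "".join(
                    rng.choice("ACGT")
                    for _ in range(rng.randint(u.min_len, u.max_len))
                )
            elif isinstance(u, ComplementUnit):
                src = bindings.get(u.target)
                if src is None:
                    return None
                rules = (
                    ps.rule_declarations[u.rules] if u.rules else DEFAULT_RULES
                )
                letters = []
                for ch in reversed(src):
                    partners = sorted(rules.pairs.get(ch, frozenset()))
                    if not partners:
                        return None
                    letters.append(rng.choice(partners))
                text = "".join(letters)
            elif isinstance(u, RepeatUnit):
                text = bindings.get(u.target)
                if text is None:
                    return None
            elif isinstance(u, AlternativeUnit):
                text = realize(rng.choice((u.left, u.right)))
                if text is None:
                    return None
            elif isinstance(u, WeightUnit):
                text = "".join(
                    "ACGT"[max(range(4), key=col.__getitem__)]
                    for col in u.matrix.columns
                )
            elif isinstance(u, LengthConstraintUnit):
                text = ""
            elif isinstance(u, (AnyOfUnit, NotAnyOfUnit)):
                pool = (
                    sorted(u.residues)
                    if isinstance(u, AnyOfUnit)
                    else sorted(set("ACDEFGHIKLMNPQRSTVWY") - u.residues)
                )
                if not pool:
                    return None
                text = rng.choice(pool)
            else:
                return None
            bindings[u.name] = text
            out.append(text)
        return "".join(out)

    witness = realize(ps.units)
    if witness is None or not witness or len(witness) > len(seq):
        return seq
    start = rng.randint(0, len(seq) - len(witness))
    return seq[:start] + witness + seq[start + len(witness):]
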