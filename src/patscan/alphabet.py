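"""Alphabets, IUPAC ambiguity expansion, and base-pairing rule sets.

Nucleotide sequences are handled on a unified DNA alphabet: RNA input is
accepted and U is canonicalized to T internally (a flag records the original
spelling so reports can echo the input convention).  Pattern letters may be
any of the 15 IUPAC nucleotide codes; protein sequences use the 20 standard
amino acids plus X (any).

Pairing rule sets drive reverse-complement matching.  A rule set maps a
pattern-side base to the set of sequence-side bases allowed opposite it.
Rule sets are directional and need not be symmetric: declaring G·U wobble
pairs for RNA, for example, is written as the explicit pair list
``{AT,TA,GC,CG,GT,TG}``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Tuple

from Bio.Seq import Seq

from .errors import InvalidResidueError, PatScanError


class Molecule(str, enum.Enum):
    NUCLEOTIDE = "nucleotide"
    PROTEIN = "protein"


def _fs(letters: str) -> FrozenSet[str]:
    return frozenset(letters)


#: The 15 IUPAC nucleotide codes, each expanded to canonical {A,C,G,T} letters.
IUPAC_NUCLEOTIDE: Dict[str, FrozenSet[str]] = {
    "A": _fs("A"), "C": _fs("C"), "G": _fs("G"), "T": _fs("T"),
    "R": _fs("AG"), "Y": _fs("CT"), "S": _fs("CG"), "W": _fs("AT"),
    "K": _fs("GT"), "M": _fs("AC"),
    "B": _fs("CGT"), "D": _fs("AGT"), "H": _fs("ACT"), "V": _fs("ACG"),
    "N": _fs("ACGT"),
}

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

IUPAC_PROTEIN: Dict[str, FrozenSet[str]] = {
    **{aa: _fs(aa) for aa in AMINO_ACIDS},
    "X": _fs(AMINO_ACIDS),
}


@dataclass(frozen=True)
class Alphabet:
    """A residue alphabet with its ambiguity expansion table."""

    molecule: Molecule
    canonical_letters: FrozenSet[str]
    ambiguity_map: Dict[str, FrozenSet[str]] = field(hash=False)

    def is_valid_letter(self, letter: str) -> bool:
        return letter in self.ambiguity_map


DNA_ALPHABET = Alphabet(Molecule.NUCLEOTIDE, _fs("ACGT"), IUPAC_NUCLEOTIDE)
PROTEIN_ALPHABET = Alphabet(Molecule.PROTEIN, _fs(AMINO_ACIDS), IUPAC_PROTEIN)


def alphabet_for(molecule: Molecule) -> Alphabet:
    molecule = Molecule(molecule)
    return DNA_ALPHABET if molecule is Molecule.NUCLEOTIDE else PROTEIN_ALPHABET


@dataclass
class PairingRules:
    """Directional base-pairing rules: pattern base -> allowed sequence bases.

    Declarations may be written with U or T; both are canonicalized to T.
    A base with no entry simply has no admissible partner (empty set).
    """

    name: str
    pairs: Dict[str, FrozenSet[str]]

    @classmethod
    def from_pairs(cls, name: str, pair_tokens: Iterable[str]) -> "PairingRules":
        """Build from two-letter tokens: token "GT" means G may pair with T."""
        mapping: Dict[str, set] = {}
        for tok in pair_tokens:
            tok = tok.upper().replace("U", "T")
            if len(tok) != 2 or any(c not in "ACGT" for c in tok):
                raise PatScanError(
                    f"pairing rule token {tok!r} must be two canonical bases"
                )
            mapping.setdefault(tok[0], set()).add(tok[1])
        return cls(name, {k: frozenset(v) for k, v in mapping.items()})


#: Watson-Crick complementation, the default for complement units.
DEFAULT_RULES = PairingRules.from_pairs("default", ["AT", "TA", "GC", "CG"])

#: The RNA wobble extension used throughout the IRE worked example.
WOBBLE_RULES = PairingRules.from_pairs(
    "wobble", ["AT", "TA", "GC", "CG", "GT", "TG"]
)


def canonicalize_sequence(raw: str, molecule: Molecule) -> Tuple[str, bool]:
    """Canonicalize a raw residue string.

    Uppercases, strips whitespace, and (for nucleotides) maps U to T.
    Returns ``(canonical, rna_flag)`` where ``rna_flag`` records whether the
    input used RNA spelling (any U present), so that reports can echo it.

    Raises :class:`InvalidResidueError` naming the first offending character
    and its 1-based position in the raw input.
    """
    alphabet = alphabet_for(molecule)
    out: List[str] = []
    rna_flag = False
    for i, ch in enumerate(raw):
        if ch.isspace():
            continue
        up = ch.upper()
        if alphabet.molecule is Molecule.NUCLEOTIDE and up == "U":
            rna_flag = True
            up = "T"
        if not alphabet.is_valid_letter(up):
            raise InvalidResidueError(ch, i + 1)
        out.append(up)
    return "".join(out), rna_flag


def expand_ambiguity(letter: str, alphabet: Alphabet) -> FrozenSet[str]:
    """Expand a pattern letter to its set of canonical letters.

    Canonical letters expand to themselves; unknown letters raise.
    """
    try:
        return alphabet.ambiguity_map[letter.upper()]
    except KeyError:
        raise PatScanError(
            f"invalid pattern character {letter!r} for {alphabet.molecule.value}"
        ) from None


def complement_partners(base: str, rules: PairingRules) -> FrozenSet[str]:
    """Sequence letters allowed opposite ``base`` under a rule set.

    An empty set is a valid answer (the base has no partner under the rules).
    """
    return rules.pairs.get(base.upper(), frozenset())


def reverse_complement(s: str, rules: PairingRules) -> List[FrozenSet[str]]:
    """Set-valued reverse-complement template of a bound nucleotide string.

    Position ``i`` of the template holds the letters admissible opposite
    ``s[len(s)-1-i]``; the engine tests candidate windows against it
    letter-by-letter.
    """
    return [complement_partners(ch, rules) for ch in reversed(s)]


def reverse_complement_sequence(s: str) -> str:
    """Plain Watson-Crick reverse complement of a sequence string.

    Used for opposite-strand scanning; IUPAC ambiguity codes are complemented
    per the standard table.
    """
    return str(Seq(s).reverse_complement())
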