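# Methods

## The matching model

A pattern set is an ordered list of typed units scanned left to right from
every start offset of a sequence.  Each unit consumes a window of the
sequence and *binds* its matched span under its name (`p1`, `p2`, …;
unnamed units are auto-named in order of appearance).  Later units may
refer back to those bindings: a **complement** unit matches the reverse
complement of the *text* an earlier unit matched, a **repeat** unit matches
that text again, and a **length constraint** checks the summed length of
earlier spans.  This back-referencing is what lets the language express
stem-loops and repeats that a regular expression cannot (the stem's second
half must pair with whatever the first half actually matched, not with a
fixed string).

### Variation budgets

String, complement and repeat units accept a budget `[m,i,d]`: at most `m`
mismatched positions, `i` extra sequence letters (insertions), and `d`
skipped template positions (deletions).  The three caps are independent —
`[1,0,0]` admits one substitution but no indel, and a window that needs an
indel is not rescued by an unused mismatch.  A window of length `w` is
considered for a template of length `t` iff `t − d ≤ w ≤ t + i`; acceptance
is decided by a depth-first alignment search over (template position,
window position, counters) with memoization on visited states and pruning
on the residual length difference.  Among accepting alignments the one
minimizing `(insertions + deletions, mismatches)` is recorded; acceptance
never depends on this tie-break.

### Ambiguity semantics

Pattern letters may be IUPAC codes; a pattern position's admissible set is
its IUPAC expansion **plus the letter itself**, and a sequence letter
matches iff it is literally a member of that set.  Consequently sequence
`N` matches pattern `N` but not pattern `A` — deliberately conservative, so
N-masked regions cannot produce spurious hits.  Range units, by contrast,
accept any alphabet letter.

### Pairing rules

Complementation is table-driven.  The default table is Watson–Crick
(`A→T, T→A, G→C, C→G`); users may declare named rule sets as directed
pairs, e.g. `r1={AT,TA,GC,CG,GT,TG}` adds G·U wobble in both directions.
Rule sets are used exactly as declared and are not forced symmetric;
declarations written with U are canonicalized to T.  Internally all
nucleotide sequence is DNA-spelled (U→T on input, restored on output when
the input was RNA).

### Search order and determinism

All enumeration orders are fixed: units left to right; range lengths from
`min` upward; budgeted window lengths from `t − d` upward; alternatives
left branch first.  At each start offset the first acceptable full
assignment is reported (one match per offset); the scan then advances one
position (`per_start`, the default) or past the match (`non_overlapping`).
Two runs on identical input are byte-identical.  Weight units score
`Σ column[letter]` with non-ACGT letters contributing 0, and accept when
the score is **≥** the threshold (a minimum is inclusive); a match's score
is the sum over participating weight units.

Reverse-strand scanning runs the same forward scan on the Watson–Crick
reverse complement of the sequence and maps coordinates back; reverse hits
are appended after forward hits, and their unit spans stay in pattern
order (so their coordinates descend along the forward strand).

### Units inside alternatives

Branch contents are ordinary named units, so a later complement may target
a unit inside a branch.  If the search path took the other branch the
target is unbound and that path simply fails — a deliberate semantics for a
case the language leaves open.  Complementing or repeating a weight or
length-constraint unit is a validation error (they bind no meaningful
text).

## Grammar

The textual language (documented in `pattern_parser`) follows the
conventions of the classic command-line pattern-search tools so published
patterns remain usable: whitespace-separated items, `name=` prefixes,
`min...max` ranges, `~name` complements with optional rule-set prefix,
bare names as repeats, `( a | b )` alternatives, `length(p1+p2) < n`,
`{(a,c,g,t),…} > t` weights, and `any(FILV)` / `notany(DE)` on protein
input (the protein set forms have no standard printed syntax; the
`any()`/`notany()` spelling is this package's choice).  Serialization emits
a unit's name only when it was written explicitly or is referenced later,
so minimal patterns stay minimal and `parse(serialize(ps)) == ps` with
byte-stable re-serialization.

## Coordinates and report formats

Internally spans are 0-based half-open.  The FASTA-style and compact
writers and GFF3 render 1-based inclusive coordinates; BED renders 0-based
half-open.  Reverse-strand hits use descending coordinates in the
FASTA-style header (`>id:[end,start]`) and ascending coordinates plus a
strand column elsewhere, since GFF3/BED forbid descending spans.  GFF3
rows use source `patscan`, type `nucleotide_motif` (or
`polypeptide_motif`), the percent-encoded pattern and per-unit sub-spans in
the attributes; BED scores clamp the weight score into 0–1000 (0 when no
weight unit participated).  The exact layouts of the FASTA-style and
compact formats are declared normative here, as no printed standard
exists for them.

## Synthetic data

`generate_planted` produces i.i.d. background at a configurable GC
fraction with `k` non-overlapping motif instances per sequence at recorded
positions (sorted uniform offsets in the slack space, shifted by the
cumulative instance lengths).  The default GC of 0.72 emulates a GC-rich
actinobacterial genome, the setting in which bacterial IRE hunting is
interesting; the background is deliberately simple — it models composition
only, not codon structure, UTR base stacking or real stem-loop density, so
passing tests demonstrate correct *matching semantics*, not sensitivity or
specificity on real UTRs.

The IRE instance sampler draws a stem (5 or 6 nt), a loop (`CAGTG` or
`GAGAG`), an optional extra loop base, an optional single stem mismatch
(a base that pairs under neither Watson–Crick nor wobble rules), and an
optional wobble pair, according to the relaxation stage requested; mixed
sampling draws uniformly over the five bacterial stages.  Every bacterial
instance carries at least one deviation from the eukaryotic canon, and
stems of a single repeated letter are resampled — the one construction
whose extra-base variant can alias back to a perfect eukaryotic IRE — so
the strict pattern's zero recovery is structural, not a property of a
particular seed.

## Oracle

`brute_force_scan` is an independent check on the engine: it enumerates
every start offset, window-length assignment, branch choice and alignment
by plain recursion (no memoization, pruning or shared matcher code beyond
the IUPAC table) in the same declared search order, and refuses patterns
whose enumeration bound exceeds ~5 × 10⁶ states.  Engine and oracle are
compared on full decompositions, not just start offsets.

## Problem sizes and tolerances

The randomized suites use sequences ≤ 200 nt, patterns ≤ 6 units and
budgets ≤ 1 — sizes chosen so the brute-force oracle stays exact and the
full suite runs in seconds on one core.  The planted-IRE study uses 10
sequences × 2 kb with 2 instances each (20 ground-truth placements); an
instance counts as recovered when a hit starts exactly at its planted
offset.  All scoring is exact integer/float arithmetic; there are no
numerical tolerances anywhere in the engine.

## Known limitations

* Scanning is naive per-offset backtracking — fine at desk scale (tens of
  kb), no suffix-index acceleration for genome-scale work.
* No match statistics (E-values); hit counts on random background must be
  judged by the user.
* One match per start offset per strand: alternative decompositions at the
  same offset are not reported.
* Pseudoknot-specific syntax is not provided beyond what complement and
  repeat units already express.
* The length-constraint bound is validated as non-negative so `> 0`
  (a non-empty constraint) is expressible.
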