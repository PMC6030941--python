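# patscan

A pattern language and backtracking search engine for complex motifs in
DNA/RNA and protein sequences.

Many biologically meaningful features are not fixed strings: an RNA
stem-loop is a segment followed, after a loop, by its *reverse complement*;
regulatory sites tolerate mismatches; transcription-factor preferences are
position weight matrices.  `patscan` lets you compose such motifs from
typed units and scan FASTA sequences for them:

| unit          | syntax                         | matches                                        |
|---------------|--------------------------------|------------------------------------------------|
| string        | `CAGTG[1,0,0]`                 | literal residues (IUPAC codes allowed), with independent mismatch/insertion/deletion caps |
| range         | `5...6`                        | 5–6 arbitrary residues (a spacer)              |
| complement    | `~p2`, `r1~p2[1,0,0]`          | reverse complement of what unit `p2` matched, optionally under custom pairing rules |
| repeat        | `p2`                           | the exact text unit `p2` matched, again        |
| alternative   | `( CAGTG \| GAGAG )`           | either branch                                  |
| length        | `length(p1+p2) < 12`           | constrains the summed length of earlier matches |
| weight        | `{(90,10,0,0),(0,0,80,20)} > 150` | per-position percentages (A,C,G,T order) summed to a score, kept if score ≥ threshold |
| any/not any   | `any(FILV)`, `notany(DE)`      | one amino-acid position from/outside a set (protein input) |
| pairing rules | `r1={AT,TA,GC,CG,GT,TG}`       | declares which base may pair with which, e.g. adding G·U wobble for RNA |

RNA input is accepted transparently (U ↔ T); hits are echoed in the input
spelling.  Variation budgets are three separate maxima, not a combined edit
distance.  Scans are deterministic: units are tried left to right, ranges
shortest first, alternatives left branch first, and the first acceptable
assignment per start offset is reported.

## Worked example: iron-response elements

Iron-response elements (IREs) are RNA stem-loops bound by aconitase/IRP
regulators: a C bulge, a paired stem, and a CAGUG loop.  The strict
eukaryotic consensus as a pattern — C, six stem bases, the loop, then the
reverse complement of the stem:

```sh
$ cat utr.fa
>s1
CGUCAAGCAGUGCUUGAC
$ patscan scan utr.fa 'p1=C p2=6...6 p3=CAGUG p4=~p2'
>s1:[1,18]
C GUCAAG CAGUG CUUGAC
```

The hit spans bases 1–18 of `s1`; the four space-separated fields are the
bulge, the 5′ stem half, the loop, and the 3′ stem half (the Watson–Crick
reverse complement of `GUCAAG`).  Bacterial IREs are more variable —
mismatched stems, 5-nt stems, an extra loop base, GAGAG loops, G·U wobble
pairs — so the strict pattern finds nothing on bacterial UTRs.  Relaxing it
step by step:

```sh
patscan scan utrs.fa \
  'r1={AT,TA,GC,CG,GT,TG} p1=C p2=5...6 p3=( CAGUG | GAGAG ) p4=0...1 p5=r1~p2[1,0,0]' \
  --format gff3
```

allows one mispaired stem position, a 5–6 nt stem, either loop, an optional
extra loop base, and wobble pairing.  Output formats: FASTA-style
(default), `compact` (TSV), `gff3`, `bed`; `--both-strands` also scans the
reverse complement, `--max-hits`/`--non-overlapping` control enumeration.

Synthetic benchmark data with known ground truth:

```sh
patscan generate --n-seqs 10 --seq-len 2000 --gc 0.72 --k-per-seq 2 \
  --seed 1 --output planted.fa --bed truth.bed
```

plants bacterial-style IRE instances in GC-rich background (GC 0.72,
*Streptomyces*-like) at recorded positions.

The same functionality is available as a library — `parse_pattern`,
`scan_sequence`, `write_hits`, `generate_planted`, `brute_force_scan` — see
`docs/methods.md` for the semantics and design choices.

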