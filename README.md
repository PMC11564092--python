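# cas13bdesign

Design toolkit for PspCas13b CRISPR RNAs (crRNAs).  PspCas13b is an
RNA-guided RNA nuclease with a 30-nt spacer; which 30-nt target window a
guide binds makes the difference between >95% and no silencing, and the
difference is largely encoded in the spacer's own nucleotide composition.
This package implements the resulting rule-based design method for anyone
building RNA-knockdown experiments: it tiles a target transcript at
single-base resolution, filters and scores every candidate spacer, ranks
them, redesigns weak guides, predicts the effect of spacer–target
mismatches, and scans a transcriptome for off-target windows.

## The method in brief

* **Tiling.** A target of length L gives L − 29 candidate spacers, each
  the reverse complement of a 30-nt sense window.  Spacers containing a
  run of ≥4 T (DNA representation) are removed — such runs terminate
  Pol III transcription of the guide cassette.
* **Scoring.** Additive per-position weights: G at spacer positions 1–2
  scores +60 each; C at positions 1/2/3/4 scores −60/−60/−50/−40; C at
  the central positions 11, 12, 15, 16, 17 scores −5 each; all other
  (position, base) pairs score 0.  Totals span [−235, +120]; candidates
  are ranked by total score.  Potent guides match the consensus
  `GGNNNNNNNNDDNNDDDNNNNNNNNNNNNN` (D = A/G/U); guides matching
  `CCCCNNNNNNCCNNCCCNNNNNNNNNNNNN` are predicted ineffective.
* **Rescue.** An ineffective guide can be redesigned by inserting a 5' G
  or substituting positions 1–2 to G-G (`rescue_spacer`).
* **Mismatch tolerance.** A rule engine maps any mismatch pattern to
  TOLERATED / PARTIAL_LOSS / LOST: up to four scattered mismatches are
  tolerated (so ~26 nt of pairing is required), 3-nt blocks are
  tolerated away from the 5' end, and larger blocks lose activity except
  in the spacer centre.
* **Off-target scan.** Ungapped (Hamming) search of a transcriptome for
  windows complementary to a spacer: ≤4 mismatches → `likely_silenced`,
  5–15 → `unlikely_silenced`, >15 → suppressed as `nonexistent`.
* **Cohort analytics.** The analyses that derived the rules: potency
  cohort splitting (>90% / <50%), position weight matrices, delta
  nucleotide probabilities, PFS composition and classifier validation.

See `docs/methods.md` for assumptions, parameters and limitations.

## Worked example

A 100-nt demo target (no poly-A runs except one, seeded RNG):

```bash
cas13bdesign design target.fasta -o candidates.tsv
```

`candidates.tsv` (first rows; 71 candidates total for a 100-nt target):

```
target_id    start_1based  end_1based  spacer_seq                      retained  filter_reason  rank  score  motif_class
demo_target  1             30          GGGCUCUGUCGUCUCGUCCUUUUCCGCCGC  False     polyT
demo_target  2             31          GGGGCUCUGUCGUCUCGUCCUUUUCCGCCG  False     polyT
demo_target  3             32          GGGGGCUCUGUCGUCUCGUCCUUUUCCGCC  False     polyT
```

The first windows are rejected: the target's `AAAA` run puts a `UUUU`
(DNA: `TTTT`) tract in their spacers.  Of the 63 retained candidates the
scores range from −185 to +115, and the top-ranked design is

```
rank 1: positions 34–63, spacer GGUGGGCCCGCGUUGUUGCUCUGCGGCCCC, score 115
```

— the 5' G-G motif contributes +120 and the single C falling on a
penalised central position (position 11) costs −5; every other C sits at
an unweighted position, so the guide scores 115.  Mismatch-tolerance
queries:

```bash
$ cas13bdesign tolerance --positions 28,29,30
TOLERATED	block3_tolerated
$ cas13bdesign tolerance --positions 5,6,7,8
LOST	block4_lost
$ cas13bdesign tolerance --positions 4,10,18,26
TOLERATED	scattered_tolerated
```

A 3-nt mismatch block at the spacer 3' end costs nothing; a 4-nt block
near the 5' end abolishes silencing; four scattered single mismatches
are tolerated (which is why the off-target scanner treats ≤4-mismatch
windows as still at risk).  Adding `--offtarget transcriptome.fasta`
to `design` writes an off-target TSV for the top 10 ranked spacers.

Library use mirrors the CLI:

```python
from cas13bdesign import generate_candidates, rank_spacers, read_fasta, scan

target = read_fasta("target.fasta")[0]
ranked = rank_spacers(generate_candidates(target))
best = ranked[0]                       # .score, .motif_class, .candidate
hits = scan(best.candidate.spacer, read_fasta("transcriptome.fasta"))
```

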