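# Methods

## Background and model

PspCas13b is an RNA-guided RNA nuclease whose CRISPR RNA (crRNA) carries a
30-nt programmable spacer followed (3') by a 36-nt direct repeat.  Target
recognition is base pairing between the spacer and a complementary 30-nt
window of the transcript (the protospacer); duplex formation activates the
HEPN nuclease domains.  Silencing efficiency varies sharply between guides
that bind neighbouring windows, and the variation is largely explained by
spacer nucleotide composition at specific positions rather than by target
accessibility or a protospacer-flanking sequence (PFS).  This package
implements the resulting design method: tile, filter, score, rank, check
mismatch tolerance, and scan for off-targets.

## Tiling and filtering (`tiling`)

A target of length L yields L − 29 candidate spacers, one per single-base
shift; each spacer is the reverse complement of its sense target window,
with spacer position 1 at the 5' end pairing the last base of the window.
Only the sense strand is tiled (the enzyme binds the transcript itself).

Candidates whose spacer, written as DNA, contains four or more consecutive
T are discarded: in the U6-driven crRNA expression cassette such a run is
a Pol III termination signal and would truncate the guide.  The filter
inspects the spacer portion only, not the spacer/direct-repeat junction —
the bundled direct repeat itself contains a 4-T run, which is part of the
native scaffold and expressed downstream of the spacer in every guide, so
filtering across the junction would reject every design.  Windows
containing N are emitted but flagged (`ambiguous_base`), because the
scoring and tolerance rules are defined only over A/C/G/U.

## Positional potency score (`scoring`)

The score is a sum of independent per-position weights learned from the
composition difference between potent and ineffective guide cohorts:

| feature                  | positions          | weight            |
|--------------------------|--------------------|-------------------|
| G (bonus)                | 1, 2               | +60 each          |
| C (5' penalty)           | 1, 2, 3, 4         | −60, −60, −50, −40|
| C (central penalty)      | 11, 12, 15, 16, 17 | −5 each           |
| everything else          | —                  | 0                 |

Totals therefore lie in [−235, +120].  Ranking is a stable descending
sort with ties broken toward the 5'-most target window, so output order
is deterministic.  Weights live in `ScoringParams` and can be replaced
from a YAML config; the published values are defaults, not constants
wired into the code path.

Consensus classification is exposed separately from the numeric score:
`predicted_potent` requires G at positions 1–2 and no C at the central
penalised positions (GGNNNNNNNNDDNNDDDNNNNNNNNNNNNN with D = A/G/U);
`predicted_ineffective` fires on a C at a −60 position (1 or 2) or C at
six or more of the nine penalised positions, approximating the
ineffective consensus (CCCCNNNNNNCCNNCCCNNNNNNNNNNNNN) without flagging
every guide that carries a single mid-spacer C.  The "any vs all C
positions" reading of the ineffective consensus is genuinely open; the
numeric score is always reported so users can apply their own cut-off.

`rescue_spacer` generates the three 5' G-enrichment redesigns of a weak
guide — G insertion (31-nt spacer), position-1 G substitution, and
positions-1/2 G-G substitution.  The insertion variant keeps the full
30-nt complementarity and adds one unpaired 5' base; 31-mers are scored
5'-anchored (table position i applies to spacer position i).  The G-G
substitution can never lower the default score, since positions 1–2 move
to the maximal +60 weights.

## Mismatch-tolerance rule engine (`tolerance`)

The engine is a total function from a set of mismatched spacer positions
to one of three ordinal labels (TOLERATED, PARTIAL_LOSS, LOST), encoding
a comprehensive spacer mutagenesis.  Outcomes in the source data are
qualitative fluorescence readouts; "near-complete" loss maps to LOST and
"substantial/partial" to PARTIAL_LOSS.

A pattern is decomposed into maximal runs.  Single runs follow block
rules: runs of 1–2 are tolerated; 3-blocks are tolerated except over the
5'-terminal positions 1–3 (where they remove the G-rich 5' motif);
4-blocks retain partial activity only when starting in positions 9–17;
5-blocks only when contained in 6–15 or 26–30; blocks of six or more
always lose activity.  Scattered patterns (≥2 runs) are tolerated when
the total is ≤4, no run exceeds two nucleotides, and no run touches
positions 1–3; multiple 2–3-nt runs, or totals of five and above, lose
activity; anything unmatched falls through to a conservative LOST with
`rule_id="fallback"`.  Block placements that were not individually
tested inherit the label of the tested span they fall inside, and blocks
straddling two tested spans take the worse label; the `rule_id` of every
answer names the rule that fired, so interpolations are auditable.

The tables ship as editable YAML (`data/tolerance_rules_30.yaml`, plus a
strictly harsher `_27.yaml` for 3'-truncated 27-nt spacers, whose
scattered tolerance collapses to a single mismatch).  Two derived
quantities are computed by enumeration over the engine rather than
stored: the maximum tolerated number of scattered mismatches (4 for the
30-nt table) and its complement, the minimum required spacer–target
pairing (26 nt).  Changing the rule table changes both.

`classify_truncation` captures the end asymmetry of spacer shortening:
removing ≥3 nt from the 5' end abolishes silencing, while the 3' end
tolerates a 3-nt truncation and degrades gradually from 4 to 15 removed.

## Off-target scan (`offtarget`)

The scan is ungapped: every window of every transcript is scored by
Hamming distance to the reverse complement of the spacer.  (The published
web tool delegates candidate search to BLAST; the categorisation it
applies is purely a mismatch count, which ungapped matching reproduces
exactly for indel-free alignments.  Indel-tolerant search is a known
divergence and out of scope.)  Categories: ≤4 mismatches
`likely_silenced` (within the enzyme's tolerance), 5–15
`unlikely_silenced`, >15 `nonexistent` and suppressed from reports.
Percent match uses the spacer length (30) as denominator.  Hits in the
likely class are further annotated with the tolerance engine's label for
their exact mismatch pattern, refining 3–4-mismatch hits into
TOLERATED / PARTIAL_LOSS / LOST.

Two interchangeable algorithms: a numpy sliding-window count
(`scan_brute`), and a pigeonhole-seeded path (`scan_seeded`) that splits
the 30-nt protospacer into `mm_cap + 1` contiguous exact seeds over a
per-transcript k-mer index — any window within the cap must contain one
seed exactly — then verifies candidates by direct counting.  `scan`
dispatches to the seeded path for caps ≤4, where seeds are long enough
(6 nt) to prune well.  The two paths are asserted identical on planted
and random fixtures.  Windows containing N are skipped.

## Cohort analytics (`cohort`)

`split_cohorts` partitions measured guides by strict thresholds: potent
means efficiency > 90%, ineffective < 50%, everything between (including
the boundaries) excluded as ambiguous.  `pwm` gives per-position
nucleotide probabilities (columns sum to 1); `delta_probabilities`
subtracts a baseline composition (columns sum to 0).  The baseline of
the delta matrices is genuinely underdetermined; the default is the
cohort-pooled nucleotide frequency, with `uniform` (0.25) and custom
vectors as alternatives, and the choice is recorded in output metadata
by the CLI.  `pfs_matrices` computes the same probability matrices for
the 4-nt flanks on each side of the protospacer; an unbiased (~0.25
everywhere) result is the expected signature of a PFS-free enzyme.
`evaluate_predictions` cross-tabulates the consensus classifier against
measured cohorts and reports the fraction of predicted-potent guides
that measure potent (and the converse), e.g. 20 confirmed of 21
predicted ⇒ 0.952.  `covariate_correlation` accepts precomputed
covariate columns (such as externally computed folding energies) and
returns a Pearson r; energy computation itself is out of scope.

## Synthetic data (`fixtures`)

All generators are pure functions of their parameters and a seed (one
`numpy.random.default_rng` per call, no global state).

* Transcriptomes: i.i.d. bases at a requested GC fraction (default 0.5),
  lengths uniform in a range.  `plant_offtarget` overwrites a window
  with the spacer's reverse complement mutated at chosen spacer
  positions — each mutated base is the first base that no longer pairs —
  so the planted mismatch count is exact by construction; overlapping
  plants raise.
* Efficiency tables: default n = 201 guides, emulating the pooled
  tiled-screen cohort.  Three latent classes (35% potent / 45%
  ineffective / 20% intermediate) with mean efficiencies 95 / 30 / 70%
  and 5-point Gaussian noise truncated to [0, 100]; the class means sit
  clearly inside the >90% / <50% cohort definitions so the split is
  informative at this noise level.  Potent-class spacers are forced to G
  at positions 1–2 and stripped of central C; ineffective-class spacers
  get a 5' C and a 60% chance of C at each remaining penalised position.
  Flanks are uniform random (no PFS bias, matching the null finding).

What the fixtures do not emulate: real transcript length/GC/repeat
structure, expression levels, isoform overlap, secondary structure, and
measurement error correlated with sequence.  Passing tests therefore
demonstrate algorithmic correctness (exact counts, recovered planted
signals, method equivalence), not predictive performance on biological
data.

## Numerical and interface choices

* Coordinates are 0-based half-open internally, 1-based inclusive in all
  TSV output (column names say so).
* Matrix identities are asserted at 1e−9; probability comparisons in
  tests use sampling-scale tolerances.
* Ranking and scan output orders are fully specified (documented
  tie-breaks), making CLI output byte-stable for fixed inputs.
* CLI exit codes: 0 success, 1 usage/validation, 2 structurally empty
  result (e.g. every candidate poly-T-filtered).
* Problem sizes in the test suite (10^5 random spacers for score bounds,
  10^3 random targets for the filter oracle, a 50-transcript 100-kb
  planted transcriptome for scanner equivalence) keep the full suite
  under a minute while exercising every contract at realistic scale.

## Known limitations

* The score is rule-based and position-independent by construction; it
  cannot capture interactions between positions or target context.
* Tolerance labels for block placements never tested experimentally are
  interpolations (flagged via `rule_id`); treat PARTIAL_LOSS boundaries
  as approximate.
* The off-target scan ignores indels and scans sense strands only; it
  does not weight hits by expression.
* No thermodynamic terms (folding or hybridisation energies) are
  computed; external predictions can be attached as covariate columns.
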