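# Mismatch-tolerance rule table for the full-length 30-nt PspCas13b spacer.
# Positions are 1-based from the spacer 5' end.  Each rule records the
# mutagenesis panel it encodes; spans not covered experimentally inherit
# the label of the tested span they fall inside (rule_id marks them as
# interpolations), and blocks straddling two tested spans take the worse
# label.
spacer_len: 30
block_rules:
  - min_len: 1
    max_len: 2
    default_label: TOLERATED
    default_rule_id: block_le2_tolerated   # single substitutions showed no significant effect
    spans: []
  - min_len: 3
    max_len: 3
    default_label: TOLERATED
    default_rule_id: block3_tolerated      # panel f: 3-nt blocks tolerated throughout
    spans:
      - {match: within, start: 1, end: 3, label: LOST, rule_id: block3_5prime_GGG, panel: "panel f: G-G-G removal at the 5' end"}
  - min_len: 4
    max_len: 4
    default_label: LOST
    default_rule_id: block4_lost           # panel e: 1-4, 5-8, 21-24, 25-28 complete loss
    spans:
      - {match: start_in, start: 9, end: 17, label: PARTIAL_LOSS, rule_id: block4_central_partial, panel: "panel e: 9-12, 13-16, 17-20 partial"}
  - min_len: 5
    max_len: 5
    default_label: LOST
    default_rule_id: block5_lost           # panel d: 1-5, 16-20, 21-25 near-complete loss
    spans:
      - {match: within, start: 6, end: 15, label: PARTIAL_LOSS, rule_id: block5_partial_6_15, panel: "panel d: 6-10, 11-15 partial"}
      - {match: within, start: 26, end: 30, label: PARTIAL_LOSS, rule_id: block5_partial_3prime, panel: "panel d: 26-30 partial"}
  - min_len: 6
    max_len: 30
    default_label: LOST
    default_rule_id: block_ge6_lost        # panel c: 6-nt blocks compromised everywhere
    spans: []
scattered_rules:
  tolerated_max_total: 4        # up to four scattered mismatches tolerated (panel g)
  tolerated_max_run_len: 2
  forbidden_5prime_start: 1     # runs touching 1-3 disturb the 5' G-rich motif
  forbidden_5prime_end: 3
  lost_multi_run_min_len: 2     # several 2-3-nt runs spread over the spacer: loss (panel g)
  lost_multi_run_max_len: 3
  lost_min_total: 5             # more than four mismatches: substantial/complete loss
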