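# Mismatch-tolerance rule table for the truncated 27-nt spacer
# (3' Delta28-30).  Shortening the spacer exacerbates mismatch
# intolerance, so this table is strictly harsher than the 30-nt one.
spacer_len: 27
block_rules:
  - min_len: 1
    max_len: 1
    default_label: TOLERATED
    default_rule_id: single_tolerated      # singles at 7 and 14 fully tolerated
    spans:
      - {match: within, start: 21, end: 21, label: PARTIAL_LOSS, rule_id: single_21_partial, panel: "single mismatch at 21: substantial loss"}
  - min_len: 2
    max_len: 2
    default_label: LOST
    default_rule_id: block2_lost_conservative   # untested; scattered pairs already lose activity
    spans: []
  - min_len: 3
    max_len: 3
    default_label: LOST
    default_rule_id: block3_lost_conservative
    spans:
      - {match: within, start: 1, end: 3, label: LOST, rule_id: block3_5prime_GGG, panel: "G-G-G to C-C-C: complete loss"}
      - {match: within, start: 4, end: 12, label: PARTIAL_LOSS, rule_id: block3_partial_4_12, panel: "4-6, 7-9, 10-12: substantial loss"}
      - {match: within, start: 13, end: 21, label: TOLERATED, rule_id: block3_tolerated_13_21, panel: "13-15, 16-18, 19-21: fully tolerated"}
      - {match: within, start: 22, end: 24, label: LOST, rule_id: block3_lost_22_24, panel: "22-24: near-complete loss"}
  - min_len: 4
    max_len: 27
    default_label: LOST
    default_rule_id: block_ge4_lost
    spans: []
scattered_rules:
  tolerated_max_total: 0        # no scattered tolerance remains at 27 nt
  tolerated_max_run_len: 2
  forbidden_5prime_start: 1
  forbidden_5prime_end: 3
  lost_multi_run_min_len: 2
  lost_multi_run_max_len: 3
  lost_min_total: 2             # 2-5 nonconsecutive mismatches: substantial/complete loss
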