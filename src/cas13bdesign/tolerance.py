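"""Rule engine mapping spacer-target mismatch patterns to predicted
activity, encoding the comprehensive spacer-mutagenesis results.

PspCas13b silencing survives small spacer-target perturbations but
collapses beyond roughly four unpaired nucleotides.  The engine is a
total function from any subset of spacer positions (1 = 5' end) to one of
three ordinal labels:

* ``TOLERATED`` — negligible loss of silencing;
* ``PARTIAL_LOSS`` — substantial but incomplete loss;
* ``LOST`` — near-complete or complete loss.

Patterns are first decomposed into maximal runs of consecutive
mismatches.  A single run is matched against length-specific block rules
(3-nt blocks tolerated except over the 5' G-G-G motif; 4- and 5-nt blocks
partial only in the spacer centre; longer blocks always lethal).
Scattered patterns (two or more runs) are tolerated only when the total
count is at most four, no run exceeds two nucleotides and no run touches
positions 1-3; multiple 2-3-nt runs or five or more total mismatches
abolish silencing.  Untested placements inherit the label of the tested
span they fall inside (flagged by ``rule_id``); blocks straddling two
tested spans take the worse label.

The rule tables ship as human-readable YAML (one per supported spacer
length: 30 nt, and a stricter 27-nt table for 3'-truncated spacers) and
round-trip through :meth:`ToleranceRules.to_yaml`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Union

import yaml


class ActivityLabel(str, Enum):
    TOLERATED = "TOLERATED"
    PARTIAL_LOSS = "PARTIAL_LOSS"
    LOST = "LOST"


_SEVERITY = {
    ActivityLabel.TOLERATED: 0,
    ActivityLabel.PARTIAL_LOSS: 1,
    ActivityLabel.LOST: 2,
}


@dataclass(frozen=True)
class Activity:
    """Predicted activity label plus the id of the rule that fired."""

    label: ActivityLabel
    rule_id: str


@dataclass(frozen=True)
class MismatchPattern:
    """A set of mismatched spacer positions (1-based, 1 = 5' end)."""

    positions: frozenset[int]
    spacer_len: int = 30

    def __post_init__(self) -> None:
        positions = frozenset(self.positions)
        object.__setattr__(self, "positions", positions)
        for p in positions:
            if not 1 <= p <= self.spacer_len:
                raise ValueError(
                    f"mismatch position {p} outside [1, {self.spacer_len}]"
                )

    @property
    def runs(self) -> list[tuple[int, int]]:
        """Maximal runs of consecutive positions as (start, end) inclusive."""
        if not self.positions:
            return []
        ordered = sorted(self.positions)
        runs = []
        start = prev = ordered[0]
        for p in ordered[1:]:
            if p == prev + 1:
                prev = p
                continue
            runs.append((start, prev))
            start = prev = p
        runs.append((start, prev))
        return runs


@dataclass(frozen=True)
class SpanRule:
    match: str  # within | start_in | equals
    start: int
    end: int
    label: ActivityLabel
    rule_id: str
    panel: str = ""

    def matches(self, block_start: int, block_end: int) -> bool:
        if self.match == "within":
            return self.start <= block_start and block_end <= self.end
        if self.match == "start_in":
            return self.start <= block_start <= self.end
        if self.match == "equals":
            return (block_start, block_end) == (self.start, self.end)
        raise ValueError(f"unknown span matcher {self.match!r}")

    def overlaps(self, block_start: int, block_end: int) -> bool:
        return block_start <= self.end and self.start <= block_end


@dataclass(frozen=True)
class BlockRule:
    min_len: int
    max_len: int
    default_label: ActivityLabel
    default_rule_id: str
    spans: tuple[SpanRule, ...] = ()


@dataclass(frozen=True)
class ScatteredRules:
    tolerated_max_total: int
    tolerated_max_run_len: int
    forbidden_5prime_start: int
    forbidden_5prime_end: int
    lost_multi_run_min_len: int
    lost_multi_run_max_len: int
    lost_min_total: int


@dataclass(frozen=True)
class ToleranceRules:
    spacer_len: int
    block_rules: tuple[BlockRule, ...]
    scattered_rules: ScatteredRules

    def __post_init__(self) -> None:
        if not self.block_rules:
            raise ValueError("empty rule table: no block rules configured")

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "spacer_len": self.spacer_len,
            "block_rules": [
                {
                    "min_len": b.min_len,
                    "max_len": b.max_len,
                    "default_label": b.default_label.value,
                    "default_rule_id": b.default_rule_id,
                    "spans": [
                        {
                            "match": s.match,
                            "start": s.start,
                            "end": s.end,
                            "label": s.label.value,
                            "rule_id": s.rule_id,
                            "panel": s.panel,
                        }
                        for s in b.spans
                    ],
                }
                for b in self.block_rules
            ],
            "scattered_rules": {
                "tolerated_max_total": self.scattered_rules.tolerated_max_total,
                "tolerated_max_run_len": self.scattered_rules.tolerated_max_run_len,
                "forbidden_5prime_start": self.scattered_rules.forbidden_5prime_start,
                "forbidden_5prime_end": self.scattered_rules.forbidden_5prime_end,
                "lost_multi_run_min_len": self.scattered_rules.lost_multi_run_min_len,
                "lost_multi_run_max_len": self.scattered_rules.lost_multi_run_max_len,
                "lost_min_total": self.scattered_rules.lost_min_total,
            },
        }

    @classmethod
    def from_dict(cls, raw: dict) -> "ToleranceRules":
        blocks = tuple(
            BlockRule(
                min_len=int(b["min_len"]),
                max_len=int(b["max_len"]),
                default_label=ActivityLabel(b["default_label"]),
                default_rule_id=str(b["default_rule_id"]),
                spans=tuple(
                    SpanRule(
                        match=str(s["match"]),
                        start=int(s["start"]),
                        end=int(s["end"]),
                        label=ActivityLabel(s["label"]),
                        rule_id=str(s["rule_id"]),
                        panel=str(s.get("panel", "")),
                    )
                    for s in b.get("spans", [])
                ),
            )
            for b in raw.get("block_rules", [])
        )
        sc = raw["scattered_rules"]
        return cls(
            spacer_len=int(raw["spacer_len"]),
            block_rules=blocks,
            scattered_rules=ScatteredRules(
                tolerated_max_total=int(sc["tolerated_max_total"]),
                tolerated_max_run_len=int(sc["tolerated_max_run_len"]),
                forbidden_5prime_start=int(sc["forbidden_5prime_start"]),
                forbidden_5prime_end=int(sc["forbidden_5prime_end"]),
                lost_multi_run_min_len=int(sc["lost_multi_run_min_len"]),
                lost_multi_run_max_len=int(sc["lost_multi_run_max_len"]),
                lost_min_total=int(sc["lost_min_total"]),
            ),
        )

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "ToleranceRules":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path: Union[str, Path]) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


_RULE_FILES = {30: "tolerance_rules_30.yaml", 27: "tolerance_rules_27.yaml"}
_RULES_CACHE: dict[int, ToleranceRules] = {}


def default_rules(spacer_len: int = 30) -> ToleranceRules:
    """The bundled rule table for a supported spacer length (30 or 27)."""
    if spacer_len not in _RULE_FILES:
        raise ValueError(
            f"no bundled rule table for spacer length {spacer_len}; "
            f"supported: {sorted(_RULE_FILES)}"
        )
    if spacer_len not in _RULES_CACHE:
        text = (
            resources.files("cas13bdesign.data")
            .joinpath(_RULE_FILES[spacer_len])
            .read_text()
        )
        _RULES_CACHE[spacer_len] = ToleranceRules.from_dict(yaml.safe_load(text))
    return _RULES_CACHE[spacer_len]


def _classify_block(
    start: int, end: int, rules: ToleranceRules
) -> Activity:
    length = end - start + 1
    for rule in rules.block_rules:
        if not rule.min_len <= length <= rule.max_len:
            continue
        for span in rule.spans:
            if span.matches(start, end):
                return Activity(span.label, span.rule_id)
        # block straddles tested spans: take the worse overlapping label
        overlapping = [s for s in rule.spans if s.overlaps(start, end)]
        if overlapping:
            worst = max(
                [s.label for s in overlapping] + [rule.default_label],
                key=_SEVERITY.get,
            )
            return Activity(worst, f"{rule.default_rule_id}_straddle")
        return Activity(rule.default_label, rule.default_rule_id)
    raise ValueError(
        f"rule table for {rules.spacer_len}-nt spacers has no rule for a "
        f"{length}-nt mismatch block"
    )


def _classify_scattered(
    pattern: MismatchPattern, rules: ToleranceRules
) -> Activity:
    sc = rules.scattered_rules
    runs = pattern.runs
    total = len(pattern.positions)
    run_lens = [e - s + 1 for s, e in runs]
    touches_5prime = any(
        s <= sc.forbidden_5prime_end and sc.forbidden_5prime_start <= e
        for s, e in runs
    )
    if (
        total <= sc.tolerated_max_total
        and max(run_lens) <= sc.tolerated_max_run_len
        and not touches_5prime
    ):
        return Activity(ActivityLabel.TOLERATED, "scattered_tolerated")
    n_multi = sum(
        1
        for ln in run_lens
        if sc.lost_multi_run_min_len <= ln <= sc.lost_multi_run_max_len
    )
    if n_multi >= 2:
        return Activity(ActivityLabel.LOST, "scattered_multi_run_lost")
    if total >= sc.lost_min_total:
        return Activity(ActivityLabel.LOST, "scattered_total_lost")
    return Activity(ActivityLabel.LOST, "fallback")


def classify_mismatch_pattern(
    pattern: Union[MismatchPattern, Iterable[int]],
    spacer_len: int = 30,
    rules: ToleranceRules | None = None,
) -> Activity:
    """Predict the activity class of a spacer-target mismatch pattern.

    Total on subsets of {1..spacer_len}: every pattern maps to exactly one
    label, with unmatched scattered cases falling through to a
    conservative ``LOST`` (rule_id ``fallback``).
    """
    if not isinstance(pattern, MismatchPattern):
        pattern = MismatchPattern(frozenset(pattern), spacer_len=spacer_len)
    rules = rules or default_rules(pattern.spacer_len)
    if rules.spacer_len != pattern.spacer_len:
        raise ValueError(
            f"rule table is for {rules.spacer_len}-nt spacers but the "
            f"pattern declares {pattern.spacer_len}"
        )
    runs = pattern.runs
    if not runs:
        return Activity(ActivityLabel.TOLERATED, "empty_pattern")
    if len(runs) == 1:
        return _classify_block(runs[0][0], runs[0][1], rules)
    return _classify_scattered(pattern, rules)


def _scattered_patterns(
    spacer_len: int, k: int, max_run_len: int, zone_end: int
) -> Iterable[frozenset[int]]:
    """All k-subsets of (zone_end, spacer_len] whose maximal runs are short."""
    candidates = range(zone_end + 1, spacer_len + 1)
    for combo in itertools.combinations(candidates, k):
        run = 1
        ok = True
        for a, b in zip(combo, combo[1:]):
            run = run + 1 if b == a + 1 else 1
            if run > max_run_len:
                ok = False
                break
        if ok:
            yield frozenset(combo)


def max_tolerated_scattered(
    spacer_len: int = 30, rules: ToleranceRules | None = None
) -> int:
    """Largest number of scattered mismatches still predicted TOLERATED.

    Enumerates scattered patterns (maximal runs of at most two
    nucleotides, sparing the 5'-terminal positions 1-3) of growing size
    through the rule engine and returns the largest size for which some
    pattern remains tolerated.  Not hard-coded: changing the rule table
    changes the answer.
    """
    rules = rules or default_rules(spacer_len)
    sc = rules.scattered_rules
    best = -1
    for k in range(0, spacer_len + 1):
        found = False
        for positions in _scattered_patterns(
            spacer_len, k, sc.tolerated_max_run_len, sc.forbidden_5prime_end
        ):
            pattern = MismatchPattern(positions, spacer_len=spacer_len)
            if (
                classify_mismatch_pattern(pattern, rules=rules).label
                is ActivityLabel.TOLERATED
            ):
                found = True
                break
        if found:
            best = k
        else:
            break
    if best < 0:
        raise ValueError("rule table tolerates no pattern, not even empty")
    return best


def min_required_pairing(
    spacer_len: int = 30, rules: ToleranceRules | None = None
) -> int:
    """Minimum number of paired spacer-target bases needed for activity.

    Complement of :func:`max_tolerated_scattered`: 30 − 4 = 26 nt under
    the default table, i.e. the enzyme requires ~26-nt base pairing.
    """
    return spacer_len - max_tolerated_scattered(spacer_len, rules)


def classify_truncation(end: str, n_removed: int) -> Activity:
    """Predict activity after truncating the spacer from one end.

    5' truncations of three or more nucleotides abolish silencing (they
    remove the G-rich 5' motif); 3' truncations are tolerated up to three
    nucleotides and lose activity gradually from 4 to 15 removed.
    """
    if end not in {"5prime", "3prime"}:
        raise ValueError(f"end must be '5prime' or '3prime', got {end!r}")
    if not 0 <= n_removed <= 30:
        raise ValueError(f"n_removed {n_removed} outside [0, 30]")
    if end == "5prime":
        if n_removed >= 3:
            return Activity(ActivityLabel.LOST, "trunc_5prime_ge3")
        return Activity(ActivityLabel.TOLERATED, "trunc_5prime_lt3")
    if n_removed <= 3:
        return Activity(ActivityLabel.TOLERATED, "trunc_3prime_le3")
    if n_removed <= 15:
        return Activity(ActivityLabel.PARTIAL_LOSS, "trunc_3prime_gradual")
    return Activity(ActivityLabel.LOST, "trunc_3prime_gt15")
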