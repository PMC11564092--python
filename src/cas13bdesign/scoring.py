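"""Position-weighted potency scoring, ranking, motif classification and
5' G-rescue variant design.

The score of a spacer is the sum of independent per-position weights
derived from the composition of potent versus ineffective guide cohorts:

* G at spacer position 1 or 2: +60 each (the 5' G-G potency motif);
* C at positions 1, 2, 3, 4: −60, −60, −50, −40;
* C at the central positions 11, 12, 15, 16, 17: −5 each;
* every other (position, base) pair contributes 0.

Under these defaults the score of any 30-mer lies in [−235, +120].
Positions are 1-based from the spacer 5' end.  Weights are overridable
via a YAML config so the published values stay defaults, not constants
baked into the code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence, Union

import yaml

from .seqio import NucleotideSequence, to_rna
from .tiling import SpacerCandidate

DEFAULT_G_BONUS: Mapping[int, int] = {1: 60, 2: 60}
DEFAULT_C_PENALTY: Mapping[int, int] = {
    1: -60,
    2: -60,
    3: -50,
    4: -40,
    11: -5,
    12: -5,
    15: -5,
    16: -5,
    17: -5,
}

#: Central positions where a C disqualifies the potent consensus
#: (GGNNNNNNNNDDNNDDDNNNNNNNNNNNNN; D = A/G/U).
CENTRAL_C_POSITIONS = frozenset({11, 12, 15, 16, 17})

#: All nine C-penalised positions of the ineffective consensus
#: (CCCCNNNNNNCCNNCCCNNNNNNNNNNNNN).
PENALIZED_C_POSITIONS = frozenset({1, 2, 3, 4} | CENTRAL_C_POSITIONS)


class MotifClass(str, Enum):
    PREDICTED_POTENT = "predicted_potent"
    PREDICTED_INEFFECTIVE = "predicted_ineffective"
    INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class ScoringParams:
    """Per-position score weights (1-based spacer positions)."""

    g_bonus: Mapping[int, int] = field(default_factory=lambda: dict(DEFAULT_G_BONUS))
    c_penalty: Mapping[int, int] = field(
        default_factory=lambda: dict(DEFAULT_C_PENALTY)
    )
    spacer_len: int = 30

    def __post_init__(self) -> None:
        for pos in list(self.g_bonus) + list(self.c_penalty):
            if not 1 <= pos <= self.spacer_len:
                raise ValueError(
                    f"weight position {pos} outside [1, {self.spacer_len}]"
                )

    def contribution(self, position: int, base: str) -> int:
        """Weight of observing ``base`` at 1-based ``position``; 0 default."""
        if base == "G":
            return self.g_bonus.get(position, 0)
        if base == "C":
            return self.c_penalty.get(position, 0)
        return 0

    @property
    def min_total(self) -> int:
        """Lower score bound (all penalties realised): −235 by default."""
        return sum(min(v, 0) for v in self.c_penalty.values()) + sum(
            min(v, 0) for v in self.g_bonus.values()
        )

    @property
    def max_total(self) -> int:
        """Upper score bound (all bonuses realised): +120 by default."""
        return sum(max(v, 0) for v in self.g_bonus.values()) + sum(
            max(v, 0) for v in self.c_penalty.values()
        )

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "ScoringParams":
        """Load weight overrides from a config file.

        Recognised keys: ``g_bonus`` and ``c_penalty`` (mappings of
        1-based position to integer weight) and ``spacer_len``.
        """
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(
            g_bonus={int(k): int(v) for k, v in raw.get("g_bonus", DEFAULT_G_BONUS).items()},
            c_penalty={
                int(k): int(v)
                for k, v in raw.get("c_penalty", DEFAULT_C_PENALTY).items()
            },
            spacer_len=int(raw.get("spacer_len", 30)),
        )

    def to_yaml(self, path: Union[str, Path]) -> None:
        Path(path).write_text(
            yaml.safe_dump(
                {
                    "spacer_len": self.spacer_len,
                    "g_bonus": dict(self.g_bonus),
                    "c_penalty": dict(self.c_penalty),
                },
                sort_keys=True,
            )
        )


DEFAULT_PARAMS = ScoringParams()


@dataclass(frozen=True)
class ScoreBreakdown:
    """Per-position contributions, their sum, and the motif class."""

    per_position: tuple[tuple[int, str, int], ...]
    total: int
    motif_class: MotifClass


def _spacer_residues(spacer: Union[NucleotideSequence, str]) -> str:
    return to_rna(spacer).residues


def score_total(
    spacer: Union[NucleotideSequence, str],
    params: ScoringParams = DEFAULT_PARAMS,
) -> int:
    """Cumulative score without the per-position breakdown (fast path).

    Only the positions carrying a nonzero weight are inspected, which is
    what makes ranking thousands of tiled candidates cheap.
    """
    residues = _spacer_residues(spacer)
    total = 0
    for pos, w in params.g_bonus.items():
        if pos <= len(residues) and residues[pos - 1] == "G":
            total += w
    for pos, w in params.c_penalty.items():
        if pos <= len(residues) and residues[pos - 1] == "C":
            total += w
    return total


def score_spacer(
    spacer: Union[NucleotideSequence, str],
    params: ScoringParams = DEFAULT_PARAMS,
    allow_variable_length: bool = False,
) -> ScoreBreakdown:
    """Score a spacer and report every per-position contribution.

    The spacer must match ``params.spacer_len`` (30 by default) unless
    ``allow_variable_length`` is set; 31-nt G-insertion rescue spacers are
    scored 5'-anchored, i.e. table position i applies to spacer position i
    and positions beyond the table contribute 0.
    """
    residues = _spacer_residues(spacer)
    if "N" in residues:
        raise ValueError("cannot score a spacer containing N")
    if len(residues) != params.spacer_len and not allow_variable_length:
        raise ValueError(
            f"spacer is {len(residues)} nt, expected {params.spacer_len}"
        )
    per_position = tuple(
        (i, base, params.contribution(i, base))
        for i, base in enumerate(residues, start=1)
    )
    total = sum(c for _, _, c in per_position)
    return ScoreBreakdown(
        per_position=per_position,
        total=total,
        motif_class=classify_spacer(residues),
    )


def classify_spacer(spacer: Union[NucleotideSequence, str]) -> MotifClass:
    """Match a spacer against the potent / ineffective consensus motifs.

    predicted_potent: G at positions 1 and 2 and no C at the central
    positions {11, 12, 15, 16, 17}.  predicted_ineffective: C at a −60
    position (1 or 2), or C at six or more of the nine penalised
    positions.  Everything else is indeterminate.
    """
    residues = _spacer_residues(spacer)
    if residues[0] == "G" and residues[1] == "G" and not any(
        residues[p - 1] == "C" for p in CENTRAL_C_POSITIONS
    ):
        return MotifClass.PREDICTED_POTENT
    if residues[0] == "C" or residues[1] == "C":
        return MotifClass.PREDICTED_INEFFECTIVE
    n_penalized_c = sum(
        1 for p in PENALIZED_C_POSITIONS if p <= len(residues) and residues[p - 1] == "C"
    )
    if n_penalized_c >= 6:
        return MotifClass.PREDICTED_INEFFECTIVE
    return MotifClass.INDETERMINATE


@dataclass(frozen=True)
class RankedSpacer:
    rank: int
    candidate: SpacerCandidate
    score: int
    motif_class: MotifClass


def rank_spacers(
    candidates: Sequence[SpacerCandidate],
    params: ScoringParams = DEFAULT_PARAMS,
) -> list[RankedSpacer]:
    """Rank retained candidates by score, descending.

    Ties break on target start ascending (5'-most window first); ranks
    start at 1.  Candidates removed by the poly-T or ambiguity filters are
    ignored.
    """
    retained = [c for c in candidates if c.retained]
    scored = sorted(
        ((score_total(c.spacer, params), c) for c in retained),
        key=lambda sc: (-sc[0], sc[1].target_start),
    )
    return [
        RankedSpacer(
            rank=i,
            candidate=c,
            score=s,
            motif_class=classify_spacer(c.spacer),
        )
        for i, (s, c) in enumerate(scored, start=1)
    ]


@dataclass(frozen=True)
class RescueVariant:
    """A 5' G-enriched redesign of an ineffective spacer.

    ``introduced_mismatches`` counts bases that no longer pair with the
    original target window: the inserted G of INS_G is one unpaired 5'
    base; substitution variants count the changed positions.
    """

    label: str
    spacer: NucleotideSequence
    introduced_mismatches: int


def rescue_spacer(spacer: Union[NucleotideSequence, str]) -> list[RescueVariant]:
    """Design the three 5' G-rescue variants of a spacer.

    INS_G prepends a G (31 nt, original 30-nt complementarity retained);
    SUB_1G substitutes position 1 with G; SUB_12GG substitutes positions
    1-2 with G-G.  Variants identical to the input are omitted.
    """
    rna = to_rna(spacer)
    residues = rna.residues
    if len(residues) != 30:
        raise ValueError(f"rescue design expects a 30-nt spacer, got {len(residues)}")
    base_id = rna.id if isinstance(spacer, NucleotideSequence) else "spacer"
    variants: list[RescueVariant] = []
    variants.append(
        RescueVariant(
            label="INS_G",
            spacer=NucleotideSequence(f"{base_id}|INS_G", "G" + residues, "RNA"),
            introduced_mismatches=1,
        )
    )
    sub1 = "G" + residues[1:]
    if sub1 != residues:
        variants.append(
            RescueVariant(
                label="SUB_1G",
                spacer=NucleotideSequence(f"{base_id}|SUB_1G", sub1, "RNA"),
                introduced_mismatches=1,
            )
        )
    sub12 = "GG" + residues[2:]
    if sub12 != residues:
        variants.append(
            RescueVariant(
                label="SUB_12GG",
                spacer=NucleotideSequence(f"{base_id}|SUB_12GG", sub12, "RNA"),
                introduced_mismatches=sum(
                    1 for a, b in zip(residues[:2], "GG") if a != b
                ),
            )
        )
    return variants
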