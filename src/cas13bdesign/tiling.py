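"""Single-nucleotide tiled spacer generation and the poly-T filter.

A PspCas13b spacer is the 30-nt reverse complement of a sense target
window; tiling a target of length L with step 1 yields L − 29 candidate
spacers whose windows overlap by 29 nt.  Spacer position 1 is the 5' end
and pairs with the last base of its target window.

Candidates whose spacer, written in DNA, carries a run of four or more
consecutive T are removed: such a run acts as a Pol III (U6) transcription
terminator and would truncate the crRNA.  Windows containing ambiguous
bases (N) are emitted but flagged, because the design rules are defined
only over A/C/G/U.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from enum import Enum

from .seqio import NucleotideSequence, reverse_complement, to_dna, to_rna

#: Canonical 36-nt PspCas13b direct repeat (crRNA scaffold).  PspCas13b
#: carries the direct repeat 3' of the spacer, so a full-length crRNA is
#: spacer (30 nt) + direct repeat (36 nt) = 66 nt.
DIRECT_REPEAT = NucleotideSequence(
    id="PspCas13b_direct_repeat",
    residues="GUUGUGGAAGGUCCAGUUUUGAGGGGCUAUUACAAC",
    alphabet="RNA",
)

#: A run of this many consecutive T (in DNA space) or more disqualifies a
#: spacer: "more than three consecutive T bases".
POLY_T_RUN = 4

_POLY_T_RE = re.compile("T" * POLY_T_RUN)


class FilterReason(str, Enum):
    NONE = "none"
    POLY_T = "polyT"
    AMBIGUOUS_BASE = "ambiguous_base"


@dataclass(frozen=True)
class SpacerCandidate:
    """One tiled spacer with its target window (0-based, half-open).

    ``spacer`` is the RNA reverse complement of
    ``target[target_start:target_end]``; spacer position 1 (5') pairs with
    target position ``target_end - 1``.
    """

    spacer: NucleotideSequence
    target_id: str
    target_start: int
    target_end: int
    retained: bool = True
    filter_reason: FilterReason = FilterReason.NONE

    @property
    def start_1based(self) -> int:
        return self.target_start + 1

    @property
    def end_1based(self) -> int:
        return self.target_end


def polyT_filter(candidate: SpacerCandidate) -> SpacerCandidate:
    """Flag the candidate if its spacer (in DNA space) has a >=4 T run.

    Only the spacer portion is examined; the direct repeat is appended
    downstream of the scored region and is not part of the filter.
    """
    dna = to_dna(candidate.spacer).residues
    if _POLY_T_RE.search(dna):
        return replace(
            candidate, retained=False, filter_reason=FilterReason.POLY_T
        )
    return replace(candidate, retained=True, filter_reason=FilterReason.NONE)


def generate_candidates(
    target: NucleotideSequence, spacer_len: int = 30
) -> list[SpacerCandidate]:
    """All single-nucleotide tiled spacer candidates for a sense target.

    Returns exactly ``len(target) - spacer_len + 1`` candidates ordered by
    target start.  Windows containing N are flagged ``ambiguous_base``;
    every other candidate passes through :func:`polyT_filter`.
    """
    rna_target = to_rna(target)
    L = len(rna_target)
    if L < spacer_len:
        raise ValueError(
            f"target {target.id!r} is {L} nt, shorter than the "
            f"{spacer_len}-nt spacer"
        )
    candidates: list[SpacerCandidate] = []
    for start in range(L - spacer_len + 1):
        window = rna_target.residues[start : start + spacer_len]
        spacer = reverse_complement(
            NucleotideSequence(
                id=f"{target.id}|{start + 1}", residues=window, alphabet="RNA"
            )
        )
        cand = SpacerCandidate(
            spacer=spacer,
            target_id=target.id,
            target_start=start,
            target_end=start + spacer_len,
        )
        if "N" in window:
            cand = replace(
                cand, retained=False, filter_reason=FilterReason.AMBIGUOUS_BASE
            )
        else:
            cand = polyT_filter(cand)
        candidates.append(cand)
    return candidates


def assemble_crrna(
    spacer: NucleotideSequence | SpacerCandidate,
    direct_repeat: NucleotideSequence = DIRECT_REPEAT,
    allow_any_length: bool = False,
) -> NucleotideSequence:
    """Join spacer and direct repeat into the mature crRNA (5'->3').

    With the default 30-nt spacer and 36-nt repeat the product is the
    66-nt crRNA.  Rescue spacers carrying a 5' G insertion are 31 nt and
    require ``allow_any_length=True``.
    """
    if isinstance(spacer, SpacerCandidate):
        spacer = spacer.spacer
    if len(spacer) != 30 and not allow_any_length:
        raise ValueError(
            f"spacer is {len(spacer)} nt; expected 30 "
            "(pass allow_any_length=True to override)"
        )
    spacer_rna = to_rna(spacer)
    repeat_rna = to_rna(direct_repeat)
    return NucleotideSequence(
        id=f"{spacer.id}|crRNA",
        residues=spacer_rna.residues + repeat_rna.residues,
        alphabet="RNA",
    )
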