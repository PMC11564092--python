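"""Deterministic synthetic data for testing and demonstration.

Everything here is a pure function of its parameters and a seed, with a
single ``numpy.random.default_rng`` generator per call and no global
random state:

* random transcriptomes at a requested GC content, optionally carrying
  planted protospacer windows with an exact number of mismatches against
  a given spacer (ground truth for the off-target scanner);
* synthetic guide-efficiency tables that emulate the structure of a
  pooled tiled screen — 30-nt spacers plus percent silencing — with a
  plantable positional composition bias (potent guides enriched for the
  5' G-G motif, ineffective guides for 5' and central C bases).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import numpy as np

from .cohort import EfficiencyRecord
from .seqio import NucleotideSequence, reverse_complement, to_dna, write_fasta

_DNA = np.array(list("ACGT"))
_DNA_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class PlantedSite:
    """A protospacer window to embed in a transcript.

    ``mismatch_positions`` are spacer coordinates (1 = 5' end); the
    planted window will disagree with the spacer's complement at exactly
    those positions.
    """

    transcript_index: int
    insert_at: int
    spacer: str
    mismatch_positions: frozenset[int] = frozenset()


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic transcriptome."""

    seed: int
    n_transcripts: int = 10
    min_length: int = 500
    max_length: int = 3000
    gc_fraction: float = 0.5
    planted_sites: tuple[PlantedSite, ...] = ()

    def __post_init__(self) -> None:
        if not 0 <= self.gc_fraction <= 1:
            raise ValueError("gc_fraction must lie in [0, 1]")
        if self.min_length > self.max_length or self.min_length < 1:
            raise ValueError("invalid length range")


def random_sequence(rng: np.random.Generator, length: int, gc_fraction: float) -> str:
    """Random DNA with independent per-base GC probability."""
    p = np.array(
        [
            (1 - gc_fraction) / 2,
            gc_fraction / 2,
            gc_fraction / 2,
            (1 - gc_fraction) / 2,
        ]
    )
    return "".join(rng.choice(_DNA, size=length, p=p))


def plant_offtarget(
    transcript: str,
    spacer: Union[NucleotideSequence, str],
    mismatch_positions: Sequence[int],
    insert_at: int,
    occupied: Sequence[tuple[int, int]] = (),
) -> str:
    """Overwrite a transcript window with a (mutated) protospacer.

    The window at ``insert_at`` becomes the reverse complement of the
    spacer, then each listed spacer position is mutated to a
    deterministic non-complementary base, so the planted window's
    mismatch count against the spacer equals ``len(mismatch_positions)``
    exactly.  ``occupied`` lists (start, end) windows already planted in
    this transcript; overlap raises.
    """
    spacer_dna = to_dna(spacer).residues
    L = len(spacer_dna)
    if not 0 <= insert_at <= len(transcript) - L:
        raise ValueError(
            f"insert_at {insert_at} leaves no room for a {L}-nt window"
        )
    for start, end in occupied:
        if insert_at < end and start < insert_at + L:
            raise ValueError(
                f"planted window at {insert_at} overlaps existing site ({start}, {end})"
            )
    window = list(
        reverse_complement(spacer_dna, alphabet="DNA").residues
    )
    seen = set()
    for p in mismatch_positions:
        if not 1 <= p <= L:
            raise ValueError(f"mismatch position {p} outside [1, {L}]")
        if p in seen:
            raise ValueError(f"duplicate mismatch position {p}")
        seen.add(p)
        j = L - p  # window index paired with spacer position p
        complement = window[j]
        # first base (A<C<G<T) that differs from the pairing base
        window[j] = next(b for b in "ACGT" if b != complement)
    return transcript[:insert_at] + "".join(window) + transcript[insert_at + L :]


def make_transcriptome(spec: FixtureSpec) -> list[NucleotideSequence]:
    """Generate a reproducible random transcriptome with planted sites."""
    rng = np.random.default_rng(spec.seed)
    lengths = rng.integers(
        spec.min_length, spec.max_length + 1, size=spec.n_transcripts
    )
    transcripts = [
        random_sequence(rng, int(length), spec.gc_fraction) for length in lengths
    ]
    occupied: dict[int, list[tuple[int, int]]] = {}
    for site in spec.planted_sites:
        idx = site.transcript_index
        if not 0 <= idx < len(transcripts):
            raise ValueError(f"planted site transcript index {idx} out of range")
        transcripts[idx] = plant_offtarget(
            transcripts[idx],
            site.spacer,
            sorted(site.mismatch_positions),
            site.insert_at,
            occupied=occupied.get(idx, ()),
        )
        L = len(to_dna(site.spacer).residues)
        occupied.setdefault(idx, []).append((site.insert_at, site.insert_at + L))
    return [
        NucleotideSequence(id=f"tx{i:04d}", residues=t, alphabet="DNA")
        for i, t in enumerate(transcripts)
    ]


def write_transcriptome(spec: FixtureSpec, path: Union[str, Path]) -> None:
    write_fasta(make_transcriptome(spec), path)


@dataclass(frozen=True)
class EfficiencyBias:
    """Planted composition bias of a synthetic efficiency table.

    Potent guides start G-G and avoid C at the central positions
    (class mean 95%); ineffective guides carry a 5' C and C bases at
    several penalised positions (class mean 30%); intermediate guides
    are unconstrained (class mean 70%).  Fractions give the class mix.
    """

    potent_mean: float = 95.0
    ineffective_mean: float = 30.0
    intermediate_mean: float = 70.0
    fractions: tuple[float, float, float] = (0.35, 0.45, 0.20)

    def __post_init__(self) -> None:
        if not np.isclose(sum(self.fractions), 1.0):
            raise ValueError("class fractions must sum to 1")


def _random_spacer(rng: np.random.Generator, length: int = 30) -> list[str]:
    return list(rng.choice(_DNA, size=length))


def make_efficiency_table(
    n: int = 201,
    bias: EfficiencyBias | None = EfficiencyBias(),
    noise_sd: float = 5.0,
    seed: int = 0,
    spacer_len: int = 30,
    with_flanks: bool = True,
) -> list[EfficiencyRecord]:
    """Synthetic guide-efficiency table with a plantable sequence bias.

    With the default bias, potent-class spacers are forced to G at
    positions 1-2 (and stripped of central C), so the potent cohort's
    delta-probability matrix must recover a positive G signal at those
    positions.  ``bias=None`` removes all composition bias.  Efficiencies
    are normal around the class mean (``noise_sd`` percent points) and
    truncated to [0, 100]; flanks are uniform random, emulating the
    absence of a PFS constraint.
    """
    rng = np.random.default_rng(seed)
    records: list[EfficiencyRecord] = []
    if bias is None:
        classes = ["intermediate"] * n
        means = {"intermediate": 70.0}
    else:
        classes = list(
            rng.choice(
                ["potent", "ineffective", "intermediate"],
                size=n,
                p=list(bias.fractions),
            )
        )
        means = {
            "potent": bias.potent_mean,
            "ineffective": bias.ineffective_mean,
            "intermediate": bias.intermediate_mean,
        }
    central = [11, 12, 15, 16, 17]
    for cls in classes:
        spacer = _random_spacer(rng, spacer_len)
        if bias is not None and cls == "potent":
            spacer[0] = spacer[1] = "G"
            for p in central:
                if spacer[p - 1] == "C":
                    spacer[p - 1] = str(rng.choice(["A", "G", "T"]))
        elif bias is not None and cls == "ineffective":
            spacer[0] = "C"
            for p in [2, 3, 4] + central:
                if rng.random() < 0.6:
                    spacer[p - 1] = "C"
        efficiency = float(
            np.clip(rng.normal(means[cls], noise_sd), 0.0, 100.0)
        )
        records.append(
            EfficiencyRecord(
                spacer="".join(spacer),
                efficiency=efficiency,
                flank_up=random_sequence(rng, 4, 0.5) if with_flanks else None,
                flank_down=random_sequence(rng, 4, 0.5) if with_flanks else None,
            )
        )
    return records
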