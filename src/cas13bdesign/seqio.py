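"""Sequence parsing, validation and alphabet handling.

All downstream modules operate on :class:`NucleotideSequence`, a thin
validated wrapper around an uppercase residue string.  Spacers and target
RNAs are canonically represented in the RNA alphabet (``U``); the poly-T
filter and oligo export work on the DNA representation (``T``).  A record
never mixes ``T`` and ``U``.

FASTA parsing is delegated to Biopython; a light line-level pre-scan adds
line-numbered error messages for malformed input.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Literal, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

Alphabet = Literal["DNA", "RNA"]

_DNA_SYMBOLS = frozenset("ACGTN")
_RNA_SYMBOLS = frozenset("ACGUN")

_DNA_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_RNA_COMPLEMENT = str.maketrans("ACGUN", "UGCAN")


class FastaParseError(ValueError):
    """Raised for malformed FASTA input, naming the offending line."""


@dataclass(frozen=True)
class NucleotideSequence:
    """A validated single-stranded nucleotide sequence.

    Parameters
    ----------
    id:
        Record label (FASTA header word).
    residues:
        Uppercase residue string over ``{A, C, G, T/U, N}``.
    alphabet:
        ``"DNA"`` or ``"RNA"``.  Auto-detected by :func:`read_fasta`
        (presence of ``U`` implies RNA, otherwise DNA).
    """

    id: str
    residues: str
    alphabet: Alphabet = "RNA"

    def __post_init__(self) -> None:
        residues = self.residues.upper()
        object.__setattr__(self, "residues", residues)
        if "T" in residues and "U" in residues:
            raise ValueError(
                f"sequence {self.id!r} mixes T and U; declare one alphabet"
            )
        allowed = _DNA_SYMBOLS if self.alphabet == "DNA" else _RNA_SYMBOLS
        bad = set(residues) - allowed
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains symbols {sorted(bad)} "
                f"not in the {self.alphabet} alphabet"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, item: Union[int, slice]) -> str:
        return self.residues[item]

    @property
    def has_ambiguous(self) -> bool:
        return "N" in self.residues


SequenceLike = Union[NucleotideSequence, str]


def _residues_of(seq: SequenceLike) -> str:
    return seq.residues if isinstance(seq, NucleotideSequence) else seq.upper()


def detect_alphabet(residues: str) -> Alphabet:
    """RNA iff a ``U`` is present; a pure A/C/G/N string counts as DNA."""
    return "RNA" if "U" in residues.upper() else "DNA"


def _prescan_fasta(text: str) -> None:
    """Line-level validation so parse errors can name the line."""
    saw_header = False
    saw_any = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        saw_any = True
        if line.startswith(">"):
            saw_header = True
            if len(line) == 1:
                raise FastaParseError(f"line {lineno}: empty FASTA header")
            continue
        if not saw_header:
            raise FastaParseError(
                f"line {lineno}: sequence data before any '>' header"
            )
        if not line.isalpha():
            raise FastaParseError(
                f"line {lineno}: non-alphabetic characters in sequence line"
            )
    if not saw_any:
        raise FastaParseError("empty FASTA file")
    if not saw_header:
        raise FastaParseError("no FASTA records found")


def read_fasta(path: Union[str, Path]) -> list[NucleotideSequence]:
    """Read a multi-record FASTA file into validated sequences.

    Residues are uppercased; the alphabet of each record is auto-detected
    (``U`` anywhere in the record makes it RNA).  A record mixing T and U,
    an empty file, or a malformed line raises :class:`FastaParseError` /
    ``ValueError``.
    """
    text = Path(path).read_text()
    _prescan_fasta(text)
    records = []
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        residues = str(rec.seq).upper()
        if not residues:
            raise FastaParseError(f"record {rec.id!r} has no sequence")
        records.append(
            NucleotideSequence(
                id=rec.id, residues=residues, alphabet=detect_alphabet(residues)
            )
        )
    return records


def write_fasta(
    records: Iterable[NucleotideSequence], path: Union[str, Path], width: int = 70
) -> None:
    """Write records as wrapped FASTA."""
    seq_records = [
        SeqRecord(Seq(r.residues), id=r.id, description="") for r in records
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(seq_records)


def reverse_complement(seq: SequenceLike, alphabet: Alphabet | None = None) -> NucleotideSequence:
    """Reverse complement in the sequence's own alphabet (N maps to N).

    An involution: applying it twice restores the input.
    """
    if isinstance(seq, NucleotideSequence):
        alphabet = seq.alphabet
        residues = seq.residues
        label = seq.id
    else:
        residues = seq.upper()
        alphabet = alphabet or detect_alphabet(residues)
        label = "revcomp"
    table = _DNA_COMPLEMENT if alphabet == "DNA" else _RNA_COMPLEMENT
    rc = residues.translate(table)[::-1]
    return NucleotideSequence(id=label, residues=rc, alphabet=alphabet)


def to_rna(seq: SequenceLike) -> NucleotideSequence:
    """Convert T→U; identity on RNA input."""
    if isinstance(seq, NucleotideSequence):
        if seq.alphabet == "RNA":
            return seq
        return NucleotideSequence(seq.id, seq.residues.replace("T", "U"), "RNA")
    return NucleotideSequence("seq", seq.upper().replace("T", "U"), "RNA")


def to_dna(seq: SequenceLike) -> NucleotideSequence:
    """Convert U→T; identity on DNA input."""
    if isinstance(seq, NucleotideSequence):
        if seq.alphabet == "DNA":
            return seq
        return NucleotideSequence(seq.id, seq.residues.replace("U", "T"), "DNA")
    return NucleotideSequence("seq", seq.upper().replace("U", "T"), "DNA")


def rename(seq: NucleotideSequence, new_id: str) -> NucleotideSequence:
    return replace(seq, id=new_id)
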