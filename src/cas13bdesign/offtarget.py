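"""Ungapped transcriptome off-target scan for a spacer.

Every length-30 window of every sense-strand transcript is compared with
the reverse complement of the spacer (Hamming distance; Cas13 binds the
transcript itself, so only the sense strand is scanned).  Hits are
categorized by mismatch count:

* ``likely_silenced`` — at most 4 mismatches, within the enzyme's
  tolerance, so the off-target transcript is at risk;
* ``unlikely_silenced`` — 5 to 15 mismatches: complementarity is partial
  and silencing activity is expected to be lost;
* ``nonexistent`` — more than 15 mismatches, suppressed from reports.

Two search paths are provided and must agree: a brute-force sliding
window count (vectorised with numpy) and a pigeonhole-seeded search that
partitions the 30-nt protospacer into ``mm_cap + 1`` exact seeds over a
k-mer index — any window with at most ``mm_cap`` mismatches must contain
one seed exactly.  Seeding is used automatically for small mismatch caps
where it prunes effectively.
"""

from __future__ import annotations

import logging
import warnings
from collections import defaultdict
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence, Union

import numpy as np

from .seqio import NucleotideSequence, reverse_complement, to_rna
from .tolerance import Activity, classify_mismatch_pattern

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OffTargetThresholds:
    """Mismatch-count boundaries of the off-target categories."""

    silencing_loss_min_mm: int = 5
    nonexistent_min_mm: int = 16  # "greater than 15"

    def __post_init__(self) -> None:
        if not 0 < self.silencing_loss_min_mm <= self.nonexistent_min_mm:
            raise ValueError(
                "require 0 < silencing_loss_min_mm <= nonexistent_min_mm"
            )


DEFAULT_THRESHOLDS = OffTargetThresholds()


class Category(str, Enum):
    LIKELY_SILENCED = "likely_silenced"
    UNLIKELY_SILENCED = "unlikely_silenced"
    NONEXISTENT = "nonexistent"


@dataclass(frozen=True)
class OffTargetHit:
    """One complementary window found in a transcript.

    ``mismatch_positions`` are spacer coordinates (1 = 5' end);
    ``percent_match`` is the fraction of paired bases over the full
    spacer length.
    """

    spacer_id: str
    transcript_id: str
    window_start: int  # 0-based inclusive
    window_end: int  # exclusive
    mismatch_count: int
    mismatch_positions: frozenset[int]
    percent_match: float
    category: Category
    tolerance: Activity | None = None


def categorize(
    mm_count: int, thresholds: OffTargetThresholds = DEFAULT_THRESHOLDS
) -> Category:
    """Map a mismatch count to its off-target category."""
    if mm_count < 0:
        raise ValueError(f"negative mismatch count {mm_count}")
    if mm_count < thresholds.silencing_loss_min_mm:
        return Category.LIKELY_SILENCED
    if mm_count < thresholds.nonexistent_min_mm:
        return Category.UNLIKELY_SILENCED
    return Category.NONEXISTENT


def count_mismatches(
    spacer: Union[NucleotideSequence, str],
    window: Union[NucleotideSequence, str],
) -> tuple[int, frozenset[int]]:
    """Mismatch count and spacer-coordinate positions for one window.

    Spacer position p (1-based from the 5' end) pairs with window
    position ``L - p`` (0-based), i.e. the window matches exactly when it
    equals the reverse complement of the spacer.
    """
    spacer_rna = to_rna(spacer).residues
    window_rna = to_rna(window).residues
    if len(spacer_rna) != len(window_rna):
        raise ValueError(
            f"spacer ({len(spacer_rna)} nt) and window ({len(window_rna)} nt) differ in length"
        )
    probe = reverse_complement(spacer_rna, alphabet="RNA").residues
    L = len(probe)
    positions = frozenset(
        L - j for j in range(L) if probe[j] != window_rna[j]
    )
    return len(positions), positions


def _encode(residues: str) -> np.ndarray:
    return np.frombuffer(residues.encode("ascii"), dtype=np.uint8)


def _windows_mismatch_counts(
    probe: np.ndarray, transcript: np.ndarray
) -> np.ndarray:
    """Mismatch count of every window via a vectorised sliding view."""
    view = np.lib.stride_tricks.sliding_window_view(transcript, len(probe))
    return (view != probe).sum(axis=1)


def _make_hit(
    spacer_id: str,
    probe: str,
    transcript: NucleotideSequence,
    start: int,
    thresholds: OffTargetThresholds,
    annotate: bool,
) -> OffTargetHit:
    L = len(probe)
    window = to_rna(transcript).residues[start : start + L]
    positions = frozenset(L - j for j in range(L) if probe[j] != window[j])
    mm = len(positions)
    category = categorize(mm, thresholds)
    tolerance = None
    if annotate and category is Category.LIKELY_SILENCED:
        tolerance = classify_mismatch_pattern(positions, spacer_len=L)
    return OffTargetHit(
        spacer_id=spacer_id,
        transcript_id=transcript.id,
        window_start=start,
        window_end=start + L,
        mismatch_count=mm,
        mismatch_positions=positions,
        percent_match=(L - mm) / L,
        category=category,
        tolerance=tolerance,
    )


def scan_brute(
    spacer: Union[NucleotideSequence, str],
    transcriptome: Sequence[NucleotideSequence],
    thresholds: OffTargetThresholds = DEFAULT_THRESHOLDS,
    max_report_mm: int = 15,
    annotate_tolerance: bool = True,
) -> list[OffTargetHit]:
    """Full sliding-window scan: count mismatches at every offset."""
    spacer_seq = to_rna(spacer)
    spacer_id = (
        spacer.id if isinstance(spacer, NucleotideSequence) else "spacer"
    )
    probe = reverse_complement(spacer_seq).residues
    probe_arr = _encode(probe)
    L = len(probe)
    hits: list[OffTargetHit] = []
    for transcript in transcriptome:
        t_rna = to_rna(transcript).residues
        if len(t_rna) < L:
            continue
        t_arr = _encode(t_rna)
        counts = _windows_mismatch_counts(probe_arr, t_arr)
        if "N" in t_rna:
            has_n = np.convolve(
                (t_arr == ord("N")).astype(int), np.ones(L, dtype=int), "valid"
            )
            counts = np.where(has_n > 0, L + 1, counts)
        for start in np.nonzero(counts <= max_report_mm)[0]:
            hits.append(
                _make_hit(
                    spacer_id,
                    probe,
                    transcript,
                    int(start),
                    thresholds,
                    annotate_tolerance,
                )
            )
    hits.sort(key=lambda h: (h.mismatch_count, h.transcript_id, h.window_start))
    return hits


def _seed_chunks(L: int, n_seeds: int) -> list[tuple[int, int]]:
    """Partition [0, L) into n_seeds contiguous chunks of near-equal size."""
    bounds = np.linspace(0, L, n_seeds + 1).astype(int)
    return [(int(a), int(b)) for a, b in zip(bounds[:-1], bounds[1:])]


def scan_seeded(
    spacer: Union[NucleotideSequence, str],
    transcriptome: Sequence[NucleotideSequence],
    thresholds: OffTargetThresholds = DEFAULT_THRESHOLDS,
    max_report_mm: int = 4,
    annotate_tolerance: bool = True,
) -> list[OffTargetHit]:
    """Pigeonhole-seeded scan for small mismatch caps.

    The protospacer (reverse complement of the spacer) is split into
    ``max_report_mm + 1`` contiguous seeds; a window within the mismatch
    cap must contain at least one seed exactly, so exact seed matches
    found through a k-mer index nominate candidate windows which are then
    verified by direct counting.
    """
    spacer_seq = to_rna(spacer)
    spacer_id = (
        spacer.id if isinstance(spacer, NucleotideSequence) else "spacer"
    )
    probe = reverse_complement(spacer_seq).residues
    L = len(probe)
    chunks = _seed_chunks(L, max_report_mm + 1)
    seeds = [(offset, probe[offset:end]) for offset, end in chunks]
    hits: list[OffTargetHit] = []
    for transcript in transcriptome:
        t_rna = to_rna(transcript).residues
        if len(t_rna) < L:
            continue
        # k-mer index per seed length over this transcript
        index: dict[int, dict[str, list[int]]] = {}
        for k in {len(s) for _, s in seeds}:
            kmer_pos: dict[str, list[int]] = defaultdict(list)
            for i in range(len(t_rna) - k + 1):
                kmer_pos[t_rna[i : i + k]].append(i)
            index[k] = kmer_pos
        candidates: set[int] = set()
        for offset, seed in seeds:
            for pos in index[len(seed)].get(seed, ()):
                start = pos - offset
                if 0 <= start <= len(t_rna) - L:
                    candidates.add(start)
        for start in sorted(candidates):
            window = t_rna[start : start + L]
            if "N" in window:
                continue
            mm = sum(1 for a, b in zip(probe, window) if a != b)
            if mm <= max_report_mm:
                hits.append(
                    _make_hit(
                        spacer_id,
                        probe,
                        transcript,
                        start,
                        thresholds,
                        annotate_tolerance,
                    )
                )
    hits.sort(key=lambda h: (h.mismatch_count, h.transcript_id, h.window_start))
    return hits


def scan(
    spacer: Union[NucleotideSequence, str],
    transcriptome: Sequence[NucleotideSequence],
    thresholds: OffTargetThresholds = DEFAULT_THRESHOLDS,
    max_report_mm: int = 15,
    annotate_tolerance: bool = True,
    method: str = "auto",
) -> list[OffTargetHit]:
    """Scan a transcriptome for windows complementary to the spacer.

    Windows with more than ``max_report_mm`` mismatches fall in the
    ``nonexistent`` class and are suppressed.  ``method`` selects
    ``"brute"``, ``"seeded"`` or ``"auto"`` (seeded when the cap is at
    most 4, where pigeonhole seeds prune effectively).
    """
    if not transcriptome:
        warnings.warn("empty transcriptome: no off-target scan performed")
        return []
    if method == "auto":
        method = "seeded" if max_report_mm <= 4 else "brute"
    if method == "seeded":
        return scan_seeded(
            spacer, transcriptome, thresholds, max_report_mm, annotate_tolerance
        )
    if method == "brute":
        return scan_brute(
            spacer, transcriptome, thresholds, max_report_mm, annotate_tolerance
        )
    raise ValueError(f"unknown scan method {method!r}")


def hits_to_records(hits: Iterable[OffTargetHit]) -> list[dict]:
    """Rows for the hits TSV (1-based window coordinates)."""
    return [
        {
            "spacer_id": h.spacer_id,
            "transcript_id": h.transcript_id,
            "start_1based": h.window_start + 1,
            "end_1based": h.window_end,
            "mm_count": h.mismatch_count,
            "percent_match": round(h.percent_match, 4),
            "category": h.category.value,
            "tolerance_label": h.tolerance.label.value if h.tolerance else "",
        }
        for h in hits
    ]
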