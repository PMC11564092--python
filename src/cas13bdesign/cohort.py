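"""Cohort analytics over measured crRNA silencing efficiencies.

These are the analyses that derived the design rules from a pooled set
of tiled-screen guides: split the cohort into potent (>90% silencing)
and ineffective (<50%) guides, compute position weight matrices (PWMs)
and delta nucleotide probabilities over the spacers, examine the
composition of the 4-nt protospacer-flanking sequences (PFS), and
evaluate how well the consensus-motif classifier predicts measured
potency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .scoring import MotifClass, classify_spacer
from .seqio import NucleotideSequence, to_rna

logger = logging.getLogger(__name__)

BASES = ("A", "C", "G", "U")
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass(frozen=True)
class EfficiencyRecord:
    """One guide with its measured silencing efficiency (percent).

    ``flank_up`` / ``flank_down`` are the 4-nt target sequences
    immediately 5' and 3' of the protospacer, used for PFS composition.
    """

    spacer: str
    efficiency: float
    target_id: str | None = None
    flank_up: str | None = None
    flank_down: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "spacer", to_rna(self.spacer).residues)
        if not 0 <= self.efficiency <= 100:
            raise ValueError(
                f"efficiency {self.efficiency} outside [0, 100] percent"
            )
        for name in ("flank_up", "flank_down"):
            val = getattr(self, name)
            if val is not None:
                object.__setattr__(self, name, to_rna(val).residues)


@dataclass(frozen=True)
class PositionMatrix:
    """4 x L nucleotide matrix over a spacer or flank cohort.

    ``kind`` is ``"probability"`` (columns sum to 1) or ``"delta"``
    (columns sum to 0); ``n`` is the cohort size the matrix was
    estimated from.  Rows are ordered A, C, G, U.
    """

    values: np.ndarray
    kind: str
    n: int

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 2 or values.shape[0] != 4:
            raise ValueError(f"expected a 4 x L matrix, got {values.shape}")
        sums = values.sum(axis=0)
        expected = 1.0 if self.kind == "probability" else 0.0
        if self.kind not in {"probability", "delta"}:
            raise ValueError(f"unknown matrix kind {self.kind!r}")
        if not np.allclose(sums, expected, atol=1e-9):
            raise ValueError(
                f"{self.kind} matrix columns must sum to {expected}"
            )

    @property
    def length(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=list(BASES),
            columns=[str(i) for i in range(1, self.length + 1)],
        )

    def write_tsv(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="base")


def read_efficiency_table(path: Union[str, Path]) -> list[EfficiencyRecord]:
    """Read a TSV with columns spacer, efficiency[, target_id, flank_up,
    flank_down]."""
    frame = pd.read_csv(path, sep="\t")
    required = {"spacer", "efficiency"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"efficiency table missing columns {sorted(missing)}")
    records = []
    for row in frame.itertuples(index=False):
        records.append(
            EfficiencyRecord(
                spacer=str(row.spacer),
                efficiency=float(row.efficiency),
                target_id=str(getattr(row, "target_id", "") or "") or None,
                flank_up=_opt(getattr(row, "flank_up", None)),
                flank_down=_opt(getattr(row, "flank_down", None)),
            )
        )
    return records


def _opt(value) -> str | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    text = str(value).strip()
    return text or None


def write_efficiency_table(
    records: Iterable[EfficiencyRecord], path: Union[str, Path]
) -> None:
    pd.DataFrame(
        [
            {
                "spacer": r.spacer,
                "efficiency": r.efficiency,
                "target_id": r.target_id or "",
                "flank_up": r.flank_up or "",
                "flank_down": r.flank_down or "",
            }
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False)


def split_cohorts(
    records: Sequence[EfficiencyRecord],
    potent_thr: float = 90.0,
    ineffective_thr: float = 50.0,
) -> tuple[list[EfficiencyRecord], list[EfficiencyRecord], list[EfficiencyRecord]]:
    """Partition guides into potent / ineffective / excluded cohorts.

    Strict inequalities: potent means efficiency > ``potent_thr`` (90%),
    ineffective means efficiency < ``ineffective_thr`` (50%); guides with
    ambiguous efficiencies in between (boundaries included) are excluded.
    The partition is exhaustive and disjoint.
    """
    if ineffective_thr > potent_thr:
        raise ValueError("ineffective threshold must not exceed potent threshold")
    potent = [r for r in records if r.efficiency > potent_thr]
    ineffective = [r for r in records if r.efficiency < ineffective_thr]
    excluded = [
        r
        for r in records
        if ineffective_thr <= r.efficiency <= potent_thr
    ]
    return potent, ineffective, excluded


def _spacer_strings(
    spacers: Sequence[Union[EfficiencyRecord, NucleotideSequence, str]]
) -> list[str]:
    out = []
    for s in spacers:
        if isinstance(s, EfficiencyRecord):
            out.append(s.spacer)
        else:
            out.append(to_rna(s).residues)
    if not out:
        raise ValueError("empty cohort: need at least one spacer")
    lengths = {len(s) for s in out}
    if len(lengths) != 1:
        raise ValueError(f"cohort mixes spacer lengths {sorted(lengths)}")
    return out


def pwm(
    spacers: Sequence[Union[EfficiencyRecord, NucleotideSequence, str]]
) -> PositionMatrix:
    """Position weight matrix: per-position nucleotide probabilities."""
    strings = _spacer_strings(spacers)
    L = len(strings[0])
    counts = np.zeros((4, L))
    for s in strings:
        for i, base in enumerate(s):
            counts[_BASE_INDEX[base], i] += 1
    return PositionMatrix(counts / len(strings), "probability", len(strings))


def delta_probabilities(
    spacers: Sequence[Union[EfficiencyRecord, NucleotideSequence, str]],
    baseline: Union[str, Sequence[float]] = "cohort_mean",
) -> PositionMatrix:
    """Per-position nucleotide probability minus a baseline composition.

    ``baseline`` is ``"cohort_mean"`` (each base's frequency pooled over
    all positions of the cohort — the default), ``"uniform"`` (0.25
    each), or a custom length-4 probability vector over A, C, G, U.
    Every column of the result sums to zero.
    """
    matrix = pwm(spacers)
    if isinstance(baseline, str):
        if baseline == "cohort_mean":
            base_vec = matrix.values.mean(axis=1)
        elif baseline == "uniform":
            base_vec = np.full(4, 0.25)
        else:
            raise ValueError(f"unknown baseline {baseline!r}")
    else:
        base_vec = np.asarray(baseline, dtype=float)
        if base_vec.shape != (4,) or not np.isclose(base_vec.sum(), 1.0):
            raise ValueError("custom baseline must be 4 probabilities summing to 1")
    delta = matrix.values - base_vec[:, None]
    return PositionMatrix(delta, "delta", matrix.n)


def pfs_matrices(
    records: Sequence[EfficiencyRecord], flank_len: int = 4
) -> tuple[PositionMatrix, PositionMatrix]:
    """PFS composition: probability matrices of the 4-nt flanks.

    Returns (upstream, downstream) matrices over records carrying both
    flanks; records with missing or mis-sized flanks are skipped with a
    warning.  An absence of positional bias (all entries near 0.25)
    indicates the enzyme is not constrained by a PFS motif.
    """
    kept = [
        r
        for r in records
        if r.flank_up is not None
        and r.flank_down is not None
        and len(r.flank_up) == flank_len
        and len(r.flank_down) == flank_len
    ]
    skipped = len(records) - len(kept)
    if skipped:
        logger.warning("pfs_matrices: skipped %d records without %d-nt flanks", skipped, flank_len)
    if not kept:
        raise ValueError("no records with complete flanks")
    upstream = pwm([r.flank_up for r in kept])
    downstream = pwm([r.flank_down for r in kept])
    return upstream, downstream


def evaluate_predictions(
    records: Sequence[EfficiencyRecord],
    classifier: Callable[[str], MotifClass] = classify_spacer,
    potent_thr: float = 90.0,
    ineffective_thr: float = 50.0,
) -> dict:
    """Confront the motif classifier with measured efficiencies.

    Reports, for guides predicted potent, the fraction whose measured
    efficiency exceeds ``potent_thr`` (precision of the potent call), the
    converse for predicted-ineffective guides, and the full confusion
    table of motif class versus measured cohort.
    """
    if not records:
        raise ValueError("no records to evaluate")
    rows = []
    for r in records:
        predicted = classifier(r.spacer)
        if r.efficiency > potent_thr:
            measured = "potent"
        elif r.efficiency < ineffective_thr:
            measured = "ineffective"
        else:
            measured = "intermediate"
        rows.append((predicted.value, measured))
    frame = pd.DataFrame(rows, columns=["predicted", "measured"])
    confusion = pd.crosstab(frame["predicted"], frame["measured"])
    summary: dict = {
        "n": len(records),
        "confusion": confusion,
    }
    potent_calls = frame[frame["predicted"] == MotifClass.PREDICTED_POTENT.value]
    if len(potent_calls):
        summary["potent_precision"] = float(
            (potent_calls["measured"] == "potent").mean()
        )
        summary["n_predicted_potent"] = int(len(potent_calls))
    ineff_calls = frame[
        frame["predicted"] == MotifClass.PREDICTED_INEFFECTIVE.value
    ]
    if len(ineff_calls):
        summary["ineffective_precision"] = float(
            (ineff_calls["measured"] == "ineffective").mean()
        )
        summary["n_predicted_ineffective"] = int(len(ineff_calls))
    return summary


def covariate_correlation(
    records: Sequence[EfficiencyRecord], covariate: Sequence[float]
) -> tuple[float, float]:
    """Pearson correlation between efficiency and a precomputed covariate
    column (e.g. an externally computed folding energy); returns (r, p)."""
    if len(records) != len(covariate):
        raise ValueError("covariate length does not match records")
    eff = [r.efficiency for r in records]
    r, p = stats.pearsonr(eff, list(covariate))
    return float(r), float(p)
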