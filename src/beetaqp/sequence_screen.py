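"""Aquaporin candidate screening and protein properties.

A candidate passes the screen when it carries two NPA-like motifs at a
plausible loop-B/loop-E spacing, enough predicted transmembrane helices,
a length within the family's range, and sufficient global-alignment identity
to at least one reference aquaporin. Molecular weight, isoelectric point and
transmembrane segments are computed in-repo: MW by summation of average
residue masses, pI by Henderson-Hasselbalch bisection, TM segments by
Kyte-Doolittle sliding-window hydropathy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from ._residues import (
    AVERAGE_RESIDUE_MASS,
    KYTE_DOOLITTLE,
    NEGATIVE_GROUPS,
    PKA_SETS,
    POSITIVE_GROUPS,
    WATER_MASS,
    validate_sequence,
)

logger = logging.getLogger(__name__)

#: Third-position variants of the NPA motif observed across the family.
NPA_THIRD_RESIDUES = frozenset("ASTLV")


@dataclass(frozen=True)
class ProteinRecord:
    """One protein with derived physicochemical properties."""

    id: str
    sequence: str
    mw: float = 0.0
    pi: float = 0.0
    tm_segments: tuple[tuple[int, int], ...] = ()

    @property
    def length(self) -> int:
        return len(self.sequence)

    @classmethod
    def from_sequence(cls, id: str, sequence: str,
                      pka_set: str = "emboss") -> "ProteinRecord":
        seq = validate_sequence(sequence)
        return cls(
            id=id, sequence=seq,
            mw=compute_mw(seq), pi=compute_pi(seq, pka_set=pka_set),
            tm_segments=tuple(predict_tm_segments(seq)),
        )


@dataclass(frozen=True)
class NpaHit:
    """One NPA-like triplet occurrence (N-P-{A,S,T,L,V})."""

    position: int
    triplet: str

    def __post_init__(self) -> None:
        if not (self.triplet[:2] == "NP" and self.triplet[2] in NPA_THIRD_RESIDUES):
            raise ValueError(f"not an NPA-like triplet: {self.triplet!r}")


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds of the candidate screen.

    The NPA spacing window reflects hourglass-fold geometry (loop B to loop E
    across three transmembrane helices); the identity floor is the in-repo
    stand-in for a profile-based domain detection.
    """

    min_npa: int = 2
    npa_spacing: tuple[int, int] = (60, 180)
    min_tm: int = 5
    length_range: tuple[int, int] = (150, 400)
    identity_floor: float = 0.30
    tm_window: int = 19
    tm_threshold: float = 1.6
    tm_min_span: int = 15
    tm_merge_gap: int = 3


@dataclass(frozen=True)
class ScreenResult:
    """Outcome of screening one protein; passed iff no filter failed."""

    protein_id: str
    npa_hits: tuple[NpaHit, ...]
    tm_count: int
    best_ref_identity: float
    fail_reasons: tuple[str, ...]

    @property
    def passed(self) -> bool:
        return not self.fail_reasons


def scan_npa_motifs(sequence: str) -> list[NpaHit]:
    """Find all non-overlapping NPA-like triplets, left to right."""
    seq = validate_sequence(sequence)
    hits: list[NpaHit] = []
    i = 0
    while i <= len(seq) - 3:
        if seq[i] == "N" and seq[i + 1] == "P" and seq[i + 2] in NPA_THIRD_RESIDUES:
            hits.append(NpaHit(position=i, triplet=seq[i:i + 3]))
            i += 3
        else:
            i += 1
    return hits


def predict_tm_segments(sequence: str, window: int = 19,
                        threshold: float = 1.6, min_span: int = 15,
                        merge_gap: int = 3) -> list[tuple[int, int]]:
    """Predict transmembrane segments from Kyte-Doolittle hydropathy.

    A window (odd length) slides over the sequence; every window whose mean
    hydropathy reaches ``threshold`` marks all residues it covers. Marked
    runs closer than ``merge_gap`` are merged and runs shorter than
    ``min_span`` discarded. Returns 0-based half-open intervals.
    """
    if window <= 0 or window % 2 == 0:
        raise ValueError(f"window must be a positive odd integer, got {window}")
    seq = validate_sequence(sequence)
    n = len(seq)
    if window > n:
        return []
    values = [KYTE_DOOLITTLE[c] for c in seq]
    # prefix sums -> window means
    prefix = [0.0]
    for v in values:
        prefix.append(prefix[-1] + v)
    covered = [False] * n
    for start in range(n - window + 1):
        mean = (prefix[start + window] - prefix[start]) / window
        if mean >= threshold:
            for i in range(start, start + window):
                covered[i] = True
    # collect runs
    runs: list[list[int]] = []
    i = 0
    while i < n:
        if covered[i]:
            j = i
            while j < n and covered[j]:
                j += 1
            runs.append([i, j])
            i = j
        else:
            i += 1
    # merge nearby runs
    merged: list[list[int]] = []
    for run in runs:
        if merged and run[0] - merged[-1][1] <= merge_gap:
            merged[-1][1] = run[1]
        else:
            merged.append(run)
    return [(a, b) for a, b in merged if b - a >= min_span]


def compute_mw(sequence: str) -> float:
    """Average molecular weight in kDa (residue masses plus one water)."""
    seq = validate_sequence(sequence)
    if not seq:
        raise ValueError("empty sequence")
    dalton = sum(AVERAGE_RESIDUE_MASS[c] for c in seq) + WATER_MASS
    return dalton / 1000.0


def net_charge(sequence: str, ph: float, pka_set: str = "emboss") -> float:
    """Henderson-Hasselbalch net charge of a peptide at a given pH."""
    seq = validate_sequence(sequence)
    if not seq:
        raise ValueError("empty sequence")
    pka = PKA_SETS[pka_set]
    pos = sum(
        1.0 / (1.0 + 10.0 ** (ph - pka[g]))
        for g in ("nterm",) + tuple(c for c in seq if c in POSITIVE_GROUPS)
    )
    neg = sum(
        1.0 / (1.0 + 10.0 ** (pka[g] - ph))
        for g in ("cterm",) + tuple(c for c in seq if c in NEGATIVE_GROUPS)
    )
    return pos - neg


def compute_pi(sequence: str, pka_set: str = "emboss",
               tolerance: float = 1e-4) -> float:
    """Isoelectric point by bisection of the net-charge function on [0, 14]."""
    lo, hi = 0.0, 14.0
    while hi - lo > tolerance:
        mid = (lo + hi) / 2.0
        if net_charge(sequence, mid, pka_set=pka_set) > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a multi-record FASTA as (id, sequence) pairs."""
    return [(rec.id, str(rec.seq).upper())
            for rec in SeqIO.parse(str(path), "fasta")]


def _spacing_ok(hits: Sequence[NpaHit], bounds: tuple[int, int]) -> bool:
    lo, hi = bounds
    for i in range(len(hits)):
        for j in range(i + 1, len(hits)):
            if lo <= hits[j].position - hits[i].position <= hi:
                return True
    return False


def screen_proteome(proteome: Iterable[tuple[str, str]] | str | Path,
                    refs: Sequence[ProteinRecord],
                    config: ScreenConfig | None = None) -> list[ScreenResult]:
    """Screen a proteome for aquaporin candidates against a reference panel.

    ``proteome`` is either a FASTA path or an iterable of (id, sequence).
    """
    from .align_extract import pairwise_identity  # local import avoids cycle

    if not refs:
        raise ValueError("reference panel must be non-empty")
    config = config or ScreenConfig()
    if isinstance(proteome, (str, Path)):
        proteome = read_fasta(proteome)
    proteome = list(proteome)
    if not proteome:
        logger.warning("empty proteome: nothing to screen")
        return []

    results: list[ScreenResult] = []
    for pid, raw_seq in proteome:
        seq = validate_sequence(raw_seq)
        hits = tuple(scan_npa_motifs(seq))
        tm = predict_tm_segments(
            seq, window=config.tm_window, threshold=config.tm_threshold,
            min_span=config.tm_min_span, merge_gap=config.tm_merge_gap,
        )
        best_identity = max(pairwise_identity(seq, ref.sequence) for ref in refs)
        reasons: list[str] = []
        if len(hits) < config.min_npa:
            reasons.append("npa_count")
        elif not _spacing_ok(hits, config.npa_spacing):
            reasons.append("npa_spacing")
        if len(tm) < config.min_tm:
            reasons.append("tm_count")
        lo, hi = config.length_range
        if not lo <= len(seq) <= hi:
            reasons.append("length")
        if best_identity < config.identity_floor:
            reasons.append("ref_identity")
        results.append(ScreenResult(
            protein_id=pid, npa_hits=hits, tm_count=len(tm),
            best_ref_identity=best_identity, fail_reasons=tuple(reasons),
        ))
    return results


def results_to_rows(results: Iterable[ScreenResult]) -> list[dict]:
    """Flatten screen results for TSV/JSON export."""
    return [
        {
            "protein_id": r.protein_id,
            "passed": r.passed,
            "npa_hits": ";".join(f"{h.position}:{h.triplet}" for h in r.npa_hits),
            "tm_count": r.tm_count,
            "best_ref_identity": round(r.best_ref_identity, 4),
            "fail_reasons": ";".join(r.fail_reasons),
        }
        for r in results
    ]
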