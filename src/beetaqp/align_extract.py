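"""Anchor alignment and diagnostic-residue extraction.

A query protein is aligned globally to an annotated anchor (BLOSUM62, affine
gaps) and the residues sitting in the anchor's diagnostic columns are read
off: the two NPA triplets, the ar/R selectivity quartet (H2, H5, LE1, LE2),
Froger's positions P1-P5 and the nine SDPs. A gap at a diagnostic column is
reported as a gap, never as a neighbouring residue; an NPA triplet with any
gapped column is reported missing.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from ._residues import validate_sequence
from .refdata import AnchorAnnotation
from .sequence_screen import NpaHit

GAP = "-"


@dataclass(frozen=True)
class AlignParams:
    """Global-alignment scoring: substitution matrix plus affine gaps."""

    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5


@dataclass(frozen=True)
class Alignment:
    """A pairwise global alignment of a query against an anchor."""

    query_id: str
    anchor_id: str
    aligned_query: str
    aligned_anchor: str
    score: float
    identity: float

    def __post_init__(self) -> None:
        if len(self.aligned_query) != len(self.aligned_anchor):
            raise ValueError("aligned strings must have equal length")


@dataclass(frozen=True)
class ResidueProfile:
    """Diagnostic residues of one query, in anchor coordinates.

    ``provenance`` maps every diagnostic label to the 0-based query index of
    the extracted residue, or the string ``"gap"``.
    """

    query_id: str
    npa_lb: str | None
    npa_le: str | None
    arr: tuple[str, str, str, str]
    froger: tuple[str, ...]
    sdp: tuple[str, ...]
    provenance: Mapping[str, int | str]


@lru_cache(maxsize=8)
def _aligner(params: AlignParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(params.matrix)
    aligner.open_gap_score = -abs(params.gap_open)
    aligner.extend_gap_score = -abs(params.gap_extend)
    return aligner


def _align_pair(query: str, target: str,
                params: AlignParams) -> tuple[str, str, float]:
    aln = _aligner(params).align(query, target)[0]
    return aln[0], aln[1], float(aln.score)


def global_align(query_id: str, query_seq: str, anchor: AnchorAnnotation,
                 params: AlignParams | None = None) -> Alignment:
    """Optimal global alignment of a query against the anchor sequence."""
    params = params or AlignParams()
    qseq = validate_sequence(query_seq)
    if not qseq or not anchor.sequence:
        raise ValueError("both sequences must be non-empty")
    aq, aa, score = _align_pair(qseq, anchor.sequence, params)
    matches = sum(1 for a, b in zip(aq, aa) if a == b and a != GAP)
    return Alignment(
        query_id=query_id, anchor_id=anchor.anchor_id,
        aligned_query=aq, aligned_anchor=aa,
        score=score, identity=matches / len(aq),
    )


def pairwise_identity(seq_a: str, seq_b: str,
                      params: AlignParams | None = None) -> float:
    """Fraction of identical columns in the optimal global alignment."""
    params = params or AlignParams()
    a, b, _ = _align_pair(validate_sequence(seq_a), validate_sequence(seq_b),
                          params)
    matches = sum(1 for x, y in zip(a, b) if x == y and x != GAP)
    return matches / len(a)


def _anchor_to_query_map(alignment: Alignment) -> dict[int, int | str]:
    """Map each anchor residue index to the aligned query index or 'gap'."""
    mapping: dict[int, int | str] = {}
    qi = ai = 0
    for qc, ac in zip(alignment.aligned_query, alignment.aligned_anchor):
        if ac != GAP:
            mapping[ai] = qi if qc != GAP else "gap"
            ai += 1
        if qc != GAP:
            qi += 1
    return mapping


def extract_profile(alignment: Alignment,
                    anchor: AnchorAnnotation) -> ResidueProfile:
    """Read the diagnostic residues of the aligned query off the anchor's
    annotated columns."""
    if alignment.anchor_id != anchor.anchor_id:
        raise ValueError(
            f"alignment anchor {alignment.anchor_id!r} does not match "
            f"annotation {anchor.anchor_id!r}"
        )
    col_map = _anchor_to_query_map(alignment)
    query_seq = alignment.aligned_query.replace(GAP, "")

    provenance: dict[int | str, int | str] = {}
    residues: dict[str, str] = {}
    for label, anchor_idx in anchor.diagnostic_columns.items():
        qpos = col_map[anchor_idx]
        provenance[label] = qpos
        residues[label] = GAP if qpos == "gap" else query_seq[qpos]

    def triplet(prefix: str) -> str | None:
        chars = [residues[f"{prefix}_{i}"] for i in range(3)]
        return None if GAP in chars else "".join(chars)

    return ResidueProfile(
        query_id=alignment.query_id,
        npa_lb=triplet("NPA_LB"),
        npa_le=triplet("NPA_LE"),
        arr=tuple(residues[l] for l in ("H2", "H5", "LE1", "LE2")),
        froger=tuple(residues[f"P{i}"] for i in range(1, 6)),
        sdp=tuple(residues[f"SDP{i}"] for i in range(1, 10)),
        provenance=provenance,
    )


def profile_for(query_id: str, query_seq: str, anchor: AnchorAnnotation,
                params: AlignParams | None = None) -> ResidueProfile:
    """Convenience: align then extract in one call."""
    return extract_profile(global_align(query_id, query_seq, anchor, params),
                           anchor)


def cross_check_npa(profile: ResidueProfile,
                    npa_hits: Sequence[NpaHit]) -> list[str]:
    """Flag disagreement between motif-scan and alignment-extracted NPA
    triplets. Returns the labels ('NPA_LB', 'NPA_LE') that disagree."""
    flags: list[str] = []
    by_pos = {h.position: h.triplet for h in npa_hits}
    for label, triplet in (("NPA_LB", profile.npa_lb), ("NPA_LE", profile.npa_le)):
        if triplet is None:
            continue
        start = profile.provenance[f"{label}_0"]
        if start == "gap" or by_pos.get(start) != triplet:
            flags.append(label)
    return flags


def profiles_to_rows(profiles: Iterable[ResidueProfile]) -> list[dict]:
    """Flatten profiles into table rows shaped like the conserved-residue
    table (gene, NPA_LB, NPA_LE, H2..LE2, P1-P5, SDP1-SDP9)."""
    rows = []
    for p in profiles:
        row: dict[str, str] = {
            "gene": p.query_id,
            "NPA_LB": p.npa_lb or "missing",
            "NPA_LE": p.npa_le or "missing",
        }
        row.update(zip(("H2", "H5", "LE1", "LE2"), p.arr))
        row.update({f"P{i}": r for i, r in enumerate(p.froger, start=1)})
        row.update({f"SDP{i}": r for i, r in enumerate(p.sdp, start=1)})
        rows.append(row)
    return rows
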