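"""Expression profiling from an RPKM matrix.

The contract boundary is a genes x samples matrix of RPKM values with a
sample-metadata sidecar (organ, condition). Provided here: heatmap-ready
log2(RPKM + pseudocount) values, per-gene stress responses as log2 fold
changes against an untreated control (strong induction/repression when
|log2 fold change| exceeds 1), and expression-breadth flags (silent /
organ-specific / expressed everywhere) against a detection floor.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

CONDITIONS = ("control", "salt", "heat")


@dataclass(frozen=True)
class SampleInfo:
    sample_id: str
    organ: str
    condition: str = "control"

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")


@dataclass
class ExpressionMatrix:
    """Genes x samples RPKM values plus per-sample metadata."""

    rpkm: pd.DataFrame  # index: gene ids, columns: sample ids
    samples: dict[str, SampleInfo]

    def __post_init__(self) -> None:
        if (self.rpkm.values < 0).any():
            raise ValueError("RPKM values must be non-negative")
        missing = [c for c in self.rpkm.columns if c not in self.samples]
        if missing:
            raise ValueError(f"samples without metadata: {missing}")

    @property
    def genes(self) -> list[str]:
        return list(self.rpkm.index)

    @classmethod
    def from_tsv(cls, rpkm_path: str | Path,
                 meta_path: str | Path) -> "ExpressionMatrix":
        rpkm = pd.read_csv(rpkm_path, sep="\t", comment="#", index_col=0)
        meta = pd.read_csv(meta_path, sep="\t", comment="#", dtype=str)
        samples = {
            row.sample: SampleInfo(row.sample, row.organ, row.condition)
            for row in meta.itertuples(index=False)
        }
        return cls(rpkm=rpkm, samples=samples)

    def to_tsv(self, rpkm_path: str | Path, meta_path: str | Path) -> None:
        self.rpkm.to_csv(rpkm_path, sep="\t", index_label="gene")
        pd.DataFrame(
            [{"sample": s.sample_id, "organ": s.organ, "condition": s.condition}
             for s in self.samples.values()]
        ).to_csv(meta_path, sep="\t", index=False)


@dataclass(frozen=True)
class StressResponse:
    """Per-gene response to one stress condition."""

    gene_id: str
    condition: str
    log2fc: float
    category: str  # UP | DOWN | UNCHANGED

    @property
    def strong(self) -> bool:
        return abs(self.log2fc) > self._strong_cut

    _strong_cut: float = 1.0


@dataclass(frozen=True)
class BreadthReport:
    """Expression breadth of one gene over organs."""

    gene_id: str
    organs_detected: int
    organs_total: int
    silent: bool
    organ_specific: bool
    expressed_everywhere: bool


def heatmap_matrix(em: ExpressionMatrix,
                   pseudocount: float = 1.0) -> pd.DataFrame:
    """Element-wise log2(RPKM + pseudocount), order preserved."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if (em.rpkm.values < 0).any():
        raise ValueError("RPKM values must be non-negative")
    return np.log2(em.rpkm + pseudocount)


def stress_response(em: ExpressionMatrix, treated_sample: str,
                    control_sample: str, pseudocount: float = 1.0,
                    strong_cut: float = 1.0) -> list[StressResponse]:
    """log2((treated + p) / (control + p)) per gene, classified UP/DOWN/
    UNCHANGED with a strong flag at |log2fc| > ``strong_cut``."""
    for s in (treated_sample, control_sample):
        if s not in em.rpkm.columns:
            raise KeyError(f"sample {s!r} not in matrix")
    condition = em.samples[treated_sample].condition
    t = em.rpkm[treated_sample].to_numpy(dtype=float)
    c = em.rpkm[control_sample].to_numpy(dtype=float)
    log2fc = np.log2((t + pseudocount) / (c + pseudocount))
    out = []
    for gene, fc in zip(em.rpkm.index, log2fc):
        category = "UP" if fc > 0 else ("DOWN" if fc < 0 else "UNCHANGED")
        out.append(StressResponse(gene_id=gene, condition=condition,
                                  log2fc=float(fc), category=category,
                                  _strong_cut=strong_cut))
    return out


def expression_breadth(em: ExpressionMatrix,
                       detect_floor: float = 1.0) -> list[BreadthReport]:
    """Per-gene organ detection counts and breadth flags.

    A gene is detected in an organ when any sample of that organ reaches
    ``detect_floor`` RPKM; silent means below floor in every sample,
    organ-specific means detected in exactly one organ.
    """
    if detect_floor < 0:
        raise ValueError("detect_floor must be >= 0")
    organs = sorted({s.organ for s in em.samples.values()})
    organ_cols = {
        organ: [sid for sid, s in em.samples.items()
                if s.organ == organ and sid in em.rpkm.columns]
        for organ in organs
    }
    reports = []
    for gene in em.rpkm.index:
        row = em.rpkm.loc[gene]
        detected = [
            organ for organ, cols in organ_cols.items()
            if cols and (row[cols] >= detect_floor).any()
        ]
        silent = bool((row < detect_floor).all())
        reports.append(BreadthReport(
            gene_id=gene, organs_detected=len(detected),
            organs_total=len(organs), silent=silent,
            organ_specific=len(detected) == 1,
            expressed_everywhere=len(detected) == len(organs),
        ))
    return reports


def responses_to_rows(responses: Iterable[StressResponse]) -> list[dict]:
    return [
        {"gene": r.gene_id, "condition": r.condition,
         "log2fc": round(r.log2fc, 4), "category": r.category,
         "strong": r.strong}
        for r in responses
    ]
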