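"""Curated reference tables for the sugar-beet aquaporin family.

This module loads and validates the packaged transcriptions of the published
catalog (per-protein properties and locus tags), the conserved-residue table
(NPA motifs, ar/R selectivity filter, Froger's positions) and the
specificity-determining-position (SDP) substrate patterns, plus the annotated
anchor sequence used to transfer diagnostic columns onto query proteins.

All tables are plain TSV/JSON/FASTA files under ``beetaqp/data`` and are
treated as ground truth by the rest of the package.
"""

from __future__ import annotations

import json
import re
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from ._residues import AMINO_ACIDS

FAMILIES = ("PIP", "TIP", "NIP", "SIP", "XIP")

SUBSTRATES = ("NH3", "boric_acid", "CO2", "H2O2", "silicic_acid", "urea")

_NAME_RE = re.compile(r"^Bv([A-Z]{3})(\d+);(\d+)$")

#: The 20 diagnostic labels an anchor annotation must define: the two NPA
#: triplets (three columns each), the ar/R quartet, Froger's P1-P5 and the
#: nine SDP columns.
ANCHOR_LABELS: tuple[str, ...] = (
    "NPA_LB_0", "NPA_LB_1", "NPA_LB_2",
    "NPA_LE_0", "NPA_LE_1", "NPA_LE_2",
    "H2", "H5", "LE1", "LE2",
    "P1", "P2", "P3", "P4", "P5",
    "SDP1", "SDP2", "SDP3", "SDP4", "SDP5", "SDP6", "SDP7", "SDP8", "SDP9",
)

GREEK_TAGS = {"alpha": "α", "beta": "β"}


class RefdataError(ValueError):
    """Raised when a curated table fails validation."""


def _data_path(name: str) -> Path:
    return Path(str(resources.files("beetaqp").joinpath("data", name)))


@dataclass(frozen=True)
class CatalogEntry:
    """One catalogued aquaporin protein (or transcript of a gene)."""

    name: str
    family: str
    subgroup: str
    transcript_tag: str | None
    gene_id: str
    protein_length: int
    mw: float
    pi: float
    tmh_count: int

    def __post_init__(self) -> None:
        m = _NAME_RE.match(self.name)
        if not m:
            raise RefdataError(f"unparseable gene name: {self.name!r}")
        if m.group(1) != self.family:
            raise RefdataError(
                f"{self.name}: name prefix {m.group(1)} does not match "
                f"family {self.family}"
            )
        if self.subgroup != f"{self.family}{m.group(2)}":
            raise RefdataError(f"{self.name}: inconsistent subgroup {self.subgroup}")
        if self.protein_length <= 0:
            raise RefdataError(f"{self.name}: non-positive protein length")
        if not 0 < self.pi < 14:
            raise RefdataError(f"{self.name}: pI {self.pi} outside (0, 14)")

    @property
    def display_name(self) -> str:
        """Name with the transcript tag rendered as a Greek letter."""
        if self.transcript_tag:
            return f"{self.name} {GREEK_TAGS.get(self.transcript_tag, self.transcript_tag)}"
        return self.name

    @property
    def full_name(self) -> str:
        """ASCII identifier unique per transcript (tag appended)."""
        return f"{self.name}{self.transcript_tag or ''}"


class Catalog(Sequence[CatalogEntry]):
    """Ordered collection of catalog entries with tally helpers."""

    def __init__(self, entries: Iterable[CatalogEntry]):
        self.entries = list(entries)
        seen: set[str] = set()
        for e in self.entries:
            if e.full_name in seen:
                raise RefdataError(f"duplicate gene name: {e.full_name}")
            seen.add(e.full_name)

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, i):  # type: ignore[override]
        return self.entries[i]

    def __iter__(self) -> Iterator[CatalogEntry]:
        return iter(self.entries)

    def family_tally(self) -> dict[str, int]:
        tally = Counter(e.family for e in self.entries)
        return {fam: tally.get(fam, 0) for fam in FAMILIES}

    def gene_count(self, level: str = "transcript") -> int:
        """Count entries at ``transcript`` level (every row) or ``gene``
        level (transcripts of one gene collapse to a single count)."""
        if level == "transcript":
            return len(self.entries)
        if level == "gene":
            return len({e.name for e in self.entries})
        raise ValueError(f"unknown counting level: {level!r}")

    def get(self, full_name: str) -> CatalogEntry:
        for e in self.entries:
            if e.full_name == full_name or e.name == full_name:
                return e
        raise KeyError(full_name)

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {
                "family": e.family, "gene": e.name,
                "transcript_tag": e.transcript_tag or "",
                "gene_id": e.gene_id, "length": e.protein_length,
                "MW": e.mw, "pI": e.pi, "TMH": e.tmh_count,
            }
            for e in self.entries
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class SubstratePattern:
    """A substrate label plus the allowed residue set at each of SDP1-9."""

    substrate: str
    allowed: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        if len(self.allowed) != 9:
            raise RefdataError(
                f"{self.substrate}: expected 9 SDP positions, got {len(self.allowed)}"
            )
        for i, s in enumerate(self.allowed, start=1):
            if not s:
                raise RefdataError(f"{self.substrate}: empty residue set at SDP{i}")
            bad = [r for r in s if r not in AMINO_ACIDS]
            if bad:
                raise RefdataError(
                    f"{self.substrate}: invalid residue {bad} at SDP{i}"
                )


@dataclass(frozen=True)
class SdpObservation:
    """Observed SDP residues of one protein under one substrate heading."""

    substrate: str
    gene: str
    residues: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.residues) != 9:
            raise RefdataError(f"{self.gene}/{self.substrate}: need 9 residues")


@dataclass(frozen=True)
class DiagnosticRow:
    """Conserved-residue table row: NPA triplets, ar/R quartet, Froger P1-P5.

    Froger values recorded as blank in the source are ``None``.
    """

    gene: str
    transcript_tag: str | None
    npa_lb: str
    npa_le: str
    arr: tuple[str, str, str, str]
    froger: tuple[str | None, ...]

    @property
    def full_name(self) -> str:
        return f"{self.gene}{self.transcript_tag or ''}"


@dataclass(frozen=True)
class AnchorAnnotation:
    """Reference sequence with hand-annotated diagnostic columns.

    ``diagnostic_columns`` maps each label in :data:`ANCHOR_LABELS` to a
    0-based residue index in ``sequence``. ar/R LE1/LE2 columns may coincide
    with SDP columns; duplicates across label groups are allowed.
    """

    anchor_id: str
    sequence: str
    diagnostic_columns: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [l for l in ANCHOR_LABELS if l not in self.diagnostic_columns]
        if missing:
            raise RefdataError(
                "anchor annotation missing label(s): " + ", ".join(missing)
            )
        n = len(self.sequence)
        for label, idx in self.diagnostic_columns.items():
            if not 0 <= idx < n:
                raise RefdataError(f"anchor column {label}={idx} outside sequence")
        lb = [self.diagnostic_columns[f"NPA_LB_{i}"] for i in range(3)]
        le = [self.diagnostic_columns[f"NPA_LE_{i}"] for i in range(3)]
        if not max(lb) < min(le):
            raise RefdataError("NPA_LB columns must precede NPA_LE columns")


def _read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str,
                       keep_default_na=False)


def load_catalog(path: str | Path | None = None) -> Catalog:
    """Load the aquaporin catalog (packaged transcription by default)."""
    path = path or _data_path("table1.tsv")
    df = _read_tsv(path)
    required = {"family", "gene", "gene_id", "length", "MW", "pI", "TMH"}
    missing = required - set(df.columns)
    if missing:
        raise RefdataError(f"catalog missing column(s): {sorted(missing)}")
    entries = []
    for row in df.itertuples(index=False):
        name = row.gene
        m = _NAME_RE.match(name)
        if not m:
            raise RefdataError(f"unparseable family prefix in gene name: {name!r}")
        tag = getattr(row, "transcript_tag", "") or None
        entries.append(CatalogEntry(
            name=name, family=row.family, subgroup=f"{m.group(1)}{m.group(2)}",
            transcript_tag=tag, gene_id=row.gene_id,
            protein_length=int(row.length), mw=float(row.MW),
            pi=float(row.pI), tmh_count=int(row.TMH),
        ))
    return Catalog(entries)


def _parse_residue_set(cell: str, where: str) -> frozenset[str]:
    residues = frozenset(r.strip().upper() for r in cell.split("/") if r.strip())
    if not residues:
        raise RefdataError(f"empty residue set in {where}")
    return residues


def load_patterns(path: str | Path | None = None) -> list[SubstratePattern]:
    """Load the six typical-transporter SDP patterns."""
    path = path or _data_path("table3_patterns.tsv")
    df = _read_tsv(path)
    cols = [f"SDP{i}" for i in range(1, 10)]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise RefdataError(
            f"pattern table must have 9 SDP columns; missing {missing}"
        )
    patterns = []
    for row in df.itertuples(index=False):
        allowed = tuple(
            _parse_residue_set(getattr(row, c), f"{row.substrate}/{c}")
            for c in cols
        )
        patterns.append(SubstratePattern(substrate=row.substrate, allowed=allowed))
    return patterns


def load_sdp_observations(path: str | Path | None = None) -> list[SdpObservation]:
    """Load the per-protein observed SDP residues, by substrate heading."""
    path = path or _data_path("table3_residues.tsv")
    df = _read_tsv(path)
    cols = [f"SDP{i}" for i in range(1, 10)]
    return [
        SdpObservation(
            substrate=row.substrate, gene=row.gene,
            residues=tuple(getattr(row, c).upper() for c in cols),
        )
        for row in df.itertuples(index=False)
    ]


def load_diagnostic_table(path: str | Path | None = None) -> list[DiagnosticRow]:
    """Load the conserved-residue table (NPA / ar/R / Froger per protein)."""
    path = path or _data_path("table2.tsv")
    df = _read_tsv(path)
    rows = []
    for row in df.itertuples(index=False):
        froger = tuple(
            None if getattr(row, p) == "*" else getattr(row, p).upper()
            for p in ("P1", "P2", "P3", "P4", "P5")
        )
        rows.append(DiagnosticRow(
            gene=row.gene, transcript_tag=row.transcript_tag or None,
            npa_lb=row.NPA_LB.upper(), npa_le=row.NPA_LE.upper(),
            arr=(row.H2.upper(), row.H5.upper(), row.LE1.upper(), row.LE2.upper()),
            froger=froger,
        ))
    return rows


def load_arr_rules(path: str | Path | None = None) -> list[dict]:
    """Load the data-driven ar/R + NPA annotation rules."""
    path = path or _data_path("arr_rules.json")
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    rules = payload["rules"]
    for rule in rules:
        if "rule_id" not in rule or "note" not in rule:
            raise RefdataError("each rule needs rule_id and note")
    return rules


def load_anchor(fasta_path: str | Path | None = None,
                sidecar_path: str | Path | None = None) -> AnchorAnnotation:
    """Load the annotated anchor: a FASTA record plus a JSON column sidecar."""
    fasta_path = fasta_path or _data_path("anchor.fasta")
    sidecar_path = sidecar_path or _data_path("anchor_columns.json")
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) != 1:
        raise RefdataError(f"anchor FASTA must hold exactly one record, got {len(records)}")
    with open(sidecar_path, encoding="utf-8") as fh:
        columns = json.load(fh)
    return AnchorAnnotation(
        anchor_id=records[0].id,
        sequence=str(records[0].seq).upper(),
        diagnostic_columns={str(k): int(v) for k, v in columns.items()},
    )
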