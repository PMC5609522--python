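"""Genome context: chromosome distribution, tandem duplication, exon
structure and exon-skipping detection.

Locus tags of the form ``Bv<chr><scheme><number>_<code>.t<k>`` encode the
chromosome and a position rank (numbers step by 10 along a chromosome), so
tandem duplication is called for same-chromosome, same-subgroup pairs whose
locus numbers lie within a small number of steps. Pairs whose tags come from
different numbering schemes (e.g. a transposable-element scaffold tag next
to a regular tag) cannot be compared by number and are reported at low
confidence instead of being dropped.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping

import gffutils

from .refdata import Catalog, CatalogEntry

_TAG_RE = re.compile(r"^Bv(\d+)(TE|ug|g)(\d+)_([A-Za-z]+)\.t(\d+)$")

#: Locus numbers along a chromosome step by this much between adjacent loci.
LOCUS_NUMBER_STEP = 10


class LocusTagError(ValueError):
    """Raised for an unparseable locus tag; carries the raw string."""


@dataclass(frozen=True)
class LocusTag:
    """Parsed structured gene identifier."""

    raw: str
    chromosome: int
    scaffold_flags: frozenset[str]  # subset of {"u", "TE"}
    locus_number: int
    short_code: str
    transcript_index: int
    _number_width: int = 6

    @property
    def scheme(self) -> str:
        """Numbering scheme: 'TE' tags are numbered independently of the
        regular ('g'/'ug') per-chromosome numbering."""
        return "TE" if "TE" in self.scaffold_flags else "g"

    def render(self) -> str:
        infix = "TE" if "TE" in self.scaffold_flags else (
            "ug" if "u" in self.scaffold_flags else "g")
        return (f"Bv{self.chromosome}{infix}"
                f"{self.locus_number:0{self._number_width}d}"
                f"_{self.short_code}.t{self.transcript_index}")


def parse_locus_tag(raw: str) -> LocusTag:
    m = _TAG_RE.match(raw)
    if not m:
        raise LocusTagError(f"unparseable locus tag: {raw!r}")
    chrom, infix, number, code, tindex = m.groups()
    flags: set[str] = set()
    if infix == "TE":
        flags.add("TE")
    elif infix == "ug":
        flags.add("u")
    return LocusTag(
        raw=raw, chromosome=int(chrom), scaffold_flags=frozenset(flags),
        locus_number=int(number), short_code=code,
        transcript_index=int(tindex), _number_width=len(number),
    )


def chromosome_distribution(catalog: Catalog | Iterable[CatalogEntry],
                            n_chromosomes: int = 9) -> dict[int, int]:
    """Entries per chromosome 1..n (zeros included)."""
    counts = {c: 0 for c in range(1, n_chromosomes + 1)}
    for entry in catalog:
        counts[parse_locus_tag(entry.gene_id).chromosome] += 1
    return counts


@dataclass(frozen=True)
class TandemPair:
    """A putative tandem-duplicated gene pair."""

    gene_a: str
    gene_b: str
    chromosome: int
    separation: int | None  # locus-number gap; None across numbering schemes
    confident: bool


def find_tandem_pairs(catalog: Catalog | Iterable[CatalogEntry],
                      max_gap: int = 2) -> list[TandemPair]:
    """Same-chromosome, same-subgroup pairs within ``max_gap`` locus-number
    steps. Pairs across incompatible tag schemes are reported with
    ``confident=False``; transcripts of a single gene are never paired."""
    entries = list(catalog)
    pairs: list[TandemPair] = []
    for ea, eb in combinations(entries, 2):
        if ea.name == eb.name:  # transcripts of the same gene
            continue
        if ea.subgroup != eb.subgroup:
            continue
        ta, tb = parse_locus_tag(ea.gene_id), parse_locus_tag(eb.gene_id)
        if ta.chromosome != tb.chromosome:
            continue
        a, b = sorted((ea.full_name, eb.full_name))
        if ta.scheme == tb.scheme:
            gap = abs(ta.locus_number - tb.locus_number)
            if gap <= max_gap * LOCUS_NUMBER_STEP:
                pairs.append(TandemPair(a, b, ta.chromosome, gap, True))
        else:
            pairs.append(TandemPair(a, b, ta.chromosome, None, False))
    return sorted(pairs, key=lambda p: (p.chromosome, p.gene_a, p.gene_b))


@dataclass(frozen=True)
class GeneModel:
    """A gene with its transcripts as ordered exon chains.

    Coordinates are 1-based inclusive (GFF3 convention); exon chains are in
    transcription order (reversed genomic order on the minus strand).
    """

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    transcripts: Mapping[str, tuple[tuple[int, int], ...]]

    def __post_init__(self) -> None:
        for tid, chain in self.transcripts.items():
            genomic = sorted(chain)
            for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
                if s2 <= e1:
                    raise ValueError(f"{tid}: overlapping exons")
            for s, e in chain:
                if not (self.start <= s <= e <= self.end):
                    raise ValueError(f"{tid}: exon ({s},{e}) outside gene bounds")


@dataclass(frozen=True)
class SplicingEvent:
    """A transcript-pair splicing relationship within one gene."""

    gene_id: str
    transcript_a: str  # the longer chain
    transcript_b: str
    kind: str  # "exon_skipping" | "other"
    skipped_exon_index: int | None  # 1-based ordinal in the longer chain


def _load_db(gff: str | Path) -> gffutils.FeatureDB:
    return gffutils.create_db(str(gff), ":memory:", force=True,
                              merge_strategy="create_unique",
                              keep_order=True)


def exon_counts(gff: str | Path) -> dict[str, int]:
    """Exon count per transcript from a GFF3 file.

    Raises ``ValueError`` if an exon lies outside its gene's bounds.
    """
    db = _load_db(gff)
    bounds = {g.id: (g.start, g.end) for g in db.features_of_type("gene")}
    counts: dict[str, int] = {}
    for mrna in db.features_of_type("mRNA"):
        gene_ids = mrna.attributes.get("Parent", [])
        n = 0
        for exon in db.children(mrna, featuretype="exon"):
            for gid in gene_ids:
                gs, ge = bounds[gid]
                if not (gs <= exon.start and exon.end <= ge):
                    raise ValueError(
                        f"exon {exon.start}-{exon.end} of {mrna.id} outside "
                        f"gene {gid} bounds {gs}-{ge}"
                    )
            n += 1
        counts[mrna.id] = n
    return counts


def gene_models_from_gff(gff: str | Path) -> list[GeneModel]:
    """Build :class:`GeneModel` objects from a GFF3 file."""
    db = _load_db(gff)
    models = []
    for gene in db.features_of_type("gene"):
        transcripts: dict[str, tuple[tuple[int, int], ...]] = {}
        for mrna in db.children(gene, featuretype="mRNA"):
            exons = sorted(
                (e.start, e.end) for e in db.children(mrna, featuretype="exon")
            )
            if gene.strand == "-":
                exons = exons[::-1]
            transcripts[mrna.id] = tuple(exons)
        models.append(GeneModel(
            gene_id=gene.id, chromosome=gene.seqid, start=gene.start,
            end=gene.end, strand=gene.strand, transcripts=transcripts,
        ))
    return models


def detect_exon_skipping(model: GeneModel) -> list[SplicingEvent]:
    """Classify each transcript pair of a gene.

    A pair is ``exon_skipping`` when the shorter chain equals the longer one
    with exactly one internal exon removed (shared exons must agree in
    coordinates); identical chains yield no event; any other difference is
    reported as ``other``.
    """
    events: list[SplicingEvent] = []
    tids = sorted(model.transcripts)
    for ta, tb in combinations(tids, 2):
        ca, cb = model.transcripts[ta], model.transcripts[tb]
        if ca == cb:
            continue
        if len(ca) < len(cb):
            ta, tb, ca, cb = tb, ta, cb, ca
        kind, skipped = "other", None
        if len(ca) == len(cb) + 1 and len(ca) >= 3:
            for k in range(1, len(ca) - 1):  # internal exons only
                if ca[:k] + ca[k + 1:] == cb:
                    kind, skipped = "exon_skipping", k + 1
                    break
        events.append(SplicingEvent(
            gene_id=model.gene_id, transcript_a=ta, transcript_b=tb,
            kind=kind, skipped_exon_index=skipped,
        ))
    return events
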