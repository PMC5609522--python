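"""Deterministic synthetic fixtures with known ground truth.

The generator emulates the study's three inputs — a proteome, a gene
annotation and an RPKM expression matrix — at small scale:

* proteins are built on a six-transmembrane hourglass scaffold (TM helices
  of strongly hydrophobic residues, hydrophilic loops) with the family's
  diagnostic residues (NPA triplets, ar/R quartet, Froger positions, SDPs)
  planted at fixed scaffold columns, subgroup by subgroup;
* decoys are random sequences scrubbed of NPA-like motifs;
* the annotation carries the subfamily exon-count conventions, two tandem
  gene pairs at adjacent locus numbers and one gene with an
  internal-exon-skipping transcript pair;
* the expression matrix plants silent, organ-specific and stress-responsive
  genes under multiplicative log-normal noise.

Everything is reproducible bit-for-bit for a fixed seed. The scaffolds are
synthetic consensus-like sequences, not database records.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._residues import AMINO_ACIDS
from .expression import ExpressionMatrix, SampleInfo
from .refdata import AnchorAnnotation, CatalogEntry
from .sequence_screen import NPA_THIRD_RESIDUES

# ---------------------------------------------------------------------------
# Scaffold architecture

_TM_ALPHABET = "IVLFA"
_TM_WEIGHTS = (0.35, 0.30, 0.20, 0.10, 0.05)
_LOOP_ALPHABET = "GSTDEKRQH"
_LOOP_WEIGHTS = (0.18, 0.16, 0.14, 0.12, 0.12, 0.10, 0.08, 0.06, 0.04)

#: (name, length, is_tm) segments of the scaffold, N- to C-terminal.
_LAYOUT = (
    ("nterm", 10, False), ("TM1", 21, True), ("loopA", 20, False),
    ("TM2", 21, True), ("loopB", 30, False), ("TM3", 21, True),
    ("loopC", 30, False), ("TM4", 21, True), ("loopD", 20, False),
    ("TM5", 21, True), ("loopE", 30, False), ("TM6", 21, True),
    ("cterm", 10, False),
)

SCAFFOLD_LENGTH = sum(length for _, length, _ in _LAYOUT)  # 276


def _segment_bounds() -> dict[str, tuple[int, int]]:
    bounds = {}
    pos = 0
    for name, length, _ in _LAYOUT:
        bounds[name] = (pos, pos + length)
        pos += length
    return bounds


SEGMENTS = _segment_bounds()

#: Planted transmembrane intervals (0-based half-open).
TM_INTERVALS: tuple[tuple[int, int], ...] = tuple(
    SEGMENTS[name] for name, _, is_tm in _LAYOUT if is_tm
)

#: Diagnostic label -> scaffold column. The two NPA triplets sit on loops B
#: and E; H2/H5 inside TM2/TM5; LE1/LE2 and P1 on loop E; P2-P5 in TM6;
#: the nine SDP columns are scattered over loops A, C and D.
DIAGNOSTIC_COLUMNS: dict[str, int] = {
    "NPA_LB_0": 85, "NPA_LB_1": 86, "NPA_LB_2": 87,
    "NPA_LE_0": 220, "NPA_LE_1": 221, "NPA_LE_2": 222,
    "H2": 60, "H5": 205, "LE1": 228, "LE2": 234,
    "P1": 240, "P2": 250, "P3": 253, "P4": 256, "P5": 259,
    "SDP1": 35, "SDP2": 40, "SDP3": 45,
    "SDP4": 128, "SDP5": 133, "SDP6": 138, "SDP7": 143,
    "SDP8": 180, "SDP9": 185,
}

_DIAGNOSTIC_SET = frozenset(DIAGNOSTIC_COLUMNS.values())

SUBGROUPS = (
    "PIP1", "PIP2", "TIP1", "TIP2", "TIP3", "TIP4", "TIP5",
    "NIP1", "NIP4", "NIP5", "NIP6", "NIP7", "SIP1", "SIP2", "XIP1",
)

#: Diagnostic residues planted per subgroup, drawn from the observed values
#: of the curated residue tables (one representative per subgroup).
SUBGROUP_DIAGNOSTICS: dict[str, dict[str, str]] = {
    "PIP1": {"npa_lb": "NPA", "npa_le": "NPA", "arr": "FHTR", "froger": "QSAFW", "sdp": "HPFLLPGGN"},
    "PIP2": {"npa_lb": "NPA", "npa_le": "NPA", "arr": "FHTR", "froger": "QSAFW", "sdp": "AGVFIHFVP"},
    "TIP1": {"npa_lb": "NPA", "npa_le": "NPA", "arr": "HIAV", "froger": "TSAYW", "sdp": "HPFFLAGSN"},
    "TIP2": {"npa_lb": "NPA", "npa_le": "NPA", "arr": "HIGR", "froger": "TSAYW", "sdp": "HPFALPGSN"},
    "TIP3": {"npa_lb": "NPA", "npa_le": "NPA", "arr": "HIAR", "froger": "TAAYW", "sdp": "AALTIHYVP"},
    "TIP4": {"npa_lb": "NPA", "npa_le": "NPA", "arr": "HIAR", "froger": "TSAYW", "sdp": "HPLALLGSN"},
    "TIP5": {"npa_lb": "NPA", "npa_le": "NPA", "arr": "NVGY", "froger": "TSAYW", "sdp": "HPFALPGSN"},
    "NIP1": {"npa_lb": "NPA", "npa_le": "NPA", "arr": "WVAR", "froger": "FSAYL", "sdp": "FHFTADLET"},
    "NIP4": {"npa_lb": "NPA", "npa_le": "NPA", "arr": "WVAR", "froger": "FSAYI", "sdp": "HPLALPGSN"},
    "NIP5": {"npa_lb": "NPS", "npa_le": "NPV", "arr": "AIGR", "froger": "FTAYM", "sdp": "TIHPELLAP"},
    "NIP6": {"npa_lb": "NPS", "npa_le": "NPV", "arr": "SIGR", "froger": "FTAYF", "sdp": "TIHPELLAP"},
    "NIP7": {"npa_lb": "NPA", "npa_le": "NPA", "arr": "AVGR", "froger": "FSAYF", "sdp": "HPIALPGSN"},
    "SIP1": {"npa_lb": "NPT", "npa_le": "NPA", "arr": "IVPN", "froger": "MAAYW", "sdp": "HPIALPGSN"},
    "SIP2": {"npa_lb": "NPL", "npa_le": "NPA", "arr": "SNGS", "froger": "FVAYW", "sdp": "HPLALPGSN"},
    "XIP1": {"npa_lb": "NPT", "npa_le": "NPA", "arr": "VSAR", "froger": "FCAFW", "sdp": "TIHPELLTP"},
}

#: Exon-count conventions per family.
FAMILY_EXON_COUNTS = {"PIP": 4, "TIP": 3, "NIP": 5, "SIP": 3, "XIP": 2}

_MASTER_SEED = 20170919
_SUBGROUP_SEED_BASE = 77000
_SUBGROUP_LOOP_DIVERGENCE = 0.22

_PLANTED_NPA_STARTS = (DIAGNOSTIC_COLUMNS["NPA_LB_0"],
                       DIAGNOSTIC_COLUMNS["NPA_LE_0"])


# ---------------------------------------------------------------------------
# Ground truth containers

@dataclass(frozen=True)
class PlantedAqp:
    """Ground truth for one planted aquaporin."""

    id: str
    subgroup: str
    npa_lb: str
    npa_le: str
    arr: tuple[str, str, str, str]
    froger: tuple[str, ...]
    sdp: tuple[str, ...]
    tm_intervals: tuple[tuple[int, int], ...]


@dataclass
class GroundTruth:
    """What the generator planted, for downstream recovery checks."""

    planted_aqps: dict[str, PlantedAqp] = field(default_factory=dict)
    decoys: list[str] = field(default_factory=list)
    tandem_pairs: list[tuple[str, str]] = field(default_factory=list)
    low_confidence_pairs: list[tuple[str, str]] = field(default_factory=list)
    splicing_events: list[tuple[str, str, str, int]] = field(default_factory=list)
    exon_counts: dict[str, int] = field(default_factory=dict)
    expression_labels: dict[str, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Scaffolds

def _scrub_npa(seq: list[str], keep_starts: Sequence[int] = (),
               protect: frozenset[int] = frozenset()) -> None:
    """Destroy every NPA-like triplet not starting at ``keep_starts``,
    editing only positions outside ``protect`` (in place)."""
    while True:
        target = None
        for i in range(len(seq) - 2):
            if (seq[i] == "N" and seq[i + 1] == "P"
                    and seq[i + 2] in NPA_THIRD_RESIDUES
                    and i not in keep_starts):
                target = i
                break
        if target is None:
            return
        for j in (target + 1, target, target + 2):
            if j not in protect:
                seq[j] = "G"
                break
        else:  # fully protected triplet: planted columns, leave it
            return


def _master_scaffold() -> list[str]:
    rng = np.random.default_rng(_MASTER_SEED)
    seq: list[str] = []
    for name, length, is_tm in _LAYOUT:
        alphabet, weights = ((_TM_ALPHABET, _TM_WEIGHTS) if is_tm
                             else (_LOOP_ALPHABET, _LOOP_WEIGHTS))
        seq.extend(rng.choice(list(alphabet), size=length, p=weights))
    return seq


def _plant_diagnostics(seq: list[str], subgroup: str) -> None:
    spec = SUBGROUP_DIAGNOSTICS[subgroup]
    for i, c in enumerate(spec["npa_lb"]):
        seq[DIAGNOSTIC_COLUMNS[f"NPA_LB_{i}"]] = c
    for i, c in enumerate(spec["npa_le"]):
        seq[DIAGNOSTIC_COLUMNS[f"NPA_LE_{i}"]] = c
    for label, c in zip(("H2", "H5", "LE1", "LE2"), spec["arr"]):
        seq[DIAGNOSTIC_COLUMNS[label]] = c
    for i, c in enumerate(spec["froger"], start=1):
        seq[DIAGNOSTIC_COLUMNS[f"P{i}"]] = c
    for i, c in enumerate(spec["sdp"], start=1):
        seq[DIAGNOSTIC_COLUMNS[f"SDP{i}"]] = c


def subgroup_scaffold(subgroup: str) -> str:
    """Deterministic consensus-like scaffold for one subgroup."""
    seq = _master_scaffold()
    rng = np.random.default_rng(_SUBGROUP_SEED_BASE + SUBGROUPS.index(subgroup))
    loop_positions = [
        p for name, _, is_tm in _LAYOUT if not is_tm
        for p in range(*SEGMENTS[name])
        if p not in _DIAGNOSTIC_SET
    ]
    for p in loop_positions:
        if rng.random() < _SUBGROUP_LOOP_DIVERGENCE:
            seq[p] = rng.choice(list(_LOOP_ALPHABET))
    _plant_diagnostics(seq, subgroup)
    _scrub_npa(seq, keep_starts=_PLANTED_NPA_STARTS, protect=_DIAGNOSTIC_SET)
    return "".join(seq)


def reference_panel() -> tuple[list[tuple[str, str]], dict[str, str]]:
    """Labelled reference panel: one scaffold per subgroup.

    Returns (records, labels) where labels maps reference id -> subgroup.
    """
    records = [(f"ref_{sg}", subgroup_scaffold(sg)) for sg in SUBGROUPS]
    labels = {rid: rid.removeprefix("ref_") for rid, _ in records}
    return records, labels


def anchor_annotation() -> AnchorAnnotation:
    """The packaged anchor: the PIP2-type scaffold with its diagnostic
    columns (water-typical F-H-T-R filter, Q-S-A-F-W Froger residues)."""
    return AnchorAnnotation(
        anchor_id="anchor_PIP2",
        sequence=subgroup_scaffold("PIP2"),
        diagnostic_columns=dict(DIAGNOSTIC_COLUMNS),
    )


# ---------------------------------------------------------------------------
# Proteome

def make_proteome(n_aqp: int = 10, n_decoy: int = 40,
                  mutation_rate: float = 0.1, seed: int = 7
                  ) -> tuple[list[tuple[str, str]], GroundTruth]:
    """Planted-aquaporin proteome plus decoys.

    Aquaporins are subgroup scaffolds mutated everywhere except the
    diagnostic columns; decoys are random sequences scrubbed of NPA-like
    motifs. Returns ((id, sequence) records, ground truth).
    """
    if not 0.0 <= mutation_rate <= 0.2:
        raise ValueError("mutation_rate must lie in [0, 0.2]")
    rng = np.random.default_rng(seed)
    truth = GroundTruth()
    records: list[tuple[str, str]] = []

    for k in range(n_aqp):
        subgroup = SUBGROUPS[k % len(SUBGROUPS)]
        seq = list(subgroup_scaffold(subgroup))
        for p in range(len(seq)):
            if p in _DIAGNOSTIC_SET:
                continue
            if rng.random() < mutation_rate:
                choices = [c for c in AMINO_ACIDS if c != seq[p]]
                seq[p] = choices[rng.integers(len(choices))]
        _scrub_npa(seq, keep_starts=_PLANTED_NPA_STARTS, protect=_DIAGNOSTIC_SET)
        pid = f"AQP{k:03d}_{subgroup}"
        records.append((pid, "".join(seq)))
        spec = SUBGROUP_DIAGNOSTICS[subgroup]
        truth.planted_aqps[pid] = PlantedAqp(
            id=pid, subgroup=subgroup,
            npa_lb=spec["npa_lb"], npa_le=spec["npa_le"],
            arr=tuple(spec["arr"]), froger=tuple(spec["froger"]),
            sdp=tuple(spec["sdp"]), tm_intervals=TM_INTERVALS,
        )

    for k in range(n_decoy):
        length = int(rng.integers(150, 351))
        seq = list(rng.choice(list(AMINO_ACIDS), size=length))
        _scrub_npa(seq)
        pid = f"DECOY{k:03d}"
        records.append((pid, "".join(seq)))
        truth.decoys.append(pid)

    return records, truth


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path,
                width: int = 60) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Gene annotation

_SUBGROUP_CHROMOSOME = {
    "PIP1": 1, "PIP2": 9, "TIP1": 7, "TIP2": 9, "TIP3": 8, "TIP4": 2,
    "TIP5": 3, "NIP1": 8, "NIP4": 2, "NIP5": 6, "NIP6": 5, "NIP7": 3,
    "SIP1": 2, "SIP2": 3, "XIP1": 9,
}


def make_annotation(seed: int = 7) -> tuple[str, list[CatalogEntry], GroundTruth]:
    """Synthetic gene models following the family exon conventions.

    Plants two tandem gene pairs (adjacent locus numbers, same subgroup) and
    one gene whose second transcript skips internal exon 2. Returns
    (GFF3 text, catalog-like entries, ground truth).
    """
    rng = np.random.default_rng(seed)
    truth = GroundTruth()
    entries: list[CatalogEntry] = []
    gff_lines = ["##gff-version 3"]

    # two genes for the tandem subgroups, one for every other subgroup
    plan: list[tuple[str, int]] = []
    for sg in SUBGROUPS:
        plan.append((sg, 1))
        if sg in ("PIP2", "NIP6"):
            plan.append((sg, 2))

    base_locus: dict[int, int] = {}
    used_names: dict[str, int] = {}
    for sg, member in plan:
        family = sg[:3]
        chrom = _SUBGROUP_CHROMOSOME[sg]
        used_names[sg] = used_names.get(sg, 0) + 1
        name = f"Bv{sg};{used_names[sg]}"
        if member == 1:
            base_locus[chrom] = base_locus.get(chrom, 0) + 5000
            locus = base_locus[chrom]
        else:  # tandem partner: adjacent locus number
            locus = base_locus[chrom] + 10
        code = "".join(rng.choice(list("abcdefghijklmnopqrstuvwxyz"), size=4))
        gene_id = f"Bv{chrom}g{locus:06d}_{code}.t1"
        entries.append(CatalogEntry(
            name=name, family=family, subgroup=sg, transcript_tag=None,
            gene_id=gene_id, protein_length=SCAFFOLD_LENGTH, mw=30.0, pi=8.0,
            tmh_count=6,
        ))

        n_exons = FAMILY_EXON_COUNTS[family]
        start = locus * 100
        exons = []
        pos = start
        for _ in range(n_exons):
            exons.append((pos, pos + 199))
            pos += 200 + 150
        end = exons[-1][1]
        gid = f"gene_{name.replace(';', '_')}"
        tid = f"{gid}.t1"
        gff_lines.append(
            f"chr{chrom}\tsynthetic\tgene\t{start}\t{end}\t.\t+\t."
            f"\tID={gid};Name={name}"
        )
        gff_lines.append(
            f"chr{chrom}\tsynthetic\tmRNA\t{start}\t{end}\t.\t+\t.\tID={tid};Parent={gid}"
        )
        for es, ee in exons:
            gff_lines.append(
                f"chr{chrom}\tsynthetic\texon\t{es}\t{ee}\t.\t+\t.\tParent={tid}"
            )
        truth.exon_counts[tid] = n_exons

        if sg == "SIP1":
            # alternative transcript skipping internal exon 2
            tid2 = f"{gid}.t2"
            gff_lines.append(
                f"chr{chrom}\tsynthetic\tmRNA\t{start}\t{end}\t.\t+\t.\tID={tid2};Parent={gid}"
            )
            for i, (es, ee) in enumerate(exons):
                if i == 1:
                    continue
                gff_lines.append(
                    f"chr{chrom}\tsynthetic\texon\t{es}\t{ee}\t.\t+\t.\tParent={tid2}"
                )
            truth.exon_counts[tid2] = n_exons - 1
            truth.splicing_events.append((gid, tid, tid2, 2))

    for sg in ("PIP2", "NIP6"):
        a, b = sorted(e.full_name for e in entries if e.subgroup == sg)
        truth.tandem_pairs.append((a, b))

    return "\n".join(gff_lines) + "\n", entries, truth


# ---------------------------------------------------------------------------
# Expression

EXPRESSION_CLASSES = (
    "baseline", "silent", "organ_specific",
    "up_salt_strong", "down_salt_strong", "up_heat_strong",
    "down_heat_strong", "up_salt_weak", "down_salt_weak",
    "up_heat_weak", "down_heat_weak",
)

STRONG_FOLD = 4.0
WEAK_FOLD = 1.5
NOISE_SIGMA = 0.1
SPECIFIC_ORGAN = "inflorescence"

DEFAULT_ORGANS = ("seedling", "root", "leaf", "inflorescence", "seed")


def make_expression(n_genes: int = 55,
                    organs: Sequence[str] = DEFAULT_ORGANS,
                    seed: int = 7, sigma: float = NOISE_SIGMA
                    ) -> tuple[ExpressionMatrix, GroundTruth]:
    """RPKM matrix with planted expression classes.

    Samples: one control sample per organ plus a leaf control/salt/heat
    trio for the stress contrasts. Baselines are log-normal (clipped away
    from the detection floor); stress effects are x4 (strong) and x1.5
    (weak); noise is multiplicative log-normal with standard deviation
    ``sigma`` in natural-log space.
    """
    rng = np.random.default_rng(seed)
    genes = [f"G{k:04d}" for k in range(n_genes)]
    labels = {g: EXPRESSION_CLASSES[k % len(EXPRESSION_CLASSES)]
              for k, g in enumerate(genes)}

    samples = {f"{o}_1": SampleInfo(f"{o}_1", o, "control") for o in organs}
    for cond in ("control", "salt", "heat"):
        sid = f"leaf_{cond}"
        samples[sid] = SampleInfo(sid, "leaf", cond)
    sample_ids = list(samples)

    def noise() -> float:
        return float(np.exp(rng.normal(0.0, sigma))) if sigma > 0 else 1.0

    rows = []
    for g in genes:
        label = labels[g]
        base = float(np.clip(np.exp(rng.normal(3.0, 0.5)), 5.0, 200.0))
        values = {}
        for sid in sample_ids:
            info = samples[sid]
            if label == "silent":
                values[sid] = 0.0
                continue
            if label == "organ_specific":
                values[sid] = base * noise() if info.organ == SPECIFIC_ORGAN else 0.0
                continue
            level = base
            if label.endswith(("salt_strong", "salt_weak",
                               "heat_strong", "heat_weak")):
                direction, cond, size = label.split("_")
                if info.condition == cond:
                    fold = STRONG_FOLD if size == "strong" else WEAK_FOLD
                    level = base * fold if direction == "up" else base / fold
            values[sid] = level * noise()
        rows.append(values)

    rpkm = pd.DataFrame(rows, index=genes, columns=sample_ids)
    truth = GroundTruth(expression_labels=labels)
    return ExpressionMatrix(rpkm=rpkm, samples=samples), truth
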