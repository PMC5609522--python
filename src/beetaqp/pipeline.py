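"""End-to-end annotation pipeline.

Runs screen -> profile -> classify -> substrate -> genome context ->
expression over one set of inputs and writes a combined per-protein
annotation table, context and expression tables, and a machine-readable run
manifest recording every threshold (so published runs are reconstructible).
Any stage failure aborts with a stage-named error and removes partial
outputs. Output is a pure function of (inputs, config, seed).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .align_extract import AlignParams, profile_for, profiles_to_rows
from .classify import assign_subfamily, build_distance_matrix, nj_tree
from .expression import (ExpressionMatrix, expression_breadth,
                         responses_to_rows, stress_response)
from .genome_context import chromosome_distribution, find_tandem_pairs
from .refdata import load_anchor, load_catalog, load_patterns
from .sequence_screen import (ScreenConfig, read_fasta, results_to_rows,
                              screen_proteome, ProteinRecord)
from .substrate_predict import (NEAR_MAX_DEFAULT, apply_arr_rules,
                                call_substrates, reports_to_rows)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """All inputs and thresholds of one pipeline run."""

    out_dir: str
    proteome_fasta: str | None = None
    panel_fasta: str | None = None
    anchor_fasta: str | None = None  # packaged anchor when None
    anchor_sidecar: str | None = None
    catalog_tsv: str | None = None  # packaged catalog when None
    gff: str | None = None
    rpkm_tsv: str | None = None
    sample_meta_tsv: str | None = None
    stress_contrasts: list[tuple[str, str]] = field(default_factory=list)
    seed: int = 0
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    align: AlignParams = field(default_factory=AlignParams)
    near_max: int = NEAR_MAX_DEFAULT
    pseudocount: float = 1.0
    detect_floor: float = 1.0
    strong_cut: float = 1.0
    max_tandem_gap: int = 2

    def to_jsonable(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh)
        raw["screen"] = ScreenConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in raw.get("screen", {}).items()
        })
        raw["align"] = AlignParams(**raw.get("align", {}))
        raw["stress_contrasts"] = [tuple(c) for c in raw.get("stress_contrasts", [])]
        return cls(**raw)


def panel_labels(records: list[tuple[str, str]]) -> dict[str, str]:
    """Subgroup labels of a reference panel: ids of the form
    ``ref_<subgroup>`` (or ``<anything>_<subgroup>``)."""
    return {rid: rid.rsplit("_", 1)[-1] for rid, _ in records}


def run_pipeline(config: RunConfig) -> dict:
    """Execute all configured stages; returns a summary dict."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    summary: dict = {}

    def write_tsv(name: str, rows: list[dict]) -> None:
        path = out_dir / name
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        written.append(path)

    stage = "configure"
    try:
        for field_name in ("proteome_fasta", "panel_fasta", "anchor_fasta",
                           "anchor_sidecar", "catalog_tsv", "gff", "rpkm_tsv",
                           "sample_meta_tsv"):
            value = getattr(config, field_name)
            if value and not Path(value).exists():
                raise ValueError(f"{field_name}: no such file: {value}")
        if config.proteome_fasta and not config.panel_fasta:
            raise ValueError("panel_fasta is required when proteome_fasta is set")
        if config.rpkm_tsv and not config.sample_meta_tsv:
            raise ValueError("sample_meta_tsv is required when rpkm_tsv is set")

        if config.proteome_fasta:
            stage = "screen"
            t0 = time.perf_counter()
            proteome = read_fasta(config.proteome_fasta)
            panel = read_fasta(config.panel_fasta)
            refs = [ProteinRecord(id=r, sequence=s) for r, s in panel]
            screen_results = screen_proteome(proteome, refs, config.screen)
            write_tsv("screen.tsv", results_to_rows(screen_results))
            passed_ids = {r.protein_id for r in screen_results if r.passed}
            summary["screened"] = len(screen_results)
            summary["passed"] = len(passed_ids)
            logger.info("screen: %d/%d passed (%.2fs)", len(passed_ids),
                        len(screen_results), time.perf_counter() - t0)

            stage = "profile"
            anchor = load_anchor(config.anchor_fasta, config.anchor_sidecar)
            candidates = [(r, s) for r, s in proteome if r in passed_ids]
            profiles = [profile_for(rid, seq, anchor, config.align)
                        for rid, seq in candidates]
            write_tsv("profiles.tsv", profiles_to_rows(profiles))

            stage = "classify"
            labels = panel_labels(panel)
            records = panel + candidates
            dm = build_distance_matrix(records, config.align)
            tree = nj_tree(dm)
            assignments = [
                assign_subfamily(rid, tree, labels, dm)
                for rid, _ in candidates
            ]
            (out_dir / "tree.nwk").write_text(tree.to_newick())
            written.append(out_dir / "tree.nwk")

            stage = "substrate"
            patterns = load_patterns()
            reports = call_substrates(profiles, patterns, config.near_max)
            write_tsv("substrates.tsv", reports_to_rows(reports))
            notes = [n for p in profiles for n in apply_arr_rules(p)]

            stage = "annotate"
            by_query = {p.query_id: p for p in profiles}
            rows = []
            for a in assignments:
                p = by_query[a.query_id]
                full = sorted(r.substrate for r in reports
                              if r.query_id == a.query_id and r.call == "FULL")
                note_ids = sorted(n.rule_id for n in notes
                                  if n.query_id == a.query_id)
                rows.append({
                    "protein_id": a.query_id, "family": a.family,
                    "subgroup": a.subgroup, "proposed_name": a.proposed_name,
                    "support": round(a.support, 4), "method": a.method,
                    "NPA_LB": p.npa_lb or "missing",
                    "NPA_LE": p.npa_le or "missing",
                    "arr": "-".join(p.arr), "froger": "-".join(p.froger),
                    "sdp": "".join(p.sdp),
                    "substrates_full": ";".join(full),
                    "notes": ";".join(note_ids),
                })
            write_tsv("annotation.tsv", rows)
            summary["annotated"] = len(rows)

        stage = "context"
        catalog = load_catalog(config.catalog_tsv)
        dist = chromosome_distribution(catalog)
        write_tsv("chromosome_distribution.tsv",
                  [{"chromosome": c, "genes": n} for c, n in dist.items()])
        pairs = find_tandem_pairs(catalog, config.max_tandem_gap)
        write_tsv("tandem_pairs.tsv", [
            {"gene_a": p.gene_a, "gene_b": p.gene_b,
             "chromosome": p.chromosome,
             "separation": "" if p.separation is None else p.separation,
             "confident": p.confident}
            for p in pairs
        ])
        summary["tandem_pairs"] = len(pairs)

        if config.gff:
            from .genome_context import (detect_exon_skipping, exon_counts,
                                         gene_models_from_gff)
            counts = exon_counts(config.gff)
            write_tsv("exon_counts.tsv",
                      [{"transcript": t, "exons": n} for t, n in sorted(counts.items())])
            events = [e for m in gene_models_from_gff(config.gff)
                      for e in detect_exon_skipping(m)]
            write_tsv("splicing_events.tsv", [
                {"gene": e.gene_id, "transcript_a": e.transcript_a,
                 "transcript_b": e.transcript_b, "kind": e.kind,
                 "skipped_exon_index": e.skipped_exon_index or ""}
                for e in events
            ])
            summary["splicing_events"] = len(
                [e for e in events if e.kind == "exon_skipping"])

        if config.rpkm_tsv:
            stage = "expression"
            em = ExpressionMatrix.from_tsv(config.rpkm_tsv,
                                           config.sample_meta_tsv)
            breadth = expression_breadth(em, config.detect_floor)
            write_tsv("expression_breadth.tsv", [
                {"gene": b.gene_id, "organs_detected": b.organs_detected,
                 "silent": b.silent, "organ_specific": b.organ_specific,
                 "expressed_everywhere": b.expressed_everywhere}
                for b in breadth
            ])
            response_rows: list[dict] = []
            for treated, control in config.stress_contrasts:
                responses = stress_response(em, treated, control,
                                            config.pseudocount,
                                            config.strong_cut)
                response_rows.extend(responses_to_rows(responses))
            if response_rows:
                write_tsv("stress_response.tsv", response_rows)
            summary["expression_genes"] = len(breadth)

        stage = "manifest"
        manifest = {
            "package_version": __version__,
            "seed": config.seed,
            "config": config.to_jsonable(),
            "outputs": sorted(p.name for p in written),
        }
        manifest_path = out_dir / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        written.append(manifest_path)
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    summary["outputs"] = sorted(p.name for p in written)
    return summary
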