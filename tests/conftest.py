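"""Shared fixtures: packaged tables and synthetic ground-truth data."""

from __future__ import annotations

import pytest

from beetaqp import synthetic_data as sd
from beetaqp.refdata import (load_anchor, load_catalog, load_diagnostic_table,
                             load_patterns, load_sdp_observations)
from beetaqp.sequence_screen import ProteinRecord


@pytest.fixture(scope="session")
def catalog():
    return load_catalog()


@pytest.fixture(scope="session")
def patterns():
    return {p.substrate: p for p in load_patterns()}


@pytest.fixture(scope="session")
def sdp_observations():
    return load_sdp_observations()


@pytest.fixture(scope="session")
def diagnostic_rows():
    return load_diagnostic_table()


@pytest.fixture(scope="session")
def anchor():
    return load_anchor()


@pytest.fixture(scope="session")
def proteome():
    """Planted proteome (10 aquaporins, 40 decoys, 10% mutation, seed 7)."""
    records, truth = sd.make_proteome(n_aqp=10, n_decoy=40,
                                      mutation_rate=0.1, seed=7)
    return records, truth


@pytest.fixture(scope="session")
def panel():
    """Labelled reference panel: (records, id->subgroup labels)."""
    return sd.reference_panel()


@pytest.fixture(scope="session")
def panel_records(panel):
    records, _ = panel
    return [ProteinRecord(id=r, sequence=s) for r, s in records]


@pytest.fixture(scope="session")
def annotation():
    """Synthetic gene models: (GFF3 text, catalog-like entries, truth)."""
    return sd.make_annotation(seed=7)


@pytest.fixture(scope="session")
def annotation_gff(annotation, tmp_path_factory):
    gff_text, _, _ = annotation
    path = tmp_path_factory.mktemp("gff") / "models.gff3"
    path.write_text(gff_text)
    return path
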