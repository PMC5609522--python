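# beetaqp

Annotation toolkit for the plant **aquaporin (AQP / MIP) gene family**, built
around the sugar-beet (*Beta vulgaris*) family: 28 catalogued proteins in
five subfamilies (7 PIP, 8 TIP, 9 NIP, 3 SIP, 1 XIP).

Aquaporins are six-transmembrane channel proteins whose transport behaviour
is readable from a handful of diagnostic residues:

* the two **NPA motifs** (Asn-Pro-Ala, variants NPS/NPT/NPL/NPV) on loops B
  and E, which form the channel's central constriction;
* the **ar/R selectivity filter** — four residues at positions H2, H5, LE1,
  LE2 — the size-exclusion barrier (F-H-T-R is the water-typical
  configuration of plasma-membrane aquaporins);
* **Froger's positions** P1–P5, which discriminate functional classes;
* nine **specificity-determining positions (SDPs)** whose composition
  predicts transport of non-aqua substrates (urea, boric acid, silicic acid,
  NH₃, CO₂, H₂O₂).

The package covers the full annotation workflow, each stage usable on its
own or through the `aqp` command line:

| stage | module | what it does |
|---|---|---|
| curated tables | `refdata` | catalog, residue table, SDP substrate patterns, annotated anchor |
| candidate screen | `sequence_screen` | dual-NPA motif scan, Kyte–Doolittle TM helices, MW, pI, identity to a reference panel |
| residue extraction | `align_extract` | global (BLOSUM62, affine-gap) alignment to an annotated anchor; reads NPA / ar/R / Froger / SDP columns |
| classification | `classify` | pairwise p-distances, in-house neighbor-joining, clade/nearest-reference subfamily assignment, column bootstrap |
| substrate calls | `substrate_predict` | SDP pattern matching with FULL / NEAR / NO calls and ar/R annotation rules |
| genome context | `genome_context` | locus-tag parsing, chromosome distribution, tandem-duplication and exon-skipping detection |
| expression | `expression` | log₂(RPKM) heatmap values, stress log₂ fold-change classes, breadth/silent/organ-specific flags |
| fixtures | `synthetic_data` | deterministic proteome / GFF3 / RPKM generators with planted ground truth |
| orchestration | `pipeline` + `cli` | one-shot `aqp run` producing annotation tables and a run manifest |

## Worked example

```python
from beetaqp import load_catalog, load_patterns, load_anchor, profile_for
from beetaqp.genome_context import chromosome_distribution, find_tandem_pairs
from beetaqp.substrate_predict import call_substrates, apply_arr_rules

catalog = load_catalog()
print("entries:", len(catalog), "families:", catalog.family_tally())
print("chromosomes:", chromosome_distribution(catalog))
for p in find_tandem_pairs(catalog):
    print("tandem:", p.gene_a, "--", p.gene_b,
          "(confident)" if p.confident else "(low confidence)")
```

prints

```
entries: 28 families: {'PIP': 7, 'TIP': 8, 'NIP': 9, 'SIP': 3, 'XIP': 1}
chromosomes: {1: 2, 2: 7, 3: 3, 4: 0, 5: 3, 6: 2, 7: 3, 8: 2, 9: 6}
tandem: BvPIP1;1 -- BvPIP1;2 (confident)
tandem: BvNIP4;1 -- BvNIP4;2 (confident)
tandem: BvNIP6;2 -- BvNIP6;3 (confident)
tandem: BvNIP5;1 -- BvNIP5;2 (low confidence)
tandem: BvPIP2;2 -- BvPIP2;3 (confident)
```

— 28 proteins, a quarter of them on chromosome 2, none on chromosome 4, and
five tandem-duplicated pairs (the NIP5 pair sits on a transposable-element
scaffold whose locus numbering is not comparable, so it is reported at low
confidence). Annotating a single query sequence:

```python
from beetaqp import synthetic_data as sd

anchor = load_anchor()
query = sd.subgroup_scaffold("NIP5")          # a NIP5-type test sequence
prof = profile_for("query1", query, anchor)
print("NPA:", prof.npa_lb, prof.npa_le, "ar/R:", "-".join(prof.arr))
full = [r.substrate for r in call_substrates([prof], load_patterns())
        if r.call == "FULL"]
print("FULL substrate calls:", full)
print("notes:", [n.rule_id for n in apply_arr_rules(prof)])
```

prints

```
NPA: NPS NPV ar/R: A-I-G-R
FULL substrate calls: ['boric_acid']
notes: ['boric_acid_nip5_like']
```

— the NPS/NPV pore with the A-I-G-R filter is the AtNIP5;1-type boric-acid
transporter configuration, and the query's SDP residues fully match the
boric-acid pattern.

The same workflow from the shell:

```bash
aqp simulate --what proteome --seed 7 --out-prefix syn
aqp screen --fasta syn_proteome.fasta --refs syn_panel.fasta  # 10/50 passed
aqp profile --fasta syn_proteome.fasta
aqp classify --fasta syn_proteome.fasta --panel syn_panel.fasta --seed 1
aqp context            # packaged catalog: distribution + tandem pairs
aqp run --config config.json   # everything, with a run manifest
```

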