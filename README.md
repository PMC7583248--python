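# larfam

A pipeline for organizing a protein superfamily and characterizing its
members: multiple sequence alignment with explicit column/residue coordinate
maps, distance-based clustering into phylogenetic groups, gene-neighborhood
(COG co-occurrence) association scoring, structure-anchored signature
profiles with information-content logos and rule-based activity
classification, and enzyme-kinetics fitting (saturation curves, competitive
inhibition, activity optima). A synthetic-data module generates protein
families, neighborhood tables, and kinetics datasets with planted ground
truth so every stage is testable end-to-end without downloads.

## Quick start

Generate a demo bundle (5 planted groups with LAR/SAR/MAR/HGR/GntE
signatures, neighborhoods with a high-probability partner COG per group,
and two kinetics designs), then run the full pipeline on it:

```bash
larfam demo --seed 0 --out-dir demo
larfam run --config demo/pipeline.yaml
cat demo/results/classification.json
```

Stage commands are independently invokable:

```bash
larfam align demo/family.fasta --out demo/aln.fasta
larfam cluster demo/aln.fasta --exclude-id REF --cutoff 0.4 --out demo/groups.tsv
larfam associate demo/groups.tsv demo/neighborhoods.tsv --window 3 \
    --assoc-threshold 0.30 --out demo/assoc.tsv
larfam signature demo/aln.fasta demo/groups.tsv demo/anchors.yaml \
    --out-dir demo/sigs --logo
larfam classify demo/aln.fasta demo/groups.tsv demo/anchors.yaml \
    --out demo/classes.json
larfam kinetics demo/kinetics_mm.csv --ki-csv demo/kinetics_ki.csv \
    --out demo/fits.json
```

Key thresholds (all CLI-exposed): neighborhood window ±3 genes,
association threshold 0.30 (strictly greater-than), clustering cutoff 0.4
with average linkage on p-distance, conservation threshold 0.7 (dominant
residue frequency).

## File formats

* **FASTA** — sequences; the aligned variant may contain `-`.
* **Neighborhood TSV** — `genome_id / anchor_gene_id / offset / cog`, one
  flanking gene per row, offsets ±1..±window (never 0).
* **Anchor YAML** — reference id, 1-based positions, expected residues,
  categories (`catalytic` / `npn_binding` / `substrate` / `other`), and the
  substrate-recognition regions (`loop`, `helix_a11`, `helix_a14`).
* **Kinetics CSV** — `S,I,v,replicate` columns plus `# enzyme_conc = <µM>`
  metadata; S and I in mM, v in µM/s.
* Reports: grouping TSV, association TSV, per-group signature TSVs,
  classification JSON, run manifest JSON.

## Library use

```python
from larfam import (
    FamilySimConfig, simulate_family, progressive_align, p_distance,
    cluster_family, build_group_profile, classify_group,
)

fam = simulate_family(FamilySimConfig(seed=0))
msa = progressive_align([fam.reference, *fam.records])
grouping = cluster_family(p_distance(msa.subset([r.id for r in fam.records])), 0.4)
config = fam.config.anchor_config("REF")
for gid, members in grouping.groups.items():
    profile = build_group_profile(msa, gid, sorted(members), config)
    print(gid, classify_group(profile, config).predicted_activity)
```
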