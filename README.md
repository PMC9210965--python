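# domtax

Classify species by their protein-domain repertoires and measure how well
the result agrees with a reference taxonomy.

Protein domains — the conserved, independently folding units Pfam models as
profile HMMs — sit between raw sequence and phenotype: which domains a
proteome contains, and how they combine on individual proteins, carries a
phylogenetic and functional signal. `domtax` implements a standardized
three-step framework over pfam_scan-style domain-hit tables, aimed at
microbial comparative genomicists who want a domain-level alternative (or
sanity check) to sequence-based classification:

1. **Profiles.** Overlapping hits on a protein are resolved by maximal bit
   score; the survivors, ordered N→C, form the protein's *domain
   architecture*. A species profile is built under one of four statistical
   models: `content` (set of distinct domain accessions), `organization`
   (set of distinct architectures), and their counted variants `f_content`
   and `f_organization`. Assemblies are screened with
   `quality = completeness − 5 × contamination`, dropping anything
   strictly below 95.
2. **Distances.** Any profile pair reduces to the overlap triple
   *(a, b, c)* — the two profile sizes and the shared part (elementwise
   minimum counts for the `f_*` models). Three distances are defined on
   it, all in [0, 1]:
   - Jaccard: `(a + b − 2c) / (a + b − c)`
   - Poisson: `sqrt(−ln(c/a) · −ln(c/b))`, clamped at 1, with `c = 0 → 1`
   - loss-corrected: `1 − c / min(a, b)`
3. **Classification.** Prim's algorithm builds the minimum spanning tree
   of the complete distance graph. Keeping only tree edges whose endpoints
   share a taxon label at the chosen rank, each taxon falls apart into
   connected groups; three standards score the agreement (lower is
   better): **arithmetic percentage** `ΣSᵢ / ΣTᵢ`, **weighted percentage**
   `mean(Sᵢ / Tᵢ)`, and the **split-taxon count** — where `Tᵢ` is taxon
   *i*'s species count and `Sᵢ` the number of its species outside its
   largest group.

The 4 × 3 = 12 model combinations are named `con/org/f_con/f_org` ×
`ja/po/lo` (e.g. `org_ja`). A seeded simulator generates domainomes with
known clade structure so the whole pipeline can be validated against a
ground truth without any downloads.

## Worked example

`examples/03_mst_clustering.py` builds a toy five-species matrix in which
one species of PhylumA (`A3`) sits closer to the PhylumB clade:

```
MST edges:
  A1 -- A2  (0.10)
  A1 -- B1  (0.40)
  B1 -- B2  (0.15)
  B1 -- A3  (0.20)
PhylumA: T=3 species, groups [2, 1], S=1 isolated
PhylumB: T=2 species, groups [2], S=0 isolated
arithmetic=0.200  weighted=0.167  split taxa=1
```

`A3` attaches to the tree through `B1`, so PhylumA splits into a main
group of two plus one isolated species: 1 of the 5 species is isolated
(arithmetic 0.2), the per-taxon isolation rates average to 0.167, and one
taxon is split. The other examples cover profile building
(`01_profiles.py`), the three distances (`02_distances.py`) and a full
simulated pipeline run across all 12 combinations
(`04_simulate_pipeline.py`).

## Command line

Each pipeline stage is also a subcommand of the `domtax` CLI
(`profile`, `distance`, `mst`, `cluster`, `metrics`), plus `run` for the
whole pipeline and `simulate` for fixtures:

```bash
domtax simulate --n-taxa 4 --species-per-taxon 5 --seed 1 -o fixture/
domtax run --input-dir fixture/ --taxonomy fixture/taxonomy.tsv \
           --quality fixture/quality.tsv -o results/
```

`run` writes, per combination, the distance matrix (square TSV, 6
decimals), the MST as Cytoscape-importable JSON, and a cluster report,
plus a combined `metrics.tsv` ranking all combinations by each standard
and a `run_summary.json`. Cluster reports are TSV with fixed column order
`taxon, T, S, n_groups, group_sizes` and a sibling `.metrics.json`
carrying the three standards.

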