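# Methods

## The model

A species is represented only by its domainome: the multiset of protein
domain architectures obtained by scanning its proteome against Pfam.
The framework deliberately discards sequence-level information — the
assumption is that the presence, multiplicity and N→C arrangement of
domains carry enough signal to recover coarse (phylum-level) structure,
and that disagreements between the domain tree and the reference taxonomy
are themselves informative.

### Overlap resolution

pfam_scan reports can assign overlapping intervals on one protein to
several families. Resolution is greedy by descending bit score: a hit is
kept iff its alignment interval (1-based, inclusive; alignment rather than
envelope bounds, as the conservative match extent) shares no residue with
an already-kept hit. Any shared position counts as overlap — no tolerance
— because a tolerance would need a parameter the data gives no way to fix.
Score ties break by lexicographically smaller accession, then smaller
start, then smaller end, so the output is a deterministic function of the
hit set, invariant to input order. Greedy-by-score is not guaranteed to
maximize total bit score over all non-overlapping subsets; it is the
implemented contract (the tests assert the greedy total never exceeds the
exhaustive optimum, not that it attains it).

### Statistical models

From the resolved architectures four profiles are derived: `content`
(distinct accessions), `organization` (distinct architecture strings,
accessions joined by `|` with order and within-protein repeats
significant, so `D1|D1|D2 ≠ D1|D2`), and their counted variants
`f_content` (every domain instance counts, including repeats within one
protein) and `f_organization` (proteins per architecture). Mixed
content/organization models are deliberately out of scope. A species with
zero surviving hits keeps an empty profile and is flagged rather than
dropped.

### Distances

All three distances are functions of the overlap triple (a, b, c). For
set profiles these are cardinalities; for frequency profiles, multiset
semantics: a and b are total counts and c is the sum of elementwise
minimum counts — the canonical generalization once "the number of
occurrences" matters.

- Jaccard `(a+b−2c)/(a+b−c)`: the fraction of the union not shared;
  appropriate when domain changes are treated as independent random
  events.
- Poisson `sqrt(−ln(c/a)·−ln(c/b))`: each factor is the Poisson-process
  branch-length estimate to the common ancestor; the geometric mean makes
  the distance symmetric. The raw expression is unbounded as c → 0, while
  the framework requires all distances in [0, 1]; it is therefore clamped
  at 1 and c = 0 maps to 1. The clamp preserves ordering below the
  boundary and only saturates pairs that are already maximally distant.
- loss-corrected `1 − c/min(a, b)`: measures shared content against the
  smaller profile, so a lineage that lost most of its domainome is not
  pushed away from its relatives.

Degenerate inputs: an empty profile is at distance 1 from any non-empty
profile and 0 from another empty one, with a logged warning; two empty
profiles are treated as identical under Jaccard as well. These cases never
arise in realistic data but must be defined for the matrix to stay total.

### MST and concordance

Prim's algorithm runs from the lexicographically smallest species ID with
ties broken by (weight, in-tree endpoint, new endpoint); the MST is not
unique under tied weights, so the tie rule pins down one reproducible
tree whose total weight is still the global minimum (verified against an
independent Kruskal implementation). Clustering keeps only tree edges
whose endpoints share the rank label; groups are the connected components
of that subgraph, so same-taxon nodes joined only through a foreign taxon
stay separate — this is what makes the metrics sensitive to misplaced
species. Species lacking the requested rank receive a unique singleton
label so the partition still covers every node. When two groups of a
taxon tie for largest, the "main part" is chosen deterministically
(descending size, then lexicographic members); Sᵢ is unaffected by the
choice. The weighted percentage divides by the number of taxa observed in
the input rather than any fixed count.

## The simulator

`domtax.simulate` emulates the statistical structure the distance models
assume: domain changes as random, independent per-protein events. Species
evolve on a fixed two-level tree (clade ancestors, then leaves) rather
than a general birth–death tree, because the concordance metrics consume
exactly a two-level taxon/species structure and the ground truth stays
unambiguous. Per-protein events per branch — loss, duplication, shuffle,
gain — fire with probability min(1, rate × branch length). Shuffles
permute domain order on multi-domain architectures (changing organization
profiles but not content profiles) and swap the domain on single-domain
architectures; this asymmetry is what gives the four statistical models
genuinely different signals to distinguish.

Defaults (chosen once as a plausible small-genome regime): 5 taxa × 6
species; 100 root proteins; architecture length ~ Poisson(2), minimum 1;
a 400-accession alphabet (comfortably above the expected distinct-domain
count); gain/loss/shuffle rates 0.05 and duplication 0.02 per protein per
unit branch; between-taxon branch 1.0 and within-taxon branch 0.05, i.e.
20× separation — clades far better separated than real phyla, which is
the point: end-to-end tests ask for perfect recovery under all 12
combinations, a property that is only guaranteed in the well-separated
regime. Fixture files synthesize non-overlapping 80-residue hits with
10-residue gaps and arbitrary positive bit scores, so overlap resolution
is a no-op unless decoy hits are explicitly requested.

What the simulator does **not** emulate: realistic Pfam length/score/
frequency distributions, horizontal transfer, rate heterogeneity across
proteins or lineages, and assembly noise. Passing recovery tests
demonstrates internal consistency of the pipeline under its own model
assumptions, not performance on real genomes.

## Numerical and design choices

- All distances are computed in double precision; matrices are dense
  (thousands of species ≈ millions of pairs remain trivial).
- Matrix writers emit 6 decimals; read/write round-trips are exact to
  1e-6 by construction.
- Quality filtering keeps quality ≥ 95 exactly: only assemblies strictly
  under the threshold are removed.
- Parsers never silently drop a data row: anything malformed raises an
  error naming the line.
- pfam_scan tables may be whitespace- or comma-delimited; the delimiter
  is sniffed from the first data line. Clan membership is ignored in
  overlap resolution: all hits are treated uniformly.
- Problem sizes in the test suite (simulations of 12–30 species, 40–100
  root proteins, MST oracles up to n = 50, 10 seeds for the end-to-end
  recovery check) keep every property exhaustively or statistically
  checkable while remaining quick to run; all scale linearly if enlarged.

## Known limitations

- Greedy overlap resolution can differ from the maximum-total-score
  non-overlapping subset on adversarial inputs.
- The Poisson clamp discards ordering information among pairs whose raw
  value exceeds 1 (all map to 1).
- The loss-corrected distance is a pseudo-distance: unrelated profile
  pairs of very different sizes can score low if the smaller profile is
  mostly shared, and it tends to fragment clusters on real data.
- Concordance metrics compare against the reference taxonomy at a single
  rank at a time; cross-rank structure is not modelled.
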