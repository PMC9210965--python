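"""End-to-end run on a simulated domainome with known clades.

Simulates 3 clades x 4 species, writes a pfam_scan-style fixture, runs
all 12 model combinations and prints the ranked agreement metrics.
"""

from pathlib import Path
from tempfile import TemporaryDirectory

from domtax import RunConfig, SimulationConfig, run_pipeline, simulate_domainomes, write_fixture

config = SimulationConfig(n_taxa=3, species_per_taxon=4, root_n_proteins=60, seed=7)
species, truth = simulate_domainomes(config)
print(f"simulated {len(species)} species in {len(truth.tree)} clades")

with TemporaryDirectory() as tmp:
    fix = Path(tmp) / "fixture"
    write_fixture(species, truth, fix)
    summary = run_pipeline(
        RunConfig(
            input_dir=fix,
            taxonomy=fix / "taxonomy.tsv",
            quality=fix / "quality.tsv",
            output_dir=Path(tmp) / "out",
            log_level="WARNING",
        )
    )

print(f"species kept after quality filter: {summary['n_species']} "
      f"(removed: {summary['removed_by_quality']})")
print(f"{'combination':12s} {'arith':>6s} {'weight':>6s} {'split':>5s}")
for row in summary["combinations"]:
    print(
        f"{row['combination']:12s} {row['arithmetic_percentage']:6.3f} "
        f"{row['weighted_percentage']:6.3f} {row['split_taxon_count']:5d}"
    )
print(
    "\nWith well-separated clades every combination should recover the\n"
    "simulated taxa exactly (all metrics 0, all combinations tied best)."
)
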