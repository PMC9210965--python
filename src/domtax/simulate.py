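"""Seeded domainome simulator with known clade structure.

Species evolve on a two-level tree: a root domainome (a bag of protein
architectures drawn from a synthetic Pfam-style alphabet) diverges into
``n_taxa`` clade ancestors along long between-taxon branches, and each
ancestor into ``species_per_taxon`` leaves along short within-taxon
branches. Along each branch every protein independently suffers

* **loss** — the architecture is removed,
* **duplication** — the architecture is copied,
* **shuffle** — multi-domain architectures have their domain order
  permuted (changing organization profiles but not content profiles);
  single-domain architectures have the domain swapped for a random one,
* **gain** — a new random architecture appears,

each with its configured per-unit-branch rate scaled by branch length.
The two-level design makes the ground-truth taxon of every species
unambiguous, so the full pipeline can be scored against a known answer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from domtax.profiles import ProteinArchitecture

#: pfam_scan columns emitted by write_fixture (same 15-column layout the
#: reader expects).
_FIXTURE_HEADER = (
    "# <seq id> <alignment start> <alignment end> <envelope start> "
    "<envelope end> <hmm acc> <hmm name> <type> <hmm start> <hmm end> "
    "<hmm length> <bit score> <E-value> <significance> <clan>"
)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a domainome simulation.

    Rates are per-protein event probabilities per unit branch length;
    the effective probability on a branch of length t is min(1, rate × t).
    Defaults give five well-separated clades of six species each, with
    between-clade branches 20× the within-clade branches.
    """

    n_taxa: int = 5
    species_per_taxon: int = 6
    root_n_proteins: int = 100
    root_arch_length_mean: float = 2.0
    domain_alphabet_size: int = 400
    gain_rate: float = 0.05
    loss_rate: float = 0.05
    duplication_rate: float = 0.02
    shuffle_rate: float = 0.05
    between_taxon_branch: float = 1.0
    within_taxon_branch: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 1 or self.species_per_taxon < 1:
            raise ValueError("n_taxa and species_per_taxon must be >= 1")
        if self.root_n_proteins < 1:
            raise ValueError("root_n_proteins must be >= 1")
        if self.domain_alphabet_size < 1:
            raise ValueError("domain_alphabet_size must be >= 1")
        for name in ("gain_rate", "loss_rate", "duplication_rate", "shuffle_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {rate}")
        if not 0.0 <= self.within_taxon_branch <= self.between_taxon_branch:
            raise ValueError(
                "need 0 <= within_taxon_branch <= between_taxon_branch"
            )
        # a branch that deterministically deletes every protein with no
        # gains would leave every species empty
        if (
            min(1.0, self.loss_rate * self.between_taxon_branch) >= 1.0
            and self.gain_rate == 0.0
        ):
            raise ValueError(
                "loss is certain on between-taxon branches and gain_rate is 0: "
                "every species would end up empty"
            )


@dataclass(frozen=True)
class GroundTruth:
    """The simulated truth: taxon labels, the clade tree, the event log."""

    labels: dict[str, str]
    tree: dict[str, list[str]]
    event_log: list[dict]


def _domain_name(index: int) -> str:
    return f"PF{index:05d}"


def _random_architecture(rng: np.random.Generator, config: SimulationConfig) -> tuple[str, ...]:
    length = max(1, int(rng.poisson(config.root_arch_length_mean)))
    idx = rng.integers(0, config.domain_alphabet_size, size=length)
    return tuple(_domain_name(int(i)) for i in idx)


def _evolve(
    archs: list[tuple[str, ...]],
    branch: float,
    rng: np.random.Generator,
    config: SimulationConfig,
    log_entry: dict,
) -> list[tuple[str, ...]]:
    p_loss = min(1.0, config.loss_rate * branch)
    p_dup = min(1.0, config.duplication_rate * branch)
    p_shuf = min(1.0, config.shuffle_rate * branch)
    p_gain = min(1.0, config.gain_rate * branch)
    out: list[tuple[str, ...]] = []
    for arch in archs:
        if rng.random() < p_loss:
            log_entry["loss"] += 1
            continue
        if rng.random() < p_shuf:
            log_entry["shuffle"] += 1
            if len(arch) > 1:
                arch = tuple(arch[i] for i in rng.permutation(len(arch)))
            else:
                arch = (_domain_name(int(rng.integers(0, config.domain_alphabet_size))),)
        out.append(arch)
        if rng.random() < p_dup:
            log_entry["duplication"] += 1
            out.append(arch)
    n_gains = int(rng.binomial(len(archs), p_gain)) if archs else 0
    for _ in range(n_gains):
        log_entry["gain"] += 1
        out.append(_random_architecture(rng, config))
    return out


def simulate_domainomes(
    config: SimulationConfig,
) -> tuple[dict[str, list[ProteinArchitecture]], GroundTruth]:
    """Simulate per-species architecture lists on a two-level clade tree.

    Returns a map species_id → architectures plus the ground truth
    (species → taxon labels, the tree and a per-branch event log).
    Byte-identical outputs for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    root = [_random_architecture(rng, config) for _ in range(config.root_n_proteins)]
    species: dict[str, list[ProteinArchitecture]] = {}
    labels: dict[str, str] = {}
    tree: dict[str, list[str]] = {}
    event_log: list[dict] = []
    for ti in range(config.n_taxa):
        taxon = f"phylum_{ti + 1:02d}"
        entry = {"branch": f"root->{taxon}", "loss": 0, "duplication": 0, "shuffle": 0, "gain": 0}
        ancestor = _evolve(root, config.between_taxon_branch, rng, config, entry)
        event_log.append(entry)
        tree[taxon] = []
        for si in range(config.species_per_taxon):
            sid = f"T{ti + 1:02d}S{si + 1:02d}"
            entry = {"branch": f"{taxon}->{sid}", "loss": 0, "duplication": 0, "shuffle": 0, "gain": 0}
            leaf = _evolve(ancestor, config.within_taxon_branch, rng, config, entry)
            event_log.append(entry)
            species[sid] = [
                ProteinArchitecture(protein_id=f"{sid}_p{i:04d}", domains=arch)
                for i, arch in enumerate(leaf)
            ]
            labels[sid] = taxon
            tree[taxon].append(sid)
    return species, GroundTruth(labels=labels, tree=tree, event_log=event_log)


def _hit_rows(
    arch: ProteinArchitecture, include_overlap_decoys: bool
) -> list[str]:
    """Synthesize pfam_scan rows for one protein: non-overlapping 80-residue
    domains laid left to right with 10-residue gaps."""
    rows = []
    start = 1
    for k, acc in enumerate(arch.domains):
        end = start + 79
        score = 100.0 + k  # arbitrary positive bit scores
        rows.append(
            f"{arch.protein_id} {start} {end} {start} {end} {acc}.1 {acc} "
            f"Domain 1 80 80 {score:.1f} 1e-10 1 No_clan"
        )
        if include_overlap_decoys and k == 0:
            # a strictly lower-scoring hit overlapping the first domain;
            # overlap resolution must discard it
            rows.append(
                f"{arch.protein_id} {start + 10} {end + 10} {start + 10} {end + 10} "
                f"PF99999.1 PF99999 Domain 1 80 80 {score - 50.0:.1f} 1e-5 1 No_clan"
            )
        start = end + 11
    return rows


def write_fixture(
    species: dict[str, list[ProteinArchitecture]],
    truth: GroundTruth,
    directory: str | Path,
    include_overlap_decoys: bool = False,
) -> dict[str, Path]:
    """Write a simulation as an on-disk fixture.

    Emits one pfam_scan-dialect hit file per species (``<id>.pfam``),
    a taxonomy table (``taxonomy.tsv``) and a quality table
    (``quality.tsv``) whose records straddle the 95 quality threshold:
    the first species scores 94 (removed at the default threshold), the
    second exactly 95, all others 100. Returns the paths written.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for sid, archs in species.items():
        rows = [_FIXTURE_HEADER]
        for arch in archs:
            rows.extend(_hit_rows(arch, include_overlap_decoys))
        path = directory / f"{sid}.pfam"
        path.write_text("\n".join(rows) + "\n")
        paths[sid] = path

    tax_lines = ["\t".join(["species_id", "phylum", "class", "order", "family", "genus", "species"])]
    for sid in species:
        taxon = truth.labels[sid]
        tax_lines.append("\t".join([sid, taxon, "", "", "", f"genus_{taxon}", sid]))
    tax_path = directory / "taxonomy.tsv"
    tax_path.write_text("\n".join(tax_lines) + "\n")
    paths["taxonomy"] = tax_path

    qual_lines = ["\t".join(["species_id", "completeness", "contamination"])]
    for i, sid in enumerate(species):
        if i == 0:
            completeness, contamination = 99.0, 1.0  # quality 94: removed
        elif i == 1:
            completeness, contamination = 100.0, 1.0  # quality 95: kept
        else:
            completeness, contamination = 100.0, 0.0
        qual_lines.append(f"{sid}\t{completeness:.1f}\t{contamination:.1f}")
    qual_path = directory / "quality.tsv"
    qual_path.write_text("\n".join(qual_lines) + "\n")
    paths["quality"] = qual_path
    return paths
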