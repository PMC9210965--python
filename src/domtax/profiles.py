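"""Step 1 — per-species domain profiles under four statistical models.

Overlapping hits on a protein are resolved greedily by bit score (the hit
with the maximal score wins any shared residue), surviving hits are ordered
N-to-C into a *domain architecture* per protein, and a species profile is
built under one of four models:

``content``
    the set of distinct domain accessions present anywhere in the species;
``f_content``
    accession → number of occurrences (every instance counts, including
    repeats within one protein);
``organization``
    the set of distinct architectures (accessions joined with ``|``,
    order and within-protein repeats significant);
``f_organization``
    architecture → number of proteins bearing it.

The quality filter implements quality = completeness − 5 × contamination,
removing assemblies strictly below the threshold (default 95).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from domtax.io import DomainHit, QualityRecord

#: The four statistical models, in canonical order.
STATISTICAL_MODELS = ("content", "organization", "f_content", "f_organization")

#: Separator joining accessions into an architecture key.
ARCH_SEP = "|"


@dataclass(frozen=True)
class ProteinArchitecture:
    """The N-to-C ordered domain sequence of one protein."""

    protein_id: str
    domains: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.domains:
            raise ValueError("architecture must contain at least one domain")

    @property
    def key(self) -> str:
        """Canonical architecture string, e.g. ``PF00001|PF00002``."""
        return ARCH_SEP.join(self.domains)


@dataclass(frozen=True)
class SpeciesProfile:
    """A species' domainome under one statistical model.

    ``items`` is a frozenset of keys for the set models and a mapping
    key → positive count for the frequency models. A species with zero
    surviving hits is retained with an empty profile and flagged.
    """

    species_id: str
    model: str
    items: frozenset[str] | Mapping[str, int]

    def __post_init__(self) -> None:
        if self.model not in STATISTICAL_MODELS:
            raise ValueError(
                f"unknown model {self.model!r}; expected one of {STATISTICAL_MODELS}"
            )
        if isinstance(self.items, Mapping) and any(c < 1 for c in self.items.values()):
            raise ValueError("frequency-model counts must be >= 1")

    @property
    def is_empty(self) -> bool:
        return len(self.items) == 0

    @property
    def size(self) -> int:
        """Profile magnitude: set cardinality, or total count for
        frequency models."""
        if isinstance(self.items, Mapping):
            return sum(self.items.values())
        return len(self.items)


@dataclass(frozen=True)
class QualityDecision:
    species_id: str
    quality: float
    kept: bool


def resolve_overlaps(hits: Sequence[DomainHit]) -> list[DomainHit]:
    """Resolve overlapping hits on one protein by maximal bit score.

    Greedy selection in descending bit-score order: a hit is kept iff its
    alignment interval shares no residue with any already-kept hit.
    Overlap means any shared position (>= 1 residue). Score ties break by
    lexicographically smaller accession, then smaller ali_start, so the
    result is deterministic and independent of input order. The survivors
    are returned sorted by ali_start.
    """
    if not hits:
        return []
    protein_ids = {h.protein_id for h in hits}
    if len(protein_ids) > 1:
        raise ValueError(f"hits span multiple proteins: {sorted(protein_ids)}")
    ranked = sorted(
        hits,
        key=lambda h: (-h.bit_score, h.domain_acc, h.ali_start, h.ali_end, h.domain_name),
    )
    kept: list[DomainHit] = []
    for hit in ranked:
        if all(hit.ali_end < k.ali_start or hit.ali_start > k.ali_end for k in kept):
            kept.append(hit)
    kept.sort(key=lambda h: h.ali_start)
    return kept


def build_architectures(hits: Iterable[DomainHit]) -> list[ProteinArchitecture]:
    """Group hits by protein, resolve overlaps, and order each group by
    ali_start into one architecture per protein with >= 1 surviving hit.

    Architectures are returned in order of first appearance of each
    protein in the input.
    """
    by_protein: dict[str, list[DomainHit]] = {}
    for hit in hits:
        by_protein.setdefault(hit.protein_id, []).append(hit)
    archs = []
    for protein_id, protein_hits in by_protein.items():
        resolved = resolve_overlaps(protein_hits)
        if resolved:
            archs.append(
                ProteinArchitecture(
                    protein_id=protein_id,
                    domains=tuple(h.domain_acc for h in resolved),
                )
            )
    return archs


def build_profile(
    architectures: Sequence[ProteinArchitecture],
    model: str,
    species_id: str = "",
) -> SpeciesProfile:
    """Build a species profile from its architectures under one model."""
    if model not in STATISTICAL_MODELS:
        raise ValueError(
            f"unknown model {model!r}; expected one of {STATISTICAL_MODELS}"
        )
    if model == "content":
        items: frozenset[str] | dict[str, int] = frozenset(
            d for a in architectures for d in a.domains
        )
    elif model == "f_content":
        items = dict(Counter(d for a in architectures for d in a.domains))
    elif model == "organization":
        items = frozenset(a.key for a in architectures)
    else:  # f_organization
        items = dict(Counter(a.key for a in architectures))
    return SpeciesProfile(species_id=species_id, model=model, items=items)


def write_profiles_tsv(profiles: Sequence[SpeciesProfile], path) -> None:
    """Serialize profiles as TSV: species_id, model, key, count.

    Set-model entries are written with count 1 and read back as sets.
    """
    from pathlib import Path

    lines = ["species_id\tmodel\tkey\tcount"]
    for p in profiles:
        if isinstance(p.items, Mapping):
            pairs = sorted(p.items.items())
        else:
            pairs = [(k, 1) for k in sorted(p.items)]
        for key, count in pairs:
            lines.append(f"{p.species_id}\t{p.model}\t{key}\t{count}")
        if not pairs:  # empty profile kept, flagged by a sentinel row
            lines.append(f"{p.species_id}\t{p.model}\t\t0")
    Path(path).write_text("\n".join(lines) + "\n")


def read_profiles_tsv(path) -> list[SpeciesProfile]:
    """Read profiles written by :func:`write_profiles_tsv`."""
    from pathlib import Path

    grouped: dict[tuple[str, str], dict[str, int]] = {}
    lines = Path(path).read_text().splitlines()
    for line in lines[1:]:
        if not line.strip():
            continue
        sid, model, key, count = line.split("\t")
        grouped.setdefault((sid, model), {})
        if int(count) > 0:
            grouped[(sid, model)][key] = int(count)
    profiles = []
    for (sid, model), items in grouped.items():
        if model in ("content", "organization"):
            profiles.append(SpeciesProfile(sid, model, frozenset(items)))
        else:
            profiles.append(SpeciesProfile(sid, model, items))
    return profiles


def quality_score(completeness: float, contamination: float) -> float:
    """Assembly quality on a percent scale: completeness − 5 × contamination.

    May be negative for heavily contaminated assemblies.
    """
    if not 0.0 <= completeness <= 100.0:
        raise ValueError(f"completeness must be in [0, 100], got {completeness}")
    if contamination < 0.0:
        raise ValueError(f"contamination must be >= 0, got {contamination}")
    return completeness - 5.0 * contamination


def filter_by_quality(
    records: Sequence[QualityRecord], threshold: float = 95.0
) -> list[QualityDecision]:
    """Flag each assembly: kept iff quality >= threshold.

    Only assemblies strictly under the threshold are removed, so a quality
    of exactly 95 is kept at the default threshold. Input order is
    preserved.
    """
    decisions = []
    for rec in records:
        q = quality_score(rec.completeness, rec.contamination)
        decisions.append(
            QualityDecision(species_id=rec.species_id, quality=q, kept=q >= threshold)
        )
    return decisions
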