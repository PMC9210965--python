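"""Readers and writers for every external format the framework touches.

Inputs: pfam_scan-style domain-hit tables, taxonomy tables and CheckM-style
quality summaries. Outputs: square distance matrices (TSV / PHYLIP),
Cytoscape-importable JSON edge lists, and taxon cluster reports.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping

if TYPE_CHECKING:  # avoid import cycle; only needed for annotations
    from domtax.distances import DistanceMatrix
    from domtax.mst import MSTree, TaxonClusterReport

logger = logging.getLogger(__name__)

#: Taxonomic ranks recognised in taxonomy tables, highest to lowest.
RANKS = ("superkingdom", "phylum", "class", "order", "family", "genus", "species")

#: Ranks required in a taxonomy table header (superkingdom is optional).
REQUIRED_RANKS = ("phylum", "class", "order", "family", "genus", "species")


class ParseError(ValueError):
    """A malformed row in an input table; the message names the line."""


@dataclass(frozen=True)
class DomainHit:
    """One Pfam match on one protein.

    Coordinates are 1-based inclusive alignment bounds, the conservative
    extent of the match. Accessions are version-stripped
    (``PF00005.27`` → ``PF00005``) so profile identity does not depend on
    Pfam release minor versions.
    """

    protein_id: str
    domain_acc: str
    domain_name: str
    ali_start: int
    ali_end: int
    bit_score: float
    e_value: float | None = None

    def __post_init__(self) -> None:
        if self.ali_start < 1:
            raise ValueError(f"ali_start must be >= 1, got {self.ali_start}")
        if self.ali_end < self.ali_start:
            raise ValueError(
                f"ali_end ({self.ali_end}) < ali_start ({self.ali_start})"
            )
        if not math.isfinite(self.bit_score):
            raise ValueError(f"bit_score must be finite, got {self.bit_score}")


@dataclass(frozen=True)
class TaxonomyRecord:
    """Ranked lineage of one species/assembly (GCF accession in real use)."""

    species_id: str
    lineage: Mapping[str, str] = field(default_factory=dict)

    def rank(self, rank: str) -> str | None:
        return self.lineage.get(rank)


@dataclass(frozen=True)
class QualityRecord:
    """CheckM-style assembly quality estimates, both on a percent scale."""

    species_id: str
    completeness: float
    contamination: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.completeness <= 100.0:
            raise ValueError(f"completeness must be in [0, 100], got {self.completeness}")
        if self.contamination < 0.0:
            raise ValueError(f"contamination must be >= 0, got {self.contamination}")


def strip_accession_version(acc: str) -> str:
    """Drop the Pfam version suffix: ``PF00005.27`` → ``PF00005``."""
    return acc.split(".", 1)[0]


# pfam_scan.pl output columns (15, whitespace- or comma-delimited):
# seq id, ali start, ali end, env start, env end, hmm acc, hmm name, type,
# hmm start, hmm end, hmm length, bit score, E-value, significance, clan
_PFAM_SCAN_NCOL = 15


def _parse_pfam_scan_row(fields: list[str], lineno: int) -> DomainHit:
    if len(fields) < _PFAM_SCAN_NCOL:
        raise ParseError(
            f"line {lineno}: expected {_PFAM_SCAN_NCOL} pfam_scan columns, got {len(fields)}"
        )
    try:
        return DomainHit(
            protein_id=fields[0],
            domain_acc=strip_accession_version(fields[5]),
            domain_name=fields[6],
            ali_start=int(fields[1]),
            ali_end=int(fields[2]),
            bit_score=float(fields[11]),
            e_value=float(fields[12]),
        )
    except ParseError:
        raise
    except ValueError as exc:
        raise ParseError(f"line {lineno}: {exc}") from exc


def _parse_tsv_row(fields: list[str], header: list[str], lineno: int) -> DomainHit:
    if len(fields) != len(header):
        raise ParseError(
            f"line {lineno}: expected {len(header)} columns, got {len(fields)}"
        )
    row = dict(zip(header, fields))
    try:
        return DomainHit(
            protein_id=row["protein_id"],
            domain_acc=strip_accession_version(row["domain_acc"]),
            domain_name=row.get("domain_name", row["domain_acc"]),
            ali_start=int(row["ali_start"]),
            ali_end=int(row["ali_end"]),
            bit_score=float(row["bit_score"]),
            e_value=float(row["e_value"]) if "e_value" in row else None,
        )
    except KeyError as exc:
        raise ParseError(f"line {lineno}: missing column {exc}") from exc
    except ValueError as exc:
        raise ParseError(f"line {lineno}: {exc}") from exc


def read_domain_hits(path: str | Path, dialect: str = "pfam_scan") -> list[DomainHit]:
    """Read a domain-hit table, preserving file row order.

    Parameters
    ----------
    path
        Hit table. Lines starting with ``#`` and blank lines are skipped.
    dialect
        ``pfam_scan`` — the 15-column pfam_scan.pl layout, whitespace- or
        comma-delimited (the delimiter is sniffed from the first data
        line); ``tsv`` — a simplified tab-separated table with a header
        row naming at least protein_id, domain_acc, ali_start, ali_end
        and bit_score.

    Raises
    ------
    ParseError
        On any malformed data row, naming the 1-based line number. No row
        is ever silently dropped.
    """
    if dialect not in ("pfam_scan", "tsv"):
        raise ValueError(f"unknown dialect {dialect!r}; expected 'pfam_scan' or 'tsv'")
    path = Path(path)
    hits: list[DomainHit] = []
    header: list[str] | None = None
    delimiter: str | None = None
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if dialect == "tsv":
                fields = line.split("\t")
                if header is None:
                    header = fields
                    continue
                hits.append(_parse_tsv_row(fields, header, lineno))
            else:
                if delimiter is None:
                    # pfam_scan.pl writes whitespace-delimited tables by
                    # default but csv exports exist too; sniff once.
                    delimiter = "," if len(line.split(",")) >= _PFAM_SCAN_NCOL else "ws"
                fields = (
                    [f.strip() for f in line.split(",")]
                    if delimiter == ","
                    else line.split()
                )
                hits.append(_parse_pfam_scan_row(fields, lineno))
    if not hits:
        logger.warning("no data rows in %s", path)
    return hits


def read_taxonomy(path: str | Path) -> dict[str, TaxonomyRecord]:
    """Read a tab-separated taxonomy table into species_id → record.

    The header must contain ``species_id`` and ``phylum``; the other ranks
    are optional and empty cells are allowed (the rank is then absent from
    the lineage). Duplicate species IDs are an error.
    """
    path = Path(path)
    records: dict[str, TaxonomyRecord] = {}
    with path.open() as fh:
        header_line = fh.readline()
        if not header_line:
            raise ParseError(f"{path}: empty taxonomy table")
        header = [h.strip() for h in header_line.rstrip("\n").split("\t")]
        if "species_id" not in header or "phylum" not in header:
            raise ParseError(
                f"{path}: taxonomy header must include 'species_id' and 'phylum', got {header}"
            )
        rank_cols = [r for r in RANKS if r in header]
        for lineno, raw in enumerate(fh, start=2):
            if not raw.strip():
                continue
            fields = raw.rstrip("\n").split("\t")
            row = dict(zip(header, fields))
            sid = row.get("species_id", "").strip()
            if not sid:
                raise ParseError(f"line {lineno}: empty species_id")
            if sid in records:
                raise ParseError(f"line {lineno}: duplicate species_id {sid!r}")
            lineage = {r: row[r].strip() for r in rank_cols if row.get(r, "").strip()}
            records[sid] = TaxonomyRecord(species_id=sid, lineage=lineage)
    return records


def read_quality(path: str | Path) -> list[QualityRecord]:
    """Read a CheckM-style summary: species_id, completeness, contamination."""
    path = Path(path)
    records: list[QualityRecord] = []
    with path.open() as fh:
        header = [h.strip() for h in fh.readline().rstrip("\n").split("\t")]
        for col in ("species_id", "completeness", "contamination"):
            if col not in header:
                raise ParseError(f"{path}: quality header missing {col!r}")
        for lineno, raw in enumerate(fh, start=2):
            if not raw.strip():
                continue
            row = dict(zip(header, raw.rstrip("\n").split("\t")))
            try:
                records.append(
                    QualityRecord(
                        species_id=row["species_id"].strip(),
                        completeness=float(row["completeness"]),
                        contamination=float(row["contamination"]),
                    )
                )
            except ValueError as exc:
                raise ParseError(f"line {lineno}: {exc}") from exc
    return records


def write_edge_list_json(
    tree: "MSTree",
    taxonomy: Mapping[str, TaxonomyRecord],
    path: str | Path,
) -> None:
    """Write an MST as a JSON document a network viewer (e.g. Cytoscape)
    can import: nodes carry their lineage as attributes for automatic
    coloring, edges carry the distance as weight."""
    nodes = []
    for sid in tree.species_ids:
        rec = taxonomy.get(sid)
        if rec is None:
            logger.warning("node %s missing from taxonomy; emitting empty lineage", sid)
            lineage: dict[str, str] = {}
        else:
            lineage = dict(rec.lineage)
        nodes.append({"id": sid, **lineage})
    edges = [
        {"source": u, "target": v, "weight": float(w)} for u, v, w in tree.edges
    ]
    doc = {"nodes": nodes, "edges": edges}
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


def read_edge_list_json(path: str | Path) -> "MSTree":
    """Read a JSON edge list back into an MSTree (inverse of the writer)."""
    from domtax.mst import MSTree

    doc = json.loads(Path(path).read_text())
    species_ids = [n["id"] for n in doc["nodes"]]
    edges = [(e["source"], e["target"], float(e["weight"])) for e in doc["edges"]]
    return MSTree(species_ids=species_ids, edges=edges)


def write_distance_matrix(
    matrix: "DistanceMatrix", path: str | Path, format: str = "square_tsv"
) -> None:
    """Write a symmetric distance matrix.

    ``square_tsv`` — header row and column of species IDs, values to six
    decimal places. ``phylip_square`` — standard square PHYLIP distance
    format (species count on the first line).
    """
    ids = matrix.species_ids
    values = matrix.values
    lines: list[str] = []
    if format == "square_tsv":
        lines.append("\t".join(["species_id", *ids]))
        for i, sid in enumerate(ids):
            lines.append("\t".join([sid, *(f"{values[i, j]:.6f}" for j in range(len(ids)))]))
    elif format == "phylip_square":
        lines.append(f"{len(ids)}")
        for i, sid in enumerate(ids):
            row = " ".join(f"{values[i, j]:.6f}" for j in range(len(ids)))
            lines.append(f"{sid:<10s} {row}")
    else:
        raise ValueError(f"unknown format {format!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_distance_matrix(path: str | Path) -> "DistanceMatrix":
    """Read a matrix written by :func:`write_distance_matrix`.

    The format is sniffed: a lone integer on the first line means PHYLIP,
    otherwise the square TSV layout is assumed.
    """
    import numpy as np

    from domtax.distances import DistanceMatrix

    text = Path(path).read_text().strip().splitlines()
    first = text[0].strip()
    if first.isdigit():  # PHYLIP
        n = int(first)
        ids, rows = [], []
        for line in text[1 : n + 1]:
            parts = line.split()
            ids.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
    else:  # square TSV
        ids_header = first.split("\t")[1:]
        ids, rows = [], []
        for line in text[1:]:
            parts = line.split("\t")
            ids.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
        if ids != ids_header:
            raise ParseError(f"{path}: row and column species IDs disagree")
    return DistanceMatrix(
        species_ids=ids,
        values=np.asarray(rows, dtype=float),
        statistical_model="unknown",
        distance_model="unknown",
    )


#: Fixed column order of the per-taxon cluster report TSV.
CLUSTER_REPORT_COLUMNS = ("taxon", "T", "S", "n_groups", "group_sizes")


def write_cluster_report(report: "TaxonClusterReport", path: str | Path) -> None:
    """Write the per-taxon cluster report as TSV plus a JSON metrics block.

    Columns (fixed order): taxon, T (total species), S (isolated species),
    n_groups, group_sizes (descending, comma-joined). A sibling
    ``<path>.metrics.json`` holds the three agreement metrics.
    """
    lines = ["\t".join(CLUSTER_REPORT_COLUMNS)]
    for entry in report.entries:
        lines.append(
            "\t".join(
                [
                    entry["taxon"],
                    str(entry["T"]),
                    str(entry["S"]),
                    str(len(entry["group_sizes"])),
                    ",".join(str(s) for s in entry["group_sizes"]),
                ]
            )
        )
    path = Path(path)
    path.write_text("\n".join(lines) + "\n")
    metrics_path = path.with_suffix(path.suffix + ".metrics.json")
    metrics_path.write_text(json.dumps(report.metrics, indent=1) + "\n")
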