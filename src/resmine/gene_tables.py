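"""Domain types and CSV I/O for gene-coordinate tables.

The tool consumes two tables exported from an annotated genome portal
(MycoCosm-style): one listing homologs of the candidate resistance gene
(the set R) and one listing core secondary-metabolite biosynthetic genes
(NRPS, PKS, terpene synthase/cyclase, DMATS — the set S).  Each row is one
gene: the genome it belongs to, its scaffold, and its coordinates as a
1-based fully-closed interval, optionally with the E-value and percent
identity of the BLAST search that produced the table.

Coordinates are 1-based inclusive throughout, so a gene occupying a single
base has length 1.  Gene centers are handled as doubled integers
(start + stop = twice the midpoint) so that half-integer midpoints never
force floating-point arithmetic into the distance predicate.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, replace

__all__ = [
    "Role",
    "GeneRecord",
    "GeneTable",
    "GeneTableError",
    "RowError",
    "read_gene_table",
    "write_gene_table",
    "center_times_two",
    "gene_length",
    "overlaps",
    "CANONICAL_HEADER",
]


class GeneTableError(ValueError):
    """A table cannot be read or fails table-level validation."""


class RowError(GeneTableError):
    """A data row fails to parse or validate; carries its 1-based line number."""

    def __init__(self, line_number: int, message: str):
        self.line_number = line_number
        super().__init__(f"line {line_number}: {message}")


class Role(enum.Enum):
    """Which of the two input sets a table holds."""

    RESISTANCE = "resistance"
    SM_CORE = "sm_core"


@dataclass(frozen=True)
class GeneRecord:
    """One annotated gene.

    Parameters
    ----------
    organism : str
        Genome/portal identifier (opaque; e.g. a MycoCosm portal name).
    gene_id : str
        Gene or protein identifier (opaque).
    scaffold : str
        Scaffold/contig identifier, matched by exact string equality.
    start, stop : int
        1-based inclusive genomic coordinates, ``1 <= start <= stop``.
    evalue : float, optional
        Search E-value of the homolog, >= 0.
    pct_identity : float, optional
        Percent identity of the homolog, in [0, 100].
    description : str, optional
        Free-text annotation.
    """

    organism: str
    gene_id: str
    scaffold: str
    start: int
    stop: int
    evalue: float | None = None
    pct_identity: float | None = None
    description: str | None = None

    def __post_init__(self) -> None:
        for name in ("organism", "gene_id", "scaffold"):
            value = getattr(self, name)
            if not isinstance(value, str) or not value.strip():
                raise ValueError(f"{name} must be a non-empty string")
            object.__setattr__(self, name, value.strip())
        if not (1 <= self.start <= self.stop):
            raise ValueError(
                f"require 1 <= start <= stop, got start={self.start} stop={self.stop}"
            )
        if self.evalue is not None and not self.evalue >= 0:
            raise ValueError(f"evalue must be >= 0, got {self.evalue}")
        if self.pct_identity is not None and not 0 <= self.pct_identity <= 100:
            raise ValueError(
                f"pct_identity must be in [0, 100], got {self.pct_identity}"
            )

    @property
    def key(self) -> tuple[str, str, str, int, int]:
        """Identity tuple used for deduplication."""
        return (self.organism, self.gene_id, self.scaffold, self.start, self.stop)


def center_times_two(g: GeneRecord) -> int:
    """Twice the interval midpoint of ``g``, an exact integer (start + stop)."""
    return g.start + g.stop


def gene_length(g: GeneRecord) -> int:
    """Length of ``g`` in base pairs under the 1-based inclusive convention."""
    return g.stop - g.start + 1


def overlaps(a: GeneRecord, b: GeneRecord) -> bool:
    """True iff ``a`` and ``b`` share at least one base on the same scaffold
    of the same genome (closed-interval intersection)."""
    return (
        a.organism == b.organism
        and a.scaffold == b.scaffold
        and a.start <= b.stop
        and b.start <= a.stop
    )


@dataclass(frozen=True)
class GeneTable:
    """A role-tagged, deduplicated, order-preserving collection of genes.

    Records identical in (organism, gene_id, scaffold, start, stop) are
    collapsed to the first occurrence at construction time.
    """

    role: Role
    records: tuple[GeneRecord, ...]
    source: str = "unknown"
    backbone_class: str | None = None

    def __post_init__(self) -> None:
        seen: dict[tuple, GeneRecord] = {}
        for rec in self.records:
            seen.setdefault(rec.key, rec)
        object.__setattr__(self, "records", tuple(seen.values()))

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def organisms(self) -> set[str]:
        return {rec.organism for rec in self.records}

    def with_records(self, records) -> "GeneTable":
        return replace(self, records=tuple(records))


# Header aliases, matched case-insensitively after stripping whitespace.
# Portals vary in their export headers; an explicit alias table keeps the
# inference testable.  Two distinct file columns resolving to one field is
# an error rather than a silent pick.
_ALIASES: dict[str, tuple[str, ...]] = {
    "organism": ("organism", "portal", "genome", "species"),
    "gene_id": ("gene_id", "geneid", "proteinid", "protein id", "id", "name"),
    "scaffold": ("scaffold", "contig", "chromosome", "chr"),
    "start": ("start", "gene start", "begin"),
    "stop": ("stop", "end", "gene stop"),
    "evalue": ("evalue", "e-value", "e value"),
    "pct_identity": ("pct_identity", "percent identity", "identity", "% identity"),
    "description": ("description", "desc", "annotation"),
}
_REQUIRED = ("organism", "gene_id", "scaffold", "start", "stop")

CANONICAL_HEADER = (
    "organism",
    "gene_id",
    "scaffold",
    "start",
    "stop",
    "evalue",
    "pct_identity",
    "description",
)


def _map_header(header: list[str]) -> dict[str, int]:
    """Resolve raw header cells to canonical field names -> column index."""
    alias_lookup = {
        alias: canon for canon, aliases in _ALIASES.items() for alias in aliases
    }
    mapping: dict[str, int] = {}
    for idx, raw in enumerate(header):
        canon = alias_lookup.get(raw.strip().lower())
        if canon is None:
            continue  # unrecognised columns are carried past, not errors
        if canon in mapping:
            raise GeneTableError(
                f"ambiguous header: columns {header[mapping[canon]]!r} and "
                f"{raw!r} both map to field {canon!r}"
            )
        mapping[canon] = idx
    missing = [name for name in _REQUIRED if name not in mapping]
    if missing:
        raise GeneTableError(
            "unreadable table: missing required column(s) "
            + ", ".join(repr(m) for m in missing)
        )
    return mapping


def _parse_int(cell: str, field_name: str, line_number: int) -> int:
    try:
        return int(cell.strip())
    except ValueError:
        raise RowError(
            line_number, f"non-numeric {field_name}: {cell!r}"
        ) from None


def _parse_optional_float(
    cell: str | None, field_name: str, line_number: int
) -> float | None:
    if cell is None or not cell.strip():
        return None
    try:
        return float(cell.strip())
    except ValueError:
        raise RowError(line_number, f"non-numeric {field_name}: {cell!r}") from None


def read_gene_table(path, role: Role, backbone_class: str | None = None) -> GeneTable:
    """Read a comma-separated gene-coordinate table.

    The first row must be a header; column names are matched
    case-insensitively against common portal-export aliases (``portal`` ->
    organism, ``proteinId`` -> gene_id, ``end`` -> stop, ...).  Rows
    identical in all mapped fields are collapsed; first-occurrence order is
    preserved.  Scientific notation is accepted for E-values.

    Raises
    ------
    GeneTableError
        If a required column is missing or two columns map to one field.
    RowError
        If a data row has a non-numeric coordinate or start > stop; the
        error names the 1-based file line.
    """
    role = Role(role)
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise GeneTableError(f"empty file: {path}") from None
        mapping = _map_header(header)
        records: list[GeneRecord] = []
        for line_number, row in enumerate(reader, start=2):
            if not any(cell.strip() for cell in row):
                continue  # blank line

            def cell(name: str) -> str | None:
                idx = mapping.get(name)
                if idx is None or idx >= len(row):
                    return None
                return row[idx]

            start = _parse_int(cell("start") or "", "start", line_number)
            stop = _parse_int(cell("stop") or "", "stop", line_number)
            if start > stop:
                raise RowError(line_number, f"start > stop ({start} > {stop})")
            try:
                rec = GeneRecord(
                    organism=(cell("organism") or ""),
                    gene_id=(cell("gene_id") or ""),
                    scaffold=(cell("scaffold") or ""),
                    start=start,
                    stop=stop,
                    evalue=_parse_optional_float(cell("evalue"), "evalue", line_number),
                    pct_identity=_parse_optional_float(
                        cell("pct_identity"), "pct_identity", line_number
                    ),
                    description=(cell("description") or None),
                )
            except ValueError as exc:
                raise RowError(line_number, str(exc)) from None
            records.append(rec)
    return GeneTable(
        role=role,
        records=tuple(records),
        source=str(path),
        backbone_class=backbone_class,
    )


def _format_float(x: float | None) -> str:
    if x is None:
        return ""
    return repr(x) if isinstance(x, float) else str(x)


def write_gene_table(table: GeneTable, path) -> None:
    """Write ``table`` as canonical CSV (header: organism,gene_id,scaffold,
    start,stop,evalue,pct_identity,description; unset optionals as empty
    cells).  Reading the file back reproduces the mapped fields."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(CANONICAL_HEADER)
        for rec in table.records:
            writer.writerow(
                [
                    rec.organism,
                    rec.gene_id,
                    rec.scaffold,
                    rec.start,
                    rec.stop,
                    _format_float(rec.evalue),
                    _format_float(rec.pct_identity),
                    rec.description or "",
                ]
            )
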