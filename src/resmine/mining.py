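"""The core resistance-gene-guided mining algorithm.

Self-resistance in fungal secondary metabolism often works by gene
duplication: a biosynthetic gene cluster (BGC) carries a resistant second
copy of the essential gene its product inhibits, while the susceptible
housekeeping copy sits elsewhere in the genome.  The miner exploits that
signature directly: given the set R of resistance-gene homologs and the
set S of core biosynthetic genes, a *hit* is a pair (r, s) with

1. the same genome (organism),
2. the same scaffold,
3. gene centers at most C base pairs apart,
4. non-overlapping intervals, and
5. length(r) at most M

where, by default, only genomes carrying at least two copies of the
resistance gene are considered (singleton elimination; self-resistance
requires both a housekeeping and a resistant allele).  The ``nocheck``
waiver disables that requirement.

Two implementations are provided: :func:`mine`, which indexes S by
(organism, scaffold) and binary-searches a doubled-center window, and
:func:`brute_force_mine`, the literal O(|R|·|S|) pair loop, retained
permanently as the testing oracle.  Their outputs are required (and
tested) to be element-wise identical.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from collections import Counter, defaultdict
from dataclasses import dataclass
from fractions import Fraction

from .gene_tables import (
    GeneRecord,
    GeneTable,
    Role,
    center_times_two,
    gene_length,
    overlaps,
)

__all__ = [
    "MinerConfig",
    "Hit",
    "HomologTable",
    "eliminate_singletons",
    "mine",
    "brute_force_mine",
    "collect_homologs",
    "format_distance",
]


@dataclass(frozen=True)
class MinerConfig:
    """Run parameters.

    Parameters
    ----------
    cutoff_c : int
        Maximum center-to-center distance C in base pairs (>= 1).  There is
        deliberately no default: the appropriate cutoff depends on the gene
        class mined; 70 000 bp is the documented working value for fungal
        BGCs (clusters range from ~11 kb to ~70 kb).
    max_gene_length_m : int or None
        Maximum resistance-gene length M in base pairs; ``None`` means
        unlimited (the default — spuriously long genes are rare enough that
        the filter is opt-in).
    singleton_check : bool
        If True (default), only genomes with >= 2 resistance-gene copies are
        mined.  False is the ``nocheck`` waiver.
    homolog_mode : bool
        Whether a homolog table is wanted alongside the hits.  The hit list
        itself is unaffected; see :func:`collect_homologs`.
    """

    cutoff_c: int
    max_gene_length_m: int | None = None
    singleton_check: bool = True
    homolog_mode: bool = False

    def __post_init__(self) -> None:
        if self.cutoff_c < 1:
            raise ValueError(f"cutoff_c must be >= 1, got {self.cutoff_c}")
        if self.max_gene_length_m is not None and self.max_gene_length_m < 1:
            raise ValueError(
                f"max_gene_length_m must be >= 1 or None, got {self.max_gene_length_m}"
            )


@dataclass(frozen=True)
class Hit:
    """One (resistance gene, SM core gene) pair passing all predicates.

    ``center_distance`` is exact (integer or half-integer, stored as a
    Fraction) — no floating point enters the distance computation.
    """

    resistance: GeneRecord
    sm: GeneRecord
    center_distance: Fraction

    @property
    def end_gap(self) -> int:
        """Bases strictly between the two (non-overlapping) genes; 0 if they abut."""
        if self.resistance.stop < self.sm.start:
            return self.sm.start - self.resistance.stop - 1
        return self.resistance.start - self.sm.stop - 1

    @property
    def organism(self) -> str:
        return self.resistance.organism


def format_distance(d: Fraction) -> str:
    """Render an exact center distance: integral values without a decimal
    point, half-integers with a ``.5`` suffix."""
    if d.denominator == 1:
        return str(d.numerator)
    return f"{d.numerator // 2}.5"


@dataclass(frozen=True)
class HomologTable:
    """Deduplicated set of resistance-gene records from genomes with hits,
    sorted by (organism, start, gene_id)."""

    entries: tuple[GeneRecord, ...]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)


def _require_roles(r_table: GeneTable, s_table: GeneTable) -> None:
    if r_table.role is not Role.RESISTANCE:
        raise ValueError(f"r_table must have role=resistance, got {r_table.role}")
    if s_table.role is not Role.SM_CORE:
        raise ValueError(f"s_table must have role=sm_core, got {s_table.role}")


def eliminate_singletons(r_table: GeneTable) -> GeneTable:
    """Drop every resistance gene whose genome carries only one copy.

    Copies are counted on the full deduplicated table, before any length
    filtering; record order is preserved.
    """
    if r_table.role is not Role.RESISTANCE:
        raise ValueError(f"r_table must have role=resistance, got {r_table.role}")
    counts = Counter(rec.organism for rec in r_table)
    return r_table.with_records(
        rec for rec in r_table if counts[rec.organism] >= 2
    )


_SORT_KEY = lambda h: (  # noqa: E731 — shared by both engines by construction
    h.resistance.organism,
    h.resistance.start,
    h.resistance.gene_id,
    h.sm.start,
    h.sm.gene_id,
)


def _make_hit(r: GeneRecord, s: GeneRecord) -> Hit:
    d2 = abs(center_times_two(r) - center_times_two(s))
    return Hit(resistance=r, sm=s, center_distance=Fraction(d2, 2))


def brute_force_mine(
    r_table: GeneTable, s_table: GeneTable, config: MinerConfig
) -> list[Hit]:
    """The literal quadratic pair loop: every (r, s) pair is checked against
    the five predicates with no indexing.  Retained as the oracle against
    which the indexed :func:`mine` is verified."""
    _require_roles(r_table, s_table)
    r_records = (
        eliminate_singletons(r_table).records
        if config.singleton_check
        else r_table.records
    )
    c2 = 2 * config.cutoff_c
    m = config.max_gene_length_m
    hits: list[Hit] = []
    for r in r_records:
        for s in s_table.records:
            if r.organism != s.organism:
                continue
            if r.scaffold != s.scaffold:
                continue
            if abs(center_times_two(r) - center_times_two(s)) > c2:
                continue
            if overlaps(r, s):
                continue
            if m is not None and gene_length(r) > m:
                continue
            hits.append(_make_hit(r, s))
    hits.sort(key=_SORT_KEY)
    return hits


def mine(r_table: GeneTable, s_table: GeneTable, config: MinerConfig) -> list[Hit]:
    """Indexed miner: groups S by (organism, scaffold), sorts each group by
    doubled center, and binary-searches the window
    ``[2*center(r) - 2C, 2*center(r) + 2C]`` for every resistance gene.

    Output contract is identical to :func:`brute_force_mine`: one Hit per
    qualifying pair (a resistance gene near two backbone genes yields two
    hits), sorted by (organism, resistance start, resistance gene_id,
    sm start, sm gene_id).
    """
    _require_roles(r_table, s_table)
    r_records = (
        eliminate_singletons(r_table).records
        if config.singleton_check
        else r_table.records
    )
    index: dict[tuple[str, str], list[tuple[int, GeneRecord]]] = defaultdict(list)
    for s in s_table.records:
        index[(s.organism, s.scaffold)].append((center_times_two(s), s))
    for group in index.values():
        group.sort(key=lambda pair: pair[0])
    centers = {key: [c for c, _ in group] for key, group in index.items()}

    c2 = 2 * config.cutoff_c
    m = config.max_gene_length_m
    hits: list[Hit] = []
    for r in r_records:
        if m is not None and gene_length(r) > m:
            continue
        group = index.get((r.organism, r.scaffold))
        if not group:
            continue
        rc2 = center_times_two(r)
        cs = centers[(r.organism, r.scaffold)]
        lo = bisect_left(cs, rc2 - c2)
        hi = bisect_right(cs, rc2 + c2)
        for _, s in group[lo:hi]:
            if overlaps(r, s):
                continue
            hits.append(_make_hit(r, s))
    hits.sort(key=_SORT_KEY)
    return hits


def collect_homologs(hits: list[Hit], r_table: GeneTable) -> HomologTable:
    """All resistance-gene records from every genome that produced a hit.

    ``r_table`` must be the same (post-singleton-elimination, if applied)
    table that produced ``hits``.  The hit genes themselves are included;
    duplicates are eliminated by set semantics.
    """
    organisms = {h.organism for h in hits}
    seen: dict[tuple, GeneRecord] = {}
    for rec in r_table:
        if rec.organism in organisms and rec.key not in seen:
            seen[rec.key] = rec
    entries = sorted(
        seen.values(), key=lambda rec: (rec.organism, rec.start, rec.gene_id)
    )
    return HomologTable(entries=tuple(entries))
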