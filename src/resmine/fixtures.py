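"""Seeded generator of portal-style gene tables with planted ground truth.

Real inputs to the miner are BLAST/KOG exports from an annotated fungal
genome portal; those depend on a live database snapshot and are not
reproducible offline.  This module fabricates structurally equivalent
tables — many genomes, several scaffolds each, genes as 1-based inclusive
intervals — with *planted* resistance/SM gene pairs at controlled center
distances plus labeled decoys, so that every engine property can be tested
against an exactly known truth set.

Each decoy class violates exactly one of the miner's predicates:

``singleton_near``
    one resistance copy only, within C of an SM gene (fails the two-copy
    rule; becomes a hit under the ``nocheck`` waiver).
``far_pair``
    two resistance copies, SM gene on the same scaffold but with center
    distance > C.
``overlapping_pair``
    two resistance copies, SM gene sharing bases with one of them.
``oversized_resistance``
    two resistance copies, one longer than M and within C of an SM gene.

Truth is computed *by construction* — never by running the miner — and a
construction-side geometric audit rejects any placement that would create
an unplanned qualifying pair, so planted-truth precision/recall tests are
exact.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, asdict
from fractions import Fraction

import yaml

from .gene_tables import GeneRecord, GeneTable, Role

__all__ = [
    "DecoyCounts",
    "PlantedPair",
    "FixtureSpec",
    "TruthSet",
    "GenerationError",
    "generate_fixture",
    "random_spec",
    "small_spec",
    "mycocosm_scale_spec",
    "spec_to_yaml",
    "spec_from_yaml",
]

_MAX_ATTEMPTS = 1000


class GenerationError(RuntimeError):
    """The spec cannot be realised without violating placement constraints."""


@dataclass(frozen=True)
class DecoyCounts:
    singleton_near: int = 0
    far_pair: int = 0
    overlapping_pair: int = 0
    oversized_resistance: int = 0

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if value < 0:
                raise ValueError(f"decoy count {name} must be >= 0, got {value}")


@dataclass(frozen=True)
class PlantedPair:
    """A resistance/SM gene pair planted at a known center distance.

    Intervals are 1-based inclusive ``(start, stop)`` tuples and must be
    disjoint.  ``n_extra_resistance_copies`` >= 1 extra copies are placed on
    other scaffolds of the same genome so the two-copy rule is satisfiable.
    """

    genome: int
    scaffold: int
    resistance: tuple[int, int]
    sm: tuple[int, int]
    n_extra_resistance_copies: int = 1

    def __post_init__(self) -> None:
        for name in ("resistance", "sm"):
            start, stop = getattr(self, name)
            if not 1 <= start <= stop:
                raise ValueError(f"{name} interval invalid: ({start}, {stop})")
        r, s = self.resistance, self.sm
        if r[0] <= s[1] and s[0] <= r[1]:
            raise ValueError("planted resistance and sm intervals must be disjoint")
        if self.n_extra_resistance_copies < 1:
            raise ValueError("n_extra_resistance_copies must be >= 1")

    @property
    def center_distance(self) -> Fraction:
        """Exact center-to-center distance implied by the placed intervals."""
        r, s = self.resistance, self.sm
        return Fraction(abs((r[0] + r[1]) - (s[0] + s[1])), 2)

    @property
    def resistance_length(self) -> int:
        return self.resistance[1] - self.resistance[0] + 1


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic genome set.

    ``cutoff_c`` and ``max_gene_length_m`` state the (C, M) at which the
    truth set is defined: a planted pair is an expected hit iff its center
    distance is <= C and its resistance gene is <= M long.
    """

    n_genomes: int
    scaffolds_per_genome: int
    scaffold_length: int
    n_background_sm_genes: int
    planted_pairs: tuple[PlantedPair, ...]
    decoys: DecoyCounts = field(default_factory=DecoyCounts)
    gene_length_range: tuple[int, int] = (900, 8000)
    seed: int = 0
    cutoff_c: int = 70_000
    max_gene_length_m: int = 50_000

    def __post_init__(self) -> None:
        if self.n_genomes < 1 or self.scaffolds_per_genome < 1:
            raise ValueError("need at least one genome and one scaffold")
        if self.n_background_sm_genes < 0:
            raise ValueError("n_background_sm_genes must be >= 0")
        lo, hi = self.gene_length_range
        if not 1 <= lo <= hi:
            raise ValueError(f"bad gene_length_range: {self.gene_length_range}")
        if hi > self.max_gene_length_m:
            raise ValueError(
                "gene_length_range max exceeds max_gene_length_m; ordinary genes "
                "would trip the length filter"
            )
        if self.cutoff_c < 1:
            raise ValueError("cutoff_c must be >= 1")
        object.__setattr__(self, "planted_pairs", tuple(self.planted_pairs))
        claimed: set[tuple[int, int]] = set()
        for pair in self.planted_pairs:
            if not 0 <= pair.genome < self.n_genomes:
                raise ValueError(f"planted pair genome {pair.genome} out of range")
            if not 0 <= pair.scaffold < self.scaffolds_per_genome:
                raise ValueError(f"planted pair scaffold {pair.scaffold} out of range")
            for start, stop in (pair.resistance, pair.sm):
                if stop > self.scaffold_length:
                    raise ValueError(
                        f"planted interval ({start}, {stop}) exceeds scaffold length"
                    )
            key = (pair.genome, pair.scaffold)
            if key in claimed:
                raise ValueError(
                    f"two planted pairs share genome/scaffold {key}; each structure "
                    "needs its own scaffold to keep truth exact"
                )
            claimed.add(key)


@dataclass(frozen=True)
class TruthSet:
    """Exact expectations for a generated fixture at its stated (C, M).

    ``expected_hits`` are (resistance gene_id, sm gene_id) pairs the miner
    must report with default settings; ``singleton_hits`` additionally
    appear under the ``nocheck`` waiver.  ``labels`` maps every gene_id to
    its construction role (planted_resistance, extra_copy, background_sm,
    or a decoy class tag).
    """

    cutoff_c: int
    max_gene_length_m: int
    expected_hits: tuple[tuple[str, str], ...]
    singleton_hits: tuple[tuple[str, str], ...]
    labels: dict[str, str]


def _org(i: int) -> str:
    return f"org{i:04d}"


def _scaf(j: int) -> str:
    return f"scaf{j:02d}"


class _Builder:
    """Stateful placement helper for one generate_fixture run."""

    def __init__(self, spec: FixtureSpec):
        self.spec = spec
        self.rng = random.Random(spec.seed)
        self.r_records: list[GeneRecord] = []
        self.s_records: list[GeneRecord] = []
        self.labels: dict[str, str] = {}
        self._next_id = 0
        self.used_scaffolds: set[tuple[int, int]] = set()
        # "singleton" genomes hold exactly one resistance gene; no other
        # structure or extra copy may be placed there, or the two-copy rule
        # would silently start passing for the decoy.
        self.genome_class: dict[int, str] = {}
        # doubled centers of placed genes, per (genome idx, scaffold idx)
        self.r_centers: dict[tuple[int, int], list[int]] = {}
        self.s_centers: dict[tuple[int, int], list[int]] = {}

    def new_id(self) -> str:
        self._next_id += 1
        return f"g{self._next_id:06d}"

    def add_resistance(self, genome: int, scaffold: int, start: int, stop: int,
                       label: str) -> GeneRecord:
        rec = GeneRecord(
            organism=_org(genome),
            gene_id=self.new_id(),
            scaffold=_scaf(scaffold),
            start=start,
            stop=stop,
            evalue=10.0 ** self.rng.uniform(-180.0, -45.0),
            pct_identity=round(self.rng.uniform(35.0, 95.0), 1),
        )
        self.r_records.append(rec)
        self.labels[rec.gene_id] = label
        self.r_centers.setdefault((genome, scaffold), []).append(start + stop)
        return rec

    def add_sm(self, genome: int, scaffold: int, start: int, stop: int,
               label: str) -> GeneRecord:
        rec = GeneRecord(
            organism=_org(genome),
            gene_id=self.new_id(),
            scaffold=_scaf(scaffold),
            start=start,
            stop=stop,
        )
        self.s_records.append(rec)
        self.labels[rec.gene_id] = label
        self.s_centers.setdefault((genome, scaffold), []).append(start + stop)
        return rec

    def random_length(self) -> int:
        lo, hi = self.spec.gene_length_range
        return self.rng.randint(lo, hi)

    def claim_free_scaffold(self, exclusive_genome: bool = False) -> tuple[int, int]:
        """A free (genome, scaffold) slot.  With ``exclusive_genome`` the
        genome must be entirely unused and is reserved as singleton-only."""
        spec = self.spec
        for _ in range(_MAX_ATTEMPTS):
            g = self.rng.randrange(spec.n_genomes)
            if exclusive_genome:
                if g in self.genome_class:
                    continue
            elif self.genome_class.get(g) == "singleton":
                continue
            key = (g, self.rng.randrange(spec.scaffolds_per_genome))
            if key not in self.used_scaffolds:
                self.used_scaffolds.add(key)
                self.genome_class[g] = "singleton" if exclusive_genome else "multi"
                return key
        raise GenerationError(
            "could not find a free scaffold for a decoy structure; "
            "increase n_genomes or scaffolds_per_genome"
        )

    def place_pair(self, distance: int, len_r: int, len_s: int,
                   overlap: bool = False) -> tuple[tuple[int, int], tuple[int, int]]:
        """Coordinates for an r/s pair at an exact center distance (or an
        overlapping pair when ``overlap``), anywhere a scaffold can hold it."""
        spec = self.spec
        if overlap:
            for _ in range(_MAX_ATTEMPTS):
                r0 = self.rng.randint(1, max(1, spec.scaffold_length - len_r - len_s))
                r1 = r0 + len_r - 1
                s0 = self.rng.randint(r0, r1)  # guaranteed shared bases
                s1 = s0 + len_s - 1
                if s1 <= spec.scaffold_length:
                    return (r0, r1), (s0, s1)
            raise GenerationError("cannot place overlapping pair on scaffold")
        # exact integer center distance requires len_s - len_r even
        if (len_s - len_r) % 2:
            len_s += 1
        offset = distance - (len_s - len_r) // 2  # s start relative to r start
        span = max(len_r, offset + len_s)
        lowest = min(0, offset)
        if span - lowest > spec.scaffold_length:
            raise GenerationError(
                f"scaffold too short for pair at center distance {distance}"
            )
        for _ in range(_MAX_ATTEMPTS):
            r0 = self.rng.randint(1 - lowest, spec.scaffold_length - span + 1 + min(0, -lowest))
            s0 = r0 + offset
            r1, s1 = r0 + len_r - 1, s0 + len_s - 1
            if r0 >= 1 and s0 >= 1 and r1 <= spec.scaffold_length and s1 <= spec.scaffold_length:
                return (r0, r1), (s0, s1)
        raise GenerationError("cannot place gene pair on scaffold")

    def place_clear_of(self, centers: list[int], length: int,
                       min_doubled_sep: int) -> tuple[int, int]:
        """An interval whose doubled center is > min_doubled_sep from every
        value in ``centers``; rejection-sampled with a bounded attempt count."""
        spec = self.spec
        if length > spec.scaffold_length:
            raise GenerationError("gene longer than scaffold")
        for _ in range(_MAX_ATTEMPTS):
            start = self.rng.randint(1, spec.scaffold_length - length + 1)
            c2 = 2 * start + length - 1
            if all(abs(c2 - other) > min_doubled_sep for other in centers):
                return start, start + length - 1
        raise GenerationError(
            "rejection sampling failed: scaffold too crowded to place a gene "
            "clear of existing genes"
        )


def generate_fixture(spec: FixtureSpec) -> tuple[GeneTable, GeneTable, TruthSet]:
    """Realise ``spec`` into a resistance table, an SM table, and its truth.

    Deterministic given ``spec.seed``: two calls with equal specs produce
    byte-identical tables.  Raises :class:`GenerationError` if the spec is
    infeasible (placements keep violating constraints after a bounded
    number of rejection attempts, or an unplanned qualifying pair cannot be
    avoided).
    """
    b = _Builder(spec)
    c2 = 2 * spec.cutoff_c

    expected: list[tuple[str, str]] = []
    singleton: list[tuple[str, str]] = []

    # --- planted pairs (explicit coordinates) -------------------------------
    extra_jobs: list[tuple[int, int, int, str]] = []  # genome, home scaffold, count, label
    for pair in spec.planted_pairs:
        b.used_scaffolds.add((pair.genome, pair.scaffold))
        b.genome_class[pair.genome] = "multi"
        r = b.add_resistance(pair.genome, pair.scaffold, *pair.resistance,
                             label="planted_resistance")
        s = b.add_sm(pair.genome, pair.scaffold, *pair.sm, label="planted_sm")
        if (pair.center_distance <= spec.cutoff_c
                and pair.resistance_length <= spec.max_gene_length_m):
            expected.append((r.gene_id, s.gene_id))
        extra_jobs.append((pair.genome, pair.scaffold,
                           pair.n_extra_resistance_copies, "extra_copy"))

    # --- decoys (randomly placed, one scaffold each) ------------------------
    def pair_distance_near() -> int:
        len_r, len_s = b.random_length(), b.random_length()
        low = (len_r + len_s) // 2 + 2  # guarantees a positive end gap
        return b.rng.randint(low, spec.cutoff_c), len_r, len_s

    for _ in range(spec.decoys.singleton_near):
        g, sc = b.claim_free_scaffold(exclusive_genome=True)
        d, len_r, len_s = pair_distance_near()
        (r0, r1), (s0, s1) = b.place_pair(d, len_r, len_s)
        r = b.add_resistance(g, sc, r0, r1, "singleton_near_resistance")
        s = b.add_sm(g, sc, s0, s1, "singleton_near_sm")
        singleton.append((r.gene_id, s.gene_id))

    for _ in range(spec.decoys.far_pair):
        g, sc = b.claim_free_scaffold()
        len_r, len_s = b.random_length(), b.random_length()
        hi = spec.scaffold_length - len_r - len_s
        d = b.rng.randint(spec.cutoff_c + 1,
                          max(spec.cutoff_c + 1, min(2 * spec.cutoff_c, hi)))
        (r0, r1), (s0, s1) = b.place_pair(d, len_r, len_s)
        b.add_resistance(g, sc, r0, r1, "far_pair_resistance")
        b.add_sm(g, sc, s0, s1, "far_pair_sm")
        extra_jobs.append((g, sc, 1, "far_pair_extra_copy"))

    for _ in range(spec.decoys.overlapping_pair):
        g, sc = b.claim_free_scaffold()
        (r0, r1), (s0, s1) = b.place_pair(0, b.random_length(), b.random_length(),
                                          overlap=True)
        b.add_resistance(g, sc, r0, r1, "overlapping_pair_resistance")
        b.add_sm(g, sc, s0, s1, "overlapping_pair_sm")
        extra_jobs.append((g, sc, 1, "overlapping_pair_extra_copy"))

    for _ in range(spec.decoys.oversized_resistance):
        g, sc = b.claim_free_scaffold()
        len_r = spec.max_gene_length_m + b.rng.randint(1, spec.max_gene_length_m // 10 + 1)
        len_s = b.random_length()
        low = (len_r + len_s) // 2 + 2
        if low > spec.cutoff_c:
            raise GenerationError(
                "oversized decoy cannot sit within C without overlapping"
            )
        d = b.rng.randint(low, spec.cutoff_c)
        (r0, r1), (s0, s1) = b.place_pair(d, len_r, len_s)
        b.add_resistance(g, sc, r0, r1, "oversized_resistance")
        b.add_sm(g, sc, s0, s1, "oversized_sm")
        extra_jobs.append((g, sc, 1, "oversized_extra_copy"))

    # --- extra resistance copies (other scaffolds, clear of all SM genes) ---
    for genome, home_scaffold, count, label in extra_jobs:
        if spec.scaffolds_per_genome < 2:
            raise GenerationError(
                "extra resistance copies need at least two scaffolds per genome"
            )
        for _ in range(count):
            for _ in range(_MAX_ATTEMPTS):
                sc = b.rng.randrange(spec.scaffolds_per_genome)
                if sc != home_scaffold:
                    break
            length = b.random_length()
            start, stop = b.place_clear_of(
                b.s_centers.get((genome, sc), []), length, c2
            )
            b.add_resistance(genome, sc, start, stop, label)

    # --- background SM genes (clear of every resistance gene by > C) --------
    for _ in range(spec.n_background_sm_genes):
        placed = False
        for _ in range(_MAX_ATTEMPTS):
            g = b.rng.randrange(spec.n_genomes)
            sc = b.rng.randrange(spec.scaffolds_per_genome)
            length = b.random_length()
            try:
                start, stop = b.place_clear_of(
                    b.r_centers.get((g, sc), []), length, c2
                )
            except GenerationError:
                continue
            b.add_sm(g, sc, start, stop, "background_sm")
            placed = True
            break
        if not placed:
            raise GenerationError("could not place a background SM gene")

    r_table = GeneTable(Role.RESISTANCE, tuple(b.r_records), source="synthetic")
    s_table = GeneTable(Role.SM_CORE, tuple(b.s_records), source="synthetic")
    truth = TruthSet(
        cutoff_c=spec.cutoff_c,
        max_gene_length_m=spec.max_gene_length_m,
        expected_hits=tuple(sorted(expected)),
        singleton_hits=tuple(sorted(singleton)),
        labels=b.labels,
    )
    _audit(spec, r_table, s_table, truth)
    return r_table, s_table, truth


def _audit(spec: FixtureSpec, r_table: GeneTable, s_table: GeneTable,
           truth: TruthSet) -> None:
    """Construction-side geometric check (not the miner): the pairs passing
    the organism/scaffold/distance/overlap/length predicates must be exactly
    the planted hits plus the singleton-decoy pairs."""
    by_scaffold: dict[tuple[str, str], list[GeneRecord]] = {}
    for s in s_table:
        by_scaffold.setdefault((s.organism, s.scaffold), []).append(s)
    qualifying: set[tuple[str, str]] = set()
    c2 = 2 * spec.cutoff_c
    for r in r_table:
        if r.stop - r.start + 1 > spec.max_gene_length_m:
            continue
        for s in by_scaffold.get((r.organism, r.scaffold), []):
            if abs((r.start + r.stop) - (s.start + s.stop)) > c2:
                continue
            if r.start <= s.stop and s.start <= r.stop:
                continue
            qualifying.add((r.gene_id, s.gene_id))
    intended = set(truth.expected_hits) | set(truth.singleton_hits)
    if qualifying != intended:
        raise GenerationError(
            "placement produced unplanned qualifying pairs: "
            f"unexpected={sorted(qualifying - intended)} "
            f"missing={sorted(intended - qualifying)}"
        )


# --------------------------------------------------------------------------
# Ready-made specs


def random_spec(
    seed: int,
    n_genomes: int = 12,
    scaffolds_per_genome: int = 4,
    scaffold_length: int = 600_000,
    n_planted: int = 4,
    n_background_sm_genes: int = 60,
    decoys: DecoyCounts = DecoyCounts(
        singleton_near=2, far_pair=2, overlapping_pair=1, oversized_resistance=1
    ),
    gene_length_range: tuple[int, int] = (900, 8000),
    cutoff_c: int = 70_000,
    max_gene_length_m: int = 50_000,
    planted_distances: tuple[int, ...] | None = None,
) -> FixtureSpec:
    """A FixtureSpec with randomly synthesised planted-pair coordinates.

    Planted center distances are drawn in [minimum separation, C] unless
    ``planted_distances`` pins them explicitly.  The planted pairs occupy
    distinct (genome, scaffold) slots chosen from the first genomes so the
    decoy placer always finds free scaffolds.
    """
    rng = random.Random(seed)
    if planted_distances is not None:
        n_planted = len(planted_distances)
    slots = [
        (g, sc) for g in range(n_genomes) for sc in range(scaffolds_per_genome)
    ]
    if n_planted > len(slots):
        raise ValueError("more planted pairs than scaffolds")
    rng.shuffle(slots)
    pairs = []
    for i in range(n_planted):
        g, sc = slots[i]
        len_r = rng.randint(*gene_length_range)
        len_s = rng.randint(*gene_length_range)
        if (len_s - len_r) % 2:
            len_s += 1
        low = (len_r + len_s) // 2 + 2
        if planted_distances is not None:
            d = planted_distances[i]
            if d < low:
                raise ValueError(
                    f"planted distance {d} too small for gene lengths drawn"
                )
        else:
            d = rng.randint(low, cutoff_c)
        offset = d - (len_s - len_r) // 2
        r0 = rng.randint(1, scaffold_length - (offset + len_s))
        pairs.append(
            PlantedPair(
                genome=g,
                scaffold=sc,
                resistance=(r0, r0 + len_r - 1),
                sm=(r0 + offset, r0 + offset + len_s - 1),
                n_extra_resistance_copies=rng.randint(1, 3),
            )
        )
    return FixtureSpec(
        n_genomes=n_genomes,
        scaffolds_per_genome=scaffolds_per_genome,
        scaffold_length=scaffold_length,
        n_background_sm_genes=n_background_sm_genes,
        planted_pairs=tuple(pairs),
        decoys=decoys,
        gene_length_range=gene_length_range,
        seed=seed,
        cutoff_c=cutoff_c,
        max_gene_length_m=max_gene_length_m,
    )


def small_spec(seed: int = 0) -> FixtureSpec:
    """A desk-size fixture: 12 genomes, 4 planted pairs, all decoy classes."""
    return random_spec(seed)


def mycocosm_scale_spec(seed: int = 0) -> FixtureSpec:
    """A spec approximating the table sizes of a full fungal-portal run:
    1800 genomes, ~28 000 SM genes, ~2300 resistance-gene homologs.

    Used for performance testing only; the composition (mostly single-copy
    or far-from-cluster homologs, a small planted-hit fraction) mimics the
    rarity of true self-resistance hits in real genome sets.
    """
    return random_spec(
        seed,
        n_genomes=1800,
        scaffolds_per_genome=6,
        scaffold_length=2_000_000,
        n_planted=50,
        n_background_sm_genes=26_350,
        decoys=DecoyCounts(
            singleton_near=1000,
            far_pair=550,
            overlapping_pair=25,
            oversized_resistance=25,
        ),
    )


# --------------------------------------------------------------------------
# Plain-text spec serialisation (documented schema: YAML mapping mirroring
# FixtureSpec fields; planted_pairs is a list of mappings).


def spec_to_yaml(spec: FixtureSpec) -> str:
    doc = {
        "n_genomes": spec.n_genomes,
        "scaffolds_per_genome": spec.scaffolds_per_genome,
        "scaffold_length": spec.scaffold_length,
        "n_background_sm_genes": spec.n_background_sm_genes,
        "gene_length_range": list(spec.gene_length_range),
        "seed": spec.seed,
        "cutoff_c": spec.cutoff_c,
        "max_gene_length_m": spec.max_gene_length_m,
        "decoys": asdict(spec.decoys),
        "planted_pairs": [
            {
                "genome": p.genome,
                "scaffold": p.scaffold,
                "resistance": list(p.resistance),
                "sm": list(p.sm),
                "n_extra_resistance_copies": p.n_extra_resistance_copies,
            }
            for p in spec.planted_pairs
        ],
    }
    return yaml.safe_dump(doc, sort_keys=False)


def spec_from_yaml(text: str) -> FixtureSpec:
    doc = yaml.safe_load(text)
    pairs = tuple(
        PlantedPair(
            genome=p["genome"],
            scaffold=p["scaffold"],
            resistance=tuple(p["resistance"]),
            sm=tuple(p["sm"]),
            n_extra_resistance_copies=p.get("n_extra_resistance_copies", 1),
        )
        for p in doc.get("planted_pairs", [])
    )
    return FixtureSpec(
        n_genomes=doc["n_genomes"],
        scaffolds_per_genome=doc["scaffolds_per_genome"],
        scaffold_length=doc["scaffold_length"],
        n_background_sm_genes=doc.get("n_background_sm_genes", 0),
        planted_pairs=pairs,
        decoys=DecoyCounts(**doc.get("decoys", {})),
        gene_length_range=tuple(doc.get("gene_length_range", (900, 8000))),
        seed=doc.get("seed", 0),
        cutoff_c=doc.get("cutoff_c", 70_000),
        max_gene_length_m=doc.get("max_gene_length_m", 50_000),
    )
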