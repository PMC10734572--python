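"""Hit/homolog serialisation and summary statistics.

Outputs follow the miner's ordering contract bit-exactly so that runs are
reproducible and diffable.  The hits CSV reports both distance readings a
curator cares about: ``center_distance`` (the miner's predicate, midpoint
to midpoint) and ``end_gap`` (bases strictly between the annotated gene
ends, the distance one sees in a genome browser).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

from .gene_tables import GeneTable, write_gene_table
from .mining import Hit, HomologTable, MinerConfig, format_distance, mine

__all__ = [
    "HITS_HEADER",
    "HistogramResult",
    "SweepResult",
    "write_hits_csv",
    "write_homologs_csv",
    "distance_histogram",
    "cutoff_sweep",
    "genome_summary",
    "plot_histogram",
]

HITS_HEADER = (
    "organism",
    "resistance_gene_id",
    "resistance_scaffold",
    "resistance_start",
    "resistance_stop",
    "resistance_evalue",
    "resistance_pct_identity",
    "sm_gene_id",
    "sm_scaffold",
    "sm_start",
    "sm_stop",
    "center_distance",
    "end_gap",
)


def _fmt_opt(x) -> str:
    if x is None:
        return ""
    return repr(x) if isinstance(x, float) else str(x)


def hit_row(h: Hit) -> list[str]:
    r, s = h.resistance, h.sm
    return [
        r.organism,
        r.gene_id,
        r.scaffold,
        str(r.start),
        str(r.stop),
        _fmt_opt(r.evalue),
        _fmt_opt(r.pct_identity),
        s.gene_id,
        s.scaffold,
        str(s.start),
        str(s.stop),
        format_distance(h.center_distance),
        str(h.end_gap),
    ]


def write_hits_csv(hits: list[Hit], path) -> None:
    """Write hits in the miner's sorted order; integral center distances
    render without a decimal point, half-integers with ``.5``."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(HITS_HEADER)
        for h in hits:
            writer.writerow(hit_row(h))


def write_homologs_csv(h: HomologTable, path) -> None:
    """Write a homolog table as a canonical gene-table CSV (already
    deduplicated and sorted by the HomologTable contract)."""
    from .gene_tables import Role

    table = GeneTable(Role.RESISTANCE, h.entries, source="homologs")
    write_gene_table(table, path)


@dataclass(frozen=True)
class HistogramResult:
    """Hit counts per center-distance bin; bins are half-open [lo, hi),
    contiguous from zero."""

    bin_width: int
    bins: tuple[tuple[int, int, int], ...]  # (lower, upper, count)
    total: int


def distance_histogram(hits: list[Hit], bin_width: int) -> HistogramResult:
    """Bin hits by center distance into [0,w), [w,2w), ... up to the
    largest observed distance.  A distance exactly on a boundary falls in
    the upper bin."""
    if bin_width < 1:
        raise ValueError(f"bin_width must be >= 1, got {bin_width}")
    if not hits:
        return HistogramResult(bin_width=bin_width, bins=(), total=0)
    indices = [int(h.center_distance // bin_width) for h in hits]
    n_bins = max(indices) + 1
    counts = [0] * n_bins
    for i in indices:
        counts[i] += 1
    bins = tuple(
        (i * bin_width, (i + 1) * bin_width, counts[i]) for i in range(n_bins)
    )
    return HistogramResult(bin_width=bin_width, bins=bins, total=len(hits))


@dataclass(frozen=True)
class SweepResult:
    """Hit and distinct-genome counts as a function of the cutoff C.
    Both are non-decreasing: raising C can only add hits."""

    cutoffs: tuple[int, ...]
    counts: tuple[int, ...]
    genomes: tuple[int, ...]


def cutoff_sweep(
    r_table: GeneTable,
    s_table: GeneTable,
    base_config: MinerConfig,
    cutoffs: list[int],
) -> SweepResult:
    """Hit counts over a strictly increasing list of cutoffs.

    Mines once at the largest cutoff and filters down by center distance;
    this equals independent per-cutoff runs because the other predicates
    (and singleton elimination) do not depend on C.
    """
    if not cutoffs:
        raise ValueError("cutoff list must not be empty")
    if any(b <= a for a, b in zip(cutoffs, cutoffs[1:])):
        raise ValueError(f"cutoffs must be strictly increasing: {cutoffs}")
    from dataclasses import replace

    full = mine(r_table, s_table, replace(base_config, cutoff_c=cutoffs[-1]))
    counts, genomes = [], []
    for c in cutoffs:
        sub = [h for h in full if h.center_distance <= c]
        counts.append(len(sub))
        genomes.append(len({h.organism for h in sub}))
    return SweepResult(
        cutoffs=tuple(cutoffs), counts=tuple(counts), genomes=tuple(genomes)
    )


def write_sweep_csv(result: SweepResult, path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(("cutoff", "hits", "genomes"))
        for c, n, g in zip(result.cutoffs, result.counts, result.genomes):
            writer.writerow((c, n, g))


def write_histogram_csv(result: HistogramResult, path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(("bin_lower", "bin_upper", "count"))
        for lo, hi, n in result.bins:
            writer.writerow((lo, hi, n))


def genome_summary(hits: list[Hit]) -> list[tuple[str, int]]:
    """(organism, hit count) rows, sorted by organism; counts sum to
    ``len(hits)``."""
    counts: dict[str, int] = {}
    for h in hits:
        counts[h.organism] = counts.get(h.organism, 0) + 1
    return sorted(counts.items())


def plot_histogram(result: HistogramResult, path) -> None:
    """Render the distance histogram to an image file (cosmetic extra;
    requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    if result.bins:
        ax.bar(
            [lo for lo, _, _ in result.bins],
            [n for _, _, n in result.bins],
            width=result.bin_width,
            align="edge",
            edgecolor="black",
        )
    ax.set_xlabel("center-to-center distance (bp)")
    ax.set_ylabel("hits")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
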