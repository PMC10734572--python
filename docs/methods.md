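# Methods

## Model of a self-resistant BGC

resmine operationalises a single biological assumption: a biosynthetic
gene cluster (BGC) whose product inhibits an essential protein tends to
carry a resistant duplicate of the target gene, physically near the
cluster's core biosynthetic (backbone) gene, while the susceptible
housekeeping allele lies elsewhere in the genome.  The method makes no
attempt to delimit cluster boundaries or to model gene content beyond
the backbone gene; it is a pure interval-proximity join with a
copy-number precondition.  That minimalism is deliberate: cluster
boundary predictors disagree with each other, whereas backbone genes
(NRPS, PKS, terpene synthase/cyclase, DMATS) are easy to enumerate from
portal searches, and proximity to one is a weak but cheap and unbiased
proxy for cluster membership.

## Predicates and conventions

A hit is a pair (r, s) with r a resistance-gene homolog and s a backbone
gene, passing: same genome; same scaffold; center distance ≤ C;
non-overlap; length(r) ≤ M.  Genomes with fewer than two homolog copies
are removed first (waivable).

* **Coordinates** are 1-based, fully closed; length = stop − start + 1.
  Portal gene-table exports follow genome-browser convention; nothing in
  the pipeline depends on the choice beyond consistency.
* **Center distance** compares doubled centers: center×2 = start + stop
  is always an integer, so the predicate |center×2(r) − center×2(s)| ≤ 2C
  is evaluated in exact integer arithmetic.  Reported distances are
  integers or half-integers, rendered as `12345` or `12345.5`.
* **Overlap** is closed-interval: sharing one base counts.  This is
  conservative (an overlapping pair is more plausibly a mis-annotation
  than a resistance arrangement) and makes a record paired with itself
  ineligible with no special-casing.
* **Singleton counting** happens on the full deduplicated homolog table,
  *before* the length filter: an oversized second copy still proves the
  genome has two copies, it just cannot itself pair.  The alternative
  ordering (count only copies ≤ M) was considered and rejected because
  the length filter exists to drop annotation artifacts from the *pair*,
  not to re-define copy number.
* **Matching** of organism and scaffold identifiers is exact,
  case-sensitive string equality after trimming: portal identifiers are
  machine-generated, and case-folding could merge distinct genomes.
  Strand is ignored throughout.
* **Ordering**: hits are sorted by (organism, resistance start,
  resistance gene_id, sm start, sm gene_id); homologs by (organism,
  start, gene_id).  The order is arbitrary but fixed, so outputs are
  byte-stable.

## Parameters

| parameter | unit | default | notes |
|---|---|---|---|
| C, `--cutoff` | bp, center-to-center | required | 70 000 bp is the documented working value for fungal BGCs, which span ~11 kb to ~70 kb; the CLI forces an explicit choice because the right value differs by gene class. |
| M, `--max-gene-length` | bp | unlimited | opt-in filter against implausibly long (mis-annotated) homolog models. |
| `--nocheck` | flag | off | waives the two-copy rule; useful for non-resistance queries (e.g. transcription factors near backbone genes), at the cost of the self-resistance rationale. |

## Engines

`mine` groups S by (organism, scaffold), sorts each group by doubled
center, and binary-searches the window [center×2(r) − 2C, center×2(r) + 2C]
per resistance gene: O((|R| + |S|) log |S|) instead of the naive
O(|R|·|S|).  `brute_force_mine` is the naive loop, kept permanently as
the oracle; the suite asserts element-wise identical output across many
random fixtures, several configurations, and both engines.  At realistic
portal scale (~2 300 × ~28 000 genes) the indexed engine completes in
well under a second on one CPU.

## The synthetic fixture generator

Real inputs come from BLAST/KOG searches against a live genome portal
and cannot be regenerated offline, so testing rests on
`resmine.generate_fixture`: seeded, deterministic synthesis of
portal-style tables in which the truth is known *by construction*, never
by running the miner.

What it emulates: many genomes with several scaffolds; genes as 1-based
intervals with lengths uniform in a configurable range (default
900–8 000 bp, the realistic span of fungal gene models; there is no
published length model to fit); planted resistance/backbone pairs at
exact chosen center distances; E-values (log-uniform, 1e-180–1e-45) and
percent identities on resistance genes, as a BLAST export would carry.
Decoys each violate exactly one predicate: `singleton_near` (one copy
only — placed in a genome reserved exclusively for it, so no other
structure can silently restore its copy number), `far_pair` (distance
> C), `overlapping_pair`, `oversized_resistance` (length > M).
Background backbone genes are rejection-sampled > C from every
resistance gene; extra homolog copies are rejection-sampled > C from
every backbone gene; each structure owns its scaffold.  A final
construction-side geometric audit re-derives all qualifying pairs and
fails generation if any unplanned pair slipped through, so
precision/recall assertions against the truth set are exact, not
approximate.  Rejection sampling is bounded (1 000 attempts) and an
infeasible spec raises a generation error rather than degrading.

The fixture's stated truth conditions are C = 70 000 bp and
M = 50 000 bp.  M must be finite for the oversized decoy class to be
well-defined; 50 kb comfortably exceeds any real fungal gene model while
staying below the scale of the planted distances.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: sequence content and homology structure
(E-values are decorative, not derived from alignments); incomplete
homolog recovery by the upstream BLAST search; fragmented assemblies
that split clusters across scaffold edges; mis-annotated split genes;
any correlation between gene density and genomic location.  On real
portal exports those effects produce false negatives (a cluster at a
scaffold edge loses its second copy to another scaffold) and occasional
extra hits (split gene models double-count), which no coordinate-only
simulation can quantify.

The `mycocosm-scale` preset reproduces only the *sizes* of a full portal
run — 1800 genomes, ~28 000 backbone genes, ~2 300 homologs, with hits
rare relative to table size — and exists for performance testing; its
hit counts are properties of the synthetic composition, not of any real
genome set.

## Numerical and degenerate-input choices

All predicate arithmetic is integer; the only floats anywhere are
optional E-value/percent-identity pass-throughs, written with `repr` so
CSV round-trips are lossless.  Histogram bins are half-open [kw, (k+1)w),
lower-inclusive from zero; a distance exactly on a boundary falls in the
upper bin.  The cutoff sweep mines once at the largest cutoff and
filters down, which equals independent per-cutoff runs because no other
predicate depends on C (asserted in the suite).  Empty tables, empty hit
lists, and single-base genes are all legal and covered by tests.
Duplicate rows (identical in all mapped fields) collapse to the first
occurrence; required-field parse failures abort with a line-numbered
error, because silently dropping rows would change hit counts invisibly.

## Known limitations

* Proximity to a backbone gene is necessary but not sufficient for
  cluster membership; hits require manual curation (genome browser,
  alignments) that is out of scope here.
* The two-copy rule fails for genuinely single-copy resistant targets,
  for genomes whose housekeeping copy was missed by the upstream search,
  and for clusters at scaffold edges in fragmented assemblies.
* The tool never sees sequences: annotation quality of the input tables
  bounds result quality.
* Problem sizes in the test suite (fixtures up to ~10⁴ genes, one
  portal-scale run of ~3×10⁴ genes) were chosen as comfortable desk-scale
  workloads; the engines are far from their limits at these sizes.
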