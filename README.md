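# resmine

Resistance-gene-guided genome mining of fungal secondary-metabolite
biosynthetic gene clusters (BGCs), from gene-coordinate tables alone.

## The problem

Many fungal BGCs encode a compound that inhibits an essential protein —
and protect their host by carrying a *resistant second copy* of the
target gene inside the cluster, while the susceptible housekeeping copy
sits elsewhere in the genome.  Classic examples are the lovastatin
cluster (a resistant HMG-CoA reductase, HMGCR) and the fellutamide B
cluster (a resistant proteasome β6 subunit).  That duplication is a
searchable signature: a genome likely harbours a BGC making an inhibitor
of protein X if

* a homolog of gene X lies close to a core secondary-metabolite (SM)
  biosynthetic gene (an NRPS, PKS, terpene synthase/cyclase, or DMATS), and
* the genome carries at least two copies of gene X.

resmine implements this search over plain CSV exports of gene
coordinates, as produced by annotated-genome portals such as MycoCosm —
no genome downloads, no cluster-boundary prediction, no sequence
analysis.  It is aimed at natural-product researchers who choose a
therapeutic target, pull the homolog and core-gene coordinate tables
from a portal, and want the candidate clusters ranked out in seconds.

## The algorithm

Let **R** be the set of candidate resistance-gene homologs and **S** the
set of core SM biosynthetic genes, each gene a 1-based inclusive
interval on a named scaffold of a named genome.  With a center-to-center
distance cutoff *C* and a maximum resistance-gene length *M*, a **hit**
is a pair (r, s) ∈ R × S such that

1. r and s are in the same genome,
2. r and s are on the same scaffold,
3. |center(r) − center(s)| ≤ C, where center(g) = (start + stop)/2,
4. r and s do not overlap, and
5. length(r) = stop − start + 1 ≤ M,

where R is first restricted to genomes with ≥ 2 homolog copies (the
self-resistance requirement; waivable with `--nocheck`).  A cluster with
two core genes in range yields two hits — that is the expected
fingerprint of two-synthase clusters like the lovastatin and fellutamide
families.  All distance arithmetic is integer-exact (doubled
coordinates), so results are bit-reproducible across platforms.

Both an indexed engine (per-scaffold sorted centers, binary-searched
windows) and the literal brute-force pair loop are included; the test
suite holds them element-wise identical.  *Homolog mode* additionally
reports every R copy from each genome with a hit, deduplicated — useful
for downstream phylogenetics of resistant vs. housekeeping alleles.

## Worked example

resmine ships a seeded generator of portal-style tables with planted
hits and labeled decoys, so you can exercise the full workflow offline:

```sh
resmine simulate --preset small --seed 7 --outdir demo
resmine mine --resistance demo/resistance.csv --sm demo/sm.csv \
    --cutoff 70000 --max-gene-length 50000 \
    --out demo/hits.csv --homologs demo/homologs.csv
```

The second command prints `4 hits in 3 genomes` to standard error and
writes `demo/hits.csv`:

```
organism,resistance_gene_id,resistance_scaffold,resistance_start,resistance_stop,resistance_evalue,resistance_pct_identity,sm_gene_id,sm_scaffold,sm_start,sm_stop,center_distance,end_gap
org0003,g000007,scaf03,255954,263360,6.75857044116799e-173,65.4,g000008,scaf03,309172,311544,50701,45811
org0003,g000005,scaf02,314329,320024,2.2083636064170943e-108,56.9,g000006,scaf02,343723,348334,28852,23698
org0008,g000003,scaf01,329408,331994,7.518892236094828e-93,39.3,g000004,scaf01,388042,393008,59824,56047
org0009,g000001,scaf03,62497,66446,5.217029019540972e-137,44.1,g000002,scaf03,74678,76375,11055,8231
```

Each row is one candidate pair: the resistance homolog (with the
E-value/percent-identity carried over from the BLAST search that built
the input table), its partner core biosynthetic gene, the
center-to-center distance the predicate tested (`center_distance`, bp),
and the annotation-end gap a genome browser would show (`end_gap`, bp).
These four pairs are exactly the fixture's planted truth — the decoys
(single-copy genomes, far pairs, overlapping pairs, oversized genes)
are correctly rejected.  Raising the cutoff can only add candidates:

```sh
resmine sweep --resistance demo/resistance.csv --sm demo/sm.csv \
    --cutoffs 10000,40000,70000,100000 --out demo/sweep.csv
```

```
cutoff,hits,genomes
10000,0,0
40000,2,2
70000,5,4
100000,12,4
```

(The sweep runs without the length filter, so the oversized decoy's pair
appears at 70 kb, and loosening to 100 kb pulls in far decoys — the
false-positive growth that makes 70 kb a sensible working cutoff.)
`resmine histogram --bin-width 10000 ...` bins hit distances the same
way.  The same operations are available as library functions
(`resmine.mine`, `resmine.cutoff_sweep`, `resmine.distance_histogram`,
`resmine.generate_fixture`, ...).

### Input format

CSV with a header row.  Column names are matched case-insensitively
against common portal aliases: `portal`/`organism`/`genome`,
`proteinId`/`id`/`name`, `scaffold`/`contig`/`chr`, `start`/`begin`,
`stop`/`end`/`gene stop`, plus optional `e-value` and
`percent identity`.  Coordinates are 1-based inclusive.  Malformed rows
abort with a line-numbered error rather than being silently dropped.

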