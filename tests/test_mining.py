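"""The five-predicate proximity join: worked examples, oracle equivalence,
monotonicity, waiver semantics, and homolog collection."""

from fractions import Fraction

import pytest

from resmine import (
    DecoyCounts,
    MinerConfig,
    Role,
    brute_force_mine,
    collect_homologs,
    eliminate_singletons,
    generate_fixture,
    mine,
    random_spec,
)
from resmine.mining import format_distance
from resmine.gene_tables import gene_length, overlaps, center_times_two

from conftest import rec, table


ENGINES = [mine, brute_force_mine]


def two_copy_r(*extra):
    """A resistance table whose orgA always passes the two-copy rule."""
    return table(
        Role.RESISTANCE,
        rec(gene_id="r1", scaffold="s1", start=10_000, stop=11_000),
        rec(gene_id="r2", scaffold="s9", start=500, stop=1_500),
        *extra,
    )


@pytest.mark.parametrize("engine", ENGINES)
def test_single_hit_with_exact_center_distance(engine):
    s_table = table(Role.SM_CORE, rec(gene_id="s1", scaffold="s1", start=70_000, stop=72_000))
    hits = engine(two_copy_r(), s_table, MinerConfig(cutoff_c=70_000))
    assert len(hits) == 1
    assert hits[0].resistance.gene_id == "r1"
    assert hits[0].center_distance == Fraction(60_500)  # |10500 - 71000|


@pytest.mark.parametrize("engine", ENGINES)
def test_different_scaffold_is_not_a_hit(engine):
    s_table = table(Role.SM_CORE, rec(gene_id="s1", scaffold="s2", start=70_000, stop=72_000))
    assert engine(two_copy_r(), s_table, MinerConfig(cutoff_c=70_000)) == []


@pytest.mark.parametrize("engine", ENGINES)
def test_overlap_is_not_a_hit_even_with_huge_cutoff(engine):
    r_table = table(
        Role.RESISTANCE,
        rec(gene_id="r1", scaffold="s1", start=100, stop=200),
        rec(gene_id="r2", scaffold="s9", start=500, stop=600),
    )
    s_table = table(Role.SM_CORE, rec(gene_id="s1", scaffold="s1", start=150, stop=1_150))
    assert engine(r_table, s_table, MinerConfig(cutoff_c=10**9)) == []


@pytest.mark.parametrize("engine", ENGINES)
def test_length_filter_boundary(engine):
    r_table = table(
        Role.RESISTANCE,
        rec(gene_id="r1", scaffold="s1", start=1, stop=50_001),  # 50 001 bp
        rec(gene_id="r2", scaffold="s9", start=500, stop=600),
    )
    s_table = table(Role.SM_CORE, rec(gene_id="s1", scaffold="s1", start=60_000, stop=61_000))
    assert engine(r_table, s_table, MinerConfig(cutoff_c=70_000, max_gene_length_m=50_000)) == []
    unlimited = engine(r_table, s_table, MinerConfig(cutoff_c=70_000))
    assert len(unlimited) == 1


@pytest.mark.parametrize("engine", ENGINES)
def test_cutoff_boundary_inclusive(engine):
    # centers exactly C apart are a hit; one base further is not
    r_table = two_copy_r()
    s = rec(gene_id="s1", scaffold="s1", start=80_500, stop=81_500)  # center 81000
    hits = engine(r_table, table(Role.SM_CORE, s), MinerConfig(cutoff_c=70_500))
    assert len(hits) == 1 and hits[0].center_distance == 70_500
    assert engine(r_table, table(Role.SM_CORE, s), MinerConfig(cutoff_c=70_499)) == []


@pytest.mark.parametrize("engine", ENGINES)
def test_half_integer_center_distance_is_exact(engine):
    r_table = table(
        Role.RESISTANCE,
        rec(gene_id="r1", scaffold="s1", start=100, stop=201),  # center 150.5
        rec(gene_id="r2", scaffold="s9", start=500, stop=600),
    )
    s_table = table(Role.SM_CORE, rec(gene_id="s1", scaffold="s1", start=300, stop=400))  # 350
    (hit,) = engine(r_table, s_table, MinerConfig(cutoff_c=1_000))
    assert hit.center_distance == Fraction(399, 2)
    assert format_distance(hit.center_distance) == "199.5"


@pytest.mark.parametrize("engine", ENGINES)
def test_shared_record_in_both_tables_never_self_pairs(engine):
    g1 = rec(gene_id="g1", scaffold="s1", start=100, stop=200)
    g2 = rec(gene_id="g1b", scaffold="s1", start=100, stop=200)
    r_table = table(Role.RESISTANCE, g1, g2)
    s_table = table(Role.SM_CORE, g1)
    assert engine(r_table, s_table, MinerConfig(cutoff_c=10**6)) == []


@pytest.mark.parametrize("engine", ENGINES)
def test_empty_sm_table_yields_no_hits(engine):
    assert engine(two_copy_r(), table(Role.SM_CORE), MinerConfig(cutoff_c=70_000)) == []


def test_wrong_roles_are_usage_errors():
    with pytest.raises(ValueError, match="role"):
        mine(table(Role.SM_CORE), table(Role.SM_CORE), MinerConfig(cutoff_c=1))
    with pytest.raises(ValueError, match="role"):
        mine(table(Role.RESISTANCE), table(Role.RESISTANCE), MinerConfig(cutoff_c=1))


def test_config_validation():
    with pytest.raises(ValueError):
        MinerConfig(cutoff_c=0)
    with pytest.raises(ValueError):
        MinerConfig(cutoff_c=10, max_gene_length_m=0)


# ---------------------------------------------------------------------------
# singleton elimination


def test_eliminate_singletons_keeps_multicopy_organisms_in_order():
    t = table(
        Role.RESISTANCE,
        rec(organism="A", gene_id="a1"),
        rec(organism="B", gene_id="b1"),
        rec(organism="A", gene_id="a2", start=300, stop=400),
        rec(organism="C", gene_id="c1"),
        rec(organism="C", gene_id="c2", start=300, stop=400),
        rec(organism="C", gene_id="c3", start=500, stop=600),
    )
    kept = eliminate_singletons(t)
    assert [r.gene_id for r in kept] == ["a1", "a2", "c1", "c2", "c3"]


def test_eliminate_singletons_all_singletons_gives_empty_table():
    t = table(Role.RESISTANCE, rec(organism="A"), rec(organism="B"))
    assert len(eliminate_singletons(t)) == 0


def test_singleton_count_uses_full_table_before_length_filter():
    # orgA's second copy is oversized: it still counts toward the two-copy
    # rule (elimination precedes the per-pair length check) but cannot
    # itself pair.
    r_table = table(
        Role.RESISTANCE,
        rec(organism="A", gene_id="short", scaffold="s1", start=10_000, stop=11_000),
        rec(organism="A", gene_id="huge", scaffold="s2", start=1, stop=60_000),
    )
    s_table = table(Role.SM_CORE, rec(organism="A", gene_id="s1", scaffold="s1", start=30_000, stop=31_000))
    config = MinerConfig(cutoff_c=70_000, max_gene_length_m=50_000)
    for engine in ENGINES:
        hits = engine(r_table, s_table, config)
        assert [h.resistance.gene_id for h in hits] == ["short"]


# ---------------------------------------------------------------------------
# oracle equivalence and order/predicate audits on random fixtures


@pytest.mark.parametrize("seed", range(12))
def test_indexed_engine_matches_brute_force_oracle(seed):
    spec = random_spec(seed, n_genomes=10, n_background_sm_genes=150)
    r_table, s_table, _ = generate_fixture(spec)
    for config in (
        MinerConfig(cutoff_c=70_000, max_gene_length_m=50_000),
        MinerConfig(cutoff_c=25_000),
        MinerConfig(cutoff_c=70_000, singleton_check=False),
    ):
        assert mine(r_table, s_table, config) == brute_force_mine(r_table, s_table, config)


def test_every_hit_satisfies_all_predicates_post_hoc():
    spec = random_spec(5)
    r_table, s_table, _ = generate_fixture(spec)
    config = MinerConfig(cutoff_c=spec.cutoff_c, max_gene_length_m=spec.max_gene_length_m)
    hits = mine(r_table, s_table, config)
    assert hits
    survivors = eliminate_singletons(r_table)
    survivor_orgs = survivors.organisms()
    for h in hits:
        r, s = h.resistance, h.sm
        assert r.organism == s.organism and r.scaffold == s.scaffold
        assert not overlaps(r, s)
        assert gene_length(r) <= config.max_gene_length_m
        assert h.center_distance <= config.cutoff_c
        assert h.center_distance == Fraction(abs(center_times_two(r) - center_times_two(s)), 2)
        assert r.organism in survivor_orgs


@pytest.mark.parametrize("seed", [3, 11])
def test_cutoff_and_length_monotonicity(seed):
    spec = random_spec(seed)
    r_table, s_table, _ = generate_fixture(spec)

    def key_set(hits):
        return {(h.resistance.gene_id, h.sm.gene_id) for h in hits}

    prev = set()
    for c in range(10_000, 110_000, 20_000):
        cur = key_set(mine(r_table, s_table, MinerConfig(cutoff_c=c)))
        assert prev <= cur
        prev = cur

    prev = set()
    for m in (2_000, 5_000, 20_000, None):
        cur = key_set(mine(r_table, s_table, MinerConfig(cutoff_c=70_000, max_gene_length_m=m)))
        assert prev <= cur
        prev = cur


@pytest.mark.parametrize("seed", [2, 9])
def test_nocheck_waiver_is_a_superset(seed):
    spec = random_spec(seed, decoys=DecoyCounts(singleton_near=4, far_pair=1,
                                                overlapping_pair=1, oversized_resistance=1))
    r_table, s_table, truth = generate_fixture(spec)
    config = MinerConfig(cutoff_c=spec.cutoff_c, max_gene_length_m=spec.max_gene_length_m)
    default = {(h.resistance.gene_id, h.sm.gene_id)
               for h in mine(r_table, s_table, config)}
    waived = {(h.resistance.gene_id, h.sm.gene_id)
              for h in mine(r_table, s_table,
                            MinerConfig(cutoff_c=spec.cutoff_c,
                                        max_gene_length_m=spec.max_gene_length_m,
                                        singleton_check=False))}
    assert default <= waived
    assert waived - default == set(truth.singleton_hits)


def test_mine_is_deterministic():
    spec = random_spec(4)
    r_table, s_table, _ = generate_fixture(spec)
    config = MinerConfig(cutoff_c=70_000)
    assert mine(r_table, s_table, config) == mine(r_table, s_table, config)


# ---------------------------------------------------------------------------
# homolog collection


def test_collect_homologs_takes_all_copies_from_hit_organisms():
    r_table = table(
        Role.RESISTANCE,
        rec(organism="A", gene_id="a1", scaffold="s1", start=10_000, stop=11_000),
        rec(organism="A", gene_id="a2", scaffold="s2", start=100, stop=900),
        rec(organism="A", gene_id="a3", scaffold="s3", start=100, stop=900),
        rec(organism="B", gene_id="b1", scaffold="s1", start=100, stop=900),
        rec(organism="B", gene_id="b2", scaffold="s2", start=100, stop=900),
    )
    s_table = table(Role.SM_CORE, rec(organism="A", gene_id="sm1", scaffold="s1",
                                      start=40_000, stop=42_000))
    hits = mine(r_table, s_table, MinerConfig(cutoff_c=70_000))
    assert len(hits) == 1
    homologs = collect_homologs(hits, r_table)
    assert [g.gene_id for g in homologs] == ["a2", "a3", "a1"]  # (organism, start, gene_id)
    assert {g.organism for g in homologs} == {"A"}


def test_collect_homologs_empty_hits_gives_empty_table():
    assert len(collect_homologs([], two_copy_r())) == 0


def test_collect_homologs_set_semantics_many_hits_same_organism():
    r_table = two_copy_r()
    s_table = table(
        Role.SM_CORE,
        rec(gene_id="sm1", scaffold="s1", start=40_000, stop=42_000),
        rec(gene_id="sm2", scaffold="s1", start=50_000, stop=52_000),
        rec(gene_id="sm3", scaffold="s1", start=60_000, stop=62_000),
    )
    hits = mine(r_table, s_table, MinerConfig(cutoff_c=70_000))
    assert len(hits) == 3
    assert collect_homologs(hits, r_table) == collect_homologs(hits[:1], r_table)
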