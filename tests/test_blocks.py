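"""Subconsomic mapping: ordering, block partition, neighbor tests, QTL calls."""

import itertools

import numpy as np
import pandas as pd
import pytest

from trabqtl import (
    GenotypeMap,
    SubconsomicSpec,
    assign_qtl,
    neighbor_tests,
    order_by_similarity,
    partition_blocks,
    simulate_subconsomic_panel,
)
from trabqtl.genmap import _distance_matrix
from trabqtl.panels import CONTROL_MEANS_6WK, paper_like_qtl

MARKERS = tuple(float(x) for x in range(10, 100, 10))


def make_map(intervals: dict, host="B6", donor="C15") -> GenotypeMap:
    iv = dict(intervals)
    iv.setdefault("B6", ())
    iv.setdefault("C15", ((0.0, 100.0),))
    return GenotypeMap(100.0, MARKERS, iv, host=host, donor=donor)


def random_map(rng: np.random.Generator, n_sub: int) -> GenotypeMap:
    iv = {}
    for i in range(n_sub):
        a, b = sorted(rng.choice(MARKERS, size=2, replace=False))
        iv[f"S{i}"] = ((float(a), float(b)),)
    return make_map(iv)


def brute_force_min_path(gmap: GenotypeMap) -> float:
    strains = sorted(gmap.strains)
    d = _distance_matrix(gmap, strains)
    idx = {s: i for i, s in enumerate(strains)}
    interior = [s for s in strains if s not in (gmap.host, gmap.donor)]
    best = np.inf
    for perm in itertools.permutations(interior):
        seq = [gmap.host, *perm, gmap.donor]
        cost = sum(d[idx[a], idx[b]] for a, b in zip(seq[:-1], seq[1:]))
        best = min(best, cost)
    return best


def path_cost(gmap: GenotypeMap, order: list[str]) -> float:
    return sum(
        gmap.symmetric_difference_mb(a, b) for a, b in zip(order[:-1], order[1:])
    )


# -- genotype map primitives -------------------------------------------


def test_symmetric_difference_basic():
    g = make_map({"A": ((10.0, 30.0),), "B": ((20.0, 40.0),)})
    assert g.symmetric_difference_mb("A", "B") == pytest.approx(20.0)
    assert g.symmetric_difference_mb("A", "A") == 0.0
    assert g.symmetric_difference_mb("B6", "C15") == pytest.approx(100.0)


def test_interval_off_grid_rejected():
    with pytest.raises(ValueError, match="marker grid"):
        make_map({"A": ((12.3, 30.0),)})


# -- ordering ----------------------------------------------------------


def test_two_strains_unique_order():
    g = GenotypeMap(100.0, MARKERS, {"B6": (), "C15": ((0.0, 100.0),)})
    assert order_by_similarity(g) == ["B6", "C15"]


def test_nested_family_orders_by_containment():
    g = make_map(
        {
            "S1": ((70.0, 100.0),),
            "S2": ((50.0, 100.0),),
            "S3": ((30.0, 100.0),),
        }
    )
    assert order_by_similarity(g) == ["B6", "S1", "S2", "S3", "C15"]


def test_ordering_matches_brute_force(rng):
    for _ in range(25):
        g = random_map(rng, int(rng.integers(2, 7)))
        order = order_by_similarity(g)
        assert path_cost(g, order) == pytest.approx(brute_force_min_path(g))
        assert order[0] == "B6" and order[-1] == "C15"


def test_ordering_deterministic_under_ties():
    # identical strains: every order is optimal, lexicographic wins
    g = make_map({"Sa": ((10.0, 50.0),), "Sb": ((10.0, 50.0),)})
    assert order_by_similarity(g) == ["B6", "Sa", "Sb", "C15"]


def test_large_panel_falls_back_to_greedy(rng):
    iv = {f"S{i:02d}": ((float(10 * (1 + i % 8)), 100.0),) for i in range(12)}
    g = make_map(iv)  # 14 strains total
    with pytest.warns(UserWarning, match="greedy"):
        order = order_by_similarity(g)
    assert sorted(order) == sorted(g.strains)


# -- block partition ---------------------------------------------------


def test_single_interior_interval_gives_three_blocks():
    g = GenotypeMap(100.0, MARKERS, {"A": ((30.0, 60.0),)}, host=None, donor=None)
    part = partition_blocks(g)
    assert part.blocks == ((0.0, 30.0), (30.0, 60.0), (60.0, 100.0))
    assert part.names == ["Block1", "Block2", "Block3"]


def test_duplicate_strains_do_not_split_blocks():
    g1 = GenotypeMap(100.0, MARKERS, {"A": ((30.0, 60.0),)}, host=None, donor=None)
    g2 = GenotypeMap(
        100.0, MARKERS, {"A": ((30.0, 60.0),), "B": ((30.0, 60.0),)},
        host=None, donor=None,
    )
    assert partition_blocks(g1).blocks == partition_blocks(g2).blocks


def test_partition_is_tiling_matching_atom_oracle(rng):
    for _ in range(25):
        g = random_map(rng, int(rng.integers(1, 7)))
        part = partition_blocks(g)
        # tiling: contiguous, gap-free, covers [0, L)
        assert part.blocks[0][0] == 0.0
        assert part.blocks[-1][1] == g.chrom_length_mb
        for (_, e1), (s2, _) in zip(part.blocks[:-1], part.blocks[1:]):
            assert e1 == s2
        # brute-force atoms from the endpoint set; merged blocks must
        # align with atom boundaries and differ in pattern
        endpoints = sorted(
            {0.0, g.chrom_length_mb}
            | {p for iv in g.intervals.values() for ab in iv for p in ab}
        )
        block_edges = {p for ab in part.blocks for p in ab}
        assert block_edges <= set(endpoints)
        for (a1, b1), (a2, b2) in zip(part.blocks[:-1], part.blocks[1:]):
            pat1 = tuple(g.covers(s, a1, b1) for s in g.strains)
            pat2 = tuple(g.covers(s, a2, b2) for s in g.strains)
            assert pat1 != pat2  # merging is maximal


def test_default_panel_has_ten_blocks():
    gmap, _ = simulate_subconsomic_panel(SubconsomicSpec(seed=0))
    assert len(partition_blocks(gmap)) == 10


# -- neighbor tests ----------------------------------------------------


def sub_panel(seed=0, **kwargs):
    spec = SubconsomicSpec(seed=seed, **kwargs)
    return simulate_subconsomic_panel(spec)


def test_pair_count_and_threshold():
    gmap, table = sub_panel()
    order = order_by_similarity(gmap)
    report = neighbor_tests(order, table, alpha_family=0.05)
    assert len(report.pairs) == len(order) - 1 == 9
    assert report.threshold == pytest.approx(0.05 / 9)


def test_extra_pair_enters_bonferroni_divisor():
    gmap, table = sub_panel()
    order = order_by_similarity(gmap)
    report = neighbor_tests(
        order, table, alpha_family=0.05, extra_pairs=(("B6", "C15"),)
    )
    assert len(report.pairs) == 10
    assert report.threshold == pytest.approx(0.005)


def test_missing_strain_named_in_error():
    gmap, table = sub_panel()
    order = order_by_similarity(gmap)
    table = table[table["strain"] != "Sub-9"]
    with pytest.raises(KeyError, match="Sub-9"):
        neighbor_tests(order, table)


def test_planted_shift_is_flagged():
    gmap, table = sub_panel()
    order = order_by_similarity(gmap)
    # shift one strain by 8 SD on TbTh
    table = table.copy()
    sd = 0.0015
    table.loc[table["strain"] == "Sub-9", "TbTh"] += 8 * sd
    report = neighbor_tests(order, table, parameters=("TbTh",))
    frame = report.frame
    flagged = frame[frame["significant"]]
    assert set(
        map(tuple, flagged[["strain_a", "strain_b"]].values)
    ) >= {("Sub-10", "Sub-9"), ("Sub-9", "Sub-8")}


def test_null_pairs_rarely_flagged():
    hits = 0
    runs = 60
    for seed in range(runs):
        gmap, table = sub_panel(seed=seed, planted_qtl=[])
        order = order_by_similarity(gmap)
        report = neighbor_tests(order, table, parameters=("BVTV",))
        hits += int(report.frame["significant"].any())
    # 9 tests/run at threshold 0.05/9 -> ~5% of runs show any flag
    assert hits <= int(0.15 * runs)


# -- QTL assignment ----------------------------------------------------


def test_default_architecture_recovered_with_directions():
    """All planted effects are called with the planted directions and
    no call localizes outside the four planted blocks.  (At the
    pairs-only Bonferroni divisor, occasional extra flags on another
    parameter of a truly-different pair are expected and tolerated;
    the rate is quantified in the acceptance suite.)"""
    gmap, table = sub_panel(seed=1)
    order = order_by_similarity(gmap)
    part = partition_blocks(gmap)
    report = neighbor_tests(order, table)
    calls = [c for c in assign_qtl(report, part, gmap) if not c.ambiguous]
    got = {(c.blocks[0], c.parameter, c.direction) for c in calls}
    planted = {
        ("Block2", "TbTh", "increase"),
        ("Block6", "BVTV", "increase"),
        ("Block8", "BVTV", "decrease"),
        ("Block8", "TbN", "decrease"),
        ("Block10", "BVTV", "decrease"),
        ("Block10", "TbN", "decrease"),
    }
    assert planted <= got
    assert {c.blocks[0] for c in calls} == {"Block2", "Block6", "Block8", "Block10"}


def test_multi_block_pair_yields_ambiguous_call():
    gmap, table = sub_panel(seed=2)
    # plant a strong shared shift across the two blocks separating
    # Sub-5 and C15 ([0, 6.64) and [21.75, 26.0))
    table = table.copy()
    table.loc[table["strain"] == "C15", "TbTh"] += 0.02
    order = order_by_similarity(gmap)
    part = partition_blocks(gmap)
    report = neighbor_tests(order, table, parameters=("TbTh",))
    calls = assign_qtl(report, part, gmap)
    amb = [c for c in calls if c.pair == ("Sub-5", "C15")]
    assert len(amb) == 1
    assert amb[0].ambiguous
    assert set(amb[0].blocks) == {"Block1", "Block3"}
    assert amb[0].direction == "increase"  # C15 carries both blocks


def test_identical_genotypes_significant_pair_is_error():
    g = make_map({"Sa": ((10.0, 50.0),), "Sb": ((10.0, 50.0),)})
    rng = np.random.default_rng(0)
    rows = []
    for s, shift in [("B6", 0), ("Sa", 0), ("Sb", 1.0), ("C15", 1.0)]:
        for i in range(6):
            rows.append(
                {
                    "strain": s,
                    "animal_id": f"{s}_{i}",
                    "age_wk": 6,
                    "BVTV": 0.1 + shift + rng.normal(0, 1e-3),
                }
            )
    table = pd.DataFrame(rows)
    order = order_by_similarity(g)
    part = partition_blocks(g)
    report = neighbor_tests(order, table, parameters=("BVTV",))
    with pytest.raises(ValueError, match="identical genotypes"):
        assign_qtl(report, part, g)


def test_lower_alpha_never_adds_calls():
    gmap, table = sub_panel(seed=3)
    order = order_by_similarity(gmap)
    part = partition_blocks(gmap)
    loose = assign_qtl(neighbor_tests(order, table, alpha_family=0.05), part, gmap)
    strict = assign_qtl(neighbor_tests(order, table, alpha_family=0.005), part, gmap)
    key = lambda c: (c.blocks, c.parameter, c.pair)
    assert {key(c) for c in strict} <= {key(c) for c in loose}


# -- simulator contracts ----------------------------------------------


def test_no_planted_qtl_means_equal_control():
    tiny = {k: 1e-6 for k in CONTROL_MEANS_6WK}
    _, table = sub_panel(planted_qtl=[], noise_sd=tiny)
    for _, grp in table.groupby("strain"):
        assert grp["BVTV"].mean() == pytest.approx(CONTROL_MEANS_6WK["BVTV"], abs=1e-5)


def test_planted_qtl_shifts_exactly_covering_strains():
    tiny = {k: 1e-6 for k in CONTROL_MEANS_6WK}
    gmap, table = sub_panel(
        planted_qtl=[((71.63, 84.21), "BVTV", -0.04)], noise_sd=tiny
    )
    shifted = {
        s
        for s, grp in table.groupby("strain")
        if grp["BVTV"].mean() < CONTROL_MEANS_6WK["BVTV"] - 0.02
    }
    covering = {s for s in gmap.strains if gmap.covers(s, 71.63, 84.21)}
    assert shifted == covering == {"Sub-8", "Sub-26", "Sub-25", "Sub-30",
                                  "Sub-11", "Sub-5", "C15"}


def test_misaligned_planted_qtl_rejected():
    with pytest.raises(ValueError, match="marker grid"):
        SubconsomicSpec(planted_qtl=[((10.0, 20.0), "BVTV", -0.04)])
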