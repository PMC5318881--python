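import numpy as np
import pandas as pd
import pytest

from paddyqtl import genoqc, simdata
from paddyqtl.core import GeneticMap, GenotypeMatrix
from paddyqtl.genoqc import QCThresholds
from paddyqtl.qtlmap import inverse_haldane, kosambi


def _gm(df):
    return GenotypeMatrix.from_frame(df)


# ---------------------------------------------------------------------------
# cascade
# ---------------------------------------------------------------------------

def toy_matrix():
    """8 lines x 8 markers with planted defects; survivors are enumerable by
    hand (see test below)."""
    NA = pd.NA
    data = {
        # m1: clean, balanced
        "m1": ["A", "A", "B", "B", "A", "B", "A", "A"],
        # m2: 50% missing -> removed at stage 1 (>= 40%)
        "m2": [NA, "A", NA, NA, NA, "B", "A", "A"],
        # m3: duplicate of m1 -> one of the pair removed at stage 2
        "m3": ["A", "A", "B", "B", "A", "B", "A", "A"],
        # m4: distorted (5/7 A = 71.4% on the reduced pop) -> removed at stage 5
        "m4": ["A", "A", "A", "A", "A", "A", "B", "B"],
        # m5: clean, balanced, other phase
        "m5": ["B", "B", "A", "A", "B", "A", "B", "B"],
        # m6: NA on 4 of the 7 lines left after stage 3 -> 3/7 = 43%
        #     called < 80% -> removed at stage 4
        "m6": ["A", "B", NA, NA, NA, "B", "A", "A"],
        # m7, m8: clean markers that keep line fingerprints distinct
        "m7": ["B", "A", "A", "B", "A", "B", "A", "A"],
        "m8": ["B", "B", "B", "A", "B", "B", "A", "A"],
    }
    idx = [f"l{i}" for i in range(1, 9)]
    df = pd.DataFrame(data, index=idx)
    # l2: heavy heterozygote (H at every clean marker) -> removed at stage 3
    df.loc["l2"] = ["H", "A", "H", "H", "H", "B", "H", "H"]
    # l8 is an exact duplicate of l7 -> removed at stage 6
    df.loc["l8"] = df.loc["l7"]
    return _gm(df)


def test_qc_cascade_matches_hand_enumeration():
    g, report = genoqc.qc_cascade(toy_matrix())
    # Hand enumeration: m2 out (50% missing); m3 out (duplicate of m1);
    # l2 out (5/6 H > 15%); m6 out (3/7 called < 80%); m4 out (5/7 A > 70%);
    # l8 out (duplicate of l7).
    assert g.marker_ids == ["m1", "m5", "m7", "m8"]
    assert g.line_ids == ["l1", "l3", "l4", "l5", "l6", "l7"]
    rep = report.to_frame().set_index("stage")
    assert rep.at["marker_missing", "n_removed"] == 1
    assert rep.at["duplicate_markers", "n_removed"] == 1
    assert rep.at["line_het", "n_removed"] == 1
    assert rep.at["marker_call_rate", "n_removed"] == 1
    assert rep.at["segregation_distortion", "n_removed"] == 1
    assert rep.at["duplicate_individuals", "n_removed"] == 1
    # conservation: in = out + removed at every stage
    assert (rep["n_in"] == rep["n_out"] + rep["n_removed"]).all()


def test_distortion_boundary_is_strict():
    # allele-A fraction exactly 0.30 -> retained
    df = pd.DataFrame(
        {"m1": ["A"] * 3 + ["B"] * 7, "m2": ["A"] * 5 + ["B"] * 5},
        index=[f"l{i}" for i in range(10)],
    )
    g, _ = genoqc.qc_cascade(_gm(df))
    assert "m1" in g.marker_ids


def test_cascade_error_names_stage():
    df = pd.DataFrame({"m1": [pd.NA] * 4}, index=list("abcd"))
    with pytest.raises(genoqc.CascadeError, match="marker_missing"):
        genoqc.qc_cascade(_gm(df))


# ---------------------------------------------------------------------------
# crossover outliers
# ---------------------------------------------------------------------------

def test_crossover_counts_match_switch_oracle(small_pop, small_map):
    counts = genoqc.count_crossovers(small_pop.genotypes, small_map)
    # independent oracle on the first 10 lines via plain python
    for i in range(10):
        total = 0
        for chrom in small_map.chromosomes:
            idx = [small_pop.genotypes.marker_index(m) for m in chrom.markers]
            calls = [small_pop.genotypes.codes[i, j] for j in idx]
            hom = [c for c in calls if c in (0, 2)]
            total += sum(1 for a, b in zip(hom, hom[1:]) if a != b)
        assert counts[i] == total


def test_crossover_outlier_removed():
    gm = simdata.simulate_map(1, 100.0, 2.0)
    pop = simdata.simulate_ril_population(gm, 150, seed=40)
    g = pop.genotypes.copy()
    # corrupt one line with alternating calls -> crossover count explodes
    g.codes[0, ::2] = 0
    g.codes[0, 1::2] = 2
    out, counts = genoqc.crossover_outlier_filter(g, gm, k=3.0)
    assert g.line_ids[0] not in out.line_ids
    assert out.n_lines == g.n_lines - 1 or out.n_lines < g.n_lines


def test_identical_counts_none_removed(small_map):
    df = pd.DataFrame(
        {m: ["A"] * 6 for m in small_map.marker_ids}, index=[f"l{i}" for i in range(6)]
    )
    g = _gm(df)
    out, counts = genoqc.crossover_outlier_filter(g, small_map)
    assert out.n_lines == 6
    assert (counts == 0).all()


# ---------------------------------------------------------------------------
# error LOD
# ---------------------------------------------------------------------------

def _dense_map(n=11, spacing=1.0):
    return simdata.simulate_map(1, (n - 1) * spacing, spacing)


def test_isolated_switch_has_highest_error_lod():
    gm = _dense_map()
    calls = ["A"] * 11
    calls[5] = "B"  # single-marker flip inside a tight A block
    df = pd.DataFrame([calls], columns=gm.marker_ids, index=["l1"])
    scores = genoqc.error_lod_scores(_gm(df), gm, error_rate=0.01)["1"]
    assert scores.columns[np.argmax(scores.iloc[0].to_numpy())] == gm.marker_ids[5]
    # at 1 cM flanks the posterior odds of a miscall are ~25:1 (LOD ~1.4)
    g2, flagged = genoqc.error_lod_filter(_gm(df), gm, error_rate=0.01, lod_cut=1.0)
    assert list(flagged["marker"]) == [gm.marker_ids[5]]
    assert g2.codes[0, 5] == -1


def test_consistent_block_not_flagged():
    gm = _dense_map()
    calls = ["A"] * 5 + ["B"] * 6  # a real crossover, block of >= 5
    df = pd.DataFrame([calls], columns=gm.marker_ids, index=["l1"])
    _, flagged = genoqc.error_lod_filter(_gm(df), gm, error_rate=0.01, lod_cut=4.0)
    assert flagged.empty


def test_error_rate_zero_forbidden(small_pop, small_map):
    with pytest.raises(ValueError):
        genoqc.error_lod_filter(small_pop.genotypes, small_map, error_rate=0.0)


# ---------------------------------------------------------------------------
# droponemarker
# ---------------------------------------------------------------------------

def test_shuffled_marker_inflates_map_and_is_dropped():
    gm = simdata.simulate_map(1, 50.0, 5.0)
    pop = simdata.simulate_ril_population(gm, 400, seed=41)
    g = pop.genotypes.copy()
    rng = np.random.default_rng(42)
    g.codes[:, 5] = rng.permutation(g.codes[:, 5])  # destroy linkage of m6
    out, new_map, dropped = genoqc.droponemarker_filter(g, gm, length_change_cut_cM=5.0)
    assert gm.marker_ids[5] in dropped
    clean_out, _, clean_dropped = genoqc.droponemarker_filter(
        pop.genotypes, gm, length_change_cut_cM=5.0
    )
    assert clean_dropped == []


def test_droponemarker_skips_small_chromosome():
    gm = simdata.simulate_map(1, 0.0, 1.0)
    df = pd.DataFrame({gm.marker_ids[0]: ["A", "B"]}, index=["l1", "l2"])
    with pytest.warns(UserWarning):
        _, _, dropped = genoqc.droponemarker_filter(_gm(df), gm)
    assert dropped == []


# ---------------------------------------------------------------------------
# composite thinning
# ---------------------------------------------------------------------------

def test_composite_thin_prefers_less_missing():
    gm = GeneticMap.from_frame(
        pd.DataFrame(
            {"marker": ["a", "b", "c"], "chrom": ["1"] * 3, "pos_cM": [0.2, 0.7, 1.5]}
        )
    )
    NA = pd.NA
    df = pd.DataFrame(
        {
            "a": ["A", "B", "A", "B", "A", "B", "A", "B", "A", "B"],  # 0% missing
            "b": [NA, "B", "A", "B", "A", "B", "A", "B", "A", "B"],  # 10% missing
            "c": ["A", "B", "A", "B", "A", "B", "A", "B", "A", "B"],
        },
        index=[f"l{i}" for i in range(10)],
    )
    kept = genoqc.composite_thin(_gm(df), gm, window_cM=1.0)
    assert kept == ["a", "c"]  # a beats b in the [0,1) window; c alone in [1,2)


def test_composite_thin_hand_scored_window():
    # 5 markers in one window with graded missingness and distortion
    gm = GeneticMap.from_frame(
        pd.DataFrame(
            {
                "marker": list("abcde"),
                "chrom": ["1"] * 5,
                "pos_cM": [0.1, 0.3, 0.5, 0.7, 0.9],
            }
        )
    )
    NA = pd.NA
    n = 20
    base = ["A", "B"] * 10
    cols = {
        "a": base[:],                      # balanced, complete -> best
        "b": [NA] * 2 + base[2:],          # some missing
        "c": ["A"] * 14 + ["B"] * 6,       # distorted
        "d": [NA] * 4 + base[4:],          # more missing
        "e": ["A"] * 16 + ["B"] * 4,       # more distorted
    }
    df = pd.DataFrame(cols, index=[f"l{i}" for i in range(n)])
    kept = genoqc.composite_thin(_gm(df), gm, window_cM=1.0)
    assert kept == ["a"]


def test_single_marker_window_always_retained():
    gm = GeneticMap.from_frame(
        pd.DataFrame({"marker": ["a"], "chrom": ["1"], "pos_cM": [0.4]})
    )
    df = pd.DataFrame({"a": [pd.NA] * 9 + ["A"]}, index=[f"l{i}" for i in range(10)])
    assert genoqc.composite_thin(_gm(df), gm) == ["a"]


# ---------------------------------------------------------------------------
# grouping / ordering
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def two_chrom_pop():
    gm = simdata.simulate_map(2, 60.0, 5.0)
    pop = simdata.simulate_ril_population(gm, 600, seed=50)
    return gm, pop


def test_grouping_and_order_recovery(two_chrom_pop):
    gm, pop = two_chrom_pop
    est = genoqc.order_and_ripple(pop.genotypes)
    assert len(est.chromosomes) == 2
    for chrom in est.chromosomes:
        # members all come from one true chromosome
        true_chroms = {m.split("m")[0] for m in chrom.markers}
        assert len(true_chroms) == 1
        # order matches the true order up to reflection
        true_idx = [int(m.split("m")[1]) for m in chrom.markers]
        assert true_idx == sorted(true_idx) or true_idx == sorted(true_idx, reverse=True)


def test_order_invariant_to_input_reversal(two_chrom_pop):
    gm, pop = two_chrom_pop
    rev = pop.genotypes.subset(markers=np.arange(pop.genotypes.n_markers)[::-1])
    est = genoqc.order_and_ripple(rev)
    for chrom in est.chromosomes:
        true_idx = [int(m.split("m")[1]) for m in chrom.markers]
        assert true_idx == sorted(true_idx) or true_idx == sorted(true_idx, reverse=True)


def test_estimated_map_length_close_to_truth(two_chrom_pop):
    gm, pop = two_chrom_pop
    est = genoqc.order_and_ripple(pop.genotypes)
    for chrom in est.chromosomes:
        assert chrom.length_cM == pytest.approx(60.0, rel=0.10)


def test_cross_ld_filter_flags_duplicated_chromosome(two_chrom_pop):
    gm, pop = two_chrom_pop
    g = pop.genotypes.copy()
    # copy chromosome-1 markers onto chromosome 2's first marker column
    j_src = g.marker_index("c1m1")
    j_dst = g.marker_index("c2m1")
    g.codes[:, j_dst] = g.codes[:, j_src]
    dropped = genoqc.cross_ld_filter(g, gm, max_abs_r=0.7)
    assert {"c1m1", "c2m1"} & set(dropped)
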