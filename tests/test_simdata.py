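import numpy as np
import pandas as pd
import pytest

from paddyqtl import simdata
from paddyqtl.genoqc import estimate_rf
from paddyqtl.qtlmap import inverse_haldane


# ---------------------------------------------------------------------------
# map
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "n_chr,length,spacing,n_expected",
    [(1, 100.0, 10.0, 11), (12, 120.0, 1.0, 1452), (1, 0.0, 1.0, 1)],
)
def test_simulate_map_marker_counts(n_chr, length, spacing, n_expected):
    gm = simdata.simulate_map(n_chr, length, spacing)
    assert gm.n_markers == n_expected
    first = gm.chromosomes[0]
    assert first.positions[0] == 0.0
    if length > 0:
        assert first.positions[-1] == pytest.approx(length)


def test_simulate_map_bad_spacing():
    with pytest.raises(ValueError):
        simdata.simulate_map(1, 100.0, 0.0)


# ---------------------------------------------------------------------------
# RIL meiosis
# ---------------------------------------------------------------------------

def test_zero_length_heterozygosity_matches_selfing_recursion():
    # single locus: expected residual heterozygosity (1/2)^(g-1)
    gm = simdata.simulate_map(1, 0.0, 1.0)
    n = 8000
    pop = simdata.simulate_ril_population(gm, n, generation=7, seed=3)
    h = float((pop.genotypes.codes == 1).mean())
    p = 0.5**6
    sd = np.sqrt(p * (1 - p) / n)
    assert abs(h - p) < 3 * sd


@pytest.mark.parametrize("generation", [2, 3, 5])
def test_heterozygosity_halves_each_generation(generation):
    gm = simdata.simulate_map(1, 0.0, 1.0)
    n = 12000
    pop = simdata.simulate_ril_population(gm, n, generation=generation, seed=4)
    h = float((pop.genotypes.codes == 1).mean())
    p = 0.5 ** (generation - 1)
    sd = np.sqrt(p * (1 - p) / n)
    assert abs(h - p) < 3 * sd


def test_unlinked_chromosomes_recombine_freely():
    gm = simdata.simulate_map(2, 0.0, 1.0)
    pop = simdata.simulate_ril_population(gm, 2000, generation=7, seed=5)
    codes = pop.genotypes.codes
    hom = ((codes[:, 0] == 0) | (codes[:, 0] == 2)) & ((codes[:, 1] == 0) | (codes[:, 1] == 2))
    mismatch = float(np.mean(codes[hom, 0] != codes[hom, 1]))
    assert abs(mismatch - 0.5) <= 0.02  # sampling bound at n≈2000


def test_linked_pair_matches_haldane_transform():
    # simulation is interference-free, so the estimated meiotic r at 10 cM
    # should match the inverse Haldane transform within sampling error
    gm = simdata.simulate_map(1, 10.0, 10.0)
    n = 4000
    pop = simdata.simulate_ril_population(gm, n, generation=7, seed=6)
    r_hat = estimate_rf(pop.genotypes, 0, 1)
    r_true = float(inverse_haldane(10.0))
    # delta-method bound on the RIL-corrected estimate
    R_true = 2 * r_true / (1 + 2 * r_true)
    sd_R = np.sqrt(R_true * (1 - R_true) / n)
    sd_r = sd_R / (2 * (1 - R_true) ** 2)
    assert abs(r_hat - r_true) < 4 * sd_r


def test_mosaic_blocks_and_determinism(small_map):
    pop1 = simdata.simulate_ril_population(small_map, 50, seed=9)
    pop2 = simdata.simulate_ril_population(small_map, 50, seed=9)
    assert np.array_equal(pop1.genotypes.codes, pop2.genotypes.codes)
    pop3 = simdata.simulate_ril_population(small_map, 50, seed=10)
    assert not np.array_equal(pop1.genotypes.codes, pop3.genotypes.codes)


def test_ril_argument_errors(small_map):
    with pytest.raises(ValueError):
        simdata.simulate_ril_population(small_map, 0)
    with pytest.raises(ValueError):
        simdata.simulate_ril_population(small_map, 5, generation=1)


# ---------------------------------------------------------------------------
# genotyping noise
# ---------------------------------------------------------------------------

def test_noise_identity(small_pop):
    out = simdata.inject_genotyping_noise(small_pop.genotypes, 0.0, 0.0, 0)
    assert np.array_equal(out.codes, small_pop.genotypes.codes)


def test_noise_masking_binomial(small_map):
    pop = simdata.simulate_ril_population(small_map, 1000, seed=12)
    g = pop.genotypes.subset(markers=np.arange(min(100, pop.genotypes.n_markers)))
    out = simdata.inject_genotyping_noise(g, missing_rate=0.2, seed=13)
    n_masked = int((out.codes == -1).sum()) - int((g.codes == -1).sum())
    total = g.codes.size
    exp = 0.2 * total
    sd = np.sqrt(total * 0.2 * 0.8)
    assert abs(n_masked - exp) < 4 * sd


def test_duplicate_markers_similar(small_pop):
    ledger = simdata.TruthLedger()
    out = simdata.inject_genotyping_noise(
        small_pop.genotypes, dup_pairs=5, seed=14, ledger=ledger
    )
    assert out.n_markers == small_pop.genotypes.n_markers + 5
    assert len(ledger.dup_markers) == 5
    for dup, src in ledger.dup_markers.items():
        a = out.codes[:, out.marker_index(dup)]
        b = out.codes[:, out.marker_index(src)]
        assert (a == b).mean() >= 0.99


def test_noise_rate_bounds(small_pop):
    with pytest.raises(ValueError):
        simdata.inject_genotyping_noise(small_pop.genotypes, missing_rate=1.0)


# ---------------------------------------------------------------------------
# layout
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def tiny_layout():
    cfg = simdata.SimConfig(
        seed=2, n_ril=300, n_chr=2, chr_length_cM=50.0, marker_spacing_cM=10.0,
        n_rows=10, n_cols=16, n_dup_ril=10, n_cohorts=2,
        qtls=[simdata.QTLTruth("1", 20.0, "height_cm", 28.0)],
    )
    gm = simdata.simulate_map(cfg.n_chr, cfg.chr_length_cM, cfg.marker_spacing_cM)
    pop = simdata.simulate_ril_population(gm, cfg.n_ril, seed=cfg.seed,
                                          extra_loci=[("1", 20.0, "1@20.0")])
    return cfg, pop, simdata.generate_layout(pop, cfg)


def test_layout_counts_and_conservation(tiny_layout):
    cfg, pop, layout = tiny_layout
    planted = layout[layout["entry_type"] != "WATER"]
    capacity = cfg.n_fields * cfg.n_rows * cfg.n_cols
    per_cohort = planted.groupby("cohort").size()
    assert (per_cohort == capacity).all()
    # every entry appears its designated number of times per cohort
    for _, grp in planted.groupby("cohort"):
        counts = grp["entry_id"].value_counts()
        assert (counts <= 2).all()
        assert (counts == 2).sum() == cfg.n_dup_ril
    # each block contains a replicated entry
    for _, grp in planted.groupby(["cohort", "block"]):
        assert grp["entry_id"].duplicated().any()


def test_layout_geometry(tiny_layout):
    _, _, layout = tiny_layout
    area = (layout["x_max"] - layout["x_min"]) * (layout["y_max"] - layout["y_min"])
    assert np.allclose(area, 1.2)
    planted = layout[layout["entry_type"] != "WATER"]
    assert (planted["n_hills"] == 30).all()
    # non-overlap within each cohort-field
    for _, grp in layout.groupby(["cohort", "field"]):
        boxes = grp[["x_min", "y_min", "x_max", "y_max"]].to_numpy()
        order = np.lexsort((boxes[:, 1], boxes[:, 0]))
        boxes = boxes[order]
        for i in range(len(boxes) - 1):
            a, b = boxes[i], boxes[i + 1]
            overlap = (
                a[0] < b[2] and b[0] < a[2] and a[1] < b[3] and b[1] < a[3]
            )
            assert not overlap


def test_layout_overflow():
    cfg = simdata.SimConfig(n_ril=300, n_rows=5, n_cols=16, n_chr=1,
                            chr_length_cM=50.0, marker_spacing_cM=10.0,
                            qtls=[simdata.QTLTruth("1", 20.0, "height_cm", 28.0)])
    gm = simdata.simulate_map(cfg.n_chr, cfg.chr_length_cM, cfg.marker_spacing_cM)
    pop = simdata.simulate_ril_population(gm, 300, seed=1, extra_loci=[("1", 20.0, "1@20.0")])
    with pytest.raises(simdata.LayoutError):
        simdata.generate_layout(pop, cfg)


# ---------------------------------------------------------------------------
# traits
# ---------------------------------------------------------------------------

def _noise_free_config(**kw):
    zero = {t: 0.0 for t in simdata.ALL_TRAITS}
    base = dict(
        seed=7, n_ril=60, n_chr=1, chr_length_cM=60.0, marker_spacing_cM=10.0,
        n_rows=4, n_cols=16, n_dup_ril=2, n_cohorts=1,
        qtls=[simdata.QTLTruth("1", 30.0, "height_cm", 10.0)],
        polygenic_sd=dict(zero), plot_noise_sd=dict(zero),
        block_effect_sd=dict(zero),
        cohort_effect={t: (0.0, 0.0, 0.0) for t in simdata.ALL_TRAITS},
        plant_sd={"height_cm": 0.0, "biomass_g": 0.0, "grain_g": 0.0},
        sparse_plot_rate=0.0,
    )
    base.update(kw)
    return simdata.SimConfig(**base)


def test_noise_free_two_phenotype_classes():
    # all variances zero, one QTL of effect a: homozygote classes sit 2a apart
    cfg = _noise_free_config()
    gm = simdata.simulate_map(1, 60.0, 10.0)
    pop = simdata.simulate_ril_population(gm, cfg.n_ril, seed=cfg.seed,
                                          extra_loci=[("1", 30.0, "1@30.0")])
    layout = simdata.generate_layout(pop, cfg)
    truth = simdata.simulate_traits(pop, layout, cfg)
    lay = truth.layout
    ril_plots = lay[lay["entry_type"] == "RIL"]
    vals = truth.plot_static("height_cm").loc[ril_plots["plot_id"]]
    dosage = truth.entry_dosage["1@30.0"].loc[ril_plots["entry_id"]].to_numpy()
    hom = np.abs(dosage) == 1
    classes = np.unique(np.round(vals.to_numpy()[hom], 9))
    assert len(classes) == 2
    assert classes[1] - classes[0] == pytest.approx(20.0)


def test_unknown_trait_raises():
    cfg = _noise_free_config(qtls=[simdata.QTLTruth("1", 30.0, "no_such_trait", 1.0)])
    gm = simdata.simulate_map(1, 60.0, 10.0)
    pop = simdata.simulate_ril_population(gm, cfg.n_ril, seed=1,
                                          extra_loci=[("1", 30.0, "1@30.0")])
    with pytest.raises(KeyError):
        simdata.generate_layout(pop, cfg)


def test_ndvi_trajectory_rises_then_falls():
    cfg = _noise_free_config()
    gm = simdata.simulate_map(1, 60.0, 10.0)
    pop = simdata.simulate_ril_population(gm, cfg.n_ril, seed=cfg.seed,
                                          extra_loci=[("1", 30.0, "1@30.0")])
    layout = simdata.generate_layout(pop, cfg)
    truth = simdata.simulate_traits(pop, layout, cfg)
    plots = truth.layout.loc[truth.layout["entry_type"] == "RIL", "plot_id"][:5]
    das = np.array([40.0, 80.0, 130.0])
    v = truth.plot_ndvi(plots, das)
    assert (v[:, 1] > v[:, 0]).all() and (v[:, 1] > v[:, 2]).all()


# ---------------------------------------------------------------------------
# sensor stream
# ---------------------------------------------------------------------------

def test_stream_deterministic_and_flat_canopy_distance():
    cfg = _noise_free_config(
        boom_height_m=1.5,
        reflectance_noise_frac=0.0, temp_noise_C=0.0,
        ultrasonic_noise_m=0.0, gps_height_noise_m=0.0,
        band_gain_range=(1.0, 1.0), temp_offset_range_C=(0.0, 0.0),
        slow_segment_rate=0.0, reverse_segment_rate=0.0, dropout_rate=0.0,
        trait_means={**simdata.SimConfig().trait_means, "height_cm": 100.0},
        qtls=[simdata.QTLTruth("1", 30.0, "height_cm", 0.0)],
    )
    gm = simdata.simulate_map(1, 60.0, 10.0)
    pop = simdata.simulate_ril_population(gm, cfg.n_ril, seed=cfg.seed,
                                          extra_loci=[("1", 30.0, "1@30.0")])
    layout = simdata.generate_layout(pop, cfg)
    truth = simdata.simulate_traits(pop, layout, cfg)
    day = 150  # canopy at its final 1.0 m height
    s1 = simdata.generate_sensor_stream(layout, truth, day, cfg, seed=21)
    s2 = simdata.generate_sensor_stream(layout, truth, day, cfg, seed=21)
    pd.testing.assert_frame_equal(s1, s2)
    # over planted plots the ultrasonic distance is boom - canopy = 0.5 m
    planted = truth.layout[truth.layout["entry_type"] == "RIL"]
    y_mid = planted.iloc[0][["y_min", "y_max"]].mean()
    col = planted.iloc[0]["col"]
    sensor = (col - 1) % 8 + 1
    grp = (col - 1) // 8
    mask = (np.abs(s1[f"s{sensor}_y"] - y_mid) < 0.3) & s1["pass_id"].str.endswith(f"g{grp + 1}")
    dist = s1.loc[mask, f"s{sensor}_dist_m"]
    assert len(dist) > 0
    assert np.allclose(dist, 0.5, atol=5e-3)


def test_stream_artifacts_recorded():
    cfg = _noise_free_config(slow_segment_rate=1.0, reverse_segment_rate=1.0)
    gm = simdata.simulate_map(1, 60.0, 10.0)
    pop = simdata.simulate_ril_population(gm, cfg.n_ril, seed=cfg.seed,
                                          extra_loci=[("1", 30.0, "1@30.0")])
    layout = simdata.generate_layout(pop, cfg)
    truth = simdata.simulate_traits(pop, layout, cfg)
    stream = simdata.generate_sensor_stream(layout, truth, 90, cfg, seed=3)
    kinds = {a["kind"] for a in truth.ledger.artifacts}
    assert {"slow", "reverse"} <= kinds
    assert (stream["speed_kph"] < 0.3).any()
    # reverse segments show decreasing y on a forward pass
    fwd = stream[stream["heading_deg"] == 0.0]
    assert (np.diff(fwd["y"].to_numpy()) < 0).any()
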