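"""Synthetic rice RIL field-trial generator with a ground-truth ledger.

Everything the analysis pipeline consumes can be simulated here: a genetic
map, an F7 recombinant-inbred population segregating at planted QTL, a
three-cohort / two-field / eight-block plot layout, per-plot trait
trajectories, manual phenotyping samples, and 5 Hz tractor sensor streams
with per-sensor biases and deliberate filter-triggering artifacts.

The simulated world (defaults):

* 1,516 F7 RILs from IR64 (A parent) x Aswina (B parent), single-seed
  descent, no crossover interference (Poisson crossovers, i.e. Haldane at
  the meiotic level).  Dosage convention: A = -1, H = 0, B = +1.
* Two adjacent fields of 49 rows x 16 plot columns per cohort; 1.0 m x 1.2 m
  plots of 30 hills on 0.20 m centres; unplanted water-reference strips at
  both ends of each field; cohort sowings offset 14 days.
* A large-effect height locus (+28 cm per Aswina allele) and a yield locus
  with a time-varying NDVI signature peaking near 90 days after sowing,
  plus smaller loci spanning all grain/harvest-index effect quadrants.
* Eight canopy sensor sets with multiplicative band gains and additive
  canopy-temperature offsets (sensor 1 is the unbiased reference), Gaussian
  sensor noise, and artifact segments (slow or reversing tractor, sparse
  plots, record dropout) that the downstream filters must catch.

Every random draw flows from one seed through named substreams, and every
injected bias or artifact is recorded on the :class:`TruthLedger`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from paddyqtl.core import (
    CODE_A,
    CODE_B,
    CODE_H,
    CODE_MISSING,
    Chromosome,
    GeneticMap,
    GenotypeMatrix,
    rng_for,
)

MPS_PER_KPH = 1000.0 / 3600.0

PLOT_W = 1.0  # m, across travel (5 hills at 0.20 m)
PLOT_L = 1.2  # m, along travel (6 hills at 0.20 m)
N_HILLS = 30
SENSORS_PER_BOOM = 8
BANDS = ("nir", "re", "red")


# ---------------------------------------------------------------------------
# configuration and truth containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConstantProfile:
    """Time-constant QTL effect (end-of-season traits)."""

    def __call__(self, das):
        return np.ones_like(np.asarray(das, dtype=float))


@dataclass(frozen=True)
class PeakProfile:
    """Gaussian-bump effect profile in [0, 1], peaking at ``peak_das``."""

    peak_das: float
    width_days: float

    def __call__(self, das):
        das = np.asarray(das, dtype=float)
        return np.exp(-0.5 * ((das - self.peak_das) / self.width_days) ** 2)


@dataclass(frozen=True)
class QTLTruth:
    """A planted QTL: signed additive effect of the Aswina (B) allele."""

    chrom: str
    pos_cM: float
    trait: str
    additive_effect: float
    profile: object = field(default_factory=ConstantProfile)

    @property
    def label(self) -> str:
        return f"{self.chrom}@{self.pos_cM:.1f}"


def default_qtls() -> list[QTLTruth]:
    """The planted architecture: a major height locus, a yield locus with a
    time-varying NDVI signature, and smaller grain/harvest-index loci that
    populate all four effect quadrants."""
    peak = PeakProfile(90.0, 15.0)
    return [
        QTLTruth("1", 100.0, "height_cm", 28.0),
        QTLTruth("3", 10.0, "grain_g", 1.8),
        QTLTruth("3", 10.0, "ndvi", 0.035, peak),
        QTLTruth("3", 10.0, "hi", 0.020),
        QTLTruth("2", 60.0, "grain_g", 0.9),
        QTLTruth("2", 60.0, "hi", 0.012),
        QTLTruth("5", 35.0, "grain_g", 0.7),
        QTLTruth("5", 35.0, "hi", 0.008),
        QTLTruth("7", 80.0, "grain_g", 0.6),
        QTLTruth("7", 80.0, "hi", 0.010),
        QTLTruth("4", 50.0, "grain_g", -1.1),
        QTLTruth("4", 50.0, "hi", -0.015),
        QTLTruth("6", 20.0, "grain_g", -0.8),
        QTLTruth("6", 20.0, "hi", -0.010),
        QTLTruth("8", 55.0, "hi", 0.009),
        QTLTruth("9", 40.0, "hi", -0.007),
        QTLTruth("1", 100.0, "biomass_g", 6.0),
        QTLTruth("3", 10.0, "dth_days", 2.5),
    ]


@dataclass
class SimConfig:
    """All knobs of the simulated trial, with the stated-world defaults."""

    seed: int = 0
    # population
    n_ril: int = 1516
    generation: int = 7
    n_chr: int = 12
    chr_length_cM: float = 120.0
    marker_spacing_cM: float = 5.0
    # layout
    n_cohorts: int = 3
    n_fields: int = 2
    n_rows: int = 49
    n_cols: int = 16
    n_blocks: int = 8
    n_dup_ril: int = 42
    cohort_offset_days: int = 14
    # trait model (per-plant / per-plot units)
    qtls: list = field(default_factory=default_qtls)
    trait_means: dict = field(
        default_factory=lambda: {
            "height_cm": 130.0,
            "dth_days": 85.0,
            "biomass_g": 40.0,
            "grain_g": 20.0,
            "hi": 0.33,
            "ndvi": 0.0,
            "ctd_C": 2.0,
        }
    )
    polygenic_sd: dict = field(
        default_factory=lambda: {
            "height_cm": 8.0,
            "dth_days": 4.0,
            "biomass_g": 4.0,
            "grain_g": 1.5,
            "hi": 0.02,
            "ndvi": 0.03,
            "ctd_C": 0.3,
        }
    )
    plot_noise_sd: dict = field(
        default_factory=lambda: {
            "height_cm": 3.0,
            "dth_days": 1.5,
            "biomass_g": 3.0,
            "grain_g": 1.2,
            "hi": 0.015,
            "ndvi": 0.015,
            "ctd_C": 0.4,
        }
    )
    plant_sd: dict = field(
        default_factory=lambda: {"height_cm": 5.0, "biomass_g": 5.0, "grain_g": 2.0}
    )
    cohort_effect: dict = field(
        default_factory=lambda: {
            "height_cm": (0.0, -2.0, 2.0),
            "dth_days": (0.0, 1.0, -1.0),
            "biomass_g": (0.0, -1.5, 1.5),
            "grain_g": (0.0, -0.8, 0.5),
            "hi": (0.0, 0.0, 0.0),
            "ndvi": (0.0, -0.01, 0.01),
            "ctd_C": (0.0, 0.0, 0.0),
        }
    )
    block_effect_sd: dict = field(
        default_factory=lambda: {
            "height_cm": 2.0,
            "dth_days": 1.0,
            "biomass_g": 1.5,
            "grain_g": 0.6,
            "hi": 0.005,
            "ndvi": 0.008,
            "ctd_C": 0.2,
        }
    )
    # canopy / sensor model
    brightness: float = 0.55  # NIR + red total reflectance scale
    soil_ndvi: float = 0.12
    boom_height_m: float = 2.8
    speed_kph: float = 1.0
    sample_hz: float = 5.0
    air_temp_C: float = 31.0
    water_temp_C: float = 24.0
    rh_pct: float = 72.0
    par: float = 1500.0
    band_gain_range: tuple = (0.9, 1.1)
    temp_offset_range_C: tuple = (-1.0, 1.0)
    reflectance_noise_frac: float = 0.01
    temp_noise_C: float = 0.3
    ultrasonic_noise_m: float = 0.02
    gps_height_noise_m: float = 0.01
    # artifacts
    slow_segment_rate: float = 0.3  # per pass
    reverse_segment_rate: float = 0.2  # per pass
    sparse_plot_rate: float = 0.01  # plots with <13 plants
    dropout_rate: float = 0.002  # record dropout
    # HTP sampling days (trial days from cohort-1 sowing; 11 dates)
    htp_days: tuple = (54, 61, 68, 75, 78, 85, 90, 97, 104, 111, 118)
    panicle_cohorts: tuple = (3,)


@dataclass
class TruthLedger:
    """Everything injected into the simulation, retrievable for oracles."""

    qtls: list = field(default_factory=list)
    band_gains: np.ndarray | None = None  # (8, 3) relative to sensor 1
    temp_offsets: np.ndarray | None = None  # (8,) degrees C
    artifacts: list = field(default_factory=list)  # dicts per artifact
    sparse_plots: list = field(default_factory=list)
    dup_markers: dict = field(default_factory=dict)
    masked_calls: int = 0
    flipped_calls: int = 0


# ---------------------------------------------------------------------------
# genetic map and RIL meiosis
# ---------------------------------------------------------------------------

def simulate_map(n_chr: int, lengths_cM, marker_spacing: float) -> GeneticMap:
    """Evenly spaced marker map; deterministic.

    ``lengths_cM`` may be a scalar (shared length) or one length per
    chromosome.  A zero-length chromosome carries a single marker at 0.
    """
    if marker_spacing <= 0:
        raise ValueError("marker spacing must be positive")
    lengths = np.broadcast_to(np.asarray(lengths_cM, dtype=float), (n_chr,))
    if np.any(lengths < 0):
        raise ValueError("chromosome lengths must be non-negative")
    chroms = []
    for i, L in enumerate(lengths, start=1):
        pos = np.arange(0.0, L + 1e-9, marker_spacing)
        if len(pos) == 0:
            pos = np.array([0.0])
        markers = tuple(f"c{i}m{j + 1}" for j in range(len(pos)))
        chroms.append(Chromosome(str(i), markers, pos))
    return GeneticMap(tuple(chroms))


@dataclass
class RILPopulation:
    """Genotyped RIL population plus hidden dosages at planted QTL."""

    genotypes: GenotypeMatrix
    generation: int
    parent_labels: tuple = ("IR64-like", "Aswina-like")
    qtl_dosage: pd.DataFrame | None = None  # lines x QTL labels, in {-1, 0, +1}
    crossover_counts: np.ndarray | None = None  # planted crossovers per line


def _gamete(rng, pos: np.ndarray, length_cM: float, h0: np.ndarray, h1: np.ndarray):
    """One meiotic product: Poisson crossovers, uniform placement."""
    n_xo = rng.poisson(length_cM / 100.0)
    start = rng.integers(2)
    if n_xo == 0:
        return (h0 if start == 0 else h1).copy(), 0
    xo = np.sort(rng.uniform(0.0, length_cM, n_xo))
    parity = (np.searchsorted(xo, pos, side="right") + start) % 2
    return np.where(parity == 0, h0, h1), n_xo


def simulate_ril_population(
    gmap: GeneticMap,
    n_ril: int,
    generation: int = 7,
    seed: int = 0,
    extra_loci: list | None = None,
) -> RILPopulation:
    """Simulate F_n RILs by single seed descent from an F1.

    Crossovers are Poisson in map length (Morgans) with uniform placement —
    no interference — so the meiotic process is Haldane even though map
    estimation downstream uses Kosambi; the mismatch is small below ~20 cM.

    ``extra_loci`` is a list of (chrom, pos_cM, label) hidden loci (planted
    QTL) whose final dosages are reported but never genotyped.
    """
    if n_ril < 1:
        raise ValueError("n_ril must be >= 1")
    if generation < 2:
        raise ValueError("generation must be >= 2 (F2 is the first selfed one)")
    rng = rng_for(seed, "meiosis")
    extra = extra_loci or []
    line_ids = [f"RIL{i + 1:04d}" for i in range(n_ril)]
    codes_parts, marker_parts = [], []
    hidden: dict[str, np.ndarray] = {lab: np.zeros(n_ril) for _, _, lab in extra}
    xo_counts = np.zeros(n_ril, dtype=int)
    for chrom in gmap.chromosomes:
        ex_here = [(p, lab) for c, p, lab in extra if c == chrom.name]
        pos = np.concatenate([chrom.positions, [p for p, _ in ex_here]])
        order = np.argsort(pos, kind="stable")
        pos_sorted = pos[order]
        n_m = chrom.n_markers
        L = max(chrom.length_cM, float(pos_sorted[-1]) if len(pos_sorted) else 0.0)
        geno = np.empty((n_ril, len(pos_sorted)), dtype=np.int8)
        for i in range(n_ril):
            h0 = np.zeros(len(pos_sorted), dtype=np.int8)
            h1 = np.ones(len(pos_sorted), dtype=np.int8)
            n_xo_line = 0
            for _ in range(generation - 1):
                g0, k0 = _gamete(rng, pos_sorted, L, h0, h1)
                g1, k1 = _gamete(rng, pos_sorted, L, h0, h1)
                h0, h1 = g0, g1
                n_xo_line += k0 + k1
            geno[i] = h0 + h1  # 0=AA, 1=H, 2=BB matches the call coding
            xo_counts[i] += n_xo_line
        inv = np.empty_like(order)
        inv[order] = np.arange(len(order))
        codes_parts.append(geno[:, inv[:n_m]])
        marker_parts.extend(chrom.markers)
        for j, (_, lab) in enumerate(ex_here):
            col = inv[n_m + j]
            hidden[lab] = geno[:, col].astype(float) - 1.0
    codes = np.concatenate(codes_parts, axis=1)
    qtl_dos = pd.DataFrame(hidden, index=line_ids) if hidden else None
    return RILPopulation(
        GenotypeMatrix(codes, line_ids, list(marker_parts)),
        generation,
        qtl_dosage=qtl_dos,
        crossover_counts=xo_counts,
    )


def inject_genotyping_noise(
    genotypes: GenotypeMatrix,
    missing_rate: float = 0.0,
    error_rate: float = 0.0,
    dup_pairs: int = 0,
    seed: int = 0,
    ledger: TruthLedger | None = None,
) -> GenotypeMatrix:
    """Mask calls, flip homozygote calls, and append near-duplicate markers.

    Duplicated columns are >= 99% similar to their source and named
    ``<src>_dup``; provenance is recorded on the ledger.
    """
    for r, name in ((missing_rate, "missing_rate"), (error_rate, "error_rate")):
        if not 0 <= r < 1:
            raise ValueError(f"{name} must lie in [0, 1)")
    rng = rng_for(seed, "genonoise")
    codes = genotypes.codes.copy()
    n, m = codes.shape
    flipped = 0
    if error_rate > 0:
        flip = (rng.random((n, m)) < error_rate) & (codes != CODE_MISSING)
        # homozygote miscalls swap parents; het miscalls become a homozygote
        new = np.where(codes == CODE_A, CODE_B, CODE_A).astype(np.int8)
        codes[flip] = new[flip]
        flipped = int(flip.sum())
    masked = 0
    if missing_rate > 0:
        mask = rng.random((n, m)) < missing_rate
        codes[mask] = CODE_MISSING
        masked = int(mask.sum())
    marker_ids = list(genotypes.marker_ids)
    dup_map: dict[str, str] = {}
    if dup_pairs > 0:
        src = rng.choice(m, size=dup_pairs, replace=False)
        extra = np.empty((n, dup_pairs), dtype=np.int8)
        for k, j in enumerate(src):
            col = codes[:, j].copy()
            n_flip = max(0, int(math.floor(0.005 * n)))  # keep >= 99% similar
            if n_flip:
                rows = rng.choice(n, size=n_flip, replace=False)
                col[rows] = np.where(col[rows] == CODE_A, CODE_B, CODE_A)
            extra[:, k] = col
            dup_map[f"{marker_ids[j]}_dup"] = marker_ids[j]
        codes = np.concatenate([codes, extra], axis=1)
        marker_ids = marker_ids + list(dup_map.keys())
    if ledger is not None:
        ledger.dup_markers.update(dup_map)
        ledger.masked_calls += masked
        ledger.flipped_calls += flipped
    return GenotypeMatrix(codes, list(genotypes.line_ids), marker_ids)


# ---------------------------------------------------------------------------
# entry genetics and layout
# ---------------------------------------------------------------------------

ALL_TRAITS = ("height_cm", "dth_days", "biomass_g", "grain_g", "hi", "ndvi", "ctd_C")


class LayoutError(ValueError):
    pass


def compute_entry_genetics(
    pop: RILPopulation, config: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-entry genetic values and QTL dosages for RILs, parents and checks.

    Returns (genetic values: entries x traits, dosages: entries x QTL labels).
    Checks are deterministic mid-scale entries; parents sit at dosage -1
    (IR64) and +1 (Aswina) for every QTL.
    """
    rng = rng_for(config.seed, "entrygen")
    qtls = config.qtls
    unknown = sorted({q.trait for q in qtls} - set(ALL_TRAITS))
    if unknown:
        raise KeyError(f"QTL configured for unknown trait(s): {unknown}")
    labels = sorted({q.label for q in qtls})
    if pop.qtl_dosage is None or not set(labels) <= set(pop.qtl_dosage.columns):
        raise ValueError("population lacks hidden dosages for the configured QTL")
    ril_ids = list(pop.genotypes.line_ids)
    capacity = config.n_fields * config.n_rows * config.n_cols
    n_checks = capacity - len(ril_ids) - config.n_dup_ril - 2
    if n_checks < 0:
        raise LayoutError(
            f"{len(ril_ids)} RILs (+{config.n_dup_ril} duplicates, 2 parents) "
            f"do not fit {capacity} plots"
        )
    entries = ril_ids + ["IR64", "ASWINA"] + [f"CHECK{i + 1:02d}" for i in range(n_checks)]
    dos = pd.DataFrame(0.0, index=entries, columns=labels)
    dos.loc[ril_ids] = pop.qtl_dosage[labels].to_numpy()
    dos.loc["IR64"] = -1.0
    dos.loc["ASWINA"] = 1.0
    gen = pd.DataFrame(0.0, index=entries, columns=list(ALL_TRAITS))
    for trait in ALL_TRAITS:
        g = np.full(len(entries), config.trait_means.get(trait, 0.0))
        for q in qtls:
            if q.trait == trait:
                g = g + q.additive_effect * dos[q.label].to_numpy()
        poly = rng.normal(0.0, config.polygenic_sd.get(trait, 0.0), len(entries))
        poly[len(ril_ids) :] = 0.0  # parents/checks: no polygenic draw
        gen[trait] = g + poly
    return gen, dos


def generate_layout(
    pop: RILPopulation, config: SimConfig, entry_genetics: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Cohort/field/block/plot layout with height-based blocking.

    Entries are ranked by true genetic height and split into ``n_blocks``
    blocks (contiguous plot runs in field order); duplicated RILs occupy two
    plots inside their block; the same entry set is re-randomised per cohort;
    sowing dates are offset by ``cohort_offset_days``.  Water-reference
    plots (unplanted) span both ends of every field.
    """
    if entry_genetics is None:
        entry_genetics, _ = compute_entry_genetics(pop, config)
    rng = rng_for(config.seed, "layout")
    capacity = config.n_fields * config.n_rows * config.n_cols
    n_ril = pop.genotypes.n_lines
    ril_ids = list(pop.genotypes.line_ids)
    n_dup = config.n_dup_ril
    if n_dup > n_ril:
        raise LayoutError("more duplicated RILs than RILs")
    # duplicated entries: evenly spaced in height rank so each block has some
    height = entry_genetics["height_cm"]
    ril_rank = height.loc[ril_ids].sort_values(kind="stable").index
    dup_ids = list(ril_rank[np.linspace(0, n_ril - 1, n_dup, dtype=int)]) if n_dup else []
    plot_entries = list(entry_genetics.index) + dup_ids
    if len(plot_entries) != capacity:
        raise LayoutError(f"{len(plot_entries)} planted plots vs capacity {capacity}")
    order = np.argsort(height.loc[plot_entries].to_numpy(), kind="stable")
    ranked = [plot_entries[i] for i in order]
    block_sizes = np.full(config.n_blocks, capacity // config.n_blocks)
    block_sizes[: capacity % config.n_blocks] += 1
    rows = []
    field_w = config.n_cols * PLOT_W
    bund = 3.0
    for cohort in range(1, config.n_cohorts + 1):
        cohort_x0 = (cohort - 1) * (config.n_fields * (field_w + bund) + 10.0)
        # plot positions in field-major, row-major order
        positions = [
            (f, r, c)
            for f in range(1, config.n_fields + 1)
            for r in range(1, config.n_rows + 1)
            for c in range(1, config.n_cols + 1)
        ]
        assigned = []
        start = 0
        for b, size in enumerate(block_sizes, start=1):
            blk = ranked[start : start + size]
            perm = rng.permutation(len(blk))
            assigned.extend((b, blk[i]) for i in perm)
            start += size
        sowing = (cohort - 1) * config.cohort_offset_days
        for (f, r, c), (b, entry) in zip(positions, assigned):
            x0 = cohort_x0 + (f - 1) * (field_w + bund) + (c - 1) * PLOT_W
            y0 = round((r - 1) * PLOT_L, 9)
            y1 = round(r * PLOT_L, 9)
            etype = (
                "PARENT"
                if entry in ("IR64", "ASWINA")
                else "CHECK"
                if entry.startswith("CHECK")
                else "RIL"
            )
            rows.append(
                (cohort, f, b, r, c, entry, etype, N_HILLS, x0, y0, x0 + PLOT_W, y1, sowing)
            )
        # water strips: one unplanted plot per column at each end of each field
        for f in range(1, config.n_fields + 1):
            for end, y0, y1 in (
                ("S", -PLOT_L, 0.0),
                ("N", round(config.n_rows * PLOT_L, 9), round((config.n_rows + 1) * PLOT_L, 9)),
            ):
                for c in range(1, config.n_cols + 1):
                    x0 = cohort_x0 + (f - 1) * (field_w + bund) + (c - 1) * PLOT_W
                    rows.append(
                        (cohort, f, 0, 0 if end == "S" else config.n_rows + 1, c,
                         f"WATER_{end}", "WATER", 0, x0, y0, x0 + PLOT_W, y1, sowing)
                    )
    layout = pd.DataFrame(
        rows,
        columns=[
            "cohort", "field", "block", "row", "col", "entry_id", "entry_type",
            "n_hills", "x_min", "y_min", "x_max", "y_max", "sowing_day",
        ],
    )
    layout.insert(
        0,
        "plot_id",
        [
            f"C{r.cohort}F{r.field}R{r.row:02d}P{r.col:02d}"
            for r in layout.itertuples()
        ],
    )
    # plant counts: full stands of 30 except deliberate sparse plots
    n_plants = np.full(len(layout), N_HILLS)
    planted = layout["entry_type"] != "WATER"
    sparse = planted & (rng.random(len(layout)) < config.sparse_plot_rate)
    n_plants[sparse] = rng.integers(6, 13, sparse.sum())
    n_plants[~planted] = 0
    layout["n_plants"] = n_plants
    return layout


# ---------------------------------------------------------------------------
# trait trajectories
# ---------------------------------------------------------------------------

def _growth_curve(das):
    """Canopy green-up x senescence curve in [0, 1] (rises, then falls)."""
    das = np.asarray(das, dtype=float)
    return 1.0 / (1.0 + np.exp(-(das - 45.0) / 8.0)) / (1.0 + np.exp((das - 115.0) / 8.0))


def _height_curve(das):
    """Logistic fraction of final canopy height reached by a given DAS."""
    das = np.asarray(das, dtype=float)
    return 1.0 / (1.0 + np.exp(-(das - 55.0) / 9.0))


class TrialTruth:
    """Noise-free plot-level trait trajectories plus all planted effects.

    ``plot_value(trait, plot_ids, das)`` returns the deterministic plot-level
    value (genetic + cohort + block + plot effects, no sensor noise).
    """

    def __init__(self, pop: RILPopulation, layout: pd.DataFrame, config: SimConfig):
        self.config = config
        self.layout = layout.set_index("plot_id", drop=False)
        self.ledger = TruthLedger(qtls=list(config.qtls))
        gen, dos = compute_entry_genetics(pop, config)
        self.entry_genetics = gen
        self.entry_dosage = dos
        rng = rng_for(config.seed, "plot-effects")
        # block effects per (cohort, block) and plot noise per plot x trait
        blocks = sorted(set(zip(layout["cohort"], layout["block"])))
        self._block_eff = {
            trait: {
                cb: rng.normal(0.0, config.block_effect_sd.get(trait, 0.0)) for cb in blocks
            }
            for trait in ALL_TRAITS
        }
        self._plot_dev = pd.DataFrame(
            {
                trait: rng.normal(0.0, config.plot_noise_sd.get(trait, 0.0), len(layout))
                for trait in ALL_TRAITS
            },
            index=layout["plot_id"],
        )
        self.ledger.sparse_plots = list(
            layout.loc[(layout["n_plants"] < 13) & (layout["entry_type"] != "WATER"), "plot_id"]
        )

    # -- static (end-of-season) plot values --------------------------------
    def plot_static(self, trait: str) -> pd.Series:
        """End-of-season plot value for every planted plot (cached)."""
        cache = getattr(self, "_static_cache", None)
        if cache is None:
            cache = self._static_cache = {}
        if trait in cache:
            return cache[trait]
        lay = self.layout[self.layout["entry_type"] != "WATER"]
        vals = self.entry_genetics[trait].loc[lay["entry_id"]].to_numpy().astype(float)
        coh = lay["cohort"].to_numpy()
        ce = np.asarray(self.config.cohort_effect.get(trait, (0.0,) * self.config.n_cohorts))
        vals = vals + ce[coh - 1]
        be = self._block_eff[trait]
        vals = vals + np.array([be[(c, b)] for c, b in zip(coh, lay["block"])])
        vals = vals + self._plot_dev.loc[lay["plot_id"], trait].to_numpy()
        out = pd.Series(vals, index=lay["plot_id"], name=trait)
        cache[trait] = out
        return out

    def _qtl_time_term(self, trait: str, entries: pd.Index, das: np.ndarray) -> np.ndarray:
        """Sum of (profile(das) - 1) x effect x dosage for non-constant QTL."""
        out = np.zeros((len(entries), np.size(das)))
        for q in self.config.qtls:
            if q.trait == trait and not isinstance(q.profile, ConstantProfile):
                d = self.entry_dosage[q.label].loc[entries].to_numpy()[:, None]
                out += q.additive_effect * d * (q.profile(das)[None, :] - 1.0)
        return out

    # -- trajectories -------------------------------------------------------
    def plot_ndvi(self, plot_ids, das) -> np.ndarray:
        """Noise-free plot NDVI at the given DAS (scalar or vector)."""
        das = np.atleast_1d(np.asarray(das, dtype=float))
        dev = self.plot_static("ndvi").loc[plot_ids].to_numpy()[:, None]
        entries = self.layout.loc[plot_ids, "entry_id"]
        base = self.config.soil_ndvi + 0.66 * _growth_curve(das)[None, :]
        v = base + dev + self._qtl_time_term("ndvi", entries, das)
        return np.clip(v, 0.02, 0.98)

    def plot_chla(self, plot_ids, das) -> np.ndarray:
        das = np.atleast_1d(np.asarray(das, dtype=float))
        g = _growth_curve(das)[None, :]
        ndvi = self.plot_ndvi(plot_ids, das)
        return 2.2 * g + 1.5 * (ndvi - self.config.soil_ndvi - 0.66 * g) + 0.1

    def plot_bands(self, plot_ids, das) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(NIR, RE, R) reflectances implied by the NDVI/Chla trajectories."""
        v = self.plot_ndvi(plot_ids, das)
        s = self.config.brightness
        nir = s * (1.0 + v) / 2.0
        red = s * (1.0 - v) / 2.0
        chla = np.maximum(self.plot_chla(plot_ids, das), 0.05)
        re = nir / (1.0 + chla)
        return nir, re, red

    def plot_height_m(self, plot_ids, das) -> np.ndarray:
        das = np.atleast_1d(np.asarray(das, dtype=float))
        final = self.plot_static("height_cm").loc[plot_ids].to_numpy()[:, None] / 100.0
        return np.maximum(final * _height_curve(das)[None, :], 0.0)

    def plot_ctd(self, plot_ids, das) -> np.ndarray:
        das = np.atleast_1d(np.asarray(das, dtype=float))
        base = self.plot_static("ctd_C").loc[plot_ids].to_numpy()[:, None]
        return base * (0.5 + 0.5 * _growth_curve(das)[None, :])

    def plot_dth(self) -> pd.Series:
        return self.plot_static("dth_days")

    def flowering_fraction(self, plot_ids, days) -> pd.DataFrame:
        """Monotone flowering fraction per plot over DAS; crosses 0.80 at DTH."""
        days = np.asarray(days, dtype=float)
        dth = self.plot_dth().loc[plot_ids].to_numpy()[:, None]
        frac = np.clip((days[None, :] - (dth - 5.0)) / 6.25, 0.0, 1.0)
        return pd.DataFrame(frac, index=plot_ids, columns=days)


def simulate_traits(pop: RILPopulation, layout: pd.DataFrame, config: SimConfig) -> TrialTruth:
    """Build the deterministic plot-level trait world for one simulated trial."""
    return TrialTruth(pop, layout, config)


def generate_manual_phenotypes(truth: TrialTruth, seed: int | None = None) -> dict:
    """Manual phenotyping campaign: flowering fractions for the DTH rule and
    three sampled plants per plot for height/biomass/panicle mass.

    Panicle mass is collected only for the configured cohorts (default 3),
    mirroring the real campaign's labour constraint.
    """
    config = truth.config
    rng = rng_for(config.seed if seed is None else seed, "manual")
    lay = truth.layout[truth.layout["entry_type"] != "WATER"]
    plot_ids = lay["plot_id"]
    days = np.arange(55.0, 130.0)
    flowering = truth.flowering_fraction(plot_ids, days)
    samples = []
    for trait, col in (("height_cm", "height_cm"), ("biomass_g", "biomass_g"), ("grain_g", "panicle_g")):
        base = truth.plot_static(trait).loc[plot_ids].to_numpy()
        sd = config.plant_sd.get(trait, 0.0)
        vals = base[:, None] + rng.normal(0.0, sd, (len(plot_ids), 3))
        df = pd.DataFrame(vals, index=plot_ids, columns=[f"{col}_p{i + 1}" for i in range(3)])
        samples.append(df)
    plants = pd.concat(samples, axis=1)
    mask = ~lay["cohort"].isin(config.panicle_cohorts).to_numpy()
    plants.loc[mask, [c for c in plants.columns if c.startswith("panicle")]] = np.nan
    plants["n_plants"] = lay["n_plants"].to_numpy()
    return {"flowering": flowering, "plants": plants}


# ---------------------------------------------------------------------------
# sensor streams
# ---------------------------------------------------------------------------

def draw_sensor_biases(config: SimConfig, ledger: TruthLedger | None = None):
    """Per-sensor multiplicative band gains and additive temperature offsets.

    Sensor 1 is the reference: gain exactly 1, offset exactly 0.
    """
    rng = rng_for(config.seed, "sensor-bias")
    lo, hi = config.band_gain_range
    gains = rng.uniform(lo, hi, (SENSORS_PER_BOOM, len(BANDS)))
    gains[0, :] = 1.0
    olo, ohi = config.temp_offset_range_C
    offsets = rng.uniform(olo, ohi, SENSORS_PER_BOOM)
    offsets[0] = 0.0
    if ledger is not None:
        ledger.band_gains = gains
        ledger.temp_offsets = offsets
    return gains, offsets


def _pass_path(rng, y_lo, y_hi, config: SimConfig, artifacts: list, pass_label: str):
    """Sample positions/speeds for one pass, with optional slow/reverse segments."""
    dt = 1.0 / config.sample_hz
    v_nom = config.speed_kph * MPS_PER_KPH
    ys, speeds = [], []
    y = y_lo
    slow = rng.random() < config.slow_segment_rate
    rev = rng.random() < config.reverse_segment_rate
    slow_at = rng.uniform(y_lo + 2, y_hi - 4) if slow else None
    rev_at = rng.uniform(y_lo + 4, y_hi - 4) if rev else None
    slow_len = 1.0
    rev_len = 0.5
    state = "fwd"
    rev_start = None
    while y < y_hi:
        v = v_nom
        if slow_at is not None and slow_at <= y < slow_at + slow_len:
            v = 0.2 * MPS_PER_KPH
        if rev_at is not None and state == "fwd" and y >= rev_at:
            state = "rev"
            rev_start = y
        if state == "rev":
            y -= v * dt
            ys.append(y)
            speeds.append(v)
            if y <= rev_start - rev_len:
                state = "done-rev"
            continue
        y += v * dt
        ys.append(y)
        speeds.append(v)
    if slow_at is not None:
        artifacts.append({"pass": pass_label, "kind": "slow", "y_lo": slow_at, "y_hi": slow_at + slow_len})
    if rev_at is not None:
        artifacts.append({"pass": pass_label, "kind": "reverse", "y_lo": rev_start - rev_len if rev_start else rev_at, "y_hi": rev_start or rev_at})
    return np.asarray(ys), np.asarray(speeds)


def generate_sensor_stream(
    layout: pd.DataFrame,
    truth: TrialTruth,
    day: int,
    config: SimConfig,
    seed: int | None = None,
    gains: np.ndarray | None = None,
    offsets: np.ndarray | None = None,
) -> pd.DataFrame:
    """One sampling day's 5 Hz stream over every cohort's fields.

    The tractor traverses each field serpentine in passes of 8 adjacent plot
    columns; the 8 sensor sets are aligned to those columns.  Readings carry
    the planted per-sensor gains/offsets, Gaussian noise, artifact segments,
    and water-reference strips at both field ends.
    """
    if gains is None or offsets is None:
        gains, offsets = draw_sensor_biases(config, truth.ledger)
    rng = rng_for(config.seed if seed is None else seed, "stream", day)
    lay = truth.layout
    n_groups = config.n_cols // SENSORS_PER_BOOM
    records = []
    t0 = 0.0
    for cohort in range(1, config.n_cohorts + 1):
        das = day - (cohort - 1) * config.cohort_offset_days
        if das < 1:
            continue
        for fld in range(1, config.n_fields + 1):
            sub = lay[(lay["cohort"] == cohort) & (lay["field"] == fld)]
            if sub.empty:
                continue
            fx0 = sub["x_min"].min()
            y_lo, y_hi = sub["y_min"].min() - 0.8, sub["y_max"].max() + 0.8
            # per-column lookup of plot ids by row band
            col_plots = {}
            for c in range(1, config.n_cols + 1):
                cc = sub[sub["col"] == c].sort_values("y_min")
                col_plots[c] = (
                    cc["y_min"].to_numpy(),
                    cc["y_max"].to_numpy(),
                    cc["plot_id"].to_list(),
                    (cc["entry_type"] == "WATER").to_numpy(),
                )
            for g in range(n_groups):
                direction = 1 if g % 2 == 0 else -1
                label = f"d{day}c{cohort}f{fld}g{g + 1}"
                ys, speeds = _pass_path(rng, y_lo, y_hi, config, truth.ledger.artifacts, label)
                if direction < 0:
                    ys = (y_hi + y_lo) - ys
                nrec = len(ys)
                t = t0 + np.arange(nrec) / config.sample_hz
                t0 = t[-1] + 5.0 if nrec else t0
                rec = {
                    "t": t,
                    "x": np.full(nrec, fx0 + (g * SENSORS_PER_BOOM + 4) * PLOT_W),
                    "y": ys,
                    "speed_kph": speeds / MPS_PER_KPH,
                    "heading_deg": np.full(nrec, 0.0 if direction > 0 else 180.0),
                    "air_temp_C": config.air_temp_C + 0.5 * np.sin(t / 600.0),
                    "rh_pct": np.full(nrec, config.rh_pct),
                    "par": np.full(nrec, config.par),
                }
                for s in range(SENSORS_PER_BOOM):
                    colno = g * SENSORS_PER_BOOM + s + 1
                    xs = fx0 + (colno - 0.5) * PLOT_W
                    ylos, yhis, pids, water_flags = col_plots[colno]
                    idx = np.searchsorted(ylos, ys, side="right") - 1
                    idx = np.clip(idx, 0, len(pids) - 1)
                    inplot = (idx >= 0) & (ys >= ylos[idx]) & (ys < yhis[idx])
                    pid_arr = np.asarray(pids, dtype=object)[idx]
                    is_water = water_flags[idx]
                    nir = np.full(nrec, config.brightness * (1 + config.soil_ndvi) / 2)
                    red = np.full(nrec, config.brightness * (1 - config.soil_ndvi) / 2)
                    re = nir / 1.15
                    h = np.zeros(nrec)
                    ct = rec["air_temp_C"] + 1.5
                    planted = inplot & ~is_water
                    if planted.any():
                        pl = pid_arr[planted]
                        bnir, bre, bred = truth.plot_bands(pl, das)
                        nir[planted] = bnir[:, 0]
                        re[planted] = bre[:, 0]
                        red[planted] = bred[:, 0]
                        h[planted] = truth.plot_height_m(pl, das)[:, 0]
                        ct[planted] = (
                            rec["air_temp_C"][planted] - truth.plot_ctd(pl, das)[:, 0]
                        )
                    wmask = inplot & is_water
                    if wmask.any():
                        ct[wmask] = config.water_temp_C
                        nir[wmask] = 0.05
                        red[wmask] = 0.04
                        re[wmask] = 0.045
                    nf = config.reflectance_noise_frac
                    nir = gains[s, 0] * nir * (1 + nf * rng.standard_normal(nrec))
                    re = gains[s, 1] * re * (1 + nf * rng.standard_normal(nrec))
                    red = gains[s, 2] * red * (1 + nf * rng.standard_normal(nrec))
                    ct = ct + offsets[s] + config.temp_noise_C * rng.standard_normal(nrec)
                    gpsh = config.boom_height_m + config.gps_height_noise_m * rng.standard_normal(nrec)
                    dist = config.boom_height_m - h + config.ultrasonic_noise_m * rng.standard_normal(nrec)
                    k = s + 1
                    rec[f"s{k}_x"] = np.full(nrec, xs)
                    rec[f"s{k}_y"] = ys
                    rec[f"s{k}_nir"] = np.clip(nir, 1e-4, 1.0)
                    rec[f"s{k}_re"] = np.clip(re, 1e-4, 1.0)
                    rec[f"s{k}_red"] = np.clip(red, 1e-4, 1.0)
                    rec[f"s{k}_ctemp_C"] = ct
                    rec[f"s{k}_dist_m"] = dist
                    rec[f"s{k}_gpsh_m"] = gpsh
                df = pd.DataFrame(rec)
                df.insert(0, "cohort", cohort)
                df.insert(1, "field", fld)
                df.insert(2, "pass_id", label)
                records.append(df)
    stream = pd.concat(records, ignore_index=True)
    if config.dropout_rate > 0:
        keep = rng.random(len(stream)) >= config.dropout_rate
        dropped = int((~keep).sum())
        if dropped:
            truth.ledger.artifacts.append({"pass": f"d{day}", "kind": "dropout", "n": dropped})
        stream = stream.loc[keep].reset_index(drop=True)
    stream["day"] = day
    return stream


# ---------------------------------------------------------------------------
# convenience: one call simulating a whole trial
# ---------------------------------------------------------------------------

@dataclass
class SimulatedTrial:
    config: SimConfig
    gmap: GeneticMap
    population: RILPopulation
    genotypes_observed: GenotypeMatrix
    layout: pd.DataFrame
    truth: TrialTruth
    manual: dict
    gains: np.ndarray
    temp_offsets: np.ndarray

    def stream_for_day(self, day: int) -> pd.DataFrame:
        return generate_sensor_stream(
            self.layout, self.truth, day, self.config,
            gains=self.gains, offsets=self.temp_offsets,
        )


def simulate_trial(
    config: SimConfig,
    missing_rate: float = 0.05,
    error_rate: float = 0.002,
    dup_pairs: int = 0,
) -> SimulatedTrial:
    """Simulate map, population, layout, traits and manual phenotypes.

    Sensor streams are generated lazily per day via ``stream_for_day`` (they
    dominate memory).
    """
    gmap = simulate_map(config.n_chr, config.chr_length_cM, config.marker_spacing_cM)
    extra = [(q.chrom, q.pos_cM, q.label) for q in config.qtls]
    seen = set()
    extra = [e for e in extra if not (e[2] in seen or seen.add(e[2]))]
    pop = simulate_ril_population(gmap, config.n_ril, config.generation, config.seed, extra)
    layout = generate_layout(pop, config)
    truth = simulate_traits(pop, layout, config)
    observed = inject_genotyping_noise(
        pop.genotypes, missing_rate, error_rate, dup_pairs, config.seed, truth.ledger
    )
    manual = generate_manual_phenotypes(truth)
    gains, offsets = draw_sensor_biases(config, truth.ledger)
    return SimulatedTrial(config, gmap, pop, observed, layout, truth, manual, gains, offsets)
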