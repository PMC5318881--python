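# paddyqtl

Field high-throughput phenotyping (HTP) and QTL mapping for large rice
recombinant-inbred-line (RIL) trials.

Tractor-mounted proximal sensors (3-band reflectance, infrared canopy
temperature, ultrasonic height) can phenotype thousands of paddy plots per
hour, repeatedly through the season. This package implements the full
analysis chain that turns such raw 5 Hz georeferenced sensor streams into
time-resolved genetic results for an F7 RIL population from a biparental
cross (IR64-type semidwarf x Aswina-type landrace):

1. **`simdata`** — a synthetic field-trial generator: Kosambi genetic map,
   F7 RILs by single-seed descent (Poisson crossovers), a 3-cohort /
   2-field / 8-block / 49x16-plot layout with height-based blocking and
   water-reference strips, plot-level trait trajectories driven by planted
   QTL (including a large-effect height locus, +28 cm per Aswina allele,
   and a yield locus whose NDVI signature peaks near 90 days after sowing),
   and raw sensor streams with per-sensor gain/offset biases and deliberate
   filter-triggering artifacts. Every injected effect is recorded in a
   truth ledger for recovery tests.
2. **`sensorproc`** — plot extraction with a 0.20 m border rule,
   cross-sensor reflectance calibration (per field run per day) and
   water-plot temperature calibration (pooled over dates), vegetation
   indices `NDVI=(NIR−R)/(NIR+R)`, `NDRE=(NIR−RE)/(NIR+RE)`,
   `Chla=NIR/RE−1`, canopy height and canopy temperature depression (CTD),
   six ordered exclusion filters (speed/reverse, plant count, sample count,
   CV, temperature range, height range), and daily plot-trait tables.
3. **`genoqc`** — the SNP/individual QC cascade (missingness, duplicate
   markers, heterozygosity, call rate, segregation distortion, duplicate
   individuals), crossover-count outliers, genotyping-error LOD from an
   HMM, drop-one-marker map inflation, composite-score 1 cM thinning, and
   recombination-fraction grouping/ordering with a ripple refinement.
4. **`qtlmap`** — the mapping engine: 2-state genotype-probability HMM on a
   1 cM pseudomarker grid (Kosambi map function, Haldane–Waddington RIL
   transition `R = 2r/(1+2r)` plus an exact finite-generation F_t
   correction for map estimation), Haley–Knott regression scans
   (`LOD = (n/2)·log10(RSS0/RSS1)` on expected dosage
   `E[x] = P(BB) − P(AA)`), genome-wide permutation thresholds, two-locus
   scans, stepwise multi-QTL selection with penalized LOD, 1.5-LOD support
   intervals, and PVE (`100·(1 − 10^(−2·LOD/n))`).
5. **`traitstats`** — manual traits (days to heading at 80% flowering,
   3-plant plot means, harvest index `panicle/(vegetative+panicle)`), LS
   means, broad-sense heritability `H² = VG/(VG + VE/r̄)`, and genetic
   correlations over time.
6. **`tsanalysis`** — per trait x date x cohort scans with per-scan
   permutation thresholds, QTL catalogs and peak histograms,
   forced-position effect trajectories of a named locus (`chrom@cM`), best
   developmental windows, and grain-yield x harvest-index effect and
   breeding-value quadrants centred on the IR64 parent.
7. **`cli_io`** — schema-checked CSV I/O, YAML configuration with hashes,
   provenance-stamped pipeline stages, and the `paddyqtl` command line.

## Worked example

```python
from paddyqtl import simdata, sensorproc, qtlmap, traitstats, tsanalysis
from paddyqtl.cli_io import demo_config

cfg = demo_config(seed=1)                 # 300 RILs, 5 chromosomes, 5 dates
trial = simdata.simulate_trial(cfg)
streams = {d: trial.stream_for_day(d) for d in cfg.htp_days}
htp = sensorproc.process_streams(streams, trial.layout)

pg = qtlmap.genotype_probabilities(trial.population.genotypes, trial.gmap)
dth = traitstats.days_to_heading(trial.manual["flowering"])
manual = traitstats.plot_phenotypes(trial.manual["plants"], dth)
height = traitstats.ls_means(manual.loc[~manual["discard"], "height_cm"].dropna(),
                             trial.layout)
pheno = height[height.index.isin(pg.line_ids)]
thr = qtlmap.permutation_threshold(pheno, pg, n_perm=200, seed=1)
scan = qtlmap.hk_scan(pheno, pg)
model = qtlmap.stepwise_select(pheno, pg, penalty=thr)
```

Printed results (seed 1):

```
simulated: 300 RILs x 105 markers; 1920 plots
height scan: peak 1@60.0, LOD 128.7, additive effect +26.0 cm (threshold 2.62)
model term 1@60.0: effect +30.6 +/- 1.0 cm, PVE 74.9%, 1.5-LOD interval [59, 62] cM
model term 1@66.0: effect -5.8 +/- 1.1 cm, PVE 9.1%, 1.5-LOD interval [60, 69] cM
H2(height) = 0.98
NDVI effect of 3@10.0 strongest around 90-90 DAS (mean |effect| 0.034)
```

The scan recovers the planted height locus (chromosome 1 at 60 cM, +28 cm
per Aswina allele) with a tight 1.5-LOD interval; the additive effect is
the trait change per Aswina allele, so homozygote classes sit twice that
apart. With a nearly noise-free phenotype the stepwise model also admits a
small compensatory linked term at 66 cM — the price of approximating the
unobserved QTL dosage by expected dosage from 5 cM-spaced markers. The
time-resolved analysis re-estimates the yield locus `3@10.0` at a fixed
position for every sampling date and finds its NDVI signal strongest near
90 days after sowing, the developmental window where canopy reflectance
best predicts yield.

The same stages run from the shell:

```sh
paddyqtl run-all --seed 1 --out runs/demo --n-perm 200
```

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the whole pipeline on a freshly simulated trial — simulation,
sensor post-processing, genotype QC, manual-trait statistics, permutation
thresholds, QTL models and the time-series analyses — writing stage
artifacts under `results/pipeline/` and the results manifest to the given
path. The statistical checks themselves (layout counts, permutation
calibration, scan-vs-oracle identity, locus recovery, sensor-bias recovery,
filter enumeration, QC enumeration) live in `tests/test_acceptance.py`.
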