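# Methods

This note documents the models, defaults and numerical choices behind
`paddyqtl`, and what the simulator does and does not emulate.

## The simulated world

### Population

F7 RILs are produced by single-seed descent from an F1 of two inbred
parents (A = IR64-like, B = Aswina-like). Each selfing generation draws two
independent gametes per individual; a gamete has a Poisson number of
crossovers with mean equal to the chromosome length in Morgans and uniform
crossover placement — i.e. **no crossover interference** (Haldane process).
Downstream estimation uses the Kosambi map function, as is conventional for
rice linkage maps; the resulting deliberate mismatch shortens estimated
intervals by ~4–5% at 5 cM spacing and is part of the documented bias of
the map-length check (below). Residual heterozygosity at F7 is
(1/2)^6 ≈ 1.6% per locus, which the tests verify against the Mendelian
recursion.

Planted QTL are "hidden loci": simulated alongside the markers but never
genotyped, with their per-line dosages (A = −1, H = 0, B = +1) recorded in
the truth ledger. An additive effect is therefore the effect per Aswina
allele, and homozygote classes differ by twice the effect (the +28 cm
height locus produces a 56 cm gap, hence a bimodal height distribution).

### Trial layout

Per cohort: two 49-row x 16-column fields (1,568 plots of 1.0 m x 1.2 m,
30 hills on 0.20 m centres); three cohorts sown 14 days apart; 1,516 RILs
with 42 of them duplicated, two parents, and check entries filling the
remainder. Entries are ranked by **true genetic height** and split into 8
blocks (the real practice used prior height knowledge; using the true value
keeps the generator deterministic). Duplicated RILs are spread evenly along
the height ranking so every block contains replicated entries. Unplanted
water-reference plots span both ends of every field, one per plot column,
so each of the 8 boom sensors crosses water on every pass.

A consequence worth noting: because blocks are a deterministic function of
entry height, entry and block-within-cohort effects are **collinear**. The
LS-means model therefore adjusts for cohort only; adding the block term
(available via `include_block=True`) splits entry means with block
coefficients and can even invert a large height effect. For the same reason
the heritability ANOVA removes cohort means only.

### Sensor platform

The tractor traverses each field serpentine in passes of 8 adjacent plot
columns at a nominal 1.0 kph, sampling at 5 Hz; the 8 sensor sets are
aligned to those columns. Each sensor set reports NIR/RE/R reflectances,
canopy temperature, ultrasonic distance and GPS sensor height; shared
channels are air temperature, RH and PAR. Reflectance bands are derived
from the plot's NDVI trajectory v(t) and a brightness scale s:
NIR = s(1+v)/2, R = s(1−v)/2, RE = NIR/(1+Chla). The NDVI base curve is a
green-up x senescence double logistic (rises to ~0.8 by 80 DAS, falls
after ~115 DAS); canopy height follows a logistic to its final value;
canopy temperature depression scales with canopy cover.

Planted distortions (all ledger-recorded): per-sensor multiplicative band
gains U(0.9, 1.1) and additive temperature offsets U(−1, 1) °C with sensor
1 the exact reference; 1% multiplicative reflectance noise, 0.3 °C
temperature noise, 2 cm ultrasonic and 1 cm GPS-height noise; slow
(<0.3 kph) and reversing tractor segments; sparse plots (<13 plants);
random record dropout.

**Not emulated:** weather-driven variation, spatial field trends, lodging,
sensor drift within a day, antenna-offset geometry, and GBS read-level
errors. A green test therefore establishes correctness of the analysis
operations and calibration recovery under the stated noise model, not
robustness to every field pathology.

## Sensor post-processing

Samples are assigned to a plot only if strictly more than 0.20 m inside its
rectangle (samples on the border line are excluded). Reflectance
calibration computes one gain per sensor x band x field traversal x day,
`gain(s,b) = mean(ref)/mean(s)`, applied multiplicatively; bands are
normalised **before** indices are computed (order matters because gains are
band-specific; the alternative order is not exposed). Temperature offsets
come from water plots pooled over all sampling dates,
`offset(s) = mean_water(ref) − mean_water(s)`, applied additively before
the 22–40 °C range filter.

The six filters run in the order listed in the package docstring; later
rules act on what earlier rules left, and a channel that drops below 4
samples *because* of the temperature/height range rules is not
re-filtered. CV uses the (n−1) standard deviation; a zero-mean channel is
excluded as undefined. Reverse motion is a negative along-track velocity
component computed per pass from positions and heading.

Because each sensor traverses different plots, the mean-ratio gain
estimate carries an irreducible error from plot composition (~1–2% at demo
scale). The acceptance check of calibration accuracy therefore uses a
uniform canopy, which isolates the operation; with biological variation the
recovered gains are unbiased but noisier.

## Genotype QC

The cascade applies, in order: marker missingness (< 40% kept), duplicate
markers (≥ 99% similarity over co-called loci, first of each pair kept),
individual heterozygosity (> 15% removed), marker call rate (< 80%
removed, on the reduced population), segregation distortion (allele-A
fraction < 30% or > 70% removed, strict bounds), duplicate individuals
(≥ 99%). Map-aware filters follow: crossover-count outliers above
median + 3·IQR (the cut replaces an unstated "abnormally high" rule);
per-call genotyping-error LOD — log10 posterior odds that a call is wrong,
from a leave-one-out HMM posterior times the emission odds ε/(1−ε), with
ε = 0.01 and cut 4.0 by default (at 1 cM flanks a lone double-crossover
call scores ≈ 1.4, so the default cut only fires on dense maps; tests use
an explicit cut); drop-one-marker map-length change (> 5 cM default);
composite thinning, `score = 1 − ½·ranknorm(missing) −
½·ranknorm(|pA − 0.5|)` with genome-wide rank normalisation making the two
components commensurable, best marker per half-open 1 cM bin, ties to the
lower position then smaller id; and a cross-chromosome LD filter (max
inter-chromosome |r| > 0.7, a package default flagged in the report).

Grouping/ordering replaces maximum-likelihood ordering with transitive
closure at rf < 0.25, greedy chaining from the tightest pair, and a
sliding-window (≤ 5 cM, ≤ 6 markers) permutation ripple; positions are
cumulative Kosambi distances. Orientation is fixed by putting the smaller
original marker index first, so orders are recovered up to whole-chromosome
reflection.

### Recombination fractions in selfed RILs

The observed mismatch fraction R between fixed lines understates nothing at
F∞ (Haldane–Waddington, R = 2r/(1+2r)) but at F7 it is a few percent
smaller. `genoqc` inverts the **exact finite-generation value**, computed by
iterating the two-locus diplotype distribution of a selfed lineage
(10-state chain) and conditioning on both loci being fixed; the inverse is
interpolated from a 400-point table and cached per generation. With this
correction the estimated chromosome length on clean data is within ~5% of
truth, the residue being the documented Kosambi-on-Haldane bias.

## QTL mapping

Genotype probabilities come from a scaled forward–backward pass over each
chromosome on a grid of 1 cM steps plus all marker positions. Transitions
use r from the inverse Kosambi transform of the inter-position distance and
the RIL correction R = 2r/(1+2r) (the F∞ form, as in standard RIL HMMs —
transition errors of order 1% matter less here than in map estimation).
Emissions allow a symmetric error rate ε = 0.01; heterozygous calls are
treated as missing (a third state is unnecessary at 1.6% residual
heterozygosity). Haley–Knott scans regress the phenotype on expected
dosage; with covariates both phenotype and dosage are projected off the
covariate span first, which reproduces the full regression exactly.
Numerically perfect fits are capped at LOD 300.

Permutation thresholds shuffle phenotype labels and take the type-7
empirical (1−α) quantile of genome-wide maxima; permutations are evaluated
in blocks via one matrix product each, so 200 permutations on a
200-line x 300-position grid take ~30 ms. Stepwise search is
forward–backward over additive terms with a per-term penalty (default: the
genome-wide 95% permutation threshold; a "0.1%" significance level is
available by passing α = 0.001 to the threshold), capped at 10 QTL,
followed by one position-refinement pass; effects and SEs come from the
final joint fit, per-term PVE from type-III drop LODs via
`100·(1 − 10^(−2·ΔLOD/n))`. Two-locus scans fit full (two dosages +
product) and additive models on a coarse grid (default 5 cM) and report the
interaction LOD; stepwise itself stays additive (epistatic model search is
out of scope).

1.5-LOD support intervals take the contiguous run around the peak with
LOD ≥ peak − 1.5 and extend one grid point each side, truncated at
chromosome ends.

## Time-resolved analysis

Each HTP trait x sampling date x cohort gets its own scan and its own
permutation threshold (per-scan thresholds, since sample sizes and
phenotype distributions differ by date). Significant chromosome peaks are
catalogued with intervals. Effect trajectories re-estimate a named locus
at a **fixed grid position** for every date (no per-date peak search, so
one locus is tracked without position jitter); per-cohort and pooled trends
are ordinary least squares of effect on DAS. The best developmental window
is the contiguous set of sampling dates maximising the mean absolute
effect, ties preferring longer then earlier windows, a fully tied profile
returning the whole span flagged as tied.

For the grain x harvest-index quadrant view, the two stepwise models'
peaks are merged into consensus loci (same chromosome within 10 cM — the
two traits localise a shared locus with a few cM of jitter, and fitting
both jittered positions jointly would split one effect across collinear
regressors). Both traits' effects are re-estimated jointly at the consensus
positions; reported effects are for the IR64 allele (the negative of the
Aswina-allele effect), and a locus whose effect on one trait is within
2 SE of zero sits on that axis. Per-line breeding values are summed fitted
effects; quadrants are centred at the IR64 parent's values (all dosages
−1).

## Numerical and policy choices

* One master seed drives named substreams per stage (FNV-hashed labels into
  a `SeedSequence`), so stages are independently reproducible.
* All thresholds default to the printed campaign values (0.20 m border,
  0.3 kph, 13 plants, 4 samples, CV 0.5, 22–40 °C, 0.10–2.60 m, 40%/99%/
  15%/80%/30–70%/99% QC bounds, 1 cM probability step, 1.5-LOD drop,
  max 10 QTL).
* Boundary readings are strict where the rules are phrased exclusively:
  CV exactly 0.5 is retained, allele-A fraction exactly 0.30 is retained,
  a sample exactly on the border line is excluded.
* Tables are written deterministically (schema-checked, key-sorted, fixed
  float format); every stage directory carries a config-hash + seed stamp
  that downstream stages verify before reading.
* The per-stage CLI commands re-derive the simulated trial from the saved
  config (simulation is deterministic given the config), rather than
  deserialising every intermediate object; `run-all` executes the stages
  in-process.

## Known limitations

* The stepwise model can add a small compensatory linked term next to a
  very strong QTL when the phenotype is nearly noise-free (expected-dosage
  approximation error is linked-correlated); the penalty guards against
  this at realistic noise but not asymptotically.
* LS means assume entry effects are estimable from cohort-adjusted data;
  with height-based blocking the block term is intentionally excluded (see
  above), so block-level micro-environment ends up in the residual.
* Genetic correlations are correlations of entry means, not bivariate
  variance-component estimates; they understate correlations when entry
  means are noisy.
* The error-LOD filter shares the HMM's F∞ transition approximation, and
  the loess presentation smoother is a small local-quadratic implementation
  intended for ~11 sampling dates, not large series.
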