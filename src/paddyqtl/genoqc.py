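"""Genotype quality control and linkage-map thinning for RIL populations.

Re-implements a GBS-style marker/individual filtering cascade:

1. markers with >= 40% missing data removed;
2. one of each pair of markers >= 99% similar removed;
3. individuals with > 15% heterozygous calls removed;
4. markers called in < 80% of the (remaining) population removed;
5. markers with segregation distortion (allele-A fraction < 30% or > 70%,
   strict) removed;
6. one of each pair of individuals >= 99% similar removed.

Plus map-aware filters: crossover-count outliers (median + k*IQR),
genotyping-error LOD (HMM leave-one-out posterior odds), single-marker map
inflation (drop-one length change), composite-score 1 cM thinning, and a
simplified grouping/ordering/ripple step (recombination-fraction grouping
with greedy chaining; a full maximum-likelihood ordering is out of scope).

Similarity between two columns/rows is the fraction of co-called loci with
identical calls.  The segregation-distortion statistic is the allele-A
fraction among homozygous calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd

from functools import lru_cache

from paddyqtl.core import CODE_MISSING, Chromosome, GeneticMap, GenotypeMatrix
from paddyqtl.qtlmap import kosambi, leave_one_out_posteriors, ril_self_R_finite


@lru_cache(maxsize=8)
def _ril_inversion_table(generation: int):
    """(R grid, r grid) for inverting the F_t RIL mismatch probability."""
    r_grid = np.linspace(0.0, 0.4999, 400)
    R_grid = np.array([ril_self_R_finite(float(r), generation) for r in r_grid])
    return R_grid, r_grid


class CascadeError(RuntimeError):
    pass


@dataclass
class QCReport:
    """Per-stage bookkeeping: markers/individuals in and out."""

    stages: list = field(default_factory=list)

    def add(self, stage: str, axis: str, n_in: int, n_out: int, params: dict | None = None):
        self.stages.append(
            {
                "stage": stage,
                "axis": axis,
                "n_in": n_in,
                "n_out": n_out,
                "n_removed": n_in - n_out,
                "params": params or {},
            }
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages)


@dataclass(frozen=True)
class QCThresholds:
    max_marker_missing: float = 0.40  # strict: keep < 0.40
    dup_marker_similarity: float = 0.99
    max_line_het: float = 0.15  # strict: remove > 0.15
    min_marker_called: float = 0.80  # strict: remove < 0.80
    distortion_lo: float = 0.30  # strict: remove < 0.30 or > 0.70
    distortion_hi: float = 0.70
    dup_line_similarity: float = 0.99


def marker_stats(genotypes: GenotypeMatrix) -> pd.DataFrame:
    """Missing fraction, allele-A fraction and het fraction per marker."""
    return pd.DataFrame(
        {
            "marker_id": genotypes.marker_ids,
            "missing_fraction": genotypes.marker_missing_fraction(),
            "allele_A_fraction": genotypes.marker_allele_A_fraction(),
            "het_fraction": genotypes.marker_het_fraction(),
        }
    )


def _pairwise_similarity(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fraction of co-called entries with identical calls between columns.

    Returns (similarity, n_co-called) as (m, m) matrices.
    """
    m = codes.shape[1]
    called = (codes != CODE_MISSING).astype(np.float32)
    co = called.T @ called
    same = np.zeros((m, m), dtype=np.float32)
    for code in np.unique(codes[codes != CODE_MISSING]):
        ind = (codes == code).astype(np.float32)
        same += ind.T @ ind
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(co > 0, same / co, 0.0)
    return sim, co


def qc_cascade(
    genotypes: GenotypeMatrix,
    thresholds: QCThresholds = QCThresholds(),
    report: QCReport | None = None,
) -> tuple[GenotypeMatrix, QCReport]:
    """Six-stage marker/individual filtering cascade (see module docstring).

    Stages run in the stated order; an empty matrix after any stage raises
    :class:`CascadeError` naming the stage.
    """
    if report is None:
        report = QCReport()
    th = thresholds
    g = genotypes

    def check(stage: str):
        if g.n_markers == 0 or g.n_lines == 0:
            raise CascadeError(f"no data left after stage {stage!r}")

    # 1. marker missingness
    n_in = g.n_markers
    keep = np.flatnonzero(g.marker_missing_fraction() < th.max_marker_missing)
    g = g.subset(markers=keep)
    report.add("marker_missing", "markers", n_in, g.n_markers, {"max_missing": th.max_marker_missing})
    check("marker_missing")
    # 2. duplicate markers
    n_in = g.n_markers
    sim, _ = _pairwise_similarity(g.codes)
    drop = np.zeros(g.n_markers, dtype=bool)
    iu, ju = np.triu_indices(g.n_markers, k=1)
    dup = sim[iu, ju] >= th.dup_marker_similarity
    for i, j in zip(iu[dup], ju[dup]):
        if not drop[i] and not drop[j]:
            drop[j] = True  # keep the first of each pair
    g = g.subset(markers=np.flatnonzero(~drop))
    report.add("duplicate_markers", "markers", n_in, g.n_markers, {"similarity": th.dup_marker_similarity})
    check("duplicate_markers")
    # 3. heterozygous individuals
    n_in = g.n_lines
    keep = np.flatnonzero(~(g.line_het_fraction() > th.max_line_het))
    g = g.subset(lines=keep)
    report.add("line_het", "individuals", n_in, g.n_lines, {"max_het": th.max_line_het})
    check("line_het")
    # 4. marker call rate (on the reduced population)
    n_in = g.n_markers
    called = 1.0 - g.marker_missing_fraction()
    keep = np.flatnonzero(~(called < th.min_marker_called))
    g = g.subset(markers=keep)
    report.add("marker_call_rate", "markers", n_in, g.n_markers, {"min_called": th.min_marker_called})
    check("marker_call_rate")
    # 5. segregation distortion (strict bounds retained)
    n_in = g.n_markers
    pa = g.marker_allele_A_fraction()
    keep = np.flatnonzero(~((pa < th.distortion_lo) | (pa > th.distortion_hi)))
    g = g.subset(markers=keep)
    report.add(
        "segregation_distortion", "markers", n_in, g.n_markers,
        {"lo": th.distortion_lo, "hi": th.distortion_hi},
    )
    check("segregation_distortion")
    # 6. duplicate individuals
    n_in = g.n_lines
    sim, _ = _pairwise_similarity(g.codes.T)
    drop = np.zeros(g.n_lines, dtype=bool)
    iu, ju = np.triu_indices(g.n_lines, k=1)
    dup = sim[iu, ju] >= th.dup_line_similarity
    for i, j in zip(iu[dup], ju[dup]):
        if not drop[i] and not drop[j]:
            drop[j] = True
    g = g.subset(lines=np.flatnonzero(~drop))
    report.add("duplicate_individuals", "individuals", n_in, g.n_lines, {"similarity": th.dup_line_similarity})
    check("duplicate_individuals")
    return g, report


# ---------------------------------------------------------------------------
# map-aware filters
# ---------------------------------------------------------------------------

def count_crossovers(genotypes: GenotypeMatrix, gmap: GeneticMap) -> np.ndarray:
    """Observed genotype switches per line along each chromosome, summed.

    H and missing calls are skipped; a switch is counted between consecutive
    informative calls that differ.
    """
    counts = np.zeros(genotypes.n_lines, dtype=int)
    for chrom in gmap.chromosomes:
        idx = [genotypes.marker_index(m) for m in chrom.markers]
        codes = genotypes.codes[:, idx]
        for i in range(genotypes.n_lines):
            row = codes[i]
            informative = row[(row == 0) | (row == 2)]
            if len(informative) > 1:
                counts[i] += int(np.sum(np.diff(informative.astype(int)) != 0))
    return counts


def crossover_outlier_filter(
    genotypes: GenotypeMatrix, gmap: GeneticMap, k: float = 3.0,
    report: QCReport | None = None,
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Remove lines with abnormally many crossovers (> median + k*IQR).

    With zero IQR only lines strictly above the median are candidates, so a
    constant count removes nobody.
    """
    counts = count_crossovers(genotypes, gmap)
    med = np.median(counts)
    q1, q3 = np.percentile(counts, [25, 75])
    iqr = q3 - q1
    cut = med + k * iqr
    keep = np.flatnonzero(counts <= cut)
    out = genotypes.subset(lines=keep)
    if report is not None:
        report.add("crossover_outliers", "individuals", genotypes.n_lines, out.n_lines,
                   {"k": k, "cut": float(cut)})
    return out, counts


def error_lod_filter(
    genotypes: GenotypeMatrix,
    gmap: GeneticMap,
    error_rate: float = 0.01,
    lod_cut: float = 4.0,
    report: QCReport | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Blank out calls whose genotyping-error LOD exceeds ``lod_cut``.

    The error LOD of a call is log10 of the posterior odds that the call is
    wrong: leave-one-out HMM posterior of the opposite state times the
    emission odds epsilon/(1-epsilon) versus the called state.
    """
    if error_rate <= 0:
        raise ValueError("error_rate must be positive")
    post = leave_one_out_posteriors(genotypes, gmap, error_rate)
    g = genotypes.copy()
    flagged = []
    for chrom_name, (markers, p) in post.items():
        for j, m in enumerate(markers):
            col = g.marker_index(m)
            calls = g.codes[:, col]
            hom = (calls == 0) | (calls == 2)
            if not hom.any():
                continue
            called_state = (calls == 2).astype(int)  # 0 for A, 1 for B
            p_called = p[np.arange(g.n_lines), j, called_state]
            p_other = 1.0 - p_called
            with np.errstate(divide="ignore"):
                lod = np.log10(
                    (p_other * error_rate) / np.maximum(p_called * (1 - error_rate), 1e-300)
                )
            bad = hom & (lod > lod_cut)
            for i in np.flatnonzero(bad):
                flagged.append({"line": g.line_ids[i], "marker": m, "chrom": chrom_name,
                                "error_lod": float(lod[i])})
                g.codes[i, col] = CODE_MISSING
    if report is not None:
        report.add("error_lod", "calls", genotypes.n_lines * genotypes.n_markers,
                   genotypes.n_lines * genotypes.n_markers - len(flagged),
                   {"error_rate": error_rate, "lod_cut": lod_cut})
    return g, pd.DataFrame(flagged)


def error_lod_scores(
    genotypes: GenotypeMatrix, gmap: GeneticMap, error_rate: float = 0.01
) -> dict[str, pd.DataFrame]:
    """Per-call error LOD per chromosome (lines x markers), for inspection."""
    post = leave_one_out_posteriors(genotypes, gmap, error_rate)
    out = {}
    for chrom_name, (markers, p) in post.items():
        cols = [genotypes.marker_index(m) for m in markers]
        calls = genotypes.codes[:, cols]
        called_state = (calls == 2).astype(int)
        p_called = np.take_along_axis(p, called_state[:, :, None], axis=2)[:, :, 0]
        with np.errstate(divide="ignore"):
            lod = np.log10(((1 - p_called) * error_rate) / np.maximum(p_called * (1 - error_rate), 1e-300))
        lod[(calls != 0) & (calls != 2)] = -np.inf
        out[chrom_name] = pd.DataFrame(lod, index=genotypes.line_ids, columns=markers)
    return out


def estimate_rf(genotypes: GenotypeMatrix, i: int, j: int, generation: int = 7) -> float:
    """Meiotic recombination fraction between two markers from RIL data.

    The observed mismatch fraction R among co-called homozygous pairs is
    inverted through the exact F_t selfing chain (finite-generation analogue
    of the Haldane-Waddington formula R = 2r/(1+2r)).
    """
    a = genotypes.codes[:, i]
    b = genotypes.codes[:, j]
    ok = ((a == 0) | (a == 2)) & ((b == 0) | (b == 2))
    if ok.sum() == 0:
        return 0.5
    R = float(np.mean(a[ok] != b[ok]))
    Rg, rg = _ril_inversion_table(generation)
    return float(min(np.interp(R, Rg, rg), 0.4999))


def _rf_matrix(codes: np.ndarray, generation: int = 7) -> np.ndarray:
    """Pairwise meiotic rf matrix for all markers (vectorised)."""
    a_is = (codes == 0).astype(np.float32)
    b_is = (codes == 2).astype(np.float32)
    hom = a_is + b_is
    co = hom.T @ hom
    same = a_is.T @ a_is + b_is.T @ b_is
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.where(co > 0, 1.0 - same / np.maximum(co, 1), 0.5)
    Rg, rg = _ril_inversion_table(generation)
    r = np.interp(np.clip(R, 0.0, 1.0), Rg, rg)
    return np.clip(r, 0.0, 0.4999)


def droponemarker_filter(
    genotypes: GenotypeMatrix,
    gmap: GeneticMap,
    length_change_cut_cM: float = 5.0,
    report: QCReport | None = None,
) -> tuple[GenotypeMatrix, GeneticMap, list[str]]:
    """Drop markers whose removal shortens their chromosome's estimated
    length by more than the cut.

    Chromosome length is the sum of adjacent-marker Kosambi distances
    (RIL-corrected rf); removing marker i replaces d(i-1,i)+d(i,i+1) with
    the directly estimated d(i-1,i+1).  Chromosomes with < 3 markers are
    skipped with a warning.
    """
    import warnings

    dropped: list[str] = []
    for chrom in gmap.chromosomes:
        if chrom.n_markers < 3:
            warnings.warn(f"chromosome {chrom.name} has < 3 markers; skipped")
            continue
        idx = [genotypes.marker_index(m) for m in chrom.markers]
        for k in range(1, chrom.n_markers - 1):
            d_left = kosambi(estimate_rf(genotypes, idx[k - 1], idx[k]))
            d_right = kosambi(estimate_rf(genotypes, idx[k], idx[k + 1]))
            d_skip = kosambi(estimate_rf(genotypes, idx[k - 1], idx[k + 1]))
            if (d_left + d_right) - d_skip > length_change_cut_cM:
                dropped.append(chrom.markers[k])
    keep = [m for m in genotypes.marker_ids if m not in set(dropped)]
    out = genotypes.subset_marker_ids(keep)
    new_map = gmap.subset(keep)
    if report is not None:
        report.add("droponemarker", "markers", genotypes.n_markers, out.n_markers,
                   {"length_change_cut_cM": length_change_cut_cM})
    return out, new_map, dropped


def composite_thin(
    genotypes: GenotypeMatrix,
    gmap: GeneticMap,
    window_cM: float = 1.0,
    report: QCReport | None = None,
) -> list[str]:
    """Keep the best marker per 1 cM window by composite score.

    score = 1 − 0.5·ranknorm(missing) − 0.5·ranknorm(|allele_A − 0.5|): equal
    weights for missingness and segregation distortion, each rank-normalised
    to [0, 1] genome-wide so the two components are commensurable.  Windows
    are half-open ``window_cM`` bins from each chromosome start; ties go to
    the lower cM position, then the lexicographically smaller id.
    """
    stats = marker_stats(genotypes).set_index("marker_id")

    def ranknorm(v: pd.Series) -> pd.Series:
        r = v.rank(method="average") - 1.0
        den = max(len(v) - 1, 1)
        return r / den

    on_map = [m for m in stats.index if any(m in c.markers for c in gmap.chromosomes)]
    stats = stats.loc[on_map]
    score = 1.0 - 0.5 * ranknorm(stats["missing_fraction"]) - 0.5 * ranknorm(
        (stats["allele_A_fraction"] - 0.5).abs()
    )
    retained: list[str] = []
    for chrom in gmap.chromosomes:
        pos = chrom.positions
        bins = np.floor(pos / window_cM).astype(int)
        for b in np.unique(bins):
            members = [
                (chrom.markers[i], pos[i]) for i in np.flatnonzero(bins == b)
                if chrom.markers[i] in score.index
            ]
            if not members:
                continue
            members.sort(key=lambda mp: (-score[mp[0]], mp[1], mp[0]))
            retained.append(members[0][0])
    if report is not None:
        report.add("composite_thin", "markers", genotypes.n_markers, len(retained),
                   {"window_cM": window_cM})
    return retained


def cross_ld_filter(
    genotypes: GenotypeMatrix, gmap: GeneticMap, max_abs_r: float = 0.7,
    report: QCReport | None = None,
) -> list[str]:
    """Drop markers in strong linkage disequilibrium with another chromosome.

    Markers whose maximum inter-chromosome dosage correlation |r| exceeds
    ``max_abs_r`` are removed (the threshold is a package choice, flagged in
    the report).
    """
    mids = [m for c in gmap.chromosomes for m in c.markers]
    idx = [genotypes.marker_index(m) for m in mids]
    D = genotypes.dosage()[:, idx]
    D = np.where(np.isnan(D), 0.0, D)
    D = D - D.mean(axis=0)
    norm = np.sqrt((D**2).sum(axis=0))
    norm[norm == 0] = 1.0
    corr = (D.T @ D) / np.outer(norm, norm)
    chrom_of = np.concatenate([[c.name] * c.n_markers for c in gmap.chromosomes])
    other = chrom_of[:, None] != chrom_of[None, :]
    max_cross = np.where(other, np.abs(corr), 0.0).max(axis=1)
    dropped = [m for m, v in zip(mids, max_cross) if v > max_abs_r]
    if report is not None:
        report.add("cross_chromosome_ld", "markers", len(mids), len(mids) - len(dropped),
                   {"max_abs_r": max_abs_r, "note": "threshold is a package default"})
    return dropped


# ---------------------------------------------------------------------------
# grouping, ordering, ripple
# ---------------------------------------------------------------------------

def order_and_ripple(
    genotypes: GenotypeMatrix,
    group_rf: float = 0.25,
    ripple_window_cM: float = 5.0,
) -> GeneticMap:
    """Group markers by linkage and order them; refine with a ripple pass.

    * grouping: transitive closure of pairs with rf < ``group_rf``;
    * initial order: greedy chaining — start from the pair with the smallest
      rf and repeatedly append the unplaced marker closest to either end;
    * ripple: sliding windows of markers spanning <= ``ripple_window_cM``
      are re-permuted to minimise the sum of adjacent rf;
    * positions: cumulative Kosambi distances from the first marker.

    Linkage groups are named L1, L2, ... in size order.
    """
    m = genotypes.n_markers
    rf = _rf_matrix(genotypes.codes)
    np.fill_diagonal(rf, 0.5)
    # grouping: union-find over linked pairs
    parent = list(range(m))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    linked = np.argwhere(rf < group_rf)
    for i, j in linked:
        if i < j:
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[rj] = ri
    groups: dict[int, list[int]] = {}
    for i in range(m):
        groups.setdefault(find(i), []).append(i)
    ordered_groups = sorted(groups.values(), key=len, reverse=True)
    chroms = []
    for gi, members in enumerate(ordered_groups, start=1):
        order = _greedy_order(rf, members)
        order = _ripple(rf, order, ripple_window_cM)
        # orient deterministically: smaller marker index first
        if order[0] > order[-1]:
            order = order[::-1]
        pos = np.concatenate(
            [[0.0], np.cumsum([kosambi(rf[a, b]) for a, b in zip(order[:-1], order[1:])])]
        )
        # enforce strictly increasing positions (tied markers get epsilon)
        for k in range(1, len(pos)):
            if pos[k] <= pos[k - 1]:
                pos[k] = pos[k - 1] + 1e-6
        chroms.append(
            Chromosome(f"L{gi}", tuple(genotypes.marker_ids[i] for i in order), pos)
        )
    return GeneticMap(tuple(chroms))


def _greedy_order(rf: np.ndarray, members: list[int]) -> list[int]:
    if len(members) <= 2:
        return list(members)
    sub = rf[np.ix_(members, members)]
    n = len(members)
    iu, ju = np.triu_indices(n, k=1)
    k = np.argmin(sub[iu, ju])
    chain = [iu[k], ju[k]]
    unused = set(range(n)) - set(chain)
    while unused:
        left, right = chain[0], chain[-1]
        best, best_rf, best_side = None, np.inf, None
        for u in unused:
            if sub[u, left] < best_rf:
                best, best_rf, best_side = u, sub[u, left], "L"
            if sub[u, right] < best_rf:
                best, best_rf, best_side = u, sub[u, right], "R"
        if best_side == "L":
            chain.insert(0, best)
        else:
            chain.append(best)
        unused.remove(best)
    return [members[i] for i in chain]


def _adjacent_rf_sum(rf: np.ndarray, order: list[int]) -> float:
    return float(sum(rf[a, b] for a, b in zip(order[:-1], order[1:])))


def _ripple(rf: np.ndarray, order: list[int], window_cM: float, max_window: int = 6) -> list[int]:
    """Sliding-window permutation refinement of a marker order."""
    improved = True
    order = list(order)
    while improved:
        improved = False
        # window size limited by span in cM and a hard count cap
        dists = [kosambi(rf[a, b]) for a, b in zip(order[:-1], order[1:])]
        for start in range(len(order) - 1):
            end = start + 1
            span = 0.0
            while end < len(order) and end - start < max_window:
                span += dists[end - 1] if end - 1 < len(dists) else 0.0
                if span > window_cM:
                    break
                end += 1
            window = order[start:end]
            if len(window) < 3:
                continue
            base = _adjacent_rf_sum(rf, order)
            best_perm, best_val = None, base
            for perm in permutations(window):
                cand = order[:start] + list(perm) + order[end:]
                val = _adjacent_rf_sum(rf, cand)
                if val < best_val - 1e-12:
                    best_perm, best_val = cand, val
            if best_perm is not None:
                order = best_perm
                improved = True
        if improved:
            continue
    return order
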