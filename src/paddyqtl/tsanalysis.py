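"""Time-resolved QTL analysis of HTP traits.

Runs one Haley–Knott scan (with its own permutation threshold) per
trait x sampling day x cohort, catalogues significant peaks, builds
peak-location histograms against manual-trait LOD curves, re-estimates a
named QTL's effect at a fixed position across dates (effect trajectories),
finds the developmental window with the strongest signal, and assembles the
grain-yield x harvest-index effect and breeding-value quadrant tables.

Conventions: QTL are labelled ``chrom@cM`` (e.g. ``3@10.0``); trajectories
use forced-position re-estimation rather than per-date peak search so one
locus is tracked without position jitter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from paddyqtl.qtlmap import (
    ProbGrid,
    QTLModel,
    fit_effects_at,
    hk_scan,
    lod_interval,
    permutation_threshold,
)

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# catalog construction
# ---------------------------------------------------------------------------

def entry_means_by_cohort(
    htp_table: pd.DataFrame, layout: pd.DataFrame, trait: str
) -> dict[tuple[int, int], pd.Series]:
    """Entry-level phenotype per (day, cohort) for one HTP trait.

    Plot values are averaged per entry within a cohort (entries have 1–2
    plots per cohort).
    """
    lay = layout.set_index("plot_id")
    sub = htp_table[(htp_table["trait"] == trait) & htp_table["value"].notna()].copy()
    sub["entry"] = lay["entry_id"].reindex(sub["plot_id"]).to_numpy()
    sub["cohort"] = lay["cohort"].reindex(sub["plot_id"]).to_numpy()
    out = {}
    for (day, cohort), grp in sub.groupby(["day", "cohort"]):
        out[(int(day), int(cohort))] = grp.groupby("entry")["value"].mean()
    return out


def scan_all(
    htp_table: pd.DataFrame,
    layout: pd.DataFrame,
    probgrid: ProbGrid,
    traits: list[str],
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    min_lines: int = 50,
    sowing_by_cohort: dict[int, int] | None = None,
) -> pd.DataFrame:
    """Per trait x day x cohort HK scans with per-scan permutation thresholds.

    Returns the QTL catalog: one row per significant chromosome peak with
    trait, cohort, day, DAS, chrom, pos, LOD, effect, interval and threshold.
    Scans with fewer than ``min_lines`` phenotyped lines are skipped (logged).
    """
    sowing_by_cohort = sowing_by_cohort or {}
    records = []
    for trait in traits:
        means = entry_means_by_cohort(htp_table, layout, trait)
        for (day, cohort), pheno in sorted(means.items()):
            pheno = pheno[pheno.index.isin(probgrid.line_ids)]
            if len(pheno) < min_lines:
                log.info("skipping %s day %s cohort %s: %d lines", trait, day, cohort, len(pheno))
                continue
            das = day - sowing_by_cohort.get(cohort, 0)
            thr = permutation_threshold(pheno, probgrid, n_perm, alpha, seed=seed)
            scan = hk_scan(pheno, probgrid)
            for chrom, grp in scan.groupby("chrom", sort=False):
                peak = grp.loc[grp["lod"].idxmax()]
                if peak["lod"] > thr:
                    ci = lod_interval(scan, chrom)
                    records.append(
                        {
                            "trait": trait,
                            "cohort": cohort,
                            "day": day,
                            "das": das,
                            "chrom": chrom,
                            "pos_cM": round(float(peak["pos_cM"]), 1),
                            "label": f"{chrom}@{peak['pos_cM']:.1f}",
                            "lod": float(peak["lod"]),
                            "effect": float(peak["effect"]),
                            "ci_lo_cM": ci[0],
                            "ci_hi_cM": ci[1],
                            "threshold": thr,
                            "significant": True,
                        }
                    )
    return pd.DataFrame(records)


def peak_histogram(catalog: pd.DataFrame, bin_cM: float = 5.0) -> pd.DataFrame:
    """Counts of significant peaks per chromosome position bin, stacked by
    trait: columns chrom, bin_lo_cM, bin_hi_cM, trait, count."""
    if catalog.empty:
        return pd.DataFrame(columns=["chrom", "bin_lo_cM", "bin_hi_cM", "trait", "count"])
    cat = catalog[catalog["significant"]].copy()
    cat["bin"] = np.floor(cat["pos_cM"] / bin_cM).astype(int)
    rows = []
    for (chrom, b, trait), grp in cat.groupby(["chrom", "bin", "trait"]):
        rows.append((chrom, b * bin_cM, (b + 1) * bin_cM, trait, len(grp)))
    return pd.DataFrame(rows, columns=["chrom", "bin_lo_cM", "bin_hi_cM", "trait", "count"])


# ---------------------------------------------------------------------------
# effect trajectories
# ---------------------------------------------------------------------------

@dataclass
class EffectTrajectory:
    """A named QTL's per-date effect estimates plus fitted time trends."""

    label: str
    trait: str
    points: pd.DataFrame  # cohort, day, das, effect, se
    cohort_trends: pd.DataFrame  # cohort, slope, intercept (effect vs DAS)
    overall_trend: tuple[float, float]  # slope, intercept


def effect_trajectory(
    htp_table: pd.DataFrame,
    layout: pd.DataFrame,
    probgrid: ProbGrid,
    qtl_label: str,
    trait: str,
    sowing_by_cohort: dict[int, int] | None = None,
    min_lines: int = 50,
) -> EffectTrajectory:
    """Re-estimate a QTL's additive effect at its fixed position for every
    date and cohort (no peak re-search), with OLS trends over DAS.
    """
    chrom, pos = qtl_label.split("@")
    pos = float(pos)
    sowing_by_cohort = sowing_by_cohort or {}
    means = entry_means_by_cohort(htp_table, layout, trait)
    rows = []
    for (day, cohort), pheno in sorted(means.items()):
        pheno = pheno[pheno.index.isin(probgrid.line_ids)]
        if len(pheno) < min_lines:
            rows.append({"cohort": cohort, "day": day, "das": np.nan, "effect": np.nan, "se": np.nan})
            continue
        das = day - sowing_by_cohort.get(cohort, 0)
        est = fit_effects_at(pheno, probgrid, [(chrom, pos)])
        rows.append(
            {
                "cohort": cohort,
                "day": day,
                "das": das,
                "effect": float(est["effect"].iloc[0]),
                "se": float(est["se"].iloc[0]),
            }
        )
    pts = pd.DataFrame(rows)
    trends = []
    for cohort, grp in pts.dropna().groupby("cohort"):
        if len(grp) >= 2:
            slope, intercept = np.polyfit(grp["das"], grp["effect"], 1)
        else:
            slope, intercept = np.nan, np.nan
        trends.append({"cohort": cohort, "slope": slope, "intercept": intercept})
    ok = pts.dropna()
    overall = tuple(np.polyfit(ok["das"], ok["effect"], 1)) if len(ok) >= 2 else (np.nan, np.nan)
    return EffectTrajectory(qtl_label, trait, pts, pd.DataFrame(trends), overall)


def best_window(points: pd.DataFrame, by: str = "effect") -> dict:
    """Contiguous DAS window maximising the mean |effect| (or LOD).

    ``points`` needs columns das and the ``by`` column (cohorts pooled by
    mean per DAS first).  Ties prefer the longer, then earlier window; a
    fully tied profile returns the whole span with ``tied=True``.
    """
    ok = points.dropna(subset=["das", by])
    if ok["das"].nunique() < 3:
        raise ValueError("need at least 3 distinct DAS values")
    per_das = ok.groupby("das")[by].apply(lambda v: np.mean(np.abs(v))).sort_index()
    das = per_das.index.to_numpy(float)
    val = per_das.to_numpy(float)
    n = len(das)
    best = None  # (mean, length, -start, i, j)
    for i in range(n):
        for j in range(i, n):
            m = float(val[i : j + 1].mean())
            key = (round(m, 12), j - i, -i)
            if best is None or key > best[0]:
                best = (key, i, j)
    (_, _, _), i, j = best
    tied = bool(np.allclose(val, val[0]))
    if tied:
        i, j = 0, n - 1
    return {
        "das_lo": float(das[i]),
        "das_hi": float(das[j]),
        "mean_signal": float(val[i : j + 1].mean()),
        "tied": tied,
    }


# ---------------------------------------------------------------------------
# effect and breeding-value quadrants
# ---------------------------------------------------------------------------

def _consensus_positions(models: list[QTLModel], merge_cM: float) -> list[tuple[str, float]]:
    """Union of model QTL positions with same-chromosome peaks within
    ``merge_cM`` collapsed to one consensus location (their mean)."""
    pts = sorted({(t.chrom, t.pos_cM) for m in models for t in m.terms})
    out: list[tuple[str, float]] = []
    for chrom, pos in pts:
        if out and out[-1][0] == chrom and abs(pos - out[-1][1]) <= merge_cM:
            out[-1] = (chrom, round((out[-1][1] + pos) / 2.0, 1))
        else:
            out.append((chrom, pos))
    return out


def effect_quadrants(
    grain_model: QTLModel,
    hi_model: QTLModel,
    grain_pheno: pd.Series,
    hi_pheno: pd.Series,
    probgrid: ProbGrid,
    merge_cM: float = 10.0,
) -> dict:
    """Joint grain-yield / harvest-index view of the fitted QTL models.

    The two models' peaks are merged into consensus locations (peaks on one
    chromosome within ``merge_cM`` are one locus); both traits' effects are
    re-estimated jointly at those fixed positions.  Effects are reported
    for the IR64 allele (the negative of the Aswina-allele effect), with a
    quadrant label; QTL whose effect on one trait is within 2 SE of zero sit
    on the axis ("axis" class).  Per-line breeding values are the summed
    fitted QTL effects; quadrants are centred at the IR64 parent's values.
    """
    if not grain_model.terms and not hi_model.terms:
        raise ValueError("both models are empty")
    positions = _consensus_positions([grain_model, hi_model], merge_cM)
    grain_fit = fit_effects_at(grain_pheno, probgrid, positions)
    hi_fit = fit_effects_at(hi_pheno, probgrid, positions)
    rows = []
    for k, (chrom, pos) in enumerate(positions):
        ge, gse = grain_fit["effect"].iloc[k], grain_fit["se"].iloc[k]
        he, hse = hi_fit["effect"].iloc[k], hi_fit["se"].iloc[k]
        ir64_g, ir64_h = -ge, -he  # IR64 allele effect = -(Aswina effect)
        g_sig = abs(ge) > 2 * gse
        h_sig = abs(he) > 2 * hse
        if g_sig and h_sig:
            quad = ("right" if ir64_g > 0 else "left") + "-" + ("top" if ir64_h > 0 else "bottom")
            cls = "both"
        elif h_sig:
            quad, cls = "hi-axis", "hi_only"
        elif g_sig:
            quad, cls = "grain-axis", "grain_only"
        else:
            quad, cls = "origin", "neither"
        rows.append(
            {
                "qtl": f"{chrom}@{pos:.1f}",
                "ir64_grain_effect": float(ir64_g),
                "ir64_hi_effect": float(ir64_h),
                "grain_se": float(gse),
                "hi_se": float(hse),
                "quadrant": quad,
                "klass": cls,
            }
        )
    qtl_table = pd.DataFrame(rows)
    # per-line breeding values: sum of fitted QTL effects times dosage
    X, _ = probgrid.dosage_matrix()
    idx = [probgrid.index_of(c, p) for c, p in positions]
    D = X[:, idx]
    bv_grain = D @ grain_fit["effect"].to_numpy()
    bv_hi = D @ hi_fit["effect"].to_numpy()
    # IR64 parent: dosage -1 at every QTL
    ir64_grain = -grain_fit["effect"].sum()
    ir64_hi = -hi_fit["effect"].sum()
    bv = pd.DataFrame(
        {"line": probgrid.line_ids, "bv_grain": bv_grain, "bv_hi": bv_hi}
    )
    bv["quadrant"] = (
        np.where(bv["bv_grain"] > ir64_grain, "right", "left")
        + "-"
        + np.where(bv["bv_hi"] > ir64_hi, "top", "bottom")
    )
    return {
        "qtl": qtl_table,
        "breeding_values": bv,
        "center": {"grain": float(ir64_grain), "hi": float(ir64_hi)},
    }
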