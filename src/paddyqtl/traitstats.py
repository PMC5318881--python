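"""Manual-trait computation and quantitative-genetic summaries.

Covers the hand-measured side of the trial — days to heading (DTH, the day
80% of a plot's plants have flowered), plot means of three sampled plants,
harvest index — and the entry-level statistics used downstream: least-squares
(LS) means adjusted for cohort and block, broad-sense heritability from a
variance-component decomposition, and genetic correlations between trait
pairs over time.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


# ---------------------------------------------------------------------------
# manual traits
# ---------------------------------------------------------------------------

def days_to_heading(flowering: pd.DataFrame) -> pd.Series:
    """First day (after sowing) the flowering fraction reaches 0.80 per plot.

    ``flowering`` is plots x days (columns are DAS, fractions monotone
    non-decreasing).  Plots that never reach 0.80 get NaN.
    """
    days = np.asarray(flowering.columns, dtype=float)
    frac = flowering.to_numpy(dtype=float)
    if np.any(np.diff(frac, axis=1) < -1e-9):
        raise ValueError("flowering fractions must be monotone non-decreasing")
    reached = frac >= 0.80
    first = np.where(reached.any(axis=1), reached.argmax(axis=1), -1)
    dth = np.where(first >= 0, days[np.clip(first, 0, None)], np.nan)
    return pd.Series(dth, index=flowering.index, name="dth_days")


def plot_phenotypes(plants: pd.DataFrame, dth: pd.Series | None = None) -> pd.DataFrame:
    """Plot-mean manual traits from three sampled plants per plot.

    Expects columns ``height_cm_p1..3``, ``biomass_g_p1..3``,
    ``panicle_g_p1..3`` and ``n_plants``.  Harvest index is
    panicle / (vegetative biomass + panicle); plots with fewer than 13
    plants carry a ``discard`` flag (their values are reported but flagged).
    """
    out = pd.DataFrame(index=plants.index)
    for trait in ("height_cm", "biomass_g", "panicle_g"):
        cols = [f"{trait}_p{i}" for i in (1, 2, 3)]
        out[trait] = plants[cols].mean(axis=1)
    total = out["biomass_g"] + out["panicle_g"]
    with np.errstate(invalid="ignore", divide="ignore"):
        out["hi"] = np.where(total > 0, out["panicle_g"] / total, np.nan)
    out["n_plants"] = plants["n_plants"]
    out["discard"] = plants["n_plants"] < 13
    if dth is not None:
        out.insert(0, "dth_days", dth.reindex(out.index))
    out.index.name = "plot_id"
    return out


# ---------------------------------------------------------------------------
# LS means
# ---------------------------------------------------------------------------

def ls_means(values: pd.Series, layout: pd.DataFrame, include_block: bool = False) -> pd.Series:
    """Least-squares entry means adjusted for cohort (and optionally block).

    Model: value ~ entry + cohort, all fixed effects; the LS mean of an
    entry is its prediction averaged equally over every observed adjustment
    level.  With balanced complete data this reduces to the raw entry mean.

    ``include_block`` adds block-within-cohort contrasts.  It is off by
    default because the trial blocks entries by their (genetic) height rank:
    an entry then sits in the same block in every cohort, block effects are
    collinear with entry effects, and adjusting for them absorbs — and can
    even invert — real genetic signal.  Only enable it for layouts whose
    blocks are randomised with respect to entries.
    """
    lay = layout.set_index("plot_id")
    df = pd.DataFrame(
        {
            "y": values,
            "entry": lay["entry_id"].reindex(values.index),
            "cohort": lay["cohort"].reindex(values.index),
            "block": lay["block"].reindex(values.index),
        }
    ).dropna()
    if df.empty:
        return pd.Series(dtype=float)
    if include_block:
        df["adj"] = (
            df["cohort"].astype(int).astype(str) + "/" + df["block"].astype(int).astype(str)
        )
    else:
        df["adj"] = df["cohort"].astype(int).astype(str)
    entries = pd.Categorical(df["entry"])
    levels = pd.Categorical(df["adj"])
    E = pd.get_dummies(entries, dtype=float).to_numpy()
    A = pd.get_dummies(levels, drop_first=True, dtype=float).to_numpy()
    X = np.column_stack([E, A])  # entry means + adjustment contrasts
    coef, _, _, _ = np.linalg.lstsq(X, df["y"].to_numpy(float), rcond=None)
    k_e = E.shape[1]
    entry_eff = coef[:k_e]
    adj_eff = coef[k_e:]
    # average adjustment contrast over all observed levels (the dropped
    # reference level contributes 0)
    mean_adj = adj_eff.sum() / (len(adj_eff) + 1)
    return pd.Series(entry_eff + mean_adj, index=entries.categories, name=values.name)


# ---------------------------------------------------------------------------
# heritability
# ---------------------------------------------------------------------------

def heritability(values: pd.Series, layout: pd.DataFrame) -> float:
    """Broad-sense heritability H² = VG / (VG + VE / r̄).

    Entry and residual variances come from a one-way ANOVA on
    cohort-adjusted values (method of moments); r̄ is the harmonic mean
    number of replicate plots per entry.  Block means are NOT removed: the
    trial blocks by genetic height, so block means carry genetic variance
    (see :func:`ls_means`).  Returns NaN when nothing is replicated.
    """
    lay = layout.set_index("plot_id")
    df = pd.DataFrame(
        {
            "y": values,
            "entry": lay["entry_id"].reindex(values.index),
            "cohort": lay["cohort"].reindex(values.index),
        }
    ).dropna()
    reps = df.groupby("entry")["y"].count()
    reps = reps[reps > 1]
    if reps.empty:
        return float("nan")
    df["adj"] = df["y"] - df.groupby("cohort")["y"].transform("mean") + df["y"].mean()
    sub = df[df["entry"].isin(reps.index)]
    grand = sub["adj"].mean()
    by_entry = sub.groupby("entry")["adj"]
    k = len(reps)
    n = len(sub)
    ss_between = float((by_entry.count() * (by_entry.mean() - grand) ** 2).sum())
    ss_within = float(((sub["adj"] - by_entry.transform("mean")) ** 2).sum())
    ms_between = ss_between / max(k - 1, 1)
    ms_within = ss_within / max(n - k, 1)
    r_bar = len(reps) / float((1.0 / reps).sum())  # harmonic mean replicates
    vg = max((ms_between - ms_within) / r_bar, 0.0)
    ve = ms_within
    denom = vg + ve / r_bar
    return float(vg / denom) if denom > 0 else float("nan")


# ---------------------------------------------------------------------------
# genetic correlations over time
# ---------------------------------------------------------------------------

def genetic_correlation(means_a: pd.Series, means_b: pd.Series) -> tuple[float, float]:
    """Pearson correlation (r, r²) between entry-level means of two traits.

    This correlates entry means rather than fitting a bivariate
    variance-component model — an approximation appropriate for large
    RIL panels.  Requires >= 3 shared entries, else (NaN, NaN).
    """
    joined = pd.concat([means_a, means_b], axis=1, join="inner").dropna()
    if len(joined) < 3:
        return float("nan"), float("nan")
    r = float(np.corrcoef(joined.iloc[:, 0], joined.iloc[:, 1])[0, 1])
    return r, r * r


def correlation_over_time(
    manual_means: pd.Series,
    htp_table: pd.DataFrame,
    layout: pd.DataFrame,
    trait: str,
    by_cohort: bool = True,
) -> pd.DataFrame:
    """Genetic correlation of a manual trait with an HTP trait per sampling
    day (and cohort): columns day, cohort, r, r2, n_entries."""
    lay = layout.set_index("plot_id")
    sub = htp_table[htp_table["trait"] == trait].copy()
    sub["entry"] = lay["entry_id"].reindex(sub["plot_id"]).to_numpy()
    sub["cohort"] = lay["cohort"].reindex(sub["plot_id"]).to_numpy()
    rows = []
    group_cols = ["day", "cohort"] if by_cohort else ["day"]
    for keys, grp in sub.groupby(group_cols):
        keys = keys if isinstance(keys, tuple) else (keys,)
        htp_means = grp.groupby("entry")["value"].mean()
        r, r2 = genetic_correlation(manual_means, htp_means)
        rows.append(dict(zip(group_cols, keys), r=r, r2=r2,
                         n_entries=len(htp_means.index.intersection(manual_means.index))))
    return pd.DataFrame(rows)


def loess_smooth(x, y, span: float = 0.75, n_out: int = 50):
    """Local quadratic (tricube-weighted) smooth with a 95% pointwise band.

    A small self-contained loess used for presentation curves of
    correlation-vs-time; returns (grid, fitted, lower, upper).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 4:
        grid = np.linspace(x.min(), x.max(), n_out) if len(x) else np.array([])
        fit = np.interp(grid, np.sort(x), y[np.argsort(x)]) if len(x) else grid
        return grid, fit, fit, fit
    k = max(int(np.ceil(span * len(x))), 4)
    grid = np.linspace(x.min(), x.max(), n_out)
    fit = np.empty(n_out)
    se = np.empty(n_out)
    for i, g in enumerate(grid):
        d = np.abs(x - g)
        h = np.sort(d)[k - 1]
        w = np.clip(1 - (d / max(h, 1e-12)) ** 3, 0, None) ** 3
        W = np.diag(w)
        A = np.column_stack([np.ones_like(x), x - g, (x - g) ** 2])
        AtW = A.T @ W
        try:
            beta, cov = np.linalg.solve(AtW @ A, np.eye(3)) @ (AtW @ y), np.linalg.inv(AtW @ A)
        except np.linalg.LinAlgError:
            beta = np.array([np.average(y, weights=np.maximum(w, 1e-12)), 0.0, 0.0])
            cov = np.eye(3)
        fit[i] = beta[0]
        resid = y - A @ beta
        dof = max(w.sum() - 3, 1.0)
        s2 = float((w * resid**2).sum() / dof)
        se[i] = np.sqrt(max(s2 * cov[0, 0], 0.0))
    return grid, fit, fit - 1.96 * se, fit + 1.96 * se
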