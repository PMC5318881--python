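"""Raw sensor-stream post-processing to plot-level daily trait tables.

Mirrors the field post-processing convention for tractor-boom proximal
sensing: samples are assigned to plots by GPS position with a 0.20 m border
exclusion, reflectance is cross-calibrated to the first sensor per field run
per day, canopy temperature is cross-calibrated against unplanted
water-reference plots pooled over all sampling dates, vegetation indices are
computed per sample, and six exclusion filters are applied in a fixed order
before plot-day means are written out:

1. all channels excluded while tractor speed < 0.3 kph or moving in reverse;
2. all channels excluded for plots with fewer than 13 plants;
3. a plot's channel excluded when it has fewer than 4 samples;
4. a plot's channel excluded when its coefficient of variation exceeds 0.5;
5. canopy-temperature samples outside 22.0–40.0 °C excluded;
6. canopy-height samples outside 0.10–2.60 m excluded.

Later rules act on what earlier rules left; per-rule exclusion counts are
logged.  CV uses the (n−1) sample standard deviation and a zero-mean channel
is excluded (undefined ratio).  Samples exactly on the border line are
excluded (strict interior); reverse motion is a negative along-track
velocity component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from paddyqtl.simdata import BANDS, SENSORS_PER_BOOM

CHANNELS = ("NDVI", "NDRE", "Chla", "CTD", "HTP_height")
_CHAN_COL = {"NDVI": "ndvi", "NDRE": "ndre", "Chla": "chla", "CTD": "ctd", "HTP_height": "height_m"}


class CalibrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class FilterThresholds:
    """Filter constants; defaults are the field campaign's printed values."""

    border_m: float = 0.20
    min_speed_kph: float = 0.3
    min_plants: int = 13
    min_samples: int = 4
    max_cv: float = 0.5
    temp_lo_C: float = 22.0
    temp_hi_C: float = 40.0
    height_lo_m: float = 0.10
    height_hi_m: float = 2.60


# ---------------------------------------------------------------------------
# plot-level sample extraction
# ---------------------------------------------------------------------------

def _along_track_velocity(stream: pd.DataFrame) -> np.ndarray:
    """Signed along-track velocity (m/s) per record, per pass.

    Positive along the nominal heading; negative means reversing.
    """
    v = np.zeros(len(stream))
    for _, grp in stream.groupby("pass_id", sort=False):
        idx = grp.index.to_numpy()
        y = grp["y"].to_numpy()
        t = grp["t"].to_numpy()
        if len(y) < 2:
            continue
        dy = np.gradient(y, t)
        sign = np.where(np.isclose(grp["heading_deg"].to_numpy() % 360.0, 0.0), 1.0, -1.0)
        v[stream.index.get_indexer(idx)] = dy * sign
    return v


def extract_plot_samples(
    stream: pd.DataFrame, layout: pd.DataFrame, border_m: float = 0.20
) -> pd.DataFrame:
    """Assign every sensor sample to at most one plot (strict interior).

    A sample is retained only if it lies more than ``border_m`` inside its
    plot's rectangle; everything else (borders, bunds, alleys) is dropped.
    Returns a long table with one row per retained (record, sensor) pair.
    """
    if stream.empty:
        import warnings

        warnings.warn("empty sensor stream: no samples extracted")
        return pd.DataFrame()
    along = _along_track_velocity(stream)
    parts = []
    for k in range(1, SENSORS_PER_BOOM + 1):
        part = pd.DataFrame(
            {
                "day": stream["day"].to_numpy(),
                "cohort": stream["cohort"].to_numpy(),
                "field": stream["field"].to_numpy(),
                "pass_id": stream["pass_id"].to_numpy(),
                "t": stream["t"].to_numpy(),
                "sensor": k,
                "x": stream[f"s{k}_x"].to_numpy(),
                "y": stream[f"s{k}_y"].to_numpy(),
                "speed_kph": stream["speed_kph"].to_numpy(),
                "along_v": along,
                "air_temp_C": stream["air_temp_C"].to_numpy(),
                "nir": stream[f"s{k}_nir"].to_numpy(),
                "re": stream[f"s{k}_re"].to_numpy(),
                "red": stream[f"s{k}_red"].to_numpy(),
                "ctemp_C": stream[f"s{k}_ctemp_C"].to_numpy(),
                "dist_m": stream[f"s{k}_dist_m"].to_numpy(),
                "gpsh_m": stream[f"s{k}_gpsh_m"].to_numpy(),
            }
        )
        parts.append(part)
    samples = pd.concat(parts, ignore_index=True)
    # plot assignment per cohort-field grid
    samples["plot_id"] = ""
    samples["is_water"] = False
    for (_, _), lgrp in layout.groupby(["cohort", "field"]):
        xe = np.unique(lgrp["x_min"])
        ye = np.unique(lgrp["y_min"])
        lut = {}
        for r in lgrp.itertuples():
            lut[(np.searchsorted(xe, r.x_min), np.searchsorted(ye, r.y_min))] = (
                r.plot_id,
                r.x_min,
                r.y_min,
                r.x_max,
                r.y_max,
                r.entry_type == "WATER",
            )
        inbox = (
            (samples["x"] >= lgrp["x_min"].min())
            & (samples["x"] < lgrp["x_max"].max())
            & (samples["y"] >= lgrp["y_min"].min())
            & (samples["y"] < lgrp["y_max"].max())
        ).to_numpy()
        if not inbox.any():
            continue
        xs = samples.loc[inbox, "x"].to_numpy()
        ys = samples.loc[inbox, "y"].to_numpy()
        ci = np.searchsorted(xe, xs, side="right") - 1
        ri = np.searchsorted(ye, ys, side="right") - 1
        pid = np.empty(len(xs), dtype=object)
        wat = np.zeros(len(xs), dtype=bool)
        pid[:] = ""
        for j in range(len(xs)):
            hit = lut.get((ci[j], ri[j]))
            if hit is None:
                continue
            p, x0, y0, x1, y1, isw = hit
            if (
                xs[j] > x0 + border_m
                and xs[j] < x1 - border_m
                and ys[j] > y0 + border_m
                and ys[j] < y1 - border_m
            ):
                pid[j] = p
                wat[j] = isw
        samples.loc[inbox, "plot_id"] = pid
        samples.loc[inbox, "is_water"] = wat
    return samples[samples["plot_id"] != ""].reset_index(drop=True)


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def calibrate_reflectance(samples: pd.DataFrame, reference: int = 1) -> pd.DataFrame:
    """Per-run multiplicative band gains normalising every sensor to the
    reference: gain(s, b) = mean_run(ref, b) / mean_run(s, b).

    A run is one field traversal on one day (day, cohort, field).  Returns a
    frame with columns day, cohort, field, sensor, band, gain; the reference
    sensor's gain is exactly 1.
    """
    rows = []
    for (day, cohort, fld), grp in samples.groupby(["day", "cohort", "field"]):
        means = grp.groupby("sensor")[list(BANDS)].mean()
        if reference not in means.index:
            raise CalibrationError(f"reference sensor {reference} has no samples in run {day}/{cohort}/{fld}")
        for s in means.index:
            for b in BANDS:
                m = means.at[s, b]
                if not np.isfinite(m) or m == 0:
                    raise CalibrationError(f"sensor {s} band {b} has zero mean in run {day}/{cohort}/{fld}")
                gain = 1.0 if s == reference else float(means.at[reference, b] / m)
                rows.append((day, cohort, fld, s, b, gain))
    return pd.DataFrame(rows, columns=["day", "cohort", "field", "sensor", "band", "gain"])


def apply_reflectance_calibration(samples: pd.DataFrame, gains: pd.DataFrame) -> pd.DataFrame:
    """Multiply each sample's bands by its run/sensor gains."""
    out = samples.copy()
    wide = gains.pivot_table(
        index=["day", "cohort", "field", "sensor"], columns="band", values="gain"
    )
    key = pd.MultiIndex.from_frame(out[["day", "cohort", "field", "sensor"]])
    aligned = wide.reindex(key)
    for b in BANDS:
        out[b] = out[b].to_numpy() * aligned[b].to_numpy()
    return out


def calibrate_canopy_temp(samples: pd.DataFrame, reference: int = 1) -> pd.Series:
    """Additive temperature offsets from unplanted water plots, pooled over
    all sampling dates: offset(s) = mean_water(ref) − mean_water(s).

    ``samples`` should span every date to be corrected (pass the
    concatenation of all days' extracted samples).
    """
    water = samples[samples["is_water"]]
    if water.empty:
        raise CalibrationError("no water-plot samples available for temperature calibration")
    means = water.groupby("sensor")["ctemp_C"].mean()
    if reference not in means.index:
        raise CalibrationError(f"reference sensor {reference} has no water samples")
    offsets = means.loc[reference] - means
    missing = set(range(1, SENSORS_PER_BOOM + 1)) - set(means.index)
    if missing:
        raise CalibrationError(f"no water-plot samples for sensors {sorted(missing)}")
    offsets.name = "offset_C"
    return offsets


# ---------------------------------------------------------------------------
# derived channels
# ---------------------------------------------------------------------------

def vegetation_indices(nir, re, red):
    """NDVI = (NIR−R)/(NIR+R); NDRE = (NIR−RE)/(NIR+RE); Chla = NIR/RE − 1."""
    nir = np.asarray(nir, dtype=float)
    re = np.asarray(re, dtype=float)
    red = np.asarray(red, dtype=float)
    ndvi = (nir - red) / (nir + red)
    ndre = (nir - re) / (nir + re)
    chla = nir / re - 1.0
    return ndvi, ndre, chla


def add_derived_channels(
    samples: pd.DataFrame,
    temp_offsets: pd.Series | None = None,
    exclusion_log: list | None = None,
) -> pd.DataFrame:
    """Attach per-sample NDVI/NDRE/Chla, calibrated canopy temperature, CTD
    and canopy height columns.

    Samples with a non-positive reflectance band get missing indices and are
    counted in the exclusion log.
    """
    out = samples.copy()
    bad = (out["nir"] <= 0) | (out["re"] <= 0) | (out["red"] <= 0)
    if exclusion_log is not None and bad.any():
        exclusion_log.append({"rule": "nonpositive_band", "scope": "sample", "n_excluded": int(bad.sum())})
    ndvi, ndre, chla = vegetation_indices(out["nir"], out["re"], out["red"])
    out["ndvi"] = np.where(bad, np.nan, ndvi)
    out["ndre"] = np.where(bad, np.nan, ndre)
    out["chla"] = np.where(bad, np.nan, chla)
    if temp_offsets is not None:
        off = temp_offsets.reindex(out["sensor"]).to_numpy()
    else:
        off = 0.0
    out["ctemp_cal_C"] = out["ctemp_C"].to_numpy() + off
    out["ctd"] = out["air_temp_C"].to_numpy() - out["ctemp_cal_C"].to_numpy()
    out["height_m"] = out["gpsh_m"].to_numpy() - out["dist_m"].to_numpy()
    return out


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def apply_filters(
    samples: pd.DataFrame,
    plant_counts: pd.Series,
    thresholds: FilterThresholds = FilterThresholds(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the six exclusion rules in order; water plots are dropped first
    (they are calibration references, not phenotyped plots).

    Returns (filtered samples with channel columns masked to NaN where a
    channel is excluded, per-rule exclusion log).
    """
    log: list[dict] = []
    out = samples[~samples["is_water"]].copy()
    th = thresholds
    # 1. speed / reverse: all channels
    bad = (out["speed_kph"] < th.min_speed_kph) | (out["along_v"] < 0)
    log.append({"rule": "speed_or_reverse", "scope": "sample", "n_excluded": int(bad.sum())})
    out = out[~bad]
    # 2. plant count: all channels
    counts = plant_counts.reindex(out["plot_id"]).to_numpy()
    bad = counts < th.min_plants
    log.append({"rule": "plant_count", "scope": "sample", "n_excluded": int(bad.sum())})
    out = out[~bad].copy()
    # 3. per-channel minimum sample count
    n_eff = out.groupby("plot_id")[list(_CHAN_COL.values())].count()
    few = n_eff < th.min_samples
    excluded_cells = 0
    for chan, col in _CHAN_COL.items():
        bad_plots = few.index[few[col]]
        if len(bad_plots):
            mask = out["plot_id"].isin(bad_plots)
            excluded_cells += int(out.loc[mask, col].notna().sum())
            out.loc[mask, col] = np.nan
    log.append({"rule": "min_samples", "scope": "plot-channel-sample", "n_excluded": excluded_cells})
    # 4. coefficient of variation per plot-channel (strict > max_cv)
    grp = out.groupby("plot_id")[list(_CHAN_COL.values())]
    mean = grp.mean()
    sd = grp.std(ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = sd.abs() / mean.abs()
    bad_cv = (cv > th.max_cv) | (mean == 0)
    excluded_cells = 0
    for chan, col in _CHAN_COL.items():
        bad_plots = bad_cv.index[bad_cv[col].fillna(False)]
        if len(bad_plots):
            mask = out["plot_id"].isin(bad_plots)
            excluded_cells += int(out.loc[mask, col].notna().sum())
            out.loc[mask, col] = np.nan
    log.append({"rule": "cv", "scope": "plot-channel-sample", "n_excluded": excluded_cells})
    # 5. canopy temperature range (per sample, CTD channel)
    bad = (out["ctemp_cal_C"] < th.temp_lo_C) | (out["ctemp_cal_C"] > th.temp_hi_C)
    bad &= out["ctd"].notna()
    log.append({"rule": "temp_range", "scope": "sample-CTD", "n_excluded": int(bad.sum())})
    out.loc[bad, "ctd"] = np.nan
    # 6. canopy height range (per sample, height channel)
    bad = (out["height_m"] < th.height_lo_m) | (out["height_m"] > th.height_hi_m)
    bad &= out["height_m"].notna()
    log.append({"rule": "height_range", "scope": "sample-height", "n_excluded": int(bad.sum())})
    out.loc[bad, "height_m"] = np.nan
    return out.reset_index(drop=True), pd.DataFrame(log)


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def aggregate_daily(samples: pd.DataFrame, layout: pd.DataFrame | None = None) -> pd.DataFrame:
    """Plot-day trait table: mean of retained samples per plot and channel.

    One row per (plot, day, trait); plots with no surviving samples for a
    channel get a missing value with the ``no_samples`` flag.  If ``layout``
    is given, every planted plot appears for every day in the input.
    """
    rows = []
    days = sorted(samples["day"].unique()) if not samples.empty else []
    if layout is not None:
        all_plots = layout.loc[layout["entry_type"] != "WATER", "plot_id"].tolist()
    else:
        all_plots = sorted(samples["plot_id"].unique())
    for day in days:
        sub = samples[samples["day"] == day]
        grp = sub.groupby("plot_id")
        agg_mean = grp[list(_CHAN_COL.values())].mean()
        agg_n = grp[list(_CHAN_COL.values())].count()
        agg_sd = grp[list(_CHAN_COL.values())].std(ddof=1)
        for plot in all_plots:
            for chan, col in _CHAN_COL.items():
                if plot in agg_mean.index and agg_n.at[plot, col] > 0:
                    m = agg_mean.at[plot, col]
                    n = int(agg_n.at[plot, col])
                    s = agg_sd.at[plot, col]
                    cv = abs(s / m) if n > 1 and m != 0 else np.nan
                    rows.append((plot, day, chan, m, n, cv, ""))
                else:
                    rows.append((plot, day, chan, np.nan, 0, np.nan, "no_samples"))
    return pd.DataFrame(
        rows, columns=["plot_id", "day", "trait", "value", "n_samples", "cv", "qc_flags"]
    )


# ---------------------------------------------------------------------------
# end-to-end convenience
# ---------------------------------------------------------------------------

def process_streams(
    streams: dict[int, pd.DataFrame],
    layout: pd.DataFrame,
    plant_counts: pd.Series | None = None,
    thresholds: FilterThresholds = FilterThresholds(),
    calibrate: bool = True,
) -> dict:
    """Full post-processing for a set of daily streams.

    Reflectance gains are estimated per run per day; temperature offsets are
    pooled over all days (water plots).  Set ``calibrate=False`` to skip
    cross-sensor normalisation (e.g. when sensors are known unbiased).

    Returns dict with keys ``table`` (plot-day trait rows), ``exclusions``,
    ``gains``, ``temp_offsets``.
    """
    if plant_counts is None:
        plant_counts = layout.set_index("plot_id")["n_plants"]
    extracted = {
        day: extract_plot_samples(stream, layout, thresholds.border_m)
        for day, stream in streams.items()
    }
    pooled = pd.concat([s for s in extracted.values() if not s.empty], ignore_index=True)
    gains = calibrate_reflectance(pooled) if calibrate else None
    offsets = calibrate_canopy_temp(pooled) if calibrate else None
    exclusion_rows = []
    tables = []
    for day, samples in extracted.items():
        if samples.empty:
            continue
        if calibrate:
            samples = apply_reflectance_calibration(samples, gains)
        extra_log: list = []
        samples = add_derived_channels(samples, offsets, extra_log)
        filtered, log = apply_filters(samples, plant_counts, thresholds)
        log = pd.concat([pd.DataFrame(extra_log), log], ignore_index=True)
        log.insert(0, "day", day)
        exclusion_rows.append(log)
        tables.append(aggregate_daily(filtered, layout))
    table = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()
    exclusions = pd.concat(exclusion_rows, ignore_index=True) if exclusion_rows else pd.DataFrame()
    return {"table": table, "exclusions": exclusions, "gains": gains, "temp_offsets": offsets}
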