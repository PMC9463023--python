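"""Occupancy measures from image-score records.

Three measures per breeding site and season, each available for three
presence filters (``any`` = 1 or 2 birds, ``single`` = exactly 1,
``pair`` = exactly 2):

return date
    First survey day on which at least one image matches the presence
    filter at the site.
occupancy frequency
    Proportion of survey days, from the return day to the end of March,
    on which the site was occupied.
relative time investment (RTI)
    Images with the site occupied divided by images in which at least one
    bird was present *anywhere in the subcolony*, summed over survey days
    from the site's return day (season-level ratio of sums; a per-day mean
    is exposed as an alternative).

A *survey day* is a day with at least one scorable image for the
subcolony; days lost to camera outages are excluded from every
denominator, never scored as absence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .daylight import dawn_dusk_minutes
from .errors import DataError, DegenerateGroupError, UndefinedMetricError

__all__ = [
    "PRESENCE_FILTERS",
    "SurveyLedger",
    "build_survey_ledger",
    "occupancy_metrics",
    "return_date",
    "occupancy_frequency",
    "relative_time_investment",
    "standardize",
    "colony_summaries",
]

PRESENCE_FILTERS = ("any", "pair", "single")


def _match_mask(counts: np.ndarray, presence_filter: str) -> np.ndarray:
    if presence_filter == "any":
        return counts >= 1
    if presence_filter == "pair":
        return counts == 2
    if presence_filter == "single":
        return counts == 1
    raise ValueError(
        f"presence_filter must be one of {PRESENCE_FILTERS}, "
        f"got {presence_filter!r}"
    )


def _ensure_season_day(records: pd.DataFrame) -> pd.DataFrame:
    if "season_day" in records.columns:
        return records
    records = records.copy()
    start_year = records["season"].astype(str).str.slice(0, 4).astype(int)
    sep1 = pd.to_datetime(start_year.astype(str) + "-09-01")
    records["season_day"] = (
        pd.to_datetime(records["date"]) - sep1
    ).dt.days.astype(np.int16)
    return records


def _check_counts(records: pd.DataFrame) -> None:
    c = records["count"].to_numpy()
    bad = (c < 0) | (c > 2)
    if bad.any():
        rows = np.flatnonzero(bad)[:5].tolist()
        raise DataError(
            f"count outside {{0,1,2}} at rows {rows} (column 'count')"
        )


@dataclass(frozen=True)
class SurveyLedger:
    """Per-day image bookkeeping for each subcolony-season.

    ``days`` has one row per (subcolony, season, season_day) with the number
    of scorable images and the number of images in which at least one bird
    was present anywhere in the subcolony.
    """

    days: pd.DataFrame

    def survey_days(self, subcolony, season) -> np.ndarray:
        d = self.days
        m = (d["subcolony"] == subcolony) & (d["season"] == season)
        return np.sort(d.loc[m, "season_day"].to_numpy())


def build_survey_ledger(records: pd.DataFrame,
                        declared_gaps=None) -> SurveyLedger:
    """Aggregate image scores into the per-day survey ledger.

    Duplicate (site, season, day, time) records are a data error; a day is a
    survey day iff at least one scorable image exists for the subcolony.
    """
    from .simulate import inject_gaps

    records = _ensure_season_day(records)
    _check_counts(records)
    dup = records.duplicated(
        subset=["site_id", "season", "season_day", "time"]
    )
    if dup.any():
        offenders = records.loc[dup, ["site_id", "season", "season_day",
                                      "time"]].head(5)
        raise DataError(
            "duplicate (site, timestamp) records:\n"
            + offenders.to_string(index=False)
        )
    if declared_gaps is not None:
        records = inject_gaps(records, declared_gaps)
    img = (
        records.assign(any_present=records["count"].to_numpy() >= 1)
        .groupby(["subcolony", "season", "season_day", "time"],
                 observed=True)["any_present"]
        .max()
        .reset_index()
    )
    days = (
        img.groupby(["subcolony", "season", "season_day"], observed=True)
        .agg(n_images=("time", "size"), n_any_images=("any_present", "sum"))
        .reset_index()
    )
    return SurveyLedger(days=days)


def occupancy_metrics(records: pd.DataFrame, presence_filter: str = "any",
                      declared_gaps=None,
                      rti_window: str = "return") -> pd.DataFrame:
    """All three occupancy measures for every site-season.

    Returns one row per (site_id, season) with the return day, the
    occupancy-frequency numerator/denominator, the RTI numerator/denominator
    (ratio-of-sums primary value plus a per-day mean), and the presence
    filter used.  Sites never occupied under the filter keep an absent
    return day and zero numerators.  ``rti_window`` is ``"return"``
    (denominator starts at the site's return day, the default) or
    ``"season"`` (whole season).
    """
    from .simulate import inject_gaps

    records = _ensure_season_day(records)
    _check_counts(records)
    if declared_gaps is not None:
        records = inject_gaps(records, declared_gaps)
    if rti_window not in ("return", "season"):
        raise ValueError("rti_window must be 'return' or 'season'")

    counts = records["count"].to_numpy()
    match = _match_mask(counts, presence_filter)

    ledger = build_survey_ledger(records)

    site_day = (
        records.assign(match=match)
        .groupby(["subcolony", "season", "site_id", "season_day"],
                 observed=True)["match"]
        .sum()
        .reset_index(name="n_match")
    )
    site_day = site_day.loc[site_day["n_match"] > 0]
    all_sites = records[["subcolony", "season", "site_id"]].drop_duplicates()

    rows = []
    for (sub, season), day_tab in ledger.days.groupby(
        ["subcolony", "season"], observed=True
    ):
        day_tab = day_tab.sort_values("season_day")
        days = day_tab["season_day"].to_numpy()
        any_img = day_tab["n_any_images"].to_numpy()
        cum_any = np.concatenate([[0], np.cumsum(any_img)])

        grp = site_day[
            (site_day["subcolony"] == sub) & (site_day["season"] == season)
        ]
        present_sites = {}
        for site_id, sd in grp.groupby("site_id", observed=True):
            present_sites[site_id] = sd
        season_sites = all_sites[
            (all_sites["subcolony"] == sub) & (all_sites["season"] == season)
        ]["site_id"]
        for site_id in season_sites:
            sd = present_sites.get(site_id)
            if sd is None or len(sd) == 0:
                rows.append({
                    "subcolony": sub, "site_id": site_id, "season": season,
                    "presence_filter": presence_filter,
                    "return_day": np.nan,
                    "occ_freq_num": 0, "occ_freq_den": 0,
                    "occ_freq": np.nan,
                    "rti_num": 0, "rti_den": 0, "rti": np.nan,
                    "rti_daily_mean": np.nan,
                })
                continue
            ret = int(sd["season_day"].min())
            i0 = int(np.searchsorted(days, ret))
            i0_rti = 0 if rti_window == "season" else i0
            freq_den = int(days.size - i0)
            freq_num = int(len(sd))
            rti_num = int(sd["n_match"].sum())
            rti_den = int(cum_any[-1] - cum_any[i0_rti])
            d_any = any_img[i0_rti:]
            site_by_day = (
                sd.set_index("season_day")["n_match"]
                .reindex(days[i0_rti:], fill_value=0)
                .to_numpy()
            )
            with np.errstate(invalid="ignore", divide="ignore"):
                daily = np.where(d_any > 0, site_by_day / d_any, np.nan)
            daily_mean = (
                float(np.nanmean(daily)) if np.any(d_any > 0) else np.nan
            )
            rows.append({
                "subcolony": sub, "site_id": site_id, "season": season,
                "presence_filter": presence_filter,
                "return_day": ret,
                "occ_freq_num": freq_num, "occ_freq_den": freq_den,
                "occ_freq": freq_num / freq_den if freq_den else np.nan,
                "rti_num": rti_num, "rti_den": rti_den,
                "rti": rti_num / rti_den if rti_den else np.nan,
                "rti_daily_mean": daily_mean,
            })

    out = pd.DataFrame(rows)
    # hard invariants on every output
    assert (out["occ_freq_num"] <= out["occ_freq_den"]).all()
    assert (out["rti_num"] <= out["rti_den"]).all()
    for col in ("occ_freq", "rti"):
        v = out[col].dropna()
        assert ((v >= 0) & (v <= 1)).all()
    return out


# ---------------------------------------------------------------------------
# single-site convenience wrappers


def _one_site(records, site, season, presence_filter):
    if not (records["site_id"] == site).any():
        raise KeyError(f"unknown site {site!r}")
    block = records.loc[records["season"] == season]
    tab = occupancy_metrics(block, presence_filter)
    row = tab.loc[tab["site_id"] == site]
    if len(row) == 0:
        raise KeyError(f"site {site!r} has no records in season {season!r}")
    return row.iloc[0]


def return_date(records, site, season, presence_filter="any"):
    """First survey day with a matching image at the site, or None."""
    row = _one_site(records, site, season, presence_filter)
    return None if pd.isna(row["return_day"]) else int(row["return_day"])


def occupancy_frequency(records, site, season, presence_filter="any"):
    """Proportion of survey days occupied from the return day to season end."""
    row = _one_site(records, site, season, presence_filter)
    if pd.isna(row["return_day"]):
        raise UndefinedMetricError(
            f"site {site!r} was never occupied in {season!r}"
        )
    if row["occ_freq_den"] == 0:
        raise UndefinedMetricError(
            f"no survey days in the occupancy window for site {site!r}"
        )
    return float(row["occ_freq"])


def relative_time_investment(records, site, season, presence_filter="any"):
    """Season-level RTI (ratio of sums) for one site."""
    row = _one_site(records, site, season, presence_filter)
    if row["rti_den"] == 0:
        raise UndefinedMetricError(
            f"RTI denominator is zero for site {site!r} in {season!r}"
        )
    return float(row["rti"])


# ---------------------------------------------------------------------------
# standardization


def standardize(values, groups) -> pd.DataFrame:
    """Z-score values within groups (sample SD, n−1 denominator).

    Returns a frame with the raw value, z value, group key, and the group
    mean/SD needed to back-transform effect sizes to natural units.  Groups
    with fewer than two distinct values, or zero spread, are degenerate.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    out = pd.DataFrame({"group": groups, "raw": values})
    means = np.empty_like(values)
    sds = np.empty_like(values)
    for g, idx in out.groupby("group", observed=True).groups.items():
        loc = np.asarray(idx)
        v = values[loc]
        if len(np.unique(v[~np.isnan(v)])) < 2:
            raise DegenerateGroupError(
                f"group {g!r} has fewer than 2 distinct values"
            )
        m, s = np.nanmean(v), np.nanstd(v, ddof=1)
        if s == 0:
            raise DegenerateGroupError(f"group {g!r} has zero SD")
        means[loc] = m
        sds[loc] = s
    out["group_mean"] = means
    out["group_sd"] = sds
    out["z"] = (values - means) / sds
    return out


# ---------------------------------------------------------------------------
# colony-level summaries


def colony_summaries(records: pd.DataFrame, declared_gaps=None
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Daily and hour-after-dawn occupancy tables.

    Daily: per (subcolony, season, day), the share of monitored sites with
    at least one occupied image.  Hourly: per hour after dawn, the mean and
    SD (across days) of the share of sites occupied in at least one image of
    that hour — overall and by calendar month.
    """
    from .simulate import inject_gaps

    records = _ensure_season_day(records)
    if declared_gaps is not None:
        records = inject_gaps(records, declared_gaps)
    n_sites = records.groupby(["subcolony", "season"], observed=True)[
        "site_id"].nunique()

    occ = records["count"].to_numpy() >= 1
    site_day = (
        records.assign(occ=occ)
        .groupby(["subcolony", "season", "season_day", "site_id"],
                 observed=True)["occ"]
        .any()
        .reset_index()
    )
    daily = (
        site_day.groupby(["subcolony", "season", "season_day"],
                         observed=True)["occ"]
        .sum()
        .reset_index(name="n_occupied")
    )
    daily["n_sites"] = daily.set_index(["subcolony", "season"]).index.map(
        n_sites
    )
    daily["prop_occupied"] = daily["n_occupied"] / daily["n_sites"]

    dawn, _ = dawn_dusk_minutes(records["season_day"].to_numpy())
    hours = np.floor(
        (records["time"].to_numpy() - dawn) / 60.0
    ).astype(int)
    rec = records.assign(occ=occ, hour_after_dawn=hours)
    rec = rec.loc[rec["hour_after_dawn"] >= 0]
    sdh = (
        rec.groupby(["subcolony", "season", "season_day",
                     "hour_after_dawn", "site_id"], observed=True)["occ"]
        .any()
        .reset_index()
    )
    per_day_hour = (
        sdh.groupby(["subcolony", "season", "season_day", "hour_after_dawn"],
                    observed=True)["occ"]
        .sum()
        .reset_index(name="n_occupied")
    )
    per_day_hour["n_sites"] = per_day_hour.set_index(
        ["subcolony", "season"]).index.map(n_sites)
    per_day_hour["prop"] = (
        per_day_hour["n_occupied"] / per_day_hour["n_sites"]
    )
    month = (pd.Timestamp("2017-09-01")
             + pd.to_timedelta(per_day_hour["season_day"], unit="D")
             ).dt.month
    per_day_hour["month"] = month

    overall = (
        per_day_hour.groupby("hour_after_dawn")["prop"]
        .agg(["mean", "std", "size"])
        .reset_index()
        .rename(columns={"size": "n_days"})
    )
    overall.insert(0, "month", "all")
    by_month = (
        per_day_hour.groupby(["month", "hour_after_dawn"])["prop"]
        .agg(["mean", "std", "size"])
        .reset_index()
        .rename(columns={"size": "n_days"})
    )
    hourly = pd.concat([overall, by_month], ignore_index=True)
    return daily, hourly
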