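"""Synthetic colony generator with known ground-truth coefficients.

The generator emulates a time-lapse study of guillemot breeding-site
occupancy over the non-breeding season (October 1 – March 31): two
subcolonies of fixed breeding sites are photographed every 15 or 30 min
during nautical daylight, and each image is scored 0/1/2 birds per site.
Site quality (a historic breeding-success proportion) shifts, on known
scales, the three occupancy measures a downstream analysis recovers —
return date (days per SD of quality), occupancy frequency and relative
time investment (logit units per SD) — and realized occupancy in turn
drives lay date and breeding success under known coefficients, so every
downstream stage of the pipeline can be tested against the truth.

Attendance structure
--------------------
Three nested Bernoulli layers reproduce the qualitative attendance
patterns of such colonies:

* a colony-wide *day gate* ``A_d ~ Bern(c(d))`` shared by all sites of a
  subcolony, whose level ``c(d)`` carries the seasonal rise to the
  ~50 % daily plateau and the early-December / early-February dips.
  Because the gate is shared and multiplicative, per-site logit-linear
  quality effects on occupancy frequency survive day-averaging
  essentially unattenuated, and the gate is what makes relative time
  investment (time at the site *given the subcolony is attended*) exceed
  occupancy frequency, as observed;
* a per-site *day occupancy* draw on gated days, with probability
  ``q_s = f_s / c̄`` where ``f_s`` is the site's target occupancy
  frequency (logit-linear in quality);
* a shared *diel image gate* following the within-day attendance curve
  (peak 1–2 h after nautical dawn, decline to zero at dusk), thinned per
  site so that the season-level relative time investment is logit-linear
  in quality.

A site always attends on its (latent, Gaussian) return day, so the
measured first-occupancy day is the latent one.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm

from .daylight import SEASON_START_DAY, dawn_dusk_minutes
from .errors import ConfigurationError, DomainError

__all__ = [
    "DielParams",
    "SeasonalParams",
    "Gap",
    "SimulationTruth",
    "SyntheticColony",
    "diel_profile",
    "seasonal_curve",
    "inject_gaps",
    "simulate_colony",
]


# ---------------------------------------------------------------------------
# parameter containers


@dataclass(frozen=True)
class DielParams:
    """Within-day attendance curve, in hours after nautical dawn.

    Piecewise log-linear rise to a peak 1.5 h after dawn, then exponential
    decline with a power taper forcing exactly zero at nautical dusk.
    """

    peak_hours: float = 1.5
    rise_rate: float = 0.35  # log-units per hour before the peak
    decay_rate: float = 0.16  # per hour after the peak
    taper_exponent: float = 0.3
    peak_level: float = 0.9  # attendance probability at the peak


@dataclass(frozen=True)
class SeasonalParams:
    """Colony-level expected daily occupancy proportion across the season.

    Logistic rise to a plateau (~50 % of sites occupied per day by
    mid-March) minus two localized Gaussian dips (early December and early
    February).  Days are counted from Sep 1; each dip is
    (center day, depth, width-SD days).
    """

    plateau: float = 0.52
    rise_midpoint: float = 60.0
    rise_scale: float = 35.0
    dips: tuple[tuple[float, float, float], ...] = (
        (95.0, 0.12, 5.0),   # early December
        (155.0, 0.10, 5.0),  # early February
    )


@dataclass(frozen=True)
class Gap:
    """An unscorable interval (camera down / fog) for one subcolony.

    ``season`` is a season label ("2018/19") or None for every season;
    days are season-days, both ends inclusive.
    """

    subcolony: int
    start_day: int
    end_day: int
    season: str | None = None


_DEFAULT_GAPS = (
    # sporadic outages totalling ~10 % of the season per subcolony; the
    # default calendar keeps outages clear of the October return window,
    # where a gap would censor first-occupancy dates
    Gap(1, 100, 109),  # mid December, subcolony 1
    Gap(1, 140, 147),  # late January, subcolony 1
    Gap(2, 92, 99),    # early December, subcolony 2
    Gap(2, 160, 168),  # mid February, subcolony 2
)

_RESPONSES = ("return_day", "occ_freq", "rti", "lay_date", "success")


def _default_site_re_sd() -> dict[str, float]:
    return {
        "return_day": 5.0,
        "occ_freq": 0.4,
        "rti": 0.4,
        "lay_date": 5.0,
        "success": 0.5,
    }


@dataclass(frozen=True)
class SimulationTruth:
    """Generator coefficients against which parameter recovery is judged.

    Defaults are the study conditions: mean return Oct 27 (season-day 56)
    with ±11.7 d total spread, mean occupancy frequency 0.46, mean relative
    time investment 0.55, and quality effects of −4.67 d/SD on return date
    and 0.82 / 0.94 logit/SD on frequency and time investment; occupancy
    frequency advances lay date by 0.93 d/SD and an earlier return raises
    the log-odds of success by 0.5 per SD.
    """

    n_sites_per_subcolony: int | tuple[int, int] = (27, 51)
    n_subcolonies: int = 2
    n_seasons: int = 3
    first_year: int = 2017

    mean_return_day: float = 56.0  # Oct 27, days since Sep 1
    sd_return_day: float = 9.5  # residual SD; with effects, total ≈ 11.7
    beta_quality_return: float = -4.67  # days per SD of quality

    mean_freq: float = 0.46
    beta_quality_freq: float = 0.82  # logit units per SD

    mean_rti: float = 0.55
    beta_quality_rti: float = 0.94  # logit units per SD

    mean_lay_day: float = 244.0  # ~May 2, days since Sep 1
    beta_freq_laydate: float = -0.93  # days per SD of occupancy frequency
    # residual SD chosen with the 5-day site effect to reproduce the
    # lay-date model's reported variance split (marginal R² ≈ .02,
    # conditional ≈ .5)
    sd_laydate: float = 4.7

    intercept_success: float = 0.8  # logit units
    beta_return_success: float = -0.5  # logit units per SD of return day

    site_re_sd: dict[str, float] = field(default_factory=_default_site_re_sd)

    image_interval: int = 15  # minutes
    first_season_interval: int | None = 30  # the pilot season ran at 30 min
    pair_prob: float = 0.5  # P(second bird | site occupied in an image)
    quality_beta_a: float = 1.3
    quality_beta_b: float = 0.9
    colony_active_level: float | None = None  # None -> mean_freq / mean_rti

    diel_params: DielParams = field(default_factory=DielParams)
    seasonal_params: SeasonalParams = field(default_factory=SeasonalParams)
    gap_spec: tuple[Gap, ...] = _DEFAULT_GAPS
    seed: int = 0

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        def _fail(name, why):
            raise ConfigurationError(f"SimulationTruth.{name}: {why}")

        sites = self.n_sites_per_subcolony
        if isinstance(sites, int):
            sites = (sites,) * self.n_subcolonies
        if len(sites) != self.n_subcolonies or any(s < 2 for s in sites):
            _fail("n_sites_per_subcolony",
                  "need >= 2 sites for each subcolony")
        if self.n_seasons < 1:
            _fail("n_seasons", "must be positive")
        for name in ("mean_freq", "mean_rti", "pair_prob"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                _fail(name, f"proportion must lie in (0,1), got {v}")
        for name in ("sd_return_day", "sd_laydate"):
            if getattr(self, name) <= 0:
                _fail(name, "SD must be > 0")
        for name, v in self.site_re_sd.items():
            if name not in _RESPONSES:
                _fail("site_re_sd", f"unknown response {name!r}")
            if v < 0:
                _fail("site_re_sd", f"{name} SD must be >= 0")
        intervals = [self.image_interval]
        if self.first_season_interval is not None:
            intervals.append(self.first_season_interval)
        for iv in intervals:
            if iv not in (15, 30):
                _fail("image_interval", f"must be 15 or 30 min, got {iv}")
        if self.colony_active_level is not None and not (
            0.0 < self.colony_active_level <= 1.0
        ):
            _fail("colony_active_level", "must lie in (0,1]")
        if not (0 <= self.seed < 2**63):
            _fail("seed", "must be a non-negative 63-bit integer")
        _validate_gaps(self.gap_spec, self.season_labels())

    # -- derived quantities -------------------------------------------------

    def sites_per_subcolony(self) -> tuple[int, ...]:
        s = self.n_sites_per_subcolony
        return (s,) * self.n_subcolonies if isinstance(s, int) else tuple(s)

    def season_labels(self) -> list[str]:
        return [
            f"{y}/{str(y + 1)[2:]}"
            for y in range(self.first_year, self.first_year + self.n_seasons)
        ]

    def interval_for_season(self, season_index: int) -> int:
        if season_index == 0 and self.first_season_interval is not None:
            return self.first_season_interval
        return self.image_interval

    def active_level(self) -> float:
        if self.colony_active_level is not None:
            return self.colony_active_level
        return min(1.0, self.mean_freq / self.mean_rti)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["gap_spec"] = [asdict(g) for g in self.gap_spec]
        return d


@dataclass(frozen=True)
class SyntheticColony:
    """One generated colony: image scores, site table, breeding table, truth."""

    image_scores: pd.DataFrame
    sites: pd.DataFrame
    breeding: pd.DataFrame
    truth: SimulationTruth

    def __post_init__(self):
        known = set(self.sites["site_id"])
        for frame, name in ((self.image_scores, "image_scores"),
                            (self.breeding, "breeding")):
            missing = set(frame["site_id"].unique()) - known
            if missing:
                raise ConfigurationError(
                    f"{name} references unknown sites: {sorted(missing)[:5]}"
                )


# ---------------------------------------------------------------------------
# curves


def diel_profile(hours_after_dawn, params: DielParams = DielParams(),
                 day_length_hours: float = 10.0):
    """Within-day attendance probability at a given time after nautical dawn.

    Unimodal with its maximum at ``params.peak_hours`` (inside 1–2 h for the
    default), exactly zero at and beyond nautical dusk.
    """
    h = np.asarray(hours_after_dawn, dtype=float)
    if np.any(h < 0):
        raise DomainError("hours_after_dawn must be non-negative")
    peak = params.peak_hours
    rising = params.peak_level * np.exp(params.rise_rate * (h - peak))
    frac = np.clip((day_length_hours - h) / (day_length_hours - peak), 0.0, None)
    falling = (
        params.peak_level
        * np.exp(-params.decay_rate * (h - peak))
        * frac ** params.taper_exponent
    )
    out = np.where(h < peak, rising, falling)
    out = np.where(h >= day_length_hours, 0.0, out)
    return out if out.ndim else float(out)


def seasonal_curve(season_day, params: SeasonalParams = SeasonalParams()):
    """Expected colony-level daily occupancy proportion on a season-day.

    Monotone logistic rise to the plateau minus two localized Gaussian dips;
    raises :class:`DomainError` outside the October–March window.
    """
    d = np.asarray(season_day, dtype=float)
    if np.any((d < SEASON_START_DAY) | (d > 212)):
        raise DomainError(
            f"season_day outside the observation window "
            f"[{SEASON_START_DAY}, 212]"
        )
    base = params.plateau * expit((d - params.rise_midpoint) / params.rise_scale)
    for center, depth, width in params.dips:
        base = base - depth * np.exp(-0.5 * ((d - center) / width) ** 2)
    out = np.clip(base, 0.0, 1.0)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# gaps


def _validate_gaps(gaps: Sequence[Gap], seasons: list[str]) -> None:
    by_key: dict[tuple, list[tuple[int, int]]] = {}
    for g in gaps:
        if g.start_day > g.end_day:
            raise ConfigurationError(
                f"gap_spec: malformed interval ({g.start_day} > {g.end_day})"
            )
        if g.start_day < SEASON_START_DAY or g.end_day > 212:
            raise ConfigurationError(
                f"gap_spec: interval [{g.start_day}, {g.end_day}] outside "
                "the season window"
            )
        if g.season is not None and g.season not in seasons:
            raise ConfigurationError(
                f"gap_spec: unknown season {g.season!r}"
            )
        for season in [g.season] if g.season else seasons:
            key = (season, g.subcolony)
            for s, e in by_key.get(key, []):
                if g.start_day <= e and s <= g.end_day:
                    raise ConfigurationError(
                        f"gap_spec: overlapping intervals for subcolony "
                        f"{g.subcolony}, season {season}"
                    )
            by_key.setdefault(key, []).append((g.start_day, g.end_day))


def inject_gaps(records: pd.DataFrame, gap_spec: Sequence[Gap],
                seasons: Sequence[str] | None = None) -> pd.DataFrame:
    """Remove all records inside the declared unscorable intervals.

    Removed days become unsurveyed (absent from the survey-day ledger), not
    zero-occupancy.  Other records are untouched.
    """
    if not len(gap_spec):
        return records
    seasons = list(seasons) if seasons is not None else sorted(
        records["season"].unique()
    )
    _validate_gaps(gap_spec, seasons)
    drop = np.zeros(len(records), dtype=bool)
    day = records["season_day"].to_numpy()
    sub = records["subcolony"].to_numpy()
    season = records["season"].to_numpy()
    for g in gap_spec:
        m = (sub == g.subcolony) & (day >= g.start_day) & (day <= g.end_day)
        if g.season is not None:
            m &= season == g.season
        drop |= m
    return records.loc[~drop].reset_index(drop=True)


# ---------------------------------------------------------------------------
# generator internals


def _season_days(year: int) -> tuple[np.ndarray, pd.DatetimeIndex]:
    """Season-day index and calendar dates for Oct 1 (year) – Mar 31."""
    dates = pd.date_range(f"{year}-10-01", f"{year + 1}-03-31", freq="D")
    days = (dates - pd.Timestamp(year=year, month=9, day=1)).days.to_numpy()
    return days, dates


def _colony_activity_curve(truth: SimulationTruth, days: np.ndarray
                           ) -> np.ndarray:
    """Per-day probability that a subcolony is attended at all.

    Derived from the configured seasonal curve by dividing out the expected
    returned fraction and the mean per-image attendance, then renormalized so
    its mean over the post-return window equals ``mean_freq / mean_rti`` —
    which is what makes the realized means of both frequency and relative
    time investment land on their configured values.
    """
    spread = float(
        np.sqrt(
            truth.beta_quality_return ** 2
            + truth.site_re_sd["return_day"] ** 2
            + truth.sd_return_day ** 2
        )
    )
    target = seasonal_curve(days, truth.seasonal_params)
    returned = norm.cdf((days - truth.mean_return_day) / spread)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = target / np.maximum(truth.mean_rti * returned, 1e-9)
    c = np.clip(c, 0.02, 1.0)
    # Normalize so that, averaged over the return-day distribution, the mean
    # gate level inside a site's own window [R, season end] equals c̄; this
    # is what puts the realized occupancy-frequency mean on mean_freq.
    w = norm.pdf((days - truth.mean_return_day) / spread)
    w /= w.sum()
    c_bar = truth.active_level()
    for _ in range(6):
        tail_means = np.cumsum(c[::-1])[::-1] / np.arange(days.size, 0, -1)
        expected = float(np.sum(w * tail_means))
        if expected <= 0:
            break
        c = np.clip(c * (c_bar / expected), 0.02, 1.0)
    return c


def _image_grid(truth: SimulationTruth, days: np.ndarray, interval: int):
    """Flat per-image arrays (day index, minutes since midnight, diel prob)."""
    dawn, dusk = dawn_dusk_minutes(days)
    times, day_idx = [], []
    for i, (a, b) in enumerate(zip(dawn, dusk)):
        start = int(np.ceil(a / interval)) * interval
        t = np.arange(start, b, interval)
        times.append(t)
        day_idx.append(np.full(t.size, i))
    times = np.concatenate(times)
    day_idx = np.concatenate(day_idx)
    hours = (times - dawn[day_idx]) / 60.0
    length = (dusk[day_idx] - dawn[day_idx]) / 60.0
    g = _diel_vec(hours, length, truth.diel_params)
    return day_idx, times, g


def _diel_vec(hours: np.ndarray, day_len: np.ndarray, p: DielParams
              ) -> np.ndarray:
    rising = p.peak_level * np.exp(p.rise_rate * (hours - p.peak_hours))
    frac = np.clip((day_len - hours) / (day_len - p.peak_hours), 0.0, None)
    falling = (
        p.peak_level * np.exp(-p.decay_rate * (hours - p.peak_hours))
        * frac ** p.taper_exponent
    )
    out = np.where(hours < p.peak_hours, rising, falling)
    return np.where(hours >= day_len, 0.0, out)


def _standardize_within(values: np.ndarray) -> np.ndarray:
    sd = values.std(ddof=1)
    if sd == 0:
        return np.zeros_like(values)
    return (values - values.mean()) / sd


def simulate_colony(truth: SimulationTruth) -> SyntheticColony:
    """Generate one synthetic colony under ``truth``.

    Returns the full image-score table (one row per site × image, counts in
    {0,1,2}, daylight only, declared gaps removed), the site table with
    qualities, and the breeding table whose lay dates and success outcomes
    were generated from the *realized* (pre-gap) occupancy metrics.
    """
    truth.validate()
    rng = np.random.default_rng(np.random.SeedSequence(truth.seed))
    seasons = truth.season_labels()
    sizes = truth.sites_per_subcolony()
    re_sd = truth.site_re_sd

    site_rows = []
    score_frames = []
    breeding_rows = []

    for sub_i, n_sites in enumerate(sizes, start=1):
        quality_raw = rng.beta(truth.quality_beta_a, truth.quality_beta_b,
                               size=n_sites)
        n_attempts = rng.integers(20, 37, size=n_sites)
        quality = np.round(quality_raw * n_attempts) / n_attempts
        z_q = _standardize_within(quality)
        site_ids = [f"s{sub_i}_{k:02d}" for k in range(1, n_sites + 1)]
        for sid, q, na in zip(site_ids, quality, n_attempts):
            site_rows.append(
                {"site_id": sid, "subcolony": sub_i, "quality": float(q),
                 "n_attempts": int(na)}
            )

        # site-level random intercepts, constant across seasons
        re = {
            name: rng.normal(0.0, re_sd[name], size=n_sites)
            for name in _RESPONSES
        }
        f_site = expit(logit(truth.mean_freq)
                       + truth.beta_quality_freq * z_q + re["occ_freq"])
        t_site = expit(logit(truth.mean_rti)
                       + truth.beta_quality_rti * z_q + re["rti"])
        c_bar = truth.active_level()
        q_site = np.minimum(f_site / c_bar, 1.0)
        r_site = np.clip(c_bar * t_site / f_site, 0.0, 1.0)

        for season_i, season in enumerate(seasons):
            year = truth.first_year + season_i
            days, dates = _season_days(year)
            n_days = days.size
            interval = truth.interval_for_season(season_i)

            # latent return day per site
            ret = (
                truth.mean_return_day
                + truth.beta_quality_return * z_q
                + re["return_day"]
                + rng.normal(0.0, truth.sd_return_day, size=n_sites)
            )
            ret_day = np.maximum(np.round(ret), days[0]).astype(int)
            returned = ret_day <= days[-1]

            # shared colony-day gate: error-diffusion (low-discrepancy)
            # thinning at rate c(d).  A Bernoulli gate would inject a shared
            # day-level random field whose window-mean noise no model term
            # downstream could attribute, miscalibrating fixed-effect SEs;
            # the deterministic pattern keeps the seasonal shape while
            # leaving site-day occupancy conditionally independent.
            c_curve = _colony_activity_curve(truth, days)
            cum = rng.random() + np.cumsum(c_curve)
            floors = np.floor(np.concatenate([[cum[0] - c_curve[0]], cum]))
            active = np.diff(floors) >= 1.0

            # per-site occupied days
            after = days[None, :] >= ret_day[:, None]
            occ = (
                after
                & active[None, :]
                & (rng.random((n_sites, n_days)) < q_site[:, None])
            )
            # a site always attends its latent return day, so the measured
            # first-occupancy day is the latent one; if the colony is quiet
            # that day the bird makes only a brief visit (a single image),
            # which keeps the subcolony any-present denominator clean
            is_return_day = days[None, :] == ret_day[:, None]
            forced_quiet = is_return_day & ~active[None, :]
            occ |= is_return_day
            occ &= returned[:, None]

            # shared diel image gate
            day_idx, times_min, g = _image_grid(truth, days, interval)
            gate = rng.random(g.size) < g
            present = (
                (occ & ~forced_quiet)[:, day_idx]
                & gate[None, :]
                & (rng.random((n_sites, g.size)) < r_site[:, None])
            )
            # guarantee >= 1 scored presence on each return day
            ret_rows = np.where(returned)[0]
            day_first_img = np.searchsorted(day_idx, np.arange(n_days))
            for s in ret_rows:
                d_pos = ret_day[s] - days[0]
                lo = day_first_img[d_pos]
                hi = (day_first_img[d_pos + 1] if d_pos + 1 < n_days
                      else g.size)
                if not present[s, lo:hi].any():
                    present[s, lo] = True

            counts = np.zeros(present.shape, dtype=np.int8)
            pair = rng.random(present.shape) < truth.pair_prob
            counts[present] = 1
            counts[present & pair] = 2

            n_img = g.size
            frame = pd.DataFrame(
                {
                    "subcolony": np.full(n_sites * n_img, sub_i,
                                         dtype=np.int8),
                    "site_id": pd.Categorical(
                        np.repeat(site_ids, n_img), categories=site_ids
                    ),
                    "season": season,
                    "date": dates.to_numpy()[np.tile(day_idx, n_sites)],
                    "season_day": np.tile(days[day_idx], n_sites).astype(
                        np.int16
                    ),
                    "time": np.tile(times_min, n_sites).astype(np.int16),
                    "count": counts.reshape(-1),
                }
            )
            score_frames.append(frame)

            # breeding outcomes are driven by the *measured* metrics — the
            # return day and occupancy frequency an observer would score
            # from the surviving (post-gap) records
            gap_days = np.zeros(n_days, dtype=bool)
            for gp in truth.gap_spec:
                if gp.subcolony != sub_i:
                    continue
                if gp.season is not None and gp.season != season:
                    continue
                lo = max(gp.start_day - days[0], 0)
                hi = min(gp.end_day - days[0], n_days - 1)
                if hi >= lo:
                    gap_days[lo:hi + 1] = True
            meas = occ & ~gap_days[None, :]
            meas_returned = returned & meas.any(axis=1)
            first = np.argmax(meas, axis=1)
            nongap_cum = np.cumsum(~gap_days)
            prev = np.where(first > 0, nongap_cum[np.maximum(first - 1, 0)],
                            0)
            den = np.maximum(nongap_cum[-1] - prev, 1)
            freq_meas = np.where(meas_returned,
                                 meas.sum(axis=1) / den, np.nan)
            ret_meas = np.where(meas_returned, days[0] + first, np.nan)
            z_ret = np.zeros(n_sites)
            z_freq = np.zeros(n_sites)
            if meas_returned.sum() >= 2:
                z_ret[meas_returned] = _standardize_within(
                    ret_meas[meas_returned]
                )
                z_freq[meas_returned] = _standardize_within(
                    freq_meas[meas_returned]
                )
            lay = (
                truth.mean_lay_day
                + truth.beta_freq_laydate * z_freq
                + re["lay_date"]
                + rng.normal(0.0, truth.sd_laydate, size=n_sites)
            )
            p_succ = expit(
                truth.intercept_success
                + truth.beta_return_success * z_ret
                + re["success"]
            )
            success = (rng.random(n_sites) < p_succ).astype(int)
            sep1 = pd.Timestamp(year=year, month=9, day=1)
            for k, sid in enumerate(site_ids):
                breeding_rows.append(
                    {
                        "site_id": sid,
                        "season": season,
                        "lay_date": (sep1 + pd.Timedelta(days=round(lay[k]))
                                     ).date().isoformat(),
                        "success": int(success[k]),
                    }
                )

    records = pd.concat(score_frames, ignore_index=True)
    records = inject_gaps(records, truth.gap_spec, seasons)
    sites = pd.DataFrame(site_rows)
    breeding = pd.DataFrame(breeding_rows)
    return SyntheticColony(records, sites, breeding, truth)


def null_truth(**overrides) -> SimulationTruth:
    """A truth with every effect and random intercept zeroed (null colony)."""
    base = SimulationTruth(
        beta_quality_return=0.0,
        beta_quality_freq=0.0,
        beta_quality_rti=0.0,
        beta_freq_laydate=0.0,
        beta_return_success=0.0,
        site_re_sd={name: 0.0 for name in _RESPONSES},
    )
    return replace(base, **overrides)
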