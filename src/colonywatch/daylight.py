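"""Dawn/dusk times from standard solar geometry.

The study colony sits at 56.2°N.  Attendance is scored only between nautical
dawn and nautical dusk (sun 12° below the horizon, zenith 102°), because
birds are never present overnight and the cameras cannot resolve night
images.  The approximation below (cosine declination plus the hour-angle
equation, no equation of time) is accurate to a few minutes, which is far
below the 15-min image cadence; times are local solar time.
"""

from __future__ import annotations

import numpy as np

STUDY_LATITUDE = 56.2
NAUTICAL_ZENITH = 102.0

#: season-day index (days since Sep 1) of the first and last observed day
SEASON_START_DAY = 30  # Oct 1
SEASON_END_DAY = 212  # Mar 31 in a leap year; 211 otherwise


def _day_of_year(season_day: np.ndarray | int) -> np.ndarray:
    # season day 0 = Sep 1 = day-of-year 244 in a non-leap year
    return (np.asarray(season_day) + 243) % 365 + 1


def solar_declination(season_day):
    """Solar declination (degrees) for a season-day (days since Sep 1)."""
    doy = _day_of_year(season_day)
    return -23.44 * np.cos(np.deg2rad(360.0 / 365.0 * (doy + 10)))


def dawn_dusk_minutes(season_day, latitude: float = STUDY_LATITUDE,
                      zenith: float = NAUTICAL_ZENITH):
    """Nautical dawn and dusk in minutes since midnight (local solar time).

    Vectorized over ``season_day``.  At 56°N the sun always crosses the
    nautical zenith, so no polar special-casing is needed.
    """
    decl = np.deg2rad(solar_declination(season_day))
    lat = np.deg2rad(latitude)
    cos_h = (np.cos(np.deg2rad(zenith)) - np.sin(lat) * np.sin(decl)) / (
        np.cos(lat) * np.cos(decl)
    )
    hour_angle = np.degrees(np.arccos(np.clip(cos_h, -1.0, 1.0)))
    half = hour_angle / 15.0  # hours either side of solar noon
    dawn = (12.0 - half) * 60.0
    dusk = (12.0 + half) * 60.0
    return dawn, dusk


def day_length_hours(season_day, latitude: float = STUDY_LATITUDE,
                     zenith: float = NAUTICAL_ZENITH):
    dawn, dusk = dawn_dusk_minutes(season_day, latitude, zenith)
    return (dusk - dawn) / 60.0
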