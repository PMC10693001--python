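"""Migratory traits from breeding/wintering coordinates and daily tracks.

Direction and distance come from the rhumb line (loxodrome, constant
bearing) between the breeding and wintering sites; timing and duration
come from projecting daily positions onto the great circle between those
sites and finding when the bird passes 30/50/70% of the route.  All
spherical computation uses a mean Earth radius of 6371.0088 km.

Group classification (fall orientation):

* NW screen first: wintering latitude >= 45 N and rhumb bearing in
  (270, 360] -> NW (so UK-wintering birds are not mislabelled SW by the
  longitude rules alone);
* wintering latitude >= 37.5 N: longitude < 5 E -> SW, > 20 E -> SE,
  else S;
* south of 37.5 N the SW cutoff tightens to 0 E (longer routes need less
  of a westerly component to reach the same longitude).

Boundary longitudes (exactly 5 E or 20 E) fall into S.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from migrasv.io import TrackedBird

EARTH_RADIUS_KM = 6371.0088

__all__ = [
    "EARTH_RADIUS_KM",
    "rhumb_bearing_distance",
    "great_circle_distance",
    "RouteGeometry",
    "route_fraction_series",
    "TimingResult",
    "timing_and_duration",
    "classify_group",
    "derive_phenotypes",
]


def rhumb_bearing_distance(
    origin: tuple[float, float], dest: tuple[float, float]
) -> tuple[float, float]:
    """Loxodrome bearing (degrees clockwise from north, [0, 360)) and
    distance (km) between two (lat, lon) points.

    Bearing is ``atan2(dlon, dpsi)`` with the stretched-latitude
    difference ``dpsi = ln[tan(pi/4 + lat2/2) / tan(pi/4 + lat1/2)]`` and
    dlon wrapped to (-pi, pi]; distance is
    ``R * sqrt(dlat^2 + q^2 dlon^2)`` with ``q = dlat/dpsi`` (``cos lat1``
    on an east-west course).
    """
    (lat1, lon1), (lat2, lon2) = origin, dest
    if (lat1, lon1) == (lat2, lon2):
        raise ValueError("rhumb bearing undefined for identical points")
    if abs(lat1) >= 90 or abs(lat2) >= 90:
        raise ValueError("rhumb line undefined at the poles")
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlam = math.radians(lon2 - lon1)
    # wrap to (-pi, pi] without the precision loss of a modulo near zero
    if dlam > math.pi:
        dlam -= 2 * math.pi
    elif dlam <= -math.pi:
        dlam += 2 * math.pi
    dpsi = math.log(math.tan(math.pi / 4 + phi2 / 2) / math.tan(math.pi / 4 + phi1 / 2))
    bearing = math.degrees(math.atan2(dlam, dpsi)) % 360.0
    if bearing >= 360.0:  # tiny negative angles round up to exactly 360
        bearing = 0.0
    q = dphi / dpsi if abs(dpsi) > 1e-12 else math.cos(phi1)
    dist = EARTH_RADIUS_KM * math.hypot(dphi, q * dlam)
    return bearing, dist


def great_circle_distance(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Haversine distance in km between (lat, lon) points."""
    phi1, lam1 = map(math.radians, a)
    phi2, lam2 = map(math.radians, b)
    s = (
        math.sin((phi2 - phi1) / 2) ** 2
        + math.cos(phi1) * math.cos(phi2) * math.sin((lam2 - lam1) / 2) ** 2
    )
    return 2 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(s)))


def _initial_bearing_rad(a: tuple[float, float], b: tuple[float, float]) -> float:
    phi1, lam1 = map(math.radians, a)
    phi2, lam2 = map(math.radians, b)
    dlam = lam2 - lam1
    y = math.sin(dlam) * math.cos(phi2)
    x = math.cos(phi1) * math.sin(phi2) - math.sin(phi1) * math.cos(phi2) * math.cos(dlam)
    return math.atan2(y, x)


def _along_track_km(
    origin: tuple[float, float], dest: tuple[float, float], point: tuple[float, float]
) -> float:
    """Along-track distance of ``point`` on the origin->dest great circle.

    Cross-track/along-track construction; points projecting behind the
    origin get a negative value.
    """
    d13 = great_circle_distance(origin, point) / EARTH_RADIUS_KM
    if d13 == 0.0:
        return 0.0
    theta13 = _initial_bearing_rad(origin, point)
    theta12 = _initial_bearing_rad(origin, dest)
    dxt = math.asin(max(-1.0, min(1.0, math.sin(d13) * math.sin(theta13 - theta12))))
    cos_ratio = math.cos(d13) / math.cos(dxt)
    dat = math.acos(max(-1.0, min(1.0, cos_ratio)))
    sign = 1.0 if math.cos(theta13 - theta12) >= 0 else -1.0
    return sign * dat * EARTH_RADIUS_KM


@dataclass
class RouteGeometry:
    """Per-day route fractions for one bird and season."""

    bird_id: str
    season: str  # "fall" or "spring"
    origin: tuple[float, float]
    dest: tuple[float, float]
    rhumb_bearing: float
    rhumb_distance: float
    gc_distance: float
    dates: list[_dt.date]
    fractions: np.ndarray  # monotone non-decreasing, in [0, 1]


def split_seasons(
    bird: TrackedBird,
) -> tuple[list[tuple[_dt.date, float, float]], list[tuple[_dt.date, float, float]]]:
    """Split the daily track into fall and spring legs.

    The split point is the first date of closest approach to the
    wintering site; it belongs to both legs.
    """
    if not bird.daily_positions:
        return [], []
    dists = [
        great_circle_distance((lat, lon), bird.wintering)
        for _, lat, lon in bird.daily_positions
    ]
    split = int(np.argmin(dists))
    return bird.daily_positions[: split + 1], bird.daily_positions[split:]


def route_fraction_series(bird: TrackedBird, season: str = "fall") -> RouteGeometry:
    """Project daily positions onto the season's great-circle route.

    Fall runs breeding -> wintering, spring the reverse.  Fractions are
    along-track distance over route length, clamped to [0, 1], with a
    cumulative maximum applied so position noise cannot make the series
    regress.
    """
    fall, spring = split_seasons(bird)
    if season == "fall":
        origin, dest, positions = bird.breeding, bird.wintering, fall
    elif season == "spring":
        origin, dest, positions = bird.wintering, bird.breeding, spring
    else:
        raise ValueError("season must be 'fall' or 'spring'")
    if len(positions) < 3:
        raise ValueError(f"bird {bird.bird_id!r}: < 3 daily positions in {season}")
    total = great_circle_distance(origin, dest)
    if total == 0:
        raise ValueError(f"bird {bird.bird_id!r}: breeding and wintering coincide")
    fractions = np.array(
        [_along_track_km(origin, dest, (lat, lon)) / total for _, lat, lon in positions]
    )
    fractions = np.maximum.accumulate(np.clip(fractions, 0.0, 1.0))
    bearing, rhumb_dist = rhumb_bearing_distance(origin, dest)
    return RouteGeometry(
        bird_id=bird.bird_id,
        season=season,
        origin=origin,
        dest=dest,
        rhumb_bearing=bearing,
        rhumb_distance=rhumb_dist,
        gc_distance=total,
        dates=[d for d, _, _ in positions],
        fractions=fractions,
    )


@dataclass
class TimingResult:
    timing: _dt.date | None  # first date at >= 50% of the route
    duration_days: int | None  # first date >= 70% minus first date >= 30%
    speed_km_per_day: float | None  # rhumb distance / duration
    complete: bool  # series reached 70%


def timing_and_duration(geometry: RouteGeometry) -> TimingResult:
    """Migration timing (50% date), 30-70% duration, and speed.

    If the fraction series never reaches 0.7 the traits are flagged
    missing; a same-day 0.3 -> 0.7 jump gives duration 0 with undefined
    speed.
    """
    eps = 1e-9  # guard against float noise at the projection thresholds
    frac = geometry.fractions
    if frac.max() < 0.7 - eps:
        return TimingResult(None, None, None, complete=False)
    d30 = geometry.dates[int(np.argmax(frac >= 0.3 - eps))]
    d50 = geometry.dates[int(np.argmax(frac >= 0.5 - eps))]
    d70 = geometry.dates[int(np.argmax(frac >= 0.7 - eps))]
    duration = (d70 - d30).days
    speed = geometry.rhumb_distance / duration if duration > 0 else None
    return TimingResult(timing=d50, duration_days=duration, speed_km_per_day=speed, complete=True)


def classify_group(
    breeding: tuple[float, float],
    wintering: tuple[float, float],
    nw_lat_cutoff: float = 45.0,
) -> str:
    """Assign a fall-orientation group label in {NW, SW, SE, S}."""
    lat, lon = wintering
    try:
        bearing, _ = rhumb_bearing_distance(breeding, wintering)
    except ValueError:
        bearing = None
    if lat >= nw_lat_cutoff and bearing is not None and 270.0 < bearing <= 360.0:
        return "NW"
    if lat >= 37.5:
        if lon < 5.0:
            return "SW"
        if lon > 20.0:
            return "SE"
        return "S"
    if lon < 0.0:
        return "SW"
    if lon > 20.0:
        return "SE"
    return "S"


def derive_phenotypes(birds: list[TrackedBird]) -> pd.DataFrame:
    """Per-bird migratory trait table.

    Columns: group, direction (deg), distance (km), winter_longitude,
    fall/spring timing (date and day-of-year), fall/spring duration
    (days), speed (km/day, fall).  Timing/duration are NaN when the track
    is absent or never reaches 70% of the route.
    """
    rows = []
    for bird in birds:
        bearing, dist = rhumb_bearing_distance(bird.breeding, bird.wintering)
        row: dict = {
            "bird_id": bird.bird_id,
            "sex": bird.sex,
            "group": classify_group(bird.breeding, bird.wintering),
            "direction": bearing,
            "distance": dist,
            "winter_longitude": bird.wintering[1],
        }
        for season in ("fall", "spring"):
            timing = duration = speed = None
            try:
                geom = route_fraction_series(bird, season)
            except ValueError:
                geom = None
            if geom is not None:
                res = timing_and_duration(geom)
                timing, duration, speed = res.timing, res.duration_days, res.speed_km_per_day
            row[f"{season}_timing"] = timing.isoformat() if timing else None
            row[f"{season}_timing_doy"] = float(timing.timetuple().tm_yday) if timing else np.nan
            row[f"{season}_duration"] = float(duration) if duration is not None else np.nan
            if season == "fall":
                row["speed"] = float(speed) if speed is not None else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
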