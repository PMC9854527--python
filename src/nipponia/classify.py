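"""Diurnal activity classification and site segmentation.

Hourly fixes are labelled night-roost / foraging / outing from
month-dependent hour windows (two month groups: March–October and
November–February), then consecutive same-label fixes are grouped into
sites, with a new site opened whenever two consecutive same-label fixes of
one individual are more than 1 km apart.

All windows are half-open ``[start, end)`` local hours; the night window
wraps midnight.  In the November–February group the windows leave
7:00–9:00 uncovered — such fixes are left unlabelled and excluded from
sites rather than force-assigned.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from enum import Enum

import numpy as np
import pandas as pd

from .geo import haversine_distance

NIGHT_ROOST = "night_roost"
FORAGING = "foraging"
OUTING = "outing"
UNLABELED = "unlabeled"


class ActivityPeriod(str, Enum):
    """Annual activity phases of the Crested Ibis."""

    REPRODUCTIVE = "reproductive"  # February–June
    COLONIAL = "colonial"          # July–October
    WINTERING = "wintering"        # November–January


#: half-open hour windows per label, keyed by month group
@dataclass(frozen=True)
class PeriodRules:
    """Hour windows (half-open, [start, end), 24-h clock) per month group.

    ``mar_oct`` applies to months 3–10, ``nov_feb`` to months 11, 12, 1, 2.
    Each entry maps a label to a list of (start_hour, end_hour) windows; a
    night window with start > end wraps midnight.
    """

    mar_oct: dict = field(
        default_factory=lambda: {
            NIGHT_ROOST: [(21, 5)],
            FORAGING: [(8, 16)],
            OUTING: [(5, 8), (16, 21)],
        }
    )
    nov_feb: dict = field(
        default_factory=lambda: {
            NIGHT_ROOST: [(20, 6)],
            FORAGING: [(9, 16)],
            OUTING: [(6, 7), (16, 20)],
        }
    )

    def windows_for_month(self, month: int) -> dict:
        return self.mar_oct if 3 <= month <= 10 else self.nov_feb


DEFAULT_RULES = PeriodRules()


def _in_window(hour: float, start: int, end: int) -> bool:
    if start <= end:
        return start <= hour < end
    return hour >= start or hour < end  # wraps midnight


def classify_fix(timestamp: datetime | pd.Timestamp, rules: PeriodRules = DEFAULT_RULES) -> str:
    """Label one timestamp night_roost / foraging / outing / unlabeled.

    The fractional hour (hour + minute/60) is tested against the month
    group's half-open windows, so 16:30 falls in a 16:00–21:00 window.
    """
    ts = pd.Timestamp(timestamp)
    hour = ts.hour + ts.minute / 60.0
    for label, windows in rules.windows_for_month(ts.month).items():
        for start, end in windows:
            if _in_window(hour, start, end):
                return label
    return UNLABELED


def assign_activity_period(timestamp: datetime | pd.Timestamp) -> ActivityPeriod:
    """Map a timestamp's month to its annual activity period."""
    month = pd.Timestamp(timestamp).month
    if 2 <= month <= 6:
        return ActivityPeriod.REPRODUCTIVE
    if 7 <= month <= 10:
        return ActivityPeriod.COLONIAL
    return ActivityPeriod.WINTERING


def label_fixes(fixes: pd.DataFrame, rules: PeriodRules = DEFAULT_RULES) -> pd.DataFrame:
    """Add ``label`` and ``activity_period`` columns to a fix table."""
    out = fixes.copy()
    ts = pd.to_datetime(out["timestamp"])
    hours = ts.dt.hour.to_numpy() + ts.dt.minute.to_numpy() / 60.0
    months = ts.dt.month.to_numpy()
    labels = np.full(len(out), UNLABELED, dtype=object)
    for group_mask, windows in (
        ((months >= 3) & (months <= 10), rules.mar_oct),
        ((months < 3) | (months > 10), rules.nov_feb),
    ):
        for label, wins in windows.items():
            hit = np.zeros(len(out), dtype=bool)
            for start, end in wins:
                if start <= end:
                    hit |= (hours >= start) & (hours < end)
                else:
                    hit |= (hours >= start) | (hours < end)
            labels[group_mask & hit] = label
    out["label"] = labels
    out["activity_period"] = [assign_activity_period(t).value for t in ts]
    return out


@dataclass
class SitePoint:
    """A run of consecutive same-label fixes treated as one site.

    The centroid is the arithmetic mean of member latitudes/longitudes;
    the activity period is the period of the first member fix.
    """

    site_id: int
    individual_id: str
    label: str
    lat: float
    lon: float
    member_index: list
    first_time: pd.Timestamp
    last_time: pd.Timestamp
    activity_period: str

    @property
    def n_members(self) -> int:
        return len(self.member_index)


def segment_sites(
    labeled: pd.DataFrame, threshold: float = 1000.0, radius: float | None = None
) -> list[SitePoint]:
    """Split each individual × label fix stream into sites by the 1-km rule.

    Within the time-ordered stream of one individual's fixes of one label,
    a new site starts when the great-circle distance from the previous
    same-label fix strictly exceeds ``threshold`` metres (exactly 1,000 m
    stays in the same site).  Unlabelled fixes are ignored.  Every labelled
    fix belongs to exactly one site.
    """
    if "label" not in labeled.columns:
        raise ValueError("fixes must carry a 'label' column (run label_fixes first)")
    kw = {} if radius is None else {"radius": radius}
    sites: list[SitePoint] = []
    site_id = 0
    work = labeled[labeled["label"] != UNLABELED]
    for (ind, label), grp in work.groupby(["individual_id", "label"], sort=True):
        grp = grp.sort_values("timestamp", kind="stable")
        lats = grp["lat"].to_numpy()
        lons = grp["lon"].to_numpy()
        idx = grp.index.to_numpy()
        times = pd.to_datetime(grp["timestamp"]).to_numpy()
        if len(grp) == 0:
            continue
        gaps = haversine_distance(lats[:-1], lons[:-1], lats[1:], lons[1:], **kw)
        breaks = np.flatnonzero(np.atleast_1d(gaps) > threshold) + 1 if len(grp) > 1 else []
        bounds = [0, *breaks, len(grp)]
        for a, b in zip(bounds[:-1], bounds[1:]):
            sites.append(
                SitePoint(
                    site_id=site_id,
                    individual_id=ind,
                    label=label,
                    lat=float(lats[a:b].mean()),
                    lon=float(lons[a:b].mean()),
                    member_index=list(idx[a:b]),
                    first_time=pd.Timestamp(times[a]),
                    last_time=pd.Timestamp(times[b - 1]),
                    activity_period=assign_activity_period(times[a]).value,
                )
            )
            site_id += 1
    return sites


def sites_to_frame(sites: list[SitePoint]) -> pd.DataFrame:
    """Tabular view of a site list (one row per site)."""
    return pd.DataFrame(
        {
            "site_id": [s.site_id for s in sites],
            "individual_id": [s.individual_id for s in sites],
            "label": [s.label for s in sites],
            "lat": [s.lat for s in sites],
            "lon": [s.lon for s in sites],
            "n_members": [s.n_members for s in sites],
            "first_time": [s.first_time for s in sites],
            "last_time": [s.last_time for s in sites],
            "activity_period": [s.activity_period for s in sites],
        }
    )
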