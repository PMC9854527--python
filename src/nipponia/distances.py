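"""Roost–foraging spatial association: nearest-roost distances and summary.

For every foraging site, the great-circle distance to the nearest
night-roost site centroid is computed; the distribution is summarized
with mean, sample standard deviation, quartiles (linear interpolation
between order statistics — the common "type 7" convention) and the share
of distances strictly exceeding a threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .classify import SitePoint
from .geo import EARTH_RADIUS_M, haversine_distance


@dataclass(frozen=True)
class DistanceSummary:
    n: int
    mean: float
    sd: float
    min: float
    q1: float
    median: float
    q3: float
    max: float
    iqr: float
    frac_over_threshold: float
    threshold: float

    def as_dict(self) -> dict:
        return asdict(self)


def nearest_roost_distances(
    foraging_sites: list[SitePoint],
    roost_sites: list[SitePoint],
    radius: float = EARTH_RADIUS_M,
) -> np.ndarray:
    """Distance (m) from each foraging-site centroid to its nearest roost."""
    if not foraging_sites or not roost_sites:
        raise ValueError("both site lists must be non-empty")
    flat = np.array([s.lat for s in foraging_sites])
    flon = np.array([s.lon for s in foraging_sites])
    rlat = np.array([s.lat for s in roost_sites])
    rlon = np.array([s.lon for s in roost_sites])
    d = haversine_distance(
        flat[:, None], flon[:, None], rlat[None, :], rlon[None, :], radius=radius
    )
    return np.atleast_2d(d).min(axis=1)


def summarize_distances(distances, threshold: float = 5000.0) -> DistanceSummary:
    """Distribution summary of a distance sample (n ≥ 1).

    Standard deviation uses the n−1 (sample) denominator; quartiles use
    linear interpolation; ``frac_over_threshold`` counts values strictly
    greater than ``threshold``.
    """
    d = np.asarray(distances, dtype=float)
    if d.size == 0:
        raise ValueError("empty distance sample")
    q1, med, q3 = np.percentile(d, [25, 50, 75])  # linear interpolation
    return DistanceSummary(
        n=int(d.size),
        mean=float(d.mean()),
        sd=float(d.std(ddof=1)) if d.size > 1 else 0.0,
        min=float(d.min()),
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        max=float(d.max()),
        iqr=float(q3 - q1),
        frac_over_threshold=float(np.mean(d > threshold)),
        threshold=float(threshold),
    )
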