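"""Pre-modeling data hygiene: spatial independence and closure.

Two filters are applied before any occupancy model is fit:

1. *Spatial independence.* A home-range reach — derived from the
   allometric home-range area of the largest fish captured — is laid
   out around every site along the (one-dimensional) stream coordinate.
   Wherever two sites' reaches overlap, the upstream member of the pair
   is removed.
2. *Closure.* Surveys from the two years are pooled into one dataset,
   which assumes the community is closed between them; any species not
   detected in both years (at the retained sites) is removed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import DETECTIONS_COLUMNS, SITES_COLUMNS

# Allometric home-range scaling for river fishes,
# log10(area m^2) = a + b * log10(length mm).
RIVER_LOG10_INTERCEPT = -2.41
RIVER_LOG10_SLOPE = 2.98


@dataclass
class FilterReport:
    """Outcome of the site- and species-level filters.

    ``removed_sites`` maps each removed site to the already-retained
    downstream neighbor whose reach it overlapped; ``removed_species``
    maps each removed species code to a human-readable reason.
    """

    retained_sites: list = field(default_factory=list)
    removed_sites: dict = field(default_factory=dict)
    retained_species: list = field(default_factory=list)
    removed_species: dict = field(default_factory=dict)
    reach_m: float | None = None

    def merge(self, other: "FilterReport") -> "FilterReport":
        return FilterReport(
            retained_sites=self.retained_sites or other.retained_sites,
            removed_sites={**self.removed_sites, **other.removed_sites},
            retained_species=self.retained_species or other.retained_species,
            removed_species={**self.removed_species, **other.removed_species},
            reach_m=self.reach_m if self.reach_m is not None else other.reach_m,
        )

    def to_json(self) -> str:
        def _clean(x):
            if isinstance(x, (np.integer,)):
                return int(x)
            if isinstance(x, (np.floating,)):
                return float(x)
            return x

        return json.dumps(
            {
                "reach_m": self.reach_m,
                "retained_sites": [_clean(s) for s in self.retained_sites],
                "removed_sites": {
                    str(k): _clean(v) for k, v in self.removed_sites.items()
                },
                "retained_species": list(self.retained_species),
                "removed_species": dict(self.removed_species),
            },
            indent=2,
        )


def home_range_area(length_mm: float, a: float, b: float) -> float:
    """Allometric home-range area, ``10 ** (a + b * log10(length))`` m^2."""
    if length_mm <= 0:
        raise ValueError("fish length must be positive")
    return 10.0 ** (a + b * np.log10(length_mm))


def home_range_reach(
    length_mm: float,
    a: float = RIVER_LOG10_INTERCEPT,
    b: float = RIVER_LOG10_SLOPE,
    conversion: str = "circle_radius",
) -> float:
    """Linear stream reach (m) attributed to a fish of the given length.

    The allometric relation yields an *area*; mapping it to a linear
    extent along a stream requires a convention. The default takes the
    radius of the circle of equal area, so reach r = sqrt(area / pi).
    """
    area = home_range_area(length_mm, a, b)
    if conversion == "circle_radius":
        return float(np.sqrt(area / np.pi))
    raise ValueError(f"unknown area-to-reach conversion {conversion!r}")


def _validate_sites(sites: pd.DataFrame) -> pd.DataFrame:
    missing = set(SITES_COLUMNS) - set(sites.columns)
    if missing:
        raise ValueError(f"sites table missing columns: {sorted(missing)}")
    if sites["position_m"].duplicated().any():
        dupes = sites.loc[sites["position_m"].duplicated(), "site_id"].tolist()
        raise ValueError(f"duplicate along-stream positions at sites {dupes}")
    if (sites["width_m"] <= 0).any():
        raise ValueError("creek width must be positive")
    if (sites["distance_to_sink_m"] < 0).any():
        raise ValueError("distance to sink lake must be non-negative")
    return sites


def remove_overlapping_sites(sites: pd.DataFrame, reach_m: float) -> FilterReport:
    """Drop sites whose home-range reaches overlap a downstream neighbor.

    Positions increase downstream (toward the sink lake). Two sites
    overlap iff their positions differ by strictly less than
    ``2 * reach_m``; scanning from the most downstream site upstream,
    a site is retained iff it does not overlap the nearest
    already-retained downstream site. The upstream member of every
    overlapping pair is thus the one removed.
    """
    if reach_m < 0:
        raise ValueError("reach must be non-negative")
    sites = _validate_sites(sites)
    ordered = sites.sort_values("position_m", ascending=False)

    retained: list = []
    removed: dict = {}
    last_pos = None
    last_id = None
    for row in ordered.itertuples():
        if last_pos is None or (last_pos - row.position_m) >= 2 * reach_m:
            retained.append(row.site_id)
            last_pos, last_id = row.position_m, row.site_id
        else:
            removed[row.site_id] = last_id
    retained.reverse()  # report in upstream-to-downstream (position) order
    return FilterReport(
        retained_sites=retained, removed_sites=removed, reach_m=float(reach_m)
    )


def closure_filter(
    detections: pd.DataFrame, retained_sites: list | None = None
) -> FilterReport:
    """Drop species not detected in both survey years.

    Detections are counted over ``retained_sites`` only (all sites when
    None). Pooling the two surveys into a single closed dataset is only
    defensible for species present in both, so anything detected in one
    year or neither is removed.
    """
    missing = set(DETECTIONS_COLUMNS) - set(detections.columns)
    if missing:
        raise ValueError(f"detections table missing columns: {sorted(missing)}")
    years = sorted(detections["year"].unique())
    if len(years) != 2:
        raise ValueError(f"expected exactly two survey years, got {years}")

    det = detections
    if retained_sites is not None:
        det = det[det["site_id"].isin(retained_sites)]

    retained, removed = [], {}
    for sp, grp in detections.groupby("species_code", sort=True):
        sub = det[det["species_code"] == sp]
        seen = {
            yr: bool((sub.loc[sub["year"] == yr, "detected"] == 1).any())
            for yr in years
        }
        if all(seen.values()):
            retained.append(sp)
        else:
            missing_years = [str(yr) for yr, ok in seen.items() if not ok]
            removed[sp] = (
                "not detected at retained sites in " + " or ".join(missing_years)
            )
    return FilterReport(retained_species=retained, removed_species=removed)


def filter_dataset(
    detections: pd.DataFrame,
    sites: pd.DataFrame,
    reach_m: float,
) -> tuple[pd.DataFrame, pd.DataFrame, FilterReport]:
    """Apply both filters; return filtered detections, sites and report."""
    site_report = remove_overlapping_sites(sites, reach_m)
    species_report = closure_filter(detections, site_report.retained_sites)
    report = site_report.merge(species_report)
    kept = detections[
        detections["site_id"].isin(report.retained_sites)
        & detections["species_code"].isin(report.retained_species)
    ].reset_index(drop=True)
    kept_sites = sites[sites["site_id"].isin(report.retained_sites)].reset_index(
        drop=True
    )
    return kept, kept_sites, report
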