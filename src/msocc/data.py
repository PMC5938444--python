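"""Detection-history containers and CSV interchange.

The central observed-data object is :class:`DetectionData`: a binary
species x site x replicate array of detections/non-detections together
with a per-replicate survey-year flag and the two standardized site
covariates (creek width, distance to the sink lake) that drive occupancy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

#: canonical column sets of the two interchange CSVs
DETECTIONS_COLUMNS = ["site_id", "species_code", "year", "replicate", "detected"]
SITES_COLUMNS = ["site_id", "position_m", "width_m", "distance_to_sink_m"]


def standardize(x: np.ndarray) -> np.ndarray:
    """Center and scale to unit sample standard deviation (ddof=1).

    A constant vector is returned as all zeros rather than NaN so that
    covariate-free model variants remain expressible.
    """
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=1) if x.size > 1 else 0.0
    if sd == 0.0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


@dataclass
class DetectionData:
    """Replicated detection histories for a fish community.

    Parameters
    ----------
    y
        int8 array of shape (n_species, n_sites, n_reps); 1 detection,
        0 non-detection, -1 missing replicate.
    year_flag
        0/1 per replicate. Flag 1 marks the *first* survey year (the
        year whose detection intercept is ``v_yr2``), flag 0 the second.
    species, sites
        Species codes and site identifiers, in array order.
    width, distance
        Standardized covariate vectors over sites (creek width and
        distance to the sink lake).
    """

    y: np.ndarray
    year_flag: np.ndarray
    species: list = field(default_factory=list)
    sites: list = field(default_factory=list)
    width: np.ndarray | None = None
    distance: np.ndarray | None = None

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=np.int8)
        if self.y.ndim != 3:
            raise ValueError("y must be species x sites x replicates")
        n_s, n_j, n_k = self.y.shape
        if not np.isin(self.y, (MISSING, 0, 1)).all():
            raise ValueError("y entries must be 0, 1 or -1 (missing)")
        self.year_flag = np.asarray(self.year_flag, dtype=np.int8)
        if self.year_flag.shape != (n_k,):
            raise ValueError("year_flag must have one entry per replicate")
        if not np.isin(self.year_flag, (0, 1)).all():
            raise ValueError("year_flag entries must be 0 or 1")
        if not self.species:
            self.species = [f"SP{i + 1:02d}" for i in range(n_s)]
        if not self.sites:
            self.sites = list(range(1, n_j + 1))
        if len(self.species) != n_s or len(self.sites) != n_j:
            raise ValueError("label lengths inconsistent with y")
        if self.width is None:
            self.width = np.zeros(n_j)
        if self.distance is None:
            self.distance = np.zeros(n_j)
        self.width = np.asarray(self.width, dtype=float)
        self.distance = np.asarray(self.distance, dtype=float)
        if self.width.shape != (n_j,) or self.distance.shape != (n_j,):
            raise ValueError("covariate vectors must have one entry per site")
        if not (np.isfinite(self.width).all() and np.isfinite(self.distance).all()):
            raise ValueError("covariates must be finite")

    # -- basic shape accessors -------------------------------------------------
    @property
    def n_species(self) -> int:
        return self.y.shape[0]

    @property
    def n_sites(self) -> int:
        return self.y.shape[1]

    @property
    def n_reps(self) -> int:
        return self.y.shape[2]

    def detected_anywhere(self) -> np.ndarray:
        """Boolean (n_species, n_sites): any detection across replicates."""
        return (self.y == 1).any(axis=2)

    def subset(self, species=None, sites=None) -> "DetectionData":
        sp_idx = (
            np.arange(self.n_species)
            if species is None
            else np.array([self.species.index(s) for s in species])
        )
        si_idx = (
            np.arange(self.n_sites)
            if sites is None
            else np.array([self.sites.index(s) for s in sites])
        )
        return DetectionData(
            y=self.y[np.ix_(sp_idx, si_idx, np.arange(self.n_reps))],
            year_flag=self.year_flag.copy(),
            species=[self.species[i] for i in sp_idx],
            sites=[self.sites[i] for i in si_idx],
            width=standardize(self.width[si_idx]),
            distance=standardize(self.distance[si_idx]),
        )

    # -- CSV interchange -------------------------------------------------------
    @classmethod
    def from_long(
        cls, detections: pd.DataFrame, sites: pd.DataFrame
    ) -> "DetectionData":
        """Build from the long detections table and the sites table.

        ``detections`` columns: site_id, species_code, year, replicate,
        detected. ``sites`` columns: site_id, position_m, width_m,
        distance_to_sink_m. Covariates are standardized here; the year
        flag is 1 for the earlier of the two survey years. (site, species,
        year, replicate) combinations absent from the table are treated
        as missing replicates.
        """
        missing = set(DETECTIONS_COLUMNS) - set(detections.columns)
        if missing:
            raise ValueError(f"detections table missing columns: {sorted(missing)}")
        missing = set(SITES_COLUMNS) - set(sites.columns)
        if missing:
            raise ValueError(f"sites table missing columns: {sorted(missing)}")

        years = sorted(detections["year"].unique())
        if len(years) > 2:
            raise ValueError("at most two survey years are supported")
        site_ids = list(sites["site_id"])
        det = detections[detections["site_id"].isin(site_ids)]
        species = sorted(det["species_code"].unique())

        # global replicate axis: years in chronological order, replicate
        # number within year; the earlier year carries flag 1
        rep_keys = sorted(
            {(int(r.year), int(r.replicate)) for r in det.itertuples()}
        )
        year_flag = np.array([1 if yr == years[0] else 0 for yr, _ in rep_keys])
        k_index = {key: k for k, key in enumerate(rep_keys)}

        y = np.full((len(species), len(site_ids), len(rep_keys)), MISSING, np.int8)
        sp_index = {s: i for i, s in enumerate(species)}
        si_index = {s: j for j, s in enumerate(site_ids)}
        for r in det.itertuples():
            i = sp_index[r.species_code]
            j = si_index[r.site_id]
            k = k_index[(int(r.year), int(r.replicate))]
            y[i, j, k] = int(r.detected)

        return cls(
            y=y,
            year_flag=year_flag,
            species=species,
            sites=site_ids,
            width=standardize(sites["width_m"].to_numpy()),
            distance=standardize(sites["distance_to_sink_m"].to_numpy()),
        )

    def to_long(self, years: tuple[int, int] = (2009, 2015)) -> pd.DataFrame:
        """Flatten to the long detections table; missing cells are omitted.

        ``years`` gives the calendar labels for flag 1 (first) and flag 0
        (second).
        """
        rows = []
        rep_counter = {0: 0, 1: 0}
        rep_number = []
        for flag in self.year_flag:
            rep_counter[int(flag)] += 1
            rep_number.append(rep_counter[int(flag)])
        year_label = {1: years[0], 0: years[1]}
        for i, sp in enumerate(self.species):
            for j, si in enumerate(self.sites):
                for k in range(self.n_reps):
                    v = self.y[i, j, k]
                    if v == MISSING:
                        continue
                    rows.append(
                        (
                            si,
                            sp,
                            year_label[int(self.year_flag[k])],
                            rep_number[k],
                            int(v),
                        )
                    )
        return pd.DataFrame(rows, columns=DETECTIONS_COLUMNS)
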