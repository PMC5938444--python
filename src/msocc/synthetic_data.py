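"""Synthetic stream-fish communities with known ground truth.

Generates replicated detection histories under the exact data-generating
process the hierarchical multispecies occupancy model assumes: species
occupancy depends linearly (on the logit scale) on two standardized site
covariates, detection is species- and survey-year-specific, and every
species-level parameter is drawn from a community-level normal
distribution. The defaults emulate a two-survey study of a small boreal
creek: 12 species, 31 sites, three trap replicates per survey year.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .data import DetectionData, standardize

_PARAM_FAMILIES = ("u", "a1", "a2", "v_yr1", "v_yr2")


@dataclass(frozen=True)
class CommunityHyperparams:
    """Means and spreads of the community-level normal distributions.

    All parameters live on the logit scale. ``u`` is the occupancy
    intercept, ``a1``/``a2`` the linear effects of standardized creek
    width and distance to the sink lake, and ``v_yr1``/``v_yr2`` the
    detection intercepts for the second and first survey year.
    """

    mu_u: float = 0.0
    sigma_u: float = 2.0
    mu_a1: float = 0.0
    sigma_a1: float = 1.0
    mu_a2: float = 0.0
    sigma_a2: float = 1.0
    mu_v1: float = -0.25
    sigma_v1: float = 1.5
    mu_v2: float = -0.25
    sigma_v2: float = 1.5

    def __post_init__(self):
        for name, value in asdict(self).items():
            if name.startswith("sigma") and value < 0:
                raise ValueError(f"{name} must be non-negative, got {value}")

    def mean_sd(self, family: str) -> tuple[float, float]:
        short = {"u": "u", "a1": "a1", "a2": "a2", "v_yr1": "v1", "v_yr2": "v2"}[family]
        return getattr(self, f"mu_{short}"), getattr(self, f"sigma_{short}")


@dataclass
class TrueCommunity:
    """Ground-truth species parameters and latent occupancy states."""

    u: np.ndarray
    a1: np.ndarray
    a2: np.ndarray
    v_yr1: np.ndarray
    v_yr2: np.ndarray
    z: np.ndarray | None = None  # (n_species, n_sites) in {0,1}

    def __post_init__(self):
        for name in _PARAM_FAMILIES:
            arr = np.asarray(getattr(self, name), dtype=float)
            if not np.isfinite(arr).all():
                raise ValueError(f"{name} must be finite")
            setattr(self, name, arr)
        if self.z is not None:
            self.z = np.asarray(self.z, dtype=np.int8)
            if self.z.ndim != 2 or self.z.shape[0] != self.u.shape[0]:
                raise ValueError("z must be n_species x n_sites")

    @property
    def n_species(self) -> int:
        return self.u.shape[0]

    def to_json(self) -> str:
        d = {k: np.asarray(getattr(self, k)).tolist() for k in _PARAM_FAMILIES}
        if self.z is not None:
            d["z"] = self.z.tolist()
        return json.dumps(d, indent=2)


@dataclass(frozen=True)
class CovariateSpec:
    """Geometry of the simulated creek.

    Site positions (m, increasing downstream toward the sink lake) are
    evenly spaced with uniform jitter along ``creek_length_m``; distance
    to the sink lake is the remaining downstream length, and creek width
    is normal around ``width_mean_m`` (floored at ``width_min_m``).
    """

    creek_length_m: float = 8000.0
    width_mean_m: float = 4.0
    width_sd_m: float = 1.5
    width_min_m: float = 0.5
    jitter_frac: float = 0.2

    def draw_sites(self, n_sites: int, rng: np.random.Generator) -> pd.DataFrame:
        spacing = self.creek_length_m / (n_sites + 1)
        base = spacing * np.arange(1, n_sites + 1)
        pos = base + rng.uniform(-self.jitter_frac, self.jitter_frac, n_sites) * spacing
        width = np.maximum(
            rng.normal(self.width_mean_m, self.width_sd_m, n_sites), self.width_min_m
        )
        return pd.DataFrame(
            {
                "site_id": np.arange(1, n_sites + 1),
                "position_m": pos,
                "width_m": width,
                "distance_to_sink_m": self.creek_length_m - pos,
            }
        )


@dataclass
class SyntheticDataset:
    """A generated dataset bundled with its ground truth and seed."""

    detections: DetectionData
    sites: pd.DataFrame
    truth: TrueCommunity
    seed: int
    psi: np.ndarray = field(repr=False, default=None)  # (n_species, n_sites)
    p: np.ndarray = field(repr=False, default=None)  # (n_species, n_reps)


def draw_species_params(
    hyper: CommunityHyperparams,
    n_species: int,
    seed: int | np.random.Generator,
) -> TrueCommunity:
    """Draw species-level parameters from the community distributions.

    Each of the five parameter families is an independent normal draw
    per species with the family's hyper-mean and hyper-sd.
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    draws = {}
    for family in _PARAM_FAMILIES:
        mu, sd = hyper.mean_sd(family)
        draws[family] = rng.normal(mu, sd, size=n_species)
    return TrueCommunity(**draws)


def generate_dataset(
    hyper: CommunityHyperparams | None = None,
    n_species: int = 12,
    n_sites: int = 31,
    n_reps_per_year: int = 3,
    covariates: CovariateSpec | None = None,
    seed: int = 0,
) -> SyntheticDataset:
    """Simulate a full two-survey detection-history dataset.

    Latent occupancy ``z[i, j]`` is Bernoulli with logit-linear
    probability in the standardized covariates; detections are Bernoulli
    with the species- and year-specific probability, and can only occur
    where ``z = 1``. Replicates are ordered first survey year (flag 1)
    then second (flag 0), ``n_reps_per_year`` each.

    The master seed is split into four independent sub-streams
    (parameters, geometry, occupancy states, detections) so that e.g.
    enlarging the community leaves the geometry unchanged.
    """
    if n_species < 1 or n_sites < 1 or n_reps_per_year < 1:
        raise ValueError("dimensions must be positive")
    hyper = hyper or CommunityHyperparams()
    covariates = covariates or CovariateSpec()

    ss = np.random.SeedSequence(seed)
    rng_params, rng_geom, rng_states, rng_det = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    truth = draw_species_params(hyper, n_species, rng_params)
    sites = covariates.draw_sites(n_sites, rng_geom)
    width1 = standardize(sites["width_m"].to_numpy())
    distance1 = standardize(sites["distance_to_sink_m"].to_numpy())

    eta = (
        truth.u[:, None]
        + truth.a1[:, None] * width1[None, :]
        + truth.a2[:, None] * distance1[None, :]
    )
    psi = expit(eta)
    z = (rng_states.random((n_species, n_sites)) < psi).astype(np.int8)
    truth.z = z

    n_reps = 2 * n_reps_per_year
    year_flag = np.array([1] * n_reps_per_year + [0] * n_reps_per_year, np.int8)
    p = np.where(
        year_flag[None, :] == 1,
        expit(truth.v_yr2)[:, None],
        expit(truth.v_yr1)[:, None],
    )
    y = (
        rng_det.random((n_species, n_sites, n_reps))
        < z[:, :, None] * p[:, None, :]
    ).astype(np.int8)

    detections = DetectionData(
        y=y,
        year_flag=year_flag,
        species=[f"SP{i + 1:02d}" for i in range(n_species)],
        sites=list(sites["site_id"]),
        width=width1,
        distance=distance1,
    )
    return SyntheticDataset(
        detections=detections, sites=sites, truth=truth, seed=seed, psi=psi, p=p
    )


def add_overlapping_sites(
    sites: pd.DataFrame,
    n_extra: int,
    reach_m: float,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Insert sites that violate the home-range spacing rule.

    Each extra site is placed a short distance *upstream* of a randomly
    chosen existing site — within ``2 * reach_m``, so the spatial
    independence filter will remove exactly the inserted sites (they are
    the upstream member of each overlapping pair). Emulates a survey
    design laid out before the home-range criterion is applied.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    base = sites.sort_values("position_m").reset_index(drop=True)
    creek_length = float(
        (base["position_m"] + base["distance_to_sink_m"]).iloc[0]
    )
    anchors = rng.choice(len(base), size=n_extra, replace=False)
    rows = []
    next_id = int(pd.to_numeric(base["site_id"], errors="coerce").max() or 0) + 1
    for a in anchors:
        offset = rng.uniform(0.2, 0.9) * 2 * reach_m
        pos = base.loc[a, "position_m"] - offset
        rows.append(
            {
                "site_id": next_id,
                "position_m": pos,
                "width_m": float(base.loc[a, "width_m"]),
                "distance_to_sink_m": creek_length - pos,
            }
        )
        next_id += 1
    out = pd.concat([base, pd.DataFrame(rows)], ignore_index=True)
    if out["position_m"].duplicated().any():  # vanishingly unlikely
        warnings.warn("duplicate positions generated; re-jittering")
        dup = out["position_m"].duplicated()
        out.loc[dup, "position_m"] += rng.uniform(0.1, 1.0, dup.sum())
    return out.sort_values("position_m", ignore_index=True)
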