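"""Synthetic DHS-like survey data with known ground truth.

The real analysis target — two waves of a national household survey with
child anthropometry — is restricted-access microdata.  This module
generates a stand-in survey table whose covariate marginals are calibrated
to the published wave-level descriptive statistics (child age, maternal
education, vaccination counts, malaria incidence, ...), with

* a toy district geography (square lattice with rook adjacency),
* primary sampling units (PSUs) nested in districts, with the DHS-style
  GPS displacement rule (rural points displaced up to 5 km, urban up to
  2 km, 1% of rural points up to 10 km),
* a household asset table from which the wealth index is built by PCA,
* known non-linear covariate effects on the mean and on the log standard
  deviation of the height-for-age z-score (HAZ), and a known smooth
  district field per wave,

so that parameter-recovery and model-selection behaviour can be tested
against truth.  Education, wealth and urban residence share a latent
factor (rho = 0.4) so confounding adjustment is exercised; all true
effects are centred within wave so the wave intercept equals the target
mean HAZ.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from distreg.bases import DistrictGraph

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "WAVE_TARGETS",
    "generate_lattice_districts",
    "generate_survey",
    "asset_index_pca",
    "regional_mean_deviation",
]

#: published wave-level calibration targets: mean (and sd where used)
WAVE_TARGETS = {
    "2007": {
        "haz_mean": -1.59,
        "age_months": (29.14, 17.03),
        "breastfeeding_months": (16.22, 7.04),
        "birth_order": (2.99, 2.38),
        "vaccinations": (5.64, 2.40),
        "mother_age_at_birth": (24.30, 6.82),
        "mother_bmi": (22.35, 3.42),
        "mother_education_years": (7.18, 3.53),
        "household_size": (6.27, 2.49),
        "malaria_incidence": (0.26, 0.11),
        "drought_index": (-0.59, 0.66),
        "population_density": (260.07, 831.22),
        "p_male": 0.4962,
        "p_urban": 0.3873,
        "n": 7936,
    },
    "2013/14": {
        "haz_mean": -1.47,
        "age_months": (29.84, 17.20),
        "breastfeeding_months": (15.69, 7.11),
        "birth_order": (2.88, 2.37),
        "vaccinations": (7.45, 2.17),
        "mother_age_at_birth": (24.08, 6.94),
        "mother_bmi": (22.57, 3.75),
        "mother_education_years": (7.81, 3.64),
        "household_size": (6.60, 2.77),
        "malaria_incidence": (0.20, 0.12),
        "drought_index": (0.37, 0.91),
        "population_density": (321.87, 1098.58),
        "p_male": 0.5008,
        "p_urban": 0.4301,
        "n": 17916,
    },
}

#: asset indicators and their (intercept, wealth loading) on the logit scale
_ASSET_MODEL = {
    "electricity": (-1.2, 1.8),
    "radio": (0.3, 0.8),
    "television": (-0.8, 1.6),
    "refrigerator": (-1.6, 1.7),
    "bicycle": (0.0, 0.4),
    "motorcycle": (-2.2, 0.9),
    "improved_water": (-0.2, 1.1),
    "finished_floor": (-0.9, 1.5),
}


def _softplus(x):
    return np.log1p(np.exp(-np.abs(x))) + np.maximum(x, 0.0)


# ---------------------------------------------------------------------------
# true effect library: qualitative shapes reported for this outcome
# (flat-then-rising education effect, U-shaped BMI, rising vaccination
# effect, malaria decline above incidence 0.3); these are test fixtures
# with known truth, not claims about any real population.

def _true_mu_effects():
    return {
        "asset_index_dev": lambda a: 0.15 * a,
        "mother_education_years": lambda e: 0.10 * _softplus(e - 8.0),
        "mother_bmi": lambda b: 0.0015 * (b - 22.5) ** 2,
        "vaccinations": lambda v: 0.03 * (v - 7.0),
        "household_size": lambda h: -0.01 * (h - 6.0),
        "malaria_incidence": lambda m: -0.8 * np.maximum(0.0, m - 0.3),
        "drought_index": lambda d: np.zeros_like(np.asarray(d, dtype=float)),
        "population_density": lambda p: 0.02 * (np.log1p(p) - 4.0),
    }


def _true_mu_tensor_effects():
    return {
        ("birth_order", "mother_age_at_birth"): lambda bo, am: (
            -0.02 * (bo - 3.0) + 0.004 * (am - 24.0)
            - 0.0015 * (bo - 3.0) * (am - 24.0)
        ),
        ("age_months", "breastfeeding_months"): lambda ag, bf: (
            -0.5 * (1.0 - np.exp(-ag / 15.0))
            + 0.004 * (bf - 16.0) * np.exp(-ag / 24.0)
        ),
    }


def _true_logsigma_effects():
    return {
        "mother_education_years": lambda e: -0.08 * _softplus(e - 8.0),
        "vaccinations": lambda v: -0.04 * (v - 7.0),
    }


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; defaults reproduce the published study scale."""

    seed: int
    n_children: dict = field(
        default_factory=lambda: {"2007": 7936, "2013/14": 17916}
    )
    lattice_side: int = 5
    psu_per_district: int = 4
    gps_displacement: bool = True
    spatial_sd_mu: float = 0.15
    spatial_sd_sigma: float = 0.08
    logsigma_intercept: float = 0.23
    boy_effect: float = -0.10
    urban_effect: float = 0.04
    wave2007_logsigma: float = 0.05
    latent_rho: float = 0.4
    km_per_cell: float = 50.0

    def __post_init__(self) -> None:
        if self.lattice_side < 2:
            raise ValueError("lattice side must be >= 2 (>= 4 districts)")
        for w in self.n_children:
            if w not in WAVE_TARGETS:
                raise ValueError(f"unknown wave {w!r}")


@dataclass
class GroundTruth:
    """Everything the generator knows: true effect functions (centred the
    same way the response was built), district fields and intercepts."""

    mu_effects: dict
    mu_tensor_effects: dict
    logsigma_effects: dict
    spatial_mu: dict  # wave -> per-district array
    spatial_logsigma: dict
    wave_intercepts: dict
    logsigma_intercept: float
    boy_effect: float
    urban_effect: float
    centering: dict  # (side, effect, wave) -> subtracted constant

    def export(self, path) -> None:
        """Machine-readable export: spatial fields, intercepts and each
        effect tabulated on a grid."""
        out = {
            "wave_intercepts": self.wave_intercepts,
            "logsigma_intercept": self.logsigma_intercept,
            "boy_effect": self.boy_effect,
            "urban_effect": self.urban_effect,
            "spatial_mu": {w: v.tolist() for w, v in self.spatial_mu.items()},
            "spatial_logsigma": {w: v.tolist() for w, v in self.spatial_logsigma.items()},
            "centering": {"|".join(map(str, k)): v for k, v in self.centering.items()},
        }
        grids = {
            "asset_index_dev": np.linspace(-2, 2, 41),
            "mother_education_years": np.linspace(0, 25, 51),
            "mother_bmi": np.linspace(14, 40, 53),
            "vaccinations": np.arange(0, 15.0),
            "household_size": np.arange(1, 16.0),
            "malaria_incidence": np.linspace(0, 1, 41),
            "drought_index": np.linspace(-3, 3, 41),
            "population_density": np.linspace(0, 5000, 51),
        }
        out["mu_effect_tables"] = {
            k: {"grid": g.tolist(), "value": self.mu_effects[k](g).tolist()}
            for k, g in grids.items() if k in self.mu_effects
        }
        out["logsigma_effect_tables"] = {
            k: {"grid": g.tolist(), "value": self.logsigma_effects[k](g).tolist()}
            for k, g in grids.items() if k in self.logsigma_effects
        }
        Path(path).write_text(json.dumps(out, indent=2))


def generate_lattice_districts(side: int) -> tuple[DistrictGraph, pd.DataFrame]:
    """``side x side`` districts with rook adjacency and unit-square
    polygons for choropleth export."""
    if side < 2:
        raise ValueError("side must be >= 2")
    nodes = [f"d{r:02d}{c:02d}" for r in range(side) for c in range(side)]
    edges = set()
    for r in range(side):
        for c in range(side):
            if c + 1 < side:
                edges.add((f"d{r:02d}{c:02d}", f"d{r:02d}{c + 1:02d}"))
            if r + 1 < side:
                edges.add((f"d{r:02d}{c:02d}", f"d{r + 1:02d}{c:02d}"))
    rows = []
    for r in range(side):
        for c in range(side):
            rows.append({
                "district": f"d{r:02d}{c:02d}", "row": r, "col": c,
                "xmin": float(c), "ymin": float(r),
                "xmax": float(c + 1), "ymax": float(r + 1),
            })
    return DistrictGraph(nodes=nodes, edges=edges), pd.DataFrame(rows)


def _smooth_lattice_field(side: int, sd: float, rng) -> np.ndarray:
    """Zero-mean smooth field on the lattice: north-south gradient plus a
    low-frequency sinusoid, scaled to the requested sd."""
    r, c = np.meshgrid(np.arange(side), np.arange(side), indexing="ij")
    base = (r - (side - 1) / 2.0) / side + 0.35 * np.sin(
        np.pi * c / max(side - 1, 1) + rng.uniform(0, np.pi)
    )
    f = base.ravel()
    f = f - f.mean()
    s = f.std()
    return f / s * sd if s > 0 else f


def asset_index_pca(assets: pd.DataFrame, orient_by: str = "electricity") -> np.ndarray:
    """Household wealth score: first principal component of the
    standardised asset-indicator matrix (Filmer-Pritchett style index),
    sign-oriented so ``orient_by`` loads positively, standardised to
    mean 0 / sd 1."""
    if len(assets) < 2:
        raise ValueError("need >= 2 households")
    X = assets.to_numpy(dtype=float)
    sd = X.std(axis=0)
    keep = sd > 0
    if keep.sum() < 2:
        raise ValueError("need >= 2 non-constant asset indicators")
    cols = [c for c, k in zip(assets.columns, keep) if k]
    Xs = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    _, _, vt = np.linalg.svd(Xs, full_matrices=False)
    loading = vt[0]
    if orient_by in cols and loading[cols.index(orient_by)] < 0:
        loading = -loading
    elif orient_by not in cols and loading.sum() < 0:
        loading = -loading
    score = Xs @ loading
    return (score - score.mean()) / score.std()


def regional_mean_deviation(score: np.ndarray, region_ids) -> np.ndarray:
    """Score minus its region mean; per-region output means are zero."""
    s = pd.Series(np.asarray(score, dtype=float))
    regions = pd.Series(np.asarray(region_ids))
    if len(s) != len(regions):
        raise ValueError("score and region ids differ in length")
    if regions.isna().any():
        raise ValueError("every household needs a region")
    return (s - s.groupby(regions).transform("mean")).to_numpy()


def _truncated_normal(rng, mean, sd, low, high, size):
    """Truncated-normal draws whose *truncated* mean equals ``mean``.

    The underlying location is shifted (solved by bisection) so that
    truncation does not bias the moment away from the calibration target.
    """
    from scipy.optimize import brentq
    from scipy.stats import truncnorm

    def trunc_mean(loc):
        a, b = (low - loc) / sd, (high - loc) / sd
        return truncnorm.mean(a, b, loc=loc, scale=sd)

    lo_loc, hi_loc = mean - 3 * sd, mean + 3 * sd
    try:
        loc = brentq(lambda m: trunc_mean(m) - mean, lo_loc, hi_loc, xtol=1e-6)
    except ValueError:  # target unreachable within bracket; fall back
        loc = mean
    a, b = (low - loc) / sd, (high - loc) / sd
    return truncnorm.rvs(a, b, loc=loc, scale=sd, size=size, random_state=rng)


def _displace(rng, x, y, urban):
    """DHS confidentiality displacement: random bearing; distance uniform
    within 2 km (urban) / 5 km (rural), with 1% of rural points up to
    10 km."""
    n = x.size
    theta = rng.uniform(0, 2 * np.pi, n)
    max_km = np.where(urban, 2.0, 5.0)
    far = (~urban) & (rng.uniform(size=n) < 0.01)
    max_km = np.where(far, 10.0, max_km)
    d = rng.uniform(0, max_km)
    return x + d * np.cos(theta), y + d * np.sin(theta)


def generate_survey(config: SyntheticConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw a synthetic two-wave child-level survey table.

    Returns the table (one row per child) and the ground-truth record used
    to build the response.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    side = config.lattice_side
    graph, _ = generate_lattice_districts(side)
    districts = graph.nodes
    S = len(districts)

    mu_eff = _true_mu_effects()
    mu_tensor = _true_mu_tensor_effects()
    ls_eff = _true_logsigma_effects()
    spatial_mu = {}
    spatial_ls = {}
    frames = []
    centering = {}
    wave_intercepts = {}

    for wave, n in sorted(config.n_children.items()):
        t = WAVE_TARGETS[wave]
        if n <= 0:
            raise ValueError(f"n for wave {wave} must be positive")

        # --- geography: PSUs nested in districts ---
        n_psu = S * config.psu_per_district
        psu_district = np.repeat(np.arange(S), config.psu_per_district)
        psu_urban = rng.uniform(size=n_psu) < t["p_urban"]
        cell = config.km_per_cell
        drow = np.array([int(d[1:3]) for d in districts])
        dcol = np.array([int(d[3:5]) for d in districts])
        psu_x = (dcol[psu_district] + rng.uniform(0.1, 0.9, n_psu)) * cell
        psu_y = (drow[psu_district] + rng.uniform(0.1, 0.9, n_psu)) * cell
        if config.gps_displacement:
            psu_x, psu_y = _displace(rng, psu_x, psu_y, psu_urban)

        child_psu = rng.integers(0, n_psu, n)
        district_idx = psu_district[child_psu]
        urban = psu_urban[child_psu]

        # --- latent wealth/education factor structure (rho = 0.4) ---
        p_u = urban.mean() if 0 < urban.mean() < 1 else 0.5
        urban_z = (urban - p_u) / np.sqrt(p_u * (1 - p_u))
        rho = config.latent_rho
        eps_w = rng.standard_normal(n)
        eps_e = rng.standard_normal(n)
        wealth = rho * urban_z + np.sqrt(1 - rho**2) * eps_w
        c_we = (rho - rho**2) / np.sqrt(1 - rho**2)
        d_e = np.sqrt(max(1.0 - rho**2 - c_we**2, 0.0))
        edu_lat = rho * urban_z + c_we * eps_w + d_e * eps_e

        em, es = t["mother_education_years"]
        education = np.clip(em + es * edu_lat, 0.0, 25.0)

        # --- household assets -> PCA wealth index ---
        assets = pd.DataFrame({
            name: (rng.uniform(size=n) < 1.0 / (1.0 + np.exp(-(a + b * wealth))))
            .astype(int)
            for name, (a, b) in _ASSET_MODEL.items()
        })
        asset_index = asset_index_pca(assets)
        district_labels = np.array(districts)[district_idx]
        asset_dev = regional_mean_deviation(asset_index, district_labels)

        # --- remaining covariates, moments matched to published targets ---
        am, _ = t["age_months"]
        age = rng.uniform(0.0, 2.0 * am, n)
        bm, bs = t["breastfeeding_months"]
        breastfeeding = _truncated_normal(rng, bm, bs, 0.0, 60.0, n)
        birth_order = 1.0 + rng.poisson(t["birth_order"][0] - 1.0, n)
        vaccinations = rng.poisson(t["vaccinations"][0], n).astype(float)
        mam, mas = t["mother_age_at_birth"]
        mother_age = _truncated_normal(rng, mam, mas, 13.0, 49.0, n)
        bmm, bms = t["mother_bmi"]
        bmi = _truncated_normal(rng, bmm, bms, 12.0, 55.0, n)
        household = 1.0 + rng.poisson(t["household_size"][0] - 1.0, n)
        gender = np.where(rng.uniform(size=n) < t["p_male"], "male", "female")

        # district-level environmental covariates
        mm, ms = t["malaria_incidence"]
        malaria_d = _truncated_normal(rng, mm, ms, 0.0, 1.0, S)
        dm, ds = t["drought_index"]
        drought_d = rng.normal(dm, ds, S)
        pm, ps = t["population_density"]
        s2 = np.log1p((ps / pm) ** 2)
        popden_psu = rng.lognormal(np.log(pm) - s2 / 2.0, np.sqrt(s2), n_psu)

        malaria = malaria_d[district_idx]
        drought = drought_d[district_idx]
        popden = popden_psu[child_psu]

        # --- true spatial fields ---
        f_mu = _smooth_lattice_field(side, config.spatial_sd_mu, rng)
        f_ls = _smooth_lattice_field(side, config.spatial_sd_sigma, rng)
        spatial_mu[wave] = f_mu
        spatial_ls[wave] = f_ls

        cov = {
            "asset_index_dev": asset_dev,
            "mother_education_years": education,
            "mother_bmi": bmi,
            "vaccinations": vaccinations,
            "household_size": household,
            "malaria_incidence": malaria,
            "drought_index": drought,
            "population_density": popden,
        }

        # --- response: centred additive truth + heteroscedastic noise ---
        eta_mu = np.zeros(n)
        for name, f in mu_eff.items():
            v = f(cov[name])
            shift = float(v.mean())
            centering[("mu", name, wave)] = shift
            eta_mu += v - shift
        for (c1, c2), f in mu_tensor.items():
            pair = {"birth_order": birth_order, "mother_age_at_birth": mother_age,
                    "age_months": age, "breastfeeding_months": breastfeeding}
            v = f(pair[c1], pair[c2])
            shift = float(v.mean())
            centering[("mu", f"{c1}*{c2}", wave)] = shift
            eta_mu += v - shift
        gender_term = np.where(gender == "male", config.boy_effect, 0.0)
        urban_term = np.where(urban, config.urban_effect, 0.0)
        for nm, v in (("gender", gender_term), ("urban", urban_term)):
            shift = float(v.mean())
            centering[("mu", nm, wave)] = shift
            eta_mu += v - shift
        sp = f_mu[district_idx]
        centering[("mu", "spatial", wave)] = float(sp.mean())
        eta_mu += sp - sp.mean()

        eta_ls = np.full(n, config.logsigma_intercept)
        if wave == "2007":
            eta_ls += config.wave2007_logsigma
        for name, f in ls_eff.items():
            v = f(cov[name])
            shift = float(v.mean())
            centering[("sigma", name, wave)] = shift
            eta_ls += v - shift
        spl = f_ls[district_idx]
        centering[("sigma", "spatial", wave)] = float(spl.mean())
        eta_ls += spl - spl.mean()

        intercept = t["haz_mean"]
        wave_intercepts[wave] = intercept
        haz = intercept + eta_mu + rng.normal(0.0, 1.0, n) * np.exp(eta_ls)

        frames.append(pd.DataFrame({
            "haz": haz,
            "gender": gender,
            "urban": np.where(urban, "urban", "rural"),
            "wave": wave,
            "age_months": age,
            "breastfeeding_months": breastfeeding,
            "birth_order": birth_order,
            "vaccinations": vaccinations,
            "mother_age_at_birth": mother_age,
            "mother_bmi": bmi,
            "mother_education_years": education,
            "household_size": household,
            "asset_index": asset_index,
            "asset_index_dev": asset_dev,
            "malaria_incidence": malaria,
            "drought_index": drought,
            "population_density": popden,
            "psu_id": [f"{wave}-psu{p:04d}" for p in child_psu],
            "district_id": district_labels,
            "psu_x_km": psu_x[child_psu],
            "psu_y_km": psu_y[child_psu],
        }))

    table = pd.concat(frames, ignore_index=True)
    truth = GroundTruth(
        mu_effects=mu_eff,
        mu_tensor_effects=mu_tensor,
        logsigma_effects=ls_eff,
        spatial_mu=spatial_mu,
        spatial_logsigma=spatial_ls,
        wave_intercepts=wave_intercepts,
        logsigma_intercept=config.logsigma_intercept,
        boy_effect=config.boy_effect,
        urban_effect=config.urban_effect,
        centering=centering,
    )
    return table, truth
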