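"""Synthetic study world with known ground truth.

The generator emulates the structure of the real inputs — gridded
population, per-type infrastructure counts, environmental fields,
night-time lights, administrative units, country covariates and health
outcomes — on a small regular grid, so every pipeline stage can be
exercised and checked against the parameters that produced the data.

Construction, layer by layer:

* **Partition** — countries are rectangular tiles of the grid, each split
  into rectangular counties; a configurable share of countries forms the
  "North" group, the rest the "South".
* **Population** — per country, a few Gaussian population clusters on top
  of a small background, scaled log-normally, so cell populations are
  clustered and right-skewed.
* **Infrastructure** — per type, counts are drawn around an intensity
  ``scale_t * relpop**(loading * c_j)`` with gamma-Poisson (negative-
  binomial-like) dispersion, where ``relpop`` is population relative to the
  country mean and ``c_j`` is the country's *concentration* parameter.  At
  ``c_j = 0`` the intensity is spatially flat and the noise terms vanish,
  so access is near-uniform and the within-country Gini is small; larger
  ``c_j`` co-locates infrastructure with population and raises inequality
  monotonically.  Type-specific ``scale_t`` values reproduce the abundance
  skew across types (energy poles vastly outnumber, e.g., waste sites).
* **Environment** — green / air / heat are smooth correlated fields in
  [0, 1] (Gaussian-filtered noise mapped through the normal CDF).
* **Night-time lights** — a noisy power law of the normalized economic
  layer, ``NTL = exp(b_true) * I'**a_true * exp(noise)``.
* **Health** — country covariates (ExpEco, ExpSoc, GiniEco, GiniSoc,
  LnPop, LnGDP) are computed from the generated grids with the package's
  own access and inequality routines, and HALE is drawn from the linear
  mixed-model predictor with group intercepts ``gamma_g`` and homoscedastic
  noise (a heteroscedastic switch exists to exercise the Levene/sandwich
  path).  DALYs are generated as a negatively related burden outcome.

All randomness flows from one seed through per-layer child seeds
(`numpy` ``SeedSequence.spawn``), so adding a layer does not perturb the
others and identical configs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.stats import norm

from infraccess.admin import AdminPartition, UNIT_COLUMNS
from infraccess.grid import GridLayer
from infraccess import layers as L
from infraccess import exposure as E
from infraccess import inequality as Q

__all__ = ["WorldConfig", "GroundTruth", "generate_world", "ground_truth", "simulate_health_panel"]

REGIONS = ("Europe", "Asia", "North America", "South America", "Oceania", "Africa")

#: Reported country-level mixed-model coefficients used as the generator's
#: default health law (response in years of healthy life expectancy).
DEFAULT_BETA = {
    "const": 66.86,
    "LnPop": -2.07,
    "LnGDP": 2.01,
    "ExpEco": 3.84,
    "ExpSoc": 2.23,
    "GiniEco": -9.95,
    "GiniSoc": 3.03,
}


@dataclass
class WorldConfig:
    """Knobs of the synthetic world.  Defaults give a small but full world."""

    seed: int = 0
    grid_shape: tuple[int, int] = (96, 192)
    cell_size_deg: float = 0.1
    origin: tuple[float, float] = (90.0, -180.0)
    n_countries: int = 166
    counties_per_country: int = 4
    north_share: float = 54 / 166  # share of countries in the North group

    # population model
    pop_clusters: int = 3
    pop_cluster_sd_cells: float = 2.5
    pop_background: float = 40.0
    pop_log_mu: float = 8.5  # cluster amplitude ~ exp(N(mu, sigma))
    pop_log_sigma: float = 0.8
    pop_noise_sigma: float = 0.35

    # infrastructure model: type -> (abundance scale, loading on log-population)
    infra_scales: dict = field(
        default_factory=lambda: {
            "telecom": 60.0,
            "energy": 400.0,
            "transport": 180.0,
            "health": 8.0,
            "education": 16.0,
            "water": 25.0,
            "waste": 12.0,
        }
    )
    infra_loading: float = 1.0
    infra_dispersion: float = 0.25  # NB-like over-dispersion at concentration 1
    infra_log_noise: float = 0.30  # multiplicative log-noise at concentration 1
    concentration_north: tuple[float, float] = (0.3, 0.8)
    concentration_south: tuple[float, float] = (0.8, 1.5)
    concentration_override: float | None = None  # force one value for every country
    north_scale_boost: float = 2.0  # North countries get denser infrastructure
    # social facilities are scarce and town-bound, so they concentrate more
    # strongly than economic networks; water/waste utilities track settlements
    # more evenly
    type_concentration_mult: dict = field(
        default_factory=lambda: {
            "telecom": 1.0,
            "energy": 1.0,
            "transport": 1.0,
            "health": 1.6,
            "education": 1.6,
            "water": 0.8,
            "waste": 0.8,
        }
    )

    # environmental fields
    env_corr_len_cells: float = 6.0

    # night-time-light law ln(NTL) = a_true ln(I') + b_true + noise
    ntl_a_true: float = 1.58
    ntl_b_true: float = 5.03
    ntl_log_noise: float = 0.25

    # health law (country level)
    beta: dict = field(default_factory=lambda: dict(DEFAULT_BETA))
    gamma_north: float = 2.0
    gamma_south: float = -2.0
    health_resid_sd: float = 3.0
    heteroscedastic: bool = False  # double the South residual sd when set
    daly_base: float = 30000.0
    daly_slope: float = -900.0  # DALYs per year of predicted HALE above baseline
    daly_resid_sd: float = 1500.0

    # GDP law ln(GDP) = gdp_const + gdp_pop_elast * ln(pop) + gdp_access_coef * ExpEco + noise
    gdp_const: float = 8.0
    gdp_pop_elast: float = 1.0
    gdp_access_coef: float = 2.0
    gdp_noise_sd: float = 0.4

    def validate(self) -> None:
        if self.n_countries < 4:
            raise ValueError("need at least 4 countries")
        if min(self.grid_shape) < 4:
            raise ValueError("grid too small")
        if self.counties_per_country < 1:
            raise ValueError("counties_per_country must be >= 1")
        for name in ("pop_log_sigma", "health_resid_sd", "daly_resid_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class GroundTruth:
    """Parameters the recovery tests compare against."""

    ntl_a_true: float
    ntl_b_true: float
    beta: dict
    gamma: dict
    concentration: dict  # country unit_id -> concentration parameter


def _tile_edges(n: int, parts: int) -> list[tuple[int, int]]:
    cuts = np.linspace(0, n, parts + 1).astype(int)
    return [(int(cuts[i]), int(cuts[i + 1])) for i in range(parts)]


def _country_tiles(shape: tuple[int, int], n_countries: int) -> list[tuple[slice, slice]]:
    nrows, ncols = shape
    tr = max(1, int(round(np.sqrt(n_countries * nrows / ncols))))
    tc = int(np.ceil(n_countries / tr))
    row_edges = _tile_edges(nrows, tr)
    col_edges = _tile_edges(ncols, tc)
    tiles = []
    for r0, r1 in row_edges:
        for c0, c1 in col_edges:
            if r1 > r0 and c1 > c0:
                tiles.append((slice(r0, r1), slice(c0, c1)))
    if len(tiles) < n_countries:
        raise ValueError(
            f"grid {shape} too small to host {n_countries} countries"
        )
    return tiles[:n_countries]


def _county_tiles(tile: tuple[slice, slice], parts: int) -> list[tuple[slice, slice]]:
    rs, cs = tile
    h, w = rs.stop - rs.start, cs.stop - cs.start
    pr = max(1, int(round(np.sqrt(parts * h / max(w, 1)))))
    pr = min(pr, h)
    pc = int(np.ceil(parts / pr))
    pc = min(pc, w)
    subs = []
    for r0, r1 in _tile_edges(h, pr):
        for c0, c1 in _tile_edges(w, pc):
            if r1 > r0 and c1 > c0:
                subs.append(
                    (slice(rs.start + r0, rs.start + r1), slice(cs.start + c0, cs.start + c1))
                )
    return subs[:parts]


def _build_partition(config: WorldConfig, rng: np.random.Generator) -> AdminPartition:
    tiles = _country_tiles(config.grid_shape, config.n_countries)
    n = config.n_countries
    n_north = int(round(config.north_share * n))
    north_ids = set(rng.choice(np.arange(1, n + 1), size=n_north, replace=False).tolist())
    unit_ids = np.zeros(config.grid_shape, dtype=np.int64)
    rows = []
    next_id = n + 1
    for cid, tile in enumerate(tiles, start=1):
        group = "North" if cid in north_ids else "South"
        region = REGIONS[(cid - 1) % len(REGIONS)]
        rows.append(
            {
                "unit_id": cid,
                "name": f"country_{cid:03d}",
                "level": "country",
                "region": region,
                "group": group,
                "parent_unit_id": 0,
            }
        )
        for sub in _county_tiles(tile, config.counties_per_country):
            unit_ids[sub] = next_id
            rows.append(
                {
                    "unit_id": next_id,
                    "name": f"county_{cid:03d}_{next_id}",
                    "level": "county",
                    "region": region,
                    "group": group,
                    "parent_unit_id": cid,
                }
            )
            next_id += 1
    units = pd.DataFrame(rows, columns=UNIT_COLUMNS)
    return AdminPartition(
        unit_ids=unit_ids,
        units=units,
        cell_size_deg=config.cell_size_deg,
        origin=config.origin,
    )


def _population_field(
    config: WorldConfig, partition: AdminPartition, rng: np.random.Generator
) -> np.ndarray:
    pop = np.zeros(config.grid_shape)
    country_ids = partition.ids_at("country")
    nrows, ncols = config.grid_shape
    rr, cc = np.mgrid[0:nrows, 0:ncols]
    for cid in partition.units_at("country")["unit_id"]:
        inside = country_ids == cid
        cells = np.argwhere(inside)
        field_c = np.full(config.grid_shape, config.pop_background)
        centers = cells[rng.integers(0, len(cells), size=config.pop_clusters)]
        for cr, ccol in centers:
            amp = float(np.exp(rng.normal(config.pop_log_mu, config.pop_log_sigma)))
            d2 = (rr - cr) ** 2 + (cc - ccol) ** 2
            field_c += amp * np.exp(-d2 / (2 * config.pop_cluster_sd_cells**2))
        noise = np.exp(rng.normal(0.0, config.pop_noise_sigma, size=config.grid_shape))
        pop[inside] = (field_c * noise)[inside]
    return pop


def _concentrations(
    config: WorldConfig, partition: AdminPartition, rng: np.random.Generator
) -> dict[int, float]:
    out = {}
    for _, row in partition.units_at("country").iterrows():
        if config.concentration_override is not None:
            c = float(config.concentration_override)
        else:
            lo, hi = (
                config.concentration_north
                if row["group"] == "North"
                else config.concentration_south
            )
            c = float(rng.uniform(lo, hi))
        out[int(row["unit_id"])] = c
    return out


def _infra_fields(
    config: WorldConfig,
    partition: AdminPartition,
    pop: np.ndarray,
    conc: dict[int, float],
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    country_ids = partition.ids_at("country")
    north = set(
        partition.units_at("country")
        .query("group == 'North'")["unit_id"]
        .tolist()
    )
    fields = {}
    for t, scale in config.infra_scales.items():
        tmult = config.type_concentration_mult.get(t, 1.0)
        counts = np.zeros(config.grid_shape)
        for cid, c_country in conc.items():
            c = c_country * tmult
            inside = country_ids == cid
            relpop = pop[inside] / pop[inside].mean()
            boost = config.north_scale_boost if cid in north else 1.0
            shape = relpop ** (config.infra_loading * c)
            # fixed per-country budget: concentration redistributes
            # infrastructure towards population rather than adding to it
            intensity = scale * boost * shape / shape.mean()
            if config.infra_log_noise * c > 0:
                intensity = intensity * np.exp(
                    rng.normal(0.0, config.infra_log_noise * c, size=intensity.shape)
                )
            disp = config.infra_dispersion * c
            if disp > 0:
                # gamma-Poisson mixture: Var = mean + disp * mean^2
                shape_p = 1.0 / disp
                lam = rng.gamma(shape_p, intensity / shape_p)
            else:
                lam = intensity
            counts[inside] = rng.poisson(lam)
        fields[t] = counts
    return fields


def _smooth_unit_field(
    shape: tuple[int, int], corr_len: float, rng: np.random.Generator
) -> np.ndarray:
    noise = rng.standard_normal(shape)
    smooth = gaussian_filter(noise, sigma=corr_len, mode="wrap")
    sd = smooth.std()
    if sd == 0:
        return np.full(shape, 0.5)
    return norm.cdf(smooth / sd)


def generate_world(config: WorldConfig):
    """Generate (layers, partition, covariate table) for one seed.

    ``layers`` maps names to :class:`GridLayer`: per-type counts under
    ``type_<name>``, plus ``population``, ``green``, ``air``, ``heat``,
    ``ntl`` and the boolean ``urban_mask``.  The covariate table has one
    row per country with group, region, LnPop, LnGDP, the access and Gini
    covariates computed from the generated grids, and the simulated
    ``Health`` (HALE, years) and ``DALYs`` outcomes.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    (
        ss_part,
        ss_pop,
        ss_conc,
        ss_infra,
        ss_env,
        ss_ntl,
        ss_health,
    ) = root.spawn(7)

    partition = _build_partition(config, np.random.default_rng(ss_part))
    pop = _population_field(config, partition, np.random.default_rng(ss_pop))
    conc = _concentrations(config, partition, np.random.default_rng(ss_conc))
    infra = _infra_fields(config, partition, pop, conc, np.random.default_rng(ss_infra))

    rng_env = np.random.default_rng(ss_env)
    green = _smooth_unit_field(config.grid_shape, config.env_corr_len_cells, rng_env)
    air = _smooth_unit_field(config.grid_shape, config.env_corr_len_cells, rng_env)
    heat = _smooth_unit_field(config.grid_shape, config.env_corr_len_cells, rng_env)

    def as_layer(arr, mask=None):
        return GridLayer(
            values=np.asarray(arr, dtype=float),
            mask=np.ones(config.grid_shape, dtype=bool) if mask is None else mask,
            cell_size_deg=config.cell_size_deg,
            origin=config.origin,
        )

    inside_any = partition.unit_ids > 0
    layers: dict[str, GridLayer] = {f"type_{t}": as_layer(v, inside_any.copy()) for t, v in infra.items()}
    layers["population"] = as_layer(pop, inside_any.copy())
    layers["green"] = as_layer(green)
    layers["air"] = as_layer(air)
    layers["heat"] = as_layer(heat)

    # NTL follows a power law of the normalized initial economic layer
    econ0 = L.aggregate_category(
        [
            L.normalize_type_layer(layers[f"type_{t}"])
            for t, cat in L.DEFAULT_TYPE_CATALOG.items()
            if cat == "economic"
        ]
    )
    rng_ntl = np.random.default_rng(ss_ntl)
    noise = (
        np.exp(rng_ntl.normal(0.0, config.ntl_log_noise, size=config.grid_shape))
        if config.ntl_log_noise > 0
        else np.ones(config.grid_shape)
    )
    ntl = np.where(
        econ0.values > 0,
        np.exp(config.ntl_b_true) * np.maximum(econ0.values, 1e-300) ** config.ntl_a_true * noise,
        0.0,
    )
    layers["ntl"] = as_layer(ntl, econ0.mask.copy())

    pop_vals = pop[inside_any]
    urban_thresh = np.quantile(pop_vals, 0.6)
    layers["urban_mask"] = as_layer((pop > urban_thresh).astype(float), inside_any.copy())

    covariates = _country_covariates(
        config, layers, partition, np.random.default_rng(ss_health)
    )
    return layers, partition, covariates


def _country_covariates(
    config: WorldConfig,
    layers: dict[str, GridLayer],
    partition: AdminPartition,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Country table with pipeline-computed covariates and simulated outcomes."""
    # socio-economic access from calibrated layers (true NTL law coefficients)
    cat_layers = {}
    for cat in ("economic", "social"):
        initial = L.aggregate_category(
            [
                L.normalize_type_layer(layers[f"type_{t}"])
                for t, c in L.DEFAULT_TYPE_CATALOG.items()
                if c == cat
            ]
        )
        fit = L.CalibrationFit(
            slope=config.ntl_a_true, intercept=config.ntl_b_true, r=1.0, n=3
        )
        cat_layers[cat] = L.apply_calibration(initial, fit)

    pop = layers["population"]
    frames = []
    for cat, layer in cat_layers.items():
        raw = E.population_weighted_access(pop, layer, partition, "country")
        frames.append(E.normalize_access(raw, "country", cat))
    access = pd.concat(frames, ignore_index=True)
    wide_access = access.pivot(index="unit_id", columns="category", values="ie_norm")

    ginis = {}
    for cat, layer in cat_layers.items():
        g = Q.unit_inequality(pop, layer, partition, "country", cat, include_inq=False)
        ginis[cat] = g.set_index("unit_id")["gini"]

    countries = partition.units_at("country").set_index("unit_id")
    ids = partition.ids_at("country")
    totals = pd.Series(
        {
            int(cid): float(pop.values[(ids == cid) & pop.mask].sum())
            for cid in countries.index
        }
    )

    df = pd.DataFrame(
        {
            "unit_id": countries.index,
            "name": countries["name"],
            "region": countries["region"],
            "group": countries["group"],
        }
    ).reset_index(drop=True)
    df["LnPop"] = np.log(totals.loc[df["unit_id"]].to_numpy())
    df["ExpEco"] = wide_access["economic"].loc[df["unit_id"]].to_numpy()
    df["ExpSoc"] = wide_access["social"].loc[df["unit_id"]].to_numpy()
    df["GiniEco"] = ginis["economic"].loc[df["unit_id"]].to_numpy()
    df["GiniSoc"] = ginis["social"].loc[df["unit_id"]].to_numpy()
    df["LnGDP"] = (
        config.gdp_const
        + config.gdp_pop_elast * df["LnPop"]
        + config.gdp_access_coef * df["ExpEco"]
        + rng.normal(0.0, config.gdp_noise_sd, size=len(df))
    )

    beta = config.beta
    gamma = np.where(df["group"] == "North", config.gamma_north, config.gamma_south)
    predictor = (
        beta["const"]
        + beta["LnPop"] * df["LnPop"]
        + beta["LnGDP"] * df["LnGDP"]
        + beta["ExpEco"] * df["ExpEco"]
        + beta["ExpSoc"] * df["ExpSoc"]
        + beta["GiniEco"] * df["GiniEco"]
        + beta["GiniSoc"] * df["GiniSoc"]
        + gamma
    )
    sd = np.full(len(df), config.health_resid_sd)
    if config.heteroscedastic:
        sd = np.where(df["group"] == "South", 2.0 * sd, sd)
    df["Health"] = predictor + rng.normal(0.0, 1.0, size=len(df)) * sd
    df["DALYs"] = (
        config.daly_base
        + config.daly_slope * (predictor - float(np.mean(predictor)))
        + rng.normal(0.0, config.daly_resid_sd, size=len(df))
    )
    return df


def ground_truth(config: WorldConfig) -> GroundTruth:
    """Ground-truth parameters of a world, for recovery tests.

    The per-country concentration values are re-derived from the same child
    seed stream used by :func:`generate_world`, so they match the generated
    world verbatim.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    ss_part, _, ss_conc, *_ = root.spawn(7)
    partition = _build_partition(config, np.random.default_rng(ss_part))
    conc = _concentrations(config, partition, np.random.default_rng(ss_conc))
    return GroundTruth(
        ntl_a_true=config.ntl_a_true,
        ntl_b_true=config.ntl_b_true,
        beta=dict(config.beta),
        gamma={"North": config.gamma_north, "South": config.gamma_south},
        concentration=conc,
    )


def simulate_health_panel(
    n_countries: int = 160,
    north_share: float = 51 / 160,
    beta: dict | None = None,
    gamma_north: float = 2.0,
    gamma_south: float = -2.0,
    resid_sd: float = 3.0,
    heteroscedastic: bool = False,
    seed: int = 0,
) -> pd.DataFrame:
    """Country health panel drawn directly from the linear mixed-model law.

    A lightweight alternative to :func:`generate_world` for repeated-fit
    studies (coverage simulations, forest importance): covariates are drawn
    from plausible marginal distributions, independent of group, and the
    response follows the same linear predictor with group intercepts.
    """
    beta = dict(DEFAULT_BETA if beta is None else beta)
    rng = np.random.default_rng(seed)
    n_north = int(round(north_share * n_countries))
    group = np.array(["North"] * n_north + ["South"] * (n_countries - n_north))
    rng.shuffle(group)
    df = pd.DataFrame(
        {
            "unit_id": np.arange(1, n_countries + 1),
            "group": group,
            "LnPop": rng.normal(16.0, 1.5, n_countries),
            "LnGDP": rng.normal(24.0, 1.8, n_countries),
            "ExpEco": rng.beta(2.0, 3.0, n_countries),
            "ExpSoc": rng.beta(2.0, 3.5, n_countries),
            "GiniEco": rng.beta(5.0, 4.0, n_countries),
            "GiniSoc": rng.beta(8.0, 2.0, n_countries),
        }
    )
    gamma = np.where(df["group"] == "North", gamma_north, gamma_south)
    predictor = beta["const"] + gamma
    for term in ("LnPop", "LnGDP", "ExpEco", "ExpSoc", "GiniEco", "GiniSoc"):
        predictor = predictor + beta[term] * df[term]
    sd = np.full(n_countries, resid_sd, dtype=float)
    if heteroscedastic:
        sd = np.where(df["group"] == "South", 2.0 * sd, sd)
    df["Health"] = predictor + rng.normal(0.0, 1.0, n_countries) * sd
    return df
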