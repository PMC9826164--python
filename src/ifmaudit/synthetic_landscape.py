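"""Synthetic forest landscapes with known ground truth.

Every downstream stage of the audit — zonal extraction, control construction,
BACI statistics, the five-hypothesis report — is exercised against scenes
fabricated here, so each scene carries the full complement of inputs the real
analysis consumes: annual true and observed AGL carbon stacks, annual binary
harvest masks, single-year species-fraction layers, covariate rasters at
native and coarse resolution, a land-class map, project polygons, and
registry-style crediting documents.  The generating configuration is retained
as ground truth.

The stand dynamics are deliberately minimal.  Each pixel's biomass grows at
the region's relative rate (a coastal analogue near +1%/yr, an interior
analogue near 0%/yr), ramping smoothly to zero as biomass approaches a
regional carrying capacity; harvest events are square patches with Poisson
yearly counts that knock biomass down to a retention fraction; harvested
stands recover toward their pre-harvest trajectory with a configurable
half-life.  A spin-up period puts the harvest/recovery sawtooth in
statistical equilibrium before the recorded years begin, so the realized
regional trend matches the configured rate.  A saturating measurement model
mimics the underestimation of dense stands by Landsat-calibrated biomass
maps.  Project documents can report accumulation faster than the simulated
truth by a configurable inflation factor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml
from scipy import ndimage
from shapely.geometry import box

from . import geodata_io as gio
from .carbon_accounting import CONSTANTS, ProjectRecord, c_to_co2
from .geodata_io import AnnualRasterStack, grid_transform

__all__ = [
    "StopHarvest",
    "GrowthBoost",
    "LandscapeConfig",
    "SyntheticScene",
    "generate_scene",
    "apply_measurement_model",
    "generate_project_documents",
]

PRIVATE_FOREST, PUBLIC, URBAN_AG = 0, 1, 2
LAND_CLASS_NAMES = {PRIVATE_FOREST: "private-forest", PUBLIC: "public", URBAN_AG: "urban/ag"}


@dataclass(frozen=True)
class StopHarvest:
    """Cease all harvest inside project polygons strictly after start_year."""

    start_year: int


@dataclass(frozen=True)
class GrowthBoost:
    """Add a constant extra accumulation (ton C/ha/yr) inside project polygons after start_year."""

    magnitude: float
    start_year: int


def _per_region(value, regions: tuple[str, ...], name: str) -> dict[str, float]:
    if isinstance(value, dict):
        missing = [r for r in regions if r not in value]
        if missing:
            raise ValueError(f"{name}: missing regions {missing}")
        return {r: float(value[r]) for r in regions}
    return {r: float(value) for r in regions}


@dataclass
class LandscapeConfig:
    """Full parameterization of a synthetic scene.

    Units: biomass in ton/ha (dry), carbon in ton C/ha, cell_size in m,
    rates as fractions per year, areas in ha.  Per-region parameters accept
    either a single number or a {region: value} mapping.
    """

    grid_shape: tuple[int, int] = (120, 120)
    cell_size: float = 30.0
    years: tuple[int, int] = (1986, 2017)          # carbon record
    harvest_end_year: int = 2021                    # harvest record extends past carbon
    regions: tuple[str, ...] = ("coastal", "interior")
    coastal_fraction: float = 0.5                   # columns assigned to regions[0]
    growth_rate_by_region: dict | float = field(
        default_factory=lambda: {"coastal": 0.0105, "interior": 0.001})
    initial_biomass_by_region: dict | float = field(
        default_factory=lambda: {"coastal": 250.0, "interior": 110.0})
    initial_noise_cv: float = 0.15                  # lognormal spatial spread of stand biomass
    carrying_capacity: dict | float = field(
        default_factory=lambda: {"coastal": 900.0, "interior": 400.0})
    harvest_prob_by_region: dict | float = field(
        default_factory=lambda: {"coastal": 0.03, "interior": 0.01})
    harvest_patch_size: int = 2                     # patch side, pixels
    harvest_interannual_cv: float = 0.3             # lognormal year-to-year factor on patch counts
    harvest_retention: float = 0.1                  # biomass fraction left by a harvest
    recovery_halflife: float = 10.0                 # yr, relaxation toward pre-harvest path
    growth_noise_cv: float = 0.03                   # persistent multiplicative pixel-year noise
    transient_noise_cv: float = 0.035               # mean-reverting pixel-year noise (recorded only)
    transient_corr_px: float = 8.0                  # spatial correlation length of transient noise
    saturation_onset: float = 210.0                 # ton C/ha, measurement model
    saturation_slope: float = 0.5                   # observed increment per true increment above onset
    species_names: tuple[str, ...] = ("redwood", "douglas_fir", "tanoak", "other")
    background_fractions: tuple[float, ...] = (0.35, 0.25, 0.20, 0.20)
    low_value_species: str = "tanoak"
    low_value_enrichment: float = 1.5               # multiplier inside biased projects
    n_projects: int = 3
    project_area_range: tuple[float, float] = (40.0, 80.0)   # ha
    project_start_year: int = 2012
    project_regions: tuple[str, ...] | None = None  # default: all in regions[0]
    project_owner_classes: tuple[str, ...] | None = None  # default: by region
    project_placement_bias: str = "none"            # none | recently_harvested | low_value_species
    bias_owner_class: str | None = None             # restrict placement bias to one owner class
    effect_injection: tuple = ()                    # StopHarvest / GrowthBoost instances
    reporting_inflation: float = 1.0                # document rate / measured rate
    baseline_fraction: float = 0.7                  # baseline stock / initial stock
    public_fraction: float = 0.15
    urban_fraction: float = 0.05
    match_resolution: float = 800.0                 # m, coarse covariate grid
    spinup_years: int = 50
    rng_seed: int = 0

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        frac_fields = {
            "coastal_fraction": self.coastal_fraction,
            "harvest_retention": self.harvest_retention,
            "baseline_fraction": self.baseline_fraction,
            "public_fraction": self.public_fraction,
            "urban_fraction": self.urban_fraction,
        }
        for name, v in frac_fields.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name, v in [("growth_rate_by_region", self.growth_rates()),
                        ("harvest_prob_by_region", self.harvest_probs())]:
            for r, x in v.items():
                if name == "harvest_prob_by_region" and not 0.0 <= x <= 1.0:
                    raise ValueError(f"{name}[{r}] must be in [0, 1], got {x}")
        if self.harvest_retention >= 1.0:
            raise ValueError(f"harvest_retention must be < 1, got {self.harvest_retention}")
        if self.years[1] - self.years[0] + 1 < 10:
            raise ValueError(f"years must span >= 10, got {self.years}")
        if self.harvest_end_year < self.years[1]:
            raise ValueError("harvest_end_year must not precede the carbon record end")
        if len(self.species_names) != len(self.background_fractions):
            raise ValueError("background_fractions must match species_names in length")
        if abs(sum(self.background_fractions) - 1.0) > 1e-9:
            raise ValueError("background_fractions must sum to 1")
        if self.low_value_species not in self.species_names:
            raise ValueError(f"low_value_species {self.low_value_species!r} not in species_names")
        if self.project_placement_bias not in ("none", "recently_harvested", "low_value_species"):
            raise ValueError(
                f"project_placement_bias must be none|recently_harvested|low_value_species, "
                f"got {self.project_placement_bias!r}")
        cell_ha = (self.cell_size ** 2) / 1e4
        total_px = self.grid_shape[0] * self.grid_shape[1]
        max_proj_px = self.n_projects * self.project_area_range[1] / cell_ha
        if max_proj_px >= 0.25 * total_px:
            raise ValueError(
                "project_area_range: total project area must stay below 25% of the landscape")

    # -- per-region accessors ----------------------------------------------

    def growth_rates(self) -> dict[str, float]:
        return _per_region(self.growth_rate_by_region, self.regions, "growth_rate_by_region")

    def initial_biomass(self) -> dict[str, float]:
        return _per_region(self.initial_biomass_by_region, self.regions,
                           "initial_biomass_by_region")

    def capacities(self) -> dict[str, float]:
        return _per_region(self.carrying_capacity, self.regions, "carrying_capacity")

    def harvest_probs(self) -> dict[str, float]:
        return _per_region(self.harvest_prob_by_region, self.regions, "harvest_prob_by_region")

    @property
    def cell_area_ha(self) -> float:
        return (self.cell_size ** 2) / 1e4

    @property
    def coarse_factor(self) -> int:
        return max(1, round(self.match_resolution / self.cell_size))

    # -- serialization ------------------------------------------------------

    def to_yaml(self, path: str) -> None:
        d = asdict(self)
        d["effect_injection"] = [
            {"kind": type(e).__name__, **asdict(e)} for e in self.effect_injection]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "LandscapeConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        effects = []
        for e in d.pop("effect_injection", []):
            kind = e.pop("kind")
            effects.append({"StopHarvest": StopHarvest, "GrowthBoost": GrowthBoost}[kind](**e))
        for key in ("grid_shape", "years", "regions", "species_names",
                    "background_fractions", "project_area_range", "project_regions",
                    "project_owner_classes"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(effect_injection=tuple(effects), **d)


@dataclass
class SyntheticScene:
    """A complete fabricated landscape with its generating truth."""

    true_carbon: AnnualRasterStack       # ton C/ha
    observed_carbon: AnnualRasterStack   # after the measurement model
    harvest: AnnualRasterStack           # binary 0/1
    species_fractions: dict[str, np.ndarray]
    covariates: dict[str, np.ndarray]    # temperature (degC), precipitation (mm/yr), site_class
    covariates_coarse: dict[str, np.ndarray]
    coarse_factor: int
    land_class: np.ndarray               # PRIVATE_FOREST / PUBLIC / URBAN_AG
    region_map: np.ndarray               # index into region_names
    region_names: tuple[str, ...]
    projects: list[ProjectRecord]
    project_masks: dict[str, np.ndarray]
    truth: LandscapeConfig

    def region_mask(self, label: str) -> np.ndarray:
        if label not in self.region_names:
            raise KeyError(f"unknown region {label!r}; have {self.region_names}")
        return self.region_map == self.region_names.index(label)

    def private_forest(self) -> np.ndarray:
        return self.land_class == PRIVATE_FOREST

    def all_project_mask(self) -> np.ndarray:
        m = np.zeros(self.region_map.shape, dtype=bool)
        for pm in self.project_masks.values():
            m |= pm
        return m


# ---------------------------------------------------------------------------
# helpers


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    """Standardized smooth Gaussian random field (mean 0, sd 1)."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="wrap")
    sd = f.std()
    return (f - f.mean()) / sd if sd > 0 else f


def apply_measurement_model(true_stack: AnnualRasterStack, onset: float,
                            slope: float) -> AnnualRasterStack:
    """Saturating observation of dense stands.

    Observed carbon equals true carbon below the onset density; above it, each
    additional ton of true carbon registers as only ``slope`` tons observed
    (piecewise linear), emulating the high-density underestimation of
    Landsat-calibrated biomass maps.  Monotone nondecreasing by construction.
    """
    if onset <= 0:
        raise ValueError(f"saturation onset must be positive, got {onset}")
    v = true_stack.values.astype(float)
    if np.any(v[np.isfinite(v)] < 0):
        raise ValueError("negative carbon density in input stack")
    obs = np.where(v > onset, onset + slope * (v - onset), v)
    return AnnualRasterStack(obs, true_stack.years.copy(), true_stack.transform,
                             true_stack.crs, true_stack.nodata, true_stack.units)


# ---------------------------------------------------------------------------
# scene generation


def _make_land_class(rng: np.random.Generator, cfg: LandscapeConfig) -> np.ndarray:
    shape = cfg.grid_shape
    lc = np.full(shape, PRIVATE_FOREST, dtype=np.int8)
    pub_field = _smooth_field(rng, shape, sigma=max(shape) / 12)
    urb_field = _smooth_field(rng, shape, sigma=max(shape) / 18)
    if cfg.public_fraction > 0:
        lc[pub_field >= np.quantile(pub_field, 1 - cfg.public_fraction)] = PUBLIC
    if cfg.urban_fraction > 0:
        thresh = np.quantile(urb_field[lc == PRIVATE_FOREST], 1 - cfg.urban_fraction)
        lc[(urb_field >= thresh) & (lc == PRIVATE_FOREST)] = URBAN_AG
    return lc


def _make_covariates(rng: np.random.Generator, cfg: LandscapeConfig) -> dict[str, np.ndarray]:
    rows, cols = cfg.grid_shape
    rr, cc = np.meshgrid(np.arange(rows) / max(rows - 1, 1),
                         np.arange(cols) / max(cols - 1, 1), indexing="ij")
    temp = 16.0 - 4.0 * rr + 1.0 * _smooth_field(rng, cfg.grid_shape, max(rows, cols) / 10)
    precip = 1900.0 - 1300.0 * cc + 150.0 * _smooth_field(rng, cfg.grid_shape, max(rows, cols) / 10)
    precip = np.clip(precip, 150.0, None)
    productivity = 0.7 * (precip - precip.mean()) / precip.std() \
        + 0.3 * _smooth_field(rng, cfg.grid_shape, max(rows, cols) / 14)
    # ordinal site productivity class, 1 (best) .. 7 (worst), better on wetter ground
    qs = np.quantile(productivity, np.linspace(0, 1, 8)[1:-1])
    site = 7 - np.searchsorted(qs, productivity)
    return {"temperature": temp, "precipitation": precip,
            "site_class": site.astype(float)}


def _harvest_events(rng: np.random.Generator, cfg: LandscapeConfig,
                    region_map: np.ndarray, land_class: np.ndarray,
                    n_years: int) -> np.ndarray:
    """(n_years, rows, cols) boolean harvest events: Poisson counts of square patches."""
    rows, cols = cfg.grid_shape
    events = np.zeros((n_years, rows, cols), dtype=bool)
    ps = cfg.harvest_patch_size
    probs = cfg.harvest_probs()
    harvestable = land_class != URBAN_AG
    cv = cfg.harvest_interannual_cv
    for ri, region in enumerate(cfg.regions):
        rmask = region_map == ri
        n_px = int(rmask.sum())
        if n_px == 0 or probs[region] <= 0:
            continue
        rows_r, cols_r = np.where(rmask)
        r0, r1 = rows_r.min(), rows_r.max()
        c0, c1 = cols_r.min(), cols_r.max()
        lam0 = probs[region] * n_px / (ps * ps)
        for t in range(n_years):
            yearfac = rng.lognormal(-0.5 * cv * cv, cv) if cv > 0 else 1.0
            k = rng.poisson(lam0 * yearfac)
            for _ in range(k):
                pr = rng.integers(r0, r1 + 1)
                pc = rng.integers(c0, c1 + 1)
                sl = (slice(pr, min(pr + ps, r1 + 1)), slice(pc, min(pc + ps, c1 + 1)))
                events[t][sl] |= rmask[sl] & harvestable[sl]
    return events


def _window_mean(field: np.ndarray, h: int, w: int) -> np.ndarray:
    """Mean of every h x w window, indexed by top-left corner (integral image)."""
    rows, cols = field.shape
    if h > rows or w > cols:
        return np.empty((0, 0))
    ii = np.zeros((rows + 1, cols + 1))
    ii[1:, 1:] = field.cumsum(0).cumsum(1)
    s = ii[h:, w:] - ii[:-h, w:] - ii[h:, :-w] + ii[:-h, :-w]
    return s / (h * w)


def _owner_classes(cfg: LandscapeConfig, proj_regions: list[str]) -> list[str]:
    """Owner class per project: explicit list, else large-timber outside the first region."""
    if cfg.project_owner_classes is not None:
        if len(cfg.project_owner_classes) != cfg.n_projects:
            raise ValueError("project_owner_classes must list one class per project")
        return list(cfg.project_owner_classes)
    return ["large-timber" if r != cfg.regions[0] else "other" for r in proj_regions]


def _place_projects(rng: np.random.Generator, cfg: LandscapeConfig,
                    region_map: np.ndarray, land_class: np.ndarray,
                    pre_start_harvest: np.ndarray,
                    low_value_field: np.ndarray) -> list[tuple[int, int, int, int, str]]:
    """Choose non-overlapping rectangular footprints (r0, c0, h, w, region).

    Each project considers a fixed number of candidate positions; the
    placement bias picks the candidate maximizing pre-placement harvest
    frequency or low-value species share, otherwise the first valid one.
    """
    rows, cols = cfg.grid_shape
    cell_ha = cfg.cell_area_ha
    taken = np.zeros(cfg.grid_shape, dtype=bool)
    if cfg.project_regions is not None:
        if len(cfg.project_regions) != cfg.n_projects:
            raise ValueError("project_regions must list one region per project")
        proj_regions = list(cfg.project_regions)
    else:
        proj_regions = [cfg.regions[0]] * cfg.n_projects
    owners = _owner_classes(cfg, proj_regions)
    placements = []
    n_candidates = 15
    for i in range(cfg.n_projects):
        region = proj_regions[i]
        biased = cfg.project_placement_bias != "none" and (
            cfg.bias_owner_class is None or owners[i] == cfg.bias_owner_class)
        ri = cfg.regions.index(region)
        area = rng.uniform(*cfg.project_area_range)
        n_px = max(4, round(area / cell_ha))
        aspect = rng.uniform(0.6, 1.6)
        h = max(2, round(math.sqrt(n_px * aspect)))
        w = max(2, round(n_px / h))
        rmask = (region_map == ri).astype(float)
        free = 1.0 - taken.astype(float)
        private = (land_class == PRIVATE_FOREST).astype(float)

        def _positions(hh: int, ww: int, min_private: float) -> np.ndarray:
            # window means over all top-left positions, via an integral image
            ok = _window_mean(rmask, hh, ww) > 0.999
            if ok.size == 0:
                return np.empty((0, 2), dtype=int)
            ok &= _window_mean(free, hh, ww) == 1.0
            ok &= _window_mean(private, hh, ww) >= min_private
            return np.argwhere(ok)

        # crowded scenes: relax the private-land share, then shrink the footprint
        pos = _positions(h, w, 0.6)
        if pos.size == 0:
            pos = _positions(h, w, 0.4)
        while pos.size == 0 and h > 2 and w > 2:
            h, w = max(2, round(h * 0.85)), max(2, round(w * 0.85))
            pos = _positions(h, w, 0.4)
        if pos.size == 0:
            raise ValueError(
                f"could not place project {i} in region {region!r}; grid too small or crowded")
        picks = pos[rng.choice(pos.shape[0], size=min(n_candidates, pos.shape[0]),
                               replace=False)]
        best, best_score = None, -np.inf
        for j, (r0, c0) in enumerate(picks):
            sl = (slice(r0, r0 + h), slice(c0, c0 + w))
            if biased and cfg.project_placement_bias == "recently_harvested":
                score = float(pre_start_harvest[sl].mean())
            elif biased and cfg.project_placement_bias == "low_value_species":
                score = float(low_value_field[sl].mean())
            else:
                score = -j  # first candidate wins
            if score > best_score:
                best, best_score = (int(r0), int(c0), h, w, region), score
        taken[best[0]:best[0] + best[2], best[1]:best[1] + best[3]] = True
        placements.append(best)
    return placements


def _make_species(rng: np.random.Generator, cfg: LandscapeConfig,
                  land_class: np.ndarray, project_mask: np.ndarray,
                  low_value_field01: np.ndarray) -> dict[str, np.ndarray]:
    """Species-fraction layers summing to 1 on vegetated pixels (NaN on urban/ag)."""
    shape = cfg.grid_shape
    bg = dict(zip(cfg.species_names, cfg.background_fractions))
    lv = cfg.low_value_species
    lv_frac = np.clip(bg[lv] * (0.5 + low_value_field01), 0.0, 0.8)
    if cfg.project_placement_bias == "low_value_species" and cfg.low_value_enrichment != 1.0:
        lv_frac = np.where(project_mask,
                           np.clip(lv_frac * cfg.low_value_enrichment, 0.0, 0.9), lv_frac)
    rest = 1.0 - lv_frac
    rest_bg = 1.0 - bg[lv]
    layers: dict[str, np.ndarray] = {}
    for name in cfg.species_names:
        if name == lv:
            layers[name] = lv_frac.copy()
        else:
            layers[name] = rest * bg[name] / rest_bg
    veg = land_class != URBAN_AG
    for name in layers:
        layers[name] = np.where(veg, layers[name], np.nan)
    return layers


def generate_scene(config: LandscapeConfig) -> SyntheticScene:
    """Simulate a complete scene from a validated configuration.

    Reproducible: the same configuration (including ``rng_seed``) yields
    bit-identical rasters.  Effect injection and placement bias reuse the same
    random draws as the unperturbed scene, so treated and untreated runs of
    one seed differ only through the injected mechanism.
    """
    cfg = config
    cfg.validate()
    rows, cols = cfg.grid_shape
    y0, y1 = cfg.years
    hy1 = cfg.harvest_end_year
    n_record = hy1 - y0 + 1
    n_total = cfg.spinup_years + n_record

    rng_land = np.random.default_rng(np.random.SeedSequence([cfg.rng_seed, 1]))
    rng_harv = np.random.default_rng(np.random.SeedSequence([cfg.rng_seed, 2]))
    rng_grow = np.random.default_rng(np.random.SeedSequence([cfg.rng_seed, 3]))
    rng_proj = np.random.default_rng(np.random.SeedSequence([cfg.rng_seed, 4]))

    # static layers -----------------------------------------------------
    split = int(round(cfg.coastal_fraction * cols))
    region_map = np.zeros(cfg.grid_shape, dtype=np.int8)
    region_map[:, split:] = min(1, len(cfg.regions) - 1)
    land_class = _make_land_class(rng_land, cfg)
    covars = _make_covariates(rng_land, cfg)
    low_value_field01 = 0.5 + 0.25 * _smooth_field(rng_land, cfg.grid_shape, max(rows, cols) / 10)

    # harvest events over spin-up + record ------------------------------
    events = _harvest_events(rng_harv, cfg, region_map, land_class, n_total)

    # project placement (bias sees only pre-start history) ---------------
    start = cfg.project_start_year
    pre_hist = events[: cfg.spinup_years + (start - y0) + 1].mean(axis=0)
    placements = _place_projects(rng_proj, cfg, region_map, land_class,
                                 pre_hist, low_value_field01)
    project_masks: dict[str, np.ndarray] = {}
    all_proj = np.zeros(cfg.grid_shape, dtype=bool)
    for i, (r0, c0, h, w, _region) in enumerate(placements):
        m = np.zeros(cfg.grid_shape, dtype=bool)
        m[r0:r0 + h, c0:c0 + w] = True
        project_masks[f"P{i + 1:03d}"] = m
        all_proj |= m

    # effect injection on the harvest record ------------------------------
    boost_biomass = np.zeros(cfg.grid_shape)
    boost_start: int | None = None
    for eff in cfg.effect_injection:
        if isinstance(eff, StopHarvest):
            t_cut = cfg.spinup_years + (eff.start_year - y0)
            events[t_cut + 1:, all_proj] = False
        elif isinstance(eff, GrowthBoost):
            boost_biomass = np.where(
                all_proj, eff.magnitude / CONSTANTS.carbon_per_biomass, 0.0)
            boost_start = eff.start_year
        else:
            raise ValueError(f"unknown effect {eff!r}")

    # stand dynamics ------------------------------------------------------
    rates = cfg.growth_rates()
    caps = cfg.capacities()
    binit = cfg.initial_biomass()
    g_map = np.zeros(cfg.grid_shape)
    k_map = np.zeros(cfg.grid_shape)
    b0_map = np.zeros(cfg.grid_shape)
    for ri, region in enumerate(cfg.regions):
        sel = region_map == ri
        g_map[sel] = rates[region]
        k_map[sel] = caps[region]
        b0_map[sel] = binit[region]
    cv0 = cfg.initial_noise_cv
    stand_noise = np.exp(cv0 * _smooth_field(rng_grow, cfg.grid_shape, max(rows, cols) / 15)
                         - 0.5 * cv0 * cv0) if cv0 > 0 else np.ones(cfg.grid_shape)
    # back-date the target so the secular trend reaches the configured initial
    # biomass exactly at the first recorded year; the spin-up then equilibrates
    # the harvest/recovery sawtooth in the growing regime, not a static one
    target = b0_map * stand_noise * np.exp(-g_map * cfg.spinup_years)
    B = target.copy()
    k_rec = math.log(2.0) / cfg.recovery_halflife
    shoulder = 0.8                                # growth ramps to 0 over the top 20% of capacity
    gcv = cfg.growth_noise_cv

    biomass_record = np.empty((y1 - y0 + 1, rows, cols))
    for t in range(n_total):
        year = y0 - cfg.spinup_years + t
        damp = np.clip((k_map - B) / ((1.0 - shoulder) * k_map), 0.0, 1.0)
        inc = g_map * B * damp
        recov = k_rec * (target - B)
        inc = np.where(recov > inc, recov, inc)
        if boost_start is not None and year > boost_start:
            inc = inc + boost_biomass
        B = B + inc
        if gcv > 0:
            B = B * np.exp(gcv * rng_grow.standard_normal(cfg.grid_shape) - 0.5 * gcv * gcv)
        B = np.where(events[t], B * cfg.harvest_retention, B)
        B = np.clip(B, 0.0, k_map)
        target = target * np.exp(g_map)
        if y0 <= year <= y1:
            # transient component: spatially correlated year-to-year fluctuation
            # of apparent biomass (moisture, phenology, map-imputation error)
            # that does not propagate into later years
            tcv = cfg.transient_noise_cv
            if tcv > 0:
                eps = _smooth_field(rng_grow, cfg.grid_shape, cfg.transient_corr_px)
                biomass_record[year - y0] = B * np.exp(tcv * eps - 0.5 * tcv * tcv)
            else:
                biomass_record[year - y0] = B

    transform = grid_transform(0.0, rows * cfg.cell_size, cfg.cell_size)
    carbon_years = np.arange(y0, y1 + 1)
    true_carbon = AnnualRasterStack(
        biomass_record * CONSTANTS.carbon_per_biomass, carbon_years, transform,
        crs="local-m", nodata=None, units="ton C/ha")
    observed = apply_measurement_model(true_carbon, cfg.saturation_onset, cfg.saturation_slope)
    harvest = AnnualRasterStack(
        events[cfg.spinup_years:].astype(np.uint8), np.arange(y0, hy1 + 1), transform,
        crs="local-m", nodata=None, units="binary")

    species = _make_species(rng_land, cfg, land_class, all_proj, low_value_field01)

    # coarse covariates ----------------------------------------------------
    factor = min(cfg.coarse_factor, rows, cols)
    coarse: dict[str, np.ndarray] = {}
    for name, layer in covars.items():
        one = AnnualRasterStack(layer[None], np.array([y0]), transform, "local-m",
                                nodata=float("nan"), units=name)
        coarse[name] = gio.block_aggregate(one, factor).values[0]

    # project polygons and documents --------------------------------------
    cell = cfg.cell_size
    owners = _owner_classes(cfg, [p[4] for p in placements])
    projects: list[ProjectRecord] = []
    for i, (r0, c0, h, w, region) in enumerate(placements):
        pid = f"P{i + 1:03d}"
        x0, x1 = c0 * cell, (c0 + w) * cell
        ytop, ybot = (rows - r0) * cell, (rows - r0 - h) * cell
        poly = box(x0, ybot, x1, ytop)
        projects.append(ProjectRecord(
            id=pid, polygon=poly, start_year=start,
            area_ha=h * w * cfg.cell_area_ha, owner_class=owners[i],
            region_label=region))

    scene = SyntheticScene(
        true_carbon=true_carbon, observed_carbon=observed, harvest=harvest,
        species_fractions=species, covariates=covars, covariates_coarse=coarse,
        coarse_factor=factor, land_class=land_class, region_map=region_map,
        region_names=cfg.regions, projects=projects, project_masks=project_masks,
        truth=cfg)
    generate_project_documents(scene, cfg.reporting_inflation)
    return scene


def generate_project_documents(scene: SyntheticScene, inflation: float) -> list[ProjectRecord]:
    """Fill in registry-style crediting documents for the scene's projects.

    The "measured" accumulation rate is the OLS slope of the true zonal AGL
    carbon series over the reporting period (start year to the end of the
    carbon record); the document reports that rate times ``inflation``.
    Reported stocks are written on the total-carbon convention (AGL / 0.806),
    the baseline is a configured fraction of the initial stock, and issuances
    are the initial above-baseline stock followed by annual increments, both
    in ton CO2e.
    """
    from .trend_stats import trend  # local import to avoid a cycle at module load

    cfg = scene.truth
    y1 = int(scene.true_carbon.years.max())
    for rec in scene.projects:
        mask = scene.project_masks[rec.id]
        if not mask.any():
            raise ValueError(f"project {rec.id}: polygon outside the grid")
        ts = gio.zonal_series(scene.true_carbon, mask)
        start = rec.start_year
        rep = ts.window(start, y1)
        measured = trend(rep).slope if len(rep.valid()) >= 3 else 0.0
        agl0 = float(ts.values[ts.years == start][0])
        doc_rate = measured * inflation
        rec.reported_stocks = {
            int(y): (agl0 + doc_rate * (y - start)) / CONSTANTS.agl_fraction
            for y in range(start, y1 + 1)
        }
        rec.reported_is_total = True
        rec.baseline_stock = cfg.baseline_fraction * agl0
        initial = c_to_co2(max(agl0 - rec.baseline_stock, 0.0) * rec.area_ha)
        annual = c_to_co2(max(doc_rate, 0.0) * rec.area_ha)
        rec.credits_issued = {start + 1: initial}
        for y in range(start + 2, y1 + 2):
            rec.credits_issued[y] = annual
    return scene.projects


# ---------------------------------------------------------------------------
# scene export


def write_scene(scene: SyntheticScene, outdir: str) -> None:
    """Write all layers (TIFF), polygons (GeoJSON), documents (CSV), config (YAML)."""
    import os

    from .carbon_accounting import records_to_csv

    os.makedirs(outdir, exist_ok=True)
    gio.write_stack(scene.true_carbon, os.path.join(outdir, "true_carbon"))
    gio.write_stack(scene.observed_carbon, os.path.join(outdir, "observed_carbon"))
    gio.write_stack(scene.harvest, os.path.join(outdir, "harvest"))
    t = scene.true_carbon.transform
    y = scene.true_carbon.years[:1]
    for name, layer in {**scene.covariates,
                        "land_class": scene.land_class.astype(float),
                        "region_map": scene.region_map.astype(float),
                        **{f"species_{k}": v for k, v in scene.species_fractions.items()},
                        }.items():
        gio.write_stack(AnnualRasterStack(layer[None], y, t, "local-m",
                                          nodata=float("nan"), units=name),
                        os.path.join(outdir, name))
    gio.write_polygons(
        os.path.join(outdir, "projects.geojson"),
        [(p.polygon, {"id": p.id, "start_year": p.start_year, "owner_class": p.owner_class})
         for p in scene.projects])
    records_to_csv(scene.projects, os.path.join(outdir, "documents.csv"))
    scene.truth.to_yaml(os.path.join(outdir, "config.yaml"))
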