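"""Calibration and recovery experiments for the audit machinery.

These routines measure the operating characteristics of the statistical core
and of the end-to-end audit on synthetic scenes:

* type-I error of the Chow and paired t-tests under their Gaussian nulls,
* detection rates of the before/after hypotheses (H4 carbon, H5 harvest) on
  scenes with and without injected management effects,
* recovery of constructed species-composition and crediting quantities.

They are used by the test suite and by the reproduction script; all
randomness is controlled through explicit seeds.
"""

from __future__ import annotations

import numpy as np

from . import geodata_io as gio
from . import trend_stats as tst
from .hypotheses_pipeline import CONSISTENT, AuditConfig, run_audit
from .synthetic_landscape import GrowthBoost, LandscapeConfig, StopHarvest, generate_scene

__all__ = [
    "chow_type1_rate",
    "paired_type1_rate",
    "detection_experiment",
    "species_emulation",
    "reporting_inflation_recovery",
    "realized_regional_rates",
]


def chow_type1_rate(n_rep: int = 2000, n_years: int = 27, alpha: float = 0.05,
                    seed: int = 0) -> float:
    """Empirical rejection rate of the Chow test on no-break Gaussian series."""
    rng = np.random.default_rng(seed)
    years = np.arange(2000, 2000 + n_years)
    bp = int(years[n_years // 2])
    rejections = 0
    for _ in range(n_rep):
        vals = 1.0 + 0.5 * (years - years[0]) + rng.normal(0.0, 1.0, n_years)
        r = tst.chow(tst.TimeSeries(years, vals), bp)
        rejections += r.p < alpha
    return rejections / n_rep


def paired_type1_rate(n_rep: int = 2000, n_pairs: int = 27, alpha: float = 0.05,
                      seed: int = 1) -> float:
    """Empirical rejection rate of the paired t-test on exchangeable Gaussian pairs."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_rep):
        a = rng.normal(0.0, 1.0, n_pairs)
        b = rng.normal(0.0, 1.0, n_pairs)
        rejections += tst.paired_test(a, b).p < alpha
    return rejections / n_rep


def _scene_config(seed: int, treated: bool, start_year: int) -> LandscapeConfig:
    effects = (StopHarvest(start_year), GrowthBoost(0.5, start_year)) if treated else ()
    return LandscapeConfig(rng_seed=seed, project_start_year=start_year,
                           effect_injection=effects)


def detection_experiment(n_scenes: int, treated: bool, seed: int = 0,
                         start_year: int = 2009) -> dict[str, float]:
    """Portfolio-level H4/H5 detection rates over replicate scenes.

    Each replicate generates a scene at the generator defaults (optionally
    with harvest cessation and a +0.5 ton C/ha/yr accumulation boost injected
    at the start year), runs the audit against buffer controls, and records
    whether the portfolio verdict for H4 (carbon slope change) and H5
    (harvest change) is consistent-with-additionality.
    """
    cfg = AuditConfig(pre_period=(1986, start_year), control_methods=("buffer",))
    h4 = h5 = 0
    base = (seed * 100_003) % (2 ** 31)
    for i in range(n_scenes):
        scene = generate_scene(_scene_config((base + i) % (2 ** 31), treated, start_year))
        report = run_audit(scene, cfg)
        h4 += report.hypotheses["H4"]["verdict"] == CONSISTENT
        h5 += report.hypotheses["H5"]["verdict"] == CONSISTENT
    return {"h4_rate": h4 / n_scenes, "h5_rate": h5 / n_scenes, "n_scenes": n_scenes}


def species_emulation(project_frac: float = 30.3, control_frac: float = 25.4,
                      n_projects: int = 8, seed: int = 3) -> tst.SpeciesComparison:
    """Recover a constructed low-value-species contrast from raster layers.

    Builds per-project patches whose tanoak share of carbon equals
    ``project_frac`` percent against surroundings at ``control_frac`` percent
    (with small per-project jitter averaging out), then measures the contrast
    through the species-composition machinery.
    """
    rng = np.random.default_rng(seed)
    side = 12
    rows = cols = side * n_projects
    total = np.full((rows, cols), 80.0)
    tan = np.full((rows, cols), control_frac / 100.0)
    pmasks, cmasks = [], []
    jit = rng.normal(0.0, 0.2, n_projects)
    jit -= jit.mean()
    for i in range(n_projects):
        block = np.zeros((rows, cols), bool)
        block[i * side:(i + 1) * side, :side] = True
        proj = np.zeros((rows, cols), bool)
        proj[i * side + 3:i * side + 9, 3:9] = True
        tan[proj] = (project_frac + jit[i]) / 100.0
        pmasks.append(proj)
        cmasks.append(block & ~proj)
    layers = {"tanoak": tan * total, "other": (1.0 - tan) * total}
    return tst.species_contrast(layers, pmasks, cmasks, "tanoak")


def reporting_inflation_recovery(inflation: float = 2.4, seed: int = 5) -> float:
    """Ratio of document-reported to map-measured accumulation on one scene."""
    scene = generate_scene(LandscapeConfig(rng_seed=seed, reporting_inflation=inflation,
                                           project_start_year=2009))
    ratios = []
    for rec in scene.projects:
        agl = rec.agl_stocks()
        years = np.array(sorted(agl), dtype=float)
        doc_rate = np.polyfit(years, [agl[int(y)] for y in years], 1)[0]
        ts = gio.zonal_series(scene.observed_carbon, scene.project_masks[rec.id])
        measured = tst.trend(ts.window(rec.start_year, int(ts.years[-1]))).slope
        if measured > 0:
            ratios.append(doc_rate / measured)
    return float(np.mean(ratios))


def realized_regional_rates(n_scenes: int = 3, seed: int = 11) -> dict[str, float]:
    """Realized percent growth and mean stocks by region, averaged over scenes."""
    pct = {"coastal": [], "interior": []}
    stock = {"coastal": [], "interior": []}
    harvest = {"coastal": [], "interior": []}
    for i in range(n_scenes):
        scene = generate_scene(LandscapeConfig(rng_seed=seed + i))
        for region in scene.region_names:
            m = scene.region_mask(region) & ~scene.all_project_mask()
            r = tst.trend(gio.zonal_series(scene.true_carbon, m))
            pct[region].append(r.percent_rate)
            stock[region].append(r.mean)
            hf = gio.zonal_fraction(scene.harvest, scene.region_mask(region))
            harvest[region].append(float(np.nanmean(hf.values)))
    return {
        "coastal_percent_rate": float(np.mean(pct["coastal"])),
        "interior_percent_rate": float(np.mean(pct["interior"])),
        "coastal_mean_stock": float(np.mean(stock["coastal"])),
        "interior_mean_stock": float(np.mean(stock["interior"])),
        "coastal_harvest_fraction": float(np.mean(harvest["coastal"])),
        "interior_harvest_fraction": float(np.mean(harvest["interior"])),
    }
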