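"""Spatial control groups for the additionality comparison.

Three constructions of "similar but non-enrolled" land:

* :func:`buffer_control` — a 2 km ring of private forest around the project
  polygon, excluding urban/agricultural and public land and every other
  project's interior (geographic adjacency as the similarity argument);
* :func:`region_control` — the regional pool: all private forest carrying the
  project's region label (coastal or interior analogue), projects excluded by
  default;
* :func:`matched_control` — covariate matching at a coarse (~800 m) grid:
  Mahalanobis distance from the project's mean temperature, precipitation and
  site-productivity class, in standardized covariate space, selecting the n
  nearest candidate cells where n matches the project's area.

Every control mask excludes the project's own pixels; statistics never mix
treatment and control.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .carbon_accounting import ProjectRecord
from .geodata_io import AnnualRasterStack, RegionMask, rasterize

__all__ = [
    "ControlSpec",
    "ControlSet",
    "buffer_control",
    "region_control",
    "matched_control",
    "coarse_fraction",
    "write_control",
]


@dataclass
class ControlSpec:
    """Parameters for control construction."""

    method: str = "buffer"                       # buffer | region | matched
    buffer_width: float = 2000.0                 # m
    exclusion_classes: tuple[str, ...] = ("urban/ag", "public", "projects")
    region_label: str = ""
    covariates: tuple[str, ...] = ("temperature", "precipitation", "site_class")
    match_resolution: float = 800.0              # m
    n_pixels: int | None = None                  # None -> area-matched
    include_projects: bool = False               # region method: keep project pixels in the pool

    def __post_init__(self) -> None:
        if self.buffer_width <= 0:
            raise ValueError(f"buffer_width must be positive, got {self.buffer_width}")
        if self.method == "matched" and not self.covariates:
            raise ValueError("matched method requires a nonempty covariate list")


@dataclass
class ControlSet:
    """One control construction for one project (or project group)."""

    project_id: str
    method: str
    mask: RegionMask
    n_pixels: int = 0
    mean_covariate_distance: float = float("nan")
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.n_pixels = self.mask.n_pixels


def _project_union_mask(template: AnnualRasterStack,
                        projects: list[ProjectRecord]) -> np.ndarray:
    m = np.zeros(template.shape, dtype=bool)
    for p in projects:
        if p.polygon is None:
            continue
        try:
            m |= rasterize(p.polygon, template).mask
        except ValueError:
            pass  # a project entirely off-grid excludes nothing
    return m


def buffer_control(
    project: ProjectRecord,
    template: AnnualRasterStack,
    private_forest: np.ndarray,
    all_projects: list[ProjectRecord],
    spec: ControlSpec | None = None,
    region_mask: np.ndarray | None = None,
) -> ControlSet:
    """Ring of private forest within ``buffer_width`` of the project boundary.

    Pixels inside the project, on non-private land, or inside any other
    project polygon are excluded; when ``region_mask`` is given the ring is
    also clipped to the project's own region, so a buffer near a regional
    boundary does not mix lands with different harvest regimes.  An empty
    result raises an error suggesting a wider buffer.
    """
    spec = spec or ControlSpec(method="buffer")
    if project.polygon is None or project.polygon.is_empty:
        raise ValueError(f"project {project.id}: no valid polygon")
    ring = project.polygon.buffer(spec.buffer_width).difference(project.polygon)
    ring_mask = rasterize(ring, template, label=f"{project.id}-buffer").mask
    others = [p for p in all_projects if p.id != project.id]
    excl = _project_union_mask(template, [project] + others)
    mask = ring_mask & np.asarray(private_forest, dtype=bool) & ~excl
    if region_mask is not None:
        mask &= np.asarray(region_mask, dtype=bool)
    if not mask.any():
        raise ValueError(
            f"project {project.id}: buffer control empty after exclusions; "
            f"try a wider buffer than {spec.buffer_width} m")
    return ControlSet(project.id, "buffer", RegionMask(mask, f"{project.id}-buffer"),
                      params={"buffer_width": spec.buffer_width})


def region_control(
    region_label: str,
    region_mask: np.ndarray,
    private_forest: np.ndarray,
    project_union: np.ndarray,
    include_projects: bool = False,
    group_id: str = "",
) -> ControlSet:
    """The regional pool: private forest of one region, projects excluded by default.

    ``include_projects=True`` reproduces the all-private-forest regional
    curves in which enrolled land remains part of the pool.
    """
    region_mask = np.asarray(region_mask, dtype=bool)
    if not region_mask.any():
        raise ValueError(f"region {region_label!r} has no pixels")
    mask = region_mask & np.asarray(private_forest, dtype=bool)
    if not include_projects:
        mask &= ~np.asarray(project_union, dtype=bool)
    if not mask.any():
        raise ValueError(f"region {region_label!r}: control empty after exclusions")
    return ControlSet(group_id or region_label, "region",
                      RegionMask(mask, f"region-{region_label}"),
                      params={"region_label": region_label,
                              "include_projects": include_projects})


def coarse_fraction(fine_mask: np.ndarray, factor: int) -> np.ndarray:
    """Fraction of each coarse cell covered by a fine boolean mask (edge blocks padded)."""
    fine_mask = np.asarray(fine_mask, dtype=float)
    rows, cols = fine_mask.shape
    pr, pc = (-rows) % factor, (-cols) % factor
    if pr or pc:
        fine_mask = np.pad(fine_mask, ((0, pr), (0, pc)))
    R, C = fine_mask.shape[0] // factor, fine_mask.shape[1] // factor
    return fine_mask.reshape(R, factor, C, factor).mean(axis=(1, 3))


def matched_control(
    project: ProjectRecord,
    project_mask_fine: np.ndarray,
    covariate_layers: dict[str, np.ndarray],
    candidate_mask: np.ndarray,
    coarse_factor: int,
    coarse_cell_area_ha: float,
    spec: ControlSpec | None = None,
) -> ControlSet:
    """Mahalanobis-nearest coarse cells matching the project's covariate profile.

    The project's mean covariates are computed over its coarse footprint
    (cells with >= 50% project coverage; if the project is smaller than half a
    cell, the best-covered cell).  Covariates are standardized (z-scored) over
    the candidate cells, the covariance is taken in that standardized space,
    and the n candidates nearest the project mean are selected, with
    n = round(project area / coarse cell area), at least 1.  Ties in distance
    break deterministically by flat cell index.  A singular covariance matrix
    falls back to its diagonal with a warning.
    """
    spec = spec or ControlSpec(method="matched")
    candidate_mask = np.asarray(candidate_mask, dtype=bool)
    names = [n for n in spec.covariates if n in covariate_layers]
    if not names:
        raise ValueError("no requested covariate layers available")
    cov_stack = np.stack([covariate_layers[n] for n in names])   # (k, R, C)
    if cov_stack.shape[1:] != candidate_mask.shape:
        raise ValueError("covariate layers and candidate mask shapes differ")
    ok = np.all(np.isfinite(cov_stack), axis=0)
    candidate_mask = candidate_mask & ok

    frac = coarse_fraction(project_mask_fine, coarse_factor)
    footprint = frac >= 0.5
    if not footprint.any():
        footprint = frac == frac.max()
    footprint &= ok
    if not footprint.any():
        raise ValueError(f"project {project.id}: no valid coarse footprint for covariates")
    candidate_mask &= frac == 0           # never match onto the project itself
    if not candidate_mask.any():
        raise ValueError(f"project {project.id}: no matching candidates left")

    cand = cov_stack[:, candidate_mask].T                      # (m, k)
    mu = cand.mean(axis=0)
    sd = cand.std(axis=0)
    sd[sd == 0] = 1.0
    z_cand = (cand - mu) / sd
    proj_mean = cov_stack[:, footprint].mean(axis=1)
    z_proj = (proj_mean - mu) / sd

    k = len(names)
    if z_cand.shape[0] > k:
        S = np.cov(z_cand, rowvar=False)
    else:
        S = np.eye(k)
    S = np.atleast_2d(S)
    try:
        if np.linalg.cond(S) > 1e10:
            raise np.linalg.LinAlgError("ill-conditioned")
        Sinv = np.linalg.inv(S)
    except np.linalg.LinAlgError:
        warnings.warn("singular covariance in matched_control; falling back to diagonal")
        d = np.clip(np.diag(S), 1e-12, None)
        Sinv = np.diag(1.0 / d)
    delta = z_cand - z_proj
    d2 = np.einsum("ij,jk,ik->i", delta, Sinv, delta)
    d2 = np.maximum(d2, 0.0)

    n = spec.n_pixels
    if n is None:
        n = max(1, round(project.area_ha / coarse_cell_area_ha))
    n = min(n, d2.size)
    flat_idx = np.flatnonzero(candidate_mask.ravel())
    order = np.lexsort((flat_idx, d2))
    chosen = flat_idx[order[:n]]
    mask = np.zeros(candidate_mask.shape, dtype=bool)
    mask.ravel()[chosen] = True
    return ControlSet(
        project.id, "matched", RegionMask(mask, f"{project.id}-matched"),
        mean_covariate_distance=float(np.sqrt(d2[order[:n]]).mean()),
        params={"covariates": names, "n_requested": int(n),
                "coarse_factor": int(coarse_factor)})


def write_control(cs: ControlSet, prefix: str, transform, crs: str = "local") -> None:
    """Serialize a control set as a TIFF mask plus a JSON sidecar of parameters."""
    import tifffile

    meta = {"transform": list(transform), "crs": crs, "nodata": None, "units": "mask",
            "year": 0}
    tifffile.imwrite(f"{prefix}.tif", cs.mask.mask.astype(np.uint8),
                     description=json.dumps(meta))
    with open(f"{prefix}.json", "w") as fh:
        json.dump({"project_id": cs.project_id, "method": cs.method,
                   "n_pixels": cs.n_pixels,
                   "mean_covariate_distance": cs.mean_covariate_distance,
                   "params": cs.params}, fh, indent=2)
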