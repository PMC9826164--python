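"""Offset-project crediting arithmetic.

California's improved-forest-management (IFM) protocol issues credits against a
static 100-year baseline: a large first issuance for the initial carbon stock
above baseline, then smaller incremental issuances as stocks grow.  This
module holds the unit conventions shared with the registry documents —
credits in ton CO2e, stocks in ton C (total or aboveground-live), remote
sensing biomass in ton/ha — and the summary statistics built on them:

* ``credit_summary``: the initial-to-annual issuance ratio and the break-even
  time for incremental growth to overtake the initial payout;
* ``reported_rate`` / ``portfolio_rate``: per-project OLS accumulation rates
  from reported stocks, and their area-weighted portfolio mean with a
  cross-project standard error.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry.base import BaseGeometry

__all__ = [
    "ConversionConstants",
    "CONSTANTS",
    "ProjectRecord",
    "CreditSummary",
    "co2_to_c",
    "c_to_co2",
    "total_to_agl",
    "agl_to_total",
    "biomass_to_c",
    "credit_summary",
    "reported_rate",
    "portfolio_rate",
    "records_to_csv",
    "records_from_csv",
]


@dataclass(frozen=True)
class ConversionConstants:
    """Mass-conversion conventions of the registry documents and biomass maps.

    c_per_co2: molar mass ratio of carbon to carbon dioxide.
    agl_fraction: mean aboveground-live share of total reported carbon stocks,
        used to place totals on the AGL convention of the biomass maps.
    carbon_per_biomass: ton C per ton dry biomass.
    """

    c_per_co2: float = 12.01 / 44.01
    agl_fraction: float = 0.806
    carbon_per_biomass: float = 0.47

    def __post_init__(self) -> None:
        for name in ("c_per_co2", "agl_fraction", "carbon_per_biomass"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")


CONSTANTS = ConversionConstants()


def _nonneg(x, name: str):
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0):
        raise ValueError(f"{name} must be non-negative")
    return arr if arr.ndim else float(arr)


def co2_to_c(x, constants: ConversionConstants = CONSTANTS):
    """ton CO2 -> ton C by the molar mass ratio 12.01/44.01."""
    return _nonneg(x, "CO2 mass") * constants.c_per_co2


def c_to_co2(x, constants: ConversionConstants = CONSTANTS):
    """ton C -> ton CO2 (inverse of :func:`co2_to_c`)."""
    return _nonneg(x, "carbon mass") / constants.c_per_co2


def total_to_agl(x, constants: ConversionConstants = CONSTANTS):
    """Total carbon stock -> aboveground-live component via the 0.806 convention."""
    return _nonneg(x, "total carbon") * constants.agl_fraction


def agl_to_total(x, constants: ConversionConstants = CONSTANTS):
    return _nonneg(x, "AGL carbon") / constants.agl_fraction


def biomass_to_c(x, constants: ConversionConstants = CONSTANTS):
    """ton dry biomass -> ton C (factor 0.47)."""
    return _nonneg(x, "biomass") * constants.carbon_per_biomass


@dataclass
class ProjectRecord:
    """One offset project: its polygon plus the crediting document.

    Stocks are densities (ton C/ha).  ``reported_is_total`` marks documents
    that report total carbon rather than the AGL component; such stocks are
    converted by the AGL fraction before comparison with the biomass maps.
    """

    id: str
    polygon: BaseGeometry | None
    start_year: int
    area_ha: float
    owner_class: str = "other"              # {"large-timber", "other"}
    baseline_stock: float = 0.0             # ton C/ha, AGL convention
    reported_stocks: dict[int, float] = field(default_factory=dict)
    reported_is_total: bool = False
    credits_issued: dict[int, float] = field(default_factory=dict)
    region_label: str = ""                  # {"coastal", "interior"}

    def __post_init__(self) -> None:
        if self.area_ha <= 0:
            raise ValueError(f"project {self.id}: area must be positive")

    def agl_stocks(self, constants: ConversionConstants = CONSTANTS) -> dict[int, float]:
        """Reported stocks on the AGL convention (ton C/ha)."""
        if self.reported_is_total:
            return {y: total_to_agl(v, constants) for y, v in self.reported_stocks.items()}
        return dict(self.reported_stocks)


@dataclass
class CreditSummary:
    initial_credits: float
    mean_annual_incremental_credits: float
    initial_to_annual_ratio: float          # NaN when annual <= 0
    break_even_years: float                 # equals the ratio when annual > 0
    defined: bool = True


def credit_summary(record: ProjectRecord) -> CreditSummary:
    """Initial vs incremental crediting and the break-even time.

    The first issuance is taken as the initial (above-baseline stocking)
    payout; subsequent issuances, averaged per year of the span they cover,
    are the incremental accumulation stream.  With a positive annual stream
    the break-even time (years for cumulative incremental credits to equal
    the initial payout) equals the initial-to-annual ratio.  With a single
    issuance or a non-positive stream the ratio is undefined and flagged.
    """
    if not record.credits_issued:
        raise ValueError(f"project {record.id}: no credit issuances")
    years = sorted(record.credits_issued)
    initial = float(record.credits_issued[years[0]])
    if len(years) < 2:
        return CreditSummary(initial, float("nan"), float("nan"), float("nan"), defined=False)
    span = years[-1] - years[0]
    incremental = float(sum(record.credits_issued[y] for y in years[1:]))
    annual = incremental / span if span > 0 else float("nan")
    if not annual > 0:
        return CreditSummary(initial, annual, float("nan"), float("nan"), defined=False)
    ratio = initial / annual
    return CreditSummary(initial, annual, ratio, ratio, defined=True)


def initial_credits_from_stock(record: ProjectRecord,
                               constants: ConversionConstants = CONSTANTS) -> float:
    """Initial issuance reconstructed as (first stock - baseline) x area, in ton CO2e.

    Fallback for documents without issuance records; stocks and baseline are
    on the AGL convention.
    """
    stocks = record.agl_stocks(constants)
    if not stocks:
        raise ValueError(f"project {record.id}: no reported stocks")
    first = stocks[min(stocks)]
    return c_to_co2(max(first - record.baseline_stock, 0.0) * record.area_ha, constants)


def reported_rate(record: ProjectRecord,
                  constants: ConversionConstants = CONSTANTS) -> float:
    """Project-reported carbon accumulation rate, ton C/ha/yr (AGL convention).

    OLS slope of reported AGL stock against year; at least two reporting
    years are required.
    """
    stocks = record.agl_stocks(constants)
    if len(stocks) < 2:
        raise ValueError(f"project {record.id}: need >=2 reported stocks for a rate")
    years = np.array(sorted(stocks), dtype=float)
    vals = np.array([stocks[int(y)] for y in years])
    return float(np.polyfit(years, vals, 1)[0])


def portfolio_rate(records: list[ProjectRecord],
                   constants: ConversionConstants = CONSTANTS) -> tuple[float, float]:
    """Area-weighted mean reported rate across projects, with cross-project SE.

    The mean is weighted by project area; the standard error is the unweighted
    SE of per-project rates across the sample, so it describes the spread of
    projects rather than of area.
    """
    if len(records) < 2:
        raise ValueError("portfolio rate requires >=2 projects")
    rates = np.array([reported_rate(r, constants) for r in records])
    areas = np.array([r.area_ha for r in records], dtype=float)
    mean = float(np.average(rates, weights=areas))
    se = float(np.std(rates, ddof=1) / np.sqrt(len(rates)))
    return mean, se


# ---------------------------------------------------------------------------
# document IO (one row per project-year)


def records_to_csv(records: list[ProjectRecord], path: str) -> pd.DataFrame:
    rows = []
    for r in records:
        years = sorted(set(r.reported_stocks) | set(r.credits_issued))
        for y in years:
            rows.append({
                "id": r.id,
                "year": y,
                "stock": r.reported_stocks.get(y, np.nan),
                "stock_basis": "total" if r.reported_is_total else "AGL",
                "credits": r.credits_issued.get(y, np.nan),
                "start_year": r.start_year,
                "area_ha": r.area_ha,
                "owner_class": r.owner_class,
                "baseline_stock": r.baseline_stock,
                "region_label": r.region_label,
            })
    df = pd.DataFrame(rows)
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    df.to_csv(path, index=False)
    return df


def records_from_csv(path: str) -> list[ProjectRecord]:
    """Rebuild project records (without polygons) from the tidy CSV form."""
    df = pd.read_csv(path)
    records = []
    for pid, grp in df.groupby("id", sort=False):
        first = grp.iloc[0]
        stocks = {int(y): float(s) for y, s in zip(grp.year, grp.stock) if np.isfinite(s)}
        credits = {int(y): float(c) for y, c in zip(grp.year, grp.credits) if np.isfinite(c)}
        records.append(ProjectRecord(
            id=str(pid),
            polygon=None,
            start_year=int(first.start_year),
            area_ha=float(first.area_ha),
            owner_class=str(first.owner_class),
            baseline_stock=float(first.baseline_stock),
            reported_stocks=stocks,
            reported_is_total=str(first.stock_basis) == "total",
            credits_issued=credits,
            region_label=str(first.region_label),
        ))
    return records
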