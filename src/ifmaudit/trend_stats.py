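"""Trend, structural-break, and paired-contrast statistics for annual zonal series.

This module is the statistical core of the additionality audit.  It operates on
:class:`TimeSeries` objects — typically per-region annual means of aboveground-live
(AGL) carbon density (ton C/ha) or annual harvested-area fractions — and provides

* ordinary-least-squares trends with percent rates (:func:`trend`),
* paired t-tests across years between a project and its control (:func:`paired_across_years`),
* Chow structural-break F-tests on a carbon slope (:func:`chow`),
* equal-window before/after-control-impact comparisons (:func:`before_after`),
* species-composition contrasts between project and control footprints
  (:func:`species_contrast`), and
* area-weighted portfolio aggregation (:func:`portfolio_aggregate`).

All tests are classical (homoskedastic, independent-errors) forms; spatial
autocorrelation corrections are out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "TimeSeries",
    "TrendResult",
    "ChowResult",
    "PairedResult",
    "SpeciesComparison",
    "BeforeAfterResult",
    "trend",
    "paired_across_years",
    "paired_test",
    "chow",
    "before_after",
    "species_contrast",
    "portfolio_aggregate",
]


@dataclass
class TimeSeries:
    """An annual series of zonal values.

    Missing region-years are represented as NaN (flagged, never zero-filled).
    ``n_pixels`` optionally records the number of valid pixels behind each
    annual value.
    """

    years: np.ndarray
    values: np.ndarray
    n_pixels: np.ndarray | None = None
    variable: str = "value"
    units: str = ""
    label: str = ""

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.years.ndim != 1 or self.years.shape != self.values.shape:
            raise ValueError("years and values must be 1-D and the same length")
        if self.years.size >= 2 and not np.all(np.diff(self.years) > 0):
            raise ValueError("years must be strictly increasing")
        if self.n_pixels is not None:
            self.n_pixels = np.asarray(self.n_pixels)
            if self.n_pixels.shape != self.years.shape:
                raise ValueError("n_pixels must match years in length")

    def __len__(self) -> int:
        return self.years.size

    def window(self, start: int, end: int) -> "TimeSeries":
        """Restrict to years in the inclusive range [start, end]."""
        sel = (self.years >= start) & (self.years <= end)
        return TimeSeries(
            self.years[sel],
            self.values[sel],
            None if self.n_pixels is None else self.n_pixels[sel],
            self.variable,
            self.units,
            self.label,
        )

    def valid(self) -> "TimeSeries":
        """Drop years whose value is missing (NaN)."""
        sel = np.isfinite(self.values)
        return TimeSeries(
            self.years[sel],
            self.values[sel],
            None if self.n_pixels is None else self.n_pixels[sel],
            self.variable,
            self.units,
            self.label,
        )


@dataclass
class TrendResult:
    slope: float            # units per year
    slope_se: float
    intercept: float
    percent_rate: float     # % of the period-mean value per year
    period: tuple[int, int]
    n_years: int
    mean: float             # period mean of the series
    mean_se: float          # SE of the mean across years
    p: float = float("nan")


@dataclass
class ChowResult:
    F: float
    p: float
    df: tuple[int, int]
    slope_before: float
    slope_after: float
    breakpoint_year: int
    n_before: int = 0
    n_after: int = 0

    @property
    def slope_change(self) -> float:
        return self.slope_after - self.slope_before


@dataclass
class PairedResult:
    mean_difference: float
    relative_difference: float  # % of the control mean
    t: float
    p: float
    n_pairs: int
    degenerate: bool = False    # zero-variance differences


@dataclass
class SpeciesComparison:
    species: str
    project_fraction: float        # pooled area-weighted % of AGL carbon
    control_fraction: float
    per_project_fractions: np.ndarray = field(default_factory=lambda: np.empty(0))
    per_control_fractions: np.ndarray = field(default_factory=lambda: np.empty(0))
    t: float = float("nan")
    p: float = float("nan")
    n_projects: int = 0


@dataclass
class BeforeAfterResult:
    """Equal-window before/after comparison for one series.

    For carbon-like series the comparison is a Chow test at the start year over
    the two windows; for harvest-like series it is a paired t-test pairing
    year ``start+i`` with ``start-w+i``.
    """

    source: str
    kind: str                   # "carbon" | "harvest"
    start_year: int
    window: int                 # w, years on each side
    before_years: tuple[int, int]
    after_years: tuple[int, int]
    chow: ChowResult | None = None
    paired: PairedResult | None = None
    excluded_reason: str | None = None

    @property
    def excluded(self) -> bool:
        return self.excluded_reason is not None


# ---------------------------------------------------------------------------
# trends


def trend(
    ts: TimeSeries,
    period: tuple[int, int] | None = None,
    percent_denominator: str = "period_mean",
) -> TrendResult:
    """OLS trend of an annual series, with its rate as a percent of stock.

    ``percent_rate`` is 100 x slope / denominator, where the denominator is the
    period-mean value by default (``percent_denominator="period_mean"``) or the
    first year's value (``"initial"``).

    Raises ``ValueError`` with fewer than 3 valid years.
    """
    if period is not None:
        ts = ts.window(*period)
    ts = ts.valid()
    n = len(ts)
    if n < 3:
        raise ValueError(f"trend requires >=3 years, got {n}")
    with warnings.catch_warnings():
        # an exactly linear series makes the residual variance 0; that's fine
        warnings.simplefilter("ignore")
        res = stats.linregress(ts.years, ts.values)
    mean = float(np.mean(ts.values))
    mean_se = float(np.std(ts.values, ddof=1) / np.sqrt(n))
    if percent_denominator == "period_mean":
        denom = mean
    elif percent_denominator == "initial":
        denom = float(ts.values[0])
    else:
        raise ValueError(f"unknown percent_denominator {percent_denominator!r}")
    pct = 100.0 * res.slope / denom if denom != 0 else float("nan")
    return TrendResult(
        slope=float(res.slope),
        slope_se=float(res.stderr),
        intercept=float(res.intercept),
        percent_rate=float(pct),
        period=(int(ts.years[0]), int(ts.years[-1])),
        n_years=n,
        mean=mean,
        mean_se=mean_se,
        p=float(res.pvalue),
    )


# ---------------------------------------------------------------------------
# paired contrasts


def paired_test(a: np.ndarray, b: np.ndarray) -> PairedResult:
    """Classic paired t-test on matched samples ``a`` (treatment) vs ``b`` (control).

    The relative difference is expressed as a percent of the control mean.
    Zero-variance differences are reported as degenerate rather than as p = 0:
    identical samples give t = 0, p = 1; a constant nonzero difference has no
    valid t statistic and is flagged.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    n = a.size
    if n < 2:
        raise ValueError(f"paired test requires >=2 pairs, got {n}")
    d = a - b
    md = float(np.mean(d))
    mb = float(np.mean(b))
    rel = 100.0 * md / mb if mb != 0 else float("nan")
    sd = float(np.std(d, ddof=1))
    if sd == 0.0:
        if md == 0.0:
            return PairedResult(0.0, rel, 0.0, 1.0, n, degenerate=True)
        return PairedResult(md, rel, float("nan"), float("nan"), n, degenerate=True)
    t = md / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    return PairedResult(md, rel, float(t), float(p), n, degenerate=False)


def difference_series(ts_a: TimeSeries, ts_b: TimeSeries) -> TimeSeries:
    """Per-year difference a - b over the common years (the BACI contrast series).

    Differencing against a control removes shocks shared by treatment and
    control (regional weather, harvest-intensity years) before trend or
    structural-break testing.
    """
    common = np.intersect1d(ts_a.years, ts_b.years)
    if common.size == 0:
        raise ValueError("series share no years")
    ia = np.searchsorted(ts_a.years, common)
    ib = np.searchsorted(ts_b.years, common)
    return TimeSeries(common, ts_a.values[ia] - ts_b.values[ib],
                      variable=f"{ts_a.variable}-diff", units=ts_a.units,
                      label=f"{ts_a.label}-minus-{ts_b.label}")


def paired_across_years(ts_a: TimeSeries, ts_b: TimeSeries) -> PairedResult:
    """Paired t-test across the common years of two series (a = project, b = control)."""
    common = np.intersect1d(ts_a.years, ts_b.years)
    if common.size == 0:
        raise ValueError("series share no years")
    ia = np.searchsorted(ts_a.years, common)
    ib = np.searchsorted(ts_b.years, common)
    return paired_test(ts_a.values[ia], ts_b.values[ib])


# ---------------------------------------------------------------------------
# structural break


def _rss(years: np.ndarray, values: np.ndarray) -> float:
    X = np.column_stack([np.ones_like(years, dtype=float), years.astype(float)])
    coef, *_ = np.linalg.lstsq(X, values, rcond=None)
    r = values - X @ coef
    return float(r @ r)


def _slope(years: np.ndarray, values: np.ndarray) -> float:
    X = np.column_stack([np.ones_like(years, dtype=float), years.astype(float)])
    coef, *_ = np.linalg.lstsq(X, values, rcond=None)
    return float(coef[1])


def chow(ts: TimeSeries, breakpoint_year: int) -> ChowResult:
    """Chow F-test for a structural break in the linear trend at a given year.

    Years <= breakpoint_year form the first segment. With k = 2 regression
    parameters (intercept and slope) per segment,

        F = [(RSS_pooled - RSS1 - RSS2)/k] / [(RSS1 + RSS2)/(n1 + n2 - 2k)].

    Requires >=3 valid years on each side. When both segments fit exactly
    (RSS1 = RSS2 = 0) but the pooled fit does not, F is infinite and p = 0.
    """
    ts = ts.valid()
    before = ts.years <= breakpoint_year
    y1, v1 = ts.years[before], ts.values[before]
    y2, v2 = ts.years[~before], ts.values[~before]
    n1, n2 = y1.size, y2.size
    if n1 < 3 or n2 < 3:
        raise ValueError(
            f"chow requires >=3 years on each side of {breakpoint_year}, got {n1} and {n2}"
        )
    k = 2
    rss_p = _rss(ts.years, ts.values)
    rss1 = _rss(y1, v1)
    rss2 = _rss(y2, v2)
    df = (k, n1 + n2 - 2 * k)
    num = (rss_p - rss1 - rss2) / k
    den = (rss1 + rss2) / df[1]
    # guard tiny negative numerators from floating-point cancellation
    scale = max(rss_p, 1e-300)
    if den <= 1e-12 * scale or den == 0.0:
        if num <= 1e-12 * scale:
            F, p = 0.0, 1.0
        else:
            F, p = float("inf"), 0.0
    else:
        F = max(num / den, 0.0)
        p = float(stats.f.sf(F, *df))
    return ChowResult(
        F=float(F),
        p=float(p),
        df=df,
        slope_before=_slope(y1, v1),
        slope_after=_slope(y2, v2),
        breakpoint_year=int(breakpoint_year),
        n_before=int(n1),
        n_after=int(n2),
    )


# ---------------------------------------------------------------------------
# before/after windows


_DEFAULT_MIN_POST = {"carbon": 3, "harvest": 7}


def _infer_kind(source: str, ts: TimeSeries) -> str:
    text = f"{source} {ts.variable}".lower()
    return "harvest" if "harvest" in text else "carbon"


def before_after(
    ts_by_source: dict[str, TimeSeries],
    start_year: int,
    data_end_by_source: dict[str, int],
    kinds: dict[str, str] | None = None,
    min_post: dict[str, int] | None = None,
) -> dict[str, BeforeAfterResult]:
    """Equal-window before/after comparison at a project's start year.

    For each source the window length is w = data_end - start_year (also capped
    by the years available before the start).  The after-window is
    [start+1, start+w] and the before-window the w years ending at the start
    year.  Carbon sources are compared with a Chow test at the start year
    restricted to the two windows; harvest sources with a paired t-test pairing
    years by their offset from the start.  A source whose post-period is
    shorter than its minimum (3 carbon years, 7 harvest years by default) is
    excluded with a reason, never silently skipped.
    """
    min_post = {**_DEFAULT_MIN_POST, **(min_post or {})}
    out: dict[str, BeforeAfterResult] = {}
    for source, ts in ts_by_source.items():
        kind = (kinds or {}).get(source) or _infer_kind(source, ts)
        end = data_end_by_source[source]
        w = min(end, int(ts.years.max())) - start_year
        w = min(w, start_year - int(ts.years.min()) + 1)
        need = min_post.get(kind, 3)
        res = BeforeAfterResult(
            source=source,
            kind=kind,
            start_year=start_year,
            window=max(w, 0),
            before_years=(start_year - w + 1, start_year),
            after_years=(start_year + 1, start_year + w),
        )
        if w < need:
            res.excluded_reason = (
                f"only {max(w, 0)} post-{kind} years available; {need} required"
            )
            out[source] = res
            continue
        windowed = ts.window(start_year - w + 1, start_year + w)
        if kind == "carbon":
            res.chow = chow(windowed, start_year)
        else:
            before = ts.window(start_year - w + 1, start_year)
            after = ts.window(start_year + 1, start_year + w)
            # pair by offset from start: year start+i with year start-w+i
            bvals = np.full(w, np.nan)
            avals = np.full(w, np.nan)
            bidx = before.years - (start_year - w + 1)
            aidx = after.years - (start_year + 1)
            bvals[bidx] = before.values
            avals[aidx] = after.values
            res.paired = paired_test(avals, bvals)
        out[source] = res
    return out


# ---------------------------------------------------------------------------
# species composition


def species_contrast(
    species_layers: dict[str, np.ndarray],
    project_masks: list[np.ndarray],
    control_masks: list[np.ndarray],
    species: str,
) -> SpeciesComparison:
    """Contrast one species' share of AGL carbon in projects vs their controls.

    ``species_layers`` maps species name to a per-pixel carbon-density layer
    (all layers aligned on one grid); a pixel's total carbon is the sum over
    species.  The per-project fraction is (species carbon / total carbon)
    within the mask, in percent; the pooled fraction sums carbon over all
    project (control) pixels so larger projects weigh in proportion to their
    carbon — the area-weighted convention.  A paired t-test across projects
    compares project vs control fractions.  Projects whose mask holds zero
    total carbon are dropped with a warning.
    """
    if species not in species_layers:
        raise KeyError(f"species {species!r} not in layer set")
    if len(project_masks) != len(control_masks):
        raise ValueError("need one control mask per project mask")
    sp = species_layers[species]
    total = np.zeros_like(sp, dtype=float)
    for layer in species_layers.values():
        total = total + np.nan_to_num(layer, nan=0.0)
    spc = np.nan_to_num(sp, nan=0.0)

    def frac(mask: np.ndarray) -> tuple[float, float, float]:
        t = float(total[mask].sum())
        s = float(spc[mask].sum())
        return (100.0 * s / t if t > 0 else float("nan")), s, t

    pf, cf = [], []
    ps = pt = cs = ct = 0.0
    for i, (pm, cm) in enumerate(zip(project_masks, control_masks)):
        f_p, s_p, t_p = frac(np.asarray(pm, dtype=bool))
        f_c, s_c, t_c = frac(np.asarray(cm, dtype=bool))
        if not np.isfinite(f_p) or not np.isfinite(f_c):
            warnings.warn(f"project {i} dropped: zero total carbon in a mask")
            continue
        pf.append(f_p)
        cf.append(f_c)
        ps += s_p
        pt += t_p
        cs += s_c
        ct += t_c
    pf_arr = np.array(pf)
    cf_arr = np.array(cf)
    comp = SpeciesComparison(
        species=species,
        project_fraction=100.0 * ps / pt if pt > 0 else float("nan"),
        control_fraction=100.0 * cs / ct if ct > 0 else float("nan"),
        per_project_fractions=pf_arr,
        per_control_fractions=cf_arr,
        n_projects=pf_arr.size,
    )
    if pf_arr.size >= 2:
        res = paired_test(pf_arr, cf_arr)
        comp.t, comp.p = res.t, res.p
    return comp


# ---------------------------------------------------------------------------
# portfolio aggregation


def portfolio_aggregate(
    series_by_project: dict[str, TimeSeries],
    weights: dict[str, float] | None = None,
) -> tuple[TimeSeries, dict]:
    """Area-weighted portfolio mean series plus cross-project summary statistics.

    The per-year portfolio value is the weighted mean across projects (weights
    default to equal).  Years not covered by every project are dropped with a
    warning.  The summary reports the weighted mean of per-project period means
    and OLS slopes, each with an unweighted standard error across projects.
    """
    if not series_by_project:
        raise ValueError("no projects to aggregate")
    ids = list(series_by_project)
    w = np.array([1.0 if weights is None else float(weights[i]) for i in ids])
    w = w / w.sum()
    common = None
    for ts in series_by_project.values():
        yrs = ts.valid().years
        common = yrs if common is None else np.intersect1d(common, yrs)
    if common.size == 0:
        raise ValueError("projects share no valid years")
    if any(common.size < ts.valid().years.size for ts in series_by_project.values()):
        warnings.warn("restricting portfolio aggregation to common years")
    mat = np.empty((len(ids), common.size))
    for row, i in enumerate(ids):
        ts = series_by_project[i]
        mat[row] = ts.values[np.searchsorted(ts.years, common)]
    first = series_by_project[ids[0]]
    agg = TimeSeries(
        common,
        w @ mat,
        variable=first.variable,
        units=first.units,
        label="portfolio",
    )
    means = mat.mean(axis=1)
    slopes = np.array(
        [_slope(common, mat[row]) for row in range(len(ids))]
        if common.size >= 2
        else [np.nan] * len(ids)
    )

    def _se(x: np.ndarray) -> float:
        return float(np.std(x, ddof=1) / np.sqrt(x.size)) if x.size >= 2 else float("nan")

    summary = {
        "n_projects": len(ids),
        "years": (int(common[0]), int(common[-1])),
        "mean": float(w @ means),
        "mean_se": _se(means),
        "slope": float(w @ slopes),
        "slope_se": _se(slopes),
    }
    return agg, summary
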