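"""Five-hypothesis additionality audit over a scene.

The audit asks whether the carbon credited to improved-forest-management
projects is additional, through five falsifiable comparisons against spatial
controls:

* H1 — pre-project carbon trend: additional management is consistent with a
  flat or declining business-as-usual trajectory; a significantly positive
  historical trend means the static baseline under-states business-as-usual.
* H2 — pre-project harvest: project lands harvested significantly more than
  controls suggests crediting forests already in post-harvest recovery;
  significantly less suggests low harvest risk.  Either cuts against
  additionality.
* H3 — pre-project species composition: enrichment of a low-timber-value
  species (e.g. tanoak) inside projects signals low harvest risk.
* H4 — post-initiation change in carbon accumulation: a significant increase
  in slope relative to both the pre-period and the controls supports
  additionality (Chow test).
* H5 — post-initiation change in harvest: a significant decrease relative to
  the pre-period and the controls supports additionality (paired t-test).

Each hypothesis yields a three-way verdict — consistent-with-additionality,
inconsistent, or inconclusive — mapped from signed effect direction and
significance at level alpha; a hypothesis with insufficient data is reported
inconclusive with a reason, never silently skipped.  The combination of the
five into one label is deliberately left to the reader: the report presents
them separately.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import controls as ctl
from . import geodata_io as gio
from . import trend_stats as tst
from .synthetic_landscape import PRIVATE_FOREST, SyntheticScene

__all__ = ["AuditConfig", "HypothesisReport", "run_audit", "owner_class_summary"]

CONSISTENT = "consistent-with-additionality"
INCONSISTENT = "inconsistent"
INCONCLUSIVE = "inconclusive"


@dataclass
class AuditConfig:
    pre_period: tuple[int, int] = (1986, 2012)
    carbon_data_end: int = 2017
    harvest_data_end: int = 2021
    control_methods: tuple[str, ...] = ("buffer", "region")
    start_year_cutoff: int = 2014          # before/after cohort
    alpha: float = 0.05
    buffer_width: float = 2000.0
    low_value_species: str = "tanoak"
    species_year: int = 2012
    min_post_carbon: int = 3
    min_post_harvest: int = 7
    percent_denominator: str = "period_mean"
    output_dir: str | None = None

    def validate(self, earliest_start: int) -> None:
        if self.pre_period[0] >= self.pre_period[1]:
            raise ValueError(f"pre_period {self.pre_period} is not a valid range")
        if self.pre_period[1] > earliest_start:
            raise ValueError(
                f"pre_period must end by the earliest project start year "
                f"({earliest_start}), got {self.pre_period}")
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")


@dataclass
class HypothesisReport:
    hypotheses: dict[str, dict]            # H1..H5 -> {verdict, comparison, ...}
    project_table: list[dict]              # one row per project
    portfolio: dict
    config: AuditConfig

    def verdicts(self) -> dict[str, str]:
        return {h: d["verdict"] for h, d in self.hypotheses.items()}

    def to_json(self, path: str) -> None:
        os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
        with open(path, "w") as fh:
            json.dump({"hypotheses": self.hypotheses,
                       "project_table": self.project_table,
                       "portfolio": self.portfolio,
                       "config": asdict(self.config)}, fh, indent=2, default=_jsonable)

    def project_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.project_table)

    def render_markdown(self) -> str:
        """Plain-text narrative; every number is taken verbatim from the stored results."""
        lines = ["# Additionality audit report", ""]
        for h in sorted(self.hypotheses):
            d = self.hypotheses[h]
            lines.append(f"## {h}: {d['title']}")
            lines.append(f"Verdict: **{d['verdict']}**")
            for k, v in d.get("comparison", {}).items():
                lines.append(f"- {k}: {_fmt(v)}")
            if d.get("reason"):
                lines.append(f"- note: {d['reason']}")
            lines.append("")
        p = self.portfolio
        lines.append("## Portfolio")
        for k, v in p.items():
            lines.append(f"- {k}: {_fmt(v)}")
        return "\n".join(lines)


def _fmt(v):
    if isinstance(v, float):
        return f"{v:.4g}"
    return v


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, tuple):
        return list(o)
    return str(o)


# ---------------------------------------------------------------------------
# verdict rules (the artifact's operationalization of the qualitative signs)


def _verdict_signed(effect: float, p: float, alpha: float,
                    positive_is: str) -> str:
    """Signed-significance rule: significant effects map by direction, else inconclusive."""
    if not np.isfinite(p):
        return INCONCLUSIVE
    if p < alpha:
        if effect > 0:
            return positive_is
        if effect < 0:
            return CONSISTENT if positive_is == INCONSISTENT else INCONSISTENT
    return INCONCLUSIVE


def _majority(verdicts: list[str]) -> str:
    if not verdicts:
        return INCONCLUSIVE
    n = len(verdicts)
    for v in (CONSISTENT, INCONSISTENT):
        if sum(x == v for x in verdicts) > n / 2:
            return v
    return INCONCLUSIVE


# ---------------------------------------------------------------------------
# the audit


def _scene_controls(scene: SyntheticScene, cfg: AuditConfig):
    """Build the requested control sets for every project."""
    private = scene.private_forest()
    proj_union = scene.all_project_mask()
    out: dict[str, dict[str, ctl.ControlSet]] = {m: {} for m in cfg.control_methods}
    spec = ctl.ControlSpec(buffer_width=cfg.buffer_width)
    for rec in scene.projects:
        if "buffer" in out:
            out["buffer"][rec.id] = ctl.buffer_control(
                rec, scene.observed_carbon, private, scene.projects, spec,
                region_mask=scene.region_mask(rec.region_label))
        if "region" in out:
            out["region"][rec.id] = ctl.region_control(
                rec.region_label, scene.region_mask(rec.region_label), private,
                proj_union, group_id=rec.id)
        if "matched" in out:
            cand = (ctl.coarse_fraction(private & ~proj_union, scene.coarse_factor) >= 0.5)
            rmask = ctl.coarse_fraction(scene.region_mask(rec.region_label),
                                        scene.coarse_factor) >= 0.5
            coarse_area = scene.observed_carbon.cell_area_ha * scene.coarse_factor ** 2
            out["matched"][rec.id] = ctl.matched_control(
                rec, scene.project_masks[rec.id], scene.covariates_coarse,
                cand & rmask, scene.coarse_factor, coarse_area)
    return out


def _control_series(scene: SyntheticScene, method: str, cs: ctl.ControlSet):
    """Carbon and harvest series for one control set (coarse-aware for matched)."""
    if method == "matched":
        f = scene.coarse_factor
        carbon = gio.block_aggregate(scene.observed_carbon, f)
        harv = gio.block_aggregate(scene.harvest, f)       # per-cell harvested fraction
        return gio.zonal_series(carbon, cs.mask), gio.zonal_series(harv, cs.mask)
    return (gio.zonal_series(scene.observed_carbon, cs.mask),
            gio.zonal_fraction(scene.harvest, cs.mask))


def run_audit(scene: SyntheticScene, config: AuditConfig | None = None) -> HypothesisReport:
    """Run the five-hypothesis audit on a scene and assemble the report.

    Deterministic: identical scene and configuration give identical report
    tables.  The carbon source is the observed (measurement-model) stack, as
    in an audit of real biomass maps.
    """
    cfg = config or AuditConfig()
    if not scene.projects:
        raise ValueError("scene has no projects to audit")
    cfg.validate(min(p.start_year for p in scene.projects))
    alpha = cfg.alpha
    primary = cfg.control_methods[0]

    control_sets = _scene_controls(scene, cfg)
    areas = {p.id: p.area_ha for p in scene.projects}

    proj_carbon: dict[str, tst.TimeSeries] = {}
    proj_harvest: dict[str, tst.TimeSeries] = {}
    ctrl_carbon: dict[str, dict[str, tst.TimeSeries]] = {m: {} for m in cfg.control_methods}
    ctrl_harvest: dict[str, dict[str, tst.TimeSeries]] = {m: {} for m in cfg.control_methods}
    for rec in scene.projects:
        mask = scene.project_masks[rec.id]
        proj_carbon[rec.id] = gio.zonal_series(scene.observed_carbon, mask)
        proj_harvest[rec.id] = gio.zonal_fraction(scene.harvest, mask)
        for m in cfg.control_methods:
            c, h = _control_series(scene, m, control_sets[m][rec.id])
            ctrl_carbon[m][rec.id] = c
            ctrl_harvest[m][rec.id] = h

    hypotheses: dict[str, dict] = {}
    rows: dict[str, dict] = {
        p.id: {"id": p.id, "start_year": p.start_year, "area_ha": p.area_ha,
               "owner_class": p.owner_class, "region": p.region_label}
        for p in scene.projects}

    # ---- H1: pre-project carbon trend -----------------------------------
    agg_proj, _ = tst.portfolio_aggregate(proj_carbon, areas)
    tr_proj = tst.trend(agg_proj, cfg.pre_period, cfg.percent_denominator)
    ctrl_rates = {}
    for m in cfg.control_methods:
        agg_c, _ = tst.portfolio_aggregate(ctrl_carbon[m], areas)
        ctrl_rates[m] = tst.trend(agg_c, cfg.pre_period, cfg.percent_denominator).percent_rate
    for pid, ts in proj_carbon.items():
        t = tst.trend(ts, cfg.pre_period, cfg.percent_denominator)
        rows[pid].update(pre_carbon_slope=t.slope, pre_carbon_percent_rate=t.percent_rate,
                         pre_carbon_mean=t.mean)
    hypotheses["H1"] = {
        "title": "pre-project carbon accumulation",
        "verdict": _verdict_signed(tr_proj.slope, tr_proj.p, alpha, INCONSISTENT),
        "comparison": {
            "project_percent_rate": tr_proj.percent_rate,
            "project_slope_tC_ha_yr": tr_proj.slope,
            "project_trend_p": tr_proj.p,
            "project_mean_stock": tr_proj.mean,
            "project_mean_stock_se": tr_proj.mean_se,
            **{f"{m}_control_percent_rate": v for m, v in ctrl_rates.items()},
        },
    }

    # ---- H2: pre-project harvest contrast --------------------------------
    h2_details, h2_verdicts = {}, []
    for m in cfg.control_methods:
        agg_p, _ = tst.portfolio_aggregate(
            {k: v.window(*cfg.pre_period) for k, v in proj_harvest.items()}, areas)
        agg_c, _ = tst.portfolio_aggregate(
            {k: v.window(*cfg.pre_period) for k, v in ctrl_harvest[m].items()}, areas)
        pr = tst.paired_across_years(agg_p, agg_c)
        h2_details[f"{m}_relative_difference_pct"] = pr.relative_difference
        h2_details[f"{m}_p"] = pr.p
        if m == primary:
            h2_verdicts.append(_verdict_signed(pr.mean_difference, pr.p, alpha, INCONSISTENT))
    for pid in proj_harvest:
        pre = proj_harvest[pid].window(*cfg.pre_period)
        rows[pid]["pre_harvest_rate"] = float(np.nanmean(pre.values))
        pr = tst.paired_across_years(pre, ctrl_harvest[primary][pid].window(*cfg.pre_period))
        rows[pid]["pre_harvest_vs_control_pct"] = pr.relative_difference
        rows[pid]["pre_harvest_vs_control_p"] = pr.p
    hypotheses["H2"] = {
        "title": "pre-project harvest vs controls",
        "verdict": h2_verdicts[0] if h2_verdicts else INCONCLUSIVE,
        "comparison": h2_details,
    }

    # ---- H3: species composition ----------------------------------------
    try:
        sp_year = cfg.species_year
        if sp_year not in scene.observed_carbon.years:
            sp_year = int(scene.observed_carbon.years[-1])
        carbon_layer = scene.observed_carbon.year(sp_year)
        species_carbon = {name: np.nan_to_num(frac, nan=0.0) * carbon_layer
                          for name, frac in scene.species_fractions.items()}
        pmasks = [scene.project_masks[p.id] for p in scene.projects]
        cmasks = [control_sets[primary][p.id].mask.mask for p in scene.projects]
        comp = tst.species_contrast(species_carbon, pmasks, cmasks, cfg.low_value_species)
        diff = comp.project_fraction - comp.control_fraction
        hypotheses["H3"] = {
            "title": f"pre-project composition of low-value species ({cfg.low_value_species})",
            "verdict": _verdict_signed(diff, comp.p, alpha, INCONSISTENT),
            "comparison": {
                "project_fraction_pct": comp.project_fraction,
                "control_fraction_pct": comp.control_fraction,
                "paired_t": comp.t, "p": comp.p, "n_projects": comp.n_projects,
            },
        }
    except (KeyError, ValueError) as err:
        hypotheses["H3"] = {"title": "pre-project species composition",
                            "verdict": INCONCLUSIVE, "comparison": {},
                            "reason": f"insufficient data: {err}"}

    # ---- H4 / H5: before/after change ------------------------------------
    cohort = [p for p in scene.projects if p.start_year <= cfg.start_year_cutoff]
    h4_verdicts, h5_verdicts = [], []
    excluded: dict[str, str] = {}
    for rec in cohort:
        pid = rec.id
        ends = {"carbon": cfg.carbon_data_end, "harvest": cfg.harvest_data_end}
        minp = {"carbon": cfg.min_post_carbon, "harvest": cfg.min_post_harvest}
        # H4 tests the project-minus-control carbon series, so shocks shared
        # with the control (regional weather/harvest-intensity years) cancel
        # and the Chow test sees only the project-specific slope change
        carbon_diff = tst.difference_series(proj_carbon[pid], ctrl_carbon[primary][pid])
        sources = {"carbon": carbon_diff, "harvest": proj_harvest[pid]}
        ba = tst.before_after(sources, rec.start_year, ends, min_post=minp)
        ba_c = tst.before_after({"harvest": ctrl_harvest[primary][pid]},
                                rec.start_year, ends, min_post=minp)
        ba_p = tst.before_after({"carbon": proj_carbon[pid]}, rec.start_year, ends,
                                min_post=minp)

        r = ba["carbon"]
        if r.excluded:
            excluded[pid] = r.excluded_reason
            rows[pid]["h4_verdict"] = INCONCLUSIVE
        else:
            ch = r.chow
            ch_p = ba_p["carbon"].chow
            d_rel = ch.slope_change                       # change relative to control
            rows[pid].update(carbon_slope_before=ch_p.slope_before,
                             carbon_slope_after=ch_p.slope_after,
                             carbon_slope_change=ch_p.slope_change,
                             carbon_slope_change_vs_control=d_rel,
                             chow_F=ch.F, chow_p=ch.p)
            if ch.p < alpha and d_rel > 0:
                v = CONSISTENT
            else:
                v = INCONSISTENT  # decrease, or no detectable increase over control
            rows[pid]["h4_verdict"] = v
            h4_verdicts.append(v)

        r = ba["harvest"]
        if r.excluded or ba_c["harvest"].excluded:
            excluded.setdefault(pid, r.excluded_reason or ba_c["harvest"].excluded_reason)
            rows[pid]["h5_verdict"] = INCONCLUSIVE
        else:
            pr, pr_c = r.paired, ba_c["harvest"].paired
            d_proj = pr.mean_difference          # after - before
            d_ctrl = pr_c.mean_difference if pr_c is not None else float("nan")
            rows[pid].update(harvest_change=d_proj, harvest_change_p=pr.p,
                             control_harvest_change=d_ctrl)
            if (np.isfinite(pr.p) and pr.p < alpha and d_proj < 0
                    and (not np.isfinite(d_ctrl) or d_proj < d_ctrl)):
                v = CONSISTENT
            elif np.isfinite(pr.p) and pr.p < alpha and d_proj > 0:
                v = INCONSISTENT
            else:
                v = INCONSISTENT  # harvest unchanged
            rows[pid]["h5_verdict"] = v
            h5_verdicts.append(v)

    for h, title, verdicts in (("H4", "post-project change in carbon accumulation", h4_verdicts),
                               ("H5", "post-project change in harvest", h5_verdicts)):
        d = {"title": title, "verdict": _majority(verdicts),
             "comparison": {"n_cohort": len(cohort),
                            "n_analyzable": len(verdicts),
                            "n_consistent": sum(v == CONSISTENT for v in verdicts),
                            "n_inconsistent": sum(v == INCONSISTENT for v in verdicts)}}
        if not cohort:
            d["verdict"] = INCONCLUSIVE
            d["reason"] = f"no projects started by {cfg.start_year_cutoff}"
        elif not verdicts:
            d["verdict"] = INCONCLUSIVE
            d["reason"] = "; ".join(f"{k}: {v}" for k, v in excluded.items())
        hypotheses[h] = d

    portfolio = {
        "n_projects": len(scene.projects),
        "total_area_ha": float(sum(p.area_ha for p in scene.projects)),
        "pre_period": cfg.pre_period,
        "primary_control": primary,
    }
    report = HypothesisReport(hypotheses, list(rows.values()), portfolio, cfg)
    if cfg.output_dir:
        os.makedirs(cfg.output_dir, exist_ok=True)
        report.to_json(os.path.join(cfg.output_dir, "report.json"))
        report.project_frame().to_csv(os.path.join(cfg.output_dir, "projects.csv"),
                                      index=False)
        with open(os.path.join(cfg.output_dir, "report.md"), "w") as fh:
            fh.write(report.render_markdown())
    return report


def owner_class_summary(report: HypothesisReport,
                        grouping: dict[str, str] | None = None) -> dict[str, dict]:
    """Aggregate before/after changes and pre-period harvest by landowner class.

    ``grouping`` optionally remaps project ids to group labels; by default
    projects group by their recorded owner class.  Each group reports its
    mean carbon-slope and harvest changes with one-sample paired-t
    significance across the group's projects, plus the mean pre-period
    harvest rate.
    """
    df = report.project_frame()
    if df.empty:
        raise ValueError("report has no project rows")
    if grouping is not None:
        df = df.assign(owner_class=[grouping.get(i) for i in df["id"]])
        if df["owner_class"].isna().any():
            missing = df.loc[df["owner_class"].isna(), "id"].tolist()
            raise ValueError(f"grouping missing labels for projects {missing}")
    out: dict[str, dict] = {}
    for label, grp in df.groupby("owner_class"):
        entry: dict = {"n_projects": int(len(grp))}
        if "pre_harvest_rate" in grp:
            entry["pre_harvest_rate"] = float(grp["pre_harvest_rate"].mean())
        for col, key in (("carbon_slope_change", "carbon_slope_change"),
                         ("harvest_change", "harvest_change")):
            if col in grp and grp[col].notna().sum() >= 2:
                vals = grp[col].dropna().to_numpy(dtype=float)
                pr = tst.paired_test(vals, np.zeros_like(vals))
                entry[key] = float(vals.mean())
                entry[f"{key}_p"] = pr.p
                entry[f"{key}_significant"] = bool(np.isfinite(pr.p) and pr.p < report.config.alpha)
            elif col in grp and grp[col].notna().any():
                entry[key] = float(grp[col].dropna().mean())
        out[label] = entry
    return out
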