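"""End-to-end pipeline: simulate → inject errors → audit → correct → analyse.

Produces the paired comparisons the audit-impact assessment needs:

* audited-subset discrepancy summaries (pre-audit vs audited, per variable /
  site / category),
* full-cohort pre-audit vs post-audit field comparisons,
* derived-variable discrepancy rates and inclusion-concordance counts,
* cumulative incidence of death and AIDS at a horizon per dataset version,
  with paired deltas,
* stratified Cox hazard-ratio contrast tables per version,
* an overlap-restricted sensitivity block (patients in both versions only).

Everything is deterministic given the master seed, which spawns per-stage
sub-seeds; every stage's artifacts are written before the next stage runs.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import audit_engine, derivation, error_injection, survival
from .cohort_model import DatasetVersion, default_registry, write_dataset
from .derivation import DerivationOptions, derive_analysis_table
from .error_injection import (
    CorrectionModel, ErrorModel, build_audit_dataset, build_post_audit,
    inject_errors, sample_audit_subset,
)
from .survival import CovariateTerm, cox_fit, hr_contrast, incidence_at, km_estimate
from .synthetic_cohort import CohortSimParams, study_scale_preset, simulate_truth

logger = logging.getLogger(__name__)

THREE_YEARS_DAYS = 1096


@dataclass
class RunConfig:
    """Full pipeline configuration; the master seed is mandatory."""

    seed: int
    sim: CohortSimParams = field(default_factory=CohortSimParams)
    error_model: ErrorModel = field(default_factory=ErrorModel)
    correction_model: CorrectionModel = field(default_factory=CorrectionModel)
    audit_per_site_target: int = 35
    audit_completion_rate: float = 0.79
    audited_fraction: float = 0.75
    derivation: DerivationOptions = field(default_factory=DerivationOptions)
    ties: str = "efron"
    competing_risks: bool = False
    horizon_days: int = THREE_YEARS_DAYS
    fit_cox: bool = True
    output_dir: str | None = None

    @classmethod
    def study_preset(cls, seed: int, scale: float = 1.0,
                     output_dir: str | None = None) -> "RunConfig":
        """Preset emulating the reference audit study's conditions, with a
        proportional size factor for small-mode runs."""
        return cls(seed=seed, sim=study_scale_preset(scale),
                   error_model=error_injection.study_error_preset(),
                   correction_model=error_injection.study_correction_preset(),
                   output_dir=output_dir)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "seed" not in raw:
            raise ValueError("run configuration must set a master seed")
        kw = dict(raw)
        if "sim" in kw:
            kw["sim"] = CohortSimParams(**kw["sim"])
        if "error_model" in kw:
            kw["error_model"] = ErrorModel(**kw["error_model"])
        if "correction_model" in kw:
            kw["correction_model"] = CorrectionModel(**kw["correction_model"])
        if "derivation" in kw:
            kw["derivation"] = DerivationOptions(**kw["derivation"])
        return cls(**kw)


@dataclass
class ImpactReport:
    """All paired estimates and summaries from one pipeline run."""

    config_seed: int
    cohort_flow: dict
    audited_summary: pd.DataFrame          # per-variable, pre-audit vs audited
    audited_overall_rate_pct: float
    audited_category_pct: dict
    full_summary: pd.DataFrame             # per-variable, pre vs post audit
    site_summary: pd.DataFrame
    derived_audited: pd.DataFrame
    derived_full: pd.DataFrame
    inclusion_audited: dict
    inclusion_full: dict
    incidence: pd.DataFrame                # endpoint x version incidence @ horizon
    deltas: pd.DataFrame
    hr_tables: pd.DataFrame | None
    sensitivity: dict | None
    notes: list = field(default_factory=list)


def _spawn_seeds(master: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(master)
    return [int(s.generate_state(1)[0] % (2 ** 31 - 1)) for s in ss.spawn(n)]


def _incidence_row(table: pd.DataFrame, endpoint: str, version: str,
                   horizon: int, site: str | None = None) -> dict:
    sub = table[table["included"]]
    if site is not None:
        sub = sub[sub["analysis_site"] == site]
    tcol, ecol = (("time_to_death_or_censor", "death_indicator") if endpoint == "death"
                  else ("time_to_aids_or_censor", "aids_indicator"))
    sub = sub[pd.to_numeric(sub[tcol], errors="coerce").notna()]
    if len(sub) == 0 or not sub[ecol].astype(bool).any():
        return {"endpoint": endpoint, "version": version, "analysis_site": site or "overall",
                "n": int(len(sub)), "incidence": 0.0 if len(sub) else np.nan,
                "ci_low": np.nan, "ci_high": np.nan, "extrapolated": False}
    s = km_estimate(sub[tcol].to_numpy(float), sub[ecol].astype(bool).to_numpy())
    inc, (lo, hi), ex = incidence_at(s, horizon)
    return {"endpoint": endpoint, "version": version, "analysis_site": site or "overall",
            "n": int(len(sub)), "incidence": inc, "ci_low": lo, "ci_high": hi,
            "extrapolated": ex}


def paired_estimates(inc: pd.DataFrame, version_a: str, version_b: str) -> pd.DataFrame:
    """Tabulate estimate, CI and difference per endpoint/site between two
    dataset versions. No significance testing is performed."""
    a = inc[inc["version"] == version_a]
    b = inc[inc["version"] == version_b]
    m = a.merge(b, on=["endpoint", "analysis_site"], suffixes=("_a", "_b"))
    if m.empty and not (a.empty and b.empty):
        raise ValueError(f"no common endpoint/site rows between "
                         f"{version_a!r} and {version_b!r}")
    m["delta"] = m["incidence_b"] - m["incidence_a"]
    m.insert(1, "versions", f"{version_b} - {version_a}")
    return m


def run_pipeline(config: RunConfig) -> ImpactReport:
    """Execute the full audit-impact pipeline deterministically."""
    seeds = _spawn_seeds(config.seed, 6)
    out_dir = Path(config.output_dir) if config.output_dir else None
    registry = default_registry()

    def persist(name: str, obj):
        if out_dir is None:
            return
        stage = out_dir / name
        if isinstance(obj, DatasetVersion):
            write_dataset(obj, stage)
        elif isinstance(obj, pd.DataFrame):
            stage.parent.mkdir(parents=True, exist_ok=True)
            df = obj.copy()
            df.to_csv(stage.with_suffix(".csv"), index=False, lineterminator="\n")

    # --- stage 1: truth -----------------------------------------------------
    sim = dataclasses.replace(config.sim, seed=seeds[0])
    truth, truth_log = simulate_truth(sim)
    persist("truth", truth)
    persist("truth_log", truth_log)

    # --- stage 2: pre-audit -------------------------------------------------
    emodel = dataclasses.replace(config.error_model, seed=seeds[1])
    pre, error_log = inject_errors(truth, emodel, registry)
    persist("pre_audit", pre)
    persist("error_log", error_log)

    # --- stage 3: audit sample + audited dataset ----------------------------
    selected, completed = sample_audit_subset(
        pre, config.audit_per_site_target, config.audit_completion_rate, seeds[2])
    uv_rates = {v: emodel.rate(v, "unverifiable")
                for v in [s.name for s in registry]}
    uv_rates["default"] = emodel.rate("default", "unverifiable")
    audited = build_audit_dataset(truth, pre, completed, uv_rates,
                                  config.audited_fraction, seeds[3], registry)
    persist("audited", audited)

    # --- stage 4: post-audit ------------------------------------------------
    cmodel = dataclasses.replace(config.correction_model, seed=seeds[4])
    post = build_post_audit(truth, pre, cmodel, pre.freeze_dates, error_log, registry)
    persist("post_audit", post)

    # --- stage 5: audit-engine summaries ------------------------------------
    comp_aud = audit_engine.audit_compare(
        pre, audited, registry, scope=set(completed),
        audited_field_mask=audited.audited_fields)
    aud_summary = audit_engine.summarize_discrepancies(comp_aud, ["variable"])
    overall_pct = audit_engine.overall_rate_percent(aud_summary)
    cat_pct = audit_engine.category_percentages(aud_summary)

    comp_full = audit_engine.audit_compare(pre, post, registry)
    full_summary = audit_engine.summarize_discrepancies(comp_full, ["variable"])
    site_summary = audit_engine.summarize_discrepancies(
        comp_full[comp_full["site_id"] != ""], ["site_id"])
    persist("audited_summary", aud_summary)
    persist("full_summary", full_summary)

    # --- stage 6: derivation ------------------------------------------------
    tables = {
        "pre_audit": derive_analysis_table(pre, config.derivation),
        "audited": derive_analysis_table(audited, config.derivation),
        "post_audit": derive_analysis_table(post, config.derivation),
    }
    for label, t in tables.items():
        persist(f"analysis_{label}", t)

    derived_aud = derivation.compare_derived(
        tables["pre_audit"][tables["pre_audit"]["patient_id"].isin(completed)],
        tables["audited"])
    derived_full = derivation.compare_derived(tables["pre_audit"], tables["post_audit"])
    incl_aud = derivation.inclusion_concordance(
        tables["pre_audit"][tables["pre_audit"]["patient_id"].isin(completed)],
        tables["audited"])
    incl_full = derivation.inclusion_concordance(tables["pre_audit"], tables["post_audit"])

    # --- stage 7: survival --------------------------------------------------
    inc_rows = []
    for label, t in tables.items():
        for endpoint in ("death", "aids"):
            inc_rows.append(_incidence_row(t, endpoint, label, config.horizon_days))
            for site in sorted(t.loc[t["included"], "analysis_site"].dropna().unique()):
                inc_rows.append(_incidence_row(t, endpoint, label,
                                               config.horizon_days, site))
    incidence = pd.DataFrame(inc_rows)
    deltas = pd.concat([
        paired_estimates(incidence, "pre_audit", "post_audit"),
        paired_estimates(incidence, "pre_audit", "audited"),
    ], ignore_index=True)

    hr_tables = None
    notes = ["cumulative incidence computed as 1 - KM per endpoint "
             "(cause-specific censoring of the competing event)"]
    if config.fit_cox:
        hr_rows = []
        contrast_spec = [
            ("age_at_art", [20, 30, 50, 60], 40),
            ("baseline_cd4", [50, 100, 200], 350),
            ("initiation_year", [2000, 2002, 2004, 2008, 2010, 2012], 2006),
            ("sex", ["male"], "female"),
            ("clinical_aids_at_baseline", ["yes"], "no"),
            ("ivdu", ["yes"], "no"),
            ("regimen_class", ["boosted_PI", "other"], "NNRTI"),
        ]
        for label in ("pre_audit", "post_audit"):
            for endpoint in ("death", "aids"):
                try:
                    fit = cox_fit(tables[label], endpoint, ties=config.ties)
                except (ValueError, KeyError) as exc:
                    notes.append(f"cox fit skipped for {label}/{endpoint}: {exc}")
                    continue
                for var, values, ref in contrast_spec:
                    for val in values:
                        try:
                            hr, (lo, hi) = hr_contrast(fit, var, val, ref)
                        except KeyError:
                            continue
                        hr_rows.append((endpoint, label, var, val, ref, hr, lo, hi,
                                        fit.converged, fit.n, fit.n_events))
        hr_tables = pd.DataFrame(hr_rows, columns=[
            "endpoint", "version", "variable", "value", "reference",
            "hr", "hr_low", "hr_high", "converged", "n", "n_events"])
        persist("hr_tables", hr_tables)

    # --- stage 8: sensitivity (overlap-restricted) --------------------------
    overlap = (set(tables["pre_audit"]["patient_id"])
               & set(tables["post_audit"]["patient_id"]))
    sens_rows = []
    for label in ("pre_audit", "post_audit"):
        t = tables[label][tables[label]["patient_id"].isin(overlap)]
        for endpoint in ("death", "aids"):
            sens_rows.append(_incidence_row(t, endpoint, label, config.horizon_days))
    sens_inc = pd.DataFrame(sens_rows)
    sensitivity = {
        "n_overlap": len(overlap),
        "incidence": sens_inc,
        "deltas": paired_estimates(sens_inc, "pre_audit", "post_audit"),
    }

    flow = {
        "truth_patients": int(truth.patients["patient_id"].nunique()),
        "pre_audit_patients": int(pre.patients["patient_id"].nunique()),
        "post_audit_patients": int(post.patients["patient_id"].nunique()),
        "patients_either": int(len(set(pre.patients["patient_id"])
                                   | set(post.patients["patient_id"]))),
        "patients_both": int(len(set(pre.patients["patient_id"])
                                 & set(post.patients["patient_id"]))),
        "newly_added": int(len(set(post.patients["patient_id"])
                               - set(pre.patients["patient_id"]))),
        "removed": int(len(set(pre.patients["patient_id"])
                           - set(post.patients["patient_id"]))),
        "selected": len(selected),
        "completed": len(completed),
        "included_pre": int(tables["pre_audit"]["included"].sum()),
        "included_post": int(tables["post_audit"]["included"].sum()),
        "included_audited": int(tables["audited"]["included"].sum()),
    }
    report = ImpactReport(
        config_seed=config.seed, cohort_flow=flow,
        audited_summary=aud_summary, audited_overall_rate_pct=overall_pct,
        audited_category_pct=cat_pct, full_summary=full_summary,
        site_summary=site_summary, derived_audited=derived_aud,
        derived_full=derived_full, inclusion_audited=incl_aud,
        inclusion_full=incl_full, incidence=incidence, deltas=deltas,
        hr_tables=hr_tables, sensitivity=sensitivity, notes=notes)
    if out_dir is not None:
        render_report(report, out_dir / "report")
    return report


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def render_report(r: ImpactReport, output_dir: str | Path) -> list[Path]:
    """Write delimited tables, a human-readable summary and figures.

    Idempotent: re-rendering the same report overwrites identical files.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    def table(name, df):
        p = out / f"{name}.csv"
        df.to_csv(p, index=False, lineterminator="\n")
        written.append(p)

    table("audited_summary", r.audited_summary)
    table("full_summary", r.full_summary)
    table("site_summary", r.site_summary)
    table("derived_audited", r.derived_audited)
    table("derived_full", r.derived_full)
    table("incidence", r.incidence)
    table("deltas", r.deltas)
    if r.hr_tables is not None:
        table("hr_contrasts", r.hr_tables)

    lines = ["# Audit impact summary", ""]
    lines.append(f"Master seed: {r.config_seed}")
    lines.append("")
    lines.append("## Cohort flow")
    for k, v in r.cohort_flow.items():
        lines.append(f"- {k}: {v}")
    lines.append("")
    lines.append("## Audited subset (pre-audit vs audited)")
    lines.append(f"- overall discrepancy rate: {r.audited_overall_rate_pct}%")
    cp = r.audited_category_pct
    lines.append(f"- of discrepancies: {cp['missing']:.0f}% missing, "
                 f"{cp['conflicting']:.0f}% conflicting, "
                 f"{cp['unverifiable']:.0f}% unverifiable")
    lines.append("")
    lines.append("## Incidence at horizon")
    ov = r.incidence[r.incidence["analysis_site"] == "overall"]
    for _, row in ov.iterrows():
        lines.append(f"- {row['endpoint']} / {row['version']}: "
                     f"{100 * row['incidence']:.1f}% "
                     f"(95% CI {100 * row['ci_low']:.1f}, {100 * row['ci_high']:.1f}) "
                     f"n={row['n']}")
    lines.append("")
    if r.sensitivity is not None and len(r.sensitivity.get("incidence", [])):
        lines.append("## Sensitivity (patients in both versions)")
        lines.append(f"- overlap n: {r.sensitivity['n_overlap']}")
    else:
        lines.append("## Sensitivity: not run")
    lines.append("")
    for n in r.notes:
        lines.append(f"note: {n}")
    p = out / "summary.md"
    p.write_text("\n".join(lines) + "\n")
    written.append(p)

    written += _render_figures(r, out)
    return written


def _render_figures(r: ImpactReport, out: Path) -> list[Path]:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    ov = r.incidence[r.incidence["analysis_site"] == "overall"]
    if len(ov):
        fig, ax = plt.subplots(figsize=(6, 4))
        for i, (_, row) in enumerate(ov.iterrows()):
            ax.errorbar(row["incidence"], i,
                        xerr=[[max(row["incidence"] - row["ci_low"], 0)],
                              [max(row["ci_high"] - row["incidence"], 0)]],
                        fmt="o", capsize=3)
        ax.set_yticks(range(len(ov)))
        ax.set_yticklabels([f"{a}/{b}" for a, b in zip(ov["endpoint"], ov["version"])])
        ax.set_xlabel("cumulative incidence at horizon")
        fig.tight_layout()
        p = out / "incidence_forest.png"
        fig.savefig(p, dpi=100)
        plt.close(fig)
        written.append(p)
    if r.hr_tables is not None and len(r.hr_tables):
        fig, ax = plt.subplots(figsize=(7, 8))
        sub = r.hr_tables[r.hr_tables["endpoint"] == "death"]
        labels = [f"{v}={x} ({ver})" for v, x, ver in
                  zip(sub["variable"], sub["value"], sub["version"])]
        ax.errorbar(sub["hr"], range(len(sub)),
                    xerr=[np.maximum(sub["hr"] - sub["hr_low"], 0),
                          np.maximum(sub["hr_high"] - sub["hr"], 0)],
                    fmt="o", capsize=2)
        ax.axvline(1.0, color="grey", lw=0.8)
        ax.set_yticks(range(len(sub)))
        ax.set_yticklabels(labels, fontsize=6)
        ax.set_xscale("log")
        ax.set_xlabel("hazard ratio (death)")
        fig.tight_layout()
        p = out / "hr_forest.png"
        fig.savefig(p, dpi=100)
        plt.close(fig)
        written.append(p)
    return written
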