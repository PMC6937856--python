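# sdvimpact

Simulation and impact assessment of **source data verification (SDV)
audits** in multi-site observational HIV cohorts.

Research networks that pool routinely collected clinical data audit a
random sample of patient records against original source documents, code
every field (A1 match, A2/A3 minor/major discrepancy, A4 present in source
but missing from the database, A5 unverifiable), feed findings back to
sites, and two years later receive a corrected data submission. This
package is for biostatisticians and data managers who want to quantify what
that whole process does to the numbers a cohort actually publishes: the
cumulative incidence of death and of AIDS-defining events after ART
initiation, and adjusted cause-specific hazard ratios.

Because real multi-site HIV data cannot be shared, the package simulates
the complete workflow with a known gold standard:

1. **synthetic_cohort** — a 9-site, 7-country cohort (patients, visits,
   CD4/viral-load labs, ART intervals, clinical events) whose death and
   AIDS times come from cause-specific proportional-hazards models with
   known coefficients;
2. **error_injection** — configurable field-level error processes
   (missingness, date/categorical/numeric corruption, systematic
   single-site effects) and record-level defects (dropped, duplicated,
   unregistered patients) produce the *pre-audit* version; a stratified
   audit sample and per-field source verification produce the *audited*
   version; a correction model plus freeze-date truncation produces the
   *post-audit* version — with a complete machine-readable error log;
3. **audit_engine** — aligns versions, assigns audit codes, and computes
   per-variable/site/category discrepancy rates
   (discrepant = missing ∪ conflicting ∪ unverifiable);
4. **derivation** — the per-patient analysis table (age at ART, nadir CD4,
   baseline clinical AIDS, regimen class, country-pooled site, times to
   death/AIDS or censoring) with the inclusion rule *adult ART initiators*;
5. **survival** — Kaplan–Meier Ŝ(t) with Greenwood variance and log–log
   95% CIs, incidence 1 − Ŝ(t) at a horizon, restricted cubic splines
   (4 knots at the 5/35/65/95th percentiles, linear beyond the boundary
   knots), and site-stratified Cox partial-likelihood fits
   (Newton–Raphson with step-halving, Efron ties) with spline-based hazard
   ratio contrasts such as HR(age 50 vs 40) = exp{(b(50) − b(40))ᵀβ̂};
6. **impact_report** — the paired pre/post and pre/audit comparisons,
   per-site breakdowns, and the overlap-restricted sensitivity analysis.

## Worked example

```python
from sdvimpact import RunConfig, run_pipeline

config = RunConfig.study_preset(seed=1, scale=0.05)   # 5% of full cohort scale
report = run_pipeline(config)

flow = report.cohort_flow
print(f"selected for audit: {flow['selected']}  completed: {flow['completed']}")
print(f"audited-subset discrepancy rate: {report.audited_overall_rate_pct}%")
cp = report.audited_category_pct
print(f"discrepancy mix: {cp['missing']:.0f}% missing, "
      f"{cp['conflicting']:.0f}% conflicting, {cp['unverifiable']:.0f}% unverifiable")
ov = report.incidence.query("analysis_site == 'overall'").set_index(["endpoint", "version"])
for endpoint in ("death", "aids"):
    pre, post = ov.loc[(endpoint, "pre_audit")], ov.loc[(endpoint, "post_audit")]
    print(f"3-year {endpoint}: pre-audit {100*pre['incidence']:.1f}% "
          f"(n={pre['n']})  post-audit {100*post['incidence']:.1f}% (n={post['n']})")
```

prints

```
selected for audit: 315  completed: 252
audited-subset discrepancy rate: 17.4%
discrepancy mix: 46% missing, 32% conflicting, 22% unverifiable
3-year death: pre-audit 7.3% (n=853)  post-audit 8.8% (n=1004)
3-year aids: pre-audit 11.8% (n=853)  post-audit 14.2% (n=1004)
```

Reading this: 35 records per site were sampled for audit (315 across nine
sites) and 252 were completed at the 79% completion rate. About 17% of the
audited fields were discrepant, driven mostly by values missing from the
database. The post-audit dataset — which recovered previously missing
patients and corrected logged errors before truncation at each site's
freeze date — yields *higher* 3-year incidence for both endpoints: missing
event and follow-up data suppress incidence, and the audit's corrections
restore it. `report.hr_tables` holds the paired adjusted hazard-ratio
contrasts (age 20/30/50/60 vs 40, nadir CD4 50/100/200 vs 350, initiation
year vs 2006, sex, IVDU, baseline AIDS, regimen class) per dataset version.

A YAML-driven CLI wraps the same pipeline:

```bash
sdv-impact run --config run.yaml
sdv-impact audit --left runs/pre_audit --right runs/post_audit --group-by variable
sdv-impact derive --input runs/post_audit --output analysis.csv
```

## Layout

```
src/sdvimpact/
  cohort_model.py      tables, variable registry, dataset versions, CSV/YAML I/O
  synthetic_cohort.py  truth simulator + TruthLog
  error_injection.py   error/correction models, audit sampling, version builders
  audit_engine.py      alignment, audit codes A1-A5, discrepancy summaries
  derivation.py        analysis table, inclusion criteria, derived-variable diffs
  survival.py          KM/Greenwood, RCS bases, stratified Cox, HR contrasts
  impact_report.py     end-to-end pipeline, paired estimates, report rendering
  cli.py               click front-end (sdv-impact)
docs/methods.md        models, assumptions, parameter defaults, design choices
tests/                 unit, property and end-to-end suites
```
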