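"""Error and correction processes turning truth into pre/audited/post versions.

Errors are injected independently per field (Bernoulli) — missingness or a
value corruption appropriate to the variable's kind — except for declared
systematic site effects, which are deterministic transforms applied to every
qualifying field at one site (e.g. a month/day swap for all dates of one
variable, mimicking a mistrained data-entry workflow). Record-level
operations (dropped or duplicated patients, unregistered patients, dropped
visits) model whole-chart defects.

Every injected operation is logged, one row per changed field or record, so
downstream audit summaries can be verified against the log exactly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort_model import (
    DatasetVersion, VariableSpec, default_registry, registry_for_version,
    variable_occurrences, MODE_LEVELS,
)

logger = logging.getLogger(__name__)

ERROR_LOG_COLUMNS = ["patient_id", "table", "variable", "occurrence",
                     "operation", "truth_value", "observed_value"]

#: levels used when corrupting categorical variables
CATEGORY_LEVELS = {
    "sex": ("male", "female"),
    "mode_of_infection": MODE_LEVELS,
    "aids_at_enrollment": ("yes", "no"),
    "death_indicator": ("yes", "no"),
    "clinical_aids": ("yes", "no"),
    "cdc_stage": ("A", "B", "C"),
    "who_stage": ("1", "2", "3", "4"),
}


@dataclass
class ErrorModel:
    """Configurable per-variable error process.

    ``rates`` maps variable name -> ``{make_missing, corrupt_value,
    unverifiable}`` probabilities; the ``"default"`` entry is the fallback.
    The ``unverifiable`` rates are consumed by :func:`build_audit_dataset`
    (source-document absence is a property of the audit, not of the stored
    value). ``date_corruption`` mixes day/month transposition, ±k-day shifts
    and year typos. ``systematic_site_effects`` is a list of
    ``(site, variable, transform)`` with transform one of
    ``month_day_swap``, ``shift:+K``/``shift:-K``, ``year:-1`` etc.
    """

    rates: dict = field(default_factory=lambda: {"default": {
        "make_missing": 0.0, "corrupt_value": 0.0, "unverifiable": 0.0}})
    date_corruption: dict = field(default_factory=lambda: {
        "transpose": 0.20, "shift": 0.60, "year_typo": 0.20})
    categorical_confusion: dict | None = None
    systematic_site_effects: list = field(default_factory=list)
    record_ops: dict = field(default_factory=lambda: {
        "drop_patient": 0.0, "duplicate_patient": 0.0,
        "add_unregistered_patient": 0.0, "drop_visit": 0.0})
    seed: int = 0

    def rate(self, variable: str, kind: str) -> float:
        base = self.rates.get("default", {})
        over = self.rates.get(variable, {})
        r = float(over.get(kind, base.get(kind, 0.0)))
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"rate {kind}={r} for {variable} outside [0,1]")
        return r

    def validate(self) -> None:
        for var, kinds in self.rates.items():
            for k in kinds:
                self.rate(var if var != "default" else "default", k)
        for op, r in self.record_ops.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"record op rate {op}={r} outside [0,1]")
        if self.categorical_confusion:
            for var, mat in self.categorical_confusion.items():
                for lvl, row in mat.items():
                    if abs(sum(row.values()) - 1.0) > 1e-9:
                        raise ValueError(
                            f"confusion row for {var}/{lvl} does not sum to 1")


@dataclass
class CorrectionModel:
    """Post-audit correction process.

    ``correction_probability`` — chance a logged pre-audit field error is
    fixed (scalar or per-variable dict with a ``"default"`` key);
    ``backlog_entry_probability`` — chance a truth child-row missing from
    pre-audit is entered; ``newly_added_patient_rate`` — chance a patient
    absent from the pre-audit submission is added; ``residual_error_rate`` —
    chance a correction itself lands on a wrong value;
    ``spurious_removal_probability`` — chance a duplicate or unregistered
    pre-audit record is removed.
    """

    correction_probability: float | dict = 0.7
    backlog_entry_probability: float = 0.6
    newly_added_patient_rate: float = 1.0
    residual_error_rate: float = 0.0
    spurious_removal_probability: float = 1.0
    seed: int = 0

    def corr_prob(self, variable: str) -> float:
        if isinstance(self.correction_probability, dict):
            d = self.correction_probability
            return float(d.get(variable, d.get("default", 0.0)))
        return float(self.correction_probability)

    def validate(self) -> None:
        probs = [self.backlog_entry_probability, self.newly_added_patient_rate,
                 self.residual_error_rate, self.spurious_removal_probability]
        if isinstance(self.correction_probability, dict):
            probs += list(self.correction_probability.values())
        else:
            probs.append(self.correction_probability)
        for p in probs:
            if not 0.0 <= float(p) <= 1.0:
                raise ValueError(f"correction probability {p} outside [0,1]")


# ---------------------------------------------------------------------------
# value corruption helpers
# ---------------------------------------------------------------------------

def _corrupt_date(ts: pd.Timestamp, rng: np.random.Generator, mix: dict) -> pd.Timestamp:
    kinds = list(mix)
    p = np.array([mix[k] for k in kinds], float)
    p = p / p.sum()
    kind = kinds[rng.choice(len(kinds), p=p)]
    if kind == "transpose" and ts.day <= 12 and ts.day != ts.month:
        return ts.replace(month=ts.day, day=ts.month)
    if kind == "year_typo":
        return ts + pd.DateOffset(years=int(rng.choice([-10, -1, 1, 10])))
    k = int(rng.integers(1, 61)) * int(rng.choice([-1, 1]))
    return ts + pd.Timedelta(days=k)


def _corrupt_value(value, spec: VariableSpec, rng: np.random.Generator,
                   model: ErrorModel, pool: list):
    if spec.value_kind == "date":
        return _corrupt_date(pd.Timestamp(value), rng, model.date_corruption)
    if spec.value_kind == "categorical":
        conf = (model.categorical_confusion or {}).get(spec.name)
        if conf and str(value) in conf:
            row = conf[str(value)]
            lvls = list(row)
            return lvls[rng.choice(len(lvls), p=np.array([row[l] for l in lvls]))]
        levels = [l for l in CATEGORY_LEVELS.get(spec.name, ()) if l != str(value)]
        if not levels:
            return str(value) + "-X"
        return levels[int(rng.integers(0, len(levels)))]
    if spec.value_kind == "numeric":
        v = float(value)
        choice = int(rng.integers(0, 3))
        if choice == 0:
            new = v * 10.0
        elif choice == 1:
            new = max(round(v / 10.0), 0.0)
        else:
            new = max(v + float(rng.integers(5, 51)) * rng.choice([-1, 1]), 0.0)
        if new == v:
            new = v + 7.0
        return new
    # string
    others = [x for x in pool if x != value]
    if others:
        return others[int(rng.integers(0, len(others)))]
    return str(value) + "-X"


def _apply_systematic(value, transform: str):
    if transform == "month_day_swap":
        ts = pd.Timestamp(value)
        if ts.day <= 12 and ts.day != ts.month:
            return ts.replace(month=ts.day, day=ts.month)
        return value
    if transform.startswith("shift:"):
        return pd.Timestamp(value) + pd.Timedelta(days=int(transform.split(":")[1]))
    if transform.startswith("year:"):
        return pd.Timestamp(value) + pd.DateOffset(years=int(transform.split(":")[1]))
    raise ValueError(f"unknown systematic transform {transform!r}")


def _fmt(v) -> str:
    if v is None or (isinstance(v, float) and math.isnan(v)) or v is pd.NaT or v is pd.NA:
        return ""
    if isinstance(v, pd.Timestamp):
        return v.strftime("%Y-%m-%d")
    return str(v)


# ---------------------------------------------------------------------------
# inject_errors
# ---------------------------------------------------------------------------

def inject_errors(truth: DatasetVersion, model: ErrorModel,
                  registry: list[VariableSpec] | None = None
                  ) -> tuple[DatasetVersion, pd.DataFrame]:
    """Produce the pre-audit dataset version and its complete error log.

    Deterministic given ``model.seed``. The returned version differs from
    truth exactly where the log says: record ops first (drops, additions),
    then deterministic systematic site effects, then independent per-field
    missingness/corruption, then patient duplication.
    """
    model.validate()
    registry = registry if registry is not None else default_registry()
    rng = np.random.default_rng(model.seed)
    ds = truth.copy()
    ds.label = "pre_audit"
    log: list[tuple] = []

    site_of = dict(zip(ds.patients["patient_id"], ds.patients["site_id"]))

    # ---- record ops: drops ------------------------------------------------
    p_drop = model.record_ops.get("drop_patient", 0.0)
    if p_drop > 0:
        pids = ds.patients["patient_id"].to_numpy()
        dropped = pids[rng.random(len(pids)) < p_drop]
        drop_set = set(dropped)
        ds.patients = ds.patients[~ds.patients["patient_id"].isin(drop_set)].reset_index(drop=True)
        for name in ("visits", "labs", "art", "events"):
            t = ds.tables[name]
            setattr(ds, name, t[~t["patient_id"].isin(drop_set)].reset_index(drop=True))
        for pid in dropped:
            log.append((pid, "patient", "*", pid, "drop_patient", "record", ""))

    p_dropv = model.record_ops.get("drop_visit", 0.0)
    if p_dropv > 0:
        v = ds.visits
        mask = rng.random(len(v)) < p_dropv
        for _, r in v[mask].iterrows():
            log.append((r["patient_id"], "visit", "*", r["row_uid"], "drop_visit",
                        "record", ""))
        ds.visits = v[~mask].reset_index(drop=True)

    # ---- record ops: additions -------------------------------------------
    p_add = model.record_ops.get("add_unregistered_patient", 0.0)
    if p_add > 0 and len(ds.patients):
        n_add = int(rng.binomial(len(ds.patients), p_add))
        sites = sorted(set(ds.patients["site_id"]))
        ctry = dict(zip(ds.patients["site_id"], ds.patients["country"]))
        add_rows = []
        for j in range(n_add):
            site = sites[int(rng.integers(0, len(sites)))]
            fd = truth.freeze_dates.get(site, pd.Timestamp("2014-06-30"))
            enroll = fd - pd.Timedelta(days=int(rng.integers(90, 3650)))
            birth = enroll - pd.Timedelta(days=int(rng.uniform(20, 60) * 365.25))
            pid = f"{site}-X{j:04d}"
            add_rows.append({
                "patient_id": pid, "site_id": site, "country": ctry[site],
                "birth_date": birth, "sex": "male" if rng.random() < 0.5 else "female",
                "mode_of_infection": "unknown", "enrollment_date": enroll,
                "aids_at_enrollment": "no", "cdc_stage": "A", "who_stage": "1",
                "clinical_aids": None, "aids_diagnosis_date": None,
                "death_indicator": "no", "death_date": None, "death_cause": None,
            })
            log.append((pid, "patient", "*", pid, "add_unregistered_patient", "", "record"))
        if add_rows:
            add_df = pd.DataFrame(add_rows)
            from .cohort_model import DATE_COLUMNS
            for c in DATE_COLUMNS["patients"]:
                add_df[c] = pd.to_datetime(add_df[c])
            add_df = add_df.astype({c: ds.patients[c].dtype for c in add_df.columns
                                    if add_df[c].isna().all()})
            ds.patients = pd.concat([ds.patients, add_df], ignore_index=True)

    # ---- systematic site effects ------------------------------------------
    reg_by_name = {s.name: s for s in registry}
    known_sites = set(truth.patients["site_id"])
    for site, var, transform in model.systematic_site_effects:
        if site not in known_sites:
            raise ValueError(f"systematic effect references unknown site {site!r}")
        if var not in reg_by_name:
            raise ValueError(f"systematic effect references unknown variable {var!r}")
        spec = reg_by_name[var]
        t = ds.table(spec.table)
        in_site = t["patient_id"].map(site_of).eq(site).to_numpy()
        if spec.row_filter is not None:
            col, val = spec.row_filter
            in_site &= (t[col] == val).to_numpy()
        idx = t.index[in_site & t[spec.column].notna().to_numpy()]
        for i in idx:
            old = t.at[i, spec.column]
            new = _apply_systematic(old, transform)
            if _fmt(new) != _fmt(old):
                t.at[i, spec.column] = new
                occ = t.at[i, "row_uid"] if spec.table != "patient" else t.at[i, "patient_id"]
                log.append((t.at[i, "patient_id"], spec.table, var, occ,
                            "systematic", _fmt(old), _fmt(new)))

    # ---- independent field errors -----------------------------------------
    pre_vars = registry_for_version(registry, "pre_audit")
    for spec in pre_vars:
        p_miss = model.rate(spec.name, "make_missing")
        p_corr = model.rate(spec.name, "corrupt_value")
        if p_miss + p_corr <= 0:
            continue
        t = ds.table(spec.table)
        mask = np.ones(len(t), bool)
        if spec.row_filter is not None:
            col, val = spec.row_filter
            mask = (t[col] == val).to_numpy()
        mask &= t[spec.column].notna().to_numpy()
        idx = t.index[mask]
        if len(idx) == 0:
            continue
        u = rng.random(len(idx))
        pool = sorted({_fmt(x) for x in t.loc[idx, spec.column]}) if spec.value_kind == "string" else []
        if spec.column in ("birth_date", "enrollment_date", "death_date",
                           "aids_diagnosis_date", "visit_date", "lab_date",
                           "start_date", "end_date", "event_date"):
            t[spec.column] = pd.to_datetime(t[spec.column])
        for i, ui in zip(idx, u):
            old = t.at[i, spec.column]
            occ = t.at[i, "row_uid"] if spec.table != "patient" else t.at[i, "patient_id"]
            pid = t.at[i, "patient_id"]
            if ui < p_miss:
                t.at[i, spec.column] = (pd.NaT if spec.value_kind == "date"
                                        else (np.nan if spec.value_kind == "numeric" else None))
                log.append((pid, spec.table, spec.name, occ, "make_missing",
                            _fmt(old), ""))
            elif ui < p_miss + p_corr:
                new = _corrupt_value(old, spec, rng, model, pool)
                t.at[i, spec.column] = new
                log.append((pid, spec.table, spec.name, occ, "corrupt_value",
                            _fmt(old), _fmt(new)))

    # ---- duplication (last, so field ops stay unambiguous) -----------------
    p_dup = model.record_ops.get("duplicate_patient", 0.0)
    if p_dup > 0 and len(ds.patients):
        pmask = rng.random(len(ds.patients)) < p_dup
        dups = ds.patients[pmask]
        for _, r in dups.iterrows():
            log.append((r["patient_id"], "patient", "*", r["patient_id"],
                        "duplicate_patient", "record", "record"))
        ds.patients = pd.concat([ds.patients, dups], ignore_index=True)

    # pre-audit submissions do not carry the post-audit replacement variables
    ds.patients["clinical_aids"] = None
    ds.patients["aids_diagnosis_date"] = pd.NaT

    error_log = pd.DataFrame(log, columns=ERROR_LOG_COLUMNS)
    return ds, error_log


# ---------------------------------------------------------------------------
# audit sampling and the audited dataset
# ---------------------------------------------------------------------------

def sample_audit_subset(pre_audit: DatasetVersion, per_site_target: int,
                        completion_rate: float, seed: int = 0
                        ) -> tuple[list[str], list[str]]:
    """Stratified random sampling of records to audit, by site, without
    replacement, plus the random subset the auditors actually completed.
    """
    if per_site_target < 1:
        raise ValueError("per_site_target must be >= 1")
    if not 0.0 <= completion_rate <= 1.0:
        raise ValueError("completion_rate must be in [0,1]")
    rng = np.random.default_rng(seed)
    selected: list[str] = []
    p = pre_audit.patients.drop_duplicates("patient_id")
    for site, grp in p.groupby("site_id", sort=True):
        ids = sorted(grp["patient_id"])
        if per_site_target >= len(ids):
            logger.warning("site %s has %d records <= target %d; selecting all",
                           site, len(ids), per_site_target)
            selected.extend(ids)
        else:
            pick = rng.choice(len(ids), size=per_site_target, replace=False)
            selected.extend(ids[i] for i in sorted(pick))
    completed = [pid for pid in selected if rng.random() < completion_rate]
    return selected, completed


def build_audit_dataset(truth: DatasetVersion, pre_audit: DatasetVersion,
                        completed_ids: list[str],
                        unverifiable_rates: float | dict = 0.0,
                        audited_fraction: float = 1.0, seed: int = 0,
                        registry: list[VariableSpec] | None = None) -> DatasetVersion:
    """Build the audited dataset version for the completed records.

    For each field of each completed patient, independently: skipped with
    probability ``1 − audited_fraction`` (the pre-audit value is retained and
    the field is excluded from audit denominators), marked unverifiable with
    the per-variable rate (source document absent; pre-audit value retained),
    or source-verified (set to the truth value). Child rows present in the
    source documents but absent from the database are recovered where their
    fields are audited.
    """
    if not 0.0 <= audited_fraction <= 1.0:
        raise ValueError("audited_fraction must be in [0,1]")
    registry = registry if registry is not None else default_registry()
    rng = np.random.default_rng(seed)
    completed = set(completed_ids)
    missing_ids = completed - set(pre_audit.patients["patient_id"])
    if missing_ids - set(truth.patients["patient_id"]):
        unknown = sorted(missing_ids - set(truth.patients["patient_id"]))
        raise ValueError(f"completed ids not found in any version: {unknown}")

    def uv_rate(var: str) -> float:
        if isinstance(unverifiable_rates, dict):
            return float(unverifiable_rates.get(var, unverifiable_rates.get("default", 0.0)))
        return float(unverifiable_rates)

    aud_vars = registry_for_version(registry, "audited")
    by_table: dict[str, list[VariableSpec]] = {}
    for s in aud_vars:
        by_table.setdefault(s.table, []).append(s)

    audited_fields: set = set()
    marks: set = set()
    out_tables: dict[str, pd.DataFrame] = {}

    for table_name, frame_name in (("patient", "patients"), ("visit", "visits"),
                                   ("lab", "labs"), ("art", "art"), ("event", "events")):
        T = truth.tables[frame_name]
        P = pre_audit.tables[frame_name]
        T = T[T["patient_id"].isin(completed)]
        P = P[P["patient_id"].isin(completed)]
        key = "patient_id" if table_name == "patient" else "row_uid"
        P = P.drop_duplicates(key, keep="first")
        t_idx = {r[key]: i for i, r in T.iterrows()}
        p_idx = {r[key]: i for i, r in P.iterrows()}
        keys = list(dict.fromkeys(list(t_idx) + [k for k in p_idx if k not in t_idx]))
        specs = by_table.get(table_name, [])
        rows = []
        for k in keys:
            in_truth = k in t_idx
            base = (T.loc[t_idx[k]] if in_truth else P.loc[p_idx[k]]).copy()
            pre_row = P.loc[p_idx[k]] if k in p_idx else None
            pid = base["patient_id"]
            any_audited = False
            for spec in specs:
                if spec.row_filter is not None:
                    col, val = spec.row_filter
                    if base[col] != val:
                        continue
                occ = k
                if not in_truth:
                    # no source document for this record at all
                    marks.add((pid, spec.name, occ))
                    audited_fields.add((pid, spec.name, occ))
                    any_audited = True
                    continue
                u = rng.random()
                if u >= audited_fraction:
                    # skipped: retain the database value, outside denominators
                    base[spec.column] = (pre_row[spec.column] if pre_row is not None
                                         else (pd.NaT if spec.value_kind == "date" else None))
                    continue
                any_audited = True
                audited_fields.add((pid, spec.name, occ))
                if rng.random() < uv_rate(spec.name):
                    marks.add((pid, spec.name, occ))
                    base[spec.column] = (pre_row[spec.column] if pre_row is not None
                                         else (pd.NaT if spec.value_kind == "date" else None))
                # else: keep the truth value already in `base`
            if table_name == "patient" or pre_row is not None or any_audited:
                rows.append(base)
        out = (pd.DataFrame(rows).reset_index(drop=True) if rows
               else truth.tables[frame_name].iloc[0:0].copy())
        out_tables[frame_name] = out

    ds = DatasetVersion(label="audited", freeze_dates=dict(pre_audit.freeze_dates),
                        unverifiable_marks=marks, audited_fields=audited_fields,
                        **out_tables)
    # audited submissions carry the pre-audit variable set
    ds.patients["clinical_aids"] = None
    ds.patients["aids_diagnosis_date"] = pd.NaT
    return ds


# ---------------------------------------------------------------------------
# post-audit construction
# ---------------------------------------------------------------------------

def build_post_audit(truth: DatasetVersion, pre_audit: DatasetVersion,
                     model: CorrectionModel, freeze_dates: dict | None = None,
                     error_log: pd.DataFrame | None = None,
                     registry: list[VariableSpec] | None = None) -> DatasetVersion:
    """Build the post-audit dataset version.

    Logged pre-audit errors are corrected toward truth according to the
    CorrectionModel; previously missing records and patients are entered;
    duplicate/unregistered records are removed; and every data point after
    the site-specific freeze date is truncated. Newly added patients are
    only those enrolled before their site's freeze date.
    """
    model.validate()
    registry = registry if registry is not None else default_registry()
    freeze = {s: pd.Timestamp(d) for s, d in
              (freeze_dates or pre_audit.freeze_dates or truth.freeze_dates).items()}
    for site in set(truth.patients["site_id"]):
        if site not in freeze:
            raise ValueError(f"freeze date missing for site {site!r}")
    rng = np.random.default_rng(model.seed)
    ds = pre_audit.copy()
    ds.label = "post_audit"
    log = error_log if error_log is not None else pd.DataFrame(columns=ERROR_LOG_COLUMNS)
    reg_by_name = {s.name: s for s in registry}

    # remove duplicates / unregistered patients
    dup_ids = set(log.loc[log["operation"] == "duplicate_patient", "patient_id"])
    for pid in sorted(dup_ids):
        if rng.random() < model.spurious_removal_probability:
            hits = ds.patients.index[ds.patients["patient_id"] == pid]
            if len(hits) > 1:
                ds.patients = ds.patients.drop(hits[1:])
    unreg_ids = sorted(set(log.loc[log["operation"] == "add_unregistered_patient", "patient_id"]))
    to_remove = {pid for pid in unreg_ids
                 if rng.random() < model.spurious_removal_probability}
    if to_remove:
        ds.patients = ds.patients[~ds.patients["patient_id"].isin(to_remove)]
    ds.patients = ds.patients.reset_index(drop=True)

    # enter patients that never made it into the pre-audit submission
    dropped = log[log["operation"] == "drop_patient"]["patient_id"].tolist()
    readd = [pid for pid in dropped if rng.random() < model.newly_added_patient_rate]
    if readd:
        site_of_truth = dict(zip(truth.patients["patient_id"], truth.patients["site_id"]))
        readd = [pid for pid in readd
                 if pd.Timestamp(truth.patients.set_index("patient_id")
                                 .at[pid, "enrollment_date"]) <= freeze[site_of_truth[pid]]]
        add_set = set(readd)
        ds.patients = pd.concat(
            [ds.patients, truth.patients[truth.patients["patient_id"].isin(add_set)]],
            ignore_index=True)
        for name in ("visits", "labs", "art", "events"):
            t = truth.tables[name]
            setattr(ds, name, pd.concat(
                [ds.tables[name], t[t["patient_id"].isin(add_set)]], ignore_index=True))

    # enter backlog child rows (dropped visits)
    dv = log[log["operation"] == "drop_visit"]
    if len(dv):
        uids = [r for r in dv["occurrence"]
                if rng.random() < model.backlog_entry_probability]
        rows = truth.visits[truth.visits["row_uid"].isin(set(uids))
                            & truth.visits["patient_id"].isin(set(ds.patients["patient_id"]))]
        ds.visits = pd.concat([ds.visits, rows], ignore_index=True)

    # correct field-level errors toward truth
    field_log = log[log["operation"].isin(["make_missing", "corrupt_value", "systematic"])]
    truth_tables = {n: truth.tables[n].set_index(
        "patient_id" if n == "patients" else "row_uid") for n in truth.tables}
    present = set(ds.patients["patient_id"])
    frame_of = {"patient": "patients", "visit": "visits", "lab": "labs",
                "art": "art", "event": "events"}
    row_of: dict[str, dict] = {}
    for fname in frame_of.values():
        t = ds.tables[fname]
        key_col = "patient_id" if fname == "patients" else "row_uid"
        m: dict = {}
        for i, k in zip(t.index, t[key_col]):
            if k not in m:  # first occurrence wins (duplicates)
                m[k] = i
        row_of[fname] = m
    for _, e in field_log.iterrows():
        var = e["variable"]
        spec = reg_by_name.get(var)
        if spec is None or e["patient_id"] not in present:
            continue
        if rng.random() >= model.corr_prob(var):
            continue
        fname = frame_of[spec.table]
        t = ds.tables[fname]
        hit = row_of[fname].get(e["occurrence"])
        if hit is None:
            continue
        ttab = truth_tables[fname]
        if e["occurrence"] not in ttab.index:
            continue
        tv = ttab.at[e["occurrence"], spec.column]
        if rng.random() < model.residual_error_rate:
            if spec.value_kind == "date" and pd.notna(tv):
                tv = pd.Timestamp(tv) + pd.Timedelta(days=45)
            elif spec.value_kind == "numeric" and pd.notna(tv):
                tv = float(tv) + 10.0
            else:
                continue  # correction failed; pre-audit value stands
        t.at[hit, spec.column] = tv

    # post-audit replacement variables, re-collected from source
    tp = truth.patients.set_index("patient_id")
    in_truth = ds.patients["patient_id"].isin(tp.index)
    ds.patients.loc[in_truth, "clinical_aids"] = (
        ds.patients.loc[in_truth, "patient_id"].map(tp["clinical_aids"]))
    ds.patients.loc[in_truth, "aids_diagnosis_date"] = (
        ds.patients.loc[in_truth, "patient_id"].map(tp["aids_diagnosis_date"]))
    ds.patients["cdc_stage"] = None
    ds.patients["who_stage"] = None

    truncate_at_freeze(ds, freeze)
    ds.freeze_dates = freeze
    for name in ds.tables:
        setattr(ds, name, ds.tables[name].reset_index(drop=True))
    return ds


def study_error_preset(seed: int = 0) -> ErrorModel:
    """Error model whose expected discrepancy profile matches the audited
    network: overall audited-subset discrepancy rate ≈ 17%, with the
    discrepancy mix ≈ 43% missing / 34% conflicting / 23% unverifiable, low
    error rates for enrollment demographics (sex ≈ 1%, birth date ≈ 4%),
    high rates for clinical event dates (≈ 49%) and ART end dates (≈ 31%),
    and ≈ 14% of truth records absent from the pre-audit submission.
    """
    d = {"make_missing": 0.072, "corrupt_value": 0.057, "unverifiable": 0.040}
    rates = {
        "default": d,
        "sex": {"make_missing": 0.002, "corrupt_value": 0.006, "unverifiable": 0.004},
        "birth_date": {"make_missing": 0.005, "corrupt_value": 0.030, "unverifiable": 0.005},
        "enrollment_date": {"make_missing": 0.005, "corrupt_value": 0.020, "unverifiable": 0.010},
        "mode_of_infection": {"make_missing": 0.040, "corrupt_value": 0.080, "unverifiable": 0.020},
        "death_indicator": {"make_missing": 0.010, "corrupt_value": 0.030, "unverifiable": 0.010},
        "death_date": {"make_missing": 0.080, "corrupt_value": 0.120, "unverifiable": 0.050},
        "art_end_date": {"make_missing": 0.160, "corrupt_value": 0.100, "unverifiable": 0.050},
        "art_start_date": {"make_missing": 0.040, "corrupt_value": 0.040, "unverifiable": 0.020},
        "event_date": {"make_missing": 0.250, "corrupt_value": 0.150, "unverifiable": 0.090},
        "event_code": {"make_missing": 0.150, "corrupt_value": 0.100, "unverifiable": 0.050},
        "aids_at_enrollment": {"make_missing": 0.100, "corrupt_value": 0.060, "unverifiable": 0.040},
    }
    return ErrorModel(rates=rates, record_ops={
        "drop_patient": 0.14, "duplicate_patient": 0.008,
        "add_unregistered_patient": 0.008, "drop_visit": 0.030}, seed=seed)


def study_correction_preset(seed: int = 0) -> CorrectionModel:
    """Correction model emulating the post-audit submission round: most
    logged errors fixed, backlog visit entry, near-complete entry of
    previously missing patients, removal of duplicate/unlocatable records.
    """
    return CorrectionModel(correction_probability=0.70,
                           backlog_entry_probability=0.60,
                           newly_added_patient_rate=0.95,
                           residual_error_rate=0.02,
                           spurious_removal_probability=0.90, seed=seed)


def truncate_at_freeze(ds: DatasetVersion, freeze: dict[str, pd.Timestamp]) -> None:
    """Remove (in place) every data point dated after its site's freeze date."""
    site_of = dict(zip(ds.patients["patient_id"], ds.patients["site_id"]))

    def fdate(pids: pd.Series) -> pd.Series:
        return pd.to_datetime(pids.map(lambda p: freeze.get(site_of.get(p))))

    p = ds.patients
    late_enroll = (pd.to_datetime(p["enrollment_date"])
                   > fdate(p["patient_id"])).fillna(False)
    ds.patients = p[~late_enroll].copy()
    p = ds.patients
    late_death = pd.to_datetime(p["death_date"]) > fdate(p["patient_id"])
    p.loc[late_death.fillna(False), ["death_indicator", "death_date", "death_cause"]] = \
        ["no", pd.NaT, None]
    late_dx = pd.to_datetime(p["aids_diagnosis_date"]) > fdate(p["patient_id"])
    p.loc[late_dx.fillna(False), "aids_diagnosis_date"] = pd.NaT

    for name, col in (("visits", "visit_date"), ("labs", "lab_date"),
                      ("events", "event_date")):
        t = ds.tables[name]
        keep = ~(pd.to_datetime(t[col]) > fdate(t["patient_id"])).fillna(False)
        setattr(ds, name, t[keep].reset_index(drop=True))
    a = ds.art
    a = a[~(pd.to_datetime(a["start_date"]) > fdate(a["patient_id"])).fillna(False)].copy()
    late_end = pd.to_datetime(a["end_date"]) > fdate(a["patient_id"])
    a.loc[late_end.fillna(False), "end_date"] = pd.NaT
    ds.art = a.reset_index(drop=True)
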