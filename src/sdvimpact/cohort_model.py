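"""Cohort data model: tables, variable registry, dataset versions, delimited-text I/O.

The cohort follows a HICDEP-like layout with five tables (patients, visits,
labs, ART intervals, clinical events). A *dataset version* is a complete
snapshot of those tables — one of ``truth``, ``pre_audit``, ``audited`` or
``post_audit`` — together with per-site freeze dates and, for the audited
version, the bookkeeping of which fields were source-verified and which could
not be verified.

Dates are exchanged as ISO 8601 strings on disk and held as pandas
``datetime64`` in memory; all date arithmetic is in whole days.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

VERSION_LABELS = ("truth", "pre_audit", "audited", "post_audit")

TABLE_NAMES = ("patients", "visits", "labs", "art", "events")

#: columns of each table as written to disk (in order)
TABLE_COLUMNS: dict[str, list[str]] = {
    "patients": [
        "patient_id", "site_id", "country", "birth_date", "sex",
        "mode_of_infection", "enrollment_date", "aids_at_enrollment",
        "cdc_stage", "who_stage", "clinical_aids", "aids_diagnosis_date",
        "death_indicator", "death_date", "death_cause",
    ],
    "visits": ["row_uid", "patient_id", "visit_date", "weight"],
    "labs": ["row_uid", "patient_id", "lab_type", "lab_date", "value"],
    "art": ["row_uid", "patient_id", "regimen", "start_date", "end_date"],
    "events": ["row_uid", "patient_id", "event_code", "event_date"],
}

DATE_COLUMNS: dict[str, list[str]] = {
    "patients": ["birth_date", "enrollment_date", "aids_diagnosis_date", "death_date"],
    "visits": ["visit_date"],
    "labs": ["lab_date"],
    "art": ["start_date", "end_date"],
    "events": ["event_date"],
}

SEX_LEVELS = ("male", "female")
MODE_LEVELS = ("heterosexual", "MSM", "IVDU", "other", "unknown")
YESNO_LEVELS = ("yes", "no")
LAB_TYPES = ("CD4", "HIV_RNA")


class DatasetError(Exception):
    """Fatal defect in a dataset directory or registry."""


# ---------------------------------------------------------------------------
# Variable registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariableSpec:
    """Registry entry for one primary variable.

    Parameters
    ----------
    name : str
        Analysis name of the variable (unique in the registry).
    table : str
        One of ``patient, visit, lab, art, event``.
    column : str
        Column of the physical table holding the value.
    value_kind : str
        One of ``date, categorical, numeric, string``.
    comparison : str
        Comparison policy: ``exact``, ``date_tolerance`` or ``case_insensitive``.
    versions : frozenset[str]
        Dataset versions (besides truth) in which the variable is collected.
    row_filter : tuple
        Optional (column, value) restriction selecting the relevant table rows
        (used for lab variables, e.g. ``("lab_type", "CD4")``).
    """

    name: str
    table: str
    column: str
    value_kind: str
    comparison: str
    versions: frozenset
    row_filter: tuple | None = None


ALL_VERSIONS = frozenset({"pre_audit", "audited", "post_audit"})
PRE_AND_AUDITED = frozenset({"pre_audit", "audited"})
POST_ONLY = frozenset({"post_audit"})


def default_registry() -> list[VariableSpec]:
    """The 21-variable primary registry.

    19 variables are collected in all three dataset versions; CDC and WHO
    stage at enrollment exist only pre-audit/audited and are replaced in the
    post-audit submission round by a clinical AIDS indicator and its
    diagnosis date, so each version exposes exactly 21 variables.
    """
    v = VariableSpec
    reg = [
        # patient-level, common
        v("sex", "patient", "sex", "categorical", "exact", ALL_VERSIONS),
        v("birth_date", "patient", "birth_date", "date", "date_tolerance", ALL_VERSIONS),
        v("mode_of_infection", "patient", "mode_of_infection", "categorical", "exact", ALL_VERSIONS),
        v("enrollment_date", "patient", "enrollment_date", "date", "date_tolerance", ALL_VERSIONS),
        v("aids_at_enrollment", "patient", "aids_at_enrollment", "categorical", "exact", ALL_VERSIONS),
        v("death_indicator", "patient", "death_indicator", "categorical", "exact", ALL_VERSIONS),
        v("death_date", "patient", "death_date", "date", "date_tolerance", ALL_VERSIONS),
        v("death_cause", "patient", "death_cause", "string", "case_insensitive", ALL_VERSIONS),
        # visit-level
        v("visit_date", "visit", "visit_date", "date", "date_tolerance", ALL_VERSIONS),
        v("weight", "visit", "weight", "numeric", "exact", ALL_VERSIONS),
        # lab-level
        v("cd4_value", "lab", "value", "numeric", "exact", ALL_VERSIONS, ("lab_type", "CD4")),
        v("cd4_date", "lab", "lab_date", "date", "date_tolerance", ALL_VERSIONS, ("lab_type", "CD4")),
        v("rna_value", "lab", "value", "numeric", "exact", ALL_VERSIONS, ("lab_type", "HIV_RNA")),
        v("rna_date", "lab", "lab_date", "date", "date_tolerance", ALL_VERSIONS, ("lab_type", "HIV_RNA")),
        # ART intervals
        v("art_regimen", "art", "regimen", "string", "case_insensitive", ALL_VERSIONS),
        v("art_start_date", "art", "start_date", "date", "date_tolerance", ALL_VERSIONS),
        v("art_end_date", "art", "end_date", "date", "date_tolerance", ALL_VERSIONS),
        # clinical events
        v("event_code", "event", "event_code", "string", "case_insensitive", ALL_VERSIONS),
        v("event_date", "event", "event_date", "date", "date_tolerance", ALL_VERSIONS),
        # pre-audit / audited only
        v("cdc_stage", "patient", "cdc_stage", "categorical", "exact", PRE_AND_AUDITED),
        v("who_stage", "patient", "who_stage", "categorical", "exact", PRE_AND_AUDITED),
        # post-audit replacements
        v("clinical_aids", "patient", "clinical_aids", "categorical", "exact", POST_ONLY),
        v("aids_diagnosis_date", "patient", "aids_diagnosis_date", "date", "date_tolerance", POST_ONLY),
    ]
    validate_registry(reg)
    return reg


def validate_registry(registry: Iterable[VariableSpec]) -> None:
    """Enforce the 19 + 2 + 2 partition and the 21-variables-per-version count."""
    reg = list(registry)
    names = [s.name for s in reg]
    if len(set(names)) != len(names):
        raise DatasetError("duplicate variable names in registry")
    common = [s for s in reg if s.versions == ALL_VERSIONS]
    pre_aud = [s for s in reg if s.versions == PRE_AND_AUDITED]
    post = [s for s in reg if s.versions == POST_ONLY]
    if not (len(common) == 19 and len(pre_aud) == 2 and len(post) == 2
            and len(reg) == 23):
        raise DatasetError(
            "registry must partition into 19 common + 2 pre/audited-only + "
            f"2 post-audit-only variables; got {len(common)}/{len(pre_aud)}/{len(post)}"
        )
    for label in ALL_VERSIONS:
        n = sum(1 for s in reg if label in s.versions)
        if n != 21:
            raise DatasetError(f"version {label} must expose 21 variables, got {n}")


def registry_for_version(registry: Iterable[VariableSpec], label: str) -> list[VariableSpec]:
    """Variables collected in a given version (truth carries all of them)."""
    if label == "truth":
        return list(registry)
    return [s for s in registry if label in s.versions]


# ---------------------------------------------------------------------------
# DatasetVersion
# ---------------------------------------------------------------------------

@dataclass
class DatasetVersion:
    """A complete snapshot of the five cohort tables plus audit bookkeeping.

    ``unverifiable_marks`` and ``audited_fields`` are sets of
    ``(patient_id, variable, occurrence)`` keys and are populated only on the
    audited version: a field either was verified against source documents
    (member of ``audited_fields``), could not be verified
    (``unverifiable_marks``), or was skipped.
    """

    label: str
    patients: pd.DataFrame
    visits: pd.DataFrame
    labs: pd.DataFrame
    art: pd.DataFrame
    events: pd.DataFrame
    freeze_dates: dict[str, pd.Timestamp] = field(default_factory=dict)
    unverifiable_marks: set = field(default_factory=set)
    audited_fields: set | None = None

    def table(self, short_name: str) -> pd.DataFrame:
        return getattr(self, {"patient": "patients", "visit": "visits",
                              "lab": "labs", "art": "art", "event": "events"}[short_name])

    @property
    def tables(self) -> dict[str, pd.DataFrame]:
        return {name: getattr(self, name) for name in TABLE_NAMES}

    def copy(self) -> "DatasetVersion":
        return replace(
            self,
            patients=self.patients.copy(),
            visits=self.visits.copy(),
            labs=self.labs.copy(),
            art=self.art.copy(),
            events=self.events.copy(),
            freeze_dates=dict(self.freeze_dates),
            unverifiable_marks=set(self.unverifiable_marks),
            audited_fields=None if self.audited_fields is None else set(self.audited_fields),
        )


def empty_dataset(label: str = "truth", freeze_dates: dict | None = None) -> DatasetVersion:
    frames = {}
    for name in TABLE_NAMES:
        df = pd.DataFrame({c: pd.Series(dtype="object") for c in TABLE_COLUMNS[name]})
        for c in DATE_COLUMNS[name]:
            df[c] = pd.Series(dtype="datetime64[ns]")
        frames[name] = df
    return DatasetVersion(label=label, freeze_dates=freeze_dates or {}, **frames)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_TABLE_FILES = {
    "patients": "patients.csv", "visits": "visits.csv", "labs": "labs.csv",
    "art": "art.csv", "events": "events.csv",
}


def _parse_dates(df: pd.DataFrame, cols: list[str], table: str) -> int:
    """Parse ISO date columns in place; unparseable cells become NaT. Returns #warnings."""
    n_bad = 0
    for c in cols:
        if c not in df.columns:
            continue
        raw = df[c].astype("string")
        parsed = pd.to_datetime(raw, format="%Y-%m-%d", errors="coerce")
        bad = raw.notna() & (raw != "") & parsed.isna()
        for idx in df.index[bad]:
            logger.warning("unparseable date %r in %s.%s (row %s); set missing",
                           raw[idx], table, c, idx)
        n_bad += int(bad.sum())
        df[c] = parsed
    return n_bad


def read_dataset(directory: str | Path, registry: list[VariableSpec] | None = None) -> DatasetVersion:
    """Read a dataset version from its directory of delimited tables.

    Raises :class:`DatasetError` if a table file is missing or contains an
    unknown column; unparseable dates are logged and set missing.
    """
    directory = Path(directory)
    registry = registry if registry is not None else default_registry()
    manifest_path = directory / "manifest.yaml"
    if not manifest_path.exists():
        raise DatasetError(f"missing manifest file: {manifest_path}")
    manifest = yaml.safe_load(manifest_path.read_text())
    label = manifest.get("label", "truth")
    if label not in VERSION_LABELS:
        raise DatasetError(f"unknown version label {label!r} in manifest")
    freeze_dates = {site: pd.Timestamp(d) for site, d in (manifest.get("freeze_dates") or {}).items()}

    frames = {}
    for name in TABLE_NAMES:
        path = directory / _TABLE_FILES[name]
        if not path.exists():
            raise DatasetError(f"missing table file: {path}")
        df = pd.read_csv(path, dtype="object", keep_default_na=True)
        unknown = set(df.columns) - set(TABLE_COLUMNS[name])
        if unknown:
            raise DatasetError(f"unknown column(s) {sorted(unknown)} in {path}")
        for c in TABLE_COLUMNS[name]:
            if c not in df.columns:
                df[c] = pd.Series([pd.NA] * len(df), dtype="object")
        df = df[TABLE_COLUMNS[name]]
        _parse_dates(df, DATE_COLUMNS[name], name)
        for c in df.columns:
            if c in ("weight", "value"):
                df[c] = pd.to_numeric(df[c], errors="coerce")
        frames[name] = df
    marks: set = set()
    marks_file = directory / "audit_marks.csv"
    if marks_file.exists():
        mdf = pd.read_csv(marks_file, dtype="object")
        marks = {tuple(r) for r in mdf[["patient_id", "variable", "occurrence"]].itertuples(index=False)}
    audited: set | None = None
    afile = directory / "audited_fields.csv"
    if afile.exists():
        adf = pd.read_csv(afile, dtype="object")
        audited = {tuple(r) for r in adf[["patient_id", "variable", "occurrence"]].itertuples(index=False)}
    return DatasetVersion(label=label, freeze_dates=freeze_dates,
                          unverifiable_marks=marks, audited_fields=audited, **frames)


def write_dataset(ds: DatasetVersion, directory: str | Path) -> list[Path]:
    """Write the five tables plus manifest (and audit bookkeeping) as CSV/YAML.

    Deterministic: two writes of the same dataset are byte-identical.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for name in TABLE_NAMES:
        df = ds.tables[name].copy()
        for c in DATE_COLUMNS[name]:
            df[c] = pd.to_datetime(df[c]).dt.strftime("%Y-%m-%d")
        path = directory / _TABLE_FILES[name]
        df.to_csv(path, index=False, lineterminator="\n")
        written.append(path)
    manifest = {
        "label": ds.label,
        "freeze_dates": {site: pd.Timestamp(d).strftime("%Y-%m-%d")
                         for site, d in sorted(ds.freeze_dates.items())},
    }
    mpath = directory / "manifest.yaml"
    mpath.write_text(yaml.safe_dump(manifest, sort_keys=True))
    written.append(mpath)
    if ds.unverifiable_marks:
        mdf = pd.DataFrame(sorted(ds.unverifiable_marks),
                           columns=["patient_id", "variable", "occurrence"])
        p = directory / "audit_marks.csv"
        mdf.to_csv(p, index=False, lineterminator="\n")
        written.append(p)
    if ds.audited_fields is not None:
        adf = pd.DataFrame(sorted(ds.audited_fields),
                           columns=["patient_id", "variable", "occurrence"])
        p = directory / "audited_fields.csv"
        adf.to_csv(p, index=False, lineterminator="\n")
        written.append(p)
    return written


def variable_occurrences(ds: DatasetVersion, spec: VariableSpec) -> pd.DataFrame:
    """All occurrences of one registry variable in a dataset version.

    Returns a frame with columns ``patient_id, occurrence, value`` — one row
    per patient for patient-level variables (occurrence = patient_id), one
    row per child-table record otherwise (occurrence = row_uid).
    """
    t = ds.table(spec.table)
    if spec.row_filter is not None:
        col, val = spec.row_filter
        t = t[t[col] == val]
    if spec.table == "patient":
        out = pd.DataFrame({"patient_id": t["patient_id"],
                            "occurrence": t["patient_id"],
                            "value": t[spec.column]})
    else:
        out = pd.DataFrame({"patient_id": t["patient_id"],
                            "occurrence": t["row_uid"],
                            "value": t[spec.column]})
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    """Counts of invariant violations per named check."""

    counts: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def is_clean(self) -> bool:
        return self.total == 0


def validate_dataset(ds: DatasetVersion) -> ValidationReport:
    """Count invariant violations without mutating the dataset.

    Checks: duplicate patient ids, orphan child rows, birth after enrollment,
    death before enrollment, death date without indicator, ART end before
    start, negative lab values, unknown lab types, empty event codes, and
    (warning-level) visits before enrollment.
    """
    p = ds.patients
    counts: dict[str, int] = {}
    counts["duplicate_patient_id"] = int(p["patient_id"].duplicated().sum())
    known = set(p["patient_id"])
    orphans = 0
    for name in ("visits", "labs", "art", "events"):
        t = ds.tables[name]
        orphans += int((~t["patient_id"].isin(known)).sum())
    counts["orphan_child_rows"] = orphans

    birth = pd.to_datetime(p["birth_date"])
    enroll = pd.to_datetime(p["enrollment_date"])
    death = pd.to_datetime(p["death_date"])
    counts["birth_after_enrollment"] = int((birth >= enroll).fillna(False).sum())
    counts["death_before_enrollment"] = int((death < enroll).fillna(False).sum())
    counts["death_date_without_indicator"] = int(
        (death.notna() & (p["death_indicator"].astype("string") != "yes")).sum())

    art = ds.art
    counts["art_end_before_start"] = int(
        (pd.to_datetime(art["end_date"]) < pd.to_datetime(art["start_date"])).fillna(False).sum())
    labs = ds.labs
    counts["negative_lab_value"] = int((pd.to_numeric(labs["value"], errors="coerce") < 0).sum())
    counts["unknown_lab_type"] = int(
        (~labs["lab_type"].isin(LAB_TYPES) & labs["lab_type"].notna()).sum())
    ev = ds.events
    code = ev["event_code"].astype("string")
    counts["empty_event_code"] = int((code.isna() | (code == "")).sum())

    enroll_by_id = dict(zip(p["patient_id"], enroll))
    vd = pd.to_datetime(ds.visits["visit_date"])
    ve = ds.visits["patient_id"].map(enroll_by_id)
    n_early = int((vd < pd.to_datetime(ve)).fillna(False).sum())
    counts["visit_before_enrollment_warning"] = n_early
    if n_early:
        logger.warning("%d visit(s) dated before enrollment (warning-level)", n_early)
    return ValidationReport(counts=counts)
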