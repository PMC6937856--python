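"""Field-level comparison of dataset versions with audit codes A1–A5.

The engine aligns two dataset versions (patients on their id; repeating
records on a stable row key when available, else greedily on nearest date
within a tolerance), compares every registry variable occurrence, and labels
each compared field with an audit code:

    A1  value matches the source document
    A2  minor discrepancy (dates within 30 days; numerics within 5% relative)
    A3  major discrepancy
    A4  value present in the source but never entered in the database
    A5  value could not be verified in the source document

A *discrepancy* is any compared field that is missing on one side,
conflicting (A2/A3) or unverifiable (A5). Summaries report discrepant /
audited counts grouped by variable, site and/or category.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort_model import (
    DatasetVersion, VariableSpec, default_registry, variable_occurrences,
)

#: default thresholds separating minor (A2) from major (A3) discrepancies
DATE_MINOR_DAYS = 30
NUMERIC_MINOR_REL = 0.05
ALIGN_TOLERANCE_DAYS = 30

CATEGORIES = ("match", "missing", "conflicting", "unverifiable", "not_audited")
DISCREPANT_CATEGORIES = ("missing", "conflicting", "unverifiable")

COMPARISON_COLUMNS = ["patient_id", "site_id", "variable", "occurrence",
                      "value_left", "value_right", "code", "category", "direction"]


@dataclass(frozen=True)
class FieldComparison:
    """One compared field occurrence across two dataset versions."""

    patient_id: str
    variable: str
    occurrence: str
    value_left: object
    value_right: object
    code: str
    category: str
    direction: str = ""
    site_id: str = ""


def _is_missing(v) -> bool:
    if v is None or v is pd.NaT or v is pd.NA:
        return True
    if isinstance(v, float) and math.isnan(v):
        return True
    try:
        return bool(pd.isna(v))
    except (TypeError, ValueError):
        return False


def compare_field(v_left, v_right, spec: VariableSpec,
                  unverifiable_mark: bool = False, *,
                  patient_id: str = "", occurrence: str = "", site_id: str = "",
                  date_minor_days: int = DATE_MINOR_DAYS,
                  numeric_minor_rel: float = NUMERIC_MINOR_REL) -> FieldComparison:
    """Compare one field under the registry's comparison rule.

    The unverifiable mark (source document absent) overrides the value
    comparison entirely. Direction records which side is missing when only
    one side holds a value.
    """
    def mk(code, category, direction=""):
        return FieldComparison(patient_id, spec.name, occurrence, v_left,
                               v_right, code, category, direction, site_id)

    if unverifiable_mark:
        return mk("A5", "unverifiable")
    lm, rm = _is_missing(v_left), _is_missing(v_right)
    if lm and rm:
        return mk("A1", "match")
    if lm:
        return mk("A4", "missing", "left_missing")
    if rm:
        return mk("A4", "missing", "right_missing")

    kind = spec.value_kind
    if kind == "date":
        try:
            a, b = pd.Timestamp(v_left), pd.Timestamp(v_right)
        except (ValueError, TypeError) as exc:
            raise TypeError(f"non-date value for date variable {spec.name}") from exc
        if a == b:
            return mk("A1", "match")
        return mk("A2" if abs((a - b).days) <= date_minor_days else "A3",
                  "conflicting")
    if kind == "numeric":
        try:
            a, b = float(v_left), float(v_right)
        except (ValueError, TypeError) as exc:
            raise TypeError(f"non-numeric value for numeric variable {spec.name}") from exc
        if a == b:
            return mk("A1", "match")
        rel = abs(a - b) / max(abs(a), abs(b))
        return mk("A2" if rel <= numeric_minor_rel else "A3", "conflicting")
    if kind == "categorical":
        return mk("A1", "match") if str(v_left) == str(v_right) else mk("A3", "conflicting")
    # string: case-insensitive
    if str(v_left).strip().lower() == str(v_right).strip().lower():
        return mk("A1", "match")
    return mk("A3", "conflicting")


# ---------------------------------------------------------------------------
# record alignment
# ---------------------------------------------------------------------------

_DATE_OF_TABLE = {"visits": "visit_date", "labs": "lab_date",
                  "art": "start_date", "events": "event_date"}


@dataclass
class Alignment:
    """Patient and per-table row alignment between two dataset versions."""

    matched: list
    left_only: list
    right_only: list
    collisions: list
    row_maps: dict = field(default_factory=dict)  # table -> DataFrame(left_key, right_key, patient_id)


def _greedy_date_match(lt: pd.DataFrame, rt: pd.DataFrame, date_col: str,
                       value_cols: list[str],
                       tolerance_days: int) -> list[tuple[int, int]]:
    """Greedy nearest-date row matching within one patient (and lab type)."""
    pairs = []
    for i in lt.index:
        for j in rt.index:
            di, dj = lt.at[i, date_col], rt.at[j, date_col]
            if pd.isna(di) or pd.isna(dj):
                delta = tolerance_days  # date missing on a side: matchable, worst rank
            else:
                delta = abs((pd.Timestamp(di) - pd.Timestamp(dj)).days)
            if delta <= tolerance_days:
                same_val = all(str(lt.at[i, c]) == str(rt.at[j, c]) for c in value_cols)
                pairs.append((delta, 0 if same_val else 1, i, j))
    pairs.sort()
    used_l, used_r, out = set(), set(), []
    for _, _, i, j in pairs:
        if i not in used_l and j not in used_r:
            used_l.add(i)
            used_r.add(j)
            out.append((i, j))
    return out


def align_records(left: DatasetVersion, right: DatasetVersion,
                  tolerance_days: int = ALIGN_TOLERANCE_DAYS) -> Alignment:
    """Align two dataset versions.

    Patients match on ``patient_id`` (duplicates are reported in the
    collision list; the first row is used). Repeating records match on
    ``row_uid`` when both sides carry one, otherwise greedily on
    (patient_id, nearest date within the tolerance, then value agreement).
    """
    lp = set(left.patients["patient_id"])
    rp = set(right.patients["patient_id"])
    collisions = sorted(set(left.patients.loc[left.patients["patient_id"].duplicated(), "patient_id"])
                        | set(right.patients.loc[right.patients["patient_id"].duplicated(), "patient_id"]))
    al = Alignment(matched=sorted(lp & rp), left_only=sorted(lp - rp),
                   right_only=sorted(rp - lp), collisions=collisions)

    for name in ("visits", "labs", "art", "events"):
        lt, rt = left.tables[name], right.tables[name]
        lt = lt.drop_duplicates("row_uid", keep="first")
        rt = rt.drop_duplicates("row_uid", keep="first")
        l_has = lt["row_uid"].notna()
        r_has = rt["row_uid"].notna()
        shared = set(lt.loc[l_has, "row_uid"]) & set(rt.loc[r_has, "row_uid"])
        rows = [(u, u) for u in sorted(shared)]
        lrest = lt[~lt["row_uid"].isin(shared)]
        rrest = rt[~rt["row_uid"].isin(shared)]
        if len(lrest) and len(rrest):
            date_col = _DATE_OF_TABLE[name]
            vcols = [c for c in lt.columns
                     if c not in ("row_uid", "patient_id", date_col)]
            group_cols = ["patient_id"] + (["lab_type"] if name == "labs" else [])
            rgrp = dict(tuple(rrest.groupby(group_cols, dropna=False)))
            for key, lg in lrest.groupby(group_cols, dropna=False):
                rg = rgrp.get(key)
                if rg is None:
                    continue
                for i, j in _greedy_date_match(lg, rg, date_col,
                                               [c for c in vcols if c != "lab_type"],
                                               tolerance_days):
                    rows.append((lt.at[i, "row_uid"], rt.at[j, "row_uid"]))
        matched_l = {a for a, _ in rows}
        matched_r = {b for _, b in rows}
        rows += [(u, None) for u in lt["row_uid"] if u not in matched_l]
        rows += [(None, u) for u in rt["row_uid"] if u not in matched_r]
        pid_of = dict(zip(lt["row_uid"], lt["patient_id"]))
        pid_of.update({u: p for u, p in zip(rt["row_uid"], rt["patient_id"])})
        al.row_maps[name] = pd.DataFrame(
            rows, columns=["left_key", "right_key"]).assign(
            patient_id=lambda d: d["left_key"].fillna(d["right_key"]).map(pid_of))
    return al


# ---------------------------------------------------------------------------
# audit comparison
# ---------------------------------------------------------------------------

def audit_compare(left: DatasetVersion, right: DatasetVersion,
                  registry: list[VariableSpec] | None = None,
                  scope: set | None = None,
                  audited_field_mask: set | None = None,
                  alignment: Alignment | None = None,
                  tolerance_days: int = ALIGN_TOLERANCE_DAYS) -> pd.DataFrame:
    """Compare every shared registry variable occurrence between two versions.

    ``scope`` restricts to a patient-id subset (e.g. the completed audit
    sample). ``audited_field_mask`` — a set of (patient_id, variable,
    occurrence) — marks which fields were actually source-verified; fields
    outside it are categorised ``not_audited`` and excluded from
    denominators. Unverifiable marks are taken from the right-hand (source)
    version. Returns one row per compared occurrence.
    """
    registry = registry if registry is not None else default_registry()
    shared = [s for s in registry
              if (left.label == "truth" or left.label in s.versions)
              and (right.label == "truth" or right.label in s.versions)]
    al = alignment if alignment is not None else align_records(left, right, tolerance_days)
    in_scope = set(al.matched) | set(al.left_only) | set(al.right_only)
    if scope is not None:
        in_scope &= set(scope)
    marks = right.unverifiable_marks or set()

    site_of = dict(zip(left.patients["patient_id"], left.patients["site_id"]))
    site_of.update({p: s for p, s in zip(right.patients["patient_id"],
                                         right.patients["site_id"])
                    if p not in site_of})

    frame_of = {"patient": "patients", "visit": "visits", "lab": "labs",
                "art": "art", "event": "events"}
    out = []
    for spec in shared:
        L = variable_occurrences(left, spec).drop_duplicates("occurrence", keep="first")
        R = variable_occurrences(right, spec).drop_duplicates("occurrence", keep="first")
        if spec.table == "patient":
            m = L.merge(R, on=["patient_id", "occurrence"], how="outer",
                        suffixes=("_l", "_r"), indicator=True)
        else:
            rmap = al.row_maps[frame_of[spec.table]]
            lvals = L.rename(columns={"occurrence": "left_key", "value": "value_l"})
            rvals = R.rename(columns={"occurrence": "right_key", "value": "value_r"})
            m = (rmap
                 .merge(lvals[["left_key", "value_l"]], on="left_key", how="left")
                 .merge(rvals[["right_key", "value_r"]], on="right_key", how="left"))
            # keep only rows where the variable applies on at least one side
            # (e.g. CD4 variables apply to CD4 lab rows only)
            applies = m["left_key"].isin(set(lvals["left_key"])) | \
                m["right_key"].isin(set(rvals["right_key"]))
            m = m[applies].copy()
            m["occurrence"] = m["left_key"].fillna(m["right_key"])
        for r in m.itertuples(index=False):
            pid = r.patient_id
            if pid not in in_scope:
                continue
            occ = r.occurrence
            key = (pid, spec.name, occ)
            if audited_field_mask is not None and key not in audited_field_mask:
                out.append((pid, site_of.get(pid, ""), spec.name, occ,
                            getattr(r, "value_l", None), getattr(r, "value_r", None),
                            "", "not_audited", ""))
                continue
            fc = compare_field(getattr(r, "value_l", None), getattr(r, "value_r", None),
                               spec, unverifiable_mark=key in marks,
                               patient_id=pid, occurrence=str(occ),
                               site_id=site_of.get(pid, ""))
            out.append((pid, fc.site_id, spec.name, occ, fc.value_left,
                        fc.value_right, fc.code, fc.category, fc.direction))
    return pd.DataFrame(out, columns=COMPARISON_COLUMNS)


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def summarize_discrepancies(comparisons: pd.DataFrame,
                            group_by: list[str] | None = None) -> pd.DataFrame:
    """Aggregate field comparisons into discrepancy-rate summaries.

    Fields categorised ``not_audited`` are excluded from denominators.
    ``rate`` = (missing + conflicting + unverifiable) / audited; reported as
    NaN (undefined) for empty groups. Category counts always sum to the
    audited count.
    """
    if comparisons.empty:
        raise ValueError("no comparisons to summarize")
    df = comparisons[comparisons["category"] != "not_audited"]
    if group_by:
        groups = df.groupby(group_by, dropna=False)
    else:
        groups = [((), df)]
    rows = []
    for key, g in groups:
        counts = g["category"].value_counts()
        audited = int(len(g))
        n_miss = int(counts.get("missing", 0))
        n_conf = int(counts.get("conflicting", 0))
        n_unv = int(counts.get("unverifiable", 0))
        n_match = int(counts.get("match", 0))
        disc = n_miss + n_conf + n_unv
        assert n_match + disc == audited
        rate = disc / audited if audited else float("nan")
        if not isinstance(key, tuple):
            key = (key,)
        rows.append(tuple(key) + (audited, disc, rate, n_match, n_miss, n_conf, n_unv))
    cols = list(group_by or []) + ["audited_count", "discrepant_count", "rate",
                                   "n_match", "n_missing", "n_conflicting",
                                   "n_unverifiable"]
    out = pd.DataFrame(rows, columns=cols)
    if group_by:
        out = out.sort_values(group_by).reset_index(drop=True)
    return out


def overall_rate_percent(summary: pd.DataFrame) -> float:
    """Overall discrepancy rate as a percentage rounded to 1 decimal
    (the convention used for the audited-subset headline rate)."""
    disc = summary["discrepant_count"].sum()
    aud = summary["audited_count"].sum()
    return round(100.0 * disc / aud, 1)


def category_percentages(summary: pd.DataFrame) -> dict[str, float]:
    """Share of discrepancies by category, as integer-rounded percentages."""
    disc = summary["discrepant_count"].sum()
    if disc == 0:
        return {"missing": 0.0, "conflicting": 0.0, "unverifiable": 0.0}
    return {
        "missing": round(100.0 * summary["n_missing"].sum() / disc),
        "conflicting": round(100.0 * summary["n_conflicting"].sum() / disc),
        "unverifiable": round(100.0 * summary["n_unverifiable"].sum() / disc),
    }
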