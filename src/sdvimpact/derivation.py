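"""Per-patient analysis table: the derived variables and inclusion criteria.

From a dataset version this module derives, for every patient, the analysis
variables the time-to-event models need: ART initiation date and age at
initiation, baseline (nadir) CD4, clinical AIDS history at baseline, initial
regimen class, country-pooled analysis site, and the times from ART
initiation to death and to first AIDS-defining event (or censoring).
Patients are excluded if they were not adults (< 18 years) at initiation or
never initiated ART.

All clocks anchor at ART initiation (earliest recorded regimen start).
Censoring is at min(site freeze date, last recorded contact), where last
contact is the latest visit or lab date.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort_model import DatasetVersion
from .synthetic_cohort import classify_regimen

logger = logging.getLogger(__name__)

DERIVED_VARIABLES = [
    "analysis_site", "age_at_art", "sex", "ivdu", "clinical_aids_at_baseline",
    "baseline_cd4", "regimen_class", "art_initiation_date", "initiation_year",
    "time_to_death_or_censor", "death_indicator", "time_to_aids_or_censor",
    "aids_indicator",
]
#: the 14 derived variables = the 13 above plus the inclusion flag
ALL_DERIVED = DERIVED_VARIABLES + ["included"]


@dataclass
class DerivationOptions:
    """Tunable derivation rules.

    ``baseline_cd4_method`` — ``"nadir"`` (minimum CD4 at or before
    initiation; the Table-1 convention) or ``"window"`` (measurement nearest
    to initiation within ``cd4_window`` days, ties broken toward the
    pre-initiation side). ``baseline_grace_days`` — events up to this many
    days after initiation count as history, not incident outcomes.
    """

    baseline_cd4_method: str = "nadir"
    cd4_window: tuple = (-180, 7)
    baseline_grace_days: int = 7


def derive_analysis_table(ds: DatasetVersion,
                          options: DerivationOptions | None = None) -> pd.DataFrame:
    """Build the analysis table (one row per patient) from a dataset version.

    Pure function of the dataset: same input, identical table.
    """
    opt = options or DerivationOptions()
    p = ds.patients.drop_duplicates("patient_id", keep="first").set_index("patient_id")
    freeze = {s: pd.Timestamp(d) for s, d in ds.freeze_dates.items()}

    art = ds.art.dropna(subset=["start_date"])
    art = art.sort_values(["patient_id", "start_date", "row_uid"])
    first_art = art.groupby("patient_id").first()

    cd4 = ds.labs[(ds.labs["lab_type"] == "CD4")
                  & ds.labs["value"].notna() & ds.labs["lab_date"].notna()]

    visits = ds.visits.dropna(subset=["visit_date"])
    last_visit = visits.groupby("patient_id")["visit_date"].max()
    last_lab = ds.labs.dropna(subset=["lab_date"]).groupby("patient_id")["lab_date"].max()

    events = ds.events.dropna(subset=["event_date"])
    ev_by_pid = {pid: g["event_date"].sort_values().to_numpy()
                 for pid, g in events.groupby("patient_id")}
    cd4_by_pid = dict(tuple(cd4.groupby("patient_id")))

    rows = []
    for pid, row in p.iterrows():
        site = row["site_id"]
        country = row["country"]
        birth = row["birth_date"]
        init = first_art["start_date"].get(pid, pd.NaT)
        regimen = first_art["regimen"].get(pid, None)

        if pd.isna(init):
            rows.append(_empty_row(pid, country, row))
            continue

        age = ((init - birth).days / 365.25) if pd.notna(birth) else np.nan
        if pd.notna(age) and age < 0:
            logger.warning("patient %s: ART start precedes birth; excluded as data defect", pid)

        grace = init + pd.Timedelta(days=opt.baseline_grace_days)

        # baseline CD4
        base_cd4 = np.nan
        g = cd4_by_pid.get(pid)
        if g is not None and len(g):
            if opt.baseline_cd4_method == "nadir":
                pre = g[g["lab_date"] <= init]
                if len(pre):
                    base_cd4 = float(pre["value"].min())
            else:
                lo, hi = opt.cd4_window
                win = g[(g["lab_date"] >= init + pd.Timedelta(days=lo))
                        & (g["lab_date"] <= init + pd.Timedelta(days=hi))].copy()
                if len(win):
                    delta = (win["lab_date"] - init).dt.days
                    # nearest wins; ties broken toward the pre-initiation side
                    win["rank"] = delta.abs() * 2 + (delta > 0).astype(int)
                    base_cd4 = float(win.sort_values(["rank", "lab_date"]).iloc[0]["value"])

        # clinical AIDS history at baseline
        evd = ev_by_pid.get(pid)
        prior_event = evd is not None and bool((evd <= np.datetime64(grace)).any())
        base_aids = (str(row.get("aids_at_enrollment")) == "yes") or prior_event

        # censoring: min(site freeze, last recorded contact)
        contacts = [d for d in (last_visit.get(pid, pd.NaT), last_lab.get(pid, pd.NaT))
                    if pd.notna(d)]
        last_contact = max(contacts) if contacts else init
        censor = min(freeze.get(site, last_contact), last_contact)

        death = str(row.get("death_indicator")) == "yes" and pd.notna(row.get("death_date"))
        if death:
            t_death = (row["death_date"] - init).days
        else:
            t_death = (censor - init).days
        t_death = max(int(t_death), 0)

        aids_ind = False
        t_aids = None
        if evd is not None:
            incident = evd[evd > np.datetime64(grace)]
            if len(incident):
                aids_ind = True
                t_aids = (pd.Timestamp(incident[0]) - init).days
        if t_aids is None:
            end = min(censor, row["death_date"]) if death else censor
            t_aids = (end - init).days
        t_aids = max(int(t_aids), 0)

        if pd.notna(age) and age < 18.0:
            incl, reason = False, "under_18"
        else:
            incl, reason = True, "none"

        rows.append({
            "patient_id": pid, "analysis_site": country,
            "age_at_art": age, "sex": row.get("sex"),
            "ivdu": _ivdu(row.get("mode_of_infection")),
            "clinical_aids_at_baseline": "yes" if base_aids else "no",
            "baseline_cd4": base_cd4,
            "regimen_class": classify_regimen(regimen),
            "art_initiation_date": init, "initiation_year": float(init.year),
            "time_to_death_or_censor": t_death, "death_indicator": bool(death),
            "time_to_aids_or_censor": t_aids, "aids_indicator": bool(aids_ind),
            "included": incl, "exclusion_reason": reason,
        })
    out = pd.DataFrame(rows)
    if len(out):
        assert (out["included"] == (out["exclusion_reason"] == "none")).all()
    return out.reset_index(drop=True)


def _ivdu(mode) -> str | None:
    if mode is None or pd.isna(mode):
        return None
    return "yes" if str(mode) == "IVDU" else "no"


def _empty_row(pid, country, row) -> dict:
    return {
        "patient_id": pid, "analysis_site": country, "age_at_art": np.nan,
        "sex": row.get("sex"), "ivdu": _ivdu(row.get("mode_of_infection")),
        "clinical_aids_at_baseline": None, "baseline_cd4": np.nan,
        "regimen_class": None, "art_initiation_date": pd.NaT,
        "initiation_year": np.nan, "time_to_death_or_censor": np.nan,
        "death_indicator": False, "time_to_aids_or_censor": np.nan,
        "aids_indicator": False, "included": False,
        "exclusion_reason": "never_art",
    }


# ---------------------------------------------------------------------------
# derived-variable comparison
# ---------------------------------------------------------------------------

def _derived_equal(a, b) -> bool:
    both_na = pd.isna(a) and pd.isna(b)
    if both_na:
        return True
    if pd.isna(a) != pd.isna(b):
        return False
    if isinstance(a, (int, float, np.floating)) and isinstance(b, (int, float, np.floating)):
        return bool(np.isclose(float(a), float(b), rtol=0, atol=1e-9))
    return a == b


def compare_derived(a: pd.DataFrame, b: pd.DataFrame,
                    variables: list[str] | None = None) -> pd.DataFrame:
    """Per-variable discrepancy rates between two analysis tables.

    The denominator is the set of patients present in at least one table; a
    derived value that differs, or is computable on one side only, counts as
    discrepant.
    """
    variables = variables or ALL_DERIVED
    ai = a.set_index("patient_id")
    bi = b.set_index("patient_id")
    pids = sorted(set(ai.index) | set(bi.index))
    rows = []
    for var in variables:
        n_disc = 0
        for pid in pids:
            va = ai.at[pid, var] if pid in ai.index else np.nan
            vb = bi.at[pid, var] if pid in bi.index else np.nan
            if not _derived_equal(va, vb):
                n_disc += 1
        rows.append((var, len(pids), n_disc,
                     n_disc / len(pids) if pids else float("nan")))
    return pd.DataFrame(rows, columns=["variable", "n", "discrepant_count", "rate"])


def inclusion_concordance(a: pd.DataFrame, b: pd.DataFrame) -> dict[str, int]:
    """Counts of patients meeting inclusion criteria in each table and both."""
    ina = set(a.loc[a["included"], "patient_id"])
    inb = set(b.loc[b["included"], "patient_id"])
    return {"included_a": len(ina), "included_b": len(inb),
            "included_both": len(ina & inb),
            "present_either": len(set(a["patient_id"]) | set(b["patient_id"]))}
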