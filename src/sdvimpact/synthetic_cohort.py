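"""Synthetic multi-site HIV cohort generator with a known gold standard.

Simulates the *truth* dataset version: patients enrolled at 9 sites in 7
countries, ART initiation, baseline and follow-up CD4 / viral-load
measurements, clinic visits, AIDS-defining events and deaths. Death and AIDS
latent times are drawn from independent cause-specific proportional-hazards
models with configurable log-hazard coefficients, so downstream survival fits
can be checked against the generating parameters.

Every latent quantity needed by recovery tests (true covariates, true event
and censoring times in days, true inclusion status) is recorded in the
TruthLog, one row per patient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cohort_model import DATE_COLUMNS, DatasetVersion, TABLE_COLUMNS

DAY = pd.Timedelta(days=1)

#: nine sites in seven countries; Argentina and Honduras contribute two sites
DEFAULT_COUNTRIES = {
    "AR-A": "argentina", "AR-B": "argentina",
    "HN-A": "honduras", "HN-B": "honduras",
    "BR-A": "brazil", "CL-A": "chile", "HT-A": "haiti",
    "MX-A": "mexico", "PE-A": "peru",
}

AIDS_EVENT_CODES = ("PCP", "TB_PULM", "TB_EXTRA", "KS", "TOXO", "CRYPTO_MEN",
                    "CMV", "WASTING", "OESOPH_CAND")
DEATH_CAUSES = ("aids_related", "cardiovascular", "malignancy", "other", "unknown")

REGIMENS = {
    "NNRTI": ("AZT+3TC+EFV", "TDF+FTC+EFV", "AZT+3TC+NVP", "TDF+3TC+NVP"),
    "boosted_PI": ("AZT+3TC+LPV/r", "TDF+FTC+ATV/r", "ABC+3TC+DRV/r"),
    "other": ("AZT+3TC+ABC", "TDF+FTC+RAL", "D4T+3TC+IDV"),
}

#: drug -> regimen class lookup used by the derivation stage
NNRTI_DRUGS = {"EFV", "NVP", "ETR", "RPV"}
BOOSTED_PI_DRUGS = {"LPV/r", "ATV/r", "DRV/r", "SQV/r", "IDV/r"}


def classify_regimen(regimen: str | None) -> str | None:
    """Map a '+'-separated drug string to {NNRTI, boosted_PI, other}."""
    if regimen is None or (isinstance(regimen, float) and math.isnan(regimen)):
        return None
    drugs = {d.strip() for d in str(regimen).split("+")}
    if drugs & NNRTI_DRUGS:
        return "NNRTI"
    if drugs & BOOSTED_PI_DRUGS:
        return "boosted_PI"
    return "other"


@dataclass
class EventHazards:
    """Cause-specific baseline rates (per person-year, at reference covariates)
    and log-hazard coefficients.

    Coefficient keys: ``age10`` (per decade above 40), ``male``, ``ivdu``,
    ``baseline_aids``, ``log2_cd4`` (per doubling of baseline CD4 relative to
    150 cells/µL), ``boosted_pi``, ``other_regimen`` (vs NNRTI), and
    ``year_amp`` — the amplitude of a smooth nonlinear calendar-year effect,
    so spline machinery downstream is exercised nontrivially.
    """

    death_rate: float = 0.022
    aids_rate: float = 0.055
    death_coef: dict = field(default_factory=lambda: {
        "age10": 0.35, "male": 0.08, "ivdu": 0.20, "baseline_aids": 0.55,
        "log2_cd4": -0.28, "boosted_pi": 0.26, "other_regimen": 0.10,
        "year_amp": 0.30,
    })
    aids_coef: dict = field(default_factory=lambda: {
        "age10": 0.00, "male": -0.08, "ivdu": 0.05, "baseline_aids": 0.70,
        "log2_cd4": -0.22, "boosted_pi": 0.05, "other_regimen": 0.05,
        "year_amp": 0.30,
    })

    def validate(self) -> None:
        for r in (self.death_rate, self.aids_rate):
            if not (0 < r < math.inf):
                raise ValueError(f"degenerate baseline hazard: {r}")


def _year_effect(year: np.ndarray, amp: float, lo: int = 1996, hi: int = 2013) -> np.ndarray:
    # smooth U-shaped log-hazard over initiation year, mean roughly zero
    z = (year - lo) / (hi - lo)
    return amp * (4.0 * (z - 0.55) ** 2 - 0.45)


@dataclass
class CohortSimParams:
    """Generating parameters for the synthetic cohort.

    Defaults emulate the audited network's structure: nine sites in seven
    Latin American countries (two countries contribute two sites each),
    enrollment 1996–2013 with site freeze dates in 2014, late ART initiation
    (median baseline CD4 ≈ 150 cells/µL), quarterly visits.
    """

    n_sites: int = 9
    countries: dict = field(default_factory=lambda: dict(DEFAULT_COUNTRIES))
    patients_per_site: int = 250
    enrollment_window: tuple = ("1996-01-01", "2013-06-30")
    freeze_dates: dict | None = None  # site -> ISO date; default staggered 2014
    art_initiation_probability: float = 0.92
    proportion_under_18: float = 0.10
    baseline_cd4_distribution: tuple = (150.0, 0.9)  # (median cells/µL, log-sd)
    visit_interval_days: tuple = (90.0, 21.0)  # (mean, jitter sd)
    event_hazards: EventHazards = field(default_factory=EventHazards)
    censoring_hazard: float = 0.07  # dropout rate per person-year
    seed: int = 0
    # secondary mixture parameters
    sex_male_prob: float = 0.60
    mode_probs: dict = field(default_factory=lambda: {
        "heterosexual": 0.55, "MSM": 0.30, "IVDU": 0.03, "other": 0.05,
        "unknown": 0.07})
    aids_at_enrollment_prob: float = 0.22
    regimen_probs: dict = field(default_factory=lambda: {
        "NNRTI": 0.60, "boosted_PI": 0.25, "other": 0.15})
    art_delay_mean_days: float = 45.0

    def validate(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.patients_per_site <= 0:
            raise ValueError("patients_per_site must be positive")
        for p in (self.art_initiation_probability, self.proportion_under_18,
                  self.sex_male_prob, self.aids_at_enrollment_prob):
            if not 0 <= p <= 1:
                raise ValueError(f"probability out of [0,1]: {p}")
        if not (0 <= self.censoring_hazard < math.inf):
            raise ValueError("censoring_hazard must be finite and >= 0")
        self.event_hazards.validate()

    @property
    def sites(self) -> list[str]:
        return list(self.countries)[: self.n_sites]

    def resolved_freeze_dates(self) -> dict[str, pd.Timestamp]:
        if self.freeze_dates:
            return {s: pd.Timestamp(d) for s, d in self.freeze_dates.items()}
        # staggered site freezes in the year after enrollment closes
        base = pd.Timestamp(self.enrollment_window[1]) + pd.Timedelta(days=270)
        return {s: base + pd.Timedelta(days=30 * i) for i, s in enumerate(self.sites)}


def study_scale_preset(scale: float = 1.0, seed: int = 0) -> CohortSimParams:
    """Preset sized so the downstream pre-audit dataset holds ≈19,000–20,000
    adults across 9 sites (after the preset error model removes ≈14% of truth
    records from the pre-audit submission). ``scale`` shrinks every site
    proportionally for small-mode runs.
    """
    per_site = max(1, round(2780 * scale))
    return CohortSimParams(patients_per_site=per_site, seed=seed)


def simulate_truth(params: CohortSimParams) -> tuple[DatasetVersion, pd.DataFrame]:
    """Simulate the truth dataset version and its TruthLog.

    Deterministic given ``params.seed``. Returns ``(dataset, truth_log)``
    where the log has one row per patient holding every latent quantity:
    true covariates, event/censoring times in days from ART initiation,
    inclusion status and per-patient child-row tallies.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    sites = params.sites
    countries = params.countries
    freeze = params.resolved_freeze_dates()
    hz = params.event_hazards

    pat_rows, visit_rows, lab_rows, art_rows, event_rows, log_rows = [], [], [], [], [], []

    enroll_lo = pd.Timestamp(params.enrollment_window[0])
    enroll_hi = pd.Timestamp(params.enrollment_window[1])
    window_days = (enroll_hi - enroll_lo).days

    mode_levels = list(params.mode_probs)
    mode_p = np.array([params.mode_probs[m] for m in mode_levels], float)
    mode_p = mode_p / mode_p.sum()
    reg_levels = list(params.regimen_probs)
    reg_p = np.array([params.regimen_probs[r] for r in reg_levels], float)
    reg_p = reg_p / reg_p.sum()

    for site in sites:
        n = params.patients_per_site
        country = countries[site]
        fdate = freeze[site]
        for i in range(n):
            pid = f"{site}-{i:05d}"
            enroll = enroll_lo + pd.Timedelta(days=int(rng.integers(0, window_days + 1)))
            under18 = rng.random() < params.proportion_under_18
            if under18:
                age_enroll = rng.uniform(5.0, 17.5)
            else:
                age_enroll = float(np.clip(rng.normal(37.0, 10.0), 18.2, 75.0))
            birth = enroll - pd.Timedelta(days=int(round(age_enroll * 365.25)))
            male = rng.random() < params.sex_male_prob
            mode = mode_levels[rng.choice(len(mode_levels), p=mode_p)]
            ivdu = mode == "IVDU"
            base_aids = rng.random() < params.aids_at_enrollment_prob
            cdc = "C" if base_aids else ("A" if rng.random() < 0.6 else "B")
            who = "4" if base_aids else str(int(rng.integers(1, 4)))

            initiates = rng.random() < params.art_initiation_probability
            admin_from_enroll = (fdate - enroll).days
            art_start = None
            if initiates:
                delay = int(min(rng.exponential(params.art_delay_mean_days),
                                365.0, max(admin_from_enroll - 30, 1)))
                art_start = enroll + pd.Timedelta(days=delay)
                if (fdate - art_start).days < 1:
                    initiates = False
                    art_start = None

            med, sd = params.baseline_cd4_distribution
            cd4_0 = float(np.round(np.exp(rng.normal(math.log(med), sd))))
            cd4_0 = max(cd4_0, 1.0)

            prior_event_date = None
            if base_aids:
                prior_event_date = enroll - pd.Timedelta(days=int(rng.integers(0, 730)))

            n_visits = n_labs = n_art = n_events = 0
            death_ind = False
            aids_ind = False
            t_death_d = t_aids_d = np.nan
            init_year = np.nan
            age_at_art = np.nan
            reg_class = None
            regimen = None
            baseline_aids_true = base_aids

            if initiates:
                age_at_art = (art_start - birth).days / 365.25
                init_year = art_start.year
                reg_class = reg_levels[rng.choice(len(reg_levels), p=reg_p)]
                regimen = REGIMENS[reg_class][int(rng.integers(0, len(REGIMENS[reg_class])))]

                cov = {
                    "age10": (age_at_art - 40.0) / 10.0,
                    "male": float(male),
                    "ivdu": float(ivdu),
                    "baseline_aids": float(base_aids),
                    "log2_cd4": math.log2(cd4_0 / 150.0),
                    "boosted_pi": float(reg_class == "boosted_PI"),
                    "other_regimen": float(reg_class == "other"),
                }
                def lp(coef):
                    s = sum(coef[k] * cov[k] for k in cov)
                    return s + _year_effect(np.array([init_year]), coef["year_amp"])[0]

                t_death_yr = rng.exponential(1.0 / (hz.death_rate * math.exp(lp(hz.death_coef))))
                t_aids_yr = rng.exponential(1.0 / (hz.aids_rate * math.exp(lp(hz.aids_coef))))
                t_drop_yr = (rng.exponential(1.0 / params.censoring_hazard)
                             if params.censoring_hazard > 0 else math.inf)
                admin_d = (fdate - art_start).days
                death_d = int(math.floor(t_death_yr * 365.25)) + 1
                aids_d = int(math.floor(t_aids_yr * 365.25)) + 1
                drop_d = (int(math.floor(t_drop_yr * 365.25)) + 1
                          if math.isfinite(t_drop_yr) else 10 ** 9)
                end_d = min(death_d, drop_d, admin_d)
                death_ind = death_d == end_d
                t_death_d = float(end_d)
                if aids_d <= end_d:
                    if aids_d > 7:
                        aids_ind = True
                        t_aids_d = float(aids_d)
                    else:
                        # an event within the baseline grace window counts as
                        # history, not an incident outcome
                        baseline_aids_true = True
                        t_aids_d = float(end_d)
                else:
                    t_aids_d = float(end_d)
                end_date = art_start + pd.Timedelta(days=int(end_d))

                # --- child rows -------------------------------------------
                # visits: enrollment, then ~quarterly, then a closing contact
                mean_iv, jit = params.visit_interval_days
                vdays = [0]
                d = 0
                total = (end_date - enroll).days
                while True:
                    d += max(7, int(round(rng.normal(mean_iv, jit))))
                    if d >= total:
                        break
                    vdays.append(d)
                vdays.append(total)  # closing contact fixes last-contact date
                vdays = sorted(set(vdays))
                wbase = float(np.clip(rng.normal(65.0, 12.0), 35.0, 140.0))
                for k, vd in enumerate(vdays):
                    visit_rows.append((f"{pid}-v{k}", pid, enroll + vd * DAY,
                                       round(wbase + rng.normal(0, 2.0), 1)))
                n_visits = len(vdays)

                # labs: baseline CD4/RNA just before initiation, follow-up after
                base_lab_date = max(enroll, art_start - pd.Timedelta(days=int(rng.integers(0, 31))))
                labs = [("CD4", base_lab_date, cd4_0),
                        ("HIV_RNA", base_lab_date,
                         float(np.round(np.exp(rng.normal(math.log(8e4), 1.1)))))]
                t = 180
                while t < end_d:
                    ldate = art_start + pd.Timedelta(days=t)
                    rec = cd4_0 + 150.0 * (1.0 - math.exp(-t / 548.0)) + rng.uniform(0, 40)
                    labs.append(("CD4", ldate, float(np.round(rec))))
                    labs.append(("HIV_RNA", ldate,
                                 float(np.round(max(19.0, np.exp(rng.normal(math.log(200), 1.5)))))))
                    t += int(round(rng.normal(182, 30)))
                for k, (lt, ld, lv) in enumerate(labs):
                    lab_rows.append((f"{pid}-l{k}", pid, lt, ld, lv))
                n_labs = len(labs)

                art_end = end_date if death_ind else None
                art_rows.append((f"{pid}-a0", pid, regimen, art_start, art_end))
                n_art = 1

                evs = []
                if prior_event_date is not None:
                    evs.append((AIDS_EVENT_CODES[int(rng.integers(0, len(AIDS_EVENT_CODES)))],
                                prior_event_date))
                if aids_d <= end_d:
                    evs.append((AIDS_EVENT_CODES[int(rng.integers(0, len(AIDS_EVENT_CODES)))],
                                art_start + pd.Timedelta(days=int(aids_d))))
                for k, (ec, ed) in enumerate(evs):
                    event_rows.append((f"{pid}-e{k}", pid, ec, ed))
                n_events = len(evs)

                death_date = end_date if death_ind else None
                death_cause = (DEATH_CAUSES[int(rng.integers(0, len(DEATH_CAUSES)))]
                               if death_ind else None)
            else:
                # never-initiators: sparse visits until dropout/freeze
                t_drop_yr = (rng.exponential(1.0 / params.censoring_hazard)
                             if params.censoring_hazard > 0 else math.inf)
                total = min(int(t_drop_yr * 365.25) + 1, admin_from_enroll)
                vdays = sorted({0, max(total, 0)})
                for k, vd in enumerate(vdays):
                    visit_rows.append((f"{pid}-v{k}", pid, enroll + vd * DAY,
                                       round(float(np.clip(rng.normal(65, 12), 35, 140)), 1)))
                n_visits = len(vdays)
                if prior_event_date is not None:
                    event_rows.append((f"{pid}-e0", pid,
                                       AIDS_EVENT_CODES[int(rng.integers(0, len(AIDS_EVENT_CODES)))],
                                       prior_event_date))
                    n_events = 1
                death_date = None
                death_cause = None

            pat_rows.append((
                pid, site, country, birth, "male" if male else "female", mode,
                enroll, "yes" if base_aids else "no", cdc, who,
                "yes" if baseline_aids_true else "no",
                (prior_event_date if prior_event_date is not None else None),
                "yes" if death_ind else "no", death_date, death_cause,
            ))
            if initiates:
                excl = "under_18" if age_at_art < 18.0 else "none"
            else:
                excl = "never_art"
            log_rows.append((
                pid, site, country, "male" if male else "female",
                age_at_art, ivdu, baseline_aids_true, cd4_0, reg_class, regimen,
                art_start, init_year, t_death_d, death_ind, t_aids_d, aids_ind,
                excl == "none", excl, under18,
                n_visits, n_labs, n_art, n_events,
            ))

    patients = pd.DataFrame(pat_rows, columns=TABLE_COLUMNS["patients"])
    visits = pd.DataFrame(visit_rows, columns=TABLE_COLUMNS["visits"])
    labs = pd.DataFrame(lab_rows, columns=TABLE_COLUMNS["labs"])
    art = pd.DataFrame(art_rows, columns=TABLE_COLUMNS["art"])
    events = pd.DataFrame(event_rows, columns=TABLE_COLUMNS["events"])
    for name, df in (("patients", patients), ("visits", visits), ("labs", labs),
                     ("art", art), ("events", events)):
        for c in DATE_COLUMNS[name]:
            df[c] = pd.to_datetime(df[c])

    truth_log = pd.DataFrame(log_rows, columns=[
        "patient_id", "site_id", "country", "sex", "age_at_art", "ivdu",
        "baseline_aids", "baseline_cd4", "regimen_class", "regimen",
        "art_initiation_date", "initiation_year",
        "t_death_days", "death_indicator", "t_aids_days", "aids_indicator",
        "included", "exclusion_reason", "under_18",
        "n_visits", "n_labs", "n_art", "n_events",
    ])

    ds = DatasetVersion(label="truth", patients=patients, visits=visits,
                        labs=labs, art=art, events=events, freeze_dates=freeze)
    return ds, truth_log
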