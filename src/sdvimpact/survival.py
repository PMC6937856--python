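"""Survival estimators for the paired analyses.

Product-limit (Kaplan–Meier) estimation with Greenwood variance and log–log
confidence intervals; cumulative incidence at a horizon as 1 − S(t);
restricted cubic spline bases (truncated-power form, linear beyond the
boundary knots) with Harrell's default knot percentiles; and Cox
proportional-hazards fitting by maximising the stratified partial likelihood
with Newton–Raphson and step-halving, Efron (default) or Breslow ties.

Continuous covariates enter the Cox design through a 4-knot restricted
cubic spline; hazard-ratio contrasts of spline-coded variables are computed
at stated values against a reference value with delta-method intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

Z95 = stats.norm.ppf(0.975)


# ---------------------------------------------------------------------------
# Kaplan–Meier
# ---------------------------------------------------------------------------

@dataclass
class StepSurvival:
    """Right-continuous step survival estimate on the event-time grid."""

    times: np.ndarray           # distinct event times (days), ascending
    survival: np.ndarray        # S(t) at each time
    variance: np.ndarray        # Greenwood variance of S(t)
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_risk: np.ndarray
    n_event: np.ndarray
    n: int = 0

    def survival_at(self, t: float) -> float:
        i = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if i < 0 else float(self.survival[i])


def km_estimate(times, events) -> StepSurvival:
    """Product-limit estimator with Greenwood variance and log–log 95% CIs."""
    t = np.asarray(times, float)
    d = np.asarray(events, bool)
    if t.size == 0:
        raise ValueError("empty input")
    if t.size != d.size:
        raise ValueError("times and events must have the same length")
    if (t < 0).any():
        raise ValueError("negative times")

    order = np.argsort(t, kind="stable")
    t, d = t[order], d[order]
    ev_times = np.unique(t[d])
    if ev_times.size == 0:
        one = np.array([1.0])
        tt = np.array([float(t.max())])
        return StepSurvival(tt, one, np.zeros(1), one, one,
                            np.array([t.size]), np.zeros(1, int), n=t.size)

    n_risk = t.size - np.searchsorted(t, ev_times, side="left")
    d_times = np.sort(t[d])
    n_event = (np.searchsorted(d_times, ev_times, side="right")
               - np.searchsorted(d_times, ev_times, side="left"))
    frac = 1.0 - n_event / n_risk
    surv = np.cumprod(frac)
    # Greenwood: Var(S) = S^2 * sum d/(n(n-d)); terms with n == d give S = 0
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = n_event / (n_risk * (n_risk - n_event))
        gw = np.cumsum(np.where(np.isfinite(terms), terms, 0.0))
        var = surv ** 2 * gw
        # log–log transformed CI: exp(-exp(log(-log S) -+ z * se))
        se_cll = np.sqrt(gw) / np.abs(np.log(surv))
        log_neglog = np.log(-np.log(surv))
        lo = np.exp(-np.exp(log_neglog + Z95 * se_cll))
        hi = np.exp(-np.exp(log_neglog - Z95 * se_cll))
    lo = np.where(surv <= 0.0, 0.0, lo)
    hi = np.where(surv <= 0.0, 0.0, hi)
    lo = np.where(surv >= 1.0, 1.0, np.nan_to_num(lo, nan=0.0))
    hi = np.where(surv >= 1.0, 1.0, np.nan_to_num(hi, nan=1.0))
    return StepSurvival(ev_times, surv, var, lo, hi, n_risk, n_event, n=t.size)


def incidence_at(s: StepSurvival, horizon: float) -> tuple[float, tuple[float, float], bool]:
    """Cumulative incidence 1 − S at a horizon, with transformed CI.

    Uses the last step at or before the horizon; if the horizon exceeds the
    last follow-up time the last value is returned with the extrapolation
    flag set.
    """
    if horizon < 0:
        raise ValueError("horizon must be >= 0")
    i = int(np.searchsorted(s.times, horizon, side="right")) - 1
    extrapolated = horizon > float(s.times[-1])
    if i < 0:
        return 0.0, (0.0, 0.0), False
    inc = 1.0 - float(s.survival[i])
    ci = (1.0 - float(s.ci_high[i]), 1.0 - float(s.ci_low[i]))
    return inc, ci, extrapolated


# ---------------------------------------------------------------------------
# restricted cubic splines
# ---------------------------------------------------------------------------

#: Harrell's default knot quantiles for k = 4
KNOT_QUANTILES_4 = (0.05, 0.35, 0.65, 0.95)


def place_knots(x, k: int = 4) -> np.ndarray:
    """Knots at the standard outer/inner percentiles (5/35/65/95 for k=4)."""
    x = np.asarray(x, float)
    x = x[np.isfinite(x)]
    if np.unique(x).size < k:
        raise ValueError(
            f"need >= {k} distinct values to place {k} knots; "
            "drop the spline for this variable")
    if k == 4:
        qs = KNOT_QUANTILES_4
    else:
        lo, hi = 0.05, 0.95
        qs = np.linspace(lo, hi, k)
    knots = np.quantile(x, qs)
    if np.unique(knots).size < k:  # heavy ties: fall back to distinct quantiles
        knots = np.quantile(np.unique(x), qs)
    knots = np.sort(knots)
    if np.unique(knots).size < k:
        raise ValueError("could not place strictly increasing knots")
    return knots


def rcs_basis(x, knots) -> np.ndarray:
    """Restricted cubic spline design columns (truncated-power form).

    Column 0 is the linear term; columns 1..k−2 are the restricted cubic
    terms normalised by (t_k − t_1)², linear beyond the boundary knots.
    """
    x = np.asarray(x, float)
    if not np.isfinite(x).all():
        raise ValueError("x contains non-finite values")
    t = np.asarray(knots, float)
    k = t.size
    norm = (t[-1] - t[0]) ** 2

    def cube(u):
        return np.clip(u, 0.0, None) ** 3

    cols = [x]
    for j in range(k - 2):
        term = (cube(x - t[j])
                - cube(x - t[k - 2]) * (t[k - 1] - t[j]) / (t[k - 1] - t[k - 2])
                + cube(x - t[k - 1]) * (t[k - 2] - t[j]) / (t[k - 1] - t[k - 2]))
        cols.append(term / norm)
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# Cox partial likelihood
# ---------------------------------------------------------------------------

@dataclass
class CovariateTerm:
    """One model term: ``kind`` is ``rcs`` (4-knot restricted cubic spline),
    ``linear``, ``binary`` (yes/no -> 1/0) or ``categorical`` (reference +
    dummy columns)."""

    name: str
    kind: str
    reference: str | None = None
    levels: tuple | None = None
    knots: np.ndarray | None = None


DEFAULT_COVARIATES = [
    CovariateTerm("age_at_art", "rcs"),
    CovariateTerm("sex", "categorical", reference="female"),
    CovariateTerm("ivdu", "binary"),
    CovariateTerm("clinical_aids_at_baseline", "binary"),
    CovariateTerm("baseline_cd4", "rcs"),
    CovariateTerm("regimen_class", "categorical", reference="NNRTI"),
    CovariateTerm("initiation_year", "rcs"),
]


@dataclass
class CoxFit:
    """Fitted stratified Cox model."""

    coef: pd.Series
    cov: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    ties: str
    strata_labels: list
    terms: list = field(default_factory=list)
    n: int = 0
    n_events: int = 0
    n_dropped: int = 0
    messages: list = field(default_factory=list)

    def hr_table(self) -> pd.DataFrame:
        se = np.sqrt(np.diag(self.cov))
        return pd.DataFrame({
            "coef": self.coef, "se": se, "hr": np.exp(self.coef),
            "hr_low": np.exp(self.coef - Z95 * se),
            "hr_high": np.exp(self.coef + Z95 * se)})


def build_design(table: pd.DataFrame, terms: list[CovariateTerm]
                 ) -> tuple[np.ndarray, list[str], list[CovariateTerm], np.ndarray]:
    """Design matrix for the included complete-case rows.

    Returns (X, column names, resolved terms with knots/levels filled in,
    boolean complete-case mask over the input rows).
    """
    resolved: list[CovariateTerm] = []
    complete = np.ones(len(table), bool)
    for t in terms:
        v = table[t.name]
        if t.kind in ("rcs", "linear"):
            complete &= pd.to_numeric(v, errors="coerce").notna().to_numpy()
        else:
            complete &= v.notna().to_numpy()
    sub = table[complete]
    cols, names = [], []
    for t in terms:
        v = sub[t.name]
        if t.kind == "rcs":
            knots = t.knots if t.knots is not None else place_knots(v.to_numpy(float), 4)
            B = rcs_basis(v.to_numpy(float), knots)
            cols.append(B)
            names += [t.name] + [t.name + "'" * (j + 1) for j in range(B.shape[1] - 1)]
            resolved.append(CovariateTerm(t.name, "rcs", knots=np.asarray(knots)))
        elif t.kind == "linear":
            cols.append(v.to_numpy(float)[:, None])
            names.append(t.name)
            resolved.append(t)
        elif t.kind == "binary":
            x = (v.astype(str).isin(["yes", "True", "true", "1"])).to_numpy(float)
            cols.append(x[:, None])
            names.append(f"{t.name}=yes")
            resolved.append(CovariateTerm(t.name, "binary", reference="no",
                                          levels=("no", "yes")))
        elif t.kind == "categorical":
            levels = t.levels or tuple(sorted(v.astype(str).unique()))
            ref = t.reference if t.reference is not None else levels[0]
            others = [l for l in levels if l != ref]
            for l in others:
                cols.append((v.astype(str) == l).to_numpy(float)[:, None])
                names.append(f"{t.name}={l}")
            resolved.append(CovariateTerm(t.name, "categorical", reference=ref,
                                          levels=tuple([ref] + others)))
        else:
            raise ValueError(f"unknown term kind {t.kind!r}")
    X = np.hstack(cols) if cols else np.empty((len(sub), 0))
    return X, names, resolved, complete


def _stratum_contrib(beta, X, time, event, ties):
    """(loglik, gradient, hessian) of one stratum's partial likelihood."""
    p = X.shape[1]
    eta = X @ beta
    eta -= eta.max()  # stabilise exponentials; cancels in all ratios
    w = np.exp(eta)
    order = np.argsort(-time, kind="stable")
    X, time, event, w, eta = X[order], time[order], event[order], w[order], eta[order]
    wx = w[:, None] * X
    wxx = np.einsum("i,ij,ik->ijk", w, X, X)
    cw = np.cumsum(w)
    cwx = np.cumsum(wx, axis=0)
    cwxx = np.cumsum(wxx, axis=0)

    ll = 0.0
    g = np.zeros(p)
    H = np.zeros((p, p))
    i = 0
    n = len(time)
    while i < n:
        j = i
        while j < n and time[j] == time[i]:
            j += 1
        ev = np.arange(i, j)[event[i:j]]
        d = ev.size
        if d:
            S0 = cw[j - 1]
            S1 = cwx[j - 1]
            S2 = cwxx[j - 1]
            ll += eta[ev].sum()
            if ties == "breslow" or d == 1:
                for _ in range(d):
                    ll -= np.log(S0) * 1.0
                    mu = S1 / S0
                    g += -mu
                    H += -(S2 / S0 - np.outer(mu, mu))
                ll += 0.0
                g += X[ev].sum(axis=0)
            else:  # Efron
                wD = w[ev].sum()
                wDx = wx[ev].sum(axis=0)
                wDxx = wxx[ev].sum(axis=0)
                g += X[ev].sum(axis=0)
                for l in range(d):
                    f = l / d
                    denom = S0 - f * wD
                    num1 = S1 - f * wDx
                    num2 = S2 - f * wDxx
                    ll -= np.log(denom)
                    mu = num1 / denom
                    g -= mu
                    H -= num2 / denom - np.outer(mu, mu)
        i = j
    return ll, g, H


def cox_fit(table: pd.DataFrame, outcome: str = "death",
            covariates: list[CovariateTerm] | None = None,
            strata: str | None = "analysis_site", ties: str = "efron",
            tol: float = 1e-6, max_iter: int = 100) -> CoxFit:
    """Fit a site-stratified Cox model on the included analysis rows.

    ``outcome`` is ``death`` (time to death or censoring) or ``aids`` (time
    to first AIDS-defining event, with death treated as censoring — the
    cause-specific hazard). Rows with a missing covariate are dropped
    (complete-case) and counted. Newton–Raphson with step-halving; converged
    when max |gradient| < ``tol``, flagged otherwise after ``max_iter``.
    """
    if outcome == "death":
        tcol, ecol = "time_to_death_or_censor", "death_indicator"
    elif outcome == "aids":
        tcol, ecol = "time_to_aids_or_censor", "aids_indicator"
    else:
        raise ValueError(f"unknown outcome {outcome!r}")
    terms = covariates if covariates is not None else DEFAULT_COVARIATES

    df = table[table["included"]].copy() if "included" in table else table.copy()
    df = df[pd.to_numeric(df[tcol], errors="coerce").notna()]
    X, names, resolved, complete = build_design(df, terms)
    sub = df[complete]
    n_dropped = int(len(df) - len(sub))
    time = sub[tcol].to_numpy(float)
    event = sub[ecol].astype(bool).to_numpy()
    if strata is not None and strata in sub:
        labels = sub[strata].astype(str).to_numpy()
    else:
        labels = np.array(["_all_"] * len(sub))

    messages: list[str] = []
    strata_data = []
    kept_labels = []
    for lab in sorted(set(labels)):
        m = labels == lab
        if not event[m].any():
            messages.append(f"stratum {lab!r} has no events; dropped from the likelihood")
            continue
        strata_data.append((X[m], time[m], event[m]))
        kept_labels.append(lab)

    p = X.shape[1]
    beta = np.zeros(p)

    def evaluate(b):
        ll, g, H = 0.0, np.zeros(p), np.zeros((p, p))
        for Xs, ts, es in strata_data:
            l_, g_, H_ = _stratum_contrib(b, Xs, ts, es, ties)
            ll += l_
            g += g_
            H += H_
        return ll, g, H

    converged = False
    n_iter = 0
    ll, g, H = evaluate(beta)
    for n_iter in range(1, max_iter + 1):
        if np.max(np.abs(g)) < tol:
            converged = True
            break
        try:
            step = linalg.solve(-H, g, assume_a="sym")
        except linalg.LinAlgError:
            step = np.linalg.pinv(-H) @ g
            messages.append("singular information matrix; pseudo-inverse step")
        # step-halving; declines within floating-point noise of the
        # log-likelihood magnitude are accepted as converged steps
        noise = 1e-9 * (abs(ll) + 1.0)
        for _ in range(30):
            ll_new, g_new, H_new = evaluate(beta + step)
            if np.isfinite(ll_new) and ll_new >= ll - noise:
                break
            step = step / 2.0
        beta = beta + step
        ll, g, H = ll_new, g_new, H_new
    else:
        messages.append("maximum iterations reached without convergence")
    if converged is False and np.max(np.abs(g)) < tol:
        converged = True
    if not converged:
        messages.append("possible separation / monotone likelihood")

    neg_H = -H
    try:
        cov = linalg.inv(neg_H)
    except linalg.LinAlgError:
        cov = np.linalg.pinv(neg_H)
    cov = (cov + cov.T) / 2.0
    return CoxFit(coef=pd.Series(beta, index=names), cov=cov, loglik=float(ll),
                  converged=converged, n_iter=n_iter, ties=ties,
                  strata_labels=kept_labels, terms=resolved, n=int(len(sub)),
                  n_events=int(event.sum()), n_dropped=n_dropped,
                  messages=messages)


def _term_columns(fit: CoxFit, name: str) -> tuple[CovariateTerm, list[int]]:
    for t in fit.terms:
        if t.name == name:
            idx = [i for i, c in enumerate(fit.coef.index)
                   if c == name or c.startswith(name + "'") or c.startswith(name + "=")]
            return t, idx
    raise KeyError(f"variable {name!r} not in fit")


def _basis_row(term: CovariateTerm, value) -> np.ndarray:
    if term.kind == "rcs":
        return rcs_basis(np.array([float(value)]), term.knots)[0]
    if term.kind == "linear":
        return np.array([float(value)])
    if term.kind == "binary":
        return np.array([1.0 if str(value) in ("yes", "True", "true", "1") else 0.0])
    # categorical dummies in fit order (levels[1:])
    return np.array([1.0 if str(value) == l else 0.0 for l in term.levels[1:]])


def hr_contrast(fit: CoxFit, variable: str, value, reference
                ) -> tuple[float, tuple[float, float]]:
    """Hazard ratio for ``variable`` at ``value`` vs ``reference``.

    HR = exp(Δbᵀβ) where Δb is the difference of the variable's design-basis
    rows; the CI is delta-method on the log scale. The reference contrast is
    exactly 1 with a degenerate interval.
    """
    term, idx = _term_columns(fit, variable)
    db = _basis_row(term, value) - _basis_row(term, reference)
    beta = fit.coef.to_numpy()[idx]
    V = fit.cov[np.ix_(idx, idx)]
    log_hr = float(db @ beta)
    se = float(np.sqrt(max(db @ V @ db, 0.0)))
    return (float(np.exp(log_hr)),
            (float(np.exp(log_hr - Z95 * se)), float(np.exp(log_hr + Z95 * se))))
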