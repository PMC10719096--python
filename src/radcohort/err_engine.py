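"""Stratified linear excess-relative-risk models on the attained-age scale.

The incidence rate is modelled as ``lambda0(t; stratum) * (1 + beta Z(t))``
where ``Z`` is the lagged cumulative ABM dose (or exam count) and ``t`` is
exact attained age.  Inference is by the stratified partial likelihood: at
each case's diagnosis age the case is compared with all members of the same
(sex, country, birth cohort[, ses]) stratum whose at-risk window covers that
age,

    l(beta) = sum_cases [ log(1 + beta Z_case) - log sum_j (1 + beta Z_j) ].

``beta`` is admissible on ``(-1/max Z, inf)``; the 95% CI is the profile-
likelihood interval {beta : 2[l(beta_hat) - l(beta)] <= chi2_{1,0.95}}.
Categorical dose effects use the same partial likelihood with a
log-linear (multiplicative) parameter per category, Wald CIs from the
observed information, and a trend test that replaces the indicators by an
ordinal score.  Effect modification is tested by a likelihood-ratio test of
window-specific betas against a common beta.

Tied event ages receive Breslow handling (each case sees the full risk-set
denominator); with continuous simulated ages exact ties have measure zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .cohort_data import Cohort, classify_outcome
from .dosimetry import DEFAULT_CUTPOINTS, categorize_dose

__all__ = [
    "BIRTH_COHORT_EDGES",
    "CategoricalFitResult",
    "ERRFitResult",
    "HeterogeneityTestResult",
    "RiskSet",
    "TrendTestResult",
    "assign_birth_cohort",
    "build_risk_sets",
    "fit_categorical_rr",
    "fit_linear_err",
    "linear_err_loglik",
    "test_heterogeneity",
    "test_trend",
]

CHI2_95_1DF = float(stats.chi2.ppf(0.95, 1))          # 3.841...
BIRTH_COHORT_EDGES = (1960, 1980, 1985, 1990, 1995, 2000, 2005, 2013)

_BETA_CAP = 1e4        # admissible-region search cap, per mGy
_EPS = 1e-12


def assign_birth_cohort(birth_year, edges=BIRTH_COHORT_EDGES) -> np.ndarray:
    """Label birth years with half-open cohort bins like '1990-1994'."""
    e = np.asarray(edges)
    y = np.asarray(birth_year, float)
    idx = np.clip(np.searchsorted(e, y, side="right") - 1, 0, len(e) - 2)
    labels = np.array([f"{e[i]}-{e[i + 1] - 1}" for i in range(len(e) - 1)])
    return labels[idx]


@dataclass
class RiskSet:
    """One case's comparison set at its exact diagnosis age.

    ``exposures`` has the case at row 0; shape (n_members,) for a scalar
    metric or (n_members, n_windows) for windowed decompositions.
    ``member_idx`` indexes the cohort's persons table (case first).
    """

    event_age: float
    stratum: tuple
    case_id: str
    member_idx: np.ndarray
    exposures: np.ndarray
    window_labels: tuple | None = None

    @property
    def n(self) -> int:
        return len(self.member_idx)

    @property
    def case_exposure(self) -> np.ndarray | float:
        return self.exposures[0]


# ---------------------------------------------------------------------------
# Risk-set construction

def _endpoint_case_mask(outcomes: pd.DataFrame, mapping: pd.DataFrame,
                        endpoint: str) -> np.ndarray:
    """Boolean mask over outcome rows that belong to the endpoint group."""
    cache: dict[tuple[str, int], bool] = {}
    out = np.zeros(len(outcomes), dtype=bool)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i, (code, beh) in enumerate(zip(outcomes["morphology_code"],
                                            outcomes["behavior_code"])):
            k = (str(code), int(beh))
            if k not in cache:
                cache[k] = endpoint in classify_outcome(k[0], k[1], mapping)
            out[i] = cache[k]
    return out


def build_risk_sets(cohort: Cohort, endpoint: str = "all_heme",
                    strata_vars: tuple = ("sex", "country", "birth_cohort"),
                    lag: float = 2.0, metric: str = "abm_dose_mean",
                    windows=None, window_by: str = "age_at_exposure",
                    interaction: str | None = None,
                    control_sample: int | None = None,
                    rng: np.random.Generator | None = None
                    ) -> list[RiskSet]:
    """Materialize one risk set per case of the endpoint.

    Members are all persons of the case's stratum with
    ``entry < event_age <= exit``; exposures are lagged cumulative doses
    evaluated at the event age.  With ``windows`` the exposure is a vector
    decomposed by age at exposure or time since exposure; with
    ``interaction`` (a persons column such as ``sex``) the scalar dose is
    routed into one column per subgroup level.  ``control_sample`` draws a
    uniform subsample of non-cases per risk set (nested case-control mode);
    the partial likelihood is unchanged.
    """
    cohort = cohort.with_followup()
    persons = cohort.persons.reset_index(drop=True)
    fu = cohort.followup.set_index("person_id")

    meta = persons.copy()
    if "birth_cohort" in strata_vars and "birth_cohort" not in meta:
        meta["birth_cohort"] = assign_birth_cohort(meta["birth_date"])
    for v in strata_vars:
        if v not in meta:
            raise ValueError(f"stratum variable {v!r} not in persons table")
    meta["entry_age"] = fu["entry_age"].reindex(meta["person_id"]).to_numpy()
    meta["exit_age"] = fu["exit_age"].reindex(meta["person_id"]).to_numpy()

    # exposure metric per exam
    exams = cohort.exams
    if metric == "exam_count":
        exam_dose = np.ones(len(exams))
    else:
        if cohort.dose_summary is None or metric not in cohort.dose_summary:
            raise ValueError(f"cohort lacks dose summary column {metric!r}")
        exam_dose = exams["exam_id"].map(
            cohort.dose_summary.set_index("exam_id")[metric]).to_numpy(float)

    # cases of the endpoint among included persons whose exit is a diagnosis
    case_mask = _endpoint_case_mask(cohort.outcomes, cohort.mapping, endpoint)
    cases = cohort.outcomes.loc[case_mask, ["person_id", "age_at_diagnosis"]]
    cases = cases.merge(meta[["person_id", "entry_age", "exit_age"]],
                        on="person_id")
    ok = (cases["entry_age"] < cases["age_at_diagnosis"]) & \
         (cases["age_at_diagnosis"] <= cases["exit_age"])
    cases = cases[ok]
    if cases.empty:
        return []

    if interaction is not None:
        if interaction == "birth_cohort" and "birth_cohort" not in meta:
            meta["birth_cohort"] = assign_birth_cohort(meta["birth_date"])
        levels = tuple(sorted(meta[interaction].astype(str).unique()))

    # integer stratum codes, persons grouped by code once
    strat_df = pd.DataFrame({v: meta[v] for v in strata_vars})
    codes, stratum_keys = pd.factorize(
        pd.MultiIndex.from_frame(strat_df), sort=True)
    n_strata = len(stratum_keys)
    p_order = np.argsort(codes, kind="stable")
    p_starts = np.searchsorted(codes[p_order], np.arange(n_strata + 1))
    local_of = np.empty(len(meta), dtype=np.intp)
    for s in range(n_strata):
        blk = p_order[p_starts[s]:p_starts[s + 1]]
        local_of[blk] = np.arange(len(blk))
    pos = pd.Series(meta.index.to_numpy(), index=meta["person_id"])

    entry_all = meta["entry_age"].to_numpy(float)
    exit_all = meta["exit_age"].to_numpy(float)

    # exams grouped by (stratum, age) once
    exam_pidx = exams["person_id"].map(pos).to_numpy(dtype=np.intp)
    exam_age = exams["age_at_exam"].to_numpy(float)
    e_codes = codes[exam_pidx]
    e_order = np.lexsort((exam_age, e_codes))
    e_starts = np.searchsorted(e_codes[e_order], np.arange(n_strata + 1))
    exam_age_s = exam_age[e_order]
    exam_dose_s = exam_dose[e_order]
    exam_owner_s = local_of[exam_pidx[e_order]]

    case_pidx = cases["person_id"].map(pos).to_numpy(dtype=np.intp)
    case_age = cases["age_at_diagnosis"].to_numpy(float)
    case_codes = codes[case_pidx]
    c_order = np.lexsort((case_age, case_codes))

    risk_sets: list[RiskSet] = []
    for ci_ in c_order:
        s = case_codes[ci_]
        stratum = tuple(stratum_keys[s])
        g_idx = p_order[p_starts[s]:p_starts[s + 1]]
        entry = entry_all[g_idx]
        exit_ = exit_all[g_idx]
        s_age = exam_age_s[e_starts[s]:e_starts[s + 1]]
        s_dose = exam_dose_s[e_starts[s]:e_starts[s + 1]]
        s_owner = exam_owner_s[e_starts[s]:e_starts[s + 1]]

        if interaction is not None:
            lvl = meta[interaction].astype(str).to_numpy()[g_idx]
            lvl_idx = np.searchsorted(np.array(levels), lvl)

        t = float(case_age[ci_])
        case_person_id = meta["person_id"].to_numpy()[case_pidx[ci_]]
        at_risk = (entry < t) & (t <= exit_)
        case_loc = int(local_of[case_pidx[ci_]])
        at_risk[case_loc] = True   # the case belongs to its own risk set
        members = np.flatnonzero(at_risk)
        # case first
        members = np.r_[case_loc,
                        members[members != case_loc]]
        if control_sample is not None and \
                len(members) - 1 > control_sample:
            if rng is None:
                rng = np.random.default_rng(0)
            picked = rng.choice(members[1:], size=control_sample,
                                replace=False)
            members = np.r_[members[0], picked]

        k = int(np.searchsorted(s_age, t - lag, side="right"))
        if windows is None and interaction is None:
            z_all = np.bincount(s_owner[:k], weights=s_dose[:k],
                                minlength=len(g_idx))
            expo = z_all[members]
            wl = None
        elif windows is not None:
            wins = [(float(a), float(b)) for a, b in windows]
            axis = (s_age[:k] if window_by == "age_at_exposure"
                    else t - s_age[:k])
            m = len(wins)
            z = np.zeros((len(g_idx), m))
            for w, (lo_w, hi_w) in enumerate(wins):
                inw = (axis >= lo_w) & (axis < hi_w)
                if inw.any():
                    z[:, w] = np.bincount(s_owner[:k][inw],
                                          weights=s_dose[:k][inw],
                                          minlength=len(g_idx))
            expo = z[members]
            wl = tuple(f"{a}-{b}" for a, b in wins)
        else:
            z_all = np.bincount(s_owner[:k], weights=s_dose[:k],
                                minlength=len(g_idx))
            m = len(levels)
            z = np.zeros((len(g_idx), m))
            z[np.arange(len(g_idx)), lvl_idx] = z_all
            expo = z[members]
            wl = levels

        if len(members) == 1:
            warnings.warn(f"case {case_person_id} has no stratum peers "
                          "at risk; risk set is uninformative")
        risk_sets.append(RiskSet(
            event_age=t, stratum=stratum,
            case_id=str(case_person_id),
            member_idx=g_idx[members], exposures=expo,
            window_labels=wl))
    return risk_sets


# ---------------------------------------------------------------------------
# Linear ERR likelihood

@dataclass
class _LinearStats:
    """Sufficient statistics of the linear model: per risk set the case
    exposure, member count and member exposure sum (the denominator of the
    partial likelihood is linear in them)."""

    z_case: np.ndarray        # (R, m)
    s: np.ndarray             # (R, m) member exposure sums
    n: np.ndarray             # (R,)
    max_z: float              # largest single member exposure component
    members: list = field(default_factory=list, repr=False)

    @property
    def m(self) -> int:
        return self.z_case.shape[1]


def _linear_stats(risk_sets: list[RiskSet]) -> _LinearStats:
    mats = [np.atleast_2d(rs.exposures.T).T for rs in risk_sets]
    m = mats[0].shape[1]
    z_case = np.array([a[0] for a in mats]).reshape(len(mats), m)
    s = np.array([a.sum(axis=0) for a in mats]).reshape(len(mats), m)
    n = np.array([a.shape[0] for a in mats], float)
    max_z = max(float(a.max(initial=0.0)) for a in mats)
    return _LinearStats(z_case, s, n, max_z, mats)


def linear_err_loglik(beta, risk_sets: list[RiskSet],
                      stats_cache: _LinearStats | None = None) -> float:
    """Stratified partial log-likelihood of RR = 1 + beta.Z.

    ``beta`` is a scalar or a vector matching the exposure columns; returns
    ``-inf`` when any member's relative risk is non-positive.
    """
    st = stats_cache if stats_cache is not None else _linear_stats(risk_sets)
    b = np.atleast_1d(np.asarray(beta, float))
    rr_case = 1.0 + st.z_case @ b
    denom = st.n + st.s @ b
    if (b >= 0).all():
        if (rr_case <= 0).any() or (denom <= 0).any():   # cannot happen, Z>=0
            return -np.inf
    else:
        for mat in st.members:
            if ((1.0 + mat @ b) <= 0).any():
                return -np.inf
    return float(np.log(rr_case).sum() - np.log(denom).sum())


@dataclass
class ERRFitResult:
    """Linear ERR fit.  ``beta_hat`` is per mGy (or per exam); multiply by
    100 for the conventional ERR/100 mGy scale (see err_per_100)."""

    beta_hat: float
    loglik: float
    ci_low: float
    ci_high: float
    n_cases: int
    boundary_flag: bool = False
    status: str = "ok"

    @property
    def err_per_100(self) -> float:
        return 100.0 * self.beta_hat

    @property
    def ci_per_100(self) -> tuple[float, float]:
        return 100.0 * self.ci_low, 100.0 * self.ci_high


def _is_informative(st: _LinearStats) -> bool:
    """True when some risk set shows exposure variation across members."""
    for mat in st.members:
        if len(mat) > 1 and (np.ptp(mat, axis=0) > 0).any():
            return True
    return False


def fit_linear_err(risk_sets: list[RiskSet], cap: float = _BETA_CAP,
                   alpha: float = 0.05) -> ERRFitResult:
    """Maximize the linear-ERR partial likelihood; profile-likelihood CI.

    The admissible region is ``(-1/max Z + eps, cap)``; a CI bound (or the
    estimate) hitting either edge sets ``boundary_flag``.  A flat likelihood
    (no within-stratum exposure variation) yields status
    ``non_identifiable`` with NaN estimates rather than a number.
    """
    if not risk_sets:
        return ERRFitResult(np.nan, np.nan, np.nan, np.nan, 0,
                            status="no_cases")
    st = _linear_stats(risk_sets)
    if st.m != 1:
        raise ValueError("fit_linear_err expects a scalar exposure; use "
                         "test_heterogeneity for windowed fits")
    n_cases = len(risk_sets)
    if not _is_informative(st):
        return ERRFitResult(np.nan, linear_err_loglik(0.0, risk_sets, st),
                            np.nan, np.nan, n_cases,
                            status="non_identifiable")
    lo = -1.0 / st.max_z + _EPS if st.max_z > 0 else -cap
    lo = lo * (1 - 1e-9) + 1e-15   # stay strictly inside

    def nll(b: float) -> float:
        v = linear_err_loglik(b, risk_sets, st)
        return -v if np.isfinite(v) else 1e12

    res = optimize.minimize_scalar(nll, bounds=(lo + abs(lo) * 1e-9, cap),
                                   method="bounded",
                                   options={"xatol": 1e-10})
    beta_hat = float(res.x)
    llmax = -float(res.fun)
    boundary = beta_hat - lo < 1e-6 * max(1.0, abs(lo)) or \
        cap - beta_hat < 1e-6 * cap

    crit = stats.chi2.ppf(1 - alpha, 1)
    target = llmax - crit / 2.0

    def dev(b: float) -> float:
        return linear_err_loglik(b, risk_sets, st) - target

    # left bound
    b_edge = lo + abs(lo) * 1e-9 if lo != 0 else _EPS
    if dev(b_edge) > 0:
        ci_low, boundary = b_edge, True
    else:
        ci_low = float(optimize.brentq(dev, b_edge, beta_hat, xtol=1e-12))
    # right bound
    if dev(cap) > 0:
        ci_high, boundary = cap, True
    else:
        ci_high = float(optimize.brentq(dev, beta_hat, cap, xtol=1e-12))
    return ERRFitResult(beta_hat, llmax, ci_low, ci_high, n_cases,
                        boundary_flag=bool(boundary))


# ---------------------------------------------------------------------------
# Categorical model

@dataclass
class CategoricalFitResult:
    """Multiplicative RR per dose category (reference = lowest)."""

    rr: np.ndarray
    ci_low: np.ndarray          # NaN for the reference
    ci_high: np.ndarray
    case_counts: np.ndarray
    loglik: float
    trend_p: float
    categories: tuple           # category labels kept after drops
    status: str = "ok"


def _category_stats(risk_sets: list[RiskSet], cutpoints
                    ) -> tuple[np.ndarray, np.ndarray]:
    """(counts n_{r,k}, case category c_r) for indicator exposures."""
    k_max = len(cutpoints) + 1
    counts = np.zeros((len(risk_sets), k_max))
    case_cat = np.zeros(len(risk_sets), dtype=int)
    for r, rs in enumerate(risk_sets):
        cat = categorize_dose(np.asarray(rs.exposures, float), cutpoints)
        counts[r] = np.bincount(cat, minlength=k_max)
        case_cat[r] = cat[0]
    return counts, case_cat


def _cond_logit_loglik(gamma_full: np.ndarray, counts: np.ndarray,
                       case_cat: np.ndarray) -> float:
    eg = np.exp(gamma_full)
    denom = counts @ eg
    return float(gamma_full[case_cat].sum() - np.log(denom).sum())


def fit_categorical_rr(risk_sets: list[RiskSet],
                       cutpoints=DEFAULT_CUTPOINTS) -> CategoricalFitResult:
    """Conditional (partial) likelihood fit of log-linear category effects.

    Categories with neither cases nor person-time are dropped with a
    warning.  Wald CIs are ``exp(gamma +- 1.96 SE)`` with SEs from the
    numerically differentiated observed information.
    """
    from statsmodels.tools.numdiff import approx_hess2

    counts, case_cat = _category_stats(risk_sets, cutpoints)
    k_max = counts.shape[1]
    occupied = (counts.sum(axis=0) > 0)
    if not occupied.all():
        dropped = np.flatnonzero(~occupied)
        warnings.warn(f"dose categories {dropped.tolist()} have no "
                      "person-time; dropped")
    keep = np.flatnonzero(occupied)
    remap = -np.ones(k_max, dtype=int)
    remap[keep] = np.arange(len(keep))
    counts = counts[:, keep]
    case_cat = remap[case_cat]
    k_eff = len(keep)

    def nll(free: np.ndarray) -> float:
        g = np.concatenate([[0.0], free])
        return -_cond_logit_loglik(g, counts, case_cat)

    def grad(free: np.ndarray) -> np.ndarray:
        g = np.concatenate([[0.0], free])
        eg = np.exp(g)
        w = counts * eg
        p = w / w.sum(axis=1, keepdims=True)
        obs = np.zeros(k_eff)
        np.add.at(obs, case_cat, 1.0)
        return (p.sum(axis=0) - obs)[1:]

    if k_eff == 1:
        gamma = np.zeros(1)
        ll = -nll(np.zeros(0))
    else:
        x0 = np.zeros(k_eff - 1)
        res = optimize.minimize(nll, x0, jac=grad, method="BFGS",
                                options={"gtol": 1e-10, "maxiter": 500})
        gamma = np.concatenate([[0.0], res.x])
        ll = -float(res.fun)

    se = np.full(k_eff, np.nan)
    if k_eff > 1:
        hess = approx_hess2(res.x, nll)
        try:
            cov = np.linalg.inv(hess)
            se[1:] = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            pass
    z = stats.norm.ppf(0.975)
    rr = np.exp(gamma)
    ci_low = np.exp(gamma - z * se)
    ci_high = np.exp(gamma + z * se)
    ci_low[0] = ci_high[0] = np.nan

    case_counts = np.bincount(case_cat, minlength=k_eff)
    trend = test_trend(risk_sets, cutpoints)
    labels = _category_labels(cutpoints)
    return CategoricalFitResult(rr=rr, ci_low=ci_low, ci_high=ci_high,
                                case_counts=case_counts, loglik=ll,
                                trend_p=trend.p_value,
                                categories=tuple(labels[i] for i in keep))


def _category_labels(cutpoints) -> list[str]:
    cuts = [0.0, *cutpoints]
    labels = [f"[{a:g},{b:g})" for a, b in zip(cuts[:-1], cuts[1:])]
    labels.append(f"[{cuts[-1]:g}+]")
    return labels


# ---------------------------------------------------------------------------
# Trend test

@dataclass
class TrendTestResult:
    p_value: float
    slope: float
    lrt_statistic: float
    status: str = "ok"


def test_trend(risk_sets: list[RiskSet], cutpoints=DEFAULT_CUTPOINTS,
               score: str = "index") -> TrendTestResult:
    """LRT for a log-linear trend in RR over ordered dose categories.

    ``score='index'`` uses the category index 0,1,2,...; ``score='mean_dose'``
    uses the mean member exposure per category.
    """
    counts, case_cat = _category_stats(risk_sets, cutpoints)
    occupied = np.flatnonzero(counts.sum(axis=0) > 0)
    occupied_cases = np.unique(case_cat)
    if len(occupied_cases) < 2:
        return TrendTestResult(np.nan, np.nan, np.nan,
                               status="single_category")
    if score == "index":
        s = np.arange(counts.shape[1], dtype=float)
    elif score == "mean_dose":
        tot = np.zeros(counts.shape[1])
        for rs in risk_sets:
            expo = np.asarray(rs.exposures, float)
            cat = categorize_dose(expo, cutpoints)
            np.add.at(tot, cat, expo)
        with np.errstate(invalid="ignore"):
            s = np.where(counts.sum(axis=0) > 0,
                         tot / np.maximum(counts.sum(axis=0), 1), 0.0)
    else:
        raise ValueError(f"unknown score {score!r}")

    def nll(theta: float) -> float:
        g = theta * s
        return -_cond_logit_loglik(g, counts, case_cat)

    ll0 = -nll(0.0)
    res = optimize.minimize_scalar(nll, bounds=(-50.0, 50.0),
                                   method="bounded",
                                   options={"xatol": 1e-10})
    ll1 = -float(res.fun)
    lrt = max(2.0 * (ll1 - ll0), 0.0)
    p = float(stats.chi2.sf(lrt, 1))
    return TrendTestResult(p_value=p, slope=float(res.x), lrt_statistic=lrt)


# ---------------------------------------------------------------------------
# Effect-modification (heterogeneity) test

@dataclass
class HeterogeneityTestResult:
    betas: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    beta_common: float
    lrt_statistic: float
    df: int
    p_value: float
    window_labels: tuple | None = None
    status: str = "ok"


def _fit_vector_err(risk_sets: list[RiskSet], st: _LinearStats,
                    x0: np.ndarray) -> tuple[np.ndarray, float]:
    def nll(b: np.ndarray) -> float:
        v = linear_err_loglik(b, risk_sets, st)
        return -v if np.isfinite(v) else 1e12

    res = optimize.minimize(nll, x0, method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-9,
                                     "maxiter": 4000})
    return np.asarray(res.x, float), -float(res.fun)


def test_heterogeneity(risk_sets: list[RiskSet], ci: bool = True,
                       cap: float = _BETA_CAP) -> HeterogeneityTestResult:
    """LRT of window-specific linear slopes against a common slope.

    ``risk_sets`` must carry windowed (vector) exposures.  Windows with zero
    total exposure are non-identifiable: their beta is reported NaN and the
    degrees of freedom shrink accordingly.
    """
    st = _linear_stats(risk_sets)
    m = st.m
    if m < 2:
        raise ValueError("heterogeneity test needs >= 2 exposure windows")

    # reduced model: common beta on summed exposure
    summed = [RiskSet(rs.event_age, rs.stratum, rs.case_id, rs.member_idx,
                      np.atleast_2d(rs.exposures.T).T.sum(axis=1))
              for rs in risk_sets]
    red = fit_linear_err(summed, cap=cap)
    if red.status != "ok":
        return HeterogeneityTestResult(
            np.full(m, np.nan), np.full(m, np.nan), np.full(m, np.nan),
            np.nan, np.nan, 0, np.nan, status=red.status)

    identifiable = st.s.sum(axis=0) > 0
    df = int(identifiable.sum()) - 1
    x0 = np.where(identifiable, red.beta_hat, 0.0)
    betas, ll_full = _fit_vector_err(risk_sets, st, x0)
    ll_full = max(ll_full, red.loglik)     # nesting guard
    lrt = max(2.0 * (ll_full - red.loglik), 0.0)
    p = float(stats.chi2.sf(lrt, df)) if df > 0 else np.nan
    betas = np.where(identifiable, betas, np.nan)

    lo_ci = np.full(m, np.nan)
    hi_ci = np.full(m, np.nan)
    if ci:
        crit = CHI2_95_1DF / 2.0
        for j in range(m):
            if not identifiable[j]:
                continue
            lo_ci[j], hi_ci[j] = _profile_component(
                risk_sets, st, betas, ll_full, j, crit, cap)
    labels = risk_sets[0].window_labels
    return HeterogeneityTestResult(betas, lo_ci, hi_ci, red.beta_hat,
                                   lrt, df, p, window_labels=labels)


def _profile_component(risk_sets, st, betas, llmax, j, crit, cap
                       ) -> tuple[float, float]:
    """Profile-likelihood CI for one window's slope (others re-optimized)."""
    m = len(betas)
    others = [i for i in range(m) if i != j]

    def prof(bj: float) -> float:
        if not others:
            return linear_err_loglik(np.array([bj]), risk_sets, st)

        def nll(bo: np.ndarray) -> float:
            b = np.empty(m)
            b[j] = bj
            b[others] = bo
            v = linear_err_loglik(b, risk_sets, st)
            return -v if np.isfinite(v) else 1e12

        res = optimize.minimize(nll, betas[others], method="Nelder-Mead",
                                options={"xatol": 1e-9, "fatol": 1e-10,
                                         "maxiter": 2000})
        return -float(res.fun)

    target = llmax - crit

    def dev(bj: float) -> float:
        return prof(bj) - target

    max_zj = max(float(np.atleast_2d(mat.T).T[:, j].max(initial=0.0))
                 for mat in st.members)
    lo_edge = (-1.0 / max_zj) * (1 - 1e-9) if max_zj > 0 else -cap
    lo = lo_edge if dev(lo_edge) > 0 else float(
        optimize.brentq(dev, lo_edge, betas[j], xtol=1e-9))
    hi = cap if dev(cap) > 0 else float(
        optimize.brentq(dev, betas[j], cap, xtol=1e-9))
    return lo, hi
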