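"""Person-year tables and the additive excess-absolute-risk Poisson model.

The individual-level follow-up is collapsed onto cells cross-classified by
attained-age band, sex, country, birth cohort and cumulative-dose stratum;
each cell carries its person-years, case count and PY-weighted mean lagged
cumulative dose.  The EAR model for the cell rate is additive,

    rate = lambda_bg(stratum) + alpha * mean_dose,

with a log-linear background in the stratification factors and ``alpha``
the excess cases per person-year per mGy (canonical unit; formatters give
the conventional "per 100,000 PYs per 100 mGy" scale).  ``alpha`` gets a
profile-likelihood CI.  Small helpers convert a fitted ERR or EAR into the
familiar projection arithmetic (percent increased risk for a typical exam;
expected excess cases among 10,000 examined children).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._persontime import split_persontime
from .cohort_data import Cohort
from .dosimetry import DEFAULT_CUTPOINTS, categorize_dose
from .err_engine import _endpoint_case_mask, assign_birth_cohort

__all__ = [
    "EARFitResult",
    "ear_per_100k_py_per_100mgy",
    "ear_per_10k_py_per_100mgy",
    "err_implied_percent_increase",
    "fit_ear",
    "implied_err_per_100mgy",
    "predict_excess_cases",
    "tabulate_person_years",
]

DEFAULT_AGE_BANDS = tuple(float(a) for a in (0, 5, 10, 15, 20, 25, 30, 40, 100))


def tabulate_person_years(cohort: Cohort, age_bands=DEFAULT_AGE_BANDS,
                          lag: float = 2.0, metric: str = "abm_dose_mean",
                          cutpoints=DEFAULT_CUTPOINTS,
                          strata_vars=("sex", "country", "birth_cohort"),
                          endpoint: str = "all_heme") -> pd.DataFrame:
    """Exact person-year table: windows split at band edges and dose steps.

    Returns one row per occupied cell with columns ``age_band``, the
    stratification variables, ``dose_cat``, ``py``, ``cases`` and
    ``mean_dose`` (PY-weighted mean lagged cumulative dose, exact because
    the dose is constant within every segment).
    """
    cohort = cohort.with_followup()
    persons = cohort.persons.reset_index(drop=True)
    fu = cohort.followup.set_index("person_id")
    meta = persons.copy()
    if "birth_cohort" in strata_vars and "birth_cohort" not in meta:
        meta["birth_cohort"] = assign_birth_cohort(meta["birth_date"])
    entry = fu["entry_age"].reindex(meta["person_id"]).to_numpy(float)
    exit_ = fu["exit_age"].reindex(meta["person_id"]).to_numpy(float)
    included = fu["included"].reindex(meta["person_id"]).to_numpy(bool)
    exit_eff = np.where(included, exit_, entry)   # excluded: zero-length

    exams = cohort.exams
    if metric == "exam_count":
        dose = np.ones(len(exams))
    else:
        if cohort.dose_summary is None or metric not in cohort.dose_summary:
            raise ValueError(f"cohort lacks dose summary column {metric!r}")
        dose = exams["exam_id"].map(
            cohort.dose_summary.set_index("exam_id")[metric]).to_numpy(float)
    pos = pd.Series(meta.index.to_numpy(), index=meta["person_id"])
    step_person = exams["person_id"].map(pos).to_numpy(dtype=np.intp)
    step_age = exams["age_at_exam"].to_numpy(float) + lag

    z_entry = np.zeros(len(meta))
    early = step_age <= entry[step_person]
    np.add.at(z_entry, step_person[early], dose[early])

    seg = split_persontime(entry, exit_eff, step_person[~early],
                           step_age[~early], dose[~early], z_entry,
                           np.asarray(age_bands, float))

    # case indicator: endpoint case in the segment that ends at exit
    case_mask = _endpoint_case_mask(cohort.outcomes, cohort.mapping, endpoint)
    case_ids = set(cohort.outcomes.loc[case_mask, "person_id"])
    is_case_person = meta["person_id"].isin(case_ids).to_numpy()
    is_diag = (fu["exit_reason"].reindex(meta["person_id"]) ==
               "diagnosis").to_numpy()
    last_seg = seg.t1 >= exit_eff[seg.person] - 1e-12
    seg_case = (last_seg & is_case_person[seg.person] &
                is_diag[seg.person] & included[seg.person]).astype(int)

    cells = pd.DataFrame({
        "age_band": seg.band,
        "dose_cat": categorize_dose(seg.z, cutpoints),
        "py": seg.length,
        "cases": seg_case,
        "dose_py": seg.z * seg.length,
    })
    for v in strata_vars:
        cells[v] = meta[v].to_numpy()[seg.person]
    keys = ["age_band", *strata_vars, "dose_cat"]
    out = cells.groupby(keys, observed=True).agg(
        py=("py", "sum"), cases=("cases", "sum"),
        dose_py=("dose_py", "sum")).reset_index()
    out["mean_dose"] = out["dose_py"] / out["py"]
    band_labels = [f"[{a:g},{b:g})" for a, b in zip(age_bands[:-1],
                                                    age_bands[1:])]
    out["age_band"] = np.asarray(band_labels)[out["age_band"].to_numpy()]
    return out.drop(columns="dose_py")


@dataclass
class EARFitResult:
    """Additive-excess Poisson fit; ``alpha`` in cases / PY / mGy."""

    alpha: float
    ci_low: float
    ci_high: float
    loglik: float
    background: pd.Series | None
    n_cases: int
    status: str = "ok"

    @property
    def per_100k_py_per_100mgy(self) -> float:
        return ear_per_100k_py_per_100mgy(self.alpha)

    @property
    def per_10k_py_per_100mgy(self) -> float:
        return ear_per_10k_py_per_100mgy(self.alpha)


def ear_per_100k_py_per_100mgy(alpha: float) -> float:
    """Canonical cases/PY/mGy -> cases per 100,000 PYs per 100 mGy."""
    return alpha * 1e5 * 100.0


def ear_per_10k_py_per_100mgy(alpha: float) -> float:
    return alpha * 1e4 * 100.0


def _design(pytable: pd.DataFrame, background_vars) -> np.ndarray:
    """One background rate per cross-classified stratum (dummy coding).

    Crossing the factors (rather than additive main effects) mirrors the
    stratified baseline of the relative-risk analysis.
    """
    key = pytable[list(background_vars)].astype(str).agg("|".join, axis=1)
    d = pd.get_dummies(key, drop_first=True)
    return np.column_stack([np.ones(len(pytable)), d.to_numpy(float)])


def fit_ear(pytable: pd.DataFrame,
            background_vars=("age_band", "sex"),
            alpha_level: float = 0.05, ci: bool = True) -> EARFitResult:
    """Maximum likelihood for rate = exp(x.theta) + alpha * mean_dose.

    The Poisson likelihood is over cell case counts with mean
    ``py * rate``; ``alpha`` is constrained so every fitted rate stays
    positive, and its CI is profile-likelihood based.  Background factors
    enter log-linearly as main effects.
    """
    cells = pytable[pytable["py"] > 0].reset_index(drop=True)
    if cells["cases"].sum() == 0:
        return EARFitResult(np.nan, np.nan, np.nan, np.nan, None, 0,
                            status="no_cases")
    if cells["mean_dose"].nunique() <= 1:
        return EARFitResult(np.nan, np.nan, np.nan, np.nan, None,
                            int(cells["cases"].sum()),
                            status="non_identifiable")
    X = _design(cells, background_vars)
    py = cells["py"].to_numpy(float)
    cases = cells["cases"].to_numpy(float)
    d = cells["mean_dose"].to_numpy(float)
    p = X.shape[1]

    def negll_grad(params: np.ndarray) -> tuple[float, np.ndarray]:
        theta, a = params[:p], params[p]
        bg = np.exp(np.clip(X @ theta, -40, 40))
        rate = bg + a * d
        bad = rate <= 0
        if bad.any():
            # linear penalty steering back into the feasible region
            viol = float((-rate[bad]).sum())
            g_theta = -(bg[bad][:, None] * X[bad]).sum(axis=0)
            g_alpha = -d[bad].sum()
            return 1e9 * (1.0 + viol), 1e9 * np.r_[g_theta, g_alpha]
        mu = py * rate
        f = float(mu.sum() - (cases * np.log(mu)).sum())
        w = (1.0 - cases / mu) * py
        g_theta = (w * bg) @ X
        g_alpha = float(w @ d)
        return f, np.r_[g_theta, g_alpha]

    def negll(params: np.ndarray) -> float:
        return negll_grad(params)[0]

    # start from the no-excess Poisson background
    import statsmodels.api as sm
    glm = sm.GLM(cases, X, family=sm.families.Poisson(),
                 offset=np.log(py)).fit()
    x0 = np.concatenate([glm.params, [0.0]])
    res = optimize.minimize(negll_grad, x0, jac=True, method="L-BFGS-B",
                            options={"maxiter": 5000, "ftol": 1e-13,
                                     "gtol": 1e-10})
    res2 = optimize.minimize(negll, res.x, method="Nelder-Mead",
                             options={"maxiter": 4000, "xatol": 1e-10,
                                      "fatol": 1e-11})
    if res2.fun < res.fun:
        res = res2
    theta_hat, a_hat = res.x[:p], float(res.x[p])
    llmax = -negll(res.x)

    if not ci:
        return EARFitResult(a_hat, np.nan, np.nan, llmax,
                            pd.Series(theta_hat, name="log_background"),
                            int(cases.sum()))

    # profile CI on alpha
    crit = stats.chi2.ppf(1 - alpha_level, 1) / 2.0

    def prof(a: float) -> float:
        def nll_t(theta: np.ndarray) -> tuple[float, np.ndarray]:
            f, g = negll_grad(np.concatenate([theta, [a]]))
            return f, g[:p]
        r = optimize.minimize(nll_t, theta_hat, jac=True, method="L-BFGS-B",
                              options={"maxiter": 5000, "ftol": 1e-13,
                                       "gtol": 1e-10})
        return -float(r.fun)

    target = llmax - crit

    def dev(a: float) -> float:
        return prof(a) - target

    # bracket outward from the estimate
    scale = max(abs(a_hat), 1e-8)
    lo_b = a_hat
    step = scale
    for _ in range(60):
        if dev(lo_b - step) < 0:
            break
        lo_b -= step
        step *= 2
    try:
        ci_low = float(optimize.brentq(dev, lo_b - step, a_hat,
                                       xtol=scale * 1e-6))
    except ValueError:
        ci_low = np.nan
    hi_b = a_hat
    step = scale
    for _ in range(60):
        if dev(hi_b + step) < 0:
            break
        hi_b += step
        step *= 2
    try:
        ci_high = float(optimize.brentq(dev, a_hat, hi_b + step,
                                        xtol=scale * 1e-6))
    except ValueError:
        ci_high = np.nan

    bg = pd.Series(theta_hat, name="log_background")
    return EARFitResult(a_hat, ci_low, ci_high, llmax, bg,
                        int(cases.sum()))


def implied_err_per_100mgy(fit: EARFitResult, pytable: pd.DataFrame,
                           background_vars=("age_band", "sex")) -> float:
    """ERR/100 mGy implied by an additive fit: alpha over the PY-weighted
    mean fitted background rate, times 100."""
    cells = pytable[pytable["py"] > 0]
    X = _design(cells.reset_index(drop=True), background_vars)
    py = cells["py"].to_numpy(float)
    lam = np.exp(X @ fit.background.to_numpy())
    lam_bar = float((lam * py).sum() / py.sum())
    return 100.0 * fit.alpha / lam_bar


# ---------------------------------------------------------------------------
# Projection arithmetic

def err_implied_percent_increase(err_per_100mgy: float,
                                 dose_mgy: float) -> float:
    """Percent increased risk for one exam of the given dose.

    Under RR = 1 + beta Z the increase is 100 * (ERR/100 mGy) * Z / 100,
    i.e. numerically ``err_per_100mgy * dose_mgy`` percent when Z is in mGy.
    """
    if 1.0 + err_per_100mgy * dose_mgy / 100.0 <= 0:
        raise ValueError("relative risk non-positive at this dose")
    return err_per_100mgy * dose_mgy


def predict_excess_cases(ear_coefficient: float, dose_mgy: float,
                         n_persons: int, years_after_exam: float,
                         lag: float = 2.0) -> float:
    """Expected excess cases among ``n_persons`` examined at ``dose_mgy``.

    ``ear_coefficient`` is canonical (cases/PY/mGy).  The exposed persons
    accrue excess rate ``alpha * dose`` from the end of the lag onward, so
    the lag removes ``lag`` of the ``years_after_exam`` at-risk years.
    """
    if years_after_exam <= lag:
        warnings.warn("projection horizon does not exceed the lag; "
                      "no excess cases accrue")
        return 0.0
    return float(ear_coefficient * dose_mgy * n_persons
                 * (years_after_exam - lag))
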