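"""Population-parameter estimation, covariate search and bootstrap.

The estimator minimizes a Laplace approximation to -2 log marginal
likelihood (numerically equivalent to first-order conditional estimation
with interaction under the additive log-scale error model). Positivity is
enforced through log transforms, bioavailability through a logit and the
CL-Vc correlation through arc-tanh; standard errors come from the inverse
Hessian of OFV/2 at the optimum, mapped back to the reporting scale by the
delta method. Interindividual variability is reported as CV% (100 sqrt of
the variance) for CL and Vc and as a logit-scale SD for F1; eta-shrinkage
is 100 (1 - SD(eta_hat)/omega).

The stepwise covariate search adds, one relation at a time, the candidate
with the largest drop in OFV among those exceeding the chi-square(1)
critical value at p = 0.01 (6.635), then deletes backwards any relation
whose removal raises OFV by less than the p = 0.001 value (10.828).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from ._engine import (
    N_STRUCT,
    STRUCT_NAMES,
    CovariateRelation,
    LaplaceEngine,
    pack_dataset,
)
from .model import StudyDataset, Subject
from .params import PopulationParameters

CHI2_FORWARD = 6.635  # chi-square(1), p = 0.01
CHI2_BACKWARD = 10.828  # chi-square(1), p = 0.001

#: reporting-scale names for random-effect IIV terms
_IIV_NAMES = {"omega2_cl": "iiv_cl_cv_pct", "omega2_vc": "iiv_vc_cv_pct"}


@dataclass
class FitResult:
    """Converged model fit with uncertainty and empirical Bayes estimates."""

    estimates: PopulationParameters
    ofv: float
    theta: np.ndarray  # transformed-scale optimum
    se: dict = field(default_factory=dict)  # reporting-scale SEs
    rse_pct: dict = field(default_factory=dict)
    shrinkage_pct: dict = field(default_factory=dict)
    eta_hat: np.ndarray | None = None
    subject_ids: list = field(default_factory=list)
    coefficients: dict = field(default_factory=dict)  # covariate/food coefficients
    relations: tuple = ()
    food_mode: str | None = None
    fixed: frozenset = frozenset()
    converged: bool = False
    n_subjects: int = 0
    n_obs: int = 0
    message: str = ""

    def reported(self) -> dict:
        """Estimates on the reporting scale (IIV as CV% / logit SD)."""
        e = self.estimates
        out = {
            "cl_typ": e.cl_typ,
            "vc_typ": e.vc_typ,
            "ka": e.ka,
            "f1_typ": e.f1_typ,
            "alpha_cl": e.alpha_cl,
            "alpha_vc": e.alpha_vc,
            "iiv_cl_cv_pct": 100.0 * math.sqrt(e.omega2_cl),
            "iiv_vc_cv_pct": 100.0 * math.sqrt(e.omega2_vc),
            "iiv_f1_logit_sd": e.omega_sd_f1_logit,
            "rho_cl_vc": e.rho_cl_vc,
            "sigma_log": e.sigma_log,
        }
        out.update(self.coefficients)
        return out

    def to_dict(self) -> dict:
        return {
            "estimates": self.estimates.to_dict(),
            "reported": self.reported(),
            "ofv": self.ofv,
            "se": self.se,
            "rse_pct": self.rse_pct,
            "shrinkage_pct": self.shrinkage_pct,
            "coefficients": self.coefficients,
            "converged": self.converged,
            "n_subjects": self.n_subjects,
            "n_obs": self.n_obs,
            "message": self.message,
        }


@dataclass
class CovariateSearchResult:
    selected: list  # retained CovariateRelation objects
    ledger: list  # per-step dicts: phase, relation, delta_ofv, decision
    final_fit: FitResult


# ---------------------------------------------------------------------------
# likelihood primitives
# ---------------------------------------------------------------------------


def subject_joint_neg2ll(
    pop: PopulationParameters, subj: Subject, eta=(0.0, 0.0, 0.0)
) -> float:
    """-2 log joint density of one subject's data and random effects.

    Sum of the Gaussian log densities of the log-scale residuals plus the
    multivariate normal log density of eta (dimensions with zero variance
    are held at zero and excluded from the prior term).
    """
    from .model import concentration_profile, individual_from_population

    obs = [o for o in subj.observations if o.usable]
    if not obs:
        raise ValueError("subject has no usable observation")
    eta = np.asarray(eta, dtype=float)
    omega = pop.omega_matrix()
    active = np.diag(omega) > 1e-10
    ind = individual_from_population(pop, subj.weight, tuple(np.where(active, eta, 0.0)))
    times = np.array([o.time for o in obs])
    pred = concentration_profile(ind, subj.doses, times)
    pred = np.maximum(pred, 1e-12)
    r = np.log([o.concentration for o in obs]) - np.log(pred)
    s2 = pop.sigma_log**2
    val = float(np.sum(r * r) / s2 + len(obs) * math.log(2.0 * math.pi * s2))
    if active.any():
        oa = omega[np.ix_(active, active)]
        ea = eta[active]
        val += float(ea @ np.linalg.solve(oa, ea))
        val += float(np.linalg.slogdet(2.0 * math.pi * oa)[1])
    return val


def laplace_ofv(pop: PopulationParameters, ds: StudyDataset) -> float:
    """Laplace -2 log marginal likelihood of the whole dataset."""
    engine = LaplaceEngine(pack_dataset(ds), wt_ref=pop.wt_ref)
    return engine.ofv(engine.theta_from_pop(pop))


# ---------------------------------------------------------------------------
# maximum-likelihood fit
# ---------------------------------------------------------------------------


def _report_transform(theta, i):
    """(value, d value / d theta_i) on the reporting scale for structural i."""
    name = STRUCT_NAMES[i]
    x = theta[i]
    if name in ("cl_typ", "vc_typ", "ka", "sigma_log"):
        v = math.exp(x)
        return name, v, v
    if name == "f1_typ":
        v = 1.0 / (1.0 + math.exp(-x))
        return name, v, v * (1.0 - v)
    if name in ("alpha_cl", "alpha_vc"):
        return name, x, 1.0
    if name in ("omega2_cl", "omega2_vc"):  # report CV% = 100 exp(x/2)
        v = 100.0 * math.exp(x / 2.0)
        return _IIV_NAMES[name], v, v / 2.0
    if name == "omega_sd_f1_logit":
        v = math.exp(x)
        return "iiv_f1_logit_sd", v, v
    if name == "rho_cl_vc":
        v = math.tanh(x)
        return name, v, 1.0 - v * v
    raise KeyError(name)


def fit_model(
    ds: StudyDataset,
    init: PopulationParameters,
    fixed: frozenset | set = frozenset(("rho_cl_vc",)),
    relations: tuple = (),
    food_mode: str | None = None,
    compute_se: bool = True,
    init_coefficients=None,
    maxiter: int = 400,
    ftol: float = 1e-9,
    eps: float = 1e-5,
    engine: LaplaceEngine | None = None,
) -> FitResult:
    """Maximum (approximate marginal) likelihood fit.

    ``fixed`` names structural parameters held at their ``init`` value; the
    CL-Vc correlation is fixed by default because the base analysis treats
    it as a configurable constant. Covariate ``relations`` and the optional
    food effect each add one coefficient (three for the four-category food
    model) initialized at zero unless ``init_coefficients`` is given.
    """
    if engine is None:
        engine = LaplaceEngine(
            pack_dataset(ds), wt_ref=init.wt_ref, relations=relations, food_mode=food_mode
        )
    theta0 = engine.theta_from_pop(init, extra=init_coefficients)
    free = np.array(
        [STRUCT_NAMES[i] not in fixed for i in range(N_STRUCT)]
        + [True] * (engine.n_theta - N_STRUCT)
    )
    engine.reset_warm_start()

    def pack_full(x):
        th = theta0.copy()
        th[free] = x
        return th

    def fun(x):
        return engine.ofv(pack_full(x))

    # wide, domain-motivated boxes on the transformed scale; they never bind
    # at plausible optima but keep the line search out of degenerate basins
    # (e.g. a food coefficient running to -inf with zero fed bioavailability)
    struct_bounds = [
        (-10.0, 10.0),  # log CL
        (-10.0, 10.0),  # log Vc
        (-10.0, 10.0),  # log ka
        (-10.0, 10.0),  # logit F1
        (-5.0, 5.0),    # alpha_CL
        (-5.0, 5.0),    # alpha_Vc
        (-15.0, 5.0),   # log omega2_CL
        (-15.0, 5.0),   # log omega2_Vc
        (-10.0, 3.0),   # log omega_F1 logit-SD
        (-5.0, 5.0),    # atanh rho
        (-10.0, 2.0),   # log sigma
    ]
    bounds = struct_bounds + [(-5.0, 5.0)] * (engine.n_theta - N_STRUCT)
    res = optimize.minimize(
        fun,
        theta0[free],
        method="L-BFGS-B",
        bounds=[b for b, f in zip(bounds, free) if f],
        options={"maxiter": maxiter, "ftol": ftol, "gtol": 1e-6, "eps": eps},
    )
    theta = pack_full(res.x)
    estimates = engine.pop_from_theta(theta)
    ofv, parts = engine.ofv(theta, return_parts=True)

    coef_names = [f"beta_{r.label()}" for r in engine.relations] + [
        f"beta_food_{c}" for c in (("fed",) if food_mode == "two" else ("light", "moderate", "heavy"))
    ][: engine.n_food]
    coefficients = dict(zip(coef_names, theta[N_STRUCT:].tolist()))

    fit = FitResult(
        estimates=estimates,
        ofv=ofv,
        theta=theta,
        eta_hat=parts["eta"],
        subject_ids=list(engine.p.subject_ids),
        coefficients=coefficients,
        relations=engine.relations,
        food_mode=food_mode,
        fixed=frozenset(fixed),
        converged=bool(res.success) and parts["converged_inner"],
        n_subjects=engine.S,
        n_obs=len(engine.p.y),
        message=str(res.message),
    )

    # eta-shrinkage on the active random effects
    st = parts["state"]
    names3 = ("eta_cl", "eta_vc", "eta_f1")
    omegas = (
        math.sqrt(estimates.omega2_cl),
        math.sqrt(estimates.omega2_vc),
        estimates.omega_sd_f1_logit,
    )
    for k in range(3):
        if st.active[k] and engine.S > 1:
            sd = float(np.std(parts["eta"][:, k], ddof=1))
            fit.shrinkage_pct[names3[k]] = 100.0 * (1.0 - sd / omegas[k])

    if compute_se:
        _attach_standard_errors(fit, engine, theta, free, coef_names)
    return fit


def _attach_standard_errors(fit, engine, theta, free, coef_names, h: float = 1e-3):
    """Delta-method SEs from the finite-difference Hessian of OFV/2."""
    idx = np.where(free)[0]
    n = len(idx)

    def f(x):
        th = theta.copy()
        th[idx] = x
        return engine.ofv(th)

    x0 = theta[idx]
    f0 = f(x0)
    hess = np.empty((n, n))
    fp = np.empty(n)
    fm = np.empty(n)
    for i in range(n):
        e = np.zeros(n)
        e[i] = h
        fp[i] = f(x0 + e)
        fm[i] = f(x0 - e)
        hess[i, i] = (fp[i] - 2.0 * f0 + fm[i]) / h**2
    for i in range(n):
        for j in range(i + 1, n):
            ei = np.zeros(n)
            ej = np.zeros(n)
            ei[i] = h
            ej[j] = h
            hess[i, j] = hess[j, i] = (
                f(x0 + ei + ej) - f(x0 + ei - ej) - f(x0 - ei + ej) + f(x0 - ei - ej)
            ) / (4.0 * h**2)
    # OFV = -2 log L, so Cov = 2 H^{-1}
    try:
        cov = 2.0 * np.linalg.inv(hess)
        bad = np.diag(cov) <= 0
        if bad.any():
            cov = 2.0 * np.linalg.pinv(hess)
    except np.linalg.LinAlgError:
        cov = 2.0 * np.linalg.pinv(hess)
    se_theta = np.sqrt(np.clip(np.diag(cov), 0.0, None))

    for pos, i in enumerate(idx):
        if i < N_STRUCT:
            name, value, deriv = _report_transform(theta, i)
        else:
            name = coef_names[i - N_STRUCT]
            value, deriv = theta[i], 1.0
        se = abs(deriv) * se_theta[pos]
        fit.se[name] = float(se)
        if value != 0:
            fit.rse_pct[name] = float(100.0 * se / abs(value))


# ---------------------------------------------------------------------------
# stepwise covariate search and food effect
# ---------------------------------------------------------------------------


def default_candidates(ds: StudyDataset) -> list:
    """Age, eGFR, sex and ethnicity against CL, Vc and F1 (weight enters
    the base model allometrically and is not re-tested)."""
    cands = []
    for cov, kind in (("age", "power"), ("egfr", "power"), ("sex", "categorical"), ("ethnicity", "categorical")):
        for par in ("cl", "vc", "f1"):
            cands.append(CovariateRelation(cov, par, kind))
    return cands


def stepwise_covariate_search(
    ds: StudyDataset,
    base: FitResult,
    candidates,
    **fit_kwargs,
) -> CovariateSearchResult:
    """Forward-inclusion (p < 0.01) / backward-deletion (p < 0.001) search."""
    unusable = set(ds.meta.get("unusable_covariates", ()))
    ledger: list[dict] = []
    pool = []
    for c in candidates:
        if c.covariate in unusable:
            ledger.append(
                {
                    "phase": "screen",
                    "relation": c.label(),
                    "delta_ofv": None,
                    "decision": "rejected: covariate unusable (>30% missing)",
                }
            )
        else:
            pool.append(c)

    fit_kwargs.setdefault("compute_se", False)
    selected: list[CovariateRelation] = []
    current = base

    def refit(rels, start_fit):
        coefs = np.zeros(len(rels) or 0)
        for i, r in enumerate(rels):
            coefs[i] = start_fit.coefficients.get(f"beta_{r.label()}", 0.0)
        return fit_model(
            ds,
            start_fit.estimates,
            fixed=start_fit.fixed,
            relations=tuple(rels),
            init_coefficients=coefs if len(rels) else None,
            **fit_kwargs,
        )

    # forward phase
    while pool:
        trials = []
        for c in pool:
            trial = refit(selected + [c], current)
            delta = current.ofv - trial.ofv
            trials.append((delta, c, trial))
            ledger.append(
                {
                    "phase": "forward",
                    "relation": c.label(),
                    "delta_ofv": float(delta),
                    "decision": "candidate" if delta >= CHI2_FORWARD else "not included",
                }
            )
        best = max(trials, key=lambda t: t[0])
        if best[0] >= CHI2_FORWARD:
            selected.append(best[1])
            pool.remove(best[1])
            current = best[2]
            ledger.append(
                {
                    "phase": "forward",
                    "relation": best[1].label(),
                    "delta_ofv": float(best[0]),
                    "decision": "included",
                }
            )
        else:
            break

    # backward phase
    changed = True
    while changed and selected:
        changed = False
        trials = []
        for c in selected:
            reduced = [r for r in selected if r is not c]
            trial = refit(reduced, current)
            delta = trial.ofv - current.ofv  # increase on deletion
            trials.append((delta, c, trial))
        worst = min(trials, key=lambda t: t[0])
        if worst[0] < CHI2_BACKWARD:
            selected.remove(worst[1])
            current = worst[2]
            changed = True
            ledger.append(
                {
                    "phase": "backward",
                    "relation": worst[1].label(),
                    "delta_ofv": float(worst[0]),
                    "decision": "removed",
                }
            )
        else:
            for delta, c, _ in trials:
                ledger.append(
                    {
                        "phase": "backward",
                        "relation": c.label(),
                        "delta_ofv": float(delta),
                        "decision": "retained",
                    }
                )
    final = current if selected else base
    return CovariateSearchResult(selected=selected, ledger=ledger, final_fit=final)


def food_effect_test(
    ds: StudyDataset,
    base: FitResult,
    categorization: str = "two",
    **fit_kwargs,
):
    """Test a food covariate on bioavailability after the stepwise search.

    Refits with a logit-scale shift of F1 for fed oral doses ('two': meal vs
    no meal; 'four': light/moderate/heavy vs none) and compares the OFV drop
    with the forward-inclusion threshold. Also returns the graphical
    summary: quartiles and 5th/95th percentiles of the empirical Bayes
    eta_F1 by food category.
    """
    oral_subjects = [s for s in ds.subjects if s.has_oral_doses]
    if not oral_subjects:
        raise ValueError("food-effect assessment requires oral observations")
    cats_present = {d.food_category for s in oral_subjects for d in s.doses if d.is_oral}
    if len(cats_present) < 2:
        return {
            "delta_ofv": None,
            "decision": "inestimable: single food category",
            "eta_f1_by_category": {},
            "fit": None,
        }
    fit_kwargs.setdefault("compute_se", False)
    trial = fit_model(
        ds,
        base.estimates,
        fixed=base.fixed,
        relations=base.relations,
        food_mode=categorization,
        **fit_kwargs,
    )
    delta = base.ofv - trial.ofv
    decision = "included" if delta >= CHI2_FORWARD else "not included"

    eta_map = dict(zip(base.subject_ids, base.eta_hat[:, 2]))
    groups: dict[str, list] = {}
    for s in oral_subjects:
        if s.id not in eta_map:
            continue
        cats = {d.food_category for d in s.doses if d.is_oral}
        if categorization == "two":
            cats = {"fed"} if cats - {"none"} else {"none"}
        for c in cats:
            groups.setdefault(c, []).append(eta_map[s.id])
    summaries = {
        c: {
            "n": len(v),
            "p5": float(np.percentile(v, 5)),
            "q1": float(np.percentile(v, 25)),
            "median": float(np.percentile(v, 50)),
            "q3": float(np.percentile(v, 75)),
            "p95": float(np.percentile(v, 95)),
        }
        for c, v in groups.items()
    }
    return {
        "delta_ofv": float(delta),
        "decision": decision,
        "eta_f1_by_category": summaries,
        "fit": trial,
    }


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------


def bootstrap(
    ds: StudyDataset,
    base: FitResult,
    n_reps: int = 200,
    seed: int = 0,
    identity_resample: bool = False,
    **fit_kwargs,
) -> dict:
    """Nonparametric bootstrap: resample subjects with replacement, refit.

    Returns 2.5/50/97.5 percentile intervals per reported parameter and the
    fraction of converged replicates (a reliability warning is attached when
    fewer than half converge). Reproducible under ``seed``.
    """
    rng = np.random.default_rng(seed)
    n = len(ds.subjects)
    fit_kwargs.setdefault("compute_se", False)
    rows = []
    n_conv = 0
    indices = []
    for _ in range(n_reps):
        idx = np.arange(n) if identity_resample else rng.integers(0, n, size=n)
        indices.append(idx)
        import copy as _copy

        subs = []
        for new_id, i in enumerate(idx, start=1):
            s = _copy.copy(ds.subjects[i])
            s.id = new_id
            subs.append(s)
        rep = StudyDataset(subjects=subs, lloq=ds.lloq, meta=dict(ds.meta))
        try:
            fit = fit_model(rep, base.estimates, fixed=base.fixed, relations=base.relations, **fit_kwargs)
        except Exception:
            continue
        if fit.converged:
            n_conv += 1
        rows.append(fit.reported())
    if not rows:
        raise RuntimeError("no bootstrap replicate could be fitted")
    import pandas as pd

    table = pd.DataFrame(rows)
    pct = table.quantile([0.025, 0.5, 0.975])
    out = {
        "percentiles": {c: {"2.5%": float(pct.loc[0.025, c]), "50%": float(pct.loc[0.5, c]), "97.5%": float(pct.loc[0.975, c])} for c in table.columns},
        "n_reps": n_reps,
        "n_fitted": len(rows),
        "converged_fraction": n_conv / max(len(rows), 1),
        "indices": [i.tolist() for i in indices],
    }
    if out["converged_fraction"] < 0.5:
        out["warning"] = "fewer than 50% of replicates converged; intervals unreliable"
    return out
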