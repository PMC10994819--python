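"""Model validation: goodness-of-fit residuals, prediction-corrected VPC and
noncompartmental-analysis concordance.

Conditional weighted residuals (CWRES) linearize the log prediction in the
random effects at the empirical Bayes mode and standardize the observed
residual by the implied marginal covariance; on data simulated from the
fitted model they are approximately standard normal. The prediction-
corrected visual predictive check rescales each observation by the ratio of
its time bin's median population prediction to its own population
prediction, then compares observed percentile curves with simulation-based
90% prediction intervals. NCA concordance compares model post-hoc exposure
metrics with trapezoid-based metrics computed directly from intensively
sampled concentrations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._engine import LaplaceEngine, pack_dataset
from .model import StudyDataset, exposure_metrics, individual_from_population


def _make_engine(fit, ds: StudyDataset) -> LaplaceEngine:
    return LaplaceEngine(
        pack_dataset(ds),
        wt_ref=fit.estimates.wt_ref,
        relations=fit.relations,
        food_mode=fit.food_mode,
    )


def gof_residuals(fit, ds: StudyDataset) -> pd.DataFrame:
    """Per-observation population/individual predictions and CWRES.

    Returns columns: subject, time, dv (ng/mL), pred, ipred (ng/mL, at
    eta = 0 and the empirical Bayes eta), and cwres on the log scale.
    """
    if not fit.converged:
        raise ValueError("goodness-of-fit requires a converged fit")
    engine = _make_engine(fit, ds)
    out = engine.predictions(fit.theta)
    p = engine.p
    ids = np.array(p.subject_ids)[p.sidx]
    return pd.DataFrame(
        {
            "subject": ids,
            "time": p.t,
            "dv": np.exp(p.y),
            "pred": np.exp(out["pred_log"]),
            "ipred": np.exp(out["ipred_log"]),
            "cwres": out["cwres"],
        }
    )


@dataclass
class VpcResult:
    """Prediction-corrected VPC summaries."""

    bin_edges: np.ndarray  # time-after-dose bin edges
    bin_mid: np.ndarray
    observed: np.ndarray  # (nbin, 3) observed 5/50/95 percentiles
    sim_lo: np.ndarray  # (nbin, 3) lower 90% PI bound of each percentile
    sim_hi: np.ndarray  # (nbin, 3) upper bound
    n_sim: int
    coverage: float  # fraction of observed bin-percentiles inside their PI
    merged_bins: int = 0
    table: pd.DataFrame | None = None


def _time_after_dose(packed) -> np.ndarray:
    tad = np.empty(len(packed.t))
    for i, (t, s) in enumerate(zip(packed.t, packed.sidx)):
        dt = t - packed.grid.time[s]
        dt = dt[(dt > 0) & (packed.grid.amt[s] > 0)]
        tad[i] = dt.min() if dt.size else t
    return tad


def _equal_count_edges(x: np.ndarray, n_bins: int, min_count: int = 5):
    """Quantile bin edges; bins with < min_count observations are merged."""
    qs = np.linspace(0, 1, n_bins + 1)
    edges = np.unique(np.quantile(x, qs))
    merged = 0
    while len(edges) > 2:
        idx = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, len(edges) - 2)
        counts = np.bincount(idx, minlength=len(edges) - 1)
        small = np.where(counts < min_count)[0]
        if not small.size:
            break
        j = small[0]
        edges = np.delete(edges, j + 1 if j < len(edges) - 2 else j)
        merged += 1
    return edges, merged


def pc_vpc(
    fit,
    ds: StudyDataset,
    n_sim: int = 200,
    seed: int = 0,
    bins: int = 8,
    percentiles=(5.0, 50.0, 95.0),
) -> VpcResult:
    """Prediction-corrected visual predictive check.

    Observations are binned on time after the most recent dose with
    equal-count bins; within each bin they are rescaled by (bin median
    population prediction / own population prediction). ``n_sim`` replicate
    datasets are simulated at the design (same times, doses, covariates)
    from the fitted parameters, corrected identically, and the 90% interval
    of each percentile across replicates is compared with the observed one.
    """
    if n_sim < 100:
        raise ValueError("n_sim must be at least 100")
    engine = _make_engine(fit, ds)
    p = engine.p
    st = engine._state(fit.theta)
    pred_log = engine._logc(st, np.zeros((engine.S, 3)))
    pred = np.exp(pred_log)
    obs = np.exp(p.y)

    tad = _time_after_dose(p)
    edges, merged = _equal_count_edges(tad, bins)
    bin_idx = np.clip(np.searchsorted(edges, tad, side="right") - 1, 0, len(edges) - 2)
    nbin = len(edges) - 1
    bin_median_pred = np.array([np.median(pred[bin_idx == b]) for b in range(nbin)])
    correction = bin_median_pred[bin_idx] / pred

    def binned_percentiles(values):
        out = np.empty((nbin, len(percentiles)))
        for b in range(nbin):
            out[b] = np.percentile(values[bin_idx == b], percentiles)
        return out

    observed = binned_percentiles(obs * correction)

    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(st.omega + 1e-12 * np.eye(3))
    sims = np.empty((n_sim, nbin, len(percentiles)))
    for r in range(n_sim):
        eta = rng.standard_normal((engine.S, 3)) @ chol.T
        eta[:, ~st.active] = 0.0
        y = engine._logc(st, eta) + st.sigma * rng.standard_normal(len(p.y))
        sims[r] = binned_percentiles(np.exp(y) * correction)
    lo = np.percentile(sims, 5.0, axis=0)
    hi = np.percentile(sims, 95.0, axis=0)
    inside = (observed >= lo) & (observed <= hi)

    mid = 0.5 * (edges[:-1] + edges[1:])
    table = pd.DataFrame(
        {
            "bin_mid_h": np.repeat(mid, len(percentiles)),
            "percentile": np.tile(percentiles, nbin),
            "observed": observed.ravel(),
            "sim_lo": lo.ravel(),
            "sim_hi": hi.ravel(),
            "inside": inside.ravel(),
        }
    )
    return VpcResult(
        bin_edges=edges,
        bin_mid=mid,
        observed=observed,
        sim_lo=lo,
        sim_hi=hi,
        n_sim=n_sim,
        coverage=float(inside.mean()),
        merged_bins=merged,
        table=table,
    )


def nca_concordance(
    fit,
    ds: StudyDataset,
    tau: float = 24.0,
    min_obs: int = 4,
    min_span: float = 18.0,
) -> dict:
    """Post-hoc model exposures vs noncompartmental exposures.

    For each subject and phase (IV / oral) the dosing interval holding the
    most observations is analyzed when it has at least ``min_obs`` samples
    spanning at least ``min_span`` hours: NCA Cavg is the linear-trapezoid
    AUC over the sampled span divided by the span, NCA Cmin the last sample;
    post-hoc values use the analytic model exposure at the empirical Bayes
    parameters over the same interval. Returns the paired table and
    geometric-mean ratios (post-hoc / NCA).
    """
    eta_map = dict(zip(fit.subject_ids, fit.eta_hat))
    rows = []
    skipped = []
    for s in ds.subjects:
        if s.id not in eta_map:
            skipped.append((s.id, "not in fit"))
            continue
        ind = individual_from_population(
            fit.estimates, s.weight, tuple(eta_map[s.id])
        )
        usable = sorted((o for o in s.observations if o.usable), key=lambda o: o.time)
        for phase, is_oral in (("iv", False), ("oral", True)):
            doses = [d for d in s.doses if d.is_oral == is_oral]
            if not doses:
                continue
            best, anchor = [], None
            for d in doses:
                win = [o for o in usable if d.time <= o.time <= d.time + tau]
                if len(win) > len(best):
                    best, anchor = win, d.time
            if len(best) < min_obs:
                skipped.append((s.id, f"{phase}: <{min_obs} observations in any interval"))
                continue
            t = np.array([o.time for o in best])
            c = np.array([o.concentration for o in best])
            span = t[-1] - t[0]
            if span < min_span:
                skipped.append((s.id, f"{phase}: sampled span {span:.1f} h too short"))
                continue
            nca_cavg = float(np.trapezoid(c, t) / span)
            nca_cmin = float(c[-1])
            m = exposure_metrics(ind, s.doses, interval_start=anchor, tau=tau)
            rows.append(
                {
                    "subject": s.id,
                    "phase": phase,
                    "nca_cavg": nca_cavg,
                    "nca_cmin": nca_cmin,
                    "posthoc_cavg": m.cavg,
                    "posthoc_cmin": m.cmin,
                }
            )
    table = pd.DataFrame(rows)
    ratios = {}
    if not table.empty:
        for metric in ("cavg", "cmin"):
            r = table[f"posthoc_{metric}"] / table[f"nca_{metric}"]
            r = r[r > 0]
            ratios[f"gm_ratio_{metric}"] = float(np.exp(np.mean(np.log(r)))) if len(r) else math.nan
    return {"table": table, "ratios": ratios, "skipped": skipped}
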