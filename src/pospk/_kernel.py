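"""Closed-form one-compartment kinetics, vectorized over subjects and doses.

Every public quantity is a superposition of single-dose solutions:

* an IV infusion at rate R = dose/T_inf contributes
  (R/CL)(1 - e^{-k t'}) while the infusion runs and
  (R/CL)(1 - e^{-k T_inf}) e^{-k (t' - T_inf)} afterwards, with k = CL/Vc;
* an oral dose contributes F D ka / (Vc (ka - k)) (e^{-k t'} - e^{-ka t'}),
  with the limiting form F D k t' e^{-k t'} / Vc when ka == k.

Doses are held in padded (n_subjects, n_doses) arrays so that whole cohorts
are evaluated with a handful of numpy operations; this is the hot path of the
Laplace estimation engine. Concentrations are returned in ng/mL (parameters
are in mg, L, h; 1 mg/L = 1000 ng/mL).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

MGL_TO_NGML = 1000.0
# relative |ka - k| below which the equal-rates limiting form is used
_KA_K_RTOL = 1e-9


@dataclass
class DoseGrid:
    """Padded per-subject dose event arrays, shape (n_subjects, n_doses)."""

    time: np.ndarray  # h since time origin
    amt: np.ndarray  # mg; 0 marks padding
    tinf: np.ndarray  # infusion duration, h (IV rows only)
    oral: np.ndarray  # bool
    fmult: np.ndarray  # per-dose bioavailability multiplier (food, formulation)

    @classmethod
    def from_lists(cls, dose_lists) -> "DoseGrid":
        """Build a grid from a list (one entry per subject) of dose tuples
        (time, amt, tinf, is_oral, fmult)."""
        n = len(dose_lists)
        d = max((len(ds) for ds in dose_lists), default=1) or 1
        time = np.zeros((n, d))
        amt = np.zeros((n, d))
        tinf = np.ones((n, d))
        oral = np.zeros((n, d), dtype=bool)
        fmult = np.ones((n, d))
        for i, ds in enumerate(dose_lists):
            for j, (t, a, ti, is_oral, fm) in enumerate(ds):
                time[i, j] = t
                amt[i, j] = a
                tinf[i, j] = ti if not is_oral else 1.0
                oral[i, j] = is_oral
                fmult[i, j] = fm
        return cls(time=time, amt=amt, tinf=tinf, oral=oral, fmult=fmult)


def _broadcast(t, sidx, grid: DoseGrid, cl, vc, ka, f1):
    """Common per-(observation, dose) quantities."""
    t = np.asarray(t, dtype=float)
    dt = t[:, None] - grid.time[sidx]  # time since each dose
    live = (dt > 0.0) & (grid.amt[sidx] > 0.0)
    dt = np.clip(dt, 0.0, None)
    with np.errstate(divide="ignore", over="ignore"):
        k = (cl / vc)[sidx][:, None]
    return dt, live, k


def _iv_conc(dt, amt, tinf, cl2, k):
    rate = amt / tinf
    u = np.minimum(dt, tinf)
    tail = np.clip(dt - tinf, 0.0, None)
    return (rate / cl2) * (-np.expm1(-k * u)) * np.exp(-k * tail)


def _iv_cum_auc(dt, amt, tinf, cl2, k):
    rate = amt / tinf
    u = np.minimum(dt, tinf)
    auc1 = (rate / cl2) * (u + np.expm1(-k * u) / k)
    tail = np.clip(dt - tinf, 0.0, None)
    c_end = (rate / cl2) * (-np.expm1(-k * tinf))
    auc2 = c_end / k * (-np.expm1(-k * tail))
    return auc1 + auc2


def _oral_conc(dt, famt, vc2, ka2, k):
    close = np.abs(ka2 - k) <= _KA_K_RTOL * np.maximum(ka2, k)
    den = np.where(close, 1.0, ka2 - k)
    a = famt * ka2 / (vc2 * den)
    general = a * (np.exp(-k * dt) - np.exp(-ka2 * dt))
    limit = famt * k * dt * np.exp(-k * dt) / vc2
    return np.where(close, limit, general)


def _oral_cum_auc(dt, famt, vc2, ka2, k):
    close = np.abs(ka2 - k) <= _KA_K_RTOL * np.maximum(ka2, k)
    den = np.where(close, 1.0, ka2 - k)
    a = famt * ka2 / (vc2 * den)
    general = a * (-np.expm1(-k * dt) / k + np.expm1(-ka2 * dt) / ka2)
    limit = famt / (vc2 * k) * (1.0 - np.exp(-k * dt) * (1.0 + k * dt))
    return np.where(close, limit, general)


def conc_at(t, sidx, grid: DoseGrid, cl, vc, ka, f1, fmult=None) -> np.ndarray:
    """Concentration (ng/mL) at times ``t`` for subjects ``sidx``.

    ``t``: (N,) times in h; ``sidx``: (N,) integer subject indices into the
    grid and parameter vectors ``cl``, ``vc``, ``ka``, ``f1`` (each (S,)).
    ``fmult`` optionally overrides the grid's per-dose bioavailability
    multiplier (shape (S, n_doses)).
    """
    dt, live, k = _broadcast(t, sidx, grid, cl, vc, ka, f1)
    amt = grid.amt[sidx]
    oral = grid.oral[sidx]
    cl2 = cl[sidx][:, None]
    vc2 = vc[sidx][:, None]
    ka2 = np.broadcast_to(ka[sidx][:, None], dt.shape)
    fm = grid.fmult if fmult is None else fmult
    famt = amt * f1[sidx][:, None] * fm[sidx]

    # extreme trial parameters may overflow to inf/nan; callers screen them
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        c_iv = _iv_conc(dt, amt, grid.tinf[sidx], cl2, k)
        c_or = _oral_conc(dt, famt, vc2, ka2, k)
        contrib = np.where(oral, c_or, c_iv)
        return MGL_TO_NGML * np.where(live, contrib, 0.0).sum(axis=1)


def cum_auc_at(t, sidx, grid: DoseGrid, cl, vc, ka, f1, fmult=None) -> np.ndarray:
    """Cumulative AUC (ng*h/mL) from the time origin to times ``t``."""
    dt, live, k = _broadcast(t, sidx, grid, cl, vc, ka, f1)
    amt = grid.amt[sidx]
    oral = grid.oral[sidx]
    cl2 = cl[sidx][:, None]
    vc2 = vc[sidx][:, None]
    ka2 = np.broadcast_to(ka[sidx][:, None], dt.shape)
    fm = grid.fmult if fmult is None else fmult
    famt = amt * f1[sidx][:, None] * fm[sidx]

    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        a_iv = _iv_cum_auc(dt, amt, grid.tinf[sidx], cl2, k)
        a_or = _oral_cum_auc(dt, famt, vc2, ka2, k)
        contrib = np.where(oral, a_or, a_iv)
        return MGL_TO_NGML * np.where(live, contrib, 0.0).sum(axis=1)
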