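"""Dataset reading and writing in a NONMEM-style rectangular CSV dialect.

One row per dose or observation. Columns:

====== =====================================================================
ID     subject number
TIME   hours since the subject's first dose; "." when the sampling time is lost
AMT    dose amount (mg) on dose rows, "." on observation rows
RATE   infusion rate (mg/h) on IV dose rows, 0 for oral doses, "." otherwise
EVID   1 dose, 0 observation
MDV    1 when DV is missing/not applicable, else 0
CMT    1 oral depot, 2 central compartment
DV     observed concentration (ng/mL), "." on dose rows
FORM   1 IV solution, 2 oral suspension (PFS), 3 tablet ("." on obs rows)
FOOD   meal category of an oral dose: 0 none / 1 light / 2 moderate / 3 heavy
WT     body weight (kg)        AGE  age (years)
SEX    1 male, 0 female        RACE 1 White, 0 other
ETHNIC 1 not Hispanic, 0 Hispanic
EGFR   estimated glomerular filtration rate (mL/min/1.73 m^2), "." if missing
====== =====================================================================

Missing numeric fields are encoded as ".". BLQ flags are assigned on load
from the dataset LLOQ.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import pandas as pd

from .model import (
    DEFAULT_LLOQ,
    FOOD_CATEGORIES,
    ROUTE_IV,
    ROUTE_PFS,
    ROUTE_TABLET,
    DoseEvent,
    Observation,
    StudyDataset,
    Subject,
)

COLUMNS = [
    "ID", "TIME", "AMT", "RATE", "EVID", "MDV", "CMT", "DV",
    "FORM", "FOOD", "WT", "AGE", "SEX", "RACE", "ETHNIC", "EGFR",
]

_FORM_CODE = {ROUTE_IV: 1, ROUTE_PFS: 2, ROUTE_TABLET: 3}
_FORM_NAME = {v: k for k, v in _FORM_CODE.items()}
MISSING = "."


def _num(x) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return MISSING
    return format(float(x), ".10g")


def write_dataset(ds: StudyDataset, path) -> None:
    """Write a StudyDataset as NONMEM-style CSV (one event per row)."""
    rows = []
    for s in ds.subjects:
        base = {
            "ID": s.id,
            "WT": _num(s.weight),
            "AGE": _num(s.age),
            "SEX": 1 if s.sex == "M" else 0,
            "RACE": 1 if s.race == "White" else 0,
            "ETHNIC": 1 if s.ethnicity == "Not Hispanic" else 0,
            "EGFR": _num(s.egfr),
        }
        events = [("dose", d.time, d) for d in s.doses] + [
            ("obs", o.time, o) for o in s.observations
        ]
        # doses before observations at equal (or missing) times
        events.sort(key=lambda e: (math.inf if math.isnan(e[1]) else e[1], e[0] != "dose"))
        for kind, _, ev in events:
            if kind == "dose":
                rate = ev.amount / ev.infusion_duration if ev.route == ROUTE_IV else 0.0
                rows.append(
                    base
                    | {
                        "TIME": _num(ev.time),
                        "AMT": _num(ev.amount),
                        "RATE": _num(rate),
                        "EVID": 1,
                        "MDV": 1,
                        "CMT": 2 if ev.route == ROUTE_IV else 1,
                        "DV": MISSING,
                        "FORM": _FORM_CODE[ev.route],
                        "FOOD": FOOD_CATEGORIES.index(ev.food_category)
                        if ev.route != ROUTE_IV
                        else MISSING,
                    }
                )
            else:
                missing_dv = ev.missing_flag or math.isnan(ev.concentration)
                rows.append(
                    base
                    | {
                        "TIME": _num(ev.time),
                        "AMT": MISSING,
                        "RATE": MISSING,
                        "EVID": 0,
                        "MDV": 1 if missing_dv else 0,
                        "CMT": 2,
                        "DV": MISSING if missing_dv else _num(ev.concentration),
                        "FORM": MISSING,
                        "FOOD": MISSING,
                    }
                )
    pd.DataFrame(rows, columns=COLUMNS).to_csv(path, index=False)


class DatasetFormatError(ValueError):
    pass


def _parse(x, row, col):
    if isinstance(x, str) and x.strip() == MISSING:
        return None
    try:
        return float(x)
    except (TypeError, ValueError):
        raise DatasetFormatError(f"row {row}: cannot parse {col}={x!r}")


def read_dataset(path, lloq: float = DEFAULT_LLOQ) -> StudyDataset:
    """Read a NONMEM-style CSV into a StudyDataset with strict validation.

    Hard errors (with offending row numbers): missing required columns,
    unknown EVID, non-positive AMT on dose rows, and decreasing event times
    within a subject. Observations with DV below the LLOQ are flagged BLQ.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str)
    missing_cols = [c for c in COLUMNS if c not in df.columns]
    if missing_cols:
        raise DatasetFormatError(f"missing required columns: {', '.join(missing_cols)}")

    subjects: dict[int, Subject] = {}
    last_time: dict[int, float] = {}
    errors: list[str] = []
    for i, rec in enumerate(df.to_dict("records"), start=2):  # header is row 1
        sid = int(float(rec["ID"]))
        if sid not in subjects:
            wt = _parse(rec["WT"], i, "WT")
            if wt is None:
                raise DatasetFormatError(f"row {i}: subject {sid} has no body weight (WT)")
            subjects[sid] = Subject(
                id=sid,
                weight=wt,
                age=_parse(rec["AGE"], i, "AGE"),
                sex="M" if float(rec["SEX"]) == 1 else "F",
                race="White" if float(rec["RACE"]) == 1 else "Other",
                ethnicity="Not Hispanic" if float(rec["ETHNIC"]) == 1 else "Hispanic",
                egfr=_parse(rec["EGFR"], i, "EGFR"),
            )
        s = subjects[sid]
        evid = int(float(rec["EVID"]))
        t = _parse(rec["TIME"], i, "TIME")
        if t is not None:
            prev = last_time.get(sid, -math.inf)
            if t < prev:
                errors.append(f"row {i}: time {t} decreases within subject {sid}")
            last_time[sid] = t
        if evid == 1:
            amt = _parse(rec["AMT"], i, "AMT")
            if amt is None or amt <= 0:
                errors.append(f"row {i}: dose row with non-positive AMT {rec['AMT']}")
                continue
            form = int(float(rec["FORM"]))
            route = _FORM_NAME.get(form)
            if route is None:
                errors.append(f"row {i}: unknown FORM code {form}")
                continue
            rate = _parse(rec["RATE"], i, "RATE")
            tinf = amt / rate if (route == ROUTE_IV and rate) else 1.5
            food = rec["FOOD"]
            has_food = isinstance(food, str) and food.strip() != MISSING
            cat = FOOD_CATEGORIES[int(float(food))] if (route != ROUTE_IV and has_food) else "none"
            s.doses.append(
                DoseEvent(
                    time=t,
                    amount=amt,
                    route=route,
                    infusion_duration=tinf,
                    food_category=cat,
                )
            )
        elif evid == 0:
            dv = _parse(rec["DV"], i, "DV")
            mdv = int(float(rec["MDV"]))
            s.observations.append(
                Observation(
                    time=math.nan if t is None else t,
                    concentration=math.nan if dv is None else dv,
                    blq_flag=bool(dv is not None and dv < lloq),
                    missing_flag=bool(mdv == 1 or dv is None),
                )
            )
        else:
            errors.append(f"row {i}: unknown EVID {evid}")
    if errors:
        raise DatasetFormatError("; ".join(errors))
    return StudyDataset(subjects=list(subjects.values()), lloq=lloq)


def write_json(obj, path) -> None:
    """Write results structures as JSON (numpy types coerced)."""

    def default(o):
        import numpy as np

        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        if hasattr(o, "to_dict"):
            return o.to_dict()
        return str(o)

    Path(path).write_text(json.dumps(obj, indent=2, default=default))
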