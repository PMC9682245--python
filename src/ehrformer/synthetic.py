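"""Synthetic ICU cohort generator with a planted acuity signal.

Each stay carries a latent acuity score that drives (a) a time trend in the
measured values of continuous variables, (b) the administration rate of a
designated rescue medication, and (c) survival time through a proportional-
hazards draw.  Event streams are highly irregular: per-variable homogeneous
point processes, a configurable fraction of vital signs arriving as
simultaneous panels, and per-stay variable subsets.  Outcome labels are six
correlated binaries (ICU readmission within the hospital encounter,
inpatient mortality, and 7/30/90-day and 1-year mortality measured from ICU
admission) plus an auxiliary long-term hospital readmission target used only
for regularization.

The generator makes no claim of physiological realism; it exists to exercise
the tokenization, modeling, and evaluation pipeline with a recoverable
signal of known strength.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

import yaml

MORTALITY_HORIZONS_HOURS = (7 * 24.0, 30 * 24.0, 90 * 24.0, 365 * 24.0)
LABEL_NAMES = [
    "icu_readmission", "inpatient_mortality",
    "mortality_7d", "mortality_30d", "mortality_90d", "mortality_1y",
    "aux_longterm_readmission",
]
N_TASKS = len(LABEL_NAMES)
ACUITY_TASKS = LABEL_NAMES[:6]  # auxiliary target excluded from acuity metrics

EVENT_COLUMNS = ["stay_id", "variable", "category", "time_hours", "value"]


@dataclass
class SimConfig:
    """Cohort-level knobs.  Defaults define the study conditions used by the
    package's synthetic benchmark; see docs/methods.md for the rationale."""

    n_patients: int = 500
    multi_stay_prob: float = 0.12
    n_vitals: int = 8
    n_labs: int = 10
    n_meds: int = 6
    n_assess: int = 6
    panel_prob: float = 0.3
    #: per-variable events per hour by category
    base_rates: dict = field(default_factory=lambda: {
        "vital": 0.10, "lab": 0.05, "medication": 0.03, "assessment": 0.08,
    })
    acuity_effect: float = 2.0
    discrete_effect: float = 0.3
    los_range_hours: tuple = (8.0, 96.0)
    hazard_scale: float = 5.0e5
    hazard_shape: float = 0.35
    acuity_sd: float = 1.75
    readmit_logit: tuple = (-2.5, 0.9)       # intercept, acuity slope
    aux_readmit_logit: tuple = (-1.5, 0.7)
    static_missing_prob: float = 0.10
    discharge_tail_hours: float = 96.0
    seed: int = 0

    def __post_init__(self):
        for name in ("multi_stay_prob", "panel_prob", "static_missing_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        for name in ("n_patients", "n_vitals", "n_labs", "n_meds", "n_assess"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for cat, rate in self.base_rates.items():
            if rate <= 0:
                raise ValueError(f"base rate for {cat!r} must be positive")
        lo, hi = self.los_range_hours
        if not (1.0 <= lo <= hi <= 240.0):
            raise ValueError("los_range_hours must lie within [1, 240] hours")
        if self.hazard_scale <= 0 or self.hazard_shape <= 0:
            raise ValueError("hazard_scale and hazard_shape must be positive")

    def to_yaml(self) -> str:
        d = asdict(self)
        d["los_range_hours"] = list(self.los_range_hours)
        d["readmit_logit"] = list(self.readmit_logit)
        d["aux_readmit_logit"] = list(self.aux_readmit_logit)
        return yaml.safe_dump(d)

    @classmethod
    def from_yaml(cls, text: str) -> "SimConfig":
        d = yaml.safe_load(text)
        for key in ("los_range_hours", "readmit_logit", "aux_readmit_logit"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SyntheticStay:
    stay_id: str
    patient_id: str
    admit_time: float
    los_hours: float
    latent_acuity: float
    events: pd.DataFrame  # columns variable, category, time_hours, value
    static_record: dict
    death_time_hours: float  # inf when the patient survives the horizon
    hospital_discharge_hours: float
    labels: np.ndarray  # (7,) in LABEL_NAMES order


def derive_labels(death_time_hours: float, los_hours: float,
                  hospital_discharge_hours: float,
                  icu_readmission: int, longterm_readmission: int) -> np.ndarray:
    """Outcome labels for one stay.

    Horizon-k mortality is ``death_time <= k`` hours measured from ICU
    admission, so the four horizons nest by construction; inpatient mortality
    is death on or before hospital discharge.  The two readmission labels are
    acuity-linked Bernoulli draws resolved by the caller.
    """
    if death_time_hours <= 0:
        raise ValueError("death time must be positive")
    if los_hours > hospital_discharge_hours:
        raise ValueError("ICU stay cannot end after hospital discharge")
    labels = np.zeros(N_TASKS)
    labels[0] = float(icu_readmission)
    labels[1] = float(death_time_hours <= hospital_discharge_hours)
    for i, horizon in enumerate(MORTALITY_HORIZONS_HOURS):
        labels[2 + i] = float(death_time_hours <= horizon)
    labels[6] = float(longterm_readmission)
    return labels


def _variable_catalog(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Fixed per-cohort variable definitions (baseline level, noise scale,
    acuity trend coefficient)."""
    rows = []
    spec = [("vital", config.n_vitals), ("lab", config.n_labs),
            ("medication", config.n_meds), ("assessment", config.n_assess)]
    for cat, n in spec:
        for i in range(n):
            name = f"{cat}_{i:03d}"
            base = rng.uniform(20.0, 120.0)
            noise_sd = rng.uniform(0.5, 2.0)
            coef = rng.choice([-1.0, 1.0]) * rng.uniform(0.5, 1.5) * noise_sd
            rows.append({"variable": name, "category": cat, "base": base,
                         "noise_sd": noise_sd, "coef": coef})
    return pd.DataFrame(rows)


def _poisson_times(rate: float, horizon: float, rng: np.random.Generator) -> np.ndarray:
    n = rng.poisson(rate * horizon)
    return np.sort(rng.uniform(0.0, horizon, size=n))


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def generate_cohort(config: SimConfig) -> list[SyntheticStay]:
    """Generate a reproducible synthetic cohort (fixed seed => identical
    cohort).  See the module docstring for the planted-signal structure."""
    rng = np.random.default_rng(config.seed)
    catalog = _variable_catalog(config, rng)
    vitals = catalog[catalog["category"] == "vital"]
    rescue_med = catalog[catalog["category"] == "medication"].iloc[0]["variable"]

    stays: list[SyntheticStay] = []
    clock = 0.0
    stay_counter = 0
    for pid_idx in range(config.n_patients):
        patient_id = f"p{pid_idx:05d}"
        n_stays = 2 if rng.random() < config.multi_stay_prob else 1
        for _ in range(n_stays):
            clock += rng.exponential(5.0)  # cohort-clock gap between admissions
            stay_id = f"s{stay_counter:06d}"
            stay_counter += 1
            acuity = rng.normal(0.0, config.acuity_sd)
            lo, hi = config.los_range_hours
            los = rng.uniform(lo, hi)
            # proportional-hazards survival draw; shape < 1 front-loads risk
            e = rng.exponential(1.0)
            death = config.hazard_scale * (e * math.exp(-acuity)) ** (1.0 / config.hazard_shape)
            if death < los:  # death in the ICU truncates the stay
                los = max(death, 1e-3)
            # hospital discharge trails ICU discharge so inpatient mortality
            # differs from the ICU-horizon labels
            discharge_eff = los + rng.exponential(config.discharge_tail_hours)

            events = _stay_events(config, rng, catalog, vitals, rescue_med,
                                  acuity, los, death)
            static = _static_record(config, rng, acuity)
            readmit = int(rng.random() < _sigmoid(config.readmit_logit[0]
                                                  + config.readmit_logit[1] * acuity))
            aux = int(rng.random() < _sigmoid(config.aux_readmit_logit[0]
                                              + config.aux_readmit_logit[1] * acuity))
            labels = derive_labels(death, los, discharge_eff, readmit, aux)
            stays.append(SyntheticStay(
                stay_id=stay_id, patient_id=patient_id, admit_time=clock,
                los_hours=los, latent_acuity=acuity, events=events,
                static_record=static, death_time_hours=death,
                hospital_discharge_hours=discharge_eff, labels=labels,
            ))
    return stays


def _stay_events(config, rng, catalog, vitals, rescue_med, acuity, los, death):
    records = []
    horizon = min(los, death)
    # simultaneous vital panels: one shared time process, all retained vitals
    vital_subset = [v for v in vitals["variable"]
                    if rng.random() < 0.9]
    if len(vital_subset) < 2 and len(vitals) >= 2:
        vital_subset = list(vitals["variable"].iloc[:2])
    panel_rate = config.panel_prob * config.base_rates["vital"]
    panel_times = _poisson_times(panel_rate, horizon, rng)
    subset_prob = {"lab": 0.6, "medication": 0.5, "assessment": 0.7}
    for row in catalog.itertuples(index=False):
        cat = row.category
        rate = config.base_rates[cat]
        if cat == "vital":
            if row.variable not in vital_subset:
                continue
            times = np.concatenate([
                panel_times,
                _poisson_times((1.0 - config.panel_prob) * rate, horizon, rng),
            ])
            times = np.sort(times)
        else:
            if rng.random() > subset_prob[cat]:
                continue
            if row.variable == rescue_med:
                rate = rate * math.exp(np.clip(acuity * config.discrete_effect, -3, 3))
            times = _poisson_times(rate, horizon, rng)
        if times.size == 0:
            continue
        trend = acuity * config.acuity_effect * (times / max(los, 1e-6))
        values = row.base + row.coef * trend + row.noise_sd * rng.standard_normal(times.size)
        for t, v in zip(times, values):
            records.append((row.variable, cat, float(t), float(v)))
    frame = pd.DataFrame(records, columns=["variable", "category", "time_hours", "value"])
    return frame.sort_values(["time_hours", "variable"], kind="stable").reset_index(drop=True)


def _static_record(config, rng, acuity) -> dict:
    record = {
        "age": float(np.clip(60.0 + 8.0 * acuity + rng.normal(0, 10), 18, 95)),
        "bmi": float(rng.normal(28.0, 5.0)),
        "charlson_index": float(rng.poisson(math.exp(0.3 + 0.3 * acuity))),
        "prior_admissions": float(rng.poisson(0.8)),
        "sex": str(rng.choice(["female", "male"])),
        "admission_type": str(rng.choice(["elective", "emergency", "transfer"],
                                         p=[0.3, 0.55, 0.15])),
        "smoking_status": str(rng.choice(["never", "former", "current"],
                                         p=[0.45, 0.35, 0.2])),
    }
    for key in list(record):
        if rng.random() < config.static_missing_prob:
            record[key] = None
    return record


# ---------------------------------------------------------------------------
# cohort IO (long-format delimited tables)


def write_cohort(stays: list[SyntheticStay], directory: str) -> None:
    os.makedirs(directory, exist_ok=True)
    event_rows = []
    for s in stays:
        if len(s.events):
            chunk = s.events.copy()
            chunk.insert(0, "stay_id", s.stay_id)
            event_rows.append(chunk)
    events = (pd.concat(event_rows, ignore_index=True)
              if event_rows else pd.DataFrame(columns=EVENT_COLUMNS))
    events[["stay_id", "variable", "time_hours", "value"]].to_csv(
        os.path.join(directory, "events.csv"), index=False, float_format="%.17g")
    variables = (events[["variable", "category"]].drop_duplicates().sort_values("variable")
                 if len(events) else pd.DataFrame(columns=["variable", "category"]))
    variables.to_csv(os.path.join(directory, "variables.csv"), index=False)

    static = pd.DataFrame([{"stay_id": s.stay_id, **{k: ("" if v is None else v)
                                                     for k, v in s.static_record.items()}}
                           for s in stays])
    if not len(static):
        static = pd.DataFrame(columns=["stay_id"])
    static.to_csv(os.path.join(directory, "static.csv"), index=False)

    meta = pd.DataFrame([{
        "stay_id": s.stay_id, "patient_id": s.patient_id,
        "admit_time": s.admit_time, "los_hours": s.los_hours,
        "latent_acuity": s.latent_acuity,
        "death_time_hours": "" if math.isinf(s.death_time_hours) else s.death_time_hours,
        "hospital_discharge_hours": s.hospital_discharge_hours,
        **{name: int(v) for name, v in zip(LABEL_NAMES, s.labels)},
    } for s in stays])
    if not len(meta):
        meta = pd.DataFrame(columns=["stay_id", "patient_id", "admit_time",
                                     "los_hours", "latent_acuity",
                                     "death_time_hours", "hospital_discharge_hours",
                                     *LABEL_NAMES])
    meta.to_csv(os.path.join(directory, "labels.csv"), index=False,
                float_format="%.17g")


def read_cohort(directory: str) -> list[SyntheticStay]:
    events = pd.read_csv(os.path.join(directory, "events.csv"),
                         dtype={"stay_id": str, "variable": str,
                                "time_hours": str, "value": str})
    for col in ("time_hours", "value"):
        def parse(x):
            try:
                return float(x)
            except (TypeError, ValueError):
                return np.nan
        parsed = events[col].map(parse)  # exact round-trip float parsing
        bad = parsed.isna() & events[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header is line 1
            raise ValueError(f"events.csv line {line}: non-numeric {col} "
                             f"value {events[col][bad.idxmax()]!r}")
        events[col] = parsed
    variables = pd.read_csv(os.path.join(directory, "variables.csv"))
    cat_map = dict(zip(variables["variable"], variables["category"]))
    events["category"] = events["variable"].map(cat_map)

    static = pd.read_csv(os.path.join(directory, "static.csv"), dtype=str,
                         keep_default_na=False)
    meta = pd.read_csv(os.path.join(directory, "labels.csv"),
                       dtype={"stay_id": str, "patient_id": str},
                       float_precision="round_trip")

    by_stay = {sid: grp.drop(columns="stay_id").reset_index(drop=True)
               for sid, grp in events.groupby("stay_id")}
    static_by_stay = {}
    for _, row in static.iterrows():
        rec = {}
        for col, val in row.items():
            if col == "stay_id":
                continue
            if val == "":
                rec[col] = None
            else:
                try:
                    rec[col] = float(val)
                except ValueError:
                    rec[col] = val
        static_by_stay[row["stay_id"]] = rec

    stays = []
    empty = pd.DataFrame(columns=["variable", "category", "time_hours", "value"])
    for _, row in meta.iterrows():
        death = row["death_time_hours"]
        death = float("inf") if pd.isna(death) else float(death)
        stays.append(SyntheticStay(
            stay_id=row["stay_id"], patient_id=row["patient_id"],
            admit_time=float(row["admit_time"]), los_hours=float(row["los_hours"]),
            latent_acuity=float(row["latent_acuity"]),
            events=by_stay.get(row["stay_id"], empty.copy()),
            static_record=static_by_stay.get(row["stay_id"], {}),
            death_time_hours=death,
            hospital_discharge_hours=float(row["hospital_discharge_hours"]),
            labels=np.array([float(row[name]) for name in LABEL_NAMES]),
        ))
    return stays
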