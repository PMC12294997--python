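"""Seeded generators for every input the pipeline consumes.

All generators draw from ``numpy.random.default_rng(seed)`` and are fully
deterministic under a fixed seed.  Ground truth is emitted alongside every
dataset so recovery can be measured:

* **vitals** — rows mimicking an ED triage table (temperature, heartrate,
  resprate, o2sat, sbp, dbp, pain) drawn uniformly from physiological
  ranges; the latent acuity g(vitals) maps a weighted sum of standardized
  deviations from normal midpoints through a sigmoid onto the 1..5 ESI
  scale, and the label is g plus Gaussian noise, clipped to [1, 5];
* **cohorts** — patient/provider profile sets, optionally with a *planted*
  matching: each patient is constructed to score far above the margin with
  exactly one provider (unique specialty token, a resource only that
  provider stocks, matching one-hot feature vectors), making the planted
  pairing the unique stable matching;
* **request streams** — Bernoulli arrivals of fresh patient requests;
* **evaluation fixtures** — statement/task/tool-call logs constructed to hit
  requested CR/TCS/TC values exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .evaluation import StatementLog, TaskRecord, ToolCall, ToolCallLog
from .profiles import PatientProfile, ProviderProfile
from .scheduler import NO_REQ, PatientRequest
from .triage_model import FEATURE_ORDER, VitalsRecord

__all__ = [
    "GeneratorConfig",
    "ConfigError",
    "VITALS_RANGES",
    "ACUITY_MODEL_DEFAULTS",
    "latent_acuity",
    "generate_vitals",
    "generate_cohort",
    "generate_requests",
    "EvalFixture",
    "generate_eval_fixtures",
]


class ConfigError(ValueError):
    """Raised for infeasible generator settings."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Shared knobs for every generator; the seed pins all randomness."""

    seed: int = 0
    n_patients: int = 20
    m_providers: int = 10
    noise_sigma: float = 0.1
    planted_matching: bool = False
    arrival_prob: float = 0.5

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ConfigError("noise_sigma must be >= 0")
        if not 0.0 <= self.arrival_prob <= 1.0:
            raise ConfigError("arrival_prob must be in [0, 1]")
        if self.n_patients < 1 or self.m_providers < 1:
            raise ConfigError("cohort sizes must be >= 1")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


#: Uniform sampling ranges spanning plausible ED physiology.
VITALS_RANGES: dict[str, tuple[float, float]] = {
    "temperature": (95.0, 104.0),
    "heartrate": (40.0, 180.0),
    "resprate": (8.0, 40.0),
    "o2sat": (70.0, 100.0),
    "sbp": (80.0, 200.0),
    "dbp": (40.0, 120.0),
    "pain": (0.0, 10.0),
}

#: Latent acuity model: per-vital normal midpoints, deviation scales and
#: weights, plus the sigmoid gain/center spreading g over the open (1, 5)
#: interval.  Weights sum to 1.
ACUITY_MODEL_DEFAULTS: dict = {
    "midpoints": {
        "temperature": 98.6,
        "heartrate": 80.0,
        "resprate": 16.0,
        "o2sat": 98.0,
        "sbp": 120.0,
        "dbp": 80.0,
        "pain": 0.0,
    },
    "scales": {
        "temperature": 2.7,
        "heartrate": 50.0,
        "resprate": 12.0,
        "o2sat": 14.0,
        "sbp": 40.0,
        "dbp": 20.0,
        "pain": 10.0,
    },
    "weights": {
        "temperature": 0.15,
        "heartrate": 0.20,
        "resprate": 0.15,
        "o2sat": 0.25,
        "sbp": 0.10,
        "dbp": 0.05,
        "pain": 0.10,
    },
    "gain": 4.0,
    "center": 0.83,
}


def latent_acuity(vitals: pd.DataFrame, params: Optional[dict] = None) -> np.ndarray:
    """g(vitals) = 5 - 4 * sigmoid(gain * (weighted deviation sum - center)).

    The weighted sum aggregates |x - midpoint| / scale per vital; sicker
    vitals push the sigmoid up and acuity toward 1 (most urgent).
    """
    p = params or ACUITY_MODEL_DEFAULTS
    z = np.zeros(len(vitals), dtype=float)
    for col in FEATURE_ORDER:
        dev = np.abs(vitals[col].to_numpy(dtype=float) - p["midpoints"][col]) / p["scales"][col]
        z += p["weights"][col] * dev
    sig = 1.0 / (1.0 + np.exp(-p["gain"] * (z - p["center"])))
    return 5.0 - 4.0 * sig


def generate_vitals(config: GeneratorConfig, n: Optional[int] = None) -> pd.DataFrame:
    """Labeled vitals table with the latent acuity stored in ``g_true``.

    The label is clip(g + N(0, sigma), 1, 5); rows where the noise band
    g +/- 3 sigma crosses the clip boundary can be excluded downstream when
    measuring noise recovery.
    """
    n = int(config.n_patients if n is None else n)
    if n < 1:
        raise ConfigError("n must be >= 1")
    rng = config.rng()
    data = {}
    for col in FEATURE_ORDER:
        lo, hi = VITALS_RANGES[col]
        data[col] = rng.uniform(lo, hi, size=n)
    data["pain"] = np.floor(data["pain"]).clip(0, 10).astype(int)
    df = pd.DataFrame(data, columns=list(FEATURE_ORDER))
    g = latent_acuity(df)
    noise = rng.normal(0.0, config.noise_sigma, size=n) if config.noise_sigma > 0 else np.zeros(n)
    df["acuity"] = np.clip(g + noise, 1.0, 5.0)
    df["g_true"] = g
    return df


_CONDITION_POOL = (
    "chest pain",
    "shortness of breath",
    "fever and cough",
    "severe headache",
    "abdominal pain",
    "arm laceration",
    "ankle fracture",
    "dizziness",
)

_SPECIALTY_POOL = (
    "cardiology",
    "pulmonology",
    "internal medicine",
    "neurology",
    "gastroenterology",
    "orthopedics",
    "emergency medicine",
    "family medicine",
)

_RESOURCE_POOL = ("ecg", "oxygen", "lab", "xray", "ct", "ultrasound", "suture")

_LOCATIONS = ("north", "south", "east", "west")


def generate_cohort(
    config: GeneratorConfig,
) -> tuple[list[PatientProfile], list[ProviderProfile], Optional[dict[str, str]]]:
    """Patients and providers, optionally with a planted unique matching.

    Planted mode (capacity-1 providers, requires n <= m): patient i gets the
    specialty token, exclusive resource and one-hot feature vector of its
    planted provider, so S(i, planted) = 1.0 while every other provider
    fails the resource constraint and scores at most 0.1 — a margin far
    above 0.2, and the planted pairing is the unique stable matching.
    """
    rng = config.rng()
    n, m = config.n_patients, config.m_providers
    if config.planted_matching:
        if n > m:
            raise ConfigError(f"planted matching needs n <= m (capacity 1); got {n} > {m}")
        patients, providers = [], []
        planted: dict[str, str] = {}
        for j in range(m):
            eye = tuple(1.0 if t == j else 0.0 for t in range(m))
            providers.append(
                ProviderProfile(
                    provider_id=f"r{j:03d}",
                    specialties=frozenset({f"spec{j:03d}"}),
                    capacity=1,
                    available_resources={f"res{j:03d}": 1},
                    location=_LOCATIONS[j % len(_LOCATIONS)],
                    services=frozenset(),
                    numeric_features=eye,
                )
            )
        targets = rng.permutation(m)[:n]
        for i in range(n):
            j = int(targets[i])
            eye = tuple(1.0 if t == j else 0.0 for t in range(m))
            patients.append(
                PatientProfile(
                    patient_id=f"p{i:03d}",
                    condition=f"spec{j:03d}",
                    urgency=5,  # demand 1: capacity term is 1 for every provider
                    required_resources={f"res{j:03d}": 1},
                    location=_LOCATIONS[j % len(_LOCATIONS)],
                    numeric_features=eye,
                )
            )
            planted[f"p{i:03d}"] = f"r{j:03d}"
        return patients, providers, planted

    patients = []
    for i in range(n):
        condition = _CONDITION_POOL[int(rng.integers(len(_CONDITION_POOL)))]
        n_res = int(rng.integers(0, 3))
        res_names = rng.choice(len(_RESOURCE_POOL), size=n_res, replace=False)
        patients.append(
            PatientProfile(
                patient_id=f"p{i:03d}",
                condition=condition,
                urgency=int(rng.integers(1, 6)),
                required_resources={_RESOURCE_POOL[int(k)]: int(rng.integers(1, 3)) for k in res_names},
                location=_LOCATIONS[int(rng.integers(len(_LOCATIONS)))],
                numeric_features=tuple(rng.uniform(0, 1, size=4)),
            )
        )
    providers = []
    for j in range(m):
        n_spec = int(rng.integers(1, 3))
        specs = rng.choice(len(_SPECIALTY_POOL), size=n_spec, replace=False)
        n_res = int(rng.integers(1, 5))
        res_names = rng.choice(len(_RESOURCE_POOL), size=n_res, replace=False)
        providers.append(
            ProviderProfile(
                provider_id=f"r{j:03d}",
                specialties=frozenset(_SPECIALTY_POOL[int(k)] for k in specs),
                capacity=int(rng.integers(1, 4)),
                available_resources={_RESOURCE_POOL[int(k)]: int(rng.integers(1, 4)) for k in res_names},
                location=_LOCATIONS[int(rng.integers(len(_LOCATIONS)))],
                services=frozenset(),
                numeric_features=tuple(rng.uniform(0, 1, size=4)),
            )
        )
    return patients, providers, None


def generate_requests(config: GeneratorConfig, T: int) -> list:
    """Length-T stream: each tick is NoReq with probability 1 - arrival_prob,
    else a fresh PatientRequest with generated vitals and complaint."""
    if T < 1:
        raise ConfigError("T must be >= 1")
    rng = config.rng()
    stream = []
    counter = 0
    for t in range(T):
        if rng.uniform() >= config.arrival_prob:
            stream.append(NO_REQ)
            continue
        row = {}
        for col in FEATURE_ORDER:
            lo, hi = VITALS_RANGES[col]
            row[col] = float(rng.uniform(lo, hi))
        row["pain"] = int(min(10, math.floor(row["pain"])))
        complaint = _CONDITION_POOL[int(rng.integers(len(_CONDITION_POOL)))]
        stream.append(
            PatientRequest(
                patient_id=f"req{counter:04d}",
                chief_complaint=complaint,
                vitals=VitalsRecord(**row),
            )
        )
        counter += 1
    return stream


@dataclass(frozen=True)
class EvalFixture:
    """Logs plus the metric values they were constructed to produce."""

    statements: StatementLog
    task: TaskRecord
    tool_calls: ToolCallLog
    expected_cr: float
    expected_tcs: float
    expected_tc: float


def generate_eval_fixtures(
    config: GeneratorConfig,
    cr: Optional[tuple[int, int]] = None,
    tcs: Optional[tuple[int, int]] = None,
    tc: Optional[tuple[int, int]] = None,
) -> EvalFixture:
    """Construct logs hitting requested metric fractions exactly.

    Each metric is requested as (numerator, denominator); unspecified
    metrics get random feasible fractions drawn from the config seed.
    """
    rng = config.rng()

    def pick(frac: Optional[tuple[int, int]]) -> tuple[int, int]:
        if frac is None:
            den = int(rng.integers(1, 13))
            num = int(rng.integers(0, den + 1))
            return num, den
        num, den = frac
        if den < 1 or not 0 <= num <= den:
            raise ConfigError(f"infeasible metric fraction {num}/{den}")
        return num, den

    cr_n, cr_d = pick(cr)
    statements = StatementLog(
        statements=tuple(
            (f"statement {i}", i < cr_n) for i in range(cr_d)
        )
    )

    tcs_n, tcs_d = pick(tcs)
    keywords = tuple(f"kw{i:02d}" for i in range(tcs_d))
    output = "report covering " + " ".join(keywords[:tcs_n]) if tcs_n else "report covering nothing"
    task = TaskRecord(
        task_description="produce a report mentioning " + " ".join(keywords),
        output=output,
        required_keywords=frozenset(keywords),
    )

    tc_n, tc_d = pick(tc)
    calls = tuple(
        ToolCall(
            expected_tool_name=f"tool_{i}",
            actual_tool_name=f"tool_{i}" if i < tc_n else "wrong_tool",
            expected_params={"arg": i},
            actual_params={"arg": i},
        )
        for i in range(tc_d)
    )
    return EvalFixture(
        statements=statements,
        task=task,
        tool_calls=ToolCallLog(calls),
        expected_cr=cr_n / cr_d,
        expected_tcs=tcs_n / tcs_d,
        expected_tc=tc_n / tc_d,
    )
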