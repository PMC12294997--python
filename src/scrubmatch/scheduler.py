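"""Discrete-time scheduling state machine.

The schedule book evolves as S(t+1) = F(S(t), R(t)) where R(t) is either a
new patient request or the distinguished NoReq value (no arrival this tick).
F is a composition of six stage functions executed history-first:

    F = F_appointment . F_logistic . F_prognosis . F_profile . F_vital . F_history

Every stage propagates NoReq untouched, so a tick without an arrival leaves
the schedule byte-for-byte identical (only the time index advances).  The
default stage suite is fully rule-based and deterministic:

* history     — look up the patient in the registry, attach the visit count;
* vital       — compute acuity from the vitals (trained triage model, or a
                coarse threshold rule when none is configured);
* profile     — assemble a PatientProfile from complaint tokens and acuity;
* prognosis   — map complaint tokens to required resources via a rule table;
* logistic    — shortlist the top-k providers by compatibility (default 3);
* appointment — run deferred acceptance against the shortlist and write the
                patient into the matched provider's first empty slot.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

from .matching import derive_ranks, gale_shapley
from .profiles import (
    DEFAULT_WEIGHTS,
    PatientProfile,
    ProviderProfile,
    ScoreWeights,
    score_compatibility,
    score_matrix,
    tokenize,
)
from .triage_model import TriageModel, VitalsRecord, acuity_to_level, predict_acuity

__all__ = [
    "NoReq",
    "NO_REQ",
    "PatientRequest",
    "SlotEntry",
    "PatientHistory",
    "SystemState",
    "StageFunction",
    "StageConfig",
    "StateError",
    "CompositionError",
    "DEFAULT_RULE_TABLE",
    "new_system_state",
    "rule_based_acuity",
    "step",
    "compose_pipeline",
    "default_stage_suite",
]

logger = logging.getLogger("scrubmatch.scheduler")


class NoReq:
    """Singleton marker for 'no new patient request this tick'."""

    _instance: Optional["NoReq"] = None

    def __new__(cls) -> "NoReq":
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "NoReq"


NO_REQ = NoReq()


@dataclass(frozen=True)
class PatientRequest:
    """A new arrival: identity, chief complaint and triage vitals."""

    patient_id: str
    chief_complaint: str
    vitals: VitalsRecord


@dataclass(frozen=True)
class SlotEntry:
    patient_id: str
    acuity: int
    required_resources: Mapping[str, int]


@dataclass
class PatientHistory:
    visits: int = 0
    last_condition: Optional[str] = None


@dataclass
class SystemState:
    """The schedule book: per-provider slot lists plus known profiles.

    Each provider owns exactly ``capacity`` slots; a slot is either None
    (free) or a SlotEntry.  A patient occupies at most one slot.
    """

    time_index: int = 0
    schedule: dict[str, list[Optional[SlotEntry]]] = field(default_factory=dict)
    registry: dict[str, PatientHistory] = field(default_factory=dict)
    provider_pool: dict[str, ProviderProfile] = field(default_factory=dict)

    def empty_slots(self, provider_id: str) -> int:
        return sum(1 for s in self.schedule[provider_id] if s is None)

    def occupied_slots(self) -> int:
        return sum(
            1 for slots in self.schedule.values() for s in slots if s is not None
        )

    def patient_slot(self, patient_id: str) -> Optional[tuple[str, int]]:
        for r, slots in self.schedule.items():
            for k, s in enumerate(slots):
                if s is not None and s.patient_id == patient_id:
                    return r, k
        return None


class StateError(ValueError):
    """Raised when a state references providers absent from its pool."""


class CompositionError(ValueError):
    """Raised when composing an empty stage list."""


def new_system_state(providers: Sequence[ProviderProfile]) -> SystemState:
    """Fresh state at t = 0 with every slot free."""
    return SystemState(
        time_index=0,
        schedule={r.provider_id: [None] * r.capacity for r in providers},
        registry={},
        provider_pool={r.provider_id: r for r in providers},
    )


@dataclass(frozen=True)
class StageFunction:
    """A named transform on (state, working-record).

    Calling a stage with the NoReq record short-circuits: the state passes
    through untouched, so NoReq propagation holds for every stage and every
    composition by construction.
    """

    name: str
    transform: Callable

    def __call__(self, state: SystemState, record):
        if record is NO_REQ:
            return state, record
        return self.transform(state, record)


def step(state: SystemState, request, pipeline: StageFunction) -> SystemState:
    """One tick: apply the pipeline and advance the time index.

    With request = NoReq the schedule is returned unchanged (deep-copied,
    so the input state is never mutated).
    """
    unknown = set(state.schedule) - set(state.provider_pool)
    if unknown:
        raise StateError(f"schedule references unknown providers {sorted(unknown)}")
    new_state = copy.deepcopy(state)
    new_state.time_index = state.time_index + 1
    if request is NO_REQ:
        return new_state
    record = {"request": request}
    new_state, _record = pipeline(new_state, record)
    return new_state


def compose_pipeline(stages: Sequence[StageFunction]) -> StageFunction:
    """Right-to-left composition: the list's last element is applied first."""
    if not stages:
        raise CompositionError("cannot compose an empty stage list")
    stages = tuple(stages)

    def transform(state: SystemState, record):
        for stage in reversed(stages):
            state, record = stage(state, record)
        return state, record

    name = " . ".join(s.name for s in stages)
    return StageFunction(name=name, transform=transform)


#: Complaint-token -> required-resource rules used by the prognosis stage.
DEFAULT_RULE_TABLE: dict[str, dict[str, int]] = {
    "chest": {"ecg": 1},
    "breath": {"oxygen": 1},
    "breathing": {"oxygen": 1},
    "fever": {"lab": 1},
    "cough": {"xray": 1},
    "headache": {"ct": 1},
    "abdominal": {"ultrasound": 1},
    "laceration": {"suture": 1},
    "fracture": {"xray": 1},
    "dizziness": {"lab": 1},
}


def rule_based_acuity(vitals: VitalsRecord) -> int:
    """Coarse deterministic acuity screen used when no model is configured.

    Counts grossly abnormal vitals (hypoxia, shock-range or crisis-range
    blood pressure, brady/tachycardia, brady/tachypnea, extreme temperature)
    and maps the count to the ESI scale; severe pain sharpens acuity by one.
    """
    flags = 0
    flags += vitals.o2sat < 90
    flags += vitals.sbp < 90 or vitals.sbp > 180
    flags += vitals.heartrate < 40 or vitals.heartrate > 130
    flags += vitals.resprate < 8 or vitals.resprate > 30
    flags += vitals.temperature < 95 or vitals.temperature > 103
    acuity = 5 - 2 * flags - (1 if vitals.pain >= 7 else 0)
    return max(1, min(5, acuity))


@dataclass(frozen=True)
class StageConfig:
    """Tunables for the default stage suite."""

    weights: ScoreWeights = DEFAULT_WEIGHTS
    rule_table: Mapping[str, Mapping[str, int]] = field(
        default_factory=lambda: DEFAULT_RULE_TABLE
    )
    shortlist_size: int = 3
    acuity_model: Optional[TriageModel] = None


def default_stage_suite(config: Optional[StageConfig] = None) -> list[StageFunction]:
    """The six stages, listed in composition order (appointment first in the
    list, history first in execution)."""
    cfg = config or StageConfig()

    def history(state: SystemState, record):
        req: PatientRequest = record["request"]
        hist = state.registry.setdefault(req.patient_id, PatientHistory())
        record["visits"] = hist.visits
        hist.visits += 1
        hist.last_condition = req.chief_complaint
        logger.info("history: patient %s visit #%d", req.patient_id, hist.visits)
        return state, record

    def vital(state: SystemState, record):
        req: PatientRequest = record["request"]
        if cfg.acuity_model is not None:
            yhat = predict_acuity(cfg.acuity_model, [req.vitals])
            record["acuity"] = int(acuity_to_level(yhat)[0])
        else:
            record["acuity"] = rule_based_acuity(req.vitals)
        logger.info("vital: patient %s acuity %d", req.patient_id, record["acuity"])
        return state, record

    def profile(state: SystemState, record):
        req: PatientRequest = record["request"]
        record["profile"] = PatientProfile(
            patient_id=req.patient_id,
            condition=req.chief_complaint,
            urgency=record["acuity"],
        )
        logger.info("profile: built illness profile for %s", req.patient_id)
        return state, record

    def prognosis(state: SystemState, record):
        req: PatientRequest = record["request"]
        resources: dict[str, int] = {}
        for token in sorted(tokenize(req.chief_complaint)):
            for res, qty in cfg.rule_table.get(token, {}).items():
                resources[res] = max(resources.get(res, 0), qty)
        if not resources:
            logger.warning(
                "prognosis: no rule-table entry for complaint %r; empty resource plan",
                req.chief_complaint,
            )
        record["profile"] = record["profile"].model_copy(
            update={"required_resources": resources}
        )
        record["required_resources"] = resources
        return state, record

    def logistic(state: SystemState, record):
        patient = record["profile"]
        candidates = [
            state.provider_pool[r]
            for r in sorted(state.provider_pool)
            if state.empty_slots(r) > 0
        ]
        scored = sorted(
            candidates,
            key=lambda r: (-score_compatibility(patient, r, cfg.weights), r.provider_id),
        )
        record["shortlist"] = [r.provider_id for r in scored[: cfg.shortlist_size]]
        logger.info("logistic: shortlist for %s = %s", patient.patient_id, record["shortlist"])
        return state, record

    def appointment(state: SystemState, record):
        patient = record["profile"]
        shortlist = record.get("shortlist", [])
        if state.patient_slot(patient.patient_id) is not None:
            record["already_scheduled"] = True
            logger.info("appointment: %s already holds a slot", patient.patient_id)
            return state, record
        if not shortlist:
            record["unmatched"] = True
            logger.info("appointment: no provider with free slots for %s", patient.patient_id)
            return state, record
        providers = [state.provider_pool[r] for r in shortlist]
        matrix = score_matrix([patient], providers, cfg.weights)
        prefs = derive_ranks(matrix)
        capacities = {r.provider_id: state.empty_slots(r.provider_id) for r in providers}
        result = gale_shapley(prefs, matrix, capacities)
        provider_id = result.provider_of(patient.patient_id)
        if provider_id is None:
            record["unmatched"] = True
            logger.info("appointment: %s left unmatched", patient.patient_id)
            return state, record
        slots = state.schedule[provider_id]
        k = next(i for i, s in enumerate(slots) if s is None)
        slots[k] = SlotEntry(
            patient_id=patient.patient_id,
            acuity=patient.urgency,
            required_resources=dict(record.get("required_resources", {})),
        )
        record["scheduled_provider"] = provider_id
        record["slot"] = k
        logger.info("appointment: %s -> %s slot %d", patient.patient_id, provider_id, k)
        return state, record

    return [
        StageFunction("appointment", appointment),
        StageFunction("logistic", logistic),
        StageFunction("prognosis", prognosis),
        StageFunction("profile", profile),
        StageFunction("vital", vital),
        StageFunction("history", history),
    ]
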