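"""Patient and provider profiles and the compatibility score S(p, r).

The matching engine consumes a single real number S(p, r) in [0, 1] per
patient-provider pair expressing how well provider ``r`` can serve patient
``p``.  The score is a convex combination of four interpretable terms:

* **hard-constraint satisfaction** — does the provider stock every resource
  (equipment, labs, beds ...) the patient requires, in sufficient quantity?
* **specialty overlap** — Jaccard similarity between the patient's condition
  tokens and the provider's specialty/service tokens;
* **feature similarity** — cosine similarity of optional numeric feature
  vectors (clamped at 0 so the score stays in [0, 1]);
* **capacity adequacy** — how much spare capacity the provider has relative
  to the demand implied by the patient's urgency.

Unmet hard constraints gate the whole score to 0: a provider that cannot
supply a required resource is incompatible no matter how well everything
else lines up.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

__all__ = [
    "PatientProfile",
    "ProviderProfile",
    "ScoreWeights",
    "CompatibilityMatrix",
    "DEFAULT_WEIGHTS",
    "tokenize",
    "hard_constraints_satisfied",
    "score_compatibility",
    "score_matrix",
]

_TOKEN_RE = re.compile(r"[0-9a-z]+")


@lru_cache(maxsize=8192)
def tokenize(text: str) -> frozenset[str]:
    """Lowercase and split on non-alphanumerics; returns the token set."""
    return frozenset(_TOKEN_RE.findall(text.lower()))


class PatientProfile(BaseModel):
    """Structured patient record feeding the compatibility score.

    ``urgency`` follows the ESI convention: 1 is the most urgent, 5 the
    least.  ``required_resources`` maps resource names to the minimum
    quantity the provider must have available.
    """

    model_config = ConfigDict(frozen=True)

    patient_id: str = Field(min_length=1)
    condition: str = ""
    urgency: int = Field(default=3, ge=1, le=5)
    required_resources: Mapping[str, int] = Field(default_factory=dict)
    location: str = ""
    feature_tokens: frozenset[str] = frozenset()
    numeric_features: Optional[tuple[float, ...]] = None

    @field_validator("required_resources")
    @classmethod
    def _nonnegative_quantities(cls, v: Mapping[str, int]) -> Mapping[str, int]:
        for name, qty in v.items():
            if qty < 0:
                raise ValueError(f"resource {name!r} has negative quantity {qty}")
        return dict(v)

    @property
    def token_set(self) -> frozenset[str]:
        """Condition tokens plus any derived categorical tokens."""
        return tokenize(self.condition) | frozenset(t.lower() for t in self.feature_tokens)


class ProviderProfile(BaseModel):
    """Provider record: specialties, open slots and stocked resources."""

    model_config = ConfigDict(frozen=True)

    provider_id: str = Field(min_length=1)
    specialties: frozenset[str] = frozenset()
    capacity: int = Field(default=1, ge=1)
    available_resources: Mapping[str, int] = Field(default_factory=dict)
    location: str = ""
    services: frozenset[str] = frozenset()
    numeric_features: Optional[tuple[float, ...]] = None

    @field_validator("available_resources")
    @classmethod
    def _nonnegative_quantities(cls, v: Mapping[str, int]) -> Mapping[str, int]:
        for name, qty in v.items():
            if qty < 0:
                raise ValueError(f"resource {name!r} has negative quantity {qty}")
        return dict(v)

    @property
    def token_set(self) -> frozenset[str]:
        """Union of tokens from every specialty and service label."""
        tokens: set[str] = set()
        for label in list(self.specialties) + list(self.services):
            tokens |= tokenize(label)
        return frozenset(tokens)


class WeightError(ValueError):
    """Raised when score weights are invalid."""


class ScoreWeights(BaseModel):
    """Nonnegative weights of the four score terms; must sum to 1."""

    model_config = ConfigDict(frozen=True)

    w_constraint: float = Field(ge=0.0, le=1.0)
    w_specialty: float = Field(ge=0.0, le=1.0)
    w_feature: float = Field(ge=0.0, le=1.0)
    w_urgency: float = Field(ge=0.0, le=1.0)

    @model_validator(mode="after")
    def _sums_to_one(self) -> "ScoreWeights":
        total = self.w_constraint + self.w_specialty + self.w_feature + self.w_urgency
        if abs(total - 1.0) > 1e-9:
            raise WeightError(f"weights must sum to 1, got {total!r}")
        return self

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.w_constraint, self.w_specialty, self.w_feature, self.w_urgency)


#: Default emphasis: constraints dominate, then specialty fit, then numeric
#: similarity, then capacity headroom.
DEFAULT_WEIGHTS = ScoreWeights(w_constraint=0.4, w_specialty=0.3, w_feature=0.2, w_urgency=0.1)


class DuplicateIdError(ValueError):
    """Raised when a cohort contains a repeated patient or provider id."""


@dataclass(frozen=True)
class CompatibilityMatrix:
    """Dense |P| x |R| matrix of scores S(p, r) in [0, 1]."""

    patients: tuple[str, ...]
    providers: tuple[str, ...]
    scores: np.ndarray

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", scores)
        if scores.shape != (len(self.patients), len(self.providers)):
            raise ValueError(
                f"score matrix shape {scores.shape} does not match "
                f"{len(self.patients)} patients x {len(self.providers)} providers"
            )
        if not np.all(np.isfinite(scores)):
            raise ValueError("scores must be finite")
        if scores.size and (scores.min() < 0.0 or scores.max() > 1.0):
            raise ValueError("scores must lie in [0, 1]")

    def score(self, patient_id: str, provider_id: str) -> float:
        return float(
            self.scores[self.patients.index(patient_id), self.providers.index(provider_id)]
        )


def hard_constraints_satisfied(patient: PatientProfile, provider: ProviderProfile) -> bool:
    """True iff the provider stocks every required resource in quantity.

    A resource absent from the provider counts as quantity 0; a patient with
    no requirements is vacuously satisfied by any provider.
    """
    avail = provider.available_resources
    return all(avail.get(name, 0) >= qty for name, qty in patient.required_resources.items())


def _jaccard(a: frozenset[str], b: frozenset[str]) -> float:
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


def _cosine(u: Optional[Sequence[float]], v: Optional[Sequence[float]]) -> float:
    if u is None or v is None:
        return 0.0
    ua, va = np.asarray(u, dtype=float), np.asarray(v, dtype=float)
    if ua.shape != va.shape:
        raise ValueError(f"numeric feature vectors differ in length: {ua.shape} vs {va.shape}")
    nu, nv = np.linalg.norm(ua), np.linalg.norm(va)
    if nu == 0.0 or nv == 0.0:
        return 0.0
    # clamp: anti-correlated features mean "no similarity", not a negative score
    return max(0.0, float(np.dot(ua, va) / (nu * nv)))


def _capacity_adequacy(provider: ProviderProfile, urgency: int) -> float:
    # ESI urgency 1 (most urgent) implies the largest demand for headroom
    demand = 6 - urgency
    return min(1.0, provider.capacity / demand)


def score_compatibility(
    patient: PatientProfile,
    provider: ProviderProfile,
    weights: ScoreWeights = DEFAULT_WEIGHTS,
) -> float:
    """Compatibility score S(p, r) in [0, 1]; higher is better.

    Unmet hard constraints gate the score to exactly 0.  Otherwise the four
    weighted terms (constraint indicator, token Jaccard, clamped cosine,
    capacity adequacy) are summed.  Deterministic: identical inputs always
    yield the identical float.
    """
    if not isinstance(weights, ScoreWeights):
        raise WeightError(f"weights must be a ScoreWeights, got {type(weights).__name__}")
    if not hard_constraints_satisfied(patient, provider):
        return 0.0
    score = (
        weights.w_constraint * 1.0
        + weights.w_specialty * _jaccard(patient.token_set, provider.token_set)
        + weights.w_feature * _cosine(patient.numeric_features, provider.numeric_features)
        + weights.w_urgency * _capacity_adequacy(provider, patient.urgency)
    )
    # guard against float drift just above 1
    return min(1.0, score)


def _check_unique(ids: Iterable[str], kind: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise DuplicateIdError(f"duplicate {kind} id {i!r}")
        seen.add(i)


def score_matrix(
    patients: Sequence[PatientProfile],
    providers: Sequence[ProviderProfile],
    weights: ScoreWeights = DEFAULT_WEIGHTS,
) -> CompatibilityMatrix:
    """Score every pair; rows follow patient order, columns provider order."""
    if not patients or not providers:
        raise ValueError("patients and providers must be nonempty")
    _check_unique((p.patient_id for p in patients), "patient")
    _check_unique((r.provider_id for r in providers), "provider")
    scores = np.empty((len(patients), len(providers)), dtype=float)
    for i, p in enumerate(patients):
        for j, r in enumerate(providers):
            scores[i, j] = score_compatibility(p, r, weights)
    return CompatibilityMatrix(
        patients=tuple(p.patient_id for p in patients),
        providers=tuple(r.provider_id for r in providers),
        scores=scores,
    )
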