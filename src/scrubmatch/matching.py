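"""Score-driven deferred acceptance (Gale-Shapley) with stability checking.

Ordinal preferences are derived from the compatibility matrix by competition
ranking: rank_p(r) = 1 + #{r' : S(p, r') > S(p, r)}, and symmetrically for
providers, so equal scores share a rank.  The patient-proposing variant of
deferred acceptance is then run: each unmatched patient proposes to its best
not-yet-approached provider; a provider at capacity displaces its worst
current assignee only for a strictly better proposer (lower rank, or equal
rank with a strictly higher raw score — the score tie-break can only fire
when preferences were supplied explicitly, since score-derived equal ranks
imply equal scores).

Patients who have proposed to every provider without being accepted are
removed from the unmatched pool and reported, which guarantees termination
within n*m proposals.  The output is stable: `verify_stability` finds no
blocking pair, and on strict preferences it is the patient-optimal stable
matching (checked against exhaustive enumeration in the test suite).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .profiles import (
    CompatibilityMatrix,
    PatientProfile,
    ProviderProfile,
    ScoreWeights,
    DEFAULT_WEIGHTS,
    score_matrix,
)

__all__ = [
    "PreferenceTable",
    "MatchResult",
    "InputError",
    "SizeError",
    "derive_ranks",
    "gale_shapley",
    "verify_stability",
    "enumerate_stable_matchings",
    "rematch_on_update",
]


class InputError(ValueError):
    """Raised when preference/matrix/capacity inputs are inconsistent."""


class SizeError(ValueError):
    """Raised when an instance exceeds the enumeration size guard."""


@dataclass(frozen=True)
class PreferenceTable:
    """Ordinal ranks for both sides; rank 1 is the most preferred.

    ``rank_p`` is keyed by (patient_id, provider_id); ``rank_r`` by
    (provider_id, patient_id).  Tables derived from a score matrix give
    equal scores equal ranks.  ``explicit`` marks tables built from
    externally supplied preference lists, where equal ranks may coexist
    with unequal scores and the score tie-break becomes live.
    """

    patients: tuple[str, ...]
    providers: tuple[str, ...]
    rank_p: Mapping[tuple[str, str], int]
    rank_r: Mapping[tuple[str, str], int]
    explicit: bool = False

    def __post_init__(self) -> None:
        for p in self.patients:
            ranks = [self.rank_p[(p, r)] for r in self.providers]
            if min(ranks, default=1) != 1 or any(k < 1 for k in ranks):
                raise InputError(f"patient {p!r}: ranks must be >= 1 with a rank-1 entry")
        for r in self.providers:
            ranks = [self.rank_r[(r, p)] for p in self.patients]
            if min(ranks, default=1) != 1 or any(k < 1 for k in ranks):
                raise InputError(f"provider {r!r}: ranks must be >= 1 with a rank-1 entry")

    @classmethod
    def from_preference_lists(
        cls,
        patient_lists: Mapping[str, Sequence[str]],
        provider_lists: Mapping[str, Sequence[str]],
    ) -> "PreferenceTable":
        """Build a table from explicit ordered preference lists."""
        patients = tuple(sorted(patient_lists))
        providers = tuple(sorted(provider_lists))
        rank_p = {
            (p, r): i + 1 for p, lst in patient_lists.items() for i, r in enumerate(lst)
        }
        rank_r = {
            (r, p): i + 1 for r, lst in provider_lists.items() for i, p in enumerate(lst)
        }
        return cls(patients, providers, rank_p, rank_r, explicit=True)


@dataclass(frozen=True)
class MatchResult:
    """Outcome of one matching run.

    ``pairs`` and ``unmatched`` partition the patient set; ``proposals``
    counts every proposal made; ``blocking_pairs`` is empty iff ``stable``.
    """

    pairs: tuple[tuple[str, str], ...]
    unmatched: tuple[str, ...]
    proposals: int
    stable: bool
    blocking_pairs: tuple[tuple[str, str], ...] = ()

    def provider_of(self, patient_id: str) -> Optional[str]:
        for p, r in self.pairs:
            if p == patient_id:
                return r
        return None


def derive_ranks(matrix: CompatibilityMatrix) -> PreferenceTable:
    """Competition-rank both sides of the score matrix (ties share a rank)."""
    rank_p: dict[tuple[str, str], int] = {}
    rank_r: dict[tuple[str, str], int] = {}
    S = matrix.scores
    for i, p in enumerate(matrix.patients):
        row = S[i, :]
        for j, r in enumerate(matrix.providers):
            rank_p[(p, r)] = 1 + int((row > row[j]).sum())
    for j, r in enumerate(matrix.providers):
        col = S[:, j]
        for i, p in enumerate(matrix.patients):
            rank_r[(r, p)] = 1 + int((col > col[i]).sum())
    return PreferenceTable(matrix.patients, matrix.providers, rank_p, rank_r)


def _check_consistent(prefs: PreferenceTable, matrix: CompatibilityMatrix) -> None:
    if set(prefs.patients) != set(matrix.patients) or set(prefs.providers) != set(
        matrix.providers
    ):
        raise InputError("preference table and score matrix cover different id sets")


def _normalize_capacities(
    providers: Sequence[str], capacities: Optional[Mapping[str, int]]
) -> dict[str, int]:
    caps = {r: 1 for r in providers}
    if capacities:
        unknown = set(capacities) - set(providers)
        if unknown:
            raise InputError(f"capacities given for unknown providers {sorted(unknown)}")
        for r, c in capacities.items():
            if c < 1:
                raise InputError(f"provider {r!r}: capacity must be >= 1, got {c}")
            caps[r] = int(c)
    return caps


def gale_shapley(
    prefs: PreferenceTable,
    matrix: CompatibilityMatrix,
    capacities: Optional[Mapping[str, int]] = None,
) -> MatchResult:
    """Patient-proposing deferred acceptance with capacity constraints.

    Deterministic: unmatched patients are processed in ascending id order
    and all score comparisons are exact floating point.  The proposal count
    never exceeds n*m.
    """
    _check_consistent(prefs, matrix)
    patients = sorted(prefs.patients)
    providers = list(prefs.providers)
    caps = _normalize_capacities(providers, capacities)
    idx_p = {p: i for i, p in enumerate(matrix.patients)}
    idx_r = {r: j for j, r in enumerate(matrix.providers)}
    S = matrix.scores

    def score(p: str, r: str) -> float:
        return float(S[idx_p[p], idx_r[r]])

    unmatched_pool: set[str] = set(patients)
    proposed: dict[str, set[str]] = {p: set() for p in patients}
    assigned: dict[str, list[str]] = {r: [] for r in providers}
    match_of: dict[str, Optional[str]] = {p: None for p in patients}
    exhausted: list[str] = []
    proposals = 0
    bound = len(patients) * len(providers)

    while unmatched_pool:
        p = min(unmatched_pool)
        unmatched_pool.remove(p)
        remaining = [r for r in providers if r not in proposed[p]]
        if not remaining:
            exhausted.append(p)  # proposed everywhere; report and terminate for p
            continue
        # best not-yet-approached provider: lowest rank, score then id tie-break
        r = min(remaining, key=lambda r_: (prefs.rank_p[(p, r_)], -score(p, r_), r_))
        proposed[p].add(r)
        proposals += 1
        assert proposals <= bound, "proposal bound n*m exceeded"
        if len(assigned[r]) < caps[r]:
            assigned[r].append(p)
            match_of[p] = r
            continue
        worst = max(
            assigned[r], key=lambda q: (prefs.rank_r[(r, q)], -score(q, r), q)
        )
        rp, rw = prefs.rank_r[(r, p)], prefs.rank_r[(r, worst)]
        if rp < rw or (rp == rw and score(p, r) > score(worst, r)):
            assigned[r].remove(worst)
            match_of[worst] = None
            unmatched_pool.add(worst)
            assigned[r].append(p)
            match_of[p] = r
        else:
            unmatched_pool.add(p)

    pairs = tuple(sorted((p, r) for p, r in match_of.items() if r is not None))
    unmatched = tuple(sorted(exhausted))
    blocking = verify_stability(
        MatchResult(pairs, unmatched, proposals, stable=True), prefs, matrix, caps
    )
    return MatchResult(pairs, unmatched, proposals, stable=not blocking, blocking_pairs=tuple(blocking))


def _strictly_prefers(
    rank: Mapping[tuple[str, str], int],
    key_new: tuple[str, str],
    key_cur: tuple[str, str],
    score_new: float,
    score_cur: float,
) -> bool:
    rn, rc = rank[key_new], rank[key_cur]
    return rn < rc or (rn == rc and score_new > score_cur)


def verify_stability(
    result: MatchResult,
    prefs: PreferenceTable,
    matrix: CompatibilityMatrix,
    capacities: Optional[Mapping[str, int]] = None,
) -> list[tuple[str, str]]:
    """Exhaustively list blocking pairs; empty list iff the matching is stable.

    (p, r) blocks iff p strictly prefers r to its current provider (an
    unmatched patient prefers any provider) and r either has spare capacity
    or strictly prefers p to one of its current assignees.  Strict preference
    means a lower rank, with the raw score as tie-break, mirroring the
    acceptance rule of the matching algorithm.
    """
    _check_consistent(prefs, matrix)
    caps = _normalize_capacities(list(prefs.providers), capacities)
    idx_p = {p: i for i, p in enumerate(matrix.patients)}
    idx_r = {r: j for j, r in enumerate(matrix.providers)}
    S = matrix.scores
    match_of = dict(result.pairs)
    assignees: dict[str, list[str]] = {r: [] for r in prefs.providers}
    for p, r in result.pairs:
        assignees[r].append(p)

    blocking: list[tuple[str, str]] = []
    for p in sorted(prefs.patients):
        cur = match_of.get(p)
        for r in prefs.providers:
            if r == cur:
                continue
            s_pr = float(S[idx_p[p], idx_r[r]])
            if cur is not None:
                s_cur = float(S[idx_p[p], idx_r[cur]])
                if not _strictly_prefers(prefs.rank_p, (p, r), (p, cur), s_pr, s_cur):
                    continue
            if len(assignees[r]) < caps[r]:
                blocking.append((p, r))
                continue
            for q in assignees[r]:
                s_qr = float(S[idx_p[q], idx_r[r]])
                if _strictly_prefers(prefs.rank_r, (r, p), (r, q), s_pr, s_qr):
                    blocking.append((p, r))
                    break
    return blocking


def enumerate_stable_matchings(
    prefs: PreferenceTable,
    matrix: CompatibilityMatrix,
    max_size: int = 8,
) -> list[tuple[tuple[str, str], ...]]:
    """All stable one-to-one matchings, by brute force (test oracle).

    Only assignments saturating min(n, m) pairs are enumerated: a partial
    assignment leaves an unmatched patient and a provider with a free slot,
    which always form a blocking pair.  Guarded to instances of at most
    ``max_size`` on each side.
    """
    n, m = len(prefs.patients), len(prefs.providers)
    if n > max_size or m > max_size:
        raise SizeError(f"instance {n}x{m} exceeds enumeration guard {max_size}")
    patients = sorted(prefs.patients)
    providers = sorted(prefs.providers)
    k = min(n, m)
    stable: list[tuple[tuple[str, str], ...]] = []
    for chosen_patients in itertools.combinations(patients, k):
        for perm in itertools.permutations(providers, k):
            pairs = tuple(sorted(zip(chosen_patients, perm)))
            matched = {p for p, _ in pairs}
            unmatched = tuple(sorted(set(patients) - matched))
            cand = MatchResult(pairs, unmatched, proposals=0, stable=True)
            if not verify_stability(cand, prefs, matrix):
                stable.append(pairs)
    return sorted(stable)


def rematch_on_update(
    result: MatchResult,
    patients: Sequence[PatientProfile],
    providers: Sequence[ProviderProfile],
    weights: ScoreWeights = DEFAULT_WEIGHTS,
) -> MatchResult:
    """Recompute scores, ranks and a fresh matching for updated profiles.

    The stale ``result`` is ignored except as the trigger: dynamic changes
    to either side invalidate derived preferences, so the whole pipeline is
    recomputed from scratch (no incremental maintenance).
    """
    matrix = score_matrix(patients, providers, weights)
    prefs = derive_ranks(matrix)
    capacities = {r.provider_id: r.capacity for r in providers}
    return gale_shapley(prefs, matrix, capacities)
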