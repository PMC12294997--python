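"""Pipeline evaluation metrics: contextual relevancy, task completeness,
tool correctness.

All three are deterministic arithmetic on structured logs.  Relevancy and
correctness annotations may come from any upstream source (human review, a
judging model, a construction with planted ground truth); this module only
does the counting:

* CR  = N_relevant / N_total over a statement log, gated at a threshold tau;
* TCS = alignment between a task description and its output — keyword
  coverage when required keywords are configured, token-set Jaccard
  otherwise — gated at tau;
* TC  = fraction of tool calls whose actual name (and, optionally, actual
  parameters) exactly match the expected call.

Gates are inclusive: metric >= tau passes.  Budget bounds cap the number of
evaluation attempts at k*m per metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .profiles import tokenize

__all__ = [
    "StatementLog",
    "TaskRecord",
    "ToolCall",
    "ToolCallLog",
    "MetricReport",
    "EmptyLogError",
    "contextual_relevancy",
    "task_completeness",
    "tool_correctness",
    "budget_check",
    "evaluate_all",
]

DEFAULT_TAU = 0.7


class EmptyLogError(ValueError):
    """Raised when a metric is requested on an empty log."""


@dataclass(frozen=True)
class StatementLog:
    """Generated statements with boolean relevancy annotations."""

    statements: tuple[tuple[str, bool], ...]

    @property
    def n_total(self) -> int:
        return len(self.statements)

    @property
    def n_relevant(self) -> int:
        return sum(1 for _, rel in self.statements if rel)


@dataclass(frozen=True)
class TaskRecord:
    """A task description, the produced output, and optional required keywords."""

    task_description: str
    output: str
    required_keywords: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.task_description:
            raise ValueError("task description must be nonempty")


@dataclass(frozen=True)
class ToolCall:
    """One expected-vs-actual tool invocation; params may be absent."""

    expected_tool_name: str
    actual_tool_name: str
    expected_params: Optional[Mapping[str, object]] = None
    actual_params: Optional[Mapping[str, object]] = None


@dataclass(frozen=True)
class ToolCallLog:
    calls: tuple[ToolCall, ...]


@dataclass(frozen=True)
class MetricReport:
    """All three metrics plus their gates and the thresholds applied."""

    cr: Optional[float]
    tcs: Optional[float]
    tc: Optional[float]
    gate_context: Optional[int]
    gate_task: Optional[int]
    tau_context: float
    tau_task: float

    def to_dict(self) -> dict:
        return {
            "contextual_relevancy": self.cr,
            "task_completeness": self.tcs,
            "tool_correctness": self.tc,
            "gate_context": self.gate_context,
            "gate_task": self.gate_task,
            "tau_context": self.tau_context,
            "tau_task": self.tau_task,
        }


def _check_tau(tau: float) -> None:
    if not 0.0 <= tau <= 1.0:
        raise ValueError(f"tau must be in [0, 1], got {tau}")


def contextual_relevancy(log: StatementLog, tau: float = DEFAULT_TAU) -> tuple[float, int]:
    """CR = relevant / total statements; gate = 1 iff CR >= tau."""
    _check_tau(tau)
    if log.n_total == 0:
        raise EmptyLogError("cannot score an empty statement log")
    cr = log.n_relevant / log.n_total
    return cr, int(cr >= tau)


def task_completeness(record: TaskRecord, tau: float = DEFAULT_TAU) -> tuple[float, int]:
    """TCS = keyword coverage of the output (Jaccard fallback); gate at tau.

    A multi-word keyword counts as covered when all of its tokens appear in
    the output's token set.  An empty output scores 0.
    """
    _check_tau(tau)
    if not record.output.strip():
        return 0.0, 0
    out_tokens = tokenize(record.output)
    if record.required_keywords:
        covered = sum(
            1 for kw in record.required_keywords if tokenize(kw) and tokenize(kw) <= out_tokens
        )
        tcs = covered / len(record.required_keywords)
    else:
        task_tokens = tokenize(record.task_description)
        union = task_tokens | out_tokens
        tcs = len(task_tokens & out_tokens) / len(union) if union else 0.0
    return tcs, int(tcs >= tau)


def tool_correctness(log: ToolCallLog, check_params: bool = False) -> float:
    """TC = exactly-matching calls / total calls.

    A call matches iff actual name equals expected name; with
    ``check_params`` the actual parameter mapping must also equal the
    expected one exactly (an expected mapping of None means "don't check").
    """
    if not log.calls:
        raise EmptyLogError("cannot score an empty tool-call log")
    correct = 0
    for call in log.calls:
        if call.actual_tool_name != call.expected_tool_name:
            continue
        if check_params and call.expected_params is not None:
            if dict(call.actual_params or {}) != dict(call.expected_params):
                continue
        correct += 1
    return correct / len(log.calls)


def budget_check(counts: Sequence[int], k: int, m: int) -> bool:
    """True iff every recorded evaluation count respects its k*m bound."""
    if k < 0 or m < 0 or any(c < 0 for c in counts):
        raise ValueError("counts and budget factors must be nonnegative")
    return all(c <= k * m for c in counts)


def evaluate_all(
    statements: Optional[StatementLog] = None,
    task: Optional[TaskRecord] = None,
    tool_calls: Optional[ToolCallLog] = None,
    tau_context: float = DEFAULT_TAU,
    tau_task: float = DEFAULT_TAU,
    check_params: bool = False,
) -> MetricReport:
    """Score whichever logs are present and assemble one report."""
    cr = gate_c = tcs = gate_t = tc = None
    if statements is not None:
        cr, gate_c = contextual_relevancy(statements, tau_context)
    if task is not None:
        tcs, gate_t = task_completeness(task, tau_task)
    if tool_calls is not None:
        tc = tool_correctness(tool_calls, check_params)
    return MetricReport(
        cr=cr, tcs=tcs, tc=tc,
        gate_context=gate_c, gate_task=gate_t,
        tau_context=tau_context, tau_task=tau_task,
    )
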