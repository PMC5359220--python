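"""The two classification procedures.

Rule route (RULEX-like): retrieve the explicit rule chunk, then check only
the rule-relevant features — member iff all three required symbols are
present. Retrieval failure yields a coin-flip guess. Because the rule check
never looks at the irrelevant dimensions, this route is blind to the
similarity manipulation by construction.

Exemplar route (EBRW-like, single-retrieval reading): cue declarative
memory with the full feature vector; a successful retrieval of any training
exemplar yields "member" (every stored exemplar is rule-compliant), a
failure yields "non-member" (a slow "no" carrying the failure latency).

Both routes share a fixed stage structure: visual encoding, two procedural
steps, one memory retrieval, and response execution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import Rule, Stimulus
from .memory import DeclarativeMemory, MemoryParams

__all__ = ["Response", "TimingParams", "exemplar_route", "rule_route", "stage_cost"]

MEMBER = "member"
NON_MEMBER = "non-member"

#: Number of procedural steps (production firings) charged per route.
N_STEPS = 2


@dataclass
class TimingParams:
    """Fixed stage costs, seconds. Only RT *differences* between conditions
    are model-constrained; the constants set the absolute scale."""

    encode_s: float = 0.555  # visual encoding of a stimulus
    step_s: float = 0.05     # one production firing
    motor_s: float = 0.21    # response execution

    def __post_init__(self) -> None:
        if min(self.encode_s, self.step_s, self.motor_s) < 0:
            raise ValueError("stage costs must be non-negative")


@dataclass
class Response:
    label: str               # MEMBER | NON_MEMBER
    latency_s: float
    route: str               # "rule" | "exemplar" | "guess"
    retrieved: object = None  # winning chunk, if any


def stage_cost(timing: TimingParams) -> float:
    return timing.encode_s + N_STEPS * timing.step_s + timing.motor_s


def rule_route(
    item: Stimulus,
    store: DeclarativeMemory,
    now: float,
    params: MemoryParams,
    timing: TimingParams,
    rng: np.random.Generator,
    strengthen: bool = True,
) -> Response:
    """Classify by retrieving the rule and matching the rule-relevant features.

    On retrieval failure the response is a uniform guess (route="guess").
    With ``strengthen`` the rule chunk logs a new reference at ``now``, so
    frequent rule use speeds later retrievals (base-level learning).
    """
    result = store.retrieve("rule", now, params, rng)
    latency = stage_cost(timing) + result.latency_s
    if not result.success:
        label = MEMBER if rng.random() < 0.5 else NON_MEMBER
        return Response(label, latency, "guess")
    rule: Rule = result.chunk.content
    if strengthen:
        result.chunk.add_reference(now)
    label = MEMBER if rule.is_compliant(item.features) else NON_MEMBER
    return Response(label, latency, "rule", result.chunk)


def exemplar_route(
    item: Stimulus,
    store: DeclarativeMemory,
    now: float,
    params: MemoryParams,
    timing: TimingParams,
    rng: np.random.Generator,
    strengthen: bool = False,
) -> Response:
    """Classify by attempting to retrieve a training exemplar.

    Success -> member (all stored exemplars are compliant); failure -> a
    slow non-member response. Exemplar traces are frozen after training by
    default (``strengthen=False``); see docs/methods.md.
    """
    result = store.retrieve("exemplar", now, params, rng, probe=item.features)
    latency = stage_cost(timing) + result.latency_s
    if not result.success:
        return Response(NON_MEMBER, latency, "exemplar")
    if strengthen:
        result.chunk.add_reference(now)
    return Response(MEMBER, latency, "exemplar", result.chunk)
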