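"""ACT-R-style declarative memory: chunks, activation, threshold retrieval.

A chunk's activation is the sum of three terms:

* base level  ``B = ln(sum_j (now - t_j)^-d)`` over its reference times,
  a power-law-decayed trace of how often and how recently it was used;
* a partial-matching adjustment (exemplar chunks only): each feature
  dimension contributes ``+match_value`` if the probe agrees with the chunk
  and ``mismatch_value`` otherwise, scaled by ``match_scale``;
* transient logistic noise of scale ``s_act``.

Retrieval takes the highest-activation candidate; it succeeds iff that
activation clears the threshold ``tau``, with latency ``F * exp(-A)``.
A failed retrieval takes ``F * exp(-tau)`` seconds. With logistic noise the
probability that a lone chunk with noise-free activation ``A`` is retrieved
is exactly ``1 / (1 + exp(-(A - tau)/s))``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "Chunk",
    "DeclarativeMemory",
    "MemoryError_",
    "MemoryParams",
    "RetrievalResult",
    "activation",
    "base_level",
    "logistic_noise",
    "partial_match",
    "retrieval_latency",
    "retrieval_probability",
]


class MemoryError_(ValueError):
    """Invalid memory query or parameterisation."""


@dataclass
class MemoryParams:
    """Declarative-memory parameters (architecture defaults unless noted).

    ``s_act`` (transient activation noise scale) has no architecture
    default; its value here comes from the calibration documented in
    docs/methods.md.
    """

    d: float = 0.5            # base-level decay exponent
    tau: float = 0.0          # retrieval threshold
    F: float = 1.0            # latency factor, seconds
    match_scale: float = 1.0  # weight per dimension in partial matching
    match_value: float = 1.0  # activation increment per matching dimension
    mismatch_value: float = -1.0  # decrement per mismatching dimension
    s_act: float = 0.25       # logistic noise scale (calibrated)

    def __post_init__(self) -> None:
        if self.d <= 0:
            raise MemoryError_("decay d must be positive")
        if self.F <= 0:
            raise MemoryError_("latency factor F must be positive")
        if self.s_act < 0:
            raise MemoryError_("noise scale s_act must be non-negative")
        if self.match_value <= self.mismatch_value:
            raise MemoryError_("match_value must exceed mismatch_value")


@dataclass
class Chunk:
    """A declarative record: a stored exemplar or the explicit rule."""

    name: str
    kind: str  # "exemplar" | "rule"
    content: object  # tuple of feature symbols, or a design.Rule
    references: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in ("exemplar", "rule"):
            raise MemoryError_(f"unknown chunk kind {self.kind!r}")
        if any(b < a for a, b in zip(self.references, self.references[1:])):
            raise MemoryError_("reference timestamps must be non-decreasing")

    def add_reference(self, t: float) -> None:
        if self.references and t < self.references[-1]:
            raise MemoryError_("reference timestamps must be non-decreasing")
        self.references.append(t)


@dataclass
class RetrievalResult:
    chunk: Chunk | None        # None on failure
    activation: float          # winning (noisy) activation; -inf if no candidates
    latency_s: float

    @property
    def success(self) -> bool:
        return self.chunk is not None


def base_level(chunk: Chunk, now: float, d: float = 0.5) -> float:
    """ln of the power-law-decayed sum over the chunk's reference times."""
    refs = np.asarray(chunk.references, dtype=float)
    if refs.size == 0:
        raise MemoryError_(f"chunk {chunk.name}: no references")
    if np.any(refs >= now):
        raise MemoryError_(f"chunk {chunk.name}: reference at or after now={now}")
    return float(np.log(np.sum((now - refs) ** -d)))


def partial_match(probe: Sequence[str], chunk: Chunk, params: MemoryParams) -> float:
    """Summed per-dimension similarity between probe and an exemplar chunk."""
    if chunk.kind != "exemplar":
        raise MemoryError_("partial matching applies to exemplar chunks only")
    content = chunk.content
    if len(probe) != len(content):
        raise MemoryError_(
            f"dimensionality mismatch: probe {len(probe)} vs chunk {len(content)}"
        )
    matches = sum(p == c for p, c in zip(probe, content))
    mismatches = len(probe) - matches
    return params.match_scale * (
        params.match_value * matches + params.mismatch_value * mismatches
    )


def logistic_noise(rng: np.random.Generator, scale: float, size: int | None = None):
    """Logistic(0, scale) noise via inverse-CDF sampling (seeded, reproducible)."""
    if scale == 0:
        return 0.0 if size is None else np.zeros(size)
    u = rng.random(size)
    return scale * np.log(u / (1.0 - u))


def activation(
    chunk: Chunk,
    probe: Sequence[str] | None,
    now: float,
    params: MemoryParams,
    rng: np.random.Generator | None = None,
) -> float:
    """Noisy activation: base level, plus partial matching for exemplar probes.

    ``probe`` must be given iff the chunk is an exemplar — the rule chunk is
    cued by kind alone, without partial matching over stimulus features.
    """
    if (probe is None) == (chunk.kind == "exemplar"):
        raise MemoryError_("probe must be supplied iff the chunk is an exemplar")
    a = base_level(chunk, now, params.d)
    if probe is not None:
        a += partial_match(probe, chunk, params)
    if params.s_act > 0:
        if rng is None:
            raise MemoryError_("rng required when s_act > 0")
        a += float(logistic_noise(rng, params.s_act))
    return a


def retrieval_probability(A: float, tau: float, s: float) -> float:
    """Closed-form probability that a lone chunk's noisy activation clears tau."""
    if s <= 0:
        raise MemoryError_("noise scale s must be positive")
    return 1.0 / (1.0 + math.exp(-(A - tau) / s))


def retrieval_latency(A: float, F: float) -> float:
    """Retrieval time in seconds: decreasing exponential of activation."""
    if F <= 0:
        raise MemoryError_("latency factor F must be positive")
    return F * math.exp(-A)


class DeclarativeMemory:
    """A store of chunks supporting cued, noisy, thresholded retrieval."""

    def __init__(self, chunks: Sequence[Chunk] = ()) -> None:
        self.chunks: list[Chunk] = list(chunks)

    def add(self, chunk: Chunk) -> Chunk:
        self.chunks.append(chunk)
        return chunk

    def by_kind(self, kind: str) -> list[Chunk]:
        return [c for c in self.chunks if c.kind == kind]

    def __len__(self) -> int:
        return len(self.chunks)

    def retrieve(
        self,
        kind: str,
        now: float,
        params: MemoryParams,
        rng: np.random.Generator,
        probe: Sequence[str] | None = None,
    ) -> RetrievalResult:
        """Sample noisy activations over candidates of ``kind``; best wins.

        The winner is retrieved iff its noisy activation clears ``tau``;
        otherwise (or with no candidates) the result is a failure carrying
        the failure latency ``F * exp(-tau)``.
        """
        candidates = self.by_kind(kind)
        fail_latency = params.F * math.exp(-params.tau)
        if not candidates:
            return RetrievalResult(None, float("-inf"), fail_latency)
        acts = np.empty(len(candidates))
        for i, c in enumerate(candidates):
            a = base_level(c, now, params.d)
            if kind == "exemplar":
                if probe is None:
                    raise MemoryError_("exemplar retrieval requires a probe")
                a += partial_match(probe, c, params)
            acts[i] = a
        if params.s_act > 0:
            acts = acts + logistic_noise(rng, params.s_act, len(candidates))
        best = np.flatnonzero(acts == acts.max())
        idx = int(best[0]) if len(best) == 1 else int(rng.choice(best))
        a_win = float(acts[idx])
        if a_win >= params.tau:
            return RetrievalResult(candidates[idx], a_win, retrieval_latency(a_win, params.F))
        return RetrievalResult(None, a_win, fail_latency)
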