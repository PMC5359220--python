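"""Orchestration of the simulated rule-application experiment.

One run = a training phase (12 rule-compliant exemplars presented three
times each, stored in declarative memory, with the rule chunk laid down at
session start), a retention gap, then 96 unique test items over four blocks
of 24 (six per compliance x similarity cell per block). On each test trial
the noisy utility comparison picks a route, the route classifies the item,
and in supervised mode the used route's success/failure counts are updated
from accuracy feedback. Test items are never added to memory.

``run_condition`` averages over independent replications (default 50);
``run_sweep`` crosses exemplar-route shares 0..1 in steps of 0.1 with both
feedback regimes. Everything is a pure function of the master seed and the
configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import analysis
from .control import RouteState, UtilityParams, bias_to_states, select_route, update_on_feedback
from .design import DesignSpec, StimulusSet, generate_design
from .memory import Chunk, DeclarativeMemory, MemoryParams
from .routes import MEMBER, NON_MEMBER, TimingParams, exemplar_route, rule_route

__all__ = [
    "RunConfig",
    "SweepResult",
    "TestPhaseResult",
    "run_condition",
    "run_sweep",
    "run_test_phase",
    "run_training",
    "SHARES",
]

log = logging.getLogger(__name__)

SHARES = tuple(round(0.1 * k, 1) for k in range(11))

TRIAL_COLUMNS = [
    "run_id", "block", "trial_index", "stimulus_id", "compliant", "similarity",
    "selected_route", "route", "label", "correct", "latency_ms", "clock_s",
]


@dataclass
class TestPhaseResult:
    trials: pd.DataFrame
    rule_state: RouteState
    exemplar_state: RouteState


@dataclass
class RunConfig:
    """Full configuration of one simulated condition.

    Defaults are the frozen study conditions; the calibration of ``s_act``
    (in :class:`MemoryParams`), ``rule_rehearsal_passes`` and
    ``prior_strength`` is documented in docs/methods.md.
    """

    mode: str = "unsupervised"          # "unsupervised" | "supervised"
    target_share: float = 0.1           # initial exemplar-route selection share
    n_runs: int = 50
    design: DesignSpec = field(default_factory=DesignSpec)
    memory: MemoryParams = field(default_factory=MemoryParams)
    timing: TimingParams = field(default_factory=TimingParams)
    utility: UtilityParams = field(default_factory=UtilityParams)
    iti_s: float = 2.0                  # inter-trial interval, training and test
    retention_gap_s: float = 90.0       # pause between training and test (calibrated)
    n_rule_rehearsals: int = 9          # rule rehearsals spread through training (calibrated)
    prior_strength: float = 100.0       # total prior success+failure count per route (calibrated)
    C_rule: float = 1.5                 # expected completion times, seconds
    C_exemplar: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("unsupervised", "supervised"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if not 0.0 <= self.target_share <= 1.0:
            raise ValueError("target_share must lie in [0, 1]")


def run_training(
    stimuli: StimulusSet,
    config: RunConfig,
    rng: np.random.Generator,
) -> tuple[DeclarativeMemory, float]:
    """Lay down the rule chunk and the 12 exemplar chunks; return (store, clock).

    The rule chunk is created at t=0 and rehearsed ``n_rule_rehearsals``
    times at evenly spaced presentations during training (how well
    practised the rule is by test time is not an architecture constant;
    see docs/methods.md). Each of the three passes presents the 12 items
    in a fresh shuffled order; every presentation appends a reference
    timestamp.
    """
    store = DeclarativeMemory()
    rule_chunk = store.add(Chunk("rule", "rule", stimuli.rule, references=[0.0]))
    ex_chunks = {
        s.id: store.add(Chunk(s.id, "exemplar", s.features, references=[]))
        for s in stimuli.training
    }
    n_presentations = (
        stimuli.spec.presentations_per_training * len(stimuli.training)
    )
    n_reh = min(config.n_rule_rehearsals, n_presentations)
    rehearse_at = {
        round(j * n_presentations / n_reh) for j in range(n_reh)
    } if n_reh else set()
    clock = config.iti_s
    i = 0
    for _ in range(stimuli.spec.presentations_per_training):
        order = list(stimuli.training)
        rng.shuffle(order)
        for s in order:
            clock += config.timing.encode_s
            ex_chunks[s.id].add_reference(clock)
            if i in rehearse_at:
                rule_chunk.add_reference(clock)
            clock += config.iti_s
            i += 1
    log.debug("training done at t=%.1fs; %d chunks", clock, len(store))
    clock += config.retention_gap_s
    return store, clock


def _blocks(stimuli: StimulusSet, rng: np.random.Generator) -> list[list]:
    """Four blocks of 24, six per compliance x similarity cell, shuffled."""
    n_blocks = 4
    cells: dict[tuple, list] = {}
    for s in stimuli.test:
        cells.setdefault((s.compliant, s.similarity), []).append(s)
    per_block = {key: len(items) // n_blocks for key, items in cells.items()}
    blocks: list[list] = [[] for _ in range(n_blocks)]
    for key, items in cells.items():
        items = list(items)
        rng.shuffle(items)
        k = per_block[key]
        for b in range(n_blocks):
            blocks[b].extend(items[b * k: (b + 1) * k])
    for b in blocks:
        rng.shuffle(b)
    return blocks


def run_test_phase(
    store: DeclarativeMemory,
    stimuli: StimulusSet,
    config: RunConfig,
    rng: np.random.Generator,
    clock: float,
    run_id: int = 0,
) -> TestPhaseResult:
    """Run the 96 test trials of one replication.

    Returns the trial records together with the final route states (whose
    success/failure counts are unchanged in unsupervised mode).

    Test items never become chunks; in supervised mode the used route's
    success/failure counts are updated from the true correctness after
    every trial (guesses are attributed to the rule route, which was the
    route selected).
    """
    supervised = config.mode == "supervised"
    rule_state, ex_state = bias_to_states(
        config.target_share,
        config.utility,
        C_rule=config.C_rule,
        C_exemplar=config.C_exemplar,
        prior_strength=config.prior_strength,
        learning_enabled=supervised,
    )
    records: list[dict] = []
    trial_index = 0
    for b, block in enumerate(_blocks(stimuli, rng), start=1):
        for item in block:
            now = clock + config.timing.encode_s
            selected = select_route(rule_state, ex_state, config.utility, rng)
            if selected == "rule":
                resp = rule_route(item, store, now, config.memory, config.timing, rng)
            else:
                resp = exemplar_route(item, store, now, config.memory, config.timing, rng)
            truth = MEMBER if item.compliant else NON_MEMBER
            correct = resp.label == truth
            if supervised:
                if selected == "rule":
                    rule_state = update_on_feedback(rule_state, correct)
                else:
                    ex_state = update_on_feedback(ex_state, correct)
            records.append(
                {
                    "run_id": run_id,
                    "block": b,
                    "trial_index": trial_index,
                    "stimulus_id": item.id,
                    "compliant": item.compliant,
                    "similarity": item.similarity,
                    "selected_route": selected,
                    "route": resp.route,
                    "label": resp.label,
                    "correct": correct,
                    "latency_ms": resp.latency_s * 1000.0,
                    "clock_s": clock,
                }
            )
            clock += resp.latency_s + config.iti_s
            trial_index += 1
    return TestPhaseResult(
        trials=pd.DataFrame.from_records(records, columns=TRIAL_COLUMNS),
        rule_state=rule_state,
        exemplar_state=ex_state,
    )


def run_once(
    config: RunConfig,
    rng: np.random.Generator,
    stimuli: StimulusSet | None = None,
    run_id: int = 0,
) -> pd.DataFrame:
    """One full replication: training, retention gap, test phase."""
    if stimuli is None:
        stimuli = generate_design(config.design)
    store, clock = run_training(stimuli, config, rng)
    return run_test_phase(store, stimuli, config, rng, clock, run_id=run_id).trials


def run_condition(
    config: RunConfig,
    stimuli: StimulusSet | None = None,
) -> analysis.ConditionResult:
    """Run ``n_runs`` independent replications and aggregate their summaries."""
    if stimuli is None:
        stimuli = generate_design(config.design)
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_runs)
    frames = [
        run_once(config, np.random.default_rng(seeds[i]), stimuli, run_id=i)
        for i in range(config.n_runs)
    ]
    trials = pd.concat(frames, ignore_index=True)
    return analysis.aggregate_runs(
        trials, mode=config.mode, target_share=config.target_share
    )


@dataclass
class SweepResult:
    table: pd.DataFrame                      # one row per (share, mode) cell
    conditions: dict[tuple[float, str], analysis.ConditionResult]


def run_sweep(
    base_config: RunConfig,
    shares: tuple[float, ...] = SHARES,
    modes: tuple[str, ...] = ("unsupervised", "supervised"),
) -> SweepResult:
    """Cross exemplar-route shares with feedback regimes (22 cells by default)."""
    stimuli = generate_design(base_config.design)
    cell_seeds = np.random.SeedSequence(base_config.seed).spawn(len(shares) * len(modes))
    rows = []
    conditions: dict[tuple[float, str], analysis.ConditionResult] = {}
    i = 0
    for mode in modes:
        for share in shares:
            cfg = replace(
                base_config,
                mode=mode,
                target_share=share,
                seed=int(cell_seeds[i].generate_state(1)[0] % (2**31)),
            )
            log.info("sweep cell mode=%s share=%.1f", mode, share)
            res = run_condition(cfg, stimuli)
            conditions[(share, mode)] = res
            rows.append(
                {
                    "mode": mode,
                    "target_share": share,
                    "mean_errors": res.mean_errors,
                    "rt_effect_ms": res.rt_effect_ms,
                    "exemplar_share": res.exemplar_share,
                    "n_runs": res.n_runs,
                }
            )
            i += 1
    return SweepResult(table=pd.DataFrame(rows), conditions=conditions)
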