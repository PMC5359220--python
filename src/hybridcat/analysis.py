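"""Summary statistics over trial records, and similarity-structure analyses.

The headline quantities per replication are the total error count over the
96 test trials and the exemplar-similarity effect on reaction time: the
mean correct-response RT to low-similarity rule-compliant items minus that
to high-similarity rule-compliant items (positive = high-similarity items
answered faster). RT cells come from correct responses only; a cell with no
correct trials is left undefined (NaN), never imputed.

``weighted_similarity_table`` characterises the stimulus design itself:
mean weighted feature similarity of each test condition to a reference set
(training or test), under differential weighting of rule-relevant versus
irrelevant dimensions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import StimulusSet

__all__ = [
    "ConditionResult",
    "HumanFixture",
    "RunSummary",
    "EXPERIMENT1",
    "EXPERIMENT3",
    "aggregate_runs",
    "compare_to_fixture",
    "summarize",
    "weighted_similarity_table",
]

CONDITIONS = [(True, "high"), (True, "low"), (False, "high"), (False, "low")]


def _condition_name(compliant: bool, similarity: str) -> str:
    return f"{'compliant' if compliant else 'non-compliant'}-{similarity}"


@dataclass
class RunSummary:
    """Per-replication summary of one 96-trial run."""

    mean_errors: float
    rt_effect_ms: float                      # NaN if either compliant RT cell is empty
    per_condition_error_rate: dict[str, float]
    per_block_rt: pd.DataFrame               # block x similarity, correct compliant RTs
    exemplar_share: float                    # share of trials the exemplar route ran
    per_block_share: pd.Series


@dataclass
class ConditionResult:
    """Run-level means over one (mode, target share) condition."""

    mode: str
    target_share: float
    n_runs: int
    mean_errors: float
    rt_effect_ms: float
    rt_effect_n: int                         # runs with a defined RT effect
    per_condition_error_rate: dict[str, float]
    per_block_rt: pd.DataFrame
    exemplar_share: float
    per_block_share: pd.Series
    per_run: pd.DataFrame
    trials: pd.DataFrame | None = None


def summarize(trials: pd.DataFrame) -> RunSummary:
    """Summarise the trial records of a single run."""
    if trials["run_id"].nunique() != 1:
        raise ValueError("summarize expects a single run; use aggregate_runs")
    errors = float((~trials["correct"]).sum())

    compliant_correct = trials[trials["compliant"] & trials["correct"]]
    rt = compliant_correct.groupby("similarity")["latency_ms"].mean()
    rt_effect = float(rt.get("low", np.nan) - rt.get("high", np.nan))

    rates = {}
    for comp, sim in CONDITIONS:
        cell = trials[(trials["compliant"] == comp) & (trials["similarity"] == sim)]
        rates[_condition_name(comp, sim)] = float((~cell["correct"]).mean())

    per_block_rt = (
        compliant_correct.pivot_table(
            index="block", columns="similarity", values="latency_ms", aggfunc="mean"
        )
        .reindex(index=sorted(trials["block"].unique()))
    )
    is_ex = trials["selected_route"] == "exemplar"
    return RunSummary(
        mean_errors=errors,
        rt_effect_ms=rt_effect,
        per_condition_error_rate=rates,
        per_block_rt=per_block_rt,
        exemplar_share=float(is_ex.mean()),
        per_block_share=is_ex.groupby(trials["block"]).mean(),
    )


def aggregate_runs(
    trials: pd.DataFrame, mode: str = "", target_share: float = float("nan")
) -> ConditionResult:
    """Aggregate multi-run trial records into run-level means.

    The RT-similarity effect is the mean over runs in which both compliant
    RT cells are defined (their count is reported as ``rt_effect_n``).
    """
    summaries = {
        run_id: summarize(df) for run_id, df in trials.groupby("run_id", sort=True)
    }
    per_run = pd.DataFrame(
        {
            "run_id": list(summaries),
            "errors": [s.mean_errors for s in summaries.values()],
            "rt_effect_ms": [s.rt_effect_ms for s in summaries.values()],
            "exemplar_share": [s.exemplar_share for s in summaries.values()],
        }
    )
    effects = per_run["rt_effect_ms"].dropna()
    rates = {
        name: float(np.mean([s.per_condition_error_rate[name] for s in summaries.values()]))
        for name in map(lambda c: _condition_name(*c), CONDITIONS)
    }
    per_block_rt = (
        pd.concat([s.per_block_rt for s in summaries.values()])
        .groupby(level=0)
        .mean()
    )
    per_block_share = (
        pd.concat([s.per_block_share for s in summaries.values()])
        .groupby(level=0)
        .mean()
    )
    return ConditionResult(
        mode=mode,
        target_share=target_share,
        n_runs=len(summaries),
        mean_errors=float(per_run["errors"].mean()),
        rt_effect_ms=float(effects.mean()) if len(effects) else float("nan"),
        rt_effect_n=int(len(effects)),
        per_condition_error_rate=rates,
        per_block_rt=per_block_rt,
        exemplar_share=float(per_run["exemplar_share"].mean()),
        per_block_share=per_block_share,
        per_run=per_run,
        trials=trials,
    )


def weighted_similarity_table(
    stimuli: StimulusSet,
    rule_weight: float = 1.0,
    irrelevant_weight: float = 1.0,
    reference: str = "training",
) -> pd.Series:
    """Normalised mean weighted similarity of each test condition to a reference set.

    Per item pair, each dimension contributes ``+w`` on a match and ``-w``
    on a mismatch, with ``w`` the rule or irrelevant class weight. Scores
    are averaged per condition (self-comparisons excluded when the
    reference is the test set) and min-max normalised to [0, 1] over the
    four-condition table.
    """
    if rule_weight < 0 or irrelevant_weight < 0:
        raise ValueError("weights must be non-negative")
    if rule_weight == 0 and irrelevant_weight == 0:
        raise ValueError("at least one weight must be positive")
    if reference not in ("training", "test"):
        raise ValueError("reference must be 'training' or 'test'")

    spec = stimuli.spec
    weights = np.array(
        [rule_weight if d in spec.rule_dims else irrelevant_weight for d in range(spec.n_dims)]
    )
    ref_items = stimuli.training if reference == "training" else stimuli.test
    ref = np.array([list(s.features) for s in ref_items])

    raw = {}
    for comp, sim in CONDITIONS:
        items = [s for s in stimuli.test if s.compliant == comp and s.similarity == sim]
        scores = []
        for s in items:
            probe = np.array(list(s.features))
            signs = np.where(ref == probe, 1.0, -1.0)  # (n_ref, n_dims)
            pair_scores = signs @ weights
            if reference == "test":
                mask = [r.id != s.id for r in ref_items]
                pair_scores = pair_scores[mask]
            scores.append(pair_scores.mean())
        raw[_condition_name(comp, sim)] = float(np.mean(scores))
    table = pd.Series(raw)
    lo, hi = table.min(), table.max()
    if hi == lo:
        return table * 0.0 + 1.0
    return (table - lo) / (hi - lo)


@dataclass(frozen=True)
class HumanFixture:
    """Printed human comparison values packaged as read-only constants."""

    experiment: int
    rt_effect_ms: float
    error_trials: float                       # errors out of 96
    error_rate_range: tuple[float, float] | None = None


#: No-feedback version of the task: 62 ms similarity effect; error rates
#: between 5 and 9% (~7 of 96 trials).
EXPERIMENT1 = HumanFixture(1, 62.0, 7.0, (0.05, 0.09))
#: Feedback version: 114 ms similarity effect; errors on 4 of 96 trials.
EXPERIMENT3 = HumanFixture(3, 114.0, 4.0)


def compare_to_fixture(
    result: ConditionResult,
    fixture: HumanFixture,
    rt_tolerance_ms: float = 15.0,
    error_tolerance: float = 2.0,
) -> dict:
    """Signed model-minus-human deltas with a per-metric verdict."""
    d_rt = result.rt_effect_ms - fixture.rt_effect_ms
    d_err = result.mean_errors - fixture.error_trials
    if fixture.error_rate_range is not None:
        lo, hi = (96 * r for r in fixture.error_rate_range)
        err_within = lo - error_tolerance <= result.mean_errors <= hi + error_tolerance
    else:
        err_within = abs(d_err) <= error_tolerance
    return {
        "rt_effect_delta_ms": float(d_rt),
        "rt_effect_within": bool(abs(d_rt) <= rt_tolerance_ms),
        "errors_delta": float(d_err),
        "errors_within": bool(err_within),
    }
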