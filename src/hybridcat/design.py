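"""Synthetic stimulus design for the rule-application task.

Stimuli are six-dimensional discrete feature vectors. Three dimensions are
rule-relevant: an item is a category member iff it carries the required
symbol on all three. Two further dimensions carry the similarity
manipulation: high-similarity test items reuse, as a pair, one of the three
value pairs seen in the training set (so each high-similarity item matches
exactly one third of the training exemplars on those dimensions), while
low-similarity test items use value pairs never seen in training. The last
dimension carries values unique within a group and unseen in training, so
that every test item is distinct from every other item in the session.

The construction makes similarity orthogonal to category membership: the 96
test items factorially cross compliance x similarity with 24 items per
cell, so responding on similarity alone is at chance. Within every cell the
multiset of feature-match counts against the 12 training exemplars is
identical across items, which is what the downstream memory model actually
sees.
"""

from __future__ import annotations

import csv
import itertools
import json
from collections import Counter
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "DesignError",
    "DesignSpec",
    "Rule",
    "Stimulus",
    "StimulusSet",
    "ValidationReport",
    "generate_design",
    "match_count",
    "validate_design",
    "read_stimuli",
    "write_stimuli",
]

SCHEMA_VERSION = 1


class DesignError(ValueError):
    """Raised when a design specification cannot be satisfied."""


def _symbol(dim: int, index: int) -> str:
    return f"d{dim}.{index}"


@dataclass(frozen=True)
class Rule:
    """Required symbol per rule-relevant dimension (exactly three entries)."""

    required: dict[int, str]

    def __post_init__(self) -> None:
        if len(self.required) != 3:
            raise DesignError("rule must constrain exactly 3 dimensions")

    def is_compliant(self, features: Sequence[str]) -> bool:
        return all(features[d] == sym for d, sym in self.required.items())


@dataclass(frozen=True)
class Stimulus:
    id: str
    features: tuple[str, ...]
    role: str  # "training" | "test"
    compliant: bool
    similarity: str  # "high" | "low" | "n/a"

    def __post_init__(self) -> None:
        if self.role not in ("training", "test"):
            raise DesignError(f"unknown role {self.role!r}")
        if self.similarity not in ("high", "low", "n/a"):
            raise DesignError(f"unknown similarity {self.similarity!r}")


@dataclass(frozen=True)
class DesignSpec:
    """Structural parameters of the stimulus set.

    Defaults reproduce the task structure: 12 rule-compliant training items
    shown three times each, and 96 unique test items, 24 per
    compliance x similarity cell, with similarity carried entirely by the
    two shared rule-irrelevant dimensions.
    """

    n_dims: int = 6
    rule_dims: tuple[int, ...] = (0, 1, 2)
    n_training: int = 12
    presentations_per_training: int = 3
    n_test: int = 96
    cell_size: int = 24
    n_shared_irrelevant: int = 2
    alphabet_sizes: tuple[int, ...] = (6, 6, 6, 6, 6, 12)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.rule_dims) != 3:
            raise DesignError("exactly 3 rule-relevant dimensions required")
        if not set(self.rule_dims) < set(range(self.n_dims)):
            raise DesignError("rule dimensions must be a strict subset of all dimensions")
        if self.n_test != 4 * self.cell_size:
            raise DesignError("n_test must equal 4 * cell_size")
        if self.n_shared_irrelevant > self.n_dims - len(self.rule_dims):
            raise DesignError("not enough irrelevant dimensions for the similarity pair")
        if len(self.alphabet_sizes) != self.n_dims:
            raise DesignError("one alphabet size per dimension required")

    @property
    def similarity_dims(self) -> tuple[int, ...]:
        free = [d for d in range(self.n_dims) if d not in self.rule_dims]
        return tuple(free[: self.n_shared_irrelevant])

    @property
    def unique_dims(self) -> tuple[int, ...]:
        free = [d for d in range(self.n_dims) if d not in self.rule_dims]
        return tuple(free[self.n_shared_irrelevant:])

    def alphabet(self, dim: int) -> list[str]:
        return [_symbol(dim, k) for k in range(self.alphabet_sizes[dim])]


@dataclass
class StimulusSet:
    spec: DesignSpec
    rule: Rule
    training: list[Stimulus]
    test: list[Stimulus]

    def __iter__(self):
        return itertools.chain(self.training, self.test)


def match_count(a: Sequence[str], b: Sequence[str]) -> int:
    """Number of dimensions on which two feature vectors agree."""
    if len(a) != len(b):
        raise DesignError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x == y for x, y in zip(a, b))


def generate_design(spec: DesignSpec | None = None) -> StimulusSet:
    """Construct a training + test set with the required match-count structure.

    Training items are partitioned into thirds by their shared-irrelevant
    value pair. High-similarity test items reuse one training pair (and so
    match exactly one third on those dimensions); low-similarity test items
    use one of three novel pairs, mirrored in group structure so that the
    test set itself carries no high/low asymmetry. Non-compliant items
    violate exactly one rule dimension, balanced across dimensions.
    """
    if spec is None:
        spec = DesignSpec()
    rng = np.random.default_rng(spec.seed)

    n_thirds = 3
    per_third = spec.n_training // n_thirds
    if spec.n_training % n_thirds:
        raise DesignError("n_training must split into three similarity thirds")
    per_group_cell = spec.cell_size // n_thirds
    if spec.cell_size % n_thirds:
        raise DesignError("cell_size must split across the three value-pair groups")

    sim_dims = spec.similarity_dims
    if len(sim_dims) != 2:
        raise DesignError("the default construction uses exactly 2 shared irrelevant dimensions")
    uniq_dims = spec.unique_dims
    if not uniq_dims:
        raise DesignError("at least one uniqueness dimension is required")
    u_dim = uniq_dims[0]

    for d in sim_dims:
        if spec.alphabet_sizes[d] < 2 * n_thirds:
            raise DesignError(
                f"dimension {d}: need {2 * n_thirds} symbols (3 training + 3 novel pairs), "
                f"have {spec.alphabet_sizes[d]}"
            )
    n_u_needed = per_third + per_group_cell
    if spec.alphabet_sizes[u_dim] < n_u_needed:
        raise DesignError(
            f"dimension {u_dim}: need {n_u_needed} symbols "
            f"({per_third} training + {per_group_cell} novel test values), "
            f"have {spec.alphabet_sizes[u_dim]}"
        )
    for d in spec.rule_dims:
        if spec.alphabet_sizes[d] < 2:
            raise DesignError(f"rule dimension {d} needs at least 2 symbols")

    rule = Rule(required={d: spec.alphabet(d)[0] for d in spec.rule_dims})

    # Shared-irrelevant value pairs: thirds 0-2 are the training pairs,
    # groups 3-5 are the novel (never-trained) pairs used by low-similarity items.
    pairs = [
        tuple(spec.alphabet(d)[k] for d in sim_dims) for k in range(2 * n_thirds)
    ]
    training_pairs, novel_pairs = pairs[:n_thirds], pairs[n_thirds:]

    u_train = spec.alphabet(u_dim)[:per_third]
    u_test = spec.alphabet(u_dim)[per_third: per_third + per_group_cell]

    def build(rule_values: dict[int, str], pair: tuple[str, ...], u: str) -> tuple[str, ...]:
        feats = [""] * spec.n_dims
        for d, sym in rule_values.items():
            feats[d] = sym
        for d, sym in zip(sim_dims, pair):
            feats[d] = sym
        feats[u_dim] = u
        for d in uniq_dims[1:]:
            feats[d] = spec.alphabet(d)[0]  # spare irrelevant dims held constant
        return tuple(feats)

    training: list[Stimulus] = []
    for k, pair in enumerate(training_pairs):
        for m in range(per_third):
            feats = build(dict(rule.required), pair, u_train[m])
            training.append(
                Stimulus(f"train-{k}-{m}", feats, "training", True, "n/a")
            )

    test: list[Stimulus] = []
    for compliant in (True, False):
        for similarity, group_pairs in (("high", training_pairs), ("low", novel_pairs)):
            for g, pair in enumerate(group_pairs):
                for m in range(per_group_cell):
                    rule_values = dict(rule.required)
                    if not compliant:
                        # Violate exactly one rule dimension; which one is
                        # balanced within each group (and hence per cell).
                        viol = spec.rule_dims[(m + g) % len(spec.rule_dims)]
                        alternatives = [
                            s for s in spec.alphabet(viol) if s != rule.required[viol]
                        ]
                        rule_values[viol] = alternatives[int(rng.integers(len(alternatives)))]
                    feats = build(rule_values, pair, u_test[m])
                    label = "c" if compliant else "v"
                    test.append(
                        Stimulus(
                            f"test-{label}-{similarity}-{g}-{m}",
                            feats, "test", compliant, similarity,
                        )
                    )

    out = StimulusSet(spec=spec, rule=rule, training=training, test=test)
    report = validate_design(out, spec)
    if not report.passed:
        raise DesignError("generated design failed validation: " + "; ".join(report.violations))
    return out


@dataclass
class ValidationReport:
    passed: bool
    violations: list[str] = field(default_factory=list)
    checks: dict[str, bool] = field(default_factory=dict)


def validate_design(stimuli: StimulusSet, spec: DesignSpec | None = None) -> ValidationReport:
    """Check cell counts, uniqueness, per-condition balance and orthogonality."""
    if spec is None:
        spec = stimuli.spec
    violations: list[str] = []
    checks: dict[str, bool] = {}

    cells = Counter((s.compliant, s.similarity) for s in stimuli.test)
    ok = all(
        cells.get((c, sim), 0) == spec.cell_size
        for c in (True, False)
        for sim in ("high", "low")
    ) and len(stimuli.test) == spec.n_test
    checks["cell_counts"] = ok
    if not ok:
        violations.append(f"cell counts {dict(cells)} != {spec.cell_size} per cell")

    seen = Counter(s.features for s in stimuli)
    dupes = [f for f, n in seen.items() if n > 1]
    checks["uniqueness"] = not dupes
    if dupes:
        violations.append(f"{len(dupes)} duplicated feature vectors")

    ok = len(stimuli.training) == spec.n_training and all(
        stimuli.rule.is_compliant(s.features) for s in stimuli.training
    )
    checks["training_compliant"] = ok
    if not ok:
        violations.append("training set is not 12 rule-compliant items")

    # Orthogonality: within each similarity level, exactly half compliant.
    for sim in ("high", "low"):
        level = [s for s in stimuli.test if s.similarity == sim]
        n_comp = sum(s.compliant for s in level)
        ok = len(level) == 2 * spec.cell_size and n_comp * 2 == len(level)
        checks[f"orthogonality_{sim}"] = ok
        if not ok:
            violations.append(
                f"similarity={sim}: {n_comp} compliant of {len(level)} (expected half)"
            )

    # Balance: identical match-count multisets within each condition.
    for (comp, sim), items in _by_condition(stimuli.test).items():
        profiles = {
            tuple(sorted(match_count(s.features, t.features) for t in stimuli.training))
            for s in items
        }
        ok = len(profiles) <= 1
        checks[f"balance_{'c' if comp else 'v'}_{sim}"] = ok
        if not ok:
            violations.append(
                f"condition ({comp},{sim}): {len(profiles)} distinct match-count profiles"
            )

    # Novelty: low-similarity value pairs absent from training.
    sim_dims = spec.similarity_dims
    train_pairs = {tuple(t.features[d] for d in sim_dims) for t in stimuli.training}
    low_pairs = {
        tuple(s.features[d] for d in sim_dims)
        for s in stimuli.test
        if s.similarity == "low"
    }
    ok = not (train_pairs & low_pairs)
    checks["novelty"] = ok
    if not ok:
        violations.append("low-similarity items reuse a trained value pair")

    return ValidationReport(passed=not violations, violations=violations, checks=checks)


def _by_condition(test: Iterable[Stimulus]) -> dict[tuple[bool, str], list[Stimulus]]:
    out: dict[tuple[bool, str], list[Stimulus]] = {}
    for s in test:
        out.setdefault((s.compliant, s.similarity), []).append(s)
    return out


# ---------------------------------------------------------------------------
# IO: CSV (flat) and JSON (with spec header), round-trip safe.

_CSV_FIELDS = ["id", "role", "compliant", "similarity"]


def write_stimuli(stimuli: StimulusSet, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = {
            "schema_version": SCHEMA_VERSION,
            "spec": asdict(stimuli.spec),
            "rule": {str(k): v for k, v in stimuli.rule.required.items()},
            "stimuli": [
                {
                    "id": s.id,
                    "role": s.role,
                    "compliant": s.compliant,
                    "similarity": s.similarity,
                    "features": list(s.features),
                }
                for s in stimuli
            ],
        }
        path.write_text(json.dumps(payload, indent=1))
        return
    n = stimuli.spec.n_dims
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_FIELDS + [f"f{i + 1}" for i in range(n)])
        for s in stimuli:
            writer.writerow(
                [s.id, s.role, int(s.compliant), s.similarity, *s.features]
            )


def read_stimuli(path: str | Path, spec: DesignSpec | None = None) -> StimulusSet:
    """Read a stimulus set written by :func:`write_stimuli`.

    CSV files need ``spec`` (the file is flat); JSON files embed it.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        if payload.get("schema_version") != SCHEMA_VERSION:
            raise DesignError(
                f"schema version {payload.get('schema_version')} != {SCHEMA_VERSION}"
            )
        raw_spec = payload["spec"]
        for key in ("rule_dims", "alphabet_sizes"):
            raw_spec[key] = tuple(raw_spec[key])
        spec = DesignSpec(**raw_spec)
        rule = Rule(required={int(k): v for k, v in payload["rule"].items()})
        rows = [
            (r["id"], r["role"], bool(r["compliant"]), r["similarity"], r["features"])
            for r in payload["stimuli"]
        ]
    else:
        if spec is None:
            spec = DesignSpec()
        rows = []
        with open(path, newline="") as fh:
            reader = csv.reader(fh)
            header = next(reader, None)
            if header is None or header[: len(_CSV_FIELDS)] != _CSV_FIELDS:
                raise DesignError(f"{path}: unrecognised header {header}")
            for i, row in enumerate(reader, start=2):
                if len(row) != len(_CSV_FIELDS) + spec.n_dims:
                    raise DesignError(
                        f"{path}:{i}: expected {len(_CSV_FIELDS) + spec.n_dims} fields, got {len(row)}"
                    )
                sid, role, comp, sim, *feats = row
                rows.append((sid, role, comp not in ("0", "False", "false"), sim, feats))
        rule = None

    training, test = [], []
    for sid, role, comp, sim, feats in rows:
        if len(feats) != spec.n_dims:
            raise DesignError(f"stimulus {sid}: {len(feats)} features under a {spec.n_dims}-dim spec")
        for d, sym in enumerate(feats):
            if sym not in spec.alphabet(d):
                raise DesignError(f"stimulus {sid}: unknown symbol {sym!r} on dimension {d}")
        s = Stimulus(sid, tuple(feats), role, comp, sim)
        (training if role == "training" else test).append(s)
    if rule is None:
        # Reconstruct the rule as the symbols shared by all training items on
        # the spec's rule dimensions (training items are all compliant).
        if not training:
            raise DesignError("CSV set has no training items; cannot infer the rule")
        rule = Rule(
            required={d: training[0].features[d] for d in spec.rule_dims}
        )
    return StimulusSet(spec=spec, rule=rule, training=training, test=test)
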