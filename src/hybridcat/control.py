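"""Route selection by noisy utility comparison, and utility learning.

Each route carries a utility ``U = P*G - C + eps`` where ``P`` is its
estimated probability of success (successes / (successes + failures)),
``G`` is the value of the goal in seconds-equivalent, ``C`` the route's
expected time cost, and ``eps`` logistic noise of scale ``s_util``. On
every trial the route with the larger noisy utility runs; over trials the
noise produces a graded blend of the two routes.

``bias_to_states`` inverts this: given a target long-run exemplar-route
share, it constructs success/failure counts whose deterministic utility
gap, pushed through the exact distribution of the difference of two
logistic noise draws, reproduces that share. Supervised mode then updates
the counts of whichever route ran, from trial feedback.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq
from scipy.stats import logistic

from .memory import logistic_noise

__all__ = [
    "ControlError",
    "RouteState",
    "UtilityParams",
    "bias_to_states",
    "probability_of_success",
    "selection_probability",
    "select_route",
    "update_on_feedback",
    "utility",
]


class ControlError(ValueError):
    pass


@dataclass
class UtilityParams:
    G: float = 20.0       # goal value, seconds-equivalent
    s_util: float = 1.0   # logistic utility-noise scale

    def __post_init__(self) -> None:
        if self.G <= 0:
            raise ControlError("G must be positive")
        if self.s_util < 0:
            raise ControlError("s_util must be non-negative")


@dataclass(frozen=True)
class RouteState:
    """Success/failure tallies and fixed time cost for one route."""

    route: str                 # "rule" | "exemplar"
    successes: float
    failures: float
    C: float = 1.5             # expected completion time, seconds
    learning_enabled: bool = False

    def __post_init__(self) -> None:
        if self.successes < 0 or self.failures < 0:
            raise ControlError("counts must be non-negative")


def probability_of_success(successes: float, failures: float) -> float:
    """Relative frequency of rewarded outcomes attributed to a route."""
    total = successes + failures
    if total <= 0:
        raise ControlError("probability of success undefined with zero total count")
    return successes / total


def utility(
    state: RouteState,
    params: UtilityParams,
    rng: np.random.Generator | None = None,
) -> float:
    """One noisy utility draw: P*G - C + logistic(0, s_util)."""
    p = probability_of_success(state.successes, state.failures)
    u = p * params.G - state.C
    if params.s_util > 0:
        if rng is None:
            raise ControlError("rng required when s_util > 0")
        u += float(logistic_noise(rng, params.s_util))
    return u


def select_route(
    rule_state: RouteState,
    exemplar_state: RouteState,
    params: UtilityParams,
    rng: np.random.Generator,
) -> str:
    """Argmax of one noisy utility draw per route (uniform tie-break)."""
    u_rule = utility(rule_state, params, rng)
    u_ex = utility(exemplar_state, params, rng)
    if u_ex > u_rule:
        return "exemplar"
    if u_rule > u_ex:
        return "rule"
    return "exemplar" if rng.random() < 0.5 else "rule"


def selection_probability(delta_u: float, s_util: float) -> float:
    """P(exemplar wins) given a deterministic utility gap ``delta_u``
    (exemplar minus rule) and iid logistic noise of scale ``s_util`` on each.

    Computed from the exact distribution of the difference of two logistic
    draws by numerical integration (the difference is not itself logistic).
    """
    if s_util == 0:
        return 0.5 if delta_u == 0 else float(delta_u > 0)
    # P(eps_r - eps_e < delta_u) = E_{eps_e}[ CDF_logistic(delta_u + eps_e) ]
    val, _ = quad(
        lambda x: logistic.pdf(x, scale=s_util) * logistic.cdf(delta_u + x, scale=s_util),
        -np.inf,
        np.inf,
    )
    return min(max(val, 0.0), 1.0)


def bias_to_states(
    target_share: float,
    params: UtilityParams,
    C_rule: float = 1.5,
    C_exemplar: float = 1.5,
    prior_strength: float = 100.0,
    learning_enabled: bool = False,
) -> tuple[RouteState, RouteState]:
    """Construct (rule_state, exemplar_state) realising a target exemplar share.

    The probability-of-success estimates are offset symmetrically around
    0.5 so that the deterministic utility gap, under the two-draw logistic
    noise model, makes the exemplar route win on ``target_share`` of
    trials. ``prior_strength`` is the total prior count per route; it
    leaves the unsupervised share untouched and sets how fast feedback
    moves the estimates in supervised mode. Shares 0 and 1 are realised by
    clamping the estimates to 0/1 (deterministic dominance: the utility gap
    of G overwhelms the noise).
    """
    if not 0.0 <= target_share <= 1.0:
        raise ControlError("target_share must lie in [0, 1]")
    if prior_strength <= 0:
        raise ControlError("prior_strength must be positive")

    if target_share in (0.0, 1.0):
        p_ex = target_share
        p_rule = 1.0 - target_share
    else:
        if params.s_util == 0:
            if target_share != 0.5:
                raise ControlError(
                    "with s_util=0 only shares 0, 0.5 and 1 are realisable; "
                    "set s_util > 0"
                )
            delta_u = 0.0
        else:
            lo, hi = -60 * params.s_util, 60 * params.s_util
            delta_u = float(
                brentq(
                    lambda d: selection_probability(d, params.s_util) - target_share,
                    lo,
                    hi,
                    xtol=1e-10,
                )
            )
        # delta_u = (p_ex - p_rule) G - (C_exemplar - C_rule); split symmetrically.
        delta = (delta_u + (C_exemplar - C_rule)) / (2.0 * params.G)
        p_ex, p_rule = 0.5 + delta, 0.5 - delta
        if not (0.0 <= p_ex <= 1.0 and 0.0 <= p_rule <= 1.0):
            raise ControlError(
                f"target share {target_share} needs success probabilities outside [0,1] "
                f"(offset {delta:+.3f}); increase G or reduce s_util"
            )

    rule_state = RouteState(
        "rule",
        successes=p_rule * prior_strength,
        failures=(1.0 - p_rule) * prior_strength,
        C=C_rule,
        learning_enabled=learning_enabled,
    )
    ex_state = RouteState(
        "exemplar",
        successes=p_ex * prior_strength,
        failures=(1.0 - p_ex) * prior_strength,
        C=C_exemplar,
        learning_enabled=learning_enabled,
    )
    return rule_state, ex_state


def update_on_feedback(state_used: RouteState, correct: bool) -> RouteState:
    """Increment the used route's success (or failure) count; pure update."""
    if not state_used.learning_enabled:
        raise ControlError("update_on_feedback requires learning_enabled")
    if correct:
        return replace(state_used, successes=state_used.successes + 1.0)
    return replace(state_used, failures=state_used.failures + 1.0)
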