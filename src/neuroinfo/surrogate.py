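"""Monte-Carlo significance testing with marginal-preserving surrogates.

A surrogate data set permutes the observation sequence of designated
variables independently, which destroys joint structure in expectation
while preserving each variable's marginal state counts exactly.  The
p-value of an observed information value is estimated as the fraction of
surrogate values greater than or equal to it (>=, so a surrogate tying the
observation counts against significance).  When no surrogate reaches the
observed value the p-value is reported at the floor 1 / (2 * n_rand) and
flagged as below resolution.

Because estimation noise biases every information measure upward, a
surrogate null is the standard way to decide whether a nonzero value means
anything; raw p-values are returned and multiple-comparison control is left
to the caller (a Benjamini-Hochberg convenience wrapper is provided).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .discretize import StateSeries

__all__ = [
    "NullSpec",
    "SignificanceResult",
    "PrecomputedNull",
    "shuffle_observations",
    "mc_test",
    "reuse_null",
    "dependent_pair_model",
    "benjamini_hochberg",
]


@dataclass(frozen=True)
class NullSpec:
    """Surrogate-generation settings.

    shuffle_roles
        Variables (indices or names) whose observation sequences are
        permuted, each independently.  For transfer entropy, permute only
        the source's past — never the receiver's own past/future, whose
        coupling the null must preserve.
    """

    n_rand: int
    seed: int | None = None
    shuffle_roles: tuple = ()
    reusable: bool = False

    def __post_init__(self) -> None:
        if self.n_rand < 1:
            raise ValueError("n_rand must be >= 1")


@dataclass
class SignificanceResult:
    """Observed statistic vs. its surrogate null distribution."""

    observed: float
    null_values: np.ndarray
    p_estimate: float
    below_resolution: bool
    p_floor: float

    @property
    def significant_at(self) -> Callable[[float], bool]:
        return lambda alpha: self.p_estimate <= alpha


@dataclass
class PrecomputedNull:
    """A null distribution reusable across measurements.

    Valid only for measurements whose per-variable marginal state counts
    are identical to those that generated the null (uniform-count binning
    with a shared observation count typically guarantees this).
    """

    null_values: np.ndarray
    marginal_counts: list[np.ndarray] = field(default_factory=list)

    @classmethod
    def from_states(cls, null_values: np.ndarray, states: StateSeries) -> "PrecomputedNull":
        return cls(np.asarray(null_values, dtype=float), _marginal_counts(states))


def _marginal_counts(states: StateSeries) -> list[np.ndarray]:
    return [
        np.bincount(states.states[:, j], minlength=int(states.n_states[j]))
        for j in range(states.n_vars)
    ]


def _resolve_roles(states: StateSeries, roles: Sequence) -> list[int]:
    if not roles:
        raise ValueError("at least one variable must be shuffled")
    return [states.index_of(r) if isinstance(r, str) else int(r) for r in roles]


def shuffle_observations(
    states: StateSeries,
    spec: NullSpec,
    rng: np.random.Generator | None = None,
) -> StateSeries:
    """Independently permute the observation sequence of designated variables.

    Per-variable marginal counts are exactly preserved; the joint structure
    between shuffled and unshuffled variables is destroyed in expectation.
    """
    if states.n_obs < 2:
        raise ValueError("need >= 2 observations to shuffle")
    idx = _resolve_roles(states, spec.shuffle_roles)
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    out = states.states.copy()
    for j in idx:
        out[:, j] = out[rng.permutation(states.n_obs), j]
    return StateSeries(out, states.n_states.copy(), list(states.names))


def _summarize(observed: float, null_values: np.ndarray, n_rand: int) -> SignificanceResult:
    count = int(np.sum(null_values >= observed))
    floor = 1.0 / (2 * n_rand)
    if count == 0:
        return SignificanceResult(observed, null_values, floor, True, floor)
    return SignificanceResult(observed, null_values, count / n_rand, False, floor)


def mc_test(
    measure: Callable[[StateSeries], float],
    states: StateSeries,
    spec: NullSpec,
) -> SignificanceResult:
    """Score ``measure`` on the data and on ``n_rand`` surrogates.

    ``measure`` maps a StateSeries to a float (e.g. a lambda closing over an
    infocore operation and its roles).  One master seed spawns independent
    per-surrogate substreams, so results are reproducible and independent of
    evaluation order.
    """
    observed = float(measure(states))
    master = np.random.default_rng(spec.seed)
    streams = master.spawn(spec.n_rand)
    idx = _resolve_roles(states, spec.shuffle_roles)
    base = states.states
    n = states.n_obs
    scratch = StateSeries(base.copy(), states.n_states.copy(), list(states.names))
    null_values = np.empty(spec.n_rand)
    for k, rng in enumerate(streams):
        for j in idx:
            scratch.states[:, j] = base[rng.permutation(n), j]
        null_values[k] = float(measure(scratch))
    return _summarize(observed, null_values, spec.n_rand)


def reuse_null(
    null: PrecomputedNull,
    states: StateSeries,
    measure: Callable[[StateSeries], float] | None = None,
    observed: float | None = None,
) -> SignificanceResult:
    """Test a new measurement against a previously computed null.

    The new measurement's per-variable marginal counts must match those
    that generated the null exactly (the precondition for sharing a null
    model); otherwise an error is raised.
    """
    new_counts = _marginal_counts(states)
    if len(new_counts) != len(null.marginal_counts) or any(
        a.shape != b.shape or np.any(a != b)
        for a, b in zip(new_counts, null.marginal_counts)
    ):
        raise ValueError(
            "marginal state counts differ from those that generated the "
            "null; a shared null model is invalid here"
        )
    if observed is None:
        if measure is None:
            raise ValueError("provide either measure or observed")
        observed = float(measure(states))
    n_rand = len(null.null_values)
    return _summarize(observed, np.asarray(null.null_values, dtype=float), n_rand)


def dependent_pair_model(
    a: float, n_obs: int, seed: int | np.random.Generator | None = None
) -> StateSeries:
    """Sample a tunable-dependence pair of binary variables.

    Joint distribution: matching states (x=y) each have probability
    0.25*(1+a), mismatching states 0.25*(1-a).  ``a=0`` gives independent
    uniform pairs (population MI 0); ``a=1`` gives identical copies
    (population MI 1 bit).
    """
    if not 0.0 <= a <= 1.0:
        raise ValueError("a must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = np.array([1 + a, 1 - a, 1 - a, 1 + a]) / 4.0
    flat = rng.choice(4, size=n_obs, p=p)
    states = np.column_stack([flat // 2, flat % 2]).astype(np.int64)
    return StateSeries(states, np.array([2, 2]), ["X", "Y"])


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """FDR-adjusted p-values (Benjamini-Hochberg step-up)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]
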