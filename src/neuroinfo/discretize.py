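"""Discretization of observations and count-based probability estimation.

Raw observations (continuous signals, spike counts, labels) are converted to
integer *state series*, optionally assembled into lagged joint observations,
and turned into joint probability tables by counting.  Every downstream
information measure consumes the :class:`JointDistribution` produced here.

Probabilities are maximum-likelihood estimates: ``p(s) = N_s / N_obs`` where
``N_s`` counts the observations of joint state ``s``.  This assumes
stationarity — every observation is a draw from one unchanging distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "BinningSpec",
    "StateSeries",
    "LagVar",
    "JointDistribution",
    "bin_uniform_width",
    "bin_uniform_count",
    "apply_binning",
    "estimate_joint",
    "marginalize",
    "conditional",
    "assemble_lagged",
]


@dataclass(frozen=True)
class BinningSpec:
    """How to discretize one variable.

    method
        ``"uniform_width"`` — equal-width bins over [min, max];
        ``"uniform_count"`` — empirical-quantile bins with (near-)equal
        occupancy, ties never split;
        ``"none"`` — input is already integer-coded.
    n_bins
        Number of states to produce (>= 2 unless method is ``"none"``).
        There is deliberately no default: bin count is an analysis parameter
        the user must choose.
    """

    method: str
    n_bins: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("uniform_width", "uniform_count", "none"):
            raise ValueError(f"unknown binning method {self.method!r}")
        if self.method != "none" and self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")


@dataclass
class StateSeries:
    """Integer-coded discrete observations, observations x variables.

    ``states[i, v]`` is the state of variable ``v`` at observation ``i``,
    in ``0 .. n_states[v] - 1``.  Variables may carry names for role-based
    lookup.
    """

    states: np.ndarray
    n_states: np.ndarray
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states)
        if self.states.ndim == 1:
            self.states = self.states[:, None]
        if not np.issubdtype(self.states.dtype, np.integer):
            raise TypeError("states must be integers; discretize first")
        self.n_states = np.atleast_1d(np.asarray(self.n_states, dtype=np.int64))
        if self.n_states.shape[0] != self.states.shape[1]:
            raise ValueError("one n_states entry per variable required")
        if self.states.size and (
            self.states.min() < 0 or np.any(self.states.max(axis=0) >= self.n_states)
        ):
            raise ValueError("state codes out of range for declared n_states")
        if not self.names:
            self.names = [f"v{i}" for i in range(self.states.shape[1])]
        elif len(self.names) != self.states.shape[1]:
            raise ValueError("one name per variable required")

    @property
    def n_obs(self) -> int:
        return self.states.shape[0]

    @property
    def n_vars(self) -> int:
        return self.states.shape[1]

    def index_of(self, name: str) -> int:
        return self.names.index(name)

    def select(self, variables: Sequence[int | str]) -> "StateSeries":
        idx = [self.index_of(v) if isinstance(v, str) else int(v) for v in variables]
        return StateSeries(
            self.states[:, idx], self.n_states[idx], [self.names[i] for i in idx]
        )

    @classmethod
    def from_columns(
        cls, columns: Sequence[np.ndarray], names: Sequence[str] | None = None
    ) -> "StateSeries":
        cols = [np.asarray(c).ravel() for c in columns]
        n = {len(c) for c in cols}
        if len(n) != 1:
            raise ValueError("columns must share the observation axis")
        states = np.column_stack(cols).astype(np.int64)
        n_states = states.max(axis=0) + 1 if states.size else np.ones(len(cols), int)
        return cls(states, n_states, list(names) if names else [])


@dataclass(frozen=True)
class LagVar:
    """Placement of one variable in a lagged joint observation.

    delay
        Time bins between this variable's observation and the reference
        time (0 = simultaneous with the reference).
    window
        Number of consecutive bins to include, ending ``delay`` bins before
        the reference; a window > 1 is encoded as a single vector-valued
        state (mixed-radix over the window).
    """

    variable: int | str
    delay: int = 0
    window: int = 1

    def __post_init__(self) -> None:
        if self.delay < 0:
            raise ValueError("delays must be >= 0")
        if self.window < 1:
            raise ValueError("window must be >= 1")


@dataclass
class JointDistribution:
    """Probability table over the joint states of 1..k variables.

    One tensor axis per variable.  When built from data, ``probabilities``
    is exactly ``counts / n_obs``.  Axes may carry names (e.g. roles like
    ``"Yfuture"``) used by role-aware measures.
    """

    probabilities: np.ndarray
    counts: np.ndarray | None = None
    n_obs: int | None = None
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if p.size == 0:
            raise ValueError("empty distribution")
        if np.any(p < 0) or not np.all(np.isfinite(p)):
            raise ValueError("probabilities must be finite and non-negative")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValueError(f"probabilities sum to {p.sum()!r}, not 1")
        self.probabilities = p
        if not self.names:
            self.names = [f"v{i}" for i in range(p.ndim)]
        elif len(self.names) != p.ndim:
            raise ValueError("one name per axis required")

    @property
    def ndim(self) -> int:
        return self.probabilities.ndim

    def axis_of(self, name: str) -> int:
        return self.names.index(name)

    def axes_of(self, axes: Sequence[int | str] | int | str) -> tuple[int, ...]:
        if isinstance(axes, (int, str)):
            axes = [axes]
        return tuple(self.axis_of(a) if isinstance(a, str) else int(a) for a in axes)


def bin_uniform_width(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Discretize into ``n_bins`` equal-width bins over [min, max].

    Intervals are half-open [lo, hi) except the last, which is closed, so the
    maximum lands in the top bin.  Constant input cannot form bins and is an
    error rather than a silent one-state variable (a one-state variable has
    zero entropy and would nullify every downstream measure).
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0 or not np.all(np.isfinite(v)):
        raise ValueError("values must be non-empty and finite")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    lo, hi = v.min(), v.max()
    if lo == hi:
        raise ValueError("degenerate range: constant input cannot be binned")
    edges = np.linspace(lo, hi, n_bins + 1)
    return np.digitize(v, edges[1:-1]).astype(np.int64)


def bin_uniform_count(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Discretize at empirical quantiles into (near-)equal-count bins.

    Each state receives floor(n / n_bins) or ceil(n / n_bins) observations
    when values are distinct.  Identical values are never split across
    states: a quantile boundary falling inside a tie group shifts to the
    group's end, so marginals can be non-uniform with heavily tied data.
    State codes are compacted to consecutive integers, so fewer than
    ``n_bins`` effective states may result (with a warning).
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0 or not np.all(np.isfinite(v)):
        raise ValueError("values must be non-empty and finite")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    uniq = np.unique(v)
    if uniq.size == 1:
        raise ValueError("degenerate range: constant input cannot be binned")
    n = v.size
    order = np.argsort(v, kind="stable")
    provisional = (np.arange(n) * n_bins) // n
    # assign every member of a tie group the bin of the group's first element
    sorted_v = v[order]
    group_start = np.zeros(n, dtype=np.int64)
    new_group = np.flatnonzero(sorted_v[1:] != sorted_v[:-1]) + 1
    group_start[new_group] = new_group
    np.maximum.accumulate(group_start, out=group_start)
    binned_sorted = provisional[group_start]
    codes = np.empty(n, dtype=np.int64)
    codes[order] = binned_sorted
    used = np.unique(codes)
    if used.size < n_bins:
        warnings.warn(
            f"only {used.size} of {n_bins} requested states are occupied "
            "(tied or too few distinct values)",
            stacklevel=2,
        )
    if used.size != used[-1] + 1:  # compact skipped codes
        remap = np.zeros(used[-1] + 1, dtype=np.int64)
        remap[used] = np.arange(used.size)
        codes = remap[codes]
    return codes


def apply_binning(
    values: np.ndarray,
    specs: Sequence[BinningSpec] | BinningSpec,
    names: Sequence[str] | None = None,
) -> StateSeries:
    """Apply per-variable binning specs to an observations x variables matrix."""
    vals = np.asarray(values)
    if vals.ndim == 1:
        vals = vals[:, None]
    if isinstance(specs, BinningSpec):
        specs = [specs] * vals.shape[1]
    if len(specs) != vals.shape[1]:
        raise ValueError("one BinningSpec per variable required")
    cols = []
    for j, spec in enumerate(specs):
        col = vals[:, j]
        if spec.method == "uniform_width":
            cols.append(bin_uniform_width(col, spec.n_bins))
        elif spec.method == "uniform_count":
            cols.append(bin_uniform_count(col, spec.n_bins))
        else:
            icol = np.asarray(col)
            if not np.all(np.isfinite(icol.astype(float))):
                raise ValueError("non-finite values rejected at ingestion")
            icol = icol.astype(np.int64)
            if np.any(icol != np.asarray(col, dtype=float)):
                raise ValueError("method 'none' requires integer-coded input")
            if icol.min() < 0:
                icol = icol - icol.min()
            cols.append(icol)
    return StateSeries.from_columns(cols, names)


def estimate_joint(
    states: StateSeries, variables: Sequence[int | str] | None = None
) -> JointDistribution:
    """Count joint states and normalize: ``p(s) = N_s / N_obs`` ."""
    if variables is not None:
        states = states.select(variables)
    if states.n_obs == 0:
        raise ValueError("zero observations")
    shape = tuple(int(k) for k in states.n_states)
    flat = np.ravel_multi_index(tuple(states.states.T), shape)
    counts = np.bincount(flat, minlength=int(np.prod(shape))).reshape(shape)
    return JointDistribution(
        counts / states.n_obs, counts=counts, n_obs=states.n_obs,
        names=list(states.names),
    )


def marginalize(
    joint: JointDistribution, keep: Sequence[int | str]
) -> JointDistribution:
    """Sum out every axis not in ``keep``; result axes follow ``keep`` order."""
    keep_ax = joint.axes_of(keep)
    if len(keep_ax) == 0:
        raise ValueError("keep must be non-empty")
    if len(set(keep_ax)) != len(keep_ax):
        raise ValueError("duplicate axes in keep")
    drop = tuple(a for a in range(joint.ndim) if a not in keep_ax)
    p = joint.probabilities.sum(axis=drop) if drop else joint.probabilities
    c = joint.counts.sum(axis=drop) if (joint.counts is not None and drop) else joint.counts
    # reorder surviving axes to match the requested order
    surviving = [a for a in range(joint.ndim) if a in keep_ax]
    perm = [surviving.index(a) for a in keep_ax]
    p = np.transpose(p, perm)
    c = np.transpose(c, perm) if c is not None else None
    return JointDistribution(
        p, counts=c, n_obs=joint.n_obs, names=[joint.names[a] for a in keep_ax]
    )


def conditional(
    joint: JointDistribution,
    target: Sequence[int | str] | int | str,
    given: Sequence[int | str] | int | str,
) -> np.ndarray:
    """Conditional probability table p(target | given) via Bayes' theorem.

    Returned array has axes ordered (*target, *given).  Conditioning states
    with zero probability are flagged with NaN rather than divided.
    """
    t_ax = joint.axes_of(target)
    g_ax = joint.axes_of(given)
    if set(t_ax) & set(g_ax):
        raise ValueError("target and given must be disjoint")
    sub = marginalize(joint, list(t_ax) + list(g_ax))
    p_tg = sub.probabilities
    p_g = p_tg.sum(axis=tuple(range(len(t_ax))))
    if np.all(p_g == 0):
        raise ValueError("all conditioning mass is zero")
    with np.errstate(divide="ignore", invalid="ignore"):
        cond = p_tg / p_g
    cond[..., p_g == 0] = np.nan
    return cond


def _encode_window(block: np.ndarray, n_states: int) -> tuple[np.ndarray, int]:
    """Mixed-radix encode an (n_obs, window) block into one state code."""
    w = block.shape[1]
    if w == 1:
        return block[:, 0], n_states
    weights = n_states ** np.arange(w)[::-1]
    return block @ weights, int(n_states**w)


def assemble_lagged(
    states: StateSeries | np.ndarray,
    roles: Mapping[str, LagVar],
    layout: str = "single_trial",
    reference_bin: int | None = None,
) -> StateSeries:
    """Assemble lagged joint observations for role-based measures.

    Single-trial layout: ``states`` is observations(time) x variables; the
    reference time slides over the series and boundary bins lacking a full
    lag tuple are dropped.  Trial-based layout: ``states`` is a 3-D integer
    array (trials x time x variables); the within-trial ``reference_bin`` is
    fixed and trials form the observation axis.

    Each role becomes one output variable named after the role; windows > 1
    are encoded as a single vector-valued state.
    """
    if not roles:
        raise ValueError("at least one role required")
    if layout == "single_trial":
        if not isinstance(states, StateSeries):
            raise TypeError("single-trial layout requires a StateSeries")
        max_back = max(lv.delay + lv.window - 1 for lv in roles.values())
        n = states.n_obs
        if max_back >= n:
            raise ValueError("delay/window exceeds series length")
        ref = np.arange(max_back, n)
        cols, ns, names = [], [], []
        for name, lv in roles.items():
            vi = states.index_of(lv.variable) if isinstance(lv.variable, str) else lv.variable
            offs = lv.delay + np.arange(lv.window)
            block = states.states[ref[:, None] - offs[None, :], vi]
            code, k = _encode_window(block, int(states.n_states[vi]))
            cols.append(code)
            ns.append(k)
            names.append(name)
        out = StateSeries.from_columns(cols, names)
        out.n_states = np.asarray(ns, dtype=np.int64)
        return out
    if layout == "trial_based":
        arr = states.states if isinstance(states, StateSeries) else np.asarray(states)
        if arr.ndim != 3:
            raise ValueError("trial-based layout requires trials x time x variables")
        if reference_bin is None:
            raise ValueError("trial-based layout requires reference_bin")
        n_time = arr.shape[1]
        cols, ns, names = [], [], []
        for name, lv in roles.items():
            vi = int(lv.variable)
            offs = lv.delay + np.arange(lv.window)
            if reference_bin - offs.max() < 0 or reference_bin >= n_time:
                raise ValueError("reference bin lacks a full lag tuple")
            block = arr[:, reference_bin - offs, vi].astype(np.int64)
            k = int(block.max()) + 1 if block.size else 1
            code, k = _encode_window(block, k)
            cols.append(code)
            ns.append(k)
            names.append(name)
        out = StateSeries.from_columns(cols, names)
        out.n_states = np.asarray(ns, dtype=np.int64)
        return out
    raise ValueError(f"unknown layout {layout!r}")
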