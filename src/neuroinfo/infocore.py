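"""Discrete information-theoretic functionals on joint probability tables.

All measures use base-2 logarithms (units: bits) and the convention
``0 * log2(0/q) = 0``: terms with zero joint probability are skipped.  Every
measure implemented here is provably non-negative, so tiny negative floating
point residues (>= -1e-12) are clamped to zero; anything more negative
signals a broken input distribution and raises.

Each functional accepts either a :class:`~neuroinfo.discretize.JointDistribution`
or a :class:`~neuroinfo.discretize.StateSeries` (estimation is then performed
internally by counting).  Axes may be addressed by index or by name/role.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .discretize import JointDistribution, StateSeries, estimate_joint, marginalize

__all__ = [
    "InfoResult",
    "PIDResult",
    "entropy",
    "conditional_entropy",
    "mutual_information",
    "conditional_mutual_information",
    "transfer_entropy",
    "i_min",
    "pid",
    "information_gain",
    "information_transmission",
]

Axes = Sequence[int | str] | int | str


@dataclass(frozen=True)
class InfoResult:
    """Value of one information measure, in bits, with its axis roles."""

    value: float
    measure: str
    variable_roles: dict = field(default_factory=dict)

    def __float__(self) -> float:
        return self.value


@dataclass(frozen=True)
class PIDResult:
    """Two-source partial information decomposition (all values in bits).

    ``total = synergy + redundancy + unique_1 + unique_2`` holds exactly,
    as do ``single_i = redundancy + unique_i``.
    """

    synergy: float
    redundancy: float
    unique_1: float
    unique_2: float
    total: float
    single_1: float
    single_2: float


def _clamp(value: float, measure: str) -> float:
    if value < 0.0:
        if value < -1e-12:
            raise ValueError(
                f"{measure} evaluated to {value}; every measure here is "
                "non-negative, so the input distribution is inconsistent"
            )
        return 0.0
    return float(value)


def _as_joint(dist: JointDistribution | StateSeries) -> JointDistribution:
    if isinstance(dist, StateSeries):
        return estimate_joint(dist)
    return dist


def _xlog2x(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


def entropy(
    dist: JointDistribution | StateSeries, axes: Axes | None = None
) -> InfoResult:
    """Shannon entropy H = sum p log2(1/p), the uncertainty of the table.

    With ``axes`` given, the marginal over those axes is taken first; a
    multi-axis table yields the joint entropy.
    """
    joint = _as_joint(dist)
    if axes is not None:
        joint = marginalize(joint, joint.axes_of(axes))
    h = -_xlog2x(joint.probabilities).sum()
    return InfoResult(_clamp(h, "entropy"), "H", {"axes": list(joint.names)})


def _check_disjoint(*axis_sets: tuple[int, ...]) -> None:
    seen: set[int] = set()
    for s in axis_sets:
        if not s:
            raise ValueError("axis sets must be non-empty")
        if seen & set(s):
            raise ValueError("axis sets must be disjoint")
        seen |= set(s)


def conditional_entropy(
    dist: JointDistribution | StateSeries, target: Axes, given: Axes
) -> InfoResult:
    """H(target | given) = H(target, given) - H(given) (chain rule)."""
    joint = _as_joint(dist)
    t, g = joint.axes_of(target), joint.axes_of(given)
    _check_disjoint(t, g)
    h_tg = entropy(joint, list(t) + list(g)).value
    h_g = entropy(joint, list(g)).value
    return InfoResult(
        _clamp(h_tg - h_g, "conditional entropy"),
        "H|",
        {"target": list(t), "given": list(g)},
    )


def mutual_information(
    dist: JointDistribution | StateSeries, side_a: Axes, side_b: Axes
) -> InfoResult:
    """I(A;B) = sum p(a,b) log2( p(a,b) / (p(a) p(b)) ), symmetric in A, B."""
    joint = _as_joint(dist)
    a, b = joint.axes_of(side_a), joint.axes_of(side_b)
    _check_disjoint(a, b)
    # canonical ascending axis order keeps the summation sequence identical
    # under side swaps, making the symmetry I(A;B) = I(B;A) bit-exact
    keep = sorted(a + b)
    sub = marginalize(joint, keep).probabilities
    pos = {ax: i for i, ax in enumerate(keep)}
    a_pos = tuple(pos[ax] for ax in a)
    b_pos = tuple(pos[ax] for ax in b)
    pa = sub.sum(axis=b_pos, keepdims=True)
    pb = sub.sum(axis=a_pos, keepdims=True)
    outer = pa * pb
    nz = sub > 0
    mi = float(np.sum(sub[nz] * np.log2(sub[nz] / outer[nz])))
    return InfoResult(_clamp(mi, "mutual information"), "MI", {"a": list(a), "b": list(b)})


def conditional_mutual_information(
    dist: JointDistribution | StateSeries, side_a: Axes, side_b: Axes, given: Axes
) -> InfoResult:
    """I(A;B|Z) = sum p(a,b,z) log2( p(a,b,z) p(z) / (p(a,z) p(b,z)) )."""
    joint = _as_joint(dist)
    a, b, z = joint.axes_of(side_a), joint.axes_of(side_b), joint.axes_of(given)
    _check_disjoint(a, b, z)
    sub = marginalize(joint, list(a) + list(b) + list(z)).probabilities
    ka, kb = len(a), len(b)
    ax_a = tuple(range(ka))
    ax_b = tuple(range(ka, ka + kb))
    p_az = sub.sum(axis=ax_b)  # axes (a, z)
    p_bz = sub.sum(axis=ax_a)  # axes (b, z)
    p_z = p_az.sum(axis=tuple(range(ka)))
    nz = sub > 0
    num = sub * p_z  # broadcasting appends z-axes
    den = (
        p_az.reshape(p_az.shape[:ka] + (1,) * kb + p_az.shape[ka:])
        * p_bz
    )
    cmi = float(np.sum(sub[nz] * np.log2(num[nz] / den[nz])))
    return InfoResult(
        _clamp(cmi, "conditional mutual information"),
        "CMI",
        {"a": list(a), "b": list(b), "given": list(z)},
    )


def transfer_entropy(
    dist: JointDistribution | StateSeries,
    future: Axes = "Yfuture",
    source_past: Axes = "Xpast",
    target_past: Axes = "Ypast",
) -> InfoResult:
    """TE(X -> Y) = I(Yfuture ; Xpast | Ypast).

    Expects a table assembled with the roles ``Yfuture``, ``Xpast`` and
    ``Ypast`` (see :func:`~neuroinfo.discretize.assemble_lagged`); a directed,
    model-free measure of the predictive influence of X's past on Y's future
    beyond what Y's own past provides.
    """
    joint = _as_joint(dist)
    try:
        f = joint.axes_of(future)
        sp = joint.axes_of(source_past)
        tp = joint.axes_of(target_past)
    except ValueError as exc:
        raise ValueError(f"required role label missing: {exc}") from exc
    res = conditional_mutual_information(joint, f, sp, tp)
    return InfoResult(res.value, "TE", {"future": list(f), "source_past": list(sp),
                                        "target_past": list(tp)})


def _specific_terms(sub: np.ndarray, n_source_axes: int) -> np.ndarray:
    """Per-target-state joint-weighted pointwise information of one source.

    ``sub`` has axes (source..., target...); returns, for each target state
    y, ``sum_x p(x, y) log2( p(x, y) / (p(x) p(y)) )``, the source's specific
    information about y (equal to p(y) * KL(p(x|y) || p(x)), hence >= 0).
    """
    src_ax = tuple(range(n_source_axes))
    tgt_ax = tuple(range(n_source_axes, sub.ndim))
    px = sub.sum(axis=tgt_ax)
    py = sub.sum(axis=src_ax)
    outer = px.reshape(px.shape + (1,) * py.ndim) * py
    nz = sub > 0
    contrib = np.zeros_like(sub)
    contrib[nz] = sub[nz] * np.log2(sub[nz] / outer[nz])
    return contrib.sum(axis=src_ax)


def i_min(
    dist: JointDistribution | StateSeries,
    sources: Sequence[Axes],
    target: Axes,
) -> InfoResult:
    """Minimum information: the Williams-Beer redundancy of two sources.

    ``Imin = sum_y min_i sum_x p(x_i, y) log2( p(x_i, y) / (p(x_i) p(y)) )``
    — the smaller of the two sources' specific information, per target
    state, summed over target states.  Each source may be a vector-valued
    set of axes.  Bounded by 0 and min_i I(X_i ; Y).
    """
    joint = _as_joint(dist)
    if len(sources) != 2:
        raise ValueError(
            "i_min supports exactly two sources; decompositions over three "
            "or more sources are not implemented"
        )
    t = joint.axes_of(target)
    s1 = joint.axes_of(sources[0])
    s2 = joint.axes_of(sources[1])
    _check_disjoint(s1, s2, t)
    terms = []
    for s in (s1, s2):
        sub = marginalize(joint, list(s) + list(t)).probabilities
        terms.append(_specific_terms(sub, len(s)))
    value = float(np.minimum(terms[0], terms[1]).sum())
    return InfoResult(_clamp(value, "Imin"), "Imin",
                      {"sources": [list(s1), list(s2)], "target": list(t)})


def pid(
    dist: JointDistribution | StateSeries,
    sources: Sequence[Axes],
    target: Axes,
) -> PIDResult:
    """Partial information decomposition with redundancy R = Imin.

    Splits I({X1,X2};Y) into synergy, redundancy and the two unique terms:
    ``U_i = I(X_i;Y) - R`` and ``S = I({X1,X2};Y) - R - U1 - U2``.
    """
    joint = _as_joint(dist)
    if len(sources) != 2:
        raise ValueError("pid supports exactly two sources")
    t = joint.axes_of(target)
    s1 = joint.axes_of(sources[0])
    s2 = joint.axes_of(sources[1])
    _check_disjoint(s1, s2, t)
    r = i_min(joint, sources, target).value
    i1 = mutual_information(joint, s1, t).value
    i2 = mutual_information(joint, s2, t).value
    i12 = mutual_information(joint, list(s1) + list(s2), t).value
    u1 = _clamp(i1 - r, "unique information (source 1)")
    u2 = _clamp(i2 - r, "unique information (source 2)")
    s = _clamp(i12 - r - u1 - u2, "synergy")
    return PIDResult(
        synergy=s, redundancy=r, unique_1=u1, unique_2=u2,
        total=i12, single_1=i1, single_2=i2,
    )


def information_gain(
    dist: JointDistribution | StateSeries,
    other: Axes = "X",
    future: Axes = "Yfuture",
    past: Axes = "Ypast",
) -> InfoResult:
    """Information Y newly gains through time about X.

    ``IG = I(X ; Yfuture) - Imin({Yfuture}, {Ypast} ; X)`` — the information
    Y's future carries about X minus the part already shared redundantly
    with Y's own past.
    """
    joint = _as_joint(dist)
    try:
        x = joint.axes_of(other)
        f = joint.axes_of(future)
        p = joint.axes_of(past)
    except ValueError as exc:
        raise ValueError(f"required role label missing: {exc}") from exc
    _check_disjoint(x, f, p)
    value = (
        mutual_information(joint, f, x).value
        - i_min(joint, [list(f), list(p)], x).value
    )
    return InfoResult(_clamp(value, "information gain"), "IG",
                      {"other": list(x), "future": list(f), "past": list(p)})


def information_transmission(
    dist: JointDistribution | StateSeries,
    other: Axes = "X",
    source_past: Axes = "Ypast",
    receiver_future: Axes = "Zfuture",
    receiver_past: Axes = "Zpast",
) -> InfoResult:
    """Information about X conveyed from Y's past into Z's future.

    ``IT = Imin({Zfuture}, {Zpast, Ypast} ; X)
         - Imin({Zfuture}, {Zpast} ; X)``:
    the redundancy between Z's future and (Z's past plus Y's past) about X,
    beyond the redundancy between Z's future and Z's past alone — i.e. the
    share of Z's future information about X attributable to Y's past.  The
    multi-axis source enters Imin as a single vector-valued source.
    """
    joint = _as_joint(dist)
    try:
        x = joint.axes_of(other)
        yp = joint.axes_of(source_past)
        zf = joint.axes_of(receiver_future)
        zp = joint.axes_of(receiver_past)
    except ValueError as exc:
        raise ValueError(f"required role label missing: {exc}") from exc
    _check_disjoint(x, yp, zf, zp)
    with_y = i_min(joint, [list(zf), list(zp) + list(yp)], x).value
    without_y = i_min(joint, [list(zf), list(zp)], x).value
    return InfoResult(
        _clamp(with_y - without_y, "information transmission"),
        "IT",
        {"other": list(x), "source_past": list(yp),
         "receiver_future": list(zf), "receiver_past": list(zp)},
    )
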