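"""Independent brute-force reference implementations.

Every function here enumerates joint states explicitly with dict-based
marginals and pure-Python arithmetic, deliberately sharing no code path
with the package's vectorized estimators.
"""

from __future__ import annotations

import itertools
import math


def _states(shape):
    return itertools.product(*(range(k) for k in shape))


def marginal(p, axes):
    """Dict {sub-state tuple: probability} over the given axes."""
    axes = tuple(axes)
    out: dict = {}
    for s in _states(p.shape):
        key = tuple(s[a] for a in axes)
        out[key] = out.get(key, 0.0) + float(p[s])
    return out


def entropy_oracle(p, axes=None):
    axes = tuple(range(p.ndim)) if axes is None else tuple(axes)
    return sum(
        q * math.log2(1.0 / q) for q in marginal(p, axes).values() if q > 0
    )


def conditional_entropy_oracle(p, target, given):
    target, given = tuple(target), tuple(given)
    p_tg = marginal(p, target + given)
    p_g = marginal(p, given)
    total = 0.0
    for key, q in p_tg.items():
        if q > 0:
            total += q * math.log2(p_g[key[len(target):]] / q)
    return total


def mi_oracle(p, a, b):
    a, b = tuple(a), tuple(b)
    pa, pb = marginal(p, a), marginal(p, b)
    total = 0.0
    for key, q in marginal(p, a + b).items():
        if q > 0:
            total += q * math.log2(q / (pa[key[: len(a)]] * pb[key[len(a):]]))
    return total


def cmi_oracle(p, a, b, z):
    a, b, z = tuple(a), tuple(b), tuple(z)
    p_abz = marginal(p, a + b + z)
    p_az = marginal(p, a + z)
    p_bz = marginal(p, b + z)
    p_z = marginal(p, z)
    total = 0.0
    for key, q in p_abz.items():
        if q > 0:
            ka, kb, kz = key[: len(a)], key[len(a): len(a) + len(b)], key[len(a) + len(b):]
            total += q * math.log2(q * p_z[kz] / (p_az[ka + kz] * p_bz[kb + kz]))
    return total


def specific_info_oracle(p, source, target, y):
    """sum_x p(x, y) log2( p(x, y) / (p(x) p(y)) ) for one target state y."""
    source, target = tuple(source), tuple(target)
    ps = marginal(p, source)
    pt = marginal(p, target)
    pst = marginal(p, source + target)
    total = 0.0
    for key, q in pst.items():
        if key[len(source):] == y and q > 0:
            total += q * math.log2(q / (ps[key[: len(source)]] * pt[y]))
    return total


def imin_oracle(p, source_1, source_2, target):
    target = tuple(target)
    total = 0.0
    for y in marginal(p, target):
        total += min(
            specific_info_oracle(p, source_1, target, y),
            specific_info_oracle(p, source_2, target, y),
        )
    return total


def pid_oracle(p, s1, s2, t):
    """(synergy, redundancy, unique_1, unique_2) from the Imin bookkeeping."""
    r = imin_oracle(p, s1, s2, t)
    i1 = mi_oracle(p, s1, t)
    i2 = mi_oracle(p, s2, t)
    i12 = mi_oracle(p, tuple(s1) + tuple(s2), t)
    u1, u2 = i1 - r, i2 - r
    return i12 - r - u1 - u2, r, u1, u2
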