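"""Independent high-precision re-implementations of the disproportionality
closed forms, used only as test oracles.

Everything here is computed with mpmath at 50 significant digits, from
the formulas written out directly — deliberately sharing no code with
``pvsignal.stats``.
"""

from __future__ import annotations

import mpmath as mp

mp.mp.dps = 50


def ror_oracle(a: int, b: int, c: int, d: int, z: str = "1.96"):
    """(ror, lo, hi) via mpmath; requires all cells >= 1."""
    a, b, c, d = mp.mpf(a), mp.mpf(b), mp.mpf(c), mp.mpf(d)
    ror = (a * d) / (b * c)
    half = mp.mpf(z) * mp.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return ror, mp.e ** (mp.log(ror) - half), mp.e ** (mp.log(ror) + half)


def bcpnn_oracle(
    a: int,
    b: int,
    c: int,
    d: int,
    alpha1: str = "1",
    beta1: str = "1",
    gamma11: str = "1",
    alpha: str = "2",
    beta: str = "2",
):
    """(E(IC), V(IC), IC-2SD) in bits via mpmath."""
    a_, b_, c_, d_ = (mp.mpf(v) for v in (a, b, c, d))
    n = a_ + b_ + c_ + d_
    a1, b1, g11 = mp.mpf(alpha1), mp.mpf(beta1), mp.mpf(gamma11)
    al, be = mp.mpf(alpha), mp.mpf(beta)
    row = a_ + b_ + a1
    col = a_ + c_ + b1
    gamma = g11 * (n + al) * (n + be) / (row * col)
    ic = mp.log((a_ + g11) * (n + al) * (n + be) / ((n + gamma) * row * col), 2)
    v = (1 / mp.log(2)) ** 2 * (
        (n - a_ + gamma - g11) / ((a_ + g11) * (1 + n + gamma))
        + (n - a_ - b_ + al - a1) / (row * (1 + n + al))
        + (n - a_ - c_ + be - b1) / (col * (1 + n + be))
    )
    return ic, v, ic - 2 * mp.sqrt(v)


def ic_asymptote(a: int, b: int, c: int, d: int):
    """The infinite-data information component log2(a*N/((a+b)(a+c)))."""
    a_, b_, c_, d_ = (mp.mpf(v) for v in (a, b, c, d))
    n = a_ + b_ + c_ + d_
    return mp.log(a_ * n / ((a_ + b_) * (a_ + c_)), 2)
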