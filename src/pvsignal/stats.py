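"""Disproportionality statistics: ROR with Wald CI, BCPNN information
component, and the dual-positivity signal rule.

Both statistics are computed from a report-level 2x2 contingency table

    =============  =========  ===========
                   event E    not E
    =============  =========  ===========
    drug D         a          b
    not D          c          d
    =============  =========  ===========

with N = a + b + c + d.

**Reporting odds ratio.**  ROR = (a*d)/(b*c), with the Wald 95% interval

    exp( ln ROR +/- z * sqrt(1/a + 1/b + 1/c + 1/d) ),  z = 1.96.

The interval is multiplicatively symmetric about the point estimate:
sqrt(ci_low * ci_high) == ROR.  When any cell is zero the estimate is
marked not estimable (no Haldane 0.5 continuity correction is applied);
a not-estimable ROR can never be positive.

**BCPNN information component.**  The Bayesian estimator of
IC = log2 p(D,E) / (p(D) p(E)) with the closed-form posterior moments of
Bate et al. (1998), Dirichlet/Beta priors with hyperparameters
alpha1 = beta1 = gamma11 = 1 and alpha = beta = 2:

    gamma = gamma11 * (N+alpha)(N+beta) / ((a+b+alpha1)(a+c+beta1))
    E(IC) = log2[ (a+gamma11)(N+alpha)(N+beta)
                  / ((N+gamma)(a+b+alpha1)(a+c+beta1)) ]
    V(IC) = (1/ln 2)^2 * [ (N-a+gamma-gamma11) / ((a+gamma11)(1+N+gamma))
                         + (N-a-b+alpha-alpha1) / ((a+b+alpha1)(1+N+alpha))
                         + (N-a-c+beta-beta1)  / ((a+c+beta1)(1+N+beta)) ]

IC-2SD = E(IC) - 2*sqrt(V(IC)) is the lower credibility bound.  The
prior smoothing handles zero cells, so no correction is needed.

**Signal rule.**  A pair is a suspicious signal only when both methods
are positive: ROR-positive means a >= 3 and ci_low > 1 (strict); BCPNN-
positive means IC-2SD > 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .model import ContingencyTable, SignalStats

_LN2_SQ_INV = 1.0 / math.log(2.0) ** 2


@dataclass(frozen=True)
class BcpnnHyperparams:
    """Prior constants of the BCPNN closed form.

    ``alpha1``/``beta1`` are the Beta prior parameters of the drug and
    event marginals, ``gamma11`` the joint-cell prior weight, and
    ``alpha``/``beta`` the corresponding prior totals.  The defaults are
    the standard choice for which E(IC) = 0 under exact independence of
    an empty database.
    """

    alpha1: float = 1.0
    beta1: float = 1.0
    gamma11: float = 1.0
    alpha: float = 2.0
    beta: float = 2.0

    def __post_init__(self) -> None:
        if min(self.alpha1, self.beta1, self.gamma11, self.alpha, self.beta) <= 0:
            raise ValueError("all BCPNN hyperparameters must be strictly positive")


def ror_with_ci(
    t: ContingencyTable, z: float = 1.96
) -> tuple[float, float, float] | None:
    """Reporting odds ratio with the Wald confidence interval.

    Returns ``(ror, ci_low, ci_high)``, or ``None`` when any cell is zero
    (the Wald estimate is then not estimable).
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    if min(a, b, c, d) == 0:
        return None
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    half = z * se
    log_ror = math.log(ror)
    return ror, math.exp(log_ror - half), math.exp(log_ror + half)


def bcpnn_ic(
    t: ContingencyTable, h: BcpnnHyperparams | None = None
) -> tuple[float, float, float]:
    """BCPNN posterior moments for one table.

    Returns ``(ic, v_ic, ic_2sd)`` where ``ic`` is E(IC) in bits,
    ``v_ic`` the posterior variance of IC, and ``ic_2sd`` the lower
    credibility bound E(IC) - 2*sqrt(V(IC)).  Zero cells are admissible.
    """
    if h is None:
        h = BcpnnHyperparams()
    a, b, c = t.a, t.b, t.c
    n = t.n
    if n < 1:
        raise ValueError("empty table: N must be >= 1")
    row = a + b + h.alpha1  # drug margin + prior
    col = a + c + h.beta1  # event margin + prior
    gamma = h.gamma11 * (n + h.alpha) * (n + h.beta) / (row * col)
    ic = math.log2((a + h.gamma11) * (n + h.alpha) * (n + h.beta) / ((n + gamma) * row * col))
    v_ic = _LN2_SQ_INV * (
        (n - a + gamma - h.gamma11) / ((a + h.gamma11) * (1 + n + gamma))
        + (n - a - b + h.alpha - h.alpha1) / (row * (1 + n + h.alpha))
        + (n - a - c + h.beta - h.beta1) / (col * (1 + n + h.beta))
    )
    return ic, v_ic, ic - 2.0 * math.sqrt(v_ic)


def classify_signal(
    ror_result: tuple[float, float, float] | None,
    bcpnn_result: tuple[float, float, float],
    a: int,
    min_cases: int = 3,
) -> SignalStats:
    """Apply the dual-positivity rule to one pair's statistics.

    ROR-positive requires at least ``min_cases`` co-reports and a lower
    Wald bound strictly above 1; a not-estimable ROR is never positive.
    BCPNN-positive requires IC-2SD strictly above 0.  The pair is a
    signal only when both are positive.
    """
    ic, _v_ic, ic_2sd = bcpnn_result
    if ror_result is None:
        ror = ci_low = ci_high = None
        ror_positive = False
    else:
        ror, ci_low, ci_high = ror_result
        ror_positive = a >= min_cases and ci_low > 1.0
    bcpnn_positive = ic_2sd > 0.0
    return SignalStats(
        ror=ror,
        ci_low=ci_low,
        ci_high=ci_high,
        ic=ic,
        ic_2sd=ic_2sd,
        ror_positive=ror_positive,
        bcpnn_positive=bcpnn_positive,
        signal=ror_positive and bcpnn_positive,
    )


def evaluate_table(
    t: ContingencyTable,
    h: BcpnnHyperparams | None = None,
    z: float = 1.96,
    min_cases: int = 3,
) -> SignalStats:
    """Convenience wrapper: ROR, BCPNN and classification in one call."""
    return classify_signal(ror_with_ci(t, z=z), bcpnn_ic(t, h), t.a, min_cases=min_cases)
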