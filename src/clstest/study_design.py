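"""Exact power and sample-size design for the CLS test.

For a one-sided exact binomial test of H0: p <= p0 against p > p0 at level
``alpha``, the critical value ``c`` is the smallest shared-mutation count
whose upper-tail null probability does not exceed ``alpha``; power against
an alternative rate ``pa`` is the exact upper tail at ``pa``.  Because the
critical value jumps as ``n`` grows, power is a sawtooth function of ``n``;
the design search therefore scans upward and returns the FIRST ``n``
meeting the target, which is the convention behind the published design
grid (e.g. p0=4%, pa=15% needs n=44 with c=5 for 80% power).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

from scipy.stats import binom as _binom

from .cls_test import binomial_upper_p
from .exceptions import SearchError, ValidationError

__all__ = ["DesignRow", "critical_value", "exact_power", "min_n_for_power", "design_table"]


@dataclass(frozen=True)
class DesignRow:
    """One design-grid row: required n and critical value for (p0, pa, alpha, power)."""

    p0: float
    pa: float
    alpha: float
    target_power: float
    n_required: int
    critical_value: int
    achieved_alpha: float
    achieved_power: float


def critical_value(n: int, p0: float, alpha: float) -> int:
    """Smallest integer c with P(X >= c | n, p0) <= alpha.

    Returns ``n + 1`` when even X = n fails to reach significance (no
    achievable rejection region at this n).
    """
    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n}")
    if not 0.0 < p0 < 1.0:
        raise ValidationError(f"p0 must lie in (0, 1), got {p0}")
    # isf gives the smallest k with P(X > k) <= alpha, so c <= k + 1;
    # step down while the tail at the lower c still fits under alpha.
    c = int(_binom.isf(alpha, n, p0)) + 1
    c = min(max(c, 0), n + 1)
    while c > 0 and binomial_upper_p(c - 1, n, p0) <= alpha:
        c -= 1
    while c <= n and binomial_upper_p(c, n, p0) > alpha:
        c += 1
    return c


def exact_power(n: int, c: int, pa: float) -> float:
    """Exact rejection probability P(X >= c | n, pa)."""
    if not 0 <= c <= n + 1:
        raise ValidationError(f"need 0 <= c <= n+1, got c={c}, n={n}")
    if c == 0:
        return 1.0
    if c > n:
        return 0.0
    return binomial_upper_p(c, n, pa)


def min_n_for_power(
    p0: float,
    pa: float,
    alpha: float = 0.05,
    target_power: float = 0.80,
    n_ceiling: int = 10**6,
) -> DesignRow:
    """Smallest n whose exact test (with its own critical value) reaches the target power.

    The scan confirms the first passing n; because of the sawtooth, larger n
    can momentarily dip back below the target, and the first-passing
    convention is the one the published design grid uses.
    """
    if not p0 < pa:
        raise ValidationError(f"need p0 < pa, got p0={p0}, pa={pa}")
    for n in range(1, n_ceiling + 1):
        c = critical_value(n, p0, alpha)
        if c > n:
            continue
        power = exact_power(n, c, pa)
        if power >= target_power:
            return DesignRow(
                p0=p0,
                pa=pa,
                alpha=alpha,
                target_power=target_power,
                n_required=n,
                critical_value=c,
                achieved_alpha=binomial_upper_p(c, n, p0),
                achieved_power=power,
            )
    raise SearchError(
        f"no n <= {n_ceiling} reaches power {target_power} for p0={p0}, pa={pa}, alpha={alpha}"
    )


def design_table(
    p0_list: Sequence[float] | Iterable[float],
    pa_list: Sequence[float] | Iterable[float],
    alpha: float = 0.05,
    target_power: float = 0.80,
) -> list[DesignRow]:
    """Design rows for the Cartesian grid of p0 and pa values, in input order."""
    p0_list, pa_list = list(p0_list), list(pa_list)
    if not p0_list or not pa_list:
        raise ValidationError("p0_list and pa_list must be non-empty")
    return [
        min_n_for_power(p0, pa, alpha, target_power)
        for p0, pa in itertools.product(p0_list, pa_list)
    ]
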