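"""Exact expected barrier-ascent times for the distinct-arc birth-death chain.

States 0..k count how many of the k band arcs have been removed.  From state
i the chain re-adds an arc with probability p_{i,i-1} = i*a^2/(i*a^2 + k - i)
(a = alpha) and removes one with probability p_{i,i+1} = (k-i)/(i*a^2 + k-i).
The expected hitting time T_i of state k satisfies the standard linear system

    T_k = 0,    T_i = 1 + p_{i,i-1} T_{i-1} + p_{i,i+1} T_{i+1},

whose minimal non-negative solution is the vector of mean hitting times.
Three independent routes to T_0 are implemented:

* a forward recurrence on d_i = T_{i-1} - T_i - 1, using
  d_1 = 0 and d_{i+1} = s_i (d_i + 2) with s_i = i*a^2/(k-i),
  so that T_0 = k + sum_j d_j;
* the closed form d_j = 2 * sum_{i=1}^{j-1} ((j-1)_i / (k-j+i)_i) * a^{2i}
  (falling factorials), with d_k = 2(a^2+1)^{k-1} - 2 by the binomial theorem;
* a dedicated tridiagonal elimination of the linear system.

The expected ascent time is bracketed by

    2(a^2+1)^{k-1} - 2 + k  <=  T_0  <=  2k(a^2+1)^{k-1} - k .
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

__all__ = ["HittingTimeResult", "hitting_time_recurrence",
           "hitting_time_linear_system", "ascent_time_bounds", "d_closed_form"]


@dataclass(frozen=True)
class HittingTimeResult:
    k: int
    alpha: float
    T: tuple  # T_0 .. T_k, T_k = 0
    d: tuple  # d_1 .. d_k, d_1 = 0
    bounds: tuple  # (lower, upper) bracketing T_0

    @property
    def T0(self):
        return self.T[0]


def _check(k: int, alpha: float) -> None:
    if k < 1:
        raise ValueError("k must be >= 1")
    if not alpha > 1:
        raise ValueError("alpha must be > 1")


def hitting_time_recurrence(k: int, alpha: float,
                            exact: bool = False) -> HittingTimeResult:
    """T_0..T_k via the d-recurrence; exact rationals when ``exact=True``."""
    _check(k, alpha)
    a2 = Fraction(alpha) ** 2 if exact else float(alpha) ** 2
    one = Fraction(1) if exact else 1.0
    d = [0 * one]  # d_1 = 0
    for i in range(1, k):
        s_i = i * a2 / (k - i)
        d.append(s_i * (d[-1] + 2))
    # T_i from the telescoping T_{i-1} - T_i = d_i + 1, T_k = 0
    T = [0 * one]
    for i in range(k, 0, -1):
        T.append(T[-1] + d[i - 1] + 1)
    T.reverse()
    lo, hi = ascent_time_bounds(k, alpha, exact=exact)
    return HittingTimeResult(k, float(alpha), tuple(T), tuple(d), (lo, hi))


def d_closed_form(k: int, j: int, alpha: float, exact: bool = False):
    """d_j as the explicit falling-factorial sum."""
    _check(k, alpha)
    if not 1 <= j <= k:
        raise ValueError(f"j must be in 1..{k}")
    a2 = Fraction(alpha) ** 2 if exact else float(alpha) ** 2
    total = Fraction(0) if exact else 0.0

    def falling(n: int, i: int) -> int:
        out = 1
        for t in range(i):
            out *= n - t
        return out

    for i in range(1, j):
        total += Fraction(falling(j - 1, i), falling(k - j + i, i)) * a2 ** i \
            if exact else falling(j - 1, i) / falling(k - j + i, i) * a2 ** i
    return 2 * total


def hitting_time_linear_system(k: int, alpha: float, exact: bool = True):
    """T_0 by tridiagonal (Thomas) elimination of the hitting-time system.

    Unknowns T_0..T_{k-1} (T_k = 0):  T_0 - T_1 = 1  and, for 0 < i < k,
    -p_down T_{i-1} + T_i - p_up T_{i+1} = 1.

    The elimination is carried out in exact rational arithmetic by default
    (a float ``alpha`` converts exactly): the system's condition number
    grows like T_0 itself — about (a^2+1)^{k-1} — so beyond k ~ 10 no
    floating-point solve, however organised, can stay near machine accuracy.
    ``exact=False`` runs the same sweep in doubles, for timing comparisons.
    """
    _check(k, alpha)
    one = Fraction(1) if exact else 1.0
    a2 = (Fraction(alpha) if exact else float(alpha)) ** 2
    n = k  # unknowns T_0 .. T_{k-1}
    sub = [0 * one] * n   # coefficient of T_{i-1}
    diag = [one] * n
    sup = [0 * one] * n   # coefficient of T_{i+1}
    rhs = [one] * n
    sup[0] = -one  # T_0 - T_1 = 1 (p_{0,1} = 1)
    for i in range(1, n):
        denom = i * a2 + (k - i)
        sub[i] = -(i * a2) / denom
        if i + 1 < n:
            sup[i] = -(k - i) / denom
        # else T_{i+1} = T_k = 0 drops out
    # forward sweep
    for i in range(1, n):
        m = sub[i] / diag[i - 1]
        diag[i] = diag[i] - m * sup[i - 1]
        rhs[i] = rhs[i] - m * rhs[i - 1]
    # back substitution
    T = [0 * one] * n
    T[n - 1] = rhs[n - 1] / diag[n - 1]
    for i in range(n - 2, -1, -1):
        T[i] = (rhs[i] - sup[i] * T[i + 1]) / diag[i]
    return float(T[0]) if not exact else T[0]


def ascent_time_bounds(k: int, alpha: float, exact: bool = False):
    """(lower, upper) = (2(a^2+1)^{k-1} - 2 + k,  2k(a^2+1)^{k-1} - k)."""
    _check(k, alpha)
    a2 = Fraction(alpha) ** 2 if exact else float(alpha) ** 2
    g = (a2 + 1) ** (k - 1)
    return 2 * g - 2 + k, 2 * k * g - k
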