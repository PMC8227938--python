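"""Sigmoid melting-curve link function and melting-temperature transform.

A protein's thermal denaturation is summarised by the fold change of
soluble protein as temperature rises: it starts near 1 at the lowest
measured temperature and decays sigmoidally toward a lower plateau ``L``.
The curve used throughout this package is

    f(L, a, b, T) = (1 - L) / (1 + exp(b - a / T)) + L

with steepness-scale ``a`` (°C) and offset ``b`` (dimensionless), both
positive so that f is strictly decreasing in T.  The melting temperature
is the midpoint of the transition, Tm = a / b, where f = (1 + L) / 2.
Temperatures are in °C everywhere; no Kelvin conversion is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

__all__ = ["CurveParams", "melting_curve", "tm"]


@dataclass(frozen=True)
class CurveParams:
    """Parameters of a single melting curve.

    Attributes
    ----------
    L : float
        Lower plateau of the fold-change curve, in [0, 1).
    a : float
        Steepness-scale parameter, units °C (enters as a/T). Must be > 0.
    b : float
        Dimensionless offset parameter. Must be > 0.
    """

    L: float
    a: float
    b: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.L < 1.0):
            raise ValueError(f"L must lie in [0, 1); got L={self.L}")
        if not self.a > 0:
            raise ValueError(f"a must be positive; got a={self.a}")
        if not self.b > 0:
            raise ValueError(f"b must be positive; got b={self.b}")

    @property
    def tm(self) -> float:
        """Melting temperature Tm = a / b (°C)."""
        return self.a / self.b


def melting_curve(params: CurveParams | None = None, T=None, *, L=None, a=None, b=None):
    """Evaluate the melting curve at temperature(s) ``T``.

    Accepts either a :class:`CurveParams` or explicit ``L``, ``a``, ``b``
    keywords (arrays allowed, broadcast against ``T``).  Returns values
    strictly between ``L`` and 1, strictly decreasing in ``T``, with
    f(a/b) = (1 + L) / 2 exactly.

    Raises
    ------
    ValueError
        If any temperature, ``a`` or ``b`` is non-positive.
    """
    if params is not None:
        L, a, b = params.L, params.a, params.b
    L = np.asarray(L, dtype=float)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise ValueError("T must be positive (°C scale)")
    if np.any(a <= 0):
        raise ValueError("a must be positive")
    if np.any(b <= 0):
        raise ValueError("b must be positive")
    # f = L + (1-L) * sigmoid(a/T - b)
    val = L + (1.0 - L) * expit(a / T - b)
    if val.ndim == 0:
        return float(val)
    return val


def tm(a, b):
    """Melting temperature Tm = a / b (°C), the midpoint of the transition."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.any(b == 0):
        raise ValueError("b must be nonzero")
    out = a / b
    if out.ndim == 0:
        return float(out)
    return out
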