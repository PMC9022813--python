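"""Melting-curve container and melting-temperature extraction."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy.optimize import brentq

from .constants import T_ZERO_C


class NoMeltingTransitionError(ValueError):
    """The bound fraction does not cross 1/2 inside the temperature span."""


@dataclass
class MeltingCurve:
    """A bound fraction theta evaluated on a temperature grid.

    ``T`` is in kelvin and ``theta`` in [0, 1], non-increasing in T for
    equilibrium duplex melting.  ``theta_fn`` is the continuous model the grid
    was sampled from; melting temperatures are extracted by root finding on it
    rather than by grid interpolation.  ``theta_lo``/``theta_hi`` optionally
    carry an uncertainty band.
    """

    T: np.ndarray
    theta: np.ndarray
    theta_fn: Optional[Callable[[float], float]] = None
    theta_lo: Optional[np.ndarray] = None
    theta_hi: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        if self.T.shape != self.theta.shape:
            raise ValueError("T and theta grids must have the same shape")

    @property
    def T_celsius(self) -> np.ndarray:
        return self.T - T_ZERO_C

    @property
    def tm(self) -> float:
        """Melting temperature in kelvin (theta = 1/2)."""
        return melting_temperature(self)

    def _continuous(self) -> Callable[[float], float]:
        if self.theta_fn is not None:
            return self.theta_fn
        # Fall back on monotone interpolation of the sampled grid.
        T, th = self.T, self.theta
        return lambda t: float(np.interp(t, T, th))


def melting_temperature(curve: MeltingCurve, tol_c: float = 0.01) -> float:
    """Root of theta(T) - 1/2 by bisection on the continuous model.

    Raises :class:`NoMeltingTransitionError` when theta does not cross 1/2
    inside the grid span, naming the bracketing values.
    """
    fn = curve._continuous()
    lo, hi = float(curve.T.min()), float(curve.T.max())
    f_lo, f_hi = fn(lo) - 0.5, fn(hi) - 0.5
    if f_lo * f_hi > 0:
        raise NoMeltingTransitionError(
            f"theta does not cross 1/2 in [{lo:.2f} K, {hi:.2f} K]: "
            f"theta({lo:.2f}) = {f_lo + 0.5:.4f}, theta({hi:.2f}) = {f_hi + 0.5:.4f}"
        )
    return float(brentq(lambda t: fn(t) - 0.5, lo, hi, xtol=tol_c))
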