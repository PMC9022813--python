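"""Contact-quenching observable: a tagged complementary pair amid the pool.

A pair of mutually complementary, fluorophore-tagged strands A*/B* is added
at concentration c_fluo each to a random-sequence pool.  The stoichiometric
ratio phi = c_fluo / (c_pool / n_b^L) measures the tagged strands' excess
over their untagged twins.  The fraction of A* bound specifically to B* is

    theta_AB = phi zeta_AB / (phi zeta_AB + sum_alpha g zeta) * theta_e_CQ,

with theta_e_CQ the total bound fraction of the tagged strands, whose
pool-sum is enriched by the phi zeta_AB term.  In the phi -> infinity limit
this reduces to the two-state melting of the isolated pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .alphabet import InvalidInputError, is_complementary_pair
from .constants import R_KCAL, mass_to_molar
from .curves import MeltingCurve
from .defects import defect_energy_arrays
from .melting import SolutionSpec, _at_salt, _theta_from_log_sum
from .thermo import (
    FreeEnergy,
    ThermoParams,
    default_params,
    default_t_grid,
    nn_free_energy_pair,
    two_state_theta,
)


@dataclass(frozen=True)
class CQSpec:
    """Tagged pair + pool for a contact-quenching calculation.

    ``dg_ab_offset`` is an additive (dH, dS) increment on the NN free energy
    of the tagged duplex — the terminal fluorophore stabilization — applied
    on top of the salt-aware NN value.  ``dg_ab_override`` replaces the NN
    energy outright (expert use; it does not track salt).
    ``dg_ab_uncertainty`` is a symmetric band (kcal/mol) on the tagged-duplex
    dG propagated to the predicted curves.
    """

    seq_a: str
    seq_b: str
    c_fluo: float
    pool: SolutionSpec
    dg_ab_offset: Optional[FreeEnergy] = None
    dg_ab_override: Optional[FreeEnergy] = None
    dg_ab_uncertainty: float = 0.0

    def __post_init__(self) -> None:
        if self.c_fluo <= 0:
            raise InvalidInputError("c_fluo must be positive")
        if len(self.seq_a) != self.pool.L:
            raise InvalidInputError("tagged strands must have the pool length")
        if not is_complementary_pair(self.seq_a, self.seq_b, self.pool.alphabet):
            raise InvalidInputError("seq_b must be the reverse-complement of seq_a")

    @property
    def phi(self) -> float:
        """Stoichiometric ratio of tagged strand to its untagged pool twin."""
        return self.c_fluo / (self.pool.c_molar / self.pool.n_species)

    def dg_ab(self, params: ThermoParams) -> FreeEnergy:
        if self.dg_ab_override is not None:
            return self.dg_ab_override
        fe = nn_free_energy_pair(self.seq_a, self.seq_b, params, self.pool.alphabet)
        if self.dg_ab_offset is not None:
            fe = fe + self.dg_ab_offset
        return fe


def stoichiometric_ratio(c_fluo: float, c_mass: float, L: int) -> float:
    """phi = c_fluo / (c_pool_molar / 4^L) for a natural-DNA pool."""
    if c_fluo <= 0 or c_mass <= 0:
        raise InvalidInputError("concentrations must be positive")
    return c_fluo / (mass_to_molar(c_mass, L) / 4.0**L)


def _cq_logs(cq: CQSpec, T: float, params: ThermoParams, dg_shift: float = 0.0):
    """(log phi*zeta_AB, log pool sum) at one temperature."""
    spec = cq.pool
    f_cg = spec.alphabet.f_cg(cq.seq_a) if spec.alphabet.strong else 0.5
    _, _, log_g, dH, dS = defect_energy_arrays(spec.L, f_cg, params, spec.alphabet)
    dG = dH - T * dS / 1000.0
    log_pool = float(logsumexp(log_g + math.log(spec.c_molar) - dG / (R_KCAL * T)))
    dg_ab = cq.dg_ab(params).dG(T) + dg_shift
    log_ab = math.log(cq.phi) + math.log(spec.c_molar) - dg_ab / (R_KCAL * T)
    return log_ab, log_pool


def theta_e_cq(
    cq: CQSpec,
    T_grid: Optional[np.ndarray] = None,
    params: Optional[ThermoParams] = None,
) -> MeltingCurve:
    """Total bound fraction of the tagged strands (to B* or to any pool strand)."""
    if params is None:
        params = default_params()
    params = _at_salt(params, cq.pool.na_molar)
    if T_grid is None:
        T_grid = default_t_grid()

    def theta_fn(T: float) -> float:
        log_ab, log_pool = _cq_logs(cq, T, params)
        return _theta_from_log_sum(cq.pool, float(np.logaddexp(log_ab, log_pool)))

    T_grid = np.asarray(T_grid, dtype=float)
    return MeltingCurve(T=T_grid, theta=np.array([theta_fn(T) for T in T_grid]),
                        theta_fn=theta_fn)


def theta_ab(
    cq: CQSpec,
    T_grid: Optional[np.ndarray] = None,
    params: Optional[ThermoParams] = None,
) -> MeltingCurve:
    """Fraction of tagged strands paired specifically with their complement.

    When ``cq.dg_ab_uncertainty`` is nonzero the returned curve carries the
    corresponding theta band (``theta_lo``/``theta_hi``).
    """
    if params is None:
        params = default_params()
    params = _at_salt(params, cq.pool.na_molar)
    if T_grid is None:
        T_grid = default_t_grid()

    def theta_at(T: float, dg_shift: float) -> float:
        log_ab, log_pool = _cq_logs(cq, T, params, dg_shift)
        total = float(np.logaddexp(log_ab, log_pool))
        share = math.exp(log_ab - total)
        return share * _theta_from_log_sum(cq.pool, total)

    def theta_fn(T: float) -> float:
        return theta_at(T, 0.0)

    T_grid = np.asarray(T_grid, dtype=float)
    theta = np.array([theta_fn(T) for T in T_grid])
    lo = hi = None
    u = cq.dg_ab_uncertainty
    if u > 0:
        lo = np.array([theta_at(T, +u) for T in T_grid])
        hi = np.array([theta_at(T, -u) for T in T_grid])
    return MeltingCurve(T=T_grid, theta=theta, theta_fn=theta_fn,
                        theta_lo=lo, theta_hi=hi)


def pair_reference_curve(cq: CQSpec, T_grid: np.ndarray,
                         params: Optional[ThermoParams] = None) -> MeltingCurve:
    """Two-state curve of the isolated tagged pair at c_fluo each, using the
    same (possibly overridden) tagged-duplex free energy."""
    if params is None:
        params = default_params()
    params = _at_salt(params, cq.pool.na_molar)
    fe = cq.dg_ab(params)
    T_grid = np.asarray(T_grid, dtype=float)

    def theta_fn(T: float) -> float:
        log_4kc = math.log(4.0 * cq.c_fluo) - fe.dG(T) / (R_KCAL * T)
        return float(two_state_theta(np.array([log_4kc]))[0])

    return MeltingCurve(T=T_grid, theta=np.array([theta_fn(T) for T in T_grid]),
                        theta_fn=theta_fn)


@dataclass
class SaltSensitivity:
    """theta_AB(phi) evaluated at several ionic strengths and one temperature."""

    T: float
    phi_grid: np.ndarray
    salts: tuple[float, ...]
    theta: np.ndarray  # shape (n_salts, n_phi)
    band: np.ndarray   # uncertainty half-width per (salt, phi); zeros if no band

    @property
    def max_abs_diff(self) -> float:
        """Largest spread of theta_AB across salts anywhere on the phi grid."""
        return float(np.max(self.theta.max(axis=0) - self.theta.min(axis=0)))

    def to_dataframe(self) -> pd.DataFrame:
        frames = []
        for i, na in enumerate(self.salts):
            frames.append(pd.DataFrame({
                "phi": self.phi_grid, "na_molar": na,
                "theta_ab": self.theta[i], "band": self.band[i],
            }))
        return pd.concat(frames, ignore_index=True)


def salt_sensitivity_ab(
    cq: CQSpec,
    T: float,
    salts: Sequence[float],
    phi_grid: Optional[np.ndarray] = None,
    params: Optional[ThermoParams] = None,
) -> SaltSensitivity:
    """theta_AB as a function of phi at each ionic strength, at fixed T.

    phi is varied the way the experiment varies it: by changing the pool
    concentration at fixed c_fluo.
    """
    import dataclasses

    if params is None:
        params = default_params()
    if phi_grid is None:
        phi_grid = np.logspace(-2, 2, 25)
    phi_grid = np.asarray(phi_grid, dtype=float)
    theta = np.zeros((len(salts), len(phi_grid)))
    band = np.zeros_like(theta)
    for i, na in enumerate(salts):
        for j, phi in enumerate(phi_grid):
            c_molar = cq.c_fluo * cq.pool.n_species / phi
            pool = SolutionSpec.from_molar(cq.pool.L, c_molar, na_molar=na,
                                           alphabet=cq.pool.alphabet)
            cq_ij = dataclasses.replace(cq, pool=pool)
            curve = theta_ab(cq_ij, np.array([T]), params)
            theta[i, j] = curve.theta[0]
            if curve.theta_lo is not None:
                band[i, j] = 0.5 * float(curve.theta_hi[0] - curve.theta_lo[0])
    return SaltSensitivity(T=T, phi_grid=phi_grid, salts=tuple(salts),
                           theta=theta, band=band)
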