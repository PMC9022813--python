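"""Pool-level melting curves of random-sequence oligomer solutions.

A random-sequence pool of length L contains all n_b^L species at equal
concentration.  The bound fraction of the composition class f_CG is

    theta_fcg = 1 - 2 / (1 + sqrt(1 + (4 / n_b^L) * sum_alpha g(L, alpha) *
                zeta_fcg(alpha))),

the same algebraic form as the melting of a self-complementary solution,
with the class-resolved statistical weights g * zeta replacing the single
pairing weight.  The ensemble curve averages the composition classes with
binomial weights p_L(f_CG) = C(L, f_CG L) / 2^L.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import logsumexp

from .alphabet import DNA4, AlphabetSpec, InvalidInputError, random_sequence
from .constants import R_KCAL, mass_to_molar, molar_to_mass
from .curves import MeltingCurve, melting_temperature  # noqa: F401  (re-export)
from .defects import classify_alignment, defect_energy_arrays
from .thermo import ThermoParams, default_params, default_t_grid, two_state_theta


@dataclass(frozen=True)
class SolutionSpec:
    """A random-sequence pool: length, total strand concentration, salt.

    ``c_mass`` is the total strand mass concentration in g/l; the molar
    concentration follows from the average single-strand molecular weight
    MW(L) = 303.7 L + 79 g/mol.
    """

    L: int
    c_mass: float
    na_molar: float = 1.0
    alphabet: AlphabetSpec = DNA4

    def __post_init__(self) -> None:
        if self.L < 2:
            raise InvalidInputError("L must be >= 2")
        if self.c_mass <= 0 or self.na_molar <= 0:
            raise InvalidInputError("concentrations must be positive")

    @classmethod
    def from_molar(cls, L: int, c_molar: float, na_molar: float = 1.0,
                   alphabet: AlphabetSpec = DNA4) -> "SolutionSpec":
        return cls(L=L, c_mass=molar_to_mass(c_molar, L), na_molar=na_molar,
                   alphabet=alphabet)

    @property
    def c_molar(self) -> float:
        return mass_to_molar(self.c_mass, self.L)

    @property
    def n_species(self) -> float:
        return float(self.alphabet.n_b) ** self.L


def composition_weights(L: int) -> np.ndarray:
    """Binomial probabilities p_L of the L + 1 strong-base composition
    classes f_CG = k / L; they sum to 1 exactly."""
    return np.array([math.comb(L, k) for k in range(L + 1)]) / 2.0**L


def _check_f_cg(L: int, f_cg: float) -> float:
    k = f_cg * L
    if abs(k - round(k)) > 1e-9:
        raise InvalidInputError(
            f"f_cg * L must be an integer number of strong bases, got {f_cg} * {L}"
        )
    if not 0 <= round(k) <= L:
        raise InvalidInputError("f_cg must lie in [0, 1]")
    return round(k) / L


def _log_pool_sum(spec: SolutionSpec, f_cg: float, T: float,
                  params: ThermoParams) -> float:
    """log of sum_alpha g * zeta at one temperature for one composition."""
    _, _, log_g, dH, dS = defect_energy_arrays(spec.L, f_cg, params, spec.alphabet)
    dG = dH - T * dS / 1000.0
    return float(logsumexp(log_g + math.log(spec.c_molar) - dG / (R_KCAL * T)))


def _theta_from_log_sum(spec: SolutionSpec, log_sum: float) -> float:
    log_x = math.log(4.0) - spec.L * math.log(spec.alphabet.n_b) + log_sum
    return float(two_state_theta(np.array([log_x]))[0])


def theta_fcg(
    spec: SolutionSpec,
    f_cg: float,
    T_grid: Optional[np.ndarray] = None,
    params: Optional[ThermoParams] = None,
) -> MeltingCurve:
    """Melting curve of the composition class f_CG of the pool."""
    if params is None:
        params = default_params()
    params = _at_salt(params, spec.na_molar)
    f_cg = _check_f_cg(spec.L, f_cg)
    if T_grid is None:
        T_grid = default_t_grid()

    def theta_fn(T: float) -> float:
        return _theta_from_log_sum(spec, _log_pool_sum(spec, f_cg, T, params))

    T_grid = np.asarray(T_grid, dtype=float)
    theta = np.array([theta_fn(T) for T in T_grid])
    return MeltingCurve(T=T_grid, theta=theta, theta_fn=theta_fn)


def theta_ensemble(
    spec: SolutionSpec,
    T_grid: Optional[np.ndarray] = None,
    params: Optional[ThermoParams] = None,
) -> MeltingCurve:
    """Ensemble melting curve: binomial composition average of theta_fcg."""
    if params is None:
        params = default_params()
    params = _at_salt(params, spec.na_molar)
    if T_grid is None:
        T_grid = default_t_grid()
    p = composition_weights(spec.L)

    def theta_fn(T: float) -> float:
        acc = 0.0
        for k in range(spec.L + 1):
            acc += p[k] * _theta_from_log_sum(
                spec, _log_pool_sum(spec, k / spec.L, T, params)
            )
        return acc

    T_grid = np.asarray(T_grid, dtype=float)
    theta = np.array([theta_fn(T) for T in T_grid])
    return MeltingCurve(T=T_grid, theta=theta, theta_fn=theta_fn)


def theta_sequence_oracle(
    ref_seq: str,
    spec: SolutionSpec,
    T_grid: Optional[np.ndarray] = None,
    params: Optional[ThermoParams] = None,
    mode: str = "exhaustive",
    n_samples: Optional[int] = None,
    seed: Optional[int] = None,
) -> MeltingCurve:
    """Melting curve of one reference sequence amid all pool partners.

    Evaluates the per-sequence double sum over every partner j and every
    mutual shift, each (partner, shift) contributing the Boltzmann weight of
    its alpha-classified parametrized energy.  ``exhaustive`` enumerates all
    n_b^L partners (L <= 6); ``sampled`` draws ``n_samples`` partners
    uniformly and rescales the partner sum by n_b^L / n_samples.
    """
    if params is None:
        params = default_params()
    params = _at_salt(params, spec.na_molar)
    alphabet = spec.alphabet
    L = spec.L
    if len(ref_seq) != L:
        raise InvalidInputError("reference length must equal spec.L")
    if T_grid is None:
        T_grid = default_t_grid()
    f_cg = alphabet.f_cg(ref_seq) if alphabet.strong else 0.5

    if mode == "exhaustive":
        if L > 6:
            raise InvalidInputError(
                "exhaustive partner enumeration is limited to L <= 6 "
                f"(n_b^L = {alphabet.n_b ** L} partners); use mode='sampled'"
            )
        partners = _all_sequences(L, alphabet)
        rescale = 1.0
    elif mode == "sampled":
        if not n_samples or n_samples < 1:
            raise InvalidInputError("sampled mode needs n_samples >= 1")
        rng = np.random.default_rng(seed)
        partners = [random_sequence(rng, L, alphabet) for _ in range(n_samples)]
        rescale = alphabet.n_b ** L / n_samples
    else:
        raise InvalidInputError(f"unknown mode {mode!r}")

    # Tally (partner, shift) alignments into defect classes, then reuse the
    # vectorized class energetics.
    counts: dict = {}
    for partner in partners:
        for shift in range(-(L - 1), L):
            alpha = classify_alignment(ref_seq, partner, shift, alphabet)
            if alpha is not None:
                counts[alpha] = counts.get(alpha, 0) + 1
    alphas, _, _, dH_all, dS_all = defect_energy_arrays(L, f_cg, params, alphabet)
    index = {a: k for k, a in enumerate(alphas)}
    rows = np.array([index[a] for a in counts])
    mult = np.array([counts[a] for a in counts], dtype=float) * rescale
    dH = dH_all[rows]
    dS = dS_all[rows]

    def theta_fn(T: float) -> float:
        dG = dH - T * dS / 1000.0
        log_sum = float(
            logsumexp(np.log(mult) + math.log(spec.c_molar) - dG / (R_KCAL * T))
        )
        return _theta_from_log_sum(spec, log_sum)

    T_grid = np.asarray(T_grid, dtype=float)
    theta = np.array([theta_fn(T) for T in T_grid])
    return MeltingCurve(T=T_grid, theta=theta, theta_fn=theta_fn)


def _all_sequences(L: int, alphabet: AlphabetSpec) -> list[str]:
    seqs = [""]
    for _ in range(L):
        seqs = [s + b for s in seqs for b in alphabet.bases]
    return seqs


def _at_salt(params: ThermoParams, na_molar: float) -> ThermoParams:
    return params if params.na_molar == na_molar else params.with_na(na_molar)
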