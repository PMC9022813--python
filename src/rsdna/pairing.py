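"""Defect-class pairing statistics and counterfactual alphabets.

theta_alpha is the fraction of all pool strands engaged in duplexes of
quality alpha at a given temperature: the class share g * zeta / sum(g' *
zeta') of the bound fraction, averaged over composition classes with the
binomial weights.  Summing over classes with equal total defect count
|alpha| gives the error-count distribution; the counterfactuals recompute
theta_0 under modified base alphabets or pairing energetics.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .alphabet import DNA4, AlphabetSpec, InvalidInputError, n_base_alphabet
from .constants import R_KCAL
from .curves import MeltingCurve
from .defects import PERFECT, DefectVector, defect_energy_arrays, enumerate_defects
from .melting import SolutionSpec, _at_salt, _theta_from_log_sum, composition_weights
from .thermo import ThermoParams, default_params, default_t_grid


@dataclass
class DefectDistribution:
    """theta_alpha over every defect class at one temperature."""

    spec: SolutionSpec
    T: float
    alphas: tuple[DefectVector, ...]
    theta: np.ndarray
    theta_e: float

    @property
    def at_T(self) -> dict[DefectVector, float]:
        return dict(zip(self.alphas, self.theta))

    @property
    def theta_perfect(self) -> float:
        """theta_0: fraction of strands in defectless duplexes."""
        return float(self.theta[self.alphas.index(PERFECT)])

    @property
    def by_total(self) -> dict[int, float]:
        return total_error_fractions(self)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "alpha_s": [a.alpha_s for a in self.alphas],
                "alpha_e1": [a.alpha_e1 for a in self.alphas],
                "alpha_e2": [a.alpha_e2 for a in self.alphas],
                "alpha_i": [a.alpha_i for a in self.alphas],
                "total": [a.total for a in self.alphas],
                "theta": self.theta,
            }
        )


def defect_fractions_fcg(
    spec: SolutionSpec,
    f_cg: float,
    T: float,
    params: Optional[ThermoParams] = None,
) -> DefectDistribution:
    """Per-class bound fractions for one composition class f_CG."""
    if params is None:
        params = default_params()
    params = _at_salt(params, spec.na_molar)
    if spec.alphabet.avg_stack is None:
        k = f_cg * spec.L
        if abs(k - round(k)) > 1e-9:
            raise InvalidInputError("f_cg * L must be an integer count of strong bases")
    alphas, _, log_g, dH, dS = defect_energy_arrays(spec.L, f_cg, params, spec.alphabet)
    dG = dH - T * dS / 1000.0
    log_w = log_g + math.log(spec.c_molar) - dG / (R_KCAL * T)
    log_sum = float(logsumexp(log_w))
    theta_e = _theta_from_log_sum(spec, log_sum)
    share = np.exp(log_w - log_sum)
    return DefectDistribution(
        spec=spec, T=T, alphas=alphas, theta=share * theta_e, theta_e=theta_e
    )


def defect_fractions_ensemble(
    spec: SolutionSpec,
    T: float,
    params: Optional[ThermoParams] = None,
) -> DefectDistribution:
    """Composition-averaged per-class bound fractions (binomial weights)."""
    if params is None:
        params = default_params()
    p = composition_weights(spec.L)
    theta = None
    theta_e = 0.0
    alphas = enumerate_defects(spec.L)
    for k in range(spec.L + 1):
        d = defect_fractions_fcg(spec, k / spec.L, T, params)
        contrib = p[k] * d.theta
        theta = contrib if theta is None else theta + contrib
        theta_e += p[k] * d.theta_e
    return DefectDistribution(spec=spec, T=T, alphas=alphas, theta=theta,
                              theta_e=theta_e)


def total_error_fractions(dist: DefectDistribution) -> dict[int, float]:
    """theta_|alpha|: bound fractions aggregated by total defect count."""
    out: dict[int, float] = {}
    for a, th in zip(dist.alphas, dist.theta):
        out[a.total] = out.get(a.total, 0.0) + th
    return dict(sorted(out.items()))


def rank_motifs(dist: DefectDistribution, k: int) -> list[tuple[DefectVector, float]]:
    """Top-k defect classes by bound fraction (ties: lexicographic alpha)."""
    if k < 1:
        raise InvalidInputError("k must be >= 1")
    order = sorted(
        zip(dist.alphas, dist.theta), key=lambda it: (-it[1], it[0].astuple())
    )
    return [(a, float(t)) for a, t in order[:k]]


# ---------------------------------------------------------------------------
# Counterfactual alphabets


def all_cg_alphabet(params: Optional[ThermoParams] = None) -> AlphabetSpec:
    """Four-letter alphabet whose every stack takes the CG-quartet average."""
    if params is None:
        params = default_params()
    st = params.stack_average_over("CG")
    return dataclasses.replace(
        DNA4,
        avg_stack=(st.dH, st.dS),
        avg_init_per_end=(params.init_strong.dH, params.init_strong.dS),
    )


def intermediate_two_base_alphabet(
    params: Optional[ThermoParams] = None,
) -> AlphabetSpec:
    """Two-letter complementary alphabet with stack energetics intermediate
    between the AT-average and the CG-average (arithmetic mean)."""
    if params is None:
        params = default_params()
    at = params.stack_average_over("AT")
    cg = params.stack_average_over("CG")
    init = 0.5 * (params.init_strong + params.init_weak)
    base = n_base_alphabet(2)
    return dataclasses.replace(
        base,
        avg_stack=(0.5 * (at.dH + cg.dH), 0.5 * (at.dS + cg.dS)),
        avg_init_per_end=(init.dH, init.dS),
    )


def uniform_n_base_alphabet(
    n_b: int, params: Optional[ThermoParams] = None
) -> AlphabetSpec:
    """n_b-letter WC-type alphabet with the natural-DNA uniform average
    stack energetics (the f_CG = 1/2 expectation)."""
    if params is None:
        params = default_params()
    st = params.stack_average_over("ACGT")
    init = 0.5 * (params.init_strong + params.init_weak)
    base = n_base_alphabet(n_b)
    return dataclasses.replace(
        base,
        avg_stack=(st.dH, st.dS),
        avg_init_per_end=(init.dH, init.dS),
    )


def counterfactual_theta_perfect(
    spec: SolutionSpec,
    T_grid: Optional[np.ndarray] = None,
    variant: Union[str, int] = "all_CG",
    params: Optional[ThermoParams] = None,
) -> MeltingCurve:
    """theta_0(T) under a modified alphabet or pairing energetics.

    ``variant`` is ``"all_CG"`` (every stack energy set to the CG average,
    natural n_b = 4 degeneracies) or an even integer n_b (generalized
    alphabet; n_b = 2 uses stack energetics intermediate between the AT and
    CG averages, n_b >= 4 the natural uniform average).
    """
    if params is None:
        params = default_params()
    if T_grid is None:
        T_grid = default_t_grid()
    if variant == "all_CG":
        alphabet = all_cg_alphabet(params)
    elif isinstance(variant, int):
        alphabet = (
            intermediate_two_base_alphabet(params)
            if variant == 2
            else uniform_n_base_alphabet(variant, params)
        )
    else:
        raise InvalidInputError(f"unknown counterfactual variant {variant!r}")
    cf_spec = dataclasses.replace(spec, alphabet=alphabet)

    # Averaged energetics carry no composition dependence, so a single
    # composition class represents the whole pool.
    def theta0_fn(T: float) -> float:
        d = defect_fractions_fcg(cf_spec, 0.5 if cf_spec.L % 2 == 0 else 0.0, T, params)
        return d.theta_perfect

    T_grid = np.asarray(T_grid, dtype=float)
    theta = np.array([theta0_fn(T) for T in T_grid])
    return MeltingCurve(T=T_grid, theta=theta, theta_fn=theta0_fn)
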