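"""Nearest-neighbor free energies and their defect-class re-parametrization.

Two routes to a duplex free energy live here:

* the sequence-specific nearest-neighbor (NN) sum for a fully complementary
  pair (:func:`nn_free_energy_pair`), using the unified stack/initiation
  table shipped with the package, and

* the averaged re-parametrization (:func:`delta_g_parametrized`) that assigns
  a free energy to a whole defect class: knowing only the sequence length L,
  the strong-base fraction f_CG and the defect vector alpha, the duplex
  energy is built from composition-averaged stacks plus averaged increments
  for dangling ends and terminal/internal mismatches.  This is what makes the
  4^L-species pool tractable.

Salt enters as the unified entropy-only correction, proportional to the
number of intact stacks and ln[Na+].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Optional

import numpy as np

from .alphabet import (
    DNA4,
    AlphabetSpec,
    InvalidInputError,
    is_complementary_pair,
)
from .constants import R_KCAL, T37
from .curves import MeltingCurve


@dataclass(frozen=True)
class FreeEnergy:
    """An (enthalpy, entropy) pair; dG(T) = dH - T * dS / 1000.

    dH in kcal/mol, dS in cal/(mol K), dG in kcal/mol.
    """

    dH: float
    dS: float

    def dG(self, T: float) -> float:
        return self.dH - T * self.dS / 1000.0

    @property
    def dG37(self) -> float:
        return self.dG(T37)

    def __add__(self, other: "FreeEnergy") -> "FreeEnergy":
        return FreeEnergy(self.dH + other.dH, self.dS + other.dS)

    def __mul__(self, k: float) -> "FreeEnergy":
        return FreeEnergy(self.dH * k, self.dS * k)

    __rmul__ = __mul__


@dataclass
class ThermoParams:
    """NN parameter set: per-quartet stacks, initiation, averaged increments.

    ``stacks`` maps every ordered quartet 5'XY3' of the 4-letter alphabet to
    its (dH, dS).  ``dangle_avg`` / ``mm_term_avg`` / ``mm_int_avg`` are the
    averaged per-defect increments used by the alpha parametrization, and
    ``salt_coeff`` the entropy-only salt coefficient in cal/(mol K) per stack
    per ln[Na+].  ``na_molar`` is the sodium concentration the parameters are
    evaluated at (the tabulated values are the 1 M reference state).
    """

    stacks: dict[str, FreeEnergy]
    init_strong: FreeEnergy
    init_weak: FreeEnergy
    dangle_avg: FreeEnergy
    mm_term_avg: FreeEnergy
    mm_int_avg: FreeEnergy
    salt_coeff: float
    na_molar: float = 1.0
    source: str = "builtin"
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.na_molar <= 0:
            raise InvalidInputError("na_molar must be positive")

    @classmethod
    def load(cls, path: Optional[str] = None, na_molar: float = 1.0) -> "ThermoParams":
        """Load a parameter table (tab-separated; '#' lines are provenance)."""
        if path is None:
            text = (resources.files("rsdna") / "data" / "nn_params.tsv").read_text()
            source = "builtin:nn_params.tsv"
        else:
            with open(path) as fh:
                text = fh.read()
            source = str(path)
        stacks: dict[str, FreeEnergy] = {}
        named: dict[str, tuple[float, ...]] = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            key, vals = parts[0], tuple(float(x) for x in parts[1:])
            if len(key) == 2 and set(key) <= set("ACGT"):
                stacks[key] = FreeEnergy(*vals)
            else:
                named[key] = vals
        missing = {a + b for a in "ACGT" for b in "ACGT"} - set(stacks)
        if missing:
            raise InvalidInputError(f"parameter table lacks WC quartets: {sorted(missing)}")
        return cls(
            stacks=stacks,
            init_strong=FreeEnergy(*named["INIT_GC"]),
            init_weak=FreeEnergy(*named["INIT_AT"]),
            dangle_avg=FreeEnergy(*named["DANGLE_AVG"]),
            mm_term_avg=FreeEnergy(*named["MM_TERM_AVG"]),
            mm_int_avg=FreeEnergy(*named["MM_INT_AVG"]),
            salt_coeff=named["SALT_COEFF"][0],
            na_molar=na_molar,
            source=source,
        )

    def with_na(self, na_molar: float) -> "ThermoParams":
        if na_molar <= 0:
            raise InvalidInputError("na_molar must be positive")
        return replace(self, na_molar=na_molar, _cache={})

    # -- composition-restricted stack averages (used by counterfactuals) ----

    def stack_average_over(self, bases: str) -> FreeEnergy:
        """Unweighted mean stack over quartets drawn from a base subset."""
        keys = [a + b for a in bases for b in bases]
        dH = float(np.mean([self.stacks[k].dH for k in keys]))
        dS = float(np.mean([self.stacks[k].dS for k in keys]))
        return FreeEnergy(dH, dS)


@dataclass(frozen=True)
class AveragedParams:
    """Composition-averaged effective energetics at a given f_CG.

    ``stack`` is the expected (dH, dS) of one WC stack, ``init`` the total
    duplex initiation (both ends), and the remaining fields the per-defect
    increments the alpha parametrization uses.
    """

    f_cg: float
    stack: FreeEnergy
    init: FreeEnergy
    dangle: FreeEnergy
    mm_term: FreeEnergy
    mm_int: FreeEnergy


def averaged_nn_params(
    f_cg: float, alphabet: AlphabetSpec = DNA4, params: Optional[ThermoParams] = None
) -> AveragedParams:
    """Expectation of the NN energetics over sequences of composition f_CG.

    Bases are drawn independently: strong (C/G-class) with probability f_CG
    (split evenly between C and G), weak with 1 - f_CG.  The averaged stack
    is the expectation over the 16 ordered quartets; at f_CG = 1/2 this is the
    unweighted table mean.  Alphabets carrying their own averaged energetics
    (counterfactual alphabets) override the quartet expectation.
    """
    if params is None:
        params = default_params()
    if not 0.0 <= f_cg <= 1.0:
        raise InvalidInputError("f_cg must lie in [0, 1]")
    cache_key = ("avg", round(f_cg, 12), alphabet.bases, alphabet.avg_stack,
                 alphabet.avg_init_per_end)
    hit = params._cache.get(cache_key)
    if hit is not None:
        return hit
    if alphabet.avg_stack is not None:
        stack = FreeEnergy(*alphabet.avg_stack)
        per_end = (
            FreeEnergy(*alphabet.avg_init_per_end)
            if alphabet.avg_init_per_end is not None
            else 0.5 * (params.init_strong + params.init_weak)
        )
        init = 2.0 * per_end
    else:
        p = {
            "A": (1 - f_cg) / 2,
            "T": (1 - f_cg) / 2,
            "C": f_cg / 2,
            "G": f_cg / 2,
        }
        dH = sum(p[x] * p[y] * params.stacks[x + y].dH for x in "ACGT" for y in "ACGT")
        dS = sum(p[x] * p[y] * params.stacks[x + y].dS for x in "ACGT" for y in "ACGT")
        stack = FreeEnergy(dH, dS)
        per_end = f_cg * params.init_strong + (1 - f_cg) * params.init_weak
        init = 2.0 * per_end
    out = AveragedParams(
        f_cg=f_cg,
        stack=stack,
        init=init,
        dangle=params.dangle_avg,
        mm_term=params.mm_term_avg,
        mm_int=params.mm_int_avg,
    )
    params._cache[cache_key] = out
    return out


def salt_correct(dS: float, n_stacks: int, na_molar: float, coeff: float = 0.368) -> float:
    """Entropy-only unified salt correction; identity at 1 M Na+."""
    if na_molar <= 0:
        raise InvalidInputError("na_molar must be positive")
    return dS + coeff * n_stacks * math.log(na_molar)


def nn_free_energy_pair(
    seq_a: str,
    seq_b: str,
    params: Optional[ThermoParams] = None,
    alphabet: AlphabetSpec = DNA4,
) -> FreeEnergy:
    """Sequence-specific NN free energy of a defectless duplex.

    ``seq_b`` must be the exact reverse-complement of ``seq_a``.  The result
    is the sum of the L-1 stack terms plus the two terminal initiation terms,
    with the salt-corrected entropy at ``params.na_molar``.
    """
    if params is None:
        params = default_params()
    alphabet.check(seq_a)
    alphabet.check(seq_b)
    if len(seq_a) < 2:
        raise InvalidInputError("need at least 2 nucleotides (one stack)")
    if not is_complementary_pair(seq_a, seq_b, alphabet):
        raise InvalidInputError(
            "nn_free_energy_pair covers defectless duplexes only: "
            "seq_b must be the reverse-complement of seq_a"
        )
    dH = 0.0
    dS = 0.0
    for i in range(len(seq_a) - 1):
        fe = params.stacks[seq_a[i : i + 2]]
        dH += fe.dH
        dS += fe.dS
    for terminal in (seq_a[0], seq_a[-1]):
        init = params.init_strong if terminal in alphabet.strong else params.init_weak
        dH += init.dH
        dS += init.dS
    dS = salt_correct(dS, len(seq_a) - 1, params.na_molar, params.salt_coeff)
    return FreeEnergy(dH, dS)


def delta_g_parametrized(
    L: int,
    alpha,
    f_cg: float,
    params: Optional[ThermoParams] = None,
    alphabet: AlphabetSpec = DNA4,
) -> FreeEnergy:
    """Averaged free energy of a duplex of class alpha at composition f_CG.

    The duplex keeps ``(L - |alpha_s| - alpha_e1 - alpha_e2 - 1) - 2*alpha_i``
    intact WC stacks (each internal mismatch breaks its two flanking stacks;
    floored at zero), pays the averaged initiation, gains one averaged
    dangling-end increment per duplex end carrying an overhang (both ends
    when the strands are shifted), and one averaged terminal- or
    internal-mismatch increment per mismatched position of the respective
    kind.  Salt corrects the entropy of the intact stacks only.
    """
    if params is None:
        params = default_params()
    from .defects import DefectVector  # local import to avoid a cycle

    if not isinstance(alpha, DefectVector):
        alpha = DefectVector(*alpha)
    alpha.validate(L)
    avg = averaged_nn_params(f_cg, alphabet, params)
    n_ext = alpha.alpha_e1 + alpha.alpha_e2
    n_stacks = max(0, (L - abs(alpha.alpha_s) - n_ext - 1) - 2 * alpha.alpha_i)
    n_dangle_ends = 2 if abs(alpha.alpha_s) >= 1 else 0
    dH = (
        n_stacks * avg.stack.dH
        + avg.init.dH
        + n_dangle_ends * avg.dangle.dH
        + n_ext * avg.mm_term.dH
        + alpha.alpha_i * avg.mm_int.dH
    )
    dS = (
        n_stacks * avg.stack.dS
        + avg.init.dS
        + n_dangle_ends * avg.dangle.dS
        + n_ext * avg.mm_term.dS
        + alpha.alpha_i * avg.mm_int.dS
    )
    dS = salt_correct(dS, n_stacks, params.na_molar, params.salt_coeff)
    return FreeEnergy(dH, dS)


def two_state_theta(log_4kc: np.ndarray) -> np.ndarray:
    """Bound fraction of the symmetric two-state quadratic, from log(4 K c).

    theta = 1 - 2 / (1 + sqrt(1 + 4 K c)), evaluated stably in log space for
    strongly bound duplexes.
    """
    log_4kc = np.asarray(log_4kc, dtype=float)
    out = np.empty_like(log_4kc)
    big = log_4kc > 500.0
    out[big] = 1.0 - 2.0 * np.exp(-log_4kc[big] / 2.0)
    x = np.exp(log_4kc[~big])
    out[~big] = 1.0 - 2.0 / (1.0 + np.sqrt(1.0 + x))
    return out


def pair_melting_curve(
    seq_a: str,
    seq_b: str,
    c_each: float,
    params: Optional[ThermoParams] = None,
    T_grid: Optional[np.ndarray] = None,
    alphabet: AlphabetSpec = DNA4,
) -> MeltingCurve:
    """Two-state melting curve of an equimolar non-self-complementary pair.

    Each strand is present at ``c_each`` mol/L.  theta(T) is the fraction of
    strands engaged in the duplex, from the mass-action quadratic.
    """
    if c_each <= 0:
        raise InvalidInputError("c_each must be positive")
    if params is None:
        params = default_params()
    if T_grid is None:
        T_grid = default_t_grid()
    fe = nn_free_energy_pair(seq_a, seq_b, params, alphabet)

    def theta_fn(T: float) -> float:
        log_4kc = math.log(4.0 * c_each) - fe.dG(T) / (R_KCAL * T)
        return float(two_state_theta(np.array([log_4kc]))[0])

    T_grid = np.asarray(T_grid, dtype=float)
    log_4kc = np.log(4.0 * c_each) - fe.dG(T_grid) / (R_KCAL * T_grid)
    return MeltingCurve(T=T_grid, theta=two_state_theta(log_4kc), theta_fn=theta_fn)


def pair_tm(seq_a: str, seq_b: str, c_each: float,
            params: Optional[ThermoParams] = None) -> float:
    """Closed-form two-state melting temperature (kelvin) of an equimolar pair.

    At theta = 1/2 the mass-action quadratic gives K = 2 / c_each, hence
    Tm = 1000 dH / (dS + R ln(c_each / 2)).
    """
    fe = nn_free_energy_pair(seq_a, seq_b, params)
    return 1000.0 * fe.dH / (fe.dS + 1000.0 * R_KCAL * math.log(c_each / 2.0))


def default_t_grid(t_min_c: float = 0.0, t_max_c: float = 95.0,
                   step_c: float = 0.25) -> np.ndarray:
    """Default temperature grid in kelvin (0-95 C, 0.25 C step)."""
    n = int(round((t_max_c - t_min_c) / step_c)) + 1
    return 273.15 + t_min_c + step_c * np.arange(n)


_DEFAULT_PARAMS: Optional[ThermoParams] = None


def default_params() -> ThermoParams:
    """The packaged unified parameter set at 1 M Na+ (cached)."""
    global _DEFAULT_PARAMS
    if _DEFAULT_PARAMS is None:
        _DEFAULT_PARAMS = ThermoParams.load()
    return _DEFAULT_PARAMS
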