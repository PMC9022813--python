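"""The alpha parametrization of duplex quality.

A duplex between two L-mers is classified by the defect vector
alpha = (alpha_s, alpha_e1, alpha_e2, alpha_i): the mutual shift, the runs of
consecutive mismatched positions touching each duplex end, and the count of
internal mismatches.  The number of partner sequences realizing a class with
a fixed reference is the degeneracy

    g(L, alpha) = n_b^|alpha_s| * (n_b - 1)^(alpha_e1 + alpha_e2 + alpha_i)
                  * C(L - 2 - |alpha_s| - alpha_e1 - alpha_e2, alpha_i),

with n_b = 4 for natural DNA.  Statistical weights are g * zeta with the
Boltzmann factor zeta = [c] exp(-dG / RT).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional

import numpy as np
import pandas as pd

from .alphabet import DNA4, AlphabetSpec, InvalidInputError
from .constants import R_KCAL, T37
from .thermo import FreeEnergy, ThermoParams, default_params, delta_g_parametrized


@dataclass(frozen=True, order=True)
class DefectVector:
    """Defect vector alpha = (alpha_s, alpha_e1, alpha_e2, alpha_i).

    The two duplex ends are distinguishable: (a, b) and (b, a) terminal-run
    counts are distinct classes.
    """

    alpha_s: int
    alpha_e1: int
    alpha_e2: int
    alpha_i: int

    @property
    def total(self) -> int:
        """|alpha|: total number of defected positions."""
        return abs(self.alpha_s) + self.alpha_e1 + self.alpha_e2 + self.alpha_i

    def paired_bases(self, L: int) -> int:
        return L - abs(self.alpha_s) - self.alpha_e1 - self.alpha_e2 - self.alpha_i

    def is_valid(self, L: int) -> bool:
        if min(self.alpha_e1, self.alpha_e2, self.alpha_i) < 0:
            return False
        if abs(self.alpha_s) > L - 1:
            return False
        # at least two paired bases (one surviving boundary pair per end)
        return self.paired_bases(L) >= 2

    def validate(self, L: int) -> None:
        if L < 2:
            raise InvalidInputError("L must be >= 2")
        if not self.is_valid(L):
            raise InvalidInputError(f"{self} is not a valid defect vector for L={L}")

    def astuple(self) -> tuple[int, int, int, int]:
        return (self.alpha_s, self.alpha_e1, self.alpha_e2, self.alpha_i)


PERFECT = DefectVector(0, 0, 0, 0)


@lru_cache(maxsize=64)
def enumerate_defects(L: int) -> tuple[DefectVector, ...]:
    """All valid defect vectors for length L, lexicographic in
    (alpha_s, alpha_e1, alpha_e2, alpha_i)."""
    if L < 2:
        raise InvalidInputError("L must be >= 2")
    out = []
    for s in range(-(L - 1), L):
        room = L - 2 - abs(s)
        for e1 in range(0, room + 1):
            for e2 in range(0, room - e1 + 1):
                for i in range(0, room - e1 - e2 + 1):
                    out.append(DefectVector(s, e1, e2, i))
    return tuple(out)


def degeneracy(L: int, alpha: DefectVector, n_b: int = 4) -> int:
    """Number of partner sequences forming a class-alpha duplex with a fixed
    reference; for n_b = 4 this is the natural-DNA count."""
    if not isinstance(alpha, DefectVector):
        alpha = DefectVector(*alpha)
    alpha.validate(L)
    n_mm = alpha.alpha_e1 + alpha.alpha_e2 + alpha.alpha_i
    interior = L - 2 - abs(alpha.alpha_s) - alpha.alpha_e1 - alpha.alpha_e2
    return n_b ** abs(alpha.alpha_s) * (n_b - 1) ** n_mm * math.comb(interior, alpha.alpha_i)


def classify_alignment(
    ref: str, partner: str, shift: int, alphabet: AlphabetSpec = DNA4
) -> Optional[DefectVector]:
    """Map one (reference, partner, shift) alignment to its defect vector.

    The partner is read antiparallel; ``shift`` = 0 aligns the 3' terminal
    base of the reference with the partner's 5' terminal base.  Mismatch runs
    touching a duplex end are external (alpha_e), every other mismatched
    position internal (alpha_i).  Alignments retaining fewer than two paired
    bases are not duplexes and yield ``None``.
    """
    alphabet.check(ref)
    alphabet.check(partner)
    L = len(ref)
    if len(partner) != L:
        raise InvalidInputError("equal-length strands only")
    if abs(shift) > L - 1:
        raise InvalidInputError(f"|shift| must be <= L-1, got {shift}")
    rp = partner[::-1]
    lo, hi = max(0, shift), min(L, L + shift)
    matched = [alphabet.complement[ref[i]] == rp[i - shift] for i in range(lo, hi)]
    m = len(matched)
    e1 = 0
    while e1 < m and not matched[e1]:
        e1 += 1
    if e1 == m:  # nothing paired at all
        return None
    e2 = 0
    while not matched[m - 1 - e2]:
        e2 += 1
    n_int = sum(1 for x in matched[e1 : m - e2] if not x)
    alpha = DefectVector(shift, e1, e2, n_int)
    return alpha if alpha.is_valid(L) else None


def best_shift(
    ref: str,
    partner: str,
    T: float,
    params: Optional[ThermoParams] = None,
    alphabet: AlphabetSpec = DNA4,
) -> Optional[tuple[DefectVector, FreeEnergy]]:
    """Most stable alignment of one pair: the minimum-dG(T) shift.

    Ties break toward the smallest |alpha_s|, then negative before positive.
    Returns ``None`` when no alignment qualifies as a duplex.
    """
    if params is None:
        params = default_params()
    L = len(ref)
    f_cg = alphabet.f_cg(ref) if alphabet.strong else 0.5
    best: Optional[tuple[float, int, int, DefectVector, FreeEnergy]] = None
    for shift in range(-(L - 1), L):
        alpha = classify_alignment(ref, partner, shift, alphabet)
        if alpha is None:
            continue
        fe = delta_g_parametrized(L, alpha, f_cg, params, alphabet)
        key = (fe.dG(T), abs(shift), 0 if shift < 0 else 1)
        if best is None or key < best[:3]:
            best = (*key, alpha, fe)
    return None if best is None else (best[3], best[4])


def log_boltzmann_factor(dG: float, T: float, c_molar: float) -> float:
    """ln zeta = ln[c] - dG / (R T)."""
    if c_molar <= 0 or T <= 0:
        raise InvalidInputError("c_molar and T must be positive")
    return math.log(c_molar) - dG / (R_KCAL * T)


def boltzmann_factor(dG, T: float, c_molar: float) -> float:
    """Statistical weight zeta = [c] exp(-dG / RT) of one pairing.

    ``dG`` may be a number (kcal/mol) or a :class:`FreeEnergy`.
    """
    if isinstance(dG, FreeEnergy):
        dG = dG.dG(T)
    return math.exp(log_boltzmann_factor(dG, T, c_molar))


# ---------------------------------------------------------------------------
# Vectorized class energetics


def _alphabet_key(alphabet: AlphabetSpec):
    return (alphabet.bases, alphabet.avg_stack, alphabet.avg_init_per_end)


def defect_energy_arrays(
    L: int,
    f_cg: float,
    params: ThermoParams,
    alphabet: AlphabetSpec = DNA4,
):
    """(alphas, g, log_g, dH, dS) arrays over all defect classes of length L.

    dS includes the salt correction at ``params.na_molar``.  Cached per
    (parameter set, alphabet, L, f_CG).
    """
    key = (L, round(f_cg, 12), _alphabet_key(alphabet), params.na_molar)
    hit = params._cache.get(key)
    if hit is not None:
        return hit
    alphas = enumerate_defects(L)
    n_b = alphabet.n_b
    dH = np.empty(len(alphas))
    dS = np.empty(len(alphas))
    g = np.empty(len(alphas), dtype=np.int64)
    for k, a in enumerate(alphas):
        fe = delta_g_parametrized(L, a, f_cg, params, alphabet)
        dH[k], dS[k] = fe.dH, fe.dS
        g[k] = degeneracy(L, a, n_b)
    out = (alphas, g, np.log(g.astype(float)), dH, dS)
    params._cache[key] = out
    return out


@dataclass
class WeightTable:
    """Per-class degeneracies and Boltzmann weights at one (L, f_CG, T).

    ``weight`` = g * zeta; ``partition_sum`` is their sum, the denominator
    sum of the pool melting formula (before the 4 / n_b^L prefactor).
    """

    L: int
    f_cg: float
    T: float
    c_molar: float
    na_molar: float
    alphas: tuple[DefectVector, ...]
    g: np.ndarray
    dH: np.ndarray
    dS: np.ndarray
    log_zeta: np.ndarray

    @property
    def zeta(self) -> np.ndarray:
        return np.exp(self.log_zeta)

    @property
    def log_weight(self) -> np.ndarray:
        return np.log(self.g) + self.log_zeta

    @property
    def weight(self) -> np.ndarray:
        return self.g * self.zeta

    @property
    def partition_sum(self) -> float:
        return float(np.sum(self.weight))

    @property
    def log_partition_sum(self) -> float:
        m = float(np.max(self.log_weight))
        return m + math.log(np.sum(np.exp(self.log_weight - m)))

    def to_dataframe(self) -> pd.DataFrame:
        dg37 = self.dH - T37 * self.dS / 1000.0
        return pd.DataFrame(
            {
                "alpha_s": [a.alpha_s for a in self.alphas],
                "alpha_e1": [a.alpha_e1 for a in self.alphas],
                "alpha_e2": [a.alpha_e2 for a in self.alphas],
                "alpha_i": [a.alpha_i for a in self.alphas],
                "g": self.g.astype(int),
                "dG_37C": dg37,
                "zeta": self.zeta,
                "weight": self.weight,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def partition_sum(
    L: int,
    f_cg: float,
    T: float,
    c_molar: float,
    params: Optional[ThermoParams] = None,
    alphabet: AlphabetSpec = DNA4,
) -> WeightTable:
    """Weight table g * zeta over every defect class at one temperature."""
    if params is None:
        params = default_params()
    if c_molar <= 0 or T <= 0:
        raise InvalidInputError("c_molar and T must be positive")
    alphas, g, _log_g, dH, dS = defect_energy_arrays(L, f_cg, params, alphabet)
    dG = dH - T * dS / 1000.0
    log_zeta = math.log(c_molar) - dG / (R_KCAL * T)
    return WeightTable(
        L=L,
        f_cg=f_cg,
        T=T,
        c_molar=c_molar,
        na_molar=params.na_molar,
        alphas=alphas,
        g=g,
        dH=dH,
        dS=dS,
        log_zeta=log_zeta,
    )
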