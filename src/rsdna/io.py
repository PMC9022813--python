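"""File formats, absorbance reduction, configuration.

Melting curves travel as two-column CSV (``T_C,theta``); absorbance traces
as ``T_C,A`` CSV.  Raw UV absorbance melts are reduced to bound-fraction
curves by the standard two-baseline protocol: linear baselines fitted in a
low-T (fully hybridized, hypochromic) and a high-T (fully melted) window,

    theta(T) = (A_upper(T) - A(T)) / (A_upper(T) - A_lower(T)),

clipped to [0, 1].  A seeded synthetic-trace generator inverts the same
construction for testing and fixtures.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, fields
from typing import Optional

import numpy as np
import pandas as pd
from Bio import SeqIO

from .alphabet import DNA4, AlphabetSpec, InvalidInputError
from .constants import T_ZERO_C
from .curves import MeltingCurve


def read_fasta(path, alphabet: AlphabetSpec = DNA4) -> dict[str, str]:
    """Read sequences from FASTA, keyed by record id, validated and uppercased."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        alphabet.check(seq)
        out[rec.id] = seq
    if not out:
        raise InvalidInputError(f"no FASTA records found in {path}")
    return out


def write_curve_csv(curve: MeltingCurve, path) -> None:
    """Write ``T_C,theta`` with 6 significant digits."""
    with open(path, "w") as fh:
        fh.write("T_C,theta\n")
        for t, th in zip(curve.T_celsius, curve.theta):
            fh.write(f"{t:.6g},{th:.6g}\n")


def read_curve_csv(path) -> MeltingCurve:
    df = pd.read_csv(path)
    return MeltingCurve(T=df["T_C"].to_numpy() + T_ZERO_C,
                        theta=df["theta"].to_numpy())


@dataclass
class AbsorbanceTrace:
    """A raw absorbance melt: temperature in Celsius, absorbance in a.u."""

    T_c: np.ndarray
    A: np.ndarray
    direction: str = "heating"

    def __post_init__(self) -> None:
        self.T_c = np.asarray(self.T_c, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        if self.T_c.shape != self.A.shape or self.T_c.ndim != 1:
            raise InvalidInputError("T_c and A must be equal-length 1-D arrays")
        d = np.diff(self.T_c)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise InvalidInputError("temperature grid must be strictly monotone")
        if not np.all(np.isfinite(self.A)):
            raise InvalidInputError("absorbance values must be finite")
        if self.direction not in ("heating", "cooling"):
            raise InvalidInputError("direction must be 'heating' or 'cooling'")

    def to_csv(self, path) -> None:
        pd.DataFrame({"T_C": self.T_c, "A": self.A}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, direction: str = "heating") -> "AbsorbanceTrace":
        df = pd.read_csv(path)
        return cls(T_c=df["T_C"].to_numpy(), A=df["A"].to_numpy(), direction=direction)


def synthesize_absorbance(
    curve: MeltingCurve,
    baseline_low: tuple[float, float] = (0.50, 0.0005),
    baseline_high: tuple[float, float] = (0.65, 0.0005),
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
) -> AbsorbanceTrace:
    """Synthetic hyperchromicity trace from a known bound-fraction curve.

    Baselines are (intercept, slope) in absorbance units vs Celsius; the
    lower baseline is the fully hybridized (hypochromic) limit.  Gaussian
    noise of standard deviation ``noise_sd`` is added with the given seed.
    """
    if noise_sd < 0:
        raise InvalidInputError("noise_sd must be >= 0")
    t = curve.T_celsius
    a_lo = baseline_low[0] + baseline_low[1] * t
    a_hi = baseline_high[0] + baseline_high[1] * t
    a = a_lo + (a_hi - a_lo) * (1.0 - curve.theta)
    if noise_sd > 0:
        a = a + np.random.default_rng(seed).normal(0.0, noise_sd, size=a.shape)
    return AbsorbanceTrace(T_c=t.copy(), A=a)


def normalize_absorbance(
    trace: AbsorbanceTrace,
    low_window: Optional[tuple[float, float]] = None,
    high_window: Optional[tuple[float, float]] = None,
) -> MeltingCurve:
    """Two-baseline reduction of an absorbance melt to theta(T).

    Windows are (T_min_C, T_max_C); by default the lowest and highest 15% of
    the temperature span.  Each window must contain at least 5 points.
    """
    t, a = trace.T_c, trace.A
    t_lo, t_hi = float(t.min()), float(t.max())
    span = t_hi - t_lo
    if low_window is None:
        low_window = (t_lo, t_lo + 0.15 * span)
    if high_window is None:
        high_window = (t_hi - 0.15 * span, t_hi)
    theta = _baseline_theta(t, a, low_window, high_window)
    order = np.argsort(t)
    t_sorted = t[order]
    theta_sorted = theta[order]
    # Tm extraction runs on a lightly smoothed continuous model (Savitzky-
    # Golay over ~4 C) so that grid noise does not jitter the 1/2 crossing;
    # the stored theta grid stays unsmoothed.
    theta_fn = None
    n_win = int(round(4.0 / max(np.median(np.diff(t_sorted)), 1e-6))) | 1
    if 5 <= n_win < theta_sorted.size:
        from scipy.signal import savgol_filter

        smooth = np.clip(savgol_filter(theta_sorted, n_win, 2), 0.0, 1.0)
        theta_fn = lambda T: float(np.interp(T, t_sorted + T_ZERO_C, smooth))
    return MeltingCurve(T=t_sorted + T_ZERO_C, theta=theta_sorted,
                        theta_fn=theta_fn)


def _baseline_theta(t, a, low_window, high_window) -> np.ndarray:
    def fit(window, name):
        lo, hi = window
        if lo < t.min() - 1e-9 or hi > t.max() + 1e-9:
            raise InvalidInputError(f"{name} baseline window {window} outside data span")
        sel = (t >= lo) & (t <= hi)
        if sel.sum() < 5:
            raise InvalidInputError(
                f"{name} baseline window {window} holds {int(sel.sum())} points (< 5)"
            )
        return np.polyfit(t[sel], a[sel], 1)

    p_low = fit(low_window, "low-T")
    p_high = fit(high_window, "high-T")
    a_lo = np.polyval(p_low, t)
    a_hi = np.polyval(p_high, t)
    gap = a_hi - a_lo
    if np.any(gap <= 0) or np.median(gap) < 1e-12:
        raise InvalidInputError(
            "degenerate baselines: upper baseline does not exceed lower baseline"
        )
    return np.clip((a_hi - a) / gap, 0.0, 1.0)


@dataclass
class RunConfig:
    """CLI-settable parameters; round-trips through a flat key=value file."""

    L: int = 12
    conc_gl: float = 0.04
    salt: float = 1.0
    tmin_c: float = 0.0
    tmax_c: float = 95.0
    tstep_c: float = 0.25
    nn_table: str = ""
    mw_per_base: float = 303.7
    mw_offset: float = 79.0
    seed: int = 0

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for f in fields(self):
                fh.write(f"{f.name} = {getattr(self, f.name)}\n")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        kwargs = {}
        types = {f.name: f.type for f in fields(cls)}
        casts = {"int": int, "float": float, "str": str}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, val = line.partition("=")
                key, val = key.strip(), val.strip()
                if key not in types:
                    raise InvalidInputError(f"unknown config key {key!r}")
                kwargs[key] = casts[types[key]](val)
        return cls(**kwargs)


def file_checksum(path) -> str:
    """SHA-256 of a file, for provenance logging."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        h.update(fh.read())
    return h.hexdigest()
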