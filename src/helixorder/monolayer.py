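"""Langmuir monolayer analyses: Pi-A isotherms, adsorption kinetics, and
acyl-chain geometry.

The compressibility modulus Cs^-1 = -A (dPi/dA) distinguishes the
liquid-disordered (gauche-rich chains, low Cs^-1) and liquid-ordered
(extended chains) states of a lipid monolayer; a phase transition shows
up as a dip in Cs^-1 between the two regime maxima.  Adsorption kinetics
Pi(t) after protein injection are summarized by the pressure increase,
initial rate and a two-phase flag (fast accumulation followed by slow
rearrangement).  The all-trans chain-extension relation links the acyl
chain length to the limiting (solid-state) bilayer thickness.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks, savgol_filter

from .exceptions import DegenerateInputError, ParameterError
from .spectra import read_xy

__all__ = [
    "Isotherm",
    "KineticsTrace",
    "PhaseTransition",
    "AdsorptionSummary",
    "read_isotherm",
    "read_kinetics",
    "compressibility_modulus",
    "detect_phase_transition",
    "adsorption_summary",
    "max_chain_length",
    "solid_bilayer_thickness",
]


@dataclass(frozen=True)
class Isotherm:
    """Surface pressure vs area per molecule at fixed temperature.

    ``area_per_molecule`` in nm^2 (recorded decreasing during
    compression; stored as given), ``surface_pressure`` in mN/m.
    """

    area_per_molecule: np.ndarray
    surface_pressure: np.ndarray
    temperature: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        a = np.asarray(self.area_per_molecule, float)
        p = np.asarray(self.surface_pressure, float)
        if a.shape != p.shape or a.ndim != 1:
            raise ParameterError("area and pressure series must be equal-length 1-D")
        if np.any(a <= 0):
            raise ParameterError("areas must be positive")
        object.__setattr__(self, "area_per_molecule", a)
        object.__setattr__(self, "surface_pressure", p)

    def __len__(self):
        return self.area_per_molecule.size


@dataclass(frozen=True)
class KineticsTrace:
    """Surface pressure vs time after an injection event.

    ``time`` in s (strictly increasing), ``surface_pressure`` in mN/m,
    ``injection_time`` in s.
    """

    time: np.ndarray
    surface_pressure: np.ndarray
    injection_time: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        t = np.asarray(self.time, float)
        p = np.asarray(self.surface_pressure, float)
        if t.shape != p.shape or t.ndim != 1:
            raise ParameterError("time and pressure series must be equal-length 1-D")
        if np.any(np.diff(t) <= 0):
            raise ParameterError("time series must be strictly increasing")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "surface_pressure", p)


def read_isotherm(path, dialect=None) -> Isotherm:
    """Two-column (area_nm2, pressure_mN/m) CSV with ``# key: value`` header."""
    a, p, meta = read_xy(path, dialect, min_points=5)
    temp = float(meta["temperature_C"]) if "temperature_C" in meta else None
    return Isotherm(a, p, temperature=temp, meta=meta)


def read_kinetics(path, dialect=None, injection_time=None) -> KineticsTrace:
    t, p, meta = read_xy(path, dialect, min_points=5)
    if injection_time is None:
        injection_time = float(meta.get("injection_time_s", t[0]))
    return KineticsTrace(t, p, injection_time=injection_time, meta=meta)


def _ascending(iso: Isotherm):
    a = iso.area_per_molecule
    diffs = np.diff(a)
    if np.all(diffs > 0):
        return a, iso.surface_pressure
    if np.all(diffs < 0):
        return a[::-1], iso.surface_pressure[::-1]
    raise ParameterError(
        "area series is not monotone; sort the isotherm by area (compression "
        "records should decrease steadily) before analysis"
    )


def compressibility_modulus(iso: Isotherm, smooth_window: int = 7, poly_order: int = 2):
    """Compressibility modulus Cs^-1 = -A (dPi/dA) in mN/m.

    Pi is Savitzky-Golay smoothed before finite differencing; the series
    is returned on the interior grid (endpoints dropped) as
    ``(area, cs_inv)``.  Exact for linear isotherms.
    """
    if len(iso) < 5:
        raise ParameterError("need at least 5 isotherm points")
    a, p = _ascending(iso)
    window = min(smooth_window, len(a) if len(a) % 2 == 1 else len(a) - 1)
    if window > poly_order:
        p_smooth = savgol_filter(p, window, poly_order)
    else:
        p_smooth = p
    dpda = np.gradient(p_smooth, a)
    cs_inv = -a * dpda
    return a[1:-1], cs_inv[1:-1]


@dataclass
class PhaseTransition:
    """Detected monolayer phase transition (or absence of one).

    ``area``/``pressure`` give the deepest Cs^-1 minimum between two
    regime maxima; ``candidates`` lists all (area, pressure, cs_min)
    minima found, deepest first.
    """

    found: bool
    area: float | None = None
    pressure: float | None = None
    cs_min: float | None = None
    candidates: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "found": self.found,
            "area_nm2": self.area,
            "pressure_mN_per_m": self.pressure,
            "cs_inv_min_mN_per_m": self.cs_min,
            "candidates": self.candidates,
        }


def detect_phase_transition(iso: Isotherm, prominence_frac: float = 0.05) -> PhaseTransition:
    """Locate the Ld/Lo transition as the Cs^-1 minimum between regime maxima.

    With fewer than two Cs^-1 maxima the isotherm is single-regime and a
    no-transition result is returned (not an error).  With several
    candidate dips the deepest minimum wins; all are reported.
    """
    area, cs = compressibility_modulus(iso)
    a_full, p_full = _ascending(iso)
    span = float(np.ptp(cs))
    if span <= 0:
        return PhaseTransition(found=False)
    maxima, _ = find_peaks(cs, prominence=prominence_frac * span)
    # end points can be regime maxima too
    interior = list(maxima)
    if cs[0] > cs[1]:
        interior = [0] + interior
    if cs[-1] > cs[-2]:
        interior = interior + [len(cs) - 1]
    if len(interior) < 2:
        return PhaseTransition(found=False)
    candidates = []
    for left, right in zip(interior, interior[1:]):
        if right - left < 2:
            continue
        seg = cs[left : right + 1]
        k = left + int(np.argmin(seg))
        depth = min(cs[left], cs[right]) - cs[k]
        if depth <= prominence_frac * span:
            continue
        a_t = float(area[k])
        p_t = float(np.interp(a_t, a_full, p_full))
        candidates.append((a_t, p_t, float(cs[k]), float(depth)))
    if not candidates:
        return PhaseTransition(found=False)
    candidates.sort(key=lambda c: -c[3])
    best = candidates[0]
    return PhaseTransition(
        found=True,
        area=best[0],
        pressure=best[1],
        cs_min=best[2],
        candidates=[c[:3] for c in candidates],
    )


@dataclass
class AdsorptionSummary:
    """Summary of a Pi(t) adsorption record."""

    delta_pi: float
    initial_rate: float
    plateau_pi: float
    two_phase: bool

    def to_dict(self) -> dict:
        return {
            "delta_pi_mN_per_m": self.delta_pi,
            "initial_rate_mN_per_m_s": self.initial_rate,
            "plateau_pi_mN_per_m": self.plateau_pi,
            "two_phase": self.two_phase,
        }


def adsorption_summary(
    k: KineticsTrace,
    initial_window: float = 200.0,
    late_fraction: float = 0.5,
) -> AdsorptionSummary:
    """Pressure increase, initial rate and two-phase flag for Pi(t).

    delta_pi = Pi(end) - Pi(injection); the initial rate is a linear fit
    over the first ``initial_window`` seconds after injection; the record
    is two-phase when the late-window slope (last ``late_fraction`` of
    the post-injection record) is below half the initial rate while the
    pressure increase exceeds the pre-injection noise.
    """
    t, p = k.time, k.surface_pressure
    if k.injection_time > t[-1]:
        raise ParameterError("injection_time lies after the end of the record")
    post = t >= k.injection_time
    t_post, p_post = t[post], p[post]
    if t_post.size < 3 or (t_post[-1] - t_post[0]) < 100.0:
        raise ParameterError("need at least 100 s of post-injection data")

    pi_inj = float(np.interp(k.injection_time, t, p))
    plateau_n = max(3, int(0.1 * t_post.size))
    plateau_pi = float(np.mean(p_post[-plateau_n:]))
    delta_pi = float(p_post[-1] - pi_inj)

    early = t_post <= t_post[0] + initial_window
    if np.count_nonzero(early) < 2:
        early[:2] = True
    initial_rate = float(np.polyfit(t_post[early], p_post[early], 1)[0])

    late_start = t_post[0] + (1.0 - late_fraction) * (t_post[-1] - t_post[0])
    late = t_post >= late_start
    late_rate = float(np.polyfit(t_post[late], p_post[late], 1)[0])

    pre = t < k.injection_time
    noise = float(np.std(p[pre])) if np.count_nonzero(pre) >= 3 else 0.0
    signal = delta_pi > max(3.0 * noise, 1e-9, 0.02 * abs(pi_inj))
    two_phase = bool(signal and initial_rate > 0 and late_rate < 0.5 * initial_rate)
    return AdsorptionSummary(
        delta_pi=delta_pi,
        initial_rate=initial_rate,
        plateau_pi=plateau_pi,
        two_phase=two_phase,
    )


def max_chain_length(n_carbons: int) -> float:
    """Maximum all-trans extension of a saturated acyl chain, in nm.

    Standard all-trans geometry: l(A) = 1.5 + 1.265 (n_C - 1) — a 1.5 A
    terminal-group correction plus 1.265 A projected C-C advance per
    bond.  A myristoyl chain (C14) comes out at 1.79 nm.
    """
    if n_carbons < 2:
        raise ParameterError("chain needs at least 2 carbons")
    return (1.5 + 1.265 * (n_carbons - 1)) / 10.0


def solid_bilayer_thickness(chain_nm: float, headgroup_nm: float = 0.8) -> float:
    """Limiting thickness (nm) of a solid-state bilayer: 2 (chain + head)."""
    if chain_nm <= 0 or headgroup_nm <= 0:
        raise ParameterError("chain and headgroup lengths must be positive")
    return 2.0 * (chain_nm + headgroup_nm)
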