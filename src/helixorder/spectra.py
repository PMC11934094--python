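"""Spectrum container, file I/O and preprocessing.

A :class:`Spectrum` is a pair of equal-length arrays — a strictly ascending
wavenumber grid (cm^-1) and dimensionless absorbance — plus free-form
metadata.  All spectroscopy stages (deconvolution, orientation analysis)
consume this type.  Readers silently re-sort descending instrument exports;
duplicate wavenumbers are rejected.

Preprocessing covers the three steps applied to reflection-absorption and
ATR spectra before band analysis: cropping to the amide I' analysis window
(1580-1780 cm^-1 by default), baseline subtraction, and normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import (
    DegenerateInputError,
    EmptyWindowError,
    ParameterError,
    SpectrumParseError,
)

__all__ = [
    "Spectrum",
    "SpectralWindow",
    "AMIDE_I_WINDOW",
    "read_spectrum",
    "write_spectrum",
    "crop",
    "subtract_baseline",
    "normalize",
    "resample_uniform",
]

MIN_POINTS = 8


@dataclass(frozen=True)
class Spectrum:
    """An IR spectrum on a strictly ascending wavenumber grid.

    Parameters
    ----------
    wavenumbers : ndarray
        Grid in cm^-1, strictly ascending.
    absorbance : ndarray
        Dimensionless absorbance (arbitrary units), same length.
    meta : dict
        Free-form metadata (instrument, temperature, electrolyte...).
    """

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        nu = np.asarray(self.wavenumbers, dtype=float)
        ab = np.asarray(self.absorbance, dtype=float)
        if nu.ndim != 1 or ab.ndim != 1:
            raise ParameterError("wavenumbers and absorbance must be 1-D arrays")
        if nu.shape != ab.shape:
            raise ParameterError(
                f"length mismatch: {nu.size} wavenumbers vs {ab.size} absorbance values"
            )
        if not (np.all(np.isfinite(nu)) and np.all(np.isfinite(ab))):
            raise ParameterError("non-finite values in spectrum")
        if nu.size >= 2 and not np.all(np.diff(nu) > 0):
            raise ParameterError("wavenumber grid must be strictly ascending")
        object.__setattr__(self, "wavenumbers", nu)
        object.__setattr__(self, "absorbance", ab)

    def __len__(self) -> int:
        return self.wavenumbers.size

    @property
    def step(self) -> float:
        """Mean grid step in cm^-1."""
        return float(np.mean(np.diff(self.wavenumbers)))

    def is_uniform(self, rtol: float = 1e-6) -> bool:
        d = np.diff(self.wavenumbers)
        return bool(np.allclose(d, d[0], rtol=rtol, atol=1e-9))

    def with_absorbance(self, absorbance: np.ndarray, **meta_updates) -> "Spectrum":
        meta = dict(self.meta)
        meta.update(meta_updates)
        return Spectrum(self.wavenumbers.copy(), np.asarray(absorbance, float), meta)


@dataclass(frozen=True)
class SpectralWindow:
    """Closed wavenumber interval [lo, hi] in cm^-1."""

    lo: float
    hi: float

    def __post_init__(self):
        if not (self.lo < self.hi):
            raise ParameterError(f"window requires lo < hi, got [{self.lo}, {self.hi}]")

    def contains(self, nu: float) -> bool:
        return self.lo <= nu <= self.hi


#: Default amide I' analysis window.
AMIDE_I_WINDOW = SpectralWindow(1580.0, 1780.0)


def _sniff_delimiter(path: Path, dialect: str | None) -> str | None:
    if dialect == "csv":
        return ","
    if dialect == "tsv":
        return "\t"
    if dialect is not None:
        raise ParameterError(f"unknown dialect {dialect!r}; use 'csv' or 'tsv'")
    suffix = path.suffix.lower()
    if suffix in (".tsv", ".tab"):
        return "\t"
    if suffix == ".csv":
        return ","
    return None  # split on any whitespace or comma


def _split_row(line: str, delim: str | None) -> list[str]:
    if delim is None:
        return line.replace(",", " ").split()
    return [tok.strip() for tok in line.split(delim)]


def read_xy(path, dialect: str | None = None, min_points: int = 2):
    """Parse a two-column numeric table.

    Returns ``(x, y, meta)``; lines starting with ``#`` are treated as
    metadata (``# key: value``) and an optional single non-numeric header
    line is skipped.  Malformed rows raise :class:`SpectrumParseError`
    naming the line number.
    """
    path = Path(path)
    if not path.exists():
        raise SpectrumParseError(f"no such file: {path}")
    delim = _sniff_delimiter(path, dialect)
    xs: list[float] = []
    ys: list[float] = []
    meta: dict = {}
    header_skipped = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, val = body.partition(":")
                    meta[key.strip()] = val.strip()
                continue
            tokens = _split_row(line, delim)
            if len(tokens) < 2:
                raise SpectrumParseError(f"{path.name}: line {lineno}: expected two columns")
            try:
                x = float(tokens[0])
                y = float(tokens[1])
            except ValueError:
                if not header_skipped and not xs:
                    header_skipped = True
                    continue
                raise SpectrumParseError(
                    f"{path.name}: line {lineno}: non-numeric value in {tokens[:2]}"
                ) from None
            xs.append(x)
            ys.append(y)
    if len(xs) < min_points:
        raise SpectrumParseError(
            f"{path.name}: only {len(xs)} data rows; need at least {min_points}"
        )
    return np.array(xs), np.array(ys), meta


def read_spectrum(path, dialect: str | None = None) -> Spectrum:
    """Read a two-column (wavenumber, absorbance) CSV/TSV file.

    The returned spectrum is sorted ascending in wavenumber regardless of
    the file order; duplicate wavenumbers are rejected.
    """
    nu, ab, meta = read_xy(path, dialect, min_points=MIN_POINTS)
    order = np.argsort(nu, kind="stable")
    nu, ab = nu[order], ab[order]
    if np.any(np.diff(nu) == 0):
        dup = nu[np.flatnonzero(np.diff(nu) == 0)[0]]
        raise SpectrumParseError(f"{Path(path).name}: duplicate wavenumber {dup} cm^-1")
    return Spectrum(nu, ab, meta)


def write_spectrum(path, s: Spectrum, dialect: str | None = None) -> None:
    """Write a spectrum as a two-column table (metadata as ``# key: value``)."""
    path = Path(path)
    delim = _sniff_delimiter(path, dialect) or ","
    with open(path, "w") as fh:
        for key, val in s.meta.items():
            fh.write(f"# {key}: {val}\n")
        fh.write(f"wavenumber_cm-1{delim}absorbance\n")
        for nu, ab in zip(s.wavenumbers, s.absorbance):
            fh.write(f"{nu:.12g}{delim}{ab:.12g}\n")


def crop(s: Spectrum, window: SpectralWindow = AMIDE_I_WINDOW) -> Spectrum:
    """Restrict a spectrum to a window; raises if the intersection is empty."""
    mask = (s.wavenumbers >= window.lo) & (s.wavenumbers <= window.hi)
    if not np.any(mask):
        raise EmptyWindowError(
            f"window [{window.lo}, {window.hi}] cm^-1 does not intersect grid "
            f"[{s.wavenumbers[0]}, {s.wavenumbers[-1]}]"
        )
    return Spectrum(s.wavenumbers[mask], s.absorbance[mask], dict(s.meta))


def subtract_baseline(
    s: Spectrum, method: str = "linear_endpoints", order: int = 1
) -> Spectrum:
    """Subtract a baseline estimated on the (already cropped) window.

    ``linear_endpoints`` draws a straight line through the first and last
    points of the window, forcing the absorbance at both ends to zero —
    the simplest reproducible background model for an isolated band
    envelope.  ``polynomial`` least-squares fits a polynomial of the given
    order to the full window and subtracts it.
    """
    nu, ab = s.wavenumbers, s.absorbance
    if method == "linear_endpoints":
        if len(s) < 2:
            raise DegenerateInputError("need at least two points for a linear baseline")
        slope = (ab[-1] - ab[0]) / (nu[-1] - nu[0])
        baseline = ab[0] + slope * (nu - nu[0])
    elif method == "polynomial":
        if order >= len(s):
            raise ParameterError(
                f"polynomial order {order} >= number of points {len(s)}: ill-posed"
            )
        coeffs = np.polyfit(nu, ab, order)
        baseline = np.polyval(coeffs, nu)
    else:
        raise ParameterError(f"unknown baseline method {method!r}")
    return s.with_absorbance(ab - baseline)


def normalize(s: Spectrum, mode: str = "max_one") -> Spectrum:
    """Scale a spectrum to unit maximum (``max_one``) or unit trapezoidal
    integral (``area_one``).  Idempotent per mode."""
    ab = s.absorbance
    if mode == "max_one":
        scale = np.max(ab)
        if scale <= 0:
            raise DegenerateInputError("cannot max-normalize a non-positive spectrum")
    elif mode == "area_one":
        scale = np.trapezoid(ab, s.wavenumbers)
        if abs(scale) < 1e-300:
            raise DegenerateInputError("cannot area-normalize a zero-area spectrum")
    else:
        raise ParameterError(f"unknown normalization mode {mode!r}")
    return s.with_absorbance(ab / scale)


def resample_uniform(s: Spectrum, step: float | None = None) -> Spectrum:
    """Linear-interpolate a spectrum onto a uniform grid (for FFT stages)."""
    if step is None:
        step = float(np.min(np.diff(s.wavenumbers)))
    if step <= 0:
        raise ParameterError("resampling step must be positive")
    lo, hi = s.wavenumbers[0], s.wavenumbers[-1]
    n = int(np.floor((hi - lo) / step)) + 1
    grid = lo + step * np.arange(n)
    return Spectrum(grid, np.interp(grid, s.wavenumbers, s.absorbance), dict(s.meta))
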