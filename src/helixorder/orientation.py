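"""Helix orientation order parameters from band intensities.

On a reflecting metal surface only the component of a transition dipole
along the surface normal absorbs (IRRAS surface selection rule), so the
integral intensity c_F of the alpha-helix amide I' band in an anisotropic
film, referenced to the intensity c_R of the same band in a randomly
oriented layer, measures the mean-square cosine of the dipole tilt theta:

    <cos^2 theta> = c_F / (3 c_R)

(a random film has <cos^2 theta> = 1/3, so equal intensities give the
magic angle, 54.74 deg).  The amide-group order parameter is the second
Legendre polynomial

    S_helix = P2(cos theta) = (3 cos^2 theta - 1) / 2,

and, since the amide I transition dipole makes a characteristic angle
alpha (34-38 deg) with the helix long axis, the order parameter of the
helix axes follows from the Legendre addition theorem:

    S_0 = S_helix / P2(cos alpha).

S_0 = 1 means helix axes perfectly aligned with the surface normal, 0
isotropic, negative values a preferentially in-plane (or inverted)
orientation — negative S_0 is a legitimate result, not an error.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import (
    DegenerateInputError,
    ParameterError,
    PipelineError,
    SingularGeometryError,
)

__all__ = [
    "MAGIC_ANGLE_DEG",
    "DEFAULT_ALPHA_RANGE",
    "p2",
    "IntensityPair",
    "OrientationResult",
    "mean_tilt_from_intensities",
    "order_parameter_from_tilt",
    "helix_axis_order_parameter",
    "order_parameter_from_vectors",
    "orientation_pipeline",
]

#: Angle where P2(cos theta) = 0 (degrees).
MAGIC_ANGLE_DEG = float(np.degrees(np.arccos(np.sqrt(1.0 / 3.0))))

#: Characteristic amide I transition-dipole / helix-axis angle range (deg).
DEFAULT_ALPHA_RANGE = (34.0, 38.0)


def p2(x):
    """Second Legendre polynomial P2(x) = (3x^2 - 1)/2."""
    x = np.asarray(x, float)
    out = 0.5 * (3.0 * x**2 - 1.0)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class IntensityPair:
    """Film and random-reference integral intensities of the helix band.

    c_F : integral intensity (absorbance cm^-1) in the oriented film.
    c_R : same quantity for an equivalent randomly oriented monolayer.
    """

    c_F: float
    c_R: float

    def __post_init__(self):
        if self.c_F < 0:
            raise ParameterError(f"c_F must be >= 0, got {self.c_F}")
        if self.c_R <= 0:
            raise DegenerateInputError(f"reference intensity c_R must be > 0, got {self.c_R}")


@dataclass
class OrientationResult:
    """Tilt angle and order parameters with their uncertainty.

    theta_deg is the mean transition-dipole tilt from the surface normal;
    s_helix = P2(cos theta); s0 = s_helix / P2(cos alpha) at the midpoint
    of ``alpha_range``, with ``s0_uncertainty`` the half-spread over the
    range combined (in quadrature) with any propagated intensity
    uncertainty.  ``flags`` records clipping / noise warnings.
    """

    theta_deg: float
    s_helix: float
    s0: float
    s0_uncertainty: float
    alpha_range: tuple[float, float]
    flags: list[str] = field(default_factory=list)
    n_samples: int | None = None

    def to_dict(self) -> dict:
        return {
            "theta_deg": self.theta_deg,
            "s_helix": self.s_helix,
            "s0": self.s0,
            "s0_uncertainty": self.s0_uncertainty,
            "alpha_range_deg": list(self.alpha_range),
            "flags": list(self.flags),
            "n_samples": self.n_samples,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def summary(self) -> str:
        lo, hi = self.alpha_range
        lines = [
            "Helix orientation analysis",
            f"  mean dipole tilt theta : {self.theta_deg:7.2f} deg",
            f"  S_helix = P2(cos th)   : {self.s_helix:7.4f}",
            f"  S_0 (alpha {lo:.0f}-{hi:.0f} deg)  : {self.s0:7.4f} +- {self.s0_uncertainty:.4f}",
        ]
        if self.n_samples:
            lines.append(f"  samples                : {self.n_samples}")
        if self.flags:
            lines.append(f"  flags: {', '.join(self.flags)}")
        return "\n".join(lines)


def mean_tilt_from_intensities(pair: IntensityPair | tuple[float, float]) -> float:
    """Mean transition-dipole tilt (degrees) from the film/reference ratio.

    Implements ``<cos^2 theta> = c_F / (3 c_R)``; ratios outside the
    physical interval [0, 3] are clipped with a warning (equality of film
    and reference gives the magic angle; ratio 3 perfect normal
    alignment).
    """
    if not isinstance(pair, IntensityPair):
        pair = IntensityPair(*pair)
    ratio = pair.c_F / pair.c_R
    if ratio > 3.0:
        warnings.warn(
            f"intensity ratio {ratio:.3f} > 3 is physically impossible; clipping",
            stacklevel=2,
        )
        ratio = 3.0
    cos2 = ratio / 3.0
    return float(np.degrees(np.arccos(np.sqrt(cos2))))


def order_parameter_from_tilt(theta_deg: float) -> float:
    """S_helix = P2(cos theta) for a tilt angle in degrees."""
    if not (0.0 <= theta_deg <= 180.0):
        raise ParameterError(f"tilt angle {theta_deg} deg outside [0, 180]")
    return p2(np.cos(np.radians(theta_deg)))


def _alpha_endpoints(alpha) -> tuple[float, float]:
    if np.isscalar(alpha):
        return float(alpha), float(alpha)
    lo, hi = (float(a) for a in alpha)
    if lo > hi:
        lo, hi = hi, lo
    return lo, hi


def helix_axis_order_parameter(
    s_helix: float,
    alpha=DEFAULT_ALPHA_RANGE,
    s_helix_uncertainty: float = 0.0,
) -> tuple[float, float]:
    """Helix-axis order parameter S_0 = S_helix / P2(cos alpha).

    ``alpha`` may be a single angle or a (lo, hi) range in degrees; for a
    range the midpoint value is returned with the half-spread over the
    range combined in quadrature with the propagated ``s_helix``
    uncertainty.  Alpha at (or a range straddling) the magic angle is a
    singular geometry.
    """
    lo, hi = _alpha_endpoints(alpha)
    p2lo, p2hi = p2(np.cos(np.radians(lo))), p2(np.cos(np.radians(hi)))
    if abs(p2lo) < 1e-9 or abs(p2hi) < 1e-9 or p2lo * p2hi < 0:
        raise SingularGeometryError(
            f"alpha range [{lo}, {hi}] deg touches the magic angle "
            f"({MAGIC_ANGLE_DEG:.2f} deg), where P2(cos alpha) = 0"
        )
    mid = 0.5 * (lo + hi)
    p2mid = p2(np.cos(np.radians(mid)))
    s0 = s_helix / p2mid
    spread = 0.5 * abs(s_helix / p2lo - s_helix / p2hi)
    propagated = abs(s_helix_uncertainty / p2mid)
    return float(s0), float(np.hypot(spread, propagated))


def order_parameter_from_cos2(
    mean_cos2: float,
    alpha=DEFAULT_ALPHA_RANGE,
    s_uncertainty: float = 0.0,
    n_samples: int | None = None,
    flags: list[str] | None = None,
) -> OrientationResult:
    """Build a full OrientationResult from a mean-square cosine."""
    mean_cos2 = float(np.clip(mean_cos2, 0.0, 1.0))
    theta = float(np.degrees(np.arccos(np.sqrt(mean_cos2))))
    s_helix = p2(np.sqrt(mean_cos2))
    s0, s0_unc = helix_axis_order_parameter(s_helix, alpha, s_uncertainty)
    lo, hi = _alpha_endpoints(alpha)
    return OrientationResult(
        theta_deg=theta,
        s_helix=float(s_helix),
        s0=s0,
        s0_uncertainty=s0_unc,
        alpha_range=(lo, hi),
        flags=list(flags or []),
        n_samples=n_samples,
    )


def order_parameter_from_vectors(
    vectors: np.ndarray,
    normal=(0.0, 0.0, 1.0),
    alpha=DEFAULT_ALPHA_RANGE,
) -> OrientationResult:
    """Order parameters from an ensemble of (transition-dipole) vectors.

    ``vectors`` is an (n, 3) array of carbonyl C->O (or other dipole)
    vectors; the mean-square cosine with the membrane normal feeds the
    same S_helix / S_0 chain as the intensity route.  Reported theta is
    arccos of the root-mean-square cosine, folded to [0, 90] deg.
    """
    v = np.asarray(vectors, float)
    if v.ndim != 2 or v.shape[1] != 3 or v.shape[0] == 0:
        raise ParameterError("vectors must be a non-empty (n, 3) array")
    norms = np.linalg.norm(v, axis=1)
    if np.any(norms <= 0):
        raise DegenerateInputError("zero-length vector in ensemble")
    n_hat = np.asarray(normal, float)
    n_hat = n_hat / np.linalg.norm(n_hat)
    cosines = (v @ n_hat) / norms
    return order_parameter_from_cos2(
        float(np.mean(cosines**2)), alpha, n_samples=v.shape[0]
    )


def orientation_pipeline(
    film,
    reference,
    alpha=DEFAULT_ALPHA_RANGE,
    reference_scale: float = 1.0,
) -> OrientationResult:
    """Chain deconvolution results to an orientation result.

    Extracts the alpha-helix component areas of the film and the randomly
    oriented reference (summing if several components share the class),
    applies the intensity-ratio relation, then S_helix and S_0.
    ``reference_scale`` rescales c_R for surface-density matching between
    film and reference (defaults to 1, i.e. intensities already
    comparable).
    """

    def _helix_area(result, side: str) -> float:
        comps = [c for c in result.components if c.assignment == "alpha_helix"]
        if not comps:
            raise PipelineError(f"{side} deconvolution has no alpha-helix component")
        return sum(c.area for c in comps)

    c_f = _helix_area(film, "film")
    c_r = _helix_area(reference, "reference") * reference_scale
    flags: list[str] = []
    ratio = c_f / c_r
    if ratio > 3.0:
        flags.append("intensity_ratio_clipped")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        theta = mean_tilt_from_intensities(IntensityPair(c_f, c_r))
    cos2 = np.cos(np.radians(theta)) ** 2
    return order_parameter_from_cos2(cos2, alpha, flags=flags)
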