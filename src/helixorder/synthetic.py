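"""Seeded synthetic-data generators with planted ground truth.

Every input the analysis pipeline consumes can be generated here:
multi-Lorentzian amide I' spectra, ensembles of ideal helices with
prescribed axis-tilt distributions and carbonyl cone angles, toy bilayers
with planted leaflet separation, two-regime Pi-A isotherms, two-phase
adsorption kinetics, and protein-membrane approach distance series.

Each generator returns ``(data, truth)`` where ``truth`` is a plain dict
sufficient to compute the expected downstream result in closed form;
identical seeds give identical output.  The solution-phase band set
mirrors a solvated flavoprotein rich in alpha-helix: five components at
1689/1675/1653/1639/1623 cm^-1 with the helix band (fwhm 34 cm^-1)
carrying half the total area.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np

from .deconvolution import BandComponent, assign_center
from .exceptions import GeneratorSpecError, ParameterError
from .monolayer import Isotherm, KineticsTrace
from .orientation import p2
from .spectra import Spectrum
from .trajectory import MolecularFrame, Trajectory

__all__ = [
    "GeneratorSpec",
    "generate",
    "solution_phase_bands",
    "membrane_phase_bands",
    "gen_spectrum",
    "gen_helix_ensemble",
    "gen_isotropic_orientations",
    "gen_bilayer",
    "gen_isotherm",
    "gen_kinetics",
    "gen_distance_series",
    "build_chain",
    "build_ideal_helix",
    "chain_to_frame",
]

# ---------------------------------------------------------------------------
# reference band sets
# ---------------------------------------------------------------------------

def solution_phase_bands(total_area: float = 1.0) -> list[BandComponent]:
    """Amide I' component set of the solvated protein.

    Five Lorentzians at 1689, 1675, 1653, 1639 and 1623 cm^-1; the
    alpha-helix band (1653 cm^-1, fwhm 34.0 cm^-1) carries 50% of the
    total area.  Minor-band widths default to 20 cm^-1 (the FSD kernel
    width) and their area split among turn/sheet/coil classes is a
    generator choice.
    """
    spec = [
        (1689.0, 20.0, 0.08),
        (1675.0, 20.0, 0.14),
        (1653.0, 34.0, 0.50),
        (1639.0, 20.0, 0.17),
        (1623.0, 20.0, 0.11),
    ]
    return [
        BandComponent(
            center=c, fwhm=w, area=a * total_area, shape="lorentzian",
            assignment=assign_center(c),
        )
        for c, w, a in spec
    ]


def membrane_phase_bands(total_area: float = 1.0, helix_enhancement: float = 1.6047,
                         aggregated: bool = False) -> list[BandComponent]:
    """Membrane-associated variant: helix band at 1650 cm^-1, fwhm 30.6,
    its area scaled by the surface-selection enhancement factor; an
    optional aggregated-beta band at 1614 cm^-1 models the Mg-free case."""
    bands = [
        (1689.0, 20.0, 0.08),
        (1675.0, 20.0, 0.14),
        (1650.0, 30.6, 0.50 * helix_enhancement),
        (1639.0, 20.0, 0.17),
        (1623.0, 20.0, 0.11),
    ]
    if aggregated:
        bands.append((1614.0, 18.0, 0.10))
    return [
        BandComponent(
            center=c, fwhm=w, area=a * total_area, shape="lorentzian",
            assignment=assign_center(c),
        )
        for c, w, a in bands
    ]


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------

def gen_spectrum(
    components: list[BandComponent] | None = None,
    baseline: tuple[float, float] = (0.0, 0.0),
    noise_sd: float = 0.0,
    grid: tuple[float, float, float] = (1580.0, 1780.0, 0.5),
    seed: int = 0,
):
    """Sum of analytic band shapes + linear baseline + Gaussian noise.

    ``baseline`` is (slope, intercept) in absorbance units per cm^-1 /
    absorbance units.  Returns ``(Spectrum, truth)``.
    """
    if components is None:
        components = solution_phase_bands()
    lo, hi, step = grid
    if step <= 0:
        raise ParameterError("grid step must be positive")
    nu = np.arange(lo, hi + step / 2, step)
    for c in components:
        if not (lo <= c.center <= hi):
            raise ParameterError(f"component at {c.center} outside grid [{lo}, {hi}]")
    ab = np.zeros_like(nu)
    for c in components:
        ab += c.profile(nu)
    slope, intercept = baseline
    ab += intercept + slope * nu
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        ab = ab + rng.normal(0.0, noise_sd, ab.shape)
    truth = {
        "components": [
            {"center": c.center, "fwhm": c.fwhm, "area": c.area,
             "shape": c.shape, "assignment": c.assignment}
            for c in components
        ],
        "baseline": {"slope": slope, "intercept": intercept},
        "noise_sd": noise_sd,
        "seed": seed,
    }
    return Spectrum(nu, ab, {"synthetic": True}), truth


# ---------------------------------------------------------------------------
# ideal helices and orientation ensembles
# ---------------------------------------------------------------------------

_BB_GEOMETRY = {
    # bond lengths (A) and angles (deg) of the peptide backbone
    "n_ca": 1.458, "ca_c": 1.525, "c_n": 1.329, "c_o": 1.231,
    "ang_n_ca_c": 111.2, "ang_ca_c_n": 116.2, "ang_c_n_ca": 121.7,
}


def _place_atom(a, b, c, bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """NeRF placement of atom d bonded to c with given internal coordinates."""
    angle = np.radians(angle_deg)
    dih = -np.radians(dihedral_deg)  # sign convention of the frame below
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [-bond * np.cos(angle),
         bond * np.sin(angle) * np.cos(dih),
         bond * np.sin(angle) * np.sin(dih)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_chain(phi_psi: list[tuple[float, float]], omega: float = 180.0) -> dict[str, np.ndarray]:
    """Backbone (N, CA, C, O) of a polypeptide from per-residue dihedrals.

    ``phi_psi`` lists (phi, psi) in degrees for each residue; residue i's
    psi and residue i+1's phi place the next peptide unit (NeRF internal
    coordinates with standard bond lengths/angles).  O is placed trans to
    the following N.  Returns arrays of shape (n_res, 3) per atom name.
    """
    n_res = len(phi_psi)
    if n_res < 2:
        raise ParameterError("need at least 2 residues")
    g = _BB_GEOMETRY
    N = np.zeros((n_res, 3))
    CA = np.zeros((n_res, 3))
    C = np.zeros((n_res, 3))
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (g["n_ca"], 0.0, 0.0)
    ang = np.radians(g["ang_n_ca_c"])
    C[0] = CA[0] + g["ca_c"] * np.array([-np.cos(ang), np.sin(ang), 0.0])
    for i in range(1, n_res):
        psi_prev = phi_psi[i - 1][1]
        phi_i = phi_psi[i][0]
        N[i] = _place_atom(N[i - 1], CA[i - 1], C[i - 1], g["c_n"], g["ang_ca_c_n"], psi_prev)
        CA[i] = _place_atom(CA[i - 1], C[i - 1], N[i], g["n_ca"], g["ang_c_n_ca"], omega)
        C[i] = _place_atom(C[i - 1], N[i], CA[i], g["ca_c"], g["ang_n_ca_c"], phi_i)
    O = np.zeros((n_res, 3))
    for i in range(n_res):
        O[i] = _place_atom(N[i], CA[i], C[i], g["c_o"], 120.8, phi_psi[i][1] + 180.0)
    return {"N": N, "CA": CA, "C": C, "O": O}


def chain_to_frame(bb: dict[str, np.ndarray], chain_id: str = "A") -> MolecularFrame:
    """Pack a built backbone into a MolecularFrame (poly-alanine labels)."""
    n_res = bb["N"].shape[0]
    names, elements, coords = [], [], []
    for atom in ("N", "CA", "C", "O"):
        names += [atom] * n_res
        elements += [atom[0]] * n_res
        coords.append(bb[atom])
    res_ids = np.tile(np.arange(1, n_res + 1), 4)
    return MolecularFrame(
        atom_name=np.array(names),
        element=np.array(elements),
        res_id=res_ids,
        res_name=np.array(["ALA"] * 4 * n_res),
        chain_id=np.array([chain_id] * 4 * n_res),
        coords=np.vstack(coords),
    )


def build_ideal_helix(n_res: int, phi: float = -57.0, psi: float = -47.0,
                      omega: float = 180.0) -> dict[str, np.ndarray]:
    """Backbone of an ideal polypeptide with uniform dihedrals (canonical
    alpha-helix by default); see :func:`build_chain`."""
    return build_chain([(phi, psi)] * n_res, omega=omega)


@lru_cache(maxsize=4)
def _template_axis(phi: float = -57.0, psi: float = -47.0) -> tuple:
    """Unit helix-axis direction of the ideal-helix template frame."""
    bb = build_ideal_helix(40, phi, psi)
    ca = bb["CA"]
    centered = ca - ca.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    if np.dot(axis, ca[-1] - ca[0]) < 0:
        axis = -axis
    return tuple(axis)


def _rotation_to(v_from: np.ndarray, v_to: np.ndarray) -> np.ndarray:
    """Minimal rotation matrix mapping unit vector v_from to v_to."""
    a, b = np.asarray(v_from, float), np.asarray(v_to, float)
    c = np.cross(a, b)
    d = float(np.dot(a, b))
    if np.linalg.norm(c) < 1e-12:
        if d > 0:
            return np.eye(3)
        # antiparallel: rotate pi about any perpendicular axis
        perp = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(a, [0.0, 1.0, 0.0])
        perp /= np.linalg.norm(perp)
        return 2.0 * np.outer(perp, perp) - np.eye(3)
    skew = np.array(
        [[0, -c[2], c[1]], [c[2], 0, -c[0]], [-c[1], c[0], 0]]
    )
    return np.eye(3) + skew + skew @ skew / (1.0 + d)


def _draw_axes(n: int, axis_tilt, rng: np.random.Generator) -> np.ndarray:
    """Unit axis directions from a tilt distribution spec.

    ``axis_tilt`` is ``("delta", beta_deg)``, ``("gaussian", beta_deg,
    sigma_deg)`` or ``"isotropic"``; azimuths are uniform.
    """
    if axis_tilt == "isotropic" or (
        isinstance(axis_tilt, (tuple, list)) and axis_tilt[0] == "isotropic"
    ):
        cos_t = rng.uniform(-1.0, 1.0, n)
    elif axis_tilt[0] == "delta":
        cos_t = np.full(n, np.cos(np.radians(float(axis_tilt[1]))))
    elif axis_tilt[0] == "gaussian":
        beta, sigma = float(axis_tilt[1]), float(axis_tilt[2])
        draws = rng.normal(beta, sigma, n)
        cos_t = np.cos(np.radians(draws))
    else:
        raise GeneratorSpecError(f"unknown axis tilt spec {axis_tilt!r}")
    sin_t = np.sqrt(np.clip(1.0 - cos_t**2, 0.0, 1.0))
    phi = rng.uniform(0.0, 2 * np.pi, n)
    return np.column_stack([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t])


def gen_helix_ensemble(
    n_helices: int,
    axis_tilt=("delta", 0.0),
    cone_alpha: float = 36.0,
    residues_per_helix: int = 12,
    seed: int = 0,
):
    """Ensemble of ideal helices with planted axis tilts and carbonyl cone.

    Helix backbones (canonical phi/psi, so the dihedral assignment labels
    them) are rotated so their axes follow the requested tilt
    distribution; each backbone carbonyl C->O unit vector is then placed
    on a cone of half-angle ``cone_alpha`` about its helix axis with
    uniform azimuth.  By the Legendre addition theorem the planted
    carbonyl order parameter is P2(cos beta) * P2(cos alpha) in
    expectation over azimuths.

    Returns ``(MolecularFrame, truth)``.
    """
    if n_helices < 1 or residues_per_helix < 4:
        raise ParameterError("need n_helices >= 1 and residues_per_helix >= 4")
    if not (0.0 < cone_alpha < 90.0):
        raise ParameterError(f"cone_alpha must be in (0, 90) deg, got {cone_alpha}")
    rng = np.random.default_rng(seed)
    bb = build_ideal_helix(residues_per_helix)
    template = np.concatenate([bb["N"], bb["CA"], bb["C"], bb["O"]])
    t_axis = np.asarray(_template_axis(), float)
    n_res = residues_per_helix

    axes = _draw_axes(n_helices, axis_tilt, rng)
    letters = [chr(ord("A") + i) for i in range(26)]
    grid_n = int(np.ceil(np.sqrt(n_helices)))
    spacing = 25.0

    names, elements, res_ids, res_names, chain_ids = [], [], [], [], []
    coords = np.empty((n_helices * 4 * n_res, 3))
    for h in range(n_helices):
        rot = _rotation_to(t_axis, axes[h])
        placed = template @ rot.T
        offset = np.array(
            [spacing * (h % grid_n), spacing * (h // grid_n), 0.0]
        )
        placed = placed + offset
        # carbonyl cone about the helix axis, uniform azimuth
        axis = axes[h]
        e1 = np.cross(axis, [0.0, 0.0, 1.0])
        if np.linalg.norm(e1) < 1e-8:
            e1 = np.cross(axis, [1.0, 0.0, 0.0])
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(axis, e1)
        az = rng.uniform(0.0, 2 * np.pi, n_res)
        ca_rad = np.radians(cone_alpha)
        dirs = (
            np.cos(ca_rad) * axis[None, :]
            + np.sin(ca_rad) * (np.cos(az)[:, None] * e1 + np.sin(az)[:, None] * e2)
        )
        c_block = placed[2 * n_res : 3 * n_res]
        placed[3 * n_res : 4 * n_res] = c_block + _BB_GEOMETRY["c_o"] * dirs
        coords[h * 4 * n_res : (h + 1) * 4 * n_res] = placed

        chain = letters[h % 26]
        base = (h // 26) * (n_res + 10) + 1
        rids = np.arange(base, base + n_res)
        for atom in ("N", "CA", "C", "O"):
            names += [atom] * n_res
            elements += [atom[0]] * n_res
            res_ids += list(rids)
            res_names += ["ALA"] * n_res
            chain_ids += [chain] * n_res

    frame = MolecularFrame(
        atom_name=np.array(names),
        element=np.array(elements),
        res_id=np.array(res_ids),
        res_name=np.array(res_names),
        chain_id=np.array(chain_ids),
        coords=coords,
    )
    cos_beta = axes[:, 2]
    truth = {
        "axis_tilts_deg": list(np.degrees(np.arccos(np.clip(cos_beta, -1, 1)))),
        "p2_axis": float(np.mean(p2(cos_beta))),
        "cone_alpha_deg": cone_alpha,
        "expected_carbonyl_s": float(
            np.mean(p2(cos_beta)) * p2(np.cos(np.radians(cone_alpha)))
        ),
        "n_carbonyls": n_helices * n_res,
        "seed": seed,
    }
    return frame, truth


def gen_isotropic_orientations(n: int, seed: int = 0) -> np.ndarray:
    """``n`` unit vectors uniform on the sphere (seeded) — the solution-
    phase (randomly oriented) reference ensemble."""
    rng = np.random.default_rng(seed)
    cos_t = rng.uniform(-1.0, 1.0, n)
    sin_t = np.sqrt(1.0 - cos_t**2)
    phi = rng.uniform(0.0, 2 * np.pi, n)
    return np.column_stack([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t])


# ---------------------------------------------------------------------------
# toy bilayer
# ---------------------------------------------------------------------------

def gen_bilayer(
    nx: int = 18,
    ny: int = 18,
    apl: float = 0.55,
    leaflet_sep: float = 4.0,
    z_jitter: float = 0.0,
    seed: int = 0,
):
    """Toy bilayer of 3-atom pseudo-lipids (P head + two chain beads).

    ``apl`` in nm^2 fixes the lattice spacing and box area; ``leaflet_sep``
    in nm plants the P-plane separation (the membrane thickness);
    ``z_jitter`` (nm) adds Gaussian scatter to the head positions.
    Returns ``(MolecularFrame, truth)``.
    """
    if nx * ny <= 0:
        raise ParameterError("need a positive lattice")
    if apl <= 0:
        raise ParameterError("area per lipid must be positive")
    rng = np.random.default_rng(seed)
    spacing = np.sqrt(apl) * 10.0  # A
    half = leaflet_sep * 10.0 / 2.0
    xs, ys = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    xy = np.column_stack([xs.ravel(), ys.ravel()]) * spacing + spacing / 2.0
    n_leaf = nx * ny

    names, elements, res_ids, res_names, chain_ids, coords = [], [], [], [], [], []
    rid = 1
    for sign, chain in ((1.0, "U"), (-1.0, "L")):
        z_head = sign * half + (
            rng.normal(0.0, z_jitter * 10.0, n_leaf) if z_jitter > 0 else 0.0
        )
        for k in range(n_leaf):
            x, y = xy[k]
            zh = z_head[k] if np.ndim(z_head) else z_head
            for name, el, dz in (("P", "P", 0.0), ("C1", "C", -sign * 4.0), ("C2", "C", -sign * 8.0)):
                names.append(name)
                elements.append(el)
                res_ids.append(rid)
                res_names.append("LIP")
                chain_ids.append(chain)
                coords.append([x, y, zh + dz])
            rid += 1
    box = np.array([nx * spacing, ny * spacing, leaflet_sep * 10.0 + 40.0])
    frame = MolecularFrame(
        atom_name=np.array(names),
        element=np.array(elements),
        res_id=np.array(res_ids),
        res_name=np.array(res_names),
        chain_id=np.array(chain_ids),
        coords=np.array(coords),
        box=box,
    )
    truth = {
        "apl_nm2": apl,
        "leaflet_sep_nm": leaflet_sep,
        "lipids_per_leaflet": n_leaf,
        "n_lipids": 2 * n_leaf,
        "z_jitter_nm": z_jitter,
        "seed": seed,
    }
    return frame, truth


# ---------------------------------------------------------------------------
# isotherms, kinetics, distance series
# ---------------------------------------------------------------------------

def gen_isotherm(
    a_range: tuple[float, float] = (0.4, 1.2),
    n_points: int = 161,
    transition_area: float = 0.60,
    transition_width: float = 0.03,
    dip_depth: float = 0.85,
    base_slope: float = 25.0,
    slope_gain: float = 90.0,
    noise_sd: float = 0.0,
    temperature: float = 24.0,
    seed: int = 0,
):
    """Two-regime compression isotherm with a planted slope-break.

    The pressure gradient magnitude m(A) = (m0 + m1 (A_max - A)) *
    (1 - depth exp(-(A - A_t)^2 / 2w^2)) rises on compression in both
    regimes but collapses near the planted transition area, producing a
    Cs^-1 dip between two regime maxima at ``transition_area`` (nm^2).
    Returns ``(Isotherm, truth)`` with the planted transition pressure.
    """
    lo, hi = a_range
    if not (lo < transition_area < hi):
        raise GeneratorSpecError("transition_area must lie inside a_range")
    a_desc = np.linspace(hi, lo, n_points)  # compression: decreasing area
    a_asc = a_desc[::-1]
    m = (base_slope + slope_gain * (hi - a_asc)) * (
        1.0 - dip_depth * np.exp(-((a_asc - transition_area) ** 2) / (2 * transition_width**2))
    )
    # integrate dPi/dA = -m from the high-area end (Pi ~ 0 at lift-off)
    pi_asc = np.concatenate(
        [[0.0], np.cumsum(-0.5 * (m[1:] + m[:-1]) * np.diff(a_asc))]
    )
    pi_asc = pi_asc - pi_asc[-1]  # Pi = 0 at the largest area
    pi_desc = pi_asc[::-1].copy()
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        pi_desc = pi_desc + rng.normal(0.0, noise_sd, pi_desc.shape)
    pi_at_transition = float(np.interp(transition_area, a_asc, pi_asc))
    iso = Isotherm(a_desc, pi_desc, temperature=temperature, meta={"synthetic": True})
    truth = {
        "transition_area_nm2": transition_area,
        "transition_pressure_mN_per_m": pi_at_transition,
        "seed": seed,
    }
    return iso, truth


def gen_kinetics(
    pi0: float = 10.0,
    delta_fast: float = 3.0,
    delta_slow: float = 1.0,
    tau_fast: float = 120.0,
    slow_end: float = 2000.0,
    injection_time: float = 200.0,
    duration: float = 2200.0,
    dt: float = 2.0,
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """Two-phase adsorption record: fast exponential accumulation followed
    by a slow linear rearrangement phase.

    Defaults emulate a monolayer held at 10 mN/m rising to ~14 mN/m
    within 2000 s of protein injection.  Returns ``(KineticsTrace,
    truth)`` with the planted total pressure increase.
    """
    t = np.arange(0.0, duration + dt / 2, dt)
    pi = np.full_like(t, pi0)
    post = t >= injection_time
    dt_post = t[post] - injection_time
    fast = delta_fast * (1.0 - np.exp(-dt_post / tau_fast))
    slow_span = max(slow_end - injection_time, 1.0)
    slow = delta_slow * np.clip(dt_post / slow_span, 0.0, 1.0)
    pi[post] = pi0 + fast + slow
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        pi = pi + rng.normal(0.0, noise_sd, pi.shape)
    trace = KineticsTrace(t, pi, injection_time=injection_time, meta={"synthetic": True})
    truth = {
        "pi0_mN_per_m": pi0,
        "delta_pi_mN_per_m": delta_fast + delta_slow,
        "two_phase": True,
        "seed": seed,
    }
    return trace, truth


def gen_distance_series(
    d0: float = 30.0,
    d_plateau: float = 2.0,
    t_bind: float = 50.0,
    duration: float = 200.0,
    dt: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """Protein-membrane approach curve: edge-to-edge distance (A) decaying
    to a bound plateau by ``t_bind`` (ns).  Returns ``(times, distances,
    truth)``."""
    t = np.arange(0.0, duration + dt / 2, dt)
    tau = t_bind / 4.0
    d = d_plateau + (d0 - d_plateau) * np.exp(-t / tau)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        d = np.maximum(d + rng.normal(0.0, noise_sd, d.shape), 0.1)
    truth = {
        "min_distance_A": float(d.min()),
        "plateau_A": d_plateau,
        "t_bind_ns": t_bind,
        "seed": seed,
    }
    return t, d, truth


# ---------------------------------------------------------------------------
# spec-driven dispatch
# ---------------------------------------------------------------------------

_KINDS = {
    "spectrum": gen_spectrum,
    "helix_ensemble": gen_helix_ensemble,
    "bilayer": gen_bilayer,
    "isotherm": gen_isotherm,
    "kinetics": gen_kinetics,
    "distance_series": gen_distance_series,
}


@dataclass(frozen=True)
class GeneratorSpec:
    """Declarative generator request: kind + seed + kind-specific params."""

    kind: str
    seed: int = 0
    parameters: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise GeneratorSpecError(
                f"unknown kind {self.kind!r}; choose from {sorted(_KINDS)}"
            )


def generate(spec: GeneratorSpec):
    """Run the generator described by a :class:`GeneratorSpec`.

    Returns whatever the kind's generator returns (data + truth);
    identical specs produce identical output.
    """
    func = _KINDS[spec.kind]
    try:
        return func(seed=spec.seed, **spec.parameters)
    except TypeError as exc:
        raise GeneratorSpecError(
            f"invalid parameters for kind {spec.kind!r}: {exc}"
        ) from exc


def write_truth(path, truth: dict) -> None:
    """Serialize a planted-truth record next to generated data."""
    Path(path).write_text(json.dumps(truth, indent=2, default=float))
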