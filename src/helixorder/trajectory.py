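"""Molecular-coordinate analyses: helix assignment, carbonyl tilts,
membrane geometry, hydrogen bonds and dual-cutoff lipid contacts.

The coordinate route to the helix-axis order parameter mirrors the
spectroscopic one: the amide I transition dipole lies along the backbone
C=O bond, so the angle theta of each helical carbonyl to the membrane
normal, averaged as <cos^2 theta> over carbonyls and frames, feeds the
same P2 chain (S_helix, then S_0) as the band-intensity ratio.

Helix assignment is a backbone-dihedral criterion (phi in [-100, -30],
psi in [-67, -7] deg, runs of >= 4 consecutive residues) — a deliberately
simplified stand-in for hydrogen-bond-aware assignment algorithms, chosen
to label canonical helices correctly.

Units: A internally, nm at reporting boundaries; the membrane normal is
+z by convention.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import (
    DegenerateInputError,
    GeometryError,
    LeafletError,
    ParameterError,
    SelectionError,
)
from .orientation import DEFAULT_ALPHA_RANGE, OrientationResult, order_parameter_from_vectors

__all__ = [
    "MolecularFrame",
    "Trajectory",
    "HelixAssignment",
    "ContactSeries",
    "read_pdb",
    "write_pdb",
    "read_xyz",
    "write_xyz",
    "dihedral",
    "assign_helices",
    "helical_content",
    "carbonyl_tilt_angles",
    "ensemble_order_parameter",
    "membrane_thickness",
    "area_per_lipid",
    "edge_to_edge_distance",
    "min_distance_series",
    "detect_hbonds",
    "dual_cutoff_contacts",
]

HELIX_PHI = (-100.0, -30.0)
HELIX_PSI = (-67.0, -7.0)
MIN_HELIX_RUN = 4


@dataclass
class MolecularFrame:
    """One frame of atomic coordinates.

    Arrays are aligned per atom: names, elements, 1-based residue ids,
    residue names, chain ids and (n, 3) coordinates in A.  ``box`` holds
    orthorhombic box lengths in A (None for non-periodic systems);
    ``membrane_normal`` defaults to +z.
    """

    atom_name: np.ndarray
    element: np.ndarray
    res_id: np.ndarray
    res_name: np.ndarray
    chain_id: np.ndarray
    coords: np.ndarray
    box: np.ndarray | None = None
    membrane_normal: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def __post_init__(self):
        self.coords = np.asarray(self.coords, float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ParameterError("coords must be (n, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise GeometryError("non-finite coordinates")
        n = self.coords.shape[0]
        for name in ("atom_name", "element", "res_id", "res_name", "chain_id"):
            arr = np.asarray(getattr(self, name))
            if arr.shape[0] != n:
                raise ParameterError(f"{name} length {arr.shape[0]} != atom count {n}")
            setattr(self, name, arr)
        if self.box is not None:
            self.box = np.asarray(self.box, float)
            if self.box.shape != (3,) or np.any(self.box <= 0):
                raise ParameterError("box must be three positive lengths (A)")
        self.membrane_normal = np.asarray(self.membrane_normal, float)
        self.membrane_normal = self.membrane_normal / np.linalg.norm(self.membrane_normal)

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    def select(self, atom_name=None, res_name=None, chain_id=None, element=None,
               res_id=None) -> np.ndarray:
        """Indices of atoms matching all given criteria (scalar or sequence)."""
        mask = np.ones(self.n_atoms, bool)
        for arr, crit in (
            (self.atom_name, atom_name),
            (self.res_name, res_name),
            (self.chain_id, chain_id),
            (self.element, element),
            (self.res_id, res_id),
        ):
            if crit is None:
                continue
            crit_arr = np.atleast_1d(crit)
            mask &= np.isin(arr, crit_arr)
        return np.flatnonzero(mask)


@dataclass
class Trajectory:
    """Ordered frames with time stamps in ns; constant atom ordering."""

    frames: list[MolecularFrame]
    times: np.ndarray | None = None

    def __post_init__(self):
        if not self.frames:
            raise ParameterError("trajectory needs at least one frame")
        n = self.frames[0].n_atoms
        if any(f.n_atoms != n for f in self.frames):
            raise ParameterError("atom count varies across frames")
        if self.times is None:
            self.times = np.arange(len(self.frames), dtype=float)
        else:
            self.times = np.asarray(self.times, float)
            if self.times.size != len(self.frames):
                raise ParameterError("times length != number of frames")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, i) -> MolecularFrame:
        return self.frames[i]


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def _frame_from_atom_array(array, box=None) -> MolecularFrame:
    if box is None and array.box is not None:
        box = np.diag(np.asarray(array.box))
        if np.any(box <= 0):
            box = None
    return MolecularFrame(
        atom_name=array.atom_name.astype(str),
        element=array.element.astype(str),
        res_id=array.res_id.astype(int),
        res_name=array.res_name.astype(str),
        chain_id=array.chain_id.astype(str),
        coords=np.asarray(array.coord, float),
        box=box,
    )


def read_pdb(path) -> Trajectory:
    """Read a (possibly multi-model) PDB file into a Trajectory."""
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure(model=None)  # AtomArrayStack; iterates AtomArrays
    frames = []
    for array in stack:
        frames.append(_frame_from_atom_array(array))
    return Trajectory(frames)


def write_pdb(path, traj: Trajectory | MolecularFrame) -> None:
    """Write a Trajectory (as MODEL/ENDMDL records) or single frame."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    if isinstance(traj, MolecularFrame):
        traj = Trajectory([traj])
    frames = traj.frames
    n = frames[0].n_atoms
    template = struc.AtomArray(n)
    f0 = frames[0]
    template.atom_name = f0.atom_name.astype("U6")
    template.element = f0.element.astype("U2")
    template.res_id = f0.res_id.astype(int)
    template.res_name = f0.res_name.astype("U5")
    template.chain_id = np.array([c[:4] for c in f0.chain_id.astype(str)], dtype="U4")
    template.hetero = np.zeros(n, bool)
    if f0.box is not None:
        template.box = np.diag(f0.box)
    if len(frames) == 1:
        template.coord = frames[0].coords
        obj = template
    else:
        obj = struc.from_template(template, np.stack([f.coords for f in frames]))
    pdb = PDBFile()
    pdb.set_structure(obj)
    pdb.write(str(path))


def read_xyz(path, box_sidecar=None) -> Trajectory:
    """Read a plain multi-frame XYZ file (element x y z); optional JSON
    sidecar ``{"box": [lx, ly, lz]}`` supplies the periodic box in A."""
    path = Path(path)
    box = None
    sidecar = Path(box_sidecar) if box_sidecar else path.with_suffix(".box.json")
    if sidecar.exists():
        box = np.asarray(json.loads(sidecar.read_text())["box"], float)
    frames = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].split()[0])
        except ValueError as exc:
            raise ParameterError(f"bad XYZ atom count at line {i + 1}") from exc
        block = lines[i + 2 : i + 2 + n]
        if len(block) < n:
            raise ParameterError("truncated XYZ frame")
        elems, coords = [], []
        for row in block:
            tok = row.split()
            elems.append(tok[0])
            coords.append([float(tok[1]), float(tok[2]), float(tok[3])])
        k = len(elems)
        frames.append(
            MolecularFrame(
                atom_name=np.array(elems),
                element=np.array(elems),
                res_id=np.arange(1, k + 1),
                res_name=np.array(["UNK"] * k),
                chain_id=np.array(["A"] * k),
                coords=np.array(coords),
                box=box,
            )
        )
        i += 2 + n
    return Trajectory(frames)


def write_xyz(path, traj: Trajectory | MolecularFrame, comment: str = "") -> None:
    if isinstance(traj, MolecularFrame):
        traj = Trajectory([traj])
    path = Path(path)
    with open(path, "w") as fh:
        for frame in traj:
            fh.write(f"{frame.n_atoms}\n{comment}\n")
            for el, (x, y, z) in zip(frame.element, frame.coords):
                fh.write(f"{el} {x:.6f} {y:.6f} {z:.6f}\n")
    if traj.frames[0].box is not None:
        path.with_suffix(".box.json").write_text(
            json.dumps({"box": list(map(float, traj.frames[0].box))})
        )


# ---------------------------------------------------------------------------
# helix assignment
# ---------------------------------------------------------------------------

def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle (degrees) of four points."""
    b0 = np.asarray(p1) - np.asarray(p0)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return float(np.degrees(np.arctan2(y, x)))


@dataclass
class HelixAssignment:
    """Per-residue helix labels and contiguous helix segments.

    ``labels`` maps (chain_id, res_id) -> bool; ``segments`` lists
    (chain_id, start_res, end_res) inclusive ranges of >= 4 residues.
    ``skipped`` records residues without complete backbones.
    """

    labels: dict
    segments: list
    skipped: list = field(default_factory=list)

    @property
    def n_helix(self) -> int:
        return sum(bool(v) for v in self.labels.values())

    @property
    def n_assignable(self) -> int:
        return len(self.labels)

    def is_helix(self, chain_id, res_id) -> bool:
        return bool(self.labels.get((str(chain_id), int(res_id)), False))


def _backbone_by_residue(frame: MolecularFrame):
    """{(chain, res_id): {atom_name: coord}} for backbone atoms, ordered."""
    residues: dict = {}
    for i in range(frame.n_atoms):
        name = str(frame.atom_name[i])
        if name not in ("N", "CA", "C", "O"):
            continue
        key = (str(frame.chain_id[i]), int(frame.res_id[i]))
        residues.setdefault(key, {})[name] = frame.coords[i]
    return residues


def assign_helices(frame: MolecularFrame) -> HelixAssignment:
    """Label residues helical by backbone dihedrals.

    A residue is helical when every *defined* backbone dihedral among
    (phi, psi) falls in the helix windows (terminal residues have only
    one defined dihedral and are judged on it alone), and it belongs to a
    run of at least 4 consecutive residues.  Residues missing backbone
    atoms are skipped with a warning list.
    """
    residues = _backbone_by_residue(frame)
    chains: dict = {}
    for (chain, rid) in residues:
        chains.setdefault(chain, []).append(rid)

    labels: dict = {}
    skipped: list = []
    for chain, rids in chains.items():
        rids = sorted(set(rids))
        for rid in rids:
            rec = residues[(chain, rid)]
            if not all(a in rec for a in ("N", "CA", "C")):
                skipped.append((chain, rid))
                continue
            prev = residues.get((chain, rid - 1))
            nxt = residues.get((chain, rid + 1))
            phi = psi = None
            if prev is not None and "C" in prev:
                phi = dihedral(prev["C"], rec["N"], rec["CA"], rec["C"])
            if nxt is not None and "N" in nxt:
                psi = dihedral(rec["N"], rec["CA"], rec["C"], nxt["N"])
            checks = []
            if phi is not None:
                checks.append(HELIX_PHI[0] <= phi <= HELIX_PHI[1])
            if psi is not None:
                checks.append(HELIX_PSI[0] <= psi <= HELIX_PSI[1])
            labels[(chain, rid)] = bool(checks) and all(checks)

    # enforce the minimum run length and collect segments
    segments: list = []
    for chain in sorted(chains):
        rids = sorted(r for (c, r) in labels if c == chain)
        run: list = []
        for rid in rids + [None]:
            if (
                rid is not None
                and labels[(chain, rid)]
                and (not run or rid == run[-1] + 1)
            ):
                run.append(rid)
            else:
                if len(run) >= MIN_HELIX_RUN:
                    segments.append((chain, run[0], run[-1]))
                else:
                    for r in run:
                        labels[(chain, r)] = False
                run = [rid] if (rid is not None and labels.get((chain, rid))) else []
        # trailing run handled by the None sentinel above
    if skipped:
        warnings.warn(f"{len(skipped)} residues skipped (incomplete backbone)", stacklevel=2)
    return HelixAssignment(labels=labels, segments=sorted(segments), skipped=skipped)


def helical_content(traj: Trajectory):
    """Per-frame helical fraction (helix residues / assignable residues).

    Returns ``(fractions, start, end)`` where fractions is a per-frame
    array aligned with ``traj.times``.
    """
    fractions = []
    for frame in traj:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assignment = assign_helices(frame)
        if assignment.n_assignable == 0:
            raise DegenerateInputError("no assignable residues in frame")
        fractions.append(assignment.n_helix / assignment.n_assignable)
    fractions = np.asarray(fractions)
    return fractions, float(fractions[0]), float(fractions[-1])


# ---------------------------------------------------------------------------
# carbonyl tilts and the coordinate-route order parameter
# ---------------------------------------------------------------------------

def _carbonyl_vectors(frame: MolecularFrame, assignment: HelixAssignment) -> np.ndarray:
    residues = _backbone_by_residue(frame)
    vecs = []
    for (chain, rid), rec in residues.items():
        if not assignment.is_helix(chain, rid):
            continue
        if "C" not in rec or "O" not in rec:
            continue
        v = rec["O"] - rec["C"]
        norm = np.linalg.norm(v)
        if norm <= 1e-12:
            raise GeometryError(f"zero-length C->O vector at {chain}:{rid}")
        vecs.append(v / norm)
    return np.asarray(vecs)


def carbonyl_tilt_angles(frame: MolecularFrame, assignment: HelixAssignment) -> np.ndarray:
    """Tilt of each helical backbone C=O bond from the membrane normal,
    folded to [0, 90] degrees (the order parameter is sign-blind)."""
    vecs = _carbonyl_vectors(frame, assignment)
    if vecs.size == 0:
        return np.empty(0)
    cosines = vecs @ frame.membrane_normal
    angles = np.degrees(np.arccos(np.clip(np.abs(cosines), 0.0, 1.0)))
    return angles


def ensemble_order_parameter(
    traj: Trajectory | MolecularFrame,
    assignment: HelixAssignment | None = None,
    alpha=DEFAULT_ALPHA_RANGE,
) -> OrientationResult:
    """Coordinate-route order parameter.

    <cos^2 theta> is averaged over all helical carbonyls and all frames,
    then converted exactly as in the intensity route: theta =
    arccos sqrt<cos^2>, S_helix = P2(cos theta), S_0 = S_helix /
    P2(cos alpha).
    """
    if isinstance(traj, MolecularFrame):
        traj = Trajectory([traj])
    if assignment is None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assignment = assign_helices(traj[0])
    all_vecs = []
    for frame in traj:
        vecs = _carbonyl_vectors(frame, assignment)
        if vecs.size:
            all_vecs.append(vecs)
    if not all_vecs:
        raise DegenerateInputError("no helical carbonyls in trajectory")
    vectors = np.vstack(all_vecs)
    return order_parameter_from_vectors(vectors, traj[0].membrane_normal, alpha)


# ---------------------------------------------------------------------------
# membrane geometry
# ---------------------------------------------------------------------------

def membrane_thickness(frame: MolecularFrame, headgroup_selector: dict | None = None) -> float:
    """Leaflet-to-leaflet distance (nm) between mean headgroup planes.

    Headgroup atoms (default: atoms named ``P``) are split into leaflets
    by the median of their z coordinates; thickness is the distance of
    the two leaflet means along the membrane normal.
    """
    selector = headgroup_selector or {"atom_name": "P"}
    idx = frame.select(**selector)
    if idx.size < 4:
        raise SelectionError(f"headgroup selection matched only {idx.size} atoms")
    z = frame.coords[idx] @ frame.membrane_normal
    zmid = np.median(z)
    upper = z[z >= zmid]
    lower = z[z < zmid]
    if upper.size < 2 or lower.size < 2 or np.ptp(z) < 1e-9:
        raise LeafletError("headgroup atoms do not split into two leaflets")
    return float(abs(upper.mean() - lower.mean())) / 10.0


def area_per_lipid(frame: MolecularFrame, lipids_per_leaflet: int) -> float:
    """In-plane box area divided by lipids per leaflet, in nm^2."""
    if lipids_per_leaflet <= 0:
        raise ParameterError("lipids_per_leaflet must be positive")
    if frame.box is None:
        raise ParameterError("area_per_lipid requires a periodic box")
    return float(frame.box[0] * frame.box[1]) / 100.0 / lipids_per_leaflet


def _min_image(delta: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    if box is not None:
        delta = delta - box * np.round(delta / box)
    return delta


def edge_to_edge_distance(
    frame: MolecularFrame, group_a, group_b, periodic: bool = True
) -> float:
    """Minimum atom-pair distance (A) between two selections.

    Selections are index arrays or ``select()`` keyword dicts; the
    minimum-image convention applies when the frame has a box and
    ``periodic`` is set.
    """
    idx_a = frame.select(**group_a) if isinstance(group_a, dict) else np.asarray(group_a)
    idx_b = frame.select(**group_b) if isinstance(group_b, dict) else np.asarray(group_b)
    if idx_a.size == 0 or idx_b.size == 0:
        raise SelectionError("empty selection in edge-to-edge distance")
    a = frame.coords[idx_a]
    b = frame.coords[idx_b]
    box = frame.box if (periodic and frame.box is not None) else None
    # chunk over the larger group to bound memory
    best = np.inf
    for start in range(0, a.shape[0], 2048):
        delta = a[start : start + 2048, None, :] - b[None, :, :]
        delta = _min_image(delta, box)
        d2 = np.einsum("ijk,ijk->ij", delta, delta)
        best = min(best, float(np.sqrt(d2.min())))
    return best


def min_distance_series(traj: Trajectory, group_a, group_b, periodic: bool = True) -> np.ndarray:
    """Per-frame minimum distance (A) between two selections."""
    return np.array(
        [edge_to_edge_distance(f, group_a, group_b, periodic) for f in traj]
    )


# ---------------------------------------------------------------------------
# hydrogen bonds
# ---------------------------------------------------------------------------

def detect_hbonds(
    frame: MolecularFrame,
    d_cut: float = 3.5,
    angle_cut: float = 30.0,
    mode: str = "dha",
) -> list[tuple[int, int, int]]:
    """Geometric hydrogen-bond detection.

    A bond is recorded when the donor-acceptor distance is <= ``d_cut`` A
    and the D-H...A deviation from linearity is <= ``angle_cut`` degrees.
    Donors/acceptors are N and O atoms; hydrogens are attached to the
    nearest heavy atom within 1.3 A.  ``mode='distance'`` (donor-only
    data, no hydrogens) applies the distance criterion alone and returns
    ``(donor, -1, acceptor)`` triples.  No polar atoms -> empty list.
    """
    polar = np.flatnonzero(np.isin(frame.element, ["N", "O"]))
    if polar.size == 0:
        return []
    coords = frame.coords
    bonds: list[tuple[int, int, int]] = []
    if mode == "distance":
        for ii, i in enumerate(polar):
            for j in polar[ii + 1 :]:
                d = np.linalg.norm(_min_image(coords[i] - coords[j], frame.box))
                if d <= d_cut and d > 0.5:
                    bonds.append((int(i), -1, int(j)))
        return bonds
    if mode != "dha":
        raise ParameterError(f"unknown hbond mode {mode!r}")

    hydrogens = np.flatnonzero(
        (frame.element == "H")
        | np.char.startswith(frame.atom_name.astype(str), "H")
    )
    for h in hydrogens:
        d_heavy = np.linalg.norm(coords[polar] - coords[h], axis=1)
        k = int(np.argmin(d_heavy))
        if d_heavy[k] > 1.3:
            continue  # hydrogen not on a polar donor
        donor = int(polar[k])
        for acc in polar:
            if acc == donor:
                continue
            da = np.linalg.norm(_min_image(coords[donor] - coords[acc], frame.box))
            if da > d_cut or da < 0.5:
                continue
            v_hd = coords[donor] - coords[h]
            v_ha = coords[acc] - coords[h]
            cosang = np.dot(v_hd, v_ha) / (np.linalg.norm(v_hd) * np.linalg.norm(v_ha))
            dha_angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
            deviation = 180.0 - dha_angle
            if deviation <= angle_cut:
                bonds.append((donor, int(h), int(acc)))
    return bonds


# ---------------------------------------------------------------------------
# dual-cutoff contacts
# ---------------------------------------------------------------------------

@dataclass
class ContactSeries:
    """Per-frame contact state from the dual-cutoff (hysteresis) scheme.

    A bound state starts when the distance drops below ``r_lower`` and
    persists until it exceeds ``r_upper`` — suppressing flicker from
    lipid conformational rearrangement as opposed to true dissociation.
    """

    distances: np.ndarray
    bound: np.ndarray
    r_lower: float
    r_upper: float

    @property
    def occupancy(self) -> float:
        return float(np.mean(self.bound))

    @property
    def mean_bound_duration(self) -> float:
        """Mean length (frames) of contiguous bound stretches (0 if none)."""
        runs = []
        count = 0
        for b in self.bound:
            if b:
                count += 1
            elif count:
                runs.append(count)
                count = 0
        if count:
            runs.append(count)
        return float(np.mean(runs)) if runs else 0.0


def dual_cutoff_contacts(
    distances, r_lower: float = 4.0, r_upper: float = 5.5
) -> ContactSeries:
    """Hysteresis thresholding of a per-frame distance series.

    ``r_lower == r_upper`` degenerates to single-cutoff thresholding.
    """
    if r_lower > r_upper:
        raise ParameterError(f"r_lower {r_lower} > r_upper {r_upper}")
    d = np.asarray(distances, float)
    bound = np.zeros(d.shape, bool)
    state = False
    for i, x in enumerate(d):
        if not state and x < r_lower:
            state = True
        elif state and x > r_upper:
            state = False
        bound[i] = state
    return ContactSeries(distances=d, bound=bound, r_lower=r_lower, r_upper=r_upper)
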