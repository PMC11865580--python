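"""Five-helix concave scaffold screening and synthetic bundle generation.

Screening applies the geometric admission rules used for concave binder
scaffolds: exactly five helices, each face-forming helix 18-22 residues
(5-6 turns), fewer than 120 residues in total, and a concave interfacial
face formed by the odd-numbered helices (H1/H3/H5).

The generators build idealized test structures: ``make_toy_bundle`` places
ideal alpha-helices (backbone + Cbeta) antiparallel with their axes on a
circular arc of radius 1/|curvature| (bowed along the helix direction on the
same sphere, so the face Cbeta shell is genuinely near-spherical), and
``make_ball_socket_complex`` builds a convex pseudo-atom ball docked into a
concave shell for interface-sign tests.  Neither stands in for physical
backbone generation; they exist so the screening rules and the convexity
sign test are exercisable end to end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .convexity import (
    CONCAVE,
    ConvexityResult,
    GeometryError,
    signed_convexity,
)
from .structure_io import AtomRecord, StructureModel, model_from_atoms

__all__ = [
    "HelixSegment",
    "ScreenRules",
    "ScaffoldScreenResult",
    "AssignmentError",
    "assign_helices",
    "concave_face_atoms",
    "screen_scaffold",
    "make_toy_bundle",
    "make_ball_socket_complex",
]

# idealized peptide geometry (lengths in A, angles in degrees)
_BOND_C_N = 1.329
_BOND_N_CA = 1.458
_BOND_CA_C = 1.525
_BOND_CA_CB = 1.521
_ANG_CA_C_N = 116.2
_ANG_C_N_CA = 121.7
_ANG_N_CA_C = 111.0
_ANG_N_CA_CB = 110.4
_IMPROPER_C_N_CA_CB = 122.55

PHI_HELIX, PSI_HELIX = -57.0, -47.0
# dihedral admission windows for helix assignment
PHI_WINDOW = (-100.0, -30.0)
PSI_WINDOW = (-80.0, -5.0)


class AssignmentError(Exception):
    """Secondary-structure assignment failed (missing backbone atoms etc.)."""


@dataclass(frozen=True)
class HelixSegment:
    start_residue: int
    end_residue: int
    chain_id: str

    @property
    def length(self) -> int:
        return self.end_residue - self.start_residue + 1


@dataclass
class ScreenRules:
    helix_len_min: int = 18
    helix_len_max: int = 22
    max_total_length: int = 119
    require_n_helices: int = 5
    face_helix_indices: tuple[int, ...] = (1, 3, 5)  # 1-based, N to C


@dataclass
class ScaffoldScreenResult:
    n_helices: int
    total_length: int
    helix_lengths: list[int]
    interfacial_helix_ids: list[int]
    face_convexity: ConvexityResult | None
    verdicts: dict[str, bool]
    passes: bool


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """IUPAC torsion angle p0-p1-p2-p3 in degrees."""
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    return math.degrees(math.atan2(m1 @ n2, n1 @ n2))


def place_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray,
    bond: float, angle_deg: float, torsion_deg: float,
) -> np.ndarray:
    """NeRF placement: position D with |CD| = bond, angle(B,C,D) and
    torsion(A,B,C,D) as requested."""
    ang, tor = math.radians(angle_deg), math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array(
        [-bond * math.cos(ang), bond * math.sin(ang) * math.cos(tor),
         -bond * math.sin(ang) * math.sin(tor)]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


def _ideal_helix_template(n_res: int, rise_per_residue: float = 1.5) -> dict[str, np.ndarray]:
    """Ideal alpha-helix backbone (+CB), axis along +y, CA centroid at origin.

    Returns arrays of shape (n_res, 3) for N, CA, C, CB.
    """
    N = [np.array([0.0, 0.0, 0.0])]
    CA = [np.array([_BOND_N_CA, 0.0, 0.0])]
    ang = math.radians(180.0 - _ANG_N_CA_C)
    C = [CA[0] + _BOND_CA_C * np.array([math.cos(ang), math.sin(ang), 0.0])]
    for _ in range(1, n_res):
        N.append(place_atom(N[-1], CA[-1], C[-1], _BOND_C_N, _ANG_CA_C_N, PSI_HELIX))
        CA.append(place_atom(CA[-1], C[-1], N[-1], _BOND_N_CA, _ANG_C_N_CA, 180.0))
        C.append(place_atom(C[-1], N[-1], CA[-1], _BOND_CA_C, _ANG_N_CA_C, PHI_HELIX))
    CB = [
        place_atom(C[i], N[i], CA[i], _BOND_CA_CB, _ANG_N_CA_CB, _IMPROPER_C_N_CA_CB)
        for i in range(n_res)
    ]
    coords = {k: np.stack(v) for k, v in (("N", N), ("CA", CA), ("C", C), ("CB", CB))}

    ca = coords["CA"]
    centroid = ca.mean(axis=0)
    ca0 = ca - centroid
    # principal axis of the CA trace = helix axis
    _, _, vt = np.linalg.svd(ca0, full_matrices=False)
    axis = vt[0]
    if axis @ (ca[-1] - ca[0]) < 0:
        axis = -axis
    # rotate axis onto +y
    y = np.array([0.0, 1.0, 0.0])
    v = np.cross(axis, y)
    s, cth = np.linalg.norm(v), float(axis @ y)
    if s < 1e-12:
        R = np.eye(3) if cth > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        R = np.eye(3) + vx + vx @ vx * ((1 - cth) / s**2)
    natural_rise = np.ptp(ca0 @ axis) / max(n_res - 1, 1)
    scale = rise_per_residue / natural_rise
    out = {}
    for k, arr in coords.items():
        local = (arr - centroid) @ R.T
        local[:, 1] *= scale
        out[k] = local
    return out


def _backbone_map(model: StructureModel) -> tuple[str, list[tuple[int, dict[str, np.ndarray]]]]:
    if len(model.chains) != 1:
        raise AssignmentError(
            f"helix assignment expects a single chain, got {sorted(model.chains)}"
        )
    chain_id = next(iter(model.chains))
    residues: dict[int, dict[str, np.ndarray]] = {}
    order: list[int] = []
    for a in model.atoms:
        if a.residue_number not in residues:
            residues[a.residue_number] = {}
            order.append(a.residue_number)
        residues[a.residue_number][a.name] = a.coords
    out = []
    for num in order:
        atoms = residues[num]
        missing = {"N", "CA", "C"} - set(atoms)
        if missing:
            raise AssignmentError(
                f"residue {chain_id}/{num}: missing backbone atom(s) {sorted(missing)}"
            )
        out.append((num, atoms))
    return chain_id, out


def assign_helices(model: StructureModel) -> list[HelixSegment]:
    """Helical segments from backbone dihedrals.

    A residue is raw-helical when its phi and psi (where defined) fall in
    (phi in [-100, -30], psi in [-80, -5]); flags are smoothed over a
    4-residue window by closing lone gaps (a single non-helical residue
    flanked by helical neighbours is absorbed, runs are never extended past
    their flanks) and maximal runs of >= 6 residues become segments, N to C.
    """
    chain_id, residues = _backbone_map(model)
    n = len(residues)
    if n < 8:
        raise AssignmentError(f"need >= 8 residues with complete backbone, got {n}")
    raw = np.zeros(n, dtype=bool)
    for i, (num, atoms) in enumerate(residues):
        ok = True
        if i > 0:
            prev_c = residues[i - 1][1]["C"]
            phi = dihedral(prev_c, atoms["N"], atoms["CA"], atoms["C"])
            ok &= PHI_WINDOW[0] <= phi <= PHI_WINDOW[1]
        if i < n - 1:
            next_n = residues[i + 1][1]["N"]
            psi = dihedral(atoms["N"], atoms["CA"], atoms["C"], next_n)
            ok &= PSI_WINDOW[0] <= psi <= PSI_WINDOW[1]
        raw[i] = ok
    smooth = raw.copy()
    smooth[1:-1] |= raw[:-2] & raw[2:]
    segments = []
    i = 0
    while i < n:
        if smooth[i]:
            j = i
            while j + 1 < n and smooth[j + 1]:
                j += 1
            if j - i + 1 >= 6:
                segments.append(
                    HelixSegment(residues[i][0], residues[j][0], chain_id)
                )
            i = j + 1
        else:
            i += 1
    return segments


def concave_face_atoms(
    model: StructureModel,
    helices: Sequence[HelixSegment],
    face_helix_indices: Sequence[int] = (1, 3, 5),
    min_projection_cos: float = 0.5,
) -> np.ndarray:
    """Cbeta coordinates (CA for GLY) of face-helix residues whose side
    chains point toward the open face.

    The open-face direction is the bundle-axis-orthogonal component of the
    vector from the bundle CA centroid to the face-helix CA centroid; a
    residue is kept when the cosine between its CA->CB direction and that
    face direction exceeds ``min_projection_cos``.  The threshold keeps the
    selected shell radially consistent (a looser 0 keeps every residue that
    merely leans face-ward and admits tangentially pointing side chains).
    """
    for k in face_helix_indices:
        if not 1 <= k <= len(helices):
            raise GeometryError(f"face helix {k} out of range (have {len(helices)})")
    ca_entries: list[tuple[int, np.ndarray]] = []
    per_res: dict[int, dict[str, np.ndarray]] = {}
    for a in model.atoms:
        per_res.setdefault(a.residue_number, {})[a.name] = a.coords
        if a.name == "CA":
            ca_entries.append((a.residue_number, a.coords))
    ca_all = np.stack([c for _, c in ca_entries])
    centroid = ca_all.mean(axis=0)
    _, _, vt = np.linalg.svd(ca_all - centroid, full_matrices=False)
    axis = vt[0]

    face_res: set[int] = set()
    for k in face_helix_indices:
        seg = helices[k - 1]
        face_res.update(range(seg.start_residue, seg.end_residue + 1))
    face_ca = np.stack([c for num, c in ca_entries if num in face_res])
    face_dir = face_ca.mean(axis=0) - centroid
    face_dir -= (face_dir @ axis) * axis
    nrm = np.linalg.norm(face_dir)
    if nrm < 1e-9:
        raise GeometryError("face helices are centred on the bundle: no face direction")
    face_dir /= nrm

    res_names = {a.residue_number: a.residue_name for a in model.atoms}
    face = []
    for num in sorted(face_res):
        atoms = per_res.get(num, {})
        if "CA" not in atoms:
            continue
        ca = atoms["CA"]
        cb = atoms.get("CB", ca if res_names.get(num) == "GLY" else None)
        if cb is None or np.array_equal(cb, ca):
            continue
        v = cb - ca
        if (v / np.linalg.norm(v)) @ face_dir > min_projection_cos:
            face.append(cb)
    if len(face) < 4:
        raise GeometryError(f"only {len(face)} face atoms (< 4): degenerate face")
    return np.stack(face)


def screen_scaffold(
    model: StructureModel,
    rules: ScreenRules | None = None,
    ransac_threshold: float = 1.0,
    max_iterations: int = 20_000,
    seed: int = 0,
) -> ScaffoldScreenResult:
    """Apply all scaffold admission rules; every verdict is reported even
    when an earlier rule already fails."""
    rules = rules or ScreenRules()
    helices = assign_helices(model)
    chain_id = next(iter(model.chains))
    total_length = len(model.residues(chain_id))
    lengths = [h.length for h in helices]

    verdicts = {
        "n_helices": len(helices) == rules.require_n_helices,
        "total_length": total_length <= rules.max_total_length,
    }
    face_ids = [k for k in rules.face_helix_indices if k <= len(helices)]
    verdicts["helix_lengths"] = bool(face_ids) and all(
        rules.helix_len_min <= helices[k - 1].length <= rules.helix_len_max
        for k in face_ids
    )
    face_convexity = None
    try:
        face = concave_face_atoms(model, helices, face_ids)
        face_convexity = signed_convexity(
            model, set(model.chains), face,
            ransac_threshold=ransac_threshold,
            max_iterations=max_iterations, seed=seed,
        )
        verdicts["concave_face"] = face_convexity.sign == CONCAVE
    except GeometryError:
        verdicts["concave_face"] = False
    return ScaffoldScreenResult(
        n_helices=len(helices),
        total_length=total_length,
        helix_lengths=lengths,
        interfacial_helix_ids=face_ids,
        face_convexity=face_convexity,
        verdicts=verdicts,
        passes=all(verdicts.values()),
    )


def make_toy_bundle(
    n_helices: int = 5,
    helix_length: int = 19,
    loop_length: int = 3,
    face_curvature: float = -0.05,
    rise_per_residue: float = 1.5,
    helix_spacing: float = 10.0,
    back_depth: float = 10.0,
    jitter_sigma: float = 0.05,
    seed: int = 0,
    chain_id: str = "A",
) -> StructureModel:
    """Parametric antiparallel helix bundle with a tunable face curvature.

    Odd helices (H1, H3, H5, ...) form the front row; their axes lie on a
    sphere of radius 1/|face_curvature| so the face is concave for negative
    curvature, convex for positive, and flat at 0.  Even helices buttress the
    back.  Helix residues are ALA (backbone + CB), loops GLY; a small
    Gaussian jitter (default 0.05 A) varies fixtures across seeds without
    leaving the helical dihedral windows.
    """
    if n_helices < 2:
        raise ValueError("need at least 2 helices")
    if abs(face_curvature) > 0.2:
        raise ValueError("|face_curvature| must be <= 0.2 (radius >= 5 A)")
    if helix_spacing < 7.0 or back_depth < 7.0:
        raise ValueError("helix axes closer than 7 A would clash")
    rng = np.random.default_rng(seed)
    template = _ideal_helix_template(helix_length, rise_per_residue)

    n_front = (n_helices + 1) // 2
    front_x = [(j - (n_front - 1) / 2.0) * helix_spacing for j in range(n_front)]

    curved = face_curvature != 0.0
    if curved:
        R = 1.0 / abs(face_curvature)
        sigma = 1.0 if face_curvature > 0 else -1.0  # +1 convex, -1 concave
        C = np.array([0.0, 0.0, -sigma * R])

        def wrap(x: float, t: float, z: float, u_off: float, rho: float) -> np.ndarray:
            u = u_off + x / rho
            v = t / rho
            w = np.array(
                [math.cos(v) * math.sin(u), math.sin(v), sigma * math.cos(v) * math.cos(u)]
            )
            return C + (rho + sigma * z) * w

    helix_coords: list[dict[str, np.ndarray]] = []
    for k in range(n_helices):
        d = 1.0 if k % 2 == 0 else -1.0
        if k % 2 == 0:
            x0, rho = front_x[k // 2], (1.0 / abs(face_curvature)) if curved else 0.0
            z_row = 0.0
        else:
            if (k + 1) // 2 < n_front:
                x0 = 0.5 * (front_x[(k - 1) // 2] + front_x[(k + 1) // 2])
            else:  # trailing back helix (even helix count): hang past the last front
                x0 = front_x[(k - 1) // 2] + 0.5 * helix_spacing
            rho = (1.0 / abs(face_curvature) + (-sigma * back_depth)) if curved else 0.0
            z_row = -back_depth
        placed = {}
        for name, arr in template.items():
            pts = arr.copy()
            pts[:, 0] *= d  # rotate pi about z for reversed helices
            pts[:, 1] *= d
            if curved:
                u_off = x0 / (1.0 / abs(face_curvature))
                rho_k = rho if k % 2 else 1.0 / abs(face_curvature)
                placed[name] = np.stack(
                    [wrap(p[0], p[1], p[2], u_off, rho_k) for p in pts]
                )
            else:
                placed[name] = pts + np.array([x0, 0.0, z_row])
        helix_coords.append(placed)

    atoms: list[AtomRecord] = []
    serial = 0
    resnum = 0

    def add_atom(name: str, element: str, resname: str, num: int, xyz: np.ndarray) -> None:
        nonlocal serial
        serial += 1
        atoms.append(
            AtomRecord(
                serial=serial, name=name, element=element, residue_name=resname,
                residue_number=num, chain_id=chain_id,
                coords=xyz + rng.normal(0.0, jitter_sigma, size=3),
                is_heavy=True, is_polar=element in ("N", "O"),
                vdw_radius={"N": 1.65, "O": 1.40}.get(element, 1.87),
            )
        )

    for k in range(n_helices):
        h = helix_coords[k]
        for i in range(helix_length):
            resnum += 1
            add_atom("N", "N", "ALA", resnum, h["N"][i])
            add_atom("CA", "C", "ALA", resnum, h["CA"][i])
            add_atom("C", "C", "ALA", resnum, h["C"][i])
            add_atom("CB", "C", "ALA", resnum, h["CB"][i])
        if k == n_helices - 1 or loop_length == 0:
            continue
        # loop: residues 1..L-1 continue from the helix end by NeRF with
        # extended torsions (phi -150, psi +150), so every loop residue owns
        # at least one dihedral far outside the helical windows; the final
        # residue is anchored from the next helix so its first residue keeps
        # an exactly helical phi.  The loop is a geometric placeholder and is
        # not required to close the chain.
        prev = {n: helix_coords[k][n][-1] for n in ("N", "CA", "C")}
        nxt = {n: helix_coords[k + 1][n][0] for n in ("N", "CA", "C")}
        phi_loop, psi_loop = -150.0, 150.0
        a, b, c = prev["N"], prev["CA"], prev["C"]
        fwd: list[np.ndarray] = []  # N, CA, C triples flattened
        # first loop N keeps the last helix residue's psi helical
        n_atom = place_atom(a, b, c, _BOND_C_N, _ANG_CA_C_N, PSI_HELIX)
        for j in range(max(loop_length - 1, 1)):
            ca_atom = place_atom(b, c, n_atom, _BOND_N_CA, _ANG_C_N_CA, 180.0)
            c_atom = place_atom(c, n_atom, ca_atom, _BOND_CA_C, _ANG_N_CA_C, phi_loop)
            fwd.extend([n_atom, ca_atom, c_atom])
            a, b, c = n_atom, ca_atom, c_atom
            n_atom = place_atom(a, b, c, _BOND_C_N, _ANG_CA_C_N, psi_loop)
        if loop_length >= 2:
            # last loop residue anchored from the next helix: C sets the next
            # helix's phi; CA sets omega; N sets this residue's psi = +150
            c_last = place_atom(nxt["C"], nxt["CA"], nxt["N"], _BOND_C_N, _ANG_C_N_CA, PHI_HELIX)
            ca_last = place_atom(nxt["CA"], nxt["N"], c_last, _BOND_CA_C, _ANG_CA_C_N, 180.0)
            n_last = place_atom(nxt["N"], c_last, ca_last, _BOND_N_CA, _ANG_N_CA_C, psi_loop)
            fwd.extend([n_last, ca_last, c_last])
        else:
            # single-residue loop: keep the forward N, anchor CA/C from the
            # next helix
            c_last = place_atom(nxt["C"], nxt["CA"], nxt["N"], _BOND_C_N, _ANG_C_N_CA, PHI_HELIX)
            ca_last = place_atom(nxt["CA"], nxt["N"], c_last, _BOND_CA_C, _ANG_CA_C_N, 180.0)
            fwd = [fwd[0], ca_last, c_last]
        for j in range(loop_length):
            resnum += 1
            add_atom("N", "N", "GLY", resnum, fwd[3 * j])
            add_atom("CA", "C", "GLY", resnum, fwd[3 * j + 1])
            add_atom("C", "C", "GLY", resnum, fwd[3 * j + 2])

    model = model_from_atoms(atoms, source_id=f"toy_bundle_c{face_curvature:+.3f}_s{seed}")
    return model


def make_ball_socket_complex(
    ball_radius: float = 6.0,
    socket_radius: float = 11.0,
    n_ball: int = 120,
    n_socket: int = 140,
    cap_half_angle_deg: float = 60.0,
    shell_thickness: float = 3.0,
    seed: int = 0,
) -> StructureModel:
    """Convex pseudo-atom ball (chain A) docked into a concave socket shell
    (chain B), for exercising interface detection and the convexity sign."""
    rng = np.random.default_rng(seed)
    from .surface import golden_spiral_points

    atoms: list[AtomRecord] = []
    serial = 0

    def add(chain: str, num: int, xyz: np.ndarray) -> None:
        nonlocal serial
        serial += 1
        atoms.append(
            AtomRecord(
                serial=serial, name="CA", element="C", residue_name="GLY",
                residue_number=num, chain_id=chain,
                coords=xyz + rng.normal(0.0, 0.05, size=3),
                is_heavy=True, is_polar=False, vdw_radius=1.87,
            )
        )

    num = 0
    for p in golden_spiral_points(n_ball) * ball_radius:
        num += 1
        add("A", num, p)
    cap_cos = math.cos(math.radians(cap_half_angle_deg))
    num = 0
    for radius in (socket_radius, socket_radius + shell_thickness):
        for p in golden_spiral_points(n_socket):
            if p[2] >= cap_cos:
                num += 1
                add("B", num, p * radius)
    return model_from_atoms(atoms, source_id="ball_socket")
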