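"""Solvent-accessible surface area and interface definition.

Per-atom SASA is computed with the Shrake-Rupley rolling-probe algorithm
using a deterministic golden-spiral point set, so that results are exactly
reproducible and per-point occlusion is monotone: adding atoms can only
remove accessible points, which makes every apo-minus-holo difference
(dSASA) non-negative by construction.

Interfacial atoms are the heavy atoms whose SASA drops by at least a
threshold (default 0.5 A^2) between the isolated partner (apo) and the full
complex (holo).  Buried area is the dSASA sum, split into polar (N, O) and
apolar contributions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import AtomRecord, StructureModel, model_from_atoms, select_atoms

__all__ = [
    "SasaMap",
    "InterfacePartition",
    "BuriedArea",
    "SurfaceError",
    "PartitionError",
    "golden_spiral_points",
    "compute_sasa",
    "interfacial_atoms",
    "interfacial_residues",
    "buried_area",
    "partition_to_tsv",
]


class SurfaceError(Exception):
    """Numeric or input failure in a surface computation."""


class PartitionError(SurfaceError):
    """Invalid partner chain sets for an interface partition."""


def golden_spiral_points(n: int) -> np.ndarray:
    """``n`` quasi-uniform points on the unit sphere (golden-section spiral)."""
    i = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = math.pi * (1.0 + math.sqrt(5.0)) * i
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


@dataclass
class SasaMap:
    """Per-atom accessible areas (A^2) aligned to a model's atom order."""

    areas: np.ndarray
    probe_radius: float
    n_sphere_points: int

    def __post_init__(self) -> None:
        self.areas = np.asarray(self.areas, dtype=float)


@dataclass
class InterfacePartition:
    """Interfacial heavy atoms of the two partners with their dSASA.

    Atom entries are ``(index_into_model, dsasa)``; the two partners' sets
    are disjoint by construction (disjoint chain sets).
    """

    partner_a_atoms: list[tuple[int, float]]
    partner_b_atoms: list[tuple[int, float]]
    partner_a_chains: frozenset[str]
    partner_b_chains: frozenset[str]
    dsasa_threshold: float
    probe_radius: float
    model: StructureModel


@dataclass
class BuriedArea:
    """Polar/apolar split of the summed interfacial dSASA, in A^2."""

    polar: float
    apolar: float
    total: float
    per_partner: dict[str, tuple[float, float]] = field(default_factory=dict)


def compute_sasa(
    model: StructureModel,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
) -> SasaMap:
    """Shrake-Rupley SASA over heavy atoms (hydrogens get area 0)."""
    if probe_radius <= 0:
        raise ValueError("probe_radius must be positive")
    if n_sphere_points < 60:
        raise ValueError("n_sphere_points must be >= 60")
    heavy_idx = model.heavy_indices()
    if heavy_idx.size == 0:
        raise SurfaceError("model has no heavy atoms")
    coords = np.stack([model.atoms[i].coords for i in heavy_idx])
    if not np.all(np.isfinite(coords)):
        bad = heavy_idx[~np.all(np.isfinite(coords), axis=1)][0]
        a = model.atoms[int(bad)]
        raise SurfaceError(
            f"non-finite coordinates on atom {a.serial} {a.chain_id}/{a.residue_number}/{a.name}"
        )
    radii = np.array([model.atoms[i].vdw_radius for i in heavy_idx]) + probe_radius
    unit = golden_spiral_points(n_sphere_points)

    tree = cKDTree(coords)
    max_r = radii.max()
    areas_heavy = np.zeros(len(heavy_idx))
    # neighbour pairs within the largest possible occlusion distance
    pairs = tree.query_ball_point(coords, r=radii + max_r)
    for k in range(len(heavy_idx)):
        neigh = [j for j in pairs[k] if j != k]
        pts = coords[k] + radii[k] * unit
        if neigh:
            nb = np.array(neigh, dtype=int)
            d2 = ((pts[:, None, :] - coords[nb][None, :, :]) ** 2).sum(axis=2)
            exposed = np.all(d2 >= (radii[nb] ** 2)[None, :], axis=1)
            n_exp = int(exposed.sum())
        else:
            n_exp = n_sphere_points
        areas_heavy[k] = 4.0 * math.pi * radii[k] ** 2 * n_exp / n_sphere_points

    areas = np.zeros(len(model.atoms))
    areas[heavy_idx] = areas_heavy
    return SasaMap(areas=areas, probe_radius=probe_radius, n_sphere_points=n_sphere_points)


def interfacial_atoms(
    model: StructureModel,
    partner_a: set[str],
    partner_b: set[str],
    dsasa_threshold: float = 0.5,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
) -> InterfacePartition:
    """Heavy atoms buried by complexation (dSASA = apo - holo >= threshold).

    Apo SASA is computed on each partner's atoms extracted from the complex
    coordinates; holo SASA on the union, with identical sampling.
    """
    partner_a, partner_b = set(partner_a), set(partner_b)
    if not partner_a or not partner_b:
        raise PartitionError("partner chain sets must be non-empty")
    if partner_a & partner_b:
        raise PartitionError(f"partner chain sets overlap: {sorted(partner_a & partner_b)}")
    missing = (partner_a | partner_b) - set(model.chains)
    if missing:
        raise PartitionError(f"chains not in model: {sorted(missing)}")

    complex_model = model.subset(sorted(partner_a) + sorted(partner_b))
    holo = compute_sasa(complex_model, probe_radius, n_sphere_points)
    # map complex_model atom order back to original model indices
    orig_index = {}
    for cid in complex_model.chains:
        start, stop = model.chains[cid]
        cstart, cstop = complex_model.chains[cid]
        for off in range(stop - start):
            orig_index[cstart + off] = start + off

    out: dict[str, list[tuple[int, float]]] = {"a": [], "b": []}
    for key, chains in (("a", partner_a), ("b", partner_b)):
        apo_model = model.subset(sorted(chains))
        apo = compute_sasa(apo_model, probe_radius, n_sphere_points)
        # apo_model order is chain-contiguous, same within-chain order as complex
        for cid in apo_model.chains:
            astart, astop = apo_model.chains[cid]
            cstart, _ = complex_model.chains[cid]
            for off in range(astop - astart):
                d = apo.areas[astart + off] - holo.areas[cstart + off]
                if d >= dsasa_threshold and apo_model.atoms[astart + off].is_heavy:
                    out[key].append((orig_index[cstart + off], float(d)))
    return InterfacePartition(
        partner_a_atoms=out["a"],
        partner_b_atoms=out["b"],
        partner_a_chains=frozenset(partner_a),
        partner_b_chains=frozenset(partner_b),
        dsasa_threshold=dsasa_threshold,
        probe_radius=probe_radius,
        model=model,
    )


def interfacial_residues(partition: InterfacePartition) -> dict[str, list[tuple[str, int, str]]]:
    """Residue-level view: a residue is interfacial iff >= 1 interfacial atom."""
    view: dict[str, list[tuple[str, int, str]]] = {"a": [], "b": []}
    for key, entries in (("a", partition.partner_a_atoms), ("b", partition.partner_b_atoms)):
        seen = set()
        for idx, _ in entries:
            a = partition.model.atoms[idx]
            k = (a.chain_id, a.residue_number, a.residue_name)
            if k not in seen:
                seen.add(k)
                view[key].append(k)
    return view


def buried_area(partition: InterfacePartition, model: StructureModel) -> BuriedArea:
    """Polar/apolar dSASA sums over both partners (summed; per-partner kept)."""
    if model is not partition.model and len(model.atoms) != len(partition.model.atoms):
        raise SurfaceError("partition was not produced from this model")
    per_partner: dict[str, tuple[float, float]] = {}
    polar = apolar = 0.0
    for key, entries in (("a", partition.partner_a_atoms), ("b", partition.partner_b_atoms)):
        p = sum(d for i, d in entries if model.atoms[i].is_polar)
        ap = sum(d for i, d in entries if not model.atoms[i].is_polar)
        per_partner[key] = (p, ap)
        polar += p
        apolar += ap
    return BuriedArea(polar=polar, apolar=apolar, total=polar + apolar, per_partner=per_partner)


def partition_to_tsv(partition: InterfacePartition, path: str | Path) -> None:
    """One row per interfacial atom: partner, chain, residue, atom, element, dsasa."""
    rows = ["partner\tchain\tresidue_number\tresidue_name\tatom\telement\tdsasa"]
    for partner, entries in (("a", partition.partner_a_atoms), ("b", partition.partner_b_atoms)):
        for idx, d in entries:
            a = partition.model.atoms[idx]
            rows.append(
                f"{partner}\t{a.chain_id}\t{a.residue_number}\t{a.residue_name}"
                f"\t{a.name}\t{a.element}\t{d:.3f}"
            )
    Path(path).write_text("\n".join(rows) + "\n")
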