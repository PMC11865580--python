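"""Signed interface convexity from RANSAC sphere fits.

The shape of an interfacial atom patch is summarized by the sphere that best
fits its coordinates under RANSAC (minimal samples of 4 points, exact-sphere
solve, inlier threshold in A, default 1.0, up to 100k iterations).  The
convexity of the patch is the reciprocal of the fitted radius, signed:
negative for concave (pocket-like) patches, positive for convex ones.

The sign comes from an inner-product test rooted at the interfacial-atom
centroid g_i: with g_p the centroid of all heavy atoms of the molecule and c
the fitted sphere center, the patch is concave when (g_p - g_i).(c - g_i) is
negative — i.e. the sphere center lies on the opposite side of the patch
from the body of the protein.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .structure_io import AtomRecord, StructureModel, select_atoms
from .surface import BuriedArea, InterfacePartition, buried_area, interfacial_atoms

__all__ = [
    "SphereFit",
    "ConvexityResult",
    "InterfaceProfile",
    "GeometryError",
    "FitFailureError",
    "IndeterminateSignError",
    "fit_sphere_lsq",
    "fit_sphere_ransac",
    "surface_sign",
    "signed_convexity",
    "profile_interface",
    "profiles_to_tsv",
]

CONCAVE = -1
CONVEX = 1

_COND_LIMIT = 1e8  # reject near-coplanar 4-point samples


class GeometryError(Exception):
    """Degenerate geometry (too few points, coplanar/collinear sets)."""


class FitFailureError(Exception):
    """RANSAC exhausted its iteration budget without a valid sphere."""


class IndeterminateSignError(Exception):
    """The concave/convex inner product is exactly zero."""


@dataclass
class SphereFit:
    center: np.ndarray
    radius: float
    inlier_indices: np.ndarray
    inlier_rmse: float
    n_iterations_used: int
    seed: int | None = None

    @property
    def inlier_fraction_of(self) -> int:
        return len(self.inlier_indices)


@dataclass
class ConvexityResult:
    """Signed convexity (1/A) of an interfacial patch."""

    signed_convexity: float
    radius: float
    sign: int
    inlier_fraction: float
    dot_product: float
    fit: SphereFit | None = None


@dataclass
class InterfaceProfile:
    """One interface-profile record: buried areas plus per-partner convexity."""

    source_id: str
    partner_a_chains: str
    partner_b_chains: str
    n_interfacial_a: int
    n_interfacial_b: int
    buried: BuriedArea
    convexity_a: ConvexityResult | None
    convexity_b: ConvexityResult | None
    dsasa_threshold: float
    ransac_threshold: float
    seed: int


def _as_points(points: Sequence[np.ndarray] | np.ndarray) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise GeometryError(f"expected an (n, 3) point array, got shape {pts.shape}")
    return pts


def fit_sphere_lsq(points: Sequence[np.ndarray] | np.ndarray) -> SphereFit:
    """Algebraic least-squares sphere through >= 4 non-coplanar points.

    Solves the linearized system ||x||^2 = 2 c.x + (r^2 - ||c||^2) in closed
    form; all points are reported as inliers (no threshold applied).
    """
    pts = _as_points(points)
    n = len(pts)
    if n < 4:
        raise GeometryError(f"need >= 4 points for a sphere fit, got {n}")
    A = np.hstack([2.0 * pts, np.ones((n, 1))])
    b = (pts**2).sum(axis=1)
    sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 4:
        raise GeometryError("points are coplanar/collinear: sphere is underdetermined")
    center = sol[:3]
    r2 = sol[3] + center @ center
    if r2 <= 0:
        raise GeometryError("degenerate sphere fit (non-positive squared radius)")
    radius = float(np.sqrt(r2))
    resid = np.linalg.norm(pts - center, axis=1) - radius
    return SphereFit(
        center=center,
        radius=radius,
        inlier_indices=np.arange(n),
        inlier_rmse=float(np.sqrt(np.mean(resid**2))),
        n_iterations_used=0,
    )


def _spheres_from_quads(quads: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exact spheres through batches of 4 points.

    quads: (m, 4, 3).  Returns (centers (m,3), radii (m,), valid (m,)) where
    invalid entries are near-coplanar samples (Frobenius condition estimate
    above 1e8) or otherwise degenerate.
    """
    p0 = quads[:, 3, :]
    A = 2.0 * (quads[:, :3, :] - p0[:, None, :])  # (m, 3, 3)
    b = (quads[:, :3, :] ** 2).sum(axis=2) - (p0**2).sum(axis=1)[:, None]
    det = np.linalg.det(A)
    # closed-form inverse via adjugate for condition estimate and solve
    a = A
    adj = np.empty_like(a)
    adj[:, 0, 0] = a[:, 1, 1] * a[:, 2, 2] - a[:, 1, 2] * a[:, 2, 1]
    adj[:, 0, 1] = a[:, 0, 2] * a[:, 2, 1] - a[:, 0, 1] * a[:, 2, 2]
    adj[:, 0, 2] = a[:, 0, 1] * a[:, 1, 2] - a[:, 0, 2] * a[:, 1, 1]
    adj[:, 1, 0] = a[:, 1, 2] * a[:, 2, 0] - a[:, 1, 0] * a[:, 2, 2]
    adj[:, 1, 1] = a[:, 0, 0] * a[:, 2, 2] - a[:, 0, 2] * a[:, 2, 0]
    adj[:, 1, 2] = a[:, 0, 2] * a[:, 1, 0] - a[:, 0, 0] * a[:, 1, 2]
    adj[:, 2, 0] = a[:, 1, 0] * a[:, 2, 1] - a[:, 1, 1] * a[:, 2, 0]
    adj[:, 2, 1] = a[:, 0, 1] * a[:, 2, 0] - a[:, 0, 0] * a[:, 2, 1]
    adj[:, 2, 2] = a[:, 0, 0] * a[:, 1, 1] - a[:, 0, 1] * a[:, 1, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = adj / det[:, None, None]
        norm_a = np.sqrt((a**2).sum(axis=(1, 2)))
        norm_inv = np.sqrt((inv**2).sum(axis=(1, 2)))
        cond = norm_a * norm_inv
    valid = np.isfinite(cond) & (cond <= _COND_LIMIT) & (det != 0)
    centers = np.einsum("mij,mj->mi", inv, b)
    radii = np.linalg.norm(quads[:, 3, :] - centers, axis=1)
    valid &= np.isfinite(radii) & (radii > 0)
    return centers, radii, valid


def fit_sphere_ransac(
    points: Sequence[np.ndarray] | np.ndarray,
    threshold: float = 1.0,
    max_iterations: int = 100_000,
    seed: int = 0,
) -> SphereFit:
    """RANSAC sphere fit: 4-point exact-sphere hypotheses, inlier counting.

    The candidate with the most inliers wins (ties: smaller inlier RMSE, then
    earlier iteration); the winner is refit by :func:`fit_sphere_lsq` on its
    inliers and the inlier set recomputed once after the refit.  Exits early
    when a candidate explains every point.  Fully reproducible given seed.
    """
    pts = _as_points(points)
    n = len(pts)
    if n < 4:
        raise GeometryError(f"need >= 4 points, got {n}")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    rng = np.random.default_rng(seed)

    best = None  # (n_inliers, -rmse, -iteration) maximized
    best_center = None
    best_radius = None
    chunk = 4096
    done = 0
    while done < max_iterations:
        m = min(chunk, max_iterations - done)
        # sample 4 distinct indices per iteration (vectorized without-replacement
        # draw: smallest-4 of a uniform key per point)
        keys = rng.random((m, n))
        idx = np.argpartition(keys, 3, axis=1)[:, :4]
        centers, radii, valid = _spheres_from_quads(pts[idx])
        if valid.any():
            v = np.flatnonzero(valid)
            d = np.linalg.norm(
                pts[None, :, :] - centers[v][:, None, :], axis=2
            )  # (v, n)
            resid = np.abs(d - radii[v][:, None])
            inl = resid <= threshold
            counts = inl.sum(axis=1)
            order = np.argsort(-counts, kind="stable")
            for j in order:
                c = int(counts[j])
                if best is not None and c < best[0]:
                    break
                rmse = float(np.sqrt(np.mean(resid[j][inl[j]] ** 2))) if c else np.inf
                it = done + int(v[j])
                key = (c, -rmse, -it)
                if best is None or key > best:
                    best = key
                    best_center = centers[v[j]]
                    best_radius = float(radii[v[j]])
        done += m
        if best is not None and best[0] == n:
            break

    if best is None:
        raise FitFailureError(
            f"no valid 4-point sphere hypothesis within {max_iterations} iterations"
        )
    # final refit on the winning inlier set, then one re-classification pass
    d = np.linalg.norm(pts - best_center, axis=1)
    inlier_idx = np.flatnonzero(np.abs(d - best_radius) <= threshold)
    center, radius = best_center, best_radius
    if len(inlier_idx) >= 4:
        try:
            refit = fit_sphere_lsq(pts[inlier_idx])
            center, radius = refit.center, refit.radius
        except GeometryError:
            pass
    d = np.linalg.norm(pts - center, axis=1)
    inlier_idx = np.flatnonzero(np.abs(d - radius) <= threshold)
    resid = d[inlier_idx] - radius
    rmse = float(np.sqrt(np.mean(resid**2))) if len(inlier_idx) else float("inf")
    return SphereFit(
        center=np.asarray(center, dtype=float),
        radius=float(radius),
        inlier_indices=inlier_idx,
        inlier_rmse=rmse,
        n_iterations_used=done,
        seed=seed,
    )


def surface_sign(
    all_heavy_coords: Sequence[np.ndarray] | np.ndarray,
    interfacial_coords: Sequence[np.ndarray] | np.ndarray,
    sphere_center: np.ndarray,
) -> tuple[int, float]:
    """Concave/convex decision for a fitted patch.

    Returns ``(sign, dot_product)`` with sign -1 (concave) when the inner
    product (g_p - g_i).(c - g_i) is negative, +1 (convex) when positive.
    """
    body = _as_points(all_heavy_coords)
    patch = _as_points(interfacial_coords)
    if len(body) == 0 or len(patch) == 0:
        raise GeometryError("coordinate lists must be non-empty")
    g_p = body.mean(axis=0)
    g_i = patch.mean(axis=0)
    dot = float((g_p - g_i) @ (np.asarray(sphere_center, dtype=float) - g_i))
    if dot == 0.0:
        raise IndeterminateSignError(
            "inner product is exactly zero; surface is flat or centroids coincide"
        )
    return (CONCAVE if dot < 0 else CONVEX), dot


def signed_convexity(
    model: StructureModel,
    partner_chains: set[str],
    interfacial: Sequence[AtomRecord] | Sequence[int] | np.ndarray,
    ransac_threshold: float = 1.0,
    max_iterations: int = 100_000,
    seed: int = 0,
) -> ConvexityResult:
    """Signed convexity (sign / radius) of one partner's interfacial patch.

    ``interfacial`` may be atom records, indices into ``model.atoms``, or a
    raw (n, 3) coordinate array of the partner's interfacial heavy atoms.
    """
    if isinstance(interfacial, np.ndarray) and interfacial.ndim == 2:
        patch = _as_points(interfacial)
    else:
        seq = list(interfacial)
        if seq and isinstance(seq[0], AtomRecord):
            patch = np.stack([a.coords for a in seq]) if seq else np.empty((0, 3))
        else:
            patch = np.stack([model.atoms[int(i)].coords for i in seq]) if seq else np.empty((0, 3))
    if len(patch) < 4:
        raise GeometryError(f"need >= 4 interfacial atoms, got {len(patch)}")
    body = np.stack(
        [a.coords for a in select_atoms(model, set(partner_chains), heavy_only=True)]
    )
    fit = fit_sphere_ransac(patch, threshold=ransac_threshold, max_iterations=max_iterations, seed=seed)
    sign, dot = surface_sign(body, patch, fit.center)
    return ConvexityResult(
        signed_convexity=sign / fit.radius,
        radius=fit.radius,
        sign=sign,
        inlier_fraction=len(fit.inlier_indices) / len(patch),
        dot_product=dot,
        fit=fit,
    )


def profile_interface(
    model: StructureModel,
    partner_a: set[str],
    partner_b: set[str],
    dsasa_threshold: float = 0.5,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
    ransac_threshold: float = 1.0,
    max_iterations: int = 100_000,
    seed: int = 0,
) -> InterfaceProfile:
    """Interface-profile record: buried polar/apolar area plus per-partner
    signed convexity, as reported for designed binder complexes."""
    partition = interfacial_atoms(
        model, partner_a, partner_b, dsasa_threshold, probe_radius, n_sphere_points
    )
    buried = buried_area(partition, model)

    def _conv(chains: set[str], entries: list[tuple[int, float]]) -> ConvexityResult | None:
        if len(entries) < 4:
            warnings.warn(
                f"partner {sorted(chains)}: {len(entries)} interfacial atoms (< 4); "
                "convexity not computed",
                stacklevel=3,
            )
            return None
        idx = [i for i, _ in entries]
        return signed_convexity(
            model, chains, idx, ransac_threshold, max_iterations, seed
        )

    return InterfaceProfile(
        source_id=model.source_id,
        partner_a_chains="".join(sorted(partner_a)),
        partner_b_chains="".join(sorted(partner_b)),
        n_interfacial_a=len(partition.partner_a_atoms),
        n_interfacial_b=len(partition.partner_b_atoms),
        buried=buried,
        convexity_a=_conv(partner_a, partition.partner_a_atoms),
        convexity_b=_conv(partner_b, partition.partner_b_atoms),
        dsasa_threshold=dsasa_threshold,
        ransac_threshold=ransac_threshold,
        seed=seed,
    )


_PROFILE_COLS = [
    "source_id", "partner_a", "partner_b", "n_interfacial_a", "n_interfacial_b",
    "buried_polar", "buried_apolar", "buried_total",
    "convexity_a", "convexity_b", "radius_a", "radius_b",
    "inlier_fraction_a", "inlier_fraction_b",
    "dsasa_threshold", "ransac_threshold", "seed",
]


def profiles_to_tsv(profiles: Sequence[InterfaceProfile], path: str | Path) -> None:
    def fmt(c: ConvexityResult | None, attr: str) -> str:
        if c is None:
            return "NA"
        return f"{getattr(c, attr):.4f}"

    rows = ["\t".join(_PROFILE_COLS)]
    for p in profiles:
        rows.append(
            "\t".join(
                [
                    p.source_id, p.partner_a_chains, p.partner_b_chains,
                    str(p.n_interfacial_a), str(p.n_interfacial_b),
                    f"{p.buried.polar:.1f}", f"{p.buried.apolar:.1f}", f"{p.buried.total:.1f}",
                    fmt(p.convexity_a, "signed_convexity"), fmt(p.convexity_b, "signed_convexity"),
                    fmt(p.convexity_a, "radius"), fmt(p.convexity_b, "radius"),
                    fmt(p.convexity_a, "inlier_fraction"), fmt(p.convexity_b, "inlier_fraction"),
                    f"{p.dsasa_threshold:g}", f"{p.ransac_threshold:g}", str(p.seed),
                ]
            )
        )
    Path(path).write_text("\n".join(rows) + "\n")
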