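"""Solvent-accessible surface area by sphere-point sampling.

The accessibility sphere of an atom has radius r_vdw + r_probe.  A
deterministic golden-spiral lattice of test points is scattered on each
atom's expanded sphere; the accessible area is the expanded-sphere area
times the fraction of points not buried inside any neighbouring expanded
sphere (Shrake–Rupley integration).  Points falling exactly on a
neighbour's sphere count as buried, which makes the estimate a
deterministic function of the coordinates and the lattice size.

Per-residue areas are sums over member atoms, decomposed along the two
atom flags into backbone/side-chain and polar/apolar parts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import RadiiTable, Structure, THREE_TO_ONE

__all__ = [
    "ResidueSASA",
    "SASAProfile",
    "sphere_points",
    "lattice_orientation",
    "atom_sasa",
    "residue_sasa",
    "sasa_profile",
    "DEFAULT_N_POINTS",
]

#: Default lattice size; at 960 points the isolated-sphere area is exact
#: to <0.5% and a doubling changes per-atom areas by well under 2%.
DEFAULT_N_POINTS = 960


@dataclass(frozen=True)
class ResidueSASA:
    """Accessible area of one residue, decomposed two ways (Å²)."""

    res_index: int
    res_name: str
    total: float
    backbone: float
    sidechain: float
    polar: float
    apolar: float


@dataclass(frozen=True)
class SASAProfile:
    """Whole-protein SASA summary: per-residue rows plus the five totals.

    ``tsa`` (total), ``tps`` (polar), ``tas`` (apolar), ``scs``
    (side chain) and ``bbs`` (backbone) satisfy
    ``tsa = tps + tas = scs + bbs`` up to floating-point roundoff.
    """

    protein_id: str
    residues: tuple[ResidueSASA, ...]

    @property
    def tsa(self) -> float:
        return sum(r.total for r in self.residues)

    @property
    def tps(self) -> float:
        return sum(r.polar for r in self.residues)

    @property
    def tas(self) -> float:
        return sum(r.apolar for r in self.residues)

    @property
    def scs(self) -> float:
        return sum(r.sidechain for r in self.residues)

    @property
    def bbs(self) -> float:
        return sum(r.backbone for r in self.residues)

    @property
    def sequence(self) -> str:
        return "".join(THREE_TO_ONE[r.res_name] for r in self.residues)


def sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral lattice of *n* unit vectors.

    Points are spaced evenly in z with azimuths advancing by the golden
    angle, giving near-uniform coverage of the sphere for any n >= 12.
    """
    if n < 12:
        raise ValueError(f"need at least 12 sphere points, got {n}")
    k = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * k + 1.0) / n
    theta = np.pi * (1.0 + np.sqrt(5.0)) * k
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    pts = np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])
    return pts / np.linalg.norm(pts, axis=1, keepdims=True)


def lattice_orientation(coords: np.ndarray) -> np.ndarray:
    """Structure-intrinsic rotation applied to the point lattice.

    The frame is anchored on the centroid c, the atom p farthest from c
    and the atom q farthest from p (ties broken by lowest atom index), so
    it moves rigidly with the structure.  Orienting the lattice by this
    rotation makes every buried/free decision — and hence every area —
    exactly equivariant under rigid motion of the coordinates.  Collinear
    structures leave the azimuthal axis free, but the buried set is then
    axially symmetric, so any deterministic completion gives identical
    areas; degenerate cases fall back to the identity.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] < 2:
        return np.eye(3)
    c = coords.mean(axis=0)
    p = coords[int(np.argmax(np.linalg.norm(coords - c, axis=1)))]
    e1 = p - c
    n1 = np.linalg.norm(e1)
    if n1 < 1e-9:
        return np.eye(3)
    e1 /= n1
    q = coords[int(np.argmax(np.linalg.norm(coords - p, axis=1)))]
    v = q - c
    v -= np.dot(v, e1) * e1
    n2 = np.linalg.norm(v)
    if n2 < 1e-9:
        # collinear: deterministic completion via the least-aligned axis
        axis = np.zeros(3)
        axis[int(np.argmin(np.abs(e1)))] = 1.0
        v = axis - np.dot(axis, e1) * e1
        n2 = np.linalg.norm(v)
    e2 = v / n2
    e3 = np.cross(e1, e2)
    return np.column_stack([e1, e2, e3])


def _atom_arrays(s: Structure) -> tuple[np.ndarray, np.ndarray]:
    coords = np.array([[a.x, a.y, a.z] for a in s.atoms()], dtype=float)
    radii = np.array([a.radius for a in s.atoms()], dtype=float)
    return coords, radii


def atom_sasa(
    s: Structure,
    radii: RadiiTable | None = None,
    n_points: int = DEFAULT_N_POINTS,
    orientation: np.ndarray | None = None,
) -> np.ndarray:
    """Per-atom accessible surface areas in Å², in structure atom order.

    Atom radii stored on the structure are used; *radii* only supplies the
    probe radius (defaults to 1.4 Å water).  The point lattice is oriented
    by the structure-intrinsic frame (see :func:`lattice_orientation`) so
    areas are invariant under rigid motion; pass an explicit *orientation*
    rotation to pin the lattice instead.  Raises ``ValueError`` if two
    atoms coincide exactly, naming both.
    """
    probe = (radii or RadiiTable()).probe_radius
    coords, vdw = _atom_arrays(s)
    if coords.shape[0] == 0:
        raise ValueError("structure has no atoms")
    expanded = vdw + probe
    if orientation is None:
        orientation = lattice_orientation(coords)
    unit = sphere_points(n_points) @ orientation.T
    n_atoms = coords.shape[0]

    tree = cKDTree(coords)
    r_max = expanded.max()
    areas = np.empty(n_atoms)
    atom_list = list(s.atoms())
    for i in range(n_atoms):
        ri = expanded[i]
        neighbours = tree.query_ball_point(coords[i], ri + r_max)
        neighbours = [j for j in neighbours if j != i]
        if neighbours:
            nb = np.asarray(neighbours)
            d = np.linalg.norm(coords[nb] - coords[i], axis=1)
            if np.any(d == 0.0):
                j = int(nb[np.argmin(d)])
                a, b = atom_list[i], atom_list[j]
                raise ValueError(
                    f"atoms at identical coordinates: "
                    f"{a.res_name}{a.res_seq}:{a.name} and "
                    f"{b.res_name}{b.res_seq}:{b.name}"
                )
            keep = d < ri + expanded[nb]
            nb = nb[keep]
        else:
            nb = np.empty(0, dtype=int)
        pts = coords[i] + ri * unit
        if nb.size:
            # buried if within (or exactly on) a neighbour's expanded sphere
            d2 = ((pts[:, None, :] - coords[nb][None, :, :]) ** 2).sum(axis=2)
            buried = (d2 <= (expanded[nb] ** 2)[None, :]).any(axis=1)
            free_frac = 1.0 - buried.mean()
        else:
            free_frac = 1.0
        areas[i] = 4.0 * np.pi * ri * ri * free_frac
    return areas


def residue_sasa(s: Structure, per_atom: np.ndarray) -> SASAProfile:
    """Aggregate per-atom areas into the per-residue profile."""
    per_atom = np.asarray(per_atom, dtype=float)
    if per_atom.shape[0] != s.n_atoms:
        raise ValueError(
            f"length mismatch: {per_atom.shape[0]} areas for {s.n_atoms} atoms"
        )
    rows: list[ResidueSASA] = []
    k = 0
    for idx, res in enumerate(s.residues):
        total = backbone = sidechain = polar = apolar = 0.0
        for a in res:
            area = float(per_atom[k])
            k += 1
            total += area
            if a.is_backbone:
                backbone += area
            else:
                sidechain += area
            if a.is_polar:
                polar += area
            else:
                apolar += area
        rows.append(
            ResidueSASA(
                res_index=idx,
                res_name=res[0].res_name,
                total=total,
                backbone=backbone,
                sidechain=sidechain,
                polar=polar,
                apolar=apolar,
            )
        )
    return SASAProfile(protein_id=s.id, residues=tuple(rows))


def sasa_profile(
    s: Structure,
    radii: RadiiTable | None = None,
    n_points: int = DEFAULT_N_POINTS,
) -> SASAProfile:
    """Convenience: per-atom integration followed by residue aggregation."""
    return residue_sasa(s, atom_sasa(s, radii, n_points))
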