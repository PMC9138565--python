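"""Synthetic structure and family generators.

This module builds every fixture the pipeline needs without touching the
network or any experimental archive:

* ideal-geometry single-chain peptides with user-chosen backbone
  dihedrals (helices, strands, arbitrary coils);
* Gly-X-Gly tripeptides with randomised backbone and side-chain
  dihedrals, the reference context for relative accessibility;
* families of related proteins — groups sharing a backbone template,
  members perturbed by Gaussian coordinate jitter, groups separated by
  dihedral shifts and sequence substitutions — with exact ground-truth
  alignments and planted cluster labels.

Backbones are grown atom by atom with the natural-extension reference
frame (NeRF) construction from standard bond lengths and angles
(Engh–Huber-style constants).  Side chains come from the idealised
chemical-component templates shipped with biotite, rigidly grafted onto
the backbone and re-dihedralised about their rotatable chi bonds.
Peptide bonds are trans (omega = 180°) unless overridden.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import biotite.structure.info as bstinfo

from .structure_io import (
    Atom,
    BACKBONE_ATOMS,
    ONE_TO_THREE,
    RadiiTable,
    Structure,
)

__all__ = [
    "BuildSpec",
    "FamilySpec",
    "FamilyData",
    "build_peptide",
    "gxg_conformers",
    "make_family",
    "CHI_ATOMS",
]

# Backbone geometry constants (Å / degrees).
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_C_N_CA = 121.7
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_CA_C_O = 120.8
#: Standard chi dihedral definitions (atom name quadruples) per residue.
CHI_ATOMS: dict[str, list[tuple[str, str, str, str]]] = {
    "R": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
          ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ"),
          ("CD", "NE", "CZ", "NH1")],
    "N": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "D": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "C": [("N", "CA", "CB", "SG")],
    "Q": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
          ("CB", "CG", "CD", "OE1")],
    "E": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
          ("CB", "CG", "CD", "OE1")],
    "H": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "I": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "L": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "K": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
          ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "M": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
          ("CB", "CG", "SD", "CE")],
    "F": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "S": [("N", "CA", "CB", "OG")],
    "T": [("N", "CA", "CB", "OG1")],
    "W": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "Y": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "V": [("N", "CA", "CB", "CG1")],
    "A": [], "G": [], "P": [],  # Pro's ring is kept in template geometry
}

CLASH_FACTOR = 0.6
MAX_RETRIES = 50


@dataclass(frozen=True)
class BuildSpec:
    """Recipe for one ideal-geometry peptide.

    ``dihedrals`` is one (phi, psi, omega) triple per residue in degrees;
    phi of the first and omega of each residue's preceding bond are
    ignored where undefined.  ``chi`` is either "template" (keep the
    idealised template rotamer), "sample" (draw uniformly per rotatable
    bond, clash-checked), or an explicit per-residue list of chi values.
    """

    sequence: str
    dihedrals: tuple[tuple[float, float, float], ...]
    chi: str | tuple[tuple[float, ...], ...] = "template"
    seed: int = 0
    id: str = "peptide"

    def __post_init__(self) -> None:
        if len(self.dihedrals) != len(self.sequence):
            raise ValueError("need one (phi, psi, omega) triple per residue")
        for c in self.sequence:
            if c not in ONE_TO_THREE:
                raise ValueError(f"non-canonical residue letter {c!r}")
        for tri in self.dihedrals:
            for ang in tri:
                if not -180.0 < ang <= 180.0:
                    raise ValueError(f"dihedral {ang} outside (-180, 180]")


@dataclass(frozen=True)
class FamilySpec:
    """Recipe for a labelled family of related synthetic proteins."""

    n_groups: int = 3
    members_per_group: int = 3
    length: int = 40
    sigma: float = 0.2
    n_edits: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_groups, self.members_per_group, self.length) < 1:
            raise ValueError("counts must be >= 1")
        if self.sigma < 0:
            raise ValueError("jitter sigma must be >= 0")


@dataclass
class FamilyData:
    structures: list[Structure]
    sequences: list[tuple[str, str]]
    alignment: list[tuple[str, str]]
    labels: dict[str, int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# geometry primitives


def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
          bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place atom D from frame atoms A-B-C (NeRF construction)."""
    angle = math.radians(angle_deg)
    dihedral = math.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(angle),
        bond * math.sin(angle) * math.cos(dihedral),
        bond * math.sin(angle) * math.sin(dihedral),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def dihedral_angle(p0, p1, p2, p3) -> float:
    """Signed dihedral p0-p1-p2-p3 in degrees."""
    b0 = np.asarray(p0) - np.asarray(p1)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return math.degrees(math.atan2(y, x))


def _kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rotation/translation mapping *mobile* onto *target* (least squares)."""
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    h = (mobile - mc).T @ (target - tc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return rot, tc - rot @ mc


# ---------------------------------------------------------------------------
# side-chain templates from the idealised chemical-component dictionary


def _sidechain_template(res3: str):
    """Heavy side-chain atoms of the idealised residue template.

    Returns (names, elements, coords, backbone_coords(N, CA, C), bonds)
    where *bonds* is a set of frozensets over retained atom names.
    """
    tmpl = bstinfo.residue(res3)
    heavy = tmpl.element != "H"
    keep_names = [n for n, h in zip(tmpl.atom_name, heavy) if h]
    name_to_idx = {n: i for i, n in enumerate(tmpl.atom_name)}
    bb = np.array([tmpl.coord[name_to_idx[n]] for n in ("N", "CA", "C")])
    side_idx = [
        i for i, n in enumerate(tmpl.atom_name)
        if heavy[i] and n not in BACKBONE_ATOMS
    ]
    names = [tmpl.atom_name[i] for i in side_idx]
    elements = [tmpl.element[i] for i in side_idx]
    coords = tmpl.coord[side_idx].astype(float)
    bonds = set()
    idx_to_name = dict(enumerate(tmpl.atom_name))
    for i, j, _ in tmpl.bonds.as_array():
        ni, nj = idx_to_name[int(i)], idx_to_name[int(j)]
        if ni in keep_names and nj in keep_names:
            bonds.add(frozenset((ni, nj)))
    _ = keep_names
    return names, elements, coords, bb, bonds


def _distal_atoms(bonds: set[frozenset], start: str, blocked: str) -> set[str]:
    """Atoms reachable from *start* without crossing the *blocked* atom."""
    adj: dict[str, set[str]] = {}
    for b in bonds:
        i, j = tuple(b)
        adj.setdefault(i, set()).add(j)
        adj.setdefault(j, set()).add(i)
    seen = {blocked, start}
    stack = [start]
    out = {start}
    while stack:
        cur = stack.pop()
        for nxt in adj.get(cur, ()):
            if nxt not in seen:
                seen.add(nxt)
                out.add(nxt)
                stack.append(nxt)
    return out


def _set_chi(
    coords: dict[str, np.ndarray],
    bonds: set[frozenset],
    quad: tuple[str, str, str, str],
    target_deg: float,
) -> None:
    """Rotate all atoms distal to the quad's central bond to the target chi."""
    a, b, c, d = quad
    current = dihedral_angle(coords[a], coords[b], coords[c], coords[d])
    delta = math.radians(target_deg - current)
    axis = coords[c] - coords[b]
    axis /= np.linalg.norm(axis)
    moving = _distal_atoms(bonds, c, b) - {c}
    cos_t, sin_t = math.cos(delta), math.sin(delta)
    for name in moving:
        if name not in coords:
            continue
        v = coords[name] - coords[c]
        coords[name] = coords[c] + (
            v * cos_t + np.cross(axis, v) * sin_t
            + axis * np.dot(axis, v) * (1.0 - cos_t)
        )


# ---------------------------------------------------------------------------
# builders


def _backbone_coords(
    dihedrals: tuple[tuple[float, float, float], ...]
) -> list[dict[str, np.ndarray]]:
    """Backbone N/CA/C/O coordinates for each residue via NeRF."""
    n_res = len(dihedrals)
    residues: list[dict[str, np.ndarray]] = []
    # first residue in a canonical frame
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([BOND_N_CA, 0.0, 0.0])
    ang = math.radians(ANGLE_N_CA_C)
    c0 = ca0 + BOND_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    residues.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, n_res):
        prev = residues[i - 1]
        psi_prev = dihedrals[i - 1][1]
        omega = dihedrals[i][2]
        phi = dihedrals[i][0]
        n_i = _nerf(prev["N"], prev["CA"], prev["C"],
                    BOND_C_N, ANGLE_CA_C_N, psi_prev)
        ca_i = _nerf(prev["CA"], prev["C"], n_i,
                     BOND_N_CA, ANGLE_C_N_CA, omega)
        c_i = _nerf(prev["C"], n_i, ca_i, BOND_CA_C, ANGLE_N_CA_C, phi)
        residues.append({"N": n_i, "CA": ca_i, "C": c_i})
    # carbonyl oxygens: anti to the next amide nitrogen; for the last
    # residue, placed from its own psi
    for i, res in enumerate(residues):
        psi = dihedrals[i][1]
        res["O"] = _nerf(res["N"], res["CA"], res["C"],
                         BOND_C_O, ANGLE_CA_C_O, psi + 180.0)
    return residues


def _place_sidechain(
    res1: str,
    bb: dict[str, np.ndarray],
    chi: tuple[float, ...] | None,
    rng: np.random.Generator | None,
) -> tuple[list[str], list[str], dict[str, np.ndarray]]:
    """Graft the template side chain onto a built backbone residue.

    Returns side-chain atom (names, elements, coords).  *chi* overrides
    template chi angles; if *rng* is given instead, chis are sampled
    uniformly from (-180, 180].
    """
    res3 = ONE_TO_THREE[res1]
    if res1 == "G":
        return [], [], {}
    names, elements, coords, tmpl_bb, bonds = _sidechain_template(res3)
    rot, trans = _kabsch(tmpl_bb, np.array([bb["N"], bb["CA"], bb["C"]]))
    placed = {n: rot @ c + trans for n, c in zip(names, coords)}
    # include the real backbone positions so chi frames are exact
    frame = dict(placed)
    frame.update({k: np.asarray(v, dtype=float) for k, v in bb.items()})
    quads = CHI_ATOMS[res1]
    if quads:
        if chi is not None:
            values: list[float] = list(chi)
        elif rng is not None:
            values = list(rng.uniform(-180.0, 180.0, size=len(quads)))
        else:
            values = []
        for quad, val in zip(quads, values):
            _set_chi(frame, bonds | {frozenset(("N", "CA")),
                                     frozenset(("CA", "C")),
                                     frozenset(("CA", "CB"))},
                     quad, float(val))
    side = {n: frame[n] for n in names}
    return names, elements, side


def _has_clash(
    residue_atoms: list[list[tuple[str, str, np.ndarray]]],
    radii: RadiiTable,
) -> bool:
    """Steric-clash test: non-neighbouring residue atom pairs closer than
    CLASH_FACTOR times the sum of van der Waals radii."""
    flat = []
    for i, res in enumerate(residue_atoms):
        for name, element, xyz in res:
            flat.append((i, name, radii.radius_of(element), xyz))
    for a in range(len(flat)):
        i, name_a, ra, xa = flat[a]
        for b in range(a + 1, len(flat)):
            j, name_b, rb, xb = flat[b]
            if j - i < 2:
                # bonded / angle-range contacts inside a residue or across
                # the peptide bond are legitimate short distances
                continue
            if np.linalg.norm(xa - xb) < CLASH_FACTOR * (ra + rb):
                return True
    return False


def _assemble(
    spec_id: str,
    sequence: str,
    residue_atoms: list[list[tuple[str, str, np.ndarray]]],
    radii: RadiiTable,
) -> Structure:
    residues: list[list[Atom]] = []
    serial = 0
    polar = {"N", "O"}
    for idx, atoms in enumerate(residue_atoms):
        res3 = ONE_TO_THREE[sequence[idx]]
        rows = []
        for name, element, xyz in atoms:
            serial += 1
            rows.append(
                Atom(
                    serial=serial, name=name, element=element,
                    res_name=res3, res_seq=idx + 1, chain="A",
                    x=float(xyz[0]), y=float(xyz[1]), z=float(xyz[2]),
                    radius=radii.radius_of(element),
                    is_backbone=name in BACKBONE_ATOMS,
                    is_polar=element in polar,
                )
            )
        residues.append(rows)
    s = Structure(id=spec_id, residues=residues)
    s.validate()
    return s


def build_peptide(spec: BuildSpec, radii: RadiiTable | None = None) -> Structure:
    """Build an ideal-geometry peptide from a :class:`BuildSpec`.

    Deterministic in the spec (including its seed when chi angles are
    sampled).  Raises ``RuntimeError`` if chi sampling cannot find a
    clash-free conformation within the retry budget.
    """
    radii = radii or RadiiTable()
    backbone = _backbone_coords(spec.dihedrals)
    rng = np.random.default_rng(spec.seed)
    sample = spec.chi == "sample"
    explicit = not isinstance(spec.chi, str)

    for attempt in range(MAX_RETRIES):
        residue_atoms: list[list[tuple[str, str, np.ndarray]]] = []
        for i, res1 in enumerate(spec.sequence):
            bb = backbone[i]
            chi = tuple(spec.chi[i]) if explicit else None
            names, elements, side = _place_sidechain(
                res1, bb, chi, rng if sample else None
            )
            atoms = [("N", "N", bb["N"]), ("CA", "C", bb["CA"]),
                     ("C", "C", bb["C"]), ("O", "O", bb["O"])]
            atoms += [(n, e, side[n]) for n, e in zip(names, elements)]
            residue_atoms.append(atoms)
        if not sample or not _has_clash(residue_atoms, radii):
            return _assemble(spec.id, spec.sequence, residue_atoms, radii)
    raise RuntimeError(
        f"no clash-free conformation for {spec.id!r} in {MAX_RETRIES} tries"
    )


def helix_spec(sequence: str, seed: int = 0, id: str = "helix") -> BuildSpec:
    """Ideal alpha-helix recipe (phi = -57°, psi = -47°)."""
    return BuildSpec(
        sequence=sequence,
        dihedrals=tuple((-57.0, -47.0, 180.0) for _ in sequence),
        seed=seed, id=id,
    )


def strand_spec(sequence: str, seed: int = 0, id: str = "strand") -> BuildSpec:
    """Extended beta-strand recipe (phi = -139°, psi = 135°)."""
    return BuildSpec(
        sequence=sequence,
        dihedrals=tuple((-139.0, 135.0, 180.0) for _ in sequence),
        seed=seed, id=id,
    )


def _random_dihedrals(
    n: int, rng: np.random.Generator
) -> tuple[tuple[float, float, float], ...]:
    """Random-conformation dihedrals: phi uniform in (-180, 0), psi uniform
    in (-180, 180), trans omega."""
    phis = rng.uniform(-180.0, 0.0, size=n)
    psis = rng.uniform(-180.0, 180.0, size=n)
    return tuple((float(p), float(q), 180.0) for p, q in zip(phis, psis))


def gxg_conformers(
    x: str,
    n: int,
    seed: int,
    radii: RadiiTable | None = None,
) -> list[Structure]:
    """Gly-X-Gly tripeptides in *n* random, clash-free conformations.

    Backbone phi/psi and side-chain chi angles are drawn uniformly from
    their documented ranges; clashed conformers are resampled.  The output
    is deterministic in (x, n, seed, radii).
    """
    if n < 1:
        raise ValueError("need n >= 1 conformers")
    if x not in ONE_TO_THREE:
        raise ValueError(f"unknown residue letter {x!r}")
    radii = radii or RadiiTable()
    rng = np.random.default_rng([seed, ord(x)])
    out: list[Structure] = []
    for k in range(n):
        for attempt in range(MAX_RETRIES):
            sub_seed = int(rng.integers(0, 2**31 - 1))
            spec = BuildSpec(
                sequence=f"G{x}G",
                dihedrals=_random_dihedrals(3, np.random.default_rng(sub_seed)),
                chi="sample",
                seed=sub_seed,
                id=f"GXG_{x}_{k}",
            )
            try:
                out.append(build_peptide(spec, radii))
                break
            except RuntimeError:
                continue
        else:
            raise RuntimeError(
                f"could not build clash-free G{x}G conformer {k} "
                f"within {MAX_RETRIES} attempts"
            )
    return out


def make_family(spec: FamilySpec, radii: RadiiTable | None = None) -> FamilyData:
    """Generate a labelled family of related synthetic proteins.

    All groups share one backbone template drawn from the random-coil
    dihedral scheme.  Each group applies its own large dihedral shift to a
    contiguous block plus ``n_edits`` sequence substitutions; each member
    then receives isotropic Gaussian coordinate jitter of width ``sigma``.
    Sequences all have equal length, so the ground-truth alignment is the
    ungapped stack of the sequences themselves.
    """
    radii = radii or RadiiTable()
    rng = np.random.default_rng(spec.seed)
    aas = "ACDEFGHIKLMNPQRSTVWY"
    base_seq = "".join(rng.choice(list(aas)) for _ in range(spec.length))
    base_dih = list(_random_dihedrals(spec.length, rng))

    structures: list[Structure] = []
    sequences: list[tuple[str, str]] = []
    labels: dict[str, int] = {}
    block = max(1, spec.length // 3)
    for g in range(spec.n_groups):
        seq = list(base_seq)
        dih = list(base_dih)
        if g > 0:
            # group-specific backbone shift over a contiguous block
            start = int(rng.integers(0, spec.length - block + 1))
            shift = float(rng.uniform(60.0, 120.0)) * (1 if g % 2 else -1)
            for i in range(start, start + block):
                phi, psi, om = dih[i]
                new_phi = min(max(phi + shift, -179.9), 0.0)
                new_psi = ((psi + shift + 180.0) % 360.0) - 180.0
                dih[i] = (new_phi, new_psi if new_psi != -180.0 else 180.0, om)
            for _ in range(spec.n_edits):
                pos = int(rng.integers(0, spec.length))
                cur = seq[pos]
                seq[pos] = rng.choice([a for a in aas if a != cur])
        gseq = "".join(seq)
        gspec = BuildSpec(
            sequence=gseq,
            dihedrals=tuple(dih),
            chi="template",
            seed=spec.seed * 1000 + g,
            id=f"g{g}",
        )
        gstruct = build_peptide(gspec, radii)
        coords = np.array([[a.x, a.y, a.z] for a in gstruct.atoms()])
        for m in range(spec.members_per_group):
            mid = f"g{g}m{m}"
            jitter = rng.normal(0.0, spec.sigma, size=coords.shape) \
                if spec.sigma > 0 else np.zeros_like(coords)
            jc = coords + jitter
            k = 0
            residues: list[list[Atom]] = []
            for res in gstruct.residues:
                rows = []
                for a in res:
                    rows.append(
                        Atom(
                            serial=a.serial, name=a.name, element=a.element,
                            res_name=a.res_name, res_seq=a.res_seq,
                            chain=a.chain,
                            x=float(jc[k, 0]), y=float(jc[k, 1]),
                            z=float(jc[k, 2]),
                            radius=a.radius, is_backbone=a.is_backbone,
                            is_polar=a.is_polar,
                        )
                    )
                    k += 1
                residues.append(rows)
            structures.append(Structure(id=mid, residues=residues))
            sequences.append((mid, gseq))
            labels[mid] = g
    alignment = list(sequences)  # equal length, ungapped by construction
    return FamilyData(
        structures=structures,
        sequences=sequences,
        alignment=alignment,
        labels=labels,
    )
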