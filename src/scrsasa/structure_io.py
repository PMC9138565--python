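"""Reading, writing and normalising single-chain protein structures.

The in-memory model is deliberately small: a :class:`Structure` is an
ordered list of residues, each an ordered list of :class:`Atom` records
carrying Cartesian coordinates, a van der Waals radius and two boolean
class flags (backbone / side chain, polar / apolar).  Everything downstream
— surface-area integration, burial classification, fingerprints — operates
on this model only.

Hydrogens are never retained: structures are treated at the united-atom
level, so every surviving atom is C, N, O or S.  Polarity is assigned by
element (N and O polar; C and S apolar), matching the polar/apolar SASA
split reported by GETAREA-style servers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import yaml

__all__ = [
    "Atom",
    "Structure",
    "RadiiTable",
    "PDBParseError",
    "FastaError",
    "read_pdb",
    "write_pdb",
    "read_fasta",
    "write_fasta",
    "THREE_TO_ONE",
    "ONE_TO_THREE",
    "BACKBONE_ATOMS",
    "SIDECHAIN_HEAVY_COUNTS",
]


class PDBParseError(ValueError):
    """Raised for malformed or unsupported PDB content."""


class FastaError(ValueError):
    """Raised for malformed FASTA content."""


#: Backbone heavy-atom names (wwPDB convention).  OXT is the C-terminal
#: carboxyl oxygen and counts as backbone.
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

#: Canonical number of heavy side-chain atoms per residue type.
SIDECHAIN_HEAVY_COUNTS: dict[str, int] = {
    "A": 1, "R": 7, "N": 4, "D": 4, "C": 2, "Q": 5, "E": 5, "G": 0,
    "H": 6, "I": 4, "L": 4, "K": 5, "M": 4, "F": 7, "P": 3, "S": 2,
    "T": 3, "W": 10, "Y": 8, "V": 3,
}

#: Elements polar at the united-atom level.
POLAR_ELEMENTS = frozenset({"N", "O"})

#: Chothia united-atom van der Waals radii (Å).
DEFAULT_RADII: dict[str, float] = {"C": 1.87, "N": 1.65, "O": 1.40, "S": 1.85}

#: Water probe radius (Å).
DEFAULT_PROBE = 1.40


@dataclass(frozen=True)
class RadiiTable:
    """Van der Waals radii per element plus the solvent probe radius.

    Parameters
    ----------
    radii
        Mapping of element symbol to van der Waals radius in Å.  All radii
        must lie in (1.0, 2.5) Å.
    probe_radius
        Radius of the solvent probe in Å (1.4 Å models a water molecule).
    name
        Provenance tag recorded in reference-table headers.
    """

    radii: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_RADII))
    probe_radius: float = DEFAULT_PROBE
    name: str = "chothia-united-atom"

    def __post_init__(self) -> None:
        for el, r in self.radii.items():
            if not 1.0 < r < 2.5:
                raise ValueError(f"radius for {el} out of range (1.0, 2.5): {r}")
        if self.probe_radius < 0:
            raise ValueError(f"probe radius must be >= 0, got {self.probe_radius}")

    def radius_of(self, element: str) -> float:
        try:
            return self.radii[element]
        except KeyError:
            raise KeyError(f"no van der Waals radius for element {element!r}") from None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RadiiTable":
        """Load a table from a ``key: value`` YAML/config file.

        Recognised keys: one per element symbol, plus ``probe_radius`` and
        optionally ``name``.
        """
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        probe = float(raw.pop("probe_radius", DEFAULT_PROBE))
        name = str(raw.pop("name", Path(path).stem))
        radii = {str(k): float(v) for k, v in raw.items()}
        return cls(radii=radii, probe_radius=probe, name=name)


@dataclass(frozen=True)
class Atom:
    serial: int
    name: str
    element: str
    res_name: str
    res_seq: int
    chain: str
    x: float
    y: float
    z: float
    radius: float
    is_backbone: bool
    is_polar: bool

    @property
    def coord(self) -> tuple[float, float, float]:
        return (self.x, self.y, self.z)


@dataclass
class Structure:
    """A single-chain protein: ordered residues of ordered atoms."""

    id: str
    residues: list[list[Atom]]

    @property
    def sequence(self) -> str:
        return "".join(THREE_TO_ONE[res[0].res_name] for res in self.residues)

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def atoms(self) -> Iterator[Atom]:
        for res in self.residues:
            yield from res

    @property
    def n_atoms(self) -> int:
        return sum(len(res) for res in self.residues)

    def validate(self) -> None:
        """Check the structural invariants; raise ``ValueError`` on breach."""
        if not self.residues:
            raise ValueError("structure has no residues")
        seen: set[tuple[str, int, str]] = set()
        prev_seq: int | None = None
        for res in self.residues:
            if not res:
                raise ValueError("empty residue in structure")
            res_name = res[0].res_name
            res_seq = res[0].res_seq
            if prev_seq is not None and res_seq < prev_seq:
                raise ValueError(f"residues out of order at res_seq {res_seq}")
            prev_seq = res_seq
            for a in res:
                if a.res_name != res_name or a.res_seq != res_seq:
                    raise ValueError(f"inconsistent residue grouping at {res_seq}")
                key = (a.chain, a.res_seq, a.name)
                if key in seen:
                    raise ValueError(f"duplicate atom {key}")
                seen.add(key)
                if a.radius <= 0:
                    raise ValueError(f"non-positive radius on atom {key}")


def _is_backbone(name: str) -> bool:
    return name in BACKBONE_ATOMS


def _classify(element: str) -> bool:
    return element in POLAR_ELEMENTS


def _element_from_record(line: str, name: str) -> str:
    el = line[76:78].strip() if len(line) >= 78 else ""
    if not el:
        # fall back to the first alphabetic character of the atom name
        el = next((c for c in name if c.isalpha()), "")
    return el.upper()


def read_pdb(
    path: str | Path,
    radii: RadiiTable | None = None,
    *,
    structure_id: str | None = None,
    chain: str | None = None,
) -> Structure:
    """Parse a PDB file into a normalised :class:`Structure`.

    HETATM records, waters, hydrogens and alternate locations other than
    'A'/blank are dropped.  Every retained atom is assigned a radius from
    *radii* and its backbone/polar flags.

    Parameters
    ----------
    path
        PDB file with at least one ATOM record.
    radii
        Radii table; defaults to the packaged Chothia united-atom set.
    chain
        Chain identifier to select.  Required if the file holds more than
        one chain.

    Raises
    ------
    PDBParseError
        On malformed ATOM lines (the message names the line number), on
        unknown residue codes, or if multiple chains are present and no
        *chain* was selected.
    """
    radii = radii or RadiiTable()
    path = Path(path)
    atoms: list[Atom] = []
    chains_seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith("ATOM"):
                continue
            try:
                serial = int(line[6:11])
                name = line[12:16].strip()
                altloc = line[16]
                res_name = line[17:20].strip()
                chain_id = line[21].strip() or "A"
                res_seq = int(line[22:26])
                icode = line[26].strip()
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
            except (ValueError, IndexError) as exc:
                raise PDBParseError(
                    f"{path.name}: malformed ATOM record at line {lineno}: {exc}"
                ) from None
            if altloc not in (" ", "", "A"):
                continue
            if res_name == "HOH":
                continue
            if res_name not in THREE_TO_ONE:
                raise PDBParseError(
                    f"{path.name}: unknown residue code {res_name!r} at line {lineno}"
                )
            element = _element_from_record(line, name)
            if element == "H" or element == "D":
                continue
            chains_seen.add(chain_id)
            if chain is not None and chain_id != chain:
                continue
            if element not in radii.radii:
                raise PDBParseError(
                    f"{path.name}: no radius for element {element!r} at line {lineno}"
                )
            # insertion codes are folded into the ordering by arrival order
            _ = icode
            atoms.append(
                Atom(
                    serial=serial,
                    name=name,
                    element=element,
                    res_name=res_name,
                    res_seq=res_seq,
                    chain=chain_id,
                    x=x, y=y, z=z,
                    radius=radii.radius_of(element),
                    is_backbone=_is_backbone(name),
                    is_polar=_classify(element),
                )
            )
    if chain is None and len(chains_seen) > 1:
        raise PDBParseError(
            f"{path.name}: multiple chains present ({sorted(chains_seen)}); "
            "select one with chain=..."
        )
    if not atoms:
        raise PDBParseError(f"{path.name}: no ATOM records retained")
    residues: list[list[Atom]] = []
    for atom in atoms:
        if residues and residues[-1][0].res_seq == atom.res_seq \
                and residues[-1][0].chain == atom.chain:
            residues[-1].append(atom)
        else:
            residues.append([atom])
    s = Structure(id=structure_id or path.stem, residues=residues)
    s.validate()
    return s


def write_pdb(s: Structure, path: str | Path) -> None:
    """Write *s* as PDB ATOM records (coordinates at 3-decimal precision)."""
    if not s.residues:
        raise ValueError("refusing to write a structure with no residues")
    s.validate()
    with open(path, "w") as fh:
        serial = 0
        for res in s.residues:
            for a in res:
                serial += 1
                name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
                fh.write(
                    f"ATOM  {serial:5d} {name:<4s} {a.res_name:<3s} "
                    f"{a.chain:1s}{a.res_seq:4d}    "
                    f"{a.x:8.3f}{a.y:8.3f}{a.z:8.3f}"
                    f"{1.0:6.2f}{0.0:6.2f}          {a.element:>2s}\n"
                )
        fh.write("END\n")


_VALID_AA = set(THREE_TO_ONE.values())


def read_fasta(
    path: str | Path, *, alignment: bool = False
) -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(id, sequence), ...]`` preserving order.

    The record id is the header token before the first whitespace.  With
    ``alignment=True`` the gap character '-' is allowed and all records
    must have equal length.
    """
    path = Path(path)
    records: list[tuple[str, str]] = []
    ids: set[str] = set()
    header: str | None = None
    chunks: list[str] = []
    allowed = _VALID_AA | ({"-"} if alignment else set())

    def flush() -> None:
        nonlocal header, chunks
        if header is None:
            return
        seq = "".join(chunks)
        records.append((header, seq))
        header, chunks = None, []

    with open(path) as fh:
        pos_base = 0
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].split()[0] if line[1:].split() else ""
                if not header:
                    raise FastaError(f"{path.name}: empty FASTA header")
                if header in ids:
                    raise FastaError(f"{path.name}: duplicate record id {header!r}")
                ids.add(header)
                pos_base = 0
            else:
                if header is None:
                    raise FastaError(f"{path.name}: sequence before first header")
                up = line.upper()
                for i, c in enumerate(up):
                    if c not in allowed:
                        raise FastaError(
                            f"{path.name}: illegal character {c!r} in record "
                            f"{header!r} at position {pos_base + i + 1}"
                        )
                chunks.append(up)
                pos_base += len(up)
    flush()
    if not records:
        raise FastaError(f"{path.name}: empty FASTA file")
    if alignment:
        lengths = {len(seq) for _, seq in records}
        if len(lengths) > 1:
            raise FastaError(
                f"{path.name}: ragged alignment (lengths {sorted(lengths)})"
            )
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path,
                width: int = 60) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
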