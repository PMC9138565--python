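"""Relative accessibility, burial classes and environment summaries.

A residue's burial is measured as the ratio of its side-chain SASA in the
folded protein to the mean side-chain SASA of the same residue type in a
Gly-X-Gly tripeptide over an ensemble of random conformations (Gly, which
has no side chain, is referenced and classified by its all-atom SASA).
Residues with ratio > 0.5 are *surface*, ratio < 0.2 *nucleus*, the rest
*intermediate*; both thresholds are strict, so a ratio of exactly 0.5 or
0.2 is intermediate.

The module ships a pinned reference table generated from a 30-conformer
ensemble with a documented seed; ``build_reference`` regenerates it (or
variants) reproducibly.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .sasa_core import DEFAULT_N_POINTS, SASAProfile, sasa_profile
from .structure_io import RadiiTable, THREE_TO_ONE

__all__ = [
    "ReferenceAccessibility",
    "EnvironmentLabel",
    "EnvironmentSummary",
    "build_reference",
    "load_packaged_reference",
    "classify",
    "summarize",
    "SURFACE_THRESHOLD",
    "NUCLEUS_THRESHOLD",
]

SURFACE_THRESHOLD = 0.5
NUCLEUS_THRESHOLD = 0.2

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class ReferenceAccessibility:
    """Per-residue-type mean side-chain SASA in the Gly-X-Gly context (Å²).

    The Gly entry is the mean *all-atom* SASA of the central Gly, since it
    has no side chain.
    """

    values: dict[str, float]
    ensemble_size: int
    seed: int
    radii_tag: str

    def __post_init__(self) -> None:
        missing = set(AMINO_ACIDS) - set(self.values)
        if missing:
            raise ValueError(f"reference lacks entries for {sorted(missing)}")
        bad = [aa for aa in AMINO_ACIDS if self.values[aa] <= 0]
        if bad:
            raise ValueError(f"non-positive reference values for {bad}")

    def __getitem__(self, aa: str) -> float:
        return self.values[aa]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# gly-x-gly reference accessibilities (A^2)\n")
            fh.write(f"# ensemble_size={self.ensemble_size} seed={self.seed} "
                     f"radii={self.radii_tag}\n")
            fh.write("residue\tmean_sidechain_sasa\n")
            for aa in AMINO_ACIDS:
                fh.write(f"{aa}\t{self.values[aa]:.6f}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ReferenceAccessibility":
        values: dict[str, float] = {}
        ensemble_size, seed, radii_tag = 0, 0, "unknown"
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line.startswith("#"):
                    for token in line.lstrip("# ").split():
                        if token.startswith("ensemble_size="):
                            ensemble_size = int(token.split("=", 1)[1])
                        elif token.startswith("seed="):
                            seed = int(token.split("=", 1)[1])
                        elif token.startswith("radii="):
                            radii_tag = token.split("=", 1)[1]
                    continue
                if not line or line.startswith("residue"):
                    continue
                aa, val = line.split("\t")
                values[aa] = float(val)
        return cls(values=values, ensemble_size=ensemble_size, seed=seed,
                   radii_tag=radii_tag)


@dataclass(frozen=True)
class EnvironmentLabel:
    res_index: int
    res_name: str
    ratio: float
    label: str  # nucleus | surface | intermediate


@dataclass(frozen=True)
class EnvironmentSummary:
    """Aggregate SASA of the nucleus and surface residue sets (Å²)."""

    nucleus_total: float
    nucleus_apolar: float
    nucleus_backbone: float
    nucleus_sidechain: float
    surface_total: float
    surface_apolar: float
    surface_backbone: float
    surface_sidechain: float
    total_ave_sasa: float
    n_nucleus: int
    n_surface: int
    n_intermediate: int


#: Seed of the packaged 30-conformer reference ensemble.
PACKAGED_REFERENCE_SEED = 42
PACKAGED_REFERENCE_N = 30


def build_reference(
    n: int = PACKAGED_REFERENCE_N,
    seed: int = PACKAGED_REFERENCE_SEED,
    radii: RadiiTable | None = None,
    n_points: int = DEFAULT_N_POINTS,
) -> ReferenceAccessibility:
    """Build the Gly-X-Gly reference table from an *n*-conformer ensemble.

    For each residue type X, *n* clash-free Gly-X-Gly tripeptides are
    generated with random backbone and side-chain dihedrals and the mean
    side-chain SASA of the central residue (all-atom for Gly) is stored.
    Deterministic in (n, seed, radii, n_points).
    """
    from .synthetic_data import gxg_conformers

    if n < 1:
        raise ValueError("ensemble size must be >= 1")
    radii = radii or RadiiTable()
    values: dict[str, float] = {}
    for aa in AMINO_ACIDS:
        total = 0.0
        for conf in gxg_conformers(aa, n, seed, radii):
            prof = sasa_profile(conf, radii, n_points)
            central = prof.residues[1]
            total += central.total if aa == "G" else central.sidechain
        values[aa] = total / n
    return ReferenceAccessibility(
        values=values, ensemble_size=n, seed=seed, radii_tag=radii.name
    )


def load_packaged_reference() -> ReferenceAccessibility:
    """Load the pinned reference table shipped with the package."""
    ref = resources.files("scrsasa") / "data" / "gxg_reference_n30.tsv"
    with resources.as_file(ref) as path:
        return ReferenceAccessibility.from_tsv(path)


def classify(
    profile: SASAProfile,
    ref: ReferenceAccessibility,
    *,
    surface_threshold: float = SURFACE_THRESHOLD,
    nucleus_threshold: float = NUCLEUS_THRESHOLD,
) -> list[EnvironmentLabel]:
    """Classify every residue of *profile* as nucleus/surface/intermediate.

    Thresholds are strict: label is surface iff ratio > *surface_threshold*
    and nucleus iff ratio < *nucleus_threshold*.
    """
    if not 0 <= nucleus_threshold < surface_threshold <= 1:
        raise ValueError("need 0 <= nucleus < surface <= 1")
    labels: list[EnvironmentLabel] = []
    for r in profile.residues:
        aa = THREE_TO_ONE[r.res_name]
        denom = ref[aa]
        numer = r.total if aa == "G" else r.sidechain
        ratio = numer / denom
        if ratio > surface_threshold:
            label = "surface"
        elif ratio < nucleus_threshold:
            label = "nucleus"
        else:
            label = "intermediate"
        labels.append(
            EnvironmentLabel(res_index=r.res_index, res_name=r.res_name,
                             ratio=ratio, label=label)
        )
    return labels


def summarize(
    profile: SASAProfile,
    labels: list[EnvironmentLabel],
    *,
    denominator: str = "classified",
) -> EnvironmentSummary:
    """Aggregate nucleus/surface SASA and the per-residue average.

    ``total_ave_sasa`` is (nucleus total + surface total) divided by the
    number of classified residues (``denominator="classified"``, the
    default) or by the full sequence length (``denominator="length"``).
    """
    if len(labels) != len(profile.residues):
        raise ValueError("labels and profile lengths differ")
    if denominator not in ("classified", "length"):
        raise ValueError(f"unknown denominator mode {denominator!r}")
    sums = {
        "nucleus": [0.0, 0.0, 0.0, 0.0],
        "surface": [0.0, 0.0, 0.0, 0.0],
    }
    counts = {"nucleus": 0, "surface": 0, "intermediate": 0}
    for r, lab in zip(profile.residues, labels):
        counts[lab.label] += 1
        if lab.label in sums:
            acc = sums[lab.label]
            acc[0] += r.total
            acc[1] += r.apolar
            acc[2] += r.backbone
            acc[3] += r.sidechain
    classified = counts["nucleus"] + counts["surface"]
    denom = classified if denominator == "classified" else len(labels)
    env_total = sums["nucleus"][0] + sums["surface"][0]
    return EnvironmentSummary(
        nucleus_total=sums["nucleus"][0],
        nucleus_apolar=sums["nucleus"][1],
        nucleus_backbone=sums["nucleus"][2],
        nucleus_sidechain=sums["nucleus"][3],
        surface_total=sums["surface"][0],
        surface_apolar=sums["surface"][1],
        surface_backbone=sums["surface"][2],
        surface_sidechain=sums["surface"][3],
        total_ave_sasa=env_total / denom if denom else 0.0,
        n_nucleus=counts["nucleus"],
        n_surface=counts["surface"],
        n_intermediate=counts["intermediate"],
    )
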