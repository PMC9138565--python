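"""Structurally conserved regions and SCR-SASA fingerprints.

A structurally conserved region (SCR) is detected here from a multiple
sequence alignment: a column is *conserved* when it is gap-free in every
sequence and its majority residue reaches a minimum frequency; maximal
runs of conserved columns at least ``min_len`` long become regions.
Explicit intervals (BED-like, 0-based half-open, in alignment
coordinates) can be supplied instead.

The SCR-SASA fingerprint of a protein is the ordered vector of its
residue SASA values over all SCR columns — the conserved-surface
descriptor used as the clustering observation.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .sasa_core import SASAProfile

__all__ = [
    "SCRSet",
    "Fingerprint",
    "identify_scrs",
    "scrs_from_intervals",
    "read_intervals",
    "fingerprint",
    "correlation_matrix",
    "residue_preferences",
]


@dataclass(frozen=True)
class SCRSet:
    """Conserved regions over one alignment.

    ``regions`` are disjoint, sorted [start, end) column intervals;
    ``maps`` gives, per sequence id, the residue index (0-based, ungapped
    coordinates) for every SCR column, region by region.
    """

    alignment_id: str
    regions: tuple[tuple[int, int], ...]
    maps: dict[str, tuple[int, ...]]

    @property
    def n_columns(self) -> int:
        return sum(e - s for s, e in self.regions)

    def __post_init__(self) -> None:
        prev_end = -1
        for s, e in self.regions:
            if s >= e:
                raise ValueError(f"empty region [{s}, {e})")
            if s < prev_end:
                raise ValueError("regions overlap or are unsorted")
            prev_end = e
        for pid, m in self.maps.items():
            if len(m) != self.n_columns:
                raise ValueError(f"map length mismatch for {pid!r}")


@dataclass(frozen=True)
class Fingerprint:
    protein_id: str
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.values):
            raise ValueError("fingerprint values must be >= 0")


def _column_maps(
    alignment: list[tuple[str, str]],
    regions: list[tuple[int, int]],
) -> dict[str, tuple[int, ...]]:
    """Residue-index maps via per-sequence gap-skipping cursors."""
    maps: dict[str, tuple[int, ...]] = {}
    for pid, seq in alignment:
        # residue index at each alignment column (or -1 on a gap)
        col_to_res = []
        cursor = 0
        for c in seq:
            if c == "-":
                col_to_res.append(-1)
            else:
                col_to_res.append(cursor)
                cursor += 1
        out: list[int] = []
        for s, e in regions:
            for col in range(s, e):
                idx = col_to_res[col]
                if idx < 0:
                    raise ValueError(
                        f"gap inside SCR column {col} for sequence {pid!r}"
                    )
                out.append(idx)
        maps[pid] = tuple(out)
    return maps


def identify_scrs(
    alignment: list[tuple[str, str]],
    min_len: int = 5,
    min_conservation: float = 0.5,
    alignment_id: str = "alignment",
) -> SCRSet:
    """Detect conserved regions in a rectangular alignment.

    A column is conserved iff it is gap-free and its majority residue
    frequency is >= *min_conservation*; maximal conserved runs of length
    >= *min_len* become regions.
    """
    if len(alignment) < 2:
        raise ValueError("need at least two aligned sequences")
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    lengths = {len(seq) for _, seq in alignment}
    if len(lengths) != 1:
        raise ValueError(f"ragged alignment (lengths {sorted(lengths)})")
    n_cols = lengths.pop()
    n_seq = len(alignment)

    conserved = []
    for col in range(n_cols):
        column = [seq[col] for _, seq in alignment]
        if "-" in column:
            conserved.append(False)
            continue
        _, top = Counter(column).most_common(1)[0]
        conserved.append(top / n_seq >= min_conservation)

    regions: list[tuple[int, int]] = []
    start = None
    for col, flag in enumerate(conserved + [False]):
        if flag and start is None:
            start = col
        elif not flag and start is not None:
            if col - start >= min_len:
                regions.append((start, col))
            start = None

    return SCRSet(
        alignment_id=alignment_id,
        regions=tuple(regions),
        maps=_column_maps(alignment, regions),
    )


def scrs_from_intervals(
    alignment: list[tuple[str, str]],
    intervals: list[tuple[int, int]],
    alignment_id: str = "alignment",
) -> SCRSet:
    """Build an :class:`SCRSet` from explicit alignment-column intervals."""
    regions = sorted(intervals)
    return SCRSet(
        alignment_id=alignment_id,
        regions=tuple(regions),
        maps=_column_maps(alignment, regions),
    )


def read_intervals(path: str | Path) -> list[tuple[int, int]]:
    """Read BED-like intervals: ``name<TAB>start<TAB>end`` (0-based, half-open)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            out.append((int(fields[-2]), int(fields[-1])))
    return out


def fingerprint(
    profiles: dict[str, SASAProfile],
    scrs: SCRSet,
    *,
    component: str = "total",
) -> list[Fingerprint]:
    """Extract one SCR-SASA fingerprint per protein in the SCR set.

    ``component`` selects the SASA component per mapped residue: "total"
    (default) or "sidechain".
    """
    if component not in ("total", "sidechain"):
        raise ValueError(f"unknown SASA component {component!r}")
    fps = []
    for pid, mapping in scrs.maps.items():
        if pid not in profiles:
            raise KeyError(f"no SASA profile for protein {pid!r}")
        prof = profiles[pid]
        values = []
        for idx in mapping:
            r = prof.residues[idx]
            values.append(r.total if component == "total" else r.sidechain)
        fps.append(Fingerprint(protein_id=pid, values=tuple(values)))
    return fps


def correlation_matrix(fps: list[Fingerprint]) -> tuple[list[str], np.ndarray]:
    """Pearson correlation matrix of the fingerprints.

    Returns (labels, matrix); the matrix is symmetric with unit diagonal.
    Zero-variance fingerprints are rejected, naming the protein.
    """
    if len(fps) < 2:
        raise ValueError("need at least two fingerprints")
    lengths = {len(fp.values) for fp in fps}
    if len(lengths) != 1 or lengths.pop() < 2:
        raise ValueError("fingerprints must share one length >= 2")
    data = np.array([fp.values for fp in fps], dtype=float)
    for fp, row in zip(fps, data):
        if np.isclose(row.std(), 0.0):
            raise ValueError(
                f"zero-variance fingerprint for protein {fp.protein_id!r}"
            )
    mat = np.corrcoef(data)
    np.fill_diagonal(mat, 1.0)
    return [fp.protein_id for fp in fps], mat


def residue_preferences(
    scrs: SCRSet, sequences: dict[str, str]
) -> dict[str, int]:
    """Count residue types over all SCR-mapped positions of all proteins."""
    counts: Counter[str] = Counter()
    for pid, mapping in scrs.maps.items():
        seq = sequences[pid]
        for idx in mapping:
            counts[seq[idx]] += 1
    return {aa: counts.get(aa, 0) for aa in "ACDEFGHIKLMNPQRSTVWY"}
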