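"""Packaged study inputs.

Ships the published amino-acid compositions of the eight *Amycolatopsis
eburnea* lipases (UniProt accessions A0A3R9KNJ9, A0A3R9DUJ4, A0A427T6P4,
A0A3R9KMI2, A0A3R9EQB2, A0A3R9F8T1, A0A3R9DV90, A0A427T2R3) and helpers
to materialise composition-faithful surrogate sequences from them.

Every sequence-level descriptor computed by :mod:`scrsasa.seqprops`
(residue count, molecular weight, pI, charge counts, aliphatic index,
GRAVY, composition) is a function of amino-acid composition alone, so a
surrogate sequence with the published composition reproduces the real
entry's descriptors exactly.  The surrogate places one Met first —
full-length bacterial entries start with the initiator methionine, which
pins the residue-specific N-terminal pKa used by the pI model — and lays
out the remaining residues deterministically; it is *synthetic* and
carries no positional information from the real proteins.
"""

from __future__ import annotations

from importlib import resources

from .seqprops import AMINO_ACIDS

__all__ = [
    "LIPASE_ACCESSIONS",
    "lipase_compositions",
    "surrogate_sequence",
    "surrogate_sequences",
]

#: Study order (lipase 1..8) -> UniProt accession.
LIPASE_ACCESSIONS: tuple[str, ...] = (
    "A0A3R9KNJ9", "A0A3R9DUJ4", "A0A427T6P4", "A0A3R9KMI2",
    "A0A3R9EQB2", "A0A3R9F8T1", "A0A3R9DV90", "A0A427T2R3",
)


def lipase_compositions() -> dict[str, dict[str, int]]:
    """Published 20-residue count maps, keyed by accession."""
    ref = resources.files("scrsasa") / "data" / "lipase_compositions.tsv"
    out: dict[str, dict[str, int]] = {}
    with ref.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        aas = header[1:]
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if not fields[0]:
                continue
            out[fields[0]] = {aa: int(v) for aa, v in zip(aas, fields[1:])}
    return out


def surrogate_sequence(composition: dict[str, int]) -> str:
    """Deterministic composition-faithful sequence (initiator Met first)."""
    counts = dict(composition)
    prefix = ""
    if counts.get("M", 0) > 0:
        counts["M"] -= 1
        prefix = "M"
    body = "".join(aa * counts.get(aa, 0) for aa in AMINO_ACIDS)
    return prefix + body


def surrogate_sequences() -> dict[str, str]:
    """Surrogate sequences for all packaged lipase compositions."""
    return {
        acc: surrogate_sequence(comp)
        for acc, comp in lipase_compositions().items()
    }
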