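"""Chou–Fasman secondary-structure prediction.

Classic propensity-based prediction: helices and sheets are seeded by
nucleation windows rich in strong formers and extended while the local
mean propensity stays favourable; turns are flagged by the four-residue
bend-probability product.  Helix, sheet and turn assignments are kept as
independent, possibly overlapping masks — the historical convention of
CFSSP-style servers, whose per-class percentages can therefore sum above
100 — with a resolved single-label track derived afterwards.

Propensity and bend-frequency tables are the published Chou & Fasman
(1978) values (see docs/methods.md for the citation context).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["SSPrediction", "predict", "P_ALPHA", "P_BETA", "P_TURN"]

P_ALPHA = {
    "E": 1.51, "M": 1.45, "A": 1.42, "L": 1.21, "K": 1.16, "F": 1.13,
    "Q": 1.11, "W": 1.08, "I": 1.08, "V": 1.06, "D": 1.01, "H": 1.00,
    "R": 0.98, "T": 0.83, "S": 0.77, "C": 0.70, "Y": 0.69, "N": 0.67,
    "P": 0.57, "G": 0.57,
}
P_BETA = {
    "V": 1.70, "I": 1.60, "Y": 1.47, "F": 1.38, "W": 1.37, "L": 1.30,
    "C": 1.19, "T": 1.19, "Q": 1.10, "M": 1.05, "R": 0.93, "N": 0.89,
    "H": 0.87, "A": 0.83, "S": 0.75, "G": 0.75, "K": 0.74, "P": 0.55,
    "D": 0.54, "E": 0.37,
}
P_TURN = {
    "N": 1.56, "G": 1.56, "P": 1.52, "D": 1.46, "S": 1.43, "C": 1.19,
    "Y": 1.14, "K": 1.01, "Q": 0.98, "T": 0.96, "W": 0.96, "R": 0.95,
    "H": 0.95, "E": 0.74, "A": 0.66, "M": 0.60, "F": 0.60, "L": 0.59,
    "V": 0.50, "I": 0.47,
}
# Bend frequencies f(i)..f(i+3) for the turn-probability product.
F_TURN = {
    "A": (0.060, 0.076, 0.035, 0.058), "R": (0.070, 0.106, 0.099, 0.085),
    "N": (0.161, 0.083, 0.191, 0.091), "D": (0.147, 0.110, 0.179, 0.081),
    "C": (0.149, 0.050, 0.117, 0.128), "Q": (0.074, 0.098, 0.037, 0.098),
    "E": (0.056, 0.060, 0.077, 0.064), "G": (0.102, 0.085, 0.190, 0.152),
    "H": (0.140, 0.047, 0.093, 0.054), "I": (0.043, 0.034, 0.013, 0.056),
    "L": (0.061, 0.025, 0.036, 0.070), "K": (0.055, 0.115, 0.072, 0.095),
    "M": (0.068, 0.082, 0.014, 0.055), "F": (0.059, 0.041, 0.065, 0.065),
    "P": (0.102, 0.301, 0.034, 0.068), "S": (0.120, 0.139, 0.125, 0.106),
    "T": (0.086, 0.108, 0.065, 0.079), "W": (0.077, 0.013, 0.064, 0.167),
    "Y": (0.082, 0.065, 0.114, 0.125), "V": (0.062, 0.048, 0.028, 0.053),
}

HELIX_WINDOW, HELIX_MIN_FORMERS = 6, 4
SHEET_WINDOW, SHEET_MIN_FORMERS = 5, 3
TURN_PRODUCT_CUTOFF = 7.5e-5


@dataclass(frozen=True)
class SSPrediction:
    """Per-residue secondary-structure masks and summary percentages."""

    sequence: str
    helix_mask: tuple[bool, ...]
    sheet_mask: tuple[bool, ...]
    turn_mask: tuple[bool, ...]
    resolved: str

    @property
    def pct_helix(self) -> float:
        return 100.0 * sum(self.helix_mask) / len(self.sequence)

    @property
    def pct_sheet(self) -> float:
        return 100.0 * sum(self.sheet_mask) / len(self.sequence)

    @property
    def pct_turn(self) -> float:
        return 100.0 * sum(self.turn_mask) / len(self.sequence)


def _mean(table: dict[str, float], frag: str) -> float:
    return sum(table[c] for c in frag) / len(frag)


def _nucleate_and_extend(
    seq: str, table: dict[str, float], window: int, min_formers: int
) -> list[bool]:
    n = len(seq)
    mask = [False] * n
    # nucleation: any window with enough residues of propensity >= 1.00
    for i in range(n - window + 1):
        frag = seq[i:i + window]
        if sum(1 for c in frag if table[c] >= 1.00) >= min_formers:
            for j in range(i, i + window):
                mask[j] = True
    # extension: grow each nucleated run while the mean propensity of the
    # trailing tetrapeptide (the four residues at the advancing edge) holds
    changed = True
    while changed:
        changed = False
        for i in range(n):
            if mask[i]:
                continue
            # extend rightwards into i
            if i >= 1 and mask[i - 1]:
                tetra = seq[max(0, i - 3):i + 1]
                if len(tetra) == 4 and _mean(table, tetra) >= 1.00:
                    mask[i] = True
                    changed = True
                    continue
            # extend leftwards into i
            if i + 1 < n and mask[i + 1]:
                tetra = seq[i:i + 4]
                if len(tetra) == 4 and _mean(table, tetra) >= 1.00:
                    mask[i] = True
                    changed = True
    return mask


def _turn_mask(seq: str) -> list[bool]:
    n = len(seq)
    mask = [False] * n
    for i in range(n - 3):
        quad = seq[i:i + 4]
        p = 1.0
        for k, c in enumerate(quad):
            p *= F_TURN[c][k]
        mean_t = _mean(P_TURN, quad)
        if (
            p > TURN_PRODUCT_CUTOFF
            and mean_t > 1.00
            and mean_t > _mean(P_ALPHA, quad)
            and mean_t > _mean(P_BETA, quad)
        ):
            for j in range(i, i + 4):
                mask[j] = True
    return mask


def predict(seq: str) -> SSPrediction:
    """Predict secondary structure for *seq* (length >= 6).

    Returns overlapping helix/sheet/turn masks plus a resolved track in
    which turns win outright and helix/sheet overlaps go to the class with
    the larger mean propensity over the contested run.
    """
    seq = seq.upper()
    if len(seq) < HELIX_WINDOW:
        raise ValueError(
            f"sequence of length {len(seq)} is shorter than the nucleation "
            f"window ({HELIX_WINDOW})"
        )
    for i, c in enumerate(seq):
        if c not in P_ALPHA:
            raise ValueError(f"illegal amino-acid letter {c!r} at position {i + 1}")

    helix = _nucleate_and_extend(seq, P_ALPHA, HELIX_WINDOW, HELIX_MIN_FORMERS)
    sheet = _nucleate_and_extend(seq, P_BETA, SHEET_WINDOW, SHEET_MIN_FORMERS)
    turn = _turn_mask(seq)

    # helix/sheet overlaps are resolved run-wise: the whole contested run
    # goes to the class with the larger mean propensity over that run
    n = len(seq)
    overlap_winner = [""] * n
    i = 0
    while i < n:
        if helix[i] and sheet[i]:
            j = i
            while j < n and helix[j] and sheet[j]:
                j += 1
            run = seq[i:j]
            winner = "H" if _mean(P_ALPHA, run) >= _mean(P_BETA, run) else "E"
            for k in range(i, j):
                overlap_winner[k] = winner
            i = j
        else:
            i += 1

    resolved = []
    for i in range(n):
        if turn[i]:
            resolved.append("T")
        elif overlap_winner[i]:
            resolved.append(overlap_winner[i])
        elif helix[i]:
            resolved.append("H")
        elif sheet[i]:
            resolved.append("E")
        else:
            resolved.append("C")
    return SSPrediction(
        sequence=seq,
        helix_mask=tuple(helix),
        sheet_mask=tuple(sheet),
        turn_mask=tuple(turn),
        resolved="".join(resolved),
    )
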