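"""The Grantham (1974) amino-acid chemical-distance matrix.

Distances combine side-chain composition, polarity and molecular volume:
D_ij = rho * sqrt(alpha*(c_i-c_j)^2 + beta*(p_i-p_j)^2 + gamma*(v_i-v_j)^2)
with rho scaling the mean pairwise distance to 100.  The published integer
table is embedded verbatim and is the authoritative source; the property
values and formula constants are kept alongside for independent
recomputation.  Note the printed table's Asp-Trp entry (181) deviates from
recomputation (~191) — the printed value is retained.
"""

from __future__ import annotations

RESIDUES = "ARNDCQEGHILKMFPSTWYV"

#: side-chain properties: composition c, polarity p, molecular volume v
PROPERTIES: dict[str, tuple[float, float, float]] = {
    "S": (1.42, 9.2, 32.0),
    "R": (0.65, 10.5, 124.0),
    "L": (0.00, 4.9, 111.0),
    "P": (0.39, 8.0, 32.5),
    "T": (0.71, 8.6, 61.0),
    "A": (0.00, 8.1, 31.0),
    "V": (0.00, 5.9, 84.0),
    "G": (0.74, 9.0, 3.0),
    "I": (0.00, 5.2, 111.0),
    "F": (0.00, 5.2, 132.0),
    "Y": (0.20, 6.2, 136.0),
    "C": (2.75, 5.5, 55.0),
    "H": (0.58, 10.4, 96.0),
    "Q": (0.89, 10.5, 85.0),
    "N": (1.33, 11.6, 56.0),
    "K": (0.33, 11.3, 119.0),
    "D": (1.38, 13.0, 54.0),
    "E": (0.92, 12.3, 83.0),
    "M": (0.00, 5.7, 105.0),
    "W": (0.13, 5.4, 170.0),
}

#: formula constants (composition, polarity, volume weights)
ALPHA, BETA, GAMMA = 1.833, 0.1018, 0.000399

# published upper-triangle table, row order as printed
_ROWS: dict[str, tuple[str, tuple[int, ...]]] = {
    "S": ("RLPTAVGIFYCHQNKDEMW", (110, 145, 74, 58, 99, 124, 56, 142, 155, 144, 112, 89, 68, 46, 121, 65, 80, 135, 177)),
    "R": ("LPTAVGIFYCHQNKDEMW", (102, 103, 71, 112, 96, 125, 97, 97, 77, 180, 29, 43, 86, 26, 96, 54, 91, 101)),
    "L": ("PTAVGIFYCHQNKDEMW", (98, 92, 96, 32, 138, 5, 22, 36, 198, 99, 113, 153, 107, 172, 138, 15, 61)),
    "P": ("TAVGIFYCHQNKDEMW", (38, 27, 68, 42, 95, 114, 110, 169, 77, 76, 91, 103, 108, 93, 87, 147)),
    "T": ("AVGIFYCHQNKDEMW", (58, 69, 59, 89, 103, 92, 149, 47, 42, 65, 78, 85, 65, 81, 128)),
    "A": ("VGIFYCHQNKDEMW", (64, 60, 94, 113, 112, 195, 86, 91, 111, 106, 126, 107, 84, 148)),
    "V": ("GIFYCHQNKDEMW", (109, 29, 50, 55, 192, 84, 96, 133, 97, 152, 121, 21, 88)),
    "G": ("IFYCHQNKDEMW", (135, 153, 147, 159, 98, 87, 80, 127, 94, 98, 127, 184)),
    "I": ("FYCHQNKDEMW", (21, 33, 198, 94, 109, 149, 102, 168, 134, 10, 61)),
    "F": ("YCHQNKDEMW", (22, 205, 100, 116, 158, 102, 177, 140, 28, 40)),
    "Y": ("CHQNKDEMW", (194, 83, 99, 143, 85, 160, 122, 36, 37)),
    "C": ("HQNKDEMW", (174, 154, 139, 202, 154, 170, 196, 215)),
    "H": ("QNKDEMW", (24, 68, 32, 81, 40, 87, 115)),
    "Q": ("NKDEMW", (46, 53, 61, 29, 101, 130)),
    "N": ("KDEMW", (94, 23, 42, 142, 174)),
    "K": ("DEMW", (101, 56, 95, 110)),
    "D": ("EMW", (45, 160, 181)),
    "E": ("MW", (126, 152)),
    "M": ("W", (67,)),
}


def _build() -> dict[tuple[str, str], int]:
    matrix: dict[tuple[str, str], int] = {}
    for a in RESIDUES:
        matrix[(a, a)] = 0
    for a, (cols, values) in _ROWS.items():
        for b, d in zip(cols, values):
            matrix[(a, b)] = d
            matrix[(b, a)] = d
    return matrix


GRANTHAM: dict[tuple[str, str], int] = _build()


def formula_distance(a: str, b: str, rho: float = 50.723) -> float:
    """Recompute a Grantham distance from the property formula (oracle use)."""
    ca, pa, va = PROPERTIES[a]
    cb, pb, vb = PROPERTIES[b]
    return rho * (
        ALPHA * (ca - cb) ** 2 + BETA * (pa - pb) ** 2 + GAMMA * (va - vb) ** 2
    ) ** 0.5
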