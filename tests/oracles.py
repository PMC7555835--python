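"""Independent brute-force oracles used by the test suite.

These deliberately re-derive everything from first principles (own IUPAC
table, full variant enumeration, quadratic DP, path unions) so they share
no code path with the implementation they check.
"""

from __future__ import annotations

import itertools

import numpy as np

# --- independent IUPAC table (retyped, not imported) ---
ORACLE_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMP = str.maketrans("ACGT", "TGCA")
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def oracle_expand(seq: str) -> list[str]:
    return ["".join(t) for t in itertools.product(*[ORACLE_IUPAC[c] for c in seq])]


def oracle_revcomp_acgt(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def brute_force_sites(
    template: str, oligos: list[str], max_mismatch: int
) -> dict[tuple[int, str], int]:
    """Min mismatch count per (1-based start, strand) over a pool of IUPAC
    oligos, by full expansion and direct window comparison (ACGT templates).

    Strand '+' compares the oligo as written, '-' compares its reverse
    complement, mirroring primer annealing to either template strand.
    """
    t = np.array([_CODE[c] for c in template], dtype=np.int8)
    out: dict[tuple[int, str], int] = {}
    probes: dict[str, list[str]] = {"+": [], "-": []}
    for oligo in oligos:
        for v in oracle_expand(oligo):
            probes["+"].append(v)
            probes["-"].append(oracle_revcomp_acgt(v))
    for strand, variants in probes.items():
        plen = len(variants[0])
        windows = np.lib.stride_tricks.sliding_window_view(t, plen)
        varr = np.array([[_CODE[c] for c in v] for v in variants], dtype=np.int8)
        mm = (windows[:, None, :] != varr[None, :, :]).sum(axis=2).min(axis=1)
        for start0 in np.nonzero(mm <= max_mismatch)[0]:
            out[(int(start0) + 1, strand)] = int(mm[start0])
    return out


# --- quadratic-time affine-gap local alignment (Gotoh), hand-rolled ---

def smith_waterman_score(
    a: str, b: str, matrix, gap_open_total: int = 12, gap_extend: int = 1
) -> float:
    """Best local alignment score; first gap residue costs gap_open_total."""
    n, m = len(a), len(b)
    NEG = -10**9
    M = [[0] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG] * (m + 1) for _ in range(n + 1)]
    Iy = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = matrix[a[i - 1], b[j - 1]]
            M[i][j] = max(
                0,
                M[i - 1][j - 1] + s,
                Ix[i - 1][j - 1] + s,
                Iy[i - 1][j - 1] + s,
            )
            Ix[i][j] = max(M[i - 1][j] - gap_open_total, Ix[i - 1][j] - gap_extend)
            Iy[i][j] = max(M[i][j - 1] - gap_open_total, Iy[i][j - 1] - gap_extend)
            if M[i][j] > best:
                best = M[i][j]
    return float(best)


# --- Faith's PD by union of root-to-tip paths ---

def faith_pd_by_path_union(tree, observed: set[str]) -> float:
    """Sum of unique branch lengths on the union of root-to-tip paths."""
    seen = set()
    total = 0.0
    for tip in tree.tips():
        if tip.name not in observed:
            continue
        node = tip
        while node.parent is not None:
            if id(node) not in seen:
                seen.add(id(node))
                total += node.length or 0.0
            node = node.parent
    return total
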