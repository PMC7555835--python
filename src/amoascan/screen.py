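"""Hybrid metagenomic short-read screening for comammox amoA.

Raw shotgun reads are translated in all six frames and locally aligned
against a clade-labelled AmoA protein panel.  A read is annotated as
comammox-amoA-like only if its best hit reaches >= 80% amino-acid identity
over >= 25 aligned amino acids (the operative published filter); clade
relative abundances are then simple annotated-read proportions.

Scoring follows BLASTX defaults: BLOSUM62 with gap open 11, extend 1
(BLAST convention - a gap of length k costs 11 + k).  The BLAST E-value
pre-filter is replaced by a raw-score floor (default 50; an exact 25-aa
match scores >= 100), since E-values require a database-size calibration
that is not part of the filter itself.  Identity is identical columns over
all aligned columns, gap columns included in the denominator.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

from .tables import CladeRATable

__all__ = [
    "ProteinRef",
    "ReadHit",
    "six_frame_translate",
    "local_align_protein",
    "screen_read",
    "compute_clade_ra",
]

_AA = set("ACDEFGHIKLMNPQRSTVWYX*")
_NT = set("ACGTN")


@dataclass(frozen=True)
class ProteinRef:
    """A clade-labelled reference protein (AmoA panel member)."""

    id: str
    clade: str  # "A" | "B", optionally subclade "A.1" etc.
    aa_seq: str

    def __post_init__(self) -> None:
        if not self.clade:
            raise ValueError(f"panel member {self.id}: missing clade label")
        bad = set(self.aa_seq.upper()) - _AA
        if bad:
            raise ValueError(f"panel member {self.id}: invalid residues {sorted(bad)}")
        object.__setattr__(self, "aa_seq", self.aa_seq.upper())

    @property
    def major_clade(self) -> str:
        return self.clade.split(".")[0]


@dataclass(frozen=True)
class ReadHit:
    read_id: str
    ref_id: str
    frame: int  # +-1, +-2, +-3
    pct_identity: float
    aln_len_aa: int
    score: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.pct_identity <= 100.0):
            raise ValueError("pct_identity out of [0, 100]")
        if self.aln_len_aa < 1:
            raise ValueError("aln_len_aa must be >= 1")


def six_frame_translate(nt_seq: str) -> dict[int, str]:
    """Translate a nucleotide sequence in frames +1..+3 and -1..-3.

    Standard genetic code; trailing partial codons are dropped, stop codons
    render as ``*`` and any codon containing N translates to ``X``.  Frame
    -k is the frame +k translation of the reverse complement.
    """
    seq = nt_seq.upper()
    if len(seq) < 3:
        raise ValueError("sequence shorter than one codon")
    bad = set(seq) - _NT
    if bad:
        raise ValueError(f"invalid nucleotide symbols {sorted(bad)} (ACGTN allowed)")
    frames: dict[int, str] = {}
    rc = str(Seq(seq).reverse_complement())
    for k in (1, 2, 3):
        for sign, s in ((1, seq), (-1, rc)):
            sub = s[k - 1:]
            sub = sub[: len(sub) - len(sub) % 3]
            frames[sign * k] = str(Seq(sub).translate()) if sub else ""
    return frames


def _make_aligner(matrix: str, gap_open: int, gap_extend: int) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    # BLAST convention: gap of length k costs open + k * extend
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


_DEFAULT_ALIGNER = None


def local_align_protein(
    query_aa: str,
    ref_aa: str,
    matrix: str = "BLOSUM62",
    gap_open: int = 11,
    gap_extend: int = 1,
) -> Optional[tuple[float, float, int]]:
    """Best Smith-Waterman local alignment of two protein sequences.

    Returns ``(score, pct_identity, aln_len)`` or None when no positive
    scoring alignment exists.  Identity counts identical columns over all
    alignment columns (internal gap columns in the denominator).
    """
    if not query_aa or not ref_aa:
        raise ValueError("empty protein sequence")
    global _DEFAULT_ALIGNER
    if matrix == "BLOSUM62" and gap_open == 11 and gap_extend == 1:
        if _DEFAULT_ALIGNER is None:
            _DEFAULT_ALIGNER = _make_aligner(matrix, gap_open, gap_extend)
        aligner = _DEFAULT_ALIGNER
    else:
        aligner = _make_aligner(matrix, gap_open, gap_extend)
    alignments = aligner.align(query_aa.upper(), ref_aa.upper())
    if len(alignments) == 0:
        return None
    aln = alignments[0]
    if aln.score <= 0:
        return None
    # column bookkeeping from the aligned segment pairs (robust to how the
    # string representation renders unaligned flanks)
    cols = 0
    matches = 0
    qseq, rseq = aln.sequences
    prev_q = prev_r = None
    for (q0, q1), (r0, r1) in zip(aln.aligned[0], aln.aligned[1]):
        if prev_q is not None:
            cols += (q0 - prev_q) + (r0 - prev_r)  # internal gap columns
        for i in range(q1 - q0):
            cols += 1
            if qseq[q0 + i] == rseq[r0 + i]:
                matches += 1
        prev_q, prev_r = q1, r1
    if cols == 0:
        return None
    return float(aln.score), 100.0 * matches / cols, cols


def screen_read(
    read_nt: str,
    panel: Sequence[ProteinRef],
    min_identity: float = 80.0,
    min_len_aa: int = 25,
    min_score: float = 50.0,
    *,
    read_id: str = "read",
) -> Optional[tuple[str, ReadHit]]:
    """Annotate one read against the panel, or return None (no hit).

    The best hit over all six frames and all panel members is chosen by
    score, then identity, then lexicographic reference id (deterministic);
    it is returned only if it passes the identity, length and score gates.
    """
    if not panel:
        raise ValueError("empty reference panel")
    frames = six_frame_translate(read_nt)
    best: tuple[float, float, str, int, int] | None = None  # score, ident, ref, frame, len
    best_ref: ProteinRef | None = None
    for frame, aa in frames.items():
        if len(aa) < 1:
            continue
        for ref in panel:
            res = local_align_protein(aa, ref.aa_seq)
            if res is None:
                continue
            score, ident, aln_len = res
            key = (score, ident, ref.id, frame, aln_len)
            if best is None or (score, ident) > (best[0], best[1]) or (
                (score, ident) == (best[0], best[1]) and ref.id < best[2]
            ):
                best = key
                best_ref = ref
    if best is None or best_ref is None:
        return None
    score, ident, ref_id, frame, aln_len = best
    if ident < min_identity or aln_len < min_len_aa or score < min_score:
        return None
    hit = ReadHit(
        read_id=read_id,
        ref_id=ref_id,
        frame=frame,
        pct_identity=ident,
        aln_len_aa=aln_len,
        score=score,
    )
    return best_ref.major_clade, hit


def compute_clade_ra(assignments: Iterable[tuple[str, str]]) -> CladeRATable:
    """Clade read counts and relative abundances from (read_id, clade) pairs.

    With counts {A: 3, B: 23} the reported percentages are 11.54 / 88.46;
    the unrounded values stay available on the returned table.
    """
    counts = Counter(clade for _read, clade in assignments)
    return CladeRATable.from_counts(dict(counts))
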