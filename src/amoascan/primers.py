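"""Degenerate primer model for the comammox *amoA* primer sets.

Two primer systems are packaged: the clade-specific mixtures
comaA-244f/659r (clade A) and comaB-244f/659r (clade B), each consisting of
six separately synthesised forward and reverse oligonucleotides, and the
total-comammox pair Ntsp-amoA-162F/359R, a single degenerate forward/reverse
pair.  A degenerate primer written with IUPAC ambiguity codes is treated as
the equimolar pool of all of its fully specified expansions.

Coordinates are 1-based inclusive on the comammox *amoA* reference numbering.
Published binding intervals are re-anchored so that the interval length
equals the oligonucleotide length: forward primers keep the published start
position, reverse primers keep the published end position (the 3'-proximal
anchor of the amplicon on each side), so that
``binding_end - binding_start + 1`` equals the oligo length and the
forward-start/reverse-end pair reproduces the published product sizes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable

__all__ = [
    "IUPAC_SETS",
    "Primer",
    "PrimerMixture",
    "expand_degenerate",
    "degeneracy",
    "reverse_complement",
    "iupac_match",
    "expected_amplicon_length",
    "load_packaged_primer_sets",
    "read_primer_table",
    "write_primer_table",
]

#: Allowed bases for each IUPAC nucleotide symbol (sorted alphabetically).
IUPAC_SETS: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT: dict[str, str] = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

#: 4-bit encoding of the allowed-base set; two symbols are compatible iff
#: the bitwise AND of their masks is non-zero.
_BASE_BIT = {"A": 1, "C": 2, "G": 4, "T": 8}
IUPAC_MASK: dict[str, int] = {
    sym: sum(_BASE_BIT[b] for b in bases) for sym, bases in IUPAC_SETS.items()
}


def _validate_iupac(seq: str, *, what: str = "sequence") -> str:
    if not seq:
        raise ValueError(f"{what} must be non-empty")
    seq = seq.upper()
    for i, ch in enumerate(seq, start=1):
        if ch not in IUPAC_SETS:
            raise ValueError(
                f"invalid IUPAC symbol {ch!r} at position {i} of {what}"
            )
    return seq


def expand_degenerate(iupac_seq: str) -> list[str]:
    """Expand an IUPAC-degenerate sequence into all fully specified variants.

    Variants are returned exactly once, in lexicographic order.  The list
    length equals :func:`degeneracy`.
    """
    seq = _validate_iupac(iupac_seq)
    pools = [IUPAC_SETS[ch] for ch in seq]
    return ["".join(p) for p in itertools.product(*pools)]


def degeneracy(iupac_seq: str) -> int:
    """Number of fully specified variants encoded by ``iupac_seq``."""
    seq = _validate_iupac(iupac_seq)
    n = 1
    for ch in seq:
        n *= len(IUPAC_SETS[ch])
    return n


def reverse_complement(iupac_seq: str) -> str:
    """IUPAC-aware reverse complement (an involution)."""
    seq = _validate_iupac(iupac_seq)
    return "".join(_COMPLEMENT[ch] for ch in reversed(seq))


def iupac_match(primer_base: str, template_base: str) -> bool:
    """True iff the allowed-base sets of the two symbols intersect.

    Symmetric; ``N`` matches everything.
    """
    p = _validate_iupac(primer_base, what="primer base")
    t = _validate_iupac(template_base, what="template base")
    if len(p) != 1 or len(t) != 1:
        raise ValueError("iupac_match compares single symbols")
    return bool(IUPAC_MASK[p] & IUPAC_MASK[t])


@dataclass(frozen=True)
class Primer:
    """A single (possibly degenerate) oligonucleotide.

    Reverse primers are stored in their own 5'->3' orientation, i.e. they
    match the reverse complement of the template's plus strand.
    """

    name: str
    iupac_seq: str
    orientation: str  # "forward" | "reverse"
    binding_start: int  # 1-based inclusive, reference coordinates
    binding_end: int  # 1-based inclusive
    source_set: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "iupac_seq", _validate_iupac(self.iupac_seq, what=f"primer {self.name}"))
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(f"orientation must be forward/reverse, got {self.orientation!r}")
        if self.binding_start > self.binding_end:
            raise ValueError(f"primer {self.name}: binding_start > binding_end")

    def __len__(self) -> int:
        return len(self.iupac_seq)

    @property
    def degeneracy(self) -> int:
        return degeneracy(self.iupac_seq)

    @property
    def masks(self) -> tuple[int, ...]:
        return tuple(IUPAC_MASK[c] for c in self.iupac_seq)


@dataclass(frozen=True)
class PrimerMixture:
    """An equimolar pool of forward and reverse primers used as one set."""

    name: str
    clade_target: str  # "cladeA" | "cladeB" | "total"
    forward: tuple[Primer, ...]
    reverse: tuple[Primer, ...]
    expected_product_len: int = 0

    def __post_init__(self) -> None:
        fwd = tuple(self.forward)
        rev = tuple(self.reverse)
        if not fwd or not rev:
            raise ValueError(f"mixture {self.name}: needs >= 1 forward and reverse primer")
        if len({p.binding_start for p in fwd}) != 1:
            raise ValueError(f"mixture {self.name}: forward members must share binding_start")
        if len({p.binding_end for p in rev}) != 1:
            raise ValueError(f"mixture {self.name}: reverse members must share binding_end")
        object.__setattr__(self, "forward", fwd)
        object.__setattr__(self, "reverse", rev)
        if self.expected_product_len == 0:
            object.__setattr__(
                self,
                "expected_product_len",
                expected_amplicon_length(fwd[0], rev[0]),
            )


def expected_amplicon_length(fwd: Primer, rev: Primer) -> int:
    """Predicted product length from the reference binding interval.

    Inclusive span from the forward primer's 5' start to the reverse
    primer's binding end: for Ntsp-amoA-162F/359R this is 359 - 162 + 1
    = 198 bp.
    """
    if fwd.binding_start > rev.binding_end:
        raise ValueError(
            f"inverted amplicon interval: forward start {fwd.binding_start} "
            f"> reverse end {rev.binding_end}"
        )
    return rev.binding_end - fwd.binding_start + 1


def read_primer_table(lines: Iterable[str]) -> dict[str, PrimerMixture]:
    """Parse the tab-separated primer-set format into mixtures.

    Columns: set, clade_target, name, orientation, sequence, start, end.
    """
    rows = []
    header: list[str] | None = None
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if header is None:
            header = fields
            expected = ["set", "clade_target", "name", "orientation", "sequence", "start", "end"]
            if header != expected:
                raise ValueError(f"primer table header must be {expected}, got {header}")
            continue
        if len(fields) != 7:
            raise ValueError(f"primer table line {lineno}: expected 7 fields, got {len(fields)}")
        rows.append(fields)
    if header is None or not rows:
        raise ValueError("primer table is empty")

    mixtures: dict[str, PrimerMixture] = {}
    for set_name, group in itertools.groupby(rows, key=lambda r: r[0]):
        group = list(group)
        clade = group[0][1]
        fwd, rev = [], []
        for _set, _clade, name, orient, seq, start, end in group:
            p = Primer(
                name=name,
                iupac_seq=seq,
                orientation=orient,
                binding_start=int(start),
                binding_end=int(end),
                source_set=set_name,
            )
            if p.binding_end - p.binding_start + 1 != len(p):
                raise ValueError(f"primer {name}: interval length != sequence length")
            (fwd if orient == "forward" else rev).append(p)
        mixtures[set_name] = PrimerMixture(
            name=set_name, clade_target=clade, forward=tuple(fwd), reverse=tuple(rev)
        )
    return mixtures


def write_primer_table(mixtures: dict[str, PrimerMixture]) -> str:
    """Serialise mixtures back to the tab-separated primer-set format."""
    out = ["set\tclade_target\tname\torientation\tsequence\tstart\tend"]
    for mix in mixtures.values():
        for p in (*mix.forward, *mix.reverse):
            out.append(
                f"{mix.name}\t{mix.clade_target}\t{p.name}\t{p.orientation}\t"
                f"{p.iupac_seq}\t{p.binding_start}\t{p.binding_end}"
            )
    return "\n".join(out) + "\n"


def load_packaged_primer_sets() -> dict[str, PrimerMixture]:
    """Load the packaged comaA / comaB / Ntsp primer mixtures.

    comaA and comaB have 6 forward + 6 reverse oligos each; Ntsp has one
    degenerate forward (degeneracy 8) and one reverse (degeneracy 16).
    """
    ref = resources.files("amoascan").joinpath("data/primer_sets.tsv")
    try:
        text = ref.read_text(encoding="utf-8")
    except OSError as exc:  # pragma: no cover - packaging failure
        raise RuntimeError(f"packaged primer data unreadable: {exc}") from exc
    mixtures = read_primer_table(text.splitlines())
    expected = {"comaA": (6, 6), "comaB": (6, 6), "Ntsp": (1, 1)}
    for name, (nf, nr) in expected.items():
        if name not in mixtures:
            raise RuntimeError(f"packaged primer data corrupted: missing set {name}")
        mix = mixtures[name]
        if (len(mix.forward), len(mix.reverse)) != (nf, nr):
            raise RuntimeError(f"packaged primer data corrupted: {name} oligo counts wrong")
    return mixtures
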