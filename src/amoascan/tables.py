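"""Shared tabular result types (clade relative-abundance tables)."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

__all__ = ["CladeRATable"]


@dataclass
class CladeRATable:
    """Per-clade read counts and relative abundances (percent).

    Percentages are computed exactly from the counts; :meth:`ra_rounded`
    gives the 2-decimal reporting form while :meth:`ra_percent` retains
    full precision.  An empty table is explicitly "undetermined" rather
    than a division by zero.
    """

    counts: dict[str, int] = field(default_factory=dict)

    @classmethod
    def from_counts(cls, counts: Mapping[str, int]) -> "CladeRATable":
        bad = {k: v for k, v in counts.items() if v < 0}
        if bad:
            raise ValueError(f"negative clade counts: {bad}")
        return cls(counts=dict(counts))

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def undetermined(self) -> bool:
        return self.total == 0

    def ra_percent(self) -> dict[str, float]:
        if self.undetermined:
            raise ValueError("relative abundance undetermined: zero assigned reads")
        t = self.total
        return {k: 100.0 * v / t for k, v in self.counts.items()}

    def ra_rounded(self, ndigits: int = 2) -> dict[str, float]:
        return {k: round(v, ndigits) for k, v in self.ra_percent().items()}

    def to_tsv(self) -> str:
        lines = ["clade\treads\tra_percent"]
        if self.undetermined:
            for clade in sorted(self.counts):
                lines.append(f"{clade}\t0\tNA")
        else:
            ra = self.ra_rounded()
            for clade in sorted(self.counts):
                lines.append(f"{clade}\t{self.counts[clade]}\t{ra[clade]:.2f}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str) -> "CladeRATable":
        lines = [ln for ln in text.splitlines() if ln.strip()]
        if not lines or lines[0].split("\t")[:2] != ["clade", "reads"]:
            raise ValueError("not a clade RA table: bad header")
        counts = {}
        for ln in lines[1:]:
            fields = ln.split("\t")
            counts[fields[0]] = int(fields[1])
        return cls.from_counts(counts)
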