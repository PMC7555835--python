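"""FASTA/FASTQ and table plumbing.

Abundance-annotated FASTA uses the ``;size=N`` header suffix dialect common
to amplicon tools; a two-column TSV (id, abundance) side-car is accepted as
an alternative.  FASTQ qualities are read and ignored.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO

from .screen import ProteinRef

__all__ = [
    "read_fasta",
    "read_sized_fasta",
    "write_sized_fasta",
    "read_reads",
    "read_protein_panel",
    "read_abundance_tsv",
]

_SIZE_RE = re.compile(r";size=(\d+)")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Plain FASTA as (id, sequence) pairs."""
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except (OSError, ValueError) as exc:
        raise ValueError(f"{path}: cannot parse FASTA ({exc})") from exc
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    return [(r.id, str(r.seq).upper()) for r in records]


def read_sized_fasta(
    path: str | Path, abundance_tsv: Optional[str | Path] = None
) -> list[tuple[str, str, int]]:
    """FASTA with ``;size=N`` annotations (or a side-car abundance TSV).

    Records without an annotation default to abundance 1.
    """
    side = read_abundance_tsv(abundance_tsv) if abundance_tsv else {}
    out = []
    for rid, seq in read_fasta(path):
        m = _SIZE_RE.search(rid)
        base_id = _SIZE_RE.sub("", rid)
        size = int(m.group(1)) if m else side.get(base_id, 1)
        if size < 1:
            raise ValueError(f"{path}: record {base_id} has abundance < 1")
        out.append((base_id, seq, size))
    return out


def write_sized_fasta(records: Iterable[tuple[str, str, int]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rid, seq, size in records:
            fh.write(f">{rid};size={size}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


def read_reads(path: str | Path) -> list[tuple[str, str]]:
    """Short reads from FASTA or FASTQ (by extension; quality ignored)."""
    p = Path(path)
    fmt = "fastq" if p.suffix.lower() in (".fastq", ".fq") else "fasta"
    try:
        records = list(SeqIO.parse(str(p), fmt))
    except (OSError, ValueError) as exc:
        raise ValueError(f"{path}: cannot parse {fmt.upper()} ({exc})") from exc
    if not records:
        raise ValueError(f"{path}: no {fmt.upper()} records")
    return [(r.id, str(r.seq).upper()) for r in records]


def read_protein_panel(
    path: str | Path, clade_tsv: Optional[str | Path] = None
) -> list[ProteinRef]:
    """Clade-labelled protein panel.

    The clade comes from a ``|cladeA|`` / ``|cladeA.1|`` header token or,
    failing that, from a two-column (id, clade) side-car TSV.
    """
    side: dict[str, str] = {}
    if clade_tsv:
        for line in Path(clade_tsv).read_text(encoding="utf-8").splitlines():
            if line.strip() and not line.startswith("#"):
                rid, clade = line.split("\t")[:2]
                side[rid] = clade
    panel = []
    for record in SeqIO.parse(str(path), "fasta"):
        header = record.description
        m = re.search(r"\|clade([AB](?:\.\d+)?)\|", header)
        clade = m.group(1) if m else side.get(record.id)
        if clade is None:
            raise ValueError(f"{path}: no clade label for panel member {record.id}")
        panel.append(ProteinRef(id=record.id, clade=clade, aa_seq=str(record.seq)))
    if not panel:
        raise ValueError(f"{path}: empty protein panel")
    return panel


def read_abundance_tsv(path: str | Path) -> dict[str, int]:
    out = {}
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise ValueError(f"{path}:{lineno}: expected two tab-separated columns")
        out[fields[0]] = int(fields[1])
    return out
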