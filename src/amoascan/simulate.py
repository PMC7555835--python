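"""Synthetic comammox-like communities with planted ground truth.

The generator emulates the structure of the study system without any
download: two clades (A and B) of ~700-bp amoA-like open reading frames
whose primer-binding regions carry the clade-diagnostic comaA / comaB
sequences plus the shared total-comammox (Ntsp) sites, a lognormal
rank-abundance distribution, a controlled per-template mismatch spectrum at
a designated primer site, amplicon pools with a mismatch amplification
gate, and 150-bp shotgun fragments with optional random background.

Every planted claim in the truth manifest is re-derivable by the analysis
modules themselves (the scanner, the amplicon extractor, the read screen),
which is what the self-consistency tests exercise.

Reference geometry (1-based, matching the packaged primer coordinates):
gene length 702 bp (234 codons, ATG start, no internal stop in frame +1);
Ntsp forward site 162-181, comaA/B forward site 244-260, Ntsp reverse site
340-359, comaA/B reverse site 644-659 (reverse sites appear on the template
as the reverse complement of the primer).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional, Sequence

import numpy as np
from Bio.Seq import Seq
from skbio import TreeNode

from . import pcr
from .primers import (
    IUPAC_MASK,
    Primer,
    PrimerMixture,
    expand_degenerate,
    load_packaged_primer_sets,
    reverse_complement,
)
from .screen import ProteinRef

__all__ = [
    "GENE_LEN",
    "SITE_COORDS",
    "PanelGene",
    "TemplateTruth",
    "SyntheticTruth",
    "make_reference_panel",
    "simulate_community",
    "simulate_amplicon_reads",
    "simulate_metagenome_reads",
    "truth_tree",
]

GENE_LEN = 702  # bp, 234 codons

#: 1-based inclusive template coordinates of the four primer-binding sites.
SITE_COORDS: dict[str, tuple[int, int]] = {
    "ntsp_fwd": (162, 181),
    "coma_fwd": (244, 260),
    "ntsp_rev": (340, 359),
    "coma_rev": (644, 659),
}

_STOPS = {"TAA", "TAG", "TGA"}
_BASES = "ACGT"
_NONSTOP_CODONS = [
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in _STOPS
]


@dataclass(frozen=True)
class PanelGene:
    id: str
    clade: str  # "A" | "B"
    seq: str


@dataclass
class TemplateTruth:
    id: str
    clade: str
    full_seq: str
    abundance: int
    site_mismatches: dict[str, int]


@dataclass
class SyntheticTruth:
    """Planted ground truth for one simulated community."""

    seed: int
    templates: list[TemplateTruth]
    clade_proportions: dict[str, float]
    amplicon_manifest: dict[str, dict[str, dict]]
    region_manifest: dict[str, dict[str, str]]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        raw = json.loads(text)
        raw["templates"] = [TemplateTruth(**t) for t in raw["templates"]]
        return cls(**raw)


def _has_internal_stop_if_placed(site_seq: str, start1: int) -> bool:
    """Would a stop codon lie fully inside this site at 1-based ``start1``?"""
    start0 = start1 - 1
    end0 = start0 + len(site_seq)
    c = (start0 + 2) // 3  # first codon fully inside
    while 3 * c + 3 <= end0:
        if site_seq[3 * c - start0:3 * c - start0 + 3] in _STOPS:
            return True
        c += 1
    return False


def _site_candidates(
    label: str, clade: str, mixtures: Mapping[str, PrimerMixture]
) -> list[str]:
    """Stop-free template-sense candidate sequences for one site."""
    coma = mixtures["comaA" if clade == "A" else "comaB"]
    ntsp = mixtures["Ntsp"]
    pools = {
        "ntsp_fwd": [(v, False) for o in ntsp.forward for v in expand_degenerate(o.iupac_seq)],
        "coma_fwd": [(v, False) for o in coma.forward for v in expand_degenerate(o.iupac_seq)],
        "ntsp_rev": [(v, True) for o in ntsp.reverse for v in expand_degenerate(o.iupac_seq)],
        "coma_rev": [(v, True) for o in coma.reverse for v in expand_degenerate(o.iupac_seq)],
    }
    start1 = SITE_COORDS[label][0]
    out = []
    for variant, is_rev in pools[label]:
        tseq = reverse_complement(variant) if is_rev else variant
        if not _has_internal_stop_if_placed(tseq, start1):
            out.append(tseq)
    if not out:  # pragma: no cover - geometry guarantees candidates exist
        raise RuntimeError(f"no stop-free variant for site {label}, clade {clade}")
    return out


def _in_any_site(pos0: int) -> bool:
    return any(s - 1 <= pos0 < e for s, e in SITE_COORDS.values())


def _repair_stops(seq: list[str], rng: np.random.Generator) -> None:
    """Mutate flank bases so no in-frame codon is a stop (sites untouched)."""
    for c in range(1, GENE_LEN // 3):
        codon = "".join(seq[3 * c:3 * c + 3])
        if codon not in _STOPS:
            continue
        options = []
        for off in range(3):
            pos0 = 3 * c + off
            if _in_any_site(pos0):
                continue
            for b in _BASES:
                if b == seq[pos0]:
                    continue
                trial = list(codon)
                trial[off] = b
                if "".join(trial) not in _STOPS:
                    options.append((pos0, b))
        if not options:  # pragma: no cover - flank-free stop codons cannot occur
            raise RuntimeError(f"unrepairable stop codon at codon {c}")
        pos0, b = options[rng.integers(len(options))]
        seq[pos0] = b


def make_reference_panel(
    n_per_clade: int = 4,
    within_clade_divergence: float = 0.02,
    seed: int = 0,
) -> tuple[list[PanelGene], list[ProteinRef]]:
    """Generate clade A/B amoA-like genes and their translated panel.

    Per clade a random ancestral open reading frame is built with the
    clade's comaA or comaB primer sites and the shared Ntsp sites planted
    at the reference positions; descendants carry third-codon-position
    (synonymous-biased) substitutions at the stated divergence, never
    inside the primer sites.  Gene ``<clade>0`` is the ancestor.
    """
    if n_per_clade < 1:
        raise ValueError("n_per_clade must be >= 1")
    if not (0.0 <= within_clade_divergence <= 0.2):
        raise ValueError("within_clade_divergence must lie in [0, 0.2]")
    rng = np.random.default_rng(seed)
    mixtures = load_packaged_primer_sets()
    genes: list[PanelGene] = []
    proteins: list[ProteinRef] = []
    for clade in ("A", "B"):
        codon_idx = rng.integers(len(_NONSTOP_CODONS), size=GENE_LEN // 3)
        seq = list("".join(_NONSTOP_CODONS[i] for i in codon_idx))
        seq[0:3] = "ATG"
        for label, (s, _e) in SITE_COORDS.items():
            cands = _site_candidates(label, clade, mixtures)
            site = cands[rng.integers(len(cands))]
            seq[s - 1:s - 1 + len(site)] = site
        _repair_stops(seq, rng)
        ancestor = "".join(seq)
        third_flanks = [p for p in range(2, GENE_LEN, 3) if not _in_any_site(p)]
        n_mut = round(within_clade_divergence * GENE_LEN)
        if n_mut > len(third_flanks):
            raise ValueError("divergence too high for the available flank positions")
        for i in range(n_per_clade):
            if i == 0:
                gene_seq = ancestor
            else:
                mseq = list(ancestor)
                picks = rng.choice(len(third_flanks), size=n_mut, replace=False)
                for pi in picks:
                    pos0 = third_flanks[pi]
                    codon_start = pos0 - pos0 % 3
                    old = mseq[pos0]
                    choices = [
                        b
                        for b in _BASES
                        if b != old
                        and "".join(mseq[codon_start:pos0]) + b
                        + "".join(mseq[pos0 + 1:codon_start + 3]) not in _STOPS
                    ]
                    mseq[pos0] = choices[rng.integers(len(choices))]
                gene_seq = "".join(mseq)
            gid = f"{clade}{i}"
            genes.append(PanelGene(id=gid, clade=clade, seq=gene_seq))
            aa = str(Seq(gene_seq).translate())
            if "*" in aa:  # pragma: no cover - construction invariant
                raise RuntimeError(f"internal stop in synthetic gene {gid}")
            proteins.append(ProteinRef(id=gid, clade=clade, aa_seq=aa))
    return genes, proteins


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Allocate ``total`` integer units proportionally to ``weights``,
    guaranteeing at least 1 unit per entry (requires total >= len)."""
    n = len(weights)
    if total < n:
        raise ValueError(f"cannot allocate {total} units to {n} templates (min 1 each)")
    raw = weights / weights.sum() * total
    alloc = np.floor(raw).astype(np.int64)
    rem = total - alloc.sum()
    order = np.argsort(-(raw - alloc), kind="stable")
    alloc[order[:rem]] += 1
    # enforce the floor of 1 by taking from the largest allocations
    while (alloc == 0).any():
        donor = int(np.argmax(alloc))
        recip = int(np.nonzero(alloc == 0)[0][0])
        alloc[donor] -= 1
        alloc[recip] += 1
    return alloc


def _union_mask(primers: Sequence[Primer], pos0: int) -> int:
    m = 0
    for p in primers:
        m |= IUPAC_MASK[p.iupac_seq[pos0]]
    return m


def _plant_site_mismatches(
    seq: list[str],
    site_label: str,
    pool: Sequence[Primer],
    k: int,
    rng: np.random.Generator,
) -> None:
    """Mutate the designated site so its pool min-mismatch count is exactly k.

    Each chosen position gets a base outside the union of allowed bases of
    every pool member at that position, so every oligo (and expansion)
    accrues the mismatch; stop codons are avoided.
    """
    if k == 0:
        return
    s, e = SITE_COORDS[site_label]
    positions = []
    for j in range(e - s + 1):
        if _union_mask(pool, j) != 15:  # some base is disallowed by all oligos
            positions.append(j)
    if k > len(positions):
        raise ValueError(f"cannot plant {k} mismatches at site {site_label}")
    picks = rng.choice(len(positions), size=k, replace=False)
    for pi in sorted(int(x) for x in picks):
        j = positions[pi]
        pos0 = s - 1 + j
        union = _union_mask(pool, j)
        codon_start = pos0 - pos0 % 3
        candidates = []
        for b, bit in zip("ACGT", (1, 2, 4, 8)):
            if union & bit:
                continue
            trial = list(seq[codon_start:codon_start + 3])
            trial[pos0 - codon_start] = b
            if "".join(trial) not in _STOPS:
                candidates.append(b)
        if not candidates:
            # tolerate a stop here rather than fail: translation of the
            # planted-mismatch region is not used downstream
            candidates = [
                b for b, bit in zip("ACGT", (1, 2, 4, 8)) if not (union & bit)
            ]
        seq[pos0] = candidates[rng.integers(len(candidates))]


def _site_region(seq: str, label: str, primer_sense: bool = True) -> str:
    s, e = SITE_COORDS[label]
    region = seq[s - 1:e]
    if primer_sense and label.endswith("_rev"):
        region = reverse_complement(region)
    return region


def _audit_sites(seq: str, clade: str, mixtures: Mapping[str, PrimerMixture]) -> dict[str, int]:
    coma = mixtures["comaA" if clade == "A" else "comaB"]
    ntsp = mixtures["Ntsp"]
    pools = {
        "ntsp_fwd": ntsp.forward,
        "coma_fwd": coma.forward,
        "ntsp_rev": ntsp.reverse,
        "coma_rev": coma.reverse,
    }
    return {
        label: pcr.min_mismatches(pool, _site_region(seq, label))[0]
        for label, pool in pools.items()
    }


def simulate_community(
    panel: Sequence[PanelGene],
    total_abundance: int = 1000,
    mu: float = 0.0,
    sigma: float = 1.5,
    planted_mismatch_spectrum: Optional[Mapping[int, float]] = None,
    clade_split: Optional[Mapping[str, float]] = None,
    mismatch_site: str = "coma_fwd",
    seed: int = 0,
) -> SyntheticTruth:
    """Plant abundances and a primer-site mismatch spectrum on a panel.

    ``clade_split`` and ``planted_mismatch_spectrum`` fractions are honoured
    exactly by abundance mass: the integer ``total_abundance`` is allocated
    to clades, then to spectrum groups within each clade (every fraction
    times its mass must be integral), and lognormal weights shape the
    within-group rank-abundance curve via largest-remainder rounding.
    """
    if not panel:
        raise ValueError("empty panel")
    spectrum = dict(planted_mismatch_spectrum or {0: 1.0})
    if abs(sum(spectrum.values()) - 1.0) > 1e-9:
        raise ValueError("mismatch spectrum fractions must sum to 1")
    clades = sorted({g.clade for g in panel})
    split = dict(clade_split) if clade_split is not None else {c: 1.0 / len(clades) for c in clades}
    if set(split) != set(clades):
        raise ValueError(f"clade_split keys {sorted(split)} != panel clades {clades}")
    if abs(sum(split.values()) - 1.0) > 1e-9:
        raise ValueError("clade_split must sum to 1")

    rng = np.random.default_rng(seed)
    mixtures = load_packaged_primer_sets()
    templates: list[TemplateTruth] = []
    for clade in clades:
        clade_mass_f = split[clade] * total_abundance
        clade_mass = int(round(clade_mass_f))
        if abs(clade_mass_f - clade_mass) > 1e-6:
            raise ValueError(f"clade {clade}: split x total_abundance not integral")
        genes = [g for g in panel if g.clade == clade]
        order = rng.permutation(len(genes))
        groups = sorted(k for k, f in spectrum.items() if f > 0)
        assignment: dict[int, list[PanelGene]] = {k: [] for k in groups}
        for i, gi in enumerate(order):
            assignment[groups[i % len(groups)]].append(genes[gi])
        pool = (mixtures["comaA" if clade == "A" else "comaB"].forward
                if mismatch_site.startswith("coma") else mixtures["Ntsp"].forward)
        if mismatch_site.endswith("_rev"):
            pool = (mixtures["comaA" if clade == "A" else "comaB"].reverse
                    if mismatch_site.startswith("coma") else mixtures["Ntsp"].reverse)
        for k in groups:
            members = assignment[k]
            if not members:
                raise ValueError(
                    f"clade {clade}: no template available for mismatch group {k}"
                )
            mass_f = spectrum[k] * clade_mass
            mass = int(round(mass_f))
            if abs(mass_f - mass) > 1e-6:
                raise ValueError(
                    f"clade {clade}, group {k}: spectrum fraction x clade mass not integral"
                )
            weights = rng.lognormal(mu, sigma, size=len(members))
            alloc = _largest_remainder(weights, mass)
            for gene, ab in zip(members, alloc):
                seq = list(gene.seq)
                _plant_site_mismatches(seq, mismatch_site, pool, k, rng)
                full = "".join(seq)
                site_mm = _audit_sites(full, clade, mixtures)
                if site_mm[mismatch_site] != k:  # pragma: no cover - audit
                    raise RuntimeError(
                        f"planted {k} mismatches at {mismatch_site} but scanner sees "
                        f"{site_mm[mismatch_site]} ({gene.id})"
                    )
                templates.append(
                    TemplateTruth(
                        id=gene.id,
                        clade=clade,
                        full_seq=full,
                        abundance=int(ab),
                        site_mismatches=site_mm,
                    )
                )
    templates.sort(key=lambda t: t.id)

    amplicon_manifest: dict[str, dict[str, dict]] = {}
    for set_name, mixture in mixtures.items():
        entry: dict[str, dict] = {}
        for t in templates:
            hits = pcr.extract_amplicons(
                t.full_seq, mixture, max_mismatch=3, template_id=t.id
            )
            if hits:
                best = min(hits, key=lambda h: (h.total_mismatches, h.fwd_site.start))
                entry[t.id] = {
                    "fwd_mm": best.fwd_site.mismatches,
                    "rev_mm": best.rev_site.mismatches,
                    "product_len": best.product_len,
                }
            else:
                entry[t.id] = {"fwd_mm": None, "rev_mm": None, "product_len": None}
        amplicon_manifest[set_name] = entry

    region_slices = {"198bp": (162, 359), "415bp": (244, 659), "503bp": (162, 659)}
    region_manifest = {
        label: {t.id: t.full_seq[s - 1:e] for t in templates}
        for label, (s, e) in region_slices.items()
    }

    return SyntheticTruth(
        seed=seed,
        templates=templates,
        clade_proportions={c: split[c] for c in clades},
        amplicon_manifest=amplicon_manifest,
        region_manifest=region_manifest,
    )


def simulate_amplicon_reads(
    truth: SyntheticTruth,
    mixture: PrimerMixture,
    max_mismatch_for_amplification: int = 1,
    per_mismatch_efficiency: float = 1.0,
) -> list[tuple[str, str, int]]:
    """Amplicon pool under a mismatch amplification gate.

    A template yields its product iff both primer sites bind within the
    mismatch allowance; the emitted abundance is the template abundance
    attenuated by ``per_mismatch_efficiency`` per total primer-site
    mismatch, rounded.  Templates failing the gate drop out silently -
    the clade-dropout failure mode of selective primer sets.
    """
    if not (0.0 < per_mismatch_efficiency <= 1.0):
        raise ValueError("per_mismatch_efficiency must lie in (0, 1]")
    out: list[tuple[str, str, int]] = []
    for t in truth.templates:
        hits = pcr.extract_amplicons(
            t.full_seq, mixture, max_mismatch_for_amplification, template_id=t.id
        )
        if not hits:
            continue
        best = min(hits, key=lambda h: (h.total_mismatches, h.fwd_site.start))
        size = int(round(t.abundance * per_mismatch_efficiency ** best.total_mismatches))
        if size >= 1:
            out.append((t.id, best.product_seq, size))
    return out


def simulate_metagenome_reads(
    truth: SyntheticTruth,
    read_len: int = 150,
    n_reads: int = 2000,
    background_fraction: float = 0.0,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], dict[str, str], dict[str, float]]:
    """Single-end shotgun fragments from the community plus random background.

    Reads are drawn from templates proportional to abundance x length, with
    uniform start positions and random strand; background reads are uniform
    random nucleotides.  Returns (reads, per-read origin clade or
    "background", expected clade proportions among on-target reads).
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    if not (0.0 <= background_fraction < 1.0):
        raise ValueError("background_fraction must lie in [0, 1)")
    for t in truth.templates:
        if read_len > len(t.full_seq):
            raise ValueError(f"read_len {read_len} exceeds template {t.id} length")
    rng = np.random.default_rng(seed)
    weights = np.array([t.abundance * len(t.full_seq) for t in truth.templates], dtype=float)
    p = weights / weights.sum()
    n_bg = int(round(background_fraction * n_reads))
    n_target = n_reads - n_bg

    reads: list[tuple[str, str]] = []
    origins: dict[str, str] = {}
    idx = rng.choice(len(truth.templates), size=n_target, p=p)
    for i, ti in enumerate(idx):
        t = truth.templates[int(ti)]
        start = int(rng.integers(len(t.full_seq) - read_len + 1))
        frag = t.full_seq[start:start + read_len]
        if rng.random() < 0.5:
            frag = reverse_complement(frag)
        rid = f"read_{i:06d}"
        reads.append((rid, frag))
        origins[rid] = t.clade
    for i in range(n_bg):
        frag = "".join(_BASES[b] for b in rng.integers(4, size=read_len))
        rid = f"bg_{i:06d}"
        reads.append((rid, frag))
        origins[rid] = "background"
    perm = rng.permutation(len(reads))
    reads = [reads[int(i)] for i in perm]

    clade_w: dict[str, float] = {}
    for t, w in zip(truth.templates, weights):
        clade_w[t.clade] = clade_w.get(t.clade, 0.0) + w
    total_w = sum(clade_w.values())
    expected = {c: w / total_w for c, w in sorted(clade_w.items())}
    return reads, origins, expected


def truth_tree(panel: Sequence[PanelGene]) -> TreeNode:
    """A simple truth tree matching the panel's construction.

    Each clade is a star of descendants hanging off its ancestor node, with
    branch lengths equal to the observed per-site divergence from the
    ancestor; the two clades join at the root with arbitrary deep branches.
    """
    clades = sorted({g.clade for g in panel})
    parts = []
    for clade in clades:
        genes = [g for g in panel if g.clade == clade]
        anc = genes[0].seq
        tips = []
        for g in genes:
            d = sum(1 for a, b in zip(anc, g.seq) if a != b) / len(anc)
            tips.append(f"{g.id}:{max(d, 1e-6):.6f}")
        parts.append(f"({','.join(tips)}):0.5")
    newick = f"({','.join(parts)});"
    return TreeNode.read([newick])
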