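"""Greedy identity-based OTU clustering and the region-length comparison.

Sequences are clustered UCLUST-style: processed in decreasing abundance
(ties by id), each sequence joins the first existing centroid it matches at
or above the identity threshold (95% by default), otherwise it founds a new
OTU.  Because input is abundance-sorted, the founder of each OTU is its
highest-abundance member and serves as centroid.

Identity between two sequences is computed from a global alignment with
free terminal gaps; terminal overhang columns are excluded from the
denominator so that nested fragments of one gene (e.g. the 198-bp region
inside the 415-bp region) still cluster together, while internal gaps do
count.  To guarantee symmetry the argument pair is canonicalised before
alignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

from Bio.Align import PairwiseAligner

from . import pcr
from .primers import Primer, PrimerMixture, load_packaged_primer_sets

__all__ = [
    "OTU",
    "RegionComparison",
    "pairwise_identity",
    "greedy_cluster",
    "extract_region",
    "default_region_specs",
    "cluster_regions_compare",
]


@dataclass
class OTU:
    otu_id: str
    centroid_id: str
    centroid_seq: str
    members: list[tuple[str, int]]  # (seq_id, abundance)
    total_abundance: int
    ra_percent: float


@dataclass
class RegionComparison:
    """OTU counts per amplified region over a common sequence set."""

    regions: dict[str, dict[str, int]]  # label -> {"n_sequences", "n_otus"}

    def __post_init__(self) -> None:
        for label, row in self.regions.items():
            if row["n_otus"] > row["n_sequences"]:
                raise ValueError(f"region {label}: more OTUs than sequences")


_DNA_ALIGNER: Optional[PairwiseAligner] = None


def _dna_aligner() -> PairwiseAligner:
    # blastn-like scoring; end gaps free so overhangs are not penalised
    global _DNA_ALIGNER
    if _DNA_ALIGNER is None:
        a = PairwiseAligner()
        a.mode = "global"
        a.match_score = 2
        a.mismatch_score = -3
        a.open_gap_score = -5
        a.extend_gap_score = -2
        if hasattr(a, "open_end_insertion_score"):
            a.open_end_insertion_score = 0
            a.extend_end_insertion_score = 0
            a.open_end_deletion_score = 0
            a.extend_end_deletion_score = 0
        else:  # older attribute names
            a.target_end_open_gap_score = 0
            a.target_end_extend_gap_score = 0
            a.query_end_open_gap_score = 0
            a.query_end_extend_gap_score = 0
        _DNA_ALIGNER = a
    return _DNA_ALIGNER


def pairwise_identity(seq1: str, seq2: str) -> float:
    """Percent identity of the overlapped (non-overhang) alignment region."""
    if not seq1 or not seq2:
        raise ValueError("empty sequence")
    a, b = sorted((seq1.upper(), seq2.upper()))
    if a == b:
        return 100.0
    aln = _dna_aligner().align(a, b)[0]
    s1, s2 = str(aln[0]), str(aln[1])
    # trim terminal overhang columns (where either sequence is gapped at an end)
    start = 0
    end = len(s1)
    while start < end and (s1[start] == "-" or s2[start] == "-"):
        start += 1
    while end > start and (s1[end - 1] == "-" or s2[end - 1] == "-"):
        end -= 1
    if end == start:
        return 0.0
    matches = sum(1 for i in range(start, end) if s1[i] == s2[i])
    return 100.0 * matches / (end - start)


def greedy_cluster(
    seqs: Sequence[tuple[str, str, int]], threshold: float = 95.0
) -> list[OTU]:
    """Cluster (id, seq, abundance) records into OTUs at ``threshold``%.

    Deterministic: abundance-descending processing order with id
    tie-breaks; a sequence joins the first (oldest) centroid reaching the
    threshold.
    """
    ordered = sorted(seqs, key=lambda r: (-r[2], r[0]))
    total = sum(r[2] for r in ordered)
    otus: list[OTU] = []
    for seq_id, seq, abundance in ordered:
        placed = False
        for otu in otus:
            if pairwise_identity(seq, otu.centroid_seq) >= threshold:
                otu.members.append((seq_id, abundance))
                otu.total_abundance += abundance
                placed = True
                break
        if not placed:
            otus.append(
                OTU(
                    otu_id=f"OTU{len(otus) + 1}",
                    centroid_id=seq_id,
                    centroid_seq=seq.upper(),
                    members=[(seq_id, abundance)],
                    total_abundance=abundance,
                    ra_percent=0.0,
                )
            )
    if total > 0:
        for otu in otus:
            otu.ra_percent = 100.0 * otu.total_abundance / total
    return otus


def extract_region(
    full_seq: str,
    fwd_primers: Sequence[Primer],
    rev_primers: Sequence[Primer],
    max_mismatch: int = 1,
) -> Optional[str]:
    """Excise the amplified region between the located primer sites.

    Returns None ("not covered") when either site is missing at the allowed
    mismatch level; with multiple candidate products the one with fewest
    total primer mismatches (then leftmost) is taken.
    """
    hits = pcr.extract_amplicons(full_seq, fwd_primers, rev_primers, max_mismatch)
    if not hits:
        return None
    best = min(hits, key=lambda h: (h.total_mismatches, h.fwd_site.start))
    return best.product_seq


def default_region_specs(
    mixtures: Optional[dict[str, PrimerMixture]] = None,
) -> dict[str, tuple[tuple[Primer, ...], tuple[Primer, ...]]]:
    """The three amplified-region definitions compared in the study.

    198bp: Ntsp-amoA-162F/359R.  415bp: comaA+comaB-244f/659r (pooled so
    both clades are excisable).  503bp: the combined span from the Ntsp
    forward site to the comaA/B reverse site.
    """
    mixtures = mixtures or load_packaged_primer_sets()
    ntsp = mixtures["Ntsp"]
    coma_fwd = mixtures["comaA"].forward + mixtures["comaB"].forward
    coma_rev = mixtures["comaA"].reverse + mixtures["comaB"].reverse
    return {
        "198bp": (ntsp.forward, ntsp.reverse),
        "415bp": (coma_fwd, coma_rev),
        "503bp": (ntsp.forward, coma_rev),
    }


def cluster_regions_compare(
    full_seqs: Sequence[tuple[str, str]],
    threshold: float = 95.0,
    regions: Optional[dict[str, tuple[tuple[Primer, ...], tuple[Primer, ...]]]] = None,
    max_mismatch: int = 1,
) -> RegionComparison:
    """Cluster the same genes restricted to each amplified region.

    Only sequences coverable by every region enter the comparison, so all
    regions cluster an identical sequence membership; a region covering no
    sequence is excluded with a warning.  Abundances are taken as 1 per
    sequence (the comparison is over unique gene records).
    """
    if len(full_seqs) < 2:
        raise ValueError("need >= 2 sequences for a region comparison")
    regions = regions or default_region_specs()
    excised: dict[str, dict[str, str]] = {}
    for label, (fwd, rev) in regions.items():
        excised[label] = {}
        for seq_id, seq in full_seqs:
            sub = extract_region(seq, fwd, rev, max_mismatch)
            if sub is not None:
                excised[label][seq_id] = sub
    usable = {label: cov for label, cov in excised.items() if cov}
    for label in regions:
        if label not in usable:
            warnings.warn(f"region {label}: no covered sequences, excluded")
    if not usable:
        raise ValueError("no region covers any sequence")
    common = set.intersection(*(set(cov) for cov in usable.values()))
    if len(common) < 2:
        raise ValueError("fewer than 2 sequences are covered by all regions")
    result: dict[str, dict[str, int]] = {}
    for label, cov in usable.items():
        records = [(sid, cov[sid], 1) for sid in sorted(common)]
        otus = greedy_cluster(records, threshold)
        result[label] = {"n_sequences": len(records), "n_otus": len(otus)}
    return RegionComparison(regions=result)
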