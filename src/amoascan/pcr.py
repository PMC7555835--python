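"""In-silico PCR: primer-binding-site scanning, amplicon extraction,
cross-primer coverage statistics and amplicon-vs-metagenome relative
abundance comparison.

Mismatch counting is IUPAC-aware Hamming distance: a primer position
mismatches a template position iff their allowed-base sets are disjoint.
The minimum over all fully specified expansions of a degenerate oligo is
therefore exactly the count of disjoint positions, because per-position
choices are independent.  Indels are not modelled.

Strand convention: a site has strand ``+`` when the oligo sequence (5'->3')
matches the template window as read on the plus strand, and strand ``-``
when the oligo matches the reverse complement of the window.  A reverse
primer bound in standard amplicon orientation therefore reports strand
``-``; on a reverse-complemented template the roles flip.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .primers import (
    IUPAC_MASK,
    IUPAC_SETS,
    Primer,
    PrimerMixture,
    reverse_complement,
)
from .tables import CladeRATable

__all__ = [
    "BindingSite",
    "AmpliconHit",
    "CoverageReport",
    "RAComparison",
    "min_mismatches",
    "scan_template",
    "extract_amplicons",
    "coverage_of_region",
    "compare_ra",
]


@dataclass(frozen=True)
class BindingSite:
    """A located primer match on a template."""

    template_id: str
    mixture_name: str
    oligo_name: str
    variant_index: int
    start: int  # 1-based inclusive template coordinates
    end: int
    strand: str  # "+" | "-"
    mismatches: int
    mismatch_positions: tuple[int, ...]  # primer-relative, 1 = 5' end

    def __post_init__(self) -> None:
        if self.mismatches != len(self.mismatch_positions):
            raise ValueError("mismatches must equal |mismatch_positions|")


@dataclass(frozen=True)
class AmpliconHit:
    """A forward/reverse site pair with the excised product."""

    template_id: str
    fwd_site: BindingSite
    rev_site: BindingSite
    product_seq: str
    product_len: int

    @property
    def total_mismatches(self) -> int:
        return self.fwd_site.mismatches + self.rev_site.mismatches


@dataclass
class CoverageReport:
    """Mismatch-bucketed primer coverage of a set of amplicons.

    ``fraction_exact`` / ``fraction_le1`` are abundance-weighted ("per read",
    the headline figure); the ``*_unweighted`` fields count each unique
    sequence once.
    """

    group_key: str
    n_sequences: int
    n_weighted: float
    counts_by_min_mismatch: dict[str, float]  # keys "0", "1", "ge2"
    fraction_exact: float
    fraction_le1: float
    fraction_exact_unweighted: float
    fraction_le1_unweighted: float
    #: abundance-weighted % of amplicons whose best window mismatches within
    #: the primer's 3'-terminal bases; None unless the mode is enabled
    fraction_3prime_mismatch: float | None = None


@dataclass
class RAComparison:
    """Per-clade amplicon vs metagenome relative abundance."""

    rows: dict[str, dict[str, float | None | bool]]
    # each row: amplicon_ra, metagenome_ra, ratio (None when undefined),
    # ratio_infinite flag


def _encode(seq: str, what: str = "template") -> list[int]:
    masks = []
    for i, ch in enumerate(seq.upper(), start=1):
        m = IUPAC_MASK.get(ch)
        if m is None:
            raise ValueError(f"invalid IUPAC symbol {ch!r} at position {i} of {what}")
        masks.append(m)
    return masks


def _mismatch_positions(oligo_masks: Sequence[int], window_masks: Sequence[int]) -> list[int]:
    return [i + 1 for i, (a, b) in enumerate(zip(oligo_masks, window_masks)) if not (a & b)]


def _best_variant_index(oligo: Primer, window: str) -> int:
    """Index (in lexicographic expansion order) of the lexicographically
    smallest expansion achieving the minimum mismatch count."""
    radix = 1
    index = 0
    digits = []
    for ch, tch in zip(oligo.iupac_seq, window.upper()):
        options = IUPAC_SETS[ch]
        tmask = IUPAC_MASK.get(tch, 0)
        compatible = [i for i, b in enumerate(options) if IUPAC_MASK[b] & tmask]
        digits.append(compatible[0] if compatible else 0)
    for ch, d in zip(reversed(oligo.iupac_seq), reversed(digits)):
        index += d * radix
        radix *= len(IUPAC_SETS[ch])
    return index


def min_mismatches(
    mixture_side: Sequence[Primer], region: str
) -> tuple[int, tuple[str, int]]:
    """Minimum IUPAC-aware Hamming distance of a region to a primer pool.

    The minimum is over every member oligo and every degenerate expansion.
    Ties break to the lowest mismatch count, then oligo order as packaged,
    then lexicographically first variant.  ``region`` must be in the
    oligos' own orientation and of equal length.
    """
    if not mixture_side:
        raise ValueError("empty primer pool")
    region = region.upper()
    olen = len(mixture_side[0])
    if any(len(o) != olen for o in mixture_side):
        raise ValueError("oligos in one pool must share length")
    if len(region) != olen:
        raise ValueError(f"region length {len(region)} != oligo length {olen}")
    rmasks = _encode(region, "region")
    best = None
    for oligo in mixture_side:
        mm = len(_mismatch_positions(oligo.masks, rmasks))
        if best is None or mm < best[0]:
            best = (mm, (oligo.name, _best_variant_index(oligo, region)))
            if mm == 0:
                break
    return best  # type: ignore[return-value]


def _scan_oligos(
    template: str,
    oligos: Sequence[Primer],
    max_mismatch: int,
    template_id: str,
    mixture_name: str,
) -> list[BindingSite]:
    """Core scanner: all sites of ``oligos`` on both strands of ``template``.

    Per (start, strand) only the best site is kept: lowest mismatch count,
    ties resolved by packaged oligo order (first wins) then lexicographic
    variant order.
    """
    template = template.upper()
    tmasks = _encode(template)
    best: dict[tuple[int, str], BindingSite] = {}
    for oligo in oligos:
        for probe, strand in (
            (oligo.iupac_seq, "+"),
            (reverse_complement(oligo.iupac_seq), "-"),
        ):
            plen = len(probe)
            pmasks = [IUPAC_MASK[c] for c in probe]
            for start0 in range(len(template) - plen + 1):
                mm = 0
                positions: list[int] = []
                for j in range(plen):
                    if not (pmasks[j] & tmasks[start0 + j]):
                        mm += 1
                        if mm > max_mismatch:
                            break
                        positions.append(j)
                if mm > max_mismatch:
                    continue
                # primer-relative mismatch positions (1 = 5' end of the oligo)
                if strand == "+":
                    primer_pos = tuple(j + 1 for j in positions)
                else:
                    primer_pos = tuple(sorted(plen - j for j in positions))
                window = template[start0:start0 + plen]
                region = window if strand == "+" else reverse_complement(window)
                site = BindingSite(
                    template_id=template_id,
                    mixture_name=mixture_name,
                    oligo_name=oligo.name,
                    variant_index=_best_variant_index(oligo, region),
                    start=start0 + 1,
                    end=start0 + plen,
                    strand=strand,
                    mismatches=mm,
                    mismatch_positions=primer_pos,
                )
                key = (site.start, strand)
                prev = best.get(key)
                if prev is None or site.mismatches < prev.mismatches:
                    best[key] = site
    return sorted(best.values(), key=lambda s: (s.start, s.strand))


def scan_template(
    template: str,
    mixture: PrimerMixture,
    max_mismatch: int,
    *,
    template_id: str = "template",
) -> list[BindingSite]:
    """All binding sites of a mixture (both sides, both strands).

    Forward and reverse pools are scanned independently so a window that
    both pools can reach reports one site per side; within a side, per
    (position, strand) only the best site is kept.  Sites are sorted by
    start position.
    """
    if not template:
        raise ValueError("empty template")
    shortest = min(len(o) for o in (*mixture.forward, *mixture.reverse))
    if len(template) < shortest:
        raise ValueError("template shorter than the shortest oligo")
    sites = _scan_oligos(template, mixture.forward, max_mismatch, template_id, mixture.name)
    sites += _scan_oligos(template, mixture.reverse, max_mismatch, template_id, mixture.name)
    return sorted(sites, key=lambda s: (s.start, s.strand, s.oligo_name))


def extract_amplicons(
    template: str,
    fwd_primers: Sequence[Primer] | PrimerMixture,
    rev_primers: Sequence[Primer] | PrimerMixture | None = None,
    max_mismatch: int = 1,
    len_bounds: tuple[int, int] | None = None,
    *,
    template_id: str = "template",
) -> list[AmpliconHit]:
    """Pair forward and reverse binding sites and excise the products.

    Every forward site is paired with the nearest compatible downstream
    reverse site (within ``len_bounds`` when given); products on the minus
    strand (reverse-orientation templates) are returned reverse-complemented
    so ``product_seq`` always reads forward-primer -> reverse-primer.
    """
    if isinstance(fwd_primers, PrimerMixture):
        mixture = fwd_primers
        fwd_list: Sequence[Primer] = mixture.forward
        rev_list: Sequence[Primer] = mixture.reverse
        mix_name = mixture.name
    else:
        if rev_primers is None:
            raise ValueError("reverse primers required")
        fwd_list = list(fwd_primers)
        rev_list = list(rev_primers)  # type: ignore[arg-type]
        mix_name = fwd_list[0].source_set or "custom"

    template = template.upper()
    fwd_sites = _scan_oligos(template, fwd_list, max_mismatch, template_id, mix_name)
    rev_sites = _scan_oligos(template, rev_list, max_mismatch, template_id, mix_name)

    hits: list[AmpliconHit] = []
    # standard orientation: forward on '+', reverse on '-', reverse downstream
    plus_fwd = [s for s in fwd_sites if s.strand == "+"]
    minus_rev = [s for s in rev_sites if s.strand == "-"]
    for fs in plus_fwd:
        candidates = [r for r in minus_rev if r.start > fs.end]
        if len_bounds is not None:
            lo, hi = len_bounds
            candidates = [r for r in candidates if lo <= r.end - fs.start + 1 <= hi]
        if not candidates:
            continue
        rs = min(candidates, key=lambda r: r.end)
        product = template[fs.start - 1:rs.end]
        hits.append(AmpliconHit(template_id, fs, rs, product, len(product)))
    # flipped orientation: reverse primer on '+', forward on '-', forward downstream
    plus_rev = [s for s in rev_sites if s.strand == "+"]
    minus_fwd = [s for s in fwd_sites if s.strand == "-"]
    for fs in minus_fwd:
        candidates = [r for r in plus_rev if r.end < fs.start]
        if len_bounds is not None:
            lo, hi = len_bounds
            candidates = [r for r in candidates if lo <= fs.end - r.start + 1 <= hi]
        if not candidates:
            continue
        rs = max(candidates, key=lambda r: r.start)
        product = reverse_complement(template[rs.start - 1:fs.end])
        hits.append(AmpliconHit(template_id, fs, rs, product, len(product)))
    hits.sort(key=lambda h: (h.fwd_site.start, h.product_len))
    return hits


def _terminal_mismatches(
    probe_side: Sequence[Primer], region: str, oligo_name: str, window: int
) -> int:
    """Mismatches of ``region`` against the named oligo's 3'-terminal bases."""
    oligo = next(p for p in probe_side if p.name == oligo_name)
    rmasks = _encode(region, "region")
    plen = len(oligo)
    return sum(
        1
        for j, (a, b) in enumerate(zip(oligo.masks, rmasks), start=1)
        if j > plen - window and not (a & b)
    )


def coverage_of_region(
    amplicons: Sequence[tuple[str, float]],
    probe_side: Sequence[Primer],
    *,
    group_key: str = "all",
    three_prime_window: int | None = None,
) -> CoverageReport:
    """Cross-primer coverage: best-window mismatch spectrum of a probe pool.

    For every (sequence, abundance) amplicon the best-matching window for
    the probe pool is located by scanning all windows (minimum mismatches
    over oligos, expansions and positions), then bucketed as exact match,
    one mismatch, or >= 2 mismatches.  This reproduces the forward-primer
    coverage analysis of the comaA/B-244f pool inside Ntsp-amoA-162F/359R
    amplicons.  With ``three_prime_window`` = k, the report additionally
    carries the weighted fraction of amplicons whose best window mismatches
    within the primer's last k bases, where mismatches hit PCR hardest.
    """
    if not amplicons:
        raise ValueError("coverage undefined for an empty amplicon list")
    if not probe_side:
        raise ValueError("empty probe pool")
    plen = len(probe_side[0])
    counts = {"0": 0.0, "1": 0.0, "ge2": 0.0}
    ucounts = {"0": 0, "1": 0, "ge2": 0}
    total_w = 0.0
    w_3prime = 0.0
    for seq, abundance in amplicons:
        if abundance < 1:
            raise ValueError("amplicon abundance must be >= 1")
        seq = seq.upper()
        if len(seq) <= plen:
            raise ValueError("amplicon not longer than the probe oligo")
        best = None
        best_region = None
        best_oligo = None
        for start0 in range(len(seq) - plen + 1):
            region = seq[start0:start0 + plen]
            mm, (oname, _vidx) = min_mismatches(probe_side, region)
            if best is None or mm < best:
                best, best_region, best_oligo = mm, region, oname
                if best == 0:
                    break
        bucket = "0" if best == 0 else ("1" if best == 1 else "ge2")
        counts[bucket] += abundance
        ucounts[bucket] += 1
        total_w += abundance
        if three_prime_window and _terminal_mismatches(
            probe_side, best_region, best_oligo, three_prime_window
        ):
            w_3prime += abundance
    return CoverageReport(
        group_key=group_key,
        n_sequences=len(amplicons),
        n_weighted=total_w,
        counts_by_min_mismatch=counts,
        fraction_exact=100.0 * counts["0"] / total_w,
        fraction_le1=100.0 * (counts["0"] + counts["1"]) / total_w,
        fraction_exact_unweighted=100.0 * ucounts["0"] / len(amplicons),
        fraction_le1_unweighted=100.0 * (ucounts["0"] + ucounts["1"]) / len(amplicons),
        fraction_3prime_mismatch=(
            100.0 * w_3prime / total_w if three_prime_window else None
        ),
    )


def compare_ra(
    amplicon_table: CladeRATable, metagenome_table: CladeRATable
) -> RAComparison:
    """Per-clade ratio of amplicon-derived to metagenome-derived RA.

    A clade absent from the metagenome (RA 0) is flagged rather than
    divided; both tables must cover the same clades and each must sum to
    100% (within 0.1).
    """
    a_ra = amplicon_table.ra_percent()
    m_ra = metagenome_table.ra_percent()
    if set(a_ra) != set(m_ra):
        raise ValueError(
            f"clade keys differ: {sorted(a_ra)} vs {sorted(m_ra)}"
        )
    for label, ra in (("amplicon", a_ra), ("metagenome", m_ra)):
        if abs(sum(ra.values()) - 100.0) > 0.1:
            raise ValueError(f"{label} RA column does not sum to 100%")
    rows: dict[str, dict] = {}
    for clade in sorted(a_ra):
        if m_ra[clade] > 0:
            ratio: float | None = a_ra[clade] / m_ra[clade]
            infinite = False
        else:
            ratio = None
            infinite = a_ra[clade] > 0
        rows[clade] = {
            "amplicon_ra": a_ra[clade],
            "metagenome_ra": m_ra[clade],
            "ratio": ratio,
            "ratio_infinite": infinite,
        }
    return RAComparison(rows=rows)
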