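"""In-silico PCR: mismatch scanning, amplicon extraction, coverage, RA."""

import numpy as np
import pytest

from amoascan.pcr import (
    compare_ra,
    coverage_of_region,
    extract_amplicons,
    min_mismatches,
    scan_template,
)
from amoascan.primers import Primer, PrimerMixture, reverse_complement
from amoascan.tables import CladeRATable

from oracles import brute_force_sites

BASES = "ACGT"


def random_seq(rng, n):
    return "".join(BASES[i] for i in rng.integers(4, size=n))


class TestMinMismatches:
    def test_exact_member_is_zero(self, mixtures):
        mm, (name, vidx) = min_mismatches(mixtures["comaA"].forward, "TACAACTGGGTGAACTA")
        assert mm == 0
        assert name == "comaA-244f_a"
        assert vidx == 0

    def test_single_substitution_is_one(self, mixtures):
        region = "GACAACTGGGTGAACTA"  # first base T->G vs comaA-244f_a
        mm, _ = min_mismatches(mixtures["comaA"].forward, region)
        assert mm == 1

    def test_degenerate_positions_are_free(self, mixtures):
        # comaB-244f_a TAYTTCTGGACGTTCTA: Y matches both C and T
        for b in "CT":
            region = f"TA{b}TTCTGGACGTTCTA"
            assert min_mismatches(mixtures["comaB"].forward, region)[0] == 0

    def test_length_mismatch_rejected(self, mixtures):
        with pytest.raises(ValueError, match="length"):
            min_mismatches(mixtures["comaA"].forward, "ACGT")

    def test_matches_exhaustive_expansion_scan(self, mixtures):
        rng = np.random.default_rng(5)
        oligos = [p.iupac_seq for p in mixtures["comaA"].forward]
        from oracles import oracle_expand

        for _ in range(50):
            region = random_seq(rng, 17)
            expected = min(
                sum(1 for x, y in zip(v, region) if x != y)
                for o in oligos
                for v in oracle_expand(o)
            )
            assert min_mismatches(mixtures["comaA"].forward, region)[0] == expected


class TestScanTemplate:
    def _planted_template(self, rng, mixtures):
        t = list(random_seq(rng, 700))
        fwd = mixtures["Ntsp"].forward[0]
        site = fwd.iupac_seq.replace("N", "A").replace("S", "C")
        t[99:99 + len(site)] = site
        return "".join(t), 100  # 1-based planted start

    def test_planted_exact_site_found(self, mixtures):
        rng = np.random.default_rng(7)
        template, start = self._planted_template(rng, mixtures)
        sites = scan_template(template, mixtures["Ntsp"], 0)
        fwd_sites = [s for s in sites if s.oligo_name == "Ntsp-amoA-162F" and s.strand == "+"]
        assert any(s.start == start and s.mismatches == 0 for s in fwd_sites)

    def test_reverse_complement_template_symmetric(self, mixtures):
        rng = np.random.default_rng(8)
        template, _ = self._planted_template(rng, mixtures)
        rc = reverse_complement(template)
        fwd = scan_template(template, mixtures["Ntsp"], 1)
        rev = scan_template(rc, mixtures["Ntsp"], 1)
        # each site maps to the mirrored position on the opposite strand
        mirrored = {
            (len(template) - s.end + 1, {"+": "-", "-": "+"}[s.strand], s.mismatches)
            for s in fwd
        }
        assert {(s.start, s.strand, s.mismatches) for s in rev} == mirrored

    @pytest.mark.parametrize("max_mismatch", [0, 1, 2])
    def test_equals_brute_force_oracle(self, mixtures, max_mismatch):
        rng = np.random.default_rng(42 + max_mismatch)
        for _ in range(5):
            template = random_seq(rng, 600)
            for side_name in ("forward", "reverse"):
                side = getattr(mixtures["comaB"], side_name)
                oracle = brute_force_sites(
                    template, [p.iupac_seq for p in side], max_mismatch
                )
                sites = scan_template(template, mixtures["comaB"], max_mismatch)
                mine = {
                    (s.start, s.strand): s.mismatches
                    for s in sites
                    if any(p.name == s.oligo_name for p in side)
                }
                assert mine == oracle

    def test_monotone_in_max_mismatch(self, mixtures):
        rng = np.random.default_rng(9)
        template = random_seq(rng, 500)
        counts = [len(scan_template(template, mixtures["Ntsp"], k)) for k in (0, 1, 2, 3)]
        assert counts == sorted(counts)

    def test_empty_template_rejected(self, mixtures):
        with pytest.raises(ValueError, match="empty"):
            scan_template("", mixtures["Ntsp"], 1)


class TestExtractAmplicons:
    def _mixture_with_planted_product(self, rng, spacing=198):
        """Random template carrying exact Ntsp fwd/rev sites 198 bp apart."""
        from amoascan.primers import load_packaged_primer_sets

        mix = load_packaged_primer_sets()["Ntsp"]
        fwd_site = mix.forward[0].iupac_seq.replace("N", "A").replace("S", "C")
        rev_site = reverse_complement(
            mix.reverse[0].iupac_seq.replace("N", "A").replace("S", "C").replace("W", "A")
        )
        t = list(random_seq(rng, 600))
        start = 100
        t[start:start + len(fwd_site)] = fwd_site
        rev_start = start + spacing - len(rev_site)
        t[rev_start:rev_start + len(rev_site)] = rev_site
        return "".join(t), mix

    def test_planted_product_has_expected_length(self):
        rng = np.random.default_rng(3)
        template, mix = self._mixture_with_planted_product(rng)
        hits = extract_amplicons(template, mix, max_mismatch=0)
        assert len(hits) == 1
        assert hits[0].product_len == 198

    def test_forward_site_alone_yields_nothing(self, mixtures):
        rng = np.random.default_rng(4)
        t = list(random_seq(rng, 400))
        site = mixtures["Ntsp"].forward[0].iupac_seq.replace("N", "A").replace("S", "C")
        t[50:50 + len(site)] = site
        assert extract_amplicons("".join(t), mixtures["Ntsp"], 0) == []

    def test_reverse_oriented_template_gives_same_product(self):
        rng = np.random.default_rng(6)
        template, mix = self._mixture_with_planted_product(rng)
        fwd_hits = extract_amplicons(template, mix, 0)
        rc_hits = extract_amplicons(reverse_complement(template), mix, 0)
        assert [h.product_seq for h in rc_hits] == [h.product_seq for h in fwd_hits]

    def test_length_bounds_filter(self):
        rng = np.random.default_rng(12)
        template, mix = self._mixture_with_planted_product(rng)
        assert extract_amplicons(template, mix, 0, len_bounds=(150, 250))
        assert extract_amplicons(template, mix, 0, len_bounds=(300, 500)) == []


class TestCoverage:
    @pytest.fixture
    def probe(self, mixtures):
        return mixtures["comaA"].forward

    def _amplicon_with(self, rng, probe, n_mismatch):
        """300-bp sequence carrying a comaA forward window at n mismatches."""
        seq = list(random_seq(rng, 300))
        site = list("TACAACTGGGTGAACTA")
        # positions where every pool member demands the same base set
        forced = [0, 3, 6, 7, 8]  # T,A,T/G?,G,G across the pool - use safe ones
        for j in range(n_mismatch):
            site[forced[j]] = {"T": "G", "A": "C", "G": "A"}[site[forced[j]]]
        seq[100:117] = site
        return "".join(seq)

    def test_all_exact_gives_full_coverage(self, probe):
        rng = np.random.default_rng(21)
        amps = [(self._amplicon_with(rng, probe, 0), 5) for _ in range(4)]
        r = coverage_of_region(amps, probe)
        assert r.fraction_exact == 100.0
        assert r.fraction_le1 == 100.0

    def test_two_mismatch_window_fails_le1(self, probe):
        rng = np.random.default_rng(22)
        r = coverage_of_region([(self._amplicon_with(rng, probe, 2), 1)], probe)
        assert r.fraction_le1 == 0.0
        assert r.counts_by_min_mismatch["ge2"] == 1

    def test_abundance_weighting(self, probe):
        rng = np.random.default_rng(23)
        amps = [
            (self._amplicon_with(rng, probe, 0), 70),
            (self._amplicon_with(rng, probe, 1), 30),
        ]
        r = coverage_of_region(amps, probe)
        assert r.fraction_exact == pytest.approx(70.0)
        assert r.fraction_le1 == pytest.approx(100.0)
        assert r.fraction_exact_unweighted == pytest.approx(50.0)

    def test_invariant_under_abundance_split(self, probe):
        rng = np.random.default_rng(24)
        a0 = self._amplicon_with(rng, probe, 0)
        a1 = self._amplicon_with(rng, probe, 1)
        whole = coverage_of_region([(a0, 60), (a1, 40)], probe)
        split = coverage_of_region([(a0, 30), (a0, 30), (a1, 40)], probe)
        assert split.fraction_exact == pytest.approx(whole.fraction_exact)
        assert split.fraction_le1 == pytest.approx(whole.fraction_le1)

    def test_three_prime_window_flags_terminal_mismatch(self, probe):
        rng = np.random.default_rng(25)
        # penultimate base T -> G: a mismatch inside the 3'-terminal 3 bases
        seq = list(random_seq(rng, 300))
        site = list("TACAACTGGGTGAACTA")
        site[15] = "G"
        seq[100:117] = site
        terminal = coverage_of_region([("".join(seq), 4)], probe, three_prime_window=3)
        assert terminal.fraction_3prime_mismatch == pytest.approx(100.0)
        # the same mismatch count at the 5' end does not trip the 3' flag
        clean = self._amplicon_with(rng, probe, 1)
        r5 = coverage_of_region([(clean, 4)], probe, three_prime_window=3)
        assert r5.fraction_3prime_mismatch == pytest.approx(0.0)
        assert coverage_of_region([(clean, 4)], probe).fraction_3prime_mismatch is None

    def test_empty_input_rejected(self, probe):
        with pytest.raises(ValueError, match="empty"):
            coverage_of_region([], probe)


class TestCompareRA:
    def test_identical_tables_ratio_one(self):
        t = CladeRATable.from_counts({"A": 70, "B": 30})
        comp = compare_ra(t, t)
        assert all(row["ratio"] == pytest.approx(1.0) for row in comp.rows.values())

    def test_printed_overestimate_ratio(self):
        # amplicon B 59.70% vs metagenome B 1.26% -> ratio ~47.4
        amp = CladeRATable.from_counts({"A": 4030, "B": 5970})
        meta = CladeRATable.from_counts({"A": 9874, "B": 126})
        comp = compare_ra(amp, meta)
        assert comp.rows["B"]["ratio"] == pytest.approx(59.70 / 1.26, rel=1e-6)

    def test_zero_metagenome_clade_flagged_not_divided(self):
        amp = CladeRATable.from_counts({"A": 50, "B": 50})
        meta = CladeRATable.from_counts({"A": 100, "B": 0})
        comp = compare_ra(amp, meta)
        assert comp.rows["B"]["ratio"] is None
        assert comp.rows["B"]["ratio_infinite"] is True

    def test_key_mismatch_rejected(self):
        amp = CladeRATable.from_counts({"A": 100})
        meta = CladeRATable.from_counts({"A": 50, "B": 50})
        with pytest.raises(ValueError, match="clade keys"):
            compare_ra(amp, meta)
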