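"""Diversity statistics: polymorphic sites, pi, G+C, SNP classes, dN/dS."""

import itertools

import numpy as np
import pytest

from mlstpop.allele_typing import assign_profiles
from mlstpop.diversity_stats import (
    FrameError,
    classify_snp_sites,
    count_polymorphic_sites,
    diversity_report,
    gc_content,
    nei_gojobori,
    nucleotide_diversity,
)

from conftest import make_dataset


class TestPolymorphicSites:
    def test_single_site(self):
        n, sites = count_polymorphic_sites(["AAAA", "AAAT"])
        assert (n, sites) == (1, [3])

    def test_n_only_variation_not_polymorphic(self):
        n, sites = count_polymorphic_sites(["AAAA", "AAAN"])
        assert (n, sites) == (0, [])

    def test_single_sequence_is_an_error(self):
        with pytest.raises(Exception):
            count_polymorphic_sites(["AAAA"])


class TestNucleotideDiversity:
    def test_single_pair(self):
        assert nucleotide_diversity(["AAAA", "AAAT"]) == pytest.approx(0.25)

    def test_hand_enumerated_three_sequences(self):
        # pairs: (1,2)=1/4, (1,3)=1/4, (2,3)=0 -> mean = 1/6
        assert nucleotide_diversity(["AAAA", "AAAT", "AAAT"]) == pytest.approx(1 / 6)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 20))
            L = int(rng.integers(5, 30))
            aln = ["".join(rng.choice(list("ACGT"), L)) for _ in range(n)]
            total = 0.0
            pairs = 0
            for a, b in itertools.combinations(aln, 2):
                total += sum(x != y for x, y in zip(a, b)) / L
                pairs += 1
            assert nucleotide_diversity(aln) == pytest.approx(total / pairs, abs=1e-12)

    def test_pairwise_n_exclusion(self):
        # pair compares only 3 sites; 1 difference -> 1/3
        assert nucleotide_diversity(["ACGN", "ACTT"]) == pytest.approx(1 / 3)

    def test_concatenated_pi_is_length_weighted_mean(self, rng):
        a1 = ["".join(rng.choice(list("ACGT"), 12)) for _ in range(5)]
        a2 = ["".join(rng.choice(list("ACGT"), 30)) for _ in range(5)]
        pi1, pi2 = nucleotide_diversity(a1), nucleotide_diversity(a2)
        concat = [x + y for x, y in zip(a1, a2)]
        expected = (12 * pi1 + 30 * pi2) / 42
        assert nucleotide_diversity(concat) == pytest.approx(expected, abs=1e-12)


class TestGCContent:
    def test_extremes(self):
        assert gc_content(["GCGC"]) == 100.0
        assert gc_content(["ATGC"]) == 50.0

    def test_n_excluded_from_denominator(self):
        assert gc_content(["GCNN"]) == 100.0


class TestClassifySnpSites:
    def test_synonymous_site(self):
        # TTT (Phe) vs TTC (Phe)
        s, n, labels = classify_snp_sites(["TTT", "TTC"])
        assert (s, n) == (1, 0) and labels[2] == {"s"}

    def test_nonsynonymous_site(self):
        # TTT (Phe) vs ATT (Ile)
        s, n, labels = classify_snp_sites(["TTT", "ATT"])
        assert (s, n) == (0, 1) and labels[0] == {"n"}

    def test_site_with_both_labels(self):
        # CTT(Leu)/CTC(Leu) synonymous pair and TTC->CTC... use third position:
        # ATT(Ile)/ATA(Ile) synonymous, ATT/ATG? combine TTA(Leu)/TTG(Leu)/TTC(Phe)
        s, n, labels = classify_snp_sites(["TTA", "TTG", "TTC"])
        assert labels[2] == {"s", "n"}
        assert s >= 1 and n >= 1

    def test_ssnp_plus_nsnp_can_exceed_polymorphic_sites(self):
        aln = ["TTA", "TTG", "TTC"]
        n_poly, _ = count_polymorphic_sites(aln)
        s, n, _ = classify_snp_sites(aln)
        assert s + n >= n_poly

    def test_frame_error_on_majority_stop(self):
        with pytest.raises(FrameError):
            classify_snp_sites(["TAATTT", "TAATTC"])

    def test_incomplete_terminal_codon_site_skipped(self):
        # polymorphic site at position 3 lies in the incomplete terminal codon
        s, n, labels = classify_snp_sites(["TTTA", "TTTG"])
        assert labels == {} and (s, n) == (0, 0)


class TestNeiGojobori:
    def test_single_synonymous_codon_pair(self):
        dn, ds, ratio = nei_gojobori(["TTT", "TTC"])
        assert dn == 0.0 and ratio == 0.0
        # uncorrected proportions: Sd=1 over S=1/3 potential synonymous sites
        dn_u, ds_u, ratio_u = nei_gojobori(["TTT", "TTC"], correction="none")
        assert (dn_u, ratio_u) == (0.0, 0.0) and ds_u == pytest.approx(3.0)

    def test_synonymous_change_in_context_positive_ds(self):
        dn, ds, ratio = nei_gojobori(["TTTGGGGGG", "TTCGGGGGG"])
        assert dn == 0.0 and ratio == 0.0 and ds > 0

    def test_identical_sequences_degenerate(self):
        dn, ds, ratio = nei_gojobori(["TTTACG", "TTTACG"])
        assert (dn, ds, ratio) == (0.0, 0.0, 0.0)

    def test_undefined_when_only_nonsynonymous(self):
        # TTT (Phe) vs GTT (Val): Nd=1, Sd=0 -> dS=0, dN>0 -> undefined
        dn, ds, ratio = nei_gojobori(["TTT", "GTT"])
        assert dn > 0 and ds == 0.0 and ratio is None

    def test_matches_independent_ng86_implementation(self, rng):
        """Cross-check against Biopython's NG86 on random codon pairs."""
        from Bio.Align import Alignment, analysis

        codons = [
            a + b + c
            for a in "ACGT" for b in "ACGT" for c in "ACGT"
            if a + b + c not in {"TAA", "TAG", "TGA"}
        ]
        checked = 0
        while checked < 8:
            s1 = "".join(rng.choice(codons, 25))
            chars = list(s1)
            for _ in range(5):
                pos = int(rng.integers(len(chars)))
                chars[pos] = "ACGT"[int(rng.integers(4))]
            s2 = "".join(chars)
            if any(
                s2[i : i + 3] in {"TAA", "TAG", "TGA"} for i in range(0, len(s2), 3)
            ):
                continue
            aln = Alignment([s1, s2], np.array([[0, len(s1)], [0, len(s2)]]))
            dn_ref, ds_ref = analysis.calculate_dn_ds(aln, method="NG86")
            dn, ds, _ = nei_gojobori([s1, s2])
            assert dn == pytest.approx(dn_ref, abs=1e-9)
            assert ds == pytest.approx(ds_ref, abs=1e-9)
            checked += 1

    def test_synonymous_only_variation_gives_zero_dn(self):
        # third-position wobble in 4-fold degenerate codons (Gly: GGN),
        # padded with conserved codons so p_S stays below saturation
        tail = "TTTAAAGATTTTAAAGAT"
        aln = [
            "GGAGGCGGT" + tail,
            "GGCGGAGGG" + tail,
            "GGTGGTGGA" + tail,
        ]
        dn, ds, ratio = nei_gojobori(aln)
        assert dn == 0.0 and ratio == 0.0 and ds > 0

    def test_dnds_increases_with_nonsynonymous_fraction(self):
        base = "GGAGGCGGTGGAGGC"  # 5 glycine codons
        # variant sets with increasing nonsynonymous content
        syn = ["GGCGGCGGTGGAGGC", base]          # 1 synonymous change
        mixed = ["GGCGGCGGTGGAGAC", base]        # 1 syn + 1 nonsyn (GGA->GAC? pos2)
        nonsyn = ["GTAGGCGGTGGAGAC", base]       # 2 nonsyn
        ratios = []
        for aln in (syn, mixed, nonsyn):
            dn, ds, r = nei_gojobori(aln)
            ratios.append(np.inf if r is None else r)
        assert ratios[0] == 0.0
        assert ratios[0] < ratios[1] <= ratios[2]


class TestDiversityReport:
    def test_rows_and_internal_consistency(self, rng):
        loci = {}
        for name, L in (("locA", 12), ("locB", 21)):
            base = "".join(rng.choice(list("ACGT"), L))
            seqs = {}
            for k in range(6):
                chars = list(base)
                if k % 2:
                    pos = int(rng.integers(L))
                    chars[pos] = {"A": "G", "C": "T", "G": "A", "T": "C"}[chars[pos]]
                seqs[f"i{k}"] = "".join(chars)
            loci[name] = seqs
        ds = make_dataset(loci)
        table = assign_profiles(ds)
        rows = diversity_report(ds, table)
        assert len(rows) == 3
        assert rows[-1].locus == "concatenated"
        assert [r.n_alleles for r in rows[:-1]] == [
            len(table.catalogs[n]) for n in ds.locus_names
        ]
        # per-locus polymorphic sites sum to the concatenated count
        assert sum(r.n_polymorphic_sites for r in rows[:-1]) == rows[-1].n_polymorphic_sites
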