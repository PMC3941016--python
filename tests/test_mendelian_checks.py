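import math
from itertools import combinations_with_replacement, product

import numpy as np
import pytest

from famsnp import (
    ComparisonCategory,
    categorize_pair,
    count_mies,
    count_trio_mies,
    detect_hemizygous_segments,
    duo_mie,
    filter_autosomes,
    make_panel,
    simulate_family,
    trio_mie,
)
from famsnp.synthetic_family import Deletion
from famsnp.mendelian_checks import segments_to_bed

from conftest import make_table

DIPLOID = ["".join(p) for p in combinations_with_replacement("ACGT", 2)]


def oracle_duo(parent, child):
    """Independent check: does any parental allele appear in the child?"""
    return all(p != c for p in parent for c in child)


def oracle_trio(father, mother, child):
    """Enumerate the 4 parental transmissions explicitly."""
    targets = {tuple(sorted(child))}
    produced = {tuple(sorted((f, m))) for f in father for m in mother}
    return not (targets & produced)


class TestDuoMie:
    @pytest.mark.parametrize("parent, child, expected", [
        ("TT", "CC", True),
        ("AG", "AA", False),
        ("AG", "CT", True),
        ("ID", "II", False),
    ])
    def test_examples(self, parent, child, expected):
        assert duo_mie(parent, child) is expected

    def test_exhaustive_oracle(self):
        for p, c in product(DIPLOID, DIPLOID):
            assert duo_mie(p, c) == oracle_duo(p, c), (p, c)

    def test_no_call_rejected(self):
        with pytest.raises(ValueError):
            duo_mie("--", "AA")


class TestTrioMie:
    @pytest.mark.parametrize("f, m, c, expected", [
        ("CC", "CC", "TT", True),
        ("AG", "AG", "AA", False),
        ("CC", "CC", "CT", True),  # the T allele is unexplained
    ])
    def test_examples(self, f, m, c, expected):
        assert trio_mie(f, m, c) is expected

    def test_exhaustive_oracle(self):
        for f, m, c in product(DIPLOID, DIPLOID, DIPLOID):
            assert trio_mie(f, m, c) == oracle_trio(f, m, c), (f, m, c)

    def test_symmetric_in_parents(self):
        for f, m, c in product(DIPLOID, DIPLOID, DIPLOID):
            assert trio_mie(f, m, c) == trio_mie(m, f, c)


class TestCountMies:
    def test_error_free_parent_child_has_none(self, clean_family):
        t = clean_family.tables
        for parent, child in [("Father", "Son"), ("Mother", "Son"),
                              ("Father", "Daughter"), ("Mother", "Daughter")]:
            assert count_mies(t[parent], t[child]).count == 0

    def test_count_increases_with_undercall_rate(self):
        counts = []
        for x in (0.001, 0.005, 0.01):
            panel = make_panel(100_000, n_chromosomes=4,
                               chrom_length=100_000_000, seed=31)
            fam = simulate_family(panel, error_x=x, seed=31)
            r = count_mies(fam.tables["Mother"], fam.tables["Daughter"])
            assert r.count > 0
            counts.append(r.count)
        assert counts[0] < counts[1] < counts[2]

    def test_unrelated_pseudo_mie_rate_matches_enumeration(self):
        """At allele frequency 0.5 the chance of fully disjoint genotypes is
        2*(p^2*q^2) = 0.125, by expectation over all genotype pairs."""
        p = q = 0.5
        geno_probs = {"aa": p * p, "ab": 2 * p * q, "bb": q * q}
        expected = sum(
            geno_probs[g1] * geno_probs[g2]
            for g1 in geno_probs for g2 in geno_probs
            if not (set(g1) & set(g2))
        )
        assert expected == pytest.approx(0.125)

        panel = make_panel(100_000, n_chromosomes=4, chrom_length=100_000_000,
                           freq_sampler=0.5, seed=32)
        fam = simulate_family(panel, error_x=0.0, seed=32)
        r = count_mies(fam.tables["Father"], fam.tables["Grandfather"],
                       relation="unrelated")
        n = 100_000
        sigma = math.sqrt(expected * (1 - expected) / n)
        assert abs(r.count / n - expected) < 3 * sigma
        assert not r.is_mie

    def test_sites_never_include_no_calls(self, noisy_family):
        t = noisy_family.tables
        r = count_mies(t["Mother"], t["Daughter"])
        gm = t["Mother"].df.set_index("marker_id")["genotype"]
        gd = t["Daughter"].df.set_index("marker_id")["genotype"]
        for chrom, pos, marker in r.sites:
            assert gm[marker] != "--" and gd[marker] != "--"

    def test_duo_mie_sites_are_conflict_sites(self, noisy_family):
        """Every duo-MIE site is a CONFLICT in the similarity categories."""
        t = noisy_family.tables
        r = count_mies(t["Father"], t["Son"])
        gm = t["Father"].df.set_index("marker_id")["genotype"]
        gs = t["Son"].df.set_index("marker_id")["genotype"]
        assert r.count > 0
        for _, _, marker in r.sites:
            assert categorize_pair(gm[marker], gs[marker]) is ComparisonCategory.CONFLICT


class TestCountTrioMies:
    def test_single_site_worked_example(self):
        f = make_table("F", [("rs1", "4", 79957622, "CC")])
        m = make_table("M", [("rs1", "4", 79957622, "CC")])
        c = make_table("C", [("rs1", "4", 79957622, "TT")])
        assert count_trio_mies(f, m, c).count == 1

    def test_error_free_trio_has_none(self, clean_family):
        t = clean_family.tables
        assert count_trio_mies(t["Father"], t["Mother"], t["Son"]).count == 0

    def test_duo_sites_contained_in_trio_sites(self, noisy_family):
        """A site where the child shares no allele with one parent is
        incompatible with any joint transmission, so (over markers called in
        all three) the duo-incompatible sites are a subset of the trio's."""
        t = noisy_family.tables
        trio_sites = set(count_trio_mies(t["Father"], t["Mother"], t["Daughter"]).sites)
        called = None
        for name in ("Father", "Mother", "Daughter"):
            mask = t[name].df["genotype"] != "--"
            ids = set(t[name].df.loc[mask, "marker_id"])
            called = ids if called is None else called & ids
        for parent in ("Father", "Mother"):
            duo_sites = {s for s in count_mies(t[parent], t["Daughter"]).sites
                         if s[2] in called}
            assert duo_sites <= trio_sites


class TestHemizygousSegments:
    @pytest.fixture(scope="class")
    def deletion_family(self):
        # ~1 marker/kb so a 10 kb deletion spans ~10 markers
        panel = make_panel(100_000, n_chromosomes=5, chrom_length=20_000_000, seed=3)
        dels = [Deletion("Mother", "2", 5_000_000, 5_010_000)]
        return simulate_family(panel, error_x=0.0, deletions=dels, seed=3)

    def test_transmitted_deletion_recovered(self, deletion_family):
        fam = deletion_family
        hap = fam.deletion_haplotype[0]
        dl = fam.deletions[0]
        mask = ((fam.panel.chromosome == dl.chromosome)
                & (fam.panel.position >= dl.start) & (fam.panel.position <= dl.end))
        assert mask.sum() >= 5
        inheritors = [c for c in ("Son", "Daughter")
                      if np.all(fam.meioses[("Mother", c)].source[mask] == hap)]
        assert inheritors, "deletion transmitted to no child under this seed"
        for child in inheritors:
            segs = detect_hemizygous_segments(fam.tables["Mother"], fam.tables[child])
            assert len(segs) == 1
            s = segs[0]
            assert s.chromosome == dl.chromosome
            assert s.start <= dl.end and s.end >= dl.start  # overlaps truth
            assert s.supporting_sites >= 3

    def test_non_inheriting_child_shows_no_segment(self, deletion_family):
        fam = deletion_family
        hap = fam.deletion_haplotype[0]
        dl = fam.deletions[0]
        mask = ((fam.panel.chromosome == dl.chromosome)
                & (fam.panel.position >= dl.start) & (fam.panel.position <= dl.end))
        for child in ("Son", "Daughter"):
            if not np.all(fam.meioses[("Mother", child)].source[mask] == hap):
                segs = detect_hemizygous_segments(fam.tables["Mother"], fam.tables[child])
                assert segs == []

    def test_deletion_site_reported_homozygous(self, deletion_family):
        """Hemizygous truth is reported as homozygous for the present allele."""
        fam = deletion_family
        dl = fam.deletions[0]
        mask = ((fam.panel.chromosome == dl.chromosome)
                & (fam.panel.position >= dl.start) & (fam.panel.position <= dl.end))
        truth = fam.true_genotypes["Mother"][mask]
        obs = fam.tables["Mother"].df.set_index("marker_id").loc[
            fam.panel.marker_ids[mask], "genotype"].to_numpy()
        assert all(len(g) == 1 for g in truth)  # single remaining allele
        assert all(o == g * 2 for g, o in zip(truth, obs))

    def test_clean_pair_yields_no_segments(self, clean_family):
        t = clean_family.tables
        assert detect_hemizygous_segments(t["Mother"], t["Daughter"]) == []

    def test_bed_output_is_zero_based_half_open(self):
        from famsnp.mendelian_checks import HemizygousSegment
        seg = HemizygousSegment("2", 101, 200, ("M", "D"), 4, 9)
        assert segments_to_bed([seg]) == "2\t100\t200\tM|D\t4\n"
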