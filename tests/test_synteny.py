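"""Locus calling, window extraction, and neighborhood pattern detection."""

import pytest

from rebscan.families import ProteinFamily, SYNTENY_REGIME
from rebscan.records import Proteome
from rebscan.simulate import random_protein
from rebscan.synteny import call_reb_loci, detect_patterns, extract_window

from conftest import make_record

import numpy as np


def linear_proteome(n_genes: int, taxon="T1", replicon="chr", length=30):
    rng = np.random.default_rng(99)
    return Proteome(
        taxon_id=taxon,
        records=[
            make_record(f"{taxon}_{replicon}_{i:04d}",
                        random_protein(length, rng),
                        taxon=taxon, replicon=replicon, index=i)
            for i in range(n_genes)
        ],
    )


def pid(i, taxon="T1", replicon="chr"):
    return f"{taxon}_{replicon}_{i:04d}"


class TestLocusCalling:
    def test_adjacent_run_with_gap_is_one_locus(self):
        proteome = linear_proteome(20)
        loci = call_reb_loci(proteome, {pid(4), pid(5), pid(6)}, max_gap=2)
        assert len(loci) == 1
        assert loci[0].index_span == (4, 6)
        assert loci[0].member_reb_ids == (pid(4), pid(5), pid(6))

    def test_intervening_gap_within_allowance_merges(self):
        proteome = linear_proteome(20)
        loci = call_reb_loci(proteome, {pid(4), pid(7)}, max_gap=2)
        assert len(loci) == 1 and loci[0].index_span == (4, 7)

    def test_far_copies_are_two_loci(self):
        proteome = linear_proteome(50)
        loci = call_reb_loci(proteome, {pid(4), pid(40)}, max_gap=2)
        assert [l.index_span for l in loci] == [(4, 4), (40, 40)]

    def test_empty_reb_set_is_empty_list(self):
        assert call_reb_loci(linear_proteome(5), set()) == []

    def test_distal_planted_copy_gives_two_loci(self, small_dataset):
        # the generator planted one extra far-away copy in the first reb taxon
        truth = small_dataset.truth
        taxon = "R01"
        proteome = small_dataset.proteome(taxon)
        loci = call_reb_loci(proteome, truth.reb_protein_ids, max_gap=3)
        got = [(l.replicon_id, l.index_span) for l in loci]
        assert sorted(got) == sorted(
            (rep, tuple(span)) for rep, span in truth.locus_positions[taxon]
        )
        assert len(got) >= 2


class TestWindowExtraction:
    def test_truncation_at_replicon_start(self):
        proteome = linear_proteome(20)
        locus = call_reb_loci(proteome, {pid(2), pid(3)}, max_gap=0)[0]
        window = extract_window(locus, proteome, k=5,
                                reb_ids={pid(2), pid(3)})
        assert window.upstream == (pid(0), pid(1))
        assert window.downstream == tuple(pid(i) for i in range(4, 9))
        assert window.truncated

    def test_full_window_mid_replicon(self):
        proteome = linear_proteome(30)
        locus = call_reb_loci(proteome, {pid(15)}, max_gap=0)[0]
        window = extract_window(locus, proteome, k=5, reb_ids={pid(15)})
        assert window.upstream == tuple(pid(i) for i in range(10, 15))
        assert window.downstream == tuple(pid(i) for i in range(16, 21))
        assert not window.truncated

    def test_windows_never_contain_reb_genes(self, small_dataset):
        truth = small_dataset.truth
        for taxon in sorted(truth.reb_taxa):
            proteome = small_dataset.proteome(taxon)
            for locus in call_reb_loci(proteome, truth.reb_protein_ids, 3):
                w = extract_window(locus, proteome, k=5,
                                   reb_ids=truth.reb_protein_ids)
                assert not (set(w.upstream) | set(w.downstream)) & truth.reb_protein_ids

    def test_group1_partners_lie_inside_window(self, small_dataset):
        truth = small_dataset.truth
        partner_ids = set().union(
            *(truth.partner_family_map[f] for f in
              ("HP1.1", "HP1.2", "HP1.3", "HP1.4"))
        )
        for taxon, kind in truth.pattern_by_taxon.items():
            if kind != "group1":
                continue
            proteome = small_dataset.proteome(taxon)
            window_ids = set()
            for locus in call_reb_loci(proteome, truth.reb_protein_ids, 3):
                w = extract_window(locus, proteome, k=5,
                                   reb_ids=truth.reb_protein_ids)
                window_ids |= set(w.upstream) | set(w.downstream)
            mine = {p for p in partner_ids if p.startswith(taxon)}
            assert mine and mine <= window_ids


class TestPatternDetection:
    @staticmethod
    def _windows_and_families(n_taxa=3, with_decoy_member_in_nonreb=False):
        """Hand-built scenario: families F1, F2 recur in every reb window;
        family D also recurs but (optionally) has a member in a non-reb
        taxon and must then be excluded genome-wide."""
        windows, fam_members = [], {"F1": set(), "F2": set(), "D": set()}
        taxon_of = {}
        proteomes = {}
        for t in range(n_taxa):
            taxon = f"R{t + 1:02d}"
            proteome = linear_proteome(15, taxon=taxon)
            proteomes[taxon] = proteome
            reb = pid(7, taxon)
            taxon_of.update({r.protein_id: taxon for r in proteome})
            locus = call_reb_loci(proteome, {reb}, 0)[0]
            windows.append(extract_window(locus, proteome, 5, {reb}))
            fam_members["F1"].add(pid(8, taxon))
            fam_members["F2"].add(pid(9, taxon))
            fam_members["D"].add(pid(6, taxon))
        if with_decoy_member_in_nonreb:
            fam_members["D"].add("N01_chr_0000")
            taxon_of["N01_chr_0000"] = "N01"
        families = [
            ProteinFamily(family_id=min(m), members=frozenset(m),
                          regime=SYNTENY_REGIME)
            for m in fam_members.values()
        ]
        # every other window gene is its own singleton family
        singles = {p for w in windows for p in w.upstream + w.downstream}
        singles -= set().union(*fam_members.values())
        families += [
            ProteinFamily(family_id=p, members=frozenset({p}),
                          regime=SYNTENY_REGIME)
            for p in singles
        ]
        reb_taxa = {f"R{t + 1:02d}" for t in range(n_taxa)}
        all_taxa = reb_taxa | ({"N01"} if with_decoy_member_in_nonreb else set())
        return windows, families, reb_taxa, all_taxa, taxon_of

    def test_recurring_exclusive_families_form_one_pattern(self):
        windows, families, reb_taxa, all_taxa, taxon_of = \
            self._windows_and_families()
        patterns = detect_patterns(windows, families, reb_taxa, all_taxa,
                                   taxon_of, min_taxa=3)
        assert len(patterns) == 1
        fams = patterns[0].family_ids
        # D has no non-reb member here, so it co-occurs with F1/F2
        assert len(fams) == 3
        assert patterns[0].supporting_taxa == frozenset(reb_taxa)

    def test_family_with_nonreb_member_is_excluded_genome_wide(self):
        windows, families, reb_taxa, all_taxa, taxon_of = \
            self._windows_and_families(with_decoy_member_in_nonreb=True)
        patterns = detect_patterns(windows, families, reb_taxa, all_taxa,
                                   taxon_of, min_taxa=3)
        assert len(patterns) == 1
        decoy_fam = next(f.family_id for f in families
                         if "N01_chr_0000" in f.members)
        assert decoy_fam not in patterns[0].family_ids

    def test_min_taxa_validation(self):
        windows, families, reb_taxa, all_taxa, taxon_of = \
            self._windows_and_families()
        with pytest.raises(ValueError):
            detect_patterns(windows, families, reb_taxa, all_taxa, taxon_of,
                            min_taxa=1)

    def test_single_taxon_yields_no_patterns(self):
        windows, families, reb_taxa, all_taxa, taxon_of = \
            self._windows_and_families(n_taxa=1)
        patterns = detect_patterns(windows, families, reb_taxa, all_taxa,
                                   taxon_of, min_taxa=2)
        assert patterns == []

    def test_adjacency_profile_orders_context(self):
        windows, families, reb_taxa, all_taxa, taxon_of = \
            self._windows_and_families()
        patterns = detect_patterns(windows, families, reb_taxa, all_taxa,
                                   taxon_of, min_taxa=3)
        profile = patterns[0].adjacency_profile["R01"]
        assert "REB" in profile
        assert len(profile) == 11  # 5 up + 1 reb + 5 down
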