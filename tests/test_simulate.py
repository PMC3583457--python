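"""The synthetic world: determinism, planted structure, and serialization."""

import numpy as np
import pytest

from rebscan.records import read_proteome
from rebscan.simulate import (
    GeneratorConfig,
    generate_dataset,
    mutate_sequence,
    random_protein,
    write_dataset,
    _KERNEL,
)


class TestConfigValidation:
    def test_zero_taxa_rejected(self):
        with pytest.raises(ValueError, match="zero taxa"):
            GeneratorConfig(n_reb_taxa=0, n_nonreb_taxa=0)

    def test_identity_floor_guard(self):
        with pytest.raises(ValueError, match="identity floor"):
            GeneratorConfig(divergence=0.85)

    def test_copies_range_validation(self):
        with pytest.raises(ValueError):
            GeneratorConfig(reb_copies_range=(0, 9))
        with pytest.raises(ValueError):
            GeneratorConfig(reb_copies_range=(5, 2))

    def test_pattern_kinds_length_checked(self):
        with pytest.raises(ValueError):
            GeneratorConfig(n_reb_taxa=3, pattern_kinds=("group1",))

    def test_json_round_trip(self):
        config = GeneratorConfig(seed=5, pattern_kinds=("group1", "none"),
                                 n_reb_taxa=2)
        assert GeneratorConfig.from_json(config.to_json()) == config


class TestSequenceModel:
    def test_substitutions_never_keep_the_residue(self):
        assert np.allclose(np.diag(_KERNEL), 0.0)

    def test_identity_matches_per_site_expectation(self, rng):
        # replacement never equals the original residue, so expected identity
        # to the ancestor is exactly 1 - divergence per site
        divergence = 0.3
        ancestor = random_protein(95, rng)
        identities = []
        for _ in range(200):
            copy = mutate_sequence(ancestor, divergence, rng)
            identities.append(
                sum(a == b for a, b in zip(ancestor, copy)) / len(ancestor)
            )
        assert np.mean(identities) == pytest.approx(1 - divergence, abs=0.05)

    def test_zero_divergence_is_identity(self, rng):
        seq = random_protein(50, rng)
        assert mutate_sequence(seq, 0.0, rng) == seq


class TestPlantedStructure:
    def test_copy_numbers_within_range(self):
        dataset = generate_dataset(GeneratorConfig(seed=2, n_reb_taxa=5,
                                                   n_nonreb_taxa=2))
        truth = dataset.truth
        for taxon in truth.reb_taxa:
            n = sum(1 for pid in truth.reb_protein_ids
                    if pid.startswith(taxon))
            assert 1 <= n <= 9

    def test_partner_families_only_in_reb_taxa(self, small_dataset):
        truth = small_dataset.truth
        for label, members in truth.partner_family_map.items():
            for pid in members:
                taxon = pid.split("_")[0]
                assert taxon in truth.reb_taxa, (label, pid)

    def test_patterns_mutually_exclusive(self, small_dataset):
        truth = small_dataset.truth
        for taxon, kind in truth.pattern_by_taxon.items():
            partners = {
                label
                for label, members in truth.partner_family_map.items()
                if any(p.startswith(taxon) for p in members)
            }
            if kind == "group1":
                assert partners == {"HP1.1", "HP1.2", "HP1.3", "HP1.4"}
            elif kind == "group2":
                assert partners == {"HP2.1", "HP2.2", "HP2.3", "HP2.4"}
            else:
                assert partners == set()

    def test_loci_are_contiguous_up_to_gap(self, small_dataset):
        config = small_dataset.config
        truth = small_dataset.truth
        for taxon, loci in truth.locus_positions.items():
            proteome = small_dataset.proteome(taxon)
            for replicon, (lo, hi) in loci:
                indices = sorted(
                    r.index for r in proteome.replicon_records(replicon)
                    if r.protein_id in truth.reb_protein_ids
                    and lo <= r.index <= hi
                )
                gaps = [b - a - 1 for a, b in zip(indices, indices[1:])]
                assert all(g <= config.locus_max_gap for g in gaps)

    def test_each_planted_protein_in_exactly_one_family(self, small_dataset):
        truth = small_dataset.truth
        seen = {}
        for label, members in truth.planted_families().items():
            for pid in members:
                assert pid not in seen, (pid, label, seen[pid])
                seen[pid] = label

    def test_promiscuous_decoy_spans_all_taxa(self, small_dataset):
        truth = small_dataset.truth
        taxa = {pid.split("_")[0]
                for pid in truth.decoy_family_map["decoy01"]}
        assert taxa == truth.reb_taxa | truth.nonreb_taxa

    def test_mean_reb_length(self, small_dataset):
        records = {r.protein_id: r for p in small_dataset.proteomes for r in p}
        lengths = [len(records[pid])
                   for pid in small_dataset.truth.reb_protein_ids]
        assert np.mean(lengths) == pytest.approx(95, abs=1)


class TestSerialization:
    def test_byte_identical_reruns(self, tmp_path):
        config = GeneratorConfig(seed=1, n_reb_taxa=2, n_nonreb_taxa=1,
                                 background_genes_per_replicon=8,
                                 decoy_family_count=3)
        out_a, out_b = tmp_path / "a", tmp_path / "b"
        write_dataset(generate_dataset(config), out_a)
        write_dataset(generate_dataset(config), out_b)
        files_a = sorted(p.name for p in out_a.iterdir())
        assert files_a == sorted(p.name for p in out_b.iterdir())
        for name in files_a:
            assert (out_a / name).read_bytes() == (out_b / name).read_bytes()

    def test_file_counts_and_manifest(self, tmp_path):
        config = GeneratorConfig(seed=3, n_reb_taxa=2, n_nonreb_taxa=1,
                                 background_genes_per_replicon=6,
                                 decoy_family_count=2)
        manifest = write_dataset(generate_dataset(config), tmp_path)
        assert len(manifest["fasta"]) == 3
        assert len(manifest["gff3"]) == 3
        assert len(manifest["truth"]) == 2
        assert manifest["seeds"] == ["seeds.faa"]

    def test_round_trip_preserves_records(self, tmp_path):
        config = GeneratorConfig(seed=4, n_reb_taxa=1, n_nonreb_taxa=1,
                                 background_genes_per_replicon=6,
                                 decoy_family_count=2)
        dataset = generate_dataset(config)
        write_dataset(dataset, tmp_path)
        for proteome in dataset.proteomes:
            loaded = read_proteome(
                proteome.taxon_id,
                tmp_path / f"{proteome.taxon_id}.faa",
                tmp_path / f"{proteome.taxon_id}.gff3",
            )
            assert loaded.records == proteome.records

    def test_gff_coordinates_valid(self, small_dataset, tmp_path):
        write_dataset(small_dataset, tmp_path)
        from rebscan.records import read_gff3_table

        for proteome in small_dataset.proteomes:
            table = read_gff3_table(tmp_path / f"{proteome.taxon_id}.gff3")
            assert (table["start"] <= table["end"]).all()
            assert (table["start"] >= 1).all()
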