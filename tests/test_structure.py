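"""Contact maps: loading, the representative-atom rule, states, details."""

import numpy as np
import pytest

from ptmkit import fixtures
from ptmkit.records import ModificationSite
from ptmkit.structure import (
    STATE_ANY_MODIFIED,
    STATE_BOTH_UNMODIFIED,
    STATE_HIGHLIGHTED,
    classify_contacts,
    closest_atom_distance,
    contact_map,
    load_structure,
    modified_contact_filter,
    residue_pair_detail,
)


def write_structure(tmp_path, toy, name="toy.pdb"):
    path = tmp_path / name
    toy.write(path)
    return path


def labeled_site(pos, label="Phospho", acc="TOY"):
    return ModificationSite(protein_accession=acc, position=pos,
                            mass_shift=79.966331, label=label,
                            mod_class="Post-translational")


class TestLoadStructure:
    def test_toy_model_residues_in_order(self, tmp_path):
        toy = fixtures.generate_toy_structure("ACDEF", "extended")
        model = load_structure(write_structure(tmp_path, toy), "TOY")
        assert [r.position for r in model.residues] == [1, 2, 3, 4, 5]
        assert [r.letter for r in model.residues] == list("ACDEF")

    def test_glycine_uses_calpha(self, tmp_path):
        toy = fixtures.generate_toy_structure("AGA", "extended")
        model = load_structure(write_structure(tmp_path, toy), "TOY")
        gly = model.residue(2)
        assert gly.name == "GLY" and not gly.used_fallback
        # glycine Ca sits at the lattice point (z = 0); others' Cb does
        assert gly.coord[2] == pytest.approx(0.0)

    def test_missing_cbeta_falls_back_to_calpha_flagged(self, tmp_path):
        pdb = (
            "ATOM      1  CA  SER A   1       0.000   0.000   0.000"
            "  1.00  0.00           C\nEND\n"
        )
        path = tmp_path / "trunc.pdb"
        path.write_text(pdb)
        model = load_structure(path, "T")
        assert model.residues[0].used_fallback

    def test_empty_structure_warns(self, tmp_path, caplog):
        path = tmp_path / "empty.pdb"
        path.write_text("END\n")
        with caplog.at_level("WARNING"):
            model = load_structure(path, "T")
        assert model.residues == []

    def test_sequence_crosscheck_logs_mismatch(self, tmp_path, caplog,
                                               small_catalog):
        toy = fixtures.generate_toy_structure("AAAA", "extended")
        with caplog.at_level("WARNING"):
            load_structure(write_structure(tmp_path, toy), "P00001",
                           small_catalog)
        assert "disagree" in caplog.text


class TestContactMap:
    def test_pair_below_cutoff_present_with_distance(self, tmp_path):
        catalog, sites, toy = fixtures.synthetic_groel_scenario()
        model = load_structure(write_structure(tmp_path, toy), "SYNGROEL")
        cmap = contact_map(model, 4.69, 2)
        assert (80, 506) in cmap
        assert cmap.distance(80, 506) == pytest.approx(4.41, abs=1e-6)

    def test_boundary_is_strictly_below_cutoff(self, tmp_path):
        catalog, sites, toy = fixtures.synthetic_groel_scenario(
            contact_distance=4.70)
        model = load_structure(write_structure(tmp_path, toy), "SYNGROEL")
        assert (80, 506) not in contact_map(model, 4.69, 2)
        # ... and a pair exactly at the cutoff is excluded too
        catalog, sites, toy = fixtures.synthetic_groel_scenario(
            contact_distance=4.69)
        model = load_structure(write_structure(tmp_path, toy), "SYNGROEL")
        assert (80, 506) not in contact_map(model, 4.69, 2)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle_on_random_coils(self, tmp_path, seed):
        sequence = "ACDEFGHIKLMNPQRSTVWY" * 3
        toy = fixtures.generate_toy_structure(sequence, "coil", seed=seed)
        model = load_structure(write_structure(tmp_path, toy, f"c{seed}.pdb"),
                               "TOY")
        cmap = contact_map(model, toy.cutoff, toy.min_separation)
        assert cmap.pairs() == toy.expected_contacts

    def test_hairpin_matches_closed_form(self, tmp_path):
        toy = fixtures.generate_toy_structure("ACDEFHIKLM", "hairpin")
        model = load_structure(write_structure(tmp_path, toy), "TOY")
        assert contact_map(model, 4.69, 2).pairs() == \
            fixtures.hairpin_closed_form(10)

    def test_monotone_in_cutoff(self, tmp_path):
        toy = fixtures.generate_toy_structure("ACDEFGHIKLMNPQRSTVWY" * 2,
                                              "coil", seed=3)
        model = load_structure(write_structure(tmp_path, toy), "TOY")
        cutoffs = [3.0, 4.0, 4.69, 6.0, 8.0]
        maps = [set(contact_map(model, c, 2).pairs()) for c in cutoffs]
        for smaller, larger in zip(maps, maps[1:]):
            assert smaller <= larger

    def test_min_separation_excludes_neighbors(self, tmp_path):
        toy = fixtures.generate_toy_structure("ACDEF", "extended")
        model = load_structure(write_structure(tmp_path, toy), "TOY")
        cmap = contact_map(model, 4.69, 1)
        assert all(j - i >= 1 for i, j in cmap.pairs())
        assert (1, 2) in cmap  # adjacent Cb 3.8 A apart admitted at sep 1
        assert (1, 2) not in contact_map(model, 4.69, 2)


class TestStates:
    def make_map(self, tmp_path):
        catalog, sites, toy = fixtures.synthetic_groel_scenario()
        model = load_structure(write_structure(tmp_path, toy), "SYNGROEL")
        return contact_map(model, 4.69, 2)

    def test_highlight_precedence(self, tmp_path):
        cmap = self.make_map(tmp_path)
        classify_contacts(cmap, [labeled_site(506, acc="SYNGROEL")],
                          highlight="Phospho")
        assert cmap.state(80, 506) == STATE_HIGHLIGHTED

    def test_other_modification_is_any_modified(self, tmp_path):
        cmap = self.make_map(tmp_path)
        classify_contacts(
            cmap, [labeled_site(506, label="Oxidation", acc="SYNGROEL")],
            highlight="Phospho")
        assert cmap.state(80, 506) == STATE_ANY_MODIFIED

    def test_no_sites_all_unmodified(self, tmp_path):
        cmap = self.make_map(tmp_path)
        classify_contacts(cmap, [])
        assert cmap.state(80, 506) == STATE_BOTH_UNMODIFIED

    def test_absent_highlight_label_warns_and_highlights_nothing(
            self, tmp_path, caplog):
        cmap = self.make_map(tmp_path)
        with caplog.at_level("WARNING"):
            classify_contacts(cmap, [labeled_site(506, label="Oxidation",
                                                  acc="SYNGROEL")],
                              highlight="Phospho")
        assert "not found" in caplog.text
        assert STATE_HIGHLIGHTED not in cmap.states.values()

    def test_exactly_one_state_per_pair(self, tmp_path):
        toy = fixtures.generate_toy_structure("ACDEFGHIKLMNPQRSTVWY" * 2,
                                              "coil", seed=1)
        model = load_structure(write_structure(tmp_path, toy), "TOY")
        cmap = contact_map(model, 6.0, 2)
        sites = [labeled_site(p) for p in (3, 9, 20)]
        classify_contacts(cmap, sites, highlight="Phospho")
        assert set(cmap.states) == set(cmap.distances)


class TestDetailAndFilter:
    def test_pair_detail_mirrors_the_phosphosite_scenario(self, tmp_path):
        catalog, sites, toy = fixtures.synthetic_groel_scenario()
        from ptmkit.unimod import label_sites, load_bundled_table
        sites = label_sites(sites, load_bundled_table())
        model = load_structure(write_structure(tmp_path, toy), "SYNGROEL")
        cmap = contact_map(model, 4.69, 2)
        detail = residue_pair_detail(cmap, (506, 80), sites)
        assert detail.distance == pytest.approx(4.41, abs=1e-6)
        assert detail.mods_i == []  # Lys80 unmodified
        (label, mass, cls) = detail.mods_j[0]
        assert label == "Phospho" and mass == pytest.approx(79.9663, abs=1e-4)

    def test_absent_pair_is_lookup_error(self, tmp_path):
        cmap = TestStates().make_map(tmp_path)
        with pytest.raises(KeyError):
            residue_pair_detail(cmap, (1, 2), [])

    def test_filter_keeps_only_modified_contacts(self, tmp_path):
        toy = fixtures.generate_toy_structure("ACDEFGHIKLMNPQRSTVWY" * 2,
                                              "coil", seed=2)
        model = load_structure(write_structure(tmp_path, toy), "TOY")
        cmap = contact_map(model, 6.0, 2)
        sites = [labeled_site(5)]
        classify_contacts(cmap, sites)
        sub = modified_contact_filter(cmap)
        assert all(5 in pair for pair in sub.pairs())
        assert all(state != STATE_BOTH_UNMODIFIED
                   for state in sub.states.values())

    def test_filter_commutes_with_classify(self, tmp_path):
        toy = fixtures.generate_toy_structure("ACDEFGHIKLMNPQRSTVWY" * 2,
                                              "coil", seed=4)
        model = load_structure(write_structure(tmp_path, toy), "TOY")
        sites = [labeled_site(p) for p in (2, 11, 30)]
        cmap1 = classify_contacts(contact_map(model, 6.0, 2), sites, "Phospho")
        filtered = modified_contact_filter(cmap1)
        reclassified = classify_contacts(filtered, sites, "Phospho")
        assert reclassified.states == {
            p: s for p, s in cmap1.states.items() if p in filtered.distances}

    def test_closest_atom_distance_not_larger_than_rule_distance(self, tmp_path):
        catalog, sites, toy = fixtures.synthetic_groel_scenario()
        model = load_structure(write_structure(tmp_path, toy), "SYNGROEL")
        cmap = contact_map(model, 4.69, 2)
        assert closest_atom_distance(model, 80, 506) <= \
            cmap.distance(80, 506) + 1e-9
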