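"""Sample-level and protein-level summary structures."""

import itertools

import numpy as np
import pytest

from ptmkit.annotation import ProteinEntry
from ptmkit.errors import UsageError
from ptmkit.records import ModificationSite, ModificationType
from ptmkit.summaries import (
    aa_mod_heatmap,
    build_sample_summary,
    class_distribution,
    modification_axis,
    modification_types,
    per_position_counts,
    presence_absence,
    shared_site_matrix,
    site_counts,
)


def site(acc="P1", pos=1, label="Phospho", mass=79.966331,
         cls="Post-translational", residue="S", count=1):
    return ModificationSite(protein_accession=acc, position=pos,
                            mass_shift=mass, label=label, mod_class=cls,
                            residue=residue, spectral_count=count)


def random_sites(rng, n, n_labels=6, n_proteins=3, max_pos=50):
    labels = [(f"mod{i}", float(10 * i + 5)) for i in range(n_labels)]
    classes = ["Post-translational", "Artefact", "Chemical derivative"]
    out = []
    for _ in range(n):
        label, mass = labels[rng.integers(n_labels)]
        out.append(site(
            acc=f"P{rng.integers(n_proteins)}",
            pos=int(rng.integers(1, max_pos + 1)),
            label=label, mass=mass,
            cls=classes[rng.integers(len(classes))],
            residue="ACDEFGHIKLMNPQRSTVWY"[rng.integers(20)],
        ))
    return out


class TestSiteCounts:
    def test_spectral_multiplicity_does_not_inflate(self):
        sites = [site(pos=10, count=3)]
        assert site_counts(sites) == {"Phospho": 1}

    def test_sites_on_different_proteins_both_count(self):
        sites = [site(acc="P1", pos=10), site(acc="P2", pos=10)]
        assert site_counts(sites) == {"Phospho": 2}

    def test_fixture_counts_recovered(self, fixture_dataset, unimod_table):
        from ptmkit.annotation import validate_sites
        from ptmkit.postprocess import apply_filters, compute_qvalues, extract_sites
        from ptmkit.unimod import label_sites
        spec, catalog, psms, truth = fixture_dataset
        filtered, report = apply_filters(compute_qvalues(psms))
        extracted = extract_sites(filtered, catalog.proteins, report)
        validated, _ = validate_sites(extracted, catalog)
        sites = label_sites(validated, unimod_table)
        assert site_counts(sites) == truth["site_counts"]
        assert class_distribution(sites) == truth["class_counts"]


class TestSharedSiteMatrix:
    def test_colocated_labels_share_a_site(self):
        sites = [site(pos=10, label="Phospho"),
                 site(pos=10, label="+103.0684", mass=103.0684,
                      cls="Ambiguous mass shift")]
        matrix = shared_site_matrix(sites)
        assert matrix.loc["Phospho", "+103.0684"] == 1
        assert matrix.loc["+103.0684", "Phospho"] == 1

    def test_disjoint_sites_share_nothing(self):
        sites = [site(pos=10, label="Phospho"),
                 site(pos=11, label="Oxidation", mass=15.9949)]
        matrix = shared_site_matrix(sites)
        assert matrix.loc["Phospho", "Oxidation"] == 0

    def test_matches_brute_force_oracle_and_diagonal(self):
        rng = np.random.default_rng(11)
        sites = random_sites(rng, 200)
        matrix = shared_site_matrix(sites)
        labels = list(matrix.index)
        # O(n^2) oracle over distinct (site, label) incidences
        incidence = {}
        for s in sites:
            incidence.setdefault(s.label, set()).add(
                (s.protein_accession, s.position))
        for a, b in itertools.product(labels, repeat=2):
            expected = len(incidence[a] & incidence[b])
            assert matrix.loc[a, b] == expected
        counts = site_counts(sites)
        for label in labels:
            assert matrix.loc[label, label] == counts[label]

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        sites = random_sites(rng, 80)
        shuffled = list(sites)
        rng.shuffle(shuffled)
        assert shared_site_matrix(sites).equals(shared_site_matrix(shuffled))


class TestClassDistribution:
    def test_counts_by_class(self):
        sites = [site(pos=1), site(pos=2),
                 site(pos=3, label="Oxidation", mass=15.9949, cls="Artefact")]
        assert class_distribution(sites) == {
            "Post-translational": 2, "Artefact": 1}

    def test_sums_to_distinct_events(self):
        rng = np.random.default_rng(3)
        sites = random_sites(rng, 150)
        distinct = {(s.protein_accession, s.position, s.label) for s in sites}
        assert sum(class_distribution(sites).values()) == len(distinct)


class TestModificationAxis:
    def test_sort_by_mass_shift(self):
        types = [ModificationType("c", 79.97), ModificationType("a", 15.99),
                 ModificationType("b", 57.02)]
        assert modification_axis(types, "mass_shift") == ["a", "b", "c"]

    def test_sort_by_count_descending_with_lexicographic_ties(self):
        types = [ModificationType("b", 1.0, count=5),
                 ModificationType("a", 2.0, count=5),
                 ModificationType("c", 3.0, count=9)]
        assert modification_axis(types, "count") == ["c", "a", "b"]

    def test_unknown_sort_key(self):
        with pytest.raises(UsageError):
            modification_axis([], "alphabetical")

    def test_permutation_invariant(self):
        rng = np.random.default_rng(2)
        types = [ModificationType(f"m{i}", float(rng.uniform(0, 100)),
                                  count=int(rng.integers(1, 5)))
                 for i in range(30)]
        for key in ("mass_shift", "count"):
            expected = modification_axis(types, key)
            for _ in range(3):
                rng.shuffle(types)
                assert modification_axis(types, key) == expected


class TestProteinLevel:
    protein = ProteinEntry("P1", "MSTYACDEFGHIKLMNPQRW")

    def test_single_site_single_cell(self):
        matrix = presence_absence(self.protein, [site(pos=7)])
        assert matrix.to_numpy().sum() == 1
        assert bool(matrix.loc["Phospho", 7])

    def test_rows_sorted_by_mass_with_lexicographic_ties(self):
        sites = [site(pos=2, label="Zeta", mass=50.0),
                 site(pos=3, label="Alpha", mass=50.0),
                 site(pos=4, label="Oxidation", mass=15.99)]
        matrix = presence_absence(self.protein, sites)
        assert list(matrix.index) == ["Oxidation", "Alpha", "Zeta"]

    def test_column_sums_equal_per_position_totals(self):
        rng = np.random.default_rng(9)
        sites = [s for s in random_sites(rng, 120, max_pos=20)
                 if s.protein_accession == "P1"]
        for s in sites:
            s.protein_accession = "P1"
        matrix = presence_absence(self.protein, sites)
        totals = per_position_counts(self.protein, sites).sum(axis=1)
        assert (matrix.sum(axis=0).to_numpy() == totals.to_numpy()).all()

    def test_position_count_includes_each_distinct_label(self):
        sites = [site(pos=5), site(pos=5, label="Oxidation", mass=15.99,
                                   cls="Artefact")]
        counts = per_position_counts(self.protein, sites)
        assert counts.loc[5].sum() == 2
        assert counts.loc[6].sum() == 0


class TestAAHeatmap:
    def test_single_modification_row_is_one(self):
        heatmap = aa_mod_heatmap([site(pos=2, residue="S")])
        assert heatmap.normalized.loc["S", "Phospho"] == 1.0
        assert heatmap.normalized.loc["S"].sum() == 1.0

    def test_proportions_within_amino_acid(self):
        sites = (
            [site(pos=i, residue="M", label="Oxidation", mass=15.99,
                  cls="Artefact") for i in (1, 2, 3)]
            + [site(pos=4, residue="M", label="Dioxidation", mass=31.99,
                    cls="Artefact")]
        )
        heatmap = aa_mod_heatmap(sites)
        assert heatmap.normalized.loc["M", "Oxidation"] == pytest.approx(0.75)
        assert heatmap.normalized.loc["M", "Dioxidation"] == pytest.approx(0.25)

    def test_row_sums_are_zero_or_one(self):
        rng = np.random.default_rng(21)
        heatmap = aa_mod_heatmap(random_sites(rng, 300))
        sums = heatmap.normalized.sum(axis=1).to_numpy()
        assert all(abs(s) < 1e-12 or abs(s - 1.0) < 1e-12 for s in sums)

    def test_raw_counts_kept_alongside(self):
        heatmap = aa_mod_heatmap([site(pos=1, residue="S"),
                                  site(pos=2, residue="S")])
        assert heatmap.raw.loc["S", "Phospho"] == 2


class TestSampleSummary:
    def test_summary_consistency_invariants(self):
        rng = np.random.default_rng(13)
        sites = random_sites(rng, 150)
        summary = build_sample_summary(sites)
        # diagonal == site counts; symmetric; class totals == labeled events
        assert (summary.shared.to_numpy() == summary.shared.to_numpy().T).all()
        for t in summary.types:
            assert summary.shared.loc[t.label, t.label] == summary.site_counts[t.label]
        distinct = {(s.protein_accession, s.position, s.label) for s in sites}
        assert sum(summary.class_counts.values()) == len(distinct)

    def test_round_trips_through_dict(self):
        rng = np.random.default_rng(17)
        summary = build_sample_summary(random_sites(rng, 60))
        from ptmkit.summaries import SampleSummary
        assert SampleSummary.from_dict(summary.to_dict()) == summary
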