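"""Parsing of site-level CSV and the three PSM table dialects."""

import pytest

from ptmkit import fixtures
from ptmkit.errors import DialectAmbiguityError, FormatError, RowError, UsageError
from ptmkit.ingest import (
    detect_dialect,
    read_generic_csv,
    read_psm_table,
    write_normalized_psm_table,
)
from ptmkit.records import Modification, PSMRecord


def write(tmp_path, name, text):
    path = tmp_path / name
    path.write_text(text, encoding="utf-8")
    return path


class TestGenericCsv:
    def test_rows_parsed_in_file_order(self, tmp_path):
        path = write(tmp_path, "sites.csv",
                     "uniprot_id,position,modification_unimod_name\n"
                     "P0A6F5,80,Phospho\nP0A6F5,506,Phospho\nP0A6F5,506,Oxidation\n")
        records = read_generic_csv(path)
        assert [(r.protein_accession, r.position, r.mod_name) for r in records] == [
            ("P0A6F5", 80, "Phospho"),
            ("P0A6F5", 506, "Phospho"),
            ("P0A6F5", 506, "Oxidation"),
        ]

    def test_header_only_yields_empty_list(self, tmp_path):
        path = write(tmp_path, "sites.csv",
                     "uniprot_id,position,modification_unimod_name\n")
        assert read_generic_csv(path) == []

    def test_missing_position_column_names_it(self, tmp_path):
        path = write(tmp_path, "sites.csv",
                     "uniprot_id,modification_unimod_name\nP1,Phospho\n")
        with pytest.raises(FormatError, match="position"):
            read_generic_csv(path)

    def test_non_integer_position_reports_line_number(self, tmp_path):
        path = write(tmp_path, "sites.csv",
                     "uniprot_id,position,modification_unimod_name\n"
                     "P1,12,Phospho\nP1,twelve,Phospho\n")
        with pytest.raises(RowError, match="line 3"):
            read_generic_csv(path)

    def test_optional_mass_shift_column(self, tmp_path):
        path = write(tmp_path, "sites.csv",
                     "uniprot_id,position,modification_unimod_name,mass_shift\n"
                     "P1,5,Phospho,79.966331\n")
        assert read_generic_csv(path)[0].mass_shift == pytest.approx(79.966331)


class TestNormalizedDialect:
    def test_single_row_identity_mapping(self, tmp_path):
        path = write(
            tmp_path, "psms.tsv",
            "spectrum_id\tpeptide\tproteins\tscore\tq_value\tis_decoy\tmodifications\n"
            "s1\tPEPTIDEK\tP1\t42.0\t\tfalse\t4:79.9663:Phospho:1\n",
        )
        (psm,) = read_psm_table(path, "normalized")
        assert psm.peptide == "PEPTIDEK"
        assert psm.modifications == (
            Modification(peptide_position=4, mass_shift=79.9663,
                         name="Phospho", n_localizations=1),
        )
        assert not psm.is_decoy and psm.q_value is None

    def test_decoy_prefix_rule(self, tmp_path):
        path = write(
            tmp_path, "psms.tsv",
            "spectrum_id\tpeptide\tproteins\tscore\tq_value\tis_decoy\tmodifications\n"
            "s1\tPEPTIDEK\trev_P12345\t1.0\t\tfalse\t\n",
        )
        # the accession prefix rule lives in the engine dialects; the
        # normalized dialect trusts its explicit column
        (psm,) = read_psm_table(path, "normalized")
        assert psm.protein_accessions == ("rev_P12345",)
        assert psm.is_decoy is False

    def test_round_trip_equals_generator_truth(self, tmp_path, fixture_dataset):
        _spec, _catalog, psms, _truth = fixture_dataset
        path = tmp_path / "psms.tsv"
        write_normalized_psm_table(psms, path)
        assert read_psm_table(path, "normalized") == psms

    def test_unknown_dialect_is_usage_error(self, tmp_path):
        path = write(tmp_path, "x.tsv", "a\tb\n")
        with pytest.raises(UsageError, match="maxquant"):
            read_psm_table(path, "maxquant")

    def test_bad_modification_string_reports_line(self, tmp_path):
        path = write(
            tmp_path, "psms.tsv",
            "spectrum_id\tpeptide\tproteins\tscore\tq_value\tis_decoy\tmodifications\n"
            "s1\tPEPTIDEK\tP1\t1.0\t\tfalse\tgarbage\n",
        )
        with pytest.raises(RowError, match="line 2"):
            read_psm_table(path, "normalized")


MSFRAGGER_HEADER = (
    "Spectrum\tPeptide\tProtein\tMapped Proteins\tHyperscore\tDelta Mass\t"
    "Assigned Modifications\tObserved Modifications\tMSFragger Localization\n"
)


class TestMsfraggerDialect:
    def test_assigned_and_open_modifications(self, tmp_path):
        path = write(
            tmp_path, "psm.tsv",
            MSFRAGGER_HEADER
            + "sp1\tPEPSIDEK\tP1\t\t31.5\t79.9663\t"
              "4S(79.9663), N-term(42.0106)\tPhospho\tPEPsIDEK\n",
        )
        (psm,) = read_psm_table(path, "msfragger")
        positions = [(m.peptide_position, m.mass_shift) for m in psm.modifications]
        assert (4, 79.9663) in positions
        assert (0, 42.0106) in positions  # N-term encoded as position 0
        open_mod = psm.modifications[-1]
        assert open_mod.name == "Phospho" and open_mod.n_localizations == 1

    def test_decoy_prefix_sets_flag(self, tmp_path):
        path = write(tmp_path, "psm.tsv",
                     MSFRAGGER_HEADER + "sp1\tPEPTIDEK\trev_P1\t\t10\t\t\t\t\n")
        assert read_psm_table(path, "msfragger")[0].is_decoy

    def test_combination_annotation_counted(self, tmp_path):
        path = write(
            tmp_path, "psm.tsv",
            MSFRAGGER_HEADER
            + "sp1\tPEPSIDEK\tP1\t\t20\t95.9612\t\tPhospho + Oxidation\tPEPsIDEK\n",
        )
        (psm,) = read_psm_table(path, "msfragger")
        assert psm.modifications[-1].n_components == 2

    def test_multiple_localizations_counted(self, tmp_path):
        path = write(
            tmp_path, "psm.tsv",
            MSFRAGGER_HEADER
            + "sp1\tPEPSSDEK\tP1\t\t20\t79.9663\t\tPhospho\tPEPssDEK\n",
        )
        (psm,) = read_psm_table(path, "msfragger")
        assert psm.modifications[-1].n_localizations == 2


class TestSageDialect:
    SAGE_HEADER = ("psm_id\tpeptide\tproteins\tfilename\tscannr\trank\tlabel\t"
                   "sage_discriminant_score\tspectrum_q\n")

    def test_proforma_bracket_modifications(self, tmp_path):
        path = write(
            tmp_path, "results.sage.tsv",
            self.SAGE_HEADER
            + "1\tPEPT[+79.9663]IDEK\tP1\trun.mzML\t17\t1\t1\t0.93\t0.002\n",
        )
        (psm,) = read_psm_table(path, "sage")
        assert psm.peptide == "PEPTIDEK"
        assert psm.modifications[0].peptide_position == 4
        assert psm.modifications[0].mass_shift == pytest.approx(79.9663)
        assert psm.q_value == pytest.approx(0.002)

    def test_label_minus_one_is_decoy(self, tmp_path):
        path = write(
            tmp_path, "results.sage.tsv",
            self.SAGE_HEADER + "1\tPEPTIDEK\trev_P1\trun.mzML\t2\t1\t-1\t0.1\t0.9\n",
        )
        assert read_psm_table(path, "sage")[0].is_decoy


class TestDetectDialect:
    @pytest.mark.parametrize(
        "header,expected",
        [
            (MSFRAGGER_HEADER, "msfragger"),
            ("psm_id\tpeptide\tproteins\tfilename\tscannr\trank\tlabel\t"
             "sage_discriminant_score\tspectrum_q\n", "sage"),
            ("spectrum_id\tpeptide\tproteins\tscore\tq_value\tis_decoy\t"
             "modifications\n", "normalized"),
            ("uniprot_id,position,modification_unimod_name\n", "generic_csv"),
        ],
    )
    def test_each_dialect_recognized(self, tmp_path, header, expected):
        path = write(tmp_path, "input.txt", header)
        assert detect_dialect(path) == expected

    def test_unknown_header_is_ambiguity_error(self, tmp_path):
        path = write(tmp_path, "input.txt", "foo\tbar\n")
        with pytest.raises(DialectAmbiguityError):
            detect_dialect(path)

    def test_header_matching_two_dialects_lists_candidates(self, tmp_path):
        header = (MSFRAGGER_HEADER.rstrip("\n") +
                  "\tspectrum_id\tpeptide\tproteins\tscore\tq_value\tis_decoy\t"
                  "modifications\n")
        path = write(tmp_path, "input.txt", header)
        with pytest.raises(DialectAmbiguityError) as excinfo:
            detect_dialect(path)
        assert set(excinfo.value.candidates) == {"msfragger", "normalized"}
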