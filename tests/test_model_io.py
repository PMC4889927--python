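"""Data model invariants and file-format round trips."""

import pytest

from dnaends import (
    Band,
    ExperimentDesign,
    IdentificationRecord,
    Phase,
    ProteinSeq,
    SampleKey,
)
from dnaends.io import (
    dump_design,
    load_design,
    load_identifications,
    read_fasta,
    read_identification_table,
    read_identifications,
    read_table,
    write_identification_table,
    write_table,
)
from dnaends.model import merge_records, parse_band


class TestProteinSeq:
    def test_minimal_record(self):
        p = ProteinSeq("P1", "MKR", "desc")
        assert (p.accession, p.sequence, p.description) == ("P1", "MKR", "desc")

    @pytest.mark.parametrize("bad", ["", "MKB", "MKX", "mkr"])
    def test_rejects_non_canonical_or_empty(self, bad):
        with pytest.raises(ValueError):
            ProteinSeq("P1", bad)

    def test_error_names_residue_and_position(self):
        with pytest.raises(ValueError, match=r"'B' at position 3"):
            ProteinSeq("P1", "MKB")


class TestFasta:
    def test_parse_and_order(self, tmp_path):
        path = tmp_path / "db.fasta"
        path.write_text(">P2 beta\nMKR\nAPK\n>P1 alpha\nMK\n")
        proteins = read_fasta(path)
        assert [p.accession for p in proteins] == ["P2", "P1"]
        assert proteins[0].sequence == "MKRAPK"
        assert proteins[0].description == "beta"

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.fasta"
        path.write_text("")
        assert read_fasta(path) == []

    def test_duplicate_accession_named(self, tmp_path):
        path = tmp_path / "dup.fasta"
        path.write_text(">P1\nMK\n>P1\nMR\n")
        with pytest.raises(ValueError, match="P1"):
            read_fasta(path)


class TestSampleKey:
    def test_coerces_labels(self):
        key = SampleKey(1, "ends", "720")
        assert key.phase is Phase.ENDS and key.band is Band.B720

    @pytest.mark.parametrize("label,band", [
        ("b480", Band.B480), ("240kDa", Band.B240), ("common", Band.COMMON),
    ])
    def test_band_label_dialects(self, label, band):
        assert parse_band(label) is band

    def test_unknown_band_is_an_error(self):
        with pytest.raises(ValueError, match="unknown band"):
            SampleKey(1, "ends", "360")

    def test_nonpositive_experiment_rejected(self):
        with pytest.raises(ValueError):
            SampleKey(0, "ends", "720")


class TestIdentifications:
    KEY = SampleKey(1, Phase.ENDS, Band.B720)

    def test_peptide_list_deduplicated(self, tmp_path):
        path = tmp_path / "ids.tsv"
        path.write_text("accession\tpeptides\nP1\tAPEPTIDEK;MK;APEPTIDEK\n")
        (record,) = read_identifications(path, self.KEY)
        assert record.n_observed == 2
        assert record.peptides == frozenset({"APEPTIDEK", "MK"})

    def test_zero_count_rejected(self, tmp_path):
        path = tmp_path / "ids.tsv"
        path.write_text("accession\tn_peptides\nP1\t0\n")
        with pytest.raises(ValueError, match="line 2"):
            read_identifications(path, self.KEY)

    def test_malformed_count_reports_line(self, tmp_path):
        path = tmp_path / "ids.tsv"
        path.write_text("accession\tn_peptides\nP1\t3\nP2\tmany\n")
        with pytest.raises(ValueError, match="line 3"):
            read_identifications(path, self.KEY)

    def test_missing_column_named(self, tmp_path):
        path = tmp_path / "ids.tsv"
        path.write_text("protein\tn_peptides\nP1\t3\n")
        with pytest.raises(ValueError, match="accession"):
            read_identifications(path, self.KEY)

    def test_repeated_accession_rows_merge_to_union(self, tmp_path):
        # union of {AK, MK} and {MK, RPEPTIDEK} computed by hand
        path = tmp_path / "ids.tsv"
        path.write_text("accession\tpeptides\nP1\tAK;MK\nP1\tMK;RPEPTIDEK\n")
        (record,) = read_identifications(path, self.KEY)
        assert record.peptides == frozenset({"AK", "MK", "RPEPTIDEK"})

    def test_record_requires_some_evidence(self):
        with pytest.raises(ValueError):
            IdentificationRecord(self.KEY, "P1", peptides=frozenset())

    def test_long_table_and_per_sample_layouts_agree(self, tmp_path):
        long = tmp_path / "long.tsv"
        long.write_text(
            "experiment\tphase\tband\taccession\tn_peptides\n"
            "1\tends\t720\tP1\t4\n"
            "2\tcontrol\tcommon\tP2\t3\n"
        )
        per_sample = tmp_path / "per_sample"
        per_sample.mkdir()
        (per_sample / "1_ends_720.tsv").write_text("accession\tn_peptides\nP1\t4\n")
        (per_sample / "2_control_common.tsv").write_text("accession\tn_peptides\nP2\t3\n")
        assert sorted(
            (r.key, r.accession, r.n_observed) for r in load_identifications(long)
        ) == sorted(
            (r.key, r.accession, r.n_observed)
            for r in load_identifications(per_sample)
        )

    def test_merge_counts_sum(self):
        records = [
            IdentificationRecord(self.KEY, "P1", n_peptides=2),
            IdentificationRecord(self.KEY, "P1", n_peptides=3),
        ]
        (merged,) = merge_records(records)
        assert merged.n_observed == 5


class TestWriteTable:
    def test_identification_table_round_trip(self, tmp_path):
        records = [
            IdentificationRecord(SampleKey(2, "control", "480"), "P2", n_peptides=3),
            IdentificationRecord(SampleKey(1, "ends", "720"), "P1", n_peptides=4),
        ]
        path = tmp_path / "ids.tsv"
        write_identification_table(records, path)
        back = read_identification_table(path)
        assert sorted((r.key, r.accession, r.n_observed) for r in back) == sorted(
            (r.key, r.accession, r.n_observed) for r in records
        )

    def test_rows_sorted_and_byte_deterministic(self, tmp_path):
        rows = [
            {"accession": "P2", "band": "480", "value": 1.5},
            {"accession": "P1", "band": "720", "value": 0.25},
            {"accession": "P1", "band": "240", "value": 2.0},
        ]
        a, b = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_table(rows, a)
        write_table(list(reversed(rows)), b)
        assert a.read_bytes() == b.read_bytes()
        frame = read_table(a)
        assert list(frame["accession"]) == ["P1", "P1", "P2"]

    def test_empty_result_is_header_only_when_columns_known(self, tmp_path):
        path = tmp_path / "empty.tsv"
        write_table([], path, columns=["accession", "value"])
        assert path.read_text() == "accession\tvalue\n"


class TestDesign:
    def test_defaults_match_study_conditions(self, design):
        assert design.n_ends_experiments == 6
        assert design.n_control_experiments == 5
        assert design.min_peptides == 3
        assert design.min_experiments_report == 3
        assert design.min_experiments_venn == 4
        assert design.specificity_cutoff == 0.9

    def test_yaml_round_trip(self, tmp_path):
        design = ExperimentDesign(min_experiments_venn=5, specificity_cutoff=0.8)
        path = tmp_path / "design.yaml"
        dump_design(design, path)
        assert load_design(path) == design

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"min_experiments_venn": 7},
            {"specificity_cutoff": 1.5},
            {"n_control_experiments": 9},
            {"min_peptides": 0},
        ],
    )
    def test_invalid_designs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ExperimentDesign(**kwargs)
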