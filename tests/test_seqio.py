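import numpy as np
import pytest

from pretata.seqio import (
    FeatureTable,
    ParseError,
    ProteinRecord,
    SSRecord,
    ValidationError,
    parse_psipred_horiz,
    parse_psipred_ss2,
    read_fasta,
    read_feature_table,
    write_fasta,
    write_feature_table,
)


class TestFasta:
    def test_amino_parse_preserves_order_and_uppercases(self, tmp_path):
        p = tmp_path / "in.fasta"
        p.write_text(">p1\nmkv\n>p2\nAC\nDE\n")
        recs = read_fasta(p, alphabet="amino")
        assert [(r.id, r.seq) for r in recs] == [("p1", "MKV"), ("p2", "ACDE")]

    def test_ss_alphabet(self, tmp_path):
        p = tmp_path / "ss.fasta"
        p.write_text(">s1\nHHEC\n")
        (rec,) = read_fasta(p, alphabet="ss")
        assert isinstance(rec, SSRecord) and rec.ss == "HHEC"

    def test_invalid_amino_character_names_record_and_letter(self, tmp_path):
        p = tmp_path / "bad.fasta"
        p.write_text(">p1\nMKB\n")
        with pytest.raises(ValidationError, match="p1.*B"):
            read_fasta(p, alphabet="amino")

    def test_non_fasta_file_is_a_parse_error(self, tmp_path):
        p = tmp_path / "notfasta.txt"
        p.write_text("MKV\nACDE\n")
        with pytest.raises(ParseError, match=":1"):
            read_fasta(p)

    def test_roundtrip(self, tmp_path):
        recs = [ProteinRecord("a", "MKV" * 30), ProteinRecord("b", "AC")]
        p = tmp_path / "out.fasta"
        write_fasta(recs, p)
        assert read_fasta(p) == recs


class TestRecordValidation:
    @pytest.mark.parametrize("cls,field,bad", [
        (ProteinRecord, "seq", "MKX"),
        (ProteinRecord, "seq", ""),
        (SSRecord, "ss", "HHG"),
        (SSRecord, "ss", ""),
    ])
    def test_invalid_records_rejected(self, cls, field, bad):
        with pytest.raises(ValidationError):
            cls("id1", bad)


class TestPsipred:
    SS2 = (
        "# PSIPRED VFORMAT (PSIPRED V4.0)\n"
        "\n"
        "   1 M C   0.997  0.001  0.001\n"
        "   2 K H   0.100  0.850  0.050\n"
        "   3 V H   0.050  0.900  0.050\n"
    )

    def test_ss2_concatenates_states(self, tmp_path):
        p = tmp_path / "x.ss2"
        p.write_text(self.SS2)
        rec = parse_psipred_ss2(p, id="q")
        assert rec.id == "q" and rec.ss == "CHH"

    def test_ss2_empty_data_is_parse_error(self, tmp_path):
        p = tmp_path / "x.ss2"
        p.write_text("# PSIPRED VFORMAT\n\n")
        with pytest.raises(ParseError, match="no data"):
            parse_psipred_ss2(p)

    def test_ss2_unknown_state_names_row(self, tmp_path):
        p = tmp_path / "x.ss2"
        p.write_text("# header\n\n   1 M G   0.9 0.05 0.05\n")
        with pytest.raises(ParseError, match=":3.*'G'"):
            parse_psipred_ss2(p)

    def test_ss2_non_consecutive_index(self, tmp_path):
        p = tmp_path / "x.ss2"
        p.write_text("# header\n\n   1 M C 0.9 0.05 0.05\n   3 K H 0.1 0.8 0.1\n")
        with pytest.raises(ParseError, match="non-consecutive"):
            parse_psipred_ss2(p)

    def test_horiz_concatenates_pred_lines(self, tmp_path):
        p = tmp_path / "x.horiz"
        p.write_text(
            "Conf: 977\nPred: CHH\n  AA: MKV\n\nConf: 99\nPred: EC\n  AA: LA\n"
        )
        assert parse_psipred_horiz(p).ss == "CHHEC"


def make_table(n_rows=2, labeled=True):
    return FeatureTable(
        row_ids=[f"r{i}" for i in range(n_rows)],
        feature_names=["f a", "f2"],
        values=np.arange(2.0 * n_rows).reshape(n_rows, 2) / 3.0,
        labels=(["positive", "negative"] * n_rows)[:n_rows] if labeled else None,
    )


class TestFeatureTableIO:
    @pytest.mark.parametrize("fmt", ["csv", "tsv", "arff"])
    @pytest.mark.parametrize("labeled", [True, False])
    def test_roundtrip(self, tmp_path, fmt, labeled):
        t = make_table(labeled=labeled)
        p = tmp_path / f"t.{fmt}"
        write_feature_table(t, p, format=fmt)
        back = read_feature_table(p, format=fmt)
        assert back.equals(t)

    @pytest.mark.parametrize("fmt", ["csv", "arff"])
    def test_empty_table_roundtrip(self, tmp_path, fmt):
        t = FeatureTable(row_ids=[], feature_names=["f1", "f2"],
                         values=np.empty((0, 2)), labels=None)
        p = tmp_path / f"t.{fmt}"
        write_feature_table(t, p, format=fmt)
        back = read_feature_table(p, format=fmt)
        assert back.n_rows == 0 and back.feature_names == ["f1", "f2"]

    def test_unlabeled_arff_has_no_class_attribute(self, tmp_path):
        p = tmp_path / "t.arff"
        write_feature_table(make_table(labeled=False), p)
        assert "class" not in p.read_text()

    def test_roundtrip_12_significant_digits(self, tmp_path):
        rng = np.random.default_rng(0)
        t = FeatureTable(
            row_ids=["a", "b", "c"],
            feature_names=[f"f{j}" for j in range(4)],
            values=rng.random((3, 4)) * 1e3,
            labels=["positive", "negative", "positive"],
        )
        p = tmp_path / "t.csv"
        write_feature_table(t, p)
        back = read_feature_table(p)
        assert np.allclose(back.values, t.values, rtol=1e-11, atol=0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            FeatureTable(row_ids=["a"], feature_names=["f"],
                         values=np.zeros((2, 1)))
        with pytest.raises(ValidationError):
            FeatureTable(row_ids=["a", "b"], feature_names=["f"],
                         values=np.zeros((2, 1)), labels=["positive"])
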