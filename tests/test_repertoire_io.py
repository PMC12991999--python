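"""Repertoire construction and table I/O: filters, merging, round trips."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import tcrgvhd as t
from tcrgvhd.repertoire import is_valid_cdr3, normalize_gene


def _write(path, header, rows):
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


AIRR_HEADER = ["junction_aa", "v_call", "j_call", "duplicate_count", "productive"]


class TestValidation:
    @pytest.mark.parametrize(
        "seq,ok",
        [
            ("CASSF", True),
            ("CASS*F", False),  # stop codon
            ("CASS_F", False),
            ("cassf", False),  # lowercase rejected
            ("", False),
            ("CABSSF", False),  # B not an amino acid
        ],
    )
    def test_cdr3_alphabet(self, seq, ok):
        assert is_valid_cdr3(seq) is ok

    def test_allele_suffix_stripped(self):
        assert normalize_gene("TRBV15*01") == "TRBV15"
        assert normalize_gene("TRBV15") == "TRBV15"

    def test_duplicate_keys_merged_by_count_sum(self):
        df = pd.DataFrame(
            {
                "cdr3_aa": ["CASSF", "CASSF", "CARDF"],
                "v_gene": ["TRBV1", "TRBV1", "TRBV2"],
                "j_gene": ["TRBJ1-1"] * 3,
                "count": [10, 5, 1],
            }
        )
        rep = t.Repertoire(sample_id="s", clonotypes=df)
        assert rep.richness == 2
        assert rep.total_reads == 16


class TestAirrReader:
    def test_duplicate_merge_and_filtering(self, tmp_path):
        p = tmp_path / "s1.tsv"
        _write(
            p,
            AIRR_HEADER,
            [
                ("CASSF", "TRBV1*01", "TRBJ1-1*01", 10, "T"),
                ("CASSF", "TRBV1", "TRBJ1-1", 5, "T"),
                ("CARDF", "TRBV2", "TRBJ1-2", 1, "T"),
                ("CANNF", "TRBV2", "TRBJ1-2", 7, "F"),  # unproductive
                ("CASS*F", "TRBV3", "TRBJ1-3", 2, "T"),  # stop codon -> dropped
            ],
        )
        rep = t.read_airr_table(p)
        assert rep.richness == 2
        assert dict(zip(rep.clonotypes["cdr3_aa"], rep.clonotypes["count"])) == {
            "CASSF": 15,
            "CARDF": 1,
        }
        assert rep.chain == "TRB"

    def test_missing_column_is_named(self, tmp_path):
        p = tmp_path / "bad.tsv"
        _write(p, ["junction_aa", "v_call", "j_call", "duplicate_count"], [])
        with pytest.raises(t.RepertoireFormatError, match="productive"):
            t.read_airr_table(p)

    def test_zero_productive_rows_is_an_error(self, tmp_path):
        p = tmp_path / "empty.tsv"
        _write(p, AIRR_HEADER, [("CASSF", "TRBV1", "TRBJ1-1", 3, "F")])
        with pytest.raises(t.EmptyRepertoireError):
            t.read_airr_table(p)

    def test_consensus_count_fallback(self, tmp_path):
        p = tmp_path / "cc.tsv"
        _write(
            p,
            ["junction_aa", "v_call", "j_call", "consensus_count", "productive"],
            [("CASSF", "TRBV1", "TRBJ1-1", 4, "T")],
        )
        assert t.read_airr_table(p).total_reads == 4

    def test_chain_filter_splits_loci(self, tmp_path):
        p = tmp_path / "mixed.tsv"
        _write(
            p,
            AIRR_HEADER,
            [
                ("CASSF", "TRBV1", "TRBJ1-1", 3, "T"),
                ("CAVRF", "TRAV2", "TRAJ4", 2, "T"),
            ],
        )
        with pytest.raises(t.RepertoireFormatError, match="mixed chains"):
            t.read_airr_table(p)
        tra = t.read_airr_table(p, chain_filter="TRA")
        assert tra.chain == "TRA" and tra.total_reads == 2


class TestSimpleDialect:
    def test_basic_read(self, tmp_path):
        p = tmp_path / "s.tsv"
        _write(p, t.io.SIMPLE_COLUMNS, [("CASSLF", "TRBV15", "TRBJ2-1", 100, "TRB")])
        rep = t.read_simple_table(p)
        assert rep.total_reads == 100 and rep.richness == 1

    def test_negative_count_rejected_with_line_number(self, tmp_path):
        p = tmp_path / "neg.tsv"
        _write(
            p,
            t.io.SIMPLE_COLUMNS,
            [("CASSLF", "TRBV15", "TRBJ2-1", -5, "TRB")],
        )
        with pytest.raises(t.RepertoireFormatError, match="line 2"):
            t.read_simple_table(p)

    def test_non_integer_count_rejected(self, tmp_path):
        p = tmp_path / "frac.tsv"
        _write(
            p,
            t.io.SIMPLE_COLUMNS,
            [("CASSLF", "TRBV15", "TRBJ2-1", 3, "TRB"),
             ("CARDLF", "TRBV1", "TRBJ2-1", "x", "TRB")],
        )
        with pytest.raises(t.RepertoireFormatError, match="line 3"):
            t.read_simple_table(p)

    def test_deterministic_parse(self, tmp_path, small_repertoire):
        p = tmp_path / "r.tsv"
        t.write_repertoire(small_repertoire, p)
        a, b = t.read_simple_table(p), t.read_simple_table(p)
        assert t.repertoire.equal_repertoires(a, b)

    def test_row_order_does_not_matter(self, tmp_path, small_repertoire):
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        t.write_repertoire(small_repertoire, p1)
        lines = p1.read_text().splitlines()
        p2.write_text("\n".join([lines[0]] + lines[:0:-1]) + "\n")
        assert t.repertoire.equal_repertoires(
            t.read_simple_table(p1, sample_id="x"),
            t.read_simple_table(p2, sample_id="x"),
        )


class TestRoundTrip:
    def test_round_trip_small(self, tmp_path, small_repertoire):
        p = tmp_path / "rt.tsv"
        t.write_repertoire(small_repertoire, p)
        back = t.read_simple_table(p, sample_id=small_repertoire.sample_id)
        assert t.repertoire.equal_repertoires(small_repertoire, back)

    def test_empty_repertoire_refused(self, tmp_path):
        rep = t.Repertoire.from_counts({"CASSF": 1}).with_counts(np.array([0]))
        with pytest.raises(t.EmptyRepertoireError):
            t.write_repertoire(rep, tmp_path / "e.tsv")

    @given(seed=st.integers(0, 2**20))
    def test_round_trip_random(self, seed, tmp_path_factory):
        rng = np.random.default_rng(seed)
        # inline generator (hypothesis cannot take function-scoped fixtures)
        n = int(rng.integers(1, 60))
        letters = list("ACDEFGHIKLMNPQRSTVWY")
        seen = set()
        while len(seen) < n:
            L = int(rng.integers(8, 18))
            seen.add("C" + "".join(rng.choice(letters, L - 2)) + "F")
        df = pd.DataFrame(
            {
                "cdr3_aa": sorted(seen),
                "v_gene": [f"TRBV{int(g)}" for g in rng.integers(1, 10, size=n)],
                "j_gene": [f"TRBJ1-{int(g)}" for g in rng.integers(1, 7, size=n)],
                "count": rng.integers(1, 1000, size=n),
            }
        )
        rep = t.Repertoire(sample_id="rt", clonotypes=df)
        p = tmp_path_factory.mktemp("rt") / "r.tsv"
        t.write_repertoire(rep, p)
        assert t.repertoire.equal_repertoires(
            rep, t.read_simple_table(p, sample_id="rt")
        )


class TestAnnotations:
    def test_vdjdb_dialect_dedup(self, tmp_path):
        p = tmp_path / "vdjdb.tsv"
        _write(
            p,
            ["gene", "cdr3", "v.segm", "j.segm", "antigen.species"],
            [
                ("TRB", "CASSIRSSYEQYF", "TRBV19*01", "TRBJ2-7*01", "CMV"),
                ("TRB", "CASSIRSSYEQYF", "TRBV19*01", "TRBJ2-7*01", "CMV"),
                ("TRB", "CASSIRSSYEQYF", "TRBV19*01", "TRBJ2-7*01", "EBV"),
            ],
        )
        recs = t.read_annotation_table(p, dialect="vdjdb")
        assert len(recs) == 2
        assert {r.antigen_species for r in recs} == {"CMV", "EBV"}
        assert recs[0].v_gene == "TRBV19"

    def test_simple_dialect(self, tmp_path):
        p = tmp_path / "simple.tsv"
        _write(
            p,
            ["cdr3_aa", "antigen_species"],
            [("CASSF", "intestine"), ("CARDF", "blood"), ("CASQF", "bone marrow")],
        )
        assert len(t.read_annotation_table(p, dialect="simple")) == 3

    def test_unknown_dialect(self, tmp_path):
        p = tmp_path / "x.tsv"
        _write(p, ["cdr3_aa", "antigen_species"], [])
        with pytest.raises(t.ConfigError):
            t.read_annotation_table(p, dialect="mystery")

    def test_empty_file_warns_and_returns_empty(self, tmp_path, caplog):
        p = tmp_path / "empty.tsv"
        _write(p, ["cdr3_aa", "antigen_species"], [])
        with caplog.at_level("WARNING"):
            assert t.read_annotation_table(p, dialect="simple") == []
        assert any("empty" in r.message for r in caplog.records)
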