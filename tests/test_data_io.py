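"""Input parsing, validation and cohort assembly."""

import numpy as np
import pandas as pd
import pytest

from mirgi.data_io import (
    ExpressionMatrix,
    ParseError,
    SchemaError,
    ValidationError,
    assemble_cohort,
    normalize_mirna_id,
    normalize_sample_id,
    packaged_network_path,
    read_clinical,
    read_expression_matrix,
    read_maf_lite,
    read_network_edges,
    write_expression_matrix,
)


def write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestExpressionMatrix:
    def test_parses_shape_and_missing_cells(self, tmp_path):
        p = write(
            tmp_path,
            "expr.tsv",
            "mirna\tS1\tS2\tS3\tS4\n"
            "miR-21\t1.0\t2.0\tNA\t4.0\n"
            "miR-24\t0.5\t0.6\t0.7\t0.8\n"
            "let-7a\t-1\t0\t1\t2\n",
        )
        m = read_expression_matrix(p)
        assert m.shape == (3, 4)
        assert m.mirna_ids == ["mir-21", "mir-24", "let-7a"]
        assert np.isnan(m.values.loc["mir-21", "S3"])
        assert m.values.loc["let-7a", "S1"] == -1

    def test_duplicate_mirna_named_in_error(self, tmp_path):
        p = write(
            tmp_path,
            "dup.tsv",
            "mirna\tS1\tS2\tS3\tS4\nmiR-21\t1\t2\t3\t4\nmiR-21\t5\t6\t7\t8\n",
        )
        with pytest.raises(ValidationError, match="mir-21"):
            read_expression_matrix(p)

    def test_non_numeric_cell_located(self, tmp_path):
        p = write(tmp_path, "bad.tsv", "mirna\tS1\tS2\nmiR-21\t1\toops\n")
        with pytest.raises(ParseError, match="oops"):
            read_expression_matrix(p)

    def test_round_trip(self, tmp_path):
        values = pd.DataFrame(
            [[1.5, np.nan], [0.0, -2.25]], index=["mir-a", "mir-b"], columns=["S1", "S2"]
        )
        write_expression_matrix(ExpressionMatrix(values), tmp_path / "rt.tsv")
        back = read_expression_matrix(tmp_path / "rt.tsv")
        pd.testing.assert_frame_equal(back.values, values)


class TestIdentifierNormalization:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("TCGA-04-1331-01A-01T-0517-13", "TCGA-04-1331-01"),
            ("  tcga-04-1331  ", "TCGA-04-1331"),
            ("Sample_9", "SAMPLE_9"),
        ],
    )
    def test_sample_ids(self, raw, expected):
        assert normalize_sample_id(raw) == expected

    @pytest.mark.parametrize(
        "raw,expected",
        [("hsa-miR-505*", "mir-505*"), ("MIR-151", "mir-151"), ("let-7a*", "let-7a*")],
    )
    def test_mirna_ids(self, raw, expected):
        assert normalize_mirna_id(raw) == expected


MAF_HEADER = "Tumor_Sample_Barcode\tHugo_Symbol\tChromosome\tStart_Position\tVariant_Classification\n"


class TestMafLite:
    def test_parses_all_rows(self, tmp_path):
        p = write(
            tmp_path,
            "m.maf",
            MAF_HEADER
            + "S1\tTP53\t17\t7579472\tMissense_Mutation\n"
            + "S1\tBRCA1\t17\t41244000\tNonsense_Mutation\n"
            + "S2\tBRCA2\t13\t32911888\tSilent\n"
            + "S3\tPTEN\t10\t89692905\tFrame_Shift_Del\n",
        )
        maf = read_maf_lite(p)
        assert len(maf.records) == 4 and len(maf.rejects) == 0
        assert list(maf.records["position"]) == [7579472, 41244000, 32911888, 89692905]

    def test_bad_rows_routed_to_reject_report(self, tmp_path):
        p = write(
            tmp_path,
            "m.maf",
            MAF_HEADER + "S1\tTP53\t17\tx\tMissense_Mutation\n" + "S2\tBRCA1\t17\t5\tSilent\n",
        )
        maf = read_maf_lite(p)
        assert len(maf.records) == 1
        assert len(maf.rejects) == 1
        assert "position" in maf.rejects["reason"].iloc[0]

    def test_header_only_is_empty_not_error(self, tmp_path):
        maf = read_maf_lite(write(tmp_path, "m.maf", MAF_HEADER))
        assert len(maf.records) == 0 and len(maf.rejects) == 0

    def test_missing_column_lists_aliases(self, tmp_path):
        p = write(tmp_path, "m.maf", "sample\tgene\tchrom\tpos\nS1\tTP53\t17\t1\n")
        with pytest.raises(SchemaError, match="variant_classification"):
            read_maf_lite(p)

    def test_accepted_plus_rejected_equals_input(self, tmp_path):
        rng = np.random.default_rng(7)
        rows = []
        for i in range(60):
            pos = "x" if rng.random() < 0.3 else str(rng.integers(1, 10**6))
            rows.append(f"S{i % 5}\tG{i}\t1\t{pos}\tSilent")
        maf = read_maf_lite(write(tmp_path, "m.maf", MAF_HEADER + "\n".join(rows) + "\n"))
        assert len(maf.records) + len(maf.rejects) == 60


class TestClinical:
    TEXT = (
        "sample_id\tos_time\tos_event\tage\tstage\tgrade\tdebulking\tplatinum_sensitive\n"
        "S1\t4.7\t1\t61\tIII\tG3\tOPTIMAL\tsensitive\n"
        "S2\t3.2\t0\t55\tIV\tG2\tsuboptimal\tresistant\n"
        "S3\t1.1\t1\t70\tIII\tG3\tweird\tNA\n"
        "S4\t0.5\t1\t48\tII\tG3\toptimal\tsensitive\n"
        "S5\t6.0\t0\t66\tIII\tG2\tunknown\tresistant\n"
    )

    def test_parses_and_normalizes(self, tmp_path):
        clin = read_clinical(write(tmp_path, "c.tsv", self.TEXT))
        assert len(clin) == 5
        assert clin.loc[0, "debulking"] == "optimal"
        assert clin.loc[2, "debulking"] == "unknown"
        assert clin.attrs["n_unknown_category"] == 1
        assert clin.loc[0, "os_time"] == pytest.approx(4.7)
        assert bool(clin.loc[0, "platinum_sensitive"]) is True
        assert list(clin["figo_stage"]) == [3, 4, 3, 2, 3]

    def test_negative_survival_time_rejected(self, tmp_path):
        text = "sample_id\tos_time\tos_event\nS1\t-1\t1\n"
        with pytest.raises(ValidationError, match="negative"):
            read_clinical(write(tmp_path, "c.tsv", text))


class TestNetwork:
    def test_packaged_fixture_contains_documented_edges(self):
        edges, summary = read_network_edges(packaged_network_path())
        assert summary == {"n_edges": 142, "n_mirnas": 75, "n_genes": 55}
        pairs = set(zip(edges["mirna_id"], edges["target_gene"]))
        for pair in [
            ("mir-24", "H2AX"), ("mir-421", "ATM"), ("mir-146a", "BRCA1"),
            ("mir-151", "ARHGDIA"), ("mir-421", "RAD17"), ("mir-505*", "RAD17"),
            ("mir-324", "RAD17"), ("let-7a*", "RAD9A"), ("mir-320", "RAD9A"),
        ]:
            assert pair in pairs

    def test_duplicate_edges_removed(self, tmp_path):
        p = write(
            tmp_path, "n.tsv",
            "mirna\tgene\tpathway\nmir-1\tBRCA1\tHR\nmir-1\tBRCA1\tHR\nmir-2\tATM\tDDS\n",
        )
        edges, summary = read_network_edges(p)
        assert summary["n_edges"] == 2

    def test_pathway_outside_vocabulary_rejected(self, tmp_path):
        p = write(tmp_path, "n.tsv", "mirna\tgene\tpathway\nmir-1\tBRCA1\tXYZ\n")
        with pytest.raises(ValidationError, match="XYZ"):
            read_network_edges(p)


def _mini_inputs(expr_samples, mut_samples, clin_samples):
    expr = ExpressionMatrix(
        pd.DataFrame(
            np.arange(2 * len(expr_samples), dtype=float).reshape(2, -1),
            index=["mir-1", "mir-2"],
            columns=expr_samples,
        )
    )
    muts = pd.DataFrame(
        {
            "sample_id": mut_samples,
            "gene_symbol": "TP53",
            "chromosome": "17",
            "position": range(1, len(mut_samples) + 1),
            "alt_allele": "T",
            "variant_class": "missense",
        }
    )
    clin = pd.DataFrame({"sample_id": clin_samples, "os_time": 1.0, "os_event": True})
    return expr, muts, clin


class TestAssembleCohort:
    def test_universe_is_intersection(self):
        expr, muts, clin = _mini_inputs(["A", "B", "C"], ["B", "C", "D"], ["A", "B", "C", "D"])
        bundle = assemble_cohort(expr, muts, clin)
        assert bundle.sample_ids == ["B", "C"]
        assert bundle.dropped == {"expression": 1, "mutations": 1, "clinical": 2}

    def test_disjoint_sets_error(self):
        expr, muts, clin = _mini_inputs(["A", "B"], ["C", "D"], ["E", "F"])
        with pytest.raises(ValidationError, match="empty"):
            assemble_cohort(expr, muts, clin)

    def test_identical_sets_keep_everything(self):
        expr, muts, clin = _mini_inputs(["A", "B", "C"], ["A", "B", "C"], ["A", "B", "C"])
        assert assemble_cohort(expr, muts, clin).n_samples == 3

    def test_row_order_independent(self):
        expr, muts, clin = _mini_inputs(["A", "B", "C"], ["C", "B", "A"], ["B", "A", "C"])
        b1 = assemble_cohort(expr, muts, clin)
        b2 = assemble_cohort(
            expr,
            muts.sample(frac=1, random_state=1),
            clin.sample(frac=1, random_state=2),
        )
        assert b1.sample_ids == b2.sample_ids
        pd.testing.assert_frame_equal(b1.mutations, b2.mutations)
        pd.testing.assert_frame_equal(b1.clinical, b2.clinical)
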