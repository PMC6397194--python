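import numpy as np
import pandas as pd
import pytest

from repairimmune.cohort_io import ExpressionMatrix, compute_zscores
from repairimmune.phenotype_score import (
    activated_t_flag,
    assemble_phenotypes,
    assign_group,
    combined_score,
    panel_comparison,
    signature_table,
    subtype_association,
)
from repairimmune.stats_core import t_test


def calls_frame(cd4, cd8):
    rows = []
    for i, (a, b) in enumerate(zip(cd4, cd8)):
        rows.append({"sample_id": f"S{i}", "cell_type": "Act_CD4", "infiltrated": a})
        rows.append({"sample_id": f"S{i}", "cell_type": "Act_CD8", "infiltrated": b})
    return pd.DataFrame(rows)


class TestActivatedTFlag:
    @pytest.mark.parametrize(
        "cd4, cd8, convention, expected",
        [
            (True, False, "either", True),
            (True, False, "both", False),
            (False, False, "either", False),
            (False, False, "both", False),
            (True, True, "either", True),
            (True, True, "both", True),
            (False, True, "cd4", False),
            (False, True, "cd8", True),
        ],
    )
    def test_conventions(self, cd4, cd8, convention, expected):
        flags = activated_t_flag(calls_frame([cd4], [cd8]), convention=convention)
        assert bool(flags.loc["S0"]) is expected

    def test_missing_cell_type_is_an_error(self):
        calls = pd.DataFrame(
            {"sample_id": ["S0"], "cell_type": ["Act_CD4"], "infiltrated": [True]}
        )
        with pytest.raises(ValueError, match="Act_CD8"):
            activated_t_flag(calls)


class TestGroups:
    @pytest.mark.parametrize(
        "repair, act, expected",
        [(False, False, "I"), (True, False, "II"), (False, True, "III"), (True, True, "IV")],
    )
    def test_mapping(self, repair, act, expected):
        assert assign_group(repair, act) == expected

    def test_groups_partition_cohort(self):
        rng = np.random.default_rng(0)
        n = 40
        repair = pd.Series(rng.random(n) < 0.5, index=[f"S{i}" for i in range(n)])
        act = pd.Series(rng.random(n) < 0.5, index=repair.index)
        z = pd.DataFrame(
            rng.normal(0, 1, (2, n)), index=["TGFB1", "WNT2"], columns=repair.index
        )
        table = assemble_phenotypes(repair, act, z)
        assert len(table) == n
        assert table["group"].value_counts().sum() == n


class TestCombinedScore:
    def _z(self, tgfb1, wnt2, samples):
        return pd.DataFrame([tgfb1, wnt2], index=["TGFB1", "WNT2"], columns=samples)

    def test_scoring_rule(self):
        samples = [f"S{i}" for i in range(4)]
        z = self._z([2.0, 1.0, -1.0, -2.0], [1.5, 0.5, -0.5, -1.5], samples)
        repair = pd.Series([False, True, True, False], index=samples)
        out = combined_score(z, repair)
        # medians are 0 and 0: S0 above both
        assert out.loc["S0", "combined_score"] == 3 and out.loc["S0", "score_class"] == "high"
        assert out.loc["S1", "combined_score"] == 2
        assert out.loc["S3", "combined_score"] == 1 and out.loc["S3", "score_class"] == "low"

    def test_exactly_median_earns_no_point(self):
        samples = ["a", "b", "c"]
        z = self._z([1.0, 0.0, -1.0], [1.0, 0.0, -1.0], samples)
        repair = pd.Series([True, True, True], index=samples)
        out = combined_score(z, repair)
        assert out.loc["b", "combined_score"] == 0

    def test_antitone_in_repair_variant(self):
        samples = ["a", "b", "c", "d"]
        z = self._z([1.0, 0.5, -0.5, -1.0], [1.0, 0.5, -0.5, -1.0], samples)
        with_var = combined_score(z, pd.Series(True, index=samples))
        without = combined_score(z, pd.Series(False, index=samples))
        assert (without["combined_score"] - with_var["combined_score"] == 1).all()

    def test_missing_gene_is_an_error(self):
        z = pd.DataFrame([[1.0, -1.0]], index=["TGFB1"], columns=["a", "b"])
        with pytest.raises(ValueError, match="WNT2"):
            combined_score(z, pd.Series([True, False], index=["a", "b"]))


class TestPanels:
    def _matrix(self, data, samples):
        return ExpressionMatrix(pd.DataFrame(data, index=["GENE1"], columns=samples))

    def test_two_group_anova_equals_t_test(self):
        rng = np.random.default_rng(1)
        samples = [f"S{i}" for i in range(20)]
        values = rng.normal(5, 1, 20)
        matrix = self._matrix([values], samples)
        groups = pd.Series(["A"] * 10 + ["B"] * 10, index=samples)
        table = panel_comparison(groups, matrix, ["GENE1"])
        t_p = t_test(values[:10], values[10:]).p
        assert table["p_anova"].iloc[0] == pytest.approx(t_p, rel=1e-9)
        assert table["p_adj"].iloc[0] == pytest.approx(t_p, rel=1e-6)

    def test_planted_group_shift_detected(self):
        rng = np.random.default_rng(2)
        hits = 0
        for rep in range(10):
            samples = [f"S{i}" for i in range(200)]
            groups = pd.Series(np.repeat(["I", "II", "III", "IV"], 50), index=samples)
            values = rng.normal(0, 1, 200)
            values[50:100] += 1.5  # group II shifted
            matrix = self._matrix([values], samples)
            table = panel_comparison(groups, matrix, ["GENE1"])
            row = table[table["comparison"] == "II vs IV"]
            hits += float(row["p_adj"].iloc[0]) < 0.01
        assert hits >= 9

    def test_degenerate_group_reported_with_reason(self):
        samples = ["a", "b", "c"]
        matrix = self._matrix([[1.0, 2.0, 3.0]], samples)
        groups = pd.Series(["A", "A", "B"], index=samples)  # B has 1 sample
        table = panel_comparison(groups, matrix, ["GENE1"])
        assert table["reason"].iloc[0] == "fewer than 2 usable groups"


class TestSignatureTable:
    def test_planted_genes_have_smallest_q(self):
        rng = np.random.default_rng(3)
        hits = 0
        for rep in range(10):
            samples = [f"S{i}" for i in range(120)]
            genes = [f"G{i:02d}" for i in range(50)]
            vals = rng.normal(10, 1, (50, 120))
            vals[:5, 60:] += 2.0  # 5 planted genes shifted in arm 2
            matrix = ExpressionMatrix(pd.DataFrame(vals, index=genes, columns=samples))
            labels = pd.Series(["low"] * 60 + ["high"] * 60, index=samples)
            table = signature_table(labels, matrix, genes)
            top5 = set(table.nsmallest(5, "q")["gene"])
            hits += top5 == set(genes[:5])
        assert hits >= 9

    def test_label_permutation_destroys_signal(self):
        rng = np.random.default_rng(4)
        samples = [f"S{i}" for i in range(120)]
        genes = [f"G{i:02d}" for i in range(20)]
        vals = rng.normal(10, 1, (20, 120))
        vals[:5, 60:] += 2.0
        matrix = ExpressionMatrix(pd.DataFrame(vals, index=genes, columns=samples))
        labels = pd.Series(["low"] * 60 + ["high"] * 60, index=samples)
        original = signature_table(labels, matrix, genes)
        permuted_labels = pd.Series(rng.permutation(labels.to_numpy()), index=samples)
        permuted = signature_table(permuted_labels, matrix, genes)
        assert permuted["q"].min() > original["q"].min()

    def test_identical_groups_yield_large_q(self):
        samples = [f"S{i}" for i in range(8)]
        vals = np.tile([1.0, 2.0, 3.0, 4.0], (3, 2))
        matrix = ExpressionMatrix(pd.DataFrame(vals, index=["A", "B", "C"], columns=samples))
        labels = pd.Series(["x"] * 4 + ["y"] * 4, index=samples)
        table = signature_table(labels, matrix, ["A", "B", "C"])
        assert (table["q"] > 0.9).all()


class TestSubtypeAssociation:
    def test_flag_aligned_with_one_level_is_significant(self):
        n = 40
        labels = pd.Series(["secretory"] * 10 + ["basal"] * 10 + ["classical"] * 10 + ["primitive"] * 10,
                           index=[f"S{i}" for i in range(n)])
        flags = pd.Series([True] * 10 + [False] * 30, index=labels.index)
        table = subtype_association(flags, labels).set_index("level")
        assert table.loc["secretory", "q"] < 0.001

    def test_single_level_is_an_error(self):
        labels = pd.Series(["basal"] * 5, index=[f"S{i}" for i in range(5)])
        flags = pd.Series([True, False, True, False, True], index=labels.index)
        with pytest.raises(ValueError, match="2 label levels"):
            subtype_association(flags, labels)

    def test_independent_flag_rarely_significant(self):
        rng = np.random.default_rng(6)
        hits = 0
        reps = 300
        for rep in range(reps):
            n = 120
            labels = pd.Series(rng.choice(["a", "b", "c", "d"], n), index=[f"S{i}" for i in range(n)])
            flags = pd.Series(rng.random(n) < 0.3, index=labels.index)
            table = subtype_association(flags, labels)
            qmin = table["q"].min()
            hits += bool(np.isnan(qmin)) or qmin >= 0.05
        assert hits / reps >= 0.90
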