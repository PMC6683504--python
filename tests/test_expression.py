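"""RPKM, differential expression, transcriptional amplification, the
regional screen, conditional contrasts, and panel-detection QC."""

import numpy as np
import pandas as pd
import pytest

from rdgenomics.datamodel import ExpressionMatrix, ValidationError
from rdgenomics.expression import (
    differential_expression,
    expression_by_group,
    panel_detection_fraction,
    regional_screen,
    rpkm,
    transcriptional_amplification,
)


def _em(values: pd.DataFrame, cytoband="1q21.1", coding=True) -> ExpressionMatrix:
    meta = pd.DataFrame({
        "cytoband": cytoband if isinstance(cytoband, list)
        else [cytoband] * len(values),
        "coding": coding if isinstance(coding, list) else [coding] * len(values),
        "length_bp": [1000] * len(values),
    }, index=values.index)
    return ExpressionMatrix(values, meta)


def _two_group_matrix(n_genes=50, n_a=10, n_b=10, seed=0, sigma=1.0):
    rng = np.random.default_rng(seed)
    cols = [f"A{i}" for i in range(n_a)] + [f"B{i}" for i in range(n_b)]
    values = pd.DataFrame(
        rng.lognormal(3.0, sigma, size=(n_genes, n_a + n_b)),
        index=[f"G{i}" for i in range(n_genes)], columns=cols)
    labels = pd.Series(["a"] * n_a + ["b"] * n_b, index=cols)
    return values, labels


class TestRpkm:
    def test_formula_and_zero(self):
        counts = pd.DataFrame({"s1": [0, 10]}, index=["A", "B"])
        lengths = pd.Series([500, 2000], index=["A", "B"])
        libs = pd.Series({"s1": 5_000_000})
        out = rpkm(counts, lengths, libs)
        assert out.loc["A", "s1"] == 0.0
        assert out.loc["B", "s1"] == pytest.approx(10 / (2 * 5))

    def test_scale_invariance(self):
        counts = pd.DataFrame({"s1": [3, 11, 0]}, index=list("ABC"))
        lengths = pd.Series([700, 1500, 900], index=list("ABC"))
        libs = pd.Series({"s1": 2_000_000})
        a = rpkm(counts, lengths, libs)
        b = rpkm(counts * 7, lengths, libs * 7)
        pd.testing.assert_frame_equal(a, b)

    def test_preserves_zeros_and_ordering_within_sample(self):
        counts = pd.DataFrame({"s1": [0, 5, 50]}, index=list("ABC"))
        lengths = pd.Series([1000, 1000, 1000], index=list("ABC"))
        out = rpkm(counts, lengths)
        col = out["s1"]
        assert col["A"] == 0 and col["B"] < col["C"]

    def test_zero_library_rejected(self):
        counts = pd.DataFrame({"s1": [1]}, index=["A"])
        with pytest.raises(ValidationError):
            rpkm(counts, pd.Series([100], index=["A"]), pd.Series({"s1": 0}))


class TestDifferentialExpression:
    def test_planted_gene_recovered(self):
        values, labels = _two_group_matrix(seed=1)
        values.loc["G0", labels == "b"] *= 2 ** 6  # ~4 sd on log2 scale
        de = differential_expression(_em(values), labels, focal_group="b")
        assert "G0" in de.significant
        assert de.table.loc["G0", "direction"] == 1

    def test_label_swap_flips_direction_not_p(self):
        values, labels = _two_group_matrix(seed=2)
        de_a = differential_expression(_em(values), labels, focal_group="a")
        de_b = differential_expression(_em(values), labels, focal_group="b")
        nonzero = de_a.table["direction"] != 0
        assert (de_a.table.loc[nonzero, "direction"]
                == -de_b.table.loc[nonzero, "direction"]).all()
        np.testing.assert_allclose(de_a.table["p"], de_b.table["p"])

    def test_null_matrix_few_significant(self):
        values, labels = _two_group_matrix(n_genes=300, seed=3)
        de = differential_expression(_em(values), labels)
        assert len(de.significant) <= 3

    def test_constant_gene_flagged(self):
        values, labels = _two_group_matrix(n_genes=5, seed=4)
        values.loc["G0"] = 7.0
        de = differential_expression(_em(values), labels)
        row = de.table.loc["G0"]
        assert row["constant"] and row["p"] == 1.0 and not row["significant"]


class TestTranscriptionalAmplification:
    def test_counting(self):
        values, labels = _two_group_matrix(n_genes=6, seed=5)
        for g in ["G0", "G1", "G2"]:
            values.loc[g, labels == "b"] *= 2 ** 8
        values.loc["G3", labels == "a"] *= 2 ** 8
        de = differential_expression(_em(values), labels, focal_group="b")
        n_sig, up = transcriptional_amplification(de)
        assert n_sig == 4
        assert up == pytest.approx(0.75)

    def test_all_up_and_empty_cases(self):
        values, labels = _two_group_matrix(n_genes=4, seed=6)
        values.loc[:, labels == "b"] *= 2 ** 8
        de = differential_expression(_em(values), labels, focal_group="b")
        assert transcriptional_amplification(de) == (4, 1.0)
        null = differential_expression(_em(values * 0 + 1.0), labels)
        assert transcriptional_amplification(null) == (0, None)

    def test_global_upshift_footprint(self):
        """A global x1.5 shift in 15 focal vs 37 reference samples
        yields an up-fraction >= 0.95 among significant genes."""
        rng = np.random.default_rng(7)
        n_focal, n_ref = 15, 37
        cols = [f"F{i}" for i in range(n_focal)] + [f"R{i}" for i in range(n_ref)]
        log2 = rng.normal(4.0, 0.5, size=(400, n_focal + n_ref)) \
            + rng.normal(4.0, 1.5, size=(400, 1))
        values = pd.DataFrame(2.0 ** log2, index=[f"G{i}" for i in range(400)],
                              columns=cols)
        values.iloc[:, :n_focal] *= 1.5
        labels = pd.Series(["compound"] * n_focal + ["other"] * n_ref,
                           index=cols)
        de = differential_expression(_em(values), labels,
                                     focal_group="compound")
        n_sig, up = transcriptional_amplification(de)
        assert n_sig > 50
        assert up >= 0.95

    def test_gene_order_invariance(self):
        values, labels = _two_group_matrix(n_genes=30, seed=8)
        values.loc["G0", labels == "b"] *= 2 ** 8
        de1 = differential_expression(_em(values), labels, focal_group="b")
        shuffled = values.sample(frac=1.0, random_state=1)
        de2 = differential_expression(_em(shuffled), labels, focal_group="b")
        assert transcriptional_amplification(de1) == \
            transcriptional_amplification(de2)


class TestRegionalScreen:
    def _region_matrix(self, seed=9):
        rng = np.random.default_rng(seed)
        genes = [f"R{i}" for i in range(19)] + ["NC1", "OUT1"]
        bands = ["18q21.1"] * 10 + ["18q21.2"] * 9 + ["18q21.2", "5q31.1"]
        coding = [True] * 19 + [False, True]
        cols = [f"S{i}" for i in range(40)]
        values = pd.DataFrame(rng.lognormal(3, 0.4, size=(21, 40)),
                              index=genes, columns=cols)
        meta = pd.DataFrame({"cytoband": bands, "coding": coding,
                             "length_bp": [1000] * 21}, index=genes)
        labels = pd.Series(["gain"] * 15 + ["other"] * 25, index=cols)
        return ExpressionMatrix(values, meta), labels

    def test_empty_region(self):
        em, labels = self._region_matrix()
        res = regional_screen(em, ["21q22"], labels, focal_group="gain")
        assert res.region_genes == [] and res.warning

    def test_planted_gene_recovered_exactly(self):
        em, labels = self._region_matrix()
        em.values.loc["R0", labels == "gain"] *= 8.0
        res = regional_screen(em, ["18q21.1", "18q21.2"], labels,
                              focal_group="gain")
        assert len(res.region_genes) == 20  # OUT1 excluded
        assert res.overexpressed == ["R0"]

    def test_coding_only_excludes_noncoding(self):
        em, labels = self._region_matrix()
        em.values.loc["NC1", labels == "gain"] *= 8.0
        res = regional_screen(em, ["18q21"], labels, focal_group="gain",
                              coding_only=True)
        assert "NC1" not in res.overexpressed
        res2 = regional_screen(em, ["18q21"], labels, focal_group="gain",
                               coding_only=False)
        assert "NC1" in res2.overexpressed


class TestExpressionByGroup:
    def test_identical_groups_null(self):
        values = pd.DataFrame([[5.0] * 8], index=["MYC"],
                              columns=[f"S{i}" for i in range(8)])
        labels = pd.Series(["x"] * 4 + ["y"] * 4, index=values.columns)
        res = expression_by_group(_em(values), "MYC", labels)
        assert res.p == pytest.approx(1.0)

    def test_conditional_association_disbands_after_exclusion(self):
        """MYC high only in amplified samples; the compound association
        exists only through the amplified subset and vanishes when those
        samples are removed."""
        rng = np.random.default_rng(10)
        n = 60
        cols = [f"S{i}" for i in range(n)]
        amp = np.zeros(n, dtype=bool)
        amp[:12] = True
        compound = np.zeros(n, dtype=bool)
        compound[:10] = True   # overlaps amplification heavily
        compound[20:28] = True
        myc = rng.normal(30, 3, n)
        myc[amp] += 40.0
        values = pd.DataFrame([np.abs(myc)], index=["MYC"], columns=cols)
        labels = pd.Series(np.where(compound, "compound", "other"), index=cols)
        em = _em(values)
        before = expression_by_group(em, "MYC", labels, focal_group="compound")
        assert before.p < 0.05
        after = expression_by_group(em, "MYC", labels, focal_group="compound",
                                    exclude_samples=np.array(cols)[amp])
        assert after.p > 0.05

    def test_empty_exclusion_is_noop(self):
        values, labels = _two_group_matrix(n_genes=3, seed=11)
        em = _em(values)
        a = expression_by_group(em, "G0", labels)
        b = expression_by_group(em, "G0", labels, exclude_samples=[])
        assert (a.statistic, a.p) == (b.statistic, b.p)

    def test_group_emptied_by_exclusion_is_skip(self):
        values, labels = _two_group_matrix(n_genes=3, n_a=3, n_b=3, seed=12)
        res = expression_by_group(
            _em(values), "G0", labels,
            exclude_samples=[c for c in values.columns if c.startswith("A")])
        assert res.skip_reason is not None


class TestPanelDetection:
    def test_counting_and_invariance(self):
        values = pd.DataFrame(
            np.vstack([np.ones((2, 10)), np.zeros((8, 10))]),
            index=[f"G{i}" for i in range(10)],
            columns=[f"S{i}" for i in range(10)])
        em = _em(values)
        panel = [f"G{i}" for i in range(10)]
        assert panel_detection_fraction(em, panel) == pytest.approx(0.2)
        assert panel_detection_fraction(em, panel[::-1]) == pytest.approx(0.2)
        assert panel_detection_fraction(em, ["G0", "G1"]) == 1.0

    def test_empty_panel_rejected(self):
        values = pd.DataFrame({"s": [1.0]}, index=["A"])
        with pytest.raises(ValidationError):
            panel_detection_fraction(_em(values), [])
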