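"""Chi-square dosage test and MEG/PEG classification."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from imprintcall import (
    CallerConfig,
    GeneAlleleCount,
    call_pair,
    chi2_dosage_test,
    classify_direction,
    combine_reciprocal,
)
from imprintcall.crosses import make_pair

CFG = CallerConfig()


def result(m, p, tissue, cfg=CFG, gene="g1", sample="d1"):
    return classify_direction(
        GeneAlleleCount(gene, sample, m, p, n_informative_snps=1), tissue, cfg
    )


class TestChi2DosageTest:
    def test_exact_embryo_null_gives_zero(self):
        chi2, p = chi2_dosage_test(10, 10, "embryo")
        assert chi2 == 0.0 and p == 1.0

    def test_exact_endosperm_null_gives_zero(self):
        chi2, p = chi2_dosage_test(20, 10, "endosperm")
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_embryo_worked_example(self):
        # (18-10)^2/10 + (2-10)^2/10 = 12.8
        chi2, p = chi2_dosage_test(18, 2, "embryo")
        assert chi2 == pytest.approx(12.8, abs=1e-12)
        assert p == pytest.approx(3.47e-4, rel=1e-2)

    def test_endosperm_worked_example(self):
        # (10-20)^2/20 + (20-10)^2/10 = 15
        chi2, _ = chi2_dosage_test(10, 20, "endosperm")
        assert chi2 == pytest.approx(15.0, abs=1e-10)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            chi2_dosage_test(0, 0, "embryo")

    @given(st.integers(0, 300), st.integers(0, 300))
    def test_matches_erfc_oracle(self, m, p):
        """Agreement with the textbook Pearson statistic and the chi2(1)
        survival function computed via erfc."""
        if m + p == 0:
            return
        for tissue, f in (("embryo", 0.5), ("endosperm", 2 / 3)):
            n = m + p
            want_chi2 = (m - n * f) ** 2 / (n * f) + (p - n * (1 - f)) ** 2 / (
                n * (1 - f)
            )
            want_p = math.erfc(math.sqrt(want_chi2 / 2.0))
            chi2, pv = chi2_dosage_test(m, p, tissue)
            assert chi2 == pytest.approx(want_chi2, abs=1e-10)
            assert pv == pytest.approx(want_p, abs=1e-10)


class TestClassifyDirection:
    @pytest.mark.parametrize(
        "m,p,tissue,status",
        [
            (18, 2, "embryo", "MEG"),
            (2, 18, "embryo", "PEG"),
            (13, 7, "embryo", "biallelic"),  # 0.65 <= 2/3, p ~0.18
            (40, 60, "endosperm", "PEG"),  # paternal 0.60 > 0.50, chi2 = 32
            (66, 34, "endosperm", "biallelic"),  # chi2 ~0.02
            (95, 5, "endosperm", "MEG"),
            (9, 10, "embryo", "untestable"),  # 19 reads < 20
            (9, 10, "endosperm", "untestable"),
        ],
    )
    def test_worked_examples(self, m, p, tissue, status):
        assert result(m, p, tissue).status == status

    def test_endosperm_meg_needs_eighty_percent(self):
        # maternal 75% is significantly biased past 2:1 but below the 80%
        # MEG threshold
        r = result(225, 75, "endosperm")
        assert r.p_value < 0.05 and r.status == "biallelic"

    def test_fraction_threshold_is_strict(self):
        # exactly 2/3 maternal in embryo must not be called MEG
        r = result(40, 20, "embryo", CallerConfig(alpha=0.5))
        assert r.maternal_fraction == pytest.approx(2 / 3)
        assert r.status == "biallelic"

    def test_min_reads_boundary(self):
        assert result(20, 0, "embryo").testable
        assert not result(19, 0, "embryo").testable


class TestCombineReciprocal:
    def test_meg_in_both_directions_is_meg(self):
        call = combine_reciprocal(result(90, 10, "embryo"), result(85, 15, "embryo"))
        assert call.status == "MEG"

    def test_allele_effect_is_not_imprinting(self):
        # same founder favoured in both directions: maternal fraction 0.9
        # then 0.1 -> MEG + PEG -> biallelic
        d1 = result(90, 10, "embryo")
        d2 = result(10, 90, "embryo")
        assert d1.status == "MEG" and d2.status == "PEG"
        assert combine_reciprocal(d1, d2).status == "biallelic"

    def test_untestable_dominates(self):
        call = combine_reciprocal(result(90, 10, "embryo"), result(9, 1, "embryo"))
        assert call.status == "untestable"

    def test_mismatched_genes_rejected(self):
        with pytest.raises(ValueError):
            combine_reciprocal(
                result(90, 10, "embryo", gene="a"), result(90, 10, "embryo", gene="b")
            )


def _counts_frame(rows):
    return pd.DataFrame(
        rows, columns=["sample_id", "gene_id", "maternal_reads", "paternal_reads"]
    )


PAIR_EMB = make_pair("BM-C/C-BM", ("BM-C", "C-BM"), {"B73", "Mo17"}, {"CAU5"}, "embryo")


class TestCallPair:
    def test_missing_direction_errors_naming_the_cross(self):
        counts = _counts_frame([("BM-C.embryo", "g1", 30, 10)])
        with pytest.raises(ValueError, match="C-BM.embryo"):
            call_pair(counts, PAIR_EMB)

    def test_duplicate_gene_rows_rejected(self):
        counts = _counts_frame(
            [
                ("BM-C.embryo", "g1", 30, 10),
                ("BM-C.embryo", "g1", 5, 5),
                ("C-BM.embryo", "g1", 30, 10),
            ]
        )
        with pytest.raises(ValueError, match="duplicate"):
            call_pair(counts, PAIR_EMB)

    def test_gene_absent_from_one_direction_is_untestable(self):
        counts = _counts_frame(
            [("BM-C.embryo", "g1", 90, 10), ("C-BM.embryo", "g2", 90, 10)]
        )
        calls = call_pair(counts, PAIR_EMB).set_index("gene_id")
        assert calls.loc["g1", "status"] == "untestable"
        assert calls.loc["g2", "status"] == "untestable"

    def test_label_antisymmetry_under_count_swap(self):
        """Swapping maternal and paternal counts in both directions maps
        MEG <-> PEG in the embryo."""
        rng = np.random.default_rng(5)
        rows, swapped = [], []
        for i in range(50):
            m1, p1 = rng.integers(0, 120, size=2)
            m2, p2 = rng.integers(0, 120, size=2)
            rows += [("BM-C.embryo", f"g{i}", m1, p1), ("C-BM.embryo", f"g{i}", m2, p2)]
            swapped += [
                ("BM-C.embryo", f"g{i}", p1, m1),
                ("C-BM.embryo", f"g{i}", p2, m2),
            ]
        a = call_pair(_counts_frame(rows), PAIR_EMB).set_index("gene_id")["status"]
        b = call_pair(_counts_frame(swapped), PAIR_EMB).set_index("gene_id")["status"]
        flip = {"MEG": "PEG", "PEG": "MEG", "biallelic": "biallelic", "untestable": "untestable"}
        assert (b == a.map(flip)).all()

    def test_monotone_in_maternal_reads(self):
        """At fixed total, adding maternal reads never turns a MEG call into
        a biallelic one."""
        total = 60
        statuses = []
        for m in range(total + 1):
            rows = [("BM-C.embryo", "g", m, total - m), ("C-BM.embryo", "g", m, total - m)]
            statuses.append(call_pair(_counts_frame(rows), PAIR_EMB)["status"][0])
        first_meg = statuses.index("MEG") if "MEG" in statuses else None
        assert first_meg is not None
        assert all(s == "MEG" for s in statuses[first_meg:])

    def test_calls_invariant_to_gene_order(self):
        rng = np.random.default_rng(7)
        rows = []
        for i in range(30):
            rows += [
                ("BM-C.embryo", f"g{i}", int(rng.integers(0, 100)), int(rng.integers(0, 100))),
                ("C-BM.embryo", f"g{i}", int(rng.integers(0, 100)), int(rng.integers(0, 100))),
            ]
        frame = _counts_frame(rows)
        shuffled = frame.sample(frac=1.0, random_state=3).reset_index(drop=True)
        a = call_pair(frame, PAIR_EMB).set_index("gene_id")["status"].sort_index()
        b = call_pair(shuffled, PAIR_EMB).set_index("gene_id")["status"].sort_index()
        assert (a == b).all()

    def test_pooled_mode_tests_summed_counts(self):
        cfg = CallerConfig(combine_mode="pooled")
        # each direction alone is untestable (<20), the pool is a clear MEG
        counts = _counts_frame(
            [("BM-C.embryo", "g1", 15, 1), ("C-BM.embryo", "g1", 15, 1)]
        )
        calls = call_pair(counts, PAIR_EMB, cfg)
        assert calls["status"][0] == "MEG"
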