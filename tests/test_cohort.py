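"""MSI calls, TMB, substitution spectra and the exact-test statistics,
checked against independent enumeration oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from oracles import fisher_two_sided_oracle, ora_oracle_enumeration

from crcprofiler import cohort


# ---------------------------------------------------------------------------
# MSI and TMB
# ---------------------------------------------------------------------------

class TestMsi:
    @pytest.mark.parametrize("score,status", [
        (0.61, "MSI"), (0.39, "MSS"),
        (0.40, "Undetermined"), (0.60, "Undetermined"), (0.5, "Undetermined"),
    ])
    def test_mantis_thresholds(self, score, status):
        assert cohort.classify_msi_mantis(score) == status

    def test_negative_score_rejected(self):
        with pytest.raises(ValueError):
            cohort.classify_msi_mantis(-0.1)

    @given(st.floats(0, 1.5))
    @settings(max_examples=300, deadline=None)
    def test_step_function(self, score):
        status = cohort.classify_msi_mantis(score)
        if score > 0.6:
            assert status == "MSI"
        elif score < 0.4:
            assert status == "MSS"
        else:
            assert status == "Undetermined"

    def test_group_msi_l_with_mss(self):
        out = cohort.group_msi(["MSI-H", "MSI-L", "MSS"])
        assert out.tolist() == ["MSI", "MSS", "MSS"]

    def test_group_empty_and_unknown(self):
        assert cohort.group_msi([]).tolist() == []
        with pytest.raises(ValueError, match="unknown"):
            cohort.group_msi(["MSI-X"])


class TestTmb:
    def test_arithmetic(self):
        df = pd.DataFrame({"patient_id": ["P1"] * 70,
                           "variant_class": ["missense"] * 70})
        out = cohort.compute_tmb(df, capture_mb=35.0)
        assert out.loc[0, "tmb"] == pytest.approx(2.0)

    def test_synonymous_only_counts_zero(self):
        df = pd.DataFrame({"patient_id": ["P1", "P1"],
                           "variant_class": ["other", "other"]})
        out = cohort.compute_tmb(df, capture_mb=35.0)
        assert out.loc[0, "tmb"] == 0.0

    def test_zero_variant_patient_reported(self):
        df = pd.DataFrame({"patient_id": ["P1"],
                           "variant_class": ["missense"]})
        out = cohort.compute_tmb(df, 35.0, patients=["P1", "P2"])
        assert out.set_index("patient_id").loc["P2", "tmb"] == 0.0

    def test_invalid_capture_rejected(self):
        with pytest.raises(ValueError):
            cohort.compute_tmb(pd.DataFrame({"patient_id": [],
                                             "variant_class": []}), 0.0)


# ---------------------------------------------------------------------------
# Substitution spectrum
# ---------------------------------------------------------------------------

class TestSpectrum:
    def test_purine_reference_collapsed(self):
        df = pd.DataFrame({"patient_id": ["P1"], "ref": ["G"], "alt": ["A"]})
        out = cohort.substitution_spectrum(df)
        assert out.loc["P1", "C>T"] == 1.0

    def test_proportions(self):
        df = pd.DataFrame({"patient_id": ["P1"] * 4,
                           "ref": ["C", "C", "T", "T"],
                           "alt": ["A", "A", "C", "C"]})
        out = cohort.substitution_spectrum(df)
        assert out.loc["P1"].tolist() == [0.5, 0, 0, 0, 0.5, 0]

    def test_indels_skipped_with_warning(self):
        df = pd.DataFrame({"patient_id": ["P1", "P1"],
                           "ref": ["C", "CA"], "alt": ["A", "C"]})
        with pytest.warns(UserWarning, match="non-SNV"):
            out = cohort.substitution_spectrum(df)
        assert out.loc["P1", "C>A"] == 1.0

    def test_no_snv_patient_all_nan(self):
        df = pd.DataFrame({"patient_id": ["P1"], "ref": ["CA"], "alt": ["C"]})
        with pytest.warns(UserWarning):
            out = cohort.substitution_spectrum(df)
        assert out.loc["P1"].isna().all()

    def test_sum_to_one_and_strand_invariance(self, rng):
        bases = np.array(list("ACGT"))
        ref = bases[rng.integers(0, 4, 200)]
        shift = rng.integers(1, 4, 200)
        alt = bases[(np.searchsorted(bases, ref) + shift) % 4]
        df = pd.DataFrame({"patient_id": ["P1"] * 200, "ref": ref, "alt": alt})
        out = cohort.substitution_spectrum(df)
        assert out.loc["P1"].sum() == pytest.approx(1.0, abs=1e-12)
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        flipped = df.assign(ref=[comp[b] for b in ref],
                            alt=[comp[b] for b in alt])
        pd.testing.assert_frame_equal(out,
                                      cohort.substitution_spectrum(flipped))


# ---------------------------------------------------------------------------
# Fisher comparison and ORA
# ---------------------------------------------------------------------------

class TestCompareMutationFreq:
    @staticmethod
    def _run(a, b, c, d, min_mutated=0):
        matrix = pd.DataFrame(
            [[1] * a + [0] * b + [1] * c + [0] * d],
            index=["G"],
            columns=[f"p{i}" for i in range(a + b + c + d)])
        groups = pd.Series(["MSI"] * (a + b) + ["MSS"] * (c + d),
                           index=matrix.columns)
        return cohort.compare_mutation_freq(matrix, groups,
                                            min_mutated=min_mutated)

    def test_symmetric_minimal_table(self):
        out = self._run(1, 0, 0, 1)
        assert out.loc[0, "p"] == pytest.approx(1.0)

    def test_two_by_two_exact_third(self):
        out = self._run(2, 0, 0, 2)
        assert out.loc[0, "p"] == pytest.approx(1 / 3)

    def test_min_mutated_rule(self):
        # gene mutated in 4 samples total is tested at min_mutated=4,
        # a gene mutated in 3 is not
        assert len(self._run(3, 1, 1, 3, min_mutated=4)) == 1
        assert len(self._run(2, 2, 1, 3, min_mutated=4)) == 0

    def test_empty_group_rejected(self):
        matrix = pd.DataFrame([[1, 0]], index=["G"], columns=["p0", "p1"])
        groups = pd.Series(["MSI", "MSI"], index=matrix.columns)
        with pytest.raises(ValueError, match="nonempty"):
            cohort.compare_mutation_freq(matrix, groups)

    def test_patient_order_invariance(self, rng):
        matrix = pd.DataFrame(rng.integers(0, 2, (10, 12)),
                              index=[f"g{i}" for i in range(10)],
                              columns=[f"p{i}" for i in range(12)])
        groups = pd.Series(["MSI"] * 6 + ["MSS"] * 6, index=matrix.columns)
        out1 = cohort.compare_mutation_freq(matrix, groups, min_mutated=1)
        shuffled = list(rng.permutation(matrix.columns))
        out2 = cohort.compare_mutation_freq(matrix[shuffled], groups,
                                            min_mutated=1)
        pd.testing.assert_frame_equal(out1, out2)

    def test_p_matches_enumeration_oracle(self, rng):
        for _ in range(30):
            a, b, c, d = rng.integers(0, 8, 4)
            if a + b == 0 or c + d == 0:
                continue
            out = self._run(int(a), int(b), int(c), int(d))
            expect = fisher_two_sided_oracle(int(a), int(b), int(c), int(d))
            assert out.loc[0, "p"] == pytest.approx(expect, abs=1e-10)

    def test_bh_adjustment_monotone_bounded(self, rng):
        matrix = pd.DataFrame(rng.integers(0, 2, (20, 14)),
                              index=[f"g{i}" for i in range(20)],
                              columns=[f"p{i}" for i in range(14)])
        groups = pd.Series(["MSI"] * 7 + ["MSS"] * 7, index=matrix.columns)
        out = cohort.compare_mutation_freq(matrix, groups, min_mutated=1)
        assert (out["p_adj"] <= 1.0 + 1e-12).all()
        assert (out["p_adj"] >= out["p"] - 1e-12).all()
        # sorted by p: adjusted values are non-decreasing
        srt = out.sort_values("p")
        assert (np.diff(srt["p_adj"]) >= -1e-12).all()


class TestOra:
    def test_hits_equal_universe(self):
        sets = {"S": ["a", "b", "c"]}
        out = cohort.ora_hypergeom({"a", "b", "c"}, {"a", "b", "c"}, sets)
        assert out.loc[0, "rich_factor"] == 1.0
        assert out.loc[0, "p"] == pytest.approx(1.0)

    def test_rich_factor_definition(self):
        universe = {f"g{i}" for i in range(100)}
        sets = {"S": [f"g{i}" for i in range(10)]}
        hits = {f"g{i}" for i in range(5)}
        out = cohort.ora_hypergeom(hits, universe, sets)
        assert out.loc[0, "rich_factor"] == 0.5

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            cohort.ora_hypergeom(set(), set(), {"S": ["a"]})

    def test_hits_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            cohort.ora_hypergeom({"x"}, {"a"}, {"S": ["a"]})

    def test_p_matches_subset_enumeration(self, rng):
        universe = [f"g{i}" for i in range(12)]
        for _ in range(5):
            members = list(rng.choice(universe, 5, replace=False))
            hits = set(rng.choice(universe, 4, replace=False))
            out = cohort.ora_hypergeom(hits, set(universe), {"S": members})
            expect = ora_oracle_enumeration(hits, universe, members)
            assert out.loc[0, "p"] == pytest.approx(expect, abs=1e-10)
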