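"""Evaluation statistics against the published clinical table and synthetic cohorts."""
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hsquant.evaluate import (
    EXTENDED_CL_GRID,
    cl_sweep,
    cohort_summary,
    compare_methods,
    detection_rates_by_subtype,
    fisher_exact_enumeration,
    fisher_exact_two_tailed,
    make_control_rows,
    sensitivity_specificity,
    youden_index,
)
from hsquant.synthetic import CohortSpec, generate_cohort


@pytest.fixture(scope="module")
def full_table(table1):
    """Fixture patients plus the 22 controls, all inside (specificity 100%
    for the quantitative methods as reported)."""
    return pd.concat([table1, make_control_rows(22)], ignore_index=True)


class TestSensitivitySpecificity:
    @pytest.mark.parametrize(
        "method,sens",
        [("q_volume", 92.59), ("q_flair", 38.89), ("q_pet", 98.15),
         ("cva_mri", 79.63), ("cva_pet", 81.48)],
    )
    def test_fixture_sensitivities(self, full_table, method, sens):
        s, spec = sensitivity_specificity(full_table, method)
        assert round(s, 2) == sens
        assert spec == 100.0

    def test_all_detected_toy_table(self):
        toy = pd.concat(
            [pd.DataFrame({"subject_id": [f"P{i}" for i in range(10)],
                           "group": "patient", "q_pet": "p"}),
             make_control_rows(5, methods=["q_pet"])],
            ignore_index=True)
        assert sensitivity_specificity(toy, "q_pet") == (100.0, 100.0)

    def test_empty_groups_rejected(self, table1):
        with pytest.raises(ValueError, match="control"):
            sensitivity_specificity(table1, "q_pet")  # no control rows
        with pytest.raises(ValueError, match="patient"):
            sensitivity_specificity(make_control_rows(5), "q_pet")

    def test_partial_control_specificity(self, table1):
        """19/22 and 20/22 inside reproduce the visual-analysis specificities."""
        t = pd.concat(
            [table1, make_control_rows(22, inside={"cva_mri": 19, "cva_pet": 20})],
            ignore_index=True)
        assert round(sensitivity_specificity(t, "cva_mri")[1], 2) == 86.36
        assert round(sensitivity_specificity(t, "cva_pet")[1], 2) == 90.91


class TestDetectionRates:
    def test_fixture_subtype_cells(self, full_table):
        qpet = detection_rates_by_subtype(full_table, "q_pet").set_index("stratum")
        assert qpet.loc["all", "detected"] == 53
        assert qpet.loc["all", "rate_percent"] == 98.15
        assert qpet.loc["3", "detected"] == 3 and qpet.loc["3", "rate_percent"] == 75.0
        cva = detection_rates_by_subtype(full_table, "cva_mri").set_index("stratum")
        assert cva.loc["1", "detected"] == 33 and cva.loc["1", "rate_percent"] == 100.0
        assert cva.loc["2", "detected"] == 9 and cva.loc["2", "rate_percent"] == 52.94
        qvol = detection_rates_by_subtype(full_table, "q_volume").set_index("stratum")
        assert qvol.loc["2", "detected"] == 15 and qvol.loc["2", "rate_percent"] == 88.24

    def test_rates_sum_to_overall_count(self, full_table):
        for m in ("q_volume", "q_flair", "q_pet"):
            df = detection_rates_by_subtype(full_table, m).set_index("stratum")
            assert df.loc[["1", "2", "3"], "detected"].sum() == df.loc["all", "detected"]

    def test_missing_subtype_errors(self):
        toy = pd.DataFrame({"subject_id": ["P1"], "group": "patient",
                            "hs_type": [1], "q_pet": ["p"]})
        with pytest.raises(ValueError, match=r"\[2, 3\]"):
            detection_rates_by_subtype(toy, "q_pet")


class TestFisher:
    def test_identical_columns_give_p_one(self):
        assert fisher_exact_two_tailed(50, 4, 50, 4) == 1.0

    def test_published_comparisons(self):
        assert round(fisher_exact_two_tailed(53, 1, 43, 11), 3) == 0.004
        assert round(fisher_exact_two_tailed(53, 1, 50, 4), 3) == 0.363

    def test_zero_margin_convention(self):
        assert fisher_exact_two_tailed(0, 0, 3, 5) == 1.0

    def test_negative_or_fractional_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_two_tailed(-1, 2, 3, 4)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(st.integers(0, 30), st.integers(0, 30), st.integers(0, 30), st.integers(0, 30))
    def test_matches_exhaustive_enumeration(self, a, b, c, d):
        """Implementation equals brute-force hypergeometric enumeration for
        every table with margins <= 60."""
        p = fisher_exact_two_tailed(a, b, c, d)
        q = fisher_exact_enumeration(a, b, c, d)
        assert math.isclose(p, q, rel_tol=1e-9, abs_tol=1e-12)


class TestCompareMethods:
    def test_fixture_significance_pattern(self, full_table):
        rep = compare_methods(full_table, "q_pet").set_index(["stratum", "method"])
        assert round(rep.loc[("all", "cva_mri"), "p_value"], 3) == 0.004
        assert round(rep.loc[("all", "cva_pet"), "p_value"], 3) == 0.008
        assert round(rep.loc[("all", "q_volume"), "p_value"], 3) == 0.363
        assert rep.loc[("all", "q_flair"), "p_value"] < 0.001
        assert rep.loc[("all", "cva_mri"), "significant"]
        assert not rep.loc[("all", "q_volume"), "significant"]
        # single-subfield (types 2 & 3) stratum
        assert round(rep.loc[("types_2_3", "cva_mri"), "p_value"], 3) == 0.001
        assert round(rep.loc[("types_2_3", "cva_pet"), "p_value"], 3) == 0.045
        assert round(rep.loc[("types_2_3", "q_volume"), "p_value"], 3) == 0.343

    def test_identical_columns_all_p_one(self, full_table):
        t = full_table.copy()
        t["copy"] = t["q_pet"]
        rep = compare_methods(t, "q_pet", others=["copy"])
        assert (rep["p_value"] == 1.0).all()

    def test_no_others_gives_empty_report(self, full_table):
        rep = compare_methods(full_table, "q_pet", others=[])
        assert len(rep) == 0


class TestCohortSummary:
    def test_fixture_follow_up(self, full_table):
        s = cohort_summary(full_table)
        assert s["n_patients"] == 54
        assert s["follow_up_mean"] == 19.78
        assert s["follow_up_sd"] == 7.00
        assert (s["follow_up_min"], s["follow_up_max"]) == (8, 35)
        assert s["hs_type_counts"] == {1: 33, 2: 17, 3: 4}

    def test_constant_follow_up(self):
        toy = pd.DataFrame({"subject_id": ["a", "b"], "group": "patient",
                            "hs_type": [1, 1], "follow_up_months": [12, 12]})
        s = cohort_summary(toy)
        assert s["follow_up_mean"] == 12.00 and s["follow_up_sd"] == 0.00


class TestClSweep:
    def test_perfect_separation_auc_one(self, separated_cohort):
        curve = cl_sweep(separated_cohort, "volume", cl_grid=EXTENDED_CL_GRID)
        assert curve.auc == 1.0
        perfect = curve.points[(curve.points.sensitivity == 100.0)
                               & (curve.points.specificity == 100.0)]
        assert len(perfect) > 0

    def test_monotone_in_cl(self, separated_cohort):
        df = generate_cohort(CohortSpec(effect={"volume": 1.5, "flair": 1.5, "suvr": 1.5},
                                        n_controls=50, n_patients=100, seed=4))
        for cohort in (separated_cohort, df):
            pts = cl_sweep(cohort, "volume").points
            assert (np.diff(pts.sensitivity) <= 1e-9).all()
            assert (np.diff(pts.specificity) >= -1e-9).all()

    def test_null_cohort_with_lateralization_auc_below_half(self):
        """Under the null, a detected patient is lateralized correctly only
        ~half the time, halving 'sensitivity' and pushing the ROC below the
        diagonal — the mechanism behind a sub-0.5 AUC."""
        df = generate_cohort(CohortSpec(
            n_controls=300, n_patients=600,
            effect={"volume": 0.0, "flair": 0.0, "suvr": 0.0}, seed=5))
        assert cl_sweep(df, "volume").auc < 0.5

    def test_label_swap_symmetry_without_lateralization(self):
        """Scoring against a FIXED control model, swapping the patient/control
        labels reflects the ROC about the diagonal, so the two AUCs sum to 1
        exactly. (With lateralization required this identity intentionally
        breaks: wrong-side detections are no longer true positives.)"""
        from hsquant.ellipse import fit_control_ellipse

        df = generate_cohort(CohortSpec(n_controls=200, n_patients=200,
                                        effect={"volume": 1.0, "flair": 1.0, "suvr": 1.0},
                                        seed=6))
        ctl = df[df.group == "control"][["volume_right", "volume_left"]].to_numpy()
        model = fit_control_ellipse(ctl, 0.5, "volume")
        swapped = df.copy()
        swapped["group"] = df["group"].map({"control": "patient", "patient": "control"})
        a = cl_sweep(df, "volume", require_lateralization=False, model=model).auc
        b = cl_sweep(swapped, "volume", require_lateralization=False, model=model).auc
        assert a + b == pytest.approx(1.0, abs=1e-6)

    def test_youden_from_printed_rates(self):
        assert youden_index(92.59, 100.0) == pytest.approx(0.9259)

    def test_sweep_is_deterministic(self, separated_cohort):
        c1 = cl_sweep(separated_cohort, "suvr")
        c2 = cl_sweep(separated_cohort, "suvr")
        pd.testing.assert_frame_equal(c1.points, c2.points)
        assert c1.auc == c2.auc and c1.optimal_cl == c2.optimal_cl
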