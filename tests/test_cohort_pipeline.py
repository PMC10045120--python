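import numpy as np
import pandas as pd
import pytest
from scipy import stats

import anndata as ad

from redoxcell import cohort_pipeline as cp
from redoxcell import kinetic_model as km
from redoxcell import synthetic_data as sd


class TestWelch:
    def test_hand_computed_example(self):
        """a=[1,2,3] vs b=[2,3,4]: t = -1.2247, df = 4 by the closed-form
        Welch and Welch-Satterthwaite formulas."""
        c = cp.welch_test([1, 2, 3], [2, 3, 4])
        assert c.t_statistic == pytest.approx(-1.224745, abs=1e-4)
        assert c.df == pytest.approx(4.0, abs=1e-9)
        assert c.p_value == pytest.approx(0.2879, abs=2e-4)

    def test_identical_groups(self):
        c = cp.welch_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert c.t_statistic == 0.0
        assert c.p_value == pytest.approx(1.0)

    def test_equal_variance_equal_n_reduces_to_student(self):
        """With equal group sizes and variances, Welch's statistic equals the
        pooled Student's t exactly."""
        rng = np.random.default_rng(4)
        a = rng.normal(0, 1, 30)
        b = rng.normal(0.5, 1, 30)
        ours = cp.welch_test(a, b)
        pooled = stats.ttest_ind(a, b, equal_var=True)
        assert ours.t_statistic == pytest.approx(pooled.statistic, rel=1e-12)

    def test_matches_reference_unequal_variance_implementation(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0, 1, 17)
        b = rng.normal(0.3, 2.5, 41)
        ours = cp.welch_test(a, b)
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert ours.t_statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-9)
        assert ours.df == pytest.approx(ref.df, rel=1e-12)

    def test_degenerate_group_rejected(self):
        with pytest.raises(ValueError, match="group b"):
            cp.welch_test([1, 2, 3], [4])

    def test_null_p_values_uniform(self):
        """Type-I calibration: under the null, p-values over 200 seeded
        replicates are uniform (KS test at alpha = 0.01)."""
        rng = np.random.default_rng(123)
        pvals = [
            cp.welch_test(rng.normal(size=25), rng.normal(size=25)).p_value
            for _ in range(200)
        ]
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestBoxStats:
    def test_whiskers_follow_iqr_rule(self):
        b = cp.box_stats([1, 2, 3, 4, 100])
        q1, q3 = np.percentile([1, 2, 3, 4, 100], [25, 75])
        assert b["whisker_high"] == pytest.approx(q3 + 1.5 * (q3 - q1))
        assert b["whisker_low"] == pytest.approx(q1 - 1.5 * (q3 - q1))
        assert b["n_outliers"] == 1


def _cohort_adata(expr_rows, patients, malignant, genes):
    X = np.asarray(expr_rows, dtype=float)
    obs = pd.DataFrame(
        {"patient_id": patients, "malignant": malignant},
        index=[f"c{i:03d}" for i in range(len(patients))],
    )
    return ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=pd.Index(list(genes))))


class TestPatientReport:
    def test_implanted_shift_detected(self):
        """A +2 SD malignant shift with 100 cells per arm is significant."""
        rng = np.random.default_rng(9)
        rows = []
        for pid in ("P1", "P2"):
            non = rng.normal(5.0, 1.0, 100)
            mal = rng.normal(7.0, 1.0, 100)
            for v, m in [(non, 0), (mal, 1)]:
                for x in v:
                    rows.append({"cell_id": f"{pid}{m}{len(rows)}", "patient_id": pid,
                                 "malignant": m, "status": "stable", "H2O2": x})
        comps, boxes = cp.patient_report(pd.DataFrame(rows))
        assert (comps["p_value"] < 0.05).all()
        assert set(boxes["group"]) == {"malignant", "non_malignant"}

    def test_single_class_patient_excluded(self):
        rng = np.random.default_rng(10)
        rows = [
            {"cell_id": f"c{i}", "patient_id": "P1", "malignant": 1,
             "status": "stable", "H2O2": x}
            for i, x in enumerate(rng.normal(5, 1, 10))
        ]
        rows += [
            {"cell_id": f"d{i}", "patient_id": "P2", "malignant": m,
             "status": "stable", "H2O2": x}
            for i, (x, m) in enumerate(zip(rng.normal(5, 1, 10), [0, 1] * 5))
        ]
        comps, _ = cp.patient_report(pd.DataFrame(rows))
        assert list(comps["patient_id"]) == ["P2"]


@pytest.fixture(scope="module")
def tiny_cohort(default_net):
    """Six identical-expression cells: everything sits at the cohort mean."""
    genes = sd.MAPPED_GENES
    row = np.full(len(genes), 5.0)
    return _cohort_adata(
        [row] * 6, ["P1"] * 6, [0, 0, 0, 1, 1, 1], genes
    )


class TestRunCohort:
    def test_identical_average_cells_identical_endpoints(self, default_net, tiny_cohort):
        eps = cp.run_cohort(tiny_cohort, default_net, dose=1e-5)
        assert (eps["status"] == "stable").all()
        for col in ("H2O2", "NADPH:NADP", "TrxSH:TrxSS", "GSH:GSSG"):
            assert eps[col].nunique() == 1

    def test_zero_dose_matches_drug_free_baseline(self, default_net, tiny_cohort,
                                                  resting_state, fast_settings):
        eps = cp.run_cohort(
            tiny_cohort, default_net, dose=0.0, baseline_state=resting_state
        )
        h_i = default_net.species_index("H2O2")
        assert eps["H2O2"].iloc[0] == pytest.approx(resting_state[h_i], rel=0.01)

    def test_rerun_is_bit_identical(self, default_net, tiny_cohort):
        a = cp.run_cohort(tiny_cohort, default_net, dose=1e-5)
        b = cp.run_cohort(tiny_cohort, default_net, dose=1e-5)
        pd.testing.assert_frame_equal(a, b)

    def test_input_order_does_not_change_output(self, default_net):
        rng = np.random.default_rng(2)
        genes = sd.MAPPED_GENES
        X = rng.uniform(1, 9, size=(6, len(genes)))
        adata = _cohort_adata(X, ["P1"] * 6, [0, 0, 0, 1, 1, 1], genes)
        shuffled = adata[rng.permutation(adata.n_obs)].copy()
        a = cp.run_cohort(adata, default_net, dose=1e-5)
        b = cp.run_cohort(shuffled, default_net, dose=1e-5)
        pd.testing.assert_frame_equal(a, b)

    def test_drug_activation_orders_h2o2(self, default_net, resting_state):
        """A cell with floored NQO1 produces less H2O2 than one at 5x the
        cohort average, all else equal."""
        genes = sd.MAPPED_GENES
        base = np.full(len(genes), 5.0)
        low, high = base.copy(), base.copy()
        i = genes.index("NQO1")
        low[i], high[i] = 0.0, 25.0
        # include average cells so the cohort mean stays near 5
        adata = _cohort_adata(
            [base, base, base, base, low, high],
            ["P1"] * 6, [0, 0, 0, 0, 1, 1], genes,
        )
        eps = cp.run_cohort(
            adata, default_net, dose=1e-5, baseline_state=resting_state
        ).set_index("cell_id")
        assert eps.loc["c004", "H2O2"] < eps.loc["c005", "H2O2"]

    def test_h2o2_span_grows_with_expression_dispersion(self, default_net, resting_state):
        """The order-of-magnitude span of endpoint H2O2 shrinks as the
        cohort's expression dispersion goes to zero."""
        spans = []
        for disp in (0.8, 0.3, 0.05):
            design = sd.CohortDesign(
                n_patients=2, cells_per_patient_per_class=8,
                dispersion=disp, patient_sd=0.0, dropout=0.0, seed=3,
            )
            adata, _ = sd.generate_cohort(design)
            eps = cp.run_cohort(adata, default_net, baseline_state=resting_state)
            h = eps.loc[eps["status"] == "stable", "H2O2"]
            spans.append(float(np.log10(h.max() / h.min())))
        assert spans[0] > spans[1] > spans[2]
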