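"""Agreement statistics against hand-computed and independent oracles."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from adpkdvol.image_io import LabelMap
from adpkdvol.metrics import (
    bland_altman,
    concordance,
    dsc,
    evaluate_run,
    icc,
    interobserver_sd,
    mean_percent_error,
    organ_volume,
    rmse,
    volume_report,
    zero_error_count,
)


def make_label_map(counts: dict[int, int], spacing=(1.0, 1.0, 1.0), shape=(12, 12, 12)):
    data = np.zeros(int(np.prod(shape)), dtype=np.uint8)
    pos = 0
    for label, n in counts.items():
        data[pos : pos + n] = label
        pos += n
    return LabelMap(data.reshape(shape), spacing)


class TestOrganVolume:
    def test_hand_arithmetic(self):
        lab = make_label_map({1: 2000}, spacing=(1.25, 1.25, 5.0), shape=(20, 20, 20))
        assert organ_volume(lab, 1) == pytest.approx(15.625)

    def test_absent_label_is_zero(self):
        assert organ_volume(make_label_map({1: 10}), 3) == 0.0

    def test_volume_report_tkv_identity(self):
        rep = volume_report(make_label_map({1: 100, 2: 80, 3: 10, 4: 20}))
        assert rep.tkv_ml == rep.right_kidney_ml + rep.left_kidney_ml
        assert rep.tkv_ml == pytest.approx(0.18)


class TestDSC:
    def test_self_agreement_is_one(self):
        m = np.random.default_rng(0).random((8, 8, 8)) > 0.5
        assert dsc(m, m) == 1.0

    def test_disjoint_nonempty_is_zero(self):
        a = np.zeros(10, bool); a[:3] = True
        b = np.zeros(10, bool); b[5:] = True
        assert dsc(a, b) == 0.0

    def test_hand_count(self):
        a = np.array([1, 1, 1, 1, 0, 0], bool)
        b = np.array([1, 1, 0, 0, 0, 0], bool)
        assert dsc(a, b) == pytest.approx(2 * 2 / 6)

    def test_both_empty_is_perfect_agreement(self):
        z = np.zeros(5, bool)
        assert dsc(z, z) == 1.0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_symmetry_and_range(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.random(50) > rng.random()
        b = rng.random(50) > rng.random()
        d = dsc(a, b)
        assert d == dsc(b, a)
        assert 0.0 <= d <= 1.0


class TestConcordance:
    def test_identity_is_one(self):
        x = np.array([1.0, 2.0, 5.0])
        assert concordance(x, x) == pytest.approx(1.0)

    def test_location_shift_penalized_unlike_pearson(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = x + 10.0
        assert concordance(x, y) < 1.0
        assert np.corrcoef(x, y)[0, 1] == pytest.approx(1.0)

    def test_hand_evaluation(self):
        # population moments: s_xy=1, s_x2=2/3, s_y2=14/9, (dmean)^2=1/9 -> 6/7
        assert concordance([1, 2, 3], [1, 2, 4]) == pytest.approx(6 / 7)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError):
            concordance([2.0, 2.0], [2.0, 2.0])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_lin_inequality_vs_pearson(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, 30)
        y = 0.5 * x + rng.normal(0, 1, 30)
        assert abs(concordance(x, y)) <= abs(np.corrcoef(x, y)[0, 1]) + 1e-12


class TestErrorMetrics:
    def test_identical_series_zero(self):
        x = np.array([100.0, 250.0])
        assert rmse(x, x) == 0.0
        assert mean_percent_error(x, x) == 0.0

    def test_rmse_hand_value(self):
        assert rmse([100.0, 200.0], [110.0, 190.0]) == pytest.approx(10.0)

    def test_percent_error_hand_value(self):
        assert mean_percent_error([200.0], [210.0]) == pytest.approx(5.0)

    def test_percent_error_scale_invariant(self):
        x = np.array([100.0, 400.0])
        y = np.array([110.0, 360.0])
        assert mean_percent_error(x, y) == pytest.approx(mean_percent_error(3 * x, 3 * y))

    def test_zero_truth_rejected(self):
        with pytest.raises(ValueError):
            mean_percent_error([0.0], [10.0])

    def test_rmse_zero_iff_identical(self):
        assert rmse([1.0, 2.0], [1.0, 2.0 + 1e-9]) > 0.0


class TestZeroErrorCount:
    def test_identical_series(self):
        x = np.arange(7, dtype=float)
        assert zero_error_count(x, x) == 7

    def test_sub_milliliter_difference_counts(self):
        assert zero_error_count([608.4], [608.2]) == 1

    def test_rounding_to_different_milliliters_does_not_count(self):
        assert zero_error_count([608.4], [609.6]) == 0


class TestBlandAltman:
    def test_identity_zero_bias_zero_width(self):
        x = np.array([100.0, 200.0, 300.0])
        ba = bland_altman(x, x)
        assert ba.bias == 0.0
        assert ba.lower_limit == ba.upper_limit == 0.0

    def test_positive_offset_gives_positive_bias(self):
        x = np.array([100.0, 200.0, 300.0])
        assert bland_altman(x, x + 10).bias > 0.0

    def test_limits_capture_95_percent_of_simulated_differences(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(200, 2000, 500)
        y = x * (1 + rng.normal(0, 0.05, 500))
        ba = bland_altman(x, y)
        inside = (ba.diffs_percent >= ba.lower_limit) & (ba.diffs_percent <= ba.upper_limit)
        assert 0.93 <= inside.mean() <= 0.97


class TestInterobserver:
    def test_hand_sd(self):
        assert interobserver_sd(np.array([[100.0, 110.0, 120.0]])) == pytest.approx(10.0)

    def test_identical_observers_zero(self):
        m = np.tile(np.array([[500.0], [700.0]]), (1, 3))
        assert interobserver_sd(m) == 0.0

    def test_monotone_with_simulated_boundary_noise(self):
        from adpkdvol.phantom import (
            OrganEllipsoid,
            PhantomSpec,
            generate_phantom,
            simulate_observer,
            truth_volume_ml,
        )

        spec = PhantomSpec(
            grid_shape=(48, 48, 24),
            spacing_mm=(3.0, 3.0, 4.0),
            organ_params={
                "right_kidney": OrganEllipsoid((40.0, 70.0, 48.0), (28.0, 22.0, 36.0), 110.0),
                "left_kidney": OrganEllipsoid((104.0, 70.0, 48.0), (28.0, 22.0, 36.0), 110.0),
            },
            cyst_params={},
            noise_sd=0.0,
        )
        truth = generate_phantom(spec).truth
        sds = []
        for noise in (2.0, 6.0):
            obs = np.array(
                [
                    [truth_volume_ml(simulate_observer(truth, noise, seed=s), 1) for s in (1, 2, 3)],
                    [truth_volume_ml(simulate_observer(truth, noise, seed=s), 2) for s in (4, 5, 6)],
                ]
            )
            sds.append(interobserver_sd(obs))
        assert sds[1] > sds[0] > 0


def icc21_anova_oracle(m):
    """From-scratch variance-components computation of ICC(2,1)."""
    m = np.asarray(m, float)
    n, k = m.shape
    grand = m.mean()
    msr = k * sum((row.mean() - grand) ** 2 for row in m) / (n - 1)
    msc = n * sum((m[:, j].mean() - grand) ** 2 for j in range(k)) / (k - 1)
    sse = sum(
        (m[i, j] - m[i].mean() - m[:, j].mean() + grand) ** 2
        for i in range(n)
        for j in range(k)
    )
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestICC:
    def test_identical_observers_heterogeneous_cases(self):
        m = np.tile(np.array([[100.0], [500.0], [900.0]]), (1, 3))
        assert icc(m) == pytest.approx(1.0)

    def test_case_independent_observers_near_zero(self):
        rng = np.random.default_rng(1)
        m = rng.normal(500, 50, (200, 3))  # no case effect at all
        assert abs(icc(m)) < 0.2

    def test_hand_table_matches_anova_oracle(self):
        m = np.array([[9.0, 2.0, 5.0], [6.0, 1.0, 3.0], [8.0, 4.0, 6.0]])
        assert icc(m) == pytest.approx(icc21_anova_oracle(m), abs=1e-12)

    def test_matches_pingouin_icc2(self):
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(2)
        case = rng.normal(0, 10, 40)
        m = case[:, None] + rng.normal(0, 3, (40, 3)) + np.array([0.0, 1.0, -1.0])
        long = pd.DataFrame(
            {
                "case": np.repeat(np.arange(40), 3),
                "rater": np.tile(np.arange(3), 40),
                "y": m.ravel(),
            }
        )
        table = pg.intraclass_corr(long, targets="case", raters="rater", ratings="y")
        # absolute-agreement single-rater row (a.k.a. ICC(2,1))
        ref = float(table.set_index("Type").loc["ICC(A,1)", "ICC"])
        assert icc(m) == pytest.approx(ref, abs=1e-9)

    def test_parameter_recovery_within_5_points(self):
        rng = np.random.default_rng(3)
        s_case, s_rater, s_noise = 10.0, 2.0, 5.0
        true_icc = s_case**2 / (s_case**2 + s_rater**2 + s_noise**2)
        m = (
            rng.normal(0, s_case, (200, 1))
            + rng.normal(0, s_rater, (1, 3))
            + rng.normal(0, s_noise, (200, 3))
        )
        assert icc(m) == pytest.approx(true_icc, abs=0.05)

    def test_too_small_tables_rejected(self):
        with pytest.raises(ValueError):
            icc(np.ones((1, 3)))
        with pytest.raises(ValueError):
            icc(np.ones((3, 1)))


class TestEvaluateRun:
    def test_perfect_predictions(self):
        truths = [make_label_map({1: 50, 2: 40, 3: 30, 4: 60}) for _ in range(3)]
        report = evaluate_run(truths, truths)
        assert (report.table["dsc"] == 1.0).all()
        assert (report.table["rmse_ml"] == 0.0).all()
        assert (report.table["mean_percent_error"] == 0.0).all()
        assert (report.table["zero_error_count"] == 3).all()

    def test_single_case_concordance_undefined_but_rest_computed(self):
        t = [make_label_map({1: 50, 2: 40, 3: 30, 4: 60})]
        report = evaluate_run(t, t)
        assert report.table["concordance"].isna().all()
        assert (report.table["dsc"] == 1.0).all()

    def test_report_schema_and_ranges(self, e2e_report):
        table = e2e_report.agreement.table
        assert set(table["organ"]) == {"right_kidney", "left_kidney", "spleen", "liver"}
        assert table["dsc"].between(0, 1).all()
        assert (table["rmse_ml"] >= 0).all()
        for col in ("concordance", "mean_percent_error", "zero_error_count",
                    "ba_bias_percent", "ba_lower_percent", "ba_upper_percent"):
            assert col in table.columns
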