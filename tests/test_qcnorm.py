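import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phosflow.io import ChannelMap
from phosflow.qcnorm import (
    FilterThresholds,
    InsufficientDataError,
    QuantMatrix,
    filter_psms,
    group_duplicate_psms,
    kde_mode,
    normalize_constrained,
)

from conftest import make_psm


class TestFilterPsms:
    def test_each_threshold_is_strict(self):
        # boundary values fail; just-inside values pass
        base = dict(ion_score=15.0, interference=30.0, fdr=1e-2,
                    tmt=(1500.0,) * 6)
        assert filter_psms([make_psm(**base)])[0] == []
        ok = make_psm(ion_score=15.01, interference=29.99, fdr=0.0099,
                      tmt=(1500.01,) * 6)
        assert filter_psms([ok])[0] == [ok]

    @pytest.mark.parametrize("kwargs,criterion", [
        (dict(ion_score=14.0), "ion_score"),
        (dict(interference=45.0), "isolation_interference"),
        (dict(tmt=(100.0,) * 6), "median_tmt"),
        (dict(fdr=0.5), "percolator_fdr"),
    ])
    def test_removal_attributed_to_first_failing_criterion(self, kwargs,
                                                           criterion):
        retained, report = filter_psms([make_psm(**kwargs)])
        assert retained == []
        assert report.removed[criterion] == 1
        assert report.n_removed == 1

    def test_transgenic_exempt_from_fdr_only(self):
        tg = make_psm(fdr=0.5, transgenic=True)
        retained, report = filter_psms([tg])
        assert retained == [tg]
        # the exemption does not cover the other criteria
        tg_low = make_psm(fdr=0.5, transgenic=True, ion_score=10.0)
        assert filter_psms([tg_low])[0] == []

    def test_all_passing_report_zeroed(self):
        psms = [make_psm(scan_id=f"s{i}") for i in range(100)]
        retained, report = filter_psms(psms)
        assert len(retained) == 100
        assert all(v == 0 for v in report.removed.values())

    def test_empty_input(self):
        retained, report = filter_psms([])
        assert retained == [] and report.n_input == 0

    def test_missing_quality_value_fails_that_criterion(self):
        psm = make_psm(ion_score=float("nan"))
        retained, report = filter_psms([psm])
        assert retained == [] and report.removed["ion_score"] == 1

    @given(st.floats(min_value=0, max_value=30))
    @settings(max_examples=25, deadline=None)
    def test_relaxing_ion_score_threshold_is_monotone(self, cutoff):
        psms = [make_psm(scan_id=f"s{i}", ion_score=s)
                for i, s in enumerate(np.linspace(0, 60, 30))]
        strict, _ = filter_psms(psms, FilterThresholds())
        relaxed, _ = filter_psms(
            psms, FilterThresholds(min_ion_score=min(cutoff, 15.0)))
        assert len(relaxed) >= len(strict)


class TestKdeMode:
    def test_symmetric_unimodal_sample(self):
        values = 2.0 + np.linspace(-1, 1, 1001) ** 3  # symmetric about 2
        assert kde_mode(values) == pytest.approx(2.0, abs=1e-2)

    def test_degenerate_constant(self):
        assert kde_mode(np.full(10, 5.0)) == 5.0

    def test_too_few_values(self):
        with pytest.raises(InsufficientDataError):
            kde_mode([1.0, 2.0])

    def test_bimodal_matches_dense_grid_oracle(self, rng):
        from scipy.stats import gaussian_kde
        values = np.concatenate([rng.normal(1.0, 0.15, 900),
                                 rng.normal(4.0, 0.15, 100)])
        grid = np.linspace(values.min(), values.max(), 200001)
        kde = gaussian_kde(values)  # Scott bandwidth, as in kde_mode
        oracle = grid[np.argmax(kde(grid))]
        assert kde_mode(values) == pytest.approx(oracle, abs=1e-3)
        assert abs(kde_mode(values) - 1.0) < 0.1

    def test_scale_equivariance(self, rng):
        values = rng.lognormal(0, 0.4, 400)
        m = kde_mode(values)
        assert kde_mode(values * 3.7) == pytest.approx(3.7 * m, rel=1e-9)


def _matrix(values):
    values = np.asarray(values, dtype=float)
    return QuantMatrix([f"r{i}" for i in range(values.shape[0])], values,
                       ChannelMap.trivial(values.shape[1]))


class TestNormalizeConstrained:
    def test_all_ones_fixed_point(self):
        out, diag = normalize_constrained(_matrix(np.ones((5, 4))))
        np.testing.assert_array_equal(out.values, np.ones((5, 4)))
        assert diag.converged and diag.n_iterations == 1

    def test_row_means_one_for_separable_matrix(self, rng):
        base = rng.uniform(1e3, 1e6, 200)
        scales = rng.uniform(0.5, 2.0, 6)
        out, diag = normalize_constrained(_matrix(np.outer(base, scales)))
        assert diag.converged
        np.testing.assert_allclose(out.values.mean(axis=1), 1.0, atol=1e-6)
        modes = [kde_mode(out.values[:, j]) for j in range(6)]
        np.testing.assert_allclose(modes, 1.0, atol=1e-4)

    def test_idempotent_on_converged_output(self, rng):
        base = rng.uniform(1e3, 1e6, 100)
        out, _ = normalize_constrained(
            _matrix(np.outer(base, rng.uniform(0.5, 2.0, 5))))
        again, diag = normalize_constrained(out)
        assert diag.converged
        assert np.abs(again.values - out.values).max() <= 1e-6

    def test_noisy_matrix_flagged_not_raised(self, rng):
        vals = rng.lognormal(0, 0.3, (60, 6))
        with pytest.warns(RuntimeWarning, match="did not converge"):
            out, diag = normalize_constrained(_matrix(vals))
        assert not diag.converged
        assert out.normalized  # result still returned

    def test_nonpositive_entry_rejected(self):
        vals = np.ones((3, 3))
        vals[1, 1] = 0.0
        with pytest.raises(ValueError, match="positive"):
            normalize_constrained(_matrix(vals))

    def test_planted_channel_scales_recovered_proportionally(self, rng):
        planted = np.linspace(0.5, 2.0, 6)
        base = 10 ** rng.uniform(3, 6, 400)
        sigma = np.sqrt(np.log(1 + 0.05 ** 2))
        noise = np.exp(rng.normal(0, sigma, (400, 6)))
        with pytest.warns(RuntimeWarning):
            _, diag = normalize_constrained(
                _matrix(base[:, None] * planted[None, :] * noise))
        ratio = diag.col_factors / planted
        assert np.abs(ratio / ratio.mean() - 1).max() < 0.05


class TestGroupDuplicatePsms:
    def test_worked_weighted_mean_example(self):
        # 100 @ 0% interference and 200 @ 50%:
        # (100*1 + 200*0.5) / (1 + 0.5) = 133.33...
        a = make_psm(scan_id="a", interference=0.0, tmt=(100.0,) * 6)
        b = make_psm(scan_id="b", interference=50.0, tmt=(200.0,) * 6)
        qm = group_duplicate_psms([a, b])
        assert qm.shape == (1, 6)
        np.testing.assert_allclose(qm.values, 400.0 / 3.0)

    def test_single_psm_passthrough(self):
        p = make_psm(interference=20.0, tmt=(10, 20, 30, 40, 50, 60))
        qm = group_duplicate_psms([p])
        np.testing.assert_array_equal(qm.values[0], p.tmt_intensities)

    def test_idempotence_equal_values_equal_interference(self):
        a = make_psm(scan_id="a", interference=10.0, tmt=(77.0,) * 6)
        b = make_psm(scan_id="b", interference=10.0, tmt=(77.0,) * 6)
        np.testing.assert_allclose(group_duplicate_psms([a, b]).values, 77.0)

    def test_order_invariance(self, rng):
        psms = [make_psm(scan_id=f"s{i}",
                         interference=float(rng.uniform(0, 90)),
                         tmt=tuple(rng.uniform(10, 1000, 6)))
                for i in range(6)]
        fwd = group_duplicate_psms(psms)
        rev = group_duplicate_psms(psms[::-1])
        np.testing.assert_allclose(fwd.values, rev.values, rtol=1e-12)

    def test_weighted_mean_within_value_range(self, rng):
        for _ in range(50):
            psms = [make_psm(scan_id=f"s{i}",
                             interference=float(rng.uniform(0, 99)),
                             tmt=tuple(rng.uniform(1, 1e5, 6)))
                    for i in range(4)]
            grouped = group_duplicate_psms(psms).values[0]
            stack = np.array([p.tmt_intensities for p in psms])
            assert (grouped >= stack.min(axis=0) - 1e-9).all()
            assert (grouped <= stack.max(axis=0) + 1e-9).all()

    def test_all_interfered_group_dropped_with_warning(self):
        a = make_psm(scan_id="a", interference=100.0)
        b = make_psm(scan_id="b", interference=100.0)
        with pytest.warns(RuntimeWarning, match="fully interfered"):
            qm = group_duplicate_psms([a, b])
        assert qm.shape[0] == 0

    def test_distinct_localizations_not_grouped(self):
        a = make_psm(scan_id="a", sequence="SVYTEIK",
                     sites=(("Y", 3, 0.99),))
        b = make_psm(scan_id="b", sequence="SVYTEIK",
                     sites=(("T", 4, 0.99),))
        assert group_duplicate_psms([a, b]).shape[0] == 2
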