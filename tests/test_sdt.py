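"""Rate corrections and same-different sensitivity models.

Frozen expected values come from standard normal-quantile table constants
(e.g. z(0.9) = 1.2815515655446) and hand arithmetic on the forward
equations; Monte-Carlo agreement with each model's decision rule is
checked at larger scale in the acceptance suite.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from encodelearn import sdt
from encodelearn.sdt import (
    DegenerateRateError,
    ModelRangeError,
    correct_rates,
    dprime_samediff_differencing,
    dprime_samediff_independent,
    dprime_yesno,
    forward_differencing,
    forward_independent,
    pc_max_independent,
    sensitivity_table,
)


class TestCorrections:
    def test_symmetric_half_is_half(self):
        for method in ("none", "half_count", "log_linear"):
            r = correct_rates(15, 15, 30, 30, method)
            assert r.h == pytest.approx(0.5 if method != "log_linear"
                                        else 15.5 / 31)

    def test_half_count_ceiling(self):
        r = correct_rates(30, 0, 30, 30, "half_count")
        assert r.h == pytest.approx(59 / 60)  # 1 - 1/(2*30)
        assert r.f == pytest.approx(1 / 60)

    def test_log_linear_floor(self):
        r = correct_rates(0, 0, 30, 30, "log_linear")
        assert r.h == pytest.approx(0.5 / 31)

    def test_none_flags_degenerate(self):
        r = correct_rates(30, 5, 30, 30, "none")
        assert r.h == 1.0 and r.degenerate

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            correct_rates(31, 0, 30, 30)
        with pytest.raises(ValueError):
            correct_rates(1, 0, 0, 30)


class TestYesNo:
    def test_equal_rates_give_zero(self):
        assert dprime_yesno(0.3, 0.3).dprime == pytest.approx(0.0)

    def test_table_values(self):
        # 2 * z(0.9), frozen from quantile tables
        assert dprime_yesno(0.9, 0.1).dprime == pytest.approx(
            2.5631031310892007, abs=1e-9)
        # half-count ceiling of a 30-trial cell: 2 * z(59/60)
        assert dprime_yesno(59 / 60, 1 / 60).dprime == pytest.approx(
            4.256090468369966, abs=1e-9)

    def test_criterion_value(self):
        # c = -(z(.9) + z(.4))/2 with z(.9)=1.28155, z(.4)=-0.25335
        est = dprime_yesno(0.9, 0.4)
        assert est.criterion == pytest.approx(-0.5141022312044004, abs=1e-9)
        assert est.criterion < 0  # liberal observer

    def test_antisymmetry_property(self):
        for h, f in [(0.7, 0.2), (0.55, 0.4), (0.95, 0.9)]:
            assert dprime_yesno(h, f).dprime == pytest.approx(
                -dprime_yesno(f, h).dprime, abs=1e-12)

    def test_domain_error_mentions_correction(self):
        with pytest.raises(DegenerateRateError, match="correction"):
            dprime_yesno(1.0, 0.1)


class TestDifferencing:
    def test_equal_rates_give_zero(self):
        assert dprime_samediff_differencing(0.4, 0.4).dprime == 0.0

    def test_worked_example(self):
        # forward at d'=2, k = -sqrt(2) z(0.1) = 1.81239 gives h = 0.55628
        est = dprime_samediff_differencing(0.5562810086218432, 0.2)
        assert est.dprime == pytest.approx(2.0, abs=1e-7)
        assert est.criterion == pytest.approx(1.8123876048736465, abs=1e-9)

    def test_roundtrip_on_grid(self):
        for d in (0.25, 1.0, 2.5, 4.0):
            for k in (0.5, 1.5, 3.0):
                h, f = forward_differencing(d, k)
                if h <= f or not (0 < f < h < 1):
                    continue
                est = dprime_samediff_differencing(h, f)
                h2, f2 = forward_differencing(est.dprime, est.criterion)
                assert (h2, f2) == pytest.approx((h, f), abs=1e-6)

    def test_signed_mirror(self):
        est = dprime_samediff_differencing(0.2, 0.5562810086218432,
                                           signed=True)
        assert est.dprime == pytest.approx(-2.0, abs=1e-7)


class TestIndependentObservation:
    def test_equal_rates_give_zero(self):
        assert dprime_samediff_independent(0.3, 0.3).dprime == 0.0

    def test_unbiased_closed_form(self):
        # pc_max(2) = Phi(1)^2 + Phi(-1)^2 = 0.733032
        assert pc_max_independent(2.0) == pytest.approx(0.7330324713371961,
                                                        abs=1e-12)
        h, f = forward_independent(2.0, 1.0)  # unbiased criterion d'/2
        assert h == pytest.approx(0.7330324713371961, abs=1e-12)
        assert (h + 1 - f) / 2 == pytest.approx(pc_max_independent(2.0),
                                                abs=1e-12)

    def test_roundtrip_on_grid(self):
        for d in (0.5, 1.5, 3.0, 4.5):
            for k_off in (-0.4, 0.2, 0.8):
                k = d / 2 + k_off
                h, f = forward_independent(d, k)
                if not (0 < f < h < 1):
                    continue
                est = dprime_samediff_independent(h, f)
                assert est.dprime == pytest.approx(d, abs=1e-9)
                h2, f2 = forward_independent(est.dprime, est.criterion)
                assert (h2, f2) == pytest.approx((h, f), abs=1e-9)

    def test_monotone_along_unbiased_manifold(self):
        # rate pairs generated by increasing d' at the unbiased criterion
        ds_in = np.arange(0.2, 5.0, 0.2)
        ds_out = []
        for d in ds_in:
            h, f = forward_independent(d, d / 2)
            ds_out.append(dprime_samediff_independent(h, f).dprime)
        assert np.all(np.diff(ds_out) > 0)
        assert ds_out == pytest.approx(list(ds_in), abs=1e-9)

    def test_boundary_estimate_monotone_in_h(self):
        # off-manifold pairs resolve through pc, monotone in h for fixed f
        f = 0.3
        ds = [dprime_samediff_independent(h, f).dprime
              for h in np.arange(0.75, 0.99, 0.02)]  # h + f > 1 region
        assert np.all(np.diff(ds) > 0)

    def test_off_manifold_continuity(self):
        # crossing h + f = 1 changes the estimate continuously
        lo = dprime_samediff_independent(0.90, 0.1 - 1e-9).dprime
        hi = dprime_samediff_independent(0.90, 0.1 + 1e-9).dprime
        assert lo == pytest.approx(hi, abs=1e-3)

    def test_off_manifold_uses_unbiased_boundary(self):
        est = dprime_samediff_independent(0.95, 0.10)
        assert est.criterion == pytest.approx(est.dprime / 2)
        assert est.dprime > 0

    def test_signed_mirror(self):
        plus = dprime_samediff_independent(0.6, 0.3).dprime
        minus = dprime_samediff_independent(0.3, 0.6, signed=True).dprime
        assert minus == pytest.approx(-plus, abs=1e-12)

    @settings(deadline=None, max_examples=60)
    @given(st.floats(0.05, 6.0), st.floats(-1.0, 1.0))
    def test_inversion_identity_property(self, d, k_off):
        k = d / 2 + k_off
        h, f = forward_independent(d, k)
        if not (1e-9 < f < h < 1 - 1e-9):
            return
        est = dprime_samediff_independent(h, f)
        assert est.dprime == pytest.approx(d, abs=1e-6)


class TestMonteCarlo:
    """Moderate-n agreement between forward equations and their rules."""

    N = 200_000

    def test_independent_rule(self):
        rng = np.random.default_rng(11)
        d, k = 1.8, 1.2
        x1 = rng.normal(0, 1, self.N)       # class-1 observation
        x2 = rng.normal(d, 1, self.N)       # class-2 observation
        hit = (x1 > k) != (x2 > k)          # categorizations disagree
        same1 = (rng.normal(0, 1, self.N // 2) > k) != \
                (rng.normal(0, 1, self.N // 2) > k)
        same2 = (rng.normal(d, 1, self.N // 2) > k) != \
                (rng.normal(d, 1, self.N // 2) > k)
        h_mc = hit.mean()
        f_mc = np.concatenate([same1, same2]).mean()
        h, f = forward_independent(d, k)
        assert h_mc == pytest.approx(h, abs=3 * np.sqrt(h * (1 - h) / self.N))
        assert f_mc == pytest.approx(f, abs=3 * np.sqrt(f * (1 - f) / self.N))

    def test_differencing_rule(self):
        rng = np.random.default_rng(12)
        d, k = 2.0, 1.8123876048736465
        diff_pairs = np.abs(rng.normal(0, 1, self.N)
                            - rng.normal(d, 1, self.N)) > k
        same_pairs = np.abs(rng.normal(0, 1, self.N)
                            - rng.normal(0, 1, self.N)) > k
        h, f = forward_differencing(d, k)
        assert diff_pairs.mean() == pytest.approx(
            h, abs=3 * np.sqrt(h * (1 - h) / self.N))
        assert same_pairs.mean() == pytest.approx(
            f, abs=3 * np.sqrt(f * (1 - f) / self.N))


class TestSensitivityTable:
    def test_hand_built_cell(self, toy_trials):
        sens = sensitivity_table(toy_trials, model="yesno", correction="none",
                                 min_trials=4)
        row = sens.iloc[0]
        # h=0.75, f=0.25: d' = z(.75) - z(.25), frozen quantile arithmetic
        assert row.dprime == pytest.approx(1.3489795003921634, abs=1e-9)
        assert row.n_trials == 8 and not row.low_n

    def test_low_n_flag_and_missing_class(self, toy_trials):
        sens = sensitivity_table(toy_trials, min_trials=20)
        assert bool(sens.iloc[0].low_n)
        only_same = toy_trials.subset(
            toy_trials.frame["pair_type"] == "same", "same-only")
        sens2 = sensitivity_table(only_same, min_trials=2)
        assert np.isnan(sens2.iloc[0].dprime)
        assert "missing" in sens2.iloc[0].error

    def test_unknown_model(self, toy_trials):
        with pytest.raises(ValueError, match="model"):
            sensitivity_table(toy_trials, model="svm")

    def test_tsv_serialization(self, toy_trials, tmp_path):
        sens = sensitivity_table(toy_trials)
        sdt.write_sensitivity_tsv(sens, tmp_path / "s.tsv")
        header = (tmp_path / "s.tsv").read_text().splitlines()[0].split("\t")
        assert header[:4] == ["participant_id", "session_index",
                              "encoding_duration_ms", "n_trials"]
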