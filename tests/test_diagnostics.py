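import math

import numpy as np
import pytest
from scipy import stats

from tsmr.diagnostics import (cochran_q, f_statistic, i2_gx, leave_one_out,
                              simex_egger, steiger_filter, steiger_r2)
from tsmr.estimators import egger, ivw
from tsmr.exceptions import (ConfigurationError, InsufficientInstrumentsError,
                             MissingDataError)

from conftest import hset_from_arrays, make_record, make_table


class TestCochranQ:
    def test_zero_dispersion(self):
        h = hset_from_arrays([0.02, 0.04, 0.05], [0.004] * 3,
                             [0.01, 0.02, 0.025], [0.004] * 3)
        stats_ = cochran_q(h)
        assert stats_.q == pytest.approx(0.0, abs=1e-20)
        assert stats_.pval == pytest.approx(1.0)

    def test_hand_computed_two_snp_case(self):
        # ratios 0 and 1 with unit weights: ivw = 0.5, Q = 0.25 + 0.25 = 0.5
        h = hset_from_arrays([1.0, 1.0], [0.1, 0.1], [0.0, 1.0], [1.0, 1.0])
        stats_ = cochran_q(h)
        assert stats_.q == pytest.approx(0.5, abs=1e-12)
        assert stats_.df == 1
        assert stats_.pval == pytest.approx(float(stats.chi2.sf(0.5, 1)), abs=1e-12)

    def test_requires_two(self):
        with pytest.raises(InsufficientInstrumentsError):
            cochran_q(hset_from_arrays([1.0], [0.1], [0.1], [0.1]))

    def test_permutation_and_scale_properties(self, rng, random_hset):
        base = cochran_q(random_hset)
        k = random_hset.kept
        perm = rng.permutation(len(k))
        shuffled = hset_from_arrays(
            [k[i].beta_exp for i in perm], [k[i].se_exp for i in perm],
            [k[i].beta_out for i in perm], [k[i].se_out for i in perm])
        assert cochran_q(shuffled).q == pytest.approx(base.q, rel=1e-12)
        scaled = hset_from_arrays(
            [i.beta_exp for i in k], [i.se_exp for i in k],
            [3.0 * i.beta_out for i in k], [i.se_out for i in k])
        # scaling beta_out alone scales ratios by 3 at fixed weights -> Q x 9
        assert cochran_q(scaled).q == pytest.approx(9.0 * base.q, rel=1e-9)


class TestI2GX:
    def test_identical_betas_floor_at_zero(self):
        h = hset_from_arrays([0.05] * 4, [0.004] * 4, [0.01] * 4, [0.004] * 4)
        assert i2_gx(h) == 0.0

    def test_stated_formula_arithmetic(self):
        # build an instance and re-evaluate the formula independently
        bx = np.array([0.02, -0.03, 0.05, 0.045, 0.01])
        sx = np.array([0.004, 0.005, 0.003, 0.004, 0.006])
        h = hset_from_arrays(bx, sx, 0.1 * bx, sx)
        x = np.abs(bx)
        w = 1.0 / sx ** 2
        q = float((((x - (w * x).sum() / w.sum()) / sx) ** 2).sum())
        expected = max(0.0, (q - 4) / q)
        assert i2_gx(h) == pytest.approx(expected, abs=1e-12)

    def test_q100_n11_gives_090(self):
        # engineer Q_GX = 100 with 11 SNPs: equal SEs, dispersion fixed
        n = 11
        x = np.linspace(0.02, 0.06, n)
        ss = float(((x - x.mean()) ** 2).sum())
        s = math.sqrt(ss / 100.0)  # => Q = SS/s^2 = 100
        h = hset_from_arrays(x, np.full(n, s), 0.1 * x, np.full(n, 0.004))
        assert i2_gx(h) == pytest.approx(0.90, abs=1e-12)

    def test_monotone_in_exposure_precision(self):
        bx = np.array([0.02, 0.03, 0.05, 0.04])
        sx = np.array([0.01, 0.012, 0.008, 0.009])
        h1 = hset_from_arrays(bx, sx, 0.1 * bx, sx)
        h2 = hset_from_arrays(bx, sx / 10.0, 0.1 * bx, sx)
        assert i2_gx(h2) > i2_gx(h1)


class TestSimexEgger:
    def _noisy_set(self, rng, L=30, theta=0.1, nome_ratio=0.6):
        gamma = np.abs(rng.normal(0, 0.05, L)) + 0.02
        sx = nome_ratio * gamma / 2.0  # se_exp comparable to beta_exp
        sy = np.full(L, 0.002)
        bx = rng.normal(gamma, sx)
        by = rng.normal(theta * gamma, sy)
        return hset_from_arrays(bx, sx, by, sy)

    def test_no_measurement_error_equals_naive(self, random_hset):
        k = random_hset.kept
        h = hset_from_arrays([i.beta_exp for i in k], [0.0] * len(k),
                             [i.beta_out for i in k], [i.se_out for i in k])
        naive = egger(h)
        corrected = simex_egger(h, B=50, seed=3)
        assert corrected.beta == naive.beta
        assert corrected.intercept == naive.intercept

    def test_deterministic_given_seed(self, random_hset):
        a = simex_egger(random_hset, B=100, seed=11)
        b = simex_egger(random_hset, B=100, seed=11)
        assert (a.beta, a.se, a.intercept, a.intercept_se) == \
               (b.beta, b.se, b.intercept, b.intercept_se)

    def test_grid_validation(self, random_hset):
        with pytest.raises(ConfigurationError):
            simex_egger(random_hset, lambda_grid=[0.5, 1.0, 1.5])
        with pytest.raises(ConfigurationError):
            simex_egger(random_hset, lambda_grid=[0.0, 1.0])

    def test_reduces_nome_attenuation(self):
        # marked NOME violation (I2_GX ~ 0.7, inside the SIMEX reporting
        # band): the corrected slope should beat the naive Egger slope in
        # >= 80% of replicates
        theta, wins, reps = 0.1, 0, 200
        rng = np.random.default_rng(2024)
        for _ in range(reps):
            h = self._noisy_set(rng, L=50, nome_ratio=0.6, theta=theta)
            naive = egger(h)
            corrected = simex_egger(h, B=150, seed=int(rng.integers(1 << 31)))
            if abs(corrected.beta - theta) < abs(naive.beta - theta):
                wins += 1
        assert wins / reps >= 0.8


class TestSteiger:
    def test_stated_formula(self):
        rec = make_record(beta=0.05, se=0.01, n=10000.0)  # t = 5
        assert steiger_r2(rec) == pytest.approx(25.0 / 10023.0, abs=1e-10)

    def test_zero_beta(self):
        assert steiger_r2(make_record(beta=0.0)) == 0.0

    def test_balanced_binary_effective_n(self):
        rec = make_record(beta=0.05, se=0.01, n=None, n_case=5000.0,
                          n_control=5000.0, trait_type="binary")
        assert rec.effective_n() == pytest.approx(10000.0)
        assert steiger_r2(rec) == pytest.approx(25.0 / 10023.0, abs=1e-10)

    def test_missing_n_errors(self):
        with pytest.raises(MissingDataError):
            steiger_r2(make_record(n=None))

    def test_monotone_in_t(self):
        r2s = [steiger_r2(make_record(beta=b, se=0.01)) for b in (0.01, 0.02, 0.05)]
        assert r2s == sorted(r2s)

    def _tables_and_set(self, n_wrong=0):
        L = 10
        exp_records, out_records = [], []
        bx, sx, by, sy = [], [], [], []
        for i in range(L):
            snp = f"rs{i + 1}"
            strong, weak = 0.05, 0.005
            b_exp = weak if i < n_wrong else strong
            b_out = strong if i < n_wrong else weak
            exp_records.append(make_record(snp, beta=b_exp, se=0.004, n=50000.0))
            out_records.append(make_record(snp, beta=b_out, se=0.004, n=50000.0))
            bx.append(b_exp); sx.append(0.004); by.append(b_out); sy.append(0.004)
        return (make_table(exp_records, "X"), make_table(out_records, "Y"),
                hset_from_arrays(bx, sx, by, sy))

    def test_all_correct_is_noop(self):
        exposure, outcome, h = self._tables_and_set(n_wrong=0)
        filtered, report = steiger_filter(h, exposure, outcome)
        assert filtered.n_kept == h.n_kept
        assert all(r.correct_direction for r in report)

    def test_one_wrong_direction_removed(self):
        exposure, outcome, h = self._tables_and_set(n_wrong=1)
        filtered, report = steiger_filter(h, exposure, outcome)
        assert filtered.n_kept == 9
        assert sum(not r.correct_direction for r in report) == 1

    def test_exact_tie_kept_and_flagged(self):
        exposure = make_table([make_record("rs1", beta=0.05, n=50000.0)], "X")
        outcome = make_table([make_record("rs1", beta=0.05, n=50000.0)], "Y")
        h = hset_from_arrays([0.05], [0.01], [0.05], [0.01])
        filtered, report = steiger_filter(h, exposure, outcome)
        assert filtered.n_kept == 1
        assert report[0].tie and not report[0].correct_direction


class TestFStatistic:
    def test_arithmetic(self):
        h = hset_from_arrays([0.02], [0.004], [0.01], [0.004])
        s = f_statistic(h)
        assert s.f_per_snp[0] == pytest.approx(25.0, abs=1e-12)
        assert s.f_mean == pytest.approx(25.0)

    def test_zero_beta(self):
        h = hset_from_arrays([0.0, 0.02], [0.004, 0.004], [0.01, 0.01],
                             [0.004, 0.004])
        # zero exposure beta is dropped at the wald step, so build directly
        from tsmr.instruments import HarmonizedInstrument, HarmonizedSet
        inst = HarmonizedInstrument("rs1", 0.0, 0.004, 0.01, 0.004,
                                    ratio=0.0, ratio_se=1.0)
        s = f_statistic(HarmonizedSet("X", "Y", [inst]))
        assert s.f_per_snp[0] == 0.0

    def test_f_r2_algebraic_identity(self, rng):
        # F ~ r2 (n-2) / (1 - r2) for the same record
        for _ in range(25):
            beta = float(rng.uniform(0.01, 0.1))
            se = float(rng.uniform(0.002, 0.02))
            n = float(rng.integers(1000, 500000))
            rec = make_record(beta=beta, se=se, n=n)
            r2 = steiger_r2(rec)
            f_from_r2 = r2 * (n - 2) / (1 - r2)
            assert (beta / se) ** 2 == pytest.approx(f_from_r2, abs=1e-9)

    def test_total_r2_sums_steiger(self):
        records = [make_record(f"rs{i+1}", beta=0.05, se=0.01, n=10000.0)
                   for i in range(3)]
        exposure = make_table(records, "X")
        h = hset_from_arrays([0.05] * 3, [0.01] * 3, [0.01] * 3, [0.01] * 3)
        s = f_statistic(h, exposure)
        assert s.r2_exposure_total == pytest.approx(3 * 25.0 / 10023.0, abs=1e-10)


class TestLeaveOneOut:
    def test_cardinality_and_subset_consistency(self, random_hset):
        results = leave_one_out(random_hset)
        assert len(results) == random_hset.n_kept
        ids = random_hset.snp_ids()
        for omitted, estimate in results:
            sub = random_hset.subset([s for s in ids if s != omitted])
            ref = ivw(sub)
            assert estimate.beta == pytest.approx(ref.beta, abs=0)
            assert estimate.se == pytest.approx(ref.se, abs=0)

    def test_homogeneous_ratios_invariant(self):
        h = hset_from_arrays([0.02, 0.04, 0.05, 0.03], [0.004] * 4,
                             [0.01, 0.02, 0.025, 0.015], [0.004] * 4)
        full = ivw(h).beta
        for _, estimate in leave_one_out(h):
            assert estimate.beta == pytest.approx(full, abs=1e-12)

    def test_planted_outlier_moves_most(self, rng):
        bx = np.full(10, 0.05)
        sy = np.full(10, 0.002)
        by = 0.1 * bx + rng.normal(0, 1, 10) * sy * 0.5
        by[3] += 0.05  # outlier
        h = hset_from_arrays(bx, np.full(10, 0.004), by, sy)
        full = ivw(h).beta
        shifts = {omitted: abs(e.beta - full) for omitted, e in leave_one_out(h)}
        assert max(shifts, key=shifts.get) == "rs4"
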