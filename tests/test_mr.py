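import numpy as np
import pandas as pd
import pytest
from scipy import stats

from somnotype import mr


def _inst(bx, sx, by, sy, snp="rs"):
    return mr.MrInstrument(snp_id=snp, beta_exposure=bx, se_exposure=sx,
                           beta_outcome=by, se_outcome=sy)


def simulate_instruments(rng, n=50, effect=0.5, pleiotropy=0.0, se_exp=0.001, se_out=0.01):
    """No-pleiotropy (InSIDE-satisfying) two-sample model with strong
    instruments."""
    bx_true = rng.uniform(0.05, 0.2, size=n)
    bx = rng.normal(bx_true, se_exp)
    by = rng.normal(effect * bx_true + pleiotropy, se_out)
    return [
        _inst(bx[i], se_exp, by[i], se_out, snp=f"rs{i}")
        for i in range(n)
    ]


class TestWaldRatio:
    def test_definition(self):
        est, se = mr.wald_ratio(_inst(0.1, 0.01, 0.05, 0.01))
        assert est == pytest.approx(0.5)
        assert se == pytest.approx(0.1)

    def test_zero_outcome(self):
        est, _ = mr.wald_ratio(_inst(0.1, 0.01, 0.0, 0.01))
        assert est == 0.0

    def test_sign_flip_invariance(self, rng):
        for _ in range(20):
            bx, by = rng.normal(size=2)
            if abs(bx) < 1e-3:
                continue
            a = mr.wald_ratio(_inst(bx, 0.01, by, 0.02))
            b = mr.wald_ratio(_inst(-bx, 0.01, -by, 0.02))
            assert a == pytest.approx(b)

    def test_zero_exposure_raises(self):
        with pytest.raises(ValueError):
            mr.wald_ratio(_inst(0.0, 0.01, 0.1, 0.01))


class TestIvw:
    def test_single_instrument_reduces_to_wald(self):
        inst = _inst(0.1, 0.01, 0.05, 0.01)
        est = mr.ivw([inst])
        wald_est, wald_se = mr.wald_ratio(inst)
        assert est.estimate == pytest.approx(wald_est)
        assert est.se == pytest.approx(wald_se)

    def test_equal_ratios(self):
        insts = [_inst(0.1, 0.01, 0.05, 0.01), _inst(0.2, 0.01, 0.10, 0.02)]
        est = mr.ivw(insts)
        assert est.estimate == pytest.approx(0.5)
        assert est.q == pytest.approx(0.0, abs=1e-20)

    def test_order_and_sign_flip_invariance(self, rng):
        insts = simulate_instruments(rng, n=10)
        base = mr.ivw(insts)
        flipped = [
            _inst(-i.beta_exposure, i.se_exposure, -i.beta_outcome, i.se_outcome, i.snp_id)
            for i in insts
        ]
        assert mr.ivw(list(reversed(insts))).estimate == pytest.approx(base.estimate)
        assert mr.ivw(flipped).estimate == pytest.approx(base.estimate)

    def test_parameter_recovery(self):
        rng = np.random.default_rng(42)
        ests = [mr.ivw(simulate_instruments(rng)).estimate for _ in range(100)]
        assert abs(np.mean(ests) - 0.5) < 0.02

    def test_type_one_error_quick(self):
        rng = np.random.default_rng(11)
        rejections = 0
        reps = 300
        for _ in range(reps):
            est = mr.ivw(simulate_instruments(rng, effect=0.0))
            rejections += est.p < 0.05
        assert 0.02 <= rejections / reps <= 0.08

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            mr.ivw([])


class TestEgger:
    def test_collinear_exact(self):
        # points exactly on y = 0.1 + 0.5 x: any weighting recovers the line
        xs = [0.1, 0.2, 0.3]
        insts = [_inst(x, 0.001, 0.1 + 0.5 * x, 0.01 * (i + 1)) for i, x in enumerate(xs)]
        est = mr.egger(insts)
        assert est.estimate == pytest.approx(0.5)
        assert est.intercept == pytest.approx(0.1)

    def test_constant_pleiotropy_recovered(self):
        rng = np.random.default_rng(5)
        slopes, intercepts = [], []
        for _ in range(100):
            insts = simulate_instruments(rng, effect=0.4, pleiotropy=0.02)
            est = mr.egger(insts)
            slopes.append(est.estimate)
            intercepts.append(est.intercept)
        assert abs(np.mean(slopes) - 0.4) < 0.02
        assert abs(np.mean(intercepts) - 0.02) < 0.005

    def test_no_pleiotropy_intercept_near_zero(self):
        rng = np.random.default_rng(6)
        intercepts = [mr.egger(simulate_instruments(rng)).intercept for _ in range(100)]
        assert abs(np.mean(intercepts)) < 0.005

    def test_intercept_type_one_error(self):
        rng = np.random.default_rng(17)
        reps, rej = 400, 0
        for _ in range(reps):
            est = mr.egger(simulate_instruments(rng, n=50))
            rej += abs(est.intercept) / est.intercept_se > stats.norm.isf(0.025)
        assert 0.02 <= rej / reps <= 0.09

    def test_needs_three(self):
        with pytest.raises(ValueError):
            mr.egger([_inst(0.1, 0.01, 0.05, 0.01)] * 2)


class TestWeightedMedian:
    def test_symmetric_equal_weights(self):
        insts = [_inst(1.0, 0.001, r, 0.1) for r in (0.4, 0.5, 0.6)]
        est = mr.weighted_median(insts, n_boot=0)
        assert est.estimate == pytest.approx(0.5)

    def test_weighted_percentile_against_interp_oracle(self, rng):
        for _ in range(100):
            v = np.sort(rng.normal(size=7))
            w = rng.uniform(0.1, 2.0, size=7)
            got = mr._weighted_median(v, w)
            cum = (np.cumsum(w) - 0.5 * w) / w.sum()
            expected = float(np.interp(0.5, cum, v))
            assert got == pytest.approx(expected)

    def test_majority_valid_robustness(self):
        # 60% valid instruments carry > 50% of the weight: the weighted
        # median stays near the truth while IVW absorbs the pleiotropy
        rng = np.random.default_rng(21)
        wm_ests, ivw_ests = [], []
        for _ in range(60):
            valid = simulate_instruments(rng, n=30, effect=0.3, se_out=0.002)
            invalid = simulate_instruments(rng, n=20, effect=0.3, pleiotropy=0.05, se_out=0.002)
            insts = valid + invalid
            wm_ests.append(mr.weighted_median(insts, n_boot=0).estimate)
            ivw_ests.append(mr.ivw(insts).estimate)
        assert abs(np.mean(wm_ests) - 0.3) < 0.03
        assert np.mean(ivw_ests) - 0.3 > 0.1

    def test_penalty_inactive_when_homogeneous(self):
        # ratios nearly identical relative to their SEs: every Q contribution
        # is tiny, so penalisation must not change the estimate
        rng = np.random.default_rng(3)
        bx = rng.uniform(0.05, 0.2, size=20)
        insts = [
            _inst(b, 0.001, 0.5 * b + rng.normal(0, 0.0005), 0.05, snp=f"rs{i}")
            for i, b in enumerate(bx)
        ]
        plain = mr.weighted_median(insts, penalised=False, n_boot=0).estimate
        pen = mr.weighted_median(insts, penalised=True, n_boot=0).estimate
        assert pen == pytest.approx(plain, abs=1e-9)

    def test_bootstrap_se_reproducible(self):
        rng = np.random.default_rng(9)
        insts = simulate_instruments(rng, n=15)
        a = mr.weighted_median(insts, n_boot=200, seed=4)
        b = mr.weighted_median(insts, n_boot=200, seed=4)
        assert a.se == b.se > 0

    def test_needs_three(self):
        with pytest.raises(ValueError):
            mr.weighted_median([_inst(0.1, 0.01, 0.05, 0.01)] * 2)


class TestCochranQ:
    def test_equal_ratios_zero(self):
        insts = [_inst(0.1, 0.01, 0.05, 0.01), _inst(0.2, 0.01, 0.10, 0.02)]
        qi, q = mr.cochran_q(insts, 0.5)
        np.testing.assert_allclose(qi, 0.0, atol=1e-18)
        assert q == pytest.approx(0.0, abs=1e-18)

    def test_null_distribution_mean(self):
        rng = np.random.default_rng(8)
        n = 20
        qs = []
        for _ in range(500):
            insts = simulate_instruments(rng, n=n)
            est = mr.ivw(insts, random_effects=False)
            qs.append(mr.cochran_q(insts, est.estimate)[1])
        assert np.mean(qs) == pytest.approx(n - 1, rel=0.1)

    def test_outlier_has_max_q(self):
        rng = np.random.default_rng(10)
        insts = simulate_instruments(rng, n=19, effect=0.5)
        outlier = _inst(0.1, 0.001, 0.1 * 0.5 * 10, 0.01, snp="rs_outlier")
        insts.append(outlier)
        est = mr.ivw(insts, random_effects=False)
        qi, _ = mr.cochran_q(insts, est.estimate)
        assert int(np.argmax(qi)) == len(insts) - 1


class TestPrune:
    def test_planted_outlier_removed(self):
        rng = np.random.default_rng(14)
        insts = simulate_instruments(rng, n=19, effect=0.5)
        insts.append(_inst(0.1, 0.001, 0.5, 0.01, snp="rs_outlier"))  # 10x ratio
        retained, excluded = mr.prune_instruments(insts)
        assert excluded == ["rs_outlier"]
        assert len(retained) == 19

    def test_specificity_on_valid_sets(self):
        rng = np.random.default_rng(15)
        removed = 0
        reps = 50
        for _ in range(reps):
            _, excluded = mr.prune_instruments(simulate_instruments(rng, n=20))
            removed += len(excluded) > 0
        assert removed / reps < 0.10

    def test_fixed_point(self):
        rng = np.random.default_rng(16)
        insts = simulate_instruments(rng, n=20)
        insts.append(_inst(0.1, 0.001, 0.5, 0.01, snp="out"))
        retained, _ = mr.prune_instruments(insts)
        again, excluded2 = mr.prune_instruments(retained)
        assert excluded2 == []
        assert len(again) == len(retained)

    def test_post_condition_max_q(self):
        rng = np.random.default_rng(18)
        insts = simulate_instruments(rng, n=25)
        insts.append(_inst(0.1, 0.001, 0.4, 0.01, snp="out"))
        retained, _ = mr.prune_instruments(insts)
        est = mr.ivw(retained, random_effects=False, weights="second_order")
        qi, _ = mr.cochran_q(retained, est.estimate, weights="second_order")
        threshold = stats.chi2.ppf(1 - 0.05 / len(retained), df=1)
        assert np.max(qi) <= threshold

    def test_needs_three(self):
        with pytest.raises(ValueError):
            mr.prune_instruments([_inst(0.1, 0.01, 0.05, 0.01)] * 2)


class TestHarmonise:
    def _frames(self):
        exposure = pd.DataFrame(
            {
                "SNP": ["rs1", "rs2", "rs3", "rs4"],
                "EA": ["A", "C", "A", "G"],
                "OA": ["G", "T", "T", "C"],
                "FREQ": [0.3, 0.2, 0.5, 0.45],
                "BETA": [0.1, 0.2, 0.15, 0.05],
                "SE": [0.01, 0.02, 0.01, 0.01],
            }
        )
        outcome = pd.DataFrame(
            {
                "SNP": ["rs1", "rs2", "rs3", "rs4"],
                "EA": ["G", "C", "A", "G"],
                "OA": ["A", "T", "T", "C"],
                "FREQ": [0.7, 0.2, 0.5, 0.4],
                "BETA": [-0.05, 0.07, 0.02, 0.01],
                "SE": [0.01, 0.01, 0.02, 0.01],
            }
        )
        return exposure, outcome

    def test_swapped_alleles_flip_outcome(self):
        exposure, outcome = self._frames()
        insts = {i.snp_id: i for i in mr.harmonise(exposure, outcome)}
        assert insts["rs1"].beta_outcome == pytest.approx(0.05)  # flipped
        assert insts["rs2"].beta_outcome == pytest.approx(0.07)

    def test_palindromic_high_maf_dropped(self):
        exposure, outcome = self._frames()
        insts = {i.snp_id: i for i in mr.harmonise(exposure, outcome)}
        assert "rs3" not in insts  # A/T with MAF 0.50 > 0.42
        assert "rs4" not in insts  # G/C with MAF 0.45 > 0.42

    def test_palindromic_low_maf_kept(self):
        exposure, outcome = self._frames()
        exposure.loc[exposure.SNP == "rs4", "FREQ"] = 0.1
        insts = {i.snp_id: i for i in mr.harmonise(exposure, outcome)}
        assert "rs4" in insts


class TestIO:
    def test_read_instruments(self, tmp_path):
        p = tmp_path / "inst.tsv"
        p.write_text(
            "SNP\tbeta_exp\tse_exp\tbeta_out\tse_out\n"
            "rs1\t0.1\t0.01\t0.05\t0.02\n"
            "rs2\t0.2\t0.01\t0.11\t0.02\n"
        )
        insts = mr.read_instruments(p)
        assert len(insts) == 2
        assert insts[0].beta_outcome == pytest.approx(0.05)

    def test_missing_column(self, tmp_path):
        p = tmp_path / "inst.tsv"
        p.write_text("SNP\tbeta_exp\tse_exp\tbeta_out\nrs1\t0.1\t0.01\t0.05\n")
        with pytest.raises(ValueError, match="se_out"):
            mr.read_instruments(p)

    def test_run_all_report(self, rng):
        insts = simulate_instruments(rng, n=12)
        report = mr.run_all(insts, methods=("ivw", "egger", "wm", "pwm"), prune=True, seed=1)
        assert set(report["estimates"]) == {"ivw", "egger", "wm", "pwm"}
        assert report["n_input"] == 12
        assert "q_total" in report
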