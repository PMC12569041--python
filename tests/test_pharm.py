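import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from korbias import pharm
from korbias.pharm import (
    CompetitionBinding,
    FourParamLogistic,
    SaturationBinding,
    bias_factor,
    cheng_prusoff,
    four_pl,
    normalize_kinetic,
    relative_activity,
    significance_stars,
)
from korbias.synthetic import FourPLTruth, GeneratorConfig, gen_binding, gen_dose_response


def _fit_curve(bottom, top, pec50, hill, noise_sd=0.0, seed=0, n_conc=8):
    truth = {("t", "G", "WT"): FourPLTruth(bottom, top, pec50, hill)}
    df, _ = gen_dose_response(
        truth, n_conc=n_conc, n_replicates=1, noise_sd=noise_sd,
        config=GeneratorConfig(seed=seed),
    )
    return FourParamLogistic.from_dataframe(df).fit()


class TestFourPL:
    @pytest.mark.parametrize(
        "bottom,top,pec50,hill",
        [(0.0, 100.0, 8.0, 1.0), (1.0, 2.5, 7.2, -1.4), (0.5, 1.5, 9.0, 1.8)],
    )
    def test_noiseless_recovery(self, bottom, top, pec50, hill):
        res = _fit_curve(bottom, top, pec50, hill)
        assert res.converged
        assert res.pec50 == pytest.approx(pec50, rel=1e-6)
        assert res.top == pytest.approx(top, rel=1e-6)
        assert res.bottom == pytest.approx(bottom, abs=1e-6 * max(1, abs(bottom)))
        assert res.hill == pytest.approx(hill, rel=1e-6)

    def test_steep_curve_hits_hill_bound(self):
        """Data generated with Hill 3 fits at the |h| <= 2 bound."""
        res = _fit_curve(0.0, 100.0, 8.0, 3.0)
        assert res.hill == pytest.approx(2.0, abs=1e-6)

    def test_flat_data_flagged(self):
        conc = np.logspace(-11, -5, 8)
        model = FourParamLogistic(conc, np.full_like(conc, 1.3))
        res = model.fit()
        assert res.flat
        assert res.span == pytest.approx(0.0, abs=1e-9)

    def test_span_is_top_minus_bottom(self):
        res = _fit_curve(0.3, 1.9, 8.0, 1.0)
        assert res.span == res.top - res.bottom

    def test_too_few_concentrations_rejected(self):
        with pytest.raises(ValueError, match="4 distinct"):
            FourParamLogistic([1e-9, 1e-8, 1e-7], [0, 1, 2])

    def test_unit_rescaling_shifts_pec50(self):
        """Rescaling concentrations by 10^k shifts pEC50 by -k, nothing else."""
        truth = {("t", "G", "WT"): FourPLTruth(0.0, 1.0, 8.0, 1.0)}
        df, _ = gen_dose_response(truth, n_replicates=1)
        res = FourParamLogistic.from_dataframe(df).fit()
        df2 = df.assign(conc_M=df["conc_M"] * 1e3)
        res2 = FourParamLogistic.from_dataframe(df2).fit()
        assert res2.pec50 == pytest.approx(res.pec50 - 3.0, abs=1e-6)
        assert res2.hill == pytest.approx(res.hill, rel=1e-6)
        assert res2.span == pytest.approx(res.span, rel=1e-6)

    def test_summary_mentions_parameters(self):
        res = _fit_curve(0.0, 100.0, 8.0, 1.0)
        text = res.summary()
        assert "pEC50" in text and "HillSlope" in text


class TestNormalizeKinetic:
    def _kinetic_df(self, well_folds, vehicle_fold=1.0):
        rows = []
        for i, (ligand, conc, fold) in enumerate(well_folds):
            for t, c in [(-30, 1000.0), (-10, 1000.0), (360, 1000.0 * fold),
                         (480, 1000.0 * fold)]:
                rows.append(
                    {"well": f"W{i}", "time_s": t, "counts": c,
                     "construct": "WT", "ligand": ligand, "conc_M": conc,
                     "replicate": 1}
                )
        for t, c in [(-30, 1000.0), (360, 1000.0 * vehicle_fold)]:
            rows.append(
                {"well": "V", "time_s": t, "counts": c, "construct": "WT",
                 "ligand": "vehicle", "conc_M": 0.0, "replicate": 1}
            )
        return pd.DataFrame(rows)

    def test_fold_change(self):
        df = self._kinetic_df([("lig", 1e-8, 1.5)], vehicle_fold=1.0)
        out = normalize_kinetic(df)
        assert out["response"].iloc[0] == pytest.approx(1.5)

    def test_vehicle_self_normalization(self):
        df = self._kinetic_df([("lig", 1e-8, 1.2)], vehicle_fold=1.2)
        out = normalize_kinetic(df)
        assert out["response"].iloc[0] == pytest.approx(1.0)

    def test_no_vehicle_errors(self):
        df = self._kinetic_df([("lig", 1e-8, 1.5)])
        df = df[df["ligand"] != "vehicle"]
        with pytest.raises(ValueError, match="vehicle"):
            normalize_kinetic(df)

    def test_empty_response_window_errors(self):
        df = self._kinetic_df([("lig", 1e-8, 1.5)])
        with pytest.raises(ValueError, match="response window"):
            normalize_kinetic(df, response_window=(1e6, 2e6))


def _results(span, pec50):
    return pharm.FourPLResults(
        bottom=0.0, top=span, pec50=pec50, hill=1.0, rss=0.0, n_obs=8,
        converged=True, flat=False,
    )


class TestRelativeActivity:
    def test_arithmetic(self):
        test = [_results(50.0, 7.0)]
        ref = [_results(100.0, 8.0)]
        ra = relative_activity(test, ref)
        assert ra.emax[0] == pytest.approx(0.5)
        assert ra.delta_pec50[0] == pytest.approx(-1.0)
        assert ra.rai[0] == pytest.approx(0.05)

    def test_identity(self):
        fits = [_results(80.0, 8.2)]
        ra = relative_activity(fits, fits)
        assert ra.emax[0] == pytest.approx(1.0)
        assert ra.delta_pec50[0] == pytest.approx(0.0)
        assert ra.rai[0] == pytest.approx(1.0)

    def test_three_replicates_mean(self):
        test = [_results(s, 8.0) for s in (40.0, 50.0, 60.0)]
        ref = [_results(100.0, 8.0)] * 3
        ra = relative_activity(test, ref)
        assert ra.emax_mean == pytest.approx(0.5)

    def test_nonpositive_reference_span_errors(self):
        with pytest.raises(ValueError, match="positive"):
            relative_activity([_results(50.0, 8.0)], [_results(0.0, 8.0)])


class TestBiasFactor:
    def test_reference_vs_itself_is_zero(self):
        fits = {"G": [_results(100.0, 8.0)] * 3, "B": [_results(50.0, 7.5)] * 3}
        res = bias_factor(fits, fits, "G", "B")
        np.testing.assert_allclose(res.ddlog_per_replicate, 0.0, atol=1e-12)
        assert res.ddlog == pytest.approx(0.0)

    def test_known_delta(self):
        # dLog_A = 0.5, dLog_B = -0.5 per replicate -> ddLog = 1.0
        test = {
            "A": [_results(100.0, 8.5)] * 3,   # log(S/EC50) ref+0.5
            "B": [_results(100.0, 7.5)] * 3,
        }
        ref = {"A": [_results(100.0, 8.0)] * 3, "B": [_results(100.0, 8.0)] * 3}
        res = bias_factor(test, ref, "A", "B")
        np.testing.assert_allclose(res.ddlog_per_replicate, 1.0, atol=1e-12)

    def test_antisymmetric_under_pathway_swap(self):
        test = {"A": [_results(90.0, 8.3), _results(85.0, 8.1)],
                "B": [_results(40.0, 7.4), _results(45.0, 7.6)]}
        ref = {"A": [_results(100.0, 8.0)] * 2, "B": [_results(50.0, 7.5)] * 2}
        ab = bias_factor(test, ref, "A", "B")
        ba = bias_factor(test, ref, "B", "A")
        np.testing.assert_allclose(
            ab.ddlog_per_replicate, -ba.ddlog_per_replicate, atol=1e-12
        )

    def test_t_statistic_matches_textbook_formula(self):
        dd = np.array([0.1, -0.1, 0.02])
        test = {"A": [_results(100.0, 8.0 + d) for d in dd],
                "B": [_results(100.0, 8.0)] * 3}
        ref = {"A": [_results(100.0, 8.0)] * 3, "B": [_results(100.0, 8.0)] * 3}
        res = bias_factor(test, ref, "A", "B")
        # closed-form one-sample t with n-1 df
        t_oracle = dd.mean() / (dd.std(ddof=1) / math.sqrt(len(dd)))
        p_oracle = 2 * stats.t.sf(abs(t_oracle), len(dd) - 1)
        assert res.t == pytest.approx(t_oracle, rel=1e-9)
        assert res.p == pytest.approx(p_oracle, rel=1e-9)
        assert res.df == 2

    def test_single_replicate_reports_values_without_test(self):
        test = {"A": [_results(100.0, 8.5)], "B": [_results(100.0, 8.0)]}
        ref = {"A": [_results(100.0, 8.0)], "B": [_results(100.0, 8.0)]}
        res = bias_factor(test, ref, "A", "B")
        assert res.t is None and res.p is None
        assert res.ddlog == pytest.approx(0.5)

    def test_mismatched_replicates_error(self):
        test = {"A": [_results(1.0, 8.0)] * 2, "B": [_results(1.0, 8.0)] * 2}
        ref = {"A": [_results(1.0, 8.0)] * 3, "B": [_results(1.0, 8.0)] * 3}
        with pytest.raises(ValueError, match="replicate"):
            bias_factor(test, ref, "A", "B")

    @pytest.mark.parametrize(
        "p,stars", [(0.2, "ns"), (0.03, "*"), (0.005, "**"), (0.0005, "***")]
    )
    def test_star_thresholds(self, p, stars):
        assert significance_stars(p) == stars


class TestSaturation:
    def test_noiseless_kd_recovery(self):
        conc = np.array([0.5, 1, 2, 4, 6, 8, 10, 12]) * 1e-9
        df, _ = gen_binding(
            "saturation", {"bmax": 4000.0, "kd": 7.79e-9, "ns": 1e10}, conc
        )
        res = SaturationBinding.from_dataframe(df).fit()
        assert res.kd_nM == pytest.approx(7.79, rel=1e-6)
        assert res.bmax == pytest.approx(4000.0, rel=1e-6)

    def test_half_saturation_point(self):
        res = SaturationBinding(
            np.array([1, 2, 5, 10]) * 1e-9,
            np.array([1000 / 6, 1000 * 2 / 7, 1000 * 0.5, 1000 * 2 / 3]),
            np.zeros(4),
        ).fit()
        assert res.predict(res.kd) == pytest.approx(res.bmax / 2)

    def test_count_scaling_equivariance(self):
        conc = np.array([0.5, 1, 2, 4, 8, 12]) * 1e-9
        df, _ = gen_binding("saturation", {"bmax": 1000.0, "kd": 5e-9}, conc)
        res1 = SaturationBinding.from_dataframe(df).fit()
        df2 = df.assign(
            counts_total=df["counts_total"] * 2,
            counts_nonspecific=df["counts_nonspecific"] * 2,
        )
        res2 = SaturationBinding.from_dataframe(df2).fit()
        assert res2.bmax == pytest.approx(2 * res1.bmax, rel=1e-9)
        assert res2.kd == pytest.approx(res1.kd, rel=1e-9)

    def test_all_nonpositive_specific_flagged_failure(self):
        with pytest.raises(ValueError, match="non-positive"):
            SaturationBinding(
                np.array([1, 2, 3, 4]) * 1e-9,
                np.zeros(4),
                np.ones(4),
            ).fit()


class TestCompetition:
    def test_cheng_prusoff_arithmetic(self):
        assert cheng_prusoff(20e-9, 10e-9, 10e-9) == pytest.approx(10e-9)

    def test_small_l_limit(self):
        ki = cheng_prusoff(20e-9, 1e-15, 10e-9)
        assert ki == pytest.approx(20e-9, rel=1e-4)

    def test_noiseless_ic50_recovery(self):
        conc = np.logspace(-10, -5, 10)
        df, _ = gen_binding(
            "competition",
            {"top": 900.0, "bottom": 50.0, "ic50": 3e-8, "hill": 1.0,
             "ns_counts": 50.0},
            conc,
        )
        res = CompetitionBinding.from_dataframe(df, 2e-9, 7.79e-9).fit()
        assert res.ic50 == pytest.approx(3e-8, rel=1e-6)
        assert res.top > res.bottom

    def test_ki_identity_bit_exact(self):
        conc = np.logspace(-10, -5, 8)
        df, _ = gen_binding(
            "competition", {"top": 500.0, "bottom": 0.0, "ic50": 1e-8}, conc
        )
        res = CompetitionBinding.from_dataframe(df, 5e-9, 1e-8).fit()
        assert res.ki == res.ic50 / (1.0 + res.radioligand_conc / res.radioligand_kd)

    def test_invalid_radioligand_params_error(self):
        with pytest.raises(ValueError, match="positive"):
            CompetitionBinding(np.logspace(-9, -6, 5), np.ones(5), -1e-9, 1e-8)


class TestRecoveryStatistics:
    """Noisy parameter recovery and type-I behaviour of the bias t-test."""

    def test_median_pec50_error_under_noise(self):
        errors = []
        for seed in range(60):
            truth = FourPLTruth(0.0, 1.0, 8.0, 1.0)
            df, _ = gen_dose_response(
                {("t", "G", "WT"): truth}, n_replicates=3,
                noise_sd=0.05, config=GeneratorConfig(seed=seed),
            )
            for _, g in df.groupby("replicate"):
                res = FourParamLogistic.from_dataframe(g).fit(n_starts=3)
                errors.append(abs(res.pec50 - 8.0))
        assert np.median(errors) < 0.1
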