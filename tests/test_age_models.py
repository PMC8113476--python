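"""Per-window age models: OLS correctness, calibration, summaries, thresholds."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from trnameth.age_models import (
    AgeModelSpec,
    WindowAgeResult,
    bonferroni_threshold,
    build_design,
    fit_age_model,
    fit_all_windows,
    fit_longitudinal,
    mixed_model_lrt,
    summarize_by_trna,
)
from trnameth.genome_annotation import GenomicInterval
from trnameth.synthetic_data import SimulationConfig, simulate_sample_table
from trnameth.window_methylome import MethylationMatrix, Window, WindowFeatureMap


def _samples(n, rng, batches=2):
    return pd.DataFrame(
        {
            "sample_id": [f"S{i}" for i in range(n)],
            "participant_id": [f"P{i}" for i in range(n)],
            "family_id": [f"F{i}" for i in range(n)],
            "zygosity": "NA",
            "age": rng.uniform(16, 82, n),
            "sex": "F",
            "batch": [f"batch{1 + i % batches}" for i in range(n)],
            "lymphocytes": rng.normal(2.0, 0.5, n).clip(0.1),
            "monocytes": rng.normal(0.5, 0.15, n).clip(0.05),
            "neutrophils": rng.normal(4.0, 1.0, n).clip(0.5),
            "eosinophils": rng.normal(0.2, 0.08, n).clip(0.01),
        }
    )


def _matrix_from(Y, samples):
    windows = [
        Window(GenomicInterval("chr1", i * 250, i * 250 + 500, name=f"w{i}"))
        for i in range(Y.shape[0])
    ]
    df = pd.DataFrame(Y, index=[w.name for w in windows], columns=samples["sample_id"])
    return MethylationMatrix(windows, df)


class TestFitAgeModel:
    def test_perfect_linear_fit(self, rng):
        samples = _samples(50, rng)
        meth = 0.1 * samples["age"].to_numpy()
        res = fit_age_model(meth, samples, AgeModelSpec(model_id=1))
        assert res.slope == pytest.approx(0.1, rel=1e-10)
        assert res.p_value < 1e-12

    def test_matches_statsmodels_to_ten_digits(self, rng):
        """Model-4 slope and partial-F p equal an independent OLS oracle."""
        import statsmodels.api as sm

        samples = _samples(80, rng)
        meth = rng.normal(5, 1, 80) + 0.01 * samples["age"].to_numpy()
        res = fit_age_model(meth, samples, AgeModelSpec(model_id=4))

        Z, names = build_design(samples, AgeModelSpec(model_id=4).covariates)
        X = np.column_stack([Z, samples["age"].to_numpy()])
        fit = sm.OLS(meth, X).fit()
        assert res.slope == pytest.approx(fit.params[-1], rel=1e-10)
        assert res.se == pytest.approx(fit.bse[-1], rel=1e-10)
        assert res.p_value == pytest.approx(fit.pvalues[-1], rel=1e-10)

    def test_model1_partial_f_equals_simple_regression(self, rng):
        samples = _samples(60, rng)
        meth = rng.normal(size=60)
        res = fit_age_model(meth, samples, AgeModelSpec(model_id=1))
        lr = stats.linregress(samples["age"], meth)
        assert res.p_value == pytest.approx(lr.pvalue, rel=1e-12)
        assert res.slope == pytest.approx(lr.slope, rel=1e-12)

    def test_age_response_same_p_different_slope(self, rng):
        samples = _samples(70, rng)
        meth = rng.normal(size=70) + 0.02 * samples["age"].to_numpy()
        fwd = fit_age_model(meth, samples, AgeModelSpec(model_id=4))
        rev = fit_age_model(meth, samples, AgeModelSpec(model_id=4, direction="age_response"))
        assert rev.p_value == pytest.approx(fwd.p_value, rel=1e-10)
        assert rev.slope != pytest.approx(fwd.slope)
        assert np.sign(rev.slope) == np.sign(fwd.slope)

    def test_zero_variance_meth_flagged(self, rng):
        samples = _samples(30, rng)
        res = fit_age_model(np.full(30, 2.0), samples, AgeModelSpec(model_id=1))
        assert res.flag == "zero_variance"
        assert res.p_value == 1.0
        assert res.slope == 0.0

    def test_rank_deficient_design_names_columns(self, rng):
        samples = _samples(40, rng)
        samples["lymphocytes"] = 2 * samples["monocytes"]
        with pytest.raises(ValueError, match="collinear.*(lymphocytes|monocytes)"):
            fit_age_model(rng.normal(size=40), samples, AgeModelSpec(model_id=3))

    def test_null_p_values_uniform(self, rng):
        """With no age effect, partial-F p-values are Uniform(0,1)."""
        samples = _samples(200, rng)
        Y = rng.normal(size=(1000, 200))
        results = fit_all_windows(_matrix_from(Y, samples), samples, AgeModelSpec(model_id=4))
        ps = np.array([r.p_value for r in results])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_orthogonal_covariate_leaves_slope_unchanged(self, rng):
        n = 128
        samples = _samples(n, rng)
        samples["batch"] = "batch1"
        age = samples["age"].to_numpy()
        # construct cell counts orthogonal to both intercept and age
        basis = np.column_stack([np.ones(n), age - age.mean()])
        Q, _ = np.linalg.qr(basis)
        raw = rng.normal(size=(n, 4))
        orth = raw - Q @ (Q.T @ raw)
        for j, col in enumerate(["lymphocytes", "monocytes", "neutrophils", "eosinophils"]):
            samples[col] = orth[:, j]
        meth = rng.normal(size=n) + 0.03 * age
        m1 = fit_age_model(meth, samples, AgeModelSpec(model_id=1))
        m3 = fit_age_model(meth, samples, AgeModelSpec(model_id=3))
        assert m3.slope == pytest.approx(m1.slope, abs=1e-8)


class TestFitAllWindows:
    def test_one_result_per_window_and_loop_equivalence(self, rng):
        samples = _samples(50, rng)
        Y = rng.normal(size=(20, 50))
        matrix = _matrix_from(Y, samples)
        batch = fit_all_windows(matrix, samples, AgeModelSpec(model_id=2))
        assert len(batch) == 20
        for i in (0, 7, 19):
            single = fit_age_model(Y[i], samples, AgeModelSpec(model_id=2))
            assert batch[i].slope == pytest.approx(single.slope, rel=1e-12)
            assert batch[i].p_value == pytest.approx(single.p_value, rel=1e-12)

    def test_empty_matrix(self, rng):
        samples = _samples(10, rng)
        matrix = _matrix_from(np.empty((0, 10)), samples)
        assert fit_all_windows(matrix, samples) == []

    def test_degenerate_window_does_not_abort_batch(self, rng):
        samples = _samples(30, rng)
        Y = rng.normal(size=(3, 30))
        Y[1] = 0.0
        results = fit_all_windows(_matrix_from(Y, samples), samples, AgeModelSpec(model_id=1))
        assert [r.flag for r in results] == ["", "zero_variance", ""]


class TestLongitudinal:
    def _long_samples(self, rng, n_participants=40, gap=7.0, slope=0.05, noise=0.05):
        rows, meth = [], []
        for p in range(n_participants):
            base = rng.uniform(20, 70)
            offset = rng.normal(0, 1)
            for visit, age in enumerate([base, base + gap]):
                rows.append(
                    {
                        "sample_id": f"S{p}_{visit}",
                        "participant_id": f"P{p}",
                        "family_id": f"F{p}",
                        "zygosity": "NA",
                        "age": age,
                        "sex": "F",
                        # batch varies within participant (per sequencing run)
                        "batch": "batch1" if (p + visit) % 2 else "batch2",
                        "lymphocytes": rng.normal(2, 0.3),
                        "monocytes": rng.normal(0.5, 0.1),
                        "neutrophils": rng.normal(4, 0.5),
                        "eosinophils": rng.normal(0.2, 0.05),
                    }
                )
                meth.append(offset + slope * age + rng.normal(0, noise))
        samples = pd.DataFrame(rows)
        return samples, np.asarray(meth)

    def test_small_gap_participants_excluded(self, rng):
        samples, meth = self._long_samples(rng, n_participants=10, gap=7.0)
        # participant P0 revisited after only 4 years: below the 5-year rule
        samples.loc[samples["participant_id"] == "P0", "age"] = [40.0, 44.0]
        matrix = _matrix_from(meth.reshape(1, -1), samples)
        fit_longitudinal(matrix, samples)  # others qualify; P0 silently dropped
        span = samples.groupby("participant_id")["age"].agg(np.ptp)
        assert span["P0"] < 5

    def test_within_person_slope_recovered(self, rng):
        samples, meth = self._long_samples(rng, slope=0.05, noise=0.02)
        matrix = _matrix_from(meth.reshape(1, -1), samples)
        (res,) = fit_longitudinal(matrix, samples)
        assert abs(res.slope - 0.05) < 2 * res.se

    def test_all_single_visit_errors(self, rng):
        samples = _samples(20, rng)
        matrix = _matrix_from(rng.normal(size=(1, 20)), samples)
        with pytest.raises(ValueError, match="longitudinal"):
            fit_longitudinal(matrix, samples)


@pytest.fixture(scope="module")
def twin_samples():
    rng = np.random.default_rng(5)
    return simulate_sample_table(SimulationConfig(n_samples=200, twin_fraction=0.5), rng)


class TestMixedModelLRT:
    def test_strong_effect_detected(self, twin_samples, rng):
        meth = 0.1 * twin_samples["age"].to_numpy() + rng.normal(0, 0.3, len(twin_samples))
        lrt, p = mixed_model_lrt(meth, twin_samples)
        assert p < 1e-6

    def test_close_to_fixed_f_without_family_variance(self, rng):
        """With zero between-family variance the LRT approximates the
        fixed-effects partial F-test."""
        samples = _samples(500, rng)  # every sample its own family: no clustering
        samples["family_id"] = [f"F{i}" for i in range(500)]
        meth = rng.normal(size=500) + 0.01 * samples["age"].to_numpy()
        lrt, p_mixed = mixed_model_lrt(meth, samples)
        fixed = fit_age_model(meth, samples, AgeModelSpec(model_id=4, direction="age_response"))
        assert p_mixed == pytest.approx(fixed.p_value, rel=1.0)  # within a factor of 2

    def test_type_one_error_controlled(self, twin_samples):
        """No-effect methylation: LRT rejects at ~nominal 5% rate."""
        rng = np.random.default_rng(0)
        rejections = 0
        n_reps = 60
        for _ in range(n_reps):
            meth = rng.normal(size=len(twin_samples))
            _, p = mixed_model_lrt(meth, twin_samples)
            rejections += p < 0.05
        assert rejections / n_reps <= 0.12

    def test_requires_families(self, rng):
        samples = _samples(30, rng)
        samples["family_id"] = "F0"
        with pytest.raises(ValueError, match="families"):
            mixed_model_lrt(rng.normal(size=30), samples)


class TestBonferroni:
    def test_study_wide_598(self):
        assert bonferroni_threshold(0.05, 598) == pytest.approx(8.36e-5, rel=5e-3)

    def test_single_test(self):
        assert bonferroni_threshold(0.05, 1) == 0.05

    def test_array_103(self):
        # direct division (0.05/103), not the sometimes-quoted 4.58e-4
        assert bonferroni_threshold(0.05, 103) == pytest.approx(4.854e-4, rel=1e-3)

    def test_strictly_decreasing_in_m(self):
        vals = [bonferroni_threshold(0.05, m) for m in range(1, 50)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)
        with pytest.raises(ValueError):
            bonferroni_threshold(1.5, 10)


class TestSummarizeByTrna:
    def _results(self, ps, slopes=None):
        slopes = slopes or [0.1] * len(ps)
        return [
            WindowAgeResult(f"w{i}", slopes[i], 0.01, ps[i]) for i in range(len(ps))
        ]

    def test_min_p_window_selected(self):
        results = self._results([0.2, 3e-6])
        fmap = WindowFeatureMap([(0, "tRNA-A"), (1, "tRNA-A")])
        (s,) = summarize_by_trna(results, fmap, {"study_wide": 8.36e-5, "genome_wide": 4.34e-9})
        assert s.significant_study_wide and not s.significant_genome_wide
        assert s.min_p == pytest.approx(3e-6)
        assert s.best_window == "w1"

    def test_not_significant_when_all_above_threshold(self):
        results = self._results([0.2, 0.01])
        fmap = WindowFeatureMap([(0, "tRNA-A"), (1, "tRNA-A")])
        (s,) = summarize_by_trna(results, fmap, {"study_wide": 1e-4, "genome_wide": 1e-9})
        assert not s.significant_study_wide

    def test_shared_window_calls_both_trnas(self):
        """One significant window overlapping two neighbouring tRNAs calls
        both (the documented any-overlap behaviour)."""
        results = self._results([1e-7])
        fmap = WindowFeatureMap([(0, "tRNA-Ile-AAT-4-1"), (0, "tRNA-Ser-AGA-2-6")])
        summaries = summarize_by_trna(results, fmap, {"study_wide": 1e-4, "genome_wide": 1e-9})
        assert all(s.significant_study_wide for s in summaries)
        assert len(summaries) == 2

    def test_no_coverage_flag(self):
        summaries = summarize_by_trna(
            [], WindowFeatureMap([]), {"study_wide": 1e-4, "genome_wide": 1e-9}, ["tRNA-X"]
        )
        assert summaries[0].flag == "no_coverage"

    def test_hypo_direction_from_slope_sign(self):
        results = self._results([1e-6], slopes=[-0.2])
        fmap = WindowFeatureMap([(0, "tRNA-A")])
        (s,) = summarize_by_trna(results, fmap, {"study_wide": 1e-4, "genome_wide": 1e-9})
        assert s.direction == "hypo"
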