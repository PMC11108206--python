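"""Harmonic regression, the dual-experiment consensus, and the FDR calculus."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from circaphase import rhythm
from circaphase.circstat import abs_phase_difference
from circaphase.rhythm import (
    consensus_cyclers,
    expected_false_positives,
    fdr_estimate,
    fdr_threshold_sweep,
    fit_harmonic,
    fit_harmonic_matrix,
)
from circaphase.simdata import SimConfig, simulate_experiment


def cosine(t, mesor, amp, phase):
    return mesor + amp * np.cos(2 * np.pi * (t - phase) / 24.0)


class TestFitHarmonic:
    def test_noiseless_closed_form(self):
        t = np.arange(0, 24, 2.0)
        fit = fit_harmonic(t, cosine(t, 3.0, 2.0, 8.0))
        assert fit.mesor == pytest.approx(3.0)
        assert fit.amplitude == pytest.approx(2.0)
        assert fit.phase == pytest.approx(8.0)
        assert fit.p_value < 1e-12

    def test_constant_series_degenerate(self):
        t = np.arange(0, 24, 2.0)
        fit = fit_harmonic(t, np.full_like(t, 5.0))
        assert fit.amplitude == 0.0
        assert fit.p_value == 1.0

    def test_too_few_timepoints(self):
        with pytest.raises(ValueError):
            fit_harmonic([0.0, 12.0, 24.0, 36.0], [1.0, 2.0, 1.0, 2.0])  # 2 distinct mod 24

    def test_phase_equivariance_under_time_shift(self, rng):
        t = np.arange(2, 26, 2.0)
        y = cosine(t, 1.0, 0.8, 15.0) + rng.normal(0, 0.3, t.size)
        base = fit_harmonic(t, y)
        for delta in (3.0, 7.5, 23.0):
            shifted = fit_harmonic(t + delta, y)
            assert abs_phase_difference(shifted.phase, (base.phase + delta) % 24) < 1e-9
            assert shifted.p_value == pytest.approx(base.p_value)

    def test_agrees_with_brute_force_least_squares(self, rng):
        """The closed-form (amplitude, phase) matches direct SSE minimization."""
        for _ in range(25):
            t = np.sort(rng.uniform(0, 24, size=12))
            y = cosine(t, rng.normal(2, 1), rng.uniform(0.5, 2), rng.uniform(0, 24))
            y += rng.normal(0, 0.4, t.size)
            fit = fit_harmonic(t, y)

            def amp_coef(phase):
                x = np.column_stack([np.ones_like(t), np.cos(2 * np.pi * (t - phase) / 24)])
                return np.linalg.lstsq(x, y, rcond=None)[0][1]

            def sse(phase):
                x = np.column_stack([np.ones_like(t), np.cos(2 * np.pi * (t - phase) / 24)])
                beta, res, *_ = np.linalg.lstsq(x, y, rcond=None)
                return float(((y - x @ beta) ** 2).sum())

            grid = np.linspace(0, 24, 481, endpoint=False)
            best = grid[np.argmin([sse(p) for p in grid])]
            ref = optimize.minimize_scalar(
                sse, bracket=(best - 0.1, best, best + 0.1), method="brent"
            ).x % 24
            if amp_coef(ref) < 0:  # SSE has antipodal minima with A sign flipped
                ref = (ref + 12.0) % 24.0
            assert abs_phase_difference(fit.phase, ref) < 1e-4

    def test_p_value_matches_statsmodels(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        t = np.arange(2, 26, 2.0)
        y = cosine(t, 2.0, 0.5, 4.0) + rng.normal(0, 0.5, t.size)
        fit = fit_harmonic(t, y)
        x = sm.add_constant(
            np.column_stack([np.cos(2 * np.pi * t / 24), np.sin(2 * np.pi * t / 24)])
        )
        ols = sm.OLS(y, x).fit()
        assert fit.f_stat == pytest.approx(ols.fvalue)
        assert fit.p_value == pytest.approx(ols.f_pvalue)

    def test_matrix_fit_matches_single_fits(self, rng):
        t = np.arange(2, 26, 2.0)
        ys = rng.normal(3, 1, size=(5, t.size))
        df = fit_harmonic_matrix(t, ys)
        for i in range(5):
            single = fit_harmonic(t, ys[i])
            assert df["phase"].iloc[i] == pytest.approx(single.phase)
            assert df["p_value"].iloc[i] == pytest.approx(single.p_value)

    def test_phase_recovery_at_moderate_noise(self):
        cfg = SimConfig(
            n_genes=500,
            frac_cycling_18=1.0,
            frac_cycling_25=1.0,
            frac_shared=1.0,
            amplitude_range=(1.0, 1.0),
            noise_sd=0.5,
            baseline_log_tpm_mean=6.0,
            baseline_log_tpm_sd=0.5,
            seed=9,
        )
        mat, truth = simulate_experiment(cfg, "V1", "25C")
        fits = rhythm.fit_experiment(mat)
        err = abs_phase_difference(fits["phase"].to_numpy(), truth["phase_25"].to_numpy())
        assert np.mean(err) < 0.5


def _fits_frame(genes, p_values, phases):
    return pd.DataFrame(
        {
            "mesor": 0.0,
            "amplitude": 1.0,
            "phase": phases,
            "f_stat": 1.0,
            "p_value": p_values,
            "n_obs": 24,
        },
        index=pd.Index(genes, name="gene_id"),
    )


class TestConsensus:
    def test_fails_one_threshold(self):
        f1 = _fits_frame(["a"], [0.05], [2.0])
        f2 = _fits_frame(["a"], [0.2], [2.0])
        assert len(consensus_cyclers(f1, f2)) == 0

    def test_phase_boundary_excluded_strictly(self):
        # phases 2 and 23: circular distance min(21, 3) = 3, not < 3
        f1 = _fits_frame(["a"], [0.05], [2.0])
        f2 = _fits_frame(["a"], [0.05], [23.0])
        assert len(consensus_cyclers(f1, f2)) == 0

    def test_included_with_circular_mean_phase(self):
        f1 = _fits_frame(["a"], [0.01], [2.0])
        f2 = _fits_frame(["a"], [0.02], [3.5])
        out = consensus_cyclers(f1, f2)
        assert list(out.index) == ["a"]
        assert out["consensus_phase"].iloc[0] == pytest.approx(2.75)

    def test_consensus_phase_wraps_midnight(self):
        f1 = _fits_frame(["a"], [0.01], [23.0])
        f2 = _fits_frame(["a"], [0.01], [1.0])
        out = consensus_cyclers(f1, f2)
        assert out["consensus_phase"].iloc[0] == pytest.approx(0.0)

    def test_mismatched_universe(self):
        f1 = _fits_frame(["a", "b"], [0.01, 0.01], [1.0, 2.0])
        f2 = _fits_frame(["a"], [0.01], [1.0])
        with pytest.raises(ValueError, match="universe"):
            consensus_cyclers(f1, f2)


class TestFalsePositiveCalculus:
    @pytest.mark.parametrize(
        ("n", "p_thr", "d_thr", "expected"),
        [(6774, 0.1, 3, 16.935), (1000, 0.0, 3, 0.0), (1000, 0.1, 3, 2.5)],
    )
    def test_expected_false_positives(self, n, p_thr, d_thr, expected):
        assert expected_false_positives(n, p_thr, d_thr) == pytest.approx(expected)

    def test_chance_pass_probability(self):
        assert expected_false_positives(1, 0.1, 3) == pytest.approx(0.0025)

    @pytest.mark.parametrize(
        ("efp", "n_det", "expected"),
        [(16.935, 242, 0.070), (16.935, 364, 0.047), (10.0, 5, 1.0)],
    )
    def test_fdr_estimate(self, efp, n_det, expected):
        assert fdr_estimate(efp, n_det) == pytest.approx(expected, abs=5e-4)

    def test_fdr_requires_detections(self):
        with pytest.raises(ValueError):
            fdr_estimate(1.0, 0)


@pytest.fixture(scope="module")
def fits():
    rng = np.random.default_rng(5)
    genes = [f"g{i}" for i in range(400)]

    def mk():
        return _fits_frame(genes, rng.uniform(0, 1, 400), rng.uniform(0, 24, 400))

    return {"18C": (mk(), mk()), "25C": (mk(), mk())}


class TestThresholdSweep:
    def test_singleton_grid_matches_direct_computation(self, fits):
        table = fdr_threshold_sweep(fits, [0.1], [3.0])
        assert len(table) == 1
        for cond in ("18C", "25C"):
            direct = len(consensus_cyclers(*fits[cond], 0.1, 3.0))
            assert table[f"n_detected_{cond}"].iloc[0] == direct
            if direct:
                efp = expected_false_positives(400, 0.1, 3.0)
                assert table[f"fdr_{cond}"].iloc[0] == pytest.approx(fdr_estimate(efp, direct))

    def test_detected_counts_monotone_in_thresholds(self, fits):
        table = fdr_threshold_sweep(fits, [0.02, 0.05, 0.1, 0.2], [1.0, 3.0, 6.0])
        for cond in ("18C", "25C"):
            pivot = table.pivot(
                index="p_threshold", columns="dphi_threshold", values=f"n_detected_{cond}"
            )
            assert (pivot.diff().dropna() >= 0).all().all()
            assert (pivot.diff(axis=1).dropna(axis=1) >= 0).all().all()

    def test_empty_grid(self, fits):
        with pytest.raises(ValueError):
            fdr_threshold_sweep(fits, [], [3.0])


class TestNullBehaviour:
    def test_null_p_values_uniform(self):
        """Single-experiment p-values under pure noise pass a KS uniformity check."""
        cfg = SimConfig(n_genes=10_000, frac_cycling_18=0.0, frac_cycling_25=0.0, seed=100)
        mat, _ = simulate_experiment(cfg, "V1", "25C")
        fits = rhythm.fit_experiment(mat)
        assert stats.kstest(fits["p_value"], "uniform").pvalue > 0.01

    def test_empirical_fdr_tracks_analytic(self):
        """With 10% true cyclers, truth-based FDR is within 3 points of analytic."""
        cfg = SimConfig(
            n_genes=4000,
            frac_cycling_18=0.1,
            frac_cycling_25=0.1,
            frac_shared=1.0,
            amplitude_range=(1.0, 2.0),
            noise_sd=0.5,
            baseline_log_tpm_mean=6.0,
            baseline_log_tpm_sd=0.5,
            seed=77,
        )
        f1 = rhythm.fit_experiment(simulate_experiment(cfg, "V1", "25C")[0])
        f2 = rhythm.fit_experiment(simulate_experiment(cfg, "V2", "25C")[0])
        cyc = consensus_cyclers(f1, f2)
        truth = simulate_experiment(cfg, "V1", "25C")[1]
        false_calls = (~truth.loc[cyc.index, "is_cycling_25"]).sum()
        empirical = false_calls / len(cyc)
        analytic = fdr_estimate(expected_false_positives(4000, 0.1, 3.0), len(cyc))
        assert abs(empirical - analytic) < 0.03
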