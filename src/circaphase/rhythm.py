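"""Harmonic-regression rhythm detection and the dual-experiment consensus.

A gene is fit per experiment by ordinary least squares of

    y = beta0 + beta1*cos(omega*t) + beta2*sin(omega*t),   omega = 2*pi/period

against an intercept-only null (F-test, (2, n-3) df). Amplitude is
``sqrt(beta1^2 + beta2^2)`` and the peak phase ``(period/2pi)*atan2(beta2,
beta1)`` mod period, i.e. the Zeitgeber hour at which the fitted cosine
peaks. A gene is called cycling when its p-value clears the threshold in
BOTH experiments and the two phase estimates agree to within the circular
tolerance; the chance rate of that event for a non-cycling gene is the
analytic product ``p_thr^2 * (2*dphi_thr/period)``, which prices the
expected number of false discoveries without any resampling.

Fits default to log2(TPM+1); raw-TPM fitting is available via
``log_transform=False``. Replicates enter as independent observations at
their timepoint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .circstat import PERIOD, abs_phase_difference, circular_mean


@dataclass(frozen=True)
class RhythmFit:
    """Per-gene harmonic-regression result (log2-TPM units unless raw)."""

    gene_id: str
    mesor: float
    amplitude: float
    phase: float  # hours in [0, period), ZT of the fitted peak
    f_stat: float
    p_value: float
    n_obs: int


def _design(times: np.ndarray, period: float) -> np.ndarray:
    omega = 2 * np.pi / period
    return np.column_stack([np.ones_like(times), np.cos(omega * times), np.sin(omega * times)])


def fit_harmonic(times, values, period: float = PERIOD, gene_id: str = "") -> RhythmFit:
    """Cosinor fit of one series: OLS on intercept + cos + sin at ``period``.

    Requires >= 4 observations at >= 3 distinct times modulo the period.
    A constant series returns amplitude 0 and p = 1 rather than erroring.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.shape != y.shape:
        raise ValueError("times and values must have equal length")
    _check_times(t, period)
    df = fit_harmonic_matrix(t, y[None, :], period=period)
    r = df.iloc[0]
    return RhythmFit(
        gene_id=gene_id,
        mesor=float(r["mesor"]),
        amplitude=float(r["amplitude"]),
        phase=float(r["phase"]),
        f_stat=float(r["f_stat"]),
        p_value=float(r["p_value"]),
        n_obs=int(r["n_obs"]),
    )


def _check_times(t: np.ndarray, period: float) -> None:
    if t.size < 4:
        raise ValueError(f"need >= 4 observations, got {t.size}")
    if np.unique(np.round(t % period, 9)).size < 3:
        raise ValueError("need >= 3 distinct timepoints modulo the period")


def fit_harmonic_matrix(times, values, period: float = PERIOD, gene_ids=None) -> pd.DataFrame:
    """Vectorized cosinor fit of many genes sharing one time vector.

    ``values`` is (n_genes, n_samples). Returns a DataFrame indexed by gene
    with columns mesor, amplitude, phase, f_stat, p_value, n_obs.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if y.ndim != 2 or y.shape[1] != t.size:
        raise ValueError("values must be (n_genes, n_samples)")
    _check_times(t, period)
    n = t.size
    x = _design(t, period)
    beta, *_ = np.linalg.lstsq(x, y.T, rcond=None)  # (3, n_genes)
    resid = y.T - x @ beta
    ss1 = (resid**2).sum(axis=0)
    ss0 = ((y - y.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    dfe = n - 3
    # guard the two degenerate limits: constant input and a perfect fit
    denom = ss1 / dfe
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ((ss0 - ss1) / 2) / denom
    scale = np.maximum(ss0, 1.0)
    constant = ss0 <= 1e-12 * scale
    perfect = (~constant) & (ss1 <= 1e-12 * scale)
    f = np.where(constant, 0.0, f)
    f = np.where(perfect, np.inf, f)
    f = np.maximum(f, 0.0)
    p = np.where(constant, 1.0, stats.f.sf(np.where(np.isfinite(f), f, 0.0), 2, dfe))
    p = np.where(perfect, 0.0, p)
    amplitude = np.hypot(beta[1], beta[2])
    amplitude = np.where(constant, 0.0, amplitude)
    phase = (np.arctan2(beta[2], beta[1]) * period / (2 * np.pi)) % period
    phase = np.where(phase >= period, 0.0, phase)  # (-eps) % p can round to p
    if gene_ids is None:
        gene_ids = pd.RangeIndex(y.shape[0])
    return pd.DataFrame(
        {
            "mesor": beta[0],
            "amplitude": amplitude,
            "phase": phase,
            "f_stat": f,
            "p_value": p,
            "n_obs": n,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )


def fit_experiment(matrix, period: float = PERIOD, log_transform: bool = True) -> pd.DataFrame:
    """Fit every gene of an :class:`~circaphase.ingest.ExpressionMatrix`.

    By default fits log2(TPM+1); the sample Zeitgeber times come from the
    matrix's sample sheet, replicates stacked as independent observations.
    """
    y = matrix.values.to_numpy(dtype=float)
    if log_transform:
        y = np.log2(y + 1.0)
    return fit_harmonic_matrix(
        matrix.samples["zt_hours"].to_numpy(dtype=float), y, period=period, gene_ids=matrix.values.index
    )


def consensus_cyclers(
    fits_v1: pd.DataFrame,
    fits_v2: pd.DataFrame,
    p_threshold: float = 0.1,
    dphi_threshold: float = 3.0,
) -> pd.DataFrame:
    """Genes passing the dual-experiment cycling criterion.

    A gene is kept iff p < ``p_threshold`` in BOTH experiments (strict) and
    the circular distance between the two phase estimates is strictly below
    ``dphi_threshold`` hours. Returns a DataFrame indexed by gene with
    phase_v1, phase_v2, consensus_phase (circular mean of the two), p_v1,
    p_v2. Both inputs must cover the same gene universe.
    """
    if set(fits_v1.index) != set(fits_v2.index):
        only = set(fits_v1.index) ^ set(fits_v2.index)
        raise ValueError(f"gene universes differ between experiments ({len(only)} unmatched)")
    f2 = fits_v2.loc[fits_v1.index]
    p1 = fits_v1["p_value"].to_numpy()
    p2 = f2["p_value"].to_numpy()
    ph1 = fits_v1["phase"].to_numpy()
    ph2 = f2["phase"].to_numpy()
    dphi = abs_phase_difference(ph1, ph2)
    keep = (p1 < p_threshold) & (p2 < p_threshold) & (dphi < dphi_threshold)
    idx = fits_v1.index[keep]
    consensus = [circular_mean([a, b]) for a, b in zip(ph1[keep], ph2[keep])]
    return pd.DataFrame(
        {
            "phase_v1": ph1[keep],
            "phase_v2": ph2[keep],
            "consensus_phase": consensus,
            "p_v1": p1[keep],
            "p_v2": p2[keep],
            "dphi": dphi[keep],
        },
        index=idx,
    )


def expected_false_positives(n_genes: int, p_threshold: float = 0.1, dphi_threshold: float = 3.0) -> float:
    """Expected count of non-cycling genes passing the dual criterion by chance.

    Under the null, per-experiment p-values are uniform and the two phase
    estimates independent and uniform on the circle, so the chance rate is
    ``p_threshold^2 * (2*dphi_threshold/24)`` and the expected count is that
    times ``n_genes`` (e.g. 6774 genes at defaults -> 16.935 ~ 17).
    """
    if not (0 <= p_threshold <= 1):
        raise ValueError("p_threshold must be in [0, 1]")
    if not (0 <= dphi_threshold <= PERIOD / 2):
        raise ValueError(f"dphi_threshold must be in [0, {PERIOD / 2}]")
    return n_genes * p_threshold**2 * (2 * dphi_threshold / PERIOD)


def fdr_estimate(expected_fp: float, n_detected: int) -> float:
    """Analytic FDR: expected false positives over detected count, capped at 1."""
    if n_detected <= 0:
        raise ValueError("n_detected must be positive")
    return min(expected_fp / n_detected, 1.0)


def fdr_threshold_sweep(
    fits: dict,
    p_grid,
    dphi_grid,
    n_genes: int | None = None,
) -> pd.DataFrame:
    """Detected counts and analytic FDR over a grid of thresholds.

    ``fits`` maps condition name -> (fits_v1, fits_v2) DataFrame pair. One
    row per (p_threshold, dphi_threshold) combination with per-condition
    detected counts and FDR estimates; detected counts are monotone
    non-decreasing in both thresholds.
    """
    p_grid = list(p_grid)
    dphi_grid = list(dphi_grid)
    if not p_grid or not dphi_grid:
        raise ValueError("grids must be non-empty")
    rows = []
    for p_thr in p_grid:
        for d_thr in dphi_grid:
            row = {"p_threshold": p_thr, "dphi_threshold": d_thr}
            for cond, (fv1, fv2) in fits.items():
                n_univ = n_genes if n_genes is not None else len(fv1)
                det = len(consensus_cyclers(fv1, fv2, p_thr, d_thr))
                efp = expected_false_positives(n_univ, p_thr, d_thr)
                row[f"n_detected_{cond}"] = det
                row[f"fdr_{cond}"] = fdr_estimate(efp, det) if det > 0 else np.nan
            rows.append(row)
    return pd.DataFrame(rows)
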