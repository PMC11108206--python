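"""Circular statistics on phases measured in hours on a 24-hour clock.

Phases live on the circle of circumference 24 (Zeitgeber hours). All public
functions take and return hours; radians are used internally only. The basic
primitives are the signed phase difference (positive = phase advance of the
first argument relative to the second) and the absolute phase difference,
which is the geodesic metric on the circle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

PERIOD = 24.0

_TWO_PI = 2.0 * np.pi
_KAPPA_CAP = 1e4


def _to_angle(phi):
    """Hours -> radians on [0, 2*pi)."""
    return (np.asarray(phi, dtype=float) % PERIOD) * _TWO_PI / PERIOD


def _to_hours(theta):
    """Radians -> hours on [0, 24)."""
    h = (np.asarray(theta, dtype=float) * PERIOD / _TWO_PI) % PERIOD
    # (-eps) % 24 can round to exactly 24.0; keep the half-open interval
    return np.where(h >= PERIOD, 0.0, h)


def signed_phase_difference(phi1, phi2):
    """Signed circular difference phi1 - phi2 in hours, in (-12, 12].

    Positive values indicate a phase advance of ``phi1`` relative to
    ``phi2``; negative values a delay. Computed as the argument of
    ``exp(i*2*pi*phi1/24) * exp(-i*2*pi*phi2/24)`` scaled back to hours,
    so wrap-around at midnight is handled correctly (e.g. 1 vs 23 -> +2).
    The antipodal boundary maps to +12.
    """
    d = np.angle(np.exp(1j * (_to_angle(phi1) - _to_angle(phi2)))) * PERIOD / _TWO_PI
    # np.angle returns (-pi, pi]; -12.0 can still appear through rounding
    d = np.where(np.isclose(d, -PERIOD / 2), PERIOD / 2, d)
    if np.ndim(d) == 0:
        return float(d)
    return d


def abs_phase_difference(phi1, phi2):
    """Absolute circular difference in hours, in [0, 12].

    min(|phi1 - phi2|, 24 - |phi1 - phi2|): the shortest way around the
    24-hour circle. Equal to ``abs(signed_phase_difference(phi1, phi2))``.
    """
    raw = np.abs(np.asarray(phi1, dtype=float) % PERIOD - np.asarray(phi2, dtype=float) % PERIOD)
    d = np.minimum(raw, PERIOD - raw)
    if np.ndim(d) == 0:
        return float(d)
    return d


def circular_mean(phases) -> float:
    """Circular mean of phases in hours, on [0, 24).

    The argument of the mean unit vector. Raises ``ValueError`` for an empty
    sample or when the resultant vector length is (numerically) zero, e.g.
    an antipodal pair, for which the mean direction is undefined.
    """
    phases = np.asarray(phases, dtype=float)
    if phases.size == 0:
        raise ValueError("circular mean of an empty sample is undefined")
    z = np.exp(1j * _to_angle(phases)).mean()
    if np.abs(z) < 1e-12:
        raise ValueError("zero resultant length: circular mean undefined")
    return float(_to_hours(np.angle(z)))


def circular_resultant_length(phases) -> float:
    """Mean resultant length R-bar in [0, 1] (1 = all phases identical)."""
    phases = np.asarray(phases, dtype=float)
    if phases.size == 0:
        raise ValueError("empty sample")
    return float(np.abs(np.exp(1j * _to_angle(phases)).mean()))


def circular_correlation(phases1, phases2) -> float:
    """Jammalamadaka-SenGupta circular correlation of paired phase samples.

    Both samples are mapped to angles ``2*pi*phi/24``; the coefficient is

        sum sin(a - a_bar) sin(b - b_bar)
        / sqrt(sum sin^2(a - a_bar) * sum sin^2(b - b_bar))

    with a_bar, b_bar the circular means. Invariant under rotations of
    either sample; 1 when the samples differ by a constant shift.
    """
    a = _to_angle(phases1)
    b = _to_angle(phases2)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.size} vs {b.size}")
    if a.size < 3:
        raise ValueError("need at least 3 pairs")
    sa = np.sin(a - np.angle(np.exp(1j * a).mean()))
    sb = np.sin(b - np.angle(np.exp(1j * b).mean()))
    denom = np.sqrt((sa**2).sum() * (sb**2).sum())
    if denom == 0:
        raise ValueError("a sample has zero angular variance")
    return float((sa * sb).sum() / denom)


def watson_wheeler_test(sample1, sample2):
    """Watson-Wheeler (Mardia uniform-scores) two-sample test on the circle.

    Pools the two samples, ranks the pooled angles (average ranks on ties),
    maps rank r to the uniform score ``2*pi*r/N``, and computes

        W = 2 * sum_g (C_g^2 + S_g^2) / n_g

    where C_g, S_g are the summed cosine/sine scores of group g. Under the
    null of a common distribution W is asymptotically chi-square with 2 df
    (two samples). Returns ``(W, p)``.
    """
    s1 = np.asarray(sample1, dtype=float)
    s2 = np.asarray(sample2, dtype=float)
    if s1.size == 0 or s2.size == 0:
        raise ValueError("empty sample")
    if min(s1.size, s2.size) < 10:
        warnings.warn("Watson-Wheeler test with a sample below 10 observations", stacklevel=2)
    pooled = np.concatenate([_to_angle(s1), _to_angle(s2)])
    labels = np.concatenate([np.zeros(s1.size, dtype=int), np.ones(s2.size, dtype=int)])
    ranks = stats.rankdata(pooled, method="average")
    beta = _TWO_PI * ranks / pooled.size
    w = 0.0
    for g, n_g in ((0, s1.size), (1, s2.size)):
        c = np.cos(beta[labels == g]).sum()
        s = np.sin(beta[labels == g]).sum()
        w += (c * c + s * s) / n_g
    w *= 2.0
    return float(w), float(stats.chi2.sf(w, df=2))


def circular_median_test(diffs, hypothesized_median: float = 0.0):
    """Exact sign test for the circular median of signed hour differences.

    Under the null that ``hypothesized_median`` is the circular median,
    observations fall on either half-circle with probability 1/2. Counts
    observations strictly clockwise (negative side) vs counter-clockwise
    (positive side) of the hypothesized median and returns the two-sided
    exact binomial p-value. Observations exactly at the median or at its
    antipode carry no sign information and are dropped from the count.
    """
    diffs = np.asarray(diffs, dtype=float)
    if diffs.size < 5:
        raise ValueError("need at least 5 observations")
    signed = signed_phase_difference(diffs, hypothesized_median)
    signed = np.atleast_1d(signed)
    pos = int(np.sum((signed > 0) & (signed < PERIOD / 2)))
    neg = int(np.sum(signed < 0))
    n_eff = pos + neg
    if n_eff == 0:
        raise ValueError("all observations on the boundary: no sign information")
    return float(stats.binomtest(pos, n_eff, 0.5, alternative="two-sided").pvalue)


# ---------------------------------------------------------------------------
# von Mises mixture


def _log_vonmises_pdf(theta, mu, kappa):
    # overflow-safe: log I0(k) = log(i0e(k)) + k
    return kappa * np.cos(theta - mu) - np.log(_TWO_PI) - (np.log(special.i0e(kappa)) + kappa)


def _kappa_from_rbar(rbar: float) -> float:
    """Invert A(kappa) = I1/I0 = rbar: Best-Fisher start + Newton refinement."""
    rbar = min(max(rbar, 0.0), 1.0 - 1e-12)
    if rbar < 1e-8:
        return 0.0
    # Best & Fisher (1981) piecewise approximation
    if rbar < 0.53:
        k = 2 * rbar + rbar**3 + 5 * rbar**5 / 6
    elif rbar < 0.85:
        k = -0.4 + 1.39 * rbar + 0.43 / (1 - rbar)
    else:
        k = 1 / (rbar**3 - 4 * rbar**2 + 3 * rbar)
    for _ in range(25):
        if k > _KAPPA_CAP:
            return _KAPPA_CAP
        a = special.i1e(k) / special.i0e(k)
        # A'(kappa) = 1 - A/kappa - A^2
        da = 1 - a / k - a * a if k > 0 else 0.5
        if da <= 0:
            break
        step = (a - rbar) / da
        k -= step
        if abs(step) < 1e-12 * max(1.0, k):
            break
    return float(min(max(k, 0.0), _KAPPA_CAP))


@dataclass
class VonMisesMixture:
    """Two-component (or small-k) von Mises mixture fit by EM on 24-h phases.

    Parameters mirror the sklearn mixture idiom: construct with
    hyper-parameters, call :meth:`fit` on a phase sample in hours, then read
    the fitted attributes ``means_`` (hours), ``kappas_``, ``weights_`` and
    ``log_likelihood_``. The best of ``n_init`` seeded restarts by final
    log-likelihood is kept. Concentrations are capped at 1e4 to keep
    near-point-mass components finite.
    """

    n_components: int = 2
    n_init: int = 10
    max_iter: int = 500
    tol: float = 1e-8
    seed: int | None = None

    means_: np.ndarray = field(default=None, repr=False)
    kappas_: np.ndarray = field(default=None, repr=False)
    weights_: np.ndarray = field(default=None, repr=False)
    log_likelihood_: float = field(default=None, repr=False)
    converged_: bool = field(default=False, repr=False)

    def fit(self, phases) -> "VonMisesMixture":
        theta = _to_angle(phases)
        if theta.size < 10:
            raise ValueError("need at least 10 observations to fit a mixture")
        rng = np.random.default_rng(self.seed)
        best = None
        for _ in range(self.n_init):
            params = self._em(theta, rng)
            if best is None or params[3] > best[3]:
                best = params
        mu, kappa, w, ll, conv = best
        order = np.argsort(_to_hours(mu))
        self.means_ = _to_hours(mu)[order]
        self.kappas_ = kappa[order]
        self.weights_ = w[order]
        self.log_likelihood_ = float(ll)
        self.converged_ = bool(conv)
        if not conv:
            warnings.warn("EM did not converge within max_iter; best iterate returned", stacklevel=2)
        return self

    def _em(self, theta, rng):
        k = self.n_components
        mu = theta[rng.choice(theta.size, size=k, replace=False)]
        kappa = np.ones(k)
        w = np.full(k, 1.0 / k)
        ll_old = -np.inf
        converged = False
        for _ in range(self.max_iter):
            log_comp = np.log(w)[:, None] + _log_vonmises_pdf(theta[None, :], mu[:, None], kappa[:, None])
            log_norm = special.logsumexp(log_comp, axis=0)
            ll = float(log_norm.sum())
            resp = np.exp(log_comp - log_norm[None, :])  # (k, n)
            nk = resp.sum(axis=1)
            nk = np.maximum(nk, 1e-300)
            w = nk / theta.size
            z = (resp * np.exp(1j * theta)[None, :]).sum(axis=1)
            mu = np.angle(z)
            rbar = np.abs(z) / nk
            kappa = np.array([_kappa_from_rbar(r) for r in rbar])
            if ll - ll_old < self.tol * max(1.0, abs(ll)) and ll >= ll_old - 1e-9:
                converged = True
                ll_old = ll
                break
            ll_old = ll
        return mu, kappa, w, ll_old, converged

    def pdf(self, phases):
        """Mixture density per hour (integrates to 1 over [0, 24))."""
        theta = _to_angle(phases)
        log_comp = np.log(self.weights_)[:, None] + _log_vonmises_pdf(
            theta[None, :], _to_angle(self.means_)[:, None], self.kappas_[:, None]
        )
        return np.exp(special.logsumexp(log_comp, axis=0)) * _TWO_PI / PERIOD


def fit_vonmises_mixture(
    phases, k: int = 2, n_init: int = 10, max_iter: int = 500, tol: float = 1e-8, seed: int | None = None
) -> VonMisesMixture:
    """Fit a k-component von Mises mixture to phases in hours (EM, restarts)."""
    return VonMisesMixture(n_components=k, n_init=n_init, max_iter=max_iter, tol=tol, seed=seed).fit(phases)
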