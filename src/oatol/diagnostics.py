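"""Posterior-interval and MCMC convergence diagnostics.

Implements the highest-posterior-density interval and the classical
Heidelberger–Welch chain diagnostics: an iterated Cramér–von Mises
stationarity test on the Brownian-bridge-normalized partial sums of the
chain (progressively discarding initial 10% increments up to 50%), and a
relative-halfwidth precision test on the retained portion.  The spectral
density at frequency zero is estimated from an AR fit with Yule–Walker
coefficients and AIC order selection, as is conventional for these
tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special


def hpd_interval(samples, prob: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing `prob` of the samples.

    Ties are broken toward the leftmost window.  Requires at least 20
    samples for the empirical interval to mean anything.
    """
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.size
    if n < 20:
        raise ValueError("need at least 20 samples for an HPD interval")
    if not 0.0 < prob <= 1.0:
        raise ValueError("prob must be in (0, 1]")
    m = int(np.ceil(prob * n))
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m - 1 :] - x[: n - m + 1]
    k = int(np.argmin(widths))
    return float(x[k]), float(x[k + m - 1])


def quantile_interval(samples, prob: float = 0.95) -> tuple[float, float]:
    """Central (equal-tail) credible interval."""
    lo, hi = np.quantile(np.asarray(samples, dtype=float), [(1 - prob) / 2, (1 + prob) / 2])
    return float(lo), float(hi)


def lag1_autocorrelation(x) -> float:
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    denom = float(x @ x)
    if denom == 0.0:
        return 0.0
    return float(x[:-1] @ x[1:]) / denom


def spectrum0_ar(x, max_order: int | None = None) -> float:
    """Spectral density of a time series at frequency zero.

    Yule–Walker AR fit with order chosen by AIC (orders 0..max_order,
    default 10*log10(n) as in standard implementations);
    S(0) = sigma^2 / (1 - sum(phi))^2.  A constant series has S(0) = 0.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 10:
        raise ValueError("series too short for a spectral estimate")
    xc = x - x.mean()
    c0 = float(xc @ xc) / n
    if c0 == 0.0:
        return 0.0
    if max_order is None:
        max_order = int(min(n - 1, np.floor(10.0 * np.log10(n))))
    # autocovariances with divisor n (biased, standard for Yule-Walker)
    acov = np.array([float(xc[: n - k] @ xc[k:]) / n for k in range(max_order + 1)])

    # Levinson-Durbin recursion, tracking innovation variance per order
    best_order, best_aic = 0, n * np.log(c0)
    best_phi: np.ndarray = np.array([])
    phi = np.zeros(0)
    v = c0
    for k in range(1, max_order + 1):
        if v <= 0:
            break
        num = acov[k] - (phi @ acov[1:k][::-1] if k > 1 else 0.0)
        refl = num / v
        phi_new = np.empty(k)
        phi_new[: k - 1] = phi - refl * phi[::-1]
        phi_new[k - 1] = refl
        v = v * (1.0 - refl**2)
        phi = phi_new
        aic = n * np.log(max(v, 1e-300)) + 2.0 * k
        if aic < best_aic:
            best_order, best_aic, best_phi = k, aic, phi.copy()
    if best_order == 0:
        return c0
    denom = (1.0 - best_phi.sum()) ** 2
    # innovation variance at the selected order
    v = c0
    phi = np.zeros(0)
    for k in range(1, best_order + 1):
        num = acov[k] - (phi @ acov[1:k][::-1] if k > 1 else 0.0)
        refl = num / v
        phi_new = np.empty(k)
        phi_new[: k - 1] = phi - refl * phi[::-1]
        phi_new[k - 1] = refl
        v = v * (1.0 - refl**2)
        phi = phi_new
    return float(v / denom)


def pcramer(q: float, eps: float = 1e-5) -> float:
    """CDF of the asymptotic Cramér–von Mises distribution at q."""
    if q <= 0:
        return 0.0
    total = 0.0
    for k in range(4):
        z = (
            special.gamma(k + 0.5)
            * np.sqrt(4.0 * k + 1.0)
            / (special.gamma(k + 1.0) * np.pi**1.5 * np.sqrt(q))
        )
        u = (4.0 * k + 1.0) ** 2 / (16.0 * q)
        if u > -np.log(eps):
            continue
        total += z * np.exp(-u) * special.kv(0.25, u)
    return float(min(max(total, 0.0), 1.0))


def cvm_stationarity(x, s0: float | None = None) -> tuple[float, float]:
    """Single-window Cramér–von Mises stationarity statistic and p-value.

    The statistic integrates the squared Brownian bridge of partial sums
    normalized by n * S(0); under stationarity it follows the asymptotic
    Cramér–von Mises distribution, so rejecting when the p-value is
    below alpha is calibrated near the nominal level on iid chains.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if s0 is None:
        s0 = spectrum0_ar(x[n // 2 :])
    bridge = np.cumsum(x) - x.mean() * np.arange(1, n + 1)
    if s0 <= 0:
        return 0.0, 1.0
    stat = float((bridge**2).sum() / (n**2 * s0))
    return stat, 1.0 - pcramer(stat)


@dataclass
class HeidelbergerWelchResult:
    stationarity_passed: bool
    start_iteration: int  # 0-based index of first retained sample
    cvm_pvalue: float
    mean: float
    halfwidth: float
    halfwidth_passed: bool
    n_used: int


def heidelberger_welch(
    x, alpha: float = 0.05, eps: float = 0.1
) -> HeidelbergerWelchResult:
    """Heidelberger–Welch stationarity and halfwidth tests for one chain.

    Stationarity: starting from the full chain and then discarding
    initial 10% increments (up to half the chain), compute the
    Cramér–von Mises statistic of the partial-sum bridge normalized by
    n * S(0), with S(0) estimated once from the second half of the
    chain; the first window whose statistic is below the alpha critical
    value passes.  Halfwidth: on the passing window, the 95% halfwidth
    1.96*sqrt(S(0)/n) must be at most `eps` times |mean|.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 100:
        raise ValueError("chain too short for Heidelberger-Welch diagnostics")
    if np.ptp(x) == 0.0:
        # constant chain: trivially stationary, zero halfwidth
        return HeidelbergerWelchResult(True, 0, 1.0, float(x[0]), 0.0, True, n)

    s0 = spectrum0_ar(x[n // 2 :])
    starts = [int(round(f * n)) for f in np.arange(0.0, 0.51, 0.1)]
    passed, pvalue, start_used = False, 0.0, starts[-1]
    for start in starts:
        _, pvalue = cvm_stationarity(x[start:], s0=s0)
        start_used = start
        if pvalue > alpha:
            passed = True
            break

    y = x[start_used:]
    ny = y.size
    ybar = float(y.mean())
    s0_ci = spectrum0_ar(y)
    halfwidth = 1.96 * np.sqrt(s0_ci / ny)
    hw_passed = bool(passed and abs(halfwidth) <= eps * abs(ybar)) if ybar != 0 else False
    if halfwidth == 0.0:
        hw_passed = bool(passed)
    return HeidelbergerWelchResult(
        stationarity_passed=passed,
        start_iteration=start_used,
        cvm_pvalue=float(pvalue),
        mean=ybar,
        halfwidth=float(halfwidth),
        halfwidth_passed=hw_passed,
        n_used=ny,
    )
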