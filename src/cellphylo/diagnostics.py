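"""MCMC convergence diagnostics: autocorrelation and effective sample size.

Mirrors the usual CODA-style workflow: inspect the trace, the posterior
density, and the autocorrelation of the sampled transition rate, and reduce
them to an effective sample size (ESS).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["autocorrelation", "ess", "EssResult"]


def autocorrelation(samples, max_lag: int) -> np.ndarray:
    """Autocorrelation r(0..max_lag): biased autocovariance over lag-0 variance.

    ``max_lag`` must be below n/2.
    """
    x = np.asarray(samples, dtype=float)
    n = x.shape[0]
    if max_lag >= n / 2:
        raise ValueError("max_lag must be < n/2")
    x = x - x.mean()
    c0 = float(x @ x) / n
    if c0 == 0.0:
        out = np.zeros(max_lag + 1)
        out[0] = 1.0
        return out
    # FFT-based autocovariance (biased: normalized by n at every lag)
    m = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(x, m)
    acov = np.fft.irfft(f * np.conjugate(f), m)[: max_lag + 1] / n
    return acov / c0


@dataclass(frozen=True)
class EssResult:
    ess: float
    tau: float  # integrated autocorrelation time
    n: int
    degenerate: bool = False

    def __float__(self) -> float:
        return self.ess


def ess(samples) -> EssResult:
    """Effective sample size by Geyer's initial positive sequence estimator.

    Sums autocorrelations in adjacent pairs ``rho(2m) + rho(2m+1)`` while the
    pair sums stay positive.  A constant series is flagged degenerate and
    reported as ESS = n.  Anti-correlated chains can legitimately yield
    ESS > n.
    """
    x = np.asarray(samples, dtype=float)
    n = x.shape[0]
    if n < 10:
        raise ValueError("need at least 10 samples")
    if np.ptp(x) == 0.0:
        return EssResult(ess=float(n), tau=1.0, n=n, degenerate=True)
    max_lag = n // 2 - 1
    rho = autocorrelation(x, max_lag)
    tau = 1.0
    m = 0
    while 2 * m + 1 <= max_lag:
        pair = rho[2 * m] + rho[2 * m + 1]
        if m > 0 and pair < 0.0:
            break
        tau += 2.0 * pair if m > 0 else 2.0 * (pair - rho[0])
        m += 1
    # tau = 1 + 2 sum_{t>=1} rho_t truncated at the first negative pair sum
    tau = max(tau, 1e-12)
    return EssResult(ess=n / tau, tau=tau, n=n)
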