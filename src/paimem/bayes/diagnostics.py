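"""Posterior summaries and MCMC convergence diagnostics.

Posteriors are summarized by their mean and the 95% highest density interval
(HDI): the narrowest interval containing the requested posterior mass, so that
every point inside is more credible than any point outside.  A contrast is
"credible" when zero lies outside the HDI of the difference.

Convergence is monitored with the Gelman-Rubin potential scale reduction
factor (rhat), the effective sample size (ESS, via Geyer's initial positive
sequence of paired autocorrelations) and the autocorrelation function.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PosteriorSummary",
    "hdi",
    "gelman_rubin",
    "ess",
    "acf",
    "summarize",
    "contrast",
]


@dataclass(frozen=True)
class PosteriorSummary:
    name: str
    mean: float
    hdi_low: float
    hdi_high: float
    rhat: float | None
    ess: float | None

    @property
    def credible_nonzero(self) -> bool:
        """True when 0 is not among the credible values (outside the HDI)."""
        return not (self.hdi_low <= 0.0 <= self.hdi_high)

    def as_dict(self) -> dict:
        return {
            "name": self.name,
            "mean": self.mean,
            "hdi_low": self.hdi_low,
            "hdi_high": self.hdi_high,
            "rhat": self.rhat,
            "ess": self.ess,
        }


def hdi(draws, mass: float = 0.95) -> tuple[float, float]:
    """Narrowest interval containing ``ceil(mass * n)`` of the sorted draws."""
    x = np.sort(np.asarray(draws, dtype=float).ravel())
    n = x.size
    if n < 100:
        raise ValueError(f"need at least 100 draws for an HDI, got {n}")
    if not 0.0 < mass <= 1.0:
        raise ValueError("mass must lie in (0, 1]")
    m = int(math.ceil(mass * n))
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m - 1 :] - x[: n - m + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])


def _as_chains(draws) -> np.ndarray:
    x = np.asarray(draws, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    if x.ndim != 2:
        raise ValueError("draws must be (n,) or (chains, n)")
    return x


def gelman_rubin(chains) -> float:
    """Potential scale reduction factor from >= 2 chains.

    Classic between/within variance ratio: identical chains give 1.0 (up to
    the (n-1)/n finite-sample factor); diverged chains give values >> 1.
    """
    x = _as_chains(chains)
    m, n = x.shape
    if m < 2:
        raise ValueError("gelman_rubin requires at least 2 chains")
    means = x.mean(axis=1)
    w = x.var(axis=1, ddof=1).mean()
    b = n * means.var(ddof=1)
    if w == 0.0:
        return 1.0
    v_hat = (n - 1) / n * w + b / n
    return float(np.sqrt(v_hat / w))


def acf(draws, max_lag: int) -> np.ndarray:
    """Autocorrelation at lags 0..max_lag (FFT-based, biased normalization)."""
    x = np.asarray(draws, dtype=float).ravel()
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 draws")
    max_lag = min(max_lag, n - 1)
    x = x - x.mean()
    size = int(2 ** math.ceil(math.log2(2 * n)))
    f = np.fft.rfft(x, size)
    ac = np.fft.irfft(f * np.conj(f))[: max_lag + 1].real
    if ac[0] == 0.0:
        out = np.zeros(max_lag + 1)
        out[0] = 1.0
        return out
    return ac / ac[0]


def ess(chains) -> float:
    """Effective sample size via Geyer's initial positive-pair sequence.

    Autocorrelations are averaged over chains; the sum of consecutive-lag
    pairs is truncated at the first non-positive pair.
    """
    x = _as_chains(chains)
    m, n = x.shape
    if n < 4:
        return float(m * n)
    if np.allclose(x.var(), 0.0):
        return float(m * n)
    max_lag = n - 2
    rho = np.mean([acf(x[c], max_lag) for c in range(m)], axis=0)
    s = 0.0
    for k in range(1, max_lag, 2):
        pair = rho[k] + rho[k + 1] if k + 1 <= max_lag else rho[k]
        if pair <= 0.0:
            break
        s += pair
    return float(min(m * n, m * n / (1.0 + 2.0 * s)))


def summarize(name: str, chains, mass: float = 0.95,
              diagnostics: bool = True) -> PosteriorSummary:
    """Mean, HDI and (for multi-chain input) rhat/ESS of one quantity."""
    x = _as_chains(chains)
    lo, hi = hdi(x.ravel(), mass)
    rhat = gelman_rubin(x) if diagnostics and x.shape[0] >= 2 else None
    n_eff = ess(x) if diagnostics else None
    return PosteriorSummary(name, float(x.mean()), lo, hi, rhat, n_eff)


def contrast(draws_a, draws_b, name: str = "contrast",
             mass: float = 0.95) -> PosteriorSummary:
    """Summary of the elementwise difference a - b; credible iff 0 outside HDI."""
    a, b = np.asarray(draws_a, dtype=float), np.asarray(draws_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("contrast requires equal-shape draw arrays")
    return summarize(name, a - b, mass=mass, diagnostics=a.ndim >= 2)
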