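"""MCMC convergence and efficiency diagnostics.

Rank-normalised split-Rhat and bulk/tail effective sample sizes, with the
acceptance thresholds used for the fitted models: Rhat < 1.01 indicates good
convergence, bulk-ESS >= 1000 reliable central estimates, and tail-ESS >=
1000 reliable extreme quantiles.

All functions take a ``(chains, draws)`` array, require at least two chains
of at least four draws, and raise :class:`UndefinedDiagnosticError` on
constant input rather than returning a silent 1.0.  The classic (non-rank,
non-split) Gelman-Rubin statistic is exposed for comparison.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.fft import next_fast_len
from scipy.stats import norm, rankdata

__all__ = [
    "UndefinedDiagnosticError",
    "split_rhat",
    "gelman_rubin",
    "ess_bulk",
    "ess_tail",
    "ess_mean",
    "diagnostics_report",
    "DiagnosticsReport",
]

RHAT_THRESHOLD = 1.01
ESS_THRESHOLD = 1000.0


class UndefinedDiagnosticError(ValueError):
    """The diagnostic is undefined for this input (e.g. constant draws)."""


def _validate(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a (chains, draws) array")
    if x.shape[0] < 2:
        raise ValueError("need >= 2 chains")
    if x.shape[1] < 4:
        raise ValueError("need >= 4 draws per chain")
    if not np.isfinite(x).all():
        raise ValueError("draws contain non-finite values")
    if np.ptp(x) == 0:
        raise UndefinedDiagnosticError("draws are constant; diagnostic undefined")
    return x


def _split(x: np.ndarray) -> np.ndarray:
    """Split each chain in half, dropping one trailing draw if odd length."""
    half = x.shape[1] // 2
    return np.vstack([x[:, :half], x[:, half : 2 * half]])


def _z_scale(x: np.ndarray) -> np.ndarray:
    """Rank-normalise draws jointly over all chains (fractional offset 3/8)."""
    r = rankdata(x, method="average").reshape(x.shape)
    return norm.ppf((r - 0.375) / (x.size + 0.25))


def _rhat_of(x: np.ndarray) -> float:
    """Potential scale reduction of already-split (and transformed) chains."""
    m, n = x.shape
    means = x.mean(axis=1)
    w = float(x.var(axis=1, ddof=1).mean())
    b = n * float(means.var(ddof=1))
    if w == 0:
        raise UndefinedDiagnosticError("zero within-chain variance")
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


def split_rhat(chains: np.ndarray) -> float:
    """Rank-normalised split-Rhat (max of the bulk and folded variants)."""
    x = _split(_validate(chains))
    bulk = _rhat_of(_z_scale(x))
    folded = _rhat_of(_z_scale(np.abs(x - np.median(x))))
    return max(bulk, folded)


def gelman_rubin(chains: np.ndarray) -> float:
    """Classic potential scale reduction factor, no splitting or ranks."""
    return _rhat_of(_validate(chains))


def _autocovariance(x: np.ndarray) -> np.ndarray:
    """Per-chain autocovariance (biased, by FFT) at all lags."""
    m, n = x.shape
    xc = x - x.mean(axis=1, keepdims=True)
    size = next_fast_len(2 * n)
    f = np.fft.rfft(xc, size, axis=1)
    acov = np.fft.irfft(f * np.conj(f), size, axis=1)[:, :n].real
    return acov / n


def _ess_of(x: np.ndarray) -> float:
    """ESS of already-split chains via Geyer's initial monotone sequence."""
    m, n = x.shape
    if np.ptp(x) == 0:
        raise UndefinedDiagnosticError("constant chains after transformation")
    acov = _autocovariance(x)
    chain_var = acov[:, 0] * n / (n - 1)
    w = float(chain_var.mean())
    mean_var = float(acov[:, 0].mean())
    var_plus = mean_var * (n - 1) / n
    if m > 1:
        var_plus += float(x.mean(axis=1).var(ddof=1))
    if var_plus == 0 or w == 0:
        raise UndefinedDiagnosticError("zero variance in ESS computation")

    rho = 1.0 - (w - acov.mean(axis=0)) / var_plus
    rho[0] = 1.0
    # Geyer pairing: Gamma_k = rho_{2k} + rho_{2k+1}, truncated at the first
    # non-positive pair and forced monotone non-increasing
    tau = 0.0
    prev_pair = np.inf
    t = 0
    while t + 1 < n:
        pair = rho[t] + rho[t + 1]
        if pair <= 0:
            break
        pair = min(pair, prev_pair)
        tau += pair
        prev_pair = pair
        t += 2
    tau_hat = max(-1.0 + 2.0 * tau, 1.0 / np.log10(m * n + 10.0))
    ess = m * n / tau_hat
    return float(min(ess, m * n * np.log10(m * n)))


def ess_mean(chains: np.ndarray) -> float:
    """ESS of the untransformed draws (controls the MCSE of posterior means)."""
    return _ess_of(_split(_validate(chains)))


def ess_bulk(chains: np.ndarray) -> float:
    """Bulk ESS: ESS of rank-normalised split chains."""
    return _ess_of(_z_scale(_split(_validate(chains))))


def ess_tail(chains: np.ndarray, quantiles: tuple[float, float] = (0.05, 0.95)) -> float:
    """Tail ESS: minimum ESS of the lower/upper exceedance indicators."""
    x = _validate(chains)
    out = []
    for q in quantiles:
        cut = np.quantile(x, q)
        ind = (x <= cut).astype(float)
        if np.ptp(ind) == 0:
            raise UndefinedDiagnosticError(
                f"quantile indicator at q={q} is constant; tail ESS undefined"
            )
        out.append(_ess_of(_split(ind)))
    return float(min(out))


class DiagnosticsReport:
    """Per-parameter Rhat / bulk-ESS / tail-ESS with a global pass flag."""

    def __init__(self, table: pd.DataFrame, rhat_threshold: float, ess_threshold: float):
        self.table = table
        self.rhat_threshold = rhat_threshold
        self.ess_threshold = ess_threshold

    @property
    def passed(self) -> bool:
        t = self.table
        ok = (
            (t["rhat"] < self.rhat_threshold)
            & (t["ess_bulk"] >= self.ess_threshold)
            & (t["ess_tail"] >= self.ess_threshold)
        )
        return bool(ok.all()) and not t[["rhat", "ess_bulk", "ess_tail"]].isna().any().any()

    def to_csv(self, path) -> None:
        out = self.table.copy()
        out["pass"] = (
            (out["rhat"] < self.rhat_threshold)
            & (out["ess_bulk"] >= self.ess_threshold)
            & (out["ess_tail"] >= self.ess_threshold)
        )
        out.to_csv(path, index=False)

    def __str__(self) -> str:
        status = "PASS" if self.passed else "FAIL"
        worst = self.table.loc[self.table["rhat"].idxmax()]
        return (
            f"diagnostics {status}: max Rhat {worst['rhat']:.4f} ({worst['parameter']}), "
            f"min bulk-ESS {self.table['ess_bulk'].min():.0f}, "
            f"min tail-ESS {self.table['ess_tail'].min():.0f}"
        )


def diagnostics_report(
    results,
    rhat_threshold: float = RHAT_THRESHOLD,
    ess_threshold: float = ESS_THRESHOLD,
) -> DiagnosticsReport:
    """Diagnostics for every parameter of a fitted model's posterior."""
    rows = []
    for k, name in enumerate(results.param_names):
        x = results.draws[:, :, k]
        try:
            rows.append(
                {
                    "parameter": name,
                    "rhat": split_rhat(x),
                    "ess_bulk": ess_bulk(x),
                    "ess_tail": ess_tail(x),
                }
            )
        except UndefinedDiagnosticError:
            rows.append(
                {"parameter": name, "rhat": np.nan, "ess_bulk": np.nan, "ess_tail": np.nan}
            )
    return DiagnosticsReport(pd.DataFrame(rows), rhat_threshold, ess_threshold)
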