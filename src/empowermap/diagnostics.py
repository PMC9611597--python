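"""MCMC convergence diagnostics: Geweke z-scores and Gelman-Rubin PSRF.

The Geweke diagnostic compares the mean of an early chain window (first
10% after burn-in) against a late window (last 50%) with a z-statistic
whose standard errors come from spectral-density-at-zero estimates on
each window, so autocorrelation within a window is accounted for.  The
spectral density is estimated with a Bartlett lag window truncated at 4%
of the window length.

The Gelman-Rubin potential scale reduction factor (PSRF) compares
between- and within-chain variance across independently seeded chains;
values near 1 (97.5% quantile below 1.02 by default) indicate that the
chains are sampling the same distribution.  The multivariate PSRF of
Brooks & Gelman summarises a parameter block jointly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def spectral_density_zero(x: np.ndarray, taper: float = 0.04) -> float:
    """Lag-window estimate of the spectral density at frequency zero.

    Bartlett weights w_l = 1 - l/(L+1) with truncation lag L = floor(taper*n).
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("window too short")
    xc = x - x.mean()
    var = xc @ xc / n
    if var == 0:
        raise ValueError("zero variance (constant chain segment)")
    lag_max = int(np.floor(taper * n))
    s = var
    for lag in range(1, lag_max + 1):
        gamma = xc[:-lag] @ xc[lag:] / n
        s += 2.0 * (1.0 - lag / (lag_max + 1.0)) * gamma
    return float(max(s, 1e-12 * var))


def geweke_z(chain, first: float = 0.10, last: float = 0.50) -> float:
    """Geweke z-score between the first and last fractions of a chain."""
    x = np.asarray(chain, dtype=float)
    n = x.size
    n1 = int(np.floor(first * n))
    n2 = int(np.floor(last * n))
    if n1 < 2 or n2 < 2:
        raise ValueError("chain too short for the requested windows")
    if n1 + n2 > n:
        raise ValueError("first and last windows overlap")
    seg1 = x[:n1]
    seg2 = x[n - n2:]
    se2_1 = spectral_density_zero(seg1) / n1
    se2_2 = spectral_density_zero(seg2) / n2
    return float((seg1.mean() - seg2.mean()) / np.sqrt(se2_1 + se2_2))


@dataclass
class DiagnosticsReport:
    """Per-parameter diagnostics plus the multivariate PSRF."""

    table: pd.DataFrame  # parameter, psrf, psrf_upper, geweke_z..., flags
    mpsrf: float | None
    psrf_threshold: float
    z_threshold: float

    @property
    def all_pass(self) -> bool:
        cols = [c for c in ("psrf_pass", "geweke_pass") if c in self.table]
        return bool(self.table[cols].all().all())


def _psrf_single(chains: np.ndarray) -> tuple[float, float]:
    """Point estimate and 97.5% quantile of the PSRF for one parameter.

    ``chains`` is (m, n).  Follows the variance decomposition of Gelman &
    Rubin (1992) with the Brooks & Gelman (1998) df correction.
    """
    m, n = chains.shape
    xbar = chains.mean(axis=1)
    s2 = chains.var(axis=1, ddof=1)
    w = s2.mean()
    b = n * xbar.var(ddof=1)
    if w == 0:
        return 1.0, 1.0
    sig2 = (n - 1) / n * w + b / n
    v = sig2 + b / (m * n)
    var_w = s2.var(ddof=1) / m if m > 1 else 0.0
    var_b = 2.0 * b * b / (m - 1)
    mu = chains.mean()
    cov_wb = (n / m) * (
        _cov(s2, xbar**2) - 2.0 * mu * _cov(s2, xbar)
    )
    var_v = (
        ((n - 1) ** 2) * var_w
        + ((1.0 + 1.0 / m) ** 2) * var_b
        + 2.0 * (n - 1) * (1.0 + 1.0 / m) * cov_wb
    ) / n**2
    if var_v <= 0 or v <= 0:
        df = np.inf
    else:
        df = 2.0 * v * v / var_v
    df_adj = (df + 3.0) / (df + 1.0) if np.isfinite(df) else 1.0
    r2_fixed = (n - 1) / n
    r2_rand = (1.0 + 1.0 / m) * b / (n * w)
    psrf = float(np.sqrt(df_adj * (r2_fixed + r2_rand)))
    # upper limit: replace the random term by its 97.5% F-quantile scaling
    df_w = 2.0 * w * w / var_w if var_w > 0 else np.inf
    if np.isfinite(df_w):
        fq = stats.f.ppf(0.975, m - 1, df_w)
    else:
        fq = stats.chi2.ppf(0.975, m - 1) / (m - 1)
    upper = float(np.sqrt(df_adj * (r2_fixed + fq * r2_rand)))
    return psrf, upper


def _cov(a: np.ndarray, b: np.ndarray) -> float:
    if a.size < 2:
        return 0.0
    return float(np.cov(a, b, ddof=1)[0, 1])


def multivariate_psrf(chains: np.ndarray) -> float:
    """Brooks-Gelman multivariate PSRF for an (m, n, p) parameter block."""
    m, n, p = chains.shape
    xbar = chains.mean(axis=1)  # (m, p)
    w = np.zeros((p, p))
    for c in range(m):
        d = chains[c] - xbar[c]
        w += d.T @ d / (n - 1)
    w /= m
    grand = xbar.mean(axis=0)
    bn = np.zeros((p, p))
    for c in range(m):
        d = (xbar[c] - grand)[:, None]
        bn += d @ d.T
    bn /= m - 1  # = B / n
    lam = np.max(np.real(np.linalg.eigvals(np.linalg.solve(w, bn))))
    return float(np.sqrt((n - 1) / n + (m + 1) / m * lam))


def gelman_rubin(
    chains: dict | np.ndarray,
    multivariate_block: str | None = "beta",
    psrf_threshold: float = 1.02,
) -> DiagnosticsReport:
    """PSRF report across >= 2 equal-length chains.

    ``chains`` maps parameter names to (m, n) arrays, or is a single (m, n)
    array.  The multivariate PSRF is computed over the named block when the
    input is the chain dictionary of a :class:`~empowermap.star.FitResult`.
    """
    if isinstance(chains, np.ndarray):
        chains = {"param": chains}
    rows = []
    scalar_chains = _as_scalar_chains(chains)
    for name, arr in scalar_chains.items():
        if arr.ndim != 2:
            raise ValueError(f"{name}: expected (m, n) chains")
        if arr.shape[0] < 2:
            raise ValueError("Gelman-Rubin needs at least 2 chains")
        psrf, upper = _psrf_single(arr)
        rows.append(
            {"parameter": name, "psrf": psrf, "psrf_upper": upper,
             "psrf_pass": upper < psrf_threshold}
        )
    table = pd.DataFrame(rows)
    mpsrf = None
    if multivariate_block is not None:
        block = [v for k, v in scalar_chains.items()
                 if k.startswith(multivariate_block)]
        if len(block) >= 2:
            stacked = np.stack(block, axis=-1)  # (m, n, p)
            mpsrf = multivariate_psrf(stacked)
    return DiagnosticsReport(
        table=table, mpsrf=mpsrf,
        psrf_threshold=psrf_threshold, z_threshold=1.96,
    )


def _as_scalar_chains(chains: dict) -> dict:
    """Flatten (m, n, ...) blocks into named scalar (m, n) chains."""
    out = {}
    for name, arr in chains.items():
        arr = np.asarray(arr)
        if arr.ndim == 2:
            out[name] = arr
        else:
            flat = arr.reshape(arr.shape[0], arr.shape[1], -1)
            for idx in range(flat.shape[2]):
                out[f"{name}[{idx}]"] = flat[:, :, idx]
    return out


def geweke_report(
    chains: dict | np.ndarray,
    first: float = 0.10,
    last: float = 0.50,
    z_threshold: float = 1.96,
) -> pd.DataFrame:
    """Geweke z per scalar parameter and chain, with pass flags."""
    if isinstance(chains, np.ndarray):
        chains = {"param": np.atleast_2d(chains)}
    rows = []
    for name, arr in _as_scalar_chains(chains).items():
        for c in range(arr.shape[0]):
            z = geweke_z(arr[c], first=first, last=last)
            rows.append(
                {"parameter": name, "chain": c, "geweke_z": z,
                 "geweke_pass": abs(z) < z_threshold}
            )
    return pd.DataFrame(rows)


def beta_chains(fit, params: tuple[str, ...] = ("beta",)) -> dict:
    """Extract the fixed-effect chains of a FitResult for diagnostics.

    By default only the 2 x 8 beta elements are reported (the 16 scalars
    the convergence assessment targets); pass more block names to widen.
    """
    return {name: fit.chains[name] for name in params}
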