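"""Bayesian multinomial logit structured additive regression (STAR).

For respondent i in region j with PSU u(ij), category probabilities follow
a 3-category multinomial logit with the "modal" category k = 3 as
reference (eta_ij3 = 0) and, for k = 1, 2,

    eta_ijk = x_ij beta_k + f_k(age_ij) + b_{u(ij),k} + s_{jk}

with priors: flat beta; cubic P-spline f_k with a second-order random-walk
prior on its 23 coefficients; iid Normal(0, tau2_psu) PSU effects; an
intrinsic Markov-random-field prior on the region effects s_k (conditional
mean the neighbour average, conditional variance tau2_region / N_j); and
IG(0.001, 0.001) hyperpriors on all three variances.  The null model drops
the structured region term.

Posterior simulation is by Gibbs sampling with Polya-Gamma augmentation.
Each category k is reduced to a conditional Bernoulli-logit problem
("partial logit"): given the other category's predictor, Y_ik is Bernoulli
with success probability logistic(eta_ik - c_ik) where
c_ik = log(sum_{l != k} exp(eta_il)).  Augmenting with
omega_i ~ PG(1, eta_ik - c_ik) makes every block update a conjugate
Gaussian (flat or GMRF prior) and every variance update conjugate
inverse-gamma — no proposal tuning.  Identifiability: after each sweep the
region effects and the spline are mean-centred, with the means absorbed
into the intercept; the spline's linear null-space component is left in
f_k.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sla

from .design import DesignMatrices, rw2_penalty
from .pg import polya_gamma
from .synthetic import RegionGraph


# ---------------------------------------------------------------------------
# Configuration and state containers


@dataclass(frozen=True)
class PriorConfig:
    """Hyperparameters of the stated priors (all defaults are the analysis's)."""

    spline_degree: int = 3
    n_knot_intervals: int = 20
    ig_a: float = 0.001
    ig_b: float = 0.001

    def __post_init__(self):
        if self.ig_a <= 0 or self.ig_b <= 0:
            raise ValueError("inverse-gamma hyperparameters must be positive")


@dataclass(frozen=True)
class McmcSettings:
    iterations: int = 120_000
    burn_in: int = 20_000
    thinning: int = 100

    def __post_init__(self):
        if not 0 <= self.burn_in < self.iterations:
            raise ValueError("burn-in must be shorter than the run")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")
        if (self.iterations - self.burn_in) % self.thinning:
            raise ValueError("(iterations - burn_in) must be divisible by thinning")

    @property
    def n_retained(self) -> int:
        return (self.iterations - self.burn_in) // self.thinning


@dataclass
class ParameterState:
    """Current values of all sampled blocks, for both categories k = 1, 2."""

    beta: np.ndarray  # (2, 8)
    gamma: np.ndarray  # (2, M)
    b: np.ndarray  # (2, n_psu)
    s: np.ndarray  # (2, J)
    tau2_age: np.ndarray  # (2,)
    tau2_psu: np.ndarray  # (2,)
    tau2_region: np.ndarray  # (2,)

    @classmethod
    def initial(
        cls, m: int, n_psu: int, n_regions: int, p: int = 8
    ) -> "ParameterState":
        return cls(
            beta=np.zeros((2, p)),
            gamma=np.zeros((2, m)),
            b=np.zeros((2, n_psu)),
            s=np.zeros((2, n_regions)),
            tau2_age=np.ones(2),
            tau2_psu=np.ones(2),
            tau2_region=np.ones(2),
        )


@dataclass
class DicResult:
    dbar: float
    dhat: float
    p_d: float
    dic: float


@dataclass
class FitResult:
    """Retained chains, posterior summaries and DIC for one model fit."""

    model: str  # "full" or "null"
    chains: dict  # name -> array with leading (n_chains, n_draws, ...)
    settings: McmcSettings
    seed: int
    psu_ids: np.ndarray
    region_ids: np.ndarray
    deviance_at_mean: float
    spline_knots: np.ndarray

    @property
    def n_chains(self) -> int:
        return self.chains["beta"].shape[0]

    @property
    def n_draws(self) -> int:
        return self.chains["beta"].shape[1]

    def pooled(self, name: str) -> np.ndarray:
        arr = self.chains[name]
        return arr.reshape(-1, *arr.shape[2:])

    def dic(self) -> DicResult:
        return compute_dic(self.pooled("deviance"), self.deviance_at_mean)


# ---------------------------------------------------------------------------
# Likelihood pieces


def multinomial_probs(eta1, eta2):
    """(pi1, pi2, pi3) from the two non-reference predictors, overflow-safe."""
    e1 = np.asarray(eta1, dtype=float)
    e2 = np.asarray(eta2, dtype=float)
    m = np.maximum(np.maximum(e1, e2), 0.0)
    x1 = np.exp(e1 - m)
    x2 = np.exp(e2 - m)
    x3 = np.exp(-m)
    denom = x1 + x2 + x3
    return x1 / denom, x2 / denom, x3 / denom


def _loglik_eta(eta1: np.ndarray, eta2: np.ndarray, y: np.ndarray) -> float:
    """Multinomial log likelihood given predictors and one-hot outcomes."""
    lse = np.logaddexp(np.logaddexp(0.0, eta1), eta2)
    return float(np.sum(y[:, 0] * eta1 + y[:, 1] * eta2 - lse))


def _linear_predictors(state: ParameterState, design: DesignMatrices) -> np.ndarray:
    eta = (
        state.beta @ design.X.T
        + state.gamma @ design.B.T
        + state.b[:, design.psu_index]
        + state.s[:, design.region_index]
    )
    return eta


def log_likelihood(state: ParameterState, design: DesignMatrices) -> float:
    eta = _linear_predictors(state, design)
    return _loglik_eta(eta[0], eta[1], design.Y)


def deviance(state: ParameterState, design: DesignMatrices) -> float:
    return -2.0 * log_likelihood(state, design)


def compute_dic(deviance_draws, deviance_at_posterior_mean: float) -> DicResult:
    """DIC = Dbar + pD with pD = Dbar - D(posterior mean of parameters)."""
    d = np.asarray(deviance_draws, dtype=float)
    if d.size == 0:
        raise ValueError("need at least one deviance draw")
    dbar = float(d.mean())
    dhat = float(deviance_at_posterior_mean)
    p_d = dbar - dhat
    return DicResult(dbar=dbar, dhat=dhat, p_d=p_d, dic=dbar + p_d)


# ---------------------------------------------------------------------------
# Gibbs sampler


def _sample_gaussian_block(
    prec: np.ndarray, lin: np.ndarray, rng
) -> np.ndarray:
    """Draw from N(prec^-1 lin, prec^-1) via Cholesky; raises if not PD."""
    try:
        chol = sla.cho_factor(prec, lower=True)
    except sla.LinAlgError as err:
        raise RuntimeError(
            f"non-positive-definite conditional precision: {err}"
        ) from err
    mean = sla.cho_solve(chol, lin)
    z = rng.standard_normal(lin.size)
    return mean + sla.solve_triangular(chol[0], z, lower=True, trans="T")


def _region_structure(design: DesignMatrices, graph: RegionGraph) -> np.ndarray:
    """Graph Laplacian ordered to match design.region_ids."""
    order = [list(graph.region_ids).index(r) for r in design.region_ids]
    missing = [r for r in design.region_ids if r not in graph.region_ids]
    if missing:
        raise ValueError(f"regions absent from adjacency graph: {missing}")
    q_full = graph.structure_matrix()
    return q_full[np.ix_(order, order)]


def mcmc_fit(
    design: DesignMatrices,
    graph: RegionGraph | None = None,
    priors: PriorConfig = PriorConfig(),
    settings: McmcSettings = McmcSettings(),
    spatial: bool = True,
    seed: int = 0,
    n_chains: int = 1,
    include_spline: bool = True,
    include_psu: bool = True,
) -> FitResult:
    """Simulate the joint posterior of the full (spatial) or null model.

    Returns retained chains for every block plus the per-draw deviance.
    Multi-chain runs offset the seed per chain.  The sum-to-zero constraint
    on the region effects is enforced every sweep (mean moved to the
    intercept), so every retained draw satisfies it.  ``include_spline`` /
    ``include_psu`` drop those terms entirely (used for reduced designs
    such as intercept-only validation fits).
    """
    if spatial:
        if graph is None:
            raise ValueError("the spatial model requires a region graph")
        comps = graph.connected_components()
        if len(comps) > 1:
            raise ValueError(
                f"region graph is disconnected ({len(comps)} components)"
            )
        q = _region_structure(design, graph)
    else:
        q = None

    m = design.B.shape[1]
    k_pen = rw2_penalty(m) if include_spline else np.zeros((m, m))
    n_ret = settings.n_retained

    chain_store: dict[str, list] = {
        k: [] for k in ("beta", "gamma", "b", "s",
                        "tau2_age", "tau2_psu", "tau2_region", "deviance")
    }
    mean_state_accum = None

    for chain_id in range(n_chains):
        chain_seed = seed + 1_000_003 * chain_id
        draws, state_sum = _run_single_chain(
            design, q, priors, settings, spatial, chain_seed, k_pen,
            include_spline, include_psu,
        )
        for k, v in draws.items():
            chain_store[k].append(v)
        if mean_state_accum is None:
            mean_state_accum = state_sum
        else:
            for k in mean_state_accum:
                mean_state_accum[k] += state_sum[k]

    chains = {k: np.stack(v) for k, v in chain_store.items()}

    # plug-in deviance at the posterior mean of everything entering eta
    total = n_chains * n_ret
    mean_state = ParameterState(
        beta=mean_state_accum["beta"] / total,
        gamma=mean_state_accum["gamma"] / total,
        b=mean_state_accum["b"] / total,
        s=mean_state_accum["s"] / total,
        tau2_age=np.ones(2), tau2_psu=np.ones(2), tau2_region=np.ones(2),
    )
    dev_at_mean = deviance(mean_state, design)
    if not np.isfinite(dev_at_mean):
        raise RuntimeError("divergent deviance at the posterior mean")

    return FitResult(
        model="full" if spatial else "null",
        chains=chains,
        settings=settings,
        seed=seed,
        psu_ids=design.psu_ids,
        region_ids=design.region_ids,
        deviance_at_mean=dev_at_mean,
        spline_knots=design.knots,
    )


def _run_single_chain(design, q, priors, settings, spatial, seed, k_pen,
                      include_spline=True, include_psu=True):
    rng = np.random.default_rng(seed)
    x, basis, y = design.X, design.B, design.Y
    n, p = x.shape
    m = basis.shape[1]
    n_psu, n_reg = design.n_psu, design.n_regions
    psu_idx, reg_idx = design.psu_index, design.region_index
    y12 = y[:, :2].astype(float)

    state = ParameterState.initial(m, n_psu, n_reg, p=p)
    eta = np.zeros((2, n))
    # cached per-k component values
    xb = np.zeros((2, n))
    f = np.zeros((2, n))
    bv = np.zeros((2, n))
    sv = np.zeros((2, n))

    n_ret = settings.n_retained
    out = {
        "beta": np.empty((n_ret, 2, p)),
        "gamma": np.empty((n_ret, 2, m)),
        "b": np.empty((n_ret, 2, n_psu)),
        "s": np.empty((n_ret, 2, n_reg)),
        "tau2_age": np.empty((n_ret, 2)),
        "tau2_psu": np.empty((n_ret, 2)),
        "tau2_region": np.empty((n_ret, 2)),
        "deviance": np.empty(n_ret),
    }
    state_sum = {
        "beta": np.zeros((2, p)), "gamma": np.zeros((2, m)),
        "b": np.zeros((2, n_psu)), "s": np.zeros((2, n_reg)),
    }
    ig_a, ig_b = priors.ig_a, priors.ig_b
    keep = 0

    for it in range(settings.iterations):
        for k in (0, 1):
            other = 1 - k
            c = np.logaddexp(0.0, eta[other])
            psi = eta[k] - c
            omega = polya_gamma(psi, int(rng.integers(1, 2**31 - 1)))
            z = (y12[:, k] - 0.5) / omega + c

            # beta: flat prior -> precision X' Omega X
            resid = z - (f[k] + bv[k] + sv[k])
            xw = x * omega[:, None]
            state.beta[k] = _sample_gaussian_block(
                x.T @ xw, xw.T @ resid, rng
            )
            xb[k] = x @ state.beta[k]

            # spline coefficients: RW2 prior, then centre (constant -> intercept)
            if include_spline:
                resid = z - (xb[k] + bv[k] + sv[k])
                bw = basis * omega[:, None]
                prec = basis.T @ bw + k_pen / state.tau2_age[k]
                state.gamma[k] = _sample_gaussian_block(prec, bw.T @ resid, rng)
                fk = basis @ state.gamma[k]
                shift = fk.mean()
                state.gamma[k] -= shift  # rows of basis sum to 1
                state.beta[k][0] += shift
                xb[k] += shift
                f[k] = fk - shift

            # PSU effects: iid prior, diagonal update
            if include_psu:
                resid = z - (xb[k] + f[k] + sv[k])
                wsum = np.bincount(psu_idx, weights=omega, minlength=n_psu)
                wres = np.bincount(psu_idx, weights=omega * resid, minlength=n_psu)
                prec_b = wsum + 1.0 / state.tau2_psu[k]
                state.b[k] = wres / prec_b + rng.standard_normal(n_psu) / np.sqrt(prec_b)
                bv[k] = state.b[k][psu_idx]

            # region effects: intrinsic MRF prior, joint dense update
            if spatial:
                resid = z - (xb[k] + f[k] + bv[k])
                wsum_r = np.bincount(reg_idx, weights=omega, minlength=n_reg)
                wres_r = np.bincount(reg_idx, weights=omega * resid, minlength=n_reg)
                prec_s = np.diag(wsum_r) + q / state.tau2_region[k]
                state.s[k] = _sample_gaussian_block(prec_s, wres_r, rng)
                sbar = state.s[k].mean()
                state.s[k] -= sbar
                state.beta[k][0] += sbar
                xb[k] += sbar
                sv[k] = state.s[k][reg_idx]

            # variance hyperparameters (conjugate inverse-gamma)
            if include_spline:
                quad = state.gamma[k] @ k_pen @ state.gamma[k]
                state.tau2_age[k] = 1.0 / rng.gamma(
                    ig_a + (m - 2) / 2.0, 1.0 / (ig_b + quad / 2.0)
                )
            if include_psu:
                state.tau2_psu[k] = 1.0 / rng.gamma(
                    ig_a + n_psu / 2.0,
                    1.0 / (ig_b + state.b[k] @ state.b[k] / 2.0),
                )
            if spatial:
                quad_s = state.s[k] @ q @ state.s[k]
                state.tau2_region[k] = 1.0 / rng.gamma(
                    ig_a + (n_reg - 1) / 2.0, 1.0 / (ig_b + quad_s / 2.0)
                )

            eta[k] = xb[k] + f[k] + bv[k] + sv[k]

        if it >= settings.burn_in and (it - settings.burn_in) % settings.thinning == 0:
            dev = -2.0 * _loglik_eta(eta[0], eta[1], y)
            if not np.isfinite(dev):
                raise RuntimeError(f"divergent deviance at iteration {it}")
            out["beta"][keep] = state.beta
            out["gamma"][keep] = state.gamma
            out["b"][keep] = state.b
            out["s"][keep] = state.s
            out["tau2_age"][keep] = state.tau2_age
            out["tau2_psu"][keep] = state.tau2_psu
            out["tau2_region"][keep] = state.tau2_region
            out["deviance"][keep] = dev
            for key in state_sum:
                state_sum[key] += getattr(state, key)
            keep += 1

    assert keep == n_ret
    return out, state_sum


# ---------------------------------------------------------------------------
# Posterior summaries


def summarize_posterior(fit: FitResult) -> pd.DataFrame:
    """Median and 95% interval per scalar parameter; odds ratios for beta.

    Quantiles use linear (type-7) interpolation.  The exp transform is
    applied to the beta interval endpoints, which is exact for quantiles
    by monotonicity.
    """
    rows = []
    covariate_names = [
        "intercept", "urban", "educ_primary", "educ_secondary+",
        "income_poorer", "income_middle", "income_richer", "income_richest",
    ]

    def add(name, draws, odds=False):
        med = float(np.median(draws))
        lo, hi = np.quantile(draws, [0.025, 0.975])
        row = {"parameter": name, "median": med, "q2.5": float(lo), "q97.5": float(hi)}
        if odds:
            row["odds_ratio"] = float(np.exp(med))
            row["odds_q2.5"] = float(np.exp(lo))
            row["odds_q97.5"] = float(np.exp(hi))
        rows.append(row)

    for k in range(2):
        beta = fit.pooled("beta")[:, k, :]
        for c, nm in enumerate(covariate_names):
            add(f"beta{k + 1}[{nm}]", beta[:, c], odds=True)
    for k in range(2):
        for name in ("tau2_age", "tau2_psu", "tau2_region"):
            draws = fit.pooled(name)[:, k]
            if fit.model == "null" and name == "tau2_region":
                continue
            add(f"{name}[k={k + 1}]", draws)
    return pd.DataFrame(rows)


def region_effect_medians(fit: FitResult) -> pd.DataFrame:
    """Posterior medians of the structured region effects s_jk (for mapping)."""
    s = fit.pooled("s")
    med = np.median(s, axis=0)  # (2, J)
    return pd.DataFrame(
        {"region": fit.region_ids, "s_k1": med[0], "s_k2": med[1]}
    )


def psu_effect_medians(fit: FitResult) -> pd.DataFrame:
    """Posterior medians of the PSU effects b_{u,k}."""
    b = fit.pooled("b")
    med = np.median(b, axis=0)
    return pd.DataFrame({"psu": fit.psu_ids, "b_k1": med[0], "b_k2": med[1]})
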