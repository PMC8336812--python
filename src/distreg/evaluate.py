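"""Model comparison and diagnostics.

DIC and WAIC from stored pointwise log-likelihoods, randomised quantile
residuals, simultaneous credible bands for posterior curves, effective
sample sizes, and extraction of smooth-term curves, linear-effect tables
and district-level spatial effects from a chain.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import norm

from distreg.bases import build_bspline_basis
from distreg.mcmc import ChainResult
from distreg.model import AssembledModel

__all__ = [
    "compute_dic",
    "compute_waic",
    "randomized_quantile_residuals",
    "simultaneous_credible_band",
    "effective_sample_size",
    "convergence_summary",
    "term_curve_samples",
    "linear_effects_table",
    "extract_spatial_effect",
]


def compute_dic(chain: ChainResult) -> tuple[float, float]:
    """Deviance information criterion and effective parameter count.

    DIC = 2 * mean(D) - D(plug-in), pD = mean(D) - D(plug-in), where the
    plug-in deviance is evaluated at the posterior means of the fitted
    mu_i and sigma_i (well defined under the exp link, unlike a
    coefficient-level plug-in).
    """
    if chain.n_saved == 0:
        raise ValueError("empty chain")
    if chain.y is None:
        raise ValueError("chain does not carry the response vector")
    mean_dev = float(np.mean(-2.0 * chain.pointwise_loglik.sum(axis=1)))
    ll_plugin = norm.logpdf(chain.y, loc=chain.mean_mu, scale=chain.mean_sigma)
    dev_plugin = float(-2.0 * ll_plugin.sum())
    p_d = mean_dev - dev_plugin
    return 2.0 * mean_dev - dev_plugin, p_d


def compute_waic(chain: ChainResult) -> tuple[float, float]:
    """Widely applicable information criterion with the variance penalty.

    WAIC = -2 * sum_i [ log mean_t p(y_i|theta_t) - var_t log p(y_i|theta_t) ].
    """
    ll = chain.pointwise_loglik
    if ll.shape[0] < 2:
        raise ValueError("WAIC needs at least 2 saved iterations")
    # log mean exp, stabilised
    m = ll.max(axis=0)
    lppd = m + np.log(np.mean(np.exp(ll - m), axis=0))
    penalty = np.var(ll, axis=0, ddof=1)
    waic = -2.0 * float(np.sum(lppd - penalty))
    return waic, 2.0 * float(np.sum(penalty))


def randomized_quantile_residuals(
    mu: np.ndarray, sigma: np.ndarray, y: np.ndarray, clip: float = 8.0
) -> np.ndarray:
    """Quantile residuals of a Gaussian fit.

    For a continuous response these are Phi^-1(F(y; mu, sigma)) — no
    randomisation step is needed — which reduces to the standardised
    residual (y - mu)/sigma; values are clipped at +-``clip`` with a
    warning to guard against overflow in downstream normality tests.
    """
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive")
    r = (np.asarray(y, dtype=float) - mu) / sigma
    if np.any(np.abs(r) > clip):
        import logging

        logging.getLogger(__name__).warning(
            "%d residual(s) beyond +-%g clipped", int(np.sum(np.abs(r) > clip)), clip
        )
        r = np.clip(r, -clip, clip)
    return r


def simultaneous_credible_band(
    samples: np.ndarray, levels: tuple = (0.80, 0.95)
) -> dict:
    """Simultaneous credible bands for a sampled curve.

    ``samples`` is (draws x grid).  The band is mean +- q * pointwise sd,
    where q is the empirical level-quantile of the max over the grid of
    the standardised absolute deviations, so at least that fraction of
    sampled curves lies entirely inside.  Grid points with zero posterior
    variance contribute nothing to the max and get zero-width bands.
    Returns mean, sd, and per level both simultaneous and pointwise
    lower/upper curves.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.shape[0] < 100:
        raise ValueError("need >= 100 draws for band calibration")
    mean = samples.mean(axis=0)
    sd = samples.std(axis=0, ddof=1)
    out = {"mean": mean, "sd": sd}
    nonzero = sd > 0
    if nonzero.any():
        dev = np.abs(samples[:, nonzero] - mean[nonzero]) / sd[nonzero]
        maxdev = dev.max(axis=1)
    else:
        maxdev = np.zeros(samples.shape[0])
    for lv in levels:
        q = float(np.quantile(maxdev, lv))
        out[f"sim_lower_{int(lv * 100)}"] = mean - q * sd
        out[f"sim_upper_{int(lv * 100)}"] = mean + q * sd
        zp = norm.ppf(0.5 + lv / 2.0)
        out[f"pw_lower_{int(lv * 100)}"] = mean - zp * sd
        out[f"pw_upper_{int(lv * 100)}"] = mean + zp * sd
    return out


def effective_sample_size(x: np.ndarray) -> float:
    """ESS via Geyer's initial monotone positive sequence estimator."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 4 or np.var(x) == 0:
        return 1.0
    xc = x - x.mean()
    acov = np.correlate(xc, xc, mode="full")[n - 1:] / n
    if acov[0] <= 0:
        return 1.0
    rho = acov / acov[0]
    # pair sums Gamma_k = rho_{2k} + rho_{2k+1}; truncate at first
    # negative pair, then enforce monotone decrease
    max_pairs = (n - 1) // 2
    gammas = []
    for k in range(max_pairs):
        g = rho[2 * k] + rho[2 * k + 1]
        if g <= 0:
            break
        gammas.append(g)
    if not gammas:
        return 1.0
    gammas = np.minimum.accumulate(gammas)
    tau = -1.0 + 2.0 * float(np.sum(gammas))
    tau = max(tau, 1.0 / n)
    return float(max(1.0, min(n, n / tau)))


def convergence_summary(chain: ChainResult) -> pd.DataFrame:
    """Per-coefficient effective sample size and posterior moments."""
    if chain.n_saved == 0:
        raise ValueError("empty chain")
    rows = []
    for (side, name), arr in sorted(chain.coefficients.items()):
        for j in range(arr.shape[1]):
            tr = arr[:, j]
            rows.append({
                "side": side, "block": name, "coef": j,
                "mean": tr.mean(), "sd": tr.std(ddof=1) if tr.size > 1 else 0.0,
                "ess": effective_sample_size(tr),
            })
    for (side, name), arr in sorted(chain.variances.items()):
        rows.append({
            "side": side, "block": f"var({name})", "coef": 0,
            "mean": arr.mean(), "sd": arr.std(ddof=1) if arr.size > 1 else 0.0,
            "ess": effective_sample_size(arr),
        })
    return pd.DataFrame(rows)


def _find_block(model: AssembledModel, side: str, name: str):
    blocks = model.mu_blocks if side == "mu" else model.sigma_blocks
    for blk in blocks:
        if blk.name == name:
            return blk
    raise KeyError(f"no block {name!r} on side {side!r}")


def term_curve_samples(
    chain: ChainResult, model: AssembledModel, side: str, name: str,
    grid: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior draws of a 1-D smooth term evaluated on a grid.

    Returns (grid, samples) with samples shaped (draws x grid).  The
    constrained coefficients are mapped back to the original basis and the
    sample-based centring is reapplied on the grid evaluation.
    """
    blk = _find_block(model, side, name)
    if blk.meta.get("kind") != "spline1d":
        raise ValueError(f"block {name!r} is not a 1-D smooth")
    bd = blk.meta["basis"]
    if grid is None:
        grid = blk.meta["grid"]
    Bg = build_bspline_basis(grid, bd)
    draws = chain.coefficients[(side, name)]
    # constrained design already centred over the sample; grid evaluation
    # uses B(grid) @ Z @ alpha
    samples = draws @ (Bg @ blk.transform).T
    return grid, samples


def linear_effects_table(chain: ChainResult, model: AssembledModel) -> pd.DataFrame:
    """Posterior mean and equal-tailed 95% credible interval for every
    fixed-effect coefficient of both predictors."""
    rows = []
    for side, bname in (("mu", "linear_mu"), ("sigma", "linear_sigma")):
        try:
            blk = _find_block(model, side, bname)
        except KeyError:
            continue
        draws = chain.coefficients[(side, bname)]
        for j, cn in enumerate(blk.meta["colnames"]):
            tr = draws[:, j]
            rows.append({
                "predictor": side, "covariate": cn,
                "posterior_mean": float(tr.mean()),
                "ci_lower": float(np.quantile(tr, 0.025)),
                "ci_upper": float(np.quantile(tr, 0.975)),
            })
    return pd.DataFrame(rows)


def extract_spatial_effect(
    chain: ChainResult, model: AssembledModel, wave=None
) -> pd.DataFrame:
    """Per-district posterior mean and sd of the spatial MRF effect.

    Keyed by district x wave; districts absent from the data still get a
    (prior-smoothed) estimate because the MRF borrows from neighbours.
    """
    blk = None
    for b in model.mu_blocks:
        if b.meta.get("kind") == "mrf":
            blk = b
            break
    if blk is None:
        raise ValueError("model has no spatial term")
    waves = blk.meta["waves"]
    if wave is not None and wave not in waves:
        raise ValueError(f"wave {wave!r} not in model waves {waves}")
    districts = blk.meta["districts"]
    S = len(districts)
    draws = chain.coefficients[("mu", blk.name)] @ blk.transform.T  # back to beta
    rows = []
    for w, wv in enumerate(waves):
        if wave is not None and wv != wave:
            continue
        sub = draws[:, w * S:(w + 1) * S]
        for s, d in enumerate(districts):
            rows.append({
                "district": d, "wave": wv,
                "posterior_mean": float(sub[:, s].mean()),
                "posterior_sd": float(sub[:, s].std(ddof=1)),
            })
    return pd.DataFrame(rows)
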