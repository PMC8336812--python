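"""Posterior simulation for the assembled location-scale model.

The sampler is a systematic-scan hybrid:

* mean-side blocks (fixed effects and smooths) have Gaussian full
  conditionals given sigma, so they are updated by exact conjugate Gibbs
  draws with precision ``B' Sigma^-1 B + K / gamma^2``;
* scale-side blocks enter the likelihood through ``sigma = exp(eta)`` and
  are updated by Metropolis-Hastings, by default with an IWLS proposal
  (Gaussian approximation to the full conditional built from the expected
  information, which is constant and equal to 2 per observation for the
  Gaussian log-scale model), with an adaptive random-walk fallback;
* every smoothing variance ``gamma_j^2`` (and the MRF variance
  ``tau^2``) has a conjugate inverse-gamma full conditional
  IG(a + rank(K)/2, b + beta'K beta / 2).

Adaptation of random-walk scales happens during burn-in only, so the
post-burn-in chain is a valid time-homogeneous Markov chain.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular

from distreg.bases import PenaltyMatrix
from distreg.model import AssembledModel, SmoothBlock

logger = logging.getLogger(__name__)

__all__ = [
    "SamplerConfig",
    "ChainResult",
    "gibbs_update_mu_block",
    "mh_update_sigma_block",
    "update_variance_parameter",
    "run_mcmc",
    "save_chain",
    "load_chain",
]

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class SamplerConfig:
    """MCMC run settings.

    ``hyper_a``/``hyper_b`` are the inverse-gamma shape/scale shared by all
    smoothing variances (the conventional diffuse IG(0.001, 0.001)).
    ``proposal_mode`` selects the scale-side proposal: ``"iwls"`` (default)
    or ``"random-walk"`` (adaptive scale, tuned during burn-in only).
    """

    seed: int
    iterations: int = 12000
    burn_in: int = 2000
    thinning: int = 10
    hyper_a: float = 0.001
    hyper_b: float = 0.001
    proposal_mode: str = "iwls"

    def __post_init__(self) -> None:
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be < iterations")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")
        if self.proposal_mode not in {"iwls", "random-walk"}:
            raise ValueError(f"unknown proposal mode {self.proposal_mode!r}")

    @property
    def n_saved(self) -> int:
        return (self.iterations - self.burn_in + self.thinning - 1) // self.thinning


@dataclass
class ChainResult:
    """Stored MCMC output.

    ``coefficients`` maps ``(side, block name)`` to a (draws x p) array;
    ``variances`` maps the same keys (penalised blocks only) to a draws
    vector; ``pointwise_loglik`` is (draws x n) and feeds DIC/WAIC;
    ``mean_mu``/``mean_sigma`` are posterior means of the fitted values
    (the DIC plug-in).
    """

    config: SamplerConfig
    coefficients: dict
    variances: dict
    pointwise_loglik: np.ndarray
    mean_mu: np.ndarray
    mean_sigma: np.ndarray
    y: np.ndarray | None = None
    acceptance: dict = field(default_factory=dict)

    @property
    def n_saved(self) -> int:
        return self.pointwise_loglik.shape[0]


def _draw_gaussian_canonical(P: np.ndarray, b: np.ndarray, rng) -> np.ndarray:
    """Draw from N(P^-1 b, P^-1) via Cholesky of the precision."""
    try:
        L = cholesky(P, lower=True)
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise np.linalg.LinAlgError(f"singular precision matrix: {exc}") from exc
    m = cho_solve((L, True), b)
    z = rng.standard_normal(P.shape[0])
    return m + solve_triangular(L, z, lower=True, trans="T")


def gibbs_update_mu_block(
    block: SmoothBlock,
    partial_residuals: np.ndarray,
    sigma: np.ndarray,
    gamma2: float | None,
    rng: np.random.Generator,
) -> np.ndarray:
    """Exact Gaussian full-conditional draw for a mean-side block.

    Full conditional: N(m, P^-1) with ``P = B' Sigma^-1 B + K/gamma^2``
    and ``P m = B' Sigma^-1 r`` where ``r`` are the partial residuals
    (response minus all other mean contributions).  A fixed-effect block
    (no penalty) uses the diffuse-prior limit ``K = 0``.
    """
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive")
    B = block.design
    w = 1.0 / sigma**2
    Bw = B * w[:, None]
    P = B.T @ Bw
    if block.penalized and gamma2 is not None:
        P = P + block.penalty.matrix / gamma2
    b = Bw.T @ partial_residuals
    try:
        return _draw_gaussian_canonical(P, b, rng)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"singular full-conditional precision in block {block.name!r}"
        ) from exc


def _sigma_log_target(
    eta: np.ndarray, sq_resid: np.ndarray, coef: np.ndarray,
    K: np.ndarray | None, tau2: float | None,
) -> float:
    ll = float(np.sum(-eta - 0.5 * sq_resid * np.exp(-2.0 * eta)))
    if K is not None and tau2 is not None:
        ll -= 0.5 * float(coef @ K @ coef) / tau2
    return ll


def mh_update_sigma_block(
    block: SmoothBlock,
    residuals: np.ndarray,
    coef: np.ndarray,
    tau2: float | None,
    offset: np.ndarray,
    rng: np.random.Generator,
    proposal_mode: str = "iwls",
    rw_scale: float = 0.1,
    burnin_assist: bool = False,
) -> tuple[np.ndarray, bool]:
    """Metropolis-Hastings update of a scale-side coefficient block.

    The full conditional is proportional to the Gaussian likelihood with
    ``sigma_i = exp(offset_i + (B alpha)_i)`` times the smoothness prior.
    The IWLS proposal builds a Gaussian approximation around the current
    state using the expected information (2 per observation), so the
    proposal precision ``2 B'B + K/tau^2`` is state-independent and only
    its mean moves; the acceptance ratio therefore includes the forward
    and reverse proposal densities.  ``random-walk`` proposes
    ``alpha + rw_scale * N(0, P^-1)`` (symmetric).

    ``burnin_assist`` (IWLS mode only, meant for burn-in iterations that
    are discarded anyway) moves a *rejected* state halfway towards the
    IWLS conditional mode.  Far from the mode the reverse-proposal
    density makes the acceptance probability of an otherwise excellent
    jump vanishingly small, which can leave a short chain stuck at its
    initial value; the damped deterministic step removes that transient
    without touching the post-burn-in transition kernel.
    """
    if not np.all(np.isfinite(residuals)):
        raise ValueError("residuals must be finite")
    B = block.design
    sq = residuals**2
    K = block.penalty.matrix if block.penalized else None
    eta_cur = offset + B @ coef
    lt_cur = _sigma_log_target(eta_cur, sq, coef, K, tau2)

    P = 2.0 * (B.T @ B)
    if K is not None and tau2 is not None:
        P = P + K / tau2
    L = cholesky(P, lower=True)

    if proposal_mode == "random-walk":
        z = rng.standard_normal(coef.size)
        step = solve_triangular(L, z, lower=True, trans="T")
        prop = coef + rw_scale * step
        eta_prop = offset + B @ prop
        if not np.all(np.isfinite(eta_prop)):
            logger.warning("non-finite proposal in block %s rejected", block.name)
            return coef, False
        lt_prop = _sigma_log_target(eta_prop, sq, prop, K, tau2)
        log_alpha = lt_prop - lt_cur
    else:
        # IWLS mean at a given state: m = P^-1 B' W (z - offset),
        # W = 2, z = eta + (sq * exp(-2 eta) - 1) / 2
        def iwls_mean(eta):
            zw = eta + 0.5 * (sq * np.exp(-2.0 * eta) - 1.0)
            return cho_solve((L, True), 2.0 * (B.T @ (zw - offset)))

        m_cur = iwls_mean(eta_cur)
        z = rng.standard_normal(coef.size)
        prop = m_cur + solve_triangular(L, z, lower=True, trans="T")
        eta_prop = offset + B @ prop
        if not np.all(np.isfinite(eta_prop)):
            logger.warning("non-finite proposal in block %s rejected", block.name)
            return coef, False
        lt_prop = _sigma_log_target(eta_prop, sq, prop, K, tau2)
        m_prop = iwls_mean(eta_prop)

        def logq(x, m):
            d = x - m
            return -0.5 * float(d @ P @ d)

        log_alpha = lt_prop - lt_cur + logq(coef, m_prop) - logq(prop, m_cur)

    if not np.isfinite(log_alpha):
        logger.warning("non-finite log target in block %s; proposal rejected", block.name)
        return coef, False
    if np.log(rng.uniform()) < log_alpha:
        return prop, True
    if burnin_assist and proposal_mode != "random-walk":
        assisted = coef + 0.5 * (m_cur - coef)
        if np.all(np.isfinite(offset + B @ assisted)):
            return assisted, False
    return coef, False


def update_variance_parameter(
    coef: np.ndarray,
    penalty: PenaltyMatrix,
    hyper_a: float,
    hyper_b: float,
    rng: np.random.Generator,
) -> float:
    """Conjugate inverse-gamma draw for a smoothing variance.

    Posterior: IG(a + rank(K)/2, b + beta'K beta/2).
    """
    quad = float(coef @ penalty.matrix @ coef)
    if quad < -1e-8 * max(1.0, float(np.abs(coef).max()) ** 2):
        raise ValueError("negative penalty quadratic form: corrupted penalty")
    quad = max(quad, 0.0)
    a_post = hyper_a + 0.5 * penalty.rank
    b_post = hyper_b + 0.5 * quad
    return float(b_post / rng.gamma(shape=a_post, scale=1.0))


def _gaussian_loglik(y, mu, sigma):
    return -0.5 * _LOG2PI - np.log(sigma) - 0.5 * ((y - mu) / sigma) ** 2


def run_mcmc(model: AssembledModel, config: SamplerConfig) -> ChainResult:
    """Systematic-scan MCMC over all blocks of both predictors.

    Sweep order per iteration: mean fixed effects, mean smooths in
    predictor order, their variances; scale fixed effects, scale smooths,
    their variances.  Pointwise log-likelihoods and running means of the
    fitted mu/sigma are stored at every saved iteration.
    """
    rng = np.random.default_rng(config.seed)
    y = model.y
    n = y.size

    # state
    coef = {}
    var = {}
    mu_contrib = {}
    sig_contrib = {}
    for blk in model.mu_blocks:
        c = np.zeros(blk.n_coef)
        if blk.name == "linear_mu":
            c[0] = float(np.mean(y))
        coef[("mu", blk.name)] = c
        mu_contrib[blk.name] = blk.design @ c
        if blk.penalized:
            var[("mu", blk.name)] = 10.0
    for blk in model.sigma_blocks:
        c = np.zeros(blk.n_coef)
        if blk.name == "linear_sigma":
            c[0] = float(np.log(np.std(y) + 1e-12))
        coef[("sigma", blk.name)] = c
        sig_contrib[blk.name] = blk.design @ c
        if blk.penalized:
            var[("sigma", blk.name)] = 10.0

    eta_mu = np.sum(list(mu_contrib.values()), axis=0)
    eta_sig = np.sum(list(sig_contrib.values()), axis=0)

    n_saved = config.n_saved
    saved_coef = {k: np.empty((n_saved, v.size)) for k, v in coef.items()}
    saved_var = {k: np.empty(n_saved) for k in var}
    loglik = np.empty((n_saved, n))
    sum_mu = np.zeros(n)
    sum_sigma = np.zeros(n)
    accept_cnt = {blk.name: 0 for blk in model.sigma_blocks}
    accept_tot = {blk.name: 0 for blk in model.sigma_blocks}
    rw_scales = {blk.name: 0.1 for blk in model.sigma_blocks}

    save_idx = 0
    for it in range(config.iterations):
        sigma = np.exp(eta_sig)

        # ---- mean side: conjugate Gibbs ----
        for blk in model.mu_blocks:
            key = ("mu", blk.name)
            partial = y - (eta_mu - mu_contrib[blk.name])
            g2 = var.get(key)
            c = gibbs_update_mu_block(blk, partial, sigma, g2, rng)
            eta_mu += blk.design @ c - mu_contrib[blk.name]
            mu_contrib[blk.name] = blk.design @ c
            coef[key] = c
            if blk.penalized:
                var[key] = update_variance_parameter(
                    c, blk.penalty, config.hyper_a, config.hyper_b, rng
                )

        # ---- scale side: MH ----
        residuals = y - eta_mu
        for blk in model.sigma_blocks:
            key = ("sigma", blk.name)
            offset = eta_sig - sig_contrib[blk.name]
            t2 = var.get(key)
            c, acc = mh_update_sigma_block(
                blk, residuals, coef[key], t2, offset, rng,
                proposal_mode=config.proposal_mode,
                rw_scale=rw_scales[blk.name],
                burnin_assist=it < config.burn_in,
            )
            eta_sig = offset + blk.design @ c
            sig_contrib[blk.name] = blk.design @ c
            coef[key] = c
            if it >= config.burn_in:
                accept_tot[blk.name] += 1
                accept_cnt[blk.name] += int(acc)
            elif config.proposal_mode == "random-walk":
                # Robbins-Monro-style scale adaptation, burn-in only
                target = 0.3
                rw_scales[blk.name] *= np.exp(
                    (1.0 if acc else 0.0) - target
                ) ** (10.0 / (it + 20.0))
            if blk.penalized:
                var[key] = update_variance_parameter(
                    c, blk.penalty, config.hyper_a, config.hyper_b, rng
                )

        if not (np.all(np.isfinite(eta_mu)) and np.all(np.isfinite(eta_sig))):
            state = {str(k): v.tolist() for k, v in coef.items()}
            raise RuntimeError(
                f"divergent chain at iteration {it}: non-finite predictor; "
                f"last state: {json.dumps(state)[:2000]}"
            )

        # ---- storage ----
        if it >= config.burn_in and (it - config.burn_in) % config.thinning == 0:
            sigma = np.exp(eta_sig)
            for k, c in coef.items():
                saved_coef[k][save_idx] = c
            for k, v in var.items():
                saved_var[k][save_idx] = v
            loglik[save_idx] = _gaussian_loglik(y, eta_mu, sigma)
            sum_mu += eta_mu
            sum_sigma += sigma
            save_idx += 1

    acceptance = {
        name: (accept_cnt[name] / accept_tot[name]) if accept_tot[name] else np.nan
        for name in accept_cnt
    }
    return ChainResult(
        config=config,
        coefficients=saved_coef,
        variances=saved_var,
        pointwise_loglik=loglik[:save_idx],
        mean_mu=sum_mu / save_idx,
        mean_sigma=sum_sigma / save_idx,
        y=y.copy(),
        acceptance=acceptance,
    )


# ---------------------------------------------------------------------------
# persistence: a directory of delimited trace files plus a JSON manifest

def save_chain(chain: ChainResult, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": {
            "seed": chain.config.seed,
            "iterations": chain.config.iterations,
            "burn_in": chain.config.burn_in,
            "thinning": chain.config.thinning,
            "hyper_a": chain.config.hyper_a,
            "hyper_b": chain.config.hyper_b,
            "proposal_mode": chain.config.proposal_mode,
        },
        "acceptance": {k: (None if np.isnan(v) else v) for k, v in chain.acceptance.items()},
        "blocks": {f"{side}.{name}": arr.shape[1] for (side, name), arr in chain.coefficients.items()},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    for (side, name), arr in chain.coefficients.items():
        np.savetxt(outdir / f"coef_{side}.{name}.tsv", arr, delimiter="\t")
    for (side, name), arr in chain.variances.items():
        np.savetxt(outdir / f"var_{side}.{name}.tsv", arr, delimiter="\t")
    np.savetxt(outdir / "pointwise_loglik.tsv", chain.pointwise_loglik, delimiter="\t")
    np.savetxt(outdir / "mean_mu.tsv", chain.mean_mu, delimiter="\t")
    np.savetxt(outdir / "mean_sigma.tsv", chain.mean_sigma, delimiter="\t")
    if chain.y is not None:
        np.savetxt(outdir / "response.tsv", chain.y, delimiter="\t")


def load_chain(outdir) -> ChainResult:
    outdir = Path(outdir)
    manifest = json.loads((outdir / "manifest.json").read_text())
    cfg = SamplerConfig(**manifest["config"])
    coefs, variances = {}, {}
    for f in outdir.glob("coef_*.tsv"):
        side, name = f.stem[len("coef_"):].split(".", 1)
        arr = np.loadtxt(f, delimiter="\t")
        p = manifest["blocks"][f"{side}.{name}"]
        coefs[(side, name)] = arr.reshape(-1, p)
    for f in outdir.glob("var_*.tsv"):
        side, name = f.stem[len("var_"):].split(".", 1)
        variances[(side, name)] = np.atleast_1d(np.loadtxt(f, delimiter="\t"))
    return ChainResult(
        config=cfg,
        coefficients=coefs,
        variances=variances,
        pointwise_loglik=np.atleast_2d(np.loadtxt(outdir / "pointwise_loglik.tsv", delimiter="\t")),
        mean_mu=np.atleast_1d(np.loadtxt(outdir / "mean_mu.tsv", delimiter="\t")),
        mean_sigma=np.atleast_1d(np.loadtxt(outdir / "mean_sigma.tsv", delimiter="\t")),
        y=(
            np.atleast_1d(np.loadtxt(outdir / "response.tsv", delimiter="\t"))
            if (outdir / "response.tsv").exists() else None
        ),
        acceptance={k: (np.nan if v is None else v) for k, v in manifest["acceptance"].items()},
    )
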