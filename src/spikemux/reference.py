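"""Brute-force grid-integration reference implementations.

These evaluate the same marginal likelihoods and Bayes factors as
:mod:`spikemux.models` and :mod:`spikemux.screen`, but by dense deterministic
quadrature over every latent variable, with none of the closed forms,
Bernstein expansions or stratified sampling the production code uses.  They
are orders of magnitude slower and exist purely as an independent
cross-check on small problems; nothing in the analysis pipeline calls them.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps
from scipy.special import gammaln, logsumexp

from .models import GammaPosterior


def _log_poisson(y: np.ndarray, lam: np.ndarray) -> np.ndarray:
    """Summed log-likelihood of counts ``y`` at each rate in ``lam`` (any shape)."""
    y = np.asarray(y, dtype=float)
    lam = np.asarray(lam, dtype=float)
    if y.size == 0:
        return np.zeros_like(lam)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = y.sum() * np.log(lam) - y.size * lam - gammaln(y + 1).sum()
    return np.where(lam > 0, out, -np.inf if y.sum() > 0 else -y.size * 0.0)


def _simpson_w(n: int, h: float) -> np.ndarray:
    """Composite-Simpson weights for n (odd) equally spaced nodes."""
    if n % 2 == 0:
        raise ValueError("Simpson rule needs an odd node count")
    w = np.ones(n)
    w[1:-1:2] = 4.0
    w[2:-1:2] = 2.0
    return w * h / 3.0


def _gamma_grid(post: GammaPosterior, n: int, eps: float = 1e-13,
                cover: "GammaPosterior | None" = None) -> tuple[np.ndarray, np.ndarray]:
    """Simpson nodes and log-weights covering essentially all posterior mass.

    ``cover`` optionally widens the range to include a second gamma density
    (e.g. the likelihood-updated posterior), so that integrands whose mass
    sits in the prior's tail are not truncated.
    """
    dists = [post] + ([cover] if cover is not None else [])
    lo = min(sps.gamma.ppf(eps, d.shape, scale=1.0 / d.rate) for d in dists)
    hi = max(sps.gamma.ppf(1.0 - eps, d.shape, scale=1.0 / d.rate) for d in dists)
    lam = np.linspace(max(lo, 1e-12), hi, n)
    logpdf = sps.gamma.logpdf(lam, post.shape, scale=1.0 / post.rate)
    return lam, logpdf + np.log(_simpson_w(n, lam[1] - lam[0]))


def ref_log_marglik_single(counts_AB, post: GammaPosterior, n_grid: int = 4001) -> float:
    y = np.asarray(counts_AB, dtype=float)
    if y.size == 0:
        return 0.0
    updated = GammaPosterior(post.shape + y.sum(), post.rate + y.size)
    lam, logw = _gamma_grid(post, n_grid, cover=updated)
    return float(logsumexp(_log_poisson(y, lam) + logw))


def ref_log_marglik_mixture(counts_AB, post_A: GammaPosterior, post_B: GammaPosterior,
                            n_rate: int = 241, n_alpha: int = 801) -> float:
    """Tensor-product trapezoid over (lambda_A, lambda_B, alpha)."""
    y = np.asarray(counts_AB, dtype=float)
    if y.size == 0:
        return 0.0
    lam_a, logw_a = _gamma_grid(post_A, n_rate)
    lam_b, logw_b = _gamma_grid(post_B, n_rate)
    alpha = np.linspace(0.0, 1.0, n_alpha)
    wa = _simpson_w(n_alpha, 1.0 / (n_alpha - 1))
    pa = np.exp(y[:, None] * np.log(lam_a)[None, :] - lam_a[None, :]
                - gammaln(y + 1)[:, None])  # (m, A)
    pb = np.exp(y[:, None] * np.log(lam_b)[None, :] - lam_b[None, :]
                - gammaln(y + 1)[:, None])
    out = np.empty((n_rate, n_rate))
    for i in range(n_rate):  # loop over lambda_A to bound memory
        mix = alpha[None, :, None] * pa[:, i][:, None, None] \
            + (1 - alpha[None, :, None]) * pb[:, None, :]  # (m, alpha, B)
        with np.errstate(divide="ignore"):
            log_like = np.log(mix).sum(axis=0)  # (alpha, B)
        out[i] = logsumexp(log_like + np.log(wa)[:, None], axis=0)
    return float(logsumexp(out + logw_a[:, None] + logw_b[None, :]))


def _ref_region_logml(y, post_A, post_B, region: str, upper_factor: float,
                      n_rate: int, n_inner: int) -> float:
    """Common machinery for the intermediate / outside hypotheses.

    For every (lambda_A, lambda_B) grid pair, the inner integral over
    lambda_AB uses a trapezoid rule on the truncated-Jeffreys density of the
    hypothesis region; the (0, min) segment of the outside region is
    integrated in u = sqrt(lambda) to absorb the lambda^(-1/2) singularity.
    """
    y = np.asarray(y, dtype=float)
    if y.size == 0:
        return 0.0
    lam_a, logw_a = _gamma_grid(post_A, n_rate)
    lam_b, logw_b = _gamma_grid(post_B, n_rate)
    la = np.repeat(lam_a, n_rate)
    lb = np.tile(lam_b, n_rate)
    lo, hi = np.minimum(la, lb), np.maximum(la, lb)
    hi = np.where(hi == lo, lo * (1 + 1e-9) + 1e-12, hi)  # degenerate diagonal pairs

    def seg_log_integral(seg_lo, seg_hi):
        # integral over [seg_lo, seg_hi] of prod Poi(y|lam) lam^(-1/2) d lam,
        # substituting lam = u^2 (d lam = 2 u du -> integrand 2 * prod Poi)
        t = np.linspace(0.0, 1.0, n_inner)
        w = _simpson_w(n_inner, 1.0 / (n_inner - 1))
        out = np.empty(len(seg_lo))
        for s in range(0, len(seg_lo), 20000):
            sl = slice(s, s + 20000)
            u = np.sqrt(seg_lo[sl])[:, None] \
                + (np.sqrt(seg_hi[sl]) - np.sqrt(seg_lo[sl]))[:, None] * t[None, :]
            log_like = _log_poisson(y, u ** 2)  # (pairs, inner)
            span = np.sqrt(seg_hi[sl]) - np.sqrt(seg_lo[sl])
            with np.errstate(divide="ignore"):
                out[sl] = logsumexp(log_like + np.log(2.0) + np.log(w)[None, :],
                                    axis=1) + np.log(span)
        return out

    if region == "intermediate":
        log_num = seg_log_integral(lo, hi)
        log_z = np.log(2.0 * (np.sqrt(hi) - np.sqrt(lo)))
    elif region == "outside":
        seg1 = seg_log_integral(np.zeros_like(lo), lo)
        seg2 = seg_log_integral(hi, upper_factor * hi)
        log_num = np.logaddexp(seg1, seg2)
        log_z = np.log(2.0 * np.sqrt(lo) + 2.0 * (np.sqrt(upper_factor * hi) - np.sqrt(hi)))
    else:
        raise ValueError(region)
    logw = logw_a[:, None] + logw_b[None, :]
    return float(logsumexp(log_num - log_z + logw.ravel()))


def ref_log_marglik_intermediate(counts_AB, post_A, post_B,
                                 n_rate: int = 121, n_inner: int = 401) -> float:
    return _ref_region_logml(counts_AB, post_A, post_B, "intermediate", 0.0,
                             n_rate, n_inner)


def ref_log_marglik_outside(counts_AB, post_A, post_B, upper_factor: float = 10.0,
                            n_rate: int = 121, n_inner: int = 401) -> float:
    return _ref_region_logml(counts_AB, post_A, post_B, "outside", upper_factor,
                             n_rate, n_inner)


# ---------------------------------------------------------------------------
# Separation Bayes factor by direct numerical integration
# ---------------------------------------------------------------------------

def _ref_jeffreys_log_ml(counts, lam_max: float = 400.0, n_grid: int = 60001) -> float:
    """Numerically integrate the likelihood against lambda^(-1/2) (in u = sqrt(lam))."""
    y = np.asarray(counts, dtype=float)
    u = np.linspace(1e-8, np.sqrt(lam_max), n_grid)
    lam = u ** 2
    log_like = _log_poisson(y, lam)
    w = _simpson_w(n_grid, u[1] - u[0])
    return float(logsumexp(log_like + np.log(2.0) + np.log(w)))


def ref_separation_bayes_factor(counts_A, counts_B) -> float:
    """Arithmetic intrinsic Bayes factor with exhaustive minimal training
    samples, every marginal evaluated by quadrature rather than closed form."""
    a = np.asarray(counts_A, dtype=int)
    b = np.asarray(counts_B, dtype=int)
    log_raw = (_ref_jeffreys_log_ml(a) + _ref_jeffreys_log_ml(b)
               - _ref_jeffreys_log_ml(np.concatenate([a, b])))
    terms = []
    for ai in a:
        for bj in b:
            lm1 = _ref_jeffreys_log_ml([ai]) + _ref_jeffreys_log_ml([bj])
            lm0 = _ref_jeffreys_log_ml([ai, bj])
            terms.append(lm0 - lm1)
    corr = logsumexp(np.array(terms)) - np.log(len(terms))
    return float(np.exp(log_raw + corr))
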