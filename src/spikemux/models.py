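"""Bayesian comparison of the four dual-stimulus spike-count hypotheses.

Given a screened triplet with single-stimulus Poisson rates lambda_A and
lambda_B, the combined-stimulus (AB) counts are modelled under four
hypotheses:

* ``single``       -- Poi(lambda_AB) with lambda_AB exactly equal to
  lambda_A or lambda_B (an equal-weight average of the two sub-models);
* ``outside``      -- Poi(lambda_AB) with lambda_AB outside the interval
  (min, max) spanned by the single-stimulus rates;
* ``intermediate`` -- Poi(lambda_AB) with lambda_AB strictly inside that
  interval;
* ``mixture``      -- per-presentation switching,
  alpha * Poi(lambda_A) + (1 - alpha) * Poi(lambda_B), with mixing weight
  alpha ~ Uniform[0, 1].

Posterior model probabilities use equal 1/4 priors.  Jeffreys' improper
prior lambda^(-1/2) on Poisson rates is made proper by conditioning on the
single-stimulus data: lambda_A and lambda_B carry their conjugate
Gamma(S + 1/2, n) posteriors, and the free rate lambda_AB of the
``outside``/``intermediate`` hypotheses carries a Jeffreys density truncated
and renormalised on the hypothesis region (the unbounded ``outside`` region
is capped at ``upper_factor`` times the larger rate).  Marginal likelihoods
integrate over lambda_A, lambda_B with defensive importance sampling driven
by a scrambled Sobol sequence; the alpha integral of the mixture is
evaluated exactly via the Bernstein-polynomial expansion of the likelihood
(a Simpson rule on an alpha grid is available as a cross-check).

The per-presentation *assignment score* is the posterior probability that
the count arose from the A component of the mixture, averaged over the same
(alpha, lambda_A, lambda_B) posterior.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats as sps
from scipy.special import betaln, gammainc, gammaincc, gammaln, logsumexp
from scipy.stats import qmc

from .screen import ScreenResult, Triplet

HYPOTHESES = ("single", "outside", "intermediate", "mixture")
WIN_PROB_CONFIDENT = 0.67  # winner at least twice as likely as best alternative
WIN_PROB_MAJORITY = 0.5    # winner at least as likely as all others combined


@dataclass(frozen=True)
class GammaPosterior:
    """Gamma(shape, rate) posterior of a Poisson rate under Jeffreys' prior."""

    shape: float
    rate: float

    def __post_init__(self):
        if self.shape <= 0 or self.rate <= 0:
            raise ValueError("shape and rate must be positive")

    @property
    def mean(self) -> float:
        return self.shape / self.rate


def rate_posterior(counts) -> GammaPosterior:
    """Conjugate update of Jeffreys' prior: shape = sum + 1/2, rate = n."""
    counts = np.asarray(counts, dtype=float)
    if counts.size == 0:
        raise ValueError("need at least one count")
    return GammaPosterior(counts.sum() + 0.5, float(counts.size))


@dataclass(frozen=True)
class QuadConfig:
    """Numerical-integration settings for the marginal likelihoods."""

    n_draws: int = 4096        # scrambled-Sobol posterior draws of (lambda_A, lambda_B)
    n_alpha: int = 201         # Simpson nodes for alpha-grid computations (odd)
    upper_factor: float = 10.0  # cap of the outside region, times max(rate)
    alpha_method: str = "exact"  # "exact" (Bernstein) or "simpson"
    seed: int = 0
    chunk: int = 1024          # draw-chunk size for alpha-grid arrays

    def __post_init__(self):
        if self.n_alpha < 101 or self.n_alpha % 2 == 0:
            raise ValueError("n_alpha must be an odd integer >= 101")
        if self.n_draws < 2000:
            raise ValueError("n_draws must be >= 2000")
        if self.upper_factor <= 1:
            raise ValueError("upper_factor must exceed 1")


@dataclass(frozen=True)
class ModelPosterior:
    p_single: float
    p_outside: float
    p_intermediate: float
    p_mixture: float
    winner: str
    win_prob: float
    mc_se: float
    log_marginals: dict

    @property
    def probs(self) -> dict:
        return {"single": self.p_single, "outside": self.p_outside,
                "intermediate": self.p_intermediate, "mixture": self.p_mixture}

    @property
    def confident(self) -> bool:
        return self.win_prob >= WIN_PROB_CONFIDENT

    @property
    def majority(self) -> bool:
        return self.win_prob > WIN_PROB_MAJORITY


@dataclass(frozen=True)
class MixtureFit:
    alpha_mean: float
    alpha_ci: tuple  # equal-tail 95% credible interval


@dataclass(frozen=True)
class TripletAnalysis:
    posterior: ModelPosterior
    mixture: MixtureFit | None
    scores: np.ndarray | None  # assignment score per AB presentation


# ---------------------------------------------------------------------------
# Rate draws
# ---------------------------------------------------------------------------

def _defensive_dim(post: GammaPosterior, counts_AB: np.ndarray, u: np.ndarray,
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Map uniform variates to rate draws with log importance weights.

    Samples come half from the single-stimulus posterior (u < 1/2) and half
    from the AB-updated posterior (the posterior refined as if every AB
    count came from this rate); the importance weight
    ``posterior / proposal-mixture`` is bounded by 2.  The second component
    covers the far-tail regions that dominate the marginal likelihood when
    the AB data conflict with the single-stimulus posterior; without it
    those integrals are badly underestimated at any practical number of
    plain posterior draws.
    """
    if counts_AB.size == 0:
        lam = sps.gamma.ppf(np.clip(u, 1e-15, 1 - 1e-15), post.shape, scale=1.0 / post.rate)
        return lam, np.zeros(u.size)
    upd = GammaPosterior(post.shape + counts_AB.sum(), post.rate + counts_AB.size)
    from_post = u < 0.5
    q1 = np.clip(2.0 * u, 1e-15, 1 - 1e-15)
    q2 = np.clip(2.0 * u - 1.0, 1e-15, 1 - 1e-15)
    lam = np.where(from_post,
                   sps.gamma.ppf(q1, post.shape, scale=1.0 / post.rate),
                   sps.gamma.ppf(q2, upd.shape, scale=1.0 / upd.rate))
    logp = sps.gamma.logpdf(lam, post.shape, scale=1.0 / post.rate)
    logu = sps.gamma.logpdf(lam, upd.shape, scale=1.0 / upd.rate)
    logq = np.logaddexp(logp, logu) - np.log(2.0)
    return lam, logp - logq


def draw_rates(post_A: GammaPosterior, post_B: GammaPosterior, n_draws: int,
               rng: np.random.Generator, counts_AB=None,
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Defensive scrambled-Sobol draws of (lambda_A, lambda_B) with log weights.

    Returns ``(lam_a, lam_b, log_w)`` such that a marginal likelihood is
    ``mean(exp(log_w) * f(lam_a, lam_b))`` for integrand ``f`` against the
    two independent gamma posteriors.  A scrambled two-dimensional Sobol
    sequence drives the inverse-CDF sampling, so the estimates converge far
    faster than iid Monte Carlo while remaining unbiased and seed-
    deterministic.  Exact rate ties (measure zero) are redrawn.
    """
    y = np.asarray([] if counts_AB is None else counts_AB, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        u = qmc.Sobol(d=2, scramble=True, seed=rng).random(n_draws)
    lam_a, logw_a = _defensive_dim(post_A, y, u[:, 0])
    lam_b, logw_b = _defensive_dim(post_B, y, u[:, 1])
    tie = lam_a == lam_b
    while tie.any():
        lam_b[tie] = sps.gamma.rvs(post_B.shape, scale=1.0 / post_B.rate,
                                   size=int(tie.sum()), random_state=rng)
        logw_b[tie] = 0.0
        tie = lam_a == lam_b
    return lam_a, lam_b, logw_a + logw_b


# ---------------------------------------------------------------------------
# Closed-form pieces
# ---------------------------------------------------------------------------

def log_marglik_single(counts_AB, post: GammaPosterior) -> float:
    """Exact negative-binomial predictive: integral of the Poisson likelihood
    against the Gamma posterior of a single shared rate."""
    y = np.asarray(counts_AB, dtype=float)
    if y.size == 0:
        return 0.0
    s, m = y.sum(), y.size
    a, b = post.shape, post.rate
    return float(gammaln(a + s) - gammaln(a) + a * np.log(b)
                 - (a + s) * np.log(b + m) - gammaln(y + 1).sum())


def _log_gamma_mass(s: float, x_lo: np.ndarray, x_hi: np.ndarray) -> np.ndarray:
    """log of P(s, x_hi) - P(s, x_lo) (regularised incomplete gamma),
    switching to upper-tail differences when both endpoints sit in the tail."""
    lower = gammainc(s, x_hi) - gammainc(s, x_lo)
    upper = gammaincc(s, x_lo) - gammaincc(s, x_hi)
    mass = np.where(x_lo > s, upper, lower)
    with np.errstate(divide="ignore"):
        return np.log(np.clip(mass, 0.0, None))


def _truncated_jeffreys_logml(counts_AB, lam_lo, lam_hi, segments) -> np.ndarray:
    """Per-draw log marginal of Poi(lambda_AB) with a Jeffreys density
    truncated to ``segments`` (list of (lo_arr, hi_arr)) and renormalised.

    For each segment, integral of prod_j Poi(y_j | lam) * lam^(-1/2) d lam
    = Gamma(S + 1/2) / m^(S + 1/2) * [P(S + 1/2, m*hi) - P(S + 1/2, m*lo)]
    and the Jeffreys normaliser of the region is sum of 2*(sqrt(hi) - sqrt(lo)).
    """
    y = np.asarray(counts_AB, dtype=float)
    s, m = y.sum() + 0.5, y.size
    const = gammaln(s) - s * np.log(m) - gammaln(y + 1).sum()
    masses = [_log_gamma_mass(s, m * lo, m * hi) for lo, hi in segments]
    log_mass = masses[0] if len(masses) == 1 else np.logaddexp(*masses)
    z = sum(2.0 * (np.sqrt(hi) - np.sqrt(lo)) for lo, hi in segments)
    return const + log_mass - np.log(z)


# ---------------------------------------------------------------------------
# Mixture marginal
# ---------------------------------------------------------------------------

def _log_pmf_table(uniq: np.ndarray, lam: np.ndarray) -> np.ndarray:
    """log Poisson pmf, shape (n_draws, n_unique)."""
    with np.errstate(divide="ignore"):
        return (uniq[None, :] * np.log(lam)[:, None] - lam[:, None]
                - gammaln(uniq + 1)[None, :])


def _mixture_logvals_exact(y: np.ndarray, lam_a: np.ndarray, lam_b: np.ndarray) -> np.ndarray:
    """Per-draw log of the exact alpha-integral of the mixture likelihood.

    The likelihood is a polynomial in alpha; writing it in the scaled
    Bernstein basis alpha^k (1-alpha)^(m-k) with positive coefficients
    (built by one convolution step per presentation) gives
    integral = sum_k c_k * B(k+1, m-k+1) with no quadrature error.
    """
    uniq, inv = np.unique(y, return_inverse=True)
    pa = np.exp(_log_pmf_table(uniq.astype(float), lam_a))
    pb = np.exp(_log_pmf_table(uniq.astype(float), lam_b))
    n_draws, m = lam_a.size, y.size
    coef = np.zeros((n_draws, m + 1))
    coef[:, 0] = 1.0
    log_scale = np.zeros(n_draws)
    tiny = np.finfo(float).tiny
    for j, u in enumerate(inv):
        a, b = pa[:, u], pb[:, u]
        scale = np.maximum(np.maximum(a, b), tiny)
        a = a / scale
        b = b / scale
        log_scale += np.log(scale)
        new = np.empty((n_draws, j + 2))
        new[:, 0] = b * coef[:, 0]
        if j:
            new[:, 1:j + 1] = a[:, None] * coef[:, :j] + b[:, None] * coef[:, 1:j + 1]
        new[:, j + 1] = a * coef[:, j]
        coef = new
    k = np.arange(m + 1)
    weights = np.exp(betaln(k + 1, m - k + 1))
    with np.errstate(divide="ignore"):
        return log_scale + np.log(coef @ weights)


def _simpson_weights(n: int) -> np.ndarray:
    w = np.ones(n)
    w[1:-1:2] = 4.0
    w[2:-1:2] = 2.0
    return w / 3.0 / (n - 1)


def _mixture_logvals_simpson(y: np.ndarray, lam_a: np.ndarray, lam_b: np.ndarray,
                             n_alpha: int) -> np.ndarray:
    uniq, inv = np.unique(y, return_inverse=True)
    mult = np.bincount(inv).astype(float)
    alpha = np.linspace(0.0, 1.0, n_alpha)
    log_w = np.log(_simpson_weights(n_alpha))
    pa = np.exp(_log_pmf_table(uniq.astype(float), lam_a))
    pb = np.exp(_log_pmf_table(uniq.astype(float), lam_b))
    with np.errstate(divide="ignore"):
        log_mix = np.log(alpha[None, :, None] * pa[:, None, :]
                         + (1 - alpha[None, :, None]) * pb[:, None, :])
    log_like = log_mix @ mult  # (draws, alpha)
    return logsumexp(log_like + log_w[None, :], axis=1)


def _average_draws(logvals: np.ndarray) -> tuple[float, float]:
    """log-mean over draws and a delta-method Monte-Carlo SE of the log."""
    finite = np.isfinite(logvals)
    if not finite.any():
        return -np.inf, 0.0
    shift = logvals[finite].max()
    w = np.exp(logvals - shift, where=np.isfinite(logvals), out=np.zeros_like(logvals))
    mean = w.mean()
    se = w.std() / (mean * np.sqrt(w.size)) if mean > 0 else 0.0
    return float(shift + np.log(mean)), float(se)


def _canonical(post_A: GammaPosterior, post_B: GammaPosterior):
    """Deterministic (hi, lo) ordering so A/B relabelling is an exact symmetry."""
    a_key = (post_A.mean, post_A.shape)
    b_key = (post_B.mean, post_B.shape)
    if a_key >= b_key:
        return post_A, post_B, True
    return post_B, post_A, False


def log_marglik_mixture(counts_AB, post_A: GammaPosterior, post_B: GammaPosterior,
                        quad: QuadConfig | None = None, seed: int | None = None,
                        ) -> tuple[float, float]:
    """Marginal likelihood of the mixture hypothesis (log value, MC SE)."""
    quad = _with_seed(quad, seed)
    y = np.asarray(counts_AB, dtype=int)
    if y.size == 0:
        return 0.0, 0.0
    hi, lo, _ = _canonical(post_A, post_B)
    rng = np.random.default_rng(quad.seed)
    lam_hi, lam_lo, logw = draw_rates(hi, lo, quad.n_draws, rng, y)
    if quad.alpha_method == "exact":
        logvals = _mixture_logvals_exact(y, lam_hi, lam_lo)
    elif quad.alpha_method == "simpson":
        logvals = _mixture_logvals_simpson(y, lam_hi, lam_lo, quad.n_alpha)
    else:
        raise ValueError(f"unknown alpha_method {quad.alpha_method!r}")
    value, se = _average_draws(logvals + logw)
    if not np.isfinite(value):
        raise FloatingPointError("mixture marginal vanished; check inputs")
    return value, se


def log_marglik_intermediate(counts_AB, post_A: GammaPosterior, post_B: GammaPosterior,
                             quad: QuadConfig | None = None, seed: int | None = None,
                             ) -> tuple[float, float]:
    """Marginal likelihood of lambda_AB strictly inside (min, max) of the rates."""
    quad = _with_seed(quad, seed)
    y = np.asarray(counts_AB, dtype=int)
    if y.size == 0:
        return 0.0, 0.0
    hi, lo, _ = _canonical(post_A, post_B)
    rng = np.random.default_rng(quad.seed)
    lam_hi, lam_lo, logw = draw_rates(hi, lo, quad.n_draws, rng, y)
    lam_lo, lam_hi = np.minimum(lam_lo, lam_hi), np.maximum(lam_lo, lam_hi)
    logvals = _truncated_jeffreys_logml(y, lam_lo, lam_hi, [(lam_lo, lam_hi)])
    return _average_draws(logvals + logw)


def log_marglik_outside(counts_AB, post_A: GammaPosterior, post_B: GammaPosterior,
                        quad: QuadConfig | None = None, seed: int | None = None,
                        ) -> tuple[float, float]:
    """Marginal likelihood of lambda_AB in (0, min) union (max, max * upper_factor)."""
    quad = _with_seed(quad, seed)
    y = np.asarray(counts_AB, dtype=int)
    if y.size == 0:
        return 0.0, 0.0
    hi, lo, _ = _canonical(post_A, post_B)
    rng = np.random.default_rng(quad.seed)
    lam_hi, lam_lo, logw = draw_rates(hi, lo, quad.n_draws, rng, y)
    lam_lo, lam_hi = np.minimum(lam_lo, lam_hi), np.maximum(lam_lo, lam_hi)
    zeros = np.zeros_like(lam_lo)
    segments = [(zeros, lam_lo), (lam_hi, quad.upper_factor * lam_hi)]
    logvals = _truncated_jeffreys_logml(y, lam_lo, lam_hi, segments)
    return _average_draws(logvals + logw)


def _with_seed(quad: QuadConfig | None, seed: int | None) -> QuadConfig:
    quad = quad or QuadConfig()
    if seed is not None:
        quad = replace(quad, seed=seed)
    return quad


# ---------------------------------------------------------------------------
# Alpha posterior and assignment scores (shared alpha-grid computation)
# ---------------------------------------------------------------------------

def _alpha_analysis(y: np.ndarray, hi: GammaPosterior, lo: GammaPosterior,
                    quad: QuadConfig) -> tuple[float, tuple, np.ndarray]:
    """Posterior mean and 95% CI of the weight on the *hi* component, and the
    per-presentation posterior probability of the hi component, all under the
    mixture model.  Orientation-free: callers map hi/lo back to A/B."""
    alpha = np.linspace(0.0, 1.0, quad.n_alpha)
    sw = _simpson_weights(quad.n_alpha)
    uniq, inv = np.unique(y, return_inverse=True)
    mult = np.bincount(inv).astype(float)
    rng = np.random.default_rng(quad.seed)
    lam_hi, lam_lo, logw = draw_rates(hi, lo, quad.n_draws, rng, y)

    # per-chunk accumulations carry their own shift; combined at the end
    chunks = []  # (shift, grid_mass, score_num, total)
    for start in range(0, quad.n_draws, quad.chunk):
        sl = slice(start, start + quad.chunk)
        pa = np.exp(_log_pmf_table(uniq.astype(float), lam_hi[sl]))
        pb = np.exp(_log_pmf_table(uniq.astype(float), lam_lo[sl]))
        mix = alpha[None, :, None] * pa[:, None, :] + (1 - alpha[None, :, None]) * pb[:, None, :]
        with np.errstate(divide="ignore"):
            log_like = np.log(mix) @ mult + logw[sl, None]
        shift = log_like.max()
        w = np.exp(log_like - shift) * sw[None, :]
        with np.errstate(invalid="ignore"):
            ratio = alpha[None, :, None] * pa[:, None, :] / mix
        ratio = np.nan_to_num(ratio, nan=0.5)
        chunks.append((shift, w.sum(axis=0), np.einsum("da,dau->u", w, ratio), w.sum()))
    top = max(c[0] for c in chunks)
    grid_mass = sum(np.exp(c[0] - top) * c[1] for c in chunks)
    score_num = sum(np.exp(c[0] - top) * c[2] for c in chunks)
    total = sum(np.exp(c[0] - top) * c[3] for c in chunks)
    mean_hi = float((grid_mass * alpha).sum() / grid_mass.sum())
    cdf = np.cumsum(grid_mass) / grid_mass.sum()
    ci_hi = (float(np.interp(0.025, cdf, alpha)), float(np.interp(0.975, cdf, alpha)))
    scores_hi = (score_num / total)[inv]
    return mean_hi, ci_hi, scores_hi


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def classify_triplet(t: Triplet, quad: QuadConfig | None = None,
                     screen: ScreenResult | None = None,
                     require_screened: bool = True,
                     fit_mixture: bool = True,
                     seed: int | None = None) -> TripletAnalysis:
    """Posterior probabilities of the four hypotheses for one triplet.

    The triplet must have passed the screening criteria (pass the
    ``ScreenResult``, or set ``require_screened=False`` for synthetic /
    diagnostic use).  ``fit_mixture`` additionally computes the mixing-weight
    posterior and the per-presentation assignment scores.
    """
    if require_screened and (screen is None or not screen.passed):
        raise ValueError("triplet has not passed screening; refusing to classify")
    quad = _with_seed(quad, seed)
    post_a = rate_posterior(t.counts_A)
    post_b = rate_posterior(t.counts_B)
    y = np.asarray(t.counts_AB, dtype=int)

    ls_parts = sorted([log_marglik_single(y, post_a), log_marglik_single(y, post_b)])
    log_single = float(np.logaddexp(ls_parts[0], ls_parts[1]) - np.log(2.0))
    log_out, se_out = log_marglik_outside(y, post_a, post_b, quad)
    log_mid, se_mid = log_marglik_intermediate(y, post_a, post_b, quad)
    log_mix, se_mix = log_marglik_mixture(y, post_a, post_b, quad)

    logs = np.array([log_single, log_out, log_mid, log_mix])
    ses = np.array([0.0, se_out, se_mid, se_mix])
    probs = np.exp(logs - logsumexp(logs))
    probs = probs / probs.sum()
    widx = int(np.argmax(probs))
    # delta-method SE of the winning probability from the marginals' MC SEs
    grad = -probs[widx] * probs
    grad[widx] += probs[widx]
    win_se = float(np.sqrt(np.sum((grad * ses) ** 2)))
    posterior = ModelPosterior(
        p_single=float(probs[0]), p_outside=float(probs[1]),
        p_intermediate=float(probs[2]), p_mixture=float(probs[3]),
        winner=HYPOTHESES[widx], win_prob=float(probs[widx]), mc_se=win_se,
        log_marginals=dict(zip(HYPOTHESES, map(float, logs))))

    mixture = scores = None
    if fit_mixture and y.size:
        hi, lo, a_is_hi = _canonical(post_a, post_b)
        mean_hi, ci_hi, scores_hi = _alpha_analysis(y, hi, lo, quad)
        if a_is_hi:
            mixture = MixtureFit(mean_hi, ci_hi)
            scores = scores_hi
        else:
            mixture = MixtureFit(1.0 - mean_hi, (1.0 - ci_hi[1], 1.0 - ci_hi[0]))
            scores = 1.0 - scores_hi
    return TripletAnalysis(posterior, mixture, scores)


def assignment_scores(t: Triplet, quad: QuadConfig | None = None,
                      method: str = "bayes") -> np.ndarray:
    """Per-AB-presentation probability in [0, 1] that the count is A-like.

    ``bayes`` averages the mixture-component posterior over the full
    (alpha, lambda_A, lambda_B) posterior; ``plugin`` evaluates it at the
    posterior-mean mixing weight and rates.
    """
    quad = quad or QuadConfig()
    post_a = rate_posterior(t.counts_A)
    post_b = rate_posterior(t.counts_B)
    y = np.asarray(t.counts_AB, dtype=float)
    hi, lo, a_is_hi = _canonical(post_a, post_b)
    if method == "bayes":
        _, _, s_hi = _alpha_analysis(y.astype(int), hi, lo, quad)
    elif method == "plugin":
        mean_hi, _, _ = _alpha_analysis(y.astype(int), hi, lo, quad)
        s_hi = plugin_scores(y, mean_hi, hi.mean, lo.mean)
    else:
        raise ValueError(f"unknown method {method!r}")
    return s_hi if a_is_hi else 1.0 - s_hi


def plugin_scores(y, alpha_hat: float, lam_a: float, lam_b: float) -> np.ndarray:
    """Mixture-component posterior at fixed (alpha, lambda_A, lambda_B)."""
    y = np.asarray(y, dtype=float)
    la = alpha_hat * sps.poisson.pmf(y, lam_a)
    lb = (1.0 - alpha_hat) * sps.poisson.pmf(y, lam_b)
    with np.errstate(invalid="ignore"):
        s = la / (la + lb)
    return np.where(np.isfinite(s), s, 0.5)


#: Lighter settings for large simulation sweeps; per-triplet accuracy stays
#: well inside the tolerances validated against the grid reference.
FAST_QUAD = QuadConfig(n_draws=2048, n_alpha=101, chunk=512)
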