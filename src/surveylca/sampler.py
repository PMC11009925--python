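"""Gibbs sampler for the (survey-weighted) overfitted latent class model.

One code path serves both the unweighted model and the weighted variant:
the weighted model raises each subject's likelihood contribution to
``w_i / kappa`` (normalised weight), which turns the conjugate Dirichlet
updates for ``pi`` and ``theta`` into updates on *weighted* counts and —
with the tempered class-assignment conditional (the default) — makes the
three full conditionals the exact Gibbs conditionals of one coherent
pseudo-posterior. With unit weights every formula collapses to the
ordinary latent class model, draw for draw.

Overfitting: ``K`` is fixed far above the plausible number of classes
(default 50) with a sparse symmetric prior ``alpha = 1/K`` on ``pi``, so
superfluous classes empty out during sampling, approximating a Dirichlet
process mixture.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .data_model import (
    CategoricalMatrix,
    PosteriorDraws,
    SamplerConfig,
    SamplerState,
    SurveyWeights,
)

__all__ = [
    "WeightedCounts",
    "weighted_counts",
    "update_pi",
    "update_theta",
    "update_z",
    "permute_labels",
    "run_gibbs",
    "log_pseudo_likelihood",
]

# floor applied to probabilities before taking logs; guards against exact
# zeros from degenerate Dirichlet draws with tiny shape parameters
_PROB_FLOOR = 1e-300


@dataclass
class WeightedCounts:
    """Weighted class occupancies and item-level cross-tabs.

    ``class_counts[k] = (1/kappa) sum_i w_i 1(z_i = k)`` and
    ``item_counts[j, c, k] = (1/kappa) sum_{i: z_i=k} w_i 1(y_ij = c+1)``;
    with unit weights these are the plain cell counts.
    """

    class_counts: np.ndarray  # (K,)
    item_counts: np.ndarray  # (p, d_max, K)


def weighted_counts(
    data: CategoricalMatrix, z: np.ndarray, weights: SurveyWeights, K: int
) -> WeightedCounts:
    """Accumulate the normalised-weight counts that drive the conjugate
    updates. ``z`` is 1-based."""
    z0 = np.asarray(z, dtype=np.int64) - 1
    if np.any(z0 < 0) or np.any(z0 >= K):
        raise ValueError("class labels must lie in [1, K]")
    wn = weights.normalized
    n, p = data.n, data.p
    d_max = data.d_max
    class_counts = np.bincount(z0, weights=wn, minlength=K)
    # flat index (j, c, k) -> (j*d_max + c)*K + k, accumulated in one bincount
    y0 = data.y - 1
    flat = (np.arange(p)[None, :] * d_max + y0) * K + z0[:, None]
    item_counts = np.bincount(
        flat.ravel(), weights=np.repeat(wn, p), minlength=p * d_max * K
    ).reshape(p, d_max, K)
    return WeightedCounts(class_counts, item_counts)


def update_pi(
    counts: WeightedCounts | np.ndarray, alpha, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``pi`` from its Dirichlet full conditional
    ``Dir(alpha_k + (1/kappa) sum_i w_i 1(z_i=k))``."""
    cc = counts.class_counts if isinstance(counts, WeightedCounts) else np.asarray(counts)
    alpha = np.broadcast_to(np.atleast_1d(np.asarray(alpha, dtype=np.float64)), cc.shape)
    if np.any(alpha <= 0):
        raise ValueError("alpha must be positive")
    g = rng.standard_gamma(alpha + cc)
    g = np.clip(g, _PROB_FLOOR, None)
    return g / g.sum()


def update_theta(
    counts: WeightedCounts,
    level_mask: np.ndarray,
    gamma: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw every ``theta_{j.|k}`` from its Dirichlet full conditional
    ``Dir(gamma + weighted item counts)``; empty classes draw from the prior.

    Returns ``(p, d_max, K)`` with zeros at levels beyond ``d_j``.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    shape = gamma + counts.item_counts
    g = rng.standard_gamma(shape)
    g = np.clip(g, _PROB_FLOOR, None)
    g *= level_mask[:, :, None]
    return g / g.sum(axis=1, keepdims=True)


def _log_membership(
    X: np.ndarray, log_theta_flat: np.ndarray, log_pi: np.ndarray
) -> np.ndarray:
    """Per-subject unnormalised log class masses
    ``log pi_k + sum_j log theta_{j, y_ij | k}`` via one matrix product.

    ``X`` is the fixed one-hot design ``(n, p*d_max)`` of the responses, so
    the p-fold gather-and-sum is a single BLAS call per sweep.
    """
    return X @ log_theta_flat + log_pi[None, :]


def _one_hot(data: CategoricalMatrix, dtype=np.float64) -> np.ndarray:
    n, p, d_max = data.n, data.p, data.d_max
    X = np.zeros((n, p * d_max), dtype=dtype)
    cols = np.arange(p)[None, :] * d_max + (data.y - 1)
    X[np.arange(n)[:, None], cols] = 1.0
    return X


def update_z(
    data: CategoricalMatrix,
    pi: np.ndarray,
    theta: np.ndarray,
    weights: SurveyWeights,
    tempered: bool,
    rng: np.random.Generator,
    X: np.ndarray | None = None,
) -> np.ndarray:
    """Draw 1-based class labels from the categorical full conditional.

    Tempered (default): ``P(z_i=k) ∝ [pi_k prod_j theta_{j,y_ij|k}]^{w_i/kappa}``
    — the complete-data conditional implied by the pseudo-likelihood.
    Untempered: the same with exponent 1. Computed in the log domain
    (p = 50 products underflow otherwise) with Gumbel-max sampling.
    """
    if X is None:
        X = _one_hot(data)
    K = pi.size
    log_theta = np.log(np.clip(theta, _PROB_FLOOR, None)).reshape(-1, K)
    log_pi = np.log(np.clip(pi, _PROB_FLOOR, None))
    logp = _log_membership(X, log_theta, log_pi)
    if not np.all(np.isfinite(logp)):
        raise FloatingPointError("non-finite log class masses in z update")
    if tempered:
        logp = logp * weights.normalized[:, None]
    gumbel = -np.log(-np.log(rng.random(logp.shape)))
    return np.argmax(logp + gumbel, axis=1).astype(np.int64) + 1


def permute_labels(
    state: SamplerState,
    rng: np.random.Generator | None = None,
    sigma: np.ndarray | None = None,
) -> SamplerState:
    """Apply a uniformly random permutation of the K class labels
    consistently to ``pi``, ``theta`` and ``z`` (random permutation sampler;
    leaves the likelihood invariant, encourages label mixing)."""
    K = state.pi.size
    if sigma is None:
        if rng is None:
            raise ValueError("provide either rng or an explicit permutation")
        sigma = rng.permutation(K)
    sigma = np.asarray(sigma)
    # sigma maps old label k -> new label sigma[k]; new parameter slot
    # sigma[k] must hold old slot k
    inverse = np.empty(K, dtype=np.int64)
    inverse[sigma] = np.arange(K)
    return SamplerState(
        z=sigma[state.z - 1] + 1,
        pi=state.pi[inverse],
        theta=state.theta[:, :, inverse],
    )


def log_pseudo_likelihood(
    data: CategoricalMatrix,
    weights: SurveyWeights,
    pi: np.ndarray,
    theta: np.ndarray,
) -> float:
    """Weighted mixture log likelihood
    ``sum_i (w_i/kappa) log sum_k pi_k prod_j theta_{j, y_ij | k}``,
    evaluated with log-sum-exp. Unit weights give the ordinary latent class
    log likelihood."""
    X = _one_hot(data)
    K = pi.size
    log_theta = np.log(np.clip(theta, _PROB_FLOOR, None)).reshape(-1, K)
    log_pi = np.log(np.clip(pi, _PROB_FLOOR, None))
    per_subject = logsumexp(_log_membership(X, log_theta, log_pi), axis=1)
    return float(np.dot(weights.normalized, per_subject))


def run_gibbs(
    data: CategoricalMatrix,
    weights: SurveyWeights | None,
    config: SamplerConfig,
) -> PosteriorDraws:
    """Run the full Gibbs sweep ``pi -> theta -> z`` (plus the optional
    random permutation move) and retain every ``thin``-th state after
    ``burn_in``. Fully reproducible from ``config.seed``.

    ``weights`` may be ``None`` or ``config.weighted`` may be ``False``;
    either way unit weights are used and the run is the unweighted model.
    """
    n, p = data.n, data.p
    if weights is not None and weights.n != n:
        raise ValueError(f"weights have length {weights.n}, data has n={n}")
    if not config.weighted or weights is None:
        weights = SurveyWeights.unit(n)
    rng = np.random.default_rng(config.seed)
    K = config.K
    alpha = config.alpha_vector()
    mask = data.level_mask()
    X = _one_hot(data)

    z = rng.integers(1, K + 1, size=n)

    # Warm start: overfitted mixtures started from uniform labels coalesce
    # into several persistent subclusters per true class, and plain Gibbs
    # has no merge move to repair that. With unequal weights (and
    # especially with tempering, which makes high-weight subjects sticky)
    # the barrier can be insurmountable, so by default the first sweeps of
    # burn-in run with unit weights — the well-mixing unweighted sampler —
    # before the weighted kernel takes over. This only affects burn-in;
    # retained draws always come from the configured kernel. With unit
    # weights the warm phase is the sampler itself, so unweighted runs are
    # unaffected, draw for draw.
    unit = SurveyWeights.unit(n)
    if config.init == "warm" and config.weighted:
        warm = config.init_sweeps
        if warm is None:
            warm = min(config.burn_in // 2, 1000)
        warm = min(warm, config.burn_in)
    else:
        warm = 0

    T = config.n_retained
    z_dtype = np.uint8 if K <= 255 else np.uint16
    pi_draws = np.empty((T, K))
    theta_draws = np.empty((T, p, data.d_max, K), dtype=np.float32)
    z_draws = np.empty((T, n), dtype=z_dtype)
    retained = np.empty(T, dtype=np.int64)

    t = 0
    for it in range(config.n_iter):
        w_it = unit if it < warm else weights
        counts = weighted_counts(data, z, w_it, K)
        pi = update_pi(counts, alpha, rng)
        theta = update_theta(counts, mask, config.gamma, rng)
        z = update_z(data, pi, theta, w_it, config.tempered_z, rng, X=X)
        if config.permute_labels:
            state = permute_labels(SamplerState(z, pi, theta), rng)
            z, pi, theta = state.z, state.pi, state.theta
        if not (np.all(np.isfinite(pi)) and np.all(np.isfinite(theta))):
            raise FloatingPointError(f"non-finite parameter at iteration {it}")
        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0 and t < T:
            pi_draws[t] = pi
            theta_draws[t] = theta
            z_draws[t] = z
            retained[t] = it
            t += 1

    return PosteriorDraws(
        pi_draws=pi_draws[:t],
        theta_draws=theta_draws[:t],
        z_draws=z_draws[:t],
        config=config,
        kappa=weights.kappa,
        level_counts=data.level_counts.copy(),
        retained_iterations=retained[:t],
    )
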