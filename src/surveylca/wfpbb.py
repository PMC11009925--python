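"""Weighted finite population Bayesian bootstrap (WFPBB) comparator.

The WFPBB "undoes" an unequal-probability design in two stages: a weighted
Pólya urn imputes a synthetic population of size ``N_target ≈ sum(w)`` from
the observed sample, and an approximate simple random sample drawn from
that synthetic population is refit with the *unweighted* overfitted latent
class model. Repeating over ``B`` pseudo-populations and pooling the
aligned posterior draws yields design-adjusted estimates without touching
the sampler itself.

Urn scheme (Cohen/Dong style): the synthetic population contains the n
observed units once each, plus ``N_target - n`` urn draws where at draw t
unit i is selected with probability proportional to
``w_i - 1 + l_{i,t-1} * (N_target - n)/n``, ``l_{i,t-1}`` being the number
of times i was already drawn. The selection probabilities sum to one at
every step because ``sum_i (w_i - 1) = N_target - n``.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .data_model import CategoricalMatrix, SamplerConfig, SurveyWeights
from .postprocess import ClassSummary, postprocess_draws
from .sampler import run_gibbs

__all__ = ["WfpbbConfig", "WfpbbResult", "polya_urn_population", "wfpbb_fit"]


@dataclass
class WfpbbConfig:
    """Settings for a WFPBB run: ``B`` pseudo-populations, SRS size ``m``
    per pseudo-population (default: the sample size), target synthetic
    population size (default: ``round(sum(w))``) and the sampler settings
    for the unweighted refits."""

    B: int = 20
    m: int | None = None
    N_target: int | None = None
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValueError("B must be >= 1")


@dataclass
class WfpbbResult:
    """Pooled output of a WFPBB run."""

    summary: ClassSummary
    pooled_pi_draws: np.ndarray  # (sum of aligned T_b, G)
    modal_patterns: np.ndarray  # (G, p) reference patterns used for alignment
    per_bootstrap: list  # ClassSummary per pseudo-population
    n_aligned: int
    n_dropped: int


def polya_urn_population(
    weights: SurveyWeights | np.ndarray,
    N_target: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw one synthetic-population multiplicity vector via the weighted
    Pólya urn.

    Returns integer multiplicities per observed unit, summing exactly to
    ``N_target``. Every observed unit appears at least once. Weights below
    one are invalid for the urn; callers should rescale.
    """
    w = weights.w if isinstance(weights, SurveyWeights) else np.asarray(weights, float)
    if rng is None:
        rng = np.random.default_rng()
    n = w.size
    if N_target is None:
        N_target = int(round(w.sum()))
    if np.any(w < 1):
        raise ValueError(
            "the Polya urn requires every weight >= 1; rescale the weights "
            "(e.g. w / w.min()) before calling"
        )
    if N_target < n:
        raise ValueError("N_target must be at least the sample size")
    extra = N_target - n
    mult = np.ones(n, dtype=np.int64)
    if extra == 0:
        return mult
    l = np.zeros(n, dtype=np.float64)  # prior urn selections per unit
    ratio = extra / n
    base = w - 1.0
    for t in range(1, extra + 1):
        probs = base + l * ratio
        # the theoretical total is extra + (t-1)*ratio; when N_target was
        # rounded from a non-integer sum(w) the actual total differs by at
        # most that rounding error, so normalise by the actual sum and
        # assert agreement within the slack
        total = extra + (t - 1) * ratio
        s = probs.sum()
        if np.any(probs < -1e-9) or abs(s - total) > 0.5 + 1e-6 * total:
            raise FloatingPointError("urn probabilities degenerated")
        i = rng.choice(n, p=np.clip(probs, 0.0, None) / s)
        l[i] += 1.0
        mult[i] += 1
    assert mult.sum() == N_target
    return mult


def _merge_redundant(
    modal: np.ndarray, pi_draws: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Merge classes with identical modal patterns, summing their
    prevalence draws. Resampling with replacement (duplicated subjects)
    makes the overfitted refits prone to splitting a true pattern into
    redundant classes; merging restores one class per distinct pattern."""
    groups: dict[tuple, list[int]] = {}
    for g, row in enumerate(modal):
        groups.setdefault(tuple(row), []).append(g)
    keys = list(groups)
    merged_modal = np.array([list(k) for k in keys], dtype=np.int64)
    merged_pi = np.stack(
        [pi_draws[:, groups[k]].sum(axis=1) for k in keys], axis=1
    )
    return merged_modal, merged_pi


def _align_to_reference(
    modal: np.ndarray, pi_draws: np.ndarray, reference_modes: np.ndarray
) -> np.ndarray | None:
    """Permute one bootstrap's classes to a reference by modal-pattern
    agreement; returns the aligned pi draws or None when the class counts
    cannot be matched."""
    G_ref = reference_modes.shape[0]
    agree = (modal[:, None, :] == reference_modes[None, :, :]).sum(axis=2)
    rows, cols = linear_sum_assignment(-agree)
    aligned = np.full((pi_draws.shape[0], G_ref), np.nan)
    for g, r in zip(rows, cols):
        aligned[:, r] = pi_draws[:, g]
    if np.isnan(aligned).all(axis=0).any():
        return None
    return aligned


def wfpbb_fit(
    data: CategoricalMatrix,
    weights: SurveyWeights,
    config: WfpbbConfig,
) -> WfpbbResult:
    """Method 2 of the benchmark: B rounds of synthetic-population
    imputation, SRS, and unweighted overfitted-LCM refit; the aligned
    posterior draws are pooled into a mixture-of-posteriors.

    Class alignment across bootstraps uses modal-pattern agreement against
    the first bootstrap's recovered patterns; bootstraps whose classes
    cannot be matched are dropped (and counted).
    """
    rng = np.random.default_rng(config.seed)
    n = data.n
    m = n if config.m is None else config.m
    w = weights.w
    if np.any(w < 1):
        warnings.warn(
            "weights below 1 rescaled to minimum 1 for the Polya urn",
            stacklevel=2,
        )
        w = w / w.min()
    N_target = int(round(w.sum())) if config.N_target is None else config.N_target
    if m > N_target:
        raise ValueError("SRS size m cannot exceed the synthetic population size")

    per_bootstrap: list[ClassSummary] = []
    boot_modal: list[np.ndarray] = []
    pi_per_boot: list[np.ndarray] = []
    for b in range(config.B):
        mult = polya_urn_population(w, N_target, rng)
        # SRS without replacement from the expanded synthetic population
        expanded = np.repeat(np.arange(n), mult)
        take = rng.choice(expanded.size, size=m, replace=False)
        idx = expanded[take]
        boot = CategoricalMatrix(data.y[idx], data.level_counts.copy())
        cfg = dataclasses.replace(
            config.sampler,
            weighted=False,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        draws = run_gibbs(boot, None, cfg)
        summary, relabelled, _ = postprocess_draws(draws)
        per_bootstrap.append(summary)
        # surviving-class pi draws (summary order), then redundancy merge
        surv = np.flatnonzero(np.median(relabelled.pi_draws, axis=0) >= 0.05)
        modal_b, pi_b = _merge_redundant(
            summary.modal_pattern, relabelled.pi_draws[:, surv]
        )
        boot_modal.append(modal_b)
        pi_per_boot.append(pi_b)

    # alignment reference: a bootstrap with the modal recovered class count
    # (the single most typical fit), not blindly the first one
    counts = np.array([m.shape[0] for m in boot_modal])
    modal_G = np.bincount(counts).argmax()
    ref = int(np.flatnonzero(counts == modal_G)[0])
    reference_modes = boot_modal[ref]

    pooled = []
    dropped = 0
    for b, (modal_b, pi_b) in enumerate(zip(boot_modal, pi_per_boot)):
        if b == ref:
            pooled.append(pi_b)
            continue
        aligned = _align_to_reference(modal_b, pi_b, reference_modes)
        if aligned is None or np.isnan(aligned).any():
            dropped += 1
            continue
        pooled.append(aligned)
    pooled_pi = np.vstack(pooled)

    # pooled theta summaries: map the reference bootstrap's (unmerged)
    # classes onto the merged patterns, averaging duplicates weighted by
    # their median prevalence
    reference = per_bootstrap[ref]
    G = reference_modes.shape[0]
    p, d_max = reference.theta_mean.shape[0], reference.theta_mean.shape[1]
    theta_mean = np.zeros((p, d_max, G))
    theta_median = np.zeros((p, d_max, G))
    for g in range(G):
        members = np.flatnonzero(
            (reference.modal_pattern == reference_modes[g][None, :]).all(axis=1)
        )
        wts = reference.prevalence[members]
        wts = wts / wts.sum()
        theta_mean[:, :, g] = reference.theta_mean[:, :, members] @ wts
        theta_median[:, :, g] = reference.theta_median[:, :, members] @ wts

    pooled_summary = ClassSummary(
        n_classes=G,
        prevalence=np.median(pooled_pi, axis=0),
        theta_mean=theta_mean,
        theta_median=theta_median,
        modal_pattern=reference_modes,
        assignments=reference.assignments,
        discard_mass_mean=reference.discard_mass_mean,
    )
    return WfpbbResult(
        summary=pooled_summary,
        pooled_pi_draws=pooled_pi,
        modal_patterns=reference_modes,
        per_bootstrap=per_bootstrap,
        n_aligned=len(pooled),
        n_dropped=dropped,
    )
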