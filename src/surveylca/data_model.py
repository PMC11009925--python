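"""Core data containers and I/O for survey latent class analysis.

The containers mirror the quantities of a latent class model for
multivariate categorical responses: an ``n x p`` matrix of 1-based
consumption levels, per-item level counts ``d_j``, positive sampling
weights with their normalisation constant ``kappa = sum(w)/n``, and the
state / retained-draw containers of the Gibbs sampler.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CategoricalMatrix",
    "SurveyWeights",
    "SamplerConfig",
    "SamplerState",
    "PosteriorDraws",
    "read_categorical_csv",
    "compute_kappa",
    "discretize_none_plus_tertiles",
    "write_results",
    "read_prevalence",
    "read_manifest",
]


@dataclass
class CategoricalMatrix:
    """An ``n x p`` matrix of categorical responses, item ``j`` taking 1-based
    levels ``1..d_j``.

    Missing values are rejected: the model requires complete response data;
    imputation, where needed, happens upstream.
    """

    y: np.ndarray
    level_counts: np.ndarray
    item_names: list[str] = field(default_factory=list)
    subject_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y)
        if self.y.ndim != 2 or self.y.shape[0] < 1 or self.y.shape[1] < 1:
            raise ValueError("y must be a 2-D matrix with n >= 1, p >= 1")
        if not np.issubdtype(self.y.dtype, np.integer):
            if pd.isna(self.y).any():
                raise ValueError("missing responses are not allowed")
            if not np.all(self.y == np.floor(self.y)):
                raise ValueError("responses must be integers")
            self.y = self.y.astype(np.int64)
        self.level_counts = np.asarray(self.level_counts, dtype=np.int64)
        if self.level_counts.shape != (self.p,):
            raise ValueError("level_counts must have length p")
        if np.any(self.level_counts < 2):
            raise ValueError("every item needs d_j >= 2 levels")
        if np.any(self.y < 1) or np.any(self.y > self.level_counts[None, :]):
            raise ValueError("responses must lie in [1, d_j] for every item")
        if not self.item_names:
            self.item_names = [f"item_{j + 1}" for j in range(self.p)]
        if not self.subject_ids:
            self.subject_ids = [str(i + 1) for i in range(self.n)]

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def p(self) -> int:
        return self.y.shape[1]

    @property
    def d_max(self) -> int:
        return int(self.level_counts.max())

    def level_mask(self) -> np.ndarray:
        """Boolean ``(p, d_max)`` mask of levels that exist per item."""
        return np.arange(self.d_max)[None, :] < self.level_counts[:, None]


@dataclass
class SurveyWeights:
    """Positive sampling weights with normalisation constant
    ``kappa = sum(w)/n`` and normalised weights ``w/kappa`` (mean 1).

    Dividing by ``kappa`` makes the weights sum to the sample size, so the
    pseudo-posterior's precision reflects ``n`` rather than the population
    size while point estimation still targets the population.
    """

    w: np.ndarray
    kappa: float = field(init=False)
    normalized: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=np.float64)
        if self.w.ndim != 1 or self.w.size < 1:
            raise ValueError("weights must be a 1-D vector")
        if np.any(~np.isfinite(self.w)) or np.any(self.w <= 0):
            raise ValueError("all sampling weights must be positive and finite")
        self.kappa = compute_kappa(self.w, self.w.size)
        self.normalized = self.w / self.kappa

    @property
    def n(self) -> int:
        return self.w.size

    @classmethod
    def unit(cls, n: int) -> "SurveyWeights":
        """Unit weights (kappa = 1); the unweighted model's degenerate case."""
        return cls(np.ones(n))


@dataclass
class SamplerConfig:
    """Gibbs sampler settings for the (weighted) overfitted latent class model.

    Defaults follow the standard protocol: ``K = 50`` latent classes, flat
    symmetric Dirichlet priors with ``alpha = 1/K`` on the class probabilities
    and ``gamma = 1`` on every item-response distribution.
    """

    K: int = 50
    alpha: float | np.ndarray | None = None
    gamma: float = 1.0
    n_iter: int = 25_000
    burn_in: int = 15_000
    thin: int = 5
    seed: int = 0
    weighted: bool = True
    permute_labels: bool = False
    tempered_z: bool = True
    init: str = "warm"
    init_sweeps: int | None = None

    def __post_init__(self) -> None:
        if self.init not in {"warm", "uniform"}:
            raise ValueError("init must be 'warm' or 'uniform'")
        if self.K < 2:
            raise ValueError("K must be >= 2")
        if self.alpha is None:
            self.alpha = 1.0 / self.K
        alpha = np.atleast_1d(np.asarray(self.alpha, dtype=np.float64))
        if alpha.size not in (1, self.K):
            raise ValueError("alpha must be a scalar or a length-K vector")
        if np.any(alpha <= 0) or self.gamma <= 0:
            raise ValueError("alpha and gamma must be positive")
        if not (0 <= self.burn_in < self.n_iter):
            raise ValueError("need 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    def alpha_vector(self) -> np.ndarray:
        return np.broadcast_to(
            np.atleast_1d(np.asarray(self.alpha, dtype=np.float64)), (self.K,)
        ).copy()

    @property
    def n_retained(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["alpha"] = np.atleast_1d(np.asarray(self.alpha)).tolist()
        return d


@dataclass
class SamplerState:
    """One Gibbs state: class labels ``z`` (1-based), class probabilities
    ``pi`` and item-response probabilities ``theta[j, c, k]``."""

    z: np.ndarray
    pi: np.ndarray
    theta: np.ndarray  # (p, d_max, K); invalid levels are zero

    def validate(self, level_mask: np.ndarray | None = None) -> None:
        K = self.pi.size
        if np.any(self.z < 1) or np.any(self.z > K):
            raise ValueError("z out of range")
        if not np.isclose(self.pi.sum(), 1.0):
            raise ValueError("pi must lie on the simplex")
        sums = self.theta.sum(axis=1)
        if not np.allclose(sums, 1.0):
            raise ValueError("theta slices must lie on the simplex")
        if np.any(self.pi <= 0):
            raise ValueError("pi entries must be strictly positive")
        valid = self.theta if level_mask is None else self.theta[level_mask]
        if np.any(valid[valid != 0] <= 0):
            raise ValueError("theta entries must be strictly positive")


@dataclass
class PosteriorDraws:
    """Thinned post-burn-in draws of ``pi``, ``theta`` and ``z``.

    ``theta_draws`` has shape ``(T, p, d_max, K)`` (float32; levels beyond
    ``d_j`` are zero), ``pi_draws`` is ``(T, K)`` and ``z_draws`` is ``(T, n)``
    in a compact integer dtype, 1-based.
    """

    pi_draws: np.ndarray
    theta_draws: np.ndarray
    z_draws: np.ndarray
    config: SamplerConfig
    kappa: float
    level_counts: np.ndarray
    retained_iterations: np.ndarray

    @property
    def T(self) -> int:
        return self.pi_draws.shape[0]

    @property
    def K(self) -> int:
        return self.pi_draws.shape[1]

    @property
    def n(self) -> int:
        return self.z_draws.shape[1]


def compute_kappa(w: Sequence[float] | np.ndarray, n: int) -> float:
    """Weight normalisation constant ``kappa = sum(w) / n``.

    Homogeneous of degree one in the weights, so ``w/kappa`` is scale-free.
    """
    w = np.asarray(w, dtype=np.float64)
    if w.size != n:
        raise ValueError(f"weight vector has length {w.size}, expected n={n}")
    if np.any(w <= 0):
        raise ValueError("all weights must be strictly positive")
    return float(w.sum() / n)


def read_categorical_csv(
    path: str | Path,
    level_counts: Sequence[int] | None = None,
    weight_col: str | None = None,
    sep: str | None = None,
) -> CategoricalMatrix | tuple[CategoricalMatrix, SurveyWeights]:
    """Read an ``n x p`` categorical response matrix from a delimited file.

    The file needs a header row; every cell must parse as a positive integer.
    ``d_j`` is inferred as the maximum observed level per item unless
    ``level_counts`` is supplied (which allows unobserved top levels).
    With ``weight_col`` set, that column is split off and returned as
    :class:`SurveyWeights`.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    weights = None
    if weight_col is not None:
        if weight_col not in df.columns:
            raise ValueError(f"weight column {weight_col!r} not found in {path}")
        weights = SurveyWeights(df.pop(weight_col).to_numpy(dtype=np.float64))
    values = df.to_numpy()
    y = np.empty(values.shape, dtype=np.int64)
    for j, col in enumerate(df.columns):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() | (numeric != np.floor(numeric)) | (numeric < 1)
        if bad.any():
            i = int(np.argmax(bad.to_numpy()))
            raise ValueError(
                f"cell at row {i + 1}, column {col!r} of {path.name} is not a "
                f"positive integer: {df[col].iloc[i]!r}"
            )
        y[:, j] = numeric.to_numpy(dtype=np.int64)
    if level_counts is None:
        d = y.max(axis=0)
        d = np.maximum(d, 2)
    else:
        d = np.asarray(level_counts, dtype=np.int64)
        if d.shape != (y.shape[1],):
            raise ValueError("level_counts must have one entry per item column")
        over = y > d[None, :]
        if over.any():
            i, j = np.argwhere(over)[0]
            raise ValueError(
                f"value {y[i, j]} at row {i + 1}, column {df.columns[j]!r} "
                f"exceeds the supplied d_j={d[j]}"
            )
    mat = CategoricalMatrix(y, d, item_names=list(df.columns))
    return (mat, weights) if weights is not None else mat


def discretize_none_plus_tertiles(x: Sequence[float] | np.ndarray) -> np.ndarray:
    """Code nonnegative consumption values as none + tertiles of positive
    consumption.

    Zero maps to level 1; positive values map to levels 2/3/4 by the
    empirical 1/3 and 2/3 quantiles of the *positive* subsample. A value
    exactly equal to a cut point goes to the lower level; consequently, with
    a single distinct positive value both cuts collapse onto it and every
    positive value gets level 2 (documented degenerate convention).
    """
    x = np.asarray(x, dtype=np.float64)
    if np.any(~np.isfinite(x)) or np.any(x < 0):
        raise ValueError("consumption values must be finite and nonnegative")
    out = np.ones(x.shape, dtype=np.int64)
    pos = x[x > 0]
    if pos.size == 0:
        return out
    if np.unique(pos).size < 3:
        warnings.warn(
            "fewer than 3 distinct positive values: tertile cuts are degenerate",
            stacklevel=2,
        )
    c1, c2 = np.quantile(pos, [1.0 / 3.0, 2.0 / 3.0])
    positive = x > 0
    out[positive] = np.where(
        x[positive] <= c1, 2, np.where(x[positive] <= c2, 3, 4)
    )
    return out


def write_results(
    draws: PosteriorDraws,
    summary,
    path: str | Path,
    extra_manifest: dict | None = None,
) -> Path:
    """Write posterior summary CSVs and a machine-readable run manifest.

    Emits ``prevalence.csv`` (posterior median pi per retained class),
    ``theta_summary.csv`` (long format: class, item, level, mean, median),
    ``modal_patterns.csv``, ``assignments.csv`` and ``manifest.json``.
    Floats are written with ``repr`` precision, so a write/read round trip
    reproduces the prevalence medians bit-exactly.
    """
    from .postprocess import ClassSummary  # local import to avoid a cycle

    if draws is None or draws.T == 0:
        raise ValueError("cannot write results for an empty draw set")
    if not isinstance(summary, ClassSummary):
        raise TypeError("summary must be a ClassSummary")
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)

    G = summary.n_classes
    pd.DataFrame(
        {"class": np.arange(1, G + 1), "prevalence_median": summary.prevalence}
    ).to_csv(out / "prevalence.csv", index=False, float_format="%.17g")

    p, d_max = summary.theta_mean.shape[0], summary.theta_mean.shape[1]
    rows = []
    for k in range(G):
        for j in range(p):
            for c in range(int(draws.level_counts[j])):
                rows.append(
                    (k + 1, j + 1, c + 1,
                     summary.theta_mean[j, c, k], summary.theta_median[j, c, k])
                )
    pd.DataFrame(
        rows, columns=["class", "item", "level", "theta_mean", "theta_median"]
    ).to_csv(out / "theta_summary.csv", index=False)

    pd.DataFrame(
        summary.modal_pattern,
        columns=[f"item_{j + 1}" for j in range(p)],
        index=pd.Index(np.arange(1, G + 1), name="class"),
    ).to_csv(out / "modal_patterns.csv")

    pd.DataFrame(
        {"subject": np.arange(1, draws.n + 1), "class": summary.assignments}
    ).to_csv(out / "assignments.csv", index=False)

    manifest = {
        "config": draws.config.to_dict(),
        "seed": draws.config.seed,
        "kappa": draws.kappa,
        "n": int(draws.n),
        "p": int(len(draws.level_counts)),
        "K": int(draws.K),
        "T": int(draws.T),
        "n_classes": int(G),
        "level_counts": draws.level_counts.tolist(),
    }
    if extra_manifest:
        manifest.update(extra_manifest)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def read_prevalence(path: str | Path) -> np.ndarray:
    """Read back the posterior-median prevalence table written by
    :func:`write_results`."""
    df = pd.read_csv(Path(path) / "prevalence.csv", float_precision="round_trip")
    return df["prevalence_median"].to_numpy(dtype=np.float64)


def read_manifest(path: str | Path) -> dict:
    return json.loads((Path(path) / "manifest.json").read_text())
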