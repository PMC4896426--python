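"""Cross-validated canonical correlation between brain and behavior.

The brain side is typically a per-subject scalar (mean temporal flexibility
of a node set); the behavior side a small set of cognitive scores. CCA
finds weight vectors a, b maximizing corr(X a, Y b) on training subjects;
with a scalar brain measure this reduces to the least-squares regression of
the brain measure on the behavioral scores.

Prediction uses k-fold cross-validation: weights are fit on the training
folds (behavior and brain standardized with training statistics only, sign
fixed so the training correlation is nonnegative), applied to the held-out
fold, and all held-out composite pairs are pooled into one Spearman rank
correlation. Significance comes from a permutation test that shuffles the
brain measure across subjects and repeats the entire cross-validated
analysis (fold scheme regenerated per permutation); one-sided p with the +1
correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CcaResult", "cv_cca", "permutation_p"]


@dataclass(frozen=True)
class CcaResult:
    rho: float
    p: float | None
    fold_weights: list[dict]
    n_permutations: int
    seed: int

    def __post_init__(self) -> None:
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError("rho must be in [-1, 1]")
        if self.p is not None and not 0.0 < self.p <= 1.0:
            raise ValueError("p must be in (0, 1]")


def _as_matrix(v) -> np.ndarray:
    x = np.asarray(v, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    return x


def _spearman(a: np.ndarray, b: np.ndarray) -> float:
    """Spearman rho via average ranks (lean; ties handled)."""
    ra = pd.Series(a).rank().to_numpy()
    rb = pd.Series(b).rank().to_numpy()
    ra = ra - ra.mean()
    rb = rb - rb.mean()
    denom = np.sqrt((ra**2).sum() * (rb**2).sum())
    if denom == 0:
        return float("nan")
    return float((ra @ rb) / denom)


def _fit_cca(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """First canonical weight pair of standardized training blocks."""
    n = x.shape[0]
    sxx = x.T @ x / n
    syy = y.T @ y / n
    sxy = x.T @ y / n
    # regularization-free whitening via eigendecomposition (blocks are tiny)
    def inv_sqrt(s):
        vals, vecs = np.linalg.eigh(s)
        if vals.min() <= 1e-12:
            raise ValueError("singular covariance in CCA training block")
        return (vecs / np.sqrt(vals)) @ vecs.T

    kx, ky = inv_sqrt(sxx), inv_sqrt(syy)
    u, _, vt = np.linalg.svd(kx @ sxy @ ky)
    return kx @ u[:, 0], ky @ vt[0]


def _folds(n: int, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    order = rng.permutation(n)
    return [np.sort(part) for part in np.array_split(order, k)]


def _cv_rho(
    x: np.ndarray, y: np.ndarray, folds: list[np.ndarray], collect=None
) -> float:
    n = x.shape[0]
    pred_brain = np.empty(n)
    pred_behav = np.empty(n)
    for test in folds:
        train = np.setdiff1d(np.arange(n), test, assume_unique=True)
        xm, xs = x[train].mean(axis=0), x[train].std(axis=0)
        ym, ys = y[train].mean(axis=0), y[train].std(axis=0)
        if (xs == 0).any():
            raise ValueError("constant brain measure in a training fold")
        if (ys == 0).any():
            raise ValueError("constant behavioral measure in a training fold")
        xt = (x[train] - xm) / xs
        yt = (y[train] - ym) / ys
        if x.shape[1] == 1:
            # scalar brain: canonical behavior weights = OLS weights of x on Y
            a = np.ones(1)
            # lstsq: minimum-norm solution tolerates collinear measures
            b, *_ = np.linalg.lstsq(yt.T @ yt, yt.T @ xt[:, 0], rcond=None)
        else:
            a, b = _fit_cca(xt, yt)
        if (xt @ a) @ (yt @ b) < 0:
            b = -b  # fix sign: training correlation >= 0
        if collect is not None:
            collect.append({"brain_weights": a.copy(), "behavior_weights": b.copy()})
        pred_brain[test] = ((x[test] - xm) / xs) @ a
        pred_behav[test] = ((y[test] - ym) / ys) @ b
    return _spearman(pred_brain, pred_behav)


def cv_cca(
    brain,
    behavior: pd.DataFrame | np.ndarray,
    k: int = 4,
    seed: int = 0,
) -> CcaResult:
    """Cross-validated CCA prediction between a brain measure and behavior.

    Returns the pooled held-out Spearman rho (no p-value; see
    :func:`permutation_p`). Requires at least 2 subjects per fold.
    """
    x = _as_matrix(brain)
    y = np.asarray(behavior, dtype=float)
    n = x.shape[0]
    if y.shape[0] != n:
        raise ValueError("brain and behavior subject counts differ")
    if n < 2 * k:
        raise ValueError(f"{n} subjects cannot fill {k} folds with >= 2 each")
    if np.ptp(x, axis=0).min() == 0:
        raise ValueError("constant brain measure")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(0,)))
    weights: list[dict] = []
    rho = _cv_rho(x, y, _folds(n, k, rng), collect=weights)
    return CcaResult(rho=rho, p=None, fold_weights=weights, n_permutations=0, seed=seed)


def permutation_p(
    brain,
    behavior: pd.DataFrame | np.ndarray,
    k: int = 4,
    n_perm: int = 10000,
    seed: int = 0,
) -> CcaResult:
    """Permutation inference for the cross-validated CCA prediction.

    The brain measure is shuffled across subjects ``n_perm`` times; the full
    cross-validated analysis (fresh fold scheme included) is repeated on
    each null dataset. One-sided p: (1 + #{null rho >= observed}) / (1 + n_perm).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    x = _as_matrix(brain)
    y = np.asarray(behavior, dtype=float)
    n = x.shape[0]
    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(0,)))
    weights: list[dict] = []
    observed = _cv_rho(x, y, _folds(n, k, rng), collect=weights)
    exceed = 0
    for _ in range(n_perm):
        xp = x[rng.permutation(n)]
        if _cv_rho(xp, y, _folds(n, k, rng)) >= observed:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return CcaResult(rho=observed, p=p, fold_weights=weights,
                     n_permutations=n_perm, seed=seed)
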