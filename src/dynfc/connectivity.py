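"""Static and time-varying (sliding-window) functional connectivity.

Time-varying connectivity uses a sliding window advancing by
``step_frames`` with exponentially decaying weights inside the window,

    w_t = w_0 * exp((t - T) / theta),  t = 1..T,
    w_0 = (1 - exp(-1/theta)) / (1 - exp(-T/theta)),

so recent frames dominate and the weights sum to one. ``theta`` defaults to
a third of the window length. Within each window all node pairs get the
weighted Pearson correlation

    r_w = sum_t w_t (x_t - xbar)(y_t - ybar)
          / sqrt(sum_t w_t (x_t - xbar)^2 * sum_t w_t (y_t - ybar)^2),

with weighted means ``xbar = sum_t w_t x_t`` (weights normalized). All
correlation matrices are Fisher z-transformed (arctanh, |r| clipped just
below 1) before averaging or community detection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import SignalSet

__all__ = [
    "WindowSpec",
    "exp_weights",
    "weighted_pearson",
    "weighted_correlation_matrix",
    "sliding_connectivity",
    "static_connectivity",
    "fisher_z",
]

_CLIP = 1.0 - 1e-7


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry.

    ``length_s`` is the window length in seconds (frames = round(length_s/dt),
    40 s at TR 0.72 s gives 56 frames); ``step_frames`` the gap between
    window starts; ``theta_fraction`` the exponential decay constant as a
    fraction of the window length (theta = T * theta_fraction, default 1/3).
    """

    length_s: float = 40.0
    step_frames: int = 1
    theta_fraction: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        if self.length_s <= 0 or self.step_frames < 1 or self.theta_fraction <= 0:
            raise ValueError("invalid window spec")

    def length_frames(self, dt: float) -> int:
        T = int(round(self.length_s / dt))
        if T < 3:
            raise ValueError(f"window of {self.length_s} s is under 3 frames at dt={dt}")
        return T

    def theta_frames(self, dt: float) -> float:
        return self.length_frames(dt) * self.theta_fraction


def exp_weights(T: int, theta: float) -> np.ndarray:
    """Exponentially decaying window weights w_1..w_T (sum exactly 1)."""
    if T < 2:
        raise ValueError("window must span at least 2 frames")
    if theta <= 0:
        raise ValueError("theta must be positive")
    t = np.arange(1, T + 1, dtype=float)
    w0 = -np.expm1(-1.0 / theta) / -np.expm1(-T / theta)
    w = w0 * np.exp((t - T) / theta)
    return w / w.sum()  # analytic sum is 1; renormalize to kill rounding


def weighted_pearson(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    """Weighted Pearson correlation of two series.

    Invariant to positive rescaling of ``w``. Returns NaN (flagged
    undefined, never silently 0) when either series has zero weighted
    variance.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    w = np.asarray(w, float)
    if not (len(x) == len(y) == len(w)):
        raise ValueError("x, y, w must share length")
    if (w < 0).any() or w.sum() <= 0:
        raise ValueError("weights must be nonnegative with positive sum")
    w = w / w.sum()
    xc = x - w @ x
    yc = y - w @ y
    vx = w @ (xc * xc)
    vy = w @ (yc * yc)
    if vx <= 0 or vy <= 0 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float((w @ (xc * yc)) / np.sqrt(vx * vy))


def weighted_correlation_matrix(data: np.ndarray, w: np.ndarray) -> np.ndarray:
    """All-pairs weighted Pearson correlation of a (nodes, frames) block.

    Rows with zero weighted variance yield NaN rows/columns (flagged, not 0).
    """
    w = np.asarray(w, float)
    w = w / w.sum()
    centered = data - (data @ w)[:, None]
    cov = (centered * w) @ centered.T
    var = np.diag(cov).copy()
    bad = (var <= 0) | (np.ptp(data, axis=1) == 0)
    var[bad] = np.nan
    denom = np.sqrt(np.outer(var, var))
    r = cov / denom
    np.fill_diagonal(r, 1.0)
    return r


def fisher_z(r: np.ndarray) -> np.ndarray:
    """Fisher z-transform with |r| clipped at 1 - 1e-7 to keep z finite."""
    return np.arctanh(np.clip(r, -_CLIP, _CLIP))


def n_windows(n_frames: int, length_frames: int, step_frames: int) -> int:
    if n_frames < length_frames:
        raise ValueError(f"{n_frames} frames cannot hold a {length_frames}-frame window")
    return (n_frames - length_frames) // step_frames + 1


def sliding_connectivity(s: SignalSet, spec: WindowSpec = WindowSpec()) -> list[np.ndarray]:
    """Per-subject stacks of windowed Fisher-z connectivity matrices.

    Returns one ``(n_windows, n_nodes, n_nodes)`` array per subject. Window
    ``t`` covers frames ``[t*step, t*step + T)`` (half-open).
    """
    T = spec.length_frames(s.dt)
    theta = spec.theta_frames(s.dt)
    w = exp_weights(T, theta)
    nw = n_windows(s.n_frames, T, spec.step_frames)
    out = []
    for mat in s.data:
        stack = np.empty((nw, s.n_nodes, s.n_nodes))
        for t in range(nw):
            start = t * spec.step_frames
            r = weighted_correlation_matrix(mat[:, start:start + T], w)
            stack[t] = fisher_z(r)
        out.append(stack)
    return out


def static_connectivity(s: SignalSet) -> np.ndarray:
    """Group-averaged static connectivity.

    Per subject: full-series Pearson correlation, Fisher z-transform; then
    the element-wise mean across subjects.
    """
    if s.n_subjects < 1:
        raise ValueError("need at least one subject")
    acc = np.zeros((s.n_nodes, s.n_nodes))
    for mat in s.data:
        acc += fisher_z(np.corrcoef(mat))
    return acc / s.n_subjects
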