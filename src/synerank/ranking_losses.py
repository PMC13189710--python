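"""Listwise and pairwise ranking losses, MSE, and the hybrid objective.

The listwise loss scores an entire response list at once. For a list with
true synergy values S = (s_1..s_n) and predictions O = (o_1..o_n) it builds
the pairwise difference matrix P_ij = s_i - s_j, masks the truly-higher
pairs M_ij = [P_ij > 0], and charges each item i a soft penalty for every
truly-lower item j whose prediction competes with o_i:

    T_i = sum_j M_ij * exp(o_j)
    L_i = ln(1 + T_i / exp(o_i))
    loss = sum_i L_i * G_i / (n - 1)

where G_i is a DCG-style gain of the (within-list min-max normalised) true
value. High-value items therefore dominate the objective: misranking the
most synergistic dose combination costs far more than misranking a weak
one. The implementation is loop-free over pairs and shift-stabilised so
that predictions up to ~1e3 in magnitude cannot overflow; it matches a
naive double loop to ~1e-9 relative.

Single-item lists (n = 1, e.g. a lone monotherapy measurement) carry no
ordering information and contribute zero ranking loss; they still train
the regression term of the hybrid objective.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._nn import Tensor, as_tensor

__all__ = [
    "ListScores",
    "LossBreakdown",
    "normalize_minmax",
    "gain",
    "urank_loss",
    "urank_loss_t",
    "pairwise_ranking_loss",
    "pairwise_ranking_loss_t",
    "mse_loss_t",
    "hybrid_loss",
    "hybrid_loss_t",
]


@dataclass(frozen=True)
class ListScores:
    """True and predicted scores for one response list."""

    s: np.ndarray
    o: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "s", np.asarray(self.s, dtype=float))
        object.__setattr__(self, "o", np.asarray(self.o, dtype=float))
        if self.s.shape != self.o.shape or self.s.ndim != 1 or self.s.size < 1:
            raise ValueError("S and O must be 1-D, same length, n >= 1")
        if not (np.all(np.isfinite(self.s)) and np.all(np.isfinite(self.o))):
            raise ValueError("scores must be finite")

    @property
    def n(self) -> int:
        return self.s.size


@dataclass(frozen=True)
class LossBreakdown:
    mse: float
    urank: float
    total: float
    lambda_rank: float


def normalize_minmax(s: np.ndarray) -> np.ndarray:
    """Min-max scale to [0, 1]; an all-tied list maps to all zeros."""
    s = np.asarray(s, dtype=float)
    lo, hi = s.min(), s.max()
    if hi == lo:
        return np.zeros_like(s)
    return (s - lo) / (hi - lo)


def gain(s: np.ndarray, gain_mode: str = "exp") -> np.ndarray:
    """Gain of the normalised true values: 2^s - 1 (exp) or 2s - 1 (linear)."""
    s = np.asarray(s, dtype=float)
    if gain_mode == "exp":
        return np.exp2(s) - 1.0
    if gain_mode == "linear":
        return 2.0 * s - 1.0
    raise ValueError(f"unknown gain_mode {gain_mode!r}")


def _mask(s: np.ndarray, tie_tol: float) -> np.ndarray:
    p = s[:, None] - s[None, :]
    m = (p > 0).astype(float)
    if tie_tol > 0:
        m[np.abs(p) <= tie_tol] = 0.0
    return m


def urank_loss_t(
    s: np.ndarray,
    o: Tensor,
    gain_mode: str = "exp",
    tie_tol: float = 0.0,
) -> Tensor:
    """Differentiable listwise loss for one list (autodiff Tensor path).

    L_i = ln(1 + T_i/exp(o_i)) is computed as a per-row log-sum-exp over
    the implicit zero term and the masked differences o_j - o_i, with a
    per-row constant shift, so no exponential ever overflows even for
    prediction magnitudes in the hundreds.
    """
    s = np.asarray(s, dtype=float)
    n = s.size
    if n == 1:
        return Tensor(0.0)
    m = _mask(s, tie_tol)
    g = gain(normalize_minmax(s), gain_mode)
    diff = o.reshape(1, n) + (-o.reshape(n, 1))  # diff_ij = o_j - o_i
    diff_data = o.data[None, :] - o.data[:, None]
    with np.errstate(invalid="ignore"):
        row_max = np.where(m, diff_data, -np.inf).max(axis=1, keepdims=True)
    shift = np.maximum(row_max, 0.0)  # include the implicit ln(1 + ...) zero term
    # push unmasked entries far negative so exp() underflows to exactly 0
    offset = np.where(m == 1.0, -shift, -1e9)
    terms = (diff + Tensor(offset)).exp() * Tensor(m)
    # exp(-c) + sum = 1 + (expm1(-c) + sum): log1p keeps precision for tiny losses
    li = (Tensor(np.expm1(-shift[:, 0])) + terms.sum(axis=1)).log1p() + Tensor(shift[:, 0])
    return (li * Tensor(g)).sum() / float(n - 1)


def urank_loss(scores: ListScores, gain_mode: str = "exp", tie_tol: float = 0.0) -> float:
    """Listwise loss value for one list (vectorised, loop-free over pairs)."""
    return urank_loss_t(scores.s, as_tensor(scores.o), gain_mode, tie_tol).item()


def pairwise_ranking_loss_t(s: np.ndarray, o: Tensor, tie_tol: float = 0.0) -> Tensor:
    """Logistic pairwise loss: mean over truly-ordered pairs of softplus(-(o_i - o_j))."""
    s = np.asarray(s, dtype=float)
    m = _mask(s, tie_tol)
    ii, jj = np.nonzero(m)
    if ii.size == 0:
        return Tensor(0.0)
    diff = o.take(ii) - o.take(jj)
    # softplus(-d) = relu(-d) + log(1 + exp(-|d|)), stable for |d| large
    x = -diff
    sp = x.relu() + (Tensor(1.0) + (-x.abs()).exp()).log()
    return sp.mean()


def pairwise_ranking_loss(scores: ListScores, tie_tol: float = 0.0) -> float:
    return pairwise_ranking_loss_t(scores.s, as_tensor(scores.o), tie_tol).item()


def mse_loss_t(s: np.ndarray, o: Tensor) -> Tensor:
    d = o - Tensor(np.asarray(s, dtype=float))
    return (d * d).mean()


def hybrid_loss_t(
    s: np.ndarray,
    o: Tensor,
    lambda_rank: float = 1.0,
    gain_mode: str = "exp",
    tie_tol: float = 0.0,
) -> tuple[Tensor, LossBreakdown]:
    """MSE + lambda * listwise loss for one list; returns (total, breakdown)."""
    if lambda_rank < 0:
        raise ValueError("lambda_rank must be non-negative")
    mse = mse_loss_t(s, o)
    ur = urank_loss_t(s, o, gain_mode, tie_tol)
    total = mse + Tensor(float(lambda_rank)) * ur
    return total, LossBreakdown(
        mse=mse.item(), urank=ur.item(), total=total.item(), lambda_rank=lambda_rank
    )


def hybrid_loss(
    scores: ListScores,
    lambda_rank: float = 1.0,
    gain_mode: str = "exp",
    tie_tol: float = 0.0,
) -> LossBreakdown:
    _, breakdown = hybrid_loss_t(scores.s, as_tensor(scores.o), lambda_rank, gain_mode, tie_tol)
    return breakdown
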