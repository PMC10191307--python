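"""Class-imbalance-weighted training objectives.

Two weightings of the categorical cross-entropy are provided. Inverse-
frequency (IF) weighting scales each true class's log-likelihood term by
w^k proportional to 1/f_k:

    J_IF = -(1/M) sum_m sum_k w^k y_m^k log h^k(x_m)

Real-world (RW) weighting additionally charges for false positives: with
w_fn^k the marginal cost of missing class k and w_fp^{kl} the marginal
cost of predicting class l when the truth is k,

    J_RW = -(1/M) sum_m [ sum_k w_fn^k y_m^k log h^k(x_m)
                          + sum_k sum_{l != k} w_fp^{kl} y_m^k log(1 - h^l(x_m)) ]

The false-positive matrix is populated from the square root of the paired
inverse stage frequencies, with a zero diagonal. Both weight constructions
are mean-normalized (mean weight 1) so loss magnitudes stay comparable
across schemes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import Tensor, as_tensor

PROB_EPS = 1e-7  # clamp floor for log arguments


@dataclass
class IFWeights:
    w: np.ndarray  # per-class, > 0

    def __post_init__(self):
        self.w = np.asarray(self.w, dtype=np.float64)
        if np.any(self.w <= 0):
            raise ValueError("IF weights must be positive")


@dataclass
class RWWeights:
    w_fn: np.ndarray  # (K,)  false-negative cost per true class
    w_fp: np.ndarray  # (K,K) false-positive cost, zero diagonal

    def __post_init__(self):
        self.w_fn = np.asarray(self.w_fn, dtype=np.float64)
        self.w_fp = np.asarray(self.w_fp, dtype=np.float64)
        K = self.w_fn.size
        if self.w_fp.shape != (K, K):
            raise ValueError("w_fp must be K x K")
        if np.any(self.w_fn <= 0):
            raise ValueError("w_fn must be positive")
        if np.any(self.w_fp < 0) or np.any(np.diag(self.w_fp) != 0):
            raise ValueError("w_fp must be nonnegative with a zero diagonal")


def if_weights(class_counts: np.ndarray) -> IFWeights:
    """Inverse-frequency class weights, mean-normalized to 1."""
    counts = np.asarray(class_counts, dtype=np.float64)
    if np.any(counts <= 0):
        raise ValueError(
            "every class needs at least one training epoch; collapse to a "
            "coarser scheme or drop the empty class before weighting")
    freq = counts / counts.sum()
    w = 1.0 / freq
    return IFWeights(w / w.mean())


def rw_weight_matrices(class_frequencies: np.ndarray) -> RWWeights:
    """RW false-negative vector and false-positive matrix from frequencies.

    w_fn^k = 1/f_k; w_fp^{kl} = sqrt((1/f_k)(1/f_l)) off the diagonal.
    Each is mean-normalized (the matrix over its off-diagonal entries).
    """
    f = np.asarray(class_frequencies, dtype=np.float64)
    if np.any(f <= 0):
        raise ValueError("class frequencies must all be positive")
    if not np.isclose(f.sum(), 1.0, atol=1e-6):
        raise ValueError("class frequencies must sum to 1")
    inv = 1.0 / f
    w_fn = inv / inv.mean()
    w_fp = np.sqrt(np.outer(inv, inv))
    np.fill_diagonal(w_fp, 0.0)
    off = ~np.eye(f.size, dtype=bool)
    w_fp = w_fp / w_fp[off].mean()
    return RWWeights(w_fn, w_fp)


def _prep(probs, targets):
    p = probs if isinstance(probs, Tensor) else as_tensor(probs)
    y = np.asarray(targets.data if isinstance(targets, Tensor) else targets,
                   dtype=np.float64)
    if p.data.shape != y.shape:
        raise ValueError(f"probs shape {p.data.shape} != targets shape {y.shape}")
    M = int(np.prod(y.shape[:-1]))  # every epoch of every window is one example
    return p, y, M


def loss_if(probs, targets, weights: IFWeights) -> Tensor:
    """IF-weighted cross-entropy; differentiable when fed Tensors."""
    p, y, M = _prep(probs, targets)
    if weights.w.size != y.shape[-1]:
        raise ValueError("weight vector length does not match class count")
    logp = p.clip(PROB_EPS, 1.0).log()
    return -(logp * (y * weights.w)).sum() * (1.0 / M)


def loss_rw(probs, targets, weights: RWWeights) -> Tensor:
    """RW-weighted cross-entropy; differentiable when fed Tensors."""
    p, y, M = _prep(probs, targets)
    if weights.w_fn.size != y.shape[-1]:
        raise ValueError("weight sizes do not match class count")
    pc = p.clip(PROB_EPS, 1.0 - PROB_EPS)
    fn_term = (pc.log() * (y * weights.w_fn)).sum()
    # row of fp costs for each example's true class: y @ w_fp has zeros on
    # the true class itself (zero diagonal)
    fp_costs = y @ weights.w_fp
    fp_term = ((1.0 - pc).log() * fp_costs).sum()
    return -(fn_term + fp_term) * (1.0 / M)


def one_hot(codes: np.ndarray, K: int) -> np.ndarray:
    codes = np.asarray(codes, dtype=np.int64)
    out = np.zeros(codes.shape + (K,))
    np.put_along_axis(out, codes[..., None], 1.0, axis=-1)
    return out
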