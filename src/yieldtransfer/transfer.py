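"""Source-to-target knowledge transfer for the yield CNN.

Fine-tuning a model trained on a data-rich source region (the "source
model") on a small target region risks two failure modes: *catastrophic
forgetting* — the fine-tune erases the general spectral features the source
data paid for — and *negative transfer* — source features that do not apply
to the target actively hurt.  Three complementary controls are provided:

* **freezing** the first ``n`` convolutional layers, which keeps the most
  general feature extractors bit-for-bit fixed;
* **L2-SP**, an L2 penalty anchored at the source weights instead of zero,
  ``(α/2)·‖w_S − w_S0‖² + (β/2)·‖w_S̄‖²``, where the "constant" part
  ``w_S`` is the conv stack and the "new" part ``w_S̄`` is the freshly
  re-initialized dense head (which is thus plain-L2 regularized);
* **BSS** (batch spectral shrinkage), ``η · Σᵢ σ₋ᵢ²`` over the ``k``
  smallest singular values of the per-batch penultimate feature matrix
  ``F = [f₁ … f_b]``, suppressing the poorly transferable spectral
  components of the representation.

The pure penalty functions (:func:`l2_penalty`, :func:`l2sp_penalty`,
:func:`bss_penalty`) are the definitions; the ``*Term`` classes wire them
(with analytic gradients) into the training loop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import WeightSet, YieldCNN

__all__ = [
    "TransferConfig",
    "init_from_source",
    "freeze_layers",
    "l2_penalty",
    "l2sp_penalty",
    "bss_penalty",
    "composite_loss",
    "L2Term",
    "L2SPTerm",
    "BSSTerm",
    "build_loss_terms",
]


@dataclass
class TransferConfig:
    """Transfer strategy for one fine-tuning run.

    ``penalty`` selects the regularizer anchoring mode: ``"l2sp"`` anchors
    the conv stack at the source weights (α) and L2-regularizes the dense
    head (β); ``"l2"`` is a plain zero-anchored penalty of strength α on all
    trainable weights; ``"none"`` disables both.  ``eta``/``k`` control BSS
    (``eta = 0`` disables it).  Defaults are the tuned operating point of
    the full method: source init, 4 frozen layers, α=0.23, β=0.77, η=0.07,
    k=1.
    """

    n_frozen_layers: int = 4
    source_init: bool = True
    alpha: float = 0.23
    beta: float = 0.77
    eta: float = 0.07
    k: int = 1
    penalty: str = "l2sp"

    def __post_init__(self) -> None:
        if not 0 <= self.n_frozen_layers:
            raise ValueError("n_frozen_layers must be >= 0")
        if min(self.alpha, self.beta, self.eta) < 0:
            raise ValueError("penalty strengths must be >= 0")
        if self.k < 0:
            raise ValueError("k must be >= 0")
        if self.penalty not in ("none", "l2", "l2sp"):
            raise ValueError(f"unknown penalty mode {self.penalty!r}")


def init_from_source(
    target: WeightSet, source: WeightSet, reinit_dense: bool = True
) -> WeightSet:
    """Initialize a target weight set from a trained source model.

    The convolutional partitions (including batch-norm state) are copied from
    the source; the dense head keeps the target's fresh initialization when
    ``reinit_dense`` (the "newly added" part of L2-SP), else it is copied
    from the source as well.
    """
    out = target.copy()
    for name, arr in source:
        part = WeightSet.partition_of(name)
        if part == "dense" and reinit_dense:
            continue
        if name not in out.arrays:
            raise ValueError(f"source parameter {name!r} missing from target")
        if out.arrays[name].shape != arr.shape:
            raise ValueError(
                f"shape mismatch for {name!r}: source {arr.shape}, "
                f"target {out.arrays[name].shape}"
            )
        out.arrays[name] = arr.copy()
    return out


def freeze_layers(model: YieldCNN, n: int) -> YieldCNN:
    """Exclude the first ``n`` convolutional layers from all weight updates.

    Frozen layers (weights, biases, batch-norm parameters and running
    statistics) are bit-identical before and after any subsequent training.
    """
    if not 0 <= n <= len(model.blocks):
        raise ValueError(
            f"n must be in [0, {len(model.blocks)}], got {n}"
        )
    model.frozen_n = n
    return model


# -- pure penalty functions -------------------------------------------------


def l2_penalty(w: np.ndarray, alpha: float) -> float:
    """Weight decay: ``(α/2)·‖w‖₂²``."""
    w = np.asarray(w, dtype=np.float64).ravel()
    return 0.5 * alpha * float(w @ w)


def l2sp_penalty(
    wS: np.ndarray,
    wS0: np.ndarray,
    wSbar: np.ndarray,
    alpha: float,
    beta: float,
) -> float:
    """Starting-point regularization:
    ``(α/2)·‖w_S − w_S0‖₂² + (β/2)·‖w_S̄‖₂²``.
    """
    wS = np.asarray(wS, dtype=np.float64).ravel()
    wS0 = np.asarray(wS0, dtype=np.float64).ravel()
    if wS.shape != wS0.shape:
        raise ValueError(
            f"constant-part shapes differ: {wS.shape} vs {wS0.shape}"
        )
    d = wS - wS0
    return 0.5 * alpha * float(d @ d) + l2_penalty(wSbar, beta)


def bss_penalty(F: np.ndarray, eta: float, k: int = 1) -> float:
    """Batch spectral shrinkage: ``η · Σᵢ₌₁..k σ₋ᵢ²`` of ``F``.

    ``F`` is the ``[feature_dim x batch]`` penultimate feature matrix;
    ``σ₋ᵢ`` are its smallest singular values.
    """
    F = np.asarray(F, dtype=np.float64)
    if F.ndim != 2:
        raise ValueError("F must be a 2-D feature matrix")
    if not np.all(np.isfinite(F)):
        raise ValueError("F contains non-finite entries")
    if k > min(F.shape):
        raise ValueError(
            f"k={k} exceeds the rank dimension min{F.shape} of the batch"
        )
    if k == 0:
        return 0.0
    sv = np.linalg.svd(F, compute_uv=False)
    smallest = np.sort(sv)[:k]
    return eta * float(np.sum(smallest**2))


def composite_loss(mse: float, penalties) -> float:
    """Total training loss: MSE plus the sum of all penalty values."""
    return float(mse) + float(np.sum(list(penalties)))


# -- training-loop terms ----------------------------------------------------
#
# Each term is called per minibatch as term(model, h) and returns
# (value, weight_grads or None, h_grad or None); h is the [batch x dim]
# penultimate activation matrix of the current forward pass.


class L2Term:
    """Zero-anchored weight decay over all trainable W matrices and biases."""

    def __init__(self, alpha: float):
        self.alpha = alpha

    def __call__(self, model: YieldCNN, h: np.ndarray):
        if self.alpha == 0.0:
            return 0.0, None, None
        value = 0.0
        grads: dict[str, np.ndarray] = {}
        for name, p in model.trainable_params().items():
            if "bn_" in name:
                continue  # batch-norm affine params are not decayed
            value += l2_penalty(p, self.alpha)
            grads[name] = self.alpha * p
        return value, grads, None


class L2SPTerm:
    """L2-SP: conv stack anchored at the source, dense head at zero.

    Frozen conv layers contribute identically zero and are skipped; the
    dense head always takes the β (plain L2) term.
    """

    def __init__(self, source: WeightSet, alpha: float, beta: float):
        self.source = source
        self.alpha = alpha
        self.beta = beta

    def __call__(self, model: YieldCNN, h: np.ndarray):
        value = 0.0
        grads: dict[str, np.ndarray] = {}
        for name, p in model.trainable_params().items():
            if "bn_" in name:
                continue
            part = WeightSet.partition_of(name)
            if part == "dense":
                value += l2_penalty(p, self.beta)
                grads[name] = self.beta * p
            else:
                p0 = self.source[name]
                d = p - p0
                value += 0.5 * self.alpha * float(np.sum(d * d))
                grads[name] = self.alpha * d
        return value, grads, None


class BSSTerm:
    """Batch spectral shrinkage on the current batch's feature matrix.

    ``F = h.T`` (features x batch); the gradient of ``η·Σ σ₋ᵢ²`` with respect
    to ``F`` is ``2η·Σ σ₋ᵢ u₋ᵢ v₋ᵢᵀ`` from the SVD ``F = U Σ Vᵀ``.
    """

    def __init__(self, eta: float, k: int = 1):
        self.eta = eta
        self.k = k

    def __call__(self, model: YieldCNN, h: np.ndarray):
        if self.eta == 0.0 or self.k == 0:
            return 0.0, None, None
        F = h.T
        k = min(self.k, min(F.shape))
        U, sv, Vt = np.linalg.svd(F, full_matrices=False)
        order = np.argsort(sv)[:k]
        value = self.eta * float(np.sum(sv[order] ** 2))
        gF = 2.0 * self.eta * (U[:, order] * sv[order]) @ Vt[order, :]
        return value, None, gF.T


def build_loss_terms(
    tc: TransferConfig, source_weights: WeightSet | None
) -> list:
    """Assemble the training penalty terms a TransferConfig prescribes."""
    terms: list = []
    if tc.penalty == "l2sp":
        if source_weights is None:
            raise ValueError("L2-SP requires source weights as the anchor")
        terms.append(L2SPTerm(source_weights, tc.alpha, tc.beta))
    elif tc.penalty == "l2":
        terms.append(L2Term(tc.alpha))
    if tc.eta > 0 and tc.k > 0:
        terms.append(BSSTerm(tc.eta, tc.k))
    return terms
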