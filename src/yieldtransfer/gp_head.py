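"""Spatio-temporal Gaussian-process correction on top of the CNN.

Yield residuals are not independent: neighbouring counties share weather and
soil, and adjacent seasons share technology and management.  The correction
head models the target as

    y(x) = f(x) + h(x)ᵀ β,

where ``h(x)`` is the CNN's penultimate feature vector, ``β`` has a Gaussian
prior centred at the trained last-layer weights (variance ``σ_b I``), and
``f`` is a zero-mean GP over the county's spatio-temporal index
``g = (g_loc, g_year)`` with squared-exponential covariance

    k(g, g') = σ² exp(−‖g_loc−g'_loc‖²/(2 r_loc²) − (g_year−g'_year)²/(2 r_year²))
               + σ_e² δ(g, g').

This is GP regression with explicit basis functions: the posterior mean at a
test point is ``h(x*)ᵀ β̄ + k*ᵀ K⁻¹ (y − Hᵀ β̄)``, i.e. the CNN prediction
(with posterior-refined last layer) plus a kriging interpolation of the
training residuals.  As ``σ_b → 0`` the basis coefficients pin to the CNN's
last layer and the head reduces to standard GP regression on the CNN's
residuals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.linalg

__all__ = ["STIndex", "GPConfig", "st_kernel", "gp_fit_predict"]


@dataclass(frozen=True)
class STIndex:
    """Spatio-temporal key of one county-season: centroid coords + year."""

    g_loc: tuple[float, float]
    g_year: float

    def __post_init__(self) -> None:
        if len(self.g_loc) != 2 or not np.all(np.isfinite(self.g_loc)):
            raise ValueError("g_loc must be a finite 2-vector")
        if not np.isfinite(self.g_year):
            raise ValueError("g_year must be finite")


@dataclass
class GPConfig:
    """Kernel and prior hyperparameters.

    ``sigma`` — signal scale σ; ``sigma_e`` — Kronecker noise σ_e;
    ``r_loc`` — spatial correlation length (same units as the centroids,
    degrees by default); ``r_year`` — temporal correlation length in years;
    ``sigma_b`` — prior variance scale of the basis coefficients β.
    """

    sigma: float = 1.0
    sigma_e: float = 0.32
    r_loc: float = 0.5
    r_year: float = 1.5
    sigma_b: float = 0.01

    def __post_init__(self) -> None:
        for name in ("sigma", "sigma_e", "r_loc", "r_year", "sigma_b"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


def _index_arrays(indices: Sequence[STIndex]) -> tuple[np.ndarray, np.ndarray]:
    loc = np.array([idx.g_loc for idx in indices], dtype=np.float64)
    year = np.array([idx.g_year for idx in indices], dtype=np.float64)
    return loc, year


def _sqexp(
    loc1: np.ndarray, yr1: np.ndarray, loc2: np.ndarray, yr2: np.ndarray, cfg: GPConfig
) -> np.ndarray:
    d2 = ((loc1[:, None, :] - loc2[None, :, :]) ** 2).sum(axis=2)
    dy2 = (yr1[:, None] - yr2[None, :]) ** 2
    return cfg.sigma**2 * np.exp(
        -d2 / (2 * cfg.r_loc**2) - dy2 / (2 * cfg.r_year**2)
    )


def st_kernel(g: STIndex, g2: STIndex, config: GPConfig) -> float:
    """Covariance between two spatio-temporal indices (noise on identity)."""
    loc1, yr1 = _index_arrays([g])
    loc2, yr2 = _index_arrays([g2])
    k = float(_sqexp(loc1, yr1, loc2, yr2, config)[0, 0])
    if tuple(g.g_loc) == tuple(g2.g_loc) and g.g_year == g2.g_year:
        k += config.sigma_e**2
    return k


def _cholesky_with_jitter(K: np.ndarray) -> np.ndarray:
    jitter = 0.0
    for jitter in (0.0, 1e-8, 1e-6, 1e-4):
        try:
            return scipy.linalg.cholesky(
                K + jitter * np.eye(K.shape[0]), lower=True
            )
        except scipy.linalg.LinAlgError:
            continue
    raise np.linalg.LinAlgError(
        "training Gram matrix is not positive definite even after adding "
        f"jitter up to {jitter}; increase sigma_e or check for duplicate "
        "spatio-temporal indices"
    )


def gp_fit_predict(
    H_train: np.ndarray,
    y_train: np.ndarray,
    idx_train: Sequence[STIndex],
    H_test: np.ndarray,
    idx_test: Sequence[STIndex],
    w_last: np.ndarray,
    config: GPConfig,
    b_last: float = 0.0,
) -> np.ndarray:
    """Posterior-mean corrected predictions at the test points.

    ``H_train``/``H_test`` are the CNN penultimate feature matrices
    ``[n x d]``; ``w_last`` (+ ``b_last``) is the trained output layer, used
    as the prior mean of the basis coefficients.  Internally the basis is
    augmented with a constant column so the bias participates in the prior.
    """
    H_train = np.asarray(H_train, dtype=np.float64)
    H_test = np.asarray(H_test, dtype=np.float64)
    y_train = np.asarray(y_train, dtype=np.float64)
    w_last = np.asarray(w_last, dtype=np.float64).ravel()
    if H_train.ndim != 2 or H_train.shape[0] != y_train.shape[0]:
        raise ValueError("H_train must be [n x d] matching y_train")
    if H_train.shape[0] != len(idx_train) or H_test.shape[0] != len(idx_test):
        raise ValueError("one spatio-temporal index is required per data point")
    if H_train.shape[1] != w_last.size or H_test.shape[1] != w_last.size:
        raise ValueError("feature dimension does not match w_last")
    for name, arr in (("H_train", H_train), ("y_train", y_train),
                      ("H_test", H_test), ("w_last", w_last)):
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"{name} contains NaN or infinite entries")

    n, d = H_train.shape
    loc_tr, yr_tr = _index_arrays(idx_train)
    loc_te, yr_te = _index_arrays(idx_test)

    K = _sqexp(loc_tr, yr_tr, loc_tr, yr_tr, config)
    K[np.diag_indices_from(K)] += config.sigma_e**2
    Ks = _sqexp(loc_te, yr_te, loc_tr, yr_tr, config)  # [n_test x n]

    L = _cholesky_with_jitter(K)

    # explicit-basis GP: basis = [h(x), 1], prior mean b = [w_last, b_last],
    # prior covariance sigma_b * I
    Ht = np.hstack([H_train, np.ones((n, 1))])  # [n x (d+1)]
    He = np.hstack([H_test, np.ones((H_test.shape[0], 1))])
    b = np.append(w_last, b_last)

    Kinv_H = scipy.linalg.cho_solve((L, True), Ht)  # K^-1 H
    Kinv_y = scipy.linalg.cho_solve((L, True), y_train)
    A = np.eye(d + 1) / config.sigma_b + Ht.T @ Kinv_H
    rhs = Ht.T @ Kinv_y + b / config.sigma_b
    beta_bar = np.linalg.solve(A, rhs)

    resid = y_train - Ht @ beta_bar
    return He @ beta_bar + Ks @ scipy.linalg.cho_solve((L, True), resid)
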