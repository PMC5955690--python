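"""Spherical-spline surface Laplacian (current source density) transform.

Scalp potential sampled at electrodes on a unit sphere is interpolated with
spherical splines of order m (Perrin-style):

    g(x) = (1/4pi) sum_{n>=1} (2n+1) / (n(n+1))^m     * P_n(x)
    h(x) = (1/4pi) sum_{n>=1} (2n+1) / (n(n+1))^(m-1) * P_n(x)

with P_n the Legendre polynomials and x the cosine of the inter-electrode
angle. Spline coefficients c solve the regularized system

    (G + lambda I) c + c0 1 = v,   sum(c) = 0

and the surface Laplacian at electrode j is -sum_i c_i h(cos theta_ij)
(so that a low-order surface harmonic Y_n maps onto -n(n+1) Y_n, the
analytic Laplacian on the unit sphere). The output scale is arbitrary CSD
units on a unit-radius head; downstream power normalization cancels it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial import legendre as npleg

from .montage import Montage
from .preprocess import EpochSet

__all__ = ["SplineBasis", "build_basis", "csd_transform", "interpolate_potential"]


def _series_weights(n_terms: int, m: int) -> tuple[np.ndarray, np.ndarray]:
    n = np.arange(1, n_terms + 1, dtype=float)
    g_w = (2 * n + 1) / ((n * (n + 1)) ** m) / (4 * np.pi)
    h_w = (2 * n + 1) / ((n * (n + 1)) ** (m - 1)) / (4 * np.pi)
    return g_w, h_w


def spline_g(x: np.ndarray, order_m: int = 4, n_terms: int = 50) -> np.ndarray:
    """g(x) evaluated by stable Legendre recurrence (legval)."""
    g_w, _ = _series_weights(n_terms, order_m)
    return npleg.legval(np.asarray(x, float), np.concatenate(([0.0], g_w)))


def spline_h(x: np.ndarray, order_m: int = 4, n_terms: int = 50) -> np.ndarray:
    _, h_w = _series_weights(n_terms, order_m)
    return npleg.legval(np.asarray(x, float), np.concatenate(([0.0], h_w)))


@dataclass
class SplineBasis:
    """Precomputed spline matrices for one electrode set."""

    labels: list[str]
    positions: np.ndarray
    order_m: int
    n_terms: int
    lambda_reg: float
    G: np.ndarray
    H: np.ndarray
    _solve: np.ndarray = None  # (n+1, n) maps v -> (c, c0)

    @property
    def n(self) -> int:
        return len(self.labels)


def build_basis(
    montage: Montage,
    labels: list[str] | None = None,
    order_m: int = 4,
    n_terms: int = 50,
    lambda_reg: float = 1e-5,
) -> SplineBasis:
    """Build G/H matrices and the factored solve operator for a channel set."""
    if order_m < 2:
        raise ValueError("spline order must be >= 2")
    labels = list(labels) if labels is not None else list(montage.analysis_labels)
    if len(labels) < 3:
        raise ValueError("need at least 3 electrodes")
    pos = np.array([montage.position(l) for l in labels])
    cosang = np.clip(pos @ pos.T, -1.0, 1.0)
    if np.any(cosang[~np.eye(len(labels), dtype=bool)] > 1 - 1e-12):
        raise ValueError("duplicate electrode positions")
    G = spline_g(cosang, order_m, n_terms)
    H = spline_h(cosang, order_m, n_terms)

    n = len(labels)
    A = np.zeros((n + 1, n + 1))
    A[:n, :n] = G + lambda_reg * np.eye(n)
    A[:n, n] = 1.0
    A[n, :n] = 1.0
    cond = np.linalg.cond(A)
    if not np.isfinite(cond) or cond > 1e14:
        raise np.linalg.LinAlgError(
            f"singular spline system (lambda={lambda_reg:g}, cond~{cond:.2e})"
        )
    Ainv = np.linalg.inv(A)
    solve = Ainv[:, :n]  # maps [v; 0] -> [c; c0]
    return SplineBasis(labels, pos, order_m, n_terms, lambda_reg, G, H, solve)


def _laplacian_matrix(basis: SplineBasis) -> np.ndarray:
    C = basis._solve[: basis.n, :]  # v -> c
    return -(basis.H @ C)


def csd_transform(epochs: EpochSet, basis: SplineBasis) -> EpochSet:
    """Apply the surface-Laplacian operator to every trial and sample.

    The epoch channel set must match the basis channel set (any order).
    """
    if set(epochs.ch_names) != set(basis.labels):
        raise ValueError("basis was built for a different channel set")
    order = [epochs.ch_names.index(l) for l in basis.labels]
    L = _laplacian_matrix(basis).astype(epochs.data.dtype)
    out = epochs.copy()
    d = epochs.data[:, order, :]
    n_tr, n_ch, n_t = d.shape
    res = L @ d.transpose(1, 0, 2).reshape(n_ch, -1)
    out.data = res.reshape(n_ch, n_tr, n_t).transpose(1, 0, 2).astype(epochs.data.dtype)
    out.ch_names = list(basis.labels)
    return out


def csd_map(values: np.ndarray, basis: SplineBasis) -> np.ndarray:
    """Surface Laplacian of a single scalp map (n_electrodes,)."""
    return _laplacian_matrix(basis) @ np.asarray(values, float)


def interpolate_potential(
    basis: SplineBasis, values: np.ndarray, query_positions: np.ndarray
) -> np.ndarray:
    """Evaluate the spline potential surface at unit-norm query positions.

    At lambda=0 the surface reproduces the measured electrode values.
    """
    q = np.atleast_2d(np.asarray(query_positions, float))
    if not np.allclose(np.linalg.norm(q, axis=1), 1.0, atol=1e-6):
        raise ValueError("query positions must be unit-norm")
    coeff = basis._solve @ np.asarray(values, float)
    c, c0 = coeff[:-1], coeff[-1]
    gq = spline_g(np.clip(q @ basis.positions.T, -1, 1), basis.order_m, basis.n_terms)
    return c0 + gq @ c
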