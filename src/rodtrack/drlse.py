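"""Distance-regularized level-set evolution (DRLSE) core.

The contour of a cell is the zero level of a scalar field ``phi`` (interior
``phi < 0``).  The energy being minimized is

    E(phi) = mu * R_p(phi) + lam * L_g(phi) + alpha * A_g(phi)

with R_p the double-well distance-regularization term, L_g the g-weighted
contour length and A_g the g-weighted interior area.  Evolution follows the
gradient flow

    d(phi)/dt = mu * div(d_p(|grad phi|) grad phi)
              + lam * delta(phi) * div(g * grad phi / |grad phi|)
              + alpha * g * delta(phi)

with smoothed Dirac/Heaviside of half-width ``eps`` and halts when the summed
squared change of the three energy terms between successive iterations drops
to the tolerance ``K``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .config import DrlseParams

_GRAD_FLOOR = 1e-10


class NumericalError(RuntimeError):
    """Non-finite field encountered during evolution."""


@dataclass
class LevelSetState:
    phi: np.ndarray
    label: int = 0


@dataclass
class EnergyTerms:
    Rp: float
    Lg: float
    Ag: float


def smooth(image: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian smoothing; ``sigma == 0`` returns the input unchanged."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    image = np.asarray(image, dtype=float)
    if sigma == 0:
        return image
    return ndimage.gaussian_filter(image, sigma, mode="nearest")


def edge_indicator(image: np.ndarray, sigma: float) -> np.ndarray:
    """g = 1 / (1 + |grad(G_sigma * I)|^2); in (0, 1], small at strong edges."""
    smoothed = smooth(image, sigma)
    gy, gx = np.gradient(smoothed)
    return 1.0 / (1.0 + gy**2 + gx**2)


def double_well_p(s):
    """Double-well potential with minima at s = 0 and s = 1."""
    s = np.asarray(s, dtype=float)
    if np.any(s < 0):
        raise ValueError("double_well_p is defined for s >= 0")
    inner = (1.0 / (2.0 * np.pi) ** 2) * (1.0 - np.cos(2.0 * np.pi * s))
    outer = 0.5 * (s - 1.0) ** 2
    out = np.where(s <= 1.0, inner, outer)
    return float(out) if out.ndim == 0 else out


def d_p(s):
    """d_p(s) = p'(s)/s with the removable singularity at 0 filled by 1."""
    s = np.asarray(s, dtype=float)
    if np.any(s < 0):
        raise ValueError("d_p is defined for s >= 0")
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        inner = np.sin(2.0 * np.pi * s) / (2.0 * np.pi * s)
        outer = (s - 1.0) / s
    out = np.where(s <= 1.0, inner, outer)
    out = np.where(s == 0, 1.0, out)
    return float(out) if out.ndim == 0 else out


def dirac_eps(x: np.ndarray, eps: float) -> np.ndarray:
    """Smoothed Dirac delta of half-width eps (cosine bump, unit mass)."""
    out = np.zeros_like(np.asarray(x, dtype=float))
    inside = np.abs(x) <= eps
    out[inside] = (1.0 / (2.0 * eps)) * (1.0 + np.cos(np.pi * x[inside] / eps))
    return out


def heaviside_eps(x: np.ndarray, eps: float) -> np.ndarray:
    """Smoothed Heaviside step, the integral of :func:`dirac_eps`."""
    x = np.asarray(x, dtype=float)
    out = np.where(x > eps, 1.0, 0.0)
    inside = np.abs(x) <= eps
    xi = x[inside]
    out[inside] = 0.5 * (1.0 + xi / eps + np.sin(np.pi * xi / eps) / np.pi)
    return out


def _neumann(phi: np.ndarray) -> np.ndarray:
    """Mirror the second interior row/column onto the border."""
    phi = phi.copy()
    phi[0, :] = phi[2, :]
    phi[-1, :] = phi[-3, :]
    phi[:, 0] = phi[:, 2]
    phi[:, -1] = phi[:, -3]
    phi[0, 0], phi[0, -1] = phi[2, 2], phi[2, -3]
    phi[-1, 0], phi[-1, -1] = phi[-3, 2], phi[-3, -3]
    return phi


def _divergence(fy: np.ndarray, fx: np.ndarray) -> np.ndarray:
    dfy, _ = np.gradient(fy)
    _, dfx = np.gradient(fx)
    return dfy + dfx


def energy_terms(state: LevelSetState, g: np.ndarray, eps: float) -> EnergyTerms:
    """The three unweighted energy integrals (R_p, L_g, A_g) of the field."""
    phi = np.asarray(state.phi, dtype=float)
    g = np.asarray(g, dtype=float)
    if phi.shape != g.shape:
        raise ValueError(f"shape mismatch: phi {phi.shape} vs g {g.shape}")
    py, px = np.gradient(phi)
    mag = np.sqrt(py**2 + px**2)
    delta = dirac_eps(phi, eps)
    rp = float(np.sum(double_well_p(mag)))
    lg = float(np.sum(g * delta * mag))
    ag = float(np.sum(g * heaviside_eps(-phi, eps)))
    return EnergyTerms(rp, lg, ag)


def stopping_delta(prev: EnergyTerms, cur: EnergyTerms) -> float:
    """Summed squared change of the three energy terms between iterations."""
    return (
        (cur.Rp - prev.Rp) ** 2
        + (cur.Lg - prev.Lg) ** 2
        + (cur.Ag - prev.Ag) ** 2
    )


def binary_initial_phi(seed_mask: np.ndarray, c0: float = 2.0) -> np.ndarray:
    """Binary-step initialization: -c0 inside the seed, +c0 outside."""
    return np.where(seed_mask, -c0, c0).astype(float)


def evolve(
    state: LevelSetState,
    g: np.ndarray,
    params: DrlseParams,
    freeze_mask: np.ndarray | None = None,
) -> tuple[LevelSetState, int]:
    """Run the gradient flow until the stopping tolerance or ``max_iter``.

    Pixels under ``freeze_mask`` keep their phi value throughout — the
    contract used for non-overlapping coevolution of neighbouring cells.
    Returns the evolved state and the number of iterations used.
    """
    phi = np.asarray(state.phi, dtype=float).copy()
    g = np.asarray(g, dtype=float)
    if phi.shape != g.shape:
        raise ValueError(f"shape mismatch: phi {phi.shape} vs g {g.shape}")
    if freeze_mask is not None and freeze_mask.shape != phi.shape:
        raise ValueError("freeze_mask shape mismatch")

    gy, gx = np.gradient(g)
    prev = energy_terms(LevelSetState(phi, state.label), g, params.eps)
    iters = 0
    for i in range(params.max_iter):
        phi = _neumann(phi)
        py, px = np.gradient(phi)
        mag = np.sqrt(py**2 + px**2)

        # distance regularization: div(d_p(|grad phi|) grad phi)
        dp = d_p(mag)
        reg = _divergence(dp * py, dp * px)

        # edge/length term: delta(phi) * div(g * grad phi / |grad phi|)
        safe = np.maximum(mag, _GRAD_FLOOR)
        ny, nx = py / safe, px / safe
        delta = dirac_eps(phi, params.eps)
        curvature = _divergence(ny, nx)
        edge = delta * (gy * ny + gx * nx + g * curvature)

        area = g * delta

        update = params.mu * reg + params.lam * edge + params.alpha * area
        if freeze_mask is not None:
            update = np.where(freeze_mask, 0.0, update)
        phi = phi + params.dt * update
        iters = i + 1

        if not np.all(np.isfinite(phi)):
            raise NumericalError(f"non-finite level-set field at iteration {iters}")

        cur = energy_terms(LevelSetState(phi, state.label), g, params.eps)
        if stopping_delta(prev, cur) <= params.K:
            break
        prev = cur

    return LevelSetState(phi, state.label), iters
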