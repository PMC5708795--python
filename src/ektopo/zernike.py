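"""Normalized Zernike polynomials and corneal aberration summary metrics.

The polynomials follow the OSA/ANSI convention: single index
``j = (n(n+2) + m) / 2`` over radial orders ``n = 0..8`` (45 terms), with
RMS (unit-variance over the unit disk) normalization, so the root sum of
squares of a coefficient vector equals the wavefront RMS in the same units.
Aberration summaries are the ones standard in corneal topography:

* HOA — RMS of all coefficients of radial order 3 through 8,
* SA  — RMS of Z(4,0) and Z(6,0) (primary and secondary spherical aberration),
* Coma — RMS of Z(3,-1) and Z(3,1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover - type-only import
    from .wavefront import OPDMap

MAX_ORDER = 8
N_TERMS = (MAX_ORDER + 1) * (MAX_ORDER + 2) // 2  # 45

__all__ = [
    "MAX_ORDER",
    "N_TERMS",
    "ZernikeIndex",
    "ZernikeCoefficients",
    "single_index_to_nm",
    "nm_to_single_index",
    "zernike_value",
    "zernike_basis",
    "fit_coefficients",
    "synthesize",
    "hoa_rms",
    "sa_rms",
    "coma_rms",
]


class InsufficientSamplesError(ValueError):
    """Raised when a pupil holds too few valid samples for a stable fit."""


@dataclass(frozen=True)
class ZernikeIndex:
    """Single-index / (radial order, azimuthal frequency) pair."""

    j: int
    n: int
    m: int

    def __post_init__(self) -> None:
        if self.j < 0 or self.n < 0:
            raise ValueError("j and n must be non-negative")
        if abs(self.m) > self.n or (self.n - abs(self.m)) % 2 != 0:
            raise ValueError(f"invalid (n, m) = ({self.n}, {self.m})")
        if 2 * self.j != self.n * (self.n + 2) + self.m:
            raise ValueError(
                f"j={self.j} inconsistent with (n, m)=({self.n}, {self.m})"
            )


def single_index_to_nm(j: int) -> ZernikeIndex:
    """Map the OSA single index ``j`` to ``(n, m)``.

    ``n = ceil((-3 + sqrt(9 + 8 j)) / 2)`` and ``m = 2 j - n (n + 2)``.
    """
    j = int(j)
    if j < 0:
        raise ValueError("j must be non-negative")
    n = math.ceil((-3.0 + math.sqrt(9.0 + 8.0 * j)) / 2.0)
    m = 2 * j - n * (n + 2)
    return ZernikeIndex(j=j, n=n, m=m)


def nm_to_single_index(n: int, m: int) -> int:
    """Map ``(n, m)`` to the OSA single index ``j = (n(n+2)+m)/2``."""
    n, m = int(n), int(m)
    if n < 0 or abs(m) > n or (n - abs(m)) % 2 != 0:
        raise ValueError(f"invalid (n, m) = ({n}, {m})")
    return (n * (n + 2) + m) // 2


def _radial(n: int, m: int, rho: np.ndarray) -> np.ndarray:
    """Radial polynomial R_n^|m|; accepts any rho >= 0."""
    am = abs(m)
    out = np.zeros_like(rho, dtype=float)
    for k in range((n - am) // 2 + 1):
        c = (
            (-1) ** k
            * math.factorial(n - k)
            / (
                math.factorial(k)
                * math.factorial((n + am) // 2 - k)
                * math.factorial((n - am) // 2 - k)
            )
        )
        out += c * rho ** (n - 2 * k)
    return out


def _norm(n: int, m: int) -> float:
    return math.sqrt(n + 1.0) if m == 0 else math.sqrt(2.0 * (n + 1.0))


def _value_unchecked(n: int, m: int, rho: np.ndarray, theta: np.ndarray) -> np.ndarray:
    r = _radial(n, m, rho) * _norm(n, m)
    if m > 0:
        return r * np.cos(m * theta)
    if m < 0:
        return r * np.sin(-m * theta)
    return r


def zernike_value(idx: ZernikeIndex, rho, theta):
    """Evaluate the RMS-normalized Zernike polynomial Z_n^m(rho, theta).

    ``rho`` must lie in [0, 1]; values outside the unit disk are an error
    (the expansion is not extrapolated).
    """
    rho = np.asarray(rho, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if np.any((rho < 0.0) | (rho > 1.0)):
        raise ValueError("rho must lie in [0, 1]")
    return _value_unchecked(idx.n, idx.m, rho, theta)


def zernike_basis(rho: np.ndarray, theta: np.ndarray, max_order: int = MAX_ORDER) -> np.ndarray:
    """Stack of all polynomials through ``max_order``: shape (n_terms, *rho.shape).

    Internal helper: does not restrict rho to the unit disk, so callers can
    evaluate the polynomial continuation outside it (used when synthesizing
    surface perturbations across a full Cartesian map).
    """
    n_terms = (max_order + 1) * (max_order + 2) // 2
    rho = np.asarray(rho, dtype=float)
    theta = np.asarray(theta, dtype=float)
    out = np.empty((n_terms,) + rho.shape, dtype=float)
    for j in range(n_terms):
        idx = single_index_to_nm(j)
        out[j] = _value_unchecked(idx.n, idx.m, rho, theta)
    return out


def gram_matrix(n_samples: int = 512, max_order: int = MAX_ORDER) -> np.ndarray:
    """Numerical Gram matrix of the basis over the unit disk.

    Cartesian pixel-center sampling at ``n_samples`` per axis; pixels cut
    by the rim are weighted by their fractional coverage (16x16
    subsampling) so the quadrature converges at the boundary. Orthonormal
    basis => identity within grid tolerance; exposed as a self-check.
    """
    h = 2.0 / n_samples
    ax = (np.arange(n_samples) + 0.5) * h - 1.0
    xx, yy = np.meshgrid(ax, ax)
    rr = np.hypot(xx, yy)
    inner = rr <= 1.0 - h
    boundary = (rr > 1.0 - h) & (rr < 1.0 + h)
    sub = (np.arange(16) + 0.5) / 16 - 0.5
    sx, sy = np.meshgrid(sub, sub)
    bx = xx[boundary][:, None] + sx.ravel()[None, :] * h
    by = yy[boundary][:, None] + sy.ravel()[None, :] * h
    frac = (np.hypot(bx, by) <= 1.0).mean(axis=1)
    rho = np.concatenate([rr[inner], np.clip(rr[boundary], 0.0, 1.0)])
    theta = np.concatenate(
        [np.arctan2(yy[inner], xx[inner]), np.arctan2(yy[boundary], xx[boundary])]
    )
    weights = np.concatenate([np.ones(int(inner.sum())), frac])
    basis = zernike_basis(rho, theta, max_order)
    return (basis * weights) @ basis.T / weights.sum()


@dataclass
class ZernikeCoefficients:
    """Zernike expansion of an OPD map over a circular pupil.

    Coefficients are in µm, indexed by the OSA single index j = 0..44.
    """

    pupil_diameter: float
    surface_label: str
    coeffs: np.ndarray
    fit_rms_residual: float = 0.0

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.coeffs.shape != (N_TERMS,):
            raise ValueError(f"expected {N_TERMS} coefficients, got {self.coeffs.shape}")
        if not np.all(np.isfinite(self.coeffs)):
            raise ValueError("coefficients must be finite")
        if self.pupil_diameter <= 0:
            raise ValueError("pupil_diameter must be positive")

    def coeff(self, n: int, m: int) -> float:
        return float(self.coeffs[nm_to_single_index(n, m)])


# Cache of fit operators keyed by grid/pupil geometry. One study re-uses a
# single grid for every eye, so the pseudo-inverse is built once.
_FIT_CACHE: dict[tuple, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}


def _fit_operator(
    grid_spacing: float,
    half_width: float,
    n_samples: int,
    pupil_diameter: float,
    max_order: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    key = (round(grid_spacing, 9), round(half_width, 9), n_samples, round(pupil_diameter, 9), max_order)
    if key not in _FIT_CACHE:
        ax = np.linspace(-half_width, half_width, n_samples)
        xx, yy = np.meshgrid(ax, ax)
        rr = np.hypot(xx, yy)
        in_pupil = rr <= pupil_diameter / 2.0 + 1e-12
        rho = rr[in_pupil] / (pupil_diameter / 2.0)
        theta = np.arctan2(yy[in_pupil], xx[in_pupil])
        basis = zernike_basis(np.clip(rho, 0.0, 1.0), theta, max_order)  # (J, Np)
        pinv = np.linalg.pinv(basis.T)  # (J, Np); OLS solve for full-pupil maps
        _FIT_CACHE[key] = (in_pupil, basis, pinv)
    return _FIT_CACHE[key]


def fit_coefficients(opd: "OPDMap", pupil_diameter: float | None = None, max_order: int = MAX_ORDER) -> ZernikeCoefficients:
    """Least-squares Zernike expansion of an OPD map over a circular pupil.

    Ordinary least squares over valid in-pupil samples, no regularization.
    Requires the pupil to lie inside the map and at least 10x as many valid
    samples as coefficients; degenerate maps are rejected, not regularized.
    """
    if pupil_diameter is None:
        pupil_diameter = opd.pupil_diameter
    if pupil_diameter / 2.0 > opd.half_width + 1e-9:
        raise ValueError("pupil exceeds the map extent")
    n_terms = (max_order + 1) * (max_order + 2) // 2
    in_pupil, basis, pinv = _fit_operator(
        opd.grid_spacing, opd.half_width, opd.opd.shape[0], pupil_diameter, max_order
    )
    valid = opd.valid_mask[in_pupil] & np.isfinite(opd.opd[in_pupil])
    n_valid = int(valid.sum())
    if n_valid < 10 * n_terms:
        raise InsufficientSamplesError(
            f"{n_valid} valid samples for {n_terms} coefficients (need >= {10 * n_terms})"
        )
    vals = opd.opd[in_pupil][valid]
    if n_valid == valid.size:
        coeffs = pinv @ vals  # common case: fully valid pupil, cached operator
        resid = vals - basis.T @ coeffs
    else:
        design = basis[:, valid].T  # (Np, J)
        coeffs, _, _, _ = np.linalg.lstsq(design, vals, rcond=None)
        resid = vals - design @ coeffs
    rms = float(np.sqrt(np.mean(resid**2)))
    if n_terms < N_TERMS:
        coeffs = np.pad(coeffs, (0, N_TERMS - n_terms))
    return ZernikeCoefficients(
        pupil_diameter=float(pupil_diameter),
        surface_label=opd.surface_label,
        coeffs=coeffs,
        fit_rms_residual=rms,
    )


def synthesize(coeffs: ZernikeCoefficients, rho: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Evaluate the expansion at normalized polar coordinates (inverse of fit)."""
    basis = zernike_basis(rho, theta, MAX_ORDER)
    return np.tensordot(coeffs.coeffs, basis, axes=(0, 0))


def _rms_over(c: ZernikeCoefficients, js: list[int]) -> float:
    return float(np.sqrt(np.sum(c.coeffs[js] ** 2)))


def hoa_rms(c: ZernikeCoefficients) -> float:
    """Higher-order aberration RMS: all terms of radial order 3 through 8."""
    js = [j for j in range(N_TERMS) if single_index_to_nm(j).n >= 3]
    return _rms_over(c, js)


def sa_rms(c: ZernikeCoefficients) -> float:
    """Spherical aberration RMS: Z(4,0) and Z(6,0)."""
    return _rms_over(c, [nm_to_single_index(4, 0), nm_to_single_index(6, 0)])


def coma_rms(c: ZernikeCoefficients) -> float:
    """Coma RMS: Z(3,-1) and Z(3,1)."""
    return _rms_over(c, [nm_to_single_index(3, -1), nm_to_single_index(3, 1)])
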