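"""Hollow-sphere diffusion model for dye transport in pitted fruit.

A pitted cherry is idealised as a hollow sphere of flesh: an inner cavity
of radius ``r_inner`` (left by the stone) and an outer flesh radius
``r_flesh``, wrapped in a thin skin of thickness ``r_skin - r_flesh``.
Dye moves by Fickian diffusion with an effective diffusivity ``D_flesh``
in the flesh; the skin is treated as a thin resistive layer with its own
effective diffusivity ``D_skin``, which collapses into a Robin (mixed)
boundary condition at the flesh surface.

In dimensionless variables

    Theta = D_flesh * t / r_flesh**2        (Fourier number, time)
    R     = r / r_flesh                     (radius, A <= R <= 1)
    a*    = (a(t) - a_s) / (a_i - a_s)      (normalised CIELAB redness)

the model is the radial diffusion equation

    da*/dTheta = d2a*/dR2 + (2/R) da*/dR

with  a* = 1 at Theta = 0,  a* = 0 at R = A (cavity wall bathed by the
solution), and the skin condition  da*/dR + H a* = 0  at R = 1, where
H = (D_skin/D_flesh) * r_flesh / (r_skin - r_flesh).

Separation of variables gives eigenfunctions

    phi_n(R) = sin(lambda_n (R - A)) / R

with the positive eigenvalues lambda_n solving the transcendental equation

    lambda cos(lambda (1-A)) + (H - 1) sin(lambda (1-A)) = 0.

This module solves the eigenvalue problem, evaluates the truncated series
solution point-wise and volume-averaged (including an optional exponential
boundary forcing with amplitude W, coefficient A0 and rate A1), and holds
the geometry / transport parameter containers shared by the rest of the
package.  Everything here is pure computation in SI units.
"""

from __future__ import annotations

import json
import math
from collections import OrderedDict
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "Geometry",
    "ForcingParams",
    "TransportParams",
    "DimensionlessState",
    "EigenSystem",
    "nondimensionalize",
    "skin_factor",
    "solve_eigenvalues",
    "series_profile",
    "series_volume_average",
    "clear_eigen_cache",
]

#: default cherry geometry: 27 mm calibre fruit, 0.4 mm skin, 1.1 mm cavity
DEFAULT_R_SKIN = 13.5e-3
DEFAULT_SKIN_THICKNESS = 4.0e-4
DEFAULT_R_INNER = 1.1e-3

#: number of series terms retained by default
DEFAULT_N_TERMS = 220


class DomainError(ValueError):
    """Input outside the admissible physical/dimensionless domain."""


class SingularityError(ValueError):
    """Forcing rate A1 collides with an eigenvalue squared."""


@dataclass(frozen=True)
class Geometry:
    """Hollow-sphere fruit geometry (SI metres).

    ``r_inner`` is the cavity (stone) radius, ``r_flesh`` the outer flesh
    radius and ``r_skin`` the outer skin radius.  ``A = r_inner/r_flesh``
    is the dimensionless cavity radius; ``A = 0`` describes an unpitted
    (solid-sphere) fruit and is supported throughout.
    """

    r_inner: float = DEFAULT_R_INNER
    r_flesh: float = DEFAULT_R_SKIN - DEFAULT_SKIN_THICKNESS
    r_skin: float = DEFAULT_R_SKIN

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_inner < self.r_flesh < self.r_skin):
            raise DomainError(
                "geometry must satisfy 0 <= r_inner < r_flesh < r_skin, got "
                f"r_inner={self.r_inner}, r_flesh={self.r_flesh}, r_skin={self.r_skin}"
            )

    @property
    def A(self) -> float:
        return self.r_inner / self.r_flesh

    @property
    def skin_thickness(self) -> float:
        return self.r_skin - self.r_flesh

    @classmethod
    def cherry(cls) -> "Geometry":
        """The default calibrated-cherry geometry."""
        return cls()


@dataclass(frozen=True)
class ForcingParams:
    """Exponential boundary-forcing term of the volume-average series.

    ``W`` is a dimensionless amplitude, ``A0`` a coefficient and ``A1`` a
    decay rate; with the default ``W = 0`` the series reduces to the pure
    eigen-decay sum for a constant boundary.
    """

    W: float = 0.0
    A0: float = 0.0
    A1: float = 0.0


@dataclass(frozen=True)
class TransportParams:
    """Effective diffusivities (m^2/s) and the derived skin Robin factor H.

    ``H`` may be supplied explicitly; when a geometry is given it is
    recomputed as ``(D_skin/D_flesh) * r_flesh / skin_thickness`` and must
    agree with any stored value to 1e-12 relative.
    """

    D_flesh: float
    D_skin: float
    H: float = float("nan")
    forcing: ForcingParams = field(default_factory=ForcingParams)

    def __post_init__(self) -> None:
        if self.D_flesh <= 0 or self.D_skin <= 0:
            raise DomainError("diffusivities must be positive")

    @classmethod
    def from_geometry(
        cls,
        D_flesh: float,
        D_skin: float,
        geom: Geometry,
        forcing: ForcingParams | None = None,
    ) -> "TransportParams":
        h = skin_factor(D_skin, D_flesh, geom)
        return cls(D_flesh, D_skin, H=h, forcing=forcing or ForcingParams())

    def check_consistency(self, geom: Geometry) -> None:
        h = skin_factor(self.D_skin, self.D_flesh, geom)
        if math.isnan(self.H):
            return
        if abs(self.H - h) > 1e-12 * max(abs(h), 1.0):
            raise DomainError(
                f"stored H={self.H!r} inconsistent with components (expected {h!r})"
            )


@dataclass(frozen=True)
class DimensionlessState:
    """A point of the dimensionless problem: (Theta, R[, a_star])."""

    Theta: float
    R: float
    a_star: float | None = None

    def __post_init__(self) -> None:
        if self.Theta < 0:
            raise DomainError("Theta must be non-negative")


def nondimensionalize(
    t: float, r: float, params: TransportParams, geom: Geometry
) -> DimensionlessState:
    """Map dimensional (t seconds, r metres) to (Theta, R).

    Theta = D_flesh * t / r_flesh^2 and R = r / r_flesh.  ``r`` must lie in
    the flesh domain [r_inner, r_flesh].
    """
    if t < 0:
        raise DomainError("time must be non-negative")
    if not (geom.r_inner <= r <= geom.r_flesh):
        raise DomainError(
            f"r={r} outside the flesh domain [{geom.r_inner}, {geom.r_flesh}]"
        )
    theta = params.D_flesh * t / geom.r_flesh**2
    return DimensionlessState(Theta=theta, R=r / geom.r_flesh)


def redimensionalize(
    state: DimensionlessState, params: TransportParams, geom: Geometry
) -> tuple[float, float]:
    """Inverse of :func:`nondimensionalize`; returns (t seconds, r metres)."""
    t = state.Theta * geom.r_flesh**2 / params.D_flesh
    return t, state.R * geom.r_flesh


def skin_factor(D_skin: float, D_flesh: float, geom: Geometry) -> float:
    """Robin boundary factor H = (D_skin/D_flesh) * r_flesh/skin_thickness.

    Encodes the thin resistive skin: the flux leaving the flesh surface is
    carried through the skin layer of thickness ``r_skin - r_flesh`` with
    diffusivity ``D_skin`` into a well-stirred bath (large mass Biot
    number, so the skin's outer face takes the bath concentration).
    """
    if D_skin <= 0 or D_flesh <= 0:
        raise DomainError("diffusivities must be positive")
    if geom.skin_thickness <= 0:
        raise DomainError("skin thickness must be positive")
    return (D_skin / D_flesh) * (geom.r_flesh / geom.skin_thickness)


# ---------------------------------------------------------------------------
# Eigenvalue problem
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EigenSystem:
    """Eigen-decomposition of the hollow-sphere diffusion operator.

    For given (A, H) stores the first ``n_terms`` positive eigenvalues
    ``lambda_n``, the weighted eigenfunction norms
    ``b_n = int_A^1 R^2 phi_n(R)^2 dR`` and the expansion coefficients
    ``c_n = int_A^1 R^2 phi_n(R) dR`` (both in closed form, validated
    against adaptive quadrature in the test-suite).
    """

    A: float
    H: float
    eigenvalues: np.ndarray
    norms: np.ndarray
    coefficients: np.ndarray

    @property
    def n_terms(self) -> int:
        return len(self.eigenvalues)

    def phi(self, R: np.ndarray | float) -> np.ndarray:
        """Eigenfunction matrix phi_n(R), shape (n_terms, len(R)).

        phi_n(R) = sin(lambda_n (R - A)) / R; at R = 0 (only reachable for
        A = 0) the regular limit lambda_n is used.
        """
        R = np.atleast_1d(np.asarray(R, dtype=float))
        lam = self.eigenvalues[:, None]
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.sin(lam * (R[None, :] - self.A)) / R[None, :]
        zero = R == 0.0
        if zero.any():
            out[:, zero] = lam
        return out

    def to_json(self) -> str:
        return json.dumps(
            {
                "A": self.A,
                "H": self.H,
                "eigenvalues": self.eigenvalues.tolist(),
                "norms": self.norms.tolist(),
                "coefficients": self.coefficients.tolist(),
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "EigenSystem":
        d = json.loads(s)
        return cls(
            A=d["A"],
            H=d["H"],
            eigenvalues=np.asarray(d["eigenvalues"]),
            norms=np.asarray(d["norms"]),
            coefficients=np.asarray(d["coefficients"]),
        )


def _char_eq(lam: np.ndarray, A: float, H: float) -> np.ndarray:
    """Transcendental characteristic equation g(lambda)."""
    L = 1.0 - A
    return lam * np.cos(lam * L) + (H - 1.0) * np.sin(lam * L)


def _char_eq_prime(lam: np.ndarray, A: float, H: float) -> np.ndarray:
    L = 1.0 - A
    return (
        np.cos(lam * L)
        - lam * L * np.sin(lam * L)
        + (H - 1.0) * L * np.cos(lam * L)
    )


class MissedRootError(RuntimeError):
    """Root scan skipped an eigenvalue; retry with a finer grid."""


def _scan_roots(A: float, H: float, n_terms: int, points_per_half_period: int) -> np.ndarray:
    """Bracket sign changes of the characteristic equation and bisect.

    The asymptotic eigenvalue spacing is pi/(1-A); the scan grid places
    ``points_per_half_period`` points per half-period so no root pair can
    hide between grid points, then refines each bracket by bisection and
    polishes with two Newton steps (vectorised over all brackets).
    """
    L = 1.0 - A
    step = math.pi / L / points_per_half_period
    # scan a margin past the asymptotic location of root n_terms
    lam_max = (n_terms + 2) * math.pi / L
    grid = np.arange(step * 1e-3, lam_max, step)
    vals = _char_eq(grid, A, H)
    sign = np.sign(vals)
    # treat exact zeros on the grid as their own bracket
    idx = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
    lo = grid[idx].copy()
    hi = grid[idx + 1].copy()
    flo = vals[idx].copy()
    for _ in range(80):  # bisection to machine precision
        mid = 0.5 * (lo + hi)
        fmid = _char_eq(mid, A, H)
        left = flo * fmid <= 0
        hi = np.where(left, mid, hi)
        lo = np.where(left, lo, mid)
        flo = np.where(left, flo, fmid)
        if np.all((hi - lo) <= 4 * np.finfo(float).eps * np.maximum(hi, 1.0)):
            break
    roots = 0.5 * (lo + hi)
    for _ in range(2):  # Newton polish
        g = _char_eq(roots, A, H)
        gp = _char_eq_prime(roots, A, H)
        delta = np.where(gp != 0, g / gp, 0.0)
        cand = roots - delta
        ok = np.abs(_char_eq(cand, A, H)) <= np.abs(g)
        roots = np.where(ok, cand, roots)
    roots = roots[roots > 1e-12]
    roots = np.unique(roots)
    if len(roots) < n_terms:
        raise MissedRootError(
            f"found {len(roots)} roots, need {n_terms}; scan grid too coarse"
        )
    roots = roots[:n_terms]
    if np.any(np.diff(roots) > 2 * math.pi / L):
        raise MissedRootError("gap between consecutive roots exceeds 2*pi/(1-A)")
    return roots


def _closed_form_norms(lam: np.ndarray, A: float) -> np.ndarray:
    # b_n = int_A^1 R^2 phi_n^2 dR = int_0^L sin^2(lam u) du
    L = 1.0 - A
    return L / 2.0 - np.sin(2.0 * lam * L) / (4.0 * lam)


def _closed_form_coefficients(lam: np.ndarray, A: float) -> np.ndarray:
    # c_n = int_A^1 R^2 phi_n dR = int_0^L (u + A) sin(lam u) du
    L = 1.0 - A
    s, c = np.sin(lam * L), np.cos(lam * L)
    return s / lam**2 - L * c / lam + A * (1.0 - c) / lam


# Exact-key memoisation: a cache hit always returns exactly what a cold
# computation would, so results never depend on cache history.  (Serialised
# systems are keyed on 12-significant-digit values externally; see
# eigen_cache_key.)
_EIGEN_CACHE: "OrderedDict[tuple[float, float, int], EigenSystem]" = OrderedDict()
_EIGEN_CACHE_MAX = 20_000


def eigen_cache_key(A: float, H: float, n_terms: int) -> str:
    """Stable string key for serialised eigen systems (12 sig. digits)."""
    return f"{A:.12g}_{H:.12g}_{n_terms}"


def clear_eigen_cache() -> None:
    _EIGEN_CACHE.clear()


def solve_eigenvalues(A: float, H: float, n_terms: int = DEFAULT_N_TERMS) -> EigenSystem:
    """First ``n_terms`` eigenvalues/norms/coefficients for given (A, H).

    Roots of ``lambda cos(lambda(1-A)) + (H-1) sin(lambda(1-A)) = 0`` are
    bracketed by a sign-change scan (8 points per asymptotic half-period,
    doubled on missed-root detection) and refined by safeguarded bisection
    plus Newton polish.  Results are memoised on the exact (A, H, n_terms)
    triple, so a cache hit is bit-identical to a cold computation.
    """
    if not (0.0 <= A < 1.0):
        raise DomainError("A must lie in [0, 1)")
    if H <= 0:
        raise DomainError("H must be positive")
    if n_terms < 1:
        raise DomainError("n_terms must be >= 1")
    key = (A, H, n_terms)
    hit = _EIGEN_CACHE.get(key)
    if hit is not None:
        return hit
    pts = 8
    last_err: MissedRootError | None = None
    while pts <= 128:
        try:
            lam = _scan_roots(A, H, n_terms, pts)
            break
        except MissedRootError as err:  # double grid density and retry
            last_err = err
            pts *= 2
    else:
        raise MissedRootError(f"root scan failed even at finest grid: {last_err}")
    eig = EigenSystem(
        A=A,
        H=H,
        eigenvalues=lam,
        norms=_closed_form_norms(lam, A),
        coefficients=_closed_form_coefficients(lam, A),
    )
    while len(_EIGEN_CACHE) >= _EIGEN_CACHE_MAX:
        _EIGEN_CACHE.popitem(last=False)
    _EIGEN_CACHE[key] = eig
    return eig


# ---------------------------------------------------------------------------
# Truncated series solution
# ---------------------------------------------------------------------------


def _forcing_weight(
    Theta: np.ndarray, lam2: np.ndarray, forcing: ForcingParams
) -> np.ndarray:
    """Forcing contribution per mode, already multiplied by exp(-lam^2 Theta).

    The bracket -W*A0/(lam^2 - A1) * (e^{(lam^2-A1)Theta} - 1) carries the
    outer e^{-lam^2 Theta}; the product is evaluated in the equivalent
    overflow-safe form -W*A0/(lam^2 - A1) * (e^{-A1 Theta} - e^{-lam^2 Theta}).
    Shape: (n_modes, n_theta).
    """
    if forcing.W == 0.0:
        return np.zeros((lam2.shape[0], Theta.shape[0]))
    denom = lam2[:, None] - forcing.A1
    if np.any(np.abs(denom) < 1e-9):
        raise SingularityError(
            "forcing rate A1 within 1e-9 of an eigenvalue squared"
        )
    num = np.exp(-forcing.A1 * Theta)[None, :] - np.exp(-lam2[:, None] * Theta[None, :])
    return -forcing.W * forcing.A0 / denom * num


def series_profile(
    Theta: float,
    R_values: Sequence[float] | np.ndarray,
    eig: EigenSystem,
    forcing: ForcingParams | None = None,
) -> np.ndarray:
    """Point-wise truncated series a*(R, Theta) at the given radii.

    a*(R,Theta) = sum_n [ c_n/b_n * e^{-lam_n^2 Theta} + forcing_n(Theta) ]
    * phi_n(R).  With W = 0 this is the pure eigen-decay expansion of the
    unit initial condition.  No clipping is applied; truncation ripples
    near Theta = 0 are left visible.
    """
    if Theta < 0:
        raise DomainError("Theta must be non-negative")
    R = np.atleast_1d(np.asarray(R_values, dtype=float))
    if np.any(R < eig.A - 1e-12) or np.any(R > 1.0 + 1e-12):
        raise DomainError(f"R values must lie in [{eig.A}, 1]")
    forcing = forcing or ForcingParams()
    lam2 = eig.eigenvalues**2
    theta_arr = np.asarray([Theta], dtype=float)
    weights = (eig.coefficients / eig.norms)[:, None] * np.exp(
        -lam2[:, None] * theta_arr[None, :]
    )
    weights = weights + _forcing_weight(theta_arr, lam2, forcing)
    return (weights[:, 0][None, :] @ eig.phi(R)).ravel()


def series_volume_average(
    Theta: float | Sequence[float] | np.ndarray,
    eig: EigenSystem,
    forcing: ForcingParams | None = None,
) -> np.ndarray | float:
    """Volume-average redness a*_V(Theta) over the flesh shell.

    a*_V = 3/(1-A^3) * sum_n { c_n^2/b_n
           - W A0/(lam_n^2 - A1) (e^{(lam_n^2-A1)Theta} - 1) c_n } e^{-lam_n^2 Theta}

    which is exactly the volume average 3/(1-A^3) int_A^1 R^2 a* dR of
    :func:`series_profile` (each phi_n integrates to c_n).
    """
    scalar = np.isscalar(Theta)
    theta = np.atleast_1d(np.asarray(Theta, dtype=float))
    if np.any(theta < 0):
        raise DomainError("Theta must be non-negative")
    forcing = forcing or ForcingParams()
    lam2 = eig.eigenvalues**2
    decay = np.exp(-lam2[:, None] * theta[None, :])
    terms = (eig.coefficients**2 / eig.norms)[:, None] * decay
    terms = terms + eig.coefficients[:, None] * _forcing_weight(theta, lam2, forcing)
    out = 3.0 / (1.0 - eig.A**3) * terms.sum(axis=0)
    return float(out[0]) if scalar else out
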