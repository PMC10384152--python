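"""Promolecular reduced-density-gradient (NCI) analysis.

The noncovalent-interaction picture evaluates, on a 3-D grid, the electron
density rho, its reduced gradient

    RDG = |grad rho| / (2 (3 pi^2)^(1/3) rho^(4/3)),

and the quantity sign(lambda_2) rho, where lambda_2 is the middle eigenvalue
of the density Hessian: low-RDG points at small density flag weak
interactions, with lambda_2 < 0 marking attraction (hydrogen bonds) and
lambda_2 > 0 steric crowding.

The density here is *promolecular*: a sum of spherically averaged atomic
densities, each a short sum of Slater-type exponentials
rho_elem(r) = sum_j c_j exp(-r / zeta_j) (atomic units). That approximation
is the standard self-contained route to NCI analysis and is the only density
this module claims to describe. Gradients and Hessians are analytic; this
module works internally in bohr and atomic units, converting from nm at the
boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ArgumentError, ModelError

BOHR_PER_NM = 1.0 / 0.0529177210903

#: Three-term Slater fits (c in a.u. density, zeta in bohr) of spherically
#: averaged free-atom densities for the elements of water and the surfactant.
PROMOLECULAR_FITS: dict[str, tuple[tuple[float, float], ...]] = {
    "H": ((0.2815, 0.5288),),
    "C": ((120.2, 0.0884), (1.172, 0.4532), (0.06255, 1.021)),
    "N": ((190.9, 0.0767), (2.247, 0.3974), (0.1237, 0.8593)),
    "O": ((289.5, 0.0669), (2.879, 0.3601), (0.1882, 0.7277)),
}

_RDG_CONST = 1.0 / (2.0 * (3.0 * np.pi**2) ** (1.0 / 3.0))

_ATOMIC_NUMBER = {"H": 1, "C": 6, "N": 7, "O": 8}


def atomic_number(element: str) -> int:
    try:
        return _ATOMIC_NUMBER[element]
    except KeyError:
        raise ModelError(f"element {element!r} not covered by the density table")


def _fits_for(elements) -> list[tuple[tuple[float, float], ...]]:
    out = []
    for e in elements:
        if e not in PROMOLECULAR_FITS:
            raise ModelError(f"element {e!r} not covered by the density table")
        out.append(PROMOLECULAR_FITS[e])
    return out


def promolecular_density(elements, coords_bohr, points_bohr):
    """rho, gradient and Hessian of the promolecular density at points.

    Everything is analytic: for one Slater term f(r) = c exp(-r/zeta),
    f' = -f/zeta and f'' = f/zeta^2, and the Hessian of f(|r - R|) is
    f'' rr^T + (f'/r)(I - rr^T) in the radial frame.

    Parameters are in bohr; returns ``(rho (M,), grad (M, 3),
    hessian (M, 3, 3))`` in atomic units. Accepts a single point as well.
    """
    coords = np.asarray(coords_bohr, dtype=float).reshape(-1, 3)
    pts = np.asarray(points_bohr, dtype=float)
    single = pts.ndim == 1
    pts = pts.reshape(-1, 3)
    fits = _fits_for(elements)
    if len(fits) != len(coords):
        raise ArgumentError("elements and coordinates differ in length")

    M = len(pts)
    rho = np.zeros(M)
    grad = np.zeros((M, 3))
    hess = np.zeros((M, 3, 3))
    eye = np.eye(3)
    for fit, R in zip(fits, coords):
        d = pts - R                                   # (M, 3)
        r = np.linalg.norm(d, axis=1)
        r_safe = np.maximum(r, 1e-12)
        u = d / r_safe[:, None]
        uu = u[:, :, None] * u[:, None, :]            # (M, 3, 3)
        for c, zeta in fit:
            f = c * np.exp(-r / zeta)
            fp = -f / zeta
            fpp = f / zeta**2
            rho += f
            grad += fp[:, None] * u
            radial = fp / r_safe
            hess += fpp[:, None, None] * uu + radial[:, None, None] * (eye - uu)
    if single:
        return float(rho[0]), grad[0], hess[0]
    return rho, grad, hess


def rdg_value(rho, grad):
    """RDG = |grad rho| / (2 (3 pi^2)^(1/3) rho^(4/3)); rho must be > 0.

    ``grad`` may be gradient vectors (..., 3) or precomputed magnitudes.
    """
    rho = np.asarray(rho, dtype=float)
    if np.any(rho <= 0):
        raise ArgumentError("RDG is undefined for non-positive density")
    g = np.asarray(grad, dtype=float)
    gnorm = np.linalg.norm(g, axis=-1) if g.shape[-1:] == (3,) and g.ndim > rho.ndim \
        else np.abs(g)
    return _RDG_CONST * gnorm / rho ** (4.0 / 3.0)


def signed_rho(hessian, rho):
    """sign(lambda_2) * rho with lambda_2 the middle Hessian eigenvalue.

    Accepts one symmetric 3x3 matrix or a stack (..., 3, 3).
    """
    H = np.asarray(hessian, dtype=float)
    if H.shape[-2:] != (3, 3):
        raise ArgumentError("Hessian must be 3x3")
    if not np.allclose(H, np.swapaxes(H, -1, -2), atol=1e-8):
        raise ArgumentError("Hessian must be symmetric")
    lam = np.linalg.eigvalsh(H)          # ascending
    lam2 = lam[..., 1]                   # middle == second largest
    return np.sign(lam2) * np.asarray(rho, dtype=float)


@dataclass
class RDGField:
    """rho, RDG and sign(lambda_2) rho on a grid, plus the scatter data."""

    grid_origin: np.ndarray   # bohr
    grid_spacing: float       # bohr
    shape: tuple
    rho: np.ndarray
    rdg: np.ndarray
    signed_rho: np.ndarray
    rho_max_cut: float

    def scatter(self) -> tuple[np.ndarray, np.ndarray]:
        """(sign(lambda_2) rho, RDG) pairs for the weak-interaction plot;
        points denser than ``rho_max_cut`` are excluded."""
        mask = (self.rho <= self.rho_max_cut) & (self.rho > 1e-10)
        return self.signed_rho[mask], self.rdg[mask]

    def scatter_text(self) -> str:
        s, g = self.scatter()
        lines = ["# signed_rho_au rdg"]
        for a, b in zip(s, g):
            lines.append(f"{a:.8f} {b:.6f}")
        return "\n".join(lines) + "\n"


def rdg_scan(elements, coords_nm, spacing_bohr: float = 0.1,
             margin_bohr: float = 3.0, rho_max_cut: float = 0.05,
             chunk: int = 200_000) -> RDGField:
    """Evaluate rho, RDG and sign(lambda_2) rho on a grid around a structure.

    The grid covers the atoms plus ``margin_bohr`` on each side at uniform
    ``spacing_bohr``. ``rho_max_cut`` (a.u.) bounds the scatter at the
    standard NCI density window. Coordinates come in nm.
    """
    coords = np.asarray(coords_nm, dtype=float).reshape(-1, 3) * BOHR_PER_NM
    if coords.size == 0:
        raise ArgumentError("empty structure")
    if spacing_bohr <= 0 or margin_bohr < 0:
        raise ArgumentError("grid spacing must be positive, margin non-negative")
    lo = coords.min(axis=0) - margin_bohr
    hi = coords.max(axis=0) + margin_bohr
    shape = tuple(np.maximum(np.ceil((hi - lo) / spacing_bohr).astype(int) + 1, 2))
    axes = [lo[k] + spacing_bohr * np.arange(shape[k]) for k in range(3)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)

    n = len(pts)
    rho = np.empty(n)
    rdg = np.empty(n)
    s_rho = np.empty(n)
    for s in range(0, n, chunk):
        block = pts[s:s + chunk]
        r, g, H = promolecular_density(elements, coords, block)
        r = np.maximum(r, 1e-30)
        rho[s:s + chunk] = r
        rdg[s:s + chunk] = _RDG_CONST * np.linalg.norm(g, axis=1) / r ** (4.0 / 3.0)
        lam2 = np.linalg.eigvalsh(H)[:, 1]
        s_rho[s:s + chunk] = np.sign(lam2) * r
    return RDGField(lo, spacing_bohr, shape, rho.reshape(shape),
                    rdg.reshape(shape), s_rho.reshape(shape), rho_max_cut)
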