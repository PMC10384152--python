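"""Number-density profiles along the surface normal, the 10-90 interfacial
thickness, and per-surfactant-area bookkeeping.

The 10-90 rule measures the distance over which the water density profile
climbs from 10% to 90% of its bulk value. For an analytic tanh flank
rho(z) = rho0/2 [1 - tanh((z - z0)/w)] the closed form is
2 atanh(0.8) w ~ 2.1972 w, which the synthetic slab generator uses as its
ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .box import PeriodicBox
from .core import Trajectory
from .exceptions import ArgumentError, ProfileShapeError

#: 10-90 width of a tanh flank per unit w.
TANH_10_90_FACTOR = 2.0 * np.arctanh(0.8)


@dataclass
class DensityProfile:
    """Frame-averaged number density (nm^-3) binned along z."""

    z_centers: np.ndarray
    density: np.ndarray
    species: str
    frames_averaged: int
    bin_width: float
    cross_section: float

    def integral_count(self) -> float:
        """Mean species count implied by the profile (mass conservation)."""
        return float(self.density.sum() * self.bin_width * self.cross_section)

    def to_text(self) -> str:
        lines = ["# z_nm density_nm^-3"]
        for z, d in zip(self.z_centers, self.density):
            lines.append(f"{z:.5f} {d:.8f}")
        return "\n".join(lines) + "\n"


def density_profile(trajectory: Trajectory, selection,
                    bin_width: float = 0.02,
                    species: str = "selection") -> DensityProfile:
    """Per-bin count / (lx ly dz), averaged over frames."""
    sel = np.asarray(selection, dtype=int)
    if sel.size == 0:
        raise ArgumentError("empty selection")
    if bin_width <= 0:
        raise ArgumentError("bin_width must be positive")
    box = trajectory[0].box
    n_bins = max(int(np.ceil(box.lz / bin_width)), 1)
    edges = np.linspace(0.0, n_bins * bin_width, n_bins + 1)
    acc = np.zeros(n_bins)
    for fr in trajectory:
        z = np.mod(fr.positions[sel][:, 2], box.lz)
        acc += np.histogram(z, bins=edges)[0]
    density = acc / (len(trajectory) * box.cross_section * bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return DensityProfile(centers, density, species, len(trajectory),
                          bin_width, box.cross_section)


@dataclass
class ThicknessResult:
    """10-90 thickness of the two interfaces of a slab profile."""

    thickness: tuple[float, float]  # (lower flank, upper flank), nm
    mean: float
    bulk_value_used: float
    z10: tuple[float, float]
    z90: tuple[float, float]

    def to_dict(self) -> dict:
        return {
            "thickness_lower_nm": self.thickness[0],
            "thickness_upper_nm": self.thickness[1],
            "thickness_mean_nm": self.mean,
            "bulk_density_nm3": self.bulk_value_used,
            "z10_nm": list(self.z10),
            "z90_nm": list(self.z90),
        }


def _crossing(z: np.ndarray, rho: np.ndarray, i_in: int, i_out: int,
              level: float) -> float:
    """Linear interpolation of the level crossing between two bins."""
    z1, z2 = z[i_in], z[i_out]
    r1, r2 = rho[i_in], rho[i_out]
    if r1 == r2:
        return float(0.5 * (z1 + z2))
    return float(z1 + (level - r1) * (z2 - z1) / (r2 - r1))


def _flank_widths(z, rho, bulk, center_idx, direction):
    """(z90, z10) on one flank; direction +1 for the upper flank.

    Both levels are located walking inward from the vacuum side, taking the
    outermost upward crossing of each: bulk-noise dips below 90% of the
    plateau then cannot masquerade as the interface, and smoothing has
    already suppressed isolated outer spikes.
    """
    n = len(rho)
    outer_in = (list(range(n - 1, center_idx - 1, -1)) if direction > 0
                else list(range(0, center_idx + 1)))

    def outermost_crossing(level):
        for prev, cur in zip(outer_in, outer_in[1:]):
            if rho[prev] < level <= rho[cur]:
                return _crossing(z, rho, cur, prev, level)
        return None

    z10 = outermost_crossing(0.1 * bulk)
    z90 = outermost_crossing(0.9 * bulk)
    if z90 is None or z10 is None:
        raise ProfileShapeError(
            "profile flank never crosses 10% and 90% of the bulk value")
    return z90, z10


def thickness_10_90(profile: DensityProfile,
                    bulk_window: tuple[float, float] | None = None,
                    smooth_window: int = 5) -> ThicknessResult:
    """10-90 thickness of each slab flank, plus their mean.

    The bulk value is the raw-profile mean over ``bulk_window`` (default:
    the central 25% of the region where the density exceeds half its
    maximum). Crossings are located on a lightly smoothed profile by linear
    interpolation; per flank, the innermost 90% crossing and the outermost
    10% crossing are used, which tolerates isolated noise spikes outside
    the interface.
    """
    z = profile.z_centers
    rho = profile.density
    if smooth_window >= 3 and len(rho) > smooth_window + 2:
        w = smooth_window + (smooth_window + 1) % 2
        rho_s = np.clip(savgol_filter(rho, w, 2), 0.0, None)
    else:
        rho_s = rho
    if bulk_window is None:
        above = np.nonzero(rho_s >= 0.5 * rho_s.max())[0]
        if above.size < 4:
            raise ProfileShapeError("no bulk plateau in the profile")
        lo_z, hi_z = z[above[0]], z[above[-1]]
        span = hi_z - lo_z
        bulk_window = (lo_z + 0.375 * span, hi_z - 0.375 * span)
    w_lo, w_hi = bulk_window
    in_bulk = (z >= w_lo) & (z <= w_hi)
    if not np.any(in_bulk):
        raise ProfileShapeError("bulk window holds no profile bins")
    bulk = float(rho[in_bulk].mean())
    if bulk <= 0:
        raise ProfileShapeError("bulk density is zero")
    center_idx = int(np.argmin(np.abs(z - 0.5 * (w_lo + w_hi))))
    z90_hi, z10_hi = _flank_widths(z, rho_s, bulk, center_idx, +1)
    z90_lo, z10_lo = _flank_widths(z, rho_s, bulk, center_idx, -1)
    t_lo = abs(z90_lo - z10_lo)
    t_hi = abs(z10_hi - z90_hi)
    return ThicknessResult(
        thickness=(t_lo, t_hi),
        mean=0.5 * (t_lo + t_hi),
        bulk_value_used=bulk,
        z10=(z10_lo, z10_hi),
        z90=(z90_lo, z90_hi),
    )


def area_per_surfactant(box: PeriodicBox, n_surfactant_total: int,
                        decimals: int = 2) -> float:
    """Interface area per molecule: (lx ly) / (N/2), rounded for labeling.

    The total count must be even and positive — the two leaflets carry equal
    numbers of molecules by construction.
    """
    if n_surfactant_total <= 0 or n_surfactant_total % 2 != 0:
        raise ArgumentError("surfactant count must be positive and even")
    area = box.cross_section / (n_surfactant_total / 2)
    return round(area, decimals)
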