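"""Geometric hydrogen-bond detection, counts, intermittent time correlation,
multi-exponential fitting and lifetimes.

A donor-acceptor pair is bonded when the minimum-image D-A distance is
within ``r_cut`` (default 0.35 nm) *and* an angular test passes. Two angle
conventions are first-class, because the underlying geometric criterion
("H-O-H angle less than 120 degrees") does not name its vertex
unambiguously:

* ``HDA`` (default): the angle at the donor between the D-H bond and the
  D-A axis is at most ``angle_cut`` (default 30 degrees) for at least one
  donor hydrogen — the GROMACS-style criterion;
* ``DHA``: the angle at the hydrogen between H->D and H->A is at least
  ``angle_cut`` (default 120 degrees, i.e. within 60 degrees of linear).

Distances and angles exactly at threshold count as bonded (closed decision),
so planted boundary geometries behave deterministically. The quaternary
nitrogen (role ``N1``) has four covalent bonds and is never a donor or an
acceptor.

The bond-survival statistics use the *intermittent* convention: C(t) is the
probability that a pair bonded at a time origin is bonded a lag t later,
regardless of breaks in between. Finite slabs give C(t) a nonzero plateau,
which a sum of decaying exponentials with unit weight cannot represent, so
the lifetime integral is evaluated on the plateau-subtracted, renormalized
curve (the raw fit is reported alongside).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .core import Trajectory
from .exceptions import ArgumentError, FitError, RoleError

_RADEG = 180.0 / np.pi


@dataclass(frozen=True)
class HBondCriterion:
    """Geometric criterion: distance cutoff (nm) plus one of two angle modes."""

    r_cut: float = 0.35
    angle_mode: str = "HDA"
    angle_cut: float | None = None

    def __post_init__(self):
        if self.r_cut <= 0:
            raise ArgumentError("r_cut must be positive")
        if self.angle_mode not in ("HDA", "DHA"):
            raise ArgumentError(f"unknown angle mode {self.angle_mode!r}")
        if self.angle_cut is None:
            object.__setattr__(
                self, "angle_cut", 30.0 if self.angle_mode == "HDA" else 120.0)
        if not (0.0 < self.angle_cut < 180.0):
            raise ArgumentError("angle_cut must lie in (0, 180)")


@dataclass
class HBondTimeSeries:
    """Per-pair 0/1 bond occupancy over time at spacing dt (ps)."""

    pair_ids: list
    h: np.ndarray
    dt: float

    def __post_init__(self):
        self.h = np.asarray(self.h)
        if self.h.ndim != 2 or len(self.pair_ids) != self.h.shape[0]:
            raise ArgumentError("occupancy matrix must be (pairs, frames)")
        if not np.isin(self.h, (0, 1)).all():
            raise ArgumentError("occupancy must be 0/1")


@dataclass
class CorrelationResult:
    """Intermittent correlation C(t) and, once fitted, its exponential terms."""

    lags: np.ndarray
    C: np.ndarray
    fit_terms: list = field(default_factory=list)
    lifetime_tau: float | None = None


@dataclass
class LifetimeResult:
    """Plateau-corrected lifetime (tau, ps) plus the raw-fit variant."""

    tau: float
    tau_raw: float
    plateau: float
    fit_terms: list
    fit_terms_raw: list


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------

def _angles_deg(cos_vals: np.ndarray) -> np.ndarray:
    return np.arccos(np.clip(cos_vals, -1.0, 1.0)) * _RADEG


def detect_hbonds(frame, donors, donor_hydrogens, acceptors,
                  criterion: HBondCriterion = HBondCriterion(),
                  topology=None) -> list[tuple[int, int]]:
    """All (donor, acceptor) pairs satisfying the criterion in one frame.

    ``donor_hydrogens`` maps each donor heavy-atom index to its bonded
    hydrogen indices (see ``Topology.donor_hydrogen_map``). Donor-acceptor
    pairs on the same atom are skipped; atoms labeled ``N1`` are excluded
    from both sides.
    """
    donors = np.asarray(donors, dtype=int)
    acceptors = np.asarray(acceptors, dtype=int)
    if topology is not None:
        n1 = set(topology.indices_with_role("N1").tolist())
        donors = np.array([d for d in donors if d not in n1], dtype=int)
        acceptors = np.array([a for a in acceptors if a not in n1], dtype=int)
    if donors.size == 0 or acceptors.size == 0:
        return []
    pos = frame.positions
    box = frame.box
    d_vec = box.minimum_image(pos[acceptors][None, :, :] - pos[donors][:, None, :])
    d_da = np.linalg.norm(d_vec, axis=-1)
    # Closed thresholds with a float-rounding epsilon: geometries planted
    # exactly at the cutoff must count as bonded deterministically.
    within = (d_da <= criterion.r_cut + 1e-9) & (
        donors[:, None] != acceptors[None, :])
    out = []
    for i in np.nonzero(within.any(axis=1))[0]:
        d_idx = int(donors[i])
        hyds = donor_hydrogens.get(d_idx, [])
        if not hyds:
            continue
        acc_ids = np.nonzero(within[i])[0]
        da = d_vec[i, acc_ids]                       # donor -> acceptor
        da_hat = da / np.linalg.norm(da, axis=1, keepdims=True)
        bonded = np.zeros(len(acc_ids), dtype=bool)
        for h in hyds:
            dh = box.minimum_image(pos[h] - pos[d_idx])
            if criterion.angle_mode == "HDA":
                dh_hat = dh / np.linalg.norm(dh)
                ang = _angles_deg(da_hat @ dh_hat)
                bonded |= ang <= criterion.angle_cut + 1e-7
            else:  # DHA: vertex at the hydrogen
                hd = -dh
                ha = da - dh
                cosv = (ha @ hd) / (
                    np.linalg.norm(ha, axis=1) * np.linalg.norm(hd))
                bonded |= _angles_deg(cosv) >= criterion.angle_cut - 1e-7
        for j, a_id in zip(bonded, acc_ids):
            if j:
                out.append((d_idx, int(acceptors[a_id])))
    return out


def water_head_selections(topology):
    """(donors, donor_hydrogens, head_acceptors) for water-to-head bonding."""
    donors = topology.require_role("OW")
    acceptors = topology.require_role("O_carboxyl")
    dh_all = topology.donor_hydrogen_map()
    donor_h = {int(d): dh_all.get(int(d), []) for d in donors}
    return donors, donor_h, acceptors


def hbond_count_per_head(trajectory: Trajectory,
                         criterion: HBondCriterion = HBondCriterion()):
    """Mean and standard deviation (over frames) of water-head hydrogen
    bonds per surfactant head."""
    top = trajectory.topology
    heads = top.residues_with_role("O_carboxyl")
    if not heads:
        raise RoleError("no labeled head acceptors")
    if top.indices_with_role("OW").size == 0:
        return 0.0, 0.0
    donors, donor_h, acceptors = water_head_selections(top)
    per_frame = []
    for fr in trajectory:
        bonds = detect_hbonds(fr, donors, donor_h, acceptors, criterion,
                              topology=top)
        per_frame.append(len(bonds) / len(heads))
    per_frame = np.array(per_frame)
    return float(per_frame.mean()), float(per_frame.std())


def hbond_time_series(trajectory: Trajectory, donors, donor_hydrogens,
                      acceptors,
                      criterion: HBondCriterion = HBondCriterion()) -> HBondTimeSeries:
    """Occupancy matrix over all pairs ever bonded along the trajectory."""
    pair_index: dict[tuple[int, int], int] = {}
    events = []
    for t, fr in enumerate(trajectory):
        for pair in detect_hbonds(fr, donors, donor_hydrogens, acceptors,
                                  criterion, topology=trajectory.topology):
            idx = pair_index.setdefault(pair, len(pair_index))
            events.append((idx, t))
    h = np.zeros((len(pair_index), len(trajectory)), dtype=np.int8)
    for idx, t in events:
        h[idx, t] = 1
    pairs = [None] * len(pair_index)
    for pair, idx in pair_index.items():
        pairs[idx] = pair
    return HBondTimeSeries(pairs, h, trajectory.dt)


# ---------------------------------------------------------------------------
# Correlation and lifetimes
# ---------------------------------------------------------------------------

def intermittent_acf(series: HBondTimeSeries, max_lag: int,
                     chunk: int = 1024) -> CorrelationResult:
    """Intermittent C(t) with multiple time origins.

    C(l) = sum_{p,t0} h[p,t0] h[p,t0+l] / sum_{p,t0<=T-1-l} h[p,t0], so
    C(0) = 1 exactly and the estimate is unbiased for stationary input.
    """
    h = series.h.astype(np.float64)
    n_pairs, T = h.shape
    if max_lag >= T:
        raise ArgumentError("max_lag must be smaller than the series length")
    if not h.any():
        raise ArgumentError("all-zero occupancy: correlation undefined")
    n_fft = int(2 ** np.ceil(np.log2(2 * T)))
    num = np.zeros(max_lag + 1)
    for s in range(0, n_pairs, chunk):
        block = h[s:s + chunk]
        F = np.fft.rfft(block, n=n_fft, axis=1)
        ac = np.fft.irfft(F * np.conj(F), n=n_fft, axis=1)[:, :max_lag + 1]
        num += ac.sum(axis=0)
    # Denominator: occupied origins available at each lag (h is 0/1).
    cs = np.concatenate([[0.0], np.cumsum(h.sum(axis=0))])
    den = np.array([cs[T - lag] for lag in range(max_lag + 1)])
    C = num / np.maximum(den, 1e-300)
    lags = np.arange(max_lag + 1) * series.dt
    return CorrelationResult(lags, C)


def _multiexp(params: np.ndarray, t: np.ndarray, n_terms: int) -> np.ndarray:
    w = params[:n_terms]
    b = np.exp(np.clip(params[n_terms:], -50.0, 50.0))
    a = w**2 / np.sum(w**2)
    return np.sum(a[:, None] * np.exp(-t[None, :] / b[:, None]), axis=0)


def fit_multiexponential(C, lags, n_terms: int = 2,
                         b_max: float | None = None) -> list[tuple[float, float]]:
    """Constrained fit C(t) ~ sum_i a_i exp(-t/b_i), a_i >= 0, sum a_i = 1.

    Weights are parameterized as squared ratios and timescales as bounded
    log values, enforcing the constraints smoothly; ``b_max`` (default
    10x the longest lag) caps the timescales, since nothing slower is
    observable in the window. Eight deterministic starts with log-spaced
    timescale guesses are tried; the best residual wins (ties to the
    smallest leading b). Terms return sorted by b.
    """
    if n_terms not in (1, 2, 3):
        raise ArgumentError("n_terms must be 1, 2 or 3")
    C = np.asarray(C, dtype=float)
    t = np.asarray(lags, dtype=float)
    if C.shape != t.shape or C.ndim != 1:
        raise ArgumentError("C and lags must be matching 1-D arrays")
    t_lo = max(t[1] - t[0], 1e-6) if len(t) > 1 else 1.0
    t_hi = max(t[-1], 10 * t_lo)
    if b_max is None:
        b_max = 10.0 * t_hi
    lb = np.concatenate([np.full(n_terms, -10.0),
                         np.full(n_terms, np.log(t_lo / 10.0))])
    ub = np.concatenate([np.full(n_terms, 10.0),
                         np.full(n_terms, np.log(b_max))])
    centers = np.geomspace(t_lo, t_hi, 8)
    best = None
    for c0 in centers:
        b0 = np.clip(c0 * np.geomspace(0.5, 2.0, n_terms),
                     t_lo / 10.0 * 1.01, b_max * 0.99)
        x0 = np.concatenate([np.ones(n_terms), np.log(b0)])
        try:
            res = least_squares(
                lambda p: _multiexp(p, t, n_terms) - C, x0, method="trf",
                bounds=(lb, ub), max_nfev=2000)
        except Exception:
            continue
        b_lead = np.min(np.exp(np.clip(res.x[n_terms:], -50.0, 50.0)))
        key = (round(res.cost, 12), b_lead)
        if best is None or key < best[0]:
            best = (key, res)
    if best is None:
        raise FitError("multi-exponential fit failed from every start")
    res = best[1]
    if not res.success and best[0][0] > 1e-3:
        raise FitError("multi-exponential fit did not converge",
                       residual_norm=float(np.sqrt(2 * res.cost)))
    w = res.x[:n_terms]
    a = w**2 / np.sum(w**2)
    b = np.exp(np.clip(res.x[n_terms:], -50.0, 50.0))
    order = np.argsort(b)
    return [(float(a[i]), float(b[i])) for i in order]


def hbond_lifetime(fit_terms) -> float:
    """tau = integral of sum a_i exp(-t/b_i) from 0 to infinity = sum a_i b_i."""
    return float(sum(a * b for a, b in fit_terms))


def correlation_lifetime(result: CorrelationResult, n_terms: int = 2,
                         tail_fraction: float = 0.2,
                         fit_floor: float = 0.02) -> LifetimeResult:
    """Fit C(t) and integrate to a lifetime, handling the finite-system
    plateau.

    The plateau is estimated as the mean of the trailing ``tail_fraction``
    of C; the corrected curve (C - p)/(1 - p) decays to zero and is fitted
    with the constrained multi-exponential, giving tau = sum a_i b_i. The
    fit window stops where the corrected curve first drops below
    ``fit_floor``: beyond that point the curve is statistical noise, and a
    multi-term fit would spend a term on noise wiggles and inflate tau. The
    uncorrected fit of the raw C is reported as ``tau_raw``.
    """
    C, lags = result.C, result.lags
    n_tail = max(int(len(C) * tail_fraction), 1)
    plateau = float(C[-n_tail:].mean())
    if plateau >= 1.0 - 1e-9:
        raise FitError("correlation never decays below its plateau")
    corrected = (C - plateau) / (1.0 - plateau)
    below = np.nonzero(corrected < fit_floor)[0]
    cut = max(int(below[0]) if below.size else len(corrected), 20)
    terms = fit_multiexponential(corrected[:cut], lags[:cut], n_terms,
                                 b_max=4.0 * lags[cut - 1])
    terms_raw = fit_multiexponential(C, lags, n_terms)
    result.fit_terms = terms
    result.lifetime_tau = hbond_lifetime(terms)
    return LifetimeResult(hbond_lifetime(terms), hbond_lifetime(terms_raw),
                          plateau, terms, terms_raw)
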