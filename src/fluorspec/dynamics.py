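"""Dihedral free-energy profiles, helicity indicator dynamics, conformer
classification and a transition-state-theory rate estimate.

The helicity of a perfluoroalkyl-like chain is summarized by the sign of
the overall-helicity dihedral (the 1-2-(n-1)-n backbone dihedral): the
left- and right-handed helices have opposite sign, and a sign change
that survives a debounce window counts as one helicity-reversal event.
The helicity lifetime tau_hel is extracted from the indicator
autocorrelation C_hel(t) = <theta(0) theta(t)> either by integrating to
the first decay below a threshold or by an exponential fit; for a pure
two-state Markov (telegraph) process with per-direction rate k both give
tau = 1/(2k).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import KB
from .errors import AnalysisError, InputError
from .spectra import autocorrelation
from .trajectory import Trajectory, dihedral_series

__all__ = [
    "FreeEnergyProfile",
    "HelicityTrace",
    "LifetimeResult",
    "TSTResult",
    "free_energy_profile",
    "helicity_trace",
    "helicity_from_angles",
    "helicity_lifetime",
    "classify_conformers",
    "tst_rate",
]


@dataclass
class FreeEnergyProfile:
    """F(phi) = -kT ln p(phi) on a uniform angular grid, min-shifted to 0.

    ``F`` is in units of kT; empty bins carry ``F = inf`` and are flagged
    in ``empty`` rather than silently interpolated.
    """

    angle_grid: np.ndarray  # bin centers, degrees
    F: np.ndarray  # kT units
    counts: np.ndarray
    temperature: float
    empty: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.empty is None:
            self.empty = self.counts == 0

    @property
    def bin_width(self) -> float:
        return float(self.angle_grid[1] - self.angle_grid[0])

    def F_kJmol(self) -> np.ndarray:
        from .constants import ENERGY_KJMOL

        return self.F * KB * self.temperature * ENERGY_KJMOL


@dataclass
class HelicityTrace:
    """Per-frame helicity indicator with debounced flip events."""

    theta: np.ndarray  # +-1 per frame
    dt: float  # fs
    flip_times: np.ndarray  # fs, strictly increasing
    dwell_times: np.ndarray  # fs
    debounce: float  # fs


@dataclass
class LifetimeResult:
    tau_ps: float
    uncertainty_ps: float
    method: str
    lower_bound: bool
    acf_time_fs: np.ndarray
    acf: np.ndarray


@dataclass
class TSTResult:
    rate_per_ps: float
    barrier_kT: float
    attempt_frequency_per_ps: float
    minima_deg: np.ndarray


def free_energy_profile(
    angles: np.ndarray,
    temperature: float = 300.0,
    bin_width: float = 2.0,
) -> FreeEnergyProfile:
    """Histogram free-energy profile of a dihedral-angle sample.

    Angles are interpreted on the signed (-180, 180] convention; the
    histogram is periodic with uniform bins of ``bin_width`` degrees.
    """
    angles = np.asarray(angles, dtype=float)
    if angles.size == 0:
        raise InputError("empty angle sample")
    if angles.size < 10_000:
        warnings.warn(
            f"only {angles.size} samples; profile will be noisy", stacklevel=2
        )
    n_bins = int(round(360.0 / bin_width))
    edges = np.linspace(-180.0, 180.0, n_bins + 1)
    wrapped = np.mod(angles + 180.0, 360.0) - 180.0
    counts, _ = np.histogram(wrapped, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    with np.errstate(divide="ignore"):
        F = -np.log(counts / counts.sum())
    F = F - F.min()
    return FreeEnergyProfile(centers, F, counts, temperature)


def helicity_from_angles(
    angles_deg: np.ndarray, dt: float, debounce: float = 100.0
) -> HelicityTrace:
    """Helicity trace from the signed overall-helicity dihedral series.

    theta = sign(angle); frames with angle exactly 0 or +-180 inherit the
    previous theta.  Sign changes that revert within the debounce window
    are treated as barrier recrossings and not counted as flips.
    """
    angles = np.asarray(angles_deg, dtype=float)
    raw = np.sign(angles)
    ties = (raw == 0) | (np.abs(np.abs(angles) - 180.0) < 1e-12)
    theta = raw.copy()
    if ties.any():
        idx = np.flatnonzero(ties)
        for i in idx:  # inherit previous state (first frame: next state)
            theta[i] = theta[i - 1] if i > 0 else 0.0
        if theta[0] == 0.0:
            nz = np.flatnonzero(theta != 0)
            theta[0] = theta[nz[0]] if nz.size else 1.0
            for i in np.flatnonzero(theta == 0):
                theta[i] = theta[i - 1]
    # run-length encode and merge runs shorter than the debounce window
    change = np.flatnonzero(np.diff(theta) != 0) + 1
    starts = np.concatenate(([0], change))
    lengths = np.diff(np.concatenate((starts, [len(theta)])))
    states = theta[starts]
    min_len = max(int(np.ceil(debounce / dt)), 1)
    merged_states: list[float] = []
    merged_lengths: list[int] = []
    for s, ln in zip(states, lengths):
        if merged_states and (ln < min_len or s == merged_states[-1]):
            # too-short excursion: absorb into the current state
            if s != merged_states[-1] and ln >= min_len:
                merged_states.append(s)
                merged_lengths.append(int(ln))
            else:
                merged_lengths[-1] += int(ln)
        else:
            merged_states.append(s)
            merged_lengths.append(int(ln))
    # a leading too-short run is absorbed forward
    while len(merged_states) > 1 and merged_lengths[0] < min_len:
        merged_lengths[1] += merged_lengths[0]
        merged_states.pop(0)
        merged_lengths.pop(0)
        if len(merged_states) > 1 and merged_states[0] == merged_states[1]:
            merged_lengths[0] += merged_lengths[1]
            merged_states.pop(1)
            merged_lengths.pop(1)
    boundaries = np.cumsum(merged_lengths)[:-1]
    flip_times = boundaries * dt
    debounced = np.repeat(merged_states, merged_lengths)
    dwell = np.diff(np.concatenate(([0.0], flip_times, [len(theta) * dt])))
    return HelicityTrace(
        theta=debounced,
        dt=dt,
        flip_times=np.asarray(flip_times, dtype=float),
        dwell_times=dwell,
        debounce=debounce,
    )


def helicity_trace(
    traj: Trajectory,
    dihedral_indices: tuple[int, int, int, int],
    debounce: float = 100.0,
) -> HelicityTrace:
    """Helicity trace of a trajectory from its overall-helicity dihedral."""
    angles = dihedral_series(traj.coordinates, dihedral_indices)
    return helicity_from_angles(angles, traj.dt, debounce)


def helicity_lifetime(
    trace: HelicityTrace,
    method: str = "integral",
    threshold: float = 0.01,
) -> LifetimeResult:
    """Helicity lifetime tau_hel from the indicator autocorrelation.

    ``integral``: tau = int_0^T* C(t) dt with T* the first crossing below
    ``threshold``.  ``expfit``: least-squares fit of exp(-t/tau) over the
    same range.  If C never decays below the threshold the result is a
    lower bound and flagged as such.
    """
    theta = trace.theta.astype(float)
    C = autocorrelation(theta, normalize=True)
    # keep at most a quarter of the trace in lags (estimator quality)
    C = C[: max(len(C) // 4, 2)]
    t = np.arange(len(C)) * trace.dt
    below = np.flatnonzero(C < threshold)
    lower_bound = below.size == 0
    t_star = len(C) - 1 if lower_bound else int(below[0])
    if method == "integral":
        tau_fs = float(np.trapezoid(C[: t_star + 1], t[: t_star + 1]))
    elif method == "expfit":
        sel = slice(0, max(t_star, 2))
        csel = np.clip(C[sel], 1e-12, None)
        # log-linear weighted fit of exp(-t/tau)
        w = csel  # weight by magnitude: approximates least squares on C
        p = np.polyfit(t[sel], np.log(csel), 1, w=w)
        tau_fs = float(-1.0 / p[0]) if p[0] < 0 else float("inf")
    else:
        raise InputError("method must be 'integral' or 'expfit'")
    # block uncertainty: four consecutive blocks
    n_blk = 4
    blk = len(theta) // n_blk
    taus = []
    if blk > 10 * max(t_star, 1):
        for b in range(n_blk):
            cb = autocorrelation(theta[b * blk : (b + 1) * blk], normalize=True)
            cb = cb[: t_star + 1]
            taus.append(np.trapezoid(cb, np.arange(len(cb)) * trace.dt))
    unc_fs = float(np.std(taus) / np.sqrt(len(taus))) if len(taus) > 1 else float("nan")
    return LifetimeResult(
        tau_ps=tau_fs / 1000.0,
        uncertainty_ps=unc_fs / 1000.0,
        method=method,
        lower_bound=lower_bound,
        acf_time_fs=t,
        acf=C,
    )


def classify_conformers(
    backbone_dihedrals: np.ndarray, trans_window: float = 60.0
) -> np.ndarray:
    """Per-frame all-trans / gauche-containing classification.

    A frame is all-trans iff every backbone dihedral lies within
    +-trans_window of +-180 deg, i.e. ``|phi| >= 180 - trans_window``
    (closed interval at the window edge).  Returns a boolean array,
    True = all-trans.
    """
    if not (0.0 < trans_window < 180.0):
        raise InputError("trans_window must lie in (0, 180)")
    phi = np.atleast_2d(np.asarray(backbone_dihedrals, dtype=float))
    return np.all(np.abs(phi) >= 180.0 - trans_window, axis=-1)


def _local_minima_periodic(F: np.ndarray) -> np.ndarray:
    prev = np.roll(F, 1)
    nxt = np.roll(F, -1)
    return np.flatnonzero((F < prev) & (F <= nxt) & np.isfinite(F))


def tst_rate(
    profile: FreeEnergyProfile,
    temperature: float | None = None,
    attempt_frequency: float | None = None,
    inertia: float = 1.0,
) -> TSTResult:
    """Transition-state-theory escape rate from the global minimum.

    k_TST = nu_attempt * exp(-dF+ / kT) with the barrier dF+ the lowest
    saddle separating the two deepest minima of the (periodic) profile.
    With ``attempt_frequency`` (ps^-1) given it is used directly; in auto
    mode it is taken from the harmonic curvature at the global minimum,
    nu = sqrt(F''_min / I) / 2 pi with F'' in energy per rad^2 and the
    reduced moment of inertia ``inertia`` (amu A^2).  Because the profile
    alone carries no time scale, auto-mode rates are meaningful mainly as
    ratios between profiles analyzed with the same inertia.
    """
    F = profile.F
    temperature = temperature if temperature is not None else profile.temperature
    minima = _local_minima_periodic(F)
    if minima.size < 2 or not np.isfinite(F).all():
        finite = F[np.isfinite(F)]
        if minima.size < 2 or (finite.max() - finite.min()) < 0.5:
            raise AnalysisError("no barrier found in profile")
    order = np.argsort(F[minima])
    i0, i1 = int(minima[order[0]]), int(minima[order[1]])
    n = len(F)
    lo, hi = sorted((i0, i1))
    arc1 = F[lo : hi + 1]
    arc2 = np.concatenate((F[hi:], F[: lo + 1]))
    barrier = float(min(arc1.max(), arc2.max()) - F[i0])
    if not np.isfinite(barrier) or barrier < 0.5:
        raise AnalysisError("no barrier found in profile")
    if attempt_frequency is None:
        # quadratic fit around the global minimum (+-5 bins, periodic)
        w = 5
        idx = (np.arange(i0 - w, i0 + w + 1)) % n
        x = np.radians(np.arange(-w, w + 1) * profile.bin_width)
        coeff = np.polyfit(x, F[idx], 2)
        curv_kT = 2.0 * coeff[0]  # kT / rad^2
        if curv_kT <= 0:
            raise AnalysisError("non-convex minimum; cannot derive attempt rate")
        curv = curv_kT * KB * temperature  # energy / rad^2
        omega = np.sqrt(curv / inertia)  # rad / fs
        attempt_frequency = omega / (2.0 * np.pi) * 1000.0  # ps^-1
    rate = attempt_frequency * np.exp(-barrier)
    return TSTResult(
        rate_per_ps=float(rate),
        barrier_kT=barrier,
        attempt_frequency_per_ps=float(attempt_frequency),
        minima_deg=profile.angle_grid[minima],
    )
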