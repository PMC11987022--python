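"""Projection of molecular motion onto normal modes, dipole
decomposition, helicity-frozen spectra and event-aligned correlation
functions.

Each frame is assigned a helicity from the sign of the overall-helicity
dihedral, rigid-fitted (carbon subset by default) to the reference of
that helicity, and projected with the mass-weighted scalar product

    q_k(t) = eta_k^(h) . sqrt(m) * (x_fit(t) - x_ref^(h)).

The molecular dipole decomposes into a rigid-body part (the rotated
reference dipole), per-mode vibrational parts mu_k^(h) q_k(t), and an
explicitly stored residual, so every approximation made downstream is
measurable rather than assumed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert

from .errors import InputError
from .modes import NormalModeSet
from .spectra import Spectrum, autocorrelation
from .trajectory import ReferencePair, Trajectory, dihedral_series

__all__ = [
    "ModeTrajectory",
    "DipoleDecomposition",
    "EventAlignedACF",
    "project_onto_modes",
    "decompose_dipole",
    "mode_spectra",
    "helicity_frozen_spectrum",
    "event_aligned_acf",
    "masked_power_spectrum",
]


@dataclass
class ModeTrajectory:
    """Per-mode normal coordinates over time."""

    q: np.ndarray  # (n_modes, T)
    dt: float
    helicity_used: np.ndarray  # (T,) of -1/+1
    frame_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    frequencies: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.frame_mask is None:
            self.frame_mask = np.ones(self.q.shape[1], dtype=bool)
        if len(self.frame_mask) != self.q.shape[1]:
            raise InputError("frame_mask must match the frame count")
        if not np.all(np.isfinite(self.q)):
            raise InputError("non-finite normal coordinates")


@dataclass
class DipoleDecomposition:
    """mu_total = mu_rb + sum_k mu_vib[k] + residual, frame by frame."""

    mu_total: np.ndarray  # (T, 3)
    mu_rb: np.ndarray  # (T, 3)
    mu_vib: np.ndarray  # (n_modes, T, 3)
    residual: np.ndarray  # (T, 3)
    dt: float
    mode_indices: np.ndarray | None = None
    frequencies: np.ndarray | None = None


@dataclass
class EventAlignedACF:
    t_fs: np.ndarray
    conditional: np.ndarray | None
    conditional_envelope: np.ndarray | None
    unconditional: np.ndarray
    unconditional_envelope: np.ndarray
    n_events: int


def _batch_kabsch(
    frames: np.ndarray,
    reference: np.ndarray,
    subset: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized proper-rotation superposition of many frames onto one
    reference.  Returns (rotations (T,3,3), fitted frames (T,n,3), rmsd).

    Reflections are excluded by the determinant sign correction, matching
    :func:`fluorspec.trajectory.rigid_fit`.
    """
    idx = np.asarray(subset, int)
    w = np.ones(idx.size) if weights is None else np.asarray(weights, float)
    a = reference[idx]
    cen_a = np.average(a, axis=0, weights=w)
    a0 = (a - cen_a) * w[:, None]
    b = frames[:, idx, :]
    cen_b = np.average(b, axis=1, weights=w)
    b0 = b - cen_b[:, None, :]
    C = np.einsum("nx,tny->txy", a0, b0)  # target^T W frame
    U, _, Vt = np.linalg.svd(C)
    det = np.linalg.det(np.einsum("txy,tyz->txz", U, Vt))
    D = np.repeat(np.eye(3)[None], len(frames), axis=0)
    D[:, 2, 2] = det
    R = np.einsum("txy,tyz,tzw->txw", U, D, Vt)
    fitted = np.einsum("txy,tay->tax", R, frames - cen_b[:, None, :]) + cen_a
    d = fitted[:, idx, :] - a[None]
    rmsd = np.sqrt(np.sum(w[None, :] * np.sum(d**2, axis=2), axis=1) / w.sum())
    return R, fitted, rmsd


def _fit_metric(
    traj: Trajectory, refs: ReferencePair, fit: str
) -> tuple[np.ndarray, np.ndarray | None]:
    if fit == "eckart":
        return np.arange(traj.n_atoms), traj.masses
    if fit == "carbons":
        return refs.fit_atom_subset, None
    raise InputError("fit must be 'eckart' or 'carbons'")


def _frame_helicity(
    traj: Trajectory, indices: tuple[int, int, int, int]
) -> np.ndarray:
    ang = dihedral_series(traj.coordinates, indices)
    h = np.sign(ang).astype(int)
    # ties inherit the previous frame's assignment
    for i in np.flatnonzero(h == 0):
        h[i] = h[i - 1] if i > 0 else 1
    return h


def project_onto_modes(
    traj: Trajectory,
    refs: ReferencePair,
    modes_minus: NormalModeSet,
    modes_plus: NormalModeSet,
    frame_mask: np.ndarray | None = None,
    fit: str = "eckart",
) -> ModeTrajectory:
    """Project every frame onto the normal modes of its helicity.

    Each frame is rigid-fitted to the matching reference before the
    mass-weighted scalar product.  ``fit='eckart'`` (default) uses a
    mass-weighted all-atom superposition, which is the metric the mode
    vectors are orthogonal to rigid motions in, so a constructed
    single-mode displacement is recovered exactly.  ``fit='carbons'``
    uses the unit-weight carbon-subset fit instead (the usual choice for
    force-field trajectories, where anharmonic deformation makes no fit
    metric exact); results are similar but recovery is only approximate.
    """
    n = traj.n_atoms
    for m in (modes_minus, modes_plus):
        if m.eta.shape[1] != 3 * n:
            raise InputError("mode vectors do not match the atom count")
    if modes_minus.n_modes != modes_plus.n_modes:
        raise InputError("helicity mode sets must pair one-to-one")
    h = _frame_helicity(traj, refs.helicity_dihedral)
    sqm = np.sqrt(traj.masses)
    subset, weights = _fit_metric(traj, refs, fit)
    q = np.empty((modes_minus.n_modes, traj.n_frames))
    for hel, modes in ((-1, modes_minus), (1, modes_plus)):
        sel = h == hel
        if not sel.any():
            continue
        ref = refs.reference(hel)
        _, fitted, _ = _batch_kabsch(
            traj.coordinates[sel], ref, subset, weights
        )
        disp = (fitted - ref[None]) * sqm[None, :, None]
        q[:, sel] = modes.eta @ disp.reshape(sel.sum(), 3 * n).T
    return ModeTrajectory(
        q=q,
        dt=traj.dt,
        helicity_used=h,
        frame_mask=(
            np.ones(traj.n_frames, bool) if frame_mask is None else frame_mask
        ),
        frequencies=modes_minus.frequencies,
    )


def decompose_dipole(
    traj: Trajectory,
    refs: ReferencePair,
    modes_minus: NormalModeSet,
    modes_plus: NormalModeSet,
    charges: np.ndarray | None = None,
    mode_indices: np.ndarray | None = None,
    fit: str = "eckart",
) -> DipoleDecomposition:
    """Decompose the point-charge molecular dipole into rigid-body,
    per-mode vibrational, and residual parts (lab frame)."""
    charges = traj.charges if charges is None else np.asarray(charges, float)
    h = _frame_helicity(traj, refs.helicity_dihedral)
    sqm = np.sqrt(traj.masses)
    subset, weights = _fit_metric(traj, refs, fit)
    n = traj.n_atoms
    n_modes = modes_minus.n_modes
    midx = np.arange(n_modes) if mode_indices is None else np.asarray(mode_indices)
    mu_total = np.einsum("a,tax->tx", charges, traj.coordinates)
    mu_rb = np.empty((traj.n_frames, 3))
    mu_vib = np.empty((len(midx), traj.n_frames, 3))
    for hel, modes in ((-1, modes_minus), (1, modes_plus)):
        sel = h == hel
        if not sel.any():
            continue
        ref = refs.reference(hel)
        R, fitted, _ = _batch_kabsch(traj.coordinates[sel], ref, subset, weights)
        mu_ref = charges @ ref
        # R maps lab -> reference frame; its transpose carries reference
        # vectors back into the lab frame
        mu_rb[sel] = np.einsum("tyx,y->tx", R, mu_ref)
        disp = (fitted - ref[None]) * sqm[None, :, None]
        q = modes.eta[midx] @ disp.reshape(sel.sum(), 3 * n).T  # (k, Tsel)
        tdip = modes.transition_dipoles[midx]  # (k, 3), reference frame
        mu_vib[:, sel, :] = np.einsum("tyx,ky,kt->ktx", R, tdip, q)
    residual = mu_total - mu_rb - mu_vib.sum(axis=0)
    return DipoleDecomposition(
        mu_total=mu_total,
        mu_rb=mu_rb,
        mu_vib=mu_vib,
        residual=residual,
        dt=traj.dt,
        mode_indices=midx,
        frequencies=modes_minus.frequencies[midx],
    )


def masked_power_spectrum(
    x: np.ndarray,
    dt: float,
    mask: np.ndarray | None = None,
    nperseg: int = 4096,
    window: str = "hann",
    overlap: float = 0.5,
    derivative: bool = False,
) -> Spectrum:
    """Welch power spectrum restricted to contiguous unmasked runs.

    Masked frames (e.g. gauche conformers) are handled by splitting the
    series into contiguous valid runs and windowing each run into
    fixed-length segments, rather than zero-filling, which would distort
    line shapes.  Runs shorter than ``nperseg`` are dropped.
    """
    from .constants import C_CM_PER_FS

    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    T = x.shape[0]
    mask = np.ones(T, bool) if mask is None else np.asarray(mask, bool)
    if window == "hann":
        w = np.hanning(nperseg)
    elif window == "none":
        w = np.ones(nperseg)
    else:
        raise InputError("window must be 'none' or 'hann'")
    step = max(int(nperseg * (1 - overlap)), 1)
    # contiguous True runs
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    acc = None
    count = 0
    for start, stop in zip(edges[::2], edges[1::2]):
        run = x[start:stop]
        if derivative:
            if len(run) < 3:
                continue
            run = np.gradient(run, dt, axis=0)
        for s in range(0, len(run) - nperseg + 1, step):
            seg = run[s : s + nperseg]
            seg = seg - seg.mean(axis=0, keepdims=True)
            f = np.fft.rfft(seg * w[:, None], axis=0)
            p = np.sum(np.abs(f) ** 2, axis=1)
            acc = p if acc is None else acc + p
            count += 1
    if count == 0:
        raise InputError(
            f"no contiguous unmasked run of at least {nperseg} frames"
        )
    freqs = np.fft.rfftfreq(nperseg, d=dt)
    norm = dt / (nperseg * np.mean(w**2)) * C_CM_PER_FS
    power = norm * acc / count
    power = 2.0 * power
    power[0] /= 2.0
    if nperseg % 2 == 0:
        power[-1] /= 2.0
    return Spectrum(
        freqs / C_CM_PER_FS,
        power,
        "power",
        {"nperseg": nperseg, "n_averages": count, "window": window},
    )


def mode_spectra(
    decomposition: DipoleDecomposition,
    nperseg: int = 4096,
    mask: np.ndarray | None = None,
) -> dict:
    """Per-mode vibrational dipole power spectra S_mudot-mudot.

    Returns a dict with per-mode spectra, the spectrum of the summed
    vibrational dipole, the sum of per-mode spectra, and the relative
    cross-term magnitude (their integrated difference), which measures
    how well the modes decouple.
    """
    T = decomposition.mu_total.shape[0]
    if T < 2**12:
        warnings.warn("fewer than 4096 frames; spectra will be coarse", stacklevel=2)
    dt = decomposition.dt
    per_mode = [
        masked_power_spectrum(mv, dt, mask, nperseg, derivative=True)
        for mv in decomposition.mu_vib
    ]
    total_vib = masked_power_spectrum(
        decomposition.mu_vib.sum(axis=0), dt, mask, nperseg, derivative=True
    )
    sum_modes = Spectrum(
        total_vib.nu,
        np.sum([s.values for s in per_mode], axis=0),
        "power",
        {"nperseg": nperseg},
    )
    denom = total_vib.integrate()
    cross = (
        abs(total_vib.integrate() - sum_modes.integrate()) / denom
        if denom > 0
        else 0.0
    )
    return {
        "per_mode": per_mode,
        "total_vib": total_vib,
        "sum_of_modes": sum_modes,
        "cross_term_fraction": cross,
        "frequencies": decomposition.frequencies,
    }


def helicity_frozen_spectrum(
    mode_traj: ModeTrajectory,
    modes: NormalModeSet,
    mode_index: int,
    nperseg: int = 4096,
) -> Spectrum:
    """Hypothetical no-dipole-rotation spectrum |mu_k^-|^2 S_qdot-qdot.

    Setting mu_k^- - mu_k^+ = 0 removes every helicity-reversal term from
    the vibrational dipole spectrum, leaving the bare normal-coordinate
    spectrum scaled by the squared transition dipole.
    """
    q = mode_traj.q[mode_index]
    s_q = masked_power_spectrum(
        q, mode_traj.dt, mode_traj.frame_mask, nperseg, derivative=True
    )
    mu2 = float(np.sum(modes.transition_dipoles[mode_index] ** 2))
    return Spectrum(
        s_q.nu,
        mu2 * s_q.values,
        "power",
        {**s_q.metadata, "frozen": True, "mu_sq": mu2},
    )


def event_aligned_acf(
    mu_vib_k: np.ndarray,
    events_fs: np.ndarray,
    dt: float,
    offset: float = 200.0,
    window: float = 2000.0,
) -> EventAlignedACF:
    """Conditional dipole ACF over sub-trajectories with a helicity flip
    at the stated offset, plus the unconditional ACF for comparison.

    Each event window starts ``offset`` fs before its flip; the
    single-origin products mu(t0).mu(t0+t) are averaged over events and
    normalized by the mean squared dipole at the origin.  Envelopes are
    analytic-signal magnitudes.
    """
    x = np.asarray(mu_vib_k, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    T = x.shape[0]
    n_lag = int(window / dt)
    off = int(offset / dt)
    starts = (np.asarray(events_fs, float) / dt).astype(int) - off
    starts = starts[(starts >= 0) & (starts + n_lag < T)]
    n_events = len(starts)
    uncond = autocorrelation(x, normalize=True)[: n_lag + 1]
    t = np.arange(n_lag + 1) * dt
    cond = env = None
    if n_events == 0:
        warnings.warn("no usable events; conditional ACF undefined", stacklevel=2)
    else:
        if n_events < 20:
            warnings.warn(
                f"only {n_events} events; conditional ACF will be noisy",
                stacklevel=2,
            )
        prods = np.array(
            [np.sum(x[s] * x[s : s + n_lag + 1], axis=1) for s in starts]
        )
        norm = np.mean(np.sum(x[starts] ** 2, axis=1))
        cond = prods.mean(axis=0) / norm
        env = np.abs(hilbert(cond))
    return EventAlignedACF(
        t_fs=t,
        conditional=cond,
        conditional_envelope=env,
        unconditional=uncond,
        unconditional_envelope=np.abs(hilbert(uncond)),
        n_events=n_events,
    )
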