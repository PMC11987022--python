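"""Synthetic generators with the statistical structure the analysis
pipeline assumes: helical-chain reference geometries, spring-network
Hessians, underdamped Langevin mode dynamics with telegraph helicity
flips, point-charge dipoles, and forward-modelled ATR spectra.

The model chain is a carbon backbone with two pendant pseudo-fluorine
sites per carbon.  The two reference conformers are exact mirror images:
left- and right-handed helices whose interior backbone dihedrals sit at
+-(180 - twist_per_dihedral) degrees, with the outer dihedrals
calibrated so the overall-helicity dihedral (atoms 1, 2, n-1, n of the
backbone) deviates from trans by exactly ``overall_twist`` degrees.

Mode dynamics are generated by the *exact* discretization of the
underdamped Langevin oscillator (an ARMA(2,1) recursion derived from the
continuous transition matrix), so equipartition and the Lorentzian
line shape of each mode hold without time-step error.  Helicity is an
independent telegraph process: flips instantaneously swap the reference
geometry and rotate every transition dipole by ``dipole_rotation_angle``
about the chain axis, isolating the conformational-exchange broadening
mechanism from barrier-crossing details.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import brentq
from scipy.signal import lfilter
from scipy.spatial.transform import Rotation

from .constants import KB, wavenumber_to_omega
from .errors import ConfigError, InputError
from .ftir import ExperimentalSpectrum, hilbert_conjugate
from .modes import NormalModeSet, compute_normal_modes
from .spectra import DipoleTrace, Spectrum
from .trajectory import ReferencePair, Trajectory, dihedral_angle

__all__ = [
    "GeneratorConfig",
    "HelicalSystem",
    "SyntheticDynamics",
    "gen_helical_references",
    "gen_mode_dynamics",
    "gen_concentration_series",
    "gen_atr_spectrum",
    "langevin_mode",
    "telegraph_process",
]

_MASS_C = 12.011
_MASS_F = 18.998403
_CHARGE_F = -0.2


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic system.

    Rates are per picosecond, angles in degrees, times in femtoseconds.
    ``flip_rate`` is the per-direction helicity flip rate (so the
    helicity lifetime of the telegraph process is 1/(2 flip_rate)).
    """

    n_carbons: int = 6
    twist_per_dihedral: float = 17.0
    overall_twist: float = 35.0
    mode_frequencies: tuple = (1135.0, 1218.0, 1276.0)  # cm^-1
    mode_damping: tuple = (0.5,)  # ps^-1, broadcast over modes
    flip_rate: float = 1.0 / (2.0 * 2.9)  # ps^-1; dilute-solution value
    dipole_rotation_angle: float = 10.0  # deg between mu_k^+ and mu_k^-
    dt: float = 1.0  # fs
    n_steps: int = 2**16
    n_steps_trajectory: int | None = None  # cap for coordinate playback
    temperature: float = 300.0  # K
    seed: int = 0
    # geometry and spring-network parameters (internal units)
    bond_cc: float = 1.54  # A
    bond_cf: float = 1.35  # A
    angle_ccc: float = 114.0  # deg
    angle_fcf: float = 107.0  # deg
    k_bond_cc: float = 0.24  # amu A^2 fs^-2 / A^2  (2400 kJ/mol/A^2)
    k_bond_cf: float = 0.33  # chosen so the strongest IR modes fall in
    # the 1000-1300 cm^-1 C-F stretching band
    k_angle: float = 0.06  # per rad^2
    k_dihedral: float = 0.05  # per rad^2; stiff enough that thermal
    # torsional motion stays harmonic and never crosses the helicity
    # branch (helicity changes only through explicit telegraph flips)

    def __post_init__(self) -> None:
        if self.flip_rate < 0:
            raise ConfigError("flip_rate must be >= 0")
        if any(f <= 0 for f in self.mode_frequencies):
            raise ConfigError("mode frequencies must be positive")
        if any(g <= 0 for g in self.mode_damping):
            raise ConfigError("mode dampings must be positive")
        if self.dt <= 0 or self.n_steps < 2:
            raise ConfigError("dt must be positive and n_steps >= 2")

    def replace(self, **kw) -> "GeneratorConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class HelicalSystem:
    """Mirror reference pair with Hessians, modes and topology."""

    refs: ReferencePair
    hessian_minus: np.ndarray
    hessian_plus: np.ndarray
    modes_minus: NormalModeSet
    modes_plus: NormalModeSet
    masses: np.ndarray
    charges: np.ndarray
    topology: pd.DataFrame
    config: GeneratorConfig


@dataclass
class SyntheticDynamics:
    """Ground-truth-bearing synthetic trajectory bundle."""

    trajectory: Trajectory
    dipole: DipoleTrace
    q: np.ndarray  # (n_modes, n_steps)
    helicity: np.ndarray  # (n_steps,) of +-1
    flip_times_fs: np.ndarray
    mode_indices: np.ndarray
    system: HelicalSystem
    config: GeneratorConfig
    mu_plus: np.ndarray | None = None  # (n_modes, 3) transition dipoles
    mu_minus: np.ndarray | None = None  # rotated set used for h = -1

    def mode_dipole_trace(self, local_index: int) -> np.ndarray:
        """(T, 3) vibrational dipole mu_k^h(t) q_k(t) of one selected
        mode, with the helicity-dependent transition dipole."""
        mu = np.where(
            (self.helicity > 0)[:, None],
            self.mu_plus[local_index][None],
            self.mu_minus[local_index][None],
        )
        return mu * self.q[local_index][:, None]


# ---------------------------------------------------------------- geometry


def _place_nerf(a, b, c, bond, angle_deg, dih_deg):
    ang = np.radians(angle_deg)
    # the -cos(ang) axis convention below realizes a dihedral of
    # 180 - dih for the raw spherical angle, so convert up front
    dih = np.radians(180.0 - dih_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(a - b, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array(
        [
            -bond * np.cos(ang),
            bond * np.sin(ang) * np.cos(dih),
            bond * np.sin(ang) * np.sin(dih),
        ]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


def _backbone(n, interior_twist, outer_twist, bond, angle, sign):
    dihs = [sign * (180.0 - outer_twist)]
    dihs += [sign * (180.0 - interior_twist)] * max(n - 5, 0)
    if n >= 6:
        dihs += [sign * (180.0 - outer_twist)]
    dihs = dihs[: n - 3]
    xs = [np.zeros(3), np.array([bond, 0.0, 0.0])]
    xs.append(
        _place_nerf(np.array([0.0, 0.0, 1.0]), xs[0], xs[1], bond, angle, 90.0)
    )
    for i in range(3, n):
        xs.append(_place_nerf(xs[i - 3], xs[i - 2], xs[i - 1], bond, angle, dihs[i - 3]))
    return np.array(xs)


def _overall_twist_of(backbone: np.ndarray) -> float:
    n = len(backbone)
    phi = dihedral_angle(backbone, (0, 1, n - 2, n - 1))
    return 180.0 - abs(phi)


def _add_fluorines(backbone: np.ndarray, bond_cf: float, angle_fcf: float):
    """Two pendant pseudo-fluorine sites per carbon, symmetric about the
    local backbone plane."""
    n = len(backbone)
    half = np.radians(angle_fcf) / 2.0
    fl = []
    for i in range(n):
        if 0 < i < n - 1:
            u = backbone[i - 1] - backbone[i]
            v = backbone[i + 1] - backbone[i]
            u /= np.linalg.norm(u)
            v /= np.linalg.norm(v)
            bis = -(u + v)
            nrm = np.cross(u, v)
        else:
            # terminal carbon: tilt away from the single neighbor, with
            # the out-of-plane normal taken from the adjacent bond pair
            j = 1 if i == 0 else n - 2
            jj = 2 if i == 0 else n - 3
            v = backbone[j] - backbone[i]
            v /= np.linalg.norm(v)
            w = backbone[jj] - backbone[j]
            bis = -(v + 0.3 * w / np.linalg.norm(w))
            nrm = np.cross(v, w)
        bis /= np.linalg.norm(bis)
        nrm /= np.linalg.norm(nrm)
        for s in (+1.0, -1.0):
            d = np.cos(half) * bis + s * np.sin(half) * nrm
            d /= np.linalg.norm(d)
            fl.append(backbone[i] + bond_cf * d)
    return np.array(fl)


def _build_reference(config: GeneratorConfig, sign: int) -> np.ndarray:
    n = config.n_carbons
    tw = config.twist_per_dihedral

    if n >= 6 and config.overall_twist is not None:

        def gap(outer):
            bb = _backbone(n, tw, outer, config.bond_cc, config.angle_ccc, sign)
            return _overall_twist_of(bb) - config.overall_twist

        try:
            outer = brentq(gap, 0.0, 60.0, xtol=1e-10)
        except ValueError:
            outer = tw
    else:
        outer = tw
    bb = _backbone(n, tw, outer, config.bond_cc, config.angle_ccc, sign)
    fl = _add_fluorines(bb, config.bond_cf, config.angle_fcf)
    return np.vstack((bb, fl))


# ------------------------------------------------------- spring Hessian


def _bond_grad(x, i, j):
    d = x[i] - x[j]
    r = np.linalg.norm(d)
    g = np.zeros_like(x)
    g[i] = d / r
    g[j] = -d / r
    return g


def _angle_grad(x, i, j, k):
    u = x[i] - x[j]
    v = x[k] - x[j]
    nu_, nv = np.linalg.norm(u), np.linalg.norm(v)
    uh, vh = u / nu_, v / nv
    cos = np.clip(uh @ vh, -1.0, 1.0)
    sin = np.sqrt(max(1.0 - cos**2, 1e-14))
    g = np.zeros_like(x)
    g[i] = (cos * uh - vh) / (nu_ * sin)
    g[k] = (cos * vh - uh) / (nv * sin)
    g[j] = -(g[i] + g[k])
    return g


def _dihedral_grad(x, i, j, k, l):
    b1 = x[j] - x[i]
    b2 = x[k] - x[j]
    b3 = x[l] - x[k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    # signs follow this package's dihedral convention (mirror image of
    # the Blondel-Karplus one); verified against finite differences
    gi = nb2 / (n1 @ n1) * n1
    gl = -nb2 / (n2 @ n2) * n2
    d12 = (b1 @ b2) / nb2**2
    d32 = (b3 @ b2) / nb2**2
    g = np.zeros_like(x)
    g[i] = gi
    g[l] = gl
    g[j] = -(1.0 + d12) * gi + d32 * gl
    g[k] = d12 * gi - (1.0 + d32) * gl
    return g


def _spring_terms(config: GeneratorConfig):
    """(kind, atoms, force constant) list for the chain topology."""
    n = config.n_carbons
    terms = []
    for i in range(n - 1):
        terms.append(("bond", (i, i + 1), config.k_bond_cc))
    for i in range(n):
        for s in range(2):
            terms.append(("bond", (i, n + 2 * i + s), config.k_bond_cf))
    for i in range(n - 2):
        terms.append(("angle", (i, i + 1, i + 2), config.k_angle))
    for i in range(n):
        f1, f2 = n + 2 * i, n + 2 * i + 1
        terms.append(("angle", (f1, i, f2), config.k_angle))
        for f in (f1, f2):
            if i > 0:
                terms.append(("angle", (f, i, i - 1), config.k_angle))
            if i < n - 1:
                terms.append(("angle", (f, i, i + 1), config.k_angle))
    for i in range(n - 3):
        terms.append(("dihedral", (i, i + 1, i + 2, i + 3), config.k_dihedral))
    # lock terminal CF2 rotation about the end C-C bonds
    for f in (n, n + 1):
        terms.append(("dihedral", (f, 0, 1, 2), config.k_dihedral))
    for f in (n + 2 * (n - 1), n + 2 * (n - 1) + 1):
        terms.append(("dihedral", (f, n - 1, n - 2, n - 3), config.k_dihedral))
    return terms


def _spring_hessian(x: np.ndarray, config: GeneratorConfig) -> np.ndarray:
    """Gauss-Newton Hessian sum_t k_t g_t g_t^T, exact at the reference
    geometry where every spring is at its minimum."""
    n3 = 3 * len(x)
    H = np.zeros((n3, n3))
    for kind, atoms, k in _spring_terms(config):
        if kind == "bond":
            g = _bond_grad(x, *atoms)
        elif kind == "angle":
            g = _angle_grad(x, *atoms)
        else:
            g = _dihedral_grad(x, *atoms)
        gv = g.ravel()
        H += k * np.outer(gv, gv)
    return H


def gen_helical_references(config: GeneratorConfig | None = None) -> HelicalSystem:
    """Mirror pair of helical references with spring Hessians and modes.

    Chains shorter than four carbons have no helical minimum (they are
    planar), so ``n_carbons < 4`` is a configuration error.
    """
    config = config or GeneratorConfig()
    n = config.n_carbons
    if n < 4:
        raise ConfigError(
            "n_carbons must be >= 4: shorter chains are planar and have "
            "no distinct helicity"
        )
    x_plus = _build_reference(config, +1)
    x_minus = x_plus.copy()
    x_minus[:, 2] *= -1.0  # exact mirror image
    n_atoms = len(x_plus)
    masses = np.concatenate((np.full(n, _MASS_C), np.full(2 * n, _MASS_F)))
    charges = np.concatenate(
        (np.full(n, -2.0 * _CHARGE_F), np.full(2 * n, _CHARGE_F))
    )
    refs = ReferencePair(
        x_ref_minus=x_minus,
        x_ref_plus=x_plus,
        fit_atom_subset=np.arange(n),
        helicity_dihedral=(0, 1, n - 2, n - 1),
    )
    H_plus = _spring_hessian(x_plus, config)
    H_minus = _spring_hessian(x_minus, config)
    modes_plus = compute_normal_modes(H_plus, masses, x_plus, charges, +1)
    # the minus conformer is the exact mirror image, so its mode set is
    # obtained by mirroring the plus eigenvectors (H- = S H+ S); this
    # keeps mode ordering, signs and degenerate subspaces consistent
    # between the two helicities, which independent diagonalization
    # would scramble
    eta_m = modes_plus.eta.reshape(modes_plus.n_modes, n_atoms, 3).copy()
    eta_m[:, :, 2] *= -1.0
    cart_m = modes_plus.cart_disp.copy()
    cart_m[:, :, 2] *= -1.0
    modes_minus = NormalModeSet(
        frequencies=modes_plus.frequencies.copy(),
        eta=eta_m.reshape(modes_plus.n_modes, -1),
        cart_disp=cart_m,
        transition_dipoles=np.einsum("a,kax->kx", charges, cart_m),
        helicity=-1,
        n_removed=modes_plus.n_removed,
        imaginary=modes_plus.imaginary.copy(),
        masses=masses,
        reference=x_minus,
        charges=charges,
    )
    topology = pd.DataFrame(
        {
            "atom_index": np.arange(n_atoms),
            "element": ["C"] * n + ["F"] * (2 * n),
            "mass": masses,
            "charge": charges,
            "molecule_id": np.zeros(n_atoms, dtype=int),
        }
    )
    return HelicalSystem(
        refs=refs,
        hessian_minus=H_minus,
        hessian_plus=H_plus,
        modes_minus=modes_minus,
        modes_plus=modes_plus,
        masses=masses,
        charges=charges,
        topology=topology,
        config=config,
    )


# ------------------------------------------------------- stochastic engine


def langevin_mode(
    nu0_cm: float,
    damping_per_ps: float,
    kT: float,
    n_steps: int,
    dt: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Exact-discretization trajectory of an underdamped Langevin
    oscillator (mass-weighted coordinate, stationary start).

    The sampled process is the ARMA(2,1) implied by the continuous
    transition matrix, so <q^2> = kT/omega0^2 and the Lorentzian line
    shape hold exactly at any time step.
    """
    w0 = wavenumber_to_omega(nu0_cm)
    gamma = damping_per_ps / 1000.0  # fs^-1
    M = np.array([[0.0, 1.0], [-(w0**2), -gamma]])
    A = expm(M * dt)
    P = np.diag([kT / w0**2, kT])
    Q = P - A @ P @ A.T
    a1 = np.trace(A)
    a2 = -np.linalg.det(A)
    h = np.array([1.0, 0.0])
    B = A - a1 * np.eye(2)
    r0 = h @ Q @ h + h @ B @ Q @ B.T @ h
    r1 = h @ B @ Q @ h
    disc = np.sqrt(max(r0**2 - 4.0 * r1**2, 0.0))
    if abs(r1) < 1e-300:
        c_ma, s2 = 0.0, r0
    else:
        c_ma = (r0 - disc) / (2.0 * r1)
        s2 = r1 / c_ma
    burn = int(20.0 / (gamma * dt))
    e = rng.normal(0.0, np.sqrt(s2), n_steps + burn)
    return lfilter([1.0, c_ma], [1.0, -a1, -a2], e)[burn:]


def telegraph_process(
    rate_per_ps: float,
    n_steps: int,
    dt: float,
    rng: np.random.Generator,
    start: int = +1,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-state Markov jump process; returns (state array, flip times fs)."""
    t_total = n_steps * dt
    if rate_per_ps <= 0:
        return np.full(n_steps, start, dtype=float), np.empty(0)
    rate = rate_per_ps / 1000.0  # fs^-1
    n_exp = int(t_total * rate * 3) + 100
    times = np.cumsum(rng.exponential(1.0 / rate, size=n_exp))
    while times[-1] < t_total:
        extra = np.cumsum(rng.exponential(1.0 / rate, size=n_exp)) + times[-1]
        times = np.concatenate((times, extra))
    times = times[times < t_total]
    flips = np.zeros(n_steps)
    np.add.at(flips, (times / dt).astype(int), 1.0)
    state = start * (-1.0) ** np.cumsum(flips)
    return state, times


def _rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    return Rotation.from_rotvec(np.radians(angle_deg) * axis).as_matrix()


def gen_mode_dynamics(
    config: GeneratorConfig,
    system: HelicalSystem | None = None,
    mode_indices: np.ndarray | None = None,
) -> SyntheticDynamics:
    """Langevin mode dynamics with telegraph helicity flips.

    Every vibrational mode of the reference pair evolves as an
    independent thermal Langevin oscillator; the helicity state swaps
    reference geometry and transition-dipole set instantaneously.  The
    returned dipole trace is the mode-resolved point-charge dipole
    mu(t) = mu_ref^h(t) + sum_k mu_k^h(t) q_k(t), with the minus-helicity
    transition dipoles obtained by rotating the plus set by
    ``dipole_rotation_angle`` about the chain axis.  Coordinates are
    reconstructed for the first ``n_steps_trajectory`` frames (default
    min(n_steps, 65536)) to bound memory.
    """
    system = system or gen_helical_references(config)
    modes_p, modes_m = system.modes_plus, system.modes_minus
    if mode_indices is None:
        mode_indices = np.flatnonzero(modes_p.frequencies > 10.0)
    mode_indices = np.asarray(mode_indices, int)
    freqs = modes_p.frequencies[mode_indices]
    nu_max = float(freqs.max())
    period_fs = 1.0 / (nu_max * 2.99792458e-5)
    if config.dt > period_fs / 10.0:
        raise ConfigError(
            f"dt={config.dt} fs too large: highest mode at {nu_max:.0f} cm^-1 "
            f"needs dt <= {period_fs / 10.0:.2f} fs"
        )
    damp = np.asarray(config.mode_damping, float)
    if damp.size == 1:
        damp = np.full(len(mode_indices), damp[0])
    elif damp.size != len(mode_indices):
        raise ConfigError("mode_damping must broadcast over selected modes")
    ss = np.random.SeedSequence(config.seed)
    child = ss.spawn(len(mode_indices) + 1)
    kT = KB * config.temperature
    q = np.empty((len(mode_indices), config.n_steps))
    for a, (k, g) in enumerate(zip(mode_indices, damp)):
        rng = np.random.default_rng(child[a])
        q[a] = langevin_mode(
            modes_p.frequencies[k], g, kT, config.n_steps, config.dt, rng
        )
    rng_tel = np.random.default_rng(child[-1])
    helicity, flip_times = telegraph_process(
        config.flip_rate, config.n_steps, config.dt, rng_tel
    )
    # transition dipoles: the minus set is the plus set rotated by the
    # requested angle.  The rotation axis is the chain axis
    # orthogonalized against each mode's dipole so that the angle
    # between mu_k^+ and mu_k^- equals dipole_rotation_angle exactly
    # regardless of the dipole's orientation.
    bb = system.refs.x_ref_plus[: config.n_carbons]
    axis = bb[-1] - bb[0]
    axis /= np.linalg.norm(axis)
    mu_p = modes_p.transition_dipoles[mode_indices]  # (k, 3)
    mu_m = np.empty_like(mu_p)
    for a, mu in enumerate(mu_p):
        norm = np.linalg.norm(mu)
        if norm < 1e-300:
            mu_m[a] = mu
            continue
        mu_hat = mu / norm
        perp = axis - (axis @ mu_hat) * mu_hat
        if np.linalg.norm(perp) < 1e-8:  # dipole parallel to the chain
            perp = np.cross(mu_hat, [0.0, 0.0, 1.0])
            if np.linalg.norm(perp) < 1e-8:
                perp = np.cross(mu_hat, [0.0, 1.0, 0.0])
        mu_m[a] = _rotation_about_axis(perp, config.dipole_rotation_angle) @ mu
    mu_ref_p = system.charges @ system.refs.x_ref_plus
    mu_ref_m = system.charges @ system.refs.x_ref_minus
    plus = helicity > 0
    mu = np.where(plus[:, None], mu_ref_p[None], mu_ref_m[None]).astype(float)
    mu += np.einsum("kt,kx,t->tx", q, mu_p, plus.astype(float))
    mu += np.einsum("kt,kx,t->tx", q, mu_m, (~plus).astype(float))
    dipole = DipoleTrace(mu, config.dt, label="synthetic molecule")
    # coordinate playback (bounded)
    n_traj = config.n_steps_trajectory or min(config.n_steps, 65536)
    n_traj = min(n_traj, config.n_steps)
    plus_t = plus[:n_traj]
    coords = np.where(
        plus_t[:, None, None],
        system.refs.x_ref_plus[None],
        system.refs.x_ref_minus[None],
    ).astype(np.float32)
    cart_p = modes_p.cart_disp[mode_indices]
    cart_m = modes_m.cart_disp[mode_indices]
    qt = q[:, :n_traj]
    coords += np.einsum(
        "kt,kax,t->tax", qt, cart_p, plus_t.astype(float)
    ).astype(np.float32)
    coords += np.einsum(
        "kt,kax,t->tax", qt, cart_m, (~plus_t).astype(float)
    ).astype(np.float32)
    traj = Trajectory(
        coordinates=coords,
        dt=config.dt,
        masses=system.masses,
        charges=system.charges,
        atom_labels=[
            f"{e}{i}" for i, e in enumerate(system.topology["element"])
        ],
        molecule_ids=system.topology["molecule_id"].to_numpy(),
    )
    return SyntheticDynamics(
        trajectory=traj,
        dipole=dipole,
        q=q,
        helicity=helicity,
        flip_times_fs=flip_times,
        mode_indices=mode_indices,
        system=system,
        config=config,
        mu_plus=mu_p,
        mu_minus=mu_m,
    )


@dataclass
class ConcentrationPoint:
    label: object
    flip_rate: float
    dynamics: SyntheticDynamics


def gen_concentration_series(
    config: GeneratorConfig,
    flip_rates: list[float],
    labels: list | None = None,
    system: HelicalSystem | None = None,
    mode_indices: np.ndarray | None = None,
) -> list[ConcentrationPoint]:
    """One dataset per flip rate with identical potential and
    thermodynamics: only the helicity kinetics differ, emulating a
    concentration series in which the free-energy landscape is fixed
    while the environment accelerates helicity reversal.

    All points share the same master seed (common random numbers), so
    the vibrational noise is matched across the series and differences
    between points reflect the flip kinetics alone.
    """
    if len(flip_rates) < 2:
        raise ConfigError("need at least 2 flip rates")
    labels = list(flip_rates) if labels is None else list(labels)
    if len(set(map(str, labels))) != len(labels):
        raise ConfigError("duplicate labels in concentration series")
    if len(labels) != len(flip_rates):
        raise ConfigError("labels must align with flip rates")
    system = system or gen_helical_references(config)
    out = []
    for lab, rate in zip(labels, flip_rates):
        sub = config.replace(flip_rate=rate)
        dyn = gen_mode_dynamics(sub, system=system, mode_indices=mode_indices)
        out.append(ConcentrationPoint(label=lab, flip_rate=rate, dynamics=dyn))
    return out


# ------------------------------------------------------------ ATR forward


def gen_atr_spectrum(
    oscillators: list[tuple[float, float, float]],
    mixing_phase: float = 90.0,
    snr: float = np.inf,
    grid: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[ExperimentalSpectrum, Spectrum]:
    """Forward-model an ATR trace from a Lorentzian-oscillator dielectric
    function.

    Each oscillator is (center cm^-1, strength, width cm^-1); Im(eps) is
    the standard damped-oscillator absorption band.  The ATR trace mixes
    Im(eps) with its Hilbert conjugate at ``mixing_phase`` degrees and
    adds Gaussian noise at the stated peak signal-to-noise ratio.
    Returns the spectrum and the ground-truth Im(eps).
    """
    if grid is None:
        grid = np.arange(900.0, 1500.0, 0.5)
    if len(oscillators) == 0:
        raise InputError("need at least one oscillator")
    nu = np.asarray(grid, float)
    im_eps = np.zeros_like(nu)
    for c, s, w in oscillators:
        if not (nu[0] <= c <= nu[-1]):
            raise InputError(f"oscillator center {c} outside the grid")
        im_eps += s * w * nu * c / ((c**2 - nu**2) ** 2 + (w * nu) ** 2)
    phi = np.radians(mixing_phase)
    trace = np.cos(phi) * im_eps + np.sin(phi) * hilbert_conjugate(im_eps)
    if np.isfinite(snr):
        rng = np.random.default_rng(seed)
        trace = trace + rng.normal(0.0, im_eps.max() / snr, size=nu.shape)
    exp = ExperimentalSpectrum(
        nu,
        trace,
        acquisition="ATR",
        resolution=float(np.median(np.diff(nu))),
        metadata={"mixing_phase_deg": mixing_phase, "snr": snr, "seed": seed},
    )
    truth = Spectrum(nu, im_eps, "dielectric", {"ground_truth": True})
    return exp, truth
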