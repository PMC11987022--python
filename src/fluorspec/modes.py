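"""Normal-mode analysis of a supplied Hessian and stick-spectrum broadening.

The Hessian is taken as input (dense text matrix or HDF5 dataset) in
internal energy units per angstrom squared (amu A^2 fs^-2 / A^2); no
force-field or electronic-structure engine is involved.  Rigid-body
translations and rotations are removed by projection onto the Eckart
subspace before diagonalization, which is robust for floppy chains where
the six smallest eigenvalues need not be the rigid ones.

Conventions (the literature often leaves these implicit):

* mode vectors ``eta`` are orthonormal in mass-weighted coordinates;
* Cartesian displacement per unit normal coordinate is
  ``cart_disp_i = eta_i / sqrt(m_i)``;
* the transition dipole of mode k is the point-charge dipole derivative
  along the mass-weighted normal coordinate,
  ``mu_k = sum_i q_i cart_disp_i^(k)`` (e*A per amu^1/2*A).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from .constants import omega_to_wavenumber
from .errors import InputError
from .spectra import Spectrum

__all__ = [
    "NormalModeSet",
    "compute_normal_modes",
    "broaden_sticks",
    "read_hessian",
    "write_hessian",
]


@dataclass
class NormalModeSet:
    """Vibrational normal modes of one helical conformer.

    frequencies are in cm^-1, sorted ascending; imaginary frequencies
    (negative Hessian eigenvalues among retained modes) are stored as
    negative wavenumbers and flagged in ``imaginary``.
    """

    frequencies: np.ndarray
    eta: np.ndarray  # (n_modes, 3n) mass-weighted, orthonormal
    cart_disp: np.ndarray  # (n_modes, n_atoms, 3)
    transition_dipoles: np.ndarray  # (n_modes, 3)
    helicity: int = 0
    n_removed: int = 6
    imaginary: np.ndarray = field(default=None)  # type: ignore[assignment]
    masses: np.ndarray | None = None
    reference: np.ndarray | None = None
    charges: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.imaginary is None:
            self.imaginary = np.zeros(len(self.frequencies), dtype=bool)

    @property
    def n_modes(self) -> int:
        return len(self.frequencies)

    def select(self, indices: np.ndarray) -> "NormalModeSet":
        idx = np.asarray(indices, int)
        return NormalModeSet(
            self.frequencies[idx],
            self.eta[idx],
            self.cart_disp[idx],
            self.transition_dipoles[idx],
            self.helicity,
            self.n_removed,
            self.imaginary[idx],
            self.masses,
            self.reference,
            self.charges,
        )

    def to_hdf5(self, path: str | Path, group: str = "modes") -> None:
        with h5py.File(path, "a") as fh:
            if group in fh:
                del fh[group]
            g = fh.create_group(group)
            g.attrs["helicity"] = self.helicity
            g.attrs["n_removed"] = self.n_removed
            for name in ("frequencies", "eta", "cart_disp", "transition_dipoles"):
                g.create_dataset(name, data=getattr(self, name))
            for name in ("masses", "reference", "charges"):
                if getattr(self, name) is not None:
                    g.create_dataset(name, data=getattr(self, name))

    @classmethod
    def from_hdf5(cls, path: str | Path, group: str = "modes") -> "NormalModeSet":
        with h5py.File(path, "r") as fh:
            g = fh[group]
            kw = {
                name: g[name][...]
                for name in ("masses", "reference", "charges")
                if name in g
            }
            return cls(
                g["frequencies"][...],
                g["eta"][...],
                g["cart_disp"][...],
                g["transition_dipoles"][...],
                int(g.attrs["helicity"]),
                int(g.attrs["n_removed"]),
                **kw,
            )


def _eckart_projector(reference: np.ndarray, masses: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the rigid translation/rotation subspace in
    mass-weighted coordinates; returns (3n, n_rigid)."""
    n = len(masses)
    sq = np.sqrt(masses)
    com = np.average(reference, axis=0, weights=masses)
    x = reference - com
    vecs = []
    for alpha in range(3):
        t = np.zeros((n, 3))
        t[:, alpha] = sq
        vecs.append(t.ravel())
    for alpha in range(3):
        e = np.zeros(3)
        e[alpha] = 1.0
        r = np.cross(x, e) * sq[:, None]
        vecs.append(r.ravel())
    v = np.array(vecs).T  # (3n, 6)
    q, r = np.linalg.qr(v)
    keep = np.abs(np.diag(r)) > 1e-10 * np.abs(np.diag(r)).max()
    return q[:, keep]


def compute_normal_modes(
    hessian: np.ndarray,
    masses: np.ndarray,
    reference: np.ndarray,
    charges: np.ndarray,
    helicity: int = 0,
    symmetry_tol: float = 1e-6,
) -> NormalModeSet:
    """Diagonalize a mass-weighted Hessian after Eckart projection.

    Parameters
    ----------
    hessian : (3n, 3n) array
        Second derivatives of the energy, internal units / A^2.
    masses : (n,) amu
    reference : (n, 3) angstrom, the geometry the Hessian was evaluated at.
    charges : (n,) elementary charges, used for point-charge transition
        dipoles.
    helicity : -1, 0 or +1 tag recorded on the result.
    """
    H = np.asarray(hessian, dtype=float)
    masses = np.asarray(masses, dtype=float)
    reference = np.asarray(reference, dtype=float)
    charges = np.asarray(charges, dtype=float)
    n = len(masses)
    if H.shape != (3 * n, 3 * n):
        raise InputError(f"hessian must be ({3*n}, {3*n})")
    if np.any(masses <= 0):
        raise InputError("masses must be positive")
    asym = np.abs(H - H.T).max()
    scale = max(np.abs(H).max(), 1.0)
    if asym > symmetry_tol * scale:
        raise InputError(f"hessian asymmetric beyond tolerance ({asym:.3g})")
    H = 0.5 * (H + H.T)
    invsq = 1.0 / np.sqrt(np.repeat(masses, 3))
    Hmw = H * invsq[:, None] * invsq[None, :]
    rigid = _eckart_projector(reference, masses)
    P = np.eye(3 * n) - rigid @ rigid.T
    Hproj = P @ Hmw @ P
    evals, evecs = np.linalg.eigh(Hproj)
    # rigid modes appear at (numerically) zero eigenvalue inside the
    # projected-out subspace; identify them by overlap with that subspace
    overlap = np.linalg.norm(rigid.T @ evecs, axis=0)
    vib = overlap < 0.5
    n_removed = int(np.sum(~vib))
    lam = evals[vib]
    eta = evecs[:, vib].T  # (n_modes, 3n)
    omega = np.sign(lam) * np.sqrt(np.abs(lam))  # rad/fs, signed
    freqs = omega_to_wavenumber(omega)
    order = np.argsort(freqs)
    freqs = freqs[order]
    eta = eta[order]
    imaginary = freqs < 0
    if np.any(imaginary):
        warnings.warn(
            f"{imaginary.sum()} imaginary frequencies among retained modes",
            stacklevel=2,
        )
    cart = (eta.reshape(-1, n, 3)) / np.sqrt(masses)[None, :, None]
    tdip = np.einsum("a,kax->kx", charges, cart)
    return NormalModeSet(
        frequencies=freqs,
        eta=eta,
        cart_disp=cart,
        transition_dipoles=tdip,
        helicity=helicity,
        n_removed=n_removed,
        imaginary=imaginary,
        masses=masses,
        reference=reference,
        charges=charges,
    )


def broaden_sticks(
    frequencies: np.ndarray,
    intensities: np.ndarray,
    fwhm: float = 5.0,
    grid: np.ndarray | None = None,
    points_per_fwhm: int = 20,
) -> Spectrum:
    """Sum of unit-area Lorentzians scaled by stick intensities.

    The default grid extends far beyond the sticks (800 fwhm, with the
    core sampled at ``points_per_fwhm``) because Lorentzian tails carry
    weight: +-10 fwhm holds only ~97 % of the area, while the default
    span conserves the total stick intensity to better than 0.1 %.
    """
    frequencies = np.atleast_1d(np.asarray(frequencies, dtype=float))
    intensities = np.atleast_1d(np.asarray(intensities, dtype=float))
    if frequencies.size == 0:
        raise InputError("empty stick list")
    if frequencies.shape != intensities.shape:
        raise InputError("frequencies and intensities must match")
    if fwhm <= 0:
        raise InputError("fwhm must be positive")
    if grid is None:
        core_lo = frequencies.min() - 10.0 * fwhm
        core_hi = frequencies.max() + 10.0 * fwhm
        npts = max(int((core_hi - core_lo) / fwhm * points_per_fwhm), 50)
        core = np.linspace(core_lo, core_hi, npts)
        # geometric tail grids capture the slowly decaying Lorentzian
        # wings without inflating the point count
        tail_lo = core_lo - np.geomspace(fwhm, 800.0 * fwhm, 300)[::-1]
        tail_hi = core_hi + np.geomspace(fwhm, 800.0 * fwhm, 300)
        grid = np.concatenate((tail_lo, core, tail_hi))
    gamma = fwhm / 2.0
    vals = np.zeros_like(grid)
    for nu0, inten in zip(frequencies, intensities):
        vals += inten * (gamma / np.pi) / ((grid - nu0) ** 2 + gamma**2)
    return Spectrum(
        nu=grid,
        values=vals,
        kind="absorbance",
        metadata={"fwhm": fwhm, "n_sticks": int(frequencies.size)},
    )


def read_hessian(path: str | Path, dataset: str = "hessian") -> np.ndarray:
    """Read a dense Hessian from whitespace-delimited text or HDF5."""
    path = Path(path)
    if path.suffix.lower() in {".h5", ".hdf5"}:
        with h5py.File(path, "r") as fh:
            return fh[dataset][...]
    return np.loadtxt(path)


def write_hessian(
    path: str | Path, hessian: np.ndarray, dataset: str = "hessian"
) -> None:
    path = Path(path)
    if path.suffix.lower() in {".h5", ".hdf5"}:
        with h5py.File(path, "a") as fh:
            if dataset in fh:
                del fh[dataset]
            fh.create_dataset(dataset, data=hessian)
    else:
        np.savetxt(path, hessian)
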