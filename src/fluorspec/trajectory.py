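"""Trajectory container, coordinate-file readers, rigid-body superposition
and dihedral geometry.

Internal units: angstrom, femtosecond, amu, elementary charge.  GRO files
(nanometres) are converted on read.  Dihedral angles follow the IUPAC
sign convention and live in (-180, 180]; :func:`to_0_360` converts to the
0-360 degree convention often used for gauche/trans state labels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .errors import FormatError, GeometryError, InputError, TopologyError

__all__ = [
    "Trajectory",
    "ReferencePair",
    "FitResult",
    "read_trajectory",
    "read_topology",
    "rigid_fit",
    "dihedral_angle",
    "dihedral_series",
    "to_0_360",
]


@dataclass
class Trajectory:
    """A fixed-topology series of molecular configurations.

    Attributes
    ----------
    coordinates : (T, n_atoms, 3) float array, angstrom
    dt : float, femtoseconds between stored frames
    masses : (n_atoms,) float array, amu
    charges : (n_atoms,) float array, elementary charge
    atom_labels : list of str, element symbol + running index
    molecule_ids : (n_atoms,) int array grouping atoms into molecules
    box : optional (3,) float array, angstrom
    """

    coordinates: np.ndarray
    dt: float
    masses: np.ndarray
    charges: np.ndarray
    atom_labels: list[str] = field(default_factory=list)
    molecule_ids: np.ndarray | None = None
    box: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise InputError("coordinates must have shape (T, n_atoms, 3)")
        if self.n_frames < 2:
            raise InputError("a trajectory needs at least 2 frames")
        if self.dt <= 0:
            raise InputError("dt must be positive")
        self.masses = np.asarray(self.masses, dtype=float)
        self.charges = np.asarray(self.charges, dtype=float)
        n = self.n_atoms
        if self.masses.shape != (n,) or self.charges.shape != (n,):
            raise TopologyError("masses/charges must be per-atom arrays")
        if np.any(self.masses <= 0):
            raise TopologyError("masses must be positive")
        if self.molecule_ids is None:
            self.molecule_ids = np.zeros(n, dtype=int)
        self.molecule_ids = np.asarray(self.molecule_ids, dtype=int)
        if self.molecule_ids.shape != (n,):
            raise TopologyError("molecule_ids must be per-atom")
        if not self.atom_labels:
            self.atom_labels = [f"X{i}" for i in range(n)]

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    def molecule(self, mol_id: int) -> "Trajectory":
        """Sub-trajectory of a single molecule."""
        sel = np.flatnonzero(self.molecule_ids == mol_id)
        if sel.size == 0:
            raise InputError(f"no atoms with molecule id {mol_id}")
        return Trajectory(
            self.coordinates[:, sel, :],
            self.dt,
            self.masses[sel],
            self.charges[sel],
            [self.atom_labels[i] for i in sel],
            np.zeros(sel.size, dtype=int),
            self.box,
        )

    def dipole_trace(self) -> np.ndarray:
        """(T, 3) point-charge dipole moment in e*A."""
        return np.einsum("a,tax->tx", self.charges, self.coordinates)


@dataclass
class ReferencePair:
    """Mirror-image (left/right helical) reference geometries.

    ``helicity_dihedral`` indexes the four atoms of the overall-helicity
    dihedral; its sign distinguishes the two conformers.
    """

    x_ref_minus: np.ndarray
    x_ref_plus: np.ndarray
    fit_atom_subset: np.ndarray
    helicity_dihedral: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        self.x_ref_minus = np.asarray(self.x_ref_minus, dtype=float)
        self.x_ref_plus = np.asarray(self.x_ref_plus, dtype=float)
        self.fit_atom_subset = np.asarray(self.fit_atom_subset, dtype=int)
        if self.x_ref_minus.shape != self.x_ref_plus.shape:
            raise InputError("reference structures must match in shape")
        if self.fit_atom_subset.size == 0:
            raise InputError("fit_atom_subset must be non-empty")
        dm = dihedral_angle(self.x_ref_minus, self.helicity_dihedral)
        dp = dihedral_angle(self.x_ref_plus, self.helicity_dihedral)
        if np.sign(dm) == np.sign(dp):
            raise InputError(
                "helicity dihedral must have opposite sign in the two "
                f"references (got {dm:.1f} and {dp:.1f} deg)"
            )

    def reference(self, helicity: int) -> np.ndarray:
        return self.x_ref_plus if helicity > 0 else self.x_ref_minus


@dataclass
class FitResult:
    """Result of a weighted rigid-body superposition."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    x_fit: np.ndarray


def read_topology(source: str | Path | pd.DataFrame) -> pd.DataFrame:
    """Read a topology table (CSV or JSON) with columns
    atom_index, element, mass, charge, molecule_id."""
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        path = Path(source)
        if path.suffix.lower() == ".json":
            df = pd.DataFrame(json.loads(path.read_text()))
        else:
            df = pd.read_csv(path)
    required = {"element", "mass", "charge", "molecule_id"}
    missing = required - set(df.columns)
    if missing:
        raise TopologyError(f"topology table lacks columns: {sorted(missing)}")
    if "atom_index" in df.columns:
        df = df.sort_values("atom_index").reset_index(drop=True)
    return df


def _parse_xyz(path: Path) -> tuple[np.ndarray, list[str]]:
    lines = path.read_text().splitlines()
    frames: list[np.ndarray] = []
    labels: list[str] = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].split()[0])
        except ValueError as exc:
            raise FormatError(f"bad XYZ atom-count line at line {i + 1}") from exc
        block = lines[i + 2 : i + 2 + n]
        if len(block) < n:
            raise FormatError("truncated XYZ frame")
        coords = np.empty((n, 3))
        frame_labels = []
        for j, ln in enumerate(block):
            parts = ln.split()
            if len(parts) < 4:
                raise FormatError(f"bad XYZ atom line: {ln!r}")
            frame_labels.append(parts[0])
            coords[j] = [float(x) for x in parts[1:4]]
        if frames and coords.shape != frames[0].shape:
            raise FormatError(
                f"inconsistent atom count across XYZ frames "
                f"({coords.shape[0]} vs {frames[0].shape[0]})"
            )
        if not labels:
            labels = frame_labels
        frames.append(coords)
        i += 2 + n
    if not frames:
        raise FormatError("no frames found in XYZ file")
    return np.stack(frames), labels


def _parse_gro(path: Path) -> tuple[np.ndarray, list[str], np.ndarray | None]:
    """Multi-frame GRO (concatenated frames); nm converted to angstrom."""
    lines = path.read_text().splitlines()
    frames: list[np.ndarray] = []
    labels: list[str] = []
    box = None
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i + 1].split()[0])
        except (IndexError, ValueError) as exc:
            raise FormatError(f"bad GRO atom-count line at line {i + 2}") from exc
        block = lines[i + 2 : i + 2 + n]
        if len(block) < n:
            raise FormatError("truncated GRO frame")
        coords = np.empty((n, 3))
        frame_labels = []
        for j, ln in enumerate(block):
            # fixed columns: resid(5) resname(5) atomname(5) atomid(5) xyz
            frame_labels.append(ln[10:15].strip())
            coords[j] = [float(ln[20:28]), float(ln[28:36]), float(ln[36:44])]
        box_line = lines[i + 2 + n].split()
        box = np.array([float(x) for x in box_line[:3]]) * 10.0
        if frames and coords.shape != frames[0].shape:
            raise FormatError("inconsistent atom count across GRO frames")
        if not labels:
            labels = frame_labels
        frames.append(coords * 10.0)
        i += 3 + n
    if not frames:
        raise FormatError("no frames found in GRO file")
    return np.stack(frames), labels, box


def read_trajectory(
    path: str | Path,
    topology: str | Path | pd.DataFrame,
    dt: float = 1.0,
) -> Trajectory:
    """Read a multi-frame XYZ or GRO coordinate file.

    Parameters
    ----------
    path
        Coordinate file; format inferred from the suffix.
    topology
        CSV/JSON path or DataFrame supplying element, mass, charge and
        molecule_id per atom.
    dt
        Time step between stored frames, fs.
    """
    path = Path(path)
    top = read_topology(topology)
    if path.suffix.lower() == ".gro":
        coords, labels, box = _parse_gro(path)
    else:
        coords, labels = _parse_xyz(path)
        box = None
    if len(top) != coords.shape[1]:
        raise TopologyError(
            f"topology has {len(top)} atoms but file has {coords.shape[1]}"
        )
    return Trajectory(
        coordinates=coords,
        dt=dt,
        masses=top["mass"].to_numpy(float),
        charges=top["charge"].to_numpy(float),
        atom_labels=[f"{e}{i}" for i, e in enumerate(top["element"])],
        molecule_ids=top["molecule_id"].to_numpy(int),
        box=box,
    )


def rigid_fit(
    frame: np.ndarray,
    reference: np.ndarray,
    subset: np.ndarray | None = None,
    weights: np.ndarray | None = None,
) -> FitResult:
    """Proper-rotation superposition of ``frame`` onto ``reference``.

    Minimizes the weighted mean-square distance over ``subset`` (default:
    all atoms).  Reflections are excluded even when they would give a
    lower residual, so that the mirror-image helical conformers are never
    silently interchanged.  The returned ``x_fit`` applies the fitted
    transform to *all* atoms of the frame.
    """
    frame = np.asarray(frame, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if frame.shape != reference.shape:
        raise InputError("frame and reference must have the same shape")
    idx = np.arange(frame.shape[0]) if subset is None else np.asarray(subset, int)
    if idx.size < 3:
        raise GeometryError("rigid fit needs at least 3 subset atoms")
    w = np.ones(idx.size) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != (idx.size,):
        raise InputError("weights must match the subset length")
    a = reference[idx]
    b = frame[idx]
    cen_a = np.average(a, axis=0, weights=w)
    cen_b = np.average(b, axis=0, weights=w)
    a0 = a - cen_a
    b0 = b - cen_b
    if np.linalg.matrix_rank(b0, tol=1e-8) < 2:
        raise GeometryError("fit subset is collinear or degenerate")
    rot, rssd = Rotation.align_vectors(a0, b0, weights=w)
    R = rot.as_matrix()
    x_fit = (frame - cen_b) @ R.T + cen_a
    rmsd = float(np.sqrt(np.sum(w * np.sum((x_fit[idx] - a) ** 2, axis=1)) / w.sum()))
    translation = cen_a - R @ cen_b
    return FitResult(rotation=R, translation=translation, rmsd=rmsd, x_fit=x_fit)


def dihedral_angle(
    coordinates: np.ndarray, indices: tuple[int, int, int, int]
) -> float:
    """Signed dihedral (IUPAC convention) of four atoms, degrees in
    (-180, 180]."""
    return float(dihedral_series(coordinates[None, ...], indices)[0])


def dihedral_series(
    coordinates: np.ndarray, indices: tuple[int, int, int, int]
) -> np.ndarray:
    """Vectorized dihedral over a (T, n, 3) coordinate series."""
    i, j, k, l = indices
    if len({i, j, k, l}) != 4:
        raise GeometryError("dihedral atoms must be pairwise distinct")
    p = np.asarray(coordinates, dtype=float)
    b0 = p[:, j] - p[:, i]
    b1 = p[:, k] - p[:, j]
    b2 = p[:, l] - p[:, k]
    nb1 = np.linalg.norm(b1, axis=1)
    for v, pair in ((b0, (i, j)), (b1, (j, k)), (b2, (k, l))):
        if np.any(np.linalg.norm(v, axis=1) < 1e-10):
            raise GeometryError(f"coincident consecutive atoms {pair}")
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / nb1[:, None])
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", m1, n2)
    ang = np.degrees(np.arctan2(y, x))
    # map -180 -> +180 to keep the range (-180, 180]
    ang[ang <= -180.0 + 1e-12] = 180.0
    return ang


def to_0_360(angle_deg: np.ndarray | float) -> np.ndarray | float:
    """Convert signed dihedrals in (-180, 180] to the [0, 360) convention."""
    return np.mod(angle_deg, 360.0)
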