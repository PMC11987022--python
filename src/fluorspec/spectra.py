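"""Power spectra, dielectric susceptibility and species decomposition of
dipole time series.

The power spectrum of a (possibly vector-valued) series v(t) sampled with
step dt follows the finite-time Fourier convention

    v~(omega) = dt * sum_n v_n exp(-i omega t_n),
    S_vv(omega) = |v~(omega)|^2 / t_max,

with Cartesian components summed.  Spectra are reported one-sided on a
wavenumber axis (cm^-1): values are densities per cm^-1, so the integral
over the axis recovers the total signal power (Parseval).  Welch-style
segment averaging (mean removal per segment, Hann window with 50 %
overlap by default) trades resolution for variance; the rectangle window
with a single segment reproduces the bare convention above exactly.

The dielectric susceptibility follows the classical Green-Kubo
linear-response form chi''(omega) proportional to omega * S_MM(omega) /
(3 V eps0 kB T) evaluated via the Wiener-Khinchin theorem in the
frequency domain.  Only proportionality to the absorption line shape is
relied on downstream, so an overall scale knob is exposed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import C_CM_PER_FS, EPSILON_0, KB, wavenumber_to_omega
from .errors import InputError

__all__ = [
    "DipoleTrace",
    "ThermoState",
    "Spectrum",
    "power_spectrum",
    "cross_spectrum",
    "dipole_derivative",
    "susceptibility",
    "species_decompose",
    "autocorrelation",
]

_KINDS = {"power", "susceptibility", "absorbance", "dielectric"}


@dataclass
class DipoleTrace:
    """Time series of a (vector) dipole moment in e*A, time step in fs."""

    values: np.ndarray
    dt: float
    label: str = "total"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        if self.values.ndim != 2:
            raise InputError("trace values must be (T,) or (T, d)")
        if self.values.shape[0] < 2:
            raise InputError("trace needs at least 2 samples")
        if not np.all(np.isfinite(self.values)):
            raise InputError("trace contains non-finite values")
        if self.dt <= 0:
            raise InputError("dt must be positive")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]


@dataclass
class ThermoState:
    """Thermodynamic state of the simulated system."""

    volume: float  # A^3
    temperature: float  # K

    def __post_init__(self) -> None:
        if self.volume <= 0 or self.temperature <= 0:
            raise InputError("volume and temperature must be positive")


@dataclass
class Spectrum:
    """A spectrum on a strictly increasing wavenumber grid (cm^-1)."""

    nu: np.ndarray
    values: np.ndarray
    kind: str = "power"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.nu = np.asarray(self.nu, dtype=float)
        self.values = np.asarray(self.values)
        if self.kind not in _KINDS:
            raise InputError(f"kind must be one of {sorted(_KINDS)}")
        if self.nu.ndim != 1 or self.values.shape[0] != self.nu.shape[0]:
            raise InputError("nu and values must be aligned 1-d arrays")
        if self.nu.size > 1 and np.any(np.diff(self.nu) <= 0):
            raise InputError("wavenumber grid must be strictly increasing")
        if self.kind == "power" and np.isrealobj(self.values):
            tol = 1e-12 * max(np.abs(self.values).max(), 1.0)
            if np.any(self.values < -tol):
                raise InputError("power spectrum has negative values")

    def integrate(self, lo: float | None = None, hi: float | None = None) -> float:
        sel = np.ones_like(self.nu, dtype=bool)
        if lo is not None:
            sel &= self.nu >= lo
        if hi is not None:
            sel &= self.nu <= hi
        return float(np.trapezoid(np.real(self.values[sel]), self.nu[sel]))

    def crop(self, lo: float, hi: float) -> "Spectrum":
        sel = (self.nu >= lo) & (self.nu <= hi)
        return Spectrum(self.nu[sel], self.values[sel], self.kind, dict(self.metadata))

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame({"nu_cm-1": self.nu})
        if np.iscomplexobj(self.values):
            df["value"] = np.real(self.values)
            df["imag"] = np.imag(self.values)
        else:
            df["value"] = self.values
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, kind: str = "power") -> "Spectrum":
        df = pd.read_csv(path)
        vals = df.iloc[:, 1].to_numpy(float)
        if df.shape[1] > 2 and "imag" in df.columns:
            vals = vals + 1j * df["imag"].to_numpy(float)
        return cls(df.iloc[:, 0].to_numpy(float), vals, kind)


def _segment_ffts(
    x: np.ndarray,
    dt: float,
    window: str,
    n_segments: int,
    overlap: float,
    detrend: bool,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Windowed segment FFTs; returns (fft array [seg, comp, freq],
    wavenumber axis, normalization factor).

    The normalization factor converts |fft|^2 sums into one-sided spectral
    densities per cm^-1 under the module's Fourier convention.
    """
    T = x.shape[0]
    if T < 16:
        raise InputError("trace too short (need >= 16 samples)")
    if n_segments < 1:
        raise InputError("n_segments must be >= 1")
    nper = T // n_segments
    if nper < 16:
        raise InputError("segments shorter than 16 samples")
    if window == "none":
        w = np.ones(nper)
    elif window == "hann":
        w = np.hanning(nper)
    else:
        raise InputError("window must be 'none' or 'hann'")
    step = nper if n_segments == 1 else max(int(nper * (1.0 - overlap)), 1)
    starts = list(range(0, T - nper + 1, step))
    segs = []
    for s in starts:
        seg = x[s : s + nper].astype(float)
        if detrend:
            seg = seg - seg.mean(axis=0, keepdims=True)
        segs.append(np.fft.rfft(seg * w[:, None], axis=0))
    ffts = np.transpose(np.array(segs), (0, 2, 1))  # (seg, comp, freq)
    f = np.fft.rfftfreq(nper, d=dt)  # cycles / fs
    nu = f / C_CM_PER_FS
    # density per cycles/fs: dt |X|^2 / (nper * mean(w^2)); one-sided x2;
    # per cm^-1: multiply by c (df = c dnu).
    norm = dt / (nper * np.mean(w**2)) * C_CM_PER_FS
    return ffts, nu, norm


def _as_array(trace: DipoleTrace | np.ndarray) -> tuple[np.ndarray, float | None]:
    if isinstance(trace, DipoleTrace):
        return trace.values, trace.dt
    x = np.asarray(trace, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    return x, None


def power_spectrum(
    trace: DipoleTrace | np.ndarray,
    window: str = "hann",
    n_segments: int = 1,
    overlap: float = 0.5,
    detrend: bool = True,
    dt: float | None = None,
) -> Spectrum:
    """One-sided power spectral density of a scalar or vector series.

    Cartesian components are summed.  ``n_segments`` counts
    non-overlapping segments; with the default 50 % overlap roughly twice
    as many windowed segments are averaged (Welch).
    """
    x, trace_dt = _as_array(trace)
    dt = trace_dt if trace_dt is not None else dt
    if dt is None:
        raise InputError("dt required for bare-array input")
    ffts, nu, norm = _segment_ffts(x, dt, window, n_segments, overlap, detrend)
    power = norm * np.mean(np.sum(np.abs(ffts) ** 2, axis=1), axis=0)
    power *= 2.0
    power[0] /= 2.0
    if ffts.shape[-1] > 1 and x.shape[0] // n_segments % 2 == 0:
        power[-1] /= 2.0
    return Spectrum(
        nu,
        power,
        "power",
        {
            "window": window,
            "n_segments": n_segments,
            "n_averages": ffts.shape[0],
            "one_sided": True,
            "dt_fs": dt,
        },
    )


def cross_spectrum(
    trace_a: DipoleTrace | np.ndarray,
    trace_b: DipoleTrace | np.ndarray,
    window: str = "hann",
    n_segments: int = 1,
    overlap: float = 0.5,
    detrend: bool = True,
    dt: float | None = None,
) -> Spectrum:
    """One-sided cross-spectral density 2*Re<a~ b~*> (components summed).

    For a == b this reduces exactly to :func:`power_spectrum` and the
    spectrum of a sum decomposes as S_aa + S_bb + 2 cross(a, b).
    """
    xa, dta = _as_array(trace_a)
    xb, dtb = _as_array(trace_b)
    dt = dta if dta is not None else (dtb if dtb is not None else dt)
    if dt is None:
        raise InputError("dt required for bare-array input")
    if xa.shape != xb.shape:
        raise InputError("cross-spectrum traces must be aligned in shape")
    fa, nu, norm = _segment_ffts(xa, dt, window, n_segments, overlap, detrend)
    fb, _, _ = _segment_ffts(xb, dt, window, n_segments, overlap, detrend)
    cross = norm * np.mean(np.sum(np.real(fa * np.conj(fb)), axis=1), axis=0)
    cross *= 2.0
    cross[0] /= 2.0
    if fa.shape[-1] > 1 and xa.shape[0] // n_segments % 2 == 0:
        cross[-1] /= 2.0
    return Spectrum(
        nu,
        cross,
        "power",
        {"window": window, "n_segments": n_segments, "cross": True, "dt_fs": dt},
    )


def dipole_derivative(trace: DipoleTrace) -> DipoleTrace:
    """Time derivative by central finite differences (one-sided at the
    ends).  Units e*A/fs."""
    if trace.n_frames < 3:
        raise InputError("derivative needs at least 3 samples")
    deriv = np.gradient(trace.values, trace.dt, axis=0)
    return DipoleTrace(deriv, trace.dt, label=f"d/dt {trace.label}")


def susceptibility(
    trace: DipoleTrace,
    state: ThermoState,
    scale: float = 1.0,
    window: str = "hann",
    n_segments: int = 1,
) -> Spectrum:
    """Imaginary part of the dielectric susceptibility from total-dipole
    fluctuations (Green-Kubo / Wiener-Khinchin).

    chi''(omega) = scale * omega * S_MM(omega) / (2 * 3 V eps0 kB T).
    The returned spectrum carries the absorption line shape
    omega*chi''(omega) in ``metadata['absorption']``.
    """
    s_mm = power_spectrum(trace, window=window, n_segments=n_segments)
    omega = wavenumber_to_omega(s_mm.nu)  # rad/fs
    pref = scale / (2.0 * 3.0 * state.volume * EPSILON_0 * KB * state.temperature)
    chi2 = pref * omega * s_mm.values
    return Spectrum(
        s_mm.nu,
        chi2,
        "susceptibility",
        {
            "component": "imag",
            "scale": scale,
            "volume_A3": state.volume,
            "temperature_K": state.temperature,
            "absorption": omega * chi2,
        },
    )


def species_decompose(
    per_molecule_traces: list[DipoleTrace],
    species: list[str],
    derivative: bool = True,
    window: str = "hann",
    n_segments: int = 1,
) -> pd.DataFrame:
    """Decompose the total spectrum into per-species self and pairwise
    cross contributions.

    Returns a tidy frame with one row per (term, wavenumber).  ``self``
    terms sum per-molecule spectra within a species; ``cross`` terms
    collect all distinct-molecule correlations, attributed to species
    pairs.  By construction self + cross = total to numerical precision.
    """
    if len(per_molecule_traces) == 0:
        raise InputError("need at least one molecular trace")
    if len(species) != len(per_molecule_traces):
        raise InputError("species labels must align with traces")
    T = per_molecule_traces[0].n_frames
    dt = per_molecule_traces[0].dt
    for tr in per_molecule_traces:
        if tr.n_frames != T or tr.dt != dt:
            raise InputError("traces misaligned in length or time step")
    arrays = []
    for tr in per_molecule_traces:
        x = dipole_derivative(tr).values if derivative else tr.values
        arrays.append(x)
    ffts = []
    for x in arrays:
        fa, nu, norm = _segment_ffts(x, dt, window, n_segments, 0.5, True)
        ffts.append(fa)
    nper_even = (T // n_segments) % 2 == 0

    def _one_sided(raw: np.ndarray) -> np.ndarray:
        out = 2.0 * raw
        out[0] /= 2.0
        if raw.shape[-1] > 1 and nper_even:
            out[-1] /= 2.0
        return out

    def _pair(fa: np.ndarray, fb: np.ndarray) -> np.ndarray:
        return _one_sided(
            norm * np.mean(np.sum(np.real(fa * np.conj(fb)), axis=1), axis=0)
        )

    uniq = sorted(set(species))
    by_species: dict[str, np.ndarray] = {
        s: np.sum([f for f, lab in zip(ffts, species) if lab == s], axis=0)
        for s in uniq
    }
    rows: dict[str, np.ndarray] = {}
    total_fft = np.sum(ffts, axis=0)
    rows["total"] = _pair(total_fft, total_fft)
    check = np.zeros_like(rows["total"])
    for s in uniq:
        self_s = np.sum(
            [_pair(f, f) for f, lab in zip(ffts, species) if lab == s], axis=0
        )
        rows[f"self:{s}"] = self_s
        check = check + self_s
        within_cross = _pair(by_species[s], by_species[s]) - self_s
        rows[f"cross:{s}|{s}"] = within_cross
        check = check + within_cross
    for i, a in enumerate(uniq):
        for b in uniq[i + 1 :]:
            c = 2.0 * _pair(by_species[a], by_species[b])
            rows[f"cross:{a}|{b}"] = c
            check = check + c
    rows["self_plus_cross"] = check
    out = pd.DataFrame({"nu_cm-1": nu, **rows})
    out.attrs["window"] = window
    out.attrs["n_segments"] = n_segments
    return out


def autocorrelation(x: np.ndarray, normalize: bool = True) -> np.ndarray:
    """FFT-based autocorrelation C(t) = <x(0).x(t)> for scalar (T,) or
    vector (T, d) series, biased estimator with 1/T normalization of lag
    products divided out (unbiased in lag)."""
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    T = x.shape[0]
    nfft = int(2 ** np.ceil(np.log2(2 * T)))
    f = np.fft.rfft(x, n=nfft, axis=0)
    acf = np.fft.irfft(np.sum(f * np.conj(f), axis=1), n=nfft)[:T]
    acf /= np.arange(T, 0, -1)
    if normalize:
        if acf[0] == 0:
            raise InputError("zero-variance series has no normalized ACF")
        acf = acf / acf[0]
    return acf
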