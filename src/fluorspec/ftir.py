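"""Experimental-spectrum arm: Kramers-Kronig separation of ATR spectra,
wavelet peak detection, constrained Lorentzian deconvolution, band
normalization and concentration / chain-length trend tables.

ATR (attenuated total reflection) spectra mix the transmission-like
component, proportional to Im(eps), with a dispersive reflection-like
component.  The two are causally linked through the Kramers-Kronig
relations, so a Hilbert-transform rotation with a single global phase
(90 degrees for the ATR configuration) recovers the transmission-like
part.  Peak maxima are located with a continuous wavelet transform using
a second-derivative-Lorentzian analyzing function on a ladder of gamma
half-widths (3-6 cm^-1), requiring ridge persistence across scales, and
bands are quantified by least-squares sums of Lorentzians with the
maxima frequencies clamped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import lmfit
import numpy as np
import pandas as pd
from scipy.signal import argrelextrema, hilbert

from .errors import AnalysisError, FormatError, InputError, NormalizationError
from .spectra import Spectrum

__all__ = [
    "ExperimentalSpectrum",
    "PeakTable",
    "BAND_ASSIGNMENTS",
    "read_spectrum",
    "kk_separate",
    "detect_peaks",
    "fit_lorentzians",
    "normalize_bands",
    "trend_analysis",
    "lorentzian",
]

#: nominal band centers (cm^-1) used only as metadata labels, matched by
#: nearest detected center within +-10 cm^-1
BAND_ASSIGNMENTS: dict[str, float] = {
    "nu_a_OP(CF3)": 1236.0,
    "nu_a_IP(CF3)": 1220.0,
    "nu_s(CF2)": 1135.0,
    "nu_s(CF3)": 1353.0,
    "rho_IP(CH3)": 1020.0,
}


@dataclass
class ExperimentalSpectrum:
    """An absorbance spectrum with acquisition metadata."""

    nu: np.ndarray
    absorbance: np.ndarray
    acquisition: str = "transmission"  # or "ATR"
    resolution: float = 2.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.nu = np.asarray(self.nu, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.nu.shape != self.absorbance.shape or self.nu.ndim != 1:
            raise InputError("nu and absorbance must be aligned 1-d arrays")
        if np.any(np.diff(self.nu) <= 0):
            raise InputError("wavenumber grid must be strictly increasing")
        if self.resolution <= 0:
            raise InputError("resolution must be positive")
        if self.acquisition not in {"transmission", "ATR"}:
            raise InputError("acquisition must be 'transmission' or 'ATR'")


@dataclass
class PeakTable:
    """Per-band parameters of a fitted spectrum.

    ``bands`` columns: center, fwhm, area, area_err, fwhm_err, height,
    assignment, area_norm (after :func:`normalize_bands`).
    """

    bands: pd.DataFrame
    normalization_reference: str | None = None
    residual_rms: float = float("nan")
    label: object = None

    def band(self, assignment: str) -> pd.Series:
        sel = self.bands[self.bands["assignment"] == assignment]
        if len(sel) == 0:
            raise KeyError(f"no band assigned {assignment!r}")
        return sel.iloc[0]

    def to_csv(self, path: str | Path) -> None:
        df = self.bands.copy()
        df["normalization_reference"] = self.normalization_reference
        df.to_csv(path, index=False)


def read_spectrum(
    path: str | Path,
    acquisition: str = "transmission",
    resolution: float = 2.0,
    **metadata,
) -> ExperimentalSpectrum:
    """Read a two-column CSV or a JCAMP-DX (XYDATA / XYPOINTS) spectrum."""
    path = Path(path)
    text = path.read_text()
    if text.lstrip().startswith("##"):
        nu, ab = _parse_jcamp(text)
    else:
        df = pd.read_csv(path)
        nu = df.iloc[:, 0].to_numpy(float)
        ab = df.iloc[:, 1].to_numpy(float)
    order = np.argsort(nu)
    return ExperimentalSpectrum(
        nu[order], ab[order], acquisition, resolution, metadata
    )


def _parse_jcamp(text: str) -> tuple[np.ndarray, np.ndarray]:
    """Minimal JCAMP-DX reader for (X++(Y..Y)) and (XY..XY) tables."""
    lines = text.splitlines()
    xfac = yfac = 1.0
    deltax = None
    mode = None
    xs: list[float] = []
    ys: list[float] = []
    for ln in lines:
        s = ln.strip()
        if s.startswith("##"):
            key, _, val = s[2:].partition("=")
            key = key.strip().upper().replace(" ", "")
            val = val.strip()
            if key == "XFACTOR":
                xfac = float(val)
            elif key == "YFACTOR":
                yfac = float(val)
            elif key == "DELTAX":
                deltax = float(val)
            elif key in {"XYDATA", "XYPOINTS"}:
                mode = "xyy" if "X++" in val.upper() else "xyxy"
            elif key == "END":
                mode = None
            continue
        if mode is None or not s:
            continue
        parts = s.replace(",", " ").split()
        vals = [float(p) for p in parts]
        if mode == "xyy":
            x0 = vals[0] * xfac
            yrow = vals[1:]
            if deltax is None and len(xs) >= 2:
                deltax = (xs[1] - xs[0])  # already scaled
            step = deltax if deltax is not None else 1.0
            for j, y in enumerate(yrow):
                xs.append(x0 + j * step)
                ys.append(y * yfac)
        else:
            for x, y in zip(vals[::2], vals[1::2]):
                xs.append(x * xfac)
                ys.append(y * yfac)
    if not xs:
        raise FormatError("no XYDATA/XYPOINTS table found in JCAMP file")
    return np.asarray(xs), np.asarray(ys)


def hilbert_conjugate(y: np.ndarray, pad_frac: float = 0.25) -> np.ndarray:
    """Hilbert-transform conjugate with edge padding to suppress
    wrap-around artifacts (H[cos] = sin convention)."""
    n = len(y)
    pad = max(int(n * pad_frac), 8)
    ext = np.concatenate((np.full(pad, y[0]), y, np.full(pad, y[-1])))
    return np.imag(hilbert(ext))[pad : pad + n]


def kk_separate(
    spectrum: ExperimentalSpectrum,
    phase_offset: float = 90.0,
) -> tuple[Spectrum, Spectrum]:
    """Separate an ATR spectrum into transmission-like and dispersive
    components via a Kramers-Kronig (Hilbert) phase rotation.

    The measured trace is modelled as cos(phi) Im(eps) + sin(phi) D with
    D the Hilbert conjugate of Im(eps); inverting gives
    Im(eps) = cos(phi) y - sin(phi) H[y].  A residual baseline offset
    (the DC component the Hilbert transform cannot restore) is
    re-anchored to the spectrum edges.  Non-ATR input passes through
    unchanged with a warning.
    """
    nu = spectrum.nu
    y = spectrum.absorbance
    if spectrum.acquisition != "ATR":
        warnings.warn("non-ATR spectrum: KK separation skipped", stacklevel=2)
        return (
            Spectrum(nu, y, "dielectric", {"kk": "skipped"}),
            Spectrum(nu, np.zeros_like(y), "dielectric", {"kk": "skipped"}),
        )
    dnu = np.diff(nu)
    if not np.allclose(dnu, dnu[0], rtol=1e-3):
        grid = np.linspace(nu[0], nu[-1], len(nu))
        y = np.interp(grid, nu, y)
        nu = grid
    phi = np.radians(phase_offset)
    hy = hilbert_conjugate(y)
    trans = np.cos(phi) * y - np.sin(phi) * hy
    disp = np.sin(phi) * y + np.cos(phi) * hy
    # re-anchor the DC level lost in the transform to the band edges
    edge = max(len(trans) // 20, 2)
    trans = trans - np.median(np.concatenate((trans[:edge], trans[-edge:])))
    meta = {"kk_phase_deg": phase_offset}
    return (
        Spectrum(nu, trans, "dielectric", meta),
        Spectrum(nu, disp, "dielectric", {**meta, "component": "dispersive"}),
    )


def _lorentzian_second_derivative_wavelet(
    dx: float, gamma: float
) -> np.ndarray:
    """Sampled analyzing function: negated second derivative of a
    Lorentzian with half-width gamma, L2-normalized."""
    half = int(np.ceil(10.0 * gamma / dx))
    x = np.arange(-half, half + 1) * dx
    lor = 1.0 / (x**2 + gamma**2)
    d2 = (2.0 * (3.0 * x**2 - gamma**2)) / (x**2 + gamma**2) ** 3
    w = -d2 * gamma**3  # scale-invariant amplitude
    return w / np.sqrt(np.sum(w**2) * dx)


def detect_peaks(
    spectrum: ExperimentalSpectrum | Spectrum,
    gamma_range: tuple[float, float] = (3.0, 6.0),
    n_scales: int = 8,
    min_ridge_scales: int = 3,
    noise_mad_factor: float = 8.0,
    full_output: bool = False,
):
    """Continuous-wavelet-transform peak detection.

    The spectrum is convolved with second-derivative-Lorentzian wavelets
    on a gamma ladder; maxima that persist as ridge lines across at
    least ``min_ridge_scales`` scales and exceed a noise-scaled
    threshold (``noise_mad_factor`` times the median absolute deviation
    of the finest-scale coefficients; the default 8 accounts for the
    ridge strength being a maximum over the scale ladder) are reported,
    with sub-grid centers from parabolic interpolation at the
    strongest-coefficient scale of each ridge.
    """
    if isinstance(spectrum, Spectrum):
        nu, y = spectrum.nu, np.real(spectrum.values)
    else:
        nu, y = spectrum.nu, spectrum.absorbance
    gmin, gmax = gamma_range
    if not (1.0 <= gmin <= gmax <= 20.0):
        raise InputError("gamma_range must lie within [1, 20] cm^-1")
    dx = float(np.median(np.diff(nu)))
    if dx > gmin / 2.0:
        raise InputError(
            f"grid spacing {dx:.2f} too coarse for gamma_min {gmin:.2f}"
        )
    gammas = np.geomspace(gmin, gmax, n_scales)
    coeffs = []
    for g in gammas:
        w = _lorentzian_second_derivative_wavelet(dx, g)
        coeffs.append(np.convolve(y, w, mode="same") * dx)
    coeffs = np.array(coeffs)  # (scale, nu), fine -> coarse
    fine = coeffs[0]
    mad = np.median(np.abs(fine - np.median(fine)))
    threshold = noise_mad_factor * mad
    maxima = [argrelextrema(c, np.greater, order=2)[0] for c in coeffs]
    # link ridges from the coarsest scale down to the finest
    ridges: list[list[int]] = [[m] for m in maxima[-1]]
    for s in range(n_scales - 2, -1, -1):
        tol = max(gammas[s] / dx, 2.0)
        cand = list(maxima[s])
        for r in ridges:
            if len(r) != (n_scales - 1 - s):
                continue  # ridge already broken
            last = r[-1]
            if cand:
                j = int(np.argmin(np.abs(np.array(cand) - last)))
                if abs(cand[j] - last) <= tol:
                    r.append(cand.pop(j))
    edge_margin = int(np.ceil(8.0 * gmax / dx))
    rows = []
    for r in ridges:
        if len(r) < min_ridge_scales:
            continue
        # ridge grew coarse->fine: element at list index m sits at scale
        # (n_scales - 1 - m); estimate the center at the scale with the
        # strongest (best-SNR) coefficient along the ridge
        scales = [n_scales - 1 - m for m in range(len(r))]
        strengths = [coeffs[s, p] for s, p in zip(scales, r)]
        best = int(np.argmax(strengths))
        s_best, pos = scales[best], r[best]
        strength = strengths[best]
        if strength < threshold:
            continue
        if pos < edge_margin or pos > len(nu) - 1 - edge_margin:
            continue  # within the wavelet support of the grid edge
        # parabolic sub-grid interpolation at the best scale
        c = coeffs[s_best]
        if 0 < pos < len(c) - 1:
            denom = c[pos - 1] - 2 * c[pos] + c[pos + 1]
            shift = 0.5 * (c[pos - 1] - c[pos + 1]) / denom if denom != 0 else 0.0
            shift = float(np.clip(shift, -1.0, 1.0))
        else:
            shift = 0.0
        rows.append(
            {
                "center": nu[pos] + shift * dx,
                "ridge_length": len(r),
                "strength": float(strength),
            }
        )
    rows.sort(key=lambda d: d["center"])
    # flag pairs closer than the wavelet resolution limit
    for i, row in enumerate(rows):
        near = [
            abs(row["center"] - other["center"]) < 2.0 * gmax
            for j, other in enumerate(rows)
            if j != i
        ]
        row["unresolved"] = bool(any(near))
    centers = np.array([r["center"] for r in rows])
    if full_output:
        return centers, pd.DataFrame(rows)
    return centers


def lorentzian(x: np.ndarray, area: float, center: float, fwhm: float) -> np.ndarray:
    """Area-parametrized Lorentzian line shape."""
    return (2.0 * area / np.pi) * fwhm / (4.0 * (x - center) ** 2 + fwhm**2)


def fit_lorentzians(
    spectrum: ExperimentalSpectrum | Spectrum,
    centers: np.ndarray,
    baseline: bool = False,
    assignments: dict[str, float] | None = None,
    label: object = None,
) -> PeakTable:
    """Fit a sum of Lorentzians with clamped centers.

    Intensities (areas) and bandwidths are the free parameters; centers
    are held fixed exactly, as is standard when maxima frequencies come
    from an independent peak-detection step.  An optional linear baseline
    can be enabled.
    """
    if isinstance(spectrum, Spectrum):
        nu, y = spectrum.nu, np.real(spectrum.values)
    else:
        nu, y = spectrum.nu, spectrum.absorbance
    centers = np.atleast_1d(np.asarray(centers, dtype=float))
    if centers.min() < nu.min() or centers.max() > nu.max():
        raise InputError("centers must lie within the spectral grid")
    dx = float(np.median(np.diff(nu)))
    params = lmfit.Parameters()
    for i, c in enumerate(centers):
        sel = np.abs(nu - c) < 10.0
        local = max(np.trapezoid(np.clip(y[sel], 0, None), nu[sel]), 1e-12)
        params.add(f"a{i}", value=local, min=0.0)
        params.add(f"w{i}", value=8.0, min=2.0 * dx, max=(nu[-1] - nu[0]))
    if baseline:
        params.add("b0", value=float(np.median(y)))
        params.add("b1", value=0.0)

    def model(p: lmfit.Parameters) -> np.ndarray:
        out = np.zeros_like(nu)
        for i, c in enumerate(centers):
            out += lorentzian(nu, p[f"a{i}"].value, c, p[f"w{i}"].value)
        if baseline:
            out += p["b0"].value + p["b1"].value * (nu - nu.mean())
        return out

    result = lmfit.minimize(lambda p: model(p) - y, params)
    if not result.success:
        raise AnalysisError(
            f"Lorentzian fit did not converge (residual {np.sqrt(np.mean(result.residual**2)):.3g})"
        )
    rows = []
    for i, c in enumerate(centers):
        a = result.params[f"a{i}"]
        w = result.params[f"w{i}"]
        degenerate = a.value < 1e-10 or w.value <= 2.0 * dx * (1 + 1e-6)
        rows.append(
            {
                "center": c,
                "area": a.value,
                "area_err": a.stderr if a.stderr is not None else np.nan,
                "fwhm": w.value,
                "fwhm_err": w.stderr if w.stderr is not None else np.nan,
                "height": 2.0 * a.value / (np.pi * w.value) if w.value > 0 else 0.0,
                "degenerate": degenerate,
            }
        )
    df = pd.DataFrame(rows)
    df["assignment"] = _assign(df["center"].to_numpy(), assignments)
    rms = float(np.sqrt(np.mean(result.residual**2)))
    return PeakTable(bands=df, residual_rms=rms, label=label)


def _assign(
    centers: np.ndarray, table: dict[str, float] | None, window: float = 10.0
) -> list[str]:
    table = BAND_ASSIGNMENTS if table is None else table
    labels = []
    for c in centers:
        best, dist = "other", window
        for name, nominal in table.items():
            d = abs(c - nominal)
            if d <= dist:
                best, dist = name, d
        labels.append(best)
    return labels


def normalize_bands(table: PeakTable, reference: str) -> PeakTable:
    """Normalize band areas to a reference band's integrated intensity."""
    sel = table.bands["assignment"] == reference
    if not sel.any():
        raise NormalizationError(f"reference band {reference!r} not in table")
    ref_area = float(table.bands.loc[sel, "area"].iloc[0])
    if ref_area <= 0:
        raise NormalizationError(f"reference band {reference!r} has zero area")
    df = table.bands.copy()
    df["area_norm"] = df["area"] / ref_area
    ref_height = float(table.bands.loc[sel, "height"].iloc[0])
    df["height_ratio"] = df["height"] / ref_height if ref_height > 0 else np.nan
    return PeakTable(
        bands=df,
        normalization_reference=reference,
        residual_rms=table.residual_rms,
        label=table.label,
    )


def trend_analysis(
    tables: list[PeakTable],
    labels: np.ndarray | None = None,
    fit: bool = True,
) -> dict:
    """Concentration / chain-length trends of band areas and widths.

    Returns ``{"series": tidy frame, "fits": per-band linear fits}``;
    fits (least squares vs the numeric label, with R^2) are only
    produced when at least three labelled tables are available.
    """
    if labels is None:
        labels = [t.label for t in tables]
    if len(labels) != len(tables):
        raise InputError("labels must align with tables")
    rows = []
    for lab, t in zip(labels, tables):
        for _, b in t.bands.iterrows():
            rows.append(
                {
                    "label": lab,
                    "assignment": b["assignment"],
                    "center": b["center"],
                    "fwhm": b["fwhm"],
                    "area": b["area"],
                    "area_norm": b.get("area_norm", np.nan),
                    "height_ratio": b.get("height_ratio", np.nan),
                }
            )
    series = pd.DataFrame(rows)
    fits = pd.DataFrame()
    if fit and len(tables) >= 3 and all(np.isreal(l) for l in labels):
        fit_rows = []
        for (assign,), grp in series.groupby(["assignment"]):
            if len(grp) < 3:
                continue
            x = grp["label"].to_numpy(float)
            for quantity in ("fwhm", "area_norm"):
                yq = grp[quantity].to_numpy(float)
                if np.any(~np.isfinite(yq)):
                    continue
                slope, intercept = np.polyfit(x, yq, 1)
                pred = slope * x + intercept
                ss_res = np.sum((yq - pred) ** 2)
                ss_tot = np.sum((yq - yq.mean()) ** 2)
                r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
                fit_rows.append(
                    {
                        "assignment": assign,
                        "quantity": quantity,
                        "slope": slope,
                        "intercept": intercept,
                        "r_squared": r2,
                    }
                )
        fits = pd.DataFrame(fit_rows)
    elif fit and len(tables) < 3:
        warnings.warn("fewer than 3 tables: linear fits omitted", stacklevel=2)
    return {"series": series, "fits": fits}
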