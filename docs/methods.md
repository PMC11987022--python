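# Methods

`fluorspec` analyzes how conformational exchange shapes infrared line
widths of helical perfluoroalkyl-like chains, from two directions: a
trajectory arm (dipole power spectra, normal-mode projection, helicity
dynamics) and an experimental arm (ATR Kramers–Kronig separation,
wavelet peak detection, constrained Lorentzian band fits). Everything
is exercised on synthetic data whose statistical structure is known
exactly, so each stage has an analytic oracle.

## The physical model

Linear perfluoroalkyl chains adopt a helical backbone; the left- and
right-handed helices are mirror-image minima separated by a modest
torsional barrier. C–F stretching normal modes are delocalized along
the backbone, and their transition dipole moments differ between the
two helicities. When a molecule reverses helicity at rate k (per
direction), the vibrational dipole μ_k^vib(t) = μ_k^{h(t)} q_k(t) is
the product of a harmonic normal-coordinate process q_k(t) and a
two-state (telegraph) factor. Because the telegraph autocorrelation is
e^(−2kt), the product's correlation decays faster, and the spectral
band — the Fourier transform of that correlation — broadens. For a
full dipole reversal (μ⁻ = −μ⁺) the excess width is exactly

    ΔFWHM = 4k / (2πc)   [cm⁻¹]

on top of the "helicity-frozen" width |μ⁻|² S_q̇q̇ set by the
vibrational damping γ alone (FWHM = γ/(2πc)). The integrated band
intensity is unchanged: exchange redistributes intensity into the
wings, it does not create or destroy it. These two statements — widths
add, areas don't change — are the package's central testable claims,
and both are verified against the analytic telegraph prediction over a
decade of flip rates.

## Units and conventions

Internal units: Å, fs, amu, elementary charge (energy unit
amu·Å²/fs² = 10⁴ kJ/mol). All spectra are one-sided densities per
cm⁻¹ on a wavenumber axis ν̃ = ω/(2πc); the integral over the axis
recovers the signal power (Parseval, tested to 2 % under 64-segment
Welch averaging). The Fourier convention is ṽ(ω) = dt·Σ v e^(−iωt),
S = |ṽ|²/t_max; the FFT path reproduces a direct O(T²) transform to
1e-10. Dihedrals are signed IUPAC angles in (−180°, 180°]; a helper
converts to the 0–360° convention used for gauche/trans labels
(gauche ±60° ↔ 60/300°, trans ±163° ↔ 163/197°).

## Normal modes and projection

Hessians are supplied as dense matrices (text or HDF5); mass-weighted
diagonalization follows projection of the rigid translations/rotations
onto the Eckart subspace (robust for floppy chains, where the six
smallest eigenvalues need not be the rigid ones). Mode vectors η are
orthonormal in mass-weighted coordinates, Cartesian displacements are
η_i/√m_i, and transition dipoles are point-charge dipole derivatives
per unit mass-weighted normal coordinate — conventions stated because
the literature usually leaves them implicit.

Frames are assigned a helicity by the sign of the overall-helicity
dihedral (atoms 1, 2, n−1, n of the backbone), rigid-fitted to the
reference of that helicity, and projected: q_k = η_k^(h)·√m(x_fit −
x_ref^(h)).

**Fit metric.** The default superposition for projection is the
mass-weighted all-atom fit. Its stationarity conditions are exactly
the Eckart conditions, which yields two exact properties: a
constructed single-mode displacement is recovered to machine precision
(including under arbitrary rigid transforms), and the point-charge
dipole decomposition μ = μ^rb + Σ μ_k q_k has identically zero
residual for any displacement inside the mode space. The unit-weight
carbon-subset fit — the customary choice for force-field trajectories,
where anharmonic deformation makes no metric exact — is available via
`fit="carbons"`; under it the residual grows linearly with
displacement amplitude (first-order rigid-rotation leakage through the
reference dipole), which the test suite measures. The residual is
always stored, never hidden, so decomposition quality is observable.

Gauche-containing frames can be masked before spectra; masked series
are split into contiguous trans runs that are Welch-windowed
individually (zero-filling would distort line shapes).

## Helicity dynamics

The helicity indicator θ(t) = sign(ϕ_overall) is debounced: sign
changes that revert within 100 fs (default) are treated as barrier
recrossings, not flips. The lifetime τ_hel comes from the indicator
ACF, either by integrating to the first decay below 0.01 (default) or
by an exponential fit. The integral estimator is biased low once the
ACF noise floor √(2τ/T) approaches the threshold; lifetime analyses
therefore use coarse sampling (0.1 ps) with long traces (≈0.8 µs),
where both reference lifetimes (2.9 ps and 1.5 ps, emulating dilute
and pure-liquid conditions via rates 1/(2τ)) are recovered within 5 %.

Free-energy profiles are −kT ln p from periodic 2° histograms
(min-shifted; empty bins flagged, not interpolated). The
transition-state-theory rate k = ν_att·exp(−ΔF‡/kT) takes the barrier
as the lowest saddle separating the two deepest minima; in auto mode
the attempt frequency comes from the harmonic curvature at the global
minimum with a user-supplied reduced inertia — the profile alone
carries no time scale, so auto-mode rates are meaningful as ratios.

## The experimental arm

ATR spectra mix the transmission-like Im(ε) with its dispersive
Kramers–Kronig partner; a Hilbert-transform rotation with a global 90°
phase recovers Im(ε). Two irreducible artifacts are handled
explicitly: the inversion is blind to the DC level of the spectrum
(re-anchored at the band-free edges), and window truncation of the
slowly decaying dispersive tails leaves a ~2 % smooth background.
Band areas are therefore quantified with the baseline-aware Lorentzian
fitter, and noisy spectra are co-added (as in FTIR practice) before
inversion; the round trip on the forward-modelled oscillator
dielectric then recovers areas to 2 % and centers to 0.5 cm⁻¹ at
single-scan SNR 20.

Peak maxima are found by a continuous wavelet transform with a
negated-second-derivative-Lorentzian analyzing function on a
geometric γ ladder (3–6 cm⁻¹, 8 scales). Ridges must persist over ≥3
scales and exceed 8× the median absolute deviation of the
finest-scale coefficients (8 rather than a smaller factor because the
ridge strength is a maximum over the ladder); centers come from
parabolic interpolation at each ridge's strongest scale, and maxima
within the wavelet support of the grid edges are discarded. Band
quantification fits a sum of Lorentzians with the maxima frequencies
clamped exactly; for concentration series the centers are detected
once on the first (narrowest-band) spectrum and held fixed, so merged
broad bands remain decomposable. Assignments (ν_a^OP(CF₃) 1236,
ν_a^IP(CF₃) 1220, ν_s(CF₂) 1135, ν_s(CF₃) 1353, ρ^IP(CH₃) 1020 cm⁻¹)
are nearest-center metadata within ±10 cm⁻¹, never inferred
spectroscopy.

## The synthetic generator

The generator exists to give every analysis stage inputs with known
ground truth; it emulates the *statistical structure* of fluorous
liquids, not their chemistry.

* **Geometry.** A carbon backbone built by internal-coordinate chain
  extension with two pendant pseudo-fluorine sites per carbon
  (q_F = −0.2 e, q_C = +0.4 e, net neutral). Interior backbone
  dihedrals sit at ±(180° − 17°); the outer pair is calibrated by
  root-finding so the overall-helicity dihedral deviates from trans by
  exactly 35°. (A uniform ideal chain cannot honor both printed
  angles at once; the middle dihedral is kept exact.) The minus
  conformer is the exact mirror image, and its mode set is obtained by
  mirroring the plus eigenvectors — H₋ = S H₊ S — which keeps mode
  ordering and degenerate subspaces consistent between helicities.
* **Hessian.** Bond/angle/dihedral springs in Gauss–Newton form
  Σ k g gᵀ with analytic internal-coordinate gradients (exact at the
  reference, where every spring is at its minimum; gradients verified
  against finite differences). Spring constants are chosen so the
  strongest IR modes fall in the 1000–1300 cm⁻¹ C–F band, and the
  torsional constant (500 kJ/mol/rad²) is stiff enough that thermal
  torsion never crosses the helicity branch — helicity changes only
  through explicit telegraph flips, keeping the harmonic analysis in
  its domain of validity. Exactly six rigid modes are removed; no
  imaginary frequencies.
* **Dynamics.** Each mode evolves by the *exact discretization* of the
  underdamped Langevin oscillator: the continuous transition matrix
  A = e^(M dt) and the stationary covariance give an ARMA(2,1)
  recursion whose sampled autocovariance equals the continuous one at
  every lag, so equipartition (⟨q²⟩ω₀² = kT) and the Lorentzian line
  width γ/(2πc) hold without time-step error. Helicity is an
  independent telegraph process; a flip instantaneously swaps
  reference geometry and transition-dipole set. Default damping
  0.5 ps⁻¹ (line width ≈2.7 cm⁻¹), default flip rate 1/(2·2.9 ps) —
  the dilute condition — temperature 300 K, dt 1 fs.
* **Dipole rotation.** μ_k⁻ is μ_k⁺ rotated by `dipole_rotation_angle`
  about the chain axis orthogonalized against that dipole, so the
  angle between the two transition dipoles equals the knob exactly
  regardless of mode orientation. Default 10° ("rotates slightly");
  mechanism analyses use 90° and 180°, where the broadening is
  maximal and analytic.
* **Concentration series.** One dataset per flip rate with a shared
  master seed (common random numbers): identical potential,
  thermodynamics and vibrational noise, differing in kinetics alone —
  so the invariance of the free-energy profile across the series is a
  sharp statement.
* **ATR forward model.** A Lorentzian-oscillator Im(ε) mixed with its
  Hilbert conjugate at a known phase plus seeded Gaussian noise.

What the generator does **not** emulate: real force-field energetics,
solvent molecules, intermolecular vibrational coupling (the mechanism
behind CF₃-band intensity reduction in dense fluorous phases, out of
scope here), resolved barrier crossings (flips are instantaneous), or
anharmonicity. Passing tests
therefore demonstrate that the *analysis chain* is correct and that
the exchange-broadening mechanism behaves as derived — not that any
particular real liquid matches the defaults.

## Ensemble averaging of line shapes

A single molecule's telegraph factor, windowed to a finite Welch
segment, has a periodogram with a spurious quasi-DC component of
weight ≈ 2τ_hel/T_seg; convolved with the vibrational line this leaves
a narrow replica of the unbroadened band that biases width fits. This
is a bias, not noise — it does not average away over segments of the
same molecule. Line-shape quantities are therefore ensemble averages
over molecules (8 in the workflow, 12 in the mechanism tests), with
segment lengths ≥2¹⁵ samples, mirroring the many-molecule averaging of
a liquid simulation. With 12 molecules at 2²¹ steps the measured
broadening matches 4k/(2πc) within 4 % across a decade of rates.

## Numerical choices

* Rotations exclude reflections (det = +1) even when a reflection
  fits better: the reference pair already encodes the mirror
  conformers, and a reflection would silently swap helicity.
* Width fits remove the derivative-spectrum tilt by multiplying with
  ((ν+ν₀)/2ν)² — the exact leading-order envelope of a damped
  oscillator's S_q̇q̇ — then fit an area-parametrized Lorentzian with
  an adaptive window (10× the current width estimate, iterated).
* Band intensities for conservation checks use direct integration of
  the tilt-flattened band over ±12 widths, which is robust where fit
  parameters are noisy.
* Welch defaults: Hann window, 50 % overlap, per-segment mean removal
  (DC dipole offsets otherwise leak into low-frequency bins); the
  rectangle window is kept for the analytic identities used in tests.
* Degenerate inputs fail loudly: empty stick lists, non-ATR input to
  the KK step (pass-through with warning), flat profiles in the TST
  analysis, too-few events in the conditional ACF (computed with a
  statistics warning above one event, undefined at zero).

## Problem sizes

Default test and acceptance sizes: 2¹⁴-step traces for the exact-FFT
check, 2²¹-step mode traces × 12 molecules for the mechanism, 2²³
coarse samples for lifetimes, 10⁶ Boltzmann samples for the
free-energy oracle, 1200-point spectra for the FTIR arm. The full
suite runs in about a minute; the acceptance script in under half a
minute.

## Known limitations

* The decomposition's exactness theorem holds only for fixed
  point-charge dipoles; polarizable or geometry-dependent dipole
  models would reintroduce a genuine quadratic residual.
* The integral lifetime estimator needs trace lengths ≫ 100 τ for its
  bias to stay under a few percent; the expfit alternative is less
  biased but noisier.
* The KK inversion's DC blindness means absolute band areas from ATR
  data are only defined relative to a baseline model.
* Helicity assignment by dihedral sign assumes vibrational
  fluctuations never cross the branch; for much floppier chains the
  debounce window, not the sign, carries the burden.
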