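# Methods

This note documents the models implemented in `helixorder`, the
numerical choices behind them, what the synthetic-data generators do and
do not emulate, and the known limitations.

## Order-parameter formalism

The surface selection rule of reflection-absorption IR spectroscopy on a
metal support states that only the transition-dipole component along the
surface normal absorbs. For an ensemble of amide I′ dipoles with tilt
θ to the normal, the film band intensity is proportional to ⟨cos²θ⟩,
while an isotropic reference layer has ⟨cos²θ⟩ = 1/3. The implemented
relation is therefore

    ⟨cos²θ⟩ = c_F / (3 c_R),

with c_F and c_R the integral α-helix amide I′ intensities of the film
and of an equivalent randomly oriented layer. This is a reconstruction
of the standard IRRAS intensity-ratio relation; it is validated against
its fixed points (c_F = c_R ⇒ θ = 54.74°, the magic angle, ⇒ S = 0;
c_F = 3c_R ⇒ θ = 0) and against the worked example θ = 43° ⇒ S₀ ≈ 0.6.
Ratios above 3 are unphysical and are clipped with a warning flag rather
than raised, since measured references carry normalization error. The
reference intensity can be rescaled by a surface-density matching factor
(`reference_scale`, default 1) when film and reference coverages differ.

The reported tilt is θ = arccos √⟨cos²θ⟩. The amide order parameter is
S_helix = P₂(cos θ) — note P₂ is affine in cos², so applying it to the
mean-square cosine equals averaging P₂ itself. Because the amide I
transition dipole makes a fixed angle α with the helix axis, the
Legendre addition theorem factorizes the measured order parameter into
axis and cone contributions, giving the helix-axis order parameter

    S₀ = S_helix / P₂(cos α).

α is treated as the literature range 34–38°: S₀ is evaluated at the
midpoint (36°) and the half-spread over the range is reported as its
uncertainty, combined in quadrature with any propagated intensity
uncertainty. α at (or a range straddling) 54.74° makes P₂(cos α) vanish
and is rejected as singular. Negative S₀ is a legitimate outcome
(helices preferentially in-plane or inverted), not an error.

The coordinate route computes the identical chain from molecular
geometry: unit C→O vectors of helix-assigned backbone carbonyls (the
amide I dipole lies along the C=O bond), cosines against the membrane
normal (+z by convention), averaged over carbonyls and frames. Tilt
angles are folded to [0°, 90°] because the order parameter is quadratic
in cos θ; the dipole sign is unobservable. Averaging is over cos²θ (not
over θ) since that is the quantity the intensity route measures; the two
routes then agree identically on the same ensemble.

## Band deconvolution

The amide I′ envelope is analyzed on the 1580–1780 cm⁻¹ window after
linear-endpoint baseline subtraction (the simplest reproducible
background model for an isolated envelope; no instrument baseline model
is assumed). Candidate band centers are the minima of a Savitzky–Golay
second derivative (window 11 points at the typical 4 cm⁻¹-resolution
grids, order 3), cross-checked against maxima of the Fourier
self-deconvolved spectrum. Candidates closer than 8 cm⁻¹ are merged,
the deeper second-derivative minimum winning, and candidates sitting on
less than 2% of the peak absorbance are discarded as curvature
artifacts.

Fourier self-deconvolution assumes Lorentzian components of fwhm
20 cm⁻¹. The interferogram is multiplied by exp(+πG|x|) under a
triangular apodization truncated at x_cut = 0.886·K/G, so an isolated
Lorentzian of the assumed width G comes out at the apodization-limited
width G/K; the narrowing factor K defaults to 2. The DC term is
untouched (area conserved; verified to better than 2%); the worst-case
amplification grows as exp(2.78·K) and sets a noise warning flag above a
configurable bound. K = 1 short-circuits to the identity, since any
apodization would otherwise alter the spectrum. The sharpened spectrum
is used only for seeding — the quantitative fit always runs on the
non-deconvolved data.

Fitting is constrained nonlinear least squares (Lorentzian default —
matching the FSD assumption — with Gaussian and pseudo-Voigt available):
centers bounded within ±5 cm⁻¹ of their seeds, widths within
6–60 cm⁻¹, areas non-negative, seeds closer than 4 cm⁻¹ rejected. A
free linear background term is included because the endpoint baseline
correction slightly over-subtracts (band wings make the window endpoints
nonzero); without it the wings of broad components are systematically
distorted. Areas are the analytic integrals of the fitted shapes, and
secondary-structure fractions are area fractions per assignment class.

The amide I′ (D₂O) assignment table: 1648–1660 α-helix, 1635–1648
random coil, 1620–1635 β-sheet, 1660–1685 turns, 1685–1695
high-frequency antiparallel β (reported as β-sheet), ≤1618 aggregated
β-sheets (intermolecular aggregation band near 1614 cm⁻¹). Only the
α-helix and aggregation anchors are firmly established; the remaining
boundaries are conventional choices, and components falling in the
1618–1620 and 1640–1648 gaps are reported as unassigned rather than
guessed.

## Helix assignment and membrane geometry

Residues are labeled helical when every defined backbone dihedral among
(φ, ψ) falls in φ ∈ [−100°, −30°], ψ ∈ [−67°, −7°], in runs of at
least 4 consecutive residues. This is a deliberately simplified,
geometry-only criterion — no hydrogen-bond energy term — chosen so that
canonical helices (φ, ψ ≈ −57°, −47°) are labeled correctly and
extended strands are not; it will differ from hydrogen-bond-aware
assignments on distorted or 3₁₀-like segments. Terminal residues carry
only one defined dihedral and are judged on it alone.

Membrane thickness splits headgroup atoms (default: atoms named `P`) by
the median of their normal-axis coordinates and measures the distance of
the leaflet means; area per lipid is in-plane box area over lipids per
leaflet. Both assume a planar bilayer with normal +z and no curvature
handling. Edge-to-edge distances are minimum atom-pair distances with
the orthorhombic minimum-image convention. Hydrogen bonds use the
geometric criterion: donor–acceptor ≤ 3.5 Å and D–H···A deviation from
linearity ≤ 30°, with hydrogens attached to the nearest heavy atom
within 1.3 Å; a distance-only mode covers hydrogen-free models.
Dual-cutoff contacts implement the hysteresis scheme — bound below
r_lower = 4.0 Å, released only above r_upper = 5.5 Å — which suppresses
flicker from lipid conformational rearrangement; equal cutoffs reduce to
plain thresholding. The cutoff defaults are conventional values for
heavy-atom lipid–protein contacts.

## Monolayer analysis

The compressibility modulus Cs⁻¹ = −A(dΠ/dA) is computed from
Savitzky–Golay-smoothed pressure (window 7, order 2) with centered
finite differences, returned on the interior grid; the scheme is exact
for linear isotherms and invariant under pressure offsets. The
liquid-disordered/liquid-ordered transition is located at the deepest
Cs⁻¹ minimum between two regime maxima; a single-regime isotherm
returns a no-transition result rather than an error, and all candidate
dips are reported. Adsorption records are summarized by
ΔΠ = Π(end) − Π(injection), the initial rate (linear fit over the
first 200 s post-injection), the plateau pressure, and a two-phase flag
raised when the late-window slope (last half of the record) falls below
half the initial rate while ΔΠ exceeds the pre-injection noise — the
signature of fast interfacial accumulation followed by slow
rearrangement.

The all-trans chain extension uses the standard geometry
l(Å) = 1.5 + 1.265·(n_C − 1): a terminal-group correction plus the
projected C–C advance per bond, which gives 1.79 nm for a C14
(myristoyl) chain. The limiting solid-state bilayer thickness is
2·(chain + headgroup), with 0.8 nm as the default polar-headgroup
thickness.

## Synthetic data: what it emulates, and what it does not

Generators are seeded (`numpy.random.default_rng`) and bit-reproducible;
each returns a planted-truth record sufficient to predict the downstream
result in closed form.

* **Spectra** are exact sums of analytic band shapes plus a linear
  baseline and additive white Gaussian noise. The solution-phase set
  places five Lorentzians at 1689/1675/1653/1639/1623 cm⁻¹ with the
  helix band (fwhm 34 cm⁻¹) at 50% of total area; the membrane-phase set
  moves the helix band to 1650 cm⁻¹ (fwhm 30.6 cm⁻¹) and scales it by a
  surface-selection enhancement factor, optionally adding a 1614 cm⁻¹
  aggregation band. Minor-band widths (20 cm⁻¹) and the minor-area split
  are generator choices fixed once; they are not anchored to published
  values. Not emulated: detector drift, water-vapor lines, scattering
  baselines, H/D-exchange kinetics — so passing tests demonstrate
  correct recovery of well-posed band mixtures, not robustness to every
  instrumental artifact.
* **Helix ensembles** build ideal poly-alanine backbones by internal
  coordinates (NeRF; rise and twist follow from canonical φ, ψ =
  −57°, −47°), rotate them to axis directions drawn from a delta,
  Gaussian, or isotropic tilt distribution, and place carbonyl O atoms
  on an exact cone of half-angle α about each axis with uniform azimuth.
  The planted carbonyl order parameter is P₂(cos β)·P₂(cos α) by the
  addition theorem. Real helices have dipole-angle dispersion and
  non-ideal geometry; the cone is exact here by construction.
* **Bilayers** are 3-atom pseudo-lipids (P head + two chain beads) on a
  lattice with planted area per lipid and leaflet separation — enough
  for every geometric observable, with no force-field realism claimed.
* **Isotherms** integrate a planted pressure-gradient profile whose
  magnitude collapses in a narrow Gaussian region around the transition
  area, producing a Cs⁻¹ dip between two regime maxima; **kinetics**
  superpose a fast exponential and a slow linear phase; **approach
  curves** decay exponentially to a bound plateau.

## Problem sizes and tolerances

The test suite and the acceptance script use ensemble sizes chosen so
Monte-Carlo error is comfortably below the assertion tolerances: 10⁶
vectors for the isotropic fixed point (standard error of S ≈ 4.5×10⁻⁴),
~2×10⁴ carbonyls per planted-tilt recovery (tolerance ±0.02), and
0.25–0.5 cm⁻¹ spectral grids matching 4 cm⁻¹-resolution instruments.
Fits assert recovery at 0.1–1 cm⁻¹ on centers and 0.2–0.5 cm⁻¹ on
widths for noiseless inputs, reflecting optimizer tolerance rather than
model error.

## Limitations

* Eq-level optical corrections (Fresnel factors of the
  metal/electrolyte/film stack) are not modeled; the intensity-ratio
  relation assumes they cancel between film and reference.
* The dihedral helix criterion ignores hydrogen bonding; fractional
  helicities on real structures will differ from hydrogen-bond-aware
  algorithms by a few percent.
* Binary trajectory formats (DCD/XTC) are not read; PDB multi-model and
  plain XYZ only.
* Force-field energetics, electrostatic surface potentials, and
  instrument control are out of scope.
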