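# helixorder

Orientation analysis of membrane-associated helical proteins from
infrared band intensities and from molecular coordinates.

## The problem

Proteins that work on membrane surfaces — for instance cryptochrome-4a of
the European robin (ErCry4a), the candidate magnetoreceptor whose
membrane docking motivated this package — are only useful to their host
if they bind in a *defined orientation*. Polarization-modulation infrared
reflection-absorption spectroscopy (PM-IRRAS) of a supported membrane
film can measure that orientation: by the surface selection rule, only
the component of a vibrational transition dipole along the surface
normal absorbs, so the intensity of the α-helix amide I′ band (backbone
C=O stretch in D₂O, near 1653 cm⁻¹) reports the mean helix tilt.

`helixorder` implements the complete analysis chain:

1. **Band deconvolution** — the overlapped amide I′ envelope
   (1580–1780 cm⁻¹) is resolved into component bands by second-derivative
   seeding, Fourier self-deconvolution (Lorentzian kernel, fwhm
   20 cm⁻¹), and constrained least-squares fitting; component areas give
   secondary-structure fractions.
2. **Order parameters** — the film/reference intensity ratio gives the
   mean transition-dipole tilt via ⟨cos²θ⟩ = c_F/(3 c_R); then

   S_helix = P₂(cos θ) = (3 cos²θ − 1)/2,  S₀ = S_helix / P₂(cos α),

   where α = 34–38° is the characteristic angle between the amide I
   transition dipole and the helix long axis. S₀ = 1 means helix axes
   along the membrane normal, 0 isotropic, negative values an in-plane or
   inverted orientation.
3. **Coordinate route** — the same S₀ from molecular structures:
   backbone C=O vectors of dihedral-assigned helices versus the membrane
   normal, averaged over carbonyls and frames. Membrane observables
   (thickness, area per lipid, edge-to-edge distances, hydrogen bonds,
   dual-cutoff lipid contacts) support the comparison.
4. **Monolayer analysis** — Langmuir Π–A compressibility modulus
   Cs⁻¹ = −A(dΠ/dA), liquid-disordered/liquid-ordered transition
   detection, adsorption kinetics Π(t), and all-trans acyl-chain
   geometry.
5. **Synthetic data** — seeded generators with planted ground truth for
   every input (spectra, helix ensembles, toy bilayers, isotherms,
   kinetics, approach curves), so the whole pipeline is testable without
   measured data.

## Worked example

```python
import helixorder as ho
from helixorder import synthetic as syn

# a randomly oriented reference and a film whose helix band is enhanced
ref_spec, _  = syn.gen_spectrum(syn.solution_phase_bands())
film_spec, _ = syn.gen_spectrum(syn.membrane_phase_bands(helix_enhancement=1.6047))

film = ho.AmideBandModel(film_spec).fit()
ref  = ho.AmideBandModel(ref_spec).fit()
print(ref.summary())

result = ho.orientation_pipeline(film, ref, alpha=(34.0, 38.0))
print(result.summary())
```

prints

```
Amide I' band deconvolution
   center    fwhm       area  fraction  assignment
  1623.00   20.00       0.11     0.110  beta_sheet
  1639.00   20.00       0.17     0.170  random_coil
  1653.00   34.00        0.5     0.500  alpha_helix
  1675.00   20.00       0.14     0.140  turn
  1689.00   20.00       0.08     0.080  beta_sheet
residual rms: 9.07e-14
  alpha_helix       50.0%
  beta_sheet        19.0%
  random_coil       17.0%
  turn              14.0%
Helix orientation analysis
  mean dipole tilt theta :   43.00 deg
  S_helix = P2(cos th)   :  0.3023
  S_0 (alpha 34-38 deg)  :  0.6276 +- 0.0657
```

Reading: the solution-phase spectrum deconvolves into five bands with
the α-helix component at 1653 cm⁻¹ (fwhm 34 cm⁻¹) carrying 50% of the
area; the film's 1.6× helix-band enhancement corresponds to a mean
dipole tilt of 43° from the membrane normal and a helix-axis order
parameter S₀ ≈ 0.6 — a strongly ordered, upright helix population. The
same number comes from coordinates:

```python
frame, truth = syn.gen_helix_ensemble(100, ("delta", 0.0), cone_alpha=43.0)
print(ho.ensemble_order_parameter(frame).summary())
#   mean dipole tilt theta :   43.00 deg
#   S_helix = P2(cos th)   :  0.3023
#   S_0 (alpha 34-38 deg)  :  0.6275 +- 0.0657
#   samples                : 1200
```

A command-line interface mirrors the library
(`helixorder deconvolve|orient|mdorient|isotherm|kinetics|simulate`);
every run writes a `report.json` with the configuration, seed and
results.

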