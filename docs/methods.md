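# Methods

This note records the models implemented in `azochrom`, their assumptions,
the defaults that matter, and the choices made where the design was
genuinely open. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Spectroscopic model

Absorbance of a cis/trans azobenzene population is strictly linear:
`A(λ) = c·l·(x_t ε_t(λ) + x_c ε_c(λ))` with path `l` in cm and total
concentration `c` in M. Only the band maxima of Pap are experimentally
anchored (trans: 326 nm / 21 500 and 423 nm / 1 380 M⁻¹cm⁻¹; cis: 293 nm /
6 700 and 426 nm / 2 120 M⁻¹cm⁻¹). The shipped default spectrum
(`IsomerSpectra.default_pap`) is a **synthetic fixture**: two Gaussian
bands per isomer, widths σ = 28/40 nm (trans) and 28/45 nm (cis), with
amplitudes solved so the summed spectrum passes exactly through the four
anchored (λ_max, ε) pairs. It is a smooth, plausible stand-in for
off-maximum wavelengths, not a claim about the true band shapes; measured
spectra can be loaded from CSV (`wavelength_nm, eps_trans, eps_cis`).
Between grid points ε is interpolated linearly (1 nm default grid, smooth
bands); outside the grid a range error is raised rather than extrapolated.

Isomer unmixing solves the 2-component linear system at ≥2 wavelengths by
unconstrained least squares and projects the solution onto the probability
simplex; a projection displacement > 0.02 is flagged, since it indicates an
inconsistent concentration or path-length input rather than noise. Systems
with condition number > 1e8 are rejected as unidentifiable.

Extinction regression is zero-intercept by design: a blank-corrected
photometer reads A = 0 at c = 0, and forcing the origin halves the slope
variance on short dilution series. The standard error uses n − 1 degrees of
freedom (one parameter).

The extinction ratio ε_trans/ε_cis = 8.3 at the 355 nm switching
wavelength is treated as a given constant where needed (PSS arithmetic);
it is not reconstructed from the synthetic band shapes.

## Photoisomerization kinetics

Both light-driven isomerization and thermal back-relaxation are first
order, so a population under constant illumination follows a single
exponential toward a rate-weighted attractor:

    x_cis(t) = x_eq + (x_cis(0) − x_eq)·exp(−(k_photo + k_thermal)·t),
    x_eq = k_photo·x_cis(PSS) / (k_photo + k_thermal).

The thermal attractor is pure trans (the ground state); the photochemical
attractor is the photostationary state of the active wavelength. The PSS
balance `x_c/x_t = ε_t Φ_tc / (ε_c Φ_ct)` is exposed through
`pss_cis_fraction` (and its inverse for the quantum-yield ratio), but the
default phases bypass quantum yields entirely and set the printed
observables directly:

| phase    | x_cis at PSS | k_photo (1/h) | rationale |
|----------|--------------|---------------|-----------|
| dark     | —            | 0             | composition frozen (thermal only) |
| uv355    | 0.95         | 5e4           | LED drives the PSS within one plate-transfer time at 1 mL/min |
| blue430  | 0.225        | 5e4           | 70–80 % trans at the PSS; midpoint of the observed 20–25 % cis |
| daylight | 0.225        | 0.1           | same PSS, but so slow that a several-CV wash sees a quasi-frozen mix |

k_thermal defaults to ln 2 / 196 h everywhere — negligible on
chromatographic timescales (minutes) but exact over storage timescales.
The LED rate constant is a device property, not a molecular one; it is a
free parameter chosen fast enough that the distinction between "PSS
reached in one plate step" and "instantaneous" is immaterial, which is the
regime a multi-mW LED at a 1 mL bed realizes.

Relaxation fitting is plain least squares on
`A(t) = A∞ − (A∞ − A0)·exp(−ln2·t/t½)`. A trace sampled every 12 h to
100 h covers only half of a 196 h half-life, so the plateau is barely
self-determined; the fitter therefore accepts a `fixed_Ainf` carried over
from a companion experiment that does reach its asymptote (the
photo-driven rise), and warns when the observed span is < 0.1·t½.
Constant traces raise an unidentifiability error rather than returning a
degenerate fit.

## Titration isotherm and K_D estimation

The forward model is the closed-form mass-action solution at the diluted
composition (see README for the full expression). It was verified
algebraically and numerically against an independent oracle that solves
`K_D = (P−b)(L−b)/b` by root bracketing on the physical branch
`0 ≤ b ≤ min(P, L)`; the two agree to < 1e-8 AU over the relevant
parameter space (this equivalence is a test and an acceptance check).
`K_D = +inf` is an explicit "no binding" sentinel giving pure dilution.

Fitting is bounded least squares over (K_D > 0, ε_free ≥ 0, ε_bound ≥ 0),
initialized from the data: ε_free from the first point, ε_bound from the
dilution-corrected last point, K_D from the free-host concentration at the
half-effect volume. No sign is assumed for ε_bound − ε_free (the
complexation shift is negative for α-CD at 326 nm but positive for β-CD).
Path length defaults to 1 cm and is exposed.

Identifiability gate: the dilution-corrected signal `A·(V₀+V_CD)/V₀` is
constant for a non-binding system, so the fitter first estimates the noise
floor robustly (MAD of second differences, which ignores the few strongly
curved points near the binding transition) and raises an unidentifiability
error when the corrected span is below 6 noise-sd or a relative floor of
1e-6. Such series carry at best a lower bound on K_D and are better
described by a straight dilution line. A warning is issued when the final
host:guest excess is < 10, where K_D and ε_bound become strongly
correlated.

Competitive blocking uses simple single-site saturation L/(L + K_D),
valid when the competitor is in large excess over the protein.

## Column simulator

Craig model: `n_plates` serial equilibrium stages; one flow step moves the
mobile contents of each plate down by one, the last plate's mobile phase
becomes effluent, and every plate then re-equilibrates by the 1:1 binding
quadratic. Defaults:

- `n_plates = 30` — with this plate count a non-binding species clears
  completely within 2 bed volumes and a K_D = 91 µM species at 10 mM
  sites migrates < 10 % of the bed over a 10-CV dark wash;
- `bed_volume = 1 mL`, `flow_rate = 1 mL/min` — bench-scale column;
- `ligand_conc = 10 mM` — a calibration parameter (the true accessible
  site density of an epoxy-coupled matrix is not measurable directly),
  set to give a dynamic capacity of order 10 mg protein per mL bed;
- `transmission = 0.5` — a single factor on photochemical rates inside
  the bed, representing the ≥ 50 % light intensity measured inside a
  packed agarose column; no depth-resolved attenuation profile is
  modelled because scattering in the opaque bed randomizes path lengths.

Simplifications, stated as such: the plate mobile volume equals
bed_volume/n_plates (void fraction 1, no hold-up volume — the qualitative
predictions quoted in bed volumes are insensitive to this at plate-model
fidelity); binding within a plate is local-equilibrium rather than
kinetic, since association/dissociation rate constants are not available;
each species/isomer pool equilibrates independently against the full site
pool, which is exact in the trace-load regime (nmol loads against ~330
nmol sites per plate) and avoids a coupled multi-species solve; and a
species with a `competitor_block` fraction is split at load time into a
bindable and a permanently blocked (mobile) sub-pool.

Illumination updates the per-plate isomer composition with the same
exponential law as in free solution (k_photo scaled by transmission),
pools free+bound material per isomer before the update, and immediately
re-equilibrates — so material switched to the non-binding cis state
becomes mobile within the same step, which is what makes UV elution sharp
(≈1.1 bed volumes to 95 % recovery in the default High-Purity run).

Sample loading is part of the flow: the declared `load_volume` of sample
enters plate 1 over the corresponding number of flow steps under the
first program step's illumination. This is what differentiates the two
operating modes: loading in the dark ("High-Purity") lets the cis
fraction of a daylight-equilibrated sample pass straight through but
freezes the retained band, while loading and washing under 430 nm light
("High-Yield") keeps reconverting cis to trans inside the bed — capturing
more material at the cost of a visibly creeping band during the wash.
Both behaviors are asserted as directional tests, not calibrated numbers.

In the large-n, trace-load limit with a dynamically maintained PSS the
band velocity reduces to the analytic retention factor
`v ≈ x_cis + x_trans·K_D/(K_D + L)` plates per step (L = site
concentration); the simulator matches this to ~2 % at 100 plates, and
band spread shrinks roughly as 1/√n_plates, as plate theory predicts.

The maltose-binding protein is the one host-cell contaminant with genuine
matrix affinity; its α-CD affinity is not separately known, so the
simulator and the lysate generator use its maltose K_D (3.5 µM) as a
documented proxy. With 5 mM maltose in the extract,
`competitive_occupancy(3.5 µM, 5 mM) ≈ 0.9993` of its pockets are
blocked, and the simulated MBP washes out essentially completely.

## Synthetic data

Generators default to the documented experimental conditions: titrations
of 50 µM guest in 2 mL with a 50 mM host stock added in 1–20 µL aliquots
to 200 µL total (1:100 final molar ratio, 10 % dilution; cis titrations
at 100 µM guest, 426 nm); relaxation traces at 12 h intervals to 100 h
(9 points); dilution series at 5–50 µM. Noise is homoscedastic Gaussian
on absorbance, default σ = 0.002 AU — an assumption about a well-behaved
diode-array photometer, not a measured value — and every generator is
bit-reproducible for a fixed seed. The ε of the bound complex is not
tabulated anywhere, so the generators use plausible shifts (21 500→19 000
for α-CD at 326 nm, →23 000 for β-CD; 2 120→2 800 for the cis/β-CD pair);
what passing recovery tests show is therefore that *the estimator
recovers the parameters of data generated by its own forward model under
realistic noise*, not that these are the true complex spectra. Real-data
features deliberately absent: baseline drift, correlated spectral noise,
mixing dead-time effects, higher-order stoichiometries.

## Known limitations

- The titration model is strictly 1:1; 2:1 inclusion modes are out of
  scope.
- The plate simulator has no axial dispersion PDE, no pH/salt
  dependence, and no fouling/reuse model; plate count is an effective,
  not a measured, quantity.
- Daylight photokinetics during washing is represented by a slow free
  parameter; its true rate depends on ambient conditions and is not
  quantified.
- Quantum yields enter only as a ratio, and only if the user chooses to
  derive PSS compositions rather than set them directly.
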