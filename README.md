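# azochrom

Quantitative models for **light-controlled affinity chromatography** of
proteins carrying an azobenzene photoswitch.

The photoswitchable amino acid *p*-(phenylazo)-L-phenylalanine (Pap) flips
between a planar *trans* ground state and a bulky, metastable *cis* state
under near-UV light. Only *trans*-Pap binds the cavity of
α-cyclodextrin (α-CD), so a protein carrying a short Pap-containing
"Azo-tag" adsorbs to an α-CD column in the dark or daylight and elutes in
plain running buffer the moment the bed is illuminated at 355 nm — no
competing ligand, no pH or salt step. `azochrom` implements the three
quantitative layers behind this separation principle:

1. **Spectroscopy** (`azochrom.spectra`) — Beer–Lambert forward model for
   cis/trans mixtures, two-wavelength isomer unmixing, and zero-intercept
   extinction-coefficient regression
   (ε₃₂₆ = 21 500 M⁻¹cm⁻¹ for *trans*-Pap).
2. **Photokinetics** (`azochrom.photokinetics`) — photostationary-state
   (PSS) composition from ε and quantum-yield ratios
   (x_cis/x_trans = ε_t Φ_tc / ε_c Φ_ct; ≈95 % *cis* at 355 nm, 70–80 %
   *trans* under daylight/430 nm), first-order approach to the PSS, and
   the slow thermal *cis*→*trans* relaxation (t½ ≈ 196 h), with a
   mono-exponential fitter.
3. **Binding** (`azochrom.binding`) — the dilution-corrected 1:1
   host–guest titration isotherm. With V₀ the initial cuvette volume,
   V_CD the cumulative titrant volume and K_D the dissociation constant,

   ```
   A(V_CD)·(V₀+V_CD) = (V₀C⁰_Pap − V_CD C⁰_CD − (V₀+V_CD)K_D)·ε_Pap/2
                     + (V₀C⁰_Pap + V_CD C⁰_CD + (V₀+V_CD)K_D)·ε_Pap·CD/2
                     + (ε_Pap − ε_Pap·CD)·√[(V₀+V_CD)²·((V₀C⁰_Pap+V_CD C⁰_CD)/(2(V₀+V_CD)) + K_D/2)² − V₀V_CD C⁰_Pap C⁰_CD]
   ```

   which is the physical root of the mass-action quadratic at the diluted
   composition, combined with Beer–Lambert absorbance. `TitrationFit`
   estimates (K_D, ε_free, ε_bound) by bounded nonlinear least squares.
4. **Column simulation** (`azochrom.column`) — a Craig theoretical-plate
   model of the α-CD bed that couples per-plate binding equilibrium,
   isomer photokinetics under programmable illumination, and stepwise
   flow, reproducing the operational behavior: tight retention of the
   *trans* state during a dark or daylight wash, immediate mobilization
   under 355 nm light, "High-Yield" capture under continuous 430 nm
   illumination versus tighter "High-Purity" retention in the dark.

A seeded generator module (`azochrom.synthetic`) produces every input the
fitters and the simulator consume — titrations, relaxation traces,
dilution series and lysate-like species mixtures (including the untagged
by-product of incomplete amber suppression) — so the entire pipeline is
testable without any instrument data.

The fitting classes follow the scikit-learn estimator protocol
(`fit`/`predict`, `get_params`, trailing-underscore attributes) and
compose with sklearn tooling; `fit_titration`, `fit_relaxation` and
`fit_extinction` are functional wrappers.

## Worked example

```python
from azochrom import (BindingParams, fit_titration, run_program, ColumnConfig,
                      Program, ProgramStep, SpeciesSpec, IsomerFractions,
                      NO_BINDING, standard_phases)
from azochrom.synthetic import NoiseModel, make_titration

# --- fit a synthetic alpha-CD / trans-Pap titration --------------------
truth = BindingParams(K_D=91e-6, eps_free=21500.0, eps_bound=19000.0)
series = make_titration(truth, noise=NoiseModel(sigma_absorbance=0.002, seed=0))
fit = fit_titration(series)
print(f"K_D = {fit.K_D_*1e6:.1f} +/- {fit.stderr_['K_D']*1e6:.1f} uM")

# --- High-Purity purification run --------------------------------------
phases = standard_phases()
poi = SpeciesSpec("poi", 10.0, IsomerFractions.from_cis(0.225),
                  K_D_trans=91e-6, K_D_cis=NO_BINDING)
host = SpeciesSpec("host", 100.0, photoactive=False)   # non-binding lysate bulk
program = Program(steps=(ProgramStep(3.0, phases["dark"]),
                         ProgramStep(3.0, phases["uv355"])), load_volume=0.1)
chrom = run_program(ColumnConfig(), [poi, host], program)
light_on = chrom.phase_start_volumes["uv355"]
print(f"eluted to 95% within {chrom.elution_volume('poi', light_on):.2f} bed volumes of UV-on")
print(f"purity in the elution window: {chrom.purity('poi', light_on, light_on+1.5):.4f}")
```

Output:

```
K_D = 96.8 +/- 4.1 uM
eluted to 95% within 1.10 bed volumes of UV-on
purity in the elution window: 1.0000
```

The fitted K_D of 96.8 ± 4.1 µM recovers the 91 µM ground truth from a
titration carrying 0.002 AU instrument noise. In the column run, the
sample is loaded in the dark (22.5 % of the tag in the non-binding *cis*
state flows through with the untagged bulk), the retained *trans*
population barely moves during a 3-bed-volume dark wash, and switching on
355 nm light elutes 95 % of the bound protein within 1.10 bed volumes at
effectively complete purity.

The same workflows are available from the shell:

```bash
azochrom make-data titration --seed 3 --out titr.csv
azochrom fit-titration --input titr.csv --v0 2.0 --c0-pap 50e-6 --c0-cd 50e-3
azochrom simulate-column --config run.yaml --out chrom.csv
```

## Layout

```
src/azochrom/
  spectra.py        Beer-Lambert model, unmixing, extinction regression
  photokinetics.py  PSS composition, isomer dynamics, relaxation fitting
  binding.py        dilution-corrected titration isotherm and K_D fitting
  column.py         Craig plate simulator with illumination programs
  synthetic.py      seeded data generators
  io.py, cli.py     CSV/YAML boundaries and the `azochrom` CLI
docs/methods.md     model assumptions, defaults, numerical choices
```
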