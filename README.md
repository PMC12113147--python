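# lnpsaxs

Small-angle X-ray scattering (SAXS) analysis of lipid nanoparticles (LNPs)
with a polydisperse spherical core–triple-shell model.

LNPs — the delivery vehicles of mRNA vaccines — organise into a hydrophobic
core wrapped by an inner lipid layer, a hydrophilic headgroup layer, and a
hydrated PEG corona. A solution SAXS curve encodes this whole radial
architecture, but extracting it needs a forward model and a fitting engine.
This package provides both, for structural scientists and formulation
developers who characterise LNPs at synchrotron beamlines or with lab
sources.

## Model

The single-particle amplitude is a telescoping sum of uniform-sphere
amplitudes over the four interfaces (core radius *R*c, shell thicknesses
*t*₁, *t*₂, *t*₃; scattering length densities ρc, ρ₁, ρ₂, ρ₃ and solvent
ρs):

```
A(q) = (ρc−ρ1)·V(Rc)·j(qRc) + (ρ1−ρ2)·V(Rc+t1)·j(q(Rc+t1))
     + (ρ2−ρ3)·V(Rc+t1+t2)·j(…) + (ρ3−ρs)·V(Rc+t1+t2+t3)·j(…)
```

with V(R) = (4/3)πR³ and j(x) = 3(sin x − x cos x)/x³. The measured
intensity averages A² over a Gaussian distribution of the core radius
(mean *R*₀, spread σ; shells ride rigidly on the core),

```
I(q) = scale · ∫ N(Rc) [A(q; Rc)]² dRc + P(q) + Bg ,
```

where P(q) = A·exp(−(q−C)²/2W²) is an optional Gaussian quasi-Bragg peak
describing the quasi-periodic mRNA–ionizable-lipid packing inside loaded
particles, and Bg is a flat background. Derived metrics: the
polydispersity index σ/R₀ and the packing repeat distance d = 2π/C.

Fitting is bounded trust-region nonlinear least squares with the standard
identifiability pins for relative-intensity data (ρs = 0, t₂ = 0.3 nm,
t₃ = 4 nm, core SLD fixed; `scale` absorbs number density and absolute
contrast).

## Worked example

`python examples/fit_mrna_curve.py` simulates an mRNA-LNP curve
(R₀ = 22.01 nm, σ = 2.65 nm, peak at 1.27 nm⁻¹, 1% noise) and fits it from
a cold start:

```
reduced chi^2       : 0.84  (about 1 = noise-limited fit)
core radius R0      : 22.01 nm   (truth 22.01)
size spread sigma   : 2.65 nm    (truth 2.65)
inner shell t1      : 1.82 nm    (truth 1.85)
peak center C       : 1.271 nm^-1 (truth 1.27)
peak width W        : 0.280 nm^-1 (truth 0.28)
sigma/R0            : 0.120  (polydispersity index)
d = 2 pi / C        : 4.94 nm  (repeat distance of the mRNA-lipid packing)
```

Every generating parameter is recovered to within a couple of percent; the
derived σ/R₀ = 0.120 quantifies size uniformity and d ≈ 4.94 nm is the
repeat distance of the internal mRNA–lipid assembly. The other examples
cover the simulation sweeps (`simulate_sweeps.py`), the N/P-ratio series
(`np_ratio_series.py`) and multi-frame QC (`frame_qc_averaging.py`).

## Command line

```
lnp-saxs simulate --preset table1-mrna --noise-level 0.01 --seed 1 --out mrna.dat
lnp-saxs fit mrna.dat --peak --out-prefix mrna_fit
lnp-saxs sweep --vary sigma --values 1,2,3,4,5,6 --out sweeps/
lnp-saxs recover --preset table2-NP3 --replicates 5 --out recovery.json
lnp-saxs frames frame*.dat --out averaged.dat
```

Input curves are plain-text 2–3 column files (q [nm⁻¹], I, optional error);
`--unit angstrom` converts Å⁻¹ grids. Named presets cover the fitted
parameter rows for empty LNPs, mRNA-LNPs and the N/P 3:1–8:1 series.

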