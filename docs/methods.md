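# Methods

## Forward model

A lipid nanoparticle is represented as a sphere of core radius Rc with
three concentric shells of thicknesses t1 (inner lipid layer), t2
(hydrophilic headgroup layer) and t3 (PEG corona), each of uniform
scattering length density (SLD). Because scattering only senses SLD
*contrasts*, the amplitude telescopes into four uniform-sphere terms, one
per interface, each the product of the SLD step, the enclosed volume
V(R) = (4/3)πR³ and the sphere shape function j(x) = 3(sin x − x cos x)/x³.
The q = 0 point is excluded from all evaluation grids (the forward delta
contribution of the solvent is unobservable); the q→0⁺ limit of the
amplitude is the plain contrast-volume sum.

j(x) is evaluated by its closed form above x = 10⁻² and by the Taylor
series 1 − x²/10 + x⁴/280 below, where the closed form loses ~8 digits to
cancellation; the two branches agree to 10⁻¹⁰ relative across the switch.

## Polydispersity

Only the core radius is polydisperse; the shells ride rigidly on it. The
core radius follows a Gaussian with mean R0 and standard deviation σ, and
the intensity is the number-weighted average of A² over that distribution:

    I(q) = scale · ∫ N(Rc) A(q; Rc)² dRc + P(q) + Bg .

The integral uses fixed 201-node Gauss–Legendre quadrature on
[max(10⁻³ nm, R0 − 6σ), R0 + 6σ]. The sub-zero tail is truncated without
renormalising: for every physically relevant σ/R0 ≤ 0.3 the truncated mass
is below 10⁻⁸, and a deterministic quadrature is exactly reproducible and
oracle-checkable (the test suite compares it against a 10⁵-node Riemann
sum at 10⁻⁴ relative). σ = 0 switches to the closed monodisperse form.

Number density n and the absolute contrast magnitude are not separately
identifiable from relative-intensity data; a single `scale` factor absorbs
both, and SLDs stay in arbitrary units with the solvent pinned at 0.

## Quasi-Bragg peak

mRNA loading creates a quasi-periodic mRNA–ionizable-lipid packing that
shows up as a broad diffraction-like bump near q ≈ 1.2 nm⁻¹. It is modelled
as an additive Gaussian A·exp(−(q−C)²/2W²) on top of the form factor,
with W interpreted as the Gaussian standard deviation — the common
convention in small-angle fitting suites; a FWHM interpretation would only
rescale W by 2.355. The repeat distance is d = 2π/C.

## Fitting

Weighted bounded least squares, minimising Σ wᵢ(Iᵢ − model(qᵢ))² with a
trust-region-reflective backend (lmfit/`least_squares`). Weights: 1/err²
when the curve carries reported uncertainties, else 1/I² ("proportional"),
which weights all decades of a log-spanning curve evenly; unweighted is
available. Defaults pin the parameters that relative-intensity LNP data
cannot resolve: ρs = 0, t2 = 0.3 nm (headgroup layer), t3 = 4 nm (hydrated
PEG-2000 corona), plus the core SLD — pinning one SLD breaks the exact
scale↔contrast degeneracy, and a config validator rejects configurations
with `scale` and all five SLDs simultaneously free. Default bounds
(R0 ∈ [5, 100] nm, σ ∈ [0.1, 10] nm, t1 ∈ [0.5, 6] nm, SLDs ∈ [±0.01],
C ∈ [0.8, 2] nm⁻¹, W ∈ [0.05, 1] nm⁻¹) span all parameter values reported
for LNP systems with margin.

Parameter standard errors come from the Jacobian-based covariance at the
optimum; goodness of fit is the reduced χ². Optional seeded multi-start
(perturbed initials, best objective wins) is available but off by default:
on the synthetic data the single bounded fit converges reliably.

Cold-start initial values are read off the curve itself: the first
windowed local minimum of I·q⁴ below 0.5 nm⁻¹ is mapped through the
uniform-sphere first zero (qR ≈ 4.493) and reduced by the nominal t1 + t2
to give R0; the background from the median of the top-q decile; the peak
center from the smoothed argmax of background-subtracted intensity on
1–2 nm⁻¹; remaining values from the base simulation geometry, with the SLD
set rescaled onto the scale of a pinned core SLD (scale is divided by the
square of the same factor, leaving the initial curve unchanged). Curves
with no detectable oscillation fall back to defaults and carry a
low-confidence flag.

## Synthetic data

The generator forward-evaluates the model on a 400-point log-spaced grid
over 0.07–4.5 nm⁻¹ (the instrument range of the targeted beamline) and
perturbs it with 1% multiplicative Gaussian noise by default — a
representative level for frame-averaged 1D synchrotron data. A
poisson-like variance mode is available. All randomness flows from a
declared seed; replicate r of an experiment uses seed + r.

What the generator does *not* emulate: instrument resolution smearing,
inter-particle structure factors (samples are assumed dilute), q-dependent
systematic backgrounds, and detector artefacts. Passing recovery tests
therefore demonstrate that the estimator is unbiased and precise when the
model is correct, not that the model is complete for any given real
formulation.

Named presets encode the fitted structural-parameter rows for empty LNPs,
mRNA-LNPs and the N/P = 3:1…8:1 series. Two preset entries are artifact
choices because they are not measurable from relative-intensity data: the
core SLD (3.0×10⁻⁴, same decade as the shell SLDs and larger in magnitude,
as expected for the dense hydrophobic core; held fixed in fits) and the
quasi-Bragg amplitude (5×10⁻², putting the peak a few-fold above the local
baseline as in measured mRNA-LNP curves; free nuisance parameter in fits).

Recovery experiments refit each noisy replicate from the truth perturbed
by ±10% uniform relative factors (seeded) — the standard design for
checking that the estimator returns to the generating values from a
basin-adjacent start — and report per-parameter medians, biases and
spreads. The acceptance script uses 5 replicates of 400-point curves,
sizes at which the medians are stable to well under a percent.

## Frame QC

Repeated short exposures are compared by Pearson correlation of log₁₀
intensity (floored at 10⁻³ × the smallest positive intensity), a
scale-invariant similarity that flags shape changes such as radiation
damage. Because it is blind to pure rescaling, a median-scale check
(frame median within [0.5, 2] of the ensemble median) supplements it.
Frames failing either check (mean off-diagonal similarity < 0.99 by
default) are excluded; the rest are averaged pointwise with the per-point
standard error of the mean as uncertainty. Grids must match exactly — no
interpolation is attempted. The similarity statistic and thresholds are
documented package choices, configurable by the caller.

## Peak-detection convention

Trend assertions on smooth simulated curves ("number of fringes") count
windowed local maxima: a point must be the unique maximum within ±5
points of log-intensity. This is robust to floating-point ripple while
resolving all physically distinct oscillations on the default grid.

## Known limitations

- Gaussian size distribution only (no log-normal/Schulz), spherical
  particles only, no multilamellar or aspherical variants.
- No resolution smearing or absolute-intensity calibration.
- The quasi-Bragg term is a single Gaussian; higher-order reflections of
  strongly ordered phases are out of scope.
- Reported parameter uncertainties are local-curvature estimates and can
  be optimistic when parameters are strongly correlated (e.g. σ with R0 at
  high polydispersity).
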