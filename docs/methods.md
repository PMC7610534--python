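# Methods

`nanowrap` models the size-dependent interaction of spherical nanoparticles
(typified by citrate-stabilised gold, 5–60 nm) with large unilamellar lipid
vesicles (LUVs, ~179 nm, DOPC/POPC), and reduces the instrument readouts such
a study produces. This note records the models, their assumptions, the
parameters that matter, and the numerical choices.

## Wrapping energetics (`elastic_theory`)

A particle of diameter d adhering to a fluid bilayer gains |W| per unit
contact area and pays bending energy set by the modulus k. For a tensionless
membrane, full wrapping becomes favourable above

d_c = 2·√(2k/|W|),

and under lateral tension σ only above

d_c,σ = 2·√(2k/(|W| − σ)),

which diverges as σ → |W|. The grouping of the radical under tension is a
deliberate choice: it recovers d_c at σ = 0, grows monotonically with σ, and
is the only dimensionally consistent reading; once chosen it is not changed.
Particles between the two diameters remain partially wrapped; below d_c they
adhere without wrapping.

Defaults: k = 8.4e-20 J (≈20 k_BT at 298 K, the canonical fluid-PC bending
modulus — the estimate behind the ~4 nm gold critical diameter never states
its modulus, so the canonical value is adopted and exposed); |W| = 42 mN/m
(bare gold on PC). With these, d_c = 4.0 nm.

The curvature-corrected contact energy on a supported bilayer,
w_s = −k_w + m/a − 2κ_SLB/a², uses the wrap **radius** a = nominal radius +
wrap margin (default 2 nm, half the 4 nm bilayer — describing a as a
"diameter equal to radius plus 2 nm" is internally inconsistent, so radius is
used). m and κ_SLB are surface-specific constants fitted elsewhere to
coarse-grained simulation; they ship without defaults and must be supplied.
The adhesion critical diameter is the doubled larger root of
k_w·a² − m·a + 2κ_SLB = 0 and refers to the **wrap** diameter; a negative
discriminant (gold) means adhesion at every size, returned as 0.

Interface convention: lengths in nm, energies in J, energies-per-area in N/m.

## Engulfment lockout (`lockout`)

Complete engulfment consumes membrane area ΔA = 4πa² and, if the vesicle is
water-impermeable on engulfment timescales, adds ΔV = (4/3)πa³ to the
enclosed volume (a = d/2 + wrap margin). A closed surface of area A encloses
at most the volume of the sphere of that area, so n engulfments are feasible
only while

(36π)^{1/3}·(V₀ + nΔV)^{2/3} ≤ (1 + ε_max)·(A₀ − nΔA).

The left side over the available area, minus one, is the area strain the n-th
engulfment demands; ε_max is the strain at which tension locks out further
complete wetting. This is a **surrogate** criterion, not a derived
maximum-tension theory: ε_max = 0.0133 was calibrated once so that a 179 nm
vesicle holds exactly two 10 nm particles and 15 nm is the largest fully
engulfable integer diameter (the admissible window is ≈[0.0130, 0.0136]), and
≈1.3% sits inside the accepted lysis-strain range of fluid PC bilayers. The
calibration is part of the model's stated conditions and is not adjusted.

Impermeable volume is the default (engulfment is fast relative to osmotic
equilibration); `water_permeable=True` drops the volume increment and can
only increase capacity. `max_engulfable_diameter` scans a 1 nm integer grid,
matching how the limiting size is quoted. The criterion contains no bending
term; bending enters only through the wrapping theory above.

## Dosimetry (`dosimetry`)

Lipids per vesicle: N_tot = 4π[(d/2)² + (d/2 − h)²]/a_lipid (both leaflets,
71 Å² per PC lipid, h = 4 nm). The liposome number concentration follows the
published form of the estimator, lipid molecules per mL divided by
N_tot·1000, giving 7.18e9 liposomes/mL at 2.5 mg/mL with the mean PC molar
mass 773.1 g/mol (mean of DOPC 786.1 and POPC 760.1, the value that
reproduces the published count; per-lipid species are selectable). Note the
dimensional quotient — molecules/mL over molecules/vesicle — is 10³ larger;
the published scaling is retained because it is the value validated by two
independent particle-counting measurements (MADLS, calcein) at ~10⁹/mL.
Calcein counting uses the lumen diameter D − 2h and the 50 mM encapsulation
concentration.

Surface areas: SA_Au = count × πd²; SA_L is provided by two routes — vesicle
count × πD² (outer sphere) or lipid count × a_lipid/2 (mean leaflet area).
Their ratio is exactly 2r_o²/(r_o² + r_in²) ≈ 1.046 at 179/4 nm; they cannot
agree more closely than that curvature offset, and which the instrument
normalisation "should" use is not determinable — both are exposed.

## Calorimetry (`itc`)

Schedule: a 0.4 µL first injection then twelve 3 µL injections at 150 s
intervals into a 205 µL cell at 298.15 K; a 60 s pre-titration equilibration
precedes the first injection so its baseline segment exists. Per window
[t_inj, t_inj + interval): the baseline is a straight line through the 20 s
before the injection and the final 20 s of the window (chosen because it
absorbs affine drift exactly, which is tested as an invariance), and the heat
is the trapezoidal integral of power − baseline, in µJ, exothermic negative.
The small first injection is integrated but flagged discardable (standard
practice); the first **full** injection is the default for ΔH since it
represents complete interaction, and the mean over full injections is also
reported. ΔH = ΔQ/SA_Au in mJ/m² (reported signed); the chained form
(ΔQ/SA_L)/(SA_Au/SA_L) is verified to coincide identically. ΔG = ΔH − TΔS is
implemented as the algebraic identity solvable for any single unknown;
entropies are inputs, never estimated here.

Noise floor: with 0.02 µW white noise at 10 Hz sampling, window integration
plus baseline-fit noise give ≈0.15 µJ sd per heat, so relative errors at the
smallest heats (−2 µJ) reach several percent; the recovery guarantee is
therefore a **median** relative error below 2% across many injections, not a
per-injection bound.

## Assays (`assays`)

Leakage: 100·(F_sample − F_control)/F_max, with F_max the post-lysis maximum
as recorded (an option normalises to F_max − F_control instead); negative
values are reported, not clipped. Emission peaks: least-squares Gaussian plus
constant baseline (a plain Gaussian, not skewed — the standard reduction for
these spectra), centre = emission maximum; fits are flagged non-converged for
flat or peak-free input (height below 3× residual sd) or a centre outside the
grid. Shift labelling: BLUE/RED beyond a ±1 nm noise threshold (the
experimental-noise band is never quantified in this setting; 1 nm is
configurable), NONE within it. Calcein calibration is an OLS line with an
inverse predictor feeding the calcein vesicle count; a first-order leakage
rate fit (F₀ + F_inf(1 − e^{−kt})) covers kinetic traces.

## Light scattering (`dls`)

Forward model: q = 4πn·sin(θ/2)/λ (630 nm as printed, 173°, n = 1.33),
Stokes–Einstein D = k_BT/(3πηd) (η = 8.90e-4 Pa·s at 25 °C), field
correlation g1(τ) = Σ w_i e^{−D_i q² τ} with Rayleigh intensity weights
w_i ∝ N_i d_i⁶, Siegert relation g2 = 1 + β g1² (β = 0.8) plus additive
Gaussian noise. Rayleigh weighting is knowingly wrong above ~60 nm (Mie
regime); the module supports signal-dominance reasoning — a 179 nm vesicle
out-scatters a 10 nm particle by (17.9)⁶ per particle, which is why bound
particles shift the whole signal to the vesicle peak — not instrument
emulation, and whether the instrument applies Mie corrections to its
intensity-weighted distributions is unknowable from outside.

Cumulant reduction: weighted quadratic fit of ln(g2 − 1) (weights g2 − 1,
the correct error propagation for additive g2 noise), restricted to
g2 − 1 > 0.01β; mean diameter by Stokes–Einstein inversion of Γ/q², PDI =
µ₂/Γ². Population-shift metric: the fast/slow mode rates are the extreme
decay rates found across both correlograms (cumulant rates always; free
two-exponential fits added only when well conditioned — both weights in
[0.02, 0.98] and rates separated by ≥2×, since a second mode is
unidentifiable in single-mode traces); each correlogram's slow-mode intensity
weight then comes from a 1-D linear projection of |g1| onto the two fixed
modes, clipped to [0, 1]. Identical inputs give exactly 0; indistinct-rate
pairs give 0 by construction.

## Synthetic data (`synthetic_data`)

Generators return (data, truth) for closed-loop recovery tests; all
randomness flows through one seeded `numpy` Generator, so equal seed and
configuration give identical output. Thermograms: one-sided exponential
pulses (τ = 8 s — only the integrated area matters downstream) sampled as
bin averages at dt = 0.1 s so the sampled trace integrates to the requested
heat without an onset artefact (residual onset bias ≈ dt/4τ ≈ 0.3%); linear
drift plus white noise (default 0.02 µW). Spectra: Gaussian on the 1 nm
490–700 nm grid. Correlograms: the forward model on a logarithmic
0.5 µs–1 s grid. Leakage: first-order rise. Sizes: lognormal by median and
geometric SD. Not emulated: instrument response functions, detector
saturation, stirring artefacts, non-Gaussian noise, vesicle polydispersity
and multilamellarity — so passing recovery tests demonstrate correctness of
the reductions under idealised noise, not robustness to every instrument
pathology.

## Problem sizes and runtime

Default analyses are closed-form or small scans (≤10³ evaluations). The
statistical guarantees are established over 100 synthetic titrations
(13 injections each, 10 Hz sampling) and 20 seeds × 7 sizes of correlogram
recovery, which complete in seconds; these sizes were chosen as the smallest
giving stable medians.

## Known limitations

- The lockout criterion is calibrated, not derived; its two headline
  predictions are inputs to the calibration, so they validate consistency,
  not the surrogate's physics.
- Rayleigh weighting in the DLS model (above) and no regularised (CONTIN-type)
  inversion or multi-angle counting.
- Measured quantities of a real study (enthalpies, leakage magnitudes,
  emission intensity drops, micrograph morphologies) are not predictable from
  first principles here; the package reproduces derived/theoretical numbers
  and provides the reduction machinery for measured ones.
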