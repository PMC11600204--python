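# Methods

This note documents the models, numerical choices and known limits of the
`fibermech` synthetic bench and measurement pipeline. Units are SI
internally (m, N, Pa, s); user-facing tables use µm, µN, kPa.

## Probe mechanics

The sensing probe is a hollow quartz capillary (outer/inner diameter
0.3/0.1 mm), clamped at one end, with the fiber resting a distance `l`
from the clamp (`l < L_p`). Small-deflection Euler–Bernoulli theory gives
the tip-referred stiffness

    k = 6 E I_z / (l² (3 L_p − l)),   I_z = π/64 (D_p⁴ − d_p⁴).

We store magnitudes; deflection toward the moving probe is positive. The
large-deflection correction is out of scope: at the ≤120 µN force cap the
tip moves ≤150 µm on a 50 mm probe (0.3 %), firmly in the linear regime.
Probe dynamics are ignored too — the camera runs at 5 Hz and loading at
≤1 Hz, so the probe is quasi-static.

The camera resolves the tip in whole pixels: the readout is
`floor(|x|/pixel_size)` with sign, so the force is an integral multiple
of `k · pixel_size`. Quartz modulus defaults to 72 GPa (literature value,
configurable). The probe lengths and the 1.1028 µm pixel are fixture
values chosen so the two bundled presets reproduce the instrument's
printed per-pixel resolutions: "short" (L_p 50 mm, l 45 mm) → 0.88 µN/px,
"long" (doubled) → 0.11 µN/px; stiffness scales as length⁻³ at a fixed
load-position ratio, hence the exact ×8 between them.

## Sample constitutive model

Each sample is a standard linear (Zener) solid — equilibrium spring `E_e`
in parallel with a Maxwell arm (`E_1`, `η_1`, relaxation time
τ₁ = η₁/E₁) — plus an additive Newtonian term `γ` active only in
solution:

    E′(ω) = E_e + E_1 (ωτ₁)²/(1+(ωτ₁)²)
    E″(ω) = E_1 ωτ₁/(1+(ωτ₁)²) + ω γ_medium

This is the minimal linear model that separates the storage/loss
dichotomy from the medium effect. The drag term lumps the viscous
friction between the porous, high-aspect-ratio microfiber and the
surrounding solution into an equivalent bulk viscosity — the mechanism is
physical (water inside the porous hydrogel communicates with the bath and
shears against it during stretch), but no constitutive law for it is
established, so a lumped dashpot calibrated to the observed in-solution
loss-factor bands is the honest choice. Cellular bundles hold their water
intracellularly and get γ ≈ 0, which is exactly why "tan δ < 0.4 in
solution" separates tissue from hydrogel.

Passive nonlinearity: σ_p(ε) = E_e (exp(c_p ε) − 1)/c_p — small-strain
modulus always E_e, exponential stiffening with dimensionless exponent
c_p (3–6 for the presets; 0 gives a linear solid, which is the regime all
linear-analysis identities are tested in).

Active muscle: a Gaussian force–length relation
F_act = a(t) · F_a · exp(−((ε − λ_opt)/w)²) with λ_opt = 5 % and
w = 3 % by default — the observed sudden force rise sits at 4–6 % strain
and the optimal-length population spans 4–7 %. Activation a(t) sums
α-function twitches `0.4 · s·e^(1−s)`, s = (t−t_i)/τ, clipped to [0, 1].
τ = 0.15 s makes a 5 Hz train fuse into a tetanic plateau ~1.7× the
single-twitch peak, matching the qualitative twitch-vs-tetanus picture;
at 1 Hz the twitches stay distinct.

### Condition→parameter maps

* **Hydrogel formulation grid (12 combinations)**: the outcome partition
  (spheres {1,2,3,5,6}; pure bundles {4,8}; residual-hydrogel bundles
  {7,9,10,11,12}) is a lookup table, not a degradation model; the factor
  triples behind the numbering are not public, so the numbering is
  abstract. Sphere conditions are flagged non-measurable (nothing to
  suspend) and never enter a funnel.
* **CoCl₂ hypoxia dose**: contractile force declines with dose through a
  logistic with half-decline at 140 µM for the optimized culture period
  (4 d growth + 1 d differentiation) and 100 µM for the original 3+3 d
  period; above ~150 µM the tissue transition also fails (drag and hence
  tan δ rise; moduli fall toward an aggregate). The shape is a modeling
  choice — only the threshold behaviour is constrained.
* **Composite bioink (6 alginate × 3 CaCl₂ × 3 diameter = 54)**: a
  separable quality score peaking at alginate 0.75 %, CaCl₂ 1 %, 200 µm
  diameter scales the active peak, the residual drag and the post-
  degradation modulus gain.

Replicate scatter: one log-normal factor (CV 15 %) common to all moduli
and viscosities — deliberately leaving tan δ invariant, since the loss
factor is a dimensionless material signature — plus independent log-normal
factors on the drag ratio (CV 8 %) and the active peak (CV 15 %). The
scatter magnitudes are chosen once to reproduce the observed band widths
(pre-culture cores spanning 0.45–1.1 in tan δ and ~0.8–4.2 kPa in |E*|);
the distributions themselves are a choice (only box–whisker scatter is
reported).

## Synthetic bench

Quasi-static coupling: at every instant the probe force `k·x` balances
the sample force at strain ε = (L_m − x)/L_0. Each time step solves this
scalar balance with Brent's method (xtol 1e-15), so the pre-quantization
balance residual is far below 1e-9 N. The Maxwell-arm stress uses its
exact exponential update for a piecewise-linear strain path; the drag
term uses a BDF2 end-of-step strain rate — with the backward difference
(a half-step-lagged average rate) the extracted phase was biased by
~0.5 % of a cycle, visible as a 1–2 % tan δ error at 200 integration
steps per cycle.

Integration runs on an internal fine grid (≥200 steps per loading cycle,
≥ the 5 Hz camera rate) and is decimated to the camera. The readout then
adds Gaussian read noise (default σ = 0.3 px) and floor-quantizes to
whole pixels. Oscillation protocol: `L_m` follows a raised cosine so the
nominal strain sweeps 0→10 % (never compressing the fiber), 5 measured
cycles after 1 settling cycle at 0.1 Hz. A `FixationError` is raised if
the instantaneous force exceeds the 120 µN liquid-bridge adhesion.

What the bench does **not** emulate: shell degradation timing and
transfer mechanics (recordings begin post-degradation), the step-increase
artifact at large probe gaps, hydrogel degradation kinetics, cell
proliferation or exosome uptake — only their phenomenological signatures
on (E*, tan δ, CF). A green population test therefore establishes that
the measurement chain recovers what the constitutive model encodes, not
that the constitutive model is biologically complete.

## Force control

The moving probe position is the only actuator; force feedback is the
vision-derived, pixel-quantized F_s at 5 Hz. The plant is identified from
a 20 s dithered calibration ramp (the dither follows the same
linearly-interpolated move profile the controller uses — identification
under a different actuation profile produced a model whose 1 Hz
predictions were ~50 % off) as

    F[k+1] = a F[k] + b1 L[k+1] + b0 L[k].

The two position taps matter: `(b0+b1)/(1−a)` is the static series
stiffness, while `b1` carries the within-interval drag response, several
times larger for in-solution fibers. A single-tap model underestimates
the move gain and the loop diverges.

The controller is a receding-horizon QP over position increments
(horizon 10, tracking weight 1, move penalty 0.05·b1² — weights and
horizon are a conventional reconstruction, the instrument's actual MPC
design is not public), with |F̂| hard-bounded at the adhesion limit minus
a three-pixel margin and increments rounded to the 0.2 µm actuator step.
Three pragmatic layers make it robust to the quantized feedback and model
mismatch, as real instrument software would:

* a constant output-disturbance estimate (innovation filter gain 0.3)
  restores offset-free tracking — the identified model alone leaves a
  static-gain-mismatch bias;
* the floor quantizer's +0.5 px expected bias is removed in the feedback
  path only (recorded readouts stay raw pixels);
* a supervisor lets an upward move consume at most a third of the
  remaining force headroom even if the true gain is 3× the identified
  one, and retreats outright at the soft ceiling. This is what keeps a
  command deliberately set above the limit saturating near ~110 µN
  peak-to-peak instead of detaching the fiber.

The oscillation command is a raised cosine phase-shifted so its crest
lands on a camera frame; at 1 Hz the 5 Hz sampling otherwise under-reads
the peak by ~10 % for purely geometric reasons. Closed-loop peak error is
≤1 % of the 15 µN command at 0.01/0.1 Hz and ~5 % at 1 Hz (5 samples per
cycle; the documented tolerance there is 10 %).

## Measurement pipeline

Stress and strain: σ_s = 4F_s/(π d_0²), ε_s = (L_m − x)/L_0, with d_0
and L_0 the initial core geometry throughout (the core is never
re-measured). The viscoelasticity extractor drops the settling cycle,
truncates to an integer number of periods (flagging any trimmed samples),
and projects both series onto exactly f_m = 0.1 Hz — for integer-period
records this coincides with the nearest FFT bin, no window needed. Then
|E*| = A_σ/A_ε and tan δ = tan(φ_σ − φ_ε), the phase difference wrapped
into [0, π/2); small negative differences (noise on nearly elastic
samples) clamp to zero with a flag. The Lissajous modulus uses the final
loop only, so start-up transients cannot bias it; for a linear plant in
steady state it equals |E*| (amplitude-ratio identity, verified to 2 %).

Contractile force: the active force–length curve is the pointwise
difference between stimulated and passive ramps on a shared strain grid
(linear-interpolation resampling with a flag if the grids drift); its
argmax is L_o, and the CF criterion value is F_s(L_o) minus the mean
passive tension of the same-diameter group (a singleton group falls back
to the sample's own passive ramp, flagged).

Error budget worth knowing: pixel quantization bounds the |E*| error by
`force_per_pixel/(A_ε · A_0)` (asserted analytically and empirically);
for the softest cores the force signal is only a few pixels and the floor
quantizer's flattening of the near-zero dwell can cost ~10 % of |E*| —
the loss-factor bands absorb this, but precision modulus work should use
a softer probe or a larger-diameter fiber.

## Screening

Criterion A (CF difference > 3 µN) and C (ΔE* > 5 kPa) aggregate
replicates by majority; criterion B (tan δ < 0.4) demands **all**
replicates below threshold, because a single high-loss sample marks
residual hydrogel in the group (this is how the 140 µM dose is demoted).
All rules are configurable. Criteria are pure predicates, so the funnel's
final selection is order-independent even though the per-stage counts
follow A→B→C. A criterion that cannot be evaluated from the available
protocol (no stimulation run → no CF; no paired pre/post moduli → no ΔE*)
is marked not-evaluable and does not reject. The dose-threshold rule
returns the largest dose such that every dose up to it passes; recurring
passes above the first failure set a non-monotonicity flag rather than an
error.

## Imaging

Synthetic frames render the probe silhouette with linear edge
anti-aliasing plus optional Gaussian intensity noise. Tip tracking runs
Harris corner detection (k = 0.05, σ = 1.5, fixed by the synthetic
contrast), keeps peaks near the reference tip row, picks the left
(tracked) corner, refines it to sub-pixel precision and rounds to whole
pixels — matching the integral-pixel force convention. Only the
bending-plane displacement is tracked; probe/camera coplanarity is
assumed perfect. Round-trips are exact for integer shifts up to ±20 px at
zero noise and within 1 px at 10 % contrast noise.

## Reproducibility

Every stochastic stage takes a seed; condition-level replicate draws use
`SeedSequence(seed, (crc32(condition), replicate))`, so a population is
bit-reproducible from its run config and independent across conditions
and replicates. Run directories contain the resolved config; rerunning a
config yields byte-identical summary tables.
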