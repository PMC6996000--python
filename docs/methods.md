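# Methods

## Model

Tissue is modelled as two compartments: extravascular water diffusing
among non-permeable blood vessels, and intravascular blood water. Vessels
are infinitely long cylinders of a single radius `Rc`, randomly oriented,
confined to a sphere of radius `Rs`, at blood volume fraction `Vf`. Only
the field *outside* a cylinder is modelled; protons whose walk enters a
vessel are discarded (the non-permeable-wall choice that avoids the cost
of reflecting boundaries), so the extravascular ensemble is conditioned
on never entering a vessel. The intravascular signal is analytical, not
walked.

Assumptions inherited from this construction:

* static susceptibility field (no flow, no exchange, no permeability);
* dilute, uncorrelated vessels — no branching, curvature or spatial
  correlation between cylinders;
* Gaussian free diffusion of tissue water (`σ = √(2 D Δt)` per axis);
* arterial blood fully saturated in single-radius experiments
  (`Y_v = 1 − OEF`), 98% saturated in the distribution experiment.

## Geometry generation

Vessel origins alternate deterministically between the sphere surface and
its interior (exact half-and-half at any count, rather than a Bernoulli
draw), with interior radii scaled by `U^(1/3)` for uniform density in
volume; orientations come from normalised 3-vectors of standard normals.
Each vessel occupies `π Rc² ×` (chord length of its axis inside the
sphere); end-cap clipping against the sphere is ignored, an `O(Rc/Rs)`
error with `Rs ≫ Rc` by construction. Vessels are added until `Vf` is
reached; the overshoot is bounded by the last vessel's volume. A
zero-chord (tangent) vessel would be degenerate and is redrawn.

`Rs` is chosen so the expected vessel count at `Vf` hits a target `N`
(default 1300) from `N π Rc² L̄ = Vf (4/3) π Rs³` with mean chord
`L̄ ≈ Rs`, then refined once empirically by `Rs ← Rs √(N_target/N_obs)`
(the count scales as `Rs²` when `L̄ ∝ Rs`). The calibrated `Rs` is
proportional to `Rc` at fixed (`Vf`, `N`), which the scaling identities
below exploit.

## Walks and phase accrual

Walks start at the sphere centre and evolve for `duration` (120 ms at
study conditions) in 20 µs steps. The field is evaluated at the position
ending each 200 µs coarse interval; whenever either bounding coarse
position of an interval lies within the proximity region
`Rc²/r² > 0.04` of any vessel, that interval's contribution is replaced
by the sum over its ten 20 µs sub-steps, which also performs entry
detection at fine resolution exactly where a wall crossing is possible
(the fine-step RMS displacement, 0.2 µm, is far below the proximity
margin of `4 Rc` for all simulated radii). Phase increments are summed
into 2 ms storage bins per proton. Each proton sees a freshly generated
vessel system; per-proton random streams are spawned from one master
seed, making populations bit-reproducible and order-independent.

Protons may leave the sphere (vessels exist only inside it); with an RMS
displacement of ~27 µm over 120 ms against `Rs` of hundreds of µm this
is negligible. Phase is only ever evaluated at `r ≥ Rc` — grazing
protons that do not enter contribute phase from the exterior field only,
which is the stated domain of the cylinder field expression.

## Signal synthesis and scaling identities

ASE recombination uses refocusing index `m = (tE − τ)/(2Δt)` and
acquisition index `n = tE/Δt` (the τ/2 shift of the refocusing pulse, so
`tSE = tE − τ`); GESSE uses `m = tSE/(2Δt)`, `n = (tSE + τ)/Δt`. τ grids
are validated against the 2 ms storage grid; no interpolation is ever
performed (all protocols used land exactly on the grid).

Four identities accelerate parameter studies, the first two exact at
archive level:

1. **Oxygenation** — phase is linear in `1 − Y`; stored increments are
   rescaled by `(1 − Y_target)/(1 − Y_nominal)` before recombination.
2. **Blood volume** — the extravascular log-magnitude is proportional to
   `Vf` (`S = exp(−Vf f(Rc, τ))`); applied to the ensemble magnitude,
   after oxygen scaling and before any T2 weighting.
3. **Diffusivity** — `τ_D ∝ Rc²/D`: scaling `Rc` by `√k` and `D` by `k`
   leaves the signal unchanged. In this implementation the identity is
   *exact under a common seed* because walks and vessel geometry scale
   jointly.
4. **Multiple radii** — signals of independently simulated radius
   populations multiply (dilute, independent perturbers).

Order of application: oxygen scaling → recombination → ensemble
magnitude → volume scaling → multi-radius product → T2 weighting →
volume-weighted mixing with the intravascular signal. A `t2_applied`
flag guards against applying T2 decay twice.

## Intravascular model

Blood signal between excitation, one refocusing pulse at `tSE/2` and
acquisition at `tE`, from the Gaussian-phase description of diffusion
among red cells: mean-square inhomogeneity
`G0 = (4/45) Hct(1−Hct) (4π Δχ (0.95−Y) B0)²` (0.95 is the red-cell
saturation at which cell and plasma susceptibilities match) and
`τ_D = R_rbc²/D_b = 3.38 ms`. The model is independent of vessel radius
and exactly symmetric in τ for ASE. The susceptibility difference is
used in its CGS convention (0.27 × 10⁻⁶) with the printed `4π`-family
geometry factors throughout the package; no SI conversion exists
anywhere.

In the distribution experiment the intravascular signal is computed per
compartment at that compartment's saturation and volume-weighted — the
natural per-compartment generalisation; a single venous-Y variant can be
obtained by passing a model with uniform saturations.

## SDR qBOLD estimator

Unknowns `(V0, R2′, ln S0 − tE·R2)` solve the log-linear system with
first row `(0, 0, 1) → ln S(0)` and rows `(1, −τ, 1) → ln S(τ)` for long
τ. Long-τ rows default to `τ > 15 ms`; if fewer than two taus qualify
(the short-τ protocol `tE = 64 ms, τ = 10–18 ms`), all positive taus are
used. The first row is fitted exactly by the least-squares solution (its
unknown appears alone there), so apparent DBV equals
`ln S_extrap(0) − ln S_meas(0)` identically and the fit is invariant to
overall signal scaling. Standard errors come from the
residual-variance-scaled covariance `σ² (AᵀA)⁻¹`. Only `τ ≥ 0` samples
are fitted; negative-τ synthesis exists for symmetry checks.

The DBV-error decomposition references the measured `S(0)` to a large
radius (1 mm), where the static dephasing regime holds and spin-echo
attenuation vanishes; the ratio cancels T2 decay.

## Vascular model

Eleven compartments (five arteriolar orders, one capillary bed, five
venular orders) with radii 60/30/15/10/5 | 2.8 | 7.5/15/22.5/45/90 µm.
Relative volume fractions are cylinder volumes `count · π r² · length`
normalised over the included compartments; they reproduce the published
32.6% (all vessels) and 41.2% (excluding arterioles) capillary shares to
the printed 0.1% precision. Saturations: arterioles `Ya = 0.98`, venules
`Yv = Ya (1 − OEF)`, capillaries `Yc = κ Ya + (1 − κ) Yv` with κ = 0.4.
Compartments sharing a radius (15 µm) reuse one phase archive — archives
are oxygenation-agnostic by linearity. The DBV ground truth is the
capillary-plus-venous share of CBV (72.4%). Deoxyhaemoglobin content
uses `100 · V0 · ρ · (Hct/0.03) · OEF`; the printed grouping of the 0.03
constant is ambiguous, the divisor reading is used, and the quantity is
a labelling variable only — it feeds no estimator.

## Fidelity tiers and numerical choices

Two tiers share identical code paths:

| tier  | protons (total/kept) | vessels/system | evolution |
|-------|----------------------|----------------|-----------|
| study | 10 000 / 5 000       | ~1300          | 120 ms    |
| desk  | 3 500 / 2 000        | ~400           | 80 ms     |

Desk-tier choices: 80 ms suffices for the `tE = 80 ms` protocol (the
recombination indexes no bin beyond `tE`); ~400 vessels per system was
validated against the analytic dilute static-dephasing signal — the
far-field truncation changes `−ln S` by < 0.3% at the longest τ; 3 500
simulated walks keep 2 000 clean protons even at the capillary radius,
where ~40% of walks enter a vessel. Desk-scale Monte Carlo error on a
fitted DBV is σ ≈ 0.004–0.008 per population.

Two variance-reduction constructions are used where quantities are
*compared* across conditions:

* **Common random numbers across radii** — with one master seed, every
  radius sees an exactly `Rc`-scaled replica of the same geometry and
  identical walks, so noise largely cancels in radius-to-radius
  comparisons. The apparent-DBV(radius) profile has a nearly flat top
  (15–45 µm values within ~0.002 of each other at OEF 40%), so peak
  localisation additionally averages profiles over several independent
  replicates before taking the grid argmax.
* **Paired scaled-vs-direct comparison** — the scaling-fidelity check
  runs the nominal and target conditions from the same seed and sphere
  radius (the lower-`Vf` vessel systems are prefixes of the higher-`Vf`
  ones), isolating the volume-scaling approximation from sampling noise.

Other numerical points: the piecewise SDR forward model is discontinuous
at its regime threshold `τ = 1.5 V0/R2′` (a property of the printed
forms, preserved as such); `φ` is returned as 0 when the cylinder axis
is parallel to B0 (the field term vanishes); a fit on a flat curve
returns `R2′ = 0, DBV = 0`; OEF is reported as 0 when both `R2′` and
`V0` vanish and is undefined (error) for `V0 = 0` with nonzero `R2′`.

## What desk-scale agreement does and does not show

The synthetic populations emulate the study conditions (3 T, Δχ = 0.27
ppm CGS, Hct 40%, D = 1 µm²/ms, T2,t = 80 ms), not real acquisitions:
there is no measurement noise, no macroscopic field inhomogeneity, no
CSF/myelin/iron compartments, and no flow. Desk-tier runs reproduce the
qualitative structure of the full-fidelity experiments (entry fractions,
R2′ plateau, DBV peak location, OEF compression) with wider error bars;
passing tests therefore validate the implementation and the direction
and rough magnitude of the diffusion biases, not their third significant
figure, and say nothing about in-vivo confounds excluded above.

## Known limitations

* The distribution experiment reproduces the compressed apparent-OEF
  range (~16–26% across the full true-OEF range) and the shallow
  apparent-R2′ relationship, but yields a median apparent DBV close to
  the capillary-plus-venous ground truth (percentage error ≈ 0), because
  the capillary compartment's strongly negative apparent-DBV bias
  cancels the venular overestimation under this model's assumptions.
* Single-radius apparent DBV is *under*estimated below ~7 µm; the
  overestimation regime starts above ~5 µm and peaks near 20–30 µm.
* GESSE synthesis is validated for its asymmetry behaviour only; no
  GESSE-based quantification pipeline is provided.
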