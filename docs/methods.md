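# Methods

`facdis` models the kinetics and strain mechanics of *facilitated
dissociation* in designed protein systems: a host A (a conformational switch
rigidly fused to a binder) holds a partner B in a long-lived binary complex
BA; an effector C binds BA and drives the switch into a state that clashes
with the partner, creating a strained ternary complex BAC from which B is
released orders of magnitude faster than from BA.

## 1. Chip-occupancy kinetic model

During an SPR dissociation window at constant effector concentration [C],
the chip species obey the pure-loss linear system

    d[BAC]/dt = -k_off,B:AC [BAC] + k_on,BA:C [BA][C] - k_off,BA:C [BAC]
    d[BA]/dt  = -k_off,B:A  [BA]  - k_on,BA:C [BA][C] + k_off,BA:C [BAC]
    d[BAn]/dt = -k_off,B:An [BAn]

with BAn an effector-unresponsive host population.  Occupancies are
dimensionless fractions of chip capacity, concentrations molar, rates s⁻¹
(the effector on-rate M⁻¹s⁻¹); free sites are not propagated during
dissociation.  The BAC/BA pair is a 2×2 constant-coefficient system solved
in closed form through the spectral form of the matrix exponential

    e^{Mt} = (e^{λ₊t}(M - λ₋I) - e^{λ₋t}(M - λ₊I)) / (λ₊ - λ₋)

The eigenvalues are always real (the off-diagonal product is non-negative)
and non-positive (pure loss), so the exponentials cannot overflow.  When
|λ₊ - λ₋| < 1e-12·max|λ| the exact repeated-root limit
e^{μt}(I + (M - μI)t) is used instead.  BAn decays as an independent single
exponential.  Round-off-scale negative occupancies are clipped to zero.

**Effective rate.**  For each [C] the half-time t₁/₂ of total bound
occupancy [BA]+[BAC] (from [BA]₀ = 1, [BAC]₀ = 0) is found by Brent root
finding on the closed form, bracketing from 10·ln2 / (smallest positive
partner off-rate) with geometric expansion; relative tolerance 1e-14.  Then
k_eff = ln 2 / t₁/₂.  k_eff runs monotonically from k_off,B:A at [C] = 0 to
k_off,B:AC at saturating effector and always lies between them.  Systems
with no open dissociation pathway (both partner off-rates zero, or partner
loss only possible through a ternary complex that cannot form) raise
`NonDissociatingError` rather than search for a non-existent root.

## 2. Multi-cycle experiment and global fit

A cycle re-loads the chip with host and records one dissociation window at
one concentration of a two-fold dilution series.  Initial conditions follow
the accumulation recursion (fraction f_responsive of freshly loaded host is
effector-responsive; the remainder joins the BAn pool), and occupancies map
to response units through S = f_n (a_BA[BA] + a_BAC[BAC] + a_BAn[BAn]).

Design choices:

* **Leftover ternary complex** at the end of a window is folded into the
  carried-over [BA]: the effector washes out between cycles.  For very slow
  effector release this assumption (BAC = 0 at cycle start) degrades, which
  is a known limit of the model, not of the implementation.
* **Gauge.**  Scaling all amplitudes by c and all f_n by 1/c leaves the
  model invariant, so f₁ ≡ 1 is enforced at construction; reported
  amplitudes are therefore unique.
* **Optimizer.**  Trust-region least squares (`scipy.optimize.least_squares`,
  `trf`) on unweighted residuals pooled over cycles; rates in log₁₀ space
  with bounds [1e-12, 1e8]; f_responsive bounded to [0,1]; multi-start with
  rate initialisations jittered up to 3× either way.  Initial guesses are
  data-driven (crude half-time rates of the lowest- and highest-[C]
  cycles).  Point estimates only; no uncertainty is reported (bootstrap is
  left to the caller).
* **Covariance flag.**  When effector association at the top concentration
  outpaces both exits from the ternary complex (k_on·[C]max >
  k_off,BA:C + k_off,B:AC), the ternary pool is in rapid pre-equilibrium
  and only ratios of the effector-binding pair are constrained; the fit
  result carries an explicit flag instead of failing.
* **Cycle order.**  Concentrations default to descending (top concentration
  first).  The high-[C] cycles strip the responsive pool quickly, exposing
  the unresponsive tail early, which helps pin a_BAn and k_off,B:An.

## 3. Curve fits

All nonlinear fits use variable projection where possible: amplitudes enter
linearly and are solved exactly for each trial rate (or K_D), so only the
nonlinear parameter is searched (log-grid plus bounded Brent), followed by a
full-parameter `least_squares` polish at tolerances 1e-15.  Noiseless inputs
are therefore recovered essentially to solver precision from any start.

* **Double exponentials.**  Components are ordered k₁ ≥ k₂.  The fit
  collapses to a single exponential when k₁/k₂ < 1.2, when the minor
  amplitude is < 1% of the total, or when the extra component does not
  reduce the residual.  The reported rate is the faster component when its
  amplitude is ≥ 25% of the total, otherwise the higher-amplitude one; any
  conflict between "faster" and "higher-amplitude" is flagged so that
  downstream analyses can log the reporting decision.
* **Mechanism discrimination.**  The linear law k_app = k_on[C] + k_off
  (induced fit) and the saturating hyperbola
  k_app = (k_switch - k_base)[C]/(K₁/₂+[C]) + k_base (conformational
  selection) are both fit; selection is by AIC with Gaussian residual
  likelihood, *small-sample corrected* (AICc).  At the 8-point
  concentration grids typical of these profiles, plain AIC admits the
  spurious extra hyperbola parameter on truly linear data about 15% of the
  time (P(χ²₁ > 2)); the AICc correction 2k(k+1)/(n-k-1) suppresses this
  while leaving large-n behavior unchanged.  ΔAICc is invariant under
  rescaling of the rate units.
* **Bound fraction.**  The exact two-component equilibrium
  f = (s - √(s² - 4[A][C]))/(2[C]), s = [A]+[C]+K_D, is evaluated in the
  product form 2[A]/(s + √(s²-4[A][C])), which is immune to the
  catastrophic cancellation of the difference form when [A][C] ≪ s².
* **Censoring.**  A fitted K_D below the labeled-effector concentration is
  reported as the upper bound K_D = [C] with `censored=True`; the raw fit
  value is retained separately for diagnostics.

## 4. Deformation geometry and spring model

The clash-to-strained deformation of the partner is treated as a rigid
pivot.  After least-squares superposition (hand-written Kabsch, proper
rotations only; reflections excluded) of the strained complex onto the
reference frame through the switch, the rigid transform carrying the
clashing partner onto the aligned strained partner is decomposed in screw
(Chasles) form: rotation angle θ ∈ [0, π], unit axis, the axis point with
minimal screw translation (chosen closest to the origin; any point on the
axis is equivalent), and the residual translation along the axis, which is
reported rather than silently discarded.  Rotations below 1e-6 rad leave
the axis undefined and return a flagged degenerate geometry.

The interface binder helix axis is the first principal component of its Cα
trace over the stated residue range (robust for near-ideal designed
helices); φ, its angle to the pivot axis, is folded to [0, π/2] since
perpendicularity is sign-free, and sin φ is the perpendicularity.

Energetics (kcal/mol at 298.15 K, R = 1.9872e-3 kcal mol⁻¹ K⁻¹; both
configurable):

    ΔΔG_exp  = R T ln( k_off,B:AC / min(k_base, k_off,B:A) )
    k        = ΔΔG / θ²                      (Hooke's law)
    ΔΔG_pred = (m sin φ + b) θ²

The floor k_base (default 2e-4 s⁻¹) models designs whose fusion adds
stabilising partner contacts that suppress binary and ternary off-rates by
the same factor.  m and b are fit by linear least squares *on the strain
energies* (design matrix [sinφ·θ², θ²]), not on the k-vs-sinφ line; R² is
reported on predicted-vs-experimental ΔΔG over the fitted cohort.  A cohort
with identical sin φ leaves m unidentifiable: the combined stiffness is
reported in b with m pinned to zero and a flag.  Exclusion of outlier
designs is caller-controlled (`exclude_designs` in the CLI), never
automatic.

## 5. Synthetic data: what it emulates and what it does not

Generators are deterministic under a fixed seed and write a ground-truth
sidecar; recovery tests read truth only from the sidecar.  Defaults:

* **SPR**: 6 cycles, effector two-fold diluted from 5 μM (descending),
  600 s windows, 1 s sampling; Gaussian noise at 1% of the per-cycle
  maximum response (a typical instrument noise floor); amplitudes 100 RU,
  f_responsive = 0.9.
* **Default truth rates** (5e-4, 2e4, 5e-3, 5e-2, 5e-5; a 100-fold
  acceleration): chosen by an a-priori identifiability design of the
  synthetic experiment.  Within a fixed 32-fold concentration span, both
  partner off-rates are determined only if the lowest cycles approach the
  base off-rate while the highest approach the ternary off-rate; a Fisher
  information check at these values gives ~2% (k_off,B:A) and ~1%
  (k_off,B:AC) standard errors at the default noise, matching the regime
  of the real experiments the generator emulates.  Rate sets with
  k_on·[C] ≫ all first-order rates in every cycle leave k_off,B:A
  structurally unidentifiable — a property of the experiment design, which
  the global fit then reports through its covariance flag and inflated
  errors, not a solver artifact.
* **k_app profiles**: 8-point two-fold grids spanning K₁/₂, 5% noise;
  linear truth k_on = 5e4 M⁻¹s⁻¹, k_off = 1e-3 s⁻¹; hyperbolic truth
  k_switch = 0.02 s⁻¹, k_base = 1e-4 s⁻¹, K₁/₂ = 2e-7 M.
* **FP titrations**: 24 wells, two-fold host dilution from 2 μM, labeled
  effector at 1 nM, 2% noise.
* **Structures**: random Cα clouds with an ideal α-helix (1.5 Å rise,
  2.3 Å radius, 100°/residue) embedded over the helix range; the strained
  partner is the clashing partner rotated by a known angle about a known
  located axis; optional isotropic coordinate noise emulates prediction
  error.  The truth sidecar records the *realized* helix axis (principal
  axis of the clean helix trace), since a finite discretely-sampled helix
  tilts slightly from its nominal direction.
* **Strain cohorts**: ~30 designs, θ ~ U(0.1, 0.6) rad, φ ~ U(0.2, 1.4)
  rad, truth m = 30, b = 5 kcal/mol/rad², optional multiplicative energy
  noise; off-rates generated consistently with the floor rule.

Not emulated: association-phase kinetics and mass transport, within-cycle
baseline drift, bulk refractive-index jumps and spike artifacts, anisotropy
instrument corrections, and real structure-prediction error beyond isotropic
coordinate noise.  A green recovery test therefore establishes correctness
of the estimators under the stated statistical model, not robustness to
instrument pathologies.

## 6. Numerical conventions and limitations

* Rates validated finite and ≥ 0 at construction; occupancies ≥ 0 with the
  capacity bound Σ ≤ 1 + 1e-6.
* Unweighted SSE across cycles (recorded in fit metadata); no per-cycle
  weighting is attempted because the noise level is shared.
* a_BAn is kept as a free amplitude distinct from a_BA, as in the response
  model; the two are near-degenerate when the unresponsive pool is tiny.
* Whether the pivot angle should be measured between centroid lines in the
  plane normal to the axis or as the full 3-D rotation angle is ambiguous
  in a purely pictorial construction; the screw rotation angle is used and
  documented, and the two agree when the residual axis translation is
  small.
* Effector depletion near the chip is ignored (constant [C], flow
  conditions).
* The k_eff-vs-[C] summary written by `fit global` uses the hyperbolic form
  k_eff = (k_max - k_min)[C]/(K₁/₂+[C]) + k_min; the choice is recorded in
  the output metadata.
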