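# facdis

Kinetics and strain mechanics of **effector-facilitated protein complex
dissociation**.

Designed protein "hosts" — a conformational switch rigidly fused to a
binder — hold a partner protein in a long-lived complex until an effector
binds, drives the switch, and pushes the partner out through a mechanically
strained ternary intermediate.  `facdis` is a toolkit for analysing the
kinetic and structural data such systems produce:

* **Chip-occupancy kinetics** — exact closed-form propagation of the SPR
  dissociation ODE system over the species BA (binary complex), BAC
  (strained ternary complex), and BAn (effector-unresponsive host), plus
  half-times and the effective dissociation rate k_eff([C]) = ln2 / t₁/₂.
* **Multi-cycle global fitting** — the per-cycle initial-condition
  recursion with accumulating unresponsive host, the response map
  S = f_n (a_BA[BA] + a_BAC[BAC] + a_BAn[BAn]), and trust-region global
  least squares over all cycles with log-space rates.
* **Mechanism discrimination** — linear (induced fit,
  k_app = k_on[C] + k_off) versus hyperbolic (conformational selection,
  k_app = (k_switch−k_base)[C]/(K₁/₂+[C]) + k_base) apparent-rate profiles,
  selected by small-sample corrected AIC.
* **Equilibrium and kinetic fluorescence polarization** — the exact
  quadratic binding isotherm with the K_D < [C] censoring rule, and
  single-exponential competition time courses.
* **Strain mechanics** — Kabsch superposition, screw-axis decomposition of
  the clash-to-strained partner pivot (angle θ, located pivot axis), helix
  axis and perpendicularity sin φ, strain energies
  ΔΔG = RT ln(k_off,B:AC / min(k_base, k_off,B:A)), and the Hooke's-law
  spring model ΔΔG_pred = (m sin φ + b) θ².
* **Synthetic data** — seeded generators for all of the above with
  ground-truth sidecars, standing in for raw instrument data.

## Worked example

```python
import facdis as fd

# a 6-cycle dissociation experiment: effector 2-fold diluted from 5 uM
rates = fd.default_rates()                   # 100-fold accelerated off-rate
schedule = fd.CycleSchedule.serial_dilution(top_conc=5e-6, n_cycles=6)
dataset, truth = fd.generate_spr_dataset(
    rates, schedule, fd.default_response(6), fd.NoiseSpec(sd=0.01, seed=1)
)

result = fd.fit_global(dataset, seed=1)
print(f"k_off,B:A  = {result.rates.k_off_B_A:.3g} /s")
print(f"k_off,B:AC = {result.rates.k_off_B_AC:.3g} /s")
print(f"fold change = {fd.fold_change(result):.0f}")
print(f"f_responsive = {result.response.f_responsive:.3f}")

keff = fd.effective_rate(result.rates, [0.0, 1e-7, 1e-6, 1e-5])
print("k_eff:", [f"{k:.2e}" for k in keff])
```

prints (seed 1):

```
k_off,B:A  = 0.000503 /s
k_off,B:AC = 0.0503 /s
fold change = 100
f_responsive = 0.891
k_eff: ['5.03e-04', '2.19e-03', '1.20e-02', '3.54e-02']
```

The fitted binary off-rate (5.0e-4 s⁻¹) and ternary off-rate (5.0e-2 s⁻¹)
recover the generating truth within ~1%, giving a ~100-fold
effector-induced acceleration; k_eff climbs from the binary off-rate at
zero effector toward the ternary off-rate at saturation, the kinetic
signature of dissociation through a ternary intermediate.  The same
workflow is scriptable from the shell:

```bash
facdis simulate spr  --config cfg.json --seed 1 --out-dir out
facdis fit global    --config fit.json --seed 1 --out-dir out
facdis strain model  --config cohort.json     --out-dir out
```

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's headline quantities from scratch with seeded
synthetic inputs: it simulates and globally fits a 6-cycle experiment,
extracts the k_eff curve and fold change, discriminates an induced-fit from
a conformational-selection profile, fits a polarization titration, recovers
a constructed pivot geometry, and fits the spring model on a 30-design
strain cohort, writing the results JSON to `--out` and a human-readable
summary next to it.
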