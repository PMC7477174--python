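# ovifnirs

Multi-distance continuous-wave fNIRS analysis for freely moving sheep:
layered photon-diffusion forward models, seeded Monte Carlo validation, a
two-step inversion separating extra-cerebral from cerebral hemoglobin, and
behavior-driven block exclusion with group-level statistics — plus a
ground-truthed synthetic-data generator so the whole chain is testable
without animal recordings.

## The problem

A wearable CW-fNIRS probe on a sheep's head records optical density (OD) at
two wavelengths (751 and 839 nm) and two source–detector distances
(ρ = 10 mm and ρ = 30 mm) per hemisphere at 10 Hz. Short-distance photons
stay almost entirely in the extra-cerebral tissue (scalp, skull, CSF;
thickness s ≈ 10 mm), while long-distance photons also sample the cortex.
The analysis exploits this:

1. **Step 1 (short channel).** ΔOD at ρ = 10 mm is fitted per time sample
   to a homogeneous semi-infinite diffusion model (Levenberg–Marquardt,
   scattering fixed at baseline), giving the extra-cerebral absorption
   change Δμ<sub>a</sub><sup>UP</sup>(t) per wavelength.
2. **Step 2 (long channel).** ΔOD at ρ = 30 mm is fitted to a two-layer
   diffusion model (slab of thickness s over a semi-infinite layer) with
   the upper layer pinned to μ<sub>a0</sub> + Δμ<sub>a</sub><sup>UP</sup>,
   giving the cerebral change Δμ<sub>a</sub><sup>DOWN</sup>(t).
3. **Beer's law.** The absolute coefficients at both wavelengths are
   converted to [O₂Hb] and [HHb] per layer with sheep-blood extinction
   coefficients (ε in cm⁻¹ mM⁻¹ — 751 nm: O₂Hb 0.752, HHb 1.672;
   839 nm: O₂Hb 1.084, HHb 0.824), then re-referenced to the 5 s
   pre-task baseline.

Blocks contaminated by interfering behaviors (head shaking, chewing,
running, jumping) are excluded from a video ethogram; subjects showing an
interfering behavior in most blocks are dropped entirely; startle blocks
are stratified into Move (flight) and Stand (freezing) groups. Group
averages are computed within subject first for the motor task and across
retained blocks for the startle test, hemispheres never pooled; a
one-sample t-test of window-mean changes provides the activation statistic.

All forward physics is validated against a seeded Monte Carlo photon
transport in the layered medium, which also quantifies photon penetration
at the two distances.

## Worked example

```sh
python analysis/01_validate_forward_models.py
python analysis/02_penetration_depth.py          # ~1 min, 1e6 photons
python analysis/03_simulate_cohorts.py
python analysis/04_run_pipeline.py
```

Output from these runs:

```
two-layer vs homogeneous limit: worst rel err 2.10e-06 over 60 cases (tolerance 1e-3)
DPF at rho=30, mua=0.015, musp=1.0: 6.19; moment vs CW-derivative worst rel err 1.02e-10
MC reflectance at 30 mm: 2.093e-07 +- 7.3e-09; diffusion: 2.017e-07 (3.7% apart)
mean max depth: 5.2 mm at 10 mm vs 11.3 mm at 30 mm
lower-layer (cerebral) pathlength fraction: 1.97% at 10 mm (threshold 5%), 14.27% at 30 mm
motor/left: cortical O2Hb amplitude +0.852 uM (planted +1.0), extra-cerebral +0.024 uM (planted 0)
```

Reading: the two-layer solver reproduces the homogeneous closed form when
both layers are identical; the differential pathlength factor from the
time-resolved first moment matches its CW log-derivative definition; the
Monte Carlo reflectance confirms diffusion theory within its validity
regime; photons detected at 10 mm spend <2% of their path in the cerebral
layer (the short-channel design assumption), versus ~14% at 30 mm; and on
a noisy synthetic cohort the pipeline recovers a planted +1 μM cortical
O₂Hb response at ~0.85–0.87 μM with near-zero leakage into the
extra-cerebral estimate — the ~12% shortfall is the intrinsic crosstalk
bias of the sequential two-step method, quantified in
[docs/methods.md](docs/methods.md).

A CLI wraps the same library: `ovifnirs simulate|mc|run` (see `--help`).

## Acceptance script

`scripts/acceptance.py` re-runs the main computation from scratch: it
generates a seeded synthetic motor cohort, executes the full pipeline
(preprocess → two-step inversion → group average → statistic), reports the
recovered cortical amplitude, and cross-checks the diffusion forward model
against a seeded Monte Carlo run:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
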