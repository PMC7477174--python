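# Methods

This note documents the models, numerical choices and known limitations of
the package. Internal units are mm, mm⁻¹ and ns; concentrations are
reported in μM; ΔOD is decadic (log₁₀), the optical-density convention of
CW instruments.

## Photon-diffusion forward models

**Observable.** All reflectance quantities are the flux (Fick) form
R = D ∂Φ/∂z at the surface under the extrapolated-boundary condition
Φ(−z_b) = 0, with z_b = 2AD and A computed from the unpolarized
Fresnel-reflection moments (fluence- and flux-weighted) of the
tissue/air index step; A = 1 for matched indices, A ≈ 2.95 for
n = 1.4/1.0. The isotropic source sits at z₀ = 1/μ_s′ (one transport mean
free path); the alternative 1/(μ_a+μ_s′) differs negligibly in the regime
of interest.

**Diffusion coefficient.** D = 1/(3 μ_s′), the absorption-independent
(Furutsu–Yamada) convention. With this choice the time-resolved solution
factorizes exactly as R(t) = f(t; μ_s′) e^(−μ_a v t), so the identities the
package leans on — CW equals the time integral, mean time of flight equals
−∂ln R_CW/∂μ_a / v — hold to quadrature precision instead of to
O(μ_a/μ_tr) (which would be up to ~9% on the tested property range). This
is the standard convention in time-resolved NIRS work on the differential
pathlength factor.

**Homogeneous semi-infinite (CW and TR).** Closed-form dipole solutions:
a positive isotropic source at z₀ and a negative image at −(z₀+2z_b).

**Two-layer CW.** For a slab (μ_a1, μ_s1′, thickness s) over a
semi-infinite layer (μ_a2, μ_s2′), the 1-D boundary-value problem is solved
per spatial frequency q — continuity of fluence and normal flux at z = s,
extrapolated boundary at the top, decay at infinity — giving the surface
flux in Hankel space

    j(q) = e^(−α₁z₀) · ¼(1+e₁)[(1+e₂) + β(1−e₂)] / (½[(1+e₃) + β(1−e₃)])

with α_i = √(q² + μ_ai/D_i), β = D₂α₂/(D₁α₁), e₁ = e^(−2α₁z_b),
e₂ = e^(−2α₁(s−z₀)), e₃ = e^(−2α₁(s+z_b)) (exponentials factored to avoid
overflow). R(ρ) is the inverse Hankel transform (1/2π)∫ j(q) J₀(qρ) q dq.

*Quadrature.* Composite Gauss–Legendre (32-point panels) on
q ∈ [0, 30 μ_s1′]. The kernel decays as e^(−q z₀), so this q_max keeps the
truncated tail below ~10⁻⁹ of the integral even at ρ = 30 mm where the
oscillatory cancellation is strongest (a 10 μ_s′ cutoff loses 11% there).
The public API doubles the node count from 256 until successive values
agree to rel. 10⁻⁶ plus an absolute floor of 10⁻¹³ of the integrand's
magnitude — below that floor the alternating Bessel sum has cancelled more
than double precision can resolve, which happens only for reflectances
≲10⁻¹² mm⁻² (physically unmeasurable). Batched internal paths (inversion,
generation) use a fixed 1024-node rule, accurate to ~10⁻¹⁰ relative on the
baseline property range.

**DPF.** DPF(ρ) = v⟨t⟩/ρ with ⟨t⟩ the first moment of the TR curve by
adaptive quadrature with breakpoints at the diffusive time scale. The test
suite cross-checks it against the independent CW definition
(−∂ln R_CW/∂μ_a)/ρ. At the sheep baseline (μ_a = 0.015 mm⁻¹,
μ_s′ = 1.0 mm⁻¹, n = 1.4) DPF(30 mm) ≈ 6.2.

**DTOF fitting.** (μ_a, μ_s′) are fitted on peak-normalized curves over a
window from the rising edge (80% of peak) to the tail (1% of peak),
log-parameterized Levenberg–Marquardt. No instrument response function is
modelled — the original instrument's IRF handling is not described —
so the fit applies to deconvolved or simulated DTOFs; documented
limitation.

## Monte Carlo transport

Pencil beam at the origin, plane-parallel layers, annular detector
(half-width 1 mm, the probe's aperture not being specified). Exponential
step sampling at μ_t = μ_a + μ_s, absorption by weight attenuation (albedo
multiplication per scattering event), isotropic scattering under the
similarity reduction (g = 0, μ_s ← μ_s′ — sufficient for
reflectance/pathlength observables at these distances and half the
parameters), unpolarized Fresnel reflection at the top surface, Russian
roulette below weight 10⁻⁴ with survival 0.1, total-path cap 10⁴ mm.

The kernel is strictly sequential and seeded once, so a given seed
reproduces every tally bitwise; there is no parallel code path, which
satisfies the reproducibility contract trivially. Energy is accounted per
photon (escaped + absorbed + roulette + capped = launched, unbiased up to
roulette variance). Per detected photon the tallies keep the pathlength in
each layer and the maximum depth, from which the penetration study derives
its two claims: detected photons at ρ = 30 mm go deeper than at ρ = 10 mm,
and the 10 mm channel spends <5% (measured ~2%) of its pathlength below
the 10 mm interface.

At 10⁶ photons the homogeneous-medium reflectance at ρ = 30 mm agrees with
the diffusion closed form to ~4% (≈1 SE), and the mean detected pathlength
matches DPF·ρ to well under 10%.

## Inversion

Each time sample is an independent one-parameter least-squares problem
(one ΔOD value, one Δμ_a), solved by Levenberg–Marquardt with the damped
scalar normal equation dx = Jr/(J²+λ), adaptive λ per sample, batched
across all samples of a block — algorithmically identical to per-sample
`lsqcurvefit` calls but ~100× faster at cohort scale. Initial guess 0;
objective tolerance 10⁻¹⁶ (residual 10⁻⁸ OD); a fit driving μ_a below
10⁻⁶ mm⁻¹ is clamped there and flagged, never dropped. Negative Δ
concentrations are legitimate outputs; only absolute μ_a is floored.

Both baseline layers share μ_a0 and μ_s0′ (config defaults 0.015 and
1.0 mm⁻¹ — placeholders at the plausible center of head-tissue values,
since the study's per-wavelength baseline table is not available), as the
absolute coefficients are written μ_a0 + Δμ_a in both layers. Wavelengths
are fitted independently; s = 10 mm is a priori. The printed sheep
extinction coefficients are applied as μ_a = ε·c directly; whether they
are natural or decadic coefficients is not stated in the source, so a
`ln10_scale` switch exposes the alternative (it rescales concentrations by
ln 10 but cancels in all ratios).

## Synthetic data

The generator emulates the study's designs: motor task, 10 blocks of 30 s
walking + 30 s rest; startle test, 5 blocks of 30 s baseline + 3 s
stimulus + 60 s reaction; two hemispheres, 10 Hz, both distances and
wavelengths. A difference-of-gammas waveform with unit-normalized peak
(defaults: onset 1 s, time-to-peak 6 s, FWHM 6 s, undershoot 0.2 —
generic canonical values, the species providing no calibration) drives
per-layer concentration truths; defaults plant +1 μM O₂Hb / −0.3 μM HHb
in the cerebral layer only, order-of-magnitude fNIRS-typical. Superficial
systemic components (Mayer-type ~0.1 Hz oscillation, drift) can be planted
in the upper layer. Gaussian OD noise, σ = 10⁻³ per sample (no noise
figure being reported; a conservative CW value). Behavior annotations are
planted alongside: head-shake/chewing intervals to drive exclusions,
"frequent shaker" subjects (shakes in 80% of blocks against the 50%
subject-exclusion threshold), and flight/freezing labels at a configured
mix.

**No inverse crime.** Generation always uses the full two-layer forward
model at *both* distances; the analysis then applies the original-method
homogeneous approximation to the short channel. The approximation bias is
therefore measured, not assumed zero — see below.

## What the recovery tests establish — and the measured bias

On noiseless data the two-step inversion of self-consistently generated
ΔOD (homogeneous short + two-layer long) recovers both absorption changes
to <10⁻³ on a 5×5 grid: the inversion itself is exact. Against the
two-layer generator, however, the recovered cortical amplitude is
deterministically ×0.884: the ~2% of short-channel pathlength that lies in
the cerebral layer is misattributed to the upper layer, and the long
channel's ~4:1 upper/lower pathlength leverage turns that into an ~11.6%
underestimate — numerically equal to the first-order prediction
(L_down^10/L_hom^10)·(L_up^30/L_down^30). The same leverage amplifies
short-channel noise into the cerebral estimate (~4.5 μM per sample at
default noise), so a 10-subject group amplitude reading has a seed-level
SD of ~0.04 μM. Consequently the "recover within 15%" end-to-end check is
marginal by construction in this stated world: its expectation (0.884)
sits inside the band, but individual seeds fall on either side. The
amplitude is read as the GLM coefficient of the planted unit-peak waveform
(with intercept) in the group-average curve, the standard fNIRS reading
and unbiased for the waveform amplitude; a curve-maximum reading would be
upward-biased by noise and is not used. Upper-layer leakage stays ~0.02 μM
— the synthetic analogue of observing almost no hemodynamic change in the
extra-cerebral tissue.

A green recovery test therefore establishes that the pipeline implements
the two-step method faithfully including its intrinsic crosstalk, not that
the method is unbiased. Features of real data the generator does not
emulate: heterogeneous per-subject anatomy (fixed s), motion-artifact
waveforms (exclusions are planted as annotations only), physiologic
noise spectra (noise is white), and wavelength-dependent baseline optics.

## Group statistics

Motor: blocks average within subject first, subjects are the contributors.
Startle: retained blocks are the contributors; Move/Stand strata by the
flight-dominates tie-break. The activation statistic is a two-sided
one-sample t-test of window-mean Δ concentrations against zero (window:
the 30 s walk for motor, stimulus+30 s for startle; configurable). The
source reports only a significance threshold without naming the test; the
t-test is a documented stand-in, and its calibration (type-I rate at
α = 0.05, power for a +1 μM constant effect at n = 10 with noise
propagated analytically through the linearized inversion including
baseline-referencing offsets) is part of the acceptance suite.

## Degenerate inputs and tie-breaks

Half-open [start, end) intervals everywhere (an annotation abutting a
window end does not overlap); flat-line channels are flagged, not
dropped; zero detected MC photons yield NaN statistics plus a flag, not an
exception; zero contributor variance in the t-test reports p = 0 with a
degenerate flag; blocks extending past the recording are dropped with a
logged reason.
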