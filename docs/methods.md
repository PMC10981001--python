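# Methods

This note documents the models, conventions and numerical choices behind
`ssia_dosekit`, and what the synthetic-data tests do and do not demonstrate.

## Study structure and data model

The package models a two-route PET study: each patient receives a
⁶⁸Ga-labelled PSMA ligand intravenously (IV) and, separately,
super-selectively intra-arterially (ssIA) into tumour-feeding arteries, with
brain PET at three time points (~90, 165, 240 min post-injection) and one
whole-body scan after the first brain scan. Per scan the analysis keeps the
tumour SUVmax (hottest voxel — robust to partial-volume effects), the
contralateral healthy-brain SUVmean (background), and the pooled parotid
SUVmean; the liver SUVmean is a single per-route value from the whole-body
scan. The on-disk format is a long CSV (patient × route × scan); route- and
patient-level values ride on scan-1 rows. A background below 0.01 SUV is an
explicit `<0.01` sentinel, never zero, so tumour-to-background ratios can be
marked undefined instead of becoming infinite.

The packaged reference cohort carries the published per-patient values of a
10-patient study (5 high-grade glioma, 5 brain metastases). Two details
matter downstream: patient 3's first ssIA scan has no tumour value but does
have a parotid value, which is kept as a *partial* measurement because the
published pooled parotid mean is only reproduced when that value enters the
pool; and per-patient body weights, injected activities and tumour volumes
were never published, so those columns are blank and dosimetry on the
reference cohort requires user-supplied or synthetic metadata.

## VOI quantification

Volumes are SUV-calibrated 3-D images with a voxel-to-world affine (mm,
RAS). A voxel belongs to a sphere VOI when its center is inside the sphere —
simple, deterministic, and what common clinical tools do. The uptake-volume
VOI is the set of voxels with SUV ≥ 2.0 (the cutoff chosen above the maximum
healthy-brain background), restricted to the 26-connected component
containing a seed (default: the hottest voxel); without the component
restriction a global threshold on a whole-body image would swallow the
salivary glands. Masks live in the voxel index space of the reference scan,
so propagating a VOI across co-registered same-grid scans is exact; grids
that differ in shape or affine raise an error rather than resampling
(registration is out of scope). The healthy-brain background VOI is an
equal-volume sphere mirrored across the sagittal midline; a tumour VOI that
straddles the midline is rejected and the caller must place an explicit
background VOI instead. Statistics were verified against exhaustive
brute-force voxel scans on random images up to 32³. No partial-volume
correction is applied anywhere.

## Cohort statistics

* **Per-patient value**: the maximum tumour SUVmax over available time
  points; organ references are the pooled (mean) parotid SUVmean over all
  scans where it was read, and the single liver SUVmean.
* **Quantiles**: the SPSS weighted-average estimator ("type 6"): position
  h = (n+1)p on the sorted sample with linear interpolation, clamped to the
  extremes. This convention — not the numpy default — reproduces the
  published IQRs of the reference cohort exactly.
* **Reporting rounding**: half away from zero at one decimal (integers for
  fold changes), applied to the shortest decimal representation so that a
  computed 142.75 prints as 142.8.
* **Tabulated-ratio convention**: when summarising the reference cohort the
  per-patient T/SG and T/L ratios are taken from the one-decimal tabulated
  columns (falling back to recomputed-and-rounded values). The unrounded
  organ means behind the published table are unavailable, and several
  summary cells fall on exact .05 ties when recomputed from one-decimal
  inputs; the tabulated-ratio convention reproduces the published medians
  (8.4 / 0.5 / 26.5) exactly, while IQR cells can still differ by ±0.1 on
  such ties. Tolerances in the tests reflect exactly this input-rounding
  ambiguity and nothing else.
* **Bootstrap**: paired mean differences use the percentile bootstrap with
  patient-level resampling, default B = 1000, a seeded generator, and
  missing pairs dropped. The point estimate is seed-independent. Empirical
  coverage on synthetic normal cohorts follows the textbook O(1/n)
  small-sample deficit of the percentile method: measured 90.7% (n=10),
  91.7% (n=20), 93.6% (n=50), 94.8% (n=100) at nominal 95%. The coverage
  acceptance test therefore runs at n=100 pairs, where the method's
  asymptotic validity — the property under test — is separable from its
  known small-n deficit. At the study's own n=10, percentile intervals
  undercover by ~4 points regardless of implementation.
* **Qualification**: patients whose T/SG ratio, rounded to one decimal as
  tabulated, reaches 0.5.
* **TBRmax** is computed per patient as the maximum over scans with a
  measurable background, but no published pooling rule reproduces the
  reference TBR summary from the per-patient table, so TBR is excluded from
  exact reproduction checks.

## TAC kinetics

SUVs convert to percentage of injected activity per mL via
%IA/mL = 100·SUV/(1000·BW) with BW in kg; multiplying by the PET uptake
volume (fixed from the scan-1 threshold VOI and reused across time points)
gives total %IA, and scaling by an administered activity gives MBq. SUVs are
assumed decay-corrected to injection time — the standard scanner convention
— so fitted rates are purely biological and carry over to a therapeutic
nuclide unchanged. Time zero is the injection.

Two 2-parameter models are fitted by bounded nonlinear least squares:
mono-exponential washout (typical after ssIA: the bolus arrives
concentrated, then clears) and one-phase association (typical after IV: the
tumour fills from circulating tracer). Fits are multi-start
(λ ∈ {0.01, 0.1, 1} h⁻¹ × A₀ from the first/last/max point, tolerances
1e-14) because three points leave little room for a bad start; a fit is
accepted early when its SSE reaches machine precision. Auto-selection fits
both models and keeps the lower SSE, breaking exact ties toward washout for
falling series. The dose chain does **not** auto-select: it fits the
route-canonical model (ssIA → washout, IV → association), because with
near-flat noisy series the model choice flips on noise and an association
fit of a washing-out series inflates the dose integral several-fold.

T_eq — the time where the fitted ssIA washout crosses the fitted IV
association — is found by scanning a 4097-point grid over a 14-day horizon
for the first sign change and refining with Brent's method; the substituted
residual is at machine precision. Crossings below 1e-6 h are reported as
"no crossing": a sub-microsecond advantage period is meaningless and would
otherwise freeze a negligible uptake into pure physical decay.

On fit identifiability: with three samples spanning 1.5–4 h and 5%
multiplicative noise, the washout rate carries limited information — for
*any* estimator the Cramér–Rao bound gives sd(λ̂) ≳ 0.028 h⁻¹, so relative
errors of ~30% are expected (and observed) for the slow clearances seen
after ssIA (λ ≈ 0.01–0.12 h⁻¹), while IV association rates (0.3–1.1 h⁻¹)
recover to ~14% median error. Noiseless series recover their generating
parameters to better than 1e-6 relative. This is a design limitation of
3-point imaging, not of the fitter, and it propagates into per-patient dose
uncertainty; cohort-level medians are far more stable (see below).

## Dosimetry

The absorbed dose is the MIRD self-dose D = Ã·S for the tumour region only;
cross-dose is neglected because alpha and beta ranges are small against the
organ scale. Three closed forms cover the kinetics (λ_b biological, λ_p
physical, all rates h⁻¹, activities MBq, Ã in MBq·h converted by 3.6×10⁹ to
Bq·s at the dose step):

* washout to infinity: Ã = A₀/(λ_b+λ_p);
* washout truncated at T_eq with pure physical decay afterwards:
  Ã = A₀/(λ_b+λ_p)·(1−e^(−(λ_b+λ_p)T_eq)) + A₀/λ_p·e^(−(λ_b+λ_p)T_eq) —
  this is the ssIA route when the fitted curves cross, and it is monotone:
  the retained tail can only add dose;
* association to infinity: Ã = A₀·(1/λ_p − 1/(λ_b+λ_p)) — the IV route.

All three match adaptive quadrature to ≤1e-8 relative over randomized
parameter grids, and the boundary identities (T_eq = 0 → A₀/λ_p;
T_eq → ∞ → the plain washout integral) hold analytically.

S-values use an analytic local-deposition model for unit-density water
spheres: S = Σ E·y·φ/m with φ = 1 for alpha and electron emissions, φ = 0
for photons, and m the sphere mass at the contrast-enhancing tumour volume.
A user-supplied absorbed-fraction table φ(kind, volume) can replace the
default where electron escape from small spheres or photon self-absorption
matters. Nuclide data (⁶⁸Ga 67.71 min; ¹⁷⁷Lu 6.647 d, 0.1479 MeV electron
energy per decay; ²²⁵Ac 9.920 d with its full progeny chain branching at
²¹³Bi, ~27.5 MeV total alpha energy per parent decay) ship as an editable
YAML table of ICRP-107-style physical constants. Progeny are assumed to
decay in situ in secular equilibrium. RBE weighting multiplies the alpha
dose component by 5 (the conventional protection-level assumption for the
actinide chain), so a pure-alpha emitter's weighted dose is exactly 5× its
physical dose and the measured ²²⁵Ac chain factor is ~4.9 (a small electron
and photon admixture keeps it below 5).

**Scope limitation, stated prominently**: the absolute per-cycle doses in Gy
published for the reference cohort are not reproducible here — the
per-patient weights and volumes behind them are unpublished, and their
S-values came from an external dosimetry program whose internals are not
re-implementable from the description. Absolute doses from this package are
model doses under the local-deposition S-value; the validated claims are
the closed-form integrals, the scaling laws (dose linear in administered
activity and Ã, S ∝ 1/volume), the RBE factor, and ground-truth recovery on
synthetic cohorts.

## Synthetic data

`simulate_cohort` draws: body weight ~ normal(80, 10) kg truncated at ±3σ;
contrast-enhancing volume log-uniform on 1–60 mL with the PET uptake volume
0.9–1.4× larger; scan times 90/165/240 min plus 0–10 min jitter; IV plateau
uniform on 5–18 SUV with association rate 0.3–1.1 h⁻¹; ssIA washout rate
0.01–0.12 h⁻¹ with the amplitude placed so the measured peak fold advantage
equals a draw from log-uniform 7–25; parotid 11–33, liver 2.4–9.1,
background 0.02–0.1 SUV; injected activity 1.5 MBq/kg for IV and 55–85% of
that for ssIA. All spans are read off the reference cohort (the kinetic
rates from exponential fits to its printed TACs); weights and volumes,
absent from any published table, are conventions of this package. Noise is
mean-one multiplicative lognormal (default CV 5%): PET SUVs are positive
with roughly proportional error. Everything is reproducible from one seed.

The generator emulates the *structure* of the clinical data, not PET
physics: no scatter, randoms, reconstruction texture, motion, or
between-scan registration error, and organ SUVs are drawn independently
rather than from a patient-level covariance. Passing tests therefore show
that the analysis chain is correct and self-consistent under the stated
noise model — not that it is robust to every artefact of real acquisitions.

`simulate_pet_volume` builds a deterministic phantom (ellipsoidal brain at a
uniform background, one lesion with a quadratic falloff peaking exactly at a
voxel center, optional parotid spheres and liver block) so VOI statistics
have analytic expectations.

End-to-end, at the study's own design (10 patients, 3 scans, 5% noise), the
cohort-median ssIA/IV dose advantage is recovered with a median
estimated/true ratio of ~1.01 across seeds (acceptance runs 20 seeds; the
test suite 100), even though individual-patient ratios scatter by tens of
percent through the λ identifiability limit above.

## Problem sizes

Default verification sizes: 1000 random parameter draws for the quadrature
checks; 200 patients (400 fits) for noisy parameter recovery; 1000 cohorts
× B=1000 at n=100 pairs for bootstrap coverage; 15 random images ≤32³ for
brute-force VOI equivalence; 100 seeds × 10 patients for end-to-end dose
recovery. These sizes give stable medians while keeping the full suite in
the low minutes on one CPU.
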