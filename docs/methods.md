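# Methods

## Scope and procedure

`redcal` implements a desk-scale simulation pipeline around the
stoichiometric CT calibration method:

1. **Tissue catalogue** (`tissue_db`): 32 reference human tissues
   (3 fat, 18 non-fat soft, 11 bone) with mass density and percentage
   weights over 13 elements, embedded in the package and round-trippable
   through a CSV dialect. Published rows sum to 99.9–100.1% because of
   rounding; they are renormalized multiplicatively on load, since every
   downstream formula assumes proper mass fractions. Rows off by more
   than 0.5 are rejected as data errors.
2. **Physics** (`physics_core`): electrons per gram, RED, power-mean
   effective atomic numbers (exponents 3.62 / 1.86, fixed constants of
   the kV model), the parametric kV CT number, Bragg-additivity mean
   excitation energy and the Bethe stopping-power ratio.
3. **Scanner fit** (`calibration.fit_kv_parameters`): (A, B, C) by
   ordinary least squares on the three physical regressors with no
   intercept — the model has exactly three interaction terms. The
   package default (A = 1.995e-2, B = 1.899e-1, C = 964.0) is a 120 kVp
   fit to a CIRS 062M electron-density phantom; refitting requires the
   vendor substitute compositions plus measured CT numbers, supplied as
   CSV.
4. **Calibration curves** (`calibration.build_calibration_curve`):
   unweighted linear least squares of the target against RED, fitted
   independently per tissue category. Segments are category-defined, not
   RED-breakpoint-defined, and are not forced continuous across category
   boundaries; whether a clinical implementation would enforce
   continuity is a presentation choice that does not affect the
   within-category statistics. Lines carry an intercept by default; a
   through-origin variant exists for sensitivity checks.
5. **Composition perturbation** (`tissue_simulator`): each nonzero
   weight is drawn independently from Normal(ω, rel_sigma·ω) and the
   vector renormalized to 100%; zero weights stay zero (σ = 5% of 0 is
   0), and density is never resampled, so a simulated tissue's RED
   changes only through its electrons per gram — the generator isolates
   the composition question and deliberately omits density variation,
   measurement noise, beam hardening and every other real-scanner
   effect. Passing tests therefore bound the composition contribution
   only, not total clinical uncertainty. rel_sigma defaults to 0.05
   (a literature-informed scale of inter-subject elemental variability)
   with 100 samples per reference tissue, i.e. 3200 simulated tissues.
6. **Uncertainty quantification** (`uncertainty_analysis`): percentage
   deviations of curve estimates from exact values; systematic σ over
   the 32 reference tissues, statistical σ over the simulated tissues
   after subtracting each parent's deviation, total by root sum of
   squares, all per category and pooled, plus maxima of |deviation|.
7. **Beam comparison** (`beam_attenuation`): mixture-rule narrow-beam
   attenuation at 60 keV and 0.8 MeV, CT numbers as 1000·μ/μ_w, and
   per-category R² of HU against RED.

## Parameters that matter

| parameter | default | units | rationale |
|---|---|---|---|
| proton energy | 175 | MeV | mid-range therapeutic energy; pooled SPR systematic σ moves < 0.05 pp between 100 and 250 MeV (asserted in the suite), so the choice is immaterial to the reported statistics |
| I_w convention | Bragg additivity over water's composition (≈ 69 eV) | — | internally consistent with tissue I_m and makes SPR(water) = 1 exactly; a fixed tabulated value (e.g. 78 eV) is selectable, and all deviation statistics are provably invariant to any positive rescaling of I_w (the common stopping-number factor cancels between truth and fit) |
| rel_sigma | 0.05 | — | the study condition: σ = 5% of nominal weight per element |
| n_per_tissue | 100 | — | the study condition; 3200 simulated tissues give a ~1.3% relative standard error on pooled σ estimates |
| std convention | sample (n−1), about the pooled mean | — | population variant behind `std_mode`; the two differ by < 0.02 pp on pooled rows (asserted) |
| A, B, C | 1.995e-2, 1.899e-1, 964.0 | — | printed scanner constants; any refit replaces them coherently everywhere |

## Element constants

Atomic weights are IUPAC 2021 standard values; elemental mean
excitation energies are the ICRU-37 values as tabulated in the Geant4
manual (H 19.2 eV … I 491 eV). Mass attenuation coefficients are
embedded narrow-beam totals *including* coherent scattering at exactly
0.060 and 0.8 MeV from standard photon cross-section tabulations —
including coherent is deliberate, because the estimand is the
unscattered-photon survival fraction and a coherently scattered photon
has interacted. A log-log interpolation utility covers off-grid
energies but the default beams use the tabulated points directly.
Small differences against any particular cross-section library show up
only in the 3rd–4th decimal of the 3-point fat R² and are tolerated.

## Numerical choices

- All intermediate quantities are double precision; rounding happens
  only at report formatting (2 decimals for the uncertainty table,
  4 for R²). The RSS identity total² = sys² + stat² is asserted
  pre-rounding to 1e-12.
- Tissue normalization folds the floating-point residual of the
  rescaling into the largest weight so stored weights sum to exactly
  100.0. This makes normalization idempotent, which in turn makes the
  CSV round trip bit-exact and the rel_sigma = 0 limit yield exactly
  zero statistical σ rather than ~1e-13 artifacts.
- The attenuation model is the closed-form Beer–Lambert expectation of
  unscattered-photon counting; a Bernoulli survival simulator is kept
  as a test oracle of that equivalence (estimator −ln(k/n)/t agrees
  with the analytic μ within 3 standard errors at n = 10⁵).
- Simulated tissues are evaluated on their parent's category segment;
  the perturbation never reassigns category, so the statistical σ
  isolates composition variation rather than classification error.
- Negative weight draws are impossible in practice at rel_sigma = 0.05
  (> 20σ); they are clamped to zero before renormalization and counted
  on the output record for extreme settings.
- RNG substreams are keyed by (seed, CRC-32 of parent name), so one
  tissue's draws are reproducible without generating the rest, and a
  run manifest (config + version + seed) makes whole runs replayable.

## What the pipeline shows

Under the study conditions the pooled systematic/statistical/total
uncertainties computed by `build_report` are ≈ 0.53 / 0.38 / 0.65 %
for the kV CT number and ≈ 0.12 / 0.18 / 0.21 % for proton SPR, and
the largest soft-tissue HU deviation (≈ 2.24%) is attributed by the
per-tissue table to thyroid, whose trace iodine (Z = 53) perturbs the
photoelectric effective atomic number far more than the logarithmic
SPR. The per-tissue deviation table exposes this attribution rather
than hard-coding it: inflated lung (ρ = 0.26) is the other candidate a
priori, and the table shows it is not the driver under these fits. MV
attenuation tracks RED with R² = 1.0000 (4 dp) in every category versus
0.97–0.999 for kV. None of these numbers is stored anywhere; every run
recomputes them.

## Limitations

- Monoenergetic beams only; no spectra, beam hardening, scatter,
  detector response or reconstruction. No shell/density-effect
  corrections beyond the first-order Bethe stopping number.
- Uncertainty in the mean excitation energies themselves is not
  propagated; the statistics quantify composition variation only.
- The perturbation model is independent Gaussian per element with a
  single global rel_sigma; correlated or element-specific variability
  (e.g. different σ for H vs Ca) is not modelled beyond the rel_sigma
  hook.
- The fat category has only 3 members, so its per-category σ and R²
  rest on 3 points and are correspondingly unstable.
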