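# redcal

Stoichiometric CT calibration and proton-range uncertainty analysis:
how well does **relative electron density (RED)** alone predict a
tissue's kilovoltage CT number and its proton **stopping-power ratio
(SPR)**?

## The problem

Proton treatment planning converts CT numbers to proton SPR through a
calibration curve. Tissues with different chemical compositions can
share a CT number yet differ in SPR (the *degeneracy effect*), which is
a principal source of proton range uncertainty. `redcal` quantifies
that effect from first principles: it computes, for a catalogue of 32
reference human tissues (3 fat, 18 non-fat soft, 11 bone) and for
Gaussian composition-perturbed variants of them, both quantities two
ways — exactly from the elemental composition, and from RED alone via
per-category linear calibration curves — and reports the spread of the
percentage deviations. A small attenuation model additionally compares
how linearly kV (60 keV) and MV (0.8 MeV) CT numbers track RED.

## The model

For a material of density ρ with elemental percentage weights ωᵢ
(atomic number Zᵢ, atomic weight Aᵢ, mean excitation energy Iᵢ):

- electrons per gram: N_g = N_A Σ (ωᵢ/100) Zᵢ/Aᵢ, and
  RED = ρ N_g / (ρ_w N_w);
- scaled kV CT number (CT number + 1000):
  HU_scale = RED · (A Z̃³·⁶² + B Ẑ¹·⁸⁶ + C), where Z̃ and Ẑ are power
  means of Z over electron fractions λᵢ = N_gᵢ/N_g with exponents 3.62
  (photoelectric) and 1.86 (coherent), and (A, B, C) are scanner
  constants (defaults fitted on a CIRS 062M phantom at 120 kVp:
  A = 1.995·10⁻², B = 1.899·10⁻¹, C = 964.0);
- proton SPR by the Bethe ratio:
  SPR = RED · [ln(2mₑc²β²/(I_m(1−β²))) − β²] / [ln(2mₑc²β²/(I_w(1−β²))) − β²],
  with ln I_m from Bragg additivity, ln I_m = Σ(ωᵢZᵢ/Aᵢ) ln Iᵢ / Σ(ωᵢZᵢ/Aᵢ);
- narrow-beam attenuation by the mixture rule μ = ρ Σ (ωᵢ/100)(μ/ρ)ᵢ and
  HU_scale = 1000 μ/μ_water.

Calibration curves are unweighted linear least-squares fits of
HU_scale (or SPR) against RED, fitted independently within each tissue
category. The **systematic** uncertainty is the standard deviation
(n−1) of the percentage deviations across the reference tissues; the
**statistical** uncertainty is the standard deviation of the simulated
tissues' deviations after subtracting each parent's deviation
(perturbation: each nonzero weight ~ Normal(ω, 0.05·ω), renormalized to
100%, 100 samples per parent, density fixed); **total** = root sum of
squares.

## Worked example

```python
import redcal as rc

bundle = rc.build_report(config=rc.SimulationConfig(seed=1))
print(bundle.report.to_frame(decimals=2).to_string())
```

```
     systematic       statistical          total       max_abs_systematic       max_abs_statistical
       HU_scale   SPR    HU_scale   SPR HU_scale   SPR           HU_scale   SPR            HU_scale   SPR
fat        0.32  0.24        0.10  0.22     0.34  0.32               0.37  0.27                0.29  0.60
soft       0.62  0.13        0.06  0.18     0.62  0.23               2.24  0.45                0.42  0.72
bone       0.44  0.03        0.64  0.16     0.77  0.16               1.01  0.06                2.15  0.61
all        0.53  0.12        0.38  0.18     0.65  0.21               2.24  0.45                2.15  0.72
```

All values are percent (1σ, or maximum absolute percentage deviation).
Reading the pooled row: estimating the kV CT number from RED carries a
0.65% total uncertainty, estimating proton SPR from RED only 0.21% —
composition variation barely disturbs the RED→SPR map. The 2.24%
soft-tissue HU outlier is thyroid, whose 0.1% iodine shifts the
photoelectric effective atomic number. The kV/MV comparison:

```python
print(rc.linearity_comparison(rc.load_tissue_table("icrp23_reference"))[["r_squared_4dp"]])
```

```
               r_squared_4dp
kV   fat              0.9709
     soft             0.9962
     bone             0.9987
MV   fat              1.0000
     soft             1.0000
     bone             1.0000
```

An MV beam, being almost purely Compton, maps RED to CT number
linearly to four decimal places of R² in every category — the physics
case for MV CT in proton range estimation.

The same pipeline is available from the shell:

```
redcal all --seed 1 --out run1/        # every stage + manifest
redcal beams --out run1/               # kV vs MV comparison only
redcal calibrate substitutes.csv       # refit A/B/C from measurements
```

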