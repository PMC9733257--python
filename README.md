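# y90dosim

Pre-treatment dosimetry for ⁹⁰Y radioembolization of liver tumors.

Before ⁹⁰Y microspheres are injected into the hepatic artery, a surrogate
tracer (⁹⁹ᵐTc-MAA) is imaged to measure how much activity shunts to the
lungs and how the remainder splits between tumor and healthy liver. Those
numbers drive the prescribed activity, the expected lung dose, and whether
treatment is safe at all. This package implements that workflow for medical
physicists and for methodological studies of how attenuation correction
(AC) and scatter correction (SC) bias the result:

* **Planar quantification** — conjugate-view geometric-mean lung shunt
  fraction from anterior/posterior whole-body counts,
  `LSF = √(La·Lp) / (√(La·Lp) + √(Lva·Lvp))`, with optional dual-energy-window
  (DEW) scatter correction `C_true = C_main − (C_low/W_low)·W_main/2`.
* **SPECT quantification** — `LSF = Lc/(Lc+LVc)` from count volumes tagged
  AC-SC / NoAC-SC / NoAC-NoSC, iso-contour region-growing segmentation of
  tumor and injected healthy liver (IHL), and a shine-through correction
  that rebuilds lung counts from the clean left-lung concentration.
* **MIRD partition model** — three-compartment dosimetry with
  `liver uptake = (1−SF)·m_liver/(m_tumor·TLR + m_liver)` (tumor uptake
  analogous), activity for a prescribed liver dose via the 184,000 rad·g/mCi
  constant, lung dose via `D(Gy) = A(GBq)·SF·49.33/M(kg)`, and the
  LSF-banded resin-sphere prescription policy (full activity < 10 % shunt,
  −20 % for 10–15 %, −40 % for 15–20 %, contraindicated above 20 %; 30 Gy
  single-session and 50 Gy cumulative lung limits).
* **Cohort statistics** — per-method deviation summaries, Welch-t /
  Mann-Whitney significance tests and Pearson R² agreement on a packaged
  18-patient LSF table.
* **Digital phantom** — a lung–liver–tumor phantom with attenuated
  parallel-beam planar projection, dual-window scatter, emulated SPECT
  modes and Poisson noise, with exact ground truth for closed-loop testing.

## Worked example

Partition-model plan for a patient with 1500 g perfused healthy liver,
a 100 g tumor with tumor-to-liver uptake ratio 5, an 11 % lung shunt, and
a 70 Gy healthy-liver prescription:

```bash
y90dosim dose --liver-dose-gy 70 --m-liver 1500 --m-tumor 100 --tlr 5 --lsf 0.11
```

```json
{
  "activity_admin_mci": 85.49,
  "activity_admin_gbq": 3.163,
  "dose_liver_gy": 70.0,
  "dose_tumor_gy": 350.0,
  "dose_lung_gy": 17.16,
  "uptake_liver": 0.6675,
  "uptake_tumor": 0.2225,
  "reduction_factor": 0.8,
  "contraindicated": false
}
```

85.5 mCi (3.16 GBq) delivers 70 Gy to the healthy liver; the tumor receives
TLR × 70 = 350 Gy, the lungs 17 Gy (below the 30 Gy session limit), and the
11 % shunt puts the patient in the 20 %-reduction prescription band.

Cohort comparison of the four LSF estimators on the packaged 18-patient
table:

```bash
y90dosim replicate --out report/
```

prints (abridged):

```
          column  mean    sd
       lsf_wb_st 0.102 0.049
  lsf_spect_acsc 0.053 0.031
       lsf_wb_sc 0.064 0.049
lsf_spect_noacsc 0.071 0.042

           method  mean_pct  min_pct  max_pct  p_welch_vs_st  p_mannwhitney_vs_st  r2_vs_acsc
  LSFspect(AC-SC)       -50      -71      -28         0.0015               0.0020        1.00
LSFspect(NoAC-SC)       -32      -68       -8         0.0550               0.0497        0.93
        LSFwb(SC)       -45      -80      -13         0.0301               0.0130        0.92
```

The standard planar LSF (mean 0.102) roughly doubles the fully corrected
SPECT/CT value (0.053); scatter-correcting the planar study (0.064) removes
most of the bias and agrees with SPECT/CT at R² = 0.92 with no significant
difference, while its partition-model consequences are a −5.3 % mean change
in suggested activity but a −53 % mean change in predicted lung dose.

Simulation and quantification are also scriptable end to end:

```bash
y90dosim simulate --out sim/ --no-noise
y90dosim quantify-spect --volume sim/spect_ac_sc.nii.gz \
    --lung-roi sim/mask_lung.nii.gz --liver-roi sim/mask_liver.nii.gz
```

which recovers the phantom's true 5 % shunt from the calibrated volume.

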