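# oculodce

Quantitative dynamic contrast-enhanced (DCE) MRI analysis for intraocular
masses such as uveal melanoma.

Ocular DCE-MRI is hard for three reasons: lesions are small (often a few
hundred voxels), the eye rotates freely inside the head during the 4-minute
dynamic scan, and melanin shortens the baseline T1 so strongly that raw
time-intensity curves are dominated by pigmentation rather than perfusion.
`oculodce` implements an eye-specific analysis chain that addresses all
three:

1. **Two-step rigid motion correction** — every dynamic frame is registered
   to a reference frame (by default the 50th timepoint) first over the full
   field of view (head motion) and then restricted to a spherical eye mask
   (gaze changes), with a single resampling through the composed transform.
   The flip-angle series, B1+ map and post-contrast anatomy are registered
   to the same reference, and the lesion mask is propagated with the stored
   transform.
2. **B1+-corrected variable-flip-angle (VFA) T1 mapping** — the spoiled
   gradient-echo signal `S = M0 sin a (1 − E1) / (1 − E1 cos a)`,
   `E1 = exp(−TR/T1)`, is inverted by the classic linearisation (slope of
   `S/sin a` vs `S/tan a`); nominal flip angles are scaled by the median
   achieved B1+ over the lesion, and a lesion-masked 26-connected 3D median
   filter removes outlier voxels without dragging in the long-T1 vitreous.
3. **Pharmacokinetic modelling** — per-voxel signal is converted to
   gadolinium concentration by full SPGR inversion (r1 = 3.4 L mmol⁻¹ s⁻¹),
   the bolus arrival time (BAT) is found by a 25-candidate residual grid
   search on the median lesion curve, and the standard Tofts model

   ```
   C(t) = Ktrans ∫₀ᵗ Cp(τ) exp(−(Ktrans/ve)(t−τ)) dτ
   ```

   is fitted voxel-wise by bounded nonlinear least squares (Ktrans ∈ [0, 5]
   min⁻¹, ve ∈ (0, 1]), using the exact piecewise-linear-AIF recursion for
   the convolution and a published population arterial input function
   (tabulated-file override available). Lesions are summarised by the
   median and interquartile range over fit-OK voxels.

A **digital eye phantom** (`oculodce.phantom`) generates the full input set
— dynamic series, flip-angle series, B1+ map, masks — from known ground
truth (geometry, T1, Ktrans/ve, rigid motion trace, Rician noise), so the
entire chain is testable end-to-end without patient data. A **sensitivity
harness** (`oculodce.sensitivity`) perturbs B1+ (±2/±5 %), T1 (±30/±60 ms)
or the registered frames (one-voxel shift over two dynamics, late vs
post-bolus) and reports the relative change of the median lesion Ktrans
and ve.

## Worked example

Generate a synthetic study and analyse it:

```bash
oculodce phantom --out demo/phantom --seed 17
```

then run the pipeline with a config like

```yaml
inputs:
  dce: demo/phantom/dce.nii.gz
  fa_series: demo/phantom/fa_series.nii.gz
  b1: demo/phantom/b1.nii.gz
  lesion_mask: demo/phantom/lesion_mask.nii.gz
  fa_angles: [2, 5, 9, 15]
eye: {center_mm: [29.375, 30.75, 14.25], radius_mm: 11.0}
registration: {enabled: false}   # the demo phantom is motionless
output: demo/out
```

```bash
oculodce run --config demo/run.yaml
cat demo/out/lesion_summary.json
```

prints (phantom generated with Ktrans 0.46 min⁻¹, ve 0.22, lesion T1
1122 ms, lesion-median B1+ 0.91):

```json
{
  "ktrans_per_min": {"median": 0.46011, "p25": 0.45750, "p75": 0.46267, "iqr": 0.00517, "n_total": 252, "n_ok": 252},
  "ve":             {"median": 0.22005, "p25": 0.21881, "p75": 0.22128, "iqr": 0.00247, "n_total": 252, "n_ok": 252},
  "t1_ms":          {"median": 1121.73, "p25": 1115.51, "p75": 1127.97, "iqr": 12.46,   "n_total": 252, "n_ok": 252},
  "b1_factor": 0.91,
  "bat_index": 5,
  "bat_mode": "auto"
}
```

The full chain recovers the generating Ktrans and ve to 0.02 % and T1 to
0.02 % at the median; the small residual spread comes from the scalar
(lesion-median) B1+ correction applied across the smooth transmit-field
gradient. The estimated bolus arrival matches the simulated one. Per-voxel Ktrans/ve/kep/RSS/flag maps are written as NIfTI
next to the summary, together with a JSON run manifest that echoes the
configuration and per-stage parameters.

The same machinery is available as a library:

```python
from oculodce import PhantomSpec, simulate_study
from oculodce.pipeline import analyze

study = simulate_study(PhantomSpec(noise_sigma=0.05, seed=3))
result = analyze(study.dynamic, study.fa_series, study.b1,
                 study.truth.lesion_mask, study.acq,
                 study.spec.resolved_eye_center(), study.spec.eye_radius_mm)
print(result.summaries["ktrans_per_min"])
```

Subcommands `register`, `t1map`, `fit` and `sensitivity` expose the
individual stages; see `oculodce --help`.

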