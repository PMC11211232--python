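# synaps

Synchronized free-running 4D flow MRI at desk scale: simulation,
pilot-tone gating, autofocus motion correction, k-t sparse SENSE
reconstruction and flow quantification.

## The problem

Whole-heart 4D flow MRI measures a time-resolved, three-directional
velocity field v(x, t) across the cardiac cycle, but the phase-contrast
(PC) acquisition that encodes velocity has poor blood-to-myocardium
contrast, which makes vessel delineation — the step every flow measurement
depends on — unreliable. Bright-blood cine sequences (e.g. fast
interrupted steady-state, FISS) have exactly the anatomical contrast PC
lacks, but carry no velocity information. This package implements the
synchronization strategy that gets both: two free-running 3D radial
sequences — a bright-blood anatomical scan and a 4-point velocity-encoded
PC scan — are acquired back-to-back (interrupt < 2 s) while a pilot tone
(PT) transmitter is recorded continuously through both. Because the PT
signal spans the two acquisitions on one clock, a single set of cardiac
triggers and one respiratory curve gate and correct both sequences, and
the reconstructed anatomical magnitude can be combined voxel-for-voxel
with the reconstructed velocity field ("SyNAPS 4D flow").

It is aimed at MRI reconstruction researchers: everything runs on a
synthetic beating, breathing torso phantom with pulsatile parabolic flow
whose ground truth (displacement coefficients, trigger times, stroke
volume, velocity field) is known exactly, so every stage is validated by
parameter recovery rather than by eye.

## The method

The pipeline runs six steps on a raw session (simulated or loaded from the
HDF5 container):

1. **Acquisition / simulation.** 3D radial spiral-phyllotaxis interleaves
   (golden-angle in-plane spokes in 2D desk-scale mode): the anatomical
   sequence uses 2000 interleaves x 24 readouts (6 modules x 4), the PC
   sequence 4820 x 21 (1 superior–inferior projection + 5 lines x 4
   velocity-encoding segments), venc = 150 cm/s, FOV 220 mm, 2.0 mm
   resolution. The forward model is an exact NUDFT of the rasterized
   phantom frame frozen at each readout's timestamp; respiration enters as
   a rigid k-space phase shift.
2. **Pilot tone.** Each PT channel is a mixture of a cardiac and a
   respiratory source plus drift, an inter-sequence step and noise.
3. **Cardiac gating.** PCA then ICA separate the cardiac source; an
   adaptive band-pass (peak ± 0.3 Hz inside 0.5–3 Hz) cleans it; local
   minima define triggers; readouts of *both* sequences are binned into
   the same cardiac phases (20 by default) from this one trigger set.
4. **Respiratory curve.** The dominant respiratory-band principal
   component, low-passed and detrended per sequence with the
   inter-sequence step removed, normalized to max |r(t)| = 1.
5. **Focused navigation (fNAV).** The heart's bulk respiratory translation
   is modeled as d(t) = c · r(t) with c in mm; c is fitted by minimizing
   the entropy of the gradient image of a pooled gridded reconstruction of
   the anatomical data, then the correction phase exp(+2πi k·d(t)) is
   applied to **both** sequences' k-space.
6. **Reconstruction and combination.** Each sequence (and each encoding
   segment) is reconstructed by k-t sparse SENSE,

       min_x  1/2 Σ_p ||E_p x_p − y_p||² + λ_t TV_cardiac(x) + λ_s TV_spatial(x)

   with λ_t/λ_s = 0.03/0.015 (anatomical) and 0.0075/0.015 (flow) after
   normalizing each acquisition to the maximum of a gridded
   reconstruction. Velocity is decoded from the four segment phases via
   the balanced Hadamard scheme, v = (2·venc/π) H⁺ φ. The SyNAPS volume
   carries the anatomical magnitude and the PC velocity on the shared
   phase grid; the "native" volume keeps the PC magnitude for comparison.

Flow analysis places planes in the two aorta-like vessels (AAo/DAo),
traces the vessel dynamically on the magnitude images (threshold +
seeded connected component, seed propagated by centroid), and reports
area(t), flow rate Q(t), net volume ∫Q dt, peak flow, Dice overlap with
the ground-truth masks, and Pearson / linear-regression / Bland-Altman /
Wilcoxon agreement statistics.

## Worked example

```python
from synaps.pipeline import run_pipeline

manifest, report = run_pipeline({"seed": 1, "n_phases": 8}, "out/")
aao = report["planes"]["AAo"]
print(f"net volume     {aao['net_volume_ml']:.1f} mL "
      f"(programmed {aao['true_net_volume_ml']:.0f} mL)")
print(f"contrast ratio SyNAPS {report['contrast']['fiss_blood_myocardium']:.2f} "
      f"vs native {report['contrast']['pc_blood_myocardium']:.2f}")
print(f"Dice vs truth  SyNAPS {aao['dice_synaps_vs_truth']:.2f} "
      f"vs native {aao['dice_native_vs_truth']:.2f}")
```

prints (about three minutes on one core):

```
net volume     29.0 mL (programmed 30 mL)
contrast ratio SyNAPS 1.49 vs native 0.71
Dice vs truth  SyNAPS 0.94 vs native 0.07
```

The phantom pumps 30 mL per beat through each vessel; the reconstructed
net volume recovers it within a few percent. The blood-to-myocardium
contrast ratio of the SyNAPS magnitude is about twice that of the native
PC magnitude — which is why dynamic vessel segmentation succeeds on the
former (Dice ≈ 0.9 against the true masks) and degrades badly on the
latter. `out/` holds every intermediate: raw HDF5 containers, the physio
record, the motion model, NIfTI volumes, per-phase flow curves (CSV) and
`flow_report.json`.

The same stages are exposed on the command line:

```bash
synaps run-all --config session.yaml --out out/
synaps simulate --config session.yaml --out out/   # or stage by stage
```

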