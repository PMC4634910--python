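# cinedense

Simulation and analysis of 2D cine **DENSE** (Displacement ENcoding with
Stimulated Echoes) cardiac MRI, built around the encoding-frequency tradeoff.

DENSE stores tissue displacement **u** in the phase of the MR signal through
the encoding frequency *k*<sub>e</sub> (cycles/mm):

φ = 2π · *k*<sub>e</sub> · u

A high *k*<sub>e</sub> gives fine displacement sensitivity but wraps the phase
as soon as |u| > 1/(2 *k*<sub>e</sub>) (5 mm at the conventional
0.10 cycles/mm) and loses signal to intra-voxel dephasing; a low
*k*<sub>e</sub> avoids wrapping but amplifies the displacement error caused by
phase noise (σ<sub>φ</sub> ≈ 1/SNR radians, hence σ<sub>u</sub> ≈
1/(2π *k*<sub>e</sub> SNR) mm). `cinedense` is for MR physicists and
image-analysis researchers who want to study this tradeoff quantitatively
without scanner data:

* an **analytic deforming left-ventricle phantom** — an incompressible
  annulus with prescribed circumferential shortening, radial thickening and
  twist, so the Lagrangian strain tensor E = ½(FᵀF − I) and the rotation
  about the end-diastolic endocardial centroid have closed forms;
* a **DENSE encoder** producing magnitude and wrapped-phase series with
  Rician noise at a target SNR, intra-voxel dephasing, *k*<sub>e</sub>-dependent
  blood-pool decay, optional 12-bit phase quantization, and the k-space echo
  geometry (stimulated echo, T1 echo, anti-echo) that governs stripe
  artifacts;
* the **analysis pipeline**: quality-guided phase unwrapping in the
  myocardial segmentation, Lagrangian trajectory reconstruction from the
  Eulerian maps, 10th-order temporal polynomial fitting, and segmental /
  global Ecc, Err and twist curves with their peaks;
* **image-quality metrics** (Rician-corrected SNR, wrapped-pixel fraction,
  blood-pool dephasing, stationary phase-noise RMSE) and **agreement
  statistics** (Bland–Altman bias and 95 % limits of agreement, a modified
  coefficient of variation, paired t-tests) for comparing encoding
  frequencies across a synthetic cohort.

## Worked example

```python
import cinedense as cd
from cinedense import metrics

cfg = cd.PhantomConfig(peak_ecc=-0.20, peak_twist_deg=8.0)   # healthy-range deformation
truth = cd.build_phantom(cfg)
seg = cd.segmentation_from_truth(truth)

series = cd.encode(truth, cd.EncodingConfig(ke_cycles_per_mm=0.10,
                                            target_snr=20.0, seed=1))
res = cd.DenseMechanicsModel(series, seg).fit()
print(res.summary())
```

```
DENSE cardiac mechanics
=======================================================
encoding frequency : 0.100 cycles/mm
frames             : 30
material points    : 228
polynomial order   : 10
-------------------------------------------------------
measure                     peak   frame      seg SD
peak Ecc (%)              -19.62      20        0.13
peak Err (%)               20.87      19        0.48
peak twist (deg)            7.96      20        0.02
=======================================================
```

The phantom was programmed with a −20 % peak global circumferential strain
and 8° of twist; at SNR 20 and *k*<sub>e</sub> = 0.10 cycles/mm the pipeline
recovers −19.6 % and 7.96°, peaking at the end-systolic frame (20).  Radial
strain is recovered with a low bias because the steep transmural strain
gradient of an incompressible wall is averaged over the pixel-scale
neighbourhood used to estimate the deformation gradient (see
`docs/methods.md`).  The `seg SD` column is the between-segment spread — near
zero here because the phantom is axisymmetric.  Wrapping vanishes at low
encoding frequency:

```python
for ke in (0.10, 0.04):
    wrapped = cd.wrapped_pixel_map(truth, seg, ke=ke)
    print(ke, metrics.wrap_fraction(wrapped, seg))   # 55.1 %  ->  0.0 %
```

A command-line interface mirrors the library (`cinedense simulate`,
`analyze`, `sweep`, `stats`); `cinedense sweep --out results/` runs a full
multi-subject encoding-frequency comparison and writes peaks, wrap-fraction,
SNR, blood-pool and Bland–Altman agreement tables with a seed manifest.

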