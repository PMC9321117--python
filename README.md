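# merlin-zte

Self-navigated retrospective rigid-body motion correction for silent 3D
zero-echo-time (ZTE) MRI — trajectory design, acquisition simulation,
non-Cartesian reconstruction, and the MERLIN motion-estimation/correction
loop, in plain scientific Python.

## Who this is for

ZTE sequences read a center-out radial spoke while the gradients are already
on, so a scan is nearly silent as long as consecutive spokes differ only
slightly in direction. MERLIN (Motion Estimation & Retrospective correction
Leveraging Interleaved Navigators) exploits the same spoke ordering for
self-navigation: low-resolution navigator images are reconstructed
continuously from a sliding window of the acquisition, registered to the
first navigator, and the estimated rigid head poses are undone directly in
k-space before the final reconstruction. This package implements that whole
loop plus a synthetic multi-coil ZTE scanner so every stage can be validated
against exact ground truth — for reconstruction researchers who want a
tested, hackable reference implementation rather than scanner-bound code.

## The method in brief

**Trajectory.** Spoke directions follow a 3D spiral phyllotaxis: spoke *i*
of interleaf *j* has azimuth φ<sub>i,j</sub> = (i·k + j)·φ<sub>G</sub> and
polar angle θ<sub>i,j</sub> = acos z<sub>i,j</sub>, where
z<sub>i,j</sub> = 1 − (i·N<sub>i</sub> + j)·Δz sweeps linearly from pole to
pole (Δz = 2/(N<sub>s</sub>N<sub>i</sub> − 1)) and
φ<sub>G</sub> = 360°/g² ≈ 137.5° is the golden angle, g = (1+√5)/2.
Subsampling the sequential golden-angle set with a Fibonacci stride
k = F(s) yields N<sub>i</sub> smooth interleaves whose internal azimuthal
step is Δφ = 360°/gˢ (7.7° for the "smoothness factor" s = 8) — small steps
mean quiet gradients; sparser interleaves mean more streaking. With
N<sub>i</sub> = k the union of interleaves is exactly the sequential
golden-angle set.

**Navigators.** Each magnetization-prepared segment acquires a fixed number
of spokes; a sliding window of N<sub>seg</sub> consecutive segments (one
interleaf's worth) is reconstructed at 3 mm by Tikhonov-regularized cgSENSE,
with coil sensitivities estimated from a low-gradient WASPI pre-scan
(channel image ÷ root-sum-of-squares) and Pipe density compensation.
Stepping the window by one segment gives
N<sub>nav</sub> = (N<sub>i</sub> − 1)·N<sub>seg</sub> + 1 navigators. The
regularized solution extrapolates the deadtime gap (the 2–3 missing samples
per spoke from transmit-receive switching) implicitly.

**Correction.** Each navigator is rigidly registered to the first one
(masked Mattes mutual information); the pose is assigned to the window's
middle segment. For a segment at pose (R, Δ̄) the trajectory is rotated,
k̄<sub>corr</sub> = Rᵀk̄, and the data gain the Fourier-shift phase ramp
y<sub>corr</sub> = y·exp(+i2π k̄·Δ̄/FOV); the corrected segments plus the
(reference-position) WASPI data feed one final cgSENSE reconstruction.

**Simulator.** Motion is injected exactly in k-space — data of a moved
object equal the static spectrum sampled at rotated coordinates times a
phase ramp — so correction with the ground-truth trace restores the static
data to machine precision, giving every downstream test a sharp oracle.

## Worked example

```python
import numpy as np
from merlin_zte import scenario_fixture, merlin_pipeline, MocoConfig

acq = scenario_fixture("steprot20_64", seed=0)   # 20-degree axial step rotations
result = merlin_pipeline(acq, MocoConfig())

est, true = result.trace, acq.truth_trace
d_rot = est.angles_deg - true.angles_deg
d_tra = est.translations_mm - true.translations_mm
print("translation RMS error [mm]:", np.sqrt((d_tra**2).sum(1).mean()).round(3))
print("rotation    RMS error [deg]:", np.sqrt((d_rot**2).sum(1).mean()).round(3))
```

prints (seed 0):

```
translation RMS error [mm]: 0.043
rotation    RMS error [deg]: 1.182
```

The translation error is far below the 3 mm navigator voxel. The rotation
error is concentrated entirely in the segments adjacent to the instructed
20° pose steps: a sliding window that straddles a step contains data from
both poses and its registration returns a weighted average of the two, so
the middle-segment estimate deviates by a fraction of the step size there.
On segments whose whole window is at a single pose the rotation RMS error
is ≈ 0.13°, the navigator-to-navigator precision of the method (the
docs/methods.md note quantifies this decomposition). The corrected image is
sharper and closer to a static reference scan than the uncorrected one for
every motion paradigm shipped in `scenario_fixture`.

The same loop is scriptable from the shell:

```bash
merlin fixture steprot20_64 --seed 0 -o acq.h5
merlin moco acq.h5 -o out --save-navs
merlin metrics out/corrected.nii.gz --ref out/uncorrected.nii.gz -o report.json
```

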