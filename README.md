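# vfamap

R1 and apparent proton-density mapping from variable flip angle (VFA)
spoiled gradient-echo (FLASH) data, including closed-form estimators
that remain accurate **outside the small-flip-angle regime**.

## The problem

Dual flip angle R1 mapping infers the longitudinal relaxation rate
R1 = 1/T1 and a signal amplitude A (proportional to proton density)
from two FLASH volumes — one PD-weighted (small flip angle), one
T1-weighted (large flip angle).  The workhorse closed-form estimator
linearizes the Ernst equation

    S_n = A sin(α_n) (1 − E_n) / (1 − cos(α_n) E_n),    E_n = exp(−R1·TR_n)

assuming both R1·TR ≪ 1 *and* small flip angles.  At 7T the transmit
field (B1+) is strongly inhomogeneous — the actual flip angle is
ft·α_nominal with ft varying roughly 45%–135% over a head — and
postmortem protocols need very large nominal angles, so the small-angle
assumption fails and the conventional estimator acquires a spatially
structured, ft-dependent bias.

`vfamap` implements the remedy: substituting the half-angle tangent
τ = 2·tan(α/2) makes the Ernst equation rational in τ, and its [1/1]
Padé approximant around R1·TR = 0,

    S_n ≈ A τ_n R1·TR_n / (τ_n²/2 + R1·TR_n),

inverts in closed form for any two volumes with **arbitrary flip angles
and unequal TRs**:

    R1 = ½ · [(S1τ1/TR1) − (S2τ2/TR2)] / [(S2/τ2) − (S1/τ1)]
    A  = S1 S2 [(TR1τ2/τ1) − (TR2τ1/τ2)] / [S2 TR1 τ2 − S1 TR2 τ1]

The package also provides the conventional small-angle closed form (same
algebra with α in place of τ), the exact two-point inversion for equal
TRs, a DESPOT1-like linearized fit for N ≥ 2 volumes, and a nonlinear
least-squares oracle — plus bias/noise simulation, a seeded synthetic
phantom generator, a voxelwise NIfTI map pipeline, and error/test-retest
statistics (ft-binned histograms, 2-D densities, within-participant
coefficient of variation).

## Worked example

Simulate the in vivo 7T protocol (nominal flips 5°/27°, TR 31.6 ms,
white-matter R1 = 0.82 s⁻¹, A = 1) at a transmit-field scale of 1.35 —
actual flip angles 6.75°/36.45° — and invert with both closed forms:

```python
import numpy as np
from vfamap import AcquisitionProtocol, PreparedAngles, TissueParams, ernst_signal
from vfamap.estimators import estimate_pade, estimate_small_angle

protocol = AcquisitionProtocol.in_vivo_7t()
tissue = TissueParams(r1_per_s=0.82, a_au=1.0)
prep = PreparedAngles.from_protocol(protocol, ft=1.35)
signals = ernst_signal(tissue, prep.alpha_rad, protocol.tr_s_array)
for name, est in [("small-angle", estimate_small_angle), ("Pade", estimate_pade)]:
    r = est(signals, prep, protocol.tr_s_array)
    print(f"{name}: R1 = {float(r.r1_per_s):.4f} /s  A = {float(r.a_au):.4f}")
```

prints

```
small-angle: R1 = 0.7870 /s  A = 1.0095
Pade: R1 = 0.8200 /s  A = 1.0000
```

The small-angle estimate is 4% low in R1 (0.787 vs the true 0.82 s⁻¹)
and 1% high in A purely because the actual angles are no longer small;
the Padé estimate recovers the ground truth.  Sweeping ft over the full
in vivo range shows the small-angle R1 bias peaking at 4% while the Padé
error stays below 0.006%:

```bash
vfamap bias-sweep --scenario invivo --out bias.csv
# invivo/small_angle: max |R1 err| = 4.020%, max |A err| = 0.951%
# invivo/pade: max |R1 err| = 0.006%, max |A err| = 0.000%
```

A full synthetic experiment — phantom generation and voxelwise fitting:

```bash
vfamap phantom --preset invivo --out-dir phantom/
vfamap fit --pdw phantom/pdw.nii --t1w phantom/t1w.nii --ft phantom/ft_map.nii \
    --flip-deg 5,27 --tr-ms 31.6 --method pade --out-dir maps/
```

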