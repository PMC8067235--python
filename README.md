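# probemech

Computational mechanics of fiber neural implants in brain tissue, with a
companion pipeline for quantifying the immune response around explanted
probes.

Chronically implanted neural probes damage the tissue around them not only
during insertion but continuously afterwards: the brain moves relative to
the skull-fixed implant with every breath (~11.4 µm at 1 Hz) and heartbeat
(~2 µm at 4 Hz), and the resulting micromotion strains the periprobe
tissue and sustains the foreign-body response.  `probemech` models this
interaction end to end for fiber probes of different base materials
(stainless steel, silica, polycarbonate, hydrogel), surface friction, and
cross-sectional geometry:

- **Tissue model** — first-order Ogden hyperelasticity in principal
  stretches, `W = (µ₁/α₁)(λ̄₁^α₁ + λ̄₂^α₁ + λ̄₃^α₁ − 3) + κ/2 (J − 1)²`,
  with µ₁ = 8.1 Pa, α₁ = 15.7 (adult rodent hippocampus, CA3SR) and a
  volumetric penalty enforcing near-incompressibility.
- **Simulation** — total-Lagrangian finite elements on a structured
  butterfly hex mesh of a 1×1×6 mm tissue block with an embedded 3 mm
  probe; node-to-node Coulomb frictional contact on the probe–tissue
  interface; implicit adaptive time stepping over the micromotion waveform
  `11.4 sin(2πt) + 2 sin(8πt)` µm.
- **Damage statistics** — equivalent (von Mises) strain fields; peak and
  mean strain in the 500 µm region of interest around the probe tip; the
  "critical region" of tissue whose peak strain exceeds 0.05, measured as
  the volume of an alpha shape over the affected elements.
- **Histology quantification** — distance–intensity profiles of
  immunofluorescence markers (GFAP, Iba1, CD68, IgG) around the probe
  track: probe detection, side/band averaging, background normalization,
  50 µm binning, one-/two-way ANOVA with Tukey post-hoc tests, and overlay
  of normalized strain and intensity profiles.
- **Synthetic data** — seed-deterministic generators for fluorescence
  images with known ground truth and for solver verification fixtures with
  closed-form references.

## Worked example

```python
import numpy as np
from probemech import fe_solver as fes

scenario = fes.Scenario(name="demo", material="hydrogel", preset="tiny",
                        total_time=0.25)
bundle = fes.run_scenario(scenario)
print(f"peak ROI max strain  {bundle['peak_roi_max']:.4f}")
print(f"peak ROI mean strain {bundle['peak_roi_mean']:.4f}")
d, v = bundle["path_profiles"]["tip"]
print(f"tip-path peak strain {v.max():.4f} at {d[np.argmax(v)]*1e3:.0f} um")
```

prints (hydrogel probe, circular 400 µm section, COF 0.3, desk-scale mesh,
first quarter-period of the waveform):

```
peak ROI max strain  0.0473
peak ROI mean strain 0.0170
tip-path peak strain 0.0279 at 0 um
```

i.e. at this scale the tissue within 500 µm of the hydrogel probe tip
experiences up to ~4.7% equivalent strain, the ROI-average peaks at ~1.7%,
and the strain decays away from the probe surface along the tip-plane
diagonal.  Swapping `material="steel"` raises the peak strain, and raising
`cof` lowers it — the orderings the study turns into design guidance.

The histology side in three lines:

```python
from probemech import synthetic_data as sd, histology_quant as hq
img, truth = sd.generate_ihc_image(sd.IHCGroundTruth(amplitude=2.0, seed=7))
profile, binned = hq.image_profile(img)   # normalized, 10 x 50 um bins
```

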