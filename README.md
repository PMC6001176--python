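# dogblur

Blind (no-reference) blur assessment for MRI slices using parallel
multiscale difference-of-Gaussian (DoG) filters.

Blur in MRI arises from patient motion, partial-volume effects,
post-acquisition smoothing and some pathologies, and it directly degrades
the edge information that drives quantitative measures such as ventricular
volumes or cortical atrophy. `dogblur` scores each 2-D slice on a
standardized [0, 1] quality scale using only the slice itself — no pristine
reference — which makes scores comparable across scanners, subjects and
image contents. It is aimed at quality-control pipelines in clinical trials
and research archives that process large slice volumes automatically.

## The method

For a slice with dimensions d1 × d2:

1. **Intensity standardization** — min–max rescale to `I_d ∈ [0, 255]`.
2. **Foreground extraction** — threshold at the mean of `I_d`, fill
   enclosed holes, drop connected components smaller than 800 px
   (8-connectivity). All subsequent means are taken over this anatomy mask.
3. **Reference feature** — the foreground mean `μ_Id`.
4. **Parallel multiscale DoG filtering** over scales `s = 1..L`,
   `L = ⌊√(d1 + d2)/2⌋`, with two schedules that coincide at `s = 1`:
   * high-energy (edge-retaining): `DoG(σ=1, σ=1+s)`
   * low-energy (edge-attenuating): `DoG(σ=s, σ=s+1)`
5. **Edge maps** — per-scale local-contrast images of each filter response
   (sample standard deviation in a 5 × 5 window); record the foreground
   means `mED1(s)`, `mED2(s)`.
6. **Quality index** from the final means `μ_CA = mED1(L)`,
   `μ_CB = mED2(L)`:

   ```
   q1 = |μ_CA − μ_CB| / μ_Id            (contrast score)
   q2 = |μ_CA − μ_CB| / (μ_Id + μ_CB)   (sharpness score)
   Q  = (q1 + q2) / 2                   (total score, clamped to [0, 1])
   ```

A detail-free (e.g. constant) slice scores exactly 0; sharp,
high-contrast slices score higher. The pipeline is deterministic and
seed-free.

The package also ships the matching evaluation toolkit: seeded
piecewise-constant MRI-like phantoms (nested-ellipse "brain" and
disk-plus-chambers "cardiac" layouts), Gaussian and linear-motion blur at
degradation levels 0–15, slice-wise batch scoring of NIfTI / DICOM /
PNG-TIFF inputs with CSV reports, and mean-opinion-score (MOS) /
Spearman-correlation validation summaries.

## Worked example

```python
import numpy as np
from dogblur import PhantomSpec, generate_phantom, apply_gaussian_blur, assess_image

phantom = generate_phantom(PhantomSpec(d1=128, d2=128, n_regions=4, seed=3))
sharp = assess_image(phantom)
blurred = assess_image(apply_gaussian_blur(phantom, 15))

t = sharp.trajectory
print(f"L={t.L}  mu_Id={t.mu_reference:.2f}  mu_CA={t.mu_ca:.2f}  mu_CB={t.mu_cb:.2f}")
print(f"sharp:   q1={sharp.score.q1:.4f} q2={sharp.score.q2:.4f} Q={sharp.score.Q:.4f}")
print(f"level15: Q={blurred.score.Q:.4f}")
```

prints

```
L=8  mu_Id=103.30  mu_CA=11.77  mu_CB=0.70
sharp:   q1=0.1072 q2=0.1065 Q=0.1069
level15: Q=0.0834
```

`L=8` scales were run for the 128 × 128 slice; the high-energy filter ends
at an edge-map mean of 11.77 versus 0.70 for the low-energy filter, and
their normalized distance gives `Q ≈ 0.107` for the sharp phantom, falling
to `0.083` after the strongest Gaussian degradation — blur compresses the
gap between the two filter banks.

From the shell:

```bash
dogblur simulate --kind motion --levels 0:15 --phantom brain --seed 7 --out sim/
dogblur score sim/brain_motion_L00.png --out report.csv
dogblur validate --objective report.csv --subjective observers.csv --out table.csv
```

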