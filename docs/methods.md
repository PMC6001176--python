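# Methods

## Model and assumptions

The metric treats an ideal MRI slice as piecewise constant: flat tissue
compartments separated by sharp boundaries. Under that model, edge content
is the only signal that distinguishes a sharp slice from a degraded one,
and the persistence of edges across Gaussian scales separates high-quality
from blurred images. Two DoG filter banks probe that persistence in
opposite directions over a shared scale range `s = 1..L`:

* the high-energy bank `G(1) − G(1+s)` keeps a fixed fine inner scale and
  widens only the surround, so its response accumulates band-pass energy
  as `s` grows;
* the low-energy bank `G(s) − G(s+1)` moves both scales upward together,
  so its response drains toward zero.

Both banks start from identical parameters `(1, 2)` at `s = 1` — this is
asserted to 1e−10 in the tests and holds exactly by construction, since the
two responses at `s = 1` are computed from the same smoothing cache. At
the final scale the gap between the foreground means of the two edge maps,
normalized by the image mean, is the quality index. Everything is computed
in double precision; the pipeline contains no randomness.

Key contracts:

* `Q = (q1 + q2)/2` exactly; `q2 ≤ q1` always (its denominator is larger
  by `μ_CB ≥ 0`); all three lie in [0, 1] after clamping.
* A constant slice cannot be min–max rescaled; it is defined to rescale to
  all zeros and score `(0, 0, 0)`, the extremely-degraded limit. This
  avoids a division by zero while agreeing with the limit the formulas
  approach as detail vanishes.
* If numerical effects ever gave `μ_CB > μ_CA`, no swap is performed: the
  formulas use the absolute distance as written, and the event is recorded
  as a per-slice warning. Likewise, a distance exceeding a validity bound
  is clamped and warned, never silently rescaled.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `L` | `⌊√(d1+d2)/2⌋`, min 2 | scale count; 11 for 256², 16 for 512², 8 for 128² phantoms. The floor keeps σ on the unit grid the schedules index. |
| `contrast_window` | 5 px | local-contrast window. 3×3 under- and 7×7 over-estimate perceived quality on 256²–512² slices, so 5×5 is the recommended fixed size; it is a knob for other geometries. |
| `contrast_operator` | `std` | sample standard deviation of the raw signed DoG response in the window; `range` (max−min) is the configurable alternative. The operator is applied to the unrectified response. |
| `min_component_area` | 800 px | foreground components below this area are removed (8-connectivity) after mean-thresholding and hole filling. |
| Gaussian kernel support | `2⌈3σ⌉+1` | unit-sum renormalized; the DoG kernel therefore sums to zero regardless of truncation. |
| boundary | symmetric (reflect) | for all convolutions and window statistics, so the image border does not manufacture edges. |

Degradation schedule: Gaussian blur at level ℓ uses a rotationally
symmetric unit-sum kernel on a w×w support with `w(ℓ)` the nearest odd
integer to `3 + (ℓ−1)·12/14` (so w(1)=3, w(15)=15) and `σ = w/6`; motion
blur uses an anti-aliased unit-sum line PSF with length and angle both
equal to ℓ. Level 0 is the identity in both families. Note the odd
rounding makes adjacent levels share a width (3,3,5,5,7,7,…), so a
degradation series contains tied images by construction.

## Implementation notes

* The multiscale loop never builds 2-D DoG kernels: each Gaussian is
  separable, so the image is smoothed once per unique width (1..L+1) with
  two 1-D passes and every DoG response is a difference of two cached
  smoothings. This is exactly equal to dense convolution with the
  outer-product kernel; the test suite verifies the equality against a
  brute-force double-loop convolution at 1e−9.
* The sliding-window standard deviation uses the `E[x²] − E[x]²` identity
  on a globally mean-centered response. Centering matters: the raw
  identity loses up to ~1e−6 absolute accuracy on near-constant windows at
  intensity scale 100, while DoG responses centered near zero agree with a
  per-window loop to ~1e−12.
* The foreground mask is computed once per slice on the rescaled image and
  reused for every per-scale edge-map mean.
* Spearman correlation uses average ranks for ties (the standard
  convention); it is undefined and rejected for constant sequences and for
  fewer than 3 pairs. Validation tables report the correlation within each
  degradation level, matching their row structure; a pooled correlation
  across levels is available separately.

## The phantom generator

Phantoms are piecewise-constant slices on a zero background: nested
ellipses with mild seeded aspect/orientation jitter (brain-like) or a disk
with small circular chamber inclusions (cardiac-like). Region intensities
are distinct draws from [40, 255]; anatomy occupies roughly the central
60% of the grid so that every blur kernel radius fits inside the zero
margin (blurring then conserves the grid mean to well under 1%). A
phantom is a pure function of its spec; the stress suite derives per-
phantom seeds from one suite seed via `numpy.random.SeedSequence`.

What the phantoms emulate: piecewise-constant tissue compartments, nested
anatomy, zero air background, controllable region count and contrast.
What they do not emulate: acquisition band-limiting (their edges are
1-pixel steps, sharper than any real MRI edge), Rician noise, bias
fields, texture within compartments, and realistic foreground fill
fractions. Passing the suite therefore demonstrates the metric's
boundedness, determinism, filter identities and gross blur sensitivity —
not its absolute calibration on clinical data, where scores sit much
higher (textured foregrounds raise the edge-map means toward `μ_Id`).

Suite sizing: 50 phantoms at 128×128 (region counts cycling 3–6,
alternating layouts) × 2 blur kinds × 16 levels, plus the two boundary
images — 1602 assessments, about half a minute on one CPU.

## Known limitations

* **Mask-driven non-monotonicity at small blur levels.** The foreground
  mask is re-derived from each test image, as a blind metric must. On
  razor-sharp, high-contrast phantoms, mild blur pushes the mean-threshold
  mask outward into the blurred edge halo; the added halo pixels raise the
  edge-map foreground mean and lower `μ_Id` simultaneously, so `Q` can
  rise slightly over the first few levels before the monotone decline
  takes over. `Q(level 0) > Q(level 15)` holds on every suite phantom, but
  the per-phantom rank correlation between level and `Q` misses the −0.9
  mark on roughly a third of phantom × kind pairs. Freezing the mask at
  its undegraded extent removes the effect entirely (verified on a
  single-disk experiment), confirming it is foreground-segmentation
  sensitivity — the method's acknowledged weak point — amplified by
  synthetic step edges, not a property of the filter banks.
* Scores on piecewise-constant phantoms are small in absolute terms
  (Q ≈ 0.05–0.22): with flat interiors, the final edge-map mean is far
  below `μ_Id`. Absolute values on textured clinical slices are not
  comparable to phantom values.
* Strictly per-slice: no through-plane blur modeling, no regional blur
  maps, no noise or bias-field indices.
* The 5×5 window is calibrated for 256²–512² slices; very different
  resolutions should revisit `contrast_window`.
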