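# Methods

## Pipeline model and assumptions

A Mooney (two-tone) image is produced by a fixed composition:
grayscale conversion → Gaussian smoothing (in floating point) → 8-bit
quantization → global threshold selection → strict binarization. The
order matters: smoothing before quantization keeps the histogram smooth,
and quantizing before the threshold search guarantees a finite candidate
space of exactly 256 integer thresholds, which both spatial selectors
enumerate exhaustively. All selectors act on the same quantized smoothed
image, including the template edge map of the edge-similarity selector,
so template and candidates are compared on the object the thresholds
actually cut.

Binarization is strict: a pixel is white iff its intensity is *greater
than* the threshold; pixels equal to the threshold are black. Because a
single global cutoff preserves the intensity ordering, the white sets at
two thresholds are always nested, and two global-threshold variants of a
non-constant image can never be exact polarity reversals (dissimilarity
ratio < 1).

## Parameters

| parameter | default | units | notes |
|---|---|---|---|
| grayscale weights | (0.2126, 0.7152, 0.0722) | – | CIE 1931 Y for sRGB primaries, applied directly to the stored 8-bit channel values; configurable |
| `gamma_decode` | off | – | optionally decode sRGB to linear light before the weighted sum and re-encode after; see open choices below |
| smoothing σ | 2 | px | light blur; a three-level stimulus design uses σ ∈ {2, 4, 6} |
| kernel truncation | 4 | σ | the Gaussian kernel is cut at 4σ and renormalized |
| smoothing boundary | `mirror` | – | mirror-reflection avoids border darkening that would bias the mean threshold |
| Canny σ | 1 | px | gradient scale of the edge detector |
| Canny hysteresis | 0.10 / 0.20 | fraction of the image's gradient-magnitude maximum | expressing them relative to each image's own contrast keeps the detector meaningful on both grayscale and binary candidates |
| Hausdorff direction | template → candidate | – | directed distance as defined for the objective; a `symmetric=True` flag gives the classical two-sided distance |
| tie-breaks | smallest threshold | – | deterministic argmax/argmin on plateaus |
| per-image threshold SD | sample (n−1) | intensity levels | `ddof=0` switches to the population form |
| quartiles / whiskers | linear interpolation / 1.5×IQR | – | the usual boxplot conventions |
| foils k | 3 | concepts | nearest Euclidean neighbours in the 13-dimension shape subspace; distance ties break alphabetically |

## Numerical choices

* Quantization rounds half away from zero and then clips to [0, 255]:
  deterministic and platform-independent, so thresholds reproduce
  bit-exactly.
* Otsu is computed from the 256-bin histogram with cumulative sums;
  candidates whose classes are empty score zero. The returned value is
  the first (smallest) maximizer of the between-class variance.
* The directed Hausdorff distance is evaluated with an exact Euclidean
  distance transform of the candidate edge map (O(HW) per candidate
  rather than O(|A|·|B|)). An empty candidate edge set is scored with
  the image diagonal √(H²+W²) so all-black/all-white candidates are
  maximally penalized instead of undefined; an empty template set
  scores 0, and a template image with *no* detectable edges makes the
  edge-similarity objective identically zero, which is rejected as an
  error rather than silently returning threshold 0.
* Edge detection delegates to scikit-image's Canny; the fraction-of-
  maximum hysteresis thresholds are converted to the absolute values it
  expects by recomputing the gradient magnitude with the same
  Gaussian-derivative steps. Canny masks the one-pixel image border, so
  a full-height step edge yields a line of height H−2, and the
  symmetric gradient of an ideal binary step ties in non-maximum
  suppression, keeping both columns adjacent to the step.
* The mean threshold is kept real-valued (not rounded): comparison
  against integer pixel values is exact either way, and rounding would
  discard information from the manifest.

## Synthetic scenes

The fixture generator replaces photographic templates with scenes that
have the statistical structure the pipeline assumes: bimodal
object-on-background mixtures (background N(40, 10), object N(200, 10)
by default, so mean and Otsu thresholds are well defined and distinct),
flat disks and nested rectangles with known edge geometry for the
spatial selectors, full-range intensity ramps, uniform noise, and
polarity-reversed binary pairs anchoring the dissimilarity ratio at 1.
All randomness comes from numpy's PCG64 generator under explicit seeds,
so a given spec reproduces byte-identical uint8 images across platforms.

What the fixtures deliberately do not emulate: photographic texture,
shading gradients, multimodal histograms with more than two modes, and
semantic content. Passing tests therefore demonstrate that the
*algorithms* are correct (each selector equals its brute-force
reference, the pipeline is deterministic, the metrics obey their
axioms), not that any particular threshold values or dissimilarity
levels will be observed on real photograph collections — those depend
on the image material.

Problem sizes: oracle-equivalence checks run on 50 seeded scenes of
32×32 pixels (the selectors are resolution-independent; the exhaustive
references are quadratic, so small frames keep the double computation
brisk); the batch-determinism check uses the full 40-template ×
4-technique × 3-σ stimulus design at 64×64.

## Design choices where the design was open

* **"CIE 1931 linear intensity mapping".** The luminance weights are
  applied directly to stored (gamma-encoded) 8-bit values by default —
  the behaviour of common scientific imaging toolchains — with
  `gamma_decode=True` available for strict linear-light luminance. The
  default is a convention, not a claim about which is more correct.
* **Hysteresis thresholds** are not dictated by the method; 0.1/0.2 of
  the gradient maximum are conventional detector defaults and are fully
  configurable (`--canny-low`, `--canny-high`).
* **Equality at the threshold** goes to black ("exceeding" read
  strictly); with the candidate domain being the pixel values
  themselves this choice is load-bearing and is therefore pinned and
  tested.
* **Foil distances** use raw embedding values without standardization;
  the shape dimensions of a similarity embedding share a common scale,
  and standardizing would silently reweight them.
* The easy/medium/difficult stratification uses half-open bins
  (p > 0.75; 0.25 < p ≤ 0.75; p ≤ 0.25) so every proportion gets
  exactly one label.

## Known limitations

* Only global thresholding: one cutoff per image. Local/adaptive
  methods, and entropy- or misclassification-based selectors, are out
  of scope.
* No colour management: ICC profiles and display gamma are ignored;
  inputs are assumed to be plain sRGB-encoded 8-bit rasters.
* No resizing: templates are processed at their native resolution.
* Foil selection requires the caller to supply the concept embedding;
  none is bundled.
* The edge-similarity objective is a directed distance; it penalizes
  template edges missing from the candidate but not spurious candidate
  edges. That is the intended objective, and the symmetric variant is
  available where both directions matter.
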