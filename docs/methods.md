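# Methods

## The measurement

The package measures the intrinsic (melanin-free) THG brightness ratio
between basal-cell cytoplasm and dermal collagen at the dermal–epidermal
junction (DEJ) of skin imaged by two-channel harmonic-generation
microscopy. For each qualified depth of a stack,

    R = (THG_cytoplasm − N) / (THG_collagen − N),

with masked THG means over the segmented cytoplasm and collagen and a
single per-stack noise term `N`: the mean THG brightness outside the
rectangular ROI at frame index 80 (≈144 µm at the 1.8 µm z-step),
clamped to the deepest frame for shorter stacks. Subtracting the same
noise from numerator and denominator makes `R` exactly invariant under
any detector gain `k` and offset `b` (`I → kI + b` maps all three terms
the same way), which the test suite checks numerically. The per-stack
ratio is the unweighted mean over qualified subimages; the cohort
statistic is the mean with its standard error (n−1 sample SD / √n) over
included stacks, each exclusion carrying one of five recorded reasons.

Assumptions inherited from the measurement design:

* the noise floor is additive, signal-independent (photomultiplier
  electronics) and depth-stationary, so a deep, signal-free frame
  estimates it;
* vignetting multiplies the optical signal, not the noise, and affects
  cytoplasm and collagen alike inside the ROI, so it cancels in `R`;
* the collagen THG signal is co-registered with the SHG signal, so SHG
  masks can be applied to THG pixels.

## Protocol constants

All constants live in one `RunConfig` and reach every phase explicitly:

| constant | default | meaning |
| --- | --- | --- |
| `roi_threshold` | 1600 | grayscale cut for ROI selection (THG) and coverage (SHG); 1600/150 ≈ 10.7 keeps SNR above the desired 10 |
| `shg_coverage_min` | 0.25 | screening: SHG coverage must be **strictly** greater |
| `min_cells` | 10 | screening: inclusive minimum of distinguishable basal cells |
| `min_qualified_subimages` | 3 | per stack, for it to enter the cohort |
| `melanin_ratio_cutoff` | 1.6 | previewing + inspecting: strictly-above excludes (phototype-I level) |
| `noise_depth_index` | 80 | frame used by the noise estimator, from the surface downward |
| `coherence_floor` | 0.3 | structure-tensor coherence for "orientation discernible" |
| `focus_floor` | 0.01 | previewing admission floor for the focus metric |
| `cell_diameter_px` | 17.4 | expected basal-cell diameter (10 µm at 0.576 µm/px); sets watershed seed spacing |

Boundary semantics are deliberate: coverage is strict (>0.25 fails at
exactly 0.25), cell count is inclusive (≥10), the melanin cutoff is
strict (1.6 itself is included), and three qualified subimages are the
minimum.

## Invented operationalisations

The original protocol relied on visual judgment for three decisions; the
package replaces them with explicit, configurable operators:

* **Focus** — variance of the discrete Laplacian normalised by the
  squared frame mean; scale-free under global gain, zero on constant
  frames. The admission floor (0.01) was calibrated once against the
  blurred synthetic scenario (whose score falls below 10⁻³ while sharp
  scenes score ≈2) and stored in the default configuration.
* **Melanin pieces** — any connected blob of ≥20 px, inside or adjacent
  to cytoplasm, brighter than twice the cytoplasm median. Melanin caps
  are rendered at several times cytoplasm brightness, so the factor two
  separates cleanly; a melanin-free scene cannot produce a 20-px blob at
  2× median from Gaussian noise.
* **Orientation clarity** — structure-tensor coherence
  (λ₁−λ₂)/(λ₁+λ₂) of the mask-averaged smoothed gradient outer product
  over the collagen mask: 1 for a single orientation, ~0 for isotropy;
  floor 0.3.

## ROI selection

The ROI is the bounding box of the largest 8-connected suprathreshold
component after (a) a 3×3 majority vote and (b) a radius-8 binary
closing. The majority vote removes isolated hot pixels so they cannot
inflate the window from the dim border. The closing is load-bearing:
basal cells and the collagen network are separated by dark interstices
up to roughly half a cell diameter wide, and without it the "largest
component" is a single tissue phase — or a fragment of one — so the
window can clip the cell field and stacks fail screening for want of
cells that are actually present. Because the noise floor (σ≈60 around
150) is more than 20 standard deviations below the 1600 threshold,
the closing cannot connect to detector noise; the bounding box is taken
over genuine suprathreshold pixels of the bridged component only.
`select_roi` is idempotent in the sense that re-running it on its own
crop never yields a larger window.

## Segmentation

**Collagen (SHG-driven).** A pixel is collagen when it is suprathreshold
(>1600) *and* its multiscale Sato tubular-filter response (scales 1–3 px)
exceeds that response's Otsu cut inside the ROI; 1-px gaps are closed,
components under 30 px dropped, and the mask is re-intersected with the
suprathreshold set so the hard invariant — no sub-threshold pixel is
ever labelled collagen — holds on every call.

**Cells (THG-driven).** Gaussian smoothing (σ=1 px), Otsu foreground,
hole filling, then a distance-transform watershed whose seeds are local
maxima at least half a cell diameter apart; every foreground component
is guaranteed at least one seed (a small component next to a taller one
would otherwise be suppressed by the global minimum-distance rule and
never labelled). Components touching the ROI border or under 100 px are
dropped. When the co-registered SHG frame is supplied, THG-bright
collagen picked up by the foreground is handled in two steps: regions
that are mostly SHG-bright (>60%) are discarded outright, and SHG-bright
pixels are stripped from the remainder — the reproducible counterpart of
manually removing fiber regions from the cell segmentation. Within each
cell the nucleus is the interior dark basin (below the cell's own Otsu
cut, ≥15 px, not touching the cell edge); nucleus thresholding is
per-cell rather than global because vignetting makes a global dark cut
meaningless. The cytoplasm measurement mask excludes sub-cut pixels
(membranes, partial-volume rims) and a 1-px guard ring around the
nucleus; the sub-cut exclusion is applied only when the cut actually
separates a dark subpopulation (≥5% of the cell), since on a
near-uniform bright cell Otsu would bisect the noise and bias the mean
upward. Component-size floors (30/100/15 px) are defaults at the
0.576 µm/px acquisition scale and are configurable.

**Manual steps.** Exclusion regions and manual cytoplasm selection are
declarative (polygons, rectangles or masks in the run configuration), so
"manual" operations are reproducible, logged, and testable. Exclusions
only ever remove pixels.

## Synthetic stacks

The generator renders, per frame: a basal-cell mosaic (dart-thrown
centres with minimum separation, nearest-centre territories clipped to
discs, 2-px dark intercellular boundaries, one dark elliptical nucleus
per cell at 0.4–0.6 of the cell diameter) and/or collagen fibers
(von-Mises-oriented smooth random walks rasterised to skeletons, given a
flat-core tube profile of radius 2 px with a 0.4-px Gaussian shoulder
via a distance transform). Epidermal frames above the DEJ band hold
cells only, the 5-frame DEJ band holds cells over fibers, deeper frames
are fiber-dominated with exponential depth attenuation (length 20 µm
below the band). The composite signal is multiplied by a radial cosine
vignette (onset at 0.75 of the half-width) and by the attenuation
factor, then additive Gaussian noise with mean 150 and σ=60 is applied
everywhere, an optional global blur emulates subject motion (applied to
the composited noisy frame — the blurred scenario's defining property is
an image too blurred to analyse), and values are clipped to the 14-bit
range. Identical parameters and seed reproduce a stack voxel for voxel.

Scene content is confined to a central disc at 0.82 of the half-width.
This mirrors the fact that only the optically uniform centre of a
scanned field is analysable, and it has a deliberate statistical
consequence: cytoplasm and collagen share the same vignette
distribution, so the vignette cancels in the ratio rather than biasing
it. Truth masks cover the whole volume; the stored reference means (and
the generator's `true_ratio`) are defined over the unvignetted core of
the DEJ band — the region a correct analysis measures — and the
calibration tests are phrased over that region.

Calibrated intensity levels (the study conditions; the source protocol
prints only the threshold 1600, the floor ~150, the cutoff 1.6 and the
final ratio, not absolute vitiligo grayscales): cytoplasm 1809, collagen
THG 1650, noise floor 150 — giving a true ratio of
(1809−150)/(1650−150) = 1.106 — plus collagen SHG 3500, nuclei 450,
boundaries 300, melanin caps 8000. Fiber channel amplitudes are
calibrated per frame against the mean core profile so that the masked
mean equals the configured value exactly in expectation; the flat-core
profile (rather than a pure Gaussian cross-section) is what makes that
calibration well defined, since it gives the tube an unambiguous truth
boundary at half maximum. Default geometry is 256×256×96 voxels with the
DEJ band at frames 24–28, 30 cells of 10 µm and 60 fibers per frame
(κ=8, walk jitter 0.04 rad/step so the field is genuinely oriented);
the full 512×512 acquisition geometry is available by parameter.

Presets: `paper_cohort` (melanin-free, the defaults), and one per
exclusion path — `melanin_containing` (melanin caps on ≥60% of cells and
cytoplasm brightened so the true ratio exceeds 1.6), `blurred` (σ=8 px),
`sparse_collagen` (4 fibers, coverage far below 25%), `few_cells`
(6 cells).

What the generator does *not* emulate: optical physics (PSF, scattering,
harmonic conversion), Poisson photon statistics (noise is Gaussian),
depth-correlated tissue (frames are rendered independently), hair
follicles, melanocyte dendrites, and real biological texture within
cytoplasm or fibers (both are flat fields plus noise). Passing the
recovery tests therefore shows the pipeline is unbiased and correctly
plumbed under the stated noise, vignetting and geometry model — not that
its segmentation accuracy transfers to arbitrary clinical images.

## Numerical choices and degenerate inputs

* Ratios are computed in double precision; reports round to 3 decimals.
* A collagen mean at or below the noise estimate invalidates the
  record (it signals a failed segmentation or bad noise frame) rather
  than producing a negative ratio.
* An empty cell foreground yields zero cells, not an error; screening
  then disqualifies the depth.
* The noise frame index clamps to the deepest frame with a log message.
* `estimate_noise` refuses an ROI covering the whole frame (no outside
  pixels); `select_roi` raises an explicit no-ROI failure when nothing
  is suprathreshold.
* SEM is reported as undefined for a single included stack; a cohort
  with zero included stacks is an error carrying the exclusion reasons.
* Stack values are validated against the declared bit depth on both
  construction and file reads; 14-bit data live in uint16 containers
  (no 14-bit TIFF exists), with metadata embedded in the
  ImageDescription tag and a YAML sidecar accepted as fallback.

## Problem sizes used by the shipped checks

The acceptance script and the headline tests run the full pipeline on
14 synthetic stacks of 256×256×96 voxels (the desk-scale default that
keeps the index-80 noise frame meaningful) and the noise estimator on
10 such stacks; unit and property tests use 160×160×7 scenes with the
same intensity structure and proportionally fewer cells and fibers.

## Known limitations

* Cell counting is approximate near the ROI border (border-touching
  cells are dropped by design, as their intensities are unreliable).
* The watershed can merge touching cells whose seeds fall closer than
  half a cell diameter; counts recover the configured density within
  ±30%, which is sufficient for the ≥10-cell screening rule but not for
  morphometry.
* DEJ depths are supplied by the operator or the generator's truth;
  automatic junction detection from image content is out of scope.
* Aggregation treats stacks as independent; several stacks from one
  patient are not nested (matching the original averaging), and no
  uncertainty beyond the SEM is reported.
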