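# Methods

## Scope and model

gliaquant quantifies projected multi-channel fluorescence stacks of brain
tissue: nuclear-stained instance segmentation, reporter colocalization,
background-corrected marker classification, per-nucleus smFISH surface
calling, fiber-band morphometry, and two-group statistics. The package
also ships a synthetic scene generator whose statistical structure matches
what the analysis assumes, so every stage can be validated against exact
ground truth. The analysis modules only ever see the rendered stack; the
ground truth is used exclusively for scoring.

## Synthetic scenes

**Geometry.** A scene is a physical box (default 200 × 200 × 10.2 μm,
i.e. 15 z-planes at 0.68 μm) sampled at 0.5 μm pixels in x/y (0.25 μm for
smFISH scenes, where individual diffraction-limited puncta must be
resolved). Nuclei are ellipsoids with equatorial radius drawn uniformly
in 2.5–4.5 μm (typical glial nuclei; the default area filter of
10–150 μm² brackets this range) and polar radius 0.8× that, clipped to
the slab.

**Placement.** Per cell class, the cell count is Poisson with mean
density × volume; cells are placed by dart throwing with a hard-core
minimum center distance of 1.5× the maximum nucleus radius, enforced in
the x/y plane because the entire analysis operates on a thin-slab
projection. Placement failure after a bounded number of attempts raises
an error naming the achievable density. Default densities follow the
measured tissue values (oligolineage 41.2 or 13.9 × 10⁴ cells/mm³ for
the control/ablated cohorts, plus 20 × 10⁴ cells/mm³ of
reporter-negative background nuclei).

**States.** Reporter (GFP), marker and probe states are independent
Bernoulli draws per cell given its class. Per-probe puncta counts are
Poisson with mean 15 in expressing and 1 in non-expressing cells — rates
chosen so the per-nucleus surface distribution is strongly bimodal around
the 1.5 μm² calling boundary, as a binary expression caller presumes; the
underlying per-cell count distributions are a modeling choice, not a
measured quantity.

**Rendering.** Nuclear channel: filled ellipsoids. Reporter: somatic
disks (nucleus radius + 1.5 μm) for reporter-positive cells. Markers:
either a membrane annulus (NG2-like, width 1.2 μm) or a somatic disk
(PDGFRa/CC1-like). Probes: hard disks of radius 0.25 μm placed uniformly
within 0.8× the nucleus radius, with a soft minimum separation of 2.5
spot radii. Fiber channel: a horizontal band of stated thickness, or
*n* discrete 1.5 μm fibers inside the band when integrated-density
measures should scale with fiber count. All amplitudes are arbitrary
units on the 16-bit scale with a per-cell brightness jitter of ±20 %, a
constant offset of 20, Gaussian PSF of σ = 0.3 μm (0.2 μm for smFISH
scenes), Poisson shot noise at 0.05 photons per intensity unit and
Gaussian read noise of σ = 2.

**Randomness.** Placement, structure layout and per-channel noise each
use a child generator spawned deterministically from the scene seed.
Scenes are therefore bit-reproducible, and rendering a subset of channels
yields arrays identical to rendering them all — the recovery studies
exploit this to skip unused channels.

**What the generator does not emulate.** Spectral bleed-through,
depth-dependent attenuation and scattering, chromatic shifts, non-glial
morphologies, anisotropic PSFs, tissue deformation, and segmentation-
adversarial textures (clumped chromatin, overlapping somata in z).
Passing recovery tests therefore demonstrates the correctness of the
measurement chain under its own assumptions, not robustness to every
failure mode of real tissue.

## Analysis chain

**Projection.** Per-pixel max (default), mean or sum over the first
*N* = 15 planes; the represented depth is N × z-step = 10.2 μm.

**Nucleus segmentation.** Gaussian smoothing (σ = 1 μm) → global Otsu →
Euclidean distance transform → peak markers (minimum separation 3 μm) →
watershed, then an inclusive projected-area filter and sequential
relabeling. Otsu's bin edges scale linearly with intensity, so labels are
invariant to a global intensity scale. A blank plane yields an empty
label map. The original protocol used a learned instance segmenter; this
classical pipeline is deterministic and dependency-free, and the function
signature is the swap-in point for a learned model.

**Area versus volume filtering.** The protocol phrase "volume of the
signal" is interpreted as projected area in μm², since filtering happens
after projection; this is the only reading consistent with a 2-D label
map.

**Reporter colocalization.** The reporter plane is smoothed identically
and thresholded; when no manual minimum intensity is supplied, Otsu
stands in for the user's signal-versus-background judgement. A nucleus is
reporter-positive when ≥ 50 % of its pixels fall in the mask (majority
overlap; the protocol states colocalization without a criterion).

**Marker classification.** Each nucleus is dilated with a disk of
⌈1 μm / pixel⌉ pixels (ceiling, so the stated radius is never
under-dilated). Background is the mean of the darkest *p* = 1 % of
pixels — "the minimum signal" read as a robust percentile rather than the
single minimum pixel, which would be noise-fragile; the definition
reduces to the minimum as p → 0 and to the global mean at p = 100.
Calls are strict `meanIntCor > threshold`; thresholds are user-supplied
or, by default, Otsu over the per-cell meanIntCor distribution (sensible
only when both positive and negative cells are present in the scene).

**Densities.** `n / (ROI area × depth) × 10⁹` cells/mm³ with depth =
planes used × z-step. The tissue-imaging conversion from projected counts
to volumetric density is not uniquely determined (section thickness vs
imaged depth), so absolute densities are treated as internally
consistent quantities; ratios and percent reductions are the comparable
surface.

**smFISH.** The probe plane is median-background-subtracted and
normalized to its maximum (making detection scale-invariant), then passed
to scale-normalized LoG blob detection with σ = 0.35 μm. Each blob's area
is the connected support at half its local peak; brighter blobs claim
pixels first, so overlapping supports never double-count surface, and the
total assigned surface never exceeds the total detected surface. A
punctum is credited to the nucleus containing its centroid (strictly
inside by default; an optional assignment radius expands labels).
Expression is called when the per-nucleus total surface strictly exceeds
1.5 μm². Co-expression percentages are reported per scene and pooled
over scenes (both conventions appear in practice; per-animal SEM uses
the per-scene values).

**Morphometry.** Rolling-ball background subtraction is grey-scale
opening with a flat disk; when the requested radius reaches the image
diagonal the opening equals the global minimum and is computed
analytically (this also avoids out-of-bounds reads observed in scipy's
morphology for footprints much larger than the image). Band thickness is
the per-column FWHM of the smoothed (σ = 2 px) vertical profile — the
longest run of pixels above half the column's peak-over-baseline —
aggregated as the median over columns; the criterion is relative, hence
scale-invariant, and where in the band a manual measurement would have
been taken is not recorded, so the median is a robustness choice. A
`manual_line` mode measures the distance between two user points,
mirroring the manual protocol. Raw integrated density is the ROI
intensity sum divided by ROI area in μm².

**Statistics.** The unit of replication is the animal (scene in
synthetic mode), never the individual cell. Welch's t statistic and the
Welch–Satterthwaite df are computed from their defining formulas with the
two-sided p from the t distribution; with zero variance in both groups,
equal means give t = 0, p = 1, and unequal means are an error. Percent
reduction is kept at full precision and rounded only for display. No
multiple-testing correction is applied, and the report header says so.

## Study conditions and problem sizes

The recovery studies use: 5 scenes per group of 200 × 200 × 10.2 μm at
41.2 vs 13.9 × 10⁴ cells/mm³ for the density-reduction study; 5 duplex
smFISH scenes of 150 × 150 × 10.2 μm at 30 × 10⁴ OPC-like cells/mm³ per
co-expression fraction (0.3/0.5/0.7), with the lineage probe expressed by
90 % of OPC-like cells and sparse (30 %) target expression in
neuron-like cells; 3 band scenes per group at 144.6 vs 23.6 μm; and
10,000 null replicates at n = 5 per group for the Welch calibration.
These sizes make each cohort's sampling error comfortably smaller than
the tolerance being tested while keeping a full run in tens of seconds.

## Known limitations

- The classical segmenter under-splits heavily overlapping projected
  nuclei; the generator's hard-core spacing keeps scenes inside its
  operating regime, as the original learned-segmenter protocol assumed.
- Otsu-derived default thresholds (reporter, markers) require both
  populations to be present in the field of view.
- Blob detection thresholds are relative to the brightest punctum in the
  plane; a single extremely bright outlier would mask dim puncta.
- Expressing cells with unusually few puncta can fall just under the
  1.5 μm² boundary, giving a small (1–3 point) downward bias in recovered
  co-expression percentages.
- Puncta are assigned by centroid containment only; puncta straddling
  the nucleus boundary go to whichever side their centroid lands on.
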