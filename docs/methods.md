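# Methods

## Problem and measurement model

Somatic homolog pairing holds homologous chromosomes in close register in
interphase nuclei; in *Drosophila* cell culture it is robust enough that a
FISH probe against a pericentromeric satellite repeat usually lights up as
a single focus per nucleus even in a largely tetraploid line. RNAi
knockdowns that loosen pairing increase the number of foci per nucleus and
the distances between them; knockdowns that enhance pairing (or drive
nonhomologous coalescence of heterochromatin) do the opposite. The package
turns single-section, two-channel FISH images of a 384-well screen into
per-nucleus and per-well pairing metrics and plate-normalised hit calls.

A nucleus is called **paired** for a locus when it shows one FISH signal,
or when the centre-to-centre distances between all pairs of its signals
are ≤ 1.0 µm (`ScoreParams.pairing_threshold_um`). Signals of the two
channels target nonhomologous loci, so cross-channel pixel overlap is a
readout of heterochromatin **clustering**, not pairing. Nuclei with no
signal are counted in the "0" bin but excluded from the paired
denominator by default: a missing signal is a detection failure, not
evidence of unpairing (`include_zero_focus_in_paired` restores them).

## Pipeline stages and the parameters that matter

**Segmentation** (`pairfish.segment`). The DAPI plane is smoothed
(Gaussian, σ = 2 px), background-corrected (white top-hat, disk radius
50 px — larger than a nucleus, so nucleus-scale structure survives), and
thresholded with an iterative Ridler–Calvard/ISODATA fixed point. The
iteration walks the induced histogram split until the split reproduces
itself, so the returned threshold satisfies
T = (mean(x ≤ T) + mean(x > T))/2 exactly; a plain |ΔT| < 0.5 stop can
stall one histogram step short of the fixed point. Components smaller
than `min_nucleus_area_px` (200) are debris. Components larger than
`cluster_area_factor` (1.3) times the reference single-nucleus area are
treated as clusters of touching nuclei and re-split by a watershed on the
smoothed Euclidean distance transform, seeded at regional maxima at least
`seed_separation_factor` (0.5) × expected nucleus radius apart. The
reference area is the **lower quartile** of component areas rather than
the median: when a third of nuclei touch, merged components inflate the
median itself (in simulated wells at touching fraction 0.3 the median
component is ~1.4× a single nucleus, and a median-relative trigger missed
most real pairs), while the lower quartile still tracks the single-nucleus
size. With these defaults, nucleus recovery on the simulated study
conditions is ≥ 99% with mean centroid error below one pixel. Border
components are dropped by default — partial nuclei bias both area and
focus counts.

**Focus detection** (`pairfish.foci`). Each nucleus is analysed on a crop
of the Gaussian-smoothed (σ = 1 px) FISH plane, thresholded at
median + k·SD of the intensities inside the nucleus (k = 2, sample SD, on
the smoothed crop). Pixels must exceed the threshold strictly, so a
zero-variance region yields no foci. Components are kept when their area
lies in [2 px, 0.25 × nucleus area]; the lower bound rejects isolated
noise pixels, the upper bound a nucleus that lights up wholesale.
Centroids are intensity-weighted and reported in µm. Touching spots are
deliberately not re-split: with component-based detection, two spots merge
once their separation drops below roughly 5 spot-sigmas, and a merged
signal is exactly what the pairing readout treats as paired.

**Scoring** (`pairfish.score`). Signal counts are binned 0/1/2/3/4/5+.
Per-nucleus inter-signal distance pools every unordered pair among the
union of both channels' foci by default (`distance_pool`;
`cross_channel_only` restricts to between-channel pairs). The distance
histogram uses 0.5 µm bins to 4 µm plus an open terminal bin; the
"far" fraction (> 4 µm) is computed over nuclei with exactly two foci.
Nuclear "volume" is the sphere-equivalent of the 2-D area,
(4/3)π(A/π)^{3/2}, and is labelled a proxy throughout — the screen
acquires single sections, not stacks. The large-nucleus cutoff is the
95th percentile (linear interpolation between order statistics) of
pooled negative-control nuclear areas, flagging at-or-above.

**Screen statistics** (`pairfish.screen`). Plate z-scores use the plate
mean and sample SD over library plus negative-control wells; positive
controls and blanks carry known effects and are excluded from the
statistics (configurable) though still scored. Primary calls require the
criterion in both replicate plates — that duplication, not a
multiple-testing correction, is the screen's false-positive control. The
multi-focus route accepts a hit when the same bin k ∈ {2,3,4} reaches
z ≥ +2 in both replicates. Validation and distance-shift tests use
Welch's t (statistic and Satterthwaite df computed in-package, p from the
t distribution); a pooled-variance variant is available. Both tests gate
on direction: a significant shift the wrong way never validates.

## The synthetic-data generator

`pairfish.simulate` emulates the screen's acquisition: one optical
section, 768×768 px at 0.2 µm/px, ~50 nuclei per field. Nuclei are
filled ellipses (projected radius 4.5 ± 0.5 µm, ellipticity ≤ 1.2,
Gaussian-blurred edges, DAPI amplitude/noise giving SNR 10); 30% are
placed touching a neighbour at centre distance 1.4–1.8× the mean radius,
which is what exercises the watershed; 5% are polyploid with double
area. FISH spots are 2-D Gaussians (σ = 0.2 µm, amplitude 30× the noise
SD) truncated at 3σ over a flat background with additive Gaussian noise.
Per channel, a nucleus is paired with probability 0.8 (channel A) or 0.7
(channel B) — matching the screen-average single-signal rates of the two
loci; a paired nucleus shows one merged spot with probability 0.95, else
two spots at a separation drawn uniformly in [0.3, 0.95] µm; an unpaired
nucleus shows two spots at Uniform[1.5, 4.5] µm, which puts roughly 5% of
two-signal nuclei beyond 4 µm, the order observed in untreated controls.
Conditional on both channels showing single merged spots, the two
channels colocalize with probability 0.4.

Design choices worth stating:

- **Ploidy does not change the signal count by default.** Pairing
  accommodates extra chromosome copies, and empirically signal count and
  nuclear volume are uncorrelated; doubling counts for polyploid nuclei
  would build a size–count correlation into the truth and contradict the
  independence the scoring stage is required to preserve.
  `polyploid_foci_factor=2` restores a count increase if wanted.
- **Disjoint chromatin territories.** Spots are placed inside their own
  nucleus's (shrunken) ellipse and outside every neighbour's (expanded)
  ellipse. Overlapping ellipses are a rendering simplification of
  touching cells; without this constraint a spot planted in the overlap
  lens is claimed by the wrong side of the watershed split and shows up
  as a spurious extra focus in the neighbour.
- **Pairing state is drawn separately from spot placement.** Cross-channel
  collisions (outside planted clustering) are resolved by re-placing
  positions only; re-drawing the state on collision measurably biased the
  realised pairing fraction upward, because unpaired two-spot geometries
  collide more often.
- Per-well seeds derive from SeedSequence(master, crc32(plate),
  crc32(well)): wells are independent but bit-reproducible, and replicate
  plates simulated from different master seeds share the planted effect
  map but not the rasters.
- The screen-level simulator draws per-well pct_single directly
  (baseline 80, between-well SD 3 percentage points, planted offsets) for
  power studies of the hit-calling machinery, where tens of thousands of
  wells are needed and rendering images would add nothing.

What the generator does **not** emulate: optics PSF structure beyond a
Gaussian, 3-D stacks, photobleaching, illumination gradients, cell-cycle
structure, debris/apoptotic nuclei, and intensity variation between
nuclei. Passing the recovery tests therefore shows the algorithms are
correct under the stated measurement model, not that the defaults are
tuned for any particular microscope's data; on real images the
segmentation and detection parameters are the knobs to revisit.

## Numerical conventions

- Coordinates in tables are µm, origin at the top-left pixel centre,
  x along columns; pixel indices 0-based; intervals half-open.
- Percentile convention: linear interpolation; the large flag is
  "at or greater".
- Sample (n−1) SD everywhere a spread is estimated.
- Degenerate inputs raise typed errors rather than returning defaults:
  single-intensity histograms, sub-2-pixel nuclei, zero-SD plates,
  both-constant-unequal t-test samples. An empty foreground is a valid
  empty well, not an error; the plate runner logs and skips failing
  wells.
- Images are written as float32 multi-page TIFF; tables as TSV with a
  fixed column order and %.6g floats, which is what makes end-to-end
  reruns byte-identical.

## Benchmark problem sizes

The recovery benchmarks (`pairfish.evaluation`, exercised by the test
suite and `scripts/acceptance.py`) use 20 wells (~1000 nuclei) for
segmentation, pairing-fraction, and independence checks; 10 wells
(~500 nuclei, all paired nuclei merged so every planted separation is
resolvable) for exact focus-count recovery; 100 runs of duplicate
384-well screens for hit-calling power/specificity; 1000 histograms for
the threshold oracle; and 10,000 null simulations for Welch calibration.
These sizes give the binomial tolerances quoted in the tests while
keeping a full run to a few minutes on one CPU.

## Known limitations

- Single-section volumes: the sphere-equivalent proxy understates true
  volumes of flattened nuclei; only its ordering matters for the
  large-nucleus flag.
- Component-based spot detection cannot resolve separations below ~5
  spot-sigmas (~1 µm at the default optics); such pairs read out as one
  focus, which is consistent with the ≤ 1 µm pairing rule but means
  "exact count" recovery is only meaningful for resolved geometries.
- The plate z-score assumes hits are rare; plates where a large fraction
  of wells carry strong effects inflate the plate SD and compress z
  (visible already with 2 strong hits in a 10-well toy plate).
- No gene-level aggregation across amplicons, no ortholog mapping, no
  marker-channel (mitotic-index) classification.
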