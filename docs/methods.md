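# Methods

## The measurement problem

AFM topographs of chain-like polysaccharides give a 2D grid of heights
(nm) in which molecules appear as narrow ridges a few nm tall on a
scanner-bowed, film-covered background. The quantities of interest are
per-molecule: height above background (the proxy for diameter, since tip
convolution inflates lateral width but not crest height), contour length,
bending angles, the angle at which two chains complex at a junction, and
the arc-length period of rope-like height alternation in intertwined
chains — and, pooled over a survey, their population distributions.

## Pipeline

### Flattening

Each scan row is fitted with a polynomial (order 3 by default, stored in a
scaled column coordinate for conditioning) and the fit subtracted. Fitting
through molecules biases the background upward under them, so flattening
is two-pass: an all-pixel fit, a provisional object mask at the
segmentation threshold on the residual, and a refit excluding those
pixels. A row whose background falls below 20 % of pixels (or below
order+1 points) aborts with an error naming the row. The flattened frame
is anchored so the background mean is exactly zero; all reported heights
are relative to it. Flattening is idempotent to < 1e-6 nm.

### Segmentation and skeletons

Foreground is `height >= 0.2 nm` (inclusive; the protocol specifies only
a minimum), 8-connected components below 20 px discarded. Skeletons are
topology-preserving thinning per component, with spur branches under 5 px
pruned and redundant staircase diagonals removed from the adjacency graph
so corners do not read as junctions. Lengths along pixel paths use the
standard √2 diagonal correction; a path's "principal" route is the
maximal-geodesic endpoint-to-endpoint path. Cyclic skeletons without
endpoints are flagged as rings and excluded from length statistics.

### Chain extraction

With a film background of 0.6 nm RMS, a 0.2 nm threshold necessarily
admits broad background excursions that merge with molecules into common
components; the original protocol resolved this by selecting chains by
eye. The automated equivalent exploits scale separation: molecules are
narrow ridges (~20 nm lateral FWHM) while film undulations are broad
(~30 nm correlation length), so *ridge contrast* — height minus a median
filter slightly wider than the molecule (9 px at 10 nm/px) — passes
molecules and suppresses film. Chain support is a hysteresis threshold on
that contrast (low 0.7 nm for continuity, seeds at 1.5 nm), intersected
with the 0.2 nm mask; pixels above 3.5 nm (≈1.5× a typical single chain)
are support on absolute height alone, because where chains pile up at
crossings the thin-ridge background model breaks down. Short gaps where
film interference locally depresses a molecule's contrast are bridged by
morphological closing with oriented line segments (11 px, 8 orientations),
keeping only fills that reconnect two distinct components — a fill
touching a single component would round the inside of a bend and chamfer
the skeleton through it.

The support skeleton is decomposed by iteratively peeling principal
paths, so every arm of a crossing is traced; peeled arms are flagged and
kept out of single-molecule statistics (they are truncated molecules).
A traced path qualifies as a chain if it is ≥ 180 nm long (the shortest
chain the reference survey reports; shorter candidates are
indistinguishable from film flickers at this pixel size), has median
ridge contrast ≥ 1.5 nm, spends ≤ 20 % of its length below the low
support level (rejecting molecule–film–molecule hybrids), and has median
height ≥ 1.2 nm. Junctions are counted as *molecular* only when at least
three incident branches carry median ridge contrast above the chain gate;
degree-3 skeleton nodes made by film spurs are tracing noise and must not
disqualify a chain from the single-molecule pool.

### Morphometry

*Profiles* sample the flattened map at each skeleton pixel (pixel-centre
values, no interpolation), with geodesic arc positions.

*Peaks*: local maxima strictly above 4 nm with a minimum arc separation
(20 nm at the operation level; the pipeline default is 40 nm, safely below
the shortest plausible rope period, because background noise on a broad
crest otherwise splits it into multiple counts). Spacings are consecutive
differences of peak positions.

*Bending angles*: at each candidate vertex, straight directions are fitted
(total least squares) to the two flanking 50 nm windows; the interior
angle is 180° minus the turn. Detection runs on coordinates smoothed over
5 px and keeps local minima of the angle with deviation ≥ 15°; each
detection must persist when re-measured at 3× the window, because a
molecular bend is scale-free whereas skeleton wobble lives at the film
correlation scale. The reported angle is re-fitted with arms spanning
[20, 100] nm from the vertex — arms touching the vertex average over the
rounded raster corner and read too straight. The pipeline additionally
drops bends whose vertex neighbourhood lacks molecular ridge contrast
(a flex measured across a bridged gap is a tracing artifact). On
constructed vertices the estimator is within 2° across 90–165°.

*Complexing angles*: junction nodes within 5 px merge into one region
(thinning splits an X into two nearby Ys). Incident branch tangents are
fitted over [20, 70] nm from the region — the same gap rule as bends,
since merging ridges distort the raster skeleton near the junction — and
branches below the ridge-contrast gate are excluded. Three branches: the
most antiparallel pair is the through-chain, and the angle between the
terminating branch and that axis is reported; four branches: the pairing
maximizing antiparallelism defines two chain axes. In an unoriented image
the supplementary pair {θ, 180−θ} cannot be disambiguated, so the obtuse
member is reported by convention.

*Linkage*: a junction-free chain with ≥ 3 qualifying peaks is rope-like;
a chain elevated above 1.6× the median single-chain height for ≥ 50 nm of
arc is parallel adherence; a junction chain reaching that level over a
shorter run is an overlap (height roughly doubles where one chain lies
across another); otherwise isolated.

### Population summary

Heights (all skeleton pixels) and lengths are pooled over complete single
molecules only — isolated, junction-free, not peeled — since assemblies
inflate heights and truncated arms deflate lengths. Heights get a
log-normal fit, lengths a Gaussian; both by maximum likelihood, which is
histogram-bin independent, with the histogram R² (fit density integrated
over the same bins) reported separately. The log-normal is parameterized
internally by (µ, σ) of the log; reported mean/sd are arithmetic. Chains
longer than 2 µm stay in the statistics but are dropped only from the
length histogram display. Chain lengths use the smoothed-coordinate
contour length (moving average over 5 px, ends linearly extrapolated so
straight paths keep their exact length): the raw √2 lattice metric
overestimates oblique curves by up to ~8 %.

## Simulator

Backbones are straight segments between Poisson-process bend events
(default rate 1/400 nm⁻¹), bend interior angles drawn from N(127.8°,
25.6°) clamped to (60°, 179°) to keep rasters traceable, and total length
from N(640, 360) nm truncated at ≥ 100 nm. A crossing molecule (default
probability 0.3) is anchored at a random interior point of a previous
molecule with tangent-to-tangent angle drawn from N(114.2°, 36.3°)
(same clamp). Peak heights are log-normal with arithmetic mean 2.3 nm and
sd 0.5 nm; a rope-mode fraction (0.2) instead modulates height
sinusoidally between 3 and 6 nm with period N(115.8, 29.2) nm (≥ 40 nm)
and random phase. Molecules render as Gaussian-cross-section ridges
(FWHM 20 nm), composed by maximum within a molecule (a rod has uniform
height) and additively between molecules. The background is correlated
Gaussian film noise (RMS 0.6 nm, correlation 30 nm) plus a per-row cubic
bow of ~10 nm so flattening is exercised. Optional tip broadening is
grayscale dilation with a spherical cap — widens, never raises. Every
draw comes from one `numpy` generator seeded by the scene seed; identical
specs give bit-identical images. Twelve molecules per 512² frame keeps
occlusion realistic without saturating the field.

What the simulator does *not* emulate: scan-line noise, scars, drift and
creep, tip changes mid-scan, true 3D intertwining of rope strands
(modelled as a single modulated backbone, sufficient for the peak-to-peak
detector), molecule flexibility between bend events (worm-like-chain
wiggle), or surface density correlations. Recovery on these scenes
therefore demonstrates correctness of the measurement chain under the
stated noise model, not robustness to every instrumental artifact.

## Expected biases under the default conditions

Truncating lengths at 100 nm makes the true mean of generated contour
lengths ≈ 690 nm rather than 640 nm, and the 180 nm minimum chain length
excludes the shortest tail; skeleton end erosion and end trimming act the
other way. The measured mean lands near the nominal 640 nm, but this is a
partial cancellation of known effects, quantified per run by the recovery
report (`analysis/03_recovery.py`). Detected bends exclude deviations
under 15°, so the detected-bend population mean sits slightly below the
generating 127.8°; the obtuse reporting convention folds acute crossing
draws upward. Both effects are visible in, and bounded by, the acceptance
tolerances.

## Degenerate inputs and numerical choices

Non-finite heights, ragged grids, and missing pixel size are rejected at
read time; grids smaller than 16×16 are refused. Zero-variance samples
raise a degenerate-fit error; non-positive values are invalid under the
log-normal. An empty segmentation is valid (empty outputs, exit code 2 in
the CLI). Ring-shaped skeletons are excluded from length statistics with
a logged warning. When a run yields no complete single molecule, the
linkage classifier falls back to the median height of all chains; with no
height reference at all, elevation-based classes are not assigned.

## Limitations

The chain extractor assumes the film's correlation length exceeds the
molecule width; a background textured at the molecule scale would defeat
the ridge-contrast gate. Bundles of more than two chains, sub-pixel ridge
localisation, and persistence-length analysis are out of scope. Angle
estimates assume branches are locally straight over the fitting window;
strongly curved arms bias them. The 0.2 nm threshold and all window sizes
are configuration, not constants, and should be recalibrated for pixel
sizes far from 10 nm/px.
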