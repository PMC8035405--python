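# Methods

This note documents the models and procedures implemented in `osteomix`,
the parameter choices that matter, what the synthetic generator does and
does not emulate, and the numerical conventions that make results
reproducible.

## Cell mixture index

**Definition.** The CMI of a two-color point set is the area under the
normalized impurity curve of a Ward agglomeration. Each foreground pixel of
the binarized cyan (osteoblast) and red (osteoclast) channels is a point;
clustering runs on coordinates only, so color never influences the merge
order. At cluster count k the size-weighted two-class Gini impurity
I(k) = Σ_c (n_c/N)(1 − p²_cyan,c − p²_red,c) is divided by the whole-set
impurity g_total = I(1), and the curve is integrated (trapezoid rule) over
merge progress x = (N − k)/(N − 1).

**Why these conventions.** Three choices are open in principle and fixed
here deliberately:

- *Normalization by g_total* makes the curve end at exactly 1 regardless of
  the color balance of the field, which is what confines the index to
  [0, 1]: without it, a field that is 90/10 cyan/red could never exceed
  0.18. A single-color field has g_total = 0 and the CMI is undefined
  (reported as null with a reason, never 0).
- *Merge progress as the abscissa* (rather than merge cost/dendrogram
  height) is bounded by construction; cost-based abscissae are unbounded
  and scale-dependent and could not guarantee a 0–1 range.
- *Trapezoidal integration* treats the curve as piecewise linear between
  the N evaluated cluster counts, which is exact for the curve as defined.

These conventions give the closed-form anchor values the tests pin down:
any bichromatic 2-point set scores exactly ½ (curve (0,0)→(1,1) regardless
of distance); the segregated quartet {(0,0),(0,1)} cyan / {(10,0),(10,1)}
red scores 1/6; the interleaved unit square scores 2/3 under the package's
tie-breaking.

**Ward implementation.** Greedy global-minimum agglomeration on the
centroid form of the Ward cost, Δ(A,B) = |A||B|/(|A|+|B|)·‖μ_A−μ_B‖².
Cost ties are broken toward the lexicographically smallest pair of cluster
creation indices (singletons 0..N−1, merge t creates id N+t), which makes
the merge sequence deterministic even on exactly symmetric configurations.
The implementation keeps a full cost matrix and recomputes one row per
merge from the stored centroids — O(N²) memory, O(N³) worst-case time but
vectorized — and is checked merge-for-merge against a naive
recompute-every-pair oracle. A nearest-neighbor-chain algorithm would be
asymptotically faster but does not produce merges in global cost order,
which the tie-break contract requires.

**Subsampling.** Tiles can hold tens of thousands of foreground pixels;
clustering caps the point count (default 2,000) by stratified uniform
subsampling per color, preserving the color proportions to within one point
with a seeded RNG. The cap, seed, and an exact no-subsampling mode are
exposed. Sweep-scale experiments use a cap of 300, where a per-tile CMI
takes ~50 ms.

**Preprocessing.** Mosaics are stitched row-major, optionally
gamma-corrected (monotone power law within the observed dynamic range;
default γ = 1 since no specific value is prescribed for the original
acquisitions), thresholded with Otsu's method *globally per channel over
the whole stitched image* (not per tile), split into equal tiles (default
4×4 = 16), and each tile is kept only if its red/cyan area ratio lies in
the closed interval [0.5, 2]. Boundary ratios pass; a tile with zero cyan
area has an undefined ratio and fails the filter rather than raising.

**Otsu convention.** 256-bin histogram over the observed min–max range
regardless of bit depth; the threshold maximizes between-class variance,
ties broken toward the lower bin; the returned threshold is the center of
the highest background bin and the mask is `image > threshold` (the same
convention scikit-image uses, which the tests exploit as an independent
cross-check alongside an exhaustive-search oracle). A constant image raises
a degenerate-histogram error. Note that Otsu on heavily unbalanced
histograms (tiny foreground over a wide noise floor) can lock onto the
noise tail; the generator's scenes keep enough foreground for the bimodal
split to dominate.

## 3-D contact analysis

Per channel: four-direction (0°, 45°, 90°, 135°) 3×3 Sobel kernels are
applied within each z-slice and combined as the root-sum-square; the
enhanced image is `raw + α·gradient`, clipped to the input range (α = 0 is
the identity). "Adjusting" raw images to edge-enhanced ones is interpreted
as this additive composition with the weight exposed as configuration
(default α = 1). Additive enhancement necessarily brightens a shell around
each object, so thresholded objects dilate by roughly a voxel per side at
α ≳ 0.5; analyses that need volume accuracy near the exclusion cutoffs
should use small α (the volume-accuracy tests use α = 0, the contact-count
experiments α = 0.5, where dilation is harmless because placements keep
6 µm clearances).

Objects are 26-connected components of the per-channel Otsu mask. Cyan
objects with volume ≤ 125 µm³ and red objects with volume ≤ 1000 µm³ are
excluded (strict ≤: boundary objects drop). Exclusion only flags table rows
— it never alters retained objects' voxels. Surface areas are estimated by
counting exposed voxel faces weighted by their physical areas (anisotropic
voxels supported); the estimate is exact on axis-aligned boxes
(2(ab+bc+ca) scaled by face areas), which the tests verify in closed form.
Face counting overestimates smooth-surface areas by up to ~1.5× (the usual
staircase effect) but is deterministic, mesh-free, and consistent across
conditions, which is what a normalization denominator needs.

The contact channel is the voxelwise intersection of the two retained
masks; its 26-connected components are contact events, each attributed to
the (cyan, red) object pair covering most of its voxels. Counts are
reported raw and per µm² (and per 1000 µm²) of total retained surface per
channel. Time-lapse volumes are analyzed per frame; no 3-D object tracking
is attempted since in-vivo contact counts, not durations, are the readout.

## 2-D contact-duration tracking

Frames are binarized per channel (Otsu), labeled with 8-connectivity, and
filtered by physical area with *retention* semantics: green ≥ 100 µm² and
red ≥ 1000 µm² are kept (boundary retained — note the deliberate asymmetry
with the 3-D *exclusion* rules, both implemented exactly as stated for
their respective assays). Objects acquire persistent identities by greedy
maximal-overlap matching between consecutive frames. Contacts are
8-connected components of the green∩red overlap, attributed to a (green,
red) pair; a track spans the frames its pair stays in overlap, with up to
`max_gap` missing frames tolerated (default 0 — strict contiguity; exposed
because imaging dropouts are common). Pair identity, not overlap-component
identity, defines the track, so two cells sliding along each other remain
one contact. Duration is (end − start + 1) × frame interval. The summary
reports per-track durations, mean, median, and the fraction of tracks at or
above a configurable "long contact" threshold (default 60 min, motivated by
control cocultures where contacts generally last under an hour).

## Synthetic scene generator

**What it emulates.** The acquisition geometry of tiled intravital skull
imaging: 16 contiguous 512×512 fields stitched 4×4 (configurable), z-stacks
at 5-µm vertical steps (31 slices by default, ~150 µm of depth), and
coculture-style time-lapse frames at a configurable interval. Osteoblasts
are many small blobs (default 240 cells, r ≈ 7 µm), osteoclasts fewer and
larger (default 120 cells, r ≈ 18 µm) — densities and radii are free
parameters chosen once to resemble published mosaics, since no acquisition
pins them.

**Mixing mechanism.** Both colors draw cells from paired cluster centers:
blue centers are uniform with a minimum spacing of 8 cluster-SDs, and each
red center sits at displacement D·(1 − λ) from its blue partner with
D = 4·cluster_sd and a random direction. λ = 0 gives fully segregated
centers, λ = 1 identical centers. Cell scatter around its center is a
truncated Gaussian (capped at 1.9 SD), which together with the blue-center
spacing guarantees — in mosaics roomy enough to honor spacing and margins —
that at λ = 0 no red cell lies within 2 SD of any blue cluster center. Mean
nearest blue-neighbor distance from red objects decreases monotonically in
λ (a generator-level invariant the tests check over 20 seeds).

**Rendering.** Blobs are logistic radial-falloff profiles whose
half-maximum sits on the nominal disk/ellipsoid boundary with a sharp edge
(width r/12 in 2-D, 6 % of the normalized radius in 3-D), over a constant
background (0.08) with additive clipped Gaussian noise; blob amplitude is
snr × background. The sharp edge keeps Otsu-recovered areas within ~5 % of
truth at high SNR while still exercising non-trivial thresholding. 3-D
truth volumes are voxel-count-exact: each blob is rasterized to
round(V/voxel volume) voxels (the closest voxels in the normalized
ellipsoid metric, ties broken lexicographically), and the same function
re-renders masks from the truth table, making truth-mask consistency exact
by construction.

**Scripted contacts.** Volumes can place a requested number of blue/red
pairs overlapping by a set margin (default 3 µm) with everything else kept
≥ 6 µm apart, so the truth contact table is exhaustive. Time-lapses accept
episode scripts (pair, start frame, end frame): during an episode the red
partner is pinned against its blue partner (the pair is shifted inside the
frame if the pin would cross the border); outside episodes all objects
random-walk (step SD 2 µm) under a pairwise repulsion that restores a
16-µm clearance between any two objects — wide enough that the soft
intensity tails of neighbors cannot bridge above the Otsu threshold and
merge segmented objects. The relaxation overshoots its target by 2 px so
repulsion chains converge; if it has not converged after 25 sweeps the
offending movable object is re-placed by rejection sampling. Contradictory
scripts (one red object owed to two partners in overlapping frames, or two
overlapping episodes for one pair) are rejected at configuration time.

**What it does not emulate.** Photophysics (bleaching, scattering, depth
attenuation, the SHG bone-surface channel), bone-surface geometry, cell
morphology beyond blob scale separation, and stitching artifacts or
inter-field illumination differences. Passing the recovery tests therefore
shows that the *algorithms* are correct on data obeying their stated
assumptions — not that real tissue meets those assumptions.

## Experiments and problem sizes

`run_cmi_experiment` sweeps λ ∈ {0, 0.25, 0.5, 0.75, 1} × 20 seeds on a
scaled mosaic (2×2 fields of 256², ~100 cells, cluster SD 28 µm, point cap
300, tile grid 2×2) chosen so a 100-scene sweep finishes in minutes on one
CPU; the segregation-vs-intermingling contrast does not depend on mosaic
extent. It reports per-λ mean CMI over passing tiles and the Spearman rank
correlation between λ and those means (also the per-scene correlation,
which is noisier by construction). `run_contact_experiment` scripts 2–4
contacts into 180×180×14 volumes (2-µm z-steps) and two 3-frame episodes
into 8-frame, 220×220 time-lapses, then measures exact count and
(start, end) recovery. Both derive all randomness from one named seed via
`SeedSequence` spawning, so a rerun from a saved config reproduces every
table bit-identically.

## Numerical conventions and edge cases

- Pixel coordinates are 0-based (row, col) with pixel centers at integers;
  clustering runs in pixel units (in-plane isotropic); physical units enter
  only through calibrated areas/volumes/surfaces.
- Impurity is updated incrementally across merges (replace two cluster
  terms by one), so curve construction is O(N) after clustering; tiny
  negative round-off is clipped to 0.
- Degenerate inputs: constant images raise in Otsu (except per-frame
  2-D segmentation, which warns and retains nothing, since one dead frame
  should not abort a time-lapse); single-color point sets raise an
  undefined-CMI error; an empty track list yields a null summary, not an
  error; tiles failing the ratio filter appear as null rows with a reason.
- Known limitations: Otsu mis-thresholds extremely unbalanced histograms;
  additive Sobel enhancement dilates object boundaries (see above); greedy
  overlap tracking can fragment identities under very large inter-frame
  displacements; CMI values depend mildly on the subsampling cap at small
  caps.
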