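# Methods

## Scope and data model

`plexcell` operates downstream of image acquisition and nuclei segmentation.
Its inputs are (a) a co-registered multichannel stack ordered
`[DAPI, AF_TRITC, AF_Cy5, marker_1 … marker_K]` plus an integer nuclei label
image, or (b) a single-cell expression table (CSV) with per-marker means, QC
features, coordinates and core ids. Stitching, registration, flat-field
correction and the segmentation model itself are upstream concerns; a naive
Otsu+watershed segmenter (`features.segment_nuclei_otsu`) exists only as a
convenience for synthetic images.

All inter-stage state is plain CSV/JSON. Coordinates are 0-based pixels
internally; micron columns are derived via the pixel size (default 0.23 µm,
the resolution class of current seqIF scanners).

## Background correction and feature extraction

Each marker plane is corrected pixel-wise against the autofluorescence plane
acquired in the same fluorescence channel before the marker's cycle:
`corrected = max(marker − AF, 0)`. Zero flooring is applied because residual
negative differences are noise, not signal.

Cell boundaries are approximated by growing each nucleus 5 px with a
Euclidean-distance (Voronoi-constrained) expansion: a contested pixel joins
its nearest nucleus, so cells never overlap. The cytoplasm compartment is the
expanded cell minus its nucleus — the only construction consistent with a
fixed-radius expansion. Nuclear markers (FoxP3, IDO-1, ki67, CD3, CD4, CD8 in
the shipped lung-TME panel) are averaged over the nucleus; all others over
the ring, falling back to the whole cell when a ring is empty. Area is
nucleus pixel count × (pixel size)²; circularity is 4πA/P² with the perimeter
taken from the nucleus boundary contour length (values can slightly exceed 1
on small rasterized regions; the table invariant allows 1 + ε).

For artifact screening (below), raw (non-background-subtracted) marker means
are measured over the *nucleus* mask for every marker regardless of
compartment: erythrocyte-like objects are bright in the object mask itself,
not in a surrounding ring.

## Two-stage QC

**Stage 1 — artifact clusters.** Erythrocytes and similar autofluorescent
objects are bright in every acquisition channel, including the unstained AF
planes, but carry only faint DAPI. Cells are clustered (Leiden, resolution
1.0, kNN graph with 40 neighbors) on median/SD-normalized raw marker +
AF-channel means (DAPI excluded), and a cluster is flagged when its mean
exceeds the global mean in at least a fraction `f` of channels (default
`f = 1.0`, i.e. all). The fraction is configurable, and
`flag_artifact_clusters` returns a per-cluster review table so a user can
curate the flags interactively instead of applying them automatically.

**Stage 2 — quantile filter.** Four features — detection probability, DAPI
mean, nucleus area, circularity — are each cut at their empirical 5% lower
quantile; area additionally at its 0.1% upper quantile. A cell is removed if
*any* cut marks it (union). Inequalities are strict and ties at a cutoff are
kept, so the removed fraction never exceeds the nominal one. Published
per-dataset cutoffs (e.g. detection probability 0.65) are realizations of
these quantile rules on a specific cohort, not constants; a
`fixed_cutoffs` override reproduces that fixed-cutoff mode.

Every stage emits a `FilterStage` whose accounting is validated
(`n_input − n_removed = n_output`, disjoint removals, chained totals).

## Automatic marker gating

Each marker column is winsorized at the upper 0.01% quantile (a handful of
saturated pixels would otherwise dominate the scale) and Z-normalized. On a
smoothed histogram density of the Z column the estimator finds the
lowest-intensity local maximum — the background population — measures its
full width at half maximum by linear interpolation of the half-maximum
crossings, converts via the Gaussian identity σ = FWHM/2.355, and sets the
positivity threshold at peak + 6σ. Six background sigmas put the expected
Gaussian false-positive rate near 10⁻⁹ while staying below any genuinely
expressing population; the multiplier is configurable (`n_sigma`).

Numerical choices:

- **Binning.** Freedman–Diaconis bin width computed on the sub-median half
  of the sample. The background is the majority below the median whenever
  positives are a minority, so this keeps the background peak resolved even
  when a strongly separated positive population inflates the full-sample
  IQR; on a pure Gaussian it merely narrows bins by ~0.6×.
- **Smoothing.** Gaussian kernel, bandwidth 2 bins (configurable). The
  implied σ-inflation on a unit Gaussian is ≈0.5–2% depending on sample
  size — within the estimator's stated 5% recovery tolerance.
- **Peak selection.** The leftmost local maximum with height ≥5% of the
  global maximum; lower bumps are treated as noise spikes.
- **Peak refinement.** When both half-maximum crossings exist, the peak
  position is their midpoint (robust to flat histogram tops); a peak
  truncated at the data edge reflects the available half-width and logs a
  warning.
- **Positivity** is strict (`z > threshold`); a value exactly at the
  threshold is negative.

The fitted `ThresholdModel` enforces `threshold = peak + n_sigma·σ` as an
identity.

## Rule-tree classification

A phenotype ruleset is a binary decision tree over marker positivity
(YAML-serializable, validated at load: unique reachable structure, no
cycles, every referenced marker in the panel). Classification descends the
tree per cell; a missing child yields `Unknown`, so partial trees are legal
and every cell receives exactly one label. Classification is vectorized over
the ≤2^k distinct binary profiles. The shipped lung-TME ruleset encodes a
standard immune-lineage hierarchy (PanCK → CD45 → T/B/myeloid → stromal/
vascular); the tree topology is configuration, not code.

For external probabilistic cell-typers the package prepares inputs with the
arcsinh transform (`arcsinh(x/150)`, the usual cofactor for 16-bit IF mean
intensities) and applies the post-rule that assignments with probability
< 0.5 become `Unknown`. The probabilistic model itself is out of scope.

## Cluster phenotyping

Unsupervised discovery runs Leiden (default resolution 0.8) on the kNN graph
(40 neighbors) of the winsorized, Z-normalized marker space — identical
normalization to the supervised path; DAPI, AF and QC columns are excluded.
The 2D UMAP embedding (min_dist 0.5) is computed only on request and only
for visualization; cluster identities never depend on it. Cluster merging
into metaclusters is explicit configuration with an audit trail;
`suggest_merge_map` offers a Ward-linkage starting point from the cluster
Z-profile matrix, mirroring the manual practice of merging clusters with
analogous expression patterns. Cluster removals (e.g. a morphology-artifact
cluster) flow through the same `FilterReport` machinery as QC. Averaged,
seeded single-cell crops (default up to 2000 per class) give per-class mean
spatial expression images for annotation; edge cells are skipped and
counted.

Note that on strongly separated mixtures Leiden at the default resolution
typically yields *more* clusters than planted populations; recovery of
ground truth is therefore assessed after profile-similarity merging, which
is also the documented analysis workflow.

## Spatial statistics

TMA cores are physically disjoint tissues, so graphs are built per core with
cross-core edges forbidden: a k-nearest-neighbor graph (default k = 6,
Euclidean on generic coordinates) symmetrized by edge union, giving every
node degree ≥ k. Exact-distance ties break toward the lower cell index.

- **Neighborhood enrichment**: the observed shared-edge count for each
  unordered class pair is compared with a null of uniformly permuted labels
  on the fixed graph (default 1000 permutations, seeded);
  z = (obs − mean)/sd. Homotypic pairs are included; zero-variance pairs
  yield NaN with a warning.
- **Interaction matrix**: raw class × class shared-edge counts, each
  undirected edge counted once; unordered-pair sums equal |E|.
- **Co-occurrence**: for anchor class A, target B and half-open distance bin
  (lo, hi], the score is P(label = B | cell at bin-distance of an A cell)
  divided by P(label = B), over (anchor, other) pairs with anchors excluded
  from their own neighbor sets. Curves are computed per core and averaged;
  cores lacking either class are skipped and counted. Under complete spatial
  randomness of labels the score is 1 in every bin, and it is invariant to
  jointly rescaling coordinates and bins. Default bins: equal-width from 0
  to half the core diameter.

## Synthetic tissue phantom

The generators emulate exactly the structure the pipeline stages consume:

- non-overlapping elliptical nuclei (rejection-sampled) in circular cores
  laid out on a grid; DAPI painted in nuclei;
- nuclear vs cytoplasmic marker localization (signal painted in the nucleus
  or the 5-px annulus), phenotype-conditional positive means (default 500
  counts over a 50-count negative background, noise SD 30 ⇒ ~15σ
  separation, above the ≥8σ regime the recovery guarantees assume);
- an all-negative "Other" phenotype and minority positive fractions per
  marker, as on real tissue;
- erythrocyte-like artifacts bright (3000 counts ≥ 5× the maximum phenotype
  mean) in every channel including the AF planes, with faint DAPI;
- per-core Gaussian hotspots per phenotype, so spatial statistics have known
  sign; detection probability a logistic function of nucleus eccentricity
  plus noise, giving the QC filter a meaningful lower tail.

Default sizes (300 cells + 30 artifacts, 768² px, 4 cores) keep the full
pipeline under ~15 s on one CPU; tests scale problem sizes (150–2000 cells,
100–1000 permutations) to keep the suite fast while leaving the estimators
in their asymptotic regime.

The phantom is deliberately not photorealistic: no PSF, no photobleaching,
no segmentation errors, Gaussian noise only, and planted populations are
cleanly separated. Passing tests therefore demonstrate that the machinery is
correct and calibrated — not that real tissue meets the separability
assumptions. On real data the load-bearing quantities are the realized
cutoffs and thresholds, which is why every stage logs them.

## Known limitations

- Thresholds are global per marker; specimen-to-specimen background shifts
  require the per-group refit option (`--per-group`), which assumes each
  group alone satisfies the background-majority assumption.
- The FWHM estimator needs a resolvable background peak; exotic
  distributions (uniform, extreme skew) fail loudly rather than guessing.
- Detection probabilities exist only when the upstream segmenter provides
  them; the image route defaults to 1.0, which neutralizes that QC cut.
- Co-occurrence on very sparse classes produces NaN bins (reported, not
  interpolated).
- The paper-scale TMA headline counts require the original multi-GB image
  and trained segmentation model; the test suite validates behavior on
  phantoms, not those cohort-specific numbers.
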