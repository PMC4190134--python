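# Methods

This note documents the models and procedures implemented in `endoseg`,
the choices made where the design was genuinely open, and what the
synthetic data can and cannot establish.

## The segmentation problem

A specular microscope images the corneal endothelium as a mosaic of
bright, roughly hexagonal cell interiors separated by thin darker
borders, modulated by a smooth intensity drift caused by the superposed
reflections of deeper (darker) corneal layers, and degraded by optical
blur and sensor noise. Segmentation means recovering a closed partition
of the image domain into cells: pairwise-disjoint labelled regions whose
union fills the domain, with a one-pixel contour set separating them.

All three implemented methods share one template — filter, find one
marker per cell, flood a relief with a marker-constrained watershed — and
differ in how markers and relief are built (see the README for the
per-method pipelines). They are deterministic functions of the image and
their control parameters.

### Morphological conventions

* Disks are discrete Euclidean balls `{(dx,dy): dx²+dy² ≤ r²}`; line
  segments are centred Bresenham rasters, point-symmetrized so that the
  erosion/dilation pair forms a true adjunction (openings anti-extensive,
  closings extensive) at every orientation.
* The alternate sequential filter applies closing-then-opening with disks
  of radius 1..order; order 0 is the identity. The ordering is exposed as
  an option (`closing_first`); neither choice protects dark borders from
  the closing at the largest radius, so the filter order effectively
  bounds the border widths that survive filtering.
* All gray-level filters use reflective border handling. Openings and
  closings are computed on a reflect-padded copy and cropped, which keeps
  their order properties valid up to the image frame.
* Segment-opening operators use 8 orientations (22.5° steps) by default;
  measurements on synthetic mosaics showed no benefit from 12.
* The skeleton-pruning step keeps a skeleton pixel iff a segment of length
  `t_s` fits inside the one-pixel tube around the skeleton through it.
  Requiring the segment to fit inside the 1-px skeleton itself would
  erase perfectly straight runs at angles between the sampled
  orientations (a discretization artifact, not a property of the
  continuous operator); the tube absorbs that staircase mismatch while
  still eliminating blobs and spurs smaller than `t_s`.
* The watershed returns labels that fully partition the domain:
  watershed-line pixels are assigned to the nearest region, and the
  published contour set is re-derived from the labels (a pixel is a
  contour pixel iff its label differs from its right or lower neighbour).
* In the Gavet–Pinoli method the final watershed floods the complement of
  the ASF-filtered image (markers still come from the opened distance map
  of the pruned linear contour estimate). Flooding the distance map
  itself was measured to redraw contours midway between skeleton
  fragments instead of on the intensity valleys, roughly doubling ε on
  clean fixtures; the intensity relief is what actually "corrects" the
  rough linear estimate.
* The threshold after the supremum of openings by segments is Otsu's
  automatic threshold, keeping the method's parameter set to
  `{c, t_s, o, s}`.

## Evaluation criteria

Both criteria compare binary contour maps and are oriented as
dissimilarities (0 = perfect) so that all tuning minimises:

* ε with tolerance ρ: normalised symmetric difference after dilating each
  set by the Euclidean disk of radius ρ (realised by thresholding the
  exact Euclidean distance transform, so ρ need not be an integer).
  ε(R,R,ρ)=0; ε is non-increasing in ρ and reaches 0 once ρ covers the
  domain; it is deliberately *not* a metric — symmetry and the triangle
  inequality fail, matching how observers compare drawings. An empty
  candidate scores #R / #(R⊕ρN).
* Figure of merit: 1 − (1/max{#R,#X}) Σ_{p∈X} 1/(1+d²(p,R)); an empty
  candidate scores 1.

The tolerance ρ is selected from repeated drawings of one image by one or
more experts: the mean ε over all ordered pairs of drawings is computed
for each integer ρ and the smallest ρ bringing it under the chosen error
level (0.05 by default) is returned, together with the whole curve.

## Parameter learning

The quality of parameter set p on image I is Q_C(A_p, I) = C(A_p(I), R(I)).
A pipeline failure (no markers, empty border estimate) is charged the
worst finite score (1 for fom, 2 for ε) so grid searches can traverse bad
regions. The best set minimises, over a user-defined grid, the mean, the
trimmed mean discarding the fraction k of *largest* (worst) values
(`floor(k·N)` values; k = 0.5 by default for reported trimmed results), or
the median of Q over the images; at k = 0 the trimmed optimum coincides
with the mean optimum exactly. Ties break to the lexicographically
smallest parameter tuple. K-fold cross-validation shuffles the images
once (seeded), learns on K−1 folds with the mean aggregator and scores the
learned tuple on the held-out fold; the fold's own best achievable mean is
reported alongside and can never exceed the learned score.

## Morphometry

ECD is the number of cells not touching the image frame divided by their
total area in mm²; frame-touching cells are excluded from every index
because their areas and adjacencies are truncated. Polymegathism is the
population coefficient of variation of the included cell areas (a
descriptive statistic of the observed field, hence the population rather
than sample standard deviation). Pleomorphism counts cells with exactly
six neighbours in the region-adjacency graph built from 4-adjacent pixel
pairs with distinct labels — the operational definition of "hexagon-like"
used by specular microscopes. Reports flag ECD below 400 cells/mm² (the
cornea can no longer be kept transparent) and below 1000 cells/mm²
(contraindication for intraocular lens implants).

## Synthetic endothelium model

Cells are the Voronoi regions of seeds on a hexagonal lattice, each seed
displaced uniformly by up to `jitter·a/2` per axis (a = lattice constant,
chosen so the unperturbed hexagon has the requested mean area). One knob
thus spans the clinical continuum: jitter 0 is the honeycomb (100 %
hexagons, area CV ≤ 2 %, discretization only); jitter 0.5 and 1.0 give
area CVs near 13 % and 28 % with hexagon fractions near 95 % and 32 %
(medians over seeds). Rendering assigns the border intensity to the
contour set dilated to `border_width`, the interior intensity elsewhere,
adds a smooth illumination field (two low-frequency sinusoids with seeded
random orientation, phase and wavelength comparable to the field of
view), then Gaussian blur, then i.i.d. Gaussian sensor noise, clipped to
[0, 255]. All randomness derives from the one seed in the spec through
named substreams, so every artefact is reproducible.

Default conditions (chosen once to emulate a low-contrast, noisy clinical
acquisition at ~0.5 µm/pixel): 256×256 px, mean cell area 1500 px²
(≈375 µm², ECD ≈ 2700 cells/mm²), jitter 0.35, border width 4 px, border
100 / interior 140 gray levels, illumination amplitude 30, blur σ = 1.2 px,
noise σ = 25. The cell scale was set so the published tuned parameters of
the linear-structure method ({c, t_s, o, s} = {2, 7, 4, 6}) are
geometrically meaningful: an ASF of order 4 must not erase the borders,
and a 7-px segment must fit a cell edge. The test fixtures additionally
use a "clean" variant (no noise, stronger contrast) representing a
well-acquired image.

### What the synthetic model does not show

The renderer produces uniform cell interiors, a smooth illumination field
and independent pixel noise. Real specular images additionally contain
non-linear dark clutter (intracellular texture, debris), out-of-focus
patches where borders vanish locally, and spatially correlated noise.
This matters for method comparison: on the synthetic model the
interior-maxima markers of the Vincent–Masters and Angulo–Matou methods
are essentially noise-immune (the ASF removes i.i.d. noise long before it
erases borders), so those two methods attain slightly lower tuned ε than
the Gavet–Pinoli method, whose linear-structure detour costs a small
fixed amount here and pays off precisely on the real-image degradations
the model omits. Conclusions about the *ranking* of the methods on
clinical images therefore do not follow from these tests; conclusions
about correctness of each pipeline, of the criteria and of the tuning
machinery do.

## Problem sizes and numerical details

The test suite and the reproduction script run on 256×256 (default) and
64×64 (criteria) images, databases of 10 images, grids of 4–8 points and
5-fold cross-validation; these sizes were chosen so the whole suite
completes in a few minutes on one core while leaving every qualitative
property (partition invariants, oracle equivalences, tuning identities,
fold bookkeeping) at full strength. Brute-force oracles (O(n²) distance
maps, iterated geodesic dilation, explicit offset unions) are kept in the
test tree and never share code with the implementation they check.

Degenerate inputs are errors, not silent results: constant images (no
structure to segment), empty reference contour maps, empty marker sets,
thresholds that erase the border estimate, and domains too small for one
cell all raise with a message naming the offending stage.
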