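# Methods

## Problem setting

Two-channel fluorescence microscopy of vesicle-scale objects (e.g.
integrin- and EGF-positive structures) acquires the channels
sequentially. Between the two exposures, objects move and the optics may
shift slightly, so two structures that travel together need not overlap
in the recorded pixels. Pixelwise colocalization statistics therefore
under-report the biology of interest. `vesassoc` quantifies
*association* instead: the fraction of detected objects in each channel
that have a counterpart in the other channel within a chosen distance,
after compensating a moderate global translation between the channels.

## Spot detection

Each channel is processed independently:

1. **Modal background subtraction.** The most common intensity value
   (mode of the integer intensity histogram) is subtracted and the result
   clipped at zero. The mode is the right location estimator for the flat
   camera background because background pixels dominate the histogram.
2. **Difference-of-Gaussians band-pass**, σ_small = 1.0 px,
   σ_large = 2.0 px by default. These values suit diffraction-limited
   spots a few pixels across; both are configurable. A constant image has
   identically zero response, so a blank frame yields zero objects rather
   than an error.
3. **Thresholding** of the DoG response, Otsu by default with a manual
   numeric override — threshold choice is acquisition-dependent and no
   single automatic rule is universally right.
4. **Size filtering** of 8-connected components: minimum area 3 px
   (fixed-cell mode) or 8 px (live mode, noisier). The filter is defined
   on component *area*, and connectivity matters at these sizes, hence
   both are stated explicitly.
5. **Centroids** are unweighted area centroids of the surviving
   components, in (x = column, y = row) pixel coordinates, sub-pixel
   valued. Intensity weighting was deliberately not used; at these spot
   sizes it changes centroids by far less than the matching distance.

## The PPM association estimator

Given model set *P* (channel 1, n points) and scene set *Q* (channel 2,
m points), the transformation class is pure translation: systematic
rotation or scaling between channels of the same field of view is not
expected, and restricting the class is what makes a global search
tractable and statistically safe.

**Candidate translations.** Every difference vector t = Q[j] − P[i] with
‖t‖ ≤ `max_translation` is a candidate. Pruning candidates to nearby
pairs loses nothing because an acceptable alignment is by definition
moderate; it also keeps the search O(#close pairs) instead of O(nm).

**Matching under a candidate.** P is translated by t; each translated
point is connected to those of its k nearest neighbors in Q (kd-tree
with the sliding-midpoint rule; exact distance ties broken by point
label for determinism) that lie within the matching distance δ. The
maximum-cardinality matching of this bipartite graph is computed with
Hopcroft–Karp. k = 10 by default: a point has at most a handful of
plausible counterparts at vesicle densities, and k only needs to exceed
the local candidate count.

**Acceptance.** A matching M is accepted iff

* |M| ≥ α · min(n, m) — the matching ratio; min() because either channel
  may legitimately contain extra (unique) objects;
* bias(M) = ‖mean over M of (Q[j] − (P[i] + t))‖ / δ ≤ β_max — residuals
  spread in all directions average toward 0, residuals that all point one
  way (the signature of pairing a shifted copy to the wrong neighbors)
  average toward 1;
* ‖t‖ ≤ `max_translation` — a drastic shift means the correspondence was
  found by chance and is not association.

Among accepted candidates the winner is chosen by largest |M|, then
smallest bias, then smallest ‖t‖, then smallest generating index pair.
Returning the best of all candidates (rather than the first acceptable
one) makes the result independent of iteration order. If no candidate is
accepted the matcher reports "no match" and the association estimate is 0.

**Association.** assoc_ch1 = |M|/n and assoc_ch2 = |M|/m, reported per
channel because the two channels generally hold different object counts.

**Defaults.** δ = 4 px, α = 0.1, β_max = 0.2, k = 10, max translation
3 px, Euclidean norm. δ and the translation limit are the physically
meaningful knobs: δ is the radius within which two objects are called
associated (set it from pixel size and the biology), and the translation
limit bounds plausible channel misalignment. α and β_max are guards
against chance correspondences and rarely need tuning.

## Biunique ICP baseline

Translation-only ICP initialized with t₀ = centroid(Q) − centroid(P).
Each iteration pairs every translated P-point with its nearest Q-point,
keeps only mutually-nearest pairs (the biuniqueness constraint), and
moves t by the mean residual; it stops when the update norm falls below
10⁻³ px or after 50 iterations, and the final matching keeps pairs within
the same δ as PPM for comparability. Translation-only (not full rigid)
keeps the transformation class identical to PPM's, so the comparison
isolates global search vs. local refinement. The known failure mode is
inherited from the initialization: extraneous objects far from the true
pattern displace the centroid, the refinement converges to a wrong local
optimum, and the pairing collapses — which the simulation's
low-association scenario exposes reliably.

## Pixelwise baselines

Pearson correlation of intensities, Manders coefficients
M_i = Σ ch_i [ch_ref > T] / Σ ch_i (Otsu threshold on the reference
channel by default, manual override available), direct mask-overlap
fractions, and an objectwise overlap (fraction of objects sharing ≥ 1
pixel with any object of the other channel). Statistics are computed
over a mask (the union of the two object masks) by default, excluding
background; whole-image mode is available since some published analyses
use it.

## Scene simulator

The simulator emulates a live-cell two-channel experiment with known
answers. Three scenarios fix the preset association levels —
high 0.7477/0.8557, intermediate 0.5225/0.4715, low 0.2072/0.2805
(ch1/ch2) — realized *exactly* by an integer construction around a
111-object baseline: `solve_counts` finds (shared, n_ch1, n_ch2) with
both ratios correct to 4 decimal places, giving 83/111/97, 58/111/123
and 23/111/82. Channel totals thus vary around 111 by design.

Shared objects are placed uniformly over the image interior with a
minimum pairwise separation of 5 px across all base locations; channel-2
shared coordinates add a global shift of preset magnitude L ∈ {0,…,3} px
in a uniformly random direction plus independent per-axis N(0, σ²)
jitter; unique objects are placed independently per channel. The 5 px
separation (chosen over a smaller value) keeps every planted spot
resolvable by the detector and, being larger than the default δ = 4 px,
guarantees the preset associations cannot be inflated by chance matches
at zero shift.

Rendering: 256×256 px frames, Gaussian spot profiles with σ = 1.5 px,
per-spot peak intensity uniform in [80, 200], flat background level 20
with additive zero-mean Gaussian noise (σ = 2), clipped at zero. These
values give a high-SNR image in which detection is reliable, so benchmark
scores measure the matcher, not the detector. The simulator does **not**
model photophysics (Poisson shot noise, bleaching), PSF anisotropy,
non-Gaussian spot shapes, clustered spatial distributions, or 3D — so
passing benchmarks demonstrate matcher behaviour under controlled
geometry, not detector performance on difficult real acquisitions.

The default benchmark grid is the full study design: shifts {0, 1, 2, 3}
× jitter σ {0, 0.5, 1.0, 1.5, 2.0, 2.5} = 24 combinations × 3 scenarios
× 10 replicates = 720 scenes. Per-scene seeds derive deterministically
from one master seed.

A time-lapse variant gives every object a Gaussian random walk from a
common initial scene; associated pairs share their walk (they move as
one unit, which is what association means dynamically) while unique
objects walk independently. Matching channel 1 at frame t against
channel 2 at frame t + n then probes robustness to imaging delay.

## Evaluation

On simulated scenes the matcher output is scored against the known
correspondence: a reported pair is a **TP** if both endpoints map to
ground-truth objects forming a true pair, otherwise an **FP** (this
includes pairs involving spurious detections); a true pair never
recovered is an **FN**. Detections map to ground-truth objects by greedy
nearest-first one-to-one assignment within a 2 px gating radius (the
choice of radius is uncritical: detection errors are ≪ the 5 px object
spacing). Precision, recall and F follow; an undefined F (no true
positives among the pairings — a "failed pairing") is recorded as a
missing value, never as zero, so failures are visible as missingness
rather than silently dragging averages.

The benchmark driver runs PPM and ICP over a scene grid (on ground-truth
coordinates, or on detected centroids via a flag) and reports a tidy
table plus mean-F summaries; the delay driver reports per-method
estimates versus frame offset, both raw and normalized by the zero-delay
value.

## Numerical and degenerate-input choices

* Empty point sets: matching returns an empty, non-accepted result
  (association 0); ICP raises, since registration of nothing is a usage
  error; the bias of an empty matching is undefined and raises.
* The matching-distance check uses a 10⁻⁹ px slack in the validator to
  absorb floating-point noise; all science-level comparisons are far
  coarser.
* kd-tree ties: neighbor lists are re-sorted by (distance rounded to
  12 decimals, label) so equidistant neighbors order deterministically.
* `solve_counts` searches channel-1 totals outward from the baseline and
  reports the nearest achievable fractions when a target is not exactly
  representable.

## Problem sizes used in the shipped checks

The test suite exercises the full 720-scene design at manifest level
(ground truth only, no rendering) and runs the rendered pipeline on
single scenes; the PPM-vs-ICP comparison uses a reduced grid
(shifts {0, 3} × σ {0, 1.0, 2.5}, 3 replicates) on ground-truth
coordinates, which already separates the two methods cleanly; exhaustive
oracle equivalence is checked on 200 random instances of ≤ 8 points per
side, where enumeration of every translation and assignment is feasible.
These sizes are the package's own trade-off between coverage and a test
suite that runs in well under a minute per module.

## Known limitations

* Translation-only: fields with rotation, scaling or nonrigid tissue
  deformation need a different transformation class.
* The association estimate counts chance proximity of unrelated objects
  within δ as association; at high object densities choose δ below the
  typical nearest-neighbor spacing or the estimate inflates.
* The candidate search is O(#close pairs × cost of one matching); for
  point sets beyond ~10³ objects per channel it becomes the dominant
  cost, though still far from interactive-rate limits.
* Strict monotonicity of mean F in jitter σ holds only up to replicate
  noise (~0.005) because chance matches perturb individual scenes.
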