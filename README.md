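# vesassoc

Object-based **association** analysis for two-channel fluorescence
microscopy, built around point-pattern matching (PPM) under translations.

In live-cell imaging the two channels are acquired sequentially, so
rapidly moving vesicles and slight channel misalignment break pixelwise
colocalization estimates (Pearson correlation, Manders coefficients,
direct mask overlap): objects that clearly travel together may never share
a pixel. `vesassoc` instead detects the fluorescent objects in each
channel, takes their centroids as two point sets *P* and *Q*, and searches
globally for a translation *t* under which subsets of *P* and *Q* fall
into one-to-one correspondence. Association is then the matched fraction
of each channel's objects — a number on the same 0–1 scale as overlap
percentages, but tolerant of moderate shifts and object movement.

## The matcher

For every candidate shift *t* = *Q<sub>j</sub>* − *P<sub>i</sub>* with
‖*t*‖ ≤ `max_translation`:

1. translate *P* by *t*;
2. connect each translated point to the scene points among its *k*
   nearest neighbors (kd-tree, sliding-midpoint rule) that lie within the
   matching distance **δ**;
3. take the maximum bipartite matching *M* of that graph (Hopcroft–Karp);
4. accept *M* only if |*M*| ≥ **α**·min(|*P*|, |*Q*|) (matching ratio),
   its **bias** ‖mean residual‖/δ ≤ β<sub>max</sub> (residuals must not
   all point one way — that signals an off-by-one match of a shifted
   copy), and ‖*t*‖ is moderate.

The best accepted matching (largest, then least biased, then smallest
shift) gives `assoc_ch1 = |M|/|P|` and `assoc_ch2 = |M|/|Q|`; if nothing
is accepted the method reports no association. A translation-only
**Biunique ICP** baseline (centroid initialization, mutual-nearest-
neighbor pairing) is included for head-to-head comparison, along with the
pixelwise estimators and a scene simulator with exact preset association
levels and full ground-truth correspondence.

## Worked example

```python
import numpy as np
from vesassoc import SimParams, PPMParams, generate_scene, detect_spots, association

# high-association scene: 83 shared objects of 111 (ch1) and 97 (ch2),
# 2 px global shift, 0.5 px per-object jitter
scene = generate_scene(SimParams(shift_magnitude=2.0, jitter_sigma=0.5, seed=3))
d1 = detect_spots(scene.images[0])
d2 = detect_spots(scene.images[1])
res = association(d1.centroids, d2.centroids, PPMParams(matching_distance=4.0))
print(len(res.matching.pairs), res.matching.translation)
print(round(res.assoc_ch1, 4), round(res.assoc_ch2, 4))
```

prints

```
83 Translation(dx=-1.5999999999999943, dy=-1.0)
0.7477 0.8557
```

The matcher recovers the applied 2 px shift (true value (−1.617, −1.178))
to within the per-object jitter, pairs the 83 planted correspondences,
and the estimated association levels reproduce the generating presets
0.7477 / 0.8557 exactly even though the channels are misaligned. The
same run from the shell:

```bash
assoc simulate --scenario high --shift 2 --sigma 0.5 --seed 3 --outdir sims/
assoc detect --image sims/high_L2_s0.5_r0.tif --frame 0 --out-prefix ch1
assoc match --ch1 ch1_centroids.csv --ch2 ch2_centroids.csv --delta 4 --out result.json
```

Other subcommands: `assoc coloc` (Pearson/Manders/overlap), `assoc
benchmark` (the PPM-vs-ICP simulation sweep), `assoc delay` (robustness
to imaging delay on time-lapse stacks).

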