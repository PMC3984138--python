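"""Scoring against ground truth, the simulation benchmark, and the
imaging-delay experiment.

A matcher's output is scored on simulated scenes where the true
correspondence is known: a reported pair is a true positive when both
endpoints map to ground-truth objects forming a true pair, a false
positive otherwise (mismatch), and a true pair never recovered is a false
negative (object not paired although a counterpart exists).  Precision,
recall and the F-measure follow.  The benchmark driver runs PPM and the
ICP baseline over a scene grid and aggregates mean F per parameter
combination; the delay driver matches channel 1 at frame t against
channel 2 at frame t+n to probe robustness to acquisition lag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .core import Matching, PointSet, PPMParams
from .detection import DetectionParams, detect_spots
from .icp import ICPParams, icp_register
from .matching import association, ppm_match
from .coloc import object_overlap, overlap_fraction
from .simulate import SyntheticScene, generate_grid

logger = logging.getLogger("vesassoc")

__all__ = [
    "MatchScore",
    "DelayResult",
    "assign_detections",
    "score_matching",
    "run_benchmark",
    "run_delay_experiment",
]


@dataclass
class MatchScore:
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) > 0 else float("nan")

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) > 0 else float("nan")

    @property
    def f_measure(self) -> float:
        p, r = self.precision, self.recall
        if np.isnan(p) or np.isnan(r) or (p + r) == 0:
            return float("nan")
        return 2 * p * r / (p + r)


@dataclass
class DelayResult:
    """Per-method association/overlap estimates as a function of frame
    delay, plus the same values normalized by the zero-delay estimate."""

    delays: List[int]
    estimates: pd.DataFrame  # index: method, columns: delay
    relative: pd.DataFrame


def assign_detections(
    detected: PointSet, gt: PointSet, radius: float = 2.0
) -> Dict[int, int]:
    """Map detected points to ground-truth objects.

    Greedy nearest-first one-to-one assignment within a gating radius;
    detections with no ground-truth object inside the radius stay
    unassigned (spurious).  Returns {detected_index: gt_index}.
    """
    if len(detected) == 0 or len(gt) == 0:
        return {}
    tree = cKDTree(gt.points)
    cand: List[Tuple[float, int, int]] = []
    for i, x in enumerate(detected.points):
        for j in tree.query_ball_point(x, radius):
            cand.append((float(np.linalg.norm(gt.points[j] - x)), i, j))
    cand.sort()
    used_det: set = set()
    used_gt: set = set()
    out: Dict[int, int] = {}
    for _, i, j in cand:
        if i in used_det or j in used_gt:
            continue
        out[i] = j
        used_det.add(i)
        used_gt.add(j)
    return out


def score_matching(
    m: Matching,
    true_pairs: Iterable[Tuple[int, int]],
    det_to_gt_ch1: Optional[Dict[int, int]] = None,
    det_to_gt_ch2: Optional[Dict[int, int]] = None,
) -> MatchScore:
    """Score a matching against the ground-truth correspondence.

    ``det_to_gt_chX`` translate detected-point indices to ground-truth
    indices (identity when the matcher ran on ground-truth coordinates).
    A matched pair whose endpoints include an unassigned (spurious)
    detection counts as a false positive.
    """
    truth = set(tuple(p) for p in true_pairs)
    tp = 0
    for i, j in m.pairs:
        g1 = i if det_to_gt_ch1 is None else det_to_gt_ch1.get(i)
        g2 = j if det_to_gt_ch2 is None else det_to_gt_ch2.get(j)
        if g1 is not None and g2 is not None and (g1, g2) in truth:
            tp += 1
    fp = len(m.pairs) - tp
    fn = len(truth) - tp
    return MatchScore(tp=tp, fp=fp, fn=fn)


def _scene_point_sets(
    scene: SyntheticScene,
    use_detection: bool,
    detection_params: Optional[DetectionParams],
    gating_radius: float,
):
    """Point sets + detection→gt maps for one scene (gt maps are identity
    when the matcher runs on ground-truth coordinates)."""
    if not use_detection:
        return scene.gt_ch1, scene.gt_ch2, None, None
    if scene.images is None:
        raise ValueError("use_detection=True requires rendered scenes")
    dp = detection_params or DetectionParams()
    det1 = detect_spots(scene.images[0], dp, channel_id=1)
    det2 = detect_spots(scene.images[1], dp, channel_id=2)
    map1 = assign_detections(det1.centroids, scene.gt_ch1, gating_radius)
    map2 = assign_detections(det2.centroids, scene.gt_ch2, gating_radius)
    return det1.centroids, det2.centroids, map1, map2


def run_benchmark(
    scenes: Optional[Iterable[SyntheticScene]] = None,
    ppm_params: Optional[PPMParams] = None,
    icp_params: Optional[ICPParams] = None,
    use_detection: bool = False,
    detection_params: Optional[DetectionParams] = None,
    gating_radius: float = 2.0,
    **grid_kwargs,
) -> pd.DataFrame:
    """Run PPM and ICP over a scene grid and score both against truth.

    Returns a tidy table, one row per scene × method, with the matching
    size, bias, translation, acceptance flag and tp/fp/fn/precision/
    recall/F.  ``scenes`` defaults to the full study grid (720 scenes);
    pass ``generate_grid(...)`` output or any scene iterable to scale
    down.  Per-scene failures are logged and skipped, the run continues.
    """
    ppm_params = ppm_params or PPMParams()
    icp_params = icp_params or ICPParams(match_radius=ppm_params.matching_distance)
    if scenes is None:
        scenes = generate_grid(render=use_detection, **grid_kwargs)

    rows = []
    for scene in scenes:
        meta = scene.meta
        scene_id = meta.get("scene_index", -1)
        try:
            p, q, map1, map2 = _scene_point_sets(
                scene, use_detection, detection_params, gating_radius
            )
            for method in ("ppm", "icp"):
                if method == "ppm":
                    m = ppm_match(p, q, ppm_params)
                else:
                    m = icp_register(p, q, icp_params)
                score = score_matching(m, scene.true_pairs, map1, map2)
                rows.append(
                    {
                        "scene": scene_id,
                        "scenario": meta.get("scenario"),
                        "shift": meta.get("shift", scene.params.shift_magnitude),
                        "sigma": meta.get("sigma", scene.params.jitter_sigma),
                        "replicate": meta.get("replicate", 0),
                        "method": method,
                        "n_matched": len(m.pairs),
                        "accepted": m.accepted,
                        "bias": m.bias,
                        "dx": m.translation.dx,
                        "dy": m.translation.dy,
                        "tp": score.tp,
                        "fp": score.fp,
                        "fn": score.fn,
                        "precision": score.precision,
                        "recall": score.recall,
                        "f_measure": score.f_measure,
                    }
                )
                logger.info(
                    "scene=%s method=%s |M|=%d bias=%.3f t=(%.2f,%.2f) F=%.3f",
                    scene_id, method, len(m.pairs), m.bias if m.pairs else float("nan"),
                    m.translation.dx, m.translation.dy, score.f_measure,
                )
        except Exception:  # per-scene failure: report and continue
            logger.exception("scene %s failed; continuing", scene_id)
    return pd.DataFrame(rows)


def summarize_benchmark(table: pd.DataFrame) -> pd.DataFrame:
    """Mean F-measure per scenario × shift × sigma × method (undefined
    F-measures are missing values and excluded from the mean)."""
    return (
        table.groupby(["scenario", "shift", "sigma", "method"], dropna=False)[
            "f_measure"
        ]
        .mean()
        .reset_index()
    )


def plot_benchmark(table: pd.DataFrame, path) -> None:
    """Mean-F summary plots vs jitter σ and vs shift magnitude."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    summary = summarize_benchmark(table)
    fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
    markers = {"ppm": "^", "icp": "o"}
    for ax, param in zip(axes, ("sigma", "shift")):
        for (scen, method), grp in summary.groupby(["scenario", "method"]):
            g = grp.groupby(param)["f_measure"].mean()
            ax.plot(g.index, g.values, marker=markers.get(method, "s"),
                    label=f"{scen}/{method}")
        ax.set_xlabel("jitter sigma (px)" if param == "sigma" else "shift (px)")
        ax.set_ylabel("mean F-measure")
    axes[0].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_delay_experiment(
    stack_ch1: Sequence[np.ndarray],
    stack_ch2: Sequence[np.ndarray],
    delays: Sequence[int],
    ppm_deltas: Sequence[float] = (4.0, 6.0, 8.0, 10.0),
    detection_params: Optional[DetectionParams] = None,
    ppm_params: Optional[PPMParams] = None,
) -> DelayResult:
    """Imaging-delay robustness driver.

    For each delay n, channel 1 at frame t is paired with channel 2 at
    frame t+n for every valid t; the table reports the mean over frames of
    the PPM association (with respect to channel 1) at each search range δ
    and of the direct pixel- and object-overlap estimates, plus the same
    values relative to the non-delayed (n = 0) estimate.
    """
    n_frames = len(stack_ch1)
    if len(stack_ch2) != n_frames:
        raise ValueError("stacks must have equal frame counts")
    delays = sorted(int(n) for n in delays)
    if delays and delays[-1] >= n_frames:
        raise ValueError("max delay must be smaller than the frame count")

    dp = detection_params or DetectionParams()
    base = ppm_params or PPMParams()
    det1 = [detect_spots(np.asarray(f), dp, channel_id=1) for f in stack_ch1]
    det2 = [detect_spots(np.asarray(f), dp, channel_id=2) for f in stack_ch2]

    methods = [f"ppm_d{g:g}" for g in ppm_deltas] + ["pixel_overlap", "object_overlap"]
    est = {m: [] for m in methods}
    for n in delays:
        acc = {m: [] for m in methods}
        for t in range(n_frames - n):
            d1, d2 = det1[t], det2[t + n]
            for g in ppm_deltas:
                params = PPMParams(
                    matching_distance=float(g),
                    matching_ratio=base.matching_ratio,
                    max_bias=base.max_bias,
                    max_neighbors=base.max_neighbors,
                    max_translation=base.max_translation,
                    norm=base.norm,
                )
                res = association(d1.centroids, d2.centroids, params)
                acc[f"ppm_d{g:g}"].append(res.assoc_ch1)
            acc["pixel_overlap"].append(overlap_fraction(d1.mask, d2.mask)[0])
            acc["object_overlap"].append(object_overlap(d1.labels, d2.labels)[0])
        for m in methods:
            est[m].append(float(np.mean(acc[m])))

    estimates = pd.DataFrame(est, index=delays).T
    estimates.columns.name = "delay"
    if 0 in delays:
        base_col = estimates[0].replace(0.0, np.nan)
        relative = estimates.div(base_col, axis=0)
    else:
        relative = estimates * np.nan
    return DelayResult(delays=list(delays), estimates=estimates, relative=relative)
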