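"""Synthetic replicas of the recognition experiments, with their scoring.

Each replica generates its design's scene set, runs the full pipeline on
every rendered frame and reports the campaign's headline rates:

* isolated objects — 64 single-fruit scenes scored by whether the fruit is
  detected, 120 single-leaf scenes scored by whether no fruit is reported;
* one fruit + one leaf collocations — 40 scenes (5 arrangements x 8
  rotations), a scene counts only if the fruit is found with no spurious
  detection;
* complex on-branch arrangements — 80 scenes of 3-4 fruits with leaves and
  a branch, scored per fruit, pooled.

All randomness derives from a single integer seed.  Thresholds come from
:func:`spherecut.pipeline.calibrate_thresholds` (one parameter set for the
whole campaign); the isolated/adherent split stays range-adaptive.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .pipeline import (
    Metrics,
    PipelineConfig,
    calibrate_thresholds,
    design_scenes,
    match_and_score,
    recognize_frame,
)
from .synthetic import render_depth

__all__ = [
    "replica_seeds",
    "calibrated_config",
    "IsolatedReplica",
    "isolated_replica",
    "collocation_replica",
    "on_branch_replica",
]


def replica_seeds(seed: int) -> dict[str, int]:
    """Derive one sub-seed per replica stage from a master seed."""
    rng = np.random.default_rng(seed)
    names = ["calibration", "isolated", "collocation", "on_branch"]
    vals = rng.integers(0, 2**31 - 1, size=len(names))
    return {name: int(v) for name, v in zip(names, vals)}


def calibrated_config(seed: int, base: Optional[PipelineConfig] = None) -> PipelineConfig:
    """Pipeline config with E0/AN0 calibrated from a rendered training set."""
    base = base or PipelineConfig()
    thresholds = calibrate_thresholds(seed, base)
    # keep the range-adaptive isolated/adherent split as the pipeline default
    return replace(base, thresholds=replace(thresholds, N0=None))


@dataclass
class IsolatedReplica:
    """Outcome of the isolated-object campaign."""

    n_fruit_scenes: int
    n_fruit_detected: int
    n_leaf_scenes: int
    n_leaf_rejected: int
    metrics: list  # per-scene Metrics, fruit scenes only

    @property
    def fruit_success_rate(self) -> float:
        return 100.0 * self.n_fruit_detected / self.n_fruit_scenes

    @property
    def leaf_rejection_rate(self) -> float:
        return 100.0 * self.n_leaf_rejected / self.n_leaf_scenes

    @property
    def combined_rate(self) -> float:
        return 100.0 * (self.n_fruit_detected + self.n_leaf_rejected) / (
            self.n_fruit_scenes + self.n_leaf_scenes
        )

    @property
    def leaf_misrecognition_rate(self) -> float:
        return 100.0 * (self.n_leaf_scenes - self.n_leaf_rejected) / self.n_leaf_scenes


def isolated_replica(seed: int, config: PipelineConfig) -> IsolatedReplica:
    """Run the isolated-object campaign: 64 fruit + 120 leaf scenes."""
    records = design_scenes("isolated", seed, config)
    n_f = det_f = n_l = rej_l = 0
    per_scene = []
    for rec in records:
        frame, truth = render_depth(rec.scene, rec.render_seed)
        detections = recognize_frame(frame, config)
        if rec.stratum == "fruit":
            m = match_and_score(detections, truth, config.match_radius)
            per_scene.append(m)
            n_f += 1
            det_f += int(m.n_success == 1)
        else:
            n_l += 1
            rej_l += int(len(detections) == 0)
    return IsolatedReplica(n_f, det_f, n_l, rej_l, per_scene)


def collocation_replica(seed: int, config: PipelineConfig) -> Metrics:
    """One-fruit-one-leaf campaign; success = detected with nothing spurious."""
    records = design_scenes("collocation", seed, config, rows=[0])
    total = Metrics()
    strict_success = 0
    for rec in records:
        frame, truth = render_depth(rec.scene, rec.render_seed)
        detections = recognize_frame(frame, config)
        m = match_and_score(detections, truth, config.match_radius)
        strict_success += int(m.n_success == 1 and m.n_misrecognition == 0)
        total = total + m
    return Metrics(
        n_fruit_truth=total.n_fruit_truth,
        n_success=strict_success,
        n_misrecognition=total.n_misrecognition,
        n_missrecognition=total.n_fruit_truth - strict_success,
        n_scenes=total.n_scenes,
    )


def on_branch_replica(seed: int, config: PipelineConfig) -> Metrics:
    """Complex on-branch campaign, scored per fruit and pooled."""
    records = design_scenes("on_branch", seed, config)
    total = Metrics()
    for rec in records:
        frame, truth = render_depth(rec.scene, rec.render_seed)
        detections = recognize_frame(frame, config)
        total = total + match_and_score(detections, truth, config.match_radius)
    return total
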