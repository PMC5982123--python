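"""End-to-end recognition pipeline, scoring and experiment replicas.

The recognition flow per frame: close-shot depth window (160-700 mm) ->
point cloud -> clustering into aggregates -> branch filtering ->
isolated/adherent split -> depth-sphere cutting (one cut for isolated
aggregates, a successive schedule for adherent ones) -> double-threshold
classification of the intersection curves -> merging of curves that belong
to one fruit.

Scoring matches detections to true fruit centers greedily (nearest pair
first, one-to-one): a matched fruit is a success, an unmatched true fruit a
miss-recognition, an unmatched detection a misrecognition.

The experiment designs replicate the physical campaigns: isolated objects
(8 fruits x 8 postures; 6 leaves x 20 postures), fruit-leaf collocations
(the six-row plan, 8 turn-table rotations of 45 deg per set), six varieties
with occluding/adhering leaves (60 deg rotations), and complex on-branch
arrangements of 3-4 fruits with leaves and branches (10 sets x 8 rotations).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .cloud import (
    Aggregate,
    closest_point,
    cluster_aggregates,
    filter_branches,
    frame_to_points,
    split_isolated_adherent,
)
from .detect import (
    Detection,
    Thresholds,
    anchor_radius,
    curve_regions,
    extract_shell,
    merge_detections,
    single_cut,
    successive_cut,
)
from .frames import DepthFrame, depth_window
from .geometry import FRUIT_SPECS, expected_curve_pixels, projected_pixel_count
from .sensor import SensorModel, make_sensor
from .synthetic import (
    CollocationSpec,
    GroundTruth,
    Scene,
    adhesion_level,
    render_depth,
    sample_scene,
)

__all__ = [
    "PipelineConfig",
    "Metrics",
    "recognize_frame",
    "match_and_score",
    "calibrate_thresholds",
    "design_scenes",
    "run_experiment",
    "ExperimentResult",
    "TABLE3_ROWS",
]

# (n_fruits, n_leaves per set, n_sets) of the collocation plan; rows with
# "3 or 4" leaves alternate 3 and 4 across sets.
TABLE3_ROWS: list[tuple[int, tuple[int, ...], int]] = [
    (1, (1,), 5),
    (1, (2,), 5),
    (1, (3, 4), 5),
    (2, (1,), 4),
    (2, (2,), 5),
    (2, (3, 4), 6),
]

_ADAPTIVE_MARGIN = 1.2  # adherent iff count >= margin * largest-single-fruit count
_MIN_DEPTH_EXTENT_FACTOR = 0.6  # aggregates shallower than this x min fruit radius are not fruit


@dataclass
class PipelineConfig:
    """Serializable configuration of the full recognition pipeline."""

    sensor_preset: str = "F200"
    sensor_overrides: dict = field(default_factory=dict)
    d_lo: float = 160.0
    d_hi: float = 700.0
    link_tau: float = 10.0
    max_minor_px: float = 6.0
    min_elong: float = 4.0
    variety: str = "tangerine"
    default_L: Optional[float] = None  # None: use the variety's cutting depth
    match_radius: Optional[float] = None  # None: per-object true radius
    thresholds: Thresholds = field(default_factory=Thresholds)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.d_lo < self.d_hi):
            raise ValueError("require 0 < d_lo < d_hi")
        if self.link_tau <= 0:
            raise ValueError("link_tau must be positive")
        if self.variety not in FRUIT_SPECS:
            raise ValueError(f"unknown variety {self.variety!r}")
        if isinstance(self.thresholds, dict):
            self.thresholds = Thresholds(**self.thresholds)

    def get_sensor(self) -> SensorModel:
        return make_sensor(self.sensor_preset, **self.sensor_overrides)

    @property
    def cut_depth(self) -> float:
        if self.default_L is not None:
            return self.default_L
        return float(FRUIT_SPECS[self.variety].L)

    def to_dict(self) -> dict:
        t = self.thresholds
        return dict(
            sensor_preset=self.sensor_preset,
            sensor_overrides=dict(self.sensor_overrides),
            d_lo=self.d_lo, d_hi=self.d_hi, link_tau=self.link_tau,
            max_minor_px=self.max_minor_px, min_elong=self.min_elong,
            variety=self.variety, default_L=self.default_L,
            match_radius=self.match_radius, seed=self.seed,
            thresholds=dict(
                E0=t.E0, AN0=t.AN0, N0=t.N0,
                shell_halfwidth=t.shell_halfwidth,
                L_start=t.L_start, L_step=t.L_step, L_max=t.L_max,
                merge_radius=t.merge_radius, ka=t.ka,
            ),
        )

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _split_aggregates(
    aggregates: list[Aggregate], config: PipelineConfig, sensor: SensorModel
) -> list[Aggregate]:
    """Label aggregates isolated/adherent.

    With a fixed N0 the spec'd point-count split applies.  The default
    (N0=None) is range-adaptive: an aggregate whose count exceeds 1.2x the
    projected pixel footprint of the largest configured-variety fruit at
    the aggregate's own closest distance cannot be a single fruit.
    """
    if config.thresholds.N0 is not None:
        return split_isolated_adherent(aggregates, config.thresholds.N0)
    r_max = FRUIT_SPECS[config.variety].max_radius
    for agg in aggregates:
        ra = closest_point(agg).r
        expected = projected_pixel_count(r_max, ra + r_max, sensor)
        extent = float(np.percentile(agg.r, 98) - np.percentile(agg.r, 2))
        crowded = agg.count >= _ADAPTIVE_MARGIN * expected
        deep = extent >= 1.5 * r_max  # deeper than any single fruit's surface
        agg.kind = "adherent" if (crowded or deep) else "isolated"
    return aggregates


def recognize_frame(frame: DepthFrame, config: PipelineConfig) -> list[Detection]:
    """Run the full depth-only recognition flow on one frame."""
    sensor = config.get_sensor()
    if frame.shape != sensor.shape:
        raise ValueError(
            f"frame shape {frame.shape} does not match sensor {sensor.shape}"
        )
    t = config.thresholds
    windowed = depth_window(frame, config.d_lo, config.d_hi)
    cloud = frame_to_points(windowed, sensor)
    if len(cloud) == 0:
        return []
    aggregates = cluster_aggregates(cloud, config.link_tau)
    aggregates = filter_branches(aggregates, config.max_minor_px, config.min_elong)
    aggregates = [a for a in aggregates if a.count >= t.AN0]  # too small for any curve
    # depth-extent veto: a sphere of the smallest configured-variety size is
    # at least ~one radius deep from pole to limb; shallower clouds are
    # grazing leaf patches or clutter
    spec = FRUIT_SPECS[config.variety]
    min_extent = _MIN_DEPTH_EXTENT_FACTOR * (spec.Dp_range[0] + spec.De_range[0]) / 4.0
    aggregates = [
        a for a in aggregates
        if np.percentile(a.r, 98) - np.percentile(a.r, 2) >= min_extent
    ]
    aggregates = _split_aggregates(aggregates, config, sensor)
    curves = []
    for agg in aggregates:
        if agg.kind == "adherent":
            extent = float(np.percentile(agg.r, 98) - np.percentile(agg.r, 2))
            L_max = max(t.L_max, extent + config.cut_depth)
            curves.extend(successive_cut(agg, t, L_max=L_max))
        else:
            got = single_cut(agg, t, config.cut_depth)
            # an unsatisfactory cut is deepened a bounded amount: a larger
            # cutting depth yields a larger, better-populated circle
            for extra in (2.0, 4.0):
                if got:
                    break
                got = single_cut(agg, t, config.cut_depth + extra)
            curves.extend(got)
    curves = _size_consistent(curves, config, sensor)
    fruit_radius = FRUIT_SPECS[config.variety].mean_radius
    return merge_detections(curves, t.merge_radius, fruit_radius=fruit_radius)


def _size_consistent(curves, config: PipelineConfig, sensor: SensorModel):
    """Drop candidate curves larger than any fruit's shell ring at that range.

    The pixel count separates fruit curves from leaves and branches in both
    directions: the double threshold bounds it from below, and this ceiling
    — the modelled ring size of the largest configured-variety fruit at the
    curve's own range, with a safety factor — bounds it from above.  Leaf
    bands produced by grazing cuts of gently curved blades are the main
    casualty.
    """
    factor = config.thresholds.an_hi_factor
    if factor is None:
        return curves
    r_max = FRUIT_SPECS[config.variety].max_radius
    kept = []
    for c in curves:
        if c.cut_depth is None or c.cut_radius <= c.cut_depth:
            kept.append(c)
            continue
        ra = c.cut_radius - c.cut_depth
        try:
            ceiling = factor * expected_curve_pixels(
                r_max, ra, c.cut_depth, config.thresholds.shell_halfwidth, sensor
            )
        except ValueError:
            kept.append(c)
            continue
        if c.AN <= ceiling:
            kept.append(c)
    return kept


@dataclass
class Metrics:
    """Detection/ground-truth contingency counts and the derived rates."""

    n_fruit_truth: int = 0
    n_success: int = 0
    n_misrecognition: int = 0
    n_missrecognition: int = 0
    n_scenes: int = 0

    def __add__(self, other: "Metrics") -> "Metrics":
        return Metrics(
            self.n_fruit_truth + other.n_fruit_truth,
            self.n_success + other.n_success,
            self.n_misrecognition + other.n_misrecognition,
            self.n_missrecognition + other.n_missrecognition,
            self.n_scenes + other.n_scenes,
        )

    @property
    def success_rate(self) -> float:
        if self.n_fruit_truth == 0:
            return float("nan")
        return 100.0 * self.n_success / self.n_fruit_truth

    @property
    def missrecognition_rate(self) -> float:
        if self.n_fruit_truth == 0:
            return float("nan")
        return 100.0 * self.n_missrecognition / self.n_fruit_truth

    @property
    def misrecognition_rate(self) -> float:
        base = self.n_fruit_truth if self.n_fruit_truth else self.n_scenes
        if base == 0:
            return float("nan")
        return 100.0 * self.n_misrecognition / base


def match_and_score(
    detections: list[Detection],
    truth: GroundTruth,
    match_radius: Optional[float] = None,
) -> Metrics:
    """Greedy nearest-first one-to-one matching of detections to true fruits.

    A detection matches a fruit when their centers lie within
    ``match_radius`` (or the fruit's own mean radius when None).
    """
    if match_radius is not None and match_radius <= 0:
        raise ValueError("match_radius must be positive")
    fruits = [o for o in truth.objects if o.kind == "fruit"]
    pairs = []
    for di, det in enumerate(detections):
        for fi, fruit in enumerate(fruits):
            dist = float(np.linalg.norm(det.center - fruit.center))
            radius = match_radius if match_radius is not None else fruit.radius
            if dist <= radius:
                pairs.append((dist, di, fi))
    pairs.sort()
    used_d: set[int] = set()
    used_f: set[int] = set()
    for _, di, fi in pairs:
        if di in used_d or fi in used_f:
            continue
        used_d.add(di)
        used_f.add(fi)
    n_success = len(used_f)
    return Metrics(
        n_fruit_truth=len(fruits),
        n_success=n_success,
        n_misrecognition=len(detections) - len(used_d),
        n_missrecognition=len(fruits) - n_success,
        n_scenes=1,
    )


# ---------------------------------------------------------------------------
# threshold calibration

def calibrate_thresholds(
    training_seed: int, config: Optional[PipelineConfig] = None
) -> Thresholds:
    """Derive E0, AN0 and N0 from a rendered labelled training set.

    Renders isolated fruits (all six varieties over the depth window),
    isolated leaves and branches; cuts each at its closest point and
    records the dominant intersection-curve eccentricity and pixel count.
    E0 is the midpoint between the 95th percentile of fruit eccentricities
    and the 5th percentile of leaf eccentricities; AN0 is half the smallest
    observed fruit count; N0 is 1.2x the largest observed single-fruit
    point-cloud size.
    """
    config = config or PipelineConfig()
    base = config.thresholds
    rng = np.random.default_rng(training_seed)
    seeds = rng.integers(0, 2**31 - 1, size=512)
    k = 0

    def next_seed() -> int:
        nonlocal k
        k += 1
        return int(seeds[k - 1])

    fruit_E, fruit_AN, fruit_counts = [], [], []
    depths = [260.0, 350.0, 440.0, 530.0, 620.0]
    for variety in FRUIT_SPECS:
        for d in depths:
            for _pose in range(2):
                spec = CollocationSpec(n_fruits=1, variety=variety, depth_range=(d, d))
                scene = sample_scene(spec, next_seed())
                frame, _ = render_depth(scene, next_seed())
                agg = _largest_aggregate(frame, config)
                if agg is None:
                    continue
                fruit_counts.append(agg.count)
                curve = _dominant_curve(agg, base, float(FRUIT_SPECS[variety].L))
                if curve is not None:
                    fruit_E.append(curve.E)
                    fruit_AN.append(curve.AN)

    leaf_E = []
    for i in range(40):
        spec = CollocationSpec(
            n_fruits=0, n_leaves=1,
            leaf_tilt_max_deg=60.0, leaf_curl_max=1.0 / 60.0,
        )
        scene = sample_scene(spec, next_seed())
        frame, _ = render_depth(scene, next_seed())
        agg = _largest_aggregate(frame, config)
        if agg is None:
            continue
        curve = _dominant_curve(agg, base, config.cut_depth)
        if curve is not None:
            leaf_E.append(curve.E)

    if not fruit_E or not leaf_E:
        raise RuntimeError("degenerate training set: a class produced no curves")

    e0 = 0.5 * (np.percentile(fruit_E, 95) + np.percentile(leaf_E, 5))
    e0 = float(np.clip(e0, 0.05, 0.99))
    an0 = max(1.0, 0.5 * min(fruit_AN))
    n0 = int(math.ceil(1.2 * max(fruit_counts)))
    return replace(base, E0=e0, AN0=an0, N0=n0)


def _largest_aggregate(frame: DepthFrame, config: PipelineConfig):
    sensor = config.get_sensor()
    cloud = frame_to_points(depth_window(frame, config.d_lo, config.d_hi), sensor)
    if len(cloud) == 0:
        return None
    aggs = cluster_aggregates(cloud, config.link_tau)
    return max(aggs, key=lambda a: a.count)


def _dominant_curve(agg, thresholds: Thresholds, L: float):
    ra = anchor_radius(agg)
    shell = extract_shell(agg, ra + L, thresholds.shell_halfwidth)
    curves = curve_regions(shell, cut_radius_mm=ra + L, source_id=agg.id, cut_depth=L)
    if not curves:
        return None
    return max(curves, key=lambda c: c.AN)


# ---------------------------------------------------------------------------
# experiment designs

@dataclass
class SceneRecord:
    scene: Scene
    stratum: str
    scoring: str  # "fruit" (per-fruit matching) | "rejection" (no-detection)
    render_seed: int


@dataclass
class ExperimentResult:
    design: str
    metrics: dict            # stratum -> Metrics
    report: pd.DataFrame
    adhesion: dict = field(default_factory=dict)  # stratum -> {level: Metrics}

    @property
    def total(self) -> Metrics:
        out = Metrics()
        for m in self.metrics.values():
            out = out + m
        return out


def _collocation_arrangement(
    n_fruits: int, n_leaves: int, seed: int, occlusion_cap: float = 0.3
) -> tuple[CollocationSpec, int]:
    """Pick an arrangement seed whose 8 rotations respect the occlusion cap.

    The cap is a condition on the generated scenes (leaves may hide at most
    `occlusion_cap` of any fruit's surface); candidate arrangements are
    screened with a low-resolution noise-free ground-truth render.
    """
    rng = np.random.default_rng(seed)
    base = CollocationSpec(
        n_fruits=n_fruits, n_leaves=n_leaves, leaf_mode="mixed",
        adherent_fruit_pairs=0,
    )
    candidate = int(rng.integers(0, 2**31 - 1))
    for _ in range(20):
        ok = True
        for rot in range(0, 360, 45):
            spec = replace(
                base, rotation_deg=float(rot), noise_sd=0.0, dropout_p=0.0,
            )
            scene = sample_scene(spec, candidate)
            scene = replace(scene, sensor=scene.sensor.scaled(160, 120))
            _, truth = render_depth(scene, 0)
            for fid in truth.fruit_ids():
                if truth.visible_fraction[fid] < 1.0 - occlusion_cap:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            return base, candidate
        candidate = int(rng.integers(0, 2**31 - 1))
    return base, candidate  # best effort; later scoring sees the cap violation


def design_scenes(
    design: str,
    seed: int,
    config: Optional[PipelineConfig] = None,
    rows: Optional[list[int]] = None,
    n_sets: Optional[int] = None,
) -> list[SceneRecord]:
    """Build the scene list of a named experiment design.

    ``rows`` restricts the collocation design to a subset of its plan rows;
    ``n_sets`` scales down the number of sets per stratum (testing aid).
    """
    config = config or PipelineConfig()
    rng = np.random.default_rng(seed)

    def sub() -> int:
        return int(rng.integers(0, 2**31 - 1))

    records: list[SceneRecord] = []
    if design == "isolated":
        n_fruit_scenes = 64 if n_sets is None else n_sets
        n_leaf_scenes = 120 if n_sets is None else n_sets
        for _ in range(n_fruit_scenes):
            spec = CollocationSpec(n_fruits=1, variety=config.variety)
            records.append(
                SceneRecord(sample_scene(spec, sub()), "fruit", "fruit", sub())
            )
        for _ in range(n_leaf_scenes):
            spec = CollocationSpec(
                n_fruits=0, n_leaves=1,
                leaf_tilt_max_deg=60.0, leaf_curl_max=1.0 / 60.0,
            )
            records.append(
                SceneRecord(sample_scene(spec, sub()), "leaf", "rejection", sub())
            )
    elif design == "collocation":
        selected = rows if rows is not None else range(len(TABLE3_ROWS))
        for ri in selected:
            n_fruits, leaf_counts, sets = TABLE3_ROWS[ri]
            sets = sets if n_sets is None else min(sets, n_sets)
            stratum = f"{n_fruits}F{'-'.join(map(str, leaf_counts))}L"
            for s in range(sets):
                n_leaves = leaf_counts[s % len(leaf_counts)]
                base, arrangement_seed = _collocation_arrangement(
                    n_fruits, n_leaves, sub()
                )
                for rot in range(0, 360, 45):
                    spec = replace(base, rotation_deg=float(rot))
                    records.append(SceneRecord(
                        sample_scene(spec, arrangement_seed), stratum, "fruit", sub()
                    ))
    elif design == "varieties":
        sets = 10 if n_sets is None else n_sets
        for variety in FRUIT_SPECS:
            for _s in range(sets):
                arrangement_seed = sub()
                for rot in range(0, 360, 60):
                    spec = CollocationSpec(
                        n_fruits=1, n_leaves=2, variety=variety,
                        leaf_mode="mixed", rotation_deg=float(rot),
                    )
                    records.append(SceneRecord(
                        sample_scene(spec, arrangement_seed), variety, "fruit", sub()
                    ))
    elif design == "on_branch":
        sets = 10 if n_sets is None else n_sets
        for s in range(sets):
            arrangement_seed = sub()
            n_fruits = 3 + (s % 2)
            for rot in range(0, 360, 45):
                spec = CollocationSpec(
                    n_fruits=n_fruits, n_leaves=3, n_branches=1,
                    adherent_fruit_pairs=1, leaf_mode="mixed",
                    rotation_deg=float(rot), backdrop_depth=850.0,
                    variety=config.variety,
                )
                records.append(SceneRecord(
                    sample_scene(spec, arrangement_seed), "on_branch", "fruit", sub()
                ))
    else:
        raise ValueError(
            f"unknown design {design!r}; valid designs: "
            "isolated, collocation, varieties, on_branch"
        )
    return records


_REPORT_COLUMNS = [
    "Stratum", "Number of Fruits", "Success Amount",
    "Number of Misrecognition", "Number of Miss-Recognition", "Success Rate/%",
]


def run_experiment(
    design: str,
    seed: int,
    config: Optional[PipelineConfig] = None,
    rows: Optional[list[int]] = None,
    n_sets: Optional[int] = None,
) -> ExperimentResult:
    """Generate a design's scenes, run recognition on each, aggregate metrics.

    Deterministic for a fixed seed.  Strata follow the design (fruit/leaf
    for isolated, plan row for collocations, variety x adhesion level for
    varieties, pooled for on-branch).
    """
    config = config or PipelineConfig()
    records = design_scenes(design, seed, config, rows=rows, n_sets=n_sets)
    metrics: dict[str, Metrics] = {}
    adhesion: dict[str, dict[str, Metrics]] = {}
    for rec in records:
        frame, truth = render_depth(rec.scene, rec.render_seed)
        detections = recognize_frame(frame, config)
        if rec.scoring == "rejection":
            m = Metrics(
                n_misrecognition=1 if detections else 0,
                n_success=0 if detections else 1,
                n_scenes=1,
            )
        else:
            m = match_and_score(detections, truth, config.match_radius)
        metrics[rec.stratum] = metrics.get(rec.stratum, Metrics()) + m
        if design == "varieties" and rec.scoring == "fruit":
            fid = truth.fruit_ids()[0]
            level = adhesion_level(truth, fid)
            bucket = adhesion.setdefault(rec.stratum, {})
            bucket[level] = bucket.get(level, Metrics()) + m

    rows_out = []
    for stratum, m in metrics.items():
        denom = m.n_fruit_truth if m.n_fruit_truth else m.n_scenes
        rate = 100.0 * m.n_success / denom if denom else float("nan")
        rows_out.append([
            stratum, m.n_fruit_truth or m.n_scenes, m.n_success,
            m.n_misrecognition, m.n_missrecognition, round(rate, 1),
        ])
    total = Metrics()
    for m in metrics.values():
        total = total + m
    denom = total.n_fruit_truth if total.n_fruit_truth else total.n_scenes
    # pooled "correct outcome" rate: fruit successes plus correct rejections
    pooled_correct = total.n_success
    pooled_n = sum(
        (m.n_fruit_truth if m.n_fruit_truth else m.n_scenes)
        for m in metrics.values()
    )
    rows_out.append([
        "total", pooled_n, pooled_correct,
        total.n_misrecognition, total.n_missrecognition,
        round(100.0 * pooled_correct / pooled_n, 1) if pooled_n else float("nan"),
    ])
    report = pd.DataFrame(rows_out, columns=_REPORT_COLUMNS)
    return ExperimentResult(design, metrics, report, adhesion)
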