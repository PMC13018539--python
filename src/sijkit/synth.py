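"""Synthetic data generation: contour-annotated slices and volumes with
two roughly vertical open contours flanking a brighter "sacrum" region,
paired T1-like/STIR-like ROI volumes with planted lesion effects, and
multi-reader label tables generated from latent truth through known
per-reader flip probabilities.

Every generator is a pure function of its spec and a seeded generator, so
fixtures regenerate bit-identically.  The images are deliberately simple
renderings (intensity ridges, blobs and bands plus noise and blur), enough
to exercise every geometric and learning code path; they are not
anatomically realistic MRI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .classify import QUADRANT_LESIONS, QUADRANTS, LesionTaskSpec
from .contour import Polyline, distance_to_polyline
from .delineation import SliceSample, targets_for_landmarks
from .multireader import LabelTable
from .roi import RoiPair


# ---------------------------------------------------------------------
# Scene generation (delineation test bed)
# ---------------------------------------------------------------------


@dataclass
class SceneSpec:
    """Parameters of a synthetic SIJ-like slice: image size, per-side
    vertex-count range, lanes keeping the two contours separated with a
    central gap (the synthetic sacrum), rendering contrast and noise, and
    a per-side absence probability emulating joints outside the field of
    view."""

    size: int = 64
    n_vertices: tuple = (4, 16)
    margin_frac: float = 0.12
    lane_centers: tuple = (0.32, 0.68)
    lane_halfwidth_frac: float = 0.10
    wobble: float = 2.0
    edge_depth: float = 0.35
    edge_width: float = 0.9
    sacrum_boost: float = 0.22
    noise_sigma: float = 0.03
    blur_sigma: float = 0.6
    absence_prob: float = 0.1
    spacing: float = 0.7  # mm / px

    def __post_init__(self):
        lo, hi = self.n_vertices
        if not (2 <= lo <= hi <= 21):
            raise ValueError("vertex counts must lie in [2, 21]")


def _random_contour(spec: SceneSpec, lane_center: float, side: str,
                    rng: np.random.Generator) -> Polyline:
    size = spec.size
    lo, hi = spec.n_vertices
    margin = spec.margin_frac * size
    span = size - 2 * margin
    n = int(rng.integers(lo, hi + 1))
    n = min(n, max(2, int(span // 2)))  # keep vertex spacing >= ~2 px
    y = np.linspace(margin, size - 1 - margin, n) + rng.normal(0, 0.8, n)
    y = np.clip(np.sort(y), 0, size - 1)
    x = lane_center * size + np.cumsum(rng.normal(0, spec.wobble, n))
    x -= x.mean() - lane_center * size
    half = spec.lane_halfwidth_frac * size
    x = np.clip(x, lane_center * size - half, lane_center * size + half)
    v = np.stack([x, y], axis=1)
    # enforce minimum spacing of 2 px between consecutive vertices
    keep = [v[0]]
    for p in v[1:]:
        if np.linalg.norm(p - keep[-1]) >= 2.0:
            keep.append(p)
    if len(keep) < 2:
        keep = [v[0], v[-1]]
    return Polyline(np.array(keep), side=side)


def _render(spec: SceneSpec, landmarks: dict, rng: np.random.Generator) -> np.ndarray:
    size = spec.size
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    img = 0.45 + 0.05 * (yy / size)  # mild vertical shading
    left, right = landmarks.get("left"), landmarks.get("right")
    if left is not None and left.present and right is not None and right.present:
        # brighter sacrum: between the two contours' mean x, tapered
        lx = np.interp(yy, left.vertices[:, 1], left.vertices[:, 0])
        rx = np.interp(yy, right.vertices[:, 1], right.vertices[:, 0])
        img += spec.sacrum_boost * ((xx > lx) & (xx < rx))
    pts = np.stack([xx.ravel(), yy.ravel()], axis=1)
    for poly in (left, right):
        if poly is not None and poly.present and len(poly) >= 2:
            d = distance_to_polyline(pts, poly).reshape(size, size)
            img -= spec.edge_depth * np.exp(-(d**2) / (2 * spec.edge_width**2))
    if spec.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, spec.blur_sigma)
    if spec.noise_sigma > 0:
        img = img + rng.normal(0, spec.noise_sigma, img.shape)
    return np.clip(img, 0.0, 1.0)


def make_slice(spec: SceneSpec, rng: np.random.Generator) -> SliceSample:
    """One annotated synthetic slice; landmark sides may be absent with
    ``spec.absence_prob`` (absent sides get all-zero target planes)."""
    landmarks = {}
    for lane, side in zip(spec.lane_centers, ("left", "right")):
        if rng.random() < spec.absence_prob:
            landmarks[side] = Polyline.absent(side)
        else:
            landmarks[side] = _random_contour(spec, lane, side, rng)
    img = _render(spec, landmarks, rng)
    targets = targets_for_landmarks(landmarks, (spec.size, spec.size))
    return SliceSample(image=img, landmarks=landmarks, targets=targets,
                       spacing=spec.spacing)


def make_volume(
    spec: SceneSpec,
    n_slices: int,
    rng: np.random.Generator,
    drift: float = 1.0,
) -> tuple[np.ndarray, list[dict]]:
    """A coherent stack: one base scene whose vertices drift smoothly from
    slice to slice (per-slice vertex displacement bounded by ``drift``).
    Both sides are present in every slice, as ROI extraction requires at
    least one slice with both joints."""
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    base = {
        side: _random_contour(spec, lane, side, rng)
        for lane, side in zip(spec.lane_centers, ("left", "right"))
    }
    volume, annotations = [], []
    offsets = {side: np.zeros(2) for side in base}
    for _ in range(n_slices):
        lms = {}
        for side, poly in base.items():
            step = rng.normal(0, drift / 3.0, 2)
            nrm = np.linalg.norm(step)
            if nrm > drift:
                step *= drift / nrm
            offsets[side] = offsets[side] + step
            v = np.clip(poly.vertices + offsets[side], 0, spec.size - 1)
            lms[side] = Polyline(v, side=side)
        volume.append(_render(spec, lms, rng))
        annotations.append(lms)
    return np.stack(volume), annotations


# ---------------------------------------------------------------------
# Lesion planting (classification test bed)
# ---------------------------------------------------------------------


@dataclass
class LesionPlant:
    """Latent lesion prevalences and their image effects inside an ROI:
    STIR-bright blob for oedema, T1-bright blob for fatty metaplasia, a
    dark notch at the joint margin for erosion, a dark para-articular band
    for sclerosis and a bright bridge across the joint for ankylosis.  All
    effects are localised and well above the noise floor, so truth is
    recoverable from simple crop statistics."""

    prevalence: dict = field(
        default_factory=lambda: {
            "oedema": 0.30, "fatty": 0.35, "erosion": 0.30,
            "sclerosis": 0.25, "ankylosis": 0.20,
        }
    )
    amplitude: dict = field(
        default_factory=lambda: {
            "oedema": 0.40, "fatty": 0.40, "erosion": 0.35,
            "sclerosis": 0.30, "ankylosis": 0.45,
        }
    )
    roi_shape: tuple = (6, 32, 32)
    noise_sigma: float = 0.05
    blur_sigma: float = 0.5


@dataclass
class ReaderModel:
    """Per-reader label noise: probability of flipping the latent truth,
    i.i.d. per task, session and sample (no intra-reader correlation by
    default; ``session_correlation`` mixes in a per-reader persistent flip
    shared across sessions)."""

    flip_rates: tuple = (0.10, 0.25)
    n_sessions: int = 3
    session_correlation: float = 0.0

    def __post_init__(self):
        if any(not (0.0 <= r < 0.5) for r in self.flip_rates):
            raise ValueError("flip rates must lie in [0, 0.5)")

    @property
    def n_readers(self) -> int:
        return len(self.flip_rates)


def _quadrant_mask(shape, quadrant: str) -> tuple:
    """Pixel block of one quadrant in a canonical (mirrored-left) crop:
    sacrum = medial half (low x, toward the midline), ilium = lateral."""
    _, h, w = shape
    ys = slice(0, h // 2) if quadrant.startswith("upper") else slice(h // 2, h)
    xs = slice(0, w // 2) if quadrant.endswith("sacrum") else slice(w // 2, w)
    return ys, xs


def _plant_effects(t1, stir, truth: dict, plant: LesionPlant, rng):
    _, h, w = t1.shape
    amp = plant.amplitude
    for lesion in QUADRANT_LESIONS:
        for quadrant in QUADRANTS:
            if not truth[f"{lesion}:{quadrant}"]:
                continue
            ys, xs = _quadrant_mask(t1.shape, quadrant)
            # keep blob centres away from quadrant boundaries so an effect
            # does not leak into the neighbouring quadrant's statistics
            cy = rng.integers(ys.start + 4, max(ys.stop - 4, ys.start + 5))
            cx = rng.integers(xs.start + 4, max(xs.stop - 4, xs.start + 5))
            yy, xx = np.mgrid[0:h, 0:w]
            blob = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * 2.0**2))
            if lesion == "oedema":
                stir += amp["oedema"] * blob
            elif lesion == "fatty":
                t1 += amp["fatty"] * blob
            else:  # erosion: notch at the joint margin, on the quadrant's side
                off = int(rng.integers(2, 5))
                ecx = w // 2 - off if quadrant.endswith("sacrum") else w // 2 + off
                notch = np.exp(-((yy - cy) ** 2 + (xx - ecx) ** 2) / (2 * 2.0**2))
                t1 -= amp["erosion"] * notch
    if truth["sclerosis"]:
        band = np.exp(-((np.arange(w) - w / 2.0) ** 2) / (2 * 3.0**2))
        t1 -= amp["sclerosis"] * band[None, None, :]
    if truth["ankylosis"]:
        bridge_y = h // 2 + int(rng.integers(-3, 4))
        bridge = np.exp(-((np.arange(h) - bridge_y) ** 2) / (2 * 2.0**2))
        t1 += amp["ankylosis"] * bridge[None, :, None]
    return t1, stir


def _make_roi_pair(truth: dict, plant: LesionPlant, side: str, rng) -> RoiPair:
    s, h, w = plant.roi_shape
    yy = np.arange(w, dtype=float)
    joint = np.exp(-((yy - w / 2.0) ** 2) / (2 * 1.2**2))
    t1 = np.full((s, h, w), 0.60) - 0.25 * joint[None, None, :]
    stir = np.full((s, h, w), 0.30) + 0.10 * joint[None, None, :]
    t1, stir = _plant_effects(t1, stir, truth, plant, rng)
    t1 += rng.normal(0, plant.noise_sigma, t1.shape)
    stir += rng.normal(0, plant.noise_sigma, stir.shape)
    if plant.blur_sigma > 0:
        t1 = ndimage.gaussian_filter(t1, (0, plant.blur_sigma, plant.blur_sigma))
        stir = ndimage.gaussian_filter(stir, (0, plant.blur_sigma, plant.blur_sigma))
    from .roi import BoundingBox

    return RoiPair(
        side=side,
        t1_crop=np.clip(t1, 0, 1.5),
        stir_crop=np.clip(stir, 0, 1.5),
        box=BoundingBox(0, 0, w, h, side=side),
        mirrored=(side == "left"),
    )


def make_lesion_dataset(
    n_patients: int,
    plant: LesionPlant | None = None,
    reader: ReaderModel | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list, LabelTable, pd.DataFrame]:
    """The classification corpus: per patient two SIJ ROI pairs (left and
    right, canonical orientation) with lesions planted according to latent
    Bernoulli truths, plus a reader-label table produced by flipping each
    truth independently per reader and session.

    Returns ``(dataset, label_table, truth)`` where dataset is a list of
    ``(sample_id, RoiPair)``, one sample per SIJ, sample_id
    "P<patient>_<side>", and truth has one row per sample and task.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    plant = plant or LesionPlant()
    reader = reader or ReaderModel()
    rng = rng or np.random.default_rng()
    spec = LesionTaskSpec()
    task_ids = spec.task_ids()
    dataset, label_rows, truth_rows = [], [], []
    for p in range(n_patients):
        for side in ("left", "right"):
            sid = f"P{p:04d}_{side}"
            truth = {}
            for tid in task_ids:
                lesion = spec.lesion_of(tid)
                truth[tid] = int(rng.random() < plant.prevalence[lesion])
            pair = _make_roi_pair(truth, plant, side, rng)
            dataset.append((sid, pair))
            for tid in task_ids:
                truth_rows.append(
                    {"sample_id": sid, "task_id": tid, "truth": truth[tid]}
                )
                for r, rate in enumerate(reader.flip_rates, start=1):
                    persistent = rng.random() < reader.session_correlation
                    pflip = rng.random() < rate
                    for sess in range(1, reader.n_sessions + 1):
                        flip = pflip if persistent else (rng.random() < rate)
                        label_rows.append(
                            {
                                "sample_id": sid,
                                "task_id": tid,
                                "reader": r,
                                "session": sess,
                                "label": truth[tid] ^ int(flip),
                            }
                        )
    table = LabelTable(pd.DataFrame(label_rows)).compute_consensus()
    return dataset, table, pd.DataFrame(truth_rows)
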