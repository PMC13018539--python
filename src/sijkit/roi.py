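"""ROI extraction: rotate a volume so the two SIJs sit level, then cut one
static, margin-free bounding box per side covering the delineation across
every slice, and crop the T1/STIR sequence pair with the shared boxes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage



@dataclass
class BoundingBox:
    """Half-open integer pixel box: x in [x0, x1), y in [y0, y1)."""

    x0: int
    y0: int
    x1: int
    y1: int
    side: str | None = None

    def __post_init__(self):
        if self.x1 <= self.x0 or self.y1 <= self.y0:
            raise ValueError("empty bounding box")

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    @property
    def height(self) -> int:
        return self.y1 - self.y0

    def contains(self, p) -> bool:
        x, y = float(p[0]), float(p[1])
        return self.x0 <= x < self.x1 and self.y0 <= y < self.y1


@dataclass
class RoiPair:
    """Dual-sequence crop of one SIJ: the same spatial box applied to the
    T1-weighted and STIR volumes (slice counts may differ per sequence).
    Left-side crops are mirrored to the canonical (right-like) orientation;
    ``mirrored`` records that so quadrant labels can be unflipped."""

    side: str
    t1_crop: np.ndarray
    stir_crop: np.ndarray
    box: BoundingBox
    rotation_deg: float = 0.0
    spacing: float = 1.0
    mirrored: bool = False
    clipped: bool = False


def _present(poly) -> bool:
    return poly is not None and poly.present and len(poly) > 0


def _gather(contours: list[dict], side: str) -> np.ndarray:
    vs = [c[side].vertices for c in contours if side in c and _present(c[side])]
    if not vs:
        raise ValueError(f"side '{side}' absent in every slice")
    return np.concatenate(vs)


def volume_alignment_angle(contours: list[dict]) -> float:
    """Mean inclination (degrees) of the upper-left->upper-right and
    lower-left->lower-right lines, with the extreme-y vertices of each side
    aggregated over all slices.  Rotating the volume by the negative of
    this angle levels the joints."""
    lv, rv = _gather(contours, "left"), _gather(contours, "right")
    upper_l, lower_l = lv[np.argmin(lv[:, 1])], lv[np.argmax(lv[:, 1])]
    upper_r, lower_r = rv[np.argmin(rv[:, 1])], rv[np.argmax(rv[:, 1])]
    ang_up = np.degrees(np.arctan2(upper_r[1] - upper_l[1], upper_r[0] - upper_l[0]))
    ang_lo = np.degrees(np.arctan2(lower_r[1] - lower_l[1], lower_r[0] - lower_l[0]))
    return float((ang_up + ang_lo) / 2.0)


def rotate_volume(
    volume: np.ndarray, contours: list[dict], degrees: float
) -> tuple[np.ndarray, list[dict]]:
    """Rotate every slice by ``-degrees`` about the slice centre (bilinear,
    zero fill); contour vertices get the exact matching rotation."""
    if not np.isfinite(degrees):
        raise ValueError("angle must be finite")
    volume = np.asarray(volume, dtype=float)
    if degrees == 0.0:
        return volume.copy(), [dict(c) for c in contours]
    h, w = volume.shape[1:]
    c = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    th = np.deg2rad(-degrees)
    R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    # output index -> input index for ndimage (row=y, col=x ordering)
    Rinv = R.T
    M = np.array([[Rinv[1, 1], Rinv[1, 0]], [Rinv[0, 1], Rinv[0, 0]]])
    t = c - Rinv @ c
    out = np.stack(
        [
            ndimage.affine_transform(
                sl, M, offset=(t[1], t[0]), order=1, mode="constant", cval=0.0
            )
            for sl in volume
        ]
    )
    new_contours = []
    for cdict in contours:
        nc = {}
        for side_name, poly in cdict.items():
            if _present(poly):
                v = (poly.vertices - c) @ R.T + c
                nc[side_name] = replace(poly, vertices=v)
            else:
                nc[side_name] = poly
        new_contours.append(nc)
    return out, new_contours


def extract_roi_boxes(contours: list[dict]) -> dict:
    """Per side, the minimum static box (floor/ceil snapped, half-open)
    covering every contour vertex of every slice; absent sides yield None."""
    boxes = {}
    for side_name in ("left", "right"):
        try:
            v = _gather(contours, side_name)
        except ValueError:
            boxes[side_name] = None
            continue
        x0, y0 = int(np.floor(v[:, 0].min())), int(np.floor(v[:, 1].min()))
        x1, y1 = int(np.floor(v[:, 0].max())) + 1, int(np.floor(v[:, 1].max())) + 1
        boxes[side_name] = BoundingBox(x0, y0, x1, y1, side=side_name)
    return boxes


def crop_roi_pair(
    t1: np.ndarray,
    stir: np.ndarray,
    boxes: dict,
    rotation_deg: float = 0.0,
    spacing: float = 1.0,
    mirror_left: bool = True,
) -> dict:
    """Apply each side's shared box to both sequences over all their slices.

    The T1 and STIR volumes are assumed registered at ROI resolution; only
    equality of in-plane shape is asserted.  Boxes reaching outside the
    image are clipped (``clipped`` flag set).
    """
    t1 = np.asarray(t1, dtype=float)
    stir = np.asarray(stir, dtype=float)
    if t1.shape[1:] != stir.shape[1:]:
        raise ValueError("T1 and STIR in-plane shapes differ; sequences unregistered")
    h, w = t1.shape[1:]
    out = {}
    for side_name, box in boxes.items():
        if box is None:
            out[side_name] = None
            continue
        cx0, cy0 = max(box.x0, 0), max(box.y0, 0)
        cx1, cy1 = min(box.x1, w), min(box.y1, h)
        clipped = (cx0, cy0, cx1, cy1) != (box.x0, box.y0, box.x1, box.y1)
        used = BoundingBox(cx0, cy0, cx1, cy1, side=side_name)
        t1c = t1[:, cy0:cy1, cx0:cx1].copy()
        stirc = stir[:, cy0:cy1, cx0:cx1].copy()
        mirrored = False
        if mirror_left and side_name == "left":
            t1c = t1c[:, :, ::-1].copy()
            stirc = stirc[:, :, ::-1].copy()
            mirrored = True
        out[side_name] = RoiPair(
            side=side_name, t1_crop=t1c, stir_crop=stirc, box=used,
            rotation_deg=rotation_deg, spacing=spacing,
            mirrored=mirrored, clipped=clipped,
        )
    return out


def align_and_extract(
    t1: np.ndarray,
    contours: list[dict],
    stir: np.ndarray | None = None,
    spacing: float = 1.0,
) -> tuple[dict, float, list[dict]]:
    """Full ROI stage: estimate the alignment angle from the contours
    (delineated on T1), rotate both sequences and the contours, then cut
    and crop the static boxes.  Returns ``(roi_pairs, angle, contours')``.
    """
    angle = volume_alignment_angle(contours)
    t1r, cr = rotate_volume(t1, contours, angle)
    if stir is None:
        stirr = t1r
    else:
        stirr, _ = rotate_volume(stir, contours, angle)
    boxes = extract_roi_boxes(cr)
    pairs = crop_roi_pair(t1r, stirr, boxes, rotation_deg=angle, spacing=spacing)
    return pairs, angle, cr
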