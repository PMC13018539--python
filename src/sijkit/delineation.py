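"""Trainable delineator: an encoder-decoder that regresses, per slice, the
8 planes of :class:`~sijkit.contour.ContourTargets` (two unit-vector-field
components plus source/sink heatmaps for each of the left and right SIJ),
its loss and augmentations, slice preprocessing, and the 21-heatmap
landmark baseline it is compared against.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize

from . import nn
from .contour import (
    ContourTargets,
    Heatmap,
    Polyline,
    VectorField2D,
    WalkParams,
    build_contour_targets,
    gaussian_heatmap,
    resample_polyline,
    suggest_sigma,
    walk_contour,
)

FIELD_PLANES = (0, 1, 4, 5)
HEAT_PLANES = (2, 3, 6, 7)


# ---------------------------------------------------------------------
# Configuration & samples
# ---------------------------------------------------------------------


@dataclass
class DelineatorConfig:
    """Network/training configuration.

    The full profile mirrors the published setup (224 px inputs, Adam with
    lr 1e-3, beta1 0.9, beta2 0.999); the desk profile is a scaled-down
    configuration for CPU-bound experiments and tests.
    """

    input_size: int = 224
    depth: int = 4
    base_width: int = 16
    out_planes: int = 8
    learning_rate: float = 1e-3
    lr_schedule: str = "constant"  # "constant" | "cosine"
    beta1: float = 0.9
    beta2: float = 0.999
    heatmap_weight_alpha: float = 10.0
    steps: int = 2000
    batch_size: int = 8
    patience: int = 20
    seed: int = 0

    def __post_init__(self):
        if self.input_size % (2**self.depth):
            raise ValueError(
                f"input_size {self.input_size} not divisible by 2^depth {2**self.depth}"
            )

    @classmethod
    def desk(cls, **kw) -> "DelineatorConfig":
        base = dict(input_size=64, depth=3, base_width=8, steps=300, batch_size=16)
        base.update(kw)
        return cls(**base)


@dataclass
class AugmentSpec:
    """Training augmentation ranges: translation/scale fractions, rotation
    in degrees (all symmetric about zero), left/right flips, additive
    Gaussian noise and Gaussian blur."""

    translate_frac: float = 0.20
    scale_frac: float = 0.20
    rotate_deg: float = 15.0
    lr_flip: bool = True
    noise_sigma: float = 0.02
    blur_sigma: float = 0.7

    @classmethod
    def identity(cls) -> "AugmentSpec":
        return cls(0.0, 0.0, 0.0, False, 0.0, 0.0)


@dataclass
class SliceSample:
    image: np.ndarray
    landmarks: dict  # side -> Polyline
    targets: ContourTargets | None = None
    spacing: float = 1.0

    @property
    def shape(self):
        return self.image.shape


def sacrum_area(left: Polyline, right: Polyline) -> float:
    """Shoelace area of the polygon spanned between the two contours (the
    synthetic 'sacrum' region used to scale the endpoint heatmaps)."""
    pts = np.concatenate([left.vertices, right.vertices[::-1]])
    x, y = pts[:, 0], pts[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)


def targets_for_landmarks(
    landmarks: dict,
    shape: tuple[int, int],
    on_contour_radius: float = 1.5,
    area_coeff: float = 0.1,
    length_coeff: float = 0.1,
) -> ContourTargets:
    """Build the 8-plane target from per-side landmarks, choosing the
    heatmap sigma from the inter-contour area when both sides are present,
    else from the contour length.

    The default proportionality coefficients give sigma ~3 px on a 64 px
    grid (about 5% of the image side) — endpoint Gaussians much narrower
    than that carry too little mass to regress stably at low resolution.
    """
    left = landmarks.get("left")
    right = landmarks.get("right")

    def ok(p):
        return p is not None and p.present and len(p) >= 2

    if ok(left) and ok(right):
        sigma = suggest_sigma(area=sacrum_area(left, right), area_coeff=area_coeff)
    elif ok(left) or ok(right):
        poly = left if ok(left) else right
        sigma = suggest_sigma(
            contour_length=poly.length(), length_coeff=length_coeff
        )
    else:
        sigma = 1.0
    return build_contour_targets(
        left if ok(left) else None,
        right if ok(right) else None,
        shape,
        sigma,
        on_contour_radius,
    )


# ---------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------


@dataclass
class SliceTransform:
    """Forward/backward coordinate map of :func:`preprocess_slice`."""

    orig_shape: tuple[int, int]
    pad_side: int
    scale: float

    def forward_points(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        return (pts + 0.5) * self.scale - 0.5

    def inverse_points(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        return (pts + 0.5) / self.scale - 0.5


def normalize_intensity(image: np.ndarray, lo_pct=1.0, hi_pct=99.0) -> np.ndarray:
    """Robust per-slice scaling to [0, 1] by the 1st/99th percentiles."""
    lo, hi = np.percentile(image, [lo_pct, hi_pct])
    if hi <= lo:
        return np.zeros_like(image, dtype=float)
    return np.clip((image - lo) / (hi - lo), 0.0, 1.0)


def preprocess_slice(
    image: np.ndarray, spacing: float = 1.0, out_size: int = 224
) -> tuple[np.ndarray, SliceTransform]:
    """Zero-pad (right/bottom) to square, then resample bicubically to
    ``out_size`` squared; the returned transform maps landmark coordinates
    between native and model space."""
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or min(image.shape) < 2:
        raise ValueError("preprocess_slice expects a non-degenerate 2D image")
    h, w = image.shape
    side = max(h, w)
    padded = np.zeros((side, side), dtype=float)
    padded[:h, :w] = image
    out = _sk_resize(
        padded, (out_size, out_size), order=3, anti_aliasing=False, mode="edge"
    )
    return out, SliceTransform((h, w), side, out_size / side)


def transform_sample(sample: SliceSample, out_size: int) -> tuple[np.ndarray, dict, SliceTransform]:
    img, tf = preprocess_slice(sample.image, sample.spacing, out_size)
    lms = {}
    for side_name, poly in sample.landmarks.items():
        if poly is not None and poly.present and len(poly):
            lms[side_name] = replace(poly, vertices=tf.forward_points(poly.vertices))
        else:
            lms[side_name] = Polyline.absent(side_name)
    return img, lms, tf


# ---------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------


def _affine_about_centre(shape, scale, theta_deg, tx, ty):
    """Forward map (x, y) -> A (x, y) + t, rotating/scaling about the
    image centre then translating."""
    h, w = shape
    c = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    th = np.deg2rad(theta_deg)
    A = scale * np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    t = c - A @ c + np.array([tx, ty])
    return A, t


def mirror_sample(sample: SliceSample) -> SliceSample:
    """Left/right mirror of a sample: image flipped in x, landmarks
    mirrored and side tags swapped, targets regenerated."""
    h, w = sample.image.shape
    img = sample.image[:, ::-1].copy()
    lms = {}
    for side_name, poly in sample.landmarks.items():
        new_side = "right" if side_name == "left" else "left"
        if poly is not None and poly.present and len(poly):
            v = poly.vertices.copy()
            v[:, 0] = (w - 1) - v[:, 0]
            lms[new_side] = Polyline(v, side=new_side)
        else:
            lms[new_side] = Polyline.absent(new_side)
    return SliceSample(img, lms, targets_for_landmarks(lms, (h, w)), sample.spacing)


def augment(sample: SliceSample, spec: AugmentSpec, rng: np.random.Generator) -> SliceSample:
    """Apply one random augmentation draw.

    Geometric transforms act on the image *and* the landmarks; the target
    planes are regenerated from the transformed landmarks rather than
    warped (warping a unit vector field would break both its norms and its
    directions).  A left/right flip mirrors x and swaps the side tags.
    Photometric transforms (noise, blur) touch only the image.  A side
    whose landmarks leave the frame is marked absent.
    """
    h, w = sample.image.shape
    img = sample.image.astype(float)
    lms = {s: p for s, p in sample.landmarks.items()}

    if spec.lr_flip and rng.random() < 0.5:
        img = img[:, ::-1].copy()
        flipped = {}
        for side_name, poly in lms.items():
            new_side = "right" if side_name == "left" else "left"
            if poly is not None and poly.present and len(poly):
                v = poly.vertices.copy()
                v[:, 0] = (w - 1) - v[:, 0]
                flipped[new_side] = Polyline(v, side=new_side)
            else:
                flipped[new_side] = Polyline.absent(new_side)
        lms = flipped

    scale = 1.0 + rng.uniform(-spec.scale_frac, spec.scale_frac)
    theta = rng.uniform(-spec.rotate_deg, spec.rotate_deg)
    tx = rng.uniform(-spec.translate_frac, spec.translate_frac) * w
    ty = rng.uniform(-spec.translate_frac, spec.translate_frac) * h
    if scale != 1.0 or theta != 0.0 or tx != 0.0 or ty != 0.0:
        A, t = _affine_about_centre((h, w), scale, theta, tx, ty)
        # ndimage maps output index (row, col) through `matrix` to input
        # index, so feed it the inverse in (y, x) order
        Ainv = np.linalg.inv(A)
        M = np.array([[Ainv[1, 1], Ainv[1, 0]], [Ainv[0, 1], Ainv[0, 0]]])
        off = -Ainv @ t
        img = ndimage.affine_transform(
            img, M, offset=(off[1], off[0]), order=1, mode="constant", cval=0.0
        )
        for side_name, poly in list(lms.items()):
            if poly is not None and poly.present and len(poly):
                v = poly.vertices @ A.T + t
                lms[side_name] = Polyline(v, side=side_name)

    for side_name, poly in list(lms.items()):
        if poly is not None and poly.present and len(poly):
            v = poly.vertices
            inside = (
                (v[:, 0] >= 0) & (v[:, 0] <= w - 1) & (v[:, 1] >= 0) & (v[:, 1] <= h - 1)
            )
            if not inside.all():
                lms[side_name] = Polyline.absent(side_name)

    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, img.shape)
    if spec.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, sigma=rng.uniform(0.0, spec.blur_sigma))

    return SliceSample(
        image=img,
        landmarks=lms,
        targets=targets_for_landmarks(lms, (h, w)),
        spacing=sample.spacing,
    )


# ---------------------------------------------------------------------
# Loss
# ---------------------------------------------------------------------


def delineation_loss(
    pred: nn.Tensor,
    target_planes: np.ndarray,
    alpha: float = 10.0,
    field_idx: tuple = FIELD_PLANES,
    heat_idx: tuple = HEAT_PLANES,
):
    """L2 on the vector-field planes plus weighted L2 on the heatmap planes
    (per-pixel weight ``1 + alpha * target``, counteracting the background's
    dominance).  Returns ``(total, field_term, heatmap_term)`` where the
    total is a differentiable scalar and the terms are floats.
    """
    tgt = np.asarray(target_planes, dtype=pred.data.dtype)
    if pred.data.shape != tgt.shape:
        raise ValueError(f"shape mismatch {pred.data.shape} vs {tgt.shape}")
    if not (np.all(np.isfinite(pred.data)) and np.all(np.isfinite(tgt))):
        raise ValueError("non-finite values in loss inputs")
    axis = 0 if pred.data.ndim == 3 else 1
    sel = (slice(None),) * axis

    field_term = nn.Tensor(np.zeros(()))
    if field_idx:
        diff = pred[sel + (list(field_idx),)] - tgt[sel + (list(field_idx),)]
        field_term = (diff**2.0).mean()
    wts = 1.0 + alpha * tgt[sel + (list(heat_idx),)]
    hdiff = pred[sel + (list(heat_idx),)] - tgt[sel + (list(heat_idx),)]
    heat_term = (nn.Tensor(wts) * hdiff**2.0).mean()
    total = field_term + heat_term
    return total, float(field_term.data), float(heat_term.data)


# ---------------------------------------------------------------------
# Network
# ---------------------------------------------------------------------


class _ConvBlock(nn.Module):
    def __init__(self, cin, cout, rng):
        self.c1 = nn.Conv2d(cin, cout, 3, rng=rng)
        self.c2 = nn.Conv2d(cout, cout, 3, rng=rng)

    def __call__(self, x):
        return nn.relu(self.c2(nn.relu(self.c1(x))))


class UNet(nn.Module):
    """Encoder-decoder with skip connections, 1 x S x S -> P x S x S.

    The input image is augmented with two normalised coordinate channels:
    which joint is "left" and which "right" is a function of absolute
    position, which translation-equivariant convolutions cannot otherwise
    see except through border effects.  Heatmap output planes are squashed
    to [0, 1] with a logistic; vector field planes are left linear and
    renormalised at use time.
    """

    def __init__(self, config: DelineatorConfig, heat_planes=HEAT_PLANES):
        rng = np.random.default_rng(config.seed)
        self.config = config
        self.heat_planes = tuple(heat_planes)
        w, d = config.base_width, config.depth
        chans = [w * 2**i for i in range(d + 1)]
        s = config.input_size
        yy, xx = np.mgrid[0:s, 0:s].astype(np.float32) / max(s - 1, 1)
        self._coords = np.stack([xx, yy])  # (2, S, S), in [0, 1]
        self.enc = [
            _ConvBlock(3 if i == 0 else chans[i - 1], chans[i], rng) for i in range(d)
        ]
        self.bottleneck = _ConvBlock(chans[d - 1], chans[d], rng)
        self.up = [nn.Conv2d(chans[i + 1], chans[i], 3, rng=rng) for i in reversed(range(d))]
        self.dec = [_ConvBlock(2 * chans[i], chans[i], rng) for i in reversed(range(d))]
        self.head = nn.Conv2d(chans[0], config.out_planes, 1, rng=rng)
        self._sig_mask = np.zeros(config.out_planes, dtype=bool)
        self._sig_mask[list(self.heat_planes)] = True
        # deterministic head start: zero weights so every seed begins at the
        # same output (field planes 0, heatmaps at background level via the
        # -3 bias) — a randomly scaled head start can consume a large part
        # of a short training budget
        self.head.weight.data[:] = 0.0
        self.head.bias.data[self._sig_mask] = -3.0

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        n = x.data.shape[0]
        coords = np.broadcast_to(self._coords, (n, 2) + self._coords.shape[1:])
        x = nn.concat([x, nn.Tensor(coords.astype(x.data.dtype))], axis=1)
        skips = []
        for blk in self.enc:
            x = blk(x)
            skips.append(x)
            x = nn.avg_pool2d(x, 2)
        x = self.bottleneck(x)
        for upconv, blk, skip in zip(self.up, self.dec, reversed(skips)):
            x = upconv(nn.upsample2x(x))
            x = blk(nn.concat([skip, x], axis=1))
        raw = self.head(x)
        # logistic squash on heatmap planes only, preserving plane order
        pieces, i, n = [], 0, raw.data.shape[1]
        while i < n:
            j = i
            while j < n and self._sig_mask[j] == self._sig_mask[i]:
                j += 1
            block = raw[:, i:j]
            pieces.append(nn.sigmoid(block) if self._sig_mask[i] else block)
            i = j
        return nn.concat(pieces, axis=1) if len(pieces) > 1 else pieces[0]

    def predict_planes(self, image: np.ndarray) -> np.ndarray:
        """Forward a single preprocessed slice, returning (P, S, S)."""
        x = nn.Tensor(image[None, None].astype(np.float32))
        return self(x).data[0].astype(float)


def build_delineator(config: DelineatorConfig) -> UNet:
    if config.out_planes != 8:
        raise ValueError("the delineator regresses exactly 8 planes")
    return UNet(config, heat_planes=HEAT_PLANES)


def build_baseline(config: DelineatorConfig, n_landmarks: int = 21) -> UNet:
    """The naive landmark baseline: one Gaussian heatmap per landmark per
    side (42 planes for 21 landmarks), same backbone."""
    cfg = replace(config, out_planes=2 * n_landmarks)
    return UNet(cfg, heat_planes=tuple(range(cfg.out_planes)))


# ---------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------


def _uvf_target(sample: SliceSample, size: int) -> np.ndarray:
    img, lms, _ = transform_sample(sample, size)
    return targets_for_landmarks(lms, (size, size)).to_planes(), img


def _baseline_target(sample: SliceSample, size: int, n_landmarks: int, sigma: float):
    img, lms, _ = transform_sample(sample, size)
    planes = np.zeros((2 * n_landmarks, size, size))
    for k, side_name in enumerate(("left", "right")):
        poly = lms.get(side_name)
        if poly is None or not poly.present or len(poly) < 2:
            continue
        res = resample_polyline(poly, n_landmarks)
        for i, v in enumerate(res.vertices):
            planes[k * n_landmarks + i] = gaussian_heatmap(v, (size, size), sigma).values
    return planes, img


def baseline_target_planes(
    landmarks: dict, shape: tuple[int, int], n_landmarks: int = 21, sigma: float = 2.0
) -> np.ndarray:
    """21 per-landmark Gaussian heatmap planes per side; annotations with
    fewer vertices are up-sampled by linear (arclength) interpolation."""
    sample = SliceSample(np.zeros(shape), landmarks)
    planes, _ = _baseline_target(sample, shape[0], n_landmarks, sigma)
    return planes


def train_delineator(
    dataset: list[SliceSample],
    config: DelineatorConfig,
    augment_spec: AugmentSpec | None = None,
    val_data: list[SliceSample] | None = None,
    model: UNet | None = None,
    baseline: bool = False,
    baseline_sigma: float = 2.0,
    eval_every: int = 50,
):
    """Train the delineator (or, with ``baseline=True``, the 21-heatmap
    landmark baseline) with Adam.  Returns ``(model, history)`` where
    history holds per-step training losses and periodic validation losses.
    Training stops at ``config.steps`` or earlier when the validation loss
    has not improved for ``config.patience`` evaluations.
    """
    if not dataset:
        raise ValueError("empty training dataset")
    size = config.input_size
    if model is None:
        model = build_baseline(config) if baseline else build_delineator(config)
    n_landmarks = model.config.out_planes // 2 if baseline else None

    def make_xy(sample, rng, spec=None):
        if spec is not None:
            sample = augment(sample, spec, rng)
        if baseline:
            planes, img = _baseline_target(sample, size, n_landmarks, baseline_sigma)
        else:
            planes, img = _uvf_target(sample, size)
        return img.astype(np.float32), planes.astype(np.float32)

    rng = np.random.default_rng(config.seed + 1)
    # left/right flips alone have only two outcomes per sample, so both
    # target sets are prebuilt; richer augmentation rebuilds per draw
    flip_only = augment_spec == AugmentSpec(0.0, 0.0, 0.0, True, 0.0, 0.0)
    cache = flip_cache = None
    if augment_spec is None or flip_only:
        cache = [make_xy(s, rng) for s in dataset]
        if flip_only:
            flip_cache = [make_xy(mirror_sample(s), rng) for s in dataset]
    val_cache = None
    if val_data:
        vrng = np.random.default_rng(config.seed + 2)
        val_cache = [make_xy(s, vrng) for s in val_data]

    opt = nn.Adam(model.parameters(), lr=config.learning_rate,
                  beta1=config.beta1, beta2=config.beta2)
    fidx = () if baseline else FIELD_PLANES
    hidx = tuple(range(model.config.out_planes)) if baseline else HEAT_PLANES
    history = {"train": [], "val": [], "val_steps": []}
    best_val, since_best = np.inf, 0
    order = np.arange(len(dataset))
    pos = len(order)

    for step in range(config.steps):
        batch_idx = []
        for _ in range(min(config.batch_size, len(dataset))):
            if pos >= len(order):
                rng.shuffle(order)
                pos = 0
            batch_idx.append(order[pos])
            pos += 1
        xs, ys = [], []
        for i in batch_idx:
            if cache is None:
                img, planes = make_xy(dataset[i], rng, augment_spec)
            elif flip_cache is not None and rng.random() < 0.5:
                img, planes = flip_cache[i]
            else:
                img, planes = cache[i]
            xs.append(img)
            ys.append(planes)
        x = nn.Tensor(np.asarray(xs, dtype=np.float32)[:, None])
        y = np.asarray(ys, dtype=np.float32)
        pred = model(x)
        loss, _, _ = delineation_loss(
            pred, y, config.heatmap_weight_alpha, fidx, hidx
        )
        if config.lr_schedule == "cosine":
            opt.lr = config.learning_rate * (
                0.05 + 0.95 * 0.5 * (1 + np.cos(np.pi * step / config.steps))
            )
        opt.zero_grad()
        loss.backward()
        opt.step()
        history["train"].append(float(loss.data))

        if val_cache and (step + 1) % eval_every == 0:
            vs = []
            for img, planes in val_cache:
                p = model(nn.Tensor(img[None, None].astype(np.float32)))
                lv, _, _ = delineation_loss(
                    p, planes[None].astype(np.float32),
                    config.heatmap_weight_alpha, fidx, hidx,
                )
                vs.append(float(lv.data))
            v = float(np.mean(vs))
            history["val"].append(v)
            history["val_steps"].append(step + 1)
            if v < best_val - 1e-6:
                best_val, since_best = v, 0
            else:
                since_best += 1
                if since_best >= config.patience:
                    break
    return model, history


# ---------------------------------------------------------------------
# Inference
# ---------------------------------------------------------------------


def planes_to_targets(planes: np.ndarray) -> ContourTargets:
    """Interpret predicted 8 planes: renormalise the field components to
    unit vectors, wrap heatmap planes with their argmax peak and a sigma
    estimated from the heatmap mass (for a unit-peak Gaussian the mass is
    ~2*pi*sigma^2)."""
    from .contour import SideTargets  # local import to keep namespace tidy

    def norm_field(ux, uy):
        n = np.hypot(ux, uy)
        n = np.where(n < 1e-8, 1.0, n)
        return VectorField2D(ux / n, uy / n)

    def wrap_heat(vals):
        vals = np.clip(vals, 0.0, None)
        sigma = float(np.sqrt(max(vals.sum(), 1e-6) / (2 * np.pi)))
        iy, ix = np.unravel_index(int(np.argmax(vals)), vals.shape)
        return Heatmap(vals, np.array([float(ix), float(iy)]), max(sigma, 0.5))

    sides = []
    for off in (0, 4):
        fld = norm_field(planes[off], planes[off + 1])
        sides.append(
            SideTargets(fld, wrap_heat(planes[off + 2]), wrap_heat(planes[off + 3]))
        )
    return ContourTargets(sides[0], sides[1])


def _unmirror_planes(planes: np.ndarray) -> np.ndarray:
    """Map the 8 planes predicted on a mirrored image back to the original
    frame: flip x, swap the left/right channel groups, negate ux."""
    p = planes[:, :, ::-1]
    out = np.concatenate([p[4:8], p[0:4]])
    out = out.copy()
    out[0] = -out[0]
    out[4] = -out[4]
    return out


def predict_planes_tta(model: "UNet", image: np.ndarray) -> np.ndarray:
    """Average the model's planes over the left/right mirror symmetry:
    predict on the image and its mirror, map the mirrored prediction back,
    and take the mean.  Suppresses side-assignment modes that are not
    mirror-consistent."""
    direct = model.predict_planes(image)
    mirrored = model.predict_planes(np.ascontiguousarray(image[:, ::-1]))
    return 0.5 * (direct + _unmirror_planes(mirrored))


def extract_contours_from_planes(
    planes: np.ndarray, walk: WalkParams | None = None
) -> dict:
    """Walk each side's predicted field between its predicted endpoints.

    Presence is endpoint-symmetric — a joint counts as present when
    *either* endpoint heatmap clears the presence threshold — because a
    visible joint produces both endpoint signals and a short-budget model
    occasionally trains one of the two much faster than the other.  An
    uncertain source heatmap can be multimodal, so walks start from up to
    ``n_starts`` local maxima and the best contour wins: converged beats
    non-converged, longer arc length beats shorter (a walk entering the
    field's contour corridor midway is necessarily shorter than one
    entering at the true source).
    """
    from dataclasses import replace as _replace

    walk = walk or WalkParams()
    tg = planes_to_targets(planes)
    out = {}
    for side_name, st in (("left", tg.left), ("right", tg.right)):
        src_peak = float(st.source.values.max(initial=0.0))
        snk_peak = float(st.sink.values.max(initial=0.0))
        if max(src_peak, snk_peak) < walk.presence_threshold:
            out[side_name] = Polyline.absent(side_name)
            continue
        unguarded = _replace(walk, presence_threshold=0.0)
        candidates = []
        for peak in _local_maxima(st.source.values, n_starts=3):
            src = Heatmap(st.source.values, peak, st.source.sigma)
            walked = walk_contour(st.field, _ArgmaxAt(src, peak), st.sink,
                                  unguarded, side=side_name)
            if walked.present and len(walked) > 1:
                candidates.append(walked)
        if not candidates:
            out[side_name] = Polyline.absent(side_name)
            continue
        out[side_name] = max(
            candidates, key=lambda p: (p.converged, p.length())
        )
    return out


def _local_maxima(values: np.ndarray, n_starts: int = 3, min_rel: float = 0.2):
    """Up to ``n_starts`` local maxima of a heatmap plane, strongest first,
    keeping only peaks above ``min_rel`` of the global maximum."""
    peak = values.max()
    if peak <= 0:
        return []
    mask = (values == ndimage.maximum_filter(values, size=7)) & (
        values >= min_rel * peak
    )
    ys, xs = np.nonzero(mask)
    order = np.argsort(values[ys, xs])[::-1][:n_starts]
    return [np.array([float(xs[i]), float(ys[i])]) for i in order]


class _ArgmaxAt:
    """Heatmap proxy whose argmax is pinned to a chosen local maximum."""

    def __init__(self, heatmap: Heatmap, peak: np.ndarray):
        self.values = heatmap.values
        self.sigma = heatmap.sigma
        self._peak = np.asarray(peak, dtype=float)

    @property
    def shape(self):
        return self.values.shape

    def argmax_point(self) -> np.ndarray:
        return self._peak.copy()


def delineate_volume(
    model: UNet,
    volume: np.ndarray,
    walk: WalkParams | None = None,
    spacing: float = 1.0,
    mirror_tta: bool = True,
) -> list[dict]:
    """Run the full per-slice pipeline on a (slices, H, W) volume:
    preprocess, predict the 8 planes (averaged over the left/right mirror
    by default), walk each side's field, and map the contours back to
    native pixel coordinates."""
    volume = np.asarray(volume, dtype=float)
    if volume.ndim != 3 or volume.shape[0] < 1:
        raise ValueError("expected a (slices, H, W) volume")
    size = model.config.input_size
    results = []
    for sl in volume:
        img, tf = preprocess_slice(normalize_intensity(sl), spacing, size)
        planes = predict_planes_tta(model, img) if mirror_tta else model.predict_planes(img)
        contours = extract_contours_from_planes(planes, walk)
        native = {}
        for side_name, poly in contours.items():
            if poly.present and len(poly):
                native[side_name] = replace(
                    poly, vertices=tf.inverse_points(poly.vertices)
                )
            else:
                native[side_name] = poly
        # the side labels are positional by definition: the left SIJ is the
        # joint at smaller x.  Project the pair onto that ordering in case
        # the network's channel assignment settled on the swap.
        lt, rt = native["left"], native["right"]
        if (
            lt.present and rt.present and len(lt) and len(rt)
            and lt.vertices[:, 0].mean() > rt.vertices[:, 0].mean()
        ):
            native["left"] = replace(rt, side="left")
            native["right"] = replace(lt, side="right")
        results.append(native)
    return results


def baseline_landmarks(
    model21: UNet, image: np.ndarray, presence_threshold: float = 0.3
) -> dict:
    """Decode the baseline's per-plane argmaxes into one 21-vertex polyline
    per side (plane order is landmark order)."""
    planes = model21.predict_planes(image)
    n = planes.shape[0] // 2
    out = {}
    for k, side_name in enumerate(("left", "right")):
        block = planes[k * n : (k + 1) * n]
        if block.max() < presence_threshold:
            out[side_name] = Polyline.absent(side_name)
            continue
        verts = []
        for plane in block:
            iy, ix = np.unravel_index(int(np.argmax(plane)), plane.shape)
            verts.append([float(ix), float(iy)])
        out[side_name] = Polyline(np.array(verts), side=side_name)
    return out
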