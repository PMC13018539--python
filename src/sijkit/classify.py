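"""Dual-sequence SIJ lesion classification with multi-reader training.

One convolutional encoder processes every T1-weighted and STIR slice of an
SIJ ROI; slice embeddings are pooled per sequence, the two pooled
embeddings concatenated, and 14 task-specific linear heads produce one
binary prediction per lesion task (3 quadrant lesions x 4 quadrants + 2
joint-level lesions).  Each task owns a consensus tree of rank-1 annotator
matrices and is trained with the multi-reader loss; at inference the root
(inter-consensus) prediction is used.  Evaluation reports AUC (rank
statistic), balanced accuracy, sensitivity and specificity on the subset
of samples carrying an inter-reader consensus label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from skimage.transform import resize as _sk_resize

from . import nn
from .multireader import ConsensusTree, LabelTable, PredictionBundle, multireader_batch_loss
from .roi import RoiPair


# ---------------------------------------------------------------------
# Task structure
# ---------------------------------------------------------------------

QUADRANTS = ("upper_ilium", "lower_ilium", "upper_sacrum", "lower_sacrum")
QUADRANT_LESIONS = ("oedema", "fatty", "erosion")
JOINT_LESIONS = ("sclerosis", "ankylosis")


@dataclass(frozen=True)
class LesionTaskSpec:
    """The 14 binary prediction tasks of one SIJ: bone-marrow oedema,
    fatty lesions and erosions at quadrant level, sclerosis and ankylosis
    at joint level."""

    quadrant_lesions: tuple = QUADRANT_LESIONS
    quadrants: tuple = QUADRANTS
    joint_lesions: tuple = JOINT_LESIONS

    def task_ids(self) -> list[str]:
        ids = [
            f"{lesion}:{quadrant}"
            for lesion in self.quadrant_lesions
            for quadrant in self.quadrants
        ]
        ids += list(self.joint_lesions)
        return ids

    @property
    def heads_per_sij(self) -> int:
        return len(self.quadrant_lesions) * len(self.quadrants) + len(self.joint_lesions)

    @property
    def heads_per_pair(self) -> int:
        return 2 * self.heads_per_sij

    def lesion_of(self, task_id: str) -> str:
        return task_id.split(":")[0]


@dataclass
class ClassifierConfig:
    """Encoder/training configuration.  The desk profile (default sizes
    here) is a shallow CPU-friendly stand-in for the full ResNet-style
    encoder topology; ``checkpoint`` allows warm-starting encoder weights."""

    crop_size: int = 32
    width: int = 8
    embed_dim: int = 64
    pooling: str = "mean"  # "mean" | "max" over slices
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    steps: int = 400
    batch_size: int = 16
    threshold: float = 0.5
    lam: float = 1.0
    seed: int = 0
    checkpoint: str | None = None

    def __post_init__(self):
        if self.pooling not in ("mean", "max"):
            raise ValueError("pooling must be 'mean' or 'max'")


@dataclass
class MetricsReport:
    task_id: str
    auc: float | None
    balanced_accuracy: float
    sensitivity: float
    specificity: float
    n: int
    threshold: float
    auc_undefined: bool = False


@dataclass
class FoldAssignment:
    folds: dict  # subject -> fold index
    k: int

    def subjects_in_fold(self, i: int) -> list:
        return [s for s, f in self.folds.items() if f == i]


# ---------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------


class SliceEncoder(nn.Module):
    """Three conv/pool stages and a linear projection: one slice
    (1, S, S) -> one embedding."""

    def __init__(self, config: ClassifierConfig, rng):
        w, s = config.width, config.crop_size
        if s % 8:
            raise ValueError("crop_size must be divisible by 8")
        self.c1 = nn.Conv2d(1, w, 3, rng=rng)
        self.c2 = nn.Conv2d(w, 2 * w, 3, rng=rng)
        self.c3 = nn.Conv2d(2 * w, 4 * w, 3, rng=rng)
        self._feat = 4 * w * (s // 8) ** 2
        # the final feature map is flattened, not pooled away: quadrant-level
        # heads need to know where in the joint a signal sits
        self.proj = nn.Linear(self._feat, config.embed_dim, rng=rng)

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        x = nn.avg_pool2d(nn.relu(self.c1(x)), 2)
        x = nn.avg_pool2d(nn.relu(self.c2(x)), 2)
        x = nn.avg_pool2d(nn.relu(self.c3(x)), 2)
        n = x.data.shape[0]
        return self.proj(x.reshape(n, self._feat))


class SIJClassifier(nn.Module):
    """Shared dual-sequence encoder, 14 task heads, one consensus tree of
    annotator matrices per task."""

    def __init__(
        self,
        config: ClassifierConfig,
        task_spec: LesionTaskSpec | None = None,
        n_readers: int = 2,
        n_sessions: int = 3,
    ):
        rng = np.random.default_rng(config.seed)
        self.config = config
        self.task_spec = task_spec or LesionTaskSpec()
        self.task_ids = self.task_spec.task_ids()
        self.encoder = SliceEncoder(config, rng)
        self.heads = [
            nn.Linear(2 * config.embed_dim, 2, rng=rng) for _ in self.task_ids
        ]
        self.trees = {
            tid: ConsensusTree(n_readers, n_sessions, seed=config.seed + i)
            for i, tid in enumerate(self.task_ids)
        }

    def parameters(self):
        params = self.encoder.parameters()
        for h in self.heads:
            params.extend(h.parameters())
        for t in self.trees.values():
            params.extend(t.parameters())
        return params

    def tree(self, task_id: str) -> ConsensusTree:
        return self.trees[task_id]


def prepare_roi_slices(roi: np.ndarray, crop_size: int) -> np.ndarray:
    """Resize each slice of a (slices, H, W) ROI to the encoder input size
    and robust-normalise intensities over the crop volume."""
    roi = np.asarray(roi, dtype=float)
    if roi.ndim != 3 or roi.shape[0] < 1:
        raise ValueError("expected a non-empty (slices, H, W) ROI volume")
    # inverted_cdf is a pure order statistic: normalisation is then exactly
    # invariant under slice duplication
    lo, hi = np.percentile(roi, [1.0, 99.0], method="inverted_cdf")
    roi = np.clip((roi - lo) / max(hi - lo, 1e-9), 0.0, 1.0)
    out = np.stack(
        [
            _sk_resize(sl, (crop_size, crop_size), order=1, anti_aliasing=False)
            for sl in roi
        ]
    )
    return out.astype(np.float32)


def encode_roi(model: SIJClassifier, roi: np.ndarray) -> np.ndarray:
    """Encode every slice independently and pool to one embedding with the
    configured pooling (mean by default)."""
    slices = prepare_roi_slices(roi, model.config.crop_size)
    emb = model.encoder(nn.Tensor(slices[:, None])).data
    if model.config.pooling == "max":
        return emb.max(axis=0)
    return emb.mean(axis=0)


def predict_lesions(model: SIJClassifier, pair: RoiPair) -> dict:
    """All 14 task predictions for one SIJ ROI pair: per task the base
    simplex and the full branched :class:`PredictionBundle`."""
    if pair.t1_crop is None or pair.stir_crop is None:
        raise ValueError("RoiPair must carry both sequences")
    e = np.concatenate([encode_roi(model, pair.t1_crop), encode_roi(model, pair.stir_crop)])
    out = {}
    for tid, head in zip(model.task_ids, model.heads):
        logits = head(nn.Tensor(e[None].astype(np.float32)))
        p = nn.softmax(logits, axis=1).data[0].astype(float)
        p = p / p.sum()
        node_preds = model.trees[tid].branch_t(nn.Tensor(p[None]))
        out[tid] = PredictionBundle(
            base=p, nodes={k: v.data[0].astype(float) for k, v in node_preds.items()}
        )
    return out


# ---------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------


def _pool_matrix(counts: list[int], pooling: str) -> np.ndarray:
    if pooling != "mean":
        raise ValueError("batched training supports mean pooling")
    P = np.zeros((len(counts), int(np.sum(counts))), dtype=np.float32)
    off = 0
    for i, c in enumerate(counts):
        P[i, off : off + c] = 1.0 / c
        off += c
    return P


def train_classifier(
    dataset: list[tuple],
    config: ClassifierConfig,
    label_table: LabelTable,
    task_spec: LesionTaskSpec | None = None,
    model: SIJClassifier | None = None,
):
    """Train the classifier with the multi-reader loss.

    ``dataset`` is a list of ``(sample_id, RoiPair)``; labels are looked up
    in ``label_table`` per sample and task.  The batch objective is the
    summed node cross-entropies plus ``lam`` times the summed annotator
    traces (entering once per batch), scaled by 1/batch for a stable step
    size.  Returns ``(model, history)``.
    """
    if not dataset:
        raise ValueError("empty training dataset")
    task_spec = task_spec or LesionTaskSpec()
    label_table.compute_consensus()
    if model is None:
        model = SIJClassifier(
            config,
            task_spec,
            n_readers=label_table.n_readers,
            n_sessions=label_table.n_sessions,
        )
        if config.checkpoint:
            model.encoder.load_state_dict(
                list(np.load(config.checkpoint, allow_pickle=True)["state"])
            )

    sample_ids = [sid for sid, _ in dataset]
    slices = []
    counts = []
    for _, pair in dataset:
        t1 = prepare_roi_slices(pair.t1_crop, config.crop_size)
        st = prepare_roi_slices(pair.stir_crop, config.crop_size)
        slices.append((t1, st))
        counts.append((t1.shape[0], st.shape[0]))
    label_mats = {
        tid: label_table.node_label_matrix(sample_ids, tid, model.trees[tid])
        for tid in model.task_ids
    }

    rng = np.random.default_rng(config.seed + 1)
    opt = nn.Adam(model.parameters(), lr=config.learning_rate,
                  beta1=config.beta1, beta2=config.beta2)
    history = {"train": []}
    order = np.arange(len(dataset))
    pos = len(order)
    for _ in range(config.steps):
        batch = []
        for _ in range(min(config.batch_size, len(dataset))):
            if pos >= len(order):
                rng.shuffle(order)
                pos = 0
            batch.append(int(order[pos]))
            pos += 1
        t1_stack = np.concatenate([slices[i][0] for i in batch])
        st_stack = np.concatenate([slices[i][1] for i in batch])
        P1 = _pool_matrix([counts[i][0] for i in batch], config.pooling)
        P2 = _pool_matrix([counts[i][1] for i in batch], config.pooling)
        e1 = nn.Tensor(P1) @ model.encoder(nn.Tensor(t1_stack[:, None]))
        e2 = nn.Tensor(P2) @ model.encoder(nn.Tensor(st_stack[:, None]))
        emb = nn.concat([e1, e2], axis=1)
        total = nn.Tensor(np.zeros(()))
        for tid, head in zip(model.task_ids, model.heads):
            p = nn.softmax(head(emb), axis=1)
            lm = label_mats[tid][batch]
            t, _, _ = multireader_batch_loss(p, lm, model.trees[tid], config.lam)
            total = total + t
        total = total * (1.0 / len(batch))
        opt.zero_grad()
        total.backward()
        opt.step()
        history["train"].append(float(total.data))
    return model, history


# ---------------------------------------------------------------------
# Cross-validation & metrics
# ---------------------------------------------------------------------


def crossval_split(subjects, k: int, seed: int = 0) -> FoldAssignment:
    """Seeded per-subject k-fold partition; every scan of a subject shares
    its subject's fold, and fold sizes differ by at most one."""
    subjects = list(dict.fromkeys(subjects))
    if k > len(subjects):
        raise ValueError("more folds than subjects")
    rng = np.random.default_rng(seed)
    order = list(subjects)
    rng.shuffle(order)
    return FoldAssignment({s: i % k for i, s in enumerate(order)}, k)


def rank_auc(scores, labels) -> float:
    """Mann-Whitney AUC with ties averaged."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("AUC undefined: one class absent")
    r = rankdata(scores)
    return float((r[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n0 * n1))


def evaluate(
    scores, labels, threshold: float = 0.5, task_id: str = ""
) -> MetricsReport:
    """AUC/BA/sensitivity/specificity of positive-class scores against
    binary (consensus) labels at the given operating threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be aligned 1D arrays")
    pos = labels == 1
    pred_pos = scores >= threshold
    tp = int((pred_pos & pos).sum())
    tn = int((~pred_pos & ~pos).sum())
    sens = tp / max(int(pos.sum()), 1)
    spec = tn / max(int((~pos).sum()), 1)
    try:
        auc = rank_auc(scores, labels)
        undefined = False
    except ValueError:
        auc, undefined = None, True
    return MetricsReport(
        task_id=task_id,
        auc=auc,
        balanced_accuracy=(sens + spec) / 2.0,
        sensitivity=sens,
        specificity=spec,
        n=len(labels),
        threshold=threshold,
        auc_undefined=undefined,
    )


def evaluate_predictions(
    pred_df: pd.DataFrame, label_table: LabelTable, threshold: float = 0.5
) -> dict:
    """Per-task metrics of root-node positive probabilities against
    inter-reader consensus labels.  ``pred_df`` needs columns sample_id,
    task_id, p_positive; samples without a consensus label are excluded."""
    inter = label_table.compute_consensus().inter_consensus_frame()
    merged = pred_df.merge(inter, on=["sample_id", "task_id"], how="inner")
    out = {}
    for tid, grp in merged.groupby("task_id"):
        out[tid] = evaluate(
            grp["p_positive"].to_numpy(), grp["label"].to_numpy(), threshold, tid
        )
    return out


def evaluate_by_lesion(
    pred_df: pd.DataFrame,
    label_table: LabelTable,
    threshold: float = 0.5,
    task_spec: LesionTaskSpec | None = None,
) -> dict:
    """One metrics row per lesion type, pooling a lesion's quadrant tasks
    into a single score/label set (joint-level lesions are single tasks)."""
    task_spec = task_spec or LesionTaskSpec()
    inter = label_table.compute_consensus().inter_consensus_frame()
    merged = pred_df.merge(inter, on=["sample_id", "task_id"], how="inner")
    merged["lesion"] = merged["task_id"].map(task_spec.lesion_of)
    out = {}
    for lesion, grp in merged.groupby("lesion"):
        out[lesion] = evaluate(
            grp["p_positive"].to_numpy(), grp["label"].to_numpy(), threshold, lesion
        )
    return out


def predictions_frame(model: SIJClassifier, dataset: list[tuple]) -> pd.DataFrame:
    """Root-node positive probability per sample and task."""
    rows = []
    for sid, pair in dataset:
        bundles = predict_lesions(model, pair)
        for tid, bundle in bundles.items():
            root = bundle.nodes[model.trees[tid].root_id]
            rows.append(
                {"sample_id": sid, "task_id": tid, "p_positive": float(root[1])}
            )
    return pd.DataFrame(rows)
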