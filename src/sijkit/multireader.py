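"""Hierarchical multi-reader learning.

Clinical-trial lesion labels come from several expert readers, each reading
the data at several blinded sessions.  Instead of collapsing these into a
single noisy target, a base prediction p is branched through a tree of
*annotator matrices*: the root models the inter-reader consensus, its
children the per-reader consensus, and their children the individual read
sessions.  Each annotator is a rank-1 perturbation of the identity,

    A = a (x) b   (outer product),   B = I + A,   p_node = norm(B p_parent),

a LoRA-like rank-1 parameterisation of a confusion matrix.  Training
minimises cross-entropy of each node's prediction against the label that
node represents (raw session labels at the leaves, intra-reader consensus
at reader nodes, inter-reader consensus at the root) plus the sum of the
traces of all annotator matrices:

    L = L_CE + sum_i tr(A_i),   i over all tree nodes.

At inference the root prediction is the best estimate against
inter-consensus ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import nn

MISSING = -1


# ---------------------------------------------------------------------
# Rank-1 annotators
# ---------------------------------------------------------------------


def rank1_matrix(a, b) -> np.ndarray:
    """Outer product A[i, j] = a[i] * b[j]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be 1D vectors of equal length")
    return np.outer(a, b)


class AnnotatorNode(nn.Module):
    """One tree node: two learnable vectors a, b of dimension C, squashed
    through ``0.5 * tanh`` so entries stay in (-0.5, 0.5), keeping B = I + A
    near the identity and the trace regulariser bounded.

    Initialisation is LoRA-style: ``a`` small random, ``b`` zero, so the
    node starts as the exact identity annotator (A = 0, trace 0) while
    gradients can still flow — at a = b = 0 the bilinear product is a
    saddle with zero gradient on both factors."""

    def __init__(self, node_id: str, n_classes: int = 2,
                 rng: np.random.Generator | None = None, init_scale: float = 0.1):
        self.node_id = node_id
        self.n_classes = n_classes
        if rng is None or init_scale == 0.0:
            self.raw_a = nn.Parameter(np.zeros(n_classes))
        else:
            self.raw_a = nn.Parameter(rng.normal(0.0, init_scale, n_classes))
        self.raw_b = nn.Parameter(np.zeros(n_classes))

    # differentiable views -------------------------------------------
    def vec_a(self) -> nn.Tensor:
        return nn.tanh(self.raw_a) * 0.5

    def vec_b(self) -> nn.Tensor:
        return nn.tanh(self.raw_b) * 0.5

    def matrix_t(self) -> nn.Tensor:
        a = self.vec_a().reshape(self.n_classes, 1)
        b = self.vec_b().reshape(1, self.n_classes)
        return a @ b

    def trace_t(self) -> nn.Tensor:
        return (self.vec_a() * self.vec_b()).sum()

    def apply_t(self, p: nn.Tensor, clamp: float = 1e-6) -> nn.Tensor:
        """Batched (N, C) simplex -> (N, C) simplex: q = (I + A) p, clamped
        to >= ``clamp`` and renormalised."""
        B = self.matrix_t() + np.eye(self.n_classes)
        q = (p @ B.transpose((1, 0))).clip_min(clamp)
        return q / q.sum(axis=1, keepdims=True)

    # numpy views -----------------------------------------------------
    @property
    def a(self) -> np.ndarray:
        return 0.5 * np.tanh(self.raw_a.data)

    @property
    def b(self) -> np.ndarray:
        return 0.5 * np.tanh(self.raw_b.data)

    @property
    def A(self) -> np.ndarray:
        return rank1_matrix(self.a, self.b)

    @property
    def B(self) -> np.ndarray:
        return np.eye(self.n_classes) + self.A

    def trace(self) -> float:
        return float(np.dot(self.a, self.b))

    def set_vectors(self, a, b) -> None:
        """Set a and b directly (values must lie strictly in (-0.5, 0.5))."""
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if np.any(np.abs(a) >= 0.5) or np.any(np.abs(b) >= 0.5):
            raise ValueError("annotator vector entries must lie in (-0.5, 0.5)")
        self.raw_a.data = np.arctanh(2.0 * a)
        self.raw_b.data = np.arctanh(2.0 * b)


def _validate_simplex(p: np.ndarray, tol: float = 1e-4) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if np.any(p < -tol) or abs(p.sum() - 1.0) > tol:
        raise ValueError("input is not on the probability simplex")
    return p


def apply_annotator(node: AnnotatorNode, p, clamp: float = 1e-6) -> np.ndarray:
    """q = (I + A) p, clamped and renormalised (single numpy simplex)."""
    p = _validate_simplex(p)
    q = np.maximum(node.B @ p, clamp)
    return q / q.sum()


# ---------------------------------------------------------------------
# Consensus tree
# ---------------------------------------------------------------------


@dataclass
class PredictionBundle:
    base: np.ndarray
    nodes: dict  # node_id -> simplex (np.ndarray)


class ConsensusTree(nn.Module):
    """Annotator nodes arranged by label-consensus hierarchy.

    For R readers and S > 1 sessions the node set is
    {root} u {R<r>} u {R<r>S<s>} (9 nodes for R=2, S=3).  With a single
    session the reader level collapses into the root's children (R=3, S=1:
    root + 3 reader nodes).
    """

    def __init__(self, n_readers: int = 2, n_sessions: int = 3, n_classes: int = 2,
                 seed: int = 0):
        if n_readers < 2 or n_sessions < 1:
            raise ValueError("need at least two readers and one session")
        self.n_readers = n_readers
        self.n_sessions = n_sessions
        self.n_classes = n_classes
        rng = np.random.default_rng(seed)
        self.root_id = "".join(f"R{r}" for r in range(1, n_readers + 1))
        self.root = AnnotatorNode(self.root_id, n_classes, rng)
        self.readers = {
            f"R{r}": AnnotatorNode(f"R{r}", n_classes, rng)
            for r in range(1, n_readers + 1)
        }
        self.sessions = {}
        if n_sessions > 1:
            for r in range(1, n_readers + 1):
                for s in range(1, n_sessions + 1):
                    nid = f"R{r}S{s}"
                    self.sessions[nid] = AnnotatorNode(nid, n_classes, rng)
        self._modules = [self.root] + list(self.readers.values()) + list(
            self.sessions.values()
        )

    @property
    def node_ids(self) -> list[str]:
        return [self.root_id] + list(self.readers) + list(self.sessions)

    def node(self, node_id: str) -> AnnotatorNode:
        if node_id == self.root_id:
            return self.root
        if node_id in self.readers:
            return self.readers[node_id]
        return self.sessions[node_id]

    def parameters(self):
        params = []
        for m in self._modules:
            params.extend(m.parameters())
        return params

    # -- branching -----------------------------------------------------
    def branch_t(self, p: nn.Tensor) -> dict:
        """Differentiable branch of a batched (N, C) base prediction into
        all node predictions."""
        out = {}
        p_root = self.root.apply_t(p)
        out[self.root_id] = p_root
        for rid, rnode in self.readers.items():
            p_r = rnode.apply_t(p_root)
            out[rid] = p_r
            for s in range(1, self.n_sessions + 1):
                nid = f"{rid}S{s}"
                if nid in self.sessions:
                    out[nid] = self.sessions[nid].apply_t(p_r)
        return out

    def trace_sum_t(self) -> nn.Tensor:
        total = nn.Tensor(np.zeros(()))
        for nid in self.node_ids:
            total = total + self.node(nid).trace_t()
        return total

    def trace_sum(self) -> float:
        return float(sum(self.node(nid).trace() for nid in self.node_ids))


def branch_predictions(p, tree: ConsensusTree) -> PredictionBundle:
    """Branch a single base simplex through the tree (root, then readers,
    then sessions) and return every node's prediction."""
    p = _validate_simplex(p)
    node_preds = tree.branch_t(nn.Tensor(p[None]))
    return PredictionBundle(
        base=p.copy(), nodes={k: v.data[0].copy() for k, v in node_preds.items()}
    )


def consensus_inference(bundle: PredictionBundle) -> np.ndarray:
    """The root (inter-reader consensus) prediction — the pipeline's best
    estimate when judged against inter-consensus labels."""
    root_id = max(bundle.nodes, key=len) if bundle.nodes else None
    # the root has the longest id (R1R2... vs R1 vs R1S1 of length 4);
    # resolve explicitly to avoid surprises:
    for nid in bundle.nodes:
        if nid.count("R") > 1:
            root_id = nid
            break
    return np.asarray(bundle.nodes[root_id], dtype=float)


# ---------------------------------------------------------------------
# Label tables and consensus labels
# ---------------------------------------------------------------------


class LabelTable:
    """Binary reader labels, one row per (sample, task, reader, session),
    with derived intra-reader and inter-reader consensus labels.

    Intra-reader consensus exists where a reader agrees with themselves at
    every session; inter-reader consensus exists where both (all) readers
    agree at every session.  Adding a disagreeing session can only turn a
    consensus value into missing, never change it.
    """

    COLUMNS = ("sample_id", "task_id", "reader", "session", "label")

    def __init__(self, df: pd.DataFrame):
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"label table missing columns: {sorted(missing)}")
        df = df.loc[:, list(self.COLUMNS)].copy()
        if not df["label"].isin([0, 1]).all():
            raise ValueError("labels must be binary (0/1)")
        if df.duplicated(["sample_id", "task_id", "reader", "session"]).any():
            raise ValueError("duplicate (sample, task, reader, session) entries")
        self.df = df.reset_index(drop=True)
        self._intra = None
        self._inter = None

    @property
    def n_readers(self) -> int:
        return int(self.df["reader"].nunique())

    @property
    def n_sessions(self) -> int:
        return int(self.df["session"].nunique())

    def compute_consensus(self) -> "LabelTable":
        """Fill the derived consensus frames (idempotent)."""
        S, R = self.n_sessions, self.n_readers
        g = self.df.groupby(["sample_id", "task_id", "reader"])["label"].agg(
            ["count", "min", "max"]
        )
        intra = g[(g["count"] == S) & (g["min"] == g["max"])]["min"].rename("label")
        self._intra = intra.reset_index()
        g2 = self.df.groupby(["sample_id", "task_id"])["label"].agg(
            ["count", "min", "max"]
        )
        inter = g2[(g2["count"] == R * S) & (g2["min"] == g2["max"])]["min"].rename(
            "label"
        )
        self._inter = inter.reset_index()
        return self

    def _ensure(self):
        if self._intra is None:
            self.compute_consensus()

    def intra_consensus(self, sample_id, task_id, reader) -> int | None:
        self._ensure()
        m = self._intra[
            (self._intra.sample_id == sample_id)
            & (self._intra.task_id == task_id)
            & (self._intra.reader == reader)
        ]
        return int(m.label.iloc[0]) if len(m) else None

    def inter_consensus(self, sample_id, task_id) -> int | None:
        self._ensure()
        m = self._inter[
            (self._inter.sample_id == sample_id) & (self._inter.task_id == task_id)
        ]
        return int(m.label.iloc[0]) if len(m) else None

    def inter_consensus_frame(self) -> pd.DataFrame:
        self._ensure()
        return self._inter.copy()

    def intra_consensus_frame(self) -> pd.DataFrame:
        self._ensure()
        return self._intra.copy()

    def node_labels(self, sample_id, task_id, tree: ConsensusTree) -> dict:
        """Labels available per tree node for one sample-task: raw session
        labels at session nodes (or reader nodes when S = 1), intra-reader
        consensus at reader nodes, inter-reader consensus at the root."""
        self._ensure()
        out = {}
        sub = self.df[(self.df.sample_id == sample_id) & (self.df.task_id == task_id)]
        for _, row in sub.iterrows():
            nid = (
                f"R{int(row.reader)}S{int(row.session)}"
                if tree.n_sessions > 1
                else f"R{int(row.reader)}"
            )
            if nid in tree.node_ids:
                out[nid] = int(row.label)
        if tree.n_sessions > 1:
            for r in range(1, tree.n_readers + 1):
                v = self.intra_consensus(sample_id, task_id, r)
                if v is not None:
                    out[f"R{r}"] = v
        v = self.inter_consensus(sample_id, task_id)
        if v is not None:
            out[tree.root_id] = v
        return out

    def node_label_matrix(self, sample_ids, task_id, tree: ConsensusTree) -> np.ndarray:
        """(n_samples, n_nodes) int matrix of node labels, MISSING where
        unavailable, in ``tree.node_ids`` order — the batched counterpart
        of :meth:`node_labels`."""
        self._ensure()
        ids = list(tree.node_ids)
        col = {nid: j for j, nid in enumerate(ids)}
        srow = {sid: i for i, sid in enumerate(sample_ids)}
        M = np.full((len(sample_ids), len(ids)), MISSING, dtype=int)
        sub = self.df[(self.df.task_id == task_id) & self.df.sample_id.isin(srow)]
        for _, row in sub.iterrows():
            nid = (
                f"R{int(row.reader)}S{int(row.session)}"
                if tree.n_sessions > 1
                else f"R{int(row.reader)}"
            )
            if nid in col:
                M[srow[row.sample_id], col[nid]] = int(row.label)
        if tree.n_sessions > 1:
            sub = self._intra[self._intra.task_id == task_id]
            for _, row in sub.iterrows():
                if row.sample_id in srow and f"R{int(row.reader)}" in col:
                    M[srow[row.sample_id], col[f"R{int(row.reader)}"]] = int(row.label)
        sub = self._inter[self._inter.task_id == task_id]
        for _, row in sub.iterrows():
            if row.sample_id in srow:
                M[srow[row.sample_id], col[tree.root_id]] = int(row.label)
        return M

    def to_csv(self, path) -> None:
        self.df.sort_values(list(self.COLUMNS)).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "LabelTable":
        return cls(pd.read_csv(path))


# ---------------------------------------------------------------------
# Loss
# ---------------------------------------------------------------------


@dataclass
class LossReport:
    total: float
    ce: float
    trace: float
    per_node_ce: dict
    no_labels: bool = False
    total_t: nn.Tensor | None = None  # differentiable total, when requested


def _ce(p: np.ndarray, label: int) -> float:
    return float(-np.log(max(p[label], 1e-12)))


def multireader_loss(
    bundle: PredictionBundle,
    labels: dict,
    tree: ConsensusTree,
    lam: float = 1.0,
) -> LossReport:
    """Per sample-task loss: cross-entropy of each node prediction against
    that node's available label, plus ``lam`` times the sum of annotator
    traces over all tree nodes.  ``labels`` maps node_id -> 0/1 (e.g. from
    :meth:`LabelTable.node_labels`)."""
    per_node = {}
    for nid, lbl in labels.items():
        if nid in bundle.nodes and lbl in (0, 1):
            per_node[nid] = _ce(bundle.nodes[nid], int(lbl))
    ce = float(sum(per_node.values()))
    tr = tree.trace_sum()
    return LossReport(
        total=ce + lam * tr,
        ce=ce,
        trace=tr,
        per_node_ce=per_node,
        no_labels=(len(per_node) == 0),
    )


def fit_linear_multireader(
    features: np.ndarray,
    label_matrix: np.ndarray,
    tree: ConsensusTree,
    lam: float = 1.0,
    steps: int = 300,
    lr: float = 0.05,
    seed: int = 0,
):
    """Fit a softmax-linear base model jointly with the tree's annotator
    matrices by full-batch Adam on the multi-reader loss.

    A deliberately small model: enough to study what the annotator
    matrices absorb (e.g. per-reader label noise) when the features
    carry the truth.  Returns ``(node_predictions, base_prediction)``
    as numpy arrays keyed by node id."""
    x = np.asarray(features, dtype=float)
    n = x.shape[0]
    rng = np.random.default_rng(seed)
    W = nn.Parameter(rng.normal(0.0, 0.1, (x.shape[1], tree.n_classes)))
    b = nn.Parameter(np.zeros(tree.n_classes))
    opt = nn.Adam([W, b] + tree.parameters(), lr=lr)
    for _ in range(steps):
        p = nn.softmax(nn.Tensor(x) @ W + b, axis=1)
        loss, _, _ = multireader_batch_loss(p, label_matrix, tree, lam)
        loss = loss * (1.0 / n)
        opt.zero_grad()
        loss.backward()
        opt.step()
    p = nn.softmax(nn.Tensor(x) @ W + b, axis=1)
    node_preds = {k: v.data.copy() for k, v in tree.branch_t(p).items()}
    return node_preds, p.data.copy()


def disagreement_rates(node_preds: dict, root_id: str) -> dict:
    """Mean probability mass each node places on the class opposite to the
    root's argmax — the model's estimate of that node's flip rate."""
    root = node_preds[root_id]
    hard = root.argmax(axis=1)
    n = len(hard)
    return {
        nid: float(np.mean(1.0 - q[np.arange(n), hard]))
        for nid, q in node_preds.items()
    }


def multireader_batch_loss(
    p_base: nn.Tensor,
    label_matrix: np.ndarray,
    tree: ConsensusTree,
    lam: float = 1.0,
) -> tuple[nn.Tensor, float, float]:
    """Differentiable batch loss: ``p_base`` (N, C), ``label_matrix``
    (N, n_nodes) with MISSING where no label exists.  Returns
    ``(total, ce_value, trace_value)``; CE is summed over available labels
    and the trace term enters once, per the loss formula."""
    node_preds = tree.branch_t(p_base)
    ce = nn.Tensor(np.zeros(()))
    n_terms = 0
    for j, nid in enumerate(tree.node_ids):
        lbl = label_matrix[:, j]
        mask = lbl != MISSING
        if not mask.any():
            continue
        q = node_preds[nid]
        rows = np.nonzero(mask)[0]
        picked = q[(rows, lbl[mask])]
        ce = ce + -(picked.clip_min(1e-12).log().sum())
        n_terms += int(mask.sum())
    trace = tree.trace_sum_t()
    total = ce + lam * trace
    return total, float(ce.data), float(trace.data)
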