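"""Rank-1 annotator matrices, consensus trees, consensus labels and the
combined multi-reader loss."""

import numpy as np
import pandas as pd
import pytest

from sijkit import nn
from sijkit.multireader import (
    MISSING,
    AnnotatorNode,
    ConsensusTree,
    LabelTable,
    apply_annotator,
    branch_predictions,
    consensus_inference,
    disagreement_rates,
    fit_linear_multireader,
    multireader_batch_loss,
    multireader_loss,
    rank1_matrix,
)


def identity_tree(R=2, S=3):
    """A tree whose every node is the exact identity annotator."""
    tree = ConsensusTree(R, S)
    for nid in tree.node_ids:
        tree.node(nid).set_vectors(np.zeros(2), np.zeros(2))
    return tree


# ------------------------------------------------------------------
# rank-1 matrices
# ------------------------------------------------------------------


def test_rank1_examples_and_loop_oracle(rng):
    assert np.array_equal(rank1_matrix([1, 0], [0, 1]), [[0, 1], [0, 0]])
    assert np.array_equal(rank1_matrix([0, 0], [3, 4]), np.zeros((2, 2)))
    for _ in range(100):
        a, b = rng.normal(size=2), rng.normal(size=2)
        A = rank1_matrix(a, b)
        for i in range(2):
            for j in range(2):
                assert A[i, j] == pytest.approx(a[i] * b[j])
        assert np.linalg.matrix_rank(np.where(np.abs(A) > 1e-12, A, 0)) <= 1
    with pytest.raises(ValueError):
        rank1_matrix([1, 2], [1, 2, 3])


def test_trace_equals_dot_product(rng):
    for _ in range(50):
        a, b = rng.uniform(-0.49, 0.49, 2), rng.uniform(-0.49, 0.49, 2)
        node = AnnotatorNode("X")
        node.set_vectors(a, b)
        assert node.trace() == pytest.approx(np.trace(rank1_matrix(a, b)))
        assert node.trace() == pytest.approx(float(a @ b))


def test_annotator_parameterisation_bounds():
    node = AnnotatorNode("X")
    node.raw_a.data[:] = [5.0, -5.0]
    node.raw_b.data[:] = [500.0, -500.0]
    assert np.all(np.abs(node.a) < 0.5)
    assert np.all(np.abs(node.b) <= 0.5)  # float tanh saturates at +-1
    with pytest.raises(ValueError):
        node.set_vectors([0.6, 0.0], [0.0, 0.0])


def test_annotator_initialises_as_identity():
    node = AnnotatorNode("X", rng=np.random.default_rng(0))
    assert np.allclose(node.A, 0.0)
    assert np.allclose(node.B, np.eye(2))
    assert node.trace() == 0.0


# ------------------------------------------------------------------
# apply_annotator
# ------------------------------------------------------------------


def test_apply_identity_and_hand_case():
    node = AnnotatorNode("X")
    assert np.allclose(apply_annotator(node, [0.3, 0.7]), [0.3, 0.7])
    node.set_vectors([0.2, -0.2], [0.4, -0.4])
    # rows of A sum to zero here, so (0.5, 0.5) is a fixed point
    assert np.allclose(apply_annotator(node, [0.5, 0.5]), [0.5, 0.5])


def test_apply_matches_brute_force(rng):
    for _ in range(100):
        node = AnnotatorNode("X")
        node.set_vectors(rng.uniform(-0.49, 0.49, 2), rng.uniform(-0.49, 0.49, 2))
        p = rng.dirichlet([1.0, 1.0])
        q = apply_annotator(node, p)
        ref = (np.eye(2) + np.outer(node.a, node.b)) @ p
        ref = np.maximum(ref, 1e-6)
        ref = ref / ref.sum()
        assert np.allclose(q, ref, atol=1e-12)
        assert q.min() >= 0 and q.sum() == pytest.approx(1.0)


def test_apply_rejects_non_simplex():
    with pytest.raises(ValueError):
        apply_annotator(AnnotatorNode("X"), [0.9, 0.4])


# ------------------------------------------------------------------
# branching
# ------------------------------------------------------------------


def test_branch_identity_tree_returns_base_everywhere():
    tree = identity_tree()
    p = np.array([0.2, 0.8])
    bundle = branch_predictions(p, tree)
    assert len(bundle.nodes) == 9
    for q in bundle.nodes.values():
        assert np.allclose(q, p, atol=1e-9)
    assert np.allclose(consensus_inference(bundle), p, atol=1e-9)


def test_branch_node_set_matches_hierarchy():
    tree = ConsensusTree(2, 3)
    assert sorted(tree.node_ids) == sorted(
        ["R1R2", "R1", "R2", "R1S1", "R1S2", "R1S3", "R2S1", "R2S2", "R2S3"]
    )
    tree31 = ConsensusTree(3, 1)
    assert sorted(tree31.node_ids) == sorted(["R1R2R3", "R1", "R2", "R3"])


def test_branch_chain_equals_longhand_composition(rng):
    tree = ConsensusTree(2, 3)
    for nid in tree.node_ids:
        tree.node(nid).set_vectors(
            rng.uniform(-0.4, 0.4, 2), rng.uniform(-0.4, 0.4, 2)
        )
    p = rng.dirichlet([1.0, 1.0])
    bundle = branch_predictions(p, tree)
    longhand = apply_annotator(
        tree.node("R1S2"),
        apply_annotator(tree.node("R1"), apply_annotator(tree.node("R1R2"), p)),
    )
    assert np.allclose(bundle.nodes["R1S2"], longhand, atol=1e-12)


def test_branch_outputs_stay_on_simplex(rng):
    tree = ConsensusTree(2, 3)
    for nid in tree.node_ids:
        tree.node(nid).set_vectors(
            rng.uniform(-0.49, 0.49, 2), rng.uniform(-0.49, 0.49, 2)
        )
    for _ in range(50):
        bundle = branch_predictions(rng.dirichlet([0.5, 0.5]), tree)
        for q in bundle.nodes.values():
            assert q.min() >= 0.0
            assert q.sum() == pytest.approx(1.0, abs=1e-6)


# ------------------------------------------------------------------
# consensus labels
# ------------------------------------------------------------------


def _table(rows):
    return LabelTable(
        pd.DataFrame(rows, columns=["sample_id", "task_id", "reader", "session", "label"])
    ).compute_consensus()


def test_consensus_unanimous_and_self_disagreement():
    rows = [("s", "t", r, s, 1) for r in (1, 2) for s in (1, 2, 3)]
    t = _table(rows)
    assert t.inter_consensus("s", "t") == 1
    assert t.intra_consensus("s", "t", 1) == 1
    rows2 = [("s", "t", 1, 1, 1), ("s", "t", 1, 2, 0), ("s", "t", 1, 3, 1)] + [
        ("s", "t", 2, s, 1) for s in (1, 2, 3)
    ]
    t2 = _table(rows2)
    assert t2.intra_consensus("s", "t", 1) is None
    assert t2.intra_consensus("s", "t", 2) == 1
    assert t2.inter_consensus("s", "t") is None


def test_consensus_matches_brute_force_scan(rng):
    rows = []
    for sample in range(40):
        for task in ("a", "b"):
            for r in (1, 2):
                for s in (1, 2, 3):
                    rows.append((sample, task, r, s, int(rng.random() < 0.5)))
    t = _table(rows)
    df = t.df
    for sample in range(40):
        for task in ("a", "b"):
            sub = df[(df.sample_id == sample) & (df.task_id == task)]
            for r in (1, 2):
                labels = sub[sub.reader == r].label.tolist()
                expect = labels[0] if len(set(labels)) == 1 else None
                assert t.intra_consensus(sample, task, r) == expect
            labels = sub.label.tolist()
            expect = labels[0] if len(set(labels)) == 1 else None
            assert t.inter_consensus(sample, task) == expect


def test_consensus_monotone_under_added_disagreement():
    rows = [("s", "t", r, s, 1) for r in (1, 2) for s in (1, 2)]
    base = _table(rows)
    assert base.inter_consensus("s", "t") == 1
    extended = _table(rows + [("s", "t", 1, 3, 0), ("s", "t", 2, 3, 1)])
    # the disagreeing session can only remove consensus, never change it
    assert extended.intra_consensus("s", "t", 1) is None
    assert extended.intra_consensus("s", "t", 2) == 1
    assert extended.inter_consensus("s", "t") is None


def test_label_table_validation():
    with pytest.raises(ValueError):
        LabelTable(pd.DataFrame({"sample_id": [1], "task_id": ["t"]}))
    with pytest.raises(ValueError):
        _table([("s", "t", 1, 1, 2)])
    with pytest.raises(ValueError):
        _table([("s", "t", 1, 1, 1), ("s", "t", 1, 1, 0)])


# ------------------------------------------------------------------
# loss
# ------------------------------------------------------------------


def test_loss_zero_at_global_optimum():
    tree = identity_tree()
    p = np.array([1.0 - 1e-12, 1e-12])
    bundle = branch_predictions(p, tree)
    labels = {nid: 0 for nid in tree.node_ids}
    rep = multireader_loss(bundle, labels, tree, lam=1.0)
    assert rep.trace == 0.0
    # the 1e-6 simplex clamp bounds the attainable CE away from exact zero
    assert rep.ce == pytest.approx(0.0, abs=1e-4)
    assert rep.total == pytest.approx(0.0, abs=1e-4)


def test_loss_trace_contribution():
    tree = identity_tree()
    tree.node("R1S1").set_vectors([0.1, 0.0], [0.4, 0.0])
    rep = multireader_loss(
        branch_predictions(np.array([0.5, 0.5]), tree), {}, tree, lam=1.0
    )
    assert rep.no_labels
    assert rep.trace == pytest.approx(0.04)
    assert rep.total == pytest.approx(0.04)


def test_loss_hand_computed_cross_entropy():
    tree = identity_tree()
    p = np.array([0.8, 0.2])
    bundle = branch_predictions(p, tree)
    labels = {"R1S1": 0, "R2": 1}
    rep = multireader_loss(bundle, labels, tree, lam=1.0)
    assert rep.per_node_ce["R1S1"] == pytest.approx(-np.log(0.8), abs=1e-9)
    assert rep.per_node_ce["R2"] == pytest.approx(-np.log(0.2), abs=1e-9)
    assert rep.total == pytest.approx(-np.log(0.8) - np.log(0.2), abs=1e-9)


def test_identity_collapse_to_plain_cross_entropy(rng):
    """With every annotator at zero the loss is exactly the sum of plain
    CE of the base prediction against each available label."""
    tree = identity_tree()
    for _ in range(20):
        p = rng.dirichlet([1.0, 1.0])
        labels = {
            nid: int(rng.integers(0, 2))
            for nid in tree.node_ids
            if rng.random() < 0.7
        }
        rep = multireader_loss(branch_predictions(p, tree), labels, tree, lam=1.0)
        clamped = np.maximum(p, 1e-6)
        clamped = clamped / clamped.sum()
        expect = sum(-np.log(clamped[v]) for v in labels.values())
        assert rep.total == pytest.approx(expect, abs=1e-10)


def test_batch_loss_matches_per_sample_loss(rng):
    tree = ConsensusTree(2, 3)
    for nid in tree.node_ids:
        tree.node(nid).set_vectors(
            rng.uniform(-0.3, 0.3, 2), rng.uniform(-0.3, 0.3, 2)
        )
    n = 16
    P = rng.dirichlet([1.0, 1.0], size=n)
    lm = rng.integers(0, 2, (n, 9))
    lm[rng.random((n, 9)) < 0.4] = MISSING
    total, ce, trace = multireader_batch_loss(nn.Tensor(P), lm, tree, lam=1.0)
    expect_ce = 0.0
    for i in range(n):
        labels = {
            nid: int(lm[i, j])
            for j, nid in enumerate(tree.node_ids)
            if lm[i, j] != MISSING
        }
        rep = multireader_loss(branch_predictions(P[i], tree), labels, tree, lam=0.0)
        expect_ce += rep.ce
    assert ce == pytest.approx(expect_ce, rel=1e-9)
    assert trace == pytest.approx(tree.trace_sum())
    assert float(total.data) == pytest.approx(expect_ce + trace, rel=1e-9)


# ------------------------------------------------------------------
# noise recovery (scaled-down smoke; the full experiment runs in the
# acceptance suite)
# ------------------------------------------------------------------


def test_session_nodes_absorb_reader_noise_smoke(rng):
    n, rates = 600, (0.05, 0.30)
    truth = rng.integers(0, 2, n)
    x = np.stack([truth + rng.normal(0, 0.2, n), 1 - truth + rng.normal(0, 0.2, n)], 1)
    rows = []
    for i, t in enumerate(truth):
        for r, rate in enumerate(rates, start=1):
            for s in (1, 2, 3):
                rows.append((i, "T", r, s, int(t) ^ int(rng.random() < rate)))
    table = _table(rows)
    tree = ConsensusTree(2, 3, seed=0)
    lm = table.node_label_matrix(list(range(n)), "T", tree)
    preds, _ = fit_linear_multireader(x, lm, tree, steps=200, seed=0)
    dr = disagreement_rates(preds, "R1R2")
    r1 = np.mean([dr[f"R1S{s}"] for s in (1, 2, 3)])
    r2 = np.mean([dr[f"R2S{s}"] for s in (1, 2, 3)])
    assert r2 > r1 + 0.1  # the noisier reader's sessions absorb more flips
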