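"""Transformer and GAT branch properties: padding invariance, attention
normalization, message locality, and permutation equivariance."""

import numpy as np
import pytest

from pathddi import nn
from pathddi.encoders import GATBranch, GATLayer, TransformerBranch


def embed(rng, B, L, d):
    return nn.Tensor(rng.normal(size=(B, L, d)))


# -- Transformer branch -------------------------------------------------------


def test_padding_tail_does_not_change_cls_output():
    rng = np.random.default_rng(0)
    branch = TransformerBranch(L=16, d_emb=8, d_model=8, n_layers=2,
                               n_head=2, d_ff=16, rng=rng)
    base = np.random.default_rng(1).normal(size=(1, 16, 8))
    x1 = base.copy()
    x2 = base.copy()
    x2[0, 6:] = 99.0          # garbage beyond the mask must be invisible
    mask = np.zeros((1, 16), dtype=bool)
    mask[0, :6] = True
    z1 = branch(nn.Tensor(x1), mask).data
    z2 = branch(nn.Tensor(x2), mask).data
    np.testing.assert_array_equal(z1, z2)


def test_zero_layers_returns_projected_cls():
    rng = np.random.default_rng(2)
    branch = TransformerBranch(L=8, d_emb=4, d_model=6, n_layers=0,
                               n_head=2, d_ff=8, rng=rng)
    x = np.random.default_rng(3).normal(size=(2, 8, 4))
    mask = np.ones((2, 8), dtype=bool)
    z = branch(nn.Tensor(x), mask).data
    expected = x[:, 0, :] @ branch.proj.weight.data + branch.proj.bias.data
    np.testing.assert_allclose(z, expected, atol=1e-12)


def test_real_tokens_influence_output_but_order_does_not():
    """Without a positional-encoding module this branch is a set encoder:
    permuting real tokens leaves the <CLS> output unchanged, while altering
    a real token's content changes it (real positions are never masked)."""
    rng = np.random.default_rng(4)
    branch = TransformerBranch(L=8, d_emb=4, d_model=4, n_layers=1,
                               n_head=2, d_ff=8, rng=rng)
    x = np.random.default_rng(5).normal(size=(1, 8, 4))
    mask = np.ones((1, 8), dtype=bool)
    z1 = branch(nn.Tensor(x), mask).data
    x_perm = x.copy()
    x_perm[0, [2, 3]] = x_perm[0, [3, 2]]
    np.testing.assert_allclose(branch(nn.Tensor(x_perm), mask).data, z1,
                               atol=1e-10)
    x_mut = x.copy()
    x_mut[0, 3] += 1.0
    assert not np.allclose(branch(nn.Tensor(x_mut), mask).data, z1)


def test_sequence_longer_than_L_rejected():
    rng = np.random.default_rng(6)
    branch = TransformerBranch(L=4, d_emb=4, d_model=4, n_layers=1,
                               n_head=2, d_ff=8, rng=rng)
    with pytest.raises(ValueError):
        branch(embed(rng, 1, 8, 4), np.ones((1, 8), dtype=bool))


# -- GAT layer ----------------------------------------------------------------


def ring_adjacency(L, atoms):
    A = np.zeros((L, L))
    for i in atoms:
        A[i, i] = 1.0
    for i, j in zip(atoms, atoms[1:] + atoms[:1]):
        A[i, j] = A[j, i] = 1.0
    return A


def test_attention_rows_sum_to_one_on_edges():
    rng = np.random.default_rng(7)
    layer = GATLayer(d_in=6, K=2, d_prime=4, rng=rng)
    L = 8
    atoms = [1, 2, 3, 4, 5]
    A = ring_adjacency(L, atoms)[None]
    H = embed(rng, 1, L, 6)
    for k in range(2):
        alpha = layer.attention(H, A, k).data[0]
        for i in atoms:
            assert alpha[i].sum() == pytest.approx(1.0, abs=1e-6)
            assert np.all(alpha[i][A[0, i] == 0] == 0.0)
        for i in range(L):
            if i not in atoms:
                np.testing.assert_array_equal(alpha[i], 0.0)


def test_singleton_neighborhood_gets_full_attention():
    rng = np.random.default_rng(8)
    layer = GATLayer(d_in=4, K=1, d_prime=3, rng=rng)
    L = 4
    A = np.zeros((1, L, L))
    A[0, 1, 1] = 1.0                       # lone atom with a self-loop
    alpha = layer.attention(embed(rng, 1, L, 4), A, 0).data[0]
    assert alpha[1, 1] == pytest.approx(1.0)


def test_two_identical_neighbors_split_attention_evenly():
    rng = np.random.default_rng(9)
    layer = GATLayer(d_in=4, K=1, d_prime=3, rng=rng)
    L = 4
    A = np.zeros((1, L, L))
    A[0, 0, 1] = A[0, 1, 0] = 1.0
    A[0, 0, 2] = A[0, 2, 0] = 1.0
    H = np.zeros((1, L, 4))
    H[0, 0] = 1.0
    H[0, 1] = H[0, 2] = 0.5                # identical neighbor features
    alpha = layer.attention(nn.Tensor(H), A, 0).data[0]
    assert alpha[0, 1] == pytest.approx(alpha[0, 2])
    assert alpha[0].sum() == pytest.approx(1.0)


def test_gat_output_width_is_K_times_dprime():
    rng = np.random.default_rng(10)
    layer = GATLayer(d_in=8, K=4, d_prime=16, rng=rng)
    A = ring_adjacency(6, [1, 2, 3])[None]
    out = layer(embed(rng, 1, 6, 8), A)
    assert out.shape == (1, 6, 64)


def test_message_locality_by_finite_differencing():
    rng = np.random.default_rng(11)
    layer = GATLayer(d_in=5, K=2, d_prime=4, rng=rng)
    L = 6
    atoms = [1, 2, 3, 4]
    A = ring_adjacency(L, atoms)[None]
    A[0, 1, 3] = A[0, 3, 1] = 0.0          # ensure 1 and 3 are non-adjacent
    H0 = np.random.default_rng(12).normal(size=(1, L, 5))

    def out_node(h, node):
        return layer(nn.Tensor(h), A).data[0, node]

    base = out_node(H0, 1)
    bumped = H0.copy()
    bumped[0, 3] += 0.37                   # perturb a non-neighbor
    np.testing.assert_allclose(out_node(bumped, 1), base, atol=1e-12)
    bumped2 = H0.copy()
    bumped2[0, 2] += 0.37                  # perturb a neighbor
    assert not np.allclose(out_node(bumped2, 1), base)


def test_gat_permutation_equivariance_and_invariant_readout():
    rng = np.random.default_rng(13)
    branch = GATBranch(d_in=5, K=2, d_prime=4, rng=rng, readout="mean")
    L = 8
    atoms = list(range(1, 8))
    rng2 = np.random.default_rng(14)
    A = np.zeros((L, L))
    for i in atoms:
        A[i, i] = 1.0
    for _ in range(8):
        i, j = rng2.choice(atoms, size=2, replace=False)
        A[i, j] = A[j, i] = 1.0
    H = rng2.normal(size=(L, 5))
    mask = np.zeros(L, dtype=bool)
    mask[atoms] = True

    perm = np.concatenate([[0], rng2.permutation(atoms)])
    A_p = A[np.ix_(perm, perm)]
    H_p = H[perm]
    mask_p = mask[perm]

    nodes = branch.gat(nn.Tensor(H[None]), A[None]).data[0]
    nodes_p = branch.gat(nn.Tensor(H_p[None]), A_p[None]).data[0]
    np.testing.assert_allclose(nodes_p, nodes[perm], atol=1e-10)

    z = branch(nn.Tensor(H[None]), A[None], mask[None]).data
    z_p = branch(nn.Tensor(H_p[None]), A_p[None], mask_p[None]).data
    np.testing.assert_allclose(z, z_p, atol=1e-10)


def test_readout_modes_and_residual():
    rng = np.random.default_rng(15)
    branch = GATBranch(d_in=4, K=2, d_prime=4, rng=rng, readout="mean")
    L = 4
    A = np.zeros((1, L, L))
    A[0, 1, 1] = 1.0
    mask = np.array([[False, True, False, False]])
    H = embed(rng, 1, L, 4)
    nodes = branch.gat(H, A)
    pooled = branch.readout(nodes, mask)
    # single atom: mean readout equals that node's output
    np.testing.assert_allclose(pooled.data[0], nodes.data[0, 1], atol=1e-12)
    # zero-initialized residual MLP output layer = identity readout
    branch.mlp_out.weight.data[...] = 0.0
    branch.mlp_out.bias.data[...] = 0.0
    z = branch(H, A, mask)
    np.testing.assert_allclose(z.data, pooled.data, atol=1e-12)
    # identical node outputs: mean and max coincide
    branch_max = GATBranch(d_in=4, K=2, d_prime=4, rng=rng, readout="max")
    same = nn.Tensor(np.tile(nodes.data[0, 1], (1, L, 1)))
    mask2 = np.array([[False, True, True, True]])
    mean_r = branch.readout(same, mask2).data
    max_r = branch_max.readout(same, mask2).data
    np.testing.assert_allclose(mean_r, max_r, atol=1e-12)
    with pytest.raises(ValueError):
        branch.readout(nodes, np.zeros((1, L), dtype=bool))
    with pytest.raises(ValueError):
        GATBranch(d_in=4, K=1, d_prime=2, rng=rng, readout="median")
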