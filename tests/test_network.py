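import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import ibrnet as ib
from ibrnet.network import all_states, state_bits, state_index

from conftest import identity_network, random_network, toy_network_n3
from _oracles import k1_quadrature


@given(st.integers(min_value=1, max_value=12), st.data())
def test_state_encoding_roundtrips(n, data):
    idx = data.draw(st.integers(min_value=0, max_value=2**n - 1))
    bits = state_bits(idx, n)
    assert state_index(bits) == idx
    assert np.array_equal(all_states(n)[idx], bits)


def test_state_index_is_msb_first():
    # gene 1 is the most significant bit
    assert state_index([1, 0, 0]) == 4
    assert state_index([0, 0, 1]) == 1


class TestEvaluate:
    def test_cell_cycle_wild_type_at_all_zeros(self, cell_cycle_wt):
        out = cell_cycle_wt.evaluate(np.zeros(10, dtype=int))
        assert out.tolist() == [0, 1, 1, 1, 0, 0, 0, 1, 1, 1]

    def test_mutant_p27_is_silenced_everywhere(self, cell_cycle_mut):
        for x in all_states(10)[:: 7]:  # spot-check a spread of states
            assert cell_cycle_mut.evaluate(x)[2] == 0

    def test_identity_network_returns_input(self):
        net = identity_network(4)
        for x in all_states(4):
            assert np.array_equal(net.evaluate(x), x)

    def test_dimension_mismatch_rejected(self, cell_cycle_wt):
        with pytest.raises(ValueError, match="shape"):
            cell_cycle_wt.evaluate(np.zeros(9, dtype=int))

    def test_transition_map_agrees_with_evaluate(self, cell_cycle_wt):
        fmap = cell_cycle_wt.transition_map()
        for idx in (0, 1, 77, 512, 1023):
            x = state_bits(idx, 10)
            assert fmap[idx] == state_index(cell_cycle_wt.evaluate(x))


class TestHamming:
    @pytest.mark.parametrize(
        "x, y, d",
        [
            ([0, 1, 1], [0, 1, 1], 0),
            ([0] * 10, [1] * 10, 10),
            ([0, 1, 1], [1, 1, 0], 2),
        ],
    )
    def test_examples(self, x, y, d):
        assert ib.hamming_distance(x, y) == d

    @given(st.lists(st.integers(0, 1), min_size=1, max_size=16), st.data())
    def test_symmetric_and_bounded(self, x, data):
        y = data.draw(st.lists(st.integers(0, 1), min_size=len(x), max_size=len(x)))
        d = ib.hamming_distance(x, y)
        assert d == ib.hamming_distance(y, x)
        assert 0 <= d <= len(x)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            ib.hamming_distance([0, 1], [0, 1, 1])


class TestConditionalTPM:
    def test_entries_n2(self):
        net = identity_network(2)
        A = ib.conditional_tpm(net, 0.1)
        # identity network: f(x) = x, so d(i -> j) = popcount(i ^ j)
        assert A[0, 0] == pytest.approx(0.81, abs=1e-15)
        assert A[0, 1] == pytest.approx(0.09, abs=1e-15)
        assert A[0, 3] == pytest.approx(0.01, abs=1e-15)

    def test_rows_sum_to_one(self, cell_cycle_wt):
        A = ib.conditional_tpm(cell_cycle_wt, 0.05)
        assert np.max(np.abs(A.sum(axis=1) - 1.0)) < 1e-12
        assert A.min() > 0

    def test_small_p_concentrates_on_deterministic_image(self):
        net = toy_network_n3()
        A = ib.conditional_tpm(net, 1e-9)
        fmap = net.transition_map()
        for i in range(8):
            assert A[i, fmap[i]] == pytest.approx(1.0, abs=1e-8)

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.2, 1.5])
    def test_invalid_p_rejected(self, p):
        with pytest.raises(ValueError, match="probability"):
            ib.conditional_tpm(identity_network(2), p)


class TestMarginalTPM:
    def test_n1_uniform_prior_gives_half_everywhere(self):
        M = ib.marginal_tpm(identity_network(1), 1.0, 1.0)
        assert np.allclose(M, 0.5, atol=1e-14)

    @pytest.mark.parametrize("a, b", [(1.0, 100.0), (3.0, 100.0), (2.5, 7.0), (1.0, 1.0)])
    def test_matches_quadrature(self, a, b, cell_cycle_wt):
        for net in (identity_network(2), toy_network_n3(), cell_cycle_wt):
            M = ib.marginal_tpm(net, a, b)
            fmap = net.transition_map()
            n = net.n
            # one entry per possible Hamming distance suffices: entries
            # depend on (n, d) only
            for d in range(n + 1):
                j = fmap[0] ^ ((1 << d) - 1)  # state at distance d from f(state 0)
                assert M[0, j] == pytest.approx(k1_quadrature(d, n, a, b), abs=1e-8)

    def test_rows_sum_to_one_cell_cycle(self, cell_cycle_wt):
        M = ib.marginal_tpm(cell_cycle_wt, 1.0, 100.0)
        assert np.max(np.abs(M.sum(axis=1) - 1.0)) < 1e-12
        assert M.min() > 0

    def test_nonpositive_shapes_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            ib.marginal_tpm(identity_network(2), 0.0, 1.0)


class TestSteadyState:
    def test_symmetric_two_state_chain(self):
        pi = ib.steady_state(np.array([[0.5, 0.5], [0.5, 0.5]]))
        assert np.allclose(pi, [0.5, 0.5], atol=1e-14)

    def test_two_state_balance(self):
        pi = ib.steady_state(np.array([[0.9, 0.1], [0.5, 0.5]]))
        assert np.allclose(pi, [5.0 / 6.0, 1.0 / 6.0], atol=1e-12)

    @pytest.mark.parametrize("variant", ["wild-type", "p27-mutant"])
    def test_fixed_point_on_cell_cycle(self, variant):
        M = ib.marginal_tpm(ib.load_cell_cycle(variant), 1.0, 100.0)
        pi = ib.steady_state(M)
        assert abs(pi.sum() - 1.0) < 1e-10
        assert np.max(np.abs(pi @ M - pi)) < 1e-10
        assert pi.min() > 0  # irreducible chain: strictly positive

    def test_non_stochastic_rejected(self):
        with pytest.raises(ValueError, match="stochastic"):
            ib.steady_state(np.array([[0.9, 0.2], [0.5, 0.5]]))


def permute_network(net, perm):
    """Relabel genes by permutation: new gene i is old gene perm[i]."""
    inv = {old: new for new, old in enumerate(perm)}
    funcs = [
        ib.GeneFunction(
            target=net.functions[old].target,
            regulators=tuple(inv[r] for r in net.functions[old].regulators),
            table=net.functions[old].table,
        )
        for old in perm
    ]
    return ib.BooleanNetwork(genes=[net.genes[old] for old in perm], functions=funcs, label=net.label)


def permute_states(perm, n):
    """Map each new-encoding state index to the old-encoding index."""
    mapping = np.empty(2**n, dtype=int)
    for idx in range(2**n):
        bits_new = state_bits(idx, n)
        bits_old = np.empty(n, dtype=int)
        for new_pos, old_pos in enumerate(perm):
            bits_old[old_pos] = bits_new[new_pos]
        mapping[idx] = state_index(bits_old)
    return mapping


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_relabeling_symmetry_of_tpms(seed):
    rng = np.random.default_rng(seed)
    net = random_network(4, rng)
    perm = list(rng.permutation(4))
    pnet = permute_network(net, perm)
    mapping = permute_states(perm, 4)
    for build in (lambda nn: ib.conditional_tpm(nn, 0.07), lambda nn: ib.marginal_tpm(nn, 2.0, 9.0)):
        M = build(net)
        Mp = build(pnet)
        assert np.allclose(Mp, M[np.ix_(mapping, mapping)], atol=1e-14)


def test_network_json_roundtrip(tmp_path, cell_cycle_wt):
    path = tmp_path / "net.json"
    cell_cycle_wt.to_json(path)
    back = ib.BooleanNetwork.from_json(path)
    assert back.genes == cell_cycle_wt.genes
    assert all(
        f1.regulators == f2.regulators and f1.table == f2.table
        for f1, f2 in zip(back.functions, cell_cycle_wt.functions)
    )


def test_malformed_truth_table_rejected():
    with pytest.raises(ValueError, match="table"):
        ib.GeneFunction(target="g", regulators=(0, 1), table=(0, 1, 1))
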