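"""Causal network integration: Jacobian exactness, structure, extraction."""

import numpy as np
import pytest

import axichain as ax
from axichain.causal import CausalTensor, tukey_outliers, zscore_outliers

from conftest import random_state


class TestCausalJacobian:
    def test_tau_zero_distinct_variables_is_zero(self, cfg4):
        p = ax.init_parameters(1, cfg4)
        t = ax.causal_jacobian(p, None, 0, source_var="r", target_var="s",
                               config=cfg4)
        assert t.values.shape == (4, 9, 4)
        assert np.all(t.values == 0.0)

    def test_tau_zero_same_variable_is_identity(self, cfg4):
        p = ax.init_parameters(1, cfg4)
        t = ax.causal_jacobian(p, None, 0, source_var="s", target_var="s",
                               config=cfg4)
        assert np.array_equal(t.values[:, 0, :], np.eye(4))

    @pytest.mark.parametrize("source,target", [("r", "s"), ("y", "b"),
                                               ("s", "s")])
    def test_matches_finite_difference_oracle(self, cfg4, source, target):
        """Exact forward-propagated Jacobians agree with the independent
        central-difference oracle on a small chain."""
        p = ax.init_parameters(2, cfg4)
        st = random_state(cfg4, seed=8)
        exact = ax.causal_jacobian(p, st, 10, source_var=source,
                                   target_var=target, config=cfg4)
        fd = ax.finite_difference_jacobian(p, st, 10, source_var=source,
                                           target_var=target, h=1e-4,
                                           config=cfg4)
        scale = np.abs(fd.values).max()
        assert scale > 0
        assert np.max(np.abs(exact.values - fd.values)) / scale < 1e-5

    def test_locality_cone(self, cfg6):
        """No influence travels faster than one cell per update step:
        J[i, :, k] = 0 whenever |i - k| > tau."""
        p = ax.init_parameters(3, cfg6)
        st = random_state(cfg6, seed=5)
        for tau in (0, 1, 2, 3):
            t = ax.causal_jacobian(p, st, tau, source_var="r",
                                   target_var="s", config=cfg6)
            i_idx, k_idx = np.meshgrid(np.arange(6), np.arange(6),
                                       indexing="ij")
            outside = np.abs(i_idx - k_idx) > tau
            assert np.all(t.values[outside[:, None, :]
                                   .repeat(9, axis=1)] == 0.0)

    def test_mirror_equivariance(self, cfg6):
        """The causal tensor of the mirrored system is the index-mirrored
        tensor (cells reversed, controller columns swapped)."""
        from axichain.params import IC_MIRROR
        p = ax.init_parameters(4, cfg6)
        st = random_state(cfg6, seed=2)
        t = ax.causal_jacobian(p, st, 12, source_var="r", target_var="s",
                               config=cfg6)
        ms, mp = ax.mirror_transform(st, p)
        tm = ax.causal_jacobian(mp, ms, 12, source_var="r", target_var="s",
                                config=cfg6)
        expected = t.values[::-1][:, IC_MIRROR][:, :, ::-1]
        assert np.allclose(tm.values, expected, atol=1e-10)

    def test_extraction_point_defaults_to_homogeneous(self, cfg4):
        p = ax.init_parameters(2, cfg4)
        t1 = ax.causal_jacobian(p, None, 5, config=cfg4)
        t2 = ax.causal_jacobian(p, ax.init_state(cfg4), 5, config=cfg4)
        assert np.array_equal(t1.values, t2.values)
        assert t1.base_state_ref == "homogeneous"

    def test_rejects_lattice_target(self, cfg4):
        with pytest.raises(ValueError):
            ax.causal_jacobian(ax.init_parameters(1, cfg4), None, 3,
                               source_var="r", target_var="r", config=cfg4)


class TestFiniteDifferenceJacobian:
    def test_zero_dynamics_zero_tensor(self, cfg4):
        t = ax.finite_difference_jacobian(ax.zero_parameters(), None, 8,
                                          config=cfg4)
        assert np.all(t.values == 0.0)

    def test_halving_h_converges_quadratically(self, cfg4):
        p = ax.init_parameters(2, cfg4)
        st = random_state(cfg4, seed=8)
        exact = ax.causal_jacobian(p, st, 6, config=cfg4)
        errs = []
        for h in (2e-3, 1e-3):
            fd = ax.finite_difference_jacobian(p, st, 6, h=h, config=cfg4)
            errs.append(np.max(np.abs(fd.values - exact.values)))
        # central differences: error drops ~4x when h halves
        assert errs[1] < errs[0] / 2.5


class TestNormalizeCI:
    def test_profile_example(self):
        vals = np.zeros((3, 1, 1))
        vals[:, 0, 0] = [-2.0, 0.0, 2.0]
        t = CausalTensor(values=vals, tau=5, source_var="r", target_var="s")
        out, degen = ax.normalize_ci(t)
        assert out[:, 0, 0].tolist() == [0.0, 0.5, 1.0]
        assert not degen.any()

    def test_scale_invariance_and_range(self, cfg4):
        p = ax.init_parameters(2, cfg4)
        t = ax.causal_jacobian(p, random_state(cfg4, seed=1), 8, config=cfg4)
        out, degen = ax.normalize_ci(t)
        assert np.all((out >= 0) & (out <= 1))
        t2 = CausalTensor(values=3.7 * t.values, tau=8, source_var="r",
                          target_var="s")
        out2, _ = ax.normalize_ci(t2)
        assert np.allclose(out, out2)


class TestOutlierRules:
    def test_tukey_single_spike(self):
        """Worked example: eight zeros and one 10 -> Q1 = Q3 = 0, IQR = 0,
        the spike sits above the upper fence."""
        vals = np.array([0, 0, 0, 0, 0, 0, 0, 0, 10.0])
        mask = tukey_outliers(vals)
        assert mask.sum() == 1 and mask[-1]

    def test_identical_entries_no_outlier(self):
        assert not tukey_outliers(np.full(9, 3.3)).any()

    def test_zscore_degenerate_safe(self):
        assert not zscore_outliers(np.zeros(9)).any()


class TestNetworkExtraction:
    def test_zero_tensor_empty_network(self, cfg4):
        t = CausalTensor(values=np.zeros((4, 9, 4)), tau=5, source_var="r",
                         target_var="s")
        net = ax.extract_causal_network(t)
        assert net.edges == []
        g = net.to_multigraph()
        assert g.number_of_nodes() == 4 and g.number_of_edges() == 0

    def test_single_spike_single_positive_edge(self):
        vals = np.zeros((4, 9, 4))
        vals[2, 8, 0] = 10.0
        t = CausalTensor(values=vals, tau=5, source_var="r", target_var="s")
        net = ax.extract_causal_network(t)
        assert len(net.edges) == 1
        e = net.edges[0]
        assert (e.source, e.target, e.sign) == (1, 3, 1)  # 1-based
        assert e.magnitude == pytest.approx(10.0)
        assert e.source_node == 9

    def test_negative_entry_negative_sign(self):
        vals = np.zeros((4, 9, 4))
        vals[1, 0, 3] = -5.0
        net = ax.extract_causal_network(
            CausalTensor(values=vals, tau=2, source_var="r", target_var="s"))
        assert net.edges[0].sign == -1

    def test_deterministic(self, cfg4):
        p = ax.init_parameters(2, cfg4)
        t = ax.causal_jacobian(p, random_state(cfg4, seed=1), 8, config=cfg4)
        n1 = ax.extract_causal_network(t)
        n2 = ax.extract_causal_network(t)
        assert n1.edge_keys() == n2.edge_keys()
        assert len(n1.edges) == len(n2.edges)

    def test_nonfinite_rejected(self):
        vals = np.full((4, 9, 4), np.nan)
        with pytest.raises(ValueError):
            ax.extract_causal_network(
                CausalTensor(values=vals, tau=1, source_var="r",
                             target_var="s"))


class TestMeanNetworkOverRandomICs:
    def test_ensemble_mean_network_from_trained_genome(self, trained):
        """Causal networks evaluated from several random initial tissues
        combine into a mean network whose edge set is the union of the
        members' and whose frequencies are occupancy fractions."""
        from axichain.experiments import sample_random_ic
        rng = np.random.default_rng(7)
        cfg = trained.config
        nets = []
        for _ in range(3):
            st = sample_random_ic(rng, cfg)
            t = trained.causal_tensor(100, init_state_=st)
            nets.append(ax.extract_causal_network(t))
        mean = ax.mean_causal_network(nets)
        assert mean.ensemble_size == 3
        union = set().union(*(n.edge_keys() for n in nets))
        assert set(mean.edge_frequency) == union
        assert all(0 < f <= 1 for f in mean.edge_frequency.values())


class TestBoundaryMarkerAnalysis:
    def test_boundary_controller_influence_computes(self, trained):
        """The same causal operator covers the boundary-marking pathway
        (source y, target b). The pole cells' organizer-like dominance of
        cross-cell influence is reported, not hard-asserted."""
        net = trained.causal_network(tau=200, source_var="y", target_var="b")
        assert net.n_cells == 12
        cross = [e for e in net.edges if e.source != e.target]
        if cross:
            pole_frac = sum(e.source in (1, 12) for e in cross) / len(cross)
            print(f"\ncross-cell y->b edges: {len(cross)}, "
                  f"from pole cells: {100 * pole_frac:.0f}%")
        for e in net.edges:
            assert 1 <= e.source <= 12 and 1 <= e.target <= 12
            assert np.isfinite(e.magnitude)


class TestMeanCausalNetwork:
    def _net(self, keys, n=4, tau=5):
        from axichain.causal import CausalNetwork, CausalEdge
        edges = [CausalEdge(source=s, target=t, sign=sg, magnitude=1.0,
                            source_node=1) for s, t, sg in keys]
        return CausalNetwork(n_cells=n, tau=tau, edges=edges)

    def test_identical_networks_frequency_one(self):
        nets = [self._net([(1, 2, 1), (3, 4, -1)])] * 3
        mean = ax.mean_causal_network(nets)
        assert mean.edge_frequency == {(1, 2, 1): 1.0, (3, 4, -1): 1.0}

    def test_partial_presence(self):
        nets = [self._net([(1, 2, 1)]), self._net([]), self._net([]),
                self._net([])]
        mean = ax.mean_causal_network(nets)
        assert mean.edge_frequency[(1, 2, 1)] == pytest.approx(0.25)

    def test_union_of_edge_sets(self):
        nets = [self._net([(1, 2, 1)]), self._net([(2, 3, -1)])]
        mean = ax.mean_causal_network(nets)
        assert set(mean.edge_frequency) == {(1, 2, 1), (2, 3, -1)}

    def test_mixed_sizes_rejected(self):
        with pytest.raises(ValueError):
            ax.mean_causal_network([self._net([], n=4), self._net([], n=6)])
        with pytest.raises(ValueError):
            ax.mean_causal_network([])
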