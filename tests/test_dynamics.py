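"""The synchronous update map: algebraic examples and structural properties."""

import numpy as np
import pytest

import axichain as ax
from axichain.dynamics import make_cache
from axichain.params import IC_ANTERIOR, IC_POSTERIOR

from conftest import random_state


def zero_bias(params):
    p = params.copy()
    for name in ("l_bias", "m_bias", "up_bias", "us_bias"):
        setattr(p, name, np.zeros_like(np.asarray(getattr(p, name))))
    return p


class TestDamping:
    def test_examples(self):
        assert ax.damping_factor(0.0) == 1.0
        assert ax.damping_factor(1.0) == pytest.approx(0.5)
        assert ax.damping_factor(2.0) == pytest.approx(1 / 3)
        assert ax.damping_factor(2.0) < ax.damping_factor(1.0)
        # negative marker levels do not amplify
        assert ax.damping_factor(-0.5) == 1.0

    def test_monotone_decreasing(self):
        b = np.linspace(0, 10, 101)
        d = ax.damping_factor(b)
        assert np.all(np.diff(d) < 0)
        assert np.all((d > 0) & (d <= 1))


class TestGjDrive:
    def test_zero_controllers(self, cfg12):
        p = ax.init_parameters(1, cfg12)
        assert ax.gj_drive(np.zeros(9), np.zeros(9), p) == 0.0

    def test_arithmetic_mean_of_contributions(self, cfg12):
        # craft controllers so the two contributions are 0.4 and -0.2
        p = ax.init_parameters(1, cfg12)
        p.ug_posterior = np.array([0.4, 0.0, 0.0])
        p.ug_anterior = np.array([-0.2, 0.0, 0.0])
        r_a = np.zeros(9)
        r_a[IC_POSTERIOR[0]] = 1.0
        r_p = np.zeros(9)
        r_p[IC_ANTERIOR[0]] = 1.0
        assert ax.gj_drive(r_a, r_p, p) == pytest.approx(0.1)

    def test_mirror_contract(self, cfg12, rng):
        # swapping the two cells AND mirroring the ug blocks leaves the
        # drive unchanged
        p = ax.init_parameters(3, cfg12)
        r1 = rng.uniform(-1, 1, 9)
        r2 = rng.uniform(-1, 1, 9)
        from axichain.params import IC_MIRROR
        d1 = ax.gj_drive(r1, r2, p)
        d2 = ax.gj_drive(r2[IC_MIRROR], r1[IC_MIRROR], p.mirror())
        assert d1 == pytest.approx(d2, abs=1e-12)

    def test_shape_mismatch(self, cfg12):
        p = ax.init_parameters(1, cfg12)
        with pytest.raises(ValueError):
            ax.gj_drive(np.zeros(6), np.zeros(9), p)


class TestStep:
    def test_zero_fixed_point_without_constant_drives(self, cfg12):
        """With the constant (bias) drives zeroed the dynamics are odd and
        the featureless all-zero tissue is invariant for any weights."""
        for seed in range(5):
            p = zero_bias(ax.init_parameters(seed, cfg12))
            st = ax.init_state(cfg12)
            assert ax.step(st, p, cfg12).max_abs() == 0.0

    def test_biases_break_the_zero_state(self, cfg12):
        # the trainable constant drives are what let a homogeneous tissue
        # start developing at all
        p = ax.init_parameters(0, cfg12)
        assert ax.step(ax.init_state(cfg12), p, cfg12).max_abs() > 0.0

    def test_chain_locality_one_step(self, cfg6):
        """Perturbing cell k's activity changes, after one step, only
        variables owned by cells k-1, k, k+1 (junctions count as owned by
        both flanking cells)."""
        p = ax.init_parameters(2, cfg6)
        st = random_state(cfg6, seed=4)
        base = ax.step(st, p, cfg6)
        k = 3
        pert = st.copy()
        pert.s[k] += 1e-3
        out = ax.step(pert, p, cfg6)
        for f in ("s", "p", "js", "b"):
            changed = np.flatnonzero(getattr(out, f) != getattr(base, f))
            assert set(changed) <= {k - 1, k, k + 1}
        changed_jg = np.flatnonzero(out.jg != base.jg)
        assert set(changed_jg) <= {k - 1, k}  # junctions touching cell k
        for f in ("r", "y"):
            changed = np.flatnonzero(
                np.any(getattr(out, f) != getattr(base, f), axis=0))
            assert set(changed) <= {k - 1, k, k + 1}

    def test_mirror_equivariance(self, cfg6):
        p = ax.init_parameters(5, cfg6)
        st = random_state(cfg6, seed=6)
        ms, mp = ax.mirror_transform(st, p)
        lhs = ax.step(ms, mp, cfg6)
        rhs = ax.step(st, p, cfg6).mirror()
        for f in lhs.field_names():
            assert np.allclose(getattr(lhs, f), getattr(rhs, f), atol=1e-10)

    def test_jg_saturation(self, cfg6):
        """|jg| <= max(|jg(0)|, jmax) along any trajectory; from rest the
        junction weights never exceed the saturation bound jmax."""
        p = ax.init_parameters(8, cfg6)
        st = ax.init_state(cfg6)
        traj = ax.simulate(st, p, cfg6, 2000)
        assert np.all(np.abs(traj.jg) <= float(p.jmax) + 1e-12)

    def test_states_remain_bounded(self, cfg6):
        p = ax.init_parameters(9, cfg6)
        traj = ax.simulate(random_state(cfg6, seed=1), p, cfg6, 2000)
        assert traj.final_state.max_abs() < 10.0


class TestSimulate:
    def test_zero_steps(self, cfg6):
        st = random_state(cfg6, seed=2)
        traj = ax.simulate(st, ax.init_parameters(0, cfg6), cfg6, 0)
        assert len(traj) == 1
        assert traj.final_state.allclose(st)

    def test_zero_trajectory_under_zero_bias(self, cfg12):
        p = zero_bias(ax.init_parameters(1, cfg12))
        traj = ax.simulate(ax.init_state(cfg12), p, cfg12, 500)
        assert traj.s.max() == 0.0 and traj.b.max() == 0.0

    def test_semigroup(self, cfg6):
        p = ax.init_parameters(4, cfg6)
        st = random_state(cfg6, seed=3)
        t1 = ax.simulate(st, p, cfg6, 100)
        t2 = ax.simulate(t1.final_state, p, cfg6, 100)
        t_full = ax.simulate(st, p, cfg6, 200)
        assert t2.final_state.allclose(t_full.final_state, atol=0)

    def test_bitwise_determinism(self, cfg6):
        p = ax.init_parameters(4, cfg6)
        st = random_state(cfg6, seed=3)
        a = ax.simulate(st, p, cfg6, 300)
        b = ax.simulate(st, p, cfg6, 300)
        for f in ("s", "p", "js", "b", "jg", "r", "y"):
            assert np.array_equal(getattr(a, f), getattr(b, f))

    def test_trajectory_recomputable(self, cfg6):
        """states[t+1] == step(states[t]) for the recorded trajectory."""
        p = ax.init_parameters(4, cfg6)
        traj = ax.simulate(random_state(cfg6, seed=3), p, cfg6, 50)
        for t in (0, 17, 49):
            nxt = ax.step(traj.state_at(t), p, cfg6)
            assert nxt.allclose(traj.state_at(t + 1), atol=0)

    def test_tail_matches_full(self, cfg6):
        p = ax.init_parameters(4, cfg6)
        st = random_state(cfg6, seed=9)
        full = ax.simulate(st, p, cfg6, 400)
        tail = ax.simulate_tail(st, p, cfg6, 400, window=50)
        assert np.allclose(tail.s, full.s[-50:], atol=0)
        assert np.allclose(tail.b, full.b[-50:], atol=0)
        assert tail.final_state.allclose(full.final_state, atol=0)

    def test_divergence_reported_with_step_index(self, cfg6):
        p = ax.init_parameters(4, cfg6)
        st = random_state(cfg6, seed=3)
        st.s[0] = np.nan
        with pytest.raises(ax.DivergenceError) as exc:
            ax.simulate(st, p, cfg6, 300)
        assert exc.value.step_index >= 0


class TestDerivativeOperators:
    def test_jvp_matches_directional_finite_difference(self, cfg6, rng):
        p = ax.init_parameters(5, cfg6)
        st = random_state(cfg6, seed=6)
        tan = st.map(lambda _, a: rng.standard_normal(a.shape))
        h = 1e-6
        plus = st.map(lambda f, a: a + h * getattr(tan, f))
        minus = st.map(lambda f, a: a - h * getattr(tan, f))
        sp, sm = ax.step(plus, p, cfg6), ax.step(minus, p, cfg6)
        jv = ax.jvp_step(st, p, cfg6, tan)
        for f in jv.field_names():
            fd = (getattr(sp, f) - getattr(sm, f)) / (2 * h)
            assert np.allclose(getattr(jv, f), fd, rtol=1e-6, atol=1e-9)

    def test_vjp_adjoint_of_jvp(self, cfg6, rng):
        """<w, J t> == <J^T w, t> for random directions."""
        p = ax.init_parameters(5, cfg6)
        st = random_state(cfg6, seed=6)
        tan = st.map(lambda _, a: rng.standard_normal(a.shape))
        cot = st.map(lambda _, a: rng.standard_normal(a.shape))
        jv = ax.jvp_step(st, p, cfg6, tan)
        cot_in, _ = ax.vjp_step(st, p, cfg6, cot)
        lhs = sum(np.vdot(getattr(cot, f), getattr(jv, f))
                  for f in cot.field_names())
        rhs = sum(np.vdot(getattr(cot_in, f), getattr(tan, f))
                  for f in cot.field_names())
        assert lhs == pytest.approx(rhs, rel=1e-12)

    def test_masked_couplings_are_inert(self, cfg6):
        """Entries of l / m_lat off the lattice edges have no effect on the
        dynamics (they are structurally zero)."""
        p = ax.init_parameters(5, cfg6)
        q = p.copy()
        from axichain.params import IC_EDGE_MASK, BC_EDGE_MASK
        q.l = q.l + 5.0 * ~IC_EDGE_MASK
        q.m_lat = q.m_lat + 5.0 * ~BC_EDGE_MASK
        st = random_state(cfg6, seed=6)
        assert ax.step(st, p, cfg6).allclose(ax.step(st, q, cfg6), atol=0)


class TestMirrorTransform:
    def test_involution(self, cfg6):
        p = ax.init_parameters(5, cfg6)
        st = random_state(cfg6, seed=7)
        ms, mp = ax.mirror_transform(*ax.mirror_transform(st, p))
        assert ms.allclose(st, atol=0)
        for name in p.field_names():
            assert np.array_equal(np.asarray(getattr(mp, name)),
                                  np.asarray(getattr(p, name)))
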