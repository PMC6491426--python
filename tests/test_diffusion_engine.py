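import numpy as np
import pytest

from lhonsim import diffusion_engine as de
from lhonsim.diffusion_engine import (
    CalibrationError,
    SimulationParams,
    apply_degeneration,
    calibrate,
    clone_model,
    init_state,
    run_to_steady_state,
    step,
    step_reference,
)
from lhonsim.fixtures import toy_stencil_cases
from lhonsim.injury_zones import InjurySpec, place_injury
from lhonsim.nerve_geometry import build_nerve


def _toy_state(
    field0: np.ndarray, codes: np.ndarray, params: SimulationParams | None = None
) -> de.SimulationState:
    """A SimulationState over an arbitrary code grid, without a nerve model."""
    import types

    n, m = codes.shape
    code_p = np.zeros((n + 2, m + 2), dtype=np.uint8)
    code_p[1:-1, 1:-1] = codes
    inside = codes != de.CODE_OUTSIDE
    jmin = np.zeros(n, dtype=np.int64)
    jmax = np.full(n, -1, dtype=np.int64)
    for r in np.nonzero(inside.any(axis=1))[0]:
        cols = np.nonzero(inside[r])[0]
        jmin[r], jmax[r] = cols[0], cols[-1]
    padded_ins = np.zeros((n + 2, m + 2), dtype=np.uint8)
    padded_ins[1:-1, 1:-1] = inside
    nbdef = (
        4
        - padded_ins[:-2, 1:-1].astype(np.int16)
        - padded_ins[2:, 1:-1]
        - padded_ins[1:-1, :-2]
        - padded_ins[1:-1, 2:]
    ).astype(np.uint8)
    Cp = np.zeros((n + 2, m + 2))
    Cp[1:-1, 1:-1] = np.where(inside, field0, 0.0)
    stub = types.SimpleNamespace(
        alive=np.zeros(0, dtype=bool),
        pix_off=np.zeros(1, dtype=np.int64),
        pix_idx=np.zeros(0, dtype=np.int64),
        label_grid=np.where(inside, -1, -2).astype(np.int32),
        grid_shape=(n, m),
        n_axons=0,
    )
    st = de.SimulationState(
        field_padded=Cp,
        model=stub,
        code_padded=code_p,
        jmin=jmin,
        jmax=jmax,
        nbdef=nbdef,
        P32=(codes == de.CODE_PERIM).astype(np.float32)
        * (np.float32((params or SimulationParams()).tables()[1][3])),
        ins32=inside.astype(np.float32),
        axon_order=np.zeros(0, dtype=np.int64),
        pix_pad=np.zeros(0, dtype=np.int64),
        perim_pad=np.zeros(0, dtype=np.int64),
        axon_sums=np.zeros(0),
        _buf=np.zeros_like(Cp),
    )
    st.total = float(st.field[inside].sum())
    return st


class TestStencil:
    def test_hand_computed_toy_cases(self):
        # 5x5 grids evolved by direct loop summation of the update rule
        for case in toy_stencil_cases(seed=0):
            p = SimulationParams(
                D_intra=case.D,
                D_extra=case.D,
                S_intra=case.S,
                S_extra=case.S,
                P_coeff=case.P,
                threshold_T=1e12,
            )
            st = _toy_state(case.field0, case.codes, p)
            for _ in range(case.n_steps):
                step(st, p)
            assert np.allclose(st.field, case.expected, rtol=1e-12, atol=1e-12)

    def test_null_dynamics(self):
        codes = np.ones((7, 7), dtype=np.uint8)
        st = _toy_state(np.zeros((7, 7)), codes)
        p = SimulationParams(P_coeff=0.0, threshold_T=1e12)
        for _ in range(5):
            step(st, p)
        assert np.all(st.field == 0.0)

    def test_homogeneous_field_fixed_point(self):
        codes = np.ones((9, 9), dtype=np.uint8)
        st = _toy_state(np.full((9, 9), 3.7), codes)
        p = SimulationParams(P_coeff=0.0, S_intra=0.0, S_extra=0.0, threshold_T=1e12)
        for _ in range(10):
            step(st, p)
        assert np.allclose(st.field, 3.7, rtol=0, atol=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_mass_conservation(self, seed):
        rng = np.random.default_rng(seed)
        codes = np.ones((20, 20), dtype=np.uint8)
        codes[rng.random((20, 20)) < 0.2] = 0  # ragged boundary
        codes[rng.random((20, 20)) < 0.3] = 2
        f0 = rng.random((20, 20)) * 10
        st = _toy_state(f0, codes)
        p = SimulationParams(P_coeff=0.0, S_intra=0.0, S_extra=0.0, threshold_T=1e12)
        t0 = st.total
        for _ in range(200):
            step(st, p)
            assert abs(st.total - t0) <= 1e-9 * t0

    def test_fast_and_general_kernels_agree_with_reference(self):
        rng = np.random.default_rng(4)
        codes = rng.integers(0, 4, size=(15, 15)).astype(np.uint8)
        f0 = rng.random((15, 15)) * 5
        # uniform constants -> fast path; mixed -> general path
        for p in (
            SimulationParams(threshold_T=1e12),
            SimulationParams(threshold_T=1e12, D_intra=0.2, D_extra=0.1,
                             S_intra=0.004, S_extra=0.006),
        ):
            st = _toy_state(f0, codes, p)
            for _ in range(3):
                expected = step_reference(st, p)
                step(st, p)
                assert np.allclose(st.field, expected, rtol=1e-9, atol=1e-12)

    def test_subtractive_variant_clips_at_zero(self):
        codes = np.ones((5, 5), dtype=np.uint8)
        st = _toy_state(np.full((5, 5), 0.001), codes)
        p = SimulationParams(
            threshold_T=1e12, scavenging="subtractive", S_intra=1.0, S_extra=1.0
        )
        step(st, p)
        assert np.all(st.field >= 0.0)
        assert st.total == 0.0

    def test_stability_bound_enforced(self):
        with pytest.raises(ValueError):
            SimulationParams(D_intra=0.3)


class TestDegeneration:
    def test_infinite_threshold_no_death(self, small_nerve, small_params):
        m = clone_model(small_nerve)
        p = SimulationParams(threshold_T=np.inf, max_iterations=300)
        res = run_to_steady_state(m, InjurySpec(preset="mid_temporal"), p)
        assert res.overall_dead_fraction == 0.0

    def test_death_at_exact_threshold(self, small_nerve):
        # an axon held exactly at the threshold mean dies this iteration
        m = clone_model(small_nerve)
        p = SimulationParams()
        st = init_state(m, p, None)
        counts = m.pixel_counts()
        st.axon_sums[:] = 0.0
        st.axon_sums[5] = p.threshold_T * counts[5]
        apply_degeneration(st, p)
        assert not m.alive[5]
        assert st.newly_dead == [5]
        assert m.death_iteration[5] == st.iteration

    def test_release_bookkeeping(self, small_nerve):
        m = clone_model(small_nerve)
        p = SimulationParams()
        st = init_state(m, p, None)
        counts = m.pixel_counts()
        st.axon_sums[:] = 0.0
        st.axon_sums[3] = p.threshold_T * counts[3]
        before = st.total
        apply_degeneration(st, p)
        assert st.total == pytest.approx(before + p.release_R)
        # pixels are extra-axonal now
        flat_codes = st.code_padded.ravel()
        assert np.all(flat_codes[st.pix_pad[m.pix_off[3]: m.pix_off[4]]] == de.CODE_EXTRA)

    def test_isolated_death_without_coupling(self, small_nerve):
        # D = 0 everywhere: one seeded axon dies, nothing propagates
        m = clone_model(small_nerve)
        p = SimulationParams(
            D_intra=0.0, D_extra=0.0, P_coeff=0.0, S_intra=0.0, S_extra=0.0,
            release_R=0.0, injury_amount=0.0, max_iterations=100,
        )
        f0 = np.zeros(m.grid_shape)
        f0.ravel()[m.axon_pixels(10)] = 2 * p.threshold_T
        res = run_to_steady_state(m, f0, p)
        assert (~res.model.alive).sum() == 1
        assert not res.model.alive[10]

    def test_monotone_cascade(self, small_nerve, small_params):
        m = clone_model(small_nerve)
        res = run_to_steady_state(m, InjurySpec(preset="mid_temporal"), small_params)
        h = res.history
        for col in ("frac_dead_small", "frac_dead_medium", "frac_dead_large", "frac_dead_all"):
            assert (np.diff(h[col]) >= 0).all()
        assert ((h[["frac_dead_small", "frac_dead_medium", "frac_dead_large"]] <= 1).all()).all()


class TestSteadyState:
    def test_zero_injury_terminates_quickly(self, small_nerve):
        m = clone_model(small_nerve)
        p = SimulationParams(injury_amount=0.0, max_iterations=3000)
        res = run_to_steady_state(m, InjurySpec(preset="mid_temporal", amount=0.0), p)
        assert res.converged
        assert res.overall_dead_fraction == 0.0
        assert res.steady_iteration < 3000

    def test_non_convergence_flagged(self, small_nerve):
        m = clone_model(small_nerve)
        p = SimulationParams(max_iterations=5)
        res = run_to_steady_state(m, InjurySpec(preset="mid_temporal"), p)
        assert not res.converged
        assert res.steady_iteration == 5

    def test_seed_determinism(self):
        outs = []
        for _ in range(2):
            m = build_nerve(scale=0.03, rng_seed=13)
            p = SimulationParams(max_iterations=3000)
            res = run_to_steady_state(m, InjurySpec(preset="mid_temporal"), p)
            outs.append(res)
        a, b = outs
        assert np.array_equal(a.model.alive, b.model.alive)
        assert np.array_equal(a.model.death_iteration, b.model.death_iteration)
        assert a.history.equals(b.history)


class TestCalibration:
    @pytest.fixture(scope="class")
    def cal_nerve(self):
        return build_nerve(scale=0.04, rng_seed=3)

    def test_survival_monotone_in_threshold(self, cal_nerve):
        outs = []
        for T in (8.0, 40.0):
            m = clone_model(cal_nerve)
            p = SimulationParams(threshold_T=T, max_iterations=4000)
            res = run_to_steady_state(m, InjurySpec(preset="mid_temporal"), p)
            outs.append(1.0 - res.overall_dead_fraction)
        assert outs[0] <= outs[1]

    def test_in_band_returns_unchanged(self, cal_nerve):
        p = SimulationParams(max_iterations=4000)
        m = clone_model(cal_nerve)
        res = run_to_steady_state(m, InjurySpec(preset="mid_temporal"), p)
        s = 1.0 - res.overall_dead_fraction
        got = calibrate(p, cal_nerve, target_survival=(s - 0.02, s + 0.02))
        assert got is p

    def test_unbracketable_target_fails(self, cal_nerve):
        p = SimulationParams(max_iterations=2000)
        with pytest.raises(CalibrationError):
            calibrate(
                p,
                cal_nerve,
                target_survival=(-0.5, -0.4),  # impossible
                bracket=(10.0, 20.0),
                max_evals=2,
            )
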