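"""Assembly, stepping and physical invariants of the bidomain solver."""

import numpy as np
import pytest

from endocv.bidomain_solver import (
    ConductivityParams,
    SimulationConfig,
    StimulusProtocol,
    assemble_system,
    element_conductivities,
    imex_bdf1_step,
    make_membrane_model,
    run_simulation,
)
from endocv.fiber_architecture import FiberField, strand_fibers
from endocv.membrane_models import CourtemancheModel, CubicReaction
from endocv.strand_geometry import StrandSpec, build_straight_strand, build_strand

from conftest import run_strand


class TestConductivityParams:
    def test_positive_required(self):
        with pytest.raises(ValueError):
            ConductivityParams(sigma_b=0.0)

    def test_anisotropy_ratios(self):
        p = ConductivityParams()
        assert p.anisotropy_ratio_i == pytest.approx(10.0)
        assert p.anisotropy_ratio_e == pytest.approx(2.5)


class TestElementConductivities:
    def _fibers(self, mesh, vec):
        els = mesh.muscle_elements
        v = np.tile(vec, (len(els), 1))
        return FiberField(elements=els, vectors=v)

    def test_axis_aligned_tensor(self, small_strand):
        f = self._fibers(small_strand, [0.0, 1.0])
        D_i, D_e = element_conductivities(f, ConductivityParams(), small_strand)
        np.testing.assert_allclose(D_i[0], [[0.45, 0.0], [0.0, 4.5]])
        np.testing.assert_allclose(D_e[0], [[1.8, 0.0], [0.0, 4.5]])

    def test_isotropic_degeneracy(self, small_strand):
        a = np.array([0.6, 0.8])
        f = self._fibers(small_strand, a)
        p = ConductivityParams(sigma_if=0.45)  # sigma_if == sigma_it
        D_i, _ = element_conductivities(f, p, small_strand)
        np.testing.assert_allclose(D_i[0], 0.45 * np.eye(2), atol=1e-14)

    @pytest.mark.parametrize("alpha", [0.3, 1.1, 2.5])
    def test_rotation_conjugates_tensor(self, small_strand, alpha):
        R = np.array([[np.cos(alpha), -np.sin(alpha)],
                      [np.sin(alpha), np.cos(alpha)]])
        f0 = self._fibers(small_strand, [0.0, 1.0])
        fr = self._fibers(small_strand, R @ [0.0, 1.0])
        p = ConductivityParams()
        D0, _ = element_conductivities(f0, p, small_strand)
        Dr, _ = element_conductivities(fr, p, small_strand)
        np.testing.assert_allclose(Dr[0], R @ D0[0] @ R.T, atol=1e-12)

    def test_eigenstructure(self, small_strand):
        a = np.array([3.0, 4.0]) / 5.0
        f = self._fibers(small_strand, a)
        p = ConductivityParams()
        D_i, _ = element_conductivities(f, p, small_strand)
        w = np.linalg.eigvalsh(D_i[0])
        np.testing.assert_allclose(sorted(w), [p.sigma_it, p.sigma_if])
        np.testing.assert_allclose(D_i[0] @ a, p.sigma_if * a)

    def test_non_unit_fiber_rejected(self, small_strand):
        els = small_strand.muscle_elements
        f = FiberField(elements=els,
                       vectors=np.tile([0.0, 1.0], (len(els), 1)))
        f.vectors[0] *= 1.1  # corrupt after construction
        with pytest.raises(ValueError, match="unit"):
            element_conductivities(f, ConductivityParams(), small_strand)


@pytest.fixture(scope="module")
def small_bath_mesh():
    spec = StrandSpec(lm=0.05, lb_endo=0.04, L=0.4, Le=0.3,
                      hX=0.01, hY=0.02)
    return build_straight_strand(spec)


class TestAssembly:
    def test_stiffness_annihilates_constants(self, small_bath_mesh):
        sys_ = assemble_system(
            small_bath_mesh, strand_fibers(small_bath_mesh),
            ConductivityParams(), dt=0.03125,
        )
        ones_V = np.ones(sys_.n_V)
        ones_U = np.ones(sys_.n_U)
        # pure-Neumann compatibility of every stiffness block
        assert np.abs(sys_.K_ii @ ones_V
                      ).max() < 1e-10 * sys_.K_ii.diagonal().max()
        assert np.abs(sys_.K_iu @ ones_U).max() < 1e-10
        assert np.abs(sys_.K_uu @ ones_U).max() < 1e-10

    def test_monolithic_matrix_symmetric(self, small_bath_mesh):
        sys_ = assemble_system(
            small_bath_mesh, strand_fibers(small_bath_mesh),
            ConductivityParams(), dt=0.03125, grounding="zero_mean",
        )
        A = sys_.matrix.tocsr()
        asym = A - A.T
        worst = np.abs(asym.data).max() if asym.nnz else 0.0
        assert worst < 1e-12 * np.abs(A.data).max()

    def test_no_bath_system_has_no_extra_rows(self, small_strand):
        sys_ = assemble_system(
            small_strand, strand_fibers(small_strand),
            ConductivityParams(), dt=0.03125,
        )
        # every node carries V: the operator is the plain two-variable
        # bidomain matrix (plus the grounding border)
        assert sys_.n_V == sys_.n_U == small_strand.n_nodes
        assert sys_.matrix.shape[0] == 2 * small_strand.n_nodes + 1

    def test_fiber_mesh_mismatch_rejected(self, small_strand, small_bath_mesh):
        with pytest.raises(ValueError, match="fiber"):
            assemble_system(
                small_bath_mesh, strand_fibers(small_strand),
                ConductivityParams(), dt=0.03125,
            )


class TestStepping:
    def test_rest_is_preserved_without_stimulus(self, small_strand):
        model = CourtemancheModel()
        sys_ = assemble_system(small_strand, strand_fibers(small_strand),
                               ConductivityParams(), dt=0.03125)
        V, W = model.initial_state(sys_.n_V)
        U = np.zeros(sys_.n_U)
        V0 = V[0]
        for k in range(100):
            V, W, U = imex_bdf1_step(sys_, model, V, W, U, k * 0.03125,
                                     None, np.array([], int))
        assert np.abs(V - V0).max() < 0.01
        assert np.abs(U).max() < 0.01

    def test_zero_mean_constraint_holds(self, small_bath_mesh):
        model = CubicReaction()
        sys_ = assemble_system(small_bath_mesh,
                               strand_fibers(small_bath_mesh),
                               ConductivityParams(), dt=0.03125)
        V, W = model.initial_state(sys_.n_V)
        U = np.zeros(sys_.n_U)
        stim = StimulusProtocol()
        stim_local = sys_.local[small_bath_mesh.stimulus_nodes]
        for k in range(60):
            V, W, U = imex_bdf1_step(sys_, model, V, W, U, k * 0.03125,
                                     stim, stim_local)
        mean_U = float(sys_.mass_all @ U / sys_.mass_all.sum())
        assert abs(mean_U) < 1e-9
        assert np.abs(U).max() > 1e-3  # the field itself is non-trivial

    def test_stimulus_depolarises_stimulated_region(self, small_strand):
        model = CourtemancheModel()
        sys_ = assemble_system(small_strand, strand_fibers(small_strand),
                               ConductivityParams(), dt=0.03125)
        V, W = model.initial_state(sys_.n_V)
        U = np.zeros(sys_.n_U)
        V_rest = V[0]
        stim = StimulusProtocol()
        stim_local = sys_.local[small_strand.stimulus_nodes]
        for k in range(32):  # 1 ms
            V, W, U = imex_bdf1_step(sys_, model, V, W, U, k * 0.03125,
                                     stim, stim_local)
        assert V[stim_local].min() > V_rest + 20.0


class TestRunSimulation:
    def test_cfl_bound_enforced(self):
        mesh, probes = build_strand(StrandSpec(lm=0.15).scaled(8))
        cfg = SimulationConfig(dt=0.5, end_time=5.0)  # hX/v_X = 0.25
        with pytest.raises(ValueError, match="CFL"):
            run_simulation(mesh, probes, cfg)

    def test_membrane_dt_bound_enforced(self):
        mesh, probes = build_strand(StrandSpec(lm=0.15).scaled(8))
        cfg = SimulationConfig(dt=0.25, end_time=5.0, membrane="cubic")
        with pytest.raises(ValueError, match="membrane"):
            run_simulation(mesh, probes, cfg)

    def test_unknown_membrane_rejected(self):
        with pytest.raises(ValueError, match="unknown membrane"):
            make_membrane_model("nygren")

    def test_no_capture_flagged(self):
        mesh, probes = build_strand(StrandSpec(lm=0.15).scaled(8))
        cfg = SimulationConfig(dt=0.0625, end_time=3.0,
                               record_electrograms=False)
        weak = StimulusProtocol(amplitude=1.0)  # far below capture
        with pytest.warns(UserWarning, match="no capture"):
            rec = run_simulation(mesh, probes, cfg, stim=weak)
        assert not rec.captured

    def test_wavefront_advances_monotonically(self):
        mesh, probes, rec = run_strand(lm=0.15, scale=8)
        iface = mesh.interface_nodes
        at = rec.activation[iface]
        ys = mesh.straight_nodes[iface, 1]
        sel = ~np.isnan(at) & (ys > 0.0)
        d = np.diff(at[sel])
        assert (d > 0).all()

    def test_sampling_on_exact_milliseconds(self):
        _, _, rec = run_strand(lm=0.15, scale=8, end_time=10.0,
                               stop_margin=50.0)
        np.testing.assert_allclose(rec.times, np.arange(len(rec.times)),
                                   atol=1e-12)

    def test_snapshots_recorded(self):
        mesh, probes, rec = run_strand(lm=0.15, scale=8, end_time=6.0,
                                       stop_margin=50.0,
                                       snapshot_times=(4.0,))
        assert len(rec.snapshots) == 1
        t, V_full, U = rec.snapshots[0]
        assert t == pytest.approx(4.0)
        # V defined on muscle nodes only
        assert np.isnan(V_full).sum() == 0  # no bath here: all muscle
        assert len(U) == mesh.n_nodes


class TestInitialConditionMode:
    def test_prescribed_depolarised_region_launches_wave(self):
        """Instead of a current stimulus, V = 30 mV prescribed on the
        bottom strip launches a propagating wave (the protocol used for
        anatomical geometries)."""
        from endocv.wave_analysis import cv_two_point

        spec = StrandSpec(lm=0.15).scaled(8)
        mesh, probes = build_strand(spec)
        cfg = SimulationConfig(
            dt=0.03125, end_time=80.0, membrane="cubic",
            record_electrograms=False, stop_margin=1.0,
            initial_activation_nodes=mesh.stimulus_nodes,
        )
        rec = run_simulation(mesh, probes, cfg, stim=None)
        assert rec.captured
        assert 40.0 < cv_two_point(rec.activation, probes) < 100.0


class TestBathGrading:
    def test_graded_bath_reproduces_uniform_bath_cv(self):
        """Coarsening the bath mesh away from the interface (boundary
        layer kept fine) leaves the endocardial CV essentially unchanged
        while shrinking the problem."""
        from endocv.wave_analysis import cv_two_point

        def cv_and_nodes(grading):
            spec = StrandSpec(lm=0.15, lb_endo=0.6, hX=0.005, hY=0.01,
                              bath_grading=grading)
            mesh, probes = build_strand(spec)
            cfg = SimulationConfig(dt=0.0625, end_time=80.0,
                                   record_electrograms=False,
                                   stop_margin=2.0)
            rec = run_simulation(mesh, probes, cfg)
            return cv_two_point(rec.activation, probes), mesh.n_nodes

        cv_u, n_u = cv_and_nodes(1.0)
        cv_g, n_g = cv_and_nodes(1.4)
        assert n_g < 0.55 * n_u
        assert cv_g == pytest.approx(cv_u, rel=0.01)


class TestFrontShape:
    def test_isotropic_front_far_more_planar_than_anisotropic(self):
        """In the bent region the transmural front tilt under isotropic
        conductivities is small (~0.1 ms) and many times smaller than the
        anisotropic tilt -- the front-shape effect the anisotropy ratio
        controls."""
        import math

        from endocv.bidomain_solver import ConductivityParams, run_simulation

        def transmural_spread(params):
            spec = StrandSpec(lm=0.15, theta=math.pi, c=1).scaled(2)
            mesh, probes = build_strand(spec)
            cfg = SimulationConfig(dt=0.0625, end_time=80.0,
                                   record_electrograms=False,
                                   stop_margin=2.0)
            rec = run_simulation(mesh, probes, cfg, params=params)
            sn, at = mesh.straight_nodes, rec.activation
            row = np.isclose(sn[:, 1], 1.2) & ~np.isnan(at)
            return at[row].max() - at[row].min()

        iso = transmural_spread(ConductivityParams(
            sigma_if=4.5, sigma_it=4.5, sigma_ef=4.5, sigma_et=4.5))
        aniso = transmural_spread(ConductivityParams())
        assert iso < 0.15          # ms: a fraction of a degree of tilt
        assert iso < aniso / 4.0   # anisotropy curves the front strongly


class TestGroundingInvariance:
    def test_bipolar_signals_identical_across_grounding_modes(self):
        kw = dict(lm=0.15, lb_endo=0.15, scale=8, membrane="cubic",
                  record_electrograms=True)
        _, _, rec_zm = run_strand(grounding="zero_mean", **kw)
        _, _, rec_pin = run_strand(grounding="pin", **kw)
        bip_zm = rec_zm.traces["Ve_p2"] - rec_zm.traces["Ve_p1"]
        bip_pin = rec_pin.traces["Ve_p2"] - rec_pin.traces["Ve_p1"]
        n = min(len(bip_zm), len(bip_pin))
        assert np.abs(bip_zm[:n] - bip_pin[:n]).max() < 1e-8
        # while the unipolar traces differ by the grounding constant
        assert np.abs(rec_zm.traces["Ve_p1"][:n]
                      - rec_pin.traces["Ve_p1"][:n]).max() > 0
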