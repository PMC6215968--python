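"""Monolithic bidomain + bath finite-element solver.

The muscle region carries the two bidomain equations for the
transmembrane potential ``V`` and the extracellular potential; the bath
carries a Poisson equation for the bath potential.  Because the
extracellular and bath potentials are continuous across the muscle-bath
interface, they are represented by a single nodal field ``U`` on the whole
mesh (``U = V_e`` in the muscle, ``U = V_b`` in the bath); interface
current continuity and the zero intracellular interface flux are natural
conditions of the weak form.  All exterior boundaries are insulated.

Discretisation: linear triangular elements with per-element anisotropic
conductivity tensors built from the fiber field, lumped mass for the
time-derivative and ionic terms (nodal ionic-current evaluation), and
first-order IMEX stepping -- membrane states advance explicitly at each
muscle node, then one sparse direct solve advances ``(V, U)`` with
diffusion implicit.  The pure-Neumann ``U`` problem is grounded either by
a zero-mean constraint (rank-one symmetric bordering, the default) or by
pinning a single node.

Units: mV, ms, cm, mS/cm, uF/cm^2, uA (so all equations hold without
conversion factors).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .fiber_architecture import FiberField, _p1_gradients, strand_fibers
from .membrane_models import CourtemancheModel, CubicReaction, MembraneModel
from .strand_geometry import MUSCLE, ProbeSet, TissueMesh

__all__ = [
    "ConductivityParams",
    "StimulusProtocol",
    "SimulationConfig",
    "SimulationRecording",
    "BidomainSystem",
    "element_conductivities",
    "assemble_system",
    "run_simulation",
    "make_membrane_model",
]


@dataclass
class ConductivityParams:
    """Conductivities (mS/cm), membrane capacitance (uF/cm^2) and
    surface-to-volume ratio (1/cm)."""

    sigma_if: float = 4.5     # intracellular, along fiber
    sigma_it: float = 0.45    # intracellular, cross fiber
    sigma_ef: float = 4.5     # extracellular, along fiber
    sigma_et: float = 1.8     # extracellular, cross fiber
    sigma_b: float = 20.0     # bath (isotropic)
    C_m: float = 1.0
    chi: float = 1000.0

    def __post_init__(self):
        for name in ("sigma_if", "sigma_it", "sigma_ef", "sigma_et",
                     "sigma_b", "C_m", "chi"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def anisotropy_ratio_i(self) -> float:
        return self.sigma_if / self.sigma_it

    @property
    def anisotropy_ratio_e(self) -> float:
        return self.sigma_ef / self.sigma_et

    def scale_longitudinal(self, factor: float) -> "ConductivityParams":
        """New parameter set with both longitudinal conductivities scaled."""
        return ConductivityParams(
            sigma_if=self.sigma_if * factor, sigma_it=self.sigma_it,
            sigma_ef=self.sigma_ef * factor, sigma_et=self.sigma_et,
            sigma_b=self.sigma_b, C_m=self.C_m, chi=self.chi,
        )


@dataclass
class StimulusProtocol:
    """Equal-and-opposite volumetric current pair confined to the tagged
    stimulus node set of the muscle.

    The extracellular and intracellular compartments receive ``+amplitude``
    and ``-amplitude`` respectively, so the total applied current is zero
    and only the transmembrane equation sees a net source.  Boundary
    surface currents and the bath current are zero throughout.
    """

    amplitude: float = 1.0e5    # uA/cm^3 (chi x 100 uA/cm^2 of membrane)
    duration: float = 2.0       # ms
    start: float = 0.0          # ms

    def active(self, t: float) -> bool:
        return self.start <= t < self.start + self.duration


@dataclass
class SimulationConfig:
    """Numerical controls for a tissue run."""

    dt: float = 0.03125              # ms
    end_time: float = 60.0           # ms (hard cap; early stop below)
    sample_interval: float = 1.0     # ms (1 kHz probe recording)
    threshold: float = -5.0          # mV activation threshold
    interpolate_crossings: bool = True
    membrane: str = "courtemanche"   # or "cubic"
    rush_larsen: bool = True         # gate integrator (False: forward Euler)
    grounding: str = "zero_mean"     # or "pin"
    pin_node: int = 0
    stop_margin: float = 10.0        # ms past the last required probe
    v_X_estimate: float = 0.08       # cm/ms, for the CFL-style dt bound
    enforce_cfl: bool = True
    record_electrograms: bool = True
    initial_activation_nodes: np.ndarray | None = None  # V = 30 mV here
    initial_activation_V: float = 30.0
    snapshot_times: Sequence[float] = ()

    def validate(self, hX: float) -> None:
        if self.dt <= 0 or self.end_time <= 0:
            raise ValueError("dt and end_time must be positive")
        if self.sample_interval / self.dt % 1 > 1e-9:
            raise ValueError("dt must divide the sample interval exactly")
        bound = hX / self.v_X_estimate
        if self.enforce_cfl and self.dt > bound * (1 + 1e-9):
            raise ValueError(
                f"dt={self.dt} violates the CFL-style bound hX/v_X="
                f"{bound:.5g} ms (hX={hX} cm, v_X={self.v_X_estimate} cm/ms)"
            )


def make_membrane_model(name_or_model) -> MembraneModel:
    if isinstance(name_or_model, MembraneModel):
        return name_or_model
    name = str(name_or_model).lower()
    if name in ("courtemanche", "crn"):
        return CourtemancheModel()
    if name == "cubic":
        return CubicReaction()
    raise ValueError(f"unknown membrane model {name_or_model!r}")


# -- conductivity tensors ---------------------------------------------------

def element_conductivities(
    fibers: FiberField, params: ConductivityParams, mesh: TissueMesh
) -> tuple[np.ndarray, np.ndarray]:
    """Per-muscle-element 2x2 tensors ``D = sigma_t I + (sigma_f -
    sigma_t) f (x) f`` for the intracellular and extracellular compartments.

    The tensors have eigenvalues exactly ``{sigma_f, sigma_t}`` with the
    fiber as the sigma_f eigenvector.  Bath elements are handled separately
    as ``sigma_b I``.
    """
    f = fibers.vectors
    norms = np.linalg.norm(f, axis=1)
    if not np.allclose(norms, 1.0, atol=1e-10):
        raise ValueError("fiber vectors must be unit length")
    eye = np.eye(2)
    ff = np.einsum("ka,kb->kab", f, f)
    D_i = params.sigma_it * eye + (params.sigma_if - params.sigma_it) * ff
    D_e = params.sigma_et * eye + (params.sigma_ef - params.sigma_et) * ff
    return D_i, D_e


def _assemble_stiffness(
    nodes: np.ndarray, tris: np.ndarray, tensors: np.ndarray, n: int
) -> sp.csr_matrix:
    """Sum over elements of ``area * grad_a . D grad_b``."""
    grads, areas = _p1_gradients(nodes, tris)
    ke = np.einsum("kad,kde,kbe,k->kab", grads, tensors, grads, areas)
    rows = np.repeat(tris, 3, axis=1).ravel()
    cols = np.tile(tris, (1, 3)).ravel()
    return sp.csr_matrix((ke.ravel(), (rows, cols)), shape=(n, n))


def _lumped_mass(tris: np.ndarray, areas: np.ndarray, n: int) -> np.ndarray:
    m = np.zeros(n)
    np.add.at(m, tris.ravel(), np.repeat(areas / 3.0, 3))
    return m


@dataclass
class BidomainSystem:
    """Assembled, factorised monolithic operator for a fixed timestep."""

    mesh: TissueMesh
    params: ConductivityParams
    dt: float
    grounding: str
    muscle_nodes: np.ndarray       # global indices carrying V
    local: np.ndarray              # global -> local V index (-1 elsewhere)
    mass_muscle: np.ndarray        # lumped mass at muscle nodes (muscle elements)
    mass_all: np.ndarray           # lumped mass over the whole domain
    K_ii: sp.csr_matrix            # V-V stiffness block
    K_iu: sp.csr_matrix            # V-U coupling (muscle rows, all columns)
    K_uu: sp.csr_matrix            # U-U block (D_i + D_e in muscle, D_b in bath)
    matrix: sp.spmatrix = field(repr=False)   # grounded monolithic operator
    lu: spla.SuperLU = field(repr=False)

    @property
    def n_V(self) -> int:
        return len(self.muscle_nodes)

    @property
    def n_U(self) -> int:
        return self.mesh.n_nodes

    def solve(self, rhs_V: np.ndarray, rhs_U: np.ndarray):
        if self.grounding == "zero_mean":
            rhs = np.concatenate([rhs_V, rhs_U, [0.0]])
            sol = self.lu.solve(rhs)
        else:
            rhs_U = rhs_U.copy()
            rhs_U[0] = 0.0  # pinned row was replaced by identity
            sol = self.lu.solve(np.concatenate([rhs_V, rhs_U]))
        return sol[: self.n_V], sol[self.n_V: self.n_V + self.n_U]


def assemble_system(
    mesh: TissueMesh,
    fibers: FiberField,
    params: ConductivityParams,
    dt: float,
    grounding: str = "zero_mean",
    pin_node: int | None = None,
) -> BidomainSystem:
    """Assemble and factorise the monolithic (V, U) operator.

    Unknowns: ``V`` on muscle nodes, ``U`` on all nodes.  The system reads

    ``[(chi C_m / dt) M_L + K_i,  K_i     ] [V]   [rhs_V]``
    ``[K_i^T,                     K_i+K_e+K_b] [U] = [rhs_U]``

    with natural zero-flux boundary conditions everywhere and grounding of
    the pure-Neumann ``U`` block.  The factorisation is reused across all
    timesteps (constant coefficients and dt).
    """
    N = mesh.n_nodes
    els_m = mesh.muscle_elements
    tris_m = mesh.triangles[els_m]
    D_i, D_e = element_conductivities(fibers, params, mesh)
    if fibers.elements.shape != els_m.shape or np.any(fibers.elements != els_m):
        raise ValueError("fiber field does not match the muscle elements")

    K_i = _assemble_stiffness(mesh.nodes, tris_m, D_i, N)
    K_e = _assemble_stiffness(mesh.nodes, tris_m, D_e, N)
    els_b = np.where(mesh.region != MUSCLE)[0]
    if len(els_b):
        tris_b = mesh.triangles[els_b]
        Db = np.broadcast_to(
            params.sigma_b * np.eye(2), (len(els_b), 2, 2)
        )
        K_b = _assemble_stiffness(mesh.nodes, tris_b, Db, N)
    else:
        K_b = sp.csr_matrix((N, N))

    mn = mesh.muscle_nodes
    local = -np.ones(N, dtype=np.int64)
    local[mn] = np.arange(len(mn))

    K_ii = K_i[mn][:, mn].tocsr()
    K_iu = K_i[mn].tocsr()
    K_uu = (K_i + K_e + K_b).tocsr()

    areas_m = mesh.areas()[els_m]
    mass_m = _lumped_mass(tris_m, areas_m, N)[mn]
    areas_all = mesh.areas()
    mass_all = _lumped_mass(mesh.triangles, areas_all, N)

    A = sp.diags(params.chi * params.C_m / dt * mass_m) + K_ii
    if grounding == "zero_mean":
        w = sp.csr_matrix(mass_all[:, None])
        big = sp.bmat(
            [
                [A, K_iu, None],
                [K_iu.T, K_uu, w],
                [None, w.T, None],
            ],
            format="csc",
        )
    elif grounding == "pin":
        p = int(pin_node if pin_node is not None else 0)
        K_uu_g = K_uu.tolil()
        K_uu_g[p, :] = 0.0
        K_uu_g[p, p] = 1.0
        K_iu_colfix = K_iu.T.tolil()
        K_iu_colfix[p, :] = 0.0
        big = sp.bmat([[A, K_iu], [K_iu_colfix.tocsr(), K_uu_g.tocsr()]],
                      format="csc")
    else:
        raise ValueError(f"unknown grounding mode {grounding!r}")

    try:
        lu = spla.splu(big)
    except RuntimeError as err:  # pragma: no cover - diagnostics path
        raise RuntimeError(
            f"singular monolithic operator after grounding={grounding!r}: "
            f"{err}"
        ) from err

    return BidomainSystem(
        mesh=mesh, params=params, dt=dt, grounding=grounding,
        muscle_nodes=mn, local=local, mass_muscle=mass_m, mass_all=mass_all,
        K_ii=K_ii, K_iu=K_iu, K_uu=K_uu, matrix=big, lu=lu,
    )


# -- recording --------------------------------------------------------------

@dataclass
class SimulationRecording:
    """Probe traces at 1 kHz, per-node activation times and snapshots."""

    times: np.ndarray                     # sample instants (ms)
    traces: dict[str, np.ndarray]         # V_x1, V_x2, Ve_x1, ..., Ve_p2
    activation: np.ndarray                # (N,) ms; NaN = not activated / bath
    threshold: float
    captured: bool                        # both activation probes fired
    probes: ProbeSet
    end_time: float
    snapshots: list[tuple[float, np.ndarray, np.ndarray]] = field(
        default_factory=list
    )  # (t, V_full_with_nan, U)

    def trace(self, name: str) -> np.ndarray:
        return self.traces[name]


def imex_bdf1_step(
    system: BidomainSystem,
    model: MembraneModel,
    V: np.ndarray,
    W: np.ndarray,
    U: np.ndarray,
    t: float,
    stim: StimulusProtocol | None,
    stim_local: np.ndarray,
    rush_larsen: bool = True,
):
    """One IMEX BDF1 step: explicit membrane update at clamped V, then a
    single implicit linear solve for (V, U)."""
    p = system.params
    W, I_ion = model.step(V, W, system.dt, rush_larsen=rush_larsen)
    rhs_V = (p.chi * p.C_m / system.dt) * system.mass_muscle * V \
        - p.chi * system.mass_muscle * I_ion
    if stim is not None and stim.active(t):
        rhs_V[stim_local] += stim.amplitude * system.mass_muscle[stim_local]
    V_new, U_new = system.solve(rhs_V, np.zeros(system.n_U))
    if not (np.all(np.isfinite(V_new)) and np.all(np.isfinite(U_new))):
        raise FloatingPointError(
            f"non-finite solution at t={t + system.dt:.4f} ms "
            f"(max |V| so far {np.nanmax(np.abs(V)):.3g} mV)"
        )
    return V_new, W, U_new


def run_simulation(
    mesh: TissueMesh,
    probes: ProbeSet,
    config: SimulationConfig,
    params: ConductivityParams | None = None,
    stim: StimulusProtocol | None = None,
    fibers: FiberField | None = None,
    model: MembraneModel | None = None,
    system: BidomainSystem | None = None,
) -> SimulationRecording:
    """Stimulate the strand and record probe traces and activation times.

    The run stops at ``config.end_time`` or, earlier, once every required
    probe has activated plus ``config.stop_margin`` ms (the margin lets the
    electrogram tails at p1/p2 be captured).  The whole pipeline is
    deterministic.
    """
    params = params or ConductivityParams()
    config.validate(mesh.spec.hX)
    if stim is None and config.initial_activation_nodes is None:
        stim = StimulusProtocol()
    fibers = fibers or strand_fibers(mesh)
    model = model or make_membrane_model(config.membrane)
    if config.dt > model.max_dt + 1e-12:
        raise ValueError(
            f"dt={config.dt} exceeds the membrane model's recommended "
            f"maximum {model.max_dt} ms"
        )
    if system is None:
        system = assemble_system(
            mesh, fibers, params, config.dt,
            grounding=config.grounding, pin_node=config.pin_node,
        )

    mn = system.muscle_nodes
    n_m = len(mn)
    V, W = model.initial_state(n_m)
    V_rest = float(V[0])
    if config.initial_activation_nodes is not None:
        V[system.local[np.asarray(config.initial_activation_nodes)]] = \
            config.initial_activation_V
    U = np.zeros(system.n_U)
    stim_local = (
        system.local[mesh.stimulus_nodes] if stim is not None else np.array([], int)
    )

    dt = config.dt
    per_sample = int(round(config.sample_interval / dt))
    n_steps = int(round(config.end_time / dt))

    probe_names = ("x1", "x2", "p1", "p2")
    probe_nodes = {
        "x1": probes.node_x1, "x2": probes.node_x2,
        "p1": probes.node_p1, "p2": probes.node_p2,
    }
    required = [probes.node_x1, probes.node_x2]
    if config.record_electrograms:
        required += [probes.node_p1, probes.node_p2]

    times = [0.0]
    traces: dict[str, list[float]] = {}
    for nm_ in probe_names:
        g = probe_nodes[nm_]
        traces[f"V_{nm_}"] = [float(V[system.local[g]])
                              if system.local[g] >= 0 else math.nan]
        traces[f"Ve_{nm_}"] = [float(U[g])]

    act_local = np.full(n_m, np.nan)
    snapshot_steps = {int(round(ts / dt)): ts for ts in config.snapshot_times}
    snapshots: list[tuple[float, np.ndarray, np.ndarray]] = []

    t = 0.0
    for k in range(n_steps):
        V_old = V
        V, W, U = imex_bdf1_step(
            system, model, V, W, U, t, stim, stim_local,
            rush_larsen=config.rush_larsen,
        )
        t = (k + 1) * dt
        newly = np.isnan(act_local) & (V >= config.threshold) & \
            (V_old < config.threshold)
        if newly.any():
            if config.interpolate_crossings:
                frac = (config.threshold - V_old[newly]) / \
                    (V[newly] - V_old[newly])
                act_local[newly] = (t - dt) + frac * dt
            else:
                act_local[newly] = t
        if (k + 1) % per_sample == 0:
            times.append(t)
            for nm_ in probe_names:
                g = probe_nodes[nm_]
                lv = system.local[g]
                traces[f"V_{nm_}"].append(float(V[lv]) if lv >= 0 else math.nan)
                traces[f"Ve_{nm_}"].append(float(U[g]))
        if (k + 1) in snapshot_steps:
            V_full = np.full(system.n_U, np.nan)
            V_full[mn] = V
            snapshots.append((t, V_full, U.copy()))
        if required:
            req_act = act_local[system.local[required]]
            if not np.isnan(req_act).any() and \
                    t >= np.nanmax(req_act) + config.stop_margin:
                break

    activation = np.full(system.n_U, np.nan)
    activation[mn] = act_local
    captured = not np.isnan(
        act_local[system.local[[probes.node_x1, probes.node_x2]]]
    ).any()
    if not captured:
        warnings.warn("no capture: activation probes never crossed threshold")

    return SimulationRecording(
        times=np.asarray(times),
        traces={k_: np.asarray(v_) for k_, v_ in traces.items()},
        activation=activation,
        threshold=config.threshold,
        captured=captured,
        probes=probes,
        end_time=t,
        snapshots=snapshots,
    )
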