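"""Ionic membrane kinetics used by the bidomain solver.

Two models are provided behind a single contract (:class:`MembraneModel`):

* :class:`CourtemancheModel` -- the Courtemanche--Ramirez--Nattel human
  atrial action-potential model (21 states: membrane potential, 15 gating
  variables and 5 ionic concentrations), vectorised over an arbitrary
  number of cells/nodes.
* :class:`CubicReaction` -- a bistable cubic reaction with no gating
  variables, whose planar travelling-wave speed has a closed form; it is
  used for numerical verification of the tissue-scale machinery.

Sign convention: the transmembrane current ``I_ion`` (uA/cm^2 of membrane)
enters the tissue equations as ``chi * (C_m dV/dt + I_ion) = diffusion``,
so a *depolarising* current is *negative*.

Units: mV, ms, mM, uA/cm^2 throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "MembraneModel",
    "CourtemancheModel",
    "CubicReaction",
    "resting_state",
    "step_membrane",
    "single_cell_ap",
    "pace",
    "APMetrics",
]

# physical constants shared by the ionic models
_R = 8.3143       # J / (mol K)
_T = 310.0        # K
_F = 96.4867      # C / mmol
_RTF = _R * _T / _F


class MembraneModel:
    """Contract for ionic kinetics.

    Subclasses expose a resting state, a one-step update of the gating /
    concentration states given a clamped membrane potential, and the
    transmembrane current at the (updated) state.
    """

    #: number of non-voltage state variables
    n_states: int = 0
    #: names of the non-voltage states, in storage order
    state_names: tuple[str, ...] = ()
    #: largest explicit timestep (ms) for which the gating update is stable
    max_dt: float = 0.0625

    def initial_state(self, n: int = 1) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(V, W)`` with ``V`` shape ``(n,)`` and ``W`` shape
        ``(n_states, n)`` -- the published initial (quiescent) state."""
        raise NotImplementedError

    def step(
        self, V: np.ndarray, W: np.ndarray, dt: float, rush_larsen: bool = False
    ) -> tuple[np.ndarray, np.ndarray]:
        """Advance the non-voltage states by ``dt`` at clamped ``V``.

        Returns ``(W_new, I_ion)`` where ``I_ion`` (uA/cm^2) is evaluated
        at the updated state and the given ``V``.
        """
        raise NotImplementedError

    def i_ion(self, V: np.ndarray, W: np.ndarray) -> np.ndarray:
        """Transmembrane current at state ``(V, W)`` without advancing it."""
        raise NotImplementedError


# --------------------------------------------------------------------------
# Courtemanche--Ramirez--Nattel 1998 human atrial model
# --------------------------------------------------------------------------

@dataclass
class CourtemancheParams:
    """Maximal conductances and exchanger/pump parameters (nS/pF, pA/pF).

    Every parameter is exposed so that variant parameter sets can be applied
    as configuration overlays without touching the kinetics code.
    """

    g_Na: float = 7.8
    g_K1: float = 0.09
    g_to: float = 0.1652
    g_Kr: float = 0.029411765
    g_Ks: float = 0.12941176
    g_CaL: float = 0.12375
    g_bCa: float = 0.001131
    g_bNa: float = 0.0006744375
    I_NaK_max: float = 0.59933874
    I_NaCa_max: float = 1600.0
    I_pCa_max: float = 0.275
    Km_Nai: float = 10.0
    Km_Ko: float = 1.5
    Km_Na: float = 87.5
    Km_Ca: float = 1.38
    k_sat: float = 0.1
    gamma: float = 0.35
    K_Q10: float = 3.0
    # external concentrations (mM)
    Na_o: float = 140.0
    K_o: float = 5.4
    Ca_o: float = 1.8
    # SR / buffering
    k_rel: float = 30.0
    I_up_max: float = 0.005
    K_up: float = 0.00092
    Ca_up_max: float = 15.0
    tau_tr: float = 180.0
    tau_u: float = 8.0
    tau_fCa: float = 2.0
    Cmdn_max: float = 0.05
    Trpn_max: float = 0.07
    Csqn_max: float = 10.0
    Km_Cmdn: float = 0.00238
    Km_Trpn: float = 0.0005
    Km_Csqn: float = 0.8
    # cell geometry
    Cm_cell: float = 100.0      # pF
    V_i: float = 13668.0        # um^3
    V_up: float = 1109.52       # um^3
    V_rel: float = 96.48        # um^3


# storage order of the 20 non-voltage states
_CRN_STATES = (
    "m", "h", "j", "oa", "oi", "ua", "ui", "xr", "xs",
    "d", "f", "fCa", "u", "v", "w",
    "Na_i", "K_i", "Ca_i", "Ca_up", "Ca_rel",
)

# quiescent state as published with the 1998 model
_CRN_Y0 = {
    "V": -81.18,
    "m": 2.908e-3, "h": 9.649e-1, "j": 9.775e-1,
    "oa": 3.043e-2, "oi": 9.992e-1,
    "ua": 4.966e-3, "ui": 9.986e-1,
    "xr": 3.296e-5, "xs": 1.869e-2,
    "d": 1.367e-4, "f": 9.996e-1, "fCa": 7.755e-1,
    "u": 0.0, "v": 1.0, "w": 9.992e-1,
    "Na_i": 11.17, "K_i": 139.0, "Ca_i": 1.013e-4,
    "Ca_up": 1.488, "Ca_rel": 1.488,
}


def _safe_ratio(num: np.ndarray, den: np.ndarray, limit: float) -> np.ndarray:
    """num/den with the removable singularity at den == 0 replaced by limit."""
    small = np.abs(den) < 1e-10
    out = np.where(small, limit, num / np.where(small, 1.0, den))
    return out


class CourtemancheModel(MembraneModel):
    """Vectorised Courtemanche--Ramirez--Nattel human atrial model."""

    n_states = len(_CRN_STATES)
    state_names = _CRN_STATES
    n_gates = 15  # leading entries of the state vector updated as gates
    max_dt = 0.0625

    def __init__(self, params: CourtemancheParams | None = None):
        self.p = params or CourtemancheParams()

    # -- state management ---------------------------------------------------

    def initial_state(self, n: int = 1) -> tuple[np.ndarray, np.ndarray]:
        V = np.full(n, _CRN_Y0["V"])
        W = np.empty((self.n_states, n))
        for k, name in enumerate(_CRN_STATES):
            W[k] = _CRN_Y0[name]
        return V, W

    # -- kinetics -----------------------------------------------------------

    def _gate_rates(self, V: np.ndarray, Ca_i: np.ndarray, Fn: np.ndarray):
        """(x_inf, tau_x) for the 15 gating variables, in storage order."""
        p = self.p
        exp = np.exp

        # fast sodium (Luo--Rudy kinetics)
        a_m = _safe_ratio(0.32 * (V + 47.13), 1.0 - exp(-0.1 * (V + 47.13)), 3.2)
        b_m = 0.08 * exp(-V / 11.0)
        low = V < -40.0
        a_h = np.where(low, 0.135 * exp(-(V + 80.0) / 6.8), 0.0)
        b_h = np.where(
            low,
            3.56 * exp(0.079 * V) + 3.1e5 * exp(0.35 * V),
            1.0 / (0.13 * (1.0 + exp(-(V + 10.66) / 11.1))),
        )
        a_j = np.where(
            low,
            (-1.2714e5 * exp(0.2444 * V) - 3.474e-5 * exp(-0.04391 * V))
            * (V + 37.78) / (1.0 + exp(0.311 * (V + 79.23))),
            0.0,
        )
        b_j = np.where(
            low,
            0.1212 * exp(-0.01052 * V) / (1.0 + exp(-0.1378 * (V + 40.14))),
            0.3 * exp(-2.535e-7 * V) / (1.0 + exp(-0.1 * (V + 32.0))),
        )

        # transient outward / ultrarapid delayed rectifier
        a_oa = 0.65 / (exp(-(V + 10.0) / 8.5) + exp(-(V - 30.0) / 59.0))
        b_oa = 0.65 / (2.5 + exp((V + 82.0) / 17.0))
        oa_inf = 1.0 / (1.0 + exp(-(V + 20.47) / 17.54))
        a_oi = 1.0 / (18.53 + exp((V + 113.7) / 10.95))
        b_oi = 1.0 / (35.56 + exp(-(V + 1.26) / 7.44))
        oi_inf = 1.0 / (1.0 + exp((V + 43.1) / 5.3))
        ua_inf = 1.0 / (1.0 + exp(-(V + 30.3) / 9.6))
        a_ui = 1.0 / (21.0 + exp(-(V - 185.0) / 28.0))
        b_ui = exp((V - 158.0) / 16.0)
        ui_inf = 1.0 / (1.0 + exp((V - 99.45) / 27.48))

        # delayed rectifiers
        a_xr = _safe_ratio(
            0.0003 * (V + 14.1), 1.0 - exp(-(V + 14.1) / 5.0), 0.0015
        )
        b_xr = _safe_ratio(
            7.3898e-5 * (V - 3.3328),
            exp((V - 3.3328) / 5.1237) - 1.0,
            7.3898e-5 * 5.1237,
        )
        xr_inf = 1.0 / (1.0 + exp(-(V + 14.1) / 6.5))
        a_xs = _safe_ratio(
            4e-5 * (V - 19.9), 1.0 - exp(-(V - 19.9) / 17.0), 4e-5 * 17.0
        )
        b_xs = _safe_ratio(
            3.5e-5 * (V - 19.9), exp((V - 19.9) / 9.0) - 1.0, 3.5e-5 * 9.0
        )
        xs_inf = (1.0 + exp(-(V - 19.9) / 12.7)) ** -0.5

        # L-type calcium
        e_d = exp(-(V + 10.0) / 6.24)
        tau_d = _safe_ratio(
            1.0 - e_d, 0.035 * (V + 10.0) * (1.0 + e_d), 1.0 / (0.035 * 6.24 * 2.0)
        )
        d_inf = 1.0 / (1.0 + exp(-(V + 10.0) / 8.0))
        f_inf = 1.0 / (1.0 + exp((V + 28.0) / 6.9))
        tau_f = 9.0 / (0.0197 * exp(-(0.0337**2) * (V + 10.0) ** 2) + 0.02)
        fCa_inf = 1.0 / (1.0 + Ca_i / 0.00035)

        # SR release gates (sigmoid arguments clipped: they saturate far
        # below the clip, so this only avoids harmless exp overflow)
        arg_u = np.clip(-(Fn - 3.4175e-13) / 1.367e-15, -500.0, 500.0)
        arg_v = np.clip(-(Fn - 6.835e-14) / 1.367e-15, -500.0, 500.0)
        u_inf = 1.0 / (1.0 + exp(arg_u))
        v_inf = 1.0 - 1.0 / (1.0 + exp(arg_v))
        tau_v = 1.91 + 2.09 / (1.0 + exp(arg_u))
        w_inf = 1.0 - 1.0 / (1.0 + exp(-(V - 40.0) / 17.0))
        e_w = exp(-(V - 7.9) / 5.0)
        tau_w = _safe_ratio(
            6.0 * (1.0 - e_w),
            (1.0 + 0.3 * e_w) * (V - 7.9),
            6.0 * 0.2 / 1.3,
        )

        KQ = p.K_Q10
        ones = np.ones_like(np.asarray(V, dtype=float))
        inf = [
            a_m / (a_m + b_m), a_h / (a_h + b_h), a_j / (a_j + b_j),
            oa_inf, oi_inf, ua_inf, ui_inf, xr_inf, xs_inf,
            d_inf, f_inf, fCa_inf, u_inf, v_inf, w_inf,
        ]
        tau = [
            1.0 / (a_m + b_m), 1.0 / (a_h + b_h), 1.0 / (a_j + b_j),
            1.0 / ((a_oa + b_oa) * KQ), 1.0 / ((a_oi + b_oi) * KQ),
            1.0 / ((a_oa + b_oa) * KQ), 1.0 / ((a_ui + b_ui) * KQ),
            1.0 / (a_xr + b_xr), 0.5 / (a_xs + b_xs),
            tau_d, tau_f, p.tau_fCa * ones, p.tau_u * ones, tau_v, tau_w,
        ]
        return np.stack(inf), np.stack(tau)

    def _currents(self, V: np.ndarray, W: np.ndarray):
        """All membrane currents in pA (whole cell, Cm_cell = 100 pF)."""
        p = self.p
        exp = np.exp
        (m, h, j, oa, oi, ua, ui, xr, xs, d, f, fCa, u, v, w,
         Na_i, K_i, Ca_i, Ca_up, Ca_rel) = W

        E_Na = _RTF * np.log(p.Na_o / Na_i)
        E_K = _RTF * np.log(p.K_o / K_i)
        E_Ca = 0.5 * _RTF * np.log(p.Ca_o / Ca_i)
        Cm = p.Cm_cell

        I_Na = Cm * p.g_Na * m**3 * h * j * (V - E_Na)
        I_K1 = Cm * p.g_K1 * (V - E_K) / (1.0 + exp(0.07 * (V + 80.0)))
        I_to = Cm * p.g_to * oa**3 * oi * (V - E_K)
        g_Kur = 0.005 + 0.05 / (1.0 + exp(-(V - 15.0) / 13.0))
        I_Kur = Cm * g_Kur * ua**3 * ui * (V - E_K)
        I_Kr = Cm * p.g_Kr * xr * (V - E_K) / (1.0 + exp((V + 15.0) / 22.4))
        I_Ks = Cm * p.g_Ks * xs**2 * (V - E_K)
        I_CaL = Cm * p.g_CaL * d * f * fCa * (V - 65.0)

        sigma = (np.exp(p.Na_o / 67.3) - 1.0) / 7.0
        f_NaK = 1.0 / (
            1.0 + 0.1245 * exp(-0.1 * V / _RTF) + 0.0365 * sigma * exp(-V / _RTF)
        )
        I_NaK = (
            Cm * p.I_NaK_max * f_NaK
            * (1.0 / (1.0 + (p.Km_Nai / Na_i) ** 1.5))
            * (p.K_o / (p.K_o + p.Km_Ko))
        )
        eg = exp(p.gamma * V / _RTF)
        eg1 = exp((p.gamma - 1.0) * V / _RTF)
        I_NaCa = (
            Cm * p.I_NaCa_max
            * (eg * Na_i**3 * p.Ca_o - eg1 * p.Na_o**3 * Ca_i)
            / (
                (p.Km_Na**3 + p.Na_o**3) * (p.Km_Ca + p.Ca_o)
                * (1.0 + p.k_sat * eg1)
            )
        )
        I_bNa = Cm * p.g_bNa * (V - E_Na)
        I_bCa = Cm * p.g_bCa * (V - E_Ca)
        I_pCa = Cm * p.I_pCa_max * Ca_i / (0.0005 + Ca_i)

        return dict(
            I_Na=I_Na, I_K1=I_K1, I_to=I_to, I_Kur=I_Kur, I_Kr=I_Kr,
            I_Ks=I_Ks, I_CaL=I_CaL, I_NaK=I_NaK, I_NaCa=I_NaCa,
            I_bNa=I_bNa, I_bCa=I_bCa, I_pCa=I_pCa,
        )

    def _conc_rates(self, W: np.ndarray, cur: dict[str, np.ndarray]):
        """d/dt of the five concentrations (mM/ms) plus SR fluxes."""
        p = self.p
        (m, h, j, oa, oi, ua, ui, xr, xs, d, f, fCa, u, v, w,
         Na_i, K_i, Ca_i, Ca_up, Ca_rel) = W

        I_rel = p.k_rel * u**2 * v * w * (Ca_rel - Ca_i)
        I_tr = (Ca_up - Ca_rel) / p.tau_tr
        I_up = p.I_up_max / (1.0 + p.K_up / Ca_i)
        I_up_leak = Ca_up * p.I_up_max / p.Ca_up_max

        FVi = _F * p.V_i
        dNa = (-3.0 * cur["I_NaK"] - 3.0 * cur["I_NaCa"]
               - cur["I_bNa"] - cur["I_Na"]) / FVi
        dK = (2.0 * cur["I_NaK"] - cur["I_K1"] - cur["I_to"]
              - cur["I_Kur"] - cur["I_Kr"] - cur["I_Ks"]) / FVi
        B1 = (
            (2.0 * cur["I_NaCa"] - cur["I_pCa"] - cur["I_CaL"] - cur["I_bCa"])
            / (2.0 * FVi)
            + (p.V_up * (I_up_leak - I_up) + I_rel * p.V_rel) / p.V_i
        )
        B2 = (
            1.0
            + p.Trpn_max * p.Km_Trpn / (Ca_i + p.Km_Trpn) ** 2
            + p.Cmdn_max * p.Km_Cmdn / (Ca_i + p.Km_Cmdn) ** 2
        )
        dCa = B1 / B2
        dCa_up = I_up - I_up_leak - I_tr * p.V_rel / p.V_up
        dCa_rel = (I_tr - I_rel) / (
            1.0 + p.Csqn_max * p.Km_Csqn / (Ca_rel + p.Km_Csqn) ** 2
        )
        return np.stack([dNa, dK, dCa, dCa_up, dCa_rel]), I_rel

    def i_ion(self, V: np.ndarray, W: np.ndarray) -> np.ndarray:
        cur = self._currents(V, W)
        total = sum(cur.values())  # pA
        return total / self.p.Cm_cell  # pA/pF == uA/cm^2 at Cm = 1 uF/cm^2

    def step(self, V, W, dt, rush_larsen=False):
        p = self.p
        cur = self._currents(V, W)
        dconc, I_rel = self._conc_rates(W, cur)
        Fn = (
            1e-12 * p.V_rel * I_rel
            - (5e-13 / _F) * (0.5 * cur["I_CaL"] - 0.2 * cur["I_NaCa"])
        )
        inf, tau = self._gate_rates(V, W[17], Fn)
        gates = W[: self.n_gates]
        if rush_larsen:
            new_gates = inf + (gates - inf) * np.exp(-dt / tau)
        else:
            new_gates = gates + dt * (inf - gates) / tau
            np.clip(new_gates, 0.0, 1.0, out=new_gates)
        W_new = np.concatenate(
            [new_gates, W[self.n_gates:] + dt * dconc], axis=0
        )
        if not np.all(np.isfinite(W_new)):
            bad = np.where(~np.isfinite(W_new))
            raise FloatingPointError(
                f"non-finite membrane state at indices {bad[0][:5]}, "
                f"nodes {bad[1][:5]}"
            )
        return W_new, self.i_ion(V, W_new)


# --------------------------------------------------------------------------
# Cubic (bistable) reaction
# --------------------------------------------------------------------------

@dataclass
class CubicReaction(MembraneModel):
    """Bistable cubic transmembrane current with no gating variables.

    ``I_ion = a (V - V_rest)(V - V_th)(V - V_peak)`` which is negative
    (depolarising) for ``V_th < V < V_peak``.  Mapped to the dimensionless
    bistable equation ``u_t = D u_xx + k u(1-u)(u-alpha)`` the planar
    travelling front speed is ``c = sqrt(k D / 2) (1 - 2 alpha)`` with
    ``k = a (V_peak - V_rest)^2 / C_m`` and
    ``alpha = (V_th - V_rest)/(V_peak - V_rest)``.

    The default rate constant is computed in closed form so that the
    continuum front speed equals ``speed_target`` for the reference
    monodomain diffusivity ``D_ref`` (the harmonic mean of the default
    longitudinal conductivities divided by chi * C_m).
    """

    V_rest: float = -81.2      # mV
    V_peak: float = 20.0       # mV
    alpha: float = 0.2         # dimensionless threshold position
    C_m: float = 1.0           # uF/cm^2
    speed_target: float = 0.07     # cm/ms, continuum front speed
    D_ref: float = 2.25e-3         # cm^2/ms (sigma_h / (chi C_m), Table values)
    a: float = field(init=False)

    n_states = 0
    state_names = ()
    max_dt = 0.03125

    def __post_init__(self):
        if not self.V_rest < self.V_th < self.V_peak:
            raise ValueError("bistability requires V_rest < V_th < V_peak")
        delta = self.V_peak - self.V_rest
        k = 2.0 * self.speed_target**2 / (self.D_ref * (1.0 - 2.0 * self.alpha) ** 2)
        self.a = k * self.C_m / delta**2

    @property
    def V_th(self) -> float:
        return self.V_rest + self.alpha * (self.V_peak - self.V_rest)

    @property
    def front_speed(self) -> float:
        """Closed-form planar front speed (cm/ms) at diffusivity D_ref."""
        delta = self.V_peak - self.V_rest
        k = self.a * delta**2 / self.C_m
        return np.sqrt(k * self.D_ref / 2.0) * (1.0 - 2.0 * self.alpha)

    def initial_state(self, n: int = 1):
        return np.full(n, self.V_rest), np.zeros((0, n))

    def i_ion(self, V, W):
        return self.a * (V - self.V_rest) * (V - self.V_th) * (V - self.V_peak)

    def step(self, V, W, dt, rush_larsen=False):
        return W, self.i_ion(V, W)


# --------------------------------------------------------------------------
# Single-cell harnesses
# --------------------------------------------------------------------------

def step_membrane(model: MembraneModel, state, V, dt, rush_larsen=False):
    """Advance the membrane state one substep at clamped V; returns
    ``(state, I_ion)``.  Thin functional wrapper over ``model.step``."""
    if dt > model.max_dt + 1e-12:
        raise ValueError(f"dt={dt} exceeds recommended maximum {model.max_dt}")
    return model.step(V, np.asarray(state), dt, rush_larsen=rush_larsen)


def resting_state(
    model: MembraneModel,
    dt: float = 0.0625,
    tol: float = 1e-6,
    horizon: float = 10_000.0,
    rush_larsen: bool = True,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Equilibrate the unstimulated single cell.

    Integrates ``C_m dV/dt = -I_ion`` from the model's published initial
    state until ``|dV/dt| < tol`` (mV/ms) or the time horizon (default
    10 s) is reached.  Returns ``(V, W, info)`` where ``info`` reports the
    residual drift.  Rush--Larsen gating keeps the fast Na gate stable at
    the equilibration timestep.
    """
    V, W = model.initial_state(1)
    Cm = getattr(model, "C_m", 1.0)
    t = 0.0
    dVdt = np.inf
    # check convergence only every few ms to keep the loop cheap
    check_every = max(1, int(round(1.0 / dt)))
    k = 0
    while t < horizon:
        W, I = model.step(V, W, dt, rush_larsen=rush_larsen)
        dV = -I / Cm
        V = V + dt * dV
        t += dt
        k += 1
        if k % check_every == 0:
            dVdt = float(np.max(np.abs(dV)))
            if dVdt < tol:
                break
    info = {"time_ms": t, "dVdt": dVdt, "converged": dVdt < tol}
    return V, W, info


@dataclass
class APMetrics:
    """Summary of a single-cell action potential."""
    V_rest: float
    V_peak: float
    apd90: float | None
    captured: bool
    dVdt_max: float


def single_cell_ap(
    model: MembraneModel,
    stim_amplitude: float = 20.0,   # uA/cm^2, depolarising
    stim_duration: float = 2.0,     # ms
    total_time: float = 500.0,      # ms
    dt: float = 0.03125,
    rush_larsen: bool = True,
    V0: np.ndarray | None = None,
    W0: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, APMetrics]:
    """Run a stimulated single cell; returns (t_ms, V_trace, metrics).

    The trace is sampled at 1 kHz.  ``apd90`` is measured from the maximum
    upstroke velocity to 90% repolarisation; a missing upstroke is flagged
    (``captured=False``), not raised.
    """
    if V0 is None or W0 is None:
        V, W = model.initial_state(1)
    else:
        V, W = V0.copy(), W0.copy()
    Cm = getattr(model, "C_m", 1.0)
    n_steps = int(round(total_time / dt))
    per_ms = int(round(1.0 / dt))
    V_rest = float(V[0])
    ts, vs = [0.0], [V_rest]
    dVdt_max, t_up = 0.0, None
    for k in range(n_steps):
        t = k * dt
        W, I = model.step(V, W, dt, rush_larsen=rush_larsen)
        stim = stim_amplitude if t < stim_duration else 0.0
        dV = (-I + stim) / Cm
        if t >= stim_duration and dV[0] > dVdt_max:
            dVdt_max, t_up = float(dV[0]), t
        V = V + dt * dV
        if (k + 1) % per_ms == 0:
            ts.append((k + 1) * dt)
            vs.append(float(V[0]))
    t_arr, v_arr = np.asarray(ts), np.asarray(vs)
    V_peak = float(v_arr.max())
    captured = V_peak > 0.0 and t_up is not None
    apd90 = None
    if captured:
        V90 = V_peak - 0.9 * (V_peak - V_rest)
        after = t_arr > t_up
        below = after & (v_arr < V90) & (t_arr > t_arr[np.argmax(v_arr)])
        if below.any():
            apd90 = float(t_arr[below][0] - t_up)
    return t_arr, v_arr, APMetrics(V_rest, V_peak, apd90, captured, dVdt_max)


def pace(
    model: MembraneModel,
    n_beats: int = 10,
    cycle_length: float = 1000.0,
    stim_amplitude: float = 20.0,
    stim_duration: float = 2.0,
    dt: float = 0.0625,
    rush_larsen: bool = True,
) -> list[dict]:
    """Pace a single cell at fixed cycle length; returns per-beat summaries
    (diastolic V and, for state-carrying models, the full pre-stimulus state)
    for beat-to-beat stability checks."""
    V, W = model.initial_state(1)
    Cm = getattr(model, "C_m", 1.0)
    steps_per_beat = int(round(cycle_length / dt))
    stim_steps = int(round(stim_duration / dt))
    beats = []
    for b in range(n_beats):
        pre_state = np.concatenate([V.copy(), W[:, 0].copy()]) if W.size else V.copy()
        V_peak = -np.inf
        for k in range(steps_per_beat):
            W, I = model.step(V, W, dt, rush_larsen=rush_larsen)
            stim = stim_amplitude if k < stim_steps else 0.0
            V = V + dt * (-I + stim) / Cm
            if V[0] > V_peak:
                V_peak = float(V[0])
        beats.append(
            {"beat": b, "pre_state": pre_state, "V_peak": V_peak,
             "V_diastolic": float(V[0])}
        )
    return beats
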