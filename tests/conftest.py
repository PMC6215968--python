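"""Shared fixtures: small meshes and cached expensive simulation runs.

The session-scoped fixtures below run the larger tissue simulations once
and share the results across the acceptance tests that need them.
"""

from __future__ import annotations

import numpy as np
import pytest

np.seterr(over="ignore")  # saturating sigmoids in the ionic models

from endocv.bidomain_solver import SimulationConfig, run_simulation
from endocv.experiment_runner import choose_dt
from endocv.strand_geometry import StrandSpec, build_strand
from endocv.wave_analysis import build_electrograms, cv_two_point


def run_strand(
    lm, kappa=0.0, lb_endo=0.0, lb_epi=0.0, scale=1.0,
    membrane="courtemanche", record_electrograms=False, **cfg_kw,
):
    """Build and run one strand; returns (mesh, probes, recording)."""
    theta = abs(kappa) * 2.0
    c = 1 if kappa >= 0 else -1
    spec = StrandSpec(lm=lm, lb_endo=lb_endo, lb_epi=lb_epi,
                      theta=theta, c=c)
    if scale != 1.0:
        spec = spec.scaled(scale)
    from endocv.bidomain_solver import make_membrane_model

    kw = dict(
        dt=min(choose_dt(spec.hX), make_membrane_model(membrane).max_dt),
        end_time=80.0, membrane=membrane,
        record_electrograms=record_electrograms,
        stop_margin=10.0 if record_electrograms else 2.0,
    )
    kw.update(cfg_kw)
    cfg = SimulationConfig(**kw)
    mesh, probes = build_strand(spec)
    rec = run_simulation(mesh, probes, cfg)
    return mesh, probes, rec


def strand_cv(*args, **kw) -> float:
    _, probes, rec = run_strand(*args, **kw)
    return cv_two_point(rec.activation, probes)


@pytest.fixture(scope="session")
def baseline_full_run():
    """Full-resolution straight strand, 1.5 mm muscle, no bath."""
    return run_strand(lm=0.15)


@pytest.fixture(scope="session")
def baseline_cv(baseline_full_run) -> float:
    _, probes, rec = baseline_full_run
    return cv_two_point(rec.activation, probes)


@pytest.fixture(scope="session")
def manifold_bath_run():
    """Full-resolution 25 um muscle with a 6 mm endocardial bath."""
    return run_strand(lm=0.0025, lb_endo=0.6, record_electrograms=True)


@pytest.fixture(scope="session")
def thick_bath_run():
    """Full-resolution 1.5 mm muscle with a 6 mm endocardial bath."""
    return run_strand(lm=0.15, lb_endo=0.6, record_electrograms=True)


@pytest.fixture(scope="session")
def small_strand():
    """Tiny straight strand mesh (no probes needed) for assembly tests."""
    from endocv.strand_geometry import build_straight_strand

    spec = StrandSpec(lm=0.05, L=0.4, Le=0.3, hX=0.01, hY=0.02)
    return build_straight_strand(spec)
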