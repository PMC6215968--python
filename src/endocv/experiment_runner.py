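"""Named experiment presets, sweep execution and result tables.

Each sweep combination builds a strand, runs the bidomain model and
reports the two-point endocardial CV (and, where electrograms are
recorded, the bipolar peak amplitude/time) as one row of a pandas
DataFrame.  Single-run failures are recorded per row and the sweep
continues.  Everything is deterministic: identical configurations produce
identical tables.
"""

from __future__ import annotations

import hashlib
import json
import math
import time
import warnings
from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bidomain_solver import (
    ConductivityParams,
    SimulationConfig,
    SimulationRecording,
    StimulusProtocol,
    make_membrane_model,
    run_simulation,
)
from .strand_geometry import StrandSpec, build_strand
from .wave_analysis import build_electrograms, cv_two_point

__all__ = [
    "SweepSpec",
    "RunResult",
    "choose_dt",
    "run_single",
    "run_sweep",
    "run_preset",
    "run_config",
    "export",
    "PRESETS",
]

#: curvature anchors (1/cm) of the preset sweeps: the named values
#: kappa = +-pi/2 and 0 plus +-pi/4 intermediates for the trend
KAPPA_GRID = (-math.pi / 2, -math.pi / 4, 0.0, math.pi / 4, math.pi / 2)
KAPPA_ANCHORS = (-math.pi / 2, 0.0, math.pi / 2)
#: muscle thicknesses (cm) of the thickness sweeps
LM_GRID = (0.0025, 0.05, 0.1, 0.15, 0.2)


def choose_dt(hX: float, v_X: float = 0.08) -> float:
    """Largest negative power of two (ms) satisfying dt <= hX / v_X."""
    bound = hX / v_X
    return 2.0 ** math.floor(math.log2(bound))


def kappa_to_bend(kappa: float, Le: float = 2.0) -> tuple[float, int]:
    """Signed curvature (1/cm) -> (theta, c).

    theta is clamped to pi so that a rounded kappa = pi/2 on the command
    line still maps to the half-turn bend.
    """
    if kappa == 0:
        return 0.0, 1
    return min(abs(kappa) * Le, math.pi), (1 if kappa > 0 else -1)


@dataclass
class SweepSpec:
    """Grid of strand/physics combinations to run."""

    lm: Sequence[float] = (0.15,)            # cm
    kappa: Sequence[float] = (0.0,)          # 1/cm
    lb_endo: Sequence[float] = (0.0,)        # cm
    lb_epi: Sequence[float] = (0.0,)         # cm
    longitudinal_factor: Sequence[float] = (1.0,)
    transverse_factor: Sequence[float] = (1.0,)
    membrane: str = "courtemanche"
    scale: float = 1.0                       # mesh-resolution scale factor
    record_electrograms: bool = False
    grounding: str = "zero_mean"

    def combinations(self) -> Iterable[dict]:
        for lm in self.lm:
            for kappa in self.kappa:
                for lbn in self.lb_endo:
                    for lbe in self.lb_epi:
                        for lf in self.longitudinal_factor:
                            for tf in self.transverse_factor:
                                yield dict(
                                    lm=lm, kappa=kappa, lb_endo=lbn,
                                    lb_epi=lbe, longitudinal_factor=lf,
                                    transverse_factor=tf,
                                )


@dataclass
class RunResult:
    row: dict
    recording: SimulationRecording | None


def _conductivity(base: ConductivityParams, lf: float, tf: float
                  ) -> ConductivityParams:
    return replace(
        base,
        sigma_if=base.sigma_if * lf, sigma_ef=base.sigma_ef * lf,
        sigma_it=base.sigma_it * tf, sigma_et=base.sigma_et * tf,
    )


def run_single(
    lm: float,
    kappa: float = 0.0,
    lb_endo: float = 0.0,
    lb_epi: float = 0.0,
    longitudinal_factor: float = 1.0,
    transverse_factor: float = 1.0,
    membrane: str = "courtemanche",
    scale: float = 1.0,
    record_electrograms: bool = False,
    grounding: str = "zero_mean",
    params: ConductivityParams | None = None,
    stim: StimulusProtocol | None = None,
    config: SimulationConfig | None = None,
    spec: StrandSpec | None = None,
    keep_recording: bool = True,
) -> RunResult:
    """One strand run; returns the result row and (optionally) the full
    recording."""
    t_start = time.perf_counter()
    if spec is not None:
        lm, kappa = spec.lm, spec.kappa
        lb_endo, lb_epi = spec.lb_endo, spec.lb_epi
    base = params or ConductivityParams()
    cparams = _conductivity(base, longitudinal_factor, transverse_factor)
    row = dict(
        lm_mm=lm * 10, kappa_per_cm=kappa, bath_endo_mm=lb_endo * 10,
        bath_epi_mm=lb_epi * 10, longitudinal_factor=longitudinal_factor,
        transverse_factor=transverse_factor, membrane=membrane,
        scale=scale, n_nodes=0, dt_ms=np.nan,
        cv_cm_s=np.nan, egm_peak_mV=np.nan, egm_peak_ms=np.nan,
        t1_ms=np.nan, t2_ms=np.nan, status="ok", error="",
    )
    recording = None
    try:
        if spec is None:
            theta, c = kappa_to_bend(kappa)
            spec = StrandSpec(lm=lm, lb_endo=lb_endo, lb_epi=lb_epi,
                              theta=theta, c=c)
            if scale != 1.0:
                spec = spec.scaled(scale)
        if config is None:
            config = SimulationConfig(
                dt=min(choose_dt(spec.hX),
                       make_membrane_model(membrane).max_dt),
                end_time=80.0,
                membrane=membrane,
                grounding=grounding,
                record_electrograms=record_electrograms,
                stop_margin=10.0 if record_electrograms else 2.0,
            )
        mesh, probes = build_strand(spec)
        row["n_nodes"] = mesh.n_nodes
        row["dt_ms"] = config.dt
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            recording = run_simulation(
                mesh, probes, config, params=cparams, stim=stim,
            )
        row["t1_ms"] = float(recording.activation[probes.node_x1])
        row["t2_ms"] = float(recording.activation[probes.node_x2])
        row["cv_cm_s"] = cv_two_point(recording.activation, probes)
        if record_electrograms:
            egm = build_electrograms(recording)
            row["egm_peak_mV"] = egm.peak_amplitude
            row["egm_peak_ms"] = egm.peak_time
    except Exception as err:  # noqa: BLE001 - sweep must continue
        row["status"] = "failed"
        row["error"] = f"{type(err).__name__}: {err}"
    row["run_time_s"] = round(time.perf_counter() - t_start, 2)
    return RunResult(row=row, recording=recording if keep_recording else None)


def run_sweep(
    sweep: SweepSpec,
    params: ConductivityParams | None = None,
    progress: bool = False,
) -> pd.DataFrame:
    rows = []
    for combo in sweep.combinations():
        res = run_single(
            membrane=sweep.membrane, scale=sweep.scale,
            record_electrograms=sweep.record_electrograms,
            grounding=sweep.grounding, params=params,
            keep_recording=False, **combo,
        )
        if progress:  # pragma: no cover - logging only
            print(
                f"  lm={combo['lm']*10:g}mm kappa={combo['kappa']:+.3f}/cm "
                f"bath={combo['lb_endo']*10:g}mm -> "
                f"CV={res.row['cv_cm_s']:.1f} cm/s "
                f"[{res.row['run_time_s']}s]"
            )
        rows.append(res.row)
    df = pd.DataFrame(rows)
    df.attrs["config_hash"] = _sweep_hash(sweep)
    df.attrs["version"] = __version__
    return df


def _sweep_hash(sweep: SweepSpec) -> str:
    payload = json.dumps(asdict(sweep), sort_keys=True, default=list)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


# -- presets ----------------------------------------------------------------

PRESETS: dict[str, SweepSpec] = {
    # thickness x curvature, no bath
    "fig3a": SweepSpec(lm=LM_GRID, kappa=KAPPA_GRID),
    # +-50% longitudinal conductivity at lm = 1.5 mm, no bath
    "fig3b": SweepSpec(lm=(0.15,), kappa=KAPPA_GRID,
                       longitudinal_factor=(0.5, 1.0, 1.5)),
    # transverse conductivity scalings (incl. the isotropic limit 10/2.5)
    "fig3c": SweepSpec(lm=(0.15,), kappa=KAPPA_GRID,
                       transverse_factor=(0.5, 1.0, 1.5, 10.0)),
    # 6 mm endocardial bath, thickness x curvature
    "fig5b": SweepSpec(lm=LM_GRID, kappa=KAPPA_GRID, lb_endo=(0.6,)),
    # symmetric 3 mm endocardial + epicardial baths
    "fig5c": SweepSpec(lm=LM_GRID, kappa=KAPPA_GRID,
                       lb_endo=(0.3,), lb_epi=(0.3,)),
    # bath-size sweep at lm = 1.5 mm
    "fig8b": SweepSpec(lm=(0.15,), kappa=KAPPA_GRID,
                       lb_endo=(0.0, 0.05, 0.1, 0.15, 0.2, 0.3, 0.6)),
    # electrogram tables: thickness sweep and bath sweep at the anchors
    "egm7": SweepSpec(lm=LM_GRID, kappa=KAPPA_ANCHORS, lb_endo=(0.6,),
                      record_electrograms=True),
    "egm9": SweepSpec(lm=(0.15,), kappa=KAPPA_ANCHORS,
                      lb_endo=(0.0, 0.05, 0.1, 0.15, 0.2, 0.3, 0.6),
                      record_electrograms=True),
}


def run_preset(
    name: str,
    scale: float = 1.0,
    membrane: str | None = None,
    progress: bool = False,
) -> pd.DataFrame:
    """Run a named experiment preset, optionally at coarser resolution."""
    if name not in PRESETS:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        )
    sweep = replace(PRESETS[name], scale=scale)
    if membrane:
        sweep = replace(sweep, membrane=membrane)
    return run_sweep(sweep, progress=progress)


# -- config files -----------------------------------------------------------

_SECTION_TYPES = {
    "strand": StrandSpec,
    "conductivity": ConductivityParams,
    "stimulus": StimulusProtocol,
    "simulation": SimulationConfig,
    "sweep": SweepSpec,
}


def _build_section(name: str, cls, data: dict):
    ftypes = {f.name: f.type for f in fields(cls)}
    bad = set(data) - set(ftypes)
    if bad:
        raise ValueError(
            f"config section '{name}' has unknown keys {sorted(bad)}; "
            f"known keys: {sorted(ftypes)}"
        )
    coerced = {}
    for k, v in data.items():
        # YAML 1.1 reads exponents like 1.0e5 as strings; coerce numerics
        if isinstance(v, str) and str(ftypes[k]).startswith("float"):
            v = float(v)
        coerced[k] = v
    return cls(**coerced)


def run_config(path: str | Path, progress: bool = False) -> pd.DataFrame:
    """Run the sweep or single run described by a YAML config file.

    Sections (all optional except one of ``strand``/``sweep``):
    ``strand``, ``sweep``, ``conductivity``, ``stimulus``, ``simulation``;
    keys match the dataclass field names (units: cm, ms, radians, mS/cm).
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    bad = set(raw) - set(_SECTION_TYPES)
    if bad:
        raise ValueError(
            f"unknown config sections {sorted(bad)}; "
            f"known: {sorted(_SECTION_TYPES)}"
        )
    params = _build_section(
        "conductivity", ConductivityParams, raw.get("conductivity", {})
    )
    if "sweep" in raw:
        sweep = _build_section("sweep", SweepSpec, raw["sweep"])
        return run_sweep(sweep, params=params, progress=progress)
    if "strand" not in raw:
        raise ValueError("config needs a 'strand' or 'sweep' section")
    strand = raw["strand"]
    known = {f.name for f in fields(StrandSpec)}
    bad = set(strand) - known
    if bad:
        raise ValueError(
            f"config section 'strand' has unknown keys {sorted(bad)}"
        )
    stim = _build_section("stimulus", StimulusProtocol, raw.get("stimulus", {})) \
        if "stimulus" in raw else None
    spec = StrandSpec(**strand)
    config = _build_section(
        "simulation", SimulationConfig, raw.get("simulation", {})
    ) if "simulation" in raw else SimulationConfig(dt=choose_dt(spec.hX))
    res = run_single(
        lm=spec.lm, spec=spec, params=params, stim=stim, config=config,
        record_electrograms=config.record_electrograms,
    )
    return pd.DataFrame([res.row])


def export(results: pd.DataFrame, directory: str | Path) -> dict[str, Path]:
    """Write the results table as CSV plus a JSON summary with provenance."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    csv_path = directory / "results.csv"
    results.to_csv(csv_path, index=False)
    summary = {
        "version": results.attrs.get("version", __version__),
        "config_hash": results.attrs.get("config_hash", ""),
        "n_runs": int(len(results)),
        "n_failed": int((results.get("status", "ok") != "ok").sum())
        if "status" in results else 0,
        "cv_cm_s": {
            "min": float(np.nanmin(results["cv_cm_s"])),
            "max": float(np.nanmax(results["cv_cm_s"])),
        } if "cv_cm_s" in results
        and np.isfinite(results["cv_cm_s"]).any() else {},
    }
    json_path = directory / "summary.json"
    json_path.write_text(json.dumps(summary, indent=2))
    return {"csv": csv_path, "json": json_path}
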