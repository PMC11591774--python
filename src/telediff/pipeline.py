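"""Reproducible end-to-end runs: synth -> quantify -> fit -> diagnose.

Every run emits a :class:`RunManifest` (config snapshot, version, seeds,
input hashes, outputs, timings) so that deterministic stages can be re-run
bit-identically from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Any, Dict, List, Optional

import numpy as np

from . import __version__
from .analytics import crossover_from_trace, rescale_relaxation
from .fitting import FitConfig, fit_params
from .imaging import quantify
from .model import Grid, InitialCondition, TransportParams
from .solver import SolverConfig, solve
from .synthetic import AcquisitionSpec, synth_image_stack

__all__ = [
    "RunManifest",
    "ReproductionConfig",
    "run_reproduction",
    "params_from_config",
    "ic_from_config",
    "grid_from_config",
]

log = logging.getLogger(__name__)

# Reference transport parameters of the hydrogel experiment's fitted model.
REFERENCE_PARAMS = TransportParams(D=4e-5, tau=1.0, k=1.5e-4)


def sha256_of(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    command: str
    config: Dict[str, Any]
    seed: Optional[int] = None
    version: str = __version__
    input_hashes: Dict[str, str] = dc_field(default_factory=dict)
    outputs: List[str] = dc_field(default_factory=list)
    timings: Dict[str, float] = dc_field(default_factory=dict)

    def save(self, path: Path) -> None:
        path = Path(path)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, default=str))


def params_from_config(d: Dict[str, Any]) -> TransportParams:
    return TransportParams(
        D=float(d.get("D", REFERENCE_PARAMS.D)),
        tau=float(d.get("tau", REFERENCE_PARAMS.tau)),
        k=float(d.get("k", REFERENCE_PARAMS.k)),
    )


def ic_from_config(d: Dict[str, Any]) -> InitialCondition:
    return InitialCondition(
        C0=float(d.get("C0", 1.0)), R=float(d.get("R", 0.9)), s=float(d.get("s", 0.44))
    )


def grid_from_config(d: Dict[str, Any], geometry: str = "cartesian-2d") -> Grid:
    return Grid(
        L=float(d.get("L", 10.0)),
        N=int(d.get("N", 200)),
        geometry=d.get("geometry", geometry),
    )


@dataclass
class ReproductionConfig:
    """One config block per run; defaults are the study conditions."""

    params: TransportParams = dc_field(default_factory=lambda: REFERENCE_PARAMS)
    ic: InitialCondition = dc_field(default_factory=InitialCondition)
    grid: Grid = dc_field(default_factory=Grid)
    duration: float = 600.0
    fps: float = 1.0
    pixel_size: float = 0.05
    frame_shape: Optional[tuple] = (200, 200)
    noise_sigma: float = 1.0
    n_center: int = 238
    window: tuple = (300.0, 600.0)
    tol: float = 0.05
    n_starts: int = 8

    @classmethod
    def from_dict(cls, d: Dict[str, Any]) -> "ReproductionConfig":
        cfg = cls(
            params=params_from_config(d),
            ic=ic_from_config(d),
            grid=grid_from_config(d),
        )
        for key in ("duration", "fps", "pixel_size", "noise_sigma", "tol"):
            if key in d:
                setattr(cfg, key, float(d[key]))
        for key in ("n_center", "n_starts"):
            if key in d:
                setattr(cfg, key, int(d[key]))
        if "frame_shape" in d:
            cfg.frame_shape = tuple(d["frame_shape"])
        if "window" in d:
            cfg.window = tuple(float(v) for v in d["window"])
        return cfg


def run_reproduction(
    config: Optional[ReproductionConfig] = None,
    seed: int = 0,
    outdir: Optional[Path] = None,
) -> Dict[str, Any]:
    """Synthesize a recording, quantify it, refit the model, and diagnose.

    Returns a report with the recovered parameters, the rescaled-trace data,
    the asymptotic slope, the crossover time, and relative deviations from
    the reference parameter set.  Any stage failure marks the stage in the
    report and aborts downstream stages.
    """
    cfg = config or ReproductionConfig()
    report: Dict[str, Any] = {"seed": seed, "stages": {}, "version": __version__}
    timings: Dict[str, float] = {}

    def run_stage(name, fn):
        t0 = time.perf_counter()
        try:
            out = fn()
        except Exception as exc:  # noqa: BLE001 - report and abort downstream
            report["stages"][name] = {"status": "failed", "error": str(exc)}
            timings[name] = time.perf_counter() - t0
            return None
        report["stages"][name] = {"status": "ok"}
        timings[name] = time.perf_counter() - t0
        return out

    spec = AcquisitionSpec(
        fps=cfg.fps,
        duration=cfg.duration,
        pixel_size=cfg.pixel_size,
        frame_shape=cfg.frame_shape,
        noise_sigma=cfg.noise_sigma,
        seed=seed,
    )
    synth_out = run_stage(
        "synth", lambda: synth_image_stack(cfg.params, cfg.ic, spec, grid=cfg.grid)
    )
    if synth_out is None:
        report["aborted_at"] = "synth"
        report["timings"] = timings
        return report
    stack, gt = synth_out

    quant = run_stage("quantify", lambda: quantify(stack, n_center=cfg.n_center))
    if quant is None:
        report["aborted_at"] = "quantify"
        report["timings"] = timings
        return report

    if cfg.params.k == 0:
        def conservation():
            rgrid = Grid(L=cfg.grid.L, N=cfg.grid.N, geometry="radial-1d")
            scfg = SolverConfig(save_times=np.array([0.0, cfg.duration]), store_fields=False)
            sol = solve(cfg.params, cfg.ic, rgrid, scfg)
            drift = abs(sol.mass[-1] - sol.mass[0]) / sol.mass[0]
            return {"relative_drift": float(drift), "passed": bool(drift < 1e-3)}

        report["mass_conservation"] = run_stage("mass_conservation", conservation)
    else:
        report["mass_conservation"] = None

    fit_cfg = FitConfig(
        n_starts=cfg.n_starts,
        ic=cfg.ic,
        grid=Grid(L=cfg.grid.L, N=cfg.grid.N, geometry="radial-1d"),
        averaging_radius=quant.trace.averaging_radius,
    )
    fit = run_stage("fit", lambda: fit_params(quant.trace, fit_cfg))
    if fit is None:
        report["aborted_at"] = "fit"
        report["timings"] = timings
        return report

    def diagnose():
        rt = rescale_relaxation(quant.trace, C0=cfg.ic.C0)
        res = crossover_from_trace(rt, window=cfg.window, tol=cfg.tol)
        return rt, res

    diag = run_stage("diagnose", diagnose)
    if diag is None:
        report["aborted_at"] = "diagnose"
        report["timings"] = timings
        return report
    rt, cross = diag

    # Leakage-vs-no-leakage slope comparison (logged, not asserted: the
    # reference direction of this effect is a matter of convention).
    def slope_comparison():
        from .analytics import asymptotic_slope
        from .fitting import model_center_trace

        times = quant.trace.times
        slopes = {}
        for label, k in (("fitted_k", fit.params.k), ("k_zero", 0.0)):
            p = TransportParams(D=fit.params.D, tau=fit.params.tau, k=k)
            vals = model_center_trace(p, times, cfg.ic, fit_cfg.grid,
                                      averaging_radius=fit_cfg.averaging_radius)
            rt_m = rescale_relaxation(
                type(quant.trace)(times, vals, fit_cfg.averaging_radius), cfg.ic.C0
            )
            slopes[label], _ = asymptotic_slope(rt_m, cfg.window)
        log.info(
            "asymptotic slope with fitted k: %.3e 1/s; without leakage: %.3e 1/s (ratio %.2f)",
            slopes["fitted_k"], slopes["k_zero"], slopes["k_zero"] / slopes["fitted_k"],
        )
        return slopes

    slopes = run_stage("slope_comparison", slope_comparison) or {}

    ref = REFERENCE_PARAMS
    report.update(
        {
            "recovered": {"D": fit.params.D, "tau": fit.params.tau, "k": fit.params.k},
            "objective": fit.objective,
            "r2": fit.r2,
            "reference": {"D": ref.D, "tau": ref.tau, "k": ref.k},
            "relative_error_vs_reference": {
                "D": abs(fit.params.D - ref.D) / ref.D,
                "tau": abs(fit.params.tau - ref.tau) / ref.tau,
                "k": abs(fit.params.k - ref.k) / ref.k,
            },
            "asymptotic_slope": cross.slope,
            "asymptotic_intercept": cross.intercept,
            "crossover_time_s": cross.t_cross,
            "crossover_tol": cross.tol,
            "slope_comparison": slopes,
            "rescaled_trace": {
                "times": rt.times[rt.valid_mask].tolist(),
                "values": rt.values[rt.valid_mask].tolist(),
            },
            "timings": timings,
        }
    )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        report_path = outdir / "report.json"
        report_path.write_text(json.dumps(report, indent=2, default=str))
        manifest = RunManifest(
            command="reproduce",
            config=dataclasses.asdict(cfg),
            seed=seed,
            outputs=[str(report_path)],
            timings=timings,
        )
        manifest.save(outdir / "manifest.json")
    return report
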