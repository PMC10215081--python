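"""Reproducible run orchestration for the two headline experiments.

``run_healthy`` executes the unimplanted pipeline (solve, normalize, smooth,
tuning map, Greenwood comparison) and ``run_sweep`` additionally runs one
implanted solve per insertion angle and tabulates the residual-hearing
deltas.  Each run writes into one output directory: a config echo, the
response and tuning tables as CSV, an HDF5 bundle, and a manifest with
SHA-256 checksums of every written file.  Runs are fully deterministic:
identical configs give byte-identical CSV outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .analysis import (
    ResidualHearingDelta,
    TuningResult,
    delta_frame,
    extract_tuning,
    normalize_response,
    residual_hearing_delta,
    smooth_profile,
    tuning_frame,
)
from .config import RunConfig
from .electrode import place_electrode
from .solver import BMResponse, solve_harmonic

__all__ = ["HealthyResult", "SweepResult", "run_healthy", "run_sweep", "make_fixtures"]

log = logging.getLogger("basilar")


@dataclass(frozen=True)
class HealthyResult:
    response: BMResponse
    tuning: TuningResult
    outdir: Path


@dataclass(frozen=True)
class SweepResult:
    healthy: HealthyResult
    implanted: dict[float, TuningResult]
    deltas: list[ResidualHearingDelta]
    outdir: Path


def _response_frame(resp: BMResponse, window: float) -> pd.DataFrame:
    norm = normalize_response(resp)
    dx = float(resp.x_grid[1] - resp.x_grid[0])
    smooth = smooth_profile(norm, dx, window)
    frames = []
    for i, f in enumerate(resp.frequencies):
        frames.append(
            pd.DataFrame(
                {
                    "frequency_Hz": float(f),
                    "x_mm": resp.x_grid,
                    "Re_u_m": resp.u[i].real,
                    "Im_u_m": resp.u[i].imag,
                    "abs_u_m": np.abs(resp.u[i]),
                    "normalized_abs": norm[i],
                    "normalized_smoothed": smooth[i],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _write_csv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, index=False, float_format="%.12g")


def _write_manifest(outdir: Path, config: RunConfig) -> None:
    entries = {}
    for p in sorted(outdir.iterdir()):
        if p.name == "manifest.json" or p.is_dir():
            continue
        entries[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    manifest = {
        "config_checksum": config.checksum,
        "config_source": config.source_path,
        "files": entries,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def _write_h5(path: Path, responses: dict[str, BMResponse]) -> None:
    with h5py.File(path, "w") as fh:
        for name, resp in responses.items():
            grp = fh.create_group(name)
            grp.create_dataset("frequencies_Hz", data=resp.frequencies)
            grp.create_dataset("x_mm", data=resp.x_grid)
            grp.create_dataset("u_m", data=resp.u)
            grp.create_dataset("stapes_displacement_m", data=resp.stapes_displacement)


def _prepare_outdir(config: RunConfig, outdir: str | Path | None) -> Path:
    out = Path(outdir) if outdir is not None else Path(config.output_dir())
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(config.to_yaml())
    return out


def _solve_healthy(config: RunConfig):
    geom = config.geometry()
    mat = config.materials()
    for msg in config.warnings_:
        log.warning("materials: %s", msg)
    stim = config.stimulus()
    settings = config.solver_settings()
    resp = solve_harmonic(geom, mat, None, stim, settings)
    tuning = extract_tuning(resp, config.smooth_window(), config.greenwood())
    return geom, mat, stim, settings, resp, tuning


def run_healthy(config: RunConfig, outdir: str | Path | None = None) -> HealthyResult:
    """Full healthy pipeline: solve, tuning table, CSV/HDF5 outputs."""
    out = _prepare_outdir(config, outdir)
    log.info("healthy run -> %s", out)
    geom, mat, stim, settings, resp, tuning = _solve_healthy(config)
    for d in resp.diagnostics:
        log.info(
            "f=%.0f Hz residual=%.2e power-balance=%.2e",
            d.frequency, d.residual, d.power_balance_error,
        )
    _write_csv(_response_frame(resp, config.smooth_window()), out / "response_healthy.csv")
    _write_csv(tuning_frame(tuning), out / "tuning_healthy.csv")
    _write_h5(out / "responses.h5", {"healthy": resp})
    _write_manifest(out, config)
    return HealthyResult(resp, tuning, out)


def run_sweep(config: RunConfig, outdir: str | Path | None = None) -> SweepResult:
    """Healthy run plus one implanted run per insertion angle, with deltas.

    Angles are processed and written in ascending order regardless of the
    order given in the config.
    """
    out = _prepare_outdir(config, outdir)
    log.info("insertion-angle sweep -> %s", out)
    geom, mat, stim, settings, resp, tuning = _solve_healthy(config)
    _write_csv(_response_frame(resp, config.smooth_window()), out / "response_healthy.csv")
    _write_csv(tuning_frame(tuning), out / "tuning_healthy.csv")

    responses: dict[str, BMResponse] = {"healthy": resp}
    implanted: dict[float, TuningResult] = {}
    deltas: list[ResidualHearingDelta] = []
    for angle in sorted(config.sweep_angles()):
        occ = place_electrode(geom, config.electrode_spec(angle), mat)
        resp_i = solve_harmonic(geom, mat, occ, stim, settings)
        tun_i = extract_tuning(resp_i, config.smooth_window(), config.greenwood())
        implanted[angle] = tun_i
        deltas.append(residual_hearing_delta(tuning, tun_i, angle))
        tag = f"{int(round(angle)):03d}deg"
        responses[f"implanted_{tag}"] = resp_i
        _write_csv(
            _response_frame(resp_i, config.smooth_window()),
            out / f"response_implanted_{tag}.csv",
        )
        log.info(
            "angle=%.0f deg: max |dx|=%.4f mm, max |ddB|=%.3f dB",
            angle, deltas[-1].max_abs_shift, deltas[-1].max_abs_db,
        )
    _write_csv(delta_frame(deltas), out / "deltas.csv")
    _write_h5(out / "responses.h5", responses)
    _write_manifest(out, config)
    return SweepResult(HealthyResult(resp, tuning, out), implanted, deltas, out)


TOY_OVERRIDES = {
    "geometry": {
        "length_mm": 2.0,
        "grid": {"dx_mm": 0.04},
    },
    "stimulus": {"frequencies_hz": [4000.0, 8000.0]},
    "output": {"directory": "runs/toy"},
}


def make_fixtures(size: str, outdir: str | Path) -> Path:
    """Write a packaged config fixture: ``"toy"`` (L=2 mm, 51 nodes) or
    ``"default"``.  Deterministic, seed-free."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if size == "toy":
        cfg = RunConfig.from_dict(TOY_OVERRIDES)
        path = outdir / "toy.yaml"
    elif size == "default":
        cfg = RunConfig.from_dict({})
        path = outdir / "default.yaml"
    else:
        raise ValueError(f"unknown fixture size {size!r}; choose 'toy' or 'default'")
    path.write_text(cfg.to_yaml())
    return path
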