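"""End-to-end orchestration: phantom -> sync -> segment -> geometry ->
flow -> hemo, with a reproducibility manifest.

The stages communicate through files in the run directory, so a run
can be resumed: stages whose outputs already exist with matching
checksums are skipped.  All tolerances that matter (inverse-fit
tolerance, closure threshold, extension factor, mesh resolutions) are
surfaced in the single YAML config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import yaml

from . import geometry, hemo, io, segment
from .flow import FluidProps, simulate_cycle
from .phantom import PhantomConfig, generate_phantom, stage_preset
from .sync import synchronize_dataset, validate_sync, SyncedDataset


DEFAULT_CONFIG: dict = {
    "seed": 7,
    "phantom": {"preset": "HH17"},
    "sync": {"n_bins": 200, "n_out": 100},
    "segment": {},
    "geometry": {
        "target_axial_layers": 20,
        "target_circumferential_divisions": 16,
        "radial_layers": 3,
        "extension_length_factor": 2.0,
    },
    "flow": {
        "density": 1060.0,
        "viscosity": 0.003,
        "tolerance": 0.01,
        "include_inertia": False,
    },
}


def load_config(path: str | Path | None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        with open(path) as f:
            user = yaml.safe_load(f) or {}
        for key, val in user.items():
            if isinstance(val, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(val)
            else:
                cfg[key] = val
    return cfg


def phantom_config_from(cfg: dict) -> PhantomConfig:
    p = dict(cfg.get("phantom", {}))
    preset = p.pop("preset", None)
    if preset:
        return stage_preset(preset, **p)
    return PhantomConfig(**p)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def series_from_synced(
    synced: SyncedDataset,
    pixel_size_mm: float,
    slice_spacing_mm: float,
    params: segment.SegmentParams | None = None,
) -> geometry.CrossSectionSeries:
    """Segment every slice/phase of a synchronized volume into a series."""
    contours = segment.segment_stack(synced.volume, pixel_size_mm, params)
    return geometry.CrossSectionSeries(
        contours=contours, slice_spacing_mm=slice_spacing_mm
    )


def doppler_targets(
    synced: SyncedDataset,
    series: geometry.CrossSectionSeries,
    beam_tilt_deg: float,
    pixel_size_mm: float,
    monitor_slice: int | None = None,
    angle_correct: bool = True,
) -> tuple[dict[int, float], int]:
    """Per-phase axial monitor velocities from the synchronized Doppler.

    The monitor is the lumen centroid pixel of the mid-tube slice
    (configurable); the measured beam-projected velocity is divided by
    cos(beam_tilt) when ``angle_correct`` (the default, since the
    phantom's beam geometry is known).  Phases whose monitor slice is
    closed are omitted.
    """
    n_phases, depth, width, n_slices = synced.doppler.shape
    k = n_slices // 2 if monitor_slice is None else monitor_slice
    scale = np.cos(np.radians(beam_tilt_deg)) if angle_correct else 1.0
    if abs(scale) < 1e-12:
        raise ValueError("beam perpendicular to the tube: no axial information")
    targets: dict[int, float] = {}
    for t in range(n_phases):
        c = series.contours[k][t]
        if c.is_closed_lumen:
            continue
        cen_px = geometry.contour_centroid(c) / pixel_size_mm  # (x, y)
        row = int(round(np.clip(cen_px[1], 0, depth - 1)))
        col = int(round(np.clip(cen_px[0], 0, width - 1)))
        targets[t] = float(synced.doppler[t, row, col, k]) / scale
    return targets, k


def meshes_for_cycle(
    series: geometry.CrossSectionSeries,
    phases: list[int] | None = None,
    **mesh_kwargs,
) -> tuple[dict[int, geometry.TubeMesh], dict[int, str]]:
    """Build per-phase meshes, skipping closed/unmeshable phases."""
    closed = series.closed_mask()
    meshes: dict[int, geometry.TubeMesh] = {}
    failures: dict[int, str] = {}
    for t in phases if phases is not None else range(series.n_phases):
        if closed[:, t].any():
            failures[t] = "closed slice"
            continue
        try:
            meshes[t] = geometry.build_mesh(series, t, **mesh_kwargs)
        except geometry.MeshError as exc:
            failures[t] = str(exc)
    return meshes, failures


@dataclasses.dataclass
class RunManifest:
    config: dict
    seed: int
    stages: dict
    outputs: dict            # name -> {path, sha256}
    coverage: float | None = None
    version: str = ""

    def save(self, path: str | Path) -> None:
        with open(path, "w") as f:
            json.dump(dataclasses.asdict(self), f, indent=2, default=str)


def run_pipeline(
    config_path: str | Path | None,
    out_dir: str | Path,
    resume: bool = False,
    stage_through: str = "hemo",
) -> RunManifest:
    """Execute the full pipeline, writing outputs and a manifest.

    ``stage_through`` stops after the named stage (phantom, sync,
    segment, geometry, flow, hemo); later stages are marked not-run.
    With ``resume``, stages whose output files exist with checksums
    matching an existing manifest are skipped.
    """
    from . import __version__

    t_start = time.time()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = load_config(config_path)
    seed = int(cfg.get("seed", 7))
    order = ["phantom", "sync", "segment", "geometry", "flow", "hemo"]
    if stage_through not in order:
        raise ValueError(f"unknown stage {stage_through!r}")
    last = order.index(stage_through)
    stages: dict = {name: {"status": "not-run"} for name in order}
    outputs: dict = {}

    prior: dict = {}
    manifest_path = out / "manifest.json"
    if resume and manifest_path.exists():
        with open(manifest_path) as f:
            prior = json.load(f).get("outputs", {})

    def fresh(name: str) -> bool:
        rec = prior.get(name)
        if not rec:
            return False
        p = Path(rec["path"])
        return p.exists() and _sha256(p) == rec["sha256"]

    def record(name: str, path: Path) -> None:
        outputs[name] = {"path": str(path), "sha256": _sha256(path)}

    # ---- phantom ------------------------------------------------------
    pcfg = phantom_config_from(cfg)
    phantom_path = out / "phantom.h5"
    if resume and fresh("phantom"):
        stages["phantom"] = {"status": "resumed"}
        ds = io.load_phantom(phantom_path)
    else:
        t0 = time.time()
        ds = generate_phantom(pcfg, seed=seed)
        io.save_phantom(ds, str(phantom_path))
        stages["phantom"] = {"status": "done", "seconds": time.time() - t0,
                             "n_slices": pcfg.n_slices}
    record("phantom", phantom_path)
    if last == 0:
        m = RunManifest(cfg, seed, stages, outputs, version=__version__)
        m.save(manifest_path)
        return m

    # ---- sync ---------------------------------------------------------
    t0 = time.time()
    scfg = cfg["sync"]
    synced = synchronize_dataset(
        ds.longitudinal, ds.cross_images, ds.cross_doppler,
        n_bins=int(scfg.get("n_bins", 200)), n_out=int(scfg.get("n_out", 100)),
    )
    synced_path = out / "synced.h5"
    io.save_synced(synced, str(synced_path))
    from . import viz

    viz.plot_cumulative_phase(synced.schedule,
                              str(out / "cumulative_phase.png"))
    pair = synced.schedule.diagnostics.get("pooled_mmode_pair_mid")
    if pair is not None:
        from .sync import LineSpec, MMode

        viz.plot_mmode_pair(
            MMode(pair[0], LineSpec("vertical", 0), 1.0),
            MMode(pair[1], LineSpec("vertical", 0), 1.0),
            str(out / "mmode_pair_mid.png"),
        )
    reports = validate_sync(ds.longitudinal_doppler, synced)
    with open(out / "sync_validation.json", "w") as f:
        json.dump(reports, f, indent=2)
    stages["sync"] = {
        "status": "done", "seconds": time.time() - t0,
        "period_frames": synced.schedule.period_frames,
        "n_out_frames": int(synced.volume.shape[0]),
    }
    record("synced", synced_path)
    record("sync_validation", out / "sync_validation.json")
    if last == 1:
        m = RunManifest(cfg, seed, stages, outputs, version=__version__)
        m.save(manifest_path)
        return m

    # ---- segment ------------------------------------------------------
    t0 = time.time()
    params = segment.SegmentParams(**cfg.get("segment", {}))
    series = series_from_synced(
        synced, pcfg.pixel_size_mm, pcfg.slice_spacing_um / 1000.0, params
    )
    contours_path = out / "contours.json"
    _save_contours(series, contours_path)
    stages["segment"] = {
        "status": "done", "seconds": time.time() - t0,
        "closed_fraction": float(series.closed_mask().mean()),
    }
    record("contours", contours_path)
    if last == 2:
        m = RunManifest(cfg, seed, stages, outputs, version=__version__)
        m.save(manifest_path)
        return m

    # ---- geometry -----------------------------------------------------
    t0 = time.time()
    am = geometry.area_motion(series)
    np.savetxt(out / "area_motion_lumen.csv", am.values, delimiter=",")
    viz.plot_area_motion(am, str(out / "area_motion_lumen.png"))
    gcfg = cfg["geometry"]
    meshes, mesh_failures = meshes_for_cycle(series, **gcfg)
    stages["geometry"] = {
        "status": "done", "seconds": time.time() - t0,
        "n_meshed_phases": len(meshes),
        "phase_lag_slope": am.phase_lag_slope,
        "centerline_length_mm": geometry.centerline_length(series),
    }
    record("area_motion", out / "area_motion_lumen.csv")
    if last == 3:
        m = RunManifest(cfg, seed, stages, outputs, version=__version__)
        m.save(manifest_path)
        return m

    # ---- flow ---------------------------------------------------------
    t0 = time.time()
    fcfg = cfg["flow"]
    props = FluidProps(
        density_kg_m3=float(fcfg.get("density", 1060.0)),
        viscosity_pa_s=float(fcfg.get("viscosity", 0.003)),
    )
    targets, monitor_slice = doppler_targets(
        synced, series, pcfg.beam_tilt_deg, pcfg.pixel_size_mm
    )
    sim = simulate_cycle(
        meshes, targets, props,
        n_phases=series.n_phases,
        tolerance=float(fcfg.get("tolerance", 0.01)),
        include_inertia=bool(fcfg.get("include_inertia", False)),
    )
    run_log = {
        "coverage": sim.coverage,
        "skipped": {str(k): v for k, v in sim.skipped.items()},
        "mesh_failures": {str(k): v for k, v in mesh_failures.items()},
        "warnings": sim.warnings,
        "fit_errors": {
            str(p): sim.fits[p].final_relative_error for p in sim.fits
        },
        "fit_solves": {str(p): sim.fits[p].n_solves for p in sim.fits},
        "monitor_slice": monitor_slice,
    }
    with open(out / "flow_log.json", "w") as f:
        json.dump(run_log, f, indent=2)
    stages["flow"] = {
        "status": "done", "seconds": time.time() - t0,
        "coverage": sim.coverage, "n_simulated": len(sim.fields),
    }
    record("flow_log", out / "flow_log.json")
    if last == 4:
        m = RunManifest(cfg, seed, stages, outputs, coverage=sim.coverage,
                        version=__version__)
        m.save(manifest_path)
        return m

    # ---- hemo ---------------------------------------------------------
    t0 = time.time()
    summary = hemo.summarize(sim, period_s=pcfg.period_s, n_phases=series.n_phases)
    series_ws = hemo.collect_wall_series(sim, pcfg.period_s, series.n_phases)
    w_t = series_ws.time_weights / series_ws.time_weights.sum()
    mean_tau = np.einsum("t,tf->f", w_t, series_ws.tau_mag)
    viz.plot_unrolled(
        hemo.unroll_surface(series_ws, mean_tau),
        str(out / "unrolled_mean_wss.png"),
        label="time-averaged |WSS| (Pa)",
    )
    summary.to_frame().to_csv(out / "summary.csv", index=False)
    import pandas as pd

    pd.DataFrame(
        {
            "theta_rad": series_ws.theta,
            "s_normalized": series_ws.s,
            "area_mm2": series_ws.areas,
            "mean_wss_pa": mean_tau,
            "peak_wss_pa": series_ws.tau_mag.max(axis=0),
            "osi": hemo.osi(series_ws),
        }
    ).to_csv(out / "wall_points.csv", index=False)
    peak_phase = max(summary.Q_waveform, key=summary.Q_waveform.get)
    hemo.export_flowfield(sim.fields[peak_phase],
                          str(out / f"field_phase{peak_phase:03d}.vtk"))
    with open(out / "summary.json", "w") as f:
        json.dump(
            {**summary.as_dict(),
             "Q_waveform": {str(k): v for k, v in summary.Q_waveform.items()}},
            f, indent=2,
        )
    stages["hemo"] = {"status": "done", "seconds": time.time() - t0}
    record("summary", out / "summary.json")

    m = RunManifest(
        cfg, seed, stages, outputs, coverage=sim.coverage, version=__version__
    )
    m.save(manifest_path)
    stages["total_seconds"] = time.time() - t_start
    return m


def _save_contours(series: geometry.CrossSectionSeries, path: Path) -> None:
    rows = []
    for k, per_phase in enumerate(series.contours):
        for t, c in enumerate(per_phase):
            rows.append(
                {
                    "slice": k,
                    "phase": t,
                    "closed": bool(c.is_closed_lumen),
                    "area_mm2": geometry.contour_area(c),
                    "centroid_mm": list(map(float, geometry.contour_centroid(c))),
                    "vertices_mm": c.vertices.round(6).tolist(),
                }
            )
    with open(path, "w") as f:
        json.dump(rows, f)
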