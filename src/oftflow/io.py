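"""Hierarchical on-disk layout for phantom and synchronized datasets.

One HDF5 file per phantom::

    /longitudinal/bmode      (t, depth, width)   float32
    /longitudinal/doppler    (t, depth, width)   float32  [mm/s]
    /cross/<k>/bmode, /cross/<k>/doppler         float32
    /truth/slice_phase_offsets, /truth/longitudinal_phase_offset,
    /truth/period_ms
    attrs: fps, frames_per_sequence, slice_spacing_um, pixel_size_um,
           beam_tilt_deg, n_slices, config (YAML snapshot)

Synchronized datasets::

    /synced/volume   (100, depth, width, n_slices)
    /synced/doppler  (100, depth, width, n_slices)
    /synced/phase_schedule/{period_frames, per_slice_shift,
                            cumulative_curve}
"""

from __future__ import annotations

import dataclasses

import h5py
import numpy as np
import yaml

from .phantom import PhantomConfig, PhantomDataset, GroundTruth, PhantomKinematics
from .sync import BModeSequence, DopplerSequence, PhaseSchedule, SyncedDataset


def _config_to_yaml(config: PhantomConfig) -> str:
    d = dataclasses.asdict(config)
    d.pop("base_radius_profile", None)  # callables are not serialized
    return yaml.safe_dump(d)


def save_phantom(ds: PhantomDataset, path: str) -> None:
    cfg = ds.truth.config
    with h5py.File(path, "w") as f:
        f.attrs["fps"] = cfg.fps
        f.attrs["frames_per_sequence"] = cfg.frames_per_sequence
        f.attrs["slice_spacing_um"] = cfg.slice_spacing_um
        f.attrs["pixel_size_um"] = cfg.pixel_size_um
        f.attrs["beam_tilt_deg"] = cfg.beam_tilt_deg
        f.attrs["n_slices"] = cfg.n_slices
        f.attrs["config"] = _config_to_yaml(cfg)
        g = f.create_group("longitudinal")
        g.create_dataset("bmode", data=ds.longitudinal.frames, dtype="f4")
        g.create_dataset("doppler", data=ds.longitudinal_doppler.frames, dtype="f4")
        g.attrs["t0_ms"] = ds.longitudinal.acquisition_start_ms
        cg = f.create_group("cross")
        for k, (b, d) in enumerate(ds.cross_sections):
            sg = cg.create_group(str(k))
            sg.create_dataset("bmode", data=b.frames, dtype="f4")
            sg.create_dataset("doppler", data=d.frames, dtype="f4")
            sg.attrs["t0_ms"] = b.acquisition_start_ms
        t = f.create_group("truth")
        t.create_dataset("slice_phase_offsets", data=ds.truth.slice_phase_offsets)
        t.attrs["longitudinal_phase_offset"] = ds.truth.longitudinal_phase_offset
        t.attrs["period_ms"] = ds.truth.period_ms


def load_phantom(path: str) -> PhantomDataset:
    with h5py.File(path, "r") as f:
        cfg = PhantomConfig(**yaml.safe_load(f.attrs["config"]))
        fps = float(f.attrs["fps"])
        longitudinal = BModeSequence(f["longitudinal/bmode"][...].astype(float), fps)
        long_dop = DopplerSequence(f["longitudinal/doppler"][...].astype(float), fps)
        cross = []
        for k in range(int(f.attrs["n_slices"])):
            b = BModeSequence(f[f"cross/{k}/bmode"][...].astype(float), fps)
            d = DopplerSequence(f[f"cross/{k}/doppler"][...].astype(float), fps)
            cross.append((b, d))
        truth = GroundTruth(
            period_ms=float(f["truth"].attrs["period_ms"]),
            slice_phase_offsets=f["truth/slice_phase_offsets"][...],
            longitudinal_phase_offset=float(
                f["truth"].attrs["longitudinal_phase_offset"]
            ),
            kinematics=PhantomKinematics(cfg),
            config=cfg,
        )
    return PhantomDataset(
        longitudinal=longitudinal,
        longitudinal_doppler=long_dop,
        cross_sections=cross,
        truth=truth,
    )


def save_synced(sd: SyncedDataset, path: str) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("synced")
        g.create_dataset("volume", data=sd.volume, dtype="f4")
        g.create_dataset("doppler", data=sd.doppler, dtype="f4")
        g.attrs["fps_equivalent"] = sd.fps_equivalent
        ps = g.create_group("phase_schedule")
        ps.attrs["period_frames"] = sd.schedule.period_frames
        ps.attrs["n_bins"] = sd.schedule.n_bins
        ps.create_dataset("per_slice_shift", data=sd.schedule.per_slice_shift)
        ps.create_dataset("cumulative_curve", data=sd.schedule.cumulative_curve)


def load_synced(path: str) -> SyncedDataset:
    with h5py.File(path, "r") as f:
        g = f["synced"]
        ps = g["phase_schedule"]
        schedule = PhaseSchedule(
            period_frames=float(ps.attrs["period_frames"]),
            per_slice_shift=ps["per_slice_shift"][...],
            cumulative_curve=ps["cumulative_curve"][...],
            n_bins=int(ps.attrs["n_bins"]),
        )
        return SyncedDataset(
            volume=g["volume"][...].astype(float),
            doppler=g["doppler"][...].astype(float),
            schedule=schedule,
            fps_equivalent=float(g.attrs["fps_equivalent"]),
        )


def export_frame_png(frame: np.ndarray, path: str) -> None:
    """Save one image frame for visual inspection."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plt.imsave(path, np.asarray(frame), cmap="gray")
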