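"""Readers and writers for the toolkit's on-disk formats.

k-space series travel as HDF5 (complex data + mask + time stamps + protocol
attributes); image series export to NIfTI (magnitude) via nibabel or HDF5
(complex); configurations are YAML; contours and strain curves are CSV.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import yaml

from .phantom import PhantomConfig
from .recon import ImageSeries
from .sampling import SamplingPlan
from .sequence import KSpaceSeries, SequenceProtocol
from .strain import StrainCurve


def save_kspace(path, kspace: KSpaceSeries) -> None:
    with h5py.File(path, "w") as h5:
        h5.create_dataset("kspace", data=kspace.data)
        h5.create_dataset("mask", data=kspace.mask)
        h5.create_dataset("line_times_ms", data=kspace.line_times)
        h5.create_dataset("frame_times_ms", data=kspace.frame_times)
        h5.attrs["pe_axis"] = kspace.pe_axis
        h5.attrs["fov_mm"] = kspace.fov
        for k, v in dataclasses.asdict(kspace.protocol).items():
            h5.attrs[f"protocol.{k}"] = v if not isinstance(v, tuple) else list(v)
        if kspace.coil_maps is not None:
            h5.create_dataset("coil_maps", data=kspace.coil_maps)
        if kspace.plan is not None:
            p = kspace.plan
            g = h5.create_group("plan")
            g.create_dataset("masks", data=p.masks)
            g.attrs.update({"n": p.n, "truncation": p.truncation,
                            "undersampling": p.undersampling, "frames": p.frames,
                            "seed": p.seed, "center_lines": p.center_lines,
                            "band_lo": p.band[0], "band_hi": p.band[1]})


def load_kspace(path) -> KSpaceSeries:
    with h5py.File(path, "r") as h5:
        prot_kwargs = {}
        for k, v in h5.attrs.items():
            if k.startswith("protocol."):
                name = k.split(".", 1)[1]
                if isinstance(v, np.ndarray):
                    v = tuple(int(x) for x in v)
                elif isinstance(v, np.generic):
                    v = v.item()
                prot_kwargs[name] = v
        protocol = SequenceProtocol(**prot_kwargs)
        plan = None
        if "plan" in h5:
            g = h5["plan"]
            plan = SamplingPlan(
                n=int(g.attrs["n"]), truncation=int(g.attrs["truncation"]),
                undersampling=int(g.attrs["undersampling"]),
                frames=int(g.attrs["frames"]), seed=int(g.attrs["seed"]),
                center_lines=int(g.attrs["center_lines"]),
                band=(int(g.attrs["band_lo"]), int(g.attrs["band_hi"])),
                masks=g["masks"][...].astype(bool))
        coil_maps = h5["coil_maps"][...] if "coil_maps" in h5 else None
        return KSpaceSeries(
            data=h5["kspace"][...], mask=h5["mask"][...].astype(bool),
            line_times=h5["line_times_ms"][...],
            frame_times=h5["frame_times_ms"][...],
            pe_axis=int(h5.attrs["pe_axis"]), fov=float(h5.attrs["fov_mm"]),
            protocol=protocol, plan=plan, coil_maps=coil_maps)


def save_image_series_nifti(path, series: ImageSeries) -> None:
    """Magnitude series as a NIfTI volume (x, y, 1, t)."""
    mag = np.abs(series.data)  # (t, ny, nx)
    vol = np.transpose(mag, (2, 1, 0))[:, :, None, :]
    affine = np.diag([series.pixel_spacing[1], series.pixel_spacing[0], 1.0, 1.0])
    img = nib.Nifti1Image(vol.astype(np.float32), affine)
    zooms = (series.pixel_spacing[1], series.pixel_spacing[0], 1.0,
             float(np.diff(series.frame_times).mean()) if series.n_frames > 1 else 1.0)
    img.header.set_zooms(zooms)
    nib.save(img, str(path))


def load_image_series_nifti(path, pe_axis: int = 0) -> ImageSeries:
    img = nib.load(str(path))
    vol = np.asarray(img.dataobj)
    if vol.ndim == 3:
        vol = vol[:, :, None, :] if vol.shape[-1] > 4 else vol[..., None]
    data = np.transpose(vol[:, :, 0, :], (2, 1, 0)).astype(float)
    zooms = img.header.get_zooms()
    dt = float(zooms[3]) if len(zooms) > 3 else 1.0
    times = np.arange(data.shape[0]) * dt
    return ImageSeries(data=data.astype(complex),
                       pixel_spacing=(float(zooms[1]), float(zooms[0])),
                       frame_times=times, provenance="external",
                       pe_axis=pe_axis)


def save_image_series_h5(path, series: ImageSeries) -> None:
    with h5py.File(path, "w") as h5:
        h5.create_dataset("images", data=series.data)
        h5.create_dataset("frame_times_ms", data=series.frame_times)
        h5.attrs["pixel_spacing_mm"] = list(series.pixel_spacing)
        h5.attrs["provenance"] = series.provenance
        h5.attrs["pe_axis"] = series.pe_axis
        h5.attrs["fov_mm"] = series.fov


def load_image_series_h5(path) -> ImageSeries:
    with h5py.File(path, "r") as h5:
        return ImageSeries(data=h5["images"][...],
                           pixel_spacing=tuple(h5.attrs["pixel_spacing_mm"]),
                           frame_times=h5["frame_times_ms"][...],
                           provenance=str(h5.attrs["provenance"]),
                           pe_axis=int(h5.attrs["pe_axis"]),
                           fov=float(h5.attrs["fov_mm"]))


def save_phantom_config(path, config: PhantomConfig) -> None:
    Path(path).write_text(yaml.safe_dump(dataclasses.asdict(config)))


def load_phantom_config(path) -> PhantomConfig:
    return PhantomConfig(**yaml.safe_load(Path(path).read_text()))


def save_protocol(path, protocol: SequenceProtocol) -> None:
    d = dataclasses.asdict(protocol)
    d["spamm_weights"] = list(d["spamm_weights"])
    Path(path).write_text(yaml.safe_dump(d))


def load_protocol(path) -> SequenceProtocol:
    d = yaml.safe_load(Path(path).read_text())
    if "spamm_weights" in d:
        d["spamm_weights"] = tuple(d["spamm_weights"])
    return SequenceProtocol(**d)


def save_contour_csv(path, contour: np.ndarray) -> None:
    """Ordered contour as CSV columns x_mm, y_mm (row-major (y, x) input)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["x_mm", "y_mm"])
        for y, x in contour:
            w.writerow([f"{x:.6f}", f"{y:.6f}"])


def load_contour_csv(path) -> np.ndarray:
    with open(path) as fh:
        rows = list(csv.DictReader(fh))
    return np.array([[float(r["y_mm"]), float(r["x_mm"])] for r in rows])


def save_strain_csv(path, curve: StrainCurve) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time_ms", "gcs", "converged_fraction"])
        frac = (curve.converged_fraction if curve.converged_fraction is not None
                else np.ones_like(curve.gcs))
        for t, g, c in zip(curve.frame_times, curve.gcs, frac):
            w.writerow([f"{t:.3f}", f"{g:.6f}", f"{c:.3f}"])


def load_pairs_csv(path):
    """CSV with columns subject_id, value_a, value_b."""
    with open(path) as fh:
        rows = list(csv.DictReader(fh))
    subj = [r["subject_id"] for r in rows]
    a = np.array([float(r["value_a"]) for r in rows])
    b = np.array([float(r["value_b"]) for r in rows])
    return subj, a, b


def save_report_json(path, report_dict: dict) -> None:
    Path(path).write_text(json.dumps(report_dict, indent=1, sort_keys=True,
                                     default=float))
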