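"""File formats: NIfTI volumes, physiological-trace TSV, sampling-pattern
exports and serialized encoded k-space."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import FormatError
from .phantom import TENSOR6_ORDER, PhysioTraces
from .sampling import EncodedData, SamplingPattern, ShotSchedule

__all__ = ["save_volume", "load_volume", "save_traces", "load_traces",
           "save_pattern_tsv", "save_pattern_png", "save_encoded",
           "load_encoded", "TENSOR6_ORDER"]


def save_volume(path: str | Path, data: np.ndarray,
                voxel_size: float = 1.0, affine: np.ndarray | None = None,
                descrip: str | None = None) -> Path:
    """Write a volume (or 4D component volume) as NIfTI-1.

    Tensor volumes (last axis 6) should pass ``descrip`` naming the component
    order; the default records the package convention.
    """
    path = Path(path)
    if affine is None:
        affine = np.diag([voxel_size] * 3 + [1.0])
    img = nib.Nifti1Image(np.asarray(data), affine)
    if descrip is None and data.ndim == 4 and data.shape[-1] == 6:
        descrip = ",".join(TENSOR6_ORDER)
    if descrip:
        img.header["descrip"] = descrip.encode()[:79]
    nib.save(img, str(path))
    return path


def load_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray, str]:
    """Read a NIfTI-1 volume; returns (array, affine, header description)."""
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
        descrip = bytes(img.header["descrip"].tobytes()).rstrip(b"\x00").decode(
            "latin1")
        return data, img.affine, descrip
    except Exception as exc:  # nibabel raises several unrelated types
        raise FormatError(f"cannot read {path} as NIfTI: {exc}") from exc


def save_traces(path: str | Path, traces: PhysioTraces) -> Path:
    """Two 2-column TSV files (time_s, amplitude): <stem>_cardiac/_resp."""
    path = Path(path)
    for name, y in (("cardiac", traces.cardiac), ("resp", traces.respiratory)):
        p = path.with_name(f"{path.stem}_{name}.tsv")
        np.savetxt(p, np.column_stack([traces.time, y]), delimiter="\t",
                   header="time_s\tamplitude", comments="")
    return path


def load_traces(path: str | Path) -> np.ndarray:
    """Read a 2-column (time_s, amplitude) TSV."""
    try:
        arr = np.loadtxt(path, delimiter="\t", skiprows=1)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("expected 2 columns")
        return arr
    except Exception as exc:
        raise FormatError(f"cannot read trace file {path}: {exc}") from exc


def save_pattern_tsv(path: str | Path, schedule: ShotSchedule) -> Path:
    """Profile list as TSV: shot, ky, kz, t_s."""
    rows = []
    for k, prof in enumerate(schedule.shot_profiles):
        t = schedule.start_times[k]
        for ky, kz in prof:
            rows.append((k, ky, kz, t))
    arr = np.array(rows, dtype=float)
    np.savetxt(path, arr, delimiter="\t", header="shot\tky\tkz\tt_s",
               comments="", fmt=["%d", "%d", "%d", "%.6f"])
    return Path(path)


def save_pattern_png(path: str | Path, pattern: SamplingPattern) -> Path:
    import imageio.v3 as iio

    iio.imwrite(str(path), (pattern.mask() * np.uint8(255)))
    return Path(path)


def save_encoded(path: str | Path, subscans: list[EncodedData],
                 directions: np.ndarray) -> Path:
    """All subscans in one .npz plus a JSON sidecar describing the layout."""
    path = Path(path)
    arrays = {}
    for d in subscans:
        for k, vals in enumerate(d.samples):
            arrays[f"s{d.direction_index}_shot{k}"] = vals
        arrays[f"s{d.direction_index}_times"] = d.schedule.start_times
        for k, prof in enumerate(d.schedule.shot_profiles):
            arrays[f"s{d.direction_index}_prof{k}"] = prof
    np.savez_compressed(path, **arrays)
    sidecar = {
        "subscan_order": [d.direction_index for d in subscans],
        "image_shape": list(subscans[0].image_shape),
        "grid": list(subscans[0].schedule.grid),
        "TR": subscans[0].schedule.TR,
        "repeats": subscans[0].schedule.repeats,
        "n_shots": subscans[0].schedule.n_shots,
        "directions": np.asarray(directions).tolist(),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path


def load_encoded(path: str | Path) -> tuple[list[EncodedData], dict]:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    npz = np.load(path if path.suffix == ".npz" else path.with_suffix(".npz"))
    subscans = []
    n_shots = sidecar["n_shots"]
    for di in sidecar["subscan_order"]:
        profiles = [npz[f"s{di}_prof{k}"] for k in range(n_shots)]
        schedule = ShotSchedule(shot_profiles=profiles,
                                start_times=npz[f"s{di}_times"],
                                TR=sidecar["TR"],
                                grid=tuple(sidecar["grid"]),
                                repeats=sidecar["repeats"])
        samples = [npz[f"s{di}_shot{k}"] for k in range(n_shots)]
        subscans.append(EncodedData(samples=samples, schedule=schedule,
                                    direction_index=di,
                                    image_shape=tuple(sidecar["image_shape"])))
    return subscans, sidecar
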