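"""End-to-end pipeline: simulate -> bin -> recon -> fit -> phasecycle -> roi
-> report.

Each stage consumes the artifacts of the previous stage from the output
directory and writes its own.  All randomness flows from the single
top-level seed through named substreams, so a fixed seed yields a
byte-identical JSON report.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as cio
from .binning import FORCES, assign_bins, bin_kspace, detect_peaks
from .errors import ConfigurationError, DependencyError
from .phantom import (PhantomSpec, StructureSpec, make_phantom,
                      make_physio_traces)
from .phasecycle import percent_change, phase_summaries, sine_fit
from .recon import ReconConfig, reconstruct
from .roitools import MaskConfig, csf_mask, roi_stats
from .sampling import (AcquisitionConfig, make_pattern, make_shot_schedule,
                       simulate_acquisition)
from .tensorfit import fit_tensor, tensor_metrics

__all__ = ["PipelineConfig", "run_pipeline", "COMMANDS"]

COMMANDS = ("simulate", "bin", "recon", "fit", "phasecycle", "roi", "report")
REPORT_SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    phantom: PhantomSpec
    acquisition: AcquisitionConfig
    recon: ReconConfig
    mask: MaskConfig
    outputs: Path
    seed: int = 0
    repeats: int = 1  # acquisition passes over the pattern
    duration_margin: float = 30.0  # extra trace seconds beyond the schedule
    cardiac_rate: float = 1.0
    resp_rate: float = 0.25
    trace_jitter: float = 0.05
    forces: tuple[str, ...] = FORCES
    s0_threshold: float = 150.0
    mobility_cutoff: float = 0.15

    def __post_init__(self) -> None:
        self.outputs = Path(self.outputs)
        # one seed drives every stage
        self.phantom.seed = self.seed
        self.acquisition.seed = self.seed

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        structures = [StructureSpec(**s) for s in raw["phantom"].pop("structures", [])]
        phantom = PhantomSpec(structures=structures, **raw["phantom"])
        acq = AcquisitionConfig(**raw.get("acquisition", {}))
        rec = ReconConfig(**raw.get("recon", {}))
        mask = MaskConfig(**raw.get("analysis", {}).get("mask", {}))
        top = {k: raw[k] for k in ("seed", "repeats", "cardiac_rate",
                                   "resp_rate", "trace_jitter")
               if k in raw}
        return cls(phantom=phantom, acquisition=acq, recon=rec, mask=mask,
                   outputs=raw.get("outputs", "."), **top)

    def config_hash(self) -> str:
        def default(o):
            if isinstance(o, Path):
                return str(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            return str(o)

        d = asdict(self)
        d.pop("outputs", None)  # where artifacts land is not scientific config
        blob = json.dumps(d, sort_keys=True, default=default)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _need(path: Path, stage: str) -> Path:
    if not path.exists():
        raise DependencyError(
            f"missing artifact {path.name}: run the '{stage}' stage first")
    return path


def _fmt(x):
    """Floats at 12 significant digits for a stable JSON report."""
    if isinstance(x, dict):
        return {k: _fmt(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_fmt(v) for v in x]
    if isinstance(x, np.ndarray):
        return _fmt(x.tolist())
    if isinstance(x, (float, np.floating)):
        return float(f"{float(x):.12g}")
    if isinstance(x, (int, np.integer)):
        return int(x)
    return x


def _stage_simulate(cfg: PipelineConfig, out: Path) -> None:
    truth = make_phantom(cfg.phantom)
    pattern = make_pattern(cfg.acquisition)
    schedule = make_shot_schedule(pattern, cfg.acquisition, repeats=cfg.repeats)
    traces = make_physio_traces(schedule.duration + cfg.duration_margin,
                                cardiac_rate=cfg.cardiac_rate,
                                resp_rate=cfg.resp_rate,
                                jitter=cfg.trace_jitter, seed=cfg.seed)
    subscans = simulate_acquisition(truth, traces, schedule, cfg.acquisition)

    vs = cfg.phantom.voxel_size
    cio.save_volume(out / "truth_tensor.nii.gz", truth.tensor0, vs)
    cio.save_volume(out / "truth_signal.nii.gz", truth.signal, vs)
    masks = np.stack(truth.structure_masks).astype(np.uint8)
    cio.save_volume(out / "truth_masks.nii.gz", np.moveaxis(masks, 0, -1), vs,
                    descrip="structure masks")
    cio.save_traces(out / "traces.tsv", traces)
    cio.save_pattern_tsv(out / "pattern.tsv", schedule)
    cio.save_encoded(out / "encoded.npz", subscans, cfg.acquisition.directions)
    np.save(out / "truth_peaks_cardiac.npy", traces.cardiac_peaks)
    np.save(out / "truth_peaks_resp.npy", traces.resp_peaks)


def _stage_bin(cfg: PipelineConfig, out: Path, forces) -> None:
    subscans, _ = cio.load_encoded(_need(out / "encoded.npz", "simulate"))
    for force in forces:
        if force == "random":
            peaks = None
        else:
            stem = "cardiac" if force == "cardiac" else "resp"
            arr = cio.load_traces(_need(out / f"traces_{stem}.tsv", "simulate"))
            peaks = detect_peaks(arr[:, 0], arr[:, 1])
        np.savez_compressed(
            out / f"binned_{force}.npz",
            **{f"s{d.direction_index}_{name}": val
               for d in subscans
               for name, val in zip(
                   ("kspace", "mask", "mult"),
                   (lambda b: (b.kspace, b.mask, b.multiplicity))(
                       bin_kspace(d, assign_bins(peaks, d.schedule, force,
                                                 seed=cfg.seed))))})


def _load_binned(out: Path, force: str, subscan: int):
    from .binning import BinnedKSpace

    npz = np.load(_need(out / f"binned_{force}.npz", "bin"))
    return BinnedKSpace(kspace=npz[f"s{subscan}_kspace"],
                        mask=npz[f"s{subscan}_mask"],
                        multiplicity=npz[f"s{subscan}_mult"],
                        direction_index=subscan)


def _stage_recon(cfg: PipelineConfig, out: Path, forces) -> None:
    vs = cfg.phantom.voxel_size
    for force in forces:
        vols = []
        for sub in range(cfg.acquisition.n_directions + 1):
            binned = _load_binned(out, force, sub)
            series = reconstruct(binned, cfg.recon, voxel_size=vs)
            vols.append(series.volumes)
        arr = np.stack(vols)  # (7, 6, X, Y, Z)
        np.save(out / f"recon_{force}.npy", arr)


def _stage_fit(cfg: PipelineConfig, out: Path, forces) -> None:
    dirs = cfg.acquisition.directions
    for force in forces:
        vols = np.load(_need(out / f"recon_{force}.npy", "recon"))
        mob, fa, valid = [], [], []
        for p in range(vols.shape[1]):
            fieldp = fit_tensor(vols[:, p], dirs, cfg.acquisition.b_value,
                                s0_threshold=cfg.s0_threshold)
            m = tensor_metrics(fieldp, cutoff=cfg.mobility_cutoff)
            mob.append(m["mobility"])
            fa.append(m["fa"])
            valid.append(m["valid"])
        np.save(out / f"mobility_{force}.npy", np.stack(mob))
        np.save(out / f"fa_{force}.npy", np.stack(fa))
        np.save(out / f"valid_{force}.npy", np.stack(valid))


def _stage_phasecycle(cfg: PipelineConfig, out: Path, forces) -> None:
    for force in forces:
        mob = np.load(_need(out / f"mobility_{force}.npy", "fit"))
        valid = np.load(_need(out / f"valid_{force}.npy", "fit")).all(axis=0)
        prof = percent_change(mob, valid=valid)
        fits = sine_fit(prof)
        np.save(out / f"profile_{force}.npy", prof.values)
        np.save(out / f"amplitude_{force}.npy", fits.gated_amplitude)
        np.save(out / f"r2_{force}.npy", fits.r2)


def _stage_roi(cfg: PipelineConfig, out: Path, forces) -> None:
    ref, _, _ = cio.load_volume(_need(out / "truth_signal.nii.gz", "simulate"))
    changes = []
    for force in forces:
        prof = np.load(_need(out / f"profile_{force}.npy", "phasecycle"))
        changes.extend(np.nan_to_num(prof[k]) for k in range(prof.shape[0]))
    mask = csf_mask(ref, changes, cfg.mask)
    np.save(out / "csf_mask.npy", mask)


def _stage_report(cfg: PipelineConfig, out: Path, forces) -> None:
    masks, _, _ = cio.load_volume(_need(out / "truth_masks.nii.gz", "simulate"))
    csf = np.load(_need(out / "csf_mask.npy", "roi"))
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "structures": [],
        "forces": {},
    }
    for force in forces:
        mob = np.load(_need(out / f"mobility_{force}.npy", "fit"))
        prof_vals = np.load(out / f"profile_{force}.npy")
        amp = np.load(out / f"amplitude_{force}.npy")
        r2 = np.load(out / f"r2_{force}.npy")
        valid = np.load(out / f"valid_{force}.npy").all(axis=0)
        from .phasecycle import PhaseProfile, SineFitResult

        prof = PhaseProfile(values=prof_vals,
                            valid=valid & np.isfinite(prof_vals).all(axis=0))
        fits = SineFitResult(amplitude=amp, phase=np.zeros_like(amp), r2=r2,
                             gated_amplitude=amp, valid=prof.valid)
        per_structure = []
        for si in range(masks.shape[-1]):
            roi = masks[..., si].astype(bool) & csf & prof.valid
            if not roi.any():
                per_structure.append(None)
                continue
            summ = phase_summaries(prof, fits, roi)
            summ.pop("n_voxels")
            stats = roi_stats(mob.mean(axis=0), roi)
            per_structure.append({
                "mobility": stats,
                "gated_amplitude_mean": float(np.mean(amp[roi])),
                **{k: v for k, v in summ.items()},
            })
        report["forces"][force] = per_structure
    for si in range(masks.shape[-1]):
        report["structures"].append({"index": si,
                                     "n_voxels": int(masks[..., si].sum())})
    (out / "report.json").write_text(
        json.dumps(_fmt(report), indent=2, sort_keys=True) + "\n")


def run_pipeline(cfg: PipelineConfig, command: str,
                 forces: tuple[str, ...] | None = None) -> Path:
    """Run one pipeline stage (or 'report' after all stages).

    Returns the output directory.  Stages must be run in order; a missing
    upstream artifact raises :class:`DependencyError` naming the stage to
    run first.
    """
    if command not in COMMANDS:
        raise ConfigurationError(f"unknown command {command!r}")
    forces = tuple(forces or cfg.forces)
    out = Path(cfg.outputs)
    out.mkdir(parents=True, exist_ok=True)
    stage = {
        "simulate": lambda: _stage_simulate(cfg, out),
        "bin": lambda: _stage_bin(cfg, out, forces),
        "recon": lambda: _stage_recon(cfg, out, forces),
        "fit": lambda: _stage_fit(cfg, out, forces),
        "phasecycle": lambda: _stage_phasecycle(cfg, out, forces),
        "roi": lambda: _stage_roi(cfg, out, forces),
        "report": lambda: _stage_report(cfg, out, forces),
    }[command]
    stage()
    return out
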