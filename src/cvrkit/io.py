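"""Reading and writing the pipeline's file formats.

NIfTI-1 for volumes (via nibabel), BIDS-flavoured TSV for events
(onset/duration/trial_type[/correct]), physio TSV (time, co2_mmHg), motion
TSV (6 unlabelled columns), and JSON sidecars carrying the repetition time.
`write_dataset` serializes a simulated cohort with a checksummed manifest so
any artifact can be regenerated from manifest + config alone.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .phantom import AtlasPhantom, ParadigmSpec, RespiratoryTrace
from .runs import BoldRun

__all__ = [
    "save_run",
    "load_run",
    "save_map",
    "load_map",
    "write_events",
    "read_events",
    "write_physio",
    "read_physio",
    "write_motion",
    "read_motion",
    "save_atlas",
    "load_atlas",
    "write_dataset",
    "sha256_of",
]

EVENT_COLUMNS = ("onset", "duration", "trial_type")


def sha256_of(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def save_run(run: BoldRun, stem: Path) -> list[Path]:
    """Write <stem>_bold.nii, its JSON sidecar, <stem>_mask.nii and motion TSV."""
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    paths = []
    bold = stem.with_name(stem.name + "_bold.nii")
    nib.save(nib.Nifti1Image(run.data.astype(np.float64), run.affine), bold)
    paths.append(bold)
    side = stem.with_name(stem.name + "_bold.json")
    meta = {k: v for k, v in run.meta.items() if k != "motion"}
    side.write_text(json.dumps({"RepetitionTime": run.tr, **meta}, indent=1, default=str))
    paths.append(side)
    maskp = stem.with_name(stem.name + "_mask.nii")
    nib.save(nib.Nifti1Image(run.mask.astype(np.uint8), run.affine), maskp)
    paths.append(maskp)
    if "motion" in run.meta:
        mot = stem.with_name(stem.name + "_motion.tsv")
        write_motion(run.meta["motion"], mot)
        paths.append(mot)
    return paths


def load_run(stem: Path, expected_tr: float | None = None) -> BoldRun:
    """Read a run written by :func:`save_run`; checks sidecar TR consistency."""
    stem = Path(stem)
    img = nib.load(stem.with_name(stem.name + "_bold.nii"))
    side = json.loads(stem.with_name(stem.name + "_bold.json").read_text())
    tr = float(side.pop("RepetitionTime"))
    if expected_tr is not None and abs(tr - expected_tr) > 1e-9:
        raise ValueError(f"sidecar TR {tr} does not match configured TR {expected_tr}")
    mask = np.asarray(nib.load(stem.with_name(stem.name + "_mask.nii")).dataobj).astype(bool)
    meta = dict(side)
    motp = stem.with_name(stem.name + "_motion.tsv")
    if motp.exists():
        meta["motion"] = read_motion(motp)
    return BoldRun(
        data=np.asarray(img.dataobj, dtype=np.float64),
        tr=tr,
        mask=mask,
        affine=np.asarray(img.affine),
        meta=meta,
    )


def save_map(volume: np.ndarray, affine: np.ndarray, path: Path, sidecar: dict | None = None) -> None:
    """Write a 3D map as NIfTI with an optional JSON sidecar (contrast, alpha, dof...)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(np.asarray(volume, np.float64), affine), path)
    if sidecar is not None:
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1, default=str))


def load_map(path: Path) -> np.ndarray:
    return np.asarray(nib.load(path).dataobj, dtype=np.float64)


def write_events(paradigm: ParadigmSpec, path: Path) -> None:
    paradigm.to_events_frame().to_csv(path, sep="\t", index=False)


def read_events(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"events file {path} is missing required column(s): {missing}")
    return df


def events_to_paradigm(df: pd.DataFrame, kind: str, total_duration: float, tr: float) -> ParadigmSpec:
    return ParadigmSpec(
        kind=kind,
        onsets=df["onset"].to_numpy(float),
        durations=df["duration"].to_numpy(float),
        conditions=[str(c) for c in df["trial_type"]],
        total_duration=total_duration,
        tr=tr,
        correctness=df["correct"].to_numpy(bool) if "correct" in df.columns else None,
    )


def write_physio(trace: RespiratoryTrace, path: Path) -> None:
    trace.to_frame().to_csv(path, sep="\t", index=False)


def read_physio(path: Path, breath_period: float = 4.0) -> RespiratoryTrace:
    """Read a physio TSV; non-uniform sampling is resampled with a warning."""
    df = pd.read_csv(path, sep="\t")
    for col in ("time", "co2_mmHg"):
        if col not in df.columns:
            raise ValueError(f"physio file {path} is missing column {col!r}")
    t = df["time"].to_numpy(float)
    co2 = df["co2_mmHg"].to_numpy(float)
    steps = np.diff(t)
    if steps.size and (steps.max() - steps.min()) > 1e-6 * max(steps.max(), 1e-12):
        dt = float(np.median(steps))
        warnings.warn("physio time grid is non-uniform; resampling by linear interpolation", stacklevel=2)
        tu = np.arange(t[0], t[-1] + dt / 2, dt)
        co2 = np.interp(tu, t, co2)
        t = tu
    return RespiratoryTrace(time=t, co2=co2, breath_period=breath_period)


def write_motion(motion: np.ndarray, path: Path) -> None:
    np.savetxt(path, np.asarray(motion, float), delimiter="\t", fmt="%.8f")


def read_motion(path: Path) -> np.ndarray:
    m = np.loadtxt(path, delimiter="\t")
    if m.ndim != 2 or m.shape[1] != 6:
        raise ValueError(f"motion file {path} must have 6 columns")
    return m


def save_atlas(phantom: AtlasPhantom, stem: Path) -> list[Path]:
    stem = Path(stem)
    p1 = stem.with_name(stem.name + "_labels.nii")
    nib.save(nib.Nifti1Image(phantom.label_volume.astype(np.int16), phantom.affine), p1)
    p2 = stem.with_name(stem.name + "_labels.json")
    p2.write_text(
        json.dumps(
            {
                "grid_shape": list(phantom.grid_shape),
                "voxel_size": list(phantom.voxel_size),
                "label_table": {str(k): v for k, v in phantom.label_table.items()},
            },
            indent=1,
        )
    )
    return [p1, p2]


def load_atlas(stem: Path) -> AtlasPhantom:
    stem = Path(stem)
    vol = np.asarray(nib.load(stem.with_name(stem.name + "_labels.nii")).dataobj).astype(np.int32)
    meta = json.loads(stem.with_name(stem.name + "_labels.json").read_text())
    return AtlasPhantom(
        label_volume=vol,
        grid_shape=tuple(meta["grid_shape"]),
        voxel_size=tuple(meta["voxel_size"]),
        label_table={int(k): v for k, v in meta["label_table"].items()},
    )


def write_dataset(runs: dict, paradigms: dict, traces: dict, out_dir: Path) -> dict:
    """Serialize a simulated dataset and return its checksummed manifest.

    ``runs`` maps a file stem (e.g. ``"sub-01_task-breathhold"``) to a
    BoldRun; ``paradigms`` maps a stem to a ParadigmSpec (written as events
    TSV); ``traces`` maps a stem to a RespiratoryTrace (physio TSV). The
    manifest (also written as ``manifest.json``) lists every file with its
    sha256. Name collisions raise.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _add(paths):
        for p in paths:
            if p in written:
                raise ValueError(f"name collision: {p}")
            written.append(p)

    for stem, run in runs.items():
        _add(save_run(run, out_dir / stem))
    for stem, par in paradigms.items():
        p = out_dir / f"{stem}_events.tsv"
        if p.exists():
            raise ValueError(f"name collision: {p}")
        write_events(par, p)
        _add([p])
    for stem, tr in traces.items():
        p = out_dir / f"{stem}_physio.tsv"
        write_physio(tr, p)
        _add([p])
    manifest = {
        "files": [{"path": p.name, "sha256": sha256_of(p)} for p in written],
        "n_files": len(written),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
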