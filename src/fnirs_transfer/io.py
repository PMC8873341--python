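"""Disk formats: cohort directories, epoch-set archives, optional SNIRF.

A cohort directory holds one TSV per subject (rows = channel x wavelength,
columns = samples) with a JSON sidecar describing geometry, schedule and
provenance, plus a manifest of SHA-256 checksums so reruns can be verified
byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from .exceptions import IntegrityError, ValidationError
from .paradigm import build_schedule
from .preprocess import EpochSet
from .recordings import OpticalRecording


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _schedule_doc(schedule) -> dict:
    s0 = schedule.series[0]
    return {
        "sessions": schedule.sessions,
        "series_per_session": schedule.series_per_session,
        "sampling_rate": schedule.sampling_rate,
        "instruction_s": s0.instruction_s,
        "task_s": s0.task_s,
        "rest_s": s0.rest_s,
        "trials_per_series": s0.n_trials,
    }


def write_recording(rec: OpticalRecording, out_dir: str | Path) -> dict:
    """Write one recording as TSV + JSON sidecar; returns file checksums."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    flat = rec.data.reshape(rec.n_channels * 2, rec.n_samples)
    tsv = out_dir / f"{rec.subject_id}.tsv"
    np.savetxt(tsv, flat, delimiter="\t", fmt="%.6g")
    sidecar = {
        "subject_id": rec.subject_id,
        "sampling_rate": rec.sampling_rate,
        "wavelengths_nm": list(rec.wavelengths_nm),
        "source_detector_mm": rec.source_detector_mm,
        "n_channels": rec.n_channels,
        "schedule": _schedule_doc(rec.schedule),
    }
    js = out_dir / f"{rec.subject_id}.json"
    js.write_text(json.dumps(sidecar, indent=2))
    return {tsv.name: _sha256(tsv), js.name: _sha256(js)}


def read_recording(out_dir: str | Path, subject_id: str) -> OpticalRecording:
    out_dir = Path(out_dir)
    sidecar = json.loads((out_dir / f"{subject_id}.json").read_text())
    flat = np.loadtxt(out_dir / f"{subject_id}.tsv", delimiter="\t")
    n_ch = sidecar["n_channels"]
    schedule = build_schedule(**sidecar["schedule"])
    return OpticalRecording(
        data=flat.reshape(n_ch, 2, -1),
        sampling_rate=sidecar["sampling_rate"],
        subject_id=sidecar["subject_id"],
        schedule=schedule,
        wavelengths_nm=tuple(sidecar["wavelengths_nm"]),
        source_detector_mm=sidecar["source_detector_mm"],
    )


def write_cohort(cohort: list[OpticalRecording], out_dir: str | Path, master_seed: int | None = None) -> Path:
    """Write every recording plus a checksum manifest; returns manifest path."""
    out_dir = Path(out_dir)
    checksums: dict[str, str] = {}
    for rec in cohort:
        checksums.update(write_recording(rec, out_dir))
    manifest = {
        "n_subjects": len(cohort),
        "master_seed": master_seed,
        "files": dict(sorted(checksums.items())),
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path


def read_cohort(out_dir: str | Path, verify: bool = True) -> list[OpticalRecording]:
    out_dir = Path(out_dir)
    manifest = json.loads((out_dir / "manifest.json").read_text())
    if verify:
        for name, digest in manifest["files"].items():
            actual = _sha256(out_dir / name)
            if actual != digest:
                raise IntegrityError(f"checksum mismatch for {name}")
    subjects = sorted({Path(n).stem for n in manifest["files"]})
    return [read_recording(out_dir, s) for s in subjects]


def save_epochs(epochs: EpochSet, path: str | Path) -> None:
    """Save an epoch set as a compressed tensor archive + JSON sidecar."""
    path = Path(path)
    np.savez_compressed(
        path.with_suffix(".npz"),
        X=epochs.X,
        y=epochs.y,
        subject_ids=epochs.subject_ids.astype(str),
        series_idx=epochs.series_idx,
    )
    sidecar = {
        "window_s": epochs.window_s,
        "step_s": epochs.step_s,
        "class_mode": epochs.class_mode,
        "sampling_rate": epochs.sampling_rate,
        "n_examples": int(epochs.n_examples),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_epochs(path: str | Path) -> EpochSet:
    path = Path(path)
    arrays = np.load(path.with_suffix(".npz"), allow_pickle=False)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    eps = EpochSet(
        X=arrays["X"],
        y=arrays["y"],
        subject_ids=arrays["subject_ids"],
        series_idx=arrays["series_idx"],
        window_s=sidecar["window_s"],
        step_s=sidecar["step_s"],
        class_mode=sidecar["class_mode"],
        sampling_rate=sidecar["sampling_rate"],
    )
    if eps.n_examples != sidecar["n_examples"]:
        raise IntegrityError("epoch archive inconsistent with its sidecar")
    return eps


def to_snirf(rec: OpticalRecording, path: str | Path) -> None:
    """Minimal SNIRF (HDF5) export of one optical recording.

    Requires the optional ``h5py`` dependency; writes the core /nirs
    structure (amplitude-style data block, wavelengths, one probe row per
    channel).  Intended for interoperability checks, not as a complete
    SNIRF writer.
    """
    try:
        import h5py
    except ImportError as exc:  # pragma: no cover
        raise ValidationError("SNIRF export requires the optional h5py dependency") from exc
    t = np.arange(rec.n_samples) / rec.sampling_rate
    # measurement list: channel-major, wavelength-minor
    data = rec.data.reshape(rec.n_channels * 2, rec.n_samples).T
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0")
        nirs = f.create_group("nirs")
        meta = nirs.create_group("metaDataTags")
        meta.create_dataset("SubjectID", data=rec.subject_id)
        meta.create_dataset("LengthUnit", data="mm")
        d1 = nirs.create_group("data1")
        d1.create_dataset("dataTimeSeries", data=data)
        d1.create_dataset("time", data=t)
        for i in range(rec.n_channels):
            for j in range(2):
                ml = d1.create_group(f"measurementList{i * 2 + j + 1}")
                ml.create_dataset("sourceIndex", data=i + 1)
                ml.create_dataset("detectorIndex", data=i + 1)
                ml.create_dataset("wavelengthIndex", data=j + 1)
                ml.create_dataset("dataType", data=99999)  # processed (dOD)
        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(rec.wavelengths_nm))
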