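"""Plain-text persistence: recordings as TSV + JSON sidecar, reports as CSV.

Layout for one subject ``<id>``::

    <id>.tsv            ROI time series, header = ROI names, one row/frame
    <id>_csf.tsv        CSF nuisance channels
    <id>_wm.tsv         WM nuisance channels
    <id>.json           sidecar: group, TR, motion, parcel/ROI intensities
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import ROICatalog
from .synthetic import SubjectRecording

__all__ = ["write_recording", "write_cohort", "load_recording", "load_dataset",
           "write_ledger", "load_ledger"]

_FLOAT_FMT = "%.10g"


def write_recording(recording: SubjectRecording, directory: str | Path) -> Path:
    """Write one recording (TSV + nuisance TSVs + JSON sidecar)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sid = recording.subject_id
    roi_path = directory / f"{sid}.tsv"
    pd.DataFrame(recording.roi_series, columns=recording.roi_names).to_csv(
        roi_path, sep="\t", index=False, float_format=_FLOAT_FMT
    )
    for tag, arr in (("csf", recording.csf_series), ("wm", recording.wm_series)):
        cols = [f"{tag}_{i}" for i in range(np.asarray(arr).shape[1])]
        pd.DataFrame(arr, columns=cols).to_csv(
            directory / f"{sid}_{tag}.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
        )
    sidecar = {
        "subject_id": sid,
        "group": recording.group,
        "tr_seconds": recording.tr_seconds,
        "motion_mm": recording.motion_mm,
        "motion_deg": recording.motion_deg,
        "parcel_means": np.asarray(recording.parcel_means, dtype=float).tolist(),
        "roi_mean_intensity": {k: float(v) for k, v in recording.roi_mean_intensity.items()},
        "csf_file": f"{sid}_csf.tsv",
        "wm_file": f"{sid}_wm.tsv",
    }
    gt = {k: v for k, v in recording.ground_truth.items() if k != "nuisance_sources"}
    if gt:
        sidecar["ground_truth"] = gt
    (directory / f"{sid}.json").write_text(json.dumps(sidecar, indent=1))
    return roi_path


def write_cohort(
    recordings: list[SubjectRecording], ledger: dict | None, directory: str | Path
) -> None:
    directory = Path(directory)
    for rec in recordings:
        write_recording(rec, directory)
    if ledger is not None:
        write_ledger(ledger, directory / "ledger.json")


def write_ledger(ledger: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(ledger, indent=1))


def load_ledger(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def load_recording(sidecar_path: str | Path, catalog: ROICatalog) -> SubjectRecording:
    """Load one subject from its JSON sidecar; validate against the catalog."""
    sidecar_path = Path(sidecar_path)
    meta = json.loads(sidecar_path.read_text())
    sid = meta["subject_id"]
    directory = sidecar_path.parent
    roi = pd.read_csv(directory / f"{sid}.tsv", sep="\t")
    if list(roi.columns) != catalog.names:
        raise ValueError(
            f"subject {sid}: ROI header does not match catalog "
            f"(got {list(roi.columns)[:3]}..., expected {catalog.names[:3]}...)"
        )
    values = roi.to_numpy(dtype=float)  # raises on non-numeric cells
    csf = pd.read_csv(directory / meta["csf_file"], sep="\t").to_numpy(dtype=float)
    wm = pd.read_csv(directory / meta["wm_file"], sep="\t").to_numpy(dtype=float)
    if csf.shape[0] != values.shape[0] or wm.shape[0] != values.shape[0]:
        raise ValueError(f"subject {sid}: inconsistent frame counts across series")
    return SubjectRecording(
        subject_id=sid,
        group=meta["group"],
        roi_names=list(roi.columns),
        roi_series=values,
        parcel_means=np.asarray(meta["parcel_means"], dtype=float),
        roi_mean_intensity=meta["roi_mean_intensity"],
        csf_series=csf,
        wm_series=wm,
        motion_mm=float(meta["motion_mm"]),
        motion_deg=float(meta["motion_deg"]),
        tr_seconds=float(meta["tr_seconds"]),
        ground_truth=meta.get("ground_truth", {}),
    )


def load_dataset(
    directory: str | Path, catalog: ROICatalog
) -> tuple[list[SubjectRecording], list[str]]:
    """Load every subject sidecar in ``directory``.

    Returns the validated recordings plus per-subject diagnostics for the
    files that failed validation.  An empty directory is a warning, not an
    error.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"no such directory: {directory}")
    sidecars = sorted(p for p in directory.glob("*.json") if p.name != "ledger.json")
    recordings: list[SubjectRecording] = []
    problems: list[str] = []
    for path in sidecars:
        try:
            recordings.append(load_recording(path, catalog))
        except Exception as exc:  # noqa: BLE001 - collect per-file diagnostics
            problems.append(f"{path.name}: {exc}")
    if not sidecars:
        warnings.warn(f"no subject sidecars found in {directory}")
    return recordings, problems
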