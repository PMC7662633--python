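"""Readers and writers for the plain-text interchange formats.

Signals travel as CSV (a ``value`` column, optional ``time_s``), motion as
three-column CSV, decompositions as ``imf1..imfK,residue`` CSV, feature
tables as named-column CSV with a trailing ``label`` column, frame
annotations as JSON lines pointing at grayscale PNG patches, generator
profiles as YAML, and evaluation reports as JSON validated by a pydantic
model (whose JSON schema ships with the package).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field

from .classify import EvalResult
from .emd import IMFDecomposition
from .features import BoundingBox, FramePair, MotionWindow
from .signal import TimeSeries
from .synthetic import ActivityProfile

__all__ = [
    "read_signal_csv",
    "write_signal_csv",
    "read_edf_channel",
    "read_motion_csv",
    "write_motion_csv",
    "write_decomposition_csv",
    "read_decomposition_csv",
    "write_feature_table",
    "read_feature_table",
    "write_annotations",
    "read_annotations",
    "read_profiles_yaml",
    "write_profiles_yaml",
    "Report",
    "write_report",
    "read_report",
]


# ---------------------------------------------------------------------------
# signals
# ---------------------------------------------------------------------------


def read_signal_csv(path: str | Path, rate_hz: float | None = None) -> TimeSeries:
    """Load a single-channel signal from CSV.

    The file must have a ``value`` column; if ``rate_hz`` is not given it
    is inferred from the median step of a ``time_s`` column.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if "value" not in df.columns:
        raise ValueError(f"{path}: expected a 'value' column, got {list(df.columns)}")
    if rate_hz is None:
        if "time_s" not in df.columns:
            raise ValueError(f"{path}: need rate_hz or a 'time_s' column")
        dt = float(np.median(np.diff(df["time_s"].to_numpy())))
        if dt <= 0:
            raise ValueError(f"{path}: non-increasing time_s column")
        rate_hz = 1.0 / dt
    return TimeSeries(df["value"].to_numpy(float), rate_hz, id=str(path))


def write_signal_csv(s: TimeSeries, path: str | Path, with_time: bool = False) -> None:
    cols = {"value": s.samples}
    if with_time:
        cols = {"time_s": s.times, **cols}
    pd.DataFrame(cols).to_csv(path, index=False)


def read_edf_channel(path: str | Path, channel: str) -> TimeSeries:
    """Load one channel of an EDF recording (requires the ``mne`` extra)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("EDF input requires the optional 'mne' dependency") from exc
    raw = mne.io.read_raw_edf(str(path), include=[channel], preload=True, verbose="error")
    if channel not in raw.ch_names:
        raise ValueError(f"{path}: channel {channel!r} not found")
    data = raw.get_data(picks=[channel])[0]
    return TimeSeries(data, float(raw.info["sfreq"]), id=channel)


def read_motion_csv(path: str | Path, rate_hz: float = 31.0) -> MotionWindow:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = {"x", "y", "z"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing motion columns {sorted(missing)}")
    return MotionWindow(
        df["x"].to_numpy(float), df["y"].to_numpy(float), df["z"].to_numpy(float), rate_hz
    )


def write_motion_csv(w: MotionWindow, path: str | Path) -> None:
    pd.DataFrame({"x": w.x, "y": w.y, "z": w.z}).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# decompositions
# ---------------------------------------------------------------------------


def write_decomposition_csv(dec: IMFDecomposition, path: str | Path) -> None:
    cols = {f"imf{i + 1}": imf.samples for i, imf in enumerate(dec.imfs)}
    cols["residue"] = dec.residue.samples
    pd.DataFrame(cols).to_csv(path, index=False)


def read_decomposition_csv(path: str | Path, rate_hz: float) -> IMFDecomposition:
    df = pd.read_csv(path, float_precision="round_trip")
    if "residue" not in df.columns:
        raise ValueError(f"{path}: missing 'residue' column")
    imf_cols = [c for c in df.columns if c.startswith("imf")]
    imf_cols.sort(key=lambda c: int(c[3:]))
    return IMFDecomposition(
        imfs=tuple(
            TimeSeries(df[c].to_numpy(float), rate_hz, id=c) for c in imf_cols
        ),
        residue=TimeSeries(df["residue"].to_numpy(float), rate_hz, id="residue"),
    )


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------


def write_feature_table(
    X: np.ndarray, names, y, path: str | Path
) -> None:
    df = pd.DataFrame(np.asarray(X, dtype=float), columns=list(names))
    df["label"] = np.asarray(y)
    df.to_csv(path, index=False)


def read_feature_table(path: str | Path) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    df = pd.read_csv(path, float_precision="round_trip")
    if "label" not in df.columns:
        raise ValueError(f"{path}: feature tables need a 'label' column")
    y = df.pop("label").to_numpy()
    return df.to_numpy(float), y, tuple(df.columns)


# ---------------------------------------------------------------------------
# frame annotations + patches
# ---------------------------------------------------------------------------


def _save_patch(patch: np.ndarray, path: Path) -> None:
    from PIL import Image

    arr = np.clip(np.asarray(patch, dtype=float), 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)


def _load_patch(path: Path) -> np.ndarray:
    from PIL import Image

    with Image.open(path) as img:
        return np.asarray(img.convert("L"), dtype=float)


def write_annotations(
    pairs: list[FramePair], ann_path: str | Path, patch_dir: str | Path
) -> None:
    """Write frame-pair annotations as JSON lines plus PNG patches.

    Consecutive pairs share frames, so frame i of pair k is written once
    under the running frame index.
    """
    ann_path = Path(ann_path)
    patch_dir = Path(patch_dir)
    patch_dir.mkdir(parents=True, exist_ok=True)
    records = []
    for k, pair in enumerate(pairs):
        for offset, (box, patch) in enumerate(
            [(pair.box_a, pair.patch_a), (pair.box_b, pair.patch_b)]
        ):
            frame = k + offset
            if offset == 0 and k > 0:
                continue  # first frame of this pair == second frame of previous
            patch_path = patch_dir / f"frame_{frame:05d}.png"
            _save_patch(patch, patch_path)
            records.append(
                {
                    "frame": frame,
                    "xmin": box.xmin,
                    "xmax": box.xmax,
                    "ymin": box.ymin,
                    "ymax": box.ymax,
                    "patch_path": str(patch_path),
                }
            )
    with open(ann_path, "w") as fh:
        for rec in records:
            fh.write(json.dumps(rec) + "\n")


def read_annotations(ann_path: str | Path) -> list[FramePair]:
    """Rebuild consecutive frame pairs from a JSON-lines annotation file."""
    records = []
    with open(ann_path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                records.append(json.loads(line))
    records.sort(key=lambda r: r["frame"])
    frames = [
        (
            BoundingBox(r["xmin"], r["xmax"], r["ymin"], r["ymax"]),
            _load_patch(Path(r["patch_path"])),
        )
        for r in records
    ]
    if len(frames) < 2:
        raise ValueError(f"{ann_path}: need at least 2 annotated frames")
    return [
        FramePair(frames[i][0], frames[i + 1][0], frames[i][1], frames[i + 1][1])
        for i in range(len(frames) - 1)
    ]


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------


def write_profiles_yaml(profiles, path: str | Path) -> None:
    payload = [
        {
            "label": p.label,
            "band_powers": dict(p.band_powers),
            "box_step_scale": p.box_step_scale,
            "motion_mean": list(p.motion_mean),
            "motion_var": list(p.motion_var),
            "noise_sd": p.noise_sd,
        }
        for p in profiles
    ]
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def read_profiles_yaml(path: str | Path) -> tuple[ActivityProfile, ...]:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return tuple(
        ActivityProfile(
            label=p["label"],
            band_powers={k: float(v) for k, v in p["band_powers"].items()},
            box_step_scale=float(p["box_step_scale"]),
            motion_mean=tuple(float(v) for v in p["motion_mean"]),
            motion_var=tuple(float(v) for v in p["motion_var"]),
            noise_sd=float(p.get("noise_sd", 1.0)),
        )
        for p in payload
    )


# ---------------------------------------------------------------------------
# evaluation reports
# ---------------------------------------------------------------------------


class PerClassMetrics(BaseModel):
    precision: float = Field(ge=0, le=1)
    recall: float = Field(ge=0, le=1)
    f1: float = Field(ge=0, le=1)


class Report(BaseModel):
    """Schema for the evaluation report JSON (shipped as report_schema.json)."""

    config: dict
    accuracy: float = Field(ge=0, le=1)
    macro_f1: float = Field(ge=0, le=1)
    labels: list[str]
    confusion: list[list[int]]
    per_class: dict[str, PerClassMetrics]


def report_from_result(result: EvalResult, config: dict) -> Report:
    d = result.to_dict()
    return Report(config=config, **d)


def write_report(result: EvalResult, config: dict, path: str | Path) -> Report:
    report = report_from_result(result, config)
    Path(path).write_text(report.model_dump_json(indent=2))
    return report


def read_report(path: str | Path) -> Report:
    return Report.model_validate_json(Path(path).read_text())
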