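"""Delimited-text serialization of trials, events and reports.

A trial is written as one TSV per channel group (time column + value
columns with axis/unit headers), a JSON manifest (schema version, sampling
rates, file names, seed and config echo) and a TSV ground-truth event table.
All times are serialized as decimal seconds with six fractional digits
(1 microsecond grain, well below the 1 ms sample grid), which makes repeated
runs byte-comparable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ManifestError
from .events import EventSeries, GroundTruthEvents
from .imu import SacralAcc
from .omc import MarkerTrack
from .signal_prep import UniformSignal

SCHEMA_VERSION = 1
_TIME_FMT = "%.6f"

log = logging.getLogger(__name__)

__all__ = ["write_trial", "read_trial_manifest", "write_event_table",
           "read_event_table", "write_ground_truth", "read_ground_truth"]


def _write_tsv(path: Path, time: np.ndarray, columns: dict[str, np.ndarray]) -> None:
    df = pd.DataFrame({"time_s": time, **columns})
    df.to_csv(path, sep="\t", index=False, float_format=_TIME_FMT)


def write_trial(trial, truth: GroundTruthEvents | None, out_dir) -> Path:
    """Write a trial's channel groups + manifest (+ ground truth if given).
    Returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    _write_tsv(out / "grf.tsv", trial.vgrf_left.times(), {
        "vgrf_left_N": trial.vgrf_left.samples,
        "vgrf_right_N": trial.vgrf_right.samples,
        "apgrf_left_N": trial.apgrf_left.samples,
        "apgrf_right_N": trial.apgrf_right.samples,
    })
    _write_tsv(out / "markers.tsv", trial.calcaneus_left.vertical.times(), {
        "cal_left_vert_m": trial.calcaneus_left.vertical.samples,
        "cal_left_ap_m": trial.calcaneus_left.anteroposterior.samples,
        "cal_right_vert_m": trial.calcaneus_right.vertical.samples,
        "cal_right_ap_m": trial.calcaneus_right.anteroposterior.samples,
        "met_left_vert_m": trial.metatarsal_left.vertical.samples,
        "met_left_ap_m": trial.metatarsal_left.anteroposterior.samples,
        "met_right_vert_m": trial.metatarsal_right.vertical.samples,
        "met_right_ap_m": trial.metatarsal_right.anteroposterior.samples,
    })
    _write_tsv(out / "sacral_acc.tsv", trial.sacral_acc.vertical.times(), {
        "acc_vert_ms2": trial.sacral_acc.vertical.samples,
        "acc_ap_ms2": trial.sacral_acc.anteroposterior.samples,
        "acc_ml_ms2": trial.sacral_acc.mediolateral.samples,
    })

    manifest = {
        "schema_version": SCHEMA_VERSION,
        "trial_id": trial.trial_id,
        "fs_grf": trial.vgrf_left.fs,
        "fs_marker": trial.calcaneus_left.fs,
        "fs_imu": trial.sacral_acc.fs,
        "files": {"grf": "grf.tsv", "markers": "markers.tsv",
                  "sacral_acc": "sacral_acc.tsv"},
        "ground_truth": "ground_truth.tsv" if truth is not None else None,
        "config": asdict(trial.config) if trial.config is not None else None,
    }
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    if truth is not None:
        write_ground_truth(truth, out / "ground_truth.tsv")
    return path


def _read_tsv(path: Path) -> pd.DataFrame:
    if not path.exists():
        raise ManifestError(f"missing channel file: {path}")
    return pd.read_csv(path, sep="\t")


def _check_fs(df: pd.DataFrame, fs: float, path: Path) -> None:
    dt = np.diff(df["time_s"].to_numpy())
    if dt.size and abs(np.median(dt) - 1.0 / fs) > 0.01 / fs:
        raise ManifestError(
            f"{path}: time spacing {np.median(dt):.6g}s does not match "
            f"manifest rate {fs} Hz")


def read_trial_manifest(path):
    """Read a trial directory back into (GaitTrial, GroundTruthEvents | None).

    Round-trips timestamps and sample values to within the serialized
    precision (1e-6)."""
    from .synthetic import GaitTrial, SyntheticConfig  # deferred: avoid cycle

    path = Path(path)
    if path.is_dir():
        path = path / "manifest.json"
    if not path.exists():
        raise ManifestError(f"manifest not found: {path}")
    manifest = json.loads(path.read_text())
    if manifest.get("schema_version") != SCHEMA_VERSION:
        raise ManifestError(
            f"unknown manifest schema version {manifest.get('schema_version')!r}")
    base = path.parent

    grf = _read_tsv(base / manifest["files"]["grf"])
    mk = _read_tsv(base / manifest["files"]["markers"])
    acc = _read_tsv(base / manifest["files"]["sacral_acc"])
    fs_grf, fs_mk, fs_imu = (manifest["fs_grf"], manifest["fs_marker"],
                             manifest["fs_imu"])
    for df, fs, name in ((grf, fs_grf, "grf"), (mk, fs_mk, "markers"),
                         (acc, fs_imu, "sacral_acc")):
        _check_fs(df, fs, base / manifest["files"][name])

    t0g = float(grf["time_s"].iloc[0])
    t0m = float(mk["time_s"].iloc[0])
    t0a = float(acc["time_s"].iloc[0])

    def sig(df, col, fs, t0, label):
        return UniformSignal(df[col].to_numpy(), fs, t0, label)

    def track(prefix, marker, foot):
        return MarkerTrack(sig(mk, f"{prefix}_vert_m", fs_mk, t0m, f"{prefix}_vert"),
                           sig(mk, f"{prefix}_ap_m", fs_mk, t0m, f"{prefix}_ap"),
                           marker, foot)

    config = manifest.get("config")
    trial = GaitTrial(
        vgrf_left=sig(grf, "vgrf_left_N", fs_grf, t0g, "vgrf_left"),
        vgrf_right=sig(grf, "vgrf_right_N", fs_grf, t0g, "vgrf_right"),
        apgrf_left=sig(grf, "apgrf_left_N", fs_grf, t0g, "apgrf_left"),
        apgrf_right=sig(grf, "apgrf_right_N", fs_grf, t0g, "apgrf_right"),
        calcaneus_left=track("cal_left", "calcaneus", "left"),
        calcaneus_right=track("cal_right", "calcaneus", "right"),
        metatarsal_left=track("met_left", "metatarsal_1", "left"),
        metatarsal_right=track("met_right", "metatarsal_1", "right"),
        sacral_acc=SacralAcc(sig(acc, "acc_vert_ms2", fs_imu, t0a, "acc_vertical"),
                             sig(acc, "acc_ap_ms2", fs_imu, t0a, "acc_ap"),
                             sig(acc, "acc_ml_ms2", fs_imu, t0a, "acc_ml")),
        config=SyntheticConfig(**config) if config else None,
        trial_id=manifest.get("trial_id", "trial"),
    )
    truth = None
    if manifest.get("ground_truth"):
        truth = read_ground_truth(base / manifest["ground_truth"])
    return trial, truth


# ---------------------------------------------------------------------------
# Event tables


def write_event_table(series_list: list[EventSeries], path) -> None:
    """Write one or more event series to the standard TSV event table
    (columns: method, foot, event_type, time_s)."""
    rows = []
    for s in series_list:
        rows += [(s.method, s.foot, "heel_strike", t) for t in s.heel_strikes]
        rows += [(s.method, s.foot, "toe_off", t) for t in s.toe_offs]
    df = pd.DataFrame(rows, columns=["method", "foot", "event_type", "time_s"])
    df = df.sort_values(["method", "foot", "time_s"], kind="stable")
    df.to_csv(path, sep="\t", index=False, float_format=_TIME_FMT)


def read_event_table(path) -> list[EventSeries]:
    """Read an event table; unsorted rows are sorted with a logged warning."""
    df = pd.read_csv(path, sep="\t")
    required = {"method", "foot", "event_type", "time_s"}
    if not required.issubset(df.columns):
        raise ManifestError(f"{path}: event table must have columns {sorted(required)}")
    out = []
    for (method, foot), grp in df.groupby(["method", "foot"], sort=True):
        hs = grp.loc[grp.event_type == "heel_strike", "time_s"].to_list()
        to = grp.loc[grp.event_type == "toe_off", "time_s"].to_list()
        if hs != sorted(hs) or to != sorted(to):
            log.warning("%s: unsorted rows for %s/%s; sorting", path, method, foot)
            hs, to = sorted(hs), sorted(to)
        out.append(EventSeries(str(method), str(foot), hs, to))
    return out


def write_ground_truth(truth: GroundTruthEvents, path) -> None:
    series = [truth.series("left"), truth.series("right")]
    write_event_table(series, path)


def read_ground_truth(path) -> GroundTruthEvents:
    series = {s.foot: s for s in read_event_table(path)}
    if "left" not in series or "right" not in series:
        raise ManifestError(f"{path}: ground truth must contain both feet")
    return GroundTruthEvents(series["left"].heel_strikes, series["left"].toe_offs,
                             series["right"].heel_strikes, series["right"].toe_offs)
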