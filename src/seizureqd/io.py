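"""Plain-text readers and writers for records, series, and reports.

Multichannel records travel as a delimited text matrix (channels as columns,
header row of labels) with a sidecar annotation CSV (``onset_s, offset_s``).
EDF reading is supported through :mod:`mne` when it is installed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import SvdStatisticSeries
from .information_state import InformationTrajectory
from .qd_policy import DetectionEvent
from .synthetic import LabeledCountSeries, MultichannelRecord


# -- multichannel records ----------------------------------------------------

def write_record(record: MultichannelRecord, samples_path: str | Path,
                 annotations_path: str | Path | None = None) -> None:
    df = pd.DataFrame(record.samples.T, columns=record.channel_labels)
    df.to_csv(samples_path, sep="\t", index=False, float_format="%.10g")
    if annotations_path is not None:
        ann = record.annotations or []
        pd.DataFrame(ann, columns=["onset_s", "offset_s"]).to_csv(
            annotations_path, index=False)


def read_record(samples_path: str | Path, rate: float,
                annotations_path: str | Path | None = None,
                ) -> MultichannelRecord:
    df = pd.read_csv(samples_path, sep="\t")
    annotations = None
    if annotations_path is not None:
        ann = pd.read_csv(annotations_path)
        annotations = list(zip(ann["onset_s"], ann["offset_s"]))
    return MultichannelRecord(df.to_numpy().T, rate, list(df.columns),
                              annotations)


def read_edf(path: str | Path,
             annotations_path: str | Path | None = None) -> MultichannelRecord:
    """Read an EDF recording (requires the optional ``mne`` dependency)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - environment-dependent
        raise ImportError("reading EDF files requires the 'mne' package "
                          "(pip install seizureqd[edf])") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    annotations = None
    if annotations_path is not None:
        ann = pd.read_csv(annotations_path)
        annotations = list(zip(ann["onset_s"], ann["offset_s"]))
    return MultichannelRecord(raw.get_data(), raw.info["sfreq"],
                              list(raw.ch_names), annotations)


# -- count series ------------------------------------------------------------

def write_counts(series: LabeledCountSeries, path: str | Path) -> None:
    pd.DataFrame({"k": np.arange(len(series)), "n_k": series.counts,
                  "x_k": series.states}).to_csv(path, index=False)


def read_counts(path: str | Path) -> LabeledCountSeries:
    df = pd.read_csv(path)
    return LabeledCountSeries(df["n_k"].to_numpy(), df["x_k"].to_numpy())


# -- statistic series, trajectories, detections ------------------------------

def write_sigma_series(stats: SvdStatisticSeries, path: str | Path) -> None:
    data = {"k_s": stats.times_s, "sigma1": stats.sigma1}
    for i in range(stats.v1.shape[1]):
        data[f"v1_{i + 1}"] = stats.v1[:, i]
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.10g")


def write_trajectory(traj: InformationTrajectory, path: str | Path) -> None:
    restarted = np.zeros(len(traj.pi), dtype=int)
    restarted[list(traj.restart_indices)] = 1
    pd.DataFrame({"k_s": np.arange(len(traj.pi)), "pi": traj.pi,
                  "L_k": traj.likelihood_ratios,
                  "restarted_flag": restarted}).to_csv(
        path, index=False, float_format="%.10g")


def write_detections(detections, path: str | Path) -> None:
    """Detections to CSV; accepts DetectionEvent lists or plain time lists."""
    rows = []
    for d in detections:
        if isinstance(d, DetectionEvent):
            rows.append({"t_s": float(d.stage), "pi": d.pi_at_detection,
                         "policy_id": d.policy_id})
        else:
            rows.append({"t_s": float(d), "pi": np.nan, "policy_id": ""})
    pd.DataFrame(rows, columns=["t_s", "pi", "policy_id"]).to_csv(
        path, index=False)


def read_detection_times(path: str | Path) -> list[float]:
    return pd.read_csv(path)["t_s"].tolist()


def write_json(doc: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(doc, indent=2, default=float) + "\n")
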