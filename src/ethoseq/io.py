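"""On-disk formats: HDF5 sessions/scores/labels, CSV manifests, JSON models,
GraphML networks, Newick dendrograms, EDF reading.

HDF5 is the native container for array-heavy artifacts; small structured
results (models, ground truth, manifests) go to JSON/CSV so runs stay
reviewable with a text editor.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import networkx as nx
import numpy as np
import pandas as pd

from .types import ARHMMModel, EEGRecording, GroundTruth, PCAModel, PoseSession, RippleEvent

__all__ = [
    "save_sessions",
    "load_sessions",
    "save_cohort_manifest",
    "save_scores",
    "load_scores",
    "save_model_json",
    "load_model_json",
    "save_pca_json",
    "load_pca_json",
    "save_labels",
    "load_labels",
    "save_eeg",
    "load_eeg",
    "read_eeg_edf",
    "save_ground_truth",
    "load_ground_truth",
    "save_graphml",
    "events_to_frame",
]


def save_sessions(path: str | Path, sessions: list[PoseSession]) -> None:
    with h5py.File(path, "w") as f:
        for i, s in enumerate(sessions):
            g = f.create_group(f"session_{i:03d}")
            g.create_dataset("features", data=s.features)
            g.create_dataset("valid_mask", data=s.valid_mask)
            g.attrs["animal_id"] = s.animal_id
            g.attrs["genotype"] = s.genotype
            g.attrs["fps"] = s.fps
            g.attrs["session_minutes"] = s.session_minutes


def load_sessions(path: str | Path) -> list[PoseSession]:
    out = []
    with h5py.File(path, "r") as f:
        for key in sorted(f.keys()):
            g = f[key]
            out.append(
                PoseSession(
                    animal_id=str(g.attrs["animal_id"]),
                    genotype=str(g.attrs["genotype"]),
                    fps=float(g.attrs["fps"]),
                    features=g["features"][()],
                    valid_mask=g["valid_mask"][()],
                    session_minutes=float(g.attrs["session_minutes"]),
                )
            )
    return out


def save_cohort_manifest(path: str | Path, sessions: list[PoseSession], files: list[str] | None = None) -> None:
    df = pd.DataFrame(
        {
            "animal_id": [s.animal_id for s in sessions],
            "genotype": [s.genotype for s in sessions],
            "file": files if files is not None else [""] * len(sessions),
        }
    )
    df.to_csv(path, index=False)


def save_scores(path: str | Path, scores: list[np.ndarray], masks: list[np.ndarray]) -> None:
    with h5py.File(path, "w") as f:
        for i, (x, m) in enumerate(zip(scores, masks)):
            g = f.create_group(f"session_{i:03d}")
            g.create_dataset("scores", data=np.asarray(x))
            g.create_dataset("valid_mask", data=np.asarray(m, dtype=bool))


def load_scores(path: str | Path) -> tuple[list[np.ndarray], list[np.ndarray]]:
    scores, masks = [], []
    with h5py.File(path, "r") as f:
        for key in sorted(f.keys()):
            scores.append(f[key]["scores"][()])
            masks.append(f[key]["valid_mask"][()])
    return scores, masks


def save_model_json(path: str | Path, model: ARHMMModel) -> None:
    payload = {
        "ar_coefs": model.ar_coefs.tolist(),
        "intercepts": model.intercepts.tolist(),
        "covariances": model.covariances.tolist(),
        "transition_matrix": model.transition_matrix.tolist(),
        "initial_distribution": model.initial_distribution.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def load_model_json(path: str | Path) -> ARHMMModel:
    d = json.loads(Path(path).read_text())
    return ARHMMModel(
        ar_coefs=np.asarray(d["ar_coefs"]),
        intercepts=np.asarray(d["intercepts"]),
        covariances=np.asarray(d["covariances"]),
        transition_matrix=np.asarray(d["transition_matrix"]),
        initial_distribution=np.asarray(d["initial_distribution"]),
    )


def save_pca_json(path: str | Path, model: PCAModel) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "mean": model.mean.tolist(),
                "loadings": model.loadings.tolist(),
                "explained_variance": model.explained_variance.tolist(),
            }
        )
    )


def load_pca_json(path: str | Path) -> PCAModel:
    d = json.loads(Path(path).read_text())
    return PCAModel(
        mean=np.asarray(d["mean"]),
        loadings=np.asarray(d["loadings"]),
        explained_variance=np.asarray(d["explained_variance"]),
    )


def save_labels(path: str | Path, labels_per_session: list[np.ndarray], key: str = "labels") -> None:
    with h5py.File(path, "w") as f:
        for i, lb in enumerate(labels_per_session):
            f.create_dataset(f"session_{i:03d}/{key}", data=np.asarray(lb, dtype=np.int64))


def load_labels(path: str | Path, key: str = "labels") -> list[np.ndarray]:
    out = []
    with h5py.File(path, "r") as f:
        for k in sorted(f.keys()):
            out.append(f[k][key][()])
    return out


def save_eeg(path: str | Path, rec: EEGRecording) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("samples", data=rec.samples)
        f.attrs["fs"] = rec.fs
        f.attrs["antialias_lowpass"] = rec.antialias_lowpass
        f.attrs["channel_names"] = [n.encode() for n in rec.channel_names]


def load_eeg(path: str | Path) -> EEGRecording:
    with h5py.File(path, "r") as f:
        names = [n.decode() if isinstance(n, bytes) else str(n) for n in f.attrs["channel_names"]]
        return EEGRecording(
            channel_names=names,
            samples=f["samples"][()],
            fs=float(f.attrs["fs"]),
            antialias_lowpass=float(f.attrs["antialias_lowpass"]),
        )


def read_eeg_edf(path: str | Path) -> EEGRecording:
    """Read an EDF recording (channel labels preserved). Requires mne."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> microvolts
    return EEGRecording(channel_names=list(raw.ch_names), samples=data, fs=float(raw.info["sfreq"]))


def save_ground_truth(path: str | Path, truths: list[GroundTruth]) -> None:
    payload = []
    for gt in truths:
        payload.append(
            {
                "states": gt.states.tolist() if gt.states is not None else None,
                "events": [
                    {
                        "channel": e.channel,
                        "start": e.start,
                        "end": e.end,
                        "n_oscillations": e.n_oscillations,
                        "peak_amplitude_ratio": e.peak_amplitude_ratio,
                        "frequency_hz": e.frequency_hz,
                    }
                    for e in gt.events
                ],
            }
        )
    Path(path).write_text(json.dumps(payload))


def load_ground_truth(path: str | Path) -> list[GroundTruth]:
    raw = json.loads(Path(path).read_text())
    out = []
    for d in raw:
        events = [RippleEvent(**e) for e in d["events"]]
        states = None if d["states"] is None else np.asarray(d["states"], dtype=np.int64)
        out.append(GroundTruth(states=states, events=events))
    return out


def save_graphml(path: str | Path, graph: nx.DiGraph) -> None:
    nx.write_graphml(graph, str(path))


def events_to_frame(events: list[RippleEvent], fs: float) -> pd.DataFrame:
    """Event list as a table (channel, start s, end s, oscillations, ratio)."""
    return pd.DataFrame(
        {
            "channel": [e.channel for e in events],
            "start_s": [e.start / fs for e in events],
            "end_s": [e.end / fs for e in events],
            "n_oscillations": [e.n_oscillations for e in events],
            "peak_amplitude_ratio": [e.peak_amplitude_ratio for e in events],
            "frequency_hz": [e.frequency_hz for e in events],
        }
    )
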