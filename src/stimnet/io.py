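"""File formats.

* Recordings: an HDF5 container (datasets ``/samples``, ``/fs``,
  ``/labels``) with a JSON sidecar carrying fs, labels and montage — this
  round-trips bit-exactly. EDF is supported read-only (EDF quantizes to 16
  bits); reading goes through MNE.
* Electrode layouts and stimulation event tables: UTF-8 TSV.
* Adjacency matrices: TSV with labels as header.
* Synthetic studies: one HDF5 file plus a JSON sidecar holding the ground
  truth for test harnesses.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .connectivity import AdjacencyMatrix
from .recording import ElectrodeLayout, Recording, StimSession
from .synthetic import GroundTruth, SyntheticStudy

__all__ = [
    "read_recording",
    "write_recording",
    "read_layout",
    "write_layout",
    "read_events",
    "write_events",
    "read_adjacency",
    "write_adjacency",
    "save_study",
    "load_study",
]

LAYOUT_COLUMNS = [
    "label", "x_mm", "y_mm", "z_mm", "soz", "spiking",
    "wm_distance_mm", "in_wm", "contact_a", "contact_b",
]
EVENT_COLUMNS = ["onset_s", "amplitude_mA", "pulse_hz"]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_recording(recording: Recording, path, format: str = "container") -> None:
    """Write a recording; only the HDF5 container format is writable."""
    if format != "container":
        raise ValueError(f"writing format {format!r} is not supported (container only)")
    if recording.n_channels == 0:
        raise ValueError("refusing to write a recording with zero channels")
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("samples", data=recording.samples)
        f.create_dataset("fs", data=float(recording.fs))
        f.create_dataset(
            "labels", data=np.array(recording.labels, dtype=h5py.string_dtype())
        )
        f.attrs["montage"] = recording.montage
    sidecar = {
        "fs": recording.fs,
        "labels": recording.labels,
        "montage": recording.montage,
        "n_channels": recording.n_channels,
        "n_samples": recording.n_samples,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))


def read_recording(path, format: str = "container") -> Recording:
    """Read a recording from the HDF5 container or an EDF file.

    EDF values are converted to microvolts; expect agreement with the
    source only to within one 16-bit quantization step.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if format == "container":
        with h5py.File(path, "r") as f:
            samples = f["samples"][()]
            fs = float(f["fs"][()])
            labels = [
                s.decode() if isinstance(s, bytes) else str(s) for s in f["labels"][()]
            ]
            montage = f.attrs.get("montage", "monopolar")
        return Recording(samples, fs, labels, montage=str(montage))
    if format == "edf":
        import mne

        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
        return Recording(
            raw.get_data() * 1e6,  # MNE loads volts; analysis runs in microvolts
            float(raw.info["sfreq"]),
            list(raw.ch_names),
            montage="monopolar",
        )
    raise ValueError(f"unknown format {format!r}")


def write_layout(layout: ElectrodeLayout, path) -> None:
    members = layout.contact_members or [(lab, lab) for lab in layout.labels]
    df = pd.DataFrame(
        {
            "label": layout.labels,
            "x_mm": layout.coordinates[:, 0],
            "y_mm": layout.coordinates[:, 1],
            "z_mm": layout.coordinates[:, 2],
            "soz": layout.soz.astype(int),
            "spiking": layout.spiking.astype(int),
            "wm_distance_mm": layout.wm_distance,
            "in_wm": layout.in_wm.astype(int),
            "contact_a": [m[0] for m in members],
            "contact_b": [m[1] for m in members],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_layout(path) -> ElectrodeLayout:
    df = pd.read_csv(path, sep="\t", dtype={"label": str, "contact_a": str, "contact_b": str})
    missing = set(LAYOUT_COLUMNS[:8]) - set(df.columns)
    if missing:
        raise ValueError(f"layout table missing columns: {sorted(missing)}")
    members = None
    if {"contact_a", "contact_b"} <= set(df.columns):
        members = list(zip(df["contact_a"], df["contact_b"]))
    return ElectrodeLayout(
        labels=list(df["label"]),
        coordinates=df[["x_mm", "y_mm", "z_mm"]].to_numpy(float),
        soz=df["soz"].to_numpy(bool),
        spiking=df["spiking"].to_numpy(bool),
        wm_distance=df["wm_distance_mm"].to_numpy(float),
        in_wm=df["in_wm"].to_numpy(bool),
        contact_members=members,
    )


def write_events(session: StimSession, path) -> None:
    pd.DataFrame(
        {
            "onset_s": session.onsets,
            "amplitude_mA": session.amplitudes,
            "pulse_hz": session.pulse_freqs,
        }
    ).to_csv(path, sep="\t", index=False)


def read_events(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"event table missing columns: {sorted(missing)}")
    return df


def write_adjacency(adj: AdjacencyMatrix, path) -> None:
    labels = adj.labels or [str(i) for i in range(adj.n_nodes)]
    df = pd.DataFrame(adj.values, index=labels, columns=labels)
    with open(path, "w", encoding="utf-8") as f:
        band = adj.band if adj.band is not None else ""
        f.write(f"# method={adj.method}\tband={band}\tn_windows={adj.n_windows}\n")
        df.to_csv(f, sep="\t")


def read_adjacency(path) -> AdjacencyMatrix:
    with open(path, encoding="utf-8") as f:
        header = f.readline()
        meta = dict(
            item.split("=", 1) for item in header.lstrip("# ").rstrip("\n").split("\t")
        )
        df = pd.read_csv(f, sep="\t", index_col=0)
    band: tuple[float, float] | float | None
    raw_band = meta.get("band", "")
    if raw_band == "":
        band = None
    elif raw_band.startswith("("):
        band = tuple(float(x) for x in raw_band.strip("()").split(","))
    else:
        band = float(raw_band)
    values = df.to_numpy(float)
    values = np.where(np.isnan(values), np.nan, (values + values.T) / 2)
    return AdjacencyMatrix(
        values,
        method=meta["method"],
        band=band,
        n_windows=int(meta.get("n_windows", 0)),
        labels=list(df.index.astype(str)),
    )


def _write_session(group: h5py.Group, session: StimSession) -> None:
    for name in ("pre", "post", "pre_art", "post_art", "onsets", "amplitudes", "pulse_freqs"):
        group.create_dataset(name, data=getattr(session, name))
    group.attrs["stim_pair"] = json.dumps(list(session.stim_pair))
    group.attrs["stim_duration"] = session.stim_duration
    group.attrs["fs"] = session.fs
    group.create_dataset(
        "labels", data=np.array(session.labels, dtype=h5py.string_dtype())
    )


def _read_session(group: h5py.Group) -> StimSession:
    labels = [s.decode() if isinstance(s, bytes) else str(s) for s in group["labels"][()]]
    return StimSession(
        stim_pair=tuple(json.loads(group.attrs["stim_pair"])),
        onsets=group["onsets"][()],
        stim_duration=float(group.attrs["stim_duration"]),
        amplitudes=group["amplitudes"][()],
        pulse_freqs=group["pulse_freqs"][()],
        fs=float(group.attrs["fs"]),
        labels=labels,
        pre=group["pre"][()],
        post=group["post"][()],
        pre_art=group["pre_art"][()],
        post_art=group["post_art"][()],
    )


def _truth_to_json(truth: GroundTruth) -> dict:
    d = dataclasses.asdict(truth)
    for k, v in d.items():
        if isinstance(v, np.ndarray):
            d[k] = v.tolist()
    d["artifact_channels"] = list(truth.artifact_channels)
    return d


def _truth_from_json(d: dict) -> GroundTruth:
    d = dict(d)
    d["mixing_weights"] = np.asarray(d["mixing_weights"], dtype=float)
    d["source_freqs"] = np.asarray(d["source_freqs"], dtype=float)
    if d.get("envelope_coupling") is not None:
        d["envelope_coupling"] = np.asarray(d["envelope_coupling"], dtype=float)
    d["artifact_channels"] = tuple(d.get("artifact_channels", ()))
    return GroundTruth(**d)


def save_study(study: SyntheticStudy, path) -> None:
    """Persist a synthetic study: HDF5 container + JSON ground-truth sidecar."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        base = f.create_group("baseline")
        base.create_dataset("samples", data=study.baseline.samples)
        base.attrs["fs"] = study.baseline.fs
        base.attrs["montage"] = study.baseline.montage
        base.create_dataset(
            "labels", data=np.array(study.baseline.labels, dtype=h5py.string_dtype())
        )
        lay = f.create_group("layout")
        lay.create_dataset("coordinates", data=study.layout.coordinates)
        lay.create_dataset("soz", data=study.layout.soz)
        lay.create_dataset("spiking", data=study.layout.spiking)
        lay.create_dataset("wm_distance", data=study.layout.wm_distance)
        lay.create_dataset("in_wm", data=study.layout.in_wm)
        lay.create_dataset(
            "labels", data=np.array(study.layout.labels, dtype=h5py.string_dtype())
        )
        members = study.layout.contact_members or []
        lay.attrs["contact_members"] = json.dumps([list(m) for m in members])
        sess = f.create_group("sessions")
        for i, s in enumerate(study.sessions):
            _write_session(sess.create_group(str(i)), s)
        for name, adj in (("coherence", study.coherence), ("distance", study.distance)):
            if adj is not None:
                g = f.create_group(f"adjacency/{name}")
                g.create_dataset("values", data=adj.values)
                g.attrs["method"] = adj.method
                g.attrs["band"] = json.dumps(adj.band)
                g.attrs["n_windows"] = adj.n_windows
    _sidecar_path(path).write_text(
        json.dumps({"truth": _truth_to_json(study.truth)}, indent=1)
    )


def load_study(path) -> SyntheticStudy:
    path = Path(path)
    sidecar = json.loads(_sidecar_path(path).read_text())
    truth = _truth_from_json(sidecar["truth"])
    with h5py.File(path, "r") as f:
        base = f["baseline"]
        labels = [
            s.decode() if isinstance(s, bytes) else str(s) for s in base["labels"][()]
        ]
        baseline = Recording(
            base["samples"][()], float(base.attrs["fs"]), labels,
            montage=str(base.attrs["montage"]),
        )
        lay = f["layout"]
        lay_labels = [
            s.decode() if isinstance(s, bytes) else str(s) for s in lay["labels"][()]
        ]
        members_raw = json.loads(lay.attrs["contact_members"])
        layout = ElectrodeLayout(
            labels=lay_labels,
            coordinates=lay["coordinates"][()],
            soz=lay["soz"][()],
            spiking=lay["spiking"][()],
            wm_distance=lay["wm_distance"][()],
            in_wm=lay["in_wm"][()],
            contact_members=[tuple(m) for m in members_raw] or None,
        )
        sessions = [
            _read_session(f["sessions"][k])
            for k in sorted(f["sessions"], key=int)
        ]
        adjs = {}
        if "adjacency" in f:
            for name in f["adjacency"]:
                g = f[f"adjacency/{name}"]
                band = json.loads(g.attrs["band"])
                adjs[name] = AdjacencyMatrix(
                    g["values"][()],
                    method=str(g.attrs["method"]),
                    band=tuple(band) if isinstance(band, list) else band,
                    n_windows=int(g.attrs["n_windows"]),
                    labels=lay_labels,
                )
    return SyntheticStudy(
        layout=layout,
        baseline=baseline,
        sessions=sessions,
        truth=truth,
        coherence=adjs.get("coherence"),
        distance=adjs.get("distance"),
    )
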