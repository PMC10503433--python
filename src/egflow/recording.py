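"""Multichannel electrogram containers and file I/O.

The on-disk container is a small HDF5 layout::

    /signals            float64, (64, n_samples), mV, row order = /labels
    /labels             fixed-length ASCII channel labels ("A1".."H8")
    /ventricular_times  optional float64 (s), QRS onsets for far-field blanking
    /aux_bipolar/<name> optional float64 bipolar traces, mV
    /pacing             optional table (time_s, site, output_class)
    attrs: sampling_rate_hz

A plain CSV reader/writer (one column per channel, header = labels) exists for
text fixtures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .geometry import BasketGeometry, label_to_grid

__all__ = [
    "PacingEvent",
    "EGMRecording",
    "RecordingError",
    "IncompleteBasketError",
    "read_recording",
    "write_recording",
    "read_recording_csv",
    "write_recording_csv",
]

PACING_OUTPUT_CLASSES = ("subthreshold", "threshold", "high")


class RecordingError(ValueError):
    """Malformed or inconsistent recording data."""


class IncompleteBasketError(RecordingError):
    """The file does not contain all 64 basket channels."""


@dataclass(frozen=True)
class PacingEvent:
    """One pacing annotation: onset time, basket-grid site label, output class."""

    time_s: float
    site: str
    output_class: str

    def __post_init__(self) -> None:
        if self.output_class not in PACING_OUTPUT_CLASSES:
            raise ValueError(
                f"unknown pacing output class {self.output_class!r}; "
                f"expected one of {PACING_OUTPUT_CLASSES}"
            )


@dataclass
class EGMRecording:
    """A unipolar basket recording plus optional bipolar channels and annotations.

    ``signals`` is (64, n_samples) in mV with rows ordered as ``channel_labels``.
    """

    signals: np.ndarray
    sampling_rate: float
    channel_labels: list[str]
    aux_bipolar: dict[str, np.ndarray] = field(default_factory=dict)
    pacing_annotations: list[PacingEvent] = field(default_factory=list)
    ventricular_times: np.ndarray | None = None
    geometry: BasketGeometry = field(default_factory=BasketGeometry)

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        if self.signals.ndim != 2:
            raise RecordingError("signals must be a 2-D (channels, samples) array")
        n_exp = self.geometry.n_splines * self.geometry.n_electrodes_per_spline
        if self.signals.shape[0] != n_exp or len(self.channel_labels) != n_exp:
            raise IncompleteBasketError(
                f"incomplete basket: expected {n_exp} unipolar channels, "
                f"got {self.signals.shape[0]} signals / {len(self.channel_labels)} labels"
            )
        for lab in self.channel_labels:
            label_to_grid(lab)  # raises on malformed labels
        if len(set(self.channel_labels)) != n_exp:
            raise RecordingError("duplicate channel labels")
        for name, sig in self.aux_bipolar.items():
            self.aux_bipolar[name] = np.asarray(sig, dtype=float)
        if self.sampling_rate <= 0:
            raise RecordingError("sampling rate must be positive")
        if self.ventricular_times is not None:
            self.ventricular_times = np.asarray(self.ventricular_times, dtype=float)
        if self.duration < 60.0:
            warnings.warn(
                f"recording is {self.duration:.1f} s; summary-map analyses "
                "canonically use >= 60 s",
                stacklevel=2,
            )

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def channel(self, label: str) -> np.ndarray:
        """Return one unipolar trace by basket label."""
        try:
            idx = self.channel_labels.index(str(label).strip().upper())
        except ValueError:
            raise KeyError(f"no channel labelled {label!r}") from None
        return self.signals[idx]

    def channel_index(self, label: str) -> int:
        return self.channel_labels.index(str(label).strip().upper())

    def grid_signals(self) -> np.ndarray:
        """Signals reshaped to (8 splines, 8 electrodes, n_samples)."""
        order = np.empty((8, 8), dtype=int)
        for i, lab in enumerate(self.channel_labels):
            loc = label_to_grid(lab)
            order[loc.row, loc.col] = i
        return self.signals[order]


def write_recording(recording: EGMRecording, path: str | Path) -> None:
    """Write a recording to the HDF5 container; lossless round-trip."""
    with h5py.File(path, "w") as f:
        f.create_dataset("signals", data=recording.signals)
        f.create_dataset(
            "labels",
            data=np.array(recording.channel_labels, dtype=h5py.string_dtype("ascii")),
        )
        f.attrs["sampling_rate_hz"] = float(recording.sampling_rate)
        if recording.ventricular_times is not None:
            f.create_dataset("ventricular_times", data=recording.ventricular_times)
        if recording.aux_bipolar:
            g = f.create_group("aux_bipolar")
            for name, sig in recording.aux_bipolar.items():
                g.create_dataset(name, data=sig)
        if recording.pacing_annotations:
            dt = np.dtype(
                [("time_s", "f8"), ("site", "S8"), ("output_class", "S16")]
            )
            tab = np.array(
                [
                    (ev.time_s, ev.site.encode(), ev.output_class.encode())
                    for ev in recording.pacing_annotations
                ],
                dtype=dt,
            )
            f.create_dataset("pacing", data=tab)


def read_recording(path: str | Path) -> EGMRecording:
    """Read a recording from the HDF5 container written by :func:`write_recording`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with h5py.File(path, "r") as f:
        if "signals" not in f or "labels" not in f:
            raise RecordingError(f"{path}: missing /signals or /labels dataset")
        if "sampling_rate_hz" not in f.attrs:
            raise RecordingError(f"{path}: missing sampling_rate_hz attribute")
        rate = float(f.attrs["sampling_rate_hz"])
        signals = f["signals"][...]
        labels = [
            s.decode() if isinstance(s, bytes) else str(s) for s in f["labels"][...]
        ]
        if signals.shape[0] != len(labels):
            raise RecordingError(f"{path}: signals/labels channel-count mismatch")
        vt = f["ventricular_times"][...] if "ventricular_times" in f else None
        aux = {}
        if "aux_bipolar" in f:
            for name, ds in f["aux_bipolar"].items():
                aux[name] = ds[...]
        pacing = []
        if "pacing" in f:
            for rec in f["pacing"][...]:
                pacing.append(
                    PacingEvent(
                        time_s=float(rec["time_s"]),
                        site=rec["site"].decode(),
                        output_class=rec["output_class"].decode(),
                    )
                )
    return EGMRecording(
        signals=signals,
        sampling_rate=rate,
        channel_labels=labels,
        aux_bipolar=aux,
        pacing_annotations=pacing,
        ventricular_times=vt,
    )


def write_recording_csv(recording: EGMRecording, path: str | Path) -> None:
    """Text-fixture writer: one column per channel, header = labels."""
    df = pd.DataFrame(recording.signals.T, columns=recording.channel_labels)
    df.to_csv(path, index=False)


def read_recording_csv(path: str | Path, sampling_rate: float) -> EGMRecording:
    """Text-fixture reader; carries no annotations."""
    df = pd.read_csv(path)
    return EGMRecording(
        signals=df.to_numpy().T,
        sampling_rate=sampling_rate,
        channel_labels=[str(c) for c in df.columns],
    )
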