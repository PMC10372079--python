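"""Recording-session data model and HDF5 container I/O.

A :class:`Session` ties together multichannel LFP (microvolts), per-channel
anatomical metadata, sorted spike units, an optional 3-axis head accelerometer
trace (g) and drug/injection metadata.  Time is in seconds, float64, with t=0
at the start of the recording; the injection time is stored explicitly and
analysis epochs are expressed relative to it.

Container layout (single HDF5 file)::

    /lfp/data      float32, channels x samples, microvolts
    /lfp/fs        Hz
    /channels      table: channel_id, structure, hemisphere, electrode_group,
                   ap, ml, dv (mm; NaN when unknown)
    /units/<uid>/spike_times   seconds
    /units/<uid>/electrode     channel_id
    /units/<uid>/waveform      float32, microvolts (optional)
    /units/<uid>/wf_fs         Hz (optional)
    /accel/data    3 x samples, g (optional; rows = AP, ML, DV)
    /accel/fs      Hz
    attributes: drug, drug_class, injection_time
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import h5py
import numpy as np

__all__ = [
    "ChannelMeta",
    "SpikeUnit",
    "Session",
    "Epoch",
    "BipolarSeries",
    "BASELINE_EPOCH",
    "DRUG_EPOCH",
    "read_session",
    "write_session",
    "make_bipolar",
    "slice_epoch",
    "SessionFormatError",
]

DRUGS = {"LSD", "DOI", "ketamine", "PCP", "amphetamine", "none"}
DRUG_CLASSES = {"5HT2A", "NMDA", "amphetamine", "baseline-only"}

# Accelerometer row convention: 0 = anteroposterior, 1 = mediolateral, 2 = dorsoventral
ACCEL_ML_AXIS = 1


class SessionFormatError(Exception):
    """Raised when a container is missing required datasets."""


@dataclass
class ChannelMeta:
    channel_id: int
    structure: str
    hemisphere: str = "left"
    electrode_group: int = 0
    coords: Optional[tuple] = None  # (AP, ML, DV) in mm


@dataclass
class SpikeUnit:
    unit_id: str
    spike_times: np.ndarray  # seconds, sorted
    electrode: int
    structure: str = ""
    waveform: Optional[np.ndarray] = None  # microvolts
    wf_fs: Optional[float] = None
    cell_type: str = "unset"  # {"PC", "IN", "X", "unset"}


@dataclass
class Epoch:
    """Analysis window in seconds relative to the injection time.

    Defaults follow the convention of averaging -35 to -5 min pre-injection
    for baseline and 30 to 60 min post-injection for the drug period.
    """

    name: str
    start: float
    end: float

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError("epoch start must precede end")


BASELINE_EPOCH = Epoch("baseline", -35 * 60.0, -5 * 60.0)
DRUG_EPOCH = Epoch("drug", 30 * 60.0, 60 * 60.0)


@dataclass
class BipolarSeries:
    pair: tuple
    structure: str
    series: np.ndarray  # microvolts, (channel a) - (channel b)


@dataclass
class Session:
    lfp: np.ndarray  # channels x samples, microvolts
    fs_lfp: float
    channels: list
    units: list = field(default_factory=list)
    accel: Optional[np.ndarray] = None  # 3 x samples, g
    fs_accel: Optional[float] = None
    injection_time: Optional[float] = None  # seconds from recording start
    drug: str = "none"
    drug_class: str = "baseline-only"

    def __post_init__(self):
        self.lfp = np.asarray(self.lfp)
        if self.lfp.ndim != 2:
            raise ValueError("lfp must be channels x samples")
        if self.lfp.shape[0] != len(self.channels):
            raise ValueError(
                f"channel table lists {len(self.channels)} channels but LFP has "
                f"{self.lfp.shape[0]} rows"
            )
        if self.fs_lfp <= 0:
            raise ValueError("fs_lfp must be positive")
        ids = [c.channel_id for c in self.channels]
        if len(set(ids)) != len(ids):
            raise ValueError("channel_id values must be unique")
        dur = self.duration
        for u in self.units:
            if len(u.spike_times) and (u.spike_times[-1] > dur or u.spike_times[0] < 0):
                raise ValueError(f"unit {u.unit_id} has spike times outside the recording")
        if self.injection_time is not None and not (0 <= self.injection_time <= dur):
            raise ValueError("injection_time outside recording duration")

    @property
    def duration(self) -> float:
        return self.lfp.shape[1] / self.fs_lfp

    @property
    def structures(self):
        seen = []
        for c in self.channels:
            if c.structure not in seen:
                seen.append(c.structure)
        return seen

    def channels_in(self, structure: str):
        return [c for c in self.channels if c.structure == structure]

    def lfp_channel(self, channel_id: int) -> np.ndarray:
        for row, c in enumerate(self.channels):
            if c.channel_id == channel_id:
                return self.lfp[row]
        raise KeyError(f"no channel with id {channel_id}")


_CHANNEL_DTYPE = np.dtype(
    [
        ("channel_id", "i8"),
        ("structure", "S32"),
        ("hemisphere", "S8"),
        ("electrode_group", "i8"),
        ("ap", "f8"),
        ("ml", "f8"),
        ("dv", "f8"),
    ]
)


def write_session(session: Session, path) -> None:
    """Write a session to the HDF5 container layout documented above."""
    with h5py.File(path, "w") as f:
        g = f.create_group("lfp")
        g.create_dataset("data", data=session.lfp.astype(np.float32))
        g.create_dataset("fs", data=float(session.fs_lfp))
        table = np.zeros(len(session.channels), dtype=_CHANNEL_DTYPE)
        for i, c in enumerate(session.channels):
            coords = c.coords if c.coords is not None else (np.nan, np.nan, np.nan)
            table[i] = (
                c.channel_id,
                c.structure.encode(),
                c.hemisphere.encode(),
                c.electrode_group,
                coords[0],
                coords[1],
                coords[2],
            )
        f.create_dataset("channels", data=table)
        if session.units:
            ug = f.create_group("units")
            for u in session.units:
                gu = ug.create_group(str(u.unit_id))
                gu.create_dataset("spike_times", data=np.asarray(u.spike_times, float))
                gu.create_dataset("electrode", data=int(u.electrode))
                if u.waveform is not None:
                    gu.create_dataset("waveform", data=u.waveform.astype(np.float32))
                    gu.create_dataset("wf_fs", data=float(u.wf_fs))
        if session.accel is not None:
            ga = f.create_group("accel")
            ga.create_dataset("data", data=session.accel.astype(np.float32))
            ga.create_dataset("fs", data=float(session.fs_accel))
        f.attrs["drug"] = session.drug
        f.attrs["drug_class"] = session.drug_class
        if session.injection_time is not None:
            f.attrs["injection_time"] = float(session.injection_time)


def read_session(path) -> Session:
    """Read a session container; optional blocks (units, accel) are tolerated."""
    with h5py.File(path, "r") as f:
        for key in ("lfp", "channels"):
            if key not in f:
                raise SessionFormatError(f"container missing required dataset '/{key}'")
        if "data" not in f["lfp"] or "fs" not in f["lfp"]:
            raise SessionFormatError("container missing '/lfp/data' or '/lfp/fs'")
        lfp = f["lfp/data"][()].astype(np.float64)
        fs = float(f["lfp/fs"][()])
        if fs <= 0:
            raise ValueError("fs_lfp must be positive")
        channels = []
        for row in f["channels"][()]:
            coords = (row["ap"], row["ml"], row["dv"])
            channels.append(
                ChannelMeta(
                    channel_id=int(row["channel_id"]),
                    structure=row["structure"].decode(),
                    hemisphere=row["hemisphere"].decode(),
                    electrode_group=int(row["electrode_group"]),
                    coords=None if np.all(np.isnan(coords)) else tuple(float(x) for x in coords),
                )
            )
        struct_of = {c.channel_id: c.structure for c in channels}
        units = []
        if "units" in f:
            for uid in sorted(f["units"]):
                gu = f["units"][uid]
                electrode = int(gu["electrode"][()])
                units.append(
                    SpikeUnit(
                        unit_id=uid,
                        spike_times=gu["spike_times"][()].astype(np.float64),
                        electrode=electrode,
                        structure=struct_of.get(electrode, ""),
                        waveform=gu["waveform"][()].astype(np.float64) if "waveform" in gu else None,
                        wf_fs=float(gu["wf_fs"][()]) if "wf_fs" in gu else None,
                    )
                )
        accel = fs_accel = None
        if "accel" in f:
            accel = f["accel/data"][()].astype(np.float64)
            fs_accel = float(f["accel/fs"][()])
        injection = float(f.attrs["injection_time"]) if "injection_time" in f.attrs else None
        return Session(
            lfp=lfp,
            fs_lfp=fs,
            channels=channels,
            units=units,
            accel=accel,
            fs_accel=fs_accel,
            injection_time=injection,
            drug=str(f.attrs.get("drug", "none")),
            drug_class=str(f.attrs.get("drug_class", "baseline-only")),
        )


def make_bipolar(session: Session, structure: str):
    """All unique same-structure electrode pairs as bipolar derivations.

    Differencing nearby electrodes cancels distant/common sources so that the
    surviving signal is locally generated.  Sign convention: (lower
    channel_id) - (higher channel_id).  Fewer than two channels yields an
    empty list.
    """
    chans = sorted(session.channels_in(structure), key=lambda c: c.channel_id)
    out = []
    for a, b in combinations(chans, 2):
        series = session.lfp_channel(a.channel_id) - session.lfp_channel(b.channel_id)
        out.append(BipolarSeries(pair=(a.channel_id, b.channel_id), structure=structure, series=series))
    return out


def slice_epoch(data, injection_time: float, epoch: Epoch, fs: Optional[float] = None):
    """Restrict a signal or spike-time array to an epoch window.

    With ``fs`` given, ``data`` is a sampled series (last axis = time) starting
    at t=0 and a slice of samples with centers in
    ``[injection_time + epoch.start, injection_time + epoch.end)`` is returned.
    Without ``fs``, ``data`` is an array of spike times (seconds) and the times
    falling in the window are returned.  Zero overlap yields an empty result
    and a warning.
    """
    t0 = injection_time + epoch.start
    t1 = injection_time + epoch.end
    data = np.asarray(data)
    if fs is not None:
        n = data.shape[-1]
        i0 = max(0, int(np.ceil(t0 * fs)))
        i1 = min(n, int(np.ceil(t1 * fs)))
        if i0 >= i1:
            warnings.warn(f"epoch '{epoch.name}' does not overlap the recording")
            return data[..., 0:0]
        return data[..., i0:i1]
    out = data[(data >= t0) & (data < t1)]
    if out.size == 0 and data.size > 0:
        warnings.warn(f"epoch '{epoch.name}' contains no spikes")
    return out
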