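"""Session data model, binning, and on-disk formats.

A :class:`Session` holds the aligned behavioral traces (whisker angle in
degrees, locomotion speed in cm/s) and per-unit spike times for one
recording.  A :class:`BinnedSession` holds kinematic features and spike
counts on a common time grid, the substrate for all encoding/decoding
models.  Times are seconds throughout; bins are half-open ``[t, t + dt)``.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import h5py
import numpy as np

#: canonical kinematic feature names (letter order L, O, A, F + phase)
SLOW_FEATURES = ("speed", "midpoint", "amplitude", "frequency")
ALL_FEATURES = SLOW_FEATURES + ("phase",)

#: bin widths (s) used by the downstream analyses
SUPPORTED_BIN_WIDTHS = (0.005, 0.015, 0.020, 0.025, 0.050, 0.100)


class SessionFormatError(Exception):
    """A session file is malformed (missing key, bad metadata)."""


class SessionValidationError(Exception):
    """Session arrays violate an invariant (NaN, out-of-range spikes)."""


@dataclass
class Session:
    """One recording: behavioral traces plus spike trains.

    Parameters
    ----------
    angle : ndarray
        Whisker angle, degrees, sampled at ``angle_rate`` Hz.
    speed : ndarray
        Locomotion speed, cm/s, sampled at ``speed_rate`` Hz.
    spikes : list of ndarray
        Per-unit spike times in seconds, each within ``[0, duration]``.
    meta : dict
        Free-form metadata; synthetic sessions store ground-truth traces
        (midpoint/amplitude/phase) and the generator seed here.
    """

    angle: np.ndarray
    angle_rate: float
    speed: np.ndarray
    speed_rate: float
    spikes: list
    unit_ids: list
    duration: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.angle = np.asarray(self.angle, dtype=float)
        self.speed = np.asarray(self.speed, dtype=float)
        self.spikes = [np.asarray(s, dtype=float) for s in self.spikes]
        self.validate()

    @property
    def n_units(self) -> int:
        return len(self.spikes)

    def validate(self):
        if self.angle_rate <= 0 or self.speed_rate <= 0:
            raise SessionValidationError("sample rates must be > 0")
        if np.isnan(self.angle).any():
            raise SessionValidationError("NaN in angle trace")
        if np.isnan(self.speed).any():
            raise SessionValidationError("NaN in speed trace")
        if len(self.spikes) != len(self.unit_ids):
            raise SessionValidationError("unit_ids / spikes length mismatch")
        for uid, st in zip(self.unit_ids, self.spikes):
            if st.size and (st.min() < 0 or st.max() > self.duration):
                raise SessionValidationError(
                    f"unit {uid}: spike times outside [0, {self.duration}]"
                )


@dataclass
class BinnedSession:
    """Kinematic features and spike counts on a common bin grid."""

    bin_width: float
    features: dict  # name -> ndarray (n_bins,)
    spike_counts: np.ndarray  # (n_units, n_bins) ints
    bin_times: np.ndarray  # bin centers, s
    unit_ids: list

    @property
    def n_bins(self) -> int:
        return len(self.bin_times)

    def __post_init__(self):
        n = self.n_bins
        for name, arr in self.features.items():
            if len(arr) != n:
                raise SessionValidationError(f"feature {name!r} length != n_bins")
        if self.spike_counts.shape[1] != n:
            raise SessionValidationError("spike_counts shape mismatch")


def _bin_mean(values: np.ndarray, rate: float, bin_width: float, n_bins: int) -> np.ndarray:
    """Arithmetic mean of a sampled series within each half-open bin."""
    t = np.arange(len(values)) / rate
    idx = np.floor(t / bin_width).astype(np.int64)
    keep = idx < n_bins
    idx, v = idx[keep], values[keep]
    cnt = np.bincount(idx, minlength=n_bins).astype(float)
    s = np.bincount(idx, weights=v, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        out = s / cnt
    return out


def _bin_circular_mean(values, rate, bin_width, n_bins):
    c = _bin_mean(np.cos(values), rate, bin_width, n_bins)
    s = _bin_mean(np.sin(values), rate, bin_width, n_bins)
    return np.arctan2(s, c)


def _bin_mode(values, rate, bin_width, n_bins, n_hist=16):
    """Occupancy-dominant value per bin: center of the fullest of 16 sub-bins."""
    t = np.arange(len(values)) / rate
    idx = np.floor(t / bin_width).astype(np.int64)
    out = np.full(n_bins, np.nan)
    lo, hi = np.nanmin(values), np.nanmax(values)
    if hi == lo:
        out[:] = lo
        return out
    edges = np.linspace(lo, hi, n_hist + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    for b in range(n_bins):
        v = values[idx == b]
        if v.size == 0:
            continue
        h, _ = np.histogram(v, bins=edges)
        out[b] = centers[np.argmax(h)]
    return out


def bin_session(
    session: Session,
    bin_width: float,
    decomp=None,
    aggregator: str = "mean",
) -> BinnedSession:
    """Bin features and spike counts into ``bin_width``-second bins.

    ``decomp`` is a :class:`whiskenc.kinematics.WhiskDecomposition`; if None
    it is computed from ``session.angle``.  Phase is averaged circularly,
    everything else arithmetically (or by the occupancy-dominant value when
    ``aggregator='occupancy-dominant'``).  The trailing partial bin is
    dropped; spike counts are exact event counts within the binned span.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    if bin_width >= session.duration:
        raise ValueError("bin_width must be smaller than session duration")
    if decomp is None:
        from .kinematics import decompose

        decomp = decompose(session.angle, session.angle_rate)

    n_bins = int(np.floor(session.duration / bin_width))
    rate = session.angle_rate
    if aggregator == "mean":
        agg = lambda v: _bin_mean(v, rate, bin_width, n_bins)  # noqa: E731
    elif aggregator == "occupancy-dominant":
        agg = lambda v: _bin_mode(v, rate, bin_width, n_bins)  # noqa: E731
    else:
        raise ValueError(f"unknown aggregator {aggregator!r}")

    features = {
        "angle": agg(session.angle),
        "midpoint": agg(decomp.midpoint),
        "amplitude": agg(decomp.amplitude),
        "frequency": agg(decomp.frequency),
        "phase": _bin_circular_mean(decomp.phase, rate, bin_width, n_bins),
        "speed": _bin_mean(session.speed, session.speed_rate, bin_width, n_bins),
    }

    span = n_bins * bin_width
    counts = np.zeros((session.n_units, n_bins), dtype=np.int64)
    for i, st in enumerate(session.spikes):
        st = st[st < span]
        counts[i] = np.bincount(
            np.floor(st / bin_width).astype(np.int64), minlength=n_bins
        )[:n_bins]

    bin_times = (np.arange(n_bins) + 0.5) * bin_width
    return BinnedSession(bin_width, features, counts, bin_times, list(session.unit_ids))


# ---------------------------------------------------------------------------
# on-disk formats: HDF5 (primary), NPZ and a CSV bundle as interchange
# ---------------------------------------------------------------------------

_REQUIRED = ("angle", "angle_rate", "speed", "speed_rate", "duration")


def _meta_split(meta):
    """Split meta into JSON-serializable scalars and ndarray entries."""
    scalars, arrays = {}, {}
    for k, v in meta.items():
        if isinstance(v, np.ndarray):
            arrays[k] = v
        elif isinstance(v, (np.generic,)):
            scalars[k] = v.item()
        else:
            scalars[k] = v
    return scalars, arrays


def write_session(session: Session, path: str, format: str = "hdf5"):
    """Write a session to disk; see :func:`read_session` for formats."""
    scalars, arrays = _meta_split(session.meta)
    if format == "hdf5":
        with h5py.File(path, "w") as f:
            beh = f.create_group("behavior")
            beh.create_dataset("angle", data=session.angle)
            beh.attrs["angle_rate"] = session.angle_rate
            beh.create_dataset("speed", data=session.speed)
            beh.attrs["speed_rate"] = session.speed_rate
            spk = f.create_group("spikes")
            for uid, st in zip(session.unit_ids, session.spikes):
                spk.create_dataset(str(uid), data=st)
            meta = f.create_group("meta")
            meta.attrs["duration"] = session.duration
            meta.attrs["unit_order"] = json.dumps([str(u) for u in session.unit_ids])
            meta.attrs["json"] = json.dumps(scalars)
            for k, v in arrays.items():
                meta.create_dataset(k, data=v)
    elif format == "npz":
        payload = {
            "angle": session.angle,
            "angle_rate": session.angle_rate,
            "speed": session.speed,
            "speed_rate": session.speed_rate,
            "duration": session.duration,
            "unit_order": np.array([str(u) for u in session.unit_ids]),
            "meta_json": np.array(json.dumps(scalars)),
        }
        for uid, st in zip(session.unit_ids, session.spikes):
            payload[f"spikes_{uid}"] = st
        for k, v in arrays.items():
            payload[f"meta_{k}"] = v
        np.savez(path, **payload)
    elif format == "csv-bundle":
        os.makedirs(path, exist_ok=True)
        np.savetxt(os.path.join(path, "angle.csv"), session.angle, delimiter=",")
        np.savetxt(os.path.join(path, "speed.csv"), session.speed, delimiter=",")
        for uid, st in zip(session.unit_ids, session.spikes):
            np.savetxt(os.path.join(path, f"spikes_{uid}.csv"), st, delimiter=",")
        blob = dict(scalars)
        blob["_arrays"] = {k: v.tolist() for k, v in arrays.items()}
        blob["_header"] = {
            "angle_rate": session.angle_rate,
            "speed_rate": session.speed_rate,
            "duration": session.duration,
            "unit_order": [str(u) for u in session.unit_ids],
        }
        with open(os.path.join(path, "meta.json"), "w") as fh:
            json.dump(blob, fh)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_session(path: str, format: str = "hdf5") -> Session:
    """Read a session written by :func:`write_session`.

    Raises :class:`SessionFormatError` naming the missing key on malformed
    input, and :class:`SessionValidationError` on invariant violations.
    """
    if format == "hdf5":
        with h5py.File(path, "r") as f:
            try:
                beh = f["behavior"]
                angle = beh["angle"][()]
                speed = beh["speed"][()]
                angle_rate = float(beh.attrs["angle_rate"])
                speed_rate = float(beh.attrs["speed_rate"])
                meta_grp = f["meta"]
                duration = float(meta_grp.attrs["duration"])
                unit_ids = json.loads(meta_grp.attrs["unit_order"])
                meta = json.loads(meta_grp.attrs["json"])
            except KeyError as e:
                raise SessionFormatError(f"missing key: {e}") from e
            spikes = [f["spikes"][str(u)][()] for u in unit_ids]
            for k in meta_grp:
                meta[k] = meta_grp[k][()]
    elif format == "npz":
        with np.load(path, allow_pickle=False) as z:
            for key in _REQUIRED:
                if key not in z:
                    raise SessionFormatError(f"missing key: {key!r}")
            angle = z["angle"]
            speed = z["speed"]
            angle_rate = float(z["angle_rate"])
            speed_rate = float(z["speed_rate"])
            duration = float(z["duration"])
            unit_ids = [str(u) for u in z["unit_order"]]
            meta = json.loads(str(z["meta_json"]))
            spikes = [z[f"spikes_{u}"] for u in unit_ids]
            for k in z.files:
                if k.startswith("meta_") and k != "meta_json":
                    meta[k[5:]] = z[k]
    elif format == "csv-bundle":
        meta_path = os.path.join(path, "meta.json")
        if not os.path.exists(meta_path):
            raise SessionFormatError("missing key: 'meta.json'")
        with open(meta_path) as fh:
            blob = json.load(fh)
        try:
            header = blob.pop("_header")
            angle_rate = header["angle_rate"]
            speed_rate = header["speed_rate"]
            duration = header["duration"]
            unit_ids = header["unit_order"]
        except KeyError as e:
            raise SessionFormatError(f"missing key: {e}") from e
        arr_blob = blob.pop("_arrays", {})
        meta = blob
        meta.update({k: np.asarray(v) for k, v in arr_blob.items()})
        for fname in ("angle.csv", "speed.csv"):
            if not os.path.exists(os.path.join(path, fname)):
                raise SessionFormatError(f"missing key: {fname!r}")
        angle = np.loadtxt(os.path.join(path, "angle.csv"), delimiter=",")
        speed = np.loadtxt(os.path.join(path, "speed.csv"), delimiter=",")
        spikes = [
            np.atleast_1d(np.loadtxt(os.path.join(path, f"spikes_{u}.csv"), delimiter=","))
            if os.path.getsize(os.path.join(path, f"spikes_{u}.csv")) > 0
            else np.empty(0)
            for u in unit_ids
        ]
    else:
        raise ValueError(f"unknown format {format!r}")

    return Session(
        angle=angle,
        angle_rate=angle_rate,
        speed=speed,
        speed_rate=speed_rate,
        spikes=spikes,
        unit_ids=unit_ids,
        duration=duration,
        meta=meta,
    )
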