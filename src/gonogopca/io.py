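"""File formats: long-format epoch tables, decomposition bundles, EDF.

The canonical interchange is a tidy long-format table with one row per
(subject, drug, block, condition, trial, channel, sample): diff-able,
language-neutral, lossless for the epoch schema.  CSV is used for small
tables and Parquet for full-size sessions.  Amplitudes must be microvolts:
the amplitude column is named ``amplitude_uv`` and any other unit suffix
is rejected.

Continuous recordings can be exchanged as EDF: a minimal plain-EDF writer
(16-bit, 1-second records, optional integer event/trigger channel) is
provided here, and reading goes through :mod:`mne`.
"""

from __future__ import annotations

import datetime as _dt
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import EpochSet, META_COLUMNS
from .montage import Montage, default_montage

AMPLITUDE_COLUMN = "amplitude_uv"
_TABLE_KEYS = ["subject", "drug", "block", "condition", "trial"]


# ---------------------------------------------------------------------------
# long-format epoch tables
# ---------------------------------------------------------------------------

def epochs_to_table(epochs: EpochSet) -> pd.DataFrame:
    n_e, n_c, n_t = epochs.data.shape
    meta = epochs.meta[list(META_COLUMNS)]
    rep = meta.loc[meta.index.repeat(n_c * n_t)].reset_index(drop=True)
    rep["channel"] = np.tile(np.repeat(epochs.channels, n_t), n_e)
    rep["time_ms"] = np.tile(epochs.times * 1000.0, n_e * n_c)
    rep[AMPLITUDE_COLUMN] = epochs.data.ravel().astype(np.float64)
    return rep


def write_epoch_table(epochs: EpochSet, path: str | Path) -> Path:
    """Write the long-format table; .csv or .parquet by extension."""
    path = Path(path)
    table = epochs_to_table(epochs)
    if path.suffix == ".parquet":
        table.to_parquet(path, index=False)
    else:
        table.to_csv(path, index=False)
    return path


def read_epoch_table(path: str | Path, montage: Montage | None = None,
                     sfreq: float | None = None) -> EpochSet:
    """Read a long-format epoch table back into an `EpochSet`.

    Validates the schema: the amplitude column must be ``amplitude_uv``
    (unit guard), channels must belong to the montage, and every epoch must
    cover the same time grid.  Malformed rows are reported by number.
    """
    path = Path(path)
    table = (pd.read_parquet(path) if path.suffix == ".parquet"
             else pd.read_csv(path))
    montage = montage or default_montage()

    if AMPLITUDE_COLUMN not in table.columns:
        other = [c for c in table.columns if c.startswith("amplitude_")]
        raise ValueError(
            f"amplitude column must be '{AMPLITUDE_COLUMN}' (microvolts); "
            f"found {other or 'none'}")
    required = set(_TABLE_KEYS) | {"channel", "time_ms", AMPLITUDE_COLUMN}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    known = set(montage.all_channels)
    bad = ~table["channel"].isin(known)
    if bad.any():
        rows = table.index[bad][:5].tolist()
        raise ValueError(
            f"unknown channels {sorted(table.loc[bad, 'channel'].unique())} "
            f"at rows {rows}")
    nan_rows = table.index[table[AMPLITUDE_COLUMN].isna()].tolist()
    if nan_rows:
        raise ValueError(f"malformed amplitude values at rows {nan_rows[:5]}")

    times_ms = np.sort(table["time_ms"].unique())
    channels = [c for c in montage.all_channels if c in set(table["channel"])]
    n_t, n_c = len(times_ms), len(channels)

    order = {c: i for i, c in enumerate(channels)}
    table = table.assign(_ch=table["channel"].map(order)).sort_values(
        _TABLE_KEYS + ["_ch", "time_ms"], kind="mergesort")
    sizes = table.groupby(_TABLE_KEYS, sort=False).size()
    if not (sizes == n_c * n_t).all():
        bad = sizes[sizes != n_c * n_t].index.tolist()[:3]
        raise ValueError(f"inconsistent channel/time grid for epochs {bad}")
    n_e = len(sizes)
    data = table[AMPLITUDE_COLUMN].to_numpy().reshape(n_e, n_c, n_t)
    meta = (table.drop_duplicates(_TABLE_KEYS)[
        [c for c in META_COLUMNS if c in table.columns]].reset_index(drop=True))
    if sfreq is None:
        dt = np.diff(times_ms)
        sfreq = 1000.0 / float(np.median(dt))
    return EpochSet(
        data=data.astype(np.float32),
        channels=channels,
        times=times_ms / 1000.0,
        sfreq=float(sfreq),
        meta=meta,
        montage=montage,
    )


# ---------------------------------------------------------------------------
# minimal plain-EDF writer + mne-backed reader
# ---------------------------------------------------------------------------

def _edf_field(value: str, width: int) -> bytes:
    s = value[:width].ljust(width)
    return s.encode("ascii")


def write_edf(path: str | Path, data_uv: np.ndarray, channels: list[str],
              sfreq: float, events: np.ndarray | None = None,
              stim_channel: str = "TRIG") -> Path:
    """Write a continuous multichannel record as plain EDF (16-bit).

    ``data_uv`` is (n_channels, n_times) in microvolts.  ``events`` are
    sample indices marked as unit pulses on an extra integer trigger
    channel, so stimulus onsets survive the round trip.  One-second data
    records; the tail is zero-padded.
    """
    path = Path(path)
    data_uv = np.asarray(data_uv, dtype=np.float64)
    n_ch, n_times = data_uv.shape
    spr = int(round(sfreq))
    if abs(sfreq - spr) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    all_data = [data_uv[i] for i in range(n_ch)]
    labels = list(channels)
    if events is not None:
        trig = np.zeros(n_times)
        trig[np.asarray(events, dtype=int)] = 1.0
        all_data.append(trig)
        labels.append(stim_channel)
    n_sig = len(all_data)
    n_rec = int(np.ceil(n_times / spr))

    phys_min, phys_max, digital = [], [], []
    for x in all_data:
        lo = float(np.min(x)); hi = float(np.max(x))
        if hi <= lo:
            hi = lo + 1.0
        pad = np.zeros(n_rec * spr)
        pad[:n_times] = x
        scale = (hi - lo) / (2 ** 16 - 1)
        dig = np.round((pad - lo) / scale - 32768.0).astype("<i2")
        phys_min.append(lo); phys_max.append(hi); digital.append(dig)

    now = _dt.datetime(2000, 1, 1)
    header = b"".join([
        _edf_field("0", 8),
        _edf_field("X X X X", 80),
        _edf_field("Startdate X X X X", 80),
        _edf_field(now.strftime("%d.%m.%y"), 8),
        _edf_field(now.strftime("%H.%M.%S"), 8),
        _edf_field(str(256 * (n_sig + 1)), 8),
        _edf_field("", 44),
        _edf_field(str(n_rec), 8),
        _edf_field("1", 8),
        _edf_field(str(n_sig), 4),
    ])
    sig_header = b"".join([
        b"".join(_edf_field(lab, 16) for lab in labels),
        b"".join(_edf_field("", 80) for _ in labels),
        b"".join(_edf_field("uV", 8) for _ in labels),
        b"".join(_edf_field(f"{phys_min[i]:.6g}"[:8], 8) for i in range(n_sig)),
        b"".join(_edf_field(f"{phys_max[i]:.6g}"[:8], 8) for i in range(n_sig)),
        b"".join(_edf_field("-32768", 8) for _ in labels),
        b"".join(_edf_field("32767", 8) for _ in labels),
        b"".join(_edf_field("", 80) for _ in labels),
        b"".join(_edf_field(str(spr), 8) for _ in labels),
        b"".join(_edf_field("", 32) for _ in labels),
    ])
    with open(path, "wb") as fh:
        fh.write(header + sig_header)
        for r in range(n_rec):
            for dig in digital:
                fh.write(dig[r * spr:(r + 1) * spr].tobytes())
    return path


def read_edf(path: str | Path, montage: Montage | None = None,
             stim_channel: str = "TRIG"
             ) -> tuple[np.ndarray, list[str], float, np.ndarray]:
    """Read a continuous EDF recording, mapping channels by montage names.

    Returns (data in microvolts, channel names, sfreq, event samples from
    the trigger channel).  Channels absent from the montage (other than the
    trigger) are rejected.
    """
    import mne

    montage = montage or default_montage()
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    names = list(raw.ch_names)
    known = set(montage.all_channels)
    data = raw.get_data()  # Volts for uV-typed channels under mne scaling

    events = np.empty(0, dtype=int)
    if stim_channel in names:
        i = names.index(stim_channel)
        trig = data[i]
        events = np.flatnonzero((trig[1:] > 0.5 * trig.max(initial=1e-9))
                                & (trig[:-1] <= 0.5 * trig.max(initial=1e-9))) + 1
        if trig[0] > 0.5 * trig.max(initial=1e-9):
            events = np.insert(events, 0, 0)
        keep = [j for j in range(len(names)) if j != i]
        data, names = data[keep], [names[j] for j in keep]
    unknown = [n for n in names if n not in known]
    if unknown:
        raise ValueError(f"channels not in montage: {unknown}")
    return data * 1e6, names, float(raw.info["sfreq"]), events


# ---------------------------------------------------------------------------
# config and small sidecars
# ---------------------------------------------------------------------------

def write_json(obj: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, default=_jsonable) + "\n")
    return path


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON-serializable: {type(x)}")


def load_config_file(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text()) or {}
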