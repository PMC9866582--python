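"""CSV record I/O.

Records are plain CSV with columns ``time_s, ch1[, ch2, ch3, cuff_mmHg]``;
scan grids are ``x_cm, y_cm, amplitude``.  CSV keeps fixtures diffable;
round trips are lossless to 1e-9.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .waveform import SignalTrace

__all__ = ["read_record", "write_record", "write_ground_truth"]

_CH_COLS = ("ch1", "ch2", "ch3")


def read_record(path):
    """Read a record CSV.

    Returns
    -------
    (dict[str, SignalTrace], SignalTrace | None)
        Channel traces keyed by column name, and the cuff-pressure trace
        if present.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as err:
        raise ValueError(f"malformed record CSV {path}: {err}") from err
    if "time_s" not in df.columns:
        raise ValueError("record CSV must have a time_s column")
    bad = df.index[df.isna().any(axis=1)]
    if len(bad):
        raise ValueError(f"malformed row at line {int(bad[0]) + 2} of {path}")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError("record must have at least 2 samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        k = int(np.argmax(dt <= 0))
        raise ValueError(f"non-monotone time column at line {k + 3} of {path}")
    if np.ptp(dt) > 1e-6 * dt.mean():
        raise ValueError("time column is not uniformly sampled")
    fs = 1.0 / dt.mean()
    channels = {c: SignalTrace(df[c].to_numpy(dtype=float), fs=fs)
                for c in _CH_COLS if c in df.columns}
    if not channels:
        raise ValueError("record CSV must have at least one ch* column")
    cuff = (SignalTrace(df["cuff_mmHg"].to_numpy(dtype=float), fs=fs, unit="mmHg")
            if "cuff_mmHg" in df.columns else None)
    return channels, cuff


def write_record(path, channels, cuff: SignalTrace | None = None) -> None:
    """Write channel traces (dict or single SignalTrace) to a record CSV."""
    if isinstance(channels, SignalTrace):
        channels = {"ch1": channels}
    traces = list(channels.values())
    n = len(traces[0])
    fs = traces[0].fs
    for tr in traces[1:]:
        if len(tr) != n or tr.fs != fs:
            raise ValueError("all channels must share length and sampling rate")
    data = {"time_s": np.arange(n) / fs}
    data.update({name: tr.samples for name, tr in channels.items()})
    if cuff is not None:
        if len(cuff) != n:
            raise ValueError("cuff trace length must match channels")
        data["cuff_mmHg"] = cuff.samples
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.12g")


def write_ground_truth(path, truth) -> None:
    """JSON sidecar with a synthetic record's per-cycle ground truth."""
    payload = {
        "label": truth.label,
        "seed": truth.seed,
        "boundaries": truth.boundaries.tolist(),
        "corrupted": truth.corrupted.astype(bool).tolist(),
        "cycles": [vars(p).copy() for p in truth.params],
    }
    Path(path).write_text(json.dumps(payload, indent=1))
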