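"""Event-matrix I/O and fluorescence transforms.

Reads list-mode FCS 3.0/3.1 files and plain CSV event tables into an
:class:`EventMatrix`, writes FCS 3.1 (float data) for fixtures, and
applies per-channel fluorescence transforms (arcsinh, logicle) so that
downstream density gating operates in a well-behaved coordinate space.
"""

from __future__ import annotations

import logging
import re
import struct
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SCATTER_RE = re.compile(r"^(FSC|SSC)", re.IGNORECASE)


class FcsFormatError(ValueError):
    """Raised when an FCS file is malformed or uses an unsupported feature."""


@dataclass
class EventMatrix:
    """A per-sample table of events x channels.

    Attributes
    ----------
    sample_id : str
        Identifier of the sample (defaults to the file stem).
    channels : list of str
        Ordered, unique channel names.
    data : ndarray, shape (n_events, n_channels)
        Event values in arbitrary (possibly transformed) units.
    transform_state : dict
        Per-channel transform descriptor, e.g. ``"linear"``,
        ``"arcsinh:150"`` or ``"logicle:T=262144,W=0.5,M=4.5,A=0"``.
    metadata : dict
        Free-form key -> string map (instrument, date, technician id, ...).
    dropped_rows : int
        Number of rows removed at load time because they contained
        NaN/non-numeric entries.
    """

    sample_id: str
    channels: list[str]
    data: np.ndarray
    transform_state: dict[str, str] = field(default_factory=dict)
    metadata: dict[str, str] = field(default_factory=dict)
    dropped_rows: int = 0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2D events x channels matrix")
        if self.data.shape[1] != len(self.channels):
            raise ValueError(
                f"data has {self.data.shape[1]} columns but "
                f"{len(self.channels)} channel names were given"
            )
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel names must be unique")
        if self.data.shape[0] < 1:
            raise ValueError("EventMatrix requires at least one event")
        if np.isnan(self.data).any():
            raise ValueError("EventMatrix data must not contain NaN")
        for ch in self.channels:
            self.transform_state.setdefault(ch, "linear")

    @property
    def n_events(self) -> int:
        return self.data.shape[0]

    def column(self, channel: str) -> np.ndarray:
        try:
            return self.data[:, self.channels.index(channel)]
        except ValueError:
            raise KeyError(f"unknown channel {channel!r}; have {self.channels}") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, columns=self.channels)


# ---------------------------------------------------------------------------
# FCS reading / writing
# ---------------------------------------------------------------------------

def _parse_text_segment(raw: bytes) -> dict[str, str]:
    if not raw:
        raise FcsFormatError("empty TEXT segment")
    delim = raw[0:1]
    body = raw[1:]
    # A doubled delimiter escapes a literal delimiter inside a value; the
    # fixtures written here never produce one, but tolerate it on read.
    parts = body.split(delim)
    if parts and parts[-1] == b"":
        parts = parts[:-1]
    pairs = {}
    for i in range(0, len(parts) - 1, 2):
        key = parts[i].decode("utf-8", "replace").strip().upper()
        val = parts[i + 1].decode("utf-8", "replace").strip()
        if key:
            pairs[key] = val
    return pairs


def read_fcs(path: str | Path, sample_id: str | None = None) -> EventMatrix:
    """Read a list-mode FCS 3.0/3.1 file into an :class:`EventMatrix`.

    Channel names are taken from ``$PnS`` when present, else ``$PnN``.
    ``$DATE`` and ``$CYT`` propagate to ``metadata``.  Supported data
    types are float (``$DATATYPE F``/``D``) and unsigned integer
    (``$DATATYPE I`` with byte-aligned ``$PnB``).

    Raises
    ------
    FcsFormatError
        On a malformed header, truncated file or unsupported keyword,
        naming the offending keyword.
    """
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < 58:
        raise FcsFormatError(f"{path.name}: file too short for an FCS header")
    version = raw[:6].decode("ascii", "replace")
    if not version.startswith("FCS3"):
        raise FcsFormatError(f"{path.name}: unsupported version {version!r}")

    def offset(lo, hi):
        txt = raw[lo:hi].decode("ascii", "replace").strip()
        try:
            return int(txt) if txt else 0
        except ValueError as exc:
            raise FcsFormatError(f"{path.name}: bad header offset {txt!r}") from exc

    text_start, text_end = offset(10, 18), offset(18, 26)
    data_start, data_end = offset(26, 34), offset(34, 42)
    if text_end <= text_start or text_end >= len(raw):
        raise FcsFormatError(f"{path.name}: TEXT segment offsets out of range")
    kw = _parse_text_segment(raw[text_start:text_end + 1])

    if data_start == 0 or data_end == 0:
        try:
            data_start = int(kw["$BEGINDATA"])
            data_end = int(kw["$ENDDATA"])
        except (KeyError, ValueError):
            raise FcsFormatError(f"{path.name}: missing $BEGINDATA/$ENDDATA") from None
    if data_end >= len(raw):
        raise FcsFormatError(f"{path.name}: DATA segment truncated ($ENDDATA past EOF)")

    mode = kw.get("$MODE", "L")
    if mode != "L":
        raise FcsFormatError(f"{path.name}: unsupported $MODE {mode!r} (list mode only)")
    try:
        n_par = int(kw["$PAR"])
        n_tot = int(kw["$TOT"])
    except (KeyError, ValueError):
        raise FcsFormatError(f"{path.name}: missing or invalid $PAR/$TOT") from None

    datatype = kw.get("$DATATYPE", "")
    byteord = kw.get("$BYTEORD", "1,2,3,4")
    little = byteord.startswith("1")
    endian = "<" if little else ">"

    bits = [int(kw.get(f"$P{i}B", "32")) for i in range(1, n_par + 1)]
    blob = raw[data_start:data_end + 1]
    if datatype == "F":
        fmt = np.dtype(endian + "f4")
        width = 4
    elif datatype == "D":
        fmt = np.dtype(endian + "f8")
        width = 8
    elif datatype == "I":
        if len(set(bits)) != 1 or bits[0] not in (8, 16, 32):
            raise FcsFormatError(
                f"{path.name}: unsupported mixed/odd $PnB widths for $DATATYPE I"
            )
        width = bits[0] // 8
        fmt = np.dtype(endian + f"u{width}")
    else:
        raise FcsFormatError(f"{path.name}: unsupported $DATATYPE {datatype!r}")

    need = n_par * n_tot * width
    if len(blob) < need:
        raise FcsFormatError(
            f"{path.name}: DATA segment holds {len(blob)} bytes, "
            f"need {need} for $TOT={n_tot} x $PAR={n_par}"
        )
    data = np.frombuffer(blob[:need], dtype=fmt).astype(np.float64).reshape(n_tot, n_par)

    channels = []
    for i in range(1, n_par + 1):
        name = kw.get(f"$P{i}S") or kw.get(f"$P{i}N") or f"P{i}"
        channels.append(name)

    nan_rows = np.isnan(data).any(axis=1)
    dropped = int(nan_rows.sum())
    if dropped:
        logger.info("%s: dropped %d rows containing NaN", path.name, dropped)
        data = data[~nan_rows]
    if data.shape[0] == 0:
        raise FcsFormatError(f"{path.name}: no events remain after NaN filtering")

    metadata = {}
    for key in ("$DATE", "$CYT"):
        if key in kw:
            metadata[key.lstrip("$")] = kw[key]
    for key, val in kw.items():
        if not key.startswith("$"):
            metadata[key] = val

    return EventMatrix(
        sample_id=sample_id or path.stem,
        channels=channels,
        data=data,
        metadata=metadata,
        dropped_rows=dropped,
    )


def write_fcs(m: EventMatrix, path: str | Path) -> None:
    """Write an :class:`EventMatrix` as FCS 3.1 with float32 data.

    Sufficient for fixtures and interchange; metadata keys ``DATE`` and
    ``CYT`` round-trip.  Data is stored little-endian ``$DATATYPE F``.
    """
    path = Path(path)
    n_tot, n_par = m.data.shape
    data_bytes = np.ascontiguousarray(m.data, dtype="<f4").tobytes()

    kw: dict[str, str] = {
        "$MODE": "L",
        "$DATATYPE": "F",
        "$BYTEORD": "1,2,3,4",
        "$PAR": str(n_par),
        "$TOT": str(n_tot),
        "$NEXTDATA": "0",
    }
    for i, ch in enumerate(m.channels, start=1):
        kw[f"$P{i}N"] = ch
        kw[f"$P{i}B"] = "32"
        kw[f"$P{i}E"] = "0,0"
        kw[f"$P{i}R"] = str(int(max(1.0, np.ceil(m.data[:, i - 1].max()))) if n_tot else 1)
    if "DATE" in m.metadata:
        kw["$DATE"] = m.metadata["DATE"]
    if "CYT" in m.metadata:
        kw["$CYT"] = m.metadata["CYT"]

    delim = "|"
    for key, val in kw.items():
        if delim in key or delim in str(val):
            raise ValueError(f"delimiter {delim!r} appears in keyword {key}={val}")

    # TEXT length depends on the data offsets which depend on TEXT length;
    # reserve fixed-width offset fields and fill them in a second pass.
    def build_text(begin_data: int, end_data: int) -> bytes:
        items = dict(kw)
        items["$BEGINDATA"] = str(begin_data)
        items["$ENDDATA"] = str(end_data)
        items["$BEGINANALYSIS"] = "0"
        items["$ENDANALYSIS"] = "0"
        body = delim + delim.join(f"{k}{delim}{v}" for k, v in items.items()) + delim
        return body.encode("utf-8")

    header_len = 58
    text = build_text(0, 0)
    for _ in range(4):  # converges once the digit counts stabilise
        text_start = header_len
        text_end = text_start + len(text) - 1
        data_start = text_end + 1
        data_end = data_start + len(data_bytes) - 1
        new_text = build_text(data_start, data_end)
        if len(new_text) == len(text):
            text = new_text
            break
        text = new_text
    else:
        raise RuntimeError("TEXT segment length failed to converge")

    def fld(v: int) -> bytes:
        s = str(v)
        if len(s) > 8:
            s = "0"  # too large for the header; reader falls back to $BEGINDATA
        return s.rjust(8).encode("ascii")

    header = b"FCS3.1    " + fld(text_start) + fld(text_end)
    header += fld(data_start if data_start <= 99999999 else 0)
    header += fld(data_end if data_end <= 99999999 else 0)
    header += fld(0) + fld(0)
    assert len(header) == header_len

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(data_bytes)


# ---------------------------------------------------------------------------
# CSV readers
# ---------------------------------------------------------------------------

def read_events_csv(path: str | Path, sample_id: str | None = None) -> EventMatrix:
    """Read a comma-separated event table with a header row of channel names.

    Rows containing non-numeric entries are dropped and counted in
    ``dropped_rows``.  An empty body raises ``ValueError``.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if df.shape[0] == 0:
        raise ValueError(f"{path.name}: CSV has a header but no event rows")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1)
    dropped = int(bad.sum())
    if dropped:
        logger.info("%s: dropped %d non-numeric rows", path.name, dropped)
    numeric = numeric[~bad]
    if numeric.shape[0] == 0:
        raise ValueError(f"{path.name}: no numeric event rows remain")
    return EventMatrix(
        sample_id=sample_id or path.stem,
        channels=list(df.columns),
        data=numeric.to_numpy(dtype=np.float64),
        dropped_rows=dropped,
    )


def read_wbc_csv(path: str | Path) -> dict[str, float]:
    """Read a WBC table (columns ``sample_id,wbc``; counts in 10^9 cells/L)."""
    df = pd.read_csv(path)
    missing = {"sample_id", "wbc"} - set(df.columns)
    if missing:
        raise ValueError(f"WBC table missing columns: {sorted(missing)}")
    wbc = {str(r.sample_id): float(r.wbc) for r in df.itertuples()}
    for sid, v in wbc.items():
        if not v > 0:
            raise ValueError(f"WBC count for {sid!r} must be > 0, got {v}")
    return wbc


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------

def _logicle_params(spec: str) -> dict[str, float]:
    params = {"T": 262144.0, "W": 0.5, "M": 4.5, "A": 0.0}
    _, _, rest = spec.partition(":")
    if rest:
        for part in rest.split(","):
            k, _, v = part.partition("=")
            k = k.strip().upper()
            if k not in params:
                raise ValueError(f"unknown logicle parameter {k!r}")
            params[k] = float(v)
    return params


def _logicle_forward(values: np.ndarray, T: float, W: float, M: float, A: float) -> np.ndarray:
    """Logicle (biexponential) transform mapping data to ~[0, 1] scale.

    Inverts the Parks–Moore biexponential numerically: the forward
    biexponential S(y) = a e^{by} - c e^{-dy} - f is evaluated on a dense
    grid and linearly interpolated, which is accurate to well below
    display resolution and strictly monotone by construction.
    """
    from scipy.optimize import brentq

    if W < 0 or M <= 0 or T <= 0:
        raise ValueError("logicle requires T>0, M>0, W>=0")
    b = (M + A) * np.log(10.0)
    w = W / (M + A)
    x2 = A / (M + A)
    x1 = x2 + w
    x0 = x2 + 2 * w
    if w == 0:
        d = b
    else:
        d = brentq(lambda dd: 2 * (np.log(dd) - np.log(b)) + w * (b + dd),
                   1e-12, b - 1e-12)
    c_a = np.exp(x0 * (b + d))
    mf_a = np.exp(b * x1) - c_a / np.exp(d * x1)
    a = T / (np.exp(b) - mf_a - c_a / np.exp(d))
    c = c_a * a
    f = -mf_a * a

    def S(y):
        return a * np.exp(b * y) - c * np.exp(-d * y) - f

    lo, hi = -0.5, 1.5
    vmin, vmax = float(np.min(values)), float(np.max(values))
    for _ in range(64):  # widen until the grid brackets the data
        if S(lo) <= vmin:
            break
        lo -= 0.5
    for _ in range(64):
        if S(hi) >= vmax:
            break
        hi += 0.5
    grid_y = np.linspace(lo, hi, 8192)
    return np.interp(values, S(grid_y), grid_y)


def transform_fn(spec: str):
    """Return the elementwise transform callable for a transform descriptor.

    Descriptors: ``"linear"``, ``"arcsinh"``/``"arcsinh:COFACTOR"``
    (default cofactor 150), ``"logicle"``/``"logicle:T=..,W=..,M=..,A=.."``.
    """
    spec = spec.strip()
    if spec == "linear":
        return lambda x: x
    if spec.startswith("arcsinh"):
        _, _, rest = spec.partition(":")
        cofactor = float(rest) if rest else 150.0
        if cofactor <= 0:
            raise ValueError("arcsinh cofactor must be positive")
        return lambda x: np.arcsinh(np.asarray(x, dtype=np.float64) / cofactor)
    if spec.startswith("logicle"):
        p = _logicle_params(spec)
        return lambda x: _logicle_forward(np.asarray(x, dtype=np.float64), **p)
    raise ValueError(f"unknown transform {spec!r}")


def normalize_transform(spec: str) -> str:
    spec = spec.strip()
    if spec == "arcsinh":
        return "arcsinh:150"
    if spec == "logicle":
        p = _logicle_params(spec)
        return "logicle:" + ",".join(f"{k}={v:g}" for k, v in p.items())
    return spec


def apply_transform(m: EventMatrix, spec: dict[str, str]) -> EventMatrix:
    """Return a new :class:`EventMatrix` with per-channel transforms applied.

    ``spec`` maps channel name -> transform descriptor.  The special key
    ``"*"`` targets every fluorescence channel (scatter channels FSC*/SSC*
    and "Time" stay linear unless listed explicitly).  Unknown channel
    names raise ``KeyError``.
    """
    resolved: dict[str, str] = {}
    if "*" in spec:
        blanket = spec["*"]
        for ch in m.channels:
            if not SCATTER_RE.match(ch) and ch.lower() != "time":
                resolved[ch] = blanket
    for ch, t in spec.items():
        if ch == "*":
            continue
        if ch not in m.channels:
            raise KeyError(f"unknown channel {ch!r}; have {m.channels}")
        resolved[ch] = t

    data = m.data.copy()
    state = dict(m.transform_state)
    for ch, t in resolved.items():
        j = m.channels.index(ch)
        data[:, j] = transform_fn(t)(data[:, j])
        state[ch] = normalize_transform(t)
    return replace(m, data=data, transform_state=state)
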