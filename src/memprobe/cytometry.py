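"""Event-level flow cytometry data: I/O, spectral compensation, gating, viability.

The central container is :class:`EventTable`, a per-event intensity matrix with
channel metadata, optional per-event acquisition times and sample annotations.
Files are exchanged either as per-event CSV (comma separated, mandatory header,
'.' decimal separator, UTF-8 — bit-exact round trip) or as FCS list-mode files
(FCS 3.0/3.1 read, FCS 3.1 float write).
"""

from __future__ import annotations

import io
import logging
import os
import struct
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import shapely

logger = logging.getLogger(__name__)

__all__ = [
    "Channel",
    "EventTable",
    "SpilloverMatrix",
    "Gate",
    "read_events",
    "write_events",
    "apply_compensation",
    "apply_gate",
    "viability_fractions",
]

_SCATTER_FORWARD = "scatter-forward"
_SCATTER_SIDE = "scatter-side"
_FLUORESCENCE = "fluorescence"
_ROLES = (_SCATTER_FORWARD, _SCATTER_SIDE, _FLUORESCENCE)


def _role_from_name(name: str) -> str:
    upper = name.upper()
    if upper.startswith("FSC"):
        return _SCATTER_FORWARD
    if upper.startswith("SSC"):
        return _SCATTER_SIDE
    return _FLUORESCENCE


@dataclass(frozen=True)
class Channel:
    """A detector channel: a scatter or fluorescence signal of the cytometer.

    ``emission_band_nm`` is the (center, full width) of the detection band-pass
    filter, e.g. (530, 30) for a 530/30 filter.
    """

    name: str
    role: str = _FLUORESCENCE
    excitation_nm: float | None = None
    emission_band_nm: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("channel name must be non-empty")
        if self.role not in _ROLES:
            raise ValueError(f"unknown channel role {self.role!r}; expected one of {_ROLES}")
        if self.emission_band_nm is not None:
            center, width = self.emission_band_nm
            if width <= 0:
                raise ValueError("emission band width must be > 0")


@dataclass
class EventTable:
    """Per-event intensity matrix (rows = events, columns = channels)."""

    events: np.ndarray
    channels: list[Channel]
    time_s: np.ndarray | None = None
    sample_meta: dict = field(default_factory=dict)
    log: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.events = np.asarray(self.events, dtype=float)
        if self.events.ndim != 2:
            raise ValueError("events must be a 2-D matrix")
        if self.events.shape[1] != len(self.channels):
            raise ValueError(
                f"event matrix has {self.events.shape[1]} columns but "
                f"{len(self.channels)} channels"
            )
        names = self.channel_names
        if len(set(names)) != len(names):
            raise ValueError("channel names must be unique")
        if self.time_s is not None:
            self.time_s = np.asarray(self.time_s, dtype=float)
            if self.time_s.shape != (self.events.shape[0],):
                raise ValueError("time_s must have one entry per event")

    @property
    def n_events(self) -> int:
        return self.events.shape[0]

    @property
    def channel_names(self) -> list[str]:
        return [c.name for c in self.channels]

    def column(self, name: str) -> np.ndarray:
        """Intensity vector of the named channel."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in table "
                           f"(have {self.channel_names})") from None
        return self.events[:, idx]

    def fluorescence_channels(self) -> list[str]:
        return [c.name for c in self.channels if c.role == _FLUORESCENCE]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.events, columns=self.channel_names)
        if self.time_s is not None:
            df.insert(0, "time_s", self.time_s)
        return df

    def take(self, index: np.ndarray) -> "EventTable":
        """Row subset preserving channel metadata, annotations and log."""
        return EventTable(
            events=self.events[index],
            channels=list(self.channels),
            time_s=None if self.time_s is None else self.time_s[index],
            sample_meta=dict(self.sample_meta),
            log=list(self.log),
        )


@dataclass(frozen=True)
class SpilloverMatrix:
    """Square spillover matrix over fluorescence channel names.

    Entry (i, j) is the fraction of dye i's signal detected in channel j, with
    the convention ``observed = true @ S`` and unit diagonal.
    """

    channel_names: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        k = len(self.channel_names)
        if m.shape != (k, k):
            raise ValueError(f"spillover matrix must be {k}x{k}, got {m.shape}")
        if not np.allclose(np.diag(m), 1.0):
            raise ValueError("spillover diagonal entries must equal 1")
        if abs(np.linalg.det(m)) < 1e-12:
            raise ValueError("spillover matrix is singular")


@dataclass(frozen=True)
class Gate:
    """A closed gating region on one or two channels.

    ``kind`` is one of ``rectangle``, ``polygon``, ``threshold-above``,
    ``threshold-below``.  Boundary points are always kept (closed regions).
    """

    kind: str
    channels: tuple[str, ...]
    bounds: tuple | None = None        # rectangle: ((xlo, xhi), (ylo, yhi)); threshold: (t,)
    vertices: tuple | None = None      # polygon: ((x, y), ...)

    def __post_init__(self) -> None:
        if self.kind == "rectangle":
            if len(self.channels) != 2 or self.bounds is None:
                raise ValueError("rectangle gate needs 2 channels and bounds")
            for lo, hi in self.bounds:
                if lo > hi:
                    raise ValueError("rectangle bounds must be ordered (lo <= hi)")
        elif self.kind == "polygon":
            if len(self.channels) != 2 or self.vertices is None or len(self.vertices) < 3:
                raise ValueError("polygon gate needs 2 channels and >= 3 vertices")
        elif self.kind in ("threshold-above", "threshold-below"):
            if len(self.channels) != 1 or self.bounds is None or len(self.bounds) != 1:
                raise ValueError("threshold gate needs 1 channel and a single bound")
        else:
            raise ValueError(f"unknown gate kind {self.kind!r}")

    def mask(self, table: EventTable) -> np.ndarray:
        for name in self.channels:
            if name not in table.channel_names:
                raise KeyError(f"gate references missing channel {name!r}")
        if self.kind == "rectangle":
            x = table.column(self.channels[0])
            y = table.column(self.channels[1])
            (xlo, xhi), (ylo, yhi) = self.bounds
            return (x >= xlo) & (x <= xhi) & (y >= ylo) & (y <= yhi)
        if self.kind == "polygon":
            x = table.column(self.channels[0])
            y = table.column(self.channels[1])
            poly = shapely.Polygon(self.vertices)
            # intersects == inside-or-on-boundary: the closed-region convention
            return shapely.intersects_xy(poly, x, y)
        value = table.column(self.channels[0])
        (t,) = self.bounds
        if self.kind == "threshold-above":
            return value >= t
        return value <= t


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_TIME_COLUMN = "time_s"


def _drop_nonfinite(events: np.ndarray, time_s: np.ndarray | None,
                    log: list[dict], source: str):
    finite = np.all(np.isfinite(events), axis=1)
    if time_s is not None:
        finite &= np.isfinite(time_s)
    n_dropped = int((~finite).sum())
    if n_dropped:
        logger.warning("%s: dropped %d events with non-finite intensities", source, n_dropped)
        log.append({"step": "read", "dropped_nonfinite": n_dropped})
        events = events[finite]
        if time_s is not None:
            time_s = time_s[finite]
    return events, time_s


def _read_csv(path) -> EventTable:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValueError(f"unparseable CSV file {path}: {exc}") from exc
    if df.columns.size == 0 or any(str(c).startswith("Unnamed") for c in df.columns):
        raise ValueError(f"CSV file {path} is missing a channel header row")
    time_s = None
    if _TIME_COLUMN in df.columns:
        time_s = df.pop(_TIME_COLUMN).to_numpy(dtype=float)
    channels = [Channel(name=str(c), role=_role_from_name(str(c))) for c in df.columns]
    events = df.to_numpy(dtype=float)
    log: list[dict] = []
    events, time_s = _drop_nonfinite(events, time_s, log, str(path))
    return EventTable(events=events, channels=channels, time_s=time_s, log=log)


def _write_csv(table: EventTable, path) -> None:
    table.to_dataframe().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# FCS I/O — minimal list-mode support (datatype F write; F and I read)
# ---------------------------------------------------------------------------

_FCS_DELIM = b"/"


def _write_fcs(table: EventTable, path) -> None:
    names = list(table.channel_names)
    data = table.events.astype("<f4")
    timestep = 1.0
    if table.time_s is not None:
        names = names + ["Time"]
        data = np.column_stack([data, (table.time_s / timestep).astype("<f4")])
    n_events, n_par = data.shape
    payload = data.tobytes()

    keywords = {
        "$BEGINANALYSIS": "0", "$ENDANALYSIS": "0",
        "$BEGINSTEXT": "0", "$ENDSTEXT": "0",
        "$BYTEORD": "1,2,3,4", "$DATATYPE": "F", "$MODE": "L",
        "$NEXTDATA": "0", "$PAR": str(n_par), "$TOT": str(n_events),
    }
    if table.time_s is not None:
        keywords["$TIMESTEP"] = repr(timestep)
    for i, name in enumerate(names, start=1):
        keywords[f"$P{i}N"] = name
        keywords[f"$P{i}B"] = "32"
        keywords[f"$P{i}E"] = "0,0"
        col_max = float(data[:, i - 1].max()) if n_events else 1.0
        keywords[f"$P{i}R"] = str(int(max(col_max, 1.0)) + 1)

    def render_text(begindata: int, enddata: int) -> bytes:
        kw = dict(keywords)
        kw["$BEGINDATA"] = str(begindata)
        kw["$ENDDATA"] = str(enddata)
        parts = [_FCS_DELIM]
        for key, value in kw.items():
            parts.append(key.encode("ascii") + _FCS_DELIM + str(value).encode("utf-8") + _FCS_DELIM)
        return b"".join(parts)

    header_len = 58
    text_start = header_len
    # offsets appear inside TEXT; iterate until the layout is stable
    begindata, enddata = 0, 0
    for _ in range(4):
        text = render_text(begindata, enddata)
        new_begin = text_start + len(text)
        new_end = new_begin + len(payload) - 1 if payload else 0
        if (new_begin, new_end) == (begindata, enddata):
            break
        begindata, enddata = new_begin, new_end
    text = render_text(begindata, enddata)
    text_end = text_start + len(text) - 1

    def offset_field(value: int) -> bytes:
        s = str(value)
        if len(s) > 8:
            s = "0"  # too large for the header; TEXT keywords carry the truth
        return s.rjust(8).encode("ascii")

    header = b"FCS3.1    " + offset_field(text_start) + offset_field(text_end)
    header += offset_field(begindata if enddata <= 99999999 else 0)
    header += offset_field(enddata if enddata <= 99999999 else 0)
    header += offset_field(0) + offset_field(0)
    assert len(header) == 58
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(payload)


def _parse_fcs_text(raw: bytes) -> dict[str, str]:
    if not raw:
        raise ValueError("FCS TEXT segment is empty")
    delim = raw[0:1]
    body = raw[1:]
    if body.endswith(delim):
        body = body[:-1]
    # double-delimiter escaping is replaced after splitting on single delimiters
    parts = body.split(delim)
    if len(parts) % 2 != 0:
        raise ValueError("FCS TEXT segment has an odd number of tokens")
    kw: dict[str, str] = {}
    for key, value in zip(parts[::2], parts[1::2]):
        kw[key.decode("utf-8", "replace").strip().upper()] = value.decode("utf-8", "replace")
    return kw


def _read_fcs(path) -> EventTable:
    with open(path, "rb") as fh:
        raw = fh.read()
    if len(raw) < 58 or not raw[:6] in (b"FCS3.0", b"FCS3.1"):
        raise ValueError(f"{path}: not an FCS 3.0/3.1 file")

    def header_offset(lo: int, hi: int) -> int:
        field_ = raw[lo:hi].decode("ascii", "replace").strip()
        return int(field_) if field_ else 0

    text_start = header_offset(10, 18)
    text_end = header_offset(18, 26)
    kw = _parse_fcs_text(raw[text_start:text_end + 1])

    def require(key: str) -> str:
        if key not in kw:
            raise ValueError(f"{path}: FCS file missing required keyword {key}")
        return kw[key]

    mode = require("$MODE")
    if mode != "L":
        raise ValueError(f"{path}: unsupported FCS $MODE {mode!r} (only list mode)")
    datatype = require("$DATATYPE")
    if datatype not in ("F", "I"):
        raise ValueError(f"{path}: unsupported FCS $DATATYPE {datatype!r}")
    n_par = int(require("$PAR"))
    n_tot = int(require("$TOT"))
    byteord = require("$BYTEORD")
    endian = "<" if byteord.startswith("1") else ">"

    data_start = header_offset(26, 34) or int(kw.get("$BEGINDATA", "0"))
    data_end = header_offset(34, 42) or int(kw.get("$ENDDATA", "0"))
    if "$BEGINDATA" in kw and int(kw["$BEGINDATA"]):
        data_start = int(kw["$BEGINDATA"])
        data_end = int(kw["$ENDDATA"])
    payload = raw[data_start:data_end + 1] if n_tot else b""

    names = [kw.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)]
    bits = [int(kw.get(f"$P{i}B", "32")) for i in range(1, n_par + 1)]
    if datatype == "F":
        if any(b != 32 for b in bits):
            raise ValueError(f"{path}: $DATATYPE F requires $PnB 32")
        data = np.frombuffer(payload, dtype=f"{endian}f4", count=n_tot * n_par)
    else:
        if len(set(bits)) != 1 or bits[0] not in (16, 32):
            raise ValueError(f"{path}: integer FCS needs uniform $PnB of 16 or 32")
        data = np.frombuffer(payload, dtype=f"{endian}u{bits[0] // 8}", count=n_tot * n_par)
    data = data.reshape(n_tot, n_par).astype(float)

    time_s = None
    time_idx = next((i for i, n in enumerate(names) if n.upper() == "TIME"), None)
    if time_idx is not None:
        timestep = float(kw.get("$TIMESTEP", "1.0"))
        time_s = data[:, time_idx] * timestep
        keep = [i for i in range(n_par) if i != time_idx]
        data = data[:, keep]
        names = [names[i] for i in keep]

    channels = [Channel(name=n, role=_role_from_name(n)) for n in names]
    log: list[dict] = []
    data, time_s = _drop_nonfinite(data, time_s, log, str(path))
    return EventTable(events=data, channels=channels, time_s=time_s, log=log)


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def _infer_format(path, fmt: str | None) -> str:
    if fmt is not None:
        fmt = fmt.upper()
        if fmt not in ("FCS", "CSV"):
            raise ValueError(f"unknown event file format {fmt!r}")
        return fmt
    ext = os.path.splitext(str(path))[1].lower()
    return "FCS" if ext == ".fcs" else "CSV"


def read_events(path, format: str | None = None) -> EventTable:
    """Read an event table from a per-event CSV or an FCS 3.0/3.1 file.

    Events with any non-finite intensity are dropped (the count is logged and
    recorded in the table's ``log``). Event order is otherwise preserved.
    """
    if not os.path.exists(str(path)):
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    return _read_csv(path) if fmt == "CSV" else _read_fcs(path)


def write_events(table: EventTable, path, format: str | None = None) -> None:
    """Write an event table as CSV (lossless) or FCS 3.1 (float32 data)."""
    fmt = _infer_format(path, format)
    if fmt == "CSV":
        _write_csv(table, path)
    else:
        _write_fcs(table, path)


def apply_compensation(table: EventTable, spillover: SpilloverMatrix) -> EventTable:
    """Spectral compensation: solve ``observed = true @ S`` for the true signals.

    Only the fluorescence columns named in the spillover matrix are unmixed;
    scatter and time columns are untouched.
    """
    fluo = table.fluorescence_channels()
    missing = [n for n in spillover.channel_names if n not in fluo]
    if missing:
        raise KeyError(f"spillover channels not in table's fluorescence channels: {missing}")
    uncovered = [n for n in fluo if n not in spillover.channel_names]
    if uncovered:
        raise KeyError(f"fluorescence channels not covered by spillover: {uncovered}")
    idx = [table.channel_names.index(n) for n in spillover.channel_names]
    observed = table.events[:, idx]
    # true = observed @ S^-1  <=>  S.T @ true.T = observed.T
    true = np.linalg.solve(spillover.matrix.T, observed.T).T
    events = table.events.copy()
    events[:, idx] = true
    out = replace(table, events=events, channels=list(table.channels),
                  sample_meta=dict(table.sample_meta), log=list(table.log))
    out.log.append({"step": "compensation", "channels": list(spillover.channel_names)})
    return out


def apply_gate(table: EventTable, gate: Gate) -> EventTable:
    """Keep the events inside the (closed) gate region.

    A gating report with kept count and fraction is appended to the table log.
    """
    mask = gate.mask(table)
    out = table.take(mask)
    kept = int(mask.sum())
    out.log.append({
        "step": "gate",
        "kind": gate.kind,
        "channels": list(gate.channels),
        "kept": kept,
        "fraction": kept / table.n_events if table.n_events else float("nan"),
    })
    return out


def viability_fractions(table: EventTable, necrosis_channel: str,
                        apoptosis_channel: str,
                        thresholds: tuple[float, float]) -> dict[str, float]:
    """Quadrant fractions on a necrosis marker x apoptosis marker plane.

    An event is marker-positive when its intensity is strictly above the
    threshold. The double-negative fraction is the "living" readout (the
    fraction of necrosis- and apoptosis-marker negative cells).
    """
    if table.n_events == 0:
        raise ValueError("viability fractions are undefined for an empty table")
    t_nec, t_apo = thresholds
    if not (np.isfinite(t_nec) and np.isfinite(t_apo)):
        raise ValueError("thresholds must be finite")
    nec = table.column(necrosis_channel) > t_nec
    apo = table.column(apoptosis_channel) > t_apo
    n = table.n_events
    return {
        "living": float((~nec & ~apo).sum()) / n,
        "necrotic_only": float((nec & ~apo).sum()) / n,
        "apoptotic_only": float((~nec & apo).sum()) / n,
        "double_positive": float((nec & apo).sum()) / n,
    }
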