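"""Polysomnogram I/O: EDF signals, stage annotations, epoch segmentation.

Reads European Data Format (EDF, 16-bit) recordings together with per-epoch
sleep-stage annotations (a minimal SHHS-style XML dialect or a plain
``epoch_index,stage`` CSV), z-score normalises each channel over the whole
recording, cuts the signals into 30-second epochs at each channel's native
sampling rate, and aligns the stage labels.

Stage vocabulary: classic R&K tokens (W, S1..S4, REM, movement/unscored)
and AASM tokens (W, N1..N3, REM) are both accepted, as are SHHS numeric
codes (0=W, 1..4=S1..S4, 5=REM, 9=unscored).  S3 and S4 merge into N3; the
3-class scheme merges N1/N2/N3 into N.
"""

from __future__ import annotations

import logging
import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "EPOCH_SECONDS",
    "ChannelEpochs",
    "EpochedRecording",
    "map_stage",
    "is_scored",
    "read_edf",
    "write_edf",
    "read_annotations",
    "write_annotations",
    "read_recording",
    "UnknownStageError",
    "NoScoredEpochsError",
    "EdfFormatError",
]

logger = logging.getLogger(__name__)

EPOCH_SECONDS = 30

# raw annotation token -> 5-class label; movement / unscored -> None
_STAGE_MAP_5: dict[str, str | None] = {
    "W": "W", "WAKE": "W", "0": "W",
    "S1": "N1", "N1": "N1", "1": "N1",
    "S2": "N2", "N2": "N2", "2": "N2",
    "S3": "N3", "3": "N3",
    "S4": "N3", "4": "N3",
    "N3": "N3",
    "REM": "REM", "R": "REM", "5": "REM",
    "M": None, "MOVEMENT": None, "MT": None, "?": None, "9": None,
    "UNSCORED": None, "U": None,
}
_TO_3 = {"W": "W", "N1": "N", "N2": "N", "N3": "N", "REM": "REM"}

STAGES_5 = ("W", "N1", "N2", "N3", "REM")
STAGES_3 = ("W", "N", "REM")


class UnknownStageError(ValueError):
    """Annotation token outside the supported stage vocabulary."""


class NoScoredEpochsError(ValueError):
    """Signals and annotations share no scored 30-s epoch."""


class EdfFormatError(ValueError):
    """Malformed EDF header or truncated record payload."""


def is_scored(token) -> bool:
    """True if the token denotes a scored sleep stage (not movement/unscored)."""
    key = str(token).strip().upper()
    if key not in _STAGE_MAP_5:
        raise UnknownStageError(f"unknown stage token {token!r}")
    return _STAGE_MAP_5[key] is not None


def map_stage(token, scheme: int = 5) -> str:
    """Map a raw annotation token to its 5-class or 3-class label."""
    key = str(token).strip().upper()
    if key not in _STAGE_MAP_5:
        raise UnknownStageError(f"unknown stage token {token!r}")
    mapped = _STAGE_MAP_5[key]
    if mapped is None:
        raise UnknownStageError(f"token {token!r} is not a scored stage")
    if scheme == 5:
        return mapped
    if scheme == 3:
        return _TO_3[mapped]
    raise ValueError(f"scheme must be 3 or 5, got {scheme}")


@dataclass
class ChannelEpochs:
    """One channel cut into epochs: n_epochs x (30 * rate) samples."""

    rate: float
    data: np.ndarray


@dataclass
class EpochedRecording:
    """Per-channel epoch matrices with one aligned stage label per epoch."""

    channels: dict[str, ChannelEpochs]
    stages: np.ndarray  # raw (scored) tokens, one per epoch

    @property
    def n_epochs(self) -> int:
        return len(self.stages)

    def __post_init__(self) -> None:
        for name, ch in self.channels.items():
            if ch.data.shape[0] != self.n_epochs:
                raise ValueError(
                    f"channel {name}: {ch.data.shape[0]} epochs != "
                    f"{self.n_epochs} labels"
                )
            expected = int(round(EPOCH_SECONDS * ch.rate))
            if ch.data.shape[1] != expected:
                raise ValueError(
                    f"channel {name}: {ch.data.shape[1]} samples/epoch, "
                    f"expected {expected}"
                )


# ---------------------------------------------------------------------------
# EDF (16-bit) reader / writer
# ---------------------------------------------------------------------------
# Minimal but standard-conforming EDF: ASCII header of 256 + 256*ns bytes,
# then data records of little-endian int16 samples, one second per record.

def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")[:width]
    return b + b" " * (width - len(b))


def write_edf(
    path: str | Path,
    signals: dict[str, tuple[float, np.ndarray]],
    *,
    physical_dim: str = "uV",
    record_seconds: float = 1.0,
) -> None:
    """Write channels (name -> (rate_hz, samples)) to a 16-bit EDF file.

    Physical scaling is chosen per channel from the data range; a trailing
    partial record is truncated with a warning.
    """
    path = Path(path)
    names = list(signals)
    rates = [signals[n][0] for n in names]
    arrays = [np.asarray(signals[n][1], dtype=float) for n in names]
    spr = [int(round(r * record_seconds)) for r in rates]
    for n, r, s in zip(names, rates, spr):
        if abs(s - r * record_seconds) > 1e-9:
            raise ValueError(f"channel {n}: rate {r} not integer per record")
    n_records = min(len(a) // s for a, s in zip(arrays, spr))
    if any(len(a) != n_records * s for a, s in zip(arrays, spr)):
        warnings.warn("truncating trailing partial EDF record")

    phys_min, phys_max, scaled = [], [], []
    for a, s in zip(arrays, spr):
        a = a[: n_records * s]
        amax = float(np.max(np.abs(a))) if a.size else 1.0
        amax = amax if amax > 0 else 1.0
        pmin, pmax = -amax, amax
        gain = (pmax - pmin) / (32767 - (-32768))
        dig = np.clip(np.round((a - pmin) / gain) + (-32768), -32768, 32767)
        phys_min.append(pmin)
        phys_max.append(pmax)
        scaled.append(dig.astype("<i2"))

    ns = len(names)
    header = b"".join(
        [
            _pad("0", 8),
            _pad("X X X X", 80),
            _pad("Startdate X X X X", 80),
            _pad("01.01.00", 8),
            _pad("00.00.00", 8),
            _pad(str(256 * (1 + ns)), 8),
            _pad("", 44),
            _pad(str(n_records), 8),
            _pad(f"{record_seconds:g}", 8),
            _pad(str(ns), 4),
        ]
    )
    fields = [
        [_pad(n, 16) for n in names],
        [_pad("", 80)] * ns,
        [_pad(physical_dim, 8)] * ns,
        [_pad(f"{v:.6g}", 8) for v in phys_min],
        [_pad(f"{v:.6g}", 8) for v in phys_max],
        [_pad("-32768", 8)] * ns,
        [_pad("32767", 8)] * ns,
        [_pad("", 80)] * ns,
        [_pad(str(s), 8) for s in spr],
        [_pad("", 32)] * ns,
    ]
    with open(path, "wb") as f:
        f.write(header)
        for fld in fields:
            f.write(b"".join(fld))
        for rec in range(n_records):
            for a, s in zip(scaled, spr):
                f.write(a[rec * s : (rec + 1) * s].tobytes())


def read_edf(path: str | Path) -> dict[str, tuple[float, np.ndarray]]:
    """Read a 16-bit EDF file into {channel: (rate_hz, physical_samples)}."""
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < 256:
        raise EdfFormatError(f"{path}: truncated EDF header")
    try:
        n_records = int(raw[236:244].decode("ascii").strip())
        rec_dur = float(raw[244:252].decode("ascii").strip())
        ns = int(raw[252:256].decode("ascii").strip())
    except ValueError as exc:
        raise EdfFormatError(f"{path}: malformed EDF header: {exc}") from exc
    if len(raw) < 256 * (1 + ns):
        raise EdfFormatError(f"{path}: truncated signal headers")

    def field(offset: int, width: int) -> list[str]:
        base = 256 + offset * ns
        return [
            raw[base + i * width : base + (i + 1) * width].decode("ascii").strip()
            for i in range(ns)
        ]

    # per-signal header block offsets (in bytes, cumulative)
    widths = [16, 80, 8, 8, 8, 8, 8, 80, 8, 32]
    offsets = np.concatenate([[0], np.cumsum(widths)])[:-1]
    labels = field(int(offsets[0]), 16)
    phys_min = [float(v) for v in field(int(offsets[3]) , 8)]
    phys_max = [float(v) for v in field(int(offsets[4]), 8)]
    dig_min = [int(v) for v in field(int(offsets[5]), 8)]
    dig_max = [int(v) for v in field(int(offsets[6]), 8)]
    spr = [int(v) for v in field(int(offsets[8]), 8)]

    payload = raw[256 * (1 + ns) :]
    rec_len = sum(spr) * 2
    if len(payload) < n_records * rec_len:
        raise EdfFormatError(f"{path}: truncated data records")
    out: dict[str, tuple[float, np.ndarray]] = {}
    samples = {i: np.empty(n_records * spr[i]) for i in range(ns)}
    for rec in range(n_records):
        base = rec * rec_len
        for i in range(ns):
            width = spr[i] * 2
            dig = np.frombuffer(payload, dtype="<i2", count=spr[i],
                                offset=base)
            gain = (phys_max[i] - phys_min[i]) / (dig_max[i] - dig_min[i])
            samples[i][rec * spr[i] : (rec + 1) * spr[i]] = (
                (dig.astype(float) - dig_min[i]) * gain + phys_min[i]
            )
            base += width
    for i in range(ns):
        out[labels[i]] = (spr[i] / rec_dur, samples[i])
    return out


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------

def write_annotations(path: str | Path, stages, dialect: str = "csv") -> None:
    """Write per-epoch stage tokens as CSV or the SHHS-style XML subset."""
    path = Path(path)
    if dialect == "csv":
        lines = ["epoch_index,stage"]
        lines += [f"{i},{s}" for i, s in enumerate(stages)]
        path.write_text("\n".join(lines) + "\n")
    elif dialect == "xml":
        root = ET.Element("PSGAnnotation")
        seq = ET.SubElement(root, "SleepStages")
        for s in stages:
            ET.SubElement(seq, "SleepStage").text = str(s)
        ET.ElementTree(root).write(path, encoding="unicode")
    else:
        raise ValueError(f"unknown annotation dialect {dialect!r}")


def read_annotations(path: str | Path) -> list[str]:
    """Read per-epoch stage tokens (CSV `epoch_index,stage` or XML subset)."""
    path = Path(path)
    text = path.read_text()
    if text.lstrip().startswith("<"):
        root = ET.fromstring(text)
        nodes = root.findall(".//SleepStage")
        if not nodes:
            raise ValueError(f"{path}: no SleepStage elements")
        return [n.text.strip() for n in nodes]
    tokens: list[str] = []
    rows = [ln for ln in text.splitlines() if ln.strip()]
    start = 1 if rows and rows[0].lower().replace(" ", "").startswith("epoch_index") else 0
    for ln in rows[start:]:
        parts = ln.split(",")
        if len(parts) != 2:
            raise ValueError(f"{path}: bad annotation row {ln!r}")
        tokens.append(parts[1].strip())
    return tokens


# ---------------------------------------------------------------------------
# Recording assembly
# ---------------------------------------------------------------------------

def read_recording(
    edf_path: str | Path,
    annotation_path: str | Path,
    channels: list[str] | None = None,
) -> EpochedRecording:
    """Read EDF + annotations into z-scored, labelled 30-s epochs.

    Channels are z-scored over the whole recording, epoch counts from signal
    duration and annotations are reconciled by truncating to the shorter
    (with a warning), and movement/unscored epochs are dropped with a logged
    count.
    """
    signals = read_edf(edf_path)
    if channels is not None:
        missing = [c for c in channels if c not in signals]
        if missing:
            raise KeyError(f"EDF lacks channel(s): {missing}")
        signals = {c: signals[c] for c in channels}
    tokens = read_annotations(annotation_path)

    n_sig_epochs = min(
        int(len(data) // (EPOCH_SECONDS * rate)) for rate, data in signals.values()
    )
    n = min(n_sig_epochs, len(tokens))
    if n == 0:
        raise NoScoredEpochsError(
            "signals and annotations share no complete 30-s epoch"
        )
    if n != n_sig_epochs or n != len(tokens):
        warnings.warn(
            f"epoch count mismatch: {n_sig_epochs} from signals vs "
            f"{len(tokens)} annotated; truncating to {n}"
        )
    tokens = tokens[:n]
    keep = np.array([is_scored(t) for t in tokens])
    dropped = int((~keep).sum())
    if dropped:
        logger.info("dropping %d movement/unscored epoch(s)", dropped)
    if not keep.any():
        raise NoScoredEpochsError("no scored epochs after dropping unscored")

    out_channels: dict[str, ChannelEpochs] = {}
    for name, (rate, data) in signals.items():
        spe = int(round(EPOCH_SECONDS * rate))
        sd = float(np.std(data))
        z = (data - float(np.mean(data))) / (sd if sd > 0 else 1.0)
        mat = z[: n * spe].reshape(n, spe)
        out_channels[name] = ChannelEpochs(rate=rate, data=mat[keep])
    stages = np.array([t for t, k in zip(tokens, keep) if k], dtype=object)
    return EpochedRecording(channels=out_channels, stages=stages)
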