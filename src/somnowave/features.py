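"""Tsallis-entropy features of wavelet sub-bands.

Every 30-s epoch of every channel is decomposed into six sub-bands and each
sub-band is summarised by a single Tsallis entropy value, giving 6 features
per channel per epoch (30 for the full five-channel montage).

The entropy of a coefficient sequence ``x`` of length N is, in the default
``normalized`` mode, the order-2 (quadratic) Tsallis entropy of the
coefficient energy distribution:

    p_i = x_i**2 / sum_j x_j**2,      TE = sum_i (p_i - p_i**2) = 1 - sum_i p_i**2

which is scale invariant, bounded in ``[0, 1 - 1/N]``, zero when all energy
sits in one coefficient and maximal when energy is spread uniformly.  The
``raw`` mode evaluates ``sum_i (x_i - x_i**2)`` on the coefficients
directly; it is scale dependent and retained for literal fidelity with the
nonextensive-statistics formulation applied to unnormalised coefficients.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .filterbank import DesignedFilterBank
from .transform import dwt5

__all__ = [
    "tsallis_entropy",
    "build_feature_table",
    "FeatureTable",
    "BAND_NAMES",
    "MissingChannelError",
]

logger = logging.getLogger(__name__)

# Coarse-to-fine sub-band order used for feature columns.
BAND_NAMES = ("a5", "d5", "d4", "d3", "d2", "d1")


class MissingChannelError(KeyError):
    """A requested channel is absent from the recording."""


def tsallis_entropy(x: np.ndarray, mode: str = "normalized") -> float:
    """Tsallis entropy of one coefficient sequence.

    ``normalized``: q=2 Tsallis entropy 1 - sum p_i**2 of the energy
    distribution p_i = x_i**2 / sum x**2; an all-zero sequence is degenerate
    and returns 0 with a warning.  ``raw``: literal sum(x - x**2).
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty coefficient sequence")
    if mode == "raw":
        return float(np.sum(x - x * x))
    if mode != "normalized":
        raise ValueError(f"unknown mode {mode!r}")
    energy = x * x
    total = energy.sum()
    if total <= 0.0:
        logger.warning("all-zero sub-band: Tsallis entropy defined as 0")
        return 0.0
    p = energy / total
    return float(1.0 - np.dot(p, p))


def _batch_entropy(coeffs: np.ndarray, mode: str) -> np.ndarray:
    """Entropy of each row of a 2-D coefficient array."""
    if mode == "raw":
        return np.sum(coeffs - coeffs * coeffs, axis=-1)
    energy = coeffs * coeffs
    total = energy.sum(axis=-1)
    degenerate = total <= 0.0
    safe_total = np.where(degenerate, 1.0, total)
    p = energy / safe_total[..., None]
    te = 1.0 - np.sum(p * p, axis=-1)
    if degenerate.any():
        logger.warning(
            "%d degenerate (all-zero) sub-band(s): entropy set to 0",
            int(degenerate.sum()),
        )
        te = np.where(degenerate, 0.0, te)
    return te


@dataclass
class FeatureTable:
    """Epochs x (channels x sub-bands) Tsallis-entropy matrix with labels."""

    values: np.ndarray
    labels: np.ndarray
    columns: list[str]
    channel_set: tuple[str, ...]
    scheme: int

    @property
    def n_epochs(self) -> int:
        return self.values.shape[0]

    def select_channels(self, channels: tuple[str, ...]) -> "FeatureTable":
        """Column-subset view for a smaller channel combination."""
        missing = [c for c in channels if c not in self.channel_set]
        if missing:
            raise MissingChannelError(f"channels not in table: {missing}")
        idx = []
        cols = []
        for ch in channels:
            for band in BAND_NAMES:
                name = f"{ch}_{band}"
                idx.append(self.columns.index(name))
                cols.append(name)
        return FeatureTable(
            values=self.values[:, idx],
            labels=self.labels,
            columns=cols,
            channel_set=tuple(channels),
            scheme=self.scheme,
        )

    def relabel(self, scheme: int) -> "FeatureTable":
        """Re-map labels into another class scheme (values are shared)."""
        from .psg_io import map_stage

        labels = np.array([map_stage(s, scheme) for s in self.labels], dtype=object)
        return FeatureTable(
            values=self.values,
            labels=labels,
            columns=self.columns,
            channel_set=self.channel_set,
            scheme=scheme,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.columns)
        df["stage"] = self.labels
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, scheme: int | None = None) -> "FeatureTable":
        df = pd.read_csv(path)
        cols = [c for c in df.columns if c != "stage"]
        channels = []
        for c in cols:
            ch = c.rsplit("_", 1)[0]
            if ch not in channels:
                channels.append(ch)
        if scheme is None:
            scheme = 3 if set(df["stage"]) <= {"W", "N", "REM"} else 5
        return cls(
            values=df[cols].to_numpy(dtype=float),
            labels=df["stage"].to_numpy(dtype=object),
            columns=cols,
            channel_set=tuple(channels),
            scheme=scheme,
        )


def build_feature_table(
    epochs,
    bank: DesignedFilterBank,
    channel_set: tuple[str, ...] | None = None,
    scheme: int = 5,
    mode: str = "normalized",
) -> FeatureTable:
    """Decompose every epoch of every channel and tabulate sub-band entropies.

    Columns are channel-major in ``channel_set`` order, with the six
    sub-bands per channel ordered coarse to fine (a5, d5, ..., d1).  Labels
    are mapped into the requested 3- or 5-class scheme.
    """
    from .psg_io import map_stage

    if channel_set is None:
        channel_set = tuple(epochs.channels)
    missing = [c for c in channel_set if c not in epochs.channels]
    if missing:
        raise MissingChannelError(f"recording lacks channel(s): {missing}")

    blocks = []
    columns = []
    for ch in channel_set:
        data = epochs.channels[ch].data  # n_epochs x samples
        bands = dwt5(data, bank).bands
        for band, name in zip(bands, BAND_NAMES):
            blocks.append(_batch_entropy(band, mode))
            columns.append(f"{ch}_{name}")
    values = np.column_stack(blocks)
    labels = np.array([map_stage(s, scheme) for s in epochs.stages], dtype=object)
    return FeatureTable(
        values=values,
        labels=labels,
        columns=columns,
        channel_set=tuple(channel_set),
        scheme=scheme,
    )
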