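"""Five-level orthogonal wavelet decomposition of 30-second epochs.

Each epoch is split by a 5-stage cascade of the two-channel analysis bank
(periodic extension, decimation by 2) into one approximation band and five
detail bands.  With an orthonormal bank and periodic extension the transform
is an orthogonal map: energy is conserved exactly and :func:`idwt5` inverts
:func:`dwt5` to machine precision.  Odd-length intermediates are zero-padded
on the right to even length; the pads are recorded so the inverse can drop
them.

All operations accept 1-D signals or 2-D arrays of stacked epochs
(``n_epochs x n_samples``) and transform along the last axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .filterbank import DesignedFilterBank

__all__ = ["SubbandSet", "dwt5", "idwt5", "TooShortError"]

N_LEVELS = 5
MIN_LENGTH = 2**N_LEVELS


class TooShortError(ValueError):
    """Input epoch shorter than the 2**5 samples needed for 5 levels."""


@dataclass
class SubbandSet:
    """Six sub-bands of one (or a batch of) epoch(s).

    ``details[i]`` holds the level-(i+1) detail band, so ``details[0]`` is
    the finest (highest-frequency) band and ``details[4]`` the coarsest;
    ``approximation`` is the level-5 low-pass residue.
    """

    approximation: np.ndarray
    details: list[np.ndarray]
    source_length: int
    level: int = N_LEVELS
    pads: list[int] = field(default_factory=lambda: [0] * N_LEVELS)

    @property
    def bands(self) -> list[np.ndarray]:
        """Coarse-to-fine ordering: approximation, detail5, ..., detail1."""
        return [self.approximation] + self.details[::-1]


def _analysis_stage(x: np.ndarray, filt: np.ndarray) -> np.ndarray:
    """Periodic convolve-decimate: y[n] = sum_k filt[k] x[(2n+k) mod N]."""
    n = x.shape[-1]
    taps = len(filt)
    reps = 1 + max(0, -(-(taps - 1) // n))  # enough copies when n < taps
    ext = np.concatenate([x] * reps, axis=-1)[..., : n + taps - 1]
    out = np.zeros(x.shape[:-1] + (n // 2,), dtype=float)
    for k, c in enumerate(filt):
        out += c * ext[..., k : k + n - 1 : 2]
    return out


def _synthesis_stage(
    lo: np.ndarray, hi: np.ndarray, h: np.ndarray, g: np.ndarray
) -> np.ndarray:
    """Adjoint of the analysis stage (exact inverse for an orthonormal bank)."""
    n = 2 * lo.shape[-1]
    up = np.zeros(lo.shape[:-1] + (n,), dtype=float)
    out = np.zeros_like(up)
    for filt, band in ((h, lo), (g, hi)):
        up[...] = 0.0
        up[..., ::2] = band
        for k, c in enumerate(filt):
            out += c * np.roll(up, k, axis=-1)
    return out


def dwt5(x: np.ndarray, bank: DesignedFilterBank) -> SubbandSet:
    """Five-level decomposition of epoch(s) ``x`` along the last axis."""
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    if n < MIN_LENGTH:
        raise TooShortError(
            f"epoch length {n} < {MIN_LENGTH} samples required for "
            f"{N_LEVELS} decomposition levels"
        )
    h, g = bank.lowpass, bank.highpass
    details: list[np.ndarray] = []
    pads: list[int] = []
    cur = x
    for _ in range(N_LEVELS):
        pad = cur.shape[-1] % 2
        if pad:
            zeros = np.zeros(cur.shape[:-1] + (1,), dtype=float)
            cur = np.concatenate([cur, zeros], axis=-1)
        pads.append(pad)
        details.append(_analysis_stage(cur, g))
        cur = _analysis_stage(cur, h)
    return SubbandSet(
        approximation=cur, details=details, source_length=n, pads=pads
    )


def idwt5(s: SubbandSet, bank: DesignedFilterBank) -> np.ndarray:
    """Invert :func:`dwt5`, reproducing the source epoch(s)."""
    h, g = bank.lowpass, bank.highpass
    if len(s.details) != N_LEVELS:
        raise ValueError(f"expected {N_LEVELS} detail bands, got {len(s.details)}")
    cur = np.asarray(s.approximation, dtype=float)
    for level in range(N_LEVELS - 1, -1, -1):
        d = np.asarray(s.details[level], dtype=float)
        if d.shape != cur.shape:
            raise ValueError(
                f"detail band at level {level + 1} has shape {d.shape}, "
                f"expected {cur.shape}"
            )
        cur = _synthesis_stage(cur, d, h, g)
        if s.pads[level]:
            cur = cur[..., : cur.shape[-1] - s.pads[level]]
    if cur.shape[-1] != s.source_length:
        raise ValueError(
            f"reconstructed length {cur.shape[-1]} != source {s.source_length}"
        )
    return cur
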