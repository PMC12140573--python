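"""Morlet time-frequency decomposition and portrait extraction.

Single-trial signals are convolved with complex Morlet wavelets whose
spectral width scales with frequency, f0 / sigma_f = 7 (equivalently
sigma_t = 7 / (2 pi f0)), on a 0.5-Hz grid.  Raw power is log-transformed
and normalized per subject and region against the mean log power over all
of that subject's trials and time points at each frequency — the task has
no clean baseline interval, so the across-trial mean takes its place.
Averaging the normalized maps over each (movement phase) x (band) cell
yields the 12 elements a region contributes to the 48-element portrait.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .elements import (
    BANDS,
    EPOCHS,
    REGIONS,
    BandEpochSpec,
    element_columns,
)
from .io import META_COLUMNS, SignalSet

__all__ = [
    "WaveletConfig",
    "TFMap",
    "morlet_transform",
    "normalize_power",
    "extract_portrait",
    "portraits_from_signals",
]


def _default_freqs() -> np.ndarray:
    # 2-60 Hz so the gamma band (36-60 Hz) is fully covered
    return np.arange(2.0, 60.0 + 1e-9, 0.5)


@dataclass
class WaveletConfig:
    """Morlet wavelet family: center-frequency grid and width ratio."""

    f0_over_sigma_f: float = 7.0
    freqs: np.ndarray = field(default_factory=_default_freqs)
    fs: float = 256.0

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.f0_over_sigma_f <= 0:
            raise ValueError("f0_over_sigma_f must be positive")
        if self.freqs.size == 0 or np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if self.freqs.max() >= self.fs / 2:
            raise ValueError("max frequency must be below Nyquist")

    def sigma_t(self, f0: float) -> float:
        """Temporal SD of the wavelet at center frequency f0 (s)."""
        return self.f0_over_sigma_f / (2.0 * np.pi * f0)

    def kernel(self, f0: float) -> np.ndarray:
        """L2-normalized complex Morlet kernel at f0, support +-5 sigma_t."""
        st = self.sigma_t(f0)
        half = int(np.ceil(5.0 * st * self.fs))
        t = np.arange(-half, half + 1) / self.fs
        w = np.exp(-(t**2) / (2.0 * st**2)) * np.exp(2j * np.pi * f0 * t)
        return w / np.linalg.norm(w)

    def min_samples(self) -> int:
        """Shortest admissible signal: the 3-sigma support at min frequency.

        Below this length no sample of the lowest-frequency estimate is
        free of edge leakage; such signals are rejected outright.
        """
        st = self.sigma_t(float(self.freqs.min()))
        return 2 * int(np.ceil(3.0 * st * self.fs)) + 1


@dataclass
class TFMap:
    """Per-trial, per-region time x frequency power map.

    ``power`` has shape (n_times, n_freqs): nonnegative raw power, or real
    log-normalized values once :func:`normalize_power` has run
    (``log_normalized`` flags which).  ``edge_mask`` marks samples within
    3 sigma_t of either signal end, where wavelet estimates lean on data
    beyond the segment.
    """

    trial_id: int
    region: str
    times: np.ndarray
    freqs: np.ndarray
    power: np.ndarray
    onset: float
    offset: float
    subject: str = ""
    edge_mask: np.ndarray | None = None
    log_normalized: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.power.shape != (self.times.size, self.freqs.size):
            raise ValueError("power must be times x freqs")
        if not self.log_normalized and (self.power < 0).any():
            raise ValueError("raw power must be nonnegative")


def morlet_transform(
    signal: np.ndarray,
    config: WaveletConfig,
    times: np.ndarray | None = None,
    trial_id: int = 0,
    region: str = REGIONS[0],
    onset: float = 0.0,
    offset: float = 0.0,
    subject: str = "",
) -> TFMap:
    """Raw wavelet power |signal * Morlet(f)|^2 on the configured grid."""
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("signal must be 1-D")
    need = config.min_samples()
    if x.size < need:
        raise ValueError(
            f"signal of {x.size} samples is shorter than the longest wavelet "
            f"({need} samples at {config.freqs.min()} Hz)"
        )
    if times is None:
        times = np.arange(x.size) / config.fs
    power = np.empty((x.size, config.freqs.size))
    edge = np.zeros((x.size, config.freqs.size), dtype=bool)
    idx = np.arange(x.size)
    for j, f0 in enumerate(config.freqs):
        w = config.kernel(f0)
        conv = fftconvolve(x.astype(complex), w, mode="same")
        power[:, j] = np.abs(conv) ** 2
        guard = int(np.ceil(3.0 * config.sigma_t(f0) * config.fs))
        edge[:, j] = (idx < guard) | (idx >= x.size - guard)
    return TFMap(
        trial_id=trial_id,
        region=region,
        times=np.asarray(times, dtype=float),
        freqs=config.freqs.copy(),
        power=power,
        onset=onset,
        offset=offset,
        subject=subject,
        edge_mask=edge,
    )


def normalize_power(tfmaps: list[TFMap]) -> list[TFMap]:
    """Log-transform and center against the across-trial mean log power.

    All maps passed in one call are treated as the trials of one subject
    and region: out(t, f) = log power(t, f) - mean over all trials and
    time points of log power at f.  Power must be strictly positive.
    """
    if not tfmaps:
        raise ValueError("no maps to normalize")
    freqs = tfmaps[0].freqs
    for m in tfmaps:
        if m.log_normalized:
            raise ValueError("maps are already log-normalized")
        if m.freqs.shape != freqs.shape or not np.allclose(m.freqs, freqs):
            raise ValueError("all maps must share the frequency grid")
        if (m.power <= 0).any():
            raise ValueError(
                f"trial {m.trial_id} region {m.region}: nonpositive power "
                "(degenerate input, cannot log-transform)"
            )
    logs = [np.log(m.power) for m in tfmaps]
    meanlog = np.vstack(logs).mean(axis=0)  # per frequency, pooled time+trials
    out = []
    for m, lp in zip(tfmaps, logs):
        out.append(
            TFMap(
                trial_id=m.trial_id,
                region=m.region,
                times=m.times,
                freqs=m.freqs,
                power=lp - meanlog,
                onset=m.onset,
                offset=m.offset,
                subject=m.subject,
                edge_mask=m.edge_mask,
                log_normalized=True,
            )
        )
    return out


def extract_portrait(
    tfmap: TFMap, spec: BandEpochSpec | None = None
) -> dict[tuple[str, str], float]:
    """Mean normalized power per (epoch, band) cell for one region.

    Returns the 12 values keyed by (epoch, band); assembling the four
    regions gives a full 48-element portrait row.
    """
    if spec is None:
        spec = BandEpochSpec()
    if not tfmap.log_normalized:
        raise ValueError("extract_portrait expects a log-normalized map")
    if tfmap.offset < tfmap.onset:
        raise ValueError(f"offset {tfmap.offset} precedes onset {tfmap.onset}")
    out = {}
    for epoch in EPOCHS:
        tmask = spec.epoch_mask(tfmap.times, epoch, tfmap.onset, tfmap.offset)
        if not tmask.any():
            raise ValueError(f"epoch {epoch!r} contains no time samples")
        for band in BANDS:
            fmask = spec.band_mask(tfmap.freqs, band)
            if not fmask.any():
                raise ValueError(f"band {band!r} contains no frequency bins")
            out[(epoch, band)] = float(tfmap.power[np.ix_(tmask, fmask)].mean())
    return out


def portraits_from_signals(
    signals: SignalSet,
    wavelet_config: WaveletConfig | None = None,
    spec: BandEpochSpec | None = None,
) -> pd.DataFrame:
    """Full pipeline: signals -> TF maps -> normalization -> trial table.

    Normalization is per subject and region, pooling that subject's trials.
    Output schema matches the standard 52-column trial table.
    """
    if wavelet_config is None:
        wavelet_config = WaveletConfig(fs=signals.fs)
    if spec is None:
        spec = BandEpochSpec()
    # group raw maps by (subject, region)
    groups: dict[tuple[str, str], list[TFMap]] = {}
    meta: dict[int, tuple] = {}
    for tr in signals.trials:
        meta[tr.trial_id] = (tr.subject, tr.category, tr.error, tr.duration)
        for ri, region in enumerate(REGIONS):
            m = morlet_transform(
                tr.data[ri],
                wavelet_config,
                times=tr.times,
                trial_id=tr.trial_id,
                region=region,
                onset=tr.onset,
                offset=tr.offset,
                subject=tr.subject,
            )
            groups.setdefault((tr.subject, region), []).append(m)

    values: dict[int, dict[str, float]] = {tid: {} for tid in meta}
    for (subject, region), maps in groups.items():
        for m in normalize_power(maps):
            cell = extract_portrait(m, spec)
            for (epoch, band), val in cell.items():
                values[m.trial_id][f"{region}_{epoch}_{band}"] = val

    rows = []
    for tid in sorted(meta):
        subject, category, error, duration = meta[tid]
        row = {"subject": subject, "category": category, "error": error, "duration": duration}
        row.update(values[tid])
        rows.append(row)
    return pd.DataFrame(rows, columns=list(META_COLUMNS) + element_columns())
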