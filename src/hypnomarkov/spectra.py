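"""Per-stage quantitative EEG: epoch periodograms, 1-Hz binning, band powers.

Each 4-s EEG epoch yields a Hanning-windowed magnitude-squared spectrum at
0.25-Hz resolution over 1.25-60.00 Hz (the 0-1 Hz range is dropped).
Quarter-Hz points are summed into 1-Hz bins labelled by their *upper* limit,
so bin 2 covers 1.25-2.00 Hz, bin 3 covers 2.25-3.00 Hz, and so on up to
bin 60.  Bins aggregate into the classical rodent bands: delta (bins 2-4),
theta (5-9), alpha (10-13), beta (14-30) and gamma (31-60).  Binning and
band aggregation are exact partitions, so total power is conserved at every
step.

Power is reported as window-corrected absolute power per bin: the Hanning
coherent gain is compensated so a unit-amplitude sinusoid contributes its
mean-square power (0.5) at its frequency regardless of the window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.signal.windows import hann

from .hypnogram_io import FINE_STAGES, Hypnogram

__all__ = [
    "FREQ_STEP",
    "FREQ_MIN",
    "FREQ_MAX",
    "N_QUARTER_HZ",
    "BANDS",
    "EpochPSD",
    "BinnedSpectrum",
    "BandPowers",
    "StageSpectrum",
    "StageSpectrumTable",
    "epoch_psd",
    "bin_to_1hz",
    "band_powers",
    "stage_average_spectrum",
]

FREQ_STEP = 0.25
FREQ_MIN = 1.25
FREQ_MAX = 60.0
N_QUARTER_HZ = 236  # 1.25, 1.50, ..., 60.00

#: Band name -> inclusive (first bin, last bin) range of 1-Hz bins.
#: Delta "1-4 Hz" maps to bins 2-4 because the 0-1 Hz range is omitted and
#: bins are labelled by upper limit.
BANDS: dict[str, tuple[int, int]] = {
    "delta": (2, 4),
    "theta": (5, 9),
    "alpha": (10, 13),
    "beta": (14, 30),
    "gamma": (31, 60),
}

_QUARTER_FREQS = FREQ_MIN + FREQ_STEP * np.arange(N_QUARTER_HZ)
_BIN_LABELS = np.arange(2, 61)


@dataclass(frozen=True)
class EpochPSD:
    """Power of one epoch at 0.25-Hz spacing over 1.25-60.00 Hz."""

    power: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.power, dtype=float)
        if p.shape != (N_QUARTER_HZ,):
            raise ValueError(
                f"expected {N_QUARTER_HZ} quarter-Hz points, got shape {p.shape}"
            )
        if np.any(p < 0):
            raise ValueError("power values must be non-negative")
        p.setflags(write=False)
        object.__setattr__(self, "power", p)

    @property
    def frequencies(self) -> np.ndarray:
        return _QUARTER_FREQS

    def total_power(self) -> float:
        return float(self.power.sum())


@dataclass(frozen=True)
class BinnedSpectrum:
    """Power per 1-Hz bin, bins labelled 2..60 by upper frequency limit."""

    power: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.power, dtype=float)
        if p.shape != (59,):
            raise ValueError(f"expected 59 one-Hz bins, got shape {p.shape}")
        p.setflags(write=False)
        object.__setattr__(self, "power", p)

    @property
    def bins(self) -> np.ndarray:
        return _BIN_LABELS

    def __getitem__(self, bin_hz: int) -> float:
        if not 2 <= bin_hz <= 60:
            raise KeyError(f"bin label must be 2..60, got {bin_hz}")
        return float(self.power[bin_hz - 2])

    def total_power(self) -> float:
        return float(self.power.sum())


@dataclass(frozen=True)
class BandPowers:
    delta: float
    theta: float
    alpha: float
    beta: float
    gamma: float

    def as_dict(self) -> dict[str, float]:
        return {b: getattr(self, b) for b in BANDS}

    def total(self) -> float:
        return float(sum(self.as_dict().values()))

    def dominant(self) -> str:
        d = self.as_dict()
        return max(d, key=d.get)  # type: ignore[arg-type]


def epoch_psd(samples: Sequence[float], fs: float = 128.0) -> EpochPSD:
    """Windowed periodogram of one 4-s epoch, truncated to 1.25-60 Hz.

    Requires exactly ``4 * fs`` samples so the FFT resolution is 0.25 Hz.
    The spectrum is single-sided and coherent-gain corrected: power at a
    bin equals ``(2 |X_k| / sum(w))^2 / 2``, the mean-square amplitude of a
    sinusoid at that frequency.
    """
    x = np.asarray(samples, dtype=float)
    n = int(round(4 * fs))
    if x.shape != (n,):
        raise ValueError(f"expected {n} samples (4 s at {fs:g} Hz), got {x.shape}")
    w = hann(n, sym=False)
    spec = np.fft.rfft(x * w)
    power = 2.0 * np.abs(spec) ** 2 / w.sum() ** 2
    lo = int(round(FREQ_MIN / FREQ_STEP))  # index of 1.25 Hz
    hi = int(round(FREQ_MAX / FREQ_STEP))  # index of 60.00 Hz
    return EpochPSD(power=power[lo : hi + 1])


def bin_to_1hz(psd: EpochPSD) -> BinnedSpectrum:
    """Sum quarter-Hz points into 1-Hz bins labelled by upper limit.

    Bin ``k`` sums the points at ``k-0.75, k-0.50, k-0.25, k.00``; bin 2
    therefore covers 1.25-2.00 Hz.  Total power is conserved exactly.
    """
    return BinnedSpectrum(power=psd.power.reshape(59, 4).sum(axis=1))


def band_powers(b: BinnedSpectrum) -> BandPowers:
    """Aggregate 1-Hz bins into the delta..gamma bands (exact partition)."""
    vals = {
        name: float(b.power[lo - 2 : hi - 1].sum()) for name, (lo, hi) in BANDS.items()
    }
    return BandPowers(**vals)


@dataclass(frozen=True)
class StageSpectrum:
    """Mean spectrum of one vigilance stage over its artifact-free epochs."""

    stage: str
    mean_psd: EpochPSD
    binned: BinnedSpectrum
    bands: BandPowers
    n_epochs: int


@dataclass(frozen=True)
class StageSpectrumTable:
    """Per-stage averaged spectra; stages with no usable epochs are absent."""

    stages: dict[str, StageSpectrum]
    subject_id: str = ""
    group: str = ""

    def __contains__(self, stage: str) -> bool:
        return stage in self.stages

    def __getitem__(self, stage: str) -> StageSpectrum:
        return self.stages[stage]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: stage, 1-Hz bin, power, epochs used."""
        records = [
            {
                "subject_id": self.subject_id,
                "group": self.group,
                "stage": st.stage,
                "bin_hz": int(b),
                "power": float(p),
                "n_epochs": st.n_epochs,
            }
            for st in self.stages.values()
            for b, p in zip(st.binned.bins, st.binned.power)
        ]
        return pd.DataFrame.from_records(records)


def stage_average_spectrum(
    epoch_psds: Iterable[EpochPSD] | np.ndarray,
    h: Hypnogram,
    *,
    window: tuple[float, float] | None = None,
) -> StageSpectrumTable:
    """Average epoch spectra per stage, excluding artifact-masked epochs.

    ``epoch_psds`` must supply one PSD per hypnogram epoch.  ``window``
    optionally restricts the analysis to ``[t0, t1)`` seconds since
    lights-on (default: the whole recording).  Averaging is a plain
    arithmetic mean, hence invariant to epoch order.
    """
    psds = [p.power if isinstance(p, EpochPSD) else np.asarray(p, float) for p in epoch_psds]
    if len(psds) != h.n_epochs:
        raise ValueError(
            f"got {len(psds)} epoch PSDs for {h.n_epochs} hypnogram epochs"
        )
    arr = np.vstack(psds)
    include = np.ones(h.n_epochs, dtype=bool)
    if h.artifact_mask is not None:
        include &= ~np.asarray(h.artifact_mask, dtype=bool)
    if window is not None:
        t0, t1 = window
        starts = h.epoch_start_times()
        include &= (starts >= t0) & (starts < t1)
    stages_present = [s for s in FINE_STAGES if s in set(h.stages)] or sorted(set(h.stages))
    table: dict[str, StageSpectrum] = {}
    labels = np.asarray(h.stages)
    for stage in stages_present:
        sel = include & (labels == stage)
        n = int(sel.sum())
        if n == 0:
            continue  # stage absent after masking: excluded from the table
        mean = EpochPSD(power=arr[sel].mean(axis=0))
        binned = bin_to_1hz(mean)
        table[stage] = StageSpectrum(
            stage=stage,
            mean_psd=mean,
            binned=binned,
            bands=band_powers(binned),
            n_epochs=n,
        )
    return StageSpectrumTable(stages=table, subject_id=h.subject_id, group=h.group)
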