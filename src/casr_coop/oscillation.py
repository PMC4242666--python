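"""Quantification of [Ca2+]o-evoked [Ca2+]i oscillation patterns.

Single cells expressing the CaSR respond to stepwise increases in bath
calcium with transient ratio spikes. Three parameters summarise a cell's
pattern:

* the **starting point** — the lowest [Ca2+]o step at which the cell shows
  at least three continuous sequential peaks (after the step-change
  transient);
* the **frequency** — qualifying peaks per minute at a designated step;
* the **ending point** — the lowest [Ca2+]o step at which oscillation
  ceases and the ratio settles on a sustained plateau.

A cell is classified oscillatory when three or more fluctuations from
baseline follow the initial peak within one step's dwell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from .protocol import StepProtocol

__all__ = [
    "Trace",
    "Peak",
    "PeakConfig",
    "OscillationFeatures",
    "PopulationSummary",
    "detect_peaks",
    "classify_oscillatory",
    "find_start_point",
    "compute_frequency",
    "find_end_point",
    "analyze_trace",
    "summarize_population",
]

MIN_OSCILLATION_PEAKS = 3  # successive fluctuations required after the initial peak


@dataclass
class Trace:
    """One cell's ratiometric fluorescence time series bound to a protocol."""

    cell_id: str
    times_s: np.ndarray
    ratios: np.ndarray
    protocol: StepProtocol
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.ratios = np.asarray(self.ratios, dtype=float)
        if self.times_s.shape != self.ratios.shape:
            raise ValueError("times and ratios must have equal length")
        if self.times_s.size < 2:
            raise ValueError("trace needs at least two samples")
        dt = np.diff(self.times_s)
        if np.any(dt <= 0):
            raise ValueError("times must be strictly increasing")
        if np.ptp(dt) > 1e-6:
            raise ValueError("trace time grid must be uniform")

    @property
    def dt(self) -> float:
        return float(self.times_s[1] - self.times_s[0])

    def window_slice(self, t0: float, t1: float) -> slice:
        i0 = int(np.searchsorted(self.times_s, t0, side="left"))
        i1 = int(np.searchsorted(self.times_s, t1, side="left"))
        return slice(i0, i1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"cell_id": self.cell_id, "time_s": self.times_s, "ratio": self.ratios}
        )


@dataclass(frozen=True)
class Peak:
    """A detected local maximum of the (smoothed) ratio signal."""

    time_s: float
    height: float
    prominence: float
    step_index: int


@dataclass
class PeakConfig:
    """Tunable peak-calling and plateau-criterion settings.

    smoothing_window_s: moving-average window before peak calling.
    prominence_factor: required prominence in units of the robust noise SD.
    min_separation_s: minimum spacing between accepted peaks.
    plateau_fraction / cv_max: a step counts as a plateau when the mean of
    the last half of its dwell is at least ``plateau_fraction`` of the
    cell's maximum ratio and the coefficient of variation over that half is
    at most ``cv_max``.
    """

    smoothing_window_s: float = 5.0
    prominence_factor: float = 3.0
    min_separation_s: float = 10.0
    plateau_fraction: float = 0.8
    cv_max: float = 0.05


def _robust_noise_sd(ratios: np.ndarray) -> float:
    """Noise SD from the scaled MAD of the first-difference signal.

    Differencing removes slow trends and spreads each spike over few
    samples, so the median absolute deviation is insensitive to them. For
    white noise the first difference has variance 2*sigma^2, hence the
    1/sqrt(2) factor on the Gaussian-consistent MAD scale.
    """
    d = np.diff(ratios)
    mad = np.median(np.abs(d - np.median(d)))
    return float(1.4826 * mad / np.sqrt(2.0))


def detect_peaks(trace: Trace, cfg: PeakConfig | None = None) -> list[Peak]:
    """Call ratio peaks on the smoothed trace.

    Local maxima must have prominence at least ``prominence_factor`` times
    the robust noise SD and be separated by ``min_separation_s``. Peaks are
    returned sorted by time and annotated with the protocol step containing
    them.
    """
    cfg = cfg or PeakConfig()
    win = max(1, int(round(cfg.smoothing_window_s / trace.dt)))
    if trace.ratios.size <= win:
        raise ValueError(
            f"trace ({trace.ratios.size} samples) shorter than smoothing window ({win})"
        )
    smoothed = ndimage.uniform_filter1d(trace.ratios, size=win, mode="nearest")
    noise_sd = _robust_noise_sd(trace.ratios)
    min_prom = cfg.prominence_factor * max(noise_sd, 1e-12)
    distance = max(1, int(round(cfg.min_separation_s / trace.dt)))
    idx, props = signal.find_peaks(smoothed, prominence=min_prom, distance=distance)
    peaks = []
    for i, prom in zip(idx, props["prominences"]):
        t = float(trace.times_s[i])
        peaks.append(
            Peak(
                time_s=t,
                height=float(smoothed[i]),
                prominence=float(prom),
                step_index=trace.protocol.step_index_at_time(t),
            )
        )
    return peaks


def classify_oscillatory(peaks: Sequence[Peak]) -> bool:
    """Apply the >= 3 successive-fluctuations rule within one step window.

    The first peak after a step change is the concentration-step transient
    and is discarded; the cell oscillates at this step only if at least
    three peaks remain.
    """
    return len(peaks) - 1 >= MIN_OSCILLATION_PEAKS


def _peaks_in_step(peaks: Sequence[Peak], step_index: int) -> list[Peak]:
    return [p for p in peaks if p.step_index == step_index]


def find_start_point(
    trace: Trace, cfg: PeakConfig | None = None, peaks: Optional[Sequence[Peak]] = None
) -> Optional[float]:
    """Lowest [Ca2+]o step at which the cell oscillates, or None.

    When two adjacent steps both qualify the lower concentration is
    reported (the cell "starts" there).
    """
    peaks = detect_peaks(trace, cfg) if peaks is None else peaks
    for i, step in enumerate(trace.protocol.steps):
        if classify_oscillatory(_peaks_in_step(peaks, i)):
            return step.ca_mM
    return None


def compute_frequency(
    trace: Trace,
    at_mM: float,
    cfg: PeakConfig | None = None,
    peaks: Optional[Sequence[Peak]] = None,
) -> float:
    """Qualifying peaks per minute at the step held at ``at_mM``.

    The initial step transient is excluded from the count; the denominator
    is the step's dwell in minutes.
    """
    step_idx = trace.protocol.step_index_for_ca(at_mM)
    peaks = detect_peaks(trace, cfg) if peaks is None else peaks
    in_step = _peaks_in_step(peaks, step_idx)
    qualifying = max(len(in_step) - 1, 0)
    t0, t1 = trace.protocol.step_window(step_idx)
    return qualifying / ((t1 - t0) / 60.0)


def _is_plateau(trace: Trace, step_index: int, cfg: PeakConfig) -> bool:
    t0, t1 = trace.protocol.step_window(step_index)
    half = trace.window_slice((t0 + t1) / 2.0, t1)
    seg = trace.ratios[half]
    if seg.size < 2:
        return False
    mean = float(np.mean(seg))
    if mean <= 0:
        return False
    if mean < cfg.plateau_fraction * float(np.max(trace.ratios)):
        return False
    return float(np.std(seg)) / mean <= cfg.cv_max


def find_end_point(
    trace: Trace, cfg: PeakConfig | None = None, peaks: Optional[Sequence[Peak]] = None
) -> Optional[float]:
    """Lowest [Ca2+]o step (at or above the starting point) where the cell
    has stopped oscillating and sits on a sustained plateau; None if the
    cell is still oscillating at the final step."""
    cfg = cfg or PeakConfig()
    peaks = detect_peaks(trace, cfg) if peaks is None else peaks
    start = find_start_point(trace, cfg, peaks=peaks)
    for i, step in enumerate(trace.protocol.steps):
        if start is not None and step.ca_mM < start:
            continue
        if classify_oscillatory(_peaks_in_step(peaks, i)):
            continue
        if _is_plateau(trace, i, cfg):
            return step.ca_mM
    return None


@dataclass(frozen=True)
class OscillationFeatures:
    """Per-cell oscillation-pattern summary."""

    cell_id: str
    oscillatory: bool
    start_mM: Optional[float]
    end_mM: Optional[float]
    freq_peaks_per_min: Optional[float]

    def __post_init__(self) -> None:
        if self.oscillatory and self.start_mM is None:
            raise ValueError("oscillatory cell must have a starting point")
        if (
            self.start_mM is not None
            and self.end_mM is not None
            and self.end_mM < self.start_mM
        ):
            raise ValueError("ending point cannot precede starting point")


def analyze_trace(
    trace: Trace,
    freq_at_mM: Optional[float] = None,
    cfg: PeakConfig | None = None,
) -> OscillationFeatures:
    """Extract the three oscillation parameters from one trace.

    ``freq_at_mM`` designates the protocol step at which the frequency is
    measured (the assay reports it at a construct-specific step); when None
    the frequency is left undefined.
    """
    cfg = cfg or PeakConfig()
    peaks = detect_peaks(trace, cfg)
    start = find_start_point(trace, cfg, peaks=peaks)
    end = find_end_point(trace, cfg, peaks=peaks) if start is not None else None
    if start is None:
        # a plateau-only cell can still have a defined ending point
        end = find_end_point(trace, cfg, peaks=peaks)
    freq = None
    if freq_at_mM is not None:
        # frequency is meaningful only for cells oscillating at that step
        step_idx = trace.protocol.step_index_for_ca(freq_at_mM)
        if classify_oscillatory(_peaks_in_step(peaks, step_idx)):
            freq = compute_frequency(trace, freq_at_mM, cfg, peaks=peaks)
    return OscillationFeatures(
        cell_id=trace.cell_id,
        oscillatory=start is not None,
        start_mM=start,
        end_mM=end,
        freq_peaks_per_min=freq,
    )


@dataclass
class PopulationSummary:
    """Distributional summary of oscillation parameters across cells."""

    n_cells: int
    fraction_oscillatory: float
    bin_edges_mM: np.ndarray
    start_hist: np.ndarray
    end_hist: np.ndarray
    mean_freq: Optional[float]
    se_freq: Optional[float]

    def start_modal_fraction(self) -> float:
        """Fraction of oscillatory cells in the modal starting-point bin."""
        total = self.start_hist.sum()
        return float(self.start_hist.max() / total) if total else np.nan

    def modal_start_mM(self) -> Optional[float]:
        """Upper edge of the modal starting-point bin.

        With (lo, hi] binning on the protocol's step concentrations the
        upper edge is the step at which those cells started to oscillate.
        """
        if self.start_hist.sum() == 0:
            return None
        return float(self.bin_edges_mM[int(np.argmax(self.start_hist)) + 1])

    def modal_end_mM(self) -> Optional[float]:
        if self.end_hist.sum() == 0:
            return None
        return float(self.bin_edges_mM[int(np.argmax(self.end_hist)) + 1])

    def to_dict(self) -> dict:
        return {
            "n_cells": self.n_cells,
            "fraction_oscillatory": self.fraction_oscillatory,
            "bin_edges_mM": list(map(float, self.bin_edges_mM)),
            "start_hist": list(map(int, self.start_hist)),
            "end_hist": list(map(int, self.end_hist)),
            "mean_freq_ppm": self.mean_freq,
            "se_freq_ppm": self.se_freq,
        }


def summarize_population(
    features: Sequence[OscillationFeatures], bin_edges_mM: Sequence[float]
) -> PopulationSummary:
    """Histogram starting/ending points and average the frequency.

    Non-oscillatory cells are excluded from the histograms but counted in
    the denominator of ``fraction_oscillatory``. Values on a bin edge are
    counted in the bin whose *upper* edge they equal, matching the
    convention that a cell starting exactly at a protocol step falls in
    that step's bin.
    """
    if not features:
        raise ValueError("summarize_population needs at least one cell")
    edges = np.asarray(bin_edges_mM, dtype=float)
    n = len(features)
    osc = [f for f in features if f.oscillatory]
    starts = np.array([f.start_mM for f in osc if f.start_mM is not None])
    ends = np.array([f.end_mM for f in osc if f.end_mM is not None])

    def hist(values: np.ndarray) -> np.ndarray:
        if values.size == 0:
            return np.zeros(edges.size - 1, dtype=int)
        # (lo, hi] binning so a start exactly at a step edge lands in its bin
        idx = np.searchsorted(edges, values, side="left") - 1
        counts = np.zeros(edges.size - 1, dtype=int)
        for i in idx:
            if 0 <= i < counts.size:
                counts[i] += 1
            else:
                warnings.warn("value outside histogram range dropped", stacklevel=2)
        return counts

    freqs = np.array(
        [f.freq_peaks_per_min for f in osc if f.freq_peaks_per_min is not None]
    )
    mean_f = float(np.mean(freqs)) if freqs.size else None
    se_f = float(np.std(freqs, ddof=1) / np.sqrt(freqs.size)) if freqs.size > 1 else None
    return PopulationSummary(
        n_cells=n,
        fraction_oscillatory=len(osc) / n,
        bin_edges_mM=edges,
        start_hist=hist(starts),
        end_hist=hist(ends),
        mean_freq=mean_f,
        se_freq=se_f,
    )


def features_to_frame(features: Sequence[OscillationFeatures]) -> pd.DataFrame:
    """Per-cell features as the canonical output table."""
    return pd.DataFrame(
        {
            "cell_id": [f.cell_id for f in features],
            "oscillatory": [f.oscillatory for f in features],
            "start_mM": [f.start_mM for f in features],
            "end_mM": [f.end_mM for f in features],
            "freq_ppm": [f.freq_peaks_per_min for f in features],
        }
    )
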