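"""Time-domain respiratory-rate estimation with adaptive sub-banding.

The rate is extracted per 60-s window by a fast time-domain breath counter:
negative-to-positive mean crossings with an amplitude hysteresis band, a
minimum inter-breath interval to merge spurious onsets, and a fractional
rate refined from the first and last onset timestamps.

The adaptive "sub-banding" scheme recognises that one parameter set cannot
serve the whole clinical range (6-41 bpm): heavy smoothing that suppresses
noise at slow rates also attenuates the higher-frequency components of fast
breathing, while a short minimum breath interval that admits fast rates lets
noise split slow breaths.  Sub-banding therefore computes a first-pass rate
with default parameters, maps it into a predefined rate band, and recomputes
the rate once with that band's own optimized parameters.  Exactly two passes
are made; there is no iteration even if the corrected rate lands in a
different band.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from . import preprocess
from .errors import InvalidParameterError, NoBreathsError
from .preprocess import RawSignal, SignalConfig, Window

Quality = Literal["ok", "low_quality", "corrupted", "no_breaths"]

BAND_TOP_BPM = 50.0


@dataclass(frozen=True)
class BandParams:
    """Counting parameters owned by one rate band.

    ``ma_points`` is the moving-average smoothing length in samples;
    ``min_breath_period_s`` the shortest admissible inter-breath interval;
    ``hysteresis_frac`` the crossing hysteresis as a fraction of the window's
    robust half-amplitude (half the 5th-95th percentile span).
    """

    ma_points: int = 15
    min_breath_period_s: float = 60.0 / (BAND_TOP_BPM + 5.0)
    hysteresis_frac: float = 0.2

    def __post_init__(self):
        if self.ma_points < 1:
            raise InvalidParameterError("ma_points must be >= 1")
        if not (0.0 < self.hysteresis_frac < 1.0):
            raise InvalidParameterError("hysteresis_frac must be in (0, 1)")
        if self.min_breath_period_s <= 0:
            raise InvalidParameterError("min_breath_period_s must be > 0")


@dataclass(frozen=True)
class BandTable:
    """Ordered contiguous rate bands, each owning a second-pass parameter set.

    Bands are half-open ``[low, high)`` so a rate on a shared bound belongs
    to the upper band; rates at or above the top band's lower bound clamp
    into the top band.
    """

    bands: tuple[tuple[float, float, BandParams], ...]
    default_params: BandParams = field(default_factory=BandParams)

    def __post_init__(self):
        bands = tuple(
            (float(lo), float(hi), p) for lo, hi, p in self.bands
        )
        object.__setattr__(self, "bands", bands)
        if not bands:
            raise InvalidParameterError("band table must contain at least one band")
        if bands[0][0] != 0.0:
            raise InvalidParameterError("first band must start at 0 bpm")
        for (lo, hi, _) in bands:
            if not (hi > lo):
                raise InvalidParameterError(f"band ({lo}, {hi}) is empty")
        for (_, hi_prev, _), (lo_next, _, _) in zip(bands, bands[1:]):
            if not math.isclose(hi_prev, lo_next):
                raise InvalidParameterError(
                    f"bands must be contiguous: {hi_prev} != {lo_next}"
                )

    @property
    def edges_bpm(self) -> list[float]:
        """Interior band boundaries (for Bland-Altman overlays)."""
        return [lo for lo, _, _ in self.bands[1:]]


def default_band_table() -> BandTable:
    """The default three-band table: 0-20, 20-27 and 27-50 bpm.

    Smoothing shortens with the band (15 / 12 / 9 moving-average points) so
    that fast, higher-frequency breathing is not smoothed away as noise,
    and the minimum breath interval per band is 60/(high_bound + 5) s so each
    band admits rates slightly beyond its upper edge.  First-pass defaults
    use the low-band smoothing with the top-band breath interval, keeping the
    whole 6-41 bpm range reachable before a band is known.
    """
    def params(ma: int, high: float) -> BandParams:
        return BandParams(ma_points=ma, min_breath_period_s=60.0 / (high + 5.0))

    return BandTable(
        bands=(
            (0.0, 20.0, params(15, 20.0)),
            (20.0, 27.0, params(12, 27.0)),
            (27.0, BAND_TOP_BPM, params(9, BAND_TOP_BPM)),
        ),
        default_params=BandParams(
            ma_points=15, min_breath_period_s=60.0 / (BAND_TOP_BPM + 5.0)
        ),
    )


@dataclass(frozen=True)
class RREstimate:
    """Per-window rate estimate with provenance of both passes."""

    rr_bpm: float
    rr_pass1_bpm: float
    band_index: int
    window_index: int
    start_s: float = 0.0
    quality: Quality = "ok"


# ---------------------------------------------------------------------------
# Breath counting
# ---------------------------------------------------------------------------

def _breath_onsets(y: np.ndarray, fs: float, params: BandParams) -> np.ndarray:
    """Breath-onset times via hysteresis mean crossings, merged by min period."""
    m = float(np.mean(y))
    p5, p95 = np.percentile(y, [5.0, 95.0])
    half_amp = (p95 - p5) / 2.0
    hyst = params.hysteresis_frac * half_amp
    if half_amp <= 0:
        return np.empty(0)
    low, high = m - hyst, m + hyst
    onsets = []
    armed = y[0] < low
    for i in range(1, y.size):
        v = y[i]
        if armed and v > high:
            onsets.append(i / fs)
            armed = False
        elif not armed and v < low:
            armed = True
    if not onsets:
        return np.empty(0)
    merged = [onsets[0]]
    for t in onsets[1:]:
        if t - merged[-1] >= params.min_breath_period_s:
            merged.append(t)
    return np.asarray(merged)


def count_breaths(window: Window, params: BandParams) -> float:
    """Rate in bpm from a conditioned window via hysteresis crossing counting.

    A breath onset is a negative-to-positive crossing of the window mean that
    first dips below ``mean - hysteresis`` and then rises above
    ``mean + hysteresis``; onsets closer than ``min_breath_period_s`` are
    merged.  With ``k >= 2`` onsets spanning time ``T``, the fractional rate
    is ``60 (k - 1) / T``.  Scaling the signal by a positive constant or
    adding an offset leaves the count unchanged.

    Raises :class:`NoBreathsError` when fewer than two onsets are found.
    """
    onsets = _breath_onsets(np.asarray(window.samples, dtype=float), window.fs, params)
    if onsets.size < 2:
        raise NoBreathsError(
            f"window {window.index}: {onsets.size} breath onset(s) found"
        )
    span = onsets[-1] - onsets[0]
    return 60.0 * (onsets.size - 1) / span


def select_band(rr_bpm: float, table: BandTable) -> int:
    """Index of the band containing ``rr_bpm``; rates above the top clamp down."""
    if not np.isfinite(rr_bpm) or rr_bpm < 0:
        raise InvalidParameterError(f"rr_bpm must be finite and >= 0, got {rr_bpm}")
    for i, (lo, hi, _) in enumerate(table.bands):
        if lo <= rr_bpm < hi:
            return i
    return len(table.bands) - 1


# ---------------------------------------------------------------------------
# Two-pass estimation
# ---------------------------------------------------------------------------

def _condition_and_count(
    window: Window, params: BandParams, config: SignalConfig
) -> tuple[float, float]:
    y, frac = preprocess.condition(
        window.samples, window.fs, params.ma_points, config
    )
    conditioned = Window(
        samples=y,
        fs=window.fs,
        index=window.index,
        start_s=window.start_s,
        artifact_fraction=frac,
        saturated=window.saturated,
    )
    return count_breaths(conditioned, params), frac


def estimate_rr_subbanded(
    window: Window,
    table: BandTable,
    config: SignalConfig | None = None,
) -> RREstimate:
    """Two-pass adaptive estimate for one raw 60-s window.

    Pass 1 conditions the raw window with the table's default parameters and
    counts breaths; the resulting rate selects a band; pass 2 reconditions
    the same raw window with that band's parameters and recounts.  A pass-2
    counting failure falls back to the pass-1 value flagged ``low_quality``
    so the minute keeps its pairing with the reference count.
    """
    cfg = config or SignalConfig(fs=window.fs)
    rr1, frac1 = _condition_and_count(window, table.default_params, cfg)
    band = select_band(rr1, table)
    band_params = table.bands[band][2]
    try:
        rr2, frac2 = _condition_and_count(window, band_params, cfg)
        quality: Quality = "ok"
    except NoBreathsError:
        rr2, frac2 = rr1, frac1
        quality = "low_quality"
    if max(frac1, frac2) > cfg.max_artifact_fraction:
        quality = "low_quality"
    return RREstimate(
        rr_bpm=rr2,
        rr_pass1_bpm=rr1,
        band_index=band,
        window_index=window.index,
        start_s=window.start_s,
        quality=quality,
    )


def estimate_rr_normal(
    window: Window,
    table: BandTable,
    config: SignalConfig | None = None,
) -> RREstimate:
    """Single-pass estimate with the table's default parameters."""
    cfg = config or SignalConfig(fs=window.fs)
    rr1, frac1 = _condition_and_count(window, table.default_params, cfg)
    quality: Quality = "low_quality" if frac1 > cfg.max_artifact_fraction else "ok"
    return RREstimate(
        rr_bpm=rr1,
        rr_pass1_bpm=rr1,
        band_index=select_band(rr1, table),
        window_index=window.index,
        start_s=window.start_s,
        quality=quality,
    )


def estimate_series(
    signal: RawSignal,
    table: BandTable,
    mode: Literal["normal", "subbanded"] = "subbanded",
    config: SignalConfig | None = None,
) -> list[RREstimate]:
    """One estimate per 60-s window of a recording.

    A recording with rail saturation anywhere is treated as corrupted in
    full, mirroring how saturated recordings are excluded from evaluation;
    every window then carries ``quality="corrupted"`` and a NaN rate.
    Windows where counting fails yield ``quality="no_breaths"`` with a NaN
    rate rather than aborting the series.
    """
    if mode not in ("normal", "subbanded"):
        raise InvalidParameterError(f"unknown mode {mode!r}")
    cfg = config or SignalConfig(fs=signal.fs)
    saturated = preprocess.detect_saturation(signal) is True
    windows = preprocess.buffer_windows(
        signal.samples, signal.fs, saturated=saturated, t0=signal.t0
    )
    estimates: list[RREstimate] = []
    for w in windows:
        if saturated:
            estimates.append(
                RREstimate(
                    rr_bpm=float("nan"),
                    rr_pass1_bpm=float("nan"),
                    band_index=0,
                    window_index=w.index,
                    start_s=w.start_s,
                    quality="corrupted",
                )
            )
            continue
        try:
            if mode == "subbanded":
                estimates.append(estimate_rr_subbanded(w, table, cfg))
            else:
                estimates.append(estimate_rr_normal(w, table, cfg))
        except NoBreathsError:
            estimates.append(
                RREstimate(
                    rr_bpm=float("nan"),
                    rr_pass1_bpm=float("nan"),
                    band_index=0,
                    window_index=w.index,
                    start_s=w.start_s,
                    quality="no_breaths",
                )
            )
    return estimates
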