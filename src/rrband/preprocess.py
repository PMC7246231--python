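"""Signal conditioning for chest-worn optical respiratory recordings.

The raw photodetector intensity carries the breathing waveform (chest-wall
motion modulating the diffusely reflected light) on top of high-frequency
noise, slow baseline drift, and occasional large motion transients.  This
module implements the conditioning chain applied before any rate is
extracted:

1. centred moving-average smoothing (high-frequency noise),
2. baseline removal by subtracting a slow moving mean (drift),
3. motion-artifact detection with the Teager-Kaiser energy operator and
   correction by linear interpolation across flagged runs,
4. ADC-rail saturation detection, and
5. buffering into consecutive non-overlapping 60-s windows.

All filters are deterministic and length-preserving; edge samples of the
centred filters are handled by shrinking the averaging window symmetrically
rather than padding, so no data is invented at window boundaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import InvalidParameterError, UncorrectableWindowError

logger = logging.getLogger(__name__)

WINDOW_SECONDS = 60.0


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RawSignal:
    """A uniformly sampled photodetector intensity series.

    Parameters
    ----------
    samples : array-like of float
        Detector intensity in arbitrary units; must be non-empty and finite.
    fs : float
        Sampling rate in Hz, constant over the series, > 0.
    t0 : float
        Start-time offset in seconds (>= 0).
    rail_low, rail_high : float, optional
        ADC saturation bounds in the same units as ``samples``.  When absent,
        saturation detection is not applicable.
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0
    rail_low: float | None = None
    rail_high: float | None = None

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1 or samples.size == 0:
            raise InvalidParameterError("samples must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(samples)):
            raise InvalidParameterError("samples must all be finite")
        if not (self.fs > 0):
            raise InvalidParameterError(f"fs must be > 0, got {self.fs}")
        if self.t0 < 0:
            raise InvalidParameterError(f"t0 must be >= 0, got {self.t0}")
        if self.rail_low is not None and self.rail_high is not None:
            if not (self.rail_low < self.rail_high):
                raise InvalidParameterError("rail_low must be < rail_high")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs


@dataclass(frozen=True)
class Window:
    """One 60-s buffer of samples with per-window quality bookkeeping."""

    samples: np.ndarray
    fs: float
    index: int
    start_s: float
    artifact_fraction: float = 0.0
    saturated: bool = False

    def __post_init__(self):
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if not (0.0 <= self.artifact_fraction <= 1.0):
            raise InvalidParameterError("artifact_fraction must be within [0, 1]")


@dataclass(frozen=True)
class TeagerEnergy:
    """Teager-Kaiser energy sequence aligned to interior source samples.

    ``psi`` has length ``len(source) - 2``: entry ``i`` corresponds to source
    sample ``i + 1``.
    """

    psi: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "psi", np.asarray(self.psi, dtype=float))


@dataclass(frozen=True)
class SignalConfig:
    """Conditioning parameters independent of the rate band.

    ``baseline_window_s`` defaults to 12 s, at least twice the 10-s breath
    period of the slowest in-range rate (6 bpm), so breathing is preserved
    while drift is removed.  ``k_thresh`` flags samples whose Teager energy
    exceeds ``k_thresh`` times the window median; flags are dilated by
    ``dilation_s`` on each side.  Windows with more than
    ``max_artifact_fraction`` of samples corrected are marked low-quality.
    """

    fs: float = 50.0
    baseline_window_s: float = 12.0
    k_thresh: float = 10.0
    dilation_s: float = 0.5
    energy_smooth_s: float = 5.0
    min_run_s: float = 0.5
    max_artifact_fraction: float = 0.25


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def moving_average(signal: Sequence[float], n_points: int) -> np.ndarray:
    """Centred moving average with symmetric edge shrink.

    Interior samples are averaged over a centred window of ``n_points``
    (an even ``n_points`` behaves as the next-lower odd length, keeping the
    window symmetric).  Near the edges the half-width shrinks to what fits,
    so the output has the same length as the input and the first and last
    samples pass through unchanged.
    """
    x = np.asarray(signal, dtype=float)
    n_points = int(n_points)
    if n_points < 1 or n_points > x.size:
        raise InvalidParameterError(
            f"n_points must be in [1, {x.size}], got {n_points}"
        )
    if n_points <= 2:
        return x.copy()
    half = (n_points - 1) // 2
    idx = np.arange(x.size)
    radius = np.minimum(half, np.minimum(idx, x.size - 1 - idx))
    # anchor at x[0] so a constant input is an exact fixed point despite
    # cumulative-sum rounding
    offset = x[0]
    csum = np.concatenate(([0.0], np.cumsum(x - offset)))
    lo = idx - radius
    hi = idx + radius
    return (csum[hi + 1] - csum[lo]) / (2 * radius + 1) + offset


def remove_baseline(
    signal: Sequence[float], fs: float, baseline_window_s: float = 12.0
) -> np.ndarray:
    """Subtract a slow trend estimated as a centred moving mean.

    The trend window (``baseline_window_s``, default 12 s) must be no longer
    than the signal; a constant input maps to exactly zeros.
    """
    x = np.asarray(signal, dtype=float)
    if baseline_window_s <= 0:
        raise InvalidParameterError("baseline_window_s must be > 0")
    n = int(round(baseline_window_s * fs))
    n = max(n, 1)
    if n > x.size:
        raise InvalidParameterError(
            f"baseline window of {n} samples exceeds signal length {x.size}"
        )
    return x - moving_average(x, n)


def teager_energy(signal: Sequence[float]) -> TeagerEnergy:
    """Teager-Kaiser energy psi(n) = x(n)^2 - x(n-1) x(n+1) over interior samples.

    For a sinusoid ``A sin(Omega n)`` the output is the constant
    ``A^2 sin^2(Omega)``, so large excursions above the window median are a
    robust marker of motion transients.
    """
    x = np.asarray(signal, dtype=float)
    if x.size < 3:
        raise InvalidParameterError("teager_energy requires at least 3 samples")
    psi = x[1:-1] ** 2 - x[:-2] * x[2:]
    return TeagerEnergy(psi=psi)


def detect_motion(
    energy: TeagerEnergy,
    k_thresh: float,
    fs: float,
    dilation_s: float = 0.5,
    smooth_s: float = 5.0,
) -> np.ndarray:
    """Flag motion-corrupted samples from the Teager energy.

    The raw Teager energy of breathing oscillates within each breath cycle
    (harmonics beat against the fundamental), so the energy is first smoothed
    over ``smooth_s`` into an envelope; a sample is flagged when its envelope
    exceeds ``k_thresh`` times the envelope median, and flags are dilated by
    ``dilation_s`` on each side to cover transient skirts.  Returns a boolean
    mask over the *source* samples (length ``len(psi) + 2``); the two edge
    samples inherit flags only through dilation.
    """
    if k_thresh <= 0:
        raise InvalidParameterError("k_thresh must be > 0")
    psi = energy.psi
    if smooth_s > 0:
        n_smooth = min(max(1, int(round(smooth_s * fs))), psi.size)
        psi = moving_average(psi, n_smooth)
    n = energy.psi.size + 2
    mask = np.zeros(n, dtype=bool)
    med = float(np.median(psi))
    # median <= 0 happens for near-constant signals; psi > 0 then only at
    # genuine transients, so the bare comparison still behaves sensibly.
    mask[1:-1] = psi > k_thresh * med if med > 0 else psi > 0
    if not mask.any():
        return mask
    guard = int(round(dilation_s * fs))
    if guard > 0:
        flagged = np.flatnonzero(mask)
        for i in flagged:
            mask[max(0, i - guard): i + guard + 1] = True
    return mask


def correct_motion(signal: Sequence[float], mask: np.ndarray) -> np.ndarray:
    """Replace flagged runs by linear interpolation between clean neighbours.

    Runs touching an edge are held at the nearest unflagged value.  Unflagged
    samples are never altered.
    """
    x = np.asarray(signal, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != x.shape:
        raise InvalidParameterError("mask must have the same length as signal")
    if not mask.any():
        return x.copy()
    if mask.all():
        raise UncorrectableWindowError("all samples flagged; window unusable")
    out = x.copy()
    good = np.flatnonzero(~mask)
    bad = np.flatnonzero(mask)
    # np.interp holds end values constant outside the clean support, which is
    # exactly the edge-hold rule.
    out[bad] = np.interp(bad, good, x[good])
    return out


def detect_saturation(signal: RawSignal, min_run: int | None = None) -> bool | None:
    """True when any run of >= ``min_run`` consecutive samples sits on a rail.

    Returns ``None`` (not applicable) when the signal carries no rail bounds.
    ``min_run`` defaults to 0.5 s of samples.
    """
    if signal.rail_low is None or signal.rail_high is None:
        return None
    if min_run is None:
        min_run = max(1, int(round(0.5 * signal.fs)))
    if min_run < 1:
        raise InvalidParameterError("min_run must be >= 1")
    x = signal.samples
    on_rail = (x <= signal.rail_low) | (x >= signal.rail_high)
    if not on_rail.any():
        return False
    # longest run of consecutive True values
    padded = np.concatenate(([False], on_rail, [False])).astype(int)
    edges = np.diff(padded)
    run_lengths = np.flatnonzero(edges == -1) - np.flatnonzero(edges == 1)
    return bool(run_lengths.max() >= min_run)


def buffer_windows(
    signal: Sequence[float],
    fs: float,
    artifact_mask: np.ndarray | None = None,
    saturated: bool = False,
    t0: float = 0.0,
) -> list[Window]:
    """Split a sample sequence into consecutive non-overlapping 60-s windows.

    Windows are aligned to the recording start; a trailing remainder shorter
    than 60 s is dropped.  ``artifact_mask`` (per-sample motion flags)
    populates each window's ``artifact_fraction``; ``saturated`` is carried
    onto every window.  A signal shorter than 60 s yields an empty list with
    a warning.
    """
    x = np.asarray(signal, dtype=float)
    n_win_samples = int(round(WINDOW_SECONDS * fs))
    n_windows = x.size // n_win_samples
    if n_windows == 0:
        logger.warning(
            "signal of %.1f s is shorter than one 60-s window; no windows produced",
            x.size / fs,
        )
        return []
    if artifact_mask is not None:
        artifact_mask = np.asarray(artifact_mask, dtype=bool)
        if artifact_mask.shape != x.shape:
            raise InvalidParameterError("artifact_mask must match signal length")
    windows = []
    for i in range(n_windows):
        lo = i * n_win_samples
        hi = lo + n_win_samples
        frac = float(artifact_mask[lo:hi].mean()) if artifact_mask is not None else 0.0
        windows.append(
            Window(
                samples=x[lo:hi],
                fs=fs,
                index=i,
                start_s=t0 + i * WINDOW_SECONDS,
                artifact_fraction=frac,
                saturated=saturated,
            )
        )
    return windows


def condition(
    samples: Sequence[float],
    fs: float,
    ma_points: int,
    config: SignalConfig | None = None,
) -> tuple[np.ndarray, float]:
    """Run the full conditioning chain on one window of raw samples.

    Smooth with ``ma_points``, remove baseline, detect motion on the Teager
    energy of the detrended signal and interpolate across flagged runs.
    Returns the conditioned samples and the fraction of motion-corrected
    samples.
    """
    cfg = config or SignalConfig(fs=fs)
    y = moving_average(samples, ma_points)
    y = remove_baseline(y, fs, cfg.baseline_window_s)
    psi = teager_energy(y)
    mask = detect_motion(psi, cfg.k_thresh, fs, cfg.dilation_s, cfg.energy_smooth_s)
    frac = float(mask.mean())
    if mask.any():
        y = correct_motion(y, mask)
    return y, frac
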