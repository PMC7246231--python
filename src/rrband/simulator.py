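"""Synthetic chest-optical respiratory signals with ground truth.

The generator is phenomenological: breathing appears in the photodetector
intensity as a quasi-periodic waveform with a fundamental at RR/60 Hz plus
weaker higher-order harmonics, riding on slow baseline drift and broadband
noise, occasionally hit by large motion/cough transients or pinned at an
ADC rail.  Breath-to-breath period jitter makes the waveform quasi- rather
than strictly periodic.  Each simulated recording carries its exact breath
onsets, so per-minute reference counts (the stand-in for manual breath
counting) and per-window true rates come from the same sample path as the
signal.

Scenario presets mirror the clinically observed failure modes: ``cough``
injects 1-s transients at ten times the breathing amplitude, and
``fast_shallow`` combines a fast rate with a weak fundamental and doubled
noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import InvalidScenarioError
from .preprocess import RawSignal, WINDOW_SECONDS

DEFAULT_HARMONIC_AMPS = (0.4, 0.15)


@dataclass(frozen=True)
class SimScenario:
    """Parameters of one simulated recording.

    Amplitudes are relative to the fundamental (amplitude 1); ``noise_sigma``
    is the standard deviation of white noise in the same units.  ``artifacts``
    is a list of ``(start_s, duration_s, relative_amplitude)`` transient
    bursts.  ``rate_jitter_cv`` is the coefficient of variation of individual
    breath periods.  The seed fixes the entire sample path.
    """

    rr_bpm: float = 18.0
    duration_s: float = 300.0
    fs: float = 50.0
    fundamental_amp: float = 1.0
    harmonic_amps: tuple[float, ...] = DEFAULT_HARMONIC_AMPS
    noise_sigma: float = 0.0
    drift_amp: float = 0.0
    drift_period_s: float = 45.0
    rate_jitter_cv: float = 0.0
    artifacts: tuple[tuple[float, float, float], ...] = ()
    saturate: bool = False
    rail_low: float = -1.5
    rail_high: float = 1.5
    seed: int = 0

    def __post_init__(self):
        if self.rr_bpm <= 0:
            raise InvalidScenarioError("rr_bpm must be > 0")
        if self.duration_s <= 0 or self.fs <= 0:
            raise InvalidScenarioError("duration_s and fs must be > 0")
        n_harmonics = 1 + len(self.harmonic_amps)
        if self.fs <= 2.0 * n_harmonics * self.rr_bpm / 60.0:
            raise InvalidScenarioError(
                f"fs={self.fs} too low for {n_harmonics} harmonics at "
                f"{self.rr_bpm} bpm"
            )
        if self.fundamental_amp < 0:
            raise InvalidScenarioError("fundamental_amp must be >= 0")
        if any(a < 0 for a in self.harmonic_amps) or self.noise_sigma < 0:
            raise InvalidScenarioError("amplitudes must be >= 0")
        if self.rate_jitter_cv < 0 or self.drift_amp < 0:
            raise InvalidScenarioError("jitter and drift amplitudes must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """Exact breath timing of a simulated recording."""

    breath_onsets_s: np.ndarray
    true_rr_per_window: np.ndarray
    artifact_intervals: tuple[tuple[float, float], ...] = ()

    def reference_counts(self, n_minutes: int | None = None) -> np.ndarray:
        """Integer breath-onset counts per minute (the manual-count stand-in)."""
        if n_minutes is None:
            n_minutes = self.true_rr_per_window.size
        counts = np.zeros(n_minutes, dtype=int)
        # nanosecond tolerance: cumulative-sum rounding must not flip an
        # onset sitting exactly on a minute boundary into the wrong bin
        onsets = self.breath_onsets_s + 1e-9
        for m in range(n_minutes):
            lo, hi = m * WINDOW_SECONDS, (m + 1) * WINDOW_SECONDS
            counts[m] = int(np.count_nonzero((onsets >= lo) & (onsets < hi)))
        return counts


def _breath_periods(scenario: SimScenario, rng: np.random.Generator) -> np.ndarray:
    """Per-breath periods with multiplicative jitter, clipped at +-3 CV."""
    nominal = 60.0 / scenario.rr_bpm
    n = int(np.ceil(scenario.duration_s / nominal)) + 3
    if scenario.rate_jitter_cv == 0:
        return np.full(n, nominal)
    eps = np.clip(rng.standard_normal(n), -3.0, 3.0)
    return nominal * (1.0 + scenario.rate_jitter_cv * eps)


def _artifact_burst(t: np.ndarray, start_s: float, dur_s: float, amp: float) -> np.ndarray:
    """Hann-windowed 8-Hz oscillatory burst, the motion/cough transient shape."""
    inside = (t >= start_s) & (t < start_s + dur_s)
    burst = np.zeros_like(t)
    u = (t[inside] - start_s) / dur_s
    burst[inside] = amp * np.sin(np.pi * u) ** 2 * np.sin(2 * np.pi * 8.0 * t[inside])
    return burst


def simulate_signal(scenario: SimScenario) -> tuple[RawSignal, GroundTruth]:
    """Generate one recording and its exact breath timing.

    The breathing component is ``sum_h amp_h sin(h * phi(t))`` where the
    phase ``phi`` advances by 2*pi per (jittered) breath; breath onsets are
    the phase zero-crossings.  Drift, white noise and artifact bursts are
    added on top; with ``saturate`` the result is clipped to the rails.
    """
    rng = np.random.default_rng(scenario.seed)
    n = int(round(scenario.duration_s * scenario.fs))
    t = np.arange(n) / scenario.fs

    periods = _breath_periods(scenario, rng)
    onsets = np.concatenate(([0.0], np.cumsum(periods)))
    # phase: piecewise-linear, 2*pi per breath
    phi = 2.0 * np.pi * np.interp(t, onsets, np.arange(onsets.size))
    rel_amps = (1.0,) + tuple(scenario.harmonic_amps)
    x = np.zeros(n)
    for h, a in enumerate(rel_amps, start=1):
        if scenario.fundamental_amp * a > 0:
            x += scenario.fundamental_amp * a * np.sin(h * phi)

    if scenario.drift_amp > 0:
        x += scenario.drift_amp * np.sin(2 * np.pi * t / scenario.drift_period_s)
    if scenario.noise_sigma > 0:
        x += scenario.noise_sigma * rng.standard_normal(n)
    for start_s, dur_s, amp in scenario.artifacts:
        x += _artifact_burst(t, start_s, dur_s, amp)
    if scenario.saturate:
        x = np.clip(x, scenario.rail_low, scenario.rail_high)

    onsets_in = onsets[onsets < scenario.duration_s]
    n_windows = int(scenario.duration_s // WINDOW_SECONDS)
    true_rr = np.empty(max(n_windows, 1))
    for w in range(max(n_windows, 1)):
        lo, hi = w * WINDOW_SECONDS, (w + 1) * WINDOW_SECONDS
        in_w = np.flatnonzero((onsets_in + 1e-9 >= lo) & (onsets_in + 1e-9 < hi))
        if in_w.size >= 2:
            # fractional rate from the mean period of breaths inside the window
            mean_period = np.mean(periods[in_w[0]: in_w[-1] + 1])
            true_rr[w] = 60.0 / mean_period
        else:
            true_rr[w] = 60.0 * in_w.size / WINDOW_SECONDS
    truth = GroundTruth(
        breath_onsets_s=onsets_in,
        true_rr_per_window=true_rr[:n_windows] if n_windows else true_rr[:0],
        artifact_intervals=tuple(
            (s, s + d) for s, d, _ in scenario.artifacts
        ),
    )
    raw = RawSignal(
        samples=x,
        fs=scenario.fs,
        rail_low=scenario.rail_low if scenario.saturate else None,
        rail_high=scenario.rail_high if scenario.saturate else None,
    )
    return raw, truth


# ---------------------------------------------------------------------------
# Scenario presets
# ---------------------------------------------------------------------------

def standard_noisy_scenario(**overrides) -> SimScenario:
    """The reference ward-grade scenario used for noisy-cohort evaluations.

    Broadband noise at the fundamental's amplitude (SNR around 0 dB), slow
    drift at half the breathing amplitude, and 5% breath-period jitter —
    chosen to stress the estimator the way general-ward chest recordings do,
    producing device-reference deviations on the few-bpm scale reported for
    bedside wearables.
    """
    base = dict(
        noise_sigma=1.0,
        drift_amp=0.5,
        drift_period_s=45.0,
        rate_jitter_cv=0.05,
    )
    base.update(overrides)
    return SimScenario(**base)

def cough_scenario(base: SimScenario, n_coughs: int = 3) -> SimScenario:
    """Inject 1-s transients at 10x the breathing amplitude."""
    rng = np.random.default_rng(base.seed + 1)
    starts = np.sort(rng.uniform(5.0, base.duration_s - 6.0, size=n_coughs))
    return replace(base, artifacts=tuple((float(s), 1.0, 10.0) for s in starts))


def fast_shallow_scenario(base: SimScenario, rng: np.random.Generator | None = None) -> SimScenario:
    """Fast (30-41 bpm) breathing with a weak fundamental and doubled noise."""
    rng = rng or np.random.default_rng(base.seed + 2)
    rr = float(rng.uniform(30.0, 41.0))
    return replace(
        base,
        rr_bpm=rr,
        fundamental_amp=0.3 * base.fundamental_amp,
        noise_sigma=2.0 * base.noise_sigma,
    )


@dataclass(frozen=True)
class CohortSubject:
    """One simulated subject: recording, truth, per-minute references."""

    subject_id: int
    signal: RawSignal
    truth: GroundTruth
    reference_counts: np.ndarray
    interrupted: np.ndarray  # per-minute flags
    age: float
    true_rr_bpm: float


def simulate_cohort(
    n_subjects: int,
    rate_range: tuple[float, float] = (6.0, 41.0),
    scenario_template: SimScenario | None = None,
    seed: int = 0,
    n_reference_minutes: int = 4,
    n_saturated: int = 0,
    n_all_interrupted: int = 0,
    n_partial_interrupted: int = 0,
) -> list[CohortSubject]:
    """Simulate a cohort of 5-minute recordings with per-minute references.

    Rates are drawn uniformly over ``rate_range``; each subject gets
    ``n_reference_minutes`` integer reference counts from its ground-truth
    onsets (four counts in five minutes by default, as in bedside manual
    counting).  The first ``n_saturated`` subjects are generated with rail
    clipping (corrupted recordings); the next ``n_all_interrupted`` have all
    reference minutes flagged interrupted; the next ``n_partial_interrupted``
    have exactly one interrupted minute.  Ages are drawn from a normal
    distribution (mean 53.7, SD 16.7 years) for age-group stratification.
    Identical arguments and seed reproduce the cohort bit for bit.
    """
    if n_subjects < 1:
        raise InvalidScenarioError("n_subjects must be >= 1")
    if n_saturated + n_all_interrupted + n_partial_interrupted > n_subjects:
        raise InvalidScenarioError("special-status counts exceed n_subjects")
    template = scenario_template or SimScenario()
    rng = np.random.default_rng(seed)
    subjects = []
    for sid in range(n_subjects):
        rr = float(rng.uniform(*rate_range))
        sub_seed = int(rng.integers(0, 2**31 - 1))
        saturate = sid < n_saturated
        scenario = replace(
            template,
            rr_bpm=rr,
            seed=sub_seed,
            saturate=saturate,
        )
        if saturate:
            # drive the waveform well past the rails so clipping engages
            scenario = replace(
                scenario,
                drift_amp=max(scenario.drift_amp, 2.0),
                drift_period_s=max(scenario.drift_period_s, 30.0),
            )
        raw, truth = simulate_signal(scenario)
        interrupted = np.zeros(n_reference_minutes, dtype=bool)
        if n_saturated <= sid < n_saturated + n_all_interrupted:
            interrupted[:] = True
        elif (
            n_saturated + n_all_interrupted
            <= sid
            < n_saturated + n_all_interrupted + n_partial_interrupted
        ):
            interrupted[int(rng.integers(0, n_reference_minutes))] = True
        age = float(rng.normal(53.7, 16.7))
        subjects.append(
            CohortSubject(
                subject_id=sid,
                signal=raw,
                truth=truth,
                reference_counts=truth.reference_counts(n_reference_minutes),
                interrupted=interrupted,
                age=age,
                true_rr_bpm=rr,
            )
        )
    return subjects
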