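"""Device-vs-reference agreement analysis.

Device rates are paired with per-minute reference counts, the per-pair
deviation (device minus reference) and midpoint are tabulated, and the
distribution of deviations is summarised by its bias (mean), sample
standard deviation and a 95% interval — either empirical 2.5th/97.5th
percentiles (default) or parametric Bland-Altman limits of agreement
(bias +- 1.96 std).  Deviations are pooled at the minute level across
subjects.

Four evaluation cases cross the reference-count handling with the
processing mode:

====  =====================  ===================
case  reference minutes      processing mode
====  =====================  ===================
1     exclude interrupts     normal
2     exclude interrupts     adaptive sub-banding
3     include interrupts     normal
4     include interrupts     adaptive sub-banding
====  =====================  ===================

"Exclude interrupts" keeps only subjects whose reference minutes are all
non-interrupted; "include interrupts" keeps any subject with at least one
non-interrupted minute and drops the interrupted minutes themselves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyResultError, InsufficientDataError, InvalidParameterError
from .rr_core import BandTable, RREstimate

logger = logging.getLogger(__name__)

IntervalMethod = Literal["empirical_percentile", "parametric_loa"]
AgeGroup = Literal["lt55", "ge55"]

AGE_SPLIT_YEARS = 55.0

CASE_DEFS: dict[int, tuple[str, str]] = {
    1: ("exclude_interrupts", "normal"),
    2: ("exclude_interrupts", "subbanded"),
    3: ("include_interrupts", "normal"),
    4: ("include_interrupts", "subbanded"),
}


@dataclass(frozen=True)
class DeviationRecord:
    """One paired minute: device estimate vs reference count."""

    subject_id: int | str
    minute_index: int
    device_rr: float
    reference_count: float
    interrupted: bool = False
    age_group: AgeGroup | None = None

    @property
    def deviation(self) -> float:
        return self.device_rr - self.reference_count

    @property
    def mean_rr(self) -> float:
        return (self.device_rr + self.reference_count) / 2.0


@dataclass(frozen=True)
class AgreementStats:
    """Summary of a deviation distribution."""

    n: int
    bias: float
    std: float
    interval95: tuple[float, float]
    interval_method: IntervalMethod
    case_label: str = ""


def age_group_of(age: float) -> AgeGroup:
    return "ge55" if age >= AGE_SPLIT_YEARS else "lt55"


# ---------------------------------------------------------------------------
# Pairing and case stratification
# ---------------------------------------------------------------------------

def pair_deviations(
    estimates: Sequence[RREstimate],
    references: Sequence[float],
    interrupts: Sequence[bool] | None = None,
    subject_id: int | str = 0,
    age: float | None = None,
) -> list[DeviationRecord]:
    """Pair per-minute device estimates with reference counts.

    Estimates and references share the minute grid (window index = minute
    index).  Minutes missing a usable device value (corrupted or no-breaths
    windows) or missing a reference are dropped with a logged reason;
    interrupt flags are carried onto the records.  Raises
    :class:`EmptyResultError` when no minute survives.
    """
    by_minute = {e.window_index: e for e in estimates}
    if interrupts is None:
        interrupts = [False] * len(references)
    group = age_group_of(age) if age is not None else None
    records: list[DeviationRecord] = []
    for minute, ref in enumerate(references):
        est = by_minute.get(minute)
        if est is None:
            logger.info("subject %s minute %d: no device estimate", subject_id, minute)
            continue
        if est.quality in ("corrupted", "no_breaths") or not np.isfinite(est.rr_bpm):
            logger.info(
                "subject %s minute %d: device estimate unusable (%s)",
                subject_id, minute, est.quality,
            )
            continue
        records.append(
            DeviationRecord(
                subject_id=subject_id,
                minute_index=minute,
                device_rr=float(est.rr_bpm),
                reference_count=float(ref),
                interrupted=bool(interrupts[minute]),
                age_group=group,
            )
        )
    if not records:
        raise EmptyResultError(f"subject {subject_id}: no pairable minutes")
    return records


def filter_case(
    records_by_mode: Mapping[str, Sequence[DeviationRecord]],
    case_id: int,
) -> tuple[list[DeviationRecord], str]:
    """Select the record subset and processing mode for one evaluation case.

    ``records_by_mode`` maps ``"normal"`` and ``"subbanded"`` to the pooled
    per-minute records of the respective processing mode.  Cases 1-2 keep
    only subjects whose minutes are all non-interrupted; cases 3-4 keep
    subjects with at least one non-interrupted minute and drop interrupted
    minutes.  Returns the filtered records and the mode used.
    """
    if case_id not in CASE_DEFS:
        raise InvalidParameterError(f"unknown case id {case_id}; expected 1-4")
    count_type, mode = CASE_DEFS[case_id]
    if mode not in records_by_mode:
        raise InvalidParameterError(f"records for mode {mode!r} not provided")
    records = list(records_by_mode[mode])
    interrupted_subjects = {r.subject_id for r in records if r.interrupted}
    if count_type == "exclude_interrupts":
        kept = [r for r in records if r.subject_id not in interrupted_subjects]
    else:
        kept = [r for r in records if not r.interrupted]
    return kept, mode


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def agreement_stats(
    records: Sequence[DeviationRecord] | Sequence[float] | np.ndarray,
    interval_method: IntervalMethod = "empirical_percentile",
    case_label: str = "",
) -> AgreementStats:
    """Bias, sample SD and 95% interval of a deviation distribution.

    Accepts either :class:`DeviationRecord` sequences or bare deviation
    arrays.  The bias is the mean deviation; the SD uses the n-1
    denominator.  The default interval is the empirical (2.5th, 97.5th)
    percentile pair; ``parametric_loa`` gives Bland-Altman limits of
    agreement bias +- 1.96 std.  Requires n >= 2.
    """
    dev = _deviations(records)
    if dev.size < 2:
        raise InsufficientDataError(f"need >= 2 deviations, got {dev.size}")
    if interval_method not in ("empirical_percentile", "parametric_loa"):
        raise InvalidParameterError(f"unknown interval method {interval_method!r}")
    bias = float(np.mean(dev))
    std = float(np.std(dev, ddof=1))
    if interval_method == "parametric_loa":
        interval = (bias - 1.96 * std, bias + 1.96 * std)
    else:
        lo, hi = np.percentile(dev, [2.5, 97.5])
        interval = (float(lo), float(hi))
    return AgreementStats(
        n=int(dev.size),
        bias=bias,
        std=std,
        interval95=interval,
        interval_method=interval_method,
        case_label=case_label,
    )


def _deviations(records) -> np.ndarray:
    if len(records) and isinstance(records[0], DeviationRecord):
        return np.asarray([r.deviation for r in records], dtype=float)
    return np.asarray(records, dtype=float)


def bland_altman_table(
    records: Sequence[DeviationRecord],
    interval_method: IntervalMethod = "empirical_percentile",
    band_table: BandTable | None = None,
) -> tuple[pd.DataFrame, AgreementStats | None, list[float]]:
    """Plot-ready Bland-Altman pairs with their stats overlay.

    Returns a DataFrame of ``(subject_id, minute_index, mean_rr, deviation)``
    rows, the :class:`AgreementStats` for the bias/interval lines (``None``
    for a single record, where the interval is degenerate), and the band
    edges in bpm for the vertical sub-band markers (empty without a table).
    """
    if not records:
        raise EmptyResultError("no records to tabulate")
    table = pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "minute_index": [r.minute_index for r in records],
            "mean_rr": [r.mean_rr for r in records],
            "deviation": [r.deviation for r in records],
        }
    )
    stats = agreement_stats(records, interval_method) if len(records) >= 2 else None
    edges = band_table.edges_bpm if band_table is not None else []
    return table, stats, edges


def bland_altman_plot(
    records: Sequence[DeviationRecord],
    interval_method: IntervalMethod = "empirical_percentile",
    band_table: BandTable | None = None,
    ax=None,
    title: str = "",
):
    """Render a Bland-Altman scatter with bias/interval lines and band edges."""
    import matplotlib.pyplot as plt

    table, stats, edges = bland_altman_table(records, interval_method, band_table)
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(table["mean_rr"], table["deviation"], s=12, alpha=0.7)
    if stats is not None:
        ax.axhline(stats.bias, color="k", lw=1)
        for y in stats.interval95:
            ax.axhline(y, color="k", lw=1, ls="--")
    for x in edges:
        ax.axvline(x, color="grey", lw=0.8, ls=":")
    ax.set_xlabel("mean of device and reference RR (bpm)")
    ax.set_ylabel("device - reference (bpm)")
    if title:
        ax.set_title(title)
    return ax


@dataclass(frozen=True)
class BoxSummary:
    """Box-plot summary numbers: median, quartiles, 1.5*IQR whiskers."""

    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float


def _box_summary(dev: np.ndarray) -> BoxSummary:
    q1, med, q3 = np.percentile(dev, [25.0, 50.0, 75.0])
    iqr = q3 - q1
    in_low = dev[dev >= q1 - 1.5 * iqr]
    in_high = dev[dev <= q3 + 1.5 * iqr]
    return BoxSummary(
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=float(in_low.min()),
        whisker_high=float(in_high.max()),
    )


def subgroup_stats(
    records: Sequence[DeviationRecord],
    grouping: Literal["age_group", "subject_id"] = "age_group",
    interval_method: IntervalMethod = "empirical_percentile",
) -> dict[str, tuple[AgreementStats, BoxSummary]]:
    """Independent agreement stats (and box-plot numbers) per group.

    Groups with fewer than two records are skipped with a log message.
    """
    groups: dict[str, list[DeviationRecord]] = {}
    for r in records:
        key = getattr(r, grouping)
        if key is None:
            continue
        groups.setdefault(str(key), []).append(r)
    out: dict[str, tuple[AgreementStats, BoxSummary]] = {}
    for key in sorted(groups):
        recs = groups[key]
        if len(recs) < 2:
            logger.info("group %s skipped: only %d record(s)", key, len(recs))
            continue
        dev = _deviations(recs)
        out[key] = (
            agreement_stats(recs, interval_method, case_label=key),
            _box_summary(dev),
        )
    return out
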