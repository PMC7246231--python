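"""File formats, configuration, and the end-to-end batch pipeline.

All on-disk artefacts are plain CSV (signals, reference counts, per-minute
estimates, deviation records, agreement stats) plus a YAML run
configuration and a JSON run log.  Signal files carry either two columns
``t_s,intensity`` (sampling rate inferred from the median timestep) or a
single ``intensity`` column with the rate supplied externally.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .agreement import (
    CASE_DEFS,
    AgreementStats,
    DeviationRecord,
    agreement_stats,
    bland_altman_table,
    filter_case,
    pair_deviations,
)
from .errors import (
    EmptyResultError,
    InvalidParameterError,
    ParseError,
    ValidationError,
)
from .preprocess import RawSignal, SignalConfig
from .rr_core import (
    BAND_TOP_BPM,
    BandParams,
    BandTable,
    RREstimate,
    default_band_table,
    estimate_series,
)

logger = logging.getLogger(__name__)

FS_REGULARITY_TOL = 0.01  # max relative deviation of any timestep from the median


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RunConfig:
    """Validated whole-run configuration with documented defaults."""

    signal: SignalConfig = field(default_factory=SignalConfig)
    bands: BandTable = field(default_factory=default_band_table)
    interval_method: Literal["empirical_percentile", "parametric_loa"] = (
        "empirical_percentile"
    )
    cases: tuple[int, ...] = (1, 2, 3, 4)
    age_split_years: float = 55.0
    seed: int = 0

    def config_hash(self) -> str:
        blob = json.dumps(_config_to_dict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


_SIGNAL_KEYS = {
    "fs", "baseline_window_s", "k_thresh", "dilation_s", "energy_smooth_s",
    "min_run_s", "max_artifact_fraction",
}
_BAND_KEYS = {"low_bpm", "high_bpm", "ma_points", "min_breath_period_s",
              "hysteresis_frac"}
_PARAM_KEYS = {"ma_points", "min_breath_period_s", "hysteresis_frac"}
_TOP_KEYS = {"signal", "bands", "default_params", "interval_method", "cases",
             "age_split_years", "seed"}


def _config_to_dict(cfg: RunConfig) -> dict:
    return {
        "signal": asdict(cfg.signal),
        "bands": [
            {"low_bpm": lo, "high_bpm": hi, **asdict(p)}
            for lo, hi, p in cfg.bands.bands
        ],
        "default_params": asdict(cfg.bands.default_params),
        "interval_method": cfg.interval_method,
        "cases": list(cfg.cases),
        "age_split_years": cfg.age_split_years,
        "seed": cfg.seed,
    }


def _check_keys(mapping: Mapping, allowed: set, context: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ValidationError(
            f"unknown key(s) {sorted(unknown)} in {context}; "
            f"allowed: {sorted(allowed)}"
        )


def load_config(path: str | Path | None = None, overrides: Mapping | None = None) -> RunConfig:
    """Load and validate a YAML run configuration.

    Unknown keys are rejected; band tables are checked for contiguity and
    full coverage of [0, 50) bpm.  ``overrides`` (flat key -> value, applied
    to the signal block and top level) win over the file, which wins over
    defaults.
    """
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValidationError(f"config root must be a mapping: {path}")
    _check_keys(data, _TOP_KEYS, "config")

    sig_block = dict(data.get("signal", {}))
    _check_keys(sig_block, _SIGNAL_KEYS, "signal block")
    if overrides:
        for k, v in overrides.items():
            if v is None:
                continue
            if k in _SIGNAL_KEYS:
                sig_block[k] = v
    signal_cfg = SignalConfig(**sig_block)

    if "bands" in data:
        rows = data["bands"]
        if not isinstance(rows, list) or not rows:
            raise ValidationError("bands must be a non-empty list")
        bands = []
        for i, row in enumerate(rows):
            _check_keys(row, _BAND_KEYS, f"band {i}")
            if "low_bpm" not in row or "high_bpm" not in row:
                raise ValidationError(f"band {i} must state low_bpm and high_bpm")
            params = BandParams(**{k: row[k] for k in _PARAM_KEYS if k in row})
            bands.append((row["low_bpm"], row["high_bpm"], params))
        default_block = dict(data.get("default_params", {}))
        _check_keys(default_block, _PARAM_KEYS, "default_params")
        table = BandTable(
            bands=tuple(bands), default_params=BandParams(**default_block)
        )
    else:
        table = default_band_table()
    if table.bands[-1][1] < BAND_TOP_BPM:
        raise ValidationError(
            f"band table must cover [0, {BAND_TOP_BPM}) bpm; "
            f"top band ends at {table.bands[-1][1]}"
        )

    kwargs: dict = {}
    for key in ("interval_method", "age_split_years", "seed"):
        if key in data:
            kwargs[key] = data[key]
        if overrides and overrides.get(key) is not None:
            kwargs[key] = overrides[key]
    if "cases" in data:
        kwargs["cases"] = tuple(int(c) for c in data["cases"])
    if overrides and overrides.get("cases") is not None:
        kwargs["cases"] = tuple(int(c) for c in overrides["cases"])
    for c in kwargs.get("cases", ()):
        if c not in CASE_DEFS:
            raise ValidationError(f"unknown case id {c}; expected 1-4")
    cfg = RunConfig(signal=signal_cfg, bands=table, **kwargs)
    if cfg.interval_method not in ("empirical_percentile", "parametric_loa"):
        raise ValidationError(f"unknown interval_method {cfg.interval_method!r}")
    return cfg


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_signal(
    path: str | Path,
    fs_override: float | None = None,
    rail_low: float | None = None,
    rail_high: float | None = None,
) -> RawSignal:
    """Read a signal CSV (``t_s,intensity`` or bare ``intensity`` column).

    With timestamps, the sampling rate is the inverse median timestep;
    non-monotone timestamps or timesteps straying more than 1% from the
    median are rejected.  A one-column file requires ``fs_override``.
    Non-numeric rows raise a :class:`ParseError` naming the offending row.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError("signal file not found", path=path)
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:  # malformed CSV structure
        raise ParseError(f"unreadable CSV: {exc}", path=path) from exc
    if df.empty:
        raise ParseError("signal file has no data rows", path=path)
    cols = [c.strip() for c in df.columns]
    df.columns = cols
    if "intensity" not in cols:
        raise ParseError(
            f"expected an 'intensity' column, found {cols}", path=path
        )
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric["intensity"].isna() | (
        numeric["t_s"].isna() if "t_s" in cols else False
    )
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based + header
        raise ParseError("non-numeric value", path=path, row=row)

    if "t_s" in cols:
        t = numeric["t_s"].to_numpy(dtype=float)
        dt = np.diff(t)
        if t.size < 2 or np.any(dt <= 0):
            raise ParseError("timestamps must be strictly increasing", path=path)
        med = float(np.median(dt))
        if np.any(np.abs(dt - med) > FS_REGULARITY_TOL * med):
            raise ParseError(
                f"irregular sampling: timestep deviates > {FS_REGULARITY_TOL:.0%} "
                "from the median", path=path,
            )
        fs = fs_override if fs_override is not None else 1.0 / med
        t0 = float(t[0])
    else:
        if fs_override is None:
            raise ParseError(
                "one-column signal file requires an explicit sampling rate",
                path=path,
            )
        fs, t0 = fs_override, 0.0
    return RawSignal(
        samples=numeric["intensity"].to_numpy(dtype=float),
        fs=float(fs),
        t0=t0,
        rail_low=rail_low,
        rail_high=rail_high,
    )


def write_signal(path: str | Path, signal: RawSignal) -> None:
    t = signal.t0 + np.arange(signal.samples.size) / signal.fs
    pd.DataFrame({"t_s": t, "intensity": signal.samples}).to_csv(path, index=False)


def write_estimates(path: str | Path, estimates: Sequence[RREstimate]) -> None:
    estimates_frame(estimates).to_csv(path, index=False)


def estimates_frame(estimates: Sequence[RREstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "window_index": [e.window_index for e in estimates],
            "start_s": [e.start_s for e in estimates],
            "rr_pass1_bpm": [e.rr_pass1_bpm for e in estimates],
            "band_index": [e.band_index for e in estimates],
            "rr_bpm": [e.rr_bpm for e in estimates],
            "quality": [e.quality for e in estimates],
        }
    )


def read_estimates(path: str | Path) -> list[RREstimate]:
    df = pd.read_csv(path)
    return [
        RREstimate(
            rr_bpm=float(r.rr_bpm),
            rr_pass1_bpm=float(r.rr_pass1_bpm),
            band_index=int(r.band_index),
            window_index=int(r.window_index),
            start_s=float(r.start_s),
            quality=str(r.quality),
        )
        for r in df.itertuples()
    ]


def read_reference_counts(path: str | Path) -> pd.DataFrame:
    """Read ``subject_id,minute_index,count,interrupted[,age]`` counts CSV."""
    path = Path(path)
    if not path.exists():
        raise ParseError("reference counts file not found", path=path)
    df = pd.read_csv(path, comment="#")
    required = {"subject_id", "minute_index", "count", "interrupted"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"missing column(s) {sorted(missing)}", path=path)
    df["interrupted"] = df["interrupted"].astype(bool)
    return df


def write_reference_counts(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False)


def stats_frame(stats_rows: Sequence[AgreementStats]) -> pd.DataFrame:
    """Agreement stats as a Table-2-shaped frame (one row per case)."""
    rows = []
    for s in stats_rows:
        case_id, count_type, mode = s.case_label.split(":") if ":" in s.case_label else ("", "", "")
        rows.append(
            {
                "case": case_id,
                "manual_count_type": count_type,
                "processing_type": mode,
                "n": s.n,
                "bias_bpm": s.bias,
                "std_bpm": s.std,
                "ci95_low_bpm": s.interval95[0],
                "ci95_high_bpm": s.interval95[1],
                "interval_method": s.interval_method,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------

def run_pipeline(
    config: RunConfig,
    signal_paths: Mapping[int | str, str | Path],
    reference_path: str | Path,
    out_dir: str | Path,
    fs_override: float | None = None,
) -> dict:
    """Estimate, pair and evaluate a batch of recordings; write all outputs.

    ``signal_paths`` maps subject id to a signal CSV.  Per-subject failures
    are logged and reported without aborting the batch.  Writes per-minute
    estimate CSVs, a pooled deviation CSV, the per-case stats CSV and a JSON
    run log (package version, config hash, per-subject status).  Output is
    deterministic for identical inputs and configuration.
    """
    if not signal_paths:
        raise EmptyResultError("no signals to process")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    refs = read_reference_counts(reference_path)

    records_by_mode: dict[str, list[DeviationRecord]] = {"normal": [], "subbanded": []}
    subject_status: dict[str, str] = {}
    for sid in sorted(signal_paths, key=str):
        try:
            raw = read_signal(signal_paths[sid], fs_override=fs_override)
            sub_refs = refs[refs["subject_id"].astype(str) == str(sid)]
            sub_refs = sub_refs.sort_values("minute_index")
            if sub_refs.empty:
                raise EmptyResultError(f"no reference counts for subject {sid}")
            counts = sub_refs["count"].to_list()
            interrupts = sub_refs["interrupted"].to_list()
            age = float(sub_refs["age"].iloc[0]) if "age" in sub_refs else None
            for mode in ("normal", "subbanded"):
                estimates = estimate_series(raw, config.bands, mode, config.signal)
                write_estimates(out_dir / f"estimates_{sid}_{mode}.csv", estimates)
                records_by_mode[mode].extend(
                    pair_deviations(estimates, counts, interrupts, sid, age)
                )
            subject_status[str(sid)] = "ok"
        except Exception as exc:
            logger.warning("subject %s failed: %s", sid, exc)
            subject_status[str(sid)] = f"error: {exc}"

    if not any(records_by_mode.values()):
        raise EmptyResultError("no subject produced pairable minutes")

    dev_rows = []
    for mode, recs in records_by_mode.items():
        for r in recs:
            dev_rows.append(
                {
                    "mode": mode,
                    "subject_id": r.subject_id,
                    "minute_index": r.minute_index,
                    "device_rr": r.device_rr,
                    "reference_count": r.reference_count,
                    "deviation": r.deviation,
                    "mean_rr": r.mean_rr,
                    "interrupted": r.interrupted,
                    "age_group": r.age_group,
                }
            )
    pd.DataFrame(dev_rows).to_csv(out_dir / "deviations.csv", index=False)

    stats_rows = []
    ba_frames = []
    for case_id in config.cases:
        recs, mode = filter_case(records_by_mode, case_id)
        if len(recs) < 2:
            logger.warning("case %d skipped: %d record(s)", case_id, len(recs))
            continue
        count_type = CASE_DEFS[case_id][0]
        stats_rows.append(
            agreement_stats(
                recs, config.interval_method,
                case_label=f"{case_id}:{count_type}:{mode}",
            )
        )
        table, _, _ = bland_altman_table(recs, config.interval_method, config.bands)
        table.insert(0, "case", case_id)
        ba_frames.append(table)

    stats_df = stats_frame(stats_rows)
    stats_df.to_csv(out_dir / "stats.csv", index=False)
    if ba_frames:
        pd.concat(ba_frames).to_csv(out_dir / "bland_altman.csv", index=False)

    run_log = {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "config": _config_to_dict(config),
        "subjects": subject_status,
        "n_cases": len(stats_rows),
    }
    with open(out_dir / "run_log.json", "w") as fh:
        json.dump(run_log, fh, indent=2, sort_keys=True)
    return {"stats": stats_df, "records_by_mode": records_by_mode, "log": run_log}
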