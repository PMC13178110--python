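"""Session FRET, ΔFRET time courses, day summaries and trapezoidal AUC.

The session statistic is deliberately simple: FRET is the mean ROI
intensity of excitation frames minus the mean of the interleaved LED-off
control frames over the one-minute interleaved window.  The subtraction
removes ambient light and any common-mode (motion) artifact; it does not
correct photobleaching, because the control frames carry no fluorescence —
the method is reproduced as practised, isosbestic-style corrections are
out of scope.

ΔFRET at hour t is the percent change from the same animal's pre-treatment
(hour-0) FRET: 100 * (F_t - F0) / F0.  The day is summarised by the
maximum and minimum ΔFRET across the recorded hours (hour 0, identically
zero, included) and by the trapezoidal area under the ΔFRET-time curve
over hours 0-3, in %·h.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import BaselineError, DegenerateDataError
from .io import ExperimentManifest, read_recording, validate_stream
from .simulate import SessionSchedule

__all__ = [
    "FretMeasurement",
    "DeltaFretSeries",
    "SessionSummary",
    "ExperimentResult",
    "compute_fret",
    "compute_delta_fret",
    "summarize_day",
    "auc_trapezoid",
    "process_experiment",
]


@dataclass(frozen=True)
class FretMeasurement:
    """Mean on-frame minus mean interleaved off-frame intensity over a window."""

    fret: float
    n_on: int
    n_off: int
    window: tuple[float, float]


@dataclass(frozen=True)
class DeltaFretSeries:
    """Per-hour percent change in FRET relative to the hour-0 baseline."""

    animal_id: str
    treatment: str
    pre_treatment_fret: float
    hours: tuple[float, ...]
    delta_fret: tuple[float, ...]
    fret: tuple[float, ...]


@dataclass(frozen=True)
class SessionSummary:
    """Max/min ΔFRET over the recording day and trapezoidal AUC (%·h).

    ``auc`` is NaN when the day is missing one of the required hours —
    a trapezoid over a gapped grid would silently measure something else.
    """

    max_delta_fret: float
    min_delta_fret: float
    auc: float

    @property
    def auc_available(self) -> bool:
        return not math.isnan(self.auc)


def compute_fret(
    frames: pd.DataFrame, window: tuple[float, float] | None = None
) -> FretMeasurement:
    """FRET over ``window`` (seconds, [start, end)): mean LED-on minus mean LED-off intensity.

    Raises :class:`DegenerateDataError` if the window holds no frames of
    either LED state (no control to subtract).
    """
    t = frames["Timestamp"].to_numpy(dtype=float)
    led = frames["LedState"].to_numpy()
    roi = frames["Region0"].to_numpy(dtype=float)
    if window is None:
        mask = np.ones(len(frames), dtype=bool)
        window = (float(t[0]), float(t[-1])) if len(t) else (0.0, 0.0)
    else:
        mask = (t >= window[0]) & (t < window[1])
    on = roi[mask & (led == 1)]
    off = roi[mask & (led == 0)]
    if len(on) == 0 or len(off) == 0:
        raise DegenerateDataError(
            f"window {window} holds {len(on)} LED-on and {len(off)} LED-off frames; "
            "both states are required to form the interleaved control"
        )
    return FretMeasurement(
        fret=float(on.mean() - off.mean()),
        n_on=int(len(on)),
        n_off=int(len(off)),
        window=(float(window[0]), float(window[1])),
    )


def compute_delta_fret(
    measurements: Mapping[float, "FretMeasurement | float"],
    animal_id: str = "",
    treatment: str = "",
) -> DeltaFretSeries:
    """ΔFRET time course: 100 * (F_t - F0) / F0 per recorded hour.

    ``measurements`` maps hour-post-administration to the session FRET
    (a :class:`FretMeasurement` or bare float).  Hour 0 must be present and
    its FRET strictly positive; the hour-0 entry of the result is exactly 0.
    """
    vals = {float(h): (m.fret if isinstance(m, FretMeasurement) else float(m))
            for h, m in measurements.items()}
    if 0.0 not in vals:
        raise BaselineError("no hour-0 (pre-treatment) measurement; ΔFRET is undefined")
    f0 = vals[0.0]
    if f0 <= 0:
        raise BaselineError(
            f"pre-treatment FRET is {f0:g} <= 0; the ΔFRET ratio is undefined "
            "(sign-inverting) for a non-positive baseline"
        )
    hours = tuple(sorted(vals))
    fret = tuple(vals[h] for h in hours)
    delta = tuple(0.0 if h == 0.0 else 100.0 * (vals[h] - f0) / f0 for h in hours)
    return DeltaFretSeries(
        animal_id=animal_id,
        treatment=treatment,
        pre_treatment_fret=f0,
        hours=hours,
        delta_fret=delta,
        fret=fret,
    )


def auc_trapezoid(hours: Sequence[float], delta_fret: Sequence[float]) -> float:
    """Trapezoidal area under the ΔFRET-time curve, in %·h.

    Sum over consecutive timepoints of (y_A + y_B)/2 * (t_B - t_A); supports
    non-uniform spacing.  Requires at least two points and strictly
    increasing hours.
    """
    t = np.asarray(hours, dtype=float)
    y = np.asarray(delta_fret, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("hours and delta_fret must be 1-D and equally long")
    if len(t) < 2:
        raise DegenerateDataError("AUC needs at least two timepoints")
    if np.any(np.diff(t) <= 0):
        raise DegenerateDataError("hours must be strictly increasing")
    return float(np.sum((y[:-1] + y[1:]) / 2.0 * np.diff(t)))


def summarize_day(
    series: DeltaFretSeries,
    required_hours: Sequence[float] = (0.0, 1.0, 2.0, 3.0),
) -> SessionSummary:
    """Max/min ΔFRET over all recorded hours (hour 0 included) plus the AUC.

    Max and min use whatever hours are available; the AUC is only computed
    when every hour in ``required_hours`` was recorded, and is NaN otherwise.
    """
    delta = np.asarray(series.delta_fret)
    have = set(series.hours)
    if set(float(h) for h in required_hours) <= have:
        auc = auc_trapezoid(series.hours, series.delta_fret)
    else:
        auc = math.nan
    return SessionSummary(
        max_delta_fret=float(delta.max()),
        min_delta_fret=float(delta.min()),
        auc=auc,
    )


@dataclass
class ExperimentResult:
    """Output of :func:`process_experiment`.

    ``cohort_table`` is the long-format table feeding the statistics layer
    (one row per animal x treatment x hour); ``summaries`` has one row per
    animal x treatment day; ``report`` records per-block failures and QC
    flags without aborting the rest of the experiment.
    """

    cohort_table: pd.DataFrame
    summaries: pd.DataFrame
    series: list[DeltaFretSeries]
    report: dict

    def write(self, out_dir) -> None:
        from pathlib import Path
        import json

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.cohort_table.to_csv(out / "delta_fret.csv", index=False)
        self.summaries.to_csv(out / "summaries.csv", index=False)
        (out / "run_report.json").write_text(json.dumps(self.report, indent=2) + "\n")


def process_experiment(
    manifest: ExperimentManifest,
    recordings: Mapping[str, pd.DataFrame] | None = None,
    schedule: SessionSchedule = SessionSchedule(),
    window: tuple[float, float] | None = None,
    required_hours: Sequence[float] | None = None,
    min_frames_per_state: int = 100,
) -> ExperimentResult:
    """Run the full per-block analysis over an experiment manifest.

    For every (animal, treatment) block: read each session's frames (from
    ``recordings`` — a mapping keyed by the manifest's file names — when
    given, else from disk), run stream QC, compute the session FRET over the
    interleaved window, form the ΔFRET series against the hour-0 baseline
    and summarise the day.  Blocks that fail (unreadable file, failed QC on
    the baseline, non-positive F0, ...) are reported and skipped; the rest
    of the experiment still processes.
    """
    if window is None:
        window = schedule.analysis_window
    if required_hours is None:
        required_hours = schedule.hours

    rows: list[dict] = []
    summary_rows: list[dict] = []
    series_out: list[DeltaFretSeries] = []
    failures: list[dict] = []
    qc_flags: list[dict] = []

    for (animal, treatment), block in manifest.blocks().items():
        meta0 = block[0]
        try:
            measurements: dict[float, FretMeasurement] = {}
            for sess in block:
                if recordings is not None and sess.file in recordings:
                    frames = recordings[sess.file]
                else:
                    frames = read_recording(manifest.resolve(sess))
                qc = validate_stream(frames, schedule, min_frames_per_state)
                if not qc.passed:
                    qc_flags.append(
                        {"animal_id": animal, "treatment": treatment,
                         "hour": sess.hour, "messages": qc.messages}
                    )
                    if sess.hour == 0.0:
                        raise BaselineError(
                            f"baseline session failed QC: {'; '.join(qc.messages)}"
                        )
                    continue  # drop this hour, keep the block
                measurements[sess.hour] = compute_fret(frames, window)
            series = compute_delta_fret(measurements, animal, treatment)
            summary = summarize_day(series, required_hours)
        except Exception as exc:  # noqa: BLE001 - per-block isolation is the contract
            failures.append(
                {"animal_id": animal, "treatment": treatment, "error": str(exc)}
            )
            continue

        series_out.append(series)
        for h, f, d in zip(series.hours, series.fret, series.delta_fret):
            rows.append(
                {
                    "animal_id": animal,
                    "genotype": meta0.genotype,
                    "treatment": treatment,
                    "dose": meta0.dose,
                    "route": meta0.route,
                    "hour": h,
                    "fret": f,
                    "delta_fret": d,
                }
            )
        summary_rows.append(
            {
                "animal_id": animal,
                "treatment": treatment,
                "max_delta_fret": summary.max_delta_fret,
                "min_delta_fret": summary.min_delta_fret,
                "auc": summary.auc,
            }
        )

    cohort = pd.DataFrame(
        rows,
        columns=["animal_id", "genotype", "treatment", "dose", "route",
                 "hour", "fret", "delta_fret"],
    )
    summaries = pd.DataFrame(
        summary_rows,
        columns=["animal_id", "treatment", "max_delta_fret", "min_delta_fret", "auc"],
    )
    report = {
        "n_blocks": len(manifest.blocks()),
        "n_processed": len(summary_rows),
        "failures": failures,
        "qc_flags": qc_flags,
        "window_s": list(window),
    }
    return ExperimentResult(cohort, summaries, series_out, report)
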