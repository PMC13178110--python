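"""Reading, writing and validating frame-level photometry recordings.

The on-disk dialect mirrors what a Bonsai acquisition workflow emits: one
row per camera frame with a frame counter, a timestamp in seconds from the
start of the recording, the excitation-LED state (1 = 415 nm LED on,
0 = interleaved control frame) and the mean pixel intensity of the fibre-face
region of interest.  CSV is canonical; XLSX is accepted because the original
acquisition produced spreadsheets.  Header names are configurable since
acquisition workflows differ.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyRecordingError, ManifestError, SchemaError
from .simulate import SessionSchedule

__all__ = [
    "CANONICAL_COLUMNS",
    "FrameRecord",
    "SessionMeta",
    "ExperimentManifest",
    "AnimalHistology",
    "StreamQC",
    "read_recording",
    "write_recording",
    "iter_records",
    "validate_stream",
    "load_manifest",
    "write_manifest",
]

#: canonical field -> default on-disk header
CANONICAL_COLUMNS: dict[str, str] = {
    "frame_index": "FrameCounter",
    "timestamp": "Timestamp",
    "led_state": "LedState",
    "roi_intensity": "Region0",
}


class FrameRecord(NamedTuple):
    frame_index: int
    timestamp: float
    led_state: int
    roi_intensity: float


@dataclass(frozen=True)
class SessionMeta:
    """Metadata for one recording session of one animal."""

    animal_id: str
    genotype: str
    treatment: str
    dose: float
    route: str
    hour: float
    file: str
    day: int | None = None


@dataclass
class ExperimentManifest:
    sessions: list[SessionMeta]
    washout_hours: float | None = None
    base_dir: Path | None = None

    def blocks(self) -> dict[tuple[str, str], list[SessionMeta]]:
        """Sessions grouped by (animal_id, treatment), hours ascending."""
        out: dict[tuple[str, str], list[SessionMeta]] = {}
        for s in self.sessions:
            out.setdefault((s.animal_id, s.treatment), []).append(s)
        for key in out:
            out[key] = sorted(out[key], key=lambda s: s.hour)
        return out

    def resolve(self, session: SessionMeta) -> Path:
        p = Path(session.file)
        return p if p.is_absolute() or self.base_dir is None else self.base_dir / p


@dataclass(frozen=True)
class AnimalHistology:
    """Post-mortem counts used by the inclusion rule."""

    animal_id: str
    eyfp_neuron_count: int
    fibre_on_target: bool = True
    days_transduction_to_euthanasia: int | None = None
    n_test_sessions: int | None = None

    def __post_init__(self) -> None:
        if self.eyfp_neuron_count < 0:
            raise ValueError("eyfp_neuron_count must be >= 0")


# ---------------------------------------------------------------------------
# recordings
# ---------------------------------------------------------------------------

def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower().lstrip(".")
    return suffix if suffix in ("csv", "xlsx") else "csv"


def read_recording(
    path: str | Path,
    fmt: str | None = None,
    columns: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read one frame-level recording into a DataFrame with canonical headers.

    Parameters
    ----------
    path
        CSV or XLSX file; format inferred from the suffix unless ``fmt`` given.
    columns
        Optional override of the canonical-field -> header map
        (defaults to :data:`CANONICAL_COLUMNS`).

    Raises
    ------
    SchemaError
        If a required column is absent (the message names it) or a row holds
        a non-numeric intensity (the message gives its index).
    EmptyRecordingError
        If the file parses to zero frames.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, fmt)
    colmap = {**CANONICAL_COLUMNS, **(columns or {})}

    if fmt == "xlsx":
        raw = pd.read_excel(path)
    else:
        try:
            raw = pd.read_csv(path)
        except pd.errors.EmptyDataError:
            raise EmptyRecordingError(f"{path} is empty") from None
    if raw.empty:
        raise EmptyRecordingError(f"{path} contains no frames")

    missing = [hdr for hdr in colmap.values() if hdr not in raw.columns]
    if missing:
        raise SchemaError(f"{path} is missing required column(s): {', '.join(missing)}")

    frames = raw[[colmap[k] for k in CANONICAL_COLUMNS]].copy()
    frames.columns = list(CANONICAL_COLUMNS.values())
    for canon, hdr in CANONICAL_COLUMNS.items():
        coerced = pd.to_numeric(frames[hdr], errors="coerce")
        bad = coerced.isna() & frames[hdr].notna() | frames[hdr].isna()
        if bad.any():
            idx = int(np.flatnonzero(bad.to_numpy())[0])
            raise SchemaError(
                f"{path}: non-numeric {hdr} value {frames[hdr].iloc[idx]!r} at row {idx}"
            )
        frames[hdr] = coerced
    frames["FrameCounter"] = frames["FrameCounter"].astype(int)
    frames["LedState"] = frames["LedState"].astype(int)
    if not frames["LedState"].isin((0, 1)).all():
        raise SchemaError(f"{path}: LedState must be 0 or 1")
    return frames.reset_index(drop=True)


def write_recording(frames: pd.DataFrame, path: str | Path, fmt: str | None = None) -> Path:
    """Write a canonical frame table to CSV or XLSX (inferred from the suffix)."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    out = frames[list(CANONICAL_COLUMNS.values())]
    if fmt == "xlsx":
        out.to_excel(path, index=False)
    else:
        out.to_csv(path, index=False)
    return path


def iter_records(frames: pd.DataFrame) -> Iterator[FrameRecord]:
    """Iterate a frame table as typed :class:`FrameRecord` tuples."""
    for row in frames.itertuples(index=False):
        yield FrameRecord(
            int(row.FrameCounter), float(row.Timestamp), int(row.LedState), float(row.Region0)
        )


# ---------------------------------------------------------------------------
# stream QC
# ---------------------------------------------------------------------------

@dataclass
class StreamQC:
    """Report-only quality summary of one frame stream; callers decide on exclusion."""

    n_frames: int
    duration_s: float
    n_on: int
    n_off: int
    n_gaps: int
    n_dropped: int
    duty_cycle: float
    passed: bool
    messages: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {**self.__dict__}


def validate_stream(
    frames: pd.DataFrame,
    schedule: SessionSchedule | None = None,
    min_frames_per_state: int = 100,
) -> StreamQC:
    """Summarise a stream and flag grossly deficient recordings.

    Counts frames per LED state, dropped-frame gaps (jumps in the frame
    counter) and the LED duty cycle; fails streams with no excitation
    frames, too few frames of either state within the analysis window, or
    non-monotonic frame counters.  Never raises: exclusion is the caller's
    decision.
    """
    msgs: list[str] = []
    n = len(frames)
    t = frames["Timestamp"].to_numpy()
    led = frames["LedState"].to_numpy()
    duration = float(t[-1] - t[0]) if n else 0.0

    idx = frames["FrameCounter"].to_numpy()
    diffs = np.diff(idx)
    if np.any(diffs <= 0):
        msgs.append("frame counter is not strictly increasing")
    gaps = diffs[diffs > 1]
    n_gaps = int(len(gaps))
    n_dropped = int((gaps - 1).sum()) if n_gaps else 0
    if n_gaps:
        msgs.append(f"{n_dropped} dropped frame(s) across {n_gaps} gap(s)")

    if schedule is not None:
        lo, hi = schedule.analysis_window
        in_win = (t >= lo) & (t < hi)
    else:
        in_win = np.ones(n, dtype=bool)
    n_on = int((led[in_win] == 1).sum())
    n_off = int((led[in_win] == 0).sum())
    duty = n_on / max(1, n_on + n_off)

    passed = True
    if n == 0:
        passed = False
        msgs.append("empty stream")
    elif n_on == 0:
        passed = False
        msgs.append("no excitation frames")
    elif n_on < min_frames_per_state or n_off < min_frames_per_state:
        passed = False
        msgs.append(
            f"too few frames per LED state in analysis window "
            f"(on={n_on}, off={n_off}, need >= {min_frames_per_state})"
        )
    if np.any(diffs <= 0):
        passed = False

    return StreamQC(
        n_frames=n,
        duration_s=duration,
        n_on=n_on,
        n_off=n_off,
        n_gaps=n_gaps,
        n_dropped=n_dropped,
        duty_cycle=duty,
        passed=passed,
        messages=msgs,
    )


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------

def load_manifest(
    path: str | Path,
    check_files: bool = True,
    require_baseline: bool = True,
) -> ExperimentManifest:
    """Load and validate a JSON experiment manifest.

    The manifest is an object with a ``sessions`` array (each entry:
    file, animal_id, genotype, treatment, dose, route, hour, optional day)
    and an optional ``washout_hours``.  Validation enforces unique
    (animal, treatment, hour) cells, an hour-0 session in every
    (animal, treatment) block, and — when ``check_files`` — that every
    referenced recording exists relative to the manifest's directory.
    """
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ManifestError(f"{path} is not valid JSON: {exc}") from exc
    if isinstance(payload, list):  # bare session array is accepted
        payload = {"sessions": payload}
    raw_sessions = payload.get("sessions")
    if not isinstance(raw_sessions, list) or not raw_sessions:
        raise ManifestError(f"{path}: manifest must contain a non-empty 'sessions' array")

    required = ("file", "animal_id", "genotype", "treatment", "dose", "route", "hour")
    sessions: list[SessionMeta] = []
    for i, entry in enumerate(raw_sessions):
        missing = [k for k in required if k not in entry]
        if missing:
            raise ManifestError(f"{path}: session {i} missing field(s) {missing}")
        sessions.append(
            SessionMeta(
                animal_id=str(entry["animal_id"]),
                genotype=str(entry["genotype"]),
                treatment=str(entry["treatment"]),
                dose=float(entry["dose"]),
                route=str(entry["route"]),
                hour=float(entry["hour"]),
                file=str(entry["file"]),
                day=int(entry["day"]) if "day" in entry else None,
            )
        )

    seen: set[tuple[str, str, float]] = set()
    for s in sessions:
        key = (s.animal_id, s.treatment, s.hour)
        if key in seen:
            raise ManifestError(f"duplicate session for animal={s.animal_id} "
                                f"treatment={s.treatment} hour={s.hour}")
        seen.add(key)

    manifest = ExperimentManifest(
        sessions=sessions,
        washout_hours=payload.get("washout_hours"),
        base_dir=path.parent,
    )
    if manifest.washout_hours is not None and manifest.washout_hours < 24:
        raise ManifestError(
            f"recorded washout of {manifest.washout_hours} h is below the 24 h minimum"
        )

    if require_baseline:
        for (animal, treatment), block in manifest.blocks().items():
            if not any(s.hour == 0.0 for s in block):
                raise ManifestError(
                    f"block animal={animal} treatment={treatment} lacks the "
                    "pre-treatment (hour-0) session"
                )
    if check_files:
        missing_files = [str(manifest.resolve(s)) for s in sessions
                         if not manifest.resolve(s).exists()]
        if missing_files:
            raise ManifestError(
                "manifest references missing recording file(s): " + ", ".join(missing_files)
            )
    return manifest


def write_manifest(manifest: ExperimentManifest, path: str | Path) -> Path:
    """Serialise a manifest back to JSON (paths kept as stored)."""
    path = Path(path)
    payload = {
        "washout_hours": manifest.washout_hours,
        "sessions": [
            {k: v for k, v in vars(s).items() if v is not None} for s in manifest.sessions
        ],
    }
    path.write_text(json.dumps(payload, indent=2) + "\n")
    return path
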