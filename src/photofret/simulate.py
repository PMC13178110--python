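"""Mechanistic simulator for in vivo FRET-sensor photometry sessions.

The generative model: neurons continuously synthesise an intact
donor--linker--acceptor sensor whose linker is cleaved by calpain.  The
intact pool S obeys

    dS/dt = k_syn - (k_deg + k_cl * a(t)) * S

where a(t) is calpain activity.  A drug perturbs activity through a
Bateman-type onset/washout curve; the camera sees ``gain * S`` counts on
excitation frames plus an ambient floor, interleaved with LED-off control
frames that see the ambient floor (and any common-mode motion artifact)
only.  Photobleaching erodes the gain with cumulative LED-on exposure.

Defaults describe a plausible recording rig and sensor: basal activity is
scaled to 1, cleavage dominates turnover (k_cl*a0 >> k_deg) so the sensor
pool responds to inhibitors within tens of minutes, and noise/bleaching
are small enough that a 1-minute interleaved window resolves a few-percent
change in FRET.  See docs/methods.md for the reasoning behind each value.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd

from .errors import PhotometryError

__all__ = [
    "SensorKineticsParams",
    "DrugEffectProfile",
    "SessionSchedule",
    "TreatmentArm",
    "SimulatedCohortSpec",
    "CohortSimulation",
    "activity_trace",
    "sensor_pool_trace",
    "render_session",
    "simulate_cohort",
    "magnitude_for_delta_fret",
]


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SensorKineticsParams:
    """Constants of the sensor/optics model.

    Parameters
    ----------
    k_syn
        Sensor synthesis rate (intensity-units per hour).
    k_deg
        Activity-independent sensor turnover (1/h).
    k_cl
        Cleavage rate per unit calpain activity (1/h per activity-unit).
    a0
        Basal calpain activity (dimensionless, >= 0).
    gain
        Fluorescence counts per unit intact sensor.
    ambient
        LED-independent background (camera counts).
    bleach_rate
        Fractional gain loss per second of cumulative LED-on exposure (1/s).
    noise_sd
        Per-frame additive Gaussian noise (camera counts).
    fps
        Camera frame rate (frames per second).
    """

    k_syn: float = 100.0
    k_deg: float = 0.2
    k_cl: float = 3.0
    a0: float = 1.0
    gain: float = 1.0
    ambient: float = 5.0
    bleach_rate: float = 1e-5
    noise_sd: float = 2.0
    fps: float = 41.0

    def __post_init__(self) -> None:
        for name in ("k_syn", "k_deg", "k_cl", "a0", "bleach_rate", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.gain <= 0:
            raise ValueError("gain must be > 0")
        if self.fps <= 0:
            raise ValueError("fps must be > 0")
        if self.k_deg + self.k_cl * self.a0 <= 0:
            raise ValueError(
                "k_deg + k_cl*a0 must be > 0 (otherwise the intact pool has no steady state)"
            )

    @property
    def steady_state(self) -> float:
        """Pre-dose intact-sensor pool, k_syn / (k_deg + k_cl*a0)."""
        return self.k_syn / (self.k_deg + self.k_cl * self.a0)


@dataclass(frozen=True)
class DrugEffectProfile:
    """Pharmacodynamic perturbation of calpain activity.

    ``kind`` is one of ``inhibitor``, ``activator``, ``vehicle``.
    ``magnitude`` is the maximal fractional change in activity (at the peak
    of the onset/washout curve): activity is a0*(1 - m*B(t)) for inhibitors
    and a0*(1 + m*B(t)) for activators, with B normalised to peak 1.
    ``k_on``/``k_off`` are the onset and washout rates in 1/h; k_off = 0
    models a sustained effect that does not wash out within the day.
    """

    kind: Literal["inhibitor", "activator", "vehicle"]
    magnitude: float = 0.0
    k_on: float = 6.0
    k_off: float = 0.3

    def __post_init__(self) -> None:
        if self.kind not in ("inhibitor", "activator", "vehicle"):
            raise ValueError(f"unknown profile kind {self.kind!r}")
        if self.kind == "vehicle" and self.magnitude != 0.0:
            raise ValueError("vehicle profile must have magnitude 0")
        if self.kind == "inhibitor" and not (0.0 <= self.magnitude < 1.0):
            raise ValueError(
                "inhibitor magnitude must lie in [0, 1); activity would go "
                "negative at the effect peak"
            )
        if self.kind == "activator" and self.magnitude < 0:
            raise ValueError("activator magnitude must be >= 0")
        if self.kind != "vehicle" and self.k_on <= 0:
            raise ValueError("k_on must be > 0")
        if self.k_off < 0:
            raise ValueError("k_off must be >= 0")

    def bateman(self, t: np.ndarray | float) -> np.ndarray:
        """Onset/washout curve normalised to peak 1; 0 for t < 0."""
        t = np.asarray(t, dtype=float)
        if self.kind == "vehicle":
            return np.zeros_like(t)
        ka, ke = self.k_on, self.k_off
        tt = np.maximum(t, 0.0)
        if ke == 0.0:
            b = 1.0 - np.exp(-ka * tt)  # sustained effect, sup B = 1
        elif math.isclose(ka, ke):
            # degenerate Bateman: shape t*exp(-k t), peak at 1/k
            b = ka * tt * np.exp(1.0 - ka * tt)
        else:
            t_peak = math.log(ka / ke) / (ka - ke)
            peak = math.exp(-ke * t_peak) - math.exp(-ka * t_peak)
            b = (np.exp(-ke * tt) - np.exp(-ka * tt)) / peak
        return np.where(t >= 0, b, 0.0)


@dataclass(frozen=True)
class SessionSchedule:
    """Recording schedule of one treatment day.

    ``hours`` are hours post-administration at which sessions are recorded
    (hour 0 is the pre-treatment baseline, immediately before dosing); each
    session is ``off_lead_s`` seconds with the LED dark followed by
    ``interleaved_s`` seconds of strictly alternating LED-on / LED-off frames.
    """

    hours: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0)
    off_lead_s: float = 60.0
    interleaved_s: float = 60.0

    def __post_init__(self) -> None:
        hours = tuple(float(h) for h in self.hours)
        object.__setattr__(self, "hours", hours)
        if len(hours) == 0 or hours[0] != 0.0:
            raise ValueError("schedule must start with the pre-treatment hour 0")
        if any(b <= a for a, b in zip(hours, hours[1:])):
            raise ValueError("hours must be strictly ascending")
        if self.off_lead_s <= 0 or self.interleaved_s <= 0:
            raise ValueError("session durations must be > 0")

    @property
    def session_s(self) -> float:
        return self.off_lead_s + self.interleaved_s

    @property
    def analysis_window(self) -> tuple[float, float]:
        """The interleaved minute, the window the FRET statistic averages."""
        return (self.off_lead_s, self.off_lead_s + self.interleaved_s)


@dataclass(frozen=True)
class TreatmentArm:
    """One treatment condition: a label plus its pharmacodynamics and dosing metadata."""

    label: str
    profile: DrugEffectProfile
    dose: float = 0.0          # mg/kg
    route: str = "s.c."


@dataclass(frozen=True)
class SimulatedCohortSpec:
    """A cohort to simulate: animals x treatments, with per-animal heterogeneity.

    ``jitter_cv`` is the coefficient of variation of lognormal per-animal
    multipliers applied to k_syn and gain (viral-expression variability);
    it does not touch the kinetic rates, so ΔFRET — a within-animal ratio —
    is unaffected by it in expectation.
    """

    n_animals: int = 8
    treatments: tuple[TreatmentArm, ...] = (
        TreatmentArm("vehicle", DrugEffectProfile("vehicle")),
        TreatmentArm("calpeptin-like", DrugEffectProfile("inhibitor", magnitude=0.25), dose=2.0),
    )
    jitter_cv: float = 0.3
    seed: int = 0
    latin_square: bool = True
    genotypes: tuple[str, ...] | None = None   # per-animal; default all "WT"

    def __post_init__(self) -> None:
        object.__setattr__(self, "treatments", tuple(self.treatments))
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")
        if len(self.treatments) < 1:
            raise ValueError("at least one treatment arm required")
        labels = [t.label for t in self.treatments]
        if len(set(labels)) != len(labels):
            raise ValueError("treatment labels must be unique")
        if self.jitter_cv < 0:
            raise ValueError("jitter_cv must be >= 0")
        if self.genotypes is not None:
            object.__setattr__(self, "genotypes", tuple(self.genotypes))
            if len(self.genotypes) != self.n_animals:
                raise ValueError("genotypes must give one entry per animal")


# ---------------------------------------------------------------------------
# kinetics
# ---------------------------------------------------------------------------

def activity_trace(
    profile: DrugEffectProfile, a0: float, t: Sequence[float] | np.ndarray
) -> np.ndarray:
    """Calpain activity a(t) on a grid of hours since administration.

    a(t) = a0 * (1 -/+ magnitude * B(t)) with B the unit-peak Bateman curve
    (- for inhibitors, + for activators); vehicle returns constant a0.
    """
    t = np.asarray(t, dtype=float)
    if t.ndim != 1:
        raise ValueError("t must be one-dimensional")
    if len(t) and (np.any(t < 0) or np.any(np.diff(t) <= 0)):
        raise ValueError("t must be non-negative and strictly increasing")
    if a0 < 0:
        raise ValueError("a0 must be >= 0")
    sign = {"inhibitor": -1.0, "activator": +1.0, "vehicle": 0.0}[profile.kind]
    a = a0 * (1.0 + sign * profile.magnitude * profile.bateman(t))
    return np.maximum(a, 0.0)


def _rk4_linear_decay(
    rate: Callable[[np.ndarray], np.ndarray],
    source: float,
    s0: float,
    t0: float,
    t1: float,
    max_step_h: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Classical fixed-step RK4 for dS/dt = source - rate(t)*S.

    Because the right-hand side is affine in S, each RK4 step reduces to
    S_{n+1} = alpha_n * S_n + beta_n with coefficients that depend only on
    rate() at the step endpoints and midpoint; we evaluate rate() for all
    steps at once and then run the scalar recurrence.  The arithmetic is
    identical to textbook RK4.
    """
    span = t1 - t0
    if span <= 0:
        return np.array([t0]), np.array([s0])
    n = max(1, int(math.ceil(span / max_step_h)))
    h = span / n
    nodes = t0 + h * np.arange(n + 1)
    mids = nodes[:-1] + h / 2.0
    r1 = rate(nodes[:-1])
    r2 = rate(mids)
    r3 = rate(nodes[1:])

    a = source
    # k_i = c_i + m_i * S  (affine in the state)
    c1 = np.full(n, a)
    m1 = -r1
    c2 = a - r2 * (h / 2.0) * c1
    m2 = -r2 * (1.0 + (h / 2.0) * m1)
    c3 = a - r2 * (h / 2.0) * c2
    m3 = -r2 * (1.0 + (h / 2.0) * m2)
    c4 = a - r3 * h * c3
    m4 = -r3 * (1.0 + h * m3)
    alpha = 1.0 + (h / 6.0) * (m1 + 2 * m2 + 2 * m3 + m4)
    beta = (h / 6.0) * (c1 + 2 * c2 + 2 * c3 + c4)

    s = np.empty(n + 1)
    s[0] = s0
    cur = s0
    for i in range(n):
        cur = alpha[i] * cur + beta[i]
        s[i + 1] = cur
    return nodes, s


def sensor_pool_trace(
    params: SensorKineticsParams,
    activity: Callable[[np.ndarray], np.ndarray] | np.ndarray,
    t_grid: Sequence[float] | np.ndarray,
    max_step_s: float = 1.0,
) -> np.ndarray:
    """Intact-sensor pool S(t) on ``t_grid`` (hours since administration).

    S starts at the pre-dose steady state k_syn/(k_deg + k_cl*a0) and follows
    dS/dt = k_syn - (k_deg + k_cl*a(t))*S, integrated by fixed-step RK4 with
    steps of at most ``max_step_s`` seconds.  ``activity`` is either a
    callable a(t) or an array aligned with ``t_grid`` (linearly interpolated
    between grid points).
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) == 0:
        raise ValueError("t_grid must be a non-empty 1-D array of hours")
    if np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    if callable(activity):
        a_fn = lambda t: np.asarray(activity(t), dtype=float)  # noqa: E731
    else:
        a_arr = np.asarray(activity, dtype=float)
        if a_arr.shape != t_grid.shape:
            raise ValueError("activity array must align with t_grid")
        a_fn = lambda t: np.interp(t, t_grid, a_arr)  # noqa: E731

    rate = lambda t: params.k_deg + params.k_cl * a_fn(t)  # noqa: E731
    s0 = params.steady_state
    nodes, s = _rk4_linear_decay(
        rate, params.k_syn, s0, float(t_grid[0]), float(t_grid[-1]), max_step_s / 3600.0
    )
    out = np.interp(t_grid, nodes, s)
    if np.any(out <= 0):
        raise PhotometryError("sensor pool went non-positive; check kinetic parameters")
    return out


def magnitude_for_delta_fret(
    params: SensorKineticsParams, target_delta_fret_pct: float
) -> float:
    """Inhibition magnitude whose *sustained* effect yields a target steady-state ΔFRET.

    Inverts S_ss(f)/S_ss(0) = (k_deg + k_cl*a0) / (k_deg + k_cl*a0*(1-f));
    with k_deg = 0 this reduces to f = d/(1+d) for ΔFRET_ss = 100*d.
    """
    d = target_delta_fret_pct / 100.0
    if d < 0:
        raise ValueError("target must be positive for an inhibitor")
    tot = params.k_deg + params.k_cl * params.a0
    f = tot * d / ((1.0 + d) * params.k_cl * params.a0)
    if not 0.0 <= f < 1.0:
        raise ValueError(
            f"target ΔFRET {target_delta_fret_pct}% is unreachable by inhibition "
            f"with these kinetics (requires f={f:.3f})"
        )
    return f


# ---------------------------------------------------------------------------
# frame rendering
# ---------------------------------------------------------------------------

def _session_led_pattern(schedule: SessionSchedule, fps: float) -> tuple[np.ndarray, np.ndarray]:
    """Frame times (s, from session start) and LED states for one session.

    Lead-in frames are all LED-off; during the interleaved window frames
    strictly alternate starting LED-off (the LED-state column, not parity,
    is authoritative downstream).
    """
    n_total = int(math.floor(schedule.session_s * fps))
    t = np.arange(n_total) / fps
    led = np.zeros(n_total, dtype=int)
    in_window = t >= schedule.off_lead_s
    idx = np.flatnonzero(in_window)
    led[idx] = np.arange(len(idx)) % 2  # off, on, off, on, ...
    return t, led


def render_session(
    params: SensorKineticsParams,
    s_window: float | np.ndarray | Callable[[np.ndarray], np.ndarray],
    schedule: SessionSchedule = SessionSchedule(),
    motion_artifact: np.ndarray | Callable[[np.ndarray], np.ndarray] | None = None,
    seed: int | np.random.Generator | None = None,
    initial_on_seconds: float = 0.0,
) -> pd.DataFrame:
    """Render one recording session as a frame table.

    ``s_window`` gives the intact-sensor pool during the session: a scalar,
    an array with one value per frame, or a callable of seconds-from-session-
    start.  LED-on frames read ``gain(t)*S(t) + ambient``, LED-off frames
    read ``ambient`` only; both receive the common-mode ``motion_artifact``
    (if any) and i.i.d. Gaussian noise.  The gain decays as
    ``gain * exp(-bleach_rate * cumulative_on_seconds)`` where exposure
    accumulates only while the LED is on (``initial_on_seconds`` carries
    exposure from earlier sessions of the same day).

    Returns a DataFrame with columns FrameCounter, Timestamp, LedState, Region0.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t, led = _session_led_pattern(schedule, params.fps)
    n = len(t)

    if callable(s_window):
        s = np.asarray(s_window(t), dtype=float)
    else:
        s = np.broadcast_to(np.asarray(s_window, dtype=float), (n,)).astype(float)
    if s.shape != (n,):
        raise ValueError(f"s_window must broadcast to {n} frames")

    # LED-on exposure accrued *before* each frame
    frame_dt = 1.0 / params.fps
    on_before = initial_on_seconds + frame_dt * (np.cumsum(led) - led)
    gain_t = params.gain * np.exp(-params.bleach_rate * on_before)

    intensity = params.ambient + led * gain_t * s
    if motion_artifact is not None:
        art = motion_artifact(t) if callable(motion_artifact) else np.asarray(motion_artifact)
        intensity = intensity + np.broadcast_to(art, (n,))
    if params.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, params.noise_sd, size=n)

    return pd.DataFrame(
        {
            "FrameCounter": np.arange(n, dtype=int),
            "Timestamp": t,
            "LedState": led,
            "Region0": intensity,
        }
    )


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

@dataclass
class CohortSimulation:
    """In-memory result of ``simulate_cohort``.

    ``manifest`` is the session-metadata dict (what the JSON manifest file
    contains); ``recordings`` maps each session's file name to its frame
    table.  When written to disk these become the exact inputs the reader
    side of the pipeline consumes.
    """

    manifest: dict
    recordings: dict[str, pd.DataFrame]
    animal_params: pd.DataFrame = field(repr=False, default=None)

    def to_manifest(self):
        """The simulated sessions as an in-memory :class:`~photofret.io.ExperimentManifest`
        (pair with ``recordings=`` in :func:`photofret.fret.process_experiment`)."""
        from .io import ExperimentManifest, SessionMeta

        return ExperimentManifest(
            sessions=[SessionMeta(**s) for s in self.manifest["sessions"]],
            washout_hours=self.manifest.get("washout_hours"),
        )

    def write(self, out_dir: str | Path, file_format: str = "csv", overwrite: bool = False) -> Path:
        """Write recordings plus ``manifest.json`` under ``out_dir``; returns the manifest path."""
        from .io import write_recording  # local import to avoid a cycle

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        manifest = {**self.manifest, "sessions": []}
        for name, frames in self.recordings.items():
            fname = str(Path(name).with_suffix(f".{file_format}"))
            target = out / fname
            if target.exists() and not overwrite:
                raise FileExistsError(f"refusing to overwrite existing {target}")
            write_recording(frames, target)
        for sess in self.manifest["sessions"]:
            sess = {**sess, "file": str(Path(sess["file"]).with_suffix(f".{file_format}"))}
            manifest["sessions"].append(sess)
        mpath = out / "manifest.json"
        if mpath.exists() and not overwrite:
            raise FileExistsError(f"refusing to overwrite existing {mpath}")
        mpath.write_text(json.dumps(manifest, indent=2) + "\n")
        return mpath


def _latin_square_orders(n_animals: int, n_treatments: int, latin: bool) -> list[list[int]]:
    if not latin:
        return [list(range(n_treatments)) for _ in range(n_animals)]
    # cyclic Latin square, rows recycled if there are more animals than treatments
    return [[(i + j) % n_treatments for j in range(n_treatments)] for i in range(n_animals)]


def simulate_cohort(
    spec: SimulatedCohortSpec,
    params: SensorKineticsParams = SensorKineticsParams(),
    schedule: SessionSchedule = SessionSchedule(),
    washout_hours: float = 24.0,
) -> CohortSimulation:
    """Simulate a full experiment: every animal receives every treatment on its
    own recording day (order balanced by a cyclic Latin square), with sessions
    at the scheduled hours; each day starts from the pre-dose steady state
    (washout >= 24 h and continuous synthesis reset both the sensor pool and
    the bleached fluorophore population).

    Per-animal lognormal multipliers on k_syn and gain model viral-expression
    variability.  The intact-pool ODE is linear in k_syn, so each treatment's
    trajectory is solved once at unit synthesis and scaled exactly per animal.

    Deterministic: a fixed ``spec.seed`` reproduces every frame byte-for-byte.
    """
    rng = np.random.default_rng(spec.seed)
    n_a, n_t = spec.n_animals, len(spec.treatments)
    genotypes = spec.genotypes or tuple("WT" for _ in range(n_a))

    # lognormal multipliers with unit mean and the requested CoV
    if spec.jitter_cv > 0:
        sigma = math.sqrt(math.log(1.0 + spec.jitter_cv**2))
        mu = -0.5 * sigma**2
        ksyn_mult = rng.lognormal(mu, sigma, size=n_a)
        gain_mult = rng.lognormal(mu, sigma, size=n_a)
    else:
        ksyn_mult = np.ones(n_a)
        gain_mult = np.ones(n_a)

    # one unit-synthesis solve per treatment profile
    sess_h = schedule.session_s / 3600.0
    t_end = schedule.hours[-1] + sess_h
    unit = replace(params, k_syn=1.0)
    dense: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for arm in spec.treatments:
        a_fn = lambda t, p=arm.profile: activity_trace(p, params.a0, np.atleast_1d(t))
        rate = lambda t, f=a_fn: params.k_deg + params.k_cl * f(t)
        nodes, s = _rk4_linear_decay(rate, 1.0, unit.steady_state, 0.0, t_end, 1.0 / 3600.0)
        dense[arm.label] = (nodes, s)

    orders = _latin_square_orders(n_a, n_t, spec.latin_square)
    sessions: list[dict] = []
    recordings: dict[str, pd.DataFrame] = {}
    for i in range(n_a):
        animal = f"m{i + 1:02d}"
        p_i = replace(
            params,
            k_syn=params.k_syn * ksyn_mult[i],
            gain=params.gain * gain_mult[i],
        )
        for day, arm_idx in enumerate(orders[i], start=1):
            arm = spec.treatments[arm_idx]
            nodes, s_unit = dense[arm.label]
            exposure = 0.0
            for hour in schedule.hours:
                if hour == 0.0:
                    s_of_t = p_i.steady_state  # pre-dose: at steady state
                else:
                    def s_of_t(ts, h=hour):
                        return p_i.k_syn * np.interp(h + ts / 3600.0, nodes, s_unit)
                frames = render_session(
                    p_i, s_of_t, schedule, seed=rng, initial_on_seconds=exposure
                )
                exposure += float(frames["LedState"].sum()) / p_i.fps
                fname = f"{animal}_{_slug(arm.label)}_h{int(hour)}.csv"
                recordings[fname] = frames
                sessions.append(
                    {
                        "file": fname,
                        "animal_id": animal,
                        "genotype": genotypes[i],
                        "treatment": arm.label,
                        "dose": arm.dose,
                        "route": arm.route,
                        "hour": float(hour),
                        "day": day,
                    }
                )

    manifest = {"washout_hours": float(washout_hours), "sessions": sessions}
    animal_params = pd.DataFrame(
        {
            "animal_id": [f"m{i + 1:02d}" for i in range(n_a)],
            "genotype": genotypes,
            "k_syn": params.k_syn * ksyn_mult,
            "gain": params.gain * gain_mult,
        }
    )
    return CohortSimulation(manifest=manifest, recordings=recordings, animal_params=animal_params)


def _slug(label: str) -> str:
    return "".join(c if c.isalnum() else "-" for c in label.strip().lower()).strip("-")
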