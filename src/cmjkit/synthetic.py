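"""Synthetic countermovement-jump force traces with known ground truth.

The generator works in velocity space: the center-of-mass vertical velocity
is built as a clamped cubic Hermite spline satisfying the jump's endpoint
constraints — v = 0 at movement onset, a single downward minimum of the
requested magnitude, an upward zero crossing exactly at the end of the
eccentric phase, and the requested take-off velocity with slope -g at
take-off (the plate force reaches zero there).  Force follows from Newton,
F = m (g + dv/dt), which guarantees that analyzing a noise-free synthetic
trial with the kinematics module recovers the generating velocity exactly
(up to discretization).  Quiet standing, flight (duration 2 v_to / g) and a
landing transient complete the trial.

Fatigue is emulated two ways, matching how high-intensity sprint exercise
shows up in real jump data: parameter scaling (shorter eccentric / longer
concentric phase, lower take-off velocity) and a multiplicative force deficit
confined to a normalized-time window (default 50-75%, the early concentric
region), applied with cosine-tapered edges so the force stays continuous.

Cohorts draw lognormal between- and within-subject multipliers on the
duration and velocity parameters (positivity-preserving) and are bit-identical
under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace


import numpy as np
import pandas as pd
from scipy.interpolate import CubicHermiteSpline

from .constants import CONDITIONS, GRAVITY
from .errors import InfeasibleProfileError
from .kinematics import KinematicSeries
from .trial_io import ForceTrial

__all__ = [
    "JumpProfileParams",
    "FatigueEffect",
    "CohortSpec",
    "simulate_velocity_profile",
    "velocity_to_force",
    "simulate_trial",
    "simulate_cohort",
    "default_fatigue_effects",
    "DEFAULT_RPE_MEANS",
]

#: Fraction of the eccentric phase at which the downward velocity bottoms out
#: (unweighting is longer than braking in a real jump).
_VMIN_FRACTION = 0.70
#: Mid-unweighting slope, as a multiple of peak_downward_velocity / t_min.
_MID_SLOPE_GAIN = 1.35
#: Peak interior slope of the unweighting spline, as a multiple of
#: peak_downward_velocity / t_min (analytic maximum of the Hermite pieces).
_UNWEIGHT_SLOPE_PEAK = 1.50
#: Multiplier on the mean braking slope used for the zero-crossing slope.
_BRAKING_SLOPE_GAIN = 1.3
#: Safety margin on the free-fall feasibility ceiling for vmin.
_VMIN_SAFETY = 0.95


def feasible_downward_velocity_limit(ecc_duration: float, g: float = GRAVITY) -> float:
    """Largest peak downward velocity reachable in ``ecc_duration`` without
    the plate force going negative (the COM cannot out-accelerate free fall).
    """
    t_min = _VMIN_FRACTION * ecc_duration
    return _VMIN_SAFETY * g * t_min / _UNWEIGHT_SLOPE_PEAK


@dataclass(frozen=True)
class JumpProfileParams:
    """Generating parameters of one jump waveform.

    Defaults describe a strong male sprint athlete's baseline jump:
    ~0.35 s eccentric / ~0.25 s concentric phase, 1.35 m/s peak downward
    velocity and 3.08 m/s take-off velocity (~49 cm jump height).
    """

    body_mass: float = 70.0  # kg
    quiet_duration: float = 1.5  # s of quiet standing before onset
    ecc_duration: float = 0.35  # s
    con_duration: float = 0.25  # s
    peak_downward_velocity: float = 1.35  # m/s (magnitude)
    takeoff_velocity: float = 3.08  # m/s
    concentric_shape: float = 0.97  # where peak velocity sits in the phase
    noise_sd: float = 5.0  # N, additive white force-plate noise
    sampling_rate: float = 1000.0  # Hz

    def __post_init__(self) -> None:
        positive = (
            "body_mass",
            "quiet_duration",
            "ecc_duration",
            "con_duration",
            "peak_downward_velocity",
            "takeoff_velocity",
            "sampling_rate",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.5 < self.concentric_shape < 1.0:
            raise ValueError("concentric_shape must lie in (0.5, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class FatigueEffect:
    """Condition-level modification applied to a baseline jump profile.

    ``con_force_reduction`` is the fractional force deficit applied over
    ``window`` (percent of normalized jump time, eccentric = 0-50%,
    concentric = 50-100%); the duration/velocity scales multiply the
    corresponding profile parameters.
    """

    con_force_reduction: float = 0.0
    window: tuple[float, float] = (50.0, 75.0)
    ecc_duration_scale: float = 1.0
    con_duration_scale: float = 1.0
    takeoff_velocity_scale: float = 1.0
    downward_velocity_scale: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.con_force_reduction < 1:
            raise ValueError("con_force_reduction must lie in [0, 1)")
        w0, w1 = self.window
        if not (0 <= w0 < w1 <= 100):
            raise ValueError("window must satisfy 0 <= start < end <= 100")
        for name in (
            "ecc_duration_scale",
            "con_duration_scale",
            "takeoff_velocity_scale",
            "downward_velocity_scale",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def is_identity(self) -> bool:
        return (
            self.con_force_reduction == 0
            and self.ecc_duration_scale == 1
            and self.con_duration_scale == 1
            and self.takeoff_velocity_scale == 1
            and self.downward_velocity_scale == 1
        )

    def apply(self, params: JumpProfileParams) -> JumpProfileParams:
        return replace(
            params,
            ecc_duration=params.ecc_duration * self.ecc_duration_scale,
            con_duration=params.con_duration * self.con_duration_scale,
            takeoff_velocity=params.takeoff_velocity * self.takeoff_velocity_scale,
            peak_downward_velocity=(
                params.peak_downward_velocity * self.downward_velocity_scale
            ),
        )


#: Lognormal sigma of the between-subject multipliers (per parameter).
DEFAULT_BETWEEN_SUBJECT_SD = {
    "ecc_duration": 0.13,
    "con_duration": 0.14,
    "peak_downward_velocity": 0.12,  # residual, on top of the duration coupling
    "takeoff_velocity": 0.055,
}
#: Lognormal sigma of the trial-to-trial (within-subject) multipliers.
DEFAULT_WITHIN_SUBJECT_SD = {
    "ecc_duration": 0.04,
    "con_duration": 0.04,
    "peak_downward_velocity": 0.04,
    "takeoff_velocity": 0.015,
}

#: Coupling of the downward-velocity multiplier to the eccentric-duration
#: multiplier: deeper (longer) countermovements descend faster.  Keeps random
#: profiles clear of the free-fall feasibility ceiling.
_VMIN_DURATION_COUPLING = 0.6

#: Session-level perceived-exertion means (Borg 6-20) used for synthetic RPE.
DEFAULT_RPE_MEANS = {
    "baseline": 10.4,
    "3min": 18.8,
    "10min": 16.6,
    "1hr": 11.0,
    "24hr": 9.2,
}


@dataclass(frozen=True)
class CohortSpec:
    """Design of a whole synthetic study."""

    n_participants: int = 10
    conditions: tuple[str, ...] = CONDITIONS
    trials_per_session: int = 3
    between_subject_sd: dict = field(
        default_factory=lambda: dict(DEFAULT_BETWEEN_SUBJECT_SD)
    )
    within_subject_sd: dict = field(
        default_factory=lambda: dict(DEFAULT_WITHIN_SUBJECT_SD)
    )
    body_mass_sd: float = 7.0  # kg, normal between-subject spread
    rpe_sd: float = 1.2  # session-level RPE noise (Borg units)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("n_participants must be >= 2")
        if self.trials_per_session < 1:
            raise ValueError("trials_per_session must be >= 1")
        if len(self.conditions) < 2:
            raise ValueError("need at least two conditions")


def _snap_durations_to_grid(params: JumpProfileParams) -> JumpProfileParams:
    """Round the phase durations to whole sample intervals so the take-off
    instant falls exactly on the sampling grid (the emitted force reaches
    zero on the final movement sample)."""
    dt = 1.0 / params.sampling_rate
    te = max(round(params.ecc_duration / dt), 2) * dt
    tc = max(round(params.con_duration / dt), 2) * dt
    if te == params.ecc_duration and tc == params.con_duration:
        return params
    return replace(params, ecc_duration=te, con_duration=tc)


def _velocity_spline(params: JumpProfileParams, g: float) -> CubicHermiteSpline:
    te, tc = params.ecc_duration, params.con_duration
    vmin, vto = params.peak_downward_velocity, params.takeoff_velocity
    t_total = te + tc
    t_min = _VMIN_FRACTION * te
    s_mid = -_MID_SLOPE_GAIN * vmin / t_min
    s_braking = _BRAKING_SLOPE_GAIN * vmin / ((1.0 - _VMIN_FRACTION) * te)
    t_pk = te + params.concentric_shape * tc
    tau = t_total - t_pk
    v_pk = vto + 0.5 * g * tau  # linear force decay to zero at take-off
    knots_t = np.array([0.0, 0.5 * t_min, t_min, te, t_pk, t_total])
    knots_v = np.array([0.0, -0.55 * vmin, -vmin, 0.0, v_pk, vto])
    knots_dv = np.array([0.0, s_mid, 0.0, s_braking, 0.0, -g])
    if np.any(np.diff(knots_t) <= 0):
        raise InfeasibleProfileError("degenerate knot spacing in jump profile")
    return CubicHermiteSpline(knots_t, knots_v, knots_dv)


def simulate_velocity_profile(
    params: JumpProfileParams, *, g: float = GRAVITY
) -> KinematicSeries:
    """Construct the movement-phase COM kinematics for one jump.

    The returned series spans onset (t = 0, v = 0) to take-off
    (t = ecc_duration + con_duration, v = takeoff_velocity); acceleration and
    displacement are the exact spline derivative/antiderivative, so the three
    arrays are mutually consistent by construction.

    Raises
    ------
    InfeasibleProfileError
        If the parameter combination implies negative plate force
        (dv/dt < -g) or a velocity shape without exactly one downward
        minimum and one upward zero crossing.
    """
    params = _snap_durations_to_grid(params)
    spl = _velocity_spline(params, g)
    t_total = params.ecc_duration + params.con_duration
    n = int(round(t_total * params.sampling_rate)) + 1
    if n < 20:
        raise InfeasibleProfileError("durations too short for the sampling rate")
    t = np.arange(n) / params.sampling_rate
    v = spl(t)
    a = spl.derivative()(t)
    s = spl.antiderivative()(t)

    if np.min(a) < -g - 1e-6:
        raise InfeasibleProfileError(
            "profile too violent: implied plate force is negative"
        )
    i_min = int(np.argmin(v))
    after = v[i_min:]
    crossings = np.sum((after[:-1] < 0) & (after[1:] >= 0))
    if v[i_min] >= 0 or crossings != 1:
        raise InfeasibleProfileError(
            "velocity profile lacks a single minimum / upward zero crossing"
        )

    power = (a + g) * v
    return KinematicSeries(
        net_acceleration=a,
        velocity=v,
        displacement=s,
        power=power,
        sampling_rate=params.sampling_rate,
        onset_index=0,
    )


def _fatigue_force_weight(
    n_move: int, te: float, tc: float, rate: float, window: tuple[float, float]
) -> np.ndarray:
    """Per-sample weight in [0, 1] of the force deficit: 1 inside the
    normalized-time window, cosine-tapered edges (2.5% width), 0 outside."""
    t = np.arange(n_move) / rate
    q = np.where(t < te, 50.0 * t / te, 50.0 + 50.0 * (t - te) / tc)
    w0, w1 = window
    edge = 2.5
    w = np.zeros(n_move)
    core = (q >= w0 + edge) & (q <= w1 - edge)
    w[core] = 1.0
    rise = (q >= w0) & (q < w0 + edge)
    w[rise] = 0.5 * (1 - np.cos(np.pi * (q[rise] - w0) / edge))
    fall = (q > w1 - edge) & (q <= w1)
    w[fall] = 0.5 * (1 - np.cos(np.pi * (w1 - q[fall]) / edge))
    return w


def velocity_to_force(
    kin: KinematicSeries,
    body_mass: float,
    quiet_duration: float,
    noise_sd: float = 0.0,
    *,
    g: float = GRAVITY,
    rng: np.random.Generator | None = None,
    landing: bool = True,
    force_deficit: float = 0.0,
    deficit_window: tuple[float, float] = (50.0, 75.0),
    ecc_duration: float | None = None,
    participant_id: str = "",
    condition: str = "",
    trial_index: int = 0,
) -> tuple[ForceTrial, dict]:
    """Assemble a full force trial around movement-phase kinematics.

    Prepends quiet standing at body weight, converts the movement
    acceleration to plate force F = m (g + a), optionally applies the
    windowed fatigue force deficit, then appends a flight phase of duration
    2 v_to / g (v_to re-measured from the possibly modified force by
    integration) and a landing transient.

    Returns the trial plus a ground-truth dict (realized take-off velocity,
    true jump height, onset time, phase durations).
    """
    rate = kin.sampling_rate
    dt = 1.0 / rate
    f_move = body_mass * (kin.net_acceleration + g)
    if np.min(f_move) < -1e-6:
        raise InfeasibleProfileError("implied negative force in movement phase")
    f_move = np.maximum(f_move, 0.0)

    n_move = f_move.size
    te = ecc_duration if ecc_duration is not None else _infer_te(kin)
    tc = (n_move - 1) * dt - te
    if force_deficit > 0:
        w = _fatigue_force_weight(n_move, te, tc, rate, deficit_window)
        f_move = f_move * (1.0 - force_deficit * w)

    # realized velocity from the (possibly modified) force
    a_real = f_move / body_mass - g
    v_real = np.concatenate(([0.0], np.cumsum(0.5 * (a_real[1:] + a_real[:-1]) * dt)))
    v_to = float(v_real[-1])
    v_peak = float(np.max(v_real))
    if v_to < 0 or (v_to == 0 and force_deficit > 0):
        raise InfeasibleProfileError("force deficit removed all upward momentum")

    n_quiet = int(round(quiet_duration * rate))
    flight_time = 2.0 * v_to / g
    n_flight = int(round(flight_time * rate))
    parts = [np.full(n_quiet, body_mass * g), f_move, np.zeros(n_flight)]
    if landing:
        n_land = int(round(0.15 * rate))
        bump = 2.5 * body_mass * g * np.sin(np.linspace(0, np.pi, n_land))
        parts += [bump, np.full(int(round(0.25 * rate)), body_mass * g)]
    force = np.concatenate(parts)
    if noise_sd > 0:
        rng = rng if rng is not None else np.random.default_rng()
        force = force + rng.normal(0.0, noise_sd, force.size)
    force = np.maximum(force, 0.0)

    trial = ForceTrial(
        force=force,
        sampling_rate=rate,
        body_mass=body_mass,
        participant_id=participant_id,
        condition=condition,
        trial_index=trial_index,
    )
    truth = {
        "onset_time": n_quiet * dt,
        "ecc_duration": te,
        "con_duration": tc,
        "takeoff_velocity": v_to,
        "peak_velocity": v_peak,
        "jump_height_cm": v_peak**2 / (2 * g) * 100.0,
        "peak_downward_velocity": float(-np.min(v_real)),
    }
    return trial, truth


def _infer_te(kin: KinematicSeries) -> float:
    """Eccentric duration of a movement-phase series: first upward zero
    crossing of velocity after its minimum."""
    v = kin.velocity
    i_min = int(np.argmin(v))
    rel = np.flatnonzero(v[i_min:] >= 0)
    if rel.size == 0:
        raise InfeasibleProfileError("no upward zero crossing in velocity")
    return (i_min + rel[0]) / kin.sampling_rate


def simulate_trial(
    params: JumpProfileParams,
    effect: FatigueEffect | None = None,
    *,
    g: float = GRAVITY,
    rng: np.random.Generator | None = None,
    landing: bool = True,
    participant_id: str = "",
    condition: str = "",
    trial_index: int = 0,
) -> tuple[ForceTrial, dict]:
    """One complete synthetic trial: parameters (+ optional fatigue effect)
    -> velocity profile -> force trace with quiet standing, flight, landing."""
    eff = effect or FatigueEffect()
    p = _snap_durations_to_grid(eff.apply(params))
    vmin_cap = feasible_downward_velocity_limit(p.ecc_duration, g)
    if p.peak_downward_velocity > vmin_cap:
        p = replace(p, peak_downward_velocity=vmin_cap)
    kin = simulate_velocity_profile(p, g=g)
    return velocity_to_force(
        kin,
        p.body_mass,
        p.quiet_duration,
        p.noise_sd,
        g=g,
        rng=rng,
        landing=landing,
        force_deficit=eff.con_force_reduction,
        deficit_window=eff.window,
        ecc_duration=p.ecc_duration,
        participant_id=participant_id,
        condition=condition,
        trial_index=trial_index,
    )


def default_fatigue_effects() -> dict[str, FatigueEffect]:
    """Per-condition effects emulating the recovery time course after a
    400 m sprint: a large deficit at 3 min that resolves over 24 h in the
    eccentric-phase parameters but persists in early-concentric force."""
    return {
        # takeoff_velocity_scale is set so that the *realized* take-off
        # velocity (after the windowed force deficit spends part of the
        # concentric impulse) lands near the intended recovery time course
        "3min": FatigueEffect(
            con_force_reduction=0.15,
            ecc_duration_scale=0.94,
            con_duration_scale=1.12,
            takeoff_velocity_scale=0.98,
            downward_velocity_scale=0.86,
        ),
        "10min": FatigueEffect(
            con_force_reduction=0.08,
            ecc_duration_scale=0.91,
            con_duration_scale=1.04,
            takeoff_velocity_scale=0.99,
            downward_velocity_scale=0.95,
        ),
        "1hr": FatigueEffect(
            con_force_reduction=0.05,
            ecc_duration_scale=0.97,
            con_duration_scale=1.08,
            takeoff_velocity_scale=1.0,
            downward_velocity_scale=0.97,
        ),
        "24hr": FatigueEffect(
            con_force_reduction=0.04,
            ecc_duration_scale=0.97,
            con_duration_scale=1.08,
            takeoff_velocity_scale=1.0,
            downward_velocity_scale=1.0,
        ),
    }


def _draw_multipliers(
    rng: np.random.Generator, sds: dict[str, float]
) -> dict[str, float]:
    # lognormal with unit median keeps every parameter positive
    m = {k: float(np.exp(rng.normal(0.0, sd))) for k, sd in sds.items()}
    if "peak_downward_velocity" in m and "ecc_duration" in m:
        m["peak_downward_velocity"] *= m["ecc_duration"] ** _VMIN_DURATION_COUPLING
    return m


def simulate_cohort(
    spec: CohortSpec,
    baseline: JumpProfileParams | None = None,
    effects: dict[str, FatigueEffect] | None = None,
    *,
    g: float = GRAVITY,
    rpe_means: dict[str, float] | None = None,
) -> tuple[list[ForceTrial], pd.DataFrame]:
    """Generate a whole study: n_participants x conditions x trials.

    Returns the trials plus a ground-truth table with one row per trial
    (generating parameters, realized take-off velocity and jump height, and
    the session RPE).  Bit-identical under a fixed ``spec.seed``.
    """
    baseline = baseline or JumpProfileParams()
    if effects is None:
        effects = {
            c: e
            for c, e in default_fatigue_effects().items()
            if c in spec.conditions
        }
    missing = [c for c in spec.conditions if c != "baseline" and c not in effects]
    if missing:
        raise ValueError(f"no FatigueEffect given for conditions: {missing}")
    rpe_means = rpe_means or DEFAULT_RPE_MEANS

    rng = np.random.default_rng(spec.seed)
    trials: list[ForceTrial] = []
    truth_rows: list[dict] = []
    for i in range(spec.n_participants):
        pid = f"P{i + 1:02d}"
        between = _draw_multipliers(rng, spec.between_subject_sd)
        mass = float(
            np.clip(rng.normal(baseline.body_mass, spec.body_mass_sd), 50.0, 110.0)
        )
        subject_params = replace(
            baseline,
            body_mass=mass,
            ecc_duration=baseline.ecc_duration * between["ecc_duration"],
            con_duration=baseline.con_duration * between["con_duration"],
            peak_downward_velocity=(
                baseline.peak_downward_velocity * between["peak_downward_velocity"]
            ),
            takeoff_velocity=baseline.takeoff_velocity * between["takeoff_velocity"],
        )
        for cond in spec.conditions:
            eff = effects.get(cond) if cond != "baseline" else None
            rpe_mu = rpe_means.get(cond, 10.0)
            rpe = float(np.clip(round(rng.normal(rpe_mu, spec.rpe_sd)), 6, 20))
            for j in range(spec.trials_per_session):
                within = _draw_multipliers(rng, spec.within_subject_sd)
                p = replace(
                    subject_params,
                    ecc_duration=subject_params.ecc_duration
                    * within["ecc_duration"],
                    con_duration=subject_params.con_duration
                    * within["con_duration"],
                    peak_downward_velocity=subject_params.peak_downward_velocity
                    * within["peak_downward_velocity"],
                    takeoff_velocity=subject_params.takeoff_velocity
                    * within["takeoff_velocity"],
                )
                trial, truth = simulate_trial(
                    p,
                    eff,
                    g=g,
                    rng=rng,
                    participant_id=pid,
                    condition=cond,
                    trial_index=j + 1,
                )
                truth_rows.append(
                    {
                        "participant": pid,
                        "condition": cond,
                        "trial": j + 1,
                        "body_mass": mass,
                        "rpe": rpe,
                        **truth,
                        "planned_takeoff_velocity": p.takeoff_velocity
                        * (eff.takeoff_velocity_scale if eff else 1.0),
                    }
                )
                trials.append(trial)
    return trials, pd.DataFrame(truth_rows)
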